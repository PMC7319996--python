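"""Estimate cell-type fractions of simulated bulk mixtures.

Builds a six-cell-type reference with planted marker genes, constructs a
signature matrix by the condition-number sweep, simulates 100 bulk
mixtures with known fractions, and deconvolves them. The mean absolute
error (MAE) says how far the estimated fractions are, on average, from
the simulated truth on the 0-1 fraction scale.
"""

import numpy as np

import tissuedecoder as td

cfg = td.SimulationConfig(
    n_features=300, n_types=6, markers_per_type=10, marker_effect=8.0,
    replicates_per_type=5, noise_cv=0.05, dirichlet_alpha=np.ones(6),
    n_mixtures=100, seed=1,
)
ref, _ = td.simulate_reference(cfg)
sig = td.build_signature(ref, g_min=5, g_max=15)
print(f"signature: {sig.values.shape[0]} features x {len(sig.cell_types)} "
      f"cell types, condition number kappa = {sig.condition_number:.3f} "
      f"at G = {sig.per_type_set_size} markers/type")

mixtures, truth = td.simulate_mixtures(td.type_profiles(ref), cfg)
estimates = td.deconvolve_dataset(mixtures, sig)
frame = td.fractions_frame(estimates)[list(truth.columns)]

mae = np.abs(frame.to_numpy() - truth.to_numpy()).mean(axis=0)
print("\nper-type mean absolute error (fractions, 0-1 scale):")
for t, e in zip(truth.columns, mae):
    print(f"  {t}: {e:.4f}")
print(f"overall MAE: {mae.mean():.4f}  "
      "(well under 0.05 means near-perfect recovery at 5% noise)")

# positive control: a reference sample deconvolved against the signature
# should land almost entirely on its own cell type
own = td.deconvolve_sample(sig.values.iloc[:, 0], sig)
top = max(own.fractions, key=own.fractions.get)
print(f"\npure '{top}' profile -> fraction {own.fractions[top]:.3f} "
      f"for {top} (rest {1 - own.fractions[top]:.3f})")
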