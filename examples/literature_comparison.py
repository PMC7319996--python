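"""Convert literature cell counts to percent of total cells and compare.

Published adipose-tissue cell counts come in incompatible units (percent
of the stromal vascular fraction, counts per gram, per 100 adipocytes,
per total nuclei...). Under two explicit assumptions — the adipocyte
fraction of total cells and the total cells per gram — every convertible
unit maps linearly onto percent of total cells, so studies and
deconvolution estimates can sit on one axis. Counts per high-power field
or per mm^2 depend on section geometry and are excluded.
"""

import numpy as np

import tissuedecoder as td

assumptions = td.ConversionAssumptions(adipocyte_fraction=0.74,
                                       cells_per_gram=2.0e7)
records = [
    td.LiteratureRecord("study_a", "macrophage", "percent_svf",
                        mean=10.0, min=5.0, max=20.0),
    td.LiteratureRecord("study_b", "macrophage", "per_gram",
                        mean=4.0e5, min=1.0e5, max=8.0e5),
    td.LiteratureRecord("study_c", "macrophage", "per_100_adipocytes",
                        mean=3.0),
    td.LiteratureRecord("study_d", "macrophage", "per_mm2", mean=12.0),
]
table = td.convert_records(records, assumptions)
print("literature records in percent of total cells:")
print(table[["study_id", "unit", "status", "percent_total_mean"]]
      .to_string(index=False))

# fake deconvolution estimates for 20 samples: ~2% macrophages
rng = np.random.default_rng(3)
estimates = []
for i in range(20):
    m = float(rng.uniform(0.005, 0.04))
    estimates.append(td.FractionEstimate(
        f"s{i}", {"macrophage": m, "rest": 1 - m}, 0.5, 0.0, 1.0))

summary = td.summarize_vs_estimates(records, estimates, "macrophage",
                                    assumptions)
print("\nliterature vs deconvolution estimates (percent of total cells):")
print(summary[["study_id", "literature_mean", "estimate_mean",
               "estimate_median"]].round(2).to_string(index=False))
print("\n(the excluded per-mm2 study does not appear: no defensible "
      "conversion exists for section-based counts)")
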