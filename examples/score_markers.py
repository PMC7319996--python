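"""Score cell-type marker genes with the primary/secondary criteria.

The primary criterion (own-type mean minus the largest other-type mean)
finds genes exclusive to one cell type; the secondary criterion (own-type
mean minus the average of the others) finds enriched genes that may be
shared. Merging related cell types — here two adipocyte depots — shows how
a pan-adipocyte gene's primary score recovers once the depot-vs-depot
comparison is removed.
"""

import numpy as np
import pandas as pd

import tissuedecoder as td

rng = np.random.default_rng(0)
grid = np.abs(rng.normal(10, 0.5, size=(30, 8)))
grid[0, 0:4] = 200.0   # pan-adipocyte gene, high in both depots
grid[1, 0:2] = 150.0   # subcutaneous-only gene
labels = (["sat_adipocyte"] * 2 + ["pat_adipocyte"] * 2
          + ["immune"] * 2 + ["endothelial"] * 2)
df = pd.DataFrame(grid, index=[f"g{i}" for i in range(30)],
                  columns=[f"s{j}" for j in range(8)])
ref = td.ReferenceSet(matrix=td.ExpressionMatrix(df),
                      labels={f"s{j}": labels[j] for j in range(8)})

profiles = td.mean_profiles(ref)
prim = td.primary_criterion(profiles)
seco = td.secondary_criterion(profiles)

print("top 3 subcutaneous-adipocyte markers (primary criterion):")
print(td.rank_markers(prim, "sat_adipocyte", top_n=3)
      [["feature_id", "score", "negative"]].to_string(index=False))
print("\ng0 primary score for sat_adipocyte "
      f"(penalized by the other depot): {prim.loc['g0', 'sat_adipocyte']:.1f}")

merged = td.merge_groups(ref, {
    "sat_adipocyte": "adipocyte", "pat_adipocyte": "adipocyte",
    "immune": "immune", "endothelial": "endothelial",
})
prim_merged = td.primary_criterion(td.mean_profiles(merged))
print(f"g0 primary score after merging depots into 'adipocyte': "
      f"{prim_merged.loc['g0', 'adipocyte']:.1f}")
print("(positive now: the gene is exclusive to adipocytes as a group)")

# sanity identities that always hold
assert (prim.to_numpy() <= seco.to_numpy() + 1e-9).all()
assert np.abs(seco.sum(axis=1)).max() < 1e-9
print("\ninvariants hold: primary <= secondary; secondary rows sum to 0")
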