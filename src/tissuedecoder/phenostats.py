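"""Nonparametric association of cell fractions with phenotypes.

Cell-type fractions live on [0, 1] and are typically skewed, so group
comparisons use rank tests: Wilcoxon signed rank for paired designs
(interventions, twin pairs), Wilcoxon rank sum for independent groups, and
a permutation test on the Spearman correlation for continuous covariates
(age, BMI). P-values across the whole cell-type x trait grid are adjusted
jointly with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expr_io import PhenotypeTable

__all__ = [
    "AssociationResult",
    "paired_test",
    "unpaired_test",
    "spearman_perm",
    "adjust_bh",
    "group_z_score",
    "associate",
]


@dataclass
class AssociationResult:
    """One (cell type, trait) association."""

    cell_type: str
    trait: str
    test: str  # signed_rank | rank_sum | spearman_perm
    statistic: float
    effect: float  # median paired diff, median group diff, or Spearman rho
    p: float
    p_adj: float | None = None
    z_score: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.p <= 1):
            raise ValueError(f"p-value out of (0, 1]: {self.p}")


def group_z_score(x: np.ndarray, y: np.ndarray) -> float:
    """Standardized group separation: mean difference over pooled SD.

    Expresses how many standard deviations of the fraction's spread
    (both groups pooled) separate the two group means.
    """
    pooled = np.concatenate([x, y])
    sd = pooled.std(ddof=1)
    if sd == 0:
        return 0.0
    return float((x.mean() - y.mean()) / sd)


def paired_test(
    x: np.ndarray | pd.Series,
    y: np.ndarray | pd.Series,
    cell_type: str = "",
    trait: str = "",
) -> AssociationResult:
    """Two-sided Wilcoxon signed-rank test on paired fraction vectors.

    Zero differences are dropped (signed-rank convention). The p-value is
    exact for n <= 25 without ties among the |differences|, and uses the
    normal approximation with continuity correction otherwise. Effect is
    the median paired difference; all differences zero gives p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    d = x - y
    nz = d[d != 0]
    if nz.size == 0:
        return AssociationResult(cell_type, trait, "signed_rank", 0.0, 0.0, 1.0,
                                 z_score=group_z_score(x, y))
    if nz.size < 3:
        raise ValueError("need >= 3 nonzero differences for the signed-rank test")
    ties = np.unique(np.abs(nz)).size < nz.size
    method = "exact" if (nz.size <= 25 and not ties) else "approx"
    res = stats.wilcoxon(x, y, zero_method="wilcox",
                         correction=(method == "approx"), method=method)
    return AssociationResult(
        cell_type, trait, "signed_rank",
        statistic=float(res.statistic),
        effect=float(np.median(d)),
        p=float(min(res.pvalue, 1.0)) if res.pvalue > 0 else np.nextafter(0, 1),
        z_score=group_z_score(x, y),
    )


def unpaired_test(
    x: np.ndarray | pd.Series,
    y: np.ndarray | pd.Series,
    cell_type: str = "",
    trait: str = "",
) -> AssociationResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test on two groups.

    Exact for small untied samples, tie-corrected normal approximation
    otherwise. Effect is the difference of group medians.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("both groups need >= 3 observations")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return AssociationResult(
        cell_type, trait, "rank_sum",
        statistic=float(res.statistic),
        effect=float(np.median(x) - np.median(y)),
        p=float(min(res.pvalue, 1.0)),
        z_score=group_z_score(x, y),
    )


def spearman_perm(
    x: np.ndarray | pd.Series,
    y: np.ndarray | pd.Series,
    n_perm: int = 10_000,
    seed: int | None = None,
    cell_type: str = "",
    trait: str = "",
) -> AssociationResult:
    """Permutation test of the Spearman rank correlation.

    rho is Pearson correlation of average ranks (ties averaged); the
    two-sided p-value is ``(#{|rho_perm| >= |rho_obs|} + 1) / (n_perm + 1)``
    over ``n_perm`` random permutations of the covariate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 4:
        raise ValueError("need paired vectors of length >= 4")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("degenerate covariate: constant input")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    n = x.size
    rho = float(rx @ ry) / n
    rng = np.random.default_rng(seed)
    # permuting the covariate's ranks leaves the rank distribution fixed,
    # so rho_perm is just a dot product with shuffled indices
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    rho_perm = (rx[perm_idx] @ ry) / n
    p = (np.count_nonzero(np.abs(rho_perm) >= abs(rho) - 1e-12) + 1) / (n_perm + 1)
    return AssociationResult(
        cell_type, trait, "spearman_perm",
        statistic=rho, effect=rho, p=float(p),
    )


def adjust_bh(results: list[AssociationResult], alpha: float = 0.05
              ) -> list[AssociationResult]:
    """Benjamini-Hochberg step-up adjustment over all supplied results.

    Adjusts jointly (the whole cell-type x trait grid counts as one family,
    e.g. 21 cell types x 16 traits = 336 comparisons). Mutates and returns
    the same result objects with ``p_adj`` filled in.
    """
    if not results:
        raise ValueError("no results to adjust")
    p = np.array([r.p for r in results])
    p_adj = multipletests(p, alpha=alpha, method="fdr_bh")[1]
    for r, q in zip(results, p_adj):
        r.p_adj = float(q)
    return results


def associate(
    fractions: pd.DataFrame,
    pheno: PhenotypeTable,
    group_trait: str | None = "group",
    paired: bool = False,
    covariate_traits: list[str] | None = None,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Run the full cell-type x trait association grid and adjust jointly.

    Parameters
    ----------
    fractions
        Samples x cell-types table of estimated fractions (diagnostic
        columns like ``P-value`` are ignored).
    pheno
        Phenotype table. For ``paired=True`` the ``pair_id`` column defines
        pairs and ``group`` must split each pair into the two arms.
    """
    diag = {"P-value", "Correlation", "RMSE"}
    cell_types = [c for c in fractions.columns if c not in diag]
    ph = pheno.data.loc[[s for s in fractions.index if s in pheno.data.index]]
    frac = fractions.loc[ph.index, cell_types]
    results: list[AssociationResult] = []
    rng = np.random.default_rng(seed)

    if group_trait and group_trait in ph.columns:
        groups = ph[group_trait].dropna()
        levels = sorted(groups.unique())
        if len(levels) != 2:
            raise ValueError(
                f"trait {group_trait!r} must have exactly 2 levels, got {levels}"
            )
        a_ids = groups.index[groups == levels[0]]
        b_ids = groups.index[groups == levels[1]]
        if paired:
            if "pair_id" not in ph.columns:
                raise ValueError("paired analysis needs a 'pair_id' column")
            pairs = ph.loc[a_ids, "pair_id"]
            b_by_pair = {ph.at[s, "pair_id"]: s for s in b_ids}
            a_sorted = list(pairs.index)
            b_sorted = [b_by_pair[p] for p in pairs]
        for ct in cell_types:
            name = f"{levels[0]}_vs_{levels[1]}"
            if paired:
                res = paired_test(
                    frac.loc[a_sorted, ct], frac.loc[b_sorted, ct],
                    cell_type=ct, trait=name,
                )
            else:
                res = unpaired_test(
                    frac.loc[a_ids, ct], frac.loc[b_ids, ct],
                    cell_type=ct, trait=name,
                )
            results.append(res)

    for cov in covariate_traits or []:
        vals = ph[cov].dropna().astype(float)
        for ct in cell_types:
            results.append(
                spearman_perm(
                    vals, frac.loc[vals.index, ct],
                    n_perm=n_perm, seed=int(rng.integers(2**31 - 1)),
                    cell_type=ct, trait=cov,
                )
            )

    if not results:
        raise ValueError("no traits to test")
    adjust_bh(results)
    return pd.DataFrame(
        [
            {
                "cell_type": r.cell_type,
                "trait": r.trait,
                "test": r.test,
                "statistic": r.statistic,
                "effect": r.effect,
                "p": r.p,
                "p_adj": r.p_adj,
                "z_score": r.z_score,
                "significant_raw": r.p < 0.05,
                "significant_adj": (r.p_adj is not None and r.p_adj < 0.05),
            }
            for r in results
        ]
    ).sort_values(["trait", "cell_type"], kind="stable").reset_index(drop=True)
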