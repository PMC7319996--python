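"""Signature-matrix construction from a labeled reference set.

A signature matrix is the regression basis for deconvolution: one column of
characteristic (mean) expression per cell type, restricted to features that
discriminate between types. Construction follows the standard recipe of the
linear deconvolution family:

1. per cell type, rank features by a differential test of that type's
   samples against all other samples (unequal-variance t-test with
   Benjamini-Hochberg FDR control, fold-change floor, fold-change ranking);
2. sweep the per-type marker-set size G over a range, at each G taking the
   union of every type's top-G features;
3. keep the union whose mean-profile submatrix has the smallest condition
   number kappa — the ratio of largest to smallest singular value, a direct
   measure of how mutually distinguishable the cell-type profiles are.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .expr_io import ReferenceSet

__all__ = [
    "MeanProfileMatrix",
    "SignatureMatrix",
    "mean_profiles",
    "differential_features",
    "condition_number",
    "build_signature",
    "signature_correlation",
]

logger = logging.getLogger(__name__)

#: Relative singular-value cutoff below which a grid counts as rank deficient.
RANK_EPS = 1e-12


@dataclass
class MeanProfileMatrix:
    """Features x cell-types grid of per-type mean expression (linear scale).

    Entry (i, j) is the arithmetic mean of feature i over all reference
    samples labeled with cell type j — the g'_ij quantity both the marker
    criteria and the signature matrix are built from.
    """

    means: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.means.to_numpy() < 0).any():
            raise ValueError("mean profiles must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return [str(f) for f in self.means.index]

    @property
    def cell_types(self) -> list[str]:
        return [str(c) for c in self.means.columns]


@dataclass
class SignatureMatrix:
    """Selected signature features x cell types, with sweep diagnostics."""

    values: pd.DataFrame
    condition_number: float
    per_type_set_size: int
    q_threshold: float | None = None
    min_fold: float | None = None
    markers: dict[str, list[str]] = field(default_factory=dict)

    @property
    def feature_ids(self) -> list[str]:
        return [str(f) for f in self.values.index]

    @property
    def cell_types(self) -> list[str]:
        return [str(c) for c in self.values.columns]


def mean_profiles(ref: ReferenceSet) -> MeanProfileMatrix:
    """Average the reference samples of each cell type into one column."""
    df = ref.matrix.data
    cols = {t: df[ref.samples_of(t)].mean(axis=1) for t in ref.cell_types}
    return MeanProfileMatrix(pd.DataFrame(cols)[ref.cell_types])


def _welch_t_vs_rest(
    x: np.ndarray, rest: np.ndarray, pooled_var_row: np.ndarray | None
) -> np.ndarray:
    """Two-sided Welch t-test p-values of group ``x`` vs ``rest``, per row.

    ``pooled_var_row`` substitutes the within-group variance for cell types
    with a single sample (no variance of their own).
    """
    n1, n2 = x.shape[1], rest.shape[1]
    m1, m2 = x.mean(axis=1), rest.mean(axis=1)
    if n2 >= 2:
        v2 = rest.var(axis=1, ddof=1)
    else:
        assert pooled_var_row is not None
        v2 = pooled_var_row
    if n1 >= 2:
        v1 = x.var(axis=1, ddof=1)
        df1 = n1 - 1
    else:
        assert pooled_var_row is not None
        v1 = pooled_var_row
        df1 = 1  # conservative
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / df1 + (v2 / n2) ** 2 / (n2 - 1))
    # zero variance in both groups: any mean difference is unambiguous
    t = np.where(se2 > 0, t, np.where(m1 != m2, np.inf, 0.0))
    df = np.where(np.isfinite(df) & (df > 0), df, 1.0)
    return 2.0 * stats.t.sf(np.abs(t), df)


def differential_features(
    ref: ReferenceSet,
    q_threshold: float = 0.3,
    min_fold: float = 1.0,
) -> dict[str, list[str]]:
    """Rank candidate marker features for each cell type.

    For each type, every feature is tested (unequal-variance t-test,
    that type's samples vs all other samples, two-sided), p-values are
    FDR-adjusted per type with Benjamini-Hochberg, and features passing
    ``q <= q_threshold`` with fold-change ``mean_type / mean_rest >=
    min_fold`` are returned ranked by decreasing fold-change.

    Cell types with a single reference sample borrow a pooled within-type
    variance from the other types (logged as a warning). A type with no
    passing feature contributes an empty list, with a warning.
    """
    if not 0 < q_threshold <= 1:
        raise ValueError("q_threshold must be in (0, 1]")
    if min_fold < 1:
        raise ValueError("min_fold must be >= 1")
    df = ref.matrix.data
    values = df.to_numpy(dtype=float)
    features = np.asarray(df.index, dtype=object)
    sample_types = np.asarray([ref.labels[s] for s in ref.matrix.sample_ids])

    counts = ref.type_counts()
    singles = [t for t, n in counts.items() if n < 2]
    pooled_var = None
    if singles:
        logger.warning(
            "cell types with a single reference sample (pooled variance "
            "fallback): %s",
            singles,
        )
        resid_ss = np.zeros(values.shape[0])
        resid_df = 0
        for t, n in counts.items():
            if n >= 2:
                sub = values[:, sample_types == t]
                resid_ss += sub.var(axis=1, ddof=1) * (n - 1)
                resid_df += n - 1
        if resid_df == 0:
            raise ValueError(
                "every cell type has a single sample; cannot estimate variance"
            )
        pooled_var = resid_ss / resid_df

    ranked: dict[str, list[str]] = {}
    eps = np.finfo(float).tiny
    for t in ref.cell_types:
        mask = sample_types == t
        x, rest = values[:, mask], values[:, ~mask]
        p = _welch_t_vs_rest(x, rest, pooled_var)
        p = np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0)
        q = multipletests(p, method="fdr_bh")[1]
        fold = x.mean(axis=1) / np.maximum(rest.mean(axis=1), eps)
        keep = (q <= q_threshold) & (fold >= min_fold)
        order = np.argsort(-fold[keep], kind="stable")
        ranked[t] = [str(f) for f in features[keep][order]]
        if not ranked[t]:
            warnings.warn(f"no differential features pass for cell type {t!r}")
    return ranked


def condition_number(values: np.ndarray | pd.DataFrame) -> float:
    """Ratio of largest to smallest singular value; inf if rank deficient."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D grid")
    s = np.linalg.svd(arr, compute_uv=False)
    if s.size == 0 or s[0] == 0 or s[-1] <= s[0] * RANK_EPS:
        return float("inf")
    return float(s[0] / s[-1])


def build_signature(
    ref: ReferenceSet,
    g_min: int = 50,
    g_max: int = 150,
    q_threshold: float = 0.3,
    min_fold: float = 1.0,
) -> SignatureMatrix:
    """Pick the marker-set size whose union minimizes the condition number.

    For each G in ``[g_min, g_max]`` the union of every cell type's top-G
    differential features indexes a candidate submatrix of the mean-profile
    matrix; the candidate with minimal kappa wins, ties going to the
    smallest G (more compact signature). Raises if every candidate is rank
    deficient — the reference then cannot separate its cell types.
    """
    if g_min > g_max or g_min < 1:
        raise ValueError("need 1 <= g_min <= g_max")
    ranked = differential_features(ref, q_threshold, min_fold)
    nonempty = sum(bool(v) for v in ranked.values())
    if nonempty < 2:
        raise ValueError(
            "differential selection produced markers for fewer than 2 cell "
            "types; reference cannot separate cell types"
        )
    profiles = mean_profiles(ref)
    best: tuple[float, int, list[str]] | None = None
    for g in range(g_min, g_max + 1):
        union: dict[str, None] = {}
        for t in ref.cell_types:
            for f in ranked[t][:g]:
                union.setdefault(f, None)
        feats = list(union)
        if len(feats) < len(ref.cell_types):
            continue
        kappa = condition_number(profiles.means.loc[feats])
        if best is None or kappa < best[0]:
            best = (kappa, g, feats)
    if best is None or not np.isfinite(best[0]):
        if best is None:
            raise ValueError(
                "no candidate feature union had enough rows; reference "
                "cannot separate cell types"
            )
        logger.warning(
            "all candidate unions are rank deficient; reporting kappa=inf"
        )
    kappa, g, feats = best
    return SignatureMatrix(
        values=profiles.means.loc[feats].copy(),
        condition_number=kappa,
        per_type_set_size=g,
        q_threshold=q_threshold,
        min_fold=min_fold,
        markers={t: ranked[t][:g] for t in ref.cell_types},
    )


def signature_correlation(
    sig: SignatureMatrix | pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation of signature columns plus a dendrogram order.

    Returns the K x K correlation grid and the leaf order of average-linkage
    hierarchical clustering on distance ``1 - r`` — the standard view of
    which cell-type signatures resemble each other (e.g. adipocytes from
    different depots, or the mesenchymal lineage).
    """
    df = sig.values if isinstance(sig, SignatureMatrix) else sig
    if df.shape[1] < 2:
        raise ValueError("need at least 2 cell types")
    if (df.std(axis=0, ddof=0) == 0).any():
        bad = df.columns[df.std(axis=0, ddof=0) == 0].tolist()
        raise ValueError(f"constant signature columns (undefined correlation): {bad}")
    corr = df.corr(method="pearson")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    # guard tiny negative round-off before squareform
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = [df.columns[i] for i in hierarchy.leaves_list(link)]
    return corr, order
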