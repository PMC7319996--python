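"""Bulk-sample deconvolution by linear-kernel nu-support-vector regression.

A bulk tissue profile is modeled as a non-negative combination of cell-type
signature profiles. For each sample the signature matrix (features x K cell
types) is the design matrix and the bulk profile the response of a
linear-kernel nu-SVR; the epsilon-insensitive loss makes the fit robust to
features whose bulk expression departs from the linear-mixing assumption
(unmodeled cell types, platform artifacts). The nu parameter, which bounds
the fraction of support vectors, is selected per sample from a small grid
by reconstruction RMSE. Negative regression weights are clipped to zero and
the rest renormalized to fractions summing to one.

Both signature and mixture are z-scored before regression (the signature
over all its entries jointly, the mixture over its own entries), which
makes the estimated fractions invariant to the overall scaling of either.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import NuSVR

from .expr_io import ExpressionMatrix
from .signature import SignatureMatrix

__all__ = [
    "FractionEstimate",
    "ArchetypeEstimate",
    "deconvolve_sample",
    "deconvolve_dataset",
    "fractions_frame",
    "fit_pvalue",
    "aggregate_archetypes",
    "DEFAULT_NUS",
    "ARCHETYPES",
]

logger = logging.getLogger(__name__)

DEFAULT_NUS: tuple[float, ...] = (0.25, 0.5, 0.75)

#: The four cellular archetypes used to roll up detailed cell types.
ARCHETYPES = ("immune", "stem_stromal", "adipocyte", "other")

#: Minimum fraction of signature features that must be present in a mixture.
MIN_FEATURE_OVERLAP = 0.5


@dataclass
class FractionEstimate:
    """Estimated relative cell-type fractions of one bulk sample."""

    sample_id: str
    fractions: dict[str, float]
    chosen_nu: float
    rmse: float
    pearson_r: float
    pvalue: float | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(list(self.fractions.values()))
        if (vals < 0).any():
            raise ValueError("fractions must be non-negative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1 (got {vals.sum()!r})")


@dataclass
class ArchetypeEstimate:
    """Fractions rolled up to the four coarse archetypes."""

    sample_id: str
    archetype_fractions: dict[str, float]


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant array")
    return (x - x.mean()) / sd


def _align(
    mix: pd.Series, sig: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    shared = sig.index.intersection(mix.index)
    overlap = len(shared) / sig.shape[0]
    if overlap < MIN_FEATURE_OVERLAP:
        raise ValueError(
            f"only {len(shared)}/{sig.shape[0]} signature features present in "
            f"the mixture ({overlap:.0%} < {MIN_FEATURE_OVERLAP:.0%})"
        )
    return mix.loc[shared].to_numpy(dtype=float), sig.loc[shared].to_numpy(
        dtype=float
    )


def _quantile_map(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Map ``values`` onto the empirical distribution of ``reference``.

    Rank-preserving: each value is replaced by the reference quantile at
    its own empirical quantile. Used for cross-platform mixtures whose
    intensity distribution differs from the signature's.
    """
    ranks = np.argsort(np.argsort(values))
    q = (ranks + 0.5) / len(values)
    return np.quantile(np.sort(reference.ravel()), q)


def deconvolve_sample(
    mix: pd.Series,
    sig: SignatureMatrix | pd.DataFrame,
    nus: Sequence[float] = DEFAULT_NUS,
    C: float = 1.0,
    clip_negative: bool = True,
    quantile_map: bool = False,
) -> FractionEstimate:
    """Estimate cell-type fractions of one bulk profile.

    Parameters
    ----------
    mix
        Linear-scale expression indexed by feature id. At least half of the
        signature's features must be present; the intersection is used.
    sig
        Signature matrix (features x cell types).
    nus
        Candidate nu values; the fit with smallest reconstruction RMSE on
        the standardized scale wins.
    C
        SVR regularization constant.
    clip_negative
        Clip negative regression weights to zero before normalizing.
    quantile_map
        Map the mixture's values onto the signature's empirical value
        distribution first (rank-preserving); off by default — platform
        matching between reference and mixture is the accurate regime.
    """
    sig_df = sig.values if isinstance(sig, SignatureMatrix) else sig
    y_raw, X_raw = _align(mix, sig_df)
    if quantile_map:
        y_raw = _quantile_map(y_raw, X_raw)
    # signature standardized over all entries jointly (column geometry kept),
    # mixture over its own entries
    X = (X_raw - X_raw.mean()) / X_raw.std()
    y = _standardize(y_raw)

    best: tuple[float, float, np.ndarray, float] | None = None
    for nu in nus:
        model = NuSVR(kernel="linear", nu=nu, C=C)
        model.fit(X, y)
        coef = model.coef_.ravel()
        recon = X @ coef + model.intercept_
        rmse = float(np.sqrt(np.mean((recon - y) ** 2)))
        r = float(np.corrcoef(recon, y)[0, 1]) if recon.std() > 0 else 0.0
        if best is None or rmse < best[0]:
            best = (rmse, float(nu), coef, r)
    rmse, chosen_nu, coef, r = best

    w = np.clip(coef, 0.0, None) if clip_negative else coef.copy()
    total = w.sum()
    if total <= 0:
        raise ValueError(
            "no admissible composition: all regression weights non-positive"
        )
    w /= total
    fractions = {str(t): float(f) for t, f in zip(sig_df.columns, w)}
    return FractionEstimate(
        sample_id=str(mix.name) if mix.name is not None else "",
        fractions=fractions,
        chosen_nu=chosen_nu,
        rmse=rmse,
        pearson_r=r,
    )


def deconvolve_dataset(
    mixtures: ExpressionMatrix,
    sig: SignatureMatrix | pd.DataFrame,
    nus: Sequence[float] = DEFAULT_NUS,
    C: float = 1.0,
    n_perm: int = 0,
    seed: int | None = None,
    quantile_map: bool = False,
) -> list[FractionEstimate]:
    """Deconvolve every column of a bulk expression matrix.

    Per-sample failures are logged and skipped; zero successes is an error.
    With ``n_perm > 0`` an empirical goodness-of-fit p-value is attached to
    each estimate (see :func:`fit_pvalue`).
    """
    sig_df = sig.values if isinstance(sig, SignatureMatrix) else sig
    shared = sig_df.index.intersection(mixtures.data.index)
    if len(shared) == 0:
        raise ValueError("mixture matrix shares no features with the signature")
    rng = np.random.default_rng(seed)
    estimates: list[FractionEstimate] = []
    for s in mixtures.sample_ids:
        col = mixtures.data[s]
        try:
            est = deconvolve_sample(col, sig_df, nus=nus, C=C,
                                    quantile_map=quantile_map)
        except ValueError as exc:
            logger.warning("sample %s failed: %s", s, exc)
            continue
        if n_perm > 0:
            est.pvalue = fit_pvalue(
                est, col, sig_df, n_perm=n_perm,
                seed=int(rng.integers(2**31 - 1)),
            )
        estimates.append(est)
    if not estimates:
        raise ValueError("deconvolution failed for every sample")
    return estimates


def fractions_frame(estimates: Sequence[FractionEstimate]) -> pd.DataFrame:
    """Tabulate estimates: one row per sample, cell types + diagnostics."""
    rows = []
    for e in estimates:
        row = {"sample_id": e.sample_id, **e.fractions}
        row["P-value"] = np.nan if e.pvalue is None else e.pvalue
        row["Correlation"] = e.pearson_r
        row["RMSE"] = e.rmse
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


def fit_pvalue(
    est: FractionEstimate,
    mix: pd.Series,
    sig: SignatureMatrix | pd.DataFrame,
    n_perm: int = 100,
    seed: int | None = None,
) -> float | None:
    """Permutation p-value for the reconstruction correlation.

    The mixture's values are permuted across features ``n_perm`` times and
    re-deconvolved; p = (#{perm r >= observed r} + 1) / (n_perm + 1).
    ``n_perm = 0`` disables the test (returns None).
    """
    if n_perm == 0:
        return None
    sig_df = sig.values if isinstance(sig, SignatureMatrix) else sig
    rng = np.random.default_rng(seed)
    hits = 0
    vals = mix.to_numpy(dtype=float)
    for _ in range(n_perm):
        perm = pd.Series(rng.permutation(vals), index=mix.index, name=mix.name)
        try:
            r = deconvolve_sample(perm, sig_df).pearson_r
        except ValueError:
            r = -1.0
        if r >= est.pearson_r:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def aggregate_archetypes(
    est: FractionEstimate, mapping: Mapping[str, str]
) -> ArchetypeEstimate:
    """Sum detailed cell-type fractions into coarse archetype fractions.

    ``mapping`` must cover every cell type in the estimate; archetype sums
    preserve the total of 1.
    """
    missing = [t for t in est.fractions if t not in mapping]
    if missing:
        raise KeyError(f"cell types without an archetype mapping: {missing}")
    out: dict[str, float] = {}
    for t, f in est.fractions.items():
        out[mapping[t]] = out.get(mapping[t], 0.0) + f
    return ArchetypeEstimate(sample_id=est.sample_id, archetype_fractions=out)
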