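"""Synthetic references, mixtures, and phenotype designs with known truth.

Stands in for the public microarray/RNA-Seq cohorts the real analyses run
on: a reference of isolated cell-type samples with planted marker
structure, bulk mixtures drawn from known fraction vectors, and phenotype
tables with planted group effects. Expression is log-normal (positive,
right-skewed, multiplicative noise — the salient features of linear-scale
microarray/RNA-Seq intensities), markers are disjoint per type and raised
by a fold-change, and every generator is deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .expr_io import ExpressionMatrix, PhenotypeTable, ReferenceSet

__all__ = [
    "SimulationConfig",
    "EffectSpec",
    "simulate_reference",
    "simulate_mixtures",
    "simulate_phenotypes",
    "type_profiles",
    "SAT_ARCHETYPE_WEIGHTS",
]

#: Average composition of subcutaneous adipose tissue by cellular archetype
#: (adipocytes, stem/stromal, immune, other), in percent of cells. Used as
#: the default Dirichlet weights when simulating 4-type mixtures.
SAT_ARCHETYPE_WEIGHTS = {
    "adipocyte": 74.0,
    "stem_stromal": 14.9,
    "immune": 7.4,
    "other": 3.7,
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic generators.

    Parameters
    ----------
    n_features, n_types
        Size of the expression universe and number of cell types K.
    markers_per_type
        Disjoint planted markers per type; ``markers_per_type * n_types``
        may not exceed ``n_features``.
    marker_effect
        Fold-change (> 1) applied to a type's markers in that type.
    replicates_per_type
        Reference samples per cell type.
    noise_cv
        Coefficient of variation of the multiplicative log-normal noise on
        reference replicates and mixtures (0 disables noise).
    dirichlet_alpha
        Length-K Dirichlet weights for mixture fractions. Default: the
        subcutaneous-tissue archetype proportions when K = 4, flat
        otherwise.
    n_mixtures
        Number of bulk mixtures to draw.
    seed
        Seed for all randomness.
    """

    n_features: int = 200
    n_types: int = 4
    markers_per_type: int = 10
    marker_effect: float = 8.0
    replicates_per_type: int = 5
    noise_cv: float = 0.05
    dirichlet_alpha: Sequence[float] | None = None
    n_mixtures: int = 50
    seed: int = 0
    base_log_mean: float = np.log(100.0)
    base_log_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_types < 2:
            raise ValueError("need at least 2 cell types")
        if self.markers_per_type * self.n_types > self.n_features:
            raise ValueError(
                "markers_per_type * n_types must not exceed n_features"
            )
        if self.marker_effect <= 1:
            raise ValueError("marker_effect must be > 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.dirichlet_alpha is not None:
            alpha = np.asarray(self.dirichlet_alpha, dtype=float)
            if alpha.size != self.n_types or (alpha <= 0).any():
                raise ValueError(
                    "dirichlet_alpha needs n_types positive entries"
                )

    def resolved_alpha(self) -> np.ndarray:
        if self.dirichlet_alpha is not None:
            return np.asarray(self.dirichlet_alpha, dtype=float)
        if self.n_types == 4:
            w = np.array(list(SAT_ARCHETYPE_WEIGHTS.values()))
            return w / w.sum() * self.n_types  # mean matches tissue archetypes
        return np.ones(self.n_types)

    def type_names(self) -> list[str]:
        if self.n_types == 4 and self.dirichlet_alpha is None:
            return list(SAT_ARCHETYPE_WEIGHTS)
        return [f"type_{j + 1}" for j in range(self.n_types)]


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(shape)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=shape)


def simulate_reference(
    cfg: SimulationConfig,
) -> tuple[ReferenceSet, pd.DataFrame]:
    """Generate a labeled reference with disjoint planted markers.

    Returns the reference set and a truth table (feature_id, cell_type)
    listing which features were planted as markers of which type. Baseline
    per-feature expression is log-normal and shared across types; each
    type's markers are multiplied by ``marker_effect`` in that type only;
    replicates get multiplicative log-normal noise with CV ``noise_cv``.
    """
    rng = np.random.default_rng(cfg.seed)
    features = [f"gene_{i + 1}" for i in range(cfg.n_features)]
    types = cfg.type_names()

    baseline = rng.lognormal(cfg.base_log_mean, cfg.base_log_sd, cfg.n_features)
    profiles = np.tile(baseline[:, None], (1, cfg.n_types))
    truth_rows = []
    for j, t in enumerate(types):
        lo = j * cfg.markers_per_type
        hi = lo + cfg.markers_per_type
        profiles[lo:hi, j] *= cfg.marker_effect
        truth_rows += [{"feature_id": features[i], "cell_type": t}
                       for i in range(lo, hi)]

    cols, labels = {}, {}
    for j, t in enumerate(types):
        for r in range(cfg.replicates_per_type):
            sid = f"{t}_rep{r + 1}"
            noise = _lognormal_noise(rng, cfg.noise_cv, cfg.n_features)
            cols[sid] = profiles[:, j] * noise
            labels[sid] = t
    matrix = ExpressionMatrix(pd.DataFrame(cols, index=features))
    ref = ReferenceSet(matrix=matrix, labels=labels, cell_types=types)
    return ref, pd.DataFrame(truth_rows)


def simulate_mixtures(
    profiles: pd.DataFrame, cfg: SimulationConfig
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Draw bulk mixtures from known fractions over the given type profiles.

    ``profiles`` is a features x types grid (e.g. the noiseless planted
    profiles via :func:`type_profiles`, or measured mean profiles). Each
    mixture is ``profiles @ f`` with ``f ~ Dirichlet(alpha)``, then
    perturbed by multiplicative log-normal noise. Returns the mixture
    matrix and the true fraction table (samples x types, rows sum to 1).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    alpha = cfg.resolved_alpha()
    if alpha.size != profiles.shape[1]:
        raise ValueError("alpha length must match the number of type profiles")
    fracs = rng.dirichlet(alpha, size=cfg.n_mixtures)
    clean = profiles.to_numpy() @ fracs.T
    noise = _lognormal_noise(rng, cfg.noise_cv, clean.shape)
    sample_ids = [f"mix_{i + 1}" for i in range(cfg.n_mixtures)]
    mixtures = ExpressionMatrix(
        pd.DataFrame(clean * noise, index=profiles.index, columns=sample_ids)
    )
    truth = pd.DataFrame(fracs, index=sample_ids, columns=profiles.columns)
    truth.index.name = "sample_id"
    return mixtures, truth


def type_profiles(ref: ReferenceSet) -> pd.DataFrame:
    """Noise-free per-type profiles from a reference (mean over replicates)."""
    df = ref.matrix.data
    return pd.DataFrame(
        {t: df[ref.samples_of(t)].mean(axis=1) for t in ref.cell_types}
    )[ref.cell_types]


@dataclass
class EffectSpec:
    """Planted group effect: shift of selected cell types between groups.

    ``shifts`` maps cell type -> additive fraction shift applied to group B
    (or to the second member of each pair); rows are renormalized to sum to
    one afterwards, so other fractions absorb the complement.
    """

    shifts: dict[str, float] = field(default_factory=dict)
    paired: bool = False


def simulate_phenotypes(
    true_fractions: pd.DataFrame,
    effect: EffectSpec,
    seed: int = 0,
) -> tuple[PhenotypeTable, pd.DataFrame]:
    """Assign samples to two groups and plant the specified fraction shifts.

    Unpaired: samples split alternately into groups A and B, and group B's
    selected cell types are shifted. Paired: every input sample becomes a
    subject with two arms sharing a ``pair_id`` (sample ids suffixed
    ``_a``/``_b``), the ``_b`` arm shifted. Returns the phenotype table and
    the (possibly expanded) fraction table with shifts applied; zero shifts
    leave fractions untouched, so downstream tests are null-calibrated.
    """
    unknown = [t for t in effect.shifts if t not in true_fractions.columns]
    if unknown:
        raise KeyError(f"shift for unknown cell types: {unknown}")

    def shifted(rows: pd.DataFrame) -> pd.DataFrame:
        out = rows.copy()
        for t, s in effect.shifts.items():
            out[t] = np.clip(out[t] + s, 0.0, None)
        return out.div(out.sum(axis=1), axis=0)

    if effect.paired:
        a = true_fractions.copy()
        b = shifted(true_fractions)
        a.index = [f"{s}_a" for s in true_fractions.index]
        b.index = [f"{s}_b" for s in true_fractions.index]
        pheno = pd.DataFrame(
            {
                "group": ["A"] * len(a) + ["B"] * len(b),
                "pair_id": [f"pair_{i + 1}" for i in range(len(a))] * 2,
            },
            index=list(a.index) + list(b.index),
        )
        pheno.index.name = "sample_id"
        return PhenotypeTable(pheno), pd.concat([a, b])

    n = len(true_fractions)
    group = np.where(np.arange(n) % 2 == 0, "A", "B")
    frac = true_fractions.copy()
    b_mask = group == "B"
    frac.loc[b_mask] = shifted(true_fractions.loc[b_mask]).to_numpy()
    pheno = pd.DataFrame({"group": group}, index=true_fractions.index.copy())
    pheno.index.name = "sample_id"
    return PhenotypeTable(pheno), frac
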