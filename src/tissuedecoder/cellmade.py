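"""Cell-type marker scoring (CellMaDe criteria).

For a mean-profile grid g'_ij (feature i, cell type j) two scores grade how
well a feature marks a cell type, both in expression units:

* primary criterion   ``g'_ij - max_{k != j} g'_ik`` — positive only for
  features essentially exclusive to the target type; the kind of marker an
  antibody-based assay (immunohistochemistry, flow cytometry) needs.
* secondary criterion ``g'_ij - mean_{k != j} g'_ik`` — enrichment relative
  to the average of the other types; combinations of secondary markers can
  identify types lacking any single exclusive marker (e.g. mesenchymal
  stem/stromal cells).

Algebraic facts used as test invariants: primary <= secondary everywhere
(a max is never below a mean), and each feature's secondary scores sum to
zero across cell types.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .expr_io import ExpressionMatrix, ReferenceSet
from .signature import MeanProfileMatrix

__all__ = [
    "primary_criterion",
    "secondary_criterion",
    "rank_markers",
    "marker_report",
    "merge_groups",
]


def _check_profiles(profiles: MeanProfileMatrix) -> pd.DataFrame:
    df = profiles.means
    if df.shape[1] < 2:
        raise ValueError("marker criteria need at least 2 cell types")
    return df


def primary_criterion(profiles: MeanProfileMatrix) -> pd.DataFrame:
    """Score each (feature, cell type): own mean minus the largest other mean."""
    df = _check_profiles(profiles)
    g = df.to_numpy(dtype=float)
    n, k = g.shape
    # max over k != j: compare against the global row max, falling back to
    # the second-largest where column j itself attains the max.
    order = np.argsort(g, axis=1)
    top = g[np.arange(n), order[:, -1]]
    second = g[np.arange(n), order[:, -2]]
    max_others = np.where(g == top[:, None], second[:, None], top[:, None])
    return pd.DataFrame(g - max_others, index=df.index, columns=df.columns)


def secondary_criterion(profiles: MeanProfileMatrix) -> pd.DataFrame:
    """Score each (feature, cell type): own mean minus the mean of the others."""
    df = _check_profiles(profiles)
    g = df.to_numpy(dtype=float)
    k = g.shape[1]
    mean_others = (g.sum(axis=1, keepdims=True) - g) / (k - 1)
    return pd.DataFrame(g - mean_others, index=df.index, columns=df.columns)


def rank_markers(
    scores: pd.DataFrame, cell_type: str, top_n: int = 10
) -> pd.DataFrame:
    """Top ``top_n`` features for one cell type by decreasing criterion value.

    Ties break lexicographically by feature id. The ``negative`` column
    flags features whose best score for this type is still negative —
    i.e. the type has no marker of this kind at all among them.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if cell_type not in scores.columns:
        raise KeyError(f"unknown cell type {cell_type!r}")
    col = scores[cell_type]
    ordered = col.iloc[
        np.lexsort((col.index.astype(str), -col.to_numpy()))
    ].head(top_n)
    return pd.DataFrame(
        {
            "feature_id": ordered.index.astype(str),
            "cell_type": cell_type,
            "score": ordered.to_numpy(),
            "rank": np.arange(1, len(ordered) + 1),
            "negative": ordered.to_numpy() < 0,
        }
    ).reset_index(drop=True)


def marker_report(profiles: MeanProfileMatrix, top_n: int = 10) -> pd.DataFrame:
    """Joint primary/secondary report over all cell types.

    One row per (feature, cell type) with both criterion values, both ranks
    (dense over all features of that type), and negative flags — the usual
    flat-file companion to per-type top-10 bar charts.
    """
    prim = primary_criterion(profiles)
    seco = secondary_criterion(profiles)
    rows = []
    for t in prim.columns:
        # ranks over the full feature universe, ties by feature id
        for grid, name in ((prim, "primary"), (seco, "secondary")):
            order = np.lexsort((grid.index.astype(str), -grid[t].to_numpy()))
            rank = np.empty(len(order), dtype=int)
            rank[order] = np.arange(1, len(order) + 1)
            grid_rank = pd.Series(rank, index=grid.index)
            if name == "primary":
                prim_rank = grid_rank
            else:
                seco_rank = grid_rank
        keep = prim_rank.sort_values().index[:top_n].union(
            seco_rank.sort_values().index[:top_n]
        )
        for f in keep:
            rows.append(
                {
                    "feature_id": str(f),
                    "cell_type": t,
                    "crit_primary": prim.at[f, t],
                    "crit_secondary": seco.at[f, t],
                    "rank_primary": int(prim_rank[f]),
                    "rank_secondary": int(seco_rank[f]),
                    "negative_primary": bool(prim.at[f, t] < 0),
                    "negative_secondary": bool(seco.at[f, t] < 0),
                }
            )
    return pd.DataFrame(rows).sort_values(
        ["cell_type", "rank_primary"], kind="stable"
    ).reset_index(drop=True)


def merge_groups(ref: ReferenceSet, merge_map: Mapping[str, str]) -> ReferenceSet:
    """Relabel reference samples by merging cell types into coarser groups.

    Typical use: pool depot-specific adipocyte types into one "adipocyte"
    label so the primary criterion stops penalising pan-adipocyte markers
    for being shared between depots. ``merge_map`` must cover every current
    cell type; merging down to fewer than 2 groups is an error.
    """
    missing = [t for t in ref.cell_types if t not in merge_map]
    if missing:
        raise KeyError(f"merge_map does not cover cell types: {missing}")
    new_types: dict[str, None] = {}
    for t in ref.cell_types:
        new_types.setdefault(merge_map[t], None)
    if len(new_types) < 2:
        raise ValueError("merging must leave at least 2 cell types")
    labels = {s: merge_map[t] for s, t in ref.labels.items()}
    return ReferenceSet(
        matrix=ExpressionMatrix(ref.matrix.data, ref.matrix.from_log2),
        labels=labels,
        cell_types=list(new_types),
    )
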