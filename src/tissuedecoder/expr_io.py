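"""Expression-matrix containers and TSV/GCT input/output.

Expression values are kept on the *linear* scale throughout the package:
deconvolution models a bulk profile as a convex combination of cell-type
profiles, which only makes sense for linear (non-logged) intensities.
Matrices whose values look log2-transformed are detected heuristically and
exponentiated by :func:`ensure_linear_scale`.

Containers wrap :class:`pandas.DataFrame` (features in rows, samples in
columns) so the rest of the package can rely on validated invariants:
unique identifiers, finite non-negative values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ReferenceSet",
    "PhenotypeTable",
    "read_expression",
    "write_expression",
    "ensure_linear_scale",
    "read_labels",
    "write_labels",
    "read_phenotypes",
]

#: Matrices whose maximum value is below this are assumed to be log2-scale.
#: Convention of the linear-mixing deconvolution family this package follows.
LOG_SCALE_MAX = 50.0


class ParseError(ValueError):
    """Raised when an input file does not conform to the expected layout."""


@dataclass
class ExpressionMatrix:
    """A features x samples grid of non-negative linear-scale expression.

    Parameters
    ----------
    data
        DataFrame with feature identifiers as the index and sample
        identifiers as columns. Values must be finite and >= 0.
    from_log2
        True if the values were exponentiated from log2 scale on load.
    """

    data: pd.DataFrame
    from_log2: bool = False

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dupes[:5]}")
        if cols.has_duplicates:
            dupes = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes[:5]}")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                "non-finite expression value at "
                f"feature {idx[bad[0]]!r}, sample {cols[bad[1]]!r}"
            )
        if values.size and (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise ValueError(
                "negative expression value at "
                f"feature {idx[bad[0]]!r}, sample {cols[bad[1]]!r} "
                "(linear-scale matrices must be non-negative)"
            )

    @property
    def feature_ids(self) -> list[str]:
        return [str(f) for f in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_features(self, features: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to the given features, preserving the given order."""
        missing = [f for f in features if f not in self.data.index]
        if missing:
            raise KeyError(f"features not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[list(features)], self.from_log2)


@dataclass
class ReferenceSet:
    """An :class:`ExpressionMatrix` of isolated cell-type samples plus labels.

    ``labels`` maps every sample id to exactly one cell-type name; the
    ordered ``cell_types`` list fixes column order for all downstream
    per-type matrices (mean profiles, signature matrices).
    """

    matrix: ExpressionMatrix
    labels: Mapping[str, str]
    cell_types: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        samples = self.matrix.sample_ids
        unlabeled = [s for s in samples if s not in self.labels]
        if unlabeled:
            raise ValueError(f"samples without a cell-type label: {unlabeled[:5]}")
        if not self.cell_types:
            seen: dict[str, None] = {}
            for s in samples:
                seen.setdefault(self.labels[s], None)
            self.cell_types = list(seen)
        counts = self.type_counts()
        empty = [t for t in self.cell_types if counts.get(t, 0) == 0]
        if empty:
            raise ValueError(f"cell types with no reference sample: {empty}")
        if len(self.cell_types) < 2:
            raise ValueError("a reference set needs at least 2 cell types")

    def type_counts(self) -> dict[str, int]:
        counts = {t: 0 for t in self.cell_types}
        for s in self.matrix.sample_ids:
            t = self.labels[s]
            if t not in counts:
                raise ValueError(f"label {t!r} of sample {s!r} not in cell_types")
            counts[t] += 1
        return counts

    def samples_of(self, cell_type: str) -> list[str]:
        return [s for s in self.matrix.sample_ids if self.labels[s] == cell_type]


@dataclass
class PhenotypeTable:
    """Per-sample phenotype annotations: group, pairing, numeric covariates.

    The underlying frame is indexed by sample id. Optional columns:
    ``group`` (categorical), ``pair_id`` (each value shared by exactly two
    samples), and any number of numeric covariate columns (BMI, age, ...).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids in phenotype table")
        if "pair_id" in self.data.columns:
            pairs = self.data["pair_id"].dropna()
            bad = [p for p, n in pairs.value_counts().items() if n != 2]
            if bad:
                raise ValueError(
                    f"pair_id values not occurring exactly twice: {bad[:5]}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    def covariates(self) -> list[str]:
        reserved = {"group", "pair_id"}
        return [c for c in self.data.columns if c not in reserved]


def _read_table(path: str | Path, fmt: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    if fmt == "tsv":
        skiprows = 0
    elif fmt == "gct":
        with open(path, "r", encoding="utf-8") as fh:
            version = fh.readline().strip()
            dims = fh.readline().split()
        if not version.startswith("#1."):
            raise ParseError(f"{path}: line 1 is not a GCT version header ({version!r})")
        if len(dims) < 2:
            raise ParseError(f"{path}: line 2 must hold the GCT dimensions")
        skiprows = 2
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'tsv' or 'gct')")

    try:
        df = pd.read_csv(path, sep="\t", skiprows=skiprows, index_col=0, dtype=str)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message varies
        raise ParseError(f"{path}: {exc}") from exc
    if df.columns.size == 0:
        raise ParseError(f"{path}: header row has no sample columns")
    # GCT files carry a Description column after the id column; drop it.
    if fmt == "gct" and df.columns[0].lower() == "description":
        df = df.drop(columns=df.columns[0])
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric value {df.iat[i, j]!r} at "
            f"feature {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise ParseError(
            f"{path}: missing value at feature {df.index[i]!r}, "
            f"sample {df.columns[j]!r} (missing values are not imputed)"
        )
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    numeric.index.name = "feature_id"
    numeric.columns.name = None
    return numeric


def read_expression(path: str | Path, fmt: str = "tsv") -> ExpressionMatrix:
    """Read an expression matrix from a TSV or GCT 1.2 file.

    The first column holds feature identifiers, the header row sample
    identifiers. Duplicate feature rows are collapsed by their row-wise
    mean (probe-level duplicates are common on arrays); sample ids must be
    unique. Raises :class:`ParseError` on malformed headers or
    non-numeric/missing cells, naming the offending coordinates.
    """
    df = _read_table(path, fmt)
    if df.index.has_duplicates:
        df = df.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(df)


def write_expression(m: ExpressionMatrix, path: str | Path, fmt: str = "tsv") -> None:
    """Write a matrix as TSV (header ``feature_id``) or GCT 1.2."""
    path = Path(path)
    df = m.data
    if fmt == "tsv":
        df.to_csv(path, sep="\t", index_label="feature_id", float_format="%.6g")
    elif fmt == "gct":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#1.2\n")
            fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
            out = df.copy()
            out.insert(0, "Description", "na")
            out.to_csv(fh, sep="\t", index_label="Name", float_format="%.6g")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def ensure_linear_scale(
    m: ExpressionMatrix, assume_log2: bool | None = None
) -> ExpressionMatrix:
    """Return ``m`` on the linear scale, exponentiating if it looks logged.

    If the maximum value is below ``LOG_SCALE_MAX`` (default 50) the matrix
    is treated as log2 and transformed by ``2**x``; otherwise it is returned
    unchanged. ``assume_log2`` overrides the heuristic in either direction.
    The ``from_log2`` flag on the result records whether a transformation
    occurred. Idempotent: a matrix already above the threshold passes
    through untouched.
    """
    values = m.data.to_numpy()
    if not np.isfinite(values).all():
        raise ValueError("expression values must be finite")
    if assume_log2 is None:
        is_log = bool(values.size == 0 or values.max() < LOG_SCALE_MAX)
    else:
        is_log = assume_log2
    if not is_log:
        if (values < 0).any():
            raise ValueError(
                "matrix judged linear-scale contains negative values; "
                "corrupt input or wrong scale flag"
            )
        return ExpressionMatrix(m.data, from_log2=False)
    return ExpressionMatrix(np.exp2(m.data), from_log2=True)


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (``sample_id``, ``cell_type``) into a dict."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "sample_id" not in cols or "cell_type" not in cols:
        raise ParseError(f"{path}: needs columns 'sample_id' and 'cell_type'")
    return dict(zip(df[cols["sample_id"]], df[cols["cell_type"]]))


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(labels), "cell_type": list(labels.values())}
    ).to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a phenotype TSV; requires a ``sample_id`` column."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: phenotype table needs a 'sample_id' column")
    df["sample_id"] = df["sample_id"].astype(str)
    return PhenotypeTable(df.set_index("sample_id"))
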