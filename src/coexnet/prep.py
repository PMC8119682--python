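"""Reading and preprocessing of expression, flag, trait and gene-set files.

The preprocessing chain reproduces a standard single-channel microarray
workflow: spots carrying two or more quality flags are masked as missing,
probes with any missing value are excluded (complete-case analysis),
intensities are converted to log2, arrays are quantile-normalized, and the
matrix is restricted to genes carrying at least one annotation, collapsing
multiple probes of a gene to the probe with the highest mean expression.
The fixed order is mask -> drop -> log2 -> normalize -> annotate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "read_expression",
    "read_flags",
    "read_traits",
    "read_gmt",
    "mask_flagged",
    "drop_incomplete_probes",
    "log2_transform",
    "quantile_normalize",
    "filter_annotated",
    "preprocess",
    "one_hot",
    "binarize",
]

_NA_VALUES = ["", "NA"]


@dataclass
class ExpressionMatrix:
    """A gene x sample expression matrix.

    ``values`` has gene ids as the row index and sample ids as columns;
    missing entries are NaN (never a magic number). ``is_log2`` records
    whether the log2 transform has been applied.
    """

    values: pd.DataFrame
    is_log2: bool = False

    def __post_init__(self) -> None:
        dup_g = self.values.index[self.values.index.duplicated()].unique()
        if len(dup_g):
            raise ValueError(f"duplicate gene id(s): {', '.join(map(str, dup_g[:5]))}")
        dup_s = self.values.columns[self.values.columns.duplicated()].unique()
        if len(dup_s):
            raise ValueError(f"duplicate sample id(s): {', '.join(map(str, dup_s[:5]))}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class GeneSetCollection:
    """GMT-style gene sets: term id -> (name, member gene ids, upper-cased)."""

    sets: dict[str, set[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {term!r} is empty")
        self.sets = {t: {g.upper() for g in m} for t, m in self.sets.items()}

    @property
    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return out


def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect in ("tsv", "tab"):
        return "\t"
    if dialect == "csv":
        return ","
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_expression(path: str | Path, dialect: str | None = None) -> ExpressionMatrix:
    """Read a raw expression matrix (gene-id first column, sample header)."""
    path = Path(path)
    sep = _sep_for(path, dialect)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dup_cols = pd.Index(header)[pd.Index(header).duplicated()].unique()
    if len(dup_cols):
        raise ValueError(f"{path.name}: duplicate sample header(s): {list(dup_cols)}")
    df = pd.read_csv(
        path, sep=sep, index_col=0, na_values=_NA_VALUES, keep_default_na=False,
    )
    if df.index.duplicated().any():
        bad = df.index[df.index.duplicated()].unique()
        raise ValueError(f"{path.name}: duplicate gene id(s): {list(bad[:5])}")
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"{path.name}: non-numeric column(s) {non_numeric}")
    return ExpressionMatrix(values=df.astype(float), is_log2=False)


def read_flags(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, dialect), index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path.name}: negative flag counts")
    return df.astype(int)


def read_traits(path: str | Path, sample_col: str = "sample_id") -> pd.DataFrame:
    """Read a sample x trait CSV; the sample-id column becomes the index."""
    path = Path(path)
    df = pd.read_csv(path, na_values=_NA_VALUES, keep_default_na=False)
    if sample_col not in df.columns:
        raise ValueError(f"{path.name}: missing sample-id column {sample_col!r}")
    df = df.set_index(sample_col)
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            pass
    return df


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3 or not any(p.strip() for p in parts[2:]):
            raise ValueError(f"{Path(path).name}:{lineno}: gene set line without members")
        term, desc = parts[0], parts[1]
        sets[term] = {g.strip() for g in parts[2:] if g.strip()}
        names[term] = desc
    return GeneSetCollection(sets=sets, names=names)


def mask_flagged(
    raw: ExpressionMatrix, flags: pd.DataFrame, max_ok_flags: int = 1
) -> ExpressionMatrix:
    """Set entries whose flag count exceeds ``max_ok_flags`` to missing.

    With the default, spots carrying two or more quality flags are
    considered to have no valid expression value.
    """
    if raw.values.shape != flags.shape:
        raise ValueError(
            f"shape mismatch: expression {raw.values.shape} vs flags {flags.shape}"
        )
    aligned = flags.to_numpy()
    masked = raw.values.where(aligned <= max_ok_flags)
    return replace(raw, values=masked)


def drop_incomplete_probes(masked: ExpressionMatrix) -> ExpressionMatrix:
    """Keep only probes with zero missing entries (order preserved)."""
    keep = masked.values.notna().all(axis=1)
    if not keep.any():
        raise ValueError("no probe survives complete-case exclusion")
    return replace(masked, values=masked.values.loc[keep])


def log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    if matrix.is_log2:
        raise ValueError("matrix is already on the log2 scale")
    vals = matrix.values.to_numpy()
    bad = np.argwhere(~(vals > 0) & ~np.isnan(vals))
    if len(bad):
        g, s = bad[0]
        raise ValueError(
            f"non-positive value {vals[g, s]!r} at gene "
            f"{matrix.values.index[g]!r}, sample {matrix.values.columns[s]!r}"
        )
    return ExpressionMatrix(values=np.log2(matrix.values), is_log2=True)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize samples (columns) against the mean distribution.

    Each column's sorted values are replaced by the across-sample means of
    order statistics; tied values receive the mean of their rank block.
    On tie-free data the operation is exactly idempotent and leaves all
    columns with identical sorted vectors. Matches the standard
    between-array quantile normalization for single-channel arrays.
    """
    df = matrix.values
    if df.isna().any().any():
        raise ValueError("quantile normalization requires a complete matrix")
    if df.shape[1] < 2:
        warnings.warn("single sample: quantile normalization is the identity")
        return replace(matrix, values=df.copy())
    x = df.to_numpy(float)
    ref = np.sort(x, axis=0).mean(axis=1)
    cum = np.concatenate([[0.0], np.cumsum(ref)])
    out = np.empty_like(x)
    from scipy.stats import rankdata

    for j in range(x.shape[1]):
        rmin = rankdata(x[:, j], method="min").astype(int)
        rmax = rankdata(x[:, j], method="max").astype(int)
        out[:, j] = (cum[rmax] - cum[rmin - 1]) / (rmax - rmin + 1)
    return replace(matrix, values=pd.DataFrame(out, index=df.index, columns=df.columns))


def filter_annotated(
    matrix: ExpressionMatrix, annotation: GeneSetCollection
) -> ExpressionMatrix:
    """Restrict to annotated genes; collapse multi-probe genes by max mean.

    Probe ids are matched to annotation gene symbols case-insensitively.
    When several probes map to one gene, the probe with the highest mean
    expression is kept (the conventional probe-collapsing rule).
    """
    annotated = annotation.all_genes
    upper = matrix.values.index.str.upper()
    keep = upper.isin(annotated)
    if not keep.any():
        raise ValueError("no gene overlaps the annotation")
    sub = matrix.values.loc[keep]
    sub_upper = pd.Index(sub.index.str.upper())
    if sub_upper.duplicated().any():
        means = sub.mean(axis=1)
        order = (
            pd.DataFrame({"gene": sub_upper, "mean": means.to_numpy()}, index=sub.index)
            .sort_values("mean", ascending=False)
        )
        best_probes = order[~order["gene"].duplicated()].index
        sub = sub.loc[sub.index.isin(best_probes)]
    return replace(matrix, values=sub)


def preprocess(
    raw: ExpressionMatrix,
    flags: pd.DataFrame | None = None,
    annotation: GeneSetCollection | None = None,
    *,
    max_ok_flags: int = 1,
    apply_log2: bool = True,
    normalize: bool = True,
) -> ExpressionMatrix:
    """Full preprocessing chain: mask -> drop -> log2 -> normalize -> annotate."""
    em = raw
    if flags is not None:
        em = mask_flagged(em, flags, max_ok_flags=max_ok_flags)
        log.info("mask_flagged: %d x %d", *em.values.shape)
    em = drop_incomplete_probes(em)
    log.info("drop_incomplete_probes: %d probes survive", em.values.shape[0])
    if apply_log2:
        em = log2_transform(em)
    if normalize:
        em = quantile_normalize(em)
    if annotation is not None:
        em = filter_annotated(em, annotation)
        log.info("filter_annotated: %d genes", em.values.shape[0])
    return em


def one_hot(
    traits: pd.DataFrame, column: str, groups: dict[str, list]
) -> pd.DataFrame:
    """Expand an ordinal column into binary indicator traits.

    ``groups`` maps the new trait name to the set of source levels coded 1,
    e.g. ``{"GCL0-1": [0, 1], "GCL2": [2], "GCL3": [3]}``. Missing source
    values stay missing in every indicator.
    """
    out = traits.copy()
    src = traits[column]
    for name, levels in groups.items():
        ind = src.isin(levels).astype(float)
        ind[src.isna()] = np.nan
        out[name] = ind
    return out.drop(columns=[column])


def binarize(
    traits: pd.DataFrame, column: str, threshold: float, name: str,
    *, below_is_one: bool = True,
) -> pd.DataFrame:
    """Dichotomize a continuous column at a threshold (<= threshold -> 1)."""
    out = traits.copy()
    src = traits[column]
    ind = (src <= threshold if below_is_one else src > threshold).astype(float)
    ind[src.isna()] = np.nan
    out[name] = ind
    return out.drop(columns=[column])
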