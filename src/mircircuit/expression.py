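"""Expression matrices, quantile normalization, fold changes, inverse-expression calls.

The experimental design is three MCF7-derived cell lines (the parental
drug-sensitive line plus a tamoxifen-resistant and a fulvestrant-resistant
subline), each profiled in duplicate on both a miRNA and an mRNA array.
Columns are named ``<cell_line>.<replicate>``; the two standard contrasts are

* ``T_vs_P`` — tamoxifen-resistant subline over parent,
* ``F_vs_P`` — fulvestrant-resistant subline over parent,

with positive log2 fold change meaning higher expression in the resistant
subline (the sign convention used throughout the package).
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "CONTRASTS",
    "ExpressionMatrix",
    "quantile_normalize",
    "fold_change",
    "fold_change_table",
    "inverse_signs",
    "is_inverse",
]

FEATURE_CLASSES = ("miRNA", "mRNA")
SCALES = ("linear", "log2")

#: Standard contrasts: contrast id -> (subline, parent).
CONTRASTS: dict[str, tuple[str, str]] = {
    "T_vs_P": ("T", "parent"),
    "F_vs_P": ("F", "parent"),
}


@dataclasses.dataclass
class ExpressionMatrix:
    """A features x samples intensity table with sample metadata.

    Parameters
    ----------
    values
        DataFrame, rows indexed by feature id, columns named
        ``<cell_line>.<replicate>``.
    feature_class
        ``"miRNA"`` or ``"mRNA"`` (one class per matrix).
    scale
        ``"linear"`` (positive intensities) or ``"log2"``.
    """

    values: pd.DataFrame
    feature_class: str
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"feature_class must be one of {FEATURE_CLASSES}, got {self.feature_class!r}")
        if self.scale not in SCALES:
            raise ValueError(f"scale must be one of {SCALES}, got {self.scale!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if self.scale == "linear" and (arr <= 0).any():
            raise ValueError("linear-scale intensities must be strictly positive")
        self.sample_meta  # validates column name format

    # -- metadata ----------------------------------------------------------

    @property
    def sample_meta(self) -> pd.DataFrame:
        """Per-column (cell_line, replicate), parsed from the column names."""
        lines, reps = [], []
        for col in self.values.columns:
            if "." not in str(col):
                raise ValueError(f"sample column {col!r} is not of the form '<cell_line>.<replicate>'")
            line, rep = str(col).rsplit(".", 1)
            lines.append(line)
            reps.append(rep)
        return pd.DataFrame({"cell_line": lines, "replicate": reps}, index=self.values.columns)

    @property
    def cell_lines(self) -> list[str]:
        return sorted(set(self.sample_meta["cell_line"]))

    # -- scale conversion --------------------------------------------------

    def to_log2(self) -> "ExpressionMatrix":
        if self.scale == "log2":
            return self
        return ExpressionMatrix(np.log2(self.values), self.feature_class, "log2")

    def to_linear(self) -> "ExpressionMatrix":
        if self.scale == "linear":
            return self
        return ExpressionMatrix(2.0**self.values, self.feature_class, "linear")

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.values.to_csv(path, sep="\t", index_label="feature_id")

    @classmethod
    def from_tsv(cls, path: Union[str, Path], feature_class: str, scale: str = "linear") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="feature_id")
        df.index.name = None
        return cls(df, feature_class, scale)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every column onto the common distribution of per-rank means.

    Rank ``r``'s normalized value is the mean over columns of each column's
    ``r``-th smallest value; tied values within a column receive the mean of
    the rank-means over their tied rank range. Within-column rank order is
    preserved and the scale flag is unchanged. Idempotent (to floating
    precision) and a fixed point on already-identical columns.
    """
    X = matrix.values.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 sample columns")
    rank_means = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        sorted_vals = col[order]
        # runs of equal sorted values share the mean of their rank-means
        grp = np.concatenate(([0], np.cumsum(sorted_vals[1:] != sorted_vals[:-1])))
        grp_mean = np.bincount(grp, weights=rank_means) / np.bincount(grp)
        out[order, j] = grp_mean[grp]
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values, matrix.feature_class, matrix.scale)


def fold_change(
    matrix: ExpressionMatrix,
    contrast: tuple[str, str],
    contrast_id: str | None = None,
) -> pd.DataFrame:
    """Per-feature fold change of a subline over the parent line.

    ``log2fc`` is the difference of replicate means on log2 scale,
    ``ratio = 2**log2fc``. Positive log2fc means the resistant subline is
    higher than the parent.

    Returns a fold-change table: one row per feature with columns
    ``feature_id, contrast_id, ratio, log2fc``.
    """
    subline, parent = contrast
    meta = matrix.sample_meta
    present = set(meta["cell_line"])
    for line in (subline, parent):
        if line not in present:
            raise ValueError(f"cell line {line!r} not present in matrix (has {sorted(present)})")
    logm = matrix.to_log2().values
    sub_cols = meta.index[meta["cell_line"] == subline]
    par_cols = meta.index[meta["cell_line"] == parent]
    log2fc = logm[sub_cols].mean(axis=1) - logm[par_cols].mean(axis=1)
    cid = contrast_id if contrast_id is not None else f"{subline}_vs_{parent}"
    return pd.DataFrame(
        {
            "feature_id": matrix.values.index.to_numpy(),
            "contrast_id": cid,
            "ratio": 2.0 ** log2fc.to_numpy(),
            "log2fc": log2fc.to_numpy(),
        }
    )


def fold_change_table(
    matrix: ExpressionMatrix,
    contrasts: Mapping[str, tuple[str, str]] = CONTRASTS,
) -> pd.DataFrame:
    """Fold-change rows for several contrasts, concatenated."""
    parts = [fold_change(matrix, pair, cid) for cid, pair in sorted(contrasts.items())]
    return pd.concat(parts, ignore_index=True)


def inverse_signs(log2fc_mirna: float, log2fc_target: float, min_abs_log2fc: float = 0.0) -> bool:
    """True iff the two log2 fold changes have strictly opposite signs and
    both magnitudes reach ``min_abs_log2fc``. A log2fc of exactly 0 never
    satisfies the condition."""
    a = float(log2fc_mirna)
    b = float(log2fc_target)
    return a * b < 0 and abs(a) >= min_abs_log2fc and abs(b) >= min_abs_log2fc


def is_inverse(fc_mirna, fc_target, min_abs_log2fc: float = 0.0) -> bool:
    """Inverse-expression call on two fold-change rows of the same contrast.

    ``fc_mirna`` / ``fc_target`` are mappings (e.g. DataFrame rows) with keys
    ``contrast_id`` and ``log2fc``. Rows from different contrasts are
    rejected.
    """
    if fc_mirna["contrast_id"] != fc_target["contrast_id"]:
        raise ValueError(
            f"contrast mismatch: {fc_mirna['contrast_id']!r} vs {fc_target['contrast_id']!r}"
        )
    return inverse_signs(fc_mirna["log2fc"], fc_target["log2fc"], min_abs_log2fc)
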