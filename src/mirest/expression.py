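"""Relative-expression profiling from stem-loop RT-PCR band intensities.

Band intensities (arbitrary densitometry units, one row per miRNA plus one
control row, one column per sample) become relative expression as
log10(miRNA / control), clamped to [-3, 3] for display, with per-miRNA
fold-class calls:

* ``high``        ratio > 2 (clearly above the control)
* ``moderate``    0.1 <= ratio <= 1 (similar to or below the control)
* ``very_low``    ratio < 0.01
* ``intermediate`` the gaps (0.01, 0.1) and (1, 2] the published bins leave
* ``undefined``   ratio not computable

Row clustering uses average linkage on 1 - Pearson correlation of the
clamped log profiles (the defaults of the classic Cluster/TreeView tool).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .seq import FormatError

__all__ = [
    "ExpressionMatrix",
    "ClusterResult",
    "CLASS_LABELS",
    "load_intensity_table",
    "relative_expression",
    "classify_fold",
    "count_classes",
    "cluster_rows",
]

CLASS_LABELS = ("high", "moderate", "very_low", "intermediate", "undefined")

CLAMP_LO, CLAMP_HI = -3.0, 3.0


@dataclass
class ExpressionMatrix:
    """Per-miRNA relative expression against the control row."""

    ratios: pd.DataFrame
    logs: pd.DataFrame
    clamped: pd.DataFrame
    classes: pd.Series
    control: str
    reference: str


def load_intensity_table(path, control: str = "U6snRNA") -> pd.DataFrame:
    """Read a miRNA x sample intensity TSV (first column = row names).

    Exactly one control row must be present and all values non-negative.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    validate_intensity_table(df, control)
    return df


def validate_intensity_table(df: pd.DataFrame, control: str) -> None:
    if list(df.index).count(control) != 1:
        raise FormatError(
            f"intensity table needs exactly one control row {control!r}"
        )
    if (df.values < 0).any():
        raise FormatError("negative intensity value")


def relative_expression(
    df: pd.DataFrame,
    control: str = "U6snRNA",
    reference: str = "max",
) -> ExpressionMatrix:
    """miRNA/control ratios, log10 values and clamped display values.

    ``reference`` selects the ratio used for the per-miRNA fold-class call:
    ``"max"`` (row maximum over samples) or a column name.  A zero control
    intensity is an error naming the column; a zero miRNA intensity gives
    log10 = -inf, clamped to -3.
    """
    validate_intensity_table(df, control)
    ctrl = df.loc[control]
    zero_cols = ctrl[ctrl <= 0]
    if len(zero_cols):
        raise ValueError(
            f"control row {control!r} is zero in column(s) "
            f"{list(zero_cols.index)}"
        )
    mir = df.drop(index=control)
    ratios = mir.div(ctrl, axis=1)
    with np.errstate(divide="ignore"):
        logs = np.log10(ratios)
    clamped = logs.clip(CLAMP_LO, CLAMP_HI)
    if reference == "max":
        ref_ratio = ratios.max(axis=1)
    else:
        if reference not in ratios.columns:
            raise ValueError(f"unknown reference column {reference!r}")
        ref_ratio = ratios[reference]
    classes = ref_ratio.map(
        lambda r: "undefined" if not np.isfinite(r) else classify_fold(r)
    )
    return ExpressionMatrix(ratios, logs, clamped, classes, control, reference)


def classify_fold(ratio: float) -> str:
    """Fold-class of a miRNA/control ratio; total on [0, inf)."""
    if ratio < 0:
        raise ValueError(f"negative expression ratio {ratio}")
    if ratio > 2:
        return "high"
    if 0.1 <= ratio <= 1:
        return "moderate"
    if ratio < 0.01:
        return "very_low"
    return "intermediate"


def count_classes(matrix: ExpressionMatrix, label: str) -> int:
    if label not in CLASS_LABELS:
        raise ValueError(f"unknown fold class {label!r}")
    return int((matrix.classes == label).sum())


@dataclass
class ClusterResult:
    order: tuple[str, ...]
    linkage: np.ndarray
    names: tuple[str, ...]

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def cluster_rows(data) -> ClusterResult:
    """Average-linkage clustering of miRNA rows on correlation distance.

    ``data`` is an :class:`ExpressionMatrix` (its clamped logs are used) or
    a DataFrame.  Rows are pre-sorted by name so the result is invariant
    under input row permutation; there is no randomness.  A constant
    (zero-variance) row has undefined correlation and is placed at
    distance 1 from everything, with a warning.
    """
    df = data.clamped if isinstance(data, ExpressionMatrix) else data
    if df.shape[0] < 2:
        raise ValueError("need at least two rows to cluster")
    df = df.sort_index(kind="stable")
    names = tuple(df.index)
    x = df.to_numpy(dtype=float)
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    constant = norms == 0
    if constant.any():
        warnings.warn(
            f"constant row(s) {list(np.array(names)[constant])}: "
            "correlation undefined, using distance 1",
            stacklevel=2,
        )
    safe = np.where(constant, 1.0, norms)
    corr = (centered @ centered.T) / np.outer(safe, safe)
    dist = 1.0 - corr
    dist[constant, :] = 1.0
    dist[:, constant] = 1.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = linkage(squareform(dist, checks=False), method="average")
    order = tuple(names[i] for i in leaves_list(z))
    return ClusterResult(order, z, names)


def cluster_to_nested_text(res: ClusterResult) -> str:
    """Merge tree as newick-like nested text with merge heights."""
    n = len(res.names)
    nodes: dict[int, str] = {i: res.names[i] for i in range(n)}
    for k, (a, b, h, _cnt) in enumerate(res.linkage):
        nodes[n + k] = f"({nodes[int(a)]},{nodes[int(b)]}):{h:.4f}"
    return nodes[n + len(res.linkage) - 1] + ";"
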