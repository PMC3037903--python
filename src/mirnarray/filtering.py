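"""Gene filtering: control removal, detection flags, expression thresholds.

A gene is kept by the detection filter when, in at least one experimental
group, the percentage of arrays on which it is flagged detected reaches the
limit L (e.g. with 4 replicates per group, requiring detection in at least 3
means L = 75).  The stricter expression filter instead requires the
normalized signal to exceed a per-array threshold — the mean of that array's
negative-control signals plus 1.5 times their standard deviation — in at
least L percent of the arrays of some group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .afe_io import ProbeLevelDataset
from .preprocess import ExpressionMatrix

REASON_CONTROL = "control"
REASON_NOT_DETECTED = "not_detected"
REASON_BELOW_THRESHOLD = "below_threshold"


@dataclass
class FilterReport:
    """Partition of the input genes into retained and removed (with reasons)."""

    retained: list[str]
    removed: list[tuple[str, str]]  # (gene, reason code)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        kept = set(self.retained)
        dropped = {g for g, _ in self.removed}
        if kept & dropped:
            raise ValueError("retained and removed gene sets overlap")

    @property
    def removed_genes(self) -> list[str]:
        return [g for g, _ in self.removed]

    def merge(self, other: "FilterReport") -> "FilterReport":
        """Compose with a downstream report applied to this report's survivors."""
        params = dict(self.params)
        params.update(other.params)
        return FilterReport(list(other.retained), self.removed + other.removed, params)

    def write(self, path: str | Path) -> None:
        rows = [(g, "retained", "") for g in self.retained] + [
            (g, "removed", r) for g, r in self.removed
        ]
        pd.DataFrame(rows, columns=["GeneName", "status", "reason"]).to_csv(
            path, sep="\t", index=False
        )


def remove_controls(dataset: ProbeLevelDataset) -> tuple[ProbeLevelDataset, FilterReport]:
    """Drop positive/negative control spots, keeping only miRNA gene features."""
    keep = dataset.control_type == 0
    removed_genes = sorted(set(dataset.gene_name[~keep]))
    retained = list(dict.fromkeys(dataset.gene_name[keep]))
    report = FilterReport(retained, [(g, REASON_CONTROL) for g in removed_genes])
    return dataset.subset_spots(keep), report


def gene_detection_flags(dataset: ProbeLevelDataset) -> pd.DataFrame:
    """Gene x array 0/1 detection matrix: a gene is detected on an array when
    any of its spots carries the detected flag."""
    mask = dataset.control_type == 0
    frame = pd.DataFrame(dataset.is_gene_detected[mask])
    return frame.groupby(pd.Series(dataset.gene_name[mask]), sort=False).max()


def _group_arrays(groups: Sequence[int]) -> dict[int, np.ndarray]:
    groups = np.asarray(groups)
    out = {}
    for g in np.unique(groups):
        cols = np.flatnonzero(groups == g)
        if cols.size == 0:
            raise ValueError(f"experimental group {g} has no arrays")
        out[int(g)] = cols
    if not out:
        raise ValueError("no experimental groups")
    return out


def detection_filter(
    flags: pd.DataFrame, groups: Sequence[int], limit: float
) -> FilterReport:
    """Keep genes whose within-group detection percentage reaches ``limit``.

    ``flags`` is a gene x array 0/1 matrix (see :func:`gene_detection_flags`),
    ``groups`` the per-array group codes, ``limit`` a percentage in [0, 100].
    """
    if not 0 <= limit <= 100:
        raise ValueError("limit must be a percentage in [0, 100]")
    cols = _group_arrays(groups)
    values = flags.to_numpy()
    best = np.zeros(len(flags))
    for idx in cols.values():
        pct = 100.0 * values[:, idx].mean(axis=1)
        best = np.maximum(best, pct)
    keep = best >= limit
    retained = [g for g, k in zip(flags.index, keep) if k]
    removed = [(g, REASON_NOT_DETECTED) for g, k in zip(flags.index, keep) if not k]
    return FilterReport(retained, removed, {"limit_detect": limit})


def negative_control_threshold(negctrl_values: np.ndarray) -> np.ndarray:
    """Per-array threshold: mean + 1.5 * sd of the negative-control signals.

    ``negctrl_values`` is a (n_controls, n_arrays) matrix on the same scale as
    the expression values; the sd uses the n-1 denominator.
    """
    values = np.asarray(negctrl_values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    if values.shape[0] < 2:
        raise ValueError("at least 2 negative-control values per array are required")
    return values.mean(axis=0) + 1.5 * values.std(axis=0, ddof=1)


def expression_filter(
    exprs: ExpressionMatrix,
    thresholds: np.ndarray,
    limit: float,
    groups: Sequence[int] | None = None,
) -> FilterReport:
    """Keep genes above the per-array threshold in >= ``limit`` percent of the
    arrays of at least one group.  Thresholds must share the log2 scale of
    ``exprs`` (a mismatch is not detectable here)."""
    if not 0 <= limit <= 100:
        raise ValueError("limit must be a percentage in [0, 100]")
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.shape != (exprs.n_arrays,):
        raise ValueError("one threshold per array is required")
    if groups is None:
        groups = exprs.groups
    cols = _group_arrays(groups)
    above = exprs.values > thresholds[None, :]
    best = np.zeros(exprs.n_genes)
    for idx in cols.values():
        best = np.maximum(best, 100.0 * above[:, idx].mean(axis=1))
    keep = best >= limit
    retained = [g for g, k in zip(exprs.gene_names, keep) if k]
    removed = [(g, REASON_BELOW_THRESHOLD) for g, k in zip(exprs.gene_names, keep) if not k]
    return FilterReport(retained, removed, {"limit_expr": limit})


def filter_expression(
    exprs: ExpressionMatrix,
    limit_detect: float | None = 75.0,
    limit_expr: float | None = None,
    detection: pd.DataFrame | None = None,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Apply the optional detection and expression-threshold filters in order.

    ``detection`` is the gene x array flag matrix; when ``limit_expr`` is set
    the per-array thresholds come from the negative-control signals carried on
    ``exprs``.  Filtering only drops rows, never alters surviving values.
    """
    report = FilterReport(list(exprs.gene_names), [])
    if limit_detect is not None:
        if detection is None:
            raise ValueError("detection flags are required for the detection filter")
        flags = detection.reindex(exprs.gene_names).fillna(0)
        report = report.merge(detection_filter(flags, exprs.groups, limit_detect))
        exprs = exprs.subset_genes(report.retained)
    if limit_expr is not None:
        if exprs.negative_control_log2 is None:
            raise ValueError(
                "expression-threshold filter requires negative-control signals"
            )
        thresholds = negative_control_threshold(exprs.negative_control_log2)
        report = report.merge(expression_filter(exprs, thresholds, limit_expr))
        exprs = exprs.subset_genes(report.retained)
    return exprs, report
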