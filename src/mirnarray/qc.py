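"""Quality assessment: reproducibility CV, reference-array MA/RLE, clustering.

The arrays' built-in probe replication (16 spots per miRNA gene) is used to
compute a per-array coefficient of variation: the CV of each replicated probe
set and its median over probe sets, one value per array.  Distribution plots
(boxplot, density), MA plots against a median reference array, relative log
expression (RLE) boxplots and a sample dendrogram round out the report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram, linkage

from .afe_io import ProbeLevelDataset
from .preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class QCSummary:
    """Per-array QC numbers: reproducibility CV, RLE median and IQR."""

    array_names: list[str]
    cv: np.ndarray
    rle_median: np.ndarray
    rle_iqr: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Array": self.array_names,
                "CV": self.cv,
                "RLE_median": self.rle_median,
                "RLE_IQR": self.rle_iqr,
            }
        )


def array_reproducibility_cv(dataset: ProbeLevelDataset) -> np.ndarray:
    """Median over replicated probe sets of sd/mean of the raw mean signal.

    Control probes are excluded, as are probes with fewer than two replicate
    spots or zero mean (logged).  One value per array; lower is better.
    """
    mask = dataset.control_type == 0
    probes = pd.Series(dataset.probe_name[mask])
    frame = pd.DataFrame(dataset.mean_signal[mask])
    counts = probes.value_counts()
    eligible = counts[counts >= 2].index
    if len(eligible) == 0:
        raise ValueError("no non-control probe has >= 2 replicate spots")
    grouped = frame.groupby(probes, sort=False)
    means = grouped.mean()
    sds = grouped.std(ddof=1)
    means = means.loc[means.index.isin(eligible)]
    sds = sds.loc[means.index]
    zero = (means == 0).any(axis=1)
    if zero.any():
        logger.info("excluding %d probe(s) with zero mean from the CV", int(zero.sum()))
        means, sds = means[~zero], sds[~zero]
    if means.empty:
        raise ValueError("no eligible probes remain for the CV computation")
    cv = sds / means
    return cv.median(axis=0).to_numpy()


def reference_array(matrix: np.ndarray) -> np.ndarray:
    """Element-wise median across arrays: each spot of the reference array is
    the median of the corresponding spots in all arrays."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] == 0:
        raise ValueError("reference array requires a non-empty spots x arrays matrix")
    return np.median(matrix, axis=1)


def ma_values(matrix: np.ndarray, array_index: int) -> tuple[np.ndarray, np.ndarray]:
    """(A, M) of one array against the median reference, on log2 input:
    M = x - reference, A = (x + reference) / 2."""
    matrix = np.asarray(matrix, dtype=float)
    if not 0 <= array_index < matrix.shape[1]:
        raise IndexError(f"array index {array_index} out of range")
    ref = reference_array(matrix)
    x = matrix[:, array_index]
    return (x + ref) / 2.0, x - ref


def rle_values(matrix: np.ndarray) -> np.ndarray:
    """Relative log expression: each spot minus the reference-array spot."""
    matrix = np.asarray(matrix, dtype=float)
    return matrix - reference_array(matrix)[:, None]


def cluster_samples(
    matrix: np.ndarray,
    gene_names: Sequence[str] | None = None,
    gene_subset: Sequence[str] | None = None,
) -> np.ndarray:
    """Hierarchically cluster arrays (complete linkage, Euclidean distance).

    ``gene_subset`` restricts the profile to the named genes.  Returns a scipy
    linkage matrix; deterministic for a given input.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[1] < 2:
        raise ValueError("clustering requires at least 2 arrays")
    if gene_subset is not None:
        if gene_names is None:
            raise ValueError("gene_subset requires gene_names")
        index = {g: i for i, g in enumerate(gene_names)}
        rows = [index[g] for g in gene_subset if g in index]
        if not rows:
            raise KeyError("gene_subset is disjoint from the gene names")
        matrix = matrix[rows]
    return linkage(matrix.T, method="complete", metric="euclidean")


def qc_summary(dataset: ProbeLevelDataset, processed: ExpressionMatrix) -> QCSummary:
    cv = array_reproducibility_cv(dataset)
    rle = rle_values(processed.values)
    q1, med, q3 = np.percentile(rle, [25, 50, 75], axis=0)
    return QCSummary(processed.array_names, cv, med, q3 - q1)


def qc_report(
    dataset: ProbeLevelDataset,
    processed: ExpressionMatrix,
    out_dir: str | Path,
    image_format: str = "png",
) -> list[Path]:
    """Write boxplot, density, MA, RLE and dendrogram images plus a QC table.

    With a single array the MA/RLE/dendrogram panels are skipped with a log
    note.  Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    values = processed.values
    names = processed.array_names
    written: list[Path] = []

    def save(fig, stem: str) -> None:
        path = out_dir / f"{stem}.{image_format}"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot([values[:, j] for j in range(values.shape[1])], tick_labels=names)
    ax.set_ylabel("log2 signal")
    ax.set_title("Processed signal per array")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    save(fig, "boxplot")

    fig, ax = plt.subplots(figsize=(6, 4))
    grid = np.linspace(values.min(), values.max(), 200)
    for j, name in enumerate(names):
        from scipy.stats import gaussian_kde

        col = values[:, j]
        if np.ptp(col) > 0:
            ax.plot(grid, gaussian_kde(col)(grid), label=name)
    ax.set_xlabel("log2 signal")
    ax.set_ylabel("density")
    ax.legend(fontsize=6)
    fig.tight_layout()
    save(fig, "density")

    if values.shape[1] >= 2:
        fig, axes = plt.subplots(
            1, values.shape[1], figsize=(3 * values.shape[1], 3), squeeze=False
        )
        for j, name in enumerate(names):
            a, m = ma_values(values, j)
            axes[0, j].scatter(a, m, s=2, alpha=0.4)
            axes[0, j].axhline(0.0, color="red", lw=0.8)
            axes[0, j].set_title(name, fontsize=8)
            axes[0, j].set_xlabel("A")
            axes[0, j].set_ylabel("M")
        fig.tight_layout()
        save(fig, "ma_plots")

        fig, ax = plt.subplots(figsize=(6, 4))
        rle = rle_values(values)
        ax.boxplot([rle[:, j] for j in range(rle.shape[1])], tick_labels=names)
        ax.axhline(0.0, color="red", lw=0.8)
        ax.set_ylabel("RLE")
        ax.tick_params(axis="x", rotation=45)
        fig.tight_layout()
        save(fig, "rle")

        fig, ax = plt.subplots(figsize=(6, 4))
        dendrogram(cluster_samples(values), labels=names, ax=ax)
        ax.set_ylabel("height")
        fig.tight_layout()
        save(fig, "dendrogram")
    else:
        logger.info("single array: skipping MA, RLE and dendrogram panels")

    summary = qc_summary(dataset, processed) if values.shape[1] >= 1 else None
    if summary is not None:
        path = out_dir / "qc_summary.tsv"
        summary.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")
        written.append(path)
    return written
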