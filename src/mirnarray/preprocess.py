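"""Two pre-processing protocols for single-color miRNA array signals.

Protocol ``tgs``: take the image software's per-gene TotalGeneSignal, make it
positive (floor at 0.5 by default, or shift by |min| + offset), log2 it, and
normalize between arrays (quantile by default, or scale).

Protocol ``rma``: robust multiarray average on the raw per-spot mean signal —
1) optional background correction under the normal + exponential convolution
model, 2) quantile normalization between arrays, 3) log2 transform, 4) median
over replicate spots of each probe, 5) summarization of each gene's probes by
median polish of the additive probe-affinity + array-effect model.  Background
correction defaults to off, which for these arrays gives less variable signal
at low intensities.

The matrix-level steps are exposed both as sklearn-style transformers
(samples = arrays in rows) and as plain functions on gene/probe x array
matrices; the transformers are the implementation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .afe_io import ProbeLevelDataset

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# containers


@dataclass
class ExpressionMatrix:
    """Gene-by-array log2 expression with group labels and provenance."""

    values: np.ndarray  # (n_genes, n_arrays), log2 scale
    gene_names: list[str]
    array_names: list[str]
    groups: np.ndarray  # integer group code per array (GErep)
    treatments: list[str]
    method: str  # "tgs" | "rma"
    options: dict = field(default_factory=dict)
    gene_probes: Mapping[str, list[str]] = field(default_factory=dict)
    negative_control_log2: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_names), len(self.array_names)):
            raise ValueError("values shape does not match gene/array names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ValueError("gene names must be unique")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_arrays(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_names)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"unknown gene(s): {', '.join(missing[:5])}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(
            values=self.values[rows],
            gene_names=list(genes),
            array_names=self.array_names,
            groups=self.groups,
            treatments=self.treatments,
            method=self.method,
            options=dict(self.options),
            gene_probes={g: self.gene_probes.get(g, []) for g in genes},
            negative_control_log2=self.negative_control_log2,
            metadata=dict(self.metadata),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_names, columns=self.array_names)

    def write(self, path: str | Path) -> None:
        """Tab-delimited matrix plus a sidecar ``.meta.tsv`` with provenance."""
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index_label="GeneName")
        meta = [("method", self.method)] + sorted(
            (k, repr(v)) for k, v in self.options.items()
        )
        pd.DataFrame(meta, columns=["key", "value"]).to_csv(
            path.with_suffix(".meta.tsv"), sep="\t", index=False
        )


@dataclass(frozen=True)
class NormexpParams:
    """Parameters of the normal + exponential convolution model.

    ``mu``/``sigma`` describe the normal background, ``alpha`` the mean of the
    exponential true signal; all in linear intensity units.
    """

    mu: float
    sigma: float
    alpha: float

    def __post_init__(self) -> None:
        if not (self.sigma > 0 and self.alpha > 0):
            raise ValueError("sigma and alpha must be positive")


# ---------------------------------------------------------------------------
# negative TGS correction


def correct_negative_tgs(
    matrix: np.ndarray, method: str = "half", offset: float = 50.0
) -> np.ndarray:
    """Make a linear-scale TGS matrix positive before log transformation.

    ``half`` replaces every value below 0.5 by 0.5 (default); ``offset`` adds
    |global minimum| + offset to every value.
    """
    matrix = np.asarray(matrix, dtype=float)
    if method == "half":
        return np.where(matrix < 0.5, 0.5, matrix)
    if method == "offset":
        if offset < 0:
            raise ValueError("offset must be nonnegative")
        shifted = matrix + abs(float(matrix.min())) + offset
        if shifted.size and shifted.min() <= 0:
            raise ValueError(
                "offset correction left non-positive values; use a positive offset"
            )
        return shifted
    raise ValueError(f"unknown negative-value method {method!r}")


# ---------------------------------------------------------------------------
# between-array normalization (sklearn transformers; samples = arrays)


class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Force every array onto a common empirical distribution.

    ``fit`` computes the reference distribution as the mean of the per-array
    sorted values; ``transform`` maps each array's values onto it by rank,
    ties receiving the mean of the reference values at their tied ranks.
    Rows are arrays, columns are genes/probes.
    """

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=1)
        self.n_features_in_ = X.shape[1]
        self.reference_distribution_ = np.sort(X, axis=1).mean(axis=0)
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_distribution_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("transform requires the same number of features as fit")
        target = self.reference_distribution_
        out = np.empty_like(X, dtype=float)
        for i, row in enumerate(X):
            out[i] = _map_to_distribution(row, target)
        return out


def _map_to_distribution(values: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Replace values by target quantiles; ties get the mean target value."""
    order = np.argsort(values, kind="stable")
    out = np.empty_like(values, dtype=float)
    sorted_vals = values[order]
    # runs of equal values share the mean of the target over their rank span
    n = len(values)
    start = 0
    while start < n:
        stop = start + 1
        while stop < n and sorted_vals[stop] == sorted_vals[start]:
            stop += 1
        out[order[start:stop]] = target[start:stop].mean()
        start = stop
    return out


class ScaleNormalizer(TransformerMixin, BaseEstimator):
    """Shift each array (log2 scale) so all medians equal the mean median."""

    def fit(self, X, y=None):
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        self.target_median_ = float(np.median(X, axis=1).mean())
        return self

    def transform(self, X):
        check_is_fitted(self, "target_median_")
        X = check_array(X)
        medians = np.median(X, axis=1)
        return X + (self.target_median_ - medians)[:, None]


def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Quantile-normalize a gene/probe x array matrix between arrays."""
    matrix = np.asarray(matrix, dtype=float)
    return QuantileNormalizer().fit_transform(matrix.T).T


def scale_normalize(matrix: np.ndarray) -> np.ndarray:
    """Median-center arrays of a log2 gene x array matrix to a common median."""
    matrix = np.asarray(matrix, dtype=float)
    return ScaleNormalizer().fit_transform(matrix.T).T


# ---------------------------------------------------------------------------
# normexp background correction


def _kde_mode(x: np.ndarray) -> float:
    """Location of the maximum of a Silverman-bandwidth Gaussian KDE."""
    kde = stats.gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def _heuristic_start(x: np.ndarray) -> tuple[float, float, float]:
    """Starting values for the likelihood fit.

    Method of moments when the third central moment is usable (mean = mu +
    alpha, variance = sigma^2 + alpha^2, third moment = 2 alpha^3);
    otherwise a density-mode heuristic: mu at the KDE mode refined on the
    sub-mode data, sigma from the RMS spread below the mode (mean-absolute
    fallback under 50 points), alpha from the mean excess above it.
    """
    m1 = x.mean()
    var = x.var()
    m3 = np.mean((x - m1) ** 3)
    if m3 > 0:
        alpha = (m3 / 2.0) ** (1.0 / 3.0)
        if var > alpha**2:
            return m1 - alpha, np.sqrt(var - alpha**2), alpha
    mu = _kde_mode(x)
    for _ in range(2):
        lower = x[x < mu]
        if lower.size < 100 or np.ptp(lower) == 0:
            break
        mu = _kde_mode(lower)
    below = mu - x[x < mu]
    above = x[x > mu] - mu
    if below.size == 0 or above.size == 0:
        raise ValueError("degenerate intensity distribution: no mass on one side of the mode")
    if below.size >= 50:
        sigma = float(np.sqrt(np.mean(below**2)))
    else:
        sigma = float(np.sqrt(np.pi / 2.0) * np.mean(below))
    return mu, sigma, float(np.mean(above))


def _normexp_nll(theta: np.ndarray, x: np.ndarray) -> float:
    mu, log_sigma, log_alpha = theta
    sigma = np.exp(log_sigma)
    alpha = np.exp(log_alpha)
    z = (x - mu - sigma**2 / alpha) / sigma
    loglik = (
        -np.log(alpha)
        + sigma**2 / (2.0 * alpha**2)
        - (x - mu) / alpha
        + stats.norm.logcdf(z)
    )
    return -float(loglik.sum())


def normexp_fit(intensities: np.ndarray) -> NormexpParams:
    """Maximum-likelihood fit of the normal + exponential convolution model.

    The observed intensity is modelled as X = B + S with background
    B ~ N(mu, sigma^2) and true signal S ~ Exp(mean alpha); the likelihood
    is maximized over (mu, log sigma, log alpha) from a method-of-moments
    start (density-mode heuristic as fallback).
    """
    x = np.asarray(intensities, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 100:
        raise ValueError(f"normexp fit requires >= 100 finite values, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("normexp fit is undefined for a constant vector")
    mu0, sigma0, alpha0 = _heuristic_start(x)
    sigma0 = max(sigma0, 1e-6 * np.ptp(x))
    alpha0 = max(alpha0, 1e-6 * np.ptp(x))
    from scipy.optimize import minimize

    res = minimize(
        _normexp_nll,
        x0=np.array([mu0, np.log(sigma0), np.log(alpha0)]),
        args=(x,),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
    )
    mu, log_sigma, log_alpha = res.x
    return NormexpParams(mu=float(mu), sigma=float(np.exp(log_sigma)), alpha=float(np.exp(log_alpha)))


def normexp_adjust(intensities: np.ndarray, params: NormexpParams) -> np.ndarray:
    """Conditional expectation of the true signal given the observed value.

    With a = x - mu - sigma^2/alpha, returns a + sigma * phi(a/sigma) /
    Phi(a/sigma); computed through log-densities so that deep-tail inputs
    never underflow to zero or negative output.
    """
    x = np.asarray(intensities, dtype=float)
    a = x - params.mu - params.sigma**2 / params.alpha
    z = a / params.sigma
    mills = np.exp(stats.norm.logpdf(z) - stats.norm.logcdf(z))
    return a + params.sigma * mills


class NormExpBackground(TransformerMixin, BaseEstimator):
    """Per-array normexp background correction (rows are arrays).

    Model parameters are intrinsic to each array, so ``transform`` fits and
    adjusts each row independently; ``fit`` only validates and records the
    fitted parameters for inspection.
    """

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_features=100)
        self.n_features_in_ = X.shape[1]
        self.params_ = [normexp_fit(row) for row in X]
        return self

    def transform(self, X):
        X = check_array(X)
        return np.vstack([normexp_adjust(row, normexp_fit(row)) for row in X])


# ---------------------------------------------------------------------------
# probe handling and median-polish summarization


def median_replicate_probes(
    matrix: np.ndarray, probe_names: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Collapse replicate spots of each probe to their per-array median.

    Returns (distinct-probe x array matrix, probe names in first-appearance
    order).  Even replicate counts use the mean of the central pair.
    """
    frame = pd.DataFrame(np.asarray(matrix, dtype=float))
    grouped = frame.groupby(pd.Series(list(probe_names)), sort=False).median()
    return grouped.to_numpy(), list(grouped.index)


@dataclass
class MedianPolishResult:
    overall: float
    row_effects: np.ndarray
    col_effects: np.ndarray
    residuals: np.ndarray
    n_iter: int
    converged: bool

    def fitted(self) -> np.ndarray:
        return self.overall + self.row_effects[:, None] + self.col_effects[None, :]


def median_polish(
    matrix: np.ndarray, tol: float = 0.01, max_iter: int = 10
) -> MedianPolishResult:
    """Tukey's median polish of an additive two-way model.

    Alternately sweeps row and column medians into the effects until the sum
    of absolute residuals changes by less than ``tol`` (relative) or
    ``max_iter`` is reached.  ``overall + row + col + residual`` reconstructs
    the input exactly at every iteration.
    """
    z = np.array(matrix, dtype=float)
    if z.ndim != 2 or z.size == 0:
        raise ValueError("median polish requires a non-empty 2-d matrix")
    nr, nc = z.shape
    overall = 0.0
    row_eff = np.zeros(nr)
    col_eff = np.zeros(nc)
    oldsum = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        rdelta = np.median(z, axis=1)
        z -= rdelta[:, None]
        row_eff += rdelta
        delta = np.median(col_eff)
        col_eff -= delta
        overall += delta

        cdelta = np.median(z, axis=0)
        z -= cdelta[None, :]
        col_eff += cdelta
        delta = np.median(row_eff)
        row_eff -= delta
        overall += delta

        newsum = float(np.abs(z).sum())
        if newsum == 0 or abs(newsum - oldsum) < tol * newsum:
            converged = True
            break
        oldsum = newsum
    return MedianPolishResult(overall, row_eff, col_eff, z, it, converged)


class RMASummarizer(TransformerMixin, BaseEstimator):
    """Summarize log2 probe-level data into per-gene values by median polish.

    Rows are arrays; column ``k`` carries the probe ``probe_names[k]``, which
    ``probe_to_gene`` maps to its gene.  The per-gene array value is the
    fitted overall effect plus that array's effect; single-probe genes pass
    through unchanged.  Output genes follow probe first-appearance order and
    are exposed as ``gene_names_`` after fitting.
    """

    def __init__(
        self,
        probe_names: Sequence[str] | None = None,
        probe_to_gene: Mapping[str, str] | None = None,
        tol: float = 0.01,
        max_iter: int = 10,
    ):
        self.probe_names = probe_names
        self.probe_to_gene = probe_to_gene
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        X = check_array(X)
        if self.probe_names is None or self.probe_to_gene is None:
            raise ValueError("probe_names and probe_to_gene are required")
        if X.shape[1] != len(self.probe_names):
            raise ValueError(
                f"X has {X.shape[1]} probe columns, expected {len(self.probe_names)}"
            )
        unmapped = [p for p in self.probe_names if p not in self.probe_to_gene]
        if unmapped:
            raise KeyError(f"probe(s) not mapped to a gene: {', '.join(unmapped[:5])}")
        self.n_features_in_ = X.shape[1]
        genes: list[str] = []
        cols_of: dict[str, list[int]] = {}
        for k, p in enumerate(self.probe_names):
            g = self.probe_to_gene[p]
            if g not in cols_of:
                cols_of[g] = []
                genes.append(g)
            cols_of[g].append(k)
        self.gene_names_ = genes
        self._gene_columns = cols_of
        return self

    def transform(self, X):
        check_is_fitted(self, "gene_names_")
        X = check_array(X)
        out = np.empty((X.shape[0], len(self.gene_names_)))
        for gi, g in enumerate(self.gene_names_):
            sub = X[:, self._gene_columns[g]].T  # probes x arrays
            if sub.shape[0] == 1:
                out[:, gi] = sub[0]
            else:
                fit = median_polish(sub, tol=self.tol, max_iter=self.max_iter)
                out[:, gi] = fit.overall + fit.col_effects
        return out


def summarize_rma(
    probe_matrix: np.ndarray,
    probe_names: Sequence[str],
    probe_to_gene: Mapping[str, str],
    tol: float = 0.01,
    max_iter: int = 10,
) -> tuple[np.ndarray, list[str]]:
    """Median-polish summarization of a probe x array log2 matrix.

    Returns (gene x array matrix, gene names in first-appearance order).
    """
    summarizer = RMASummarizer(
        probe_names=list(probe_names), probe_to_gene=probe_to_gene, tol=tol, max_iter=max_iter
    )
    values = summarizer.fit_transform(np.asarray(probe_matrix, dtype=float).T)
    return values.T, summarizer.gene_names_


# ---------------------------------------------------------------------------
# full protocols


def _gene_probe_map(dataset: ProbeLevelDataset, mask: np.ndarray) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for g, p in zip(dataset.gene_name[mask], dataset.probe_name[mask]):
        out.setdefault(g, [])
        if p not in out[g]:
            out[g].append(p)
    return out


def _negative_control_log2(dataset: ProbeLevelDataset) -> np.ndarray | None:
    neg = dataset.control_type == -1
    if not neg.any():
        return None
    vals = correct_negative_tgs(dataset.processed_signal[neg], method="half")
    return np.log2(vals)


def tgs_pipeline(
    dataset: ProbeLevelDataset,
    normalization: str = "quantile",
    negative_method: str = "half",
    offset: float = 50.0,
) -> ExpressionMatrix:
    """Protocol 1: normalize the image software's TotalGeneSignal.

    Collapses the per-spot TGS to one row per gene (it is constant over a
    gene's spots), corrects negatives, log2-transforms, then normalizes
    between arrays on the log2 scale.
    """
    mask = dataset.control_type == 0
    if not mask.any():
        raise ValueError("dataset contains no miRNA gene features")
    genes: list[str] = []
    rows = []
    first_spot: dict[str, int] = {}
    for i in np.flatnonzero(mask):
        g = dataset.gene_name[i]
        if g not in first_spot:
            first_spot[g] = i
            genes.append(g)
            rows.append(dataset.total_gene_signal[i])
        else:
            if not np.allclose(
                dataset.total_gene_signal[i], dataset.total_gene_signal[first_spot[g]]
            ):
                raise ValueError(f"TotalGeneSignal is not constant over spots of gene {g!r}")
    tgs = np.asarray(rows, dtype=float)
    tgs = correct_negative_tgs(tgs, method=negative_method, offset=offset)
    log2_tgs = np.log2(tgs)
    if normalization == "quantile":
        values = quantile_normalize(log2_tgs)
    elif normalization == "scale":
        values = scale_normalize(log2_tgs)
    elif normalization == "none":
        values = log2_tgs
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return ExpressionMatrix(
        values=values,
        gene_names=genes,
        array_names=dataset.array_names,
        groups=dataset.targets.ge_rep,
        treatments=dataset.targets.treatments,
        method="tgs",
        options={
            "normalization": normalization,
            "negative_method": negative_method,
            "offset": offset,
        },
        gene_probes=_gene_probe_map(dataset, mask),
        negative_control_log2=_negative_control_log2(dataset),
    )


def rma_pipeline(
    dataset: ProbeLevelDataset,
    background: bool = False,
    normalization: str = "quantile",
) -> ExpressionMatrix:
    """Protocol 2: robust multiarray average of the raw mean signal.

    Steps, on non-control spots: optional normexp background correction per
    array; quantile normalization between arrays (on the linear scale, per
    the protocol's step order); log2; median over each probe's replicate
    spots; median-polish summarization per gene.
    """
    mask = dataset.control_type == 0
    if not mask.any():
        raise ValueError("dataset contains no miRNA gene features")
    signal = dataset.mean_signal[mask]
    if background:
        corrected = np.empty_like(signal)
        for j in range(signal.shape[1]):
            params = normexp_fit(signal[:, j])
            corrected[:, j] = normexp_adjust(signal[:, j], params)
        signal = corrected
    if normalization == "quantile":
        signal = quantile_normalize(signal)
    elif normalization != "none":
        raise ValueError(f"unknown normalization {normalization!r}")
    if signal.min() <= 0:
        logger.info("flooring %d non-positive signals at 0.5 before log2", int((signal <= 0).sum()))
        signal = np.where(signal < 0.5, 0.5, signal)
    log2_signal = np.log2(signal)
    probe_matrix, probe_names = median_replicate_probes(log2_signal, dataset.probe_name[mask])
    probe_to_gene = {}
    for p, g in zip(dataset.probe_name[mask], dataset.gene_name[mask]):
        probe_to_gene.setdefault(p, g)
    values, genes = summarize_rma(probe_matrix, probe_names, probe_to_gene)
    return ExpressionMatrix(
        values=values,
        gene_names=genes,
        array_names=dataset.array_names,
        groups=dataset.targets.ge_rep,
        treatments=dataset.targets.treatments,
        method="rma",
        options={"background": background, "normalization": normalization},
        gene_probes=_gene_probe_map(dataset, mask),
        negative_control_log2=_negative_control_log2(dataset),
    )
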