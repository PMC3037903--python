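"""Gene-wise linear models with empirical-Bayes moderated statistics.

Every gene g gets an ordinary least-squares fit of its log2 expression on a
shared design matrix, giving coefficient estimates, a residual standard
deviation s_g on d_g degrees of freedom, and unscaled standard deviations u
from the design geometry.  The gene-wise variances are then shrunk toward a
prior: assuming s_g^2 ~ s0^2 chi^2_{d_g}/d_g with s0^2 itself scaled inverse
chi-square with d0 degrees of freedom, the posterior variance is

    s~_g^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g),

and the moderated t-statistic t~ = beta_c / (u_c s~_g) is referred to a t
distribution on d0 + d_g degrees of freedom.  (d0, s0^2) are estimated by
moment-matching the log variances through digamma/trigamma identities.  An
analogous moderated F covers several contrasts at once.

The machinery is packaged as the sklearn-style estimator
:class:`ModeratedLinearModel` (samples = arrays); the module functions wrap
it in the gene x array orientation of the rest of the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .afe_io import TargetTable
from .preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)

MIRBASE_URL = "http://microrna.sanger.ac.uk/cgi-bin/sequences/mirna_entry.pl?id="

RESULT_COLUMNS = ["Probe", "Gene", "M", "A", "t", "pval", "adj.pval", "fdr.pval"]


# ---------------------------------------------------------------------------
# design and contrast matrices


@dataclass
class DesignMatrix:
    """Arrays x coefficients matrix with treatment-mean coding.

    One indicator column per treatment group (no intercept), so contrasts are
    direct group differences; blocking covariates enter as centered
    indicator columns for their non-reference levels.
    """

    values: np.ndarray
    coef_names: list[str]
    factors: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != len(self.coef_names):
            raise ValueError("coefficient names do not match design columns")
        rank = np.linalg.matrix_rank(self.values)
        if rank < self.values.shape[1]:
            raise ValueError(
                "design matrix is rank deficient; confounded column(s): "
                + ", ".join(_confounded_columns(self.values, self.coef_names))
            )

    @property
    def n_arrays(self) -> int:
        return self.values.shape[0]

    @property
    def rank(self) -> int:
        return self.values.shape[1]


def _confounded_columns(values: np.ndarray, names: Sequence[str]) -> list[str]:
    from scipy.linalg import qr

    r = np.linalg.matrix_rank(values)
    _, _, piv = qr(values, pivoting=True)
    return [names[i] for i in sorted(piv[r:])]


@dataclass
class ContrastMatrix:
    """Coefficients x contrasts matrix."""

    values: np.ndarray
    contrast_names: list[str]
    coef_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.coef_names), len(self.contrast_names)):
            raise ValueError("contrast matrix shape does not match names")
        if (self.values == 0).all(axis=0).any():
            raise ValueError("contrast matrix contains an all-zero contrast")


def build_design(targets: TargetTable, factors: Sequence[str] = ("Treatment",)) -> DesignMatrix:
    """Build a design matrix from target-file factors.

    The first factor must be ``Treatment`` (or another column defining the
    groups of interest) and is coded as one indicator per level; subsequent
    factors are blocking covariates coded as centered indicators.
    """
    frame = targets.frame
    for f in factors:
        if f not in frame.columns:
            raise KeyError(f"factor {f!r} is not a column of the target file")
    primary, *blocking = factors
    levels = list(dict.fromkeys(str(v) for v in frame[primary]))
    cols = [np.asarray([1.0 if str(v) == lev else 0.0 for v in frame[primary]]) for lev in levels]
    names = list(levels)
    for f in blocking:
        flevels = list(dict.fromkeys(str(v) for v in frame[f]))
        for lev in flevels[1:]:
            ind = np.asarray([1.0 if str(v) == lev else 0.0 for v in frame[f]])
            cols.append(ind - ind.mean())
            names.append(f"{f}{lev}")
    return DesignMatrix(np.column_stack(cols), names, list(factors))


def make_contrasts(specs: Sequence[str], design: DesignMatrix) -> ContrastMatrix:
    """Parse contrast strings like ``"B-A"`` into a contrast matrix."""
    matrix = np.zeros((len(design.coef_names), len(specs)))
    index = {n: i for i, n in enumerate(design.coef_names)}
    for k, spec in enumerate(specs):
        for sign, term in _parse_terms(spec):
            if term not in index:
                raise KeyError(f"contrast {spec!r} references unknown coefficient {term!r}")
            matrix[index[term], k] += sign
    return ContrastMatrix(matrix, [s.replace(" ", "") for s in specs], list(design.coef_names))


def _parse_terms(spec: str) -> list[tuple[float, str]]:
    terms = []
    token = ""
    sign = 1.0
    for ch in spec.replace(" ", "") + "+":
        if ch in "+-":
            if token:
                terms.append((sign, token))
            sign = 1.0 if ch == "+" else -1.0
            token = ""
        else:
            token += ch
    if not terms:
        raise ValueError(f"empty contrast specification {spec!r}")
    return terms


# ---------------------------------------------------------------------------
# fits and moderation


@dataclass
class LinearFit:
    """Per-gene least-squares results (possibly after contrast rotation)."""

    coefficients: np.ndarray  # genes x coefficients (or contrasts)
    stdev_unscaled: np.ndarray  # unscaled sd per coefficient, from (X'X)^-1
    sigma: np.ndarray  # residual sd per gene
    df_residual: int
    amean: np.ndarray  # mean log2 intensity per gene
    cov_coefficients: np.ndarray  # (X'X)^-1 (or C' (X'X)^-1 C)
    coef_names: list[str]
    gene_names: list[str]


@dataclass
class ModeratedStats:
    """Empirical-Bayes moderated statistics for a set of contrasts."""

    df_prior: float
    s2_prior: float
    s2_post: np.ndarray  # per gene
    t: np.ndarray  # genes x contrasts
    p_value: np.ndarray
    df_total: float
    F: np.ndarray
    F_p_value: np.ndarray
    coefficients: np.ndarray
    amean: np.ndarray
    contrast_names: list[str]
    gene_names: list[str]


def lm_fit(exprs: ExpressionMatrix, design: DesignMatrix) -> LinearFit:
    """Ordinary least squares of every gene on the shared design."""
    Y = exprs.values  # genes x arrays
    X = design.values
    if X.shape[0] != Y.shape[1]:
        raise ValueError("design rows must match expression columns")
    df_residual = X.shape[0] - design.rank
    if df_residual <= 0:
        raise ValueError("no residual degrees of freedom: add replicate arrays")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = Y @ X @ xtx_inv  # genes x p
    resid = Y - beta @ X.T
    rss = (resid**2).sum(axis=1)
    sigma = np.sqrt(rss / df_residual)
    stdev_unscaled = np.tile(np.sqrt(np.diag(xtx_inv)), (Y.shape[0], 1))
    return LinearFit(
        coefficients=beta,
        stdev_unscaled=stdev_unscaled,
        sigma=sigma,
        df_residual=df_residual,
        amean=Y.mean(axis=1),
        cov_coefficients=xtx_inv,
        coef_names=list(design.coef_names),
        gene_names=list(exprs.gene_names),
    )


def contrast_fit(fit: LinearFit, contrasts: ContrastMatrix) -> LinearFit:
    """Rotate a coefficient fit into contrast space."""
    C = contrasts.values
    if C.shape[0] != len(fit.coef_names):
        raise ValueError("contrast rows must match fit coefficients")
    cov = C.T @ fit.cov_coefficients @ C
    return LinearFit(
        coefficients=fit.coefficients @ C,
        stdev_unscaled=np.tile(np.sqrt(np.diag(cov)), (fit.coefficients.shape[0], 1)),
        sigma=fit.sigma,
        df_residual=fit.df_residual,
        amean=fit.amean,
        cov_coefficients=cov,
        coef_names=list(contrasts.contrast_names),
        gene_names=list(fit.gene_names),
    )


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma inverse requires a positive target")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) / x < 1e-10:
            break
    return x


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matching estimate of (d0, s0^2) from gene-wise variances.

    Works on e_g = log s_g^2 - psi(d/2) + log(d/2), whose mean and excess
    variance over trigamma(d/2) identify the scaled inverse chi-square prior.
    A non-positive excess gives d0 = infinity (no dispersion beyond chance).
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2 > 0
    if not positive.any():
        raise ValueError("all gene variances are zero; moderation is undefined")
    z = np.log(s2[positive])
    n = z.size
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    if n < 2:
        return np.inf, float(np.exp(emean))
    evar = float(((e - emean) ** 2).sum() / (n - 1)) - float(polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    df_prior = 2.0 * trigamma_inverse(evar)
    s2_prior = float(np.exp(emean + digamma(df_prior / 2.0) - np.log(df_prior / 2.0)))
    return df_prior, s2_prior


def moderate(fit: LinearFit, df_prior: float | None = None, s2_prior: float | None = None) -> ModeratedStats:
    """Empirical-Bayes moderation of a (contrast) fit.

    ``df_prior``/``s2_prior`` may be injected (e.g. to study the d0 -> 0
    ordinary-t limit); by default they are estimated from the data.
    """
    if fit.coefficients.shape[0] < 2:
        raise ValueError("moderation requires at least 2 genes")
    s2 = fit.sigma**2
    d = float(fit.df_residual)
    if df_prior is None or s2_prior is None:
        df_prior, s2_prior = estimate_prior(s2, d)
    if np.isinf(df_prior):
        s2_post = np.full_like(s2, s2_prior)
    else:
        s2_post = (df_prior * s2_prior + d * s2) / (df_prior + d)
    df_total = df_prior + d
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fit.coefficients / (fit.stdev_unscaled * np.sqrt(s2_post)[:, None])
    p = 2.0 * stats.t.sf(np.abs(t), df_total)

    # moderated F over all contrasts, accounting for their correlation
    cov = fit.cov_coefficients
    r = np.linalg.matrix_rank(cov)
    cov_inv = np.linalg.pinv(cov)
    quad = np.einsum("gi,ij,gj->g", fit.coefficients, cov_inv, fit.coefficients)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = quad / (r * s2_post)
    if np.isinf(df_total):
        F_p = stats.chi2.sf(F * r, r)  # F_{r,inf} limit
    else:
        F_p = stats.f.sf(F, r, df_total)
    return ModeratedStats(
        df_prior=df_prior,
        s2_prior=s2_prior,
        s2_post=s2_post,
        t=t,
        p_value=p,
        df_total=df_total,
        F=F,
        F_p_value=F_p,
        coefficients=fit.coefficients,
        amean=fit.amean,
        contrast_names=list(fit.coef_names),
        gene_names=list(fit.gene_names),
    )


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment of a p-value vector."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def decide_tests(
    stats_: ModeratedStats,
    method: str = "separated",
    adjust: str = "BH",
    cutoff: float = 0.05,
) -> pd.DataFrame:
    """Call each gene/contrast up (+1), down (-1) or not significant (0).

    ``separated`` adjusts each contrast's t p-values independently.
    ``nestedF`` first screens genes by the BH-adjusted moderated F, then
    calls contrasts within screened genes at the unadjusted t p-value (an
    approximation to gene-wise closed testing).
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must lie in (0, 1]")
    if adjust not in ("BH", "none"):
        raise ValueError(f"unknown adjust method {adjust!r}")
    signs = np.sign(stats_.coefficients).astype(int)
    if method == "separated":
        decision = np.zeros_like(signs)
        for k in range(stats_.p_value.shape[1]):
            p = stats_.p_value[:, k]
            if adjust == "BH":
                p = bh_adjust(p)
            decision[:, k] = np.where(p < cutoff, signs[:, k], 0)
    elif method == "nestedF":
        fp = stats_.F_p_value
        screened = (bh_adjust(fp) if adjust == "BH" else fp) < cutoff
        decision = np.where(
            screened[:, None] & (stats_.p_value < cutoff), signs, 0
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame(decision, index=stats_.gene_names, columns=stats_.contrast_names)


def significant_table(
    stats_: ModeratedStats,
    contrast: str,
    gene_probes: Mapping[str, Sequence[str]] | None = None,
    adjust: str = "BH",
) -> pd.DataFrame:
    """Per-gene statistics table for one contrast, all analyzed genes.

    Columns: Probe (the lexicographically smallest probe interrogating the
    gene), Gene, M (log2 fold change), A (mean log2 intensity), t, pval,
    adj.pval (equal to pval under "none", to fdr.pval under "BH") and
    fdr.pval (always the BH-adjusted value).  Sorted by pval.
    """
    if contrast not in stats_.contrast_names:
        raise KeyError(f"unknown contrast {contrast!r}")
    k = stats_.contrast_names.index(contrast)
    p = stats_.p_value[:, k]
    fdr = bh_adjust(p)
    if adjust == "BH":
        adj = fdr
    elif adjust == "none":
        adj = p
    else:
        raise ValueError(f"unknown adjust method {adjust!r}")
    gene_probes = gene_probes or {}
    probes = [min(gene_probes.get(g, [g])) for g in stats_.gene_names]
    table = pd.DataFrame(
        {
            "Probe": probes,
            "Gene": stats_.gene_names,
            "M": stats_.coefficients[:, k],
            "A": stats_.amean,
            "t": stats_.t[:, k],
            "pval": p,
            "adj.pval": adj,
            "fdr.pval": fdr,
        }
    )
    return table.sort_values("pval", kind="stable").reset_index(drop=True)


def write_reports(
    tables: Mapping[str, pd.DataFrame],
    decisions: pd.DataFrame,
    out_dir: str | Path,
    cutoff: float = 0.05,
) -> list[Path]:
    """Write per-contrast TSV tables, miRBase-linked HTML of the significant
    genes, and MA plots with the significant genes highlighted."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for contrast, table in tables.items():
        stem = contrast.replace("/", "_")
        tsv = out_dir / f"de_{stem}.tsv"
        table.to_csv(tsv, sep="\t", index=False)
        written.append(tsv)

        sig_genes = decisions.index[decisions[contrast] != 0]
        sig = table[table["Gene"].isin(sig_genes)]
        html = out_dir / f"de_{stem}.html"
        with open(html, "w", encoding="utf-8") as fh:
            fh.write("<html><head><title>Significant miRNAs: " + contrast + "</title></head><body>\n")
            fh.write(f"<h1>Contrast {contrast}</h1>\n<ul>\n")
            for _, row in sig.iterrows():
                fh.write(
                    f'<li><a href="{MIRBASE_URL}{row.Gene}">{row.Gene}</a> '
                    f"M={row.M:.3f} adj.pval={row['adj.pval']:.3g}</li>\n"
                )
            fh.write("</ul></body></html>\n")
        written.append(html)

        fig, ax = plt.subplots(figsize=(5, 4))
        is_sig = table["Gene"].isin(sig_genes)
        ax.scatter(table["A"][~is_sig], table["M"][~is_sig], s=4, alpha=0.4, color="grey")
        ax.scatter(table["A"][is_sig], table["M"][is_sig], s=8, color="red")
        ax.axhline(0.0, color="black", lw=0.8)
        ax.set_xlabel("A (mean log2 intensity)")
        ax.set_ylabel("M (log2 fold change)")
        ax.set_title(contrast)
        fig.tight_layout()
        png = out_dir / f"de_{stem}_ma.png"
        fig.savefig(png, dpi=100)
        plt.close(fig)
        written.append(png)
    return written


# ---------------------------------------------------------------------------
# sklearn-style estimator


class ModeratedLinearModel(BaseEstimator):
    """Gene-wise moderated linear model (samples = arrays, features = genes).

    Parameters
    ----------
    design : array-like of shape (n_arrays, n_coefficients)
        Design matrix, or a :class:`DesignMatrix`.
    contrasts : array-like of shape (n_coefficients, n_contrasts), optional
        Contrast matrix applied after fitting; defaults to the identity.

    Attributes (after ``fit``)
    --------------------------
    coef_, stdev_unscaled_, sigma_, df_residual_, df_prior_, s2_prior_,
    s2_post_, t_, p_value_, F_, F_p_value_.
    """

    def __init__(self, design=None, contrasts=None):
        self.design = design
        self.contrasts = contrasts

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-d arrays x genes matrix")
        if self.design is None:
            raise ValueError("a design matrix is required")
        design = self.design
        if not isinstance(design, DesignMatrix):
            design = DesignMatrix(
                np.asarray(design, dtype=float),
                [f"coef{i}" for i in range(np.asarray(design).shape[1])],
            )
        exprs = ExpressionMatrix(
            values=X.T,
            gene_names=[f"g{i}" for i in range(X.shape[1])],
            array_names=[f"a{j}" for j in range(X.shape[0])],
            groups=np.ones(X.shape[0], dtype=int),
            treatments=["?"] * X.shape[0],
            method="none",
        )
        fit = lm_fit(exprs, design)
        if self.contrasts is not None:
            contrasts = self.contrasts
            if not isinstance(contrasts, ContrastMatrix):
                c = np.asarray(contrasts, dtype=float)
                contrasts = ContrastMatrix(
                    c, [f"c{i}" for i in range(c.shape[1])], list(design.coef_names)
                )
            fit = contrast_fit(fit, contrasts)
        stats_ = moderate(fit)
        self.coef_ = fit.coefficients
        self.stdev_unscaled_ = fit.stdev_unscaled
        self.sigma_ = fit.sigma
        self.df_residual_ = fit.df_residual
        self.amean_ = fit.amean
        self.df_prior_ = stats_.df_prior
        self.s2_prior_ = stats_.s2_prior
        self.s2_post_ = stats_.s2_post
        self.t_ = stats_.t
        self.p_value_ = stats_.p_value
        self.F_ = stats_.F
        self.F_p_value_ = stats_.F_p_value
        self.stats_ = stats_
        self.n_features_in_ = X.shape[1]
        return self

    def decide_tests(self, method="separated", adjust="BH", cutoff=0.05) -> pd.DataFrame:
        return decide_tests(self.stats_, method=method, adjust=adjust, cutoff=cutoff)
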