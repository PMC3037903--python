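# Methods

This note documents the models and estimators implemented in `mirnarray`,
the defaults chosen where the design was genuinely open, what the synthetic
data generator does and does not emulate, and the package's numerical
conventions and limitations.

## Input model

Single-color Agilent miRNA arrays measure each miRNA gene with 2–4 distinct
probes replicated across the slide; the AFE image software exports per-spot
raw mean signal, a background-subtracted processed signal, per-probe and
per-gene summaries, and boolean quality flags. `mirnarray` treats these
exports as data: it never recomputes image-level statistics, and carries
`gBGUsed` (local background plus spatial-detrend value) only as a column.
Two file dialects are read — flat single-header tables and the blocked
FEPARAMS/STATS/FEATURES vendor layout, of which only the FEATURES block is
used. Columns are matched by exact name; unknown columns are ignored with a
log line, missing optional columns are filled with a sentinel (NaN for
signals, 0 for flags) and logged, and any non-numeric signal cell is a hard
error naming the row. Quality-flag values are coerced to {0, 1} (any nonzero
parse maps to 1).

AFE's summaries obey, per array: TotalProbeSignal(probe) = mean of the
probe's background-subtracted replicate signals × replicate count, and
TotalGeneSignal(gene) = Σ over the gene's distinct probes of TPS. The
generator recomputes both from the simulated processed signal with exactly
these formulas. (An alternative reading defines TGS as TPS × number of
probes; the two coincide only when all probes of a gene agree, and the sum
over distinct probes is the definition implemented.)

## Pre-processing protocols

**TGS protocol.** TGS is constant over a gene's spots and is collapsed to one
row per gene (a non-constant gene is an error). Background subtraction can
make it negative, so before the log transform either every value < 0.5 is
floored at 0.5 (default) or |global min| + offset is added (offset strictly
positive required when the shifted minimum would not be). Normalization
(quantile default, or scale = median-centering to the mean column median, or
none) is applied **after** the log2 transform; the ordering is a package
choice made for comparability with the RMA path, which also performs its
model fit on the log2 scale.

**RMA protocol.** Five steps on non-control spots, in order: (1) optional
normexp background correction, per array; (2) quantile normalization between
arrays — on the linear scale, because the protocol's step order places it
before the log transform (classic RMA implementations normalize post-log at
probe level; the step order implemented here follows the platform protocol
literally); (3) log2; (4) median over each probe's replicate spots (even
counts: mean of the central pair — the convention used everywhere in the
package); (5) per-gene median polish of the probes × arrays submatrix, the
gene value for array j being the fitted overall plus array-j effect.
Single-probe genes pass through. Default `background=off`: on this platform
background correction mainly inflates low-intensity variability.

**Quantile normalization.** The reference distribution is the mean of the
per-array sorted values; each array's values are replaced by reference
values at their ranks, ties receiving the mean of the reference values over
the tied rank span. Consequence worth knowing: the "all arrays share one
sorted value set" property is exact only for tie-free arrays — tie averaging
(deliberately) introduces values outside the reference set, and idempotence
likewise holds tie-free. Control spots are excluded from both the reference
computation and everything downstream of it.

**Normexp background correction.** Observed intensity X = B + S with
B ~ N(μ, σ²) and S ~ Exp(mean α). The correction replaces x by
E[S | X = x] = a + σ·φ(a/σ)/Φ(a/σ) with a = x − μ − σ²/α, evaluated through
log-densities (`logpdf − logcdf`) so deep-tail inputs never underflow to a
non-positive output; the result is strictly positive and increasing in x.
Parameters are estimated per array by maximum likelihood over
(μ, log σ, log α) (Nelder–Mead on the exact convolution log-likelihood),
started from method-of-moments values (mean = μ + α, var = σ² + α², third
central moment = 2α³) with a density-mode heuristic as fallback. A
mode-based estimator was considered and rejected: the convolution density's
mode sits at μ + σ²/α + zσ (z ≈ 2.4 when σ/α ≈ 0.02), systematically above
the background mean, and heavy right skew inflates a Silverman-bandwidth KDE
mode further; the MLE recovers μ and α to within a percent on simulated
data and is exactly scale-equivariant. At least 100 finite values are
required; constant input is an error.

**Median polish.** Alternating row/column median sweeps of the additive
two-way model, rows first, accumulating the swept medians into the row,
column and overall effects so that overall + row + col + residual
reconstructs the input exactly at every iteration. Convergence when the sum
of absolute residuals changes by less than `tol` (default 0.01, relative) or
after `max_iter` (default 10) sweeps; even-length medians average the
central pair. The implementation is cross-checked in the test suite against
an independent scalar-loop reimplementation (agreement ≤ 1e-12) and against
R's `stats::medpolish` via Rscript.

## Quality assessment

*Array reproducibility CV*: per array, the CV (sd/mean, n−1 denominator) of
each replicated non-control probe's raw mean signals, summarized by the
median over probes; computed on the linear scale because the CV of log
values is not scale-free. Probes with zero mean are excluded with a log
line. *Reference array*: element-wise median across arrays. *MA values*:
M = x − reference, A = (x + reference)/2 on log2 data. *RLE*: x − reference
per spot, reported as per-array medians and IQRs (expected to center on
zero when few genes change). *Clustering*: complete-linkage agglomeration
on Euclidean distances between arrays, optionally restricted to a gene
subset; deterministic given the input.

## Filtering

A gene's detection status on an array is the maximum of its spots' detected
flags (one detected probe ⇒ gene detected). The detection filter keeps a
gene when max over groups of (100 × detected/group size) ≥ L, with ≥ so
that 3 of 4 replicates passes exactly at L = 75. The expression filter uses
per-array thresholds mean + 1.5·sd (n−1) of that array's negative-control
log2 signals — per-array rather than pooled, because between-array
normalization does not equalize the control populations — and the same
≥ L-percent-in-some-group rule. Filter order: controls → detection →
threshold; both gene filters are optional and independently parameterized;
filtering only removes rows, never changes surviving values. Saturation and
outlier flags are carried in the data but drive no filtering rule.

## Differential expression

Design matrices use treatment-mean coding (one indicator per group, no
intercept) so contrasts are direct group differences; additional factors
(e.g. Subject for paired designs) enter as centered indicator columns for
their non-reference levels. Rank deficiency is an error naming the
confounded columns (QR with pivoting).

Per gene, ordinary least squares gives β̂, residual sd s_g on
d_g = n − rank(X) degrees of freedom, and unscaled sds u from diag((XᵀX)⁻¹)
(contrasts: diag(Cᵀ(XᵀX)⁻¹C)). The variance prior (d₀, s₀²) is estimated by
moment matching on e_g = log s²_g − ψ(d_g/2) + log(d_g/2): the excess of
var(e) over ψ′(d_g/2) is inverted through the trigamma function (Newton
iteration) to give d₀, and s₀² follows from the mean of e. Non-positive
excess ⇒ d₀ = ∞ and s̃² ≡ s₀² (documented branch); genes with s_g = 0 are
excluded from estimation and receive the shrunken prior variance. The
moderated t̃ = β̂_c/(u_c s̃_g) with s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g) is
two-sided against t on d₀ + d_g df; the moderated F is
β̂ᵀ(Cᵀ(XᵀX)⁻¹C)⁻¹β̂/(r·s̃²) on (r, d₀ + d_g) df, with the χ² limit when
d₀ = ∞. The whole stack is cross-checked against limma's
lmFit/contrasts.fit/eBayes in the test suite (agreement to ~1e-8 on t).

Gene selection: `separated` adjusts each contrast's p-values independently
(BH or none) and calls sign(β̂_c) at adjusted p < cutoff; `nestedF` screens
genes by BH-adjusted moderated F, then calls contrasts within screened genes
at the unadjusted t p-value — a simplification of gene-wise closed testing,
documented as such. Result tables list **all** analyzed genes with columns
Probe (the lexicographically smallest probe of the gene), Gene, M, A, t,
pval, adj.pval, fdr.pval; fdr.pval is always the BH value and adj.pval
equals pval under "none" and fdr.pval under "BH". The prior and total
degrees of freedom are exposed on the statistics object, not as table
columns. HTML reports link each significant miRNA to the miRBase registry
(`http://microrna.sanger.ac.uk/...`); no live lookup is performed.

## Synthetic data generator

The generator emulates the v2.0 design — 723 human + 76 viral miRNA genes
split 362/45/390/2 over 2/3/4/1-probe classes at 16 spots per gene (the
3-probe class uses the closest-to-even replicate split 6/5/5), positive
controls at 20 spots over 4 probes (10 genes by default), and 200
negative-control spots (10 probes × 20; the count is a free parameter) —
and draws log2 mean signal = gene baseline + group effect + probe affinity
+ noise, with affinities zero-sum within each gene. Defaults: baselines
N(9, 1.5²) log2 units, affinity sd 0.7, replicate noise sd 0.1 (typical
within-array replicate scatter for this platform: the implied linear-scale
CV ≈ ln 2 × 0.1 ≈ 7%), 20 spike-in genes at +2 log2 units split between
groups B and C, and the canonical 6-array layout (treatments A/B/C × 2
subjects). Backgrounds are per-array constants N(30, 5²) plus a linear
gradient of 10 intensity units across the spot index — an emulation of the
spatial detrend surface as *data*, not a recomputation of it. Negative
controls are N(40, 8²) raw intensities. The detection flag is set for all
of a gene's spots when its brightest probe-level processed signal exceeds
3× the array's noise scale (the sd of its negative-control processed
signals), mirroring the "signal three-fold above error" rule without
modelling pixel-level errors. The realized per-gene/group effects are
attached as ground truth and written beside the AFE files.

What the generator does **not** emulate: saturation and outlier flags
(always 0), probe sequence effects beyond a scalar affinity, spatially
correlated noise, intensity-dependent variance, or cross-hybridization.
Passing tests therefore demonstrate correctness of the algorithms under the
additive model, not robustness to every artifact of real slides.

A property worth remembering when interpreting recovery tests: quantile
normalization assumes near-identical array distributions, so a spike-in set
concentrated in one group is attenuated (the more so the brighter the
spiked genes); with the default balanced spikes at realistic fractions
(20/799 genes) recovery through the full RMA pipeline is accurate to
~0.1 log2 units at noise sd 0.1.

## Numerical conventions and edge cases

- Medians of even-length sets are the mean of the central pair, everywhere.
- Quantile/scale normalization are deterministic; clustering ties resolve
  by input order (scipy's conventions).
- `decide_tests` requires cutoff ∈ (0, 1]; p-values outside [0, 1] are
  errors in `bh_adjust`.
- Moderation requires ≥ 2 genes and at least one positive s²_g; all-zero
  variances are an error (a truly noise-free dataset has no estimable
  error distribution).
- Seeds: every stochastic component takes a single integer seed
  (`numpy.random.default_rng`); identical seed + config ⇒ byte-identical
  files, verified by checksum manifests (the run log, which carries
  timestamps, is excluded from the manifest).
- Expression matrices are written as TSV with a sidecar `.meta.tsv`
  recording the protocol and options used.

## Problem sizes in tests

The test suite runs scaled-down designs (15 miRNA genes) for most
integration tests and the full 799-gene design where composition or
realistic spike fractions matter; simulation-based calibration checks use
10,000 genes (prior recovery), 2,000 genes (null type-I error), 50 × 200
genes (power), and 50,000 draws (normexp recovery). These sizes give
stable statistics at interactive runtimes.
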