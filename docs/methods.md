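# Methods

## The cascade model

The classifier addresses a rejection-option problem: given a methylation
profile from a liver or peritoneal tumor biopsy, decide between PAAD,
iCCA and normal bile duct tissue — or refuse to decide. Refusal matters
because the classifier will meet profiles from carcinomas it was never
trained on (mimickers); a softmax layer alone would force one of three
labels onto them.

**Features.** The top k CpGs ranked by standard deviation (denominator
n−1) across the reference samples, ties broken by probe id ascending so
the feature list is reproducible. k = 2048 by default. Missing features at
predict time (e.g. probes absent from a newer array generation) are
imputed with the reference-set mean, up to a floor of 90% present.

**Anomaly layer.** Four sigmoid MLPs trained by stratified fourfold
cross-validation (network i trains on the folds other than i, fold i
supplies its validation metric). The sample score is the arithmetic mean
of the four sigmoid outputs; pass iff score ≥ 0.5. Mean-combination was
chosen over majority vote for smoothness; both are configurable. Default
training recipe: 5 hidden layers × 2048 units, learning rate 0.0088,
dropout 0.2, L1 0.00067, 228 epochs.

**Classification layer.** Softmax MLP over the three positive classes.
The hidden widths follow a rounded geometric grid from 256 down to 16
over 8 layers (256, 172, 116, 78, 52, 35, 24, 16 — ratio (16/256)^(1/7));
learning rate 0.00895, dropout 0, L1 0.00441, 191 epochs.

**Threshold layer.** Only the argmax class is tested against its
threshold (testing all classes simultaneously would be ill-defined);
"reaches" means ≥. Defaults: PAAD 0.8, iCCA 0.8, NormalBile 0.5. Raising
any threshold can only move calls into NoMatch, never the reverse — a
monotonicity the tests enforce.

All networks are plain numpy implementations (He initialization, ReLU,
inverted dropout, Adam, cross-entropy + L1) so that every weight is a
deterministic function of the seed; the bundle serializes to JSON +
arrays and round-trips to bit-identical predictions.

**Batch correction inside the cascade** operates on the selected features
(select → correct → classify), is fitted once with the class label as a
preserved covariate and the storage material (FFPE/frozen) as batch, and
is then frozen: at deployment each new sample receives a per-probe affine
transform that depends only on its own batch label, never on companion
samples. Unseen batch labels get the identity transform with a warning
(configurable to a hard error).

## Preprocessing

Two profiles. The `analysis` profile removes probes with detection
p > 0.01 in any sample (strict >), fewer than 3 beads in ≥ 5% of samples
(strict <), SNP-associated probes, multi-hit probes, chrX/Y probes, and
probes outside the configured platform intersection — attribution to the
first failing rule in that order, while the surviving set is
order-independent. The `classifier` profile skips filtering entirely:
the cascade only reads its fixed feature list. Platform harmonization
collapses EPICv2 replicate-suffixed probe ids by averaging and intersects
probe sets (intersect first, then QC; configurable). Normalization state
is never shared across cohorts.

**BMIQ.** Per sample, a 3-state beta mixture is fitted by EM separately
to type-I and type-II probes (moment-matching M-steps; deterministic
tertile initialization, which keeps the fit stable even when the type-II
distribution is strongly compressed). Type-II probes are split into
U/H/M states at the empirical quantiles of the fitted component weights —
contiguous intervals by construction, which makes the overall map
monotone. U is quantile-mapped through the type-II U component onto the
type-I U component (lower tail), M likewise through the upper tail, and
the hemimethylated middle is rescaled by an affine dilation anchored at
the mapped U-max/M-min with the original inter-state gaps preserved.
Type-I values pass through unchanged. Betas are clamped to
[1e−6, 1−1e−6] before fitting.

## Batch correction (reComBat)

Standard parametric ComBat with an L2 penalty λ on the standardization
regression (batch indicators + optional covariates to preserve; default
λ = 1e−3, λ = 0 recovers classic ComBat, verified against `sva::ComBat`
to < 1e−5). Per-batch location/scale parameters are shrunk with a normal /
inverse-gamma prior estimated by the method of moments and solved by the
usual fixed-point iteration. Zero-variance probes are passed through
unchanged with a warning; a single batch at λ = 0 is the identity to
machine precision.

## Copy-number profiling

Per probe: log2(query total intensity / median of the normal panel),
median-centered per sample. The panel median replaces conumee's fitted
least-squares combination of controls — more robust and directly
testable. Probes are averaged into genome-ordered bins of 20 probes
(default; at this size single-bin noise in the synthetic cohorts sits
well below the call threshold). Each chromosome is segmented by recursive
binary splitting on the two-sample t statistic; a split is accepted while
the between-side mean difference is ≥ τ/2 and both sides keep ≥ 3 bins.
A segment is called gain/loss iff |mean| > τ = 0.15 (strict, resolving
the ambiguous "at least more than" phrasing; configurable). Sex
chromosomes are excluded by default because the sex mix of the normal
panel confounds their ratios. Group summaries report per-bin gain/loss
frequencies; gene-level group comparisons use Fisher's exact test (2×2
via the hypergeometric distribution, 2×3 via Freeman–Halton full
enumeration) with Bonferroni correction, the number of tests an explicit
argument. A gene counts as deleted/amplified if any overlapping segment
is called.

## Differential methylation

Per-probe two-group linear model on beta values; the reported "logFC" is
the difference of mean betas (the conventional 0.2 threshold is only
meaningful on the beta scale — running on M-values instead is left as
configuration). The moderated t uses an inverse-gamma prior on residual
variances with hyperparameters (d0, s0²) estimated by trigamma-matching
method of moments on log s²; posterior variance
s̃² = (d0·s0² + df·s²)/(d0 + df), reference distribution t with d0+df df.
Verified against `limma::eBayes` to ~1e−12 (relative) for finite d0.
If the variance moments show no excess dispersion the prior degenerates
to d0 = ∞ with a warning. d0 = 0 reproduces the ordinary two-sample t.
DMPs require adjusted p < 0.01 AND |logFC| > 0.2, both strict.
Benjamini–Hochberg adjustment across probes; enhancer/promoter
annotation splits gene sets by direction; over-representation uses the
one-sided hypergeometric test against a user-supplied universe and GMT
gene sets, BH-adjusted across sets.

## Embeddings

The eigenvector-then-t-SNE convention: PCA to k leading components, then
t-SNE at the requested perplexity (defaults k = 30, perplexity 15,
5000 iterations), deterministic for a fixed seed, with the perplexity
< (n−1)/3 constraint enforced up front.

## Synthetic cohorts

The generator emulates the structure the pipeline assumes, not genome
biology. A shared bimodal background of probe means (mixture of
Beta(2,8) and Beta(8,2)); each class owns a disjoint block of
informative probes (2% of probes by default) shifted by delta toward the
opposite methylation pole, so no clipping occurs for delta ≤ 0.5. A
sample's beta is purity·class + (1−purity)·contaminant + Gaussian noise
(SD 0.05) + a constant shift (0.05) for FFPE samples, clipped to [0,1].
The contaminant archetype stands in for normal/immune infiltrate and
reproduces the known low-purity failure mode where diluted tumor
profiles drift toward the contaminating tissue. Total intensities are
log-normal around a platform constant with the methylated share set by
the final beta, so β = M/(M+U) holds exactly; copy-number spikes scale
both channels by state/2 (state 0 floored at 1% so intensities stay
positive), leaving beta untouched. Platform masks set absent probes to
NaN; the synthetic EPICv2 manifest carries replicate-suffixed probe ids
to exercise suffix collapsing.

Default study conditions for the end-to-end run: 3 positive classes
(140/140/120 samples) + 10 mimicker classes (80 each), delta 0.3, noise
0.05, purity 0.6–1.0, FFPE shift 0.05 — cohort sizes mirroring a
reference set of ~400 and a negative class of ~800. To keep a full
train-and-score cycle around ten seconds on one CPU the default desk
configuration uses 6000 probes, k = 256 features, anomaly networks
[128, 128] × 60 epochs and a classifier [128, 64, 32, 16] × 120 epochs;
the full-size recipes above remain the package defaults for
`CascadeClassifier` used directly.

What passing tests show — and what they do not: the synthetic classes
are conditionally independent Gaussians around archetype means, far
cleaner than real tumor methylomes (no CpG-CpG correlation, no subtype
structure, no probe-specific noise). Perfect accuracy here demonstrates
that the pipeline's plumbing, determinism and decision logic are
correct, not that the published cohort-level accuracies transfer.

## Numerical and design choices

- All RNG flows from explicit integer seeds (numpy `default_rng`;
  stratified folds seeded); reruns are byte-identical.
- EM stops on relative log-likelihood change < 1e−5 or 100 iterations,
  returning the best iterate with a warning on non-convergence.
- Argmax ties in the threshold layer resolve to the first class in
  declaration order (PAAD, iCCA, NormalBile).
- Beta-mixture shape parameters floored at 0.01; ComBat fixed-point
  convergence at relative change < 1e−4.
- The published hyperparameter-search optima are hard defaults; the
  search itself is not re-run.

## Known limitations

- No IDAT ingestion: inputs are beta/intensity matrices, so
  control-probe-based normalization (FunNorm, Noob) is out of scope; a
  pass-through hook marks where it would sit.
- No tumor-purity estimation; CNV calls apply τ uniformly rather than
  weighting by tumor cell content.
- Parametric ComBat priors only; no reference-batch or nonparametric
  mode.
- Recursive binary segmentation rather than CBS; adequate for the call
  rule, noted as an extension point.
- Two-group DMP contrasts only; multi-factor designs are out of scope.
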