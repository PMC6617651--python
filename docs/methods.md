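# Methods

This note documents the models, numerical choices and limitations behind
`methsig`. Notation: β is the methylation fraction at a CpG (methylated /
total signal, in [0, 1]); Δβ is the difference of case and control group
means at one CpG; logit(β) = log(β/(1−β)).

## Differential methylation model

For probe *g* with β vector **y**ᵍ over *n* derivation samples and design
matrix **X** (intercept, case indicator, age in years, sex code, estimated
monocyte proportion), the package fits ordinary least squares probe by
probe, giving the group coefficient *b*ᵍ, residual mean square *s*²ᵍ and
common residual df *d = n − rank(X)*. Empirical-Bayes moderation assumes

    s²ᵍ | σ²ᵍ ~ σ²ᵍ χ²_d / d,      1/σ²ᵍ ~ χ²_{d₀} / (d₀ s₀²),

i.e. the true variances follow a scaled inverse-chi-square prior, so the
observed s² are scaled-F. The hyperparameters (d₀, s₀²) are estimated by
matching the mean and variance of log s² (the trigamma function is inverted
by Newton iteration); the posterior variance is the precision-weighted
average s̃²ᵍ = (d₀s₀² + d s²ᵍ)/(d₀ + d) and the moderated t statistic
*b*ᵍ / (seᵍ √(s̃²ᵍ)) is referred to Student's t with d₀ + d df. The finite-d₀
branch reproduces limma's `fitFDist`/`eBayes` to ~1e-11 relative error (a
test cross-checks this through Rscript). When the moment estimate of d₀ is
nonpositive or nonfinite (no excess dispersion in log s²), d₀ is set to ∞
and s₀² to the geometric mean of s², so exactly homogeneous variances pass
through unchanged; this differs deliberately from limma, which applies a
digamma bias correction in that branch as well.

P-values are two-sided (both gains and losses of methylation are expected),
BH-adjusted by the step-up rule, and the signature is the set of probes with
adjusted p < α (default 0.05) **and** |Δβ| > 0.10, both strict. Δβ is the
*raw* difference of group means, not the adjusted coefficient: the threshold
expresses a biologically meaningful methylation difference on the original
scale; the covariate-adjusted coefficient is reported alongside. Probes with
any missing β among derivation samples are dropped before fitting to keep
*d* uniform. Derivation is restricted to case/control samples older than
`min_age` (default 2 years), because early-childhood DNAm drifts strongly
with age.

## Scoring and decomposition

The classifier stores per-probe medians of the derivation cases and controls
over the signature CpGs (even group sizes use the midpoint median) plus each
group's observed [min, max] range. A query vector is scored by
`r(B_sig, case profile) − r(B_sig, control profile)` (Pearson); the decision
boundary is 0, a score of exactly 0 labels "benign" with a warning. Scores
are invariant to affine transforms of the query and antisymmetric under
profile swap; both properties are asserted exactly in tests. Up to 10%
missing signature values are tolerated via pairwise-complete correlation.

Range-overlap decomposition treats the group ranges as closed intervals
("within the range" read inclusively): case-typical means inside the case
range and outside the control range, and symmetrically; inside both is
"both", outside both "neither". With 8 derivation cases, a genuinely
case-like measurement falls outside the observed case min–max with
probability ≈ 2/9, so the case-typical fraction systematically understates
the true mosaic fraction by roughly that factor — the recovery tolerance of
±0.10 used in the tests reflects this inherent bias of min–max ranges, not
measurement error alone.

## Cell-type deconvolution

Bulk blood β at marker CpGs is modelled as a nonnegative mixture of
sorted-cell reference profiles with Σc ≤ 1 (not = 1), leaving room for
unmodelled cell types; the residual norm is reported per sample. The
constrained problem is solved by nonnegative least squares on a design
augmented with a slack component and a sum-to-one row weighted by 1e6 —
equivalent to the usual quadratic program, deterministic, and exact (1e-9)
on noiseless mixtures. Marker probes are chosen per cell type as the
most hyper- and hypomethylated probes by one-vs-rest equal-variance t.
Group comparison of estimated proportions uses the equal-variance two-sample
t-test. Only the monocyte estimate is passed downstream as a covariate;
monocyte and CD4⁺ T proportions are strongly anticorrelated in composition
shifts, so a single covariate captures most of the confound.

## DMR detection

Probes are clustered by position: consecutive probes on a chromosome join a
cluster iff their gap is strictly below `max_gap` (500 bp; a gap of exactly
500 splits). Candidates are maximal same-sign runs with |adjusted group
coefficient| > 0.10; a sign flip ends a run. The region statistic is the
area Σ|coef| (the bumphunter default; no loess smoothing of coefficients —
the minimum run length already enforces spatial support). Null areas come
from a residual bootstrap of the group-free model: residual vectors are
resampled across samples with replacement, added to the null fitted values,
and the full model refitted. The add-one pooled p-value
(1 + #{null ≥ area}) / (1 + #null) avoids zeros; DMRs are reported at
p < 0.01 with ≥ 4 CpGs.

A consequence of pooling: p can never fall below 1/(1 + N_null). With β
noise sd 0.03 the per-probe probability of a null coefficient exceeding 0.10
is tiny, so N_null scales with the probe count. The DMR recovery checks
therefore run on a 300,000-probe panel (null pools of ~150–320 areas, p
floor ≤ 0.007), the regime of a real ~800k-probe array; at a few thousand
probes the floor sits above 0.01 and the unit tests instead assert that
planted regions carry the smallest achievable pooled p.

## Enrichment

Probes are mapped to deduplicated gene symbols through the manifest; each
gene set is tested with the upper-tail hypergeometric probability of the
observed foreground overlap given the background gene universe (the
post-QC probe set). Terms need ≥ 2 foreground hits to be reported; BH is
applied across reported terms (raw p is kept too). The 2×2 overlap test is
the Pearson chi-square with 1 df and no continuity correction.

## Synthetic data

The generator emulates the study design the workflow assumes, with full
ground truth. Defaults are the nominal study conditions and are not meant to
be tuned per run:

| parameter | default | meaning |
|---|---|---|
| `n_probes` | 20,000 | probe panel size (scaled-down array) |
| `n_cases` / `n_controls` | 8 / 23 | derivation cohort |
| `n_signature` | 300 | planted signature CpGs |
| `effect_delta` | 0.15 | planted β-scale group shift at signature CpGs |
| `hyper_fraction` | 0.5 | fraction of effects increasing β |
| `noise_sd` | 0.03 | β-scale measurement sd per probe |
| `n_celltypes` | 6 | CD4T, CD8T, NK, B, Mono, Gran |
| `n_discriminating` | 50 | marker probes per cell type |
| `n_dmrs` / `dmr_len` | 3 / 6 | planted contiguous DMRs (members of the signature) |
| `age_range` | 3–40 y | sample ages (uniform) |

Baselines are drawn from a bimodal mixture (Beta modes with means ≈ 0.10 and
0.85), matching genome-wide β distributions. Bulk samples are
proportion-weighted mixtures of cell-type profiles; proportions are
Dirichlet with concentration 150 around realistic blood composition, and
case concentrations shift ≈ +0.06 toward monocytes and −0.06 away from CD4⁺
T cells, reproducing the composition confound the monocyte covariate must
absorb. Ages are uniform on `age_range` for both groups (age-matched
design); 100 probes carry a ±0.003 β/year age slope and 50 carry a ±0.05
sex offset.

Effects and noise are applied on the logit scale and mapped back through the
inverse logit, so β never leaves (0, 1) and there are no truncation spikes
at 0/1. Because the inverse logit both compresses means and rescales
variances, the per-probe logit noise sd is solved numerically (21-node
Gauss–Hermite quadrature plus bisection) so the induced β-scale sd equals
`noise_sd` at every baseline, and at signature probes the case-group logit
offset and noise sd are solved jointly so the case mean shifts by exactly
`effect_delta` while the case β-scale sd stays at `noise_sd`. Without the
joint solve, extreme-baseline probes acquire inflated case-group variance
and the nominal conditions are not what they claim.

Artifact probes (SNP-adjacent 1%, cross-reactive 1%, detection failures
0.1%, non-CpG 0.5%, sex-chromosome 2%) are drawn disjointly from
signature/marker/covariate probes so QC recall is well defined. Probe
positions use inter-probe gaps ≥ `max_gap` except inside planted DMR runs
(gaps 50–300 bp), so clusters are exactly the planted regions. Mosaic
samples draw control-like cell proportions and carry the case effect at a
Bernoulli(`fraction`) subset of signature probes; the mask is recorded.
`generate_reference_panel` rebuilds the identical cell profiles from the
same seed, emulating an external sorted-cell reference that is *consistent*
with the bulk data.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: Infinium I/II chemistry differences, chip and
batch effects, spatially correlated probe noise, genotype-driven trimodal
probes, population structure in the controls, or realistic linkage between
gene annotations and effects (genes are synthetic blocks of 10 probes).
Classifier separation at the planted effect size is expected to be perfect;
real cohorts with smaller effects or heterogeneous phenotypes need not be.

## Numerical and design choices

- Coordinates are 1-based fully closed (Illumina manifest convention); BED
  export converts to 0-based half-open at the boundary.
- Tables are TSV with `NA` for missing; β round-trips at ≥ 10 significant
  digits. The signature model serializes to one JSON document.
- Signature ordering: adjusted p, then |Δβ| descending, then probe id — a
  total, reproducible order.
- "Detection flaw" is operationalized as detection p > 0.01 in ≥ 1 sample
  (recorded in the QC report metadata); the upstream convention varies and
  the threshold is exposed as `detection_p_cutoff`. Filter counts are
  attributed sequentially (a probe failing two rules counts once, at the
  first), so counts sum to the total removed; the surviving set is
  order-invariant and the filters idempotent.
- Empty signatures are legal at selection time but scoring refuses them; the
  pipeline aborts at the scoring stage with a partial-results manifest.
- Clustering of samples (heatmap-style) uses Euclidean distance with
  complete linkage by default; linkage is configurable since the convention
  is not universal.
- All simulation randomness flows through `numpy.random.SeedSequence`
  spawning, so the probe architecture, sample draws and noise are
  independently reproducible, and derived seeds stay below 2³¹.

## Problem sizes used in the checks

Unit tests run a 4,000-probe / 120-signature study end to end; the
acceptance checks run the nominal 20,000-probe study (with 10 + 50 held-out
validation samples), 20 null replicates at 2,000 probes, a 300,000-probe
panel for DMR recovery (see above), and 50,000 probes for moderation
hyperparameter recovery. These sizes are the package's own choices balancing
statistical resolution against a laptop-scale run; the workflow itself is
size-agnostic.
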