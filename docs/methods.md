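# Methods

## Scope and data model

`pmdkit` segments a WGBS methylome into partially methylated domains (PMDs)
and highly methylated domains (HMDs), integrates calls across sample groups,
and tests region-level hypomethylation between groups. All coordinates are
0-based half-open throughout; input CpG tracks are assumed destranded (one
record per CpG dyad, as produced by standard bisulfite pipelines). Two
coverage thresholds coexist deliberately: segmentation and domain-level
methylation summaries use ≥ 5 informative reads, region-level differential
tests default to ≥ 3; both are parameters and every run logs the value used.

## Solo CpGs and windowing

A CpG is *solo* when at most 2 other CpGs lie within ±75 bp (a 151-bp window
centred on it; ties at exactly 75 bp count). Solo status is a property of
the CpG landscape: neighbours are counted against all CpG positions, not
just those surviving the coverage filter — otherwise members of a dense
cluster whose neighbours were dropped for low coverage would masquerade as
isolated sites and contaminate the solo set with island-like methylation.

Windows are consecutive, non-overlapping blocks of 201 coverage-filtered
**solo** CpGs per chromosome. Restricting the windows to solo CpGs excludes
CpG-island context from all three features at once; without it the
score–methylation correlation in HMD windows is dominated by unmethylated,
low-score islands and turns strongly positive, which both inverts the
feature's intended sign structure and couples it to island density rather
than methylation loss. (`FeatureConfig.windows_on="all"` restores windowing
over every retained CpG for comparison.) A terminal remainder of ≥ half a
window stands alone, smaller remainders merge into the preceding window,
and chromosomes with less than half a window of CpGs are skipped. Window
spans are made contiguous (each window ends where the next begins) so that
domains assembled from window runs tile the windowed genome without gaps.

## Window features

* **alpha** — the MLE of a symmetric Beta(α, α) over the window's β values,
  clamped to [10⁻³, 1−10⁻³] and optimized by bounded scalar search on
  α ∈ [0.01, 100] (reproducible to < 10⁻⁶). The symmetric-Beta MLE over
  per-CpG fractions was chosen over a beta-binomial over read counts for
  determinism and simplicity; its qualitative behaviour is the one that
  matters for segmentation: polarized windows give small α, intermediate
  windows give large α (≥ 1 for pure intermediate data).
* **pcc** — Pearson correlation between the per-CpG hypomethylation score
  and β over the window. Zero-variance windows return the defined fallback 0
  with an `undefined` flag (the window is excluded from HMM fitting but
  keeps its place in the genome partition); fewer than 10 usable pairs is
  undefined outright.
* **m_value** — log₂(β̄/(1−β̄)) with β̄ clamped to [0.01, 0.99].

The score source is pluggable, in order of precedence: an external score
track; a genome FASTA through the flanking-base proxy (both CG flanks A/T →
1.0, one → 0.5, none → 0.0, N → missing); otherwise the emission degrades to
(alpha, M-value) with a loud warning, since PCC cannot be computed.

## Model selection (2D vs 3D)

If the 10th percentile of all solo-CpG β values (linear-interpolation
quantile) is strictly below 0.025, the sample is treated as
extreme-methylation-loss and the 3D feature model (alpha, pcc, m_value) is
selected; otherwise the 2D model (alpha, pcc). Fewer than 1000 solo CpGs
triggers a warning and the 2D default. The rationale: when PMD methylation
collapses toward zero, the PMD β distribution is itself polarized (α < 1,
indistinguishable in kind from an HMD) and within-PMD variance vanishes
(PCC uninformative); only the raw methylation level — the M-value — still
separates the states.

## HMM segmentation

Emissions are two-state multivariate Gaussians with full covariance over
z-scored features (standardization constants stored in the model and reused
at decode time). Fitting is EM (`hmmlearn` provides the machinery) on the
concatenated per-chromosome sequences of defined windows; chromosome
boundaries reset the chain and are never bridged. Initialization is a
deterministic median split on alpha — windows at or above the median seed
one state — with an optional multi-restart mode that perturbs the initial
means with a seeded RNG and keeps the best log-likelihood; restart 0 is
always the deterministic split, so a fit is reproducible given its seed.
Convergence is declared when the relative log-likelihood improvement falls
below 10⁻⁴ (default) or after 500 iterations (the model is then returned
with a non-converged flag and a warning). The log-likelihood trace is
retained and checked to be non-decreasing; machine-noise terminal dips from
covariance flooring (diagonal regularization 10⁻⁶ when needed) are clipped,
anything larger is an error. A state left with ≤ 2 windows raises a
degenerate-state error suggesting the other feature model.

**State identifiability.** Each model labels its states using only its own
emission features. A model without the M-value dimension applies the field's
alpha semantics — PMD is the state with the larger mean alpha. A model
carrying the M-value labels PMD as the lower-mean-M state. This split is
deliberate: under extreme loss both states have α < 1 and the alpha ranking
inverts (collapsed PMDs are *more* polarized than HMDs), so a forced 2D fit
on such a sample mislabels the states and its recovery collapses — the
documented failure mode that motivates the 3D model and the selection rule.
Labelling 2D states by window methylation instead would smuggle the third
feature into the 2D model and mask that failure.

Decoding is per-chromosome Viterbi; windows with undefined features inherit
the state of the nearest defined window (ties toward the preceding one).
Same-state runs merge into domains carrying the CpG-weighted mean β; runs
shorter than `min_windows` (default 1, i.e. no size filter — no minimum PMD
length is imposed) are absorbed into the flanking run with more windows,
interior runs first. Blacklist subtraction is a plain interval difference;
fragments keep their state and summary.

## Multi-sample categorization

Per-sample PMD sets are fused on the breakpoint partition of the genome (the
resolution of a multi-set intersection), so category boundaries are exactly
the union of sample boundaries and no minimum segment length is imposed —
tiny slivers are possible and are reported as-is. Thresholds follow the
wording "at least two-thirds" (inclusive ≥) and "fewer than one-third"
(strict <): with 3 samples per group, 2/3 occurrence qualifies as common.
Segments that are neither common nor sufficiently absent are reported as
`unassigned` rather than dropped, so category base pairs always conserve the
partition total. Genome-fraction and F1 computations are base-pair-level;
blacklist base pairs can be excluded from the genome-fraction denominator.

## Region statistics

Region means are per-sample averages of qualifying CpG β values
(coverage filter; optional restriction to solo or solo-WCGW CpGs, the
latter needing a score at or above a configurable cutoff, default 1.0 =
both flanks W under the proxy). Differential classification runs a
one-tailed two-sample t-test per region — Welch by default, pooled-variance
switchable, since the unequal-variance form is the safer default when group
variances differ — with Benjamini–Hochberg correction across tested regions.
Regions lacking ≥ 2 defined means per group are reported `untested`. The
FDR threshold is a required argument with named presets 0.05 and 0.1 (both
in circulation for the tumor-specific call); zero-variance identical groups
get p = 1 by convention, zero-variance separated groups p = 0. The DMR-style
filter keeps regions with q < 0.05 and |Δβ| > 0.2, both inequalities strict.
A masking utility subtracts (e.g.) group-common PMDs from a region set
before testing, and 10-kb tile means (with optional CpG-island masking)
support genome-wide visualization.

## Simulator

The generator emits the exact dialects the readers consume and is fully
determined by one seed through named substreams. Defaults are the study
conditions used throughout the tests: a 10-Mb genome in two 5-Mb
chromosomes; ~50k CpGs at 200-bp mean spacing; PMD architecture fraction
0.4 with mean PMD length 800 kb; PMD depth 0.6 (0.03 under the extreme-loss
flag), HMD level 0.85; Beta concentrations 8 (PMD) and 20 (HMD) so the PMD
distribution is the broader one; Gamma–Poisson coverage with mean 10 and
shape 8; 3+3 samples per group with boundary-jitter breadth overlap 0.9.

CpGs arrive as isolated singletons (always solo; units are kept ≥ 80 bp
apart) or island-like clusters of four CpGs at 20-bp spacing (never solo),
mixed to hit the configured solo fraction (0.5) exactly in expectation.
Scores in [0, 1] stand in for a sequence-derived loss-propensity score: a
WCGW-like fraction (0.35) of solo CpGs scores high, clusters score low. Two
realism components shape the methylation landscape: cluster CpGs are
constitutively unmethylated (β ≈ 0.1), emulating islands, and 15% of solo
CpGs are constitutively lowly methylated, emulating regulatory elements —
this low component is what makes the HMD β distribution polarized rather
than unimodal-high, as real HMDs are. Inside PMDs the latent methylation is
depth − effect·score (effect 0.3), clamped to [0.01, 0.99], which produces
the negative within-PMD score–methylation correlation the PCC feature
detects; outside PMDs the score has no effect. Per-CpG β is a Beta draw
around the latent mean, observed β is a binomial read fraction at the drawn
coverage, and zero-coverage CpGs are not emitted.

Domain architecture allocates a fixed per-chromosome PMD budget over
Gamma-distributed segment lengths, so the realized architecture fraction
equals the target exactly while boundary placement stays stochastic. Each
PMD segment is assigned shared / group-A / group-B status (all three
guaranteed non-empty; the complement is shared HMD), group members inherit
the shared and own-group segments with per-sample Gaussian boundary jitter
scaled by (1 − breadth overlap), and the extreme-loss flag changes depth
only, never the architecture. An optional FASTA emitter writes a genome
whose CG flanking bases encode each CpG's score class, so the proxy-score
path can be exercised end to end.

**What the simulator does not emulate** — and hence what passing tests do
not establish about real data: real chromosome sequence, island positioning
and shore gradients; within-domain depth gradients and partially eroded
domain edges; sample-to-sample depth heterogeneity within a group;
mappability structure in coverage; and any correlation between the score
and sequence beyond the three proxy classes. Recovery figures on simulated
data (F1 ≈ 0.95–0.99) are therefore upper bounds driven mainly by window
quantization of domain boundaries, not estimates of accuracy on tissue
methylomes.

## Problem sizes and numerical choices

The default simulated genome (10 Mb, ~50k CpGs, ~110 solo-CpG windows per
sample) is the package's standard test condition: large enough for ~8 PMD
segments and stable EM fits, small enough that a full simulate-and-call
cycle takes about a second. Alpha optimization tolerance is 10⁻⁸ (checked
against a 10⁻³-step grid oracle to 10⁻³); PCC is clamped to [−1, 1] after
the covariance formula; quantiles use linear interpolation; BH is the
standard step-up. Duplicate CpG positions in input are collapsed keep-first
with a warning (upstream pileup output does not specify tie handling).

## Known limitations

* The HMM assumes Gaussian emissions on transformed features; alpha is
  bounded below by the optimizer's domain, so fully collapsed windows pile
  up near α = 0.01 and their emission is only approximately Gaussian.
* Domain boundaries are quantized to window edges (~70 kb at default solo
  density); callers needing finer boundaries should reduce `window_cpgs` at
  the cost of noisier features.
* The per-CpG score is treated as exchangeable with the neural-network-style
  scores it stands in for; no attempt is made to learn one from sequence.
* `categorize` covers the span between the first and last observed
  breakpoint per chromosome (interior zero-occurrence gaps are categorized
  as shared HMD); telomeric stretches outside any sample's calls are not
  reported.
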