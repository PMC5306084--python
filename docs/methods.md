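# Methods

## Scope and data model

The package scores how chemicals disturb the transcriptome of
differentiating human pluripotent stem cells.  Inputs are already
log2-summarized expression matrices (probe sets × samples; probe-level
background correction and summarization are out of scope), a sample
design table (roles `day0_control`, `diff_control`, `treated`,
`vehicle_control`, plus compound, concentration, batch, replicate), a
probe→gene-symbol annotation, GMT gene-set collections, and viability
plate readouts.

Identifier namespaces are explicit everywhere: every regulon or gene-set
object is tagged `probe` or `gene`, and set operations across namespaces
raise instead of silently mixing probe sets with gene symbols.  Missing
expression values are rejected at read time — the source platform is
complete, and downstream statistics assume full matrices.  Concentrations
are compared only within one declared unit.

## Preprocessing

**Quantile normalization** equalizes per-sample distributions by mapping
each column to the across-column mean of order statistics.  Ties get the
mean of the reference values over the tied ranks (midrank policy); the
choice matters only for discrete-valued inputs.

**Batch correction** follows the empirical-Bayes location/scale model:
per-probe least-squares means over batch + biological group are removed,
per-batch location (additive, log2) and scale (multiplicative) effects
are estimated on the standardized residuals and shrunk across probes —
by the nonparametric Monte-Carlo-integration posterior (default, matching
the original workflow) or the parametric normal/inverse-gamma solution
(O(probes) instead of O(probes²) per batch; the pipeline exposes it for
large matrices).  Corrected data are back-transformed so group-mean
differences are preserved.  Guard rails: a single batch passes through
unchanged, batches of size 1 and batch–group confounding raise, and
zero-residual-variance probes pass through with a warning.

The correction is *not* exactly idempotent: a second pass re-estimates
near-null effects and shrinks them, moving values by an amount roughly an
order of magnitude below the replicate noise (measured ≈ 0.02 log2 mean
absolute at 500 probes).  The property test asserts this honest bound
rather than literal fixed-point behavior.  Order of operations is
quantile normalization on the combined matrix first, then batch
correction; this is recorded in the run manifest.

## Differential expression and gene calling

Per probe, a pooled-variance two-sample test (one-way ANOVA with two
levels, F = t²; Welch available as an option) with two-sided p-values,
Benjamini–Hochberg FDR over all probes of the array (no pre-filtering),
and a significance gate

    significant ⇔ |linear FC| ≥ 1.5  AND  q ≤ 0.05

with both thresholds as parameters.  The fold-change gate is inclusive
(≥ 1.5) and the multiplicity gate acts on the FDR-adjusted value; fold
changes are computed as 2^Δ(log2 means), signed (−2^−Δ below 1).  Probes
with zero variance and equal means get p = 1 by convention.

D-genes come from the day-0 vs end-stage control contrast, T-genes from
each treated vs end-stage control contrast; `call_regulons` splits
significant probes by sign into disjoint up/down sets.  Fold-change tiers
(2/5/10-fold) and top-k-by-FDR selection (ties broken by raw p, then
probe id; all probes returned when fewer than k are significant) support
the descriptive summaries.

## Indices

For D-gene and T-gene sets on an array of N probes with overlap
O = |D ∩ T| (direction ignored for the headline indices; directional
quadrants reported alongside):

    D_p = O / D                 fraction of the developmental programme hit
    D_i = (O / T) / (D / N)     enrichment over random expectation

D_i is undefined (NaN, reason "no T-genes") when a compound deregulates
nothing — a negative test, not zero enrichment.  The identity
D_i = (O·N)/(T·D) = D_p·N/T holds algebraically and is property-tested.
O/T itself (the fraction of compound-deregulated genes that are
developmental) is reported as `t_fraction`; it is the quantity a reader
might mistake for D_p, so both are exposed explicitly.

Overlap significance is the hypergeometric upper tail
P(X ≥ O), X ~ Hypergeom(N, D, T) — equivalent to a one-sided Fisher
exact test on the 2×2 table.  One-sided because the scientific question
is overrepresentation.

N defaults to the number of rows in the supplied matrix rather than the
hard-coded array size (54,675 for HG-U133 Plus 2.0), so filtered matrices
stay self-consistent.  For category-restricted indices (per
differentiation process), D and O are intersected with the category while
T and the background N stay global; categories without developmental
members are skipped with a log entry.  Baseline stratification classifies
probes as high-expression when the mean over day-0 controls or end-stage
controls strictly exceeds 6 (log2).  Concentration profiles emit one
index row per dose, sorted ascending; doses with T = 0 carry D_p = 0 and
undefined D_i.

## Consensus and diagnostic genes

A gene counts as deregulated by a compound if at least one annotated
probe set passes the gate; significant probes in both directions make the
gene *inconsistent*, which counts toward neither direction (mirroring the
network-overlay rule).  Multi-gene probes contribute to every mapped
gene.  A consensus gene is called in the same direction by at least
`min_count` compounds of a class; the per-system presets from the source
study are UKK mercurials 3, UKN1 mercurials 4, UKK HDACi 4, UKN1 HDACi 5.

Diagnostic ranking filters consensus genes by six criteria:
multi-compound support (≥ min_count), preference for high fold changes
(the ranking key), developmental membership, antagonism of the
developmental direction, baseline log2 expression > 6 at day 0 or end
stage, and — because "function is understood" is not computable — an
optional curated allow-list; without one the criterion is skipped with a
log note.  Ranking order: supporting compounds desc, mean |FC| desc,
gene id asc.

## TF co-expression network

Pairwise mutual information between gene expression vectors is estimated
with the Kraskov–Stögbauer–Grassberger k-nearest-neighbour estimator
(algorithm 1, max-norm, k = 9 by default), with a tiny seeded jitter
(1e-10) to break exact value ties and negative estimates floored at 0.
CLR background correction computes, per gene, z-scores of each pair
against the gene's off-diagonal MI distribution (floored at 0) and
combines them as sqrt(z_i² + z_j²).

Edges are kept for TF pairs scoring in the top quantile (default top
0.1 %).  The quantile is computed *after* restriction to the TF list —
the alternative order is a documented flag-level choice, and with m TF
pairs the kept count is ceil(0.001·m), with pairs tied at the threshold
all retained (superset rule, logged).  Communities come from greedy
modularity maximization; the 18 largest are retained for enrichment, with
those under 6 genes flagged and dropped.  Per-community term enrichment
is the same one-sided hypergeometric test with the network's node set as
background, reporting terms at unadjusted p < 0.05.  The regulation
overlay marks TFs up/down from a gene-level regulation map, removes
inconsistently regulated TFs, and reports per-community affected counts
and fractions.  Graph layout is delegated to any plotting backend and is
not part of the validated contract.

## BMC10

Viability = 100·(signal − mean blank)/(mean vehicle − mean blank), with
technical replicates averaged within an experiment and biological
replicates kept separate.  Each replicate is fitted with a decreasing
four-parameter logistic on log10 concentration — top initialized at 100
and bounded [80, 120], bottom bounded [0, 50], Hill slope (0.1, 10],
EC50 within three decades of the tested range.  The parameterization and
bounds are this package's choice; the source protocol names only "a
sigmoidal dose–response fit".  Flat responses (range < 5 %) are flagged
degenerate with no EC50; non-convergent fits are excluded from averaging
with a warning.

Fitted curves are averaged pointwise on a shared log10 grid (pointwise
mean rather than parameter averaging — closer to a graphical read-off),
and BMC10 is the concentration where the averaged curve crosses 90 %
viability, solved exactly with a root finder and then snapped to the last
measured concentration at or below the crossing; the interpolated
crossing is reported alongside for transparency.  A curve that never
drops below 90 % yields "above tested range"; a curve already below 90 %
at the lowest dose returns that lowest dose with a warning.

## Synthetic data

The generator emulates an HG-U133-Plus-2.0-like study: log2 baselines
~ Normal(7, 2²), default 20,000 probe sets (a full-size mode exists; the
reduced default keeps simulations fast without changing any rate being
estimated), four replicates per group, replicate noise SD 0.25 log2.
Planted developmental probes shift between day 0 and the end stage;
planted toxicant probes shift treated samples against the end stage, with
a configurable overlap drawn from the D set and an antagonism fraction
(default 0.8) of overlap probes opposing the developmental sign.  Planted
|log2FC| is uniform on [0.8, 3.3] by default — spanning sub-threshold to
tenfold so both significant and borderline probes exist; recovery checks
use the strong-effect condition |log2FC| ≥ 1.5.  Optional additive +
multiplicative batch effects are applied per batch, with replicates
spread round-robin over batches so batch never confounds biology.
Annotation maps two consecutive probes per synthetic gene symbol with a
5 % multi-mapping rate.  Truth objects carry exact memberships and
effects, so every downstream statistic's expected value is known without
re-running the pipeline.

Co-expression data use a latent-factor model (x = √ρ·f + √(1−ρ)·e,
within-module correlation ρ, cross-module ≈ 0).  Viability plates are
generated from a 4PL truth with blank and vehicle wells and configurable
fluorescence noise.

What the generator does *not* emulate: probe-level Affymetrix noise,
heavy-tailed intensity distributions, correlated probes within real
genes, dose-dependent transcriptional programmes beyond planted set
membership, or plate-position effects.  Passing recovery tests therefore
demonstrates correctness of the statistical machinery under the stated
model, not performance on real arrays.

## Numerical choices and edge cases

- BH-FDR delegates to the standard step-up implementation and is checked
  against an independent hand-written step-up to 1e-12.
- The Fisher/hypergeometric test is exact (scipy's survival function),
  checked against direct combinatorial summation.
- KSG marginal counts use strict inequality via sorted-array bisection;
  the estimator's own noise (~1e-4 under row reordering, from jitter
  interacting with boundary ties) bounds the symmetry tolerance.
- Degenerate DGE probes: zero variance with equal means → p = 1; zero
  variance with unequal means → p = 0.
- All randomness flows through explicit integer seeds; pipeline reruns
  with the same config are byte-identical (manifests include input
  hashes, never timestamps).

## Limitations

- The published network node/edge counts depend on an external tissue
  atlas and TF database versions and are not reproduced here; the network
  stage is validated on planted-module recovery instead.
- Consensus/diagnostic calling reconciles multi-gene probes by letting a
  probe support every mapped gene; other reconciliation policies are
  plausible and would change borderline calls.
- Nonparametric batch correction is quadratic in the probe count per
  batch; use the parametric mode for full-size arrays.
- The sigmoid parameterization for viability fits is a convention, and
  BMC10 inherits the measured concentration grid's resolution by design
  (the read-off snaps to tested doses).
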