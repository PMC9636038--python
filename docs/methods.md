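# Methods

This note documents the statistical models implemented in `clonechron`,
the defaults chosen where the design was genuinely open, the numerical
details that matter for reproducing results, and the limits of what the
bundled simulator can demonstrate.

## Cancer cell fraction

For a substitution with `alt` of `depth` reads in a sample of purity ρ,
the purity-adjusted VAF is `alt/depth/ρ`. The CCF follows fixed rules by
allele-specific copy-number state (from Battenberg-style segments):

| state | major/minor | CCF |
|---|---|---|
| diploid | 1+1 | 2 × adjusted VAF |
| LOH | minor 0 | 1 × adjusted VAF |
| gain, single copy | 2+1, m=1 | 3 × adjusted VAF |
| gain, duplicated allele | 2+1, m=2 | 1.5 × adjusted VAF |

Any other state (higher amplification, balanced 2+2, …) is excluded with a
logged count rather than generalized. CCFs are **not** capped at 1; raw
values are retained so that the downstream clustering sees the full
distribution.

Allele assignment on gains compares binomial likelihoods of the observed
counts under the expected VAFs ξ(m) = m·ρ/(2(1−ρ) + 3ρ), m ∈ {1, 2}, with
equal priors; exact ties break to the single-copy class. In multi-region
tumors the assignment is made once, in the region with the highest purity
(where ξ(1) and ξ(2) are farthest apart), and shared across regions.

*Exactness caveat.* The ×2 rule is exact at any purity (ξ(1)/ρ = 1/2 for a
clonal diploid het), as is the LOH rule at total copy number 2. The gain
rules ×3 and ×1.5 are exact only in the pure-tumor limit: at purity ρ a
truly clonal single-copy gain mutation maps to CCF 3/(2+ρ). The rules are
implemented as stated because they are the analysis's defining contract;
the closed-loop identity tests assert exactness exactly where it holds.

## Presence filtering

Per-locus error rates pool alt/total counts across the panel of normals
with a symmetric pseudocount (default 0.5, preventing a degenerate zero
rate), capped at 0.5: ε = (alt + c)/(depth + 2c). Each (variant, sample)
pair gets a one-sided exact binomial p-value P(X ≥ alt | depth, ε); zero
alt reads give p = 1 and can never be called present. Correction is
Benjamini–Hochberg across **all** tests in the run by default
(Bonferroni available); the acceptance threshold is a corrected p < 0.001.
Global rather than per-sample correction was chosen because the decision
of interest — which regions share a mutation — spans samples. No
overdispersion (beta-binomial) is modelled; the panel is assumed clean of
true somatic signal.

## Dirichlet-process clustering

Mutation i in sample s is emitted as
`alt_is ~ Binomial(depth_is, π_zs · ξ_is)`, where ξ_is is the expected VAF
of a fully clonal mutation at that locus (multiplicity, total CN, purity)
and π_ks is cluster k's CCF center in sample s — one shared assignment
with per-sample centers, i.e. an S-dimensional process. The DP is
approximated by stick-breaking truncated at K = 30, far above observed
cluster counts. The concentration is fixed (default 1.0) or given a
Gamma(1, 1) prior with the standard conjugate update.

**Sensitivity adjustment.** A mutation enters the dataset only if the
caller saw it, so each cluster's likelihood is divided by the detection
probability — at least `min_alt_detect` (default 4, a typical caller
floor) alt reads in at least one sample:
`P_det = 1 − Π_s P(X_s < min_alt_detect | depth_s, π_ks ξ_is)`.
For a single region this reduces to the plain per-sample detection
probability. Without this term, low-CCF clusters are dragged upward by the
truncation of undetectable mutations.

**Sampling.** Assignments are Gumbel-max draws from the conditional
categorical; stick weights are conjugate Beta updates; centers, rendered
non-conjugate by the detection term, move by per-coordinate Metropolis
with a Beta proposal (concentration 80) on [0, 1.5] — centers above 1 are
allowed because raw CCFs exceed 1. Empty sticks are refreshed from the
uniform prior to keep exploration alive. Binomial CDFs use the regularized
incomplete beta function.

**Reporting.** Hard assignments are the modal cluster over post-burn-in
sweeps (default 2000 iterations, 500 burn-in); per-mutation posteriors are
the visit frequencies and sum to one. Clusters below `min_cluster_size`
(default 5) merge into the nearest retained center, with their posterior
mass folded in. Reported centers are the per-sample binomial MLE over
final members, Σ alt / Σ depth·ξ — this is robust to transient label
splits during sampling, at the cost of re-introducing a small upward bias
for clusters near the detection floor (negligible for CCF ≥ 0.2 at ~80×).
A drift of more than one occupied cluster between the two halves of the
trace logs a non-convergence warning; results are still returned.

## Pigeonhole phylogeny

A cluster may descend from another only if the candidate ancestor's center
is at least the descendant's minus a tolerance in **every** sample, and
children of one parent may not sum beyond the parent plus the tolerance in
any sample. The default tolerance 0.05 absolute CCF is roughly two
binomial standard errors of a cluster center at 80× coverage. Construction
is greedy in decreasing mean CCF: each cluster attaches to its most recent
feasible ancestor (ties to the larger, then lexically earlier cluster, for
determinism); sibling-sum violations are resolved by nesting the smaller
sibling inside the larger where feasible, otherwise a constraint error
names the offending pair and sample. The invariant is re-asserted on the
finished tree. Newick output carries cluster ids as node labels and
cluster mutation counts as branch lengths.

## Molecular clock

**Rate model.** Per-sample burden y (substitutions passing presence
filtering; for a multi-region donor, the post-clustering union, since
unplaceable low-CCF mutations inflate raw counts) regressed on age with
no intercept — zero somatic burden at birth:

    y_ij = age_ij · (r + b_i) + e_ij,  b_i ~ N(0, τ²), e_ij ~ N(0, σ²)

fitted by maximum likelihood with the variance ratio λ = τ²/σ² profiled
out (the per-donor covariance is rank-one, so GLS quantities have closed
forms). The fit is cross-checked against `statsmodels` MixedLM in the test
suite. With a single donor the model is unidentifiable and a Poisson
regression through the origin (r = Σy/Σage) is substituted with a warning.
BLUP donor slopes are exposed; timing functions use the donor's slope when
available and otherwise the cohort rate, and record which was used.

**Event timing.** On a 2+1 gained arm, clonal mutations at multiplicity 2
predate the gain; they accrued on one chromosome copy at (r/2)·f per year,
where f = gained-arm length / (callable genome / 2) is computed from the
segment table (callable diploid genome default 2.9 Gb, configurable
because it is a pipeline property, not a biological constant). Hence
t_gain = n_dup / ((r/2)·f) and t_MRCA = n_clonal / r. Bootstrap CIs
resample counts as Poisson (mutation acquisition is a Poisson process —
not multinomial) and the rate from a positive-truncated normal with the
fitted SE; CIs are 2.5/97.5 percentiles of 1000 replicates by default.
When fewer than `min_dup` (default 3) duplicated mutations exist the point
estimate is still reported but flagged `insufficient_duplicated_mutations`
— with ~1 duplicated mutation the gain is not reliably timeable and only
the MRCA should be reported. t_gain ≤ t_MRCA is expected for any clonal
gain and is asserted (with bootstrap tolerance) on simulated tumors.

## Spectra

Substitutions collapse to the pyrimidine strand and bin into the standard
96 channels (six substitution classes × 16 flanking contexts, alphabetical
flanks). Clonal/subclonal spectra are compared by cosine similarity; since
no canonical test statistic exists for "the spectra do not differ", a
bootstrap null resampling both spectra from the pooled multinomial
provides a p-value. Note that the cosine of two finite samples from the
*same* process is well below 1: approximately Σp² / (Σp² + Σp(1−p)/n),
about 0.85 at n = 500 and 0.94 at n = 1000 for a spread 96-channel
distribution — comparisons should be read against that baseline, which is
what the bootstrap null does.

## Simulator

`sim_evolution` generates the structure the analysis assumes: a genome of
two synthetic chromosomes (chr1 carries a lost arm at 1+0 and a gained arm
at 2+1 — the isochromosome pattern; chr2 is diploid), a clone tree whose
CCFs obey the pigeonhole constraint in every region (validated, with the
violating pair named), Poisson depths (floored at 1) around configurable
means, binomial alt counts at the expected VAF implied by (CCF, purity,
CN, multiplicity), uniform positions within arms, trinucleotide contexts
drawn from a configurable 96-category distribution (uniform by default,
emitted on a random strand), and a pooled panel of normals with
Binomial(panel_depth, panel_error_rate) alt counts. Truncal mutations on
the gained arm split into a Poisson-distributed multiplicity-2 class with
mean (r/2)·f·t_gain and a multiplicity-1 remainder; all other mutations
place across arms with copy-number-weighted probabilities. Per-cluster
mutation counts are fixed by default (deterministic tests) or
Poisson-drawn (rate-recovery tests). Everything is deterministic given the
seed.

Defaults mirror the study conditions the package was designed around:
tumor depth 82×, normal depth 43×, purity 0.81, rate 26 substitutions/
year, donor age 29, gain at 2 years, arm_fraction 0.04, and a default
clone spec of an 80-mutation trunk (MRCA ≈ 3.1 y) plus a 648-mutation
subclone at CCF 0.25 (per-sample burden ≈ 730, high subclonality).
`five_region_spec()` encodes a five-region architecture — short trunk,
three intermediate nodes of which two split into private leaves — whose
reconstruction must show five terminal branches.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: mapping artifacts and strand bias, subclonal or
sample-discordant copy number, overdispersed (non-binomial) read counts,
germline leakage in the panel, kataegis or signature heterogeneity along
the genome, indels and rearrangements, whole-genome duplication, and
selection (no driver events; the clone tree is specified, not evolved).

## Problem sizes

The test suite and worked examples run at desk scale by design: clusters
of 40–150 mutations at depth 80–100, Gibbs runs of 300–900 iterations
(2000 by default in production settings), 100-replicate coverage studies
with 500-sample bootstraps, and 10⁴-locus null studies for the presence
filter. These sizes were chosen so each statistical check has adequate
power (center SEs ≤ 0.01, coverage MC error ≈ 3%) while the whole suite
completes in a few minutes on one core.

## Known limitations

- Gain-region CCF rules are purity-approximate (see above); at purity 0.8
  a clonal single-copy-gain mutation reads CCF ≈ 1.07.
- Battenberg subclonal copy-number states are collapsed to the major
  clone's state; mutations on unsupported states are dropped, not modelled.
- The DP sampler uses no label-switching moves; modal assignments and
  MLE centers are robust to this, but posterior spreads of centers are not
  reported.
- Reported cluster centers near the detection floor retain a small upward
  selection bias.
- The single-region rate substitution (donor BLUP, else cohort rate) is a
  pragmatic choice; with one donor the Poisson fallback understates rate
  uncertainty.
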