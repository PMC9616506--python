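# Methods

This note documents the models, conventions and numerical choices behind
`clonepulse`, and what the synthetic-data experiments do and do not
establish about real data.

## Bulk allele-specific clonality

A copy-number aberration in a bulk sample is modelled as a two-population
mixture: a fraction MSF (mutated sample fraction) of cells carries the
aberrant genotype (N_A minor / N_B major allele copies, total N_t) and
the remainder carries the background genotype (N_p copies, N_p = 2 for
diploid stroma). The two array measurements invert this mixture:

* intensity route: `MSF = (N_p * 2^log2R - N_p) / (N_t - N_p)`. Undefined
  for copy-neutral events (N_t = N_p), which carry no intensity signal.
* allelic route: `MSF = (1 - 2*mBAF) / (mBAF * (N_A + N_B - 2) - N_B + 1)`,
  with mBAF the mirrored frequency of the major allele in [0.5, 1].
  Undefined for allelically balanced genotypes (N_A = N_B), whose mBAF
  stays 0.5 at any mixture fraction.

Orientation convention: N_B is the *major* allele in aberrant cells
(N_A <= N_B; violating inputs are swapped with a warning). With this
orientation the printed formula is the exact inverse of the forward
allele-mixture model, which the round-trip tests verify to 1e-9 over the
full (m, N_A, N_B) grid.

Clamping: inverted MSF values within 0.05 of [0, 1] are clamped into the
unit interval (measurement noise); values further out are returned
unclamped with an out-of-range flag, because overshoot of that size
indicates a mis-specified allelic composition rather than noise.

Segments entering the analysis must span >= 50 kbp and be supported by
>= 50 array probes, both boundaries inclusive; coordinates are 1-based
inclusive (SEG dialect) and length = end - start + 1.

Purity (TCF) is the mean MSF of the aberrations designated clonal, with
the interval of clonal events TCF +/- 2*SD_MSF (sample SD, ddof = 1; zero
for a single value). The interval is applied on the MSF scale; dividing
both bounds by TCF gives the identical classifier on the MCF scale, so
the two published renderings of the interval formula are equivalent. An
MSF exactly on a bound counts as clonal; clonal aberrations get MCF set
to exactly 1, subclonal ones keep MCF = MSF / TCF (clamped to [0, 1]).

Clonal designation is a manual step in the original workflow. The default
path takes an explicit per-segment designation; an automated proxy
(`designate_clonal_auto`) instead takes the densest cluster of MSF values
inside a 0.1-wide window containing the maximum MSF.

Precision under noise: with Gaussian noise of sd sigma on log2R, error
propagation gives sd(MSF) = N_p * ln2 * 2^log2R * sigma / |N_t - N_p| —
about 0.03–0.04 at sigma = 0.02 for single-copy gains near clonality.
Per-segment MSF is therefore only accurate to roughly +/-0.06 (95%) in
the worst case, while TCF, an average over several clonal segments, is
recovered within +/-0.05 in >= 95% of simulated samples. The simulation
tests assert exactly these two statements (unbiasedness with calibrated
per-segment coverage; sample-level purity recovery).

High-grade amplifications: the total ploidy N_t used for their MSF is
whatever the allelic composition declares; such calls are inherently
low-confidence because N_t for an amplification is poorly identified.

## Single-cell CNA events and clones

Input is an integer copy-state matrix on ~1-Mb bins (BED convention,
0-based half-open) by cells. Candidate events are maximal runs of
consecutive same-chromosome bins at a constant state deviating from the
baseline ploidy (2 by default, per-cell overridable for WGD cells). Two
curation cutoffs grade runs:

* imbalance: >= 5 consecutive bins;
* high-grade amplification: >= 2 consecutive bins at a state at least
  `amplification_state_threshold` (default baseline + 3, i.e. >= 5 copies
  on a diploid background — MYCN-level amplification is far above a
  single-copy gain; no published value exists, so the default is a
  documented choice). A run qualifying for both grades is emitted once,
  as an amplification.

By default a single dissenting bin breaks a run (the strict, reproducible
reading of a manual curation step). For noisy data two knobs exist:
`max_gap_bins` merges same-state runs separated by at most that many
dissenting bins (the gap is absorbed), and `match_tolerance_bins` in
clone grouping snaps events whose span boundaries differ by at most that
many bins onto the variant carried by the most cells. Exact-set grouping
is brittle by construction — a single boundary-bin flip makes a cell's
event set unique and splits it into a singleton clone — so with per-bin
flip noise of 1% the strict defaults recover essentially no clone
structure, while `max_gap_bins=1` with `match_tolerance_bins=2` recovers
the planted partition with adjusted Rand index >= 0.9 in >= 90% of
replicates (20 cells, 3 clones, events >= 8 bins). Noise-free calling is
exact under the strict defaults, and that exactness is what the
acceptance tests pin down.

Clones are cells with identical event sets; event-free cells form the
designated "baseline" clone. Labels (C1, C2, ... by decreasing size,
ties toward the lexicographically smallest member cell) are deterministic
under cell reordering. The event matrix is binary over the union of
events, rows in genomic order, clone columns weighted by cell count.

## Maximum-parsimony clone trees

Events are binary characters on a tree rooted at an unaberrated (all-zero)
ancestor; gain and loss of a character each cost one change (unordered
Fitch counting — no published character model exists, so the minimal
standard choice is used). The score of a topology is the summed per-event
Fitch minimum, including the root edge. The implementation packs all
characters of a node's Fitch state set into one integer, two bits per
event, so an up-pass costs a constant number of big-integer operations
per node.

Search: exhaustive enumeration of all rooted binary topologies (memoized
per leaf count; (2n-3)!! trees, practical to ~9 leaves and guaranteed
optimal — the default for <= 7 leaves) or, for larger inputs, stepwise
addition with randomized tie-breaking followed by best-improvement
nearest-neighbor-interchange hill climbing, restarted from 10 seeded
addition orders. Among co-optimal trees the lexicographically smallest
canonical (sorted-newick) form is returned, making output reproducible.
The heuristic matches the exhaustive optimum on 200 random matrices with
3–7 leaves and up to 12 events in the acceptance suite; this is an
empirical check, not a guarantee — NNI searches can in principle stop in
local optima.

Edge labels (events acquired/lost) come from a standard minimum-change
refinement: the up-pass preliminary sets, then a down-pass that keeps the
parent's state when possible and otherwise prefers presence. The stem is
the intersection of all leaves' event sets. Homoplasy: per event, the
Fitch minimum-change count on the *fixed* tree; a count >= 2 means the
event cannot be explained by a single origin and is flagged as parallel
(a loss also counts as a change, so a gained-then-lost event is flagged
as well — the count is a lower bound on independent appearances).
Cross-model convergence matches events by chromosome, direction and
reciprocal span overlap >= 50%.

Maximum-likelihood reconstruction is deliberately out of scope; the trees
here are interpreted combinatorially, not parameterized.

## Heterogeneity indices

* CNAB = sum over clones of f(clone) x CNA(clone), where CNA(clone) is
  the summed |copy deviation from a diploid cell| over the clone's
  aberrations, stem events excluded (so models are compared on what they
  accumulated beyond shared starting material). The deviation reference
  is diploid by default and configurable (e.g. the sample's modal ploidy
  for WGD models). CNAB is linear in clone frequencies.
* Simpson's index of diversity Ds = 1 - sum(f^2) over clone frequencies:
  0 for a monoclonal tumor, bounded by 1 - 1/k for k clones, maximized at
  the uniform mixture. Both bulk-deconvolved clone frequencies and
  single-cell clone counts are accepted — the definition only needs a
  normalized frequency vector.
* Private-aberration fraction: the share of a tumor's non-stem clones
  (exact event-set equality; optionally individual events under the
  convergence rule) found in no other tumor of the same model. Requires
  >= 2 tumors.

Fish-plot export works on the cellular-prevalence scale (a clone plus all
its descendants), the scale on which parent–child nesting is meaningful;
`to_prevalence` converts the disjoint clone fractions (which sum to 1 and
can never violate nesting) using the clone tree. Validation rejects any
time point where a clone's children sum above the clone itself
(tolerance 1e-6), names the offending time and clones, fills absent
clones with 0, interpolates linearly, and places a clone's emergence at
the midpoint before its first nonzero observation (the standard fish-plot
convention).

## Signatures and survival filtering

Samples are scored by the average z score over a signature's genes; each
gene is standardized across samples (population sd, ddof = 0), constant
genes are dropped with a warning. Variable-gene selection ranks by sample
variance (ddof = 1 — the estimator is not published; sample variance is
the documented choice), descending, ties toward the lexicographically
smaller identifier.

Merged signatures are provenance-tracked unions. A gene claimed by both a
signature and its opposing set goes to the side with more supporting
source lists; ties are dropped from both sides and recorded.

The survival filter re-implements the Kaplan–Meier/log-rank machinery
from its standard definitions so the chain is self-contained and
testable: patients split at the median of the gene's expression (ties to
the low arm — the common "median cut" convention, flippable), then the
1-df log-rank chi-square with the hypergeometric variance at each death
time. The implementation is cross-checked against lifelines in the test
suite, and its null p-values are uniform (KS distance < 0.08 at 1,000
replicates). BH adjustment runs across the signature's genes
(statsmodels' step-up implementation behind the `bh_fdr` surface);
retained = q < 0.05. A directional filter (on by default when the
signature declares a prognosis) additionally requires the worse-survival
arm to match the declared direction — whether the original analysis
filtered on direction is not stated, so the step is off-switchable.

## Treatment response

V = pi * l * s^2 / 6 (mm^3) from caliper long/short sides (swapped inputs
corrected with a warning). Response classes follow the PPTP framework on
volume relative to baseline (first observation at/after randomization),
evaluated over the treatment window: CR when the volume drops below the
measurable minimum (default 100 mm^3), maintained CR when that still
holds at the last in-window observation, PR at >= 50% regression without
CR, PD at >= 25% growth without ever regressing past 50%, SD otherwise.
Relapse is regrowth above 200 mm^3 after a CR or after surgical
resection. The exact published parameterization (evaluation window,
minimum SD duration) lives in an unavailable supplement; these defaults
are this package's documented choices, echoed into every output, not the
original study's values. Relative-volume classes are scale-invariant;
CR/relapse use absolute thresholds and scale with them.

## Synthetic data

All generators are pure functions of (seed, config); regeneration is
bit-identical. The genome model is the 22 autosomes at GRCh38 lengths
rounded to 1-Mb bins (no sex chromosomes — the modelled CNAs are
autosome-dominated).

* Clone trees: random attachment of each new clone to a uniformly drawn
  existing clone; per-branch events drawn without within-lineage span
  overlap (lengths 8–30 bins, copy changes +1/+1/-1/+2 by default);
  optional whole-genome doubling at the stem doubles the baseline.
  Parent event sets nest within child sets by construction.
* Bulk segments: true MSF = purity x (summed frequency of carrying
  clones); log2R and mBAF from the forward mixture models plus Gaussian
  noise (sigma_log2r = 0.02, sigma_baf = 0.01; mBAF noise mirrored back
  into [0.5, 1]); optional decoy segments planted below the curation
  filter. At zero noise the forward model is the exact inverse of the
  MSF formulas (asserted over a grid).
* Single-cell matrices: cells drawn from a clone mixture; per-bin states
  from the clone's lineage events; independent per-(bin, cell) +/-1
  perturbations at rate `flip_noise` (default 0.01), clipped at zero.
* Expression/survival: gene baselines N(mu_g, 1); a planted signature
  shifted by delta (default 1.0) in one sample group; patients carry a
  latent score s ~ N(0,1) that signature genes load on, with survival
  times exponential at hazard h0 * exp(beta * s) and independent
  exponential censoring tuned to ~30%. `beta_for_halves_hazard_ratio`
  converts a between-median-halves hazard ratio into beta via the mean
  half-gap 2*sqrt(2/pi) of a standard normal.
* Volume series: piecewise-exponential trajectories per response
  archetype (PD, SD, PR, CR, CR with relapse, surgery cured, surgery
  relapsed) from a 500 mm^3 baseline, sampled every 3 days over 70 days
  with a 42-day treatment window, with multiplicative log-normal noise
  (sd 0.05 on the log scale).

Noise defaults were chosen once to be visibly nontrivial yet recoverable
by the corresponding estimator; all are config-exposed.

### What the synthetic experiments do not show

The generators emulate the *statistical structure* of the study's inputs
— mixture signals, run-length event structure, nested clone frequencies,
proportional-hazards expression links, archetypal growth curves — not
real measurement physics. They contain no probe-level artifacts, GC or
mappability waves, segmentation errors, doublets, batch effects, or
deviations from proportional hazards. Passing tests therefore establish
that the *computations* are correct and well-calibrated under their own
stated models, not that the upstream assays behave this way. Results that
require the original tumors or external patient cohorts (specific gene
lists, survival curves of named models) are out of reach at desk scale
and are not claimed.

## Problem sizes used

Simulation-backed checks run at sizes that keep the full suite under a
minute of compute for each module: 200 samples for purity recovery, 100
replicates for noisy clone-partition recovery, 200 random matrices for
parsimony optimality, 1,000 replicates for log-rank null calibration,
200 null cohorts for FDR control, 50 cohorts at n = 300 for power, and
50 seeds x 7 archetypes for response round-trips.
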