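# Methods

This note records the statistical models implemented in `mitopop`, the
defaults and why they were chosen, the numerical decisions, and what
the synthetic-data calibration does and does not demonstrate.

## Input model and site filtering

All statistics operate on an alignment of equal-length haploid
sequences over `{A,C,G,T,-,N}` with a sample→population map (and an
optional population→basin map). The default gap policy is *complete
deletion*: any column containing `-` or `N` in any sequence is removed
before analysis, and the retained original column numbers (1-based)
travel with the filtered alignment. This mirrors the default of the
standard desktop tools for this workflow and guarantees every
statistic sees the same site set; the alternative (`none`) is exposed
but untreated columns then count toward Hamming distances. Sequences
differing only at deleted columns collapse into one haplotype — a
deliberate consequence of the policy. `U` is rejected: the package is
DNA-only by contract.

## Diversity indices

For haplotype counts c₁…c_m with n = Σcᵢ and pᵢ = cᵢ/n:

- Hd = n/(n−1)·(1 − Σpᵢ²), Nei's unbiased gene diversity. This equals
  exactly the probability that two sequences drawn *without*
  replacement are different haplotypes, which is how the test-suite
  checks it by enumeration. Monomorphic samples give Hd = 0; n < 2 is
  an error rather than a silent 0.
- k = Σ_{i<j} cᵢcⱼ dᵢⱼ / C(n,2) with d the haplotype Hamming matrix:
  the mean over all unordered sequence pairs, same-haplotype pairs
  included at distance 0.
- π = k/L with L the post-filter alignment length.

Report rounding follows the field's convention (Hd and k to 3
decimals, π to 4); all returned values are full precision.

## Distances

Transitions are A↔G and C↔T; everything else is a transversion. The
Kimura 2-parameter distance is d = −½ln(1−2P−Q) − ¼ln(1−2Q) on the
transition/transversion proportions P, Q, raising a saturation error
when a log argument is non-positive rather than returning NaN.
Population-level distances are count-weighted means over sequence
pairs: dxy (between-population mean) and the net distance
da = dxy − (π_X + π_Y)/2. Sampling noise can push da slightly
negative; it is clamped to zero with a warning, since a negative net
distance has no interpretation at this scale. Population trees use
dxy under K2P by default.

## AMOVA and Φst

The two-level analysis of molecular variance uses squared
inter-haplotype substitution counts (Φ-statistics, the convention of
the standard permutation-testing software): SSD_total is the sum of
squared distances over all pairs divided by N, SSD_within the per-
population analogue, with df = (P−1, N−P), σ²_b = SSD_within/df_within
and σ²_a = (SSD_among/df_among − σ²_b)/n′ where
n′ = (N − Σn_p²/N)/(P−1). Φst = σ²_a/(σ²_a+σ²_b); negative estimates
are reported as computed (they are legitimate sampling outcomes), and
the degenerate all-identical case reports Φst = 0 by convention.
Significance comes from permuting individuals among populations with
sample sizes fixed; p = (hits+1)/(n_perm+1) so that p is never zero.
Pairwise Φst runs a two-population AMOVA per pair (1000 permutations
by default) and flags significance after Bonferroni correction at the
adjusted 0.05 (`*`) and 0.01 (`**`) tiers over the C(P,2) tests. A
three-level (basin/population/individual) partition is deliberately
out of scope.

## Neutrality tests

Tajima's D uses the 1989 constants (a₁…e₂ as usually written);
S = 0 raises an "undefined" error, which is semantically different
from D = 0. Fu's Fs computes S′ = Pr(K ≥ K_obs | θ, n) under the Ewens
sampling formula, Pr(K=k) = |s(n,k)|θᵏ / (θ(θ+1)⋯(θ+n−1)), with
unsigned Stirling numbers of the first kind built by the row
recurrence in log space — the log-space form plays the role of
per-row rescaling and keeps n ≈ 200–250 exact to ~1e−10 (the
test-suite checks normalisation at n = 250). The θ plug-in is k (the
π-based estimate), the conventional choice of the standard
implementations. K_obs = 1 returns +∞ (S′ = 1: nothing can be
rejected). Optional p-values for D and Fs are estimated by simulating
constant-size coalescent replicates at θ̂_W and reporting
Pr(statistic_sim ≤ statistic_obs), one-tailed toward expansion.

## Mismatch distributions and expansion dating

The observed mismatch distribution is the count-weighted frequency
spectrum of pairwise difference counts. Two model tiers are fitted by
least squares on the frequency scale:

- `poisson`: F_i = e^{−τ}τ^i/i!, the pure-expansion limit — closed
  form, used as a verification target;
- `rh92` (default): the sudden-expansion law
  F_i = F̂_i(θ₁) + e^{−τ(θ₁+1)/θ₁} Σ_j (F̂_j(θ₀)−F̂_j(θ₁)) τ^{i−j}/(i−j)!
  with equilibrium term F̂_i(θ) = θ^i/(θ+1)^{i+1}. The implementation
  was verified against direct numerical integration of the pair-
  coalescence derivation and against both analytic limits (τ = 0 →
  equilibrium at θ₀; θ₀ = 0, θ₁ → ∞ → Poisson).

τ is estimated by least squares (grid initialisation over τ, θ₀ and
Δ = θ₁−θ₀ followed by bounded L-BFGS-B; fully deterministic), not by
the mode of the observed histogram — the mode is a coarse integer
statistic, though it is exposed separately (`tau_mode`) because some
workflows quote it. An all-mass-at-zero histogram returns the τ = 0
boundary with a warning. Equilibrium and kernel terms are evaluated in
log space: the naive power form overflows int64/float64 at the large-θ
limits the fit explores.

Expansion time is t = Tτ/(2µk) with T the generation time in years, µ
the per-site per-generation mutation rate and k the fragment length. µ
is a required user input and may be a range, yielding a time interval;
no default is supplied because published mitochondrial rates vary by
an order of magnitude.

## Trees

UPGMA and NJ are implemented in-package so that tie-breaking is
deterministic (lexicographically smallest label pair) and trees are
bit-reproducible; scikit-bio provides the TreeNode container and
Newick I/O, and its independent NJ implementation plus scipy's
average-linkage serve as cross-check oracles in the tests, never as
the implementation. NJ clamps negative branch lengths to zero and
transfers the deficit to the sister edge, preserving path lengths.
Bootstrap support resamples alignment columns with replacement,
rebuilds the population tree per replicate, and scores each internal
edge of the reference tree by the percentage of replicates containing
its bipartition. Bipartitions carried by (near-)zero-length edges are
treated as unresolved and excluded — without this, deterministic
tie-breaking would manufacture 100% support from uninformative data.
An optional outgroup label re-roots the NJ tree for display; fetching
outgroup sequences from databases is out of scope.

## Haplotype networks

The minimum spanning network is the union of all minimum spanning
trees (an edge is kept when its endpoints lie in different components
of the strictly-lighter subgraph). Median joining (ε = 0) iteratively
proposes majority-consensus vectors of node triplets — restricted to
triplets whose mutual distances are within the current network
diameter, a runtime bound — and accepts the proposal that most lowers
the minimum-spanning cost, stopping at a fixed point; unused medians
are pruned. "Ancestral weights" are pooled relative frequencies: on
star-like data this is exactly what network software prints as the
outgroup weight, and it is documented as that proxy rather than a
reimplementation of any tool's internal score.

## The synthetic-data generator

The generator is the package's calibration instrument and stands in
for surveys whose raw sequences are not public. It simulates a Kingman
coalescent in units of 2N generations under three histories: constant
size; sudden expansion (coalescence at the present rate until
t_change = τ_true/θ₁ units back, then at the rate inflated by θ₁/θ₀ —
the truth record stores τ_true = θ₁·t_change in mutational units, the
scale the mismatch fit estimates); and a symmetric island model
(within-deme coalescence, per-lineage migration at M/2). Mutations are
infinite-sites dropped onto a finite fragment (default 647 bp):
Poisson(θ/2 × branch length) per branch, each at a previously
untouched uniformly drawn column (collisions resample; exhaustion is
an error), with transition-biased substitutions (4:1 default, so K2P
is exercised meaningfully) over a COI-like base composition
(A/C/G/T = 0.26/0.19/0.33/0.22). The `study_shape_config` preset
mirrors a typical multi-basin survey: 11 populations, 197 sequences,
647 bp, θ = 1.2 (pooled k near 1, the low-diversity regime of such
surveys).

What the calibration shows: E[TMRCA], E[total length], E[S] and E[k]
match coalescent theory; constant-size replicates centre Tajima's D
near zero while expansion replicates drive D and Fs negative; the
mismatch fit recovers a known τ within ±25% (median). What it does not
show: robustness to features real data have and the generator lacks —
recurrent/back mutation, rate heterogeneity across sites, sequencing
error, selection, recombination (absent by design for mtDNA) and
unequal deme sizes. Passing tests certify the estimators under the
stated models, not those violations.

## Problem sizes used in the automated checks

The statistical suites run at sizes chosen to make Monte-Carlo error
comfortably smaller than the asserted tolerances while keeping the
suite quick: 2000 constant-size replicates (n = 30, θ = 5) for the
D/S/k calibration at 3–8% tolerances, 200 expansion replicates
(n = 100) for τ recovery, 50 random tables for the exact enumeration
oracles (1e−9), 200 null datasets for permutation-p uniformity, and
100–400 bootstrap replicates for tree supports.

## Known limitations

- Fu's Fs p-values use the simulation route only; the package does not
  reproduce any particular desktop tool's analytic approximation.
- The median-joining search is greedy (best single median per
  iteration) and bounded by the network diameter; for very reticulate
  data it may add fewer medians than exhaustive implementations.
- AMOVA is two-level only; basin-level hierarchical partitions are
  reported descriptively (per-basin diversity rows), not as a
  three-level variance decomposition.
- Counts-only input yields exactly the statistics computable without
  sequences (Hd, frequencies); everything else is skipped with an
  explicit reason in the pipeline report.
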