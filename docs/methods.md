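# Methods

## The analysis in one paragraph

A SELEX experiment iterates selection (binding to an immobilized
protein) and amplification over a random-core nucleic-acid library,
sequencing an aliquot after each round. The analysis recovers each
read's variable region, discards reads with any base below Q30,
tallies per-round sequence frequencies, keeps sequences that exceed a
detection threshold in at least one round, clusters them into families
by edit distance, and characterizes the winning families: abundance
trajectories, consensus logos, G-doublet content and quadruplex
G-scores. Competition immunoprecipitations and gene-list overlaps are
analyzed with the matching elementary statistics (fold-enrichment
ratios with exact rank tests; hypergeometric tails).

## Read processing

Reads are `flank5 + core + flank3` with a fixed-length random core (26
nt for the DNA design, 50 nt for the RNA design). Flank matching is
substitution-only and anchored: the 5′ flank may start at offsets 0–4
(sequencing occasionally clips a leading base), the 3′ flank is sought
at the position implied by the core length ± 2 nt; up to
`max_flank_mismatch` (default 2) substitutions are allowed per flank.
Indel errors in a flank therefore cost the read, which is acceptable
at Illumina error profiles where substitutions dominate. Rejections
(`low_quality`, `flank5_missing`, `flank3_missing`, `bad_length`) are
tallied, never fatal, and the report asserts
raw = passed + Σ rejected each round. Phred+33 is assumed with the
offset configurable. RNA is handled as its sequenced cDNA: sequences
are normalized to the DNA alphabet (U→T) internally and re-printed as
U when the design chemistry is RNA. An empty read passes the
(vacuous) quality filter and is rejected at extraction.

One published-design oddity is recorded rather than resolved: the RNA
library is described as 91-mers, but the printed 23-nt flanks plus the
50-nt core total 96 nt. The package uses the printed sequences.

## Detection and enrichment

Frequencies are computed over quality-passing, successfully extracted
reads only. Detection is strict: frequency > `min_freq` (3e-5 for the
DNA screen, 5e-5 = 50 copies per million for the RNA screen) in at
least one round; a sequence at exactly the threshold is excluded.
Detected sequences carry their full frequency series (0 where absent),
and the per-round "pool fraction" is the summed frequency of the
detected set. Composition tracking is count-weighted (reads, not
unique sequences), since it describes the library, and equals 25% per
base for an unbiased round 0.

k-mer logos: the `top_n` (default 20) most frequent 8-mers of the last
round are ungapped-aligned to the single most frequent one, trying
offsets −3..+3 and keeping the highest identity (ties resolved toward
offset 0, then the smaller shift); a frequency-weighted PWM is built
over the reference width, renormalizing columns where shifted k-mers
do not cover a position. The alignment rule is this package's own
choice — displayed aligned k-mer stacks rarely state one — and `top_n`
is exposed because logos over the top handful and over a large set
genuinely differ.

## Family clustering

The distance is Levenshtein (substitutions, insertions, deletions all
cost 1; computed with edlib) and the threshold is 10. The clustering
algorithm is greedy and abundance-ordered: the unassigned sequence
with the highest last-round frequency (ties: lexicographically
smaller) seeds a family and absorbs every unassigned sequence within
the threshold. This is deterministic, standard for aptamer pools, and
avoids the chaining that single linkage produces between distinct
G-rich families. Each family records its members, per-round abundance
(sum of member frequencies) and internal diameter (max pairwise
distance), the latter so the observation that real families are much
tighter than the threshold can be checked descriptively. Family
logos weight seeds by family abundance by default; a
`member_weighted` flag spreads each family's weight over its members
instead.

## G-quadruplex scoring

A candidate is four maximal G-runs of length ≥ `min_run` (default 2)
spanning ≤ `max_len` (default 30) nt; loops are the inter-run gaps,
tetrads the shortest run length. All 4-subsets of runs within the span
bound are enumerated, so overlapping candidates are all reported. The
integer score is

    g_score = 27 + 12·(tetrads − 2) − Σ loops − (max loop − min loop)

The two penalties implement the standard QGRS principles (shorter
total loops better; more even loops better) and the tetrad term
dominates both. The additive constants are this package's
calibration: published QGRS-style scores state the principles but not
the constants, so they were fixed by requiring the known anchor — the
28-nt G₂-rich consensus `GGNNGGNNGGNGGANGGANGGNNGGAGG` scores exactly
21 with default parameters (all five of its consecutive-run candidates
score 21; skipping a run only lengthens loops and lowers the score).
Consequences worth knowing: a two-tetrad candidate with zero-length
even loops would score 27, and scores can go negative for sprawling
candidates near the span limit. Because runs are maximal, a single
long G-run (e.g. G₈) is one run, not four — adequate for G₂-rich
aptamer pools, but not a general-purpose quadruplex finder. `N` is a
non-G wildcard: it can sit in a loop but never extends a run.

The relaxed-consensus matcher compiles the pattern
G₂N₁₋₄G₂N₁₋₃G₂N₁₋₃G₂AN₁₋₂G₂AU₀₋₁G₂N₁₋₃G₂AN₀₋₂G₂ to a regular
expression over the DNA alphabet (N = any base) and reports the
longest match per start position. Note the pattern's fixed A/AU
anchors: only instantiations consistent with them match (the pattern
string itself contains no concrete bases at N positions and is not its
own instance).

## Competition statistics

Retention frequencies are counts normalized within a replicate (they
sum to 1, so depressed retention of some aptamers mechanically
inflates the rest — ratios, not absolute affinities). The fold
enrichment FE = count(target)/count(scr50) is computed per replicate
and is scale-invariant. Zero control counts raise an error directing
the caller to the optional +0.5 pseudocount (off by default; the
control being "basically absent" should be loud, not silent).

Condition comparisons are two-tailed. The Mann–Whitney U test uses
full enumeration of all C(n₁+n₂, n₁) labelings when n₁+n₂ ≤ 12, with
midrank (0.5) tie handling, and the p-value defined as
P(|U − n₁n₂/2| ≥ |U_obs − n₁n₂/2|); larger samples use the normal
approximation with tie correction (scipy). The Student's t test is
scipy's two-sample test. One statistical caveat is inherited from the
assay design and left visible: with a single replicate per condition,
the per-aptamer ratios are pooled into one sample for testing (the
`pooled` entry); treating different aptamers' ratios as exchangeable
replicates is unusual, and the package exposes it without endorsing
it. Note also that the exact Mann–Whitney at 3 vs 3 replicates cannot
reach p < 0.1, so small-replicate power and calibration checks in the
test suite use the t-test branch on near-normal deep-count ratios.

## Gene-list overlap

Identifiers are upper-cased and de-duplicated; the overlap test
reports k, the expectation n₁n₂/N, the representation factor
k/(n₁n₂/N) and the exact upper tail P(X ≥ k) of
Hypergeometric(N, n₁, n₂), summed in log space (gammaln + logsumexp)
so deep tails (10⁻¹² and far beyond) are exact to rounding. The
universe size N is a required argument: it dominates the p-value and
a silent default would be misleading. With the study-sized lists
(360, 3381, k = 114) and N = 20 000 the tail is 3.15e−12.

## The simulator

What it emulates: (a) uniform random cores between the printed flanks,
optionally seeded with planted motif classes — either explicit founder
sequences (a "family": identical molecules whose read-level variants
come from sequencing error) or a pattern instantiated into founders;
(b) selection as independent Bernoulli retention with probability
`nonspecific_retention` × selection weight (capped at 1), followed by
resampling with replacement to the constant pool size (PCR), so a
planted class with advantage s follows f′ = s·f/(s·f + 1 − f) in
expectation — latency, then takeoff; (c) sequencing as sampling with
replacement, substitution errors at `per_base_error`, qualities
uniform in 30–40 except a `quality_fail_fraction` of reads that get
one sub-30 base and thus fail the Q30 filter; (d) multinomial
competition counts at given retention ratios; (e) gene universes with
an exactly planted overlap. Every draw flows through one seeded
generator; outputs are byte-identical across runs.

Defaults are the study conditions: 50-nt RNA core, pool size 10⁵,
six rounds, 10⁵ reads/round, one planted G₂-rich founder (a fixed
instantiation of the consensus embedded in random background) with
selection weight 10 and initial frequency 10⁻³, nonspecific retention
0.05, per-base error 0.002, 10% quality-fail reads. The retention and
error levels are generic bead-SELEX/Illumina magnitudes chosen once;
at these settings the simulated trajectory (0.001 → 0.01 → 0.09 → 0.50
→ 0.91 → 0.99 → 0.999) shows the round-3 takeoff characteristic of
real selections, G content climbs from 25% to ~40%, and the planted
family ends >99% of the pool.

What it does not emulate — and hence what passing tests do not show
about real data: PCR amplification bias and chimeras (resampling is
uniform; a hook exists in the design for bias), secondary-structure- or
chemistry-dependent binding (Li⁺/K⁺ effects enter only as condition
labels with different retention ratios), indel sequencing errors,
position-dependent quality decay, negative-selection rounds (available
only as a flat depletion option), and carry-over contamination.
A visible emergent artifact: the 5% nonspecific retention bottleneck
gives every background survivor ~20 copies after amplification, so
early rounds "detect" thousands of background sequences at the 50/10⁶
threshold; they form singleton families that melt away as the planted
family takes over — qualitatively like the real family-count collapse
after round 5, though for a partly different reason (drift through a
bottleneck rather than competition among specific binders).

## Problem sizes and numerical choices

The test suite runs the full-scale recovery (6 rounds × 10⁵ reads,
~5 000 detected sequences clustered) in under a minute and the 10⁴-run
null calibration of the FE test in a few seconds; hypothesis-based
property tests are derandomized for reproducibility. Floating-point
tolerances: PWM columns sum to 1 within 1e-9; the log-space
hypergeometric tail matches direct summation within 1e-12 on all
N ≤ 30 instances; family-abundance bookkeeping matches pool fractions
within 1e-9. Determinism contracts (same seed → identical pools,
byte-identical FASTQ, identical pipeline reports) are tested directly.

## Known limitations

* The G-score constants are a calibration to one anchor plus ordering
  principles; scores are comparable within this package, not
  guaranteed to match any external tool's output beyond the anchor.
* Greedy clustering is order-dependent by design (abundance order);
  it is reproducible but not an optimal partition.
* The flank matcher tolerates substitutions only; indel-containing
  flanks are counted as rejections.
* The exact Mann–Whitney enumeration is O(C(n₁+n₂, n₁)) and switched
  off above 12 pooled observations.
* `enumerate_gqs` considers maximal G-runs only; it will not split a
  long G-run into multiple tracts.
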