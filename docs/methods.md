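# Methods

## The measurement and the statistic

DMS methylates the base-pairing face of accessible A and C nucleotides.  Under
mutational-profiling (MaP) reverse transcription, each adduct is recorded as a
mutation in the cDNA, so one sequencing read reports multiple modification
events on the *same* molecule.  If two nucleotides are structurally coupled —
for example they are alternately exposed in two conformations of an ensemble —
their modification events co-occur (or mutually exclude) across molecules.

For every position pair (i, j), i < j, the package maintains a 2×2 contingency
table over all quality-passing reads covering both positions:

|            | j mutated | j unmutated |
|------------|-----------|-------------|
| i mutated  | n11       | n10         |
| i unmutated| n01       | n00         |

Independence is tested with the continuity-corrected (Yates) chi-squared
statistic,

    chi2 = N (max(0, |n11·n00 − n10·n01| − N/2))² / (R1 R2 C1 C2),

where N = n11+n10+n01+n00 and R/C are the row/column marginals.  The
correction term is clamped at zero, which is the behaviour of standard
implementations (scipy adjusts each cell by at most its distance to the
expectation); without the clamp, near-independent tables would get a spurious
positive statistic.  Correlation strength and direction come from the phi
coefficient,

    phi = (n11·n00 − n10·n01) / sqrt(R1 R2 C1 C2),

the Pearson correlation of the two binary outcomes.  Pairs with chi-squared
*strictly above* 20 (1 df; upper-tail probability 7.7×10⁻⁶ < 10⁻⁵) and
pairwise depth N ≥ `depth_min` are reported as RINGs (RNA interaction
groups).  No multiple-testing correction is applied beyond the fixed
criterion; this is deliberate and matches the method the package implements.

`depth_min` defaults to 10,000.  The chi-squared approximation is poor at low
N for the small effect sizes (|phi| ≈ 0.01–0.03) seen in cells;
empirically ~50,000 co-observations are needed there, which is why
`detection_interval` summarizes, per pair separation, whether the library
geometry actually delivers that depth.  Synthetic scenarios use larger effect
sizes, so a lower depth floor is usable and keeps desk-scale runs tractable;
both knobs are exposed.

## Accumulation without storing reads

Memory depends only on the RNA length: three L×L count matrices (pair
coverage; i-mutated-and-j-covered; both-mutated) fully determine every pair's
table.  Per read chunk, coverage contributes axis-aligned rectangles (one per
ordered pair of covered intervals) applied to a 2-D difference array;
mutation×interval terms contribute row-wise difference updates; only
mutation–mutation pairs are enumerated explicitly (a handful per read).  A
final prefix-sum materializes the matrices.  This makes per-read work linear
in the number of intervals and mutations rather than quadratic in covered
length.  Correctness is pinned by an exact cell-by-cell comparison against a
naive per-read, per-pair recount on hundreds of randomized micro-fixtures.

Because pairs are indexed independently, paired-end mates separated by a gap
contribute every co-covered pair across the gap — this is what extends the
detection reach to the insert size (500–700 nt) rather than the read length.

The quality rule (drop bases below the phred cutoff from coverage and
mutations) is applied before counting and is idempotent.  Masked positions
(high background mutation rate in an untreated control, typically sequence
polymorphisms) contribute to no table; `flag_high_background` builds such a
mask with a default rule of untreated rate > 0.03 at depth ≥ 100.  The rule
itself is a package default — only the masking mechanism, not a specific
cutoff, is inherent to the method.

## Replicate merging

A pair is retained only if called independently in both biological
replicates, with the same phi sign.  The merged record keeps the mean phi,
the minimum chi-squared, and the summed depth/table — conservative,
order-independent combiners.  The sign-consistency requirement and the choice
of combiners are package decisions; intersection across replicates is the
method's defining filter.

## Network analysis

Nucleotides are nodes; each ring is an undirected edge weighted by |phi|,
with the sign kept as an attribute (modularity on negative weights is
ill-defined, and the magnitude is what the published weight floor refers to;
a flag allows signed weights for other uses).  The filter is: drop edges with
weight ≤ 0.015, then take the k-core with k = 3 (iterative peeling).
Communities come from Louvain modularity maximization on edge weights at
resolution 1.0, via networkx's seeded implementation; community ids are
relabelled by decreasing size so output is reproducible bit-for-bit given the
seed.

Node strength (weighted degree) is banded strong (> 0.25), medium
([0.1, 0.25], both ends inclusive), weak (< 0.1).  Edge strength is banded at
the 50th/75th weight percentiles: strong ≥ p75, medium in [p50, p75), weak
below.  Percentiles use the upper nearest-rank convention (0-based index
⌊q·n⌋ of the ascending weights): with weights {0.1, 0.2, 0.3, 0.4} only 0.4
is strong and 0.3 is medium, and when all weights tie every edge is strong.
Thresholds are recorded in the outputs so every category is recomputable.

Differential comparisons between conditions operate on the union of edge
sets with absent edges at weight 0: an edge is strengthened when its weight
rises by at least `delta_min` (default 0.01) and weakened when it falls by as
much.

## Footprinting

The conventional per-nucleotide readout is rate = mutations / coverage at
each position.  Differences between conditions are called with a Poisson-
approximation z-statistic, z = (r_a − r_b)/sqrt(r_a/N_a + r_b/N_b), requiring
both |z| ≥ 5 and |Δrate| ≥ 0.01 (defaults; both are configuration keys).  The
dual threshold makes "notable difference" operational: the z-floor controls
false positives across ~1,500 positions, the absolute floor suppresses
trivially significant but tiny differences at extreme depth.

## The synthetic generator

Each molecule draws one binary factor per block (occupancy p_k); a member
position i is modified with probability b_i + f_k·d_i, non-members with b_i.
The observed mutation is `modified OR Bernoulli(e)` with e the background
error; since the two events are independent this is sampled as a single
Bernoulli per covered base.  Binary per-block factors are the simplest
generative model producing block-structured correlations with a closed-form
phi:

    phi(i,j) = cov_f · d_i d_j (1−e)² / sqrt(r'_i(1−r'_i) r'_j(1−r'_j)),

with cov_f = p(1−p) within a block, cov_f = ρ·sqrt(p_a(1−p_a)p_b(1−p_b)) for
a coupled block pair, and r' = r + e(1−r) the error-folded marginal.  MaP
detection efficiency is fixed at 1.0 (every adduct becomes a mutation) so the
oracle stays exact.

Read geometry: insert uniform on [500, 700] (the library's size selection),
fragment start uniform over the valid range, two 150-nt mates at the fragment
ends with a gap when insert > 300.  Per-base low-quality calls are i.i.d. at
2% — a single scalar stands in for the real, highly structured quality
landscape.  Byte-identical output follows from a single seeded PCG64 stream.

The stock "default-domain" scenario is a 1542-nt random-composition RNA with
four 40-member blocks laid out like small-subunit rRNA domains: body (1–560),
platform (561–890), and two *interleaved* head blocks, outer-head within
930–1380 and inner-head+spine combining 930–1380 positions with a distal
1397–1535 stretch (so same-block pairs span > 400 nt and must be linked
through mate gaps).  Occupancy 0.5 and increment 0.3 give within-block
phi ≈ 0.14–0.16; base rates are uniform 0.01–0.05 on A/C and 0.002 on the
near-inert G/U; 200,000 fragments per replicate.  The scenario's structure
(sequence, members, per-position rates) comes from a fixed internal seed, so
replicates and conditions share latent structure while the read seed varies.

The "ligand" scenario adds (i) protection — the outer-head member closest to
position 1192 has its modification probability multiplied by 0.25, mimicking
a drug footprint — and (ii) coupling of the outer-head and inner-head+spine
factors at joint-occupancy correlation 0.8, creating cross-community
correlations with unchanged marginal rates, i.e. a change invisible to
per-nucleotide profiles.  The "null" scenario has no blocks and full-length
coverage on a short reference, giving every pair maximal depth for
false-positive calibration.

What the generator deliberately omits: reverse-transcriptase drop-off and
position-dependent priming bias, PCR duplicates, alignment artifacts,
realistic quality-score distributions, multi-nucleotide deletions, and
in-cell effect sizes (planted |phi| is ~10× the 0.015 network floor, chosen
for statistical power at 200k reads rather than realism).  Passing tests
therefore demonstrate correctness of the counting, statistics and graph
machinery under the stated generative model — not robustness to upstream
artifacts of real libraries.

## Problem sizes and numerical choices

- Stock runs use L = 1542 and 200,000 fragments per replicate (~35 s per
  two-replicate pipeline pass); community-recovery checks repeat the full
  pipeline ten times with fresh read seeds and require the modal outcome.
- Parameter-recovery checks compare empirical phi to the closed form within
  4/√N per pair, over planted pairs with N ≥ 50 and non-degenerate marginals;
  pairs the read geometry never co-covers (separations ~150–280 nt fall
  between mate length and minimum mate gap) carry no empirical phi and are
  excluded.
- Chi-squared/phi return 0 / "undefined" on zero marginals rather than NaN
  propagating into calls; the boundary at the significance criterion is
  strict (a pair at exactly 20 is not called).
- Louvain ties are resolved by the seed; community ids by decreasing size,
  then smallest member.
- The per-pair count matrices are int64 (exact); statistics are computed in
  float64, and TSV output rounds to 6 significant digits.

## Known limitations

- The strict-vs-inclusive reading of the chi-squared criterion and the
  clamped correction are pinned choices; implementations differing on these
  details will disagree on boundary pairs.
- Replicate merging statistics beyond intersection are conventions, not
  estimators with known sampling theory.
- Community detection inherits Louvain's resolution limit; very small true
  communities can be absorbed at resolution 1.0.
- The phi recovery bound 4/√N is an asymptotic normal band and can narrowly
  fail for pairs with very skewed marginals at moderate depth.
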