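# Methods

## Scope and shape

`ystar` implements a complete desk-scale analogue of a targeted
Y-chromosome resequencing study: simulation of genealogies and pooled
capture reads (`simulate`), genotype-state calling and filtering
(`calls`), perfect-phylogeny reconstruction (`tree`), strict-clock dating
(`clock`), star-expansion detection and naming (`expansions`), capture
bait design (`baits`), and an orchestrating pipeline with CLI
(`pipeline`, `cli`). Read mapping, duplicate removal and indel
realignment are out of scope: the pipeline's native input is a
per-sample × per-site table of reference/alternative read counts.

## The generative model

Scenarios are scripted rooted trees with explicit node ages in years
(tips at 0), rather than coalescent draws, so that every simulation
carries exact ground truth for round-trip tests. Three builders cover the
study conditions:

- `star_scenario(k, star_age, root_age)` — one true multifurcation of
  degree k (internal branch length exactly zero) in a small binary
  backbone;
- `binary_scenario(n, root_age, min_age)` — a random binary clock tree
  whose n−2 internal split ages are uniform on (min_age, root_age), with
  lineages merged pairwise at random. This emulates a drift-dominated
  background in which divergences are binary and scattered through time;
  it is deliberately not a constant-size Kingman coalescent, whose burst
  of near-simultaneous recent coalescences would itself look star-like
  at these sample sizes;
- `multi_star_scenario` — a binary background (splits kept older than
  9,000 years) with planted star clades; the default is the study
  condition used throughout: 49 tips, root at 54,100 years, three k=10
  stars at 5,400 / 6,500 / 6,800 years.

Mutations follow a strict clock: each branch of duration Δt receives
Poisson(μ·L·Δt) mutations at distinct uniform positions in [0, L)
(infinite sites; collisions redrawn; error if the count would exceed L).
Defaults μ = 1×10⁻⁹ /bp/year and L = 3.9×10⁶ bp give the working
constant of one substitution per 256.4 years. Reads are simulated per
cell as Poisson(depth_mean) coverage with a symmetric per-read miscall
probability (defaults 6× and 10⁻³, the coverage regime the calling rules
were designed for). One master seed drives deterministic per-stage
generators.

What the simulator does not emulate: reference bias, mapping artifacts,
barcode confusion between pooled samples (the curation states `x`/`@`
are therefore accepted on input but never generated), homopolymer/STR
context errors, and heterogeneous per-sample library quality. Coverage
is homogeneous across samples by construction — a consequence discussed
under "quality tiers" below. Passing tests on this generator therefore
validate the statistical machinery, not robustness to alignment-level
artifacts.

## Calling and filtering

`call_state` is a total function on count pairs: `-` with zero coverage;
`1` when alt ≥ 2 reads and alt ≥ 3/4 of coverage; `0` when ref ≥ 3/4 of
positive coverage; `?` otherwise. Both fraction thresholds are inclusive
(a 3-of-4 read split is called), and the `0` rule deliberately mirrors
the `1` rule's fraction with no minimum read count, so a single
reference read yields a definite `0`. Derived calls seen in exactly one
sample are demoted to `?` unless backed by ≥ 4 alternative reads
(`apply_private_filter`). Site selection requires strictly more than
`min_informative`·n/`total_samples` unambiguous cells (defaults 100/110,
reproducing the published behavior exactly at n = 110 and scaling
proportionally otherwise); monomorphic sites are dropped before tree
building. Known consequence at 6× coverage: ~15% of true private SNPs
fall below the 4-read floor and are discarded, so terminal branch
lengths — and with them star ages — run ~10–15% young. This is the
faithful behavior of the thresholds, not a defect of the estimator, and
it cancels in rank comparisons between contemporaneous nodes.

## Tree building

With a known ancestral state (the reference allele), a set of binary
sites admits a perfect phylogeny iff every pair of derived-carrier sets
is nested or disjoint; clades are then exactly the carrier sets ordered
by inclusion, and every site lands on the edge subtending its carrier
set. `build_tree` constructs this directly. Conflicting sites are
resolved greedily: carrier sets are admitted in order of decreasing
support (number of sites sharing the set), then decreasing size, then
lexicographic site ID; a set incompatible with an admitted one is
flagged homoplasic, reported for curation, and left unplaced. Support
comes first because the realistic conflict is a stray miscall corrupting
one or two sites of a well-supported clade — the automated analogue of
resolving conflicts by consistency with the rest of the phylogeny.
Multifurcations are kept native; no arbitrary binary resolution is ever
introduced, since polytomies are the object of study.

## Imputation

Missing/ambiguous cells are filled by small parsimony on a guide
topology (`pipeline.impute_with_guide`). The guide is built from the
unambiguous (complete) columns only: a column with a missing cell cannot
distinguish a clade from the same clade minus the missing sample, and
treating `?` as ancestral plants spurious nested splits inside
polytomies. A first imputation pass on that guide, a rebuild, and a
second pass on the refined topology recover sparsely supported edges.
Per site, the attainable-state sets of all maximum-parsimony assignments
are computed by a vectorized two-pass (Sankoff-style) recursion; a tip
whose set is a singleton takes that state, and a genuine tie — both
states attainable at minimal cost — is drawn uniformly from the two
alleles under the run seed. A missing tip whose only evidence is a
single observed relative is *not* a tie (parsimony prefers zero changes);
ties arise in symmetric configurations such as a polytomy with balanced
0/1 votes.

Limits of imputation: a masked carrier at a private site leaves no
signal anywhere in the matrix, so no method can restore it; parsimony
returns the ancestral state there. At 5% random masking of the default
study matrix this irreducible class is ~1.6% of masked cells, and
measured recovery sits at that floor (≥ 99% of signal-bearing cells,
~97.6% overall).

## Dating and the clock test

Node age = (mean node-to-tip substitution count)/(μ·L). Because
descendant tips share branches, the mean is not a sum of independent
Poissons; the CI nevertheless treats it as a single Poisson count — the
same approximation behind the ±z/√n theory — which makes intervals
conservative on real tree shapes (measured coverage ~100% at nominal
95% on 49-tip clock trees). Three interval methods: normal (default;
half-width 1.96/√n̄, i.e. ±13.5% at n̄ = 210), exact Garwood chi-square
(±13.8% at n̄ = 210; defined at n̄ = 0, where it reduces to the
rule-of-three regime), and a Gamma(n̄+1, μ·L) central credible interval
under a flat rate prior — the closed-form stand-in for MCMC dating: with
a fixed rate and a strict clock, node age estimation *is* Poisson rate
estimation, so no sampler is needed.

Clock validity is checked with the Poisson index of dispersion
D = Σ(nᵢ−n̄)²/n̄ on root-to-tip counts against χ²(k−1), an explicit
stand-in for a likelihood-ratio clock test (and labelled as such in
reports). Its ~5% size holds for independent counts (measured 4.9% at
k = 49, n̄ = 210 over 1,000 sets) and its power against a 2× rate split
between two halves of the tips exceeds 80% at those sizes; on
tree-structured counts the shared-branch correlation shrinks D, making
the test conservative — it under-rejects, never spuriously rejects, so a
high p-value on a real tree remains the intended "no violation" reading.

`rate_from_outgroup` calibrates an alternative rate from an interspecies
comparison: n substitutions between two species diverged t years ago
imply n/(2t) substitutions per lineage-year over the compared region;
re-dating scales a node's count by the fraction of sites with homologous
outgroup loci before dividing. With the worked inputs (45,800
substitutions, 6 Myr divergence, 3/4 comparable) a 210-count root
re-dates to ≈ 41.3 kyr.

## Star detection and naming

`collapse_short_branches` contracts every internal branch whose duration
cannot exceed the window: the upper one-sided 95% Poisson bound on a
branch with n substitutions is χ²₀.₉₅(2n+2)/2 / (μ·L) years — 768 years
for n = 0 (the rule of three), 1,216 for n = 1, so at the default
1,000-year window only substitution-free branches contract. Contraction
re-attaches children to the parent and adds the contracted count to each
re-attached child edge, preserving every root-to-tip path count exactly
(the contracted site IDs are recorded once, not duplicated). The
operation is idempotent. `detect_stars` then reports every internal node
with ≥ 5 children, its window bound, and its age; it warns when L ≤ 1 Mbp,
where even a zero-count branch cannot be confined to 1,000 years.

Naming assigns Greek letters (Oα, Oβ, …) to expansion nodes — not to any
defining SNP, so names survive later splitting of upstream markers — in
a stable documented order: decreasing descendant-clade size, then
decreasing age, then node name. (Published names follow clade identity,
which synthetic data lacks.) `descent_fraction` sums user-supplied,
survey-derived frequencies of disjoint clades; frequencies are inputs,
not estimates from the sequenced sample.

Detection performance under the study conditions (measured over 100
noisy replicates): all three planted k=10 stars recovered with exact
membership in ~96%, zero stars on fully binary histories in ~98%. The
residual failures are single depth-1 miscalled reads whose 1–2-site
spurious edges legitimately survive the n ≥ 1 collapse bound and split a
polytomy. Rank-ordering the 6.5- and 6.8-kyr stars by estimated age is
intrinsically unreliable at k = 10: the age estimator's SD is ~410 years
per star, so the 300-year gap is resolved in only ~70% of replicates —
a sample-size limit of the estimator, not of the implementation.

## Bait design

Targets are tiled into `window`-bp fragments every `step` bp (defaults
70/10). A fragment is kept iff it occurs exactly once in the whole
genome (its own origin) at Hamming distance ≤ `max_mismatches` (default
2), counting both strands; `N` matches nothing. Matching is an exact
seeded search: the fragment splits into `max_mismatches`+1 disjoint
seeds, so any qualifying occurrence preserves at least one seed intact
(pigeonhole) and is found by k-mer lookup plus O(window) verification —
exhaustive by construction, no external aligner, no heuristics. Kept
fragment ranges are unioned (overlap or abutment merges; at step <
window the distinction only matters for pathological inputs) and merged
ranges shorter than `min_merged_length` (default 240 bp) are dropped.
BED output is 0-based half-open; a companion TSV is 1-based inclusive.
Complexity is O(genome) indexing plus O(fragments × candidates); the
implementation targets desk-scale genomes (≤ ~100 kb in the validation
suite), not 3-Gbp references. A brute-force full Hamming scan
(`unique_regions_bruteforce`) serves as the independent reference; the
two agree interval-for-interval on 100 random genomes with planted exact
and near duplications.

## Numerical and design choices

- Inclusive 3/4 thresholds at exact ties (documented; ties are exact in
  binary floating point since 0.75 is representable).
- Rooting by declaring the reference allele ancestral at every site; an
  outgroup sample can serve instead by recoding against it upstream.
- Quality tiers (good > 6×, moderate 1–6×, low < 1×) are implemented and
  used to restrict dating via `date_tier="good"`; the pipeline default
  dates with all tips because simulated coverage is homogeneous —
  Poisson(6) sample means concentrate at exactly the 6× boundary, which
  would make the strict tier empty or arbitrary. On real data with
  heterogeneous libraries the "good" restriction is the intended mode.
- Sites carry 0-based positions internally and 1-based positions in all
  human-readable files.
- Every output file carries the package version, a configuration hash
  and the master seed; reruns are byte-identical.
- Problem sizes in the validation suite (49 tips, 200/100/1,000
  replicates, ≤ ~2-kb bait genomes) are chosen so the whole suite
  completes in minutes while keeping binomial uncertainty on measured
  rates at the few-percent level.

## Known limitations

Homoplasy handling is flag-and-report, not model-based; heavily
conflicted matrices need curation. The CI-coverage guarantee is
conservative rather than calibrated (shared-branch correlation is not
modelled). The simulator's homogeneous coverage understates the value of
the quality-tier machinery. Bait design is desk-scale by design. The
dispersion clock test has no power against rate variation that preserves
total root-to-tip counts.
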