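# Methods

## The scanning model

The scanner formalizes island discovery as a three-state machine over the
sorted SNP records of one chromosome.  SNPs are classified by global
alternate-allele frequency:

* **impactful** — AF in [`impactful_lo`, `impactful_hi`] (default 0.30–0.70,
  inclusive at both ends).  These carry identity information: intermediate
  frequencies maximize heterozygosity across a population without selecting
  for any subpopulation.
* **ignorable** — AF ≤ `conserved_max_af` (0.005) or ≥ `conserved_min_af_hi`
  (0.995).  Near-fixed sites are treated as invisible: they do not disturb a
  conserved segment.
* **relevant** — everything in between.  These contribute no identity signal
  under the model but any such polymorphism disqualifies a stretch from
  serving as a primer-binding flank.

A candidate island anchors at an impactful SNP whose preceding
`min_flank_len` bases (150 bp) contain no impactful/relevant SNP and no N
base (state LV1 established).  The high-variance state absorbs subsequent
impactful and relevant SNPs while the core — anchor to last absorbed SNP —
stays within `max_island_len` (400 bp).  Once `min_impactful` (3) impactful
SNPs are counted, the machine looks for a clean `min_flank_len` run
immediately after the last in-core SNP (LV2); any SNP breaking that run is
absorbed if the core still fits, otherwise the candidate fails and scanning
resumes at the event after the failed anchor.  On success the verified LV2
run may immediately serve as the next island's LV1.

Two semantic choices were genuinely open and are resolved as follows:

* **Greedy maximal extension.**  After the minimum SNP count is reached, the
  scanner keeps absorbing SNPs until the trailing flank is clean, rather
  than closing at exactly `min_impactful`.  More markers per amplicon means
  more identity information per sequencing target, which is the design goal;
  it also yields a canonical, deduplicated island set in a single pass
  instead of three per-k passes.
* **The length cap applies to the core only.**  Flanks add a fixed 150 bp on
  each side and are not counted against the 400 bp window.  An alternative
  reading caps the whole ~700 bp amplicon; the config accepts any
  `max_island_len`, so that variant is reachable by setting 400 → 100.

The scan is linear in the number of SNPs; the test suite checks it against
an O(n²) brute-force candidate enumerator on a thousand seeded chromosomes.

## Sequence-chemistry filters

Two predicates reject targets whose sequence degrades short-read accuracy.
Both scan the **full target window including flanks**, since the entire
amplicon is sequenced.

* **Homopolymer clusters.**  A `window_len` = 20 bp window slides one base
  at a time.  Within a window, maximal runs of one nucleotide of length
  ≥ `cluster_min_run` = 4 are clusters; if clusters of a single nucleotide
  total ≥ `cluster_total` = 10 bases, the target is rejected.  The summed
  reading (two runs of five count) is deliberately the stricter of the two
  possible readings — it contains the single-run-of-ten reading as a special
  case.  Runs truncated by a window edge count at their truncated length.
* **Tandem repeats.**  A unit of `unit_min`..`unit_max` = 2..7 bp repeated
  strictly more than `max_consecutive_repeats` = 5 times consecutively
  rejects the target.  Detection compares the sequence to itself at each
  offset u: a maximal run of L positions with s[i] = s[i+u] is a period-u
  stretch holding ⌊L/u⌋+1 copies of its leading unit.  Units whose primitive
  root is a single base are skipped (that is homopolymer content, governed
  by the first rule); roots of length ≥ 2 are equivalent to testing the
  primitive unit directly.  N matches nothing, including another N.

## Primer-feasibility (uniqueness) filter

The published workflow used BLASTn to require flank subsequences "unique"
against the whole genome.  BLAST parameters are a poorly reproducible
operationalization, so this package defines uniqueness exactly: a flank
position is *anchored* when its `seed_len` = 15-mer occurs exactly once
genome-wide in canonical form (a k-mer and its reverse complement share a
count, because a primer site duplicated on the opposite strand still
mis-primes).  Maximal anchored runs of r positions define unique stretches
of r + 14 bases; an island survives when both flanks contain a stretch
strictly longer than `min_unique_stretch` = 25 bp.  Exact matching is
stricter than BLAST similarity for near-identical duplications and blind to
diverged paralogs; it is deterministic, dependency-free and directly
checkable against substring counting, which the tests do on ~100 kb genomes.

## Zygosity calling

With x reference-base calls at depth n, p = x/n, the two-sided critical
value z = Φ⁻¹(1 − α/2) (1.96 at the default `confidence_level` = 0.95) and
σ_p = √(p(1−p)/n), the Wald interval p ± z·σ_p is computed only when the
large-sample criterion n·p·(1−p) ≥ `normal_criterion_min` = 10 holds.  The
Wald form (not Wilson/score) is used deliberately — the criterion exists
precisely as its validity guard.

The criterion can never pass at p ∈ {0, 1}, yet a clean homozygote at any
error-free site produces exactly that evidence; such sites receive a
degenerate point interval when n ≥ `degenerate_min_depth` = 20.  Without
this fallback every pure homozygote would be uncallable.  Sites like
x = 99/100 (p̂ = 0.99, np̂(1−p̂) ≈ 0.99) remain **no-calls**: this is a real
property of the criterion, not an implementation artifact, and at depth
~100 with 0.5% sequencing error it leaves roughly a fifth of genotypes
uncalled (almost all homozygotes).  Consequently "genotype accuracy" in this
package means **concordance among emitted codes**, reported alongside the
call rate; the calls that are made are essentially always correct.

Classification is by interval–zone overlap: homozygous variant 0–0.1,
heterozygous 0.4–0.6, homozygous reference 0.9–1.0 (closed zones).  Exactly
one overlap yields the call and its code (1/2/3); several overlaps yield
`ambiguous` (impossible once n ≥ 385, where the half-width is ≤ 0.05); none
yields `out_of_zone`.  A profile's mixture flag fires when the out-of-zone
plus ambiguous fraction of interval-bearing calls exceeds 0.2: discordant
genotypes in a 1:1 two-contributor mixture put expected allele fractions at
0.25/0.75, squarely between the zones, while single-contributor profiles
concentrate inside them.

## Profile comparison

Percent similarity between two profiles is matched codes over
pairwise-complete positions.  Euclidean distance is computed on the raw
1/2/3 codes over the columns complete across *all* samples — pairwise-
complete distances can violate the assumptions of hierarchical clustering.
Under depth-limited calling the all-complete column set can be empty for
large cohorts; the pipeline then reports similarity but skips the
dendrogram, with a warning.  Complete-linkage agglomeration is implemented
directly (about forty lines) so that tie-breaking is fully specified —
among minimal-distance pairs, the pair with the lexicographically smallest
member ids merges first — and verified against SciPy's implementation on
tie-free inputs.  Merge heights are complete-linkage maxima and therefore
non-decreasing toward the root; the tree exports as Newick with branch
lengths from height differences.

## Synthetic data

The generator emulates the study conditions end to end:

* **Genome & variants** — uniform random A/C/G/T chromosomes (default two of
  12 kb) with ten planted islands of 3–5 impactful SNPs (AF ~ U[0.30, 0.70])
  in cores of 60–390 bp.  Planted SNP spacing keeps consecutive gaps below
  the flank length so the planted coordinates are exactly what a correct
  scan must report.  Background SNPs (density 0.002/bp) span the full AF
  spectrum — 65% near-fixed, 25% relevant, 10% impactful — and are excluded
  from a guard zone of `max_island_len` + `min_flank_len` around each
  planted core so they can neither join nor shadow a planted island.
* **Read counts** — genotypes drawn per sample per SNP under Hardy–Weinberg
  from the population AF; depth ~ Poisson(`mean_depth` = 100); reference
  calls ~ Binomial(n, μ) with μ = 1−ε, 0.5, ε for the three genotypes and
  ε = `error_rate` = 0.005 approximating short-read substitution error.
  Mixtures average the contributors' μ at the stated ratio (default 1:1).

What this does **not** emulate: linkage disequilibrium between island SNPs,
mapping bias and alignment artifacts, depth overdispersion beyond Poisson,
strand effects, indels, and real genomic repeat structure (uniform random
sequence is far less repetitive than a human genome, so the chemistry and
uniqueness filters fire much less often than the published genome-wide
funnel would suggest).  Passing tests therefore demonstrate correctness of
the algorithms under their stated model, not performance on GRCh37 with the
full 1000 Genomes catalogue.

## Numerical and interface conventions

* Coordinates are 1-based closed internally (VCF convention); the only
  conversion to 0-based half-open happens when writing BED.
* AF precedence on input: the VCF INFO AF field wins; otherwise AF is
  recomputed as alternate-allele count over called alleles from genotype
  columns.  Only biallelic SNVs are retained.  Unsorted VCFs are a hard
  error rather than being silently resorted.
* All randomness flows through `numpy.random.default_rng(seed)`; identical
  seeds give byte-identical FASTA/VCF/BED/TSV outputs.
* Interval bounds are clipped to [0, 1]; zone checks use closed intervals;
  similarity fractions are reported at 2 decimals in the report-style
  matrix (counts above the diagonal, fractions below).

## Known limitations

* Within-island haplotype phase is not reconstructed; profiles are per-SNP
  zygosity vectors.  Distinct zygosity-code vectors per island across
  samples are the nearest computable analog of island "species" counts.
* The uniqueness filter's exact-match criterion is a different
  operationalization than a similarity search; borderline primer sites can
  be judged differently than BLAST would.
* The mixture flag detects contributor mixtures via zone escape only; it
  does not estimate mixture ratios or deconvolve contributors.
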