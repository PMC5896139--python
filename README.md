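# snpislands

Design of compact SNP-island panels for human identity testing, and the
downstream zygosity-profile analysis that uses them.

A **SNP island** is a short genomic window (at most 400 bp here) containing
several intermediate-frequency SNPs, flanked on both sides by conserved
sequence suitable for primer placement.  Because each island packs multiple
identity-informative markers into a single amplicon, a small multiplex panel
of islands can discriminate individuals, distinguish single- from
multiple-contributor DNA, and group samples by profile relatedness — the
core tasks of forensic identity typing.

The package covers both halves of that workflow:

**Panel design** (`tia scan` → `tia filter-seq` → `tia filter-unique`)

1. A three-state scanner walks each chromosome of an allele-frequency
   annotated genome.  *Impactful* SNPs have global alternate-allele
   frequency in [0.30, 0.70]; near-fixed SNPs (AF ≤ 0.5% or ≥ 99.5%) are
   invisible; everything in between is *relevant* and breaks conserved
   segments.  An island needs ≥ 150 bp of conserved sequence on each side
   and at least 3 impactful SNPs inside a ≤ 400 bp core.
2. Islands whose sequence would disturb short-read chemistry are rejected:
   single-nucleotide runs (≥ 4 bases each) totalling ≥ 10 bases of one
   nucleotide inside any 20 bp window, or any 2–7 bp unit repeated more than
   5 times consecutively.
3. Islands survive only if each flank contains a genome-unique stretch
   longer than 25 bp (exact canonical 15-mer uniqueness, counting
   reverse-complement occurrences), so primers can be placed specifically.

**Identity profiling** (`tia call` → `tia compare`)

At each panel SNP sequenced to depth *n* with *x* reference-base calls, the
sample proportion *p = x/n* gets a normal-approximation confidence interval
*p ± Z₀.₀₂₅·√(p(1−p)/n)* whenever *np(1−p) ≥ 10*.  The interval's overlap
with the zygosity zones — 0.9–1.0 homozygous reference (code 1), 0.4–0.6
heterozygous (code 2), 0–0.1 homozygous variant (code 3) — yields the call.
Intervals overlapping no zone mark *out-of-zone* sites; a profile with many
of them is flagged as a DNA mixture.  Profiles are compared by percent
similarity (matched codes / shared calls) and clustered by Euclidean
distance with complete linkage.

A seeded simulator (`tia simulate`) generates genomes with planted islands,
matching allele-frequency VCFs, and genotype-dependent read-count tables
(including two-contributor mixtures) so the whole pipeline is testable
without any external data.

## Worked example

```bash
tia simulate --seed 1 --samples 6 --out-dir fixtures
tia pipeline --vcf fixtures/variants.vcf --fasta fixtures/genome.fa \
             --counts fixtures/counts.tsv --out-dir run
```

prints

```
funnel: {'scan': 10, 'sequence_filter': 10, 'uniqueness_filter': 10}  categories: {'5+': 3, '4': 3, '3': 4}
mixture-flagged samples: none
```

The funnel counts islands surviving each design stage — the scanner found
all ten planted islands, and none were lost to the chemistry or uniqueness
filters on this seed (with other seeds the filters do fire on random
homopolymers and repeats).  The categories split the final panel by
impactful-SNP content (three islands with ≥ 5 SNPs, three with 4, four
with 3).  No single-contributor sample was flagged as a mixture.

Calling zygosities directly shows the per-SNP statistics:

```bash
tia call --counts fixtures/counts.tsv --out calls.tsv
# 182 of 234 SNP observations received a zygosity code
head -4 calls.tsv
```

```
sample  chrom  pos   ref_calls  depth  p         ci_low    ci_high   call     code
S01     chr1   1000  94         94     1         1         1         hom_ref  1
S01     chr1   1126  53         107    0.495327  0.400593  0.590061  het      2
S01     chr1   1195  53         102    0.519608  0.42265   0.616566  het      2
```

The first site is a saturated homozygote (point interval at 1); the next
two are heterozygotes whose intervals sit inside the 0.4–0.6 zone.  The 52
observations without a code are honest no-calls: homozygous sites with a
few error reads (e.g. 99 of 100) fail the *np(1−p) ≥ 10* large-sample
criterion without reaching the degenerate *p ∈ {0,1}* fallback, so no
interval — and no call — is produced.

## Layout

| module | contents |
| --- | --- |
| `snpislands.genome_io` | FASTA/VCF input, BED/TSV island output, coordinate conventions |
| `snpislands.scanner` | three-state island scanner and island categorization |
| `snpislands.sequence_filters` | homopolymer-cluster and tandem-repeat rejection |
| `snpislands.uniqueness` | canonical k-mer index and primer-feasibility filter |
| `snpislands.zygosity` | proportion intervals, zone classification, mixture flag |
| `snpislands.profiles` | similarity matrix, Euclidean distance, complete-linkage tree |
| `snpislands.simulate` | seeded genome/VCF/read-count generators with planted truth |
| `snpislands.pipeline`, `snpislands.cli` | stage wiring and the `tia` command |

See `docs/methods.md` for the underlying model, parameter meanings, and the
package's design choices.
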