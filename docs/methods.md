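# Methods

## The variant-pool model

All tools operate on a *variant pool*: an ordered list of variant records
plus a sample roster, loaded from a VCF (v4.0–4.3, plain or gzipped) and
optionally restricted to a subset of the file's samples. Coordinates are
VCF-native — 1-based, fully closed — and are never converted internally.

Two normalizations happen at load time:

- **Co-located merging.** Records sharing `(CHROM, POS, REF)` within one file
  are merged into a single multi-alternate record, with genotype allele
  indices remapped onto the merged ALT list. This gives per-alternate
  matching a single well-defined record per site. When merged records
  disagree, the first record wins ID/QUAL/FILTER, disagreeing INFO keys are
  dropped, and a sample's first non-missing genotype wins.
- **Sorting** by (chromosome, position, REF), with natural chromosome order
  (numeric names first, `chr` prefix ignored for ordering).

Records with `ALT=.` (monomorphic reference) are rejected at parse time; the
set-operation semantics are defined per alternate and have no meaningful
behavior for a record with none.

Output is always VCFv4.2. Missing QUAL/DP serialize as `.` and are treated as
absent in statistics, never as zero. Sample-name collisions across pools
(same ID in two input files) are disambiguated in outputs by prefixing
`poolId.`; operands drawn from the *same* pool share samples without
renaming, so `union(A, A)` is idempotent.

## Matching semantics

The comparison unit is the **variant key** `(CHROM, POS, REF, ALT)`, one per
alternate. The `position` intersect method matches on `(CHROM, POS, REF)`
only. Multi-allelic records match under `variant` if at least one alternate
key matches, and complements remove alternates individually — a record
survives with its unmatched alternates.

Genotype-level intersects keep a key only when every selected sample in
every operand satisfies the category, evaluated **against the matching
alternate**: a `0/2` call is heterozygous for alternate #2 only. `het`
requires exactly one reference allele, so a genotype with two different
alternate alleles is not het. A no-call (or partially missing call) fails
every category, dropping the site: the categories quantify over "all sample
genotypes", and a missing genotype attests to none of them.

`exact_match` (intersect) and `exact_genotype` (complement) compare
phase-insensitive allele *multisets resolved to allele strings* (`0|1`
equals `1/0`; the same variant matches across files whose ALT columns order
alleles differently), and require one identical called genotype across all
selected samples of all operands. A subtrahend sample that is missing or
uncalled makes the match fail (record retained).

Output records in intersect/union take ID/QUAL/FILTER from the first operand
carrying the site; INFO keys whose values disagree between operands are
dropped (first-wins is deterministic and auditable). Under record-level
methods a carried genotype may reference an alternate that the output record
does not contain (e.g. the non-shared alternate of a multi-allelic site);
such alleles are masked to `.` rather than silently re-pointed, since the
output ALT set is fixed by the matching rule.

The `position` method's outputs carry the union of the operands' alternates
and genotypes (which genotypes the original record-level output carried is
otherwise under-determined).

The four-way **compare** is exactly the composition intersect(`variant`) +
two complements(`variant`) + union, so its outputs obey the partition law
`keys(common) ⊎ keys(unique_A) ⊎ keys(unique_B) = keys(union)` — a property
the test suite asserts on randomized inputs.

One intersect method and one complement method apply per invocation (CLI
flags `--intersect-type`, `--complement-type`, both defaulting to
`het_or_homo_alt`); per-operation overrides would require extending the
operation syntax. Auto-assigned operation IDs are `op0, op1, ...` in token
order.

## Header repair and validation

`repair_header` adds the minimum meta-information needed for a file to
re-parse strictly: a leading `##fileformat` line, `##FORMAT` lines for GT
(and DP when depths are present), generic `##INFO` lines
(`Number=.,Type=String`, or `Number=0,Type=Flag` for valueless keys) for
every INFO key in use, and `##FILTER`/`##contig` lines for the filters and
chromosomes the records reference. It preserves existing lines in order and
is idempotent. It does not attempt to reconstruct descriptive metadata it
cannot know.

The strict validator (`validate_vcf`) parses with htslib via pysam and
additionally requires every contig/INFO/FORMAT/FILTER used by records to be
declared — htslib alone only warns and silently patches its in-memory header.
Reading, by contrast, is a native lenient parser: repairing invalid headers
is a feature, and htslib refuses exactly the broken files the repair exists
for. The validator is also the independent cross-check that everything the
toolkit writes is standard-conformant.

## Statistics

**Pool summary** counts are per alternate: SNV (`len(REF)=len(ALT)=1`),
insertion (`len(ALT)>len(REF)`), deletion (`len(ALT)<len(REF)`), structural
(symbolic ALT such as `<DEL>`, or SVTYPE present). Equal-length multi-base
substitutions fall in none of the named classes. Depth statistics pool all
non-missing per-sample DP values; quality statistics all non-missing QUAL.

**Per-variant rows** (one per record–alternate pair) count alleles from
fully called genotypes only; no-call samples are excluded from both numerator
and denominator, so `ref + alt ≤ 2 × called` with equality on biallelic
records.

**Association** is allelic: per alternate, a 2×2 table of case/control ×
(designated alternate / any other allele). Each called diploid genotype
contributes two alleles (haploid: one); other alternates of a multi-allelic
record count toward the "other" cell; no-call and unphenotyped samples are
excluded. The odds ratio is `(a·d)/(b·c)`, with the Haldane–Anscombe +0.5
added to every cell iff any cell is zero — the correction keeps the odds
ratio finite but is never applied to the test statistic. The p-value is a
1-df Pearson chi-square on the uncorrected table, replaced by Fisher's exact
test whenever any expected cell count is below 5 (the standard validity rule
for the chi-square approximation). The allelic chi-square with Fisher
fallback is the most common VCF-level allelic test; genotype-model
(dominant/recessive) tests and covariate adjustment are out of scope. No
multiple-testing correction is applied — the p-value column is emitted raw
for downstream correction. Phenotypes use the two-column `sample TAB status`
format with 1 = control, 2 = case (Plink convention).

## The synthetic-data generator

`vtc.fixtures` emulates a small cohort genotyped at independent sites:

- Genotypes drawn per site under Hardy–Weinberg equilibrium at a configured
  total alternate frequency `maf` (default 0.2), split equally among
  alternates at multi-allelic sites.
- Site classes: SNVs with uniform ACGT alleles; 1–5 bp insertions/deletions
  anchored on a reference base per VCF convention; symbolic `<DEL>`
  structural records with SVTYPE/END INFO. Default mix: 10 % indels, 2 % SV,
  10 % multi-allelic, 5 % no-call genotypes, 5 % missing DP — small but
  non-zero rates so every code path that handles these features is exercised.
- Depth ~ Poisson(30), QUAL ~ Uniform(20, 100): typical short-read joint
  calls.
- Positions strictly increasing per chromosome; identical config + seed give
  byte-identical files. Pool pairs share exactly
  `round(shared_fraction × n_variants)` sites (identical REF/ALT), with
  genotypes drawn independently per pool and per-pool sample rosters.
- Case/control labels are Bernoulli(0.5) per sample. With `planted_or` set,
  genotypes are drawn retrospectively: controls at alternate frequency
  `maf`, cases at the frequency whose allele odds are `planted_or` times the
  control odds, so every variant has the same true allelic odds ratio —
  which is what lets a single cohort provide many replicate variants for
  parameter-recovery checks. (A prospective logistic model was considered
  and rejected: one label vector cannot give hundreds of variants an
  identical marginal allelic odds ratio.)

Every run emits a manifest recording the written keys, per-alternate classes,
the genotype matrix exactly as serialized, and labels; the VCF text is
written by the generator itself, independently of the package's writer, so
generated files are an external check on both reader and writer.

What the generator does **not** emulate: linkage disequilibrium between
sites, sequencing or genotyping error, related samples, population structure,
realistic allele-frequency spectra, or left-alignment ambiguity of indels.
Passing tests therefore demonstrate correctness of the set algebra, parsing
and counting on clean, independent sites — not robustness to the
representation ambiguities of real call sets (which variant normalization,
explicitly out of scope, would address).

## Test and verification design

Set operations are verified against literal brute-force oracles
(`tests/oracles.py`): independent re-implementations of each matching rule
using linear scans over plain tuples, sharing no code with the engine. The
randomized acceptance checks run all 11 method variants over 100 seeded pool
pairs of up to 200 records and 6 samples — sizes chosen to cover all shape
variation (2–6 samples, 50–200 records, multi-allelic and symbolic alleles,
missing data) while keeping the full suite around ten seconds.

Association calibration uses 500 null variants in a cohort of 100 (fraction
of p < 0.05 expected 0.05 ± 0.02, the ±2σ binomial band at that count);
power/recovery uses 200 variants with a planted odds ratio of 3 in a cohort
of 200, asserting the median estimate lies in [2.5, 3.6] (the discrete table
makes individual estimates noisy; the median across replicates is stable).

## Known limitations

- Ploidy other than 1 or 2 round-trips through the model, but the het /
  homo-alt categories are defined for diploid calls only.
- No BCF, tabix, Plink or CSV support; no left-alignment/variant
  normalization or liftover; no per-operation method overrides; no union
  genotype filters.
- INFO values are carried as opaque strings; disagreeing INFO keys are
  dropped on merge rather than reconciled per the declared Number/Type.
- `repair_header` restores only required meta lines; descriptive lines it
  cannot infer stay absent.
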