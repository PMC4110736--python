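# vtc — genotype-aware set operations and statistics for VCF files

`vtc` is a toolkit for comparing and analyzing variants stored in the Variant
Call Format (VCF), aimed at researchers who need to combine or contrast call
sets across samples and files — for example intersecting the variants carried
by all affected individuals of several families, each stored in its own
multi-sample VCF.

Most variant set tooling matches records by chromosome and position alone and
works on single-sample files. `vtc` instead operates on **variant pools** — a
named set of variant records plus a sample roster, possibly a user-selected
subset of a file's samples — and lets set operations reach down to the
genotype level:

- **Intersect** with five genotype-level methods (`het`, `homo_alt`,
  `het_or_homo_alt`, `homo_ref`, `exact_match`) and two record-level methods
  (`variant`: match on CHROM, POS, REF, ALT; `position`: CHROM, POS, REF
  only). Genotype-level methods require *every* selected sample in *every*
  operand to satisfy the category; a `./.` no-call never satisfies any.
  "Heterozygous" requires one reference allele — a `1/2` call at a
  tri-allelic site is not treated as het.
- **Complement** (per alternate) with `variant`, `het_or_homo_alt`, or
  `exact_genotype` matching; a multi-allelic record keeps its unmatched
  alternates.
- **Union** of all variants and selected samples regardless of genotype;
  samples missing a variant get a no-call (`./.`).
- A four-way **compare** (`--compare`): common variants, unique to each
  input, and the combined union, written as four VCFs with a count summary.
- **VarStats**: pool-level and per-variant summaries, and per-alternate
  allelic case-control association with odds ratios and p-values.
- **Header repair** (adds missing required meta lines such as `##FORMAT` GT)
  and `chr`-prefix normalization across files that disagree.

Operations compose through a compact syntax with *operation stringing*:

```
myOP=i[file1:file2] myOP2=c[myOP:file3]
```

intersects `file1` and `file2` (all samples), then subtracts `file3` from the
result. Sample subsets are selected per operand: `i[f1[s1,s2]:f2[s3]]`.

Matching is allelic: the comparison unit is the `(CHROM, POS, REF, ALT)` key,
one per alternate, so multi-allelic records match "if at least one alternate
matches" and are subtracted per alternate. The allelic association test
builds a 2×2 allele-count table per alternate (case/control × designated
alternate/other), reports the odds ratio `(a·d)/(b·c)` (Haldane–Anscombe +0.5
on all cells when any cell is zero), and a 1-df Pearson chi-square p-value
(Fisher's exact when any expected cell is below 5). No multiple-testing
correction is applied.

## Worked example

Generate a seeded synthetic pool pair with 30 % shared sites, run the
four-way compare, then a chained intersect/complement, then a summary:

```
$ printf '{"seed": 4, "n_variants": 100, "n_samples": 3, "shared_fraction": 0.3}' > cfg.json
$ vtc fixtures --config cfg.json --pair -o data
wrote data/A.vcf, data/B.vcf (32 shared variant keys)

$ vtc setoperator -i A=data/A.vcf -i B=data/B.vcf --compare -o cmp
pool            records
common          30
unique_A        70
unique_B        70
union           170
```

30 of each file's 100 records share a site with the other file (the 32 shared
*keys* include multi-allelic sites contributing two alternates); 70 records
are unique to each file, and the union holds 30 + 70 + 70 = 170 records.
`cmp/` now contains `common.vcf`, `unique_A.vcf`, `unique_B.vcf`, `union.vcf`.

```
$ vtc setoperator -i A=data/A.vcf -i B=data/B.vcf \
      -s "shared=i[A:B] aOnly=c[A:shared]" \
      --intersect-type variant --complement-type variant -o aOnly.vcf
wrote aOnly.vcf (70 records)

$ vtc varstats -i p=data/A.vcf --summary
Pool: p
Total variants           100
SNVs                     102
Insertions               2
Deletions                2
Structural variants      4
Multi-alternate records  10
Depth min/max/mean       18/48/29.95
Qual min/max/mean        20.7/98/59.15
```

Class counts are per alternate (10 multi-allelic records push the SNV count
above the record count). For association, the generator also writes
phenotype labels (`1`=control, `2`=case):

```
$ vtc varstats -i p=assoc/synthetic.vcf --association --phenotype assoc/phenotypes.txt -o study
wrote study.assoc.tsv (108 rows)
$ head -3 study.assoc.tsv
CHROM  POS   ID  REF  ALT  CASE_ALT  CASE_REF  CTRL_ALT  CTRL_REF  OR        P         TEST
1      1153  .   C    G    7         41        10        56        0.956098  0.932988  chisq
1      1278  .   C    A    10        42        12        52        1.03175   0.947627  chisq
```

One row per alternate: the allele-count table, the odds ratio, the p-value
and which test produced it.

The same pipelines are available as library calls (`vtc.read_vcf`,
`vtc.intersect`, `vtc.compare`, `vtc.associate`, ...); the CLI is a thin
layer over them.

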