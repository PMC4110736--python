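"""Pool and per-variant summary statistics, and allelic case-control tests.

The association test is an allelic one: each called diploid genotype
contributes two alleles to a 2x2 table of (case/control) x (designated
alternate / any other allele), per alternate allele.  The odds ratio is
``(a*d)/(b*c)`` with the Haldane–Anscombe +0.5 correction applied to every
cell when any cell is zero (the correction affects the odds ratio only, never
the test statistic).  P-values come from a 1-df Pearson chi-square on the
uncorrected table, falling back to Fisher's exact test whenever any expected
cell count is below 5.  No multiple-testing correction is applied; downstream
tools can correct the emitted p-value column.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats as _st

from .errors import AssociationError, PhenotypeError
from .vcf_model import VariantKey, VariantPool, VariantRecord, variant_keys

__all__ = [
    "PoolSummary",
    "VariantSummary",
    "PhenotypeTable",
    "AssociationResult",
    "classify_alt",
    "summarize",
    "per_variant_stats",
    "read_phenotypes",
    "build_contingency",
    "associate",
    "ASSOC_HEADER",
]

CASE = "case"
CONTROL = "control"


def classify_alt(ref: str, alt: str, info: dict) -> str:
    """Classify one alternate: snv / insertion / deletion / structural / other.

    Symbolic alternates (``<DEL>`` etc.) or records carrying SVTYPE count as
    structural; equal-length multi-base substitutions fall into "other" and
    are not tallied in any named class.
    """
    if alt.startswith("<") or "SVTYPE" in info:
        return "structural"
    if len(ref) == 1 and len(alt) == 1:
        return "snv"
    if len(alt) > len(ref):
        return "insertion"
    if len(alt) < len(ref):
        return "deletion"
    return "other"


def _stats(values: Sequence[float]) -> tuple[float | None, float | None, float | None]:
    if not values:
        return (None, None, None)
    arr = np.asarray(values, dtype=float)
    return (float(arr.min()), float(arr.max()), float(arr.mean()))


@dataclass(frozen=True)
class PoolSummary:
    """High-level metrics for one pool (alternate-level class counts)."""

    n_variants: int
    n_snv: int
    n_insertion: int
    n_deletion: int
    n_structural: int
    n_multi_alt: int
    depth_min: float | None
    depth_max: float | None
    depth_mean: float | None
    qual_min: float | None
    qual_max: float | None
    qual_mean: float | None

    def format(self) -> str:
        def f(x):
            return "NA" if x is None else (f"{x:.4g}" if isinstance(x, float) else str(x))
        rows = [
            ("Total variants", self.n_variants),
            ("SNVs", self.n_snv),
            ("Insertions", self.n_insertion),
            ("Deletions", self.n_deletion),
            ("Structural variants", self.n_structural),
            ("Multi-alternate records", self.n_multi_alt),
            ("Depth min/max/mean",
             f"{f(self.depth_min)}/{f(self.depth_max)}/{f(self.depth_mean)}"),
            ("Qual min/max/mean",
             f"{f(self.qual_min)}/{f(self.qual_max)}/{f(self.qual_mean)}"),
        ]
        width = max(len(r[0]) for r in rows)
        return "\n".join(f"{k:<{width}}  {f(v) if not isinstance(v, str) else v}"
                         for k, v in rows)


def summarize(pool: VariantPool) -> PoolSummary:
    """Quick pool summary: record count, per-class alternate counts,
    depth/quality ranges over all non-missing values."""
    counts = {"snv": 0, "insertion": 0, "deletion": 0, "structural": 0, "other": 0}
    n_multi = 0
    depths: list[float] = []
    quals: list[float] = []
    for rec in pool.records:
        if len(rec.alts) >= 2:
            n_multi += 1
        for alt in rec.alts:
            counts[classify_alt(rec.ref, alt, rec.info)] += 1
        depths.extend(d for d in rec.depths.values() if d is not None)
        if rec.qual is not None:
            quals.append(rec.qual)
    dmin, dmax, dmean = _stats(depths)
    qmin, qmax, qmean = _stats(quals)
    return PoolSummary(
        n_variants=len(pool.records), n_snv=counts["snv"],
        n_insertion=counts["insertion"], n_deletion=counts["deletion"],
        n_structural=counts["structural"], n_multi_alt=n_multi,
        depth_min=dmin, depth_max=dmax, depth_mean=dmean,
        qual_min=qmin, qual_max=qmax, qual_mean=qmean,
    )


@dataclass(frozen=True)
class VariantSummary:
    """Per-(record, alternate) allelic counts and depth/quality stats."""

    key: VariantKey
    ref_allele_count: int
    alt_allele_count: int
    n_called_samples: int
    depth_min: float | None
    depth_max: float | None
    depth_mean: float | None
    qual: float | None


def per_variant_stats(pool: VariantPool) -> list[VariantSummary]:
    """One row per (record, alternate); counts use called genotypes only."""
    out: list[VariantSummary] = []
    for rec in pool.records:
        called = [g for g in (rec.genotype(s) for s in pool.samples) if g.is_called]
        n_called = len(called)
        dp = [d for d in (rec.depths.get(s) for s in pool.samples) if d is not None]
        dmin, dmax, dmean = _stats(dp)
        for ai, alt in enumerate(rec.alts, start=1):
            ref_n = sum(1 for g in called for a in g.alleles if a == 0)
            alt_n = sum(1 for g in called for a in g.alleles if a == ai)
            out.append(VariantSummary(
                key=VariantKey(rec.chrom, rec.pos, rec.ref, alt),
                ref_allele_count=ref_n, alt_allele_count=alt_n,
                n_called_samples=n_called,
                depth_min=dmin, depth_max=dmax, depth_mean=dmean, qual=rec.qual,
            ))
    return out


def write_variant_stats(rows: Sequence[VariantSummary], path: str | Path) -> Path:
    path = Path(path)
    cols = ["CHROM", "POS", "REF", "ALT", "REF_COUNT", "ALT_COUNT", "N_CALLED",
            "DP_MIN", "DP_MAX", "DP_MEAN", "QUAL"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            def f(x):
                return "NA" if x is None else f"{x:g}"
            fh.write("\t".join([
                r.key.chrom, str(r.key.pos), r.key.ref, r.key.alt,
                str(r.ref_allele_count), str(r.alt_allele_count),
                str(r.n_called_samples), f(r.depth_min), f(r.depth_max),
                f(r.depth_mean), f(r.qual),
            ]) + "\n")
    return path


# ---------------------------------------------------------------------------
# Case-control association


@dataclass(frozen=True)
class PhenotypeTable:
    """Sample ID -> case/control status."""

    status: dict[str, str]

    def cases(self) -> list[str]:
        return [s for s, st in self.status.items() if st == CASE]

    def controls(self) -> list[str]:
        return [s for s, st in self.status.items() if st == CONTROL]


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a two-column, tab-separated phenotype file (1=control, 2=case)."""
    status: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise PhenotypeError(
                    f"line {lineno}: expected 'sample<TAB>status', got {line!r}"
                )
            sample, code = parts
            if sample in status:
                raise PhenotypeError(f"line {lineno}: duplicate sample {sample!r}")
            if code == "1":
                status[sample] = CONTROL
            elif code == "2":
                status[sample] = CASE
            else:
                raise PhenotypeError(
                    f"line {lineno}: status must be 1 (control) or 2 (case), got {code!r}"
                )
    if not status:
        raise PhenotypeError(f"{path}: no phenotype entries")
    return PhenotypeTable(status)


def build_contingency(
    record: VariantRecord, alt_index: int, phen: PhenotypeTable
) -> tuple[int, int, int, int]:
    """Allele-count 2x2 table (case-alt, case-other, control-alt, control-other).

    ``alt_index`` is the 1-based allele index of the designated alternate.
    Each fully called genotype contributes one allele per chromosome copy
    (two for diploid, one for haploid); an allele counts as "alt" iff it
    equals the designated alternate — other alternates fall in the non-alt
    cell.  No-call samples and samples without a phenotype are excluded.
    """
    if not (1 <= alt_index <= len(record.alts)):
        raise ValueError(f"alt_index {alt_index} out of range for {len(record.alts)} alt(s)")
    a = b = c = d = 0
    for sample, st in phen.status.items():
        g = record.genotypes.get(sample)
        if g is None or not g.is_called:
            continue
        for allele in g.alleles:
            if st == CASE:
                if allele == alt_index:
                    a += 1
                else:
                    b += 1
            else:
                if allele == alt_index:
                    c += 1
                else:
                    d += 1
    return (a, b, c, d)


@dataclass(frozen=True)
class AssociationResult:
    """Per-(record, alternate) allelic association."""

    key: VariantKey
    id: str
    table: tuple[int, int, int, int]  # case-alt, case-ref, control-alt, control-ref
    odds_ratio: float | None
    p_value: float | None
    test_name: str


def odds_ratio(table: tuple[int, int, int, int]) -> float | None:
    """(a*d)/(b*c); +0.5 on every cell iff any cell is zero; None on an
    empty table."""
    a, b, c, d = table
    if a + b + c + d == 0:
        return None
    if min(table) == 0:
        a, b, c, d = (x + 0.5 for x in table)
    return (a * d) / (b * c)


def _p_value(table: tuple[int, int, int, int]) -> tuple[float | None, str]:
    a, b, c, d = table
    n = a + b + c + d
    if n == 0:
        return (None, "none")
    arr = np.array([[a, b], [c, d]], dtype=float)
    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)
    expected = np.outer(rows, cols) / n
    if expected.min() < 5:
        return (float(_st.fisher_exact(arr)[1]), "fisher")
    chi2, p, _, _ = _st.chi2_contingency(arr, correction=False)
    return (float(p), "chisq")


ASSOC_HEADER = ["CHROM", "POS", "ID", "REF", "ALT", "CASE_ALT", "CASE_REF",
                "CTRL_ALT", "CTRL_REF", "OR", "P", "TEST"]


def associate(
    pool: VariantPool, phen: PhenotypeTable, out_path: str | Path | None = None
) -> list[AssociationResult]:
    """Allelic association for every (record, alternate) in the pool.

    Requires at least one case and one control among the pool's samples.
    Records where no phenotyped sample is called still yield a row, with
    missing odds ratio and p-value.  When ``out_path`` is given, results are
    written as a tab-delimited table, one line per alternate.
    """
    used = {s: st for s, st in phen.status.items() if s in pool.samples}
    n_case = sum(1 for st in used.values() if st == CASE)
    n_ctrl = sum(1 for st in used.values() if st == CONTROL)
    if n_case == 0 or n_ctrl == 0:
        raise AssociationError(
            f"association needs >=1 case and >=1 control among pool samples "
            f"(found {n_case} case(s), {n_ctrl} control(s))"
        )
    used_tab = PhenotypeTable(used)
    results: list[AssociationResult] = []
    for rec in pool.records:
        for ai in range(1, len(rec.alts) + 1):
            table = build_contingency(rec, ai, used_tab)
            p, test = _p_value(table)
            results.append(AssociationResult(
                key=VariantKey(rec.chrom, rec.pos, rec.ref, rec.alts[ai - 1]),
                id=rec.id, table=table, odds_ratio=odds_ratio(table),
                p_value=p, test_name=test,
            ))
    if out_path is not None:
        with open(out_path, "w") as fh:
            fh.write("\t".join(ASSOC_HEADER) + "\n")
            for r in results:
                orr = "NA" if r.odds_ratio is None else f"{r.odds_ratio:.6g}"
                p = "NA" if r.p_value is None else f"{r.p_value:.6g}"
                fh.write("\t".join([
                    r.key.chrom, str(r.key.pos), r.id, r.key.ref, r.key.alt,
                    *(str(x) for x in r.table), orr, p, r.test_name,
                ]) + "\n")
    return results
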