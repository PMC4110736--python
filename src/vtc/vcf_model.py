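"""VCF reading/writing and the variant-pool data model.

The central container is the :class:`VariantPool`: a named, ordered collection
of :class:`VariantRecord` objects together with a sample roster.  A pool may
hold all samples of a file or a user-selected subset, which is what lets the
set-operation engine mix single- and multi-sample VCFs freely.

Coordinates are VCF-native (1-based, fully closed) throughout; they are never
converted internally.  Records sharing ``(chrom, pos, ref)`` within one file
are merged into a single multi-alternate record at load time, with genotype
allele indices remapped, so that per-alternate matching has one well-defined
record per site to test.

Reading is deliberately lenient about headers (repairing broken headers is a
feature of this toolkit); :func:`validate_vcf` provides the strict check,
backed by htslib via pysam.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .errors import UnknownSampleError, VcfParseError, VcfValidationError

__all__ = [
    "Genotype",
    "VariantRecord",
    "VariantPool",
    "SamplePool",
    "VariantKey",
    "NO_CALL",
    "read_vcf",
    "write_vcf",
    "repair_header",
    "normalize_chr",
    "variant_keys",
    "pool_keys",
    "validate_vcf",
]


@dataclass(frozen=True)
class Genotype:
    """One sample's call at one record.

    ``alleles`` holds allele indices (0 = REF, k >= 1 = k-th ALT); ``None``
    marks a missing allele.  A genotype is a *no-call* iff every allele is
    missing; it serializes as ``./.`` (unphased).  Diploid calls are the norm
    but any ploidy round-trips.
    """

    alleles: tuple[int | None, ...]
    phased: bool = False

    @property
    def is_nocall(self) -> bool:
        return all(a is None for a in self.alleles)

    @property
    def is_called(self) -> bool:
        """Fully called: no missing allele."""
        return len(self.alleles) > 0 and all(a is not None for a in self.alleles)

    def allele_strings(self, ref: str, alts: Sequence[str]) -> tuple[str, ...] | None:
        """Resolve indices to allele strings, sorted (phase-insensitive).

        Returns ``None`` unless the genotype is fully called.  Allele strings
        are portable across files whose ALT columns order alleles differently,
        unlike raw indices.
        """
        if not self.is_called:
            return None
        out = []
        for a in self.alleles:
            out.append(ref if a == 0 else alts[a - 1])  # type: ignore[index]
        return tuple(sorted(out))

    def __str__(self) -> str:
        # no-calls always serialize unphased ("./.")
        sep = "|" if self.phased and not self.is_nocall else "/"
        return sep.join("." if a is None else str(a) for a in self.alleles)


NO_CALL = Genotype((None, None))


@dataclass(frozen=True)
class VariantKey:
    """Canonical comparison unit: one (record, alternate) pair."""

    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass
class VariantRecord:
    """One VCF data line: locus, alleles, site annotations, per-sample calls."""

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    id: str = "."
    qual: float | None = None
    filter: str = "."
    info: dict[str, object] = field(default_factory=dict)
    genotypes: dict[str, Genotype] = field(default_factory=dict)
    depths: dict[str, int | None] = field(default_factory=dict)

    def genotype(self, sample: str) -> Genotype:
        """The sample's genotype, no-call when the sample is absent."""
        return self.genotypes.get(sample, NO_CALL)

    @property
    def site(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.ref)


def variant_keys(record: VariantRecord) -> list[VariantKey]:
    """One key per alternate, in ALT order."""
    return [VariantKey(record.chrom, record.pos, record.ref, a) for a in record.alts]


def pool_keys(pool: "VariantPool") -> set[VariantKey]:
    return {k for rec in pool.records for k in variant_keys(rec)}


_CHROM_NUM = re.compile(r"^(chr)?(\d+)$", re.IGNORECASE)


def chrom_sort_key(chrom: str) -> tuple[int, int, str]:
    """Natural chromosome order: numbers first, then names; 'chr' ignored."""
    m = _CHROM_NUM.match(chrom)
    if m:
        return (0, int(m.group(2)), "")
    bare = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return (1, 0, bare)


def record_sort_key(rec: VariantRecord) -> tuple[tuple[int, int, str], int, str]:
    return (chrom_sort_key(rec.chrom), rec.pos, rec.ref)


@dataclass
class VariantPool:
    """A named variant set: records plus the sample roster they refer to."""

    pool_id: str
    samples: list[str] = field(default_factory=list)
    records: list[VariantRecord] = field(default_factory=list)
    header_lines: list[str] = field(default_factory=list)

    def sort(self) -> None:
        self.records.sort(key=record_sort_key)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class SamplePool:
    """An ordered subset of one pool's samples, as used by one operand."""

    pool_id: str
    sample_ids: tuple[str, ...]


# ---------------------------------------------------------------------------
# Parsing


def _parse_genotype(token: str) -> Genotype:
    phased = "|" in token
    parts = re.split(r"[/|]", token)
    alleles: list[int | None] = []
    for p in parts:
        if p in (".", ""):
            alleles.append(None)
        else:
            alleles.append(int(p))
    if all(a is None for a in alleles):
        return NO_CALL if len(alleles) == 2 else Genotype(tuple(alleles))
    return Genotype(tuple(alleles), phased)


def _parse_info(text: str) -> dict[str, object]:
    info: dict[str, object] = {}
    if text == "." or text == "":
        return info
    for item in text.split(";"):
        if not item:
            continue
        if "=" in item:
            k, v = item.split("=", 1)
            info[k] = v
        else:
            info[item] = True  # flag
    return info


def _parse_data_line(fields: list[str], samples: list[str], lineno: int) -> VariantRecord:
    if len(fields) < 8:
        raise VcfParseError(f"line {lineno}: expected >=8 tab-separated fields, got {len(fields)}")
    chrom, pos_s, vid, ref, alt_s, qual_s, filt, info_s = fields[:8]
    try:
        pos = int(pos_s)
    except ValueError:
        raise VcfParseError(f"line {lineno}: POS is not an integer: {pos_s!r}") from None
    if not ref:
        raise VcfParseError(f"line {lineno}: empty REF allele")
    if alt_s in (".", ""):
        raise VcfParseError(
            f"line {lineno}: monomorphic-reference record (ALT='.') is not supported"
        )
    alts = tuple(alt_s.split(","))
    qual: float | None
    if qual_s in (".", ""):
        qual = None
    else:
        try:
            qual = float(qual_s)
        except ValueError:
            raise VcfParseError(f"line {lineno}: QUAL is not numeric: {qual_s!r}") from None

    genotypes: dict[str, Genotype] = {}
    depths: dict[str, int | None] = {}
    if samples:
        if len(fields) < 9 + len(samples):
            raise VcfParseError(
                f"line {lineno}: {len(samples)} sample columns declared in header, "
                f"found {max(0, len(fields) - 9)}"
            )
        fmt = fields[8].split(":")
        try:
            gt_i = fmt.index("GT")
        except ValueError:
            gt_i = None
        dp_i = fmt.index("DP") if "DP" in fmt else None
        for s, col in zip(samples, fields[9:]):
            sub = col.split(":")
            if gt_i is not None and gt_i < len(sub):
                try:
                    gt = _parse_genotype(sub[gt_i])
                except ValueError:
                    raise VcfParseError(
                        f"line {lineno}: bad genotype {sub[gt_i]!r} for sample {s}"
                    ) from None
            else:
                gt = NO_CALL
            for a in gt.alleles:
                if a is not None and a > len(alts):
                    raise VcfParseError(
                        f"line {lineno}: genotype allele index {a} out of range "
                        f"for {len(alts)} alternate(s)"
                    )
            genotypes[s] = gt
            if dp_i is not None and dp_i < len(sub) and sub[dp_i] not in (".", ""):
                try:
                    depths[s] = int(sub[dp_i])
                except ValueError:
                    raise VcfParseError(
                        f"line {lineno}: bad DP {sub[dp_i]!r} for sample {s}"
                    ) from None
            else:
                depths[s] = None
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alts=alts, id=vid, qual=qual,
        filter=filt, info=_parse_info(info_s), genotypes=genotypes, depths=depths,
    )


def remap_genotype(g: Genotype, record: VariantRecord, new_alts: Sequence[str]) -> Genotype:
    """Re-index a genotype from ``record``'s ALT list onto ``new_alts``.

    Alleles whose alternate string is absent from ``new_alts`` become missing;
    the reference allele (0) always survives.
    """
    out: list[int | None] = []
    for a in g.alleles:
        if a is None or a == 0:
            out.append(a)
            continue
        alt = record.alts[a - 1]
        try:
            out.append(new_alts.index(alt) + 1)
        except ValueError:
            out.append(None)
    return Genotype(tuple(out), g.phased)


def merge_colocated(records: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Merge records sharing (chrom, pos, ref) into multi-alternate records.

    First record at a site wins QUAL/FILTER/ID; INFO keys whose values disagree
    between merged records are dropped; a sample's first non-missing genotype
    wins.  Genotype allele indices are remapped onto the merged ALT list.
    """
    by_site: dict[tuple[str, int, str], VariantRecord] = {}
    order: list[tuple[str, int, str]] = []
    for rec in records:
        site = rec.site
        if site not in by_site:
            by_site[site] = rec
            order.append(site)
            continue
        base = by_site[site]
        merged_alts = list(base.alts)
        for a in rec.alts:
            if a not in merged_alts:
                merged_alts.append(a)
        new_gts = {
            s: remap_genotype(g, base, merged_alts) for s, g in base.genotypes.items()
        }
        for s, g in rec.genotypes.items():
            g2 = remap_genotype(g, rec, merged_alts)
            if s not in new_gts or new_gts[s].is_nocall:
                new_gts[s] = g2
        new_dp = dict(base.depths)
        for s, d in rec.depths.items():
            if new_dp.get(s) is None:
                new_dp[s] = d
        new_info = {
            k: v for k, v in base.info.items()
            if k not in rec.info or rec.info[k] == v
        }
        by_site[site] = replace(
            base, alts=tuple(merged_alts), genotypes=new_gts, depths=new_dp, info=new_info
        )
    return [by_site[s] for s in order]


def read_vcf(
    path: str | Path,
    pool_id: str | None = None,
    sample_subset: Sequence[str] | None = None,
) -> VariantPool:
    """Read a VCF (plain or gzipped) into a :class:`VariantPool`.

    ``sample_subset`` restricts the pool to the named samples (all samples when
    omitted); genotype and depth columns for other samples are dropped.
    Records are sorted and co-located records merged per the pool invariants.

    Raises :class:`VcfParseError` naming the line number on a malformed data
    line, and :class:`UnknownSampleError` listing the available samples when a
    subset member is not in the header.
    """
    path = Path(path)
    pid = pool_id if pool_id is not None else path.stem.removesuffix(".vcf")
    opener = gzip.open if path.suffix == ".gz" else open
    header_lines: list[str] = []
    file_samples: list[str] = []
    records: list[VariantRecord] = []
    saw_chrom_line = False
    with opener(path, "rt") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            if line.startswith("##"):
                header_lines.append(line)
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) > 9:
                    file_samples = cols[9:]
                elif len(cols) == 10:
                    file_samples = cols[9:]
                saw_chrom_line = True
                continue
            if line.startswith("#"):
                header_lines.append(line)
                continue
            if not saw_chrom_line:
                raise VcfParseError(f"line {lineno}: data before #CHROM header line")
            records.append(_parse_data_line(line.split("\t"), file_samples, lineno))

    if sample_subset is not None:
        missing = [s for s in sample_subset if s not in file_samples]
        if missing:
            raise UnknownSampleError(
                f"unknown sample(s) {', '.join(missing)} in {path.name}; "
                f"available: {', '.join(file_samples) or '(none)'}"
            )
        keep = list(sample_subset)
        for rec in records:
            rec.genotypes = {s: rec.genotypes[s] for s in keep if s in rec.genotypes}
            rec.depths = {s: rec.depths[s] for s in keep if s in rec.depths}
        samples = keep
    else:
        samples = list(file_samples)

    pool = VariantPool(pool_id=pid, samples=samples,
                       records=merge_colocated(records), header_lines=header_lines)
    pool.sort()
    return pool


# ---------------------------------------------------------------------------
# Writing and header repair

_META_ID = re.compile(r"^##(?P<kind>\w+)=<ID=(?P<id>[^,>]+)")
_FILEFORMAT = re.compile(r"^##fileformat=")


def _defined_ids(header_lines: Sequence[str]) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {"INFO": set(), "FORMAT": set(), "FILTER": set(), "contig": set()}
    for line in header_lines:
        m = _META_ID.match(line)
        if m and m.group("kind") in out:
            out[m.group("kind")].add(m.group("id"))
    return out


def repair_header(header_lines: Sequence[str], pool: VariantPool) -> list[str]:
    """Add the minimum meta-information required for the pool to be valid VCF.

    Guarantees a leading ``##fileformat`` line and meta lines for every FORMAT
    field (GT, and DP when any record carries depths), INFO key, FILTER value
    and contig actually used by the pool's records.  Unknown INFO keys get a
    generic ``Number=.,Type=String`` line (``Number=0,Type=Flag`` for
    valueless keys).  Existing lines are preserved in order; the function is
    idempotent.
    """
    lines = [l for l in header_lines if not l.startswith("#CHROM")]
    ff = [l for l in lines if _FILEFORMAT.match(l)]
    rest = [l for l in lines if not _FILEFORMAT.match(l)]
    if ff:
        lines = [ff[0]] + rest
    else:
        lines = ["##fileformat=VCFv4.2"] + rest

    defined = _defined_ids(lines)
    additions: list[str] = []

    has_genotypes = bool(pool.samples)
    has_depths = any(d is not None for rec in pool.records for d in rec.depths.values())
    if has_genotypes and "GT" not in defined["FORMAT"]:
        additions.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if has_depths and "DP" not in defined["FORMAT"]:
        additions.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')

    info_keys: dict[str, bool] = {}  # key -> ever used as flag
    filters: list[str] = []
    contigs: list[str] = []
    for rec in pool.records:
        for k, v in rec.info.items():
            flag = v is True
            info_keys[k] = info_keys.get(k, True) and flag
        for f in rec.filter.split(";"):
            if f not in ("", ".", "PASS") and f not in filters:
                filters.append(f)
        if rec.chrom not in contigs:
            contigs.append(rec.chrom)

    for k, is_flag in info_keys.items():
        if k in defined["INFO"]:
            continue
        if is_flag:
            additions.append(f'##INFO=<ID={k},Number=0,Type=Flag,Description="Unknown">')
        else:
            additions.append(f'##INFO=<ID={k},Number=.,Type=String,Description="Unknown">')
    for f in filters:
        if f not in defined["FILTER"]:
            additions.append(f'##FILTER=<ID={f},Description="Unknown">')
    for c in sorted(set(contigs) - defined["contig"], key=chrom_sort_key):
        additions.append(f"##contig=<ID={c}>")

    return lines + additions


def _fmt_qual(q: float | None) -> str:
    if q is None:
        return "."
    if float(q).is_integer():
        return str(int(q))
    return f"{q:g}"


def write_vcf(pool: VariantPool, path: str | Path, repair: bool = True) -> Path:
    """Write the pool as VCFv4.2 with all pool samples as columns.

    With ``repair`` (the default) the header is passed through
    :func:`repair_header` first, so the output always re-parses under a strict
    validator.  Missing QUAL/DP/genotypes serialize as ``.`` / ``./.``.
    """
    path = Path(path)
    header = repair_header(pool.header_lines, pool) if repair else list(pool.header_lines)
    header = ["##fileformat=VCFv4.2"] + [l for l in header if not _FILEFORMAT.match(l)]

    emit_dp = any(d is not None for rec in pool.records for d in rec.depths.values())
    fmt = "GT:DP" if emit_dp else "GT"
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if pool.samples:
        cols += ["FORMAT"] + list(pool.samples)

    with open(path, "w") as fh:
        for line in header:
            fh.write(line + "\n")
        fh.write("\t".join(cols) + "\n")
        for rec in pool.records:
            info = ";".join(
                k if v is True else f"{k}={v}" for k, v in rec.info.items()
            ) or "."
            row = [
                rec.chrom, str(rec.pos), rec.id or ".", rec.ref, ",".join(rec.alts),
                _fmt_qual(rec.qual), rec.filter or ".", info,
            ]
            if pool.samples:
                row.append(fmt)
                for s in pool.samples:
                    gt = str(rec.genotype(s))
                    if emit_dp:
                        d = rec.depths.get(s)
                        gt += ":" + ("." if d is None else str(d))
                    row.append(gt)
            fh.write("\t".join(row) + "\n")
    return path


# ---------------------------------------------------------------------------
# Chromosome-prefix normalization


def _norm_chrom(name: str, mode: str) -> str:
    if mode == "add":
        return name if name.startswith("chr") else "chr" + name
    if mode == "remove":
        return name[3:] if name.startswith("chr") else name
    raise ValueError(f"mode must be 'add' or 'remove', got {mode!r}")


_CONTIG_LINE = re.compile(r"^(##contig=<ID=)([^,>]+)(.*)$")


def normalize_chr(pool: VariantPool, mode: str) -> VariantPool:
    """Prepend or strip the ``chr`` prefix on every record and contig line.

    ``mode='add'`` leaves already-prefixed names unchanged; ``mode='remove'``
    strips the prefix where present.  Idempotent per mode; no other renaming
    (chrM/MT are handled like any other name).
    """
    new_records = [replace(rec, chrom=_norm_chrom(rec.chrom, mode)) for rec in pool.records]
    new_header = []
    for line in pool.header_lines:
        m = _CONTIG_LINE.match(line)
        if m:
            line = m.group(1) + _norm_chrom(m.group(2), mode) + m.group(3)
        new_header.append(line)
    out = VariantPool(pool_id=pool.pool_id, samples=list(pool.samples),
                      records=new_records, header_lines=new_header)
    out.sort()
    return out


# ---------------------------------------------------------------------------
# Strict validation (htslib-backed)


def validate_vcf(path: str | Path) -> None:
    """Strictly validate a VCF file; raise :class:`VcfValidationError` if not.

    Uses htslib (via pysam) to parse, then additionally requires every contig,
    INFO key, FORMAT field and FILTER used by the records to be declared in
    the header (htslib alone only warns about these).
    """
    import pysam

    path = str(path)
    try:
        vf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise VcfValidationError(f"{path}: not parseable as VCF: {exc}") from exc
    with vf:
        # capture declared IDs before iterating: htslib silently adds
        # undeclared keys to the in-memory header as records are parsed
        contigs = set(vf.header.contigs)
        infos = set(vf.header.info)
        formats = set(vf.header.formats)
        filters = set(vf.header.filters)
        problems: list[str] = []
        for i, rec in enumerate(vf, start=1):
            if rec.chrom not in contigs:
                problems.append(f"record {i}: contig {rec.chrom} undeclared")
            for k in rec.info:
                if k not in infos:
                    problems.append(f"record {i}: INFO {k} undeclared")
            for k in rec.format:
                if k not in formats:
                    problems.append(f"record {i}: FORMAT {k} undeclared")
            for k in rec.filter:
                if k not in filters:
                    problems.append(f"record {i}: FILTER {k} undeclared")
            if problems:
                break
    if problems:
        raise VcfValidationError(f"{path}: " + "; ".join(problems))
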