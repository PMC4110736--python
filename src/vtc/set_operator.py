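"""Genotype-aware set operations over variant pools, plus the operation DSL.

Operations are written in a compact bracket syntax, one token per operation::

    oId=operator[poolRef[sample,sample,...]:poolRef:...]

where ``operator`` is ``i`` (intersect), ``c`` (complement) or ``u`` (union),
a sample list restricts an operand to a subset of that pool's samples (all
samples when omitted), and ``oId`` names the result so later tokens in the
same command can reference it ("operation stringing").  Omitted IDs are
auto-assigned ``op0, op1, ...`` in token order.

Matching semantics
------------------
The matching unit for the ``variant`` method and all genotype-level methods
is the ``(chrom, pos, ref, alt)`` key, evaluated per alternate; multi-allelic
records match if at least one alternate matches.  The ``position`` method
matches on ``(chrom, pos, ref)`` only.  Genotype-level intersects require
*every* selected sample in *every* operand to satisfy the genotype predicate;
a no-call never satisfies any predicate.  At multi-allelic sites the predicate
is evaluated against the matching alternate: a ``0/2`` call is heterozygous
for alternate #2 only.  ``het`` requires one reference allele — a call with
two different alternate alleles does not count as heterozygous.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

from .errors import (
    DslArityError,
    DslResolutionError,
    DslSyntaxError,
    UnknownSampleError,
)
from .vcf_model import (
    NO_CALL,
    Genotype,
    SamplePool,
    VariantKey,
    VariantPool,
    VariantRecord,
    pool_keys,
    remap_genotype,
    write_vcf,
)

__all__ = [
    "Operator",
    "IntersectMethod",
    "ComplementMethod",
    "OperationSpec",
    "ComparisonResult",
    "parse_operations",
    "genotype_satisfies",
    "intersect",
    "complement",
    "union",
    "execute",
    "compare",
]


class Operator(str, Enum):
    INTERSECT = "intersect"
    COMPLEMENT = "complement"
    UNION = "union"

    @property
    def char(self) -> str:
        return {"intersect": "i", "complement": "c", "union": "u"}[self.value]


_CHAR_TO_OP = {"i": Operator.INTERSECT, "c": Operator.COMPLEMENT, "u": Operator.UNION}


class IntersectMethod(str, Enum):
    """Five genotype-level methods and two record-level methods."""

    HET = "het"
    HOMO_ALT = "homo_alt"
    HET_OR_HOMO_ALT = "het_or_homo_alt"
    HOMO_REF = "homo_ref"
    EXACT_MATCH = "exact_match"
    VARIANT = "variant"        # record-level: chrom,pos,ref,alt
    POSITION = "position"      # record-level: chrom,pos,ref

    @property
    def is_genotype_level(self) -> bool:
        return self not in (IntersectMethod.VARIANT, IntersectMethod.POSITION)


class ComplementMethod(str, Enum):
    HET_OR_HOMO_ALT = "het_or_homo_alt"
    EXACT_GENOTYPE = "exact_genotype"
    VARIANT = "variant"


@dataclass(frozen=True)
class OperationSpec:
    """One parsed DSL operation."""

    op_id: str
    operator: Operator
    operands: tuple[tuple[str, tuple[str, ...] | None], ...]  # (pool_ref, samples|all)

    def render(self) -> str:
        parts = []
        for ref, samples in self.operands:
            parts.append(ref if samples is None else f"{ref}[{','.join(samples)}]")
        return f"{self.op_id}={self.operator.char}[{':'.join(parts)}]"


_NAME = re.compile(r"[^=\[\]:,]+")


def _parse_token(token: str, auto_id: str) -> OperationSpec:
    """Parse one operation token; positions in errors are 0-based characters."""
    i = 0
    op_id = auto_id
    eq = token.find("=")
    br = token.find("[")
    if br < 0:
        raise DslSyntaxError(f"{token!r}: missing '[' in operation")
    if 0 <= eq < br:
        op_id = token[:eq]
        if not op_id or not _NAME.fullmatch(op_id):
            raise DslSyntaxError(f"{token!r}: invalid operation ID before '=' (position 0)")
        i = eq + 1
    opchar = token[i:br]
    if opchar not in _CHAR_TO_OP:
        raise DslSyntaxError(
            f"{token!r}: unknown operator {opchar!r} at position {i}; expected i, c or u"
        )
    if not token.endswith("]"):
        raise DslSyntaxError(f"{token!r}: missing closing ']' at position {len(token) - 1}")
    body = token[br + 1 : -1]

    operands: list[tuple[str, tuple[str, ...] | None]] = []
    j = 0
    while j <= len(body):
        m = _NAME.match(body, j)
        if not m:
            raise DslSyntaxError(
                f"{token!r}: expected pool reference at position {br + 1 + j}"
            )
        ref = m.group(0)
        j = m.end()
        samples: tuple[str, ...] | None = None
        if j < len(body) and body[j] == "[":
            close = body.find("]", j)
            if close < 0:
                raise DslSyntaxError(
                    f"{token!r}: unclosed sample list at position {br + 1 + j}"
                )
            inner = body[j + 1 : close]
            samples = tuple(s for s in inner.split(",") if s)
            if not samples:
                raise DslSyntaxError(
                    f"{token!r}: empty sample list at position {br + 1 + j}"
                )
            j = close + 1
        operands.append((ref, samples))
        if j == len(body):
            break
        if body[j] != ":":
            raise DslSyntaxError(
                f"{token!r}: expected ':' between operands at position {br + 1 + j}"
            )
        j += 1
    return OperationSpec(op_id, _CHAR_TO_OP[opchar], tuple(operands))


def parse_operations(
    spec: str | Sequence[str], known_pool_ids: set[str] | Sequence[str]
) -> list[OperationSpec]:
    """Parse a whitespace-separated operation string (or token list).

    Later operations may reference earlier operation IDs; forward references
    and unknown pool references raise :class:`DslResolutionError`, duplicate
    IDs raise too, and complement tokens must have exactly two operands.
    """
    tokens = spec.split() if isinstance(spec, str) else list(spec)
    if not tokens:
        raise DslSyntaxError("empty operation string")
    known = set(known_pool_ids)
    defined: set[str] = set()
    specs: list[OperationSpec] = []
    for n, tok in enumerate(tokens):
        op = _parse_token(tok, auto_id=f"op{n}")
        if op.op_id in defined or op.op_id in known:
            raise DslResolutionError(f"duplicate operation ID {op.op_id!r}")
        if op.operator is Operator.COMPLEMENT and len(op.operands) != 2:
            raise DslArityError(
                f"complement takes exactly 2 operands (minuend first), got {len(op.operands)}"
            )
        if len(op.operands) < 2:
            raise DslArityError(
                f"{op.operator.value} requires >=2 operands, got {len(op.operands)}"
            )
        for ref, _ in op.operands:
            if ref not in known and ref not in defined:
                raise DslResolutionError(
                    f"operand {ref!r} in operation {op.op_id!r} does not resolve to an "
                    f"input pool or an earlier operation"
                )
        defined.add(op.op_id)
        specs.append(op)
    return specs


# ---------------------------------------------------------------------------
# Genotype predicates


def genotype_satisfies(
    g: Genotype, method: IntersectMethod, alt_index: int | None = None
) -> bool:
    """Does one genotype fall into the method's category?

    ``alt_index`` is the 1-based allele index of the alternate under test in
    the genotype's own record; when given, only that alternate counts as
    "variant".  No-calls (and partially missing calls) fail every method.
    """
    if method in (IntersectMethod.VARIANT, IntersectMethod.POSITION,
                  IntersectMethod.EXACT_MATCH):
        raise ValueError(f"{method.value} is not a per-genotype predicate")
    if not g.is_called:
        return False
    alleles = sorted(g.alleles)  # type: ignore[type-var]
    if method is IntersectMethod.HOMO_REF:
        return all(a == 0 for a in alleles)
    is_alt = (lambda a: a == alt_index) if alt_index is not None else (lambda a: a > 0)
    if len(alleles) != 2:
        return False  # het/homo-alt categories are defined for diploid calls
    a, b = alleles
    het = a == 0 and is_alt(b)       # one REF allele required: 1/2 is not het
    homo = a == b and is_alt(a)
    if method is IntersectMethod.HET:
        return het
    if method is IntersectMethod.HOMO_ALT:
        return homo
    return het or homo               # HET_OR_HOMO_ALT


# ---------------------------------------------------------------------------
# Operand plumbing

Operand = tuple[VariantPool, SamplePool | None]


@dataclass
class _Op:
    pool: VariantPool
    samples: tuple[str, ...]              # selected sample IDs (pool-local)
    out_names: dict[str, str]             # pool-local ID -> output roster ID
    key_index: dict[VariantKey, tuple[VariantRecord, int]] = field(default_factory=dict)
    site_index: dict[tuple[str, int, str], VariantRecord] = field(default_factory=dict)

    def index(self) -> None:
        for rec in self.pool.records:
            self.site_index[rec.site] = rec
            for ai, alt in enumerate(rec.alts):
                self.key_index[VariantKey(rec.chrom, rec.pos, rec.ref, alt)] = (rec, ai)


def _normalize_operands(operands: Sequence[Operand]) -> list[_Op]:
    """Validate sample selections and compute collision-free output names.

    A sample ID appearing in operands from two *different* pools is
    disambiguated in outputs as ``poolId.sampleId``.
    """
    sel: list[tuple[VariantPool, tuple[str, ...]]] = []
    for pool, sp in operands:
        if sp is None:
            samples = tuple(pool.samples)
        else:
            missing = [s for s in sp.sample_ids if s not in pool.samples]
            if missing:
                raise UnknownSampleError(
                    f"unknown sample(s) {', '.join(missing)} in pool {pool.pool_id!r}; "
                    f"available: {', '.join(pool.samples) or '(none)'}"
                )
            samples = tuple(sp.sample_ids)
        sel.append((pool, samples))

    owners: dict[str, set[str]] = {}
    for pool, samples in sel:
        for s in samples:
            owners.setdefault(s, set()).add(pool.pool_id)
    ops = []
    for pool, samples in sel:
        names = {
            s: (s if len(owners[s]) == 1 else f"{pool.pool_id}.{s}") for s in samples
        }
        op = _Op(pool, samples, names)
        op.index()
        ops.append(op)
    return ops


def _roster(ops: Sequence[_Op]) -> list[str]:
    seen: list[str] = []
    for op in ops:
        for s in op.samples:
            n = op.out_names[s]
            if n not in seen:
                seen.append(n)
    return seen


def _merge_site_annotations(recs: Sequence[VariantRecord]) -> tuple[str, float | None, str, dict]:
    """ID/QUAL/FILTER from the first record carrying the site; INFO keys whose
    values disagree with any other carrier are dropped."""
    base = recs[0]
    info = dict(base.info)
    for other in recs[1:]:
        for k in list(info):
            if k in other.info and other.info[k] != info[k]:
                del info[k]
    return base.id, base.qual, base.filter, info


def _build_output_record(
    site_recs: Sequence[tuple[_Op, VariantRecord]],
    out_alts: Sequence[str],
    fill_nocall: Sequence[str] = (),
) -> VariantRecord:
    """Assemble a merged output record re-indexed onto ``out_alts``.

    Each sample keeps its original genotype (first operand wins on duplicate
    output names); alleles referencing alternates absent from ``out_alts``
    become missing.
    """
    op0, rec0 = site_recs[0]
    vid, qual, filt, info = _merge_site_annotations([r for _, r in site_recs])
    genotypes: dict[str, Genotype] = {}
    depths: dict[str, int | None] = {}
    for op, rec in site_recs:
        for s in op.samples:
            name = op.out_names[s]
            if name in genotypes:
                continue
            genotypes[name] = remap_genotype(rec.genotype(s), rec, out_alts)
            depths[name] = rec.depths.get(s)
    for name in fill_nocall:
        genotypes.setdefault(name, NO_CALL)
        depths.setdefault(name, None)
    return VariantRecord(
        chrom=rec0.chrom, pos=rec0.pos, ref=rec0.ref, alts=tuple(out_alts),
        id=vid, qual=qual, filter=filt, info=info, genotypes=genotypes, depths=depths,
    )


def _genotype_strings(rec: VariantRecord, sample: str) -> tuple[str, ...] | None:
    return rec.genotype(sample).allele_strings(rec.ref, rec.alts)


def _result_pool(result_id: str, ops: Sequence[_Op], records: list[VariantRecord]) -> VariantPool:
    pool = VariantPool(
        pool_id=result_id,
        samples=_roster(ops),
        records=records,
        header_lines=list(ops[0].pool.header_lines),
    )
    pool.sort()
    return pool


# ---------------------------------------------------------------------------
# Core operations


def intersect(
    operands: Sequence[Operand],
    method: IntersectMethod = IntersectMethod.HET_OR_HOMO_ALT,
    result_id: str = "intersect",
) -> VariantPool:
    """Intersect two or more operands.

    Record-level ``position`` keeps a site iff every operand carries a record
    with equal (chrom, pos, ref); ``variant`` additionally requires at least
    one shared alternate, and the output record carries exactly the shared
    alternates.  Genotype-level methods further require every selected sample
    in every operand to satisfy the predicate for a shared alternate
    (``exact_match``: one identical called genotype — phase-insensitive allele
    multiset — across all selected samples of all operands).  The output
    roster is the union of selected samples, each carrying its original
    genotype.
    """
    if len(operands) < 2:
        raise DslArityError("intersect requires >=2 operands")
    ops = _normalize_operands(operands)
    first = ops[0]
    out_records: list[VariantRecord] = []

    if method is IntersectMethod.POSITION:
        for rec in first.pool.records:
            if all(rec.site in op.site_index for op in ops):
                site_recs = [(op, op.site_index[rec.site]) for op in ops]
                alts: list[str] = []
                for _, r in site_recs:
                    for a in r.alts:
                        if a not in alts:
                            alts.append(a)
                out_records.append(_build_output_record(site_recs, alts))
        return _result_pool(result_id, ops, out_records)

    for rec in first.pool.records:
        shared = [
            alt for alt in rec.alts
            if all(VariantKey(rec.chrom, rec.pos, rec.ref, alt) in op.key_index for op in ops)
        ]
        if not shared:
            continue
        if method is IntersectMethod.VARIANT:
            kept = shared
        elif method is IntersectMethod.EXACT_MATCH:
            sigs = set()
            ok = True
            for op in ops:
                r, _ = op.key_index[VariantKey(rec.chrom, rec.pos, rec.ref, shared[0])]
                for s in op.samples:
                    sig = _genotype_strings(r, s)
                    if sig is None:  # no-call fails
                        ok = False
                        break
                    sigs.add(sig)
                if not ok:
                    break
            kept = shared if ok and len(sigs) == 1 else []
        else:
            kept = []
            for alt in shared:
                key = VariantKey(rec.chrom, rec.pos, rec.ref, alt)
                good = True
                for op in ops:
                    r, ai = op.key_index[key]
                    if not all(
                        genotype_satisfies(r.genotype(s), method, alt_index=ai + 1)
                        for s in op.samples
                    ):
                        good = False
                        break
                if good:
                    kept.append(alt)
        if not kept:
            continue
        site_recs = [(op, op.site_index[rec.site]) for op in ops]
        out_records.append(_build_output_record(site_recs, kept))
    return _result_pool(result_id, ops, out_records)


def complement(
    minuend: Operand,
    subtrahend: Operand,
    method: ComplementMethod = ComplementMethod.HET_OR_HOMO_ALT,
    result_id: str = "complement",
) -> VariantPool:
    """Subtract the subtrahend's variants from the minuend, per alternate.

    ``variant`` removes an alternate iff its (chrom, pos, ref, alt) key occurs
    in the subtrahend; a record keeps its unmatched alternates.
    ``het_or_homo_alt`` additionally requires every selected sample in *both*
    pools to be heterozygous or homozygous for that alternate;
    ``exact_genotype`` requires all samples across both pools to share one
    identical called genotype.  The result keeps the minuend's selected
    samples only.
    """
    m, s = _normalize_operands([minuend, subtrahend])
    out_records: list[VariantRecord] = []
    for rec in m.pool.records:
        kept: list[str] = []
        for ai, alt in enumerate(rec.alts):
            key = VariantKey(rec.chrom, rec.pos, rec.ref, alt)
            if key not in s.key_index:
                kept.append(alt)
                continue
            s_rec, s_ai = s.key_index[key]
            if method is ComplementMethod.VARIANT:
                remove = True
            elif method is ComplementMethod.HET_OR_HOMO_ALT:
                remove = all(
                    genotype_satisfies(
                        rec.genotype(x), IntersectMethod.HET_OR_HOMO_ALT, alt_index=ai + 1
                    )
                    for x in m.samples
                ) and all(
                    genotype_satisfies(
                        s_rec.genotype(x), IntersectMethod.HET_OR_HOMO_ALT, alt_index=s_ai + 1
                    )
                    for x in s.samples
                )
            else:  # EXACT_GENOTYPE
                sigs = set()
                remove = True
                for r, samples in ((rec, m.samples), (s_rec, s.samples)):
                    for x in samples:
                        sig = _genotype_strings(r, x)
                        if sig is None:  # missing/no-call never matches
                            remove = False
                            break
                        sigs.add(sig)
                    if not remove:
                        break
                remove = remove and len(sigs) == 1
            if not remove:
                kept.append(alt)
        if not kept:
            continue
        genotypes = {
            m.out_names[x]: remap_genotype(rec.genotype(x), rec, kept) for x in m.samples
        }
        depths = {m.out_names[x]: rec.depths.get(x) for x in m.samples}
        out_records.append(
            replace(rec, alts=tuple(kept), genotypes=genotypes, depths=depths)
        )
    return _result_pool(result_id, [m], out_records)


def union(operands: Sequence[Operand], result_id: str = "union") -> VariantPool:
    """Combine all variants and selected samples regardless of genotype.

    Co-located records are merged into one multi-alternate record with
    genotypes re-indexed; a sample absent at a site gets a no-call (``./.``).
    """
    if len(operands) < 2:
        raise DslArityError("union requires >=2 operands")
    ops = _normalize_operands(operands)
    roster = _roster(ops)

    sites: list[tuple[str, int, str]] = []
    carriers: dict[tuple[str, int, str], list[tuple[_Op, VariantRecord]]] = {}
    for op in ops:
        for rec in op.pool.records:
            if rec.site not in carriers:
                carriers[rec.site] = []
                sites.append(rec.site)
            carriers[rec.site].append((op, rec))

    out_records = []
    for site in sites:
        site_recs = carriers[site]
        alts: list[str] = []
        for _, r in site_recs:
            for a in r.alts:
                if a not in alts:
                    alts.append(a)
        out_records.append(_build_output_record(site_recs, alts, fill_nocall=roster))
    return _result_pool(result_id, ops, out_records)


# ---------------------------------------------------------------------------
# Execution of parsed operation lists


def execute(
    specs: Sequence[OperationSpec],
    pools: Mapping[str, VariantPool],
    intersect_method: IntersectMethod = IntersectMethod.HET_OR_HOMO_ALT,
    complement_method: ComplementMethod = ComplementMethod.HET_OR_HOMO_ALT,
    emit_intermediates: bool = False,
    out_dir: str | Path | None = None,
    final_path: str | Path | None = None,
) -> dict[str, VariantPool]:
    """Run operations in order, registering each result under its op ID.

    One intersect method and one complement method apply to every operation in
    the command.  With ``emit_intermediates`` every non-final result is
    written to ``<out_dir>/<oId>.vcf``; the final result is always written
    (to ``final_path`` when given, else ``<out_dir>/<oId>.vcf``) provided an
    output location is configured.
    """
    env: dict[str, VariantPool] = dict(pools)
    results: dict[str, VariantPool] = {}
    out_dir = Path(out_dir) if out_dir is not None else None
    for n, spec in enumerate(specs):
        operands: list[Operand] = []
        for ref, samples in spec.operands:
            if ref not in env:
                raise DslResolutionError(
                    f"operation {spec.op_id!r} references unknown pool {ref!r}"
                )
            pool = env[ref]
            sp = SamplePool(ref, tuple(samples)) if samples is not None else None
            operands.append((pool, sp))
        if spec.operator is Operator.INTERSECT:
            res = intersect(operands, intersect_method, result_id=spec.op_id)
        elif spec.operator is Operator.COMPLEMENT:
            res = complement(operands[0], operands[1], complement_method,
                             result_id=spec.op_id)
        else:
            res = union(operands, result_id=spec.op_id)
        env[spec.op_id] = res
        results[spec.op_id] = res
        is_final = n == len(specs) - 1
        if is_final:
            if final_path is not None:
                write_vcf(res, final_path)
            elif out_dir is not None:
                write_vcf(res, out_dir / f"{spec.op_id}.vcf")
        elif emit_intermediates and out_dir is not None:
            write_vcf(res, out_dir / f"{spec.op_id}.vcf")
    return results


# ---------------------------------------------------------------------------
# Four-way compare


@dataclass
class ComparisonResult:
    """Common variants, the two unique sets, and the combined union."""

    common: VariantPool
    unique_a: VariantPool
    unique_b: VariantPool
    combined: VariantPool

    @property
    def summary(self) -> dict[str, int]:
        return {
            p.pool_id: len(p.records)
            for p in (self.common, self.unique_a, self.unique_b, self.combined)
        }


def compare(
    pool_a: Operand, pool_b: Operand, out_dir: str | Path | None = None
) -> ComparisonResult:
    """The four-operation compare workflow on exactly two inputs.

    Runs a record-level (``variant``) intersect for the common set, the two
    complements for the unique sets, and a union for the combined set.  When
    ``out_dir`` is given, writes ``common.vcf``, ``unique_<A>.vcf``,
    ``unique_<B>.vcf`` and ``union.vcf``.
    """
    a_id = pool_a[0].pool_id
    b_id = pool_b[0].pool_id
    result = ComparisonResult(
        common=intersect([pool_a, pool_b], IntersectMethod.VARIANT, result_id="common"),
        unique_a=complement(pool_a, pool_b, ComplementMethod.VARIANT,
                            result_id=f"unique_{a_id}"),
        unique_b=complement(pool_b, pool_a, ComplementMethod.VARIANT,
                            result_id=f"unique_{b_id}"),
        combined=union([pool_a, pool_b], result_id="union"),
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_vcf(result.common, out_dir / "common.vcf")
        write_vcf(result.unique_a, out_dir / f"unique_{a_id}.vcf")
        write_vcf(result.unique_b, out_dir / f"unique_{b_id}.vcf")
        write_vcf(result.combined, out_dir / "union.vcf")
    return result
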