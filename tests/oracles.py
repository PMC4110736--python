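"""Independent brute-force oracles for the set-operation semantics.

Everything here is written directly from the matching rules' definitions,
on plain tuples, with linear scans — deliberately sharing no code with
vtc.set_operator — so tests can compare the engine against a literal
evaluation of each predicate.
"""

from __future__ import annotations

Key = tuple[str, int, str, str]          # chrom, pos, ref, alt
Site = tuple[str, int, str]              # chrom, pos, ref


def keys_of(pool) -> set[Key]:
    return {
        (r.chrom, r.pos, r.ref, alt) for r in pool.records for alt in r.alts
    }


def sites_of(pool) -> set[Site]:
    return {(r.chrom, r.pos, r.ref) for r in pool.records}


def _find_record(pool, site: Site):
    for r in pool.records:
        if (r.chrom, r.pos, r.ref) == site:
            return r
    return None


def _gt_indices(record, sample):
    g = record.genotypes.get(sample)
    if g is None:
        return (None, None)
    return tuple(g.alleles)


def _called(idx) -> bool:
    return len(idx) > 0 and all(a is not None for a in idx)


def _gt_strings(record, sample):
    """Phase-insensitive allele-string multiset; None when not fully called."""
    idx = _gt_indices(record, sample)
    if not _called(idx):
        return None
    return tuple(sorted(record.ref if a == 0 else record.alts[a - 1] for a in idx))


def gt_in_category(idx, category: str, alt_index: int) -> bool:
    """Literal genotype categories; het requires one reference allele."""
    if not _called(idx):
        return False
    if category == "homo_ref":
        return all(a == 0 for a in idx)
    if len(idx) != 2:
        return False
    a, b = sorted(idx)
    if category == "het":
        return a == 0 and b == alt_index
    if category == "homo_alt":
        return a == alt_index and b == alt_index
    if category == "het_or_homo_alt":
        return (a == 0 and b == alt_index) or (a == b == alt_index)
    raise ValueError(category)


def _selected(pool, samples):
    return list(pool.samples) if samples is None else list(samples)


def brute_intersect_keys(operands, method: str) -> set[Key]:
    """operands: list of (pool, sample_ids_or_None). Returns expected keys.

    For 'position' the returned keys are all alternates of every operand at
    the shared sites (the engine's output records carry the union of alts).
    """
    pools = [(p, _selected(p, s)) for p, s in operands]
    if method == "position":
        shared_sites = set.intersection(*(sites_of(p) for p, _ in pools))
        out: set[Key] = set()
        for site in shared_sites:
            for p, _ in pools:
                r = _find_record(p, site)
                if r is not None:
                    out.update((r.chrom, r.pos, r.ref, a) for a in r.alts)
        return out

    candidate = set.intersection(*(keys_of(p) for p, _ in pools))
    if method == "variant":
        return candidate
    out = set()
    for key in candidate:
        chrom, pos, ref, alt = key
        if method == "exact_match":
            sigs = set()
            ok = True
            for p, samples in pools:
                r = _find_record(p, (chrom, pos, ref))
                for s in samples:
                    sig = _gt_strings(r, s)
                    if sig is None:
                        ok = False
                        break
                    sigs.add(sig)
                if not ok:
                    break
            if ok and len(sigs) == 1:
                out.add(key)
            continue
        ok = True
        for p, samples in pools:
            r = _find_record(p, (chrom, pos, ref))
            ai = list(r.alts).index(alt) + 1
            for s in samples:
                if not gt_in_category(_gt_indices(r, s), method, ai):
                    ok = False
                    break
            if not ok:
                break
        if ok:
            out.add(key)
    return out


def brute_complement_keys(minuend, subtrahend, method: str) -> set[Key]:
    (mp, ms), (sp, ss) = (minuend, subtrahend)
    m_samples = _selected(mp, ms)
    s_samples = _selected(sp, ss)
    sub_keys = keys_of(sp)
    out = set()
    for key in keys_of(mp):
        if key not in sub_keys:
            out.add(key)
            continue
        chrom, pos, ref, alt = key
        m_rec = _find_record(mp, (chrom, pos, ref))
        s_rec = _find_record(sp, (chrom, pos, ref))
        if method == "variant":
            removed = True
        elif method == "het_or_homo_alt":
            m_ai = list(m_rec.alts).index(alt) + 1
            s_ai = list(s_rec.alts).index(alt) + 1
            removed = all(
                gt_in_category(_gt_indices(m_rec, s), "het_or_homo_alt", m_ai)
                for s in m_samples
            ) and all(
                gt_in_category(_gt_indices(s_rec, s), "het_or_homo_alt", s_ai)
                for s in s_samples
            )
        elif method == "exact_genotype":
            sigs = set()
            removed = True
            for rec, samples in ((m_rec, m_samples), (s_rec, s_samples)):
                for s in samples:
                    sig = _gt_strings(rec, s)
                    if sig is None:
                        removed = False
                        break
                    sigs.add(sig)
                if not removed:
                    break
            removed = removed and len(sigs) == 1
        else:
            raise ValueError(method)
        if not removed:
            out.add(key)
    return out


def brute_union_keys(operands) -> set[Key]:
    return set.union(*(keys_of(p) for p, _ in operands))


# ---------------------------------------------------------------------------
# Genotype-content oracle


def masked_gt_strings(record, sample, out_alts):
    """Expected output genotype for a carried sample: the original alleles,
    with alternates not representable in ``out_alts`` masked to None."""
    idx = _gt_indices(record, sample)
    out = []
    for a in idx:
        if a is None:
            out.append(None)
        elif a == 0:
            out.append(record.ref)
        else:
            alt = record.alts[a - 1]
            out.append(alt if alt in out_alts else None)
    return tuple(sorted(out, key=lambda x: (x is None, x)))


def result_gt_strings(record, sample):
    """Genotype of an output record as (string|None) multiset."""
    idx = _gt_indices(record, sample)
    out = []
    for a in idx:
        if a is None:
            out.append(None)
        elif a == 0:
            out.append(record.ref)
        else:
            out.append(record.alts[a - 1])
    return tuple(sorted(out, key=lambda x: (x is None, x)))


def check_genotype_content(result_pool, operands) -> None:
    """Every output genotype equals the sample's original (masked) genotype.

    Assumes sample IDs are unique across operand pools (no renaming), which
    holds for all generated pool pairs.
    """
    source: dict[str, tuple] = {}
    for p, samples in operands:
        for s in _selected(p, samples):
            source.setdefault(s, (p, s))
    for rec in result_pool.records:
        site = (rec.chrom, rec.pos, rec.ref)
        for out_name in result_pool.samples:
            pool, local = source[out_name]
            src = _find_record(pool, site)
            if src is None:
                expected = (None, None)
            else:
                expected = masked_gt_strings(src, local, rec.alts)
            got = result_gt_strings(rec, out_name)
            assert got == expected, (
                f"{site} sample {out_name}: got {got}, expected {expected}"
            )
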