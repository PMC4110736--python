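"""Shared builders for hand-crafted pools and generated pool pairs."""

from __future__ import annotations

import pytest

from vtc import (
    Genotype,
    GeneratorConfig,
    VariantPool,
    VariantRecord,
    generate_pool_pair,
    read_vcf,
)


def gt(s: str) -> Genotype:
    """Parse a genotype string like '0/1', '1|0' or './.'."""
    phased = "|" in s
    alleles = tuple(None if a == "." else int(a) for a in s.replace("|", "/").split("/"))
    return Genotype(alleles, phased)


def make_record(chrom="chr1", pos=100, ref="A", alts=("G",), genotypes=None,
                depths=None, qual=50.0, filter="PASS", info=None, vid="."):
    genotypes = {s: gt(v) for s, v in (genotypes or {}).items()}
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alts=tuple(alts), id=vid, qual=qual,
        filter=filter, info=dict(info or {}), genotypes=genotypes,
        depths=dict(depths or {}),
    )


def make_pool(pool_id="p", samples=(), records=(), header_lines=()):
    pool = VariantPool(
        pool_id=pool_id, samples=list(samples), records=list(records),
        header_lines=list(header_lines) or ["##fileformat=VCFv4.2"],
    )
    pool.sort()
    return pool


def generated_pair(tmp_path, seed, n_variants=100, n_samples=3, **kw):
    """Generate a pool pair on disk and load it back through the reader."""
    cfg = GeneratorConfig(seed=seed, n_variants=n_variants, n_samples=n_samples, **kw)
    pa, pb, manifest = generate_pool_pair(cfg, tmp_path / f"pair{seed}")
    return read_vcf(pa, "A"), read_vcf(pb, "B"), manifest


@pytest.fixture
def pair(tmp_path):
    return generated_pair(tmp_path, seed=1)
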