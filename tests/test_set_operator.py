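"""Set-operation semantics: genotype predicates, the three operations,
execution with stringing, and the four-way compare."""

import pytest

from vtc import (
    ComplementMethod,
    IntersectMethod,
    compare,
    complement,
    execute,
    genotype_satisfies,
    intersect,
    parse_operations,
    pool_keys,
    read_vcf,
    union,
    validate_vcf,
)
from vtc.vcf_model import VariantKey

from conftest import generated_pair, gt, make_pool, make_record
import oracles

GT_METHODS = [IntersectMethod.HET, IntersectMethod.HOMO_ALT,
              IntersectMethod.HET_OR_HOMO_ALT, IntersectMethod.HOMO_REF]


class TestGenotypePredicates:
    @pytest.mark.parametrize("g, method, expected", [
        ("0/1", IntersectMethod.HET, True),
        ("1/0", IntersectMethod.HET, True),
        ("1/2", IntersectMethod.HET, False),   # two different alts: not het
        ("1/1", IntersectMethod.HET, False),
        ("1/1", IntersectMethod.HOMO_ALT, True),
        ("0/1", IntersectMethod.HOMO_ALT, False),
        ("0/0", IntersectMethod.HOMO_ALT, False),
        ("0/1", IntersectMethod.HET_OR_HOMO_ALT, True),
        ("2/2", IntersectMethod.HET_OR_HOMO_ALT, True),
        ("0/0", IntersectMethod.HOMO_REF, True),
        ("0/1", IntersectMethod.HOMO_REF, False),
    ])
    def test_categories(self, g, method, expected):
        assert genotype_satisfies(gt(g), method) is expected

    @pytest.mark.parametrize("method", GT_METHODS)
    def test_no_call_fails_every_method(self, method):
        assert not genotype_satisfies(gt("./."), method)
        assert not genotype_satisfies(gt("./1"), method)

    def test_alternate_specific_evaluation(self):
        # 0/2 is het for alternate #2 only
        assert genotype_satisfies(gt("0/2"), IntersectMethod.HET, alt_index=2)
        assert not genotype_satisfies(gt("0/2"), IntersectMethod.HET, alt_index=1)
        assert genotype_satisfies(gt("2/2"), IntersectMethod.HOMO_ALT, alt_index=2)

    def test_record_level_methods_are_not_per_genotype(self):
        with pytest.raises(ValueError):
            genotype_satisfies(gt("0/1"), IntersectMethod.VARIANT)


def _two_pools():
    a = make_pool("A", samples=["s1"], records=[
        make_record(chrom="chr1", pos=100, ref="A", alts=("G",),
                    genotypes={"s1": "0/1"})])
    b = make_pool("B", samples=["s2"], records=[
        make_record(chrom="chr1", pos=100, ref="A", alts=("G",),
                    genotypes={"s2": "0/1"})])
    return a, b


class TestIntersect:
    def test_het_at_matching_variant_merges_samples(self):
        a, b = _two_pools()
        res = intersect([(a, None), (b, None)], IntersectMethod.HET)
        assert len(res.records) == 1
        assert res.samples == ["s1", "s2"]
        assert str(res.records[0].genotypes["s1"]) == "0/1"
        assert str(res.records[0].genotypes["s2"]) == "0/1"

    def test_variant_method_matches_on_any_shared_alternate(self):
        a = make_pool("A", records=[make_record(alts=("G", "T"))])
        b = make_pool("B", records=[make_record(alts=("T", "C"))])
        res = intersect([(a, None), (b, None)], IntersectMethod.VARIANT)
        assert len(res.records) == 1
        assert res.records[0].alts == ("T",)

    def test_position_method_ignores_alternates(self):
        a = make_pool("A", records=[make_record(alts=("G",))])
        b = make_pool("B", records=[make_record(alts=("T",))])
        assert not intersect([(a, None), (b, None)], IntersectMethod.VARIANT).records
        res = intersect([(a, None), (b, None)], IntersectMethod.POSITION)
        assert len(res.records) == 1
        assert set(res.records[0].alts) == {"G", "T"}

    def test_genotype_level_failure_drops_site(self):
        a, b = _two_pools()
        b.records[0].genotypes["s2"] = gt("1/1")
        assert not intersect([(a, None), (b, None)], IntersectMethod.HET).records
        # but both calls carry the alternate, so het_or_homo_alt keeps it
        assert intersect([(a, None), (b, None)],
                         IntersectMethod.HET_OR_HOMO_ALT).records

    def test_exact_match_requires_identical_genotypes_phase_insensitive(self):
        a, b = _two_pools()
        b.records[0].genotypes["s2"] = gt("1|0")  # same alleles, phased
        assert intersect([(a, None), (b, None)], IntersectMethod.EXACT_MATCH).records
        b.records[0].genotypes["s2"] = gt("1/1")
        assert not intersect([(a, None), (b, None)],
                             IntersectMethod.EXACT_MATCH).records

    def test_sample_subset_restricts_the_check(self):
        a, b = _two_pools()
        a.samples = ["s1", "extra"]
        a.records[0].genotypes["extra"] = gt("0/0")
        from vtc import SamplePool
        assert not intersect([(a, None), (b, None)], IntersectMethod.HET).records
        res = intersect([(a, SamplePool("A", ("s1",))), (b, None)],
                        IntersectMethod.HET)
        assert len(res.records) == 1 and res.samples == ["s1", "s2"]

    def test_sample_name_collision_prefixed_with_pool_id(self):
        a, b = _two_pools()
        b.samples = ["s1"]
        b.records[0].genotypes = {"s1": gt("0/1")}
        res = intersect([(a, None), (b, None)], IntersectMethod.HET)
        assert res.samples == ["A.s1", "B.s1"]


class TestComplement:
    def test_empty_subtrahend_returns_minuend(self):
        a, _ = _two_pools()
        b = make_pool("B", samples=["s2"])
        res = complement((a, None), (b, None), ComplementMethod.VARIANT)
        assert pool_keys(res) == pool_keys(a)

    def test_exact_genotype_retains_on_mismatch(self):
        a, b = _two_pools()
        b.records[0].genotypes["s2"] = gt("1/1")
        res = complement((a, None), (b, None), ComplementMethod.EXACT_GENOTYPE)
        assert len(res.records) == 1
        res2 = complement((a, None), (b, None), ComplementMethod.VARIANT)
        assert not res2.records

    def test_per_alternate_removal_keeps_unmatched_alts(self):
        a = make_pool("A", samples=["s1"], records=[
            make_record(alts=("G", "T"), genotypes={"s1": "1/2"})])
        b = make_pool("B", records=[make_record(alts=("G",))])
        res = complement((a, None), (b, None), ComplementMethod.VARIANT)
        assert len(res.records) == 1
        assert res.records[0].alts == ("T",)
        # the removed alternate G is no longer representable: masked allele
        assert str(res.records[0].genotypes["s1"]) == "./1"

    def test_self_complement_is_empty(self, pair):
        a, _, _ = pair
        assert not complement((a, None), (a, None), ComplementMethod.VARIANT).records

    def test_result_keeps_minuend_samples_only(self):
        a, b = _two_pools()
        res = complement((a, None), (b, None), ComplementMethod.EXACT_GENOTYPE)
        assert res.samples == ["s1"]


class TestUnion:
    def test_missing_samples_get_no_call(self):
        a = make_pool("A", samples=["s1"], records=[
            make_record(chrom="chr1", pos=100, genotypes={"s1": "0/1"})])
        b = make_pool("B", samples=["s2"], records=[
            make_record(chrom="chr2", pos=200, genotypes={"s2": "1/1"})])
        res = union([(a, None), (b, None)])
        assert len(res.records) == 2
        r1, r2 = res.records
        assert str(r1.genotypes["s2"]) == "./."
        assert str(r2.genotypes["s1"]) == "./."

    def test_self_union_is_idempotent(self, pair):
        a, _, _ = pair
        res = union([(a, None), (a, None)])
        assert pool_keys(res) == pool_keys(a)
        assert res.samples == a.samples
        for ra, rr in zip(a.records, res.records):
            assert {s: str(g) for s, g in ra.genotypes.items()} == \
                   {s: str(g) for s, g in rr.genotypes.items()}

    def test_colocated_records_merge_into_multiallelic(self):
        a = make_pool("A", samples=["s1"],
                      records=[make_record(alts=("G",), genotypes={"s1": "0/1"})])
        b = make_pool("B", samples=["s2"],
                      records=[make_record(alts=("T",), genotypes={"s2": "1/1"})])
        res = union([(a, None), (b, None)])
        assert len(res.records) == 1
        rec = res.records[0]
        assert rec.alts == ("G", "T")
        assert str(rec.genotypes["s2"]) == "2/2"


class TestOracleEquivalence:
    """Engine output equals a literal brute-force evaluation of each rule."""

    @pytest.mark.parametrize("seed", range(5))
    def test_intersect_all_methods(self, tmp_path, seed):
        a, b, _ = generated_pair(tmp_path, seed, n_variants=80, n_samples=3,
                                 multi_alt_fraction=0.2)
        operands = [(a, None), (b, None)]
        for method in IntersectMethod:
            res = intersect(operands, method)
            got = oracles.keys_of(res)
            expected = oracles.brute_intersect_keys(operands, method.value)
            assert got == expected, method
            oracles.check_genotype_content(res, operands)

    @pytest.mark.parametrize("seed", range(5))
    def test_complement_all_methods(self, tmp_path, seed):
        a, b, _ = generated_pair(tmp_path, seed + 10, n_variants=80, n_samples=3,
                                 multi_alt_fraction=0.2)
        for method in ComplementMethod:
            res = complement((a, None), (b, None), method)
            expected = oracles.brute_complement_keys((a, None), (b, None),
                                                     method.value)
            assert oracles.keys_of(res) == expected, method

    def test_union_keys_and_content(self, tmp_path):
        for seed in (5, 6, 7):
            a, b, _ = generated_pair(tmp_path, seed, n_variants=80)
            operands = [(a, None), (b, None)]
            res = union(operands)
            assert oracles.keys_of(res) == oracles.brute_union_keys(operands)
            oracles.check_genotype_content(res, operands)
            # every (sample, site) cell is populated
            for rec in res.records:
                assert set(rec.genotypes) == set(res.samples)

    def test_monotonicity_of_methods(self, pair):
        a, b, _ = pair
        operands = [(a, None), (b, None)]
        var_keys = pool_keys(intersect(operands, IntersectMethod.VARIANT))
        pos_sites = {(k.chrom, k.pos, k.ref)
                     for k in pool_keys(intersect(operands, IntersectMethod.POSITION))}
        for method in GT_METHODS + [IntersectMethod.EXACT_MATCH]:
            keys = pool_keys(intersect(operands, method))
            assert keys <= var_keys
        assert {(k.chrom, k.pos, k.ref) for k in var_keys} <= pos_sites

    def test_commutativity(self, pair):
        a, b, _ = pair
        assert pool_keys(intersect([(a, None), (b, None)], IntersectMethod.VARIANT)) \
            == pool_keys(intersect([(b, None), (a, None)], IntersectMethod.VARIANT))
        assert pool_keys(union([(a, None), (b, None)])) \
            == pool_keys(union([(b, None), (a, None)]))


class TestExecute:
    def test_single_operation_registered_under_id(self, pair):
        a, b, _ = pair
        specs = parse_operations("myOP=i[A:B]", {"A", "B"})
        results = execute(specs, {"A": a, "B": b})
        assert set(results) == {"myOP"}

    def test_stringing_with_intermediate_files(self, tmp_path, pair):
        a, b, _ = pair
        specs = parse_operations("x=u[A:B] y=c[x:B]", {"A", "B"})
        execute(specs, {"A": a, "B": b},
                complement_method=ComplementMethod.VARIANT,
                emit_intermediates=True, out_dir=tmp_path)
        assert (tmp_path / "x.vcf").exists() and (tmp_path / "y.vcf").exists()
        validate_vcf(tmp_path / "x.vcf")
        validate_vcf(tmp_path / "y.vcf")
        # composing the oracles reproduces the chained result
        u_keys = oracles.brute_union_keys([(a, None), (b, None)])
        expected = u_keys - oracles.keys_of(b)
        assert oracles.keys_of(read_vcf(tmp_path / "y.vcf", "y")) == expected

    def test_chained_result_usable_as_operand(self, pair):
        a, b, _ = pair
        specs = parse_operations("x=i[A:B] y=u[x:A]", {"A", "B"})
        results = execute(specs, {"A": a, "B": b},
                          intersect_method=IntersectMethod.VARIANT)
        assert pool_keys(results["y"]) == pool_keys(a) | pool_keys(results["x"])


class TestCompare:
    def test_identical_inputs(self, pair):
        a, _, _ = pair
        a2 = make_pool("A2", samples=list(a.samples), records=list(a.records))
        res = compare((a, None), (a2, None))
        assert not res.unique_a.records and not res.unique_b.records
        assert pool_keys(res.common) == pool_keys(res.combined) == pool_keys(a)

    def test_disjoint_inputs(self, tmp_path):
        a, b, _ = generated_pair(tmp_path, 20, n_variants=40, shared_fraction=0.0)
        res = compare((a, None), (b, None))
        assert not res.common.records
        assert pool_keys(res.combined) == pool_keys(a) | pool_keys(b)

    def test_partition_law_and_files(self, tmp_path):
        a, b, _ = generated_pair(tmp_path, 21, n_variants=100)
        res = compare((a, None), (b, None), out_dir=tmp_path / "cmp")
        kc, ka, kb, ku = (pool_keys(p) for p in
                          (res.common, res.unique_a, res.unique_b, res.combined))
        assert kc | ka | kb == ku
        assert not (kc & ka) and not (kc & kb) and not (ka & kb)
        for name in ("common.vcf", "unique_A.vcf", "unique_B.vcf", "union.vcf"):
            validate_vcf(tmp_path / "cmp" / name)
        assert res.summary["union"] == len(res.combined.records)
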