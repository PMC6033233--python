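"""Bin planning, indexed search vs the brute-force oracle, overflow."""

import numpy as np
import pytest

from guidescout.bitcodec import decode_bases, encode_bases
from guidescout.database import TargetDatabase, build_database
from guidescout.discovery import discover_targets
from guidescout.fixtures import plant_offtargets, synth_genome
from guidescout.search import (
    MODE_LINEAR, MODE_SELECTIVE, SearchResult, brute_force_search,
    full_scan_fallback_decision, plan_bins, search, sites_from_strings,
)


def hit_tuples(res: SearchResult):
    return [(h.sequence, h.mismatches, h.occurrences, h.positions)
            for h in res.hits]


def assert_results_equal(a: list[SearchResult], b: list[SearchResult]):
    assert len(a) == len(b)
    for ra, rb in zip(a, b):
        assert ra.overflow == rb.overflow
        assert hit_tuples(ra) == hit_tuples(rb)


@pytest.fixture(scope="module")
def indexed(tmp_path_factory, small_genome, cas9):
    path = tmp_path_factory.mktemp("sdb") / "g.db"
    build_database(small_genome, cas9, path)
    return TargetDatabase(path)


class TestPlanBins:
    def test_k0_plans_exactly_own_prefix(self, indexed, cas9):
        guides = sites_from_strings(["ACGTACGTACGTACGTACGTAGG"], cas9)
        per_guide, global_set = plan_bins(guides, 0, indexed.header)
        p = indexed.header.prefix_len
        assert per_guide[0] == {encode_bases("ACGTACG")}
        assert global_set == per_guide[0]

    def test_k_at_least_p_plans_everything(self, indexed, cas9):
        guides = sites_from_strings(["ACGTACGTACGTACGTACGTAGG"], cas9)
        p = indexed.header.prefix_len
        per_guide, global_set = plan_bins(guides, p, indexed.header)
        assert len(global_set) == 4 ** p

    def test_matches_exhaustive_prefix_enumeration(self, indexed, cas9, rng):
        p = indexed.header.prefix_len
        guides = sites_from_strings(
            ["".join(rng.choice(list("ACGT"), 20)) + "AGG" for _ in range(5)],
            cas9)
        per_guide, _ = plan_bins(guides, 3, indexed.header)
        for g, planned in zip(guides, per_guide):
            expect = {
                code for code in range(4 ** p)
                if sum(x != y for x, y in zip(
                    decode_bases(code, p), g.protospacer[:p])) <= 3
            }
            assert planned == expect


class TestFallbackDecision:
    def test_single_guide_k0_is_selective(self, indexed, cas9):
        guides = sites_from_strings(["ACGTACGTACGTACGTACGTAGG"], cas9)
        _, global_set = plan_bins(guides, 0, indexed.header)
        assert full_scan_fallback_decision(global_set, indexed.header) == MODE_SELECTIVE

    def test_k_at_least_p_is_linear(self, indexed, cas9):
        guides = sites_from_strings(["ACGTACGTACGTACGTACGTAGG"], cas9)
        _, global_set = plan_bins(guides, indexed.header.prefix_len, indexed.header)
        assert full_scan_fallback_decision(global_set, indexed.header) == MODE_LINEAR

    def test_empty_database_stays_selective(self, tmp_path, cas9):
        path = tmp_path / "e.db"
        header = build_database({"c": "ATATATAT"}, cas9, path)
        assert full_scan_fallback_decision(set(range(100)), header) == MODE_SELECTIVE


class TestSearchExactness:
    def test_verbatim_guide_k0_self_hit_only(self, small_genome, indexed, cas9):
        sites = list(discover_targets(small_genome, cas9))
        # pick a site whose sequence occurs exactly once
        seqs = {}
        for s in sites:
            seqs.setdefault(s.protospacer + s.pam, []).append(s)
        seq, occ = next((k, v) for k, v in sorted(seqs.items()) if len(v) == 1)
        guides = sites_from_strings([seq], cas9)
        (res,) = search(indexed, guides, k=0)
        assert len(res.hits) == 1
        assert res.hits[0].sequence == seq
        assert res.hits[0].mismatches == 0
        assert res.hits[0].positions == [(occ[0].contig, occ[0].start, occ[0].strand)]

    @pytest.mark.parametrize("k", [0, 1, 2, 4])
    def test_equals_oracle_on_random_guides(self, small_genome, indexed, cas9, k, rng):
        guides = sites_from_strings(
            ["".join(rng.choice(list("ACGT"), 20)) + "TGG" for _ in range(25)],
            cas9)
        # make some guides near-copies of genomic sites so hits exist
        genomic = list(discover_targets(small_genome, cas9))[:25]
        guides += [sites_from_strings([g.protospacer + g.pam], cas9)[0]
                   for g in genomic[:10]]
        got = search(indexed, guides, k=k)
        expect = brute_force_search(small_genome, guides, k, cas9)
        assert_results_equal(got, expect)

    def test_monotone_hit_growth_in_k(self, small_genome, indexed, cas9):
        guide = sites_from_strings(
            [list(discover_targets(small_genome, cas9))[3].protospacer + "AGG"],
            cas9)
        prev = set()
        for k in range(5):
            (res,) = search(indexed, guide, k=k)
            cur = {(h.sequence) for h in res.hits}
            assert prev <= cur
            assert all(h.mismatches <= k for h in res.hits)
            prev = cur

    def test_empty_guide_list(self, indexed):
        assert search(indexed, [], k=3) == []

    def test_enzyme_mismatch_is_hard_error(self, indexed, cpf1):
        guides = sites_from_strings(["TTTA" + "A" * 20], cpf1)
        with pytest.raises(ValueError, match="does not match database enzyme"):
            search(indexed, guides, k=1, enzyme=cpf1)


class TestPlantedRecovery:
    def test_exact_recovery_of_planted_distances(self, tmp_path, cas9):
        genome = synth_genome(seed=31, length=60_000, n_contigs=2)
        guide = sites_from_strings(["ACCTGACGGATTACTGCAAGCGG"], cas9)[0]
        spec = [(1, 5), (2, 4), (3, 5), (4, 4), (5, 5)]
        genome, truth = plant_offtargets(genome, guide, cas9, spec, seed=13)
        path = tmp_path / "plant.db"
        build_database(genome, cas9, path)
        with TargetDatabase(path) as db:
            (res,) = search(db, [guide], k=4)
        assert not res.overflow
        hit_positions = {pos: h.mismatches
                         for h in res.hits for pos in h.positions}
        for rec in truth:
            if rec.d <= 4:
                assert hit_positions[(rec.contig, rec.pos, rec.strand)] == rec.d
            else:
                assert (rec.contig, rec.pos, rec.strand) not in hit_positions
        # and the whole result agrees with the oracle, background included
        (expect,) = brute_force_search(genome, [guide], 4, cas9)
        assert_results_equal([res], [expect])


class TestTraversalEquivalence:
    @pytest.mark.parametrize("k", [0, 2, 5])
    def test_forced_modes_agree(self, small_genome, indexed, cas9, k, rng):
        guides = sites_from_strings(
            ["".join(rng.choice(list("ACGT"), 20)) + "CGG" for _ in range(10)],
            cas9)
        lin = search(indexed, guides, k=k, mode=MODE_LINEAR)
        sel = search(indexed, guides, k=k, mode=MODE_SELECTIVE)
        assert_results_equal(lin, sel)

    def test_auto_goes_linear_when_k_reaches_prefix_len(self, tmp_path, cas9, small_genome):
        path = tmp_path / "p5.db"
        build_database(small_genome, cas9, path, prefix_len=5)
        with TargetDatabase(path) as db:
            guides = sites_from_strings(["ACGTACGTACGTACGTACGTAGG"], cas9)
            stats = {}
            search(db, guides, k=5, stats=stats)
            assert stats["mode"] == MODE_LINEAR
            stats = {}
            search(db, guides, k=0, stats=stats)
            assert stats["mode"] == MODE_SELECTIVE


@pytest.fixture(scope="module")
def repeat_db(tmp_path_factory, cas9):
    """Genome carrying ~2500 copies of one site (tandem with spacers)."""
    site = "GATTACAGATTACAGATTACAGGG"[:23]  # 20-mer + GGG PAM
    rng = np.random.default_rng(5)
    blocks = []
    for _ in range(2500):
        blocks.append(site)
        blocks.append("".join(rng.choice(list("ACGT"), 9)))
    genome = {"rep": "".join(blocks)}
    path = tmp_path_factory.mktemp("ovf") / "rep.db"
    build_database(genome, cas9, path)
    return genome, site, TargetDatabase(path)


class TestOverflow:
    def test_default_limit_flags_overflow(self, repeat_db, cas9):
        genome, site, db = repeat_db
        guides = sites_from_strings([site], cas9)
        (res,) = search(db, guides, k=0)  # default limit 2000
        assert res.overflow

    def test_high_limit_does_not_overflow_and_counts_occurrences(self, repeat_db, cas9):
        genome, site, db = repeat_db
        guides = sites_from_strings([site], cas9)
        (res,) = search(db, guides, k=0, limit=10_000)
        assert not res.overflow
        assert sum(h.occurrences for h in res.hits) >= 2500

    def test_overflow_agrees_with_oracle(self, repeat_db, cas9):
        genome, site, db = repeat_db
        guides = sites_from_strings([site], cas9)
        for limit in (2000, 10_000):
            got = search(db, guides, k=1, limit=limit)
            expect = brute_force_search(genome, guides, 1, cas9, limit=limit)
            assert_results_equal(got, expect)
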