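"""Hsu/CFD specificity scores, design flags, self-hit policy, reciprocal."""

import csv
from importlib import resources as importlib_resources
from itertools import combinations

import numpy as np
import pytest

from guidescout.discovery import TargetSite
from guidescout.scoring import (
    CfdTable, cfd_max, cfd_score, flag_basic, hsu_aggregate, hsu_single,
    load_cfd_table, load_hsu_weights, reciprocal_offtargets, remove_self_hit,
)
from guidescout.search import OffTargetHit, SearchResult


@pytest.fixture(scope="module")
def weights():
    return load_hsu_weights()


@pytest.fixture(scope="module")
def cfd_table():
    return load_cfd_table()


def mutate(proto: str, positions: dict[int, str]) -> str:
    out = list(proto)
    for pos1, base in positions.items():  # 1-based, PAM-distal first
        out[pos1 - 1] = base
    return "".join(out)


GUIDE = "ACGTACGTACGTACGTACGT"


def closed_form_hsu(weights, positions):
    """Independent closed-form evaluation scripted from the formula."""
    m = len(positions)
    if m == 0:
        return 100.0
    prod = 1.0
    for p in positions:
        prod *= 1 - weights[p - 1]
    if m == 1:
        return 100.0 * prod
    pairs = list(combinations(positions, 2))
    mean_d = sum(abs(a - b) for a, b in pairs) / len(pairs)
    return 100.0 * prod / ((((19 - mean_d) / 19) * 4) + 1) / m**2


class TestHsuSingle:
    def test_zero_mismatches_scores_100(self, weights):
        assert hsu_single(GUIDE, GUIDE, weights) == 100.0

    def test_single_mismatch_at_zero_weight_position(self, weights):
        # position 1 carries weight 0 in the bundled table: the penalty
        # product is 1 and the distance/count damping is unity for m = 1
        assert weights[0] == 0.0
        off = mutate(GUIDE, {1: "T"})
        assert hsu_single(GUIDE, off, weights) == pytest.approx(100.0)

    @pytest.mark.parametrize("positions", [
        (5,), (20,), (3, 17), (1, 2), (6, 11, 19), (2, 7, 9, 14, 18),
    ])
    def test_matches_scripted_closed_form(self, weights, positions):
        subs = {p: ("T" if GUIDE[p - 1] != "T" else "G") for p in positions}
        off = mutate(GUIDE, subs)
        assert hsu_single(GUIDE, off, weights) == pytest.approx(
            closed_form_hsu(weights, list(positions)))

    def test_non_increasing_when_adding_a_mismatch(self, weights, rng):
        for _ in range(500):
            n = int(rng.integers(1, 5))
            pos = sorted(rng.choice(np.arange(1, 21), size=n, replace=False))
            extra = int(rng.choice([p for p in range(1, 21) if p not in pos]))
            base = closed_form_hsu(weights, list(pos))
            more = closed_form_hsu(weights, sorted(list(pos) + [extra]))
            assert more <= base + 1e-12

    def test_non_20mer_returns_no_score(self, weights):
        assert hsu_single(GUIDE[:18], GUIDE[:18], weights) is None

    def test_bounds(self, weights, rng):
        for _ in range(300):
            off = "".join(rng.choice(list("ACGT"), 20))
            s = hsu_single(GUIDE, off, weights)
            assert 0.0 < s <= 100.0


class TestHsuAggregate:
    def hit(self, proto, occ=1):
        return OffTargetHit(proto + "AGG", sum(a != b for a, b in zip(proto, GUIDE)),
                            occ, [])

    def test_no_offtargets_scores_100(self, weights, cas9):
        assert hsu_aggregate(GUIDE, [], weights, cas9) == 100.0

    def test_single_perfect_offtarget_scores_50(self, weights, cas9):
        assert hsu_aggregate(GUIDE, [self.hit(GUIDE)], weights, cas9) == \
            pytest.approx(50.0)

    def test_occurrences_each_count(self, weights, cas9):
        one = hsu_aggregate(GUIDE, [self.hit(GUIDE, occ=1)], weights, cas9)
        three = hsu_aggregate(GUIDE, [self.hit(GUIDE, occ=3)], weights, cas9)
        assert three == pytest.approx(100.0 * 100.0 / (100.0 + 300.0))
        assert three < one

    def test_adding_any_hit_strictly_decreases(self, weights, cas9, rng):
        hits = []
        prev = 100.0
        for _ in range(10):
            off = mutate(GUIDE, {int(rng.integers(1, 21)): "G"})
            if off == GUIDE:
                continue
            hits.append(self.hit(off))
            cur = hsu_aggregate(GUIDE, hits, weights, cas9)
            assert cur < prev
            prev = cur

    def test_hit_order_invariance(self, weights, cas9, rng):
        hits = [self.hit(mutate(GUIDE, {p: "C"})) for p in (2, 9, 15)
                if mutate(GUIDE, {p: "C"}) != GUIDE]
        fwd = hsu_aggregate(GUIDE, hits, weights, cas9)
        rev = hsu_aggregate(GUIDE, hits[::-1], weights, cas9)
        assert fwd == pytest.approx(rev)

    def test_cpf1_guides_get_no_score(self, weights, cpf1):
        assert hsu_aggregate("A" * 20, [], weights, cpf1) is None


def cfd_file_oracle(guide, off_proto, off_pam):
    """Recompute CFD straight from the resource TSVs with csv readers."""
    res = importlib_resources.files("guidescout.resources")
    rna = {"A": "A", "C": "C", "G": "G", "T": "U"}
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    mm = {}
    with importlib_resources.as_file(
            res.joinpath("cfd_mismatch_penalties_synthetic.tsv")) as p:
        for row in csv.DictReader(
                (l for l in open(p) if not l.startswith("#")), delimiter="\t"):
            mm[(int(row["position"]), row["guide_rna"], row["dna"])] = \
                float(row["penalty"])
    pam = {}
    with importlib_resources.as_file(res.joinpath("cfd_pam_penalties.tsv")) as p:
        for row in csv.DictReader(
                (l for l in open(p) if not l.startswith("#")), delimiter="\t"):
            pam[row["pam_tail"]] = float(row["penalty"])
    score = pam[off_pam[1:]]
    for i, (g, o) in enumerate(zip(guide, off_proto), start=1):
        if g != o:
            score *= mm[(i, rna[g], comp[o])]
    return score


class TestCfd:
    def test_identical_with_canonical_pam_is_one(self, cfd_table):
        assert cfd_score(GUIDE, GUIDE, "AGG", cfd_table) == 1.0
        assert cfd_score(GUIDE, GUIDE, "TGG", cfd_table) == 1.0

    def test_single_mismatch_is_one_table_entry_times_pam(self, cfd_table):
        off = mutate(GUIDE, {7: "A"})  # guide G -> off A at position 7
        expected = cfd_table.penalty[(7, "G", "T")] * cfd_table.pam_penalty["GG"]
        assert cfd_score(GUIDE, off, "AGG", cfd_table) == pytest.approx(expected)

    def test_nag_pam_applies_alternative_penalty(self, cfd_table):
        got = cfd_score(GUIDE, GUIDE, "TAG", cfd_table)
        assert got == pytest.approx(cfd_table.pam_penalty["AG"])

    def test_random_hits_match_file_level_oracle(self, cfd_table, rng):
        for _ in range(50):
            off = "".join(rng.choice(list("ACGT"), 20))
            pam = rng.choice(list("ACGT")) + "GG"
            got = cfd_score(GUIDE, off, pam, cfd_table)
            assert got == pytest.approx(cfd_file_oracle(GUIDE, off, pam))
            assert 0.0 <= got <= 1.0

    def test_unknown_pam_tail_penalised_to_zero(self, cfd_table, caplog):
        table = CfdTable(penalty=cfd_table.penalty,
                         pam_penalty={"GG": 1.0})
        assert cfd_score(GUIDE, GUIDE, "AAG", table) == 0.0

    def test_cfd_max_is_worst_hit_and_zero_when_empty(self, cfd_table, cas9):
        assert cfd_max(GUIDE, [], cfd_table, cas9) == 0.0
        hits = [
            OffTargetHit(mutate(GUIDE, {3: "C", 9: "A"}) + "AGG", 2, 1, []),
            OffTargetHit(GUIDE + "CGG", 0, 1, []),
        ]
        assert cfd_max(GUIDE, hits, cfd_table, cas9) == pytest.approx(1.0)
        assert cfd_max(GUIDE, hits[::-1], cfd_table, cas9) == pytest.approx(1.0)

    def test_cpf1_guides_get_no_score(self, cfd_table, cpf1):
        assert cfd_max("A" * 20, [], cfd_table, cpf1) is None


class TestFlags:
    @pytest.mark.parametrize("proto,expect", [
        ("G" * 20, {"gc_high": True, "gc_low": False, "polyT": False}),
        ("ATATATATATATATATATAT", {"gc_high": False, "gc_low": True, "polyT": False}),
        ("ACGTTTTACGTACGTACGTA", {"gc_high": False, "gc_low": False, "polyT": True}),
        ("ACGTACGTACGTACGTACGT", {"gc_high": False, "gc_low": False, "polyT": False}),
    ])
    def test_documented_flag_cases(self, proto, expect):
        assert flag_basic(proto) == expect

    def test_thresholds_are_strict(self):
        # exactly 75% / 25% GC raises no flag
        assert not flag_basic("G" * 15 + "A" * 5)["gc_high"]
        assert not flag_basic("G" * 5 + "A" * 15)["gc_low"]


def _site(contig, start, strand, proto=GUIDE, pam="AGG"):
    return TargetSite(contig, start, start + 23, strand, proto, pam)


class TestSelfHitRemoval:
    def test_coordinate_match_removes_one_occurrence(self, cas9):
        g = _site("chr1", 100, "+")
        hit = OffTargetHit(GUIDE + "AGG", 0, 2,
                           [("chr1", 100, "+"), ("chr2", 5, "-")])
        res = SearchResult(g, [hit])
        (kept,) = remove_self_hit(res, cas9)
        assert kept.occurrences == 1
        assert kept.positions == [("chr2", 5, "-")]

    def test_self_only_hit_disappears(self, cas9):
        g = _site("chr1", 100, "+")
        res = SearchResult(g, [OffTargetHit(GUIDE + "AGG", 0, 1,
                                            [("chr1", 100, "+")])])
        assert remove_self_hit(res, cas9) == []

    def test_sequence_fallback_without_positions(self, cas9):
        g = _site("q", 0, "+")
        res = SearchResult(g, [OffTargetHit(GUIDE + "AGG", 0, 3, [])])
        (kept,) = remove_self_hit(res, cas9)
        assert kept.occurrences == 2

    def test_non_self_hits_untouched(self, cas9):
        g = _site("chr1", 100, "+")
        other = OffTargetHit(mutate(GUIDE, {4: "C"}) + "AGG", 1, 1,
                             [("chr9", 7, "+")])
        res = SearchResult(g, [other])
        assert remove_self_hit(res, cas9) == [other]


class TestReciprocal:
    def test_hits_on_other_contig_do_not_flag(self, cas9):
        g = _site("chr1", 100, "+")
        res = SearchResult(g, [OffTargetHit(GUIDE + "AGG", 0, 1,
                                            [("chr2", 150, "+")])])
        assert reciprocal_offtargets([res], {"chr1": [(0, 1000)]}, cas9) == [False]

    def test_two_near_identical_sites_in_one_region_both_flag(self, cas9):
        a = SearchResult(_site("chr1", 100, "+"),
                         [OffTargetHit(GUIDE + "AGG", 1, 1, [("chr1", 400, "-")])])
        b = SearchResult(_site("chr1", 400, "-"),
                         [OffTargetHit(GUIDE + "AGG", 1, 1, [("chr1", 100, "+")])])
        region = {"chr1": [(0, 1000)]}
        assert reciprocal_offtargets([a, b], region, cas9) == [True, True]

    def test_own_site_never_counts(self, cas9):
        g = _site("chr1", 100, "+")
        res = SearchResult(g, [OffTargetHit(GUIDE + "AGG", 0, 1,
                                            [("chr1", 100, "+")])])
        assert reciprocal_offtargets([res], {"chr1": [(0, 1000)]}, cas9) == [False]

    def test_empty_region_set_all_false(self, cas9):
        g = _site("chr1", 100, "+")
        res = SearchResult(g, [OffTargetHit(GUIDE + "AGG", 0, 1,
                                            [("chr1", 900, "+")])])
        assert reciprocal_offtargets([res], {}, cas9) == [False]
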