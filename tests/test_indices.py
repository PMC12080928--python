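"""AAI, POCP, OrthoANI and the species-delineation rule."""

import itertools

import numpy as np
import pytest

from taxoforce import (
    GenomeRecord,
    compute_aai,
    compute_pocp,
    orthoani,
    reciprocal_best_hits,
    species_call,
)
from taxoforce.indices import (
    AAI_DEFAULT_FILTERS,
    HitFilters,
    RBHPair,
    exact_align_hits,
    fragment_genome,
)
from taxoforce.io import HitRecord
from taxoforce.simulate import simulate_proteome_pair


def _hit(q, s, pident=90.0, bitscore=100.0, evalue=1e-30, length=100):
    return HitRecord(q, s, pident, length, 0, 0, 1, length, 1, length, evalue, bitscore)


class TestReciprocalBestHits:
    def test_symmetric_one_protein_pair(self):
        pairs = reciprocal_best_hits([_hit("p", "q", 90.0)], [_hit("q", "p", 90.0)])
        assert [(p.protein_a, p.protein_b, p.pident) for p in pairs] == [("p", "q", 90.0)]

    def test_non_reciprocal_pair_excluded(self):
        # p's best is q, but q's best is r
        hits_ab = [_hit("p", "q", 90.0, bitscore=100)]
        hits_ba = [_hit("q", "r", 95.0, bitscore=200), _hit("q", "p", 90.0, bitscore=100)]
        assert reciprocal_best_hits(hits_ab, hits_ba) == []

    def test_matches_brute_force_over_crossing_bitscores(self):
        """Exhaustive best-hit oracle on a 3×3 protein toy with crossing scores."""
        rng = np.random.default_rng(7)
        a_prots = ["a1", "a2", "a3"]
        b_prots = ["b1", "b2", "b3"]
        hits_ab = [
            _hit(a, b, pident=float(rng.uniform(40, 99)), bitscore=float(rng.integers(50, 300)))
            for a, b in itertools.product(a_prots, b_prots)
        ]
        hits_ba = [
            _hit(b, a, pident=float(rng.uniform(40, 99)), bitscore=float(rng.integers(50, 300)))
            for b, a in itertools.product(b_prots, a_prots)
        ]

        def best(hits, query):  # independent: sort-based, not dict-based
            mine = [h for h in hits if h.query_id == query]
            return sorted(mine, key=lambda h: (-h.bitscore, h.evalue, h.subject_id))[0]

        expected = set()
        for a in a_prots:
            b = best(hits_ab, a).subject_id
            if best(hits_ba, b).subject_id == a:
                expected.add((a, b))
        got = {
            (p.protein_a, p.protein_b)
            for p in reciprocal_best_hits(hits_ab, hits_ba)
        }
        assert got == expected

    def test_coverage_filter_uses_query_lengths(self):
        # alignment covers 50 of 100 residues: fails 0.7, passes 0.3
        h_ab = HitRecord("p", "q", 90.0, 50, 5, 0, 1, 50, 1, 50, 1e-30, 100.0)
        h_ba = HitRecord("q", "p", 90.0, 50, 5, 0, 1, 50, 1, 50, 1e-30, 100.0)
        lengths = {"p": 100}, {"q": 100}
        assert (
            reciprocal_best_hits([h_ab], [h_ba], AAI_DEFAULT_FILTERS, *lengths) == []
        )
        loose = HitFilters(min_pident=30, min_cov=0.3, max_evalue=1e-3)
        assert len(reciprocal_best_hits([h_ab], [h_ba], loose, *lengths)) == 1

    def test_empty_filtered_list_is_empty_result(self):
        weak = [_hit("p", "q", pident=10.0)]
        assert reciprocal_best_hits(weak, weak) == []


class TestAAI:
    def test_mean_of_pidents(self):
        pairs = [RBHPair("a", "b", p) for p in (70.0, 80.0, 90.0)]
        res = compute_aai(pairs)
        assert res.value == pytest.approx(80.0)
        assert res.support["n"] == 3
        assert res.sd == pytest.approx(10.0)

    def test_single_pair_has_no_sd(self):
        res = compute_aai([RBHPair("a", "b", 55.5)])
        assert res.value == pytest.approx(55.5)
        assert res.sd is None

    def test_no_orthologs_flagged(self):
        res = compute_aai([])
        assert res.value is None
        assert res.flag == "no_orthologs"

    def test_identical_proteomes_give_100(self):
        a, b, hits_ab, hits_ba = simulate_proteome_pair(100.0, n_proteins=10, seed=1)
        pairs = reciprocal_best_hits(hits_ab, hits_ba)
        assert compute_aai(pairs).value == pytest.approx(100.0)

    def test_monotone_under_increasing_divergence(self):
        values = []
        for target in (100.0, 95.0, 85.0, 70.0):
            _, _, ab, ba = simulate_proteome_pair(target, n_proteins=30, seed=4)
            values.append(compute_aai(reciprocal_best_hits(ab, ba)).value)
        assert values == sorted(values, reverse=True)


class TestPOCP:
    def test_closed_formula(self):
        # C1=2 of t1=4 qualify, C2=3 of t2=6 qualify → 100·5/10 = 50
        hits_ab = [_hit(f"a{i}", "b1", evalue=1e-10) for i in range(2)]
        hits_ba = [_hit(f"b{i}", "a1", evalue=1e-10) for i in range(3)]
        res = compute_pocp(hits_ab, hits_ba, t1=4, t2=6)
        assert res.value == pytest.approx(50.0)
        assert res.support == {"C1": 2, "C2": 3, "T1": 4, "T2": 6}

    def test_identical_proteomes_give_100_and_no_hits_give_0(self):
        _, _, ab, ba = simulate_proteome_pair(100.0, n_proteins=8, seed=2)
        assert compute_pocp(ab, ba, 8, 8).value == pytest.approx(100.0)
        assert compute_pocp([], [], 8, 8).value == pytest.approx(0.0)

    def test_empty_proteomes_error(self):
        with pytest.raises(ValueError):
            compute_pocp([], [], 0, 0)

    def test_relaxing_evalue_never_decreases_pocp(self):
        rng = np.random.default_rng(11)
        hits_ab = [
            _hit(f"a{i}", f"b{i}", pident=60.0, evalue=float(10.0 ** -rng.integers(3, 30)))
            for i in range(20)
        ]
        hits_ba = [
            _hit(f"b{i}", f"a{i}", pident=60.0, evalue=float(10.0 ** -rng.integers(3, 30)))
            for i in range(20)
        ]
        values = []
        for max_e in (1e-20, 1e-10, 1e-5, 1e-3):
            f = HitFilters(min_pident=50, min_cov=0.5, max_evalue=max_e)
            values.append(compute_pocp(hits_ab, hits_ba, 20, 20, f).value)
        assert values == sorted(values)


class TestOrthoANI:
    def test_genome_vs_itself_is_100(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=2100))
        g = GenomeRecord("g", [seq])
        res = orthoani(g, g)
        assert res.value == pytest.approx(100.0)

    def test_two_fragment_toy_is_95(self):
        """One identical 1020-bp fragment plus one at 90% identity → mean 95."""
        rng = np.random.default_rng(5)
        frag1 = rng.choice(list("ACGT"), size=1020)
        frag2 = rng.choice(list("ACGT"), size=1020)
        mutated = frag2.copy()
        pos = rng.choice(1020, size=102, replace=False)
        other = {"A": "C", "C": "G", "G": "T", "T": "A"}
        for p in pos:
            mutated[p] = other[mutated[p]]
        ga = GenomeRecord("ga", ["".join(frag1) + "".join(frag2)])
        gb = GenomeRecord("gb", ["".join(frag1) + "".join(mutated)])
        res = orthoani(ga, gb)
        assert res.value == pytest.approx(95.0)
        assert res.support["n_pairs"] == 2
        # exhaustive pairing oracle: all 2×2 alignments, best per fragment
        hits = exact_align_hits(fragment_genome(ga), fragment_genome(gb), min_pident=0)
        by_query = {}
        for h in hits:
            if h.query_id not in by_query or h.pident > by_query[h.query_id].pident:
                by_query[h.query_id] = h
        assert sorted(h.pident for h in by_query.values()) == [90.0, 100.0]

    def test_substitution_rate_recovered(self):
        """ANI tracks 100·(1−s) within ±1 for s ≤ 0.1 with the exact backend."""
        rng = np.random.default_rng(9)
        base = rng.choice(list("ACGT"), size=4 * 1020)
        other = {"A": "C", "C": "G", "G": "T", "T": "A"}
        for s in (0.02, 0.05, 0.1):
            mutated = base.copy()
            pos = rng.random(base.size) < s
            for p in np.flatnonzero(pos):
                mutated[p] = other[mutated[p]]
            res = orthoani(
                GenomeRecord("a", ["".join(base)]), GenomeRecord("b", ["".join(mutated)])
            )
            assert res.value == pytest.approx(100 * (1 - s), abs=1.0)

    def test_too_short_genome_flagged(self):
        res = orthoani(GenomeRecord("a", ["ACGT" * 10]), GenomeRecord("b", ["ACGT" * 10]))
        assert res.value is None
        assert res.flag == "below_detection"


class TestSpeciesCall:
    @pytest.mark.parametrize(
        "ani,ddh,verdict",
        [
            (100.0, 80.0, "same_species"),
            (71.31, None, "different_species"),
            (95.5, None, "ambiguous"),
            (97.0, None, "same_species"),
            (97.0, 60.0, "ambiguous"),  # indices conflict
            (90.0, 75.0, "ambiguous"),  # indices conflict
            (90.0, 30.0, "different_species"),
        ],
    )
    def test_rule_table(self, ani, ddh, verdict):
        assert species_call(ani, ddh).verdict == verdict

    def test_out_of_range_ani_rejected(self):
        with pytest.raises(ValueError):
            species_call(104.0)


class TestIndexInvariants:
    def test_all_indices_symmetric_and_bounded(self):
        a, b, ab, ba = simulate_proteome_pair(85.0, n_proteins=20, seed=3)
        aai_fwd = compute_aai(reciprocal_best_hits(ab, ba)).value
        aai_rev = compute_aai(reciprocal_best_hits(ba, ab)).value
        assert aai_fwd == pytest.approx(aai_rev)
        pocp_fwd = compute_pocp(ab, ba, a.protein_count, b.protein_count).value
        pocp_rev = compute_pocp(ba, ab, b.protein_count, a.protein_count).value
        assert pocp_fwd == pytest.approx(pocp_rev)
        for v in (aai_fwd, pocp_fwd):
            assert 0 <= v <= 100
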