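"""Homology predicate thresholds and the seed/profile search machinery."""

import numpy as np
import pytest

from rebscan.homology import (
    HomologyEdge,
    SearchHit,
    build_profile,
    is_homologous,
    iterate_profile_search,
    search_with_seeds,
)
from rebscan.simulate import mutate_sequence, random_protein

from conftest import make_record


class TestPredicate:
    def test_identical_sequences_pass_any_thresholds(self, rng):
        seq = random_protein(50, rng)
        a, b = make_record("a", seq), make_record("b", seq)
        for sim, lth in ((40.0, 0.20), (99.0, 0.01), (100.0, 1.0)):
            ok, edge = is_homologous(a, b, sim, lth)
            assert ok and edge is not None
            assert edge.percent_similarity == 100.0
            assert edge.length_diff_fraction == 0.0

    def test_length_boundary_is_strict(self, rng):
        # 100 vs 80: |100-80|/100 = 0.20 which is NOT < 0.20
        seq = random_protein(100, rng)
        a = make_record("a", seq)
        b = make_record("b", seq[:80])
        ok, edge = is_homologous(a, b, sim_threshold=1.0, len_threshold=0.20)
        assert not ok and edge is None

    def test_length_100_vs_81_with_similar_sequences_passes(self, rng):
        # 19/100 = 0.19 < 0.20; a lightly diverged truncation stays well
        # above 40% similarity
        seq = random_protein(100, rng)
        a = make_record("a", seq)
        b = make_record("b", mutate_sequence(seq, 0.1, rng)[:81])
        ok, edge = is_homologous(a, b, sim_threshold=40.0, len_threshold=0.20)
        assert ok
        assert edge.length_diff_fraction == pytest.approx(0.19)
        assert edge.percent_similarity >= 40.0

    def test_symmetric(self, rng):
        for _ in range(6):
            base = random_protein(60, rng)
            a = make_record("a", base)
            b = make_record("b", mutate_sequence(base, 0.35, rng))
            assert (is_homologous(a, b, 40.0, 0.20)[0]
                    == is_homologous(b, a, 40.0, 0.20)[0])

    def test_unrelated_pairs_are_rejected(self, rng):
        # the chance gate (and the <=0 score rule) keeps random pairs out
        calls = [
            is_homologous(make_record("a", random_protein(80, rng)),
                          make_record("b", random_protein(80, rng)),
                          40.0, 0.20)[0]
            for _ in range(25)
        ]
        assert not any(calls)

    def test_threshold_validation(self, rng):
        a = make_record("a", random_protein(10, rng))
        with pytest.raises(ValueError):
            is_homologous(a, a, sim_threshold=0.0)
        with pytest.raises(ValueError):
            is_homologous(a, a, len_threshold=1.5)

    def test_edge_pair_is_unordered(self):
        edge = HomologyEdge(("z", "a"), 50.0, 40.0, 0.1)
        assert edge.pair == ("a", "z")


class TestSeedSearch:
    def test_seed_finds_itself(self, rng):
        seq = random_protein(60, rng)
        seed = make_record("seed0", seq)
        db = [make_record("self0", seq)] + [
            make_record(f"n{i:02d}", random_protein(60, rng)) for i in range(15)
        ]
        hits = search_with_seeds([seed], db, e_cutoff=1e-3, n_shuffles=30,
                                 rng_seed=0)
        assert "self0" in {h.subject_id for h in hits}

    def test_pure_shuffle_database_yields_nothing(self, rng):
        # subjects that are shuffles of the seed share its composition but
        # none of its order: nothing should reach e <= 1e-3
        seq = random_protein(60, rng)
        seed = make_record("seed0", seq)
        residues = list(seq)
        db = []
        for i in range(20):
            rng.shuffle(residues)
            db.append(make_record(f"shuf{i:02d}", "".join(residues)))
        hits = search_with_seeds([seed], db, e_cutoff=1e-3, n_shuffles=40,
                                 rng_seed=1)
        assert hits == []

    def test_planted_homolog_recall_is_complete(self, rng):
        ancestor = random_protein(95, rng)
        seed = make_record("seed0", mutate_sequence(ancestor, 0.05, rng))
        planted = [
            make_record(f"reb{i:02d}", mutate_sequence(ancestor, 0.2, rng))
            for i in range(8)
        ]
        noise = [
            make_record(f"bg{i:03d}",
                        random_protein(int(rng.integers(60, 300)), rng))
            for i in range(50)
        ]
        hits = search_with_seeds([seed], planted + noise, e_cutoff=1e-3,
                                 n_shuffles=30, rng_seed=2)
        found = {h.subject_id for h in hits}
        assert found == {r.protein_id for r in planted}

    def test_best_seed_tie_break_is_lexicographic(self, rng):
        seq = random_protein(50, rng)
        seeds = [make_record("seedB", seq), make_record("seedA", seq)]
        db = [make_record("subj0", seq)]
        hits = search_with_seeds(seeds, db, e_cutoff=1.0, n_shuffles=20,
                                 rng_seed=0)
        assert hits[0].query_seed_id == "seedA"

    def test_invalid_cutoff(self, rng):
        seed = make_record("s", random_protein(20, rng))
        with pytest.raises(ValueError):
            search_with_seeds([seed], [seed], e_cutoff=0.0)

    def test_hits_are_deterministic_under_seed(self, rng):
        ancestor = random_protein(80, rng)
        seed = make_record("seed0", ancestor)
        db = [make_record(f"p{i}", mutate_sequence(ancestor, 0.25, rng))
              for i in range(5)]
        h1 = search_with_seeds([seed], db, n_shuffles=20, rng_seed=7)
        h2 = search_with_seeds([seed], db, n_shuffles=20, rng_seed=7)
        assert h1 == h2


@pytest.fixture(scope="module")
def chain():
    """Two-step divergence chain: seed -> intermediates -> far homolog.

    The far sequence sits two 0.5-divergence steps from the seed — beyond
    direct pairwise reach at e <= 1e-3 — but only ~0.5 from the
    intermediates the profile is built on.
    """
    rng = np.random.default_rng(3)
    length = 60
    seed_seq = random_protein(length, rng)
    mbase = mutate_sequence(seed_seq, 0.5, rng)
    mids = [make_record(f"mid{i:02d}", mutate_sequence(mbase, 0.08, rng),
                        index=i) for i in range(4)]
    far = make_record("far00", mutate_sequence(mbase, 0.5, rng), index=4)
    noise = [make_record(f"noise{i:02d}", random_protein(length, rng),
                         index=5 + i) for i in range(40)]
    db = mids + [far] + noise
    seed = make_record("seedA0", seed_seq, index=99)
    return seed, db


class TestProfileSearch:

    def test_direct_search_misses_far_homolog(self, chain):
        seed, db = chain
        hits = search_with_seeds([seed], db, e_cutoff=1e-3, n_shuffles=40,
                                 rng_seed=3)
        ids = {h.subject_id for h in hits}
        assert {f"mid{i:02d}" for i in range(4)} <= ids
        assert "far00" not in ids

    def test_profile_iteration_recovers_far_homolog_only(self, chain):
        seed, db = chain
        direct = search_with_seeds([seed], db, e_cutoff=1e-3, n_shuffles=40,
                                   rng_seed=3)
        final, profile = iterate_profile_search(
            direct, db, max_iters=4, inclusion_e=1e-3, n_shuffles=40,
            rng_seed=3,
        )
        final_ids = {h.subject_id for h in final}
        assert "far00" in final_ids
        assert not any(i.startswith("noise") for i in final_ids)
        assert profile is not None and len(profile) > 0

    def test_zero_iterations_is_identity(self, chain):
        seed, db = chain
        direct = search_with_seeds([seed], db, e_cutoff=1e-3, n_shuffles=40,
                                   rng_seed=3)
        same, profile = iterate_profile_search(direct, db, max_iters=0)
        assert {h.subject_id for h in same} == {h.subject_id for h in direct}
        assert profile is None

    def test_monotone_hit_set(self, chain):
        seed, db = chain
        direct = search_with_seeds([seed], db, e_cutoff=1e-3, n_shuffles=40,
                                   rng_seed=3)
        final, _ = iterate_profile_search(direct, db, max_iters=4,
                                          inclusion_e=1e-3, n_shuffles=40,
                                          rng_seed=3)
        assert {h.subject_id for h in direct} <= {h.subject_id for h in final}

    def test_fixpoint_when_nothing_to_add(self, rng):
        # all homologs already found: one extra pass converges, adds nothing
        ancestor = random_protein(70, rng)
        members = [make_record(f"m{i}", mutate_sequence(ancestor, 0.15, rng),
                               index=i) for i in range(5)]
        noise = [make_record(f"x{i}", random_protein(70, rng), index=10 + i)
                 for i in range(20)]
        db = members + noise
        initial = [
            SearchHit(query_seed_id="m0", subject_id=m.protein_id,
                      raw_score=100.0 + i, empirical_p=0.0, evalue=0.0)
            for i, m in enumerate(members)
        ]
        final, _ = iterate_profile_search(initial, db, max_iters=3,
                                          inclusion_e=1e-3, n_shuffles=30,
                                          rng_seed=5)
        assert {h.subject_id for h in final} == {m.protein_id for m in members}

    def test_empty_initial_hits_raise(self, chain):
        _, db = chain
        with pytest.raises(ValueError):
            iterate_profile_search([], db)

    def test_profile_needs_members(self, rng):
        master = make_record("m", random_protein(30, rng))
        with pytest.raises(ValueError):
            build_profile(master, [])


def test_searchhit_validates_probability():
    with pytest.raises(ValueError):
        SearchHit("s", "x", 1.0, empirical_p=1.5, evalue=0.0)
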