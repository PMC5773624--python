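"""Tanimoto screening, Euclidean distances and nearest-neighbor enrichment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ahrscreen.chemspace import ScoreMatrix
from ahrscreen.descriptors import FingerprintSet, N_FINGERPRINT_BITS
from ahrscreen.similarity import (
    euclidean_distance,
    fingerprint_screen,
    nearest_neighbor_screen,
    tanimoto,
    tanimoto_matrix,
)


def fp(*on_bits):
    v = np.zeros(N_FINGERPRINT_BITS, dtype=bool)
    v[list(on_bits)] = True
    return v


def fpset(ids, rows):
    return FingerprintSet(list(ids), np.stack(rows))


bitvec = st.lists(st.booleans(), min_size=N_FINGERPRINT_BITS,
                  max_size=N_FINGERPRINT_BITS).map(lambda v: np.array(v, dtype=bool))


class TestTanimoto:
    def test_identical_vectors_give_one(self):
        v = fp(*range(10))
        assert tanimoto(v, v) == 1.0

    def test_disjoint_vectors_give_zero(self):
        assert tanimoto(fp(0, 1, 2), fp(10, 11)) == 0.0

    def test_direct_substitution(self):
        a = fp(*range(8))          # n_A = 8
        b = fp(*range(4), 20, 21)  # n_B = 6, n_same = 4
        assert tanimoto(a, b) == pytest.approx(4 / 10)

    def test_all_zero_pair_rejected(self):
        z = np.zeros(N_FINGERPRINT_BITS, dtype=bool)
        with pytest.raises(ValueError):
            tanimoto(z, z)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tanimoto(fp(1), np.zeros(10, dtype=bool))

    @settings(derandomize=True, max_examples=50)
    @given(a=bitvec, b=bitvec)
    def test_matches_set_formula_oracle_and_is_symmetric(self, a, b):
        if not a.any() and not b.any():
            return
        sa, sb = set(np.flatnonzero(a)), set(np.flatnonzero(b))
        oracle = len(sa & sb) / len(sa | sb)
        assert tanimoto(a, b) == pytest.approx(oracle)
        assert tanimoto(b, a) == pytest.approx(tanimoto(a, b))

    def test_matrix_agrees_with_scalar(self, rng):
        bits = rng.random((6, N_FINGERPRINT_BITS)) < 0.2
        bits[:, 0] = True  # avoid all-zero rows
        fps = fpset([f"m{i}" for i in range(6)], list(bits))
        mat = tanimoto_matrix(fps, fps)
        for i in range(6):
            for j in range(6):
                assert mat[i, j] == pytest.approx(tanimoto(bits[i], bits[j]))


class TestFingerprintScreen:
    def test_cutoff_boundary_inclusive(self):
        ref = fpset(["r"], [fp(*range(10))])
        # 6 shared of 10 vs 6: TC = 6/10 = 0.60 exactly
        hit = fpset(["h"], [fp(*range(6))])
        hits, table = fingerprint_screen(ref, hit, tc_cutoff=0.60)
        assert hits == {"h"}
        assert table[0].reference_id == "r"
        assert table[0].value == pytest.approx(0.60)

    def test_just_below_cutoff_misses(self):
        ref = fpset(["r"], [fp(*range(17))])
        cand = fpset(["c"], [fp(*range(10))])  # 10/17 = 0.588
        hits, _ = fingerprint_screen(ref, cand)
        assert hits == set()

    def test_matches_all_pairs_oracle(self, rng):
        refs = fpset([f"r{i}" for i in range(5)],
                     list(rng.random((5, N_FINGERPRINT_BITS)) < 0.3))
        cands = fpset([f"c{i}" for i in range(40)],
                      list(rng.random((40, N_FINGERPRINT_BITS)) < 0.3))
        hits, _ = fingerprint_screen(refs, cands, tc_cutoff=0.35)
        oracle = {
            cid for j, cid in enumerate(cands.ids)
            if max(tanimoto(r, cands.bits[j]) for r in refs.bits) >= 0.35
        }
        assert hits == oracle

    def test_permutation_invariance(self, rng):
        bits = rng.random((30, N_FINGERPRINT_BITS)) < 0.3
        refs = fpset(["r0", "r1"], list(rng.random((2, N_FINGERPRINT_BITS)) < 0.3))
        ids = [f"c{i}" for i in range(30)]
        fwd, _ = fingerprint_screen(refs, fpset(ids, list(bits)), 0.3)
        rev, _ = fingerprint_screen(refs, fpset(ids[::-1], list(bits[::-1])), 0.3)
        assert fwd == rev

    def test_raising_cutoff_never_adds_hits(self, rng):
        refs = fpset(["r"], [rng.random(N_FINGERPRINT_BITS) < 0.4])
        cands = fpset([f"c{i}" for i in range(25)],
                      list(rng.random((25, N_FINGERPRINT_BITS)) < 0.4))
        loose, _ = fingerprint_screen(refs, cands, 0.3)
        strict, _ = fingerprint_screen(refs, cands, 0.5)
        assert strict <= loose

    def test_empty_reference_set_rejected(self):
        cands = fpset(["c"], [fp(1)])
        empty = FingerprintSet([], np.zeros((0, N_FINGERPRINT_BITS), dtype=bool))
        with pytest.raises(ValueError):
            fingerprint_screen(empty, cands)


class TestEuclidean:
    def test_identity(self):
        assert euclidean_distance(np.array([1.0, 2.0]), np.array([1.0, 2.0])) == 0.0

    def test_three_four_five(self):
        assert euclidean_distance(np.zeros(2), np.array([3.0, 4.0])) == 5.0

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            euclidean_distance(np.zeros(2), np.zeros(3))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-50, 50), min_size=5, max_size=5),
           st.lists(st.floats(-50, 50), min_size=5, max_size=5),
           st.lists(st.floats(-50, 50), min_size=5, max_size=5))
    def test_metric_axioms_and_elementwise_oracle(self, p, q, r):
        p, q, r = map(np.asarray, (p, q, r))
        oracle = float(np.sqrt(sum((qi - pi) ** 2 for pi, qi in zip(p, q))))
        assert euclidean_distance(p, q) == pytest.approx(oracle, abs=1e-12)
        assert euclidean_distance(p, q) == euclidean_distance(q, p)
        assert euclidean_distance(p, r) <= \
            euclidean_distance(p, q) + euclidean_distance(q, r) + 1e-9


class TestNearestNeighborScreen:
    def scores(self, ids, arr, tag=1):
        return ScoreMatrix(list(ids), np.asarray(arr, dtype=float), model_tag=tag)

    def test_capacity_caps_at_ten_nearest(self):
        ref = self.scores(["r"], [[0.0, 0.0]])
        cands = self.scores([f"c{i:02d}" for i in range(12)],
                            [[0.1 * (i + 1), 0.0] for i in range(12)])
        hits, lists = nearest_neighbor_screen(ref, cands, ed_cutoff=5.0)
        assert len(lists[0].neighbors) == 10
        assert hits == {f"c{i:02d}" for i in range(10)}
        eds = [ed for _, ed in lists[0].neighbors]
        assert eds == sorted(eds)

    def test_no_candidate_within_cutoff(self):
        ref = self.scores(["r"], [[0.0, 0.0]])
        cands = self.scores(["c"], [[100.0, 0.0]])
        hits, lists = nearest_neighbor_screen(ref, cands)
        assert hits == set() and lists[0].neighbors == []

    def test_ties_at_capacity_resolved_lexicographically(self):
        ref = self.scores(["r"], [[0.0]])
        ids = [f"c{i}" for i in range(9)] + ["tie_b", "tie_a"]
        pos = [[0.1 * (i + 1)] for i in range(9)] + [[2.0], [2.0]]
        hits, lists = nearest_neighbor_screen(ref, self.scores(ids, pos),
                                              ed_cutoff=5.0)
        kept = [cid for cid, _ in lists[0].neighbors]
        assert kept[-1] == "tie_a" and "tie_b" not in kept

    def test_permutation_invariance_and_brute_force_oracle(self, rng):
        refs = self.scores(["r0", "r1"], rng.normal(size=(2, 3)))
        ids = [f"c{i:02d}" for i in range(30)]
        pos = rng.normal(size=(30, 3)) * 2
        hits, lists = nearest_neighbor_screen(refs, self.scores(ids, pos),
                                              ed_cutoff=3.0)
        perm = rng.permutation(30)
        hits_p, _ = nearest_neighbor_screen(
            refs, self.scores([ids[i] for i in perm], pos[perm]), ed_cutoff=3.0)
        assert hits == hits_p
        # brute-force oracle per reference
        for i, nl in enumerate(lists):
            ds = sorted(
                ((float(np.linalg.norm(refs.scores[i] - pos[j])), ids[j])
                 for j in range(30)),
                key=lambda t: (t[0], t[1]))
            expected = [(cid, d) for d, cid in ds if d <= 3.0][:10]
            assert [c for c, _ in nl.neighbors] == [c for c, _ in expected]

    def test_lowering_cutoff_never_adds_hits(self, rng):
        refs = self.scores(["r"], rng.normal(size=(1, 2)))
        cands = self.scores([f"c{i}" for i in range(20)],
                            rng.normal(size=(20, 2)) * 3)
        wide, _ = nearest_neighbor_screen(refs, cands, ed_cutoff=5.0)
        narrow, _ = nearest_neighbor_screen(refs, cands, ed_cutoff=2.0)
        assert narrow <= wide

    def test_model_mismatch_rejected(self):
        a = self.scores(["r"], [[0.0]], tag=1)
        b = self.scores(["c"], [[0.0]], tag=2)
        with pytest.raises(ValueError, match="different PCA models"):
            nearest_neighbor_screen(a, b)
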