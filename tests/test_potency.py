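import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from potencyscreen import (
    FingerprintMatrix,
    LabeledDataset,
    classify_potency,
    nearest_similarities,
    potency,
    score_queries,
    similarity_pair,
    tanimoto_absent,
    tanimoto_present,
)

bitvec = st.lists(st.integers(0, 1), min_size=1, max_size=16)


def _refs(rows, labels, names=None):
    rows = np.asarray(rows, dtype=np.uint8)
    names = names or [f"f{i}" for i in range(rows.shape[1])]
    mat = FingerprintMatrix(
        [f"r{i}" for i in range(rows.shape[0])], names, rows
    )
    return LabeledDataset(mat, labels)


class TestTanimoto:
    def test_present_hand_enumeration(self):
        # intersection {f0}, union {f0,f1,f2}
        assert tanimoto_present([1, 1, 0, 0], [1, 0, 1, 0]) == pytest.approx(1 / 3)

    def test_present_identity_and_disjoint(self):
        assert tanimoto_present([1, 0, 1], [1, 0, 1]) == 1.0
        assert tanimoto_present([1, 0], [0, 1]) == 0.0

    def test_absent_hand_enumeration(self):
        # complements [0,0,1,1] and [0,1,0,1]: intersection 1, union 3
        assert tanimoto_absent([1, 1, 0, 0], [1, 0, 1, 0]) == pytest.approx(1 / 3)

    def test_absent_identity_and_disjoint(self):
        assert tanimoto_absent([0, 0, 1], [0, 0, 1]) == 1.0
        assert tanimoto_absent([0, 1], [1, 0]) == 0.0

    def test_all_zero_pair_scores_zero_with_flag(self):
        pair = similarity_pair([0, 0], [0, 0])
        assert pair.ts1 == 0.0 and pair.degenerate_ts1
        pair = similarity_pair([1, 1], [1, 1])
        assert pair.ts0 == 0.0 and pair.degenerate_ts0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            tanimoto_present([1, 0], [1, 0, 1])

    @settings(deadline=None, derandomize=True)
    @given(bitvec, bitvec)
    def test_symmetry(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        assert tanimoto_present(x, y) == tanimoto_present(y, x)
        assert tanimoto_absent(x, y) == tanimoto_absent(y, x)

    @settings(deadline=None, derandomize=True)
    @given(bitvec, bitvec)
    def test_absent_equals_present_on_complements(self, x, y):
        n = min(len(x), len(y))
        x = np.array(x[:n], dtype=np.uint8)
        y = np.array(y[:n], dtype=np.uint8)
        assert tanimoto_absent(x, y) == tanimoto_present(1 - x, 1 - y)


class TestPotencyScore:
    def test_direct_arithmetic(self):
        assert potency(1.0, 0.8, 0.4, 0.3) == pytest.approx(0.6)

    def test_symmetric_inputs_cancel(self):
        for a, b in [(0.3, 0.9), (0.0, 0.0), (1.0, 0.2)]:
            assert potency(a, b, a, b) == 0.0

    def test_extreme_case(self):
        assert potency(0.0, 0.0, 1.0, 1.0) == -1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            potency(1.2, 0.0, 0.0, 0.0)

    @pytest.mark.parametrize(
        "ps,threshold,expected",
        [(0.6, 0.0, "active"), (0.0, 0.0, "inactive"), (-0.2, -0.3, "active")],
    )
    def test_classification_rule(self, ps, threshold, expected):
        assert classify_potency(ps, threshold) == expected


class TestNearestSimilarities:
    def test_identical_active_found(self):
        refs = _refs([[1, 0, 1], [0, 1, 0]], ["active", "inactive"])
        res = nearest_similarities([1, 0, 1], refs)
        assert res.ha_ts1 == 1.0
        assert res.nearest_active_id == "r0"

    def test_query_matching_both_classes_scores_zero(self):
        refs = _refs([[1, 0, 1], [1, 0, 1]], ["active", "inactive"])
        res = nearest_similarities([1, 0, 1], refs)
        assert res.potency == 0.0

    def test_maxima_over_enumerated_pairs(self):
        # three actives with known ts1/ts0 to the query, one inactive
        query = np.array([1, 1, 0, 0, 0], dtype=np.uint8)
        refs = _refs(
            [[1, 0, 1, 1, 1],   # ts1 1/5
             [1, 1, 0, 0, 1],   # ts1 2/3
             [0, 0, 0, 0, 0],   # ts1 0, ts0 3/5
             [0, 0, 1, 1, 1]],  # inactive
            ["active", "active", "active", "inactive"],
        )
        res = nearest_similarities(query, refs)
        ha1 = max(tanimoto_present(query, r) for r in refs.matrix.values[:3])
        ha0 = max(tanimoto_absent(query, r) for r in refs.matrix.values[:3])
        assert res.ha_ts1 == pytest.approx(ha1)
        assert res.ha_ts0 == pytest.approx(ha0)

    def test_exclude_id_removes_self_match(self):
        refs = _refs(
            [[1, 0, 1], [1, 1, 1], [0, 1, 0]],
            ["active", "active", "inactive"],
        )
        with_self = nearest_similarities([1, 0, 1], refs)
        without = nearest_similarities([1, 0, 1], refs, exclude_id="r0")
        assert with_self.ha_ts1 == 1.0
        assert without.ha_ts1 < 1.0
        assert without.nearest_active_id == "r1"

    def test_empty_class_after_exclusion_rejected(self):
        refs = _refs([[1, 0], [0, 1]], ["active", "inactive"])
        with pytest.raises(ValueError):
            nearest_similarities([1, 0], refs, exclude_id="r0")

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 21))
        bits = int(rng.integers(2, 17))
        rows = rng.integers(0, 2, size=(n, bits), dtype=np.uint8)
        labels = ["active"] * (n // 2) + ["inactive"] * (n - n // 2)
        refs = _refs(rows, labels)
        query = rng.integers(0, 2, size=bits, dtype=np.uint8)
        res = nearest_similarities(query, refs)
        act = rows[: n // 2]
        ina = rows[n // 2:]
        assert res.ha_ts1 == max(tanimoto_present(query, r) for r in act)
        assert res.ha_ts0 == max(tanimoto_absent(query, r) for r in act)
        assert res.hn_ts1 == max(tanimoto_present(query, r) for r in ina)
        assert res.hn_ts0 == max(tanimoto_absent(query, r) for r in ina)
        assert res.potency == pytest.approx(
            max(res.ha_ts1, res.ha_ts0) - max(res.hn_ts1, res.hn_ts0)
        )
        assert -1.0 <= res.potency <= 1.0

    def test_swapping_reference_classes_negates_potency(self, rng):
        rows = rng.integers(0, 2, size=(10, 8), dtype=np.uint8)
        labels = ["active"] * 5 + ["inactive"] * 5
        swapped = ["inactive"] * 5 + ["active"] * 5
        query = rng.integers(0, 2, size=8, dtype=np.uint8)
        a = nearest_similarities(query, _refs(rows, labels))
        b = nearest_similarities(query, _refs(rows, swapped))
        assert a.potency == pytest.approx(-b.potency)


class TestScoreQueries:
    def test_matches_per_query_results(self, rng):
        rows = rng.integers(0, 2, size=(12, 10), dtype=np.uint8)
        labels = (["active"] * 6) + (["inactive"] * 6)
        refs = _refs(rows, labels)
        queries = rng.integers(0, 2, size=(5, 10), dtype=np.uint8)
        bulk = score_queries(queries, refs)
        single = [nearest_similarities(q, refs).potency for q in queries]
        assert bulk == pytest.approx(single)

    def test_exclude_self_masks_diagonal(self, rng):
        rows = rng.integers(0, 2, size=(8, 6), dtype=np.uint8)
        refs = _refs(rows, ["active"] * 4 + ["inactive"] * 4)
        scores = score_queries(rows, refs, exclude_self=True)
        expected = [
            nearest_similarities(rows[i], refs, exclude_id=f"r{i}").potency
            for i in range(8)
        ]
        assert scores == pytest.approx(expected)
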