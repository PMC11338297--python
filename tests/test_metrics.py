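"""Categoricality, alignment, bridging, and filters, against hand-computed
fixtures, brute-force oracles, and geometric invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata, spearmanr

from sortalign import metrics
from sortalign.metrics import (
    ComparabilityError,
    DataError,
    UndefinedStatisticError,
    alignment,
    alignment_matrix,
    categoricality,
    dyad_bridge,
    fisher_z,
    pairwise_distances,
    participant_filter,
    rt_filter,
    subset_alignment,
)
from sortalign.simulate import SortRecord, SorterConfig, simulate_sort
from tests.conftest import FOUR_CATS, make_sort

# hand-computed distances of the 4-item fixture, in canonical pair order
# (A1,A2) (A1,B1) (A1,B2) (A2,B1) (A2,B2) (B1,B2)
FOUR_DISTS = [1.0, 10.0, np.sqrt(101), np.sqrt(101), 10.0, 1.0]


def transform(positions, scale=1.0, angle=0.0, shift=(0.0, 0.0), reflect=False):
    """Similarity transform of a point set (for invariance checks)."""
    xy = np.asarray(positions, dtype=float)
    if reflect:
        xy = xy * [-1, 1]
    c, s = np.cos(angle), np.sin(angle)
    xy = scale * xy @ np.array([[c, -s], [s, c]]).T + shift
    return xy


class TestPairwiseDistances:
    def test_three_four_five(self):
        rec = make_sort([(0, 0), (3, 4)], ids=("a", "b"))
        assert pairwise_distances(rec).distances.tolist() == [5.0]

    def test_twenty_items_give_190_pairs(self, twenty_ids):
        rec = simulate_sort(twenty_ids, SorterConfig(rng_seed=0))
        dv = pairwise_distances(rec)
        assert len(dv.distances) == len(dv.pair_ids) == 190

    def test_four_item_fixture_matches_hand_computation(self, four_item_sort):
        dv = pairwise_distances(four_item_sort)
        assert np.allclose(dv.distances, FOUR_DISTS)
        assert dv.pair_ids[0] == ("A1", "A2") and dv.pair_ids[-1] == ("B1", "B2")

    def test_canonical_order_independent_of_input_order(self, four_item_sort):
        shuffled = make_sort(
            [(10, 0), (0, 0), (10, 1), (0, 1)], ids=("B1", "A1", "B2", "A2")
        )
        a, b = pairwise_distances(four_item_sort), pairwise_distances(shuffled)
        assert a.pair_ids == b.pair_ids
        assert np.allclose(a.distances, b.distances)

    def test_duplicate_item_ids_rejected(self):
        rec = make_sort([(0, 0), (1, 1)], ids=("a", "a"))
        with pytest.raises(DataError):
            pairwise_distances(rec)


class TestCategoricality:
    def test_equal_between_and_within_means_give_zero(self):
        # rectangle with b = 3a/4 equalizes the two mean distances:
        # within = 4; between = (3 + 5 + 5 + 3) / 4 = 4
        rec = make_sort([(0, 0), (4, 0), (0, 3), (4, 3)])
        score = categoricality(rec, FOUR_CATS)
        assert score.mean_between == pytest.approx(score.mean_within)
        assert score.score == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_fixture(self, four_item_sort):
        score = categoricality(four_item_sort, FOUR_CATS)
        assert score.mean_within == pytest.approx(1.0)
        assert score.mean_between == pytest.approx((20 + 2 * np.sqrt(101)) / 4)
        assert score.score == pytest.approx(np.log((20 + 2 * np.sqrt(101)) / 4))
        assert score.score == pytest.approx(2.305, abs=1e-3)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        scale=st.floats(0.05, 20),
        angle=st.floats(0, 2 * np.pi),
        dx=st.floats(-500, 500),
        dy=st.floats(-500, 500),
        reflect=st.booleans(),
    )
    def test_invariant_under_similarity_transforms(self, scale, angle, dx, dy, reflect):
        base = [(0, 0), (0, 1), (10, 0), (10, 1)]
        moved = transform(base, scale, angle, (dx, dy), reflect)
        a = categoricality(make_sort(base, canvas=(10**6, 10**6)), FOUR_CATS)
        b = categoricality(
            make_sort(moved - moved.min(0), canvas=(10**6, 10**6)), FOUR_CATS
        )
        assert b.score == pytest.approx(a.score, abs=1e-9)

    def test_coincident_within_category_items_undefined(self):
        rec = make_sort([(0, 0), (0, 0), (5, 5), (5, 5)])
        with pytest.raises(UndefinedStatisticError):
            categoricality(rec, FOUR_CATS)

    def test_needs_two_items_per_category(self):
        rec = make_sort([(0, 0), (1, 0), (2, 0)], ids=("A1", "A2", "B1"))
        with pytest.raises(DataError):
            categoricality(rec, {"A1": "A", "A2": "A", "B1": "B"})


class TestAlignment:
    def test_self_alignment_is_clipped_rho_one(self, four_item_sort):
        dv = pairwise_distances(four_item_sort)
        rho, z = alignment(dv, dv)
        assert rho == pytest.approx(1.0)
        assert z == pytest.approx(np.arctanh(1 - 1e-6))

    def test_hand_computed_pair(self, four_item_sort, four_item_sort_b):
        rho, z = alignment(
            pairwise_distances(four_item_sort), pairwise_distances(four_item_sort_b)
        )
        # independently derived on the six hand-computed distances
        assert rho == pytest.approx(7 / np.sqrt(16 * 17), abs=1e-12)
        assert rho == pytest.approx(0.42, abs=0.01)
        assert z == pytest.approx(np.arctanh(rho))

    def test_symmetric(self, four_item_sort, four_item_sort_b):
        d1 = pairwise_distances(four_item_sort)
        d2 = pairwise_distances(four_item_sort_b)
        assert alignment(d1, d2) == alignment(d2, d1)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        scale=st.floats(0.05, 20),
        angle=st.floats(0, 2 * np.pi),
        dx=st.floats(-300, 300),
        dy=st.floats(-300, 300),
        reflect=st.booleans(),
    )
    def test_invariant_under_similarity_transform_of_one_sort(
        self, scale, angle, dx, dy, reflect
    ):
        # tie-free second sort: exact ties would break under the 1e-15
        # distance perturbations a float rotation introduces
        base = make_sort([(0, 0), (0, 1), (10, 0), (10, 1)])
        other = make_sort([(0, 0), (0, 2), (4, 0), (9, 1.5)], pid="q")
        d1 = pairwise_distances(base)
        moved = transform(other.positions, scale, angle, (dx, dy), reflect)
        rec = make_sort(moved - moved.min(0), canvas=(10**6, 10**6), pid="q")
        rho0, _ = alignment(d1, pairwise_distances(other))
        rho1, _ = alignment(d1, pairwise_distances(rec))
        assert rho1 == pytest.approx(rho0, abs=1e-9)

    def test_matches_rank_then_pearson_oracle(self, rng):
        # brute-force oracle: average-rank then Pearson, cross-checked with
        # scipy's spearmanr; agreement demanded to 1e-12
        for _ in range(25):
            x = rng.uniform(0, 100, 45)
            y = rng.uniform(0, 100, 45)
            y[:10] = x[:10]  # inject ties across and within vectors
            x[5:8] = x[5]
            ids = [f"i{k}" for k in range(45)]
            pairs = tuple(zip(ids, ids[1:] + ids[:1]))
            d1 = metrics.DistanceVector("a", pairs, x)
            d2 = metrics.DistanceVector("b", pairs, y)
            rho, _ = alignment(d1, d2)
            rx, ry = rankdata(x), rankdata(y)
            oracle = np.corrcoef(rx, ry)[0, 1]
            assert rho == pytest.approx(oracle, abs=1e-12)
            assert rho == pytest.approx(spearmanr(x, y).statistic, abs=1e-12)

    def test_mismatched_item_sets_rejected(self, four_item_sort):
        other = make_sort([(0, 0), (1, 1), (2, 2), (3, 3)], ids=("C1", "C2", "C3", "C4"))
        with pytest.raises(ComparabilityError):
            alignment(pairwise_distances(four_item_sort), pairwise_distances(other))

    def test_zero_variance_vector_undefined(self, four_item_sort):
        d1 = pairwise_distances(four_item_sort)
        flat = metrics.DistanceVector("f", d1.pair_ids, np.ones(len(d1.pair_ids)))
        with pytest.raises(UndefinedStatisticError):
            alignment(d1, flat)


class TestSubsetAlignment:
    def test_subset_sizes_for_ten_per_category(self, twenty_ids, twenty_cats):
        a = simulate_sort(twenty_ids, SorterConfig(rng_seed=0))
        d = pairwise_distances(a)
        same = [p for p in d.pair_ids if twenty_cats[p[0]] == twenty_cats[p[1]]]
        assert len(same) == 90 and len(d.pair_ids) - len(same) == 100

    def test_identical_sorts_align_on_both_subsets(self, twenty_ids, twenty_cats):
        a = simulate_sort(twenty_ids, SorterConfig(rng_seed=1))
        d = pairwise_distances(a)
        for subset in ("within_category", "between_category"):
            rho, _ = subset_alignment(d, d, subset, twenty_cats)
            assert rho == pytest.approx(1.0)

    def test_unknown_subset_rejected(self, four_item_sort):
        d = pairwise_distances(four_item_sort)
        with pytest.raises(ValueError):
            subset_alignment(d, d, "diagonal", FOUR_CATS)


class TestDyadBridge:
    def test_reference_values(self):
        assert dyad_bridge(1.0, 0.4) == (0.4, 1.0, pytest.approx(0.6))

    def test_symmetric_and_degenerate(self):
        assert dyad_bridge(0.2, 0.9) == dyad_bridge(0.9, 0.2)
        lo, hi, diff = dyad_bridge(0.7, 0.7)
        assert lo == hi == 0.7 and diff == 0.0


class TestAlignmentMatrix:
    def test_identical_sorts_all_at_clip(self, twenty_ids, twenty_cats):
        base = simulate_sort(twenty_ids, SorterConfig(rng_seed=0))
        cohort = [
            SortRecord(f"p{i}", "c", base.item_ids, base.positions,
                       base.canvas_w, base.canvas_h)
            for i in range(3)
        ]
        res = alignment_matrix(cohort, twenty_cats)
        clip = np.arctanh(1 - 1e-6)
        assert np.allclose(res.mean_z, clip)
        assert len(res.dyads) == 3

    def test_dyad_count_and_agreement_with_pairwise_calls(self, twenty_ids, twenty_cats):
        cohort = [
            simulate_sort(twenty_ids, SorterConfig(rng_seed=s), participant_id=f"p{s}",
                          condition="c")
            for s in range(5)
        ]
        res = alignment_matrix(cohort, twenty_cats)
        assert len(res.dyads) == 5 * 4 // 2
        dvs = [pairwise_distances(r) for r in cohort]
        for d in res.dyads:
            i = res.participant_ids.index(d.id_i)
            j = res.participant_ids.index(d.id_j)
            rho, z = alignment(dvs[i], dvs[j])
            assert d.rho == pytest.approx(rho, abs=1e-10)
            assert d.z_alignment == pytest.approx(z, abs=1e-10)

    def test_cross_condition_dyads_absent(self, twenty_ids, twenty_cats):
        cohort = [
            simulate_sort(twenty_ids, SorterConfig(rng_seed=s), participant_id=f"p{s}",
                          condition="c1" if s < 2 else "c2")
            for s in range(4)
        ]
        res = alignment_matrix(cohort, twenty_cats)
        assert len(res.dyads) == 2  # one per condition
        assert np.isnan(res.z[0, 2]) and np.isnan(res.z[0, 3])

    def test_singleton_condition_rejected(self, twenty_ids):
        cohort = [
            simulate_sort(twenty_ids, SorterConfig(rng_seed=s), participant_id=f"p{s}",
                          condition="solo" if s == 0 else "rest")
            for s in range(3)
        ]
        with pytest.raises(metrics.CohortError):
            alignment_matrix(cohort)


class TestFilters:
    def test_rt_floor_and_upper_tail(self):
        rts = [100.0, 200.0, 300.0, 400.0, 5000.0]
        arr = np.array(rts)
        upper = arr.mean() + 2 * arr.std(ddof=1)
        oracle = [v for v in rts if 150 <= v <= upper]
        assert rt_filter(rts) == oracle
        assert 100.0 not in rt_filter(rts)

    def test_identical_rts_all_kept(self):
        assert rt_filter([400.0] * 10) == [400.0] * 10

    def test_twenty_rt_fixture_matches_enumeration(self, rng):
        rts = list(np.round(rng.normal(600, 150, 20), 1))
        arr = np.array(rts)
        upper = arr.mean() + 2 * arr.std(ddof=1)
        oracle = [v for v in rts if 150 <= v <= upper]
        assert rt_filter(rts) == oracle

    def test_empty_input(self):
        assert rt_filter([]) == []

    def test_participant_rules(self, twenty_ids):
        recs = []
        for i, moved in enumerate([True, False, True, True, True]):
            rec = simulate_sort(twenty_ids, SorterConfig(rng_seed=i),
                                participant_id=f"p{i}")
            recs.append(
                SortRecord(rec.participant_id, rec.condition, rec.item_ids,
                           rec.positions, rec.canvas_w, rec.canvas_h, moved_all=moved)
            )
        logs = {
            "p2": {"accuracy": 0.79},
            "p3": {"accuracy": 0.80, "catch_correct": 7},
            "p4": {"catch_correct": 6},
        }
        kept, reasons = participant_filter(recs, logs)
        assert [r.participant_id for r in kept] == ["p0", "p3"]
        assert reasons == {
            "p0": "ok", "p1": "sort-incomplete", "p2": "low-accuracy",
            "p3": "ok", "p4": "catch-fail",
        }


def test_fisher_z_clips_extremes():
    assert np.isfinite(fisher_z(1.0)) and np.isfinite(fisher_z(-1.0))
    assert fisher_z(0.5) == pytest.approx(np.arctanh(0.5))
    assert fisher_z(-1.0) == -fisher_z(1.0)
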