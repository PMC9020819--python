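"""Behaviour RDM construction, percentile conversion, level stratification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import percsim as ps
from percsim.arrangements import (
    ArrangementError,
    build_behaviour_rdm,
    distances_from_arrangement,
    intersubject_correlation,
    stratify_levels,
)
from percsim.rdm import EXCLUDED, RDMError, to_percentiles
from oracles import brute_force_percentiles, oracle_stratify


def _points(coords, exemplars=None):
    exemplars = exemplars or list(range(1, len(coords) + 1))
    return pd.DataFrame(
        [(e, x, y) for e, (x, y) in zip(exemplars, coords)],
        columns=["exemplar", "x", "y"],
    )


def _category_rdm(percentiles):
    """Single-category RDM frame with prescribed percentile entries."""
    pairs = [(1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4)]
    return pd.DataFrame(
        [(1, i, j, p, p) for (i, j), p in zip(pairs, percentiles)],
        columns=["category", "exemplar_i", "exemplar_j", "raw", "percentile"],
    )


class TestDistances:
    def test_unit_square_distances(self):
        d = distances_from_arrangement(
            _points([(0, 0), (1, 0), (1, 1), (0, 1)])
        )
        assert len(d) == 6
        got = sorted(np.round(d["raw"], 12))
        expected = sorted([1, 1, 1, 1, np.sqrt(2), np.sqrt(2)])
        np.testing.assert_allclose(got, expected)

    def test_coincident_points_give_zero_distances(self):
        d = distances_from_arrangement(_points([(0.1, 0.2)] * 4))
        assert (d["raw"] == 0).all()

    def test_duplicate_exemplars_rejected(self):
        with pytest.raises(ArrangementError):
            distances_from_arrangement(
                _points([(0, 0), (1, 0), (0, 1), (1, 1)], [1, 1, 2, 3])
            )


class TestPercentiles:
    def test_strict_ranks(self):
        np.testing.assert_allclose(
            to_percentiles([0.2, 0.5, 0.9]), [0.0, 0.5, 1.0]
        )

    def test_tie_convention(self):
        np.testing.assert_allclose(to_percentiles([0.3, 0.3]), [0.5, 0.5])

    def test_all_equal_warns_and_returns_half(self):
        with pytest.warns(UserWarning):
            out = to_percentiles([1.0, 1.0, 1.0])
        np.testing.assert_allclose(out, 0.5)

    @given(
        st.lists(
            st.floats(0, 10, allow_nan=False, width=32), min_size=2, max_size=60
        )
    )
    @settings(deadline=None, max_examples=60)
    def test_matches_brute_force_rank_oracle(self, values):
        np.testing.assert_allclose(
            to_percentiles(values), brute_force_percentiles(values), atol=1e-12
        )

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=30)
    def test_invariant_to_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.1, 5.0, size=60)
        np.testing.assert_allclose(
            to_percentiles(x), to_percentiles(np.exp(2 * x + 1)), atol=1e-12
        )


class TestBehaviourRDM:
    def test_sixty_entries_under_default_design(self, small_study):
        obs1 = small_study.arrangements.query("observer == 1")
        rdm = build_behaviour_rdm(obs1)
        assert len(rdm) == 60
        assert rdm.groupby("category").size().eq(6).all()

    def test_single_category_spans_unit_interval(self):
        arr = pd.DataFrame(
            [(1, 1, e, x, y) for e, (x, y) in enumerate(
                [(0, 0), (0.3, 0), (0.1, 0.5), (-0.4, -0.2)], start=1
            )],
            columns=["observer", "category", "exemplar", "x", "y"],
        )
        rdm = build_behaviour_rdm(arr)
        assert len(rdm) == 6
        assert rdm["percentile"].min() == 0.0
        assert rdm["percentile"].max() == 1.0

    def test_identical_arrangements_give_identical_rdms(self, small_study):
        obs1 = small_study.arrangements.query("observer == 1")
        copy = obs1.assign(observer=99)
        a = build_behaviour_rdm(obs1).drop(columns="observer")
        b = build_behaviour_rdm(copy).drop(columns="observer")
        pd.testing.assert_frame_equal(a, b)

    def test_missing_category_reported(self, small_study):
        obs1 = small_study.arrangements.query("observer == 1 and category != 4")
        with pytest.raises(ArrangementError, match="4"):
            build_behaviour_rdm(obs1)


class TestStratifyLevels:
    def test_well_separated_levels(self):
        rdm = _category_rdm([0.1, 0.1, 0.5, 0.5, 0.9, 0.9])
        part = stratify_levels(rdm, min_gap=0.1)
        by_pct = part.groupby("level")["percentile"].unique()
        assert set(by_pct["high"]) == {0.1}
        assert set(by_pct["medium"]) == {0.5}
        assert set(by_pct["low"]) == {0.9}
        assert EXCLUDED not in part["level"].values

    def test_gap_violation_excludes_both_straddling_entries(self):
        rdm = _category_rdm([0.10, 0.16, 0.21, 0.5, 0.8, 0.9])
        part = stratify_levels(rdm, min_gap=0.1)
        excluded = sorted(part.loc[part["level"] == EXCLUDED, "percentile"])
        assert excluded == [0.16, 0.21]
        assert sorted(part.loc[part["level"] == "low", "percentile"]) == [0.8, 0.9]

    def test_twenty_entries_per_level_before_exclusion(self, small_behaviour_rdms):
        part = ps.stratify_levels(
            small_behaviour_rdms[1].drop(columns="level"), min_gap=0.0
        )
        counts = part["level"].value_counts()
        assert counts["high"] == counts["medium"] == counts["low"] == 20

    def test_matches_exhaustive_oracle_on_random_categories(self):
        rng = np.random.default_rng(12345)
        for _ in range(1000):
            pct = np.round(rng.uniform(0, 1, size=6), 3)
            part = stratify_levels(_category_rdm(pct), min_gap=0.1)
            np.testing.assert_array_equal(
                part["level"].to_numpy(), oracle_stratify(pct)
            )

    def test_level_means_ordered(self, small_behaviour_rdms):
        for rdm in small_behaviour_rdms.values():
            kept = rdm[rdm["level"] != EXCLUDED]
            means = kept.groupby("level")["percentile"].mean()
            assert means["high"] < means["medium"] < means["low"]

    def test_level_assignment_invariant_to_exemplar_relabelling(self):
        pct = [0.05, 0.2, 0.45, 0.6, 0.85, 0.95]
        base = stratify_levels(_category_rdm(pct), min_gap=0.1)
        swapped = _category_rdm(pct)
        relabel = {1: 3, 2: 1, 3: 4, 4: 2}
        ij = swapped[["exemplar_i", "exemplar_j"]].apply(
            lambda r: sorted((relabel[r.iloc[0]], relabel[r.iloc[1]])), axis=1
        )
        swapped["exemplar_i"] = [p[0] for p in ij]
        swapped["exemplar_j"] = [p[1] for p in ij]
        part = stratify_levels(swapped, min_gap=0.1)
        # same multiset of (percentile, level) assignments
        a = sorted(zip(base["percentile"], base["level"]))
        b = sorted(zip(part["percentile"], part["level"]))
        assert a == b


class TestIntersubjectCorrelation:
    def test_identical_observers_agree_perfectly(self, small_behaviour_rdms):
        template = small_behaviour_rdms[1]
        rdms = {o: template.assign(observer=o) for o in range(1, 5)}
        isc = intersubject_correlation(rdms)
        np.testing.assert_allclose(isc.per_observer_r, 1.0)

    def test_noise_observer_has_low_agreement(self, small_behaviour_rdms):
        rng = np.random.default_rng(0)
        rdms = {o: r.copy() for o, r in small_behaviour_rdms.items()}
        noisy = rdms[1].copy()
        noisy["percentile"] = rng.permutation(noisy["percentile"].to_numpy())
        rdms[1] = noisy
        isc = intersubject_correlation(rdms)
        assert abs(isc.per_observer_r[1]) < 0.4
        assert isc.per_observer_r.drop(1).min() > isc.per_observer_r[1]

    def test_needs_three_observers(self, small_behaviour_rdms):
        with pytest.raises(RDMError):
            intersubject_correlation(
                {o: small_behaviour_rdms[o] for o in (1, 2)}
            )

    def test_level_subsets_use_own_partition(self, small_behaviour_rdms):
        whole = intersubject_correlation(small_behaviour_rdms, "whole")
        high = intersubject_correlation(small_behaviour_rdms, "high")
        assert -1 <= high.mean_r <= 1
        assert high.mean_r != pytest.approx(whole.mean_r)
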