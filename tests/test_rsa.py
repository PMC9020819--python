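"""Brain-behaviour statistics: correlations, group tests, i-index, nulls."""

import numpy as np
import pandas as pd
import pytest

from percsim import rsa
from percsim.rdm import PAIR_KEY, RDMError, average_rdm
from percsim.rsa import (
    CorrelationResult,
    brain_behaviour_correlation,
    compare_regions,
    correlation_matrix,
    group_inference,
    i_index,
    i_index_from_matrix,
    model_rdm_correlation,
    permutation_null_i_index,
)


class TestBrainBehaviourCorrelation:
    def test_identical_rdms_correlate_perfectly(self, small_behaviour_rdms):
        rdm = small_behaviour_rdms[1]
        res = brain_behaviour_correlation(rdm, rdm, "whole")
        assert res.r == pytest.approx(1.0)
        assert res.n_entries == 60

    def test_shuffled_entries_near_zero_on_average(self, small_behaviour_rdms):
        rdm = small_behaviour_rdms[1]
        rng = np.random.default_rng(0)
        rs = []
        for _ in range(100):
            shuffled = rdm.copy()
            shuffled["percentile"] = rng.permutation(
                shuffled["percentile"].to_numpy()
            )
            rs.append(brain_behaviour_correlation(shuffled, rdm).r)
        assert abs(np.mean(rs)) < 0.05

    def test_level_subset_uses_behaviour_partition(
        self, small_brain_rdms, small_behaviour_rdms
    ):
        res = brain_behaviour_correlation(
            small_brain_rdms["PrC-like"][1], small_behaviour_rdms[1], "high"
        )
        n_high = (small_behaviour_rdms[1]["level"] == "high").sum()
        assert res.n_entries == n_high

    def test_excluded_pairs_dropped_from_both_sides(
        self, small_brain_rdms, small_behaviour_rdms
    ):
        behav = small_behaviour_rdms[2]
        total_level = sum(
            (behav["level"] == lvl).sum() for lvl in ("low", "medium", "high")
        )
        n = sum(
            brain_behaviour_correlation(
                small_brain_rdms["noise"][2], behav, lvl
            ).n_entries
            for lvl in ("low", "medium", "high")
        )
        assert n == total_level < 60

    def test_too_few_entries_rejected(self, small_behaviour_rdms):
        tiny = small_behaviour_rdms[1].head(2)
        with pytest.raises(RDMError):
            brain_behaviour_correlation(tiny, tiny)


class TestGroupInference:
    def _results(self, rs, region="R", subset="whole"):
        return [
            CorrelationResult(observer=o, region=region, subset=subset, r=r, n_entries=60)
            for o, r in enumerate(rs, start=1)
        ]

    def test_all_zero_correlations_give_t_zero(self):
        g = group_inference(self._results([0.0] * 8), n_tests=1)[0]
        assert g.t == 0.0
        assert g.p_raw == pytest.approx(0.5)

    def test_constant_positive_correlations_hit_machine_floor(self):
        g = group_inference(self._results([0.4] * 8), n_tests=1)[0]
        assert g.p_raw <= np.finfo(float).tiny
        assert g.p_bonferroni < 0.05

    def test_bonferroni_scales_and_caps(self):
        rs = [0.2, 0.1, 0.3, 0.15, 0.25, 0.18]
        g1 = group_inference(self._results(rs), n_tests=1)[0]
        g4 = group_inference(self._results(rs), n_tests=4)[0]
        assert g4.p_bonferroni == pytest.approx(min(1.0, g1.p_raw * 4))
        g_huge = group_inference(self._results([0.01, -0.01, 0.0, 0.02]), n_tests=10**6)[0]
        assert g_huge.p_bonferroni == 1.0

    def test_df_is_observers_minus_one(self):
        g = group_inference(self._results([0.1, 0.2, 0.3, 0.4, 0.5]), n_tests=1)[0]
        assert g.df == 4

    def test_invariant_to_observer_ordering(self):
        rs = [0.31, -0.05, 0.22, 0.4, 0.11]
        a = group_inference(self._results(rs), n_tests=2)[0]
        b = group_inference(self._results(rs[::-1]), n_tests=2)[0]
        assert a.t == pytest.approx(b.t)
        assert a.p_bonferroni == pytest.approx(b.p_bonferroni)


class TestCompareRegions:
    def _results(self, pairs):
        out = []
        for o, (ra, rb) in enumerate(pairs, start=1):
            out.append(CorrelationResult(o, "A", "whole", ra, 60))
            out.append(CorrelationResult(o, "B", "whole", rb, 60))
        return out

    def test_identical_regions_give_t_zero(self):
        res = self._results([(0.2, 0.2), (0.3, 0.3), (0.1, 0.1)])
        g = compare_regions(res, "A", "B", "whole")
        assert g.t == 0.0

    def test_swap_negates_t(self):
        res = self._results([(0.5, 0.2), (0.4, 0.1), (0.6, 0.35), (0.3, 0.2)])
        ab = compare_regions(res, "A", "B", "whole")
        ba = compare_regions(res, "B", "A", "whole")
        assert ab.t == pytest.approx(-ba.t)
        assert ab.p_raw == pytest.approx(ba.p_raw)

    def test_fidelity_order_detected(self, small_brain_rdms, small_behaviour_rdms):
        results = []
        for region in ("PrC-like", "noise"):
            for o, behav in small_behaviour_rdms.items():
                results.append(
                    brain_behaviour_correlation(
                        small_brain_rdms[region][o], behav, "whole",
                        region=region, observer=o,
                    )
                )
        g = compare_regions(results, "PrC-like", "noise", "whole")
        assert g.t > 0
        assert g.p_raw < 0.05

    def test_mismatched_observers_rejected(self):
        res = self._results([(0.1, 0.2), (0.3, 0.4)])
        res.append(CorrelationResult(9, "A", "whole", 0.5, 60))
        with pytest.raises(RDMError):
            compare_regions(res, "A", "B", "whole")


class TestIIndex:
    def test_identical_behaviour_rdms_give_zero_i(
        self, small_brain_rdms, small_behaviour_rdms
    ):
        template = small_behaviour_rdms[3]
        behaviours = {o: template.assign(observer=o) for o in range(1, 7)}
        res = i_index(small_brain_rdms["PrC-like"], behaviours, "whole")
        np.testing.assert_allclose(res.i_per_observer, 0.0, atol=1e-12)

    def test_two_observer_antisymmetry(self):
        mat = pd.DataFrame([[0.8, 0.2], [0.1, 0.6]], index=[1, 2], columns=[1, 2])
        res = i_index_from_matrix(mat, "R", "whole")
        swapped = mat.iloc[::-1, ::-1]
        res2 = i_index_from_matrix(swapped, "R", "whole")
        assert res.i_per_observer[1] == pytest.approx(res2.i_per_observer[1])
        assert res.mean_i == pytest.approx(res2.mean_i)

    def test_i_equals_within_minus_between(self, small_brain_rdms, small_behaviour_rdms):
        res = i_index(small_brain_rdms["PrC-like"], small_behaviour_rdms)
        np.testing.assert_allclose(
            res.i_per_observer, res.within_r - res.between_r, atol=1e-12
        )

    def test_observer_specific_region_recovers_positive_i(
        self, small_brain_rdms, small_behaviour_rdms
    ):
        prc = i_index(small_brain_rdms["PrC-like"], small_behaviour_rdms)
        loc = i_index(small_brain_rdms["LOC-like"], small_behaviour_rdms)
        assert prc.mean_i > 0.05
        assert abs(loc.mean_i) < prc.mean_i

    def test_shared_only_region_dissociates(
        self, small_brain_rdms, small_behaviour_rdms
    ):
        """Whole-range correlation positive while i hovers near zero."""
        loc = i_index(small_brain_rdms["LOC-like"], small_behaviour_rdms)
        assert loc.within_r.mean() > 0.05
        assert abs(loc.mean_i) < 0.05


class TestPermutationNull:
    def test_p_values_valid_and_reproducible(
        self, small_brain_rdms, small_behaviour_rdms
    ):
        kwargs = dict(n_perm=300, seed=12)
        a = permutation_null_i_index(
            small_brain_rdms["noise"], small_behaviour_rdms, **kwargs
        )
        b = permutation_null_i_index(
            small_brain_rdms["noise"], small_behaviour_rdms, **kwargs
        )
        assert 0.0 < a.p_perm <= 1.0
        assert a.p_perm == b.p_perm
        assert a.sem_randomization == b.sem_randomization

    def test_null_region_p_moderate(self, small_brain_rdms, small_behaviour_rdms):
        res = permutation_null_i_index(
            small_brain_rdms["noise"], small_behaviour_rdms, n_perm=500, seed=3
        )
        assert res.p_perm > 0.05

    def test_minimum_permutations_enforced(
        self, small_brain_rdms, small_behaviour_rdms
    ):
        with pytest.raises(RDMError):
            permutation_null_i_index(
                small_brain_rdms["noise"], small_behaviour_rdms, n_perm=10
            )

    def test_identity_permutation_tolerated(self):
        # labels may map to themselves: the null must still be well defined
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(4, 4))
        mat = pd.DataFrame(vals, index=range(4), columns=range(4))
        from percsim.rsa import _null_mean_i

        identity = np.arange(4)
        point = i_index_from_matrix(mat, "R", "whole")
        assert _null_mean_i(vals, identity) == pytest.approx(point.mean_i)


class TestModelRDMCorrelation:
    def test_model_equals_target(self, small_behaviour_rdms):
        rdm = small_behaviour_rdms[1]
        r, n = model_rdm_correlation(rdm, rdm)
        assert r == pytest.approx(1.0)
        assert n == 60

    def test_average_of_identical_observers_is_any_observer(
        self, small_behaviour_rdms
    ):
        template = small_behaviour_rdms[2]
        avg = average_rdm([template.assign(observer=o) for o in range(1, 5)])
        r, _ = model_rdm_correlation(avg, template)
        assert r == pytest.approx(1.0)

    def test_intermediate_feature_region_correlates_with_model(self, small_study):
        """A model RDM built from the generator's intermediate features tracks
        regions that encode those features, and not a pure-noise region."""
        import percsim as ps
        from percsim import neural
        from percsim.design import exemplar_pairs
        from percsim.rdm import make_rdm_frame

        gt = small_study.ground_truth
        rows = []
        for c in range(1, gt.config.n_categories + 1):
            for i, j in exemplar_pairs():
                d = np.linalg.norm(
                    gt.intermediate[c - 1, i - 1] - gt.intermediate[c - 1, j - 1]
                )
                rows.append((c, i, j, d))
        model = make_rdm_frame(
            pd.DataFrame(rows, columns=["category", "exemplar_i", "exemplar_j", "raw"])
        )
        regions = {
            "inter": ps.RegionSpec("inter", w_intermediate=1.0, sigma_noise=1.0),
            "nil": ps.RegionSpec("nil", sigma_noise=1.0, pure_noise_ok=True),
        }
        rs = {}
        for name, region in regions.items():
            vals = []
            for o in (1, 2, 3):
                pset = ps.simulate_voxel_patterns(
                    gt, o, region, small_study.trials[o]
                )
                brain = neural.brain_rdm_from_patterns(pset)
                vals.append(model_rdm_correlation(model, brain)[0])
            rs[name] = np.mean(vals)
        assert rs["inter"] > rs["nil"]
        assert rs["inter"] > 0.3
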