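"""Brain RDM construction and pattern stability."""

import numpy as np
import pandas as pd
import pytest

import percsim as ps
from percsim import neural
from percsim.neural import (
    PatternDataError,
    build_brain_rdm,
    exemplar_mean_patterns,
    split_half_stability,
)
from percsim.synthetic import NeuralPatternSet, RegionSpec
from percsim.rdm import make_rdm_frame


def _means_from_blocks(blocks):
    """Build an exemplar-means frame from {(category, exemplar): vector}."""
    idx = pd.MultiIndex.from_tuples(sorted(blocks), names=["category", "exemplar"])
    return pd.DataFrame([blocks[k] for k in sorted(blocks)], index=idx)


class TestExemplarMeans:
    def test_default_design_aggregates_24_trials(self):
        cfg = ps.StudyConfig(n_observers=1, seed=1)
        gt = ps.make_ground_truth(cfg)
        trials = ps.generate_trial_sequence(cfg, seed=1)
        pset = ps.simulate_voxel_patterns(
            gt, 1, RegionSpec("r", w_shared=1.0), trials
        )
        nr = trials[trials["trial_type"] == "no_response"]
        assert nr.groupby(["category", "exemplar"]).size().eq(24).all()
        means = exemplar_mean_patterns(pset)
        assert means.shape == (40, 60)

    def test_single_trial_subset_equals_that_trial(self, small_study):
        pset = small_study.patterns[(1, "PrC-like")]
        one_run = exemplar_mean_patterns(pset, run_subset=[2])
        trials = pset.trials
        mask = (
            (trials["run"] == 2)
            & (trials["trial_type"] == "no_response")
            & (trials["category"] == 3)
            & (trials["exemplar"] == 1)
        ).to_numpy()
        manual = pset.data[mask].mean(axis=0)
        np.testing.assert_allclose(one_run.loc[(3, 1)].to_numpy(), manual)

    def test_catch_trials_excluded(self, small_study):
        pset = small_study.patterns[(1, "noise")]
        trials = pset.trials
        means = exemplar_mean_patterns(pset)
        mask = (
            (trials["trial_type"] == "no_response")
            & (trials["category"] == 1)
            & (trials["exemplar"] == 1)
        ).to_numpy()
        np.testing.assert_allclose(
            means.loc[(1, 1)].to_numpy(), pset.data[mask].mean(axis=0)
        )

    def test_empty_run_subset_raises(self, small_study):
        pset = small_study.patterns[(1, "noise")]
        with pytest.raises(PatternDataError):
            exemplar_mean_patterns(pset, run_subset=[99])


class TestBrainRDM:
    def test_identical_patterns_have_zero_dissimilarity(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        means = _means_from_blocks(
            {(1, 1): v, (1, 2): v, (1, 3): v * 2 + 1, (1, 4): v[::-1]}
        )
        rdm = build_brain_rdm(means)
        pair = rdm.query("exemplar_i == 1 and exemplar_j == 2")
        assert pair["raw"].iloc[0] == pytest.approx(0.0)
        # affine-related pattern also at zero correlation distance
        pair13 = rdm.query("exemplar_i == 1 and exemplar_j == 3")
        assert pair13["raw"].iloc[0] == pytest.approx(0.0)

    def test_orthogonal_centred_patterns_at_one(self):
        means = _means_from_blocks(
            {
                (1, 1): np.array([1.0, -1.0, 1.0, -1.0]),
                (1, 2): np.array([1.0, 1.0, -1.0, -1.0]),
                (1, 3): np.array([3.0, 1.0, 0.0, 2.0]),
                (1, 4): np.array([0.0, 5.0, 1.0, 2.0]),
            }
        )
        rdm = build_brain_rdm(means)
        pair = rdm.query("exemplar_i == 1 and exemplar_j == 2")
        assert pair["raw"].iloc[0] == pytest.approx(1.0)

    def test_percentiles_match_shared_oracle(self):
        from oracles import brute_force_percentiles

        rng = np.random.default_rng(7)
        means = _means_from_blocks(
            {
                (c, e): rng.normal(size=30)
                for c in range(1, 11)
                for e in range(1, 5)
            }
        )
        rdm = build_brain_rdm(means)
        assert len(rdm) == 60
        np.testing.assert_allclose(
            rdm["percentile"], brute_force_percentiles(rdm["raw"]), atol=1e-12
        )

    def test_zero_variance_pattern_rejected(self):
        means = _means_from_blocks(
            {
                (1, 1): np.ones(4),
                (1, 2): np.arange(4.0),
                (1, 3): np.arange(4.0) * 2,
                (1, 4): np.arange(4.0) ** 2,
            }
        )
        with pytest.raises(PatternDataError):
            build_brain_rdm(means)

    def test_invariant_to_voxel_permutation_and_offset(self, small_study):
        pset = small_study.patterns[(2, "PrC-like")]
        rdm = neural.brain_rdm_from_patterns(pset)
        rng = np.random.default_rng(1)
        shuffled = NeuralPatternSet(
            observer=pset.observer,
            region=pset.region,
            trials=pset.trials,
            data=pset.data[:, rng.permutation(pset.data.shape[1])] + 11.5,
        )
        rdm2 = neural.brain_rdm_from_patterns(shuffled)
        np.testing.assert_allclose(rdm["raw"], rdm2["raw"], atol=1e-10)

    def test_percentiles_invariant_to_monotone_transform_of_dissimilarity(self):
        rng = np.random.default_rng(3)
        raw = rng.uniform(0.1, 1.9, size=60)
        pairs = [
            (c, i, j)
            for c in range(1, 11)
            for (i, j) in [(1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4)]
        ]
        base = make_rdm_frame(
            pd.DataFrame(
                [(c, i, j, r) for (c, i, j), r in zip(pairs, raw)],
                columns=["category", "exemplar_i", "exemplar_j", "raw"],
            )
        )
        warped = make_rdm_frame(base.assign(raw=np.exp(3 * base["raw"])))
        np.testing.assert_allclose(base["percentile"], warped["percentile"])


class TestSplitHalfStability:
    def _pset(self, sigma, seed=5):
        cfg = ps.StudyConfig(n_observers=1, n_runs=4, seed=seed)
        gt = ps.make_ground_truth(cfg)
        trials = ps.generate_trial_sequence(cfg, seed=seed)
        region = RegionSpec("r", w_shared=1.0, sigma_noise=sigma)
        return ps.simulate_voxel_patterns(gt, 1, region, trials)

    def test_noiseless_region_perfectly_stable(self):
        assert split_half_stability(self._pset(0.0)) == pytest.approx(1.0)

    def test_stability_decreases_with_noise(self):
        r_low = split_half_stability(self._pset(0.5))
        r_high = split_half_stability(self._pset(8.0))
        assert r_low > r_high

    def test_pure_noise_region_unstable_on_average(self):
        rs = []
        for seed in range(8):
            cfg = ps.StudyConfig(n_observers=1, n_runs=4, seed=seed)
            gt = ps.make_ground_truth(cfg)
            trials = ps.generate_trial_sequence(cfg, seed=seed)
            region = RegionSpec("n", sigma_noise=1.0, pure_noise_ok=True)
            rs.append(
                split_half_stability(ps.simulate_voxel_patterns(gt, 1, region, trials))
            )
        assert abs(np.mean(rs)) < 0.2

    def test_single_run_rejected(self):
        cfg = ps.StudyConfig(n_observers=1, n_runs=1, seed=2)
        gt = ps.make_ground_truth(cfg)
        trials = ps.generate_trial_sequence(cfg, seed=2)
        pset = ps.simulate_voxel_patterns(
            gt, 1, RegionSpec("r", w_shared=1.0), trials
        )
        with pytest.raises(PatternDataError):
            split_half_stability(pset)
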