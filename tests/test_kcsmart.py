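"""Aggregate profiles, kernel-smoothed estimates, and the randomization null."""

import numpy as np
import pandas as pd
import pytest

from metacgh.genome import Genome
from metacgh.io import AcghDataset, CloneMap
from metacgh.kcsmart import (KseProfile, aggregate_profile, kse, kse_correlation,
                             kse_null_threshold, kse_pointwise_pvalues, kse_profile,
                             significant_regions, with_null_thresholds)
from metacgh.simulate import AberrationSegment, generate_cohort

from conftest import small_spec


def brute_force_kse(aggregate, clone_map, grid, width):
    """Untruncated double loop, the independent smoothing oracle."""
    out = np.zeros(len(grid))
    for gi, (gc, gx) in enumerate(zip(grid["chromosome"], grid["bp"])):
        for a, cc, cp in zip(aggregate, clone_map.chromosome, clone_map.position_bp):
            if cc == gc:
                out[gi] += a * np.exp(-((gx - cp) ** 2) / (2 * width**2))
    return out


class TestAggregate:
    def test_sign_split(self, toy_clone_map):
        log2 = np.zeros((2, len(toy_clone_map)))
        log2[0, 0], log2[1, 0] = 0.5, -0.3
        ds = AcghDataset(toy_clone_map, log2, ["a", "b"], np.repeat("G", 2))
        assert aggregate_profile(ds, "gain")[0] == pytest.approx(0.5)
        assert aggregate_profile(ds, "loss")[0] == pytest.approx(-0.3)

    def test_all_negative_clone_has_zero_gain(self, toy_clone_map):
        log2 = np.full((3, len(toy_clone_map)), -0.2)
        ds = AcghDataset(toy_clone_map, log2, list("abc"), np.repeat("G", 3))
        assert np.all(aggregate_profile(ds, "gain") == 0.0)

    def test_matches_bruteforce_loop(self, toy_dataset):
        gain = aggregate_profile(toy_dataset, "gain")
        loss = aggregate_profile(toy_dataset, "loss")
        for c in range(toy_dataset.log2.shape[1]):
            g = sum(max(v, 0.0) for v in toy_dataset.log2[:, c])
            l = sum(min(v, 0.0) for v in toy_dataset.log2[:, c])
            assert gain[c] == pytest.approx(g) and loss[c] == pytest.approx(l)

    def test_missing_contributes_zero(self, toy_clone_map):
        log2 = np.full((2, len(toy_clone_map)), 0.4)
        log2[0, 0] = np.nan
        ds = AcghDataset(toy_clone_map, log2, ["a", "b"], np.repeat("G", 2))
        assert aggregate_profile(ds, "gain")[0] == pytest.approx(0.4)


class TestKse:
    def test_kernel_closed_forms(self):
        gen = Genome({"1": 10_000_000}, {"1": 4_000_000})
        df = pd.DataFrame({"clone_id": ["c"], "chromosome": ["1"], "position_bp": [2_500_000]})
        cm = CloneMap.from_positions(df, gen)
        width = 1_000_000
        grid, vals = kse(np.array([1.0]), cm, grid_spacing_bp=1_000_000, kernel_width_bp=width)
        at = dict(zip(grid["bp"], vals))
        assert at[2_500_000] == pytest.approx(1.0)            # lag 0
        assert at[3_500_000] == pytest.approx(np.exp(-0.5))   # one kernel width away

    def test_matches_untruncated_bruteforce(self, toy_clone_map):
        rng = np.random.default_rng(7)
        agg = rng.uniform(0, 3, size=len(toy_clone_map))
        grid, vals = kse(agg, toy_clone_map, 500_000, 800_000)
        oracle = brute_force_kse(agg, toy_clone_map, grid, 800_000)
        assert np.max(np.abs(vals - oracle)) <= 1e-4 * np.max(np.abs(oracle))

    def test_no_smoothing_across_chromosomes(self, toy_clone_map):
        agg = np.zeros(len(toy_clone_map))
        agg[toy_clone_map.chromosome == "1"] = 5.0
        grid, vals = kse(agg, toy_clone_map, 500_000, 2_000_000)
        assert np.all(vals[grid["chromosome"].to_numpy() == "2"] == 0.0)

    def test_linearity_and_doubling(self, toy_clone_map, toy_dataset):
        a = aggregate_profile(toy_dataset, "gain")
        rng = np.random.default_rng(0)
        b = rng.uniform(0, 1, size=len(a))
        _, va = kse(a, toy_clone_map, 500_000)
        _, vb = kse(b, toy_clone_map, 500_000)
        _, vab = kse(a + b, toy_clone_map, 500_000)
        assert np.allclose(vab, va + vb)
        doubled = toy_dataset.subset_samples(np.r_[np.arange(12), np.arange(12)])
        p1 = kse_profile(toy_dataset, 500_000)
        p2 = kse_profile(doubled, 500_000)
        assert np.allclose(p2.kse_gain, 2 * p1.kse_gain)
        assert np.allclose(p2.kse_loss, 2 * p1.kse_loss)

    def test_sign_invariants(self, toy_dataset):
        p = kse_profile(toy_dataset, 500_000)
        assert np.all(p.kse_gain >= 0) and np.all(p.kse_loss <= 0)


class TestNullThreshold:
    def test_seed_contract(self, toy_dataset):
        t1 = kse_null_threshold(toy_dataset, "gain", 500_000, n_permutations=50, seed=3)
        t2 = kse_null_threshold(toy_dataset, "gain", 500_000, n_permutations=50, seed=3)
        t3 = kse_null_threshold(toy_dataset, "gain", 500_000, n_permutations=50, seed=4)
        assert t1 == t2 and t1 != t3

    def test_alpha_one_gives_min_of_maxima(self, toy_dataset):
        t = kse_null_threshold(toy_dataset, "gain", 500_000, n_permutations=30,
                               alpha=1.0, seed=0)
        prof = kse_profile(toy_dataset, 500_000)
        assert prof.kse_gain.max() >= t  # the real profile exceeds it somewhere

    def test_too_few_permutations_rejected(self, toy_dataset):
        with pytest.raises(ValueError, match="at least 20"):
            kse_null_threshold(toy_dataset, "gain", 500_000, n_permutations=10)
        with pytest.raises(ValueError, match="too small"):
            kse_null_threshold(toy_dataset, "gain", 500_000, n_permutations=25,
                               alpha=0.001)

    def test_pointwise_bonferroni_track(self, toy_dataset):
        df = kse_pointwise_pvalues(toy_dataset, "gain", 500_000,
                                   n_permutations=50, seed=1)
        assert ((df["p_value"] > 0) & (df["p_value"] <= 1)).all()
        assert (df["p_bonferroni"] >= df["p_value"]).all()


def _profile_with_thresholds(grid, gain, loss, tg, tl, spacing):
    return KseProfile(grid, gain, loss, 1e6, spacing, 1,
                      threshold_gain=tg, threshold_loss=tl, n_permutations=99)


class TestSignificantRegions:
    def test_below_threshold_empty(self, toy_clone_map):
        grid, vals = kse(np.ones(len(toy_clone_map)), toy_clone_map, 500_000)
        prof = _profile_with_thresholds(grid, vals, -vals, vals.max() + 1,
                                        -vals.max() - 1, 500_000)
        assert len(significant_regions(prof)) == 0

    def test_thresholds_required(self, toy_dataset):
        with pytest.raises(ValueError, match="no thresholds"):
            significant_regions(kse_profile(toy_dataset, 500_000))

    def test_planted_gain_yields_one_overlapping_region(self):
        seg = AberrationSegment("20", 35_000_000, 55_000_000, 1.0, 1.0)
        spec = small_spec(shared_segments=[], specific_segments=[seg],
                          noise_sd=0.1, sample_offset_sd=0.0,
                          group_sizes={"A": 10}, seed=21)
        ds, _ = generate_cohort(spec)
        prof = kse_profile(ds, 250_000)
        prof = with_null_thresholds(prof, ds, n_permutations=99, seed=1)
        regions = significant_regions(prof)
        gains = regions[regions["sign"] == "gain"]
        assert len(gains) == 1
        r = gains.iloc[0]
        assert r["chromosome"] == "20"
        assert r["start_bp"] < 55_000_000 and r["end_bp"] > 35_000_000

    def test_two_separated_gains_ordered(self):
        segs = [AberrationSegment("17", 5_000_000, 15_000_000, 1.2, 1.0),
                AberrationSegment("17", 50_000_000, 60_000_000, 1.2, 1.0)]
        spec = small_spec(chromosomes=("17",), shared_segments=[], specific_segments=segs,
                          noise_sd=0.1, sample_offset_sd=0.0, group_sizes={"A": 10}, seed=22)
        ds, _ = generate_cohort(spec)
        prof = kse_profile(ds, 250_000)
        prof = with_null_thresholds(prof, ds, n_permutations=99, seed=5)
        gains = significant_regions(prof).query("sign == 'gain'").reset_index(drop=True)
        assert len(gains) == 2
        assert gains.loc[0, "end_bp"] <= gains.loc[1, "start_bp"]
        assert gains.loc[0, "start_bp"] < 15_000_000
        assert gains.loc[1, "end_bp"] > 50_000_000


class TestCorrelation:
    def _profile(self, grid, gain, loss):
        return KseProfile(grid, gain, loss, 1e6, 500_000, 1)

    def test_self_and_negation(self, toy_dataset):
        p = kse_profile(toy_dataset, 500_000)
        q = self._profile(p.grid, -p.kse_gain + p.kse_gain.mean() * 2, p.kse_loss)
        assert kse_correlation(p, p, "gain") == pytest.approx(1.0)
        assert kse_correlation(p, q, "gain") == pytest.approx(-1.0)

    def test_grid_mismatch_and_zero_variance(self, toy_dataset):
        p = kse_profile(toy_dataset, 500_000)
        q = kse_profile(toy_dataset, 250_000)
        with pytest.raises(ValueError, match="different grids"):
            kse_correlation(p, q, "gain")
        flat = self._profile(p.grid, np.ones_like(p.kse_gain), p.kse_loss)
        with pytest.warns(UserWarning, match="zero-variance"):
            assert np.isnan(kse_correlation(p, flat, "gain"))

    def test_replicate_cohorts_highly_correlated(self):
        """Two cohorts drawn from the same spec (different seeds) share the
        recurrent-aberration landscape."""
        p1 = kse_profile(generate_cohort(small_spec(seed=31))[0], 250_000)
        p2 = kse_profile(generate_cohort(small_spec(seed=32))[0], 250_000)
        assert kse_correlation(p1, p2, "gain") > 0.8
        assert kse_correlation(p1, p2, "loss") > 0.8
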