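"""Phase-bin statistics: centering, MC baselines, contrasts, PRI, FDR."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from clasphase import PhaseBinGrid, SimConfig
from clasphase.simulate import simulate_trial_table
from clasphase.stats import (benjamini_hochberg, bin_contrast_tests,
                             build_bin_summaries, compute_pri, mc_baseline,
                             mean_center, pri_group_tests,
                             spindle_likelihood_null,
                             spindle_likelihood_tests, welch_t,
                             continuous_phase_analysis)

GRID = PhaseBinGrid()


class TestMeanCenter:
    def test_simple_example(self):
        np.testing.assert_allclose(mean_center([10, 20, 30]), [-10, 0, 10])

    def test_single_value_becomes_zero(self):
        np.testing.assert_allclose(mean_center([7.0]), [0.0])

    def test_subjects_centered_independently(self):
        df = pd.DataFrame({"subject_id": [0, 0, 1, 1],
                           "is_stim": [True] * 4,
                           "v": [1.0, 3.0, 10.0, 30.0]})
        from clasphase.stats import mean_center_by_subject
        out = mean_center_by_subject(df, "v")
        assert out[df.subject_id == 0].sum() == pytest.approx(0.0)
        assert out[df.subject_id == 1].sum() == pytest.approx(0.0)


class TestMcBaseline:
    def test_degenerate_values_reproduce_constant(self, rng):
        draws = mc_baseline(np.full(10, 4.2), 200, rng)
        np.testing.assert_allclose(draws, 4.2)

    def test_draw_mean_matches_sample_mean(self, rng):
        values = rng.normal(10, 2, size=50)
        draws = mc_baseline(values, 200, rng)
        se = values.std(ddof=1) / np.sqrt(200)
        assert abs(draws.mean() - values.mean()) < 3 * values.std(ddof=1) / np.sqrt(200) + 1.0

    def test_single_value_is_missing_bin(self, rng):
        assert mc_baseline(np.array([1.0]), 200, rng) is None

    def test_seeded_reproducibility(self):
        v = np.arange(10.0)
        d1 = mc_baseline(v, 200, np.random.default_rng(5))
        d2 = mc_baseline(v, 200, np.random.default_rng(5))
        np.testing.assert_array_equal(d1, d2)


class TestWelch:
    def test_matches_scipy(self, rng):
        for _ in range(10):
            a = rng.normal(0, 1, 30)
            b = rng.normal(0.3, 2, 45)
            t, p = welch_t(a, b)
            ref = sps.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(ref.statistic, rel=1e-9)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_zero_variance_pair_gives_zero(self):
        t, p = welch_t(np.full(5, 1.0), np.full(5, 1.0))
        assert t == 0.0


class TestBenjaminiHochberg:
    def test_worked_example(self):
        reject, _ = benjamini_hochberg([0.01, 0.02, 0.04, 0.06], alpha=0.05)
        assert reject.tolist() == [True, True, False, False]

    def test_all_tiny_all_rejected(self):
        reject, _ = benjamini_hochberg([0.001] * 8)
        assert reject.all()

    def test_all_large_none_rejected(self):
        reject, _ = benjamini_hochberg([0.9] * 8)
        assert not reject.any()

    def test_adjusted_p_monotone_in_rank(self, rng):
        p = rng.uniform(size=50)
        _, p_adj = benjamini_hochberg(p)
        order = np.argsort(p)
        assert np.all(np.diff(p_adj[order]) >= -1e-12)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])


class TestPri:
    def test_forced_ordering(self, rng):
        dists = {0: rng.normal(0, 0.001, 200),
                 1: rng.normal(1, 0.001, 200),
                 2: rng.normal(2, 0.001, 200)}
        pri = compute_pri(dists, 3)
        assert [pri[0], pri[1], pri[2]] == [-1.0, 0.0, 1.0]

    def test_identical_constant_distributions_give_zero(self):
        dists = {b: np.full(200, 3.3) for b in range(4)}
        assert all(v == 0.0 for v in compute_pri(dists, 4).values())

    def test_range_and_antisymmetry(self, rng):
        dists = {b: rng.normal(rng.normal(), 1, 200) for b in range(24)}
        pri = compute_pri(dists, 24)
        vals = np.array(list(pri.values()))
        assert np.all(vals >= -1) and np.all(vals <= 1)
        assert np.sum(vals) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for trial in range(5):
            bins = list(range(rng.integers(3, 7)))
            dists = {b: rng.normal(rng.normal(), rng.uniform(0.5, 2), 20)
                     for b in bins}
            pri = compute_pri(dists, len(bins))
            # oracle: double loop over scipy Welch t-tests
            for a in bins:
                signs = []
                for b in bins:
                    if a == b:
                        continue
                    t = sps.ttest_ind(dists[a], dists[b],
                                      equal_var=False).statistic
                    signs.append(np.sign(t))
                assert pri[a] == pytest.approx(np.mean(signs))


class TestSpindleLikelihoodNull:
    def test_all_positive_gives_one(self, rng):
        assert spindle_likelihood_null(np.ones(30, bool), rng=rng) == 1.0

    def test_all_negative_hits_continuity_floor(self, rng):
        m = int(np.floor(2 / 3 * 30))
        assert spindle_likelihood_null(np.zeros(30, bool), rng=rng) == \
            pytest.approx(1.0 / (2 * m))

    def test_half_likelihood_geometric_mean_slightly_below(self, rng):
        flags = np.zeros(300, bool)
        flags[:150] = True
        null = spindle_likelihood_null(flags, rng=rng)
        assert 0.45 <= null <= 0.50

    def test_too_few_trials_raise(self, rng):
        with pytest.raises(ValueError):
            spindle_likelihood_null(np.ones(2, bool), rng=rng)


def _null_table(seed, n_subjects=8, n_stim=120, n_unstim=60):
    cfg = SimConfig(n_subjects=n_subjects, seed=seed,
                    evoked_gain_so=0.0, evoked_gain_lf=0.0, evoked_gain_hf=0.0,
                    evoked_spindle_gain_so=0.0, evoked_hr_gain_so=0.0,
                    evoked_base_amp=180.0)
    return simulate_trial_table(cfg, n_stim, n_unstim,
                                np.random.default_rng(seed))


class TestBinContrasts:
    def test_zero_contrasts_are_never_significant(self):
        grid = GRID
        from clasphase.stats import BinSummary
        summaries = {}
        for subj in range(6):
            for b in range(24):
                summaries[(subj, b)] = BinSummary(
                    subject_id=subj, bin_index=b, bin_center=grid.centers[b],
                    n_stim=10, n_unstim=10, stim_mean=0.0, unstim_mean=0.0,
                    mc_draws=np.zeros(200))
        out = bin_contrast_tests(summaries, grid)
        assert not out["significant"].any()

    def test_injected_effect_detected_in_covering_bins(self):
        cfg = SimConfig(n_subjects=12, seed=100, evoked_gain_so=30.0,
                        evoked_gain_lf=0.0, evoked_gain_hf=0.0)
        tab = simulate_trial_table(cfg, 200, 100, np.random.default_rng(100),
                                   resid_sd_uv=15.0)
        summaries = build_bin_summaries(tab, "phi_so", "so_p2p_uv", GRID,
                                        seed=100)
        out = bin_contrast_tests(summaries, GRID)
        sig = out[out["significant"]]["bin_center"].to_numpy()
        covering = sig[np.abs((sig - 75.0 + 180) % 360 - 180) <= 30]
        assert len(covering) > 0

    def test_untested_bins_excluded_from_family(self):
        tab = _null_table(1, n_subjects=2)
        summaries = build_bin_summaries(tab, "phi_so", "so_p2p_uv", GRID, seed=1)
        out = bin_contrast_tests(summaries, GRID, min_subjects=3)
        assert (~out["tested"]).all()
        assert out["p_fdr"].isna().all()

    def test_end_to_end_reproducibility_given_seed(self):
        tab = _null_table(7)
        t1 = continuous_phase_analysis(tab, seed=7)
        t2 = continuous_phase_analysis(tab, seed=7)
        for k in t1:
            pd.testing.assert_frame_equal(t1[k], t2[k])


class TestSpindleLikelihoodTests:
    def test_identical_conditions_not_significant(self):
        tab = _null_table(3)
        out = spindle_likelihood_tests(tab, "phi_so", GRID, seed=3)
        assert not out["significant"].any()

    def test_single_subject_is_untested(self):
        tab = _null_table(4, n_subjects=1)
        out = spindle_likelihood_tests(tab, "phi_so", GRID, seed=4)
        assert not out["tested"].any()

    def test_so_coupling_detected_only_for_so_phase(self):
        cfg = SimConfig(n_subjects=12, seed=11, evoked_spindle_gain_so=0.25)
        tab = simulate_trial_table(cfg, 250, 120, np.random.default_rng(11))
        out_so = spindle_likelihood_tests(tab, "phi_so", GRID, seed=11)
        out_lf = spindle_likelihood_tests(tab, "phi_lf", GRID, seed=11)
        out_hf = spindle_likelihood_tests(tab, "phi_hf", GRID, seed=11)
        assert out_so["significant"].sum() >= 1
        assert out_lf["significant"].sum() == 0
        assert out_hf["significant"].sum() == 0


class TestPriGroup:
    def test_group_pri_peaks_near_injected_optimum(self):
        cfg = SimConfig(n_subjects=10, seed=21, evoked_gain_so=30.0,
                        evoked_gain_lf=0.0, evoked_gain_hf=0.0)
        tab = simulate_trial_table(cfg, 250, 120, np.random.default_rng(21),
                                   resid_sd_uv=15.0)
        summaries = build_bin_summaries(tab, "phi_so", "so_p2p_uv", GRID,
                                        seed=21)
        out = pri_group_tests(summaries, GRID)
        best = out.loc[out["mean_pri"].idxmax(), "bin_center"]
        assert abs((best - 75.0 + 180) % 360 - 180) <= 30.0
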