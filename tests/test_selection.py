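"""FIR deconvolution r^2, permutation nulls, FDR and cluster selection."""

import numpy as np
import pandas as pd
import pytest

import bold_linearity as bl
from bold_linearity.core import TimeCourse
from bold_linearity.selection import (
    NullDistribution,
    build_null,
    fdr_bh,
    fir_r2,
    select_voxels,
    stimulus_indicator,
)


def _tc(values, unit="percent"):
    return TimeCourse(np.asarray(values, float), 1.0, unit=unit)


def _noiseless_localizer():
    # compact-support HRF (c = 0, decayed below 1e-7 by 24 s) so the
    # 25-sample FIR window spans the whole impulse response
    hrf = bl.HRFParams(4.0, 5.0, 10.0, 1.2, 1.0, 0.0, 0.5)
    par = bl.generate_paradigm("localizer")
    neural = bl.NeuralModel(adaptation_baseline=(0.0, 15.0))
    tc = bl.simulate_voxel(par, hrf, neural, bl.NoiseModel.zero())
    return bl.percent_signal_change(tc, 0), stimulus_indicator(par)


class TestFirR2:
    def test_noiseless_block_response_fully_explained(self):
        tc, stim = _noiseless_localizer()
        fir, r2 = fir_r2(tc, stim, 25)
        assert r2 == pytest.approx(1.0, abs=1e-9)
        assert fir.mean_early_response() > 0

    def test_stimulus_orthogonal_course(self):
        par = bl.generate_paradigm("localizer")
        t = np.arange(240.0)
        tc = _tc(np.sin(2 * np.pi * t / 240 * 7.3))  # unrelated frequency
        _, r2 = fir_r2(tc, stimulus_indicator(par), 1)
        assert r2 < 0.05

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        par = bl.generate_paradigm("localizer")
        stim = stimulus_indicator(par)
        y = rng.normal(0, 1, 240)
        _, r2 = fir_r2(_tc(y), stim, 25)
        # explicit pseudoinverse oracle
        X = np.zeros((240, 26))
        for k in range(25):
            X[k:, k] = stim[: 240 - k]
        X[:, 25] = 1.0
        beta = np.linalg.pinv(X) @ y
        resid = y - X @ beta
        r2_oracle = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
        assert r2 > 0
        assert r2 == pytest.approx(r2_oracle, abs=1e-10)

    def test_affine_invariance(self):
        tc, stim = _noiseless_localizer()
        rng = np.random.default_rng(1)
        noisy = tc.with_values(tc.values + rng.normal(0, 0.3, len(tc)))
        _, r2 = fir_r2(noisy, stim, 25)
        _, r2_scaled = fir_r2(noisy.with_values(3.0 * noisy.values + 7.0), stim, 25)
        assert r2_scaled == pytest.approx(r2, abs=1e-10)

    def test_rank_deficient_design_rejected(self):
        with pytest.raises(ValueError, match="rank-deficient"):
            fir_r2(_tc(np.random.default_rng(0).normal(0, 1, 100)),
                   np.ones(100), 5)  # constant stimulus collinear w/ intercept


class TestBuildNull:
    @staticmethod
    def _null(n_total=500, seed=0, **kw):
        rng = np.random.default_rng(42)
        sources = [TimeCourse(rng.normal(0, 1, 240), 1.0, unit="raw")
                   for _ in range(4)]
        par = bl.generate_paradigm("localizer")
        stim = stimulus_indicator(par)
        return build_null(
            sources,
            pipeline=lambda tc: bl.preprocess_localizer(
                tc.with_values(tc.values + 100.0)),
            statistic=lambda tc: fir_r2(tc, stim, 25)[1],
            n_total=n_total, seed=seed, **kw)

    def test_threshold_is_empirical_quantile(self):
        null = self._null()
        assert null.threshold(0.05) == pytest.approx(
            np.quantile(null.samples, 0.95))
        assert null.threshold(0.001) == pytest.approx(
            np.quantile(null.samples, 0.999))

    def test_threshold_fraction_calibrated(self):
        null = self._null(n_total=1000)
        frac = np.mean(null.samples > null.threshold(0.05))
        assert frac == pytest.approx(0.05, abs=2 * np.sqrt(0.05 * 0.95 / 1000))

    def test_shuffle_preserves_value_multiset(self):
        src = TimeCourse(np.arange(240.0), 1.0)
        seen = []
        build_null([src], pipeline=lambda tc: tc,
                   statistic=lambda tc: seen.append(np.sort(tc.values)) or 0.0,
                   n_total=100, seed=3)
        for vals in seen:
            assert np.array_equal(vals, np.arange(240.0))

    def test_ar1_null_runs(self):
        null = self._null(n_total=100, null_model="ar1")
        assert len(null.samples) == 100
        assert np.all((null.samples >= 0) & (null.samples <= 1))

    def test_empirical_fpr_never_zero(self):
        null = NullDistribution("r2", np.linspace(0, 1, 999))
        assert null.empirical_fpr(2.0) == pytest.approx(1 / 1000)


class TestFdrBH:
    def test_hand_worked_example(self):
        adjusted, reject = fdr_bh([0.01, 0.02, 0.03, 0.04], 0.05)
        assert adjusted == pytest.approx([0.04, 0.04, 0.04, 0.04])
        assert reject.all()

    def test_single_p_unchanged(self):
        adjusted, _ = fdr_bh([0.123])
        assert adjusted == pytest.approx([0.123])

    def test_uniform_small_p_all_rejected(self):
        _, reject = fdr_bh([0.0005] * 8, 0.001)
        assert reject.all()

    def test_matches_brute_force_step_up(self):
        """BH adjusted p-values equal the textbook step-up definition
        min_{j >= rank(i)} (m * p_(j) / j) on 1000 random p-vectors."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            m = rng.integers(1, 40)
            p = rng.uniform(0, 1, m)
            adjusted, _ = fdr_bh(p, 0.05)
            order = np.argsort(p)
            sorted_adj = np.minimum.accumulate(
                (m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
            oracle = np.minimum(1.0, sorted_adj)[np.argsort(order)]
            assert np.max(np.abs(adjusted - oracle)) < 1e-12


class TestSelectVoxels:
    @staticmethod
    def _table(r2s, coords=None):
        n = len(r2s)
        coords = coords or [(i, 0, 0) for i in range(n)]
        return pd.DataFrame({
            "voxel_id": range(n),
            "x": [c[0] for c in coords], "y": [c[1] for c in coords],
            "z": [c[2] for c in coords], "r2": r2s,
            "fir_positive": [True] * n,
        })

    NULL = NullDistribution("r2", np.linspace(0, 0.4, 2000))

    def test_all_subthreshold_selects_nothing(self):
        out = select_voxels(self._table([0.1, 0.2, 0.15]), self.NULL,
                            q=0.01, min_cluster=1)
        assert not out["selected"].any()

    def test_isolated_voxel_excluded_by_cluster_rule(self):
        coords = [(0, 0, 0), (5, 5, 0), (5, 6, 0)]
        out = select_voxels(self._table([0.9, 0.9, 0.9], coords), self.NULL,
                            q=0.05, min_cluster=2)
        assert out["selected"].tolist() == [False, True, True]

    def test_planted_block_recovered_exactly(self):
        coords = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0),
                  (4, 4, 0), (5, 5, 1), (6, 4, 0), (7, 7, 1)]
        r2s = [0.9, 0.85, 0.95, 0.88] + [0.1, 0.15, 0.12, 0.2]
        out = select_voxels(self._table(r2s, coords), self.NULL,
                            q=0.05, min_cluster=4)
        assert out["selected"].tolist() == [True] * 4 + [False] * 4

    def test_negative_fir_response_disqualifies(self):
        table = self._table([0.9, 0.9, 0.9, 0.9])
        table.loc[0, "fir_positive"] = False
        out = select_voxels(table, self.NULL, q=0.05, min_cluster=1)
        assert out["selected"].tolist() == [False, True, True, True]

    def test_missing_coords_rejected_for_clustering(self):
        table = self._table([0.9, 0.9]).drop(columns=["z"])
        with pytest.raises(ValueError, match="coordinates"):
            select_voxels(table, self.NULL, q=0.05, min_cluster=2)

    def test_false_selection_rate_on_pure_noise(self):
        """Empirical false-selection proportion at q=0.05, min_cluster=1
        stays within 2 SE of nominal over 50 pure-noise datasets."""
        n_datasets, n_vox = 50, 8
        total, selected = 0, 0
        for i in range(n_datasets):
            cfg = bl.SimulationConfig(seed=10_000 + i, active_fraction=0.0)
            ds = bl.simulate_dataset(n_vox, cfg)
            settings = bl.AnalysisSettings(n_null=150, seed=i)
            table = bl.workflow.localizer_r2_table(ds, settings)
            null = bl.workflow.localizer_null(ds, settings)
            out = select_voxels(table, null, q=0.05, min_cluster=1)
            total += n_vox
            selected += int(out["selected"].sum())
        rate = selected / total
        assert rate <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / total)
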