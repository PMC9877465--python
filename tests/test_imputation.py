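"""GP imputation of missing FHR samples and its recovery metrics."""

import numpy as np
import pytest

from edmgp.imputation import ImputationResult, ImputationTask, evaluate, impute, missingness_sweep
from edmgp.series import TimeSeries
from edmgp.simulate import SyntheticCTGConfig, make_mask, simulate_ctg


def _masked(ts, mask):
    out = ts.copy()
    out.values[mask] = np.nan
    return out


@pytest.fixture(scope="module")
def ctg_segment():
    """Complete 2-min coupled CTG segment at 4 Hz with a contraction inside."""
    cfg = SyntheticCTGConfig(
        duration_min=2.0, contraction_rate_per_10min=10.0,
        deceleration_gain_bpm=35.0, deceleration_lag_s=2.0,
        contraction_width_s=8.0, variability_lengthscale_s=2.5,
    )
    return simulate_ctg(cfg, seed=3)


class TestEvaluate:
    def test_log_mse_unit_residuals(self):
        res = ImputationResult(np.array([0, 1]), np.array([1.0, 1.0]), None, "cubic_spline")
        with pytest.warns(UserWarning, match="zero energy"):
            log_mse, snr = evaluate(np.zeros(2), res)
        assert log_mse == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(snr)

    def test_snr_hand_example(self):
        res = ImputationResult(np.array([0]), np.array([1.0]), None, "cubic_spline")
        _, snr = evaluate(np.array([2.0]), res)
        assert snr == pytest.approx(10 * np.log10(4.0), abs=1e-9)

    def test_joint_scaling_homogeneity(self):
        rng = np.random.default_rng(0)
        s = rng.normal(140, 5, 30)
        shat = s + rng.normal(0, 1, 30)
        res1 = ImputationResult(np.arange(30), shat, None, "x")
        res2 = ImputationResult(np.arange(30), 3 * shat, None, "x")
        lm1, snr1 = evaluate(s, res1)
        lm2, snr2 = evaluate(3 * s, res2)
        assert snr2 == pytest.approx(snr1, rel=1e-12)
        assert lm2 - lm1 == pytest.approx(2 * np.log(3), rel=1e-9)

    def test_zero_residual_gives_inf_snr(self):
        res = ImputationResult(np.array([0]), np.array([2.0]), None, "x")
        log_mse, snr = evaluate(np.array([2.0]), res)
        assert snr == np.inf and log_mse == -np.inf

    def test_zero_truth_energy_warns_with_nan_snr(self):
        res = ImputationResult(np.array([0]), np.array([1.0]), None, "x")
        with pytest.warns(UserWarning, match="zero energy"):
            _, snr = evaluate(np.array([0.0]), res)
        assert np.isnan(snr)

    def test_vacuous_task_metrics_undefined(self):
        res = ImputationResult(np.empty(0, int), np.empty(0), None, "x")
        with pytest.raises(ValueError, match="vacuous"):
            evaluate(np.zeros(3), res)


class TestImpute:
    def test_no_missing_returns_empty(self, ctg_segment):
        fhr, ua = ctg_segment
        res = impute(ImputationTask(fhr, ua))
        assert res.mean.size == 0 and res.missing_index.size == 0

    def test_interior_point_on_smooth_signal(self):
        t = np.arange(480) / 4.0
        x = 140 + 10 * np.sin(2 * np.pi * t / 60)
        masked = x.copy()
        masked[200] = np.nan
        task = ImputationTask(TimeSeries(masked), method="gp_time_only", seed=0)
        res = impute(task)
        assert abs(res.mean[0] - x[200]) < 0.1

    def test_estimates_cover_exactly_missing_indices(self, ctg_segment):
        fhr, ua = ctg_segment
        mask = make_mask(fhr.n, fraction=0.3, seed=5)
        res = impute(ImputationTask(_masked(fhr, mask), ua))
        np.testing.assert_array_equal(res.missing_index, np.flatnonzero(mask))
        assert res.mean.size == mask.sum()

    def test_posterior_variance_at_least_noise_floor(self, ctg_segment):
        fhr, ua = ctg_segment
        mask = make_mask(fhr.n, fraction=0.2, seed=1)
        res = impute(ImputationTask(_masked(fhr, mask), ua))
        noise = res.hyperparameters["noise_variance"]
        assert np.all(res.variance >= noise - 1e-9)

    def test_constant_ua_reduces_to_time_only(self, ctg_segment):
        """With the UA column constant, the bivariate GP should reproduce the
        time-only predictions within optimizer tolerance."""
        fhr, ua = ctg_segment
        mask = make_mask(fhr.n, fraction=0.2, seed=2)
        flat_ua = TimeSeries(np.full(ua.n, 20.0), fs=ua.fs)
        m = _masked(fhr, mask)
        res_bi = impute(ImputationTask(m, flat_ua, method="gp_bivariate", seed=0))
        res_t = impute(ImputationTask(m, None, method="gp_time_only", seed=0))
        rmse = np.sqrt(np.mean((res_bi.mean - res_t.mean) ** 2))
        assert rmse < 1.0  # bpm; same information content up to optimizer noise

    def test_all_missing_rejected(self):
        ts = TimeSeries(np.full(100, np.nan))
        with pytest.raises(ValueError, match="entirely missing"):
            impute(ImputationTask(ts, method="cubic_spline"))

    def test_bivariate_without_ua_rejected(self):
        vals = np.ones(100)
        vals[5] = np.nan
        with pytest.raises(ValueError, match="requires a synchronized UA"):
            impute(ImputationTask(TimeSeries(vals), None, method="gp_bivariate"))

    def test_unknown_method_rejected(self, ctg_segment):
        fhr, ua = ctg_segment
        with pytest.raises(ValueError, match="unknown method"):
            ImputationTask(fhr, ua, method="kriging")


class TestSweep:
    def test_table_is_reproducible(self, ctg_segment):
        fhr, ua = ctg_segment
        kw = dict(fractions=(0.3,), repeats=2, seed=9, methods=("cubic_spline",))
        t1 = missingness_sweep(fhr, ua, **kw)
        t2 = missingness_sweep(fhr, ua, **kw)
        assert t1.equals(t2)

    def test_extreme_fraction_skipped(self, ctg_segment):
        fhr, ua = ctg_segment
        with pytest.warns(UserWarning, match="skipped"):
            t = missingness_sweep(fhr, ua, fractions=(0.999,), repeats=1,
                                  methods=("cubic_spline",))
        assert t.empty

    def test_bivariate_gp_matches_or_beats_time_only(self, ctg_segment):
        """With the nested warm start the bivariate GP never does worse than
        the time-only GP on average: the UA dimension is activated only when
        it pays (under uniform random missingness on this generator it ties)."""
        fhr, ua = ctg_segment
        table = missingness_sweep(
            fhr, ua, fractions=(0.5,), repeats=5, seed=0, fit_maxiter=100,
            methods=("gp_bivariate", "gp_time_only"),
        )
        means = table.groupby("method")["snr"].mean()
        assert means["gp_bivariate"] >= means["gp_time_only"] - 0.5
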