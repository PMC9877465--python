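"""Hausdorff interaction feature, baseline CTG features, pH correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import directed_hausdorff

from edmgp.features import (
    FeatureConfig,
    approximate_entropy,
    band_energies,
    baseline_features,
    feature_ph_correlation,
    hausdorff,
    manifold_interaction,
    sample_entropy,
    short_long_term_variability,
)
from edmgp.manifold import ManifoldConfig
from edmgp.series import TimeSeries
from edmgp.simulate import SyntheticCTGConfig, simulate_ctg

FAST = FeatureConfig(
    E=6, manifold=ManifoldConfig(n_inducing=15, max_points=150, maxiter=120)
)


class TestHausdorff:
    def test_identity(self):
        A = np.random.default_rng(0).standard_normal((20, 3))
        assert hausdorff(A, A) == 0.0

    def test_hand_example_1d(self):
        A = np.array([[0.0], [1.0]])
        B = np.array([[0.0], [10.0]])
        assert hausdorff(A, B) == 9.0

    def test_matches_scipy_oracle_and_metric_properties(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            A = rng.standard_normal((rng.integers(2, 15), 3))
            B = rng.standard_normal((rng.integers(2, 15), 3))
            C = rng.standard_normal((rng.integers(2, 15), 3))
            h_ab = hausdorff(A, B)
            oracle = max(directed_hausdorff(A, B)[0], directed_hausdorff(B, A)[0])
            assert h_ab == pytest.approx(oracle, abs=1e-12)
            # metric properties
            assert h_ab == pytest.approx(hausdorff(B, A))
            assert h_ab >= 0
            assert h_ab <= hausdorff(A, C) + hausdorff(C, B) + 1e-12

    def test_brute_force_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        A = rng.standard_normal((50, 3))
        B = rng.standard_normal((50, 3))

        def directed(P, Q):
            return max(min(np.linalg.norm(p - q) for q in Q) for p in P)

        assert hausdorff(A, B) == pytest.approx(max(directed(A, B), directed(B, A)), abs=1e-12)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            hausdorff(np.empty((0, 2)), np.zeros((3, 2)))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            hausdorff(np.zeros((3, 2)), np.zeros((3, 4)))


class TestManifoldInteraction:
    def test_identical_series_zero_distance(self):
        t = np.arange(700)
        x = np.sin(2 * np.pi * t / 50) + 0.1 * np.random.default_rng(0).standard_normal(t.size)
        # same series, same seed on both channels -> identical manifolds
        cfg = FeatureConfig(
            E=6, manifold=ManifoldConfig(n_inducing=15, max_points=150, maxiter=120)
        )
        cfg.manifold.seed = 5
        h_aa = manifold_interaction(x, x, cfg)
        # reconstruction seeds differ per channel, so allow optimizer-level slack
        assert h_aa < 1.5

    def test_symmetric_in_arguments(self):
        A = np.random.default_rng(0).standard_normal((30, 2))
        B = np.random.default_rng(1).standard_normal((40, 2))
        assert hausdorff(A, B) == hausdorff(B, A)


class TestBaselineFeatures:
    def test_sinusoid_energy_lands_in_lf_band(self):
        fs = 4.0
        t = np.arange(int(10 * 60 * fs)) / fs
        ts = TimeSeries(np.sin(2 * np.pi * 0.1 * t), fs=fs)
        bands = band_energies(ts)
        assert bands["lf"] / bands["total"] >= 0.99

    def test_band_energies_partition_total_power(self):
        rng = np.random.default_rng(2)
        ts = TimeSeries(rng.standard_normal(4 * 600), fs=4.0)
        bands = band_energies(ts)
        in_band = bands["vlf"] + bands["lf"] + bands["mf"] + bands["hf"]
        # 4 Hz sampling puts the whole 0-2 Hz periodogram inside the bands
        assert in_band == pytest.approx(bands["total"], rel=1e-6)

    def test_constant_series_has_zero_variability_and_entropy(self):
        ts = TimeSeries(np.full(4 * 240, 140.0), fs=4.0)
        stv, ltv = short_long_term_variability(ts)
        assert stv == 0.0 and ltv == 0.0
        assert sample_entropy(ts) == 0.0
        assert approximate_entropy(ts) == 0.0

    def test_noise_has_higher_sample_entropy_than_sinusoid(self):
        rng = np.random.default_rng(3)
        n = 800
        noise = rng.standard_normal(n)
        t = np.arange(n)
        sine = np.sqrt(2.0) * np.sin(2 * np.pi * t / 50)  # matched variance
        assert sample_entropy(noise) > sample_entropy(sine)

    def test_short_segment_rejected_for_stv(self):
        ts = TimeSeries(np.ones(100), fs=4.0)
        with pytest.raises(ValueError, match="2 minutes"):
            short_long_term_variability(ts)

    def test_full_feature_vector_on_synthetic_ctg(self):
        fhr, _ = simulate_ctg(SyntheticCTGConfig(duration_min=4), seed=0)
        feats = baseline_features(fhr)
        for key in ("stv", "ltv", "vlf", "lf", "mf", "hf", "apen", "sampen"):
            assert feats[key] >= 0
        assert np.isfinite(feats["lf_mf_hf_ratio"])


class TestPhCorrelation:
    def _table(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({"f1": rng.standard_normal(n), "f2": rng.standard_normal(n)})

    def test_feature_equal_to_ph_has_unit_correlation(self):
        df = self._table()
        ph = df["f1"].to_numpy()
        corr = feature_ph_correlation(df, ph)
        assert corr.loc["f1", "ph"] == pytest.approx(1.0)

    def test_negated_feature_has_minus_one(self):
        df = self._table()
        corr = feature_ph_correlation(df, -df["f2"].to_numpy())
        assert corr.loc["f2", "ph"] == pytest.approx(-1.0)

    def test_constant_column_rejected(self):
        df = self._table()
        df["f3"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            feature_ph_correlation(df, df["f1"].to_numpy())

    def test_too_few_records_rejected(self):
        df = self._table(n=2)
        with pytest.raises(ValueError, match="at least 3"):
            feature_ph_correlation(df, np.array([7.2, 7.3]))

    def test_planted_correlation_recovered(self):
        """Simulation shaped like the cohort analysis: a feature generated as
        -0.12 x standardized pH + matched-variance noise recovers the planted
        correlation within its 95% sampling band at n=200."""
        rng = np.random.default_rng(42)
        n = 200
        ph = rng.normal(7.2, 0.08, n)
        z = (ph - ph.mean()) / ph.std()
        rho = -0.12
        h = rho * z + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        df = pd.DataFrame({"hd": h, "other": rng.standard_normal(n)})
        corr = feature_ph_correlation(df, ph)
        assert corr.loc["hd", "ph"] == pytest.approx(rho, abs=0.15)
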