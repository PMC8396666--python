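"""Stress reduction, block averaging, Hooke fits, slippage recovery."""

import numpy as np
import pytest

from fibrilmetrics.core import Trajectory
from fibrilmetrics.mechanics import (
    StressSeries,
    StressStrainCurve,
    StressStrainPoint,
    block_average,
    build_curve,
    detect_equilibration,
    fit_youngs_modulus,
    slippage_profile,
)
from fibrilmetrics.metrics import end_to_end
from fibrilmetrics.synthetic import (
    StrainSpec,
    StressSeriesSpec,
    apply_strain,
    gen_stress_series,
)


class TestBlockAverage:
    def test_constant_vector(self):
        mean, se = block_average(np.full(100, 3.7))
        assert (mean, se) == (pytest.approx(3.7), 0.0)

    def test_hand_computed_two_blocks(self):
        mean, se = block_average([1.0, 2.0, 3.0, 4.0], n_blocks=2)
        assert mean == pytest.approx(2.5)
        # block means (1.5, 3.5); sample std sqrt(2); se = sqrt(2)/sqrt(2) = 1
        assert se == pytest.approx(1.0)

    def test_mean_equals_plain_mean_with_remainder(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=107)  # 107 = 10*10 + 7 remainder
        mean, _ = block_average(v, n_blocks=10)
        assert mean == pytest.approx(v.mean(), abs=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            block_average([1.0, 2.0], n_blocks=10)

    def test_iid_se_calibration(self):
        """For i.i.d. data the block SE approximates 1/sqrt(n)."""
        rng = np.random.default_rng(5)
        ses = []
        for _ in range(100):
            _, se = block_average(rng.normal(size=10_000))
            ses.append(se)
        assert np.mean(ses) == pytest.approx(1.0 / 100.0, rel=0.3)


class TestEquilibration:
    def test_constant_series_first_point(self):
        s = StressSeries(np.arange(1, 101, dtype=float), np.full(100, 2.0))
        assert detect_equilibration(s) == 1.0

    def test_exponential_relaxation_within_5_tau(self):
        spec = StressSeriesSpec(modulus_E=500.0, epsilon=0.04, tau_eq=10.0,
                                noise_sd=0.0, n_points=1000, dt=0.1)
        t_eq = detect_equilibration(gen_stress_series(spec, seed=0))
        assert t_eq <= 50.0

    def test_linear_drift_errors(self):
        t = np.arange(1, 201, dtype=float)
        with pytest.raises(ValueError, match="plateau"):
            detect_equilibration(StressSeries(t, 0.5 * t))

    def test_too_short_rejected(self):
        t = np.arange(1, 20, dtype=float)
        with pytest.raises(ValueError):
            detect_equilibration(StressSeries(t, np.zeros_like(t)))


def noiseless_curve(E=500.0, strains=(0.0, 0.01, 0.02, 0.03, 0.04, 0.05)):
    series = {
        eps: gen_stress_series(
            StressSeriesSpec(modulus_E=E, epsilon=eps, tau_eq=5.0,
                             noise_sd=0.0, n_points=600, dt=0.1), seed=0)
        for eps in strains
    }
    return series


class TestBuildCurve:
    def test_noiseless_points_on_hooke_line(self):
        curve = build_curve(noiseless_curve())
        for p in curve.points:
            if p.epsilon > 0:
                assert p.mean_stress == pytest.approx(500.0 * p.epsilon, rel=0.01)

    def test_sigma0_subtracted(self):
        t = np.arange(1, 101, dtype=float)
        series = {0.0: StressSeries(t, np.full(100, 0.1), sigma0=0.1)}
        curve = build_curve(series)
        assert curve.points[0].mean_stress == pytest.approx(0.0, abs=1e-12)

    def test_missing_reference_rejected(self):
        series = noiseless_curve(strains=(0.01, 0.02))
        with pytest.raises(ValueError, match="eps=0"):
            build_curve(series)

    def test_duplicate_strains_rejected(self):
        p = StressStrainPoint(0.01, 5.0, 0.1)
        with pytest.raises(ValueError, match="duplicate"):
            StressStrainCurve([StressStrainPoint(0.0, 0.0, 0.0), p, p])

    def test_auto_mode_skips_transient_on_noisy_series(self):
        """With realistic noise the half-comparison rule rejects windows that
        still contain the relaxation transient."""
        series = {
            eps: gen_stress_series(
                StressSeriesSpec(modulus_E=500.0, epsilon=eps, tau_eq=10.0,
                                 noise_sd=1.0, n_points=1000, dt=0.1),
                seed=31 + int(eps * 1000))
            for eps in (0.0, 0.04)
        }
        t_eq = detect_equilibration(series[0.04])
        curve = build_curve(series, mode="auto")
        point = [p for p in curve.points if p.epsilon == 0.04][0]
        assert point.mean_stress == pytest.approx(20.0, abs=5 * point.se + 0.3)


class TestYoungsModulus:
    def test_exact_points_machine_precision(self):
        points = [StressStrainPoint(e, 321.0 * e, 0.0) for e in
                  (0.0, 0.01, 0.03, 0.05)]
        E, se = fit_youngs_modulus(StressStrainCurve(points))
        assert E == pytest.approx(321.0, rel=1e-12)
        assert se == pytest.approx(0.0, abs=1e-9)

    def test_single_point_ratio(self):
        points = [StressStrainPoint(0.0, 0.0, 0.0), StressStrainPoint(0.05, 25.0, 0.0)]
        E, _ = fit_youngs_modulus(StressStrainCurve(points))
        assert E == pytest.approx(500.0)

    def test_points_beyond_linear_regime_ignored(self):
        points = [StressStrainPoint(0.0, 0.0, 0.0),
                  StressStrainPoint(0.02, 10.0, 0.0),
                  StressStrainPoint(0.10, 20.0, 0.0)]  # softened, outside eps_max
        E, _ = fit_youngs_modulus(StressStrainCurve(points))
        assert E == pytest.approx(500.0)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(2)
        points = [StressStrainPoint(0.0, 0.0, 0.1)] + [
            StressStrainPoint(e, 400 * e + rng.normal(0, 0.5), 0.5)
            for e in (0.01, 0.02, 0.03, 0.04, 0.05)
        ]
        E1, _ = fit_youngs_modulus(StressStrainCurve(points))
        scaled = [StressStrainPoint(p.epsilon, 3.0 * p.mean_stress, 3.0 * p.se)
                  for p in points]
        E3, _ = fit_youngs_modulus(StressStrainCurve(scaled))
        assert E3 == pytest.approx(3.0 * E1, rel=1e-12)

    def test_no_points_in_range_rejected(self):
        points = [StressStrainPoint(0.0, 0.0, 0.0), StressStrainPoint(0.08, 40.0, 0.0)]
        with pytest.raises(ValueError):
            fit_youngs_modulus(StressStrainCurve(points), eps_max=0.05)

    def test_monte_carlo_recovery_and_coverage(self):
        """Noisy pipelines: mean recovered E within 2%, ~95% of +-2 SE
        intervals cover the truth."""
        E_true = 500.0
        strains = (0.0, 0.01, 0.02, 0.03, 0.04, 0.05)
        estimates, covered = [], 0
        n_seeds = 50
        for seed in range(n_seeds):
            series = {
                eps: gen_stress_series(
                    StressSeriesSpec(modulus_E=E_true, epsilon=eps),
                    seed=1000 * seed + k)
                for k, eps in enumerate(strains)
            }
            curve = build_curve(series)
            E, se = fit_youngs_modulus(curve)
            estimates.append(E)
            if abs(E - E_true) <= 2 * se:
                covered += 1
        assert np.mean(estimates) == pytest.approx(E_true, rel=0.02)
        assert covered / n_seeds >= 0.90


class TestSlippage:
    def test_affine_response_no_slippage(self):
        points = [StressStrainPoint(0.0, 0.0, 0.0, 1.0)] + [
            StressStrainPoint(e, 500 * e, 0.1, 1.0 + e) for e in (0.01, 0.03, 0.05)
        ]
        s = slippage_profile(StressStrainCurve(points))
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in s.values())

    def test_rigid_cell_elongation_full_slippage(self):
        points = [StressStrainPoint(0.0, 0.0, 0.0, 1.0),
                  StressStrainPoint(0.04, 20.0, 0.1, 1.0)]
        s = slippage_profile(StressStrainCurve(points))
        assert s[0.04] == pytest.approx(1.0)

    def test_generator_slippage_recovered(self, small_frame):
        f_true = 0.3
        L0, _ = end_to_end(Trajectory.from_frame(small_frame))
        for eps in (0.01, 0.03, 0.05):
            strained = apply_strain(small_frame,
                                    StrainSpec(epsilon=eps, slippage=f_true))
            L, _ = end_to_end(Trajectory.from_frame(strained))
            s = 1.0 - (L / L0 - 1.0) / eps
            assert s == pytest.approx(f_true, abs=1e-9)

    def test_no_usable_points_rejected(self):
        points = [StressStrainPoint(0.0, 0.0, 0.0, 1.0)]
        with pytest.raises(ValueError):
            slippage_profile(StressStrainCurve(points))


def test_stress_series_csv_round_trip(tmp_path):
    spec = StressSeriesSpec(modulus_E=400.0, epsilon=0.02)
    series = gen_stress_series(spec, seed=3)
    path = tmp_path / "stress.csv"
    series.to_csv(path)
    back = StressSeries.from_csv(path)
    assert np.allclose(back.times, series.times)
    assert np.allclose(back.sigma_parallel, series.sigma_parallel)
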