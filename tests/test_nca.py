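import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irinopbpk.nca import (
    InsufficientDataError,
    InvalidSlopeError,
    ObservedDataset,
    auc_extrapolate,
    auc_trapezoid,
    cmax_tmax,
    mrt,
    run_nca,
    terminal_slope,
)
from irinopbpk.pbpk_engine import DoseRegimen


def dataset(t, c, species="X", regimen=None):
    return ObservedDataset(samples={species: (np.asarray(t, float),
                                              np.asarray(c, float))},
                           regimen=regimen)


def mono_exp(t, c0, k):
    return c0 * np.exp(-k * np.asarray(t, float))


class TestAucTrapezoid:
    def test_reference_sn38_auc(self, observed):
        assert auc_trapezoid(observed, "SN-38") == pytest.approx(26.74, abs=0.005)

    def test_reference_cpt11_auc(self, observed):
        assert auc_trapezoid(observed, "CPT-11") == pytest.approx(1444.965,
                                                                  abs=1e-9)

    def test_rectangle(self):
        ds = dataset([1.0, 3.0], [5.0, 5.0])
        assert auc_trapezoid(ds, "X") == pytest.approx(5.0 * 2.0 * 60.0)

    def test_single_point_rejected(self):
        with pytest.raises(InsufficientDataError):
            auc_trapezoid(dataset([1.0], [5.0]), "X")

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(2, 20), st.integers(0, 10_000))
    def test_matches_pairwise_sum_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        t = np.sort(rng.uniform(0, 30, n))
        t += np.arange(n) * 1e-6  # enforce strict increase
        c = rng.uniform(0, 20, n)
        expected = sum((t[i + 1] - t[i]) * (c[i + 1] + c[i]) / 2.0
                       for i in range(n - 1)) * 60.0
        assert auc_trapezoid(dataset(t, c), "X") == pytest.approx(
            expected, abs=1e-9 * max(1.0, expected))


class TestCmaxTmax:
    def test_reference_cpt11(self, observed):
        assert cmax_tmax(observed, "CPT-11") == (11.6, 1.56)

    def test_reference_sn38(self, observed):
        assert cmax_tmax(observed, "SN-38") == (0.1, 1.56)

    def test_monotone_decreasing_profile_peaks_first(self):
        ds = dataset([1, 2, 3], [9.0, 4.0, 1.0])
        assert cmax_tmax(ds, "X") == (9.0, 1.0)

    def test_tie_broken_by_earliest_time(self):
        ds = dataset([1, 2, 3], [7.0, 7.0, 1.0])
        assert cmax_tmax(ds, "X") == (7.0, 1.0)


class TestTerminalSlope:
    def test_exact_mono_exponential(self):
        t = np.linspace(1, 20, 8)
        ds = dataset(t, mono_exp(t, 10.0, 0.3))
        lam, t_half = terminal_slope(ds, "X")
        assert lam == pytest.approx(0.3, abs=1e-10)
        assert t_half == pytest.approx(math.log(2) / 0.3, abs=1e-10)

    def test_reference_cpt11_tail_matches_regression_oracle(self, observed):
        # closed-form least squares on the last three log-concentrations
        t = np.array([9.5, 13.5, 25.5])
        y = np.log(np.array([0.8, 0.38, 0.14]))
        n = 3
        slope = (n * (t * y).sum() - t.sum() * y.sum()) \
            / (n * (t * t).sum() - t.sum() ** 2)
        lam, t_half = terminal_slope(observed, "CPT-11", 3)
        assert lam == pytest.approx(-slope, rel=1e-10)
        assert t_half == pytest.approx(math.log(2) / -slope, rel=1e-10)

    def test_noisy_recovery_within_five_percent(self):
        rng = np.random.default_rng(2024)
        t = np.linspace(2, 30, 8)
        k = 0.25
        estimates = []
        for _ in range(100):
            c = mono_exp(t, 5.0, k) * np.exp(rng.normal(0, 0.1, len(t)))
            _, t_half = terminal_slope(dataset(t, c), "X", 8)
            estimates.append(t_half)
        assert abs(np.median(estimates) - math.log(2) / k) \
            < 0.05 * math.log(2) / k

    def test_auto_selection_prefers_linear_tail(self):
        t = np.array([0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 24.0])
        c = 8.0 * np.exp(-1.5 * t) + 2.0 * np.exp(-0.1 * t)
        lam, _ = terminal_slope(dataset(t, c), "X", 3, selection="auto")
        assert lam == pytest.approx(0.1, rel=0.05)

    def test_nonpositive_terminal_concentration_rejected(self):
        with pytest.raises(InsufficientDataError):
            terminal_slope(dataset([1, 2, 3], [1.0, 0.5, 0.0]), "X")


class TestAucExtrapolate:
    def test_zero_tail(self):
        ds = dataset([1, 2, 3], [4.0, 2.0, 0.0])
        auc_inf, pct = auc_extrapolate(ds, "X", 0.5)
        assert auc_inf == auc_trapezoid(ds, "X")
        assert pct == 0.0

    def test_five_half_lives_extrapolation_fraction(self):
        k = 0.4
        t = np.linspace(0, 5 * math.log(2) / k, 400)
        ds = dataset(t, mono_exp(t, 10.0, k))
        _, pct = auc_extrapolate(ds, "X", k)
        assert abs(pct - 100.0 * 2.0**-5) < 1.0

    def test_tail_linear_in_last_concentration(self):
        base = dataset([1, 2, 3], [4.0, 2.0, 1.0])
        double = dataset([1, 2, 3], [4.0, 2.0, 2.0])
        lam = 0.3
        inc1 = auc_extrapolate(base, "X", lam)[0] - auc_trapezoid(base, "X")
        inc2 = auc_extrapolate(double, "X", lam)[0] - auc_trapezoid(double, "X")
        assert inc2 == pytest.approx(2.0 * inc1, rel=1e-12)

    def test_invalid_lambda_rejected(self):
        with pytest.raises(InvalidSlopeError):
            auc_extrapolate(dataset([1, 2], [1.0, 0.5]), "X", 0.0)


class TestMrt:
    def test_bolus_mono_exponential(self):
        k = 0.2
        t = np.linspace(0.01, 60, 4000)
        ds = dataset(t, mono_exp(t, 10.0, k))
        assert mrt(ds, "X", 0.0) == pytest.approx(1.0 / k, rel=0.01)

    def test_infusion_correction_is_half_duration(self):
        t = np.linspace(0.5, 30, 50)
        ds = dataset(t, mono_exp(t, 5.0, 0.3))
        tau_min = 90.0
        assert mrt(ds, "X", 0.0) - mrt(ds, "X", tau_min) \
            == pytest.approx(tau_min / 60.0 / 2.0, abs=1e-12)

    def test_aumc_against_brute_force_oracle(self, observed):
        t, c = observed.get("CPT-11")
        aumc_oracle = sum((t[i + 1] - t[i])
                          * (t[i + 1] * c[i + 1] + t[i] * c[i]) / 2.0
                          for i in range(len(t) - 1))
        assert float(np.trapezoid(t * c, t)) == pytest.approx(aumc_oracle,
                                                              abs=1e-9)


class TestRunNca:
    def test_mono_exponential_recovers_clearance_and_volume(self):
        k, v, bw = 0.2, 50.0, 70.0  # 1/h, L, kg
        dose = 1000.0  # umol bolus
        t = np.linspace(0.001, 80, 8000)
        ds = dataset(t, dose / v * np.exp(-k * t),
                     regimen=DoseRegimen(total_dose=1.0, dose_per_bsa=None,
                                         infusion_duration=1e-6))
        res = run_nca(ds, "X", dose_umol=dose, body_weight=bw)
        cl_true = k * v / 60.0 * 1000.0 / bw   # ml/min/kg
        assert res.clearance == pytest.approx(cl_true, rel=0.01)
        assert res.vd_plasma == pytest.approx(v * 1000.0 / bw, rel=0.01)
        assert res.half_life == pytest.approx(math.log(2) / k, rel=0.01)

    def test_reference_sn38_auc_via_full_nca(self, observed):
        res = run_nca(observed, "SN-38")
        assert res.auc_tend == pytest.approx(26.74, abs=0.005)
        assert res.auc_inf > res.auc_tend
        assert res.pct_auc_extrapolated == pytest.approx(
            100.0 * (res.auc_inf - res.auc_tend) / res.auc_inf, abs=1e-12)

    def test_single_point_yields_not_available_fields(self):
        res = run_nca(dataset([2.0], [3.0]), "X")
        assert res.cmax == 3.0 and res.tmax == 2.0
        for name in ("auc_tend", "auc_inf", "half_life", "mrt",
                     "clearance", "vd_plasma"):
            assert math.isnan(getattr(res, name))

    def test_duplicate_point_insertion_is_invariant(self, observed):
        t, c = observed.get("CPT-11")
        t2 = np.insert(t, 3, t[3])
        c2 = np.insert(c, 3, c[3])
        a = run_nca(observed, "CPT-11")
        b = run_nca(dataset(t2, c2, species="CPT-11"), "CPT-11")
        assert a.auc_tend == b.auc_tend
        assert a.lambda_z == b.lambda_z

    def test_unsorted_times_rejected(self):
        with pytest.raises(InsufficientDataError):
            dataset([1.0, 3.0, 2.0], [3.0, 2.0, 1.0])
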