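"""Unit tests for the non-compartmental analysis engine."""

import math

import numpy as np
import pytest

from herbipk import auc_0_t, find_cmax_tmax, fit_lambda_z, run_nca
from herbipk.errors import (
    InsufficientDataError,
    NoQuantifiableDataError,
    TerminalPhaseError,
)
from herbipk.pk_nca import _segment_areas, usable_points

from _oracles import brute_force_lambda_z, trapezoid_sums

from conftest import make_profile


class TestCmaxTmax:
    @pytest.mark.parametrize(
        "times, concs, expected",
        [
            ([0.083, 0.25, 0.5, 1], [10, 728, 300, 100], (728.0, 0.25)),
            ([0.25, 0.5, 1, 2], [5, 7, 7, 2], (7.0, 0.5)),  # tie -> earliest
            ([1, 2, 3], [9, 4, 1], (9.0, 1.0)),  # monotone decline
        ],
    )
    def test_examples(self, times, concs, expected):
        assert find_cmax_tmax(make_profile(times, concs)) == expected

    def test_all_blq_raises(self):
        p = make_profile([1, 2, 3], [0.1, 0.1, 0.1], blq=[1, 1, 1], lloq=1.0)
        with pytest.raises(NoQuantifiableDataError):
            find_cmax_tmax(p)

    def test_blq_points_excluded_from_cmax(self):
        # a huge BLQ-flagged artefact must not become Cmax
        p = make_profile([1, 2, 3], [5.0, 999.0, 2.0], blq=[0, 1, 0], lloq=1.0)
        assert find_cmax_tmax(p) == (5.0, 1.0)


class TestAUC:
    def test_rectangle(self):
        p = make_profile([0, 1, 2], [10, 10, 10])
        auc, _ = auc_0_t(p, method="linear")
        assert auc == pytest.approx(20.0)

    def test_triangle_with_blq_endpoints(self):
        # zero endpoints are BLQ: the leading one stays as 0, the trailing drops
        p = make_profile([0, 1, 2], [0, 10, 0], blq=[1, 0, 1], lloq=1.0)
        auc, aumc = auc_0_t(p, method="linear")
        assert auc == pytest.approx(5.0)
        assert aumc == pytest.approx(5.0)  # (0*0 + 1*10)/2

    def test_log_down_segment_closed_form(self):
        auc, _ = _segment_areas(0.0, 1.0, 10.0, 5.0, log_down=True)
        assert auc == pytest.approx(5.0 / math.log(2.0), rel=1e-12)

    def test_log_down_matches_fine_grid_integral(self):
        # exponential interpolation between (0,20) and (1,10): numeric oracle
        lam = math.log(2.0)
        tt = np.linspace(0, 1, 200001)
        numeric = np.trapezoid(20.0 * np.exp(-lam * tt), tt)
        auc, _ = _segment_areas(0.0, 1.0, 20.0, 10.0, log_down=True)
        assert auc == pytest.approx(numeric, rel=1e-9)

    def test_log_down_profile(self):
        p = make_profile([0, 1, 2], [20, 10, 5])
        auc, _ = auc_0_t(p, method="linear-up/log-down")
        assert auc == pytest.approx(15.0 / math.log(2.0), rel=1e-12)

    def test_log_rule_falls_back_on_rise(self):
        # rising segment uses the linear rule even under linear-up/log-down
        p = make_profile([0, 1, 2], [5, 10, 5])
        auc_mixed, _ = auc_0_t(p, method="linear-up/log-down")
        assert auc_mixed == pytest.approx(7.5 + 5.0 / math.log(2.0), rel=1e-12)

    def test_collinear_midpoint_invariance(self):
        rng = np.random.default_rng(7)
        times = np.array([0.5, 1.0, 2.0, 4.0, 8.0])
        concs = rng.uniform(1, 100, size=len(times))
        base, _ = auc_0_t(make_profile(times, concs), "linear")
        # insert the linear midpoint of segment 2: AUC must not change
        # (AUMC may: t*C(t) is quadratic along a linear-C segment)
        tm = 0.5 * (times[2] + times[3])
        cm = 0.5 * (concs[2] + concs[3])
        t2 = np.insert(times, 3, tm)
        c2 = np.insert(concs, 3, cm)
        auc2, _ = auc_0_t(make_profile(t2, c2), "linear")
        assert auc2 == pytest.approx(base, rel=1e-12)

    def test_matches_explicit_segment_sums(self):
        rng = np.random.default_rng(3)
        times = np.sort(rng.uniform(0.1, 24, size=9))
        concs = rng.uniform(1, 500, size=9)
        p = make_profile(times, concs)
        auc, aumc = auc_0_t(p, "linear")
        o_auc, o_aumc = trapezoid_sums(times, concs)
        assert auc == pytest.approx(o_auc, rel=1e-12)
        assert aumc == pytest.approx(o_aumc, rel=1e-12)

    def test_insufficient_points(self):
        # only the first point is quantifiable; both trailing BLQ points drop
        p = make_profile([1, 2, 3], [10.0, 0.1, 0.1], blq=[0, 1, 1], lloq=1.0)
        with pytest.raises(InsufficientDataError):
            auc_0_t(p)


class TestLambdaZ:
    def test_exact_exponential_recovers_rate(self):
        # mono-exponential tail after an early peak: every window is exact
        tail_t = np.array([4.0, 8.0, 12.0, 24.0])
        concs = np.concatenate([[1000.0], 100.0 * np.exp(-0.5 * tail_t)])
        p = make_profile(np.concatenate([[0.1], tail_t]), concs)
        fit = fit_lambda_z(p)
        assert fit.lambda_z == pytest.approx(0.5, rel=1e-12)
        assert fit.adj_r2 == pytest.approx(1.0)
        assert fit.n_points == 4  # ties broken toward the longest window

    @pytest.mark.parametrize("k", [3, 4, 5, 6])
    def test_any_window_on_noise_free_decay(self, k):
        t = np.linspace(1, 20, k + 1)
        concs = np.concatenate([[500.0], 80.0 * np.exp(-0.31 * t[1:])])
        p = make_profile(t, concs)
        fit = fit_lambda_z(p, min_points=3)
        assert fit.lambda_z == pytest.approx(0.31, rel=1e-10)

    def test_rising_terminal_phase_not_estimable(self):
        p = make_profile([1, 2, 3, 4, 5], [50, 1, 2, 3, 4])
        with pytest.raises(TerminalPhaseError):
            fit_lambda_z(p)

    def test_too_few_points(self):
        p = make_profile([1, 2, 3], [0.01, 10, 5], blq=[1, 0, 0], lloq=1.0)
        with pytest.raises(InsufficientDataError):
            fit_lambda_z(p)

    def test_matches_brute_force_on_noisy_decay(self):
        rng = np.random.default_rng(2024)
        times = np.array([0.083, 0.25, 0.5, 1, 2, 4, 8, 12, 24], dtype=float)
        for _ in range(25):
            ke = rng.uniform(0.05, 0.8)
            ka = rng.uniform(2.0, 20.0)
            scale = rng.uniform(10, 1000)
            c = scale * ka / (ka - ke) * (np.exp(-ke * times) - np.exp(-ka * times))
            c = np.maximum(c * (1 + 0.1 * rng.normal(size=len(times))), 1e-3)
            p = make_profile(times, c)
            oracle = brute_force_lambda_z(times, c)
            if oracle is None:
                with pytest.raises((TerminalPhaseError, InsufficientDataError)):
                    fit_lambda_z(p)
                continue
            fit = fit_lambda_z(p)
            lz, icpt, n_pts, adj = oracle
            assert fit.n_points == n_pts
            assert fit.lambda_z == pytest.approx(lz, rel=1e-9)
            assert fit.intercept == pytest.approx(icpt, rel=1e-9)


class TestRunNCA:
    def test_halving_sequence_hand_arithmetic(self):
        p = make_profile([1, 2, 3], [10, 5, 2.5])
        r = run_nca(p)
        assert (r.cmax, r.tmax) == (10.0, 1.0)
        assert r.lambda_fit.lambda_z == pytest.approx(math.log(2.0), rel=1e-10)
        assert r.t_half == pytest.approx(1.0, rel=1e-10)
        assert r.auc_0_t == pytest.approx(11.25)
        assert r.auc_0_inf == pytest.approx(11.25 + 2.5 / math.log(2.0), rel=1e-10)
        assert r.mrt_0_inf == pytest.approx(r.aumc_0_inf / r.auc_0_inf)
        assert 0 <= r.pct_extrapolated < 100

    def test_lambda_not_estimable_contract(self):
        # quantifiable data but a rising tail: AUC0-t present, tail fields None
        p = make_profile([1, 2, 3, 4, 5], [50, 1, 2, 3, 4])
        r = run_nca(p)
        assert r.auc_0_t > 0
        for fld in ("auc_0_inf", "t_half", "mrt_0_inf", "vz_f", "clz_f",
                    "pct_extrapolated"):
            assert getattr(r, fld) is None

    def test_halving_concentrations_scales_parameters(self):
        times = np.array([0.25, 0.5, 1, 2, 4, 8, 12, 24], dtype=float)
        concs = 300.0 * np.exp(-0.3 * times) * (1 - np.exp(-6 * times))
        p1 = make_profile(times, concs, dose=100.0)
        p2 = make_profile(times, concs / 2.0, dose=100.0)
        r1, r2 = run_nca(p1), run_nca(p2)
        assert r2.cmax == pytest.approx(r1.cmax / 2)
        assert r2.auc_0_t == pytest.approx(r1.auc_0_t / 2, rel=1e-12)
        assert r2.auc_0_inf == pytest.approx(r1.auc_0_inf / 2, rel=1e-9)
        assert r2.tmax == r1.tmax
        assert r2.t_half == pytest.approx(r1.t_half, rel=1e-9)
        assert r2.clz_f == pytest.approx(2 * r1.clz_f, rel=1e-9)
        assert r2.vz_f == pytest.approx(2 * r1.vz_f, rel=1e-9)

    def test_auc_inf_dominates_auc_t(self):
        rng = np.random.default_rng(11)
        times = np.array([0.083, 0.25, 0.5, 1, 2, 4, 8, 12, 24])
        for _ in range(20):
            ke = rng.uniform(0.05, 0.6)
            c = rng.uniform(50, 800) * np.exp(-ke * times) * (1 - np.exp(-8 * times))
            c *= np.exp(0.05 * rng.normal(size=len(times)))
            r = run_nca(make_profile(times, c))
            if r.auc_0_inf is not None:
                assert r.auc_0_inf >= r.auc_0_t >= 0

    def test_zero_dose_leaves_clearance_unset(self):
        p = make_profile([1, 2, 3, 4], [100, 50, 25, 12.5], dose=0.0)
        r = run_nca(p)
        assert r.clz_f is None and r.vz_f is None
        assert r.auc_0_inf is not None


class TestBLQPolicy:
    def test_trailing_and_interior_blq(self):
        times = [0.25, 0.5, 1, 2, 4, 8]
        concs = [0.0, 100, 50, 0.2, 10, 0.1]
        blq = [1, 0, 0, 1, 0, 1]
        t, c = usable_points(make_profile(times, concs, blq=blq, lloq=1.0))
        # leading BLQ kept as 0, interior dropped, trailing dropped
        assert list(t) == [0.25, 0.5, 1, 4]
        assert list(c) == [0.0, 100, 50, 10]
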