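"""Hill fitting, rundown correction, parallel fits, profile intervals."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pentafit as pf
from pentafit.dose_response import Curve, _hill, likelihood_interval
from pentafit.synthetic import DoseResponseScenario, simulate_dose_response


def hill_by_hand(a, i_max, ec50, n_h):
    """Independent evaluation of the Hill equation via exp/log only."""
    if a == 0:
        return 0.0
    return i_max / (1.0 + math.exp(n_h * (math.log(ec50) - math.log(a))))


class TestHillResponse:
    def test_half_maximum_identity(self):
        fit = pf.HillFit(i_max=3.2, ec50=17.0, n_h=2.1)
        assert pf.hill_response(17.0, fit) == pytest.approx(1.6, rel=1e-12)

    def test_limits(self):
        fit = pf.HillFit(i_max=2.0, ec50=10.0, n_h=1.5)
        assert pf.hill_response(0.0, fit) == 0.0
        assert pf.hill_response(1e12, fit) == pytest.approx(2.0, rel=1e-6)

    def test_against_hand_evaluation(self):
        # wild-type-like parameters, evaluated independently above
        fit = pf.HillFit(i_max=1.0, ec50=91.1, n_h=1.65)
        expected = hill_by_hand(30.0, 1.0, 91.1, 1.65)
        assert pf.hill_response(30.0, fit) == pytest.approx(expected, rel=1e-12)

    def test_negative_concentration_rejected(self):
        fit = pf.HillFit(i_max=1.0, ec50=1.0, n_h=1.0)
        with pytest.raises(pf.DomainError):
            pf.hill_response(-1.0, fit)

    @settings(max_examples=50, deadline=None)
    @given(
        ec50=st.floats(0.1, 1e4),
        n_h=st.floats(0.3, 5.0),
        i_max=st.floats(0.1, 1e4),
    )
    def test_monotone_in_concentration_and_imax(self, ec50, n_h, i_max):
        fit = pf.HillFit(i_max=i_max, ec50=ec50, n_h=n_h)
        conc = np.geomspace(ec50 * 1e-3, ec50 * 1e3, 40)
        resp = pf.hill_response(conc, fit)
        assert np.all(np.diff(resp) >= 0)
        fit2 = pf.HillFit(i_max=i_max * 2, ec50=ec50, n_h=n_h)
        assert np.all(pf.hill_response(conc, fit2) >= resp)


class TestRundownCorrect:
    def _cell(self, std_responses, test_responses):
        apps = []
        si, ti = iter(std_responses), iter(test_responses)
        # pattern: std t t std t t ... std
        pattern = ["s", "t", "t"] * (len(test_responses) // 2) + ["s"]
        for p in pattern:
            if p == "s":
                apps.append(pf.Application("ACh", 20.0, next(si), True))
            else:
                apps.append(pf.Application("ACh", 100.0, next(ti), False))
        return pf.DoseResponseCell("c1", apps)

    def test_equal_standards_identity(self):
        cell = self._cell([5.0, 5.0, 5.0], [2.0, 3.0, 4.0, 1.0])
        out = pf.rundown_correct(cell)
        for a, b in zip(cell.applications, out.applications):
            assert b.response == pytest.approx(a.response, rel=1e-12)

    def test_linear_decline_recovered_exactly(self):
        # standards decline linearly in application index to 80%; tests are
        # scaled by the same interpolated decline -> correction inverts it
        true_tests = [2.0, 3.0, 4.0, 1.0]
        n_apps = 7  # s t t s t t s
        decline = np.linspace(1.0, 0.8, n_apps)
        std0 = 5.0
        stds = [std0 * decline[0], std0 * decline[3], std0 * decline[6]]
        tests = [t * decline[i] for t, i in zip(true_tests, [1, 2, 4, 5])]
        out = pf.rundown_correct(self._cell(stds, tests))
        got = [a.response for a in out.applications if not a.is_standard]
        assert got == pytest.approx(true_tests, rel=1e-12)

    def test_single_standard_errors(self):
        apps = [
            pf.Application("ACh", 20.0, 5.0, True),
            pf.Application("ACh", 100.0, 2.0, False),
        ]
        with pytest.raises(pf.InsufficientDataError, match="skip correction|uncorrected"):
            pf.rundown_correct(pf.DoseResponseCell("c1", apps))


class TestFitHill:
    def test_noiseless_recovery(self):
        truth = pf.HillFit(i_max=2050.0, ec50=172.0, n_h=1.56)
        scen = DoseResponseScenario(
            true_hill=truth, noise_cv=0.0, rundown_per_application=0.0, n_cells=1
        )
        cells, _ = simulate_dose_response(scen, seed=0)
        fit = pf.fit_hill(pf.rundown_correct(cells[0]))
        assert fit.converged
        assert fit.i_max == pytest.approx(2050.0, rel=1e-6)
        assert fit.ec50 == pytest.approx(172.0, rel=1e-6)
        assert fit.n_h == pytest.approx(1.56, rel=1e-6)

    def test_noisy_recovery_within_own_interval(self):
        truth = pf.HillFit(i_max=2050.0, ec50=172.0, n_h=1.56)
        scen = DoseResponseScenario(
            true_hill=truth, noise_cv=0.05, rundown_per_application=0.0, n_cells=1
        )
        cells, _ = simulate_dose_response(scen, seed=7)
        fit = pf.fit_hill(pf.rundown_correct(cells[0]))
        assert fit.converged
        lo = fit.ec50 - 1.96 * fit.se_ec50
        hi = fit.ec50 + 1.96 * fit.se_ec50
        assert lo <= 172.0 <= hi

    def test_too_few_concentrations(self):
        apps = [
            pf.Application("ACh", c, r, False)
            for c, r in [(1.0, 0.1), (10.0, 0.5), (100.0, 0.9)]
        ]
        with pytest.raises(pf.InsufficientDataError):
            pf.fit_hill(pf.DoseResponseCell("c1", apps))

    def test_response_scaling_equivariance(self):
        conc = np.geomspace(1, 1000, 8)
        resp = _hill(conc, 2.0, 30.0, 1.4)
        cell = pf.DoseResponseCell(
            "c", [pf.Application("ACh", c, r, False) for c, r in zip(conc, resp)]
        )
        scaled = pf.DoseResponseCell(
            "c", [pf.Application("ACh", c, 3.5 * r, False) for c, r in zip(conc, resp)]
        )
        f1, f2 = pf.fit_hill(cell), pf.fit_hill(scaled)
        assert f2.i_max == pytest.approx(3.5 * f1.i_max, rel=1e-6)
        assert f2.ec50 == pytest.approx(f1.ec50, rel=1e-6)
        assert f2.n_h == pytest.approx(f1.n_h, rel=1e-6)


class TestParallelFit:
    def _curves(self, ec50s, n_h=1.6, npts=10):
        out = []
        for label, e in ec50s.items():
            conc = np.geomspace(e / 50, e * 50, npts)
            out.append(Curve(label, conc, _hill(conc, 1.0, e, n_h)))
        return out

    def test_self_ratio_is_one(self):
        conc = np.geomspace(1, 1000, 10)
        resp = _hill(conc, 1.0, 91.1, 1.6)
        noisy = resp * np.random.default_rng(3).lognormal(0, 0.03, conc.size)
        c1 = Curve("a", conc, noisy)
        c2 = Curve("b", conc, noisy.copy())
        res = pf.parallel_fit([c1, c2], "a")
        assert res.dose_ratios["a"] == 1.0
        iv = res.likelihood_intervals["b"]
        assert iv.low <= 1.0 <= iv.high

    def test_constructed_ratio_recovered(self):
        res = pf.parallel_fit(self._curves({"wt": 91.1, "mut": 5.51}), "wt")
        assert res.dose_ratios["mut"] == pytest.approx(5.51 / 91.1, rel=1e-6)

    def test_shifted_copies_return_construction_ratios(self):
        ratios = {"a": 1.0, "b": 0.2, "c": 3.7}
        curves = self._curves({k: 50.0 * v for k, v in ratios.items()})
        res = pf.parallel_fit(curves, "a", compute_intervals=False)
        for k, v in ratios.items():
            assert res.dose_ratios[k] == pytest.approx(v, rel=1e-6)

    def test_reference_relabelling_inverts_ratio(self):
        curves = self._curves({"wt": 91.1, "mut": 18.6})
        r1 = pf.parallel_fit(curves, "wt", compute_intervals=False)
        r2 = pf.parallel_fit(curves, "mut", compute_intervals=False)
        assert math.log10(r2.dose_ratios["wt"]) == pytest.approx(
            -math.log10(r1.dose_ratios["mut"]), abs=1e-6
        )

    def test_nonparallel_curves_flagged(self):
        conc = np.geomspace(1, 3000, 12)
        rng = np.random.default_rng(5)
        c1 = Curve("a", conc, _hill(conc, 1.0, 91.1, 0.9) * rng.lognormal(0, 0.02, conc.size))
        c2 = Curve("b", conc, _hill(conc, 1.0, 30.0, 2.4) * rng.lognormal(0, 0.02, conc.size))
        res = pf.parallel_fit([c1, c2], "a", compute_intervals=False)
        # the fit itself succeeds but the free-slope comparison exposes it
        assert res.parallelism_p < 0.01
        assert abs(res.free_slopes["a"] - res.free_slopes["b"]) > 1.0

    def test_missing_reference_errors(self):
        with pytest.raises(pf.ValidationError):
            pf.parallel_fit(self._curves({"a": 10.0}), "nope")


class TestLikelihoodInterval:
    def test_gaussian_mean_matches_two_se(self):
        # sample-mean model: profile RSS is quadratic; the 2.01-unit
        # interval approaches estimate +/- 2.005*SE as n grows
        rng = np.random.default_rng(0)
        y = rng.normal(5.0, 2.0, 200)
        muhat = y.mean()
        rss_min = float(((y - muhat) ** 2).sum())

        def profile(mu):
            return float(((y - mu) ** 2).sum())

        iv = likelihood_interval(profile, muhat, rss_min, y.size, delta=2.01)
        se = y.std(ddof=1) / math.sqrt(y.size)
        half = math.sqrt(2 * 2.01) * se
        assert iv.high - muhat == pytest.approx(half, rel=0.02)
        assert muhat - iv.low == pytest.approx(half, rel=0.02)

    def test_delta_to_zero_collapses(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0.0, 1.0, 50)
        muhat = y.mean()
        rss_min = float(((y - muhat) ** 2).sum())
        iv = likelihood_interval(
            lambda mu: float(((y - mu) ** 2).sum()), muhat, rss_min, y.size, delta=1e-10
        )
        assert iv.high - iv.low < 1e-4

    def test_grid_profile_oracle(self):
        # dense grid scan of the profiled RSS is the independent oracle for
        # the interval endpoints of a parallel-fit dose ratio
        rng = np.random.default_rng(3)
        conc = np.geomspace(1, 2000, 9)
        c1 = Curve("wt", conc, _hill(conc, 1.0, 91.1, 1.6) * rng.lognormal(0, 0.05, 9))
        c2 = Curve(
            "mut", conc / 5, _hill(conc / 5, 1.0, 18.0, 1.6) * rng.lognormal(0, 0.05, 9)
        )
        res = pf.parallel_fit([c1, c2], "wt")
        iv = res.likelihood_intervals["mut"]
        # oracle: profile over a dense log10-ratio grid
        from pentafit.dose_response import _fit_parallel

        n_obs = 18
        _, rss_min = _fit_parallel([c1, c2], 0)
        target = rss_min * math.exp(2 * 2.01 / n_obs)
        grid = np.linspace(math.log10(iv.low) - 0.3, math.log10(iv.high) + 0.3, 400)
        prof = np.array([_fit_parallel([c1, c2], 0, fixed={4: g})[1] for g in grid])
        below = grid[prof <= target]
        lo_oracle, hi_oracle = 10.0 ** below[0], 10.0 ** below[-1]
        assert iv.low == pytest.approx(lo_oracle, rel=5e-3)
        assert iv.high == pytest.approx(hi_oracle, rel=5e-3)
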