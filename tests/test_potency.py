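"""Partial-curve potency ratios, Fieller intervals, parallelism checks."""

import math
import warnings

import numpy as np
import pytest

import pentafit as pf
from pentafit.dose_response import _hill
from pentafit.potency import FiellerInterval, fieller_interval
from pentafit.synthetic import simulate_partial_curves


def make_cell(points, standard="ACh", cell_id="c1"):
    return pf.PartialCurveSet(
        cell_id=cell_id,
        points={a: (np.asarray(c, float), np.asarray(r, float)) for a, (c, r) in points.items()},
        standard_agonist=standard,
    )


class TestParallelPowerLaw:
    def test_one_logunit_shift_gives_ratio_ten(self):
        conc = np.array([1.0, 3.0, 10.0])
        resp = 0.1 * conc**1.5  # slope 1.5 line in log-log space
        cell = make_cell({"ACh": (conc, resp), "X": (conc / 10.0, resp)})
        fit = pf.fit_parallel_powerlaw(cell)
        assert fit.potency_ratios["X"] == pytest.approx(10.0, rel=1e-9)
        assert fit.slope == pytest.approx(1.5, abs=1e-9)

    def test_standard_against_itself_is_one(self):
        conc = np.array([1.0, 3.0, 10.0])
        cell = make_cell({"ACh": (conc, 0.1 * conc**2)})
        # a one-agonist panel is rejected; add a copy under another name
        cell2 = make_cell({"ACh": (conc, 0.1 * conc**2), "ACh2": (conc, 0.1 * conc**2)})
        fit = pf.fit_parallel_powerlaw(cell2)
        assert fit.potency_ratios["ACh"] == 1.0
        assert fit.potency_ratios["ACh2"] == pytest.approx(1.0, rel=1e-9)
        with pytest.raises(pf.InsufficientDataError):
            pf.fit_parallel_powerlaw(cell)

    def test_hill_built_panel_recovers_table_ratio(self):
        # ACh EC50 309.5 µM vs DMPP 30.3 µM, equal slopes, sampled at the
        # foot of the curve: true potency ratio 309.5/30.3 = 10.2
        rng = np.random.default_rng(12)
        ratios = []
        for i in range(20):
            cells, _ = simulate_partial_curves(
                {"ACh": 309.5, "DMPP": 30.3},
                n_h=2.19,
                i_max=686.0,
                seed=rng,
                n_cells=1,
                noise_cv=0.02,
                max_fraction=0.08,
            )
            fit = pf.fit_parallel_powerlaw(cells[0])
            ratios.append(fit.potency_ratios["DMPP"])
        mean = float(np.mean(ratios))
        mc_err = float(np.std(ratios, ddof=1) / math.sqrt(len(ratios)))
        assert mean == pytest.approx(309.5 / 30.3, abs=max(3 * mc_err, 0.35))

    def test_scale_equivariance(self):
        conc = np.array([1.0, 3.0, 10.0])
        resp = 0.1 * conc**1.5
        base = make_cell({"ACh": (conc, resp), "X": (conc / 5, resp)})
        scaled = make_cell({"ACh": (conc, resp), "X": (conc / 5 * 7.0, resp)})
        f1 = pf.fit_parallel_powerlaw(base)
        f2 = pf.fit_parallel_powerlaw(scaled)
        assert f2.potency_ratios["X"] == pytest.approx(f1.potency_ratios["X"] / 7.0, rel=1e-9)

    def test_parallel_equals_free_when_exactly_parallel(self):
        conc = np.array([1.0, 3.0, 10.0, 30.0])
        resp = 0.02 * conc**1.8
        cell = make_cell({"ACh": (conc, resp), "X": (conc / 4, resp)})
        par = pf.fit_parallel_powerlaw(cell)
        free = pf.fit_free_slopes(cell)
        for a in ("ACh", "X"):
            assert free[a][0] == pytest.approx(par.slope, abs=1e-9)


class TestFieller:
    def test_degenerate_reduces_to_t_interval(self):
        # zero-variance denominator, zero covariance: plain t interval on
        # the numerator, scaled by the denominator
        iv = fieller_interval(2.0, 4.0, var_numerator=0.09, var_denominator=0.0,
                              covariance=0.0, t_value=2.0)
        assert iv.low == pytest.approx(0.5 - 2.0 * 0.3 / 4.0, rel=1e-12)
        assert iv.high == pytest.approx(0.5 + 2.0 * 0.3 / 4.0, rel=1e-12)

    def test_contains_estimate(self):
        iv = fieller_interval(1.0, 1.0, 0.04, 0.04, 0.01, 2.1)
        assert iv.low <= 1.0 <= iv.high and not iv.unbounded

    def test_unbounded_flag_when_denominator_indistinct_from_zero(self):
        iv = fieller_interval(1.0, 0.5, 0.04, 1.0, 0.0, 2.0)
        assert iv.unbounded and iv.g >= 1.0

    def test_bootstrap_oracle(self):
        # parametric bootstrap of the ratio m/s under the same joint normal
        # is the independent oracle for the Fieller bounds
        m, s = 1.3, 2.0
        var_m, var_s, cov = 0.04, 0.02, 0.01
        z = 1.959963984540054  # normal quantile as t with large df
        iv = fieller_interval(m, s, var_m, var_s, cov, z)
        rng = np.random.default_rng(11)
        cov_mat = np.array([[var_m, cov], [cov, var_s]])
        draws = rng.multivariate_normal([m, s], cov_mat, size=100_000)
        ratios = draws[:, 0] / draws[:, 1]
        lo, hi = np.quantile(ratios, [0.025, 0.975])
        assert iv.low == pytest.approx(lo, rel=0.02)
        assert iv.high == pytest.approx(hi, rel=0.02)


class TestFreeSlopes:
    def test_exact_linear_loglog_slope(self):
        conc = np.array([1.0, 10.0, 100.0])
        cell = make_cell({"ACh": (conc, 0.5 * conc**2), "X": (conc, 0.1 * conc**2)})
        slopes = pf.fit_free_slopes(cell)
        assert slopes["X"][0] == pytest.approx(2.0, abs=1e-10)

    def test_low_concentration_limit_is_hill_slope(self):
        # at concentrations far below the EC50 the log-log slope of the
        # Hill curve tends to n_h
        n_h = 1.45
        for top_frac, tol in ((1e-2, 0.02), (1e-4, 0.001)):
            conc = 309.5 * top_frac * np.array([0.25, 0.5, 1.0])
            resp = _hill(conc, 1.0, 309.5, n_h)
            cell = make_cell({"ACh": (conc, resp), "X": (conc, resp)})
            slopes = pf.fit_free_slopes(cell)
            assert slopes["ACh"][0] == pytest.approx(n_h, abs=n_h * tol * 3)

    def test_single_point_agonist_skipped_with_warning(self):
        cell = make_cell(
            {"ACh": ([1.0, 10.0], [0.1, 1.0]), "X": ([5.0], [0.3])}
        )
        with pytest.warns(UserWarning, match="skipped"):
            slopes = pf.fit_free_slopes(cell)
        assert "X" not in slopes


class TestPooling:
    def _panel_cells(self, true_ratio, n_cells, seed, noise=0.02):
        cells, _ = simulate_partial_curves(
            {"ACh": 309.5, "DMPP": 309.5 / true_ratio},
            n_h=2.0,
            i_max=700.0,
            seed=seed,
            n_cells=n_cells,
            noise_cv=noise,
        )
        return [pf.fit_parallel_powerlaw(c) for c in cells]

    def test_identical_ratios_zero_sem(self):
        fits = self._panel_cells(2.0, 3, seed=4, noise=0.0)
        table = pf.pool_potency(fits)
        row = table.set_index("agonist").loc["DMPP"]
        assert row["sem"] == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("true_ratio,n_cells", [(1.0, 9), (10.0, 8)])
    def test_recovery_within_three_sem(self, true_ratio, n_cells):
        fits = self._panel_cells(true_ratio, n_cells, seed=42 + n_cells)
        table = pf.pool_potency(fits).set_index("agonist")
        row = table.loc["DMPP"]
        tol = max(3 * row["sem"], 0.02 * true_ratio)
        assert row["potency_ratio"] == pytest.approx(true_ratio, abs=tol)

    def test_single_cell_agonist_flagged(self):
        fits = self._panel_cells(2.0, 1, seed=9)
        with pytest.warns(UserWarning, match="single cell"):
            table = pf.pool_potency(fits)
        row = table.set_index("agonist").loc["DMPP"]
        assert bool(row["single_cell"]) and math.isnan(row["sem"])

    def test_rank_order_preserved_on_table_panel(self):
        # potency panel patterned on the oocyte measurements: epibatidine >>
        # lobeline > nicotine ~ cytisine > ACh > carbachol
        truth = {
            "ACh": 1.0,
            "epibatidine": 6290.0,
            "lobeline": 7.35,
            "nicotine": 1.43,
            "cytisine": 1.40,
            "carbachol": 0.094,
        }
        ok = 0
        rng = np.random.default_rng(17)
        n_rep = 40
        for _ in range(n_rep):
            cells, _ = simulate_partial_curves(
                {a: 138.0 / p for a, p in truth.items()},
                n_h=1.45,
                i_max=1270.0,
                seed=rng,
                n_cells=2,
                noise_cv=0.02,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fits = [pf.fit_parallel_powerlaw(c) for c in cells]
                table = pf.pool_potency(fits).set_index("agonist")
            est = table["potency_ratio"]
            order_ok = (
                est["epibatidine"] > est["lobeline"] > est["nicotine"]
                and est["epibatidine"] > 100 * est["lobeline"]
                and est["cytisine"] > est["ACh"] > est["carbachol"]
            )
            ok += order_ok
        assert ok / n_rep >= 0.95
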