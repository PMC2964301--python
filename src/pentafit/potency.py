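"""Agonist potency ratios from partial (foot-of-curve) dose-response data.

At concentrations well below the EC50 the Hill equation reduces to a power
law, I ≈ I_max (A/EC50)^nH, i.e. a straight line of slope nH in log-log
coordinates. Within one cell, a panel of agonists probed with 2-3 low
concentrations each is therefore fitted as a set of parallel lines: one
common slope s and a per-agonist intercept c_a. The horizontal displacement
of agonist a from the standard agonist (ACh) is (c_a − c_std)/s decades, and
the potency ratio — how many-fold more potent than ACh the agonist is — is
10^((c_a − c_std)/s). Confidence intervals for this ratio of two jointly
normal regression estimates come from Fieller's theorem; fitting each
agonist with its own free slope provides the parallelism check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from ._errors import DomainError, InsufficientDataError, ValidationError

__all__ = [
    "PartialCurveSet",
    "ParallelPowerLawFit",
    "FiellerInterval",
    "fit_parallel_powerlaw",
    "fieller_interval",
    "fit_free_slopes",
    "pool_potency",
]


@dataclass
class PartialCurveSet:
    """One cell's foot-of-curve points for a panel of agonists.

    ``points`` maps agonist name -> (concentration µM, response nA) arrays.
    Every cell must include the standard agonist (ACh by default).
    """

    cell_id: str
    points: dict[str, tuple[np.ndarray, np.ndarray]]
    standard_agonist: str = "ACh"

    def __post_init__(self) -> None:
        if self.standard_agonist not in self.points:
            raise ValidationError(
                f"cell {self.cell_id}: standard agonist "
                f"{self.standard_agonist!r} missing from the panel"
            )
        clean = {}
        for agonist, (conc, resp) in self.points.items():
            conc = np.asarray(conc, dtype=float)
            resp = np.asarray(resp, dtype=float)
            if conc.shape != resp.shape:
                raise ValidationError(f"{agonist}: shape mismatch")
            if np.any(conc <= 0):
                raise ValidationError(f"{agonist}: concentrations must be > 0")
            clean[agonist] = (conc, resp)
        self.points = clean


@dataclass
class FiellerInterval:
    low: float
    high: float
    unbounded: bool = False
    g: float = float("nan")


@dataclass
class ParallelPowerLawFit:
    """Common-slope log-log fit of one cell's agonist panel."""

    cell_id: str
    slope: float
    se_slope: float
    intercepts: dict[str, float]
    potency_ratios: dict[str, float]
    fieller_intervals: dict[str, FiellerInterval]  # on the ratio (not log) scale
    residual_df: int
    rss: float
    n_excluded_nonpositive: int = 0
    skipped_agonists: list[str] = field(default_factory=list)


def _usable_points(cell: PartialCurveSet) -> tuple[dict, int, list[str]]:
    """Drop non-positive responses (cannot be logged) and 1-point agonists."""
    usable = {}
    n_dropped = 0
    skipped = []
    for agonist, (conc, resp) in cell.points.items():
        keep = resp > 0
        n_dropped += int((~keep).sum())
        if keep.sum() < 2:
            skipped.append(agonist)
            continue
        usable[agonist] = (conc[keep], resp[keep])
    if n_dropped:
        warnings.warn(
            f"cell {cell.cell_id}: excluded {n_dropped} non-positive "
            "responses before log transform"
        )
    for agonist in skipped:
        warnings.warn(
            f"cell {cell.cell_id}: agonist {agonist!r} has < 2 usable "
            "points; skipped"
        )
    return usable, n_dropped, skipped


def fit_parallel_powerlaw(cell: PartialCurveSet) -> ParallelPowerLawFit:
    """Fit all agonists of one cell with parallel power functions.

    Ordinary least squares of log10(response) on log10(concentration) with
    one common slope and per-agonist intercepts, equal weighting. The
    potency ratio of agonist a is 10^((c_a − c_std)/s) with a Fieller
    interval from the joint covariance of the intercept difference and the
    slope.
    """
    usable, n_dropped, skipped = _usable_points(cell)
    if cell.standard_agonist not in usable:
        raise InsufficientDataError(
            f"cell {cell.cell_id}: standard agonist has < 2 usable points"
        )
    if len(usable) < 2:
        raise InsufficientDataError(
            f"cell {cell.cell_id}: need >= 2 agonists with >= 2 points"
        )
    agonists = sorted(usable, key=lambda a: (a != cell.standard_agonist, a))
    rows_y, rows_x = [], []
    for j, agonist in enumerate(agonists):
        conc, resp = usable[agonist]
        for c, r in zip(conc, resp):
            ind = np.zeros(len(agonists) + 1)
            ind[j] = 1.0
            ind[-1] = np.log10(c)
            rows_x.append(ind)
            rows_y.append(np.log10(r))
    X = np.array(rows_x)
    y = np.array(rows_y)
    n, p = X.shape
    df = n - p
    if df < 1:
        raise InsufficientDataError(
            f"cell {cell.cell_id}: no residual degrees of freedom (n={n}, p={p})"
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    s2 = rss / df
    cov = s2 * np.linalg.inv(X.T @ X)
    slope = float(beta[-1])
    se_slope = float(np.sqrt(cov[-1, -1]))
    intercepts = {a: float(beta[j]) for j, a in enumerate(agonists)}

    t_val = float(t_dist.ppf(0.975, df))
    std_j = agonists.index(cell.standard_agonist)
    ratios: dict[str, float] = {}
    cis: dict[str, FiellerInterval] = {}
    for j, agonist in enumerate(agonists):
        if agonist == cell.standard_agonist:
            ratios[agonist] = 1.0
            cis[agonist] = FiellerInterval(1.0, 1.0, False, 0.0)
            continue
        m = beta[j] - beta[std_j]
        var_m = cov[j, j] + cov[std_j, std_j] - 2.0 * cov[j, std_j]
        cov_ms = cov[j, -1] - cov[std_j, -1]
        shift = m / slope
        ratios[agonist] = float(10.0 ** shift)
        iv = fieller_interval(
            numerator=float(m),
            denominator=slope,
            var_numerator=float(var_m),
            var_denominator=float(cov[-1, -1]),
            covariance=float(cov_ms),
            t_value=t_val,
        )
        cis[agonist] = FiellerInterval(
            10.0 ** iv.low if np.isfinite(iv.low) else 0.0,
            10.0 ** iv.high if np.isfinite(iv.high) else float("inf"),
            iv.unbounded,
            iv.g,
        )
    return ParallelPowerLawFit(
        cell_id=cell.cell_id,
        slope=slope,
        se_slope=se_slope,
        intercepts=intercepts,
        potency_ratios=ratios,
        fieller_intervals=cis,
        residual_df=df,
        rss=rss,
        n_excluded_nonpositive=n_dropped,
        skipped_agonists=skipped,
    )


def fieller_interval(
    numerator: float,
    denominator: float,
    var_numerator: float,
    var_denominator: float,
    covariance: float,
    t_value: float,
) -> FiellerInterval:
    """Fieller confidence bounds for the ratio numerator/denominator.

    Classical formulation for a ratio of jointly normal estimates: with
    g = t²·var(den)/den², the bounds are

        [ρ − g·cov/var_den ± (t/|den|)·sqrt(var_num − 2ρ·cov + ρ²·var_den
                                            − g·(var_num − cov²/var_den))] / (1 − g)

    where ρ is the point estimate. If g >= 1 the denominator is not
    significantly different from zero and the interval is unbounded — this
    is flagged, not raised.
    """
    if denominator == 0:
        raise DomainError("denominator estimate must be nonzero")
    rho = numerator / denominator
    g = t_value**2 * var_denominator / denominator**2
    if g >= 1.0:
        return FiellerInterval(-np.inf, np.inf, True, g)
    disc = (
        var_numerator
        - 2.0 * rho * covariance
        + rho**2 * var_denominator
        - g * (var_numerator - covariance**2 / var_denominator if var_denominator > 0 else 0.0)
    )
    disc = max(disc, 0.0)
    center = rho - g * (covariance / var_denominator if var_denominator > 0 else 0.0)
    half = (t_value / abs(denominator)) * np.sqrt(disc)
    low = (center - half) / (1.0 - g)
    high = (center + half) / (1.0 - g)
    return FiellerInterval(min(low, high), max(low, high), False, g)


def fit_free_slopes(cell: PartialCurveSet) -> dict[str, tuple[float, float]]:
    """Independent log-log regressions: per-agonist (slope, SE).

    The parallelism check: at low concentration the log-log slope of each
    agonist tends to its Hill coefficient, so roughly equal free slopes
    justify the common-slope fit.
    """
    usable, _, _ = _usable_points(cell)
    if not usable:
        raise InsufficientDataError(f"cell {cell.cell_id}: no usable agonists")
    out = {}
    for agonist, (conc, resp) in usable.items():
        x = np.log10(conc)
        y = np.log10(resp)
        X = np.column_stack([np.ones_like(x), x])
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        df = x.size - 2
        if df > 0:
            s2 = float(resid @ resid) / df
            se = float(np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1]))
        else:
            se = float("nan")
        out[agonist] = (float(beta[1]), se)
    return out


def pool_potency(
    fits: list[ParallelPowerLawFit],
    free_slope_fits: list[dict[str, tuple[float, float]]] | None = None,
) -> pd.DataFrame:
    """Combine per-cell potency fits into a summary table.

    One row per agonist: unweighted mean potency ratio across cells ± SEM,
    the combined Fieller interval (per-cell bounds averaged on the log
    scale), the mean free log-log slope, and the cell count. An agonist
    seen in a single cell gets its mean with the SEM omitted and flagged.
    """
    if not fits:
        raise InsufficientDataError("no cells to pool")
    records = []
    agonists: list[str] = []
    for f in fits:
        for a in f.potency_ratios:
            if a not in agonists:
                agonists.append(a)
    for agonist in agonists:
        ratios = [f.potency_ratios[agonist] for f in fits if agonist in f.potency_ratios]
        ivs = [
            f.fieller_intervals[agonist]
            for f in fits
            if agonist in f.fieller_intervals and not f.fieller_intervals[agonist].unbounded
        ]
        n = len(ratios)
        mean = float(np.mean(ratios))
        sem = float(np.std(ratios, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        if ivs:
            low = float(10.0 ** np.mean([np.log10(max(iv.low, 1e-300)) for iv in ivs]))
            high = float(10.0 ** np.mean([np.log10(iv.high) for iv in ivs]))
        else:
            low = high = float("nan")
        slope = sem_slope = float("nan")
        if free_slope_fits is not None:
            slopes = [d[agonist][0] for d in free_slope_fits if agonist in d]
            if slopes:
                slope = float(np.mean(slopes))
                if len(slopes) > 1:
                    sem_slope = float(np.std(slopes, ddof=1) / np.sqrt(len(slopes)))
        records.append(
            {
                "agonist": agonist,
                "potency_ratio": mean,
                "sem": sem,
                "ci_low": low,
                "ci_high": high,
                "log_log_slope": slope,
                "slope_sem": sem_slope,
                "n_cells": n,
                "single_cell": n == 1,
            }
        )
        if n == 1:
            warnings.warn(f"agonist {agonist!r} present in a single cell; SEM omitted")
    return pd.DataFrame.from_records(records)
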