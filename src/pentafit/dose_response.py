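"""Hill-equation fitting of whole-cell dose-response curves.

The unit of analysis is one cell's ordered sequence of agonist applications,
with a standard near-EC20 application of the reference agonist interleaved
(typically every third response) to track rundown. The stages here are

1. rundown correction against the interleaved standards,
2. per-cell Hill fits (``fit_hill``),
3. normalization of each cell's curve to its own fitted maximum and pooling
   per receptor type,
4. a simultaneous "parallel" fit of the pooled curves constrained to a
   single shared Hill slope, parameterized so that each non-reference curve
   carries a dose ratio relative to the reference curve, and
5. profile-likelihood ("2.01-unit") intervals for those dose ratios.

The Hill equation used throughout is

    I(A) = I_max * A^nH / (A^nH + EC50^nH)

with agonist concentration A in µM. Responses are treated as magnitudes of
inward current (nA), or dimensionless after normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

from ._errors import (
    DomainError,
    FitFailureError,
    InsufficientDataError,
    ValidationError,
)

__all__ = [
    "Application",
    "DoseResponseCell",
    "HillFit",
    "Curve",
    "ParallelFitResult",
    "LikelihoodInterval",
    "hill_response",
    "rundown_correct",
    "fit_hill",
    "normalize_to_fitted_max",
    "pool_curves",
    "parallel_fit",
    "likelihood_interval",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Application:
    """One agonist application within a cell's recording."""

    agonist: str
    concentration: float  # µM
    response: float  # nA (magnitude of inward current)
    is_standard: bool = False


@dataclass
class DoseResponseCell:
    """One cell's ordered agonist applications, standards interleaved."""

    cell_id: str
    applications: list[Application]

    def __post_init__(self) -> None:
        for i, app in enumerate(self.applications):
            if not app.concentration > 0:
                raise ValidationError(
                    f"cell {self.cell_id}, application {i}: concentration "
                    f"must be positive, got {app.concentration}"
                )
            if app.response < 0:
                raise ValidationError(
                    f"cell {self.cell_id}, application {i}: responses are "
                    f"magnitudes and must be >= 0, got {app.response}"
                )
        stds = self.standards
        if stds:
            agonists = {a.agonist for a in stds}
            concs = {a.concentration for a in stds}
            if len(agonists) > 1 or len(concs) > 1:
                raise ValidationError(
                    f"cell {self.cell_id}: standard applications must all "
                    "use one agonist at one concentration"
                )

    @property
    def standards(self) -> list[Application]:
        return [a for a in self.applications if a.is_standard]

    @property
    def tests(self) -> list[Application]:
        return [a for a in self.applications if not a.is_standard]

    def test_points(self, agonist: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Concentration / response arrays of the non-standard applications."""
        apps = self.tests
        if agonist is not None:
            apps = [a for a in apps if a.agonist == agonist]
        conc = np.array([a.concentration for a in apps], dtype=float)
        resp = np.array([a.response for a in apps], dtype=float)
        return conc, resp


@dataclass
class HillFit:
    """Hill-equation parameters for one curve.

    ``i_max`` is in nA for raw currents and dimensionless for normalized
    curves; ``ec50`` is in µM; ``n_h`` is the Hill coefficient.
    """

    i_max: float
    ec50: float
    n_h: float
    se_i_max: float = float("nan")
    se_ec50: float = float("nan")
    se_n_h: float = float("nan")
    rss: float = float("nan")
    n_points: int = 0
    converged: bool = True
    message: str = ""

    def __post_init__(self) -> None:
        if not (self.i_max > 0 and self.ec50 > 0 and self.n_h > 0):
            raise ValidationError(
                "HillFit requires i_max > 0, ec50 > 0, n_h > 0; got "
                f"i_max={self.i_max}, ec50={self.ec50}, n_h={self.n_h}"
            )


@dataclass
class Curve:
    """A (possibly pooled) normalized concentration-response curve."""

    label: str
    concentration: np.ndarray
    response: np.ndarray

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.concentration.shape != self.response.shape:
            raise ValidationError(f"curve {self.label}: shape mismatch")
        if np.any(self.concentration <= 0):
            raise ValidationError(f"curve {self.label}: concentrations must be > 0")


@dataclass
class LikelihoodInterval:
    low: float
    high: float
    open_low: bool = False
    open_high: bool = False

    def as_tuple(self) -> tuple[float, float]:
        return (self.low, self.high)


@dataclass
class ParallelFitResult:
    """Simultaneous equal-slope Hill fit of several pooled curves.

    Each non-reference curve's EC50 is parameterized as
    ``reference_ec50 * dose_ratio``; the potency ratio reported in the
    summary tables is the reciprocal of the dose ratio.
    """

    shared_n_h: float
    reference_ec50: float
    reference: str
    labels: list[str]
    dose_ratios: dict[str, float]
    likelihood_intervals: dict[str, LikelihoodInterval]
    i_max: dict[str, float]
    rss: float
    n_points: int
    # lack-of-parallelism diagnostic (shared slope vs free slopes)
    free_slopes: dict[str, float] = field(default_factory=dict)
    rss_free: float = float("nan")
    parallelism_f: float = float("nan")
    parallelism_p: float = float("nan")

    def potency_ratio(self, label: str) -> float:
        return 1.0 / self.dose_ratios[label]


# ---------------------------------------------------------------------------
# the Hill equation
# ---------------------------------------------------------------------------


def _hill(conc: np.ndarray, i_max: float, ec50: float, n_h: float) -> np.ndarray:
    conc = np.asarray(conc, dtype=float)
    with np.errstate(divide="ignore"):
        # compute in log space to avoid overflow for large n_h * log(A)
        ratio = np.power(10.0, n_h * (np.log10(ec50) - np.log10(np.where(conc > 0, conc, np.nan))))
    out = i_max / (1.0 + ratio)
    return np.where(conc == 0, 0.0, out)


def hill_response(concentration, params: HillFit):
    """Evaluate the Hill equation at ``concentration`` (µM).

    Returns ``i_max * A^nH / (A^nH + EC50^nH)``; 0 at A = 0. Raises
    :class:`DomainError` for negative concentrations.
    """
    conc = np.asarray(concentration, dtype=float)
    if np.any(conc < 0):
        raise DomainError("concentration must be >= 0")
    out = _hill(conc, params.i_max, params.ec50, params.n_h)
    if np.isscalar(concentration) or conc.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# rundown correction
# ---------------------------------------------------------------------------


def rundown_correct(cell: DoseResponseCell) -> DoseResponseCell:
    """Correct a cell's responses for rundown using interleaved standards.

    The standard responses are interpolated linearly in application index;
    every test response is multiplied by (first standard response) /
    (interpolated standard response at that index), and the standards
    themselves map to the first standard's value. Requires at least two
    standards bracketing the test applications.
    """
    idx_std = [i for i, a in enumerate(cell.applications) if a.is_standard]
    if len(idx_std) < 2:
        raise InsufficientDataError(
            f"cell {cell.cell_id}: rundown correction needs >= 2 standard "
            "applications; pass the cell through uncorrected explicitly if "
            "no standards were recorded"
        )
    idx_test = [i for i, a in enumerate(cell.applications) if not a.is_standard]
    if idx_test and (min(idx_test) < idx_std[0] or max(idx_test) > idx_std[-1]):
        raise ValidationError(
            f"cell {cell.cell_id}: standards must bracket the test "
            "applications for interpolation"
        )
    std_resp = np.array([cell.applications[i].response for i in idx_std], float)
    if np.any(std_resp <= 0):
        raise ValidationError(f"cell {cell.cell_id}: standard responses must be > 0")
    first = std_resp[0]
    corrected: list[Application] = []
    for i, app in enumerate(cell.applications):
        if app.is_standard:
            corrected.append(replace(app, response=first))
        else:
            interp = float(np.interp(i, idx_std, std_resp))
            corrected.append(replace(app, response=app.response * first / interp))
    return DoseResponseCell(cell_id=cell.cell_id, applications=corrected)


# ---------------------------------------------------------------------------
# per-cell Hill fit
# ---------------------------------------------------------------------------

# internal parameterization: (i_max, log10 ec50, n_h)
_NH_LO, _NH_HI = 1e-2, 20.0


def _fit_hill_points(
    conc: np.ndarray, resp: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, bool, str]:
    """Bounded least squares on (i_max, log10 ec50, n_h); several starts."""
    lc = np.log10(conc)
    resp_max = float(resp.max())
    # EC50 start: concentration whose response is nearest half the max observed
    half_idx = int(np.argmin(np.abs(resp - 0.5 * resp_max)))
    lec50_0 = float(lc[half_idx])
    lo = np.array([1e-12, lc.min() - 3.0, _NH_LO])
    hi = np.array([np.inf, lc.max() + 3.0, _NH_HI])

    def residuals(x):
        i_max, lec50, n_h = x
        return _hill(conc, i_max, 10.0 ** lec50, n_h) - resp

    def try_starts(starts):
        best = None
        for nh0, dlec in starts:
            x0 = np.array(
                [max(resp_max, 1e-9), np.clip(lec50_0 + dlec, lo[1], hi[1]), nh0]
            )
            try:
                sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf")
            except Exception:  # pragma: no cover - optimizer blow-ups
                continue
            if best is None or sol.cost < best.cost - 1e-12:
                best = sol
        return best

    best = try_starts([(1.5, 0.0), (1.0, 0.0), (2.5, 0.0)])
    if best is None or not best.success:
        # degenerate data can be multimodal: widen the start grid
        wider = try_starts(
            [(nh0, dlec) for nh0 in (0.5, 1.5, 4.0) for dlec in (-1.0, -0.5, 0.5, 1.0)]
        )
        if wider is not None and (best is None or wider.cost < best.cost - 1e-12):
            best = wider
    if best is None:
        raise FitFailureError("Hill fit did not converge from any start")
    x = best.x
    # hitting a bound (other than the huge i_max upper bound) means the
    # optimum is outside the meaningful parameter region: flag, don't clip
    at_bound = (
        x[1] <= lo[1] + 1e-9
        or x[1] >= hi[1] - 1e-9
        or x[2] <= _NH_LO + 1e-9
        or x[2] >= _NH_HI - 1e-9
    )
    rss = float(2.0 * best.cost)
    dof = conc.size - 3
    s2 = rss / dof if dof > 0 else float("nan")
    J = best.jac
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(3, np.nan)
    msg = "optimizer hit a parameter bound" if at_bound else ""
    return x, se, rss, (not at_bound) and best.success, msg


def fit_hill(cell: DoseResponseCell, agonist: str | None = None) -> HillFit:
    """Fit the Hill equation to one cell's non-standard applications.

    Equal weights; standard errors from the approximate covariance at the
    optimum (delta method for EC50, which is fitted on the log10 scale).
    Requires at least 4 distinct test concentrations. A fit whose optimum
    sits on a parameter bound is returned with ``converged=False`` rather
    than silently clipped.
    """
    conc, resp = cell.test_points(agonist)
    if np.unique(conc).size < 4:
        raise InsufficientDataError(
            f"cell {cell.cell_id}: Hill fit needs >= 4 distinct "
            f"concentrations, got {np.unique(conc).size}"
        )
    x, se, rss, ok, msg = _fit_hill_points(conc, resp)
    i_max, lec50, n_h = x
    ec50 = 10.0 ** lec50
    return HillFit(
        i_max=float(i_max),
        ec50=float(ec50),
        n_h=float(n_h),
        se_i_max=float(se[0]),
        se_ec50=float(math.log(10.0) * ec50 * se[1]),
        se_n_h=float(se[2]),
        rss=rss,
        n_points=int(conc.size),
        converged=bool(ok),
        message=msg,
    )


def normalize_to_fitted_max(
    cell: DoseResponseCell, fit: HillFit | None = None, agonist: str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """One cell's test points normalized to its own fitted maximum."""
    if fit is None:
        fit = fit_hill(cell, agonist)
    conc, resp = cell.test_points(agonist)
    return conc, resp / fit.i_max


def pool_curves(
    label: str, cells: Sequence[DoseResponseCell], agonist: str | None = None
) -> Curve:
    """Normalize each cell to its fitted maximum and pool into one curve."""
    concs, resps = [], []
    for cell in cells:
        c, r = normalize_to_fitted_max(cell, agonist=agonist)
        concs.append(c)
        resps.append(r)
    return Curve(label, np.concatenate(concs), np.concatenate(resps))


# ---------------------------------------------------------------------------
# parallel (equal-slope) fits and dose ratios
# ---------------------------------------------------------------------------


def _parallel_residuals(
    theta: np.ndarray,
    curves: list[Curve],
    ref_pos: int,
    fixed: dict[int, float] | None = None,
) -> np.ndarray:
    """Residual vector of the shared-slope model.

    theta layout: [n_h, log10 ref_ec50, i_max_0..i_max_{k-1},
                   log10 dose_ratio for each non-reference curve in order].
    ``fixed`` maps theta indices to frozen values (used for profiling).
    """
    k = len(curves)
    full = np.empty(2 * k + 1)
    free_idx = [i for i in range(2 * k + 1) if not (fixed and i in fixed)]
    full[free_idx] = theta
    if fixed:
        for i, v in fixed.items():
            full[i] = v
    n_h = full[0]
    lref = full[1]
    i_maxes = full[2 : 2 + k]
    lratios = full[2 + k :]
    res = []
    j = 0
    for pos, curve in enumerate(curves):
        if pos == ref_pos:
            lec50 = lref
        else:
            lec50 = lref + lratios[j]
            j += 1
        res.append(_hill(curve.concentration, i_maxes[pos], 10.0 ** lec50, n_h) - curve.response)
    return np.concatenate(res)


def _fit_parallel(
    curves: list[Curve],
    ref_pos: int,
    fixed: dict[int, float] | None = None,
    x0_full: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Minimize the shared-slope RSS; returns full theta and RSS."""
    k = len(curves)
    if x0_full is None:
        x0_full = _parallel_start(curves, ref_pos)
    free_idx = [i for i in range(2 * k + 1) if not (fixed and i in fixed)]
    lo = np.full(2 * k + 1, -np.inf)
    hi = np.full(2 * k + 1, np.inf)
    lo[0] = _NH_LO
    hi[0] = _NH_HI
    lo[2 : 2 + k] = 1e-12
    all_lc = np.concatenate([c.concentration for c in curves])
    lo[1] = np.log10(all_lc.min()) - 4.0
    hi[1] = np.log10(all_lc.max()) + 4.0
    sol = least_squares(
        _parallel_residuals,
        x0_full[free_idx],
        bounds=(lo[free_idx], hi[free_idx]),
        args=(curves, ref_pos, fixed),
        method="trf",
    )
    full = np.empty(2 * k + 1)
    full[free_idx] = sol.x
    if fixed:
        for i, v in fixed.items():
            full[i] = v
    return full, float(2.0 * sol.cost)


def _parallel_start(curves: list[Curve], ref_pos: int) -> np.ndarray:
    """Starting point from independent per-curve Hill fits."""
    k = len(curves)
    fits = []
    for c in curves:
        try:
            x, *_ = _fit_hill_points(c.concentration, c.response)
        except FitFailureError:
            x = np.array([max(c.response.max(), 1e-9), np.log10(np.median(c.concentration)), 1.5])
        fits.append(x)
    x0 = np.empty(2 * k + 1)
    x0[0] = float(np.clip(np.mean([f[2] for f in fits]), _NH_LO * 2, _NH_HI / 2))
    x0[1] = fits[ref_pos][1]
    x0[2 : 2 + k] = [f[0] for f in fits]
    j = 2 + k
    for pos in range(k):
        if pos != ref_pos:
            x0[j] = fits[pos][1] - fits[ref_pos][1]
            j += 1
    return x0


def parallel_fit(
    curves: Sequence[Curve],
    reference: str,
    likelihood_delta: float = 2.01,
    compute_intervals: bool = True,
    free_slope_diagnostic: bool = True,
) -> ParallelFitResult:
    """Simultaneous Hill fit of pooled curves with one shared Hill slope.

    Each non-reference curve's EC50 is ``reference_ec50 * dose_ratio``; the
    dose ratios get ``likelihood_delta``-unit profile-likelihood intervals.
    A lack-of-parallelism diagnostic (extra-sum-of-squares F comparing the
    shared-slope fit against per-curve free slopes) is attached when
    ``free_slope_diagnostic`` is true.
    """
    curves = list(curves)
    labels = [c.label for c in curves]
    if reference not in labels:
        raise ValidationError(f"reference label {reference!r} not among {labels}")
    ref_pos = labels.index(reference)
    k = len(curves)
    theta, rss = _fit_parallel(curves, ref_pos)
    n_obs = int(sum(c.concentration.size for c in curves))
    n_h = float(theta[0])
    ref_ec50 = float(10.0 ** theta[1])
    i_maxes = {lab: float(v) for lab, v in zip(labels, theta[2 : 2 + k])}
    nonref = [lab for lab in labels if lab != reference]
    lratios = theta[2 + k :]
    dose_ratios = {reference: 1.0}
    for lab, lr in zip(nonref, lratios):
        dose_ratios[lab] = float(10.0 ** lr)

    intervals: dict[str, LikelihoodInterval] = {}
    if compute_intervals:
        for j, lab in enumerate(nonref):
            t_idx = 2 + k + j

            def profile_rss(lval: float, _idx=t_idx) -> float:
                _, r = _fit_parallel(curves, ref_pos, fixed={_idx: lval}, x0_full=theta.copy())
                return r

            iv = likelihood_interval(
                profile_rss,
                estimate=float(np.log10(dose_ratios[lab])),
                rss_min=rss,
                n_obs=n_obs,
                delta=likelihood_delta,
                lo_bound=-8.0,
                hi_bound=8.0,
            )
            intervals[lab] = LikelihoodInterval(
                10.0 ** iv.low, 10.0 ** iv.high, iv.open_low, iv.open_high
            )

    result = ParallelFitResult(
        shared_n_h=n_h,
        reference_ec50=ref_ec50,
        reference=reference,
        labels=labels,
        dose_ratios=dose_ratios,
        likelihood_intervals=intervals,
        i_max=i_maxes,
        rss=rss,
        n_points=n_obs,
    )

    if free_slope_diagnostic and k > 1:
        free_slopes = {}
        rss_free = 0.0
        for c in curves:
            x, _, r, _, _ = _fit_hill_points(c.concentration, c.response)
            free_slopes[c.label] = float(x[2])
            rss_free += r
        # nested comparison: shared slope (2k+1 params) vs free slopes (3k)
        df_extra = k - 1
        df_resid = n_obs - 3 * k
        if df_extra > 0 and df_resid > 0 and rss_free > 0:
            f_stat = ((rss - rss_free) / df_extra) / (rss_free / df_resid)
            from scipy.stats import f as f_dist

            result.parallelism_f = float(f_stat)
            result.parallelism_p = float(f_dist.sf(max(f_stat, 0.0), df_extra, df_resid))
        result.free_slopes = free_slopes
        result.rss_free = rss_free
    return result


# ---------------------------------------------------------------------------
# profile-likelihood intervals
# ---------------------------------------------------------------------------


def likelihood_interval(
    profile_rss: Callable[[float], float],
    estimate: float,
    rss_min: float,
    n_obs: int,
    delta: float = 2.01,
    lo_bound: float = -np.inf,
    hi_bound: float = np.inf,
    initial_step: float | None = None,
) -> LikelihoodInterval:
    """Profile-likelihood interval for one parameter of a Gaussian model.

    With the noise variance profiled out, the drop in profile log-likelihood
    at parameter value p is (n/2)·ln(RSS(p)/RSS_min); the interval collects
    the p where this drop is below ``delta``. The search walks outward from
    the estimate on each side with a doubling step until the threshold is
    crossed, then brackets the crossing with Brent's method. A side that
    never crosses within its bound is returned at the bound and flagged
    open.
    """
    if delta <= 0:
        raise DomainError("delta must be > 0")
    if rss_min < 0 or n_obs < 1:
        raise DomainError("need rss_min >= 0 and n_obs >= 1")
    target = rss_min * math.exp(2.0 * delta / n_obs)
    if rss_min == 0.0:
        # perfect fit: any increase crosses immediately; degenerate interval
        return LikelihoodInterval(estimate, estimate)

    def height(p: float) -> float:
        return profile_rss(p) - target

    step0 = initial_step if initial_step is not None else max(abs(estimate) * 0.05, 0.01)

    def search(direction: float) -> tuple[float, bool]:
        step = step0
        prev = estimate
        bound = hi_bound if direction > 0 else lo_bound
        for _ in range(60):
            p = estimate + direction * step
            if direction > 0 and p > bound:
                p = bound
            if direction < 0 and p < bound:
                p = bound
            if height(p) > 0:
                return brentq(height, min(prev, p), max(prev, p), xtol=1e-10), False
            if p == bound:
                return bound, True
            prev = p
            step *= 2.0
        return prev, True

    low, open_low = search(-1.0)
    high, open_high = search(+1.0)
    return LikelihoodInterval(low, high, open_low, open_high)
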