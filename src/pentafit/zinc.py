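"""Zn²⁺ modulation of ACh responses: biphasic vs inhibition-only fits.

ACh is applied at its EC20 together with increasing Zn²⁺; each response is
normalized to the ACh-alone control, so the curve starts at 1. Two nested
models are fitted to response vs x = log10([Zn²⁺] µM):

* inhibition-only — a single descending logistic,
      I(x) = 1 + min_effect · L(x; IC50, nH)
  with min_effect ≤ 0 (−1 is complete block);

* biphasic — the sum of an enhancing and an inhibiting logistic,
      I(x) = 1 + w·(max_effect − 1)·L(x; EC50, nH1)
               + (1 − w)·min_effect·L(x; IC50, nH2)

where L(x; c50, n) = 1 / (1 + 10^(n·(log10 c50 − x))) rises from 0 to 1,
so both models are anchored at the control response 1 as x → −∞.

Only the amplitude products w·(max_effect−1) and (1−w)·min_effect enter the
model curve, so w, max_effect and min_effect are not separately
identifiable; the fit estimates the two amplitudes and reports w/max/min
under the convention w = 0.5 (see the methods note). Classification as
biphasic requires both a significant extra-sum-of-squares F test over the
single-logistic model and a fitted peak enhancement above a margin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import f as f_dist

from ._errors import DomainError, InsufficientDataError, ValidationError

__all__ = [
    "ZincCurve",
    "BiphasicFit",
    "SingleHillFit",
    "ZincFitPair",
    "ZincClassification",
    "biphasic_response",
    "single_hill_response",
    "fit_biphasic",
    "classify_modulation",
]


@dataclass
class ZincCurve:
    """Zn²⁺ concentration (µM) vs ACh response normalized to control."""

    zinc_um: np.ndarray
    response: np.ndarray
    ach_concentration: float = float("nan")  # the EC20 used, µM
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.zinc_um = np.asarray(self.zinc_um, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.zinc_um.shape != self.response.shape:
            raise ValidationError("zinc/response shape mismatch")
        if np.any(self.zinc_um <= 0):
            raise ValidationError("zinc concentrations must be > 0")
        if np.any(self.response < 0):
            raise ValidationError("normalized responses must be >= 0")


@dataclass
class BiphasicFit:
    """Parameters of the two-component logistic model (x = log10 µM)."""

    w: float
    max_effect: float
    min_effect: float
    ec50_zn: float  # µM
    ic50_zn: float  # µM
    n_h1: float
    n_h2: float
    rss: float = float("nan")
    n_points: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise DomainError(f"w must be in [0, 1], got {self.w}")
        if not (self.ec50_zn > 0 and self.ic50_zn > 0):
            raise DomainError("ec50_zn and ic50_zn must be > 0")
        if not (self.n_h1 > 0 and self.n_h2 > 0):
            raise DomainError("Hill coefficients must be > 0")

    @property
    def enhancement_amplitude(self) -> float:
        """w·(max_effect − 1): the identifiable size of the enhancing limb."""
        return self.w * (self.max_effect - 1.0)

    @property
    def inhibition_amplitude(self) -> float:
        """(1 − w)·min_effect: the identifiable size of the inhibiting limb."""
        return (1.0 - self.w) * self.min_effect


@dataclass
class SingleHillFit:
    """Descending single-logistic (inhibition-only) model."""

    min_effect: float  # <= 0; -1 is complete inhibition
    ic50_zn: float
    n_h: float
    rss: float = float("nan")
    n_points: int = 0
    converged: bool = True


@dataclass
class ZincFitPair:
    biphasic: BiphasicFit | None
    single: SingleHillFit | None
    n_points: int


@dataclass
class ZincClassification:
    kind: str  # "biphasic" | "inhibition_only"
    f_statistic: float
    p_value: float
    peak_enhancement: float  # fitted maximum response minus 1
    low_confidence: bool = False
    note: str = ""


def _logistic(x, c50_um, n):
    return 1.0 / (1.0 + 10.0 ** (n * (np.log10(c50_um) - np.asarray(x, dtype=float))))


def biphasic_response(x, fit: BiphasicFit):
    """Evaluate the biphasic model at x = log10([Zn²⁺] µM)."""
    out = (
        1.0
        + fit.w * (fit.max_effect - 1.0) * _logistic(x, fit.ec50_zn, fit.n_h1)
        + (1.0 - fit.w) * fit.min_effect * _logistic(x, fit.ic50_zn, fit.n_h2)
    )
    return float(out) if np.isscalar(x) else out


def single_hill_response(x, fit: SingleHillFit):
    """Evaluate the inhibition-only model at x = log10([Zn²⁺] µM)."""
    out = 1.0 + fit.min_effect * _logistic(x, fit.ic50_zn, fit.n_h)
    return float(out) if np.isscalar(x) else out


def _fit_single(x: np.ndarray, y: np.ndarray) -> SingleHillFit:
    # params: (min_effect, log10 ic50, n_h)
    def resid(p):
        return 1.0 + p[0] * _logistic(x, 10.0 ** p[1], p[2]) - y

    lo = [-1.5, x.min() - 4.0, 0.05]
    hi = [0.0, x.max() + 4.0, 15.0]
    best = None
    for lic0 in (np.median(x), x.max()):
        for nh0 in (1.0, 2.0):
            p0 = np.clip([min(y.min() - 1.0, -1e-3), lic0, nh0], lo, hi)
            sol = least_squares(resid, p0, bounds=(lo, hi), method="trf")
            if best is None or sol.cost < best.cost:
                best = sol
    p = best.x
    return SingleHillFit(
        min_effect=float(p[0]),
        ic50_zn=float(10.0 ** p[1]),
        n_h=float(p[2]),
        rss=float(2.0 * best.cost),
        n_points=int(x.size),
        converged=bool(best.success),
    )


def _fit_biphasic_amplitudes(x: np.ndarray, y: np.ndarray):
    # params: (a1, log10 ec50, n1, a2, log10 ic50, n2); a1 = w(max-1) >= 0,
    # a2 = (1-w) min <= 0
    def resid(p):
        return (
            1.0
            + p[0] * _logistic(x, 10.0 ** p[1], p[2])
            + p[3] * _logistic(x, 10.0 ** p[4], p[5])
            - y
        )

    span = x.max() - x.min()
    lo = [0.0, x.min() - 4.0, 0.05, -1.5, x.min() - 4.0, 0.05]
    hi = [10.0, x.max() + 4.0, 15.0, 0.0, x.max() + 4.0, 15.0]
    peak = float(y.max())
    i_peak = int(np.argmax(y))
    best = None
    starts = []
    for nh in (1.5, 2.0):
        starts.append([max(peak - 1.0, 0.05), x[i_peak], nh, -1.0, x[i_peak] + span / 3, nh])
        starts.append([0.01, np.median(x), nh, min(y.min() - 1.0, -0.05), np.median(x), nh])
    for p0 in starts:
        p0 = np.clip(p0, lo, hi)
        sol = least_squares(resid, p0, bounds=(lo, hi), method="trf")
        if best is None or sol.cost < best.cost:
            best = sol
    p = best.x
    return p, float(2.0 * best.cost), bool(best.success)


def fit_biphasic(curve: ZincCurve, w_convention: float = 0.5) -> ZincFitPair:
    """Fit both the biphasic and the inhibition-only model to one curve.

    Requires >= 6 Zn²⁺ concentrations spanning >= 2 log units. The biphasic
    model is fitted in its identifiable amplitude parameterization; w, max
    and min are reported under the ``w_convention`` weight split. Each
    model that fails to converge is returned as None; both failing raises.
    """
    x = np.log10(curve.zinc_um)
    y = curve.response
    if np.unique(curve.zinc_um).size < 6:
        raise InsufficientDataError("need >= 6 distinct Zn2+ concentrations")
    if x.max() - x.min() < 2.0:
        raise InsufficientDataError("Zn2+ concentrations must span >= 2 log units")
    single = None
    biph = None
    try:
        single = _fit_single(x, y)
        if not single.converged:
            single = None
    except Exception:
        single = None
    try:
        p, rss, ok = _fit_biphasic_amplitudes(x, y)
        a1, lec, n1, a2, lic, n2 = p
        w = w_convention
        biph = BiphasicFit(
            w=w,
            max_effect=1.0 + a1 / w if w > 0 else 1.0,
            min_effect=a2 / (1.0 - w) if w < 1 else 0.0,
            ec50_zn=float(10.0 ** lec),
            ic50_zn=float(10.0 ** lic),
            n_h1=float(n1),
            n_h2=float(n2),
            rss=rss,
            n_points=int(x.size),
            converged=ok,
        )
        if not ok:
            biph = None
    except Exception:
        biph = None
    if single is None and biph is None:
        raise DomainError("neither zinc model converged")
    return ZincFitPair(biphasic=biph, single=single, n_points=int(x.size))


def classify_modulation(
    pair: ZincFitPair,
    alpha: float = 0.05,
    enhancement_margin: float = 0.10,
    x_grid: np.ndarray | None = None,
) -> ZincClassification:
    """Call a curve biphasic or inhibition-only from the fitted model pair.

    Biphasic requires (a) the biphasic model to reduce the residual sum of
    squares significantly over the nested single-logistic model
    (extra-sum-of-squares F test at ``alpha``) and (b) a fitted peak
    enhancement exceeding ``enhancement_margin`` above the control response.
    With only one converged model the call comes from that model and is
    flagged low-confidence.
    """
    if pair.biphasic is None and pair.single is None:
        raise DomainError("no converged model to classify from")
    if x_grid is None:
        x_grid = np.linspace(-2.0, 6.0, 801)

    if pair.biphasic is not None:
        peak = float(np.max(biphasic_response(x_grid, pair.biphasic)) - 1.0)
    else:
        peak = 0.0

    if pair.biphasic is None:
        return ZincClassification(
            "inhibition_only", float("nan"), float("nan"), 0.0, True,
            "biphasic model did not converge",
        )
    if pair.single is None:
        kind = "biphasic" if peak > enhancement_margin else "inhibition_only"
        return ZincClassification(
            kind, float("nan"), float("nan"), peak, True,
            "single-logistic model did not converge",
        )

    n = pair.n_points
    df1 = n - 3  # single model params
    df2 = n - 6  # biphasic amplitude parameterization
    if df2 <= 0:
        return ZincClassification(
            "inhibition_only", float("nan"), float("nan"), peak, True,
            "too few points for the model comparison",
        )
    rss1, rss2 = pair.single.rss, pair.biphasic.rss
    if rss2 <= 0:
        f_stat, p_val = float("inf"), 0.0
    else:
        f_stat = max((rss1 - rss2) / (df1 - df2), 0.0) / (rss2 / df2)
        p_val = float(f_dist.sf(f_stat, df1 - df2, df2))
    note = ""
    if peak <= 1e-3 and abs(pair.single.min_effect) <= 1e-3:
        note = "zero-effect curve"
    kind = "biphasic" if (p_val < alpha and peak > enhancement_margin) else "inhibition_only"
    return ZincClassification(kind, float(f_stat), p_val, peak, False, note)
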