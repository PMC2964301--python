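"""Subunit copy-number inference from reporter-mutation EC50 shifts.

A hydrophilic 9' Leu→Thr reporter mutation in the pore-lining M2 helix
multiplies agonist potency by an approximately constant factor r per mutant
copy in the pentamer. A receptor carrying the mutation on every copy of one
subunit therefore shifts its EC50 by r^n, where n is that subunit's copy
number, and log10(EC50) falls linearly with the number of mutant copies with
slope −log10(r). For an α/β heteropentamer the two candidate assignments
are (α,β) = (2,3) or (3,2): whichever makes the per-copy shift factor
inferred from the α-mutant agree better (on the log scale) with the one from
the β-mutant is the called stoichiometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._errors import DomainError, InsufficientDataError

__all__ = [
    "StoichiometryFit",
    "CopyLineFit",
    "per_copy_shift",
    "fit_copy_line",
    "infer_stoichiometry",
    "equal_efficacy_ec50",
]

#: The two pentameric candidate assignments, as (alpha copies, beta copies).
CANDIDATE_ASSIGNMENTS = ((2, 3), (3, 2))


@dataclass
class CopyLineFit:
    """OLS of log10(EC50) on mutant copy number."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def predicted_ec50(self, copies: float) -> float:
        return float(10.0 ** (self.intercept + self.slope * copies))

    @property
    def implied_r(self) -> float:
        """Per-copy shift factor implied by the slope (r = 10^-slope)."""
        return float(10.0 ** (-self.slope))


@dataclass
class StoichiometryFit:
    """Result of the two-candidate stoichiometry inference."""

    r: float
    assignment: dict[str, int]  # {"alpha": copies, "beta": copies}
    consistency_score: float  # |log10 r_alpha - log10 r_beta| at the winner
    candidate_scores: dict[tuple[int, int], float]
    r_alpha: float
    r_beta: float
    ambiguous: bool = False
    r_alpha_interval: tuple[float, float] | None = None
    r_beta_interval: tuple[float, float] | None = None
    intervals_overlap: bool | None = None
    regression: CopyLineFit | None = None

    def __post_init__(self) -> None:
        if self.assignment["alpha"] + self.assignment["beta"] != 5:
            raise DomainError("copy counts must sum to 5")


def per_copy_shift(
    potency_ratio: float,
    copies: int,
    interval: tuple[float, float] | None = None,
) -> float | tuple[float, tuple[float, float]]:
    """Per-copy EC50 shift factor r = potency_ratio^(1/copies).

    ``copies`` must be 1, 2 or 3 (the copy counts a mutated subunit can
    have in an α/β pentamer with the other subunit present). An interval on
    the potency ratio, if given, is transformed endpoint-wise by the same
    monotone root and returned alongside.
    """
    if copies not in (1, 2, 3):
        raise DomainError(f"copies must be 1, 2 or 3, got {copies}")
    if not potency_ratio > 0:
        raise DomainError(f"potency ratio must be > 0, got {potency_ratio}")
    r = potency_ratio ** (1.0 / copies)
    if interval is None:
        return r
    lo, hi = interval
    if not (lo > 0 and hi > 0):
        raise DomainError("interval endpoints must be > 0")
    return r, (lo ** (1.0 / copies), hi ** (1.0 / copies))


def fit_copy_line(points: list[tuple[int, float]]) -> CopyLineFit:
    """OLS of log10(EC50 µM) on mutant copy count.

    On data generated from the r-per-copy model the slope is exactly
    −log10(r); R² quantifies how well the unitary-shift model holds.
    """
    if len(points) < 3:
        raise InsufficientDataError("need >= 3 (copies, EC50) points")
    copies = np.array([p[0] for p in points], dtype=float)
    ec50 = np.array([p[1] for p in points], dtype=float)
    if np.any(ec50 <= 0):
        raise DomainError("EC50 values must be > 0")
    if np.unique(copies).size < 2:
        raise InsufficientDataError("need >= 2 distinct copy counts")
    y = np.log10(ec50)
    x = copies
    xbar, ybar = x.mean(), y.mean()
    sxx = float(((x - xbar) ** 2).sum())
    sxy = float(((x - xbar) * (y - ybar)).sum())
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    ss_res = float(((y - intercept - slope * x) ** 2).sum())
    ss_tot = float(((y - ybar) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return CopyLineFit(slope=slope, intercept=intercept, r_squared=r2, n_points=len(points))


def infer_stoichiometry(
    ratio_alpha_mutant: float,
    ratio_beta_mutant: float,
    interval_alpha: tuple[float, float] | None = None,
    interval_beta: tuple[float, float] | None = None,
    ec50s: dict[int, float] | None = None,
    tie_tol: float = 1e-12,
) -> StoichiometryFit:
    """Choose between the 2α:3β and 3α:2β assignments.

    For each candidate, the per-copy factor is computed from the α-mutant
    potency ratio with the α copy count and from the β-mutant ratio with
    the β copy count; the candidate minimizing the log-scale discrepancy
    |log r_α − log r_β| wins. Equal scores are flagged ambiguous. When
    ratio intervals are supplied they are transformed by the winning
    candidate's roots and attached, along with whether the two per-copy
    intervals overlap — non-overlap would argue against the call, overlap
    supports it; no formal test is attempted.
    """
    if not (ratio_alpha_mutant > 0 and ratio_beta_mutant > 0):
        raise DomainError("both potency ratios must be > 0")
    scores: dict[tuple[int, int], float] = {}
    details = {}
    for alpha_copies, beta_copies in CANDIDATE_ASSIGNMENTS:
        r_a = ratio_alpha_mutant ** (1.0 / alpha_copies)
        r_b = ratio_beta_mutant ** (1.0 / beta_copies)
        scores[(alpha_copies, beta_copies)] = abs(math.log10(r_a) - math.log10(r_b))
        details[(alpha_copies, beta_copies)] = (r_a, r_b)
    (a1, s1), (a2, s2) = sorted(scores.items(), key=lambda kv: kv[1])
    ambiguous = abs(s1 - s2) <= tie_tol
    winner = a1
    r_a, r_b = details[winner]
    r = float(math.sqrt(r_a * r_b))  # geometric mean of the two estimates

    iv_a = iv_b = None
    overlap = None
    if interval_alpha is not None:
        _, iv_a = per_copy_shift(ratio_alpha_mutant, winner[0], interval_alpha)
    if interval_beta is not None:
        _, iv_b = per_copy_shift(ratio_beta_mutant, winner[1], interval_beta)
    if iv_a is not None and iv_b is not None:
        overlap = not (iv_a[1] < iv_b[0] or iv_b[1] < iv_a[0])

    regression = None
    if ec50s is not None and len(ec50s) >= 3:
        regression = fit_copy_line(sorted(ec50s.items()))

    return StoichiometryFit(
        r=r,
        assignment={"alpha": winner[0], "beta": winner[1]},
        consistency_score=s1,
        candidate_scores=scores,
        r_alpha=float(r_a),
        r_beta=float(r_b),
        ambiguous=ambiguous,
        r_alpha_interval=iv_a,
        r_beta_interval=iv_b,
        intervals_overlap=overlap,
        regression=regression,
    )


def equal_efficacy_ec50(reference_ec50: float, potency_ratio: float) -> float:
    """EC50 extrapolated from a foot-of-curve potency ratio.

    Under identical efficacy, an agonist x-fold more potent than the
    reference has EC50 = reference_ec50 / x.
    """
    if not (reference_ec50 > 0 and potency_ratio > 0):
        raise DomainError("reference_ec50 and potency_ratio must be > 0")
    return reference_ec50 / potency_ratio
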