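"""Single-channel analysis of idealized open/shut event lists.

The input is an idealized record — alternating open/shut intervals with
durations (ms) and an amplitude (pA) for each opening — plus the recording
metadata needed downstream (holding potential, filter cutoff, imposed
resolution). The stages:

* resolvable-opening filter: only openings longer than twice the filter
  rise time have well-defined amplitudes and enter amplitude analysis;
* Gaussian mixture fit of the fitted amplitudes (one component per
  conductance class);
* chord conductance, g = i / |V_hold − V_rev|;
* burst segmentation at a critical shut time tcrit: openings separated by
  shut intervals shorter than tcrit belong to one burst;
* per-conductance-class burst statistics (counts, proportions, durations),
  assigning each burst to the mixture component with the highest posterior
  density at the burst's mean open amplitude.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from ._errors import DomainError, InsufficientDataError, ValidationError

__all__ = [
    "Event",
    "IdealizedRecord",
    "AmplitudeMixture",
    "Burst",
    "BurstSet",
    "filter_resolvable",
    "fit_amplitude_mixture",
    "chord_conductance",
    "segment_bursts",
    "burst_class_stats",
    "count_direct_transitions",
]

#: Rise-time constant for a Gaussian-response filter: T_r = 0.3321 / f_c.
GAUSSIAN_RISE_TIME_CONSTANT = 0.3321


@dataclass(frozen=True)
class Event:
    state: str  # "open" | "shut"
    duration: float  # ms
    amplitude: float = float("nan")  # pA, open events only


@dataclass
class IdealizedRecord:
    """Alternating open/shut events with recording metadata."""

    events: list[Event]
    holding_potential: float  # mV
    filter_cutoff: float  # kHz
    resolution: float  # µs

    def __post_init__(self) -> None:
        for i, ev in enumerate(self.events):
            if ev.state not in ("open", "shut"):
                raise ValidationError(f"event {i}: state must be open/shut")
            if not ev.duration > 0:
                raise ValidationError(f"event {i}: duration must be > 0 ms")
            if i > 0 and ev.state == self.events[i - 1].state:
                raise ValidationError(f"event {i}: states must strictly alternate")

    @property
    def openings(self) -> list[Event]:
        return [e for e in self.events if e.state == "open"]

    def total_open_time(self) -> float:
        return float(sum(e.duration for e in self.openings))


@dataclass
class AmplitudeMixture:
    """Gaussian components of the fitted-amplitude distribution."""

    components: list[tuple[float, float, float]]  # (mean pA, sd pA, area)
    n_openings_used: int

    def __post_init__(self) -> None:
        if not self.components:
            raise ValidationError("mixture needs >= 1 component")
        areas = [c[2] for c in self.components]
        if abs(sum(areas) - 1.0) > 1e-6:
            raise ValidationError("component areas must sum to 1")
        means = [c[0] for c in self.components]
        if any(m <= 0 for m in means) or any(
            b <= a for a, b in zip(means, means[1:])
        ):
            raise ValidationError("means must be positive and strictly increasing")

    def posterior(self, amplitude: float) -> np.ndarray:
        dens = np.array(
            [area * norm.pdf(amplitude, mean, sd) for mean, sd, area in self.components]
        )
        total = dens.sum()
        return dens / total if total > 0 else dens

    def assign(self, amplitude: float, z_threshold: float = 4.0) -> int:
        """Index of the most probable component, or -1 if the amplitude is
        more than ``z_threshold`` SDs from every component mean."""
        z = np.array(
            [abs(amplitude - mean) / sd for mean, sd, _ in self.components]
        )
        if np.all(z > z_threshold):
            return -1
        return int(np.argmax(self.posterior(amplitude)))


@dataclass(frozen=True)
class Burst:
    start: float  # ms from record start
    duration: float  # ms, first opening start to last opening end
    n_openings: int
    open_time: float  # ms, summed open durations
    mean_amplitude: float  # pA (nan if no opening has a defined amplitude)
    conductance_class: str = ""


@dataclass
class BurstSet:
    bursts: list[Burst]
    tcrit: float  # ms

    def __len__(self) -> int:
        return len(self.bursts)

    def total_open_time(self) -> float:
        return float(sum(b.open_time for b in self.bursts))

    def total_openings(self) -> int:
        return int(sum(b.n_openings for b in self.bursts))


# ---------------------------------------------------------------------------


def rise_time(filter_cutoff_khz: float, constant: float = GAUSSIAN_RISE_TIME_CONSTANT) -> float:
    """10-90% rise time (ms) of a Gaussian-response filter of cutoff f_c (kHz)."""
    if not filter_cutoff_khz > 0:
        raise DomainError("filter cutoff must be > 0 kHz")
    return constant / filter_cutoff_khz


def filter_resolvable(
    record: IdealizedRecord, constant: float = GAUSSIAN_RISE_TIME_CONSTANT
) -> tuple[np.ndarray, np.ndarray]:
    """Amplitudes of openings long enough to have well-defined amplitudes.

    An opening enters amplitude analysis only if its duration exceeds twice
    the filter rise time; shorter openings stay in the event sequence (they
    still count for burst structure) but are excluded here. Returns
    (amplitudes, durations) of the retained openings; empty arrays (with a
    warning) if nothing survives.
    """
    t_r = rise_time(record.filter_cutoff, constant)
    keep = [
        (e.amplitude, e.duration)
        for e in record.openings
        if e.duration > 2.0 * t_r and not math.isnan(e.amplitude)
    ]
    if not keep:
        warnings.warn("no opening exceeds twice the filter rise time")
        return np.array([]), np.array([])
    amps, durs = zip(*keep)
    return np.array(amps, float), np.array(durs, float)


def fit_amplitude_mixture(
    amplitudes: np.ndarray,
    k: int | str = "auto",
    min_openings: int = 100,
    random_state: int = 0,
) -> AmplitudeMixture:
    """Maximum-likelihood Gaussian mixture of fitted open amplitudes.

    ``k`` is 1, 2, 3 or "auto" (BIC selection over k in {1, 2, 3}).
    Requires at least ``min_openings`` amplitudes — amplitude estimates
    from few openings are unreliable, so the floor is enforced, not warned.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    if amplitudes.size < min_openings:
        raise InsufficientDataError(
            f"amplitude mixture needs >= {min_openings} openings, got {amplitudes.size}"
        )
    X = amplitudes.reshape(-1, 1)

    def fit_k(kk: int) -> GaussianMixture:
        return GaussianMixture(
            n_components=kk, n_init=5, random_state=random_state
        ).fit(X)

    if k == "auto":
        models = {kk: fit_k(kk) for kk in (1, 2, 3)}
        best_k = min(models, key=lambda kk: models[kk].bic(X))
        gm = models[best_k]
    else:
        if k not in (1, 2, 3):
            raise DomainError("k must be 1, 2, 3 or 'auto'")
        gm = fit_k(int(k))
    comps = sorted(
        zip(
            gm.means_.ravel().tolist(),
            np.sqrt(gm.covariances_.ravel()).tolist(),
            gm.weights_.ravel().tolist(),
        )
    )
    # renormalize areas against floating-point drift
    total = sum(c[2] for c in comps)
    comps = [(m, s, a / total) for m, s, a in comps]
    return AmplitudeMixture(components=comps, n_openings_used=int(amplitudes.size))


def chord_conductance(
    amplitude_pa: float, holding_potential_mv: float, reversal_potential_mv: float = 0.0
) -> float:
    """Chord conductance in pS: g = i / |V_hold − V_rev| (pA/mV → nS → pS)."""
    driving = abs(holding_potential_mv - reversal_potential_mv)
    if driving == 0:
        raise DomainError("holding potential equals reversal potential")
    return amplitude_pa / driving * 1000.0


def segment_bursts(record: IdealizedRecord, tcrit: float) -> BurstSet:
    """Group openings into bursts at critical shut time ``tcrit`` (ms).

    Openings separated by shut intervals shorter than tcrit form one burst;
    a shut interval >= tcrit ends the burst. Burst duration runs from the
    first opening's start to the last opening's end, so total open time and
    opening count are conserved exactly for any tcrit.
    """
    if not tcrit > record.resolution / 1000.0:
        raise DomainError("tcrit must exceed the imposed resolution")
    bursts: list[Burst] = []
    t = 0.0
    current: list[tuple[float, Event]] = []  # (start time, opening)

    def close_burst() -> None:
        if not current:
            return
        start = current[0][0]
        end = current[-1][0] + current[-1][1].duration
        amps = [e.amplitude for _, e in current if not math.isnan(e.amplitude)]
        bursts.append(
            Burst(
                start=start,
                duration=end - start,
                n_openings=len(current),
                open_time=float(sum(e.duration for _, e in current)),
                mean_amplitude=float(np.mean(amps)) if amps else float("nan"),
            )
        )
        current.clear()

    for ev in record.events:
        if ev.state == "open":
            current.append((t, ev))
        else:
            if ev.duration >= tcrit:
                close_burst()
        t += ev.duration
    close_burst()
    return BurstSet(bursts=bursts, tcrit=tcrit)


def burst_class_stats(
    bursts: BurstSet,
    mixture: AmplitudeMixture,
    holding_potential_mv: float = -100.0,
    reversal_potential_mv: float = 0.0,
    z_threshold: float = 4.0,
) -> pd.DataFrame:
    """Per-conductance-class burst summary.

    Each burst is assigned to the mixture component with the highest
    posterior density at the burst's mean open amplitude (bursts with mean
    amplitude more than ``z_threshold`` SDs from every component are
    "unassigned"). One row per class: burst count, proportion of all
    bursts, mean duration ± SEM, mean amplitude and mean chord conductance.
    """
    if not bursts.bursts:
        return pd.DataFrame(
            columns=[
                "conductance_class", "n_bursts", "proportion", "mean_duration_ms",
                "sem_duration_ms", "mean_amplitude_pa", "mean_conductance_ps",
            ]
        )
    labels = []
    for b in bursts.bursts:
        if math.isnan(b.mean_amplitude):
            labels.append(-1)
        else:
            labels.append(mixture.assign(b.mean_amplitude, z_threshold))
    n_total = len(bursts.bursts)
    records = []
    for idx in sorted(set(labels)):
        sel = [b for b, lab in zip(bursts.bursts, labels) if lab == idx]
        durs = np.array([b.duration for b in sel])
        amps = np.array([b.mean_amplitude for b in sel if not math.isnan(b.mean_amplitude)])
        name = "unassigned" if idx < 0 else f"class_{idx}"
        mean_amp = float(amps.mean()) if amps.size else float("nan")
        records.append(
            {
                "conductance_class": name,
                "n_bursts": len(sel),
                "proportion": len(sel) / n_total,
                "mean_duration_ms": float(durs.mean()),
                "sem_duration_ms": float(durs.std(ddof=1) / np.sqrt(durs.size))
                if durs.size > 1
                else float("nan"),
                "mean_amplitude_pa": mean_amp,
                "mean_conductance_ps": chord_conductance(
                    mean_amp, holding_potential_mv, reversal_potential_mv
                )
                if not math.isnan(mean_amp)
                else float("nan"),
            }
        )
    return pd.DataFrame.from_records(records)


def count_direct_transitions(
    record: IdealizedRecord, mixture: AmplitudeMixture, z_threshold: float = 4.0
) -> int:
    """Diagnostic: consecutive openings (separated by one shut gap) that
    belong to different conductance classes — expected 0 if the classes are
    produced by different receptor molecules."""
    opens = [e for e in record.openings if not math.isnan(e.amplitude)]
    n = 0
    prev = None
    for e in opens:
        cls = mixture.assign(e.amplitude, z_threshold)
        if prev is not None and cls >= 0 and prev >= 0 and cls != prev:
            n += 1
        prev = cls
    return n
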