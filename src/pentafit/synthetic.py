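"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure the analysis assumes, so
every stage can be exercised and validated without recordings:

* whole-cell dose-response protocols — Hill-curve truth per receptor set,
  multiplicative lognormal noise on peak currents, geometric rundown per
  application, and a near-EC20 standard application interleaved every third
  response (descending dose order);
* reporter-mutation panels — mutant EC50s displaced from the wild type by
  r^copies under a chosen (α, β) copy assignment;
* Zn²⁺ modulation curves from either the biphasic or the inhibition-only
  truth;
* idealized single-channel records as alternating open/shut event lists
  drawn from one or more conductance classes (exponential durations,
  Gaussian amplitudes), with the stated resolution imposed.

Every generator returns its ground truth alongside the data; the bundle
writer emits ``*_truth.json`` sidecars next to each table so downstream
recovery checks read truth only from the sidecar.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from ._errors import DomainError, ValidationError
from .dose_response import Application, DoseResponseCell, HillFit, _hill
from .single_channel import Event, IdealizedRecord
from .zinc import BiphasicFit, SingleHillFit, ZincCurve, biphasic_response, single_hill_response

__all__ = [
    "DoseResponseScenario",
    "ChannelClassSpec",
    "simulate_dose_response",
    "simulate_mutation_panel",
    "simulate_partial_curves",
    "simulate_zinc_curve",
    "simulate_single_channel",
    "impose_resolution",
    "default_concentrations",
    "write_bundle",
]


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------


def default_concentrations(ec50: float, n: int = 8, span_decades: float = 3.0) -> np.ndarray:
    """Descending geometric concentration series centred on the EC50."""
    hi = ec50 * 10.0 ** (span_decades / 2.0)
    lo = ec50 * 10.0 ** (-span_decades / 2.0)
    return np.geomspace(hi, lo, n)


@dataclass
class DoseResponseScenario:
    """Truth and protocol for one receptor set's dose-response experiment."""

    true_hill: HillFit
    concentrations: np.ndarray | None = None  # µM, descending
    n_cells: int = 6
    noise_cv: float = 0.05
    rundown_per_application: float = 0.02
    standard_every: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.rundown_per_application < 0.1:
            raise ValidationError("rundown_per_application must be in [0, 0.1)")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if self.concentrations is None:
            self.concentrations = default_concentrations(self.true_hill.ec50)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.concentrations.size == 0:
            raise ValidationError("concentration list must not be empty")


@dataclass
class ChannelClassSpec:
    """One conductance class of a single-channel record."""

    amplitude_mean: float  # pA
    amplitude_sd: float  # pA
    mean_burst_duration: float  # ms
    mean_openings_per_burst: float
    within_burst_gap_mean: float  # ms
    between_burst_gap_mean: float  # ms
    relative_frequency: float  # fraction of bursts

    def __post_init__(self) -> None:
        if not self.within_burst_gap_mean < self.between_burst_gap_mean:
            raise ValidationError("within-burst gaps must be shorter than between-burst gaps")
        if self.mean_openings_per_burst < 1:
            raise ValidationError("mean openings per burst must be >= 1")

    @property
    def mean_open_duration(self) -> float:
        """Open-period mean implied by the burst duration and structure."""
        n = self.mean_openings_per_burst
        open_total = self.mean_burst_duration - (n - 1) * self.within_burst_gap_mean
        if open_total <= 0:
            raise ValidationError("burst duration too short for the stated gap structure")
        return open_total / n


#: Low-conductance class: small-amplitude openings in long bursts.
LOW_CONDUCTANCE_CLASS = ChannelClassSpec(
    amplitude_mean=2.6,
    amplitude_sd=0.5,
    mean_burst_duration=100.0,
    mean_openings_per_burst=10.0,
    within_burst_gap_mean=1.0,
    between_burst_gap_mean=500.0,
    relative_frequency=1.0,
)

#: High-conductance class: larger openings in short bursts.
HIGH_CONDUCTANCE_CLASS = ChannelClassSpec(
    amplitude_mean=3.9,
    amplitude_sd=0.4,
    mean_burst_duration=14.0,
    mean_openings_per_burst=3.0,
    within_burst_gap_mean=0.5,
    between_burst_gap_mean=500.0,
    relative_frequency=1.0,
)


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with unit mean and coefficient of variation cv."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def _ec20(fit: HillFit) -> float:
    """Concentration giving 20% of the fitted maximum."""
    return fit.ec50 * (0.2 / 0.8) ** (1.0 / fit.n_h)


# ---------------------------------------------------------------------------
# dose-response
# ---------------------------------------------------------------------------


def simulate_dose_response(
    scenario: DoseResponseScenario, seed: int | np.random.Generator
) -> tuple[list[DoseResponseCell], dict]:
    """Simulate one receptor set's cells under the stated protocol.

    Per cell: the test concentrations are applied in the given (descending)
    order with a standard near-EC20 application interleaved every
    ``standard_every`` responses (and one closing standard so the standards
    bracket the tests). Each response is Hill truth × cumulative geometric
    rundown × lognormal noise. Returns the cells and a truth dict.
    """
    rng = np.random.default_rng(seed)
    fit = scenario.true_hill
    std_conc = _ec20(fit)
    cells = []
    for i in range(scenario.n_cells):
        apps: list[Application] = []
        k = 0  # application index

        def respond(conc: float) -> float:
            nonlocal k
            truth = float(_hill(np.array([conc]), fit.i_max, fit.ec50, fit.n_h)[0])
            decay = (1.0 - scenario.rundown_per_application) ** k
            k += 1
            return truth * decay * float(_lognormal_factor(rng, scenario.noise_cv))

        for j, conc in enumerate(scenario.concentrations):
            if j % max(scenario.standard_every - 1, 1) == 0:
                apps.append(Application("ACh", std_conc, respond(std_conc), True))
            apps.append(Application("ACh", float(conc), respond(float(conc)), False))
        apps.append(Application("ACh", std_conc, respond(std_conc), True))
        cells.append(DoseResponseCell(cell_id=f"cell{i + 1:02d}", applications=apps))
    truth = {
        "i_max": fit.i_max,
        "ec50": fit.ec50,
        "n_h": fit.n_h,
        "noise_cv": scenario.noise_cv,
        "rundown_per_application": scenario.rundown_per_application,
        "standard_concentration": std_conc,
        "n_cells": scenario.n_cells,
    }
    return cells, truth


def simulate_mutation_panel(
    wild_type: HillFit,
    r: float,
    assignment: tuple[int, int],
    seed: int | np.random.Generator,
    n_cells: int = 6,
    noise_cv: float = 0.05,
    rundown_per_application: float = 0.02,
) -> tuple[dict[str, list[DoseResponseCell]], dict]:
    """Simulate wild-type, α-mutant and β-mutant dose-response sets.

    Under the per-copy shift model, the mutant EC50 is the wild-type EC50
    divided by r raised to the mutated subunit's copy count in the
    ``assignment`` = (α copies, β copies). Everything else is shared.
    """
    if r < 1:
        raise DomainError("per-copy factor r must be >= 1")
    if tuple(assignment) not in ((2, 3), (3, 2)):
        raise DomainError("assignment must be (2, 3) or (3, 2)")
    rng = np.random.default_rng(seed)
    alpha_copies, beta_copies = assignment
    sets: dict[str, list[DoseResponseCell]] = {}
    truths: dict[str, dict] = {}
    for label, copies in (("wt", 0), ("alpha_mut", alpha_copies), ("beta_mut", beta_copies)):
        fit = HillFit(
            i_max=wild_type.i_max,
            ec50=wild_type.ec50 / r**copies,
            n_h=wild_type.n_h,
        )
        scen = DoseResponseScenario(
            true_hill=fit,
            n_cells=n_cells,
            noise_cv=noise_cv,
            rundown_per_application=rundown_per_application,
        )
        cells, truth = simulate_dose_response(scen, rng)
        truth["mutant_copies"] = copies
        sets[label] = cells
        truths[label] = truth
    truth_all = {
        "r": r,
        "assignment": {"alpha": alpha_copies, "beta": beta_copies},
        "sets": truths,
        "true_potency_ratio_alpha_mut": r**alpha_copies,
        "true_potency_ratio_beta_mut": r**beta_copies,
    }
    return sets, truth_all


def simulate_partial_curves(
    agonist_ec50s: dict[str, float],
    n_h: float,
    i_max: float,
    seed: int | np.random.Generator,
    n_cells: int = 8,
    points_per_agonist: int = 3,
    max_fraction: float = 0.08,
    noise_cv: float = 0.02,
    standard_agonist: str = "ACh",
) -> tuple[list, dict]:
    """Foot-of-curve panels for potency-ratio estimation.

    Each cell probes every agonist at 2-3 concentrations chosen so the
    noiseless responses stay below ``max_fraction`` of the maximum (the
    foot-of-curve condition); responses are Hill truth × lognormal noise.
    True potency ratio of agonist a = EC50(standard)/EC50(a) under equal
    Hill slope and efficacy.
    """
    from .potency import PartialCurveSet

    if standard_agonist not in agonist_ec50s:
        raise DomainError("standard agonist must be in the panel")
    rng = np.random.default_rng(seed)
    # top concentration giving max_fraction of I_max: A = EC50*(f/(1-f))^(1/nH)
    frac = (max_fraction / (1.0 - max_fraction)) ** (1.0 / n_h)
    cells = []
    for i in range(n_cells):
        pts = {}
        for agonist, ec50 in agonist_ec50s.items():
            top = ec50 * frac
            concs = top * 2.0 ** -np.arange(points_per_agonist)[::-1]
            resp = _hill(concs, i_max, ec50, n_h) * _lognormal_factor(
                rng, noise_cv, size=concs.size
            )
            pts[agonist] = (concs, resp)
        cells.append(
            PartialCurveSet(cell_id=f"cell{i + 1:02d}", points=pts, standard_agonist=standard_agonist)
        )
    std = agonist_ec50s[standard_agonist]
    truth = {
        "n_h": n_h,
        "i_max": i_max,
        "agonist_ec50s": dict(agonist_ec50s),
        "true_potency_ratios": {a: std / e for a, e in agonist_ec50s.items()},
        "noise_cv": noise_cv,
    }
    return cells, truth


# ---------------------------------------------------------------------------
# zinc
# ---------------------------------------------------------------------------


def simulate_zinc_curve(
    truth: BiphasicFit | SingleHillFit,
    concentrations_um: np.ndarray | None = None,
    noise_cv: float = 0.05,
    seed: int | np.random.Generator = 0,
    cell_id: str = "",
) -> tuple[ZincCurve, dict]:
    """Normalized ACh responses across a Zn²⁺ concentration series."""
    rng = np.random.default_rng(seed)
    if concentrations_um is None:
        concentrations_um = np.geomspace(1.0, 1e4, 10)
    concentrations_um = np.asarray(concentrations_um, dtype=float)
    x = np.log10(concentrations_um)
    if isinstance(truth, BiphasicFit):
        clean = biphasic_response(x, truth)
        truth_dict = {"model": "biphasic", **asdict(truth)}
    else:
        clean = single_hill_response(x, truth)
        truth_dict = {"model": "single_hill", **asdict(truth)}
    resp = np.maximum(clean * _lognormal_factor(rng, noise_cv, size=x.size), 0.0)
    truth_dict["noise_cv"] = noise_cv
    return ZincCurve(zinc_um=concentrations_um, response=resp, cell_id=cell_id), truth_dict


#: Inhibition-only Zn²⁺ truth used for the three-α-like study condition.
INHIBITION_ONLY_TRUTH = SingleHillFit(min_effect=-1.0, ic50_zn=400.0, n_h=1.4)

#: Biphasic Zn²⁺ truth used for the two-α-like study condition: enhancement
#: peaking around +70% near 168 µM, inhibition with IC50 3.2 mM.
BIPHASIC_TRUTH = BiphasicFit(
    w=0.5,
    max_effect=1.0 + 0.7 / 0.5,  # enhancement amplitude 0.7
    min_effect=-1.0 / 0.5,  # inhibition amplitude -1 (complete block)
    ec50_zn=168.2,
    ic50_zn=3200.0,
    n_h1=1.8,
    n_h2=2.1,
)


# ---------------------------------------------------------------------------
# single channel
# ---------------------------------------------------------------------------


def impose_resolution(events: list[Event], resolution_us: float) -> list[Event]:
    """Impose a fixed temporal resolution on an event list.

    Intervals shorter than the resolution are unresolvable and are absorbed
    into the preceding interval (the following same-state interval then
    concatenates); leading unresolvable intervals are dropped. Amplitudes
    of concatenated openings are duration-weighted. Never produces a
    non-positive duration.
    """
    res_ms = resolution_us / 1000.0
    out: list[list] = []  # [state, duration, amplitude]
    for ev in events:
        if out and ev.state == out[-1][0]:
            prev = out[-1]
            if ev.state == "open":
                tot = prev[1] + ev.duration
                a_prev = prev[2] if not math.isnan(prev[2]) else ev.amplitude
                a_ev = ev.amplitude if not math.isnan(ev.amplitude) else a_prev
                prev[2] = (a_prev * prev[1] + a_ev * ev.duration) / tot
            prev[1] += ev.duration
            continue
        if ev.duration < res_ms:
            if out:
                out[-1][1] += ev.duration
            # else: drop a leading unresolvable interval
            continue
        out.append([ev.state, ev.duration, ev.amplitude])
    return [Event(state=s, duration=d, amplitude=a) for s, d, a in out]


def simulate_single_channel(
    classes: list[ChannelClassSpec],
    record_duration_s: float = 60.0,
    resolution_us: float = 100.0,
    seed: int | np.random.Generator = 0,
    holding_potential_mv: float = -100.0,
    filter_cutoff_khz: float = 1.0,
) -> tuple[IdealizedRecord, dict]:
    """Simulate an idealized outside-out record from one or more classes.

    Bursts are drawn by class ``relative_frequency``; opening counts are
    geometric with the stated mean, durations exponential, amplitudes
    Gaussian per class. The stated resolution is imposed on the raw event
    list. The truth sidecar records each generated burst's class.
    """
    if not classes:
        raise DomainError("need >= 1 channel class")
    freqs = np.array([c.relative_frequency for c in classes], dtype=float)
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValidationError("class relative frequencies must sum to 1")
    res_ms = resolution_us / 1000.0
    for c in classes:
        if resolution_us / 1000.0 >= c.within_burst_gap_mean:
            import warnings

            warnings.warn(
                "imposed resolution is not small against the within-burst "
                "gap mean; severe censoring of burst structure expected"
            )
    rng = np.random.default_rng(seed)
    events: list[Event] = []
    burst_truth = []
    t = 0.0
    total_ms = record_duration_s * 1000.0
    while t < total_ms:
        ci = int(rng.choice(len(classes), p=freqs))
        spec = classes[ci]
        gap = float(rng.exponential(spec.between_burst_gap_mean)) + res_ms
        events.append(Event("shut", gap))
        t += gap
        n_open = int(rng.geometric(1.0 / spec.mean_openings_per_burst))
        open_mean = spec.mean_open_duration
        burst_open_time = 0.0
        for j in range(n_open):
            if j > 0:
                g = max(float(rng.exponential(spec.within_burst_gap_mean)), res_ms * 1.01)
                events.append(Event("shut", g))
                t += g
            d = max(float(rng.exponential(open_mean)), res_ms * 1.01)
            amp = float(abs(rng.normal(spec.amplitude_mean, spec.amplitude_sd)))
            events.append(Event("open", d, amp))
            t += d
            burst_open_time += d
        burst_truth.append({"class_index": ci, "n_openings": n_open, "open_time_ms": burst_open_time})
    events = impose_resolution(events, resolution_us)
    record = IdealizedRecord(
        events=events,
        holding_potential=holding_potential_mv,
        filter_cutoff=filter_cutoff_khz,
        resolution=resolution_us,
    )
    truth = {
        "classes": [asdict(c) for c in classes],
        "bursts": burst_truth,
        "record_duration_s": record_duration_s,
    }
    return record, truth


# ---------------------------------------------------------------------------
# full bundle
# ---------------------------------------------------------------------------


def write_bundle(out_dir: str | Path, seed: int = 0) -> dict:
    """Write the full synthetic study bundle under ``out_dir``.

    The bundle mirrors the study conditions of the analysis: a HEK-like
    1∶1 reporter-mutation panel (wild-type EC50 91.1 µM, Hill slope 1.65,
    per-copy factor 2.65 under a 3α:2β assignment), oocyte-like 1∶9 and
    9∶1 panels, a two-ratio agonist potency panel, biphasic and
    inhibition-only Zn²⁺ curves, and single-channel records with one or
    both conductance classes. Each table gets a ``*_truth.json`` sidecar.
    Returns a manifest of the files written.
    """
    from . import io as pio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest: dict = {"seed": seed, "files": {}}

    def fork() -> np.random.Generator:
        return np.random.default_rng(rng.integers(0, 2**31 - 1))

    panels = {
        "hek_1to1": dict(
            wild_type=HillFit(i_max=6.67, ec50=91.1, n_h=1.65), r=2.65, assignment=(3, 2)
        ),
        "oocyte_1to9": dict(
            wild_type=HillFit(i_max=1270.0, ec50=138.0, n_h=1.79), r=2.9, assignment=(2, 3)
        ),
        "oocyte_9to1": dict(
            wild_type=HillFit(i_max=686.0, ec50=309.5, n_h=2.41), r=3.4, assignment=(3, 2)
        ),
    }
    for name, kw in panels.items():
        sets, truth = simulate_mutation_panel(seed=fork(), **kw)
        paths = {}
        for label, cells in sets.items():
            p = out / f"{name}_{label}.tsv"
            pio.write_dose_response_table(cells, p)
            paths[label] = str(p)
        tp = out / f"{name}_truth.json"
        tp.write_text(json.dumps(truth, indent=1, sort_keys=True))
        manifest["files"][name] = {"tables": paths, "truth": str(tp)}

    # agonist potency panels (EC50s in µM; ACh is the standard)
    potency_panels = {
        "potency_1to9": dict(
            agonist_ec50s={"ACh": 138.0, "DMPP": 138.0 / 0.99, "carbachol": 138.0 / 0.094},
            n_h=1.45,
            i_max=1270.0,
        ),
        "potency_9to1": dict(
            agonist_ec50s={"ACh": 309.5, "DMPP": 309.5 / 10.2, "carbachol": 309.5 / 0.093},
            n_h=2.19,
            i_max=686.0,
        ),
    }
    for name, kw in potency_panels.items():
        cells, truth = simulate_partial_curves(seed=fork(), **kw)
        p = out / f"{name}.tsv"
        pio.write_partial_curve_table(cells, p)
        tp = out / f"{name}_truth.json"
        tp.write_text(json.dumps(truth, indent=1, sort_keys=True))
        manifest["files"][name] = {"tables": {"partial": str(p)}, "truth": str(tp)}

    zincs = {
        "zinc_2alpha": BIPHASIC_TRUTH,
        "zinc_3alpha": INHIBITION_ONLY_TRUTH,
    }
    for name, truth_fit in zincs.items():
        curves = []
        truths = []
        for i in range(5):
            c, tr = simulate_zinc_curve(truth_fit, seed=fork(), cell_id=f"cell{i + 1:02d}")
            curves.append(c)
            truths.append(tr)
        p = out / f"{name}.tsv"
        pio.write_zinc_table(curves, p)
        tp = out / f"{name}_truth.json"
        tp.write_text(json.dumps(truths[0], indent=1, sort_keys=True))
        manifest["files"][name] = {"tables": {"zinc": str(p)}, "truth": str(tp)}

    channels = {
        "sc_1to9": [
            ChannelClassSpec(**{**asdict(LOW_CONDUCTANCE_CLASS), "relative_frequency": 1.0})
        ],
        "sc_9to1": [
            ChannelClassSpec(**{**asdict(LOW_CONDUCTANCE_CLASS), "relative_frequency": 0.08}),
            ChannelClassSpec(**{**asdict(HIGH_CONDUCTANCE_CLASS), "relative_frequency": 0.92}),
        ],
    }
    for name, classes in channels.items():
        rec, truth = simulate_single_channel(classes, record_duration_s=120.0, seed=fork())
        p = out / f"{name}.tsv"
        pio.write_event_table(rec, p)
        tp = out / f"{name}_truth.json"
        tp.write_text(json.dumps(truth, indent=1, sort_keys=True))
        manifest["files"][name] = {"tables": {"events": str(p)}, "truth": str(tp)}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
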