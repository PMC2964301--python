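"""End-to-end pipeline driver chaining the analysis stages.

``run_pipeline`` takes whatever inputs are available — dose-response tables
per receptor set, a partial-curve agonist panel, zinc tables, idealized
single-channel event lists — runs every stage whose input is present (a
stage with no input is skipped with a logged warning), writes one
tab-separated result table per stage plus a machine-readable
``summary.json``, and logs the seed, package versions and every fitted
parameter.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from ._errors import InsufficientDataError, PentafitError
from .config import AnalysisConfig
from .dose_response import fit_hill, parallel_fit, pool_curves, rundown_correct
from .potency import fit_free_slopes, fit_parallel_powerlaw, pool_potency
from .single_channel import (
    burst_class_stats,
    count_direct_transitions,
    filter_resolvable,
    fit_amplitude_mixture,
    segment_bursts,
)
from .stoichiometry import infer_stoichiometry
from .zinc import classify_modulation, fit_biphasic

log = logging.getLogger("pentafit")

__all__ = ["PipelineInputs", "run_pipeline", "inputs_from_bundle"]


@dataclass
class PipelineInputs:
    """File paths for the pipeline stages; any subset may be provided.

    ``dose_response`` maps receptor-set labels (e.g. per panel:
    wt/alpha_mut/beta_mut) to table paths; ``reference`` names the
    wild-type label and ``alpha_label``/``beta_label`` the mutant sets for
    the stoichiometry call. ``panels`` allows several independent
    dose-response panels, each its own mapping.
    """

    panels: dict[str, dict[str, Path]] = field(default_factory=dict)
    reference: str = "wt"
    alpha_label: str = "alpha_mut"
    beta_label: str = "beta_mut"
    partial_curves: dict[str, Path] = field(default_factory=dict)
    zinc: dict[str, Path] = field(default_factory=dict)
    single_channel: dict[str, Path] = field(default_factory=dict)

    def any_stage(self) -> bool:
        return bool(self.panels or self.partial_curves or self.zinc or self.single_channel)


def inputs_from_bundle(manifest_path: str | Path) -> PipelineInputs:
    """Build PipelineInputs from a synthetic bundle's manifest.json."""
    manifest = json.loads(Path(manifest_path).read_text())
    inputs = PipelineInputs()
    for name, entry in manifest["files"].items():
        tables = {k: Path(v) for k, v in entry["tables"].items()}
        if set(tables) >= {"wt", "alpha_mut", "beta_mut"}:
            inputs.panels[name] = tables
        elif "partial" in tables:
            inputs.partial_curves[name] = tables["partial"]
        elif "zinc" in tables:
            inputs.zinc[name] = tables["zinc"]
        elif "events" in tables:
            inputs.single_channel[name] = tables["events"]
    return inputs


def _dose_response_stage(
    inputs: PipelineInputs, config: AnalysisConfig, out: Path, summary: dict
) -> None:
    hill_rows, ratio_rows, stoich_rows = [], [], []
    for panel, tables in sorted(inputs.panels.items()):
        curves = []
        for label in sorted(tables):
            cells = pio.read_dose_response_table(tables[label], config)
            corrected = []
            for cell in cells:
                try:
                    cell = rundown_correct(cell)
                except InsufficientDataError:
                    log.warning("%s/%s/%s: <2 standards, rundown correction skipped",
                                panel, label, cell.cell_id)
                corrected.append(cell)
            for cell in corrected:
                fit = fit_hill(cell)
                log.info("%s/%s/%s: i_max=%.4g ec50=%.4g n_h=%.3g",
                         panel, label, cell.cell_id, fit.i_max, fit.ec50, fit.n_h)
                hill_rows.append(
                    {
                        "panel": panel,
                        "curve": label,
                        "cell_id": cell.cell_id,
                        "i_max": fit.i_max,
                        "se_i_max": fit.se_i_max,
                        "ec50_um": fit.ec50,
                        "se_ec50_um": fit.se_ec50,
                        "n_h": fit.n_h,
                        "se_n_h": fit.se_n_h,
                        "rss": fit.rss,
                        "n_points": fit.n_points,
                        "converged": fit.converged,
                    }
                )
            curves.append(pool_curves(label, corrected))
        if len(curves) < 2 or inputs.reference not in [c.label for c in curves]:
            log.warning("panel %s: no reference curve, parallel fit skipped", panel)
            continue
        pf = parallel_fit(curves, inputs.reference, config.likelihood_delta)
        for label in pf.labels:
            iv = pf.likelihood_intervals.get(label)
            ratio_rows.append(
                {
                    "panel": panel,
                    "curve": label,
                    "shared_n_h": pf.shared_n_h,
                    "reference_ec50_um": pf.reference_ec50,
                    "dose_ratio": pf.dose_ratios[label],
                    "potency_ratio": 1.0 / pf.dose_ratios[label],
                    "ratio_ci_low": 1.0 / iv.high if iv else np.nan,
                    "ratio_ci_high": 1.0 / iv.low if iv else np.nan,
                    "parallelism_f": pf.parallelism_f,
                    "parallelism_p": pf.parallelism_p,
                }
            )
        if {inputs.alpha_label, inputs.beta_label} <= set(pf.dose_ratios):
            ra = 1.0 / pf.dose_ratios[inputs.alpha_label]
            rb = 1.0 / pf.dose_ratios[inputs.beta_label]
            iva = pf.likelihood_intervals.get(inputs.alpha_label)
            ivb = pf.likelihood_intervals.get(inputs.beta_label)
            call = infer_stoichiometry(
                ra,
                rb,
                interval_alpha=(1.0 / iva.high, 1.0 / iva.low) if iva else None,
                interval_beta=(1.0 / ivb.high, 1.0 / ivb.low) if ivb else None,
            )
            log.info("panel %s: stoichiometry %da:%db (r=%.3g, score=%.3g)",
                     panel, call.assignment["alpha"], call.assignment["beta"],
                     call.r, call.consistency_score)
            stoich_rows.append(
                {
                    "panel": panel,
                    "ratio_alpha_mut": ra,
                    "ratio_beta_mut": rb,
                    "alpha_copies": call.assignment["alpha"],
                    "beta_copies": call.assignment["beta"],
                    "r_per_copy": call.r,
                    "consistency_score": call.consistency_score,
                    "score_2a3b": call.candidate_scores[(2, 3)],
                    "score_3a2b": call.candidate_scores[(3, 2)],
                    "ambiguous": call.ambiguous,
                }
            )
            summary.setdefault("stoichiometry", {})[panel] = {
                "assignment": call.assignment,
                "r": call.r,
                "ambiguous": call.ambiguous,
            }
    if hill_rows:
        pd.DataFrame(hill_rows).to_csv(out / "hill_fits.tsv", sep="\t", index=False)
        summary["hill_fits"] = str(out / "hill_fits.tsv")
    if ratio_rows:
        pd.DataFrame(ratio_rows).to_csv(out / "parallel_fits.tsv", sep="\t", index=False)
        summary["parallel_fits"] = str(out / "parallel_fits.tsv")
    if stoich_rows:
        pd.DataFrame(stoich_rows).to_csv(out / "stoichiometry.tsv", sep="\t", index=False)
        summary["stoichiometry_table"] = str(out / "stoichiometry.tsv")


def _potency_stage(
    inputs: PipelineInputs, config: AnalysisConfig, out: Path, summary: dict
) -> None:
    for name, path in sorted(inputs.partial_curves.items()):
        cells = pio.read_partial_curve_table(path)
        fits, slopes = [], []
        for cell in cells:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fits.append(fit_parallel_powerlaw(cell))
                slopes.append({a: sv for a, sv in fit_free_slopes(cell).items()})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = pool_potency(fits, slopes)
        table.insert(0, "panel", name)
        p = out / f"potency_{name}.tsv"
        table.to_csv(p, sep="\t", index=False)
        summary.setdefault("potency", {})[name] = str(p)
        for row in table.itertuples():
            log.info("%s: %s potency=%.4g n=%d", name, row.agonist, row.potency_ratio, row.n_cells)


def _zinc_stage(
    inputs: PipelineInputs, config: AnalysisConfig, out: Path, summary: dict
) -> None:
    rows = []
    for name, path in sorted(inputs.zinc.items()):
        for curve in pio.read_zinc_table(path):
            pair = fit_biphasic(curve)
            cls = classify_modulation(pair)
            row = {
                "panel": name,
                "cell_id": curve.cell_id,
                "classification": cls.kind,
                "f_statistic": cls.f_statistic,
                "p_value": cls.p_value,
                "peak_enhancement": cls.peak_enhancement,
                "low_confidence": cls.low_confidence,
            }
            if pair.biphasic is not None:
                row.update(
                    ec50_zn_um=pair.biphasic.ec50_zn,
                    ic50_zn_um=pair.biphasic.ic50_zn,
                    n_h1=pair.biphasic.n_h1,
                    n_h2=pair.biphasic.n_h2,
                    enhancement_amplitude=pair.biphasic.enhancement_amplitude,
                    inhibition_amplitude=pair.biphasic.inhibition_amplitude,
                )
            if pair.single is not None:
                row.update(
                    single_ic50_zn_um=pair.single.ic50_zn,
                    single_n_h=pair.single.n_h,
                    single_min_effect=pair.single.min_effect,
                )
            rows.append(row)
            log.info("%s/%s: %s (peak %.2f)", name, curve.cell_id, cls.kind, cls.peak_enhancement)
    if rows:
        pd.DataFrame(rows).to_csv(out / "zinc_fits.tsv", sep="\t", index=False)
        summary["zinc_fits"] = str(out / "zinc_fits.tsv")


def _single_channel_stage(
    inputs: PipelineInputs, config: AnalysisConfig, out: Path, summary: dict
) -> None:
    mix_rows, class_frames = [], []
    for name, path in sorted(inputs.single_channel.items()):
        record = pio.read_event_table(path)
        amps, _ = filter_resolvable(record)
        try:
            mixture = fit_amplitude_mixture(amps, k="auto", random_state=config.random_seed)
        except InsufficientDataError as exc:
            log.warning("%s: %s", name, exc)
            continue
        for i, (mean, sd, area) in enumerate(mixture.components):
            mix_rows.append(
                {
                    "record": name,
                    "component": i,
                    "mean_pa": mean,
                    "sd_pa": sd,
                    "area": area,
                    "conductance_ps": mean / abs(record.holding_potential - config.reversal_potential) * 1000.0,
                    "n_openings_used": mixture.n_openings_used,
                }
            )
        bursts = segment_bursts(record, config.tcrit)
        stats = burst_class_stats(
            bursts, mixture, record.holding_potential, config.reversal_potential
        )
        stats.insert(0, "record", name)
        stats["direct_transitions"] = count_direct_transitions(record, mixture)
        class_frames.append(stats)
        log.info("%s: %d bursts, %d mixture component(s)", name, len(bursts), len(mixture.components))
    if mix_rows:
        pd.DataFrame(mix_rows).to_csv(out / "amplitude_mixtures.tsv", sep="\t", index=False)
        summary["amplitude_mixtures"] = str(out / "amplitude_mixtures.tsv")
    if class_frames:
        pd.concat(class_frames).to_csv(out / "burst_class_stats.tsv", sep="\t", index=False)
        summary["burst_class_stats"] = str(out / "burst_class_stats.tsv")


def run_pipeline(
    config: AnalysisConfig, inputs: PipelineInputs, out_dir: str | Path
) -> dict:
    """Run every stage whose inputs are present; write tables + summary.

    Returns the summary dict (also written to ``summary.json``). Raises if
    no stage has inputs.
    """
    if not inputs.any_stage():
        raise PentafitError("no stage has inputs")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.random_seed, "versions": _versions()}
    log.info("pipeline start: seed=%d out=%s", config.random_seed, out)

    stages = [
        ("dose_response", bool(inputs.panels), _dose_response_stage),
        ("potency", bool(inputs.partial_curves), _potency_stage),
        ("zinc", bool(inputs.zinc), _zinc_stage),
        ("single_channel", bool(inputs.single_channel), _single_channel_stage),
    ]
    for name, present, fn in stages:
        if not present:
            log.warning("stage %s skipped: no applicable input", name)
            summary.setdefault("skipped", []).append(name)
            continue
        fn(inputs, config, out, summary)
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary


def _versions() -> dict:
    import numpy
    import pandas
    import scipy
    import sklearn

    from . import __version__

    return {
        "pentafit": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "scikit-learn": sklearn.__version__,
    }
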