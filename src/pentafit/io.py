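"""Readers and writers for the pipeline's delimiter-separated table formats.

All tables are tab-separated text with a header row; event lists carry
their recording metadata as ``# key: value`` comment lines above the
header. Concentrations are µM throughout.

Formats
-------
dose-response   cell_id, application_index, agonist, concentration,
                response, is_standard
partial curves  cell_id, agonist, concentration, response
zinc            cell_id, zinc_um, normalized_response
event list      state, duration_ms, amplitude_pA  (+ metadata comments)
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import pandas as pd

from ._errors import FormatError, ValidationError
from .config import AnalysisConfig
from .dose_response import Application, DoseResponseCell
from .potency import PartialCurveSet
from .single_channel import Event, IdealizedRecord
from .zinc import ZincCurve

__all__ = [
    "read_dose_response_table",
    "write_dose_response_table",
    "read_partial_curve_table",
    "write_partial_curve_table",
    "read_zinc_table",
    "write_zinc_table",
    "read_event_table",
    "write_event_table",
]

_DR_COLUMNS = [
    "cell_id",
    "application_index",
    "agonist",
    "concentration",
    "response",
    "is_standard",
]


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return df


def read_dose_response_table(
    path: str | Path, config: AnalysisConfig | None = None
) -> list[DoseResponseCell]:
    """Read a dose-response table into one record per cell.

    Applications are ordered by ``application_index`` within each cell.
    Non-positive concentrations are a validation error naming the row.
    """
    df = _read_tsv(path, _DR_COLUMNS)
    bad = df.index[df["concentration"] <= 0]
    if len(bad):
        raise ValidationError(
            f"{path}: non-positive concentration in row(s) {list(bad[:5])}"
        )
    cells = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("application_index")
        apps = [
            Application(
                agonist=str(row.agonist),
                concentration=float(row.concentration),
                response=float(row.response),
                is_standard=bool(row.is_standard),
            )
            for row in grp.itertuples()
        ]
        cells.append(DoseResponseCell(cell_id=str(cell_id), applications=apps))
    return cells


def write_dose_response_table(cells: Sequence[DoseResponseCell], path: str | Path) -> None:
    rows = []
    for cell in cells:
        for i, app in enumerate(cell.applications):
            rows.append(
                {
                    "cell_id": cell.cell_id,
                    "application_index": i,
                    "agonist": app.agonist,
                    "concentration": repr(app.concentration),
                    "response": repr(app.response),
                    "is_standard": app.is_standard,
                }
            )
    pd.DataFrame(rows, columns=_DR_COLUMNS).to_csv(path, sep="\t", index=False)


def read_partial_curve_table(
    path: str | Path, standard_agonist: str = "ACh"
) -> list[PartialCurveSet]:
    df = _read_tsv(path, ["cell_id", "agonist", "concentration", "response"])
    bad = df.index[df["concentration"] <= 0]
    if len(bad):
        raise ValidationError(
            f"{path}: non-positive concentration in row(s) {list(bad[:5])}"
        )
    cells = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        pts = {}
        for agonist, sub in grp.groupby("agonist", sort=True):
            pts[str(agonist)] = (
                sub["concentration"].to_numpy(float),
                sub["response"].to_numpy(float),
            )
        cells.append(
            PartialCurveSet(cell_id=str(cell_id), points=pts, standard_agonist=standard_agonist)
        )
    return cells


def write_partial_curve_table(cells: Sequence[PartialCurveSet], path: str | Path) -> None:
    rows = []
    for cell in cells:
        for agonist in sorted(cell.points):
            conc, resp = cell.points[agonist]
            for c, r in zip(conc, resp):
                rows.append(
                    {
                        "cell_id": cell.cell_id,
                        "agonist": agonist,
                        "concentration": repr(float(c)),
                        "response": repr(float(r)),
                    }
                )
    pd.DataFrame(rows, columns=["cell_id", "agonist", "concentration", "response"]).to_csv(
        path, sep="\t", index=False
    )


def read_zinc_table(path: str | Path) -> list[ZincCurve]:
    df = _read_tsv(path, ["cell_id", "zinc_um", "normalized_response"])
    curves = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        curves.append(
            ZincCurve(
                zinc_um=grp["zinc_um"].to_numpy(float),
                response=grp["normalized_response"].to_numpy(float),
                cell_id=str(cell_id),
            )
        )
    return curves


def write_zinc_table(curves: Sequence[ZincCurve], path: str | Path) -> None:
    rows = []
    for curve in curves:
        for z, r in zip(curve.zinc_um, curve.response):
            rows.append(
                {
                    "cell_id": curve.cell_id,
                    "zinc_um": repr(float(z)),
                    "normalized_response": repr(float(r)),
                }
            )
    pd.DataFrame(rows, columns=["cell_id", "zinc_um", "normalized_response"]).to_csv(
        path, sep="\t", index=False
    )


_EVENT_META = {
    "holding_potential_mv": "holding_potential",
    "filter_cutoff_khz": "filter_cutoff",
    "resolution_us": "resolution",
}


def read_event_table(path: str | Path) -> IdealizedRecord:
    """Read an idealized event list with its ``# key: value`` metadata."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = float(value.strip())
    missing = [k for k in _EVENT_META if k not in meta]
    if missing:
        raise FormatError(f"{path}: missing metadata line(s) {missing}")
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    for col in ("state", "duration_ms", "amplitude_pA"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    events = [
        Event(
            state=str(row.state),
            duration=float(row.duration_ms),
            amplitude=float(row.amplitude_pA),
        )
        for row in df.itertuples()
    ]
    kwargs = {attr: meta[key] for key, attr in _EVENT_META.items()}
    return IdealizedRecord(events=events, **kwargs)


def write_event_table(record: IdealizedRecord, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# holding_potential_mv: {record.holding_potential!r}\n")
        fh.write(f"# filter_cutoff_khz: {record.filter_cutoff!r}\n")
        fh.write(f"# resolution_us: {record.resolution!r}\n")
        fh.write("state\tduration_ms\tamplitude_pA\n")
        for ev in record.events:
            amp = "nan" if math.isnan(ev.amplitude) else repr(ev.amplitude)
            fh.write(f"{ev.state}\t{ev.duration!r}\t{amp}\n")
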