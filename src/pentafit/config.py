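"""Analysis configuration.

All concentrations in the pipeline are micromolar and all log transforms are
base 10; the config records the handful of constants that the individual
stages share (likelihood-interval depth, Fieller confidence level, burst
critical shut time, filter cutoff, imposed resolution, holding/reversal
potentials).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from ._errors import FormatError, ValidationError

#: Default holding potentials (mV) for the three recording configurations.
DEFAULT_HOLDING_POTENTIALS = {
    "oocyte": -70.0,
    "hek_whole_cell": -30.0,
    "outside_out": -100.0,
}


@dataclass
class AnalysisConfig:
    """Constants shared across pipeline stages.

    Parameters
    ----------
    random_seed:
        Seed for the run's master random stream (forked per stage).
    concentration_unit:
        Fixed to micromolar; any other value is rejected.
    holding_potentials:
        Holding potential (mV) per preparation.
    reversal_potential:
        Assumed single-channel reversal potential (mV); chord conductances
        use the driving force ``|holding - reversal|``.
    likelihood_delta:
        Depth of the profile-log-likelihood interval in log-likelihood
        units. The default 2.01 corresponds to roughly +/- 2 SD for a
        Gaussian parameter.
    fieller_confidence:
        Two-sided confidence level for Fieller ratio intervals.
    tcrit:
        Critical shut time (ms) separating bursts.
    filter_cutoff:
        Bessel/Gaussian filter cutoff (kHz) used for the resolvable-opening
        rule.
    resolution:
        Imposed event resolution (microseconds).
    """

    random_seed: int = 0
    concentration_unit: str = "uM"
    holding_potentials: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HOLDING_POTENTIALS)
    )
    reversal_potential: float = 0.0
    likelihood_delta: float = 2.01
    fieller_confidence: float = 0.95
    tcrit: float = 5.0
    filter_cutoff: float = 1.0
    resolution: float = 100.0

    def __post_init__(self) -> None:
        if self.concentration_unit not in ("uM", "µM"):
            raise ValidationError(
                "concentrations are handled in µM only; got unit "
                f"{self.concentration_unit!r}"
            )
        self.concentration_unit = "uM"
        if not self.likelihood_delta > 0:
            raise ValidationError("likelihood_delta must be > 0")
        if not 0.0 < self.fieller_confidence < 1.0:
            raise ValidationError("fieller_confidence must be in (0, 1)")
        if not self.tcrit > 0:
            raise ValidationError("tcrit must be > 0 ms")
        if not self.resolution > 0:
            raise ValidationError("resolution must be > 0 µs")
        if not self.filter_cutoff > 0:
            raise ValidationError("filter_cutoff must be > 0 kHz")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load a flat key-value YAML document mirroring the fields."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise FormatError(f"config file {path} is not a flat mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
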