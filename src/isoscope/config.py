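"""Scenario specifications and their configuration-file dialect.

A scenario describes one candidate micro-evolutionary history for a set of
small founded populations ("sinks") splitting from a large ancestral
population ("source"): uniform priors over sink effective size and sink-sink
gene flow, fixed source size/growth, and uniform split times. The three
study scenarios differ only in the sink-Ne and sink-migration priors:

1. small effective size, low gene flow    (Ne 100-300, m 0-0.005)
2. small effective size, high gene flow   (Ne 100-300, m 0.015-0.02)
3. moderate effective size, low gene flow (Ne 700-900, m 0-0.005)

For the Y chromosome the same effective sizes are paired with halved gene
flow, reflecting patrilocality (women move between villages more than men).
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field, replace

from .errors import ConfigError, ValidationError

#: Default Y-STR locus panel.
DEFAULT_STR_LOCI = ["DYS19", "DYS390", "DYS391", "DYS392", "DYS393"]

#: Default per-locus, per-generation stepwise mutation rates for the panel.
#: These are package defaults in the range of published father-son estimates
#: for these loci; override via MutationSpec / scenario config for other
#: panels or rate sets.
DEFAULT_STR_RATES = {
    "DYS19": 2.2e-3,
    "DYS390": 2.1e-3,
    "DYS391": 2.6e-3,
    "DYS392": 5.0e-4,
    "DYS393": 1.1e-3,
}

#: Default whole-region substitution rate for the mtDNA control-region
#: segment, per year (converted to per-generation inside the simulator).
DEFAULT_MT_RATE_PER_YEAR = 5.2023e-5

#: Default generation time in years.
DEFAULT_GENERATION_YEARS = 25.0

#: Default HKY shape parameters. kappa and the stationary base frequencies
#: are package defaults typical of the mtDNA control region (strong
#: transition bias, G-poor), not externally estimated values.
DEFAULT_HKY_KAPPA = 40.0
DEFAULT_HKY_FREQS = (0.31, 0.31, 0.13, 0.25)  # A, C, G, T


@dataclass(frozen=True)
class ScenarioSpec:
    """Prior ranges and fixed demographic settings for one scenario/marker."""

    name: str
    sink_ne_range: tuple[float, float]
    sink_migration_range: tuple[float, float]
    marker: str = "mtdna"  # "mtdna" | "ystr"
    n_sinks: int = 3
    split_time_range: tuple[float, float] = (32.0, 48.0)
    source_ne: float = 1e5
    source_growth: float = 0.03
    sink_growth: float = 0.017
    source_to_sink_m: float = 0.0001
    sink_to_source_m: float = 0.001
    sample_size_per_sink: int = 50
    seq_length_bp: int = 333
    str_loci: tuple[str, ...] = tuple(DEFAULT_STR_LOCI)

    def __post_init__(self) -> None:
        if self.marker not in ("mtdna", "ystr"):
            raise ValidationError(f"unknown marker {self.marker!r}")
        for label, (low, high) in (
            ("sink_ne_range", self.sink_ne_range),
            ("sink_migration_range", self.sink_migration_range),
            ("split_time_range", self.split_time_range),
        ):
            if low > high:
                raise ValidationError(f"{label}: low {low} > high {high}")
        for label, value in (
            ("sink_migration_range low", self.sink_migration_range[0]),
            ("sink_migration_range high", self.sink_migration_range[1]),
            ("source_to_sink_m", self.source_to_sink_m),
            ("sink_to_source_m", self.sink_to_source_m),
        ):
            if not 0.0 <= value < 1.0:
                raise ValidationError(f"{label} = {value} outside [0, 1)")
        if self.sink_ne_range[0] <= 0 or self.source_ne <= 0:
            raise ValidationError("effective sizes must be positive")
        if self.n_sinks < 1 or self.sample_size_per_sink < 1:
            raise ValidationError("need at least one sink and one sample per sink")
        if self.seq_length_bp < 1:
            raise ValidationError("seq_length_bp must be >= 1")

    def ystr_paired(self) -> "ScenarioSpec":
        """The Y-chromosome counterpart: same sizes, all gene flow halved."""
        return replace(
            self,
            marker="ystr",
            sink_migration_range=(
                self.sink_migration_range[0] / 2.0,
                self.sink_migration_range[1] / 2.0,
            ),
            source_to_sink_m=self.source_to_sink_m / 2.0,
            sink_to_source_m=self.sink_to_source_m / 2.0,
        )


#: The three study scenarios (mtDNA priors; Y via :meth:`ScenarioSpec.ystr_paired`).
STUDY_SCENARIOS = {
    "scenario1": dict(sink_ne_range=(100.0, 300.0), sink_migration_range=(0.0, 0.005)),
    "scenario2": dict(sink_ne_range=(100.0, 300.0), sink_migration_range=(0.015, 0.02)),
    "scenario3": dict(sink_ne_range=(700.0, 900.0), sink_migration_range=(0.0, 0.005)),
}


def default_scenarios(markers=("mtdna", "ystr")) -> list[ScenarioSpec]:
    """The built-in study scenarios for the requested markers."""
    specs = []
    for name, kw in STUDY_SCENARIOS.items():
        base = ScenarioSpec(name=name, marker="mtdna", **kw)
        if "mtdna" in markers:
            specs.append(base)
        if "ystr" in markers:
            specs.append(base.ystr_paired())
    return specs


_RANGE_KEYS = {
    "sink_ne": "sink_ne_range",
    "sink_migration": "sink_migration_range",
    "split_time": "split_time_range",
}
_SCALAR_KEYS = {
    "source_ne": float,
    "source_growth": float,
    "sink_growth": float,
    "source_to_sink_m": float,
    "sink_to_source_m": float,
    "sample_size_per_sink": int,
    "seq_length_bp": int,
    "n_sinks": int,
}


def _parse_range(section_name: str, key: str, raw: str) -> tuple[float, float]:
    parts = [p.strip() for p in raw.split(",")]
    if len(parts) != 2:
        raise ConfigError(f"[{section_name}] {key}: expected 'low,high', got {raw!r}")
    low, high = float(parts[0]), float(parts[1])
    if low > high:
        raise ValidationError(f"[{section_name}] {key}: low {low} > high {high}")
    return low, high


def read_scenario_config(path) -> list[ScenarioSpec]:
    """Parse an INI-like scenario config into one spec per scenario per marker.

    Each section defines one scenario. Required keys: ``sink_ne`` and
    ``sink_migration`` as ``low,high`` pairs. Optional keys override the
    built-in defaults; ``markers = mtdna,ystr`` requests paired specs, where
    the Y member carries halved gene flow.
    """
    parser = configparser.ConfigParser()
    read_ok = parser.read(str(path))
    if not read_ok:
        raise ConfigError(f"could not read scenario config {path}")
    specs: list[ScenarioSpec] = []
    for section_name in parser.sections():
        section = parser[section_name]
        kwargs: dict = {"name": section_name}
        for key in ("sink_ne", "sink_migration"):
            if key not in section:
                raise ConfigError(f"[{section_name}] missing required key {key!r}")
        for key, target in _RANGE_KEYS.items():
            if key in section:
                kwargs[target] = _parse_range(section_name, key, section[key])
        for key, cast in _SCALAR_KEYS.items():
            if key in section:
                kwargs[key] = cast(section[key])
        if "str_loci" in section:
            kwargs["str_loci"] = tuple(
                s.strip() for s in section["str_loci"].split(",") if s.strip()
            )
        markers = [
            m.strip()
            for m in section.get("markers", "mtdna").split(",")
            if m.strip()
        ]
        base = ScenarioSpec(marker="mtdna", **kwargs)
        if "mtdna" in markers:
            specs.append(base)
        if "ystr" in markers:
            specs.append(base.ystr_paired())
        unknown = set(markers) - {"mtdna", "ystr"}
        if unknown:
            raise ConfigError(f"[{section_name}] unknown markers {sorted(unknown)}")
    if not specs:
        raise ConfigError(f"{path}: no scenario sections found")
    return specs
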