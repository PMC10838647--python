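"""File I/O and run configuration.

Observation tables travel as UTF-8 CSV with a header row; parameter sets
and fit results as JSON; run configurations as YAML (JSON is a YAML subset
and is accepted transparently).  Times are minutes throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .dataset import ObservedDataset
from .params import HPAParameters
from .simulate import InjectionEvent, SamplingScheme, default_events, default_scheme
from .synth import PopulationSpec

__all__ = [
    "read_observations",
    "write_observations",
    "RunConfig",
    "load_config",
]


def read_observations(path) -> ObservedDataset:
    """Read and validate a GC-observations CSV.

    Required columns: ``individual_id``, ``sampling_class``, ``time_min``,
    ``gc_value``; optional: ``gr_expression``, ``group``.  Class labels are
    normalized case-insensitively onto the canonical four-class vocabulary.
    Validation failures raise ``ValueError`` naming the offending rows.
    """
    df = pd.read_csv(path)
    return ObservedDataset.from_frame(df)


def write_observations(dataset: ObservedDataset, path) -> None:
    dataset.to_csv(path)


def _events_from_config(items) -> list[InjectionEvent]:
    events = []
    for it in items:
        events.append(InjectionEvent(
            time=float(it["time"]), target=str(it["target"]).upper(),
            amount=float(it["amount"]),
        ))
    return events


def _scheme_from_config(d) -> SamplingScheme:
    times = {k: float(v) for k, v in d["times"].items()}
    windows = {k: (float(v[0]), float(v[1])) for k, v in d.get("windows", {}).items()}
    return SamplingScheme(times=times, windows=windows)


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run.

    Loaded from YAML/JSON; every section is optional and falls back to the
    package defaults.  The seed governs all randomness of the run.
    """

    params: HPAParameters = field(default_factory=HPAParameters)
    free: tuple[str, ...] = ("b", "k_O", "b_O", "G_tot")
    scheme: SamplingScheme = field(default_factory=default_scheme)
    events: list = field(default_factory=default_events)
    synth: PopulationSpec = field(default_factory=PopulationSpec)
    gr_grid: list | None = None
    b_grid: list | None = None
    horizon: float = 180.0
    error_model: str = "gaussian"
    n_starts: int = 1
    seed: int = 0
    outdir: Path = Path(".")
    verbosity: int = 1

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kw = {}
        if "params" in d:
            kw["params"] = HPAParameters.from_dict(d["params"]).validate()
        if "free" in d:
            kw["free"] = tuple(d["free"])
        if "scheme" in d:
            kw["scheme"] = _scheme_from_config(d["scheme"])
        if "events" in d:
            kw["events"] = _events_from_config(d["events"])
        if "synth" in d:
            kw["synth"] = PopulationSpec(**d["synth"]).validate()
        for key in ("gr_grid", "b_grid", "horizon", "error_model", "n_starts", "seed", "verbosity"):
            if key in d:
                kw[key] = d[key]
        if "outdir" in d:
            kw["outdir"] = Path(d["outdir"])
        if "seed" in kw and not isinstance(kw["seed"], int):
            raise ValueError("seed must be an integer")
        return cls(**kw)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "free": list(self.free),
            "scheme": {
                "times": dict(self.scheme.times),
                "windows": {k: list(v) for k, v in self.scheme.windows.items()},
            },
            "events": [
                {"time": e.time, "target": e.target, "amount": e.amount}
                for e in self.events
            ],
            "horizon": self.horizon,
            "error_model": self.error_model,
            "n_starts": self.n_starts,
            "seed": self.seed,
            "outdir": str(self.outdir),
            "verbosity": self.verbosity,
        }


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML (or JSON) file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    if not isinstance(d, dict):
        raise ValueError(f"config root must be a mapping, got {type(d).__name__}")
    return RunConfig.from_dict(d)
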