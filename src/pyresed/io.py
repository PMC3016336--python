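"""Run configuration, delimited time-series I/O, and logging setup.

Output conventions: delimited (CSV) tables with ISO-8601 dates and units
embedded in column names (e.g. ``flow_m3_d``, ``ssc_kg_m3``,
``bed_bifenthrin_ng_g``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "RunConfig",
    "setup_logging",
    "read_daily_table",
    "write_node_series",
    "write_audit",
]


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


@dataclass
class RunConfig:
    """Validated configuration of one simulation run."""

    scenario_dir: Path
    output_dir: Path
    seed: int = 0
    start: str | None = None
    end: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        raw["scenario_dir"] = Path(raw["scenario_dir"])
        raw["output_dir"] = Path(raw["output_dir"])
        return cls(**raw)

    def validate(self) -> None:
        if not self.scenario_dir.is_dir():
            raise ValueError(f"scenario_dir does not exist: {self.scenario_dir}")
        self.output_dir.mkdir(parents=True, exist_ok=True)


def read_daily_table(path, date_column: str = "date") -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=[date_column])
    df[date_column] = df[date_column].dt.date
    return df


def write_node_series(node_daily: dict[str, pd.DataFrame], directory) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for node, df in node_daily.items():
        path = directory / f"node_{node}.csv"
        df.to_csv(path, index=False, float_format="%.10g")
        written.append(path)
    return written


def _plain(value):
    """Recursively coerce numpy scalars so YAML can represent the audit."""
    if isinstance(value, dict):
        return {k: _plain(v) for k, v in value.items()}
    if hasattr(value, "item"):
        return value.item()
    return value


def write_audit(audit: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(_plain(audit), sort_keys=False))
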