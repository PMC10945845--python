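"""CSV/YAML input and output with a documented schema.

Events and women tables travel as plain CSV.  Timestamps are ISO-8601 in
the file and seconds (float, from an arbitrary origin) in memory; the
origin used when writing is 2012-01-01T00:00:00 UTC.  Configurations are
YAML with a ``schema_version`` field.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import pandas as pd
import yaml

from .simulate import SimConfig

__all__ = [
    "EVENT_COLUMNS",
    "WOMAN_COLUMNS",
    "write_events",
    "read_events",
    "write_women",
    "read_women",
    "attach_women",
    "config_to_yaml",
    "config_from_yaml",
]

TIME_ORIGIN = pd.Timestamp("2012-01-01T00:00:00Z")
SCHEMA_VERSION = 1

EVENT_COLUMNS = [
    "reader_id",
    "center_id",
    "woman_id",
    "decision_timestamp",
    "decision",
    "intended_order_index",
    "arm",
    "direction",
    "reader_role",
    "moved",
]
WOMAN_COLUMNS = ["woman_id", "age", "first_screen", "cancer_status"]


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    out = events[EVENT_COLUMNS].copy()
    out["decision_timestamp"] = (
        TIME_ORIGIN + pd.to_timedelta(out["decision_timestamp"], unit="s")
    ).dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
    out.to_csv(path, index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"events file missing columns: {sorted(missing)}")
    ts = pd.to_datetime(df["decision_timestamp"], utc=True, format="ISO8601")
    df["decision_timestamp"] = (ts - TIME_ORIGIN).dt.total_seconds()
    df["moved"] = df["moved"].astype(bool)
    return df


def write_women(women: pd.DataFrame, path: str | Path) -> None:
    women[WOMAN_COLUMNS].to_csv(path, index=False)


def read_women(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(WOMAN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"women file missing columns: {sorted(missing)}")
    df["first_screen"] = df["first_screen"].astype(bool)
    return df


def attach_women(events: pd.DataFrame, women: pd.DataFrame) -> pd.DataFrame:
    """Join woman-level covariates (age, first_screen, cancer_status) onto events."""
    return events.merge(women[WOMAN_COLUMNS], on="woman_id", how="left", validate="m:1")


def _band_key_to_list(d: dict) -> list:
    return [[lo if math.isfinite(lo) else None, hi if math.isfinite(hi) else None, v] for (lo, hi), v in d.items()]


def _band_list_to_key(rows: list) -> dict:
    out = {}
    for lo, hi, v in rows:
        out[(float(lo) if lo is not None else -math.inf, float(hi) if hi is not None else math.inf)] = v
    return out


def config_to_yaml(config: SimConfig, path: str | Path) -> None:
    d = dataclasses.asdict(config)
    d["reset_fraction_by_break_band"] = _band_key_to_list(config.reset_fraction_by_break_band)
    d["break_length_mixture"] = [
        [list(band), w] for band, w in config.break_length_mixture
    ]
    d["age_range"] = list(config.age_range)
    payload = {"schema_version": SCHEMA_VERSION, "sim": d}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def config_from_yaml(path: str | Path) -> SimConfig:
    payload = yaml.safe_load(Path(path).read_text())
    if payload.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported config schema_version {payload.get('schema_version')!r}; "
            f"expected {SCHEMA_VERSION}"
        )
    d = dict(payload["sim"])
    d["reset_fraction_by_break_band"] = _band_list_to_key(d["reset_fraction_by_break_band"])
    d["break_length_mixture"] = [
        ((float(b[0]), float(b[1])), float(w)) for b, w in d["break_length_mixture"]
    ]
    d["age_range"] = tuple(d["age_range"])
    return SimConfig(**d)
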