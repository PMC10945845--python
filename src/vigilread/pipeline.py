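"""End-to-end pipeline: simulate -> sessionize -> metrics -> models -> robustness.

A single seed drives everything; the run manifest records the seed, a hash
of the configuration and row counts at every stage, so two runs with the
same configuration are bit-identical and verifiably so (equal manifest
hashes).  Real event/women CSVs matching the documented schema can be
supplied instead of the simulator.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as vio
from .metrics import accuracy_by_bin, rates_by_position, sdt_by_bin
from .models import fit_detection_model, fit_recall_model, fit_time_model, predict_curve
from .robustness import (
    break_band_analysis,
    forward_reverse_comparison,
    min_session_length_stratification,
    moved_case_sensitivity,
)
from .sessions import BreakDefinition, apply_exclusions, exclusion_audit, included, segment_sessions
from .simulate import SimConfig, simulate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs"]

logger = logging.getLogger("vigilread")


@dataclass(frozen=True)
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    break_definitions: tuple[float, ...] = (20.0,)
    confidence_level: float = 0.95
    output_dir: str = "vigilread_run"
    seed: int | None = None
    fit_models: bool = True
    run_robustness: bool = True
    min_session_lengths: tuple[int, ...] = (1, 30, 60)

    def __post_init__(self) -> None:
        if not self.break_definitions:
            raise ValueError("at least one break definition is required")
        if not 0.0 < self.confidence_level < 1.0:
            raise ValueError("confidence_level must lie in (0, 1)")

    def resolved_sim(self) -> SimConfig:
        if self.seed is None:
            return self.sim
        return dataclasses.replace(self.sim, seed=self.seed)


def _config_hash(config: PipelineConfig) -> str:
    def canon(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            o = dataclasses.asdict(o)
        if isinstance(o, dict):
            return sorted((str(k), canon(v)) for k, v in o.items())
        if isinstance(o, (list, tuple)):
            return [canon(v) for v in o]
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return o

    blob = json.dumps(canon(config), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write versioned outputs.

    Returns the manifest (also written to ``manifest.json``): seed, config
    hash, and row counts at each stage.  Any stage failure raises with the
    stage name; the partial manifest written so far is preserved.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = config.resolved_sim()
    manifest: dict = {
        "seed": sim.seed,
        "config_hash": _config_hash(config),
        "stages": {},
    }
    manifest_path = out_dir / "manifest.json"

    def checkpoint() -> None:
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    stage = "simulate"
    try:
        logger.info("simulating cohort (seed=%d)", sim.seed)
        women, events = simulate_cohort(sim)
        vio.write_women(women, out_dir / "women.csv")
        vio.write_events(events, out_dir / "events.csv")
        vio.config_to_yaml(sim, out_dir / "sim_config.yaml")
        manifest["stages"][stage] = {"women": len(women), "events": len(events)}
        checkpoint()

        merged = vio.attach_women(events, women)
        for minutes in config.break_definitions:
            stage = f"break_{minutes:g}min"
            bd = BreakDefinition(minutes)
            sub_dir = out_dir / f"break_{minutes:g}min"
            sub_dir.mkdir(exist_ok=True)
            positioned = segment_sessions(merged, bd)
            flagged = apply_exclusions(positioned)
            audit = exclusion_audit(flagged)
            analysis = included(flagged)
            analysis = analysis[analysis["position"] <= 200]
            stage_info = {"positioned": len(positioned), "analysis": len(analysis)}
            stage_info["exclusions"] = {k: int(v) for k, v in audit.items()}

            rates = rates_by_position(analysis, config.confidence_level)
            rates.to_csv(sub_dir / "rates_by_position.csv", index=False)
            accuracy_by_bin(analysis, config.confidence_level).to_csv(
                sub_dir / "accuracy_by_bin.csv", index=False
            )
            sdt_by_bin(analysis, config.confidence_level).to_csv(
                sub_dir / "sdt_by_bin.csv", index=False
            )

            if config.fit_models:
                time_flagged = apply_exclusions(positioned, for_time_model=True)
                time_records = included(time_flagged)
                fits = {
                    "recall": fit_recall_model(analysis),
                    "cancer_detected": fit_detection_model(analysis),
                    "reading_time": fit_time_model(time_records),
                }
                model_blob = {}
                for name, fit in fits.items():
                    model_blob[name] = fit.to_dict()
                    if fit.converged:
                        positions = np.arange(2, int(fit.position_range[1]) + 1)
                        curve = predict_curve(fit, positions)
                        curve.to_csv(sub_dir / f"curve_{name}.csv", index=False)
                (sub_dir / "models.json").write_text(
                    json.dumps(model_blob, indent=2, sort_keys=True)
                )
                stage_info["models_converged"] = {
                    k: bool(v.converged) for k, v in fits.items()
                }

            if config.run_robustness:
                fr = forward_reverse_comparison(merged, bd)
                fr.to_csv(sub_dir / "forward_reverse.csv", index=False)
                msl = min_session_length_stratification(
                    analysis, list(config.min_session_lengths)
                )
                msl.to_csv(sub_dir / "min_session_length.csv", index=False)
                bb = break_band_analysis(analysis)
                bb.to_csv(sub_dir / "break_bands.csv", index=False)
                mc = moved_case_sensitivity(
                    included(apply_exclusions(positioned.assign(moved=False)))
                    .loc[lambda d: d["reader_role"] == "first"]
                    .loc[lambda d: d["position"] <= 200],
                    analysis,
                )
                mc.to_csv(sub_dir / "moved_case_sensitivity.csv", index=False)

            manifest["stages"][stage] = stage_info
            checkpoint()
    except Exception as err:
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        checkpoint()
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    checkpoint()
    return manifest


def validate_inputs(events_file: str | Path, women_file: str | Path) -> list[dict]:
    """Validate external event/women CSVs against the documented schema.

    Returns a machine-readable list of violations (empty = valid): schema
    presence, enum values, per-reader timestamp monotonicity, and
    referential integrity between events and women.
    """
    violations: list[dict] = []
    try:
        events = vio.read_events(events_file)
    except (OSError, ValueError) as err:
        return [{"kind": "unreadable_events", "detail": str(err)}]
    try:
        women = vio.read_women(women_file)
    except (OSError, ValueError) as err:
        return [{"kind": "unreadable_women", "detail": str(err)}]

    enums = {
        "decision": {"recall", "no_recall"},
        "arm": {"control", "intervention"},
        "direction": {"forward", "reverse"},
        "reader_role": {"first", "second"},
    }
    for col, allowed in enums.items():
        bad = set(events[col].unique()) - allowed
        if bad:
            violations.append(
                {"kind": "bad_enum", "column": col, "values": sorted(map(str, bad))}
            )
    if (events["intended_order_index"] < 1).any():
        violations.append({"kind": "bad_intended_order_index", "detail": "must be >= 1"})

    for reader, sub in events.groupby("reader_id"):
        ts = sub["decision_timestamp"].to_numpy()
        d = np.diff(ts)
        if (d < 0).any():
            violations.append({"kind": "timestamps_not_monotone", "reader_id": str(reader)})
        elif (d == 0).any():
            violations.append({"kind": "duplicate_timestamps", "reader_id": str(reader)})

    known = set(women["woman_id"])
    unknown = set(events["woman_id"]) - known
    if unknown:
        violations.append(
            {
                "kind": "unknown_woman",
                "count": len(unknown),
                "examples": sorted(map(int, list(unknown)[:5])),
            }
        )
    bad_status = set(women["cancer_status"].unique()) - {
        "screen_detectable",
        "interval",
        "none",
    }
    if bad_status:
        violations.append(
            {"kind": "bad_enum", "column": "cancer_status", "values": sorted(map(str, bad_status))}
        )
    if (women["age"] <= 0).any():
        violations.append({"kind": "nonpositive_age"})
    return violations
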