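"""Configuration, serialization and run manifests.

All outputs are plain text: curves and sweep tables as CSV, fit summaries
and configs as JSON, with floats serialized at repr-faithful precision so
that re-reading a table reproduces it exactly and repeated writes of the
same result are checksum-identical.  Every output directory receives a
manifest recording the config hash, base seed, package version and a
SHA-256 checksum per file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .curves import AcquisitionCurve
from .fitting import FitComparison, FitResult
from .scenarios import ScenarioConfig, ScenarioResult

__all__ = [
    "ConfigError",
    "RunManifest",
    "load_config",
    "save_config",
    "write_outputs",
    "event_log_frame",
    "write_event_log",
]

logger = logging.getLogger("acqcurves")

_EVENT_COLUMNS = [
    "run_id",
    "event_index",
    "focal",
    "demonstrator",
    "demo_variant",
    "focal_before",
    "focal_after",
    "copy_succeeded",
    "freq_state",
    "freq_history_full",
    "freq_history_window",
]


class ConfigError(ValueError):
    """A configuration file violated the schema; the message names the key."""


_FIELD_NAMES = {f.name for f in dataclasses.fields(ScenarioConfig)}


def load_config(path: Union[str, Path]) -> ScenarioConfig:
    """Read a YAML or JSON scenario config, validating every field.

    Unknown keys are rejected; missing keys fall back to the canonical
    defaults (N = 100, 10000 events, 1000 replicates, ...).
    """
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    unknown = set(data) - _FIELD_NAMES
    if unknown:
        raise ConfigError(
            f"unknown config key(s) {sorted(unknown)}; allowed: {sorted(_FIELD_NAMES)}"
        )
    try:
        return ScenarioConfig(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def save_config(config: ScenarioConfig, path: Union[str, Path]) -> None:
    path = Path(path)
    data = config.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=True))
    else:
        path.write_text(_json_dumps(data))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _json_dumps(data) -> str:
    return json.dumps(data, indent=2, sort_keys=True, default=_json_default) + "\n"


def _float_csv(df: pd.DataFrame, path: Path) -> None:
    # shortest round-trip repr per float, so re-reading is lossless
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def read_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a CSV written by this module with lossless float parsing."""
    return pd.read_csv(path, float_precision="round_trip")


def _fit_to_dict(fit: Optional[FitResult]) -> Optional[dict]:
    if fit is None:
        return None
    return {
        "model": fit.model,
        "params": fit.params,
        "r_squared": fit.r_squared,
        "converged": fit.converged,
    }


def _comparison_to_dict(comp: FitComparison) -> dict:
    return {
        "linear": _fit_to_dict(comp.linear),
        "sigmoid": _fit_to_dict(comp.sigmoid),
        "relative_fit": comp.relative_fit,
        "better": comp.better,
    }


@dataclasses.dataclass
class RunManifest:
    """Provenance record written alongside every output set."""

    config_hash: str
    base_seed: Optional[int]
    package_version: str
    files: dict[str, str]  # relative path -> sha256
    created_utc: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_outputs(result: ScenarioResult, outdir: Union[str, Path]) -> RunManifest:
    """Serialize a scenario result: curve CSVs, fit JSON, tables, manifest.

    The manifest's ``config_hash`` is the SHA-256 of the canonical config
    JSON; file checksums cover every written output, so two writes of the
    same result are checksum-identical (timestamps live only in the
    manifest itself).
    """
    from . import __version__

    outdir = Path(outdir)
    if not outdir.exists():
        logger.info("creating output directory %s", outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        config_text = _json_dumps(result.config)
        (outdir / "config.json").write_text(config_text)
        written.append(outdir / "config.json")
        for label, curve in result.curves.items():
            p = outdir / f"curve_{label}.csv"
            _float_csv(curve.to_frame(), p)
            written.append(p)
        if result.comparisons:
            fits = {k: _comparison_to_dict(v) for k, v in result.comparisons.items()}
            p = outdir / "fits.json"
            p.write_text(_json_dumps(fits))
            written.append(p)
        for label, table in result.tables.items():
            p = outdir / f"table_{label}.csv"
            _float_csv(table, p)
            written.append(p)
        summary = {
            "scenario": result.name,
            "verdicts": result.verdicts,
            "extras": {
                k: v for k, v in result.extras.items() if _is_jsonable(v)
            },
        }
        p = outdir / "summary.json"
        p.write_text(_json_dumps(summary))
        written.append(p)
    except OSError:
        for p in written:  # partial-output cleanup
            p.unlink(missing_ok=True)
        raise
    manifest = RunManifest(
        config_hash=hashlib.sha256(config_text.encode()).hexdigest(),
        base_seed=result.config.get("base_seed"),
        package_version=__version__,
        files={p.name: _sha256(p) for p in written},
        created_utc=datetime.now(timezone.utc).isoformat(),
    )
    (outdir / "manifest.json").write_text(_json_dumps(manifest.to_dict()))
    return manifest


def _is_jsonable(value) -> bool:
    try:
        json.dumps(value, default=_json_default)
        return True
    except TypeError:
        return False


def event_log_frame(runs, window_t: int = 10) -> pd.DataFrame:
    """Flatten runs into the canonical per-event table.

    One row per event with the fixed column set (NA for missing
    demonstrators and undefined history frequencies), file-compatible with
    the measurement module's expectations.
    """
    from .measure import FrequencySpec, run_frequencies

    frames = []
    full_spec = FrequencySpec(source="behaviour_full_history")
    win_spec = FrequencySpec(source="behaviour_window", window_t=window_t)
    for run_id, run in enumerate(runs):
        demo = run.demonstrator.astype(object)
        demo[run.demonstrator < 0] = pd.NA
        demo_v = np.where(run.demo_variant == 1, "A", "B").astype(object)
        demo_v[run.demo_variant < 0] = pd.NA
        frames.append(
            pd.DataFrame(
                {
                    "run_id": run_id,
                    "event_index": np.arange(run.n_events),
                    "focal": run.focal,
                    "demonstrator": demo,
                    "demo_variant": demo_v,
                    "focal_before": np.where(run.focal_before == 1, "A", "B"),
                    "focal_after": np.where(run.focal_after == 1, "A", "B"),
                    "copy_succeeded": run.copy_succeeded.astype(bool),
                    "freq_state": run.freq_state(),
                    "freq_history_full": run_frequencies(run, full_spec),
                    "freq_history_window": run_frequencies(run, win_spec),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[_EVENT_COLUMNS]


def write_event_log(runs, path: Union[str, Path], window_t: int = 10) -> None:
    event_log_frame(runs, window_t=window_t).to_csv(path, index=False, na_rep="NA")
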