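"""Tabular and array file IO: events TSV, ratings CSV, amplitude CSV,
epochs (npz + JSON manifest), stats JSON and run configuration files."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import Epochs, validate_events
from .exceptions import ConfigurationError

EVENTS_COLUMNS = ["onset_sample", "identity", "response", "rt_ms"]


# -- events -----------------------------------------------------------------

def write_events_tsv(path, events: pd.DataFrame) -> None:
    validate_events(events)
    events.to_csv(path, sep="\t", index=False, columns=EVENTS_COLUMNS)


def read_events_tsv(path) -> pd.DataFrame:
    events = pd.read_csv(path, sep="\t")
    return validate_events(events)


# -- ratings ----------------------------------------------------------------

def write_ratings_csv(path, ratings: pd.DataFrame) -> None:
    ratings.to_csv(path, index=False)


def read_ratings_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


# -- amplitude table --------------------------------------------------------

def write_amplitudes_csv(path, table: pd.DataFrame,
                         config_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_hash: {config_hash}\n")
        table.to_csv(fh, index=False)


def read_amplitudes_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# -- epochs -----------------------------------------------------------------

def write_epochs(path_npz, epochs: Epochs, config_hash: str | None = None) -> None:
    """Binary epoch array plus a JSON sidecar manifest (same stem)."""
    path_npz = Path(path_npz)
    np.savez_compressed(path_npz, data=epochs.data,
                        interpolated=epochs.interpolated,
                        channel_global_bad=epochs.channel_global_bad)
    manifest = {
        "conditions": list(map(str, epochs.conditions)),
        "epoch_flags": epochs.epoch_flags,
        "channel_labels": epochs.channel_labels,
        "sampling_rate_hz": epochs.sampling_rate_hz,
        "window_ms": list(epochs.window_ms),
        "stage": epochs.stage,
        "meta": epochs.meta,
        "config_hash": config_hash,
    }
    with open(path_npz.with_suffix(".json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def read_epochs(path_npz) -> Epochs:
    path_npz = Path(path_npz)
    arrays = np.load(path_npz)
    with open(path_npz.with_suffix(".json")) as fh:
        manifest = json.load(fh)
    return Epochs(
        data=arrays["data"],
        conditions=np.array(manifest["conditions"], dtype=object),
        sampling_rate_hz=manifest["sampling_rate_hz"],
        channel_labels=manifest["channel_labels"],
        window_ms=tuple(manifest["window_ms"]),
        epoch_flags=list(manifest["epoch_flags"]),
        channel_global_bad=arrays["channel_global_bad"],
        interpolated=arrays["interpolated"],
        stage=manifest["stage"],
        meta=manifest["meta"],
    )


# -- JSON helpers -----------------------------------------------------------

def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict())
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_json(path, payload: dict) -> None:
    """Deterministic JSON: sorted keys, no timestamps, repr floats."""
    with open(path, "w") as fh:
        json.dump(_jsonable(payload), fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_config_file(path) -> dict:
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            payload = yaml.safe_load(fh)
        elif path.suffix == ".json":
            payload = json.load(fh)
        else:
            raise ConfigurationError(f"unsupported config format: {path.suffix}")
    if not isinstance(payload, dict):
        raise ConfigurationError("config file must hold a mapping")
    return payload
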