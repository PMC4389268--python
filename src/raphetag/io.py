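"""Reading and writing session bundles.

A bundle is a directory of plain delimited tables plus one YAML config so
fixtures stay inspectable with standard tools:

    config.yaml                 TaskConfig + metadata (incl. ground truth)
    blocks.csv                  id,block_type,first_trial,last_trial,tone_onset_s
    trials.csv                  index,block_id,trial_type,cs_onset_s,cs_offset_s,
                                us_onset_s,outcome_delivered
    licks.csv                   time_s
    free_rewards.csv            time_s
    spikes.csv                  unit_id,time_s
    light_pulses.csv            onset_s,duration_s,train_id,train_frequency_hz
    waveforms/<unit_id>.csv     spike_index,channel,sample_index,voltage_uv
    noise/<unit_id>.csv         spike_index,channel,sample_index,voltage_uv
    light_traces/<unit_id>.csv  pulse_index,sample_index,voltage_uv   (optional)
    choices.csv                 trial,chosen_port                     (optional)

Indices are explicit columns, never row order.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .session import (
    BLOCK_COLUMNS,
    CHOICE_COLUMNS,
    LIGHT_COLUMNS,
    TRIAL_COLUMNS,
    Session,
    TaskConfig,
    WaveformSet,
)


class MissingComponentError(FileNotFoundError):
    """A required bundle table is absent."""


REQUIRED_TABLES = ("blocks.csv", "trials.csv", "licks.csv", "free_rewards.csv",
                   "spikes.csv", "light_pulses.csv")


def _sanitize(unit_id: str) -> str:
    return "".join(c if (c.isalnum() or c in "-_") else "_" for c in str(unit_id))


def write_session(session: Session, path) -> None:
    """Write ``session`` as a bundle directory at ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    cfg = {
        "task_config": session.config.to_dict(),
        "metadata": _jsonable(session.metadata),
        "waveform_sample_rates": {
            uid: float(ws.sample_rate) for uid, ws in session.waveforms.items()
        },
    }
    (path / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))

    session.blocks.to_csv(path / "blocks.csv", index=False, columns=BLOCK_COLUMNS)
    session.trials.to_csv(path / "trials.csv", index=False, columns=TRIAL_COLUMNS)
    pd.DataFrame({"time_s": np.asarray(session.lick_times, float)}).to_csv(
        path / "licks.csv", index=False)
    pd.DataFrame({"time_s": np.asarray(session.free_reward_times, float)}).to_csv(
        path / "free_rewards.csv", index=False)

    rows = []
    for uid in session.unit_ids:
        t = np.asarray(session.spike_trains[uid], float)
        rows.append(pd.DataFrame({"unit_id": uid, "time_s": t}))
    spikes = (pd.concat(rows, ignore_index=True) if rows
              else pd.DataFrame(columns=["unit_id", "time_s"]))
    spikes.to_csv(path / "spikes.csv", index=False)

    session.light_pulses.to_csv(path / "light_pulses.csv", index=False,
                                columns=LIGHT_COLUMNS)

    (path / "waveforms").mkdir(exist_ok=True)
    (path / "noise").mkdir(exist_ok=True)
    for uid, ws in session.waveforms.items():
        _write_snippets(path / "waveforms" / f"{_sanitize(uid)}.csv",
                        ws.snippets, ws.spike_indices)
        _write_snippets(path / "noise" / f"{_sanitize(uid)}.csv",
                        ws.noise_snippets, np.arange(ws.noise_snippets.shape[0]))

    if session.light_traces:
        (path / "light_traces").mkdir(exist_ok=True)
        for uid, traces in session.light_traces.items():
            traces = np.asarray(traces, float)
            n_p, n_s = traces.shape
            df = pd.DataFrame({
                "pulse_index": np.repeat(np.arange(n_p), n_s),
                "sample_index": np.tile(np.arange(n_s), n_p),
                "voltage_uv": traces.ravel(),
            })
            df.to_csv(path / "light_traces" / f"{_sanitize(uid)}.csv", index=False)

    if session.choices is not None:
        session.choices.to_csv(path / "choices.csv", index=False,
                               columns=CHOICE_COLUMNS)


def read_session(path) -> Session:
    """Read a bundle directory written by :func:`write_session`."""
    path = Path(path)
    cfg_path = path / "config.yaml"
    if not cfg_path.exists():
        cfg_path = path / "config.json"
    if not cfg_path.exists():
        raise MissingComponentError(f"missing component: config.yaml in {path}")
    for name in REQUIRED_TABLES:
        if not (path / name).exists():
            raise MissingComponentError(f"missing component: {name} in {path}")

    if cfg_path.suffix == ".json":
        cfg = json.loads(cfg_path.read_text())
    else:
        cfg = yaml.safe_load(cfg_path.read_text())
    config = TaskConfig.from_dict(cfg.get("task_config", {}))
    sample_rates = cfg.get("waveform_sample_rates", {})

    blocks = _read_csv(path / "blocks.csv", BLOCK_COLUMNS)
    trials = _read_csv(path / "trials.csv", TRIAL_COLUMNS)
    if len(trials):
        trials["outcome_delivered"] = trials["outcome_delivered"].astype(bool)
    licks = _read_csv(path / "licks.csv", ["time_s"])["time_s"].to_numpy(float)
    frees = _read_csv(path / "free_rewards.csv", ["time_s"])["time_s"].to_numpy(float)
    spikes = _read_csv(path / "spikes.csv", ["unit_id", "time_s"])
    light = _read_csv(path / "light_pulses.csv", LIGHT_COLUMNS)

    spike_trains = {
        str(uid): np.sort(grp["time_s"].to_numpy(float))
        for uid, grp in spikes.groupby("unit_id")
    }

    waveforms = {}
    wf_dir = path / "waveforms"
    if wf_dir.is_dir():
        for f in sorted(wf_dir.glob("*.csv")):
            uid = f.stem
            snippets, spike_idx = _read_snippets(f)
            noise_f = path / "noise" / f.name
            noise, _ = (_read_snippets(noise_f) if noise_f.exists()
                        else (np.zeros((0,) + snippets.shape[1:]), None))
            waveforms[uid] = WaveformSet(
                unit_id=uid,
                sample_rate=float(sample_rates.get(uid, 32000.0)),
                snippets=snippets,
                noise_snippets=noise,
                spike_indices=spike_idx,
            )

    light_traces = {}
    lt_dir = path / "light_traces"
    if lt_dir.is_dir():
        for f in sorted(lt_dir.glob("*.csv")):
            df = pd.read_csv(f)
            n_p = int(df["pulse_index"].max()) + 1 if len(df) else 0
            n_s = int(df["sample_index"].max()) + 1 if len(df) else 0
            arr = np.zeros((n_p, n_s))
            arr[df["pulse_index"].to_numpy(int),
                df["sample_index"].to_numpy(int)] = df["voltage_uv"].to_numpy(float)
            light_traces[f.stem] = arr

    choices = None
    if (path / "choices.csv").exists():
        choices = _read_csv(path / "choices.csv", CHOICE_COLUMNS)

    return Session(
        config=config,
        blocks=blocks,
        trials=trials,
        lick_times=licks,
        free_reward_times=frees,
        spike_trains=spike_trains,
        waveforms=waveforms,
        light_pulses=light,
        light_traces=light_traces,
        choices=choices,
        metadata=cfg.get("metadata", {}) or {},
    )


def _read_csv(path: Path, columns) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed table {path.name}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing and len(df):
        raise ValueError(f"table {path.name} lacks columns {missing}")
    if not len(df):
        return pd.DataFrame(columns=columns)
    return df


def _write_snippets(path: Path, snippets: np.ndarray, indices: np.ndarray) -> None:
    snippets = np.asarray(snippets, float)
    if snippets.ndim != 3:
        snippets = snippets.reshape((0, 4, 32))
    n, c, s = snippets.shape
    indices = np.asarray(indices, int)
    if len(indices) != n:
        indices = np.arange(n)
    df = pd.DataFrame({
        "spike_index": np.repeat(indices, c * s),
        "channel": np.tile(np.repeat(np.arange(c), s), n),
        "sample_index": np.tile(np.arange(s), n * c),
        "voltage_uv": snippets.ravel(),
    })
    df.to_csv(path, index=False)


def _read_snippets(path: Path):
    df = pd.read_csv(path)
    if not len(df):
        return np.zeros((0, 4, 32)), np.zeros(0, dtype=int)
    spike_idx = np.unique(df["spike_index"].to_numpy(int))
    n = len(spike_idx)
    c = int(df["channel"].max()) + 1
    s = int(df["sample_index"].max()) + 1
    pos = {v: i for i, v in enumerate(spike_idx)}
    arr = np.zeros((n, c, s))
    arr[[pos[v] for v in df["spike_index"]],
        df["channel"].to_numpy(int),
        df["sample_index"].to_numpy(int)] = df["voltage_uv"].to_numpy(float)
    return arr, spike_idx


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
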