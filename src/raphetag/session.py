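"""Session data model for blocked classical-conditioning recordings.

A session is a single head-fixed recording: a sequence of trials organised
in blocks of like valence (reward / neutral / punishment), plus per-unit
spike trains, tetrode waveform snippets, and the light-pulse protocol used
for optogenetic tagging.  All event times are seconds from session start;
trial-aligned analyses place CS (odor) onset at time zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

TRIAL_TYPES = (
    "reward_big",
    "reward_small",
    "reward_zero",
    "neutral",
    "punishment_air",
    "punishment_quinine",
)

REWARD_TYPES = ("reward_big", "reward_small")
PUNISHMENT_TYPES = ("punishment_air", "punishment_quinine")

TRIAL_COLUMNS = [
    "index",
    "block_id",
    "trial_type",
    "cs_onset_s",
    "cs_offset_s",
    "us_onset_s",
    "outcome_delivered",
]
BLOCK_COLUMNS = ["id", "block_type", "first_trial", "last_trial", "tone_onset_s"]
LIGHT_COLUMNS = ["onset_s", "duration_s", "train_id", "train_frequency_hz"]
CHOICE_COLUMNS = ["trial", "chosen_port"]


@dataclass
class TaskConfig:
    """Timing and block structure of the conditioning task.

    Defaults reproduce the standard protocol: 1-s odor CS, 1-s trace delay,
    outcome analysed over 500 ms, blocks of 10 trials, exponential ITIs
    with a 10-s mean (flat hazard), and a 15-kHz tone ending 1 s before the
    first trial of each block.
    """

    cs_duration: float = 1.0
    delay_duration: float = 1.0
    us_window: float = 0.5
    block_length: int = 10
    block_types: tuple = ("reward_big", "punishment_air")
    block_order: str = "alternating"
    iti_scale: float = 10.0
    iti_truncation: Optional[float] = None
    tone_frequency: float = 15000.0
    tone_duration: float = 1.0
    tone_lead: float = 1.0
    omission_probability: float = 0.0
    neutral_replacement_probability: float = 0.0
    n_trials_total: int = 40

    def validate(self) -> None:
        for name in ("cs_duration", "delay_duration", "us_window", "iti_scale",
                     "tone_duration", "tone_lead"):
            if getattr(self, name) <= 0:
                raise ValueError(f"TaskConfig.{name} must be > 0")
        if self.iti_truncation is not None and self.iti_truncation <= 0:
            raise ValueError("TaskConfig.iti_truncation must be > 0 when set")
        for name in ("omission_probability", "neutral_replacement_probability"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"TaskConfig.{name} must be in [0, 1]")
        if self.block_length < 1:
            raise ValueError("TaskConfig.block_length must be >= 1")
        if self.block_order not in ("alternating", "random"):
            raise ValueError("TaskConfig.block_order must be 'alternating' or 'random'")
        unknown = set(self.block_types) - set(TRIAL_TYPES)
        if unknown:
            raise ValueError(f"unknown block types: {sorted(unknown)}")
        if self.n_trials_total % self.block_length != 0:
            raise ValueError("n_trials_total must be a multiple of block_length")

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["block_types"] = list(self.block_types)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        known = {f.name for f in fields(cls)}
        kwargs = {k: v for k, v in d.items() if k in known}
        if "block_types" in kwargs:
            kwargs["block_types"] = tuple(kwargs["block_types"])
        return cls(**kwargs)


@dataclass
class WaveformSet:
    """Tetrode waveform snippets for one unit.

    ``snippets`` has shape (n_spikes, n_channels, n_samples) in microvolts;
    ``spike_indices`` maps each snippet to its index in the unit's spike
    train (snippets may be a subsample of all spikes).  ``noise_snippets``
    are cut from spike-free epochs with the same geometry.
    """

    unit_id: str
    sample_rate: float = 32000.0
    snippets: np.ndarray = field(default_factory=lambda: np.zeros((0, 4, 32)))
    noise_snippets: np.ndarray = field(default_factory=lambda: np.zeros((0, 4, 32)))
    spike_indices: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    @property
    def n_channels(self) -> int:
        return self.snippets.shape[1] if self.snippets.size else 4

    @property
    def n_samples(self) -> int:
        return self.snippets.shape[2] if self.snippets.size else 0

    def mean_waveform(self) -> np.ndarray:
        """Mean spontaneous waveform, shape (n_channels, n_samples)."""
        if self.snippets.shape[0] == 0:
            raise ValueError(f"unit {self.unit_id}: no snippets")
        return self.snippets.mean(axis=0)

    def dominant_channel(self) -> int:
        """Tetrode channel with the largest mean absolute peak."""
        mw = self.mean_waveform()
        return int(np.argmax(np.abs(mw).max(axis=1)))


@dataclass
class Session:
    """One recording session: task events plus per-unit spike data."""

    config: TaskConfig
    blocks: pd.DataFrame
    trials: pd.DataFrame
    lick_times: np.ndarray = field(default_factory=lambda: np.zeros(0))
    free_reward_times: np.ndarray = field(default_factory=lambda: np.zeros(0))
    spike_trains: dict = field(default_factory=dict)  # unit_id -> 1d float array
    waveforms: dict = field(default_factory=dict)  # unit_id -> WaveformSet
    light_pulses: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=LIGHT_COLUMNS)
    )
    # unit_id -> (n_pulses, n_samples) dominant-channel voltage in the 10-ms
    # window after each light pulse; filled by the simulator / acquisition.
    light_traces: dict = field(default_factory=dict)
    choices: Optional[pd.DataFrame] = None
    metadata: dict = field(default_factory=dict)

    @property
    def unit_ids(self) -> list:
        return sorted(self.spike_trains)

    def span(self) -> float:
        """Session duration in seconds (end of last known event)."""
        candidates = [0.0]
        if len(self.trials):
            candidates.append(float(self.trials["us_onset_s"].max()) + 10.0)
        for t in self.spike_trains.values():
            if len(t):
                candidates.append(float(t[-1]))
        if len(self.light_pulses):
            candidates.append(float(self.light_pulses["onset_s"].max()) + 1.0)
        return max(candidates)


class Violation(NamedTuple):
    """A single invariant violation; data, not an exception."""

    field: str
    index: object
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}[{self.index}]: {self.message}"


def validate_session(session: Session) -> list:
    """Check all session invariants; return a list of :class:`Violation`.

    An empty list means the session is well formed.  Violations carry the
    offending field name and index so callers can locate bad rows.
    """
    out: list = []
    try:
        session.config.validate()
    except ValueError as exc:
        out.append(Violation("config", None, str(exc)))

    trials = session.trials
    blocks = session.blocks

    # trial ordering and epoch geometry
    cs_on = trials["cs_onset_s"].to_numpy(float)
    cs_off = trials["cs_offset_s"].to_numpy(float)
    us_on = trials["us_onset_s"].to_numpy(float)
    for i in np.nonzero(~((cs_on < cs_off) & (cs_off < us_on)))[0]:
        out.append(Violation("trials", int(trials["index"].iloc[i]),
                             "trial ordering: require cs_onset < cs_offset < us_onset"))
    bad_delay = np.nonzero(
        np.abs((us_on - cs_off) - session.config.delay_duration) > 1e-6)[0]
    for i in bad_delay:
        out.append(Violation("trials", int(trials["index"].iloc[i]),
                             "us_onset - cs_offset != delay_duration"))
    if len(trials) > 1 and np.any(np.diff(cs_on) <= 0):
        i = int(np.nonzero(np.diff(cs_on) <= 0)[0][0]) + 1
        out.append(Violation("trials", int(trials["index"].iloc[i]),
                             "trials not ordered by cs_onset"))

    known_blocks = set(blocks["id"].tolist()) if len(blocks) else set()
    for i, b in enumerate(trials["block_id"].tolist()):
        if b not in known_blocks:
            out.append(Violation("trials", int(trials["index"].iloc[i]),
                                 f"block_id {b} not in blocks table"))

    # blocks: contiguous, non-overlapping trial ranges
    if len(blocks):
        firsts = blocks["first_trial"].to_numpy(int)
        lasts = blocks["last_trial"].to_numpy(int)
        if np.any(lasts < firsts):
            i = int(np.nonzero(lasts < firsts)[0][0])
            out.append(Violation("blocks", int(blocks["id"].iloc[i]),
                                 "last_trial < first_trial"))
        order = np.argsort(firsts)
        for j in range(1, len(order)):
            if firsts[order[j]] != lasts[order[j - 1]] + 1:
                out.append(Violation("blocks", int(blocks["id"].iloc[order[j]]),
                                     "block trial ranges not contiguous"))

    span = session.span()
    for uid, times in session.spike_trains.items():
        times = np.asarray(times, float)
        if len(times) > 1:
            bad = np.nonzero(np.diff(times) <= 0)[0]
            for i in bad[:5]:
                out.append(Violation(f"spike_trains.{uid}", int(i) + 1,
                                     "spike times not strictly increasing"))
        if len(times) and (times[0] < 0 or times[-1] > span + 1e-9):
            out.append(Violation(f"spike_trains.{uid}", None,
                                 "spike times outside session span"))

    for uid, ws in session.waveforms.items():
        if uid not in session.spike_trains:
            out.append(Violation(f"waveforms.{uid}", None,
                                 "waveform set without matching spike train"))
        if ws.sample_rate <= 0:
            out.append(Violation(f"waveforms.{uid}", None, "sample_rate must be > 0"))
        if (ws.snippets.size and ws.noise_snippets.size
                and ws.snippets.shape[1:] != ws.noise_snippets.shape[1:]):
            out.append(Violation(f"waveforms.{uid}", None,
                                 "spike and noise snippets differ in geometry"))

    lp = session.light_pulses
    if len(lp):
        onsets = lp["onset_s"].to_numpy(float)
        if np.any(np.diff(onsets) <= 0):
            i = int(np.nonzero(np.diff(onsets) <= 0)[0][0]) + 1
            out.append(Violation("light_pulses", i, "onsets not increasing"))
        for tid, grp in lp.groupby("train_id"):
            freq = float(grp["train_frequency_hz"].iloc[0])
            if len(grp) > 1:
                gaps = np.diff(grp["onset_s"].to_numpy(float))
                if np.any(np.abs(gaps - 1.0 / freq) > 1e-6):
                    out.append(Violation("light_pulses", int(tid),
                                         "inter-pulse interval != 1/train_frequency"))
    return out
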