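"""Synthetic session generator.

Emulates the statistical structure of blocked classical-conditioning
recordings from dorsal raphe: exponential (flat-hazard) inter-trial
intervals, 10-trial blocks of like valence, tonic block-dependent rate
shifts of order 1-2 spikes/s, brief (<500 ms) phasic CS/US responses,
slow within-session drift, and ChR2 light-evoked spiking with
frequency-dependent probability and latency.  Every session carries its
generative ground truth in ``Session.metadata`` so downstream analyses
have parameter-recovery tests.

Spike trains are inhomogeneous Poisson processes sampled by thinning of

    lambda(t) = max(0, baseline + block_gain(t) + phasic(t) + drift * t)

where phasic responses are rectangular rate pulses (amplitude, onset
latency, duration) after each CS and delivered US.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .session import (
    BLOCK_COLUMNS,
    LIGHT_COLUMNS,
    REWARD_TYPES,
    TRIAL_COLUMNS,
    Session,
    TaskConfig,
    WaveformSet,
)

DETECTION_WINDOW_S = 0.010  # light-evoked spikes are scored in this window


@dataclass
class NeuronProfile:
    """Generative parameters for one simulated unit.

    ``block_gain`` maps block type to an additive tonic rate change in
    spikes/s, applied from the block's tone to the next block's tone.
    ``cs_response`` / ``us_response`` map trial type to a rectangular rate
    pulse (amplitude spikes/s, onset latency ms, duration ms); the special
    key ``"free_reward"`` in ``us_response`` shapes responses to rewards
    delivered outside the task.  ``evoked_probability`` maps light-train
    frequency (Hz) to the per-pulse probability of a ChR2-evoked spike.
    """

    unit_id: str
    cell_class: str = "unidentified_like"
    baseline_rate: float = 5.0
    block_gain: dict = field(default_factory=dict)
    cs_response: dict = field(default_factory=dict)
    us_response: dict = field(default_factory=dict)
    drift_slope: float = 0.0  # spikes/s per hour
    is_tagged: bool = False
    evoked_probability: dict = field(default_factory=dict)
    evoked_latency_mean: float = 3.0  # ms
    evoked_latency_sd: float = 0.5  # ms
    waveform_template: Optional[np.ndarray] = None  # (n_channels, n_samples) uV
    waveform_noise_sd: float = 5.0  # uV

    def validate(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if self.evoked_latency_sd < 0:
            raise ValueError("evoked_latency_sd must be >= 0")
        for f, p in self.evoked_probability.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"evoked_probability[{f}] outside [0, 1]")


@dataclass
class CohortConfig:
    """A simulated experiment: one task configuration, many units."""

    task_config: TaskConfig
    profiles: list
    n_sessions: int = 1
    master_seed: int = 0
    pre_task_duration: float = 120.0  # s of free-reward epoch before the task
    n_free_rewards: int = 10
    lick_baseline_rate: float = 0.5  # licks/s outside anticipation
    lick_anticipatory_rate: dict = field(
        default_factory=lambda: {t: 6.0 for t in REWARD_TYPES})
    lick_tone_rate: dict = field(default_factory=dict)  # block_type -> licks/s
    light_frequencies: tuple = (1.0, 5.0, 10.0, 20.0, 50.0)
    n_trains_per_frequency: int = 2
    choice_preference: Optional[float] = None  # water vs water+airpuff task

    def validate(self) -> None:
        self.task_config.validate()
        ids = [p.unit_id for p in self.profiles]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate unit ids in cohort profiles")
        for p in self.profiles:
            p.validate()


# ---------------------------------------------------------------------------
# task schedule
# ---------------------------------------------------------------------------

def sample_iti(scale: float, truncation: Optional[float], rng: np.random.Generator,
               size: Optional[int] = None):
    """Draw inter-trial intervals from an exponential density with mean
    ``scale`` (flat hazard).  If ``truncation`` is set, redraw any sample
    exceeding it (truncated exponential)."""
    if scale <= 0:
        raise ValueError("iti scale must be > 0")
    if truncation is not None and truncation <= 0:
        raise ValueError("iti truncation must be > 0")
    scalar = size is None
    n = 1 if scalar else int(size)
    out = rng.exponential(scale, size=n)
    if truncation is not None:
        bad = out > truncation
        while np.any(bad):
            out[bad] = rng.exponential(scale, size=int(bad.sum()))
            bad = out > truncation
    return float(out[0]) if scalar else out


def generate_task_schedule(config: TaskConfig, rng: np.random.Generator,
                           time_offset: float = 0.0):
    """Lay out blocks and trials; returns ``(blocks, trials)`` DataFrames.

    The first CS of each block is preceded by a block-change tone ending
    ``tone_lead`` seconds earlier; ITIs at block boundaries are extended
    to fit the tone when the exponential draw is too short.
    """
    config.validate()
    n_blocks = config.n_trials_total // config.block_length
    tone_span = config.tone_duration + config.tone_lead

    types = list(config.block_types)
    if config.block_order == "alternating":
        block_types = [types[i % len(types)] for i in range(n_blocks)]
    else:
        tiled = (types * (n_blocks // len(types) + 1))[:n_blocks]
        block_types = list(rng.permutation(tiled))

    trial_rows = []
    block_rows = []
    t = time_offset + tone_span  # first CS; first tone at time_offset
    idx = 0
    for b, btype in enumerate(block_types):
        first = idx
        tone_onset = t - tone_span
        for k in range(config.block_length):
            ttype = btype
            if (config.neutral_replacement_probability > 0 and btype != "neutral"
                    and rng.random() < config.neutral_replacement_probability):
                ttype = "neutral"
            cs_on = t
            cs_off = cs_on + config.cs_duration
            us_on = cs_off + config.delay_duration
            delivered = True
            if ttype in REWARD_TYPES and rng.random() < config.omission_probability:
                delivered = False
            if ttype == "neutral" or ttype == "reward_zero":
                delivered = False
            trial_rows.append((idx, b, ttype, cs_on, cs_off, us_on, delivered))
            idx += 1
            iti = sample_iti(config.iti_scale, config.iti_truncation, rng)
            if k == config.block_length - 1 and b < n_blocks - 1:
                iti = max(iti, tone_span + 0.1)
            t = us_on + iti
        block_rows.append((b, btype, first, idx - 1, tone_onset))

    blocks = pd.DataFrame(block_rows, columns=BLOCK_COLUMNS)
    trials = pd.DataFrame(trial_rows, columns=TRIAL_COLUMNS)
    return blocks, trials


# ---------------------------------------------------------------------------
# rate functions and Poisson sampling
# ---------------------------------------------------------------------------

class StepRate:
    """Piecewise-constant rate built from (start, stop, amplitude) intervals."""

    def __init__(self, span: float):
        self.span = float(span)
        self._events: list = [(0.0, 0.0)]

    def add(self, start: float, stop: float, amplitude: float) -> None:
        start = max(0.0, float(start))
        stop = min(self.span, float(stop))
        if stop <= start or amplitude == 0.0:
            return
        self._events.append((start, amplitude))
        self._events.append((stop, -amplitude))

    def compile(self):
        ev = np.array(self._events)
        order = np.argsort(ev[:, 0], kind="stable")
        times = ev[order, 0]
        levels = np.cumsum(ev[order, 1])
        # collapse simultaneous events
        keep = np.append(np.diff(times) > 0, True)
        return times[keep], levels[keep]


def _evaluate_rate(t: np.ndarray, edges: np.ndarray, levels: np.ndarray,
                   baseline: float, drift_per_s: float) -> np.ndarray:
    idx = np.searchsorted(edges, t, side="right") - 1
    lam = baseline + levels[np.clip(idx, 0, len(levels) - 1)] + drift_per_s * t
    return np.maximum(lam, 0.0)


def _sample_inhomogeneous(edges, levels, baseline, drift_per_s, span, rng):
    """Thinning sampler for a step-plus-linear rate on [0, span]."""
    seg_edges = np.append(edges, span)
    ends = np.maximum(seg_edges[:-1], seg_edges[1:])
    lam_max = float(np.max(np.maximum(
        baseline + levels + drift_per_s * seg_edges[:-1],
        baseline + levels + drift_per_s * ends)))
    lam_max = max(lam_max, 0.0)
    if lam_max == 0.0 or span <= 0:
        return np.zeros(0)
    n = rng.poisson(lam_max * span)
    if n == 0:
        return np.zeros(0)
    cand = np.sort(rng.uniform(0.0, span, size=n))
    lam = _evaluate_rate(cand, edges, levels, baseline, drift_per_s)
    keep = rng.random(n) < lam / lam_max
    times = cand[keep]
    # enforce strict monotonicity (duplicates have measure zero but guard)
    if len(times) > 1:
        times = times[np.append(True, np.diff(times) > 0)]
    return times


def build_rate_function(profile: NeuronProfile, blocks: pd.DataFrame,
                        trials: pd.DataFrame, span: float,
                        free_reward_times: Sequence[float] = ()) -> StepRate:
    """Assemble the step component of the unit's rate function."""
    step = StepRate(span)
    if len(blocks):
        starts = blocks["tone_onset_s"].to_numpy(float)
        order = np.argsort(starts)
        sorted_starts = starts[order]
        for j, i in enumerate(order):
            gain = profile.block_gain.get(blocks["block_type"].iloc[i], 0.0)
            start = max(0.0, sorted_starts[j])
            stop = sorted_starts[j + 1] if j + 1 < len(order) else span
            step.add(start, stop, gain)
    for _, tr in trials.iterrows():
        ttype = tr["trial_type"]
        if ttype in profile.cs_response:
            amp, lat_ms, dur_ms = profile.cs_response[ttype]
            start = tr["cs_onset_s"] + lat_ms / 1000.0
            step.add(start, start + dur_ms / 1000.0, amp)
        if tr["outcome_delivered"] and ttype in profile.us_response:
            amp, lat_ms, dur_ms = profile.us_response[ttype]
            start = tr["us_onset_s"] + lat_ms / 1000.0
            step.add(start, start + dur_ms / 1000.0, amp)
    if "free_reward" in profile.us_response:
        amp, lat_ms, dur_ms = profile.us_response["free_reward"]
        for t0 in free_reward_times:
            start = t0 + lat_ms / 1000.0
            step.add(start, start + dur_ms / 1000.0, amp)
    return step


def generate_spike_train(profile: NeuronProfile, blocks: pd.DataFrame,
                         trials: pd.DataFrame, span: float,
                         rng: np.random.Generator,
                         free_reward_times: Sequence[float] = ()) -> np.ndarray:
    """Sample the unit's spontaneous/task-driven spike train on [0, span]."""
    profile.validate()
    step = build_rate_function(profile, blocks, trials, span, free_reward_times)
    edges, levels = step.compile()
    return _sample_inhomogeneous(edges, levels, profile.baseline_rate,
                                 profile.drift_slope / 3600.0, span, rng)


def generate_lick_train(blocks: pd.DataFrame, trials: pd.DataFrame, span: float,
                        rng: np.random.Generator, *, baseline_rate: float = 0.5,
                        anticipatory_rate: Optional[dict] = None,
                        tone_rate: Optional[dict] = None,
                        tone_duration: float = 1.0) -> np.ndarray:
    """Poisson licking: baseline everywhere, elevated in the CS-US delay of
    anticipated trial types, optionally elevated during block-change tones."""
    step = StepRate(span)
    anticipatory_rate = anticipatory_rate or {}
    tone_rate = tone_rate or {}
    for _, tr in trials.iterrows():
        extra = anticipatory_rate.get(tr["trial_type"], 0.0)
        step.add(tr["cs_offset_s"], tr["us_onset_s"], extra)
    for _, blk in blocks.iterrows():
        extra = tone_rate.get(blk["block_type"], 0.0)
        step.add(blk["tone_onset_s"], blk["tone_onset_s"] + tone_duration, extra)
    edges, levels = step.compile()
    return _sample_inhomogeneous(edges, levels, baseline_rate, 0.0, span, rng)


# ---------------------------------------------------------------------------
# light stimulation
# ---------------------------------------------------------------------------

def build_light_protocol(start: float, frequencies=(1.0, 5.0, 10.0, 20.0, 50.0),
                         n_trains_per_frequency: int = 2, n_pulses: int = 10,
                         pulse_duration: float = 0.005,
                         inter_train_gap: float = 2.0) -> pd.DataFrame:
    """Trains of ``n_pulses`` 5-ms pulses at each stimulation frequency."""
    rows = []
    t = float(start)
    train_id = 0
    for freq in frequencies:
        for _ in range(n_trains_per_frequency):
            onsets = t + np.arange(n_pulses) / freq
            for o in onsets:
                rows.append((o, pulse_duration, train_id, freq))
            t = onsets[-1] + pulse_duration + inter_train_gap
            train_id += 1
    return pd.DataFrame(rows, columns=LIGHT_COLUMNS)


def generate_light_session(profile: NeuronProfile, pulses: pd.DataFrame,
                           rng: np.random.Generator):
    """Sample ChR2-evoked spikes for each light pulse.

    Each pulse evokes at most one spike, with probability
    ``evoked_probability[train_frequency]`` and latency drawn from a
    Normal(mean, sd) clipped to (0, 10] ms.  Returns ``(evoked_times,
    evoked_mask)`` with one mask entry per pulse.
    """
    profile.validate()
    onsets = pulses["onset_s"].to_numpy(float)
    freqs = pulses["train_frequency_hz"].to_numpy(float)
    probs = np.array([profile.evoked_probability.get(f, 0.0) for f in freqs])
    evoked = rng.random(len(onsets)) < probs
    lat_ms = rng.normal(profile.evoked_latency_mean, profile.evoked_latency_sd,
                        size=len(onsets))
    lat_ms = np.clip(lat_ms, 1e-3, 10.0)
    times = onsets[evoked] + lat_ms[evoked] / 1000.0
    return times, evoked


def merge_spike_trains(*trains) -> np.ndarray:
    """Union of sorted spike-time arrays, strictly increasing."""
    merged = np.sort(np.concatenate([np.asarray(t, float) for t in trains]))
    if len(merged) > 1:
        merged = merged[np.append(True, np.diff(merged) > 1e-9)]
    return merged


# ---------------------------------------------------------------------------
# waveforms
# ---------------------------------------------------------------------------

def make_waveform_template(rng: np.random.Generator, *, amplitude: float = 120.0,
                           width_samples: float = 5.0, n_channels: int = 4,
                           n_samples: int = 32, trough_sample: int = 10,
                           overshoot: float = 0.45) -> np.ndarray:
    """Biphasic extracellular spike template, microvolts.

    A negative trough followed by a slower positive overshoot; channel
    amplitudes fall off to mimic tetrode geometry.  ``width_samples``
    controls the spike duration at 32 kHz.
    """
    i = np.arange(n_samples)
    shape = (-np.exp(-0.5 * ((i - trough_sample) / width_samples) ** 2)
             + overshoot * np.exp(-0.5 * ((i - trough_sample - 2.0 * width_samples)
                                          / (1.6 * width_samples)) ** 2))
    shape = shape / np.max(np.abs(shape))
    weights = np.sort(rng.uniform(0.3, 1.0, size=n_channels))[::-1]
    weights[0] = 1.0
    return amplitude * weights[:, None] * shape[None, :]


def synthesize_waveforms(profile: NeuronProfile, spike_times: np.ndarray,
                         rng: np.random.Generator, *,
                         pulses: Optional[pd.DataFrame] = None,
                         max_snippets: int = 1000, n_noise: int = 300,
                         sample_rate: float = 32000.0):
    """Cut per-spike snippets (template + i.i.d. Gaussian noise) and per-pulse
    light-window voltage traces.

    All spikes inside light-detection windows receive snippets; outside
    them, a random subsample of up to ``max_snippets`` spikes does.  The
    traces cover the 10 ms after each pulse on the dominant channel and
    contain noise plus the template wherever a spike (evoked or coincident
    spontaneous) falls in the window; for a unit with no spikes there the
    traces are pure noise.  Returns ``(WaveformSet, traces)``; ``traces``
    is None when ``pulses`` is None.
    """
    template = profile.waveform_template
    if template is None:
        template = make_waveform_template(np.random.default_rng(0))
    template = np.asarray(template, float)
    n_channels, n_samples = template.shape
    spike_times = np.asarray(spike_times, float)
    n_spikes = len(spike_times)

    in_window = np.zeros(n_spikes, dtype=bool)
    if pulses is not None and len(pulses) and n_spikes:
        onsets = pulses["onset_s"].to_numpy(float)
        prev = np.searchsorted(onsets, spike_times, side="right") - 1
        valid = prev >= 0
        in_window[valid] = (spike_times[valid] - onsets[prev[valid]]
                            <= DETECTION_WINDOW_S)

    chosen = np.nonzero(in_window)[0]
    others = np.nonzero(~in_window)[0]
    if len(others) > max_snippets:
        others = np.sort(rng.choice(others, size=max_snippets, replace=False))
    idx = np.sort(np.concatenate([chosen, others])).astype(int)

    snippets = (template[None, :, :]
                + rng.normal(0.0, profile.waveform_noise_sd,
                             size=(len(idx), n_channels, n_samples)))
    noise = rng.normal(0.0, profile.waveform_noise_sd,
                       size=(n_noise, n_channels, n_samples))
    ws = WaveformSet(unit_id=profile.unit_id, sample_rate=sample_rate,
                     snippets=snippets, noise_snippets=noise, spike_indices=idx)

    traces = None
    if pulses is not None:
        n_win = int(round(DETECTION_WINDOW_S * sample_rate))
        onsets = pulses["onset_s"].to_numpy(float)
        traces = rng.normal(0.0, profile.waveform_noise_sd,
                            size=(len(onsets), n_win))
        dom = int(np.argmax(np.abs(template).max(axis=1)))
        trough = int(np.argmax(np.abs(template[dom])))
        for p, onset in enumerate(onsets):
            hits = spike_times[(spike_times > onset)
                               & (spike_times <= onset + DETECTION_WINDOW_S)]
            for t_sp in hits:
                # align the template trough to the spike time
                s0 = int(round((t_sp - onset) * sample_rate)) - trough
                a = max(0, s0)
                b = min(n_win, s0 + n_samples)
                if b > a:
                    traces[p, a:b] += template[dom, a - s0:b - s0]
    return ws, traces


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def _unit_seed(master_seed: int, session_index: int, unit_id: str) -> np.random.SeedSequence:
    # crc32 gives a stable per-unit stream: adding a unit never perturbs others
    return np.random.SeedSequence([master_seed, session_index,
                                   zlib.crc32(str(unit_id).encode())])


def generate_cohort(config: CohortConfig) -> list:
    """Simulate ``n_sessions`` full sessions for the configured cohort.

    Deterministic given ``master_seed``; each (session, unit) pair gets an
    independent child random stream.  Ground-truth generative parameters
    are stored in each session's metadata under ``"ground_truth"``.
    """
    config.validate()
    sessions = []
    for s in range(config.n_sessions):
        rng = np.random.default_rng(
            np.random.SeedSequence([config.master_seed, s, 2 ** 20]))
        blocks, trials = generate_task_schedule(
            config.task_config, rng, time_offset=config.pre_task_duration)

        free_rewards = np.sort(rng.uniform(
            5.0, max(10.0, config.pre_task_duration - 5.0),
            size=config.n_free_rewards)) if config.n_free_rewards else np.zeros(0)

        task_end = float(trials["us_onset_s"].max()) + 10.0
        pulses = build_light_protocol(
            task_end, frequencies=config.light_frequencies,
            n_trains_per_frequency=config.n_trains_per_frequency)
        span = float(pulses["onset_s"].max()) + 1.0

        licks = generate_lick_train(
            blocks, trials, span, rng,
            baseline_rate=config.lick_baseline_rate,
            anticipatory_rate=config.lick_anticipatory_rate,
            tone_rate=config.lick_tone_rate,
            tone_duration=config.task_config.tone_duration)

        spike_trains = {}
        waveforms = {}
        light_traces = {}
        truth = []
        for profile in config.profiles:
            urng = np.random.default_rng(
                _unit_seed(config.master_seed, s, profile.unit_id))
            spont = generate_spike_train(profile, blocks, trials, span, urng,
                                         free_reward_times=free_rewards)
            evoked_times, evoked_mask = generate_light_session(profile, pulses, urng)
            train = merge_spike_trains(spont, evoked_times)
            ws, traces = synthesize_waveforms(profile, train, urng, pulses=pulses)
            spike_trains[profile.unit_id] = train
            waveforms[profile.unit_id] = ws
            light_traces[profile.unit_id] = traces
            truth.append({
                "unit_id": profile.unit_id,
                "cell_class": profile.cell_class,
                "is_tagged": bool(profile.is_tagged),
                "baseline_rate": float(profile.baseline_rate),
                "block_gain": dict(profile.block_gain),
                "drift_slope": float(profile.drift_slope),
                "evoked_probability": {str(k): float(v) for k, v
                                       in profile.evoked_probability.items()},
                "n_evoked": int(evoked_mask.sum()),
            })

        choices = None
        if config.choice_preference is not None:
            n = len(trials)
            picks = np.where(rng.random(n) < config.choice_preference,
                             "water", "water_plus_airpuff")
            choices = pd.DataFrame({"trial": np.arange(n), "chosen_port": picks})

        sessions.append(Session(
            config=config.task_config,
            blocks=blocks,
            trials=trials,
            lick_times=licks,
            free_reward_times=free_rewards,
            spike_trains=spike_trains,
            waveforms=waveforms,
            light_pulses=pulses,
            light_traces=light_traces,
            choices=choices,
            metadata={
                "master_seed": config.master_seed,
                "session_index": s,
                "ground_truth": truth,
                "tagged_units": [p.unit_id for p in config.profiles if p.is_tagged],
            },
        ))
    return sessions
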