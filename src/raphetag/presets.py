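"""Cohort presets mirroring the four task variants.

These encode the study conditions the analyses are tested against:
10-trial reward/punishment blocks with a 10-s mean exponential ITI,
tonic block gains around 1-2 spikes/s, punishment-US excitations lasting
~315 ms and reward-CS excitations lasting ~235 ms, ChR2-evoked spiking
with high reliability at low train frequencies that drops at 50 Hz, and
sessions of 400-700 trials.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .session import Session, TaskConfig
from .simulate import (
    CohortConfig,
    NeuronProfile,
    build_light_protocol,
    generate_light_session,
    merge_spike_trains,
    make_waveform_template,
    synthesize_waveforms,
)

# per-pulse ChR2 spike probability vs train frequency (Hz)
TAGGED_EVOKED_PROBABILITY = {1.0: 0.95, 5.0: 0.92, 10.0: 0.88, 20.0: 0.75, 50.0: 0.5}

PRESET_BLOCKS = {
    "paper_like": ("reward_big", "punishment_air"),
    "value_salience": ("reward_big", "neutral", "punishment_air"),
    "reward_size": ("reward_big", "reward_small", "reward_zero"),
    "quinine": ("reward_big", "neutral", "punishment_air", "punishment_quinine"),
    "choice_task": ("reward_big", "punishment_air"),
}


def serotonergic_profile(unit_id: str, rng: np.random.Generator, *,
                         tagged: bool = True,
                         block_types=("reward_big", "punishment_air"),
                         us_duration_ms: float = 315.0,
                         cs_duration_ms: float = 235.0) -> NeuronProfile:
    """A serotonergic-like unit: tonic value coding plus brief phasic
    responses to punishments and reward-predicting cues."""
    gain = rng.uniform(1.0, 2.0)  # reward-vs-punishment tonic difference
    sign = 1.0 if rng.random() < 0.6 else -1.0
    block_gain = {}
    for bt in block_types:
        if bt.startswith("reward"):
            size = {"reward_big": 1.0, "reward_small": 0.5, "reward_zero": 0.0}.get(bt, 1.0)
            block_gain[bt] = sign * gain * size / 2.0
        elif bt.startswith("punishment"):
            block_gain[bt] = -sign * gain / 2.0
        else:
            block_gain[bt] = 0.0
    cs_resp = {}
    us_resp = {}
    for bt in block_types:
        if bt.startswith("reward"):
            cs_resp[bt] = (rng.uniform(5.0, 9.0), rng.uniform(30.0, 90.0),
                           max(80.0, rng.normal(cs_duration_ms, 60.0)))
            us_resp[bt] = (rng.uniform(3.0, 6.0), rng.uniform(30.0, 90.0),
                           max(80.0, rng.normal(250.0, 60.0)))
        elif bt.startswith("punishment"):
            cs_resp[bt] = (rng.uniform(1.0, 3.0), rng.uniform(30.0, 90.0), 150.0)
            us_resp[bt] = (rng.uniform(8.0, 14.0), rng.uniform(20.0, 60.0),
                           max(80.0, rng.normal(us_duration_ms, 80.0)))
    # weak, slow excitation by unexpected reward
    us_resp["free_reward"] = (rng.uniform(2.0, 4.0), rng.uniform(80.0, 150.0), 400.0)
    return NeuronProfile(
        unit_id=unit_id,
        cell_class="serotonergic_like",
        baseline_rate=rng.uniform(3.0, 8.0),
        block_gain=block_gain,
        cs_response=cs_resp,
        us_response=us_resp,
        drift_slope=rng.normal(-0.5, 0.3),
        is_tagged=tagged,
        evoked_probability=dict(TAGGED_EVOKED_PROBABILITY) if tagged else {},
        evoked_latency_mean=rng.uniform(2.0, 5.0),
        evoked_latency_sd=rng.uniform(0.3, 0.8),
        waveform_template=make_waveform_template(
            rng, amplitude=rng.uniform(100.0, 180.0),
            width_samples=rng.uniform(5.0, 7.0)),
        waveform_noise_sd=rng.uniform(4.0, 8.0),
    )


def dopaminergic_profile(unit_id: str, rng: np.random.Generator, *,
                         tagged: bool = True) -> NeuronProfile:
    """A dopaminergic-like unit: no tonic block coding, strong phasic
    excitation by reward cues and large response to unexpected reward."""
    return NeuronProfile(
        unit_id=unit_id,
        cell_class="dopaminergic_like",
        baseline_rate=rng.uniform(4.0, 9.0),
        block_gain={},
        cs_response={"reward_big": (rng.uniform(10.0, 16.0), rng.uniform(50.0, 120.0),
                                    max(100.0, rng.normal(300.0, 60.0)))},
        us_response={"reward_big": (rng.uniform(2.0, 4.0), 50.0, 200.0),
                     "free_reward": (rng.uniform(15.0, 25.0), rng.uniform(30.0, 60.0),
                                     200.0)},
        drift_slope=0.0,
        is_tagged=tagged,
        evoked_probability=dict(TAGGED_EVOKED_PROBABILITY) if tagged else {},
        evoked_latency_mean=rng.uniform(2.0, 4.0),
        evoked_latency_sd=rng.uniform(0.3, 0.8),
        waveform_template=make_waveform_template(
            rng, amplitude=rng.uniform(100.0, 180.0),
            width_samples=rng.uniform(3.0, 4.5)),
        waveform_noise_sd=rng.uniform(4.0, 8.0),
    )


def unidentified_profile(unit_id: str, rng: np.random.Generator) -> NeuronProfile:
    """An untagged unit with heterogeneous task responses and no
    light-evoked spiking; coincident spontaneous spikes are its only
    activity in light windows."""
    block_gain = {}
    if rng.random() < 0.4:
        g = rng.uniform(0.5, 2.0) * (1 if rng.random() < 0.5 else -1)
        block_gain = {"reward_big": g / 2.0, "punishment_air": -g / 2.0}
    cs_resp = {}
    us_resp = {}
    if rng.random() < 0.7:
        amp = rng.uniform(-4.0, 8.0)
        cs_resp["reward_big"] = (amp, rng.uniform(40.0, 150.0),
                                 max(100.0, rng.normal(450.0, 150.0)))
        us_resp["punishment_air"] = (rng.uniform(-4.0, 10.0), rng.uniform(30.0, 120.0),
                                     max(100.0, rng.normal(500.0, 150.0)))
    return NeuronProfile(
        unit_id=unit_id,
        cell_class="unidentified_like",
        baseline_rate=rng.uniform(2.0, 12.0),
        block_gain=block_gain,
        cs_response=cs_resp,
        us_response=us_resp,
        drift_slope=rng.normal(0.0, 0.3),
        is_tagged=False,
        evoked_probability={},
        evoked_latency_mean=3.0,
        evoked_latency_sd=0.5,
        waveform_template=make_waveform_template(
            rng, amplitude=rng.uniform(80.0, 180.0),
            width_samples=rng.uniform(3.5, 6.5)),
        waveform_noise_sd=rng.uniform(4.0, 8.0),
    )


def _draw_n_trials(rng: np.random.Generator, block_length: int = 10) -> int:
    """Session length: 533 +/- 120 trials, clipped to the 400-700 range and
    rounded to a whole number of blocks."""
    n = int(np.clip(rng.normal(533.0, 120.0), 400, 700))
    return (n // block_length) * block_length


def paper_like_cohort(master_seed: int = 0, *, n_units: int = 30, n_tagged: int = 8,
                      preset: str = "paper_like", n_sessions: int = 1,
                      n_trials: Optional[int] = None) -> CohortConfig:
    """Build a cohort config for one of the task variants.

    ``preset`` selects the block structure: ``paper_like`` (reward vs
    air-puff blocks, alternating), ``value_salience`` (adds neutral blocks,
    random order), ``reward_size`` (zero/small/big reward blocks),
    ``quinine`` (adds a gustatory punishment), ``choice_task`` (adds a
    two-alternative choice table).
    """
    rng = np.random.default_rng(np.random.SeedSequence([master_seed, 2 ** 19]))
    block_types = PRESET_BLOCKS[preset]
    if n_trials is None:
        n_trials = _draw_n_trials(rng)
    n_blocks_needed = len(block_types)
    n_trials = max(n_trials, 10 * n_blocks_needed)
    task = TaskConfig(
        block_types=block_types,
        block_order="alternating" if preset == "paper_like" else "random",
        n_trials_total=n_trials,
        omission_probability=0.1 if preset == "paper_like" else 0.0,
    )
    profiles = []
    for i in range(n_units):
        uid = f"u{i:03d}"
        if i < n_tagged:
            profiles.append(serotonergic_profile(uid, rng, tagged=True,
                                                 block_types=block_types))
        else:
            profiles.append(unidentified_profile(uid, rng))
    return CohortConfig(
        task_config=task,
        profiles=profiles,
        n_sessions=n_sessions,
        master_seed=master_seed,
        lick_tone_rate={bt: (4.0 if bt.startswith("reward") else 0.5)
                        for bt in block_types},
        choice_preference=0.9 if preset == "choice_task" else None,
    )


def simulate_tagging_session(master_seed: int = 0, *, n_units: int = 30,
                             n_tagged: int = 8, spont_duration: float = 240.0,
                             n_trains_per_frequency: int = 2) -> Session:
    """Light-stimulation epoch only: spontaneous firing plus the pulse-train
    protocol, for exercising the tagging pipeline without a full task.

    Mirrors how tagging data are collected outside the behavioral session.
    """
    rng = np.random.default_rng(np.random.SeedSequence([master_seed, 2 ** 18]))
    pulses = build_light_protocol(5.0, n_trains_per_frequency=n_trains_per_frequency)
    span = max(float(pulses["onset_s"].max()) + 1.0, spont_duration)

    import pandas as pd

    from .session import BLOCK_COLUMNS, TRIAL_COLUMNS

    spike_trains = {}
    waveforms = {}
    light_traces = {}
    truth = []
    for i in range(n_units):
        uid = f"u{i:03d}"
        tagged = i < n_tagged
        if tagged:
            profile = serotonergic_profile(uid, rng, tagged=True)
        else:
            profile = unidentified_profile(uid, rng)
        profile.block_gain = {}
        profile.cs_response = {}
        profile.us_response = {}
        profile.drift_slope = 0.0
        urng = np.random.default_rng(
            np.random.SeedSequence([master_seed, 2 ** 18 + 1 + i]))
        spont = urng.uniform(0.0, span, size=urng.poisson(profile.baseline_rate * span))
        spont = np.sort(spont)
        evoked_times, _ = generate_light_session(profile, pulses, urng)
        train = merge_spike_trains(spont, evoked_times)
        ws, traces = synthesize_waveforms(profile, train, urng, pulses=pulses,
                                          max_snippets=400, n_noise=200)
        spike_trains[uid] = train
        waveforms[uid] = ws
        light_traces[uid] = traces
        truth.append({"unit_id": uid, "is_tagged": tagged,
                      "cell_class": profile.cell_class,
                      "baseline_rate": float(profile.baseline_rate)})

    return Session(
        config=TaskConfig(),
        blocks=pd.DataFrame(columns=BLOCK_COLUMNS),
        trials=pd.DataFrame(columns=TRIAL_COLUMNS),
        spike_trains=spike_trains,
        waveforms=waveforms,
        light_pulses=pulses,
        light_traces=light_traces,
        metadata={"master_seed": master_seed, "ground_truth": truth,
                  "tagged_units": [t["unit_id"] for t in truth if t["is_tagged"]]},
    )
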