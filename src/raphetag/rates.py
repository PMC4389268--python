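"""Trial-aligned firing-rate estimation.

PSTHs use 10-ms half-open bins.  Spike density functions convolve spikes
with a causal kernel resembling a postsynaptic potential,

    k(t) = (1 - exp(-t)) * exp(-t / 200),   t in ms, t >= 0,

normalized to unit area so densities read in spikes/s; the kernel rises
within a few ms (peak at ln(201) ~= 5.3 ms) and decays with a 200-ms time
constant, and is truncated at 1000 ms (five decay constants).  Epoch
rates follow the standard windows: baseline = 1 s pre-CS, CS = odor on
to off, delay = odor off to outcome, US = outcome to +500 ms, pre-trial
= 2 s pre-CS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PSTH_BIN_S = 0.010
SDF_GRID_S = 0.001
KERNEL_RISE_MS = 1.0
KERNEL_DECAY_MS = 200.0
KERNEL_TRUNCATION_MS = 1000.0


@dataclass
class PSTH:
    align_label: str
    bin_edges: np.ndarray  # seconds relative to alignment, len n_bins+1
    counts: np.ndarray  # (n_trials, n_bins)

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    def mean_rate(self) -> np.ndarray:
        return self.counts.mean(axis=0) / PSTH_BIN_S


@dataclass
class SpikeDensity:
    align_label: str
    time_s: np.ndarray  # grid, seconds relative to alignment
    rates: np.ndarray  # (n_trials, n_grid), spikes/s

    def mean(self) -> np.ndarray:
        return self.rates.mean(axis=0)


def psp_kernel(grid_ms: float = 1.0) -> np.ndarray:
    """The unit-area causal kernel sampled on a millisecond grid.

    Returned values are in 1/s so that convolving 1-ms spike counts with
    the kernel yields spikes/s directly.
    """
    t = np.arange(0.0, KERNEL_TRUNCATION_MS, grid_ms)
    k = (1.0 - np.exp(-t / KERNEL_RISE_MS)) * np.exp(-t / KERNEL_DECAY_MS)
    k /= k.sum() * (grid_ms / 1000.0)  # unit area in seconds
    return k


def _aligned_counts(spikes: np.ndarray, align_times: np.ndarray,
                    window: tuple, bin_s: float) -> tuple:
    pre, post = window
    if pre + post <= 0:
        raise ValueError("window must span > 0")
    n_bins = int(round((pre + post) / bin_s))
    edges = -pre + bin_s * np.arange(n_bins + 1)
    spikes = np.asarray(spikes, float)
    counts = np.zeros((len(align_times), n_bins))
    for i, t0 in enumerate(np.asarray(align_times, float)):
        rel = spikes[(spikes >= t0 - pre) & (spikes < t0 + post)] - t0
        # half-open bins [edge, edge + bin); the epsilon absorbs float
        # subtraction noise so edge spikes land in their own bin
        idx = np.floor((rel + pre) / bin_s + 1e-9).astype(int)
        np.add.at(counts[i], np.clip(idx, 0, n_bins - 1), 1.0)
    return edges, counts


def compute_psth(spikes, align_times, window: tuple,
                 align_label: str = "cs_onset") -> PSTH:
    """Peristimulus time histogram with 10-ms half-open bins.

    ``window`` is ``(pre, post)`` in seconds; bins run from ``-pre`` to
    ``+post`` relative to each alignment time.
    """
    if len(align_times) == 0:
        raise ValueError("no alignment times")
    edges, counts = _aligned_counts(spikes, align_times, window, PSTH_BIN_S)
    return PSTH(align_label=align_label, bin_edges=edges, counts=counts)


def spike_density(spikes, align_times, window: tuple,
                  align_label: str = "cs_onset") -> SpikeDensity:
    """Per-trial spike density on a 1-ms grid, spikes/s.

    Spikes up to one kernel length before the window contribute, so the
    density at the window's left edge is unbiased.
    """
    if len(align_times) == 0:
        raise ValueError("no alignment times")
    pre, post = window
    pad = KERNEL_TRUNCATION_MS / 1000.0
    _, counts = _aligned_counts(spikes, align_times, (pre + pad, post), SDF_GRID_S)
    kernel = psp_kernel(SDF_GRID_S * 1000.0)
    n_pad = int(round(pad / SDF_GRID_S))
    n_out = counts.shape[1] - n_pad
    rates = np.empty((counts.shape[0], n_out))
    for i in range(counts.shape[0]):
        full = np.convolve(counts[i], kernel)[: counts.shape[1]]
        rates[i] = full[n_pad:]
    time_s = -pre + SDF_GRID_S * np.arange(n_out)
    return SpikeDensity(align_label=align_label, time_s=time_s, rates=rates)


EPOCHS = ("pretrial", "baseline", "cs", "delay", "us")


def epoch_firing_rates(spikes, trials: pd.DataFrame,
                       us_window: float = 0.5) -> pd.DataFrame:
    """Trial-by-trial firing rate (count / duration) in each named epoch.

    For trials whose preceding inter-trial gap is shorter than the 2-s
    pre-trial window, the rate uses the available span and the row is
    flagged ``pretrial_truncated``.
    """
    spikes = np.asarray(spikes, float)
    cs_on = trials["cs_onset_s"].to_numpy(float)
    cs_off = trials["cs_offset_s"].to_numpy(float)
    us_on = trials["us_onset_s"].to_numpy(float)
    # the pre-trial window never reaches back past the previous outcome
    prev_end = np.concatenate([[0.0], us_on[:-1]])

    def count(a, b):
        return np.searchsorted(spikes, b) - np.searchsorted(spikes, a)

    rows = []
    for i in range(len(trials)):
        pre_start = max(cs_on[i] - 2.0, prev_end[i], 0.0)
        pre_span = cs_on[i] - pre_start
        truncated = pre_span < 2.0 - 1e-9
        if pre_span <= 0:
            raise ValueError(f"trial {i}: non-positive pre-trial span")
        epochs = {
            "pretrial": (pre_start, cs_on[i]),
            "baseline": (cs_on[i] - 1.0, cs_on[i]),
            "cs": (cs_on[i], cs_off[i]),
            "delay": (cs_off[i], us_on[i]),
            "us": (us_on[i], us_on[i] + us_window),
        }
        row = {"trial": int(trials["index"].iloc[i]),
               "trial_type": trials["trial_type"].iloc[i],
               "block_id": int(trials["block_id"].iloc[i]),
               "outcome_delivered": bool(trials["outcome_delivered"].iloc[i]),
               "pretrial_truncated": bool(truncated)}
        for name, (a, b) in epochs.items():
            if b - a <= 0:
                raise ValueError(f"trial {i}: epoch {name} has non-positive span")
            row[f"{name}_rate"] = count(a, b) / (b - a)
        rows.append(row)
    return pd.DataFrame(rows)


def block_timecourse(spikes, span: float, *, count_bin_s: float = 1.0,
                     smoothing_span_s: float = 60.0) -> pd.DataFrame:
    """Session-long firing-rate series: 1-s counts smoothed by a centered
    sliding mean (default 60 s)."""
    spikes = np.asarray(spikes, float)
    n_bins = int(np.ceil(span / count_bin_s))
    counts, _ = np.histogram(spikes, bins=n_bins, range=(0.0, n_bins * count_bin_s))
    rate = counts / count_bin_s
    w = max(1, int(round(smoothing_span_s / count_bin_s)))
    kernel = np.ones(w) / w
    # centered moving average with edge renormalization
    smooth = np.convolve(rate, kernel, mode="same")
    norm = np.convolve(np.ones_like(rate), kernel, mode="same")
    smooth = smooth / norm
    t = (np.arange(n_bins) + 0.5) * count_bin_s
    return pd.DataFrame({"time_s": t, "rate_hz": smooth})
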