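"""Identification of ChR2-expressing units from light-stimulation epochs.

A unit counts as opto-tagged when (i) its light-evoked response clusters
with the light-responsive group in (energy, waveform-distance) space,
(ii) a sufficient fraction of pulses evoke a spike, and (iii) the evoked
waveform matches the unit's spontaneous spikes.  Energy is the integral
of the squared voltage of the light-evoked response; distance is the
Euclidean norm between the peak-aligned mean spontaneous spike and the
light-evoked response over the spontaneous spike's duration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.mixture import GaussianMixture

from .session import Session, WaveformSet

DETECTION_WINDOW_S = 0.010
SPIKE_FRACTION_THRESHOLD = 0.20  # boundary inclusive
DEFAULT_RELIABILITY_THRESHOLD = 0.20


@dataclass
class LightResponse:
    """Per-unit summary of light-evoked activity."""

    unit_id: str
    evoked: np.ndarray  # per-pulse bool
    latency_ms: np.ndarray  # per-pulse, NaN where not evoked
    evoked_fraction: float
    is_spike_response: bool
    response_waveform: np.ndarray  # dominant-channel, uV
    energy: float  # uV^2 * ms
    distance: float  # uV
    per_frequency: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class TagDecision:
    unit_id: str
    cluster_label: str  # light_responsive | non_responsive
    reliable: bool
    tagged: bool
    bic_table: Optional[pd.DataFrame] = None


@dataclass
class SpikeDurationResult:
    duration_ms: float
    first_sample: int
    last_sample: int
    note: str = ""


# ---------------------------------------------------------------------------
# evoked-spike detection
# ---------------------------------------------------------------------------

def _dominant_peak_index(w: np.ndarray) -> int:
    """Index of the larger (in absolute value) of the max and min."""
    return int(np.argmax(np.abs(w)))


def waveform_matches(snippet: np.ndarray, mean_waveform: np.ndarray,
                     channel: int, *, min_correlation: float = 0.9,
                     amplitude_tolerance: float = 0.5) -> bool:
    """Scale-tolerant shape match on the dominant channel: Pearson
    correlation >= ``min_correlation`` and peak amplitude within
    +/-``amplitude_tolerance`` of the unit mean."""
    a = np.asarray(snippet[channel], float)
    b = np.asarray(mean_waveform[channel], float)
    if a.std() == 0 or b.std() == 0:
        return False
    r = float(np.corrcoef(a, b)[0, 1])
    pa = np.abs(a).max()
    pb = np.abs(b).max()
    if pb == 0:
        return False
    return r >= min_correlation and abs(pa - pb) <= amplitude_tolerance * pb


def spontaneous_mean_waveform(spikes: np.ndarray, pulses: pd.DataFrame,
                              waveforms: WaveformSet) -> np.ndarray:
    """Mean waveform of spikes outside light-detection windows."""
    if waveforms.snippets.shape[0] == 0:
        raise ValueError(f"unit {waveforms.unit_id}: no snippets")
    times = np.asarray(spikes, float)[waveforms.spike_indices]
    mask = np.ones(len(times), dtype=bool)
    if len(pulses):
        onsets = pulses["onset_s"].to_numpy(float)
        prev = np.searchsorted(onsets, times, side="right") - 1
        valid = prev >= 0
        mask[valid] &= (times[valid] - onsets[prev[valid]]) > DETECTION_WINDOW_S
    if mask.sum() == 0:
        mask[:] = True  # fall back to all snippets
    return waveforms.snippets[mask].mean(axis=0)


def detect_evoked_spikes(spikes: np.ndarray, pulses: pd.DataFrame,
                         waveforms: WaveformSet, *, min_correlation: float = 0.9):
    """Score each light pulse: does the first unit spike within 10 ms of
    pulse onset match the unit's spontaneous waveform?

    Returns ``(flags, latencies_ms)`` arrays, one entry per pulse; latency
    is NaN where no matching spike occurred.
    """
    if not len(pulses):
        raise ValueError("no light pulses")
    onsets = pulses["onset_s"].to_numpy(float)
    spikes = np.asarray(spikes, float)
    flags = np.zeros(len(onsets), dtype=bool)
    lat = np.full(len(onsets), np.nan)
    if len(spikes) == 0:
        return flags, lat

    mean_wf = spontaneous_mean_waveform(spikes, pulses, waveforms)
    channel = int(np.argmax(np.abs(mean_wf).max(axis=1)))
    snippet_of = {int(i): k for k, i in enumerate(waveforms.spike_indices)}

    for p, onset in enumerate(onsets):
        lo = int(np.searchsorted(spikes, onset, side="right"))
        hi = int(np.searchsorted(spikes, onset + DETECTION_WINDOW_S, side="right"))
        for j in range(lo, hi):
            k = snippet_of.get(j)
            matched = (k is not None and waveform_matches(
                waveforms.snippets[k], mean_wf, channel,
                min_correlation=min_correlation))
            if matched:
                # first matching spike in the window sets the latency
                flags[p] = True
                lat[p] = (spikes[j] - onset) * 1000.0
                break
    return flags, lat


# ---------------------------------------------------------------------------
# response waveform, energy, distance
# ---------------------------------------------------------------------------

def waveform_energy(waveform: np.ndarray, sample_rate: float) -> float:
    """Integral of the squared voltage, in uV^2 * ms."""
    w = np.asarray(waveform, float)
    if w.size == 0:
        raise ValueError("empty waveform")
    dt_ms = 1000.0 / sample_rate
    return float(np.sum(w ** 2) * dt_ms)


def waveform_distance(spontaneous_mean: np.ndarray, light_response: np.ndarray,
                      spike_duration_ms: float, sample_rate: float,
                      *, max_shift_fraction: float = 0.25) -> float:
    """Euclidean distance between the peak-aligned waveforms over the span
    of the spontaneous spike's duration.

    The light response is shifted by the integer sample offset that brings
    its dominant peak (larger of |max| and |min|) onto the spontaneous
    mean's dominant peak, the shift bounded to ``max_shift_fraction`` of
    the snippet length; samples shifted out of range are dropped from both
    waveforms symmetrically.  When the extremum is flat (several samples
    within 5% of the peak voltage, common for averaged waveforms), each
    tied sample is an alignment candidate and the smallest resulting
    distance is returned.
    """
    a = np.asarray(spontaneous_mean, float)
    b = np.asarray(light_response, float)
    n = len(a)
    n_dur = int(round(spike_duration_ms * sample_rate / 1000.0))
    if n_dur > n or n_dur > len(b):
        raise ValueError("spike_duration longer than waveform")
    if n_dur < 1:
        n_dur = 1

    pa = _dominant_peak_index(a)
    peak_b = np.abs(b).max()
    if peak_b == 0:
        pb_candidates = [_dominant_peak_index(b)]
    else:
        pb_candidates = np.nonzero(np.abs(b) >= 0.95 * peak_b)[0]
    max_shift = int(round(max_shift_fraction * n))

    # window of n_dur samples centred on the spontaneous dominant peak
    start = int(np.clip(pa - n_dur // 2, 0, n - n_dur))
    idx_a = np.arange(start, start + n_dur)
    best = np.inf
    for pb in pb_candidates:
        shift = int(np.clip(pa - int(pb), -max_shift, max_shift))
        idx_b = idx_a - shift
        valid = (idx_b >= 0) & (idx_b < len(b))
        d = float(np.linalg.norm(a[idx_a[valid]] - b[idx_b[valid]]))
        best = min(best, d)
    return best


def light_response(unit_id: str, flags: np.ndarray, latencies_ms: np.ndarray,
                   traces: np.ndarray, spikes: np.ndarray, pulses: pd.DataFrame,
                   waveforms: WaveformSet,
                   spike_duration_ms: Optional[float] = None) -> LightResponse:
    """Summarise a unit's light-evoked activity.

    If at least 20% of pulses evoked a matching spike, the response
    waveform is the mean evoked-spike snippet; otherwise it is the
    trace segment (snippet-length, dominant channel) attaining the
    maximum absolute voltage across the 10-ms windows, and the unit is
    flagged as having a sub-threshold (non-spike) response.
    """
    flags = np.asarray(flags, bool)
    if flags.size == 0:
        raise ValueError("undefined light response: zero pulses")
    fraction = float(flags.mean())
    mean_wf = spontaneous_mean_waveform(spikes, pulses, waveforms)
    channel = int(np.argmax(np.abs(mean_wf).max(axis=1)))
    n_samples = waveforms.n_samples

    if fraction >= SPIKE_FRACTION_THRESHOLD:
        is_spike = True
        onsets = pulses["onset_s"].to_numpy(float)
        snippet_of = {int(i): k for k, i in enumerate(waveforms.spike_indices)}
        picks = []
        for p in np.nonzero(flags)[0]:
            t_sp = onsets[p] + latencies_ms[p] / 1000.0
            j = int(np.searchsorted(spikes, t_sp - 1e-9))
            k = snippet_of.get(j)
            if k is not None:
                picks.append(waveforms.snippets[k, channel])
        response = (np.mean(picks, axis=0) if picks
                    else mean_wf[channel])
    else:
        is_spike = False
        traces = np.asarray(traces, float)
        p_max, s_max = np.unravel_index(np.argmax(np.abs(traces)), traces.shape)
        start = int(np.clip(s_max - n_samples // 2, 0, traces.shape[1] - n_samples))
        response = traces[p_max, start:start + n_samples]

    if spike_duration_ms is None:
        try:
            dur = measure_spike_duration(waveforms)
            spike_duration_ms = dur.duration_ms
        except ValueError:  # too few snippets to measure
            spike_duration_ms = 0.0
        if spike_duration_ms <= 0:
            spike_duration_ms = n_samples * 1000.0 / waveforms.sample_rate
    energy = waveform_energy(response, waveforms.sample_rate)
    distance = waveform_distance(mean_wf[channel], response, spike_duration_ms,
                                 waveforms.sample_rate)
    profile = latency_frequency_profile(flags, latencies_ms, pulses)
    return LightResponse(
        unit_id=unit_id, evoked=flags, latency_ms=latencies_ms,
        evoked_fraction=fraction, is_spike_response=is_spike,
        response_waveform=np.asarray(response, float),
        energy=energy, distance=distance, per_frequency=profile,
    )


def latency_frequency_profile(flags: np.ndarray, latencies_ms: np.ndarray,
                              pulses: pd.DataFrame) -> pd.DataFrame:
    """Evoked probability and latency mean/SD per stimulation frequency.

    Frequencies with no evoked spikes report NaN latencies (missing, not
    zero); frequencies with no pulses are absent from the table.
    """
    freqs = pulses["train_frequency_hz"].to_numpy(float)
    rows = []
    for f in np.unique(freqs):
        sel = freqs == f
        ev = np.asarray(flags, bool)[sel]
        lat = np.asarray(latencies_ms, float)[sel][ev]
        rows.append({
            "train_frequency_hz": f,
            "n_pulses": int(sel.sum()),
            "evoked_probability": float(ev.mean()) if sel.sum() else np.nan,
            "latency_mean_ms": float(lat.mean()) if len(lat) else np.nan,
            "latency_sd_ms": float(lat.std(ddof=1)) if len(lat) > 1 else np.nan,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# spike duration
# ---------------------------------------------------------------------------

def measure_spike_duration(waveforms: WaveformSet, alpha: float = 0.05,
                           max_snippets: int = 200) -> SpikeDurationResult:
    """Span over which snippet voltage differs from noise.

    Per-sample Wilcoxon rank-sum tests of snippet voltages against noise
    voltages on the dominant channel, Bonferroni-corrected over samples;
    duration runs from the first to the last significant sample.
    """
    if waveforms.snippets.shape[0] < 20 or waveforms.noise_snippets.shape[0] < 20:
        raise ValueError("need >= 20 spike and noise snippets")
    ch = waveforms.dominant_channel()
    sn = waveforms.snippets[:, ch, :]
    nz = waveforms.noise_snippets[:, ch, :]
    if sn.shape[0] > max_snippets:
        sn = sn[:: sn.shape[0] // max_snippets + 1][:max_snippets]
    if nz.shape[0] > max_snippets:
        nz = nz[:: nz.shape[0] // max_snippets + 1][:max_snippets]
    n_samples = sn.shape[1]
    corrected = alpha / n_samples
    sig = np.zeros(n_samples, dtype=bool)
    for s in range(n_samples):
        _, p = stats.ranksums(sn[:, s], nz[:, s])
        sig[s] = p < corrected
    if not sig.any():
        return SpikeDurationResult(0.0, -1, -1, note="no significant span")
    first = int(np.argmax(sig))
    last = int(n_samples - 1 - np.argmax(sig[::-1]))
    duration_ms = (last - first + 1) * 1000.0 / waveforms.sample_rate
    return SpikeDurationResult(duration_ms, first, last)


# ---------------------------------------------------------------------------
# clustering and tagging decision
# ---------------------------------------------------------------------------

_COVARIANCE_TYPES = ("spherical", "tied", "diag", "full")


def cluster_light_features(features: pd.DataFrame, *, random_state: int = 0):
    """Two-component Gaussian-mixture clustering of per-unit
    (energy, distance) pairs, on log10 scales.

    Models over several covariance parameterizations are initialized from
    Ward agglomerative clustering and selected by BIC.  The component with
    the higher (energy - distance) score in transformed space is labelled
    ``light_responsive``.  Returns ``(assignments, bic_table)`` where
    ``assignments`` maps unit_id -> cluster label.
    """
    if len(features) < 4:
        raise ValueError("need >= 4 units to cluster")
    eps = np.finfo(float).tiny
    X = np.column_stack([
        np.log10(features["energy"].to_numpy(float) + eps),
        np.log10(features["distance"].to_numpy(float) + eps),
    ])
    if np.allclose(X.std(axis=0), 0.0):
        warnings.warn("degenerate light features: all units identical; "
                      "no light-responsive cluster", stacklevel=2)
        return ({u: "non_responsive" for u in features["unit_id"]},
                pd.DataFrame(columns=["covariance_type", "bic", "selected"]))

    # model-based initialization: 2-way cut of a Ward tree
    init_labels = fcluster(linkage(X, method="ward"), 2, criterion="maxclust") - 1
    means_init = np.vstack([X[init_labels == k].mean(axis=0) for k in (0, 1)])

    best = None
    rows = []
    for cov in _COVARIANCE_TYPES:
        gm = GaussianMixture(n_components=2, covariance_type=cov,
                             means_init=means_init, n_init=1,
                             random_state=random_state, reg_covar=1e-6)
        gm.fit(X)
        bic = gm.bic(X)
        rows.append({"covariance_type": cov, "bic": bic})
        if best is None or bic < best[1]:
            best = (gm, bic, cov)
    gm, _, best_cov = best
    labels = gm.predict(X)
    bic_table = pd.DataFrame(rows)
    bic_table["selected"] = bic_table["covariance_type"] == best_cov

    # light-responsive component: high energy, low distance
    score = [gm.means_[k, 0] - gm.means_[k, 1] for k in (0, 1)]
    responsive = int(np.argmax(score))
    names = {responsive: "light_responsive", 1 - responsive: "non_responsive"}
    assignments = {u: names[l] for u, l in zip(features["unit_id"], labels)}
    return assignments, bic_table


def decide_tag(unit_id: str, cluster_label: str, response: LightResponse,
               reliability_threshold: float = DEFAULT_RELIABILITY_THRESHOLD,
               bic_table: Optional[pd.DataFrame] = None) -> TagDecision:
    """A unit is tagged iff it sits in the light-responsive cluster AND it
    reliably fired to light AND its response was an actual spike."""
    reliable = response.evoked_fraction >= reliability_threshold
    tagged = (cluster_label == "light_responsive" and reliable
              and response.is_spike_response)
    return TagDecision(unit_id=unit_id, cluster_label=cluster_label,
                       reliable=reliable, tagged=tagged, bic_table=bic_table)


# ---------------------------------------------------------------------------
# session-level pipeline
# ---------------------------------------------------------------------------

def tag_session(session: Session, *,
                reliability_threshold: float = DEFAULT_RELIABILITY_THRESHOLD,
                random_state: int = 0):
    """Run the full tagging pipeline on one session.

    Returns ``(tagging, responses)``: a per-unit summary DataFrame
    (unit_id, energy, distance, evoked_probability, cluster_label,
    reliable, tagged) and the dict of :class:`LightResponse` objects.
    """
    pulses = session.light_pulses
    if not len(pulses):
        raise ValueError("session has no light pulses")
    responses = {}
    rows = []
    for uid in session.unit_ids:
        if uid not in session.waveforms:
            continue
        spikes = session.spike_trains[uid]
        ws = session.waveforms[uid]
        flags, lat = detect_evoked_spikes(spikes, pulses, ws)
        traces = session.light_traces.get(uid)
        if traces is None:
            n_win = int(round(DETECTION_WINDOW_S * ws.sample_rate))
            traces = np.zeros((len(pulses), n_win))
        resp = light_response(uid, flags, lat, traces, spikes, pulses, ws)
        responses[uid] = resp
        rows.append({"unit_id": uid, "energy": resp.energy,
                     "distance": resp.distance,
                     "evoked_probability": resp.evoked_fraction})
    features = pd.DataFrame(rows)
    assignments, bic_table = cluster_light_features(features,
                                                    random_state=random_state)
    decisions = []
    for uid in features["unit_id"]:
        d = decide_tag(uid, assignments[uid], responses[uid],
                       reliability_threshold, bic_table)
        decisions.append({"unit_id": uid, "cluster_label": d.cluster_label,
                          "reliable": d.reliable, "tagged": d.tagged})
    tagging = features.merge(pd.DataFrame(decisions), on="unit_id")
    return tagging, responses
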