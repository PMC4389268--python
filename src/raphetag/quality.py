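"""Unit-isolation and spike-property metrics.

Inclusion criteria follow common practice for tetrode recordings:
L-ratio < 0.05 and SNR > 5 dB.  The L-ratio sums chi-square tail
probabilities of non-cluster events' squared Mahalanobis distances to
the unit cluster, normalized by the number of unit spikes; it
approximates the fraction of contaminated spikes.  The feature space is
the first two principal components of the snippets on each tetrode
channel (d = 8).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score
from sklearn.mixture import GaussianMixture
from sklearn.preprocessing import StandardScaler

from .optotag import measure_spike_duration
from .session import WaveformSet

L_RATIO_BOUND = 0.05
SNR_BOUND_DB = 5.0
N_PCS_PER_CHANNEL = 2


@dataclass
class QualityMetrics:
    unit_id: str
    l_ratio: float
    snr_db: float
    isi_cv: float
    spike_duration_ms: float
    mean_rate: float

    def passes_inclusion(self) -> bool:
        return self.l_ratio < L_RATIO_BOUND and self.snr_db > SNR_BOUND_DB


def l_ratio(unit_features: np.ndarray, noise_features: np.ndarray) -> float:
    """L-ratio of a unit cluster against non-unit events.

    L = sum over non-unit events of 1 - F_chi2(D^2; d), normalized by the
    number of unit spikes, where D^2 is the squared Mahalanobis distance
    to the unit cluster in d-dimensional feature space.
    """
    X = np.asarray(unit_features, float)
    Y = np.asarray(noise_features, float)
    n, d = X.shape
    if n < d + 1:
        raise ValueError(f"need >= {d + 1} unit spikes for {d}-d features")
    mu = X.mean(axis=0)
    cov = np.cov(X, rowvar=False)
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular feature covariance; reduce the feature "
                         "dimension") from exc
    diff = Y - mu
    d2 = np.einsum("ij,jk,ik->i", diff, cov_inv, diff)
    return float(np.sum(sps.chi2.sf(d2, df=d)) / n)


def waveform_pc_features(waveforms: WaveformSet,
                         n_pcs: int = N_PCS_PER_CHANNEL):
    """Per-channel principal-component features of spike and noise
    snippets, concatenated across channels (d = channels * n_pcs).

    The PCA basis is fit on the spike snippets and noise snippets are
    projected into it, so noise events are scored in the unit's own
    feature space.
    """
    sn = waveforms.snippets
    nz = waveforms.noise_snippets
    feats_sn = []
    feats_nz = []
    for c in range(sn.shape[1]):
        pca = PCA(n_components=n_pcs)
        feats_sn.append(pca.fit_transform(sn[:, c, :]))
        feats_nz.append(pca.transform(nz[:, c, :]))
    return np.hstack(feats_sn), np.hstack(feats_nz)


def snr_db(mean_waveform: np.ndarray, noise_snippets: np.ndarray,
           channel: int = None) -> float:
    """Signal-to-noise ratio in dB: 20 log10(peak-to-peak / (2 sd_noise)).

    Computed on the dominant channel when ``mean_waveform`` is 2-d.  A
    zero noise SD yields +inf (flagged to the caller by the value itself).
    """
    mw = np.asarray(mean_waveform, float)
    nz = np.asarray(noise_snippets, float)
    if mw.size == 0 or nz.size == 0:
        raise ValueError("empty input")
    if mw.ndim == 2:
        if channel is None:
            channel = int(np.argmax(np.abs(mw).max(axis=1)))
        mw = mw[channel]
        if nz.ndim == 3:
            nz = nz[:, channel, :]
    ptp = float(mw.max() - mw.min())
    sd = float(nz.std())
    if sd == 0:
        return float("inf")
    return float(20.0 * np.log10(ptp / (2.0 * sd)))


def isi_stats(spike_times, n_hist_bins: int = 50) -> tuple:
    """Coefficient of variation of the inter-spike intervals plus a
    log-spaced ISI histogram.  CV = 0 for a clock-like train, ~1 for a
    Poisson train."""
    t = np.asarray(spike_times, float)
    if len(t) < 3:
        raise ValueError("need >= 3 spikes")
    isi = np.diff(t)
    cv = float(isi.std(ddof=0) / isi.mean())
    lo = max(isi.min(), 1e-4)
    edges = np.logspace(np.log10(lo), np.log10(isi.max() + 1e-12), n_hist_bins + 1)
    counts, edges = np.histogram(isi, bins=edges)
    hist = pd.DataFrame({"isi_low_s": edges[:-1], "isi_high_s": edges[1:],
                         "count": counts})
    return cv, hist


def unit_quality_metrics(unit_id: str, spike_times, waveforms: WaveformSet,
                         span: float) -> QualityMetrics:
    """All isolation/spike-property metrics for one unit."""
    feats_sn, feats_nz = waveform_pc_features(waveforms)
    lr = l_ratio(feats_sn, feats_nz)
    snr = snr_db(waveforms.mean_waveform(), waveforms.noise_snippets)
    cv, _ = isi_stats(spike_times)
    dur = measure_spike_duration(waveforms)
    rate = len(spike_times) / span if span > 0 else float("nan")
    return QualityMetrics(unit_id=unit_id, l_ratio=lr, snr_db=snr, isi_cv=cv,
                          spike_duration_ms=dur.duration_ms, mean_rate=rate)


def waveform_classifiability(features: pd.DataFrame, *,
                             random_state: int = 0) -> dict:
    """Can tagged units be told apart from untagged ones by spike duration,
    firing rate, and ISI CV alone?

    Runs 2-cluster GMM and k-means on the standardized feature triple and
    reports the adjusted Rand agreement of each with the tagged labels
    (chance ~ 0), plus a rank-sum test of spike duration between groups.
    ``features`` needs columns spike_duration_ms, mean_rate, isi_cv,
    is_tagged.
    """
    if len(features) < 10:
        raise ValueError("need >= 10 units")
    labels = features["is_tagged"].to_numpy(bool)
    if labels.sum() < 2:
        raise ValueError("need >= 2 tagged units")
    X = features[["spike_duration_ms", "mean_rate", "isi_cv"]].to_numpy(float)
    if np.allclose(X.std(axis=0), 0.0):
        return {"gmm_agreement": 0.0, "kmeans_agreement": 0.0,
                "duration_test": None, "note": "inseparable"}
    Xs = StandardScaler().fit_transform(X)
    gmm = GaussianMixture(n_components=2, n_init=5,
                          random_state=random_state).fit_predict(Xs)
    km = KMeans(n_clusters=2, n_init=10, random_state=random_state).fit_predict(Xs)
    dur_tagged = features.loc[labels, "spike_duration_ms"].to_numpy(float)
    dur_untagged = features.loc[~labels, "spike_duration_ms"].to_numpy(float)
    stat, p = sps.ranksums(dur_tagged, dur_untagged)
    return {
        "gmm_agreement": float(adjusted_rand_score(labels, gmm)),
        "kmeans_agreement": float(adjusted_rand_score(labels, km)),
        "duration_test": {"statistic": float(stat), "p_value": float(p)},
        "note": "",
    }
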