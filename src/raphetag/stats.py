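"""Hypothesis tests, discriminability analyses, and coding classifications.

The workhorse is the sliding-window auROC: the area under the ROC curve
between trial firing-rate distributions in 100-ms bins and the pooled
baseline distribution (100-ms bins of the 1-s pre-CS window), computed
via the tie-corrected Mann-Whitney U statistic (auROC = U / (n1 * n2)).
0.5 means indistinguishable from baseline, >0.5 excitation, <0.5
inhibition.  Per-bin significance uses rank-sum tests with Bonferroni
correction over the bins of the trace; response duration is 100 ms times
the number of significant bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

AUROC_BIN_S = 0.100
BASELINE_SPAN_S = 1.0


@dataclass
class TestResult:
    statistic: float
    p_value: float
    effect_size: Optional[float] = None  # Cohen's U3 where applicable
    direction: str = "none"  # "+", "-", or "none"
    n: tuple = ()

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


@dataclass
class AurocTrace:
    unit_id: str
    condition: str
    bin_centers_s: np.ndarray
    auroc: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray  # Bonferroni-corrected
    bonferroni_m: int
    alpha: float = 0.05


@dataclass
class CodingLabel:
    label: str  # value | salience | unclassified
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)


# ---------------------------------------------------------------------------
# auROC machinery
# ---------------------------------------------------------------------------

def mann_whitney_auroc(sample: np.ndarray, baseline: np.ndarray) -> float:
    """Tie-corrected auROC: P(sample > baseline) + 0.5 * P(tie).

    Computed from average ranks, so two identical samples give exactly
    0.5.  Equals the exhaustive concordant-pair count divided by n1*n2.
    """
    a = np.asarray(sample, float)
    b = np.asarray(baseline, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sample")
    ranks = sps.rankdata(np.concatenate([a, b]))
    r1 = ranks[: len(a)].sum()
    u = r1 - len(a) * (len(a) + 1) / 2.0
    return float(u / (len(a) * len(b)))


def baseline_bin_rates(spikes: np.ndarray, cs_onsets: np.ndarray,
                       bin_s: float = AUROC_BIN_S,
                       span_s: float = BASELINE_SPAN_S) -> np.ndarray:
    """Pooled baseline sample: firing rate in each 100-ms bin of every
    trial's 1-s pre-CS window (10 bins per trial)."""
    spikes = np.asarray(spikes, float)
    n_bins = int(round(span_s / bin_s))
    out = []
    for t0 in np.asarray(cs_onsets, float):
        edges = t0 - span_s + bin_s * np.arange(n_bins + 1)
        counts = np.diff(np.searchsorted(spikes, edges))
        out.append(counts / bin_s)
    return np.concatenate(out) if out else np.zeros(0)


def sliding_auroc(trial_rates: np.ndarray, bin_centers_s: np.ndarray,
                  baseline: np.ndarray, *, alpha: float = 0.05,
                  unit_id: str = "", condition: str = "") -> AurocTrace:
    """auROC trace from per-trial binned rates vs the pooled baseline.

    ``trial_rates`` has shape (n_trials, n_bins); each bin's across-trial
    sample is compared to ``baseline`` with a tie-corrected Mann-Whitney
    U; two-sided rank-sum p-values are Bonferroni-corrected over the
    number of bins in the trace.
    """
    trial_rates = np.asarray(trial_rates, float)
    if trial_rates.shape[0] < 5:
        raise ValueError("need >= 5 trials")
    if len(baseline) == 0:
        raise ValueError("empty baseline")
    n_bins = trial_rates.shape[1]
    auroc = np.empty(n_bins)
    pvals = np.empty(n_bins)
    for j in range(n_bins):
        col = trial_rates[:, j]
        auroc[j] = mann_whitney_auroc(col, baseline)
        if np.ptp(col) == 0 and np.ptp(baseline) == 0 and col[0] == baseline[0]:
            pvals[j] = 1.0
        else:
            pvals[j] = sps.mannwhitneyu(col, baseline,
                                        alternative="two-sided").pvalue
    significant = pvals < alpha / n_bins
    return AurocTrace(unit_id=unit_id, condition=condition,
                      bin_centers_s=np.asarray(bin_centers_s, float),
                      auroc=auroc, p_values=pvals, significant=significant,
                      bonferroni_m=n_bins, alpha=alpha)


def trial_bin_rates(spikes: np.ndarray, cs_onsets: np.ndarray,
                    window: tuple, bin_s: float = AUROC_BIN_S):
    """Per-trial firing rates in 100-ms bins of the trial-aligned window.

    Returns ``(rates, bin_centers)`` with rates of shape
    (n_trials, n_bins).
    """
    spikes = np.asarray(spikes, float)
    pre, post = window
    n_bins = int(round((pre + post) / bin_s))
    rel_edges = -pre + bin_s * np.arange(n_bins + 1)
    rates = np.empty((len(cs_onsets), n_bins))
    for i, t0 in enumerate(np.asarray(cs_onsets, float)):
        counts = np.diff(np.searchsorted(spikes, t0 + rel_edges))
        rates[i] = counts / bin_s
    centers = rel_edges[:-1] + bin_s / 2.0
    return rates, centers


def auroc_trace_for_condition(spikes, trials: pd.DataFrame, trial_types,
                              *, window: tuple = (0.0, 2.5), alpha: float = 0.05,
                              unit_id: str = "", condition: str = "") -> AurocTrace:
    """Convenience wrapper: build the baseline from the 1-s pre-CS windows
    of the selected trials (baselines are condition-specific) and compare
    each 100-ms trial bin to it."""
    if isinstance(trial_types, str):
        trial_types = (trial_types,)
    sel = trials[trials["trial_type"].isin(trial_types)]
    cs = sel["cs_onset_s"].to_numpy(float)
    baseline = baseline_bin_rates(spikes, cs)
    rates, centers = trial_bin_rates(spikes, cs, window)
    return sliding_auroc(rates, centers, baseline, alpha=alpha,
                         unit_id=unit_id, condition=condition)


def response_duration(p_values: np.ndarray, alpha: float = 0.05,
                      bonferroni_m: Optional[int] = None) -> float:
    """Duration of the significant response in ms: 100 ms per bin with a
    Bonferroni-corrected p below ``alpha``."""
    p = np.asarray(p_values, float)
    m = bonferroni_m if bonferroni_m is not None else len(p)
    return float(100.0 * np.sum(p < alpha / m))


# ---------------------------------------------------------------------------
# two-sample and regression tests
# ---------------------------------------------------------------------------

def cohens_u3(reference: np.ndarray, comparison: np.ndarray) -> float:
    """Fraction of the comparison sample below the reference median."""
    a = np.asarray(reference, float)
    b = np.asarray(comparison, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sample")
    med = np.median(a)
    return float(np.mean(b < med) + 0.5 * np.mean(b == med))


def rate_comparison(sample_a, sample_b) -> TestResult:
    """Two-sided Wilcoxon rank-sum comparison of two rate samples, with
    direction from the median difference and Cohen's U3 attached."""
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sample")
    if np.ptp(np.concatenate([a, b])) == 0:
        return TestResult(0.0, 1.0, 0.5, "none", (len(a), len(b)))
    stat, p = sps.ranksums(a, b)
    diff = np.median(a) - np.median(b)
    direction = "+" if diff > 0 else ("-" if diff < 0 else "none")
    return TestResult(float(stat), float(p), cohens_u3(b, a), direction,
                      (len(a), len(b)))


def feature_correlation(x, y) -> TestResult:
    """Pearson correlation with t statistic t = r sqrt(n-2) / sqrt(1-r^2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    r, p = sps.pearsonr(x, y)
    n = len(x)
    t = r * np.sqrt(n - 2) / np.sqrt(max(1.0 - r * r, np.finfo(float).tiny))
    direction = "+" if r > 0 else ("-" if r < 0 else "none")
    return TestResult(float(t), float(p), None, direction, (n,))


def firing_rate_drift(rates_in_order) -> tuple:
    """OLS slope of rate against trial index, with its t-test.

    Returns ``(slope_per_trial, TestResult)``; constant input yields slope
    0 with p = 1.
    """
    y = np.asarray(rates_in_order, float)
    if len(y) < 10:
        raise ValueError("need >= 10 trials")
    x = np.arange(len(y), dtype=float)
    if np.ptp(y) == 0:
        return 0.0, TestResult(0.0, 1.0, None, "none", (len(y),))
    res = sps.linregress(x, y)
    direction = "+" if res.slope > 0 else ("-" if res.slope < 0 else "none")
    t = res.slope / res.stderr if res.stderr > 0 else 0.0
    return float(res.slope), TestResult(float(t), float(res.pvalue), None,
                                        direction, (len(y),))


# ---------------------------------------------------------------------------
# ANOVA-based analyses
# ---------------------------------------------------------------------------

def task_modulation_anova(epoch_rates: pd.DataFrame, *, alpha: float = 0.01):
    """Two-factor ANOVA (epoch x outcome type, with interaction) on
    trial-by-trial epoch firing rates.

    ``epoch_rates`` is the wide table from
    :func:`raphetag.rates.epoch_firing_rates`.  A unit is task-modulated
    when any of the three effects is significant at ``alpha``.  Returns
    ``(modulated, anova_table)``.
    """
    types = epoch_rates["trial_type"].unique()
    if len(types) < 2:
        raise ValueError("need >= 2 outcome types; "
                         f"got {sorted(types)}")
    counts = epoch_rates.groupby("trial_type").size()
    if (counts < 5).any():
        lacking = counts[counts < 5].index.tolist()
        raise ValueError(f"need >= 5 trials per outcome type; missing cells: {lacking}")
    long = epoch_rates.melt(
        id_vars=["trial", "trial_type"],
        value_vars=["baseline_rate", "cs_rate", "delay_rate", "us_rate"],
        var_name="epoch", value_name="rate")
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    model = ols("rate ~ C(epoch) * C(trial_type)", data=long).fit()
    table = sm.stats.anova_lm(model, typ=2)
    ps = table["PR(>F)"].iloc[:3]
    modulated = bool(np.nanmin(ps.to_numpy()) < alpha)
    return modulated, table


def _tukey(groups: dict, alpha: float = 0.05) -> pd.DataFrame:
    values = np.concatenate([np.asarray(v, float) for v in groups.values()])
    labels = np.concatenate([[k] * len(v) for k, v in groups.items()])
    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    return pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])


def _tukey_significant(pairwise: pd.DataFrame, a: str, b: str) -> tuple:
    """(significant, mean_diff a->b) for one Tukey pair."""
    for _, row in pairwise.iterrows():
        if {row["group1"], row["group2"]} == {a, b}:
            diff = float(row["meandiff"])
            if row["group1"] == b:
                diff = -diff
            return bool(row["reject"]), diff
    raise KeyError(f"pair ({a}, {b}) not in Tukey table")


def classify_value_salience(pretrial_rates: dict, alpha: float = 0.05) -> CodingLabel:
    """Classify tonic block coding as value- or salience-type.

    ``pretrial_rates`` maps ``{"reward": ..., "neutral": ..., "punishment":
    ...}`` to per-trial rate arrays.  Salience: reward and punishment both
    significantly above, or both below, neutral (Tukey HSD).  Value:
    reward differs from punishment and neutral is not significantly
    beyond both.  Otherwise unclassified.
    """
    for key in ("reward", "neutral", "punishment"):
        if key not in pretrial_rates or len(pretrial_rates[key]) == 0:
            raise ValueError(f"missing block type: {key}")
    groups = {k: np.asarray(v, float) for k, v in pretrial_rates.items()}
    if np.ptp(np.concatenate(list(groups.values()))) == 0:
        return CodingLabel("unclassified")
    pw = _tukey(groups, alpha)
    # diffs oriented as (condition minus neutral)
    rn_sig, rn_diff = _tukey_significant(pw, "neutral", "reward")
    pn_sig, pn_diff = _tukey_significant(pw, "neutral", "punishment")
    rp_sig, _ = _tukey_significant(pw, "reward", "punishment")

    both_above = rn_sig and pn_sig and rn_diff > 0 and pn_diff > 0
    both_below = rn_sig and pn_sig and rn_diff < 0 and pn_diff < 0
    if both_above or both_below:
        return CodingLabel("salience", pw)
    neutral_beyond = (rn_sig and pn_sig
                      and ((rn_diff < 0 and pn_diff < 0)
                           or (rn_diff > 0 and pn_diff > 0)))
    if rp_sig and not neutral_beyond:
        return CodingLabel("value", pw)
    return CodingLabel("unclassified", pw)


def reward_size_monotonicity(rates_by_size: dict, alpha: float = 0.05) -> str:
    """Strictly ordered condition means across zero/small/big reward blocks
    with the extreme pair Tukey-significant -> ``increasing`` or
    ``decreasing``; otherwise ``non_monotonic``."""
    for key in ("zero", "small", "big"):
        if key not in rates_by_size or len(rates_by_size[key]) == 0:
            raise ValueError(f"missing reward-size condition: {key}")
    groups = {k: np.asarray(v, float) for k, v in rates_by_size.items()}
    means = {k: v.mean() for k, v in groups.items()}
    if np.ptp(np.concatenate(list(groups.values()))) == 0:
        return "non_monotonic"
    pw = _tukey(groups, alpha)
    # diff is mean(big) - mean(zero)
    extreme_sig, extreme_diff = _tukey_significant(pw, "zero", "big")
    if means["zero"] < means["small"] < means["big"] and extreme_sig and extreme_diff > 0:
        return "increasing"
    if means["zero"] > means["small"] > means["big"] and extreme_sig and extreme_diff < 0:
        return "decreasing"
    return "non_monotonic"


def within_block_dynamics(epoch_rates: pd.DataFrame, block_length: int,
                          value_column: str = "pretrial_rate") -> pd.DataFrame:
    """Normalized mean rate profile by trial position within block.

    Rates are z-scored across positions within each unit series before
    averaging (a constant series maps to zeros), then averaged per
    position.  ``epoch_rates`` needs ``block_id`` and ``trial`` columns.
    """
    if block_length < 2:
        raise ValueError("block_length must be >= 2")
    df = epoch_rates.copy()
    first_in_block = df.groupby("block_id")["trial"].transform("min")
    df["position"] = df["trial"] - first_in_block
    prof = df.groupby("position")[value_column].mean()
    vals = prof.to_numpy(float)
    sd = vals.std(ddof=0)
    z = (vals - vals.mean()) / sd if sd > 0 else np.zeros_like(vals)
    per_pos = df.groupby("position")[value_column]
    return pd.DataFrame({
        "position": prof.index.to_numpy(int),
        "mean_rate": vals,
        "z_rate": z,
        "sem": per_pos.sem().to_numpy(float),
    })


def population_within_block_profile(per_unit_profiles: list) -> pd.DataFrame:
    """Average z-scored within-block profiles across units."""
    z = np.vstack([p["z_rate"].to_numpy(float) for p in per_unit_profiles])
    return pd.DataFrame({
        "position": per_unit_profiles[0]["position"],
        "z_mean": z.mean(axis=0),
        "z_sem": z.std(axis=0, ddof=1) / np.sqrt(z.shape[0]) if z.shape[0] > 1
                 else np.zeros(z.shape[1]),
    })


# ---------------------------------------------------------------------------
# outcome and behavior tests
# ---------------------------------------------------------------------------

def expected_vs_unexpected(us_rates, free_reward_rates) -> tuple:
    """Unexpected minus expected mean reward response, with rank-sum test.

    Returns ``(mean_difference, TestResult)``.
    """
    a = np.asarray(free_reward_rates, float)  # unexpected
    b = np.asarray(us_rates, float)  # expected
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sample")
    diff = float(a.mean() - b.mean())
    result = rate_comparison(a, b)
    return diff, result


def peak_latency(mean_density: np.ndarray, time_s: np.ndarray,
                 window: tuple) -> float:
    """Time (ms, relative to alignment) of the maximum of the mean density
    within ``window`` (seconds); ties resolve to the earliest sample."""
    t = np.asarray(time_s, float)
    d = np.asarray(mean_density, float)
    sel = (t >= window[0]) & (t < window[1])
    if not sel.any():
        raise ValueError("empty search window")
    idx = np.argmax(d[sel])  # argmax returns the first maximum
    return float(t[sel][idx] * 1000.0)


def _window_rate(times: np.ndarray, a: float, b: float) -> float:
    times = np.asarray(times, float)
    return (np.searchsorted(times, b) - np.searchsorted(times, a)) / (b - a)


def anticipatory_lick_test(lick_times, trials: pd.DataFrame,
                           alpha: float = 0.001) -> dict:
    """Do mice lick more in the delay before rewards?

    One-way ANOVA on delay-period lick rates across trial types, plus
    pairwise Welch t-tests of reward against each other type.  Returns a
    dict with the ANOVA :class:`TestResult` and per-pair results.
    """
    groups = {}
    for ttype, grp in trials.groupby("trial_type"):
        rates = [_window_rate(lick_times, r["cs_offset_s"], r["us_onset_s"])
                 for _, r in grp.iterrows()]
        if len(rates) >= 5:
            groups[ttype] = np.asarray(rates, float)
    if len(groups) < 2:
        raise ValueError("need >= 2 trial types with >= 5 trials")
    samples = list(groups.values())
    if np.ptp(np.concatenate(samples)) == 0:
        anova = TestResult(0.0, 1.0, None, "none",
                           tuple(len(s) for s in samples))
    else:
        f, p = sps.f_oneway(*samples)
        anova = TestResult(float(f), float(p), None,
                           "+" if p < alpha else "none",
                           tuple(len(s) for s in samples))
    pairwise = {}
    reward_keys = [k for k in groups if k.startswith("reward")]
    for rk in reward_keys:
        for other, vals in groups.items():
            if other == rk:
                continue
            both = np.concatenate([groups[rk], vals])
            if np.ptp(both) == 0:
                pairwise[(rk, other)] = TestResult(0.0, 1.0, 0.5, "none",
                                                   (len(groups[rk]), len(vals)))
                continue
            t, p = sps.ttest_ind(groups[rk], vals, equal_var=False)
            d = np.mean(groups[rk]) - np.mean(vals)
            pairwise[(rk, other)] = TestResult(
                float(t), float(p), cohens_u3(vals, groups[rk]),
                "+" if d > 0 else ("-" if d < 0 else "none"),
                (len(groups[rk]), len(vals)))
    return {"anova": anova, "pairwise": pairwise}


def block_tone_lick_test(reward_tone_rates, punishment_tone_rates) -> TestResult:
    """Paired Wilcoxon signed-rank test of tone-period lick rates before
    reward vs punishment blocks."""
    a = np.asarray(reward_tone_rates, float)
    b = np.asarray(punishment_tone_rates, float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need >= 2 paired observations")
    d = a - b
    if np.all(d == 0):
        return TestResult(0.0, 1.0, None, "none", (len(a),))
    stat, p = sps.wilcoxon(a, b)
    direction = "+" if np.median(d) > 0 else ("-" if np.median(d) < 0 else "none")
    return TestResult(float(stat), float(p), None, direction, (len(a),))


def choice_preference_test(choices: pd.DataFrame, *, alpha: float = 0.05) -> dict:
    """Proportion of safe (water-only) choices with an exact binomial test
    against 0.5."""
    if len(choices) < 20:
        raise ValueError("need >= 20 choices")
    k = int((choices["chosen_port"] == "water").sum())
    n = len(choices)
    res = sps.binomtest(k, n, 0.5)
    prop = k / n
    return {"proportion_water": prop,
            "test": TestResult(float(k), float(res.pvalue), None,
                               "+" if prop > 0.5 else ("-" if prop < 0.5 else "none"),
                               (n,))}


def count_proportion(k: int, n: int, confidence: float = 0.95) -> dict:
    """Percentage k/n with an exact (Clopper-Pearson) confidence interval.

    The percentage is rounded to one decimal for reporting, matching how
    cell counts are conventionally quoted.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    ci = sps.binomtest(k, n).proportion_ci(confidence_level=confidence,
                                           method="exact")
    return {
        "percent": round(100.0 * k / n, 1),
        "ci_low_percent": 100.0 * ci.low,
        "ci_high_percent": 100.0 * ci.high,
        "k": k,
        "n": n,
    }


def proportion_bins_test(significant_a: int, total_a: int,
                         significant_b: int, total_b: int) -> dict:
    """Fisher's exact test on two proportions of significant 100-ms bins.

    Returns the conditional-MLE odds ratio (NaN for zero-margin tables)
    and the exact two-sided p-value.
    """
    table = np.array([[significant_a, total_a - significant_a],
                      [significant_b, total_b - significant_b]])
    if np.any(table < 0) or total_a <= 0 or total_b <= 0:
        raise ValueError("counts must be >= 0 with positive totals")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        return {"odds_ratio": float("nan"), "p_value": 1.0}
    res = sps.contingency.odds_ratio(table, kind="conditional")
    _, p = sps.fisher_exact(table)
    return {"odds_ratio": float(res.statistic), "p_value": float(p)}
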