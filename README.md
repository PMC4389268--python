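# raphetag

Identification of optogenetically tagged dorsal raphe serotonergic
neurons and quantification of their reward/punishment coding, as a
tested, reusable pipeline driven by a synthetic-session simulator.

## The problem

Extracellular recordings from the dorsal raphe contain a mix of cell
types, and serotonergic neurons cannot be told apart by spike shape or
firing statistics alone. The reliable approach is *opto-tagging*:
express channelrhodopsin-2 (ChR2) in serotonergic neurons, deliver
trains of brief (5-ms) light pulses at 1–50 Hz, and identify units whose
short-latency light-evoked spikes match their spontaneous waveform. Once
identified, the question is what these neurons encode during a blocked
classical-conditioning task — odor cues (CS) predicting water reward,
nothing, or air-puff punishment, arranged in blocks of 10 like trials
with flat-hazard (exponential, 10-s mean) inter-trial intervals — on two
timescales:

- **tonic**: sustained pre-trial firing-rate differences of order
  1–2 spikes s⁻¹ between reward and punishment blocks, persisting across
  minutes (value vs salience coding, reward-size monotonicity);
- **phasic**: brief (<500 ms) excitations or inhibitions after cues and
  outcomes, quantified by the area under the ROC curve (auROC) between
  trial firing rates and baseline in sliding 100-ms windows.

No recordings are distributed with this package. Instead the
`simulate` module generates sessions with the full statistical
structure the analyses assume — inhomogeneous-Poisson spike trains with
block gains, rectangular phasic responses, slow drift, ChR2-evoked
spiking with frequency-dependent probability and latency, tetrode
waveform snippets — together with ground-truth labels, so every stage of
the pipeline has a parameter-recovery test.

## Core methods

**Tagging** (module `optotag`). For each unit and each light pulse, the
first spike within 10 ms whose snippet matches the unit's mean
spontaneous waveform counts as light-evoked. If at least 20% of pulses
evoked a spike, the light response is the mean evoked waveform;
otherwise it is the maximum-|v| trace segment from the 10-ms windows.
Two scalars summarize each unit: the energy E = ∫v²dt of the light
response and the Euclidean distance between the peak-aligned mean
spontaneous spike and the light response over the spike's duration. A
2-component Gaussian mixture over (log₁₀E, log₁₀d) — several covariance
parameterizations, Ward-tree initialization, BIC model selection —
separates light-responsive from non-responsive units; a unit is *tagged*
iff it falls in the light-responsive cluster **and** responded reliably
(evoked fraction ≥ 0.20) **and** its response was an actual spike.

**Rates** (module `rates`). PSTHs in 10-ms bins; spike density functions
by convolution with the causal kernel k(t) = (1 − e^(−t)) e^(−t/200)
(t in ms), normalized to unit area; epoch rates for baseline (1 s
pre-CS), CS, delay, US (500 ms), and the 2-s pre-trial window.

**Statistics** (module `stats`). Sliding-window auROC via the
tie-corrected Mann–Whitney U (auROC = U/n₁n₂; 0.5 = no change),
Bonferroni-corrected per-bin rank-sum tests, response duration = 100 ms
× number of significant bins, two-factor (epoch × outcome) ANOVA for
task modulation, Tukey-HSD-based value/salience classification and
reward-size monotonicity, Pearson correlations with
t = r√(n−2)/√(1−r²), Cohen's U₃ effect sizes, OLS drift slopes,
within-block dynamics, Fisher's exact test on proportions of
significant bins, and exact binomial proportions with Clopper–Pearson
intervals.

**Quality** (module `quality`). L-ratio (χ²-tail sum of Mahalanobis
distances of noise events in an 8-d PCA waveform space, normalized by
cluster size), SNR in dB (peak-to-peak over twice the noise SD), ISI
coefficient of variation, rank-sum spike duration, and the (negative)
waveform-based classifiability analysis.

## Worked example

```python
from raphetag.presets import simulate_tagging_session
from raphetag.optotag import tag_session

session = simulate_tagging_session(1, n_units=10, n_tagged=3)
tagging, responses = tag_session(session)
print(tagging[["unit_id", "energy", "distance",
               "evoked_probability", "tagged"]].round(2).head(5))
```

```
unit_id  energy  distance  evoked_probability  tagged
   u000 6139.07      4.83                0.82    True
   u001 7431.91      5.28                0.82    True
   u002 4200.78      3.09                0.77    True
   u003 1914.71     36.05                0.08   False
   u004 6023.21     35.96                0.11   False
```

Tagged units show high light-evoked energy, a light response close to
their spontaneous waveform (small distance), and reliable evoked spiking;
here the pipeline recovers exactly the three ground-truth tagged units.
The per-frequency profile of one tagged unit shows the expected drop in
following probability at high stimulation frequencies:

```
train_frequency_hz  n_pulses  evoked_probability  latency_mean_ms  latency_sd_ms
               1.0        20                0.85             2.50           0.84
               5.0        20                0.95             2.96           1.51
              10.0        20                0.90             2.65           0.79
              20.0        20                0.60             2.41           0.58
              50.0        20                0.80             2.74           0.68
```

The same flow is available from the shell:

```bash
raphetag simulate --seed 5 --preset paper_like --out bundle/
raphetag tag     --bundle bundle/ --out tag/
raphetag analyze --bundle bundle/ --out tables/
raphetag report  --tables tables/ --out report.txt
```

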