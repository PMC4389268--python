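# Methods

This note documents the models and procedures implemented in
`raphetag`, the parameters that matter, and the design choices made
where the design was genuinely open.

## Task and session model

A session is a sequence of trials grouped into blocks of a single
valence. Timing defaults (`TaskConfig`): 1-s odor CS, 1-s trace delay,
outcomes analysed over the 500 ms after US onset, 10 trials per block,
inter-trial intervals drawn from an exponential density with mean
`iti_scale` = 10 s. The exponential ITI gives a flat hazard, so the
animal cannot anticipate trial onset; an optional truncation redraws
ITIs above a cutoff (off by default — the observed-ITI summary one
would emulate implies some truncation, but no value is documented, so
it is exposed as a knob rather than guessed). A 15-kHz tone of 1 s
signals each block change and ends 1 s before the block's first CS;
when the exponential draw at a block boundary is too short to fit the
tone, the boundary ITI is extended to tone span + 0.1 s (affects at
most one ITI in ten, and only its lower tail). All event times are
seconds from session start; trial-aligned analyses put CS onset at 0.

Bundles on disk are directories of plain CSV tables plus one YAML
config, with explicit index columns. One extension beyond the obvious
tables: `light_traces/<unit_id>.csv` stores the dominant-channel
voltage in the 10-ms window after each light pulse, which the
sub-threshold branch of the tagging analysis needs.

## Synthetic sessions

Spike trains are inhomogeneous Poisson processes sampled by thinning of

    λ(t) = max(0, baseline + block_gain(t) + Σ phasic(t) + drift·t)

- `block_gain` is a per-block-type additive rate (spikes/s) applied
  from the block's tone to the next block's tone. The presets draw the
  reward-vs-punishment tonic difference uniformly from 1–2 spikes/s,
  with a random sign per unit (60% reward-preferring).
- Phasic CS/US responses are rectangular rate pulses (amplitude, onset
  latency, duration). Rectangles were chosen over alpha-like shapes
  because their duration is exactly recoverable by the
  duration-of-significant-response statistic, which is what the
  recovery tests assert. Preset durations are drawn around 315 ms (SD
  80) for punishment-US responses and around 235 ms (SD 60) for
  reward-CS responses; amplitudes 8–14 and 5–9 spikes/s respectively.
- Drift is linear in time, in spikes/s per hour (preset −0.5 ± 0.3).
- ChR2-evoked spiking: per pulse, a Bernoulli draw with
  frequency-dependent probability (preset 0.95 at 1 Hz falling to 0.5
  at 50 Hz) emits one spike at a Normal(latency mean, SD) latency
  clipped to (0, 10] ms. Latency means are drawn from 2–5 ms.
- Waveforms: each spike snippet is a fixed biphasic tetrode template
  plus i.i.d. Gaussian noise per sample and channel; noise snippets
  are pure noise. Light-window traces are noise plus the template
  wherever a spike (evoked or coincident spontaneous) falls in the
  window.
- Sessions default to a trial count drawn as 533 ± 120, clipped to
  400–700 and rounded to whole blocks, matching a realistic day of
  training.

Seeding: a single master seed; each (session, unit) pair derives its
child stream from `SeedSequence([master, session, crc32(unit_id)])`, so
adding a unit never perturbs the others and cohorts are bit-reproducible.

What the generator does **not** emulate: correlated noise across units
or electrodes, spike-sorting errors, bursting/refractory structure
(ISIs are exponential), electrode drift in waveform shape, lick-spout
artifacts, and continuous raw voltage. Tests passing on this generator
therefore demonstrate correctness of the analysis chain under its
stated statistical assumptions, not robustness to every failure mode of
real tetrode data.

## Tagging pipeline

Detection: for each pulse, the first spike in (onset, onset + 10 ms]
whose snippet matches the unit's mean spontaneous waveform counts as
evoked. The match criterion (not standardized anywhere) is Pearson
r ≥ 0.9 on the dominant channel plus peak amplitude within ±50% — a
scale-tolerant shape match.

Response summary: with evoked fraction ≥ 0.20 (boundary inclusive) the
response waveform is the mean evoked snippet and the unit has a
spike response; below that, the response is the snippet-length trace
segment attaining the maximum absolute voltage across windows. Energy
is Σv²·Δt in µV²·ms; distance is the Euclidean norm between the
peak-aligned spontaneous mean and the response over the samples spanned
by the measured spike duration, with the shift bounded to ±¼ of the
snippet. Two numerical details:

- *Flat extrema.* Averaged waveforms can have troughs flat to within
  the noise of the mean, so the integer argmax of |v| is unstable by
  ±1 sample, which inflates the distance of a genuinely matching
  response ~15-fold. All samples within 5% of the peak voltage are
  therefore treated as alignment candidates and the minimum distance is
  reported.
- *Channel handling.* All scalar waveform metrics (energy, distance,
  duration, SNR) use the dominant tetrode channel — the one with the
  largest mean absolute peak.

Spike duration: per-sample rank-sum tests of snippet voltage against
noise voltage, Bonferroni-corrected over samples; the duration runs
from the first to the last significant sample. Unit with no
significant sample report duration 0 with a note.

Clustering: 2-component Gaussian mixtures on (log₁₀ energy,
log₁₀ distance) over spherical/tied/diag/full covariance
parameterizations, means initialized from a 2-way Ward cut, selected by
BIC; the component with the higher (energy − distance) score in log
space is the light-responsive one. The log features are used raw:
standardizing them was tried and let the spherical model win BIC with a
split through the tagged cluster on ~10% of simulated cohorts.

Decision: tagged ⇔ light-responsive cluster ∧ evoked fraction ≥ 0.20
∧ spike response. The reliability threshold reuses the 20%
sub-threshold rule; units that land in the responsive cluster through
chance coincidences of spontaneous spikes with pulses are rejected by
this conjunct. Note the margin is thin for very fast units: at
20 spikes/s the per-pulse coincidence probability is
1 − e^(−0.2) ≈ 0.18, and with n pulses the sampled fraction exceeds
0.20 with probability P(Bin(n, 0.18) ≥ 0.2n) — about 0.37 at n = 100.
The tests assert rejection against this binomial model rather than a
flat rate, and real use should prefer more pulses for high-rate units.

## Rate estimation

The spike-density kernel is k(t) = (1 − e^(−t)) e^(−t/200) with t in
milliseconds (1-ms rise, 200-ms decay, consistent with sub-second
response durations), truncated at 1000 ms (five decay constants, <1%
of peak) and normalized to unit area so densities read in spikes/s;
it is evaluated on a 1-ms grid and peaks ln(201) ≈ 5.3 ms after a
spike. PSTH bins are half-open [edge, edge + 10 ms) with a 1e-9
epsilon guard so edge spikes land deterministically. Whether the
original analyses normalized their kernel is not documented; unit-area
normalization affects absolute densities only, not any comparative
statistic.

Epoch windows: pre-trial = 2 s before CS onset, baseline = 1 s before
CS, CS = odor on→off, delay = odor off→US, US = US→+500 ms. When the
preceding ITI is shorter than 2 s, the pre-trial window is clipped at
the previous trial's US onset and the trial is flagged
`pretrial_truncated`. Tonic analyses (value/salience classification,
pre-trial block comparisons in the CLI) exclude flagged trials: a 2-s
rate estimated over a fraction of a second has variance inflated by
the inverse of the span and single clipped trials otherwise dominate
the group comparisons.

The session timecourse is a 60-s centered sliding mean of 1-s spike
counts. A display-only smoothing spline is deliberately absent from all
statistics.

## Discriminability statistics

The auROC trace compares, for each trial-aligned 100-ms bin, the
across-trial firing-rate sample to the pooled baseline sample (the ten
100-ms bins of each selected trial's 1-s pre-CS window). Baselines are
condition-specific: punishment analyses use pre-punishment baselines,
reward analyses pre-reward baselines. The statistic is the
tie-corrected Mann–Whitney auROC (identical samples give exactly 0.5);
per-bin two-sided rank-sum p-values are Bonferroni-corrected over the
number of bins in the trace (25 for the default CS→US+500 ms window),
and response duration is 100 ms per significant bin.

One deliberate deviation: the binwise samples are spike counts per
100-ms bin (a boxcar density) rather than averages of the
psp-kernel density. The kernel's 200-ms decay smears a rectangular
response two or more bins past its true end, which would bias the
duration statistic upward and defeat exact duration recovery; the
kernel density is still used where a dense rate estimate is needed
(peak latency, display). With boxcar bins, recovered durations match
generative durations within one bin quantum in the tests.

Value/salience classification operationalizes the verbal rule as:
one-way ANOVA + Tukey HSD over {reward, neutral, punishment} pre-trial
rates; *salience* iff reward and punishment are both significantly
above, or both below, neutral; *value* iff reward differs significantly
from punishment and neutral is not significantly beyond both extremes;
otherwise unclassified. Reward-size monotonicity requires strictly
ordered means across zero/small/big with the extreme pair
Tukey-significant. Task modulation is declared when any of the three
two-factor ANOVA effects (epoch, outcome, interaction) has p < 0.01 —
an inclusive reading of "task-related". Counting "n of N significant
units" applies no correction across units, and the report says so.

Cohen's U₃ is the fraction of the comparison sample below the
reference median (orientation fixed here; only the magnitude convention
matters downstream).

## Unit quality

L-ratio: with unit feature vectors X (mean µ, covariance S) in d = 8
dimensions (first two principal components per tetrode channel, PCA
fit on the unit's snippets, noise events projected into the same
basis), L = Σ over non-unit events of (1 − F_{χ²,d}(D²)) with D² the
squared Mahalanobis distance to the cluster, divided by the number of
unit spikes. SNR (no standard definition; stated in output metadata) is
20·log₁₀(peak-to-peak of the dominant-channel mean / 2·noise SD) dB.
Inclusion thresholds: L-ratio < 0.05, SNR > 5 dB. ISI CV uses the
population SD over mean of successive differences; the classifiability
report runs 2-cluster GMM and k-means on standardized (duration, rate,
ISI CV) and reports adjusted Rand agreement with the tagged labels.

## Problem sizes in the test suite

The suite exercises every recovery claim at sizes chosen to keep the
statistics decisive: tagging recovery uses 100 cohorts of 30 units with
a light-only protocol of 100 pulses per unit (tagging data are
collected outside the behavioral session, so no task simulation is
needed there); duration recovery uses 10-unit cohorts of 80-trial
sessions; drift recovery uses 530-trial sessions (a realistic day);
type-I calibration uses 2,000 null replicates per test, with group
sizes (n = 20 rank-sum/signed-rank, n = 29 correlation, 300-trial
binomial) at which the discrete tests' attainable size is within the
asserted band of the nominal level. Bundle round-trips use 30-trial
sessions so the waveform tables stay small.

## Known limitations

- The thinning sampler treats λ as piecewise-linear-in-t with
  step changes; responses triggered by undelivered outcomes (omission
  trials) are absent by construction, which is the intended semantics.
- The tagging GMM assumes exactly two clusters; cohorts that genuinely
  contain an intermediate class (e.g., partially expressing units) will
  be split by the reliability conjunct, not by the mixture.
- `detect_evoked_spikes` requires snippets for the spikes in light
  windows; the simulator guarantees this, and real loaders must too.
- The exact-binomial and signed-rank tests are conservative at small n;
  calibration is asserted at sizes where discreteness is negligible.
- Lick events are stored raw; no debouncing is applied anywhere.
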