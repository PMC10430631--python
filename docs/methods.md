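# Methods

## Data model and conventions

All times are integer milliseconds from session start; intervals are
half-open `[start, end)`, so a bin edge is never double-counted. Spike
times are rounded to the nearest millisecond and 1-ms duplicates collapsed
to one spike (true sub-millisecond doublets are implausible given the
refractory period). Sessions are stored as plain CSV/JSON
(`blocks.csv`, `rewards.csv`, `events.csv`, `spikes.csv`, `rwaves.csv`,
`meta.json`); writing is byte-stable for a fixed session, and reading
re-validates every structural invariant (ordered non-overlapping blocks,
events inside their blocks, duration bounds per modality, location 11 ⇔
sham, strictly increasing spike/R-wave times).

Sham puffs carry `modality="sham"` and are never pooled with airflow
unless an analysis asks for it explicitly; they control for the auditory
component of the airflow apparatus.

## Synthetic session generator

The generator is the package's test bed; its defaults reproduce the
standard design:

* **Blocks** — airflow, grooming, airflow, grooming, airflow, separated by
  20-s gaps (groomer entry/exit).
* **Airflow blocks** — 10 pseudo-random permutations of the 11 nozzle
  locations, 1-s puffs with 3-s ISI, a 1-s juice reward window after each
  set (≈7.5 min/block).
* **Grooming blocks** — 5 sets of 10 sweeps at the upper muzzle then 10 at
  the brow; sweep durations uniform on [1, 2] s, ISIs uniform on [2, 4] s;
  one reward window at block end (≈7.5–9 min/block).
* **Spikes** — inhomogeneous Poisson with intensity
  `rate(t) = baseline(block kind) + Σ evoked kernels`, drawn per 1-ms bin
  and rounded/deduplicated like real data. Airflow-like kernels are a
  sustained gain over the stimulus plus a 100-ms onset transient at 3×
  gain; grooming kernels may instead be triangular ramps peaking
  mid-stimulus (tracking finger-pressure time courses). Exact kernel
  shapes are a modeling choice — only their qualitative form is
  constrained — so recovery tests target window-averaged rates.
* **Heart** — R waves by integrate-to-threshold over
  `r(t) = BPM(kind)/60000 · (1 + depth(kind)·sin(2πf t))`, with optional
  `(start, duration, ΔBPM)` tachycardia episodes added as rate offsets.
  The draw is deterministic given the config; across-session variability
  comes from per-session configs. Context defaults: airflow 110 BPM /
  RSA depth 0.02, grooming 95 BPM / depth 0.10 at 0.30 Hz — grooming is
  bradycardic with stronger respiratory sinus arrhythmia.
* **Reproducibility** — one seed per session; each unit draws from a
  substream keyed by `crc32(unit_id)`, so adding a unit never perturbs
  another unit's spikes.

Context units in the demo population shift their Poisson baseline between
contexts by a *standardized* 0.5 (the grooming rate is solved from
`d = (λ_g − λ_a)/sqrt((λ_g + λ_a)/2)`), with the groomer-present rate
midway — an additive social-context signal.

What the generator does **not** emulate: spike-sorting noise and unit
instability, bursting/refractory structure, slow non-stationary drift
within blocks, correlated population variability, respiration itself, or
movement artifacts in the EKG. Passing recovery tests therefore
demonstrates correctness of the analysis code under the stated generative
model, not robustness to every pathology of real recordings; the
within-condition effect-size controls and artifact rules are exercised by
construction (e.g., injected drift, injected artifact IBIs) rather than by
realistic physiology.

## Responsivity

Pre-stimulus window `[onset−1000, onset−250)`, post `[onset+200, offset)`;
per-trial *rates* (not counts) are compared with a two-sided paired t test
so variable-duration sweeps are handled naturally. A response requires
p < 0.05 **and** |Δ| ≥ 1 Hz; the 1-Hz floor makes the test conservative
(type-I rate below nominal α, verified by simulation). Units enter the
analysis with ≥1 Hz session-wide mean rate, a stability flag (supplied by
sorting QC; no drift detection is implemented here), and ≥10 trials per
required location. Tactile labels compare modalities only at groomed
locations. Proportions are compared with the 2×2 chi-squared test without
continuity correction (computed in closed form; degenerate margins give
χ² = 0, p = 1).

Zero-variance paired differences short-circuit the t test (p = 1 for zero
difference, p = 0 otherwise) instead of propagating NaNs.

## Baseline extraction and context classification

Per block, baseline = block span minus every stimulus window padded by
300 ms on each side, minus reward windows (inter-block gaps are outside
blocks by construction). Segments are concatenated per block and cut into
consecutive full 1-s bins — short segments contribute jointly, trailing
partial bins are dropped. This is verified bin-for-bin against a
brute-force 1-ms timeline mask on random sessions.

Z-scores are computed per unit over all retained bins of the four analysis
blocks jointly (per-block Z-scoring would erase the context signal).
Effect sizes are computed on raw Hz; `d_s` is scale-invariant so this
matters only for display. When a session has three airflow blocks the
analysis uses the first two airflow and first two grooming blocks, and
requires ≥60 bins in each; the classification rule is
`|d_GA| > 0.2` and `|d_GA| ≥ 1.5·max(|d_GG|, |d_AA|)` with absolute values
throughout (the direction of within-condition drift is irrelevant to the
control it provides), the sign of `d_GA` giving groom-up vs groom-down.
Zero pooled SD returns 0 for equal means and raises otherwise.

The groomer-presence analysis takes per-unit mean baseline rates (raw Hz)
in the three conditions and reports paired steps (groomer-present vs
absent airflow; grooming vs groomer-present airflow) per direction group
with paired t tests.

## Decoding

Single-unit decoding: 1-D linear SVM (scikit-learn `LinearSVC`, C = 1 —
on 1-D inputs accuracy is insensitive to C over a wide range; the constant
is a config knob) with the majority context down-sampled (seeded) and
stratified 10-fold CV (stratification preserves the balanced counts per
fold). The permutation null re-runs the *entire* balanced CV per label
shuffle; significance = true accuracy above the 97.5th percentile of the
null. Percentile (2.5/97.5) intervals are used for all 95% CIs. CV
accuracy may fall below 50% for weak units; the null still centres on 50%.

Pseudo-populations pair same-context bins uniformly at random across units
per bootstrap draw (units are not simultaneously recorded, so no bin
correspondence exists), 60 bins per block per unit, sampling units with
replacement by default. The population curve reports mean and percentile
CI per set size; the minimum population size is the smallest set whose CI
lower bound exceeds the accuracy threshold (default 0.95). Default
resampling counts are desk-scale (1,000 permutations, 500 bootstraps);
`full=True` / `--full` restores 10,000.

PCA separability projects the bins × units matrix onto the first principal
component and 2-means clusters the projection; accuracy is the better of
the two cluster-to-label assignments.

## Autonomic analysis

IBIs outside the open interval (250, 1500) ms are artifacts — the
boundary values map to exactly 240/40 BPM, the stated exclusion edges, so
they are rejected (strictness is a documented choice). Instantaneous HR
(60000/IBI at each retained beat) is interpolated to a 1-ms grid with
modified Akima cubic Hermite interpolation (`scipy`'s `makima`), which
avoids the overshoot of ordinary cubic splines at artifact gaps.

For spectral analysis the HR series is decimated to 4 Hz — the RSA band
tops out at 0.5 Hz, so 4 Hz leaves an 4× margin while keeping 60-s windows
at 240 samples (the 1-ms grid is retained for episode detection and
display). Multitaper PSDs use 7 DPSS tapers with NW = 4, the unique
choice consistent with K = 2NW−1 = 7 tapers and a ±0.067 Hz half-bandwidth
(≤ the nominal ±0.07 Hz) on a 60-s window; windows step by 3 s and are
mean-removed. RSA strength per window is the mean power within one
half-bandwidth of the largest local maximum in 0.25–0.5 Hz (ties broken
toward lower frequency; windows with no in-band local maximum fall back to
the band mean and are flagged with a NaN peak). Normalization is
`(strength − μ)/μ` with μ the **median** across windows, as specified —
the median window is exactly 0.

Episode detection: within grooming blocks, maximal contiguous spans with
HR > stable-period mean + 2 SD lasting ≥10 s. The stable period can be
supplied or auto-selected as the longest artifact-free grooming span with
HR within ±2 SD of its own mean, clipped to 6–20 min. Grooming
responsivity during episodes re-runs the standard pre/post test on sweeps
whose onsets fall inside episodes (pooled across locations, since episode
sweep counts are small); fewer than 10 such sweeps is an
insufficient-data outcome, not an error.

## Pipeline

`run_all` wires the stages, writes a manifest (config + version + seeds),
logs every exclusion with its reason, and emits CSV tables plus a
`summary.json` with label counts, the SVM/effect-size overlap partition,
HR/RSA per block kind, and episode results. Outputs are byte-identical
for identical (config, seed). All p values are reported raw — no
multiple-comparison correction is applied anywhere, and outputs say so by
construction (one p per planned contrast).

## Problem sizes

Defaults are chosen for desk-scale runs: demo sessions of ~40 min with
~11 units; test-suite resampling at 100–1,000 permutations and 15–500
bootstraps; the acceptance calibration uses 120 baseline bins per
condition and 1,000 permutations. All counts scale up by configuration
(`--full` for the paper-scale 10,000 resamples).

## Known limitations

* The stability flag is taken from upstream QC; no drift detection.
* Grooming sweep onsets are treated as exact (no transducer-alignment
  jitter is modeled).
* The airflow-duration variant (1.5 s in early sessions) is accepted by
  the schema but the generator emits 1-s puffs by default.
* `R` in the RSA normalization uses the median as written even though μ
  conventionally denotes a mean; with symmetric strength distributions the
  difference is negligible.
* k-means separability has no external numeric anchor; it is validated by
  construction (separated vs identical clusters) only.
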