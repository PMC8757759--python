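# Methods

This note documents the models, conventions and numerical choices behind
`hdsemg`, and what the synthetic-data tests do and do not establish about
real recordings.

## Grid model and coordinate conventions

The electrode grid is 13 rows × 5 columns with one unpopulated corner
position (64 electrodes) and an 8 mm inter-electrode distance, all
configurable.  Grid indices are 1-based; the **row axis (x)** runs along the
muscle-fiber direction (the long, 13-electrode axis), the **column axis
(y)** across it.  Which of the 65 positions the physical array omits is not
fixed by the hardware documentation available to us; this package's
documented default is `(1, 1)`.  CoG coordinates are reported in
electrode-index units (so a uniform full grid has its barycentre at
(7.0, 3.0)); `CoGPoint.to_mm(ied_mm)` converts to millimetres when a
physical scale is preferred.

Signals are held in mV throughout.  The interchange format (TSV matrix +
JSON sidecar) declares the on-disk unit (V, mV, µV) and is converted on
load; round-trips are lossless for metadata and better than 1e-9 mV for
signals.

## Preprocessing

- **Band-pass 20–400 Hz**, zero-phase 4th-order Butterworth
  (`sosfiltfilt`).  The filter family is a package choice: Butterworth is
  standard EMG practice and the forward–backward application preserves
  envelope timing, which matters for CoG trajectories.  Passband gain is
  within a few percent of unity away from the edges (verified at 100 Hz);
  5 Hz is attenuated below 0.1.
- **Single-differential montage**: channel `(i, j) = s(i,j) − s(i+1,j)`
  along the fiber axis; pairs touching a missing electrode are dropped, so
  the default grid yields 59 differential channels on a 12-row geometry.
  Differential signals suppress components common to the whole grid.
- **Contraction segmentation**: the smoothed (100 ms moving average)
  dynamometer torque — or, absent torque, the rectified grid-mean EMG
  envelope — is thresholded at 10% of its peak; the segment spans the first
  to last crossing.  Threshold and smoothing are configurable; segments
  shorter than the analysis epoch are rejected.
- **Windowed RMS maps**: non-overlapping 250 ms windows tile the segment by
  default.  250 ms is used both for the midpoint feature epoch and for the
  trajectory windows; a 1 s window reproduces the per-second amplitude
  tiling used in amplitude summaries.  Overlap is supported but defaults to
  0 (the window length is a sensitivity parameter, surfaced in the config
  and CLI).

## Feature conventions

Two deliberate aggregation conventions, chosen where the per-channel
definitions do not by themselves produce one number per trial:

- **Which montage feeds which feature.**  Entropy, CoV and differential
  intensity are computed from the single-differential map (59 channels on
  the default grid); intensity, mean RMS and median frequency from the
  monopolar map/signals.  Keeping intensity on the monopolar map is what
  makes I and DI distinct, mutually informative quantities; channel counts
  follow the actual valid-channel count rather than hard-coding 59, so
  grids with extra dropouts remain analyzable.
- **DI aggregation.**  The differential-intensity definition is per channel
  pair; the trial-level scalar is the common log of the *mean* differential
  RMS, mirroring the intensity formula, so I and DI are commensurable.

Entropy uses `q_i = RMS_i²/Σ RMS_k²` and is reported in bits; `0 ≤ E ≤
log2(n_valid)`, invariant under positive rescaling.  CoV uses the
population SD and is reported in percent.  Both I and DI shift by exactly
+1 per tenfold amplitude scaling.

**Median frequency** is computed per channel on the midpoint epoch with a
Hann-windowed periodogram; the median is the *smallest* frequency at which
cumulative power reaches half the total (the tie-break that matters for
discrete spectra with isolated lines), then averaged over non-silent
channels.  Whether a practitioner pools spectra before or after taking the
median is a real degree of freedom; per-channel-then-average is this
package's convention.

## CoG estimation

The barycentre weights are the map amplitudes themselves (the estimator is
linear in `HM`, not in its square), making the CoG invariant under positive
rescaling and translation-equivariant.  The **point method** reduces a
contraction to one reference map — `peak_intensity` (default for dynamic
contractions), `midpoint`, or `peak_torque` — while the **trajectory
method** evaluates every window and summarises each axis by mean,
variance, SD and range.  Variance and SD are both emitted, labelled
unambiguously, since report tables in the field mix the two.

CoG is computed on the monopolar 13×5 map by default: the coordinate frame
of the 13-row grid is the natural one for reporting, and the differential
map's 12-row index frame would carry a systematic half-row offset for
sources symmetric about an electrode row (the differential channel sits
*between* its two electrodes).  Any `ActivationMap`, including differential
ones, can still be passed to `cog_point` directly.

All-zero windows (possible at contraction edges under aggressive
thresholds) are skipped with a warning rather than failing the trajectory;
the trajectory errors only if every window is empty.

## Synthetic grid EMG

The generator emulates the recordings at the level the spatial analysis
sees — per-channel RMS topography and spectrum — not at the motor-unit
level.  Per channel:

```
signal(t) = amplitude_mv · w(ch, t) · force(t) · carrier(ch, t) + noise(t)
```

- `carrier` — independent unit-RMS Gaussian processes, synthesised in the
  frequency domain with a brick-wall 20–400 Hz band, so the in-band
  spectrum is exactly flat (median frequency 210 Hz, the band midpoint — a
  sharp spectral oracle).  An optional `common_drive` fraction mixes in one
  shared carrier so common-mode rejection of the differential montage is
  testable.
- `w(ch, t)` — an anisotropic Gaussian spatial envelope over the grid whose
  centre follows configurable `(t, x, y)` waypoints (linear interpolation);
  the envelope weight is the per-channel ground truth for RMS topography
  and the centre path the ground truth for CoG trajectories.
- `force(t)` — a trapezoidal effort (onset delay, ramp up, plateau, ramp
  down) standing in for the isokinetic contraction, also emitted as a
  100 Hz torque channel scaled to a peak torque.
- `noise` — white Gaussian at the hardware noise floor.

Defaults are the study-like conditions: 1024 Hz, 3 s trials with a 0.5 s
ramp and 1 s plateau, peak envelope RMS `amplitude_mv = 0.2` (observed
trial mean RMS spans roughly 0.04–0.34 mV), noise floor 0.002 mV (the
amplifier spec, < 2 µV RMS), and a broad envelope (σ_rows = 4.0,
σ_cols = 2.5) that yields near-ceiling entropy (≈ 5.5–5.6 of 5.88 bits)
and CoV ≈ 30–35%, as seen in able-bodied cohorts.  Localized- and
drifting-source scenarios used in tests narrow the envelope to
σ = (1.5, 1.0) to represent focal activation.  Identical seeds give
bit-identical recordings.

**What the generator does not model**, hence what passing tests do not
show about real data: motor-unit action-potential shapes, recruitment and
firing statistics, volume conduction (adjacent channels are independent by
default, so the differential map's amplitude sits *above* the monopolar
one rather than below it as in real, spatially correlated EMG), the
physiological ~50–120 Hz spectral concentration (the synthetic spectrum is
flat in-band, so simulated median frequencies cluster near 210 Hz, not
~80 Hz), electrode–skin impedance drift, movement artefact, or power-line
interference.  Tests against this generator validate the *estimators*
(recovery of known topography, centres, drifts, spectra and calibrated
error rates), not physiological realism.

## Statistics

Shapiro–Wilk, paired t-tests and Pearson correlation delegate to
`scipy.stats`.  Bonferroni adjustment is `min(1, p · m)` over the `m`
condition pairs present in the input, with significance judged on the
adjusted p at α = 0.05 (configurable); under a simulated null cohort
(14 subjects, 3 speeds, no effect) the measured family-wise error is
≈ 0.05, checked at Monte-Carlo precision over 1000 repetitions.  Paired
differences with zero variance are handled explicitly (identical pairs →
t = 0, p = 1; a constant nonzero shift → p = 0) since the t statistic is
undefined there.  Replicate trials are averaged within subject × speed
before pairing.  Zero-variance series make the Pearson correlation
undefined and are reported as such rather than as NaN surprises.

## Problem sizes and determinism

Simulation-backed checks use 2.5–6 s trials (64 channels at 1024 Hz),
cohorts of 4–14 subjects × 3 speeds, 20 seeds for recovery studies and
1000 repetitions for error-rate calibration; these sizes give Monte-Carlo
margins comfortably inside the asserted tolerances while keeping the full
suite and the acceptance script fast.  All randomness flows from explicit
seeds through `numpy.random.default_rng`; the pipeline writes tables with
a fixed float format, so a config plus seeds reproduces byte-identical
reports.

## Known limitations

- The generator's independence between channels exaggerates differential
  amplitudes (see above); a spatially correlated source model would be the
  natural extension.
- Envelope truncation at the grid boundary biases the recovered CoG of
  near-edge sources toward the grid centre by a few hundredths of an
  index unit; the noise floor adds a similar small centripetal pull
  (visible as drift-range estimates slightly below the configured drift).
- Segmentation assumes a single contraction per recording; repeated
  efforts need manual segments.
- Bad-channel masking beyond the geometry's missing list relies on the
  sidecar's channel map (drop the channel and list its position as
  missing); no automatic artefact detection is attempted.
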