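# hdsemg

Spatial analysis of **high-density surface EMG (HDsEMG)** grid recordings:
amplitude activation maps, their scalar features, and centre-of-gravity
(CoG) trajectories over dynamic contractions.

HDsEMG records a muscle through a 2D grid of closely spaced electrodes — here
a 13 × 5 array (64 active sites, 8 mm inter-electrode distance) over the
rectus femoris during isokinetic knee extensions at 60/90/120 °/s.  The RMS
amplitude of each channel over a short window forms an *activation map*
`HM`, with `HM_ij` the RMS of the electrode at grid position *(i, j)*.  This
package computes the standard spatial features of such maps, both classical
and trajectory-based barycentre estimates, and the group statistics used to
compare them — plus a synthetic grid-EMG generator with known ground truth,
so the whole pipeline is testable without access to recordings.

## Features of one contraction epoch

From a 250 ms epoch centred at the contraction midpoint:

- **Intensity** `I = log10( (1/N) Σ_ij HM_ij )` — log mean amplitude of the
  monopolar map (log scale because EMG amplitude grows nonlinearly with force).
- **Differential intensity** `DI` — the same log-mean amplitude on the
  single-differential map (adjacent electrodes along the fiber axis
  subtracted; 59 channels on the default grid).
- **Modified entropy** `E = −Σ_i q_i log2 q_i`, `q_i = HM_i² / Σ_k HM_k²` —
  maximal (`log2 N`) for spatially uniform activity, 0 when one channel
  carries everything.
- **CoV** `= 100 · SD(HM)/mean(HM)` — heterogeneity, opposite in sense to
  entropy.
- **Mean RMS** (mV) and **median frequency** (the frequency splitting the
  epoch's power spectrum into equal halves, averaged over channels).

## Centre of gravity

`CoG = Σ_ij HM_ij (i, j) / Σ_ij HM_ij`, in electrode-index units with *x*
along the 13-row fiber axis.  Two estimators:

- **point method** — the CoG of one reference map (the peak-intensity
  window for dynamic contractions, or the midpoint epoch);
- **trajectory method** — the CoG of every 250 ms window from the beginning
  to the end of the contraction, summarised per axis by mean, variance/SD
  and min–max range.

Their agreement is quantified by Pearson *r*/*r²* per axis and speed.

## Worked example

```python
from hdsemg import SimulationConfig, simulate_recording, ContractionAnalysis

cfg = SimulationConfig(seed=42, sigma_rows=2.0, sigma_cols=1.2,
                       center_path=((0.0, 6.5, 3.0),))
recording, truth = simulate_recording(cfg)   # 64-ch grid, 1024 Hz, torque at 100 Hz
results = ContractionAnalysis(recording).fit()
print(results.summary())
```

```
Contraction spatial analysis
============================================================
grid                 13x5 (64 electrodes, IED 8 mm)
speed / side         90 deg/s / -
segment              0.560-2.460 s (torque-threshold)
windows              7 x 0.25 s
------------------------------------------------------------
entropy                4.3795 bits
CoV                    100.88 %
intensity             -1.3436 log10-mV
diff. intensity       -1.1487 log10-mV
mean RMS               0.0453 mV
median frequency       206.19 Hz
------------------------------------------------------------
CoG (point, peak_intensity)  x=6.510  y=3.011
CoG (trajectory mean)      x=6.529  y=2.999
CoG trajectory var         x=0.0003  y=0.0001
CoG trajectory range       x=0.053  y=0.022
```

The simulated source is centred at row 6.5, column 3.0 with a fairly
localized envelope: both CoG estimators recover the configured centre to
about 0.03 electrode spacings, the localization shows up as entropy well
below the 59-channel ceiling of `log2 59 ≈ 5.88` bits together with a high
CoV, and the median frequency sits at the midpoint of the 20–400 Hz
synthesis band.  `results.plot_map()` / `results.plot_trajectory()` draw the
map and the CoG path.

Cohort-level work uses the same pattern: `SpeedComparison(feature_table).fit()`
(Shapiro–Wilk checks plus Bonferroni-corrected paired t-tests across speeds)
and `CoGMethodAgreement(table=cog_table).fit()`.

## Command line

```bash
hdsemg simulate --seed 3 --out trial/          # signal.tsv + sidecar.json + torque + ground truth
hdsemg features --signal trial/signal.tsv --sidecar trial/sidecar.json
hdsemg cog      --signal trial/signal.tsv --sidecar trial/sidecar.json --out cogdir/
hdsemg report   --config cohort.yaml --seed 1 --out report/
```

`report` writes TSV tables (per-trial features, CoG point + trajectory
summaries, method correlations, speed tests, normality checks), per-trial
map matrices and trajectories, and a `run_log.json` with every parameter
and seed; identical configs and seeds reproduce byte-identical tables.

Recordings interchange as a TSV signal matrix (samples × channels, header
of electrode ids) plus a JSON sidecar declaring sampling rate, unit
(V/mV/µV), grid geometry, channel map, mode and labels.

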