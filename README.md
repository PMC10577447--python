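# rfttag

Simulation and analysis tools for **rapid invisible frequency tagging
(RFT)** experiments recorded with MEG.

RFT modulates the luminance of a screen patch sinusoidally at frequencies
above the flicker-fusion threshold (> 60 Hz). The flicker is imperceptible,
but visual cortex phase-locks to it and produces a steady-state visual
evoked field (SSVEF) at the drive frequency. Because the drive is recorded
directly with a photodiode, the response is best quantified as the
trial-averaged magnitude-squared coherence between each MEG sensor *x(t)*
and the photodiode *y(t)*:

```
Coh_xy(f) = |C_xy(f)|^2 / (C_xx(f) · C_yy(f))
```

where `C_xy(f)` is the mean over trials of `X_k(f) · conj(Y_k(f))` for the
Hanning-tapered Fourier coefficients of trial *k*, and `C_xx`, `C_yy` are
the corresponding trial-averaged power spectra. Coherence lies in [0, 1];
1 means perfect phase alignment between brain signal and flicker.

The package is aimed at researchers planning or analysing frequency-tagging
experiments: it generates the stimulus-side objects (drive waveforms with
half-Hanning ramps, spatially tapered patches, session schedules), simulates
multi-sensor MEG with a fully known tagging response so every analysis stage
can be validated, and implements the estimation and inference chain —
coherence/power spectra, time–frequency maps, planar-gradiometer pair
combination, sensor-level cluster-based permutation tests with a Wilcoxon
signed-rank clustering statistic, a per-participant permutation criterion,
lateralization indices, and condition-slope summaries.

## Worked example

Simulate a frequency-sweep session (60–100 Hz in 4 Hz steps, the 100 Hz
line-frequency harmonic excluded from analysis) for six synthetic
participants and run the full analysis:

```python
from rfttag.pipeline import RunConfig, run_pipeline

cfg = RunConfig(session_type="FREQ", master_seed=7, out_dir="demo",
                n_participants=6, n_trials_per_condition=12,
                n_perm_cluster=500, n_perm_participant=500)
res = run_pipeline(cfg)
print(res["summary"][["freq_hz", "mean_coh_stim", "mean_coh_base",
                      "pct_participants_significant",
                      "n_significant_clusters", "min_cluster_p"]])
```

which prints:

```
 freq_hz  mean_coh_stim  mean_coh_base  pct_participants_significant  n_significant_clusters  min_cluster_p
  60.000          0.370          0.082                       100.000                       1          0.031
  64.000          0.331          0.077                       100.000                       1          0.031
  68.000          0.281          0.082                       100.000                       1          0.031
  72.000          0.237          0.097                       100.000                       1          0.031
  76.000          0.186          0.086                        66.667                       0          0.094
  80.000          0.137          0.078                        50.000                       0          0.594
  84.000          0.091          0.086                        16.667                       0          0.875
  88.000          0.078          0.089                         0.000                       0            NaN
  92.000          0.087          0.085                         0.000                       0            NaN
  96.000          0.083          0.092                         0.000                       0          0.562
```

`mean_coh_stim` is the grand-average coherence at the tagging frequency
over posterior combined gradiometers in the full-stimulation interval
(0–1 s); `mean_coh_base` the same quantity in the pre-stimulus baseline
(−1.2 to −0.2 s), which sits at the estimator's 1/N bias floor.
Coherence declines roughly linearly with drive frequency (here the fitted
slope is −0.035 per 4 Hz, SE 0.004) and reaches baseline near 88 Hz; the
percentage of participants passing the individual permutation criterion
drops from 100 % below 76 Hz to zero at 88 Hz, mirroring how detectability
falls off with tagging frequency. `min_cluster_p` is the smallest
cluster-permutation p-value of the stimulation-vs-baseline contrast (NaN
when no sensor survives the cluster-forming threshold).

The same entry point runs patch-size sweeps (`session_type="SIZE"`) and the
3 × 5 position grid (`"POSITION"`, adding lateralization indices to the
report). A command-line interface mirrors the stages:

```sh
rft simulate-drive --freq 60 --fs 1440 --train 1.4 --ramp 0.2 --out drive.tsv
rft run --config config.yaml
rft design-check            # 1/dT separation rule and intermodulation table
```

## Layout

| module | contents |
| --- | --- |
| `rfttag.stimulus` | drive waveforms, spatial tapers, session schedules |
| `rfttag.synthmeg` | sensor layouts, gain model, synthetic epoch simulation |
| `rfttag.spectral` | tapered DFT, coherence/power, pair combination, TFR |
| `rfttag.stats` | Wilcoxon, cluster permutation, participant permutation, LI, slopes |
| `rfttag.design` | tagging-frequency separation and intermodulation arithmetic |
| `rfttag.pipeline` | `RunConfig`, staged orchestration, bundled fixtures |
| `rfttag.cli` | the `rft` command |

See `docs/methods.md` for the modelling assumptions, parameter defaults,
and numerical conventions.
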