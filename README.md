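# fmgsampling

How slowly can upper-limb **force myography (FMG)** be sampled without losing
signal content? FMG straps register muscle activity as pressure changes under
an array of force-sensing resistors; wearable platforms would like to sample
them as slowly as power budgets allow. This package implements the complete
analysis that answers the question, for researchers and wearable-device
engineers working with multichannel FMG (or similar slow mechanophysiological
signals):

1. **Synthetic cohort** — a seeded generator emulating a 12-participant
   study: 7 rapid hand actions (3 isometric, 4 dynamic) x 3 trials x two
   8-channel straps (forearm, wrist) at 1 kHz for 5 s (504 labelled trials),
   with slow baseline drift, a harmonic voluntary-action train near the
   ~6.5 Hz maximum hand speed, motion artifacts for dynamic actions, strap
   bias, and a white noise floor.
2. **Normalization** — `x' = (x − min)/(max − min)` over a configurable scope
   (default: all trials and channels of one participant's one strap).
3. **Reconstruction error** — plain decimation at integer steps 2–1000
   (500 Hz down to 1 Hz equivalent), reconstruction on the original grid by
   `linear` / `cubic` (PCHIP) / `spline` (not-a-knot) interpolation, and the
   pooled mean RMSE

   &nbsp;&nbsp;&nbsp;&nbsp;avg RMSE = √( Σⱼ Σᵢ (xᵢⱼ − x′ᵢⱼ)² / (n·m) )

   over n samples and m = 8 channels, summarized as 5/25/50/75/95th
   percentile curves per category (action type x placement).
4. **Bandwidth** — one-sided periodogram (and Burg/Yule-Walker AR spectra) on
   the 0.2–500 Hz grid with DC excluded, bin-wise maximum across channels,
   95th-percentile curve across a category's trials, band upper edge at the
   highest frequency still reaching 1% of the curve's maximum, and the
   **Nyquist minimum sampling rate** = round(2 x upper edge).
5. **Factor analysis** — RMSE values at 10–100 Hz resampling binned into nine
   10 Hz groups, N-way fixed-effects ANOVA (frequency group, action type,
   placement, participant, interpolation + interpolation interactions, Type
   II tests), and Tukey HSD comparisons across frequency groups.

## Worked example

```python
from fmgsampling import SyntheticConfig
from fmgsampling.pipeline import RunConfig, run_pipeline

cfg = RunConfig(
    synthetic=SyntheticConfig(seed=1, n_participants=4, n_trials=2),
    steps=(10, 20, 40, 100, 200),
)
report = run_pipeline(cfg)
for label, s in report.categories.items():
    print(label, s)
print(report.anova[["F", "p"]].round(4).head(5))
```

prints

```
isometric_forearm {'upper_bound_hz': 6.0, 'min_sampling_hz': 12, 'max_power_freq': 0.2, 'rmse_p95_at_100hz': 0.000559, 'n_trials': 24}
dynamic_forearm  {'upper_bound_hz': 6.4, 'min_sampling_hz': 13, 'max_power_freq': 0.2, 'rmse_p95_at_100hz': 0.000738, 'n_trials': 32}
isometric_wrist  {'upper_bound_hz': 5.8, 'min_sampling_hz': 12, 'max_power_freq': 0.2, 'rmse_p95_at_100hz': 0.000588, 'n_trials': 24}
dynamic_wrist    {'upper_bound_hz': 6.4, 'min_sampling_hz': 13, 'max_power_freq': 0.2, 'rmse_p95_at_100hz': 0.000801, 'n_trials': 32}
                         F       p
C(freq_group)   14595.9958  0.0000
C(action_type)    585.2114  0.0000
C(participant)      6.0951  0.0004
C(placement)       12.2519  0.0005
C(method)          18.4932  0.0000
```

Reading the output: every category's power spectrum peaks at the lowest
resolved bin (0.2 Hz, slow baseline variation); the 1%-of-max band edge of
the 95th-percentile spectrum sits just above the voluntary-action rate, and
is strictly higher for dynamic actions (motion artifacts) than isometric
ones; doubling it gives the per-category minimum sampling rate; and at a
100 Hz resampling rate the 95th-percentile reconstruction error is below
0.001 of the normalized range in all categories. The ANOVA attributes by far
the most error variance to the resampling-frequency group. See
`docs/methods.md` for the signal model, calibration constraints, and what
the synthetic cohort does and does not emulate.

The same stages are available as a CLI:

```bash
fmg simulate --out trials/ --seed 1
fmg sweep --in trials/ --steps 10:100 --out rmse.csv
fmg anova --rmse rmse.csv --out stats/
fmg run --seed 1 --out results/        # full pipeline
```

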