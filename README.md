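# pulserel

Benchmark-free reliability assessment for wearable cardiac biometrics.

Wrist-worn PPG sensors stream heart rate (BPM) and heart rate variability
(rMSSD, ms) through daily life, where no ECG reference is available. Validity
against a benchmark cannot be checked there — but *reliability* can, from the
sensor's own data. `pulserel` implements a two-sided reliability framework
for such streams, for researchers running ambulatory studies with wearables
and ecological momentary assessment (EMA):

- **Between-person reliability** — does the measurement distinguish people?
  Modelling a sample as `x_ij = mu + r_i + v_ij` with participant effects
  `r_i ~ N(0, sigma_r^2)` and noise `v_ij ~ N(0, sigma_v^2)`, the population
  reliability is `rho = sigma_r^2 / (sigma_r^2 + sigma_v^2)`, estimated by
  the one-way random-effects single-measure intraclass correlation

  ```
  ICC(1,1) = (MSBS - MSWS) / (MSBS + (k - 1) MSWS)
  ```

  with Shrout–Fleiss F-based 95% confidence intervals, a one-sided F test of
  ICC = 0, Searle's effective k0 for unbalanced designs, and qualitative
  labels (>= 0.75 excellent, 0.40–0.75 good, 0.25–0.40 fair, < 0.25 poor).

- **Within-person reliability** — does the measurement agree with itself in
  the same state? Each analysis unit's samples (e.g. one participant-night)
  are split into halves, either *time-sensitively* (odd/even by acquisition
  order, pairing samples as close in time as possible) or *randomly*,
  repeated 1000 times. A linear mixed model `half_y ~ a + beta * half_x +
  (1|participant) [+ (1|situation)]` fitted by REML with Satterthwaite
  degrees of freedom yields the reliability slope *beta*; the mean beta over
  random splits is the resampling estimate.

Around these sit the supporting stages of an ambulatory study pipeline:
artifact filtering (drop zero-valued samples, then values beyond 2 SD of the
participant's mean), sleep segmentation from BPM sampling density (runs of
>= 2 h with gaps <= 15 min, longest run per noon-to-noon study day),
study exclusion rules, EMA affect scoring, and six lagged mixed models
linking daily affect to sleep/wake biometrics with Bonferroni correction
(m = 6). A variance-components simulator generates ground-truth streams —
5-minute sampling grid, dense nightly sleep window, thinned wakeful
sampling, zero artifacts and spikes — so the whole pipeline is testable
offline.

## Worked example

```python
from pulserel import (SimulationConfig, decompose_oneway, icc_single,
                      classify_icc)
from pulserel.synthetic import simulate_components

cfg = SimulationConfig(mu=70, sigma_r=1, sigma_s=0, sigma_v=1,
                       n_participants=60, n_situations=6, k_replicates=1,
                       seed=7)                      # population rho = 0.5
res = icc_single(decompose_oneway(simulate_components(cfg).replicates()))
print(f"{res.estimate:.3f} [{res.ci_low:.3f} {res.ci_high:.3f}]",
      classify_icc(res.estimate))
```

prints

```
0.502 [0.392 0.620] good
```

— the estimate recovers the population reliability of 0.5 implied by equal
participant and noise variances, the 95% CI covers it, and 0.502 falls in
the "good" band. The split-half side (examples/03) on a simulated HRV week
with wakeful noise far above sleep noise prints

```
sleep time-sensitive: beta = 1.000, t(9.9) = 64.21, p = 2.4e-14 (70 units)
sleep random x300   : mean beta = 0.988, SD = 0.017
wake  time-sensitive: beta = 0.418, t(41.2) = 4.28, p = 0.00011 (70 units)
wake  random x300   : mean beta = 0.320, SD = 0.133
```

— nightly HRV agrees with itself almost perfectly while wakeful HRV is
mostly noise, the ordering this framework is designed to expose.

The `examples/` directory walks through each capability: ICC estimation,
sleep segmentation, split-half reliability, EMA associations, and the full
report pipeline. A thin CLI mirrors the pipeline stages:

```
pulserel simulate --out samples.csv --ema-out ema.csv --seed 3
pulserel clean samples.csv --out clean.csv
pulserel segment clean.csv --out intervals.tsv
pulserel icc clean.csv --metric bpm --condition-key day
pulserel splithalf clean.csv --metric bpm --method random
pulserel report --samples clean.csv --ema ema.csv --out-dir report/
```

Report tables mirror the standard layouts: between-person rows of
(label, ICC(1,1), 95% CI, N) and within-person rows of (label, mean beta,
SD of beta across iterations). Identical config and seed reproduce
byte-identical tables.

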