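# calyxatp

Presynaptic ATP bioenergetics and EPSC train analysis for sustained
high-frequency transmission at the calyx of Held.

## The problem

The calyx of Held, a giant glutamatergic terminal in the auditory
brainstem, sustains transmission at 100 Hz and above for minutes. When
mitochondrial ATP production (oxidative phosphorylation, OxPhos) is
blocked in mature terminals, transmission failures appear only after tens
of seconds of sustained stimulation and worsen across repeated trains —
evidence of a large ATP reserve that is progressively exhausted. This
package implements, for electrophysiologists and modelers:

- a kinetic model linking relative presynaptic ATP to the
  transmission-failure rate, and its estimation from failure-rate time
  courses;
- the standard train metrics for depressing synapses (depression and
  recovery time constants, paired-pulse ratio, steady-state depression,
  readily-releasable-pool charge, time to failure, spontaneous events);
- a seeded synthetic-data generator emulating the stimulation protocols
  and the stochastic failure process, so the whole pipeline is testable
  without recordings.

## The model

Relative ATP (basal level ≡ 1) obeys

    d[ATP]/dt = γ_b − γ_b·[ATP] − γ_i(t)·[ATP]

with basal consumption rate γ_b and activity-dependent consumption γ_i
during the *i*-th sustained train. For a constant rate γ₁ (first train)
the solution is monoexponential decay from 1 to the steady state
1/(1 + γ₁/γ_b). The probability that a stimulus fails is a Hill function
of the instantaneous ATP level,

    Failure(%) = 100 / (1 + ([ATP]/K)^h),

with half-failure level K and cooperativity h. Later trains start from a
depleted ATP level and their demand grows during the train,
γ_i(t) = γ₁ + (γ_iᵐᵃˣ − γ₁)·t^h_i/(K_i^h_i + t^h_i). Parameters are
estimated by bounded multi-start nonlinear least squares, sequentially:
the first train fixes (γ_b, γ₁, h, K); each later train contributes its
onset ATP and consumption schedule. See `docs/methods.md` for assumptions,
defaults and identifiability caveats.

## Worked example

```python
import numpy as np
from calyxatp import (FailureRateSeries, FitConfig, fit_first_train,
                      predict_series, printed_base_params)

base = printed_base_params()          # γ_b=0.0065, γ₁=0.11, h=6, K=4.6%
t = np.arange(0.5, 150.0, 1.0)        # 1-s bins over a 150-s train
series = FailureRateSeries(1, t, predict_series(t, base))
fit = fit_first_train(series, FitConfig(n_starts=10, seed=17))
print({k: round(v, 4) for k, v in fit.params.items()})
print("fold increase:", round(fit.params["gamma_1"] / fit.params["gamma_b"], 1))
```

prints

```
{'gamma_b': 0.0065, 'gamma_1': 0.11, 'h': 6.0, 'K_rel': 0.046}
fold increase: 16.9
```

i.e. refitting the model's own noise-free first-train failure curve
returns the generating parameters: a ~17-fold rise in ATP consumption
from rest to stimulation, cooperativity h = 6, and a 50 % failure rate
once ATP falls to 4.6 % of basal.

The numbered drivers under `analysis/` run the full study pipeline:
`01_simulate_cohorts.py` (control and OxPhos-blocked cohorts, three
100 Hz × 150 s trains), `02_train_metrics.py` (burst and recovery
metrics), `03_fit_energy_model.py` (simulate → analyze → subtract → fit at
study scale), `04_refit_reported_model.py` (noise-free self-consistency
refit). Each writes its tables under `results/`.

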