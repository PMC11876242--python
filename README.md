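# enzkin

Enzyme-kinetics analysis for constant-voltage GFET (graphene field-effect
transistor) biosensors.

Heme peroxidases such as horseradish peroxidase (HRP) — and the bare heme
cofactor acting as a minimal peroxidase mimic — oxidize a cosubstrate (ABTS,
ascorbic acid) using H2O2, and are themselves progressively destroyed by
their substrate through the compound III pathway ("suicide inactivation").
A GFET operated at fixed gate and drain voltages transduces the oxidized
product into a drain–source current, giving real-time, label-free progress
curves. This package provides the full analysis chain for such measurements,
plus a synthetic study generator so every stage is testable without a
device:

1. **kinetics** — the Michaelis–Menten (MM) ODE system
   `E + S ⇌ C → E + P` (with `K_M = (k2 + k_cat)/k1`,
   `V_max = k_cat·E_total`), the peroxidase catalytic network with
   compound I/II/III intermediates and irreversible bleaching, and
   initial-rate extraction from progress curves.
2. **gfet_signal** — calibration curves (`|ΔI_ds|` vs product
   concentration), automatic linear-range detection, and the bidirectional
   current ↔ concentration mapping with seeded noise.
3. **synthetic_data** — a ~100-condition study over enzyme ∈ {HRP, heme},
   pH ∈ {4, 7}, 18–25 °C and substrate 25–1000 μM, generated from a smooth
   ground-truth parameter law, reproducible from one master seed.
4. **inference** — Bayesian inversion of (K_M, k_cat) from rate-vs-substrate
   data: v ~ N(V_max·S/(K_M+S), σ), log-uniform priors, adaptive
   random-walk Metropolis in log space, split-R̂ diagnostics.
5. **surrogate** — an MLP (ReLU hidden layers, logistic range-bounded
   output, Adam) trained on the inversion posteriors, predicting (K_M,
   k_cat) for unseen conditions, with per-epoch RMSE tracking and an 80/20
   enzyme-stratified split.
6. **pipeline / CLI** — one seeded, manifest-hashed run tying the stages
   together: `enzkin simulate | calibrate | rates | invert | train |
   predict | run`.

See `docs/methods.md` for the models, assumptions and defaults.

## Worked example

Infer MM parameters from a 7-point rate series (true values: K_M = 100 μM,
k_cat = 10 /s, E_total = 0.02 μM, 5% multiplicative noise):

```python
import numpy as np
from enzkin.kinetics import mm_rate
from enzkin.inference import RateDataset, PriorSpec, run_mcmc, summarize_posterior

rng = np.random.default_rng(0)
S = np.array([25., 50., 100., 250., 500., 750., 1000.])          # μM
v = mm_rate(S, V_max=10.0 * 0.02, K_M=100.0) * (1 + 0.05 * rng.standard_normal(7))
data = RateDataset(S=S, v_obs=np.maximum(v, 0), E_total=0.02)

post = run_mcmc(data, PriorSpec(noise_scale=float(v.mean())),
                n_chains=4, n_steps=20_000, seed=1)
print(summarize_posterior(post).to_string(index=False))
```

```
parameter     median       mean        sd       q05        q95     rhat
      K_M 104.809135 106.525558 18.801050 84.382703 130.778603 1.004266
    k_cat  10.286484  10.306183  0.432850  9.732599  10.912010 1.004239
 noise_sd   0.006143   0.007113  0.003763  0.003619   0.013950 1.004550
```

The posterior medians land within ~5% of the true K_M and ~3% of the true
k_cat; the 90% credible intervals ([84, 131] μM and [9.7, 10.9] /s) cover
both, and R̂ ≈ 1.00 indicates the four chains agree. `noise_sd` is the
inferred measurement noise on the rates (μM/s).

The same from the shell, end to end:

```sh
enzkin run --seed 7          # simulate → calibrate → rates → invert → train
enzkin predict enzkin_run/surrogate.json \
    --enzyme HRP --ph 7 --temperature 22 --conc 100
```

The run directory contains the condition table, traces, extracted rates,
posterior medians, the trained surrogate, per-condition
(truth, posterior, surrogate) triplets and a SHA-256 manifest; rerunning
with the same seed reproduces every file byte-for-byte.

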