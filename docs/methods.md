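# Methods

This note documents the models, algorithms, defaults and design choices in
`enzkin`, in the spirit of a methods section: what each stage assumes, which
knobs matter, and what the synthetic study can and cannot demonstrate.

## Kinetic models

**Michaelis–Menten (MM) mechanism.** The four-species system

```
E + S  <->(k1, k2)  C  ->(k_cat)  E + P
```

is integrated without the quasi-steady-state (QSS) approximation:

```
dS/dt = -k1·E·S + k2·C          dC/dt =  k1·E·S - (k2 + k_cat)·C
dE/dt = -k1·E·S + (k2 + k_cat)·C   dP/dt = k_cat·C
```

with `K_M = (k2 + k_cat)/k1` and `V_max = k_cat·E_total` always derived,
never stored. Units are fixed package-wide: concentrations in μM, time in
seconds, rates in μM/s; any unit conversion happens at I/O boundaries.
The closed-form rate `v = V_max·S/(K_M + S)` is exact only in the QSS
regime; the package treats agreement between the ODE initial rate and the
closed form (≤1% relative when `E_total ≤ 0.01·S0` and binding is fast,
`k1·S0 ≥ 100·k_cat`) as a correctness check on both implementations.

**Peroxidase catalytic network.** The heme-peroxidase cycle is modelled with
mass-action kinetics over the species E, compound I, compound II,
compound III, inactive enzyme, H2O2, reducing cosubstrate AH2 (ascorbic acid
or reduced ABTS) and oxidized product:

| pathway | reaction | rate constant | default |
|---|---|---|---|
| 1 | E + H2O2 → CpdI | `k_p1` | 1e-2 /(μM·s) |
| 1b | CpdI + H2O2 → CpdII | `k_p1b` | 1e-4 /(μM·s) |
| 2 | CpdI + AH2 → CpdII + Prod | `k_p2` | 5e-2 /(μM·s) |
| 3 | CpdII + AH2 → E + Prod | `k_p3` | 2e-2 /(μM·s) |
| 5 | CpdII + H2O2 → CpdIII | `k_p5` | 5e-4 /(μM·s) |
| 6 | CpdIII → E_inactive | `k_p6` | 5e-2 /s |
| 4 | CpdIII → E (optional recovery) | `k_p4` | 0 |

Pathway 1b — the catalase-like reduction of compound I by peroxide itself —
is required for the experimentally observed zero-cosubstrate behaviour:
without it, compound II (and hence compound III and bleaching) could never
form when AH2 = 0, yet bleaching in the *absence* of reducing substrate is
precisely the suicide-inactivation phenomenon of interest. Its default is
small (two orders below `k_p1`), so with cosubstrate present the normal
cycle dominates. The shunt rate `k_p5` is chosen so that a sufficient
cosubstrate pool wins the competition for compound II (per-pass shunt
probability of a few percent); this reproduces the ordering seen in
insufficient (75 μM) vs sufficient (500 μM) cosubstrate experiments at
50 μM H2O2. All rate constants are literature-plausible magnitudes, i.e.
synthetic ground truth, not fitted values.

**Numerics.** LSODA with `rtol = 1e-8`, `atol = 1e-10`; the tight tolerances
exist so that conservation checks (enzyme total, substrate mass balance) are
meaningful at 10× solver tolerance. Solver round-off can produce tiny
negative concentrations; these are clamped to zero on output only, never
inside the right-hand side. Trajectories are bit-reproducible: the module
contains no randomness.

**Initial rates.** `initial_rate_series` fits a least-squares slope to the
earliest contiguous points with less than `fraction` substrate conversion.
The window is located on a 5-point moving average (so one noisy sample
cannot truncate it) but the slope uses raw points. `fraction = 0.05` is the
accuracy-first default for clean simulated curves (depletion bias ≈2% at the
lowest substrate of the default series); the pipeline uses `fraction = 0.1`
for measured/noisy traces, accepting ≤4% bias at 25 μM substrate in exchange
for half the slope variance.

## GFET signal model

The transducer operates at constant gate and drain voltages; the oxidized
product (e.g. the ABTS radical cation) shifts the drain–source current. The
calibration model is an affine map `|ΔI| = slope·c + intercept` valid over a
detected linear range.

- **Linear-range detection** searches contiguous *prefix* windows anchored
  at the lowest concentration (amperometric calibration curves are linear
  from the bottom and saturate at the top) and reports the longest window
  whose ordinary-least-squares fit reaches the requested r² (default 0.99)
  with ≥3 points.
- **Forward model** (trace synthesis): `I(t) = baseline + slope·sat(c(t)) +
  intercept + N(0, noise_sd²)`, where `sat` is the identity inside the
  linear range and a smooth rational plateau `high + x/(1 + x/w)` above it
  (continuous, unit slope at the breakpoint, bounded) — the exact plateau
  shape of a saturated transducer is not specified by theory, only its
  qualitative form. The seed is mandatory; identical seeds give identical
  traces.
- **Inversion**: `c(t) = (|ΔI(t)| − intercept)/slope` with the baseline
  defined as the first sample of the trace (real measurements return to
  baseline after washing, making a per-trace reference natural). The
  magnitude is applied trace-wise — the dominant sign of the whole
  excursion — because the shift direction is a property of the operating
  point (graphene's ambipolar conduction), and folding each noisy sample
  individually would bias near-baseline values upward. The unclamped series
  is exposed alongside the zero-clamped one so regression can use unbiased
  noise. Values above the linear range are flagged, never dropped.

## Synthetic study generator

The generator emulates a two-enzyme constant-voltage study: HRP and free
heme (a minimal peroxidase mimic), pH ∈ {4, 7}, temperatures 18–25 °C, and
the substrate series 25, 50, 100, 250, 500, 750, 1000 μM. The default grid
is the ABTS series at three temperatures (18, 22, 25 °C) for each enzyme ×
pH combination, plus one H2O2-varied series per enzyme at its optimal pH and
22 °C — 98 conditions, matching the ~100-case scale of such studies. The
cosubstrate is held at 2.5 mM (large excess) in MM-mode generation so
single-substrate kinetics applies.

The ground-truth law mapping conditions to parameters is a modelling device
(no functional law is measurable from two pH points and a narrow temperature
window): Arrhenius-like in temperature, Gaussian in pH for `k_cat`,
log-linear in pH for `K_M`:

```
k_cat = kcat_ref · exp(Ea_like·(T − 22)) · exp(−((pH − pH_opt)/pH_width)²)
K_M   = K_M_ref · exp(K_M_pH_slope·(pH − pH_opt))
```

with pH_opt = 7 for HRP and 4 for heme (their measured activity optima) and
reference magnitudes `kcat_ref` 50 /s (HRP) and 5 /s (heme), `K_M_ref` 150
and 400 μM. Current noise is Gaussian with standard deviation equal to 5%
of each trace's full-scale response — amperometric noise scales with signal,
and a single absolute noise level would drown the low-activity assays the
design deliberately includes. Per-condition seeds derive from the master
seed and the condition index through `numpy.random.SeedSequence`, so the
study is a pure function of its inputs and regenerates bit-identically in
any order.

**What the generator does not emulate:** Dirac-point sweeps and transfer
characteristics, drift and washing artifacts, electrode fouling,
direct-electron-transfer doping, pipetting error in the substrate series,
or replicate-to-replicate device variability. Tests passing on this
generator therefore demonstrate the correctness of the analysis chain under
its stated noise model, not robustness to every artifact of real devices.

## Bayesian inversion

The observable is the initial rate at each substrate level of a series; the
likelihood is `v_obs ~ N(mm_rate(S; k_cat·E_total, K_M), noise_sd)` with
`noise_sd` inferred jointly (measurement noise is never known a priori).
Default priors are deliberately uninformative: log-uniform `K_M` over
[1, 10⁴] μM and `k_cat` over [10⁻², 10³] /s — spanning reported peroxidase
ranges — and a half-normal prior on `noise_sd` whose scale the pipeline ties
to the mean observed rate of the series, so assays spanning decades of
activity are treated alike. All prior families and bounds are
config-overridable.

The sampler is adaptive random-walk Metropolis in log-parameter space:
during burn-in (default half the chain) a global scale targets a 0.2–0.5
acceptance rate and a per-component shape adapts to the recent draw spreads;
after burn-in the proposal is frozen, so the kept samples come from a valid
Metropolis chain. Chains (≥2, default 4 × 20 000 steps; the pipeline uses a
reduced 2 × 4 000 budget that the recovery experiments show is sufficient
for median estimates) start from a jittered method-of-moments estimate when
data are present, and from prior draws otherwise. Convergence is summarized
by split-R̂ per parameter; R̂ > 1.2 or a frozen chain produces a warning and
`converged=False`, never an exception. A likelihood-free mode (`data=None`)
exists purely to verify that the sampler reproduces its prior.

Inversion runs per assay series — a single (S, v) point cannot identify two
parameters — and every condition in a series carries that series' posterior.

## MLP surrogate

A fully connected regressor maps condition features (enzyme one-hot, pH,
temperature, substrate one-hot, substrate concentration) to log K_M and
log k_cat, with labels taken from the posterior medians of the per-series
inversions. Hidden layers (default 2 × 64) use the rectifier; the output
layer is a logistic squashed onto per-parameter [low, high] log ranges, so a
prediction can never leave the declared range — by default the envelope of
the training labels with half a label-span of margin (at least one log
unit), which keeps the logistic well-resolved; fixed envelopes can be
configured instead. Inputs are standardized by training-set mean and
standard deviation.

Training minimizes mean-squared error in the bounded log space with the
adaptive-moment (Adam) optimizer, full-batch by default, with a geometric
learning-rate decay (5e-3 down to 10% over the run) and mild decoupled
weight decay (1e-4). The decay is what makes the 10-epoch moving average of
the training RMSE non-increasing late in training — a property the test
suite checks. The 80/20 train/test split is stratified by enzyme (the two
enzymes occupy different kinetic regimes) and both the split seed and the
initialization seed are explicit, so a configuration reproduces its RMSE
history exactly. The forward pass, gradients and optimizer are explicit
numpy, which lets the model serialize losslessly to JSON.

Note that labels are constant within an assay series while the substrate
concentration feature varies; the concentration feature is deliberately kept
(the condition table is the interface a practitioner has), and the network
learns its irrelevance to the labels.

## Pipeline and reproducibility

`run_pipeline` executes simulate → calibrate → rates → invert → train →
diagnostics, writing CSV/JSON artifacts plus a manifest with a SHA-256 hash
per file. A single master seed fans out to per-stage seeds via labeled
`SeedSequence` derivation (`stage_seed(master, "simulate")`, …), so one
integer reproduces the entire study byte-for-byte. The diagnostics stage
emits, for every condition, the (ground truth, posterior median, surrogate
prediction) triplet for both parameters.

## Problem sizes

Default experiment scales were chosen to keep a full desk run in minutes:
98 conditions × 121 time points per trace (60 s at ≈2 Hz), per-series
inversions at 2 chains × 4 000 steps in the pipeline, 800 training epochs
for the surrogate, and 50-replicate recovery experiments for sampler
validation. All are configuration values, not constants.

## Known limitations

- The initial-rate likelihood discards progress-curve shape information; a
  progress-curve likelihood is a natural extension point.
- The surrogate interpolates within the condition grid; extrapolation
  beyond the trained pH/temperature window is range-bounded but untested.
- The peroxidase network omits spectroscopic observables, compound-I radical
  chemistry and Fe(III)-release electrochemistry; `E_inact` is a terminal
  bookkeeping species.
- Credible-interval calibration is verified at the study's noise level (5%);
  strongly heteroscedastic or non-Gaussian noise would require a different
  likelihood.
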