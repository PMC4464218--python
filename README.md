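# noisecascade

Cell-to-cell variability distorts what population-averaged measurements
say about gene circuits. `noisecascade` is an in-silico framework for
quantifying that distortion in interconnected transcriptional modules: it
simulates single-cell steady-state outputs of Hill-modelled cascades
under multiplicative lognormal noise, identifies module and whole-network
transfer functions from the population averages (the quantity a plate
reader reports), and measures how the identified parameters spread across
noise conditions and deviate from the generating ("true") values.

It is aimed at synthetic and systems biologists who characterize genetic
parts (inducible devices, NOT/YES gates) via central-tendency
measurements and re-use them to predict composite circuits — and who need
to know how much of an apparent "unpredictability" can be explained by
noise alone.

## Model

Each module's steady-state transfer function is a four-parameter Hill
equation, in relative promoter units (RPU):

- activating: `y = δ + α / (1 + (k/x)^η)` (output `δ` at `x = 0`)
- repressing: `y = δ + α / (1 + (x/k)^η)`

where `δ` is the basal rate, `δ + α` the maximum, `k` the half-effect
input and `η` the Hill coefficient. A cascade feeds each stage's output
to the next; stage 1 is driven by the inducer 3OC6-HSL (nM).

Cell-to-cell variability multiplies a stage's deterministic output `y`
by a lognormal factor `v = exp(g)`, `g ~ N(0, σ²)`, under one of two laws:

- constant-CV: `σ² = ln(1 + CV²)`, the same at every induction;
- constant-VAR: `σ² = ln(1 + VAR/y²)`, induction-dependent.

Since `E[v] = exp(σ²/2)`, the deterministic value is rescaled by
`exp(−σ²/2)` ("mean correction") so different noise entities share
identical population-averaged curves. Shared (extrinsic) noise between
two sites is modelled by correlating their Gaussian log-components with
coefficient `ρ ∈ [0, 1]`.

Identification fits Hill functions to per-induction population averages
by bounded nonlinear least squares; a whole network is also fitted as a
black-box Hill function `OUTPUT₃ = δ* + α*/(1 + (k*/HSL)^η*)`. Study
drivers summarize estimates by their sample CV across noise conditions
and their maximum percentage difference from the generating parameters.

## Worked example

Characterize the TetR/Ptet NOT gate through a two-module network whose
input device carries constant-CV lognormal noise (CV = 0.15, 0.55, 0.75;
10,000 cells per induction):

```python
import noisecascade as nc
from noisecascade.experiments import StudyConfig
from noisecascade.population_sim import SimulationConfig

params = nc.builtin_params()
cfg = StudyConfig(
    gate=params["tetr_ptet"], noise_model="constant_cv",
    entities=(0.15, 0.55, 0.75), sim=SimulationConfig(master_seed=1),
)
fits, summary = nc.characterize_module(cfg)
print(summary.estimates[["entity", "alpha", "delta", "k", "eta"]].round(3).to_string(index=False))
print("CV across entities (%):", {p: round(v, 1) for p, v in summary.headline_cv.items()})
print("max % diff vs truth:  ", {p: round(v, 1) for p, v in summary.headline_max_diff.items()})
```

prints

```
 entity  alpha  delta     k   eta
   0.15  3.004  0.049 0.202 1.961
   0.55  3.049  0.034 0.226 1.631
   0.75  3.069  0.024 0.247 1.482
CV across entities (%): {'alpha': 1.1, 'k': 10.0, 'eta': 14.5}
max % diff vs truth:   {'alpha': 2.3, 'k': 23.6, 'eta': 25.9}
```

Read: the estimates barely move across noise entities (CV of η ≈ 14%),
so population averages characterize the gate *reproducibly* — yet they
drift systematically from the generating values (η estimated up to 26%
below its true 2.0, k up to 24% above its true 0.2 RPU), because
averaging a noisy input through a nonlinear gate biases the curve.
Recovering the true parameters would require knowing the noise.

The same drivers run from the shell:

```bash
noisecascade characterize --out results --seed 1
noisecascade reproduce-all --out results --seed 1   # all built-in studies
```

`reproduce-all` writes the module-characterization tables, the
sensitivity and extrinsic-noise scans, the black-box prediction,
reference and simulation tables, the 81-way comparison table, and a JSON
manifest with a sha256 checksum per file; identical seed gives
byte-identical CSVs.

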