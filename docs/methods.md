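# Methods

## Scope and model

`noisecascade` studies steady-state transcriptional cascades: an
inducible input device (LuxR/Plux, driven by 3OC6-HSL) feeding one or
two downstream gates (TetR/Ptet or LacI/Plac NOT gates, or a mock YES
gate). Every module is a four-parameter Hill function of its input —
basal rate δ (RPU), span α (RPU), half-effect input k (nM for the input
device, RPU downstream), Hill coefficient η. The activating form is
defined to take the value δ at zero input (the continuous limit of
`δ + α/(1 + (k/x)^η)`), so basal activity is well defined without a
special case in callers. Composition is purely serial: the per-cell
synthesis rate of stage i is the Hill function of that same cell's
stage-(i−1) output, i.e. cells are tracked, never re-sampled, which is
what makes inter-site noise correlation meaningful.

There is no dynamics: no ODEs, no Gillespie-style mechanistic
simulation. Noise enters only as a multiplicative lognormal factor on a
stage's steady-state output, which is the empirically motivated
description of fluorescence distributions in clonal bacterial
populations. No detection floor is applied to outputs.

## Noise laws and mean correction

A noisy stage multiplies its deterministic output y by `v = exp(g)`,
`g ~ N(0, σ²)`, i.i.d. across cells and inductions. Two laws fix σ²:

- **constant-CV** — the coefficient of variation of the noisy output is
  the same everywhere: `σ² = ln(1 + CV²)`. Default entities 0.15, 0.55,
  0.75, the realistic range for bacterial cell-to-cell variability.
- **constant-VAR** — the absolute variance is the same everywhere:
  `σ² = ln(1 + VAR/y²)`, so relative noise is enormous at basal output
  (VAR = 0.05 at y = 0.05 RPU gives σ² = ln 21). Default entities 0.05,
  0.10, 0.15 RPU².

Because `E[v] = exp(σ²/2) > 1`, the deterministic value is rescaled by
`exp(−σ²/2)` before noise is applied ("mean correction", on by default
at every site), so the population mean equals the deterministic transfer
curve exactly and different noise entities present identical averaged
inputs to downstream modules — the construction that isolates the effect
of noise *shape* from a shift of the mean.

When constant-VAR noise sits on a stage whose own deterministic value
varies from cell to cell (because its input is already noisy), σ² is
computed per cell from that cell's deterministic output. This keeps the
per-cell variance contract; the alternative (a single σ² from the
population-level curve) is equally defensible but breaks the "constant
variance" reading at the cell level. This is an interpretation, not a
rule the reference studies pin down, since those apply constant-VAR
noise only where the interpretation coincides with the obvious one or in
comparisons robust to it.

Extrinsic noise: when two sites are noisy, their standard-normal
log-components are drawn with correlation ρ (ρ = 0 purely intrinsic,
ρ = 1 purely extrinsic). ρ is defined on the Gaussian log scale; the
lognormal-scale Pearson correlation is slightly smaller, which is
documented rather than compensated. With per-cell σ² on the second site
the pairwise log-correlation of the standardized components is still ρ.

## Simulation and seeds

Populations are 10,000 cells per induction (the study scale throughout;
structural tests use smaller populations). The default induction grid is
{0} ∪ 14 log-spaced points over 0.1–10⁵ nM, spanning the input device's
k = 700 nM with more than three decades on each side so both plateaus
are observed; black-box (end-to-end) fits use a dense 102-point version
of the same span, since the fitted η* of a composed cascade — which is
not exactly Hill-shaped — depends mildly on grid density (it saturates
near 1.70 on this span). All grids are configurable and every driver
records its own.

Randomness flows from one master seed per study; child seeds for each
(noise entity, site, induction) cell are derived deterministically via
`numpy` seed sequences, so any single induction can be re-simulated in
isolation and full runs are byte-reproducible.

The "95% intervals" reported with population summaries are the
2.5th–97.5th percentiles of the single-cell distribution — cell-to-cell
spread, not standard error of the mean.

## Identification

Transfer functions are fitted to per-induction population averages by
`scipy.optimize.least_squares` (trust-region reflective) on **linear**
scale residuals with all four parameters bounded below by zero. Linear
weighting reflects what a plate-reader fit does and deliberately
down-weights the basal region; δ is therefore reported but unstable, and
is excluded from headline spread statistics. Initialisation is
heuristic — δ₀ = min(y), α₀ = range(y), k₀ = x at mid-response, η₀ = 1 —
with three multi-starts (k and η jittered ×3 and ÷3), best residual
wins, ties to the first start; fits are deterministic given (x, y,
init). Non-convergence and flat data are flagged on the result rather
than raised, so one failed condition marks itself, not the whole study.
No confidence intervals are computed: the object of study is the spread
of point estimates across noise conditions, mirroring how the
characterization experiments it emulates are analysed.

## Study statistics

- **CV across estimates**: sample standard deviation (n−1 denominator)
  over mean, ×100. The n−1 convention is frozen by a regression test
  (the triplet {3.00, 3.04, 3.06} gives 1.0% only with ddof = 1).
- **Maximum percentage difference**: max |estimate − reference| /
  reference × 100, the reference being the generating value in module
  studies and the noiseless black-box fit in prediction studies.
- **Cross-comparison**: the 9 predicted black-box parameter sets versus
  the 9 simulated ones, all 81 ordered pairs, deviation normalised by
  the **predicted** value (the convention is fixed by reproducing the
  printed headline deviation from printed table cells; the
  simulated-denominator reading gives a very different number).

The three-module simulation study applies constant-CV noise to OUTPUT₁
and OUTPUT₂ independently (ρ = 0) with mean correction at both sites;
the extrinsic-noise sweep couples the two sites with ρ ∈ {0, 0.25, 0.5,
0.75, 1} and compares against the nominal generating parameters (with
corrected noise, no truth rescaling is needed; for constant-CV noise the
uncorrected-noise-plus-rescaled-truth bookkeeping is algebraically
identical).

## What the generator does and does not emulate

The synthetic populations capture: lognormal single-cell output
distributions, noise-entity-dependent distortion of averaged transfer
curves (a Jensen-gap effect through the nonlinear gates), propagation
and logic-dependent amplification/attenuation of noise (YES gates
amplify correlated upstream fluctuations, NOT gates compensate them),
and intrinsic/extrinsic decomposition via ρ. They do **not** emulate:
measurement-instrument noise, cell growth and dilution, retroactivity
between modules, bistability, time correlation of noise, or
context-dependence of parameters themselves. Passing tests therefore
show how much apparent unpredictability *noise alone* can generate in a
modular cascade — they do not certify that real circuits are modular,
nor that real noise is exactly lognormal.

## Numerical choices and degenerate inputs

- Activating Hill at x = 0 returns δ exactly (no ε-offset of the grid).
- Noise on a stage whose deterministic output is ≤ 0 is a domain error
  (a lognormal factor cannot produce mass at 0).
- Flat response data yields a flagged, non-converged fit with α at its
  bound rather than an exception.
- CV of estimates with zero mean is undefined and flagged.
- Statistical test bounds use 3 standard errors (≈99.7% coverage); the
  study-level headline statistics carry Monte-Carlo spread of roughly
  ±0.5 percentage points (s.d. across master seeds at 10,000 cells),
  which is the basis for the tolerances used in the end-to-end tests.

## Known limitations

- The constant-VAR law is undefined at a true-zero deterministic output;
  modules here have strictly positive basal rates, which the validation
  enforces.
- η* of a composed cascade is grid-sensitive at the few-percent level
  because the composition is only approximately Hill; k*, α*, δ* are
  robust.
- δ estimates are reported for completeness but should not be
  interpreted quantitatively (linear-scale fitting barely constrains
  them).
- The 81-way comparison depends on which set is the normaliser; both
  numbers are derivable from the output table, the headline uses the
  predicted-set denominator.
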