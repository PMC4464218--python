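"""Study drivers: module characterization, sensitivity and extrinsic-noise
scans, black-box prediction vs simulation, and the 81-way cross-comparison.

Every driver follows the same experimental logic: simulate single-cell
data for a network under a prescribed noise condition, collapse it to
population averages per induction (what a plate reader would report),
identify Hill transfer functions from those averages, and summarize how
the estimates spread across noise conditions (sample CV) and deviate from
the generating "true" parameters (maximum percentage difference).

The basal parameter delta is reported everywhere but excluded from the
headline CV / max-difference statistics: it sits orders of magnitude
below the dynamic range and its estimate is unstable, so its relative
spread is not informative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_models import ACTIVATING, REPRESSING, HillParams, NetworkSpec, builtin_params
from .identification import FitResult, fit_hill, predict_blackbox
from .noise import CONSTANT_CV, CONSTANT_VAR, NoiseSpec
from .population_sim import (
    SimulationConfig,
    default_hsl_grid,
    dense_hsl_grid,
    simulate_network,
)

__all__ = [
    "StudyConfig",
    "ComparisonSummary",
    "CV_ENTITIES",
    "VAR_ENTITIES",
    "cv_across",
    "max_pct_diff",
    "characterize_module",
    "sensitivity_scan",
    "extrinsic_sweep",
    "blackbox_noiseless_reference",
    "blackbox_prediction_study",
    "blackbox_simulation_study",
    "cross_compare",
]

# Noise entities of the reference studies: realistic cell-to-cell
# variability spans CV 15-75%; the constant-variance alternative uses
# absolute variances 0.05-0.15 RPU^2.
CV_ENTITIES = (0.15, 0.55, 0.75)
VAR_ENTITIES = (0.05, 0.10, 0.15)

PARAM_NAMES = ("alpha", "delta", "k", "eta")
HEADLINE_PARAMS = ("alpha", "k", "eta")


def _child_seed(master_seed: int, *key) -> int:
    """Deterministic sub-seed (< 2^31) for one condition of a study."""
    ss = np.random.SeedSequence([int(master_seed)] + [int(k) for k in key])
    return int(ss.generate_state(1)[0] % (2**31))


def cv_across(values) -> float:
    """Sample CV (%) across estimates: std (n-1 denominator) / mean x 100."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 estimates")
    if not np.all(np.isfinite(arr)):
        raise ValueError("estimates must be finite")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero-mean estimates")
    return float(arr.std(ddof=1) / mean * 100.0)


def max_pct_diff(values, truth: float) -> float:
    """Largest |estimate - truth| / truth, in percent."""
    if truth <= 0:
        raise ValueError("truth must be positive")
    arr = np.asarray(values, dtype=float)
    return float(np.max(np.abs(arr - truth) / truth) * 100.0)


@dataclass(frozen=True)
class StudyConfig:
    """One module-characterization study.

    The module under study (``gate``) is driven by the inducible input
    device; lognormal noise of the given model is applied to the input
    device's output at each level in ``entities``.  ``output2_noise``
    optionally adds a noise site on the gate's own output, whose Gaussian
    log-component is correlated with the upstream one by ``rho``.
    """

    gate: HillParams
    input_device: HillParams = None
    noise_model: str = CONSTANT_CV
    entities: tuple = CV_ENTITIES
    output2_noise: NoiseSpec | None = None
    rho: float = 0.0
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    corrected: bool = True

    def __post_init__(self) -> None:
        if self.input_device is None:
            object.__setattr__(self, "input_device", builtin_params()["input_device"])
        if len(self.entities) < 1:
            raise ValueError("need at least one noise entity")
        if any(e < 0 for e in self.entities):
            raise ValueError("noise entities must be non-negative")


@dataclass
class ComparisonSummary:
    """Spread of estimates across conditions and deviation from truth."""

    estimates: pd.DataFrame            # one row per condition, columns = params
    cv: dict                           # param -> sample CV across conditions (%)
    max_diff: dict                     # param -> max % difference vs truth
    truth: dict                        # param -> generating value

    @property
    def headline_cv(self) -> dict:
        return {p: self.cv[p] for p in HEADLINE_PARAMS if p in self.cv}

    @property
    def headline_max_diff(self) -> dict:
        return {p: self.max_diff[p] for p in HEADLINE_PARAMS if p in self.max_diff}


def _summarize_estimates(estimates: pd.DataFrame, truth: dict) -> ComparisonSummary:
    cv = {}
    md = {}
    for p in PARAM_NAMES:
        vals = estimates[p].to_numpy()
        try:
            cv[p] = cv_across(vals) if len(vals) >= 2 else 0.0
        except ValueError:
            cv[p] = float("nan")
        if p in truth and truth[p] > 0:
            md[p] = max_pct_diff(vals, truth[p])
    return ComparisonSummary(estimates=estimates, cv=cv, max_diff=md, truth=truth)


def _two_module_network(cfg: StudyConfig, entity: float) -> NetworkSpec:
    site1 = NoiseSpec(model=cfg.noise_model, level=entity, corrected=cfg.corrected)
    return NetworkSpec(
        stages=(("output1", cfg.input_device), ("output2", cfg.gate)),
        noise_sites=(site1, cfg.output2_noise),
        rho=cfg.rho if cfg.output2_noise is not None else 0.0,
    )


def characterize_module(cfg: StudyConfig, init_from_truth: bool = False):
    """Identify a gate's transfer function under each noise entity.

    For each entity: simulate the two-module network, average OUTPUT1 and
    OUTPUT2 per induction, and fit the gate's Hill function (its own
    logic) to averaged OUTPUT2 vs averaged OUTPUT1.  Returns the list of
    per-entity :class:`FitResult` and a :class:`ComparisonSummary` of the
    estimates against the generating parameters.
    """
    fits: list[FitResult] = []
    rows = []
    for j, entity in enumerate(cfg.entities):
        net = _two_module_network(cfg, entity)
        sim = replace(cfg.sim, master_seed=_child_seed(cfg.sim.master_seed, j))
        samples = simulate_network(net, sim)
        x = samples[0].mean
        y = samples[1].mean
        init = cfg.gate if init_from_truth else None
        fit = fit_hill(x, y, logic=cfg.gate.logic, init=init)
        fits.append(fit)
        rows.append(
            {"entity": entity, "converged": fit.converged, **{
                p: getattr(fit.params, p) for p in PARAM_NAMES
            }}
        )
    estimates = pd.DataFrame(rows)
    truth = {p: getattr(cfg.gate, p) for p in PARAM_NAMES}
    return fits, _summarize_estimates(estimates, truth)


def sensitivity_scan(varied: str, grid, cfg: StudyConfig) -> pd.DataFrame:
    """Repeat the characterization while sweeping one gate parameter.

    ``varied`` is ``"k"`` or ``"eta"``; for each grid value the gate's
    parameter is replaced (others nominal), the study re-run, and the
    per-parameter CV and max % difference collected.
    """
    if varied not in ("k", "eta"):
        raise ValueError("varied must be 'k' or 'eta'")
    rows = []
    for g, value in enumerate(grid):
        gate = cfg.gate.with_(**{varied: float(value)})
        sub = replace(
            cfg, gate=gate,
            sim=replace(cfg.sim, master_seed=_child_seed(cfg.sim.master_seed, 71, g)),
        )
        _, summary = characterize_module(sub)
        row = {"varied": varied, "value": float(value)}
        for p in PARAM_NAMES:
            row[f"cv_{p}"] = summary.cv[p]
            row[f"maxdiff_{p}"] = summary.max_diff.get(p, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)


def extrinsic_sweep(rho_values, cfg: StudyConfig) -> pd.DataFrame:
    """Characterize the gate with noise on both outputs, sweeping rho.

    The gate output carries its own noise site (CV 0.15 by default)
    whose Gaussian log-noise is correlated with the upstream site by
    rho; rho = 0 is purely intrinsic noise, rho = 1 purely extrinsic.
    Both sites are mean-corrected, so estimates are compared against the
    nominal generating parameters.
    """
    if cfg.output2_noise is None:
        cfg = replace(cfg, output2_noise=NoiseSpec(model=CONSTANT_CV, level=0.15))
    rows = []
    for r, rho in enumerate(rho_values):
        sub = replace(
            cfg, rho=float(rho),
            sim=replace(cfg.sim, master_seed=_child_seed(cfg.sim.master_seed, 83, r)),
        )
        _, summary = characterize_module(sub)
        row = {"rho": float(rho)}
        for p in PARAM_NAMES:
            row[f"cv_{p}"] = summary.cv[p]
            row[f"maxdiff_{p}"] = summary.max_diff.get(p, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)


# --- black-box (end-to-end) studies --------------------------------------

def blackbox_noiseless_reference(input_params: HillParams, tet_params: HillParams,
                                 lac_params: HillParams, grid=None) -> FitResult:
    """Deterministic reference: fit the end-to-end Hill function of the
    noiseless three-module cascade built from generating parameters."""
    if grid is None:
        grid = dense_hsl_grid()
    return predict_blackbox(input_params, [tet_params, lac_params], grid)


def blackbox_prediction_study(tet_sets, lac_sets, input_params: HillParams,
                              grid=None):
    """Predict the network's black-box function from module estimates.

    All 3 x 3 combinations of the identified TetR-gate and LacI-gate
    parameter sets are composed noiselessly with the nominal input device
    and fitted end-to-end.  Returns the 9 fits, a tidy estimates table,
    and the per-parameter sample CV across the 9.
    """
    if grid is None:
        grid = dense_hsl_grid()
    fits = []
    rows = []
    for a, tet in enumerate(tet_sets):
        for b, lac in enumerate(lac_sets):
            fit = predict_blackbox(input_params, [tet, lac], grid)
            fits.append(fit)
            rows.append(
                {"tet_set": a, "lac_set": b, **{
                    p: getattr(fit.params, p) for p in PARAM_NAMES
                }}
            )
    estimates = pd.DataFrame(rows)
    cv = {p: (cv_across(estimates[p]) if len(estimates) > 1 else 0.0)
          for p in HEADLINE_PARAMS}
    return fits, estimates, cv


def blackbox_simulation_study(input_params: HillParams, tet_params: HillParams,
                              lac_params: HillParams,
                              entities1=CV_ENTITIES, entities2=CV_ENTITIES,
                              rho: float = 0.0, sim: SimulationConfig | None = None,
                              grid=None):
    """Simulate the noisy three-module network and fit its black-box function.

    For each (CV1, CV2) pair, constant-CV mean-corrected noise is applied
    to OUTPUT1 and OUTPUT2 (independently unless ``rho`` couples them),
    OUTPUT3 is averaged per induction, and the end-to-end activating Hill
    function of the inducer is fitted.  Returns the 9 fits, a tidy
    estimates table, and per-parameter CVs across the 9.
    """
    if sim is None:
        sim = SimulationConfig()
    if grid is None:
        grid = dense_hsl_grid()
    sim = replace(sim, hsl_grid=np.asarray(grid, dtype=float))
    fits = []
    rows = []
    for a, cv2 in enumerate(entities2):
        for b, cv1 in enumerate(entities1):
            net = NetworkSpec(
                stages=(
                    ("output1", input_params),
                    ("output2", tet_params),
                    ("output3", lac_params),
                ),
                noise_sites=(
                    NoiseSpec(model=CONSTANT_CV, level=cv1),
                    NoiseSpec(model=CONSTANT_CV, level=cv2),
                    None,
                ),
                rho=rho,
            )
            run = replace(sim, master_seed=_child_seed(sim.master_seed, 97, a, b))
            samples = simulate_network(net, run)
            fit = fit_hill(run.hsl_grid, samples[2].mean, logic=ACTIVATING)
            fits.append(fit)
            rows.append(
                {"cv1": cv1, "cv2": cv2, **{
                    p: getattr(fit.params, p) for p in PARAM_NAMES
                }}
            )
    estimates = pd.DataFrame(rows)
    cv = {p: (cv_across(estimates[p]) if len(estimates) > 1 else 0.0)
          for p in HEADLINE_PARAMS}
    return fits, estimates, cv


def cross_compare(predicted, simulated) -> dict:
    """All-pairs deviation between predicted and simulated black-box sets.

    For each parameter, computes |simulated - predicted| / predicted x 100
    over every ordered (predicted, simulated) pair (81 for two sets of 9)
    and reports the maximum with the identities of the pair attaining it.
    """
    pred = [f.params if isinstance(f, FitResult) else f for f in predicted]
    sims = [f.params if isinstance(f, FitResult) else f for f in simulated]
    if not pred or not sims:
        raise ValueError("both parameter sets must be non-empty")
    out = {}
    for p in PARAM_NAMES:
        pv = np.array([getattr(q, p) for q in pred])
        sv = np.array([getattr(q, p) for q in sims])
        with np.errstate(divide="ignore", invalid="ignore"):
            diff = np.abs(sv[None, :] - pv[:, None]) / pv[:, None] * 100.0
        diff = np.where(np.isfinite(diff), diff, -np.inf)  # zero denominators
        if not np.any(np.isfinite(diff)):
            continue
        i, j = np.unravel_index(np.argmax(diff), diff.shape)
        out[p] = {
            "max_pct_diff": float(diff[i, j]),
            "predicted_index": int(i),
            "simulated_index": int(j),
            "n_pairs": int(diff.size),
        }
    return out
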