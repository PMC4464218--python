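"""Hill transfer-function fitting from population-averaged data.

Modules are identified the way a plate-reader experiment would: the
per-induction population averages of a module's input and output signals
are fitted with a four-parameter Hill function by bounded nonlinear least
squares on the linear scale.  The same machinery fits the black-box
end-to-end Hill function of a whole cascade against the inducer
concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .core_models import ACTIVATING, HillParams, cascade_response, hill_response, NetworkSpec

__all__ = ["FitResult", "fit_hill", "predict_blackbox"]

_BOUND_TOL = 1e-10


@dataclass(frozen=True)
class FitResult:
    """Estimated Hill parameters with fit diagnostics."""

    params: HillParams
    residual_norm: float
    converged: bool
    init: HillParams
    bounds_hit: tuple = ()

    def as_dict(self) -> dict:
        return {
            "params": self.params.as_dict(),
            "residual_norm": self.residual_norm,
            "converged": self.converged,
            "init": self.init.as_dict(),
            "bounds_hit": list(self.bounds_hit),
        }


def _default_init(x: np.ndarray, y: np.ndarray, logic: str) -> HillParams:
    """Heuristic start: basal from min(y), span from the y range, k at mid-response."""
    d0 = float(np.min(y))
    a0 = float(np.max(y) - np.min(y))
    if a0 <= 0:
        a0 = max(abs(d0), 1.0)
    mid = (np.max(y) + np.min(y)) / 2.0
    k0 = float(x[np.argmin(np.abs(y - mid))])
    if k0 <= 0:
        pos = x[x > 0]
        k0 = float(pos.min()) if pos.size else 1.0
    return HillParams(alpha=a0, delta=max(d0, 0.0), k=k0, eta=1.0, logic=logic)


def _starts(init: HillParams) -> list:
    """Multi-start set: the init plus k and eta jittered x3 and /3."""
    return [
        init,
        init.with_(k=init.k * 3.0, eta=init.eta * 3.0),
        init.with_(k=init.k / 3.0, eta=init.eta / 3.0),
    ]


def fit_hill(x, y, logic: str = ACTIVATING, init: HillParams | None = None,
             n_starts: int = 3) -> FitResult:
    """Fit a Hill function to (input, population-averaged output) pairs.

    Minimizes linear-scale residuals ``y - hill(params, x)`` over
    (alpha, delta, k, eta), all bounded below by 0.  Deterministic for a
    given ``(x, y, init)``; the default three starts jitter k and eta to
    guard against local minima, ties broken by start order.
    Non-convergence is flagged on the result, not raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 5:
        raise ValueError("need at least 5 points to fit 4 parameters")
    if np.any(x < 0):
        raise ValueError("inputs must be non-negative")
    if np.any(y <= 0):
        raise ValueError("outputs must be positive")

    if init is None:
        init = _default_init(x, y, logic)
    if np.ptp(y) == 0:
        # Flat data: every (alpha->0, delta=y) limit fits; flag it.
        return FitResult(
            params=init, residual_norm=0.0, converged=False, init=init,
            bounds_hit=("alpha",),
        )

    def residuals(theta: np.ndarray) -> np.ndarray:
        p = HillParams(
            alpha=max(theta[0], 1e-300), delta=theta[1],
            k=max(theta[2], 1e-300), eta=max(theta[3], 1e-300), logic=logic,
        )
        return hill_response(p, x) - y

    lb = np.zeros(4)
    ub = np.full(4, np.inf)
    best = None
    for start in _starts(init)[:max(1, n_starts)]:
        theta0 = np.maximum(
            [start.alpha, start.delta, start.k, start.eta], 1e-12
        )
        sol = least_squares(residuals, theta0, bounds=(lb, ub), method="trf")
        if best is None or sol.cost < best.cost:
            best = sol

    theta = best.x
    hit = tuple(
        name for name, v in zip(("alpha", "delta", "k", "eta"), theta)
        if v <= _BOUND_TOL
    )
    params = HillParams(
        alpha=max(theta[0], 1e-300), delta=max(theta[1], 0.0),
        k=max(theta[2], 1e-300), eta=max(theta[3], 1e-300), logic=logic,
    )
    return FitResult(
        params=params,
        residual_norm=float(2.0 * best.cost),  # least_squares cost = 0.5 * SSR
        converged=bool(best.success),
        init=init,
        bounds_hit=hit,
    )


def predict_blackbox(input_params: HillParams, downstream_params: list,
                     hsl_grid, init: HillParams | None = None) -> FitResult:
    """Predict a cascade's end-to-end Hill function from module parameters.

    Composes the given transfer functions deterministically (no noise)
    over the inducer grid and fits an activating Hill function of the
    inducer concentration to the final output, returning the starred
    black-box parameters.
    """
    stages = [("input", input_params)] + [
        (f"module{i + 2}", p) for i, p in enumerate(downstream_params)
    ]
    net = NetworkSpec(stages=tuple(stages))
    grid = np.asarray(hsl_grid, dtype=float)
    out = cascade_response(net, grid)[stages[-1][0]]
    return fit_hill(grid, out, logic=ACTIVATING, init=init)
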