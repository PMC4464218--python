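"""Deterministic steady-state transfer functions of genetic modules.

Each module (an inducible device, a NOT gate, a YES gate) is described at
steady state by a four-parameter Hill function mapping its input signal to
the synthesis rate, in relative promoter units (RPU), of the protein it
drives.  Cascades of modules are composed by feeding each stage's output to
the next stage's input; the external input of the first stage is the
concentration (nM) of the quorum-sensing inducer 3OC6-HSL.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

import numpy as np

__all__ = [
    "HillParams",
    "NetworkSpec",
    "hill_response",
    "cascade_response",
    "load_params",
    "dump_params",
    "builtin_params",
]

ACTIVATING = "activating"
REPRESSING = "repressing"


@dataclass(frozen=True)
class HillParams:
    """Four-parameter Hill description of one module's transfer function.

    Parameters
    ----------
    alpha
        Maximal increment of the synthesis rate over basal (RPU); the
        output spans [delta, delta + alpha].
    delta
        Basal synthesis rate when the module is fully off (RPU).
    k
        Half-effect input level: the input at which the output is
        delta + alpha/2.  In nM for the inducer-driven input module, in
        RPU for modules driven by an upstream module.
    eta
        Hill coefficient (dimensionless steepness).
    logic
        ``"activating"`` for output increasing with input (inducible
        device, YES gate), ``"repressing"`` for output decreasing with
        input (NOT gate).
    """

    alpha: float
    delta: float
    k: float
    eta: float
    logic: str = ACTIVATING

    def __post_init__(self) -> None:
        if not (self.alpha > 0):
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if not (self.delta >= 0):
            raise ValueError(f"delta must be non-negative, got {self.delta}")
        if not (self.k > 0):
            raise ValueError(f"k must be positive, got {self.k}")
        if not (self.eta > 0):
            raise ValueError(f"eta must be positive, got {self.eta}")
        if self.logic not in (ACTIVATING, REPRESSING):
            raise ValueError(
                f"logic must be {ACTIVATING!r} or {REPRESSING!r}, got {self.logic!r}"
            )

    def with_(self, **changes) -> "HillParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    def as_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "delta": self.delta,
            "k": self.k,
            "eta": self.eta,
            "logic": self.logic,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HillParams":
        return cls(
            alpha=float(d["alpha"]),
            delta=float(d["delta"]),
            k=float(d["k"]),
            eta=float(d["eta"]),
            logic=str(d.get("logic", ACTIVATING)),
        )


def hill_response(params: HillParams, x):
    """Evaluate a module's steady-state Hill transfer function.

    Activating logic returns ``delta + alpha / (1 + (k/x)**eta)`` with the
    continuous limit ``delta`` at ``x = 0``; repressing logic returns
    ``delta + alpha / (1 + (x/k)**eta)``.  Scalar input gives a scalar,
    array input an array of the same shape.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("input must be finite")
    if np.any(arr < 0):
        raise ValueError("input must be non-negative")
    if params.logic == REPRESSING:
        out = params.delta + params.alpha / (1.0 + (arr / params.k) ** params.eta)
    else:
        # (k/x)^eta diverges at x=0; define the limit value delta explicitly
        # (basal activity with no input present).
        safe = np.where(arr > 0, arr, 1.0)
        out = np.where(
            arr > 0,
            params.delta + params.alpha / (1.0 + (params.k / safe) ** params.eta),
            params.delta,
        )
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class NetworkSpec:
    """An ordered cascade of modules with optional per-stage noise sites.

    ``stages`` is an ordered list of ``(name, HillParams)``; stage 1
    consumes the external inducer and stage i > 1 consumes stage i-1's
    output.  ``noise_sites`` (from :mod:`noisecascade.noise`) assigns a
    noise law to each stage's output; ``None`` or a "none" spec leaves the
    stage deterministic.  ``rho`` is the correlation between the Gaussian
    log-noise components of the first two noisy sites: 0 for purely
    intrinsic (independent) noise, 1 for purely extrinsic (shared) noise.
    """

    stages: tuple
    noise_sites: tuple = ()
    input_name: str = "3OC6-HSL"
    rho: float = 0.0

    def __post_init__(self) -> None:
        if len(self.stages) == 0:
            raise ValueError("network needs at least one stage")
        object.__setattr__(self, "stages", tuple(self.stages))
        sites = tuple(self.noise_sites) if self.noise_sites else tuple(
            [None] * len(self.stages)
        )
        if len(sites) != len(self.stages):
            raise ValueError(
                f"{len(sites)} noise sites for {len(self.stages)} stages"
            )
        object.__setattr__(self, "noise_sites", sites)
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError(f"rho must lie in [0, 1], got {self.rho}")

    @property
    def names(self) -> tuple:
        return tuple(name for name, _ in self.stages)

    def params(self, name: str) -> HillParams:
        for n, p in self.stages:
            if n == name:
                return p
        raise KeyError(name)


def cascade_response(network: NetworkSpec, hsl) -> dict:
    """Noiseless composition of a cascade over an inducer grid.

    Returns a dict mapping stage name to its deterministic output (RPU)
    on the grid: stage 1 is evaluated on ``hsl``, each later stage on the
    previous stage's output.
    """
    arr = np.atleast_1d(np.asarray(hsl, dtype=float))
    if arr.size == 0:
        raise ValueError("empty induction grid")
    out: dict = {}
    signal = arr
    for name, params in network.stages:
        signal = hill_response(params, signal)
        out[name] = signal
    return out


# --- parameter-set (de)serialization -------------------------------------

def dump_params(sets: dict, path) -> None:
    """Write a dict of name -> HillParams as a JSON document."""
    doc = {name: p.as_dict() for name, p in sets.items()}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


def load_params(path) -> dict:
    """Read a JSON document of name -> HillParams."""
    with open(path) as fh:
        doc = json.load(fh)
    return {name: HillParams.from_dict(d) for name, d in doc.items()}


def builtin_params() -> dict:
    """The nominal parameter sets of the lux/tet/lac/mock-YES modules.

    Keys: ``input_device`` (LuxR/Plux 3OC6-HSL-inducible device),
    ``tetr_ptet`` (TetR/Ptet NOT gate), ``laci_plac`` (LacI/Plac NOT
    gate), ``yes_gate`` (mock activator A/PA with the TetR gate's
    numerical parameters).
    """
    ref = resources.files("noisecascade.data").joinpath("module_params.json")
    with ref.open() as fh:
        doc = json.load(fh)
    return {name: HillParams.from_dict(d) for name, d in doc.items()}
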