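"""Lognormal multiplicative noise on module outputs.

Cell-to-cell variability is modelled as a positive multiplicative factor
``v = exp(g)`` applied to a module's deterministic output, with ``g``
Gaussian of mean 0 and variance ``sigma2``.  Two laws fix ``sigma2``:

* constant-CV — the coefficient of variation of the noisy output is the
  same at every induction level, so ``sigma2 = ln(1 + CV^2)`` everywhere;
* constant-VAR — the absolute variance of the noisy output is the same at
  every induction level, so ``sigma2 = ln(1 + VAR / y^2)`` depends on the
  local deterministic output ``y``.

Because ``E[v] = exp(sigma2/2) > 1``, multiplying by raw noise inflates
the population mean; the mean correction rescales the deterministic value
by ``exp(-sigma2/2)`` so that the population average is preserved exactly,
letting different noise entities share identical population-averaged
transfer curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NoiseSpec",
    "NoiseDraw",
    "sigma2_from_cv",
    "sigma2_from_var",
    "lognormal_moments",
    "mean_correction",
    "draw_noise",
    "draw_correlated_noise",
    "site_rng",
]

NONE = "none"
CONSTANT_CV = "constant_cv"
CONSTANT_VAR = "constant_var"


@dataclass(frozen=True)
class NoiseSpec:
    """Noise law attached to one module output.

    ``model`` is one of ``"none"``, ``"constant_cv"``, ``"constant_var"``;
    ``level`` is the CV (dimensionless) or the VAR (RPU^2) accordingly.
    ``corrected`` keeps the population mean equal to the deterministic
    value (on by default).
    """

    model: str = NONE
    level: float = 0.0
    corrected: bool = True
    label: str = ""

    def __post_init__(self) -> None:
        if self.model not in (NONE, CONSTANT_CV, CONSTANT_VAR):
            raise ValueError(f"unknown noise model {self.model!r}")
        if self.level < 0:
            raise ValueError(f"level must be non-negative, got {self.level}")

    @property
    def active(self) -> bool:
        return self.model != NONE and self.level > 0

    def sigma2(self, y):
        """sigma^2 of the Gaussian log-noise at deterministic output ``y``.

        Scalar for constant-CV; elementwise in ``y`` for constant-VAR
        (per-cell when ``y`` is a vector of per-cell values).
        """
        if not self.active:
            return np.zeros_like(np.asarray(y, dtype=float)) if np.ndim(y) else 0.0
        if self.model == CONSTANT_CV:
            s2 = sigma2_from_cv(self.level)
            return np.full_like(np.asarray(y, dtype=float), s2) if np.ndim(y) else s2
        return sigma2_from_var(self.level, y)

    def as_dict(self) -> dict:
        return {
            "model": self.model,
            "level": self.level,
            "corrected": self.corrected,
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseSpec":
        return cls(
            model=str(d.get("model", NONE)),
            level=float(d.get("level", 0.0)),
            corrected=bool(d.get("corrected", True)),
            label=str(d.get("label", "")),
        )


@dataclass(frozen=True)
class NoiseDraw:
    """A vector of multiplicative lognormal noise factors."""

    samples: np.ndarray
    sigma2: float
    seed: object = None

    def __post_init__(self) -> None:
        if np.any(self.samples <= 0):
            raise ValueError("lognormal factors must be positive")


def sigma2_from_cv(cv: float) -> float:
    """Gaussian log-variance giving a lognormal factor with the target CV."""
    if cv < 0:
        raise ValueError(f"cv must be non-negative, got {cv}")
    return float(np.log1p(cv * cv))


def sigma2_from_var(var: float, y_pop):
    """Gaussian log-variance giving target output variance ``var`` at mean ``y_pop``.

    Depends on the induction point through ``y_pop``; vectorized over
    ``y_pop`` for per-cell application downstream of a noisy stage.
    """
    if var < 0:
        raise ValueError(f"var must be non-negative, got {var}")
    y = np.asarray(y_pop, dtype=float)
    if np.any(y <= 0):
        raise ValueError("y_pop must be positive")
    out = np.log1p(var / (y * y))
    return float(out) if np.ndim(y_pop) == 0 else out


def lognormal_moments(sigma2: float):
    """Mean and variance of the lognormal noise factor exp(N(0, sigma2))."""
    if np.any(np.asarray(sigma2) < 0):
        raise ValueError("sigma2 must be non-negative")
    ave = np.exp(np.asarray(sigma2, dtype=float) / 2.0)
    var = np.exp(np.asarray(sigma2, dtype=float)) * np.expm1(np.asarray(sigma2, dtype=float))
    if np.ndim(sigma2) == 0:
        return float(ave), float(var)
    return ave, var


def mean_correction(y_pop, sigma2):
    """Deterministic value rescaled so the noisy population mean is ``y_pop``."""
    y = np.asarray(y_pop, dtype=float)
    if np.any(y <= 0):
        raise ValueError("y_pop must be positive")
    out = y * np.exp(-np.asarray(sigma2, dtype=float) / 2.0)
    return float(out) if np.ndim(y_pop) == 0 and np.ndim(sigma2) == 0 else out


def site_rng(master_seed: int, *key: int) -> np.random.Generator:
    """Child generator for a (site, induction) cell of a study.

    Derived deterministically from the master seed and the integer key so
    any single induction can be re-simulated in isolation.
    """
    return np.random.default_rng([int(master_seed)] + [int(k) for k in key])


def _gaussian_factors(rng: np.random.Generator, sigma2, n: int) -> np.ndarray:
    z = rng.standard_normal(n)
    return np.exp(np.sqrt(np.asarray(sigma2, dtype=float)) * z)


def draw_noise(sigma2, n: int, seed) -> NoiseDraw:
    """Draw ``n`` i.i.d. lognormal factors exp(N(0, sigma2)).

    ``sigma2`` may be a scalar or a length-``n`` vector (per-cell
    variances, as used for constant-VAR noise downstream of a noisy
    stage).  ``seed`` may be an int or an existing Generator.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    s2 = np.asarray(sigma2, dtype=float)
    if np.any(s2 < 0):
        raise ValueError("sigma2 must be non-negative")
    if s2.ndim not in (0, 1) or (s2.ndim == 1 and s2.size != n):
        raise ValueError("sigma2 must be scalar or length n")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return NoiseDraw(samples=_gaussian_factors(rng, s2, n), sigma2=sigma2, seed=seed)


def draw_correlated_noise(sigma2_a, sigma2_b, rho: float, n: int, seed):
    """Draw a correlated pair of lognormal factor vectors.

    The Gaussian log-components share correlation ``rho`` (0 = purely
    intrinsic/independent, 1 = purely extrinsic/shared); each is then
    scaled by its own sigma, so the marginals match :func:`draw_noise`.
    Note ``rho`` is the correlation of the log-noise; on the lognormal
    scale the Pearson correlation is slightly smaller.
    """
    if not (0.0 <= rho <= 1.0):
        raise ValueError(f"rho must lie in [0, 1], got {rho}")
    if n < 1:
        raise ValueError("n must be at least 1")
    for s2 in (sigma2_a, sigma2_b):
        if np.any(np.asarray(s2) < 0):
            raise ValueError("sigma2 must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(1.0 - rho * rho) * rng.standard_normal(n)
    fa = np.exp(np.sqrt(np.asarray(sigma2_a, dtype=float)) * z1)
    fb = np.exp(np.sqrt(np.asarray(sigma2_b, dtype=float)) * z2)
    return (
        NoiseDraw(samples=fa, sigma2=sigma2_a, seed=seed),
        NoiseDraw(samples=fb, sigma2=sigma2_b, seed=seed),
    )
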