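"""Von Mises perceptual noise, category posteriors, and percept classification.

Stimulus feature angles are corrupted by independent Von Mises noise with
concentrations ``kappa_color`` and ``kappa_shape``. An observer holding a
percept ``theta`` assigns posterior mass to the two feature categories under
a Von Mises centered on the percept with the same concentration; because the
Von Mises CDF has no closed form, the half-circle mass is computed by
numerical quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import expit, i0e

from ruleswitch.task import wrap_angle

HALF_PI = math.pi / 2.0

#: Number of quadrature intervals for the category posterior.
QUADRATURE_NODES = 1024


@dataclass(frozen=True)
class PerceptParams:
    """Concentrations of the perceptual noise (kappa = 0 is uniform, inf noiseless)."""

    kappa_color: float
    kappa_shape: float

    def __post_init__(self):
        for name in ("kappa_color", "kappa_shape"):
            k = getattr(self, name)
            if math.isnan(k) or k < 0:
                raise ValueError(f"{name} must be non-negative, got {k}")


@dataclass(frozen=True)
class Percept:
    """A noisy observation of the two feature angles, each in (-pi, pi]."""

    color_angle: float
    shape_angle: float


def sample_percept_angle(mean: float, kappa: float, rng: np.random.Generator) -> float:
    """One Von Mises draw centered on ``mean`` with concentration ``kappa``."""
    if math.isinf(kappa):
        return wrap_angle(mean)
    if kappa == 0.0:
        return wrap_angle(rng.uniform(-math.pi, math.pi))
    return wrap_angle(rng.vonmises(mean, kappa))


def perceive(stimulus, params: PerceptParams, rng: np.random.Generator) -> Percept:
    """Corrupt a stimulus into a percept: independent Von Mises draws per feature."""
    return Percept(
        color_angle=sample_percept_angle(stimulus.color_angle, params.kappa_color, rng),
        shape_angle=sample_percept_angle(stimulus.shape_angle, params.kappa_shape, rng),
    )


def category_posterior(percept_angle, kappa: float, n_nodes: int = QUADRATURE_NODES):
    """Posterior mass of the +1 category (the half-circle around angle 0).

    Integrates a Von Mises density centered on the percept with concentration
    ``kappa`` over [-pi/2, pi/2] by composite Simpson quadrature. Accepts a
    scalar or an array of percept angles.
    """
    theta = np.asarray(percept_angle, dtype=float)
    scalar = theta.ndim == 0
    theta = np.atleast_1d(theta)
    if math.isinf(kappa):
        wrapped = np.vectorize(wrap_angle)(theta)
        out = np.where(np.abs(wrapped) < HALF_PI, 1.0, 0.0)
        out = np.where(np.isclose(np.abs(wrapped), HALF_PI), 0.5, out)
    elif kappa == 0.0:
        out = np.full(theta.shape, 0.5)
    else:
        x = np.linspace(-HALF_PI, HALF_PI, n_nodes + 1)
        # exp(kappa*(cos - 1)) with i0e keeps the ratio finite for large kappa.
        integrand = np.exp(kappa * (np.cos(x[None, :] - theta[:, None]) - 1.0))
        h = math.pi / n_nodes
        weights = np.full(n_nodes + 1, 2.0)
        weights[1::2] = 4.0
        weights[0] = weights[-1] = 1.0
        numerator = integrand @ weights * (h / 3.0)
        out = numerator / (2.0 * math.pi * i0e(kappa))
        np.clip(out, 0.0, 1.0, out=out)
    return float(out[0]) if scalar else out


@lru_cache(maxsize=64)
def _posterior_grid(kappa: float, grid_size: int) -> tuple[np.ndarray, np.ndarray]:
    angles = np.linspace(-math.pi, math.pi, grid_size + 1)
    return angles, category_posterior(angles, kappa)


class CachedCategoryPosterior:
    """Category posterior for one kappa, tabulated on a dense angle grid.

    Simulation and particle filtering evaluate the posterior once per trial
    (or per particle); linear interpolation on a 4096-point grid reproduces
    the quadrature to well below the behavioral noise floor.
    """

    def __init__(self, kappa: float, grid_size: int = 4096):
        self.kappa = float(kappa)
        if math.isinf(self.kappa) or self.kappa == 0.0:
            self._grid = None
        else:
            self._angles, self._grid = _posterior_grid(self.kappa, grid_size)

    def __call__(self, percept_angle):
        if self._grid is None:
            return category_posterior(percept_angle, self.kappa)
        theta = (np.asarray(percept_angle) + math.pi) % (2.0 * math.pi) - math.pi
        return np.interp(theta, self._angles, self._grid)


def classify_binary(percept_angle: float) -> int:
    """Hard classification of a percept: +1 on the category-1 half-circle.

    Exact boundary percepts (a measure-zero event) classify as +1.
    """
    return 1 if abs(wrap_angle(percept_angle)) <= HALF_PI else -1


def classify_smooth(percept_angle, steepness: float = 20.0):
    """Differentiable surrogate for :func:`classify_binary`.

    A sum of two logistic sigmoids with the given steepness (per radian)
    placed at the category boundaries; approaches the hard +/-1 labels as the
    steepness grows. Exists to mirror gradient-based fitting approximations;
    simulation always uses the hard classifier.
    """
    theta = np.asarray(percept_angle, dtype=float)
    wrapped = (theta + math.pi) % (2.0 * math.pi) - math.pi
    val = 2.0 * (expit(steepness * (wrapped + HALF_PI)) - expit(steepness * (wrapped - HALF_PI))) - 1.0
    return float(val) if np.ndim(percept_angle) == 0 else val
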