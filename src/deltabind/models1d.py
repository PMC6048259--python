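"""Analytic one-dimensional benchmark potentials and a vectorized sampler.

These are the closed-form reference systems used to validate the enhanced
sampling machinery: for a single coordinate the Boltzmann free-energy
profile equals the potential itself (up to an additive constant), so
recovery can be checked against an exact answer.  The sampler propagates
many independent walkers at once with the same BAOAB splitting used by the
bead-model engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import KB, KCAL_PER_MOL_AKMA


@dataclass
class Harmonic1D:
    """V(x) = k/2 (x - x0)^2, k in kcal/mol/A^2."""

    k: float = 2.0
    x0: float = 0.0

    def energy(self, x):
        return 0.5 * self.k * (np.asarray(x) - self.x0) ** 2

    def force(self, x):
        return -self.k * (np.asarray(x) - self.x0)


@dataclass
class DoubleWell1D:
    """V(x) = h ((x/a)^2 - 1)^2: minima at +-a, barrier h at x = 0."""

    barrier: float = 3.0  # kcal/mol
    half_separation: float = 1.2  # A

    def energy(self, x):
        u = (np.asarray(x) / self.half_separation) ** 2 - 1.0
        return self.barrier * u**2

    def force(self, x):
        x = np.asarray(x)
        a2 = self.half_separation**2
        return -self.barrier * 4.0 * x * (x**2 / a2 - 1.0) / a2


def baoab_1d(
    force_fn,
    x0: np.ndarray,
    n_steps: int,
    timestep: float,
    friction: float,
    temperature: float,
    rng: np.random.Generator,
    mass: float = 12.0,
    save_stride: int = 10,
    frame_callback=None,
):
    """BAOAB propagation of independent 1-D walkers.

    ``force_fn(x)`` must be vectorized over the walker axis.  Returns the
    saved positions, shape (n_saved, n_walkers), including the initial frame.
    ``frame_callback(step, x)`` runs every step (used for bias deposition).
    """
    x = np.array(x0, dtype=float)
    conv = KCAL_PER_MOL_AKMA
    v = rng.normal(size=x.shape) * np.sqrt(KB * temperature * conv / mass)
    gamma = friction * 1e-3
    c1 = np.exp(-gamma * timestep)
    c2 = np.sqrt(max(0.0, 1.0 - c1 * c1)) * np.sqrt(KB * temperature * conv / mass)
    f = force_fn(x)

    saved = [x.copy()]
    for step in range(1, n_steps + 1):
        v = v + 0.5 * timestep * f * conv / mass
        x = x + 0.5 * timestep * v
        v = c1 * v + c2 * rng.normal(size=x.shape)
        x = x + 0.5 * timestep * v
        f = force_fn(x)
        v = v + 0.5 * timestep * f * conv / mass
        if frame_callback is not None:
            frame_callback(step, x)
        if step % save_stride == 0:
            saved.append(x.copy())
    return np.asarray(saved)
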