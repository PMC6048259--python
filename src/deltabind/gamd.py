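"""Gaussian-accelerated sampling: boost estimation, boosted dynamics, reweighting.

A harmonic boost V_boost = k/2 (E - V)^2 is added whenever the unbiased
potential V falls below a threshold E, flattening basins while preserving
the rank order of states.  The boost parameters (k0, k, E) are estimated
from the statistics of an unbiased stage so that the boost's standard
deviation stays below a user cap sigma0, which keeps the second-order
cumulant reweighting accurate.  Reweighting multiplies the biased bin
probabilities p'(RC) by per-bin averages of exp(V_boost / kB T) - either the
direct exponential average or its second-order cumulant approximation - and
renormalizes over the occupied bins; free energies follow as
F = -kB T ln p, shifted to a zero minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE, KB
from .dynamics import (
    IntegratorConfig,
    LangevinState,
    forces,
    langevin_step,
    maxwell_boltzmann_velocities,
    potential_energy,
    run_cmd,
)
from .models1d import baoab_1d
from .toysys import ToySystem
from .trajectory import TrajectoryEnsemble


class DegenerateStatisticsError(ValueError):
    """The unbiased potential samples carry no usable spread."""


@dataclass
class BoostParameters:
    """Boost-potential parameters and the unbiased-potential statistics behind them."""

    vmax: float
    vmin: float
    vmean: float
    sigma_v: float
    sigma0: float
    k0: float
    k: float  # 1/(kcal/mol)
    e_threshold: float

    def __post_init__(self) -> None:
        if not (self.vmin <= self.vmean <= self.vmax):
            raise ValueError("require Vmin <= Vmean <= Vmax")
        if not (0.0 <= self.k0 <= 1.0 + 1e-12):
            raise ValueError("k0 must lie in [0, 1]")
        span = self.vmax - self.vmin
        if span > 0 and self.k > 1.0 / span + 1e-12:
            raise ValueError("k exceeds 1/(Vmax - Vmin)")
        upper = self.vmin + (1.0 / self.k if self.k > 0 else np.inf)
        if not (self.vmax - 1e-9 <= self.e_threshold <= upper + 1e-9):
            raise ValueError("E_threshold outside [Vmax, Vmin + 1/k]")

    @property
    def predicted_boost_std(self) -> float:
        return self.k * (self.e_threshold - self.vmean) * self.sigma_v


def estimate_boost_params(
    v_samples, sigma0: float, threshold: str = "lower"
) -> BoostParameters:
    """Estimate (k0, k, E) from unbiased potential samples.

    ``threshold='lower'`` uses the conservative E = Vmax choice;
    ``'upper'`` uses E = Vmin + 1/k with the corresponding k0 estimate,
    falling back to the lower bound when that k0 leaves (0, 1].
    """
    v = np.asarray(v_samples, dtype=float)
    if v.size < 2:
        raise DegenerateStatisticsError("need at least 2 potential samples")
    vmax, vmin, vmean = float(v.max()), float(v.min()), float(v.mean())
    sigma_v = float(v.std())
    if vmax == vmin or sigma_v == 0.0:
        raise DegenerateStatisticsError("potential samples have zero spread")
    span = vmax - vmin

    k0 = min(1.0, (sigma0 / sigma_v) * span / (vmax - vmean))
    e = vmax
    if threshold == "upper":
        k0_up = (1.0 - sigma0 / sigma_v) * span / (vmean - vmin)
        if 0.0 < k0_up <= 1.0:
            k0 = k0_up
            e = vmin + span / k0
        # else: fall back to the lower-bound form already computed
    elif threshold != "lower":
        raise ValueError("threshold must be 'lower' or 'upper'")

    k = k0 / span
    return BoostParameters(
        vmax=vmax,
        vmin=vmin,
        vmean=vmean,
        sigma_v=sigma_v,
        sigma0=sigma0,
        k0=k0,
        k=k,
        e_threshold=e,
    )


def boost(v, params: BoostParameters):
    """(V_updated, V_boost) for potentials ``v`` (scalar or array)."""
    v = np.asarray(v, dtype=float)
    below = v < params.e_threshold
    vb = np.where(below, 0.5 * params.k * (params.e_threshold - v) ** 2, 0.0)
    out = v + vb
    if np.isscalar(v) or v.ndim == 0:
        return float(out), float(vb)
    return out, vb


def _boost_force_scale(v, params: BoostParameters):
    """Multiplier on the unbiased force: 1 - k (E - V) below threshold, else 1."""
    v = np.asarray(v, dtype=float)
    return np.where(
        v < params.e_threshold,
        1.0 - params.k * (params.e_threshold - v),
        1.0,
    )


def run_gamd(
    system: ToySystem,
    config: IntegratorConfig,
    params: BoostParameters | None = None,
    cmd_stage_steps: int | None = None,
    sigma0: float = 6.0,
    initial_coords: np.ndarray | None = None,
) -> TrajectoryEnsemble:
    """Boosted Langevin run of a toy system.

    If ``params`` is omitted, an unbiased pre-stage of ``cmd_stage_steps``
    (default: half the production length) estimates them; re-estimation is
    frozen once production starts.
    """
    if params is None:
        pre = IntegratorConfig(
            timestep=config.timestep,
            friction=config.friction,
            temperature=config.temperature,
            n_steps=cmd_stage_steps
            if cmd_stage_steps is not None
            else max(2, config.n_steps // 2),
            save_stride=max(1, config.save_stride // 2),
            seed=config.seed + 1,
        )
        stage = run_cmd(system, pre, initial_coords=initial_coords)
        params = estimate_boost_params(stage.frame_potential, sigma0)
        initial_coords = stage.coords[-1]

    rng = np.random.default_rng(config.seed)
    coords = (
        system.bead_positions.copy()
        if initial_coords is None
        else np.array(initial_coords, dtype=float)
    )
    vel = maxwell_boltzmann_velocities(system.bead_masses, config.temperature, rng)

    def force_fn(x):
        v = potential_energy(system, x)
        return forces(system, x) * _boost_force_scale(v, params)

    state = LangevinState(coords, vel, force_fn(coords))
    v0 = potential_energy(system, coords)
    _, vb0 = boost(v0, params)
    saved, pots, boosts = [coords.copy()], [v0], [vb0]
    for step in range(1, config.n_steps + 1):
        state = langevin_step(state, system, config, rng, force_fn=force_fn)
        if step % config.save_stride == 0:
            v = potential_energy(system, state.coords)
            _, vb = boost(v, params)
            saved.append(state.coords.copy())
            pots.append(v)
            boosts.append(vb)
    return TrajectoryEnsemble(
        coords=np.asarray(saved),
        frame_potential=np.asarray(pots),
        frame_boost=np.asarray(boosts),
        timestep=config.timestep * config.save_stride,
        temperature=config.temperature,
        seed=config.seed,
        provenance="GaMD",
        extra={"boost_params": params},
    )


def run_gamd_1d(
    potential,
    n_walkers: int = 32,
    cmd_steps: int = 5000,
    gamd_steps: int = 40000,
    timestep: float = 5.0,
    friction: float = 2.0,
    temperature: float = DEFAULT_TEMPERATURE,
    sigma0: float = 6.0,
    seed: int = 0,
    save_stride: int = 10,
    x0=None,
    params: BoostParameters | None = None,
):
    """GaMD on a 1-D analytic potential with vectorized walkers.

    Returns (positions, v_orig, v_boost, params); position/energy arrays are
    flattened over frames x walkers.
    """
    rng = np.random.default_rng(seed)
    if x0 is None:
        x0 = rng.normal(0.0, 0.5, size=n_walkers)
    x0 = np.asarray(x0, dtype=float)

    if params is None:
        xs = baoab_1d(
            potential.force, x0, cmd_steps, timestep, friction, temperature, rng,
            save_stride=save_stride,
        )
        params = estimate_boost_params(potential.energy(xs).ravel(), sigma0)
        x0 = xs[-1]

    def force_fn(x):
        return potential.force(x) * _boost_force_scale(potential.energy(x), params)

    xs = baoab_1d(
        force_fn, x0, gamd_steps, timestep, friction, temperature, rng,
        save_stride=save_stride,
    )
    v = potential.energy(xs).ravel()
    _, vb = boost(v, params)
    return xs.ravel(), v, vb, params


# ---------------------------------------------------------------------------
# reweighting and free-energy landscapes
# ---------------------------------------------------------------------------


@dataclass
class FreeEnergyLandscape:
    """Binned probabilities and free energies along one or two reaction coordinates.

    Empty bins carry NaN probabilities/energies and are excluded from the
    normalization; ``low_confidence`` flags occupied bins whose variance term
    rests on a single sample.
    """

    edges: tuple  # per-dimension bin edges
    p_prime: np.ndarray
    p: np.ndarray
    F: np.ndarray | None
    counts: np.ndarray
    temperature: float
    estimator: str = "exponential"
    low_confidence: np.ndarray | None = None

    @property
    def n_dims(self) -> int:
        return len(self.edges)

    def bin_centers(self, dim: int = 0) -> np.ndarray:
        e = self.edges[dim]
        return 0.5 * (e[:-1] + e[1:])


def _bin_rc(rc_values, bin_edges):
    rc = np.asarray(rc_values, dtype=float)
    if rc.ndim == 1:
        rc = rc[:, None]
    if isinstance(bin_edges, np.ndarray) and bin_edges.ndim == 1:
        edges = (bin_edges,)
    else:
        edges = tuple(np.asarray(e, dtype=float) for e in bin_edges)
    if rc.shape[1] != len(edges):
        raise ValueError("reaction-coordinate dimensionality does not match bin edges")
    shape = tuple(len(e) - 1 for e in edges)
    idx = []
    valid = np.ones(rc.shape[0], dtype=bool)
    for d, e in enumerate(edges):
        k = np.searchsorted(e, rc[:, d], side="right") - 1
        k = np.where(rc[:, d] == e[-1], len(e) - 2, k)  # top edge inclusive
        valid &= (k >= 0) & (k < shape[d])
        idx.append(k)
    flat = np.ravel_multi_index(
        tuple(np.clip(k, 0, s - 1) for k, s in zip(idx, shape)), shape
    )
    return edges, shape, flat, valid


def _reweight(rc_values, v_boost, bin_edges, T, estimator):
    vb = np.asarray(v_boost, dtype=float)
    rc = np.asarray(rc_values, dtype=float)
    n = rc.shape[0] if rc.ndim > 0 else rc.size
    if vb.shape[0] != n:
        raise ValueError("rc_values and v_boost must have equal length")
    edges, shape, flat, valid = _bin_rc(rc, bin_edges)
    flat, vb = flat[valid], vb[valid]
    nbins = int(np.prod(shape))
    counts = np.bincount(flat, minlength=nbins).astype(float)
    occupied = counts > 0
    p_prime = counts / counts.sum()

    beta = 1.0 / (KB * T)
    low_conf = np.zeros(nbins, dtype=bool)
    with np.errstate(invalid="ignore", divide="ignore"):
        if estimator == "exponential":
            # log-sum-exp per bin for numerical stability
            m = np.full(nbins, -np.inf)
            np.maximum.at(m, flat, beta * vb)
            s = np.zeros(nbins)
            np.add.at(s, flat, np.exp(beta * vb - m[flat]))
            log_avg = np.where(occupied, m + np.log(s) - np.log(counts), np.nan)
        elif estimator == "cumulant2":
            mean = np.zeros(nbins)
            np.add.at(mean, flat, vb)
            mean = np.where(occupied, mean / counts, np.nan)
            var = np.zeros(nbins)
            np.add.at(var, flat, (vb - np.where(np.isnan(mean[flat]), 0, mean[flat])) ** 2)
            var = np.where(occupied, var / counts, np.nan)
            low_conf = occupied & (counts == 1)
            log_avg = beta * mean + 0.5 * beta**2 * var
        else:
            raise ValueError("estimator must be 'exponential' or 'cumulant2'")

    log_w = np.where(occupied, np.log(np.where(occupied, p_prime, 1.0)) + log_avg, -np.inf)
    log_w -= log_w[occupied].max()
    w = np.exp(log_w)
    p = w / w[occupied].sum()
    p = np.where(occupied, p, np.nan)
    p_prime = np.where(occupied, p_prime, np.nan)

    return FreeEnergyLandscape(
        edges=edges,
        p_prime=p_prime.reshape(shape),
        p=p.reshape(shape),
        F=None,
        counts=counts.reshape(shape),
        temperature=T,
        estimator=estimator,
        low_confidence=low_conf.reshape(shape),
    )


def reweight_exponential(rc_values, v_boost, bin_edges, T=DEFAULT_TEMPERATURE):
    """Eq-9-style reweighting with the full per-bin exponential average."""
    return _reweight(rc_values, v_boost, bin_edges, T, "exponential")


def reweight_cumulant2(rc_values, v_boost, bin_edges, T=DEFAULT_TEMPERATURE):
    """Reweighting with the second-order cumulant expansion of the average."""
    return _reweight(rc_values, v_boost, bin_edges, T, "cumulant2")


def landscape_free_energy(landscape: FreeEnergyLandscape) -> FreeEnergyLandscape:
    """Fill F = -kB T ln p, shifted so the occupied minimum is zero."""
    with np.errstate(invalid="ignore", divide="ignore"):
        F = -KB * landscape.temperature * np.log(landscape.p)
    if np.all(np.isnan(F)):
        raise ValueError("landscape has no occupied bins")
    F = F - np.nanmin(F)
    landscape.F = F
    return landscape
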