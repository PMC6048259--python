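"""Canonical-ensemble Langevin sampling of toy systems.

Forces are the exact gradients of the toy potential: harmonic bonds
(E = k/2 (r - r0)^2), a Lennard-Jones pair term, an exponentially screened
Coulomb term (effective dielectric + screening length are system
properties), and optional harmonic positional restraints.  Integration uses
the BAOAB splitting of Langevin dynamics, which gives accurate
configurational sampling at the friction and timestep scales used here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import COULOMB, DEFAULT_TEMPERATURE, KB, KCAL_PER_MOL_AKMA
from .toysys import ToySystem
from .trajectory import TrajectoryEnsemble

_MIN_PAIR_DISTANCE = 1e-6


class SingularityError(FloatingPointError):
    """Two interacting beads coincide; the pair terms are undefined."""


@dataclass
class IntegratorConfig:
    """Langevin integrator settings.

    friction follows the collision-frequency convention (1/ps); the 2 ps^-1
    default matches the thermostat setting used for the reference all-atom
    systems, and 310 K is the physiological target temperature.
    """

    timestep: float = 5.0  # fs
    friction: float = 2.0  # 1/ps
    temperature: float = DEFAULT_TEMPERATURE  # K
    n_steps: int = 1000
    save_stride: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")
        if self.save_stride < 1:
            raise ValueError("save_stride must be >= 1")
        if self.n_steps < 0:
            raise ValueError("n_steps must be non-negative")


def _pair_geometry(coords: np.ndarray):
    diff = coords[:, None, :] - coords[None, :, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    return diff, r


def potential_energy(system: ToySystem, coords: np.ndarray, return_terms: bool = False):
    """Total potential (kcal/mol), optionally with the per-term breakdown."""
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates contain non-finite values")
    terms = {}

    i, j = system.bonds[:, 0], system.bonds[:, 1]
    dr = np.linalg.norm(coords[i] - coords[j], axis=1)
    terms["bond"] = float(
        np.sum(0.5 * system.bond_params[:, 0] * (dr - system.bond_params[:, 1]) ** 2)
    )

    _, r = _pair_geometry(coords)
    mask = system.nb_mask
    rm = r[mask]
    if rm.size and rm.min() < _MIN_PAIR_DISTANCE:
        raise SingularityError("overlapping beads at zero distance")
    iu = np.triu(mask)
    r_u = np.where(iu, r, np.inf)
    sr6 = (system.sigma / r_u) ** 6
    terms["vdw"] = float(np.sum(4.0 * system.eps * (sr6**2 - sr6), where=iu))
    qq = np.outer(system.bead_charges, system.bead_charges)
    with np.errstate(over="ignore"):
        elec = (
            COULOMB
            / system.dielectric
            * qq
            * np.exp(-r_u / system.screening_length)
            / r_u
        )
    terms["coulomb"] = float(np.sum(np.where(iu, elec, 0.0)))

    terms["restraint"] = 0.0
    if system.restraints is not None:
        idx, ref, k = system.restraints
        terms["restraint"] = float(
            0.5 * k * np.sum((coords[idx] - ref) ** 2)
        )

    total = sum(terms.values())
    if return_terms:
        return total, terms
    return total


def forces(system: ToySystem, coords: np.ndarray) -> np.ndarray:
    """-dV/dx for every bead, kcal/mol/A."""
    coords = np.asarray(coords, dtype=float)
    f = np.zeros_like(coords)

    i, j = system.bonds[:, 0], system.bonds[:, 1]
    dvec = coords[i] - coords[j]
    dr = np.linalg.norm(dvec, axis=1)
    if np.any(dr < _MIN_PAIR_DISTANCE):
        raise SingularityError("bonded beads at zero distance")
    fb = (-system.bond_params[:, 0] * (dr - system.bond_params[:, 1]) / dr)[:, None] * dvec
    np.add.at(f, i, fb)
    np.add.at(f, j, -fb)

    diff, r = _pair_geometry(coords)
    mask = system.nb_mask
    rm = np.where(mask, r, np.inf)
    if np.any(rm[mask] < _MIN_PAIR_DISTANCE):
        raise SingularityError("overlapping beads at zero distance")
    sr6 = (system.sigma / rm) ** 6
    # dV/dr for LJ: 4 eps (-12 sr12 + 6 sr6)/r ; force magnitude = -dV/dr
    lj_mag = 4.0 * system.eps * (12.0 * sr6**2 - 6.0 * sr6) / rm
    qq = np.outer(system.bead_charges, system.bead_charges)
    pref = COULOMB / system.dielectric
    lam = system.screening_length
    elec_mag = pref * qq * np.exp(-rm / lam) * (1.0 / rm**2 + 1.0 / (rm * lam))
    mag = np.where(mask, lj_mag + elec_mag, 0.0)
    f += np.einsum("ij,ijk->ik", mag / rm, diff)

    if system.restraints is not None:
        idx, ref, k = system.restraints
        f[idx] += -k * (coords[idx] - ref)

    if not np.all(np.isfinite(f)):
        raise FloatingPointError("non-finite force encountered")
    return f


@dataclass
class LangevinState:
    coords: np.ndarray
    velocities: np.ndarray  # A/fs
    forces: np.ndarray | None = None


def maxwell_boltzmann_velocities(
    masses: np.ndarray, temperature: float, rng: np.random.Generator
) -> np.ndarray:
    sigma = np.sqrt(KB * temperature * KCAL_PER_MOL_AKMA / masses)
    return rng.normal(size=(masses.size, 3)) * sigma[:, None]


def langevin_step(
    state: LangevinState,
    system: ToySystem,
    config: IntegratorConfig,
    rng: np.random.Generator,
    force_fn=None,
) -> LangevinState:
    """One BAOAB update.  ``force_fn(coords)`` defaults to the system forces."""
    if force_fn is None:
        force_fn = lambda x: forces(system, x)  # noqa: E731
    dt = config.timestep
    m = system.bead_masses[:, None]
    gamma = config.friction * 1e-3  # 1/ps -> 1/fs
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(max(0.0, 1.0 - c1 * c1)) * np.sqrt(
        KB * config.temperature * KCAL_PER_MOL_AKMA / system.bead_masses
    )[:, None]

    f = state.forces if state.forces is not None else force_fn(state.coords)
    v = state.velocities + 0.5 * dt * f * KCAL_PER_MOL_AKMA / m
    x = state.coords + 0.5 * dt * v
    v = c1 * v + c2 * rng.normal(size=v.shape)
    x = x + 0.5 * dt * v
    f = force_fn(x)
    v = v + 0.5 * dt * f * KCAL_PER_MOL_AKMA / m
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(v))):
        raise FloatingPointError("non-finite state after integration step")
    return LangevinState(coords=x, velocities=v, forces=f)


def run_cmd(
    system: ToySystem,
    config: IntegratorConfig,
    initial_coords: np.ndarray | None = None,
) -> TrajectoryEnsemble:
    """Unbiased Langevin run; saves the initial frame plus every stride-th step."""
    rng = np.random.default_rng(config.seed)
    coords = (
        system.bead_positions.copy()
        if initial_coords is None
        else np.array(initial_coords, dtype=float)
    )
    vel = maxwell_boltzmann_velocities(system.bead_masses, config.temperature, rng)
    state = LangevinState(coords, vel, forces(system, coords))

    saved, pots = [coords.copy()], [potential_energy(system, coords)]
    for step in range(1, config.n_steps + 1):
        state = langevin_step(state, system, config, rng)
        if step % config.save_stride == 0:
            saved.append(state.coords.copy())
            pots.append(potential_energy(system, state.coords))
    frames = np.asarray(saved)
    return TrajectoryEnsemble(
        coords=frames,
        frame_potential=np.asarray(pots),
        frame_boost=np.zeros(len(saved)),
        timestep=config.timestep * config.save_stride,
        temperature=config.temperature,
        seed=config.seed,
        provenance="cMD",
    )
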