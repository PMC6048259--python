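"""Adaptive-bias free-energy sampling along collective variables.

Collective variables are built from four anchor bead groups T, U, W, X:
the distance CV separates V = CoM(T u U) from Y = CoM(W u X); the angle CV
is the T-U-Y group-centre angle; the torsion CV is the T-U-W-X group-centre
dihedral.  A flooding bias grows on a grid over one or two CVs - each step
deposits a compactly-supported biweight kernel with energy kB*T*dt/tau - until
the bias mirrors the negative free-energy profile.  Binding free energies
come from integrating the Boltzmann weight of the PMF over bound and
unbound windows of the separation coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .constants import DEFAULT_TEMPERATURE, KB
from .dynamics import (
    IntegratorConfig,
    LangevinState,
    forces,
    langevin_step,
    maxwell_boltzmann_velocities,
    potential_energy,
)
from .gamd import FreeEnergyLandscape
from .models1d import baoab_1d
from .toysys import ToySystem
from .trajectory import TrajectoryEnsemble


class DegenerateGeometryError(ValueError):
    """Coincident group centres make the collective variable undefined."""


@dataclass
class CollectiveVariable:
    """A distance, angle or torsion built on anchor bead groups.

    ``groups`` holds the bead-index sets (T, U, W, X); the angle CV uses the
    centres of T and U plus Y = CoM(W u X); the torsion uses all four group
    centres.  Centres are mass-weighted when masses are attached.
    """

    kind: str  # distance | angle | torsion
    groups: tuple  # (T, U, W, X) bead-index arrays
    masses: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("distance", "angle", "torsion"):
            raise ValueError("kind must be distance, angle or torsion")
        self.groups = tuple(np.asarray(g, dtype=int) for g in self.groups)
        if len(self.groups) != 4:
            raise ValueError("four anchor groups (T, U, W, X) are required")
        if any(g.size == 0 for g in self.groups):
            raise ValueError("anchor groups must be non-empty")
        seen = set()
        for g in self.groups:
            s = set(g.tolist())
            if seen & s:
                raise ValueError("anchor groups must be disjoint")
            seen |= s

    def _com(self, coords, idx):
        if self.masses is None:
            return coords[idx].mean(axis=0)
        w = self.masses[idx] / self.masses[idx].sum()
        return w @ coords[idx]

    def centers(self, coords) -> np.ndarray:
        """The centre points the CV is built from (depends on kind)."""
        T, U, W, X = self.groups
        if self.kind == "distance":
            return np.array(
                [
                    self._com(coords, np.concatenate([T, U])),
                    self._com(coords, np.concatenate([W, X])),
                ]
            )
        if self.kind == "angle":
            return np.array(
                [
                    self._com(coords, T),
                    self._com(coords, U),
                    self._com(coords, np.concatenate([W, X])),
                ]
            )
        return np.array([self._com(coords, g) for g in self.groups])

    def value_from_centers(self, c: np.ndarray) -> float:
        if self.kind == "distance":
            return float(np.linalg.norm(c[0] - c[1]))
        if self.kind == "angle":
            a, b = c[0] - c[1], c[2] - c[1]
            na, nb = np.linalg.norm(a), np.linalg.norm(b)
            if na < 1e-10 or nb < 1e-10:
                raise DegenerateGeometryError("coincident centres in angle CV")
            cosang = np.clip(a @ b / (na * nb), -1.0, 1.0)
            return float(np.degrees(np.arccos(cosang)))
        b1, b2, b3 = c[1] - c[0], c[2] - c[1], c[3] - c[2]
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        nb2 = np.linalg.norm(b2)
        if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10 or nb2 < 1e-10:
            raise DegenerateGeometryError("collinear centres in torsion CV")
        x = n1 @ n2
        y = np.cross(n1, n2) @ b2 / nb2
        ang = float(np.degrees(np.arctan2(y, x)))
        return 180.0 if ang == -180.0 else ang


def eval_cv(coords: np.ndarray, cv: CollectiveVariable) -> float:
    """Evaluate one collective variable (A for distances, degrees otherwise)."""
    coords = np.asarray(coords, dtype=float)
    c = cv.centers(coords)
    if cv.kind == "distance":
        v = cv.value_from_centers(c)
        if v < 1e-10:
            raise DegenerateGeometryError("coincident centres in distance CV")
        return v
    return cv.value_from_centers(c)


def separation_cv(system: ToySystem) -> CollectiveVariable:
    """The receptor-ligand separation CV: halves of each chain as T,U / W,X."""
    rec, lig = system.chain_beads("A"), system.chain_beads("B")
    return CollectiveVariable(
        kind="distance",
        groups=(
            rec[: len(rec) // 2 or 1],
            rec[len(rec) // 2 or 1 :] if len(rec) > 1 else rec[:1],
            lig[: len(lig) // 2 or 1],
            lig[len(lig) // 2 or 1 :] if len(lig) > 1 else lig[:1],
        ),
        masses=system.bead_masses,
    )


def _cv_gradient(coords: np.ndarray, cv: CollectiveVariable, h: float = 1e-5):
    """dCV/dx via the chain rule through the group centres.

    The CV depends on bead coordinates only through 2-4 centre points, so a
    finite difference over the centres (cheap, <= 12 dims) chained with the
    analytic centre weights gives the full-dimension gradient.
    """
    c = cv.centers(coords)
    dcv_dc = np.zeros_like(c)
    for p in range(c.shape[0]):
        for d in range(3):
            cp = c.copy()
            cp[p, d] += h
            cm = c.copy()
            cm[p, d] -= h
            vp, vm = cv.value_from_centers(cp), cv.value_from_centers(cm)
            if cv.kind == "torsion":  # unwrap across the +-180 seam
                if vp - vm > 180.0:
                    vp -= 360.0
                elif vm - vp > 180.0:
                    vm -= 360.0
            dcv_dc[p, d] = (vp - vm) / (2 * h)

    grad = np.zeros_like(coords)
    T, U, W, X = cv.groups
    if cv.kind == "distance":
        center_groups = [np.concatenate([T, U]), np.concatenate([W, X])]
    elif cv.kind == "angle":
        center_groups = [T, U, np.concatenate([W, X])]
    else:
        center_groups = [T, U, W, X]
    for p, idx in enumerate(center_groups):
        if cv.masses is None:
            w = np.full(idx.size, 1.0 / idx.size)
        else:
            w = cv.masses[idx] / cv.masses[idx].sum()
        grad[idx] += w[:, None] * dcv_dc[p][None, :]
    return grad


# ---------------------------------------------------------------------------
# flooding bias
# ---------------------------------------------------------------------------


@dataclass
class BiasState:
    """Accumulated flooding bias on a 1-D or 2-D collective-variable grid."""

    edges: tuple  # per-dimension node edges; bias lives on the nodes
    bias: np.ndarray = None  # kcal/mol per node
    tau: float = 5.0  # ps, flooding timescale
    temperature: float = DEFAULT_TEMPERATURE
    kernel_halfwidth_cells: int = 4
    boundary: str = "reject"  # deposits outside the grid: "reject" | "clip"
    n_deposits: int = 0
    snapshots: list = field(default_factory=list)
    converged: bool = False

    def __post_init__(self) -> None:
        self.edges = tuple(np.asarray(e, dtype=float) for e in self.edges)
        if self.bias is None:
            self.bias = np.zeros(tuple(len(e) for e in self.edges))
        if np.any(self.bias < 0) or not np.all(np.isfinite(self.bias)):
            raise ValueError("bias must be finite and non-negative")
        if self.boundary not in ("reject", "clip"):
            raise ValueError("boundary must be 'reject' or 'clip'")

    @property
    def n_dims(self) -> int:
        return len(self.edges)

    def _kernel_1d(self, edges, value):
        cell = edges[1] - edges[0]
        hw = self.kernel_halfwidth_cells * cell
        u = (edges - value) / hw
        w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        return w

    def interp(self, cv_value) -> float:
        """Multilinear interpolation of the bias at a CV point."""
        v = np.atleast_1d(np.asarray(cv_value, dtype=float))
        idx, frac = [], []
        for d, e in enumerate(self.edges):
            x = np.clip(v[d], e[0], e[-1])
            k = min(int(np.searchsorted(e, x, side="right") - 1), len(e) - 2)
            idx.append(k)
            frac.append((x - e[k]) / (e[k + 1] - e[k]))
        if self.n_dims == 1:
            k, f = idx[0], frac[0]
            return float((1 - f) * self.bias[k] + f * self.bias[k + 1])
        (ki, fi), (kj, fj) = zip(idx, frac)
        b = self.bias
        return float(
            (1 - fi) * (1 - fj) * b[ki, kj]
            + fi * (1 - fj) * b[ki + 1, kj]
            + (1 - fi) * fj * b[ki, kj + 1]
            + fi * fj * b[ki + 1, kj + 1]
        )

    def gradient(self, cv_value) -> np.ndarray:
        """dB/dCV at a point, from central differences on the node grid."""
        v = np.atleast_1d(np.asarray(cv_value, dtype=float))
        out = np.zeros(self.n_dims)
        for d, e in enumerate(self.edges):
            h = 0.5 * (e[1] - e[0])
            vp, vm = v.copy(), v.copy()
            vp[d] = min(v[d] + h, e[-1])
            vm[d] = max(v[d] - h, e[0])
            if vp[d] == vm[d]:
                continue
            out[d] = (self.interp(vp) - self.interp(vm)) / (vp[d] - vm[d])
        return out


def deposit_bias(state: BiasState, cv_value, dt: float) -> BiasState:
    """Add one kernel deposit of energy kB*T*dt/tau centred at ``cv_value``.

    ``dt`` is in fs; tau in ps.  Deposits outside the grid are rejected or
    clipped to the edge according to the state's boundary rule.
    """
    v = np.atleast_1d(np.asarray(cv_value, dtype=float))
    for d, e in enumerate(self_edges := state.edges):
        if v[d] < e[0] or v[d] > e[-1]:
            if state.boundary == "reject":
                return state
            v[d] = np.clip(v[d], e[0], e[-1])
    amp = KB * state.temperature * (dt * 1e-3) / state.tau
    kernels = [state._kernel_1d(e, v[d]) for d, e in enumerate(self_edges)]
    if state.n_dims == 1:
        state.bias += amp * kernels[0]
    else:
        state.bias += amp * np.outer(kernels[0], kernels[1])
    state.n_deposits += 1
    return state


def pmf_from_bias(state: BiasState, average_last: float = 0.5) -> FreeEnergyLandscape:
    """F = -bias (shifted to zero minimum), node grid re-expressed as bins.

    When bias snapshots were recorded, the bias is averaged over the final
    ``average_last`` fraction of them to damp deposition noise.
    """
    if state.snapshots:
        n = max(1, int(len(state.snapshots) * average_last))
        bias = np.mean(state.snapshots[-n:], axis=0)
    else:
        bias = state.bias
    F = -(bias - bias.max())  # min F = 0 where bias is largest
    # express node grid as narrow bins centred on the nodes
    edges = []
    for e in state.edges:
        cell = e[1] - e[0]
        edges.append(np.concatenate([[e[0] - cell / 2], e + cell / 2]))
    p = np.exp(-F / (KB * state.temperature))
    p = p / p.sum()
    return FreeEnergyLandscape(
        edges=tuple(edges),
        p_prime=p.copy(),
        p=p,
        F=F,
        counts=np.full(F.shape, np.nan),
        temperature=state.temperature,
        estimator="abmd",
    )


def check_convergence(state: BiasState, window_fraction: float = 0.1,
                      threshold: float = 0.2) -> bool:
    """Flag convergence when consecutive window-averaged bias shapes agree.

    Compares the mean bias over the last two ``window_fraction`` windows of
    the snapshot history after removing each window's own offset (flooding
    raises the bias uniformly once the profile has converged); converged
    when the residual max |dF| is below ``threshold`` kcal/mol.
    """
    n = len(state.snapshots)
    w = max(1, int(n * window_fraction))
    if n < 2 * w:
        return False
    a = np.mean(state.snapshots[-2 * w : -w], axis=0)
    b = np.mean(state.snapshots[-w:], axis=0)
    # compare only the well-flooded region: unvisited high-F nodes trail the
    # uniform growth of the converged profile indefinitely
    mask = b > 0.25 * b.max()
    if mask.sum() < 3:
        return False
    a, b = a - a[mask].mean(), b - b[mask].mean()
    state.converged = bool(np.max(np.abs(a[mask] - b[mask])) < threshold)
    return state.converged


def run_abmd(
    system: ToySystem,
    cvs,
    config: IntegratorConfig,
    grid_edges,
    tau: float = 5.0,
    kernel_halfwidth_cells: int = 4,
    wall_k: float = 10.0,
    initial_coords: np.ndarray | None = None,
    snapshot_every: int = 1000,
):
    """Flooding run of a toy system along one or two collective variables.

    Returns ``(BiasState, TrajectoryEnsemble)``.  Forces include the negative
    bias gradient chained through the CVs plus harmonic walls confining the
    CVs to the grid.  ``tau = inf`` disables deposition (reduces to cMD).
    """
    if isinstance(cvs, CollectiveVariable):
        cvs = [cvs]
    cvs = list(cvs)
    if len(cvs) not in (1, 2):
        raise ValueError("run_abmd takes one or two collective variables")
    edges = tuple(np.asarray(e, dtype=float) for e in (
        (grid_edges,) if isinstance(grid_edges, np.ndarray) and np.ndim(grid_edges) == 1
        else grid_edges
    ))
    state = BiasState(
        edges=edges,
        tau=tau,
        temperature=config.temperature,
        kernel_halfwidth_cells=kernel_halfwidth_cells,
    )

    rng = np.random.default_rng(config.seed)
    coords = (
        system.bead_positions.copy()
        if initial_coords is None
        else np.array(initial_coords, dtype=float)
    )
    vel = maxwell_boltzmann_velocities(system.bead_masses, config.temperature, rng)

    def cv_values(x):
        return np.array([eval_cv(x, cv) for cv in cvs])

    def force_fn(x):
        f = forces(system, x)
        v = cv_values(x)
        g = state.gradient(v)
        for d, cv in enumerate(cvs):
            dcv = _cv_gradient(x, cv)
            f += -g[d] * dcv
            lo, hi = state.edges[d][0], state.edges[d][-1]
            if v[d] < lo:
                f += -wall_k * (v[d] - lo) * dcv
            elif v[d] > hi:
                f += -wall_k * (v[d] - hi) * dcv
        return f

    ls = LangevinState(coords, vel, force_fn(coords))
    saved, pots = [coords.copy()], [potential_energy(system, coords)]
    for step in range(1, config.n_steps + 1):
        ls = langevin_step(ls, system, config, rng, force_fn=force_fn)
        if np.isfinite(tau):
            deposit_bias(state, cv_values(ls.coords), config.timestep)
        if step % snapshot_every == 0:
            state.snapshots.append(state.bias.copy())
        if step % config.save_stride == 0:
            saved.append(ls.coords.copy())
            pots.append(potential_energy(system, ls.coords))
    check_convergence(state)
    traj = TrajectoryEnsemble(
        coords=np.asarray(saved),
        frame_potential=np.asarray(pots),
        frame_boost=np.zeros(len(saved)),
        timestep=config.timestep * config.save_stride,
        temperature=config.temperature,
        seed=config.seed,
        provenance="ABMD",
    )
    return state, traj


def flood_1d(
    potential,
    grid: np.ndarray,
    n_steps: int = 500000,
    timestep: float = 2.0,
    friction: float = 2.0,
    temperature: float = DEFAULT_TEMPERATURE,
    tau: float = 4.0,
    seed: int = 0,
    kernel_halfwidth_cells: int = 4,
    wall_k: float = 20.0,
    snapshot_every: int = 2000,
    x0: float = 0.0,
) -> BiasState:
    """Flooding of a 1-D analytic potential with the coordinate itself as CV."""
    state = BiasState(
        edges=(np.asarray(grid, dtype=float),),
        tau=tau,
        temperature=temperature,
        kernel_halfwidth_cells=kernel_halfwidth_cells,
    )
    rng = np.random.default_rng(seed)
    lo, hi = grid[0], grid[-1]

    def force_fn(x):
        out = potential.force(x)
        for i, xi in enumerate(np.atleast_1d(x)):
            g = state.gradient([xi])[0]
            wall = 0.0
            if xi < lo:
                wall = -wall_k * (xi - lo)
            elif xi > hi:
                wall = -wall_k * (xi - hi)
            out = np.asarray(out, dtype=float)
            out.flat[i] += -g + wall
        return out

    def callback(step, x):
        deposit_bias(state, [float(np.atleast_1d(x)[0])], timestep)
        if step % snapshot_every == 0:
            state.snapshots.append(state.bias.copy())

    baoab_1d(
        force_fn,
        np.array([x0]),
        n_steps,
        timestep,
        friction,
        temperature,
        rng,
        save_stride=n_steps,  # positions not needed, bias is the product
        frame_callback=callback,
    )
    check_convergence(state)
    return state


# ---------------------------------------------------------------------------
# binding free energies
# ---------------------------------------------------------------------------


@dataclass
class BindingResult:
    """Per-variant binding free energies and the mutant-vs-WT comparison."""

    dg_wt: float
    dg_mut: float
    dg_wt_unc: float
    dg_mut_unc: float
    ddg: float
    ddg_unc: float
    kd_ratio: float
    temperature: float
    method: str  # ABMD | MMPBSA

    def __post_init__(self) -> None:
        expected = float(np.exp(self.ddg / (KB * self.temperature)))
        if not np.isclose(self.kd_ratio, expected, rtol=1e-9):
            raise ValueError("kd_ratio inconsistent with ddG and T")
        if self.dg_wt_unc < 0 or self.dg_mut_unc < 0 or self.ddg_unc < 0:
            raise ValueError("uncertainties must be non-negative")


def binding_dg(
    pmf: FreeEnergyLandscape, bound_window, unbound_window
) -> float:
    """dG = -kB T ln( sum_bound e^{-F/kBT} / sum_unbound e^{-F/kBT} ).

    Windows are intervals of the first reaction coordinate; for a 2-D PMF the
    Boltzmann weight is summed over the second coordinate.  No standard-state
    volume correction is applied.
    """
    if pmf.F is None:
        raise ValueError("PMF free energies not filled")
    b_lo, b_hi = bound_window
    u_lo, u_hi = unbound_window
    if not (b_hi <= u_lo or u_hi <= b_lo):
        raise ValueError("bound and unbound windows must be disjoint")
    centers = pmf.bin_centers(0)
    beta = 1.0 / (KB * pmf.temperature)
    with np.errstate(invalid="ignore"):
        w = np.exp(-beta * np.nan_to_num(pmf.F, nan=np.inf))
    if pmf.n_dims == 2:
        w = w.sum(axis=1)
    bound = w[(centers >= b_lo) & (centers <= b_hi)]
    unbound = w[(centers >= u_lo) & (centers <= u_hi)]
    if bound.size == 0 or unbound.size == 0:
        raise ValueError("empty bound or unbound window")
    zb, zu = bound.sum(), unbound.sum()
    if zb == 0 or zu == 0:
        raise ValueError("window carries zero Boltzmann weight")
    return float(-KB * pmf.temperature * np.log(zb / zu))


def delta_delta_g(dg_mut: float, dg_wt: float,
                  unc_mut: float = 0.0, unc_wt: float = 0.0):
    """ddG = dG_mut - dG_wt with quadrature-propagated uncertainty."""
    return float(dg_mut - dg_wt), float(np.hypot(unc_mut, unc_wt))


def kd_ratio(ddg: float, T: float = DEFAULT_TEMPERATURE) -> float:
    """Fold-change in dissociation constant implied by ddG: exp(ddG / kB T)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return float(np.exp(ddg / (KB * T)))


def binding_result(dgs_wt, dgs_mut, T: float = DEFAULT_TEMPERATURE,
                   method: str = "ABMD") -> BindingResult:
    """Aggregate replicate dG values into a BindingResult (spread = std)."""
    dgs_wt = np.asarray(dgs_wt, dtype=float)
    dgs_mut = np.asarray(dgs_mut, dtype=float)
    dg_wt, dg_mut = dgs_wt.mean(), dgs_mut.mean()
    u_wt = dgs_wt.std(ddof=1) if dgs_wt.size > 1 else 0.0
    u_mut = dgs_mut.std(ddof=1) if dgs_mut.size > 1 else 0.0
    ddg, ddg_unc = delta_delta_g(dg_mut, dg_wt, u_mut, u_wt)
    return BindingResult(
        dg_wt=float(dg_wt),
        dg_mut=float(dg_mut),
        dg_wt_unc=float(u_wt),
        dg_mut_unc=float(u_mut),
        ddg=ddg,
        ddg_unc=ddg_unc,
        kd_ratio=kd_ratio(ddg, T),
        temperature=T,
        method=method,
    )


def significance_ddg(replicate_ddgs, null: float = 0.0, method: str = "t",
                     n_permutations: int = 10000, seed: int = 0) -> float:
    """One-sided p-value for ddG > null across replicates.

    ``method='t'``: one-sample t-test; ``'permutation'``: sign-flip test.
    """
    x = np.asarray(replicate_ddgs, dtype=float)
    if x.size < 2 or np.all(x == x[0]):
        # no spread: significance cannot be claimed unless trivially at null
        return 1.0 if x.mean() <= null else 0.5 if x.size < 2 else 1.0
    if method == "t":
        res = stats.ttest_1samp(x, null, alternative="greater")
        return float(res.pvalue)
    if method == "permutation":
        rng = np.random.default_rng(seed)
        centered = x - null
        obs = centered.mean()
        signs = rng.choice([-1.0, 1.0], size=(n_permutations, x.size))
        perm = (signs * np.abs(centered)).mean(axis=1)
        return float((1 + np.sum(perm >= obs)) / (1 + n_permutations))
    raise ValueError("method must be 't' or 'permutation'")
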