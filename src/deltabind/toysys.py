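"""Coarse-grained receptor-ligand toy complexes and synthetic ensembles.

The toy dimer is a minimal bead model of a receptor (chain A) bound to a
ligand (chain B) across a flat interface.  Each residue carries a backbone
bead (CA) and a sidechain bead (SB); interface donor residues additionally
carry an explicit hydrogen bead (H) so that the donor-H-acceptor hydrogen
bond geometry can be evaluated exactly.  The force field is harmonic bonds
plus a Lennard-Jones pair term and a screened Coulomb term.

Two variants are built from the same blueprint: the wild type (WT) and a
mutant (MUT) in which one designated interface residue loses its attractive
interface parameters and its two sequence neighbours are weakened - a
parameter-level analogue of a single-residue interface deletion such as
TorsinA's dystonia-causing dE303 acting on the LULL1 interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectory import TrajectoryEnsemble

# Geometry blueprint (A)
SPACING = 4.5  # residue spacing along the chain axis (x)
SB_Y_REC = 1.8  # receptor sidechain bead height above backbone
H_Y = 2.8  # donor hydrogen height
SB_Y_LIG = 4.6  # ligand sidechain bead height (=> reference D..A distance 2.8)
CA_Y_LIG = 6.4  # ligand backbone height
DISSOCIATION_OFFSET = 25.0  # y-translation defining the unbound reference

# Per-bead-type parameters
BEAD_MASS = {"CA": 12.0, "SB": 32.0, "H": 1.0}
BEAD_RADIUS = {"CA": 1.9, "SB": 2.0, "H": 1.0}
BEAD_EPS = {"CA": 0.15, "SB": 0.25, "H": 0.0}  # kcal/mol
BEAD_SIGMA = {"CA": 3.6, "SB": 3.4, "H": 1.0}  # A

# Interface well for an aligned donor-acceptor sidechain pair
INTERFACE_EPS = 3.5  # kcal/mol
INTERFACE_SIGMA = 2.8 / 2 ** (1.0 / 6.0)  # LJ minimum at the 2.8 A D..A distance
HB_CHARGE = 0.25  # |e| on donor hydrogens and acceptor sidechains

# Mutant perturbation: the deleted residue loses its interface attraction and
# charges; its two sequence neighbours are weakened.
MUT_SITE_EPS = 0.05
MUT_NEIGHBOR_EPS = 1.5
MUT_NEIGHBOR_CHARGE_SCALE = 0.6

BOND_CA_CA = (10.0, SPACING)  # (k kcal/mol/A^2, r0 A); E = k/2 (r-r0)^2
BOND_CA_CA2 = (2.0, 2 * SPACING)  # second-neighbour stiffener keeps chains extended
BOND_CA_SB = (10.0, SB_Y_REC)
BOND_SB_H = (30.0, 1.0)


class SystemSizeError(ValueError):
    """Raised for non-positive residue counts."""


@dataclass
class ToySystem:
    """A coarse-grained two-chain complex with its force-field parameters."""

    bead_positions: np.ndarray  # (n, 3) reference bound coordinates
    bead_masses: np.ndarray
    bead_charges: np.ndarray
    bead_radii: np.ndarray
    bead_names: list
    residue_ids: np.ndarray  # per bead, global residue index
    residue_names: list  # per residue
    chain_ids: list  # per residue, "A" (receptor) or "B" (ligand)
    bonds: np.ndarray  # (m, 2) bead indices
    bond_params: np.ndarray  # (m, 2) = (k, r0)
    eps: np.ndarray  # (n, n) pair well depths
    sigma: np.ndarray  # (n, n) pair LJ sigma
    nb_mask: np.ndarray  # (n, n) bool, True where the nonbonded terms apply
    hbond_sites: list  # (donor bead, hydrogen bead, tuple of acceptor beads)
    variant: str = "WT"
    dielectric: float = 2.0  # effective dielectric of the screened Coulomb term
    screening_length: float = 10.0  # A, exponential screening in the dynamics FF
    restraints: tuple | None = None  # (bead idx array, ref coords, k kcal/mol/A^2)
    mutation_record: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.bead_names)
        self.bead_positions = np.asarray(self.bead_positions, dtype=float)
        for name in ("bead_masses", "bead_charges", "bead_radii"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.bonds = np.asarray(self.bonds, dtype=int).reshape(-1, 2)
        self.bond_params = np.asarray(self.bond_params, dtype=float).reshape(-1, 2)
        if self.bead_positions.shape != (n, 3):
            raise ValueError("bead_positions must be (n_beads, 3)")
        if self.residue_ids.shape != (n,):
            raise ValueError("residue_ids must label every bead")
        if np.any(self.bead_masses <= 0) or np.any(self.bead_radii <= 0):
            raise ValueError("masses and radii must be positive")
        if np.any(self.sigma[self.nb_mask] <= 0):
            raise ValueError("pair sigmas must be positive")
        if self.bonds.size and (self.bonds.min() < 0 or self.bonds.max() >= n):
            raise ValueError("bond list references invalid bead indices")
        n_res = len(self.residue_names)
        if len(self.chain_ids) != n_res:
            raise ValueError("chain_ids must label every residue")
        if self.residue_ids.min() < 0 or self.residue_ids.max() >= n_res:
            raise ValueError("residue_ids reference undefined residues")
        if self.variant not in ("WT", "MUT"):
            raise ValueError("variant must be WT or MUT")

    # ---- topology helpers -------------------------------------------------
    @property
    def n_beads(self) -> int:
        return len(self.bead_names)

    @property
    def n_residues(self) -> int:
        return len(self.residue_names)

    def residue_beads(self, residue: int) -> np.ndarray:
        return np.flatnonzero(self.residue_ids == residue)

    def chain_residues(self, chain: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.chain_ids) == chain)

    def chain_beads(self, chain: str) -> np.ndarray:
        res = set(self.chain_residues(chain).tolist())
        return np.flatnonzero([self.residue_ids[i] in res for i in range(self.n_beads)])

    @property
    def receptor_residues(self) -> np.ndarray:
        return self.chain_residues("A")

    @property
    def ligand_residues(self) -> np.ndarray:
        return self.chain_residues("B")

    def dissociated_positions(self, offset: float = DISSOCIATION_OFFSET) -> np.ndarray:
        """Reference coordinates with the ligand translated away from the interface."""
        coords = self.bead_positions.copy()
        coords[self.chain_beads("B"), 1] += offset
        return coords

    def copy(self) -> "ToySystem":
        return ToySystem(
            bead_positions=self.bead_positions.copy(),
            bead_masses=self.bead_masses.copy(),
            bead_charges=self.bead_charges.copy(),
            bead_radii=self.bead_radii.copy(),
            bead_names=list(self.bead_names),
            residue_ids=self.residue_ids.copy(),
            residue_names=list(self.residue_names),
            chain_ids=list(self.chain_ids),
            bonds=self.bonds.copy(),
            bond_params=self.bond_params.copy(),
            eps=self.eps.copy(),
            sigma=self.sigma.copy(),
            nb_mask=self.nb_mask.copy(),
            hbond_sites=list(self.hbond_sites),
            variant=self.variant,
            dielectric=self.dielectric,
            screening_length=self.screening_length,
            restraints=None
            if self.restraints is None
            else (
                self.restraints[0].copy(),
                self.restraints[1].copy(),
                float(self.restraints[2]),
            ),
            mutation_record=dict(self.mutation_record),
            meta=dict(self.meta),
        )


def build_toy_dimer(
    n_receptor_res: int, n_ligand_res: int, variant: str = "WT", seed: int = 0
) -> ToySystem:
    """Build the WT or MUT toy dimer.

    Ligand residue j sits opposite receptor residue j; every aligned receptor
    residue is a hydrogen-bond donor and every ligand sidechain bead is an
    acceptor candidate.  The mutation site is the middle aligned residue; for
    MUT its interface well depth collapses, its charges are zeroed and its two
    sequence neighbours are weakened.  ``seed`` adds a tiny deterministic
    jitter to the reference coordinates (identical for WT and MUT, so the two
    variants differ only in the declared parameter set).
    """
    if n_receptor_res < 1 or n_ligand_res < 1:
        raise SystemSizeError(
            f"residue counts must be >= 1, got {n_receptor_res}, {n_ligand_res}"
        )
    if variant not in ("WT", "MUT"):
        raise ValueError("variant must be WT or MUT")

    n_aligned = min(n_receptor_res, n_ligand_res)
    mut_site = n_aligned // 2 if n_aligned > 1 else 0

    names, masses, radii, charges = [], [], [], []
    res_ids, res_names, chain_ids = [], [], []
    positions, bonds, bond_params = [], [], []
    base_eps, base_sigma = [], []
    ca_index: dict = {}
    sb_index: dict = {}
    h_index: dict = {}

    def add_bead(name, pos, res, charge):
        names.append(name)
        masses.append(BEAD_MASS[name])
        radii.append(BEAD_RADIUS[name])
        base_eps.append(BEAD_EPS[name])
        base_sigma.append(BEAD_SIGMA[name])
        charges.append(charge)
        positions.append(pos)
        res_ids.append(res)
        return len(names) - 1

    res = 0
    # receptor chain A
    for i in range(n_receptor_res):
        x = i * SPACING
        donor = i < n_aligned
        q_ca = -HB_CHARGE if donor else 0.0
        ca = add_bead("CA", (x, 0.0, 0.0), res, q_ca)
        sb = add_bead("SB", (x, SB_Y_REC, 0.0), res, 0.0)
        ca_index[("A", i)] = ca
        sb_index[("A", i)] = sb
        bonds.append((ca, sb))
        bond_params.append(BOND_CA_SB)
        if donor:
            h = add_bead("H", (x, H_Y, 0.0), res, HB_CHARGE)
            h_index[("A", i)] = h
            bonds.append((sb, h))
            bond_params.append(BOND_SB_H)
        if i > 0:
            bonds.append((ca_index[("A", i - 1)], ca))
            bond_params.append(BOND_CA_CA)
        if i > 1:
            bonds.append((ca_index[("A", i - 2)], ca))
            bond_params.append(BOND_CA_CA2)
        res_names.append(f"R{i + 1:02d}")
        chain_ids.append("A")
        res += 1

    # ligand chain B (every ligand sidechain is an H-bond acceptor)
    for j in range(n_ligand_res):
        x = j * SPACING
        ca = add_bead("CA", (x, CA_Y_LIG, 0.0), res, HB_CHARGE)
        sb = add_bead("SB", (x, SB_Y_LIG, 0.0), res, -HB_CHARGE)
        ca_index[("B", j)] = ca
        sb_index[("B", j)] = sb
        bonds.append((ca, sb))
        bond_params.append(BOND_CA_SB)
        if j > 0:
            bonds.append((ca_index[("B", j - 1)], ca))
            bond_params.append(BOND_CA_CA)
        if j > 1:
            bonds.append((ca_index[("B", j - 2)], ca))
            bond_params.append(BOND_CA_CA2)
        res_names.append(f"L{j + 1:02d}")
        chain_ids.append("B")
        res += 1

    n = len(names)
    base_eps = np.asarray(base_eps)
    base_sigma = np.asarray(base_sigma)
    eps = np.sqrt(np.outer(base_eps, base_eps))
    sigma = 0.5 * (base_sigma[:, None] + base_sigma[None, :])

    res_ids_arr = np.asarray(res_ids)
    nb_mask = res_ids_arr[:, None] != res_ids_arr[None, :]
    for (i, j) in bonds:
        nb_mask[i, j] = nb_mask[j, i] = False
    np.fill_diagonal(nb_mask, False)

    mutation_record: dict = {}
    for i in range(n_aligned):
        bi, bj = sb_index[("A", i)], sb_index[("B", i)]
        pair_eps = INTERFACE_EPS
        if variant == "MUT":
            if i == mut_site:
                pair_eps = MUT_SITE_EPS
            elif abs(i - mut_site) == 1:
                pair_eps = MUT_NEIGHBOR_EPS
        eps[bi, bj] = eps[bj, bi] = pair_eps
        sigma[bi, bj] = sigma[bj, bi] = INTERFACE_SIGMA
        if variant == "MUT" and pair_eps != INTERFACE_EPS:
            mutation_record[("pair_eps", bi, bj)] = (INTERFACE_EPS, pair_eps)

    charges = np.asarray(charges, dtype=float)
    if variant == "MUT":
        for i in range(n_aligned):
            scale = None
            if i == mut_site:
                scale = 0.0
            elif abs(i - mut_site) == 1:
                scale = MUT_NEIGHBOR_CHARGE_SCALE
            if scale is None:
                continue
            for key in (("A", i),):
                for bead in (ca_index[key], h_index.get(key)):
                    if bead is None or charges[bead] == 0.0:
                        continue
                    mutation_record[("charge", bead)] = (
                        charges[bead],
                        charges[bead] * scale,
                    )
                    charges[bead] = charges[bead] * scale

    hbond_sites = []
    acceptors = tuple(sb_index[("B", j)] for j in range(n_ligand_res))
    for i in range(n_aligned):
        hbond_sites.append((sb_index[("A", i)], h_index[("A", i)], acceptors))

    rng = np.random.default_rng(seed)
    positions = np.asarray(positions, dtype=float)
    positions = positions + rng.normal(0.0, 0.01, size=positions.shape)

    return ToySystem(
        bead_positions=positions,
        bead_masses=np.asarray(masses),
        bead_charges=charges,
        bead_radii=np.asarray(radii),
        bead_names=names,
        residue_ids=res_ids_arr,
        residue_names=res_names,
        chain_ids=chain_ids,
        bonds=np.asarray(bonds),
        bond_params=np.asarray(bond_params),
        eps=eps,
        sigma=sigma,
        nb_mask=nb_mask,
        hbond_sites=hbond_sites,
        variant=variant,
        mutation_record=mutation_record,
        meta={
            "n_receptor_res": n_receptor_res,
            "n_ligand_res": n_ligand_res,
            "seed": seed,
            "mut_site": mut_site,
        },
    )


def decouple(system: ToySystem) -> ToySystem:
    """Zero every cross-chain pair parameter and all charges (null-binding model)."""
    out = system.copy()
    rec = out.chain_beads("A")
    lig = out.chain_beads("B")
    out.eps[np.ix_(rec, lig)] = 0.0
    out.eps[np.ix_(lig, rec)] = 0.0
    out.bead_charges[:] = 0.0
    out.meta["decoupled"] = True
    return out


def mutation_parameter_diff(wt: ToySystem, mut: ToySystem) -> dict:
    """Enumerate every force-field parameter that differs between two systems.

    Returns a dict keyed like ``ToySystem.mutation_record`` so a test can
    verify the MUT/WT difference is exactly the declared set.
    """
    if wt.n_beads != mut.n_beads:
        raise ValueError("systems must share a topology")
    diff: dict = {}
    for i in range(wt.n_beads):
        if wt.bead_charges[i] != mut.bead_charges[i]:
            diff[("charge", i)] = (wt.bead_charges[i], mut.bead_charges[i])
    ii, jj = np.nonzero(~np.isclose(wt.eps, mut.eps))
    for i, j in zip(ii, jj):
        if i < j:
            diff[("pair_eps", int(i), int(j))] = (wt.eps[i, j], mut.eps[i, j])
    ii, jj = np.nonzero(~np.isclose(wt.sigma, mut.sigma))
    for i, j in zip(ii, jj):
        if i < j:
            diff[("pair_sigma", int(i), int(j))] = (wt.sigma[i, j], mut.sigma[i, j])
    if not np.allclose(wt.bond_params, mut.bond_params):
        diff[("bond_params",)] = None
    if not np.allclose(wt.bead_masses, mut.bead_masses) or not np.allclose(
        wt.bead_radii, mut.bead_radii
    ):
        diff[("bead_props",)] = None
    return diff


# ---------------------------------------------------------------------------
# synthetic ensembles with prescribed contact / hydrogen-bond statistics
# ---------------------------------------------------------------------------


@dataclass
class EnsembleSpec:
    """Prescription for a synthetic interface ensemble.

    ``contact_probs`` maps (receptor residue index, ligand residue index) -
    both 0-based within their chain - to the fraction of frames in which the
    pair's centre-of-mass distance satisfies the 6 A contact criterion.
    ``hbond_probs`` does the same for the 3.0 A / >=135 deg hydrogen-bond
    criterion of the pair's donor site.  A ligand residue may appear in at
    most one prescription so the placements stay independent and exact.
    """

    n_frames: int
    contact_probs: dict = field(default_factory=dict)
    hbond_probs: dict = field(default_factory=dict)
    noise: float = 0.08  # A, per-bead Gaussian jitter
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise < 0:
            raise ValueError("noise must be non-negative")
        used = []
        for probs in (self.contact_probs, self.hbond_probs):
            for (i, j), p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"probability for pair {(i, j)} outside [0, 1]")
                used.append(j)
        if len(used) != len(set(used)):
            raise ValueError(
                "each ligand residue may appear in at most one prescription"
            )


def _local_to_global(system: ToySystem, chain: str, local: int) -> int:
    res = system.chain_residues(chain)
    if local < 0 or local >= len(res):
        raise ValueError(f"chain {chain} has no residue {local}")
    return int(res[local])


def make_interface_ensemble(system: ToySystem, spec: EnsembleSpec) -> TrajectoryEnsemble:
    """Generate a geometry-only ensemble matching the prescribed statistics.

    Frames start from the bound reference, get Gaussian jitter, then each
    prescribed pair is placed exactly inside or outside its criterion by a
    rigid move of the ligand residue.  Frame energies are zero: fingerprint
    analyses must not depend on the dynamics engine.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    base = system.bead_positions
    masses = system.bead_masses
    frames = np.empty((spec.n_frames, system.n_beads, 3))

    contact_placements = []
    for (i, j), p in spec.contact_probs.items():
        gi = _local_to_global(system, "A", i)
        gj = _local_to_global(system, "B", j)
        contact_placements.append((system.residue_beads(gi), system.residue_beads(gj), p))

    hb_placements = []
    site_by_donor_res = {}
    for donor, hydrogen, acceptors in system.hbond_sites:
        site_by_donor_res[int(system.residue_ids[donor])] = (donor, hydrogen)
    for (i, j), p in spec.hbond_probs.items():
        gi = _local_to_global(system, "A", i)
        gj = _local_to_global(system, "B", j)
        if gi not in site_by_donor_res:
            raise ValueError(f"receptor residue {i} has no hydrogen-bond donor site")
        donor, hydrogen = site_by_donor_res[gi]
        sb_j = [
            b
            for b in system.residue_beads(gj)
            if system.bead_names[b] == "SB"
        ]
        if not sb_j:
            raise ValueError(f"ligand residue {j} has no acceptor bead")
        hb_placements.append((donor, hydrogen, sb_j[0], system.residue_beads(gj), p))

    for f in range(spec.n_frames):
        coords = base + rng.normal(0.0, spec.noise, size=base.shape)

        for rec_beads, lig_beads, p in contact_placements:
            hit = rng.random() < p
            target = rng.uniform(4.0, 5.6) if hit else rng.uniform(7.0, 9.5)
            w_rec = masses[rec_beads] / masses[rec_beads].sum()
            rec_com = w_rec @ coords[rec_beads]
            w_lig = masses[lig_beads] / masses[lig_beads].sum()
            lig_com = w_lig @ coords[lig_beads]
            goal = rec_com + np.array([0.0, target, 0.0])
            coords[lig_beads] += goal - lig_com

        for donor, hydrogen, acceptor, lig_beads, p in hb_placements:
            hit = rng.random() < p
            d_pos, h_pos = coords[donor], coords[hydrogen]
            u = h_pos - d_pos
            u = u / np.linalg.norm(u)
            # random unit vector perpendicular to u
            v = rng.normal(size=3)
            v -= (v @ u) * u
            v /= np.linalg.norm(v)
            r_dh = float(np.linalg.norm(h_pos - d_pos))
            if hit:
                phi = np.radians(rng.uniform(155.0, 180.0))  # A-H-D angle
                d_target = rng.uniform(2.6, 2.9)  # donor..acceptor distance
                # |HA| solving the triangle for the exact target distance
                disc = d_target**2 - (r_dh * np.sin(phi)) ** 2
                a_len = r_dh * np.cos(phi) + np.sqrt(max(disc, 0.0))
                direction = np.cos(phi) * (-u) + np.sin(phi) * v
                a_pos = h_pos + a_len * direction
            else:
                d_target = rng.uniform(3.3, 4.5)  # collinear but beyond 3.0 A
                a_pos = h_pos + (d_target - r_dh) * u
            coords[lig_beads] += a_pos - coords[acceptor]

        frames[f] = coords

    zeros = np.zeros(spec.n_frames)
    return TrajectoryEnsemble(
        coords=frames,
        frame_potential=zeros.copy(),
        frame_boost=zeros.copy(),
        timestep=0.0,
        temperature=0.0,
        seed=spec.seed,
        provenance="synthetic",
    )
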