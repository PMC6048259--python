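"""Trajectory interaction analysis: contacts, hydrogen bonds, HbR statistics,
difference maps, RMSD/RMSF and native-contact reaction coordinates.

Conventions fixed here: a residue pair is "in contact" when the distance
between the residues' centres of mass is within (<=) 6 A; a hydrogen bond is
recorded when a donor heavy atom is within (<=) 3.0 A of an acceptor and the
acceptor-hydrogen-donor angle is >= 135 deg; frame subsampling takes every
stride-th frame starting at the first.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_DOWN, Decimal

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .toysys import ToySystem
from .trajectory import TrajectoryEnsemble

CONTACT_CUTOFF = 6.0  # A, centre-of-mass criterion
HBOND_DISTANCE = 3.0  # A, donor..acceptor heavy-atom distance
HBOND_ANGLE = 135.0  # deg, acceptor-H-donor


def residue_com(system: ToySystem, coords: np.ndarray, residue: int) -> np.ndarray:
    """Mass-weighted centre of mass of one residue."""
    beads = system.residue_beads(residue)
    w = system.bead_masses[beads] / system.bead_masses[beads].sum()
    return w @ np.asarray(coords)[beads]


def _chain_res_coms(system: ToySystem, coords: np.ndarray, residues) -> np.ndarray:
    return np.array([residue_com(system, coords, int(r)) for r in residues])


@dataclass
class ContactMap:
    """Receptor-residue x ligand-residue contact frequencies in [0, 1]."""

    frequencies: np.ndarray  # (n_rec_res, n_lig_res)
    receptor_residues: np.ndarray  # global residue indices (rows)
    ligand_residues: np.ndarray  # global residue indices (columns)
    cutoff: float
    n_frames: int


def contact_map(
    traj: TrajectoryEnsemble, system: ToySystem, cutoff: float = CONTACT_CUTOFF
) -> ContactMap:
    """Fraction of frames in which each cross-chain residue pair is in contact."""
    rec = system.receptor_residues
    lig = system.ligand_residues
    hits = np.zeros((rec.size, lig.size))
    for f in range(traj.n_frames):
        rc = _chain_res_coms(system, traj.coords[f], rec)
        lc = _chain_res_coms(system, traj.coords[f], lig)
        d = np.linalg.norm(rc[:, None, :] - lc[None, :, :], axis=2)
        hits += d <= cutoff
    return ContactMap(
        frequencies=hits / traj.n_frames,
        receptor_residues=rec,
        ligand_residues=lig,
        cutoff=cutoff,
        n_frames=traj.n_frames,
    )


def contact_difference(map_mut: ContactMap, map_wt: ContactMap) -> np.ndarray:
    """Elementwise mutant - wild-type frequency change (negative = weakened)."""
    if map_mut.frequencies.shape != map_wt.frequencies.shape:
        raise ValueError("contact maps must cover the same residue grid")
    return map_mut.frequencies - map_wt.frequencies


@dataclass
class HBondRecord:
    donor: int
    hydrogen: int
    acceptor: int
    distance: float  # donor..acceptor, A
    angle: float  # acceptor-H-donor, deg
    frame: int = 0

    def __post_init__(self) -> None:
        if self.distance > HBOND_DISTANCE + 1e-12:
            raise ValueError("record violates the distance criterion")
        if self.angle < HBOND_ANGLE - 1e-12:
            raise ValueError("record violates the angle criterion")


def detect_hbonds(system: ToySystem, coords: np.ndarray, frame: int = 0):
    """All donor-H-acceptor triplets meeting the 3.0 A / >=135 deg criterion."""
    coords = np.asarray(coords, dtype=float)
    records = []
    for donor, hydrogen, acceptors in system.hbond_sites:
        if hydrogen is None:
            raise ValueError(f"donor bead {donor} has no hydrogen bead")
        d_pos, h_pos = coords[donor], coords[hydrogen]
        for acc in acceptors:
            a_pos = coords[acc]
            dist = float(np.linalg.norm(d_pos - a_pos))
            if dist > HBOND_DISTANCE:
                continue
            v1, v2 = a_pos - h_pos, d_pos - h_pos
            n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
            if n1 < 1e-10 or n2 < 1e-10:
                continue
            ang = float(
                np.degrees(np.arccos(np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)))
            )
            if ang >= HBOND_ANGLE:
                records.append(
                    HBondRecord(donor, hydrogen, int(acc), dist, ang, frame)
                )
    return records


def subsample(frame_indices, stride: int):
    """Every stride-th frame starting at the first; length = ceil(n / stride)."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    idx = np.asarray(frame_indices)
    return idx[::stride]


def hbond_pair_counts(
    traj: TrajectoryEnsemble, system: ToySystem, stride: int = 1
) -> dict:
    """Total hydrogen-bond counts per residue pair over subsampled frames.

    Counts carry multiplicity: a frame with two bonds between the same
    residue pair contributes two.
    """
    counts: dict = {}
    frames = subsample(np.arange(traj.n_frames), stride)
    for f in frames:
        for rec in detect_hbonds(system, traj.coords[f], frame=int(f)):
            pair = (
                int(system.residue_ids[rec.donor]),
                int(system.residue_ids[rec.acceptor]),
            )
            counts[pair] = counts.get(pair, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# HbR statistics (four-system hydrogen-bond ratio table)
# ---------------------------------------------------------------------------


def _ratio(num: int, den: int) -> float:
    """HbR with the zero-denominator convention (ratio = 0)."""
    return 0.0 if den == 0 else num / den


def round_ratio(num: int, den: int, decimals: int = 2) -> float:
    """Display rounding of a count ratio: exact decimal, ties rounded down.

    The printed reference table resolves the only exact tie (0.375) downward,
    so half-down is the convention that reproduces every printed entry.
    """
    if den == 0:
        return 0.0
    q = Decimal(num) / Decimal(den)
    return float(q.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_DOWN))


def hbr_display_decimals(hbr1_counts, hbr2_counts) -> int:
    """2 decimals, escalated to 3 when the two ratios collide at 2 but differ."""
    (n1, d1), (n2, d2) = hbr1_counts, hbr2_counts
    r1, r2 = _ratio(n1, d1), _ratio(n2, d2)
    if r1 != r2 and round_ratio(n1, d1) == round_ratio(n2, d2):
        return 3
    return 2


def hbr_table(counts_tlv, counts_tdelv, counts_tl, counts_tdel) -> pd.DataFrame:
    """HbR1/HbR2 table across the four systems.

    Inputs map residue-pair keys to hydrogen-bond counts in: wild type +
    nanobody (TLV), mutant + nanobody (TdELV), wild type alone (TL), mutant
    alone (TdEL).  HbR1 = TdELV/TLV and HbR2 = TdEL/TL with the
    zero-denominator-gives-0 convention.  The comparison flag is "Yes" when
    HbR1 > HbR2 (nanobody-induced stabilisation of the mutant complex), "No"
    when both are defined and HbR1 <= HbR2, and "-" (indeterminate) when the
    mutant counts vanish in both conditions.
    """
    pairs = sorted(
        set(counts_tlv) | set(counts_tdelv) | set(counts_tl) | set(counts_tdel),
        key=lambda p: str(p),
    )
    rows = []
    for pair in pairs:
        tlv = int(counts_tlv.get(pair, 0))
        tdelv = int(counts_tdelv.get(pair, 0))
        tl = int(counts_tl.get(pair, 0))
        tdel = int(counts_tdel.get(pair, 0))
        if min(tlv, tdelv, tl, tdel) < 0:
            raise ValueError("hydrogen-bond counts must be non-negative")
        hbr1, hbr2 = _ratio(tdelv, tlv), _ratio(tdel, tl)
        if tdelv == 0 and tdel == 0:
            flag = "-"
        elif hbr1 > hbr2:
            flag = "Yes"
        else:
            flag = "No"
        dec = hbr_display_decimals((tdelv, tlv), (tdel, tl))
        rows.append(
            {
                "pair": pair,
                "tlv": tlv,
                "tdelv": tdelv,
                "hbr1": hbr1,
                "hbr1_display": round_ratio(tdelv, tlv, dec),
                "tl": tl,
                "tdel": tdel,
                "hbr2": hbr2,
                "hbr2_display": round_ratio(tdel, tl, dec),
                "display_decimals": dec,
                "flag": flag,
            }
        )
    return pd.DataFrame(rows)


def hbond_count_significance(
    per_frame_counts_a, per_frame_counts_b, block: int = 10
) -> float:
    """Two-sided Mann-Whitney U on block-averaged per-frame totals.

    Blocking (non-overlapping means of ``block`` frames) blunts the frame
    autocorrelation of MD-like series.
    """
    from scipy import stats

    a = np.asarray(per_frame_counts_a, dtype=float)
    b = np.asarray(per_frame_counts_b, dtype=float)

    def blocked(x):
        n = (x.size // block) * block
        if n == 0:
            return x
        return x[:n].reshape(-1, block).mean(axis=1)

    ba, bb = blocked(a), blocked(b)
    if np.array_equal(ba, bb):
        return 1.0
    res = stats.mannwhitneyu(ba, bb, alternative="two-sided")
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# RMSD / RMSF / native contacts
# ---------------------------------------------------------------------------


def _superpose(mobile: np.ndarray, reference: np.ndarray, weights=None):
    """Optimal-rotation least-squares fit; returns transformed mobile coords."""
    w = None if weights is None else np.asarray(weights, dtype=float)
    mc = np.average(mobile, axis=0, weights=w)
    rc = np.average(reference, axis=0, weights=w)
    rot, _ = Rotation.align_vectors(reference - rc, mobile - mc, weights=w)
    return rot.apply(mobile - mc) + rc


def rmsd(coords: np.ndarray, ref_coords: np.ndarray, selection=None) -> float:
    """Least-squares superposition RMSD (A)."""
    coords = np.asarray(coords, dtype=float)
    ref = np.asarray(ref_coords, dtype=float)
    if selection is not None:
        sel = np.asarray(selection, dtype=int)
        coords, ref = coords[sel], ref[sel]
    fitted = _superpose(coords, ref)
    return float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))


def rmsf(traj: TrajectoryEnsemble, system: ToySystem, selection=None) -> pd.DataFrame:
    """Per-residue fluctuation about the mean structure after superposition.

    Frames are aligned to the first frame, a mean structure is formed, frames
    are re-aligned to it, and the per-bead variance is aggregated into a
    mass-weighted per-residue RMSF.
    """
    sel = (
        np.arange(system.n_beads)
        if selection is None
        else np.asarray(selection, dtype=int)
    )
    frames = traj.coords[:, sel, :]
    aligned = np.array([_superpose(f, frames[0]) for f in frames])
    mean = aligned.mean(axis=0)
    aligned = np.array([_superpose(f, mean) for f in aligned])
    mean = aligned.mean(axis=0)
    var = np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0)  # per bead

    res_ids = system.residue_ids[sel]
    masses = system.bead_masses[sel]
    rows = []
    for r in np.unique(res_ids):
        m = res_ids == r
        w = masses[m] / masses[m].sum()
        rows.append(
            {
                "residue": int(r),
                "name": system.residue_names[int(r)],
                "chain": system.chain_ids[int(r)],
                "rmsf": float(np.sqrt(w @ var[m])),
            }
        )
    return pd.DataFrame(rows)


def reference_contacts(
    system: ToySystem, coords: np.ndarray | None = None, cutoff: float = CONTACT_CUTOFF
):
    """Cross-chain residue pairs in contact in a reference structure."""
    coords = system.bead_positions if coords is None else coords
    rec, lig = system.receptor_residues, system.ligand_residues
    rc = _chain_res_coms(system, coords, rec)
    lc = _chain_res_coms(system, coords, lig)
    d = np.linalg.norm(rc[:, None, :] - lc[None, :, :], axis=2)
    ii, jj = np.nonzero(d <= cutoff)
    return [(int(rec[i]), int(lig[j])) for i, j in zip(ii, jj)]


def native_contact_fraction(
    coords: np.ndarray, system: ToySystem, reference, cutoff: float = CONTACT_CUTOFF
) -> float:
    """Fraction Q of reference residue contacts present in this frame."""
    if len(reference) == 0:
        raise ValueError("reference contact set is empty")
    hits = 0
    for ri, rj in reference:
        d = np.linalg.norm(
            residue_com(system, coords, ri) - residue_com(system, coords, rj)
        )
        if d <= cutoff:
            hits += 1
    return hits / len(reference)
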