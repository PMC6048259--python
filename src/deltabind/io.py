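"""File formats: fixed-width PDB for systems, a binary container for trajectories.

PDB files written here carry ``REMARK 250`` lines recording how the toy
system was built (variant, chain sizes, seed) so that a system file can be
reloaded as a full ``ToySystem`` with force-field parameters regenerated
deterministically.  Coordinates follow the PDB fixed-width convention
(3 decimals); receptor is chain A, ligand chain B, residues numbered from 1
per chain.

Trajectories use a small self-describing binary format ("DTJ"): a fixed
header (magic, version, shape, field flags, timestep, temperature, seed,
provenance) followed by float64 coordinate and energy arrays.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

from .trajectory import PROVENANCES, TrajectoryEnsemble
from .toysys import ToySystem, build_toy_dimer


class PdbParseError(ValueError):
    """Malformed PDB record; the message names the offending line number."""


@dataclass
class PdbModel:
    """Plain coordinate model parsed from a PDB file."""

    bead_names: list
    residue_names: list  # per bead
    residue_seq: list  # per bead, per-chain numbering as printed
    chain_ids: list  # per bead
    coords: np.ndarray
    remarks: dict


def write_pdb(system: ToySystem, coords: np.ndarray, path) -> None:
    """Write a system + coordinates as fixed-width PDB ATOM records."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (system.n_beads, 3):
        raise ValueError(
            f"coordinate count {coords.shape} does not match bead count {system.n_beads}"
        )
    lines = []
    meta = system.meta
    if {"n_receptor_res", "n_ligand_res", "seed"} <= set(meta):
        lines.append(
            "REMARK 250 DELTABIND "
            f"variant={system.variant} nrec={meta['n_receptor_res']} "
            f"nlig={meta['n_ligand_res']} seed={meta['seed']}"
        )
    serial = 0
    # per-chain residue numbering from 1
    res_seq = {}
    counter = {}
    for r, chain in enumerate(system.chain_ids):
        counter[chain] = counter.get(chain, 0) + 1
        res_seq[r] = counter[chain]
    prev_chain = None
    for i in range(system.n_beads):
        r = int(system.residue_ids[i])
        chain = system.chain_ids[r]
        if prev_chain is not None and chain != prev_chain:
            lines.append("TER")
        prev_chain = chain
        serial += 1
        name = system.bead_names[i]
        x, y, z = coords[i]
        lines.append(
            f"ATOM  {serial:>5d} {name:<4s}{system.residue_names[r]:>4s} "
            f"{chain}{res_seq[r]:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{1.0:6.2f}{0.0:6.2f}          {name[0]:>2s}"
        )
    lines.append("TER")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_pdb(path) -> PdbModel:
    """Parse ATOM records (and DELTABIND remarks) from a PDB file."""
    names, res_names, res_seq, chains = [], [], [], []
    xyz = []
    remarks: dict = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("REMARK 250 DELTABIND"):
                for token in line.split()[3:]:
                    key, _, value = token.partition("=")
                    remarks[key] = value
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if len(line) < 54:
                raise PdbParseError(f"line {lineno}: truncated ATOM record")
            try:
                names.append(line[12:16].strip())
                res_names.append(line[17:21].strip())
                chains.append(line[21].strip())
                res_seq.append(int(line[22:26]))
                xyz.append(
                    (float(line[30:38]), float(line[38:46]), float(line[46:54]))
                )
            except ValueError as exc:
                raise PdbParseError(f"line {lineno}: {exc}") from exc
    return PdbModel(
        bead_names=names,
        residue_names=res_names,
        residue_seq=res_seq,
        chain_ids=chains,
        coords=np.asarray(xyz, dtype=float).reshape(-1, 3),
        remarks=remarks,
    )


def load_system(path) -> ToySystem:
    """Rebuild a full ToySystem from a PDB written by :func:`write_pdb`.

    The force field is regenerated from the construction metadata in the
    DELTABIND remark; coordinates come from the file.
    """
    model = read_pdb(path)
    required = {"variant", "nrec", "nlig", "seed"}
    if not required <= set(model.remarks):
        raise PdbParseError(
            "PDB lacks the DELTABIND construction remark; cannot rebuild the system"
        )
    system = build_toy_dimer(
        int(model.remarks["nrec"]),
        int(model.remarks["nlig"]),
        model.remarks["variant"],
        int(model.remarks["seed"]),
    )
    if model.coords.shape[0] != system.n_beads:
        raise PdbParseError(
            f"PDB has {model.coords.shape[0]} beads, metadata implies {system.n_beads}"
        )
    system.bead_positions = model.coords
    return system


# ---------------------------------------------------------------------------
# DTJ binary trajectory container
# ---------------------------------------------------------------------------

_MAGIC = b"DTJ1"
_HEADER = struct.Struct("<4sIQQBddq B")  # magic, version, frames, beads, flags,
# timestep, temperature, seed, provenance code


class TrajectoryFormatError(ValueError):
    pass


def write_traj(ensemble: TrajectoryEnsemble, path) -> None:
    flags = 0b11  # potentials and boosts always stored
    header = _HEADER.pack(
        _MAGIC,
        1,
        ensemble.n_frames,
        ensemble.n_beads,
        flags,
        float(ensemble.timestep),
        float(ensemble.temperature),
        int(ensemble.seed),
        PROVENANCES.index(ensemble.provenance),
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(np.ascontiguousarray(ensemble.coords, dtype="<f8").tobytes())
        fh.write(np.ascontiguousarray(ensemble.frame_potential, dtype="<f8").tobytes())
        fh.write(np.ascontiguousarray(ensemble.frame_boost, dtype="<f8").tobytes())


def read_traj(path) -> TrajectoryEnsemble:
    with open(path, "rb") as fh:
        raw = fh.read(_HEADER.size)
        if len(raw) < _HEADER.size:
            raise TrajectoryFormatError("truncated header (empty or clipped file)")
        magic, version, n_frames, n_beads, flags, dt, temp, seed, prov = _HEADER.unpack(
            raw
        )
        if magic != _MAGIC:
            raise TrajectoryFormatError(f"bad magic {magic!r}")
        if version != 1:
            raise TrajectoryFormatError(f"unsupported format version {version}")
        n_c = n_frames * n_beads * 3
        body = np.frombuffer(fh.read(), dtype="<f8")
        expected = n_c + 2 * n_frames
        if body.size != expected:
            raise TrajectoryFormatError(
                f"payload size {body.size} does not match header shape ({expected})"
            )
    coords = body[:n_c].reshape(n_frames, n_beads, 3).copy()
    pot = body[n_c : n_c + n_frames].copy()
    boost = body[n_c + n_frames :].copy()
    return TrajectoryEnsemble(
        coords=coords,
        frame_potential=pot,
        frame_boost=boost,
        timestep=dt,
        temperature=temp,
        seed=seed,
        provenance=PROVENANCES[prov],
    )
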