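"""Trajectory container shared by the sampling engines and the analyses."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PROVENANCES = ("cMD", "GaMD", "ABMD", "synthetic")


@dataclass
class TrajectoryEnsemble:
    """Frames of bead coordinates plus per-frame energy bookkeeping.

    ``frame_potential`` holds the unbiased potential V_original of each saved
    frame; ``frame_boost`` holds the boost energy V_boost added by an
    accelerated run (zero for unbiased or synthetic ensembles).
    """

    coords: np.ndarray  # (n_frames, n_beads, 3), A
    frame_potential: np.ndarray  # (n_frames,), kcal/mol
    frame_boost: np.ndarray  # (n_frames,), kcal/mol
    timestep: float = 0.0  # fs between saved frames' parent steps
    temperature: float = 0.0  # K
    seed: int = 0
    provenance: str = "synthetic"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.frame_potential = np.asarray(self.frame_potential, dtype=float)
        self.frame_boost = np.asarray(self.frame_boost, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, beads, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("a trajectory needs at least one frame")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")
        n = self.coords.shape[0]
        if self.frame_potential.shape != (n,) or self.frame_boost.shape != (n,):
            raise ValueError("per-frame energy arrays must match the frame count")
        if np.any(self.frame_boost < 0):
            raise ValueError("frame_boost must be non-negative")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"provenance must be one of {PROVENANCES}")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_beads(self) -> int:
        return self.coords.shape[1]

    def sliced(self, idx) -> "TrajectoryEnsemble":
        """Return a sub-trajectory restricted to the given frame indices."""
        idx = np.asarray(idx)
        return TrajectoryEnsemble(
            coords=self.coords[idx],
            frame_potential=self.frame_potential[idx],
            frame_boost=self.frame_boost[idx],
            timestep=self.timestep,
            temperature=self.temperature,
            seed=self.seed,
            provenance=self.provenance,
            extra=dict(self.extra),
        )

    def discard_equilibration(self, fraction: float = 0.1) -> "TrajectoryEnsemble":
        """Drop the first ``fraction`` of frames (burn-in window)."""
        if not 0.0 <= fraction < 1.0:
            raise ValueError("fraction must be in [0, 1)")
        start = int(np.floor(self.n_frames * fraction))
        start = min(start, self.n_frames - 1)
        return self.sliced(np.arange(start, self.n_frames))
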