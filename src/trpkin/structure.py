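"""Backbone-flexibility analysis: rigid-body superposition, per-residue Calpha
RMSF profiles, and RMSF differences between two systems.

Frames are superposed onto the first frame by the least-squares optimal
rigid transform (proper rotation, via scipy's Kabsch implementation), then
the root-mean-square fluctuation of each atom about its post-superposition
mean position (or optionally about its first-frame position) is reported per
residue. The signed difference of two profiles localises flexibility
changes, e.g. between apo- and metal-loaded protein.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, InsufficientDataError, InvalidInputError


@dataclass(frozen=True)
class Trajectory:
    """Per-frame Calpha coordinates (frames x atoms x 3, Angstrom)."""

    coords: np.ndarray
    residue_ids: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        r = np.asarray(self.residue_ids)
        object.__setattr__(self, "coords", c)
        object.__setattr__(self, "residue_ids", r)
        if c.ndim != 3 or c.shape[2] != 3:
            raise InvalidInputError("coords must have shape (frames, atoms, 3)")
        if r.shape != (c.shape[1],):
            raise InvalidInputError("one residue id per atom is required")
        if not np.all(np.isfinite(c)):
            raise InvalidInputError("coordinates contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


@dataclass(frozen=True)
class RMSFProfile:
    """Per-residue fluctuation magnitudes (Angstrom) with the reference policy
    recorded ('mean_structure', 'first_frame', or 'difference')."""

    residue_ids: np.ndarray
    rmsf_A: np.ndarray
    reference_policy: str

    def __post_init__(self) -> None:
        if np.asarray(self.residue_ids).shape != np.asarray(self.rmsf_A).shape:
            raise InvalidInputError("one RMSF value per residue is required")


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns (rotation 3x3 with det +1, translation 3-vector, rmsd in the
    input units) such that ``mobile @ rotation.T + translation`` best matches
    ``reference``.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise InvalidInputError("point sets must be matching (n, 3) arrays")
    if mob.shape[0] < 3:
        raise InvalidInputError("need >= 3 points for a unique superposition")
    w = np.ones(len(mob)) if weights is None else np.asarray(weights, dtype=float)
    wsum = w.sum()
    cm = (w[:, None] * mob).sum(axis=0) / wsum
    cr = (w[:, None] * ref).sum(axis=0) / wsum
    mob_c, ref_c = mob - cm, ref - cr
    if (
        np.linalg.matrix_rank(ref_c, tol=1e-8 * max(1.0, np.abs(ref_c).max())) < 2
        or np.linalg.matrix_rank(mob_c, tol=1e-8 * max(1.0, np.abs(mob_c).max())) < 2
    ):
        raise DegenerateGeometryError(
            "point set is collinear or coincident; rotation is not unique"
        )
    rot, _ = Rotation.align_vectors(ref_c, mob_c, weights=w)
    R = rot.as_matrix()
    moved = mob_c @ R.T
    rmsd = float(np.sqrt((w * ((moved - ref_c) ** 2).sum(axis=1)).sum() / wsum))
    translation = cr - cm @ R.T
    return R, translation, rmsd


def superpose_trajectory(traj: Trajectory, reference_frame: int = 0) -> Trajectory:
    """Superpose every frame onto one reference frame (unweighted)."""
    ref = traj.coords[reference_frame]
    aligned = np.empty_like(traj.coords)
    for i, frame in enumerate(traj.coords):
        R, t, _ = superpose(frame, ref)
        aligned[i] = frame @ R.T + t
    return Trajectory(coords=aligned, residue_ids=traj.residue_ids)


def rmsf(traj: Trajectory, ref_policy: str = "mean_structure") -> RMSFProfile:
    """Per-residue Calpha RMSF after superposing all frames onto frame 1.

    ``mean_structure`` (default, the standard convention) measures
    fluctuations about the post-superposition mean position;
    ``first_frame`` measures deviations from the first-frame coordinates.
    """
    if traj.n_frames < 2:
        raise InsufficientDataError("RMSF needs at least 2 frames")
    if ref_policy not in ("mean_structure", "first_frame"):
        raise InvalidInputError(f"unknown reference policy {ref_policy!r}")
    aligned = superpose_trajectory(traj, reference_frame=0)
    ref = (
        aligned.coords.mean(axis=0)
        if ref_policy == "mean_structure"
        else aligned.coords[0]
    )
    dev2 = ((aligned.coords - ref) ** 2).sum(axis=2)  # (frames, atoms)
    values = np.sqrt(dev2.mean(axis=0))
    return RMSFProfile(
        residue_ids=traj.residue_ids.copy(), rmsf_A=values, reference_policy=ref_policy
    )


def delta_rmsf(a: RMSFProfile, b: RMSFProfile) -> RMSFProfile:
    """Signed per-residue difference a - b; residue indices must match."""
    if a.residue_ids.shape != b.residue_ids.shape or np.any(
        a.residue_ids != b.residue_ids
    ):
        raise InvalidInputError("residue indices of the two profiles do not match")
    return RMSFProfile(
        residue_ids=a.residue_ids.copy(),
        rmsf_A=a.rmsf_A - b.rmsf_A,
        reference_policy="difference",
    )
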