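"""Anchor atoms and the aligned ligand-RMSD collective variable.

The collective variable biased during the simulation is the RMSD of the
ligand heavy atoms relative to their coordinates at the end of equilibration,
measured after superposing each frame onto the reference using "anchor"
atoms: binding-site protein Cα atoms. The superposition removes global
protein translation/rotation so the CV reports genuine ligand motion within
the pocket.

Units: structural coordinates are Å; the CV value is returned in nm, matching
the convention in which the Gaussian hill width (0.002 nm) is expressed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .system_io import ComplexStructure

__all__ = [
    "AnchorSelection",
    "AlignedRmsdCV",
    "RigidTransform",
    "select_anchor_atoms",
    "superpose_on_anchors",
    "evaluate_cv",
    "flat_bottom_restraint",
    "ANGSTROM_PER_NM",
]

ANGSTROM_PER_NM = 10.0


@dataclass(frozen=True)
class AnchorSelection:
    """Protein Cα atoms near the ligand, used for frame superposition."""

    atom_indices: np.ndarray
    cutoff_used: float  # Å, after any auto-expansion

    def __post_init__(self) -> None:
        object.__setattr__(self, "atom_indices",
                           np.asarray(self.atom_indices, dtype=int))
        if len(self.atom_indices) < 3:
            raise ValueError("anchor selection needs >= 3 atoms")


@dataclass(frozen=True)
class RigidTransform:
    """x -> rotation @ x + translation (proper rotation, det = +1)."""

    rotation: np.ndarray     # (3, 3)
    translation: np.ndarray  # (3,)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class AlignedRmsdCV:
    """Reference coordinates + ligand heavy atoms + anchors defining the CV."""

    reference_coords: np.ndarray      # (n_atoms, 3) Å, full system
    ligand_heavy_indices: np.ndarray  # indices into the full system
    anchor: AnchorSelection

    def __post_init__(self) -> None:
        self.reference_coords = np.asarray(self.reference_coords, dtype=float)
        self.ligand_heavy_indices = np.asarray(self.ligand_heavy_indices, dtype=int)
        if len(self.ligand_heavy_indices) == 0:
            raise ValueError("ligand_heavy_indices must be non-empty")

    @classmethod
    def from_complex(cls, complex: ComplexStructure, anchor_cutoff: float = 10.0,
                     reference_coords: np.ndarray | None = None) -> "AlignedRmsdCV":
        ref = complex.coords if reference_coords is None else np.asarray(reference_coords, float)
        return cls(reference_coords=ref,
                   ligand_heavy_indices=complex.ligand_heavy_indices,
                   anchor=select_anchor_atoms(complex, anchor_cutoff))


def select_anchor_atoms(complex: ComplexStructure, cutoff: float = 10.0) -> AnchorSelection:
    """All protein Cα atoms with any ligand heavy atom within ``cutoff`` Å.

    If fewer than 3 qualify, the cutoff is widened in 1 Å steps until at
    least 3 do; ``cutoff_used`` records the final value.
    """
    ca = complex.calpha_indices
    if len(ca) == 0:
        raise ValueError("protein has no Calpha atoms; cannot select anchors")
    lig = complex.ligand_heavy_indices
    if len(lig) == 0:
        raise ValueError("complex has no ligand heavy atoms")
    coords = complex.coords
    dmin = cdist(coords[ca], coords[lig]).min(axis=1)
    c = float(cutoff)
    while np.count_nonzero(dmin <= c) < 3:
        if c > dmin.max() + 1.0:  # unreachable guard; all Cα are within dmin.max()
            raise ValueError("cannot find 3 anchor atoms")
        c += 1.0
    return AnchorSelection(atom_indices=ca[dmin <= c], cutoff_used=c)


def superpose_on_anchors(frame: np.ndarray, cv: AlignedRmsdCV) -> RigidTransform:
    """Least-squares (Kabsch) rigid transform taking the frame's anchor atoms
    onto the reference anchor atoms."""
    idx = cv.anchor.atom_indices
    mobile = np.asarray(frame, dtype=float)[idx]
    target = cv.reference_coords[idx]
    mob_c = mobile.mean(axis=0)
    tgt_c = target.mean(axis=0)
    a = mobile - mob_c
    b = target - tgt_c
    # degenerate (collinear) anchors leave the rotation underdetermined
    if np.linalg.matrix_rank(a, tol=1e-8) < 2:
        raise ValueError("anchor atoms are collinear; superposition is degenerate")
    rot, _ = Rotation.align_vectors(b, a)
    r = rot.as_matrix()
    return RigidTransform(rotation=r, translation=tgt_c - r @ mob_c)


def evaluate_cv(frame: np.ndarray, cv: AlignedRmsdCV) -> float:
    """Aligned RMSD (nm) of the ligand heavy atoms versus the reference.

    The frame is superposed on the anchors, then the plain (no ligand
    fitting) RMSD of the ligand heavy atoms is computed.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape != cv.reference_coords.shape:
        raise ValueError("frame atom count differs from reference")
    tf = superpose_on_anchors(frame, cv)
    lig = cv.ligand_heavy_indices
    moved = tf.apply(frame[lig])
    ref = cv.reference_coords[lig]
    rmsd_A = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return rmsd_A / ANGSTROM_PER_NM


def flat_bottom_restraint(frame: np.ndarray, cv: AlignedRmsdCV,
                          radius: float, k: float = 0.0) -> float:
    """Flat-bottom energy (kcal/mol) between ligand and anchor centroids.

    Zero inside ``radius`` (nm); half-harmonic ``0.5*k*(d - radius)**2``
    outside, with ``k`` in kcal/mol/nm². The protocol default k = 0 makes
    this a pure bookkeeping wrapper.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if k < 0:
        raise ValueError("k must be >= 0")
    frame = np.asarray(frame, dtype=float)
    d_A = np.linalg.norm(frame[cv.ligand_heavy_indices].mean(axis=0)
                         - frame[cv.anchor.atom_indices].mean(axis=0))
    d = d_A / ANGSTROM_PER_NM
    if d <= radius or k == 0.0:
        return 0.0
    return 0.5 * k * (d - radius) ** 2
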