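"""Pose-stability scoring of biased trajectories.

Four metrics summarise how much a candidate pose moved under the bias:

* **PoseScore** — tail-window mean of the anchor-aligned ligand heavy-atom
  RMSD (Å). Lower = the pose stayed put.
* **PersScore** — fraction of the protein-ligand hydrogen bonds present at
  the start that persist through the tail window. Undefined (flagged, value
  0) when the pose forms no initial hydrogen bonds.
* **ContactScore** — tail-window mean of the protein-ligand heavy-atom
  contact count (pairs within 3.5 Å, inclusive) divided by the count at the
  start. May exceed 1 if contacts increase; not clipped.
* **CompScore** — PoseScore − 5·ContactScore (coefficient configurable);
  more negative = more stable.

All series are measured every 100 ps (configurable stride) and the tail
window defaults to the last 2 ns of the run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .anchors_cv import AlignedRmsdCV, ANGSTROM_PER_NM, evaluate_cv
from .config import ProtocolConfig
from .system_io import ComplexStructure, Trajectory

__all__ = [
    "ScoreSeries",
    "PoseScores",
    "recenter_trajectory",
    "rmsd_series",
    "pose_score",
    "detect_hbonds",
    "pers_score",
    "contact_count",
    "contact_score",
    "comp_score",
    "score_replica",
]

COVALENT_H_CUTOFF = 1.25  # Å, H bonded to nearest heavy atom within this
HBOND_ELEMENTS = {"N", "O", "S"}


@dataclass
class ScoreSeries:
    """Per-frame measurements behind the pose-stability scores."""

    times: np.ndarray                 # ps
    rmsd: np.ndarray                  # Å
    n_hbonds: np.ndarray              # protein-ligand H-bonds per frame
    n_contacts: np.ndarray            # protein-ligand heavy contacts per frame
    initial_hbonds: frozenset         # (donor, hydrogen, acceptor) at frame 0
    initial_contacts: int
    n_initial_hbonds_present: np.ndarray = field(default=None)  # per frame

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        for name in ("rmsd", "n_hbonds", "n_contacts"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != len(self.times):
                raise ValueError(f"{name} length differs from times")
            setattr(self, name, arr)
        if self.initial_contacts < 0:
            raise ValueError("initial_contacts must be >= 0")
        if self.n_initial_hbonds_present is None:
            self.n_initial_hbonds_present = np.zeros(len(self.times), dtype=int)


@dataclass
class PoseScores:
    pose_score: float       # Å
    pers_score: float       # in [0, 1]
    contact_score: float    # >= 0, unclipped
    comp_score: float
    pers_defined: bool = True

    def __post_init__(self) -> None:
        if self.pose_score < 0:
            raise ValueError("pose_score must be >= 0")
        if not 0.0 <= self.pers_score <= 1.0:
            raise ValueError("pers_score must be in [0, 1]")


# --------------------------------------------------------------------------
# trajectory preparation
# --------------------------------------------------------------------------

def recenter_trajectory(traj: Trajectory, complex: ComplexStructure) -> Trajectory:
    """Make the solute whole across periodic boundaries and center it.

    The ligand is shifted, as a rigid group, by the whole-box translation
    that brings its centroid into the protein centroid's minimum image, then
    the solute centroid is moved to the box center. Orthorhombic boxes only;
    a missing box passes frames through unchanged with a warning flag.
    """
    if traj.box is None:
        warnings.warn("no box information; recentering skipped", stacklevel=2)
        return Trajectory(frames=traj.frames.copy(), times=traj.times.copy(),
                          box=None, recentered=False)
    lengths = traj.box[:3]
    if not np.allclose(traj.box[3:], 90.0):
        raise ValueError("recentering supports orthorhombic boxes only")
    prot = complex.protein_indices
    lig = complex.ligand_indices
    frames = traj.frames.copy()
    for f in frames:
        shift = np.round((f[lig].mean(axis=0) - f[prot].mean(axis=0)) / lengths)
        f[lig] -= shift * lengths
        solute = np.concatenate([prot, lig])
        f += lengths / 2.0 - f[solute].mean(axis=0)
    return Trajectory(frames=frames, times=traj.times.copy(), box=traj.box.copy(),
                      recentered=True)


def _stride_indices(times: np.ndarray, stride_ps: float) -> np.ndarray:
    """Frames lying on the stride grid anchored at the first frame."""
    rel = (times - times[0]) / stride_ps
    on_grid = np.abs(rel - np.round(rel)) < 1e-6
    idx = np.nonzero(on_grid)[0]
    return idx if len(idx) >= 2 else np.arange(len(times))


def rmsd_series(traj: Trajectory, cv: AlignedRmsdCV) -> np.ndarray:
    """Anchor-aligned ligand heavy-atom RMSD (Å) for every frame."""
    return np.array([evaluate_cv(f, cv) * ANGSTROM_PER_NM for f in traj.frames])


# --------------------------------------------------------------------------
# per-frame geometry
# --------------------------------------------------------------------------

def _pair_distances(a: np.ndarray, b: np.ndarray, box) -> np.ndarray:
    if box is None:
        return cdist(a, b)
    lengths = np.asarray(box[:3], dtype=float)
    d = a[:, None, :] - b[None, :, :]
    d -= np.round(d / lengths) * lengths
    return np.sqrt(np.sum(d * d, axis=-1))


def contact_count(frame: np.ndarray, complex: ComplexStructure,
                  cutoff: float = 3.5) -> int:
    """Protein-heavy/ligand-heavy atom pairs within ``cutoff`` Å (inclusive,
    minimum-image when a box is present)."""
    frame = np.asarray(frame, dtype=float)
    p = complex.protein_heavy_indices
    l = complex.ligand_heavy_indices
    if len(p) == 0 or len(l) == 0:
        return 0
    d = _pair_distances(frame[p], frame[l], complex.box)
    return int(np.count_nonzero(d <= cutoff))


def detect_hbonds(frame: np.ndarray, complex: ComplexStructure,
                  d_cutoff: float = 3.5, angle_cutoff: float = 150.0) -> frozenset:
    """Protein-ligand hydrogen bonds as (donor, hydrogen, acceptor) triples.

    Geometric criterion: donor and acceptor are N/O/S heavy atoms on opposite
    sides of the interface, donor-acceptor distance <= ``d_cutoff`` Å and
    donor-H-acceptor angle >= ``angle_cutoff`` degrees. Hydrogens are
    assigned to the nearest heavy atom within a covalent cutoff.
    """
    frame = np.asarray(frame, dtype=float)
    atoms = complex.atoms
    hbonds = []
    for donor_role, acceptor_role in (("protein", "ligand"), ("ligand", "protein")):
        polar_d = [a.index for a in atoms
                   if a.role == donor_role and a.element in HBOND_ELEMENTS]
        acceptors = np.array([a.index for a in atoms
                              if a.role == acceptor_role and a.element in HBOND_ELEMENTS],
                             dtype=int)
        hydrogens = np.array([a.index for a in atoms
                              if a.role == donor_role and a.element == "H"], dtype=int)
        if not polar_d or len(acceptors) == 0 or len(hydrogens) == 0:
            continue
        # attach each hydrogen to its nearest polar heavy atom if covalent
        dh = _pair_distances(frame[hydrogens], frame[np.array(polar_d)], complex.box)
        for hi, h_idx in enumerate(hydrogens):
            di = int(np.argmin(dh[hi]))
            if dh[hi, di] > COVALENT_H_CUTOFF:
                continue
            d_idx = polar_d[di]
            da = _pair_distances(frame[[d_idx]], frame[acceptors], complex.box)[0]
            for ai, a_idx in enumerate(acceptors):
                if da[ai] > d_cutoff or a_idx == d_idx:
                    continue
                v1 = frame[d_idx] - frame[h_idx]
                v2 = frame[a_idx] - frame[h_idx]
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                if angle >= angle_cutoff:
                    hbonds.append((int(d_idx), int(h_idx), int(a_idx)))
    return frozenset(hbonds)


# --------------------------------------------------------------------------
# score summaries
# --------------------------------------------------------------------------

def _tail_mask(times: np.ndarray, tail_ns: float) -> np.ndarray:
    span_ns = (times[-1] - times[0]) / 1000.0
    if span_ns + 1e-9 < tail_ns:
        raise ValueError(
            f"trajectory spans {span_ns:.3f} ns, shorter than the "
            f"{tail_ns} ns tail window")
    mask = times > times[-1] - tail_ns * 1000.0
    if not np.any(mask):  # degenerate: tail == full length
        mask = np.ones_like(times, dtype=bool)
    return mask


def pose_score(series: ScoreSeries, tail_ns: float = 2.0) -> float:
    """Mean aligned ligand RMSD (Å) over the tail window."""
    return float(np.mean(series.rmsd[_tail_mask(series.times, tail_ns)]))


def pers_score(series: ScoreSeries, tail_ns: float = 2.0) -> tuple[float, bool]:
    """(fraction of initial hydrogen bonds persisting in the tail, defined?).

    Returns (0.0, False) when the pose forms no hydrogen bonds at the start
    — the metric's documented failure mode for apolar binders.
    """
    n0 = len(series.initial_hbonds)
    if n0 == 0:
        return 0.0, False
    mask = _tail_mask(series.times, tail_ns)
    frac = series.n_initial_hbonds_present[mask] / n0
    return float(np.mean(frac)), True


def contact_score(series: ScoreSeries, tail_ns: float = 2.0) -> float:
    """Tail-mean contact count normalised by the initial count (unclipped)."""
    if series.initial_contacts == 0:
        raise ValueError("no initial contacts; pose not in the pocket")
    mask = _tail_mask(series.times, tail_ns)
    return float(np.mean(series.n_contacts[mask] / series.initial_contacts))


def comp_score(pose_score: float, contact_score: float,
               coefficient: float = 5.0) -> float:
    """Composite stability score: PoseScore − coefficient·ContactScore."""
    if not (np.isfinite(pose_score) and np.isfinite(contact_score)):
        raise ValueError("scores must be finite")
    return float(pose_score - coefficient * contact_score)


# --------------------------------------------------------------------------
# replica pipeline
# --------------------------------------------------------------------------

def extract_series(traj: Trajectory, complex: ComplexStructure, cv: AlignedRmsdCV,
                   cfg: ProtocolConfig) -> ScoreSeries:
    """Measure RMSD, hydrogen bonds and contacts on the stride grid."""
    idx = _stride_indices(traj.times, cfg.stride_ps)
    frames = traj.frames[idx]
    times = traj.times[idx]
    rmsd = np.array([evaluate_cv(f, cv) * ANGSTROM_PER_NM for f in frames])
    initial_hb = detect_hbonds(frames[0], complex, cfg.hbond_distance, cfg.hbond_angle)
    initial_ct = contact_count(frames[0], complex, cfg.contact_cutoff)
    n_hb = np.empty(len(frames), dtype=int)
    n_ct = np.empty(len(frames), dtype=int)
    n_init_present = np.empty(len(frames), dtype=int)
    for i, f in enumerate(frames):
        hb = detect_hbonds(f, complex, cfg.hbond_distance, cfg.hbond_angle)
        n_hb[i] = len(hb)
        n_init_present[i] = len(hb & initial_hb)
        n_ct[i] = contact_count(f, complex, cfg.contact_cutoff)
    return ScoreSeries(times=times, rmsd=rmsd, n_hbonds=n_hb, n_contacts=n_ct,
                       initial_hbonds=initial_hb, initial_contacts=initial_ct,
                       n_initial_hbonds_present=n_init_present)


def score_replica(traj: Trajectory, complex: ComplexStructure, cv: AlignedRmsdCV,
                  cfg: ProtocolConfig | None = None) -> tuple[PoseScores, ScoreSeries]:
    """Recenter, measure, and summarise one replica trajectory."""
    cfg = cfg or ProtocolConfig()
    if traj.box is not None and not traj.recentered:
        traj = recenter_trajectory(traj, complex)
    series = extract_series(traj, complex, cv, cfg)
    ps = pose_score(series, cfg.tail_ns)
    prs, defined = pers_score(series, cfg.tail_ns)
    cs = contact_score(series, cfg.tail_ns)
    comp = comp_score(ps, cs, cfg.compscore_coefficient)
    return PoseScores(pose_score=ps, pers_score=prs, contact_score=cs,
                      comp_score=comp, pers_defined=defined), series
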