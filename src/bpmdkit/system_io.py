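"""Structures, trajectories and tabular I/O.

The structural data model is deliberately small: a flat list of
:class:`AtomRecord` with a role (protein / ligand / solvent / ion) assigned to
every atom, wrapped in :class:`ComplexStructure`. Coordinates are stored in Å
throughout; the metadynamics boundary converts to nm in exactly one place
(:func:`bpmdkit.anchors_cv.evaluate_cv`).

File formats go through established readers: PDB and DCD/XTC via MDAnalysis,
SDF pose files via RDKit. Hills logs use a PLUMED-style whitespace table and
score tables are plain CSV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "ComplexStructure",
    "PoseSet",
    "Trajectory",
    "HillRecord",
    "LigandNotFoundError",
    "PoseFileError",
    "read_complex",
    "read_pose_set",
    "pose_complex",
    "write_complex",
    "read_trajectory",
    "write_trajectory",
    "read_hills",
    "write_hills",
    "read_score_table",
    "write_score_table",
]

# standard protein residues (incl. common protonation variants)
PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HID", "HIE", "HIP", "ASH", "GLH", "LYN", "CYX", "CYM", "ACE", "NME",
}
WATER_RESNAMES = {"HOH", "WAT", "TIP3", "TIP", "SOL", "SPC", "T3P", "T4P"}
ION_RESNAMES = {
    "NA", "CL", "K", "MG", "ZN", "CA", "MN", "FE", "LI", "BR", "F", "I",
    "CS", "RB", "SR", "BA", "CD", "NI", "CU", "NA+", "CL-", "K+", "MG2",
}


class LigandNotFoundError(ValueError):
    """Raised when the requested ligand residue name is absent."""


class PoseFileError(ValueError):
    """Raised for malformed multi-model pose files."""


def infer_element(name: str) -> str:
    """Element from an atom name's first alphabetic character (PDB fallback)."""
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {name!r}")


@dataclass
class AtomRecord:
    index: int
    name: str
    element: str
    resname: str
    resid: int
    chain: str
    coords: np.ndarray  # (3,) Å
    is_heavy: bool
    role: str  # protein | ligand | solvent | ion

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.index}: coords must be a finite 3-vector")
        if self.role not in ("protein", "ligand", "solvent", "ion"):
            raise ValueError(f"atom {self.index}: invalid role {self.role!r}")


@dataclass
class ComplexStructure:
    """A protein-ligand complex: atoms, optional box, ligand residue name."""

    atoms: list[AtomRecord]
    ligand_resname: str
    box: Optional[np.ndarray] = None  # (6,) lengths Å + angles deg

    def __post_init__(self) -> None:
        seen = set()
        for a in self.atoms:
            if a.index in seen:
                raise ValueError(f"duplicate atom index {a.index}")
            seen.add(a.index)
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (6,) or np.any(self.box[:3] <= 0):
                raise ValueError("box must be 3 positive lengths + 3 angles")
        roles = {a.role for a in self.atoms}
        if "protein" not in roles or "ligand" not in roles:
            raise ValueError("complex needs at least one protein and one ligand atom")

    # -- cached index helpers -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    def _indices(self, predicate) -> np.ndarray:
        return np.array([a.index for a in self.atoms if predicate(a)], dtype=int)

    @property
    def protein_indices(self) -> np.ndarray:
        return self._indices(lambda a: a.role == "protein")

    @property
    def protein_heavy_indices(self) -> np.ndarray:
        return self._indices(lambda a: a.role == "protein" and a.is_heavy)

    @property
    def ligand_indices(self) -> np.ndarray:
        return self._indices(lambda a: a.role == "ligand")

    @property
    def ligand_heavy_indices(self) -> np.ndarray:
        return self._indices(lambda a: a.role == "ligand" and a.is_heavy)

    @property
    def calpha_indices(self) -> np.ndarray:
        return self._indices(lambda a: a.role == "protein" and a.name == "CA")


@dataclass
class PoseSet:
    """A ligand-free receptor plus candidate ligand poses sharing one topology."""

    receptor: ComplexStructure | list[AtomRecord]
    ligand_atoms: list[AtomRecord]  # template metadata; coords = pose 1
    poses: list[tuple[int | str, np.ndarray]]  # (pose_id, (n_lig, 3) Å)
    native_ligand: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n = len(self.ligand_atoms)
        ids = [pid for pid, _ in self.poses]
        if len(set(ids)) != len(ids):
            raise ValueError("pose_id values must be unique")
        for pid, xyz in self.poses:
            if np.asarray(xyz).shape != (n, 3):
                raise ValueError(f"pose {pid}: expected {n} ligand atoms")
        if self.native_ligand is not None and np.asarray(self.native_ligand).shape != (n, 3):
            raise ValueError("native ligand atom count differs from poses")

    @property
    def pose_ids(self) -> list:
        return [pid for pid, _ in self.poses]

    def pose_coords(self, pose_id) -> np.ndarray:
        for pid, xyz in self.poses:
            if pid == pose_id:
                return np.asarray(xyz, dtype=float)
        raise KeyError(f"no pose with id {pose_id!r}")


@dataclass
class Trajectory:
    """Frames (Å) with times (ps) over a fixed atom set."""

    frames: np.ndarray          # (n_frames, n_atoms, 3)
    times: np.ndarray           # (n_frames,) ps, strictly increasing
    box: Optional[np.ndarray] = None  # (6,) as ComplexStructure.box
    recentered: bool = False

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if len(self.times) != len(self.frames):
            raise ValueError("times and frames length mismatch")
        if len(self.times) and self.times[0] < 0:
            raise ValueError("times must start at >= 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


@dataclass(frozen=True)
class HillRecord:
    """One deposited Gaussian: time (ps), center and width (nm, CV units),
    effective height after well-tempered rescaling (kcal/mol), bias factor."""

    time: float
    center: float
    width: float
    height: float
    bias_factor: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("hill width must be > 0")
        if self.height < 0:
            raise ValueError("hill height must be >= 0")


# --------------------------------------------------------------------------
# structure reading
# --------------------------------------------------------------------------

def _assign_role(resname: str, ligand_resname: Optional[str], n_in_residue: int) -> str:
    if ligand_resname is not None and resname == ligand_resname:
        return "ligand"
    if resname in PROTEIN_RESNAMES:
        return "protein"
    if resname in WATER_RESNAMES:
        return "solvent"
    if resname in ION_RESNAMES:
        return "ion"
    # unknown residue: monatomic -> ion, polyatomic -> environment (solvent)
    return "ion" if n_in_residue == 1 else "solvent"


def _records_from_universe(u, ligand_resname: Optional[str]) -> list[AtomRecord]:
    atoms = u.atoms
    try:
        elements = [e if e.strip() else None for e in atoms.elements]
    except Exception:
        elements = [None] * len(atoms)
    try:
        chains = list(atoms.chainIDs)
    except Exception:
        try:
            chains = list(atoms.segids)
        except Exception:
            chains = [""] * len(atoms)
    residue_sizes = {r.resindex: len(r.atoms) for r in u.residues}
    records = []
    for i, a in enumerate(atoms):
        el = elements[i] or infer_element(a.name)
        el = el.strip().upper()
        role = _assign_role(a.resname, ligand_resname, residue_sizes[a.resindex])
        records.append(AtomRecord(
            index=i, name=a.name, element=el, resname=a.resname,
            resid=int(a.resid), chain=str(chains[i]).strip(),
            coords=a.position.astype(float), is_heavy=(el != "H"), role=role,
        ))
    return records


def _load_universe(path: str | Path, top: Optional[str | Path] = None):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if top is not None:
                return mda.Universe(str(top), str(path))
            return mda.Universe(str(path))
        except Exception as exc:  # normalise parser failures
            raise ValueError(f"could not parse structure file {path}: {exc}") from exc


def read_complex(path: str | Path, ligand_resname: str) -> ComplexStructure:
    """Read a protein-ligand complex from a PDB file.

    Roles are assigned per residue name: standard amino acids are protein,
    ``ligand_resname`` is the ligand, water models are solvent, and monatomic
    ions are ions. A missing ligand residue is an explicit error.
    """
    u = _load_universe(path)
    records = _records_from_universe(u, ligand_resname)
    if not any(r.role == "ligand" for r in records):
        raise LigandNotFoundError(
            f"ligand residue not found: no residue named {ligand_resname!r} in {path}")
    box = None
    if u.dimensions is not None and np.all(u.dimensions[:3] > 0):
        box = np.asarray(u.dimensions, dtype=float)
    return ComplexStructure(atoms=records, ligand_resname=ligand_resname, box=box)


def _scan_pdb_model_counts(path: Path) -> list[int]:
    """Atom counts per MODEL block (single implicit model if no MODEL cards)."""
    counts: list[int] = []
    current = 0
    in_model = False
    for line in path.read_text().splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            in_model = True
            current = 0
        elif rec == "ENDMDL":
            counts.append(current)
            in_model = False
        elif rec in ("ATOM", "HETATM"):
            current += 1
    if not counts and current:
        counts = [current]
    elif in_model and current:
        counts.append(current)
    return counts


def _read_ligand_models_pdb(path: Path, ligand_resname: Optional[str]):
    counts = _scan_pdb_model_counts(path)
    if len(set(counts)) > 1:
        bad = next(m for m, c in enumerate(counts, start=1) if c != counts[0])
        raise PoseFileError(
            f"inconsistent atom counts across models in {path}: model {bad} "
            f"has {counts[bad - 1]} atoms, expected {counts[0]}")
    u = _load_universe(path)
    resname = ligand_resname or u.atoms.residues[0].resname
    records = _records_from_universe(u, resname)
    frames = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ts in u.trajectory:
            frames.append(u.atoms.positions.astype(float).copy())
    return records, frames, resname


def _read_ligand_models_sdf(path: Path):
    from rdkit import Chem

    suppl = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    records: list[AtomRecord] = []
    frames: list[np.ndarray] = []
    for m, mol in enumerate(suppl):
        if mol is None:
            raise PoseFileError(f"unreadable SDF record {m + 1} in {path}")
        conf = mol.GetConformer()
        xyz = np.array(conf.GetPositions(), dtype=float)
        if records and len(xyz) != len(records):
            raise PoseFileError(
                f"inconsistent atom counts across models in {path}: record {m + 1} "
                f"has {len(xyz)} atoms, expected {len(records)}")
        if not records:
            for i, atom in enumerate(mol.GetAtoms()):
                el = atom.GetSymbol().upper()
                records.append(AtomRecord(
                    index=i, name=f"{el}{i + 1}", element=el, resname="LIG",
                    resid=1, chain="", coords=xyz[i], is_heavy=(el != "H"),
                    role="ligand"))
        frames.append(xyz)
    if not frames:
        raise PoseFileError(f"no molecules in SDF file {path}")
    return records, frames


def read_pose_set(
    receptor_path: str | Path,
    poses_path: str | Path,
    native_path: Optional[str | Path] = None,
    ligand_resname: Optional[str] = None,
) -> PoseSet:
    """Load a receptor plus candidate ligand poses (multi-model PDB or SDF)."""
    u = _load_universe(receptor_path)
    receptor = _records_from_universe(u, None)

    poses_path = Path(poses_path)
    if poses_path.suffix.lower() == ".sdf":
        lig_records, frames = _read_ligand_models_sdf(poses_path)
    else:
        lig_records, frames, _ = _read_ligand_models_pdb(poses_path, ligand_resname)
    # re-base ligand records so they describe the ligand only
    lig_records = [replace(r, role="ligand") for r in lig_records]

    native = None
    if native_path is not None:
        p = Path(native_path)
        if p.suffix.lower() == ".sdf":
            _, nat_frames = _read_ligand_models_sdf(p)
        else:
            _, nat_frames, _ = _read_ligand_models_pdb(p, ligand_resname)
        native = nat_frames[0]
        if native.shape != frames[0].shape:
            raise PoseFileError("native ligand atom count differs from poses")

    poses = [(m + 1, xyz) for m, xyz in enumerate(frames)]
    return PoseSet(receptor=receptor, ligand_atoms=lig_records,
                   poses=poses, native_ligand=native)


def pose_complex(pose_set: PoseSet, pose_id, box: Optional[np.ndarray] = None) -> ComplexStructure:
    """Assemble receptor + one candidate pose into a scorable complex."""
    xyz = pose_set.pose_coords(pose_id)
    receptor = pose_set.receptor
    rec_atoms = receptor.atoms if isinstance(receptor, ComplexStructure) else receptor
    lig_resname = pose_set.ligand_atoms[0].resname
    atoms: list[AtomRecord] = []
    for a in rec_atoms:
        atoms.append(replace(a, index=len(atoms)))
    for a, pos in zip(pose_set.ligand_atoms, xyz):
        atoms.append(replace(a, index=len(atoms), coords=np.asarray(pos, float)))
    return ComplexStructure(atoms=atoms, ligand_resname=lig_resname, box=box)


# --------------------------------------------------------------------------
# structure / trajectory writing (MDAnalysis-backed)
# --------------------------------------------------------------------------

def to_mda_universe(complex: ComplexStructure):
    """Build an in-memory MDAnalysis Universe mirroring a ComplexStructure."""
    import MDAnalysis as mda

    n = complex.n_atoms
    resids_keys: list[tuple] = []
    atom_resindex = np.empty(n, dtype=int)
    for i, a in enumerate(complex.atoms):
        key = (a.chain, a.resid, a.resname)
        if not resids_keys or resids_keys[-1] != key:
            resids_keys.append(key)
        atom_resindex[i] = len(resids_keys) - 1
    u = mda.Universe.empty(n, n_residues=len(resids_keys),
                           atom_resindex=atom_resindex, trajectory=True)
    u.add_TopologyAttr("names", [a.name for a in complex.atoms])
    u.add_TopologyAttr("elements", [a.element for a in complex.atoms])
    u.add_TopologyAttr("resnames", [k[2] for k in resids_keys])
    u.add_TopologyAttr("resids", [k[1] for k in resids_keys])
    u.add_TopologyAttr("chainIDs", [a.chain or "A" for a in complex.atoms])
    u.atoms.positions = complex.coords
    if complex.box is not None:
        u.dimensions = complex.box
    return u


def write_complex(complex: ComplexStructure, path: str | Path) -> None:
    u = to_mda_universe(complex)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_trajectory(traj: Trajectory, complex: ComplexStructure, path: str | Path) -> None:
    """Write frames to DCD/XTC via MDAnalysis (times implied by constant dt)."""
    import MDAnalysis as mda

    u = to_mda_universe(complex)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=traj.n_atoms) as w:
            for frame in traj.frames:
                u.atoms.positions = frame
                w.write(u.atoms)


def read_trajectory(complex: ComplexStructure, path: str | Path,
                    dt_ps: Optional[float] = None) -> Trajectory:
    """Read a DCD/XTC trajectory over the atoms of ``complex``.

    ``dt_ps`` overrides the (often unreliable) time metadata of DCD files.
    """
    import MDAnalysis as mda

    u = to_mda_universe(complex)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u2 = mda.Universe.empty(complex.n_atoms, trajectory=True)
        u2.load_new(str(path))
        frames, times = [], []
        for k, ts in enumerate(u2.trajectory):
            frames.append(ts.positions.astype(float).copy())
            times.append(k * dt_ps if dt_ps is not None else float(ts.time))
    return Trajectory(frames=np.array(frames), times=np.array(times), box=complex.box)


# --------------------------------------------------------------------------
# hills log (PLUMED-style whitespace table)
# --------------------------------------------------------------------------

_HILLS_HEADER = "#! FIELDS time cv sigma_cv height biasf"


def write_hills(hills: Sequence[HillRecord], path: str | Path) -> None:
    times = [h.time for h in hills]
    if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("hills must be time-ordered")
    lines = [_HILLS_HEADER]
    for h in hills:
        lines.append(f"{h.time:>14.6e} {h.center:>14.6e} {h.width:>14.6e} "
                     f"{h.height:>14.6e} {h.bias_factor:>10.4f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_hills(path: str | Path) -> list[HillRecord]:
    hills = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        t, c, w, h, g = (float(x) for x in line.split())
        hills.append(HillRecord(time=t, center=c, width=w, height=h, bias_factor=g))
    return hills


# --------------------------------------------------------------------------
# score tables (CSV)
# --------------------------------------------------------------------------

SCORE_COLUMNS = ["pose_id", "replica", "PoseScore", "PersScore", "ContactScore", "CompScore"]


def write_score_table(rows: Sequence[dict], path: str | Path) -> None:
    """Write per-replica (or per-pose, replica='mean') score records as CSV."""
    if not rows:
        raise ValueError("rows must be non-empty")
    df = pd.DataFrame(list(rows))[SCORE_COLUMNS]
    df.to_csv(path, index=False, float_format="%.6f")


def read_score_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
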