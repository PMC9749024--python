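"""Synthetic complexes and trajectories with known ground truth.

The toy complex is a rigid pseudo-protein built for testability, not
physical realism:

* a scaffold of Cα-labelled atoms on two rings well outside contact range,
  so anchor selection and alignment run on the real code paths;
* "contact units" — one protein heavy atom placed 3.2 Å from one designated
  ligand heavy atom, radially, so every unit contributes exactly one
  protein-ligand contact at the 3.5 Å cutoff;
* hydrogen-bond units — a protein N-H donor aimed at a ligand oxygen with
  ideal geometry (N···O 2.9 Å, angle 180°); each also counts as one contact.

Synthetic trajectories realise prescribed schedules exactly: the ligand
drifts rigidly so the aligned RMSD tracks ``rmsd_schedule``; contact-unit
atoms either track the ligand (contact retained) or are pushed out of range
(contact broken) per ``contact_schedule``; hydrogen bonds are broken without
losing the contact by rotating the donor hydrogen away. A global rigid
"wobble" can be layered on every frame to exercise anchor alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .anchors_cv import AlignedRmsdCV
from .config import ProtocolConfig
from .metadynamics import (BiasState, KB_KCAL_MOL_K, MetadParams, bias_force,
                           deposit_hill)
from .system_io import AtomRecord, ComplexStructure, PoseSet, Trajectory

__all__ = [
    "SyntheticSpec",
    "ToyComplexFixture",
    "constant",
    "linear_ramp",
    "make_toy_complex",
    "synth_trajectory",
    "ScheduledEngine",
    "ToyPocketEngine",
]


def constant(value: float) -> Callable[[float], float]:
    return lambda t: value


def linear_ramp(t_end_ps: float, v_end: float, v_start: float = 0.0) -> Callable[[float], float]:
    """Value ramping linearly from v_start at t=0 to v_end at t_end (then flat)."""
    def f(t: float) -> float:
        u = min(max(t / t_end_ps, 0.0), 1.0)
        return v_start + (v_end - v_start) * u
    return f


@dataclass
class SyntheticSpec:
    """Ground-truth schedules and sizes for a synthetic system."""

    n_protein_atoms: int = 24          # scaffold Cα count
    n_ligand_heavy: int = 8
    n_contacts: int = 6                # initial protein-ligand contacts
    n_hbonds: int = 2                  # initial hydrogen bonds (each is a contact)
    rmsd_schedule: Callable[[float], float] = None     # t (ps) -> Å
    contact_schedule: Callable[[float], float] = None  # t -> fraction of initial
    hbond_schedule: Callable[[float], float] = None    # t -> retained bond count
    noise_sigma: float = 0.0           # Å, rigid per-frame jitter on the ligand
    seed: int = 0
    duration_ns: float = 10.0
    stride_ps: float = 100.0
    wobble_deg: float = 0.0            # global rigid rotation amplitude
    wobble_trans_A: float = 0.0        # global rigid translation amplitude
    box_length: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_ligand_heavy < 1:
            raise ValueError("n_ligand_heavy must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_hbonds > self.n_contacts:
            raise ValueError("every hydrogen bond is a contact: n_hbonds <= n_contacts")
        if self.n_contacts > self.n_ligand_heavy:
            raise ValueError(
                "impossible contact request: at most one contact per ligand heavy atom")
        if self.rmsd_schedule is None:
            self.rmsd_schedule = constant(0.0)
        if self.contact_schedule is None:
            self.contact_schedule = constant(1.0)
        if self.hbond_schedule is None:
            self.hbond_schedule = constant(float(self.n_hbonds))


@dataclass
class ContactUnit:
    """One engineered protein-ligand contact (optionally a hydrogen bond)."""

    ligand_atom: int           # index into the complex
    protein_atoms: list[int]   # heavy atom (+ hydrogen for H-bond units)
    is_hbond: bool
    far_offset: np.ndarray     # xy push that breaks the contact


@dataclass
class ToyComplexFixture:
    complex: ComplexStructure
    pose_set: PoseSet
    contact_units: list[ContactUnit]
    bound_ligand_coords: np.ndarray


def _ligand_ring(n: int) -> np.ndarray:
    """n atoms on an xy-circle with ~1.5 Å nearest-neighbour spacing."""
    if n == 1:
        return np.zeros((1, 3))
    r = 1.5 / (2.0 * math.sin(math.pi / n))
    ang = 2.0 * math.pi * np.arange(n) / n
    return np.column_stack([r * np.cos(ang), r * np.sin(ang), np.zeros(n)])


def make_toy_complex(spec: SyntheticSpec,
                     pose_rmsds_A: Sequence[float] = (),
                     include_native: bool = True) -> ToyComplexFixture:
    """Build the rigid toy complex and a pose set.

    Pose 1 is the bound geometry; each entry of ``pose_rmsds_A`` adds a pose
    displaced rigidly along +z by that distance (a uniform translation has
    RMSD equal to its length). The bound coordinates double as the native
    reference when ``include_native``.
    """
    lig_xyz = _ligand_ring(spec.n_ligand_heavy)
    lig_r = float(np.linalg.norm(lig_xyz[0][:2])) if spec.n_ligand_heavy > 1 else 0.0

    atoms: list[AtomRecord] = []
    resid = 0

    def add(name, element, resname, role, xyz, heavy=True):
        atoms.append(AtomRecord(index=len(atoms), name=name, element=element,
                                resname=resname, resid=resid, chain="A",
                                coords=np.asarray(xyz, float), is_heavy=heavy,
                                role=role))
        return len(atoms) - 1

    # scaffold: two Cα rings at z = ±4, radius lig_r + 8 (outside contact range)
    n_ring = max(spec.n_protein_atoms // 2, 3)
    scaffold_r = lig_r + 8.0
    for z in (+4.0, -4.0):
        for k in range(n_ring):
            a = 2.0 * math.pi * k / n_ring + (0.3 if z > 0 else 0.0)
            resid += 1
            add("CA", "C", "ALA", "protein",
                [scaffold_r * math.cos(a), scaffold_r * math.sin(a), z])

    # contact units: hydrogen-bond units first, then plain CB contacts
    units: list[ContactUnit] = []
    for j in range(spec.n_contacts):
        lig_pos = lig_xyz[j]
        u_r = lig_pos.copy()
        nrm = np.linalg.norm(u_r)
        u_r = u_r / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
        resid += 1
        if j < spec.n_hbonds:
            n_pos = lig_pos + 2.9 * u_r
            h_pos = lig_pos + 1.9 * u_r  # on the N···O axis, 1.0 Å from N
            n_idx = add("N", "N", "ALA", "protein", n_pos)
            h_idx = add("H", "H", "ALA", "protein", h_pos, heavy=False)
            units.append(ContactUnit(ligand_atom=-1, protein_atoms=[n_idx, h_idx],
                                     is_hbond=True, far_offset=4.0 * u_r))
        else:
            cb_idx = add("CB", "C", "ALA", "protein", lig_pos + 3.2 * u_r)
            units.append(ContactUnit(ligand_atom=-1, protein_atoms=[cb_idx],
                                     is_hbond=False, far_offset=4.0 * u_r))

    # ligand last; oxygens for the hydrogen-bond acceptors, carbons otherwise
    resid += 1
    lig_start = len(atoms)
    for j in range(spec.n_ligand_heavy):
        if j < spec.n_hbonds:
            add(f"O{j + 1}", "O", "LIG", "ligand", lig_xyz[j])
        else:
            add(f"C{j + 1}", "C", "LIG", "ligand", lig_xyz[j])
    for j, unit in enumerate(units):
        unit.ligand_atom = lig_start + j

    box = None
    if spec.box_length is not None:
        box = np.array([spec.box_length] * 3 + [90.0] * 3)
        for a in atoms:  # keep everything well inside the box
            a.coords = a.coords + spec.box_length / 2.0
        lig_xyz = lig_xyz + spec.box_length / 2.0

    complex = ComplexStructure(atoms=atoms, ligand_resname="LIG", box=box)

    # sanity: the construction must realise the requested counts exactly
    from .scoring import contact_count, detect_hbonds
    got_contacts = contact_count(complex.coords, complex)
    got_hbonds = len(detect_hbonds(complex.coords, complex))
    if got_contacts != spec.n_contacts or got_hbonds != spec.n_hbonds:
        raise ValueError(
            f"impossible contact request: built {got_contacts} contacts / "
            f"{got_hbonds} H-bonds, wanted {spec.n_contacts} / {spec.n_hbonds}")

    receptor = [a for a in atoms if a.role == "protein"]
    ligand_atoms = [replace(a) for a in atoms if a.role == "ligand"]
    bound = np.array([a.coords for a in ligand_atoms])
    poses = [(1, bound.copy())]
    for m, d in enumerate(pose_rmsds_A, start=2):
        poses.append((m, bound + np.array([0.0, 0.0, float(d)])))
    pose_set = PoseSet(receptor=receptor, ligand_atoms=ligand_atoms, poses=poses,
                       native_ligand=bound.copy() if include_native else None)
    return ToyComplexFixture(complex=complex, pose_set=pose_set,
                             contact_units=units, bound_ligand_coords=bound)


def _wobble_transform(rng: np.random.Generator, deg: float, trans: float):
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    angle = math.radians(rng.normal(0.0, deg))
    from scipy.spatial.transform import Rotation
    r = Rotation.from_rotvec(angle * axis).as_matrix()
    b = rng.normal(0.0, trans / math.sqrt(3.0), 3) if trans > 0 else np.zeros(3)
    return r, b


def synth_trajectory(fixture: ToyComplexFixture, spec: SyntheticSpec,
                     pose_id=1, seed: Optional[int] = None,
                     duration_ns: Optional[float] = None) -> Trajectory:
    """Frames realising the spec's RMSD/contact/H-bond schedules.

    The schedules are relative to the chosen pose's own starting geometry:
    contact-unit atoms are shifted along with the pose offset, so every pose
    starts fully "in the pocket" and stability differences come entirely
    from the schedules.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    duration_ps = (duration_ns if duration_ns is not None else spec.duration_ns) * 1000.0
    times = np.arange(0.0, duration_ps + spec.stride_ps / 2, spec.stride_ps)

    complex = fixture.complex
    offset = fixture.pose_set.pose_coords(pose_id) - fixture.bound_ligand_coords
    if not np.allclose(offset, offset[0]):
        raise ValueError("synthetic poses must be rigid translations of the bound pose")
    offset = offset[0]

    lig_idx = complex.ligand_indices
    base = complex.coords
    base[lig_idx] += offset
    for unit in fixture.contact_units:
        base[unit.protein_atoms] += offset

    n_units = len(fixture.contact_units)
    n_hb = sum(1 for u in fixture.contact_units if u.is_hbond)
    e_z = np.array([0.0, 0.0, 1.0])
    frames = np.empty((len(times), complex.n_atoms, 3))
    for i, t in enumerate(times):
        coords = base.copy()
        disp = spec.rmsd_schedule(t) * e_z
        if spec.noise_sigma > 0:
            disp = disp + rng.normal(0.0, spec.noise_sigma / math.sqrt(3.0), 3)
        coords[lig_idx] += disp
        r_c = int(round(np.clip(spec.contact_schedule(t), 0.0, 1.0) * n_units))
        r_h = int(round(np.clip(spec.hbond_schedule(t), 0, n_hb)))
        if r_h > r_c:
            raise ValueError(
                f"schedule conflict at t={t} ps: {r_h} H-bonds retained but "
                f"only {r_c} contacts (an H-bond implies a contact)")
        for j, unit in enumerate(fixture.contact_units):
            if j < r_c:
                coords[unit.protein_atoms] += disp  # track: contact retained
                if unit.is_hbond and j >= r_h:
                    n_idx, h_idx = unit.protein_atoms
                    coords[h_idx] = coords[n_idx] + e_z  # rotate H: bond broken
            else:
                coords[unit.protein_atoms] += unit.far_offset  # out of range
        if spec.wobble_deg > 0 or spec.wobble_trans_A > 0:
            r, b = _wobble_transform(rng, spec.wobble_deg, spec.wobble_trans_A)
            center = coords.mean(axis=0)
            coords = (coords - center) @ r.T + center + b
        frames[i] = coords
    box = complex.box.copy() if complex.box is not None else None
    return Trajectory(frames=frames, times=times, box=box)


# --------------------------------------------------------------------------
# engines
# --------------------------------------------------------------------------

class ScheduledEngine:
    """Mock engine: replays per-pose schedules instead of running dynamics.

    Satisfies the Engine protocol; records the params it received so tests
    can assert protocol plumbing.
    """

    def __init__(self, fixture: ToyComplexFixture,
                 specs: dict[object, SyntheticSpec]):
        self.fixture = fixture
        self.specs = dict(specs)
        self.last_params: Optional[MetadParams] = None
        self.last_seed: Optional[int] = None

    def run(self, pose_id, complex: ComplexStructure, cv: AlignedRmsdCV,
            params: MetadParams, seed: int) -> Trajectory:
        self.last_params = params
        self.last_seed = seed
        spec = self.specs[pose_id]
        pose_index = list(self.fixture.pose_set.pose_ids).index(pose_id)
        return synth_trajectory(self.fixture, spec, pose_id=pose_id,
                                seed=seed + 7919 * pose_index,
                                duration_ns=params.duration_ns)


class ToyPocketEngine:
    """Langevin dynamics of the rigid ligand in a harmonic pocket, biased by
    well-tempered metadynamics on the ligand-displacement CV.

    The ligand translates as a rigid body; the pocket potential is
    U = ½ k |r|² (k in kcal/mol/Å², per pose) and the metadynamics bias acts
    on s = |r| expressed in nm. Deeper pockets resist the bias longer, so
    pose stability emerges from the dynamics rather than from a script.
    Mass is the effective value in kcal/mol·ps²/Å² (≈ amu / 418.4).
    """

    def __init__(self, fixture: ToyComplexFixture,
                 k_pocket: dict[object, float] | float = 1.0,
                 mass: float = 0.7, friction: float = 5.0,
                 timestep_fs: float = 2.0, save_ps: float = 10.0):
        self.fixture = fixture
        self.k_pocket = k_pocket
        self.mass = mass
        self.friction = friction
        self.timestep_fs = timestep_fs
        self.save_ps = save_ps
        self.last_bias: Optional[BiasState] = None

    def _k(self, pose_id) -> float:
        if isinstance(self.k_pocket, dict):
            return float(self.k_pocket[pose_id])
        return float(self.k_pocket)

    def run(self, pose_id, complex: ComplexStructure, cv: AlignedRmsdCV,
            params: MetadParams, seed: int) -> Trajectory:
        rng = np.random.default_rng(seed)
        dt = self.timestep_fs * 1e-3
        n_steps = int(round(params.duration_ns * 1000.0 / dt))
        pace_steps = max(1, int(round(params.pace_ps / dt)))
        save_steps = max(1, int(round(self.save_ps / dt)))
        k = self._k(pose_id)
        kT = KB_KCAL_MOL_K * params.temperature_K
        m = self.mass
        c1 = math.exp(-self.friction * dt)
        c2 = math.sqrt(kT / m * (1.0 - c1 * c1))

        bias = BiasState(params=params)
        r = np.zeros(3)  # ligand displacement from the pose, Å
        v = np.zeros(3)

        def force(r: np.ndarray) -> np.ndarray:
            f = -k * r
            s = np.linalg.norm(r)
            if bias.hills and s > 1e-12:
                # dV/ds in kcal/mol/nm -> kcal/mol/Å along r-hat
                f = f + (bias_force(bias, s / 10.0) / 10.0) * (r / s)
            return f

        base = complex.coords
        lig_idx = complex.ligand_indices
        f = force(r)
        frames, times = [base.copy()], [0.0]  # the pose itself is frame 0
        for step in range(1, n_steps + 1):
            v = v + (0.5 * dt / m) * f
            r = r + 0.5 * dt * v
            v = c1 * v + c2 * rng.standard_normal(3)
            r = r + 0.5 * dt * v
            if step % pace_steps == 0:
                deposit_hill(bias, float(np.linalg.norm(r)) / 10.0, step * dt)
            f = force(r)
            v = v + (0.5 * dt / m) * f
            if step % save_steps == 0:
                coords = base.copy()
                coords[lig_idx] += r
                frames.append(coords)
                times.append(step * dt)
        self.last_bias = bias
        box = complex.box.copy() if complex.box is not None else None
        return Trajectory(frames=np.array(frames), times=np.array(times), box=box)
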