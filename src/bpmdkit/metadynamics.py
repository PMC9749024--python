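"""Engine-agnostic well-tempered metadynamics.

Hills are Gaussians in the collective variable s:

    V(s) = sum_i w_i * exp(-(s - s_i)^2 / (2 sigma^2))

with the well-tempered rule scaling each new hill's height by the bias
already present at the deposition point:

    w = w0 * exp(-V(s) / (kB * (gamma - 1) * T))

so the accumulated bias converges and the free energy surface is recovered
as F(s) = -(gamma / (gamma - 1)) * V(s).

The module also ships a BAOAB-discretised Langevin integrator on analytic
toy potentials (1D/2D double wells, harmonic) so the full deposit/bias/FES
machinery can be exercised end-to-end in seconds, without an external MD
engine. All-atom dynamics is delegated to an :class:`Engine` adapter.

Units: energies kcal/mol, temperatures K, times ps, CV in nm (or the toy
potential's natural length unit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Protocol, runtime_checkable

import numpy as np

from .config import ProtocolConfig
from .system_io import ComplexStructure, HillRecord, Trajectory
from .anchors_cv import AlignedRmsdCV

__all__ = [
    "KB_KCAL_MOL_K",
    "MetadParams",
    "BiasState",
    "ToyPotential",
    "DoubleWell1D",
    "DoubleWell2D",
    "Harmonic",
    "ToySystem",
    "CVTrace",
    "effective_hill_height",
    "bias_energy",
    "bias_force",
    "deposit_hill",
    "run_toy_metad",
    "reconstruct_fes",
    "analytic_basin_delta_f",
    "Engine",
    "OpenMMEngine",
]

KB_KCAL_MOL_K = 0.0019872041  # Boltzmann constant, kcal/mol/K


@dataclass
class MetadParams:
    """Well-tempered metadynamics parameters."""

    height: float = 0.3        # w0, kcal/mol
    width: float = 0.002       # sigma, nm (CV units)
    pace_ps: float = 100.0     # tau, ps between depositions
    bias_factor: float = 4.0   # gamma
    temperature_K: float = 300.0
    duration_ns: float = 10.0
    n_replicas: int = 10

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("height and width must be > 0")
        if self.bias_factor <= 1:
            raise ValueError("bias_factor must be > 1 (well-tempered)")

    @classmethod
    def from_config(cls, cfg: ProtocolConfig) -> "MetadParams":
        return cls(height=cfg.hill_height, width=cfg.hill_width,
                   pace_ps=cfg.pace_ps, bias_factor=cfg.bias_factor,
                   temperature_K=cfg.temperature_K, duration_ns=cfg.duration_ns,
                   n_replicas=cfg.n_replicas)

    @property
    def delta_T(self) -> float:
        return (self.bias_factor - 1.0) * self.temperature_K


@dataclass
class BiasState:
    """Accumulated hills defining the bias potential."""

    params: MetadParams
    hills: list[HillRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        # parallel arrays for vectorised evaluation
        self._centers = np.array([h.center for h in self.hills])
        self._widths = np.array([h.width for h in self.hills])
        self._heights = np.array([h.height for h in self.hills])

    def _append(self, h: HillRecord) -> None:
        self.hills.append(h)
        self._centers = np.append(self._centers, h.center)
        self._widths = np.append(self._widths, h.width)
        self._heights = np.append(self._heights, h.height)


def bias_energy(bias: BiasState, s) -> float | np.ndarray:
    """Bias potential V(s); accepts a scalar CV value or a grid."""
    s = np.asarray(s, dtype=float)
    if len(bias.hills) == 0:
        return np.zeros(s.shape) if s.ndim else 0.0
    z = (s[..., None] - bias._centers) / bias._widths
    v = np.sum(bias._heights * np.exp(-0.5 * z * z), axis=-1)
    return v if s.ndim else float(v)


def bias_force(bias: BiasState, s) -> float | np.ndarray:
    """-dV/ds at the CV value(s) s."""
    s = np.asarray(s, dtype=float)
    if len(bias.hills) == 0:
        return np.zeros(s.shape) if s.ndim else 0.0
    d = s[..., None] - bias._centers
    z = d / bias._widths
    f = np.sum(bias._heights * np.exp(-0.5 * z * z) * d / bias._widths**2, axis=-1)
    return f if s.ndim else float(f)


def effective_hill_height(bias: BiasState, s: float) -> float:
    """Height of the next hill at s under the well-tempered rescaling rule."""
    p = bias.params
    if p.bias_factor <= 1:
        raise ValueError("bias_factor must be > 1")
    return p.height * math.exp(-bias_energy(bias, s) / (KB_KCAL_MOL_K * p.delta_T))


def deposit_hill(bias: BiasState, s: float, t: float) -> BiasState:
    """Append a hill at CV value s and time t (ps); mutates and returns bias.

    The recorded height is the effective height evaluated against the bias
    present *before* this hill.
    """
    if bias.hills and t < bias.hills[-1].time:
        raise ValueError(
            f"hill at t={t} ps is earlier than the last deposited hill "
            f"(t={bias.hills[-1].time} ps)")
    h = effective_hill_height(bias, s)
    bias._append(HillRecord(time=float(t), center=float(s), width=bias.params.width,
                            height=h, bias_factor=bias.params.bias_factor))
    return bias


def reconstruct_fes(bias: BiasState, grid: np.ndarray) -> np.ndarray:
    """Free energy on a CV grid, F = -(gamma/(gamma-1)) V(s), min-shifted to 0."""
    if len(bias.hills) == 0:
        raise ValueError("cannot reconstruct a free energy surface from an empty bias")
    g = bias.params.bias_factor
    f = -(g / (g - 1.0)) * bias_energy(bias, np.asarray(grid, dtype=float))
    return f - f.min()


# --------------------------------------------------------------------------
# toy potentials and Langevin dynamics
# --------------------------------------------------------------------------

class ToyPotential(Protocol):
    def energy(self, x: np.ndarray) -> float: ...
    def force(self, x: np.ndarray) -> np.ndarray: ...


@dataclass(frozen=True)
class DoubleWell1D:
    """U(x) = a (x^2 - 1)^2 + tilt * x; minima near x = ±1, barrier ≈ a."""

    a: float = 2.0
    tilt: float = 0.0

    def energy(self, x: np.ndarray) -> float:
        x0 = float(np.atleast_1d(x)[0])
        return self.a * (x0 * x0 - 1.0) ** 2 + self.tilt * x0

    def force(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        f = np.zeros_like(x)
        f[0] = -(4.0 * self.a * x[0] * (x[0] * x[0] - 1.0) + self.tilt)
        return f


@dataclass(frozen=True)
class DoubleWell2D:
    """Double well along x, harmonic along y: U = a(x²−1)² + ½ k y²."""

    a: float = 2.0
    k: float = 5.0

    def energy(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        return self.a * (x[0] ** 2 - 1.0) ** 2 + 0.5 * self.k * x[1] ** 2

    def force(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.array([-4.0 * self.a * x[0] * (x[0] ** 2 - 1.0), -self.k * x[1]])


@dataclass(frozen=True)
class Harmonic:
    k: float = 1.0

    def energy(self, x: np.ndarray) -> float:
        return 0.5 * self.k * float(np.sum(np.asarray(x) ** 2))

    def force(self, x: np.ndarray) -> np.ndarray:
        return -self.k * np.asarray(x, dtype=float)


@dataclass
class ToySystem:
    """Single particle on an analytic potential, Langevin-thermostatted.

    Mass is in kcal/mol·ps²/len²; with mass 1 and kT ≈ 0.6 kcal/mol the
    thermal velocity is O(1) len/ps, so ps-scale runs explore the wells.
    """

    potential: ToyPotential
    position: np.ndarray = field(default_factory=lambda: np.array([-1.0]))
    velocity: Optional[np.ndarray] = None
    mass: float = 1.0
    friction: float = 5.0      # ps^-1
    temperature_K: float = 300.0
    timestep_fs: float = 2.0

    def __post_init__(self) -> None:
        self.position = np.atleast_1d(np.asarray(self.position, dtype=float))
        if self.velocity is None:
            self.velocity = np.zeros_like(self.position)
        if self.friction <= 0:
            raise ValueError("friction must be > 0")


@dataclass
class CVTrace:
    """Sampled CV values over time (the toy engine's 'trajectory')."""

    times: np.ndarray  # ps
    values: np.ndarray


def run_toy_metad(system: ToySystem, params: MetadParams, seed: int,
                  save_ps: Optional[float] = None,
                  bound: float = 50.0) -> tuple[CVTrace, BiasState]:
    """Well-tempered metadynamics on a toy system; CV = first coordinate.

    BAOAB-split Langevin dynamics with total force -∇(U + V_bias); a hill is
    deposited every ``params.pace_ps``. Bitwise deterministic for a fixed
    seed. CV samples are recorded every ``save_ps`` (default: the pace).

    Raises RuntimeError if |CV| exceeds ``bound`` (divergence).
    """
    rng = np.random.default_rng(seed)
    dt = system.timestep_fs * 1e-3  # ps
    n_steps = int(round(params.duration_ns * 1000.0 / dt))
    pace_steps = max(1, int(round(params.pace_ps / dt)))
    save_ps = params.pace_ps if save_ps is None else save_ps
    save_steps = max(1, int(round(save_ps / dt)))

    x = system.position.copy()
    v = system.velocity.copy()
    m = system.mass
    kT = KB_KCAL_MOL_K * system.temperature_K
    c1 = math.exp(-system.friction * dt)
    c2 = math.sqrt(kT / m * (1.0 - c1 * c1))
    ndim = len(x)

    bias = BiasState(params=params)

    def total_force(x: np.ndarray) -> np.ndarray:
        f = system.potential.force(x)
        if bias.hills:
            f = f.copy()
            f[0] += bias_force(bias, x[0])
        return f

    f = total_force(x)
    times_out, cv_out = [], []
    # pre-draw noise in chunks to keep the loop lean while staying seeded
    chunk = 10000
    noise = rng.standard_normal((chunk, ndim))
    ptr = 0
    for step in range(1, n_steps + 1):
        v = v + (0.5 * dt / m) * f
        x = x + 0.5 * dt * v
        if ptr == chunk:
            noise = rng.standard_normal((chunk, ndim))
            ptr = 0
        v = c1 * v + c2 * noise[ptr]
        ptr += 1
        x = x + 0.5 * dt * v
        if step % pace_steps == 0:
            if not np.isfinite(x[0]) or abs(x[0]) > bound:
                raise RuntimeError(f"toy trajectory diverged at step {step} (CV={x[0]})")
            deposit_hill(bias, float(x[0]), step * dt)
        f = total_force(x)
        v = v + (0.5 * dt / m) * f
        if step % save_steps == 0:
            times_out.append(step * dt)
            cv_out.append(x[0])
    return CVTrace(times=np.array(times_out), values=np.array(cv_out)), bias


def analytic_basin_delta_f(potential: ToyPotential, temperature_K: float,
                           split: float = 0.0, lo: float = -3.0, hi: float = 3.0,
                           n: int = 20001) -> float:
    """Free-energy difference F(right basin) - F(left basin) by quadrature.

    Boltzmann-integrates exp(-U/kT) over [lo, split] and [split, hi] on a
    dense grid (1D potentials only).
    """
    from scipy.integrate import simpson

    kT = KB_KCAL_MOL_K * temperature_K

    def partition(a: float, b: float) -> float:
        xs = np.linspace(a, b, n)
        u = np.array([potential.energy(np.array([x])) for x in xs])
        return simpson(np.exp(-u / kT), x=xs)

    return float(-kT * math.log(partition(split, hi) / partition(lo, split)))


# --------------------------------------------------------------------------
# engine adapter
# --------------------------------------------------------------------------

@runtime_checkable
class Engine(Protocol):
    """Produces one biased replica trajectory for a pose complex.

    Implementations: the scheduled mock engine in :mod:`bpmdkit.fixtures`,
    the toy pocket engine there, or a user adapter wrapping an external MD
    engine.
    """

    def run(self, pose_id, complex: ComplexStructure, cv: AlignedRmsdCV,
            params: MetadParams, seed: int) -> Trajectory: ...


class OpenMMEngine:
    """Adapter contract for all-atom biased dynamics via OpenMM.

    The production protocol this adapter stands for: Langevin dynamics at
    300 K with 1 ps⁻¹ friction and a 4 fs hydrogen-mass-repartitioned step,
    PME electrostatics with a 10 Å cutoff, and the ligand-RMSD CV biased per
    the supplied MetadParams. Parametrised systems (topology + coordinates)
    must come from upstream tooling; this package does not build force
    fields. Instantiation fails with a clear error when OpenMM is not
    installed.
    """

    def __init__(self) -> None:
        try:
            import openmm  # noqa: F401
        except ImportError as exc:
            raise ImportError(
                "OpenMM is an optional dependency and is not installed; "
                "install openmm or supply another Engine implementation "
                "(e.g. the toy or mock engines in bpmdkit.fixtures)") from exc

    def run(self, pose_id, complex: ComplexStructure, cv: AlignedRmsdCV,
            params: MetadParams, seed: int) -> Trajectory:
        raise NotImplementedError(
            "all-atom dynamics requires a parametrised system; wrap your "
            "OpenMM setup in an object satisfying the Engine protocol")
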