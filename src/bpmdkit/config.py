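"""Protocol configuration.

All tunable protocol parameters live in one dataclass so a single YAML file
fully specifies a campaign: metadynamics settings (hill height/width, pace,
bias factor, temperature, duration, replica count), anchor/restraint geometry,
and the scoring thresholds (contact cutoff, hydrogen-bond geometry, tail
window, measurement stride, composite-score coefficient).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml


@dataclass
class ProtocolConfig:
    """Every user-tunable parameter of the biasing and scoring protocol.

    Distances are in Å except ``hill_width`` and ``restraint_radius`` which,
    like the collective variable itself, are in nm.
    """

    # --- anchor selection and restraint ---
    anchor_cutoff: float = 10.0      # Å, Cα-to-ligand-heavy pocket radius
    restraint_radius: float = 1.0    # nm, flat-bottom radius
    restraint_k: float = 0.0         # kcal/mol/nm^2; 0 = bookkeeping only

    # --- well-tempered metadynamics ---
    hill_height: float = 0.3         # kcal/mol (0.3 or 0.05 are the studied values)
    hill_width: float = 0.002        # nm, Gaussian sigma on the RMSD CV
    pace_ps: float = 100.0           # ps between hill depositions
    bias_factor: float = 4.0         # gamma > 1
    temperature_K: float = 300.0
    duration_ns: float = 10.0
    n_replicas: int = 10
    seed: int = 0                    # master seed; replica i uses seed + i

    # --- scoring ---
    contact_cutoff: float = 3.5      # Å, heavy-atom contact threshold (inclusive)
    hbond_distance: float = 3.5      # Å, donor-acceptor cutoff
    hbond_angle: float = 150.0       # deg, minimum donor-H-acceptor angle
    tail_ns: float = 2.0             # ns, averaging window at the end of the run
    stride_ps: float = 100.0         # ps, measurement stride for all series
    compscore_coefficient: float = 5.0

    # --- provenance flags (recorded, not acted on) ---
    water_equilibrated: bool = False  # whether GCMC/MD water equilibration was run upstream

    def __post_init__(self) -> None:
        if self.hill_height <= 0:
            raise ValueError("hill_height must be > 0")
        if self.hill_width <= 0:
            raise ValueError("hill_width must be > 0")
        if self.bias_factor <= 1:
            raise ValueError("bias_factor must be > 1")
        if self.n_replicas < 1:
            raise ValueError("n_replicas must be >= 1")
        if self.pace_ps <= 0 or self.stride_ps <= 0:
            raise ValueError("pace_ps and stride_ps must be > 0")
        if self.tail_ns <= 0 or self.duration_ns <= 0:
            raise ValueError("tail_ns and duration_ns must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ProtocolConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
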