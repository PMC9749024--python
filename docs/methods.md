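# Methods

## The model

`bpmdkit` treats pose validation as a stability experiment. A candidate
pose defines a reference geometry; well-tempered metadynamics deposits
repulsive Gaussian bias along the pose's aligned ligand-RMSD, actively
pushing the ligand away from that geometry. A pose that sits in a deep
effective free-energy minimum needs a lot of accumulated bias before it
moves; a mis-docked pose drifts early and loses its interaction network.
Scores summarise the endpoint of that perturbation, and replica averaging
(default 10 independent runs per pose) absorbs the stochasticity of any
single trajectory.

The package deliberately separates three layers:

1. **CV and bias bookkeeping** — exact, engine-agnostic, unit-tested
   against closed forms;
2. **dynamics** — pluggable through the `Engine` protocol (toy Langevin,
   scheduled mock, or a user-supplied all-atom adapter);
3. **scoring and ranking** — pure functions of a trajectory plus a config.

## Collective variable

Anchor atoms are the protein Cα atoms with any ligand heavy atom within
`anchor_cutoff` (default 10 Å, a conventional pocket radius). If fewer
than three qualify the cutoff grows in 1 Å steps until three do —
superposition needs three non-collinear points — and the final value is
recorded. The per-frame superposition is a proper-rotation Kabsch fit on
the anchors (via `scipy.spatial.transform.Rotation.align_vectors`);
collinear anchors raise rather than silently produce an ill-conditioned
rotation. The CV is the RMSD of ligand heavy atoms against the reference
after that fit, with **no** ligand fitting, reported in nm (the hill width
σ = 0.002 nm is quoted in nm; structural code stays in PDB-native Å, and
the Å→nm conversion lives in `evaluate_cv` alone).

The CV assumes pre-imaged (whole, recentred) frames; the scoring layer's
`recenter_trajectory` performs that for orthorhombic boxes by shifting the
ligand into the protein centroid's minimum image. A flat-bottom wrapper
between the ligand and anchor centroids is provided for parity with the
production protocol, but its force constant defaults to 0 — with k = 0 it
exerts no force and is pure bookkeeping; the parameter is exposed rather
than second-guessed.

## Well-tempered metadynamics

Hills are stored unmerged (no grid binning): desk-scale runs deposit at
most a few thousand hills, and exactness beats speed at that size. Each
deposit records the *effective* height

w = w₀ · exp(−V(s)/(k_B ΔT)), ΔT = (γ−1)T, k_B = 0.0019872041 kcal/mol/K,

evaluated against the bias present before the hill; heights at a revisited
CV value therefore decay geometrically and are non-increasing, the
well-tempered convergence property. The FES estimate is
F(s) = −γ/(γ−1)·V(s), min-shifted to zero.

Defaults follow the production protocol: w₀ = 0.3 kcal/mol (0.05 for
gentler perturbation), σ = 0.002 nm, pace 100 ps, γ = 4, T = 300 K, 10 ns,
10 replicas. A 100 ps pace is unusually sparse for metadynamics (100 hills
per run); it is kept as the default for fidelity to the protocol but the
pace is a first-class config key, and the desk-scale convergence tests use
1 ps.

## Toy engine

The built-in integrator is BAOAB-split Langevin (standard, stable
splitting; the half-step force evaluations bracket the
Ornstein–Uhlenbeck kick), 2 fs timestep, friction 5 ps⁻¹, reduced units
(energy kcal/mol, time ps, mass in kcal·mol⁻¹·ps²·len⁻²). The CV is the
first coordinate. Noise is pre-drawn in chunks from a seeded PCG64
generator, making runs bitwise reproducible.

Free-energy recovery is exercised on the 1D double well a(x²−1)² with
a = 2.0 kcal/mol — a ≈ 3.4 k_BT barrier at 300 K, chosen once as a system
a single 2 ns biased run can converge — with σ = 0.05 in CV units (about
a tenth of the well half-width), pace 1 ps, and 5 replicas alternating
their starting well. The independent oracle is Boltzmann quadrature
(Simpson on a dense grid, basins split at x = 0, the split point counted
in both basins). The observed mean basin-ΔF error is well inside the
0.5 kcal/mol band the stack asserts.

`ToyPocketEngine` extends this to pose campaigns: the ligand translates
rigidly in a harmonic pocket U = ½k|r|², biased on s = |r|; pocket depth is
per-pose, so stability ordering emerges from dynamics rather than a
script. Frame 0 is the pose itself so the initial contact network is
always defined.

## Scoring

- Series are measured on a 100 ps stride grid anchored at the first
  frame; if the trajectory's frames do not lie on that grid, all frames
  are used.
- **PoseScore**: tail-window (default last 2 ns) mean of the aligned
  RMSD, in Å. The tail window (rather than the full run) is used for
  symmetry with ContactScore and is configurable.
- **Contacts** are protein-heavy/ligand-heavy pairs within 3.5 Å,
  *inclusive* at the boundary (one convention had to be picked; it is
  documented and tested). Minimum-image distances are used when a box is
  present. Waters and ions are excluded. No interaction typing: a contact
  is a contact.
- **ContactScore** is the tail mean of the contact count divided by the
  frame-0 count, unclipped above 1 (an increase in contacts is
  information, not an error). Zero initial contacts is an error — the
  pose is not in the pocket.
- **Hydrogen bonds** (geometry is a package choice, as common
  trajectory-analysis defaults): donor and acceptor are N/O/S across the
  interface, donor–acceptor ≤ 3.5 Å, donor–H–acceptor angle ≥ 150°;
  hydrogens attach to the nearest donor-side polar atom within 1.25 Å.
  **PersScore** is the tail-mean fraction of frame-0 bonds still present;
  with no initial bonds it returns 0 with a `pers_defined=False` flag —
  the metric's documented failure mode for apolar binders, and the reason
  ContactScore exists.
- **CompScore = PoseScore − 5·ContactScore.** The persistence term of the
  original composite is replaced by ContactScore; the coefficient is a
  config key (`compscore_coefficient`, default 5). Lower is stabler; a
  perfectly rigid binder scores exactly −5.

## Campaign, ranking, statistics

Replica i uses seed `master_seed + i` — reproducible, independent
streams. Poses are ranked by mean CompScore ascending with deterministic
tie-breaks (mean PoseScore, then pose id). A replica failure is recorded;
a pose leaves the ranking only if every replica failed. Top-pose
classification compares the pose's *initial* ligand coordinates to the
native geometry (heavy atoms, no ligand fitting; receptor frames
coincide, so the anchor superposition is the identity), at 2 and 3 Å
thresholds. Replica score variability is reported as SD but does not
enter the ranking.

Pearson r comes from `scipy.stats.pearsonr`. The paired two-sided
Wilcoxon signed-rank test is implemented in-package because the required
contract — zero differences dropped, average ranks for ties, exact null
by enumerating all 2ⁿ sign assignments for n ≤ 15 (valid under ties),
tie-corrected normal approximation above — is not scipy's default
surface; scipy is the cross-check in the tests on untied data.

## Synthetic data

The generator emulates exactly the features the scoring stack measures,
and nothing else:

- a rigid Cα scaffold (two rings, outside contact range) so anchor
  selection and alignment run on real code paths;
- engineered contact units, each contributing exactly one
  protein–ligand contact pair at 3.2 Å; hydrogen-bond units with ideal
  N–H···O geometry (2.9 Å, 180°) that also count as one contact;
- trajectories that realise prescribed RMSD/contact/H-bond schedules
  exactly: the ligand drifts rigidly (uniform translation ⇒ RMSD equals
  the displacement), retained contact atoms track the ligand, broken
  ones are pushed 4 Å out of range, broken H-bonds rotate the hydrogen
  off-axis while keeping the heavy-atom contact;
- optional rigid per-frame noise and a global rigid wobble to exercise
  alignment invariance;
- construction is verified at build time: if the requested interface
  cannot be realised exactly, the generator raises.

What this does **not** emulate: internal ligand flexibility, induced-fit
receptor motion, solvent, force-field physics, or correlated noise.
Passing tests therefore demonstrate that the measurement and ranking
machinery is correct and invariant, not that the protocol's success rates
transfer to real protein–ligand systems — benchmark-scale claims require
all-atom simulations through an external engine adapter.

## Numerical choices and limitations

- Boltzmann constant fixed at 0.0019872041 kcal/mol/K everywhere.
- Contact boundary inclusive; stride grid tolerance 1e-6; hill round-trip
  format `%.6e` (6 significant figures).
- Ligands are single residues identified by residue name; mmCIF,
  topology building and charge assignment are out of scope.
- Recentering supports orthorhombic boxes and assumes each molecule is
  whole within a frame.
- `OpenMMEngine` is a contract: it raises a clear optional-dependency
  error without OpenMM and expects users to wrap their parametrised
  all-atom setup in the `Engine` protocol. Production equilibration
  (minimisation, restrained NVT, 4 fs HMR step, PME 10 Å) and GCMC water
  equilibration are upstream concerns; the config records whether water
  equilibration was performed (`water_equilibrated`) but the package does
  not implement it.
- Desk-scale test sizes: 1–2 ns toy runs, 1 ps pace, 3–10 replicas,
  ~40-atom complexes — chosen so the full stack, including free-energy
  convergence, runs in minutes while leaving every algorithmic path
  identical to production settings.
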