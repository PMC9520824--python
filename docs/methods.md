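# Methods

## The problem

Large, flexible, multivalent charged ligands — here a five-unit hybrid
compound GCP–Lys–AIE–Lys–GCP, with two cationic
guanidiniocarbonyl-pyrrole (GCP) oxo-anion binders, two lysine linkers
and a central aggregation-induced-emission (AIE) luminophore — do not
bind into well-defined pockets.  They attach loosely to acidic protein
surfaces (the motivating target is the 14-3-3ζ homodimer) through
charge–charge interactions, which puts them outside the assumptions of
classical docking tools, while all-atom molecular dynamics cannot
sample their conformational freedom at acceptable cost.  `annealdock`
implements the intermediate resolution that works: per-fragment
electrostatic affinity grids around the rigid protein, a coarse-grained
bead-spring ligand, and a large ensemble of simulated-annealing
Metropolis Monte Carlo searches whose low-energy poses are clustered
and checked against the dimer's C2 symmetry.

## Energy model

The ligand is five beads on the nodes of a regular lattice.  Its total
energy is

    E_total = ½ Σ_{i=1..4} k_i (l_i − l_i^eq)²
              + E_g^GCP1 + E_g^Lys1 + E_g^Lys2 + E_g^GCP2

with hard constraints treated as +∞: any non-bonded bead pair closer
than the hard-core diameter `a`, or any bead on a sterically forbidden
node, invalidates the conformation.  The four charged beads read their
interaction energy from pre-computed affinity grids (`E_g`); the AIE
bead is sterically present but has no grid term.

Default parameterization (the production ligand):

| parameter | value | unit | origin |
|---|---|---|---|
| l₁ = l₄ (GCP–Lys) | 6 | Å | atomistic ligand model |
| l₂ = l₃ (Lys–AIE) | 13 | Å | atomistic ligand model |
| k₁ = k₄ | 12 | k_B·T/Ų | Gaussian-chain scaling k ∝ 1/l² |
| k₂ = k₃ | 3 | k_B·T/Ų | Gaussian-chain scaling |
| a | 9.6 | Å | mean pairwise sum of non-bonded bead radii |

k_B·T-unit spring constants are converted to kJ/(mol·Å²) once, at a
fixed reference temperature (default 300 K), and are **not** rescaled
with the annealing temperature: the Hamiltonian must be
temperature-independent for the Metropolis chain to have a well-defined
stationary distribution at each level.

The hard core applies to the six non-bonded pairs only; bonded
neighbours are exempt, and the boundary case d = a is allowed (the
repulsion is ∞ for d < a, 0 for d ≥ a).

## Affinity grids

The protein's electrostatic potential can be supplied externally as an
OpenDX grid (e.g. an APBS Poisson–Boltzmann solution) or computed
internally as a Debye–Hückel screened-Coulomb superposition,

    φ(x) = Σ_i C q_i exp(−κ·max(0, r_i − R_i)) / (ε_r r_i),

with κ from the standard closed form of the ionic strength
(I = ½ Σ c z²; the production solvent is 0.1 M NaCl + 0.01 M MgCl₂,
I = 0.13 M) and ε_r the water permittivity (79).  The internal
potential has no dielectric boundary (the protein permittivity is
accepted for interface compatibility but unused) and no non-linear
screening; it exists so the whole pipeline is self-contained and its
limits are exact and testable (at κ = 0 it reduces to the Coulomb
superposition to machine precision).  Nodes within 0.5 Å of an atom
center are clamped to the 0.5 Å value to avoid the singularity.

A rigid probe fragment (GCP or lysine, read from a small PQR file) is
then scanned over every node for a set of quasi-uniform random
rotations (default 150, deterministic per seed, the first rotation
always the identity).  Probe atom positions between nodes are
interpolated trilinearly; a probe atom leaving the lattice or touching
a forbidden corner node with non-zero weight makes that rotation +∞.
Per node the rotation energies are combined either as the minimum or as
the Boltzmann-weighted free energy −k_B T ln[(1/N) Σ exp(−E_r/k_B T)]
at 300 K (the default; rotations at +∞ contribute zero weight).  Steric
exclusion is a strict inequality: a node is forbidden iff it lies
strictly inside an atom's van der Waals sphere (optionally inflated by
a probe pad).

The production grid resolution is 0.4 Å; coarser grids lose the C2
symmetry of the target, which is why the synthetic fixtures (3 Å) need
the move-scale adjustment described below.

## Annealing protocol

Each run fixes the AIE bead on a node drawn from a placement layer —
all allowed nodes within a thickness of the protein van der Waals
surface, default 19 Å = l₁ + l₂, so the chain can always fold back
onto the surface.  The surface distance is min_i(|x − c_i| − R_i) when
the protein structure is available; with only a mask, the Euclidean
distance transform of the forbidden region is used instead.

The other four beads start on random allowed nodes at approximately
their equilibrium distances and then undergo Metropolis MC: one mobile
bead chosen uniformly, displaced by an integer vector with components
uniform on {−m, …, +m} (production m = 6 grid lengths = 2.4 Å),
accepted with probability min(1, exp(−ΔE/k_B T)).  Cooling is geometric
(default α = 0.95) from T₀ = 3000 K; each level ends after 10000
proposals or 1000 acceptances, whichever comes first, and the run ends
once a level's acceptance ratio falls below 1% (or a level-count
safeguard, default 200, is reached).  The production ensemble is 4000
restarts.  Per-run random streams are spawned from the master seed, so
ensembles are bit-reproducible and order-stable; the final energy is
re-evaluated from the final conformation rather than taken from the
incrementally tracked value.

The proposal/acceptance loop is compiled with numba.  NumPy
`Generator` bit streams are identical in compiled and interpreted code,
so the pure-Python operations (`propose_move`, `delta_energy`,
`metropolis_accept`) replay a compiled level exactly; the test suite
pins this equivalence bit for bit.

### Coarse-lattice schedule

The <1% stop and the ±6-node move are calibrated for 0.4 Å lattices.
Two artifacts appear on the 3 Å fixture lattices: (a) ±6 nodes is
±18 Å, so almost every proposal violates a spring; (b) the null
proposal (zero displacement, always accepted since ΔE = 0) alone has
probability (2m+1)⁻³ — at m = 2 that is 0.8%, so the acceptance ratio
hovers at the stop threshold and runs freeze while k_B T is still
≈ 7 kJ/mol, occasionally diffusing out of an already-found minimum
just before termination.  The fixture-scale protocol therefore uses
m = 1 (3 Å moves, matching the production move length) with the stop
rule inert and the schedule bounded at 40–60 levels, which cools to
k_B T ≈ 10⁻³ kJ/mol, far below the smallest energy differences in the
fixtures.  Production defaults are untouched.

## Synthetic fixtures and the oracle

`make_planted_minimum_instance` builds a self-contained problem: a
single spherical forbidden region (one atom of radius 6 Å) at the grid
center, an AIE anchor node standing off the surface, and Gaussian wells
(half-width one node, default depth 50 kJ/mol) planted in the GCP and
Lys grids at spring-compatible offsets, over zero-mean Gaussian
background noise (default σ = 0.5 kJ/mol).  One (Lys, GCP) well pair is
planted per half-chain, on opposite tangential sides of the anchor with
all mutual hard-core distances respected, so the global optimum pins
all four charged beads in wells.  (With a single pair, the free
half-chain's optimum is the argmin of the background noise — a needle
that independent restarts cannot reproducibly locate, which would make
exact ensemble-vs-oracle comparisons meaningless.)

The C2 variant symmetrizes the noise, mirrors the well layout and
anchor under a 180° rotation about the z axis, and re-symmetrizes the
final fields so the two grids are bit-exactly symmetric.  Two
subtleties are handled at generation time: the anchor stands further
off the surface so that no near-axis placement can reach wells of both
mirror images at once; and because the anchor enters the energy only
through two spring lengths, any well pair leaves a whole circle of
geometrically equivalent anchors — with lattice-aligned wells that
circle passes through many lattice nodes and the optimum is massively
degenerate.  The generator breaks the well-pair axis alignment
(deterministic tie-break directions) and certifies numerically that the
minimal-strain anchor over the whole layer is unique up to the mirror
pair, with a clear gap (> 0.5 kJ/mol) to the next-best anchor.

`brute_force_global_minimum` enumerates both (Lys, GCP) half-chains
over all allowed nodes within spring reach (equilibrium ± 4.5 Å by
default) of their anchors, sorts them by energy and combines them under
the cross hard-core constraints with a branch-and-bound sweep.  It is
exact over the enumerated set; placements outside the reach pad are
excluded because their spring strain alone (≥ ½·k·4.5² ≈ 76 kJ/mol for
the soft springs) exceeds any planted well depth.  Oracle energies are
reported through the production energy function, so equality
comparisons are meaningful at 1e-9 kJ/mol.

## Analysis

Final-energy histograms (log-scaled counts, energies untouched),
lowest-k run extraction (ties broken by run index), k-medoids (PAM:
greedy BUILD + full SWAP, cost non-increasing) on the AIE positions of
the lowest-energy fraction of runs (default 5%), with silhouette-based
automatic k in [2, 10]; a C2 symmetry score (median distance from the
180°-rotated point set to its nearest original point — 0 for an
exactly symmetric set, 2r for a single point at axis distance r); and
residue contact reports (residues with any atom within a cutoff,
default 5 Å, of any bead center, with the nearest bead kind).  The
symmetry axis is supplied by the user; the tool does not infer
biological symmetry axes.

## What the fixtures do and do not show

Passing tests demonstrate that the sampler is a correct Metropolis
chain (calibrated acceptance, Boltzmann-distributed occupancies on an
enumerable state space), that the restart ensemble finds exact global
optima of rugged planted landscapes, and that exactly symmetric inputs
yield symmetric predictions.  The fixtures do not emulate real protein
electrostatics: wells are isotropic Gaussians, the steric region is a
sphere, and the background noise is uncorrelated — so the tests say
nothing about the physical accuracy of a Debye–Hückel potential versus
a non-linear Poisson–Boltzmann solution, about desolvation (not
modeled, as acknowledged for the grid approach generally), or about
the adequacy of 150 rotations for a particular fragment.  Production
use should feed APBS/Epitopsy-grade grids through the DX reader.

## Numerical choices

- Energies in kJ/mol, lengths in Å, charges in |e|; k_B =
  0.0083145 kJ/(mol·K), Coulomb constant 1389.35 kJ·Å/(mol·e²).
- Beads live on nodes; distances are Cartesian (anisotropic spacing
  supported).  Node (i,j,k) sits at origin + spacing∘(i,j,k), 0-based.
- DX serialization: z-index fastest (APBS convention); forbidden nodes
  written as a 1e30 kJ/mol sentinel and recovered by thresholding on
  read (DX has no mask channel), so round-trips preserve allowed-node
  values and the mask but not values hidden under the mask.
- PQR: whitespace-separated and fixed-column dialects accepted,
  detected per line; chain id optional.
- Off-grid proposals are evaluated as +∞ and rejected, not re-drawn;
  +∞ rejections consume no uniform draw.
- Acceptance ratios are measured per completed level.
- The fixed-temperature occupancy diagnostic thins its samples
  (default parameter, tests use every 250th step) because raw per-step
  Metropolis occupancies are autocorrelated and would inflate
  frequency-based goodness-of-fit statistics.

## Known limitations

- No dielectric boundary or desolvation in the built-in potential.
- The chain length is fixed at five beads; the AIE bead is immobile
  within a run (as in the production protocol).
- k-medoids is O(n²·k·iterations); intended for the low-energy subset
  (tens to hundreds of points), not whole ensembles.
- The non-linear Poisson–Boltzmann solve and FFT-accelerated probe
  correlation are out of scope; the direct scan is meant for desk-scale
  grids.
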