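"""Coarse-grained five-bead ligand and its energy function.

The ligand is a bead-spring chain GCP–Lys–AIE–Lys–GCP: two cationic
guanidiniocarbonyl-pyrrole (GCP) head groups, two lysine linkers and a
central aggregation-induced-emission (AIE) luminophore.  Consecutive
beads are joined by harmonic springs; non-bonded bead pairs repel as
hard spheres of common diameter ``a``.  The four charged beads (GCP and
Lys) interact with the protein through pre-computed affinity grids; the
AIE bead is sterically present but carries no grid term.

Total energy of a conformation:

    E_total = ½ Σ_{i=1..4} k_i (l_i − l_i^eq)²
              + E_g^GCP1 + E_g^Lys1 + E_g^Lys2 + E_g^GCP2

where ``l_i`` is the bond length between beads i and i+1, plus a hard
+∞ penalty when a non-bonded pair comes closer than ``a`` or a bead sits
on a sterically forbidden grid node.

Beads live on grid nodes (Monte-Carlo moves are defined in grid
lengths); all distances are Cartesian Å.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KB
from .io_formats import GridSpec, ScalarGrid

__all__ = [
    "BEAD_KINDS",
    "MOBILE_BEADS",
    "AIE_BEAD",
    "NON_BONDED_PAIRS",
    "BeadSpringLigand",
    "Conformation",
    "default_ligand",
    "bond_lengths",
    "spring_energy",
    "hard_core_ok",
    "grid_energy",
    "total_energy",
]

#: Chain composition, N- to C-like order.
BEAD_KINDS = ("GCP", "Lys", "AIE", "Lys", "GCP")

#: Index of the fixed central luminophore bead.
AIE_BEAD = 2

#: Beads that Monte-Carlo moves may displace.
MOBILE_BEADS = (0, 1, 3, 4)

#: All non-bonded pairs; bonded neighbours are exempt from the hard core.
NON_BONDED_PAIRS = ((0, 2), (0, 3), (0, 4), (1, 3), (1, 4), (2, 4))

#: Which affinity grid each bead reads from (None = no grid term).
BEAD_GRID = ("gcp", "lys", None, "lys", "gcp")


@dataclass(frozen=True)
class BeadSpringLigand:
    """Parameters of the five-bead chain.

    ``spring_eq_lengths``/``spring_constants`` are ordered along the
    chain: (GCP–Lys, Lys–AIE, AIE–Lys, Lys–GCP).  Constants are stored
    in kJ/(mol·Å²); ``reference_temperature`` records the temperature at
    which k_B·T-unit inputs were converted and is *not* rescaled during
    annealing (the Hamiltonian is temperature-independent).
    """

    spring_eq_lengths: tuple[float, float, float, float]
    spring_constants: tuple[float, float, float, float]
    hard_core: float
    reference_temperature: float = 300.0
    bead_kinds: tuple[str, ...] = BEAD_KINDS

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "spring_eq_lengths", tuple(float(v) for v in self.spring_eq_lengths)
        )
        object.__setattr__(
            self, "spring_constants", tuple(float(v) for v in self.spring_constants)
        )
        if len(self.spring_eq_lengths) != 4 or len(self.spring_constants) != 4:
            raise ValueError("five-bead chain needs exactly four springs")
        if any(l <= 0 for l in self.spring_eq_lengths):
            raise ValueError("equilibrium lengths must be > 0")
        if any(k <= 0 for k in self.spring_constants):
            raise ValueError("spring constants must be > 0")
        if self.hard_core <= 0:
            raise ValueError("hard-core diameter must be > 0")
        if self.reference_temperature <= 0:
            raise ValueError("reference temperature must be > 0")

    @property
    def kbt(self) -> float:
        """k_B·T_ref in kJ/mol."""
        return KB * self.reference_temperature


@dataclass
class Conformation:
    """Current bead positions as integer grid-node triples, shape (5, 3).

    The AIE bead is element ``AIE_BEAD`` of the chain.
    """

    bead_nodes: np.ndarray

    def __post_init__(self) -> None:
        self.bead_nodes = np.asarray(self.bead_nodes, dtype=np.int64)
        if self.bead_nodes.shape != (5, 3):
            raise ValueError("a conformation is five integer node triples")

    def copy(self) -> "Conformation":
        return Conformation(self.bead_nodes.copy())


def default_ligand(reference_T: float = 300.0) -> BeadSpringLigand:
    """The production ligand parameterization.

    Equilibrium lengths 6 Å (GCP–Lys) and 13 Å (Lys–AIE); spring
    constants 12 and 3 k_B·T/Å² converted to kJ/(mol·Å²) at
    ``reference_T``; hard-core diameter a = 9.6 Å (average pairwise sum
    of non-bonded bead radii in the atomistic ligand model).
    """
    if reference_T <= 0:
        raise ValueError("reference temperature must be > 0")
    kbt = KB * reference_T
    return BeadSpringLigand(
        spring_eq_lengths=(6.0, 13.0, 13.0, 6.0),
        spring_constants=(12.0 * kbt, 3.0 * kbt, 3.0 * kbt, 12.0 * kbt),
        hard_core=9.6,
        reference_temperature=reference_T,
    )


def bond_lengths(conf: Conformation, spec: GridSpec) -> np.ndarray:
    """Euclidean lengths (Å) of the four bonds, Cartesian node centers."""
    cart = conf.bead_nodes * spec.spacing  # origin cancels in differences
    return np.linalg.norm(np.diff(cart, axis=0), axis=1)


def spring_energy(conf: Conformation, ligand: BeadSpringLigand, spec: GridSpec) -> float:
    """Harmonic term ½ Σ k_i (l_i − l_i^eq)², kJ/mol."""
    lengths = bond_lengths(conf, spec)
    k = np.asarray(ligand.spring_constants)
    leq = np.asarray(ligand.spring_eq_lengths)
    return float(0.5 * np.sum(k * (lengths - leq) ** 2))


def hard_core_ok(conf: Conformation, ligand: BeadSpringLigand, spec: GridSpec) -> bool:
    """True iff every non-bonded pair keeps distance d ≥ a.

    The repulsion is a hard sphere: +∞ for d < a, 0 for d ≥ a, so the
    boundary d = a is allowed.  Bonded neighbours are exempt.
    """
    cart = conf.bead_nodes * spec.spacing
    a2 = ligand.hard_core**2
    for i, j in NON_BONDED_PAIRS:
        d = cart[i] - cart[j]
        if float(d @ d) < a2:
            return False
    return True


def grid_energy(conf: Conformation, gcp_grid: ScalarGrid, lys_grid: ScalarGrid) -> float:
    """Sum of affinity-grid values under the four charged beads, kJ/mol.

    +∞ if any of the four beads is out of bounds or on a forbidden node
    of its grid.  The AIE bead contributes no grid term.
    """
    if not gcp_grid.spec.same_geometry(lys_grid.spec):
        raise ValueError("GCP and Lys affinity grids must share geometry")
    total = 0.0
    shape = np.array(gcp_grid.spec.shape)
    for b, kind in enumerate(BEAD_GRID):
        if kind is None:
            continue
        node = conf.bead_nodes[b]
        if np.any(node < 0) or np.any(node >= shape):
            return np.inf
        grid = gcp_grid if kind == "gcp" else lys_grid
        idx = (int(node[0]), int(node[1]), int(node[2]))
        if grid.forbidden[idx]:
            return np.inf
        total += float(grid.values[idx])
    return total


def total_energy(
    conf: Conformation,
    ligand: BeadSpringLigand,
    gcp_grid: ScalarGrid,
    lys_grid: ScalarGrid,
) -> float:
    """Full Hamiltonian: +∞ on hard-core violation or forbidden node,
    otherwise spring + grid energy."""
    if not hard_core_ok(conf, ligand, gcp_grid.spec):
        return np.inf
    e_grid = grid_energy(conf, gcp_grid, lys_grid)
    if np.isinf(e_grid):
        return np.inf
    return spring_energy(conf, ligand, gcp_grid.spec) + e_grid
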