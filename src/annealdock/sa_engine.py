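"""Simulated annealing of the bead-spring ligand on affinity grids.

Each run fixes the central AIE bead on a node of a placement layer
around the protein surface and anneals the four charged beads with
Metropolis Monte Carlo: single-bead moves of at most ``max_displacement``
grid lengths per axis, geometric cooling from a very high starting
temperature, each temperature level capped by a move and an
accepted-move budget, and the whole run terminated once a level's
acceptance ratio drops below ``stop_acceptance``.

An ensemble of many such restarts (the production protocol uses 4000)
maps the low-energy binding regions; the per-run final energies feed the
downstream histogram/clustering analysis.

The inner proposal loop is compiled with numba.  NumPy ``Generator``
streams drawn inside compiled code are bit-identical to the interpreted
ones, so the pure-Python operations (``propose_move``,
``metropolis_accept``, ``delta_energy``) replay the compiled trajectory
exactly; a regression test holds the two paths together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import ndimage

from .constants import KB
from .io_formats import GridSpec, ProteinStructure, ScalarGrid
from .ligand_model import (
    AIE_BEAD,
    MOBILE_BEADS,
    BeadSpringLigand,
    Conformation,
    hard_core_ok,
    total_energy,
)

__all__ = [
    "SAConfig",
    "LevelStats",
    "SARunResult",
    "SAState",
    "InitializationError",
    "placement_layer",
    "init_conformation",
    "propose_move",
    "metropolis_accept",
    "delta_energy",
    "run_level",
    "simulated_annealing",
    "run_ensemble",
    "fixed_temperature_counts",
]


class InitializationError(RuntimeError):
    """No feasible starting conformation could be built."""


@dataclass(frozen=True)
class SAConfig:
    """Annealing schedule and move parameters.

    Defaults follow the production protocol: start at 3000 K, geometric
    cooling, levels capped at 10000 proposals or 1000 acceptances, stop
    below 1% acceptance, single-bead moves of up to 6 grid lengths per
    axis.
    """

    T0: float = 3000.0
    cooling_factor: float = 0.95
    level_max_moves: int = 10000
    level_max_accepted: int = 1000
    stop_acceptance: float = 0.01
    max_displacement: int = 6
    max_levels: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T0 <= 0:
            raise ValueError("T0 must be > 0")
        if not (0.0 < self.cooling_factor < 1.0):
            raise ValueError("cooling_factor must be in (0, 1)")
        if self.level_max_moves < 1 or self.level_max_accepted < 1 or self.max_levels < 1:
            raise ValueError("level caps must be positive")
        if not (0.0 < self.stop_acceptance < 1.0):
            raise ValueError("stop_acceptance must be in (0, 1)")
        if self.max_displacement < 1:
            raise ValueError("max_displacement must be >= 1")


@dataclass
class LevelStats:
    """Outcome of one temperature level."""

    temperature: float
    proposals: int
    acceptances: int
    best_energy_so_far: float

    @property
    def acceptance_ratio(self) -> float:
        return self.acceptances / self.proposals if self.proposals else 0.0


@dataclass
class SARunResult:
    """Outcome of one annealing run (one fixed AIE placement)."""

    aie_node: tuple[int, int, int]
    final_conformation: Conformation
    final_total_energy: float
    levels: list[LevelStats]
    terminated_by: str
    run_id: int = -1


@dataclass
class SAState:
    """Mutable Markov-chain state: conformation plus its tracked energy."""

    conf: Conformation
    energy: float


# --------------------------------------------------------------------------
# AIE placement layer
# --------------------------------------------------------------------------

def placement_layer(
    mask: np.ndarray,
    spec: GridSpec,
    thickness: float = 19.0,
    protein: ProteinStructure | None = None,
) -> np.ndarray:
    """Allowed nodes within ``thickness`` Å of the protein surface,
    as an (N, 3) array of node triples.

    With a protein given, the surface distance of a node is
    ``min_i(|x − c_i| − R_i)`` over atoms (distance to the van der Waals
    surface); without one it falls back to the Euclidean distance
    transform of the forbidden region.  The default thickness, 19 Å,
    is the AIE-to-GCP equilibrium distance of the production ligand
    (13 Å + 6 Å), so every layer node can in principle fold the chain
    back onto the surface.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != spec.shape:
        raise ValueError(f"mask shape {mask.shape} != grid shape {spec.shape}")
    if not mask.any():
        raise ValueError(
            "the mask has no forbidden nodes: there is no protein surface "
            "to anchor the placement layer"
        )
    if protein is not None:
        xs, ys, zs = spec.node_coordinates()
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        nodes = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
        dist = np.full(nodes.shape[0], np.inf)
        for atom in protein.atoms:
            r = np.linalg.norm(nodes - atom.position, axis=1) - atom.radius
            np.minimum(dist, r, out=dist)
        in_layer = (~mask.reshape(-1)) & (dist < thickness)
        layer = np.argwhere(in_layer.reshape(spec.shape))
    else:
        edt = ndimage.distance_transform_edt(~mask, sampling=spec.spacing)
        layer = np.argwhere((~mask) & (edt <= thickness))
    if layer.shape[0] == 0:
        raise ValueError(
            "placement layer is empty; enlarge the grid margins or the "
            "layer thickness"
        )
    return layer.astype(np.int64)


# --------------------------------------------------------------------------
# Initial conformation
# --------------------------------------------------------------------------

def _shell_offsets(spec: GridSpec, target: float, tol: float) -> np.ndarray:
    """Integer node offsets whose Cartesian length is in
    [target − tol, target + tol]."""
    reach = target + tol
    nmax = np.ceil(reach / spec.spacing).astype(int)
    ax = [np.arange(-n, n + 1) for n in nmax]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    offs = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
    d = np.linalg.norm(offs * spec.spacing, axis=1)
    keep = (d >= target - tol) & (d <= reach)
    return offs[keep]


def init_conformation(
    aie_node: np.ndarray,
    ligand: BeadSpringLigand,
    gcp_grid: ScalarGrid,
    lys_grid: ScalarGrid,
    rng: np.random.Generator,
    shell_tol: float = 3.0,
    max_retries: int = 1000,
) -> Conformation:
    """Random feasible starting conformation around a fixed AIE node.

    Each Lys bead is drawn on an allowed node at ≈ the Lys–AIE
    equilibrium distance of the AIE bead (± ``shell_tol`` Å), each GCP
    bead at ≈ the GCP–Lys equilibrium distance of its Lys; draws are
    retried until the hard core is satisfied and the total energy is
    finite.  Deterministic for a given generator state.
    """
    spec = gcp_grid.spec
    aie_node = np.asarray(aie_node, dtype=np.int64)
    shape = np.array(spec.shape)
    if np.any(aie_node < 0) or np.any(aie_node >= shape):
        raise InitializationError(f"AIE node {tuple(aie_node)} is out of grid bounds")
    if gcp_grid.forbidden[tuple(aie_node)] or lys_grid.forbidden[tuple(aie_node)]:
        raise InitializationError(f"AIE node {tuple(aie_node)} is sterically forbidden")

    lys_offs = _shell_offsets(spec, ligand.spring_eq_lengths[1], shell_tol)
    gcp_offs = _shell_offsets(spec, ligand.spring_eq_lengths[0], shell_tol)

    def _draw(anchor: np.ndarray, offs: np.ndarray, forb: np.ndarray) -> np.ndarray | None:
        node = anchor + offs[rng.integers(offs.shape[0])]
        if np.any(node < 0) or np.any(node >= shape):
            return None
        if forb[tuple(node)]:
            return None
        return node

    for _ in range(max_retries):
        lys1 = _draw(aie_node, lys_offs, lys_grid.forbidden)
        if lys1 is None:
            continue
        gcp1 = _draw(lys1, gcp_offs, gcp_grid.forbidden)
        if gcp1 is None:
            continue
        lys2 = _draw(aie_node, lys_offs, lys_grid.forbidden)
        if lys2 is None:
            continue
        gcp2 = _draw(lys2, gcp_offs, gcp_grid.forbidden)
        if gcp2 is None:
            continue
        conf = Conformation(np.array([gcp1, lys1, aie_node, lys2, gcp2]))
        if hard_core_ok(conf, ligand, spec) and np.isfinite(
            total_energy(conf, ligand, gcp_grid, lys_grid)
        ):
            return conf
    raise InitializationError(
        "no feasible starting conformation around AIE node "
        f"{tuple(int(v) for v in aie_node)} after {max_retries} attempts"
    )


# --------------------------------------------------------------------------
# Elementary Markov-chain operations (pure Python)
# --------------------------------------------------------------------------

def propose_move(
    conf: Conformation, config: SAConfig, rng: np.random.Generator
) -> tuple[int, Conformation]:
    """Draw one single-bead move: a mobile bead chosen uniformly, each
    displacement component uniform on {−max_displacement, …,
    +max_displacement}.  The AIE bead never moves.  Returns the moved
    bead index and the candidate conformation (which may be
    infeasible — rejection happens downstream)."""
    m = MOBILE_BEADS[int(rng.integers(0, len(MOBILE_BEADS)))]
    d = config.max_displacement
    disp = np.array(
        [int(rng.integers(-d, d + 1)) for _ in range(3)], dtype=np.int64
    )
    cand = conf.copy()
    cand.bead_nodes[m] += disp
    return m, cand


def metropolis_accept(delta_E: float, T: float, rng: np.random.Generator) -> bool:
    """Metropolis criterion: accept when ΔE ≤ 0, else with probability
    exp(−ΔE/(k_B·T)); ΔE = +∞ is rejected without consuming a draw."""
    if T <= 0:
        raise ValueError("temperature must be > 0")
    if delta_E <= 0.0:
        return True
    if not np.isfinite(delta_E):
        return False
    return float(rng.random()) < np.exp(-delta_E / (KB * T))


def delta_energy(
    state: SAState,
    moved_bead: int,
    candidate: Conformation,
    ligand: BeadSpringLigand,
    gcp_grid: ScalarGrid,
    lys_grid: ScalarGrid,
) -> float:
    """Energy change of a single-bead move, evaluated incrementally
    (only the touched bonds, the moved bead's grid term and its
    hard-core pairs).  Mirrors the compiled kernel arithmetic."""
    return _delta_e_kernel(
        state.conf.bead_nodes,
        np.asarray(candidate.bead_nodes[moved_bead]),
        moved_bead,
        gcp_grid.values,
        gcp_grid.forbidden,
        lys_grid.values,
        lys_grid.forbidden,
        gcp_grid.spec.spacing,
        np.asarray(ligand.spring_constants),
        np.asarray(ligand.spring_eq_lengths),
        ligand.hard_core**2,
    )


# --------------------------------------------------------------------------
# Compiled core
# --------------------------------------------------------------------------

# grid code per bead: 0 = GCP grid, 1 = Lys grid, 2 = no grid term (AIE)
_BEAD_GRID_CODE = np.array([0, 1, 2, 1, 0], dtype=np.int64)
_MOBILE = np.array(MOBILE_BEADS, dtype=np.int64)


@njit(cache=False)
def _delta_e_kernel(
    beads, new_node, m, gcp_vals, gcp_forb, lys_vals, lys_forb,
    spacing, k_arr, leq_arr, a2,
):
    nx, ny, nz = gcp_vals.shape
    # bounds
    if (
        new_node[0] < 0 or new_node[0] >= nx
        or new_node[1] < 0 or new_node[1] >= ny
        or new_node[2] < 0 or new_node[2] >= nz
    ):
        return np.inf
    # forbidden node of the bead's own grid (both grids share the mask
    # by construction, but they are checked independently)
    code = _BEAD_GRID_CODE[m]
    if code == 0:
        if gcp_forb[new_node[0], new_node[1], new_node[2]]:
            return np.inf
    elif code == 1:
        if lys_forb[new_node[0], new_node[1], new_node[2]]:
            return np.inf
    # hard core against non-bonded partners
    for j in range(5):
        if j == m or j == m - 1 or j == m + 1:
            continue
        dx = (new_node[0] - beads[j, 0]) * spacing[0]
        dy = (new_node[1] - beads[j, 1]) * spacing[1]
        dz = (new_node[2] - beads[j, 2]) * spacing[2]
        if dx * dx + dy * dy + dz * dz < a2:
            return np.inf
    de = 0.0
    # grid term of the moved bead
    if code == 0:
        de += (
            gcp_vals[new_node[0], new_node[1], new_node[2]]
            - gcp_vals[beads[m, 0], beads[m, 1], beads[m, 2]]
        )
    elif code == 1:
        de += (
            lys_vals[new_node[0], new_node[1], new_node[2]]
            - lys_vals[beads[m, 0], beads[m, 1], beads[m, 2]]
        )
    # touched bonds: (m-1, m) and (m, m+1)
    for bond in (m - 1, m):
        if bond < 0 or bond > 3:
            continue
        # bond endpoints are (bond, bond+1); the one that is not m:
        if bond == m:
            other = m + 1
        else:
            other = m - 1
        dxo = (beads[m, 0] - beads[other, 0]) * spacing[0]
        dyo = (beads[m, 1] - beads[other, 1]) * spacing[1]
        dzo = (beads[m, 2] - beads[other, 2]) * spacing[2]
        l_old = np.sqrt(dxo * dxo + dyo * dyo + dzo * dzo)
        dxn = (new_node[0] - beads[other, 0]) * spacing[0]
        dyn = (new_node[1] - beads[other, 1]) * spacing[1]
        dzn = (new_node[2] - beads[other, 2]) * spacing[2]
        l_new = np.sqrt(dxn * dxn + dyn * dyn + dzn * dzn)
        dl_new = l_new - leq_arr[bond]
        dl_old = l_old - leq_arr[bond]
        de += 0.5 * k_arr[bond] * (dl_new * dl_new - dl_old * dl_old)
    return de


@njit(cache=False)
def _step_kernel(
    beads, energy, T, max_disp,
    gcp_vals, gcp_forb, lys_vals, lys_forb,
    spacing, k_arr, leq_arr, a2, kb, rng,
):
    """One proposal + Metropolis decision.  Returns (accepted, energy)."""
    m = _MOBILE[rng.integers(0, 4)]
    new_node = np.empty(3, dtype=np.int64)
    for d in range(3):
        new_node[d] = beads[m, d] + rng.integers(-max_disp, max_disp + 1)
    de = _delta_e_kernel(
        beads, new_node, m, gcp_vals, gcp_forb, lys_vals, lys_forb,
        spacing, k_arr, leq_arr, a2,
    )
    accept = False
    if de <= 0.0:
        accept = True
    elif np.isfinite(de):
        if rng.random() < np.exp(-de / (kb * T)):
            accept = True
    if accept:
        beads[m, 0] = new_node[0]
        beads[m, 1] = new_node[1]
        beads[m, 2] = new_node[2]
        energy = energy + de
    return accept, energy


@njit(cache=False)
def _level_kernel(
    beads, energy, T, max_moves, max_accepted, max_disp,
    gcp_vals, gcp_forb, lys_vals, lys_forb,
    spacing, k_arr, leq_arr, a2, kb, rng,
):
    """One temperature level: propose until a cap is reached.
    Returns (proposals, acceptances, energy, best_energy_in_level)."""
    proposals = 0
    acceptances = 0
    best = energy
    while proposals < max_moves and acceptances < max_accepted:
        accepted, energy = _step_kernel(
            beads, energy, T, max_disp,
            gcp_vals, gcp_forb, lys_vals, lys_forb,
            spacing, k_arr, leq_arr, a2, kb, rng,
        )
        proposals += 1
        if accepted:
            acceptances += 1
            if energy < best:
                best = energy
    return proposals, acceptances, energy, best


@njit(cache=False)
def _count_kernel(
    beads, energy, T, n_steps, thin, max_disp, track_bead, counts,
    gcp_vals, gcp_forb, lys_vals, lys_forb,
    spacing, k_arr, leq_arr, a2, kb, rng,
):
    """Fixed-temperature chain recording the occupancy of one bead's
    (flattened) node index every ``thin`` steps.  Detailed-balance
    diagnostic."""
    ny = gcp_vals.shape[1]
    nz = gcp_vals.shape[2]
    for step in range(n_steps):
        _, energy = _step_kernel(
            beads, energy, T, max_disp,
            gcp_vals, gcp_forb, lys_vals, lys_forb,
            spacing, k_arr, leq_arr, a2, kb, rng,
        )
        if (step + 1) % thin == 0:
            flat = (beads[track_bead, 0] * ny + beads[track_bead, 1]) * nz + beads[
                track_bead, 2
            ]
            counts[flat] += 1
    return energy


def _grid_arrays(gcp_grid: ScalarGrid, lys_grid: ScalarGrid):
    return (
        np.ascontiguousarray(gcp_grid.values),
        np.ascontiguousarray(gcp_grid.forbidden),
        np.ascontiguousarray(lys_grid.values),
        np.ascontiguousarray(lys_grid.forbidden),
    )


# --------------------------------------------------------------------------
# Level / run / ensemble drivers
# --------------------------------------------------------------------------

def run_level(
    state: SAState,
    T: float,
    ligand: BeadSpringLigand,
    gcp_grid: ScalarGrid,
    lys_grid: ScalarGrid,
    config: SAConfig,
    rng: np.random.Generator,
) -> LevelStats:
    """Run one Metropolis level at temperature ``T``; the state is
    updated in place and the level statistics returned."""
    if T <= 0:
        raise ValueError("temperature must be > 0")
    gv, gf, lv, lf = _grid_arrays(gcp_grid, lys_grid)
    beads = state.conf.bead_nodes
    proposals, acceptances, energy, best = _level_kernel(
        beads, state.energy, T,
        config.level_max_moves, config.level_max_accepted, config.max_displacement,
        gv, gf, lv, lf,
        gcp_grid.spec.spacing,
        np.asarray(ligand.spring_constants), np.asarray(ligand.spring_eq_lengths),
        ligand.hard_core**2, KB, rng,
    )
    state.energy = float(energy)
    return LevelStats(T, int(proposals), int(acceptances), float(best))


def simulated_annealing(
    aie_node: np.ndarray,
    ligand: BeadSpringLigand,
    gcp_grid: ScalarGrid,
    lys_grid: ScalarGrid,
    config: SAConfig,
    rng: np.random.Generator | None = None,
    run_id: int = -1,
) -> SARunResult:
    """One annealing run with the AIE bead fixed on ``aie_node``.

    Temperature levels follow T0·αⁿ until a level's acceptance ratio
    drops below ``stop_acceptance`` or ``max_levels`` is reached.  The
    reported final energy is re-evaluated from the final conformation
    (not the incrementally tracked value).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    conf = init_conformation(aie_node, ligand, gcp_grid, lys_grid, rng)
    state = SAState(conf, total_energy(conf, ligand, gcp_grid, lys_grid))
    levels: list[LevelStats] = []
    best = state.energy
    terminated_by = "max_levels"
    for n in range(config.max_levels):
        T = config.T0 * config.cooling_factor**n
        stats = run_level(state, T, ligand, gcp_grid, lys_grid, config, rng)
        best = min(best, stats.best_energy_so_far)
        stats.best_energy_so_far = best
        levels.append(stats)
        if stats.acceptance_ratio < config.stop_acceptance:
            terminated_by = "acceptance"
            break
    final_energy = total_energy(state.conf, ligand, gcp_grid, lys_grid)
    return SARunResult(
        aie_node=tuple(int(v) for v in np.asarray(aie_node)),
        final_conformation=state.conf,
        final_total_energy=float(final_energy),
        levels=levels,
        terminated_by=terminated_by,
        run_id=run_id,
    )


def run_ensemble(
    n_runs: int,
    layer: np.ndarray,
    ligand: BeadSpringLigand,
    gcp_grid: ScalarGrid,
    lys_grid: ScalarGrid,
    config: SAConfig,
) -> list[SARunResult]:
    """Independent annealing restarts with AIE nodes drawn uniformly
    (with replacement) from the placement layer.

    Per-run random streams are spawned deterministically from the master
    seed, so the result list is reproducible and order-stable.  The
    production protocol uses ``n_runs=4000``.
    """
    layer = np.asarray(layer, dtype=np.int64)
    if layer.ndim != 2 or layer.shape[1] != 3 or layer.shape[0] == 0:
        raise ValueError("layer must be a non-empty (N, 3) array of nodes")
    children = np.random.SeedSequence(config.seed).spawn(n_runs)
    results: list[SARunResult] = []
    for i in range(n_runs):
        rng = np.random.default_rng(children[i])
        aie = layer[int(rng.integers(layer.shape[0]))]
        results.append(
            simulated_annealing(
                aie, ligand, gcp_grid, lys_grid, config, rng=rng, run_id=i
            )
        )
    return results


def fixed_temperature_counts(
    state: SAState,
    T: float,
    n_steps: int,
    ligand: BeadSpringLigand,
    gcp_grid: ScalarGrid,
    lys_grid: ScalarGrid,
    config: SAConfig,
    rng: np.random.Generator,
    track_bead: int = 0,
    thin: int = 1,
) -> np.ndarray:
    """Run a fixed-temperature Metropolis chain and return per-node
    visit counts (flattened, C order) of one bead, recorded every
    ``thin`` steps.

    This is a detailed-balance diagnostic: on an enumerable state space
    the visit frequencies must converge to Boltzmann weights.  Thinning
    decorrelates successive occupancy samples so that frequency-based
    goodness-of-fit statistics keep their nominal distribution.
    """
    if track_bead == AIE_BEAD:
        raise ValueError("the AIE bead is fixed; tracking it is vacuous")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    gv, gf, lv, lf = _grid_arrays(gcp_grid, lys_grid)
    counts = np.zeros(gcp_grid.spec.n_nodes, dtype=np.int64)
    energy = _count_kernel(
        state.conf.bead_nodes, state.energy, T, n_steps, thin, config.max_displacement,
        track_bead, counts,
        gv, gf, lv, lf,
        gcp_grid.spec.spacing,
        np.asarray(ligand.spring_constants), np.asarray(ligand.spring_eq_lengths),
        ligand.hard_core**2, KB, rng,
    )
    state.energy = float(energy)
    return counts
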