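"""Synthetic instances and exact oracles.

Everything here exists so the whole pipeline can be exercised and
verified without external structures or electrostatics solvers: toy
proteins with controllable geometry and charge, affinity grids with
*planted* energy wells at ligand-compatible positions, an exact
brute-force enumeration of the global energy minimum, and emitters for
the production parameter files.

The planted instances are deliberately coarse (default spacing 3 Å,
shapes ≤ 15³) so that the enumeration oracle stays exact and fast; the
energy function is never approximated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .affinity_grids import IonicSolvent, steric_mask
from .constants import KB
from .io_formats import (
    Atom,
    GridSpec,
    ProteinStructure,
    ScalarGrid,
    save_yaml_config,
)
from .ligand_model import BeadSpringLigand, Conformation, default_ligand, total_energy
from .sa_engine import SAConfig, _shell_offsets, init_conformation, placement_layer

__all__ = [
    "PlantedInstance",
    "make_toy_protein",
    "make_planted_minimum_instance",
    "brute_force_global_minimum",
    "random_feasible_energies",
    "make_reference_configs",
    "ligand_from_config",
    "sa_config_from_config",
]


@dataclass
class PlantedInstance:
    """A self-contained synthetic docking problem.

    Affinity grids equal zero-mean background noise plus Gaussian wells
    of known depth at planted nodes; the mask carves a convex
    protein-like forbidden region; the AIE placement layer and a planted
    AIE anchor node are recorded, together with the C2 axis when the
    instance was mirrored.
    """

    gcp_grid: ScalarGrid
    lys_grid: ScalarGrid
    mask: np.ndarray
    protein: ProteinStructure
    layer: np.ndarray
    aie_node: np.ndarray
    gcp_well_nodes: list[tuple[int, int, int]]
    lys_well_nodes: list[tuple[int, int, int]]
    well_depth: float
    noise_sigma: float
    c2_axis: tuple[np.ndarray, np.ndarray] | None = None
    mirrored_aie_node: np.ndarray | None = None

    @property
    def spec(self) -> GridSpec:
        return self.gcp_grid.spec


def make_toy_protein(
    n_atoms: int,
    arrangement: str = "sphere",
    charge_pattern="alternating",
    seed: int = 0,
    radius: float = 1.5,
    extent: float = 5.0,
    center: np.ndarray | None = None,
) -> ProteinStructure:
    """Small synthetic PQR-writable structure.

    Arrangements: ``sphere`` (atoms on a sphere of radius ``extent``),
    ``plane`` (a z = 0 patch), ``two_lobes`` (``n_atoms`` per lobe at
    x = ±``extent``, exactly C2-symmetric about the z axis through the
    center).  ``charge_pattern`` is a number (uniform charge), a
    sequence (cycled), or ``"alternating"`` (+1/−1).
    """
    if n_atoms < 1:
        raise ValueError("need at least one atom")
    rng = np.random.default_rng(seed)
    center = np.zeros(3) if center is None else np.asarray(center, dtype=float)

    def _charges(n: int) -> np.ndarray:
        if isinstance(charge_pattern, str):
            if charge_pattern == "alternating":
                return np.array([1.0 if i % 2 == 0 else -1.0 for i in range(n)])
            raise ValueError(f"unknown charge pattern {charge_pattern!r}")
        if np.isscalar(charge_pattern):
            return np.full(n, float(charge_pattern))
        seq = list(charge_pattern)
        return np.array([float(seq[i % len(seq)]) for i in range(n)])

    if arrangement == "sphere":
        v = rng.normal(size=(n_atoms, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pos = center + extent * v
        charges = _charges(n_atoms)
    elif arrangement == "plane":
        side = int(np.ceil(np.sqrt(n_atoms)))
        xs = np.linspace(-extent, extent, side)
        gx, gy = np.meshgrid(xs, xs, indexing="ij")
        pos = center + np.stack(
            [gx.ravel(), gy.ravel(), np.zeros(side * side)], axis=1
        )[:n_atoms]
        charges = _charges(n_atoms)
    elif arrangement == "two_lobes":
        lobe = rng.normal(scale=extent / 3.0, size=(n_atoms, 3))
        lobe[:, 0] += extent
        mirrored = lobe.copy()
        mirrored[:, 0] *= -1.0  # 180° about the z axis
        mirrored[:, 1] *= -1.0
        pos = center + np.vstack([lobe, mirrored])
        charges = np.tile(_charges(n_atoms), 2)
    else:
        raise ValueError(f"unknown arrangement {arrangement!r}")

    atoms = [
        Atom(
            serial=i + 1,
            name="C",
            res_name="TOY",
            chain_id="A",
            res_seq=i + 1,
            position=p,
            charge=q,
            radius=radius,
        )
        for i, (p, q) in enumerate(zip(pos, charges))
    ]
    return ProteinStructure(atoms)


def _centered_spec(shape, spacing) -> GridSpec:
    shape = tuple(int(n) for n in shape)
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    origin = -(np.array(shape) - 1) / 2.0 * spacing
    return GridSpec(origin, spacing, shape)


def _add_well(values: np.ndarray, spec: GridSpec, node, depth: float) -> None:
    """Subtract a Gaussian well (half-width one node) centered on a node."""
    node = np.asarray(node)
    sigma_nodes = 1.0 / np.sqrt(2.0 * np.log(2.0))
    idx = [np.arange(n) for n in spec.shape]
    d2 = (
        ((idx[0] - node[0]) ** 2)[:, None, None]
        + ((idx[1] - node[1]) ** 2)[None, :, None]
        + ((idx[2] - node[2]) ** 2)[None, None, :]
    )
    values -= depth * np.exp(-d2 / (2.0 * sigma_nodes**2))


def _c2_mirror_values(values: np.ndarray) -> np.ndarray:
    """180° rotation about the z axis through the lattice center
    (valid for the centered grids built here)."""
    return values[::-1, ::-1, :]


def _c2_mirror_node(node: np.ndarray, shape) -> np.ndarray:
    node = np.asarray(node)
    return np.array([shape[0] - 1 - node[0], shape[1] - 1 - node[1], node[2]])


def make_planted_minimum_instance(
    shape=(15, 15, 15),
    spacing=3.0,
    well_depth: float = 50.0,
    noise_sigma: float = 0.5,
    seed: int = 0,
    ligand: BeadSpringLigand | None = None,
    c2_mirror: bool = False,
    layer_thickness: float = 19.0,
    aie_standoff: float | None = None,
) -> PlantedInstance:
    """Build a planted-minimum instance.

    A single protein-like forbidden ball sits at the grid center.  An
    AIE anchor node is placed near the surface; one Lys well is planted
    at ≈ the Lys–AIE equilibrium distance from it and one GCP well at
    ≈ the GCP–Lys equilibrium distance from the Lys well, so the
    default ligand can reach both with little spring strain.  Both
    grids are the wells plus zero-mean Gaussian background noise.

    With ``c2_mirror`` the protein, grids, wells and anchor are made
    exactly symmetric under a 180° rotation about the z axis through
    the grid center.
    """
    if ligand is None:
        ligand = default_ligand()
    spec = _centered_spec(shape, spacing)
    rng = np.random.default_rng(seed)
    s = spec.spacing

    prot_radius = 6.0
    protein = ProteinStructure(
        [
            Atom(1, "C", "TOY", "A", 1, np.zeros(3), -2.0, prot_radius),
        ]
    )
    mask = steric_mask(protein, spec)

    # anchor the AIE bead near the surface on the +x axis; C2 instances
    # stand it further off so the two mirrored binding regions stay
    # geometrically separated from the symmetry axis (an axis-adjacent
    # anchor must not be able to reach wells of both sides)
    if aie_standoff is None:
        aie_standoff = 3.0 * float(s[0]) if c2_mirror else 2.0 * float(s[0])
    center_node = (np.array(spec.shape) - 1) // 2
    aie_node = center_node + np.array(
        [int(np.ceil((prot_radius + aie_standoff) / s[0])), 0, 0]
    )
    if np.any(aie_node >= spec.shape):
        raise ValueError("grid too small for the planted geometry")

    l_gcp, l_lys = ligand.spring_eq_lengths[0], ligand.spring_eq_lengths[1]
    shape_arr = np.array(spec.shape)

    def _pick_well(anchor: np.ndarray, target: float, direction: float = 1.0,
                   keep_clear=(), min_lateral: float = 0.0,
                   tiebreak: np.ndarray | None = None) -> np.ndarray:
        """Nearest-to-equilibrium offset whose node is in bounds, allowed
        and (optionally) at hard-core distance from another bead.  A mild
        tangential (+y) preference keeps wells inside the lattice."""
        offs = _shell_offsets(spec, target, 0.5 * target)
        d = np.linalg.norm(offs * s, axis=1)
        score = (
            np.abs(d - target)
            - 1e-3 * direction * offs[:, 1]
            + 1e-3 * np.abs(offs[:, 0])
            + 5e-4 * np.abs(offs[:, 2])
        )
        if tiebreak is not None:
            score = score - 1e-4 * (offs @ np.asarray(tiebreak, dtype=float))
        for idx in np.argsort(score, kind="stable"):
            node = anchor + offs[idx]
            if np.any(node < 0) or np.any(node >= shape_arr) or mask[tuple(node)]:
                continue
            if any(
                np.linalg.norm((node - point) * s) < min_d
                for point, min_d in keep_clear
            ):
                continue
            if min_lateral > 0.0:
                cart = spec.node_to_cart(node)
                if np.hypot(cart[0], cart[1]) < min_lateral:
                    continue
            return node
        raise ValueError("no admissible well node; grid too small for the geometry")

    # one (Lys, GCP) well pair per half-chain, on opposite tangential
    # sides of the anchor, all mutual hard-core distances respected so
    # the global minimum pins every charged bead in a well.  On C2
    # instances the wells must not drift toward the symmetry axis, or a
    # self-symmetric anchor near the axis could reach wells of both
    # mirror images at once.
    a = ligand.hard_core
    aie_cart = spec.node_to_cart(aie_node)
    min_lat = np.hypot(aie_cart[0], aie_cart[1]) - float(s[0]) if c2_mirror else 0.0
    layer = placement_layer(mask, spec, layer_thickness, protein=protein)

    def _place_wells(tiebreak):
        lys_1 = _pick_well(aie_node, l_lys, direction=1.0, min_lateral=min_lat)
        gcp_1 = _pick_well(
            lys_1, l_gcp, direction=1.0, keep_clear=((aie_node, a),),
            min_lateral=min_lat,
        )
        lys_2 = _pick_well(
            aie_node, l_lys, direction=-1.0,
            keep_clear=((lys_1, a), (gcp_1, a)),
            min_lateral=min_lat, tiebreak=tiebreak,
        )
        gcp_2 = _pick_well(
            lys_2, l_gcp, direction=-1.0,
            keep_clear=((aie_node, a), (lys_1, a), (gcp_1, a)),
            min_lateral=min_lat,
        )
        return lys_1, gcp_1, lys_2, gcp_2

    def _anchor_strain_gap(lys_1, lys_2):
        """Spring strain of the anchor over the layer, assuming both Lys
        beads pinned in their wells.  Returns (sorted strains, argsort).
        Used to certify a unique (up to mirror) optimal anchor on C2
        instances; a lattice-aligned well pair leaves a whole circle of
        exactly degenerate anchors."""
        cart = spec.node_to_cart(layer)
        k2 = ligand.spring_constants[1]

        def _strain(wells):
            c1 = spec.node_to_cart(np.asarray(wells[0]))
            c2c = spec.node_to_cart(np.asarray(wells[1]))
            d1 = np.linalg.norm(cart - c1, axis=1)
            d2 = np.linalg.norm(cart - c2c, axis=1)
            return 0.5 * k2 * ((d1 - l_lys) ** 2 + (d2 - l_lys) ** 2)

        strain = _strain((lys_1, lys_2))
        strain_m = _strain(
            (_c2_mirror_node(lys_1, spec.shape), _c2_mirror_node(lys_2, spec.shape))
        )
        e = np.minimum(strain, strain_m)
        order = np.argsort(e, kind="stable")
        return e[order], order

    if not c2_mirror:
        lys_well_1, gcp_well_1, lys_well_2, gcp_well_2 = _place_wells(None)
    else:
        for tiebreak in ([-1, 0, 3], [1, 0, 3], [-2, 0, 1], [2, 0, -3], [1, 0, -2], None):
            lys_well_1, gcp_well_1, lys_well_2, gcp_well_2 = _place_wells(tiebreak)
            e_sorted, order = _anchor_strain_gap(lys_well_1, lys_well_2)
            pair_tied = e_sorted[1] - e_sorted[0] < 1e-9
            clear_gap = e_sorted[2] - e_sorted[0] > 0.5
            n0, n1 = layer[order[0]], layer[order[1]]
            mirrored = np.array_equal(_c2_mirror_node(n0, spec.shape), n1)
            if pair_tied and clear_gap and mirrored:
                break
        else:
            raise ValueError(
                "could not find a well layout with a unique (mirror-paired) "
                "optimal anchor; adjust the planted geometry"
            )

    noise_gcp = rng.normal(scale=noise_sigma, size=spec.shape) if noise_sigma > 0 else np.zeros(spec.shape)
    noise_lys = rng.normal(scale=noise_sigma, size=spec.shape) if noise_sigma > 0 else np.zeros(spec.shape)
    gcp_wells = [gcp_well_1, gcp_well_2]
    lys_wells = [lys_well_1, lys_well_2]
    c2_axis = None
    mirrored_aie = None
    if c2_mirror:
        # symmetrize the background and mirror the whole well layout
        noise_gcp = 0.5 * (noise_gcp + _c2_mirror_values(noise_gcp))
        noise_lys = 0.5 * (noise_lys + _c2_mirror_values(noise_lys))
        gcp_wells += [_c2_mirror_node(n, spec.shape) for n in gcp_wells]
        lys_wells += [_c2_mirror_node(n, spec.shape) for n in lys_wells]
        mirrored_aie = _c2_mirror_node(aie_node, spec.shape)
        c2_axis = (np.zeros(3), np.array([0.0, 0.0, 1.0]))
    gcp_vals = noise_gcp.copy()
    lys_vals = noise_lys.copy()
    for node in gcp_wells:
        _add_well(gcp_vals, spec, node, well_depth)
    for node in lys_wells:
        _add_well(lys_vals, spec, node, well_depth)
    if c2_mirror:
        # re-symmetrize: summation order of the well contributions is
        # not mirror-invariant at the last ulp
        gcp_vals = 0.5 * (gcp_vals + _c2_mirror_values(gcp_vals))
        lys_vals = 0.5 * (lys_vals + _c2_mirror_values(lys_vals))
    gcp_wells = [tuple(int(v) for v in n) for n in gcp_wells]
    lys_wells = [tuple(int(v) for v in n) for n in lys_wells]

    gcp_grid = ScalarGrid(spec, gcp_vals, mask.copy())
    lys_grid = ScalarGrid(spec, lys_vals, mask.copy())

    instance = PlantedInstance(
        gcp_grid=gcp_grid,
        lys_grid=lys_grid,
        mask=mask,
        protein=protein,
        layer=layer,
        aie_node=aie_node,
        gcp_well_nodes=gcp_wells,
        lys_well_nodes=lys_wells,
        well_depth=well_depth,
        noise_sigma=noise_sigma,
        c2_axis=c2_axis,
        mirrored_aie_node=mirrored_aie,
    )
    _verify_feasible(instance, ligand)
    return instance


def _verify_feasible(instance: PlantedInstance, ligand: BeadSpringLigand) -> None:
    """Check every layer node can seed a chain: an allowed Lys node at
    Lys–AIE reach, and an allowed GCP node at GCP–Lys reach of it; plus
    a full feasible conformation at the planted anchor."""
    spec = instance.spec
    shape = np.array(spec.shape)
    lys_offs = _shell_offsets(spec, ligand.spring_eq_lengths[1], 3.0)
    gcp_offs = _shell_offsets(spec, ligand.spring_eq_lengths[0], 3.0)
    forb = instance.mask
    for node in instance.layer:
        lys_cand = node + lys_offs
        ok = np.all((lys_cand >= 0) & (lys_cand < shape), axis=1)
        lys_cand = lys_cand[ok]
        lys_cand = lys_cand[~forb[lys_cand[:, 0], lys_cand[:, 1], lys_cand[:, 2]]]
        if lys_cand.size == 0:
            raise ValueError(f"layer node {tuple(node)} cannot place a Lys bead")
        gcp_cand = lys_cand[0] + gcp_offs
        ok = np.all((gcp_cand >= 0) & (gcp_cand < shape), axis=1)
        gcp_cand = gcp_cand[ok]
        if not np.any(~forb[gcp_cand[:, 0], gcp_cand[:, 1], gcp_cand[:, 2]]):
            raise ValueError(f"layer node {tuple(node)} cannot place a GCP bead")
    init_conformation(
        instance.aie_node, ligand, instance.gcp_grid, instance.lys_grid,
        np.random.default_rng(0),
    )


# --------------------------------------------------------------------------
# Exact enumeration oracle
# --------------------------------------------------------------------------

def _half_chain_states(
    spec: GridSpec,
    aie: np.ndarray,
    lys_forb: np.ndarray,
    gcp_forb: np.ndarray,
    lys_vals: np.ndarray,
    gcp_vals: np.ndarray,
    k_gcp: float,
    leq_gcp: float,
    k_lys: float,
    leq_lys: float,
    a: float,
    reach_pad: float,
    max_states: int,
):
    """Enumerate (Lys, GCP) half-chain placements around the fixed AIE
    bead with their energy contribution (two springs + two grid terms +
    the within-half hard-core pair GCP–AIE)."""
    shape = np.array(spec.shape)
    s = spec.spacing
    lys_offs = _shell_offsets(spec, leq_lys, reach_pad)
    gcp_offs = _shell_offsets(spec, leq_gcp, reach_pad)

    lys_nodes = aie + lys_offs
    ok = np.all((lys_nodes >= 0) & (lys_nodes < shape), axis=1)
    lys_nodes = lys_nodes[ok]
    lys_nodes = lys_nodes[~lys_forb[lys_nodes[:, 0], lys_nodes[:, 1], lys_nodes[:, 2]]]
    n_states = lys_nodes.shape[0] * gcp_offs.shape[0]
    if n_states > max_states:
        raise ValueError(
            f"candidate enumeration would visit {n_states} half-chain states "
            f"(> {max_states}); use a coarser grid spacing or smaller reach_pad"
        )
    lys_rep = np.repeat(lys_nodes, gcp_offs.shape[0], axis=0)
    gcp_nodes = lys_rep + np.tile(gcp_offs, (lys_nodes.shape[0], 1))
    ok = np.all((gcp_nodes >= 0) & (gcp_nodes < shape), axis=1)
    lys_rep, gcp_nodes = lys_rep[ok], gcp_nodes[ok]
    ok = ~gcp_forb[gcp_nodes[:, 0], gcp_nodes[:, 1], gcp_nodes[:, 2]]
    lys_rep, gcp_nodes = lys_rep[ok], gcp_nodes[ok]
    # within-half hard core: GCP vs AIE
    d_ga = np.linalg.norm((gcp_nodes - aie) * s, axis=1)
    ok = d_ga >= a
    lys_rep, gcp_nodes = lys_rep[ok], gcp_nodes[ok]

    l_lys = np.linalg.norm((lys_rep - aie) * s, axis=1)
    l_gcp = np.linalg.norm((gcp_nodes - lys_rep) * s, axis=1)
    energy = (
        0.5 * k_lys * (l_lys - leq_lys) ** 2
        + 0.5 * k_gcp * (l_gcp - leq_gcp) ** 2
        + lys_vals[lys_rep[:, 0], lys_rep[:, 1], lys_rep[:, 2]]
        + gcp_vals[gcp_nodes[:, 0], gcp_nodes[:, 1], gcp_nodes[:, 2]]
    )
    order = np.argsort(energy, kind="stable")
    return lys_rep[order], gcp_nodes[order], energy[order]


def brute_force_global_minimum(
    instance: PlantedInstance,
    ligand: BeadSpringLigand,
    aie_node: np.ndarray | None = None,
    reach_pad: float = 4.5,
    max_states: int = 2_000_000,
) -> tuple[float, Conformation]:
    """Exact global minimum of the ligand energy with the AIE bead fixed.

    Both (Lys, GCP) half-chains are enumerated over all allowed nodes
    within spring reach (equilibrium length ± ``reach_pad``) of their
    anchor, sorted by energy, and combined under the cross hard-core
    constraints with a branch-and-bound sweep.  Exact over the
    enumerated set and deterministic; states outside the reach pad are
    excluded because their spring strain alone exceeds any well depth
    used in the planted fixtures.
    """
    spec = instance.spec
    aie = np.asarray(instance.aie_node if aie_node is None else aie_node, dtype=np.int64)
    s = spec.spacing
    a = ligand.hard_core
    gv, lv = instance.gcp_grid.values, instance.lys_grid.values
    gf, lf = instance.gcp_grid.forbidden, instance.lys_grid.forbidden
    leq = ligand.spring_eq_lengths
    k = ligand.spring_constants

    lys1, gcp1, e1 = _half_chain_states(
        spec, aie, lf, gf, lv, gv, k[0], leq[0], k[1], leq[1], a, reach_pad, max_states
    )
    lys2, gcp2, e2 = _half_chain_states(
        spec, aie, lf, gf, lv, gv, k[3], leq[3], k[2], leq[2], a, reach_pad, max_states
    )
    if e1.size == 0 or e2.size == 0:
        raise ValueError("no feasible half-chain placements; nothing to enumerate")

    a2 = a * a
    best = np.inf
    best_state = None
    cart_lys2 = lys2 * s
    cart_gcp2 = gcp2 * s
    for i in range(e1.size):
        if e1[i] + e2[0] >= best:
            break
        hi = np.searchsorted(e2, best - e1[i]) if np.isfinite(best) else e2.size
        if hi == 0:
            continue
        cl1 = lys1[i] * s
        cg1 = gcp1[i] * s
        d = cart_lys2[:hi] - cg1
        ok = np.einsum("ij,ij->i", d, d) >= a2  # GCP1–Lys2
        d = cart_gcp2[:hi] - cg1
        ok &= np.einsum("ij,ij->i", d, d) >= a2  # GCP1–GCP2
        d = cart_lys2[:hi] - cl1
        ok &= np.einsum("ij,ij->i", d, d) >= a2  # Lys1–Lys2
        d = cart_gcp2[:hi] - cl1
        ok &= np.einsum("ij,ij->i", d, d) >= a2  # Lys1–GCP2
        if not np.any(ok):
            continue
        j = int(np.nonzero(ok)[0][0])  # e2 is sorted: first feasible is best
        total = e1[i] + e2[j]
        if total < best:
            best = total
            best_state = (gcp1[i], lys1[i], aie, lys2[j], gcp2[j])
    if best_state is None:
        raise ValueError("no feasible full conformation in the enumerated set")
    conf = Conformation(np.array(best_state))
    # report the energy exactly as the production energy function computes it
    energy = total_energy(conf, ligand, instance.gcp_grid, instance.lys_grid)
    return float(energy), conf


def random_feasible_energies(
    instance: PlantedInstance,
    ligand: BeadSpringLigand,
    n_samples: int,
    seed: int = 0,
    aie_node: np.ndarray | None = None,
    reach_pad: float = 4.5,
) -> np.ndarray:
    """Energies of random conformations drawn from the oracle's
    candidate shells (cross-check that no sample beats the oracle)."""
    rng = np.random.default_rng(seed)
    spec = instance.spec
    aie = np.asarray(instance.aie_node if aie_node is None else aie_node, dtype=np.int64)
    lys_offs = _shell_offsets(spec, ligand.spring_eq_lengths[1], reach_pad)
    gcp_offs = _shell_offsets(spec, ligand.spring_eq_lengths[0], reach_pad)
    li = rng.integers(lys_offs.shape[0], size=(n_samples, 2))
    gi = rng.integers(gcp_offs.shape[0], size=(n_samples, 2))
    out = np.empty(n_samples)
    for i in range(n_samples):
        lys1 = aie + lys_offs[li[i, 0]]
        lys2 = aie + lys_offs[li[i, 1]]
        conf = Conformation(
            np.array([lys1 + gcp_offs[gi[i, 0]], lys1, aie, lys2, gcp_offs[gi[i, 1]] + lys2])
        )
        out[i] = total_energy(conf, ligand, instance.gcp_grid, instance.lys_grid)
    return out


# --------------------------------------------------------------------------
# Production parameter files
# --------------------------------------------------------------------------

def make_reference_configs(outdir: str | Path) -> dict[str, Path]:
    """Emit YAML files with the production parameters: 0.4 Å grids, 150
    probe rotations, 0.1 M NaCl + 0.01 M MgCl₂ at ε_protein/ε_water =
    2/79, the (6, 13, 13, 6 Å; 12, 3, 3, 12 k_B·T/Å²; a = 9.6 Å)
    ligand, and the (3000 K, 10000/1000 caps, 1% stop, 6-grid-length
    moves, 4000 restarts) annealing schedule."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scan = {
        "grid_spacing_A": 0.4,
        "n_rotations": 150,
        "mode": "boltzmann",
        "reference_temperature_K": 300.0,
        "solvent": {
            "nacl_mol_per_L": 0.1,
            "mgcl2_mol_per_L": 0.01,
            "eps_water": 79.0,
            "eps_protein": 2.0,
            "temperature_K": 300.0,
        },
    }
    lig = {
        "spring_eq_lengths_A": [6.0, 13.0, 13.0, 6.0],
        "spring_constants": [12.0, 3.0, 3.0, 12.0],
        "spring_constant_units": "kBT_per_A2",
        "hard_core_A": 9.6,
        "reference_temperature_K": 300.0,
    }
    sa = {
        "T0_K": 3000.0,
        "cooling_factor": 0.95,
        "level_max_moves": 10000,
        "level_max_accepted": 1000,
        "stop_acceptance": 0.01,
        "max_displacement_grid_lengths": 6,
        "max_levels": 200,
        "n_runs": 4000,
        "seed": 0,
    }
    paths = {}
    for name, data in (("scan", scan), ("ligand", lig), ("sa", sa)):
        path = outdir / f"{name}.yaml"
        save_yaml_config(data, path)
        paths[name] = path
    return paths


def ligand_from_config(data: dict) -> BeadSpringLigand:
    """Build a ligand from a config mapping (as written by
    :func:`make_reference_configs`).  Spring constants may be given in
    k_B·T/Å² (converted at the reference temperature) or kJ/(mol·Å²)."""
    ref_T = float(data.get("reference_temperature_K", 300.0))
    k = [float(v) for v in data["spring_constants"]]
    units = data.get("spring_constant_units", "kBT_per_A2")
    if units == "kBT_per_A2":
        k = [v * KB * ref_T for v in k]
    elif units != "kJ_per_mol_A2":
        raise ValueError(f"unknown spring constant units {units!r}")
    return BeadSpringLigand(
        spring_eq_lengths=tuple(float(v) for v in data["spring_eq_lengths_A"]),
        spring_constants=tuple(k),
        hard_core=float(data["hard_core_A"]),
        reference_temperature=ref_T,
    )


def sa_config_from_config(data: dict) -> tuple[SAConfig, int]:
    """Build an annealing config from a config mapping.  Returns the
    config and the ensemble size."""
    cfg = SAConfig(
        T0=float(data.get("T0_K", 3000.0)),
        cooling_factor=float(data.get("cooling_factor", 0.95)),
        level_max_moves=int(data.get("level_max_moves", 10000)),
        level_max_accepted=int(data.get("level_max_accepted", 1000)),
        stop_acceptance=float(data.get("stop_acceptance", 0.01)),
        max_displacement=int(data.get("max_displacement_grid_lengths", 6)),
        max_levels=int(data.get("max_levels", 200)),
        seed=int(data.get("seed", 0)),
    )
    return cfg, int(data.get("n_runs", 4000))


def solvent_from_config(data: dict) -> IonicSolvent:
    """Build an electrolyte description from a scan-config mapping."""
    return IonicSolvent.from_salts(
        nacl=float(data.get("nacl_mol_per_L", 0.0)),
        mgcl2=float(data.get("mgcl2_mol_per_L", 0.0)),
        eps_water=float(data.get("eps_water", 79.0)),
        eps_protein=float(data.get("eps_protein", 2.0)),
        temperature=float(data.get("temperature_K", 300.0)),
    )
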