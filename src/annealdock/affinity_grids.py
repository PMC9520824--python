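"""Per-fragment affinity grids around a protein.

A rigid, charged probe fragment (e.g. a guanidiniocarbonyl-pyrrole head
group or a lysine side chain) is scanned over a regular lattice
surrounding the protein.  At each node the probe's electrostatic
interaction energy with the protein potential is evaluated for a set of
rotations and combined into a single per-node affinity, producing a
"pre-computed Hamiltonian" for the grid-based ligand model.

The protein potential can either be read from an external OpenDX file
(e.g. an APBS Poisson–Boltzmann solution) or generated internally from a
PQR structure with a screened-Coulomb (Debye–Hückel) superposition.  The
internal potential has lower physical fidelity — no dielectric boundary,
no non-linear screening — but the same grid contract, which keeps the
whole pipeline self-contained and testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import COULOMB_KJ_A, EPS0_SI, E_CHARGE_SI, KB, KB_SI, N_AVOGADRO
from .io_formats import GridSpec, ProteinStructure, ScalarGrid

__all__ = [
    "IonicSolvent",
    "Probe",
    "ScanConfig",
    "ionic_strength",
    "inverse_debye_length",
    "dh_potential_grid",
    "steric_mask",
    "rotation_set",
    "probe_energy",
    "probe_scan",
]


@dataclass(frozen=True)
class IonicSolvent:
    """Implicit electrolyte: ionic species plus dielectric environment.

    ``species`` is a list of ``(concentration mol/L, integer valence)``
    pairs and must be electroneutral.  ``eps_protein`` is carried for
    interface completeness; the built-in screened-Coulomb potential has
    no dielectric boundary and does not use it.
    """

    species: tuple[tuple[float, int], ...] = ()
    eps_water: float = 79.0
    eps_protein: float = 2.0
    temperature: float = 300.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "species", tuple((float(c), int(z)) for c, z in self.species)
        )
        if any(c < 0 for c, _ in self.species):
            raise ValueError("ionic concentrations must be >= 0")
        if self.eps_water <= 0 or self.eps_protein <= 0:
            raise ValueError("relative permittivities must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        net = sum(c * z for c, z in self.species)
        if abs(net) > 1e-9:
            raise ValueError(f"species list is not electroneutral (net {net:g} mol·e/L)")

    @classmethod
    def from_salts(
        cls,
        nacl: float = 0.0,
        mgcl2: float = 0.0,
        eps_water: float = 79.0,
        eps_protein: float = 2.0,
        temperature: float = 300.0,
    ) -> "IonicSolvent":
        """Convenience constructor from NaCl / MgCl₂ molarities."""
        species: list[tuple[float, int]] = []
        if nacl > 0:
            species.append((nacl, 1))
        if mgcl2 > 0:
            species.append((mgcl2, 2))
        cl = nacl + 2.0 * mgcl2
        if cl > 0:
            species.append((cl, -1))
        return cls(tuple(species), eps_water, eps_protein, temperature)


@dataclass(frozen=True)
class Probe:
    """Rigid molecular probe: atoms as (offset Å from probe center,
    charge |e|, radius Å)."""

    atoms: tuple[tuple[np.ndarray, float, float], ...]
    label: str = "probe"

    def __post_init__(self) -> None:
        atoms = tuple(
            (np.asarray(off, dtype=float), float(q), float(r)) for off, q, r in self.atoms
        )
        if not atoms:
            raise ValueError("probe must have at least one atom")
        for off, _, _ in atoms:
            if off.shape != (3,) or not np.all(np.isfinite(off)):
                raise ValueError("probe atom offsets must be finite 3-vectors")
        object.__setattr__(self, "atoms", atoms)

    @classmethod
    def from_structure(cls, structure: ProteinStructure, label: str = "probe") -> "Probe":
        """Build a probe from a small PQR structure, centered on its
        geometric center."""
        center = structure.positions.mean(axis=0)
        atoms = tuple(
            (a.position - center, a.charge, a.radius) for a in structure.atoms
        )
        return cls(atoms, label)

    @property
    def offsets(self) -> np.ndarray:
        return np.array([off for off, _, _ in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return np.array([q for _, q, _ in self.atoms])


@dataclass(frozen=True)
class ScanConfig:
    """Rotational-scan settings.

    ``mode='boltzmann'`` combines the per-rotation energies into a free
    energy at ``reference_temperature``; ``mode='min'`` keeps the
    best-rotation energy.
    """

    n_rotations: int = 150
    mode: str = "boltzmann"
    reference_temperature: float = 300.0
    rotation_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rotations < 1:
            raise ValueError("n_rotations must be >= 1")
        if self.mode not in ("boltzmann", "min"):
            raise ValueError(f"unknown combination mode {self.mode!r}")
        if self.reference_temperature <= 0:
            raise ValueError("reference temperature must be > 0")


def ionic_strength(solvent: IonicSolvent) -> float:
    """Ionic strength I = ½ Σ cᵢ zᵢ², mol/L."""
    return 0.5 * sum(c * z * z for c, z in solvent.species)


def inverse_debye_length(solvent: IonicSolvent) -> float:
    """Inverse Debye screening length κ, Å⁻¹.

    κ² = 2·e²·N_A·(1000·I) / (ε₀·ε_r·k_B·T) in SI units; κ = 0 for zero
    ionic strength.  At 0.1 mol/L 1:1 salt in water near room
    temperature this gives the textbook Debye length of ≈ 9.6 Å.
    """
    I = ionic_strength(solvent)
    if I == 0.0:
        return 0.0
    kappa_sq_si = (
        2.0
        * E_CHARGE_SI**2
        * N_AVOGADRO
        * (1000.0 * I)
        / (EPS0_SI * solvent.eps_water * KB_SI * solvent.temperature)
    )
    return float(np.sqrt(kappa_sq_si) * 1e-10)  # 1/m -> 1/Å


def dh_potential_grid(
    protein: ProteinStructure,
    gridspec: GridSpec,
    solvent: IonicSolvent,
    clamp_radius: float = 0.5,
) -> ScalarGrid:
    """Screened-Coulomb potential of the protein on a lattice,
    kJ/mol per |e|.

    φ(x) = Σᵢ C·qᵢ·exp(−κ·max(0, r−Rᵢ)) / (ε_r·r), with C the Coulomb
    constant in kJ·Å/(mol·e²) and Rᵢ the atom radius (screening starts at
    the atom surface).  Nodes closer than ``clamp_radius`` to an atom
    center are clamped to the value at ``clamp_radius`` to avoid the
    singularity.
    """
    if len(protein) == 0:
        raise ValueError("cannot compute a potential for an empty structure")
    kappa = inverse_debye_length(solvent)
    xs, ys, zs = gridspec.node_coordinates()
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
    phi = np.zeros(nodes.shape[0])
    pref = COULOMB_KJ_A / solvent.eps_water
    for atom in protein.atoms:
        r = np.linalg.norm(nodes - atom.position, axis=1)
        r = np.maximum(r, clamp_radius)
        screened = np.exp(-kappa * np.maximum(0.0, r - atom.radius))
        phi += pref * atom.charge * screened / r
    return ScalarGrid(gridspec, phi.reshape(gridspec.shape))


def steric_mask(
    protein: ProteinStructure, gridspec: GridSpec, probe_pad: float = 0.0
) -> np.ndarray:
    """Boolean exclusion mask: node forbidden iff strictly inside some
    atom's van der Waals sphere inflated by ``probe_pad`` (Å)."""
    xs, ys, zs = gridspec.node_coordinates()
    mask = np.zeros(gridspec.shape, dtype=bool)
    for atom in protein.atoms:
        cutoff = atom.radius + probe_pad
        if cutoff <= 0:
            continue
        # restrict to the bounding box of the sphere
        ix = np.nonzero(np.abs(xs - atom.position[0]) < cutoff)[0]
        iy = np.nonzero(np.abs(ys - atom.position[1]) < cutoff)[0]
        iz = np.nonzero(np.abs(zs - atom.position[2]) < cutoff)[0]
        if ix.size == 0 or iy.size == 0 or iz.size == 0:
            continue
        dx2 = (xs[ix] - atom.position[0]) ** 2
        dy2 = (ys[iy] - atom.position[1]) ** 2
        dz2 = (zs[iz] - atom.position[2]) ** 2
        d2 = dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]
        sub = mask[np.ix_(ix, iy, iz)]
        mask[np.ix_(ix, iy, iz)] = sub | (d2 < cutoff**2)
    return mask


def rotation_set(n: int, seed: int = 0) -> np.ndarray:
    """``n`` rotation matrices, quasi-uniform over SO(3), deterministic
    in ``seed``.  The first element is always the identity, so ``n=1``
    degenerates to the unrotated probe."""
    if n < 1:
        raise ValueError("need at least one rotation")
    mats = [np.eye(3)]
    if n > 1:
        rng = np.random.default_rng(seed)
        mats.extend(Rotation.random(n - 1, random_state=rng).as_matrix())
    return np.array(mats)


def _trilinear(
    pos: np.ndarray, potential: ScalarGrid, mask: np.ndarray
) -> float:
    """Trilinear interpolation of the potential at one Cartesian point.

    Returns +inf outside the lattice hull or when a corner node carrying
    non-zero interpolation weight is forbidden.
    """
    spec = potential.spec
    frac = (pos - spec.origin) / spec.spacing
    if np.any(frac < 0) or np.any(frac > np.array(spec.shape) - 1):
        return np.inf
    i0 = np.minimum(np.floor(frac).astype(int), np.array(spec.shape) - 2)
    i0 = np.maximum(i0, 0)
    t = frac - i0
    value = 0.0
    for cx in (0, 1):
        wx = t[0] if cx else 1.0 - t[0]
        if wx == 0.0:
            continue
        for cy in (0, 1):
            wy = t[1] if cy else 1.0 - t[1]
            if wy == 0.0:
                continue
            for cz in (0, 1):
                wz = t[2] if cz else 1.0 - t[2]
                if wz == 0.0:
                    continue
                idx = (i0[0] + cx, i0[1] + cy, i0[2] + cz)
                if mask[idx]:
                    return np.inf
                value += wx * wy * wz * potential.values[idx]
    return value


def probe_energy(
    node: tuple[int, int, int],
    rotation: np.ndarray,
    probe: Probe,
    potential: ScalarGrid,
    mask: np.ndarray,
) -> float:
    """Interaction energy (kJ/mol) of the rotated probe centered on a
    node: Σᵢ qᵢ·φ(node + R·offsetᵢ), trilinear in φ; +∞ if any probe
    atom leaves the lattice or touches a forbidden cell."""
    center = potential.spec.node_to_cart(np.asarray(node))
    total = 0.0
    for off, q, _ in probe.atoms:
        phi = _trilinear(center + rotation @ off, potential, mask)
        if np.isinf(phi):
            return np.inf
        total += q * phi
    return total


def _shifted_potential(
    potential: ScalarGrid, mask: np.ndarray, shift: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """φ sampled at every node displaced by a fixed Cartesian ``shift``,
    via trilinear interpolation.  Returns ``(values, invalid)`` where
    ``invalid`` flags nodes whose displaced position leaves the lattice
    hull or touches a forbidden corner node with non-zero weight.
    Vectorized over the whole lattice (the displaced positions keep the
    lattice structure, so each corner contribution is a shifted copy of
    φ)."""
    spec = potential.spec
    shape = np.array(spec.shape)
    frac = shift / spec.spacing
    base = np.floor(frac).astype(int)
    t = frac - base
    out = np.zeros(spec.shape)
    bad = np.zeros(spec.shape, dtype=bool)
    axes_idx = [np.arange(n) for n in spec.shape]
    for cx in (0, 1):
        wx = t[0] if cx else 1.0 - t[0]
        for cy in (0, 1):
            wy = t[1] if cy else 1.0 - t[1]
            for cz in (0, 1):
                wz = t[2] if cz else 1.0 - t[2]
                w = wx * wy * wz
                if w == 0.0:
                    continue
                idx = []
                valid = []
                for d, c in zip(range(3), (cx, cy, cz)):
                    shifted = axes_idx[d] + base[d] + c
                    valid.append((shifted >= 0) & (shifted < shape[d]))
                    idx.append(np.clip(shifted, 0, shape[d] - 1))
                vals = potential.values[np.ix_(idx[0], idx[1], idx[2])]
                forb = mask[np.ix_(idx[0], idx[1], idx[2])]
                ok = (
                    valid[0][:, None, None]
                    & valid[1][None, :, None]
                    & valid[2][None, None, :]
                )
                bad |= ~ok | forb
                out += w * vals
    out[bad] = 0.0
    return out, bad


def probe_scan(
    potential: ScalarGrid,
    mask: np.ndarray,
    probe: Probe,
    config: ScanConfig | None = None,
) -> ScalarGrid:
    """Scan the probe over every lattice node and rotation, producing an
    affinity grid (kJ/mol).

    Per node the rotation energies are combined according to
    ``config.mode``: the minimum, or the Boltzmann-weighted free energy
    −k_B·T·ln[(1/N)·Σ_r exp(−E_r/k_B·T)] where rotations with E = +∞
    contribute zero weight.  A node where every rotation is +∞ is marked
    forbidden in the output.
    """
    if config is None:
        config = ScanConfig()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != potential.spec.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match potential grid "
            f"shape {potential.spec.shape}"
        )
    rotations = rotation_set(config.n_rotations, config.rotation_seed)
    kbt = KB * config.reference_temperature
    n_rot = rotations.shape[0]

    best = np.full(potential.spec.shape, np.inf)
    # online log-sum-exp accumulators for the boltzmann mode
    lse_max = np.full(potential.spec.shape, -np.inf)  # max of -E/kBT
    lse_sum = np.zeros(potential.spec.shape)

    for rot in rotations:
        energy = np.zeros(potential.spec.shape)
        invalid = np.zeros(potential.spec.shape, dtype=bool)
        for off, q, _ in probe.atoms:
            phi, bad = _shifted_potential(potential, mask, rot @ off)
            energy += q * phi
            invalid |= bad
        energy[invalid] = np.inf
        np.minimum(best, energy, out=best)
        if config.mode == "boltzmann":
            neg = np.where(np.isfinite(energy), -energy / kbt, -np.inf)
            new_max = np.maximum(lse_max, neg)
            with np.errstate(invalid="ignore"):
                scale = np.where(np.isfinite(new_max), np.exp(lse_max - new_max), 0.0)
                term = np.where(np.isfinite(neg), np.exp(neg - new_max), 0.0)
            lse_sum = lse_sum * scale + term
            lse_max = new_max

    all_forbidden = ~np.isfinite(best)
    if config.mode == "min":
        values = np.where(all_forbidden, 0.0, best)
    else:
        with np.errstate(divide="ignore"):
            log_mean = lse_max + np.log(lse_sum) - np.log(n_rot)
        values = np.where(all_forbidden, 0.0, -kbt * log_mean)
    out_forbidden = mask | all_forbidden
    return ScalarGrid(potential.spec, values, out_forbidden)
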