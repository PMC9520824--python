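"""Readers and writers for the formats the tool lives on.

Three families of artifacts are handled here:

* OpenDX scalar grids (the APBS dialect) holding electrostatic potentials
  or per-fragment affinity maps on a regular lattice,
* PQR protein structures (PDB2PQR output: coordinates plus per-atom
  partial charge and van der Waals radius),
* run-result tables of the annealing ensemble (CSV, one row per run, and
  JSON with the full per-level statistics).

Grids carry an explicit boolean ``forbidden`` mask (sterically excluded
nodes, energy treated as +∞).  DX has no mask channel, so forbidden nodes
are serialized as a large sentinel value (default ``1e30``) and recovered
on read by thresholding.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "INF_SENTINEL",
    "GridSpec",
    "ScalarGrid",
    "Atom",
    "ProteinStructure",
    "read_dx",
    "write_dx",
    "read_pqr",
    "write_pqr",
    "net_charge",
    "net_charge_int",
    "results_to_csv",
    "results_to_json",
    "load_yaml_config",
    "save_yaml_config",
]

#: Default energy sentinel standing in for +∞ inside DX files.
INF_SENTINEL = 1e30


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular 3-D lattice.

    ``origin`` is the Cartesian position (Å) of node ``(0, 0, 0)``;
    node ``(i, j, k)`` sits at ``origin + spacing * (i, j, k)`` with
    0-based indices.
    """

    origin: np.ndarray
    spacing: np.ndarray
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "spacing", np.asarray(self.spacing, dtype=float))
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        if self.origin.shape != (3,) or self.spacing.shape != (3,):
            raise ValueError("origin and spacing must be 3-vectors")
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise ValueError(f"shape components must be >= 1, got {self.shape}")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.shape))

    def node_to_cart(self, nodes: np.ndarray) -> np.ndarray:
        """Cartesian centers (Å) of integer node triples (…, 3)."""
        return self.origin + np.asarray(nodes, dtype=float) * self.spacing

    def cart_to_node(self, pos: np.ndarray) -> np.ndarray:
        """Nearest node triple for Cartesian positions (…, 3)."""
        return np.rint((np.asarray(pos, dtype=float) - self.origin) / self.spacing).astype(np.int64)

    def in_bounds(self, nodes: np.ndarray) -> np.ndarray:
        nodes = np.asarray(nodes)
        return np.all((nodes >= 0) & (nodes < np.array(self.shape)), axis=-1)

    def node_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis Cartesian node coordinates."""
        return tuple(
            self.origin[d] + self.spacing[d] * np.arange(self.shape[d]) for d in range(3)
        )

    def same_geometry(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.spacing, other.spacing, atol=tol)
        )


@dataclass
class ScalarGrid:
    """A scalar field on a regular lattice with a steric-exclusion mask.

    ``values`` holds one energy (kJ/mol) or potential (kJ/mol per |e|)
    per node; ``forbidden`` flags nodes a ligand bead may not occupy.
    """

    spec: GridSpec
    values: np.ndarray
    forbidden: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.spec.shape}"
            )
        if self.forbidden is None:
            self.forbidden = np.zeros(self.spec.shape, dtype=bool)
        else:
            self.forbidden = np.asarray(self.forbidden, dtype=bool)
            if self.forbidden.shape != self.spec.shape:
                raise ValueError(
                    f"forbidden shape {self.forbidden.shape} != grid shape {self.spec.shape}"
                )

    @property
    def origin(self) -> np.ndarray:
        return self.spec.origin

    @property
    def spacing(self) -> np.ndarray:
        return self.spec.spacing

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.spec.shape

    def allclose(self, other: "ScalarGrid", rtol: float = 1e-6) -> bool:
        """Geometry, mask and allowed-node values agree.  Values under
        forbidden nodes are excluded: serialization replaces them with
        the +∞ sentinel, so they carry no information."""
        if not self.spec.same_geometry(other.spec):
            return False
        if not np.array_equal(self.forbidden, other.forbidden):
            return False
        free = ~self.forbidden
        return bool(
            np.allclose(self.values[free], other.values[free], rtol=rtol, atol=0.0)
        )


#: Alias used where the grid holds probe interaction energies.
AffinityGrid = ScalarGrid


@dataclass
class Atom:
    """One PQR record: position in Å, partial charge in |e|, radius in Å."""

    serial: int
    name: str
    res_name: str
    chain_id: str
    res_seq: int
    position: np.ndarray
    charge: float
    radius: float

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if self.radius < 0:
            raise ValueError(f"atom radius must be >= 0, got {self.radius}")


@dataclass
class ProteinStructure:
    """Ordered collection of PQR atoms."""

    atoms: list[Atom] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)


class DXParseError(ValueError):
    """Malformed OpenDX input; the message names the offending line."""


class PQRParseError(ValueError):
    """Malformed PQR input; the message names the offending line."""


# --------------------------------------------------------------------------
# OpenDX scalar grids
# --------------------------------------------------------------------------

def read_dx(path: str | Path, inf_sentinel: float = INF_SENTINEL) -> ScalarGrid:
    """Read an OpenDX scalar grid (APBS ``gridpositions`` dialect).

    Values follow the DX convention: the last (z) index varies fastest.
    Nodes whose value is ``>= inf_sentinel`` are flagged forbidden.
    """
    path = Path(path)
    shape: tuple[int, int, int] | None = None
    origin: np.ndarray | None = None
    deltas: list[np.ndarray] = []
    data_values: list[float] = []
    n_items: int | None = None
    in_data = False

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if in_data:
                if line.startswith(("attribute", "component", "object", "end")):
                    in_data = False
                    continue
                try:
                    data_values.extend(float(tok) for tok in line.split())
                except ValueError as exc:
                    raise DXParseError(
                        f"{path}:{lineno}: non-numeric data value in line {line!r}"
                    ) from exc
                continue
            tokens = line.split()
            if tokens[0] == "object" and "gridpositions" in tokens:
                try:
                    shape = tuple(int(t) for t in tokens[-3:])  # type: ignore[assignment]
                except ValueError as exc:
                    raise DXParseError(
                        f"{path}:{lineno}: bad gridpositions counts in line {line!r}"
                    ) from exc
            elif tokens[0] == "origin":
                try:
                    origin = np.array([float(t) for t in tokens[1:4]])
                except (ValueError, IndexError) as exc:
                    raise DXParseError(
                        f"{path}:{lineno}: bad origin in line {line!r}"
                    ) from exc
            elif tokens[0] == "delta":
                try:
                    deltas.append(np.array([float(t) for t in tokens[1:4]]))
                except (ValueError, IndexError) as exc:
                    raise DXParseError(
                        f"{path}:{lineno}: bad delta in line {line!r}"
                    ) from exc
            elif tokens[0] == "object" and "array" in tokens:
                if "items" in tokens:
                    try:
                        n_items = int(tokens[tokens.index("items") + 1])
                    except (ValueError, IndexError) as exc:
                        raise DXParseError(
                            f"{path}:{lineno}: bad item count in line {line!r}"
                        ) from exc
                in_data = True

    if shape is None:
        raise DXParseError(f"{path}: no 'object ... gridpositions counts' header line")
    if origin is None:
        raise DXParseError(f"{path}: no 'origin' header line")
    if len(deltas) != 3:
        raise DXParseError(f"{path}: expected 3 'delta' lines, found {len(deltas)}")
    delta_matrix = np.array(deltas)
    if not np.allclose(delta_matrix, np.diag(np.diag(delta_matrix))):
        raise DXParseError(f"{path}: non-diagonal delta matrix (skewed grids unsupported)")
    spacing = np.diag(delta_matrix)

    n_expected = int(np.prod(shape))
    if n_items is not None and n_items != n_expected:
        raise DXParseError(
            f"{path}: data array declares {n_items} items but grid shape {shape} "
            f"implies {n_expected}"
        )
    if len(data_values) != n_expected:
        raise DXParseError(
            f"{path}: found {len(data_values)} data values, expected {n_expected} "
            f"for shape {shape}"
        )

    values = np.array(data_values, dtype=float).reshape(shape)  # z fastest = C order
    forbidden = values >= inf_sentinel
    return ScalarGrid(GridSpec(origin, spacing, shape), values, forbidden)


def write_dx(
    grid: ScalarGrid,
    path: str | Path,
    inf_sentinel: float = INF_SENTINEL,
    comment: str = "",
) -> None:
    """Write a grid as OpenDX text readable by APBS-family tools.

    Forbidden nodes are serialized as ``inf_sentinel``.
    """
    nx, ny, nz = grid.shape
    values = np.where(grid.forbidden, inf_sentinel, grid.values)
    flat = values.reshape(-1)  # C order: z fastest, per the DX convention
    path = Path(path)
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.12g} {:.12g} {:.12g}\n".format(*grid.origin))
        fh.write(f"delta {grid.spacing[0]:.12g} 0 0\n")
        fh.write(f"delta 0 {grid.spacing[1]:.12g} 0\n")
        fh.write(f"delta 0 0 {grid.spacing[2]:.12g}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {flat.size} data follows\n"
        )
        for i in range(0, flat.size, 3):
            chunk = flat[i : i + 3]
            fh.write(" ".join(f"{v:.12g}" for v in chunk) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "regular positions regular connections" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')


# --------------------------------------------------------------------------
# PQR structures
# --------------------------------------------------------------------------

def _parse_pqr_record(line: str, lineno: int, path: Path) -> Atom:
    tokens = line.split()
    # PDB2PQR writes whitespace-separated fields; the chain id column is
    # optional.  Count back from the end: the last 5 numeric fields are
    # always x y z charge radius.
    if len(tokens) < 9:
        raise PQRParseError(
            f"{path}:{lineno}: too few fields in record {line.rstrip()!r}"
        )
    try:
        x, y, z, charge, radius = (float(t) for t in tokens[-5:])
    except ValueError as exc:
        raise PQRParseError(
            f"{path}:{lineno}: non-numeric coordinate/charge/radius field in "
            f"record {line.rstrip()!r}"
        ) from exc
    head = tokens[: len(tokens) - 5]
    # head = [record, serial, name, resname, (chain), resseq]
    if len(head) == 6:
        _, serial_s, name, res_name, chain_id, res_seq_s = head
    elif len(head) == 5:
        _, serial_s, name, res_name, res_seq_s = head
        chain_id = ""
    else:
        raise PQRParseError(
            f"{path}:{lineno}: unrecognized field layout in record {line.rstrip()!r}"
        )
    try:
        serial = int(serial_s)
        # residue numbers may carry insertion codes; strip trailing letters
        res_seq = int("".join(c for c in res_seq_s if c.isdigit() or c == "-") or 0)
    except ValueError as exc:
        raise PQRParseError(
            f"{path}:{lineno}: non-numeric serial/residue number in record "
            f"{line.rstrip()!r}"
        ) from exc
    return Atom(serial, name, res_name, chain_id, res_seq, np.array([x, y, z]), charge, radius)


def _parse_pqr_record_columns(line: str, lineno: int, path: Path) -> Atom:
    """Fixed-column fallback (PDB-like layout with charge/radius appended)."""
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        res_name = line[17:20].strip()
        chain_id = line[21].strip()
        res_seq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        tail = line[46:].split()
        z, charge, radius = float(tail[0]), float(tail[1]), float(tail[2])
    except (ValueError, IndexError) as exc:
        raise PQRParseError(
            f"{path}:{lineno}: cannot parse record {line.rstrip()!r} in either the "
            "whitespace-separated or the fixed-column PQR dialect"
        ) from exc
    return Atom(serial, name, res_name, chain_id, res_seq, np.array([x, y, z]), charge, radius)


def read_pqr(path: str | Path) -> ProteinStructure:
    """Read a PQR structure, accepting whitespace-separated and
    fixed-column dialects (detected per line)."""
    path = Path(path)
    atoms: list[Atom] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            try:
                atoms.append(_parse_pqr_record(line, lineno, path))
            except PQRParseError:
                atoms.append(_parse_pqr_record_columns(line, lineno, path))
    if not atoms:
        raise PQRParseError(f"{path}: no parseable ATOM/HETATM records")
    return ProteinStructure(atoms)


def write_pqr(structure: ProteinStructure, path: str | Path) -> None:
    """Write a whitespace-separated PQR file (PDB2PQR-compatible)."""
    with open(path, "w") as fh:
        for a in structure.atoms:
            chain = a.chain_id if a.chain_id else ""
            fields = [
                "ATOM",
                f"{a.serial}",
                a.name,
                a.res_name,
            ]
            if chain:
                fields.append(chain)
            fields.append(f"{a.res_seq}")
            fields += [
                f"{a.position[0]:.4f}",
                f"{a.position[1]:.4f}",
                f"{a.position[2]:.4f}",
                f"{a.charge:.4f}",
                f"{a.radius:.4f}",
            ]
            fh.write(" ".join(f"{f:>7s}" if i else f"{f:<6s}" for i, f in enumerate(fields)))
            fh.write("\n")
        fh.write("END\n")


def net_charge(structure: ProteinStructure) -> float:
    """Sum of partial charges, |e|."""
    if not structure.atoms:
        raise ValueError("net_charge of an empty structure is undefined")
    return float(np.sum(structure.charges))


def net_charge_int(structure: ProteinStructure) -> int:
    """Net charge rounded to the nearest integer |e|."""
    return int(round(net_charge(structure)))


# --------------------------------------------------------------------------
# Run-result tables
# --------------------------------------------------------------------------

def results_to_csv(results: Sequence, path: str | Path) -> pd.DataFrame:
    """Export an annealing ensemble as CSV: one row per run.

    Columns: run id, AIE node, final bead nodes, final total energy,
    level count, termination reason.
    """
    rows = []
    for r in results:
        beads = np.asarray(r.final_conformation.bead_nodes)
        row = {
            "run_id": r.run_id,
            "aie_i": int(r.aie_node[0]),
            "aie_j": int(r.aie_node[1]),
            "aie_k": int(r.aie_node[2]),
            "final_energy_kj_mol": r.final_total_energy,
            "n_levels": len(r.levels),
            "terminated_by": r.terminated_by,
        }
        for b in range(beads.shape[0]):
            for d, ax in enumerate("ijk"):
                row[f"bead{b}_{ax}"] = int(beads[b, d])
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def results_to_json(results: Sequence, path: str | Path) -> None:
    """Export full per-level statistics of an ensemble as JSON."""
    payload = []
    for r in results:
        payload.append(
            {
                "run_id": r.run_id,
                "aie_node": [int(v) for v in r.aie_node],
                "final_bead_nodes": np.asarray(r.final_conformation.bead_nodes).tolist(),
                "final_total_energy_kj_mol": r.final_total_energy,
                "terminated_by": r.terminated_by,
                "levels": [
                    {
                        "temperature_K": lv.temperature,
                        "proposals": lv.proposals,
                        "acceptances": lv.acceptances,
                        "acceptance_ratio": lv.acceptance_ratio,
                        "best_energy_so_far_kj_mol": lv.best_energy_so_far,
                    }
                    for lv in r.levels
                ],
            }
        )
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


# --------------------------------------------------------------------------
# YAML configs
# --------------------------------------------------------------------------

def load_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return data


def save_yaml_config(data: dict, path: str | Path) -> None:
    def _clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return _clean(dataclasses.asdict(obj))
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    with open(path, "w") as fh:
        yaml.safe_dump(_clean(data), fh, sort_keys=False)
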