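"""Post-processing of annealing ensembles.

Final-energy histograms, extraction of minimum-energy conformations,
k-medoids clustering of the low-energy binding positions, a C2-symmetry
score for the resulting point sets (homodimers such as 14-3-3ζ bind
symmetric site pairs), and residue contact reports against the protein
structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from sklearn.metrics import silhouette_score

from .io_formats import GridSpec, ProteinStructure
from .ligand_model import BEAD_KINDS

__all__ = [
    "ClusterSummary",
    "energy_histogram",
    "min_energy_conformations",
    "cluster_medoids",
    "c2_symmetry_score",
    "contact_report",
    "low_energy_positions",
]


@dataclass
class ClusterSummary:
    """k-medoids partition of binding positions.

    Medoids are data points (Å); ``members`` maps each input index to
    its cluster; ``cost`` is the total within-cluster Euclidean distance.
    """

    medoid_indices: np.ndarray
    medoids: np.ndarray
    members: np.ndarray
    k: int
    cost: float
    energy_min: np.ndarray
    energy_median: np.ndarray


def energy_histogram(
    results, bins=50, log_counts: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of final total energies over an ensemble.

    Returns (bin edges, counts).  With ``log_counts`` the counts are
    log10-transformed (empty bins → NaN); the energies themselves are
    never transformed.
    """
    energies = np.array([r.final_total_energy for r in results], dtype=float)
    finite = energies[np.isfinite(energies)]
    if finite.size == 0:
        raise ValueError("no finite final energies to histogram")
    counts, edges = np.histogram(finite, bins=bins)
    if log_counts:
        with np.errstate(divide="ignore"):
            counts = np.where(counts > 0, np.log10(counts), np.nan)
    return edges, counts


def min_energy_conformations(results, k: int = 1):
    """The ``k`` lowest-final-energy runs, ascending; ties broken by run
    order (lower index first)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(results):
        raise ValueError(f"requested {k} runs but the ensemble has {len(results)}")
    order = sorted(
        range(len(results)), key=lambda i: (results[i].final_total_energy, i)
    )
    return [results[i] for i in order[:k]]


def low_energy_positions(
    results, spec: GridSpec, fraction: float = 0.05, bead: str = "aie"
) -> np.ndarray:
    """Cartesian positions (Å) of one bead over the lowest-energy
    fraction of runs (at least one run).

    ``bead`` is 'aie' or a chain index 0–4; the AIE position is the
    anchor the production analysis clusters on.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    n = max(1, int(round(fraction * len(results))))
    chosen = min_energy_conformations(results, n)
    idx = 2 if bead == "aie" else int(bead)
    nodes = np.array([r.final_conformation.bead_nodes[idx] for r in chosen])
    return spec.node_to_cart(nodes)


# --------------------------------------------------------------------------
# k-medoids (PAM)
# --------------------------------------------------------------------------

def _pam(dist: np.ndarray, k: int, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Partitioning-around-medoids on a precomputed distance matrix.

    Greedy BUILD initialization followed by SWAP passes; the cost (total
    distance of points to their medoid) never increases.
    """
    n = dist.shape[0]
    # BUILD: first medoid minimizes total distance; the rest maximize gain
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        current = dist[:, medoids].min(axis=1)
        gains = np.maximum(current[None, :] - dist, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = list(dict.fromkeys(medoids))
    # top up in the degenerate all-identical case
    pool = [i for i in range(n) if i not in medoids]
    rng.shuffle(pool)
    while len(medoids) < k and pool:
        medoids.append(pool.pop())
    cost = dist[:, medoids].min(axis=1).sum()
    improved = True
    while improved:
        improved = False
        for mi, m in enumerate(list(medoids)):
            for h in range(n):
                if h in medoids:
                    continue
                trial = list(medoids)
                trial[mi] = h
                trial_cost = dist[:, trial].min(axis=1).sum()
                if trial_cost < cost - 1e-12:
                    medoids = trial
                    cost = trial_cost
                    improved = True
    members = np.asarray(medoids)[np.argmin(dist[:, medoids], axis=1)]
    return np.array(medoids), float(cost), members


def cluster_medoids(
    positions: np.ndarray,
    k: int | str = "auto",
    seed: int = 0,
    energies: np.ndarray | None = None,
    k_range: tuple[int, int] = (2, 10),
) -> ClusterSummary:
    """k-medoids clustering of 3-D positions.

    ``k`` may be an integer or 'auto', which picks k in ``k_range`` by
    the best silhouette score.  Per-cluster energy statistics are filled
    when ``energies`` is given.
    """
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    n = positions.shape[0]
    if n == 0:
        raise ValueError("no positions to cluster")
    rng = np.random.default_rng(seed)
    dist = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)

    def _fit(kk: int):
        if kk > n:
            raise ValueError(f"cannot form {kk} clusters from {n} points")
        return _pam(dist, kk, rng)

    if k == "auto":
        best = None
        lo, hi = k_range
        for kk in range(lo, min(hi, n - 1) + 1):
            medoids, cost, members = _fit(kk)
            if len(np.unique(members)) < 2:
                continue
            score = silhouette_score(dist, members, metric="precomputed")
            if best is None or score > best[0]:
                best = (score, kk, medoids, cost, members)
        if best is None:  # fewer than 3 points, or degenerate
            medoids, cost, members = _fit(min(n, lo))
            kk = len(medoids)
        else:
            _, kk, medoids, cost, members = best
    else:
        kk = int(k)
        medoids, cost, members = _fit(kk)

    e_min = np.full(len(medoids), np.nan)
    e_med = np.full(len(medoids), np.nan)
    if energies is not None:
        energies = np.asarray(energies, dtype=float)
        for ci, m in enumerate(medoids):
            sel = energies[members == m]
            if sel.size:
                e_min[ci] = sel.min()
                e_med[ci] = float(np.median(sel))
    return ClusterSummary(
        medoid_indices=np.asarray(medoids),
        medoids=positions[np.asarray(medoids)],
        members=members,
        k=len(medoids),
        cost=cost,
        energy_min=e_min,
        energy_median=e_med,
    )


# --------------------------------------------------------------------------
# C2 symmetry
# --------------------------------------------------------------------------

def c2_rotate(positions: np.ndarray, axis_point: np.ndarray, axis_dir: np.ndarray) -> np.ndarray:
    """Apply a 180° rotation about the axis through ``axis_point`` along
    ``axis_dir`` to a set of points."""
    axis_point = np.asarray(axis_point, dtype=float)
    u = np.asarray(axis_dir, dtype=float)
    norm = np.linalg.norm(u)
    if norm == 0:
        raise ValueError("axis direction must be non-zero")
    u = u / norm
    rot = 2.0 * np.outer(u, u) - np.eye(3)
    return axis_point + (np.asarray(positions, dtype=float) - axis_point) @ rot.T


def c2_symmetry_score(
    positions: np.ndarray, axis_point: np.ndarray, axis_dir: np.ndarray
) -> float:
    """How C2-symmetric a point set is about a given axis, in Å.

    All points are rotated by 180° about the axis; the score is the
    median distance from each rotated point to its nearest original
    point.  0 means the set is exactly symmetric.
    """
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    if positions.shape[0] == 0:
        raise ValueError("need at least one position")
    rotated = c2_rotate(positions, axis_point, axis_dir)
    tree = cKDTree(positions)
    d, _ = tree.query(rotated)
    return float(np.median(d))


# --------------------------------------------------------------------------
# Residue contacts
# --------------------------------------------------------------------------

def contact_report(
    conf,
    spec: GridSpec,
    protein: ProteinStructure,
    cutoff: float = 5.0,
) -> list[tuple[str, float, str]]:
    """Residues with any atom within ``cutoff`` Å of any bead center.

    Returns ``(residue label, minimum distance Å, nearest bead kind)``
    tuples sorted by distance.  Residue labels are
    ``chain:resname:resseq``.
    """
    bead_cart = spec.node_to_cart(conf.bead_nodes)
    best: dict[str, tuple[float, str]] = {}
    for atom in protein.atoms:
        d = np.linalg.norm(bead_cart - atom.position, axis=1)
        b = int(np.argmin(d))
        dmin = float(d[b])
        if dmin >= cutoff:
            continue
        label = f"{atom.chain_id}:{atom.res_name}:{atom.res_seq}"
        if label not in best or dmin < best[label][0]:
            best[label] = (dmin, BEAD_KINDS[b])
    report = [(label, dist, bead) for label, (dist, bead) in best.items()]
    report.sort(key=lambda t: t[1])
    return report
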