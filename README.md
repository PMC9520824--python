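# annealdock

Binding-site prediction for large, flexible, multivalent charged
ligands on protein surfaces.

Classical docking assumes a compact ligand and a well-defined pocket;
all-atom molecular dynamics cannot affordably sample a floppy
five-unit chain diffusing over a protein surface.  `annealdock` covers
the regime in between, for ligands such as GCP–Lys–AIE–Lys–GCP hybrids
(two cationic guanidiniocarbonyl-pyrrole anion binders, two lysine
linkers, one aggregation-induced-emission luminophore) binding acidic
targets like the 14-3-3ζ homodimer:

1. **Affinity grids** — each charged fragment is scanned as a rigid
   probe over a lattice around the protein (150 rotations per node,
   Boltzmann- or minimum-combined), against an electrostatic potential
   read from an APBS-style OpenDX file or computed internally as a
   Debye–Hückel screened-Coulomb superposition from a PQR structure.
2. **Coarse-grained ligand** — a five-bead bead-spring chain with
   harmonic bonds, hard-sphere excluded volume between non-bonded
   beads, and grid-lookup protein interactions:

   E = ½ Σᵢ kᵢ(lᵢ − lᵢᵉᑫ)² + E_g^GCP1 + E_g^Lys1 + E_g^Lys2 + E_g^GCP2

   (defaults: l = 6/13/13/6 Å, k = 12/3/3/12 k_BT/Å², hard core
   a = 9.6 Å).
3. **Simulated annealing ensemble** — thousands of independent
   Metropolis Monte-Carlo restarts (default 4000), each with the
   central bead fixed on a random node of a layer around the protein
   surface, cooled geometrically from 3000 K until the acceptance
   ratio collapses.  The compiled (numba) inner loop is
   bit-reproducible from a master seed.
4. **Analysis** — final-energy histograms, minimum-energy
   conformations, k-medoids clustering of low-energy positions, a C2
   symmetry score for homodimeric targets, and residue contact
   reports.

A synthetic-fixture module generates planted-minimum instances with an
exact brute-force enumeration oracle, so the whole pipeline is testable
offline; see `docs/methods.md` for the model, the schedule, and what
the fixtures do and do not demonstrate.

## Worked example

Generate a synthetic instance (toy protein PQR, GCP/Lys affinity grids
with planted wells, steric mask, production parameter files), anneal a
200-restart ensemble with a lattice-appropriate schedule, and analyze:

```bash
annealdock fixtures --outdir demo --seed 3
annealdock anneal \
    --gcp-dx demo/gcp_affinity.dx --lys-dx demo/lys_affinity.dx \
    --pqr demo/toy_protein.pqr --sa-config demo/sa_coarse.yaml \
    --seed 5 --out-csv demo/runs.csv --out-json demo/runs.json
annealdock analyze --results-csv demo/runs.csv \
    --spacing 3.0 --origin=-21,-21,-21 --k 2 --out-prefix demo/analysis
```

where `demo/sa_coarse.yaml` sets `max_displacement_grid_lengths: 1`,
`cooling_factor: 0.9`, `max_levels: 60`, `n_runs: 200` (the 3 Å demo
lattice needs 3 Å moves; the defaults are tuned for 0.4 Å production
grids).  The anneal step prints

```
200 runs -> demo/runs.csv; min final energy -193.371 kJ/mol
```

and `demo/analysis_summary.json` contains

```json
{
 "n_runs": 200,
 "min_energy_kj_mol": -193.3706035230257,
 "top_runs": [
  {"run_id": 64, "final_energy_kj_mol": -193.3706035230257},
  {"run_id": 100, "final_energy_kj_mol": -170.42744974714435}
 ],
 "n_clusters": 2,
 "cluster_cost_A": 66.06913283192465
}
```

Reading: the deepest restart (−193.4 kJ/mol) found the planted wells —
its four charged beads sit in the two GCP and two Lys energy minima
(≈ 4 × 50 kJ/mol of well depth plus noise and a little spring strain);
the run ids identify rows in `runs.csv`, whose bead-node columns give
the pose.  The two cluster medoids in `analysis_clusters.csv` are the
Cartesian positions (Å) of the low-energy anchor regions.

The same objects are available as a library:

```python
from annealdock import (make_planted_minimum_instance, default_ligand,
                        brute_force_global_minimum)
from annealdock.sa_engine import SAConfig, simulated_annealing

inst = make_planted_minimum_instance(seed=3)
ligand = default_ligand()
e_star, conf = brute_force_global_minimum(inst, ligand)  # exact optimum
run = simulated_annealing(inst.aie_node, ligand, inst.gcp_grid, inst.lys_grid,
                          SAConfig(seed=5, max_displacement=1,
                                   cooling_factor=0.9, max_levels=60))
print(run.final_total_energy - e_star)  # 0.0 when the restart converged
```

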