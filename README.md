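# hydrosite

Binding-site analysis for protein pockets built around three ideas from
structure-based drug design on GPCRs and similar targets:

1. **Probe interaction fields.** A chemical probe (water OH2, aromatic
   carbon C1=, methyl C3, hydrophobic DRY) is swept over a 3D lattice and
   its interaction energy with the receptor is summed at each point,
   `E = E_LJ + E_elec + E_hb`.  Local minima below a contour level are
   *hotspots*; the composite **CRY** probe, `min(C1=, DRY)` pointwise,
   maps lipophilic and hydrophobic hotspots in one field.  The C3 probe's
   +1 kcal/mol level set defines the pocket surface.

2. **Explicit water networks.** Waters are placed iteratively into
   OH2-probe hotspots — the field is recomputed after every placement,
   with the energy cutoff raised from −8 to −1 kcal/mol — then relaxed by
   rigid-body Metropolis Monte Carlo and rescored in full context.  Each
   water gets an estimated free energy relative to bulk solvent,

       dG_est = (E_OH2,context − E_bulk) + 0.5 · max(0, −E_CRY),

   and the conventional four-colour label: red (> 3.5 kcal/mol,
   "unhappy"), yellow (2.0–3.5), grey (−1.0–2.0), blue (< −1.0,
   "happy").  Unhappy waters in lipophilic subpockets flag druggable
   sites; network differences between a complex and its mutants or
   analogues rationalize affinity changes such as a "magic methyl".

3. **Binding free energies on a path CV.**  Stage 1 ratchets a system
   from unbound to bound with adiabatic-bias dynamics (harmonic bias
   active only beyond the best distance reached so far; six segments,
   target ÷100 and spring ×100 per segment) and resamples the trajectory
   into 102 snapshots.  Stage 2 runs one well-tempered metadynamics
   walker per snapshot (300 K, bias factor γ = 50, first Gaussian
   3 kcal/mol, σ = 0.1) on the progress-along-path variable
   `s = Σ tᵢ e^(−λDᵢ) / Σ e^(−λDᵢ)`, all writing to one shared hills
   ledger; `ΔG_bind = F(bound) − F(unbound)` from the reconstructed
   profile.

Everything runs on synthetic toy systems with planted ground truth — a
carbon-shell cavity with engineered hydration sites and lipophilic cups,
rigid toy ligands, a bulk water box, and 1D binding landscapes whose
free-energy differences are known by quadrature — so the whole protocol
is testable end to end without external structures.  Real PDB files are
read and written through the same interfaces.

## Worked example

```python
import numpy as np
from hydrosite import fixtures, waternet, workbench
from hydrosite.metadyn import run_binding_path, run_metascore

# explicit water network for the methyl-bearing toy complex
config = workbench.RunConfig(
    fixture={"kind": "magic_methyl"}, seed=1, n_sweeps=40,
    schedule=waternet.PlacementSchedule(placement_radius=7.0, rescore_radius=7.0),
)
bundle = workbench.run_waterflap_pipeline(config)
net = bundle["network"]
classes = {}
for s in net.scores:
    classes[s.class_label] = classes.get(s.class_label, 0) + 1
print(f"placed {len(net.waters)} waters, {len(net.scores)} scored "
      f"(bulk reference {bundle['bulk_reference']:.2f} kcal/mol)")
print("classes:", dict(sorted(classes.items())))

# binding free energy of a -5 kcal/mol toy landscape
land = fixtures.make_binding_landscape(depth_bound=-5.0, barrier=3.0)
snapshots = run_binding_path(land, seed=1)
result = run_metascore(land, snapshots, seed=101)
print(f"snapshots: {len(snapshots)}")
print(f"dG_bind = {result.delta_g_bind:.2f} kcal/mol "
      f"(quadrature ground truth {land.analytic_delta_f():.2f})")
```

prints

```
placed 34 waters, 27 scored (bulk reference -12.33 kcal/mol)
classes: {'blue': 2, 'grey': 12, 'red': 9, 'yellow': 4}
snapshots: 102
dG_bind = -4.21 kcal/mol (quadrature ground truth -4.00)
```

The 34 waters fill the toy cavity around the ligand; the scored subset
(within the rescore radius) splits into happy waters at the engineered
hydration sites (blue/grey) and unhappy ones lining the apolar walls
(yellow/red) — the bulk reference of −12.3 kcal/mol is the zero point of
that scale.  The binding-path stage emits exactly 102 snapshot
configurations spanning the binding event, and the shared-hills
metadynamics stage recovers the planted −4.0 kcal/mol well depth to
within a fraction of a kcal/mol.

A `hydrosite` command-line tool wraps the same pipelines
(`waterflap`, `druggability`, `metascore`, `bpm`); see
`hydrosite --help`.

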