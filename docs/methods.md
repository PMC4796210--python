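# Methods

`hydrosite` implements a binding-site analysis stack for protein pockets:
GRID-style probe interaction fields, iterative explicit-water network
generation with happiness scoring, a hotspot/unhappy-water druggability
assessment, and a two-stage binding free-energy protocol (ratchet binding
path + shared-hills well-tempered metadynamics on a path collective
variable).  Everything is exercised on synthetic toy systems with planted
ground truth, so every claim the test suite makes is checkable against
construction or quadrature.

## Energy model

The probe field at a lattice point is the sum over environment atoms of

* **Lennard-Jones** 12-6 term, `eps_ij[(rmin_ij/r)^12 − 2(rmin_ij/r)^6]`,
  with Lorentz–Berthelot combination over a small per-class parameter
  table (`data/atom_types.yaml`).  Classes: sp3/sp2 carbon, polar N,
  polar O, sulfur, hydrogen.
* **Electrostatics** with a distance-dependent dielectric,
  `332.06 q_p q_a / (4 r^2)` kcal/mol — the common implicit-solvent
  choice `eps_r = 4r`.
* **Hydrogen bond**: a 12-10 well of depth 4.0 kcal/mol at r0 = 2.9 Å
  between an H-bond-capable probe and donor/acceptor heavy atoms,
  modulated by a `cos²` directional lobe.  Waters carry explicit lobes
  (both O–H bonds plus the anti-bisector acceptor direction); receptor
  and ligand polar atoms carry a single lobe pointing away from their
  covalent parent.  Without the receptor lobes the field develops
  spurious minima *behind* H-bond partners and planted hydration sites
  stop being local minima; with them, the minimum sits where the
  chemistry says it should.

Values are clamped at +100 kcal/mol so atom cores stay finite.  The grid
default is 0.5 Å spacing.

Probes: `OH2` (water, H-bond capable), `C1=` (aromatic carbon,
lipophilic), `C3` (methyl; its +1 kcal/mol level set defines the pocket
surface), and `DRY` = neutral-carbon LJ + a −0.85 kcal/mol burial reward
(≥ 50 % of the 26 lattice neighbours sterically closed) + a penalty equal
to the local attractive water H-bond energy, so DRY goes dark near polar
groups.  `CRY` is the pointwise minimum of `C1=` and `DRY`.  Hotspots are
26-neighbourhood local minima below a threshold, deduplicated greedily
within 1.5 Å.  Default contour levels: −2.7 kcal/mol lipophilic (−2.5
also in circulation and accepted), −6.0 water, +1.0 pocket surface.

## Water networks

Placement iterates water-probe hotspot filling: compute the OH2 field of
the environment *including all waters placed so far*, occupy hotspots
below the running cutoff (skipping anything within 2.4 Å of an oxygen or
heavy atom), and raise the cutoff from −8 to −1 kcal/mol in 1 kcal/mol
steps until a level adds nothing.  Each new water's hydrogens are
oriented over 60 deterministic trial orientations plus a greedy
refinement against the explicit pair energy.  Placement searches within
10 Å of the ligand centroid (pocket centroid when apo).

Relaxation is rigid-body Metropolis Monte Carlo (water moves ≤ 0.2 Å /
15°; optional ligand moves ≤ 0.1 Å / 5°; receptor fixed) on the explicit
pair energy: typed LJ + screened Coulomb on all three water sites + the
directional H-bond term, TIP3P-like charges (−0.834/+0.417) and geometry
(0.9572 Å, 104.52°).  MC replaces the original protocol's short
restrained MD; it serves the same purpose (settling an H-bonded network)
and is reproducible per seed.  Note that because placement already
optimizes orientations, relaxation from a placed network equilibrates at
temperature rather than descending; the energy-decrease property is
demonstrated from orientation-scrambled starts.

Scoring: waters within 8 Å of the ligand get
`dG_est = (E_OH2,context − E_bulk) + 0.5·max(0, −E_CRY)`, where the
context energy is the OH2 probe at the oxygen with receptor, ligand and
every other water present, and E_CRY is evaluated against receptor +
ligand only.  The bulk reference is the mean in-context OH2 energy of
interior waters (≥ 4 Å from the faces) of a jittered-lattice box at
0.0334 Å⁻³; a 21 Å box is the smallest giving ≥ 20 interior waters.  The
0.5 lipophilic weight is a design choice that makes weakly H-bonded
waters inside lipophilic hotspots score unhappy, as the qualitative
picture demands; it is exposed as a parameter.  Classes: red > 3.5,
yellow (2.0, 3.5], grey [−1.0, 2.0], blue < −1.0 kcal/mol.  For apo
druggability runs the rescore radius is widened to cover the whole
searched pocket, since the 8 Å rule has no ligand to centre on.

Druggability: for every CRY hotspot below the lipophilic threshold,
record the distance to the nearest OH2 hotspot and count red/yellow
waters within 4 Å; a subpocket is druggable when both a polar hotspot
and at least one unhappy water sit inside that radius.  The 4 Å
adjacency radius is a design choice (the motif is described visually in
the literature, never numerically).

## Synthetic fixtures

The toy cavity is a two-layer carbon shell (radii 12 / 14.2 Å, ~3 Å
spacing, small per-seed jitter).  Polar sites are realized as a serine
OG plus two backbone carbonyls aimed at the site from a symmetric
70°-cone tripod — the symmetry pins the water-probe minimum on the
planted point (a two-partner site leaves a banana-shaped valley whose
minimum wanders ~1 Å).  Lipophilic sites are cups of ~40 apolar carbons
at radius 4.0 Å — the carbon–carbon LJ optimum, so a methyl at the cup
centre feels zero net force and fluctuates minimally.

The magic-methyl scenario adds, on the serine side of the cup, a
one-water alcove: blocked by the methyl (2.1 Å) but clear of the
des-methyl attachment carbon (2.8–3.0 Å), with a carbonyl pin holding
the seated water in register and a backing ring collimating the pin so
no off-axis pose exists.  The ligand is a linear five-heavy-atom rod
(methyl–linker–amine anchor–two-carbon tail); a one-sided wall beside
the tail tip blocks the rigid-body rotations that would otherwise absorb
the water's push, so hydration of the alcove translates the ligand off
the serine and measurably lengthens the anchor H-bond.  The mutation
scenario adds a spectator serine in a semi-enclosed nook (apolar belt,
one or two neighbour waters): the nook water owes most of its happiness
to the OG and is re-classified unhappier when the serine is truncated to
alanine.

The fixtures emulate the energetic motifs the methods consume —
directional hydration sites, enclosed lipophilic subpockets, a displaced
water, a perturbable network — not protein topology: no backbone
connectivity, no 7-helix architecture, rigid receptors, rigid toy
ligands.  Passing tests therefore demonstrate that the machinery
responds correctly to those motifs at realistic energy scales, not that
it reproduces any particular receptor's thermodynamics.

The bulk box and all generators are bit-deterministic per seed.  Toy
binding landscapes are 1D: a flat unbound region at x = 0, a Gaussian
bound well at x = 1 (width 0.1), a Gaussian barrier at x = 0.5, stiff
confining walls at −0.15 / 1.15, and named additive Gaussian
perturbations on the bound well standing in for mutations.  The manifest
free-energy difference is the Boltzmann quadrature over ±0.3 windows
around the wells.  The walls sit close to the wells deliberately: the
path CV saturates for far-out configurations, and bias deposited in the
saturated region cannot be localized.

## Binding free-energy protocol

Stage 1 (binding path): overdamped Langevin (Euler–Maruyama, step 0.002,
unit friction) under an adiabatic-bias ratchet — a harmonic bias acting
only when the distance ρ to the bound state exceeds the best value
reached so far, floored at the segment target.  Six segments; after each
the target is divided by 100 and the spring constant multiplied by 100
from initial values of 10 distance units and 1 kJ mol⁻¹ nm⁻²
(0.00239 kcal mol⁻¹ Å⁻²).  The late-segment springs reach ~10⁷
kcal mol⁻¹ Å⁻², far beyond explicit-Euler stability, so the ratchet
spring is integrated by its exact exponential relaxation (operator
splitting), stable for any stiffness.  The trajectory is resampled to
102 snapshots at first-passage frames of uniformly spaced ρ levels —
uniform-in-time resampling would collapse ~97 % of snapshots onto the
bound basin, because the toy ratchet parks there from the second segment
on.  "Binding reached" means the final ρ is below a 0.1-unit tolerance
(the literal final target of 10⁻⁹ is beneath thermal noise by
construction).

Stage 2 (metadynamics): each snapshot seeds a walker on the
progress-along-path variable
`s = Σ tᵢ e^(−λDᵢ) / Σ e^(−λDᵢ)` with two reference frames (unbound,
bound).  λ defaults to 0.6 (inverse squared distance, appropriate for
frames several Å apart); the unit-separated toy frames use λ = 3.0 so
the endpoints map to s ≈ 0.05 / 0.95 with a mild logistic slope.  All
walkers advance *concurrently* (synchronous steps against one shared
hills ledger, deposits in walker order) — sequential execution lets
early walkers flood one basin and herds every later walker into the
other, freezing 15–25 kcal/mol asymmetries into the bias.  Heights
follow the well-tempered rule `h = h₀ e^(−V/(k_B(γ−1)T))` with γ = 50,
T = 300 K, σ = 0.1, h₀ = 3 kcal/mol.

Estimator: deposition stops after 75 % of the run; the final quarter
samples under the frozen bias and is reweighted umbrella-style (each
configuration weighted by `e^{+V(s)/kT}`).  State free energies are
Boltzmann sums of the reweighted density over the bound (s ∈ [0.85, 1])
and unbound (s ∈ [0, 0.15]) windows, and
`ΔG_bind = F_bound − F_unbound`.  Point statistics (min/mean of the
accumulated-bias profile) are not used for ΔG because any residual
transient structure in V scales with its magnitude and dwarfs a
few-kcal/mol signal; the hills-based reconstruction
`F(s) = −(γ/(γ−1)) V(s)` remains available as
`reconstruct_free_energy`.

Deposition scale: the class defaults keep the reference protocol
(h₀ = 3 kcal/mol — the first-hill height the conformance tests read).
That scale is appropriate for binding events with tens of kcal/mol of
relief; on a 3–5 kcal/mol toy landscape it over-deposits by two orders
of magnitude and walkers end up pinned in the saturated CV corners.
Toy applications therefore use `TOY_METAD_PARAMS`
(h₀ = 0.015 kcal/mol ≪ kT, 40 000 steps per walker, stride 100),
calibrated once against the convergence properties: a symmetric double
well must score 0 and an asymmetric well must match its quadrature
manifest, with the error monotone in h₀.  `compare_variants` reuses one
reference binding path per seed for all variants and runs each variant's
metadynamics with the same noise stream, so correlated errors cancel in
ΔΔG.

## Numerical choices and degenerate inputs

* Seeds: every stochastic routine takes an explicit seed;
  `numpy.random.default_rng` throughout.  Fixture generators are
  bit-deterministic per seed.
* Clash rule 2.4 Å (O–O and O–heavy) enforced at placement, proposal
  rejection during MC, and re-validated after every pipeline stage.
* Empty environments give identically zero fields; empty hills lists,
  unscored networks, apo-on-apo stripping, GLY mutations and
  non-terminal substituent strips raise typed errors.
* Placement aborts with diagnostics after 200 rounds (never observed
  under the defaults; typical runs converge in ~20).
* Problem sizes: pipelines on the toy systems use a 0.5 Å grid over a
  ~24 Å cube (~10⁵ lattice points, ~500 atoms), 30–130 waters, and MC
  relaxations of tens of sweeps; metadynamics runs integrate ~4 × 10⁶
  walker-steps per estimate.  A full waterflap pipeline takes seconds to
  tens of seconds on one CPU core.

## Known limitations

* The energy model is a transparent surrogate, not a fitted force
  field; absolute energies are only meaningful relative to the bulk
  reference computed with the same model.
* Probe H-bonding is orientation-optimal by construction (the probe has
  no orientation state), which overcounts coordination in dense polar
  clusters; the directional lobes bound the effect.
* MC relaxation with rigid bodies cannot reproduce kinetic quantities
  (residence times, off-rates); only equilibrium-ish rearrangements.
* The metadynamics stack is validated on 1D toy landscapes.  The path
  CV, ratchet, and shared-ledger machinery are dimension-agnostic, but
  no all-atom claims are made, and the reference deposition scale is not
  re-validated here against any real receptor.
* Tautomers, protonation states and CONECT-based bond perception are out
  of scope; typing comes solely from the residue/atom lookup with an
  element fallback.
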