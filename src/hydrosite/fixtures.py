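"""Synthetic fixtures with planted ground truth.

Every analysis in this package is exercised on toy systems whose answers
are known by construction:

* ``make_toy_cavity`` — a hollow shell of carbon atoms (~12 A radius)
  with planted polar sites (serine hydroxyl + backbone carbonyl aimed at
  the site, so the water probe has a deep directional minimum there) and
  lipophilic subpockets (a cup of apolar carbons carved into the wall,
  giving a C1=/CRY hotspot at the cup center).
* ``make_toy_ligand`` — a rigid ligand whose heavy atoms sit on planted
  sites: an H-bonding anchor on a polar site, an optional terminal methyl
  filling a lipophilic site.
* ``make_magic_methyl_scenario`` — the methyl / des-methyl ligand pair in
  a cavity built so that removing the methyl vacates a small hydrophobic
  pocket that water can occupy, while the ligand is held only by a
  hydrogen-bond anchor perpendicular to the pocket axis.
* ``make_bulk_box`` — jittered-lattice water at 0.0334 molecules/A^3
  (~1 g/cm^3), the bulk reference for hydration-site scoring.
* ``make_binding_landscape`` — a 1D double-well potential with an
  analytically known (quadrature) free-energy difference, the oracle for
  the metadynamics machinery.

All generators are deterministic per seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import integrate

from .structures import (
    Atom,
    MolecularStructure,
    ReceptorComplex,
    StructureError,
    WaterMolecule,
    type_complex,
    assign_atom_types,
)

__all__ = [
    "PlantedSite",
    "ToyLandscape",
    "make_toy_cavity",
    "make_toy_ligand",
    "make_magic_methyl_scenario",
    "make_mutation_scenario",
    "make_bulk_box",
    "make_binding_landscape",
    "write_fixture",
]

KB = 0.0019872041  # kcal/mol/K

#: Bulk water number density, molecules per A^3 (~1 g/cm^3).
BULK_DENSITY = 0.0334

# Cavity geometry (A)
SHELL_RADII = (12.0, 14.2)
SHELL_SPACING = 3.0
POLAR_SITE_RADIUS = 6.5
LIPO_SITE_RADIUS = 8.8
CUP_RADIUS = 4.0
MIN_SITE_ANGLE = 62.0  # degrees between planted directions


@dataclass(frozen=True)
class PlantedSite:
    position: np.ndarray
    character: str       # polar | lipophilic
    intended_role: str   # hydration-site | hotspot

    def as_dict(self) -> dict:
        return {
            "position": [float(x) for x in self.position],
            "character": self.character,
            "intended_role": self.intended_role,
        }


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def _perpendicular(u: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, u)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    w = np.cross(u, ref)
    return w / np.linalg.norm(w)


class _AtomFactory:
    def __init__(self) -> None:
        self.serial = 0

    def __call__(self, name, element, resname, resnum, chain, pos) -> Atom:
        self.serial += 1
        return Atom(
            serial=self.serial, name=name, element=element, residue_name=resname,
            residue_number=resnum, chain=chain, position=np.asarray(pos, dtype=float),
        )


def _add_serine(new, atoms, site, dir_og, resnum) -> None:
    """Serine whose OG aims at the planted site from 2.9 A away."""
    og = site + 2.9 * dir_og
    axis = dir_og
    perp = _perpendicular(axis)
    cb = og + 1.43 * axis
    ca = cb + 1.53 * (0.8 * axis + 0.6 * perp)
    n = ca + 1.46 * (0.55 * axis - 0.84 * perp)
    c = ca + 1.52 * (0.3 * axis + 0.95 * perp)
    o = c + 1.23 * axis
    for name, el, pos in (
        ("N", "N", n), ("CA", "C", ca), ("C", "C", c), ("O", "O", o),
        ("CB", "C", cb), ("OG", "O", og),
    ):
        atoms.append(new(name, el, "SER", resnum, "A", pos))


def _add_carbonyl(new, atoms, site, dir_o, resnum) -> None:
    """Glycine-like backbone carbonyl aimed at the planted site."""
    o = site + 2.9 * dir_o
    c = o + 1.23 * dir_o
    perp = _perpendicular(dir_o)
    ca = c + 1.52 * (0.6 * dir_o + 0.8 * perp)
    n = ca + 1.46 * (0.6 * dir_o - 0.8 * perp)
    for name, el, pos in (("N", "N", n), ("CA", "C", ca), ("C", "C", c), ("O", "O", o)):
        atoms.append(new(name, el, "GLY", resnum, "A", pos))


def _add_cup(new, atoms, site, opening_dir, resnum_start, rng) -> int:
    """Apolar cup around the site, open toward ``opening_dir``."""
    normals = _fibonacci_sphere(64)
    kept = normals[normals @ (-opening_dir) > -0.25]
    existing = np.array([a.position for a in atoms]) if atoms else np.zeros((0, 3))
    resnum = resnum_start
    for nrm in kept:
        pos = site + CUP_RADIUS * nrm + rng.normal(0.0, 0.05, size=3)
        if len(existing) and np.linalg.norm(existing - pos, axis=1).min() < 2.4:
            continue
        atoms.append(new("CA", "C", "SHL", resnum, "B", pos))
        resnum += 1
    return resnum


def _sample_directions(rng: np.random.Generator, n: int, existing: list[np.ndarray]) -> list[np.ndarray]:
    out: list[np.ndarray] = []
    min_cos = math.cos(math.radians(MIN_SITE_ANGLE))
    for _ in range(n):
        for _try in range(500):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            if all(np.dot(v, w) < min_cos for w in existing + out):
                out.append(v)
                break
        else:
            raise StructureError("cannot place planted sites >= 3 A apart")
    return out


def make_toy_cavity(
    n_polar_sites: int,
    n_lipophilic_sites: int,
    seed: int,
    polar_dirs: Optional[list[np.ndarray]] = None,
    lipo_dirs: Optional[list[np.ndarray]] = None,
    polar_partner_dirs: Optional[list[tuple[np.ndarray, np.ndarray]]] = None,
) -> tuple[ReceptorComplex, list[PlantedSite]]:
    """Hollow pseudo-receptor shell with planted polar and lipophilic sites.

    Returns the typed complex (no ligand, no waters) and the ground-truth
    manifest.  The optional direction arguments let scenario builders pin
    the geometry; by default directions are sampled per seed with enough
    angular separation to keep sites >= 3 A apart.
    """
    if n_polar_sites < 0 or n_lipophilic_sites < 0:
        raise ValueError("site counts must be >= 0")
    rng = np.random.default_rng(seed)
    new = _AtomFactory()
    atoms: list[Atom] = []
    sites: list[PlantedSite] = []

    if lipo_dirs is None:
        lipo_dirs = _sample_directions(rng, n_lipophilic_sites, [])
    if polar_dirs is None:
        polar_dirs = _sample_directions(rng, n_polar_sites, list(lipo_dirs))

    # planted residues first, shell afterwards (so we can carve around them)
    resnum = 500
    for i, v in enumerate(polar_dirs):
        vn = v / np.linalg.norm(v)
        site = POLAR_SITE_RADIUS * np.asarray(v, dtype=float)
        if polar_partner_dirs is not None:
            partners = [np.asarray(d, dtype=float) for d in polar_partner_dirs[i]]
        else:
            # symmetric tripod: three H-bond partners on a 70-degree cone
            # around the outward radial, 120 degrees apart, so the water
            # probe minimum is pinned at the site by symmetry
            p1 = _perpendicular(vn)
            p2 = np.cross(vn, p1)
            c70, s70 = math.cos(math.radians(70.0)), math.sin(math.radians(70.0))
            partners = [
                c70 * vn + s70 * (math.cos(phi) * p1 + math.sin(phi) * p2)
                for phi in (0.0, 2.0 * math.pi / 3.0, 4.0 * math.pi / 3.0)
            ]
        _add_serine(new, atoms, site, partners[0], resnum)
        resnum += 1
        for d in partners[1:]:
            _add_carbonyl(new, atoms, site, d, resnum + 1)
            resnum += 1
        resnum += 1
        sites.append(PlantedSite(site, "polar", "hydration-site"))

    cup_resnum = 800
    for u in lipo_dirs:
        site = LIPO_SITE_RADIUS * u
        cup_resnum = _add_cup(new, atoms, site, -u, cup_resnum, rng)
        sites.append(PlantedSite(site, "lipophilic", "hotspot"))

    planted_pos = np.array([a.position for a in atoms]) if atoms else np.zeros((0, 3))
    lipo_centers = [LIPO_SITE_RADIUS * u for u in lipo_dirs]

    shell_resnum = 1
    for radius in SHELL_RADII:
        n = int(round(4.0 * math.pi * radius**2 / SHELL_SPACING**2))
        for nrm in _fibonacci_sphere(n):
            pos = radius * nrm + rng.normal(0.0, 0.12, size=3)
            if any(np.linalg.norm(pos - c) < CUP_RADIUS + 1.6 for c in lipo_centers):
                continue
            if len(planted_pos) and np.linalg.norm(planted_pos - pos, axis=1).min() < 2.6:
                continue
            atoms.append(new("CA", "C", "SHL", shell_resnum, "S", pos))
            shell_resnum += 1

    receptor = MolecularStructure(atoms=atoms, role="receptor",
                                  provenance=f"toy cavity seed={seed}")
    receptor.validate()
    complex = type_complex(ReceptorComplex(receptor=receptor))
    positions = [s.position for s in sites]
    for i in range(len(positions)):
        for j in range(i + 1, len(positions)):
            if np.linalg.norm(positions[i] - positions[j]) < 3.0:
                raise StructureError("planted sites closer than 3 A")
    return complex, sites


def make_toy_ligand(
    occupies: list[PlantedSite], with_methyl: bool = True
) -> MolecularStructure:
    """Rigid toy ligand covering the given planted sites.

    The first polar site gets the H-bond anchor (an amine-like nitrogen,
    named N1); the first lipophilic site gets the terminal methyl (CM) when
    ``with_methyl`` is set.  A straight sp3-carbon linker connects them.
    """
    if not occupies:
        raise ValueError("ligand must occupy at least one site")
    polar = next((s for s in occupies if s.character == "polar"), None)
    lipo = next((s for s in occupies if s.character == "lipophilic"), None)
    atoms: list[Atom] = []
    new = _AtomFactory()

    def chain_between(a: np.ndarray, b: np.ndarray) -> list[np.ndarray]:
        d = np.linalg.norm(b - a)
        t = (b - a) / d
        k = max(int(round(d / 1.5)) - 1, 0)
        return [a + 1.5 * (i + 1) * t for i in range(k)]

    if polar is not None and lipo is not None:
        if with_methyl:
            atoms.append(new("CM", "C", "LIG", 1, "L", lipo.position))
        for i, pos in enumerate(chain_between(lipo.position, polar.position), start=2):
            atoms.append(new(f"C{i}", "C", "LIG", 1, "L", pos))
        atoms.append(new("N1", "N", "LIG", 1, "L", polar.position))
    elif polar is not None:
        atoms.append(new("N1", "N", "LIG", 1, "L", polar.position))
        if with_methyl:
            atoms.append(new("CM", "C", "LIG", 1, "L", polar.position + np.array([1.5, 0, 0])))
    else:
        assert lipo is not None
        if with_methyl:
            atoms.append(new("CM", "C", "LIG", 1, "L", lipo.position))
        else:
            atoms.append(new("C2", "C", "LIG", 1, "L", lipo.position + np.array([1.5, 0, 0])))

    ligand = MolecularStructure(atoms=atoms, role="ligand", provenance="toy ligand")
    assign_atom_types(ligand)
    ligand.validate()
    return ligand


def _add_scenario_pocket(
    atoms: list[Atom], site: np.ndarray, axis_u: np.ndarray,
    alcove: np.ndarray, rng: np.random.Generator,
) -> None:
    """Main apolar cup at ``site`` plus a one-water alcove at ``alcove``."""
    new = _AtomFactory()
    new.serial = max((a.serial for a in atoms), default=0)
    existing = np.array([a.position for a in atoms]) if atoms else np.zeros((0, 3))
    resnum = 800
    added: list[np.ndarray] = []
    # main cup, opening toward the cavity center, holed around the alcove
    for nrm in _fibonacci_sphere(64):
        if nrm @ axis_u <= -0.25:
            continue
        pos = site + CUP_RADIUS * nrm + rng.normal(0.0, 0.05, size=3)
        if np.linalg.norm(pos - alcove) < 3.4:
            continue
        if len(existing) and np.linalg.norm(existing - pos, axis=1).min() < 2.4:
            continue
        atoms.append(new("CA", "C", "SHL", resnum, "B", pos))
        added.append(pos)
        resnum += 1
    # H-bond pin for the alcove water: a carbonyl aimed at the alcove from
    # behind, so the water that replaces the methyl is held in register
    # against the ligand attachment carbon
    w_hat = alcove - site
    w_hat = w_hat / np.linalg.norm(w_hat)
    _add_carbonyl(new, atoms, alcove, w_hat, 810)
    pin_o = alcove + 2.9 * w_hat
    added.extend(a.position for a in atoms[-4:])
    # apolar backing ring closing the alcove around the carbonyl; a narrow
    # channel along the pin->alcove axis is kept open so the pin can only
    # hydrogen-bond a water sitting in the alcove seat itself
    cos_chan = math.cos(math.radians(38.0))
    for nrm in _fibonacci_sphere(96):
        if nrm @ w_hat <= 0.2:
            continue
        pos = alcove + 3.7 * nrm + rng.normal(0.0, 0.05, size=3)
        v_pin = pos - pin_o
        r_pin = np.linalg.norm(v_pin)
        if r_pin < 4.0 and (v_pin / r_pin) @ (-w_hat) > cos_chan:
            continue  # leave the H-bond channel open
        if np.linalg.norm(pos - alcove) < 3.2:
            continue
        if added and min(np.linalg.norm(pos - q) for q in added) < 1.0:
            continue
        if len(existing) and np.linalg.norm(existing - pos, axis=1).min() < 2.4:
            continue
        atoms.append(new("CA", "C", "SHL", resnum, "B", pos))
        added.append(pos)
        resnum += 1


def make_magic_methyl_scenario(seed: int) -> dict:
    """Methyl / des-methyl ligand pair in a purpose-built cavity.

    The lipophilic pocket sits on the +u radial axis; the ligand runs
    along u with its terminal methyl at the pocket center and the anchor
    nitrogen hydrogen-bonded sideways (along +w) to a serine OG.  The
    pocket carries a one-water alcove on the serine side, placed so that
    the methyl blocks it (2.1 A) while the des-methyl attachment carbon
    does not (2.8 A): on methyl removal the alcove hydrates and the
    seated water presses the ligand away from the serine.

    A two-carbon tail below the anchor runs past a one-sided wall on its
    +w flank: rotations of the rigid ligand about the anchor would swing
    the tail into that wall, so the alcove push can only *translate* the
    ligand along -w — which lengthens the serine anchor H-bond.
    """
    rng = np.random.default_rng(seed)
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    w = _perpendicular(u)
    lipo_site = LIPO_SITE_RADIUS * u
    anchor_site = lipo_site - 3.2 * u  # short lever: one linker carbon
    polar_dir = anchor_site / np.linalg.norm(anchor_site)

    complex, _ = make_toy_cavity(
        1, 1, seed,
        polar_dirs=[polar_dir * (np.linalg.norm(anchor_site) / POLAR_SITE_RADIUS)],
        lipo_dirs=[u],
        polar_partner_dirs=[(w,)],
    )
    # replace the generic cup (chain B) with the alcove-bearing pocket
    complex.receptor.atoms = [a for a in complex.receptor.atoms if a.chain != "B"]
    alcove = lipo_site + 2.0 * w + 0.46 * u
    n_before = len(complex.receptor.atoms)
    _add_scenario_pocket(complex.receptor.atoms, lipo_site, u, alcove, rng)
    pocket_pos = np.array([a.position for a in complex.receptor.atoms[n_before:]])
    complex.receptor.atoms = [
        a for a in complex.receptor.atoms[:n_before]
        if a.chain != "S" or np.linalg.norm(pocket_pos - a.position, axis=1).min() >= 2.4
    ] + complex.receptor.atoms[n_before:]
    assign_atom_types(complex.receptor)
    complex.receptor.validate()
    sites = [
        PlantedSite(anchor_site, "polar", "hydration-site"),
        PlantedSite(lipo_site, "lipophilic", "hotspot"),
    ]

    def scenario_ligand(with_methyl: bool) -> MolecularStructure:
        new = _AtomFactory()
        atoms = []
        if with_methyl:
            atoms.append(new("CM", "C", "LIG", 1, "L", lipo_site))
        atoms.append(new("C2", "C", "LIG", 1, "L", lipo_site - 1.5 * u))
        atoms.append(new("N1", "N", "LIG", 1, "L", anchor_site))
        atoms.append(new("C4", "C", "LIG", 1, "L", anchor_site - 1.5 * u))
        atoms.append(new("C5", "C", "LIG", 1, "L", anchor_site - 3.0 * u))
        lig = MolecularStructure(atoms=atoms, role="ligand",
                                 provenance="magic-methyl toy ligand")
        assign_atom_types(lig)
        lig.validate()
        return lig

    # one-sided wall on the +w flank of the tail tip (rotation stop)
    new = _AtomFactory()
    new.serial = max(a.serial for a in complex.receptor.atoms)
    c5 = anchor_site - 3.0 * u
    q = np.cross(u, w)
    wall_resnum = 950
    for offset in (np.zeros(3), 1.7 * q, -1.7 * q, 1.7 * u, -1.7 * u):
        pos = c5 + 3.9 * w + offset
        cur = np.array([a.position for a in complex.receptor.atoms])
        if np.linalg.norm(cur - pos, axis=1).min() < 1.0:
            continue
        complex.receptor.atoms.append(
            new("CA", "C", "SHL", wall_resnum, "B", pos))
        wall_resnum += 1
    assign_atom_types(complex.receptor)
    complex.receptor.validate()

    ligand_me = scenario_ligand(True)
    ligand_des = scenario_ligand(False)
    holo_me = ReceptorComplex(receptor=complex.receptor.copy(), ligand=ligand_me)
    holo_des = ReceptorComplex(receptor=complex.receptor.copy(), ligand=ligand_des)
    return {
        "with_methyl": holo_me,
        "des_methyl": holo_des,
        "sites": sites,
        "anchor_site": anchor_site,
        "lipo_site": lipo_site,
        "alcove": alcove,
        "axis": u,
        "anchor_perp": w,
    }


def make_mutation_scenario(seed: int) -> dict:
    """Holo cavity with a spectator hydration site whose serine can be mutated.

    The ligand occupies polar site 1 and the lipophilic cup; polar site 2
    hosts a network water whose happiness depends on the serine OG — the
    SER->ALA mutant of that residue is the destabilizing perturbation.
    """
    scen = make_magic_methyl_scenario(seed)
    complex = scen["with_methyl"]
    rng = np.random.default_rng(seed + 1)
    u = scen["axis"]
    for _try in range(500):
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        # 65-74 degrees off the ligand axis: clear of the ligand chain but
        # safely inside the rescore radius around the ligand centroid
        if 0.28 < np.dot(v, u) < 0.42:
            break
    site2 = 4.6 * v
    atoms = complex.receptor.atoms
    new = _AtomFactory()
    new.serial = max(a.serial for a in atoms)
    extra: list[Atom] = []
    # single-partner nook: the serine OG plus an apolar belt shielding the
    # site from most neighbor waters, so the water here owes its happiness
    # chiefly to the serine and is visibly re-classified when it is truncated
    _add_serine(new, extra, site2, v, 700)
    lig_pos = complex.ligand.positions(heavy_only=True)
    extra_pos = np.array([a.position for a in extra])
    belt_resnum = 900
    for nrm in _fibonacci_sphere(48):
        if not (-0.1 < nrm @ v < 0.62):
            continue
        pos = site2 + 3.8 * nrm + rng.normal(0.0, 0.05, size=3)
        if np.linalg.norm(extra_pos - pos, axis=1).min() < 2.4:
            continue
        if np.linalg.norm(lig_pos - pos, axis=1).min() < 3.2:
            continue
        cur = np.array([a.position for a in complex.receptor.atoms])
        if np.linalg.norm(cur - pos, axis=1).min() < 1.0:
            continue
        extra.append(new("CA", "C", "SHL", belt_resnum, "C", pos))
        belt_resnum += 1
        extra_pos = np.array([a.position for a in extra])
    # drop shell atoms that would clash with the new residues
    complex.receptor.atoms = [
        a for a in atoms
        if a.chain != "S" or np.linalg.norm(extra_pos - a.position, axis=1).min() >= 2.6
    ] + extra
    assign_atom_types(complex.receptor)
    complex.receptor.validate()
    sites = scen["sites"] + [PlantedSite(site2, "polar", "hydration-site")]
    return {
        "complex": complex,
        "sites": sites,
        "mutation": ("A", 700),       # the spectator serine
        "mutation_site": site2,
        "anchor_site": scen["anchor_site"],
        "lipo_site": scen["lipo_site"],
    }


# ---------------------------------------------------------------------------
# Bulk water box
# ---------------------------------------------------------------------------

def make_bulk_box(edge: float, seed: int) -> list[WaterMolecule]:
    """Waters on a jittered lattice at bulk density with random orientations."""
    if edge < 12.0:
        raise ValueError("bulk box edge must be >= 12 A")
    rng = np.random.default_rng(seed)
    n = int(round(BULK_DENSITY * edge**3))
    a = (1.0 / BULK_DENSITY) ** (1.0 / 3.0)
    m = int(math.ceil(edge / a))
    ii, jj, kk = np.meshgrid(*(np.arange(m),) * 3, indexing="ij")
    centers = (np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) + 0.5) * a
    centers = centers[np.all(centers < edge, axis=1)]
    if len(centers) < n:
        raise ValueError("lattice too small for requested density")
    order = np.argsort(np.linalg.norm(centers - edge / 2.0, axis=1), kind="stable")
    centers = centers[order[:n]]
    jitter = rng.uniform(-0.15, 0.15, size=centers.shape)
    centers = centers + jitter
    waters = []
    for c in centers:
        axis = rng.normal(size=3)
        twist = rng.uniform(0.0, 2.0 * math.pi)
        waters.append(WaterMolecule.from_orientation(c, axis, twist))
    pos = np.array([w.oxygen for w in waters])
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    assert d.min() >= 2.4, "bulk lattice produced an O-O clash"
    return waters


# ---------------------------------------------------------------------------
# Toy binding landscapes
# ---------------------------------------------------------------------------

@dataclass
class ToyLandscape:
    """1D double-well surrogate for a ligand binding event.

    The unbound state is a flat region around x = 0 (reference energy 0),
    the bound state a Gaussian well at x = 1, with a Gaussian barrier in
    between and stiff confining walls.  Named perturbations model point
    mutations as additive Gaussians on the bound well.
    """

    terms: list[tuple[float, float, float]]  # (center, amplitude, sigma)
    perturbations: dict[str, list[tuple[float, float, float]]] = field(default_factory=dict)
    temperature: float = 300.0
    dimension: int = 1
    # stiff confinement just outside the two wells: keeps the dynamics in
    # the region where the path CV still resolves position (s saturates
    # toward 0/1 for far-out configurations, which would otherwise soak
    # up bias the profile cannot localize)
    walls: tuple[float, float, float] = (-0.15, 1.15, 200.0)  # lo, hi, k
    seed: int = 0
    bound_x: float = 1.0
    start_x: float = 0.0
    offset: float = 0.0  # constant energy shift (free energies are invariant)

    def _terms_for(self, variant: Optional[str]) -> list[tuple[float, float, float]]:
        terms = list(self.terms)
        if variant is not None:
            if variant not in self.perturbations:
                raise KeyError(f"unknown variant {variant!r}")
            terms += self.perturbations[variant]
        return terms

    def potential(self, x, variant: Optional[str] = None):
        x = np.asarray(x, dtype=float)
        v = np.zeros_like(x)
        for c, amp, sig in self._terms_for(variant):
            v = v + amp * np.exp(-((x - c) ** 2) / (2.0 * sig**2))
        lo, hi, k = self.walls
        v = v + k * np.where(x < lo, (x - lo) ** 2, 0.0)
        v = v + k * np.where(x > hi, (x - hi) ** 2, 0.0)
        return v + self.offset

    def gradient(self, x, variant: Optional[str] = None):
        x = np.asarray(x, dtype=float)
        g = np.zeros_like(x)
        for c, amp, sig in self._terms_for(variant):
            g = g + amp * np.exp(-((x - c) ** 2) / (2.0 * sig**2)) * (-(x - c) / sig**2)
        lo, hi, k = self.walls
        g = g + 2.0 * k * np.where(x < lo, x - lo, 0.0)
        g = g + 2.0 * k * np.where(x > hi, x - hi, 0.0)
        return g

    def rho(self, x) -> float:
        """Distance to the bound state (the ratchet coordinate)."""
        return float(abs(x - self.bound_x))

    def path_cv(self):
        """Progress-along-path CV between the unbound and bound frames.

        The reference frames are one distance unit apart (vs several A for
        a real ligand), so lambda is scaled up to 3.0 per squared unit to
        keep the endpoints near s = 0 and s = 1 with a mild logistic slope.
        """
        from .metadyn import PathCV

        return PathCV(frames=[self.start_x, self.bound_x], lam=3.0)

    def analytic_delta_f(self, variant: Optional[str] = None,
                         window: float = 0.3) -> float:
        """Bound-minus-unbound free energy from the Boltzmann integral."""
        beta = 1.0 / (KB * self.temperature)

        def boltz(x):
            # the constant offset cancels in the ratio; dropping it here
            # keeps the quadrature exactly shift-invariant
            return math.exp(-beta * (float(self.potential(x, variant)) - self.offset))

        zb, _ = integrate.quad(boltz, self.bound_x - window, self.bound_x + window,
                               limit=200)
        zu, _ = integrate.quad(boltz, self.start_x - window, self.start_x + window,
                               limit=200)
        return -KB * self.temperature * math.log(zb / zu)

    def manifest(self) -> dict:
        out = {"delta_f": self.analytic_delta_f(), "temperature": self.temperature,
               "seed": self.seed}
        for name in self.perturbations:
            out[f"delta_f_{name}"] = self.analytic_delta_f(name)
        return out


#: Width of the bound well / barrier Gaussians (dimensionless CV units).
WELL_SIGMA = 0.1
BARRIER_SIGMA = 0.09


def make_binding_landscape(
    depth_bound: float,
    barrier: float,
    perturbation: float = 0.0,
    seed: int = 0,
    temperature: float = 300.0,
) -> ToyLandscape:
    """Double-well landscape: flat unbound region, bound well of the given
    depth at x = 1, Gaussian barrier at x = 0.5.  A nonzero ``perturbation``
    registers a named 'mutant' variant adding that amplitude on the bound
    well (positive = destabilizing)."""
    if depth_bound >= 0:
        raise ValueError("depth_bound must be negative")
    if barrier < 0:
        raise ValueError("barrier must be >= 0")
    terms = [(1.0, depth_bound, WELL_SIGMA)]
    if barrier > 0:
        terms.append((0.5, barrier, BARRIER_SIGMA))
    perturbations = {}
    if perturbation != 0.0:
        perturbations["mutant"] = [(1.0, perturbation, WELL_SIGMA)]
    return ToyLandscape(terms=terms, perturbations=perturbations,
                        temperature=temperature, seed=seed)


def write_fixture(
    complex: ReceptorComplex, sites: list[PlantedSite], directory: str | Path
) -> None:
    """Write the fixture PDB plus its JSON ground-truth manifest."""
    from .structures import write_pdb

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_pdb(complex, directory / "fixture.pdb")
    manifest = {"sites": [s.as_dict() for s in sites]}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
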