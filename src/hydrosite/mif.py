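"""Probe interaction fields on a lattice: hotspots, pocket surface, CRY.

A chemical probe (water OH2, aromatic carbon C1=, methyl C3, hydrophobic
DRY) is swept over a 3D grid around the binding site and its interaction
energy with every environment atom is summed at each lattice point:

    E(p) = E_LJ + E_elec + E_hb

* ``E_LJ``   — 12-6 Lennard-Jones with Lorentz-Berthelot combination,
* ``E_elec`` — Coulomb with a distance-dependent dielectric (eps_r = 4r),
* ``E_hb``   — directional 12-10 hydrogen-bond well (depth 4 kcal/mol at
  2.9 A), modulated by a cos^2 lobe factor when the partner's hydrogens
  are explicit (waters), isotropic otherwise.

The DRY probe is the neutral-carbon LJ term plus a burial entropy reward
and a penalty proportional to the local water H-bond energy, so it lights
up hydrophobic enclosures and goes dark near polar groups.  CRY is the
pointwise best (minimum) of C1= and DRY — one map covering lipophilic and
hydrophobic hotspots alike, and the lipophilic half of the water scores.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import ndimage

from .structures import (
    Atom,
    MolecularStructure,
    ReceptorComplex,
    WaterMolecule,
    vdw_parameters,
)

__all__ = [
    "GridSpec",
    "ProbeDefinition",
    "ScalarField",
    "Hotspot",
    "PROBES",
    "Environment",
    "compute_probe_field",
    "probe_energy_at_points",
    "cry_field",
    "cry_at_points",
    "find_hotspots",
    "pocket_surface",
]

COULOMB = 332.06          # kcal mol^-1 A e^-2
HB_DEPTH = 4.0            # kcal/mol well depth of the 12-10 term
HB_R0 = 2.9               # A, ideal donor-acceptor distance
ENERGY_CLAMP = 100.0      # kcal/mol, cap inside atom cores
DRY_HB_WEIGHT = 1.0       # w in E_DRY = E_LJ + S_dry + w*|E_hb,OH2|
BURIAL_LEVEL = 1.0        # kcal/mol: neighbor counts as inaccessible above this


@dataclass(frozen=True)
class GridSpec:
    origin: tuple[float, float, float]
    spacing: float
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if any(n < 2 for n in self.shape):
            raise ValueError("grid shape components must be >= 2")

    @classmethod
    def fit(
        cls,
        positions: np.ndarray,
        spacing: float = 0.5,
        margin: float = 4.0,
    ) -> "GridSpec":
        positions = np.asarray(positions, dtype=float)
        lo = positions.min(axis=0) - margin
        hi = positions.max(axis=0) + margin
        shape = tuple(int(np.ceil((h - l) / spacing)) + 1 for l, h in zip(lo, hi))
        return cls(origin=tuple(lo), spacing=spacing, shape=shape)

    @classmethod
    def cube(cls, center: Sequence[float], half_extent: float, spacing: float = 0.5) -> "GridSpec":
        center = np.asarray(center, dtype=float)
        n = int(np.ceil(2 * half_extent / spacing)) + 1
        origin = center - spacing * (n - 1) / 2.0
        return cls(origin=tuple(origin), spacing=spacing, shape=(n, n, n))

    @property
    def n_points(self) -> int:
        return int(np.prod(self.shape))

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        o = np.asarray(self.origin)
        return tuple(o[i] + self.spacing * np.arange(self.shape[i]) for i in range(3))

    def points(self) -> np.ndarray:
        ax, ay, az = self.axes()
        gx, gy, gz = np.meshgrid(ax, ay, az, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    def index_position(self, idx: tuple[int, int, int]) -> np.ndarray:
        return np.asarray(self.origin) + self.spacing * np.asarray(idx, dtype=float)


@dataclass(frozen=True)
class ProbeDefinition:
    name: str
    vdw_epsilon: float      # kcal/mol
    vdw_rmin: float         # A (probe-probe rmin; combined as rmin/2 + atom rmin/2)
    charge: float = 0.0
    hbond_capable: bool = False
    entropy_reward: float = 0.0  # kcal/mol, DRY only (applied where buried)


PROBES: dict[str, ProbeDefinition] = {
    "OH2": ProbeDefinition("OH2", vdw_epsilon=0.1521, vdw_rmin=3.50, hbond_capable=True),
    "C1=": ProbeDefinition("C1=", vdw_epsilon=0.12, vdw_rmin=3.80),
    "C3": ProbeDefinition("C3", vdw_epsilon=0.08, vdw_rmin=4.00),
    "DRY": ProbeDefinition("DRY", vdw_epsilon=0.08, vdw_rmin=4.00, entropy_reward=-0.85),
}

#: Default contour / detection thresholds (kcal/mol), mirroring common usage:
#: lipophilic hotspots at -2.7 (a -2.5 alternative is also in circulation),
#: water hotspots at -6.0, pocket surface at +1.0.
DEFAULT_THRESHOLDS = {"C1=": -2.7, "CRY": -2.7, "OH2": -6.0, "C3": 1.0}


@dataclass
class ScalarField:
    grid: GridSpec
    values: np.ndarray
    probe: ProbeDefinition
    environment_hash: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(self.grid.shape)

    def to_dx(self, path: str | Path) -> None:
        """Write the field in OpenDX format for visualization."""
        g = self.grid
        with open(path, "w") as fh:
            fh.write(f"object 1 class gridpositions counts {g.shape[0]} {g.shape[1]} {g.shape[2]}\n")
            fh.write("origin {:.6f} {:.6f} {:.6f}\n".format(*g.origin))
            fh.write(f"delta {g.spacing:.6f} 0 0\n")
            fh.write(f"delta 0 {g.spacing:.6f} 0\n")
            fh.write(f"delta 0 0 {g.spacing:.6f}\n")
            fh.write(f"object 2 class gridconnections counts {g.shape[0]} {g.shape[1]} {g.shape[2]}\n")
            fh.write(
                f"object 3 class array type double rank 0 items {g.n_points} data follows\n"
            )
            flat = self.values.ravel()
            for i in range(0, len(flat), 3):
                fh.write(" ".join(f"{v:.6e}" for v in flat[i : i + 3]) + "\n")
            fh.write('attribute "dep" string "positions"\n')
            fh.write('object "density" class field\n')


@dataclass(frozen=True)
class Hotspot:
    position: np.ndarray
    energy: float
    probe: str


# ---------------------------------------------------------------------------
# Environment preparation
# ---------------------------------------------------------------------------

_ROLE_CODES = {"none": 0, "donor": 1, "acceptor": 2, "both": 3}

#: TIP3P-like water site parameters used when waters enter an environment.
WATER_O = ("polar_O", -0.834, "both")
WATER_H = ("hydrogen", 0.417, "none")


class Environment:
    """Typed environment atoms flattened to arrays for fast field sums.

    Waters contribute three sites; their explicit hydrogens also drive the
    directional factor of the H-bond term (donor lobes along each O-H bond,
    an acceptor lobe opposite the H-H bisector).
    """

    def __init__(
        self,
        structures: Iterable[MolecularStructure] = (),
        waters: Iterable[WaterMolecule] = (),
    ):
        pos, rmin_half, eps, charge, role = [], [], [], [], []
        lobes: list[Optional[np.ndarray]] = []  # (k,3) unit lobe dirs, or None
        for struct in structures:
            heavy = struct.heavy_atoms()
            heavy_pos = np.array([a.position for a in heavy]) if heavy else np.zeros((0, 3))
            for a in struct.atoms:
                if a.vdw_class is None:
                    raise ValueError(
                        f"untyped atom {a.serial} {a.name} {a.residue_name}; "
                        "run assign_atom_types first"
                    )
                rh, ep = vdw_parameters(a.vdw_class)
                pos.append(a.position)
                rmin_half.append(rh)
                eps.append(ep)
                charge.append(a.partial_charge)
                role.append(_ROLE_CODES[a.hbond_role])
                lobes.append(self._bond_lobe(a, heavy_pos))
        for w in waters:
            o = np.asarray(w.oxygen, dtype=float)
            b1 = w.h1 - o
            b2 = w.h2 - o
            b1 = b1 / np.linalg.norm(b1)
            b2 = b2 / np.linalg.norm(b2)
            bis = b1 + b2
            bis /= np.linalg.norm(bis)
            for (cls_name, q, rl), p, lb in (
                (WATER_O, o, np.stack([b1, b2, -bis])),
                (WATER_H, np.asarray(w.h1, dtype=float), None),
                (WATER_H, np.asarray(w.h2, dtype=float), None),
            ):
                rh, ep = vdw_parameters(cls_name)
                pos.append(p)
                rmin_half.append(rh)
                eps.append(ep)
                charge.append(q)
                role.append(_ROLE_CODES[rl])
                lobes.append(lb)
        self.positions = np.asarray(pos, dtype=float).reshape(-1, 3)
        self.rmin_half = np.asarray(rmin_half, dtype=float)
        self.epsilon = np.asarray(eps, dtype=float)
        self.charge = np.asarray(charge, dtype=float)
        self.role = np.asarray(role, dtype=int)
        self.lobes = lobes
        # dense (N, 3, 3) lobe array for vectorized pair sums; atoms without
        # lobes are flagged and treated as isotropic
        n = len(self.positions)
        self.has_lobes = np.array([lb is not None for lb in lobes], dtype=bool)
        self.lobes_dense = np.zeros((n, 3, 3))
        for i, lb in enumerate(lobes):
            if lb is not None:
                k = lb.shape[0]
                self.lobes_dense[i, :k] = lb

    @staticmethod
    def _bond_lobe(atom: Atom, heavy_pos: np.ndarray) -> Optional[np.ndarray]:
        """Directional lobe for a polar heavy atom: away from its bonded parent.

        Hydrogens and lone pairs of an sp2/sp3 O or N point into the
        hemisphere opposite the covalent bond; restricting the H-bond term
        to that lobe stops spurious minima behind the residue.
        """
        if atom.hbond_role == "none" or not atom.is_heavy:
            return None
        d = np.linalg.norm(heavy_pos - atom.position, axis=1) if len(heavy_pos) else np.array([])
        nearby = (d > 1e-6) & (d <= 1.9)
        if not nearby.any():
            return None
        parent = heavy_pos[nearby][np.argmin(d[nearby])]
        lobe = atom.position - parent
        lobe = lobe / np.linalg.norm(lobe)
        return lobe.reshape(1, 3)

    @classmethod
    def from_complex(
        cls, complex: ReceptorComplex, include_waters: bool = True,
        extra_waters: Iterable[WaterMolecule] = (),
    ) -> "Environment":
        waters = list(complex.waters) if include_waters else []
        waters.extend(extra_waters)
        return cls(complex.environment_structures(), waters)

    def __len__(self) -> int:
        return len(self.positions)

    def content_hash(self) -> str:
        h = hashlib.md5()
        h.update(self.positions.tobytes())
        h.update(self.charge.tobytes())
        h.update(self.role.tobytes())
        return h.hexdigest()[:12]


# ---------------------------------------------------------------------------
# Pairwise energy evaluation
# ---------------------------------------------------------------------------

def _pair_terms(
    points: np.ndarray,
    env: Environment,
    probe: ProbeDefinition,
    include_lj: bool = True,
    include_elec: bool = True,
    include_hb: bool = True,
) -> np.ndarray:
    """Sum of probe-atom pair energies at each point (unclamped)."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    total = np.zeros(len(points))
    for i in range(len(env)):
        d = points - env.positions[i]
        r = np.linalg.norm(d, axis=1)
        r = np.maximum(r, 1e-6)
        if include_lj and probe.vdw_epsilon > 0:
            eps_ij = np.sqrt(probe.vdw_epsilon * env.epsilon[i])
            rmin_ij = probe.vdw_rmin / 2.0 + env.rmin_half[i]
            x6 = (rmin_ij / r) ** 6
            total += eps_ij * (x6 * x6 - 2.0 * x6)
        if include_elec and probe.charge != 0.0 and env.charge[i] != 0.0:
            total += COULOMB * probe.charge * env.charge[i] / (4.0 * r * r)
        if include_hb and probe.hbond_capable and env.role[i] != 0:
            xr = HB_R0 / r
            base = HB_DEPTH * (5.0 * xr**12 - 6.0 * xr**10)
            lb = env.lobes[i]
            if lb is None:
                factor = 1.0
            else:
                u = d / r[:, None]
                cosines = u @ lb.T
                factor = np.clip(cosines, 0.0, None).max(axis=1) ** 2
            total += base * factor
    return total


def probe_energy_at_points(
    points: np.ndarray, env: Environment, probe: ProbeDefinition | str
) -> np.ndarray:
    """Probe interaction energy at arbitrary points (kcal/mol, clamped).

    Handles the composite DRY recipe; for grids prefer compute_probe_field,
    which resolves burial on the lattice.
    """
    if isinstance(probe, str):
        probe = PROBES[probe]
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(env) == 0:
        return np.zeros(len(points))
    if probe.name == "DRY":
        values = _dry_energy_points(points, env)
    else:
        values = _pair_terms(points, env, probe)
    return np.minimum(values, ENERGY_CLAMP)


def _hb_water_component(points: np.ndarray, env: Environment) -> np.ndarray:
    """Attractive water-probe H-bond energy at each point (<= 0)."""
    hb = _pair_terms(points, env, PROBES["OH2"], include_lj=False, include_elec=False)
    return np.minimum(hb, 0.0)


_NEIGHBOR_OFFSETS = np.array(
    [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ],
    dtype=float,
)


def _dry_energy_points(points: np.ndarray, env: Environment, spacing: float = 0.5) -> np.ndarray:
    probe = PROBES["DRY"]
    lj = _pair_terms(points, env, probe, include_elec=False, include_hb=False)
    # burial: fraction of the 26 lattice neighbors that are sterically closed
    neigh = points[:, None, :] + spacing * _NEIGHBOR_OFFSETS[None, :, :]
    neigh_lj = _pair_terms(neigh.reshape(-1, 3), env, probe,
                           include_elec=False, include_hb=False).reshape(len(points), 26)
    buried = (neigh_lj >= BURIAL_LEVEL).sum(axis=1) >= 13
    hb = _hb_water_component(points, env)
    return lj + probe.entropy_reward * buried + DRY_HB_WEIGHT * np.abs(hb)


def compute_probe_field(
    environment: ReceptorComplex | Environment,
    probe: ProbeDefinition | str,
    grid: GridSpec,
) -> ScalarField:
    """Evaluate a probe field over a lattice.

    ``environment`` may be a prepared :class:`Environment` or a complex
    (receptor + ligand + any explicit waters).  Values are clamped at
    +100 kcal/mol so atom cores stay finite.
    """
    if isinstance(probe, str):
        probe = PROBES[probe]
    env = (
        environment
        if isinstance(environment, Environment)
        else Environment.from_complex(environment)
    )
    points = grid.points()
    if len(env) == 0:
        values = np.zeros(grid.n_points)
    elif probe.name == "DRY":
        values = _dry_energy_grid(points, env, grid)
    else:
        values = _pair_terms(points, env, probe)
    values = np.minimum(values, ENERGY_CLAMP)
    return ScalarField(grid=grid, values=values, probe=probe,
                       environment_hash=env.content_hash())


def _dry_energy_grid(points: np.ndarray, env: Environment, grid: GridSpec) -> np.ndarray:
    probe = PROBES["DRY"]
    lj = _pair_terms(points, env, probe, include_elec=False, include_hb=False)
    closed = (lj >= BURIAL_LEVEL).reshape(grid.shape).astype(float)
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    n_closed = ndimage.convolve(closed, kernel, mode="constant", cval=0.0)
    buried = (n_closed >= 13).ravel()
    hb = _hb_water_component(points, env)
    return lj + probe.entropy_reward * buried + DRY_HB_WEIGHT * np.abs(hb)


# ---------------------------------------------------------------------------
# Derived objects
# ---------------------------------------------------------------------------

def cry_field(c1_field: ScalarField, dry_field: ScalarField) -> ScalarField:
    """Composite CRY map: pointwise most favorable of C1= and DRY."""
    if c1_field.grid != dry_field.grid:
        raise ValueError("CRY requires identical grids for C1= and DRY")
    values = np.minimum(c1_field.values, dry_field.values)
    probe = ProbeDefinition("CRY", vdw_epsilon=0.0, vdw_rmin=0.0)
    return ScalarField(grid=c1_field.grid, values=values, probe=probe,
                       environment_hash=c1_field.environment_hash)


def cry_at_points(points: np.ndarray, env: Environment) -> np.ndarray:
    c1 = probe_energy_at_points(points, env, "C1=")
    dry = probe_energy_at_points(points, env, "DRY")
    return np.minimum(c1, dry)


def find_hotspots(field: ScalarField, threshold: float) -> list[Hotspot]:
    """Grid-local minima below threshold, deduplicated within 1.5 A.

    Minima over the 26-neighborhood; greedy non-maximum suppression keeps
    the deepest of any cluster closer than 1.5 A.  Sorted by energy.
    """
    v = field.values
    local_min = v <= ndimage.minimum_filter(v, size=3, mode="constant", cval=np.inf)
    mask = local_min & (v <= threshold)
    idx = np.argwhere(mask)
    if len(idx) == 0:
        return []
    energies = v[tuple(idx.T)]
    order = np.argsort(energies, kind="stable")
    idx = idx[order]
    energies = energies[order]
    positions = np.asarray(field.grid.origin) + field.grid.spacing * idx.astype(float)
    kept: list[Hotspot] = []
    kept_pos: list[np.ndarray] = []
    for p, e in zip(positions, energies):
        if any(np.linalg.norm(p - q) < 1.5 for q in kept_pos):
            continue
        kept.append(Hotspot(position=p, energy=float(e), probe=field.probe.name))
        kept_pos.append(p)
    return kept


def pocket_surface(c3_field: ScalarField, level: float = 1.0) -> np.ndarray:
    """Boolean accessibility mask: True where a ligand carbon can sit."""
    return c3_field.values < level
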