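"""Explicit water networks: placement, relaxation, scoring, comparison.

The protocol mirrors an iterative hotspot-filling scheme: water-probe
hotspots are computed for the current environment (receptor, ligand, and
every water placed so far), the best positions below an energy cutoff are
occupied, and the cutoff is raised step by step from -8 to -1 kcal/mol
until no further water fits.  The raw network is then relaxed by rigid-body
Metropolis Monte Carlo and each water near the ligand is rescored in full
context with the water (OH2) and lipophilic (CRY) probes:

    dG_est = (E_OH2,context - E_bulk) + lambda_lip * max(0, -E_CRY)

relative to a bulk reference calibrated on a jittered water box.  Scores
map onto the conventional four-color happiness scale (red above +3.5,
yellow to +2.0, grey to -1.0, blue below).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import networkx as nx
import numpy as np

from .mif import (
    COULOMB,
    ENERGY_CLAMP,
    HB_DEPTH,
    HB_R0,
    Environment,
    GridSpec,
    PROBES,
    ScalarField,
    cry_at_points,
    find_hotspots,
    probe_energy_at_points,
    _pair_terms,
)
from .structures import (
    MolecularStructure,
    ReceptorComplex,
    WaterMolecule,
    vdw_parameters,
)

__all__ = [
    "PlacementSchedule",
    "HydrationSiteScore",
    "ClassificationScheme",
    "WaterNetwork",
    "NetworkDiff",
    "calibrate_bulk_reference",
    "place_waters_iterative",
    "relax_network",
    "rescore_waters",
    "classify_waters",
    "hbond_graph",
    "compare_networks",
    "network_total_energy",
]

KB = 0.0019872041  # kcal/mol/K

#: Weight of the lipophilic (CRY) term in the water score.
LAMBDA_LIP = 0.5

_WATER_O_PARAMS = vdw_parameters("polar_O")
_WATER_H_PARAMS = vdw_parameters("hydrogen")
_Q_O, _Q_H = -0.834, 0.417


@dataclass(frozen=True)
class PlacementSchedule:
    initial_cutoff: float = -8.0   # kcal/mol
    final_cutoff: float = -1.0
    step: float = 1.0
    placement_radius: float = 10.0  # A from ligand (or pocket) centroid
    rescore_radius: float = 8.0
    clash_distance: float = 2.4

    def __post_init__(self) -> None:
        if not (self.initial_cutoff < self.final_cutoff < 0):
            raise ValueError("need initial_cutoff < final_cutoff < 0")
        if self.placement_radius <= 0 or self.rescore_radius <= 0:
            raise ValueError("radii must be positive")

    def cutoffs(self) -> np.ndarray:
        return np.arange(self.initial_cutoff, self.final_cutoff + 1e-9, self.step)


@dataclass
class HydrationSiteScore:
    water_index: int
    e_oh2_context: float
    e_cry: float
    delta_g_est: float
    class_label: Optional[str] = None


@dataclass(frozen=True)
class ClassificationScheme:
    red_above: float = 3.5
    yellow_above: float = 2.0
    grey_above: float = -1.0

    def __post_init__(self) -> None:
        if not (self.red_above > self.yellow_above > self.grey_above):
            raise ValueError("classification boundaries must be decreasing")

    def label(self, dg: float) -> str:
        if dg > self.red_above:
            return "red"
        if dg > self.yellow_above:
            return "yellow"
        if dg >= self.grey_above:
            return "grey"
        return "blue"


@dataclass
class WaterNetwork:
    waters: list[WaterMolecule] = field(default_factory=list)
    scores: list[HydrationSiteScore] = field(default_factory=list)
    bulk_reference: float = math.nan
    schedule: PlacementSchedule = field(default_factory=PlacementSchedule)

    def copy(self) -> "WaterNetwork":
        return WaterNetwork(
            waters=[w.copy() for w in self.waters],
            scores=[replace(s) for s in self.scores],
            bulk_reference=self.bulk_reference,
            schedule=self.schedule,
        )

    def oxygen_positions(self) -> np.ndarray:
        if not self.waters:
            return np.zeros((0, 3))
        return np.array([w.oxygen for w in self.waters])

    def score_for(self, index: int) -> Optional[HydrationSiteScore]:
        for s in self.scores:
            if s.water_index == index:
                return s
        return None

    def validate_clashes(self, complex: Optional[ReceptorComplex] = None) -> None:
        cd = self.schedule.clash_distance
        pos = self.oxygen_positions()
        if len(pos) > 1:
            d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() < cd - 1e-9:
                raise ValueError(f"water O-O clash: {d.min():.2f} A < {cd}")
        if complex is not None and len(pos):
            heavy = np.concatenate(
                [s.positions(heavy_only=True) for s in complex.environment_structures()]
            )
            d = np.linalg.norm(pos[:, None, :] - heavy[None, :, :], axis=-1)
            if d.min() < cd - 1e-9:
                raise ValueError(f"water-heavy clash: {d.min():.2f} A < {cd}")


# ---------------------------------------------------------------------------
# Explicit pair energies (shared by orientation search and MC relaxation)
# ---------------------------------------------------------------------------

def _water_arrays(waters: list[WaterMolecule]):
    """Site positions and directional lobes for a list of waters."""
    n = len(waters)
    o = np.zeros((n, 3)); h1 = np.zeros((n, 3)); h2 = np.zeros((n, 3))
    lobes = np.zeros((n, 3, 3))
    for i, w in enumerate(waters):
        o[i], h1[i], h2[i] = w.oxygen, w.h1, w.h2
        b1 = w.h1 - w.oxygen
        b2 = w.h2 - w.oxygen
        b1 /= np.linalg.norm(b1)
        b2 /= np.linalg.norm(b2)
        bis = b1 + b2
        bis /= np.linalg.norm(bis)
        lobes[i] = np.stack([b1, b2, -bis])
    return o, h1, h2, lobes


def _hb_radial(r: np.ndarray) -> np.ndarray:
    xr = HB_R0 / np.maximum(r, 1e-6)
    return HB_DEPTH * (5.0 * xr**12 - 6.0 * xr**10)


def _lobe_factor(lobes: np.ndarray, directions: np.ndarray) -> np.ndarray:
    """max over lobes of clipped cos^2 toward each unit direction (m,3)."""
    cosines = directions @ lobes.T
    return np.clip(cosines, 0.0, None).max(axis=1) ** 2


def _self_lobes(w: WaterMolecule) -> np.ndarray:
    b1 = w.h1 - w.oxygen
    b2 = w.h2 - w.oxygen
    b1 = b1 / np.linalg.norm(b1)
    b2 = b2 / np.linalg.norm(b2)
    bis = b1 + b2
    bis /= np.linalg.norm(bis)
    return np.stack([b1, b2, -bis])


def _env_lobe_factor(env: Environment, idx: np.ndarray, directions: np.ndarray) -> np.ndarray:
    """Angular factor of environment atoms ``idx`` toward unit ``directions``."""
    cos = np.einsum("mld,md->ml", env.lobes_dense[idx], directions)
    f = np.clip(cos, 0.0, None).max(axis=1) ** 2
    return np.where(env.has_lobes[idx], f, 1.0)


def water_env_energy(w: WaterMolecule, env: Environment, cutoff: float = 8.0) -> float:
    """Interaction of one water with a fixed typed environment (kcal/mol).

    LJ and screened Coulomb (eps_r = 4r) on all three sites, plus the
    directional 12-10 H-bond term between the water oxygen and the
    environment's donors/acceptors.  Environment waters carry their own
    lobes; the combined angular factor is the product of both sides.
    """
    if len(env) == 0:
        return 0.0
    d_o = env.positions - w.oxygen
    r_o = np.linalg.norm(d_o, axis=1)
    near = r_o <= cutoff
    if not near.any():
        return 0.0
    idx = np.where(near)[0]
    pos = env.positions[idx]
    r_o = np.maximum(r_o[idx], 1e-6)
    total = 0.0
    # LJ + Coulomb per site
    for site, q, (rh, ep) in (
        (w.oxygen, _Q_O, _WATER_O_PARAMS),
        (w.h1, _Q_H, _WATER_H_PARAMS),
        (w.h2, _Q_H, _WATER_H_PARAMS),
    ):
        d = pos - site
        r = np.maximum(np.linalg.norm(d, axis=1), 1e-6)
        eps_ij = np.sqrt(ep * env.epsilon[idx])
        rmin_ij = rh + env.rmin_half[idx]
        x6 = (rmin_ij / r) ** 6
        total += float(np.sum(eps_ij * (x6 * x6 - 2.0 * x6)))
        qq = q * env.charge[idx]
        total += float(np.sum(COULOMB * qq / (4.0 * r * r)))
    # directional H-bond term, O vs polar heavies
    polar = env.role[idx] != 0
    if polar.any():
        p_idx = idx[polar]
        d = env.positions[p_idx] - w.oxygen
        r = np.maximum(np.linalg.norm(d, axis=1), 1e-6)
        u = d / r[:, None]
        f_self = _lobe_factor(_self_lobes(w), u)
        f_env = _env_lobe_factor(env, p_idx, -u)
        total += float(np.sum(_hb_radial(r) * f_self * f_env))
    return min(total, ENERGY_CLAMP)


def _water_water_energies(
    w: WaterMolecule, o, h1, h2, lobes, mask: np.ndarray, cutoff: float = 8.0
) -> float:
    """Sum of pair energies between ``w`` and the masked waters."""
    if not mask.any():
        return 0.0
    d = o[mask] - w.oxygen
    r = np.linalg.norm(d, axis=1)
    near = r <= cutoff
    if not near.any():
        return 0.0
    sel = np.where(mask)[0][near]
    r = np.maximum(r[near], 1e-6)
    u = (o[sel] - w.oxygen) / r[:, None]
    rh_o, ep_o = _WATER_O_PARAMS
    x6 = ((2.0 * rh_o) / r) ** 6
    total = float(np.sum(ep_o * (x6 * x6 - 2.0 * x6)))
    # site-site Coulomb
    wl0 = _self_lobes(w)
    sites_a = np.stack([w.oxygen, w.h1, w.h2])
    q_a = np.array([_Q_O, _Q_H, _Q_H])
    sites_b = np.stack([o[sel], h1[sel], h2[sel]], axis=1)  # (m, 3 sites, 3)
    q_b = np.array([_Q_O, _Q_H, _Q_H])
    dd = sites_b[:, None, :, :] - sites_a[None, :, None, :]
    rr = np.maximum(np.linalg.norm(dd, axis=-1), 1e-6)  # (m, 3, 3)
    qq = q_a[None, :, None] * q_b[None, None, :]
    total += float(np.sum(COULOMB * qq / (4.0 * rr * rr)))
    # H-bond with both-sides angular factor
    f_a = _lobe_factor(wl0, u)
    cos_b = np.einsum("mld,md->ml", lobes[sel], -u)
    f_b = np.clip(cos_b, 0.0, None).max(axis=1) ** 2
    total += float(np.sum(_hb_radial(r) * f_a * f_b))
    return min(total, ENERGY_CLAMP)


def network_total_energy(
    complex: ReceptorComplex,
    network: WaterNetwork,
    ligand: Optional[MolecularStructure] = None,
) -> float:
    """Total explicit-pair energy of the network (plus mobile-ligand terms).

    Waters against receptor+ligand, all water-water pairs, and — when a
    ligand structure is passed — its interaction with the receptor.  The
    same function drives the Metropolis acceptance in relax_network.
    """
    ligand = ligand if ligand is not None else complex.ligand
    receptor_env = Environment([complex.receptor])
    ligand_env = Environment([ligand]) if ligand is not None else None
    waters = network.waters
    o, h1, h2, lobes = _water_arrays(waters) if waters else (None,) * 4
    total = 0.0
    for i, w in enumerate(waters):
        total += water_env_energy(w, receptor_env)
        if ligand_env is not None:
            total += water_env_energy(w, ligand_env)
        mask = np.zeros(len(waters), dtype=bool)
        mask[i + 1 :] = True
        total += _water_water_energies(w, o, h1, h2, lobes, mask)
    if ligand is not None:
        total += _structure_env_energy(ligand, receptor_env)
    return total


def _structure_env_energy(struct: MolecularStructure, env: Environment) -> float:
    """Rigid structure vs environment: LJ + screened Coulomb + radial H-bond."""
    if len(env) == 0 or not struct.atoms:
        return 0.0
    total = 0.0
    for a in struct.atoms:
        rh, ep = vdw_parameters(a.vdw_class)
        d = env.positions - a.position
        r = np.maximum(np.linalg.norm(d, axis=1), 1e-6)
        sel = r <= 10.0
        if not sel.any():
            continue
        r = r[sel]
        eps_ij = np.sqrt(ep * env.epsilon[sel])
        rmin_ij = rh + env.rmin_half[sel]
        x6 = (rmin_ij / r) ** 6
        total += float(np.sum(eps_ij * (x6 * x6 - 2.0 * x6)))
        total += float(np.sum(COULOMB * a.partial_charge * env.charge[sel] / (4.0 * r * r)))
        if a.hbond_role != "none":
            a_donor = a.hbond_role in ("donor", "both")
            a_acc = a.hbond_role in ("acceptor", "both")
            roles = env.role[sel]
            compatible = (
                (a_donor & np.isin(roles, (2, 3))) | (a_acc & np.isin(roles, (1, 3)))
            )
            if compatible.any():
                rr = r[compatible]
                # environment waters modulate with their lobes
                u = (d[sel][compatible]) / rr[:, None]
                env_idx = np.where(sel)[0][compatible]
                f_env = np.ones(len(env_idx))
                for k, j in enumerate(env_idx):
                    lb = env.lobes[j]
                    if lb is not None:
                        f_env[k] = _lobe_factor(lb, (-u[k]).reshape(1, 3))[0]
                total += float(np.sum(_hb_radial(rr) * f_env))
    return total


# ---------------------------------------------------------------------------
# Bulk calibration
# ---------------------------------------------------------------------------

def calibrate_bulk_reference(box: list[WaterMolecule]) -> float:
    """Mean in-context OH2 probe energy over interior bulk waters.

    Interior = oxygens at least 4 A from every face of the box's bounding
    cube; each is scored against all other waters.  This is the zero point
    of the happiness scale.
    """
    if not box:
        raise ValueError("empty bulk box")
    pos = np.array([w.oxygen for w in box])
    lo = pos.min(axis=0)
    hi = pos.max(axis=0)
    interior = np.where(
        np.all((pos >= lo + 4.0) & (pos <= hi - 4.0), axis=1)
    )[0]
    if len(interior) < 20:
        raise ValueError(
            f"only {len(interior)} interior waters; use a bigger box (edge >= ~21 A)"
        )
    energies = []
    for i in interior:
        others = [w for j, w in enumerate(box) if j != i]
        env = Environment([], others)
        e = probe_energy_at_points(box[i].oxygen.reshape(1, 3), env, "OH2")[0]
        energies.append(e)
    return float(np.mean(energies))


# ---------------------------------------------------------------------------
# Iterative placement
# ---------------------------------------------------------------------------

_ORIENT_AXES = None


def _orientation_trials() -> list[tuple[np.ndarray, float]]:
    """60 deterministic trial orientations (20 bisector axes x 3 twists)."""
    global _ORIENT_AXES
    if _ORIENT_AXES is None:
        from .fixtures import _fibonacci_sphere

        axes = _fibonacci_sphere(20)
        _ORIENT_AXES = [
            (axes[i], t) for i in range(20) for t in (0.0, 2.0 * math.pi / 3, 4.0 * math.pi / 3)
        ]
    return _ORIENT_AXES


def _orient_water(position: np.ndarray, context: Environment) -> WaterMolecule:
    """Pick the rigid-water orientation minimizing the explicit pair energy."""
    best = None
    best_e = np.inf
    for axis, twist in _orientation_trials():
        w = WaterMolecule.from_orientation(position, axis, twist)
        e = water_env_energy(w, context, cutoff=6.0)
        if e < best_e:
            best_e, best = e, (axis, twist)
    axis, twist = best
    # greedy refinement around the best trial
    w_best = WaterMolecule.from_orientation(position, axis, twist)
    deltas = [np.array(v, dtype=float) for v in
              ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))]
    for _round in range(2):
        improved = False
        for dax in deltas:
            for dtw in (-0.17, 0.0, 0.17):
                new_axis = axis + 0.18 * dax
                w_try = WaterMolecule.from_orientation(position, new_axis, twist + dtw)
                e = water_env_energy(w_try, context, cutoff=6.0)
                if e < best_e - 1e-9:
                    best_e, axis, twist, w_best = e, new_axis, twist + dtw, w_try
                    improved = True
        if not improved:
            break
    return w_best


def place_waters_iterative(
    environment: ReceptorComplex,
    schedule: PlacementSchedule,
    center: np.ndarray,
    grid_spacing: float = 0.5,
    max_rounds: int = 200,
) -> WaterNetwork:
    """Fill the site with waters by iterated OH2 hotspot placement.

    The cutoff is raised level by level from the initial to the final
    value; at each level hotspots of the current field (environment plus
    all placed waters) are occupied in order of increasing energy,
    skipping clashes, and the field is updated after every placement.
    A level ends when it adds nothing; the run ends after the final level.
    """
    center = np.asarray(center, dtype=float)
    env0 = Environment.from_complex(environment)
    grid = GridSpec.cube(center, schedule.placement_radius + 2.0, grid_spacing)
    points = grid.points()
    base = (
        _pair_terms(points, env0, PROBES["OH2"]) if len(env0) else np.zeros(len(points))
    )
    heavy = [
        s.positions(heavy_only=True) for s in environment.environment_structures()
    ]
    heavy = np.concatenate([h for h in heavy if len(h)] or [np.zeros((0, 3))])
    existing_o = [w.oxygen for w in environment.waters]
    field_values = base.copy()
    placed: list[WaterMolecule] = []
    rounds = 0
    in_range = np.linalg.norm(points - center, axis=1) <= schedule.placement_radius
    for cutoff in schedule.cutoffs():
        while True:
            rounds += 1
            if rounds > max_rounds:
                raise RuntimeError(
                    f"water placement did not converge within {max_rounds} rounds "
                    f"(cutoff {cutoff:.1f}, {len(placed)} waters placed)"
                )
            masked = np.where(in_range, field_values, np.inf)
            fld = ScalarField(grid=grid, values=np.minimum(masked, ENERGY_CLAMP),
                              probe=PROBES["OH2"])
            spots = find_hotspots(fld, cutoff)
            added = 0
            for h in spots:
                blockers = [heavy] + [np.asarray(existing_o).reshape(-1, 3)] if existing_o else [heavy]
                blockers.append(np.array([w.oxygen for w in placed]).reshape(-1, 3)
                                if placed else np.zeros((0, 3)))
                all_block = np.concatenate([b for b in blockers if len(b)] or [np.zeros((0, 3))])
                if len(all_block) and np.linalg.norm(all_block - h.position, axis=1).min() < schedule.clash_distance:
                    continue
                context = Environment.from_complex(environment, extra_waters=placed)
                w = _orient_water(h.position, context)
                w.placement_iteration = rounds
                w.placement_energy = float(h.energy)
                placed.append(w)
                contrib = _pair_terms(points, Environment([], [w]), PROBES["OH2"])
                field_values = field_values + contrib
                added += 1
            if added == 0:
                break
    net = WaterNetwork(waters=placed, schedule=schedule)
    net.validate_clashes(environment)
    return net


# ---------------------------------------------------------------------------
# Monte-Carlo relaxation
# ---------------------------------------------------------------------------

def relax_network(
    complex: ReceptorComplex,
    network: WaterNetwork,
    n_sweeps: int,
    mobile_ligand: bool = False,
    temperature: float = 300.0,
    seed: int = 0,
) -> tuple[WaterNetwork, Optional[MolecularStructure]]:
    """Metropolis relaxation with rigid-body water (and optional ligand) moves.

    Waters translate up to 0.2 A and rotate up to 15 degrees per attempt;
    the ligand, when mobile, translates up to 0.1 A and rotates up to
    5 degrees about its centroid while the receptor stays fixed.  Moves
    that put a water oxygen within the clash distance of any heavy atom
    are rejected outright.  Returns the relaxed network and the (possibly
    displaced) ligand.
    """
    if n_sweeps < 0:
        raise ValueError("n_sweeps must be >= 0")
    if not network.waters and not mobile_ligand:
        return network.copy(), (complex.ligand.copy() if complex.ligand else None)
    out = network.copy()
    ligand = complex.ligand.copy() if complex.ligand is not None else None
    if n_sweeps == 0:
        return out, ligand
    rng = np.random.default_rng(seed)
    beta = 1.0 / (KB * temperature)
    receptor_env = Environment([complex.receptor])
    receptor_heavy = complex.receptor.positions(heavy_only=True)
    cd = network.schedule.clash_distance
    waters = out.waters
    o, h1, h2, lobes = _water_arrays(waters) if waters else (
        np.zeros((0, 3)), np.zeros((0, 3)), np.zeros((0, 3)), np.zeros((0, 3, 3)))

    def ligand_env() -> Optional[Environment]:
        return Environment([ligand]) if ligand is not None else None

    lig_env = ligand_env()
    lig_heavy = ligand.positions(heavy_only=True) if ligand is not None else np.zeros((0, 3))

    def water_energy(i: int, w: WaterMolecule) -> float:
        e = water_env_energy(w, receptor_env)
        if lig_env is not None:
            e += water_env_energy(w, lig_env)
        mask = np.ones(len(waters), dtype=bool)
        mask[i] = False
        e += _water_water_energies(w, o, h1, h2, lobes, mask)
        return e

    def ligand_energy(struct: MolecularStructure) -> float:
        e = _structure_env_energy(struct, receptor_env)
        env_l = Environment([struct])
        for w in waters:
            e += water_env_energy(w, env_l)
        return e

    for _sweep in range(n_sweeps):
        for i in range(len(waters)):
            w = waters[i]
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            trans = direction * rng.uniform(0.0, 0.2)
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            angle = rng.uniform(-math.radians(15.0), math.radians(15.0))
            rot = _rotation_matrix(axis, angle)
            w_new = w.transformed(rot, trans)
            new_o = w_new.oxygen
            blockers = [receptor_heavy, lig_heavy, np.delete(o, i, axis=0)]
            blockers = np.concatenate([b for b in blockers if len(b)] or [np.zeros((0, 3))])
            if len(blockers) and np.linalg.norm(blockers - new_o, axis=1).min() < cd:
                continue
            de = water_energy(i, w_new) - water_energy(i, w)
            if de <= 0 or rng.random() < math.exp(-beta * de):
                waters[i] = w_new
                o[i], h1[i], h2[i] = w_new.oxygen, w_new.h1, w_new.h2
                _, _, _, lb = _water_arrays([w_new])
                lobes[i] = lb[0]
        if mobile_ligand and ligand is not None:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            trans = direction * rng.uniform(0.0, 0.1)
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            angle = rng.uniform(-math.radians(5.0), math.radians(5.0))
            rot = _rotation_matrix(axis, angle)
            trial = ligand.copy()
            centroid = trial.positions().mean(axis=0)
            for a in trial.atoms:
                a.position = centroid + rot @ (a.position - centroid) + trans
            t_heavy = trial.positions(heavy_only=True)
            if len(o) and len(t_heavy):
                if np.linalg.norm(o[:, None, :] - t_heavy[None, :, :], axis=-1).min() < cd:
                    continue
            de = ligand_energy(trial) - ligand_energy(ligand)
            if de <= 0 or rng.random() < math.exp(-beta * de):
                ligand = trial
                lig_env = ligand_env()
                lig_heavy = ligand.positions(heavy_only=True)
    out.waters = waters
    out.validate_clashes(ReceptorComplex(receptor=complex.receptor, ligand=ligand))
    return out, ligand


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    x, y, z = axis
    return np.array([
        [c + x * x * (1 - c), x * y * (1 - c) - z * s, x * z * (1 - c) + y * s],
        [y * x * (1 - c) + z * s, c + y * y * (1 - c), y * z * (1 - c) - x * s],
        [z * x * (1 - c) - y * s, z * y * (1 - c) + x * s, c + z * z * (1 - c)],
    ])


# ---------------------------------------------------------------------------
# Scoring / classification / comparison
# ---------------------------------------------------------------------------

def rescore_waters(
    complex: ReceptorComplex,
    network: WaterNetwork,
    bulk_reference: float,
    lambda_lip: float = LAMBDA_LIP,
) -> WaterNetwork:
    """Score every water within the rescore radius of the ligand.

    e_oh2_context: OH2 probe at the oxygen with the full environment
    (receptor, ligand, every other network water); e_cry: CRY value there
    with receptor+ligand only; dG_est combines both against bulk.
    Waters beyond the radius carry no score.
    """
    if not np.isfinite(bulk_reference):
        raise ValueError("bulk reference not calibrated")
    out = network.copy()
    out.bulk_reference = float(bulk_reference)
    if complex.ligand is not None and complex.ligand.atoms:
        center = complex.ligand.positions(heavy_only=True).mean(axis=0)
    elif out.waters:
        center = out.oxygen_positions().mean(axis=0)
    else:
        center = complex.receptor.positions().mean(axis=0)
    env_static = Environment.from_complex(complex, include_waters=False)
    out.scores = []
    for i, w in enumerate(out.waters):
        if np.linalg.norm(w.oxygen - center) > network.schedule.rescore_radius:
            continue
        others = [x for j, x in enumerate(out.waters) if j != i] + list(complex.waters)
        env_full = Environment.from_complex(complex, include_waters=False,
                                            extra_waters=others)
        e_oh2 = float(probe_energy_at_points(w.oxygen.reshape(1, 3), env_full, "OH2")[0])
        e_cry = float(cry_at_points(w.oxygen.reshape(1, 3), env_static)[0])
        dg = (e_oh2 - bulk_reference) + lambda_lip * max(0.0, -e_cry)
        out.scores.append(
            HydrationSiteScore(water_index=i, e_oh2_context=e_oh2, e_cry=e_cry,
                               delta_g_est=dg)
        )
    return out


def classify_waters(
    network: WaterNetwork, scheme: ClassificationScheme = ClassificationScheme()
) -> WaterNetwork:
    """Attach the four-color class label to every scored water."""
    if network.waters and not network.scores:
        raise ValueError("network has no scores; run rescore_waters first")
    out = network.copy()
    for s in out.scores:
        s.class_label = scheme.label(s.delta_g_est)
    return out


def hbond_graph(complex: ReceptorComplex, network: WaterNetwork) -> nx.Graph:
    """Hydrogen-bond graph over waters and polar receptor/ligand atoms.

    Edge criterion: donor-acceptor heavy distance <= 3.5 A and, where the
    donor has explicit hydrogens (waters), a D-H...A angle >= 120 degrees.
    Receptor donors carry no explicit H and pass on distance alone.
    """
    g = nx.Graph()
    waters = network.waters
    for i in range(len(waters)):
        g.add_node(("water", i))
    polar_atoms = [
        a
        for s in complex.environment_structures()
        for a in s.atoms
        if a.hbond_role != "none" and a.is_heavy
    ]
    for a in polar_atoms:
        g.add_node(("atom", a.serial))

    def dha_ok(donor_o, hs, acceptor) -> bool:
        for h in hs:
            v1 = donor_o - h
            v2 = acceptor - h
            c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            if math.degrees(math.acos(float(np.clip(c, -1, 1)))) >= 120.0:
                return True
        return False

    for i, wi in enumerate(waters):
        for j in range(i + 1, len(waters)):
            wj = waters[j]
            d = float(np.linalg.norm(wi.oxygen - wj.oxygen))
            if d > 3.5:
                continue
            if dha_ok(wi.oxygen, (wi.h1, wi.h2), wj.oxygen) or dha_ok(
                wj.oxygen, (wj.h1, wj.h2), wi.oxygen
            ):
                g.add_edge(("water", i), ("water", j), distance=d)
        for a in polar_atoms:
            d = float(np.linalg.norm(wi.oxygen - a.position))
            if d > 3.5:
                continue
            acceptor_side = a.hbond_role in ("acceptor", "both")
            donor_side = a.hbond_role in ("donor", "both")
            ok = False
            if acceptor_side and dha_ok(wi.oxygen, (wi.h1, wi.h2), a.position):
                ok = True
            if not ok and donor_side:
                ok = True  # no explicit H on the environment donor
            if ok:
                g.add_edge(("water", i), ("atom", a.serial), distance=d)
    nx.set_node_attributes(g, dict(g.degree()), "degree")
    return g


@dataclass
class NetworkDiff:
    gained: list[int]                 # indices in network b
    lost: list[int]                   # indices in network a
    reclassified: list[tuple[int, int, str, str]]  # (ia, ib, label_a, label_b)
    delta_sum_dg: float               # region-restricted sum(b) - sum(a)
    matched: list[tuple[int, int, float]]


def compare_networks(
    a: WaterNetwork,
    b: WaterNetwork,
    region: tuple[np.ndarray, float],
) -> NetworkDiff:
    """Greedy O-O matching (<= 1.0 A) between two scored networks."""
    if (a.waters and not a.scores) or (b.waters and not b.scores):
        raise ValueError("both networks must be scored before comparison")
    center, radius = np.asarray(region[0], dtype=float), float(region[1])
    pa = a.oxygen_positions()
    pb = b.oxygen_positions()
    pairs = []
    for i in range(len(pa)):
        for j in range(len(pb)):
            d = float(np.linalg.norm(pa[i] - pb[j]))
            if d <= 1.0:
                pairs.append((d, i, j))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched = []
    for d, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched.append((i, j, d))
    lost = [i for i in range(len(pa)) if i not in used_a]
    gained = [j for j in range(len(pb)) if j not in used_b]
    reclassified = []
    for i, j, _d in matched:
        sa, sb = a.score_for(i), b.score_for(j)
        if sa and sb and sa.class_label and sb.class_label and sa.class_label != sb.class_label:
            reclassified.append((i, j, sa.class_label, sb.class_label))

    def region_sum(net: WaterNetwork) -> float:
        total = 0.0
        for s in net.scores:
            if np.linalg.norm(net.waters[s.water_index].oxygen - center) <= radius:
                total += s.delta_g_est
        return total

    return NetworkDiff(
        gained=gained,
        lost=lost,
        reclassified=reclassified,
        delta_sum_dg=region_sum(b) - region_sum(a),
        matched=matched,
    )
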