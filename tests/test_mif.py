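"""Probe interaction fields: oracle equivalence, hotspots, CRY, surface."""

import numpy as np
import pytest

from hydrosite import mif
from hydrosite.structures import (
    Atom,
    MolecularStructure,
    ReceptorComplex,
    assign_atom_types,
    make_pseudo_apo,
)

from helpers import naive_probe_energy


def _small_environment(scenario, n_atoms=17, n_waters=1):
    """A <=20-atom slice of the scenario receptor plus a water."""
    atoms = [a.copy() for a in scenario["with_methyl"].receptor.atoms[:n_atoms]]
    rec = MolecularStructure(atoms=atoms)
    assign_atom_types(rec)
    from hydrosite.fixtures import make_bulk_box

    waters = make_bulk_box(15.0, seed=2)[:n_waters]
    center = rec.positions().mean(axis=0)
    for w in waters:
        shift = center - w.oxygen + np.array([3.5, 0.5, -0.5])
        w.oxygen = w.oxygen + shift
        w.h1 = w.h1 + shift
        w.h2 = w.h2 + shift
    return mif.Environment([rec], waters)


@pytest.mark.parametrize("probe_name", ["OH2", "C1=", "C3"])
def test_field_matches_naive_double_loop(scenario, probe_name):
    """Vectorized field equals a plain-loop oracle to 1e-9 kcal/mol."""
    env = _small_environment(scenario)
    probe = mif.PROBES[probe_name]
    grid = mif.GridSpec.cube(env.positions.mean(axis=0), 2.0, 0.45)
    assert grid.n_points <= 1000
    field = mif.compute_probe_field(env, probe, grid)
    pts = grid.points()
    for idx in range(0, grid.n_points, 37):
        expected = naive_probe_energy(pts[idx], env, probe)
        assert abs(field.values.ravel()[idx] - expected) <= 1e-9


def test_single_neutral_atom_closed_form():
    rec = MolecularStructure(atoms=[Atom(1, "CA", "C", "SHL", 1, "A", np.zeros(3))])
    assign_atom_types(rec)
    env = mif.Environment([rec])
    probe = mif.PROBES["C3"]
    r = 4.3
    value = mif.probe_energy_at_points(np.array([[r, 0.0, 0.0]]), env, probe)[0]
    eps = np.sqrt(probe.vdw_epsilon * 0.10)
    rmin = probe.vdw_rmin / 2.0 + 2.00
    expected = eps * ((rmin / r) ** 12 - 2.0 * (rmin / r) ** 6)
    assert abs(value - expected) < 1e-9


def test_rigid_rotation_invariance(scenario):
    """Rotating environment and sample points together changes nothing."""
    positions = _small_environment(scenario, n_atoms=10, n_waters=0).positions
    probe = mif.PROBES["OH2"]
    pts = positions.mean(axis=0) + np.array(
        [[3.0, 0.0, 0.0], [0.0, 4.0, 1.0], [-2.0, 2.0, 2.0]]
    )
    theta = 0.731
    rot = np.array([
        [np.cos(theta), -np.sin(theta), 0.0],
        [np.sin(theta), np.cos(theta), 0.0],
        [0.0, 0.0, 1.0],
    ])

    def carbon_env(coords):
        rec = MolecularStructure(atoms=[
            Atom(i + 1, "CA", "C", "SHL", i + 1, "A", p)
            for i, p in enumerate(coords)
        ])
        assign_atom_types(rec)
        return mif.Environment([rec])

    before = mif.probe_energy_at_points(pts, carbon_env(positions), probe)
    after = mif.probe_energy_at_points(
        pts @ rot.T, carbon_env(positions @ rot.T), probe
    )
    assert np.abs(before - after).max() < 1e-6


def test_empty_environment_gives_zero_field():
    env = mif.Environment([])
    grid = mif.GridSpec.cube(np.zeros(3), 2.0, 1.0)
    field = mif.compute_probe_field(env, "OH2", grid)
    assert np.all(field.values == 0.0)


def test_deleting_attractive_atom_never_deepens_lj_field():
    atoms = [
        Atom(i + 1, "CA", "C", "SHL", i + 1, "A", np.array(p))
        for i, p in enumerate([(0, 0, 0), (4, 0, 0), (0, 4, 0), (2, 2, 3)])
    ]
    rec = MolecularStructure(atoms=atoms)
    assign_atom_types(rec)
    grid = mif.GridSpec.cube(np.array([1.5, 1.5, 1.0]), 4.0, 0.8)
    full = mif.compute_probe_field(mif.Environment([rec]), "C3", grid)
    rec2 = MolecularStructure(atoms=[a.copy() for a in atoms[:-1]])
    assign_atom_types(rec2)
    reduced = mif.compute_probe_field(mif.Environment([rec2]), "C3", grid)
    # only where the removed atom was in its attractive regime (beyond the
    # pair rmin) — removing a repulsive core legitimately deepens the field
    pair_rmin = mif.PROBES["C3"].vdw_rmin / 2.0 + 2.00
    dist = np.linalg.norm(grid.points() - atoms[-1].position, axis=1)
    attractive = (dist > pair_rmin).reshape(grid.shape)
    clamp_free = full.values < mif.ENERGY_CLAMP
    mask = attractive & clamp_free
    assert np.all(reduced.values[mask] >= full.values[mask] - 1e-9)


def test_cry_is_pointwise_minimum(cavity21):
    complex, sites = cavity21
    env = mif.Environment.from_complex(complex)
    lipo = next(s for s in sites if s.character == "lipophilic")
    grid = mif.GridSpec.cube(lipo.position, 4.0, 0.5)
    c1 = mif.compute_probe_field(env, "C1=", grid)
    dry = mif.compute_probe_field(env, "DRY", grid)
    cry = mif.cry_field(c1, dry)
    assert np.array_equal(cry.values, np.minimum(c1.values, dry.values))
    assert np.all(cry.values <= c1.values)
    assert cry.probe.name == "CRY"
    same = mif.cry_field(c1, c1)
    assert np.array_equal(same.values, c1.values)
    other_grid = mif.GridSpec.cube(lipo.position, 4.0, 0.55)
    with pytest.raises(ValueError):
        mif.cry_field(c1, mif.compute_probe_field(env, "DRY", other_grid))


def test_hotspots_empty_for_flat_field():
    grid = mif.GridSpec.cube(np.zeros(3), 2.0, 1.0)
    flat = mif.ScalarField(grid=grid, values=np.zeros(grid.shape),
                           probe=mif.PROBES["C1="])
    assert mif.find_hotspots(flat, -2.7) == []


def test_hotspot_suppression_keeps_deepest_within_1_5A():
    grid = mif.GridSpec(origin=(0.0, 0.0, 0.0), spacing=0.5, shape=(9, 5, 5))
    values = np.zeros(grid.shape)
    values[2, 2, 2] = -5.0   # at x=1.0
    values[4, 2, 2] = -3.0   # at x=2.0, 1.0 A away -> suppressed
    values[8, 2, 2] = -4.0   # at x=4.0, own hotspot
    field = mif.ScalarField(grid=grid, values=values, probe=mif.PROBES["C1="])
    spots = mif.find_hotspots(field, -2.0)
    assert len(spots) == 2
    assert spots[0].energy == -5.0 and spots[1].energy == -4.0
    assert [s.energy for s in spots] == sorted(s.energy for s in spots)


def test_pocket_surface_inside_atom_and_cavity(cavity21):
    complex, _ = cavity21
    env = mif.Environment.from_complex(complex)
    grid = mif.GridSpec.cube(np.zeros(3), 10.0, 0.5)
    c3 = mif.compute_probe_field(env, "C3", grid)
    mask = mif.pocket_surface(c3, 1.0)
    center_idx = tuple(n // 2 for n in grid.shape)
    assert mask[center_idx]  # cavity center is accessible
    atom = complex.receptor.atoms[0].position
    ijk = tuple(
        int(round((atom[k] - grid.origin[k]) / grid.spacing)) for k in range(3)
    )
    if all(0 <= ijk[k] < grid.shape[k] for k in range(3)):
        assert not mask[ijk]


def test_pseudo_apo_pocket_volume_exceeds_holo(scenario):
    holo = scenario["with_methyl"]
    apo = make_pseudo_apo(holo)
    center = holo.ligand.positions(heavy_only=True).mean(axis=0)
    grid = mif.GridSpec.cube(center, 6.0, 0.5)
    v_holo = mif.pocket_surface(
        mif.compute_probe_field(mif.Environment.from_complex(holo), "C3", grid)
    ).sum()
    v_apo = mif.pocket_surface(
        mif.compute_probe_field(mif.Environment.from_complex(apo), "C3", grid)
    ).sum()
    assert v_apo > v_holo


def test_untyped_atoms_rejected():
    rec = MolecularStructure(atoms=[Atom(1, "CA", "C", "SHL", 1, "A", np.zeros(3))])
    with pytest.raises(ValueError, match="untyped"):
        mif.Environment([rec])


def test_dx_export_round_numbers(tmp_path):
    grid = mif.GridSpec.cube(np.zeros(3), 1.0, 1.0)
    field = mif.ScalarField(grid=grid, values=np.arange(grid.n_points, dtype=float),
                            probe=mif.PROBES["C3"])
    path = tmp_path / "f.dx"
    field.to_dx(path)
    text = path.read_text()
    assert f"items {grid.n_points}" in text
    data = [float(x) for line in text.splitlines()
            if line and line[0] in "0123456789-."
            for x in line.split()]
    # last data value round-trips
    assert max(data) == grid.n_points - 1
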