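"""Water network placement, relaxation, scoring and comparison."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hydrosite import fixtures, waternet
from hydrosite.structures import (
    MolecularStructure,
    ReceptorComplex,
    WaterMolecule,
)
from hydrosite.waternet import (
    ClassificationScheme,
    NetworkDiff,
    PlacementSchedule,
    WaterNetwork,
    calibrate_bulk_reference,
    classify_waters,
    compare_networks,
    hbond_graph,
    network_total_energy,
    place_waters_iterative,
    relax_network,
    rescore_waters,
)

from helpers import brute_force_hbond_pairs


def test_schedule_defaults_echo_protocol():
    s = PlacementSchedule()
    assert (s.initial_cutoff, s.final_cutoff) == (-8.0, -1.0)
    assert s.placement_radius == 10.0 and s.rescore_radius == 8.0
    assert s.clash_distance == 2.4
    with pytest.raises(ValueError):
        PlacementSchedule(initial_cutoff=-1.0, final_cutoff=-8.0)


def test_classification_boundaries():
    scheme = ClassificationScheme()
    assert scheme.label(4.0) == "red"
    assert scheme.label(3.5) == "yellow"   # red is strictly above 3.5
    assert scheme.label(3.0) == "yellow"
    assert scheme.label(0.0) == "grey"
    assert scheme.label(-1.0) == "grey"
    assert scheme.label(-1.01) == "blue"
    with pytest.raises(ValueError):
        ClassificationScheme(red_above=1.0, yellow_above=2.0)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.floats(min_value=-50, max_value=50, allow_nan=False))
def test_classification_partitions_the_line(dg):
    """Every value maps to exactly one of the four classes."""
    scheme = ClassificationScheme()
    label = scheme.label(dg)
    assert label in {"red", "yellow", "grey", "blue"}
    if label == "red":
        assert dg > 3.5
    elif label == "yellow":
        assert 2.0 < dg <= 3.5
    elif label == "grey":
        assert -1.0 <= dg <= 2.0
    else:
        assert dg < -1.0


def test_bulk_reference_is_negative_and_stable(bulk_box, bulk_reference):
    assert bulk_reference < 0
    assert calibrate_bulk_reference(bulk_box) == bulk_reference  # deterministic
    bigger = fixtures.make_bulk_box(24.0, seed=2)
    assert abs(calibrate_bulk_reference(bigger) - bulk_reference) < 0.3


def test_bulk_reference_needs_interior_waters():
    small = fixtures.make_bulk_box(14.0, seed=1)
    with pytest.raises(ValueError, match="interior"):
        calibrate_bulk_reference(small)


def test_placement_empty_when_no_favorable_site():
    empty = ReceptorComplex(receptor=MolecularStructure(atoms=[]))
    net = place_waters_iterative(empty, PlacementSchedule(), np.zeros(3))
    assert net.waters == []


def test_placement_recovers_planted_polar_sites(holo_apo_pair, holo_apo_networks):
    _, _, sites = holo_apo_pair
    _, net_apo = holo_apo_networks
    for site in sites:
        if site.character != "polar":
            continue
        d = np.linalg.norm(net_apo.oxygen_positions() - site.position, axis=1)
        assert d.min() <= 0.75
    assert len(net_apo.waters) >= 3


def test_placement_energies_respect_cutoffs(holo_apo_networks):
    net_holo, _ = holo_apo_networks
    for w in net_holo.waters:
        assert w.placement_energy <= net_holo.schedule.final_cutoff + 1e-9
        assert w.placement_iteration >= 1
    net_holo.validate_clashes()


def test_relax_zero_sweeps_is_identity(scenario, scenario_networks):
    holo = scenario["with_methyl"]
    net = scenario_networks["with_methyl"]
    out, lig = relax_network(holo, net, 0, mobile_ligand=True, seed=1)
    assert all(
        np.array_equal(a.oxygen, b.oxygen) for a, b in zip(out.waters, net.waters)
    )
    assert np.array_equal(
        lig.positions(), holo.ligand.positions()
    )
    with pytest.raises(ValueError):
        relax_network(holo, net, -1)


def test_relax_reduces_energy_of_scrambled_orientations(scenario, scenario_networks):
    """From randomized hydrogen orientations, MC relaxation lowers the
    total pair energy (mean over seeds)."""
    holo = scenario["with_methyl"]
    base = scenario_networks["with_methyl"]
    rng = np.random.default_rng(0)
    scrambled = base.copy()
    scrambled.waters = [
        WaterMolecule.from_orientation(w.oxygen, rng.normal(size=3),
                                       rng.uniform(0, 2 * math.pi))
        for w in base.waters
    ]
    e0 = network_total_energy(holo, scrambled)
    drops = []
    for seed in range(1, 6):
        relaxed, _ = relax_network(holo, scrambled, 25, seed=seed)
        drops.append(network_total_energy(holo, relaxed) - e0)
    assert np.mean(drops) < 0


def test_relax_is_reproducible_per_seed(scenario, scenario_networks):
    holo = scenario["with_methyl"]
    net = scenario_networks["with_methyl"]
    a, _ = relax_network(holo, net, 10, seed=42)
    b, _ = relax_network(holo, net, 10, seed=42)
    assert all(np.array_equal(x.oxygen, y.oxygen) for x, y in zip(a.waters, b.waters))


def test_rescore_bulk_waters_near_zero(bulk_box, bulk_reference):
    """Scoring bulk waters against the bulk reference gives dG ~ 0."""
    empty = ReceptorComplex(receptor=MolecularStructure(atoms=[]))
    net = WaterNetwork(waters=[w.copy() for w in bulk_box],
                       schedule=PlacementSchedule(rescore_radius=6.0))
    scored = rescore_waters(empty, net, bulk_reference)
    assert scored.scores, "no interior water scored"
    dgs = [s.delta_g_est for s in scored.scores]
    assert abs(float(np.median(dgs))) < 0.5
    # waters beyond the rescore radius carry no score
    assert len(scored.scores) < len(bulk_box)


def test_rescore_requires_calibration(scenario, scenario_networks):
    with pytest.raises(ValueError):
        rescore_waters(scenario["with_methyl"],
                       scenario_networks["with_methyl"], math.nan)


def test_lipophilic_pocket_water_scores_unhappy(bulk_reference):
    """A water in an apolar subpocket sits above bulk (dG > 0)."""
    complex, sites = fixtures.make_toy_cavity(0, 1, seed=5)
    lipo = sites[0]
    sched = PlacementSchedule(placement_radius=6.0, rescore_radius=6.0)
    net = place_waters_iterative(complex, sched, lipo.position)
    d = np.linalg.norm(net.oxygen_positions() - lipo.position, axis=1)
    assert d.min() <= 3.0, "pocket was not hydrated"
    scored = rescore_waters(complex, net, bulk_reference)
    scored = classify_waters(scored)
    idx = int(d.argmin())
    score = scored.score_for(idx)
    assert score is not None
    assert score.delta_g_est > 0
    assert score.class_label in ("red", "yellow")


def test_classify_requires_scores(scenario_networks):
    net = scenario_networks["with_methyl"]
    with pytest.raises(ValueError):
        classify_waters(net)


def test_hbond_graph_ideal_pair_and_isolate():
    # donor with one O-H bond aimed straight at the acceptor oxygen
    ang = math.radians(104.52)
    w1 = WaterMolecule(
        oxygen=np.zeros(3),
        h1=np.array([0.9572, 0.0, 0.0]),
        h2=0.9572 * np.array([math.cos(ang), math.sin(ang), 0.0]),
    )
    w2 = WaterMolecule.from_orientation([2.8, 0, 0], [1, 0, 0])
    w3 = WaterMolecule.from_orientation([0, 9, 0], [0, 0, 1])
    empty = ReceptorComplex(receptor=MolecularStructure(atoms=[]))
    g = hbond_graph(empty, WaterNetwork(waters=[w1, w2, w3]))
    assert g.has_edge(("water", 0), ("water", 1))
    assert g.degree(("water", 2)) == 0
    assert g.nodes[("water", 2)]["degree"] == 0


def test_hbond_graph_matches_brute_force(bulk_box):
    waters = [w.copy() for w in bulk_box[:40]]
    empty = ReceptorComplex(receptor=MolecularStructure(atoms=[]))
    g = hbond_graph(empty, WaterNetwork(waters=waters))
    got = {tuple(sorted((u[1], v[1]))) for u, v in g.edges
           if u[0] == "water" and v[0] == "water"}
    expected = {tuple(sorted(p)) for p in brute_force_hbond_pairs(waters)}
    assert got == expected


def _scored_network(positions, dgs):
    waters = [WaterMolecule.from_orientation(p, [0, 0, 1]) for p in positions]
    net = WaterNetwork(waters=waters)
    scheme = ClassificationScheme()
    net.scores = [
        waternet.HydrationSiteScore(i, e, 0.0, e, scheme.label(e))
        for i, e in enumerate(dgs)
    ]
    return net


def test_compare_identity_is_empty_diff():
    net = _scored_network([[0, 0, 0], [3, 0, 0]], [0.5, -2.0])
    diff = compare_networks(net, net, (np.zeros(3), 10.0))
    assert diff.gained == [] and diff.lost == [] and diff.reclassified == []
    assert diff.delta_sum_dg == 0.0


def test_compare_reports_gains_losses_and_reclassification():
    a = _scored_network([[0, 0, 0], [3, 0, 0], [9, 0, 0]], [0.0, 0.0, 1.0])
    b = _scored_network([[0.4, 0, 0], [3.0, 0.2, 0], [15, 0, 0]], [0.0, 4.0, 0.0])
    diff = compare_networks(a, b, (np.zeros(3), 5.0))
    assert diff.lost == [2]
    assert diff.gained == [2]
    assert any(la == "grey" and lb == "red" for _, _, la, lb in diff.reclassified)
    # region sum: b has 0.0+4.0 inside, a has 0.0+0.0 inside
    assert diff.delta_sum_dg == pytest.approx(4.0)


def test_compare_requires_scores():
    a = _scored_network([[0, 0, 0]], [0.0])
    b = WaterNetwork(waters=[WaterMolecule.from_orientation([0, 0, 0], [0, 0, 1])])
    with pytest.raises(ValueError):
        compare_networks(a, b, (np.zeros(3), 5.0))


def test_des_methyl_gains_pocket_water(scenario, scenario_networks, bulk_reference):
    """The vacated lipophilic site is hydrated only without the methyl."""
    lipo = scenario["lipo_site"]
    scored = {}
    for name in ("with_methyl", "des_methyl"):
        net = rescore_waters(scenario[name], scenario_networks[name], bulk_reference)
        scored[name] = classify_waters(net)
    diff = compare_networks(scored["with_methyl"], scored["des_methyl"],
                            (lipo, 3.0))
    gained_near = [
        j for j in diff.gained
        if np.linalg.norm(scored["des_methyl"].waters[j].oxygen - lipo) <= 3.0
    ]
    assert len(gained_near) >= 1


def test_network_validity_after_operations(scenario, scenario_networks):
    holo = scenario["with_methyl"]
    net = scenario_networks["with_methyl"]
    net.validate_clashes(holo)
    relaxed, lig = relax_network(holo, net, 15, mobile_ligand=True, seed=3)
    relaxed.validate_clashes(ReceptorComplex(receptor=holo.receptor, ligand=lig))
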