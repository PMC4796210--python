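"""Shared fixtures: expensive synthetic systems built once per session."""

import numpy as np
import pytest

from hydrosite import fixtures, waternet
from hydrosite.structures import ReceptorComplex, make_pseudo_apo


@pytest.fixture(scope="session")
def cavity21():
    """Generic cavity with 2 polar sites and 1 lipophilic cup."""
    complex, sites = fixtures.make_toy_cavity(2, 1, seed=3)
    return complex, sites


@pytest.fixture(scope="session")
def scenario():
    return fixtures.make_magic_methyl_scenario(seed=1)


@pytest.fixture(scope="session")
def bulk_box():
    return fixtures.make_bulk_box(21.0, seed=1)


@pytest.fixture(scope="session")
def bulk_reference(bulk_box):
    return waternet.calibrate_bulk_reference(bulk_box)


@pytest.fixture(scope="session")
def fast_schedule():
    """Default cutoffs, smaller search radius for quick scenario runs."""
    return waternet.PlacementSchedule(placement_radius=7.0, rescore_radius=7.0)


@pytest.fixture(scope="session")
def scenario_networks(scenario, fast_schedule):
    """Placed (unrelaxed) networks for the methyl / des-methyl pair."""
    nets = {}
    for name in ("with_methyl", "des_methyl"):
        cpx = scenario[name]
        center = cpx.ligand.positions(heavy_only=True).mean(axis=0)
        nets[name] = waternet.place_waters_iterative(cpx, fast_schedule, center)
    return nets


@pytest.fixture(scope="session")
def holo_apo_pair(cavity21):
    """Generic cavity with a site-covering ligand, holo and pseudo-apo."""
    complex, sites = cavity21
    ligand = fixtures.make_toy_ligand(sites, with_methyl=True)
    holo = ReceptorComplex(receptor=complex.receptor, ligand=ligand)
    apo = make_pseudo_apo(holo)
    return holo, apo, sites


@pytest.fixture(scope="session")
def holo_apo_networks(holo_apo_pair):
    holo, apo, sites = holo_apo_pair
    sched = waternet.PlacementSchedule()
    # holo placement is centred on the ligand, apo on the pocket centroid
    net_holo = waternet.place_waters_iterative(
        holo, sched, holo.ligand.positions(heavy_only=True).mean(axis=0))
    net_apo = waternet.place_waters_iterative(
        apo, sched, apo.receptor.positions().mean(axis=0))
    return net_holo, net_apo
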