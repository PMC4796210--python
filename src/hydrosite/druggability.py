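"""Druggability assessment from lipophilic hotspots and unhappy waters.

A subpocket is promising for ligand design when a lipophilic (CRY)
hotspot sits next to a water (OH2) hotspot and the explicit network
places high-energy ("unhappy") waters there — displacing those waters is
the dominant binding-energy payout.  A lipophilic-only hotspot with no
adjacent polar partner is scored not druggable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from pydantic import BaseModel

from .mif import (
    DEFAULT_THRESHOLDS,
    Environment,
    GridSpec,
    Hotspot,
    compute_probe_field,
    cry_field,
    find_hotspots,
    pocket_surface,
)
from .structures import ReceptorComplex
from .waternet import WaterNetwork

__all__ = ["SubpocketAssessment", "DruggabilityReport", "assess_druggability",
           "DruggabilityReportModel"]


@dataclass
class SubpocketAssessment:
    lipophilic_hotspot: Hotspot
    nearest_polar_hotspot_distance: Optional[float]
    unhappy_water_count: int
    druggable: bool


@dataclass
class DruggabilityReport:
    subpockets: list[SubpocketAssessment] = field(default_factory=list)
    pocket_volume: float = 0.0  # A^3
    summary_flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return DruggabilityReportModel.from_report(self).model_dump()


class SubpocketModel(BaseModel):
    position: list[float]
    energy: float
    probe: str
    nearest_polar_hotspot_distance: Optional[float]
    unhappy_water_count: int
    druggable: bool


class DruggabilityReportModel(BaseModel):
    """Serialization schema for the report (validated on round trip)."""

    subpockets: list[SubpocketModel]
    pocket_volume: float
    summary_flags: list[str]

    @classmethod
    def from_report(cls, report: DruggabilityReport) -> "DruggabilityReportModel":
        return cls(
            subpockets=[
                SubpocketModel(
                    position=[float(x) for x in sp.lipophilic_hotspot.position],
                    energy=sp.lipophilic_hotspot.energy,
                    probe=sp.lipophilic_hotspot.probe,
                    nearest_polar_hotspot_distance=sp.nearest_polar_hotspot_distance,
                    unhappy_water_count=sp.unhappy_water_count,
                    druggable=sp.druggable,
                )
                for sp in report.subpockets
            ],
            pocket_volume=report.pocket_volume,
            summary_flags=report.summary_flags,
        )


def assess_druggability(
    complex: ReceptorComplex,
    network: WaterNetwork,
    c1_threshold: float = DEFAULT_THRESHOLDS["C1="],
    oh2_threshold: float = DEFAULT_THRESHOLDS["OH2"],
    adjacency: float = 4.0,
    grid_spacing: float = 0.5,
    pocket_radius: float = 10.0,
) -> DruggabilityReport:
    """Per-subpocket druggability from CRY/OH2 hotspots and scored waters.

    For each CRY hotspot below the lipophilic threshold the report records
    the distance to the nearest water-probe hotspot and the number of
    red/yellow network waters within the adjacency radius (default 4 A);
    the subpocket is druggable when both a polar hotspot and at least one
    unhappy water sit inside that radius.  Pocket volume is the
    C3-accessible volume within ``pocket_radius`` of the pocket centroid.
    """
    if network.waters and not all(s.class_label for s in network.scores):
        raise ValueError("network must be scored and classified")
    if network.waters:
        center = network.oxygen_positions().mean(axis=0)
    else:
        center = complex.receptor.positions().mean(axis=0)
    env = Environment.from_complex(complex, include_waters=False)
    grid = GridSpec.cube(center, pocket_radius + 2.0, grid_spacing)
    c1 = compute_probe_field(env, "C1=", grid)
    dry = compute_probe_field(env, "DRY", grid)
    cry = cry_field(c1, dry)
    oh2 = compute_probe_field(env, "OH2", grid)
    c3 = compute_probe_field(env, "C3", grid)

    lipo_spots = find_hotspots(cry, c1_threshold)
    polar_spots = find_hotspots(oh2, oh2_threshold)
    unhappy_pos = np.array(
        [
            network.waters[s.water_index].oxygen
            for s in network.scores
            if s.class_label in ("red", "yellow")
        ]
    ).reshape(-1, 3)

    subpockets = []
    for spot in lipo_spots:  # find_hotspots sorts by energy ascending
        if polar_spots:
            dists = [float(np.linalg.norm(spot.position - p.position)) for p in polar_spots]
            nearest = min(dists)
        else:
            nearest = None
        n_unhappy = (
            int((np.linalg.norm(unhappy_pos - spot.position, axis=1) <= adjacency).sum())
            if len(unhappy_pos)
            else 0
        )
        druggable = (nearest is not None and nearest <= adjacency) and n_unhappy >= 1
        subpockets.append(
            SubpocketAssessment(
                lipophilic_hotspot=spot,
                nearest_polar_hotspot_distance=nearest,
                unhappy_water_count=n_unhappy,
                druggable=druggable,
            )
        )

    mask = pocket_surface(c3, DEFAULT_THRESHOLDS["C3"])
    within = (
        np.linalg.norm(grid.points() - center, axis=1) <= pocket_radius
    ).reshape(grid.shape)
    volume = float((mask & within).sum()) * grid.spacing**3

    flags = []
    if any(sp.druggable for sp in subpockets):
        flags.append("druggable-subpocket-present")
    for sp in subpockets:
        if sp.nearest_polar_hotspot_distance is None or sp.nearest_polar_hotspot_distance > adjacency:
            flags.append("lipophilic-only-hotspot")
            break
    if len(lipo_spots) >= 2:
        span = max(
            float(np.linalg.norm(a.position - b.position))
            for a in lipo_spots for b in lipo_spots
        )
        flags.append(f"hotspot-span:{span:.1f}A")
    return DruggabilityReport(
        subpockets=subpockets, pocket_volume=volume, summary_flags=flags
    )
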