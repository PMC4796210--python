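"""End-to-end pipelines tying the modules together.

Each pipeline consumes a serializable :class:`RunConfig` (fixture recipe
or PDB path, schedules, seed) and archives everything needed to
reproduce its outputs — the config itself, the seed, the scored network,
and per-stage logs — into a bundle directory.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import fixtures, metadyn, waternet
from .druggability import DruggabilityReport, DruggabilityReportModel, assess_druggability
from .structures import (
    ReceptorComplex,
    make_pseudo_apo,
    mutate_to_alanine,
    read_pdb,
    type_complex,
    write_pdb,
)
from .waternet import (
    ClassificationScheme,
    PlacementSchedule,
    WaterNetwork,
    calibrate_bulk_reference,
    classify_waters,
    compare_networks,
    hbond_graph,
    place_waters_iterative,
    relax_network,
    rescore_waters,
)

__all__ = [
    "RunConfig",
    "run_waterflap_pipeline",
    "run_druggability_pipeline",
    "run_bpm_interpretation",
    "build_complex",
]

DEFAULT_BULK_EDGE = 21.0


@dataclass
class RunConfig:
    # input: either a PDB path or a fixture recipe
    pdb_path: Optional[str] = None
    fixture: Optional[dict] = None   # {"kind": "magic_methyl"|"mutation"|"cavity", ...}
    pseudo_apo: bool = False
    seed: int = 0
    n_sweeps: int = 150
    mobile_ligand: bool = False
    temperature: float = 300.0
    bulk_edge: float = DEFAULT_BULK_EDGE
    schedule: PlacementSchedule = field(default_factory=PlacementSchedule)
    scheme: ClassificationScheme = field(default_factory=ClassificationScheme)
    output_dir: Optional[str] = None

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "schedule" in raw and isinstance(raw["schedule"], dict):
            raw["schedule"] = PlacementSchedule(**raw["schedule"])
        if "scheme" in raw and isinstance(raw["scheme"], dict):
            raw["scheme"] = ClassificationScheme(**raw["scheme"])
        return cls(**raw)


def build_complex(config: RunConfig) -> ReceptorComplex:
    """Materialize the input complex from a PDB path or fixture recipe."""
    if config.pdb_path:
        complex = type_complex(read_pdb(config.pdb_path))
    elif config.fixture:
        recipe = dict(config.fixture)
        kind = recipe.pop("kind", "magic_methyl")
        if kind == "magic_methyl":
            scen = fixtures.make_magic_methyl_scenario(config.seed)
            complex = scen["des_methyl" if recipe.get("des_methyl") else "with_methyl"]
        elif kind == "mutation":
            complex = fixtures.make_mutation_scenario(config.seed)["complex"]
        elif kind == "cavity":
            complex, _sites = fixtures.make_toy_cavity(
                recipe.get("n_polar", 2), recipe.get("n_lipophilic", 1), config.seed
            )
        else:
            raise ValueError(f"unknown fixture kind {kind!r}")
    else:
        raise ValueError("config needs either pdb_path or fixture")
    if config.pseudo_apo and complex.ligand is not None:
        complex = make_pseudo_apo(complex)
    return complex


def _pocket_center(complex: ReceptorComplex) -> np.ndarray:
    if complex.ligand is not None and complex.ligand.atoms:
        return complex.ligand.positions(heavy_only=True).mean(axis=0)
    # apo: geometric center of the receptor shell encloses the pocket
    return complex.receptor.positions().mean(axis=0)


def _scores_frame(network: WaterNetwork) -> pd.DataFrame:
    rows = []
    for s in network.scores:
        w = network.waters[s.water_index]
        rows.append(
            {
                "water_index": s.water_index,
                "x": w.oxygen[0], "y": w.oxygen[1], "z": w.oxygen[2],
                "placement_iteration": w.placement_iteration,
                "placement_energy": w.placement_energy,
                "e_oh2_context": s.e_oh2_context,
                "e_cry": s.e_cry,
                "delta_g_est": s.delta_g_est,
                "class": s.class_label,
            }
        )
    return pd.DataFrame(rows)


def run_waterflap_pipeline(
    config: RunConfig, complex: Optional[ReceptorComplex] = None
) -> dict:
    """place -> relax -> rescore -> classify, with archived intermediates.

    Returns a bundle dict (complex, network, ligand, scores table, graph,
    log); when ``config.output_dir`` is set the bundle is also written to
    disk (network PDB, score CSV, H-bond edge list, config YAML).
    """
    log: list[dict] = []

    def stage(name):
        t0 = time.perf_counter()

        def done(**counts):
            log.append({"stage": name, "seconds": round(time.perf_counter() - t0, 3),
                        **counts})

        return done

    try:
        done = stage("build")
        if complex is None:
            complex = build_complex(config)
        center = _pocket_center(complex)
        done(atoms=len(complex.receptor.atoms))

        done = stage("bulk-calibration")
        box = fixtures.make_bulk_box(config.bulk_edge, seed=config.seed)
        bulk_ref = calibrate_bulk_reference(box)
        done(bulk_reference=round(bulk_ref, 3))

        done = stage("place")
        network = place_waters_iterative(complex, config.schedule, center)
        done(waters=len(network.waters))

        done = stage("relax")
        network, ligand = relax_network(
            complex, network, n_sweeps=config.n_sweeps,
            mobile_ligand=config.mobile_ligand,
            temperature=config.temperature, seed=config.seed,
        )
        relaxed = ReceptorComplex(receptor=complex.receptor, ligand=ligand,
                                  waters=complex.waters)
        done(waters=len(network.waters))

        done = stage("rescore")
        network = rescore_waters(relaxed, network, bulk_ref)
        network = classify_waters(network, config.scheme)
        done(scored=len(network.scores))

        done = stage("graph")
        graph = hbond_graph(relaxed, network)
        done(edges=graph.number_of_edges())
    except Exception as exc:
        stage_name = log[-1]["stage"] if log else "build"
        raise RuntimeError(f"waterflap pipeline failed after stage "
                           f"{stage_name!r}: {exc}") from exc

    network.validate_clashes(relaxed)
    bundle = {
        "complex": relaxed,
        "network": network,
        "ligand": ligand,
        "bulk_reference": bulk_ref,
        "scores": _scores_frame(network),
        "graph": graph,
        "log": log,
        "config": config,
    }
    if config.output_dir:
        _write_waterflap_bundle(bundle, Path(config.output_dir))
    return bundle


def _write_waterflap_bundle(bundle: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    relaxed: ReceptorComplex = bundle["complex"]
    network: WaterNetwork = bundle["network"]
    out_complex = ReceptorComplex(
        receptor=relaxed.receptor, ligand=relaxed.ligand, waters=network.waters
    )
    write_pdb(out_complex, outdir / "network.pdb")
    bundle["scores"].to_csv(outdir / "scores.csv", index=False)
    edges = [
        {"a": str(u), "b": str(v), "distance": d.get("distance")}
        for u, v, d in bundle["graph"].edges(data=True)
    ]
    (outdir / "hbond_graph.json").write_text(json.dumps(edges, indent=2))
    (outdir / "log.json").write_text(json.dumps(bundle["log"], indent=2))
    (outdir / "config.yaml").write_text(yaml.safe_dump(bundle["config"].to_dict()))


def run_druggability_pipeline(
    config: RunConfig, complex: Optional[ReceptorComplex] = None
) -> dict:
    """Waterflap run followed by the hotspot/unhappy-water assessment.

    For a pseudo-apo site the 8-A ligand-centred rescore rule has no
    ligand to centre on; every placed water in the searched pocket is
    scored instead, so rim subpockets keep their unhappy-water counts.
    """
    if complex is None:
        complex = build_complex(config)
    if complex.is_pseudo_apo:
        schedule = replace(
            config.schedule,
            rescore_radius=max(config.schedule.rescore_radius,
                               config.schedule.placement_radius + 2.0),
        )
        config = replace(config, schedule=schedule)
    bundle = run_waterflap_pipeline(config, complex)
    report: DruggabilityReport = assess_druggability(
        bundle["complex"], bundle["network"]
    )
    bundle["report"] = report
    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        payload = report.as_dict()
        DruggabilityReportModel.model_validate(payload)  # schema check
        (outdir / "report.json").write_text(json.dumps(payload, indent=2))
        lines = [f"pocket volume: {report.pocket_volume:.0f} A^3"]
        for i, sp in enumerate(report.subpockets):
            lines.append(
                f"subpocket {i}: CRY {sp.lipophilic_hotspot.energy:.2f} kcal/mol, "
                f"polar at {sp.nearest_polar_hotspot_distance}, "
                f"unhappy waters {sp.unhappy_water_count}, druggable={sp.druggable}"
            )
        lines += [f"flag: {f}" for f in report.summary_flags]
        (outdir / "report.txt").write_text("\n".join(lines) + "\n")
    return bundle


def _unhappy_in(network: WaterNetwork, center: np.ndarray, radius: float) -> int:
    return sum(
        1
        for s in network.scores
        if s.class_label in ("red", "yellow")
        and np.linalg.norm(network.waters[s.water_index].oxygen - center) <= radius
    )


def run_bpm_interpretation(
    config: RunConfig,
    mutations: list[tuple[str, int]],
    landscape: Optional[fixtures.ToyLandscape] = None,
    metad_params: Optional[metadyn.WTMetaDParameters] = None,
    seeds: tuple[int, ...] = (1, 2, 3, 4, 5),
) -> dict:
    """Mutation interpretation: water-network diff plus binding-score table.

    For each (chain, residue) mutation the spectator residue is truncated
    to alanine, the waterflap pipeline re-run, and the scored network
    compared with the reference in a sphere around the mutated residue.
    When a toy landscape with named variants is supplied, the matching
    metadynamics comparison table is attached.
    """
    reference = run_waterflap_pipeline(config)
    ref_complex = reference["complex"]
    results = {"reference": reference, "mutants": {}}
    for chain, resnum in mutations:
        base = build_complex(config)
        if any(a.chain == chain and a.residue_number == resnum and a.residue_name == "ALA"
               for a in base.receptor.atoms):
            mut_complex = base  # identity mutation
        else:
            mut_complex = mutate_to_alanine(base, chain, resnum)
        if mut_complex.metadata.get("mutation_noop"):
            results["mutants"][(chain, resnum)] = {"diff": None, "noop": True}
            continue
        # region of interest: where the truncated side-chain group used to be
        res_atoms = [
            a for a in base.receptor.atoms
            if a.chain == chain and a.residue_number == resnum
        ]
        side = [a.position for a in res_atoms
                if a.name not in ("N", "CA", "C", "O", "OXT", "CB")]
        region_center = np.mean(side if side else [a.position for a in res_atoms],
                                axis=0)
        region = (region_center, 4.5)
        mut_bundle = run_waterflap_pipeline(
            replace(config, output_dir=None), complex=mut_complex,
        )
        diff = compare_networks(reference["network"], mut_bundle["network"], region)
        n_ref = _unhappy_in(reference["network"], *region)
        n_mut = _unhappy_in(mut_bundle["network"], *region)
        results["mutants"][(chain, resnum)] = {
            "diff": diff, "bundle": mut_bundle, "noop": False,
            "unhappy_reference": n_ref, "unhappy_mutant": n_mut,
            "unhappy_delta": n_mut - n_ref,
        }
    if landscape is not None:
        variants = {"reference": None}
        variants.update({name: name for name in landscape.perturbations})
        results["metascore"] = metadyn.compare_variants(
            landscape, variants,
            params=metad_params or metadyn.WTMetaDParameters(),
            seeds=seeds,
        )
    return results
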