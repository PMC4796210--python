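"""Molecular structures: PDB I/O, simplified force-field typing, and edits.

The package works on three kinds of structures — a receptor, an optional
ligand, and explicit three-site waters — all reduced to typed point atoms
(element, Lennard-Jones class, partial charge, hydrogen-bond role).  Typing
comes from a packaged YAML lookup keyed by ``(residue_name, atom_name)`` with
an element-level fallback, so every interaction energy in the package is
reproducible from plain text.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import gemmi
import numpy as np
import yaml

__all__ = [
    "Atom",
    "MolecularStructure",
    "WaterMolecule",
    "ReceptorComplex",
    "StructureError",
    "PDBParseError",
    "read_pdb",
    "write_pdb",
    "assign_atom_types",
    "load_typing_table",
    "mutate_to_alanine",
    "make_pseudo_apo",
    "strip_substituent",
]

WATER_RESIDUES = {"HOH", "WAT", "SOL", "TIP3"}
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

#: TIP3P-like rigid water geometry (Angstrom / degrees).
OH_BOND = 0.9572
HOH_ANGLE = 104.52


class StructureError(ValueError):
    """Invalid structure or illegal structure edit."""


class PDBParseError(StructureError):
    """Unreadable or malformed PDB input."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain: str
    position: np.ndarray
    partial_charge: float = 0.0
    vdw_class: Optional[str] = None
    hbond_role: str = "none"

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise StructureError(f"atom {self.serial} ({self.name}): bad position")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"

    def copy(self) -> "Atom":
        return replace(self, position=self.position.copy())


@dataclass
class MolecularStructure:
    atoms: list[Atom] = field(default_factory=list)
    role: str = "receptor"  # receptor | ligand | water
    provenance: str = ""

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def positions(self, heavy_only: bool = False) -> np.ndarray:
        atoms = self.heavy_atoms() if heavy_only else self.atoms
        if not atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in atoms])

    def copy(self) -> "MolecularStructure":
        return MolecularStructure(
            atoms=[a.copy() for a in self.atoms],
            role=self.role,
            provenance=self.provenance,
        )

    def validate(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise StructureError("duplicate atom serials")
        pos = self.positions(heavy_only=True)
        if len(pos) > 1:
            d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() < 0.8:
                i, j = np.unravel_index(d.argmin(), d.shape)
                raise StructureError(
                    f"heavy atoms closer than 0.8 A (pair {i}, {j}: {d.min():.2f} A)"
                )


@dataclass
class WaterMolecule:
    """Rigid three-site water with explicit hydrogens."""

    oxygen: np.ndarray
    h1: np.ndarray
    h2: np.ndarray
    placement_iteration: int = -1
    placement_energy: float = math.nan

    def __post_init__(self) -> None:
        self.oxygen = np.asarray(self.oxygen, dtype=float)
        self.h1 = np.asarray(self.h1, dtype=float)
        self.h2 = np.asarray(self.h2, dtype=float)

    @classmethod
    def from_orientation(
        cls, oxygen: Iterable[float], axis: Iterable[float], twist: float = 0.0, **kw
    ) -> "WaterMolecule":
        """Build an ideal-geometry water with its bisector along ``axis``."""
        o = np.asarray(oxygen, dtype=float)
        z = np.asarray(axis, dtype=float)
        nz = np.linalg.norm(z)
        z = z / nz if nz > 0 else np.array([0.0, 0.0, 1.0])
        ref = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(ref, z)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        x = np.cross(z, ref)
        x /= np.linalg.norm(x)
        x = math.cos(twist) * x + math.sin(twist) * np.cross(z, x)
        half = math.radians(HOH_ANGLE / 2.0)
        h1 = o + OH_BOND * (math.cos(half) * z + math.sin(half) * x)
        h2 = o + OH_BOND * (math.cos(half) * z - math.sin(half) * x)
        return cls(oxygen=o, h1=h1, h2=h2, **kw)

    def validate(self) -> None:
        d1 = np.linalg.norm(self.h1 - self.oxygen)
        d2 = np.linalg.norm(self.h2 - self.oxygen)
        if abs(d1 - OH_BOND) > 1e-3 or abs(d2 - OH_BOND) > 1e-3:
            raise StructureError(f"water O-H bond lengths off ideal: {d1:.4f}, {d2:.4f}")
        v1 = (self.h1 - self.oxygen) / d1
        v2 = (self.h2 - self.oxygen) / d2
        ang = math.degrees(math.acos(float(np.clip(np.dot(v1, v2), -1, 1))))
        if abs(ang - HOH_ANGLE) > 0.1:
            raise StructureError(f"water H-O-H angle off ideal: {ang:.3f}")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "WaterMolecule":
        o = self.oxygen
        return WaterMolecule(
            oxygen=o + translation,
            h1=o + translation + rotation @ (self.h1 - o),
            h2=o + translation + rotation @ (self.h2 - o),
            placement_iteration=self.placement_iteration,
            placement_energy=self.placement_energy,
        )

    def copy(self) -> "WaterMolecule":
        return WaterMolecule(
            self.oxygen.copy(), self.h1.copy(), self.h2.copy(),
            self.placement_iteration, self.placement_energy,
        )


@dataclass
class ReceptorComplex:
    receptor: MolecularStructure
    ligand: Optional[MolecularStructure] = None
    waters: list[WaterMolecule] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def is_pseudo_apo(self) -> bool:
        return self.ligand is None

    def environment_structures(self) -> list[MolecularStructure]:
        out = [self.receptor]
        if self.ligand is not None:
            out.append(self.ligand)
        return out

    def copy(self) -> "ReceptorComplex":
        return ReceptorComplex(
            receptor=self.receptor.copy(),
            ligand=self.ligand.copy() if self.ligand else None,
            waters=[w.copy() for w in self.waters],
            metadata=dict(self.metadata),
        )


# ---------------------------------------------------------------------------
# PDB input / output (via gemmi)
# ---------------------------------------------------------------------------

def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if not name:
        return "C"
    if name[0].isdigit():
        name = name[1:]
    return name[0].upper()


def read_pdb(path: str | Path) -> ReceptorComplex:
    """Read a PDB file into receptor / ligand / crystallographic waters.

    ATOM records (and HETATM records of standard residues) go to the
    receptor; the largest non-water HETATM group is taken as the ligand;
    HOH residues become explicit waters (hydrogens generated along +z when
    the file stores only the oxygen).
    """
    path = Path(path)
    if not path.exists():
        raise PDBParseError(f"no such file: {path}")
    _prescan_pdb(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.setup_entities()
    receptor = MolecularStructure(role="receptor", provenance=str(path))
    waters: list[WaterMolecule] = []
    het_groups: dict[tuple, list[Atom]] = {}
    n_atoms = 0
    for model in st:
        for chain in model:
            for res in chain:
                atoms = []
                for at in res:
                    el = at.element.name if at.element else _guess_element(at.name)
                    atoms.append(
                        Atom(
                            serial=at.serial,
                            name=at.name,
                            element=el or _guess_element(at.name),
                            residue_name=res.name,
                            residue_number=res.seqid.num,
                            chain=chain.name,
                            position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        )
                    )
                n_atoms += len(atoms)
                if res.name in WATER_RESIDUES:
                    waters.append(_water_from_atoms(atoms))
                elif res.het_flag == "H":
                    het_groups.setdefault((chain.name, res.name, res.seqid.num), []).extend(atoms)
                else:
                    receptor.atoms.extend(atoms)
        break  # first model only
    if n_atoms == 0:
        raise PDBParseError(f"{path}: no atoms found")
    ligand = None
    if het_groups:
        # largest heavy-atom count wins
        key = max(het_groups, key=lambda k: sum(a.is_heavy for a in het_groups[k]))
        ligand = MolecularStructure(
            atoms=het_groups.pop(key), role="ligand", provenance=str(path)
        )
        for extra in het_groups.values():  # remaining het groups stay with receptor
            receptor.atoms.extend(extra)
    return ReceptorComplex(receptor=receptor, ligand=ligand, waters=waters)


def _prescan_pdb(path: Path) -> None:
    """Light syntactic check so malformed records fail with a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                except (ValueError, IndexError):
                    raise PDBParseError(
                        f"{path}:{lineno}: malformed coordinate record"
                    ) from None


def _water_from_atoms(atoms: list[Atom]) -> WaterMolecule:
    o = next((a for a in atoms if a.element.upper() == "O"), None)
    if o is None:
        raise PDBParseError("water residue without oxygen")
    hs = [a for a in atoms if a.element.upper() == "H"]
    if len(hs) >= 2:
        w = WaterMolecule(oxygen=o.position, h1=hs[0].position, h2=hs[1].position)
    else:
        w = WaterMolecule.from_orientation(o.position, axis=[0.0, 0.0, 1.0])
    return w


def write_pdb(complex: ReceptorComplex, path: str | Path) -> None:
    """Write the complex as PDB; waters become HOH with explicit hydrogens."""
    if not complex.receptor.atoms and complex.ligand is None and not complex.waters:
        raise StructureError("refusing to write an empty complex")
    st = gemmi.Structure()
    st.name = "hydrosite"
    model = gemmi.Model("1")
    serial = 1

    def add_chain(name: str, atoms: list[Atom]) -> int:
        nonlocal serial
        chain = gemmi.Chain(name)
        groups: list[tuple[tuple, list[Atom]]] = []
        for a in atoms:
            key = (a.residue_name, a.residue_number)
            if not groups or groups[-1][0] != key:
                groups.append((key, []))
            groups[-1][1].append(a)
        for (resname, resnum), group in groups:
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(resnum, " ")
            res.het_flag = "H" if resname in WATER_RESIDUES or name == "L" else "A"
            for a in group:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.position)
                ga.serial = serial
                serial += 1
                res.add_atom(ga)
            chain.add_residue(res)  # gemmi copies: residue must be complete
        model.add_chain(chain)
        return serial

    if complex.receptor.atoms:
        add_chain("A", complex.receptor.atoms)
    if complex.ligand is not None and complex.ligand.atoms:
        add_chain("L", complex.ligand.atoms)
    if complex.waters:
        water_atoms = []
        for i, w in enumerate(complex.waters, start=1):
            for nm, pos, el in (("O", w.oxygen, "O"), ("H1", w.h1, "H"), ("H2", w.h2, "H")):
                water_atoms.append(
                    Atom(serial=0, name=nm, element=el, residue_name="HOH",
                         residue_number=i, chain="W", position=pos)
                )
        add_chain("W", water_atoms)
    st.add_model(model)
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except OSError as exc:
        raise StructureError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Atom typing
# ---------------------------------------------------------------------------

_TABLE_CACHE: Optional[dict] = None


def load_typing_table() -> dict:
    global _TABLE_CACHE
    if _TABLE_CACHE is None:
        text = resources.files("hydrosite.data").joinpath("atom_types.yaml").read_text()
        _TABLE_CACHE = yaml.safe_load(text)
    return _TABLE_CACHE


def vdw_parameters(vdw_class: str) -> tuple[float, float]:
    """Return (rmin_half, epsilon) for a Lennard-Jones class."""
    entry = load_typing_table()["vdw_classes"][vdw_class]
    return float(entry["rmin_half"]), float(entry["epsilon"])


def assign_atom_types(structure: MolecularStructure) -> MolecularStructure:
    """Assign vdw_class, partial_charge and hbond_role to every atom (in place).

    Lookup order: (residue_name, atom_name); backbone names for standard
    residues; element fallback with neutral charge.  Unknown elements raise.
    """
    table = load_typing_table()
    residues = table["residues"]
    backbone = table["_backbone"]
    elements = table["elements"]
    for atom in structure.atoms:
        entry = None
        res = residues.get(atom.residue_name)
        if res is not None:
            entry = res.get(atom.name)
            if entry is None and atom.residue_name not in WATER_RESIDUES:
                entry = backbone.get(atom.name)
        if entry is None:
            el = atom.element.upper()
            entry = elements.get(el)
            if entry is None:
                raise StructureError(
                    f"unknown element {atom.element!r} for atom "
                    f"{atom.serial} {atom.name} {atom.residue_name}{atom.residue_number}"
                )
        atom.vdw_class, atom.partial_charge, atom.hbond_role = (
            entry[0], float(entry[1]), entry[2],
        )
        if atom.element.upper() == "C":
            atom.hbond_role = "none"
    return structure


def type_complex(complex: ReceptorComplex) -> ReceptorComplex:
    """Type receptor and ligand in place; waters are typed implicitly."""
    assign_atom_types(complex.receptor)
    if complex.ligand is not None:
        assign_atom_types(complex.ligand)
    return complex


# ---------------------------------------------------------------------------
# Structure edits
# ---------------------------------------------------------------------------

def mutate_to_alanine(
    complex: ReceptorComplex, chain: str, residue_number: int
) -> ReceptorComplex:
    """Truncate a residue's side chain past C-beta, renaming it ALA.

    Backbone coordinates are untouched.  Mutating an ALA is a no-op (flagged
    in ``metadata['mutation_noop']``); GLY has no C-beta and raises.
    """
    out = complex.copy()
    res_atoms = [
        a for a in out.receptor.atoms
        if a.chain == chain and a.residue_number == residue_number
    ]
    if not res_atoms:
        raise StructureError(f"no residue {chain}/{residue_number}")
    resname = res_atoms[0].residue_name
    if resname == "GLY":
        raise StructureError("GLY has no C-beta; cannot mutate to ALA")
    out.metadata["mutation_noop"] = False
    if resname == "ALA":
        out.metadata["mutation_noop"] = True
        return out
    keep_names = BACKBONE_ATOMS | {"CB", "H", "HA"}
    removed = {
        id(a) for a in res_atoms
        if a.name not in keep_names
    }
    out.receptor.atoms = [a for a in out.receptor.atoms if id(a) not in removed]
    table = load_typing_table()
    for a in out.receptor.atoms:
        if a.chain == chain and a.residue_number == residue_number:
            a.residue_name = "ALA"
            if a.name == "CB":
                entry = table["residues"]["ALA"]["CB"]
                a.vdw_class, a.partial_charge, a.hbond_role = entry[0], float(entry[1]), entry[2]
    return out


def make_pseudo_apo(complex: ReceptorComplex) -> ReceptorComplex:
    """Drop the ligand, keeping receptor and waters (the pseudo-apo state)."""
    if complex.ligand is None:
        raise StructureError("complex is already apo")
    out = complex.copy()
    out.ligand = None
    return out


def strip_substituent(ligand: MolecularStructure, atom_serial: int) -> MolecularStructure:
    """Remove a terminal heavy atom (plus its hydrogens), capping with one H.

    The atom must have exactly one heavy neighbor within 1.8 A; removing a
    ring or linker atom would fragment the ligand and raises instead.
    """
    out = ligand.copy()
    target = next((a for a in out.atoms if a.serial == atom_serial), None)
    if target is None:
        raise StructureError(f"no atom with serial {atom_serial}")
    if not target.is_heavy:
        raise StructureError("substituent must be a heavy atom")
    heavies = [a for a in out.atoms if a.is_heavy and a.serial != atom_serial]
    neighbors = [
        a for a in heavies if np.linalg.norm(a.position - target.position) <= 1.8
    ]
    if len(neighbors) != 1:
        raise StructureError(
            f"atom {atom_serial} is not terminal ({len(neighbors)} heavy neighbors)"
        )
    attach = neighbors[0]
    drop = {id(target)}
    for a in out.atoms:
        if not a.is_heavy and np.linalg.norm(a.position - target.position) <= 1.2:
            drop.add(id(a))
    out.atoms = [a for a in out.atoms if id(a) not in drop]
    bond = target.position - attach.position
    bond /= np.linalg.norm(bond)
    max_serial = max(a.serial for a in out.atoms)
    cap = Atom(
        serial=max_serial + 1,
        name="HX",
        element="H",
        residue_name=attach.residue_name,
        residue_number=attach.residue_number,
        chain=attach.chain,
        position=attach.position + 1.09 * bond,
        vdw_class="hydrogen",
        hbond_role="none",
    )
    out.atoms.append(cap)
    return out
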