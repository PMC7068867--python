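"""Reading PDB-format complexes and splitting them into protein and ligand atoms.

Only the coordinate records matter downstream: ATOM/HETATM lines of the
first MODEL, with hydrogens removed and alternate locations collapsed to a
single coordinate per atom.  Hetero groups with fewer than six heavy atoms
are treated as experimental artifacts (sulfate, glycerol, ...) and never
become ligands; water is excluded outright.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable

logger = logging.getLogger(__name__)

#: Minimum heavy-atom count for a hetero group to count as a ligand.
MIN_LIGAND_ATOMS = 6

WATER_NAMES = {"HOH", "DOD", "WAT"}

STANDARD_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

# Two-letter element symbols that can appear in atom names; used when the
# element columns (77-78) are blank.
_TWO_LETTER_ELEMENTS = {
    "BR", "CL", "FE", "MG", "MN", "ZN", "CA", "NA", "CU", "CO", "NI", "SE",
    "CD", "HG", "AS", "AL", "LI", "BE", "SI", "MO", "RU", "PT", "AU", "PB",
}


class PDBParseError(ValueError):
    """Raised when a PDB text cannot be parsed into coordinate records."""


@dataclass(frozen=True)
class AtomRecord:
    """One heavy-atom coordinate record."""

    serial: int
    atom_name: str
    element: str
    alt_loc: str
    residue_name: str
    residue_number: int
    insertion_code: str
    chain_id: str
    x: float
    y: float
    z: float
    record_kind: str  # "polymer" | "hetero"
    occupancy: float = 1.0

    @property
    def coord(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)

    @property
    def residue_key(self) -> tuple[str, str, int, str]:
        return (self.chain_id, self.residue_name, self.residue_number, self.insertion_code)


@dataclass
class StructureModel:
    """All atoms of a single model of one structure."""

    structure_id: str
    atoms: list[AtomRecord] = field(default_factory=list)
    model_number: int = 1

    def chains(self) -> set[str]:
        return {a.chain_id for a in self.atoms}


@dataclass
class LigandInstance:
    """One copy of a hetero ligand: (het code, residue number, chain)."""

    ligand_name: str
    residue_number: int
    chain_id: str
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def instance_id(self) -> str:
        return f"{self.ligand_name}_{self.chain_id}{self.residue_number}"


def _infer_element(atom_name: str, residue_name: str, record_kind: str) -> str:
    """Infer the element when columns 77-78 are blank.

    Follows the wwPDB naming convention: for four-character names or names
    starting in column 13 the first character belongs to the element; a
    leading digit (e.g. ``1HB``) marks a hydrogen-style name.
    """
    name = atom_name.strip()
    if not name:
        return ""
    if name[0].isdigit():
        name = name[1:]
        if not name:
            return ""
    # Names left-padded with a space start at column 14 -> one-letter element.
    if atom_name[:1] != " " and len(atom_name.strip()) >= 2:
        two = name[:2].upper()
        if two in _TWO_LETTER_ELEMENTS and (record_kind == "hetero" or residue_name not in STANDARD_AMINO_ACIDS):
            return two.capitalize()
        # In standard residues "CA" is an alpha carbon, not calcium.
        if two == "HG" and residue_name in STANDARD_AMINO_ACIDS:
            return "H"
    return name[0].upper()


def _parse_coordinate_line(line: str, line_no: int) -> AtomRecord:
    kind = "polymer" if line.startswith("ATOM") else "hetero"
    try:
        serial = int(line[6:11])
        atom_name = line[12:16]
        alt_loc = line[16:17].strip()
        residue_name = line[17:20].strip()
        chain_id = line[21:22].strip()
        residue_number = int(line[22:26])
        insertion_code = line[26:27].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = line[76:78].strip().capitalize() if len(line) >= 77 else ""
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed coordinate record at line {line_no}: {line.rstrip()!r}") from exc
    if not element:
        element = _infer_element(atom_name, residue_name, kind)
    if not element:
        raise PDBParseError(f"cannot infer element at line {line_no}: {line.rstrip()!r}")
    if not all(math.isfinite(v) for v in (x, y, z)):
        raise PDBParseError(f"non-finite coordinate at line {line_no}: {line.rstrip()!r}")
    return AtomRecord(
        serial=serial,
        atom_name=atom_name.strip(),
        element=element,
        alt_loc=alt_loc,
        residue_name=residue_name,
        residue_number=residue_number,
        insertion_code=insertion_code,
        chain_id=chain_id,
        x=x, y=y, z=z,
        record_kind=kind,
        occupancy=occupancy,
    )


def _collapse_alt_locs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one coordinate per (residue, atom name): highest occupancy,
    ties broken by the alphabetically first alt-loc label."""
    best: dict[tuple, AtomRecord] = {}
    order: list[tuple] = []
    for atom in atoms:
        key = (*atom.residue_key, atom.atom_name)
        if key not in best:
            best[key] = atom
            order.append(key)
        else:
            cur = best[key]
            if (atom.occupancy, _alt_rank(atom.alt_loc)) > (cur.occupancy, _alt_rank(cur.alt_loc)):
                best[key] = atom
    return [replace(best[k], alt_loc="") for k in order]


def _alt_rank(label: str) -> float:
    # Higher is better: blank labels win ties, then A > B > ...
    if not label:
        return 0.0
    return -ord(label[0])


def parse_pdb(pdb_text: str, structure_id: str) -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    Only the first MODEL is retained; alternate locations are collapsed to
    the highest-occupancy conformer.  Raises :class:`PDBParseError` when no
    coordinate record is present or a record is malformed.
    """
    atoms: list[AtomRecord] = []
    model_number = 1
    in_skipped_model = False
    seen_model = False
    for line_no, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            if seen_model:
                in_skipped_model = True
            else:
                seen_model = True
                try:
                    model_number = int(line.split()[1])
                except (IndexError, ValueError):
                    model_number = 1
        elif rec == "ENDMDL":
            continue
        elif rec in ("ATOM", "HETATM"):
            if in_skipped_model:
                continue
            atoms.append(_parse_coordinate_line(line, line_no))
    if not atoms:
        raise PDBParseError(f"no ATOM/HETATM records found in {structure_id!r}")
    atoms = _collapse_alt_locs(atoms)
    return StructureModel(structure_id=structure_id, atoms=atoms, model_number=model_number)


def write_pdb(model: StructureModel) -> str:
    """Serialize a model back to PDB-format text (coordinate records only)."""
    lines = []
    for a in model.atoms:
        rec = "ATOM  " if a.record_kind == "polymer" else "HETATM"
        name = a.atom_name
        # wwPDB alignment: 1-3 char names of 1-letter elements start at col 14.
        if len(name) < 4 and len(a.element) == 1:
            name = " " + name
        lines.append(
            f"{rec}{a.serial:>5d} {name:<4s}{a.alt_loc or ' ':1s}{a.residue_name:>3s} "
            f"{a.chain_id:1s}{a.residue_number:>4d}{a.insertion_code or ' ':1s}   "
            f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}          "
            f"{a.element.upper():>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def strip_hydrogens(model: StructureModel) -> StructureModel:
    """Remove hydrogen and deuterium atoms, preserving order of the rest."""
    heavy = [a for a in model.atoms if a.element.upper() not in ("H", "D")]
    return StructureModel(structure_id=model.structure_id, atoms=heavy,
                          model_number=model.model_number)


def _require_chain(model: StructureModel, chain_id: str) -> None:
    if chain_id not in model.chains():
        raise KeyError(
            f"chain {chain_id!r} not present in {model.structure_id!r}; "
            f"available: {sorted(model.chains())}"
        )


def extract_ligands(model: StructureModel, chain_id: str) -> list[LigandInstance]:
    """Hetero residues of the chain that qualify as ligands.

    Excluded: water, standard amino acids (covers modified-residue records
    kept in the polymer), and hetero groups with fewer than
    :data:`MIN_LIGAND_ATOMS` heavy atoms (experimental artifacts).
    """
    _require_chain(model, chain_id)
    groups: dict[tuple, list[AtomRecord]] = {}
    for atom in model.atoms:
        if atom.record_kind != "hetero" or atom.chain_id != chain_id:
            continue
        if atom.residue_name in WATER_NAMES or atom.residue_name in STANDARD_AMINO_ACIDS:
            continue
        groups.setdefault(atom.residue_key, []).append(atom)
    ligands = []
    for (chain, name, number, _icode), atoms in groups.items():
        if len(atoms) < MIN_LIGAND_ATOMS:
            logger.info("dropping artifact ligand %s %s%d (%d heavy atoms < %d)",
                        name, chain, number, len(atoms), MIN_LIGAND_ATOMS)
            continue
        ligands.append(LigandInstance(ligand_name=name, residue_number=number,
                                      chain_id=chain, atoms=atoms))
    return ligands


def protein_atoms(model: StructureModel, chain_id: str) -> list[AtomRecord]:
    """Polymer-record atoms of standard amino acids on the chain.

    Modified residues recorded as HETATM (e.g. MSE) are excluded: their
    physicochemical typing is undefined in the residue table.
    """
    _require_chain(model, chain_id)
    return [
        a for a in model.atoms
        if a.record_kind == "polymer"
        and a.chain_id == chain_id
        and a.residue_name in STANDARD_AMINO_ACIDS
    ]


def iter_residues(atoms: Iterable[AtomRecord]):
    """Group atoms by residue, preserving first-seen order."""
    groups: dict[tuple, list[AtomRecord]] = {}
    for atom in atoms:
        groups.setdefault(atom.residue_key, []).append(atom)
    yield from groups.items()
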