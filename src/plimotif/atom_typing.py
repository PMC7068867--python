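"""Physicochemical typing of protein and ligand heavy atoms.

Every atom that may participate in an interface edge carries a set of types
from a closed six-symbol vocabulary: acceptor, aromatic, donor, hydrophobic,
negative, positive.  Protein atoms are typed by table lookup (the packaged
table encodes standard pharmacophore conventions for the 20 amino acids at
pH 7); ligand atoms are typed by rule-based perception on the heavy-atom
geometry -- covalent bonds from covalent radii, aromatic rings from planar
5/6-rings, protonation states from pH-7 heuristics -- with an optional
per-(het code, atom name) override table taking precedence.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional

import numpy as np
import networkx as nx

from plimotif.structure_io import AtomRecord, LigandInstance

logger = logging.getLogger(__name__)

#: The closed vocabulary, in canonical (alphabetical) order.
PHYSCHEM_TYPES = ("acceptor", "aromatic", "donor", "hydrophobic", "negative", "positive")

#: Two-letter codes used in feature names and compact output.
TYPE_CODES = {
    "acceptor": "ACC",
    "aromatic": "ARO",
    "donor": "DON",
    "hydrophobic": "HP",
    "negative": "NEG",
    "positive": "POS",
}
CODE_TYPES = {v: k for k, v in TYPE_CODES.items()}


class TypingError(KeyError):
    """Raised when a (residue, atom) pair has no table entry."""


@dataclass(frozen=True)
class TypedAtom:
    """A heavy atom with its molecule role and physicochemical type set."""

    atom: AtomRecord
    molecule_role: str  # "protein" | "ligand"
    types: frozenset[str]

    @property
    def sorted_types(self) -> tuple[str, ...]:
        return tuple(sorted(self.types))

    @property
    def mining_label(self) -> str:
        """Node label used for mining: role prefix + sorted type set."""
        prefix = "P" if self.molecule_role == "protein" else "L"
        return f"{prefix}:{','.join(self.sorted_types)}"


class TypingTable:
    """Mapping (residue_name, atom_name) -> frozenset of types.

    A residue name of ``*`` acts as a wildcard (used for the C-terminal
    carboxylate oxygen OXT, which can follow any residue).
    """

    def __init__(self, entries: Mapping[tuple[str, str], Iterable[str]] | None = None):
        self._entries: dict[tuple[str, str], frozenset[str]] = {}
        if entries:
            for (res, atom), types in entries.items():
                self.add(res, atom, types)

    def add(self, residue_name: str, atom_name: str, types: Iterable[str]) -> None:
        tset = frozenset(types)
        bad = tset - set(PHYSCHEM_TYPES)
        if bad:
            raise ValueError(f"unknown physicochemical types {sorted(bad)} for "
                             f"({residue_name}, {atom_name})")
        self._entries[(residue_name.upper(), atom_name.upper())] = tset

    def __contains__(self, key: tuple[str, str]) -> bool:
        res, atom = key
        return (res.upper(), atom.upper()) in self._entries or ("*", atom.upper()) in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def lookup(self, residue_name: str, atom_name: str) -> frozenset[str]:
        key = (residue_name.upper(), atom_name.upper())
        if key in self._entries:
            return self._entries[key]
        wild = ("*", atom_name.upper())
        if wild in self._entries:
            return self._entries[wild]
        raise TypingError(f"no typing entry for residue {residue_name!r}, atom {atom_name!r}")

    def get(self, residue_name: str, atom_name: str) -> Optional[frozenset[str]]:
        try:
            return self.lookup(residue_name, atom_name)
        except TypingError:
            return None

    def residues(self) -> set[str]:
        return {res for res, _ in self._entries}


def load_typing_table(text: str) -> TypingTable:
    """Parse the tab-separated typing-table format.

    Columns: residue_name, atom_name, comma-separated types ('-' = empty);
    '#' starts a comment.
    """
    table = TypingTable()
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"typing table line {line_no}: expected 3 tab-separated "
                             f"columns, got {len(parts)}: {raw!r}")
        res, atom, types_field = (p.strip() for p in parts)
        types = [] if types_field == "-" else [t.strip() for t in types_field.split(",")]
        table.add(res, atom, types)
    return table


def default_typing_table() -> TypingTable:
    """The packaged protein typing table."""
    text = resources.files("plimotif.data").joinpath("protein_atom_types.tsv").read_text()
    return load_typing_table(text)


def type_protein_atom(residue_name: str, atom_name: str, table: TypingTable) -> frozenset[str]:
    """Table lookup for one protein heavy atom; may be empty (no edges)."""
    return table.lookup(residue_name, atom_name)


def type_protein_atoms(atoms: Iterable[AtomRecord], table: TypingTable) -> list[TypedAtom]:
    return [TypedAtom(atom=a, molecule_role="protein",
                      types=type_protein_atom(a.residue_name, a.atom_name, table))
            for a in atoms]


# --------------------------------------------------------------------------
# Ligand perception
# --------------------------------------------------------------------------

# Single-bond covalent radii (Å); bonds are perceived when
# d <= r_i + r_j + BOND_TOLERANCE.
_COVALENT_RADII = {
    "C": 0.77, "N": 0.75, "O": 0.73, "P": 1.10, "S": 1.03, "B": 0.82,
    "F": 0.71, "Cl": 0.99, "Br": 1.14, "I": 1.33, "Se": 1.17, "Si": 1.11,
}
_BOND_TOLERANCE = 0.45
_HALOGENS = {"F", "Cl", "Br", "I"}

# A C-O bond shorter than this is treated as a double bond (carbonyl);
# longer single bonds indicate hydroxyl/ether oxygens.
_CARBONYL_CO_MAX = 1.30

# Maximum RMS deviation (Å) from the best-fit plane for a ring to count
# as aromatic.
_PLANARITY_TOL = 0.15


def perceive_bonds(atoms: list[AtomRecord]) -> nx.Graph:
    """Covalent bond graph of a ligand from heavy-atom distances."""
    g = nx.Graph()
    coords = np.array([a.coord for a in atoms])
    for i, a in enumerate(atoms):
        g.add_node(i, element=a.element, name=a.atom_name)
    for i, j in itertools.combinations(range(len(atoms)), 2):
        ri = _COVALENT_RADII.get(atoms[i].element)
        rj = _COVALENT_RADII.get(atoms[j].element)
        if ri is None or rj is None:
            continue
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if 0.4 < d <= ri + rj + _BOND_TOLERANCE:
            g.add_edge(i, j, distance=d)
    return g


def _is_planar(coords: np.ndarray) -> bool:
    centered = coords - coords.mean(axis=0)
    # Smallest singular value = RMS-ish deviation from the best-fit plane.
    sv = np.linalg.svd(centered, compute_uv=False)
    return sv[-1] / np.sqrt(len(coords)) < _PLANARITY_TOL


def aromatic_atoms(atoms: list[AtomRecord], bonds: nx.Graph) -> set[int]:
    """Indices of atoms in planar 5/6-membered rings of C/N/O/S.

    Geometric aromaticity: without hydrogens or bond orders, planarity of
    the ring plus sp2-compatible connectivity (ring carbons with at most
    three heavy neighbours) is the usable signal.
    """
    aromatic: set[int] = set()
    for ring in nx.cycle_basis(bonds):
        if len(ring) not in (5, 6):
            continue
        if not all(atoms[i].element in ("C", "N", "O", "S") for i in ring):
            continue
        if any(atoms[i].element == "C" and bonds.degree(i) > 3 for i in ring):
            continue
        coords = np.array([atoms[i].coord for i in ring])
        if _is_planar(coords):
            aromatic.update(ring)
    return aromatic


def _type_oxygen(i: int, atoms: list[AtomRecord], bonds: nx.Graph,
                 aromatic: set[int]) -> set[str]:
    nbrs = list(bonds.neighbors(i))
    types: set[str] = set()
    if i in aromatic:
        types.add("aromatic")
    if len(nbrs) == 0:
        return types | {"acceptor"}
    if len(nbrs) >= 2:
        # Ether / ester / bridging phosphate oxygen: weak acceptor.
        return types | {"acceptor"}
    j = nbrs[0]
    el = atoms[j].element
    if el in ("P", "S"):
        # Terminal oxygen of a phosphate/sulfate-like group: at pH 7 the
        # terminal oxygens share the negative charge.
        return types | {"acceptor", "negative"}
    if el == "N":
        return types | {"acceptor", "negative"}  # N-oxide
    if el == "C":
        carbon_oxygens = [k for k in bonds.neighbors(j)
                          if atoms[k].element == "O" and bonds.degree(k) == 1]
        if len(carbon_oxygens) >= 2:
            return types | {"acceptor", "negative"}  # carboxylate
        if bonds.edges[i, j]["distance"] <= _CARBONYL_CO_MAX:
            return types | {"acceptor"}  # carbonyl
        return types | {"donor", "acceptor"}  # hydroxyl
    return types | {"acceptor"}


def _type_nitrogen(i: int, atoms: list[AtomRecord], bonds: nx.Graph,
                   aromatic: set[int]) -> set[str]:
    nbrs = list(bonds.neighbors(i))
    types: set[str] = set()
    if i in aromatic:
        types.add("aromatic")
        ring_nbrs = [j for j in nbrs if j in aromatic]
        if len(nbrs) == 2 and len(ring_nbrs) == 2:
            # Pyridine-like ring nitrogen: lone pair in plane.
            types.add("acceptor")
        # Three-coordinate ring N (pyrrole-like with a substituent): no
        # H and no accessible lone pair; aromatic only.
        return types

    def is_carbonyl_carbon(j: int) -> bool:
        return atoms[j].element == "C" and any(
            atoms[k].element == "O" and bonds.degree(k) == 1
            and bonds.edges[j, k]["distance"] <= _CARBONYL_CO_MAX
            for k in bonds.neighbors(j)
        )

    def is_guanidinium_carbon(j: int) -> bool:
        return atoms[j].element == "C" and sum(
            1 for k in bonds.neighbors(j) if atoms[k].element == "N") >= 3

    if any(is_guanidinium_carbon(j) for j in nbrs):
        return types | {"donor", "positive"}
    if any(is_carbonyl_carbon(j) for j in nbrs):
        # Amide nitrogen: H-bond donor, not protonated at pH 7.
        return types | {"donor"} if len(nbrs) <= 2 else types
    if any(j in aromatic for j in nbrs):
        # Aniline-like exocyclic amine: donor, weakly basic.
        return types | {"donor"} if len(nbrs) <= 2 else types
    # Aliphatic amine: protonated at pH 7.
    if len(nbrs) <= 2:
        return types | {"donor", "positive"}
    return types | {"positive"}


def perceive_ligand_types(atoms: list[AtomRecord]) -> list[frozenset[str]]:
    """Rule-based type perception for one ligand's heavy atoms."""
    bonds = perceive_bonds(atoms)
    aromatic = aromatic_atoms(atoms, bonds)
    out: list[frozenset[str]] = []
    for i, a in enumerate(atoms):
        el = a.element
        types: set[str] = set()
        if el == "C":
            if i in aromatic:
                types.add("aromatic")
            nbr_elements = {atoms[j].element for j in bonds.neighbors(i)}
            if nbr_elements <= {"C", "S", "H"} and bonds.degree(i) > 0:
                types.add("hydrophobic")
        elif el == "O":
            types = _type_oxygen(i, atoms, bonds, aromatic)
        elif el == "N":
            types = _type_nitrogen(i, atoms, bonds, aromatic)
        elif el == "S":
            if i in aromatic:
                types.add("aromatic")
            elif bonds.degree(i) >= 2:
                types.add("hydrophobic")  # thioether
        elif el in _HALOGENS:
            types.add("hydrophobic")
        elif el == "P":
            pass  # phosphorus itself carries no pharmacophore type here
        else:
            logger.warning("no typing rule for element %s (atom %s); typed empty",
                           el, a.atom_name)
        out.append(frozenset(types))
    return out


def type_ligand_atoms(ligand: LigandInstance,
                      overrides: Optional[TypingTable] = None) -> list[TypedAtom]:
    """Type every heavy atom of a ligand instance.

    Overrides are keyed (het code, atom name) and replace the rule result
    entirely when present.
    """
    perceived = perceive_ligand_types(ligand.atoms)
    typed = []
    for atom, types in zip(ligand.atoms, perceived):
        if overrides is not None:
            override = overrides.get(ligand.ligand_name, atom.atom_name)
            if override is not None:
                types = override
        typed.append(TypedAtom(atom=atom, molecule_role="ligand", types=types))
    return typed
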