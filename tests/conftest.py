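import pytest
from hypothesis import settings

from plimotif.atom_typing import default_typing_table

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from plimotif.fixtures import InterfaceContact, make_profile_dataset


@pytest.fixture(scope="session")
def typing_table():
    return default_typing_table()


#: Two engineered interaction-profile families used across tests: one
#: hydrogen-bond/hydrophobic/aromatic profile, one charged profile with a
#: shared ligand atom that yields a connected 3-node repulsive motif.
FAMILY_A = (
    InterfaceContact("SER", "OG", ("acceptor",), 2.5),
    InterfaceContact("LEU", "CD1", ("hydrophobic",), 3.5),
    InterfaceContact("PHE", "CZ", ("aromatic", "hydrophobic"), 3.4),
)
FAMILY_B = (
    InterfaceContact("ASP", "OD1", ("acceptor", "negative"), 5.0, ligand_atom="O1G"),
    InterfaceContact("GLU", "OE1", ("acceptor", "negative"), 5.0, ligand_atom="O1G"),
    InterfaceContact("LYS", "NZ", ("acceptor", "negative"), 4.0),
)


@pytest.fixture(scope="session")
def family_dataset(tmp_path_factory):
    """(structures list, override table) for the two-family fixture set."""
    root = tmp_path_factory.mktemp("family_pdbs")
    entries, overrides = make_profile_dataset({"A": list(FAMILY_A), "B": list(FAMILY_B)}, 3)
    structures = []
    for sid, text, chain in entries:
        p = root / f"{sid}.pdb"
        p.write_text(text)
        structures.append((str(p), chain))
    overrides_path = root / "overrides.tsv"
    lines = [f"{res}\t{atom}\t{','.join(sorted(types)) or '-'}"
             for (res, atom), types in sorted(overrides._entries.items())]
    overrides_path.write_text("\n".join(lines) + "\n")
    return structures, overrides, str(overrides_path)
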