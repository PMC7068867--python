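# Methods

`plimotif` detects conserved interaction motifs at protein–ligand
interfaces. This note documents the model behind each stage, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the known limitations.

## Interface graphs

Each (protein chain, ligand instance) pair is modelled as an undirected
labeled bipartite multigraph G = (P, L, E): P are protein heavy atoms, L
ligand heavy atoms, and every edge in E joins P to L. Hydrogens (element
H or D) are removed before any contact computation so that X-ray and
neutron/NMR structures are treated alike; only the first model of a
multi-model file is used, and alternate locations are collapsed to the
highest-occupancy conformer (ties to the alphabetically first label), so
each atom has one coordinate. Hetero groups with fewer than 6 heavy atoms
are treated as crystallization artifacts (sulfate, glycerol, ...) and
never become ligands; water (HOH/DOD/WAT) is excluded outright, as
water-mediated interactions are out of scope. Ligand instances are keyed
by (het code, residue number, chain), so two copies of the same compound
give two graphs. Modified residues recorded as HETATM inside the polymer
(e.g. MSE) are neither protein nor ligand by default because the typing
table does not cover them; an override entry restores them if desired.

A contact is any cross pair (i ∈ P, j ∈ L) with Euclidean distance
d(i, j) ≤ 6.0 Å (the largest criteria window). Contacts are classified by
the endpoint type sets and per-class inclusive distance windows:

| interaction       | condition                    | window (Å) |
|-------------------|------------------------------|------------|
| aromatic stacking | both aromatic                | 1.5 – 3.5  |
| hydrogen bond     | an acceptor and a donor      | 2.0 – 3.0  |
| hydrophobic       | both hydrophobic             | 2.0 – 3.8  |
| repulsive         | same formal charge           | 2.0 – 6.0  |
| salt bridge       | opposite formal charge       | 2.0 – 6.0  |

Every window bound is compared with `<=` in exact floating point; users
can override any window. A pair satisfying several conditions yields one
parallel edge per satisfied class rather than a single prioritized edge —
downstream filtering by edge class then loses nothing. Aromatic stacking
is evaluated atom-pairwise, not per ring centroid, because the criteria
are stated per atom pair; the printed 1.5 Å lower bound admits physically
implausible clashes and is implemented as stated. Covalently bound
ligands are not special-cased and will contribute short-distance edges
(documented limitation). Distances are reported to 0.01 Å.

## Atom typing

Types come from a closed six-symbol vocabulary: acceptor, aromatic,
donor, hydrophobic, negative, positive; an atom may carry several.

Protein atoms are typed by table lookup. The packaged table
(`data/protein_atom_types.tsv`) encodes standard pH-7 pharmacophore
conventions for all heavy atoms of the 20 standard amino acids: backbone
amide N donor (except PRO), carbonyl O acceptor, Cα and carbonyl C
untyped; carboxylates of ASP/GLU acceptor+negative; LYS NZ and the ARG
guanidinium nitrogens donor+positive; HIS ring nitrogens
donor+acceptor (the neutral tautomer is the pH-7 default — no positive
charge); SER/THR/TYR hydroxyls donor+acceptor; aliphatic carbons bonded
only to C/S hydrophobic; ring atoms of PHE/TYR/TRP/HIS aromatic, with
ring carbons adjacent to ring nitrogens or hydroxyls losing the
hydrophobic flag. A wildcard residue `*` covers the C-terminal OXT. The
table is a plain TSV so a user with a preferred convention can substitute
their own file verbatim.

Ligand atoms are typed by rule-based perception on heavy-atom geometry,
since input files carry neither hydrogens nor bond orders:

- covalent bonds where d ≤ r_i + r_j + 0.45 Å (single-bond covalent radii);
- aromatic rings are planar (RMS plane deviation < 0.15 Å) 5/6-rings of
  C/N/O/S whose carbons have ≤ 3 heavy neighbours;
- carbons bonded only to C/S are hydrophobic;
- a terminal oxygen on P/S is acceptor+negative (ionized
  phosphate/sulfate at pH 7), terminal oxygens of a carboxylate likewise;
  a C–O bond ≤ 1.30 Å marks a carbonyl (acceptor), longer single bonds a
  hydroxyl (donor+acceptor); two-coordinate oxygens are weak acceptors;
- pyridine-like ring nitrogens (two ring neighbours) are
  aromatic+acceptor; three-coordinate ring nitrogens aromatic only;
  amide and aniline-like nitrogens donor; aliphatic amines and
  guanidinium nitrogens donor+positive (protonated at pH 7);
- halogens are hydrophobic; metals and other elements receive an empty
  type set with a logged warning and simply form no edges.

This is a fixed-pH heuristic, not a titration model: no pKa prediction,
no tautomer enumeration, no partial charges. An override table keyed
(het code, atom name) replaces the rule result entirely where present,
which both restores exactness for curated compounds and lets synthetic
fixtures bypass perception. The perception rules are cross-checked in the
test suite against RDKit's pharmacophore feature factory on small
analogue molecules.

## Path features and clustering

Each graph is summarised by binary (property, path length, property)
features: `HP-4-HP` means two hydrophobic atoms joined by some simple
(node-repetition-free) path of four edges. All simple paths up to a cap
are enumerated — not only shortest paths — because presence features make
the more inclusive reading harmless; the cap (default 10 edges,
configurable, recorded in run metadata) bounds the exponential worst
case. A node with t types contributes each type independently at either
endpoint; endpoint order is canonicalized lexicographically; parallel
edges do not multiply paths (a path is a node sequence); molecule role is
deliberately not part of the key. Features are presence bits, not counts.

The graph × feature matrix is reduced by SVD: rows are embedded as U·S
truncated to the smallest rank capturing 90% of squared singular-value
mass, capped at min(n−1, 100). Signs are fixed so each component's
largest-magnitude loading is positive, making the embedding reproducible.
Graphs are then grouped by one of three algorithms — PAM k-medoids
(deterministic greedy BUILD plus SWAP hill-climbing, Euclidean distances,
seed used only when duplicate points make BUILD indifferent; the
default), Ward agglomerative, or spectral with RBF affinity whose
bandwidth is set from the median pairwise distance — and scored by the
average silhouette width (default) or the Calinski–Harabasz index. The
best k in 2..min(15, n−1) wins, ties toward smaller k. Degenerate
conventions: a per-point silhouette is 0 when max(a, b) = 0, singleton
clusters contribute 0, and a labeling with fewer than two non-empty
groups scores −∞ so model selection never chooses it. The k range is a
documented default, not a derived quantity.

## Motif mining

Frequent connected subgraphs are mined per cluster with gSpan: patterns
grow by rightmost extension of DFS codes, and each pattern is explored
exactly once because only minimal DFS codes are expanded. support(g) is
the number of dataset graphs containing g; the threshold is
ceil(fraction × n) ("at least" semantics), swept by default over
0.1..1.0 in steps of 0.1. Node labels serialize the molecule role plus
the sorted type set (`L:acceptor,negative`), so typing combinations stay
distinct and protein/ligand sides never merge; parallel typed edges are
kept as distinct labeled edges, with DFS codes tracking concrete edge
identities so a backward extension may revisit a node pair through a
second, differently-labeled edge. The minimum motif is one edge;
single-node patterns are not reported. Pattern growth can be truncated
by an edge cap (the pipeline default is 12 edges) to bound worst-case
search on low support fractions.

Within one (cluster, fraction) result set only maximal motifs are kept:
a motif subgraph-isomorphic to another reported motif of the same run is
dropped (no information is lost — it is contained in what remains).
Containment and mapping use VF2 subgraph monomorphism with exact label
equality on nodes and sub-multiset matching on parallel edge labels.
Mapping a motif onto an input graph enumerates all placements, collapsed
to one per node-image set so automorphic re-labelings of the same atoms
count once; enumeration is capped at 10,000 placements per (motif,
graph) with a logged truncation. Per-ligand-atom statistics count
(placement, motif edge) incidences on each ligand atom name and the
number of distinct graphs contributing at least one incidence — the
"interactions in N input graphs" reading of motif edge incidences, since
a looser "all graph edges on that atom" reading would not be tied to the
motif. The miner is verified against a shipped brute-force
frequent-connected-subgraph enumerator (exhaustive edge-subset growth
with permutation-canonical certificates), and the mapper against a
brute-force injective-map enumerator, both deliberately independent of
the production code paths.

## Synthetic data

Two generators define the test and acceptance conditions.

`make_profile_complex` emits PDB text whose interface realizes a chosen
contact list exactly: each new ligand atom sits in its own slot 25 Å from
the others (so no unintended pair enters any window), protein partners
fan out around shared ligand atoms, distances are validated to 0.001 Å,
and fillers pad the ligand to the six-atom minimum. The protein side uses
real residue/atom names so table typing runs unmodified; the ligand side
uses a synthetic het code with an override table, exercising the override
path. The two-family dataset used throughout (three complexes per
family; one hydrogen-bond/hydrophobic/aromatic profile, one charged
profile whose shared acceptor/negative ligand atom is contacted by two
like-charged protein atoms, giving a connected double-repulsive motif)
deliberately emulates the separation structure of real interface
families, not their geometry: bond lengths, angles, packing and the
chemistry of real ligands are absent, so passing tests demonstrate the
correctness of the graph/mining machinery, not typing accuracy on real
compounds.

`make_planted_dataset` draws labeled bipartite multigraphs with a 5-node
motif planted in exactly round(plant_fraction × n) graphs (default 20
graphs, fraction 0.7, 3 seeded noise edges per graph); non-planted
graphs are verified motif-free and their noise resampled otherwise. All
generation is deterministic under the seed.

Problem sizes in the default test run and the acceptance script — 50
random datasets of 3–6 graphs with ≤ 8 nodes each for the miner/mapper
oracle comparisons, 20 seeds of 20 graphs for planted recovery, 6
complexes for the end-to-end run — were chosen so that exhaustive
brute-force enumeration remains exact and the whole suite completes in
well under a minute; they are the package's own verification scale.

## Known limitations

- Ligand typing is heuristic; exactness on real compounds depends on the
  override table. Aromaticity detection is geometric and will miss
  distorted rings or accept fortuitously planar ones.
- No angle term for hydrogen bonds, no halogen bonds, no cation–π, no
  water-mediated interactions, no ring-centroid stacking geometry.
- Covalent protein–ligand links produce spurious short-distance edges.
- Simple-path feature enumeration is exponential without the length cap;
  dense pathological interfaces may need a lower cap.
- gSpan on very low support fractions over large clusters can be
  expensive; the edge cap truncates pattern growth there.
- Reading mmCIF, biological-assembly expansion, and symmetry mates are
  out of scope; inputs are single-conformer PDB files.
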