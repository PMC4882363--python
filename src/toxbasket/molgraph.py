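"""Heavy-atom molecular graphs with the atom descriptors atom-pair fingerprints need.

Structures are parsed with RDKit (aromaticity perceived, nitro groups
normalized to the charge-separated form by the sanitizer) and reduced to a
light-weight graph of heavy atoms.  Each atom carries the three-part
descriptor used downstream: element symbol, heavy-neighbor count, and a
pi-electron count in {0, 1, 2}.

The pi-electron count of an atom is::

    min(2, n_double_bonds + 2 * n_triple_bonds + (1 if aromatic else 0))

so an aromatic ring carbon has 1 pi electron, a carbonyl/nitro oxygen has 1,
a nitrile nitrogen has 2, and sp3 atoms have 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx
from rdkit import Chem
from rdkit import RDLogger

__all__ = [
    "AtomNode",
    "MolecularGraph",
    "ParseError",
    "parse_smiles",
    "topological_distances",
    "read_smiles_file",
    "read_sdf",
]

RDLogger.DisableLog("rdApp.*")


class ParseError(ValueError):
    """A structure could not be parsed; carries the offending chemical id."""

    def __init__(self, chem_id: str, message: str):
        super().__init__(f"chemical {chem_id!r}: {message}")
        self.chem_id = chem_id


@dataclass(frozen=True)
class AtomNode:
    """Descriptor of one heavy atom: element, heavy-atom degree, pi electrons."""

    element: str
    heavy_neighbors: int
    pi_electrons: int

    def __post_init__(self) -> None:
        if self.heavy_neighbors < 0:
            raise ValueError("heavy_neighbors must be >= 0")
        if self.pi_electrons not in (0, 1, 2):
            raise ValueError("pi_electrons must be in {0, 1, 2}")


@dataclass(frozen=True)
class MolecularGraph:
    """Connected heavy-atom graph of a single chemical.

    ``bonds`` holds undirected edges ``(i, j, order)`` with ``i < j`` and
    order one of 1, 2, 3 or the string ``"ar"`` for aromatic bonds.
    """

    id: str
    atoms: tuple[AtomNode, ...]
    bonds: tuple[tuple[int, int, object], ...] = field(default=())

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        for i, j, order in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"invalid bond endpoints ({i}, {j})")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)
            if order not in (1, 2, 3, "ar"):
                raise ValueError(f"invalid bond order {order!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def degree(self, i: int) -> int:
        return sum(1 for a, b, _ in self.bonds if i in (a, b))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from((i, j) for i, j, _ in self.bonds)
        return g


_PI_CAP = 2

_BOND_ORDERS = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: "ar",
}


def _pi_electrons(atom: Chem.Atom) -> int:
    n_double = sum(
        1 for b in atom.GetBonds() if b.GetBondType() == Chem.BondType.DOUBLE
    )
    n_triple = sum(
        1 for b in atom.GetBonds() if b.GetBondType() == Chem.BondType.TRIPLE
    )
    return min(_PI_CAP, n_double + 2 * n_triple + (1 if atom.GetIsAromatic() else 0))


def _from_rdkit(mol: Chem.Mol, chem_id: str) -> MolecularGraph:
    """Build a MolecularGraph from a sanitized RDKit mol, keeping the largest fragment."""
    mol = Chem.RemoveHs(mol)
    frags = Chem.GetMolFrags(mol)
    if not frags or mol.GetNumAtoms() == 0:
        raise ParseError(chem_id, "no heavy atoms after fragment selection")
    # largest fragment; GetMolFrags preserves writing order, so on ties the
    # fragment appearing first in the input wins
    best = max(frags, key=len)
    keep = set(best)
    index = {old: new for new, old in enumerate(best)}

    atoms = []
    for old in best:
        a = mol.GetAtomWithIdx(old)
        heavy = sum(1 for nb in a.GetNeighbors() if nb.GetIdx() in keep)
        atoms.append(AtomNode(a.GetSymbol(), heavy, _pi_electrons(a)))
    bonds = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in keep and j in keep:
            ni, nj = index[i], index[j]
            if ni > nj:
                ni, nj = nj, ni
            bonds.append((ni, nj, _BOND_ORDERS[b.GetBondType()]))
    return MolecularGraph(id=chem_id, atoms=tuple(atoms), bonds=tuple(sorted(bonds, key=lambda t: (t[0], t[1]))))


def parse_smiles(smiles: str, chem_id: str = "") -> MolecularGraph:
    """Parse a SMILES string into a heavy-atom :class:`MolecularGraph`.

    Aromaticity is perceived and nitro groups are normalized to the
    charge-separated form.  For disconnected inputs (salts) only the fragment
    with the most heavy atoms is kept.

    Raises :class:`ParseError` for unparsable or heavy-atom-free input.
    """
    if not smiles or not smiles.strip():
        raise ParseError(chem_id, "empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(chem_id, f"unparsable SMILES {smiles!r}")
    return _from_rdkit(mol, chem_id)


def topological_distances(g: MolecularGraph) -> dict[tuple[int, int], int]:
    """All-pairs shortest-path bond counts of a connected graph.

    Returns a dense mapping ``(i, j) -> distance`` for every ordered pair,
    with ``distance(i, i) = 0``.
    """
    nxg = g.to_networkx()
    dist: dict[tuple[int, int], int] = {}
    for i, lengths in nx.all_pairs_shortest_path_length(nxg):
        for j, d in lengths.items():
            dist[(i, j)] = d
    if len(dist) != g.n_atoms**2:
        raise ValueError(f"graph {g.id!r} is not connected")
    return dist


def read_smiles_file(path: str | Path) -> Iterator[MolecularGraph]:
    """Read a SMILES file: one record per line, ``SMILES<whitespace>id``.

    Blank lines are skipped; a missing id defaults to the line number.
    """
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            chem_id = parts[1].strip() if len(parts) > 1 else f"line{lineno}"
            yield parse_smiles(smiles, chem_id)


def read_sdf(path: str | Path) -> Iterator[MolecularGraph]:
    """Read a V2000 SDF; the molecule title (or record index) is the id."""
    supplier = Chem.SDMolSupplier(str(path), removeHs=True)
    for idx, mol in enumerate(supplier):
        chem_id = f"record{idx}"
        if mol is None:
            raise ParseError(chem_id, "unparsable SDF record")
        title = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        yield _from_rdkit(mol, title.strip() or chem_id)


def parse_structures(graphs: Iterable[MolecularGraph]) -> dict[str, MolecularGraph]:
    """Collect graphs into an id-keyed dict, rejecting duplicate ids."""
    out: dict[str, MolecularGraph] = {}
    for g in graphs:
        if g.id in out:
            raise ValueError(f"duplicate chemical id {g.id!r}")
        out[g.id] = g
    return out
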