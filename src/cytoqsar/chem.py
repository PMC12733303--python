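"""Structure parsing, standardization and curation filters.

Every downstream stage (activity curation, descriptors, modelling) consumes
the :class:`MoleculeGraph` produced here.  The curation policy mirrors the
dataset-construction rules used for cell-line cytotoxicity training sets:
records that are mixtures, carry a net formal charge, are inorganic, or
exceed a molecular-mass cutoff (default 1250 Da, strict) are removed rather
than repaired.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "MoleculeGraph",
    "CurationVerdict",
    "ParseError",
    "parse_structure",
    "molecular_weight",
    "curate_structure",
    "canonical_key",
    "read_structures_csv",
    "read_smiles_file",
    "read_sdf",
    "write_curated_csv",
]

HALOGENS = frozenset({"F", "Cl", "Br", "I"})

CurationReason = Literal["ok", "mixture", "charged", "inorganic", "overweight", "parse_error"]


class ParseError(ValueError):
    """Raised when a structure string cannot be interpreted."""

    def __init__(self, text: str, message: str = "unparsable structure"):
        self.text = text
        super().__init__(f"{message}: {text!r}")


@dataclass(frozen=True)
class Atom:
    element: str
    formal_charge: int
    n_hydrogens: int
    aromatic: bool


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: float  # 1, 2, 3 or 1.5 for aromatic


@dataclass(frozen=True)
class MoleculeGraph:
    """Immutable heavy-atom graph with explicit hydrogen counts.

    All descriptor and curation computations are pure functions of this
    graph; the underlying RDKit molecule is retained only as a cached
    handle for mass/logP/canonicalisation queries.
    """

    atoms: tuple[Atom, ...]
    bonds: tuple[Bond, ...]
    source: str
    _rdmol: Chem.Mol = field(repr=False, compare=False, hash=False)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ValueError(f"bond ({b.i},{b.j}) indexes outside {n} atoms")
            if b.i == b.j:
                raise ValueError(f"self-bond on atom {b.i}")
        for a in self.atoms:
            if a.n_hydrogens < 0:
                raise ValueError("negative hydrogen count")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, i: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.i == i:
                out.append(b.j)
            elif b.j == i:
                out.append(b.i)
        return out

    def adjacency_lists(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in self.atoms]
        for b in self.bonds:
            adj[b.i].append(b.j)
            adj[b.j].append(b.i)
        return adj


@dataclass(frozen=True)
class CurationVerdict:
    accepted: bool
    reason: CurationReason

    def __post_init__(self) -> None:
        if self.accepted != (self.reason == "ok"):
            raise ValueError("accepted must hold exactly when reason == 'ok'")


_BOND_ORDER = {
    Chem.BondType.SINGLE: 1.0,
    Chem.BondType.DOUBLE: 2.0,
    Chem.BondType.TRIPLE: 3.0,
    Chem.BondType.AROMATIC: 1.5,
}


def _from_rdkit(mol: Chem.Mol, source: str) -> MoleculeGraph:
    atoms = tuple(
        Atom(
            element=a.GetSymbol(),
            formal_charge=a.GetFormalCharge(),
            n_hydrogens=a.GetTotalNumHs(),
            aromatic=a.GetIsAromatic(),
        )
        for a in mol.GetAtoms()
    )
    bonds = tuple(
        Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _BOND_ORDER.get(b.GetBondType(), 1.0))
        for b in mol.GetBonds()
    )
    return MoleculeGraph(atoms=atoms, bonds=bonds, source=source, _rdmol=mol)


def parse_structure(text: str) -> MoleculeGraph:
    """Parse a SMILES string or a MOL block into a :class:`MoleculeGraph`.

    MOL blocks are recognised by embedded newlines. Raises
    :class:`ParseError` on malformed input.
    """
    if not text or not text.strip():
        raise ParseError(text, "empty structure")
    if "\n" in text:
        mol = Chem.MolFromMolBlock(text, sanitize=True)
    else:
        mol = Chem.MolFromSmiles(text, sanitize=True)
    if mol is None:
        raise ParseError(text)
    return _from_rdkit(mol, text)


def molecular_weight(mol: MoleculeGraph) -> float:
    """Average molecular weight in Daltons, implicit hydrogens included."""
    return float(Descriptors.MolWt(mol._rdmol))


def _n_components(mol: MoleculeGraph) -> int:
    n = mol.n_atoms
    if n == 0:
        return 0
    adj = mol.adjacency_lists()
    seen = [False] * n
    comps = 0
    for start in range(n):
        if seen[start]:
            continue
        comps += 1
        stack = [start]
        seen[start] = True
        while stack:
            v = stack.pop()
            for w in adj[v]:
                if not seen[w]:
                    seen[w] = True
                    stack.append(w)
    return comps


def _is_organic(mol: MoleculeGraph) -> bool:
    # organic: at least one carbon with a C-C or C-H bond
    for i, a in enumerate(mol.atoms):
        if a.element != "C":
            continue
        if a.n_hydrogens > 0:
            return True
        if any(mol.atoms[j].element == "C" for j in mol.neighbors(i)):
            return True
    return False


def curate_structure(mol: MoleculeGraph, max_mass: float = 1250.0) -> CurationVerdict:
    """Apply the record-removal filters in fixed order.

    Order: mixture (multiple fragments, no desalting attempted) -> net
    formal charge != 0 -> inorganic (no carbon, or carbon without any C-C
    or C-H bond) -> mass strictly above ``max_mass``.
    """
    if _n_components(mol) > 1:
        return CurationVerdict(False, "mixture")
    if sum(a.formal_charge for a in mol.atoms) != 0:
        return CurationVerdict(False, "charged")
    if not _is_organic(mol):
        return CurationVerdict(False, "inorganic")
    if molecular_weight(mol) > max_mass:
        return CurationVerdict(False, "overweight")
    return CurationVerdict(True, "ok")


def canonical_key(mol: MoleculeGraph) -> str:
    """Canonical SMILES identity, stable under atom reordering."""
    return Chem.MolToSmiles(mol._rdmol)


# ---------------------------------------------------------------------------
# readers / writers


def read_smiles_file(path: str) -> Iterator[tuple[str, str]]:
    """Yield (identifier, smiles) from a one-SMILES-per-line file.

    Lines may be 'SMILES' or 'SMILES<whitespace>ID'; missing ids get a
    1-based line number.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            ident = parts[1].strip() if len(parts) > 1 else f"line{lineno}"
            yield ident, smiles


def read_structures_csv(path: str, id_col: str = "compound_id", smiles_col: str = "smiles") -> Iterator[tuple[str, str]]:
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            yield row[id_col], row[smiles_col]


def read_sdf(path: str) -> Iterator[MoleculeGraph]:
    supplier = Chem.SDMolSupplier(path, sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            raise ParseError(f"<record {i} of {path}>")
        yield _from_rdkit(mol, Chem.MolToSmiles(mol))


def write_curated_csv(
    path: str, entries: Iterable[tuple[str, MoleculeGraph | None, CurationVerdict]]
) -> dict[str, int]:
    """Write (id, canonical structure, verdict) rows; returns reason tally."""
    tally: dict[str, int] = {}
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["compound_id", "canonical_smiles", "accepted", "reason"])
        for ident, mol, verdict in entries:
            key = canonical_key(mol) if (mol is not None and verdict.accepted) else ""
            w.writerow([ident, key, verdict.accepted, verdict.reason])
            tally[verdict.reason] = tally.get(verdict.reason, 0) + 1
    return tally
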