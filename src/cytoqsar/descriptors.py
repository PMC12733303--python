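"""Molecular descriptors: atom-neighborhood strings, quantitative atom
neighborhoods, and whole-molecule properties.

Three families feed the regression models:

* **MNA** (multilevel neighborhoods of atoms): per atom, a canonical string
  encoding the atom type and, recursively, the sorted strings of its bonded
  neighbors up to a chosen level.  Molecule-level features are occurrence
  counts over a vocabulary frozen from the training set.
* **QNA** (quantitative neighborhoods of atoms): per atom, a pair (P, Q)
  derived from tabulated atomic ionization potentials and electron
  affinities propagated over the heavy-atom bond graph through a truncated
  matrix exponential.  Molecule-level features are Gaussian-bump averages on
  a grid spanning the training set's (P, Q) range.
* **Whole-molecule**: ten scalar properties (topological length and volume,
  lipophilicity, charge counts, H-bond donor/acceptor counts, aromatic-atom
  count, molecular weight, halogen count).

All operations are pure functions of the molecule graph and invariant under
atom relabeling.
"""

from __future__ import annotations

import hashlib
import logging
from collections import Counter, deque
from dataclasses import dataclass

import numpy as np
from rdkit.Chem import Crippen, Descriptors, Lipinski
from rdkit.Chem import GetPeriodicTable

from .chem import HALOGENS, MoleculeGraph

logger = logging.getLogger(__name__)

__all__ = [
    "DescriptorConfig",
    "UnsupportedElementError",
    "mna_atom_strings",
    "mna_descriptors",
    "qna_atom_values",
    "QnaGrid",
    "wholemol_descriptors",
    "WHOLEMOL_LABELS",
    "Featurizer",
    "assemble_matrix",
]


class UnsupportedElementError(ValueError):
    pass


# ---------------------------------------------------------------------------
# MNA


def _atom_type(mol: MoleculeGraph, i: int) -> str:
    a = mol.atoms[i]
    t = a.element
    if a.aromatic:
        t += "a"
    if a.n_hydrogens:
        t += f"H{a.n_hydrogens}"
    if a.formal_charge > 0:
        t += "+" * a.formal_charge
    elif a.formal_charge < 0:
        t += "-" * (-a.formal_charge)
    return t


def mna_atom_strings(mol: MoleculeGraph, level: int) -> list[str]:
    """Canonical neighborhood string of every heavy atom at one level.

    Level 0 is the typed atom itself; level k wraps the atom type around the
    lexicographically sorted level-(k-1) strings of its bonded neighbors.
    """
    if level < 0:
        raise ValueError("level must be >= 0")
    adj = mol.adjacency_lists()
    current = [_atom_type(mol, i) for i in range(mol.n_atoms)]
    for _ in range(level):
        current = [
            f"{_atom_type(mol, i)}({','.join(sorted(current[j] for j in adj[i]))})"
            for i in range(mol.n_atoms)
        ]
    return current


def mna_descriptors(mol: MoleculeGraph, level: int) -> Counter[str]:
    """Multiset of neighborhood strings over all levels 0..level."""
    out: Counter[str] = Counter()
    for lvl in range(level + 1):
        out.update(f"{lvl}|{s}" for s in mna_atom_strings(mol, lvl))
    return out


# ---------------------------------------------------------------------------
# QNA

# Experimental first ionization potentials and electron affinities (eV).
_IP_EV = {
    "H": 13.598, "B": 8.298, "C": 11.260, "N": 14.534, "O": 13.618,
    "F": 17.423, "Si": 8.151, "P": 10.487, "S": 10.360, "Cl": 12.968,
    "Br": 11.814, "I": 10.451,
}
_EA_EV = {
    "H": 0.754, "B": 0.280, "C": 1.262, "N": -0.070, "O": 1.461,
    "F": 3.401, "Si": 1.389, "P": 0.746, "S": 2.077, "Cl": 3.613,
    "Br": 3.364, "I": 3.059,
}

# Highest adjacency power kept in the exp(-C/2) series.  24 terms keep the
# truncation error below 1e-6 against the dense matrix exponential for any
# molecule of <= ~30 heavy atoms (spectral radius of C/2 stays around 1.5).
_EXP_TRUNCATION = 24


def _ab_values(mol: MoleculeGraph) -> tuple[np.ndarray, np.ndarray]:
    a = np.empty(mol.n_atoms)
    b = np.empty(mol.n_atoms)
    for i, atom in enumerate(mol.atoms):
        try:
            ip, ea = _IP_EV[atom.element], _EA_EV[atom.element]
        except KeyError:
            raise UnsupportedElementError(
                f"no ionization/affinity data for element {atom.element!r}"
            ) from None
        a[i] = 0.5 * (ip + ea)
        b[i] = (ip - ea) ** -0.5
    return a, b


def adjacency_matrix(mol: MoleculeGraph) -> np.ndarray:
    c = np.zeros((mol.n_atoms, mol.n_atoms))
    for bd in mol.bonds:
        c[bd.i, bd.j] = 1.0
        c[bd.j, bd.i] = 1.0
    return c


def qna_atom_values(mol: MoleculeGraph, truncation: int = _EXP_TRUNCATION) -> np.ndarray:
    """Per-atom (P, Q) pairs, shape (n_atoms, 2).

    With A_k = (IP_k + EA_k)/2 and B_k = (IP_k - EA_k)^(-1/2), the propagation
    matrix is the series of exp(-C/2) truncated after the ``truncation``-th
    power of the adjacency matrix C, and

        P_i = B_i * sum_k M_ik B_k,   Q_i = B_i * sum_k M_ik B_k A_k.
    """
    a, b = _ab_values(mol)
    c = adjacency_matrix(mol)
    m = np.eye(mol.n_atoms)
    term = np.eye(mol.n_atoms)
    for t in range(1, truncation + 1):
        term = term @ (-0.5 * c) / t
        m = m + term
    p = b * (m @ b)
    q = b * (m @ (b * a))
    return np.column_stack([p, q])


@dataclass(frozen=True)
class QnaGrid:
    """Fixed Gaussian-bump grid over the training set's (P, Q) plane."""

    p_edges: tuple[float, float]
    q_edges: tuple[float, float]
    resolution: int

    @classmethod
    def fit(cls, atom_values: list[np.ndarray], resolution: int) -> "QnaGrid":
        if resolution < 2:
            raise ValueError("grid resolution must be >= 2")
        stacked = np.vstack([v for v in atom_values if len(v)])
        p_lo, q_lo = stacked.min(axis=0)
        p_hi, q_hi = stacked.max(axis=0)
        # degenerate axes get a unit span so the grid stays well defined
        if p_hi - p_lo < 1e-9:
            p_lo, p_hi = p_lo - 0.5, p_hi + 0.5
        if q_hi - q_lo < 1e-9:
            q_lo, q_hi = q_lo - 0.5, q_hi + 0.5
        return cls((float(p_lo), float(p_hi)), (float(q_lo), float(q_hi)), resolution)

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        g = self.resolution
        return (
            np.linspace(self.p_edges[0], self.p_edges[1], g),
            np.linspace(self.q_edges[0], self.q_edges[1], g),
        )

    def sigmas(self) -> tuple[float, float]:
        g = self.resolution
        return (
            (self.p_edges[1] - self.p_edges[0]) / (g - 1),
            (self.q_edges[1] - self.q_edges[0]) / (g - 1),
        )

    def features(self, atom_values: np.ndarray) -> np.ndarray:
        """Mean over atoms of each Gaussian bump evaluated at (P_i, Q_i)."""
        pc, qc = self.centers()
        sp, sq = self.sigmas()
        if len(atom_values) == 0:
            return np.zeros(self.resolution**2)
        p = atom_values[:, 0][:, None]
        q = atom_values[:, 1][:, None]
        bp = np.exp(-0.5 * ((p - pc[None, :]) / sp) ** 2)  # atoms x g
        bq = np.exp(-0.5 * ((q - qc[None, :]) / sq) ** 2)
        # outer product per atom, averaged over atoms, flattened row-major
        return (bp[:, :, None] * bq[:, None, :]).mean(axis=0).ravel()


# ---------------------------------------------------------------------------
# whole-molecule descriptors

WHOLEMOL_LABELS = (
    "topological_length",
    "topological_volume",
    "lipophilicity",
    "n_positive_charges",
    "n_negative_charges",
    "n_hbond_acceptors",
    "n_hbond_donors",
    "n_aromatic_atoms",
    "molecular_weight",
    "n_halogen_atoms",
)

_PT = GetPeriodicTable()


def _graph_diameter(mol: MoleculeGraph) -> int:
    # longest shortest path in bonds; components beyond the first ignored
    adj = mol.adjacency_lists()
    n = mol.n_atoms
    diameter = 0
    for start in range(n):
        dist = [-1] * n
        dist[start] = 0
        queue = deque([start])
        while queue:
            v = queue.popleft()
            for w in adj[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
        diameter = max(diameter, max(d for d in dist if d >= 0))
    return diameter


def wholemol_descriptors(mol: MoleculeGraph) -> np.ndarray:
    """The ten whole-molecule quantities, ordered as WHOLEMOL_LABELS."""
    rd = mol._rdmol
    return np.array([
        float(_graph_diameter(mol)),
        float(sum(_PT.GetRcovalent(a.element) for a in mol.atoms)),
        float(Crippen.MolLogP(rd)),
        float(sum(1 for a in mol.atoms if a.formal_charge > 0)),
        float(sum(1 for a in mol.atoms if a.formal_charge < 0)),
        float(Lipinski.NumHAcceptors(rd)),
        float(Lipinski.NumHDonors(rd)),
        float(sum(1 for a in mol.atoms if a.aromatic)),
        float(Descriptors.MolWt(rd)),
        float(sum(1 for a in mol.atoms if a.element in HALOGENS)),
    ])


# ---------------------------------------------------------------------------
# matrix assembly


@dataclass(frozen=True)
class DescriptorConfig:
    families: frozenset[str] = frozenset({"MNA", "QNA", "wholemol"})
    mna_level: int = 2
    mna_top_k: int = 512
    qna_resolution: int = 6
    variant_seed: int = 0

    def __post_init__(self) -> None:
        if not self.families:
            raise ValueError("at least one descriptor family must be enabled")
        if not self.families <= {"MNA", "QNA", "wholemol"}:
            raise ValueError(f"unknown families: {self.families}")
        if "MNA" in self.families and self.mna_level not in (1, 2, 3):
            raise ValueError("MNA level must be 1, 2 or 3")
        if "QNA" in self.families and self.qna_resolution < 2:
            raise ValueError("QNA grid resolution must be >= 2")


@dataclass
class Featurizer:
    """Frozen featurization state: vocabulary, grid, column scalers.

    Fit once on a training set; ``transform`` then maps any molecule to the
    same standardized column space, so query-time features of a training
    compound equal its training row.
    """

    config: DescriptorConfig
    mna_vocab: tuple[str, ...] = ()
    qna_grid: QnaGrid | None = None
    labels: tuple[str, ...] = ()
    kept: np.ndarray | None = None  # indices of non-constant raw columns
    means: np.ndarray | None = None
    stds: np.ndarray | None = None

    @property
    def vocab_hash(self) -> str:
        h = hashlib.sha256()
        for s in self.mna_vocab:
            h.update(s.encode())
        h.update(repr(self.qna_grid).encode())
        h.update(repr(sorted(self.config.families)).encode())
        return h.hexdigest()[:16]

    # -- fitting -----------------------------------------------------------

    def fit(self, molecules: list[MoleculeGraph]) -> "Featurizer":
        cfg = self.config
        if "MNA" in cfg.families:
            counts: Counter[str] = Counter()
            for m in molecules:
                counts.update(mna_descriptors(m, cfg.mna_level))
            # most frequent first, ties broken lexicographically
            ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
            self.mna_vocab = tuple(s for s, _ in ranked[: cfg.mna_top_k])
        if "QNA" in cfg.families:
            self.qna_grid = QnaGrid.fit(
                [qna_atom_values(m) for m in molecules], cfg.qna_resolution
            )
        raw, labels = self._raw_matrix(molecules)
        stds = raw.std(axis=0)
        kept = np.flatnonzero(stds > 1e-12)
        if len(kept) < raw.shape[1]:
            logger.info("dropped %d zero-variance columns", raw.shape[1] - len(kept))
        if len(kept) == 0:
            raise ValueError("all descriptor columns are constant on this training set")
        self.kept = kept
        self.means = raw[:, kept].mean(axis=0)
        self.stds = stds[kept]
        self.labels = tuple(labels[i] for i in kept)
        return self

    def _raw_row(self, mol: MoleculeGraph) -> np.ndarray:
        cfg = self.config
        parts = []
        if "MNA" in cfg.families:
            ms = mna_descriptors(mol, cfg.mna_level)
            parts.append(np.array([float(ms.get(s, 0)) for s in self.mna_vocab]))
        if "QNA" in cfg.families:
            assert self.qna_grid is not None
            parts.append(self.qna_grid.features(qna_atom_values(mol)))
        if "wholemol" in cfg.families:
            parts.append(wholemol_descriptors(mol))
        return np.concatenate(parts)

    def _raw_matrix(self, molecules: list[MoleculeGraph]) -> tuple[np.ndarray, list[str]]:
        labels: list[str] = []
        cfg = self.config
        if "MNA" in cfg.families:
            labels += [f"mna:{s}" for s in self.mna_vocab]
        if "QNA" in cfg.families:
            g = cfg.qna_resolution
            labels += [f"qna:{i},{j}" for i in range(g) for j in range(g)]
        if "wholemol" in cfg.families:
            labels += [f"wm:{s}" for s in WHOLEMOL_LABELS]
        return np.vstack([self._raw_row(m) for m in molecules]), labels

    # -- transform ---------------------------------------------------------

    def transform(self, molecules: list[MoleculeGraph]) -> np.ndarray:
        if self.kept is None:
            raise RuntimeError("featurizer not fitted")
        raw, _ = self._raw_matrix(molecules)
        return (raw[:, self.kept] - self.means) / self.stds


def assemble_matrix(
    molecules: list[MoleculeGraph], config: DescriptorConfig
) -> tuple[np.ndarray, tuple[str, ...], Featurizer]:
    """Fit a featurizer on the molecules and return (X, labels, featurizer).

    Columns are standardized to zero mean / unit variance with the scalers
    stored on the featurizer; constant columns are dropped.
    """
    if not molecules:
        raise ValueError("empty molecule list")
    feat = Featurizer(config=config).fit(molecules)
    return feat.transform(molecules), feat.labels, feat
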