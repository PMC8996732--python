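"""Hydrogen-suppressed molecular graphs and per-atom input featurization.

Each precursor molecule is represented as a graph over its heavy atoms with
bond orders on the edges (aromatic bonds carry order 1.5).  Every atom is
described by a base vector

    [one-hot element | heavy-neighbour count | implicit valence |
     explicit valence | aromatic flag]

and the model input for an atom is the concatenation of three blocks: the
unscaled base vector, a first-shell aggregate and a second-shell aggregate,
where each shell aggregate sums the base vectors of the atom and its
neighbours weighted by bond order (the second shell additionally includes
atoms at graph distance two, weighted by the product of bond orders along
the connecting path).  The two shell blocks are min-max scaled to [0, 1]
with bounds fitted on a training corpus, so the model can separate "atomic"
from "environmental" information.

Valence conventions: implicit valence is the total hydrogen count of the
atom and explicit valence is the sum of bond orders to heavy neighbours.
Both are invariant to whether hydrogens were written explicitly in the
input SMILES, so featurization depends only on the heavy-atom graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from scipy import sparse
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ELEMENT_VOCABULARY",
    "AtomRecord",
    "MolecularGraph",
    "AtomFeaturizer",
    "parse_smiles",
    "atom_base_vector",
    "atom_base_matrix",
    "shell_aggregate",
    "fit_scaling",
    "featurize_molecule",
]

#: Ordered element vocabulary covering organic cage precursors.  An element
#: outside this list is an error, never a silent "other" bucket: bucketing
#: would silently corrupt per-atom attribution downstream.
ELEMENT_VOCABULARY: tuple[str, ...] = (
    "C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "Si", "B",
)


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be turned into a molecular graph."""


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom: element, connectivity and valence summary."""

    symbol: str
    n_heavy_neighbors: int
    implicit_valence: float  # total hydrogen count
    explicit_valence: float  # sum of bond orders to heavy neighbours
    aromatic: bool


@dataclass(frozen=True)
class MolecularGraph:
    """Hydrogen-suppressed atom/bond graph of one precursor.

    Bonds are stored once per undirected edge with ``i < j``; adjacency is
    symmetric by construction.  Atom order is the input order of the RDKit
    parse, so downstream per-atom quantities map back to the SMILES stably.
    """

    atoms: tuple[AtomRecord, ...]
    bonds: tuple[tuple[int, int, float], ...]
    smiles: str = ""

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j, order in self.bonds:
            if not (0 <= i < j < n):
                raise ValueError(f"bond ({i},{j}) out of range for {n} atoms")
            if order <= 0:
                raise ValueError(f"non-positive bond order {order} on ({i},{j})")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def adjacency(self) -> sparse.csr_matrix:
        """Symmetric bond-order-weighted adjacency matrix."""
        n = self.n_atoms
        if not self.bonds:
            return sparse.csr_matrix((n, n))
        ii, jj, ww = zip(*self.bonds)
        rows = np.concatenate([ii, jj])
        cols = np.concatenate([jj, ii])
        data = np.concatenate([ww, ww]).astype(float)
        return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))

    def neighbor_lists(self) -> list[list[tuple[int, float]]]:
        nbrs: list[list[tuple[int, float]]] = [[] for _ in range(self.n_atoms)]
        for i, j, order in self.bonds:
            nbrs[i].append((j, order))
            nbrs[j].append((i, order))
        return nbrs

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, smiles: str = "") -> "MolecularGraph":
        mol = Chem.RemoveHs(mol)
        atoms = []
        for atom in mol.GetAtoms():
            heavy_order_sum = sum(
                b.GetBondTypeAsDouble() for b in atom.GetBonds()
            )
            atoms.append(
                AtomRecord(
                    symbol=atom.GetSymbol(),
                    n_heavy_neighbors=atom.GetDegree(),
                    implicit_valence=float(atom.GetTotalNumHs()),
                    explicit_valence=float(heavy_order_sum),
                    aromatic=bool(atom.GetIsAromatic()),
                )
            )
        bonds = []
        for bond in mol.GetBonds():
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            if i > j:
                i, j = j, i
            bonds.append((i, j, float(bond.GetBondTypeAsDouble())))
        bonds.sort()
        return cls(atoms=tuple(atoms), bonds=tuple(bonds), smiles=smiles)


def parse_smiles(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a hydrogen-suppressed :class:`MolecularGraph`.

    Aromatic perception is applied; explicit hydrogens are folded into the
    heavy-atom records.  Multi-fragment (disconnected) SMILES are rejected
    because a precursor is a single molecule.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    if len(Chem.GetMolFrags(mol)) != 1:
        raise SmilesParseError(f"disconnected multi-fragment SMILES: {smiles!r}")
    return MolecularGraph.from_rdkit(mol, smiles=smiles)


def atom_base_vector(
    graph: MolecularGraph,
    atom_index: int,
    vocab: Sequence[str] = ELEMENT_VOCABULARY,
) -> np.ndarray:
    """Base vector of one atom: ``[one-hot element | #heavy nbrs | implicit
    valence | explicit valence | aromatic]``."""
    atom = graph.atoms[atom_index]
    if atom.symbol not in vocab:
        raise ValueError(
            f"element {atom.symbol!r} (atom {atom_index}) not in vocabulary "
            f"{list(vocab)}"
        )
    vec = np.zeros(len(vocab) + 4)
    vec[list(vocab).index(atom.symbol)] = 1.0
    vec[len(vocab)] = atom.n_heavy_neighbors
    vec[len(vocab) + 1] = atom.implicit_valence
    vec[len(vocab) + 2] = atom.explicit_valence
    vec[len(vocab) + 3] = 1.0 if atom.aromatic else 0.0
    return vec


def atom_base_matrix(
    graph: MolecularGraph, vocab: Sequence[str] = ELEMENT_VOCABULARY
) -> np.ndarray:
    """Stack of base vectors for all atoms, in graph atom order."""
    if graph.n_atoms == 0:
        return np.zeros((0, len(vocab) + 4))
    return np.stack(
        [atom_base_vector(graph, i, vocab) for i in range(graph.n_atoms)]
    )


def _second_shell_weights(graph: MolecularGraph) -> sparse.csr_matrix:
    """Weights w_ik for atoms k at graph distance exactly 2 from i.

    w_ik is the product of bond orders along the two-bond path; when rings
    offer parallel paths the maximum product is used.
    """
    n = graph.n_atoms
    nbrs = graph.neighbor_lists()
    rows, cols, data = [], [], []
    for i in range(n):
        first = {j for j, _ in nbrs[i]}
        best: dict[int, float] = {}
        for j, o_ij in nbrs[i]:
            for k, o_jk in nbrs[j]:
                if k == i or k in first:
                    continue
                w = o_ij * o_jk
                if w > best.get(k, 0.0):
                    best[k] = w
        for k, w in best.items():
            rows.append(i)
            cols.append(k)
            data.append(w)
    return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))


def shell_aggregate(
    graph: MolecularGraph, base_vectors: np.ndarray, degree: int
) -> np.ndarray:
    """Bond-order-weighted neighbourhood sums of the base vectors.

    Degree 1: row i = base_i + sum over neighbours j of order(i,j) * base_j.
    Degree 2: additionally + sum over distance-2 atoms k of w_ik * base_k,
    with w_ik the maximum product of bond orders over connecting two-bond
    paths.  The self term always carries weight 1.
    """
    if degree not in (1, 2):
        raise ValueError(f"degree must be 1 or 2, got {degree}")
    if base_vectors.shape[0] != graph.n_atoms:
        raise ValueError(
            f"base_vectors has {base_vectors.shape[0]} rows for "
            f"{graph.n_atoms} atoms"
        )
    adj = graph.adjacency()
    out = base_vectors + adj @ base_vectors
    if degree == 2:
        out = out + _second_shell_weights(graph) @ base_vectors
    return out


class AtomFeaturizer(TransformerMixin, BaseEstimator):
    """Per-atom input featurization with fitted shell-aggregate scaling.

    ``fit`` records per-dimension min/max of the first- and second-shell
    aggregates over all atoms of a training corpus; ``transform`` emits, for
    each atom, the concatenation ``(v_atom | scaled shell-1 | scaled
    shell-2)`` with the shell blocks min-max scaled and clipped to [0, 1].
    Dimensions constant on the corpus are mapped to 0.

    Parameters
    ----------
    vocabulary : ordered element symbols; an element outside it is an error.
    """

    def __init__(self, vocabulary: Sequence[str] = ELEMENT_VOCABULARY):
        self.vocabulary = tuple(vocabulary)

    @property
    def base_dim(self) -> int:
        return len(self.vocabulary) + 4

    @property
    def feature_dim(self) -> int:
        return 3 * self.base_dim

    def fit(self, corpus: Iterable[MolecularGraph | str], y=None) -> "AtomFeaturizer":
        graphs = [g if isinstance(g, MolecularGraph) else parse_smiles(g)
                  for g in corpus]
        if not graphs:
            raise ValueError("cannot fit featurizer scaling on an empty corpus")
        agg1, agg2 = [], []
        for g in graphs:
            base = atom_base_matrix(g, self.vocabulary)
            agg1.append(shell_aggregate(g, base, 1))
            agg2.append(shell_aggregate(g, base, 2))
        a1 = np.vstack(agg1)
        a2 = np.vstack(agg2)
        self.nbr_min_, self.nbr_max_ = self._bounds(a1)
        self.nbr2_min_, self.nbr2_max_ = self._bounds(a2)
        self.n_molecules_ = len(graphs)
        return self

    @staticmethod
    def _bounds(stacked: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lo = stacked.min(axis=0)
        hi = stacked.max(axis=0)
        constant = hi <= lo
        hi = np.where(constant, lo + 1.0, hi)  # constant dims scale to 0
        return lo, hi

    def _check_fitted(self) -> None:
        if not hasattr(self, "nbr_min_"):
            raise RuntimeError("AtomFeaturizer is not fitted; call fit() first")

    def transform(self, graph: MolecularGraph | str) -> np.ndarray:
        """Featurize one molecule into its (n_atoms, 3 * base_dim) matrix."""
        self._check_fitted()
        if isinstance(graph, str):
            graph = parse_smiles(graph)
        base = atom_base_matrix(graph, self.vocabulary)
        s1 = self._scale(shell_aggregate(graph, base, 1), self.nbr_min_, self.nbr_max_)
        s2 = self._scale(shell_aggregate(graph, base, 2), self.nbr2_min_, self.nbr2_max_)
        return np.hstack([base, s1, s2])

    @staticmethod
    def _scale(values: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
        return np.clip((values - lo) / (hi - lo), 0.0, 1.0)

    def to_header(self) -> dict:
        """Machine-readable description of the feature layout and scaling."""
        self._check_fitted()
        return {
            "vocabulary": list(self.vocabulary),
            "base_layout": list(self.vocabulary)
            + ["n_heavy_neighbors", "implicit_valence", "explicit_valence", "aromatic"],
            "blocks": ["v_atom", "v_neighbour_scaled", "v_2nd_neighbour_scaled"],
            "nbr_min": self.nbr_min_.tolist(),
            "nbr_max": self.nbr_max_.tolist(),
            "nbr2_min": self.nbr2_min_.tolist(),
            "nbr2_max": self.nbr2_max_.tolist(),
        }

    @classmethod
    def from_header(cls, header: dict) -> "AtomFeaturizer":
        feat = cls(vocabulary=tuple(header["vocabulary"]))
        feat.nbr_min_ = np.asarray(header["nbr_min"], dtype=float)
        feat.nbr_max_ = np.asarray(header["nbr_max"], dtype=float)
        feat.nbr2_min_ = np.asarray(header["nbr2_min"], dtype=float)
        feat.nbr2_max_ = np.asarray(header["nbr2_max"], dtype=float)
        feat.n_molecules_ = header.get("n_molecules", 0)
        return feat


def fit_scaling(
    corpus: Iterable[MolecularGraph | str],
    vocabulary: Sequence[str] = ELEMENT_VOCABULARY,
) -> AtomFeaturizer:
    """Fit shell-aggregate min-max bounds on a corpus (thin wrapper)."""
    return AtomFeaturizer(vocabulary=vocabulary).fit(corpus)


def featurize_molecule(
    graph: MolecularGraph | str, state: AtomFeaturizer
) -> np.ndarray:
    """Featurize one molecule with a fitted scaling state (thin wrapper)."""
    return state.transform(graph)
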