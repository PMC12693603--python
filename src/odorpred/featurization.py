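"""SMILES → molecular graph conversion with fixed atom/bond feature layouts.

Each heavy atom becomes a node carrying a 25-dimensional feature vector and
each chemical bond becomes two directed edges carrying identical
6-dimensional feature vectors.  The atom layout is frozen, top to bottom:

====================  ====
element one-hot (C, N, O, S, F, Cl, Br, P, Na)   9
atomic number Z                                   1
formal charge q                                   1
explicit valence                                  1
radical electron count                            1
explicit hydrogen count                           1
implicit hydrogen count                           1
hybridization one-hot (sp, sp2, sp3)              3
aromaticity flag                                  1
heavy-atom degree deg(v)                          1
ring flags (any, 3-, 4-, 5-, 6-membered)          5
====================  ====
total                                            25

The bond layout is: bond-type one-hot (single, double, triple, aromatic),
conjugation flag, ring flag — 6 slots.  Hydrogens stay implicit; no node
ever has Z = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

ELEMENTS = ("C", "N", "O", "S", "F", "Cl", "Br", "P", "Na")
ATOM_FEATURE_DIM = 25
BOND_FEATURE_DIM = 6

_HYBRIDIZATIONS = (
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
)
_BOND_TYPES = (
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
)


class UnsupportedElementError(ValueError):
    """Raised when a molecule contains an element outside the 9-element vocabulary."""


@dataclass
class MolecularGraph:
    """A featurized molecular graph.

    Attributes
    ----------
    node_features : (n, 25) float array
    edge_index : (2, 2m) int array; every chemical bond appears in both
        directions, so column j holds the directed edge src→dst.
    edge_features : (2m, 6) float array; the two directed copies of a bond
        carry identical features.
    smiles : the source SMILES string.
    """

    node_features: np.ndarray
    edge_index: np.ndarray
    edge_features: np.ndarray
    smiles: str = ""

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_index.shape[1]

    def to_dict(self) -> dict:
        return {
            "smiles": self.smiles,
            "node_features": self.node_features.tolist(),
            "edge_index": self.edge_index.tolist(),
            "edge_features": self.edge_features.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MolecularGraph":
        return cls(
            node_features=np.asarray(d["node_features"], dtype=np.float64),
            edge_index=np.asarray(d["edge_index"], dtype=np.int64).reshape(2, -1),
            edge_features=np.asarray(d["edge_features"], dtype=np.float64).reshape(-1, BOND_FEATURE_DIM),
            smiles=d.get("smiles", ""),
        )


def featurize_atom(atom: Chem.Atom, *, strict: bool = True) -> np.ndarray:
    """Build the 25-dimensional feature vector of one RDKit atom.

    In strict mode an element outside the supported vocabulary raises
    :class:`UnsupportedElementError`; in lenient mode the identity block is
    left all-zero and a warning is emitted (a silent zero block would
    corrupt training unnoticed).
    """
    v = np.zeros(ATOM_FEATURE_DIM, dtype=np.float64)
    symbol = atom.GetSymbol()
    if symbol in ELEMENTS:
        v[ELEMENTS.index(symbol)] = 1.0
    elif strict:
        raise UnsupportedElementError(
            f"unsupported element {symbol!r} in molecule "
            f"{Chem.MolToSmiles(atom.GetOwningMol())!r}"
        )
    else:
        warnings.warn(f"element {symbol!r} outside vocabulary; identity block zeroed")
    v[9] = atom.GetAtomicNum()
    v[10] = atom.GetFormalCharge()
    v[11] = atom.GetExplicitValence()
    v[12] = atom.GetNumRadicalElectrons()
    v[13] = atom.GetNumExplicitHs()
    v[14] = atom.GetNumImplicitHs()
    hyb = atom.GetHybridization()
    if hyb in _HYBRIDIZATIONS:  # anything else (e.g. sp3d) leaves the block zero
        v[15 + _HYBRIDIZATIONS.index(hyb)] = 1.0
    v[18] = float(atom.GetIsAromatic())
    v[19] = atom.GetDegree()  # heavy-atom degree, implicit H excluded
    v[20] = float(atom.IsInRing())
    for i, size in enumerate((3, 4, 5, 6)):
        v[21 + i] = float(atom.IsInRingSize(size))
    return v


def featurize_bond(bond: Chem.Bond) -> np.ndarray:
    """Build the 6-dimensional feature vector of one RDKit bond."""
    v = np.zeros(BOND_FEATURE_DIM, dtype=np.float64)
    bt = bond.GetBondType()
    if bt in _BOND_TYPES:
        v[_BOND_TYPES.index(bt)] = 1.0
    v[4] = float(bond.GetIsConjugated())
    v[5] = float(bond.IsInRing())
    return v


def smiles_to_graph(smiles: str, *, strict: bool = True) -> MolecularGraph:
    """Parse a SMILES string and featurize it.

    Node order is RDKit's atom order of the parsed molecule, which is
    deterministic for a given input string.  Raises ``ValueError`` on an
    unparseable input and :class:`UnsupportedElementError` (strict mode)
    when an element falls outside the 9-element vocabulary.
    """
    if not smiles:
        raise ValueError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"could not parse SMILES: {smiles!r}")
    nodes = np.stack([featurize_atom(a, strict=strict) for a in mol.GetAtoms()])
    src, dst, efeat = [], [], []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        f = featurize_bond(bond)
        src += [i, j]
        dst += [j, i]
        efeat += [f, f]
    edge_index = (
        np.array([src, dst], dtype=np.int64)
        if src
        else np.zeros((2, 0), dtype=np.int64)
    )
    edge_features = (
        np.stack(efeat) if efeat else np.zeros((0, BOND_FEATURE_DIM), dtype=np.float64)
    )
    return MolecularGraph(nodes, edge_index, edge_features, smiles=smiles)


def smiles_list_to_graphs(smiles_list, *, strict: bool = True, skip_invalid: bool = False):
    """Featurize many SMILES. With ``skip_invalid`` problem molecules are
    dropped with a warning instead of aborting the batch."""
    graphs = []
    for s in smiles_list:
        try:
            graphs.append(smiles_to_graph(s, strict=strict))
        except (ValueError, UnsupportedElementError):
            if not skip_invalid:
                raise
            warnings.warn(f"skipping unfeaturizable molecule {s!r}")
    return graphs
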