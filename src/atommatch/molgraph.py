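"""Featurized molecular graphs.

A molecule is represented as an undirected graph G(V, A, X, E): heavy atoms are
nodes, chemical bonds are edges, ``X`` stacks a per-atom feature vector built
from one-hot blocks (element, degree, charge, hybridization, valence, ring and
aromaticity flags, scaled mass/radii, chirality, hydrogen count) and ``E``
carries a six-dimensional feature vector per bond (bond-type one-hot,
conjugation, ring membership).  Hydrogens attached to heavy atoms are implicit:
they contribute to the "# Hydrogen" feature but are never nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

__all__ = [
    "ATOM_VOCAB",
    "FeatureSchema",
    "ATOM_SCHEMA",
    "MoleculeGraph",
    "featurize_atom",
    "featurize_bond",
    "mol_to_graph",
    "graph_from_smiles",
    "graph_to_tsv",
]


#: Canonical 64-element atom-type vocabulary, atomic-number order.  The scheme
#: defines no catch-all slot: elements outside this list are rejected loudly.
ATOM_VOCAB: tuple[str, ...] = (
    "H", "Li", "Be", "B", "C", "N", "O", "F", "Na", "Mg", "Al", "Si", "P", "S",
    "Cl", "K", "Ca", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn", "Ga",
    "Ge", "As", "Se", "Br", "Rb", "Sr", "Y", "Zr", "Nb", "Mo", "Ru", "Rh",
    "Pd", "Ag", "Cd", "In", "Sn", "Sb", "Te", "I", "Cs", "Ba", "La", "Ce",
    "Nd", "Sm", "Gd", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg", "Tl", "Pb",
    "Bi",
)
_VOCAB_INDEX = {s: i for i, s in enumerate(ATOM_VOCAB)}

# Min-max scaling bounds, frozen so featurization is reproducible.  Computed
# once over ATOM_VOCAB from the RDKit periodic table.
_MASS_MIN, _MASS_MAX = 1.008, 208.98
_RVDW_MIN, _RVDW_MAX = 1.20, 3.00
_RCOV_MIN, _RCOV_MAX = 0.31, 2.44

_HYBRIDIZATIONS = (
    Chem.HybridizationType.S,
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
)  # + "Other" slot

_CHIRALITY = (
    Chem.ChiralType.CHI_UNSPECIFIED,
    Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
)  # + "Other" slot

_BOND_TYPES = (
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
)


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature-block layout for atoms and bonds."""

    atom_blocks: tuple[tuple[str, int, str], ...]
    bond_blocks: tuple[tuple[str, int], ...]

    @property
    def atom_feature_len(self) -> int:
        return sum(size for _, size, _ in self.atom_blocks)

    @property
    def bond_feature_len(self) -> int:
        return sum(size for _, size in self.bond_blocks)

    def atom_block_slice(self, name: str) -> slice:
        start = 0
        for bname, size, _ in self.atom_blocks:
            if bname == name:
                return slice(start, start + size)
            start += size
        raise KeyError(name)


ATOM_SCHEMA = FeatureSchema(
    atom_blocks=(
        ("atom_type", 64, "one_hot"),
        ("heavy_neighbors", 6, "one_hot"),       # 0,1,2,3,4,>4
        ("formal_charge", 8, "one_hot"),         # -3..3, Extreme
        ("hybridization", 7, "one_hot"),         # s,sp,sp2,sp3,sp3d,sp3d2,Other
        ("explicit_valence", 6, "one_hot"),      # 1..6
        ("is_in_ring", 1, "scalar"),
        ("aromaticity", 1, "scalar"),
        ("atomic_mass_scaled", 1, "scalar"),
        ("vdw_radius_scaled", 1, "scalar"),
        ("covalent_radius_scaled", 1, "scalar"),
        ("chirality_type", 4, "one_hot"),        # Unspecified, CW, CCW, Other
        ("num_hydrogen", 6, "one_hot"),          # 0,1,2,3,4,>4
    ),
    bond_blocks=(
        ("bond_type", 4),                        # single, double, triple, aromatic
        ("conjugated", 1),
        ("in_ring", 1),
    ),
)

ATOM_FEATURE_LEN = ATOM_SCHEMA.atom_feature_len   # 106
BOND_FEATURE_LEN = ATOM_SCHEMA.bond_feature_len   # 6


class FeaturizationError(ValueError):
    """Raised when a molecule cannot be featurized under the fixed schema."""


@dataclass
class MoleculeGraph:
    """A featurized molecular graph G(V, A, X, E) over heavy atoms.

    ``bond_features`` is stored sparsely: one row per directed edge, aligned
    with ``edge_index`` columns; rows for (i, j) and (j, i) are identical.
    ``dense_bond_features()`` exposes the |V| x |V| x 6 view on demand.
    """

    atom_count: int
    atom_symbols: list[str]
    adjacency: np.ndarray                 # (n, n) int8, symmetric, zero diag
    atom_features: np.ndarray             # (n, 106) float64
    edge_index: np.ndarray                # (2, 2m) int64, both directions
    bond_features: np.ndarray             # (2m, 6) float64
    atom_map_numbers: list[int] = field(default_factory=list)
    mol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    def neighbors(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.adjacency[i])

    def dense_bond_features(self) -> np.ndarray:
        dense = np.zeros((self.atom_count, self.atom_count, BOND_FEATURE_LEN))
        src, dst = self.edge_index
        dense[src, dst] = self.bond_features
        return dense

    def bond_order(self, i: int, j: int) -> float:
        """Bond order between atoms i and j (1.5 for aromatic); 0 if unbonded."""
        bond = self.mol.GetBondBetweenAtoms(int(i), int(j)) if self.mol else None
        if bond is None:
            return 0.0
        return float(bond.GetBondTypeAsDouble())


def _one_hot(index: int, size: int) -> np.ndarray:
    vec = np.zeros(size)
    vec[index] = 1.0
    return vec


def featurize_atom(atom: Chem.Atom) -> np.ndarray:
    """Concatenated one-hot/scalar feature vector (length 106) for one atom.

    Out-of-range categorical values fall into each block's catch-all slot
    where one exists ("More than four", "Extreme", "Other"); element symbols
    outside the 64-slot vocabulary and valences outside 1..6 are rejected,
    since those blocks define no catch-all.
    """
    symbol = atom.GetSymbol()
    if symbol not in _VOCAB_INDEX:
        raise FeaturizationError(
            f"element {symbol!r} is not in the fixed 64-element atom-type "
            "vocabulary (no catch-all slot exists)"
        )
    blocks = [_one_hot(_VOCAB_INDEX[symbol], 64)]

    heavy = sum(1 for nb in atom.GetNeighbors() if nb.GetAtomicNum() > 1)
    blocks.append(_one_hot(min(heavy, 5), 6))

    charge = atom.GetFormalCharge()
    blocks.append(_one_hot(charge + 3 if -3 <= charge <= 3 else 7, 8))

    hyb = atom.GetHybridization()
    hyb_idx = _HYBRIDIZATIONS.index(hyb) if hyb in _HYBRIDIZATIONS else 6
    blocks.append(_one_hot(hyb_idx, 7))

    valence = atom.GetTotalValence()
    if not 1 <= valence <= 6:
        raise FeaturizationError(
            f"valence {valence} of atom {atom.GetIdx()} ({symbol}) is outside "
            "the 1..6 range the valence block encodes"
        )
    blocks.append(_one_hot(valence - 1, 6))

    blocks.append(np.array([float(atom.IsInRing())]))
    blocks.append(np.array([float(atom.GetIsAromatic())]))

    pt = Chem.GetPeriodicTable()
    mass = (atom.GetMass() - _MASS_MIN) / (_MASS_MAX - _MASS_MIN)
    rvdw = (pt.GetRvdw(symbol) - _RVDW_MIN) / (_RVDW_MAX - _RVDW_MIN)
    rcov = (pt.GetRcovalent(symbol) - _RCOV_MIN) / (_RCOV_MAX - _RCOV_MIN)
    blocks.append(np.array([mass]))
    blocks.append(np.array([rvdw]))
    blocks.append(np.array([rcov]))

    tag = atom.GetChiralTag()
    chi_idx = _CHIRALITY.index(tag) if tag in _CHIRALITY else 3
    blocks.append(_one_hot(chi_idx, 4))

    blocks.append(_one_hot(min(atom.GetTotalNumHs(), 5), 6))
    return np.concatenate(blocks)


def featurize_bond(bond: Chem.Bond) -> np.ndarray:
    """Six-dimensional bond feature vector: type one-hot, conjugated, in-ring."""
    btype = bond.GetBondType()
    if btype not in _BOND_TYPES:
        raise FeaturizationError(
            f"unrecognized bond order {btype} between atoms "
            f"{bond.GetBeginAtomIdx()} and {bond.GetEndAtomIdx()}"
        )
    return np.concatenate([
        _one_hot(_BOND_TYPES.index(btype), 4),
        np.array([float(bond.GetIsConjugated())]),
        np.array([float(bond.IsInRing())]),
    ])


def mol_to_graph(mol: Chem.Mol) -> MoleculeGraph:
    """Build a MoleculeGraph from a sanitized RDKit molecule (heavy atoms only)."""
    mol = Chem.RemoveHs(mol)
    n = mol.GetNumAtoms()
    if n == 0:
        raise FeaturizationError("molecule has no heavy atoms")
    symbols = [a.GetSymbol() for a in mol.GetAtoms()]
    X = np.stack([featurize_atom(a) for a in mol.GetAtoms()])
    A = np.zeros((n, n), dtype=np.int8)
    src, dst, efeat = [], [], []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        A[i, j] = A[j, i] = 1
        vec = featurize_bond(bond)
        src += [i, j]
        dst += [j, i]
        efeat += [vec, vec]
    edge_index = (np.array([src, dst], dtype=np.int64)
                  if src else np.zeros((2, 0), dtype=np.int64))
    E = np.stack(efeat) if efeat else np.zeros((0, BOND_FEATURE_LEN))
    return MoleculeGraph(
        atom_count=n,
        atom_symbols=symbols,
        adjacency=A,
        atom_features=X,
        edge_index=edge_index,
        bond_features=E,
        atom_map_numbers=[a.GetAtomMapNum() for a in mol.GetAtoms()],
        mol=mol,
    )


def graph_from_smiles(smiles: str) -> MoleculeGraph:
    """Parse a SMILES string and featurize it; atom-map numbers are kept."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(f"could not parse SMILES record: {smiles!r}")
    return mol_to_graph(mol)


def graph_to_tsv(graph: MoleculeGraph) -> str:
    """Debug dump: an atom table and an edge table as TSV text."""
    lines = ["# atoms", "index\tsymbol\tmap_number\tdegree"]
    for i, sym in enumerate(graph.atom_symbols):
        mapno = graph.atom_map_numbers[i] if graph.atom_map_numbers else 0
        lines.append(f"{i}\t{sym}\t{mapno}\t{int(graph.adjacency[i].sum())}")
    feat_names = [f"{name}_{k}" for name, size in ATOM_SCHEMA.bond_blocks
                  for k in range(size)]
    lines += ["# bonds", "i\tj\t" + "\t".join(feat_names)]
    seen = set()
    src, dst = graph.edge_index
    for k in range(src.size):
        i, j = int(src[k]), int(dst[k])
        if (j, i) in seen or (i, j) in seen:
            continue
        seen.add((i, j))
        feats = "\t".join(f"{v:g}" for v in graph.bond_features[k])
        lines.append(f"{i}\t{j}\t{feats}")
    return "\n".join(lines) + "\n"
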