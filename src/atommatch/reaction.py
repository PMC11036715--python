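"""Reaction records, reaction edits and ground-truth correspondences.

A reaction record is one TSV line::

    reaction_smiles <TAB> lost_h <TAB> gained_h <TAB> deleted_bonds <TAB> added_bonds

where ``reaction_smiles`` is an atom-mapped ``reactants>>products`` string and
the four edit fields list atoms that lost a hydrogen, atoms that gained one,
bonds removed and bonds formed, all referenced by atom-map number.  Atom lists
are comma-separated; bond lists are semicolon-separated ``i-j`` pairs, with an
optional ``:order`` suffix on added bonds (default single).

Products are constructed by applying the edits to the reactant graph, so every
reaction is balanced by construction: the heavy-atom element multiset is
conserved and the ground-truth correspondence is a permutation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .molgraph import FeaturizationError, MoleculeGraph, mol_to_graph

__all__ = [
    "ReactionEdits",
    "Reaction",
    "RecordError",
    "EditError",
    "ValidationReport",
    "parse_reaction_record",
    "format_reaction_record",
    "reaction_from_record",
    "reaction_to_record",
    "apply_edits",
    "invert_edits",
    "validate_product",
    "permute_reaction",
    "remap_reaction",
    "split_dataset",
    "main_component",
]

# Maximum permitted valence per element for product validation; elements not
# listed fall back to the RDKit default valence.
MAX_VALENCE = {"C": 4, "N": 3, "O": 2, "F": 1, "P": 5, "S": 6,
               "Cl": 1, "Br": 1, "I": 1, "B": 3, "Si": 4, "H": 1}

_BOND_ORDER_TO_TYPE = {
    1.0: Chem.BondType.SINGLE,
    2.0: Chem.BondType.DOUBLE,
    3.0: Chem.BondType.TRIPLE,
    1.5: Chem.BondType.AROMATIC,
}


class RecordError(ValueError):
    """A malformed reaction record."""


class EditError(ValueError):
    """Reaction edits that cannot be applied to the reactant graph."""


@dataclass
class ReactionEdits:
    """The four reaction-edit lists, referenced by atom-map number."""

    lost_h: list[int] = field(default_factory=list)
    gained_h: list[int] = field(default_factory=list)
    deleted_bonds: list[tuple[int, int]] = field(default_factory=list)
    added_bonds: list[tuple[int, int, float]] = field(default_factory=list)

    def referenced_maps(self) -> set[int]:
        maps = set(self.lost_h) | set(self.gained_h)
        for i, j in self.deleted_bonds:
            maps |= {i, j}
        for i, j, _ in self.added_bonds:
            maps |= {i, j}
        return maps

    def is_empty(self) -> bool:
        return not (self.lost_h or self.gained_h
                    or self.deleted_bonds or self.added_bonds)

    def validate(self, available_maps: set[int]) -> None:
        dangling = self.referenced_maps() - available_maps
        if dangling:
            raise EditError(
                "edit references atom-map number(s) absent from the reactant "
                f"side: {sorted(dangling)}"
            )
        deleted = {frozenset(b) for b in self.deleted_bonds}
        for i, j, order in self.added_bonds:
            if frozenset((i, j)) in deleted and order == 1.0:
                # identical delete+add would be a no-op edit pair
                raise EditError(
                    f"bond {i}-{j} is both deleted and added with the same order"
                )


@dataclass
class Reaction:
    """A balanced reaction: reactant/product graphs, edits and ground truth.

    ``gt_matrix[i, j] = 1`` iff reactant atom ``i`` corresponds to product
    atom ``j``; it is always a permutation matrix.
    """

    reactants: MoleculeGraph
    products: MoleculeGraph
    edits: ReactionEdits
    gt_matrix: np.ndarray

    def __post_init__(self) -> None:
        gt = np.asarray(self.gt_matrix)
        nR, nP = self.reactants.atom_count, self.products.atom_count
        if gt.shape != (nR, nP):
            raise ValueError(f"gt_matrix shape {gt.shape} != ({nR}, {nP})")
        if not (np.all(gt.sum(0) == 1) and np.all(gt.sum(1) == 1)):
            raise ValueError("gt_matrix is not a permutation matrix")
        if sorted(self.reactants.atom_symbols) != sorted(self.products.atom_symbols):
            raise ValueError("reaction is not balanced: element multisets differ")

    @property
    def gt_permutation(self) -> np.ndarray:
        """pi_gt as an index array: reactant atom i maps to product atom pi[i]."""
        return np.argmax(self.gt_matrix, axis=1)

    @property
    def n_atoms(self) -> int:
        return self.reactants.atom_count


def _parse_atom_list(text: str, fieldname: str) -> list[int]:
    if not text:
        return []
    try:
        return [int(tok) for tok in text.split(",")]
    except ValueError as exc:
        raise RecordError(f"bad atom list in field {fieldname!r}: {text!r}") from exc


def _parse_bond_list(text: str, fieldname: str, with_order: bool):
    if not text:
        return []
    out = []
    for tok in text.split(";"):
        try:
            if with_order and ":" in tok:
                pair, order = tok.split(":")
                i, j = pair.split("-")
                out.append((int(i), int(j), float(order)))
            else:
                i, j = tok.split("-")
                out.append((int(i), int(j), 1.0) if with_order
                           else (int(i), int(j)))
        except ValueError as exc:
            raise RecordError(f"bad bond token {tok!r} in field {fieldname!r}") from exc
    return out


def parse_reaction_record(line: str, lineno: int | None = None):
    """Parse one TSV record into ``(reaction_smiles, ReactionEdits)``."""
    where = f" (line {lineno})" if lineno is not None else ""
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 5:
        raise RecordError(
            f"expected 5 tab-separated fields, got {len(fields)}{where}"
        )
    smiles, lost, gained, deleted, added = fields
    if ">>" not in smiles:
        raise RecordError(f"first field is not a reaction SMILES{where}: {smiles!r}")
    edits = ReactionEdits(
        lost_h=_parse_atom_list(lost, "lost_h"),
        gained_h=_parse_atom_list(gained, "gained_h"),
        deleted_bonds=_parse_bond_list(deleted, "deleted_bonds", with_order=False),
        added_bonds=_parse_bond_list(added, "added_bonds", with_order=True),
    )
    return smiles, edits


def format_reaction_record(smiles: str, edits: ReactionEdits) -> str:
    """Serialize a record canonically (sorted edit lists) to one TSV line."""
    lost = ",".join(str(m) for m in sorted(edits.lost_h))
    gained = ",".join(str(m) for m in sorted(edits.gained_h))
    deleted = ";".join(f"{min(i, j)}-{max(i, j)}"
                       for i, j in sorted(map(sorted, edits.deleted_bonds)))
    added = ";".join(
        f"{i}-{j}:{order:g}"
        for i, j, order in sorted((min(i, j), max(i, j), o)
                                  for i, j, o in edits.added_bonds))
    return "\t".join([smiles, lost, gained, deleted, added])


def _map_index(graph: MoleculeGraph) -> dict[int, int]:
    """atom-map number -> atom index; unmapped graphs get 1-based identity."""
    if graph.atom_map_numbers and any(graph.atom_map_numbers):
        return {m: i for i, m in enumerate(graph.atom_map_numbers)}
    return {i + 1: i for i in range(graph.atom_count)}


def apply_edits(reactants: MoleculeGraph, edits: ReactionEdits) -> MoleculeGraph:
    """Construct the product graph by applying reaction edits to the reactants.

    Hydrogen counts are frozen first (adjusted by the lost/gained lists), then
    bonds are deleted and added; the result is re-sanitized, so aromaticity is
    re-perceived on the edited structure.  Product atoms keep the reactant
    atom order and atom-map numbers, so the induced correspondence is the
    identity.
    """
    by_map = _map_index(reactants)
    edits.validate(set(by_map))
    mol = Chem.RWMol(reactants.mol)
    Chem.Kekulize(mol, clearAromaticFlags=True)

    lost = {m: edits.lost_h.count(m) for m in set(edits.lost_h)}
    gained = {m: edits.gained_h.count(m) for m in set(edits.gained_h)}
    for atom in mol.GetAtoms():
        mapno = reactants.atom_map_numbers[atom.GetIdx()] or (atom.GetIdx() + 1)
        new_h = atom.GetTotalNumHs() + gained.get(mapno, 0) - lost.get(mapno, 0)
        if new_h < 0:
            raise EditError(
                f"atom with map number {mapno} would end up with {new_h} hydrogens"
            )
        atom.SetNumExplicitHs(new_h)
        atom.SetNoImplicit(True)

    for mi, mj in edits.deleted_bonds:
        i, j = by_map[mi], by_map[mj]
        if mol.GetBondBetweenAtoms(i, j) is None:
            raise EditError(f"cannot delete non-existent bond {mi}-{mj}")
        mol.RemoveBond(i, j)
    for mi, mj, order in edits.added_bonds:
        i, j = by_map[mi], by_map[mj]
        if mol.GetBondBetweenAtoms(i, j) is not None:
            raise EditError(f"cannot add duplicate bond {mi}-{mj}")
        if order not in _BOND_ORDER_TO_TYPE:
            raise EditError(f"unrecognized bond order {order} for bond {mi}-{mj}")
        mol.AddBond(i, j, _BOND_ORDER_TO_TYPE[order])

    product = mol.GetMol()
    try:
        Chem.SanitizeMol(product)
    except Exception as exc:  # noqa: BLE001 - RDKit raises several types
        raise EditError(f"edited product failed sanitization: {exc}") from exc
    return mol_to_graph(product)


@dataclass
class ValidationReport:
    ok: bool
    reasons: list[str]

    def __bool__(self) -> bool:
        return self.ok


def validate_product(product: MoleculeGraph | Chem.Mol) -> ValidationReport:
    """Check valence constraints on a (possibly unsanitized) product.

    Fails iff some atom's total valence exceeds its element's permitted
    maximum; returns the offending atoms as reasons rather than raising.
    """
    mol = product.mol if isinstance(product, MoleculeGraph) else product
    if mol is None:
        raise ValueError("product graph carries no molecule handle")
    mol.UpdatePropertyCache(strict=False)
    pt = Chem.GetPeriodicTable()
    reasons = []
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        allowed = MAX_VALENCE.get(sym)
        if allowed is None:
            allowed = max(pt.GetValenceList(sym) or [8])
        v = atom.GetTotalValence()
        if v > allowed:
            reasons.append(
                f"atom {atom.GetIdx()} ({sym}) has valence {v} > {allowed}"
            )
    return ValidationReport(ok=not reasons, reasons=reasons)


def main_component(graph: MoleculeGraph) -> Chem.Mol:
    """Largest fragment by heavy-atom count; ties broken by canonical SMILES."""
    frags = Chem.GetMolFrags(graph.mol, asMols=True, sanitizeFrags=False)
    return max(frags, key=lambda m: (m.GetNumAtoms(), Chem.MolToSmiles(m)))


def reaction_from_record(line: str, lineno: int | None = None,
                         check_product: bool = True) -> Reaction:
    """Build a Reaction from a TSV record.

    The product graph is taken from the record's product side (whose atom-map
    numbers, matched against the reactant side's, define the ground-truth
    correspondence); the edit lists are replayed on the reactants and the
    rebuilt product's main component is compared against it as a consistency
    check when ``check_product`` is set.
    """
    smiles, edits = parse_reaction_record(line, lineno)
    r_smiles, p_smiles = smiles.split(">>")
    try:
        reactants = mol_to_graph(_mol_from_smiles(r_smiles))
        products = mol_to_graph(_mol_from_smiles(p_smiles))
    except FeaturizationError as exc:
        where = f" (line {lineno})" if lineno is not None else ""
        raise RecordError(f"{exc}{where}") from exc

    r_maps = _map_index(reactants)
    p_maps = _map_index(products)
    if set(r_maps) != set(p_maps):
        raise RecordError("reactant and product atom-map numbers differ")
    gt = np.zeros((reactants.atom_count, products.atom_count), dtype=np.int8)
    for m, i in r_maps.items():
        gt[i, p_maps[m]] = 1

    if check_product:
        rebuilt = apply_edits(reactants, edits)
        report = validate_product(rebuilt)
        if not report:
            raise RecordError("; ".join(report.reasons))
        got = Chem.MolToSmiles(_strip_maps(main_component(rebuilt)))
        want = Chem.MolToSmiles(_strip_maps(main_component(products)))
        if got != want:
            raise RecordError(
                f"edits replay to main component {got}, record states {want}"
            )
    return Reaction(reactants=reactants, products=products, edits=edits,
                    gt_matrix=gt)


def reaction_to_record(reaction: Reaction) -> str:
    """Serialize a Reaction back to its canonical TSV record."""
    smiles = (Chem.MolToSmiles(reaction.reactants.mol) + ">>"
              + Chem.MolToSmiles(reaction.products.mol))
    return format_reaction_record(smiles, reaction.edits)


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise RecordError(f"could not parse SMILES: {smiles!r}")
    return mol


def _strip_maps(mol: Chem.Mol) -> Chem.Mol:
    mol = Chem.Mol(mol)
    for atom in mol.GetAtoms():
        atom.SetAtomMapNum(0)
    return mol


def invert_edits(reactants: MoleculeGraph, edits: ReactionEdits) -> ReactionEdits:
    """Edits that undo ``edits`` when applied to the edited product.

    Deleted bonds are re-added with their original reactant bond order;
    added bonds are deleted; the hydrogen lists swap roles.
    """
    by_map = _map_index(reactants)
    re_added = []
    for mi, mj in edits.deleted_bonds:
        i, j = by_map[mi], by_map[mj]
        bond = reactants.mol.GetBondBetweenAtoms(i, j)
        if bond is None:
            raise EditError(f"cannot invert deletion of missing bond {mi}-{mj}")
        re_added.append((mi, mj, float(bond.GetBondTypeAsDouble())))
    return ReactionEdits(
        lost_h=list(edits.gained_h),
        gained_h=list(edits.lost_h),
        deleted_bonds=[(i, j) for i, j, _ in edits.added_bonds],
        added_bonds=re_added,
    )


def permute_reaction(reaction: Reaction, order_R, order_P) -> Reaction:
    """Reorder atoms on both sides by explicit orders (new index -> old index).

    The ground-truth matrix is conjugated so it encodes the same chemical
    correspondence; atom-map numbers travel with their atoms, so the edit
    lists are unchanged.
    """
    order_R = np.asarray(order_R)
    order_P = np.asarray(order_P)
    new_R = mol_to_graph(Chem.RenumberAtoms(reaction.reactants.mol,
                                            [int(k) for k in order_R]))
    new_P = mol_to_graph(Chem.RenumberAtoms(reaction.products.mol,
                                            [int(k) for k in order_P]))
    gt = np.asarray(reaction.gt_matrix)[np.ix_(order_R, order_P)]
    return Reaction(reactants=new_R, products=new_P, edits=reaction.edits,
                    gt_matrix=gt)


def remap_reaction(reaction: Reaction, seed: int) -> Reaction:
    """Scramble atom positions to remove position dependence.

    Both sides are independently permuted by seeded uniform permutations and
    the ground-truth matrix updated accordingly; the same seed always yields
    the same output.
    """
    rng = np.random.default_rng(seed)
    order_R = rng.permutation(reaction.reactants.atom_count)
    order_P = rng.permutation(reaction.products.atom_count)
    return permute_reaction(reaction, order_R, order_P)


def split_dataset(records: list, seed: int,
                  fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)):
    """Seeded, reproducible train/validation/test split (default 70/10/20)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    n_train = round(len(records) * fractions[0])
    n_val = round(len(records) * fractions[1])
    train = [records[i] for i in order[:n_train]]
    val = [records[i] for i in order[n_train:n_train + n_val]]
    test = [records[i] for i in order[n_train + n_val:]]
    return train, val, test
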