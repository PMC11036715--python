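"""Reaction records, edit application, validation, remapping, splits."""

import numpy as np
import pytest
from rdkit import Chem

from atommatch.molgraph import graph_from_smiles
from atommatch.reaction import (EditError, Reaction, ReactionEdits,
                                RecordError, apply_edits,
                                format_reaction_record, invert_edits,
                                parse_reaction_record, permute_reaction,
                                reaction_from_record, reaction_to_record,
                                remap_reaction, split_dataset,
                                validate_product)
from atommatch.synthetic import GeneratorConfig, generate_reaction


def _mapped(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    for atom in mol.GetAtoms():
        atom.SetAtomMapNum(atom.GetIdx() + 1)
    return Chem.MolToSmiles(mol)


def test_identity_record_parses_to_identity_reaction():
    s = _mapped("CCO")
    rxn = reaction_from_record(f"{s}>>{s}\t\t\t\t")
    assert rxn.edits.is_empty()
    assert np.array_equal(rxn.gt_matrix, np.eye(3))
    assert np.array_equal(rxn.reactants.adjacency, rxn.products.adjacency)


def test_record_writer_parser_byte_identity(rng):
    cfg = GeneratorConfig(atom_range=(5, 9), seed=3)
    gen = np.random.default_rng(3)
    for _ in range(10):
        line, rxn = generate_reaction(cfg, gen)
        assert reaction_to_record(rxn) == line
        reparsed = reaction_from_record(line)
        assert reaction_to_record(reparsed) == line


def test_dangling_map_number_named_in_error():
    s = _mapped("CCO")
    with pytest.raises(EditError, match="99"):
        reaction_from_record(f"{s}>>{s}\t\t\t\t2-99:1")


def test_malformed_line_reports_line_number():
    with pytest.raises(RecordError, match="line 7"):
        parse_reaction_record("only-one-field", lineno=7)


def test_missing_reaction_arrow_rejected():
    with pytest.raises(RecordError, match="reaction SMILES"):
        parse_reaction_record("CCO\t\t\t\t")


def test_empty_edits_identity_application():
    reactants = graph_from_smiles(_mapped("CC(C)=O"))
    product = apply_edits(reactants, ReactionEdits())
    assert np.array_equal(product.adjacency, reactants.adjacency)
    assert product.atom_symbols == reactants.atom_symbols


def test_delete_then_inverse_add_restores_adjacency():
    reactants = graph_from_smiles(_mapped("CCCO"))
    edits = ReactionEdits(deleted_bonds=[(2, 3)], gained_h=[2, 3])
    product = apply_edits(reactants, edits)
    assert product.adjacency.sum() == reactants.adjacency.sum() - 2
    back = apply_edits(product, invert_edits(reactants, edits))
    assert np.array_equal(back.adjacency, reactants.adjacency)


def test_negative_hydrogen_count_rejected():
    reactants = graph_from_smiles(_mapped("FC(F)(F)F"))  # central C has no H
    edits = ReactionEdits(lost_h=[1], added_bonds=[])
    with pytest.raises(EditError, match="hydrogen"):
        apply_edits(reactants, edits)


def test_duplicate_bond_rejected():
    reactants = graph_from_smiles(_mapped("CCO"))
    edits = ReactionEdits(added_bonds=[(1, 2, 1.0)], lost_h=[1, 2])
    with pytest.raises(EditError, match="duplicate"):
        apply_edits(reactants, edits)


def test_product_adjacency_is_reactant_xor_edits():
    gen = np.random.default_rng(17)
    cfg = GeneratorConfig(atom_range=(6, 12), edit_range=(1, 3), seed=17)
    for _ in range(15):
        _, rxn = generate_reaction(cfg, gen, remap=False)
        prod = apply_edits(rxn.reactants, rxn.edits)
        by_map = {m: i for i, m in enumerate(rxn.reactants.atom_map_numbers)}
        expected = rxn.reactants.adjacency.copy()
        for mi, mj in rxn.edits.deleted_bonds:
            expected[by_map[mi], by_map[mj]] = 0
            expected[by_map[mj], by_map[mi]] = 0
        for mi, mj, _ in rxn.edits.added_bonds:
            expected[by_map[mi], by_map[mj]] = 1
            expected[by_map[mj], by_map[mi]] = 1
        assert np.array_equal(prod.adjacency, expected)


def test_validate_product_pentavalent_carbon_fails():
    mol = Chem.MolFromSmiles("C(C)(C)(C)(C)C", sanitize=False)
    mol.UpdatePropertyCache(strict=False)
    report = validate_product(mol)
    assert not report.ok
    assert any("valence 5" in r for r in report.reasons)


def test_validate_product_water_like_oxygen_passes():
    assert validate_product(graph_from_smiles("CO").mol).ok


def test_generated_products_all_validate():
    gen = np.random.default_rng(23)
    cfg = GeneratorConfig(atom_range=(5, 12), seed=23)
    for _ in range(30):
        _, rxn = generate_reaction(cfg, gen)
        assert validate_product(rxn.products).ok


def test_remap_deterministic_and_permutation(small_reactions):
    rxn = small_reactions[0]
    a = remap_reaction(rxn, seed=5)
    b = remap_reaction(rxn, seed=5)
    assert np.array_equal(a.gt_matrix, b.gt_matrix)
    assert a.reactants.atom_symbols == b.reactants.atom_symbols
    assert np.all(a.gt_matrix.sum(0) == 1) and np.all(a.gt_matrix.sum(1) == 1)


def test_remap_preserves_bond_correspondence(small_reactions):
    for rxn in small_reactions[:8]:
        remapped = remap_reaction(rxn, seed=9)
        pi = remapped.gt_permutation
        deleted = {frozenset(b) for b in remapped.edits.deleted_bonds}
        maps = remapped.reactants.atom_map_numbers
        A_R = remapped.reactants.adjacency
        A_P = remapped.products.adjacency
        for i in range(remapped.n_atoms):
            for j in range(i + 1, remapped.n_atoms):
                if A_R[i, j] and frozenset((maps[i], maps[j])) not in deleted:
                    assert A_P[pi[i], pi[j]] == 1


def test_double_permutation_composes(small_reactions):
    rxn = small_reactions[1]
    nR, nP = rxn.gt_matrix.shape
    rng = np.random.default_rng(2)
    pR1, pP1 = rng.permutation(nR), rng.permutation(nP)
    pR2, pP2 = rng.permutation(nR), rng.permutation(nP)
    once = permute_reaction(permute_reaction(rxn, pR1, pP1), pR2, pP2)
    composed = permute_reaction(rxn, pR1[pR2], pP1[pP2])
    assert np.array_equal(once.gt_matrix, composed.gt_matrix)
    assert once.reactants.atom_symbols == composed.reactants.atom_symbols
    assert np.array_equal(once.reactants.adjacency,
                          composed.reactants.adjacency)


def test_element_conservation(small_reactions):
    for rxn in small_reactions:
        assert sorted(rxn.reactants.atom_symbols) == \
            sorted(rxn.products.atom_symbols)


def test_unbalanced_reaction_rejected():
    r = graph_from_smiles(_mapped("CCO"))
    p = graph_from_smiles(_mapped("CCC"))
    with pytest.raises(ValueError, match="balanced"):
        Reaction(reactants=r, products=p, edits=ReactionEdits(),
                 gt_matrix=np.eye(3))


def test_split_is_70_10_20_disjoint_and_deterministic():
    records = [f"record-{i}" for i in range(100)]
    train, val, test = split_dataset(records, seed=4)
    assert (len(train), len(val), len(test)) == (70, 10, 20)
    assert not (set(train) & set(val)) and not (set(train) & set(test))
    assert not (set(val) & set(test))
    again = split_dataset(records, seed=4)
    assert (train, val, test) == again
    different = split_dataset(records, seed=5)
    assert different[0] != train


def test_format_round_trip_of_edit_fields():
    edits = ReactionEdits(lost_h=[3, 1], gained_h=[2],
                          deleted_bonds=[(4, 2)], added_bonds=[(1, 3, 2.0)])
    line = format_reaction_record("CC>>CC", edits)
    smiles, parsed = parse_reaction_record(line)
    assert smiles == "CC>>CC"
    assert sorted(parsed.lost_h) == [1, 3]
    assert parsed.gained_h == [2]
    assert parsed.deleted_bonds == [(2, 4)]
    assert parsed.added_bonds == [(1, 3, 2.0)]
    assert format_reaction_record(smiles, parsed) == line
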