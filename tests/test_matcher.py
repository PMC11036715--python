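"""Encoder, affinity, normalization, pooling, loss and training loop."""

import numpy as np
import pytest
from rdkit import Chem

import scipy.optimize

from atommatch import nn
from atommatch.matcher import (AtomMappingModel, MatcherConfig,
                               TrainingDivergedError, affinity, embed_graph,
                               load_checkpoint, nll_loss, normalize,
                               predict_mapping, symmetry_pool,
                               save_checkpoint, _greedy_assignment)
from atommatch.molgraph import (ATOM_FEATURE_LEN, BOND_FEATURE_LEN,
                                graph_from_smiles, mol_to_graph)
from atommatch.symmetry import EquivalencePartition, equivalence_classes
from atommatch.synthetic import GeneratorConfig, generate_reaction

from conftest import identity_reaction


def _params(embed_dim=8, layers=2, seed=0):
    return nn.init_params(ATOM_FEATURE_LEN, BOND_FEATURE_LEN, embed_dim,
                          layers, seed)


# ---------------------------------------------------------------- embedding

def test_embedding_shape_includes_layer_zero():
    cfg = MatcherConfig(embed_dim=8, mp_layers=2)
    graph = graph_from_smiles("CCO")
    H = embed_graph(graph, _params(), cfg)
    assert H.shape == (3, (cfg.mp_layers + 1) * cfg.embed_dim)
    cfg_nojk = MatcherConfig(embed_dim=8, mp_layers=2, jumping_knowledge=False)
    assert embed_graph(graph, _params(), cfg_nojk).shape == (3, 8)


@pytest.mark.parametrize("aggregate", ["sum", "mean", "max"])
def test_encoder_equivariance(aggregate):
    cfg = MatcherConfig(embed_dim=8, mp_layers=3, aggregate=aggregate)
    params = _params(8, 3, seed=2)
    mol = Chem.MolFromSmiles("CC(=O)OC1CCCCC1N")
    graph = mol_to_graph(mol)
    order = list(np.random.default_rng(0).permutation(mol.GetNumAtoms()))
    permuted = mol_to_graph(Chem.RenumberAtoms(mol, [int(i) for i in order]))
    H = embed_graph(graph, params, cfg)
    H_perm = embed_graph(permuted, params, cfg)
    assert np.max(np.abs(H_perm - H[order])) < 1e-10


def test_wl_equivalent_atoms_get_identical_embeddings():
    """The encoder cannot exceed WL discrimination: equivalent atoms embed
    identically, which is the mechanism behind split correspondence mass."""
    cfg = MatcherConfig(embed_dim=8, mp_layers=3)
    params = _params(8, 3, seed=4)
    rxn = identity_reaction("CC(C)(Cl)Cl")
    H = embed_graph(rxn.reactants, params, cfg)
    for cls in equivalence_classes(rxn.reactants).classes:
        for i in cls[1:]:
            assert np.allclose(H[i], H[cls[0]], atol=1e-12)
    # hence M_tilde rows/columns coincide for equivalent atoms
    M_tilde = normalize(affinity(H, H))
    for cls in equivalence_classes(rxn.products).classes:
        for i in cls[1:]:
            assert np.allclose(M_tilde[:, i], M_tilde[:, cls[0]], atol=1e-12)
            assert np.allclose(M_tilde[i], M_tilde[cls[0]], atol=1e-12)


def test_single_atom_zero_weight_forward_is_bias_pathway():
    cfg = MatcherConfig(embed_dim=4, mp_layers=2)
    params = {k: np.zeros_like(v) for k, v in _params(4, 2).items()}
    rng = np.random.default_rng(8)
    for key in ("b_in", "b1_0", "b2_0", "b1_1", "b2_1"):
        params[key] = rng.normal(size=4)
    graph = graph_from_smiles("C")
    H = embed_graph(graph, params, cfg)
    # independent hand computation: no neighbours, so each layer sees only
    # its bias chain: h0 = b_in; h_{l+1} = relu(b1_l) @ W2 + b2_l = b2_l
    expected = np.concatenate([params["b_in"], params["b2_0"], params["b2_1"]])
    assert np.allclose(H[0], expected, atol=1e-12)


# ----------------------------------------------------- affinity + softmax

def test_affinity_matches_double_loop_oracle(rng):
    H_R = rng.normal(size=(5, 7))
    H_P = rng.normal(size=(6, 7))
    M = affinity(H_R, H_P)
    for i in range(5):
        for j in range(6):
            assert abs(M[i, j] - sum(H_R[i, k] * H_P[j, k]
                                     for k in range(7))) < 1e-12


def test_affinity_orthonormal_rows_give_identity():
    H = np.eye(4)
    assert np.allclose(affinity(H, H), np.eye(4))


def test_affinity_gram_symmetry(rng):
    H = rng.normal(size=(5, 9))
    M = affinity(H, H)
    assert np.allclose(M, M.T)


def test_affinity_width_mismatch():
    with pytest.raises(ValueError, match="width"):
        affinity(np.zeros((2, 3)), np.zeros((2, 4)))


def test_softmax_uniform_on_zero_input():
    M = normalize(np.zeros((3, 4)))
    assert np.allclose(M, 0.25)


def test_softmax_shift_invariance(rng):
    M_hat = rng.normal(size=(4, 5))
    shifted = M_hat + 3.7  # constant shift within each slice
    assert np.allclose(normalize(M_hat), normalize(shifted))


def test_softmax_hand_values():
    M_hat = np.array([[np.log(2.0), 0.0], [0.0, np.log(2.0)]])
    M = normalize(M_hat)
    assert np.allclose(M, [[2 / 3, 1 / 3], [1 / 3, 2 / 3]])


@pytest.mark.parametrize("axis,sum_axis", [("per_reactant_atom", 1),
                                           ("per_product_atom", 0)])
def test_softmax_slices_sum_to_one(rng, axis, sum_axis):
    M_hat = rng.normal(scale=40, size=(7, 9))  # large scale: stability check
    M = normalize(M_hat, axis=axis)
    assert np.allclose(M.sum(axis=sum_axis), 1.0, atol=1e-6)
    # strictly positive always; the upper bound saturates to 1.0 in floats
    # only at extreme affinity scales
    assert np.all(M > 0) and np.all(M <= 1)
    moderate = normalize(rng.normal(size=(7, 9)), axis=axis)
    assert np.all(moderate > 0) and np.all(moderate < 1)


# ------------------------------------------------------------- pooling

def test_pool_identity_for_singleton_classes(rng):
    M = normalize(rng.normal(size=(4, 4)))
    singles = EquivalencePartition(classes=[[0], [1], [2], [3]])
    assert np.allclose(symmetry_pool(M, singles), M)


def test_pool_uniform_class_of_two():
    M = np.full((3, 4), 0.25)
    part = EquivalencePartition(classes=[[0, 1], [2], [3]])
    pooled = symmetry_pool(M, part)
    assert np.allclose(pooled[:, [0, 1]], 0.5)
    assert np.allclose(pooled[:, [2, 3]], 0.25)


def test_pool_resolves_split_mass():
    # two equivalent product atoms sharing 0.5/0.5 mass pool to 1.0
    M = np.array([[0.5, 0.5, 0.0], [0.25, 0.25, 0.5], [0.0, 0.0, 1.0]])
    part = EquivalencePartition(classes=[[0, 1], [2]])
    pooled = symmetry_pool(M, part)
    assert pooled[0, 0] == pooled[0, 1] == 1.0


def test_pool_never_decreases_and_conserves_mass(rng):
    M = normalize(rng.normal(size=(5, 6)))
    part = EquivalencePartition(classes=[[0, 3], [1], [2, 4, 5]])
    pooled = symmetry_pool(M, part)
    assert np.all(pooled >= M - 1e-15)
    # per-representative mass equals the row total of M
    reps = [c[0] for c in part.classes]
    assert np.allclose(pooled[:, reps].sum(axis=1), M.sum(axis=1))


# --------------------------------------------------------------- loss

def test_loss_zero_on_exact_permutation():
    M = np.eye(5)[[1, 0, 3, 2, 4]]
    assert nll_loss(M, np.array([1, 0, 3, 2, 4])) == 0.0


def test_loss_uniform_closed_form():
    n = 4
    M = np.full((n, n), 1 / n)
    assert abs(nll_loss(M, np.arange(n)) - n * np.log(n)) < 1e-9


def test_loss_decreases_when_gt_mass_grows():
    gt = np.arange(3)
    losses = []
    for w in (1.0, 2.0, 4.0):
        M_hat = np.zeros((3, 3))
        M_hat[gt, gt] = np.log(w)
        losses.append(nll_loss(normalize(M_hat), gt))
    assert losses[0] > losses[1] > losses[2]


def test_loss_clamps_zero_probability():
    M = np.eye(2)  # off-diagonal zeros
    loss = nll_loss(M, np.array([1, 0]), eps=1e-12)
    assert np.isfinite(loss) and loss > 0


# ------------------------------------------------------------ training

def _tiny_reaction():
    gen = np.random.default_rng(5)
    cfg = GeneratorConfig(atom_range=(5, 7), edit_range=(1, 1),
                          symmetry_fraction=0.0, seed=5)
    return generate_reaction(cfg, gen)[1]


def test_overfit_single_reaction():
    rxn = _tiny_reaction()
    cfg = MatcherConfig(embed_dim=16, mp_layers=2, learning_rate=1e-2,
                        seed=0, max_epochs=60, batch_size=16,
                        early_stopping_patience=60)
    model = AtomMappingModel([rxn] * 50, config=cfg)
    res = model.fit()
    losses = [h["train_loss"] for h in res.history]
    assert all(b <= a + 1e-9 for a, b in zip(losses[:5], losses[1:6]))
    assert min(losses) < 0.1


def test_identical_seeds_identical_history():
    rxn = _tiny_reaction()
    cfg = MatcherConfig(embed_dim=8, mp_layers=2, seed=3, max_epochs=4,
                        early_stopping_patience=10)
    h1 = AtomMappingModel([rxn] * 10, config=cfg).fit().history
    h2 = AtomMappingModel([rxn] * 10, config=cfg).fit().history
    assert h1 == h2  # bitwise-identical losses


def test_divergence_aborts_with_diagnostics():
    # the epsilon clamp keeps ordinary training finite even at huge learning
    # rates, so corrupt an input to exercise the non-finite abort path
    rxn = _tiny_reaction()
    cfg = MatcherConfig(embed_dim=8, mp_layers=2, seed=0, max_epochs=5,
                        early_stopping_patience=5)
    model = AtomMappingModel([rxn] * 10, config=cfg)
    model._train[0].data_R.X = model._train[0].data_R.X.copy()
    model._train[0].data_R.X[0, 0] = np.inf
    with pytest.raises(TrainingDivergedError, match="epoch"):
        model.fit()


def test_results_summary_and_checkpoint_roundtrip(tmp_path):
    rxn = _tiny_reaction()
    cfg = MatcherConfig(embed_dim=8, mp_layers=2, seed=1, max_epochs=2,
                        early_stopping_patience=5)
    res = AtomMappingModel([rxn] * 5, [rxn], cfg).fit()
    text = res.summary()
    assert "embed_dim" in text and "best epoch" in text
    path = tmp_path / "ckpt.npz"
    res.save(path)
    params, config, history = load_checkpoint(path)
    assert config == cfg
    assert history == res.history
    for k, v in res.params.items():
        assert np.array_equal(params[k], v)


# ---------------------------------------------------------- prediction

def test_ranked_lists_cover_all_product_atoms():
    rxn = _tiny_reaction()
    pred = predict_mapping(rxn, _params(8, 2, seed=0),
                           MatcherConfig(embed_dim=8, mp_layers=2))
    nR, nP = rxn.gt_matrix.shape
    assert pred.rankings.shape == (nR, nP)
    for row in pred.rankings:
        assert sorted(row) == list(range(nP))
    assert sorted(pred.assignment) == list(range(nP))


def test_greedy_matches_optimal_on_dominant_matrices(rng):
    for _ in range(25):
        n = int(rng.integers(3, 7))
        perm = rng.permutation(n)
        M = rng.uniform(0.0, 0.2, size=(n, n))
        M[np.arange(n), perm] = rng.uniform(0.7, 1.0, size=n)
        greedy = _greedy_assignment(M)
        _, optimal = scipy.optimize.linear_sum_assignment(-np.log(M + 1e-12))
        assert np.array_equal(greedy, optimal)
        assert np.array_equal(greedy, perm)


def test_probability_matrices_invariants(small_reactions):
    cfg = MatcherConfig(embed_dim=8, mp_layers=2)
    params = _params(8, 2, seed=6)
    for rxn in small_reactions[:5]:
        pred = predict_mapping(rxn, params, cfg)
        M = pred.matrices
        assert np.allclose(M.probabilities.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(M.pooled >= M.probabilities - 1e-15)
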