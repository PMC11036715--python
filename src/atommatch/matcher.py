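"""The atom matching network: learned graph matching with symmetry pooling.

A shared-weight GIN encoder embeds reactant and product atoms into a common
space (with Jumping-Knowledge concatenation across message-passing layers).
Dot products between embeddings give an affinity matrix ``M_hat``; a softmax
over each reactant atom's row turns it into matching probabilities
``M_tilde``; summing probability mass over each product atom's topological
equivalence class gives the symmetry-pooled matrix ``M``, so the model is
never penalized for failing to distinguish chemically indistinguishable
atoms.  Training minimizes the negative log-likelihood of the pooled
ground-truth correspondence,

    L = - sum_i log M[i, pi_gt(i)].

The public surface follows the Model/Results convention: build an
:class:`AtomMappingModel` from reactions and a :class:`MatcherConfig`, call
``fit()`` to obtain an :class:`AtomMappingResults` carrying the learned
weights, the loss history, diagnostics and prediction/evaluation methods.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, asdict

import numpy as np
import scipy.optimize

from . import nn
from .molgraph import MoleculeGraph, ATOM_FEATURE_LEN, BOND_FEATURE_LEN
from .reaction import Reaction
from .symmetry import EquivalencePartition, equivalence_classes

logger = logging.getLogger(__name__)

__all__ = [
    "MatcherConfig",
    "CorrespondenceMatrices",
    "MappingPrediction",
    "AtomMappingModel",
    "AtomMappingResults",
    "embed_graph",
    "affinity",
    "normalize",
    "symmetry_pool",
    "class_pool_matrix",
    "nll_loss",
    "predict_mapping",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_SCHEMA = 1


@dataclass
class MatcherConfig:
    """Hyperparameters of the matching network.

    ``embed_dim=64`` is the desk-scale default; the large-scale setting
    (embed_dim 512, 3 message-passing layers, Adam at 1e-4) remains
    selectable.  ``normalization_axis`` chooses which slice of the affinity
    matrix the softmax turns into a distribution: ``per_reactant_atom``
    (default — each reactant atom distributes probability over product
    candidates, the reading the loss and top@k ranking require) or
    ``per_product_atom``.
    """

    embed_dim: int = 64
    mp_layers: int = 3
    learning_rate: float = 1e-4
    jumping_knowledge: bool = True
    aggregate: str = "sum"
    normalization_axis: str = "per_reactant_atom"
    seed: int = 0
    early_stopping_patience: int = 10
    min_delta: float = 1e-4
    max_epochs: int = 200
    batch_size: int = 16
    symmetry_aware_loss: bool = True
    eps_clamp: float = 1e-12

    def __post_init__(self) -> None:
        if self.embed_dim < 1 or self.mp_layers < 1:
            raise ValueError("embed_dim and mp_layers must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.aggregate not in ("sum", "mean", "max"):
            raise ValueError(f"unknown aggregate {self.aggregate!r}")
        if self.normalization_axis not in ("per_reactant_atom",
                                           "per_product_atom"):
            raise ValueError(
                f"unknown normalization_axis {self.normalization_axis!r}")


@dataclass
class CorrespondenceMatrices:
    """Raw affinities, matching probabilities and symmetry-pooled mass."""

    affinity: np.ndarray       # M_hat, |V_R| x |V_P|
    probabilities: np.ndarray  # M_tilde, same shape, slices sum to 1
    pooled: np.ndarray         # M, probability mass summed per product class


@dataclass
class MappingPrediction:
    """Ranked candidates and a one-to-one assignment for one reaction."""

    rankings: np.ndarray       # (|V_R|, |V_P|) product indices, best first
    assignment: np.ndarray     # (|V_R|,) product index per reactant atom
    matrices: CorrespondenceMatrices


# ---------------------------------------------------------------------------
# functional core


def embed_graph(graph: MoleculeGraph | nn.GraphData, params: dict,
                config: MatcherConfig) -> np.ndarray:
    """Node-embedding matrix, one row per atom (equivariant in atom order)."""
    data = graph if isinstance(graph, nn.GraphData) else nn.GraphData.from_graph(graph)
    H, _ = nn.encoder_forward(data, params, config.mp_layers,
                              config.jumping_knowledge, config.aggregate)
    return H


def affinity(H_R: np.ndarray, H_P: np.ndarray) -> np.ndarray:
    """Pairwise dot-product matching scores M_hat[i, j] = <H_R[i], H_P[j]>."""
    if H_R.shape[1] != H_P.shape[1]:
        raise ValueError(
            f"embedding widths differ: {H_R.shape[1]} vs {H_P.shape[1]}")
    return H_R @ H_P.T


def normalize(M_hat: np.ndarray,
              axis: str = "per_reactant_atom") -> np.ndarray:
    """Softmax of the affinity matrix along the configured slice.

    Stabilized by max-subtraction; every slice of the result sums to one.
    """
    ax = 1 if axis == "per_reactant_atom" else 0
    shifted = M_hat - M_hat.max(axis=ax, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=ax, keepdims=True)


def class_pool_matrix(partition: EquivalencePartition) -> np.ndarray:
    """C[j', j] = 1 iff product atoms j' and j are topologically equivalent.

    Right-multiplying M_tilde by C sums each row's probability mass over the
    class of every column, so all members of a class share a pooled value.
    """
    n = partition.n_atoms
    C = np.zeros((n, n))
    for members in partition.classes:
        idx = np.asarray(members)
        C[np.ix_(idx, idx)] = 1.0
    return C


def symmetry_pool(M_tilde: np.ndarray,
                  product_classes: EquivalencePartition) -> np.ndarray:
    """Aggregate matching probability over product equivalence classes."""
    if product_classes.n_atoms != M_tilde.shape[1]:
        raise ValueError(
            f"partition covers {product_classes.n_atoms} atoms but the "
            f"probability matrix has {M_tilde.shape[1]} product columns")
    return M_tilde @ class_pool_matrix(product_classes)


def nll_loss(M: np.ndarray, gt: np.ndarray, eps: float = 1e-12) -> float:
    """Negative log-likelihood of the ground-truth correspondences.

    ``gt`` is pi_gt as an index array (reactant atom i -> product atom
    pi[i]) or the equivalent permutation matrix.  Zero probabilities are
    clamped at ``eps`` with a warning.
    """
    gt = np.asarray(gt)
    if gt.ndim == 2:
        gt = np.argmax(gt, axis=1)
    p = M[np.arange(M.shape[0]), gt]
    if np.any(p <= 0):
        logger.warning("clamping %d zero ground-truth probabilities at %g",
                       int(np.sum(p <= 0)), eps)
    return float(-np.sum(np.log(np.maximum(p, eps))) + 0.0)


def _rank_rows(M_tilde: np.ndarray) -> np.ndarray:
    """Per-row candidate ranking, descending; ties broken by atom index."""
    # stable sort of -row keeps ascending column index among ties
    return np.argsort(-M_tilde, axis=1, kind="stable")


def _greedy_assignment(M_tilde: np.ndarray) -> np.ndarray:
    nR, nP = M_tilde.shape
    order = sorted(((-M_tilde[i, j], i, j) for i in range(nR)
                    for j in range(nP)))
    out = np.full(nR, -1, dtype=np.int64)
    used = np.zeros(nP, dtype=bool)
    for _, i, j in order:
        if out[i] < 0 and not used[j]:
            out[i] = j
            used[j] = True
    return out


def _optimal_assignment(M_tilde: np.ndarray, eps: float) -> np.ndarray:
    cost = -np.log(np.maximum(M_tilde, eps))
    _, cols = scipy.optimize.linear_sum_assignment(cost)
    return cols


def predict_mapping(reaction: Reaction, params: dict, config: MatcherConfig,
                    assignment: str = "greedy") -> MappingPrediction:
    """Rank product candidates per reactant atom and emit a one-to-one map.

    Rankings sort each reactant atom's probability row in descending order
    (ties by ascending product index).  The emitted mapping is the greedy
    highest-probability assignment without column reuse; ``assignment=
    "optimal"`` solves the linear assignment problem instead.
    """
    H_R = embed_graph(reaction.reactants, params, config)
    H_P = embed_graph(reaction.products, params, config)
    M_hat = affinity(H_R, H_P)
    M_tilde = normalize(M_hat, config.normalization_axis)
    pooled = symmetry_pool(M_tilde, equivalence_classes(reaction.products))
    if assignment == "greedy":
        assign = _greedy_assignment(M_tilde)
    elif assignment == "optimal":
        assign = _optimal_assignment(M_tilde, config.eps_clamp)
    else:
        raise ValueError(f"unknown assignment mode {assignment!r}")
    return MappingPrediction(
        rankings=_rank_rows(M_tilde),
        assignment=assign,
        matrices=CorrespondenceMatrices(M_hat, M_tilde, pooled),
    )


# ---------------------------------------------------------------------------
# training


@dataclass
class _PackedReaction:
    data_R: nn.GraphData
    data_P: nn.GraphData
    gt: np.ndarray          # pi_gt index array
    pool: np.ndarray        # class pool matrix of the product side
    class_of_gt: np.ndarray  # per reactant atom: bool mask over product atoms


def _pack(reaction: Reaction, symmetry_aware: bool) -> _PackedReaction:
    gt = reaction.gt_permutation
    if symmetry_aware:
        partition = equivalence_classes(reaction.products)
        C = class_pool_matrix(partition)
    else:
        C = np.eye(reaction.products.atom_count)
    return _PackedReaction(
        data_R=nn.GraphData.from_graph(reaction.reactants),
        data_P=nn.GraphData.from_graph(reaction.products),
        gt=gt,
        pool=C,
        class_of_gt=C[:, gt].T.astype(bool),
    )


def _forward_backward(packed: _PackedReaction, params: dict,
                      config: MatcherConfig, grads: dict | None) -> float:
    """Loss for one reaction; accumulates parameter gradients if given."""
    H_R, cache_R = nn.encoder_forward(packed.data_R, params, config.mp_layers,
                                      config.jumping_knowledge,
                                      config.aggregate)
    H_P, cache_P = nn.encoder_forward(packed.data_P, params, config.mp_layers,
                                      config.jumping_knowledge,
                                      config.aggregate)
    M_hat = H_R @ H_P.T
    ax = 1 if config.normalization_axis == "per_reactant_atom" else 0
    shifted = M_hat - M_hat.max(axis=ax, keepdims=True)
    e = np.exp(shifted)
    M_tilde = e / e.sum(axis=ax, keepdims=True)
    nR = M_tilde.shape[0]
    # pooled ground-truth probability per reactant atom
    p = np.maximum((M_tilde * packed.class_of_gt).sum(axis=1),
                   config.eps_clamp)
    loss = float(-np.sum(np.log(p)))
    if grads is None:
        return loss
    # dL/dM_tilde: -1/p_i on the ground-truth class columns
    dMt = np.where(packed.class_of_gt, -(1.0 / p)[:, None], 0.0)
    # softmax backward along the normalization slice
    if ax == 1:
        inner = (dMt * M_tilde).sum(axis=1, keepdims=True)
    else:
        inner = (dMt * M_tilde).sum(axis=0, keepdims=True)
    dM_hat = M_tilde * (dMt - inner)
    dH_R = dM_hat @ H_P
    dH_P = dM_hat.T @ H_R
    nn.encoder_backward(dH_R, packed.data_R, params, cache_R, grads)
    nn.encoder_backward(dH_P, packed.data_P, params, cache_P, grads)
    return loss


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


class AtomMappingModel:
    """Graph-matching model over a set of balanced, ground-truth reactions.

    Parameters
    ----------
    train_reactions
        Reactions used for gradient updates.
    val_reactions
        Held-out reactions scored each epoch for early stopping; when omitted,
        training runs for ``config.max_epochs`` epochs.
    config
        Hyperparameters; see :class:`MatcherConfig`.
    """

    def __init__(self, train_reactions: list[Reaction],
                 val_reactions: list[Reaction] | None = None,
                 config: MatcherConfig | None = None):
        if not train_reactions:
            raise ValueError("train_reactions must be nonempty")
        self.config = config or MatcherConfig()
        self.train_reactions = train_reactions
        self.val_reactions = val_reactions or []
        sym = self.config.symmetry_aware_loss
        self._train = [_pack(r, sym) for r in train_reactions]
        self._val = [_pack(r, sym) for r in self.val_reactions]

    @classmethod
    def from_records(cls, train_lines: list[str],
                     val_lines: list[str] | None = None,
                     config: MatcherConfig | None = None) -> "AtomMappingModel":
        """Build the model from reaction-record TSV lines."""
        from .reaction import reaction_from_record
        train = [reaction_from_record(l, i + 1)
                 for i, l in enumerate(train_lines) if l.strip()]
        val = [reaction_from_record(l, i + 1)
               for i, l in enumerate(val_lines or []) if l.strip()]
        return cls(train, val or None, config)

    def _epoch_loss(self, packed: list[_PackedReaction], params: dict) -> float:
        return float(np.mean([_forward_backward(p, params, self.config, None)
                              for p in packed]))

    def fit(self, verbose: bool = False) -> "AtomMappingResults":
        """Train with Adam and early stopping; deterministic given the seed."""
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        params = nn.init_params(ATOM_FEATURE_LEN, BOND_FEATURE_LEN,
                                cfg.embed_dim, cfg.mp_layers, cfg.seed)
        opt = nn.Adam(params, lr=cfg.learning_rate)
        history: list[dict] = []
        best_val = np.inf
        best_params = {k: v.copy() for k, v in params.items()}
        best_epoch = 0
        patience_left = cfg.early_stopping_patience
        t0 = time.time()
        for epoch in range(1, cfg.max_epochs + 1):
            order = rng.permutation(len(self._train))
            epoch_losses = []
            for start in range(0, len(order), cfg.batch_size):
                batch = [self._train[i] for i in order[start:start + cfg.batch_size]]
                grads = {k: np.zeros_like(v) for k, v in params.items()}
                batch_loss = 0.0
                for packed in batch:
                    batch_loss += _forward_backward(packed, params, cfg, grads)
                for k in grads:
                    grads[k] /= len(batch)
                batch_loss /= len(batch)
                if not np.isfinite(batch_loss):
                    raise TrainingDivergedError(
                        f"non-finite loss at epoch {epoch} "
                        f"(lr={cfg.learning_rate}, embed_dim={cfg.embed_dim})")
                epoch_losses.append(batch_loss)
                opt.step(params, grads)
            train_loss = float(np.mean(epoch_losses))
            val_loss = (self._epoch_loss(self._val, params)
                        if self._val else np.nan)
            history.append({"epoch": epoch, "train_loss": train_loss,
                            "val_loss": val_loss})
            if verbose:
                logger.info("epoch=%d train_loss=%.6f val_loss=%.6f",
                            epoch, train_loss, val_loss)
            monitor = val_loss if self._val else train_loss
            if monitor < best_val - cfg.min_delta:
                best_val = monitor
                best_params = {k: v.copy() for k, v in params.items()}
                best_epoch = epoch
                patience_left = cfg.early_stopping_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break
        return AtomMappingResults(
            model=self, params=best_params, history=history,
            best_epoch=best_epoch, best_val_loss=float(best_val),
            wall_time=time.time() - t0,
        )


@dataclass
class AtomMappingResults:
    """Fitted matching network: weights, training history and diagnostics."""

    model: AtomMappingModel
    params: dict[str, np.ndarray]
    history: list[dict]
    best_epoch: int
    best_val_loss: float
    wall_time: float = 0.0

    @property
    def config(self) -> MatcherConfig:
        return self.model.config

    def predict(self, reaction: Reaction,
                assignment: str = "greedy") -> MappingPrediction:
        return predict_mapping(reaction, self.params, self.config, assignment)

    def evaluate(self, reactions: list[Reaction], ks=(1, 3, 5, 10)):
        """Symmetry-aware evaluation report on held-out reactions."""
        from .evaluate import evaluate_reactions
        return evaluate_reactions(reactions, self.params, self.config, ks=ks)

    def summary(self) -> str:
        cfg = asdict(self.config)
        n_params = sum(v.size for v in self.params.values())
        lines = [
            "Atom Mapping Results",
            "=" * 60,
            f"{'training reactions':<30}{len(self.model.train_reactions):>10}",
            f"{'validation reactions':<30}{len(self.model.val_reactions):>10}",
            f"{'parameters':<30}{n_params:>10}",
            f"{'epochs run':<30}{len(self.history):>10}",
            f"{'best epoch':<30}{self.best_epoch:>10}",
            f"{'best monitored loss':<30}{self.best_val_loss:>10.4f}",
            f"{'wall time (s)':<30}{self.wall_time:>10.1f}",
            "-" * 60,
        ]
        for key in ("embed_dim", "mp_layers", "learning_rate",
                    "jumping_knowledge", "aggregate", "normalization_axis",
                    "batch_size", "seed"):
            lines.append(f"{key:<30}{cfg[key]!s:>10}")
        return "\n".join(lines)

    def save(self, path) -> None:
        save_checkpoint(path, self.params, self.config, self.history,
                        self.best_epoch)


def save_checkpoint(path, params: dict, config: MatcherConfig,
                    history: list[dict], best_epoch: int = 0) -> None:
    """Single-archive checkpoint: config echo + weights + history, versioned."""
    meta = {"schema": CHECKPOINT_SCHEMA, "config": asdict(config),
            "history": history, "best_epoch": best_epoch}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **params)


def load_checkpoint(path) -> tuple[dict, MatcherConfig, list[dict]]:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        if meta["schema"] != CHECKPOINT_SCHEMA:
            raise ValueError(f"unsupported checkpoint schema {meta['schema']}")
        params = {k: archive[k] for k in archive.files if k != "__meta__"}
    return params, MatcherConfig(**meta["config"]), meta["history"]
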