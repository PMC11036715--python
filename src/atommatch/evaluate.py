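"""Symmetry-aware evaluation of predicted atom mappings.

A reactant atom's prediction counts as a hit at ``k`` when any member of the
ground-truth product atom's topological-equivalence class appears among its
first ``k`` ranked candidates; a reaction is correctly mapped at ``k`` when
every reactant atom hits.  The dataset-level "average accuracy" is the mean
over reactions of the per-reaction fraction of atoms hit at k = 1 (the
per-atom pooled mean is reported alongside for transparency, as is the strict
exact-index variant which ignores symmetry).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .symmetry import EquivalencePartition, equivalence_classes

__all__ = [
    "EvalReport",
    "ReactionResult",
    "atom_hit_at_k",
    "reaction_correct_at_k",
    "average_accuracy",
    "evaluate_rankings",
    "evaluate_reactions",
    "evaluate_assignments",
]

DEFAULT_KS = (1, 3, 5, 10)


@dataclass
class ReactionResult:
    """Per-reaction tallies: atom hits at each k and correctness flags."""

    atom_hits: dict[int, int]      # k -> number of reactant atoms hit
    atom_total: int
    correct_at_k: dict[int, bool]  # k -> every atom hit
    strict_hits: int = 0           # exact-index hits at k = 1

    def accuracy(self, k: int = 1) -> float:
        return self.atom_hits[k] / self.atom_total


@dataclass
class EvalReport:
    """Dataset-level evaluation summary (percentages in [0, 100])."""

    avg_accuracy: float                    # reaction-mean atom accuracy at k=1
    topk_reaction_pct: dict[int, float]    # k -> % of reactions fully correct
    per_reaction: list[ReactionResult]
    strict_avg_accuracy: float = 0.0       # same but exact-index (no symmetry)
    atom_pooled_accuracy: float = 0.0      # atoms pooled across reactions
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "avg_accuracy": self.avg_accuracy,
            "strict_avg_accuracy": self.strict_avg_accuracy,
            "atom_pooled_accuracy": self.atom_pooled_accuracy,
            "topk_reaction_pct": {str(k): v
                                  for k, v in self.topk_reaction_pct.items()},
            "n_reactions": len(self.per_reaction),
            **self.extras,
        }


def atom_hit_at_k(ranking, gt_atom: int,
                  product_classes: EquivalencePartition, k: int) -> bool:
    """True iff a member of ``gt_atom``'s equivalence class is in the top k."""
    ranking = np.asarray(ranking)
    if not 0 <= gt_atom < product_classes.n_atoms:
        raise IndexError(f"ground-truth atom {gt_atom} outside product range")
    if k < 1:
        raise ValueError("k must be >= 1")
    cls = set(product_classes.members(int(gt_atom)))
    return any(int(c) in cls for c in ranking[:k])


def reaction_correct_at_k(atom_hits: int, atom_total: int,
                          require_fraction: float = 1.0) -> bool:
    """A reaction is correctly mapped when (all of) its atoms hit.

    ``require_fraction`` relaxes the all-atoms requirement to a fraction
    threshold; the default 1.0 is the strictest reading.
    """
    return atom_hits >= require_fraction * atom_total


def _score_reaction(rankings: np.ndarray, gt: np.ndarray,
                    partition: EquivalencePartition, ks,
                    reactant_classes: EquivalencePartition | None,
                    require_fraction: float) -> ReactionResult:
    nR = rankings.shape[0]
    class_of = partition.class_of()
    hit = {k: np.zeros(nR, dtype=bool) for k in ks}
    strict = 0
    for i in range(nR):
        gt_cls = class_of[gt[i]]
        for k in ks:
            hit[k][i] = bool(np.any(class_of[rankings[i, :k]] == gt_cls))
        strict += int(rankings[i, 0] == gt[i])
    if reactant_classes is not None:
        # flag-enabled tolerance: a reactant atom also hits when an equivalent
        # reactant atom's ranking row contains the ground-truth class
        for members in reactant_classes.classes:
            if len(members) > 1:
                for k in ks:
                    if np.any(hit[k][members]):
                        hit[k][members] = True
    atom_hits = {k: int(hit[k].sum()) for k in ks}
    return ReactionResult(
        atom_hits=atom_hits,
        atom_total=nR,
        correct_at_k={k: reaction_correct_at_k(atom_hits[k], nR,
                                               require_fraction) for k in ks},
        strict_hits=strict,
    )


def average_accuracy(results: list[ReactionResult], k: int = 1) -> float:
    """Mean over reactions of per-reaction atom accuracy at ``k``, as a %."""
    if not results:
        raise ValueError("empty result set")
    return 100.0 * float(np.mean([r.accuracy(k) for r in results]))


def evaluate_rankings(items, ks=DEFAULT_KS, reactant_tolerance: bool = False,
                      require_fraction: float = 1.0) -> EvalReport:
    """Score (rankings, gt_permutation, product_partition[, reactant_partition])
    tuples into an :class:`EvalReport`."""
    per: list[ReactionResult] = []
    for item in items:
        rankings, gt, partition = item[0], np.asarray(item[1]), item[2]
        reactant_classes = item[3] if reactant_tolerance and len(item) > 3 else None
        per.append(_score_reaction(np.asarray(rankings), gt, partition, ks,
                                   reactant_classes, require_fraction))
    if not per:
        raise ValueError("empty result set")
    total_atoms = sum(r.atom_total for r in per)
    report = EvalReport(
        avg_accuracy=average_accuracy(per, k=min(ks)),
        strict_avg_accuracy=100.0 * float(
            np.mean([r.strict_hits / r.atom_total for r in per])),
        atom_pooled_accuracy=100.0 * sum(r.atom_hits[min(ks)] for r in per)
        / total_atoms,
        topk_reaction_pct={k: 100.0 * float(
            np.mean([r.correct_at_k[k] for r in per])) for k in ks},
        per_reaction=per,
    )
    return report


def evaluate_reactions(reactions, params, config, ks=DEFAULT_KS,
                       reactant_tolerance: bool = False,
                       require_fraction: float = 1.0) -> EvalReport:
    """Predict rankings for each reaction with a fitted model and score them."""
    from .matcher import predict_mapping

    items = []
    for rxn in reactions:
        pred = predict_mapping(rxn, params, config)
        items.append((pred.rankings, rxn.gt_permutation,
                      equivalence_classes(rxn.products),
                      equivalence_classes(rxn.reactants)))
    return evaluate_rankings(items, ks=ks, reactant_tolerance=reactant_tolerance,
                             require_fraction=require_fraction)


def evaluate_assignments(items, reactant_tolerance: bool = False,
                         require_fraction: float = 1.0) -> EvalReport:
    """Score one-to-one assignments (k = 1 only): (assignment, gt, partition)."""
    wrapped = [(np.asarray(a)[:, None], gt, part, *rest)
               for a, gt, part, *rest in items]
    return evaluate_rankings(wrapped, ks=(1,),
                             reactant_tolerance=reactant_tolerance,
                             require_fraction=require_fraction)
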