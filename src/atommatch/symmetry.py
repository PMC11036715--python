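"""Topological equivalence of atoms via Weisfeiler-Lehman refinement.

Many molecules are symmetric: swapping two atoms with identical chemical
environments yields an equally valid atom mapping.  This module detects such
topologically equivalent atoms with an adapted Weisfeiler-Lehman (WL) colour
refinement — labels start as atomic symbols and are iteratively replaced by a
canonical combination of the current label with the sorted multiset of
neighbour labels.  Two atoms are topologically equivalent when they share an
element symbol and their three-hop neighbourhoods agree, i.e. their labels
coincide after three refinement iterations.

The same machinery enumerates every atom mapping of a reaction that differs
from a known one only by swaps of equivalent atoms.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .molgraph import MoleculeGraph

__all__ = [
    "WLColoring",
    "EquivalencePartition",
    "wl_refine",
    "equivalence_classes",
    "class_automorphisms",
    "enumerate_symmetric_mappings",
    "MappingExplosionError",
]

DEFAULT_WL_ITERATIONS = 3  # "three hop" equivalence


@dataclass
class WLColoring:
    """Per-atom label strings for every refinement step t = 0..T."""

    labels: list[list[str]]

    @property
    def iterations(self) -> int:
        return len(self.labels) - 1

    def partition(self, t: int = -1) -> list[list[int]]:
        """Atom-index classes induced by the labels at step ``t``."""
        groups: dict[str, list[int]] = {}
        for i, lab in enumerate(self.labels[t]):
            groups.setdefault(lab, []).append(i)
        return sorted(groups.values())


@dataclass
class EquivalencePartition:
    """Disjoint classes of topologically equivalent atoms covering all atoms."""

    classes: list[list[int]]

    @property
    def n_atoms(self) -> int:
        return sum(len(c) for c in self.classes)

    def class_of(self) -> np.ndarray:
        """Array mapping each atom index to its class index."""
        out = np.empty(self.n_atoms, dtype=np.int64)
        for ci, members in enumerate(self.classes):
            out[members] = ci
        return out

    def members(self, atom: int) -> list[int]:
        for c in self.classes:
            if atom in c:
                return c
        raise IndexError(f"atom {atom} not covered by the partition")

    @property
    def n_nontrivial(self) -> int:
        return sum(1 for c in self.classes if len(c) > 1)


def wl_refine(
    graph: MoleculeGraph,
    iterations: int = DEFAULT_WL_ITERATIONS,
    include_bond_order: bool = False,
) -> WLColoring:
    """Run WL colour refinement for ``iterations`` steps.

    label(i, t+1) = label(i, t) + "(" + sorted multiset of neighbour labels
    at step t + ")".  Canonical strings are used instead of integer hashes so
    there is no collision risk at molecule scale.  With
    ``include_bond_order`` each neighbour token carries the connecting bond's
    order, giving a stricter equivalence.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    current = list(graph.atom_symbols)
    history = [list(current)]
    for _ in range(iterations):
        new = []
        for i in range(graph.atom_count):
            tokens = []
            for j in graph.neighbors(i):
                tok = current[j]
                if include_bond_order:
                    tok = f"{tok}~{graph.bond_order(i, int(j)):g}"
                tokens.append(tok)
            new.append(current[i] + "(" + ",".join(sorted(tokens)) + ")")
        history.append(new)
        # compact ids between rounds keep label strings short; the canonical
        # relabeling preserves the induced partition exactly
        canon = {lab: f"#{k}" for k, lab in enumerate(sorted(set(new)))}
        current = [canon[lab] for lab in new]
    return WLColoring(labels=history)


def equivalence_classes(
    graph: MoleculeGraph,
    iterations: int = DEFAULT_WL_ITERATIONS,
    include_bond_order: bool = False,
) -> EquivalencePartition:
    """Partition atoms into topological-equivalence classes (WL, 3 iterations)."""
    coloring = wl_refine(graph, iterations, include_bond_order)
    return EquivalencePartition(classes=coloring.partition(-1))


class MappingExplosionError(RuntimeError):
    """Raised when symmetric-mapping enumeration would exceed the size cap."""


def class_automorphisms(
    graph: MoleculeGraph,
    partition: EquivalencePartition,
    cap: int = 10_000,
) -> list[np.ndarray]:
    """All adjacency-preserving permutations that move atoms only within
    their equivalence classes.

    Every graph automorphism preserves WL classes, so this search space
    contains the full automorphism group restricted to molecule symmetry;
    candidates are per-class permutation products filtered by an exact
    adjacency check.  Aborts if the candidate count exceeds ``cap``.
    """
    total = 1
    for c in partition.classes:
        for k in range(2, len(c) + 1):
            total *= k
        if total > cap:
            raise MappingExplosionError(
                f"symmetry enumeration would examine more than {cap} candidate "
                "permutations; raise the cap to proceed"
            )
    A = graph.adjacency
    perms: list[np.ndarray] = []
    class_perms = [list(itertools.permutations(c)) for c in partition.classes]
    for combo in itertools.product(*class_perms):
        sigma = np.empty(graph.atom_count, dtype=np.int64)
        for members, image in zip(partition.classes, combo):
            sigma[members] = image
        if np.array_equal(A[np.ix_(sigma, sigma)], A):
            perms.append(sigma)
    return perms


def enumerate_symmetric_mappings(
    reaction,
    partition_R: EquivalencePartition | None = None,
    partition_P: EquivalencePartition | None = None,
    cap: int = 10_000,
) -> list[np.ndarray]:
    """All valid correspondence matrices derivable from a reaction's known
    mapping by permuting topologically equivalent atoms on either side.

    Returns deduplicated permutation matrices sigma_P @ M_gt @ sigma_R over
    class-preserving automorphisms of each side; the known mapping itself is
    always among them.
    """
    if partition_R is None:
        partition_R = equivalence_classes(reaction.reactants)
    if partition_P is None:
        partition_P = equivalence_classes(reaction.products)
    gt = np.asarray(reaction.gt_matrix)
    auts_R = class_automorphisms(reaction.reactants, partition_R, cap)
    auts_P = class_automorphisms(reaction.products, partition_P, cap)
    if len(auts_R) * len(auts_P) > cap:
        raise MappingExplosionError(
            f"{len(auts_R)} x {len(auts_P)} automorphism combinations exceed "
            f"the cap of {cap}"
        )
    seen: dict[bytes, np.ndarray] = {}
    for sR in auts_R:
        # rows permuted by the reactant automorphism
        gt_r = gt[sR]
        for sP in auts_P:
            mapped = gt_r[:, sP]
            seen.setdefault(mapped.tobytes(), mapped)
    return list(seen.values())
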