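"""Seeded generator of desk-scale reaction datasets with known ground truth.

Molecules are grown as random trees over a small organic palette (C, N, O, S,
F, Cl with standard maximum valences) with occasional double bonds and up to
two ring closures; a configurable fraction of molecules is built by mirroring
a random fragment so that at least one nontrivial topological-equivalence
class exists.  Reaction edits (bond deletions/additions with the implied
hydrogen bookkeeping) are rejection-sampled so every product is valence-legal,
and each reaction is finally position-scrambled by a seeded remap.  The
ground-truth correspondence is known by construction, so every other module
is testable without external downloads.

Aromatic systems are deliberately excluded (any draw that RDKit perceives as
aromatic is redrawn): kekulization ambiguity would make the hydrogen
bookkeeping of bond edits ill-defined on symmetric rings.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from rdkit import Chem

from .molgraph import MoleculeGraph, mol_to_graph
from .reaction import (Reaction, ReactionEdits, apply_edits, remap_reaction,
                       reaction_to_record, split_dataset)

__all__ = ["GeneratorConfig", "generate_molecule", "generate_reaction",
           "generate_dataset"]

#: Standard maximum valences for the toy palette.
PALETTE_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "F": 1, "Cl": 1}


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic-reaction generator."""

    n_reactions: int = 1000
    atom_range: tuple[int, int] = (6, 16)
    edit_range: tuple[int, int] = (1, 3)
    symmetry_fraction: float = 0.4
    element_palette: tuple[str, ...] = ("C", "N", "O", "S", "F", "Cl")
    seed: int = 0
    double_bond_prob: float = 0.15
    ring_prob: float = 0.3

    def __post_init__(self) -> None:
        if self.atom_range[0] > self.atom_range[1]:
            raise ValueError("atom_range min > max")
        if self.edit_range[0] > self.edit_range[1]:
            raise ValueError("edit_range min > max")
        if not self.element_palette:
            raise ValueError("element palette is empty")
        unknown = set(self.element_palette) - set(PALETTE_VALENCE)
        if unknown:
            raise ValueError(f"palette elements without a valence rule: {unknown}")


class _Builder:
    """Incremental molecule under construction with free-valence bookkeeping."""

    def __init__(self):
        self.symbols: list[str] = []
        self.bonds: dict[tuple[int, int], int] = {}
        self.free: list[int] = []

    def add_atom(self, symbol: str) -> int:
        self.symbols.append(symbol)
        self.free.append(PALETTE_VALENCE[symbol])
        return len(self.symbols) - 1

    def add_bond(self, i: int, j: int, order: int) -> None:
        assert self.free[i] >= order and self.free[j] >= order
        self.bonds[(min(i, j), max(i, j))] = order
        self.free[i] -= order
        self.free[j] -= order

    def bonded(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in self.bonds

    def distance(self, i: int, j: int) -> int:
        """BFS bond-count distance between atoms i and j."""
        adj: dict[int, list[int]] = {k: [] for k in range(len(self.symbols))}
        for (a, b) in self.bonds:
            adj[a].append(b)
            adj[b].append(a)
        frontier, dist, seen = [i], 0, {i}
        while frontier:
            if j in frontier:
                return dist
            dist += 1
            frontier = [n for f in frontier for n in adj[f] if n not in seen]
            seen.update(frontier)
        return -1

    def to_mol(self) -> Chem.Mol:
        mol = Chem.RWMol()
        for sym in self.symbols:
            mol.AddAtom(Chem.Atom(sym))
        order_map = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                     3: Chem.BondType.TRIPLE}
        for (i, j), order in self.bonds.items():
            mol.AddBond(i, j, order_map[order])
        out = mol.GetMol()
        Chem.SanitizeMol(out)
        return out


def _grow_fragment(builder: _Builder, n: int, config: GeneratorConfig,
                   rng: np.random.Generator, root_reserve: int = 0) -> int | None:
    """Grow a random tree fragment of ``n`` atoms; returns the root index.

    ``root_reserve`` valence units on the root are kept free for later
    attachment (mirroring, central joins).
    """
    palette = list(config.element_palette)
    # root must support the reserved attachment plus at least one child
    heavy = [s for s in palette if PALETTE_VALENCE[s] >= max(2, root_reserve + (1 if n > 1 else 0))]
    if not heavy:
        return None
    root = builder.add_atom(heavy[rng.integers(len(heavy))])
    members = [root]
    for _ in range(n - 1):
        hosts = [a for a in members
                 if builder.free[a] - (root_reserve if a == root else 0) >= 1]
        if not hosts:
            return None
        host = hosts[rng.integers(len(hosts))]
        host_free = builder.free[host] - (root_reserve if host == root else 0)
        sym = palette[rng.integers(len(palette))]
        order = 1
        if (config.double_bond_prob > rng.random()
                and host_free >= 2 and PALETTE_VALENCE[sym] >= 2):
            order = 2
        new = builder.add_atom(sym)
        builder.add_bond(host, new, order)
        members.append(new)
    # optional ring closures within the fragment (ring size >= 4)
    for _ in range(2):
        if rng.random() >= config.ring_prob:
            continue
        candidates = [(a, b) for ai, a in enumerate(members)
                      for b in members[ai + 1:]
                      if not builder.bonded(a, b)
                      and builder.free[a] - (root_reserve if a == root else 0) >= 1
                      and builder.free[b] - (root_reserve if b == root else 0) >= 1
                      and builder.distance(a, b) >= 3]
        if candidates:
            a, b = candidates[rng.integers(len(candidates))]
            builder.add_bond(a, b, 1)
    return root


def _build_molecule(config: GeneratorConfig, rng: np.random.Generator,
                    symmetric: bool) -> Chem.Mol | None:
    n = int(rng.integers(config.atom_range[0], config.atom_range[1] + 1))
    builder = _Builder()
    if symmetric and n >= 2:
        half = (n - 1) // 2 if n % 2 else n // 2
        frag = _Builder()
        if _grow_fragment(frag, half, config, rng, root_reserve=1) is None:
            return None
        # mirror: two identical copies joined directly (even n) or through a
        # central carbon (odd n); the copies are exchangeable by construction
        for sym in frag.symbols + frag.symbols:
            builder.add_atom(sym)
        off = half
        for (i, j), order in frag.bonds.items():
            builder.add_bond(i, j, order)
            builder.add_bond(i + off, j + off, order)
        if n % 2:
            center = builder.add_atom("C")
            builder.add_bond(0, center, 1)
            builder.add_bond(off, center, 1)
        else:
            builder.add_bond(0, off, 1)
    else:
        if _grow_fragment(builder, n, config, rng) is None:
            return None
    try:
        mol = builder.to_mol()
    except Exception:  # noqa: BLE001 - any sanitize failure triggers a redraw
        return None
    if any(b.GetIsAromatic() for b in mol.GetBonds()):
        return None  # aromatic draws are excluded (see module docstring)
    return mol


def generate_molecule(config: GeneratorConfig,
                      rng: np.random.Generator) -> MoleculeGraph:
    """Draw one connected, valence-legal molecule (retries internally).

    With probability ``symmetry_fraction`` the molecule is built by mirroring
    a random fragment, guaranteeing a nontrivial equivalence class; otherwise
    random growth is redrawn (bounded) when it lands on an incidentally
    symmetric structure, so the knob controls the symmetric share crisply.
    """
    from .symmetry import equivalence_classes

    symmetric = rng.random() < config.symmetry_fraction
    fallback = None
    for _ in range(200):
        mol = _build_molecule(config, rng, symmetric)
        if mol is None:
            continue
        for atom in mol.GetAtoms():
            atom.SetAtomMapNum(atom.GetIdx() + 1)
        graph = mol_to_graph(mol)
        if symmetric or equivalence_classes(graph).n_nontrivial == 0:
            return graph
        if fallback is None:
            fallback = graph  # accepted if no asymmetric draw shows up
    if fallback is not None:
        return fallback
    raise RuntimeError("molecule generation failed after 200 attempts")


def _sample_edits(graph: MoleculeGraph, config: GeneratorConfig,
                  rng: np.random.Generator) -> ReactionEdits | None:
    """Sample legal edits relative to the original reactant.

    Deleting a bond of order o frees o hydrogens on each endpoint; adding a
    single bond consumes one on each, so valence legality is preserved
    exactly.  Each atom pair is touched at most once.
    """
    n_edits = int(rng.integers(config.edit_range[0], config.edit_range[1] + 1))
    mol = graph.mol
    free_h = [a.GetTotalNumHs() for a in mol.GetAtoms()]
    maps = graph.atom_map_numbers
    original = {(min(i, j), max(i, j)): int(b.GetBondTypeAsDouble())
                for b in mol.GetBonds()
                for i, j in [(b.GetBeginAtomIdx(), b.GetEndAtomIdx())]}
    touched: set[tuple[int, int]] = set()
    edits = ReactionEdits()
    for _ in range(n_edits):
        for _attempt in range(30):
            if rng.random() < 0.5:
                pool = [p for p in original if p not in touched]
                if not pool:
                    continue
                i, j = pool[rng.integers(len(pool))]
                order = original[(i, j)]
                edits.deleted_bonds.append((maps[i], maps[j]))
                edits.gained_h += [maps[i]] * order + [maps[j]] * order
                free_h[i] += order
                free_h[j] += order
                touched.add((i, j))
                break
            else:
                n = graph.atom_count
                pairs = [(a, b) for a in range(n) for b in range(a + 1, n)
                         if (a, b) not in original and (a, b) not in touched
                         and free_h[a] >= 1 and free_h[b] >= 1]
                if not pairs:
                    continue
                i, j = pairs[rng.integers(len(pairs))]
                edits.added_bonds.append((maps[i], maps[j], 1.0))
                edits.lost_h += [maps[i], maps[j]]
                free_h[i] -= 1
                free_h[j] -= 1
                touched.add((i, j))
                break
        else:
            return None
    return edits


def generate_reaction(config: GeneratorConfig, rng: np.random.Generator,
                      remap: bool = True) -> tuple[str, Reaction]:
    """Draw one balanced reaction; returns (TSV record line, Reaction).

    The product is constructed by applying the sampled edits to the reactant
    (identity correspondence), then both sides are independently permuted by
    a seeded remap so atom positions carry no information.  The record line
    round-trips through the parser to an identical reaction.
    """
    for _ in range(200):
        reactants = generate_molecule(config, rng)
        edits = _sample_edits(reactants, config, rng)
        if edits is None:
            continue
        try:
            products = apply_edits(reactants, edits)
        except Exception:  # noqa: BLE001 - resample on any edit failure
            continue
        gt = np.eye(reactants.atom_count, dtype=np.int8)
        reaction = Reaction(reactants=reactants, products=products,
                            edits=edits, gt_matrix=gt)
        if remap:
            reaction = remap_reaction(reaction,
                                      seed=int(rng.integers(2 ** 31)))
        line = reaction_to_record(reaction)
        # the writer canonicalizes atom order, so return the re-parsed
        # reaction: record and object then agree index-for-index
        from .reaction import reaction_from_record
        return line, reaction_from_record(line, check_product=False)
    raise RuntimeError("reaction generation failed after 200 attempts")


def generate_dataset(config: GeneratorConfig, out_dir=None):
    """Generate ``n_reactions`` records and split them 70/10/20, seeded.

    When ``out_dir`` is given, writes ``train.tsv``/``val.tsv``/``test.tsv``
    plus a JSON manifest (seed, config echo, counts); re-running with the
    same config reproduces byte-identical files.  Returns the three record
    lists and the manifest dict.
    """
    if config.n_reactions < 10:
        raise ValueError("need at least 10 reactions for a 70/10/20 split")
    rng = np.random.default_rng(config.seed)
    records = [generate_reaction(config, rng)[0]
               for _ in range(config.n_reactions)]
    train, val, test = split_dataset(records, seed=config.seed)
    manifest = {
        "seed": config.seed,
        "config": {**asdict(config),
                   "atom_range": list(config.atom_range),
                   "edit_range": list(config.edit_range),
                   "element_palette": list(config.element_palette)},
        "counts": {"train": len(train), "val": len(val), "test": len(test)},
        "generated_at": time.strftime("%Y-%m-%d"),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, lines in (("train", train), ("val", val), ("test", test)):
            (out / f"{name}.tsv").write_text("\n".join(lines) + "\n")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return train, val, test, manifest
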