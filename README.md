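# atommatch

Symmetry-aware atom mapping of chemical reactions via deep graph matching.

## The problem

Atom mapping assigns each atom in the reactants of a chemical reaction to its
corresponding atom in the products — the prerequisite for identifying reaction
centres, extracting templates and tracing bond changes. `atommatch` treats
this as a *graph matching* problem: reactant and product molecules become
featurized graphs G(V, A, X, E), a shared-weight graph neural encoder embeds
every atom, and a learned correspondence matrix scores all reactant–product
atom pairs.

Many molecules are symmetric. When two atoms are topologically equivalent
(same element, same three-hop environment), any mapping that swaps them is
equally valid, and a model should never be penalized for picking either. The
package detects such atoms with an adapted Weisfeiler-Lehman (WL) colour
refinement and uses the resulting equivalence classes both in the training
loss and in evaluation.

## The model

- **Featurization** — heavy atoms only; per-atom features are the
  concatenation of one-hot blocks (64-element atom type, heavy-neighbour
  count, formal charge, hybridization, valence 1–6, ring/aromaticity flags,
  min–max-scaled mass and radii, chirality type, hydrogen count; 106
  dimensions total) and six-dimensional bond features (type one-hot,
  conjugation, ring membership).
- **Encoder** — a GIN (graph isomorphism network) with edge features,
  `h_i ← MLP(h_i + Σ_j ReLU(h_j + W_e e_ij))`, three message-passing layers,
  Jumping-Knowledge concatenation of all layer outputs. Both sides share
  weights: `H_R = GNN(A_R, X_R, E_R)`, `H_P = GNN(A_P, X_P, E_P)`.
- **Matching** — affinities `M̂ = H_R H_Pᵀ`; probabilities `M̃` by softmax
  over each reactant atom's row; symmetry pooling sums `M̃` over each product
  atom's WL equivalence class to give `M`.
- **Loss** — negative log-likelihood of the ground-truth correspondence,
  `L = −Σ_i log M[i, π_gt(i)]`, minimized with Adam (fixed learning rate
  1e-4) and early stopping on validation loss.

Reaction records carry a reaction SMILES plus four edit lists (atoms that
lost/gained hydrogen, deleted and added bonds); products are reconstructed by
applying the edits to the reactants, so every reaction is balanced and the
ground-truth correspondence is a permutation matrix. A seeded synthetic
generator produces desk-scale datasets with controllable molecular symmetry,
so nothing needs downloading.

The implementation is pure NumPy (forward and reverse passes written out
explicitly); RDKit handles molecule parsing, valence checking and SMILES I/O.

## Worked example

```python
import numpy as np
from atommatch import (GeneratorConfig, generate_dataset,
                       AtomMappingModel, MatcherConfig)
from atommatch.reaction import reaction_from_record
from atommatch.evaluate import evaluate_reactions

cfg = GeneratorConfig(n_reactions=200, atom_range=(6, 12), seed=42)
train, val, test, _ = generate_dataset(cfg)
tr = [reaction_from_record(l) for l in train]
va = [reaction_from_record(l) for l in val]
te = [reaction_from_record(l) for l in test]

model = AtomMappingModel(tr, va, MatcherConfig(embed_dim=32, seed=42,
                                               max_epochs=60))
res = model.fit()
print(res.summary())
report = evaluate_reactions(te, res.params, res.config,
                            reactant_tolerance=True)
print(f"symmetry-aware average accuracy: {report.avg_accuracy:.1f}%")
print(f"strict (exact-index) accuracy:   {report.strict_avg_accuracy:.1f}%")
```

prints (3.5 s of training on one CPU):

```
Atom Mapping Results
============================================================
training reactions                   140
validation reactions                  20
parameters                         10432
epochs run                            60
best epoch                            60
...
symmetry-aware average accuracy: 78.5%
strict (exact-index) accuracy:   59.4%
```

The gap between the two accuracies is the symmetry effect: the strict score
penalizes the model for choices among topologically equivalent atoms that are
chemically indistinguishable, the symmetry-aware score does not. With the
full desk-scale setting (1,000 reactions, embedding dimension 64) the
symmetry-aware accuracy reaches ≈ 93%.

The command line offers the same pipeline:

```bash
atommatch generate --n 200 --seed 42 --out-dir data/
atommatch train --train data/train.tsv --val data/val.tsv --out model.npz
atommatch map --checkpoint model.npz --in data/test.tsv --out pred.smi
atommatch evaluate --pred pred.smi --gt gt.smi --out report.json
atommatch symmetry "CC(C)(Cl)Cl"
```

The last command prints the topological-equivalence classes of
2,2-dichloropropane — the two methyl carbons and the two chlorines pair up:

```
{0, 2}
{1}
{3, 4}
```

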