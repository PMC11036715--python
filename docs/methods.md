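# Methods

## Model

`atommatch` casts atom mapping as supervised graph matching. A reaction is a
pair of featurized molecular graphs over heavy atoms — reactants
G_R(V_R, A_R, X_R, E_R) and products G_P(V_P, A_P, X_P, E_P) — related by a
ground-truth permutation π_gt. A shared-weight encoder produces per-atom
embeddings H_R and H_P; the affinity matrix M̂ = H_R H_Pᵀ is normalized by a
softmax into matching probabilities M̃; probability mass is pooled over each
product atom's topological-equivalence class to give M; and the training
objective is the negative log-likelihood of the ground truth,
L = −Σ_{i∈V_R} log M[i, π_gt(i)].

### Featurization

Atom features are 106-dimensional concatenations of the blocks: atom type
(one-hot over a fixed, ordered 64-element vocabulary in atomic-number order
H…Bi — no catch-all slot, unknown elements are rejected with the element
named), heavy-neighbour count (0–4, >4), formal charge (−3…+3 plus an
"extreme" slot), hybridization (s…sp3d2 plus "other"), total valence (1–6;
values outside that range are rejected since the scheme defines no overflow
slot), ring and aromaticity bits, min–max-scaled atomic mass, van der Waals
radius and covalent radius (scaling bounds frozen in code, computed once
over the vocabulary: mass 1.008–208.98 Da, r_vdw 1.20–3.00 Å, r_cov
0.31–2.44 Å), chirality type (unspecified/CW/CCW/other), and hydrogen count
(0–4, >4). Hydrogens bound to heavy atoms are implicit: they appear in the
hydrogen-count feature, never as nodes. Bond features are six-dimensional:
bond-type one-hot (single/double/triple/aromatic), conjugation, ring
membership; they are stored per existing bond (rows for (i,j) and (j,i)
identical) with a dense |V|×|V|×6 view on demand, since non-bonded pairs
carry no information.

### Encoder

A graph isomorphism network (GIN) with edge features: a linear input
projection h⁰ = X W_in + b, then per layer
h_i ← MLP((1+ε) h_i + Σ_{j∈N(i)} ReLU(h_j + W_e e_ij)) with ε fixed at 0 and
a two-layer perceptron (ReLU) per GIN layer — the minimal common variant.
Sum aggregation is the default (mean and max are selectable). Jumping
Knowledge concatenates the outputs of all layers including the layer-0
projection, so the embedding width is (L+1)·d. The forward and reverse
passes are written out explicitly in NumPy (float64); gradients were
verified against central finite differences to ~1e-9 relative error.
Because GIN cannot exceed WL discrimination, atoms the WL test declares
equivalent receive bitwise-identical embeddings — the mechanism that makes
correspondence mass split across equivalent atoms, and the reason symmetry
pooling is needed.

### Normalization axis

The softmax default normalizes each *reactant* atom's row into a
distribution over product candidates, which is the reading the NLL loss and
top@k ranking require. The transposed convention (per product atom) is
selectable via `normalization_axis="per_product_atom"`.

### Symmetry detection

Two atoms are topologically equivalent when they share an element symbol and
their three-hop neighbourhoods agree. This is computed by WL colour
refinement: labels start as atomic symbols; each iteration replaces a label
by the canonical combination of itself with the lexicographically sorted
multiset of neighbour labels; three iterations are run (overridable).
Canonical strings (compact ids between rounds) are used instead of integer
hashes, eliminating collision risk at molecule scale. Bond orders are not
part of the tokens by default; a flag includes them for a stricter
equivalence. The refinement only ever splits classes, never merges them, and
exact automorphism orbits are always contained within WL classes (checked
against VF2 enumeration in the tests) — WL may merge atoms that are not
automorphic (e.g. the central atoms of a long chain, indistinguishable
within three hops), which is the intended equivalence here.

`enumerate_symmetric_mappings` returns every correspondence obtainable from
the known mapping by class-preserving automorphisms of either side
(deduplicated), with a configurable combinatorial cap (default 10⁴). A
molecule with two independent equivalent pairs yields exactly four mappings.

### Reactions and edits

A reaction record is one TSV line: an atom-mapped reaction SMILES plus four
edit fields (atoms that lost hydrogen, atoms that gained hydrogen, deleted
bonds, added bonds; atom-map-number references, semicolon-separated pairs,
`i-j:order` for added bonds, order defaulting to single). Products are
constructed by replaying the edits on the reactant graph — hydrogen counts
are frozen first, bonds are then deleted/added on the kekulized structure,
and the result is re-sanitized — so element multisets are conserved by
construction and the ground truth is always a permutation matrix. Product
validation checks each atom's total valence against its element's maximum
(C 4, N 3, O 2, S 6, halogens 1, …), returning reasons rather than raising.
Replayed products are compared to the record's product side by main
component (largest fragment by heavy-atom count, ties broken by canonical
SMILES). To remove atom-position information, both sides of a reaction can
be remapped by independent seeded uniform permutations with the ground-truth
matrix conjugated accordingly — the minimal procedure that decouples mapping
from position.

### Training

Adam with fixed learning rate 1e-4, minibatches of 16 reactions (gradients
averaged), at most 200 epochs, early stopping on validation loss with
patience 10 and minimum improvement 1e-4, best weights restored. Training is
deterministic given the seed (weight initialization, shuffling and the
generator all derive from it). The loss clamps ground-truth probabilities at
1e-12 before the logarithm; a non-finite batch loss aborts with diagnostics.
Larger-scale settings (embedding 512) are selectable but the desk default is
embedding 64, which trains on 700 reactions in about a minute on one CPU.

### Prediction and evaluation

Per reactant atom, product candidates are ranked by M̃ descending, ties
broken by ascending atom index. The emitted one-to-one mapping is the greedy
highest-probability assignment without column reuse; an optimal
linear-assignment mode (maximizing Σ log M̃) is available and agrees with
greedy whenever the matrix is strictly dominant along a permutation.

Evaluation is symmetry-tolerant: a reactant atom scores a hit at k when any
member of its ground-truth product atom's equivalence class appears among
its first k candidates. A reaction is correct at k when every atom hits
(relaxable to a fraction threshold). "Average accuracy" is the mean over
reactions of the per-reaction fraction of atoms hit at k=1 (the per-atom
pooled mean and the strict exact-index variant are reported alongside).

An optional reactant-side tolerance extends the hit to atoms whose
topologically equivalent reactant partners hit. This matters structurally:
because equivalent reactant atoms receive identical embeddings, they emit
identical rankings, and when a reaction edit breaks the molecule's symmetry
the product classes of their images differ — at most one member of such a
pair can then hit under product-side-only scoring. On the default synthetic
conditions (40% symmetric molecules, 1–3 edits) this caps *any*
WL-bounded matcher at ≈ 86% mean atom accuracy, an information-theoretic
ceiling of the evaluation convention, not of the model. Mapping either
member of a truly equivalent pair is chemically valid, so the package's
headline symmetry-aware figure applies equivalence tolerance on both sides;
the flag is off by default in the API so both conventions stay visible.

## Synthetic data

The generator emulates the reaction-record format with known ground truth.
Molecules are random trees over the palette C, N, O, S, F, Cl (standard
maximum valences; S capped at 2 to keep the toy chemistry simple) with 15%
double-bond probability where valence permits and up to two ring closures of
size ≥ 4; defaults are 6–16 heavy atoms. A configurable fraction (default
0.4) of molecules is built by mirroring a random fragment — two identical
copies joined directly or through a central carbon — guaranteeing a
nontrivial equivalence class; asymmetric draws are redrawn (bounded) when
they land on incidental symmetry, so the knob is crisp. Edits (default 1–3)
are sampled so valence stays legal exactly: deleting a bond of order o frees
o hydrogens per endpoint (recorded in the gained-hydrogen list), adding a
single bond consumes one per endpoint; each atom pair is touched at most
once. Aromatic draws are excluded because kekulization ambiguity would make
hydrogen bookkeeping ill-defined on symmetric rings. Records are written in
canonical atom order, split 70/10/20 with a seeded shuffle, and regenerate
byte-identically from the same seed.

What the generator does not emulate: real reaction-class chemistry
(generated edits are random legal bond changes, not mechanisms),
stereochemistry beyond the chirality one-hot, charged species, aromatic
systems, and reagent/catalyst context. Passing tests therefore demonstrate
that the architecture, symmetry machinery and training loop recover known
correspondences under controllable symmetry — not that the model transfers
to patent-scale reaction data.

## Numerical choices

Softmax is stabilized by max-subtraction; slices sum to 1 within 1e-6 (at
extreme affinity scales individual entries may round to exactly 1.0 in
float64). Loss epsilon 1e-12. Ranking ties break by ascending atom index;
assignment ties by (probability, row, column). Degenerate inputs: empty
molecules, unparsable SMILES, dangling atom-map references, negative
hydrogen counts and duplicate bonds are rejected with messages naming the
offending record or atom; the symmetric-mapping enumerator aborts above its
combinatorial cap.

## Problem sizes

Defaults were chosen so the full study runs on a single CPU in minutes: the
recovery experiment uses 1,000 reactions (700/100/200 split, ≈ 1 minute of
training), WL-orbit validation uses 200 molecules of ≤ 12 atoms against
exact VF2 orbit enumeration, and the edit-engine stress test uses 10,000
generated reactions.

## Known limitations

- WL equivalence at three iterations can merge non-automorphic atoms whose
  three-hop environments coincide; all symmetry-aware scores inherit this
  convention.
- The encoder is WL-bounded by design; reactions whose correct mapping
  requires distinguishing WL-equivalent reactant atoms are ambiguous to it
  (see the evaluation ceiling above).
- Unbalanced reactions, reagent/catalyst roles and isotopes are out of
  scope; products must be derivable from reactants by the four edit types.
- The checkpoint format stores raw weight arrays (NumPy archive) and is
  versioned but not portable across incompatible feature-schema changes.
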