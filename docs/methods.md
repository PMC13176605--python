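# Methods

`pathddi` predicts typed drug–drug interactions (DDIs) for a pair of drugs
by fusing three per-drug representations and explains predicted
interactions by ranking the biological pathways that topologically bridge
the two drugs' knowledge-graph neighborhoods.  This note describes the
model, the procedures, the tunable parameters, the synthetic data the
package is validated on, and the limits of what those validations show.

## Model

### Sequence branch (`z_trans`)

A SMILES string is split by a single compiled regular expression whose
alternation is ordered longest-match-first: bracket atom groups
`\[[^\]]+\]`, two-letter halogens (`Cl`, `Br`; lowercase variants when case
sensitivity is off), two-digit ring closures `%nn`, then any single
character.  This guarantees the cover property — concatenating the tokens
reproduces the input — which the test suite asserts for every fixture and
generated string.  Four special tokens occupy the lowest vocabulary IDs:
`<PAD>`, `<UNK>`, `<CLS>`, `<SEP>` (`<SEP>` is reserved but never placed).
Sequences are prepended with `<CLS>` and truncated or padded to length `L`
(default 128; desk-scale default 64).

Token IDs are embedded (width `d_emb`), projected to `d_model`, and encoded
by `N` post-norm Transformer encoder layers with `n_head` attention heads
and feed-forward width `d_ff`.  A key padding mask removes `<PAD>`
positions from attention exactly (the mask value underflows to zero weight
in float64), so the `<CLS>` output — the sequence representation
`z_trans` — is bitwise independent of padding length.  No positional
encoding is added in this branch; positional signal enters only through
the graph branch below.  A consequence verified in the tests: the sequence
branch is a *set* encoder — permuting real tokens leaves `z_trans`
unchanged, while changing a token's identity changes it.

### Graph branch (`z_gat`)

The token list is re-read as a walk over atoms to build a fixed-size
`L x L` weighted adjacency aligned to token positions (position 0 is
`<CLS>`, never an atom).  Atom tokens (element symbols, aromatic lowercase
atoms, bracket groups) become nodes; consecutive atoms bond with the
pending bond weight; `(` pushes and `)` pops the attachment atom; matching
ring-closure digits bond their opening atoms.  Bond weights follow
multiplicities: `-` 1, `=` 2, `#` 3, `:` or an implicit bond between two
aromatic atoms 1.5.  A ring closure takes the bond marker immediately
before the closing digit if present, otherwise the aromatic-implicit or
single weight.  Stereochemistry marks are parsed but create no geometry;
self-loops (weight 1) are added on the atom diagonal by default.  On a
20-molecule panel of real drugs the builder's atom counts and bond sets
match RDKit's parse exactly (RDKit is used only as an independent oracle,
never as a product path).

Node features are `H = (E + P)` at atom rows and zero elsewhere, where `E`
are the (shared) token embeddings and `P` is a sinusoidal encoding with a
logistic envelope:

    P[pos, 2k]   = sin(pos / 10000^(2k/d)) * g(pos)
    P[pos, 2k+1] = cos(pos / 10000^(2k/d)) * g(pos)
    g(pos)       = 1 / (1 + exp(-pos / 100))

The placement of the envelope is configurable (`positional_decay`:
`logistic` multiplies the amplitude — the default — `argument` applies it
inside the sinusoid, `none` disables it), because the published form of
the formula is ambiguous about it; all variants keep entries in [-1, 1].
The positional-ablation mode (`use_positional=False`) drops `P` entirely
and is a supported end-to-end configuration.

A single K-head graph-attention layer runs over the adjacency: per head,
attention logits `LeakyReLU(a_src·Wh_i + a_dst·Wh_j)` (slope 0.2) exist
only on edges (self-loops included), are softmax-normalized over each
node's neighbors, and aggregate messages `W h_j` scaled by the bond weight
`A_ij` (a switch restricts weights to defining the edge set).  Per-head
outputs pass through an ELU and concatenate to width `K·d'`.  A masked
mean (or max) readout over atom positions followed by a one-hidden-layer
residual MLP yields `z_gat`.  The layer is permutation-equivariant and the
readout permutation-invariant, verified by relabeling tests.

### Knowledge-graph branch (`z_kg`)

The heterogeneous knowledge graph (DRKG-style `Family::identifier`
entities) is filtered to the Compound/Gene/Pathway/Disease(/Side-effect)
families — variants CGPDS and CGPD — keeping an edge only when both
endpoints survive.  Drugs left without edges get a self-loop so walks do
not degenerate.  From each drug, independent random walks with restart
(restart probability 0.3) sample a neighborhood; `spread` caps the number
of distinct visited nodes.  Within the neighborhood, only nodes within 4
undirected hops of the nearest pathway node are kept (the
pathway-anchoring step); drugs with no reachable pathway, or no usable
edges, are removed together with every interaction row touching them.
Every stage logs node/edge counts so real-data runs can be audited
step by step.  All hop computations treat the multigraph as undirected and
use its simple-graph projection.

For a retained drug, the stored embedding vectors of its entities (sorted
lexicographically) and distinct relation types (sorted lexicographically)
are stacked row-wise into `M_d` of shape `(S, dim)`, `S = |E_d| + |R_d|`,
with no pre-aggregation.  A 2-D convolution (kernel 5x5, stride 3x3, zero
padding 1, `C` output channels) followed by LeakyReLU, global average
pooling over the spatial grid, and an affine projection produces
`z_kg` (width `d_kg = 20`) for any `S` — the mapping is size-invariant.
Numerical choice: matrices with fewer than 3 rows are zero-padded to 3,
since the kernel/stride combination would otherwise produce an empty
output grid for `S <= 2`.  Embedding stores are external, frozen inputs:
they are never fine-tuned, and the per-fold `M_d` artifacts are
byte-compared in training to enforce the frozen-feature contract.  The
aggregator's weights, in contrast, train jointly with the classifier.

Triple plausibility uses the translational score `f(h,r,t) =
||h + r - t||^2`.  A toy margin-ranking trainer (SGD over head/tail
corruption, entities renormalized to the unit sphere) exists solely to
produce realistic synthetic stores at test scale.

### Fusion and classifier

For a pair `(a, b)` the joint feature is the fixed-order concatenation
`x = [z_trans_a || z_gat_a || z_kg_a || z_trans_b || z_gat_b || z_kg_b]`,
width `D = 2(d_model + K d' + d_kg)` (424 at the published dimensions).
Ablation variants keep subsets of the three blocks; the `+sp` suffix of
the KG variants toggles the pathway/shortest-path extraction in
preprocessing rather than the fusion layout.  The head is
`[D -> 256 -> 128 -> C]` with batch normalization, LeakyReLU, and dropout
0.3; probabilities are the softmax of its logits, and binary mode uses a
2-logit softmax for uniformity.  Pairs are used in the order given (an
optional augmentation switch would symmetrize; default off).

Training minimizes cross-entropy with Adam (lr 1e-3, betas 0.9/0.999).
Evaluation uses stratified k-fold cross-validation over pairs (classes
with fewer than k members are pooled into a reported remainder stratum for
splitting only), or a drug-disjoint split in which drugs are partitioned
and folds test exclusively on holdout–holdout pairs, with the zero-overlap
certificate logged.  Early stopping halts after `patience = 10` epochs
without a validation-accuracy improvement and restores the best-epoch
checkpoint.  Per-epoch history goes to CSV; metric reports include
accuracy, weighted and macro precision/recall/F1, a per-class table with
absent-class flags, and ROC-AUC/PR-AUC in binary mode.

### Neural-network core

No deep-learning framework is used: the package carries a small
reverse-mode automatic-differentiation engine over numpy arrays
(`pathddi.nn`) with the layers the architecture needs (linear, embedding,
layer/batch norm, dropout, multi-head self-attention, im2col convolution)
and Adam.  Gradient correctness is established by finite differencing in
the test suite, and the convolution is checked against
`scipy.signal.correlate2d`.  Everything runs in float64 on one CPU.

## Interpretability pipeline

Explanation is strictly post hoc: it consumes subgraphs and interaction
labels, never feeding back into training.  Two drug subgraphs are merged
by node/edge union; a pathway shared by both subgraphs is the candidate
mediating context (only then does the Drug A–Pathway X–Drug B pattern
connect the neighborhoods).  Within each merged graph, four centralities
are computed with networkx — degree (normalized by `n-1`), betweenness
(normalized, via shortest-path counts), closeness (per component), and
eigenvector centrality (power iteration, tolerance 1e-8, 10,000-iteration
cap, per component) — and verified in tests against brute-force oracles on
every connected graph of at most 6 nodes.

For one anchor drug and interaction label, centralities of each candidate
pathway (the anchor subgraph's pathway nodes) are sampled across
interacting partners (paired under that label) and noninteracting partners
(paired under label 0).  The screen then:

1. drops pathways covered by fewer than `coverage_min = 0.3` of the
   interacting partners;
2. runs a two-sided Mann–Whitney U test per centrality (groups smaller
   than 2 are skipped and noted; all-tied samples get p = 1);
3. applies Benjamini–Hochberg FDR correction across the anchor's full
   (pathway x centrality) hypothesis family;
4. keeps pathways with at least one significant centrality, all
   significant centralities shifted toward the interacting group, and
   Cliff's delta at least `delta_min = 0.147` (the conventional "small"
   effect) on each significant centrality;
5. ranks survivors by the weighted separation score
   `0.40·s_bet + 0.30·s_eig + 0.20·s_deg + 0.10·s_clo`, where `s_c` is the
   standardized mean difference (mean difference over pooled SD, capped at
   10 when the pooled SD is zero); ties break lexicographically by pathway
   ID.  Optional multipliers for coverage and eigenvector prominence are
   config-exposed and off by default.

The separation statistic and the threshold defaults are this package's
choices where the published description names the ingredients but not the
combining formula.  Kernel-density summaries of the centrality
distributions (with the pooled 95th percentile, linear-interpolation
convention, and a rug of points above it) are descriptive visuals only —
the samples come from overlapping merged subgraphs and are not
independent; inference lives in the screening stage alone.

On planted scenarios where interacting partners connect to the anchor
through a designated bridging pathway, the screen ranks the planted
pathway first in 20/20 seeded replicates; under shuffled labels the
fraction of (anchor, pathway) records passing the full screen is ~0.3%,
well under the 5% nominal level.

## Synthetic data

The generators produce every input the pipeline needs, in the package's
own file formats, from one seed:

* **Knowledge graph** — typed nodes in all five families; every drug gets
  a base Drug–Gene–Pathway anchor (no drug is unreachable by
  construction); each planted interacting pair gets a dedicated mediator
  path Drug–Gene–Pathway–Gene–Drug through fresh bridge genes, so 4-hop
  extraction retains it; decoy edges (gene–disease, drug–side-effect,
  dead-end genes) add heterogeneous clutter without directly connecting
  two drug neighborhoods.  Mediator-pathway usage follows a Zipf-like long
  tail, mirroring the pronounced class imbalance of real interaction data.
* **SMILES** — a fixed panel of 20 real drug molecules (covering Cl/Br,
  bracket atoms, charges, stereo marks, fused rings) plus grammar-generated
  strings; every emitted string satisfies the tokenizer's cover property.
* **Labels** — a planted pair's class is a deterministic function of its
  mediator pathway (pathway index modulo the positive-class count);
  non-planted sampled pairs take class 0; labels flip uniformly with a
  configurable noise rate in [0, 0.5).
* **Embeddings** — Gaussian entity vectors; in translational mode each
  relation vector is the mean of `t - h` over its triples so true triples
  score low; pathway vectors share per-family centroids plus noise, the
  way pretrained biomedical embeddings place functionally related pathways
  near each other.

Desk-scale defaults (50 drugs, 200 pairs, 24 pathways, walk budget
100 steps x 50 iterations with spread 120, 32-dimensional embeddings)
complete the full pipeline in seconds; the large-scale values
(20,000 steps, 10,000 iterations, spread 10^6, 400-dimensional stores,
L = 128) are reachable through the same configuration fields.

### What the synthetic validations do and do not show

The suite demonstrates: mechanical correctness of every stage against
independent oracles; exact invariants (padding invariance, hop guarantee,
size invariance, fold disjointness, frozen features, seeded determinism);
training capacity (the full model fits 500 noise-free pairs to >= 95%
training accuracy within 200 epochs on one CPU); and recovery plus
type-I control of the interpretability screen.

They deliberately do not demonstrate held-out generalization of the
classifier.  At mediator density 0.3 each drug participates in many
planted pairs, so two drugs' pathway inventories overlap heavily by
chance, and with O(100) training pairs even a supervised oracle given
explicit shared-pathway-family features cannot beat the majority-class
baseline; the neural model reaches training accuracy 1.0 while held-out
accuracy stays near the majority rate.  Learning the compositional
pathway-sharing rule requires data volumes orders of magnitude beyond desk
scale, so cross-validated accuracy on the synthetic sets should be read as
a pipeline audit, not a performance claim.  Real-data performance is
outside the scope of this package's validations.

## Degenerate inputs and numerical conventions

* Empty SMILES, unterminated bracket groups, unmatched `)`, and ring
  digits left open (including by truncation at `L`) are errors that name
  the offending token or digit.
* Unknown embedding identifiers raise a lookup error naming the
  identifier — never a silent zero vector.
* Attention mask fill is -1e30, which underflows to an exact zero weight
  after the softmax shift; fully masked rows cannot occur (the `<CLS>` key
  is never masked, and edgeless graph rows are zeroed explicitly).
* Batch-norm running statistics update with momentum 0.1; evaluation uses
  the running estimates.
* Classes with fewer than k members in stratified splitting are pooled
  into a remainder stratum and reported; per-class metrics with zero
  support are flagged `absent_from_test` rather than silently zeroed.
* Serialization of per-drug subgraph matrices is plain text with 12
  significant digits, making the per-fold byte comparison meaningful.

## Known limitations

* Valence, kekulization, and stereochemistry-aware geometry are out of
  scope for the graph builder; `%nn` ring closures are supported
  defensively.
* The walk sampler is a restart walk with uniform transitions; relation
  types do not weight transitions.
* Aromatic bond weight 1.5 is a convention; the oracle comparison ignores
  weights on aromatic systems.
* Whether the convolution in the aggregator is followed by an activation
  is unstated in the published description; LeakyReLU is used here,
  matching the activation family of the rest of the architecture.
* Pair order is not symmetrized during training.
* Desk-scale generalization is limited, as discussed above.
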