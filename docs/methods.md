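# Methods

## The problem and the model

`metacpi` predicts whether a small molecule binds a protein, under the
hard constraint that the proteins of interest come from families with no
labelled ligand at all. The package treats this as an out-of-distribution
(OOD) generalization problem at the *family* level: every split —
training, development, test — is a partition of whole families, and all
model selection is done on families the model never trained on ("stress
selection").

The model is a three-stage pipeline with explicit weight transfer:

**Stage 1 — distilled-sequence language model.** A family MSA is reduced
to the columns whose gap fraction is at most `max_gap_fraction`
(default 0.5); the retained columns, read in order and grouped in threes,
give each member an ordered sequence of amino-acid *triplet* tokens. Gaps
are ordinary token characters (`"A-D"` is a token), so indels survive
distillation, and a trailing partial group is padded with `-`. The
occupancy (gap-fraction) criterion is this package's operationalization of
"evolutionarily informative columns"; it is the simplest choice consistent
with keeping indel structure and it is configurable. Triplets with corpus
frequency below `min_count` encode to `UNK`. A transformer with
ALBERT-style cross-layer weight sharing (default: embedding 64, 2 layers,
4 heads; the tests and reference experiments use 16/2/2) is pretrained
with masked-language modelling: exactly `round(0.15·n)` positions (at
least one) are replaced by `MASK` — pure masking, no 80/10/10 split,
because nothing in the objective requires corruption diversity at this
scale — and predicted with an untied output head.

**Stage 2 — binding-site distogram.** A pocket contributes two distance
matrices: Cα–Cα between pocket residues, and the ligand-atom-to-residue
matrix whose (i, j) entry is the *minimum* over residue j's atoms of the
distance to ligand atom i. The prediction target is the atom–residue
matrix, discretized into 10 classes by histogram equalization: interior
bin edges at the k/10 empirical quantiles of the pooled *training*
distances, frozen and reused for validation/test so labels are comparable
across complexes. Labels follow half-open intervals `[edge_k, edge_{k+1})`
with the last interval closed; duplicate edges (ties) and edges equal to
the global minimum are collapsed with a warning, shrinking the effective
class count rather than leaving empty classes. A binary contact variant
(`distance ≤ 8 Å`, inclusive — the conventional contact-map threshold; the
source method leaves it unspecified) is available behind the same API.
The Cα matrix is computed and stored as an optional auxiliary target but
is not trained on by default.

Residue embeddings are selected from the protein encoder output by 0/1
selector matrices; a residue maps to (rank // 3, rank % 3) of its
alignment column's rank among retained columns, and residues in discarded
columns are dropped (as is the second of two residues landing in the same
triplet row — selector rows must be distinct). The pairwise interaction
tensor holds elementwise products of selected residue and atom vectors;
the printed Gram form `(H_p)ᵀ H_c` is implemented as an alternative mode
(it requires equal selected counts and is a (d × d) summary), but the
pairwise mode is the default because the distogram labels are per pair.
Two-way attentive pooling (`s_ij = uᵀ tanh(W f_ij)`, row/column softmax
over marginal max scores, attention-weighted row- and column-side means,
concatenated) produces a complex-level context vector; each pair is
classified from its pair feature concatenated with that context. A
per-complex 10-way head would be incompatible with per-pair labels, so
the per-pair reading is adopted and recorded as an interpretation.

**Stage 3 — CPI with out-of-cluster meta-learning.** The protein encoder,
chemical encoder (a GIN: k rounds of `h_v ← MLP((1+ε)h_v + Σ_{u∈N(v)} h_u)`
with learnable ε initialized at 0, sum pooling) and pooling weights are
carried over; the distogram head is dropped; a residual classifier of two
linear layers with a skip connection and sigmoid output is freshly
initialized. Protein summary = mean over distilled positions; chemical
summary = sum over atoms (both configurable). Training is MAML-style:

- within each split, every family's pairs are partitioned support:query
  = 5:1; single-class families stay unsplit, are flagged, and never reach
  balanced sampling;
- each outer step samples `families_per_meta_batch` (default 4) families,
  by size-proportional weight (uniform optional);
- the inner loop takes `L` (default 2) gradient steps of size α (0.05) on
  positive/negative-balanced batches of `K` (8) support pairs, sampling
  with replacement when a class is smaller than K/2 — one batch per inner
  step, which resolves the ambiguity between a sampled K-batch and a
  per-point loop in favour of "L optimization steps";
- query batches are uniform draws from the query set (balance is a
  support-side requirement only; a family's query subset may legitimately
  be class-skewed);
- the outer update sums the query losses of the adapted weights across
  the sampled families and takes one step of size β. First-order mode
  (default) treats adapted weights as constants; second-order mode
  differentiates through the inner trajectory and is exercised by the
  finite-difference tests.

Plain SGD implements the inner and outer steps literally; gradients are
globally norm-clipped (default max norm 1.0) because at desk scale the
sum-pooled GIN features make raw early-training gradients large enough to
destabilize fixed step sizes. Clipping is off (`max_grad_norm=None`) in
the algebraic-reduction tests, which require bit-exact equivalence with
plain SGD when `L = 0` and one family is sampled per outer step. All
randomness flows from a single seeded generator with a documented
consumption order (families, then per family the L support batches, then
the query batch), which is what makes those reductions testable. Stages
1–2 use Adam (lr 1e-2) with small batches (4 sequences / 1 complex per
step) — the pseudocode's plain steps apply to the meta-stage only, and
the structure stage's optimizer is stated as Adam by its source.

## Evaluation, selection, significance, screening

ROC-AUC and PR-AUC are computed with scikit-learn behind the package's
API and are cross-checked in the tests against an O(n²) concordance count
(ties at ½) and a step-wise average-precision accumulation. Stress
selection picks the checkpoint with the best OOD-dev PR-AUC (PR is the
more informative curve under class imbalance; the metric is
configurable), breaking ties toward the earliest step — the less-trained,
less-overfit instance. The deployment gap is OOD-test minus OOD-dev, per
metric, signed.

The significance model is the extreme-value law
`p(x) = exp(−exp(a·x − b))` with defaults a = 21.7678, b = 11.0939 and
E-value multiplier 2.0×10¹⁰ (≈10⁶ chemicals × 2×10⁴ human proteins; the
printed multiplier is taken as-is). `fit_significance` estimates (a, b)
by least squares of `log(−log p̂)` on the score, with plotting positions
p̂_k = k/(n+1) over descending ranks (avoids p̂ = 0) and reports R².
Enrichment factors use a top set of ⌈fraction·n⌉ by score, ties at the
cutoff broken by stable input order with a warning. The dual-D1/D3
antagonist filter passes a compound iff Ki < 100 nM at DRD1 and DRD3 and
Ki > 100 nM at DRD2 — strict inequalities, so a boundary Ki of exactly
100 nM fails.

## The synthetic generator

The generator emulates the *shape* of the real inputs at desk scale:

- **Families** (default 40 × 6 members, length 48): random ancestral
  sequence; members by point mutations (rate 0.1) outside a mutation-free
  6-column motif, plus short indels (rate 0.05) — deletions become gaps
  in the member's row, insertions add a column gapped in everyone else,
  so the output is a consistent MSA without running an aligner.
- **Molecules** (default 60, 6–14 heavy atoms): random valence-safe
  C/N/O graphs (tree growth with occasional double bonds and one
  single-bond ring closure) serialized via RDKit to canonical SMILES;
  draws whose rings would be perceived aromatic are rejected in favour of
  an acyclic re-draw, keeping the promised single/double-bond grammar.
- **Complexes**: the ligand "pose" exposes the molecule's first n atoms,
  placed around the origin at element-dependent radii; intended pocket
  residues get a side-chain atom at a closest-approach distance that
  grows with the amino-acid index (2.6–4.4 Å, inside the 4.5 Å cutoff)
  and a Cα 1–3 Å further out; all other residues sit on a 15–30 Å shell.
  Extraction at the default cutoff therefore recovers the intended pocket
  exactly. The identity–geometry coupling is deliberate: histogram
  equalization makes the marginal bin distribution uniform by
  construction, so without identity-dependent geometry no predictor could
  beat ln 10 and structure pretraining would be vacuous.
- **Activities** (default 40 pairs/family, noise ε = 0.1): the planted
  rule scores a pair by the inner product of a family latent (a fixed
  random table summed over the motif's letters) and a molecule latent (a
  fixed random projection of standardized graph statistics: atom/bond
  counts, element counts, double bonds, mean degree, cycle rank); label =
  1 iff the score is positive, flipped with probability ε. The rule is
  one global function — held-out families obey it too — so cross-family
  transfer is learnable, and Bayes-optimal accuracy is exactly 1 − ε.
  ε = 0.1 keeps perfect scores unreachable so overfitting shows up in the
  deployment gap.

What the generator does **not** emulate: real secondary/tertiary
structure, realistic chemistry or binding physics, family-size and
class-imbalance skews of curated databases, assay noise structure, or
sequence-similarity gradients between splits. Passing tests therefore
demonstrate that the pipeline's machinery — distillation, supervision
construction, meta-optimization, selection, calibration — behaves as
specified and can exploit a planted cross-family signal; they do not
certify performance on real chemical-genomics data.

## Reference experiment sizes

The canned experiments (`metacpi.experiments`) use embedding 16, two
shared transformer layers, two heads: `pipeline_smoke` runs 200 MLM
steps, 300 distogram steps and 30 outer meta-steps on a 20-family
dataset; `ood_generalization_trial` meta-trains 120 outer steps on the
40-family benchmark split 30/5/5 with checkpoints (and OOD-dev reports)
every 10. These sizes are the package's reference workload — small enough
to iterate on freely, large enough that both pretraining losses beat
their uniform baselines and OOD transfer clears chance.

## Known limitations

- The autodiff engine is tape-based pure Python over float64 NumPy;
  it is sized for these models, not for production-scale training.
- The minimal PDB dialect (via gemmi) handles ATOM/HETATM with blank or
  'A' altlocs; no insertion codes, occupancy logic or mmCIF breadth.
- Histogram-equalized classes can collapse under heavy ties; the code
  warns and shrinks the class count rather than inventing empty bins.
- First-order meta-training is the default; second-order is available
  but costs a deeper graph and is exercised only on small problems.
- MSA column selection uses occupancy alone; conservation-score
  weighting would be a natural extension and the threshold is exposed.
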