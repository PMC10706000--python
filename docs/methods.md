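# Methods

## Model

The generator is an autoregressive transformer decoder over SMILES tokens
whose internal representation is regularized, during training only, by a
graph view of the same molecule.

**Sequence decoder.** Sequences are laid out as
`[property slots] SEP [scaffold tokens] SEP BOS molecule EOS PAD…`, with
absent condition segments omitted together with their SEP.  The decoder has
8 pre-layer-norm blocks by default (masked 8-head scaled dot-product
attention, residual, 4×d GELU feed-forward, residual), d_model = 256,
learned absolute position embeddings, and a maximum sequence length of 100
tokens.  Attention is `softmax(QKᵀ/√d_k)V` under a strict causal mask.
Conditioned property values are injected continuously: each conditioned
property owns one reserved prefix slot whose embedding is the affine map
`value·w_p + b_p` of the (dataset-standardized) scalar; no binning scheme is
introduced.  Scaffold conditioning is a tokenized scaffold SMILES prefix
between SEP markers.

**Graph encoder.** Molecules are heavy-atom graphs; node features are the
concatenation of four one-hot blocks — atom type over
{C, N, O, F, S, Cl, Br, I, P, B, other}, degree 0–5, hydrogen count 0–4,
implicit valence 0–5 — so each row sums to exactly 4, and out-of-range
values land in the final bucket instead of raising.  Two graph-attention
layers follow: per head, scores `e_ij = LeakyReLU(aᵀ[Wh_i ‖ Wh_j])` are
softmax-normalized over each node's neighborhood (self-loop always included,
so isolated atoms are well defined), the coefficient-weighted aggregation is
passed through a **sigmoid** — the per-head activation this model family
prints, kept deliberately even though canonical graph-attention networks use
ELU — and the K head outputs are concatenated.  Layer 1 uses K = 4 heads;
layer 2 a single head producing the alignment dimension d.  A ReLU and a
global max pool over nodes give a permutation-invariant molecule embedding
z^A.  The encoder runs only inside the training objective; sampling never
constructs a graph (an instrumentation counter in `chem` lets tests assert
this).

**Objective.** `L = L_BT + L_ground`, summed unweighted.  `L_ground` is mean
next-token cross-entropy under teacher forcing, masked to the molecule span
(condition prefix and PAD positions excluded).  `L_BT` is the Barlow Twins
form `Σᵢ(1−Cᵢᵢ)² + λ Σ_{i≠j} C_ij²` with λ = 0.005, where C is the batch
cross-correlation between z^A and the sequence embedding z^B (final hidden
states mean-pooled over non-PAD positions, then one fully connected map to
dimension d).  C is computed as `C_ij = Σ_b z^A_{b,i} z^B_{b,j} /
(‖z^A_i‖‖z^B_j‖)`; a `standardize` flag (default on) first centers each
dimension across the batch, matching the original redundancy-reduction
method — the literal uncentered form is also available since which variant
is intended is ambiguous in this model family's description.  Note that with
the norm denominators a variance division would cancel, so standardization
reduces to centering.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `d_model` | 256 | decoder width (compact-GPT convention) |
| `decoder_layers` | 8 | 4/8/12 exposed for the depth ablation |
| `n_heads` | 8 | attention heads |
| `max_len` | 100 | hard sequence cap; over-length molecules are skipped with a logged count |
| `alignment_dim` d | 64 | shared dim of z^A/z^B; unstated upstream. Keep d < batch size when standardizing: the centered batch cross-correlation has rank ≤ batch−1, so a larger d makes the identity target unreachable and the alignment gradient never quiets down |
| λ | 0.005 | off-diagonal Barlow Twins weight |
| dropout | 0.1 | decoder and graph encoder |
| LeakyReLU slope | 0.2 | canonical graph-attention default |
| lr / schedule | 6e-4, cosine with 10% linear warm-up, AdamW(0.9, 0.99), weight decay 0.01 on matrices only | GPT-family defaults; unstated upstream |
| batch size | 256 (16 at toy scale) | alignment needs ≥ 2 when standardizing |
| grad clip | 1.0 global norm | stabilizes the early phase when L_BT (≈ d at initialization) dwarfs L_ground |
| temperature | 1.0 multinomial | benchmark convention; temperature 0 is greedy; top-k off by default |

Property targets are standardized with training-set mean/std stored in the
checkpoint, so conditioning scalars are O(1) regardless of units.

## Numerical choices

- All computation is float64 on a small reverse-mode autodiff core
  (`graphgpt.nn`): checkpoints reload bitwise, and a single seed drives
  initialization, shuffling, dropout and sampling, making same-seed runs
  identical.
- Masking uses an additive −1e9 before softmax; causal attention
  additionally multiplies by the binary mask so future weights are exactly 0.
- Max pooling splits gradient evenly across ties.
- `cross_correlation` raises on a zero-norm embedding dimension (naming the
  dimension); the training path passes `eps = 1e-8` instead so a transiently
  dead dimension contributes zero correlation rather than aborting a run.
- The Fréchet matrix square root uses `scipy.linalg.sqrtm` with the
  imaginary part discarded and tiny negative results clipped to 0;
  covariances non-PSD beyond −1e-6 are rejected.
- A non-finite loss aborts training with the step and loss breakdown.
- Batches are cropped to the longest non-PAD length present, which changes
  nothing numerically (losses are masked) but speeds up short molecules.

## Evaluation suite

- **Validity / uniqueness / novelty**: parseable fraction of all samples;
  distinct canonical SMILES among the valid; fraction of those distinct
  molecules absent from the canonicalized training set.  Zero denominators
  report 0 with a `degenerate` flag rather than raising.
- **IntDiv_p** = `1 − ((1/|S|²) Σ T(s₁,s₂)^p)^{1/p}` over all ordered pairs
  including self-pairs, Tanimoto on Morgan radius-2/2048-bit fingerprints
  (the benchmark convention; the p-th root makes IntDiv2 ≤ IntDiv1 as in the
  published tables).
- **Fréchet distance** `‖μ_G−μ_D‖² + Tr(Σ_G+Σ_D−2(Σ_GΣ_D)^{1/2})` with the
  benchmark score transform `exp(−0.2·FCD)`.  The featurizer is pluggable:
  the bundled default standardizes nine physicochemical descriptors against
  the reference set, so the pipeline runs with no download; literal
  ChemNet-activation FCD values require plugging in that network's
  featurizer, and no descriptor-based value here is comparable to printed
  ChemNet numbers.
- **KL score** `S = (1/k) Σ exp(−D_KL,k)` over the nine-descriptor set
  (BertzCT, MolWt, Crippen logP, TPSA, H-bond acceptors/donors, rotatable
  bonds, aromatic and aliphatic ring counts), each divergence computed as
  `D_KL(reference ‖ generated)` on a shared 50-bin discretization whose
  edges come from the reference side, with 1e-10 additive smoothing;
  out-of-range generated values are clipped into the edge bins.
- **Condition deviation**: per targeted property, SD is the population
  standard deviation of generated values about their own mean and MAD the
  mean absolute deviation from the target, computed over all valid samples
  (duplicates are not removed; whether they should be is unspecified
  upstream, and keeping them avoids coupling the statistic to uniqueness).

## Synthetic data

`fixtures` assembles molecules from a closed grammar: a core (benzene,
pyridine, cyclohexane, or a short alkyl chain) decorated with 0–3
substituents from {methyl, ethyl, propyl, hydroxyl, amino, F, Cl, Br,
acetyl, carboxyl} under a heavy-atom budget (default 16).  Outputs are valid
and canonical by construction and TPSA spans ~0–115 Å² (polar substituents
accumulate), which is what the conditioning experiments need.  The grammar
emulates the size and token alphabet of drug-like molecules but **not** the
property distributions, scaffold diversity, or stereochemistry of the public
training corpora; passing toy-scale tests therefore demonstrates mechanism
(the pipeline learns, conditions, and evaluates correctly), not
state-of-the-art generation quality on real libraries.

## Toy protocols and problem sizes

`experiments` fixes the desk-scale study: a 2-layer, 64-dim, 4-head decoder
with alignment dim 8 (below the batch size of 16, for the rank reason
above); 500 grammar molecules (seed 3) for the unconditional
protocol (30 epochs, 300 samples) and 400 for the TPSA-conditioned protocol
(20 epochs, 120 samples per target, targets 20 and 60 Å², three training
seeds, graph encoder on and off).  These sizes make a full sweep a
minutes-scale job on one CPU while leaving the qualitative signals —
falling cross-entropy, majority-valid samples, target-ordered generated
TPSA means, and the graph-on/graph-off contrast — measurable.

## Known limitations

- No key-value caching: sampling re-runs the full prefix each step, which is
  fine at toy scale and slow for 10,000-sample runs at full model size.
- Heavy-atom graphs ignore bond types and stereochemistry; scaffolds are the
  standard Bemis–Murcko variant (exocyclic double bonds not generalized).
- The descriptor-based Fréchet featurizer is a different feature space from
  neural-activation featurizers; compare like with like.
- At desk scale the unweighted alignment term measurably costs the decoder:
  in the toy ablation the graph-aligned arm shows somewhat lower sampling
  validity and a larger condition SD than the sequence-only arm, consistently
  across seeds.  The benefit the alignment is meant to buy evidently needs
  full-scale training (millions of molecules, wide batches) to show up; the
  toy protocol measures the mechanical switches and reports the SD contrast
  as it is.
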