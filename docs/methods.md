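# Methods

## Problem and model

The package classifies plant small secreted peptides (SSPs, positive class)
against non-secreted peptides from two parallel views of each molecule: the
amino-acid sequence over the 20-letter alphabet and a 3-state secondary
structure string (H helix, E strand, C coil) of the same length. Structures
are consumed as input; predicting them is out of scope (in practice they come
from an external secondary-structure predictor, or — for the synthetic
benchmark — from the generator's deterministic rule).

Each view has its own encoder tower: token embedding plus the standard fixed
sinusoidal positional encoding `PE(pos,2i) = sin(pos/10000^{2i/d})`,
`PE(pos,2i+1) = cos(pos/10000^{2i/d})`; a stack of pre-LayerNorm Transformer
encoder layers (`x ← x + MSA(LN(x))`, `x ← x + MLP(LN(x))`); a bidirectional
GRU whose gates follow the bias-free form `z_t = σ(W_z[h_{t−1},x_t])`,
`r_t = σ(W_r[h_{t−1},x_t])`, `h̃_t = tanh(W[r_t∘h_{t−1},x_t])`,
`h_t = (1−z_t)∘h_{t−1} + z_t∘h̃_t`; and a two-layer projection MLP from the
concatenated final forward/backward GRU states to the representation `v`.
The two towers never share parameters. Batches are right-padded; pad
positions are masked out of attention and never advance the GRU state, so a
sequence's representation is identical alone or inside a padded batch (this
is tested).

## Losses and the freezing contract

Pairs `(X₁, X₂)` carry the indicator `Y` (0 same label, 1 different). Per
view, the contrastive loss is `L₁ = ½(1−Y)D² + ½·Y·max(0, m−D)²` with
`D = ‖v₁−v₂‖₂` and margin `m > 0`: same-label pairs are pulled together,
different-label pairs are pushed apart until they leave the margin radius.
Per-view sigmoid discriminators are trained with cross-entropy on
**detached** representations, so in the combined per-pair loss
`L = L₁(v₁,v₂,Y) + L₂(v₁,Y₁) + L₂(v₂,Y₂)` (summed over both views) the
cross-entropy terms update discriminator parameters only. This freezing
contract — towers learn only from the contrastive geometry, heads only from
cross-entropy — is asserted by autodiff tests that check the relevant
gradient blocks are identically zero. The cross-entropy probability is
clamped at ε = 1e−7.

Whether the cross-entropy terms should use per-view or fused scores is
genuinely open; this implementation reads them per view, as the formula is
written, and trains the fused head separately. A single margin `m` serves
both views.

## Training protocol

Each epoch has two phases. (i) *Siamese phase*: freshly sampled pairs
(seeded; 50/50 same/different-label target, no self-pairs, one pair per
training record by default) are mini-batched by length and optimized with
Adam. (ii) *Fusion phase*: tower representations are computed once (towers
frozen — the cached features cannot propagate gradients), and the fused-view
discriminator over `[v_seq, v_struct]` is trained by cross-entropy for
`fusion_passes` sweeps, plus `final_fusion_passes` extra sweeps after the
last epoch so the head converges against the final geometry. Inference uses
the fused head only; a peptide is positive when the score strictly exceeds
0.5.

Two stabilizers address the small scale of the problem:

- **Seeded multi-restart.** The contrastive phase occasionally starts in a
  flat basin and makes no progress within the epoch budget. `train()` probes
  `n_restarts` (default 3) candidate initializations for `restart_epochs`
  (default 3) epochs each and continues the candidate with the best training
  accuracy. Fully deterministic given the seed.
- **Best-epoch restoration.** Because the fused head is retrained against a
  moving geometry, the final epoch is high-variance; after training, the
  parameters of the epoch with the best *training* accuracy are restored
  (held-out data plays no role in the selection).

Divergence (non-finite loss) aborts with a diagnostic rather than continuing.

### Default configuration

| parameter | default | meaning |
|---|---|---|
| `d_model` | 32 | embedding / encoder width |
| `n_encoder_layers` | 2 | Transformer encoder layers (*n*) |
| `n_heads` | 2 | attention heads (`d_model` divisible by `n_heads`) |
| `gru_hidden` | 32 | per-direction GRU state size |
| `gru_layers` | 1 | stacked Bi-GRU layers (*K*) |
| `proj_dim` | 32 | representation length of `v` |
| `dropout` | 0.0 | disabled by default (see below) |
| `max_len` | 250 | longest accepted peptide (preprotein upper bound) |
| `margin` | 2.0 | contrastive margin `m` |
| epochs / batch / lr | 50 / 32 / 5e−3 | Adam; the benchmark uses 20 epochs |

The architecture, not its width, is the substance: the sizes are chosen so
the full benchmark (400 training peptides, ≤120 residues) trains in minutes
on one CPU core, and every value is overridable from the YAML config or the
API. Dropout is available but off by default: at this scale the per-batch
mask noise measurably stalls the contrastive phase, and the benchmark shows
no overfitting gap that would motivate it. All computation is float64, which
keeps the finite-difference gradient checks tight.

## Metrics

ACC, SP (= TN/(TN+FP)), SE (= TP/(TP+FN)) and MCC with the standard Matthews
form `(TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FN)(TN+FP))`; any zero factor in
the denominator yields MCC = 0 by convention. (Printed renderings of this
formula sometimes drop the subtraction and the root; only the standard form
is bounded in [−1, 1] and is what "balanced metric" can mean, so that is what
is implemented, cross-checked against scikit-learn on 1 000 random tables.)

## Handcrafted encodings

AAC (20 composition fractions), CTD composition/transition/distribution over
the 13-property × 3-group physicochemical tables (39/39/195 values; the D
descriptor records the 1st/25%/50%/75%/100% occurrence positions of each
group as a percentage of length, zeros for absent groups), and Conjoint Triad
(343 class-triple counts over the 7 dipole/volume classes, normalized by the
maximum count). The grouping tables follow the widely used
iLearnPlus/iFeature conventions and are vendored as constants so tests can
pin them; CTD-D, CTD-T and CTriad are verified against independent
brute-force re-implementations. Encodings are fed to baseline classifiers
raw (no scaling) — a documented choice; the logistic-regression and other
scikit-learn baselines in `ssplearn.baselines` consume them as-is.

## Interpretability pipeline

**Mutagenesis scan.** Every position is substituted by each of the 19
alternative residues and rescored; `deltas[p,a]` is the score change, zero by
construction at the wild-type residue. The structure view is held fixed at
the wild-type structure: mutant structures are unknowable without re-running
an external predictor, so this is a deliberate, documented approximation
(it also lets the scan encode the structure once and reuse it, halving cost).
The scan itself is exhaustive — it *is* the brute-force reference — so tests
target its invariants and constructed scorers with known sensitivities.

**Contributions.** Summing deltas *toward* each target residue over positions
and peptides gives one score per amino acid and class, reported beside the
class amino-acid composition. The opposite (*from*-residue) accumulation is
also exposed, since either orientation of the substitution grid is a
defensible reading; the to-residue direction is the default used in reports.

**Importance and binning.** Per-position importance is the mean |Δ| over the
19 substitutions (mean, not sum, so values are comparable if the alphabet
changes). Variable-length peptides share one axis by position ratio:
position `p` of a length-`L` peptide maps to bin `⌊p·n_bins/L⌋` (exact
integer arithmetic; the float form misassigns bins at exact multiples).
Within a peptide, bin values are summed; bins with no positions (possible
when `L < n_bins`) are NaN, not zero. The residue×position map uses 50 bins
and is emitted both raw and occupancy-normalized; the region profile uses 25.

**Clipping.** Forward clipping at ratio `r` removes the first `⌊rL⌋` residues
(conserving the tail); backward clipping removes the last `⌊rL⌋`. Structures
are clipped identically, and ratio 0 reproduces the unclipped metrics
exactly. The default grid is 0 to 0.9 in steps of 0.1.

**Motif extraction.** The contiguous window of `window_bins` position-ratio
bins with the largest pooled importance is mapped back to residue coordinates
per peptide; the extracted subsequences (truncated to the shortest window)
build a PWM with pseudocount 0.01, each position summing to 1, exported in
MEME minimal format for downstream motif-comparison tools.

**Projections.** PCA (deterministic up to sign) and seeded t-SNE produce 2-D
coordinates of the latent representations with labels preserved.

## Synthetic benchmark

The generator emulates the statistical structure of a curated SSP benchmark
so the whole pipeline is testable without downloads: balanced classes;
lengths uniform in 40–120 (inside the real preprotein range, short enough for
fast CPU training); positives enriched in I/L/F (weight 1.5) with the motif
`KLIFK` implanted at a uniformly drawn start within the first 15% of the
sequence ("head" mode; alternative modes place it uniformly or in an
arbitrary ratio band); negatives enriched in Q/P (weight 1.5) with cysteine
up-weighted 4× over the final 20% of positions. Structures follow a
deterministic local rule — a 3-residue window is H if hydrophobic residues
(AVLIMFW) form a majority of at least two, C if none, E otherwise — chosen so
the structure view carries real, consistent signal: cysteine is deliberately
excluded from the helix-favoring set (it is ambivalent, disulfide-forming),
which makes the C-rich negative tails read as coil runs rather than spurious
helix. Implanted spans are recorded in dataset metadata as ground truth for
recovery tests.

These choices balance two stated properties: a bare I+L+F-fraction threshold
still classifies above 0.8 accuracy (the problem is honestly solvable, so a
model reaching ~0.97 is meaningful), while the motif remains the dominant
*localized* signal, so mutagenesis importance concentrates on the implant and
the head/tail clipping asymmetry emerges. With stronger composition bias the
classifier stops needing the motif and no interpretability method could
localize it — a property of the data, not of the explanation method.

What the generator does **not** emulate: real SSP sequence statistics beyond
these biases (no signal-peptide cleavage sites, no family structure, no
homology between records), predictor-derived structures with their error
modes, or class imbalance. Passing the benchmark therefore demonstrates that
the architecture, losses, training protocol and interpretability pipeline
work as specified — not that the model would reach comparable accuracy on
curated plant peptide data.

## Numerical and design notes

- The autodiff engine records a dynamic graph over float64 NumPy arrays;
  gradients accumulate copy-on-write, embedding lookups scatter-add into the
  parent buffer, and `no_grad()` disables recording for inference. Verified
  against central finite differences at the operation, layer and full-tower
  level.
- Euclidean distances used in losses carry a 1e−12 shift under the square
  root so the gradient at coincident representations is finite.
- Pair sampling targets an even same/different split because an unbalanced
  indicator starves one branch of the contrastive loss.
- `predict` maps a score of exactly 0.5 to the negative class (strict
  inequality).
- PCA/t-SNE come from scikit-learn; t-SNE perplexity is capped at
  `(n−1)/3` so small datasets remain valid inputs.
- Checkpoints are single `.npz` files with the config embedded as JSON;
  CLI runs write a manifest (config, seed, package version, input checksums).

## Known limitations

- Mutant structures are approximated by the wild-type structure during
  mutagenesis (see above).
- The contrastive objective can collapse a view whose class signal is weak
  relative to its intra-class variance; multi-restart mitigates but does not
  eliminate this, and the structure view separates less sharply than the
  sequence view on the benchmark.
- Training cost is dominated by Python-level graph overhead in the GRU time
  loop, which bounds practical dataset sizes to a few thousand peptides.
- The benchmark's problem sizes (400/100 records, 20 epochs) are the
  package's default experiment scale; larger runs are configuration changes.
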