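# Methods

This note records the model, the procedures and the numerical choices behind
`sulfsite`, in the order data flows through the pipeline.

## Problem setting

S-sulfenylation is the reversible oxidation of a cysteine thiol to sulfenic
acid, a redox post-translational modification. Candidate sites are
represented as 21-residue peptide windows centered on a cysteine (ten
residues per flank); where the protein ends inside the window the placeholder
residue `X` pads the flank, and non-standard codes (B, Z, U, O, J) are mapped
to `X`. The task is binary classification of the central cysteine.

To curb homology bias, windows sharing more than 40% sequence similarity are
removed. "Similarity" is implemented as the fraction of identical aligned
positions over the gapless 21-mers, with `X`–`X` counting as a match — the
simplest deterministic reading for equal-length ungapped windows.
Deduplication is a greedy first-seen-kept scan, which makes the result
order-stable. The operation is scope-agnostic: callers decide whether to
apply it within classes, across classes, or over train and test jointly.

## Feature streams

**Semantic stream.** Windows are decomposed into overlapping residue
trigrams and the trigrams are treated as the atomic tokens of a skip-gram
model with negative sampling (the tractable standard estimator of the full
softmax objective). Each trigram receives one trained vector; there is no
finer decomposition, so out-of-vocabulary trigrams embed to the zero vector,
which is neutral under the downstream linear maps. A 21-mer yields 19
trigrams; to align this stream 1:1 with the 21 per-residue profile rows, the
window is X-flanked to 23 residues before decomposition, making trigram *i*
centered on residue *i*. Defaults: dimension 60, context window 5 (the
context size is not a sensitive choice at this corpus size), 5 negatives per
target, linearly decaying learning rate from 0.05. Embeddings are always
trained on training-split windows only, never on evaluation windows.

**Evolutionary stream.** Position-specific scoring matrices (PSSMs) carry
per-position substitution log-odds from iterative profile alignment. The
package parses the standard PSI-BLAST ASCII layout (log-odds block only; the
weighted-percentage block is ignored — a config switch exposes the
alternative), remapping columns to the canonical order `ARNDCQEGHILKMFPSTWYV`
taken from the file's own header. The provenance recipe for real profiles is
PSI-BLAST, three iterations, E = 0.001, against NR; the package never runs
it. Window features are the profile rows at center ± 10 with all-zero rows
for the X pads, squashed through the logistic 1/(1+e^(−x)) by default so the
recurrent network sees bounded inputs. Where no real profile exists
(synthetic studies, tests), a seed-deterministic synthetic profile gives the
observed residue a high integer score (5–9) and other columns small noise
(−3…2); X positions stay zero.

Baselines for feature comparisons: BLOSUM62 rows (Biopython's published
matrix), amino-acid composition over non-X positions, and one-hot over the
21-symbol alphabet.

## Class balancing

The real benchmark is ~1:7.6 positive:negative, so the training pipeline
oversamples the minority class. SMOTE interpolates
`x_new = x_base + λ·(x_neigh − x_base)`, λ ~ U[0,1], with the neighbor drawn
from the k = 5 nearest minority points; SVMSMOTE restricts the base points to
the minority-class support vectors of a soft-margin linear SVM (C = 2),
concentrating synthesis near the decision boundary. The SVM is fitted on
both classes — a one-class fit cannot define a boundary — and when the data
exceeds 3,000 points the fit uses a class-balanced random subsample of that
size (the kernel fit is quadratic in n; support-vector identification is
insensitive to this at the separations involved, and interpolation always
uses the full minority set). Pure interpolation only: no danger/safe-region
extrapolation variants. Random over-/under-sampling and NearMiss-1 are
baselines. All methods leave majority rows byte-identical, never drop a
minority row (oversamplers), and are seed-deterministic. Resampling operates
on flattened 21·d vectors; the model reshapes back.

## The predictor

Each stream runs through its own bidirectional LSTM (standard gate
equations) with two modifications: the backward pass is initialised from a
trainable weighted sum over **all** forward hidden states,
`h0_b = σ(Σ_i w_i·h_i_f)` (the formula over all states is implemented; zeros
initialise the backward cell state, which the formulation leaves open), and
a residual blend `h_t ← α_res·h_t + (1−α_res)·h_{t−1}` with α_res = 0.5 is
applied along the forward direction only, exactly as the recurrence is
written; a flag can mirror it backward. One layer per stream by default
(depth is configurable).

The fusion module projects both BiLSTM outputs to a common width d through
sigmoid-activated linear maps, refines each with multi-head self-attention
(3 heads; per-head scaling √d_head, the standard multi-head realization),
then exchanges them through two cross-attentions — queries from one stream
against keys/values of the other, the orientation that keeps the final
additions dimension-consistent — and combines

    H_F = α·(H_PW + H2_W) + (1−α)·(H_WP + H2_P)

with α a *trainable* scalar stored as a logit (initialised to σ(0) = 0.5).
The residual α_res and the fusion α are deliberately distinct parameters.
Mean-pooling over the 21 positions feeds a dense stack (128 → 64 → 1 by
default, ReLU between layers) with a logistic output.

Training minimises binary cross-entropy with Adam (lr 10⁻³ default), carves
a stratified 10% validation split off the training data, early-stops on
validation loss with a patience of 3, and restores the best-epoch
parameters. A fixed seed controls initialisation, shuffling and the split,
so CPU runs are bit-reproducible.

The network runs on a small in-package reverse-mode autodiff engine over
NumPy arrays. The full LSTM sweep is implemented as a single graph operation
with hand-derived backpropagation through time; it is tested to agree with
the composition of the public per-step operations to 1e-10 (values and
gradients), and the engine itself is verified against central finite
differences. Training in float32 halves memory traffic; the default is
float64 so that the formula-level oracles hold to 1e-8.

## Evaluation

Sn, Sp and ACC are reported as percentages; MCC on [−1, 1]; undefined ratios
surface as explicit `None`, never silent zeros. Confusion counts threshold at
0.5 with ties classified positive (fixed for determinism). auROC uses the
Mann–Whitney rank formulation with midranks; auPRC is step integration
Σ(R_i − R_{i−1})·P_i. Cross-validation is stratified k-fold (default 10×10
with per-repeat seeds); resampling and embedding training happen inside the
training folds only, and the validation split for early stopping is carved
from the training folds, so no information reaches the test fold.

The two-sample logo statistic compares per-position residue frequencies
(non-X denominators) between positive and negative window sets with a pooled
two-proportion z-test — asymptotically equivalent to the t-test on binary
indicators used by the original logo method. Default α = 0.05, uncorrected,
matching apparent practice in this literature; a permissive α = 0.5 and
Benjamini–Hochberg correction are available by flag. Rendering is out of
scope; the statistic is the product.

## Compression-based feature sufficiency

Kolmogorov complexity is approximated by DEFLATE level 9 (zlib) compressed
size. The information-loss rate of a feature map f is

    η_loss ≈ (C(f(X) ‖ X) − C(f(X))) / C(X)

with an 8-byte NUL-containing sentinel between the streams. Feature matrices
serialize canonically: row-major fixed-point with 4 fractional digits,
−0.0 normalised, `\n` per row — compressed size depends on the text
encoding, so this is pinned and recorded (compressor id + level) in every
report. η_loss is clamped to [0, 1] for reporting (compressor overhead can
push the raw estimate slightly outside; the raw value is kept and logged).

Two properties of the estimator matter for interpretation. First, DEFLATE
exploits only literal byte repeats: decimal-serialized numeric features share
no substrings with raw residue letters, so η_loss for a numeric feature map
reflects the serialization as much as the information content, and absolute
values are not comparable across serializations. Second, a single 21-residue
window compresses to ~29 bytes, most of which is container overhead, so
per-window η_loss has a floor near 0.4 even for a byte-identical feature
map; the pooled aggregation (concatenate all windows, all features) removes
the overhead and is the scale at which the identity map scores ≤ 0.15.
Per-sample mean ± std remains the default reporting unit because it is the
finest reproducible choice. Headline loss rates published for the real
benchmark depend on the original serialization and data and are not
reproduced here.

The same compressor ranks resampling strategies by retained information
content: duplicate-heavy oversampling barely increases compressed size of
the serialized training table, down-sampling shrinks it markedly.

## Synthetic data: what it emulates and what it does not

The generator draws window residues i.i.d. per position from Swiss-Prot-like
background frequencies, with the central cysteine fixed, and plants
position-specific enrichment in positives as additive probability boosts
(the boosted residue gets `background + boost`; the rest are rescaled). The
default planted signal — K and E boosted by +0.15 each at positions ±1, ±2,
±3 — emulates the charged-residue enrichment reported around
redox-reactive cysteines, at an effect size whose Bayes-optimal separability
is auROC ≈ 0.89 (computed by the likelihood-ratio classifier on the
generating distributions). Passing the end-to-end check therefore shows the
pipeline recovers most of the separability its input admits; it does not
show real-data performance, because real flanks are not positionally
independent, real PSSMs carry homology signal the synthetic profiles lack,
and real class imbalance interacts with sequence redundancy.

## Problem sizes and schedules used in the checks

The end-to-end acceptance check trains on 2,000 positive / 4,000 negative
planted windows (SVMSMOTE-balanced to 4,000/4,000), tests on 500/1,000, with
hidden size 16, fusion width 30, 3 heads, embedding dim 60, 18 epochs at
batch 256 and learning rate 6·10⁻³, across 5 seeds (label-shuffled controls
across the same seeds). These sizes keep a full 10-run study at
desk scale while leaving the tuned Length/Dim/Head configuration untouched.
The acceptance script uses 1,000/2,000 training windows for the same reason.
The optimisation occasionally sits on an early plateau (attention outputs
are near-uniform until the recurrent features diversify), so early
stopping is consulted only after a minimum-epoch floor.

## Known limitations

- No GPU path; the engine is NumPy-bound and single-threaded.
- Synthetic profiles are a structural stand-in for PSI-BLAST output, not a
  statistical model of evolutionary conservation.
- The compression estimator's absolute values are serialization-bound (see
  above); only comparisons under the pinned configuration are meaningful.
- Attention weights are a plausibility proxy for residue importance, not a
  causal attribution.
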