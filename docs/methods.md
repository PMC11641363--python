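# Methods

This note documents the model implemented by `enhancerrl`, the choices
made where the design was genuinely open, the synthetic study the
package runs at desk scale, and the limits of what those runs
demonstrate.

## Model

**Tokenisation and vocabulary.**  A sequence of length *N* is split
into its *N − k + 1* overlapping k-mers (step 1, default *k* = 4).  The
vocabulary is built from the training partition only: k-mers are ranked
by descending corpus frequency and assigned ids from 2 upward, with
frequency ties broken lexicographically so vocabularies are identical
across runs.  Id 0 is the unknown token (k-mers never seen in
training), id 1 the padding token.  Every training k-mer enters the
vocabulary — with 4^k ≤ 4096 for k ≤ 6 a frequency cutoff would buy
nothing.  Sequences are encoded to a fixed token length `L_max`
(truncating long token lists, padding short ones); the default `L_max`
is the median token count of the training corpus, which equals
*N − k + 1* for fixed-length data.

**Embedding.**  A learnable `vocab × d` embedding (Gaussian init,
sd 0.1) maps ids to vectors; pad positions embed like any token but are
excluded from attention and from pooling (see below) so pooled features
do not depend on padding length.

**ResNet branch.**  A simplified 1-D ResNet-18: a stem convolution,
then four stages of two residual blocks
(conv → batch-norm → ReLU → conv → batch-norm, plus an identity skip, or
a strided 1×1 projection skip when shape changes, ReLU after the sum).
Stage widths are (64, 128, 256, 512) scaled by a configurable factor;
stages 2–4 halve the length with stride 2.  The final feature map is
globally average-pooled over positions and linearly projected to the
branch width (default 64).  Pooling + projection was chosen for the
"flattening" step because it is length-robust and matches the
documented 64-wide branch output.

**Transformer branch.**  Sinusoidal positional encoding (base 10⁴,
sine on even slots, cosine on odd slots) is added to the embeddings;
a stack of post-norm encoder blocks follows (multi-head self-attention
→ add & layer-norm → ReLU feed-forward of width 4d → add & layer-norm).
Attention logits receive −10⁹ at pad keys, so pad positions get zero
attention weight; the √d_h query scaling is folded into Q before the
score matmul.  The block output is mean-pooled over non-pad positions
and linearly projected to the branch width (default 128 = d).

**Fusion and classification.**  The branch vectors are concatenated,
ResNet entries first — 64 + 128 = 192 features under the default
configuration.  The classifier head is linear → ReLU → linear → sigmoid
on a single logit (matching the binary cross-entropy loss).  A binary
mask over the fused dimensions is applied elementwise before the head;
a missing mask and the all-ones mask are byte-identical forward passes.

**PPO feature reduction.**  The environment state is the fused feature
averaged over the batch; the action is one keep/discard bit per fused
dimension, applied to every sample of that batch; the reward is the
fraction of the batch the classifier then labels correctly; an episode
is one pass over the loader.  The policy factorises as independent
Bernoulli variables per dimension — the tractable choice for a 192-bit
action space — with the action log-probability the sum of per-bit
terms.  Actor and critic are two-hidden-layer MLPs (width 256) on the
state; the actor's final bias is initialised to +1 so the initial
policy sits near the all-ones mask (the operating point phase 1
trained) and prunes selectively rather than disrupting half the
features at the first rollout.  Updates use GAE(γ = 0.99, λ = 0.95)
advantages, normalised within the buffer, and maximise the clipped
surrogate objective (ε = 0.2) minus a value-function loss
(coefficient 0.5) plus an entropy bonus (coefficient 0.01), for 4
passes per update with Adam at 3·10⁻⁴.  None of the advantage
estimator, agent architecture or these coefficients is prescribed by
the method itself; they are this package's choices and are all
configurable.

**Three-phase training.**  Phase 1 trains embedding, branches and head
under the all-ones mask by minimising mean binary cross-entropy
(probabilities clamped to (10⁻⁷, 1 − 10⁻⁷)).  Phase 2 freezes the
network — it runs in inference mode, so neither parameters nor
batch-norm statistics move, verifiable by hash — and trains the agent
on rollout rewards, one update per epoch.  Phase 3 interleaves both:
per batch, extract features, sample a mask from the agent, classify
through the mask and take one supervised step; after the epoch's last
batch, exactly one PPO update from that epoch's transitions.  The main
optimiser is Adam (default lr 10⁻³, decayed ×0.5 for phase 3 — the
joint phase perturbs a nearly-converged network, and the smaller step
keeps checkpoints near the optimum), with optional decoupled weight
decay.  After every epoch with a validation set, validation accuracy is
measured — under the all-ones mask in phase 1, under the epoch's greedy
mask in phase 3 — and the best (network, agent, mask) triple is kept;
the stored mask is reused at evaluation so the selected operating point
is reproduced exactly.  Dropped-module ablations shrink the fused
vector (and the agent's state/action space) to the surviving
dimensions rather than zero-padding.

## Evaluation

Accuracy, sensitivity, specificity and MCC are computed exactly from
confusion counts at threshold 0.5 (configurable); MCC is defined as 0
when a denominator factor vanishes, the conventional value for an
undefined correlation.  AUC is the rank-based (Mann–Whitney) area with
midrank ties.  On class-balanced data ACC ≡ (SN + SP)/2, which is how
the package's acceptance checks reconstruct published accuracy cells
from published SN/SP pairs.  Classifier pairs are compared with the
exact-binomial McNemar test on discordant predictions (two-sided); the
exact variant is preferred to the χ² approximation because discordance
counts at desk scale are small.

## Synthetic data and the desk-scale study

The generator emulates the shape of the 200-bp balanced enhancer
benchmarks: `n_pos` positives drawn with per-base GC probability
`gc_pos` (G vs C uniform within the pair, likewise A vs T), carrying a
planted motif at a uniform random offset with probability `motif_prob`,
and `n_neg` negatives at `gc_neg` with no motif.  Defaults: GC 0.6 vs
0.4, motif `CGCGCG` at probability 0.8, 1484 + 1484 records — the
benchmark's class sizes.  CpG enrichment in positives is emergent (GC
enrichment plus a CpG-rich motif), not imposed, mirroring the
biological association of GC content and CpG density with enhancer
activity.  The generator makes no attempt at real enhancer grammar —
no transcription-factor binding-site libraries, no chromatin signal —
so passing results demonstrate that the pipeline learns and that its
contracts hold, not benchmark-level biology.

The bundled study (`config.desk_preset`) trains on 500 + 500 records
with a 10% validation split (seed 75) and tests on 100 + 100 records,
using a reduced network sized for a single CPU: 32-dim embeddings,
branch widths 16 + 32 (preserving the default 64:128
ResNet:Transformer proportion), stage widths scaled ×0.125, kernel 5,
one encoder block with 4 heads, `L_max` = 128 tokens (the first 131 bp
of each record — sufficient, since the composition signal is uniform
along the sequence), batch 64, phases 16/8/10, lr 2·10⁻³, weight decay
10⁻².  Under these conditions the full pipeline reaches ≈ 0.95 test
accuracy (the bag-of-4-mers information ceiling at this length is
≈ 0.99).

Two regularisers in the head are shaped like the masking operation
itself: elementwise dropout (0.2) on the fused vector, and *branch
dropout* (0.4) — zeroing one entire branch slice per affected sample,
uncompensated, exactly as a real mask would.  Both exist because the
fused model otherwise shortcut-learns: the convolutional branch can
memorise the small training set (training accuracy 1.0) faster than
the attention branch learns the generalising composition features,
which stalls the latter's gradient.  Branch dropout forces each branch
to remain independently predictive.

## Known limitations

* On composition-dominated synthetic data the Transformer branch alone
  (mean pooling ≈ a learned bag of k-mers) is near the information
  ceiling, and the fused model does not always beat that ablation: the
  convolutional branch contributes memorisation noise that the PPO
  agent has no incentive to prune, because its reward is
  *training*-batch accuracy, where those features help.  This is a
  property of the reward design, visible precisely because the
  synthetic task is solvable by composition alone; on data whose signal
  requires local motif grammar the convolutional branch is the one
  carrying irreplaceable information.
* The per-sample Pearson correlation between PCA-reduced fused features
  and the six reference statistics (GC, CpG count, base fractions;
  standardised per dimension so the count does not dominate) pairs
  component *i* with reference dimension *i* in a fixed order.  PCA
  component signs are arbitrary with respect to the class axis, so the
  *sign* of the positives-vs-negatives gap in this statistic varies
  between fits; only its magnitude indicates class structure.
* The autograd engine is float64 and single-threaded NumPy; it is exact
  (gradients verified against finite differences) but roughly two
  orders of magnitude slower than a compiled framework, which is why
  the desk preset reduces widths and depth rather than epochs.
* Checkpoint `.npz` files store parameters, vocabulary and
  configuration, but not optimiser state; resuming training mid-phase
  is not supported.
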