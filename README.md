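# enhancerrl

Binary classification of enhancer DNA sequences with a fused
convolutional/attention feature extractor and a reinforcement-learning
feature-masking agent.

Enhancers are short cis-regulatory elements that up-regulate target
genes, often from a distance.  Recognising them from sequence alone is a
standard benchmark problem in regulatory genomics: given a 200-bp
A/C/G/T string, predict enhancer vs non-enhancer (or strong vs weak
enhancer).  `enhancerrl` implements one family of solutions end to end:

1. **k-mer tokenisation.**  Each sequence of length *N* becomes the
   *N − k + 1* overlapping k-mers (default *k* = 4).  A frequency-ranked
   vocabulary maps k-mers to integer ids — most frequent k-mer gets id 2;
   ids 0 and 1 are reserved for unknown and padding tokens — and a
   learnable embedding turns ids into dense vectors.
2. **Two feature branches.**  A simplified 1-D ResNet-18 (four stages of
   two residual conv blocks) extracts local, hierarchical motif
   features; a Transformer encoder with sinusoidal positional encoding
   and pad-masked multi-head self-attention extracts long-range
   contextual features, mean-pooled over non-pad positions.
3. **Fusion and masking.**  The branch outputs are concatenated —
   ResNet entries first — into a fused vector *z* ∈ ℝ^192 under the
   default 64 + 128 widths.  A PPO (proximal policy optimisation) agent
   observes the batch-averaged fused vector and emits a binary mask
   *a* ∈ {0,1}^192 (independent Bernoulli per dimension); the masked
   vector *a ⊙ z* feeds a sigmoid classifier head.
4. **Training.**  Three phases: (i) supervised pretraining of
   embedding + branches + head under an all-ones mask, minimising binary
   cross-entropy; (ii) PPO pretraining against the frozen network, with
   reward *R = N′/N*, the fraction of the batch classified correctly
   under the sampled mask, and the clipped surrogate objective
   L^CLIP(θ) = E[min(r_t(θ) Â_t, clip(r_t(θ), 1−ε, 1+ε) Â_t)];
   (iii) joint training with one PPO update per epoch.  The best
   (network, agent, mask) triple on validation accuracy is kept.

Evaluation reports SN, SP, ACC, MCC and AUC, and an exact-binomial
McNemar test compares paired classifiers.  Interpretability utilities
export per-batch mask heatmaps, ResNet-vs-Transformer keep-rates, and
per-sample correlations of the (PCA-reduced) fused features with six
reference sequence statistics — GC content, CpG-dinucleotide count, and
the four nucleotide fractions — that are biologically associated with
enhancer activity.

Because the original benchmark data are external, the package ships a
synthetic generator that emulates their shape: balanced 200-bp classes
whose positives are GC-enriched and carry a planted CpG-rich motif.
All training and tests run on this synthetic data on a single CPU.

The neural-network layer is a small self-contained reverse-mode
autograd engine over NumPy (`enhancerrl.nn`) providing embeddings, 1-D
convolution, batch/layer normalisation, attention primitives and Adam.

## Worked example

```python
from enhancerrl.config import desk_preset
from enhancerrl.model import EnhancerClassifier
from enhancerrl.synthetic import SynthConfig, generate

cfg = desk_preset(seed=42)              # reduced single-CPU configuration
train = generate(cfg.synth)             # 500 + 500 labelled 200-bp records
test = generate(SynthConfig(n_pos=100, n_neg=100, seed=43))

model = EnhancerClassifier(train, split_fraction=0.1, split_seed=75,
                           net_config=cfg.network, train_config=cfg.train,
                           ppo_hparams=cfg.ppo)
results = model.fit()                   # three-phase schedule, ~2-3 min
print(results.summary())
report = results.evaluate(test)
print(f"SN={report.sn:.3f} SP={report.sp:.3f} ACC={report.acc:.3f} "
      f"MCC={report.mcc:.3f} AUC={report.auc:.3f}")
```

Output from the run above:

```
Enhancer classifier fit
===============================================
training records        900
validation records      100
k-mer length            4
vocabulary size         258
token length (L_max)    128
embedding dim           32
fused feature dim       48
  ResNet slice          [0, 16)
  Transformer slice     [16, 48)
phase epochs            16/8/10
best validation acc     0.9500
mask keep fraction      0.7292
===============================================
SN=0.980 SP=0.930 ACC=0.955 MCC=0.911 AUC=0.993
```

The summary shows the fused-feature layout (ResNet entries first), the
phase schedule, and the fraction of feature dimensions the trained PPO
mask keeps.  The metric row reads as: 98% of true enhancers and 93% of
non-enhancers are recognised, for an overall accuracy of 95.5% on the
held-out synthetic test set; MCC and AUC summarise the same predictions
threshold-dependently and threshold-freely.

## Command line

```bash
enhancerrl synth --n-pos 500 --n-neg 500 --fasta data.fa    # generate data
enhancerrl train --fasta data.fa --run-dir runs/demo        # three phases
enhancerrl eval  --checkpoint runs/demo/checkpoint.npz --fasta data.fa
enhancerrl ablate --fasta data.fa --drop resnet             # module ablation
enhancerrl interpret --fasta data.fa                        # heatmaps + corr.
```

Labels travel either in a TSV table (`--labels`) or in FASTA headers as
`>id|label`.  `--preset paper` switches to the full-scale architecture
(128-dim embedding, 192-dim fusion); the default `desk` preset is sized
for a single CPU.

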