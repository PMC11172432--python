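# dfppi — sequence-only protein–protein interaction prediction

`dfppi` predicts whether two proteins physically interact using nothing but
their amino-acid sequences. It is aimed at computational biologists who
want a self-contained, reproducible implementation of a two-channel
feature-fusion classifier: one channel consumes handcrafted sequence
descriptors, the other a learned residue-embedding representation, and a
convex fusion layer combines them before a shared classification head.

## The model

Each protein sequence is encoded twice:

* **Handcrafted channel** — a 910-dimensional descriptor vector
  `h = LD ∥ F ∥ A⁺`:
  * **LD** (local descriptor, 630 dims): the sequence is cut into ten
    overlapping regions (seven spanning 25 % of the length, three spanning
    75 %); each region is summarized over a 7-group physicochemical
    alphabet by composition (7 group frequencies), transition (21
    adjacent group-pair alternation rates) and distribution (normalized
    positions of the first/25 %/50 %/75 %/last occurrence of each group).
  * **F-vector** (140 dims): for each of the 35 ways of collapsing the 7
    groups into classes of sizes 4/1/1/1, residues are placed on the unit
    circle — residue *j* of class *G<sub>k</sub>* sits at angle
    θ<sub>j</sub> = (n<sub>j</sub>(G<sub>k</sub>)/(n(G<sub>k</sub>)+1) + k)·π/2 —
    and the point cloud is summarized by (mean<sub>x</sub>, var<sub>x</sub>,
    mean<sub>y</sub>, var<sub>y</sub>).
  * **APAACplus** (20+4λ dims, λ=30): amphiphilic pseudo-amino-acid
    composition — residue frequencies plus lagged hydrophobicity and
    hydrophilicity pair correlations
    τ<sub>k</sub> = (1/(L−k)) Σ h<sub>i</sub>h<sub>i+k</sub> — extended
    with tripeptide terms
    υ<sub>k</sub> = (1/(L−2k)) Σ h<sub>i</sub>h<sub>i+k</sub>h<sub>i+2k</sub>,
    all normalized by the shared denominator Σf + w₁Στ + w₂Συ.
* **Embedding channel** — the sequence is tokenized (tokens 0–19 the
  standard residues, 20–24 the non-standard codes B/O/U/X/Z, 25 padding),
  truncated/right-padded to a fixed length N (the floor of the mean
  training-sequence length), and passed through a trainable 26×d embedding
  layer initialized from paragraph-vector (PV-DM) training on an external
  sequence corpus. The flattened N×d block feeds the channel.

Each channel is a dense→relu→batch-norm→dropout stack
(defaults 1024-512-256-128 for the handcrafted channel, 2048-512-256-128
for the embedding channel). The per-protein outputs are fused as

    f = ω·h′ + (1−ω)·e′          (ω = 0.5 by default, f ∈ R¹²⁸)

and the pair representation (f_A + f_B)/2 passes through a 16-unit dense
layer into a 2-way softmax; the second coordinate is the interaction
probability. Training minimizes binary cross-entropy with Adam under
time-based learning-rate decay lr_t = lr₀/(1+δt). The network, its
backward pass and the PV-DM trainer are implemented directly in numpy;
the gradients are verified against finite differences in the test suite
and all runs are bitwise-reproducible under fixed seeds.

Evaluation utilities cover the standard panel (Acc, Sen, Spe, Pre, NPV,
F1, MCC, AUROC, AUPRC), stratified k-fold cross-validation with
mean ± SD, the positive-only threshold-accuracy AUC protocol, F1-based
threshold selection on a holdout split, and PPI-network edge
reconstruction counting.

A synthetic-data module generates benchmark-shaped datasets with a planted
interaction rule (complementary sequence motifs), so the entire pipeline
is testable without any external downloads.

## Worked example

```python
import numpy as np
import dfppi as d
from dfppi.network import ModelConfig, TrainConfig

# a balanced synthetic benchmark with a planted motif-pair rule
syn = d.SyntheticConfig(n_pairs=400, seed=7)
pairs, records = d.gen_pair_dataset(syn)

# residue embeddings from a disjoint corpus
corpus = d.build_corpus(d.gen_corpus(100, syn, exclude=records), records)
emb = d.train_embeddings(corpus, d.EmbeddingConfig(dim=32, seed=7))

rng = np.random.default_rng(0)
order = rng.permutation(len(pairs))
train, test = [pairs[i] for i in order[:320]], [pairs[i] for i in order[320:]]

cfg = ModelConfig(omega=0.5, channel1_sizes=(128, 64, 32, 32),
                  channel2_sizes=(256, 64, 32, 32), seed=0)
res = d.DFPPI(train, records, config=cfg, embeddings=emb).fit(
    TrainConfig(epochs=10, batch_size=64, seed=0))
print(res.summary())

yhat, probs = res.predict(test, threshold=0.5)
y = np.array([p.label for p in test])
rep = d.full_report(y, yhat, probs)
print(f"held-out accuracy: {rep.acc:.3f}")
print(f"held-out F1:       {rep.f1:.3f}")
print(f"held-out AUROC:    {rep.auroc:.3f}")
```

Output:

```
Two-channel PPI fusion model
========================================
training pairs:        320
unique proteins:       640
token length N:        101
embedding dim:         32
channel 1 sizes:       [128, 64, 32, 32]
channel 2 sizes:       [256, 64, 32, 32]
fusion weight omega:   0.5
shared blocks:         False
epochs / batch size:   10 / 64
initial learning rate: 0.001
first-epoch loss:      1.0654
final-epoch loss:      0.2322

held-out accuracy: 0.787
held-out F1:       0.746
held-out AUROC:    0.863
```

The summary reports the fitted configuration and the training-loss
trajectory; the held-out panel shows that even 320 training pairs recover
most of the planted interaction rule (larger runs, as in the reproduction
script below, reach ~0.94 cross-validated accuracy).

## Command line

The same pipeline is exposed as a `dfppi` CLI:

```sh
dfppi simulate pairs --n-pairs 2000 --seed 1 --out data/
dfppi train-embeddings --corpus corpus.fasta --exclude data/sequences.fasta \
      --dim 32 --out emb.tsv
dfppi train --pairs data/pairs.tsv --fasta data/sequences.fasta \
      --embeddings emb.tsv --omega 0.5 --out model/
dfppi predict --model model/ --pairs test.tsv --fasta data/sequences.fasta \
      --threshold 0.5 --out preds.tsv
dfppi crossval --pairs data/pairs.tsv --fasta data/sequences.fasta \
      --k 5 --report cv.json
```

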