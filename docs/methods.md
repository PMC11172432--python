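# Methods

This note documents the model implemented by `dfppi`, the choices made
where the design was genuinely open, the synthetic benchmark the tests
run on, and what those tests do and do not establish.

## Problem setting

Given two amino-acid sequences, predict a binary interaction label. The
classifier sees each protein through two complementary representations —
a fixed-length handcrafted descriptor vector and a learned token-embedding
view — and fuses them inside a neural network. Nothing beyond sequence is
used: no structure, no evolutionary profiles, no annotations.

## Handcrafted descriptors

**Group alphabet.** The 20 standard residues are partitioned into seven
physicochemical groups: {A,G,V}, {I,L,F,P}, {Y,M,T,S}, {H,N,Q,W}, {R,K},
{D,E}, {C} — the standard dipole/side-chain-volume grouping of the local
descriptor literature. The grouping is a `GroupAlphabet` value and can be
replaced wholesale.

**Local descriptor (630 dims).** Ten overlapping regions: seven windows
of 25 % of the length starting at 0, 12.5, …, 75 %, and three windows of
75 % starting at 0, 12.5, 25 %. This is the unique overlapping layout
consistent with "seven quarter-length and three three-quarter-length
regions"; the three long windows jointly cover the whole sequence. A
fraction window (s, e) maps to 1-based residues ⌊sL⌋+1 … ⌊eL⌋, which
guarantees non-empty regions for L ≥ 8 (shorter sequences are rejected
with an error naming the minimum). Per region: 7 composition frequencies,
21 unordered group-pair transition rates (denominator L−1; defined as 0
for single-residue regions), and 35 distribution values — for each group
the normalized 1-based position of its first, 25th-percentile, median,
75th-percentile and last occurrence, where the q-quantile occurrence is
occurrence number max(1, ⌈q·n⌉) among the group's n occurrences (this
convention reproduces [0.05, 0.25, 0.50, 0.75, 1.00] on a length-20
homopolymer), zeros when the group is absent.

**F-vector (140 dims).** All C(7,4) = 35 ways of choosing four groups
into class G0 are enumerated lexicographically; the three leftover groups
fill G1–G3 in ascending group order. Under one assignment, the j-th
residue of class Gk is placed at angle
(n_j(Gk)/(n(Gk)+1) + k)·π/2 on the unit circle, where n_j counts class-k
residues among the first j and n(Gk) is the class total, so each class
sweeps its own quarter arc in occurrence order. The descriptor stores the
mean and the sample variance (denominator L−1, no square root — the
dispersion is kept as a variance) of each coordinate per assignment.
For a single-residue sequence the variances are defined as 0.

**APAAC and APAACplus.** Classic amphiphilic pseudo-amino-acid
composition uses 20 residue frequencies plus 2λ lagged correlation terms
τ: for lag k = 1…λ, the mean over positions of h⁽¹⁾ᵢh⁽¹⁾ᵢ₊ₖ
(hydrophobicity) and h⁽²⁾ᵢh⁽²⁾ᵢ₊ₖ (hydrophilicity). APAACplus appends 2λ
tripeptide terms υ: the mean of the triple products hᵢhᵢ₊ₖhᵢ₊₂ₖ for both
property scales. All entries share the denominator
C = Σf + w₁Στ + w₂Συ (C = Σf + w₁Στ for plain APAAC). Defaults λ = 30,
w₁ = w₂ = 0.5. Terms whose averaging window is empty (L−k ≤ 0 or
L−2k ≤ 0) are set to 0 rather than raising, so 50-residue benchmark
sequences stay encodable. The hydropathy scales are the canonical
pseudo-amino-acid composition tables (Tanford-style hydrophobicity,
Hopp–Woods hydrophilicity), shipped as a package data file and z-scored
over the 20 residues (population SD); any other scales can be supplied.

Non-standard residue codes are stripped before handcrafted encoding (the
descriptors are defined over the 20 standard residues only); tokenization
for the embedding channel keeps them as dedicated tokens.

## Embedding channel

Sequences are treated as documents of residue words (1-grams) and a
distributed-memory paragraph-vector model is trained over a corpus that
excludes (by exact sequence string) every protein in the pair data. The
vocabulary has 26 tokens, so the output layer is an exact full softmax.
Training applies one batched gradient step per document per epoch (all
positions of a document averaged): with a 25-word effective vocabulary
this converges quickly, is fully vectorized, and makes the run
deterministic — documents are first sorted canonically, then visited in a
seed-controlled shuffle, so the result is invariant to input order.
Pinned hyper-parameters: dim 32 (the width that performed best in the
dimension sweep), window 5, min_count 1 (no token may be dropped from a
26-token vocabulary), 10 epochs, learning rate 0.05. Word vectors become
the 26×d embedding matrix (padding row 25 held at zero); document vectors
are discarded. The matrix initializes the classifier's embedding layer,
which remains trainable; the padding row's gradient is pinned to zero so
padding stays inert throughout training.

## Network and training

Per protein, channel 1 receives the standardized 910-dim handcrafted
vector and channel 2 the flattened N×d embedding block (flattening keeps
positional information; mean-pooling was rejected because it destroys
order, and the wide 2048-unit first layer of the embedding channel is
sized for a flat input). Each dense layer is followed by relu, batch
normalization and dropout, in that order. The channel outputs (both 128
wide by default) are fused per protein as f = ω·h′ + (1−ω)·e′; the two
per-protein vectors are averaged and passed through dense(16) → relu →
norm → dropout → dense(2) → softmax. The loss is binary cross-entropy on
the interaction coordinate (identical to 2-class categorical
cross-entropy with one-hot targets), optimized by Adam (β₁ = 0.9,
β₂ = 0.999, ε = 1e-8) with time-based decay lr_t = lr₀/(1 + δ·t), t the
epoch index, δ defaulting to lr₀/epochs.

Open choices resolved here:

* **Fused width 128**, matching the convex combination of two 128-dim
  channel outputs (a competing statement of 256 would be inconsistent
  with elementwise fusion).
* **Block sharing.** The A- and B-side MLP blocks have separate weights
  by default, as drawn in the two-block architecture; a
  `share_block_weights=True` siamese option is exposed because the
  averaging head is symmetric, and under sharing predictions are exactly
  invariant to swapping the pair (asserted in tests). The embedding table
  is shared in both modes — it is a vocabulary lookup, not a block
  parameter.
* **Dropout 0.2, batch size 128, 45 epochs** as defaults where no value
  was prescribed; all configurable.
* **Feature scaling.** The 910-dim handcrafted vectors are standardized
  with training-set statistics only (constant features pass through
  unscaled); raw descriptor magnitudes differ by orders of magnitude and
  destabilize batch-norm otherwise.
* **Thresholding.** A pair is called interacting when its probability is
  ≥ the threshold (ties predicted positive); thresholds outside [0, 1]
  are rejected.

The whole forward/backward pass is hand-written numpy; correctness of the
bespoke wiring (two channels, convex fusion, pair averaging, pinned
padding row) is guarded by a central-difference gradient check at
tolerance 1e-4 and by the fusion identities (ω = 1 makes predictions
independent of token inputs, ω = 0 of handcrafted inputs). With fixed
seeds, initialization, shuffling and dropout all derive from one
generator, so training is bitwise-reproducible on a single worker.

## Evaluation protocols

Threshold metrics follow the standard confusion-count definitions, with
MCC = (TP·TN − FP·FN)/√(P·N·(TP+FP)·(TN+FN)). Zero-denominator ratios
are reported as 0 with a RuntimeWarning so that fold aggregation remains
total. AUROC uses midrank tie handling (Mann–Whitney equivalent) and
AUPRC step integration of the precision–recall curve, both via
scikit-learn; tests verify them against an exhaustive pairwise-comparison
oracle. Cross-validation uses stratified folds (the class-balanced
variant of random splitting; it reduces fold variance) with mean and
sample SD per metric, reproducible from the seed; a shared descriptor
cache may be reused across folds because descriptors are deterministic
per sequence, while scaling and all trainable state remain fold-local.
The fixed token length N is the floor of the mean sequence length
(sequence length carries no label information at desk scale, where
lengths are i.i.d. across classes).

For positive-only transfer sets, accuracy(t) — the fraction of
probabilities ≥ t — is integrated over t ∈ [0, 1] by the trapezoid rule
on a uniform 1001-point grid (the integration rule is a documented choice;
a fully confident model scores 1, uniformly spread probabilities score
0.5). Threshold selection scans [0.5, 1] in steps of 0.001 and returns
the smallest grid point maximizing F1 on the holdout; the pipeline
command implements the 8:1 train/holdout split. Network reconstruction
scores every edge of a known interaction network and reports
recovered/total at a chosen threshold; any object exposing the
`predict(pairs, threshold, records)` surface can be scored, including the
synthetic generator's analytic oracle.

## Synthetic benchmark

The generator emulates curated PPI benchmarks in shape: balanced classes
(⌈n/2⌉ positives), i.i.d. residues from a configurable composition
(uniform by default), lengths uniform on a range whose minimum is at
least 50 residues (mirroring the usual short-sequence filter), an
embedding corpus disjoint by sequence string from the pair data, and
small edge-list networks. The planted signal is a complementary motif
pair: positives carry `motif_a` (default `WCWCWCWC`) in protein A and
`motif_b` (default `HKHKHKHK`) in protein B at random positions;
negatives carry neither. The alternating two-letter repeats were chosen
so that every channel can in principle detect them: they shift residue
composition (LD composition, APAAC frequencies), create bursts of
specific group transitions (LD transition features) and strong lag-1
property correlations (APAACplus), and are visible to the embedding
channel as token patterns. `insertion_rate` scales signal strength — at
0 the data contain no signal and any classifier sits at chance — and
`label_noise` flips labels, capping achievable accuracy at 1 − noise.
The default length range is 50–150 aa, keeping the fixed token length
near 100 (small-protein scale); the generator accepts any range with
min ≥ 50, up to the multi-thousand-residue regime of real proteomes.

Toy networks mirror hub-and-partner topologies (such as a one-core
network): nodes are split into a motif_a side and a motif_b side and
edges run between the sides, oriented motif_a side first, so every edge
matches the planted pair rule; a `MotifOracle` classifier — perfect on
noise-free generated data by construction — is provided to exercise
evaluation protocols independently of any trained model.

**What the synthetic benchmark does not show.** Real interactomes carry
domain structure, phylogenetic correlation, compositional bias and
negative sets drawn from distinct subcellular compartments; none of that
is imitated. Passing the planted-motif recovery test demonstrates that
the pipeline can learn a genuine sequence-pair signal end-to-end and that
fusion does not hurt — it does not certify benchmark-level accuracy on
biological data.

## Desk-scale problem sizes

The recovery experiment used by the tests and by
`scripts/acceptance.py` runs 5-fold cross-validation of three models
(fused ω = 0.5, handcrafted-only ω = 1, embedding-only ω = 0) on 2 000
balanced pairs with certain motif insertion and no label noise,
embeddings of width 32 pre-trained on a 300-document disjoint corpus.
For these runs the channel widths are reduced to 128-64-32-32 /
256-64-32-32 and training is 10 epochs at batch size 128 — the package's
desk-scale configuration; the full-width defaults (1024-512-256-128 /
2048-512-256-128, 45 epochs) remain the library defaults for real
datasets. Under these conditions the fused model reaches ≈ 0.94
cross-validated accuracy, the handcrafted channel alone ≈ 0.94, the
embedding channel alone ≈ 0.85–0.88, and fusion stays within two
accuracy points of the better single channel. The embedding channel is
the weaker of the two here because a flattened-position MLP must learn a
position-invariant motif detector from scratch, whereas the descriptors
aggregate over positions by construction.

## Known limitations

* The numpy network is CPU-only and single-threaded by design;
  full-width training on datasets of tens of thousands of pairs is
  feasible but slow compared to GPU frameworks.
* Batch normalization uses running statistics with momentum 0.9 for
  inference; very short trainings can leave those statistics poorly
  calibrated.
* The PV-DM trainer's document-batched update is an intentional
  simplification appropriate for a 26-token vocabulary; it is not a
  general-purpose paragraph-vector implementation.
* Descriptors reject sequences shorter than 8 standard residues (region
  scheme) and sequences containing no standard residues at all.
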