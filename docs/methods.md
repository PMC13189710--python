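# Methods

`synerank` predicts the response of drug-combination dose points in cancer
cell lines and — more importantly — their *relative ordering* within each
dose-response matrix, using a multi-modal neural model trained under a
hybrid regression + listwise-ranking objective. This note records the
model, its assumptions, the synthetic study conditions, and the numerical
and design choices a maintainer would want to know.

## Problem setting

A measurement is a tuple (drug1, drug2, dose1, dose2, cell line, response)
on the percent-growth scale (100 = untreated growth, 0 = complete growth
inhibition, negative = net cell killing). Monotherapy rows carry a null
second drug and dose2 = 0. All measurements sharing an *unordered* drug
pair and a cell line form a response list — one dose-response matrix —
the unit over which ranking is defined and scored. The practically
relevant question is rarely "what is the exact response at (d1, d2)?" but
"which dose combinations of this pair in this cell line work best?";
the training objective is aligned with that question.

## Model

Three encoders feed a shared prediction head:

* **Drug encoder** — character-level SMILES tokens (two-character atom
  symbols Cl/Br/Si/Se kept whole) through a learned token embedding, two
  1-D convolution layers with ReLU, global max pooling, and a dense map
  to a 128-dimensional molecular embedding. The all-pad token sequence
  (index 0) is the null drug of monotherapy rows; its embedding is
  learned like any other. Ablation variants: ECFP circular fingerprints
  (radius 2, 1024 bits) either projected to 128 dims by an affine layer
  or fed folded straight into the head.
* **Dose encoder** — parameter-free sinusoidal code of the scaled dose
  position r: component i equals sin(r·10^(−4i/64)) for even i and
  cos(r·10^(−4i/64)) for odd i, i = 0…63, a geometric frequency ladder.
  Raw molar concentrations (~1e−9…1e−4) would collapse onto the lowest
  frequencies, so the default position is −log10(molarity) (1 µM → 6);
  dose 0 (the empty monotherapy slot) maps to position 0 by convention.
  `minmax` and `raw` scalings exist for sensitivity checks, as does a
  learned single-affine-layer "linear" dose encoder used as an ablation.
* **Cell encoder** — the expression profile of the top-k most variable
  genes (population variance across cell lines, ties broken by input
  order; k = 1000 at full scale), gene-wise z-scored, through a two-layer
  MLP to a 256-dimensional embedding.

The head concatenates [drug1, drug2, dose1, dose2, cell] (640 dims at the
default widths) and regresses one scalar through dense layers
(512 → 128 → 1 by default). Everything runs in float64 on a small
tape-based autodiff engine (`_nn.py`) written for this package; with a
fixed seed, initialisation, training and inference are bit-reproducible
on CPU.

**Embedding centering.** Drug and cell embeddings are centered by their
library means (computed over all drugs / cell lines in the dataset during
training, stored in the checkpoint for inference). Centering costs the
head nothing — it is an input shift — but makes the zero vector represent
an *average* drug or cell line. That matters for interpretation: the
attribution baseline (below) is the zero embedding, and with centering a
zero baseline means "a typical input", so attributions measure deviation
from average rather than distance from an arbitrary operating point.

## Objective

For one response list with true values S = (s_1…s_n) and predictions
O = (o_1…o_n):

    P_ij = s_i − s_j          pairwise true differences
    M_ij = 1 iff P_ij > 0     (optional tie tolerance ε on |P_ij|)
    T_i  = Σ_j M_ij exp(o_j)
    L_i  = ln(1 + T_i / exp(o_i))
    urank(S, O) = Σ_i L_i · G_i / (n − 1)

with a DCG-style gain G_i = 2^{s̃_i} − 1 of the within-list min-max
normalised value s̃ (a linear gain 2s̃ − 1 is available for sensitivity
analysis). Lists of length one contribute zero ranking loss — there is no
order to learn — but still train the regression term. The training
objective is `MSE + λ · urank` with λ = 1 by default, MSE taken on the
(not list-normalised) targets.

Numerics: the listwise loss is computed loop-free over pairs as a per-row
log-sum-exp over {0} ∪ {o_j − o_i : M_ij = 1} with a per-row shift, the
final log through `log1p` so tiny losses keep full precision. It matches
a naive double loop to ~1e−15 relative and stays finite for prediction
magnitudes in the thousands. The pairwise ablation loss is the mean
logistic loss over truly-ordered pairs, computed with a stable softplus.

## Training

Batches are assembled from whole response lists (a list never straddles a
batch boundary — the listwise term is undefined on partial lists); lists
are shuffled every epoch. The optimizer is Adam with decoupled weight
decay. Targets are standardised to zero mean / unit variance on the
training set; the statistics ride in the checkpoint and predictions are
mapped back, so reported metrics are on the raw response scale (the
correlation metrics are affine-invariant anyway). Gradients are clipped
at global norm 25 — high enough never to touch routine updates, low
enough to stop the rare blow-up that otherwise leaves the model at the
constant predictor. An optional training-time augmentation swaps
(drug1, dose1) ↔ (drug2, dose2) on combination rows with probability 1/2
per epoch, teaching the model drug-order symmetry; it is off by default
and recommended whenever the interpretation layer will be used.

Two presets exist. The full-scale configuration is 10 000 epochs, batch
256, learning rate 1e−4, weight decay 1e−5. The desk preset — the default
everywhere in the tests and the acceptance script — is 200 epochs, batch
256, learning rate 5e−3, with a thinner architecture (32-channel convs,
128-hidden cell MLP, 128/64 head, 200 genes). Problem sizes throughout
the test suite (≈100–230 response lists, 4×4 dose grids) were chosen so a
single training run completes in tens of seconds on one CPU while leaving
the learning problem non-trivial.

## Evaluation scenarios

* **S1** — random entries held out *within* every dose-response matrix
  (each list's entries are split round-robin over the folds after a
  seeded shuffle): interpolation inside known combinations.
* **S2** — entire unordered drug pairs held out across all cell lines:
  generalisation to novel combinations. Monotherapy rows always stay in
  training and are never tested.
* **S3** — as S2 with monotherapy rows also removed from training: novel
  combinations without any single-agent anchor.

Fold assignment is a pure function of the seed; the per-fold test sets
partition the eligible records. Metrics: Pearson r over all test records
(reported 0 with a flag when degenerate), mean within-list Spearman over
test lists with ≥ 2 entries, and mean NDCG@k (k = 5 by default) with
within-list min-max-normalised true responses as relevance.

## Interpretation

For a trained model, integrated gradients attribute a prediction to the
fused embedding dimensions relative to the zero baseline, using a
midpoint Riemann discretisation (64 steps by default; the completeness
residual |Σ Attr − (f(x) − f(0))| is reported and is exactly 0 for a
linear head). Test predictions are min-max normalised; combination
triplets whose maximum score over the dose grid exceeds a threshold
(default 0.8) are ranked and truncated to the top 50. Per selected
triplet, the dimensions of each modality whose |attribution| exceeds 60 %
of that modality's maximum (arg-max force-included) are zeroed one
modality at a time, and the prediction drops Δ = original − ablated
decide the driver label: the modality with the largest Δ if it beats the
runner-up by `dominance_margin × |original|` (default 0.1), else
Balanced. With swap-augmented models, each drug's Δ can additionally be
averaged over both input orientations (`symmetrize=True`), which removes
slot-assignment noise and measurably stabilises driver labels; dose
embeddings are attributed but never ablated.

## Synthetic study conditions

The generator emulates an ALMANAC-shaped screen. Monotherapy inhibition
per (drug, cell) is a Hill curve E(d) = Emax·d^h/(EC50^h + d^h) with
Emax ∈ [30, 95] %, log10 EC50 ∈ [−7.5, −5.5], h ∈ [0.8, 2.5]; the
combination reference composes the two inhibitions under Bliss
independence (natural on the percent-growth scale), and an interaction
excess γ_pc·g(d1, d2) is added, where g is a Gaussian bump peaking
mid-grid (optimal-dose identification is a real task, not a corner
pick) and γ_pc ∈ [0, 40] blends a pair baseline with a latent-cell-factor
projection so genuinely cell-driven synergies exist. Gaussian measurement
noise (sd 2 percent-growth by default) is added and responses are clipped
to [−100, 120] with clip events counted. Expression is latent cell
vectors × random gene loadings plus log-normal-scaled gene noise, giving
the heteroscedastic per-gene variance the filter needs. Dose grids default
to {1e−8, 1e−7, 1e−6, 1e−5} M per drug. Ground truth (noise-free response
per record, γ and driver tag per pair × cell) ships as a JSON sidecar.

The tagged ablation fixture assigns each pair a driver (drug1 / drug2 /
cell, cycling deterministically) and makes γ a function of that
modality's latent factor alone. When it is used to validate the driver
classifier, the Hill backbone is flattened (degenerate parameter ranges)
and γ is drawn negative (the interaction *raises* percent growth), so the
top-scoring triplets are exactly the strongly-driven ones and the tagged
modality is the only systematic source of variation — the recovery test
then isolates the attribution machinery rather than the confounds.

What the generator does **not** emulate: assay plate effects and
replicate structure, correlated drug-target biology (drugs are a fixed
small SMILES library), tissue-of-origin stratification of cell lines,
and the heavy-tailed empirical response distribution of real screens.
Passing tests therefore certify the machinery (losses, splits,
optimisation, attribution) under controlled conditions, not performance
on NCI-ALMANAC-scale data.

## Known limitations

* The desk preset's ranking quality saturates on the noiseless benchmark;
  the hybrid-vs-regression contrast there is consistent in direction but
  small in magnitude.
* Driver recovery by attribution-guided ablation is well above chance but
  far from perfect (~0.45–0.5 pooled over seeds): within one pair the two
  drug embeddings are partially interchangeable evidence, a genuine
  identifiability limit of post-hoc per-sample attribution.
* The engine is single-threaded float64 numpy; it is sized for desk-scale
  experiments, not for hundreds of thousands of measurements.
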