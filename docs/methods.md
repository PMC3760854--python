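# Methods

This note defines the model implemented by `pepbind`, the defaults chosen,
and the numerical decisions that matter for reproducing its behaviour.

## Candidate regions and fragments

A candidate is a 50-residue window of the parent sequence (`WINDOW_LENGTH`).
Given a motif instance, the window is centred on the motif midpoint
`ceil((start + end) / 2)`; if the midpoint falls within 25 residues of a
terminus the terminal 50 residues are taken instead, so the window never
runs off the sequence, and a parent of 50 residues or fewer is used whole.
Windows are only analysed when they look disordered: the mean of the
per-residue disorder track must strictly exceed 0.5.

Each window is decomposed into all overlapping k-mers (default k = 3,
giving L − k + 1 fragments). Fragment coordinates are 1-based offsets
within the region.

## Docking track

Each fragment is docked into the partner's peptide-binding site by a
pluggable engine (the `DockingEngine` protocol). The bundled adapter runs
AutoDock Vina: the receptor is the complex with the crystallographic
peptide chain removed, and the search box is the axis-aligned bounding box
of that peptide grown by 2 × 5 Å of padding, with each edge clamped to
30 Å. Only the best (most negative, kcal/mol) pose per fragment is kept.

Per-residue aggregation assigns each residue the best score over the
fragments covering it. The raw track is then normalised per region:
`norm = |s| / |s_min|` for negative scores, with non-negative scores
mapped to 0, so the strongest affinity in the region is pinned at 1.
Normalisation is per region because affinities against different receptors
are not directly comparable.

In batch runs a fragment whose docking fails is retried once and then
imputed with the median raw score of the region's successful fragments
(with a warning); a region fails only if every fragment fails.

## Input encoding

Each residue is a 26-channel vector:

| channels | content |
|---|---|
| 0–19 | one-hot amino acid over `ACDEFGHIKLMNPQRSTVWY` |
| 20 | parent sequence length / 1000 |
| 21–23 | predicted helix/strand/coil probabilities (a simplex) |
| 24 | predicted disorder in [0, 1] |
| 25 | normalised docking score in [0, 1] |

Feature ablations zero-fill deselected channel groups rather than changing
the model shape, so all variants share one architecture.

## Network

Three two-layer feed-forward networks (tanh hidden layers) define a
bidirectional recurrence over the region:

- a forward net maps `(x_j, h_{j-1})` to `h_j` (11 hidden-state units,
  20 hidden-layer units, tanh output squash);
- a backward net maps `(x_j, g_{j+1})` to `g_j` symmetrically;
- an output net maps `(x_{j-w/2..j+w/2}, h_{j-1}, g_{j+1})` — a w-residue
  input window plus the two flanking hidden states — through a sigmoid to
  the per-residue binding probability.

Boundary hidden states are zero, as are input positions outside the
region. Weights are initialised uniformly in (−0.1, 0.1). An ensemble
averages the probabilities of three models with input windows 7, 9 and 11.

## Training and evaluation

Training is full-batch gradient descent on the mean binary cross-entropy
over all residues of all training regions, with analytic backpropagation
through both chains. Sequences are grouped by length and processed as
(batch, length, channel) arrays; the input-window view is precomputed once
per run since the inputs are constant across epochs.

The learning rate is halved whenever the best-so-far training error has
failed to improve (strictly) for 50 consecutive epochs (`patience`); the
stagnation counter resets after each halving. The reference schedule is
10,000 epochs at learning rate 0.01. The package's desk-scale default
(`DESK_CONFIG`: 120 epochs at learning rate 0.5) is this implementation's
own choice for the synthetic corpora, which converge far earlier; it is
used by the demos and the signal-recovery experiment.

Evaluation pools out-of-fold predictions over all regions of a 10-fold
cross-validation (folds disjoint, sizes differing by at most one, every
region predicted exactly once by models that never saw it) and computes
residue-level ROC/AUC. The ROC uses the score ≥ threshold convention with
no intermediate-point dropping, and the trapezoidal AUC is exactly the
Mann–Whitney pairwise probability with ties counted one half — a property
the test suite verifies exhaustively for small inputs. Motif-level calls
average the per-residue probabilities over each motif instance and compare
against a 0.4 decision threshold.

## Synthetic corpus

The generator fabricates what the real inputs look like without any
external data or binaries: 84 regions of 50 residues with compositionally
uniform sequences (so sequence alone is uninformative), one planted
contiguous binding span of 3–12 residues per region, coil-tilted Dirichlet
secondary-structure simplexes, smoothed high-disorder tracks guaranteed to
pass the disorder filter, and a deterministic mock docking engine whose
best-pose affinity is `−(4 + effect × fraction of fragment residues
labelled positive)` plus Gaussian noise (defaults: effect 2, σ 0.1
kcal/mol), with noise keyed on (seed, offset, peptide) so results are
independent of call order. The corpus builder runs the real fragment
pipeline end to end, so consumers see exactly what a live docking run
would produce. The generator does **not** emulate real motif biology,
receptor structure, or docking physics; it exists to give the learning and
evaluation machinery a controlled, recoverable signal.

## Numerical notes

- Gradient correctness is asserted with the per-tensor relative error
  `‖g_a − g_n‖_∞ / (‖g_a‖_∞ + ‖g_n‖_∞) < 1e−5` against central finite
  differences. An elementwise relative error is not used because
  finite differences lose all significant digits on near-zero gradient
  entries (catastrophic cancellation at ε = 1e−6), which would flag
  correct analytic gradients; the observed per-tensor error is ~1e−7.
- The sigmoid and the cross-entropy are computed in the numerically
  stable log-sum-exp forms, so training does not overflow for large
  logits.
- All stochastic components (initialisation, fold assignment, the mock
  engine, the corpus generator) are seeded; corpora and training runs
  regenerate bit-identically.

## Limitations

- Live docking quality is bounded by Vina's scoring of very short
  peptides; the adapter is tested against canned engine output, not a
  packaged binary.
- The disorder and secondary-structure tracks are consumed, not produced:
  external predictors must supply them (TSV with a `position` column).
- The desk-scale training schedule is tuned for the synthetic corpora;
  real corpora will need the longer reference schedule and their own
  learning-rate choice.
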