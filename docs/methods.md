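# Methods

## Model

The package assumes that per-residue hidden states of a protein language
model place structurally similar local segments close together in embedding
space, even when the underlying sequences are unrelated. Detection of
locally similar structural regions is then a signal-processing problem on
the window-level cosine similarity matrix of a protein pair:

1. mean-pool per-residue embeddings over a sliding window of size *w*
   (*n* − *w* + 1 windows for a length-*n* protein);
2. compute the cosine similarity of every window pair;
3. min–max rescale the matrix to [−1, 1] and sharpen it with the scaled
   sigmoid R(x) = scale · (σ(sharpness · (x − midpoint)) − 0.5) · 2, which is
   zero at the midpoint, strictly increasing, and bounded by ±scale;
4. run a Smith–Waterman-style dynamic program over the resulting reward
   matrix with a linear per-step indel penalty.

The local regime floors scores at zero so the alignment can start and end
anywhere; the fitting regime initializes the first motif row to zero (free
start anywhere in the candidate), charges `−i · indel` in the first column
(the motif may not skip its own start), drops the zero floor, and takes the
score maximum over the last motif row, so the motif is consumed end to end.
Window intervals map back to residue intervals as [first, last + *w* − 1].

## Parameters

| parameter | default | meaning |
|---|---|---|
| `w` | 3 | sliding-window size, residues; smaller windows resolve finer structure but admit more background signal |
| `midpoint` | 0.2 | rescaled similarity at which the reward changes sign |
| `sharpness` | 9 | steepness of the sigmoid around the midpoint |
| `scale` | 3 | reward bound; sets match rewards relative to the indel cost |
| `indel_penalty` | 10 | cost per gap step (linear gap model) |

The defaults are the configuration used for the benchmark experiments; the
grid enumerator covers midpoint 0–1 (step 0.1) × sharpness 1–10 × scale 1–10,
1100 combinations. Grid-search output deliberately exposes *all* per-setting
columns (score, detected lengths, precision/recall/F1) rather than a
hard-coded "best" objective, because region length and alignment accuracy
trade off against each other and the right balance is analysis-specific.

## Numerical and design choices

- **Rescaling scope** is per comparison matrix (its own min/max), with a
  `rescale=False` ablation flag; fixed theoretical cosine bounds are the
  plausible alternative reading and can be had by disabling rescaling.
  Constant matrices rescale to all zeros instead of erroring.
- **Zero-norm window vectors** get cosine 0 (neutral), since simulated
  matrices may legitimately contain zero rows. Cosines are clamped to
  [−1, 1] against last-ulp overshoot; everything is double precision.
- **Gap model is linear**, a single per-step penalty; affine gaps are out of
  scope. Traceback tie-breaking is deterministic: diagonal, then up (gap in
  the second protein), then left, with score-cell ties broken toward the
  smallest (i, j); this makes reports byte-reproducible.
- **Fitting terminal gaps** in the motif are charged at the full indel rate
  (H[i, 0] = −i · indel). The zero-cost-terminal-gap alternative would favor
  partial motif placements; charging them keeps the end-to-end reading
  strict.
- **Screening ranks by raw fitting score** (a normalized score column is
  emitted for inspection only); ties break by library id so rankings are
  input-order invariant. Members shorter than the window score −∞ and sink
  to the bottom with a warning. Multi-copy motif carriers are scored by
  their single best fit.
- **Ground-truth precision/recall/F1** operates at residue-pair level over
  the predicted alignment path: matched windows expand to their *w* residue
  pairs, a predicted pair is a true positive if it lies within Chebyshev
  distance `slack` (default 0) of an unused truth pair, and each truth pair
  is matchable once. A cell-threshold reading of heatmap accuracy is a
  plausible alternative; the path-based reading is implemented because it
  evaluates exactly what the aligner outputs. Interval-form ground truth is
  expanded assuming co-linear gapless correspondence; gapped truths must be
  supplied as explicit pair lists.
- The pLM adapters prepend ProstT5's amino-acid direction prefix token
  (`<AA2fold>`, the mode its encoder was trained with) and strip it plus the
  trailing special token so exactly *n* rows come back; nonstandard residues
  (B, Z, U, O, J, \*) canonicalize to `X` before embedding.

## What the simulator emulates — and what it does not

`winalign.simulate` generates embedding matrices directly: i.i.d. standard
Gaussian background rows, with one shared latent block copied into both
members of a pair (or into library positives) and perturbed by independent
Gaussian noise of scale `noise_sigma` per copy. This reproduces the one
geometric property the method relies on — planted regions are mutually
similar and dissimilar from background — with controllable strength, and it
is a pure function of its integer seed.

It does **not** emulate real pLM embedding geometry: no anisotropy or shared
global directions, no smooth correlation between neighboring residues
(beyond what window pooling introduces), no secondary-structure periodicity,
and gapless co-linear correspondences only. Passing the recovery studies
therefore demonstrates correctness and statistical behavior of the
*pipeline*, not the structural fidelity of any particular language model;
real-data performance is bounded by how well the chosen pLM separates
structurally similar from dissimilar local contexts.

Reference study sizes (chosen as the package's standard simulated
conditions): pair recovery uses 120-residue pairs with a 30-residue planted
block at noise 0.2, d = 64, 20 seeds; screening uses 5 positives among 50
members of length 120 at noise 0.3, 20 seeds. Recovery is measured as the
interval Jaccard between detected and planted regions, taken as the minimum
over the two sequences (the stricter of the two plausible definitions).

## Known limitations

- Straightforward O(mn) Python DP; adequate up to a few thousand windows per
  sequence but not engineered for proteome-scale pairwise sweeps.
- One best alignment per pair is returned (the region pair with the highest
  score); suboptimal alignments would require masked re-runs.
- TM-score validation of detected regions requires external structural
  tools and is out of scope; the package emits region coordinates only.
- The `synthetic` provider is a locality-respecting stand-in, not a model of
  protein structure: two sequence windows embed identically iff their local
  contexts are identical strings.
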