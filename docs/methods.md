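# Methods

## Pipeline overview

`issgraph` decodes registered multi-cycle, multi-channel ISS image stacks in
six stages: intensity normalization, per-channel spot detection, signal
probability prediction, cross-channel merging, graph decoding, and quality
scoring. Downstream modules build patch-level expression matrices, define
spatial compartments, and compare per-gene patterns to reference grids.
This note records the model assumptions, parameter choices, and the design
decisions taken where several readings were defensible.

## Normalization (`imgprep`)

Background and signal levels are estimated per (cycle, channel) from `n`
random 128 x 128 px patches (default `n = 50`): background is the mean of
per-patch intensity modes, signal the 99th percentile of per-patch 98th
intensity percentiles. Intensities are mapped affinely so background -> 0
and signal -> 1; negative values are clipped at 0, values above 1 retained
(bright rolonies legitimately exceed the robust signal estimate). The mode
is computed on binned intensities (unit bins for integer data, 256 equal
bins for float), since the mode of continuous data is otherwise undefined.
Normalization statistics are estimated per whole image and applied to all
tiles; the nuclei channel is never normalized (it plays no role in
decoding). The percentile scheme presumes that some sampled patches are
dense in signal — true of tissue, where cell-body layers concentrate
rolonies; on data without any dense region the signal estimate collapses
toward background and the affine rescaling amplifies noise. A constant
channel raises a `DegenerateChannelError` naming the channel.

Tiling is a strict partition into non-overlapping squares (default
1028 px); per-tile alignment refinement is translation-only subpixel phase
correlation of each cycle's anchor channel against a reference cycle.
Whole-slide multiresolution registration is assumed done upstream.

## Spot detection and merging (`spots`)

Candidates are the h-maxima (regional maxima of height >= `h`) of each
normalized base-channel image after white top-hat filtering (disk radius
2 px, about one rolony radius at x20). The default `h = 0.05` on the
normalized scale is deliberately generous — downstream probability and
quality filtering, not the detection threshold, removes noise. Candidate
positions are the plateau centroid refined by a 3 x 3 intensity center of
mass; without the refinement, integer snapping adds up to ~0.7 px of
spurious inter-cycle distance, enough to push genuinely linked detections
past `d_max` at sub-pixel jitter levels.

Within a cycle, candidates of *different* channels whose rounded pixels
coincide or are 4-adjacent are grouped transitively; each group keeps its
highest-intensity member (ties: smallest `(channel, x, y)`), recording the
suppressed detections for later quality scoring. Same-channel candidates
are never linked directly.

## Signal probability (`sigprob`)

Each candidate receives a probability of being true signal predicted from
the 5 x 5 intensity window centered on it (edge-replicated at borders). The
predictor contract is pluggable; the default is an L2-regularized logistic
regression on the 25 pixels plus four summary features (center, max, mean,
sd), class-balanced by downsampling and seeded. The decoding equations
consume only the probabilities, so any window classifier with a
`predict_windows` method can stand in.

On synthetic data, training labels mark candidates near a full-strength
emission (a rolony's direct spot, or an injected false spot) as signal;
dim bleed-through copies and background windows are noise. This is a
deliberate contract: a bleed duplicate that escapes pixel-adjacency merging
is demoted in the graph precisely by its low predicted probability.
Probabilities are clamped to `[1e-6, 1]` before `-log` so node costs stay
finite.

## Graph decoding (`graphdecode`)

Defaults `d_th = 2 px`, `d_max = 3 px`, `k = 1.0`; all exposed in
configuration. Graph construction follows a fixed order: components from
any-cycle-pair links within `d_th`; forced edges between unconnected
consecutive-cycle detections closer than `d_max`, added within components
only; removal of non-consecutive-cycle edges; source/sink attachment.
Components spanning fewer cycles than the barcode length yield no reads.

The solver is a successive-shortest-path min-cost max-flow on the split-node
network with unit capacities: all costs are non-negative, so each
augmentation is one Dijkstra under Johnson potentials, augmenting one unit
at a time. Within an augmentation, exact cost ties prefer the
lexicographically smallest candidate-id sequence; across augmentations,
residual rerouting between exactly tied optima can still settle on a
different but equally optimal path set, so the shipped guarantee is strict
run-to-run determinism plus optimality (verified against exhaustive
enumeration), not a canonical tie choice. Natural logarithms are used
throughout (`w_i`, `w_ij`, and `mu_s`).

Barcodes not in the codebook are retained as `UNEXPECTED`; they are the
negative class for sigma calibration and are dropped by the read filter.

## Read quality (`readqc`)

`Q_sb` uses as competitors exactly the detections merged away in that cycle
with probability above 0.5. `Q_s` is the *sum* of per-base qualities scaled
by `mu_s` (a threshold of 2 on a 4-5 cycle sum is the natural reading), and
the quality threshold is inclusive (`Q_s >= 2`). The distance-penalty
weight defaults to `sigma = 5.0`, suitable for sub-pixel jitter; whenever a
run contains both targeted and unexpected barcodes, `calibrate_sigma`
replaces it by the AUC-maximizing value over a log-spaced grid
(20 points in [0.5, 10] by default, smallest sigma on ties).

## Synthetic data (`simdata`)

The image simulator renders each rolony as a Gaussian spot (sd `psf_sigma`)
in the barcode-letter channel and the anchor channel each cycle, with
per-cycle Gaussian jitter, a fixed-fraction copy in one spectrally adjacent
channel (A->C->G->T->A), flat background plus Gaussian read noise, dim
nuclei blobs, and Poisson-distributed false spots per base-channel image.
Defaults: 256 px frames, 200 rolonies, background 100 counts, read noise
sd 3, amplitudes lognormal around 700, bleed-through 0.1, jitter sd 0.5 px,
4 px minimum rolony separation, and half the rolonies concentrated in a
central hotspot. The hotspot and the letter-balanced codebook helper
reflect two properties of real experiments that the normalization estimator
depends on: tissue has dense regions, and probe panels use all four bases
evenly per cycle. Not emulated: autofluorescence texture, optical
aberrations, z-structure, or unconstrained rolony crowding — so passing
end-to-end tests demonstrate the decoding logic under realistic geometry
and noise, not robustness to every tissue artifact.

The worked-example fixture hard-codes 14 detections whose positions and
probabilities realize the canonical decoding topology (two components,
three decodable paths, two noise detections, direct and forced edges); the
numbers are constructed inputs, not measured data.

The tissue-expression generator plants `G` vertical-stripe regions on a
patch grid (default 3 regions on 9 x 9 patches) with disjoint
Poisson-expressed gene programs (rate 15 vs background 0.3) under a
lognormal per-patch density factor, and names the first 18 program genes
after the reduced marker panel so panel subsetting stays informative. The
81-patch scale is deliberate: regions must comfortably exceed the k = 15
neighborhood of the cluster graph, while staying below the scale at which
modularity-style community detection begins subdividing internally uniform
regions (the known resolution-limit behavior at the default resolution).

## Expression matrices and compartments (`exprmat`, `compart`)

Patches stride by the tile size with a symmetric overlap margin per side —
the only reading under which 128 px tiles with 128 px overlap give the
stated 384 px footprint; membership intervals are half-open. Gene filtering
(total reads < 500, computed on pre-patch read totals) precedes patch
filtering (< 10 reads); both thresholds are parameters so desk-scale
synthetic runs remain testable. Normalization is Anscombe
(`2 sqrt(x + 3/8)`), then per-gene OLS regression on `log(total + 1)`
replaced by residuals, then per-gene standardization; a state flag rejects
double normalization, and zero-variance genes are zeroed with a warning.

Embedding is joint UMAP over concatenated samples (`n_neighbors = 15`,
`min_dist = 0.1`, seeded; 3-d axes min-max normalized for RGB). Clustering
is Leiden (RB-configuration, resolution 1.0) on the symmetrized k = 15
nearest-neighbor graph of the 50-d embedding. Cluster profiles are raw
counts summed per cluster, divided by cluster area (patch count) and scaled
to unit total; cross-sample matching is average-linkage hierarchical
clustering on `1 - Pearson r`, with a tree cut (e.g. 20 groups) for a
top-compartment view. Differential expression per compartment-vs-rest uses
the Wilcoxon rank-sum test in its tie-corrected Mann-Whitney form (counts
are heavily tied), Benjamini-Hochberg correction within compartment, and a
log fold-change of means with a +1 pseudocount; compartments under 3
patches are skipped with a warning.

## Atlas comparison (`atlaskl`)

Per-gene read positions are rescaled to the reference grid and turned into
a density by Gaussian KDE with covariance factor 0.05 — implemented as the
bandwidth scaling applied to the data covariance (SciPy's
`gaussian_kde(bw_method=0.05)`); the alternative reading (a multiplier on
the covariance itself) would correspond to the square root of this factor.
Densities are normalized to mass 1, and `KL(ISS || reference)` is computed
with a `1e-12` floor on the reference inside the log (keeping sparse grids
finite) rather than intersecting supports. Match tables score each gene by
`KL(self pair) - min KL(off pairs)` and sort ascending, so genes whose
decoded pattern uniquely matches their own reference lead the table.
Reference grids are consumed as plain 2-D arrays; selecting a coronal level
from a 3-D atlas is the caller's responsibility. Note that KDE bandwidths
far below the grid spacing alias on coarse grids; patterns whose spread is
comparable to the grid (as for tissue-scale expression) are unaffected.

## Known limitations

- 2-D only: no z-stacks, no 3-D decoding.
- No error-correcting barcode matching (exact codebook lookup only).
- The default window classifier is linear; heavily textured backgrounds
  would need a stronger predictor behind the same contract.
- Compartment recovery guarantees are stated for well-separated planted
  programs; real tissue boundaries are gradual and mixed patches will blur
  cluster edges.
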