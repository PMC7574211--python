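# issgraph

Graph-based decoding of **in situ sequencing (ISS)** fluorescence image
series into spatially mapped gene reads, and unsupervised definition of
spatial tissue compartments from the resulting expression maps.

ISS reads out barcoded padlock-probe products (*rolonies*) by cyclic
imaging: in every sequencing cycle each rolony emits one diffraction-limited
spot in the base channel (A, C, G or T) of its current barcode letter, next
to a nuclei stain and a general "anchor" stain. Decoding means linking each
rolony's spots across cycles into a barcode, despite spectral bleed-through,
residual mis-registration, and noise detections. `issgraph` is aimed at
spatial-transcriptomics analysts who have registered image stacks and a
codebook, and want quality-scored reads plus downstream tissue-compartment
maps.

## The decoding model

Every detected spot *i* becomes a split node pair joined by an edge of cost

```
w_i = -log(p_i)
```

where `p_i` is a learned probability that the detection is true signal.
Detections in different cycles at Euclidean distance `d_ij` are joined by
edges of cost

```
w_ij = -log(1 / (1 + k * d_ij))
```

Connected components are formed from links shorter than `d_th`; within a
component, extra *forced* edges join consecutive-cycle detections closer
than `d_max`; non-consecutive-cycle edges are removed, and a source/sink are
attached to the first/last cycle. Solving the network by **maximum flow of
minimum cost** (unit capacities, successive shortest paths) yields
node-disjoint paths — one per rolony — whose channel letters form the
barcodes. Each read *s* over *n* cycles is scored

```
Q_s = mu_s * sum_b Q_sb,    mu_s = clip(1 - log(1 + d) / sigma, 0, 1)
```

with per-base quality `Q_sb = I*p / (I*p + max_c I_c*p_c)` against merged
competitor detections (else `Q_sb = p`), and `d` the widest gap between the
path's detections. `sigma` is calibrated by maximizing the ROC AUC that
`Q_s` achieves separating codebook-matching from unexpected barcodes.

Downstream, quality-filtered reads are counted over overlapping 384 px
patches (128 px tiles, 128 px overlap), variance-stabilized (Anscombe),
density-corrected and standardized, embedded with UMAP (3-d for RGB maps,
50-d for clustering), clustered with Leiden into spatial compartments,
matched across samples by profile correlation, and compared per-gene against
reference expression grids by KL divergence.

## Worked example

```python
from issgraph import build_graph, decode, solve
from issgraph.simdata import fig1a_fixture

fx = fig1a_fixture()                 # 14 labeled detections, 4 cycles
graph = build_graph(fx.detections)   # d_th = 2 px, d_max = 3 px, k = 1
print(len(graph.components))         # -> 2
for read in decode(solve(graph), fx.codebook):
    print([c.id for c in read.path], read.barcode, read.gene)
```

prints

```
2
[1, 5, 8, 12] TAGT g1
[3, 6, 10, 13] GCAC g2
[4, 7, 11, 14] GCAG g3
```

The 14 detections split into two spatial components; component A contains
one decodable path (TAGT) plus two noise detections the solver leaves
unused, and component B resolves two interleaved rolonies (GCAC, GCAG) as
two node-disjoint minimum-cost paths.

An end-to-end synthetic run (simulate, train the spot classifier, decode,
filter at `Q_s >= 2`):

```python
from issgraph import SimConfig, score_decoding, simulate_iss
from issgraph.pipeline import decode_stack, train_model_from_simulation
from issgraph.simdata import balanced_codebook

codebook = balanced_codebook(8, n_cycles=4, seed=0)
model = train_model_from_simulation(SimConfig(seed=0), codebook, seed=0)
stack, truth = simulate_iss(SimConfig(seed=1), codebook)
result = decode_stack(stack, codebook, model)
print(score_decoding(truth, result.reads, match_radius=2.0))
# -> (0.985, 1.0)   i.e. recall 98.5%, precision 100% on 200 rolonies
```

A command-line interface mirrors the library
(`issgraph simulate|normalize|decode|classify-train|qc|express|cluster|atlas-compare`).

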