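"""Synthetic ISS image series with known ground truth.

Emulates the imaging physics that the decoding pipeline must tolerate:
rolonies (rolling-circle products) emit one diffraction-limited Gaussian
spot per cycle in the base channel of their current barcode letter and in
the general anchor stain every cycle; a fixed fraction of each spot bleeds
into one other base channel; per-cycle positional jitter emulates residual
mis-registration; autofluorescent background, read noise and spurious
"false" spots complete the picture.  Not emulated: tissue autofluorescence
texture, optical aberrations, or 3-D structure.

Also ships a small hand-built fixture realizing the canonical worked example
of the decoding graph (14 detections, two connected components, three
decodable paths), and a scoring helper matching decoded reads to ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graphdecode import Codebook
from .imgprep import BASE_CHANNELS, CHANNEL_ROLES, ChannelStack
from .spots import SignalCandidate

# bleed-through destination per source channel (spectrally adjacent dye)
BLEED_PARTNER = {"A": "C", "C": "G", "G": "T", "T": "A"}


@dataclass
class GroundTruthRolony:
    """One simulated rolony with its true position and barcode."""

    id: int
    x: float
    y: float
    gene: str
    barcode: str
    amplitude: float


@dataclass
class SimConfig:
    """Study conditions of a simulated ISS experiment.

    Defaults reflect epifluorescence ISS at x20: a ~1.5 px PSF sigma,
    sub-pixel cycle-to-cycle jitter, 10% spectral bleed-through, camera
    background around 100 counts with a few counts of read noise, and rolony
    peak amplitudes a few hundred counts above background.
    """

    image_size: int = 256
    n_cycles: int = 4
    n_rolonies: int = 200
    psf_sigma: float = 1.5
    background_level: float = 100.0
    noise_sd: float = 3.0
    bleedthrough_fraction: float = 0.1
    jitter_sd: float = 0.5
    false_spot_rate: float = 2.0
    seed: int = 0
    amplitude_mean: float = 700.0
    amplitude_cv: float = 0.2
    min_separation: float = 4.0
    border_margin: float = 5.0
    # fraction of rolonies concentrated in the central half-side square,
    # emulating the dense cell-body layers of real tissue (the percentile
    # signal estimate expects such dense regions to exist)
    hotspot_fraction: float = 0.5

    def __post_init__(self):
        if self.n_cycles < 2:
            raise ValueError("n_cycles must be >= 2")
        for name in ("psf_sigma", "noise_sd", "jitter_sd", "false_spot_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0 <= self.bleedthrough_fraction < 1):
            raise ValueError("bleedthrough_fraction must be in [0, 1)")


def balanced_codebook(n_genes: int, n_cycles: int = 4,
                      seed: int = 0) -> Codebook:
    """Random codebook with balanced letter usage per cycle.

    Gene panels are designed so every base channel carries a comparable
    number of rolonies in every cycle; this helper emulates that by drawing
    each cycle's letters as a shuffled balanced assignment, re-drawing on
    barcode collisions.
    """
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        cols = []
        for _c in range(n_cycles):
            letters = np.tile(list("ACGT"), n_genes // 4 + 1)[:n_genes]
            rng.shuffle(letters)
            cols.append(letters)
        barcodes = ["".join(col[i] for col in cols) for i in range(n_genes)]
        if len(set(barcodes)) == n_genes:
            return Codebook({f"gene{i + 1:02d}": bc
                             for i, bc in enumerate(barcodes)})
    raise RuntimeError("could not draw a collision-free codebook")


def _add_spot(img: np.ndarray, x: float, y: float, amp: float, sigma: float):
    """Stamp a 2-D Gaussian of peak ``amp`` at subpixel (x, y)."""
    r = max(2, int(np.ceil(4 * sigma)))
    h, w = img.shape
    c0, c1 = max(0, int(x) - r), min(w, int(x) + r + 1)
    r0, r1 = max(0, int(y) - r), min(h, int(y) + r + 1)
    if c0 >= c1 or r0 >= r1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    img[r0:r1, c0:c1] += amp * np.exp(
        -((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma ** 2))


def _sample_positions(rng, n, size, margin, min_sep, hotspot_fraction=0.0):
    """Positions with minimum pairwise separation (rejection sampling).

    A ``hotspot_fraction`` share of the points is confined to the central
    square of half the image side, mimicking tissue regions of high cell
    density; the rest is uniform over the full frame.
    """
    n_hot = int(round(n * hotspot_fraction))
    lo_hot, hi_hot = size * 0.25, size * 0.75
    pts = []
    tries = 0
    while len(pts) < n:
        tries += 1
        if tries > 1000 * max(n, 1):
            raise RuntimeError("could not place rolonies; lower n or min_sep")
        if len(pts) < n_hot:
            p = rng.uniform(max(lo_hot, margin), min(hi_hot, size - margin),
                            size=2)
        else:
            p = rng.uniform(margin, size - margin, size=2)
        if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= min_sep ** 2
               for q in pts):
            pts.append(p)
    return pts


def simulate_iss(config: SimConfig, codebook: Codebook):
    """Render a synthetic image stack; returns (ChannelStack, ground truth).

    Each rolony contributes a Gaussian spot (sd = ``psf_sigma``) to exactly
    one base channel per cycle (its barcode letter) and to the anchor channel
    every cycle; the per-cycle position is the true position plus Gaussian
    jitter.  A ``bleedthrough_fraction`` copy of every base-channel spot
    lands in one spectrally adjacent channel.  False spots are added per
    base-channel image at ``false_spot_rate`` (Poisson).  Identical config
    (including seed) gives bit-identical output.
    """
    if codebook.entries and codebook.barcode_length != config.n_cycles:
        raise ValueError("codebook barcode length must equal n_cycles")
    for bc in codebook.entries.values():
        if set(bc) - set("ACGT"):
            raise ValueError(f"invalid barcode letter in {bc}")
    rng = np.random.default_rng(config.seed)
    size = config.image_size
    genes = codebook.genes
    if config.n_rolonies > 0 and not genes:
        raise ValueError("non-empty codebook required to place rolonies")

    truth = []
    positions = _sample_positions(rng, config.n_rolonies, size,
                                  config.border_margin,
                                  config.min_separation,
                                  config.hotspot_fraction)
    for i, (x, y) in enumerate(positions):
        gene = genes[rng.integers(len(genes))]
        amp = float(config.amplitude_mean * rng.lognormal(
            0.0, config.amplitude_cv))
        truth.append(GroundTruthRolony(
            id=i, x=float(x), y=float(y), gene=gene,
            barcode=codebook.entries[gene], amplitude=amp))

    n_ch = len(CHANNEL_ROLES)
    images = np.full((config.n_cycles, n_ch, size, size),
                     config.background_level, dtype=float)
    ch_idx = {role: CHANNEL_ROLES.index(role) for role in CHANNEL_ROLES}

    # dim nuclei blobs: context only, never decoded
    nuc = images[:, ch_idx["nuclei"]]
    for _ in range(max(1, size // 32)):
        nx, ny = rng.uniform(0, size, 2)
        for c in range(config.n_cycles):
            _add_spot(nuc[c], nx, ny, 50.0, 6.0)

    for rol in truth:
        for c in range(config.n_cycles):
            jx, jy = rng.normal(0.0, config.jitter_sd, 2) \
                if config.jitter_sd > 0 else (0.0, 0.0)
            x, y = rol.x + jx, rol.y + jy
            letter = rol.barcode[c]
            _add_spot(images[c, ch_idx[letter]], x, y, rol.amplitude,
                      config.psf_sigma)
            if config.bleedthrough_fraction > 0:
                _add_spot(images[c, ch_idx[BLEED_PARTNER[letter]]], x, y,
                          rol.amplitude * config.bleedthrough_fraction,
                          config.psf_sigma)
            _add_spot(images[c, ch_idx["anchor"]], x, y,
                      0.8 * rol.amplitude, config.psf_sigma)

    false_spots = []
    if config.false_spot_rate > 0:
        for c in range(config.n_cycles):
            for letter in BASE_CHANNELS:
                for _ in range(rng.poisson(config.false_spot_rate)):
                    fx, fy = rng.uniform(0, size, 2)
                    amp = float(0.4 * config.amplitude_mean *
                                rng.lognormal(0.0, 0.3))
                    _add_spot(images[c, ch_idx[letter]], fx, fy, amp,
                              config.psf_sigma)
                    false_spots.append((c + 1, letter, float(fx), float(fy)))

    if config.noise_sd > 0:
        images += rng.normal(0.0, config.noise_sd, images.shape)

    stack = ChannelStack(images=images, channel_roles=CHANNEL_ROLES,
                         meta={"simulated": True, "seed": config.seed,
                               "false_spots": false_spots})
    return stack, truth


def truth_to_frame(truth) -> pd.DataFrame:
    return pd.DataFrame([{"id": t.id, "x": t.x, "y": t.y, "gene": t.gene,
                          "barcode": t.barcode, "amplitude": t.amplitude}
                         for t in truth])


def score_decoding(truth, reads, match_radius: float = 2.0):
    """Greedy one-to-one matching of reads to ground truth.

    A read matches a truth rolony when it lies within ``match_radius`` and
    carries the same barcode; pairs are accepted closest-first.  Returns
    ``(recall, precision)`` = matched/|truth| and matched/|reads|; with no
    reads the precision is ``None``.  Empty truth is an error (recall would
    be undefined).
    """
    if match_radius <= 0:
        raise ValueError("match_radius must be > 0")
    if not truth:
        raise ValueError("empty ground truth: recall is undefined")
    if not reads:
        return 0.0, None
    pairs = []
    for ti, t in enumerate(truth):
        for ri, r in enumerate(reads):
            d = float(np.hypot(t.x - r.x, t.y - r.y))
            if d <= match_radius and t.barcode == r.barcode:
                pairs.append((d, ti, ri))
    pairs.sort()
    used_t, used_r = set(), set()
    matched = 0
    for d, ti, ri in pairs:
        if ti in used_t or ri in used_r:
            continue
        used_t.add(ti)
        used_r.add(ri)
        matched += 1
    return matched / len(truth), matched / len(reads)


def simulate_tissue_expression(n_regions: int = 3, grid_shape=(9, 9),
                               program_genes_per_region: int = 6,
                               extra_informative: int = 3,
                               n_noise_genes: int = 9,
                               program_rate: float = 15.0,
                               background_rate: float = 0.3,
                               density_sd: float = 0.3,
                               gene_names=None, seed: int = 0):
    """Synthetic patch-level tissue with planted spatial compartments.

    Lays ``grid_shape`` patches in vertical-stripe regions.  Each region
    strongly expresses its own disjoint gene program (Poisson counts at
    ``program_rate``; all other genes at ``background_rate``), modulated by a
    per-patch lognormal density factor emulating varying cell content.  By
    default the first ``n_regions * program_genes_per_region`` genes are
    taken from the 18-gene reduced marker panel, so that subsetting to that
    panel retains one informative program per region; ``extra_informative``
    additional genes per region and ``n_noise_genes`` flat genes complete the
    panel.

    Returns ``(PatchExpression raw, region_labels)`` with one label per
    patch.  Not emulated: smooth regional boundaries, mixed-program patches,
    or anatomically shaped regions.
    """
    from .compart import MARKER_PANEL
    from .exprmat import PatchExpression, PatchGrid

    rng = np.random.default_rng(seed)
    n_rows, n_cols = grid_shape
    n_patches = n_rows * n_cols
    n_program = n_regions * program_genes_per_region
    n_extra = n_regions * extra_informative
    if gene_names is None:
        if n_program > len(MARKER_PANEL):
            raise ValueError("not enough marker genes for the programs")
        gene_names = (list(MARKER_PANEL[:n_program])
                      + [f"prog_extra{i}" for i in range(n_extra)]
                      + [f"flat{i}" for i in range(n_noise_genes)])
    genes = list(gene_names)

    col_idx = np.tile(np.arange(n_cols), n_rows)
    labels = np.minimum(col_idx * n_regions // n_cols, n_regions - 1)

    rate = np.full((n_patches, len(genes)), background_rate)
    for r in range(n_regions):
        members = labels == r
        prog = list(range(r * program_genes_per_region,
                          (r + 1) * program_genes_per_region))
        prog += [n_program + r * extra_informative + i
                 for i in range(extra_informative)]
        rate[np.ix_(members, prog)] = program_rate
    density = rng.lognormal(0.0, density_sd, size=n_patches)
    counts = rng.poisson(rate * density[:, None])

    grid = PatchGrid(extent=(n_cols * 128, n_rows * 128))
    table = grid.patch_table()
    expr = PatchExpression(
        counts=counts, genes=genes, patches=table,
        gene_read_totals={g: int(t) for g, t in
                          zip(genes, counts.sum(axis=0))},
        meta={"planted_regions": n_regions, "seed": seed})
    return expr, labels


# ---------------------------------------------------------------------------
# worked-example fixture: 14 detections, 2 components, 3 decodable paths
# ---------------------------------------------------------------------------

@dataclass
class Fig1aFixture:
    """Hand-built decoding example over 4 cycles.

    Component A holds one rolony (path D1-D5-D8-D12, sequence TAGT) plus two
    lower-probability noise detections (D2 in cycle 1, D9 in cycle 3);
    component B holds two nearby rolonies (D3-D6-D10-D13 -> GCAC and
    D4-D7-D11-D14 -> GCAG) whose chains are close enough that direct and
    forced connections interleave.  Positions and probabilities are chosen by
    construction to realize this topology at the default graph parameters
    (d_th = 2 px, d_max = 3 px).
    """

    detections: list
    expected_components: int = 2
    expected_sequences: frozenset = frozenset({"TAGT", "GCAC", "GCAG"})
    expected_paths: tuple = ((1, 5, 8, 12), (3, 6, 10, 13), (4, 7, 11, 14))
    codebook: Codebook = field(
        default_factory=lambda: Codebook(
            {"g1": "TAGT", "g2": "GCAC", "g3": "GCAG"}))


_FIG1A = [
    # (label, cycle, channel, x, y, probability)
    (1, 1, "T", 10.0, 10.0, 0.90),
    (2, 1, "A", 10.9, 11.7, 0.30),
    (3, 1, "G", 30.0, 30.0, 0.90),
    (4, 1, "G", 32.5, 30.0, 0.90),
    (5, 2, "A", 10.3, 10.1, 0.90),
    (6, 2, "C", 30.2, 30.1, 0.89),
    (7, 2, "C", 32.6, 30.2, 0.91),
    (8, 3, "G", 10.1, 9.9, 0.88),
    (9, 3, "C", 11.9, 10.3, 0.35),
    (10, 3, "A", 31.0, 29.9, 0.88),
    (11, 3, "A", 32.4, 29.8, 0.90),
    (12, 4, "T", 10.2, 10.2, 0.92),
    (13, 4, "C", 30.0, 30.2, 0.92),
    (14, 4, "G", 32.7, 30.1, 0.90),
]


def fig1a_fixture() -> Fig1aFixture:
    """The 14-detection worked example of the decoding graph."""
    detections = [
        SignalCandidate(id=label, cycle=cycle, channel=channel, x=x, y=y,
                        intensity=p, probability=p)
        for label, cycle, channel, x, y, p in _FIG1A]
    return Fig1aFixture(detections=detections)
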