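"""End-to-end decoding: images in, quality-scored gene reads out.

Chains the per-stage modules: normalization -> per-channel spot detection ->
signal probability prediction -> cross-channel merging -> detection-graph
construction -> min-cost max-flow decoding -> quality scoring and filtering.
Probabilities are predicted for *all* detections before merging so that
merged-away competitors keep the probabilities needed for per-base quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import imgprep, readqc, sigprob, spots
from .graphdecode import Codebook, build_graph, decode, solve


@dataclass
class DecodeConfig:
    """Tunable parameters of the decode chain (see module docs for units)."""

    h: float = 0.05
    tophat_radius: int = 2
    k: float = 1.0
    d_th: float = 2.0
    d_max: float = 3.0
    quality_threshold: float = 2.0
    sigma: float = 5.0
    calibrate_sigma: bool = False
    n_norm_patches: int = 50
    norm_patch_size: int = 128
    seed: int = 0


@dataclass
class DecodeResult:
    """Reads plus the intermediate state useful for QC and debugging."""

    reads: list                     # quality-filtered codebook matches
    all_reads: list                 # every decoded path, incl. UNEXPECTED
    candidates: list                # merged candidates with probabilities
    sigma: float
    sigma_table: list | None = None
    stats: dict = field(default_factory=dict)


def decode_stack(stack, codebook: Codebook, model,
                 config: DecodeConfig | None = None,
                 normalized: bool = False) -> DecodeResult:
    """Decode one registered image stack into gene reads.

    ``model`` is a fitted :class:`~issgraph.sigprob.ProbabilityModel` (or any
    object with the same ``predict_windows`` contract).  Set
    ``normalized=True`` when the stack's intensities are already scaled to
    background 0 / signal 1.
    """
    cfg = config or DecodeConfig()
    if not normalized:
        stats = imgprep.estimate_normalization(
            stack, n_patches=cfg.n_norm_patches,
            patch_size=min(cfg.norm_patch_size, *stack.shape), seed=cfg.seed)
        stack = imgprep.normalize(stack, stats)

    candidates = spots.detect_stack(stack, h=cfg.h,
                                    tophat_radius=cfg.tophat_radius)
    sigprob.predict(model, candidates, stack)
    merged = spots.merge_stack(candidates)

    graph = build_graph(merged, k=cfg.k, d_th=cfg.d_th, d_max=cfg.d_max,
                        n_cycles=stack.n_cycles)
    paths = solve(graph)
    all_reads = decode(paths, codebook)

    sigma, table = cfg.sigma, None
    if cfg.calibrate_sigma:
        try:
            sigma, table = readqc.calibrate_sigma(all_reads, codebook)
        except ValueError:
            sigma = cfg.sigma       # single-class run: keep the default
    params = readqc.QualityParams(sigma=sigma,
                                  quality_threshold=cfg.quality_threshold)
    readqc.score_reads(all_reads, params)
    reads = readqc.filter_reads(all_reads, cfg.quality_threshold)
    return DecodeResult(
        reads=reads, all_reads=all_reads, candidates=merged, sigma=sigma,
        sigma_table=table,
        stats={"n_candidates_raw": len(candidates),
               "n_candidates_merged": len(merged),
               "n_paths": len(paths), "n_reads_kept": len(reads)})


def train_model_from_simulation(config, codebook: Codebook, seed: int = 0,
                                decode_config: DecodeConfig | None = None):
    """Fit the default probability model on one simulated stack.

    Simulates a training stack (ground truth known), detects candidates at
    the production settings, labels them by proximity to true emissions, and
    trains the window classifier.  Returns the fitted model.
    """
    from dataclasses import replace

    from .simdata import simulate_iss

    cfg = decode_config or DecodeConfig()
    train_stack, truth = simulate_iss(replace(config, seed=seed), codebook)
    stats = imgprep.estimate_normalization(
        train_stack, n_patches=cfg.n_norm_patches,
        patch_size=min(cfg.norm_patch_size, *train_stack.shape),
        seed=seed)
    norm = imgprep.normalize(train_stack, stats)
    candidates = spots.detect_stack(norm, h=cfg.h,
                                    tophat_radius=cfg.tophat_radius)
    examples = sigprob.training_examples_from_truth(norm, candidates, truth)
    return sigprob.train(examples, seed=seed)
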