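"""Per-read quality scoring, sigma calibration, and read filtering.

A decoded sequence s over n cycles gets

    Q_s = mu_s * sum_b Q_sb,        b = 1..n

where Q_sb is the per-base quality of the detection used in cycle b and
mu_s = clip(1 - log(1+d)/sigma, 0, 1) penalizes paths whose detections lie
far apart (d = maximum pairwise distance along the path).  If competing
detections with probability > 0.5 were merged away in a cycle,

    Q_sb = I p / (I p + max_c I_c p_c),

otherwise Q_sb = p.  sigma is calibrated as the value maximizing the ROC AUC
of Q_s separating codebook-matching reads from unexpected barcodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .graphdecode import UNEXPECTED, Codebook, DecodedRead

COMPETITOR_PROBABILITY_FLOOR = 0.5


@dataclass
class QualityParams:
    """Knobs of the read-quality model.

    ``sigma`` weights the distance penalty (larger = more tolerant of spread
    paths); ``quality_threshold`` is applied inclusively to Q_s.  The default
    sigma suits sub-pixel-jitter data and should be replaced by
    :func:`calibrate_sigma` whenever unexpected barcodes are available.
    """

    sigma: float = 5.0
    quality_threshold: float = 2.0
    competitor_probability_floor: float = COMPETITOR_PROBABILITY_FLOOR

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


def base_quality(detection, competitors=None) -> float:
    """Per-base quality Q_sb of one detection against its merged competitors.

    Competitors are the detections merged away in the same cycle whose signal
    probability exceeds 0.5; absent competitors, Q_sb is simply the
    detection's probability.
    """
    if detection.intensity < 0:
        raise ValueError("negative intensity")
    p = detection.probability
    rivals = [c for c in (competitors or [])
              if c.probability is not None
              and c.probability > COMPETITOR_PROBABILITY_FLOOR]
    if not rivals:
        return float(p)
    own = detection.intensity * p
    best = max(c.intensity * c.probability for c in rivals)
    return float(own / (own + best))


def distance_penalty(max_pair_distance: float, sigma: float) -> float:
    """mu_s = clip(1 - log(1+d)/sigma, 0, 1)."""
    if max_pair_distance < 0:
        raise ValueError("distance must be >= 0")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return float(np.clip(1.0 - math.log1p(max_pair_distance) / sigma, 0.0, 1.0))


def read_quality(read: DecodedRead, params: QualityParams) -> float:
    """Q_s = mu_s * sum of per-base qualities; fills the read in place.

    Competitors for each base are taken from the path detections'
    ``merged_from`` records.
    """
    qsb = [base_quality(det, det.merged_from) for det in read.path]
    mu = distance_penalty(read.max_pair_distance, params.sigma)
    read.per_base_quality = qsb
    read.quality = float(mu * sum(qsb))
    return read.quality


def score_reads(reads, params: QualityParams):
    """Apply :func:`read_quality` to every read; returns the same list."""
    for r in reads:
        read_quality(r, params)
    return reads


def default_sigma_grid(n: int = 20, lo: float = 0.5, hi: float = 10.0):
    return list(np.geomspace(lo, hi, n))


def calibrate_sigma(reads, codebook: Codebook, sigma_grid=None):
    """Pick sigma maximizing ROC AUC of Q_s for targeted vs unexpected reads.

    Positives are reads whose barcode matches the codebook, negatives the
    unexpected barcodes.  Returns ``(sigma_star, table)`` where ``table`` is a
    list of ``(sigma, auc)`` pairs; ties go to the smallest sigma.
    """
    if sigma_grid is None:
        sigma_grid = default_sigma_grid()
    if not sigma_grid:
        raise ValueError("sigma grid is empty")
    labels = np.array([r.gene != UNEXPECTED for r in reads], dtype=int)
    if labels.min() == labels.max():
        raise ValueError(
            "sigma calibration needs both targeted and unexpected reads")
    table = []
    for sigma in sorted(sigma_grid):
        params = QualityParams(sigma=sigma)
        q = [read_quality(r, params) for r in reads]
        table.append((float(sigma), float(roc_auc_score(labels, q))))
    best_sigma, _ = max(table, key=lambda t: (t[1], -t[0]))
    return best_sigma, table


def filter_reads(reads, quality_threshold: float = 2.0):
    """Keep codebook-matching reads with Q_s >= threshold (inclusive)."""
    kept = []
    for r in reads:
        if r.quality is None:
            raise ValueError("read qualities not computed; run score_reads")
        if r.gene != UNEXPECTED and r.quality >= quality_threshold:
            kept.append(r)
    return kept
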