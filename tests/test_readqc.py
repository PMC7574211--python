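"""Read quality formulas, sigma calibration, and filtering."""

import math

import numpy as np
import pytest

from issgraph import (Codebook, QualityParams, base_quality, calibrate_sigma,
                      distance_penalty, filter_reads, read_quality)
from issgraph.graphdecode import UNEXPECTED, DecodedRead
from issgraph.spots import SignalCandidate


def _det(intensity, p, cycle=1, channel="A", merged=()):
    d = SignalCandidate(id=0, cycle=cycle, channel=channel, x=0.0, y=0.0,
                        intensity=intensity, probability=p)
    d.merged_from = list(merged)
    return d


def _rival(intensity, p):
    return SignalCandidate(id=99, cycle=1, channel="C", x=0.0, y=0.0,
                           intensity=intensity, probability=p)


def _read(base_dets, d=0.0, gene="g", barcode="AAAA"):
    return DecodedRead(path=base_dets, barcode=barcode, x=0, y=0, gene=gene,
                       max_pair_distance=d)


class TestBaseQuality:
    def test_no_competitors_returns_probability(self):
        assert base_quality(_det(1.0, 0.9)) == pytest.approx(0.9)

    def test_identical_competitor_gives_half(self):
        assert base_quality(_det(0.7, 0.8), [_rival(0.7, 0.8)]) == \
            pytest.approx(0.5)

    def test_strongest_competitor_wins(self):
        q = base_quality(_det(1.0, 0.8), [_rival(0.5, 0.6),
                                          _rival(0.4, 0.9)])
        assert q == pytest.approx(0.8 / (0.8 + 0.36))

    def test_low_probability_competitors_ignored(self):
        """Merged detections at p <= 0.5 do not dilute the base quality."""
        assert base_quality(_det(1.0, 0.9), [_rival(5.0, 0.5)]) == \
            pytest.approx(0.9)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            base_quality(_det(-0.1, 0.9))


class TestDistancePenalty:
    def test_zero_distance_full_score(self):
        assert distance_penalty(0.0, sigma=2.0) == 1.0

    def test_clip_boundary(self):
        sigma = 1.7
        assert distance_penalty(math.e ** sigma - 1, sigma) == \
            pytest.approx(0.0, abs=1e-12)
        assert distance_penalty(math.e ** sigma, sigma) == 0.0

    def test_hand_computed_value(self):
        assert distance_penalty(3.0, sigma=2.0) == \
            pytest.approx(1 - math.log(4) / 2)


class TestReadQuality:
    def test_upper_bound_four_cycles(self):
        read = _read([_det(1.0, 1.0, cycle=c) for c in range(1, 5)], d=0.0)
        assert read_quality(read, QualityParams(sigma=2.0)) == \
            pytest.approx(4.0)

    def test_distance_annihilates(self):
        read = _read([_det(1.0, 1.0, cycle=c) for c in range(1, 5)],
                     d=100.0)
        assert read_quality(read, QualityParams(sigma=2.0)) == 0.0

    def test_weighted_sum(self):
        dets = [_det(1.0, p, cycle=c)
                for c, p in enumerate((0.9, 0.8, 0.7, 0.6), start=1)]
        read = _read(dets, d=0.0)
        params = QualityParams(sigma=2.0)
        q = read_quality(read, params)
        # pick d so that mu_s = 0.5: log(1+d) = sigma/2
        read2 = _read(dets, d=math.e - 1)
        params2 = QualityParams(sigma=2 * math.log(math.e))
        assert read_quality(read2, params2) == pytest.approx(0.5 * 3.0)
        assert q == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_distance(self, seed):
        rng = np.random.default_rng(seed)
        dets = [_det(1.0, float(rng.uniform(0.5, 1)), cycle=c)
                for c in range(1, 5)]
        params = QualityParams(sigma=float(rng.uniform(1, 8)))
        qs = [read_quality(_read(list(dets), d=d), params)
              for d in np.linspace(0, 20, 30)]
        assert all(a >= b - 1e-12 for a, b in zip(qs, qs[1:]))

    def test_random_parameterizations_match_direct_formulas(self):
        """Q_sb, mu_s, Q_s agree with literal formula evaluation to 1e-12."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(2, 6))
            sigma = float(rng.uniform(0.5, 10))
            d = float(rng.uniform(0, 30))
            dets, expected_qsb = [], []
            for c in range(1, n + 1):
                I = float(rng.uniform(0.05, 3))
                p = float(rng.uniform(0.01, 1))
                rivals = [_rival(float(rng.uniform(0.05, 3)),
                                 float(rng.uniform(0.01, 1)))
                          for _ in range(rng.integers(0, 3))]
                dets.append(_det(I, p, cycle=c, merged=rivals))
                live = [r for r in rivals if r.probability > 0.5]
                if live:
                    best = max(r.intensity * r.probability for r in live)
                    expected_qsb.append(I * p / (I * p + best))
                else:
                    expected_qsb.append(p)
            mu = min(1.0, max(0.0, 1 - math.log(1 + d) / sigma))
            expected_q = mu * sum(expected_qsb)
            read = _read(dets, d=d)
            q = read_quality(read, QualityParams(sigma=sigma))
            assert q == pytest.approx(expected_q, abs=1e-12)
            assert read.per_base_quality == pytest.approx(expected_qsb,
                                                          abs=1e-12)
            assert 0.0 <= q <= n
            assert all(0.0 <= v <= 1.0 for v in read.per_base_quality)


def _scored_reads(n_pos, n_neg, d_pos, d_neg, seed=0):
    rng = np.random.default_rng(seed)
    reads = []
    for i in range(n_pos + n_neg):
        pos = i < n_pos
        dets = [_det(1.0, float(rng.uniform(0.7, 1.0)), cycle=c)
                for c in range(1, 5)]
        d = float(rng.uniform(*(d_pos if pos else d_neg)))
        reads.append(_read(dets, d=d, gene="g" if pos else UNEXPECTED))
    return reads


class TestCalibrateSigma:
    def test_separable_reaches_perfect_auc(self):
        reads = _scored_reads(30, 30, d_pos=(0.0, 0.5), d_neg=(8.0, 20.0))
        sigma, table = calibrate_sigma(reads, Codebook({}),
                                       sigma_grid=[0.5, 1, 2, 3])
        assert max(auc for _, auc in table) == pytest.approx(1.0)
        # at sigma small enough, distant negatives are annihilated entirely
        assert sigma <= 3

    def test_finite_sigma_beats_extremes(self):
        """When off-target paths are systematically spread out, a finite
        sigma separates better than an effectively unpenalized one."""
        reads = _scored_reads(40, 40, d_pos=(0.0, 2.0), d_neg=(3.0, 15.0),
                              seed=1)
        sigma, table = calibrate_sigma(
            reads, Codebook({}), sigma_grid=list(np.geomspace(0.5, 500, 25)))
        aucs = dict(table)
        assert aucs[sigma] >= 0.9
        assert aucs[sigma] > aucs[max(aucs)]

    def test_permuted_labels_auc_near_half(self):
        rng = np.random.default_rng(2)
        reads = _scored_reads(100, 100, d_pos=(0, 5), d_neg=(0, 5), seed=2)
        genes = [r.gene for r in reads]
        rng.shuffle(genes)
        for r, g in zip(reads, genes):
            r.gene = g
        _, table = calibrate_sigma(reads, Codebook({}), sigma_grid=[2.0])
        assert table[0][1] == pytest.approx(0.5, abs=0.1)

    def test_single_class_rejected(self):
        reads = _scored_reads(10, 0, d_pos=(0, 1), d_neg=(0, 1))
        with pytest.raises(ValueError):
            calibrate_sigma(reads, Codebook({}), sigma_grid=[1.0])

    def test_auc_matches_pairwise_concordance(self):
        """ROC AUC equals the brute-force concordance count on 1000 reads."""
        reads = _scored_reads(500, 500, d_pos=(0, 6), d_neg=(2, 12), seed=3)
        _, table = calibrate_sigma(reads, Codebook({}), sigma_grid=[3.0])
        auc = table[0][1]
        q = np.array([r.quality for r in reads])
        pos, neg = q[:500], q[500:]
        gt = (pos[:, None] > neg[None, :]).sum()
        eq = (pos[:, None] == neg[None, :]).sum()
        brute = (gt + 0.5 * eq) / (500 * 500)
        assert auc == pytest.approx(brute, abs=1e-9)


class TestFilterReads:
    def test_threshold_inclusive(self):
        reads = _scored_reads(3, 0, d_pos=(0, 0), d_neg=(0, 0))
        for r, q in zip(reads, (1.9, 2.0, 2.5)):
            r.quality = q
        assert len(filter_reads(reads, 2.0)) == 2

    def test_zero_threshold_keeps_matches(self):
        reads = _scored_reads(5, 2, d_pos=(0, 1), d_neg=(0, 1))
        for r in reads:
            read_quality(r, QualityParams())
        assert len(filter_reads(reads, 0.0)) == 5

    def test_unexpected_always_dropped(self):
        reads = _scored_reads(0, 4, d_pos=(0, 1), d_neg=(0, 1))
        for r in reads:
            read_quality(r, QualityParams())
        assert filter_reads(reads, 0.0) == []

    def test_unscored_reads_rejected(self):
        reads = _scored_reads(1, 0, d_pos=(0, 0), d_neg=(0, 0))
        reads[0].quality = None
        with pytest.raises(ValueError):
            filter_reads(reads, 2.0)
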