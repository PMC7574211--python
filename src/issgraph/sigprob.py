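"""Signal-vs-noise probability prediction for candidates.

Each candidate gets a probability of being true signal, predicted from the
5x5 pixel intensity window centered on it.  The predictor is pluggable:
anything implementing ``predict_proba`` over flattened windows works.  The
default is a regularized logistic classifier on the 25 window pixels plus
four summary features (center, max, mean, sd) — the decoding graph consumes
only the probabilities, so the classifier architecture is interchangeable.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.preprocessing import StandardScaler

WINDOW = 5  # pixels, fixed by the contract
PROBABILITY_FLOOR = 1e-6


@dataclass
class WindowExample:
    """One 5x5 normalized-intensity window with a signal/noise label."""

    window: np.ndarray
    label: int  # 1 = signal, 0 = noise

    def __post_init__(self):
        self.window = np.asarray(self.window, dtype=float)
        if self.window.shape != (WINDOW, WINDOW):
            raise ValueError(f"window must be {WINDOW}x{WINDOW}")


def _features(windows: np.ndarray) -> np.ndarray:
    flat = windows.reshape(len(windows), -1)
    center = windows[:, WINDOW // 2, WINDOW // 2][:, None]
    return np.hstack([flat, center, flat.max(axis=1, keepdims=True),
                      flat.mean(axis=1, keepdims=True),
                      flat.std(axis=1, keepdims=True)])


@dataclass
class ProbabilityModel:
    """Fitted window classifier with training metadata."""

    scaler: StandardScaler
    classifier: LogisticRegression
    version: str = "logistic-1"
    n_examples: int = 0
    seed: int = 0
    training_auc: float | None = None

    def predict_windows(self, windows: np.ndarray) -> np.ndarray:
        """Probabilities in [floor, 1] for an (n, 5, 5) window array."""
        X = self.scaler.transform(_features(np.asarray(windows, dtype=float)))
        p = self.classifier.predict_proba(X)[:, 1]
        return np.clip(p, PROBABILITY_FLOOR, 1.0)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "ProbabilityModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, cls):
            raise TypeError("not a ProbabilityModel file")
        return model


def train(examples, seed: int = 0) -> ProbabilityModel:
    """Fit the default window classifier; balanced by majority downsampling.

    Raises on single-class input.  The training ROC AUC is stored on the
    model for reporting.
    """
    labels = np.array([e.label for e in examples], dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("training requires both signal and noise examples")
    windows = np.stack([e.window for e in examples])
    rng = np.random.default_rng(seed)
    idx_pos = np.flatnonzero(labels == 1)
    idx_neg = np.flatnonzero(labels == 0)
    n = min(len(idx_pos), len(idx_neg))
    keep = np.concatenate([rng.choice(idx_pos, n, replace=False),
                           rng.choice(idx_neg, n, replace=False)])
    keep.sort()
    X = _features(windows[keep])
    y = labels[keep]
    scaler = StandardScaler().fit(X)
    clf = LogisticRegression(C=1.0, max_iter=2000, random_state=seed)
    clf.fit(scaler.transform(X), y)
    model = ProbabilityModel(scaler=scaler, classifier=clf,
                             n_examples=len(keep), seed=seed)
    scores = model.predict_windows(windows[keep])
    model.training_auc = float(roc_auc_score(y, scores))
    return model


def extract_window(image: np.ndarray, x: float, y: float) -> np.ndarray:
    """5x5 window centered at the candidate's pixel, edge-replicated."""
    half = WINDOW // 2
    r = int(np.floor(y + 0.5))
    c = int(np.floor(x + 0.5))
    padded = np.pad(image, half, mode="edge")
    return padded[r:r + WINDOW, c:c + WINDOW]


def predict(model: ProbabilityModel, candidates, stack) -> list:
    """Fill each candidate's ``probability`` from its image window.

    The window is taken from the candidate's own (cycle, channel) image of
    the normalized stack; candidate order is preserved.
    """
    if model.classifier is None or not hasattr(model.classifier, "coef_"):
        raise ValueError("model is not fitted")
    if not candidates:
        return []
    windows = np.stack([
        extract_window(stack.get(c.cycle - 1, c.channel), c.x, c.y)
        for c in candidates])
    probs = model.predict_windows(windows)
    for cand, p in zip(candidates, probs):
        cand.probability = float(p)
    return list(candidates)


def training_examples_from_truth(stack, candidates, truth,
                                 match_radius: float = 2.0,
                                 n_background: int | None = None,
                                 seed: int = 0):
    """Label detected candidates against simulated ground truth.

    A candidate is a *signal* example when a true full-strength emission — a
    rolony's direct spot or an injected false spot — lies within
    ``match_radius`` in the candidate's (cycle, channel) image.  Dim
    bleed-through copies and everything else are noise: low predicted
    probabilities are precisely how the decoding graph demotes bleed
    duplicates that escape pixel-adjacency merging.  Because clean images
    nominate few pure-noise candidates, ``n_background`` random windows far
    from every emission (default: as many as there are candidates) are
    appended as additional noise examples.
    """
    from .imgprep import BASE_CHANNELS

    false_spots = stack.meta.get("false_spots", [])
    emitters: dict = {}
    for t in truth:
        for cyc1, letter in enumerate(t.barcode, start=1):
            emitters.setdefault((cyc1, letter), []).append((t.x, t.y))
    for cyc1, letter, fx, fy in false_spots:
        emitters.setdefault((cyc1, letter), []).append((fx, fy))
    emit_pos = {key: np.array(v) for key, v in emitters.items()}

    def near_emitter(cyc1, letter, x, y, radius):
        pos = emit_pos.get((cyc1, letter))
        if pos is None or len(pos) == 0:
            return False
        return bool((np.hypot(pos[:, 0] - x, pos[:, 1] - y) <= radius).any())

    examples = []
    for cand in candidates:
        label = near_emitter(cand.cycle, cand.channel, cand.x, cand.y,
                             match_radius)
        window = extract_window(stack.get(cand.cycle - 1, cand.channel),
                                cand.x, cand.y)
        examples.append(WindowExample(window=window, label=int(label)))

    rng = np.random.default_rng(seed)
    n_bg = len(candidates) if n_background is None else n_background
    h, w = stack.shape
    placed, attempts = 0, 0
    while placed < n_bg and attempts < 50 * max(n_bg, 1):
        attempts += 1
        cyc1 = int(rng.integers(1, stack.n_cycles + 1))
        letter = BASE_CHANNELS[rng.integers(4)]
        x = float(rng.uniform(0, w - 1))
        y = float(rng.uniform(0, h - 1))
        if near_emitter(cyc1, letter, x, y, 2 * match_radius):
            continue
        window = extract_window(stack.get(cyc1 - 1, letter), x, y)
        examples.append(WindowExample(window=window, label=0))
        placed += 1
    return examples
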