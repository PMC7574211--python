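"""Image normalization, tiling, and per-tile alignment refinement.

Registered in situ sequencing (ISS) image series arrive as one 2-D image per
(sequencing cycle, fluorescent channel).  Each cycle carries six channels: a
nuclei stain, a general ("anchor") stain that marks every rolony regardless of
its current base, and four base channels A/C/G/T.  This module provides the
:class:`ChannelStack` container, background/signal estimation from random
patches, min-max style intensity normalization, non-overlapping tiling, and a
translation-only per-tile alignment refinement against the anchor channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile
import yaml
from skimage.registration import phase_cross_correlation
from scipy import ndimage

BASE_CHANNELS = ("A", "C", "G", "T")
CHANNEL_ROLES = ("nuclei", "anchor") + BASE_CHANNELS


class DegenerateChannelError(ValueError):
    """Raised when a channel's signal estimate does not exceed its background."""


@dataclass
class ChannelStack:
    """Registered ISS image tensor indexed by (cycle, channel).

    Parameters
    ----------
    images
        Array of shape ``(n_cycles, n_channels, H, W)``.
    channel_roles
        Role label per channel axis entry; must contain exactly one
        ``"nuclei"``, one ``"anchor"`` and the four bases A, C, G, T.
    pixel_size
        Optional physical pixel size in microns.
    origin
        Global (row, col) pixel offset of this stack; tiles produced by
        :func:`tile` carry their position here.
    """

    images: np.ndarray
    channel_roles: tuple = CHANNEL_ROLES
    pixel_size: float | None = None
    origin: tuple = (0, 0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.images = np.asarray(self.images)
        self.channel_roles = tuple(self.channel_roles)
        if self.images.ndim != 4:
            raise ValueError("images must have shape (n_cycles, n_channels, H, W)")
        if self.images.shape[1] != len(self.channel_roles):
            raise ValueError("channel axis does not match channel_roles")
        for role in ("nuclei", "anchor"):
            if self.channel_roles.count(role) != 1:
                raise ValueError(f"exactly one {role!r} channel required")
        if set(BASE_CHANNELS) - set(self.channel_roles):
            raise ValueError("base channels must be exactly A, C, G, T")

    @property
    def n_cycles(self) -> int:
        return self.images.shape[0]

    @property
    def shape(self) -> tuple:
        return self.images.shape[2:]

    def channel_index(self, role: str) -> int:
        return self.channel_roles.index(role)

    def get(self, cycle: int, role: str) -> np.ndarray:
        """Image for 0-based ``cycle`` and channel ``role``."""
        return self.images[cycle, self.channel_index(role)]

    def save(self, prefix) -> None:
        """Write one multi-page TIFF per cycle (pages follow channel order)."""
        for c in range(self.n_cycles):
            tifffile.imwrite(f"{prefix}_cycle{c + 1}.tif",
                             self.images[c].astype(np.float32))

    @classmethod
    def load(cls, paths, channel_roles=CHANNEL_ROLES, **kw) -> "ChannelStack":
        """Read a stack from one multi-page TIFF per cycle."""
        images = np.stack([tifffile.imread(p) for p in paths])
        return cls(images=images, channel_roles=channel_roles, **kw)


@dataclass
class NormalizationStats:
    """Per-(cycle, channel) background and signal levels.

    ``background[cycle][role]`` is the mean of per-patch intensity modes over
    randomly sampled patches; ``signal[cycle][role]`` is the 99th percentile of
    per-patch 98th intensity percentiles.  Only anchor and base channels are
    covered; the nuclei channel is never normalized.
    """

    background: dict
    signal: dict
    n_patches: int
    patch_size: int
    seed: int

    def to_yaml(self, path) -> None:
        payload = {
            "n_patches": self.n_patches,
            "patch_size": self.patch_size,
            "seed": self.seed,
            "background": {c: {r: float(v) for r, v in d.items()}
                           for c, d in self.background.items()},
            "signal": {c: {r: float(v) for r, v in d.items()}
                       for c, d in self.signal.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "NormalizationStats":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(background=payload["background"], signal=payload["signal"],
                   n_patches=payload["n_patches"],
                   patch_size=payload["patch_size"], seed=payload["seed"])


def _patch_mode(patch: np.ndarray) -> float:
    """Mode of a patch's intensities on a binned histogram.

    Integer-valued data are binned at unit width; float data use 256 equal
    bins over the observed range (the mode of truly continuous data is
    undefined otherwise).  Returns the center of the most populated bin.
    """
    flat = patch.ravel()
    if flat.size == 0:
        raise ValueError("empty patch")
    is_integral = np.issubdtype(flat.dtype, np.integer) or np.allclose(
        flat, np.round(flat))
    lo, hi = float(flat.min()), float(flat.max())
    if lo == hi:
        return lo
    if is_integral:
        edges = np.arange(np.floor(lo) - 0.5, np.ceil(hi) + 1.5)
    else:
        edges = np.linspace(lo, hi, 257)
    hist, edges = np.histogram(flat, bins=edges)
    i = int(np.argmax(hist))
    return float(0.5 * (edges[i] + edges[i + 1]))


def estimate_normalization(stack: ChannelStack, n_patches: int = 50,
                           patch_size: int = 128, seed: int = 0,
                           ) -> NormalizationStats:
    """Estimate background/signal per (cycle, anchor-or-base channel).

    ``n_patches`` square patches of side ``patch_size`` are sampled uniformly
    (seeded).  Background = mean of patch modes; signal = 99th percentile of
    per-patch 98th percentiles.

    Raises
    ------
    DegenerateChannelError
        If any channel's signal estimate does not exceed its background
        (e.g. a constant image), naming the offending (cycle, channel).
    ValueError
        If ``patch_size`` exceeds the image dimensions.
    """
    h, w = stack.shape
    if patch_size > h or patch_size > w:
        raise ValueError(f"patch_size {patch_size} exceeds image size {(h, w)}")
    if n_patches < 1:
        raise ValueError("n_patches must be >= 1")
    rng = np.random.default_rng(seed)
    rows = rng.integers(0, h - patch_size + 1, size=n_patches)
    cols = rng.integers(0, w - patch_size + 1, size=n_patches)
    background, signal = {}, {}
    for cycle in range(stack.n_cycles):
        background[cycle], signal[cycle] = {}, {}
        for role in ("anchor",) + BASE_CHANNELS:
            img = stack.get(cycle, role)
            modes, p98s = [], []
            for r, c in zip(rows, cols):
                patch = img[r:r + patch_size, c:c + patch_size]
                modes.append(_patch_mode(patch))
                p98s.append(float(np.percentile(patch, 98)))
            bg = float(np.mean(modes))
            sig = float(np.percentile(p98s, 99))
            if sig <= bg:
                raise DegenerateChannelError(
                    f"cycle {cycle + 1} channel {role}: signal estimate "
                    f"{sig} does not exceed background {bg}")
            background[cycle][role] = bg
            signal[cycle][role] = sig
    return NormalizationStats(background=background, signal=signal,
                              n_patches=n_patches, patch_size=patch_size,
                              seed=seed)


def normalize(stack: ChannelStack, stats: NormalizationStats) -> ChannelStack:
    """Rescale intensities so background maps to 0 and signal to 1.

    Output = ``(raw - background) / (signal - background)``, clipped below at
    0; values above 1 are retained (bright rolonies may exceed the robust
    signal estimate).  The nuclei channel passes through untouched.
    """
    out = stack.images.astype(float).copy()
    for cycle in range(stack.n_cycles):
        for role in ("anchor",) + BASE_CHANNELS:
            try:
                bg = stats.background[cycle][role]
                sig = stats.signal[cycle][role]
            except KeyError:
                raise KeyError(
                    f"normalization stats missing cycle {cycle + 1} "
                    f"channel {role}") from None
            ch = stack.channel_index(role)
            out[cycle, ch] = np.clip(
                (out[cycle, ch] - bg) / (sig - bg), 0.0, None)
    return replace(stack, images=out,
                   meta={**stack.meta, "normalized": True})


def tile(stack: ChannelStack, tile_size: int = 1028):
    """Split into non-overlapping tiles; edge tiles may be smaller.

    Returns a list of ``(tile_origin, ChannelStack)`` with ``tile_origin`` in
    global 0-based (row, col) pixel coordinates.  The tiles partition the
    image: concatenating them reconstructs it exactly.
    """
    if tile_size < 1:
        raise ValueError("tile_size must be >= 1")
    h, w = stack.shape
    tiles = []
    for r0 in range(0, h, tile_size):
        for c0 in range(0, w, tile_size):
            sub = stack.images[:, :, r0:r0 + tile_size, c0:c0 + tile_size]
            origin = (stack.origin[0] + r0, stack.origin[1] + c0)
            tiles.append((origin, replace(stack, images=sub, origin=origin)))
    return tiles


def refine_alignment(tile_stack: ChannelStack, reference_cycle: int = 0,
                     upsample_factor: int = 10) -> ChannelStack:
    """Translation-only refinement of each cycle against a reference cycle.

    The anchor channel of every cycle is cross-correlated against the
    reference cycle's anchor (subpixel phase correlation); the recovered
    (row, col) shift is applied to all channels of that cycle.  Shifts are
    recorded in ``meta["shifts"]``.  A flat anchor yields a zero shift with a
    warning.
    """
    anchor = tile_stack.channel_index("anchor")
    ref = tile_stack.images[reference_cycle, anchor].astype(float)
    out = tile_stack.images.astype(float).copy()
    shifts = []
    for cycle in range(tile_stack.n_cycles):
        mov = tile_stack.images[cycle, anchor].astype(float)
        if np.ptp(ref) == 0 or np.ptp(mov) == 0:
            warnings.warn(
                f"flat anchor image in cycle {cycle + 1}; no shift applied")
            shifts.append((0.0, 0.0))
            continue
        shift, _, _ = phase_cross_correlation(
            ref, mov, upsample_factor=upsample_factor, normalization="phase")
        shifts.append((float(shift[0]), float(shift[1])))
        if cycle != reference_cycle and np.any(shift != 0):
            for ch in range(out.shape[1]):
                out[cycle, ch] = ndimage.shift(
                    out[cycle, ch], shift, order=1, mode="nearest")
    return replace(tile_stack, images=out,
                   meta={**tile_stack.meta, "shifts": shifts})
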