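"""Foreground-mask generation for the target channel.

Two backends mirror the tool's two operating modes: binarization of an
externally produced per-voxel probability map (the pixel-classifier
route), and Otsu thresholding of the raw channel (the classical
ablation).  Both can optionally run through the 512×512 per-plane
resampling convention: planes are downsampled to the prediction
resolution, binarized there, and the mask is upsampled back with
nearest-neighbor interpolation so no soft edges are re-thresholded.

Threshold semantics are fixed for bit-reproducibility: Otsu masks use
strict ``>`` against the chosen threshold, probability cutoffs use
``>=``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .imgio import Manifest, MultiChannelStack, find_companion, read_probmap

PREDICTION_SIZE = (512, 512)


@dataclass
class BinaryMask:
    """3D boolean foreground mask with the originating channel's spacing."""

    mask: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D (z,y,x)")
        if self.mask.dtype != bool:
            self.mask = self.mask.astype(bool)


@dataclass
class ProbabilityMap:
    """Per-voxel foreground probability in [0, 1]."""

    probs: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.probs.ndim != 3:
            raise ValueError("probability map must be 3D")
        if self.probs.size and (self.probs.min() < 0 or self.probs.max() > 1):
            raise ValueError("probabilities must lie in [0, 1]")


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float | None:
    """Otsu's threshold over a flat intensity sample.

    Builds an ``nbins``-bin histogram over [min, max] and returns the bin
    edge maximizing between-class variance; the mask convention is
    ``intensity > t``.  Returns None for a degenerate (zero-variance)
    sample, which callers map to an all-background mask.

    Ties in the between-class-variance curve resolve to the lowest
    qualifying threshold (first argmax in ascending threshold order).
    """
    values = np.asarray(values).ravel()
    if values.size == 0:
        raise ValueError("empty intensity sample")
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        return None

    hist, edges = np.histogram(values, bins=nbins, range=(lo, hi))
    hist = hist.astype(np.float64)
    total = hist.sum()

    # candidate thresholds: upper edge of each bin except the last
    # (foreground = bins strictly above the cut)
    w0 = np.cumsum(hist)[:-1]
    w1 = total - w0
    centers = (edges[:-1] + edges[1:]) / 2.0
    cum_mean = np.cumsum(hist * centers)[:-1]
    total_mean = (hist * centers).sum()
    valid = (w0 > 0) & (w1 > 0)
    between = np.zeros(nbins - 1)
    mu0 = np.divide(cum_mean, w0, out=np.zeros_like(between), where=valid)
    mu1 = np.divide(total_mean - cum_mean, w1, out=np.zeros_like(between), where=valid)
    between[valid] = (w0[valid] * w1[valid] * (mu0[valid] - mu1[valid]) ** 2)
    # empty bins between modes create exact plateaus of the criterion; take
    # the lowest qualifying threshold (relative tolerance absorbs summation
    # round-off so the tie-break is order-independent)
    best = int(np.flatnonzero(between >= between.max() * (1 - 1e-9))[0])
    return float(edges[best + 1])


def otsu_binarize(channel: np.ndarray, spacing=(1.0, 1.0, 1.0), per_plane: bool = False) -> BinaryMask:
    """Binarize a 3D intensity grid with a global Otsu threshold.

    The threshold is computed once over the whole stack (a per-plane
    variant exists for exploration, but plane-wise thresholds fluctuate
    with depth attenuation).  A zero-variance stack yields an
    all-background mask.
    """
    channel = np.asarray(channel)
    if channel.size == 0:
        raise ValueError("empty intensity grid")
    if channel.ndim != 3:
        raise ValueError("channel must be 3D (z,y,x)")
    if per_plane:
        mask = np.zeros(channel.shape, dtype=bool)
        for z in range(channel.shape[0]):
            t = otsu_threshold(channel[z])
            if t is not None:
                mask[z] = channel[z] > t
        return BinaryMask(mask=mask, spacing=spacing)
    t = otsu_threshold(channel)
    if t is None:
        return BinaryMask(mask=np.zeros(channel.shape, dtype=bool), spacing=spacing)
    return BinaryMask(mask=channel > t, spacing=spacing)


def binarize_probmap(p: ProbabilityMap, cutoff: float = 0.5) -> BinaryMask:
    """Threshold a probability map at ``cutoff`` (inclusive)."""
    if not 0.0 < cutoff < 1.0:
        raise ValueError(f"cutoff must lie in (0, 1), got {cutoff}")
    return BinaryMask(mask=p.probs >= cutoff, spacing=p.spacing)


def resample_plane(plane: np.ndarray, target: tuple[int, int] = PREDICTION_SIZE, mode: str = "intensity") -> np.ndarray:
    """Resample one 2D plane to ``target`` shape.

    ``intensity`` mode uses bilinear interpolation; ``label`` mode uses
    nearest-neighbor (introduces no new values).  A plane already at the
    target shape is returned unchanged.
    """
    if plane.ndim != 2 or plane.size == 0:
        raise ValueError("plane must be a non-empty 2D grid")
    if any(t <= 0 for t in target):
        raise ValueError(f"target size must be positive, got {target}")
    if plane.shape == tuple(target):
        return plane
    if mode == "intensity":
        return resize(plane, target, order=1, preserve_range=True, anti_aliasing=False)
    if mode == "label":
        return resize(plane, target, order=0, preserve_range=True, anti_aliasing=False).astype(plane.dtype)
    raise ValueError(f"unknown resample mode {mode!r}")


def _resample_stack(volume: np.ndarray, target: tuple[int, int], mode: str) -> np.ndarray:
    out = np.empty((volume.shape[0], *target), dtype=volume.dtype if mode == "label" else np.float64)
    for z in range(volume.shape[0]):
        out[z] = resample_plane(volume[z], target, mode)
    return out


def segment_target(
    stack: MultiChannelStack,
    manifest: Manifest,
    *,
    prob_cutoff: float = 0.5,
    resample: bool = False,
    otsu_per_plane: bool = False,
    probmap: np.ndarray | None = None,
    stack_path=None,
) -> BinaryMask:
    """Produce the target channel's foreground mask per the manifest backend.

    ``probmap`` may be passed directly (tests, library use); otherwise it
    is located on disk from the manifest's ``probmap_pattern`` relative
    to ``stack_path``.  With ``resample``, planes are taken to 512×512
    before binarization and the binary result is upsampled back.
    """
    channel = stack.channels[manifest.target_channel]
    orig_yx = channel.shape[1:]

    if manifest.backend == "otsu":
        source = channel
        if resample:
            source = _resample_stack(np.asarray(channel, dtype=np.float64), PREDICTION_SIZE, "intensity")
        mask = otsu_binarize(source, spacing=stack.spacing, per_plane=otsu_per_plane).mask
    elif manifest.backend == "probmap":
        if probmap is None:
            if stack_path is None:
                raise ValueError("probmap backend needs either a probmap array or the stack path")
            probmap = read_probmap(find_companion(stack_path, manifest.probmap_pattern))
        probmap = np.asarray(probmap, dtype=np.float64)
        if probmap.shape != channel.shape:
            raise ValueError(
                f"probability map shape {probmap.shape} does not match stack shape {channel.shape}"
            )
        if resample:
            probmap = np.clip(_resample_stack(probmap, PREDICTION_SIZE, "intensity"), 0.0, 1.0)
        mask = binarize_probmap(ProbabilityMap(probs=probmap, spacing=stack.spacing), prob_cutoff).mask
    else:  # pragma: no cover - manifest validation forbids this
        raise ValueError(f"unknown backend {manifest.backend!r}")

    if resample and mask.shape[1:] != orig_yx:
        mask = _resample_stack(mask.astype(np.uint8), orig_yx, "label").astype(bool)
    return BinaryMask(mask=mask, spacing=stack.spacing)
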