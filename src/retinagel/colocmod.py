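"""Two-channel co-localization statistics and marker surface coverage.

Implements Pearson correlation over all pixels, Manders M1/M2 intensity
coefficients, the co-localized pixel fraction (|both above threshold| /
|either above threshold|), and a spatial block-permutation p-value that
respects autocorrelation by shuffling image blocks rather than pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .io import DegenerateImageError

#: Intensity tolerance applied at threshold comparisons (0.01% of the
#: normalized [0, 1] scale).
DEFAULT_TOLERANCE = 1e-4


@dataclass
class ColocStats:
    pearson_r: float
    m1: float | None
    m2: float | None
    coloc_fraction: float
    p_value: float | None
    threshold_a: float
    threshold_b: float


@dataclass
class CoverageResult:
    marker: str
    colored_px: int
    total_px: int

    @property
    def coverage(self) -> float:
        return 100.0 * self.colored_px / self.total_px


def _block_permute(img: np.ndarray, block: int, rng) -> np.ndarray:
    """Shuffle an image's non-overlapping blocks (padded with edge values)."""
    h, w = img.shape
    ph = (-h) % block
    pw = (-w) % block
    padded = np.pad(img, ((0, ph), (0, pw)), mode="edge")
    bh, bw = padded.shape[0] // block, padded.shape[1] // block
    blocks = padded.reshape(bh, block, bw, block).transpose(0, 2, 1, 3)
    blocks = blocks.reshape(bh * bw, block, block)
    perm = rng.permutation(bh * bw)
    shuffled = blocks[perm].reshape(bh, bw, block, block)
    out = shuffled.transpose(0, 2, 1, 3).reshape(bh * block, bw * block)
    return out[:h, :w]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel()
    b = b.ravel()
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def coloc_stats(ch_a: np.ndarray, ch_b: np.ndarray,
                threshold_mode: str = "otsu",
                thresholds: tuple[float, float] | None = None,
                tolerance: float = DEFAULT_TOLERANCE,
                n_perm: int = 500, block: int = 16,
                seed: int = 0) -> ColocStats:
    """Pearson, Manders M1/M2, co-localized fraction and permutation p.

    Parameters
    ----------
    threshold_mode : "otsu" picks a per-channel Otsu threshold; "fixed"
        uses the ``thresholds`` pair.
    n_perm : permutations for the p-value (blocks of ``block`` px of
        channel b shuffled; p = fraction of permuted Pearson r >= the
        observed one, with the +1 correction).  ``n_perm=0`` skips it.
    """
    a = np.asarray(ch_a, dtype=float)
    b = np.asarray(ch_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channels must share shape")
    if threshold_mode == "otsu":
        if a.max() == a.min() or b.max() == b.min():
            raise DegenerateImageError("constant channel: Otsu undefined")
        ta, tb = float(threshold_otsu(a)), float(threshold_otsu(b))
    elif threshold_mode == "fixed":
        if thresholds is None:
            raise ValueError("fixed mode requires thresholds=(ta, tb)")
        ta, tb = thresholds
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")

    mask_a = a > ta - tolerance
    mask_b = b > tb - tolerance
    r = _pearson(a, b)

    sum_a = a[mask_a].sum()
    sum_b = b[mask_b].sum()
    m1 = float(a[mask_a & mask_b].sum() / sum_a) if mask_a.any() and sum_a > 0 else None
    m2 = float(b[mask_a & mask_b].sum() / sum_b) if mask_b.any() and sum_b > 0 else None

    union = int((mask_a | mask_b).sum())
    coloc_fraction = float((mask_a & mask_b).sum() / union) if union else 0.0

    p_value = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            r_perm = _pearson(a, _block_permute(b, block, rng))
            if r_perm >= r:
                hits += 1
        p_value = (hits + 1) / (n_perm + 1)

    return ColocStats(pearson_r=r, m1=m1, m2=m2,
                      coloc_fraction=coloc_fraction, p_value=p_value,
                      threshold_a=ta, threshold_b=tb)


def surface_coverage(channel: np.ndarray, threshold: float,
                     tolerance: float = DEFAULT_TOLERANCE,
                     marker: str = "marker") -> CoverageResult:
    """Percent of pixels whose intensity exceeds ``threshold - tolerance``."""
    ch = np.asarray(channel, dtype=float)
    colored = int((ch > threshold - tolerance).sum())
    return CoverageResult(marker=marker, colored_px=colored,
                          total_px=int(ch.size))
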