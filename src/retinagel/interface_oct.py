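"""Gel-ILM interface attachment and OCT gel-mass quantification.

Attachment analysis walks the retina's vitreal boundary, resampled at
1 µm steps, and marks a step attached when a gel pixel lies within a
small gap tolerance.  Percentages are reported per consecutive 200 µm
segment and overall; unattached runs are reported as holes, and a
per-position heat map aggregates attachment across slides.

OCT analysis registers B-scan frames (integer translation), averages
them, counts Otsu foreground pixels and subtracts a no-injection
baseline: the surplus is the gel pixel count, normalized to day 0 to
give an in vivo degradation curve comparable with in vitro assays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.registration import phase_cross_correlation

from .degradekit import DegradationSeries
from .io import RetinagelError, logger


@dataclass
class InterfaceTrace:
    """Arc-length-ordered boundary with per-step attachment flags."""

    positions: np.ndarray    # arc length, µm
    attached: np.ndarray     # bool per step
    step: float = 1.0        # µm

    @property
    def length(self) -> float:
        return float(self.positions[-1] - self.positions[0] + self.step)


@dataclass
class AttachmentResult:
    trace: InterfaceTrace
    segment_percents: list          # per full 200 µm segment
    partial_segment_percent: float | None
    overall_percent: float
    holes: list                     # (start µm, length µm)


@dataclass
class AggregateAttachment:
    heatmap: np.ndarray             # per-position fraction of slides attached
    overall_percent: float          # mean of per-slide overall percentages
    per_slide: list


@dataclass
class GelMassSeries:
    day: np.ndarray
    gel_px: np.ndarray
    normalized_mass: np.ndarray

    def to_degradation_series(self) -> DegradationSeries:
        """Remaining-mass series as released fractions (for curve comparison)."""
        return DegradationSeries(
            t=self.day.astype(float),
            released_fraction=np.clip(1.0 - self.normalized_mass, 0, 1.05),
            condition="in_vivo", time_unit="day")


# --------------------------------------------------------------------------
# Interface attachment
# --------------------------------------------------------------------------

def _vitreal_boundary(retina_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Topmost retina pixel per column, ordered by column (row, col)."""
    cols = np.flatnonzero(retina_mask.any(axis=0))
    if cols.size == 0:
        raise RetinagelError("retina mask empty")
    rows = np.argmax(retina_mask[:, cols], axis=0)
    return rows.astype(float), cols.astype(float)


def trace_from_masks(gel_mask: np.ndarray, retina_mask: np.ndarray,
                     pixel_size: float, gap_tolerance_px: float = 2.0,
                     step_um: float = 1.0) -> InterfaceTrace:
    """Build the attachment trace from gel and retina masks."""
    rows, cols = _vitreal_boundary(retina_mask)
    # cumulative arc length along the boundary polyline, in µm
    seglen = np.hypot(np.diff(rows), np.diff(cols)) * pixel_size
    arc = np.concatenate([[0.0], np.cumsum(seglen)])
    n_steps = max(1, int(np.floor(arc[-1] / step_um)) + 1)
    s = np.arange(n_steps) * step_um
    r_interp = np.interp(s, arc, rows)
    c_interp = np.interp(s, arc, cols)
    if gel_mask.any():
        dist = ndimage.distance_transform_edt(~gel_mask.astype(bool))
        ri = np.clip(np.round(r_interp).astype(int), 0, gel_mask.shape[0] - 1)
        ci = np.clip(np.round(c_interp).astype(int), 0, gel_mask.shape[1] - 1)
        attached = dist[ri, ci] <= gap_tolerance_px
    else:
        attached = np.zeros(n_steps, dtype=bool)
    return InterfaceTrace(positions=s, attached=attached, step=step_um)


def analyze_trace(trace: InterfaceTrace,
                  segment_length_um: float = 200.0) -> AttachmentResult:
    """Per-segment / overall attachment percentages and hole list."""
    att = trace.attached
    n = att.size
    steps_per_seg = int(round(segment_length_um / trace.step))
    n_full = n // steps_per_seg
    seg_pcts = [100.0 * att[i * steps_per_seg:(i + 1) * steps_per_seg].mean()
                for i in range(n_full)]
    rem = att[n_full * steps_per_seg:]
    partial = 100.0 * rem.mean() if rem.size else None
    if n_full == 0:
        logger.warning("boundary shorter than one %g µm segment", segment_length_um)
    overall = 100.0 * att.mean()
    holes = []
    i = 0
    while i < n:
        if not att[i]:
            j = i
            while j + 1 < n and not att[j + 1]:
                j += 1
            holes.append((float(trace.positions[i]),
                          float((j - i + 1) * trace.step)))
            i = j + 1
        else:
            i += 1
    return AttachmentResult(trace=trace, segment_percents=seg_pcts,
                            partial_segment_percent=partial,
                            overall_percent=overall, holes=holes)


def measure_attachment(gel_mask: np.ndarray, retina_mask: np.ndarray,
                       pixel_size: float, gap_tolerance_px: float = 2.0,
                       segment_length_um: float = 200.0) -> AttachmentResult:
    """Attachment analysis of one slide from its gel and retina masks."""
    trace = trace_from_masks(gel_mask, retina_mask, pixel_size,
                             gap_tolerance_px)
    return analyze_trace(trace, segment_length_um)


def aggregate_attachment(results) -> AggregateAttachment:
    """Aggregate slides: per-position mean attachment (heat map) and
    the mean of per-slide overall percentages."""
    results = list(results)
    if not results:
        raise ValueError("no slides")
    n_pos = min(r.trace.attached.size for r in results)
    flags = np.stack([r.trace.attached[:n_pos].astype(float) for r in results])
    return AggregateAttachment(heatmap=flags.mean(axis=0),
                               overall_percent=float(np.mean(
                                   [r.overall_percent for r in results])),
                               per_slide=results)


# --------------------------------------------------------------------------
# OCT quantification
# --------------------------------------------------------------------------

def preprocess_oct(frames: np.ndarray,
                   max_shift_fraction: float = 0.25) -> np.ndarray:
    """Register frames to the first (integer translation) and average.

    Breathing-movement artifacts translate frames; phase correlation
    recovers the shift.  Frames requiring a shift above
    ``max_shift_fraction`` of the frame size are dropped with a warning.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        return frames
    ref = frames[0]
    kept = [ref]
    lim = max_shift_fraction * np.array(ref.shape)
    for i, frame in enumerate(frames[1:], start=1):
        shift, _, _ = phase_cross_correlation(ref, frame)
        shift = np.round(shift).astype(int)
        if np.any(np.abs(shift) > lim):
            logger.warning("frame %d dropped: shift %s too large", i, shift)
            continue
        kept.append(np.roll(frame, shift, axis=(0, 1)))
    return np.mean(kept, axis=0)


def quantify_gel(oct_image: np.ndarray, baseline_foreground_px: int) -> int:
    """Surplus Otsu-foreground pixels relative to a no-injection baseline."""
    img = np.asarray(oct_image, dtype=float)
    if img.max() == img.min():
        return 0
    fg = int((img > threshold_otsu(img)).sum())
    return max(0, fg - int(baseline_foreground_px))


def baseline_foreground(control_images) -> int:
    """Mean Otsu-foreground count over control (no-injection) scans."""
    counts = []
    for img in control_images:
        img = np.asarray(img, dtype=float)
        counts.append(int((img > threshold_otsu(img)).sum()))
    return int(round(np.mean(counts)))


def gel_mass_series(day_stacks: dict, baseline_foreground_px: int) -> GelMassSeries:
    """Per-day gel pixel counts normalized to the first (day-0) scan.

    ``day_stacks`` maps integer day -> frame stack.  Missing days simply
    leave gaps; no interpolation is applied.
    """
    days = np.array(sorted(day_stacks), dtype=int)
    if days.size == 0:
        raise ValueError("no days given")
    gel = np.array([quantify_gel(preprocess_oct(day_stacks[d]),
                                 baseline_foreground_px) for d in days])
    if gel[0] == 0:
        raise RetinagelError("day-0 gel pixel count is zero; cannot normalize")
    return GelMassSeries(day=days, gel_px=gel,
                         normalized_mass=gel / float(gel[0]))
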