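"""Synthetic data generators with embedded ground truth.

Every pipeline in this package is exercised against data produced here:
Brownian bead tracks in a medium whose MSD exponent decays through the
sol-gel transition, selective enzymatic degradation curves, live/dead
fluorescence fields, retina cross-sections with annotated layers and
engrafted cells, gel-ILM interface masks with a preset attachment
probability, and OCT B-scan series with decaying gel islands.

Named presets encode the study conditions (gel point 42 s for Gtn-HPA,
151 s / 167 s for IPN75 / IPN50; 75/25 composition for IPN75; 79/59/50%
interface attachment for IPN50/IPN75/Gtn-HPA; 40% of engrafted cells in
the ganglion cell layer and 56% of the 5e4-cell dose engrafted for
IPN50).  Every generator is deterministic given (preset, seed) and
always returns its ground truth alongside the data.

Gelation model
--------------
The paper-level observable is a windowed MSD scaling ``MSD ~ tau**alpha(t)``
with ``alpha`` falling from a liquid-like to a gel-like exponent;
``alpha = 0.5`` is, through the GSER, exactly the G' = G'' crossover.
Tracks are generated as locally-fractional-Gaussian displacement
increments: within short blocks the increments are stationary fractional
Gaussian noise with Hurst exponent ``H = alpha(t)/2``, blocks being
independent.  ``alpha(t) = alpha_gel + (alpha_liquid - alpha_gel) *
logistic((t_gel - t)/transition_width)``; presets use exponent pairs
symmetric about 0.5 so the alpha = 0.5 crossing sits exactly at t_gel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import ndimage

from .degradekit import DegradationSeries
from .engraftmap import LayerMask, RETINAL_LAYERS
from .io import DEFAULT_SEED, PackingError, PresetError
from .rheolab import Track


def _rng(preset_seed: int, seed: int | None):
    return np.random.default_rng(preset_seed if seed is None else seed)


# ==========================================================================
# Gelation tracks
# ==========================================================================

class GelationPreset(BaseModel):
    name: str
    t_gel: float = Field(gt=0, description="s")
    alpha_liquid: float = Field(gt=0.5, le=1.0)
    alpha_gel: float = Field(ge=0.0, lt=0.5)
    transition_width: float = Field(gt=0, description="s")
    msd_amplitude: float = Field(ge=0, description="µm²/s^alpha; 0 freezes beads")
    n_beads: int = Field(ge=1)
    frame_interval: float = Field(gt=0, description="s")
    duration: float = Field(gt=0, description="s")
    bead_radius: float = Field(7.5, gt=0, description="µm")
    temperature: float = Field(310.15, gt=0, description="K")
    localization_sd: float = Field(0.0, ge=0, description="µm")
    seed: int = DEFAULT_SEED

    @model_validator(mode="after")
    def _check(self) -> "GelationPreset":
        if self.duration <= self.t_gel:
            raise ValueError("duration must exceed t_gel")
        if self.duration <= 2 * self.frame_interval:
            raise ValueError("duration must exceed two frame intervals")
        return self

    def alpha_of(self, t) -> np.ndarray:
        """MSD exponent alpha(t) along the gelation."""
        t = np.asarray(t, dtype=float)
        z = (self.t_gel - t) / self.transition_width
        logistic = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
        return self.alpha_gel + (self.alpha_liquid - self.alpha_gel) * logistic

    @property
    def t_alpha_half(self) -> float:
        """Exact time at which alpha(t) crosses 0.5 (the true gel point)."""
        frac = (0.5 - self.alpha_gel) / (self.alpha_liquid - self.alpha_gel)
        return self.t_gel - self.transition_width * math.log(frac / (1 - frac))


GELATION_PRESETS = {
    "gtn_hpa": GelationPreset(name="gtn_hpa", t_gel=42.0, alpha_liquid=0.9,
                              alpha_gel=0.1, transition_width=8.0,
                              msd_amplitude=0.1, n_beads=15,
                              frame_interval=0.1, duration=240.0),
    "ipn75": GelationPreset(name="ipn75", t_gel=151.0, alpha_liquid=0.9,
                            alpha_gel=0.1, transition_width=8.0,
                            msd_amplitude=0.1, n_beads=15,
                            frame_interval=0.1, duration=300.0),
    "ipn50": GelationPreset(name="ipn50", t_gel=167.0, alpha_liquid=0.9,
                            alpha_gel=0.1, transition_width=8.0,
                            msd_amplitude=0.1, n_beads=15,
                            frame_interval=0.1, duration=300.0),
}


@dataclass
class GelationTruth:
    preset: GelationPreset
    alpha_curve: pd.DataFrame        # t, alpha
    t_gel: float
    t_alpha_half: float


def _fgn_cholesky(alpha: float, n: int) -> np.ndarray:
    """Cholesky factor of the unit-variance fGn correlation, H = alpha/2."""
    h2 = alpha                     # 2H
    k = np.arange(n, dtype=float)
    rho = 0.5 * (np.abs(k + 1) ** h2 - 2 * np.abs(k) ** h2
                 + np.abs(k - 1) ** h2)
    idx = np.abs(k[:, None] - k[None, :]).astype(int)
    corr = rho[idx]
    # tiny jitter guards against numerically semidefinite cases
    return np.linalg.cholesky(corr + 1e-12 * np.eye(n))


def simulate_tracks_constant_alpha(alpha: float, msd_amplitude: float,
                                   n_beads: int, frame_interval: float,
                                   duration: float, rng,
                                   localization_sd: float = 0.0):
    """Tracks with a fixed MSD exponent (oracle helper; alpha=1 is Brownian)."""
    n_steps = int(round(duration / frame_interval))
    var = 0.5 * msd_amplitude * frame_interval ** alpha   # per dimension
    if alpha == 1.0:
        inc = rng.normal(0.0, math.sqrt(var), size=(n_beads, n_steps, 2))
    else:
        chol = _fgn_cholesky(alpha, n_steps)
        z = rng.standard_normal((n_steps, n_beads * 2))
        inc = (chol @ z).reshape(n_steps, n_beads, 2).transpose(1, 0, 2)
        inc *= math.sqrt(var)
    return _tracks_from_increments(inc, frame_interval, rng, localization_sd)


def _tracks_from_increments(inc: np.ndarray, frame_interval: float, rng,
                            localization_sd: float):
    n_beads, n_steps, _ = inc.shape
    pos = np.concatenate([np.zeros((n_beads, 1, 2)), np.cumsum(inc, axis=1)],
                         axis=1)
    if localization_sd > 0:
        pos = pos + rng.normal(0.0, localization_sd, size=pos.shape)
    t = np.arange(n_steps + 1) * frame_interval
    return [Track(particle_id=i, t=t, x=pos[i, :, 0], y=pos[i, :, 1])
            for i in range(n_beads)]


def simulate_gelation_tracks(preset: GelationPreset, seed: int | None = None,
                             block_s: float = 4.0):
    """Bead tracks through gelation, plus the ground-truth alpha(t) curve.

    Increments are fractional Gaussian noise with a locally constant
    exponent, sampled block-by-block (``block_s`` seconds per block, the
    exponent evaluated at the block center) with the per-dimension step
    variance ``msd_amplitude/2 * dt**alpha`` so that the windowed 2D MSD
    scales as ``msd_amplitude * tau**alpha(t)``.
    """
    rng = _rng(preset.seed, seed)
    dt = preset.frame_interval
    n_steps = int(round(preset.duration / dt))
    n_block = max(2, int(round(block_s / dt)))

    chol_cache: dict[float, np.ndarray] = {}
    incs = []
    start = 0
    while start < n_steps:
        n = min(n_block, n_steps - start)
        t_center = (start + n / 2.0) * dt
        alpha = float(preset.alpha_of(t_center))
        key = round(alpha, 4)
        if key not in chol_cache or chol_cache[key].shape[0] != n:
            chol_cache = {k: v for k, v in chol_cache.items()
                          if v.shape[0] == n} if n != n_block else chol_cache
            chol_cache[key] = _fgn_cholesky(alpha, n)
        var = 0.5 * preset.msd_amplitude * dt ** alpha
        z = rng.standard_normal((n, preset.n_beads * 2))
        block = (chol_cache[key] @ z) * math.sqrt(var)
        incs.append(block.reshape(n, preset.n_beads, 2))
        start += n
    inc = np.concatenate(incs, axis=0).transpose(1, 0, 2)
    tracks = _tracks_from_increments(inc, dt, rng, preset.localization_sd)
    t_frames = np.arange(n_steps + 1) * dt
    truth = GelationTruth(
        preset=preset,
        alpha_curve=pd.DataFrame({"t": t_frames,
                                  "alpha": preset.alpha_of(t_frames)}),
        t_gel=preset.t_gel, t_alpha_half=preset.t_alpha_half)
    return tracks, truth


# ==========================================================================
# Degradation assays
# ==========================================================================

class DegradationPreset(BaseModel):
    name: str
    f_gtn: float = Field(ge=0, le=1)
    k_coll: float = Field(gt=0, description="1/min (or 1/day for in vivo)")
    k_hyal: float = Field(gt=0)
    noise_sd: float = Field(ge=0)
    sampling_interval: float = Field(gt=0, description="min")
    duration: float = Field(gt=0, description="min")
    time_unit: str = "min"
    seed: int = DEFAULT_SEED

    @property
    def f_ha(self) -> float:
        return 1.0 - self.f_gtn


DEGRADATION_PRESETS = {
    "ipn75": DegradationPreset(name="ipn75", f_gtn=0.75, k_coll=0.08,
                               k_hyal=0.06, noise_sd=0.02,
                               sampling_interval=5.0, duration=60.0),
    "ipn50": DegradationPreset(name="ipn50", f_gtn=0.50, k_coll=0.08,
                               k_hyal=0.06, noise_sd=0.02,
                               sampling_interval=5.0, duration=60.0),
    "ipn25": DegradationPreset(name="ipn25", f_gtn=0.25, k_coll=0.08,
                               k_hyal=0.06, noise_sd=0.02,
                               sampling_interval=5.0, duration=60.0),
    "gtn_hpa": DegradationPreset(name="gtn_hpa", f_gtn=1.0, k_coll=0.08,
                                 k_hyal=0.06, noise_sd=0.02,
                                 sampling_interval=5.0, duration=60.0),
    "ha_tyr": DegradationPreset(name="ha_tyr", f_gtn=0.0, k_coll=0.08,
                                k_hyal=0.06, noise_sd=0.02,
                                sampling_interval=5.0, duration=60.0),
    # slow assay at vitreal enzyme concentrations (0.5 U/ml collagenase,
    # 0.3 U/ml hyaluronidase), both enzymes, sampled daily
    "ipn50_invivo": DegradationPreset(name="ipn50_invivo", f_gtn=0.50,
                                      k_coll=0.45, k_hyal=0.30,
                                      noise_sd=0.02, sampling_interval=1.0,
                                      duration=9.0, time_unit="day"),
}

ENZYME_CONDITIONS = ("collagenase", "hyaluronidase", "both")


def simulate_degradation(preset: DegradationPreset, enzyme: str,
                         seed: int | None = None):
    """Cumulative released-mass series for one enzyme condition.

    Collagenase releases the gelatin fraction, hyaluronidase the
    hyaluronan fraction, both enzymes everything (rate = sum of the
    susceptible-fraction-weighted rates).  Gaussian noise of
    ``noise_sd`` is added and the curve clipped to [0, 1].
    """
    if enzyme not in ENZYME_CONDITIONS:
        raise PresetError(f"unknown enzyme condition {enzyme!r}")
    rng = _rng(preset.seed, seed)
    t = np.arange(preset.sampling_interval, preset.duration + 1e-9,
                  preset.sampling_interval)
    if enzyme == "collagenase":
        f_target, k = preset.f_gtn, preset.k_coll
    elif enzyme == "hyaluronidase":
        f_target, k = preset.f_ha, preset.k_hyal
    else:
        f_target = 1.0
        k = preset.f_gtn * preset.k_coll + preset.f_ha * preset.k_hyal
    clean = f_target * (1.0 - np.exp(-k * t))
    noisy = np.clip(clean + rng.normal(0.0, preset.noise_sd, size=t.shape),
                    0.0, 1.0)
    series = DegradationSeries(t=t, released_fraction=noisy,
                               condition=enzyme if enzyme != "both" else "both",
                               time_unit=preset.time_unit)
    truth = {"f_target": f_target, "k": k, "clean": clean}
    return series, truth


# ==========================================================================
# Live/dead fluorescence fields
# ==========================================================================

class FieldPreset(BaseModel):
    name: str
    image_shape: tuple = (256, 256)
    pixel_size: float = Field(1.0, gt=0, description="µm/px")
    n_live: int = Field(ge=0)
    n_dead: int = Field(ge=0)
    cell_radius_range: tuple = (4.0, 9.0)     # µm
    elongation_fraction: float = Field(0.2, ge=0, le=1)
    snr: float = Field(10.0, gt=0)
    seed: int = DEFAULT_SEED


FIELD_PRESETS = {
    "default": FieldPreset(name="default", n_live=12, n_dead=4),
    "viability70": FieldPreset(name="viability70", n_live=14, n_dead=6),
    "viability80": FieldPreset(name="viability80", n_live=16, n_dead=4),
}


def _paint_ellipse(canvas: np.ndarray, cy: float, cx: float, ry: float,
                   rx: float, angle_deg: float, amplitude: float) -> np.ndarray:
    """Paint a filled rotated ellipse; returns the painted boolean mask."""
    h, w = canvas.shape
    ext = int(math.ceil(max(ry, rx))) + 2
    y0, y1 = max(0, int(cy) - ext), min(h, int(cy) + ext + 1)
    x0, x1 = max(0, int(cx) - ext), min(w, int(cx) + ext + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    th = math.radians(angle_deg)
    dx = xx - cx
    dy = yy - cy
    u = dx * math.cos(th) + dy * math.sin(th)
    v = -dx * math.sin(th) + dy * math.cos(th)
    inside = (u / rx) ** 2 + (v / ry) ** 2 <= 1.0
    mask = np.zeros_like(canvas, dtype=bool)
    mask[y0:y1, x0:x1] = inside
    canvas[mask] = np.maximum(canvas[mask], amplitude)
    return mask


def render_field(preset: FieldPreset, seed: int | None = None):
    """Render one live/dead field; returns (channels, truth table).

    Cells are Gaussian-smoothed discs (or moderately elongated ellipses)
    at the preset SNR over a low, noisy background; non-overlapping
    placement is enforced so counts are segmentation-recoverable.
    """
    rng = _rng(preset.seed, seed)
    h, w = preset.image_shape
    ps = preset.pixel_size
    r_lo, r_hi = preset.cell_radius_range
    r_hi_px = r_hi / ps
    n_total = preset.n_live + preset.n_dead
    if n_total * math.pi * (3 * r_hi_px) ** 2 > 0.9 * h * w:
        raise PackingError("cell count exceeds the field packing bound")
    channels = {"live": np.zeros((h, w)), "dead": np.zeros((h, w))}
    occupied = np.zeros((h, w), dtype=bool)
    margin = int(math.ceil(3 * r_hi_px)) + 2
    rows = []
    classes = ["live"] * preset.n_live + ["dead"] * preset.n_dead
    for i, cls in enumerate(classes):
        r_um = rng.uniform(r_lo, r_hi)
        elongated = rng.random() < preset.elongation_fraction
        rx = r_um / ps * (rng.uniform(1.6, 2.4) if elongated else 1.0)
        ry = r_um / ps
        angle = rng.uniform(-90, 90) if elongated else 0.0
        placed = False
        for _ in range(400):
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            probe = np.zeros((h, w))
            mask = _paint_ellipse(probe, cy, cx, ry + 3, rx + 3, angle, 1.0)
            if not occupied[mask].any():
                placed = True
                break
        if not placed:
            raise PackingError("could not place all cells without contact")
        amp = rng.uniform(0.7, 1.0)
        _paint_ellipse(channels[cls], cy, cx, ry, rx, angle, amp)
        occupied |= mask
        rows.append({"cell": i, "channel": cls, "x": cx * ps, "y": cy * ps,
                     "radius": r_um, "elongated": elongated})
    for name in channels:
        ch = ndimage.gaussian_filter(channels[name], 1.0)
        ch = ch + rng.normal(0.05, 1.0 / preset.snr, size=ch.shape)
        channels[name] = np.clip(ch, 0.0, 1.0)
    truth = pd.DataFrame(rows, columns=["cell", "channel", "x", "y",
                                        "radius", "elongated"])
    return channels, truth


# ==========================================================================
# Retina sections with engrafted cells
# ==========================================================================

class RetinaSectionPreset(BaseModel):
    name: str
    layer_order: tuple = RETINAL_LAYERS
    layer_fractions: dict
    n_cells_per_field: int = Field(ge=1)
    n_fields: int = Field(ge=1)
    size_class_mix: tuple = (0.55, 0.30, 0.15)    # (r<=30, 30-150, >150 µm)
    orientation_sd: float = Field(10.0, ge=0, description="deg")
    coloc_level: float = Field(0.9, ge=0, le=1)
    injected_total: int = 50_000
    engraft_fraction: float = Field(gt=0, le=1)
    image_shape: tuple = (320, 384)
    pixel_size: float = Field(1.5, gt=0)
    snr: float = Field(10.0, gt=0)
    seed: int = DEFAULT_SEED

    @model_validator(mode="after")
    def _check(self) -> "RetinaSectionPreset":
        for layer in self.layer_fractions:
            if layer not in self.layer_order:
                raise ValueError(f"unknown layer name {layer!r}")
        if abs(sum(self.layer_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("layer_fractions must sum to 1")
        if abs(sum(self.size_class_mix) - 1.0) > 1e-9:
            raise ValueError("size_class_mix must sum to 1")
        return self

    @property
    def fields_per_retina_scale(self) -> float:
        """Cells in the analyzed injection region per cell seen in one field."""
        return self.engraft_fraction * self.injected_total / self.n_cells_per_field


RETINA_PRESETS = {
    "ipn50": RetinaSectionPreset(
        name="ipn50", engraft_fraction=0.56, n_cells_per_field=18, n_fields=60,
        layer_fractions={"vitreous": 0.03, "GCL": 0.40, "IPL": 0.12,
                         "INL": 0.42, "ONL": 0.03},
        size_class_mix=(0.55, 0.30, 0.15)),
    "ipn75": RetinaSectionPreset(
        name="ipn75", engraft_fraction=0.53, n_cells_per_field=17, n_fields=60,
        layer_fractions={"vitreous": 0.03, "GCL": 0.40, "IPL": 0.12,
                         "INL": 0.42, "ONL": 0.03},
        size_class_mix=(0.55, 0.30, 0.15)),
    "gtn_hpa": RetinaSectionPreset(
        name="gtn_hpa", engraft_fraction=0.52, n_cells_per_field=17, n_fields=60,
        layer_fractions={"vitreous": 0.03, "GCL": 0.40, "IPL": 0.12,
                         "INL": 0.42, "ONL": 0.03},
        size_class_mix=(0.55, 0.30, 0.15)),
    # saline control: fewer engrafted cells, GCL occupancy set so the
    # per-field GCL cell count is half the IPN50 one, and no
    # long-process cells
    "pbs": RetinaSectionPreset(
        name="pbs", engraft_fraction=0.38, n_cells_per_field=12, n_fields=60,
        layer_fractions={"vitreous": 0.03, "GCL": 0.30, "IPL": 0.12,
                         "INL": 0.515, "ONL": 0.035},
        size_class_mix=(0.85, 0.15, 0.0)),
}

_LAYER_BAND_FRACTIONS = (0.17, 0.20, 0.20, 0.21, 0.22)


@dataclass
class RetinaField:
    channels: dict              # human, reporter
    layer_mask: LayerMask
    truth: pd.DataFrame


def make_layer_mask(shape: tuple, pixel_size: float,
                    layer_order=RETINAL_LAYERS) -> LayerMask:
    """Horizontal-band annotation covering the field (vitreous on top)."""
    h, w = shape
    edges = np.concatenate([[0.0], np.cumsum(_LAYER_BAND_FRACTIONS)]) * h
    labels = np.zeros(shape, dtype=np.int32)
    names = {}
    for i, name in enumerate(layer_order):
        lo, hi = int(round(edges[i])), int(round(edges[i + 1])) if i + 1 < len(edges) else h
        if i == len(layer_order) - 1:
            hi = h
        labels[lo:hi, :] = i + 1
        names[name] = i + 1
    return LayerMask(labels=labels, names=names, pixel_size=pixel_size)


def _band_rows(shape, layer_index) -> tuple[int, int]:
    h = shape[0]
    edges = np.concatenate([[0.0], np.cumsum(_LAYER_BAND_FRACTIONS)]) * h
    lo = int(round(edges[layer_index]))
    hi = int(round(edges[layer_index + 1])) if layer_index + 1 < len(edges) else h
    if layer_index == len(_LAYER_BAND_FRACTIONS) - 1:
        hi = h
    return lo, hi


def render_retina_sections(preset: RetinaSectionPreset, seed: int | None = None,
                           n_fields: int | None = None):
    """Render annotated retina fields with engrafted cells.

    Per cell: layer drawn from ``layer_fractions``, size class from
    ``size_class_mix`` (round cells are discs, medium/long are elongated
    bars lying along the layer with orientation ~ N(0, orientation_sd),
    clamped so the cell stays inside its band), and a ``coloc_level``
    fraction of its pixels shared between the human-marker and reporter
    channels.  Returns ``(fields, truth)`` where truth pools all per-cell
    tables and records the extrapolation scale.
    """
    rng = _rng(preset.seed, seed)
    n_fields = preset.n_fields if n_fields is None else n_fields
    h, w = preset.image_shape
    ps = preset.pixel_size
    layer_names = list(preset.layer_order)
    layer_probs = np.array([preset.layer_fractions.get(n, 0.0)
                            for n in layer_names])
    margin = 7   # keep whole cells clear of the deleted 5 px border
    fields = []
    for fi in range(n_fields):
        human = np.zeros((h, w))
        reporter = np.zeros((h, w))
        occupied = np.zeros((h, w), dtype=bool)
        rows = []
        for ci in range(preset.n_cells_per_field):
            li = int(rng.choice(len(layer_names), p=layer_probs))
            sc = int(rng.choice(3, p=np.array(preset.size_class_mix)))
            band_lo, band_hi = _band_rows((h, w), li)
            band_h_um = (band_hi - band_lo) * ps
            if sc == 0:
                feret = rng.uniform(10.0, 20.0)
                length_um, width_um = feret, feret
                theta = float("nan")
            else:
                length_um = rng.uniform(40.0, 120.0) if sc == 1 else \
                    rng.uniform(160.0, min(220.0, (w - 2 * margin - 4) * ps))
                width_um = rng.uniform(8.0, 14.0)
                theta = rng.normal(0.0, preset.orientation_sd)
                v_half_max = band_h_um / 2.0 - width_um / 2.0 - 3.0 * ps
                s_max = min(1.0, max(0.05, v_half_max / (length_um / 2.0)))
                t_max = math.degrees(math.asin(s_max))
                theta = float(np.clip(theta, -t_max, t_max))
            rx = length_um / 2.0 / ps
            ry = width_um / 2.0 / ps
            v_ext = abs(rx * math.sin(math.radians(theta if sc else 0.0))) + ry
            placed_mask = None
            for attempt in range(200):
                row_lo = band_lo + v_ext + 1
                row_hi = band_hi - v_ext - 1
                if row_hi <= row_lo:
                    cy = (band_lo + band_hi) / 2.0
                else:
                    cy = rng.uniform(row_lo, row_hi)
                cy = float(np.clip(cy, margin + v_ext, h - margin - v_ext))
                x_ext = abs(rx * math.cos(math.radians(theta if sc else 0.0))) + ry
                cx = rng.uniform(margin + x_ext, w - margin - x_ext)
                probe = np.zeros((h, w))
                # screen angle convention: image y axis points down; a 5 px
                # guard ring keeps neighbours unmergeable by closing + blur
                pm = _paint_ellipse(probe, cy, cx, ry + 5, rx + 5,
                                    -(theta if sc else 0.0), 1.0)
                if not occupied[pm].any() or attempt == 199:
                    placed_mask = _paint_ellipse(probe * 0, cy, cx, ry, rx,
                                                 -(theta if sc else 0.0), 1.0)
                    occupied |= pm
                    break
            amp = rng.uniform(0.6, 1.0)
            ys, xs = np.nonzero(placed_mask)
            n_px = ys.size
            n_co = int(round(preset.coloc_level * n_px))
            perm = rng.permutation(n_px)
            co = perm[:n_co]
            rest = perm[n_co:]
            half = rest.size // 2
            human_idx = np.concatenate([co, rest[:half]])
            rep_idx = np.concatenate([co, rest[half:]])
            human[ys[human_idx], xs[human_idx]] = np.maximum(
                human[ys[human_idx], xs[human_idx]], amp)
            reporter[ys[rep_idx], xs[rep_idx]] = np.maximum(
                reporter[ys[rep_idx], xs[rep_idx]], amp)
            rows.append({"field": fi, "cell": ci, "layer": layer_names[li],
                         "size_class": ("round", "medium", "long")[sc],
                         "r_true": length_um, "theta_true": theta,
                         "x": cx * ps, "y": cy * ps,
                         "coloc_level": preset.coloc_level})
        # dim artifacts that the high-threshold fusion filter must reject
        for _ in range(2):
            _paint_ellipse(human, rng.uniform(20, h - 20),
                           rng.uniform(20, w - 20), 4, 4, 0.0, 0.15)
        human = np.clip(ndimage.gaussian_filter(human, 1.0)
                        + rng.normal(0.03, 1.0 / preset.snr, size=(h, w)), 0, 1)
        reporter = np.clip(ndimage.gaussian_filter(reporter, 1.0)
                           + rng.normal(0.03, 1.0 / preset.snr, size=(h, w)), 0, 1)
        fields.append(RetinaField(
            channels={"human": human, "reporter": reporter},
            layer_mask=make_layer_mask((h, w), ps, preset.layer_order),
            truth=pd.DataFrame(rows)))
    truth = {
        "cells": pd.concat([f.truth for f in fields], ignore_index=True),
        "fields_per_retina_scale": preset.fields_per_retina_scale,
        "injected_total": preset.injected_total,
        "engraft_fraction": preset.engraft_fraction,
    }
    return fields, truth


# ==========================================================================
# Gel-ILM interface slides
# ==========================================================================

class InterfacePreset(BaseModel):
    name: str
    boundary_length: float = Field(ge=200.0, description="µm")
    attach_prob: float = Field(ge=0, le=1)
    hole_length_scale: float = Field(gt=0, description="µm")
    n_slides: int = Field(ge=1)
    pixel_size: float = Field(1.0, gt=0)
    seed: int = DEFAULT_SEED


INTERFACE_PRESETS = {
    "ipn50": InterfacePreset(name="ipn50", boundary_length=600.0,
                             attach_prob=0.79, hole_length_scale=30.0,
                             n_slides=10),
    "ipn75": InterfacePreset(name="ipn75", boundary_length=600.0,
                             attach_prob=0.59, hole_length_scale=30.0,
                             n_slides=10),
    "gtn_hpa": InterfacePreset(name="gtn_hpa", boundary_length=600.0,
                               attach_prob=0.50, hole_length_scale=30.0,
                               n_slides=10),
}


@dataclass
class InterfaceSlide:
    gel_mask: np.ndarray
    retina_mask: np.ndarray
    flags: np.ndarray           # truth attachment per 1 µm boundary step


def _attachment_flags(n_um: int, p: float, hole_scale: float, rng) -> np.ndarray:
    """Correlated binary attachment process (alternating exponential runs)."""
    if p >= 1.0:
        return np.ones(n_um, dtype=bool)
    if p <= 0.0:
        return np.zeros(n_um, dtype=bool)
    att_scale = hole_scale * p / (1.0 - p)
    flags = np.empty(n_um, dtype=bool)
    pos = 0
    state = rng.random() < p
    while pos < n_um:
        scale = att_scale if state else hole_scale
        run = max(1, int(round(rng.exponential(scale))))
        flags[pos:pos + run] = state
        pos += run
        state = not state
    return flags


def render_interface(preset: InterfacePreset, seed: int | None = None):
    """Synthetic gel/retina mask pairs with known attachment flags.

    The vitreal boundary is a gently curved line; gel pixels touch it
    exactly where the flags are true, and detached gel blobs float well
    above the gap tolerance inside some holes.
    """
    rng = _rng(preset.seed, seed)
    ps = preset.pixel_size
    width = int(round(preset.boundary_length / ps))
    height = 80
    slides = []
    for _ in range(preset.n_slides):
        flags = _attachment_flags(width, preset.attach_prob,
                                  preset.hole_length_scale / ps, rng)
        phase = rng.uniform(0, 2 * math.pi)
        x = np.arange(width)
        boundary = (45 + 6 * np.sin(2 * math.pi * x / width * 2 + phase))
        boundary = np.round(boundary).astype(int)
        retina = np.zeros((height, width), dtype=bool)
        gel = np.zeros((height, width), dtype=bool)
        for c in range(width):
            retina[boundary[c]:, c] = True
            if flags[c]:
                gel[boundary[c] - 3:boundary[c], c] = True
        # detached gel inside some holes, beyond the gap tolerance
        in_hole = ~flags
        starts = np.flatnonzero(in_hole & ~np.roll(in_hole, 1))
        for s in starts:
            e = s
            while e + 1 < width and in_hole[e + 1]:
                e += 1
            if e - s > 8 and rng.random() < 0.5:
                mid = (s + e) // 2
                top = boundary[mid] - 12
                gel[max(0, top):max(0, top + 3), s + 2:e - 1] = True
        slides.append(InterfaceSlide(gel_mask=gel, retina_mask=retina,
                                     flags=flags))
    truth = {"attach_prob": preset.attach_prob,
             "mean_flag": float(np.mean([s.flags.mean() for s in slides]))}
    return slides, truth


# ==========================================================================
# OCT series
# ==========================================================================

class OCTPreset(BaseModel):
    name: str
    image_shape: tuple = (160, 300)
    retina_foreground_px: int = Field(ge=0)
    gel_px_day0: int = Field(ge=0)
    decay_rate: float = Field(ge=0, description="1/day, inverse exponential")
    n_days: int = Field(ge=1)
    speckle_sd: float = Field(0.05, ge=0)
    n_frames: int = Field(4, ge=1)
    seed: int = DEFAULT_SEED


OCT_PRESETS = {
    "ipn50": OCTPreset(name="ipn50", retina_foreground_px=9000,
                       gel_px_day0=3000, decay_rate=0.35, n_days=10),
    "halflife_demo": OCTPreset(name="halflife_demo", retina_foreground_px=9000,
                               gel_px_day0=3000, decay_rate=math.log(2),
                               n_days=4),
    "control": OCTPreset(name="control", retina_foreground_px=9000,
                         gel_px_day0=0, decay_rate=0.0, n_days=3),
}


def render_oct_series(preset: OCTPreset, seed: int | None = None):
    """Per-day OCT frame stacks plus ground-truth gel pixel counts.

    Each day shares a fixed bright curved retina band
    (``retina_foreground_px`` above-threshold pixels); gel islands on
    top of it total ``gel_px_day0 * exp(-decay_rate * day)`` pixels.
    Frames carry multiplicative speckle and random small integer
    translations to exercise the registration step.
    """
    rng = _rng(preset.seed, seed)
    h, w = preset.image_shape
    thickness = max(1, int(round(preset.retina_foreground_px / w)))
    phase = rng.uniform(0, 2 * math.pi)
    x = np.arange(w)
    top = np.round(70 + 15 * np.sin(2 * math.pi * x / w + phase)).astype(int)
    retina = np.zeros((h, w), dtype=bool)
    for c in range(w):
        retina[top[c]:top[c] + thickness, c] = True
    days = np.arange(preset.n_days)
    stacks = {}
    gel_counts = []
    for day in days:
        target = int(round(preset.gel_px_day0 * math.exp(-preset.decay_rate * day)))
        gel = np.zeros((h, w), dtype=bool)
        guard = 0
        while gel.sum() < target and guard < 200:
            guard += 1
            c = int(rng.uniform(20, w - 20))
            ry = rng.uniform(4, 9)
            rx = rng.uniform(6, 14)
            cy = top[c] - ry - rng.uniform(1, 6)
            probe = np.zeros((h, w))
            m = _paint_ellipse(probe, cy, c, ry, rx, 0.0, 1.0)
            gel |= m & ~retina
        excess = int(gel.sum()) - target
        if excess > 0:
            ys, xs = np.nonzero(gel)
            drop = rng.choice(ys.size, size=excess, replace=False)
            gel[ys[drop], xs[drop]] = False
        base = np.full((h, w), 0.05)
        base[retina] = 0.8
        base[gel] = 0.65
        frames = []
        for _ in range(preset.n_frames):
            fr = base * (1.0 + rng.normal(0.0, preset.speckle_sd, size=(h, w)))
            dy, dx = rng.integers(-4, 5, size=2)
            frames.append(np.roll(np.roll(fr, dy, axis=0), dx, axis=1))
        stacks[int(day)] = np.stack(frames)
        gel_counts.append(int(gel.sum()))
    truth = pd.DataFrame({"day": days, "gel_px": gel_counts,
                          "normalized_mass": (np.array(gel_counts)
                                              / max(gel_counts[0], 1))})
    truth.attrs["retina_foreground_px"] = int(retina.sum())
    return stacks, truth
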