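"""In vivo engraftment quantification in retinal sections.

Detects injected cells with a dual-threshold "fusion" segmentation
(low threshold ~10% of normalized intensity for recall, high threshold
~0.3 for precision; low-threshold components that contain no
high-threshold pixel are discarded; a 5 px image border is deleted),
assigns each cell to its annotated retinal layer, measures extent
(max Feret diameter) and orientation relative to the layer's long axis,
bins cells into size classes (round r <= 30 µm, medium 30-150 µm, long
> 150 µm), and extrapolates the engrafted percentage of the injected
cell dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label as sk_label, regionprops
from skimage.morphology import closing as morph_closing, disk, opening as morph_opening

from .io import RunConfig, DEFAULT_CONFIG, logger
from .viamap import LabeledImage

#: Cells injected per eye (5e4 cells in 3 µL).
DEFAULT_INJECTED_TOTAL = 50_000

RETINAL_LAYERS = ("vitreous", "GCL", "IPL", "INL", "ONL")

SIZE_CLASS_BOUNDS_UM = (30.0, 150.0)   # r <= 30 round, <= 150 medium, else long


@dataclass
class LayerMask:
    """Named integer annotation of retinal layers over a field.

    ``labels`` maps every annotated pixel to exactly one layer id from
    ``names`` (0 = unannotated background).  Per-layer orientation is
    the major-axis angle of the layer's moments-equivalent ellipse.
    """

    labels: np.ndarray
    names: dict            # name -> integer id
    pixel_size: float = 1.0
    _angles: dict = field(default_factory=dict, repr=False)

    def id_of(self, name: str) -> int:
        if name not in self.names:
            raise KeyError(f"unknown layer {name!r}")
        return self.names[name]

    def name_of(self, layer_id: int) -> str:
        for name, lid in self.names.items():
            if lid == layer_id:
                return name
        raise KeyError(layer_id)

    def layer_angle(self, name: str) -> float:
        """Major-axis angle (degrees, x-axis reference) of a layer."""
        if name not in self._angles:
            mask = self.labels == self.id_of(name)
            if not mask.any():
                raise ValueError(f"layer {name!r} empty")
            self._angles[name] = _principal_angle(mask)
        return self._angles[name]


@dataclass
class EngraftedCell:
    label: int
    area: float            # µm²
    r: float               # max Feret diameter, µm
    r_ellipse: float       # ellipse major-axis length, µm
    theta: float           # degrees in [-90, 90], relative to layer
    layer: str
    size_class: str
    coloc_pass: bool = True
    reliable: bool = True


@dataclass
class EngraftmentSummary:
    per_layer_percent: dict
    percent_engrafted_of_injected: float
    polar: pd.DataFrame          # columns: r, theta, size_class, layer
    n_fields: int
    total_cells: int
    mean_cells_per_field: float
    layer_counts: dict


# --------------------------------------------------------------------------
# Fusion segmentation
# --------------------------------------------------------------------------

def fusion_segment(image: np.ndarray, config: RunConfig = DEFAULT_CONFIG,
                   pixel_size: float | None = None) -> LabeledImage:
    """Dual-threshold fusion segmentation of one fluorescence channel.

    Normalizes intensities to [0, 1], applies a Gaussian blur
    (sigma = 1 px), thresholds at ``config.low_threshold`` (recall mask),
    closes then opens with a 2 px disc, labels 8-connected components,
    and keeps only components containing at least one pixel above
    ``config.high_threshold`` (precision filter).  Finally all pixels
    within ``config.border_px`` of the image border are deleted and
    emptied labels dropped.  A constant image yields an empty labeling,
    not an error.
    """
    im = np.asarray(image, dtype=float)
    if im.ndim != 2:
        raise ValueError("fusion_segment expects a 2D array")
    ps = pixel_size if pixel_size is not None else config.pixel_size
    rng_span = im.max() - im.min()
    if rng_span == 0:
        return LabeledImage(channels={"raw": im},
                            labels=np.zeros(im.shape, dtype=np.int32),
                            pixel_size=ps)
    norm = (im - im.min()) / rng_span
    if config.blur_sigma_px > 0:
        norm = ndimage.gaussian_filter(norm, config.blur_sigma_px)
    low = norm > config.low_threshold
    low = morph_closing(low, disk(config.closing_radius_px))
    low = morph_opening(low, disk(config.opening_radius_px))
    labels = sk_label(low, connectivity=2)
    high = norm > config.high_threshold
    keep = np.unique(labels[high])
    keep = keep[keep > 0]
    labels[~np.isin(labels, keep)] = 0
    b = config.border_px
    if b > 0:
        labels[:b, :] = 0
        labels[-b:, :] = 0
        labels[:, :b] = 0
        labels[:, -b:] = 0
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(np.unique(labels[labels > 0]), start=1):
        out[labels == old] = new
    return LabeledImage(channels={"raw": im}, labels=out, pixel_size=ps)


# --------------------------------------------------------------------------
# Orientation, extent and layer assignment
# --------------------------------------------------------------------------

def _principal_angle(mask: np.ndarray) -> float:
    """Major-axis angle of a pixel set, degrees CCW from the +x axis,
    in image coordinates (y down); result in (-90, 90]."""
    ys, xs = np.nonzero(mask)
    x = xs - xs.mean()
    y = ys - ys.mean()
    mu20 = np.mean(x * x)
    mu02 = np.mean(y * y)
    mu11 = np.mean(x * y)
    # y axis points down; negate to get the usual CCW angle convention
    ang = 0.5 * math.degrees(math.atan2(2.0 * -mu11, mu20 - mu02))
    return _wrap_angle(ang)


def _wrap_angle(deg: float) -> float:
    """Wrap an axial angle to (-90, 90]."""
    wrapped = (deg + 90.0) % 180.0 - 90.0
    return 90.0 if wrapped == -90.0 else wrapped


def size_class_of(r_um: float) -> str:
    lo, hi = SIZE_CLASS_BOUNDS_UM
    if r_um <= lo:
        return "round"
    if r_um <= hi:
        return "medium"
    return "long"


def fit_orientation(cell_mask: np.ndarray, layers: LayerMask,
                    layer_name: str) -> tuple[float, float, float, bool]:
    """Cell extent and orientation relative to its layer.

    Returns ``(r_um, r_ellipse_um, theta_deg, reliable)``.  The cell
    angle is the major-axis angle of the moments-equivalent ellipse of
    its pixel set; theta is the axial difference to the layer angle,
    wrapped to [-90, 90].  ``r`` is the max Feret diameter in µm.
    """
    n_px = int(cell_mask.sum())
    if n_px == 0:
        raise ValueError("empty cell mask")
    reliable = n_px >= 5
    region = regionprops(cell_mask.astype(np.uint8))[0]
    ps = layers.pixel_size
    r_um = float(region.feret_diameter_max * ps)
    r_ellipse = float(region.axis_major_length * ps)
    cell_angle = _principal_angle(cell_mask)
    theta = _wrap_angle(cell_angle - layers.layer_angle(layer_name))
    return r_um, r_ellipse, theta, reliable


def assign_layer(cell_mask: np.ndarray, layers: LayerMask) -> str:
    """Layer with maximum pixel overlap; ties go to the centroid's layer.

    A cell overlapping no annotated layer is assigned "vitreous" when
    that layer exists, else "background".
    """
    ids = layers.labels[cell_mask]
    ids = ids[ids > 0]
    fallback = "vitreous" if "vitreous" in layers.names else "background"
    if ids.size == 0:
        return fallback
    counts = np.bincount(ids)
    best = counts.max()
    winners = np.flatnonzero(counts == best)
    if len(winners) > 1:
        ys, xs = np.nonzero(cell_mask)
        cy, cx = int(round(ys.mean())), int(round(xs.mean()))
        centroid_id = layers.labels[cy, cx]
        if centroid_id in winners:
            return layers.name_of(int(centroid_id))
    return layers.name_of(int(winners[0]))


def analyze_field(image: np.ndarray, layers: LayerMask,
                  config: RunConfig = DEFAULT_CONFIG,
                  reporter: np.ndarray | None = None,
                  coloc_threshold: float = 0.2,
                  coloc_min_fraction: float = 0.7) -> pd.DataFrame:
    """Segment one field and measure every detected cell.

    When a ``reporter`` channel is given, each cell additionally gets a
    ``coloc_pass`` flag: the fraction of its pixels above
    ``coloc_threshold`` in both channels, over those above it in either,
    must reach ``coloc_min_fraction``.
    """
    labeled = fusion_segment(image, config, pixel_size=layers.pixel_size)
    rows = []
    for region in regionprops(labeled.labels):
        mask = np.zeros(labeled.labels.shape, dtype=bool)
        mask[region.slice] = region.image
        layer = assign_layer(mask, layers)
        if layer in layers.names:
            r_um, r_ell, theta, reliable = fit_orientation(mask, layers, layer)
        else:
            r_um = r_ell = theta = float("nan")
            reliable = False
        coloc_pass = True
        if reporter is not None:
            a = image[mask] > coloc_threshold
            b = reporter[mask] > coloc_threshold
            union = (a | b).sum()
            coloc_pass = bool(union and (a & b).sum() / union
                              >= coloc_min_fraction)
        rows.append({"label": region.label,
                     "area": region.area * layers.pixel_size ** 2,
                     "r": r_um, "r_ellipse": r_ell, "theta": theta,
                     "layer": layer, "size_class": size_class_of(r_um)
                     if np.isfinite(r_um) else "round",
                     "coloc_pass": coloc_pass, "reliable": reliable})
    return pd.DataFrame(rows, columns=["label", "area", "r", "r_ellipse",
                                       "theta", "layer", "size_class",
                                       "coloc_pass", "reliable"])


def summarize_engraftment(field_tables, injected_total: int = DEFAULT_INJECTED_TOTAL,
                          fields_per_retina_scale: float = 1.0) -> EngraftmentSummary:
    """Aggregate per-field cell tables into the engraftment summary.

    Per-layer percentages are over all assigned cells.  The engrafted
    percentage extrapolates the mean per-field count to the analyzed
    injection region via ``fields_per_retina_scale`` (how many cells the
    whole region holds per cell seen in one field) and divides by the
    injected dose.
    """
    tables = [t for t in field_tables]
    n_fields = len(tables)
    if n_fields == 0:
        raise ValueError("need at least one field")
    all_cells = (pd.concat(tables, ignore_index=True) if any(len(t) for t in tables)
                 else pd.DataFrame(columns=["layer", "r", "theta", "size_class"]))
    total = len(all_cells)
    if total == 0:
        logger.warning("zero cells across all fields")
        return EngraftmentSummary(per_layer_percent={}, percent_engrafted_of_injected=0.0,
                                  polar=all_cells, n_fields=n_fields, total_cells=0,
                                  mean_cells_per_field=0.0, layer_counts={})
    layer_counts = all_cells["layer"].value_counts().to_dict()
    per_layer = {k: 100.0 * v / total for k, v in layer_counts.items()}
    mean_per_field = total / n_fields
    percent = 100.0 * mean_per_field * fields_per_retina_scale / injected_total
    polar = all_cells[["r", "theta", "size_class", "layer"]].copy()
    return EngraftmentSummary(per_layer_percent=per_layer,
                              percent_engrafted_of_injected=percent,
                              polar=polar, n_fields=n_fields, total_cells=total,
                              mean_cells_per_field=mean_per_field,
                              layer_counts=layer_counts)
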