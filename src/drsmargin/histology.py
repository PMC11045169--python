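"""Ground-truth quantification from (synthetic) stained sections.

Mirrors the histopathology workflow that produces the labels the
classifier is trained against: a band up to 2 mm deep under the black ink
mark on the resection surface is delineated; the tumor area percentage
inside the band comes from the annotation mask; the remaining healthy
tissue is split into fat and connective tissue by a green-channel
intensity threshold; and for malignant locations the minimum, central and
maximum perpendicular ink-to-tumor distances are measured.  A location is
labeled malignant iff *any* tumor tissue lies within the band.

All geometry is 2-D (area fractions of the section); distances are
converted to millimetres through the pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt

from .simulate import LABEL_CODES, GroundTruth, SectionImage

__all__ = [
    "BandRegion",
    "band_region",
    "tissue_percentages",
    "margin_distances",
    "label_location",
    "quantify_section",
    "DEFAULT_GREEN_THRESHOLD",
]

# Calibrated once against the synthetic renderer's palette: fat is rendered
# with green > 200, connective and tumor below.
DEFAULT_GREEN_THRESHOLD = 200


@dataclass(frozen=True)
class BandRegion:
    """Pixels within ``depth_mm`` of the ink polyline, on the tissue side."""

    mask: np.ndarray  # (H, W) bool
    depth_mm: float

    def __post_init__(self) -> None:
        if self.depth_mm < 0:
            raise ValueError("depth must be >= 0")


def _polyline_raster(section: SectionImage) -> np.ndarray:
    """Rasterize the ink polyline onto the image grid."""
    h, w = section.label_mask.shape
    ink = np.zeros((h, w), dtype=bool)
    pts = section.ink_polyline
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        steps = int(max(abs(r1 - r0), abs(c1 - c0))) + 1
        rr = np.round(np.linspace(r0, r1, steps)).astype(int)
        cc = np.round(np.linspace(c0, c1, steps)).astype(int)
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        ink[rr[ok], cc[ok]] = True
    if not ink.any():
        raise ValueError("ink polyline lies outside the image")
    return ink


def _distance_to_ink_px(section: SectionImage) -> np.ndarray:
    ink = _polyline_raster(section)
    return distance_transform_edt(~ink)


def band_region(section: SectionImage, depth_mm: float = 2.0) -> BandRegion:
    """Band of pixels within ``depth_mm`` of the ink, on the tissue side.

    The tissue side of the ink line is the half-plane (relative to the
    chord from the polyline's first to last point) holding the majority of
    non-background pixels.
    """
    dist_px = _distance_to_ink_px(section)
    depth_px = depth_mm * 1000.0 / section.pixel_size_um
    near = dist_px > 0 if depth_mm == 0 else dist_px <= depth_px
    if depth_mm == 0:
        return BandRegion(mask=np.zeros_like(near, dtype=bool), depth_mm=depth_mm)

    h, w = section.label_mask.shape
    rows, cols = np.mgrid[0:h, 0:w]
    (r0, c0), (r1, c1) = section.ink_polyline[0], section.ink_polyline[-1]
    # signed side of the first-to-last chord
    side = (c1 - c0) * (rows - r0) - (r1 - r0) * (cols - c0)
    tissue = section.label_mask != LABEL_CODES["background"]
    if not tissue.any():
        raise ValueError("section contains no tissue")
    pos = int(np.sum(tissue & (side > 0)))
    neg = int(np.sum(tissue & (side < 0)))
    tissue_side = side > 0 if pos >= neg else side < 0
    mask = near & tissue_side
    if not mask.any():
        raise ValueError("band region is empty (ink not adjacent to tissue)")
    return BandRegion(mask=mask, depth_mm=depth_mm)


def tissue_percentages(
    section: SectionImage,
    region: BandRegion,
    green_threshold: int = DEFAULT_GREEN_THRESHOLD,
) -> tuple[float, float, float]:
    """(tumor_pct, fat_pct, connective_pct) over the band's tissue pixels.

    Tumor comes from the annotation mask; the remaining non-background
    pixels are split by the green channel (above threshold = fat).
    """
    if not region.mask.any():
        raise ValueError("empty band region")
    in_band = region.mask
    labels = section.label_mask[in_band]
    tissue = labels != LABEL_CODES["background"]
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        raise ValueError("band region contains only background")
    tumor = labels == LABEL_CODES["tumor"]
    green = section.rgb[in_band][:, 1]
    healthy = tissue & ~tumor
    fat = healthy & (green > green_threshold)
    connective = healthy & ~fat
    tumor_pct = 100.0 * tumor.sum() / n_tissue
    fat_pct = 100.0 * fat.sum() / n_tissue
    connective_pct = 100.0 - tumor_pct - fat_pct
    return float(tumor_pct), float(fat_pct), float(connective_pct)


def margin_distances(
    section: SectionImage, region: BandRegion
) -> tuple[float, float, float, float] | None:
    """(min, central, max, mean) perpendicular ink-to-tumor distances in mm.

    Per polyline sample point, the distance to the nearest tumor pixel in
    the band; min/max over sample points (max capped at the band depth),
    central at the arc-length midpoint, mean = (min + central + max) / 3.
    Returns None when no tumor lies in the band (healthy location).
    """
    tumor_mask = (section.label_mask == LABEL_CODES["tumor"]) & region.mask
    if not tumor_mask.any():
        return None
    dist_to_tumor_px = distance_transform_edt(~tumor_mask)
    mm_per_px = section.pixel_size_um / 1000.0

    pts = section.ink_polyline
    seg = np.sqrt(np.sum(np.diff(pts, axis=0) ** 2, axis=1))
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    n_samples = max(64, int(arc[-1]) + 1)
    s = np.linspace(0.0, arc[-1], n_samples)
    rr = np.interp(s, arc, pts[:, 0])
    cc = np.interp(s, arc, pts[:, 1])
    h, w = section.label_mask.shape
    ri = np.clip(np.round(rr).astype(int), 0, h - 1)
    ci = np.clip(np.round(cc).astype(int), 0, w - 1)
    d = dist_to_tumor_px[ri, ci] * mm_per_px

    d_min = float(d.min())
    d_max = float(min(d.max(), region.depth_mm))
    d_central = float(d[n_samples // 2])
    d_mean = (d_min + d_central + d_max) / 3.0
    return d_min, d_central, d_max, d_mean


def label_location(tumor_pct: float) -> str:
    """Malignant iff any tumor tissue is present in the band."""
    if not (0.0 <= tumor_pct <= 100.0):
        raise ValueError("tumor_pct must lie in [0, 100]")
    return "malignant" if tumor_pct > 0 else "healthy"


def quantify_section(
    section: SectionImage,
    location_id: str = "",
    depth_mm: float = 2.0,
    green_threshold: int = DEFAULT_GREEN_THRESHOLD,
) -> GroundTruth:
    """Full quantification of one section into a GroundTruth record."""
    region = band_region(section, depth_mm)
    tumor_pct, fat_pct, connective_pct = tissue_percentages(section, region, green_threshold)
    label = label_location(tumor_pct)
    distances = margin_distances(section, region) if tumor_pct > 0 else None
    kwargs = {}
    if distances is not None:
        d_min, d_central, d_max, d_mean = distances
        kwargs = {
            "margin_distance_min": d_min,
            "margin_distance_central": d_central,
            "margin_distance_max": d_max,
            "margin_distance_mean": d_mean,
        }
    return GroundTruth(
        location_id=location_id,
        tumor_pct=tumor_pct,
        fat_pct=fat_pct,
        connective_pct=connective_pct,
        label=label,
        **kwargs,
    )
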