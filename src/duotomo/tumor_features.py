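"""Tumor/boundary/reference zones and the diagnostic image features.

Zones follow the dual-modal reading convention: the tumor zone is the
hypoechoic core of the mass, the boundary zone is the surrounding echogenic
halo (a dilation band of configurable width, default 3 mm), and the reference
zone is breast tissue spanning the tumor's depth band but more than 5 mm away
from the outer edge of the boundary, so that amplitude statistics can be
normalised against healthy tissue at comparable optical fluence.

Eleven features are extracted per mass: four skeleton-derived vascular
count/density features and four photoacoustic amplitude features (mean and
90th-percentile tumor amplitude relative to the reference zone, and the SD of
amplitude over vessel pixels in the tumor and boundary zones), plus three
anatomical ultrasound features (form factor, axis ratio, intratumoral echo
SD).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import UndefinedFeatureError, ZoneConstructionError
from .geometry import ImagingGrid
from .pact_recon import ReconImage
from .vessel_postproc import VesselSkeleton, _trace_segments

__all__ = [
    "ZoneMasks",
    "FeatureVector",
    "PACT_FEATURES",
    "URCT_FEATURES",
    "ALL_FEATURES",
    "define_zones",
    "extract_features",
    "form_factor",
    "axis_ratio",
    "angiogenesis_occurrence",
    "vascular_distance_metric",
    "exclude_superficial",
]

PACT_FEATURES = (
    "v_count_tumor",
    "v_count_boundary",
    "v_density_tumor",
    "v_density_boundary",
    "amp_mean_tumor_rel",
    "amp_p90_tumor_rel",
    "amp_hetero_sd_tumor",
    "amp_hetero_sd_boundary",
)
URCT_FEATURES = ("form_factor", "axis_ratio", "echo_sd_tumor")
ALL_FEATURES = PACT_FEATURES + URCT_FEATURES


@dataclass
class ZoneMasks:
    tumor: np.ndarray
    boundary: np.ndarray
    reference: np.ndarray
    breast: np.ndarray
    skin_depth_mm: np.ndarray
    grid: ImagingGrid


@dataclass
class FeatureVector:
    mass_id: str
    label: str
    v_count_tumor: float
    v_count_boundary: float
    v_density_tumor: float
    v_density_boundary: float
    amp_mean_tumor_rel: float
    amp_p90_tumor_rel: float
    amp_hetero_sd_tumor: float
    amp_hetero_sd_boundary: float
    form_factor: float
    axis_ratio: float
    echo_sd_tumor: float

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def define_zones(
    us_img: ReconImage,
    tumor_mask: np.ndarray,
    skin_depth_mm: np.ndarray,
    halo_width_mm: float = 3.0,
    reference_margin_mm: float = 5.0,
    breast_mask: np.ndarray | None = None,
) -> ZoneMasks:
    """Construct tumor / boundary / reference zone masks on the image grid.

    The reference zone is restricted to the tumor's depth band and lies
    strictly more than ``reference_margin_mm`` from the outer edge of the
    boundary zone.
    """
    grid = us_img.grid
    tumor = np.asarray(tumor_mask, dtype=bool)
    if not tumor.any():
        raise ZoneConstructionError("tumor mask is empty")
    pitch = grid.pitch_mm
    if breast_mask is None:
        depth = grid.depth_of_row_mm[:, None]
        breast_mask = depth > (skin_depth_mm[None, :] + 0.5)
    breast_mask = np.asarray(breast_mask, dtype=bool)
    if np.any(tumor & ~breast_mask):
        raise ZoneConstructionError("tumor mask extends outside the breast")

    halo_px = max(int(round(halo_width_mm / pitch)), 1)
    boundary = ndimage.binary_dilation(tumor, iterations=halo_px) & ~tumor

    rows = np.nonzero(tumor.any(axis=1))[0]
    band = np.zeros_like(tumor)
    band[rows.min(): rows.max() + 1, :] = True

    dist = ndimage.distance_transform_edt(~(tumor | boundary), sampling=pitch)
    reference = breast_mask & band & (dist > reference_margin_mm)
    if not reference.any():
        raise ZoneConstructionError("no eligible reference pixels")
    return ZoneMasks(
        tumor=tumor, boundary=boundary, reference=reference,
        breast=breast_mask, skin_depth_mm=skin_depth_mm, grid=grid,
    )


def _zone_vessel_stats(skeleton: VesselSkeleton, zone: np.ndarray):
    count = 0
    for seg in skeleton.segments:
        if np.any(zone[seg[:, 0], seg[:, 1]]):
            count += 1
    density = float(skeleton.skeleton_mask[zone].sum() / max(zone.sum(), 1))
    return float(count), density


def extract_features(
    pa_img: ReconImage,
    us_img: ReconImage,
    skeleton: VesselSkeleton,
    zones: ZoneMasks,
    mass_id: str = "",
    label: str = "",
) -> FeatureVector:
    """Compute the 11 diagnostic features for one mass.

    Amplitude features are taken on the unipolar photoacoustic image and
    normalised by the same statistic in the reference zone; heterogeneity is
    the SD of amplitude over skeleton pixels inside the zone (0 when the zone
    holds no vessel pixels); anatomical features come from the tumor mask and
    the conditioned ultrasound image.
    """
    pa = pa_img.pixels
    us = us_img.pixels
    t, b, r = zones.tumor, zones.boundary, zones.reference
    if not r.any():
        raise UndefinedFeatureError("empty reference zone")
    ref_mean = float(pa[r].mean())
    ref_p90 = float(np.percentile(pa[r], 90))
    if ref_mean == 0 or ref_p90 == 0:
        raise UndefinedFeatureError("reference statistic is zero")

    c_t, d_t = _zone_vessel_stats(skeleton, t)
    c_b, d_b = _zone_vessel_stats(skeleton, b)

    def vessel_sd(zone):
        sel = skeleton.skeleton_mask & zone
        return float(pa[sel].std()) if sel.any() else 0.0

    return FeatureVector(
        mass_id=mass_id,
        label=label,
        v_count_tumor=c_t,
        v_count_boundary=c_b,
        v_density_tumor=d_t,
        v_density_boundary=d_b,
        amp_mean_tumor_rel=float(pa[t].mean() / ref_mean),
        amp_p90_tumor_rel=float(np.percentile(pa[t], 90) / ref_p90),
        amp_hetero_sd_tumor=vessel_sd(t),
        amp_hetero_sd_boundary=vessel_sd(b),
        form_factor=form_factor(t, pitch_mm=zones.grid.pitch_mm),
        axis_ratio=axis_ratio(t),
        echo_sd_tumor=float(us[t].std()),
    )


def form_factor(mask: np.ndarray, pitch_mm: float = 1.0) -> float:
    """Circularity 4*pi*A/P^2 with a sub-pixel marching-squares perimeter.

    The mask is lightly smoothed (sigma = 1 px) before contour extraction so
    that the perimeter follows the underlying shape instead of the pixel
    staircase; a rasterised disk then scores ~1 and a square ~pi/4.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    area = mask.sum() * pitch_mm**2
    padded = np.pad(mask.astype(float), 2)
    smooth = ndimage.gaussian_filter(padded, 1.0)
    perim = sum(
        np.hypot(*np.diff(c, axis=0).T).sum()
        for c in measure.find_contours(smooth, 0.5)
    ) * pitch_mm
    if perim == 0:
        raise ValueError("degenerate mask with zero perimeter")
    return float(4.0 * np.pi * area / perim**2)


def axis_ratio(mask: np.ndarray) -> float:
    """Major/minor axis length of the best-fit second-moment ellipse."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    props = measure.regionprops(mask.astype(np.uint8))[0]
    if props.axis_minor_length == 0:
        raise ValueError("degenerate mask: zero minor axis")
    return float(props.axis_major_length / props.axis_minor_length)


def angiogenesis_occurrence(
    skeleton_mask: np.ndarray,
    breast_mask: np.ndarray,
    pitch_mm: float,
    tile_mm: float = 4.0,
    factor: float = 1.5,
) -> tuple[int, float]:
    """Count 4mm x 4mm tiles whose vessel density exceeds 1.5x the breast mean.

    Tiles are nonoverlapping; only tiles fully inside the breast mask are
    eligible.  Returns ``(count, rate)`` with rate = count / eligible tiles.
    """
    tile_px = max(int(round(tile_mm / pitch_mm)), 1)
    skel = np.asarray(skeleton_mask, dtype=bool)
    breast = np.asarray(breast_mask, dtype=bool)
    n_y, n_x = breast.shape
    if n_y < tile_px or n_x < tile_px or not breast.any():
        raise ValueError("breast region smaller than one tile")
    mean_density = skel[breast].sum() / breast.sum()
    count = 0
    eligible = 0
    for r0 in range(0, n_y - tile_px + 1, tile_px):
        for c0 in range(0, n_x - tile_px + 1, tile_px):
            tile_b = breast[r0: r0 + tile_px, c0: c0 + tile_px]
            if not tile_b.all():
                continue
            eligible += 1
            density = skel[r0: r0 + tile_px, c0: c0 + tile_px].sum() / tile_px**2
            if density > factor * mean_density:
                count += 1
    if eligible == 0:
        raise ValueError("no tile fits fully inside the breast")
    return count, count / eligible


def vascular_distance_metric(
    segments: list[np.ndarray], pitch_mm: float = 1.0
) -> tuple[np.ndarray, float]:
    """Endpoint chord length over path length per vessel segment, and mean.

    1 for a straight vessel, approaching 0 with tortuosity; exactly 0 for a
    closed loop (coincident endpoints).
    """
    ratios = []
    for seg in segments:
        if seg.shape[0] < 2:
            raise ValueError("segment with fewer than 2 pixels")
        steps = np.diff(seg.astype(float), axis=0)
        path = np.hypot(steps[:, 0], steps[:, 1]).sum() * pitch_mm
        chord = np.hypot(*(seg[-1] - seg[0]).astype(float)) * pitch_mm
        # coincident endpoints (closed loop) flag as fully tortuous
        ratios.append(0.0 if chord < 1e-6 else min(chord / path, 1.0))
    ratios = np.asarray(ratios)
    return ratios, float(ratios.mean()) if ratios.size else float("nan")


def exclude_superficial(
    skeleton: VesselSkeleton,
    skin_depth_mm: np.ndarray,
    margin_mm: float = 6.0,
) -> VesselSkeleton:
    """Drop skeleton pixels within ``margin_mm`` of the skin surface.

    Remaining pixels are re-traced into segments, so partially superficial
    vessels are truncated rather than discarded.
    """
    if margin_mm <= 0:
        return skeleton
    grid = skeleton.source_grid
    depth = grid.depth_of_row_mm[:, None] - skin_depth_mm[None, :]
    keep = skeleton.skeleton_mask & (depth >= margin_mm)
    return VesselSkeleton(keep, _trace_segments(keep), grid)
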