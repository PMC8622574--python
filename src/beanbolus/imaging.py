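"""Segmentation and measurement of bolus particles on plate photographs.

The measurement chain mirrors how dispersed bolus particles are
photographed: the blue plate is isolated by hue thresholding, small
bright low-saturation specular reflections are removed, the particles
are detected and labelled, pixel counts are converted to mm^2 using a
calibration marker of known physical length, particles below the 1 mm
sieve cut-off are dropped, and each particle is assigned to the dark
seed-coat ("black") or light cotyledon ("white") class by 2-means
clustering of its mean colour.

Particle support is determined by colour distance from the plate
background (every pixel that is not plate-blue is particle candidate),
which is exact on flat-background photographs; a Canny edge map is
computed alongside and used to flag particles whose colour support is
not bounded by detected edges.  Particles touching the plate rim are
retained but flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.color import rgb2hsv
from skimage.feature import canny
from skimage.measure import label, regionprops
from sklearn.cluster import KMeans

__all__ = [
    "Calibration",
    "PlateNotFoundError",
    "calibrate",
    "isolate_plate",
    "remove_reflections",
    "detect_particles",
    "measure_areas",
    "classify_particles",
    "apply_sieve_filter",
    "segment_image",
    "analyze_bolus",
]

#: hue of the default plate background, degrees on the HSV circle
PLATE_HUE_DEG = 225.0


class PlateNotFoundError(ValueError):
    """No sufficiently large blue plate region in the image."""


@dataclass(frozen=True)
class Calibration:
    """Spatial scale of a plate photograph."""

    mm_per_px: float

    def __post_init__(self) -> None:
        if not self.mm_per_px > 0:
            raise ValueError("mm_per_px must be positive")

    @property
    def mm2_per_px(self) -> float:
        return self.mm_per_px**2


def calibrate(marker_length_mm: float, marker_length_px: float) -> Calibration:
    """Scale factor from a reference marker: mm_per_px = mm / px."""
    if marker_length_mm <= 0 or marker_length_px <= 0:
        raise ValueError("marker lengths must be positive")
    return Calibration(mm_per_px=marker_length_mm / marker_length_px)


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.shape[0] == 0:
        raise ValueError("expected a non-empty RGB image (H, W, 3)")
    return image


def isolate_plate(
    image: np.ndarray,
    hue_center_deg: float = PLATE_HUE_DEG,
    hue_window_deg: float = 40.0,
    min_fraction: float = 0.2,
    min_saturation: float = 0.25,
    min_value: float = 0.15,
) -> np.ndarray:
    """Binary mask of the plate: largest connected blue region, holes filled.

    Pixels whose hue lies within ``hue_window_deg`` of ``hue_center_deg``
    (and that are reasonably saturated and bright) are plate candidates;
    the largest connected candidate component, with enclosed holes
    (particles) filled, is returned.  Raises :class:`PlateNotFoundError`
    if the mask covers less than ``min_fraction`` of the image.
    """
    image = _check_rgb(image)
    hsv = rgb2hsv(image)
    hue_deg = hsv[..., 0] * 360.0
    delta = np.abs((hue_deg - hue_center_deg + 180.0) % 360.0 - 180.0)
    cand = (delta <= hue_window_deg) & (hsv[..., 1] >= min_saturation) & (
        hsv[..., 2] >= min_value
    )
    lab, n = ndi.label(cand)
    if n == 0:
        raise PlateNotFoundError("no blue plate region found")
    sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    mask = lab == (1 + int(np.argmax(sizes)))
    mask = ndi.binary_fill_holes(mask)
    if mask.mean() < min_fraction:
        raise PlateNotFoundError(
            f"plate covers {mask.mean():.1%} of the image, below {min_fraction:.0%}"
        )
    return mask


def remove_reflections(
    image: np.ndarray,
    plate_mask: np.ndarray,
    calibration: Calibration,
    brightness_min: float = 0.9,
    saturation_max: float = 0.12,
    max_area_mm2: float = 1.0,
) -> np.ndarray:
    """Drop specular reflections from the plate mask.

    Connected regions that are simultaneously bright (value >=
    ``brightness_min``), low-saturation (<= ``saturation_max``) and small
    (< ``max_area_mm2``) are reassigned to background, i.e. removed from
    the returned mask.  Everything else is untouched; a no-op when
    nothing matches.
    """
    image = _check_rgb(image)
    hsv = rgb2hsv(image)
    cand = (
        plate_mask
        & (hsv[..., 2] >= brightness_min)
        & (hsv[..., 1] <= saturation_max)
    )
    cleaned = plate_mask.copy()
    if not cand.any():
        return cleaned
    lab, n = ndi.label(cand)
    sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    max_px = max_area_mm2 / calibration.mm2_per_px
    for i, sz in enumerate(sizes, start=1):
        if sz < max_px:
            cleaned[lab == i] = False
    return cleaned


def detect_particles(
    image: np.ndarray,
    plate_mask: np.ndarray,
    colour_threshold: float = 60.0,
    canny_sigma: float = 1.4,
) -> pd.DataFrame:
    """Detect and label individual particles inside the plate.

    Particle support is the set of plate pixels whose Euclidean RGB
    distance from the plate background colour (the median colour over
    the mask) exceeds ``colour_threshold``; connected components of that
    support are the particles.  A Canny edge map (``canny_sigma``) is
    computed and each particle's boundary is checked against it:
    particles without edge support are flagged (``edge_support`` < 0.5),
    as are particles touching the plate rim (``boundary_flag``).

    Returns one row per particle: particle_id, pixel_count, centroid,
    mean colour, boundary/edge flags.
    """
    image = _check_rgb(image)
    if not plate_mask.any():
        return _empty_particles()
    rgb = image.astype(np.float64)
    bg = np.median(rgb[plate_mask], axis=0)
    distance = np.linalg.norm(rgb - bg, axis=-1)
    fg = plate_mask & (distance > colour_threshold)
    if not fg.any():
        return _empty_particles()

    gray = rgb.mean(axis=-1) / 255.0
    edges = canny(gray, sigma=canny_sigma)
    edge_zone = ndi.binary_dilation(edges, iterations=2)

    labels = label(fg, connectivity=2)
    rim = ndi.binary_dilation(~plate_mask)
    rows = []
    for prop in regionprops(labels, intensity_image=rgb):
        coords = tuple(prop.coords.T)
        local = prop.image  # bbox-local mask, cheap to erode
        boundary = local & ~ndi.binary_erosion(local)
        n_bound = int(boundary.sum())
        edge_local = edge_zone[prop.slice]
        edge_support = float((boundary & edge_local).sum() / n_bound) if n_bound else 0.0
        rows.append(
            dict(
                particle_id=prop.label,
                pixel_count=int(prop.area),
                centroid_y_px=float(prop.centroid[0]),
                centroid_x_px=float(prop.centroid[1]),
                mean_r=float(prop.intensity_mean[0]),
                mean_g=float(prop.intensity_mean[1]),
                mean_b=float(prop.intensity_mean[2]),
                boundary_flag=bool(rim[coords].any()),
                edge_support=edge_support,
            )
        )
    return pd.DataFrame(rows) if rows else _empty_particles()


def _empty_particles() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "particle_id",
            "pixel_count",
            "centroid_y_px",
            "centroid_x_px",
            "mean_r",
            "mean_g",
            "mean_b",
            "boundary_flag",
            "edge_support",
        ]
    )


def measure_areas(records: pd.DataFrame, calibration: Calibration) -> pd.DataFrame:
    """Convert pixel counts to areas: area_mm2 = pixel_count * mm_per_px^2.

    Zero-pixel records are excluded; output is sorted by particle_id.
    """
    if calibration is None:
        raise ValueError("calibration is required to measure areas")
    out = records[records["pixel_count"] > 0].copy()
    out["area_mm2"] = out["pixel_count"] * calibration.mm2_per_px
    return out.sort_values("particle_id").reset_index(drop=True)


def luminance(r, g, b):
    """Rec. 601 luma of an RGB triple (0-255 scale)."""
    return 0.299 * np.asarray(r) + 0.587 * np.asarray(g) + 0.114 * np.asarray(b)


def classify_particles(records: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Assign each particle to "black" (seed coat) or "white" (cotyledon).

    2-means clustering on per-particle mean RGB; the cluster with the
    lower mean luminance is labelled "black".  Deterministic for a fixed
    seed.  Degenerate inputs (fewer than 2 particles, or all colours
    identical) collapse to a single class chosen by luminance against
    mid-grey, with a warning.
    """
    out = records.copy()
    if len(out) == 0:
        out["class"] = pd.Series(dtype=object)
        return out
    feats = out[["mean_r", "mean_g", "mean_b"]].to_numpy(dtype=float)
    lum = luminance(feats[:, 0], feats[:, 1], feats[:, 2])
    if len(out) < 2 or np.ptp(feats, axis=0).max() < 1e-9:
        warnings.warn(
            "fewer than 2 distinct particle colours; assigning a single class",
            stacklevel=2,
        )
        out["class"] = np.where(lum > 127.5, "white", "black")
        return out
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(feats)
    centre_lum = luminance(*km.cluster_centers_.T)
    black_cluster = int(np.argmin(centre_lum))
    out["class"] = np.where(km.labels_ == black_cluster, "black", "white")
    return out


def apply_sieve_filter(
    records: pd.DataFrame, min_equivalent_diameter_mm: float = 1.0
) -> pd.DataFrame:
    """Keep particles whose equivalent circular diameter meets the sieve.

    d = 2*sqrt(A/pi); the default 1 mm threshold mimics washing the bolus
    on a 1 mm sieve (area >= pi/4 mm^2).
    """
    if min_equivalent_diameter_mm < 0:
        raise ValueError("threshold must be non-negative")
    if "area_mm2" not in records.columns:
        raise ValueError("areas must be measured before sieving")
    d = 2.0 * np.sqrt(records["area_mm2"] / np.pi)
    return records[d >= min_equivalent_diameter_mm].reset_index(drop=True)


def segment_image(
    image: np.ndarray,
    calibration: Calibration,
    source_id: str = "image",
    min_equivalent_diameter_mm: float = 1.0,
    classify: bool = True,
    seed: int = 0,
    **detect_kwargs,
) -> pd.DataFrame:
    """Full single-image pipeline: isolate, de-reflect, detect, measure,
    sieve and (optionally) classify."""
    plate = isolate_plate(image)
    cleaned = remove_reflections(image, plate, calibration)
    records = detect_particles(image, cleaned, **detect_kwargs)
    records = measure_areas(records, calibration)
    records = apply_sieve_filter(records, min_equivalent_diameter_mm)
    if classify and len(records):
        records = classify_particles(records, seed=seed)
    records.insert(1, "source_id", source_id)
    return records


def analyze_bolus(
    images,
    calibration: Calibration,
    source_ids=None,
    min_equivalent_diameter_mm: float = 1.0,
    seed: int = 0,
    **detect_kwargs,
) -> pd.DataFrame:
    """Pool particles from several photographs of one bolus.

    Runs the single-image pipeline on each photograph, then concatenates
    the records with re-keyed unique particle ids.  Classification is
    performed once on the pooled records so both colour classes share a
    common clustering.
    """
    images = list(images)
    if not images:
        raise ValueError("need at least one image")
    if source_ids is None:
        source_ids = [f"image_{i}" for i in range(len(images))]
    parts = []
    for img, sid in zip(images, source_ids):
        parts.append(
            segment_image(
                img,
                calibration,
                source_id=sid,
                min_equivalent_diameter_mm=min_equivalent_diameter_mm,
                classify=False,
                **detect_kwargs,
            )
        )
    pooled = pd.concat(parts, ignore_index=True)
    pooled["particle_id"] = np.arange(1, len(pooled) + 1)
    if len(pooled):
        pooled = classify_particles(pooled, seed=seed)
    return pooled
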