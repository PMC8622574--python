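"""Synthetic inputs with known ground truth for the whole pipeline.

Four generators emulate the measured raw data of a bean-bolus mastication
study so that every downstream module can be exercised and validated
without any real photographs or assay data:

* :func:`render_plate` draws dispersed bolus particles (dark seed-coat
  and light cotyledon fragments as perturbed ellipses) on a blue plate
  disc with a calibration marker of known millimetre length, optionally
  with small specular-reflection blobs, and returns the exact per-particle
  ground truth.
* :func:`generate_curve` produces starch (fractional conversion) or
  protein (zero order) digestion time courses with additive Gaussian
  noise.
* :func:`generate_panel` produces a participant panel with designed
  fast / slow / inconsistent chewing-duration structure and a salivary
  amylase activity calibrated to a target duration-amylase correlation.
* :func:`generate_tpa_curve` builds a double-compression force curve
  with known hardness, area ratio and stroke-duration ratio.

Two particle-area samplers are provided.  :func:`sample_rosin_rammler`
inverts the Rosin-Rammler cumulative *area* law directly, so its draws
sit at uniformly random area quantiles: their count-ECDF estimates the
law itself.  A physical particle population whose area-weighted
cumulative follows the law must instead be drawn from the size-debiased
number density f(x)/x, which :func:`sample_particle_areas` does (areas
are length-biased: weighting particles by their own area would otherwise
inflate the apparent median).  Plates are rendered from the latter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.special import gammaincinv
from skimage.draw import polygon as draw_polygon

from .kinetics import DigestaTimeSeries, fractional_conversion
from .psd import LN2

__all__ = [
    "PlateSpec",
    "GroundTruth",
    "CurveSpec",
    "PanelSpec",
    "PanelResult",
    "PackingError",
    "sample_rosin_rammler",
    "sample_particle_areas",
    "render_plate",
    "generate_curve",
    "generate_panel",
    "generate_tpa_curve",
    "write_plate_bundle",
    "digesta_frame",
]

PLATE_BLUE = (30, 60, 150)
BACKGROUND_GREY = (70, 70, 70)
MARKER_COLOUR = (12, 12, 12)
WHITE_PARTICLE = (225, 214, 182)  # cream cotyledon
BLACK_PARTICLE = (35, 30, 30)  # seed coat
REFLECTION_COLOUR = (250, 250, 250)


class PackingError(RuntimeError):
    """Raised when requested particles cannot be placed on the plate."""


@dataclass(frozen=True)
class PlateSpec:
    """Recipe for one synthetic bolus-plate photograph."""

    n_white: int = 30
    n_black: int = 20
    rr_white: tuple[float, float] = (3.5, 1.9)  # (x50 mm^2, b)
    rr_black: tuple[float, float] = (6.7, 1.7)
    plate_diameter_mm: float = 177.0
    background_colour: tuple[int, int, int] = PLATE_BLUE
    n_reflections: int = 0
    marker_length_mm: float = 20.0
    image_size_px: int = 1200
    min_area_mm2: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (x50, b) in (("rr_white", self.rr_white), ("rr_black", self.rr_black)):
            if not (x50 > 0 and b > 0):
                raise ValueError(f"{name}: x50 and b must be positive")
        if self.n_white < 0 or self.n_black < 0 or self.n_reflections < 0:
            raise ValueError("counts must be non-negative")
        if not self.marker_length_mm > 0:
            raise ValueError("marker_length_mm must be positive")
        if self.image_size_px < 200:
            raise ValueError("image_size_px too small")


@dataclass
class GroundTruth:
    """Exact rendering record: one row per particle, plus the calibration."""

    particles: pd.DataFrame  # particle_id, class, area_mm2, pixel_count, centroids
    mm_per_px: float
    marker_length_mm: float
    marker_length_px: int
    plate_mask: np.ndarray = field(repr=False)


def sample_rosin_rammler(n: int, x50: float, b: float, seed=None) -> np.ndarray:
    """Draw ``n`` values by inverting the Rosin-Rammler cumulative law.

    x = x50 * (-ln(1 - u) / ln 2)^(1/b) with u ~ Uniform(0, 1).  Each
    draw sits at a uniformly random quantile of the cumulative *area*
    distribution, so the count-ECDF of the draws estimates the law.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (x50 > 0 and b > 0):
        raise ValueError("x50 and b must be positive")
    rng = np.random.default_rng(seed)
    u = rng.uniform(0.0, 1.0, size=n)
    return x50 * np.power(-np.log1p(-u) / LN2, 1.0 / b)


def sample_particle_areas(
    n: int,
    x50: float,
    b: float,
    seed=None,
    stratified: bool = False,
    min_area_mm2: float = 0.0,
) -> np.ndarray:
    """Sample a particle population whose area-weighted cumulative follows
    the Rosin-Rammler law with parameters (x50, b).

    The number density is the size-debiased f(x)/x: with
    y = (x/lam)^b and lam = x50 / (ln 2)^(1/b), y follows a
    Gamma(1 - 1/b) distribution (requires b > 1, which holds for
    masticated bean boluses where b is around 1.5-1.9).  With
    ``stratified=True`` the count-quantiles of that law are returned
    instead of random draws, giving a deterministic ("noiseless")
    population.  ``min_area_mm2`` truncates the small-area tail by
    rejection (random mode) or by conditioning (stratified mode).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (x50 > 0 and b > 1):
        raise ValueError("x50 must be positive and b > 1")
    lam = x50 / LN2 ** (1.0 / b)
    shape = 1.0 - 1.0 / b

    if stratified:
        from scipy.special import gammainc

        p = (np.arange(n) + 0.5) / n
        p0 = 0.0
        if min_area_mm2 > 0:
            p0 = float(gammainc(shape, (min_area_mm2 / lam) ** b))
        y = gammaincinv(shape, p0 + p * (1.0 - p0))
        return lam * np.power(y, 1.0 / b)

    rng = np.random.default_rng(seed)
    out = np.empty(0)
    while out.size < n:
        y = rng.gamma(shape, 1.0, size=2 * (n - out.size) + 8)
        x = lam * np.power(y, 1.0 / b)
        if min_area_mm2 > 0:
            x = x[x >= min_area_mm2]
        out = np.concatenate([out, x])
    return out[:n]


def _blob_polygon(rng: np.random.Generator, n_vertices: int = 96) -> np.ndarray:
    """Unit-area perturbed-ellipse polygon (closed, counter-clockwise)."""
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    aspect = rng.uniform(1.0, 3.0)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    # low-order radial noise keeps the outline convex-ish but irregular
    wobble = np.zeros_like(theta)
    for k in (2, 3, 4):
        wobble += rng.uniform(0.0, 0.05) * np.sin(k * theta + rng.uniform(0, 2 * np.pi))
    a, c = np.sqrt(aspect), 1.0 / np.sqrt(aspect)
    x = a * np.cos(theta) * (1.0 + wobble)
    y = c * np.sin(theta) * (1.0 + wobble)
    xr = x * np.cos(phi) - y * np.sin(phi)
    yr = x * np.sin(phi) + y * np.cos(phi)
    verts = np.column_stack([xr, yr])
    # normalise to unit area (shoelace)
    area = 0.5 * abs(
        np.dot(verts[:, 0], np.roll(verts[:, 1], -1))
        - np.dot(verts[:, 1], np.roll(verts[:, 0], -1))
    )
    return verts / np.sqrt(area)


def _rasterise_at_count(
    poly: np.ndarray, target_px: float, cy: float, cx: float, shape: tuple[int, int]
):
    """Scale and rasterise a unit-area polygon so the pixel count matches
    ``target_px`` as closely as the grid allows."""
    scale = np.sqrt(target_px)
    best = None

    def attempt(s):
        nonlocal best
        rr, cc = draw_polygon(cy + poly[:, 1] * s, cx + poly[:, 0] * s, shape)
        if rr.size == 0:
            return None
        err = abs(rr.size - target_px)
        if best is None or err < best[0]:
            best = (err, rr, cc)
        return rr.size

    for _ in range(8):
        count = attempt(scale)
        if count is None:
            scale *= 1.3
            continue
        if best[0] <= 0.55:
            break
        scale *= np.sqrt(target_px / count)
    if best is not None and best[0] > 0.55:
        # pixel counts move in integer jumps; a fine scan around the
        # multiplicative optimum usually lands on the nearest integer
        for f in np.linspace(0.994, 1.006, 13):
            attempt(scale * f)
            if best[0] <= 0.55:
                break
    if best is None:
        return np.empty(0, int), np.empty(0, int)
    return best[1], best[2]


def render_plate(spec: PlateSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a bolus plate image and its exact ground truth.

    The plate is a blue disc on a grey backdrop with a dark rectangular
    calibration marker of known millimetre length in the top-left corner
    (outside the disc).  Particles are non-overlapping perturbed ellipses
    whose pixel-count areas are driven to the sampled target areas;
    cotyledon ("white") blobs are light, seed-coat ("black") blobs dark.
    Optional reflection artifacts are small near-white low-saturation
    discs under 1 mm^2.  Deterministic for a fixed spec.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size_px
    nominal = spec.plate_diameter_mm / (0.88 * size)
    marker_px = max(int(round(spec.marker_length_mm / nominal)), 4)
    mm_per_px = spec.marker_length_mm / marker_px
    px_area = mm_per_px**2

    img = np.empty((size, size, 3), dtype=np.uint8)
    img[...] = BACKGROUND_GREY
    yy, xx = np.mgrid[0:size, 0:size]
    centre = (size - 1) / 2.0
    radius_px = spec.plate_diameter_mm / 2.0 / mm_per_px
    dist = np.hypot(yy - centre, xx - centre)
    plate_mask = dist <= radius_px
    img[plate_mask] = spec.background_colour

    # calibration marker: horizontal bar in the top-left corner
    mh = max(size // 120, 4)
    marker_slice = (slice(6, 6 + mh), slice(8, 8 + marker_px))
    if plate_mask[marker_slice].any():
        raise PackingError("calibration marker would overlap the plate disc")
    img[marker_slice] = MARKER_COLOUR

    areas_white = (
        sample_particle_areas(
            spec.n_white, *spec.rr_white, seed=rng, min_area_mm2=spec.min_area_mm2
        )
        if spec.n_white
        else np.empty(0)
    )
    areas_black = (
        sample_particle_areas(
            spec.n_black, *spec.rr_black, seed=rng, min_area_mm2=spec.min_area_mm2
        )
        if spec.n_black
        else np.empty(0)
    )
    requests = [("white", a) for a in areas_white] + [("black", a) for a in areas_black]
    plate_area_mm2 = np.pi * (spec.plate_diameter_mm / 2.0) ** 2
    if sum(a for _, a in requests) > 0.6 * plate_area_mm2:
        raise PackingError("requested particle area exceeds 60% of the plate area")
    # place large particles first
    requests.sort(key=lambda t: -t[1])

    occupied = np.zeros((size, size), dtype=bool)
    allowed = dist <= radius_px - 4.0
    records = []
    inner_r = radius_px - 6.0
    for cls, area_mm2 in requests:
        target_px = max(area_mm2 / px_area, 4.0)
        poly = _blob_polygon(rng)
        placed = False
        for _ in range(400):
            rad = inner_r * np.sqrt(rng.uniform(0.0, 1.0))
            ang = rng.uniform(0.0, 2.0 * np.pi)
            cy = centre + rad * np.sin(ang)
            cx = centre + rad * np.cos(ang)
            rr, cc = _rasterise_at_count(poly, target_px, cy, cx, (size, size))
            if rr.size == 0:
                continue
            if not allowed[rr, cc].all():
                continue
            # enforce a >= 2 px clearance between particles
            blob = np.zeros((size, size), dtype=bool)
            blob[rr, cc] = True
            grown = ndi.binary_dilation(blob, iterations=2)
            if (grown & occupied).any():
                continue
            occupied |= grown
            colour = WHITE_PARTICLE if cls == "white" else BLACK_PARTICLE
            img[rr, cc] = colour
            records.append(
                dict(
                    particle_id=len(records) + 1,
                    **{"class": cls},
                    requested_area_mm2=float(area_mm2),
                    pixel_count=int(rr.size),
                    area_mm2=float(rr.size * px_area),
                    centroid_x_px=float(cc.mean()),
                    centroid_y_px=float(rr.mean()),
                )
            )
            placed = True
            break
        if not placed:
            raise PackingError(
                f"could not place a {cls} particle of {area_mm2:.2f} mm^2 "
                f"after 400 attempts"
            )

    for _ in range(spec.n_reflections):
        refl_area = rng.uniform(0.3, 0.8)  # mm^2, below the removal ceiling
        r_px = np.sqrt(refl_area / px_area / np.pi)
        for _ in range(200):
            rad = inner_r * np.sqrt(rng.uniform(0.0, 1.0))
            ang = rng.uniform(0.0, 2.0 * np.pi)
            cy, cx = centre + rad * np.sin(ang), centre + rad * np.cos(ang)
            blob = np.hypot(yy - cy, xx - cx) <= r_px
            if (ndi.binary_dilation(blob, iterations=2) & occupied).any():
                continue
            img[blob] = REFLECTION_COLOUR
            break

    # mild sensor noise; small enough never to flip a colour class
    noise = rng.normal(0.0, 1.5, size=img.shape)
    img = np.clip(img.astype(np.float64) + noise, 0, 255).astype(np.uint8)

    truth = GroundTruth(
        particles=pd.DataFrame(
            records,
            columns=[
                "particle_id",
                "class",
                "requested_area_mm2",
                "pixel_count",
                "area_mm2",
                "centroid_x_px",
                "centroid_y_px",
            ],
        ),
        mm_per_px=mm_per_px,
        marker_length_mm=spec.marker_length_mm,
        marker_length_px=marker_px,
        plate_mask=plate_mask,
    )
    return img, truth


@dataclass(frozen=True)
class CurveSpec:
    """Recipe for one synthetic digestion time course."""

    model: str  # fractional_conversion | zero_order
    params: tuple[float, ...]  # (S0, Sf, ks) or (P0, kp)
    timepoints: tuple[float, ...]
    noise_sd: float = 0.0
    phase: str = "intestinal"
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints, dtype=float)
        if t.size == 0 or np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be non-negative and strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.model == "fractional_conversion":
            S0, Sf, ks = self.params
            if not (Sf >= S0 >= 0 and ks > 0):
                raise ValueError("need Sf >= S0 >= 0 and ks > 0")
        elif self.model == "zero_order":
            P0, _kp = self.params
            if P0 < 0:
                raise ValueError("P0 must be non-negative")
        else:
            raise ValueError(f"unknown model {self.model!r}")


def generate_curve(spec: CurveSpec) -> DigestaTimeSeries:
    """Evaluate the kinetic model on the grid and add Gaussian noise."""
    t = np.asarray(spec.timepoints, dtype=float)
    if spec.model == "fractional_conversion":
        S0, Sf, ks = spec.params
        clean = fractional_conversion(t, S0, Sf, ks)
        analyte = "glucose"
    else:
        P0, kp = spec.params
        clean = P0 + kp * t
        analyte = "serine"
    rng = np.random.default_rng(spec.seed)
    values = np.asarray(clean, dtype=float) + rng.normal(0.0, spec.noise_sd, size=t.size)
    return DigestaTimeSeries(t=t, value=values, phase=spec.phase, analyte=analyte)


@dataclass(frozen=True)
class PanelSpec:
    """Recipe for a participant panel with designed chewer-group structure."""

    n_fast: int = 9
    n_slow: int = 6
    n_inconsistent: int = 2
    samples: tuple[str, ...] = ("A", "B", "C")
    design_medians: tuple[float, ...] = (28.5, 29.0, 24.75)  # s, per sample
    fast_offset_s: tuple[float, float] = (2.0, 15.0)
    slow_offset_s: tuple[float, float] = (2.0, 45.0)
    inconsistent_offset_s: tuple[float, float] = (2.0, 10.0)
    target_r: float = 0.88  # duration vs amylase
    amylase_intercept: float = 0.02  # CU/mL
    amylase_slope: float = 0.004  # CU/mL per s
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_fast, self.n_slow, self.n_inconsistent) < 0:
            raise ValueError("group counts must be non-negative")
        if len(self.design_medians) != len(self.samples):
            raise ValueError("one design median per sample required")
        if self.n_inconsistent > 0 and len(self.samples) < 2:
            raise ValueError("inconsistent chewers require at least 2 samples")
        for lo, hi in (self.fast_offset_s, self.slow_offset_s, self.inconsistent_offset_s):
            if not (0 < lo <= hi):
                raise ValueError("offset ranges must be positive and ordered")
        if abs(self.target_r) > 1:
            raise ValueError("|target_r| must be <= 1")
        if min(self.design_medians) - self.fast_offset_s[1] <= 0:
            raise ValueError("fast offsets would produce non-positive durations")


@dataclass
class PanelResult:
    table: pd.DataFrame
    design_medians: pd.Series


def generate_panel(spec: PanelSpec) -> PanelResult:
    """Generate a panel whose durations realise the designed chewer groups.

    Fast chewers sit strictly below, slow chewers strictly above, the
    designed per-sample median in every sample; inconsistent chewers
    alternate sides across samples.  Amylase activity is a linear
    function of the mean chewing duration plus Gaussian noise whose
    variance is calibrated so the panel's duration-amylase Pearson
    correlation approximates ``target_r``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    ns = len(spec.samples)

    def offsets(bounds, size):
        return rng.uniform(bounds[0], bounds[1], size=size)

    for _ in range(spec.n_fast):
        durs = np.asarray(spec.design_medians) - offsets(spec.fast_offset_s, ns)
        rows.append(("fast", durs))
    for _ in range(spec.n_slow):
        durs = np.asarray(spec.design_medians) + offsets(spec.slow_offset_s, ns)
        rows.append(("slow", durs))
    for i in range(spec.n_inconsistent):
        signs = np.array([1 if (i + j) % 2 else -1 for j in range(ns)], dtype=float)
        durs = np.asarray(spec.design_medians) + signs * offsets(
            spec.inconsistent_offset_s, ns
        )
        rows.append(("inconsistent", durs))

    table = pd.DataFrame(
        {
            "participant_id": [f"P{i + 1}" for i in range(len(rows))],
            "group_design": [g for g, _ in rows],
        }
    )
    for j, s in enumerate(spec.samples):
        table[f"duration_{s}_s"] = [d[j] for _, d in rows]
    dur_mean = table[[f"duration_{s}_s" for s in spec.samples]].mean(axis=1)
    table["duration_s"] = dur_mean

    slope = spec.amylase_slope * np.sign(spec.target_r) if spec.target_r else 0.0
    signal = spec.amylase_intercept + slope * dur_mean.to_numpy()
    r = abs(spec.target_r)
    sd_dur = float(np.std(dur_mean.to_numpy(), ddof=1)) if len(rows) > 1 else 0.0
    if 0 < r < 1 and sd_dur > 0:
        noise_sd = abs(spec.amylase_slope) * sd_dur * np.sqrt(1.0 / r**2 - 1.0)
    else:
        noise_sd = 0.0
    table["amylase_cu_per_ml"] = signal + rng.normal(0.0, noise_sd, size=len(rows))

    medians = pd.Series(
        spec.design_medians, index=[f"duration_{s}_s" for s in spec.samples]
    )
    return PanelResult(table=table, design_medians=medians)


def generate_tpa_curve(
    hardness: float = 10.0,
    area_ratio: float = 0.5,
    duration_ratio: float = 0.8,
    resilience: float = 1.0,
    compression_s: float = 1.0,
    rest_s: float = 0.5,
    points_per_segment: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-bite force curve with known TPA parameters.

    Each cycle is a triangular force pulse.  The first peaks at
    ``hardness`` (N) with compression stroke ``compression_s`` (s) and
    withdrawal stroke ``resilience * compression_s``; the second cycle's
    stroke durations are scaled by ``duration_ratio`` and its peak chosen
    so its total area is ``area_ratio`` times the first cycle's.
    """
    if min(hardness, area_ratio, duration_ratio, resilience, compression_s) <= 0:
        raise ValueError("all curve parameters must be positive")
    d_r1, d_f1 = compression_s, resilience * compression_s
    d_r2, d_f2 = duration_ratio * d_r1, duration_ratio * d_f1
    peak2 = area_ratio * hardness * (d_r1 + d_f1) / (d_r2 + d_f2)
    segs = [
        (rest_s, 0.0, 0.0),
        (d_r1, 0.0, hardness),
        (d_f1, hardness, 0.0),
        (rest_s, 0.0, 0.0),
        (d_r2, 0.0, peak2),
        (d_f2, peak2, 0.0),
        (rest_s, 0.0, 0.0),
    ]
    t_parts, f_parts = [], []
    t0 = 0.0
    for dur, f_a, f_b in segs:
        tt = np.linspace(0.0, dur, points_per_segment, endpoint=False)
        t_parts.append(t0 + tt)
        f_parts.append(f_a + (f_b - f_a) * tt / dur)
        t0 += dur
    t_parts.append(np.array([t0]))
    f_parts.append(np.array([0.0]))
    return np.concatenate(t_parts), np.concatenate(f_parts)


def digesta_frame(series_list) -> pd.DataFrame:
    """Tidy digesta table (time_min, phase, analyte, value_mg)."""
    frames = [
        pd.DataFrame(
            {
                "time_min": s.t,
                "phase": s.phase,
                "analyte": s.analyte,
                "value_mg": s.value,
            }
        )
        for s in series_list
    ]
    return pd.concat(frames, ignore_index=True)


def write_plate_bundle(out_dir, image: np.ndarray, truth: GroundTruth, stem: str = "plate"):
    """Write PNG image + ground-truth CSV + calibration sidecar CSV."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out / f"{stem}.png", image)
    truth.particles.to_csv(out / f"{stem}_truth.csv", index=False)
    pd.DataFrame(
        {
            "marker_length_mm": [truth.marker_length_mm],
            "marker_length_px": [truth.marker_length_px],
            "mm_per_px": [truth.mm_per_px],
        }
    ).to_csv(out / f"{stem}_calibration.csv", index=False)
    return out / f"{stem}.png"
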