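"""Quantifying Cd migration from membrane-blot fluorescence imprints.

The imprint workflow: a dye-saturated membrane pressed onto the root-box
face records Cd2+ as fluorescence; the digitized image carries one gray
value per pixel (0 = black ... 256 = white).  Circular calibration films
of known Cd content expose the gray -> concentration map; the "hotspot"
statistic is the percentage of pixels more than a set fraction (default
25%) above the image mean; root-Cd colocalization is a Mantel test over
block summaries of the root mask and the level map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from PIL import Image
from sklearn.isotonic import IsotonicRegression

from .errors import (
    DegenerateCalibrationError,
    DegenerateInputError,
    InsufficientDataError,
)
from .integrate import mantel

__all__ = [
    "CalibrationCurve",
    "ConcentrationMap",
    "HotspotSummary",
    "fit_calibration",
    "invert_to_concentration",
    "detect_hotspots",
    "colocalization",
    "render_pseudocolor",
]


def _validate_gray(image) -> np.ndarray:
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2 or min(arr.shape) < 8:
        raise DegenerateInputError("gray image must be 2-D and at least 8x8")
    if not np.isfinite(arr).all():
        raise DegenerateInputError("gray image contains non-finite values")
    if arr.min() < 0 or arr.max() > 256:
        raise DegenerateInputError("gray values must lie in [0, 256]")
    return arr


@dataclass
class CalibrationCurve:
    """Monotone gray -> concentration map fitted from calibration films.

    ``kind`` is "linear" (least-squares concentration on gray) or
    "monotone-piecewise" (pool-adjacent-violators isotonic fit with linear
    interpolation between films).  Outside the calibrated gray range the
    boundary segment extrapolates (linear) or the boundary value holds
    (piecewise).
    """

    kind: str
    grays: np.ndarray
    concentrations: np.ndarray
    slope: float | None
    intercept: float | None
    fit_r2: float

    def __call__(self, gray) -> np.ndarray:
        gray = np.asarray(gray, dtype=float)
        if self.kind == "linear":
            return self.intercept + self.slope * gray
        return np.interp(gray, self.grays, self.concentrations)

    @property
    def gray_range(self) -> tuple[float, float]:
        return float(self.grays.min()), float(self.grays.max())


def fit_calibration(series, kind: str = "linear",
                    allow_decreasing: bool = False) -> CalibrationCurve:
    """Fit the concentration-on-gray calibration from film measurements.

    ``series`` is a sequence of (concentration mg/kg, mean gray) points —
    concentration is the controlled quantity, gray the measured one, so
    the regression inverts directly onto images.  Fluorescence is assumed
    to increase with Cd; a fitted decreasing map raises unless
    ``allow_decreasing`` (inverted-polarity dyes).
    """
    pts = [(float(c), float(g)) for c, g in series]
    need = 2 if kind == "linear" else 3
    if len(pts) < need:
        raise InsufficientDataError(
            f"{kind} calibration needs >= {need} films, got {len(pts)}"
        )
    conc = np.array([c for c, _ in pts])
    gray = np.array([g for _, g in pts])
    if (conc < 0).any():
        raise DegenerateCalibrationError("negative film concentration")
    for g in np.unique(gray):
        vals = conc[gray == g]
        if vals.size > 1 and np.ptp(vals) > 0:
            raise DegenerateCalibrationError(
                f"films with identical gray {g} but different concentrations"
            )

    order = np.argsort(gray)
    gray_s, conc_s = gray[order], conc[order]

    if kind == "linear":
        if np.ptp(gray_s) == 0:
            raise DegenerateCalibrationError("all films have the same gray value")
        slope, intercept = np.polyfit(gray_s, conc_s, 1)
        fitted = intercept + slope * gray_s
        curve = CalibrationCurve("linear", gray_s, fitted, float(slope),
                                 float(intercept), _r2(conc_s, fitted))
        if slope < 0 and not allow_decreasing:
            raise DegenerateCalibrationError(
                "fitted calibration is decreasing; pass allow_decreasing=True "
                "for inverted-polarity dyes"
            )
        return curve
    if kind == "monotone-piecewise":
        iso = IsotonicRegression(increasing=True)
        fitted = iso.fit_transform(gray_s, conc_s)
        # collapse duplicate grays (PAVA already pools their values)
        ug, idx = np.unique(gray_s, return_index=True)
        return CalibrationCurve("monotone-piecewise", ug, fitted[idx],
                                None, None, _r2(conc_s, fitted))
    raise ValueError(f"unknown calibration kind {kind!r}")


def _r2(y, fitted) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 1.0
    return 1.0 - float(np.sum((y - fitted) ** 2)) / ss_tot


@dataclass
class ConcentrationMap:
    """Per-pixel Cd concentration (mg/kg, clamped at 0)."""

    pixels: np.ndarray
    extrapolated: bool   # any pixel outside the calibrated gray range

    @property
    def shape(self):
        return self.pixels.shape


def invert_to_concentration(image, curve: CalibrationCurve) -> ConcentrationMap:
    """Apply the calibration to every pixel; negatives clamp to 0."""
    arr = _validate_gray(image)
    lo, hi = curve.gray_range
    extrapolated = bool((arr < lo).any() or (arr > hi).any())
    conc = np.clip(curve(arr), 0.0, None)
    return ConcentrationMap(conc, extrapolated)


@dataclass
class HotspotSummary:
    """Pixels more than ``fraction`` above the image mean.

    ``hotspot_percent`` is the migration statistic: 100 x (hotspot
    pixels) / (total pixels).  The threshold is relative, so rescaling the
    raster by any positive factor leaves the mask unchanged.
    """

    mask: np.ndarray
    threshold_value: float
    hotspot_percent: float
    mean_level: float
    fraction_above_mean: float


def detect_hotspots(level_map, fraction_above_mean: float = 0.25) -> HotspotSummary:
    """Mark pixels strictly greater than (1 + fraction) x mean level.

    Works on gray rasters or concentration maps; a constant map yields 0%
    (the strict inequality makes the uniform field unambiguous).
    """
    arr = level_map.pixels if isinstance(level_map, ConcentrationMap) else level_map
    arr = np.asarray(arr, dtype=float)
    if arr.size == 0:
        raise DegenerateInputError("empty level map")
    mean = float(arr.mean())
    threshold = (1.0 + fraction_above_mean) * mean
    mask = arr > threshold
    return HotspotSummary(
        mask=mask,
        threshold_value=threshold,
        hotspot_percent=100.0 * float(mask.sum()) / arr.size,
        mean_level=mean,
        fraction_above_mean=fraction_above_mean,
    )


def _tile_summaries(root, level, block):
    rows, cols = root.shape
    nr, nc = rows // block, cols // block
    if nr * nc < 10:
        raise DegenerateInputError(
            f"block={block} yields {nr * nc} tiles; need >= 10"
        )
    r_crop, c_crop = nr * block, nc * block
    root_t = root[:r_crop, :c_crop].reshape(nr, block, nc, block)
    level_t = level[:r_crop, :c_crop].reshape(nr, block, nc, block)
    root_frac = root_t.mean(axis=(1, 3)).ravel()
    level_mean = level_t.mean(axis=(1, 3)).ravel()
    return root_frac, level_mean


def colocalization(root_mask, level_map, block: int = 8,
                   n_perm: int = 999, seed: int | None = 0):
    """Root-Cd colocalization as a Mantel test over block summaries.

    Both rasters are partitioned into ``block`` x ``block`` tiles (edges
    cropped to full tiles); per tile the root-pixel fraction and the mean
    level are summarized, Euclidean distance matrices are built over the
    tiles for each variable, and a Spearman Mantel test with ``n_perm``
    permutations gives (r, p).
    """
    root = (np.asarray(root_mask) != 0).astype(float)
    arr = level_map.pixels if isinstance(level_map, ConcentrationMap) else level_map
    arr = np.asarray(arr, dtype=float)
    if root.shape != arr.shape:
        raise DegenerateInputError("root mask and level map shapes differ")
    if root.sum() == 0:
        raise DegenerateInputError("all-zero root mask carries no root signal")
    root_frac, level_mean = _tile_summaries(root, arr, block)
    d_root = np.abs(root_frac[:, None] - root_frac[None, :])
    d_level = np.abs(level_mean[:, None] - level_mean[None, :])
    return mantel(d_root, d_level, method="spearman", n_perm=n_perm, seed=seed)


def render_pseudocolor(level_map, out_path,
                       fraction_above_mean: float = 0.25) -> np.ndarray:
    """Write a blue->red pseudocolor PNG with hotspots forced pure red.

    The diverging blue->red map runs blue (lowest level) to red
    (highest); pixels flagged by :func:`detect_hotspots` are overwritten
    with pure red (255, 0, 0), which the colormap itself never emits, so
    red pixel count equals hotspot pixel count exactly.  Returns the RGB
    array.
    """
    arr = level_map.pixels if isinstance(level_map, ConcentrationMap) else level_map
    arr = np.asarray(arr, dtype=float)
    span = np.ptp(arr)
    norm = (arr - arr.min()) / span if span > 0 else np.zeros_like(arr)
    rgb = (colormaps["coolwarm"](norm)[..., :3] * 255).astype(np.uint8)
    hot = detect_hotspots(arr, fraction_above_mean).mask
    rgb[hot] = (255, 0, 0)
    Image.fromarray(rgb).save(out_path)
    return rgb
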