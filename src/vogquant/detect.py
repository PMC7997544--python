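"""Per-channel diffraction-limited particle detection.

Crocker-Grier style: band-pass the projected image, find candidate local
maxima, refine each centroid by iterated intensity-weighted center of mass
in a circular mask, then collect per-detection attributes (mass, radius of
gyration, eccentricity) from the mask around the refined centroid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu

__all__ = [
    "DetectionTable",
    "bandpass",
    "locate",
    "compute_features",
    "measure_at",
    "filter_detections",
]


@dataclass
class DetectionTable:
    """Detections of one channel plus the metadata needed downstream.

    ``df`` columns: x_um, y_um (sub-pixel centroid, physical units, pixel
    centers at integer pixel coordinates times ``pixel_size_um``), x_px,
    y_px, mass (background-corrected integrated intensity, photons),
    size_um (radius of gyration), ecc (eccentricity in [0, 1]), raw_peak.
    """

    df: pd.DataFrame
    pixel_size_um: float
    channel: str | None = None
    field_shape_px: tuple[int, int] | None = None  # (height, width)
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def positions_um(self) -> np.ndarray:
        return self.df[["x_um", "y_um"]].to_numpy(dtype=float)

    @property
    def field_bounds_um(self) -> tuple[float, float] | None:
        if self.field_shape_px is None:
            return None
        h, w = self.field_shape_px
        return w * self.pixel_size_um, h * self.pixel_size_um


_COLUMNS = ["x_um", "y_um", "x_px", "y_px", "mass", "size_um", "ecc", "raw_peak"]


def _empty_df() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=float) for c in _COLUMNS})


def bandpass(image: np.ndarray, noise_scale_px: float = 1.0, object_scale_px: float = 7.0) -> np.ndarray:
    """Difference-of-Gaussians filter: suppress pixel noise and slow background.

    Subtracts a wide Gaussian blur (scale ``object_scale_px``) from a narrow
    one (``noise_scale_px``) and clips negatives to zero.
    """
    if noise_scale_px >= object_scale_px:
        raise ValueError("noise_scale_px must be smaller than object_scale_px")
    img = np.asarray(image, dtype=np.float64)
    low = ndimage.gaussian_filter(img, noise_scale_px)
    background = ndimage.gaussian_filter(img, object_scale_px)
    return np.clip(low - background, 0.0, None)


@lru_cache(maxsize=32)
def _circular_mask(radius: float) -> tuple[np.ndarray, int]:
    r_int = int(math.ceil(radius))
    yy, xx = np.mgrid[-r_int : r_int + 1, -r_int : r_int + 1]
    return (yy**2 + xx**2) <= radius**2, r_int


@lru_cache(maxsize=32)
def _offset_grids(r_int: int) -> tuple[np.ndarray, np.ndarray]:
    yy, xx = np.mgrid[-r_int : r_int + 1, -r_int : r_int + 1]
    return yy, xx


def _suppress_close(points: np.ndarray, brightness: np.ndarray, separation: float) -> np.ndarray:
    """Greedy brightness-ranked suppression: of any pair closer than
    ``separation`` only the brighter survives.  Returns indices kept."""
    if len(points) == 0:
        return np.empty(0, dtype=int)
    tree = cKDTree(points)
    neighbours: dict[int, list[int]] = {}
    for i, j in tree.query_pairs(separation):
        neighbours.setdefault(i, []).append(j)
        neighbours.setdefault(j, []).append(i)
    alive = np.ones(len(points), dtype=bool)
    kept = []
    for i in np.argsort(brightness)[::-1]:
        if not alive[i]:
            continue
        kept.append(int(i))
        for j in neighbours.get(int(i), ()):
            alive[j] = False
    return np.array(sorted(kept), dtype=int)


def _refine_centroid(
    image: np.ndarray, y0: int, x0: int, radius: float, max_iter: int = 10, tol: float = 0.005
) -> tuple[float, float] | None:
    """Iterated intensity-weighted center of mass in a circular mask.

    Returns (y, x) in pixels, or None if the mask leaves the image or holds
    no intensity.  The integer mask center walks toward the centroid until
    the sub-pixel shift falls below ``tol`` pixels.
    """
    mask, r_int = _circular_mask(radius)
    yy, xx = _offset_grids(r_int)
    h, w = image.shape
    cy, cx = y0, x0
    off_y = off_x = 0.0
    for _ in range(max_iter):
        if cy - r_int < 0 or cx - r_int < 0 or cy + r_int >= h or cx + r_int >= w:
            return None
        win = image[cy - r_int : cy + r_int + 1, cx - r_int : cx + r_int + 1]
        weights = np.where(mask, np.clip(win, 0.0, None), 0.0)
        total = weights.sum()
        if total <= 0:
            return None
        new_off_y = float((weights * yy).sum() / total)
        new_off_x = float((weights * xx).sum() / total)
        shift = math.hypot(new_off_y - off_y, new_off_x - off_x)
        off_y, off_x = new_off_y, new_off_x
        # walk the mask center when the centroid strays from it
        step_y = int(round(off_y)) if abs(off_y) > 0.6 else 0
        step_x = int(round(off_x)) if abs(off_x) > 0.6 else 0
        if step_y or step_x:
            cy += step_y
            cx += step_x
            off_y -= step_y
            off_x -= step_x
            continue
        if shift < tol:
            break
    return cy + off_y, cx + off_x


def compute_features(
    image: np.ndarray,
    centroid_yx_px: tuple[float, float],
    mask_radius_px: float,
    pixel_size_um: float = 1.0,
    background: str = "annulus",
    floor_pixels: bool = True,
) -> tuple[float, float, float]:
    """Mass, radius of gyration and eccentricity in a mask around a centroid.

    mass = sum of (I - local background) over the circular mask, floored at
    zero per pixel by default; local background is the annulus median
    (``background = 'annulus'``) or zero (``'none'``, for images already
    background-subtracted).  ``floor_pixels=False`` sums the residuals
    without the per-pixel floor, which keeps the mass estimator unbiased for
    dim spots (the floor rectifies noise and inflates weak masses); the
    shape moments always use the floored weights.  size is the intensity-
    weighted radius of gyration in um; ecc comes from the second central
    moments.  A degenerate all-zero mask returns ``(0.0, nan, nan)``.
    """
    img = np.asarray(image, dtype=float)
    y, x = centroid_yx_px
    cy, cx = int(round(y)), int(round(x))
    mask, r_int = _circular_mask(mask_radius_px)
    h, w = img.shape
    if cy - r_int < 0 or cx - r_int < 0 or cy + r_int >= h or cx + r_int >= w:
        raise ValueError("feature mask extends outside the image")
    win = img[cy - r_int : cy + r_int + 1, cx - r_int : cx + r_int + 1]

    bg = 0.0
    if background == "annulus":
        r_out = int(math.ceil(mask_radius_px)) + 2
        y0, y1 = max(cy - r_out, 0), min(cy + r_out + 1, h)
        x0, x1 = max(cx - r_out, 0), min(cx + r_out + 1, w)
        yy, xx = np.mgrid[y0 - cy : y1 - cy, x0 - cx : x1 - cx]
        rr2 = yy**2 + xx**2
        ring = (rr2 > mask_radius_px**2) & (rr2 <= r_out**2)
        if ring.any():
            bg = float(np.median(img[y0:y1, x0:x1][ring]))
    elif background != "none":
        raise ValueError("background must be 'annulus' or 'none'")

    vals = np.where(mask, np.clip(win - bg, 0.0, None), 0.0)
    if floor_pixels:
        mass = float(vals.sum())
    else:
        mass = float((win[mask] - bg).sum())
    if vals.sum() <= 0:
        return (0.0 if floor_pixels else mass), float("nan"), float("nan")

    w_sum = float(vals.sum())
    yy, xx = _offset_grids(r_int)
    my = float((vals * yy).sum() / w_sum)
    mx = float((vals * xx).sum() / w_sum)
    dy, dx = yy - my, xx - mx
    syy = float((vals * dy**2).sum() / w_sum)
    sxx = float((vals * dx**2).sum() / w_sum)
    sxy = float((vals * dy * dx).sum() / w_sum)
    size_um = math.sqrt(max(syy + sxx, 0.0)) * pixel_size_um
    tr, det = syy + sxx, syy * sxx - sxy**2
    disc = max(tr**2 / 4.0 - det, 0.0)
    lam1 = tr / 2.0 + math.sqrt(disc)
    lam2 = tr / 2.0 - math.sqrt(disc)
    ecc = math.sqrt(max(1.0 - lam2 / lam1, 0.0)) if lam1 > 0 else 0.0
    return mass, size_um, ecc


def locate(
    image: np.ndarray,
    pixel_size_um: float,
    diameter_px: int = 7,
    separation_px: float | None = None,
    min_mass: float | None = None,
    percentile: float = 64.0,
    noise_scale_px: float = 1.0,
    channel: str | None = None,
) -> DetectionTable:
    """Detect diffraction-limited spots with sub-pixel centroids.

    Candidates are local maxima of the band-passed image above the given
    percentile of its positive pixels; of any pair closer than
    ``separation_px`` only the brighter survives.  Centroids are refined by
    iterated center of mass in a circular mask of radius ``diameter_px/2``
    (convergence 0.005 px or 10 iterations); detections within that radius
    of the field edge are discarded, as are detections below ``min_mass``.
    ``min_mass=None`` sets the threshold from Otsu's method on candidate
    masses (a blank or sparse image falls back to no mass filtering).
    """
    if diameter_px % 2 == 0:
        raise ValueError("diameter_px must be odd")
    if separation_px is None:
        separation_px = float(diameter_px)
    if separation_px < diameter_px:
        raise ValueError("separation_px must be >= diameter_px")

    img = np.asarray(image, dtype=float)
    params = {
        "diameter_px": diameter_px,
        "separation_px": separation_px,
        "min_mass": min_mass,
        "percentile": percentile,
        "noise_scale_px": noise_scale_px,
    }

    def _table(df: pd.DataFrame, used_min_mass) -> DetectionTable:
        p = dict(params)
        p["min_mass_used"] = used_min_mass
        return DetectionTable(
            df=df.reset_index(drop=True),
            pixel_size_um=pixel_size_um,
            channel=channel,
            field_shape_px=img.shape,
            params=p,
        )

    bp = bandpass(img, noise_scale_px, float(diameter_px))
    positive = bp[bp > 0]
    if positive.size == 0:
        return _table(_empty_df(), min_mass)
    threshold = np.percentile(positive, percentile)

    foot = int(2 * math.floor(separation_px / 2) + 1)
    local_max = bp == ndimage.maximum_filter(bp, size=foot)
    cand_y, cand_x = np.nonzero(local_max & (bp > threshold))
    if cand_y.size == 0:
        return _table(_empty_df(), min_mass)

    # greedy brightness-ranked suppression of near-coincident candidates
    pts = np.column_stack([cand_y, cand_x]).astype(float)
    kept = pts[_suppress_close(pts, bp[cand_y, cand_x], separation_px)]
    radius = diameter_px / 2.0

    rows = []
    for y0, x0 in kept:
        ref = _refine_centroid(bp, int(y0), int(x0), radius)
        if ref is None:
            continue
        y, x = ref
        h, w = img.shape
        if y < radius or x < radius or y > h - 1 - radius or x > w - 1 - radius:
            continue
        mass, size_um, ecc = compute_features(bp, (y, x), radius, pixel_size_um, background="none")
        if mass <= 0:
            continue
        rows.append(
            {
                "x_um": x * pixel_size_um,
                "y_um": y * pixel_size_um,
                "x_px": x,
                "y_px": y,
                "mass": mass,
                "size_um": size_um,
                "ecc": ecc,
                "raw_peak": float(img[int(round(y)), int(round(x))]),
            }
        )
    if not rows:
        return _table(_empty_df(), min_mass)
    df = pd.DataFrame(rows)

    # drop duplicate convergences to the same maximum, keep the brighter
    pos = df[["y_px", "x_px"]].to_numpy()
    df = df.iloc[_suppress_close(pos, df["mass"].to_numpy(), separation_px)].reset_index(drop=True)

    used_min_mass = min_mass
    if min_mass is None:
        masses = df["mass"].to_numpy()
        if masses.size >= 10 and np.ptp(masses) > 0:
            # masses of noise speckle and of real particles differ multiplicatively,
            # so Otsu separates them on the log scale
            used_min_mass = float(np.exp(threshold_otsu(np.log(masses), nbins=128)))
        else:
            used_min_mass = 0.0
    df = df[df["mass"] >= used_min_mass]
    return _table(df, used_min_mass)


def measure_at(
    image: np.ndarray,
    centroids_px: np.ndarray,
    pixel_size_um: float,
    mask_radius_px: float = 3.5,
    background: str = "annulus",
    floor_pixels: bool = False,
    channel: str | None = None,
) -> DetectionTable:
    """Anchored mask photometry: features at externally supplied centroids.

    Measures mass/size/ecc at each (y, x) pixel position — typically the
    detections of a bright reference channel — on another channel's image.
    The default (annulus background, no per-pixel floor) gives an unbiased
    integrated-intensity estimate even for spots near or below the detection
    floor, where detection-based selection would bias the population toward
    its bright tail.  Positions whose mask leaves the image are dropped.
    """
    img = np.asarray(image, dtype=float)
    rows = []
    n_dropped = 0
    for y, x in np.asarray(centroids_px, dtype=float):
        try:
            mass, size_um, ecc = compute_features(
                img, (y, x), mask_radius_px, pixel_size_um, background, floor_pixels
            )
        except ValueError:
            n_dropped += 1
            continue
        rows.append(
            {
                "x_um": x * pixel_size_um,
                "y_um": y * pixel_size_um,
                "x_px": x,
                "y_px": y,
                "mass": mass,
                "size_um": size_um,
                "ecc": ecc,
                "raw_peak": float(img[int(round(y)), int(round(x))]),
            }
        )
    df = pd.DataFrame(rows, columns=_COLUMNS) if rows else _empty_df()
    return DetectionTable(
        df=df,
        pixel_size_um=pixel_size_um,
        channel=channel,
        field_shape_px=img.shape,
        params={
            "anchored": True,
            "mask_radius_px": mask_radius_px,
            "background": background,
            "floor_pixels": floor_pixels,
            "n_dropped_edge": n_dropped,
        },
    )


def filter_detections(table: DetectionTable, predicates: dict) -> DetectionTable:
    """Subset a DetectionTable by attribute ranges.

    ``predicates`` maps a column name (mass, size_um, ecc, ...) to a
    ``(lo, hi)`` pair; either bound may be None.  Applied predicates are
    recorded in the output metadata.
    """
    df = table.df
    keep = np.ones(len(df), dtype=bool)
    for col, (lo, hi) in predicates.items():
        if col not in df.columns:
            raise KeyError(f"unknown detection attribute {col!r}")
        vals = df[col].to_numpy()
        if lo is not None:
            keep &= vals >= lo
        if hi is not None:
            keep &= vals <= hi
    params = dict(table.params)
    params.setdefault("filters", []).append({k: list(v) for k, v in predicates.items()})
    return replace(table, df=df[keep].reset_index(drop=True), params=params)
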