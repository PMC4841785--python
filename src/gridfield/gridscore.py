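"""Spatial autocorrelograms and grid statistics.

The hexagonal ("60-degree") gridness of a rate map is computed from a ring
of its spatial autocorrelogram containing the six peaks closest to the
centre.  The ring is correlated with rotated copies of itself and the score
contrasts the rotations where a hexagon matches (60, 120 degrees) against
those where it does not (30, 90, 150):

    gridness60 = (C60 + C120)/2 - (C30 + C90 + C150)/3

The square ("90-degree") variant contrasts 90 against 45/135:

    gridness90 = C90 - (C45 + C135)/2

Both scores are invariant to scaling the map or adding a constant.  Grid
spacing is the median centre-to-peak distance of the six nearest peaks;
grid orientation is the angle of the peak nearest the positive x-axis
folded into [-30, 30); the alignment with the box axes is
min(|alpha|, 30 - |alpha|), in [0, 15].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "GridScore",
    "autocorrelogram",
    "find_peaks",
    "gridness60",
    "gridness90",
    "grid_spacing",
    "grid_orientation",
    "grid_alignment",
    "score_map",
    "detect_modules",
]


@dataclass
class GridScore:
    """Grid statistics of one rate map."""

    gridness60: float
    gridness90: float
    spacing: float  # arena length units; nan if peaks not found
    orientation: float  # degrees in [-30, 30); nan if peaks not found
    alignment: float  # degrees in [0, 15]; nan if peaks not found


def autocorrelogram(rate_map: np.ndarray, periodic: bool = True) -> np.ndarray:
    """2D spatial Pearson autocorrelation of a rate map.

    Returns an odd-sided raster with value exactly 1 at the centre pixel and
    the point symmetry C(d) = C(-d).  For ``periodic`` maps the correlation
    at each lag is taken over the full (wrapped) overlap, which is the exact
    Pearson correlation of the map with its cyclic shift.  For non-periodic
    maps a masked sliding Pearson correlation is used (each lag normalised
    over the overlapping region only).
    """
    f = np.asarray(rate_map, dtype=float)
    if f.ndim != 2:
        raise ValueError("rate map must be 2D")
    if np.ptp(f) == 0:
        raise ValueError("constant rate map has no autocorrelogram")
    ny, nx = f.shape
    if periodic:
        g = f - f.mean()
        denom = np.sum(g * g)
        F = np.fft.fft2(g)
        ac = np.fft.ifft2(F * np.conj(F)).real / denom
        ac = np.fft.fftshift(ac)
        cy, cx = ny // 2, nx // 2
        # crop to odd side so the zero-lag pixel is the exact centre
        r = min(cy, cx, ny - 1 - cy, nx - 1 - cx)
        return ac[cy - r : cy + r + 1, cx - r : cx + r + 1]
    return _masked_autocorrelogram(f)


def _masked_autocorrelogram(f: np.ndarray) -> np.ndarray:
    """Sliding Pearson autocorrelation over overlapping pixels (FFT sums)."""
    ny, nx = f.shape
    ones = np.ones_like(f)

    def xcorr(a, b):
        # full linear cross-correlation sum_x a(x) b(x+d) via zero-padded FFT
        pa = np.fft.fft2(a, s=(2 * ny - 1, 2 * nx - 1))
        pb = np.fft.fft2(b, s=(2 * ny - 1, 2 * nx - 1))
        return np.fft.fftshift(np.fft.ifft2(pa * np.conj(pb)).real)

    n = xcorr(ones, ones)
    sf = xcorr(f, ones)
    sg = xcorr(ones, f)
    sff = xcorr(f * f, ones)
    sgg = xcorr(ones, f * f)
    sfg = xcorr(f, f)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = sfg - sf * sg / n
        var1 = sff - sf * sf / n
        var2 = sgg - sg * sg / n
        ac = num / np.sqrt(var1 * var2)
    ac[n < 20] = np.nan  # too little overlap for a meaningful correlation
    c = np.array(ac.shape) // 2
    ac[tuple(c)] = 1.0
    return ac


def find_peaks(ac: np.ndarray, smooth_sigma: float = 1.0, max_peaks: int = 6) -> np.ndarray:
    """Off-centre local maxima of an autocorrelogram, nearest first.

    Returns (n, 2) array of (dy, dx) pixel offsets from the centre of the
    ``max_peaks`` nearest peaks.  Peaks are 8-neighbourhood local maxima of
    the lightly smoothed autocorrelogram with positive correlation.
    """
    a = np.asarray(ac, dtype=float)
    finite = np.isfinite(a)
    a = np.where(finite, a, -np.inf)
    if smooth_sigma > 0:
        sm = ndimage.gaussian_filter(np.where(finite, ac, 0.0), smooth_sigma, mode="nearest")
        norm = ndimage.gaussian_filter(finite.astype(float), smooth_sigma, mode="nearest")
        with np.errstate(invalid="ignore"):
            a = np.where(norm > 0, sm / norm, -np.inf)
    cy, cx = np.array(a.shape) // 2
    local_max = (a == ndimage.maximum_filter(a, size=3, mode="nearest")) & np.isfinite(a) & (a > 0)
    ys, xs = np.nonzero(local_max)
    dy, dx = ys - cy, xs - cx
    dist = np.hypot(dy, dx)
    # exclude the central peak (and its smoothing plateau)
    keep = dist > 2.0
    dy, dx, dist = dy[keep], dx[keep], dist[keep]
    if len(dist) == 0:
        return np.empty((0, 2), dtype=int)
    order = np.argsort(dist)[:max_peaks]
    return np.column_stack([dy[order], dx[order]])


def _annulus(ac_shape, peaks: np.ndarray) -> tuple[float, float]:
    """Ring radii (pixels) framing the six nearest peaks; fallback when absent."""
    half = min(ac_shape) // 2
    if len(peaks) >= 6:
        d = np.hypot(peaks[:, 0], peaks[:, 1])
        inner = 0.5 * d.min()
        outer = min(1.25 * np.sort(d)[5], half)
    else:
        inner, outer = 0.2 * half, 0.7 * half
    if inner >= outer:
        inner, outer = 0.2 * half, 0.7 * half
    return inner, outer


def _rotational_correlations(ac: np.ndarray, angles, inner: float, outer: float) -> dict:
    """Pearson correlation of the ring with its rotations, one per angle."""
    a = np.asarray(ac, dtype=float)
    cy, cx = np.array(a.shape) // 2
    yy, xx = np.indices(a.shape)
    rr = np.hypot(yy - cy, xx - cx)
    ring = (rr >= inner) & (rr <= outer)
    base_valid = np.isfinite(a)
    filled = np.where(base_valid, a, 0.0)
    out = {}
    for ang in angles:
        rot = ndimage.rotate(filled, ang, reshape=False, order=1, mode="constant", cval=np.nan)
        rot_valid = ndimage.rotate(
            base_valid.astype(float), ang, reshape=False, order=1, mode="constant", cval=0.0
        )
        mask = ring & base_valid & np.isfinite(rot) & (rot_valid > 0.99)
        x, y = a[mask], rot[mask]
        if len(x) < 10 or x.std() == 0 or y.std() == 0:
            out[ang] = 0.0
        else:
            out[ang] = float(np.corrcoef(x, y)[0, 1])
    return out


def gridness60(ac: np.ndarray, smooth_sigma: float = 1.0) -> float:
    """Hexagonal gridness: (C60+C120)/2 - (C30+C90+C150)/3 on the peak ring."""
    peaks = find_peaks(ac, smooth_sigma)
    inner, outer = _annulus(ac.shape, peaks)
    c = _rotational_correlations(ac, (30, 60, 90, 120, 150), inner, outer)
    return 0.5 * (c[60] + c[120]) - (c[30] + c[90] + c[150]) / 3.0


def gridness90(ac: np.ndarray, smooth_sigma: float = 1.0) -> float:
    """Square gridness: C90 - (C45+C135)/2 on the peak ring."""
    peaks = find_peaks(ac, smooth_sigma)
    inner, outer = _annulus(ac.shape, peaks)
    c = _rotational_correlations(ac, (45, 90, 135), inner, outer)
    return c[90] - 0.5 * (c[45] + c[135])


def grid_spacing(ac: np.ndarray, pixel_size: float = 1.0, smooth_sigma: float = 1.0) -> float:
    """Median distance from the centre to the six nearest peaks, arena units."""
    peaks = find_peaks(ac, smooth_sigma)
    if len(peaks) < 6:
        return float("nan")
    d = np.hypot(peaks[:, 0], peaks[:, 1])
    return float(np.median(d) * pixel_size)


def grid_orientation(ac: np.ndarray, smooth_sigma: float = 1.0) -> float:
    """Angle (degrees, folded to [-30, 30)) of the peak nearest the +x axis."""
    peaks = find_peaks(ac, smooth_sigma)
    if len(peaks) < 6:
        return float("nan")
    ang = np.degrees(np.arctan2(peaks[:, 0], peaks[:, 1]))  # (dy, dx)
    folded = (ang + 30.0) % 60.0 - 30.0
    return float(folded[np.argmin(np.abs(folded))])


def grid_alignment(alpha: float) -> float:
    """Minimal angle between the grid axes and the box axes: min(|a|, 30-|a|)."""
    if np.isnan(alpha):
        return float("nan")
    a = abs(alpha)
    return float(min(a, 30.0 - a))


def score_map(
    rate_map: np.ndarray,
    pixel_size: float = 1.0,
    periodic: bool = True,
    smooth_sigma: float = 1.0,
) -> GridScore:
    """All grid statistics of one rate map."""
    ac = autocorrelogram(rate_map, periodic=periodic)
    alpha = grid_orientation(ac, smooth_sigma)
    return GridScore(
        gridness60=gridness60(ac, smooth_sigma),
        gridness90=gridness90(ac, smooth_sigma),
        spacing=grid_spacing(ac, pixel_size, smooth_sigma),
        orientation=alpha,
        alignment=grid_alignment(alpha),
    )


def detect_modules(
    spacings: np.ndarray,
    gridness: np.ndarray | None = None,
    gridness_threshold: float = 0.7,
    min_ratio: float = 1.1,
    max_iter: int = 100,
):
    """Two-cluster split of grid spacings into modules.

    Clusters log-spacings of maps whose gridness exceeds the threshold with
    1D 2-means; returns ``(labels, ratio)`` where ratio = larger centroid /
    smaller centroid, or ``(labels, None)`` when only a single module is
    resolvable (all spacings equal, or the centroid ratio below
    ``min_ratio``).  Labels are 0 for the small-spacing module, 1 for the
    large one, -1 for maps excluded by the gridness threshold.
    """
    spacings = np.asarray(spacings, dtype=float)
    labels = np.full(len(spacings), -1, dtype=int)
    sel = np.isfinite(spacings)
    if gridness is not None:
        sel &= np.asarray(gridness, dtype=float) > gridness_threshold
    s = spacings[sel]
    if len(s) < 2:
        raise ValueError("need at least 2 qualifying maps to detect modules")
    x = np.log(s)
    if np.ptp(x) == 0:
        labels[sel] = 0
        return labels, None
    c = np.array([x.min(), x.max()])
    assign = np.zeros(len(x), dtype=int)
    for _ in range(max_iter):
        new = (np.abs(x - c[1]) < np.abs(x - c[0])).astype(int)
        if np.array_equal(new, assign) and _ > 0:
            break
        assign = new
        for k in (0, 1):
            if np.any(assign == k):
                c[k] = x[assign == k].mean()
    if not (np.any(assign == 0) and np.any(assign == 1)):
        labels[sel] = 0
        return labels, None
    centroids = np.exp(c)
    ratio = float(centroids.max() / centroids.min())
    if ratio < min_ratio:
        labels[sel] = 0
        return labels, None
    # label 0 = smaller spacing
    small = int(np.argmin(c))
    labels[sel] = (assign != small).astype(int)
    return labels, ratio
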