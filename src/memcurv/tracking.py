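"""Vesicle contour detection on 2-D confocal slices.

The vesicle membrane appears as a bright ring.  Detection proceeds in three
steps, each with sub-pixel care:

1. :func:`detect_contour` — interpolate the (Gaussian pre-smoothed) image
   along rays cast outward from a rough centre estimate; the intensity
   maximum along each ray estimates the perimeter.
2. :func:`refine_subpixel` — around each per-ray maximum, fit a line to the
   discrete derivative in a 5-sample window; its zero crossing is the
   sub-pixel perimeter radius.
3. :func:`fit_circle` — algebraic least-squares circle through the refined
   perimeter points.

Overlapping particle signals are refined by a two-Gaussian least-squares
fit (:func:`refine_overlapping_pair`).

Coordinate convention: pixel centres at integer coordinates, origin at the
first pixel, x = column, y = row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .errors import SingularFitError


@dataclass
class ContourFit:
    """Least-squares circle fit of a vesicle contour."""

    centre: tuple[float, float]      # (x_c, y_c) [px]
    radius: float                    # [px]
    points: np.ndarray               # (N, 2) perimeter points used
    residual_rms: float              # [px]
    n_rays: int = 0
    n_dropped: int = 0


def detect_contour(
    image: np.ndarray,
    centre_guess: tuple[float, float],
    n_rays: int = 180,
    step: float = 1.0,
    smooth_sigma: float = 1.0,
    r_max: float | None = None,
) -> pd.DataFrame:
    """Per-ray radial intensity maxima around ``centre_guess``.

    Returns a frame with columns ``angle``, ``radius`` (arg-max along the
    ray, in px from the guess), ``radius_refined`` (sub-pixel), and ``ok``.
    Rays whose maximum falls at the profile ends (no interior edge before
    leaving the image) are flagged ``ok = False`` and dropped from counts.
    """
    if n_rays < 8:
        raise ValueError("need at least 8 rays")
    img = np.asarray(image, dtype=float)
    ny, nx = img.shape
    xc, yc = centre_guess
    if not (0 <= xc < nx and 0 <= yc < ny):
        raise ValueError("centre guess outside the image")
    if smooth_sigma > 0:
        img = ndimage.gaussian_filter(img, smooth_sigma)
    if r_max is None:
        r_max = float(np.hypot(nx, ny))
    angles = np.linspace(0.0, 2 * np.pi, n_rays, endpoint=False)
    rows = []
    for th in angles:
        dx, dy = np.cos(th), np.sin(th)
        # radii until the ray leaves the frame
        n_steps = int(r_max / step)
        r = np.arange(n_steps) * step
        x = xc + r * dx
        y = yc + r * dy
        inside = (x >= 0) & (x <= nx - 1) & (y >= 0) & (y <= ny - 1)
        r, x, y = r[inside], x[inside], y[inside]
        if len(r) < 5:
            rows.append((th, np.nan, np.nan, False))
            continue
        prof = ndimage.map_coordinates(img, np.vstack([y, x]), order=1)
        k = int(np.argmax(prof))
        if k < 2 or k > len(prof) - 3 or prof[k] <= prof.mean() + 1e-12:
            rows.append((th, np.nan, np.nan, False))
            continue
        refined, ok = refine_subpixel(prof, k)
        rows.append((th, r[k], refined * step, ok))
    return pd.DataFrame(rows, columns=["angle", "radius", "radius_refined", "ok"])


def refine_subpixel(profile: np.ndarray, peak_index: int, window: int = 5) -> tuple[float, bool]:
    """Sub-pixel peak position via linear regression on the discrete derivative.

    Within a ``window``-sample region centred on the peak, the discrete
    first difference crosses zero at the peak; a straight-line fit to the
    differences locates that crossing at sub-pixel resolution.  Returns
    ``(position, ok)``; on a degenerate profile (non-negative slope) the
    integer peak is returned with ``ok = False``.
    """
    prof = np.asarray(profile, dtype=float)
    half = window // 2
    if peak_index < half or peak_index > len(prof) - half - 1:
        return float(peak_index), False
    lo, hi = peak_index - half, peak_index + half
    d = np.diff(prof[lo:hi + 1])              # derivative samples at lo+0.5 ...
    pos = np.arange(lo, hi) + 0.5
    A = np.vstack([pos, np.ones_like(pos)]).T
    slope, intercept = np.linalg.lstsq(A, d, rcond=None)[0]
    if slope >= 0:
        return float(peak_index), False
    x0 = -intercept / slope
    if not (lo <= x0 <= hi):
        return float(peak_index), False
    return float(x0), True


def fit_circle(points: np.ndarray) -> ContourFit:
    """Algebraic (Kasa) least-squares circle through 2-D points.

    Solves the linearised system ``x^2 + y^2 = 2 a x + 2 b y + c``; exact
    for three non-collinear points.  Collinear or coincident points raise
    :class:`SingularFitError`.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise SingularFitError("need at least 3 points")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x ** 2 + y ** 2
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise SingularFitError("points are collinear or coincident")
    a, bb, c = sol
    r2 = c + a ** 2 + bb ** 2
    if r2 <= 0:
        raise SingularFitError("degenerate circle")
    radius = float(np.sqrt(r2))
    resid = np.sqrt((x - a) ** 2 + (y - bb) ** 2) - radius
    return ContourFit(
        centre=(float(a), float(bb)),
        radius=radius,
        points=pts,
        residual_rms=float(np.sqrt(np.mean(resid ** 2))),
    )


def track_vesicle(
    image: np.ndarray,
    centre_guess: tuple[float, float],
    n_rays: int = 180,
    smooth_sigma: float = 1.0,
) -> ContourFit:
    """Full pipeline: rays -> sub-pixel perimeter -> circle fit."""
    det = detect_contour(image, centre_guess, n_rays=n_rays, smooth_sigma=smooth_sigma)
    ok = det[det["ok"]]
    xc, yc = centre_guess
    pts = np.column_stack([
        xc + ok["radius_refined"] * np.cos(ok["angle"]),
        yc + ok["radius_refined"] * np.sin(ok["angle"]),
    ])
    fit = fit_circle(pts)
    fit.n_rays = n_rays
    fit.n_dropped = int(n_rays - len(ok))
    return fit


def _two_gaussians(params, x, y):
    x1, y1, x2, y2, a1, a2, sig, bg = params
    g1 = a1 * np.exp(-((x - x1) ** 2 + (y - y1) ** 2) / (2 * sig ** 2))
    g2 = a2 * np.exp(-((x - x2) ** 2 + (y - y2) ** 2) / (2 * sig ** 2))
    return g1 + g2 + bg


def refine_overlapping_pair(
    patch: np.ndarray,
    guesses: tuple[tuple[float, float], tuple[float, float]],
    sigma_guess: float = 1.5,
) -> tuple[np.ndarray, bool]:
    """Refine two overlapping spot centres by a two-Gaussian + background fit.

    Centre-of-mass tracking biases overlapping features towards each other;
    the joint fit removes that bias.  Returns ``(centres (2,2), converged)``;
    on failure (no convergence, or the two Gaussians collapsing onto one
    another) the input guesses are returned flagged ``False``.
    """
    img = np.asarray(patch, dtype=float)
    (x1, y1), (x2, y2) = guesses
    ny, nx = img.shape
    if not (0 <= x1 < nx and 0 <= y1 < ny and 0 <= x2 < nx and 0 <= y2 < ny):
        raise ValueError("guesses must lie inside the patch")
    sep0 = np.hypot(x2 - x1, y2 - y1)
    if sep0 <= 0:
        raise ValueError("guesses must be distinct")
    y, x = np.mgrid[0:ny, 0:nx]
    amp0 = float(img.max() - img.min())
    p0 = np.array([x1, y1, x2, y2, amp0, amp0, sigma_guess, float(img.min())])

    def resid(p):
        return (_two_gaussians(p, x, y) - img).ravel()

    try:
        res = optimize.least_squares(resid, p0, max_nfev=2000)
    except Exception:
        return np.array(guesses, dtype=float), False
    c = np.array([[res.x[0], res.x[1]], [res.x[2], res.x[3]]])
    sep = np.hypot(*(c[1] - c[0]))
    degenerate = (sep < 0.2) or (min(abs(res.x[4]), abs(res.x[5])) < 0.05 * amp0)
    if not res.success or degenerate or not np.all(np.isfinite(c)):
        return np.array(guesses, dtype=float), False
    return c, True
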