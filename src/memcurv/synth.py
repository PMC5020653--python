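"""Synthetic data generators with known ground truth.

Every generator returns its ground truth alongside the data, so downstream
analyses can be tested closed-loop (generate -> analyse -> compare):

* :func:`simulate_pair_on_sphere` — two particles diffusing on a spherical
  vesicle under a prescribed pair potential u(s), emitted in the exact
  format of an experimental trajectory table (2-D image coordinates plus
  vesicle centre/radius).
* :func:`render_vesicle_image` — a confocal-like 2-D slice: a Gaussian ring
  for the vesicle equator plus Gaussian spots for particles, with
  Poisson-Gaussian noise at a prescribed SNR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SphereBrownianConfig:
    """Conditions for the Brownian pair-on-a-sphere generator.

    Defaults mimic the tracking experiments: a micron-sized particle
    (D ~ 0.4 um^2/s on a membrane), video-rate sampling, a vesicle of
    ~10 um diameter.  The imposed potential is a callable u(s) in kBT
    (s in um); ``None`` means non-interacting.
    """

    R: float = 5.0               # vesicle radius [um]
    D: float = 0.4               # diffusion coefficient [um^2/s]
    dt: float = 0.05             # frame interval [s]
    n_steps: int = 20000
    D_p: float = 1.0             # particle diameter [um]
    wrapped: bool = True
    potential: object = None     # callable u(s) -> kBT, or None
    substeps: int = 5            # integrator steps per recorded frame
    seed: int = 0

    def __post_init__(self):
        if min(self.R, self.D, self.dt) <= 0:
            raise ValueError("R, D and dt must be > 0")
        if self.substeps < 1:
            raise ValueError("substeps must be >= 1")
        if np.sqrt(2 * self.D * self.dt) > 0.2 * self.R:
            raise ValueError("time step too large: rms step exceeds 0.2 R")


def gaussian_well(depth: float, s0: float, width: float):
    """Tabulated-potential helper: ``u(s) = -depth * exp(-(s-s0)^2/2w^2)``."""

    def u(s):
        return -depth * np.exp(-0.5 * ((np.asarray(s, float) - s0) / width) ** 2)

    return u


def _rotate_about(u, axis, angle):
    """Rodrigues rotation of unit vector(s) u about unit ``axis``."""
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(angle), np.sin(angle)
    return u * c + np.cross(axis, u) * s + axis * np.dot(axis, u) * (1 - c)


def simulate_pair_on_sphere(config: SphereBrownianConfig) -> tuple[pd.DataFrame, dict]:
    """Overdamped Brownian dynamics of two particles on a sphere.

    Each integrator step adds an isotropic tangent-plane Gaussian
    displacement of variance ``2 D dt_sub`` per axis plus the deterministic
    drift ``-D dt_sub du/ds`` directed along the great circle towards/away
    from the partner, then re-projects radially onto the sphere
    (Euler-Maruyama with projection).  ``substeps`` integrator steps of
    ``dt_sub = dt / substeps`` are taken per recorded frame, which keeps the
    integrator bias (O(D dt_sub / w^2) for a potential of width w) well
    below the statistical resolution of the inference tests.

    Returns ``(table, truth)``: the table has the experimental trajectory
    format (columns frame, particle, x_um, y_um, wrapped, xc_um, yc_um,
    R_um, segment) where x/y are image-plane projections and ``segment``
    increments whenever the two particles stop sharing a hemisphere (the
    condition under which 2-D -> 3-D reconstruction is exact); the truth
    dict carries the 3-D positions and true geodesic separations.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    R_track = cfg.R + (-0.5 * cfg.D_p if cfg.wrapped else 0.5 * cfg.D_p)
    # particle centres live on the sphere of radius R_track; separations
    # (and the imposed potential's argument) are membrane-attachment
    # geodesics, i.e. arc length on the vesicle sphere of radius R
    u1 = np.array([0.0, 0.0, 1.0])
    u2 = _rotate_about(u1, np.array([1.0, 0.0, 0.0]), 0.3 * np.pi)
    dt_sub = cfg.dt / cfg.substeps
    sigma = np.sqrt(2 * cfg.D * dt_sub)
    pos = np.empty((cfg.n_steps, 2, 3))
    sep = np.empty(cfg.n_steps)
    eps = 1e-7
    for t in range(cfg.n_steps * cfg.substeps):
        for u, v in ((u1, u2), (u2, u1)):
            # tangent basis at u
            ref = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
            e1 = np.cross(u, ref)
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(u, e1)
            step = sigma * rng.standard_normal(2)
            disp = step[0] * e1 + step[1] * e2
            if cfg.potential is not None:
                cosang = np.clip(np.dot(u, v), -1.0, 1.0)
                s = cfg.R * np.arccos(cosang)
                du = (cfg.potential(s + eps) - cfg.potential(s - eps)) / (2 * eps)
                # unit tangent at u pointing away from v along the great circle;
                # dU/d(arc on the tracking sphere) = u'(s) * R / R_track
                tdir = u * cosang - v
                nt = np.linalg.norm(tdir)
                if nt > 1e-12:
                    # drift = -D dU/d(arc): down the energy gradient
                    disp -= cfg.D * dt_sub * du * (cfg.R / R_track) * (tdir / nt)
            w = u + disp / R_track
            w /= np.linalg.norm(w)
            u[:] = w
        if (t + 1) % cfg.substeps:
            continue
        f = (t + 1) // cfg.substeps - 1
        pos[f, 0] = u1 * R_track
        pos[f, 1] = u2 * R_track
        sep[f] = cfg.R * np.arccos(np.clip(np.dot(u1, u2), -1, 1))
    # observation window: frames are recorded only while both particles
    # share a hemisphere (both near the same vesicle pole, where the 2-D
    # depth reconstruction is exact); contiguous recorded runs form segments
    same = np.sign(pos[:, 0, 2]) == np.sign(pos[:, 1, 2])
    seg_all = np.concatenate([[0], np.cumsum(np.abs(np.diff(same.astype(int))))]).astype(int)
    frames = np.arange(cfg.n_steps)
    rows = []
    for k in (0, 1):
        rows.append(pd.DataFrame({
            "frame": frames[same],
            "particle": k,
            "x_um": pos[same, k, 0],
            "y_um": pos[same, k, 1],
            "wrapped": cfg.wrapped,
            "xc_um": 0.0,
            "yc_um": 0.0,
            "R_um": cfg.R,
            "segment": seg_all[same],
        }))
    table = pd.concat(rows, ignore_index=True).sort_values(["frame", "particle"], kind="stable")
    truth = {
        "positions": pos,
        "separations": sep,
        "R_track": R_track,
        "config": cfg,
        "same_hemisphere": same,
    }
    return table.reset_index(drop=True), truth


# ---------------------------------------------------------------------------
# synthetic confocal slices
# ---------------------------------------------------------------------------

def render_vesicle_image(
    R: float,
    centre: tuple[float, float],
    shape: tuple[int, int] = (256, 256),
    ring_width: float = 2.0,
    snr: float = 10.0,
    particle_positions: tuple | list = (),
    particle_sigma: float = 1.5,
    particle_amplitude: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Render a 2-D vesicle slice: Gaussian ring + Gaussian particle spots.

    Coordinates are (x = column, y = row) with pixel centres at integer
    positions.  ``snr`` is the ring peak amplitude divided by the noise
    standard deviation at the peak (Poisson photon noise plus Gaussian read
    noise); ``snr = inf`` renders the noiseless field.  Returns the image
    (float, shape (rows, cols)) and the ground-truth dict.
    """
    ny, nx = shape
    xc, yc = centre
    if not (0 <= xc < nx and 0 <= yc < ny):
        raise ValueError("vesicle centre must be inside the frame")
    if R + 2 * ring_width > max(nx, ny):
        raise ValueError("vesicle does not fit in the frame")
    y, x = np.mgrid[0:ny, 0:nx]
    rho = np.sqrt((x - xc) ** 2 + (y - yc) ** 2)
    img = np.exp(-0.5 * ((rho - R) / ring_width) ** 2)
    for (px, py) in particle_positions:
        img += particle_amplitude * np.exp(
            -0.5 * (((x - px) ** 2 + (y - py) ** 2) / particle_sigma ** 2))
    if np.isfinite(snr):
        rng = np.random.default_rng(seed)
        # split noise budget between photon (Poisson) and read (Gaussian) noise
        var_peak = 1.0 / snr ** 2
        n_photons = 2.0 / var_peak           # Poisson contributes var_peak/2 at peak
        read_sigma = np.sqrt(var_peak / 2.0)
        img = rng.poisson(img * n_photons) / n_photons + read_sigma * rng.standard_normal(img.shape)
    truth = {
        "R": R,
        "centre": (xc, yc),
        "ring_width": ring_width,
        "snr": snr,
        "particles": list(particle_positions),
        "particle_sigma": particle_sigma,
    }
    return img, truth
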