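"""Inference of the pair interaction u(s) from particle trajectories.

The experimental observables are 2-D image-plane tracks of two particles
bound to a spherical vesicle, plus the tracked vesicle centre and radius.
The pipeline is:

1. :func:`reconstruct_3d` — lift each 2-D position onto the sphere of radius
   ``R + h``, where ``h = +D_p/2`` for a non-wrapped particle (outside) and
   ``-D_p/2`` for a wrapped one (protruding inside).
2. :func:`geodesic_separation` — great-circle distance between the two
   particles' membrane attachment points (radial projections).
3. :func:`build_transition_matrix` — binned separation transition counts
   ``C_ij`` at a fixed frame lag; segments are pooled by summing counts.
4. :func:`stationary_distribution` — stationary vector of the row-normalised
   transition matrix (after detailed-balance symmetrisation).
5. :func:`potential_from_distribution` — Boltzmann inversion
   ``u(s) = -ln(pi(s) / J(s)) + c`` with the spherical density of states
   ``J(s) ~ sin(s/R)``, zeroed on the far-field third of the visited bins.

The transition-matrix route equals a plain Boltzmann histogram for
perfectly equilibrated data but is robust to trajectories that sample
separations unevenly in time.

The depth-coordinate sign is not observable in a single 2-D slice; it is
taken constant within a trajectory segment.  Geodesic separations are
unchanged under a simultaneous sign flip of both particles' depth, so the
convention is exact whenever the two particles are on the same hemisphere,
and segments should be split where that stops holding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .errors import (
    InsufficientDataError,
    OffsetUndefinedError,
    OutOfSphereError,
    UndefinedDirectionError,
)

REQUIRED_COLUMNS = ("frame", "particle", "x_um", "y_um", "wrapped", "xc_um", "yc_um", "R_um")


def validate_trajectories(df: pd.DataFrame) -> pd.DataFrame:
    """Check a trajectory table and return it with a ``segment`` column."""
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing trajectory column {col!r}")
    if df["R_um"].min() <= 0:
        raise ValueError("vesicle radius must be > 0")
    if df["frame"].min() < 0:
        raise ValueError("frames must be non-negative")
    ids = np.sort(df["particle"].unique())
    if len(ids) != 2:
        raise ValueError(f"pair analysis needs exactly 2 particle ids, got {len(ids)}")
    for pid in ids:
        fr = df.loc[df["particle"] == pid, "frame"].to_numpy()
        if np.any(np.diff(fr) <= 0):
            raise ValueError(f"frames of particle {pid} not strictly increasing")
    out = df.copy()
    if "segment" not in out.columns:
        out["segment"] = 0
    return out


def reconstruct_3d(
    df: pd.DataFrame,
    D_p: float,
    hemisphere_sign: int = 1,
    slack: float = 0.2,
) -> pd.DataFrame:
    """Lift 2-D tracked positions onto the vesicle sphere.

    Adds columns ``x_rel, y_rel, z_rel`` (relative to the vesicle centre)
    and ``clamped``.  The particle-centre sphere has radius ``R + h`` with
    ``h = +-D_p/2`` according to the wrapping state.  Points outside the
    projected disc by less than ``slack`` (one bin width, in um) are clamped
    onto the equator and flagged; larger excursions raise
    :class:`OutOfSphereError`.
    """
    out = df.copy()
    h = np.where(out["wrapped"].astype(bool), -0.5 * D_p, 0.5 * D_p)
    r_eff = out["R_um"].to_numpy() + h
    x = out["x_um"].to_numpy() - out["xc_um"].to_numpy()
    y = out["y_um"].to_numpy() - out["yc_um"].to_numpy()
    z2 = r_eff ** 2 - x ** 2 - y ** 2
    rho = np.sqrt(x ** 2 + y ** 2)
    over = rho - r_eff
    if np.any(over > slack):
        raise OutOfSphereError(
            f"{int(np.sum(over > slack))} points lie more than {slack} um outside "
            "the projected sphere"
        )
    clamped = z2 < 0
    scale = np.where(clamped, r_eff / np.maximum(rho, 1e-300), 1.0)
    out["x_rel"] = x * scale
    out["y_rel"] = y * scale
    out["z_rel"] = hemisphere_sign * np.sqrt(np.maximum(z2, 0.0))
    out["clamped"] = clamped
    return out


def geodesic_separation(p1, p2, R: float):
    """Great-circle distance on the sphere of radius ``R``.

    ``p1``, ``p2`` are 3-vectors (or ``(N, 3)`` arrays) of positions relative
    to the vesicle centre; the attachment points are their radial projections
    onto the membrane sphere.
    """
    a = np.atleast_2d(np.asarray(p1, dtype=float))
    b = np.atleast_2d(np.asarray(p2, dtype=float))
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    if np.any(na == 0) or np.any(nb == 0):
        raise UndefinedDirectionError("zero vector has no direction on the sphere")
    cosang = np.clip(np.einsum("ij,ij->i", a, b) / (na * nb), -1.0, 1.0)
    s = R * np.arccos(cosang)
    return float(s[0]) if np.asarray(p1).ndim == 1 else s


def separation_series(df: pd.DataFrame, D_p: float, slack: float = 0.2) -> list[np.ndarray]:
    """Per-segment geodesic separation time series from a trajectory table.

    The depth sign is constant per segment; since geodesic separations are
    invariant under a joint sign flip, reconstruction uses the ``+`` sign
    throughout and the per-segment convention is exact.
    """
    df = validate_trajectories(df)
    ids = np.sort(df["particle"].unique())
    rec = reconstruct_3d(df, D_p, slack=slack)
    a = rec[rec["particle"] == ids[0]].set_index("frame")
    b = rec[rec["particle"] == ids[1]].set_index("frame")
    common = a.index.intersection(b.index)
    if len(common) == 0:
        return []
    cols = ["x_rel", "y_rel", "z_rel"]
    pa = a.loc[common, cols].to_numpy()
    pb = b.loc[common, cols].to_numpy()
    R = float(a.loc[common, "R_um"].mean())
    s = np.asarray(geodesic_separation(pa, pb, R))
    seg_ids = a.loc[common, "segment"].to_numpy()
    cuts = np.nonzero(np.diff(seg_ids) != 0)[0] + 1
    return [chunk for chunk in np.split(s, cuts) if len(chunk)]


@dataclass
class TransitionMatrix:
    """Binned separation transition counts and row-normalised probabilities.

    ``boundary_bins`` records the bins of the first/last ``lag`` samples of
    every segment: those samples enter only half as many ordered pairs as
    interior ones, and the stationary estimator compensates for that.
    """

    bin_edges: np.ndarray
    counts: np.ndarray      # C_ij, integer ordered-pair counts
    lag: int
    boundary_bins: np.ndarray | None = None

    @property
    def probabilities(self) -> np.ndarray:
        """Row-normalised ``P_ij``; empty rows stay all-zero (flagged)."""
        rows = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            P = np.where(rows > 0, self.counts / np.maximum(rows, 1), 0.0)
        return P

    @property
    def empty_rows(self) -> np.ndarray:
        return np.nonzero(self.counts.sum(axis=1) == 0)[0]

    @property
    def bin_centres(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def build_transition_matrix(
    series: np.ndarray | list,
    bin_edges: np.ndarray,
    lag: int = 1,
) -> TransitionMatrix:
    """Count binned transitions ``s(t) -> s(t + lag)`` within each segment.

    ``series`` is one separation time series or a list of them (segments /
    vesicles); counts are pooled by summation before any normalisation.
    """
    if isinstance(series, np.ndarray) and series.ndim == 1:
        series = [series]
    bin_edges = np.asarray(bin_edges, dtype=float)
    n = len(bin_edges) - 1
    C = np.zeros((n, n), dtype=np.int64)
    total = 0
    boundary = []
    for s in series:
        s = np.asarray(s, dtype=float)
        total += len(s)
        if len(s) <= lag:
            continue
        idx = np.digitize(s, bin_edges) - 1
        valid = (idx >= 0) & (idx < n)
        i, j = idx[:-lag], idx[lag:]
        ok = valid[:-lag] & valid[lag:]
        np.add.at(C, (i[ok], j[ok]), 1)
        ends = np.concatenate([idx[:lag], idx[-lag:]])
        boundary.extend(ends[(ends >= 0) & (ends < n)].tolist())
    for s in series:
        s = np.asarray(s, dtype=float)
        if len(s) > lag:
            continue
        # segments too short to hold a transition still carry occupancy:
        # twice in the boundary list = one full unit of stationary weight
        idx = np.digitize(s, bin_edges) - 1
        for b in idx[(idx >= 0) & (idx < n)]:
            boundary.extend([int(b), int(b)])
    if total < 2:
        raise InsufficientDataError("need at least 2 samples")
    if C.sum() == 0:
        raise InsufficientDataError("no transitions fall inside the bins")
    return TransitionMatrix(bin_edges, C, lag, np.asarray(boundary, dtype=np.int64))


def stationary_distribution(tm: TransitionMatrix) -> np.ndarray:
    """Stationary probability vector of the separation chain.

    Counts are symmetrised (``C <- (C + C^T)/2``, detailed balance of an
    equilibrium chain) and restricted to the largest communicating class;
    the leading left eigenvector of the row-normalised matrix is returned,
    zero-padded on unvisited bins.  If several disjoint classes carry data a
    warning is issued and only the largest (by counts) is used.

    Symmetrised counts weight every sample by the number of ordered pairs it
    participates in; segment-end samples participate in half as many, so
    they receive compensating half-weight self-loops (without this, heavily
    segmented data underweights the separations at which segments tend to
    end).
    """
    S = 0.5 * (tm.counts + tm.counts.T).astype(float)
    if tm.boundary_bins is not None and len(tm.boundary_bins):
        np.add.at(S, (tm.boundary_bins, tm.boundary_bins), 0.5)
    n = S.shape[0]
    ncomp, labels = connected_components(S > 0, directed=False)
    weights = np.array([S[labels == k][:, labels == k].sum() for k in range(ncomp)])
    nontrivial = np.sum(weights > 0)
    if nontrivial > 1:
        warnings.warn(
            f"{nontrivial} disjoint communicating classes; using the largest",
            RuntimeWarning,
        )
    k = int(np.argmax(weights))
    mask = (labels == k) & (S.sum(axis=1) > 0)
    sub = S[np.ix_(mask, mask)]
    P = sub / sub.sum(axis=1, keepdims=True)
    vals, vecs = np.linalg.eig(P.T)
    i = int(np.argmax(vals.real))
    pi_sub = np.abs(vecs[:, i].real)
    pi_sub /= pi_sub.sum()
    pi = np.zeros(n)
    pi[mask] = pi_sub
    return pi


@dataclass
class PotentialCurve:
    """Binned pair potential u(s) in kBT with per-bin statistics."""

    s: np.ndarray            # bin centres [um]
    u: np.ndarray            # potential [kBT]; NaN on unvisited bins
    counts: np.ndarray       # per-bin occupation counts
    stderr: np.ndarray | None = None
    bin_edges: np.ndarray | None = None
    R: float | None = None

    def to_frame(self) -> pd.DataFrame:
        d = {"s_um": self.s, "u_kBT": self.u, "n": self.counts}
        if self.stderr is not None:
            d["stderr_kBT"] = self.stderr
        return pd.DataFrame(d)


def potential_from_distribution(
    pi: np.ndarray,
    bin_edges: np.ndarray,
    R: float,
    far_field_fraction: float = 1.0 / 3.0,
    jacobian: bool = True,
    counts: np.ndarray | None = None,
    hemisphere_censored: bool = False,
) -> PotentialCurve:
    """Boltzmann inversion of the stationary separation distribution.

    ``u(s_i) = -ln(pi_i / J_i) + c`` with the geodesic density of states
    ``J_i ~ sin(s_i / R) * ds`` (the uniform measure for two independent
    points on a sphere is not flat in arc distance; omitting J fabricates a
    spurious entropic potential).  The constant ``c`` zeroes the
    count-weighted mean of ``u`` over the far-field fraction
    (largest-separation third) of the visited bins.

    With ``hemisphere_censored`` the data are known to contain only frames
    where both particles share a hemisphere (the condition under which 2-D
    reconstruction is exact); the visibility of a pair at separation angle
    ``theta`` is then ``1 - theta/pi`` (the classic random-great-circle
    result), which multiplies the density of states.
    """
    if R <= 0:
        raise ValueError("R must be > 0")
    pi = np.asarray(pi, dtype=float)
    bin_edges = np.asarray(bin_edges, dtype=float)
    s = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    widths = np.diff(bin_edges)
    visited = pi > 0
    theta = np.clip(s / R, 0.0, np.pi)
    J = np.sin(theta) * widths if jacobian else widths.copy()
    if hemisphere_censored:
        J = J * (1.0 - theta / np.pi)
    u = np.full_like(pi, np.nan)
    good = visited & (J > 0)
    u[good] = -np.log(pi[good] / J[good])
    vis_idx = np.nonzero(good)[0]
    if len(vis_idx) == 0:
        raise OffsetUndefinedError("no visited bins")
    n_far = max(int(round(far_field_fraction * len(vis_idx))), 1)
    far = vis_idx[-n_far:]
    if len(far) == 0:
        raise OffsetUndefinedError("no far-field bins to define u = 0")
    if counts is not None and np.sum(counts[far]) > 0:
        u -= float(np.average(u[far], weights=counts[far]))
    else:
        u -= np.nanmean(u[far])
    if counts is None:
        counts = np.zeros_like(pi)
    return PotentialCurve(s, u, counts, bin_edges=bin_edges, R=R)


def potential_from_histogram(
    series,
    bin_edges: np.ndarray,
    R: float,
    far_field_fraction: float = 1.0 / 3.0,
    jacobian: bool = True,
    hemisphere_censored: bool = False,
) -> PotentialCurve:
    """Naive Boltzmann inversion of the plain occupancy histogram.

    Used as an independent cross-check of the transition-matrix route: the
    two coincide for long equilibrated trajectories.
    """
    if isinstance(series, np.ndarray) and series.ndim == 1:
        series = [series]
    allsep = np.concatenate([np.asarray(s, dtype=float) for s in series])
    counts, _ = np.histogram(allsep, bins=bin_edges)
    if counts.sum() == 0:
        raise InsufficientDataError("no samples inside the bins")
    pi = counts / counts.sum()
    return potential_from_distribution(pi, bin_edges, R, far_field_fraction, jacobian,
                                       counts, hemisphere_censored)


def infer_potential(
    df: pd.DataFrame,
    D_p: float,
    bin_width: float = 0.2,
    lag: int = 1,
    jacobian: bool = True,
    far_field_fraction: float = 1.0 / 3.0,
    n_bootstrap: int = 100,
    seed: int = 0,
    bin_edges: np.ndarray | None = None,
    hemisphere_censored: bool = True,
    block_frames: int = 300,
) -> PotentialCurve:
    """Full pipeline: trajectory table -> pair potential curve.

    Uncertainty is estimated by block bootstrap: consecutive trajectory
    segments are grouped into blocks of at least ``block_frames`` samples
    (so each block spans several correlation times even when hemisphere
    censoring chops the data into short segments), the blocks are resampled
    with replacement ``n_bootstrap`` times and the potential recomputed;
    the per-bin standard deviation across replicates is reported.
    Requires at least one far-field bin to anchor u = 0.
    """
    series = separation_series(df, D_p, slack=bin_width)
    if not series:
        raise InsufficientDataError("no overlapping frames between the two particles")
    allsep = np.concatenate(series)
    if bin_edges is None:
        lo = 0.0
        hi = allsep.max() + bin_width
        bin_edges = np.arange(lo, hi + bin_width, bin_width)
    tm = build_transition_matrix(series, bin_edges, lag)
    pi = stationary_distribution(tm)
    counts, _ = np.histogram(allsep, bins=bin_edges)
    curve = potential_from_distribution(pi, bin_edges, _mean_R(df),
                                        far_field_fraction, jacobian, counts,
                                        hemisphere_censored)
    # block bootstrap over groups of consecutive segments
    if n_bootstrap > 0 and len(series) >= 1:
        rng = np.random.default_rng(seed)
        blocks = _group_segments(series, block_frames)
        if len(blocks) < 4:
            blocks = series if len(series) > 1 else _split_blocks(series[0], 10)
        reps = np.full((n_bootstrap, len(curve.s)), np.nan)
        for b in range(n_bootstrap):
            pick = []
            for i in rng.integers(0, len(blocks), len(blocks)):
                blk = blocks[i]
                pick.extend(blk if isinstance(blk, list) else [blk])
            try:
                tm_b = build_transition_matrix(pick, bin_edges, lag)
                pi_b = stationary_distribution(tm_b)
                c_b = potential_from_distribution(pi_b, bin_edges, _mean_R(df),
                                                  far_field_fraction, jacobian,
                                                  hemisphere_censored=hemisphere_censored)
                reps[b] = c_b.u
            except (InsufficientDataError, OffsetUndefinedError):
                continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            curve.stderr = np.nanstd(reps, axis=0)
    return curve


def _mean_R(df: pd.DataFrame) -> float:
    return float(df["R_um"].mean())


def _group_segments(series: list, block_frames: int) -> list[list[np.ndarray]]:
    """Group consecutive segments into blocks of >= block_frames samples."""
    blocks: list[list[np.ndarray]] = []
    cur: list[np.ndarray] = []
    n = 0
    for s in series:
        cur.append(s)
        n += len(s)
        if n >= block_frames:
            blocks.append(cur)
            cur = []
            n = 0
    if cur:
        if blocks:
            blocks[-1] = blocks[-1] + cur
        else:
            blocks.append(cur)
    return blocks


def _split_blocks(series: np.ndarray, n_blocks: int) -> list[np.ndarray]:
    series = np.asarray(series)
    n = max(len(series) // n_blocks, 1)
    return [series[i:i + n] for i in range(0, len(series), n) if len(series[i:i + n]) > 1]
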