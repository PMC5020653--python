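"""Constrained two-particle wrapping experiment.

Two adhesive particles are held (frozen) at a prescribed geodesic
separation on the vesicle; the membrane is pre-relaxed until it wraps both
particles, then annealed to its minimum-energy shape.  Scanning the
separation yields the excess curvature energy profile — the membrane-
mediated pair interaction.  The excess is referenced to the largest scanned
separation (far-field zero convention).  Separations are in units of the
particle diameter ``D_p`` and measured as the geodesic arc between the
radial projections of the particle centres onto the vesicle sphere.

There is no absolute length scale in the model: profiles for different
``(D_v, D_p)`` at fixed ratio collapse in ``s / D_p``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig
from .energy import ParticleState
from .errors import InfeasibleConfigurationError
from .mesh import build_triangulated_sphere
from .montecarlo import AnnealSchedule, McState, anneal

#: coarse-graining floor: below 1.5 D_p there are no longer two layers of
#: vertices between the particles and the discrete model loses meaning
MIN_SEPARATION = 1.5


@dataclass
class SeparationProfile:
    """Excess curvature energy vs separation, with replicate statistics."""

    separations: np.ndarray          # [D_p]
    excess_energy: np.ndarray        # [kBT], 0 at the largest separation
    stderr: np.ndarray               # [kBT]
    bending: np.ndarray              # mean absolute bending energy [kBT]
    adhesion: np.ndarray             # mean adhesion energy [kBT]
    n_replicates: np.ndarray
    flagged: np.ndarray              # replicates excluded as unwrapped
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "s_over_Dp": self.separations,
            "excess_kBT": self.excess_energy,
            "stderr_kBT": self.stderr,
            "bending_kBT": self.bending,
            "adhesion_kBT": self.adhesion,
            "n_rep": self.n_replicates,
            "n_flagged": self.flagged,
        })


def pair_positions(config: SimConfig, separation: float) -> tuple[np.ndarray, np.ndarray]:
    """Particle centres for a prescribed geodesic separation (in D_p).

    Both particles sit just outside the vesicle sphere at radial distance
    ``R_v + l_m`` with their adhesive cones pointing at the membrane; the
    arc between their radial projections is ``separation * D_p``.
    """
    if separation < MIN_SEPARATION:
        raise InfeasibleConfigurationError(
            f"separation {separation} D_p below the coarse-graining floor {MIN_SEPARATION}")
    phi = separation * config.D_p / config.R_v  # polar angle between the two
    if phi > np.pi:
        raise InfeasibleConfigurationError(
            f"separation {separation} D_p exceeds half the vesicle circumference")
    r_c = config.R_v + 0.5 * (config.l + config.D_p)
    u1 = np.array([np.sin(phi / 2), 0.0, np.cos(phi / 2)])
    u2 = np.array([-np.sin(phi / 2), 0.0, np.cos(phi / 2)])
    return r_c * u1, r_c * u2


def initialize_wrapped_pair(
    config: SimConfig,
    separation: float,
    seed: int = 0,
    plateau_tol: float = 0.05,
    capture_shell: float = 1.2,
) -> McState:
    """Build the two-particle state and pre-relax until both are wrapped.

    Wrapping proceeds in two stages.  First the adhesion cut-off is widened
    to a *capture* shell of ``capture_shell`` tether lengths above contact,
    which gives the flat membrane a gradient to fold along, and the system
    is run at T = 1 until the adhesion energy plateaus (relative change
    below ``plateau_tol`` per chunk, budget ``config.wrap_sweeps``).  Then
    the cut-off is restored to the single-layer value (``cutoff_factor *
    l_m``); the loosely captured outer vertices release and the remaining
    contact layer is locked — its population stays constant from here on,
    which is the precondition for reading the membrane-mediated interaction
    off the bending energy alone.  The particles are immobilised (their
    positions are the scan's control variables).
    """
    from dataclasses import replace as _replace

    c1, c2 = pair_positions(config, separation)
    mesh = build_triangulated_sphere(config.vertex_count(), config.R_v,
                                     l_min=config.l, l_max=config.l_max)
    m = mesh.measure()
    params = config.energy_params(A_t=config.area_factor * m.total_area,
                                  V_t=m.enclosed_volume)
    capture_factor = 1.0 + capture_shell * config.l / params.l_m
    particles = [
        ParticleState(c1, config.D_p, -c1 / np.linalg.norm(c1), mobile=False),
        ParticleState(c2, config.D_p, -c2 / np.linalg.norm(c2), mobile=False),
    ]
    state = McState.from_mesh(
        mesh, particles,
        _replace(params, cutoff_factor=max(capture_factor, params.cutoff_factor)),
        seed=seed, amp_vertex=config.amp_vertex, amp_particle=config.amp_particle)
    chunk = max(config.wrap_sweeps // 10, 1)
    prev = None
    for _ in range(10):
        trace = state.run(chunk, 1.0, config.flip_fraction)
        adh = float(trace["adhesion"].iloc[-chunk // 4:].mean())
        if prev is not None and abs(adh - prev) < plateau_tol * abs(adh):
            break
        prev = adh
    state.params = params
    state._refresh()
    state.run(max(chunk // 2, 1), 1.0, config.flip_fraction)
    return state


def adhering_counts(state: McState) -> np.ndarray:
    """Number of vertices adhering to each particle."""
    return (state.adh < -1e-9).sum(axis=0)


def _rot_y(p: np.ndarray, theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    out = p.copy()
    out[..., 0] = c * p[..., 0] + s * p[..., 2]
    out[..., 2] = -s * p[..., 0] + c * p[..., 2]
    return out


def _set_pair_separation(state: McState, config: SimConfig, separation: float) -> None:
    """Rotate the two frozen particles to a new geodesic separation.

    Each particle is rotated about the vesicle centre (in the xz great-
    circle plane); the membrane vertices inside its adhesive pocket are
    co-rotated rigidly, so particle-vertex hard cores are preserved exactly
    even for vertices pressed against the contact distance.  A short
    projection pass separates any vertex pairs pushed inside the tether
    hard core at the pocket boundary.
    """
    from scipy.spatial import cKDTree

    phi = separation * config.D_p / config.R_v
    alpha = np.arctan2(state.ppos[:2, 0], state.ppos[:2, 2])  # current angles
    target = np.array([phi / 2, -phi / 2])
    deltas = target - alpha
    d0 = np.linalg.norm(state.pos - state.ppos[0], axis=1)
    d1 = np.linalg.norm(state.pos - state.ppos[1], axis=1)
    # smooth co-rotation field: rigid (weight 1) inside the adhesive shell,
    # decaying linearly to 0 over two tether lengths beyond it, so no vertex
    # pair is compressed abruptly at the pocket boundary
    pocket_r = state.params.r_cut
    falloff = 2.0 * state.params.l

    def weight(d):
        return np.clip(1.0 - (d - pocket_r) / falloff, 0.0, 1.0)

    theta_v = weight(d0) * deltas[0] + weight(d1) * deltas[1]
    moved = theta_v != 0.0
    # _rot_y(p, theta) increases the position angle alpha = atan2(x, z)
    c, s = np.cos(theta_v[moved]), np.sin(theta_v[moved])
    x, z = state.pos[moved, 0].copy(), state.pos[moved, 2].copy()
    state.pos[moved, 0] = c * x + s * z
    state.pos[moved, 2] = -s * x + c * z
    for i in range(2):
        state.ppos[i] = _rot_y(state.ppos[i], deltas[i])
        state.paxis[i] = -state.ppos[i] / np.linalg.norm(state.ppos[i])
    # constraint-projection passes: separate vertex pairs inside the tether
    # hard core (possible at the pocket boundary) and push vertices back out
    # of the particle hard cores; residual vertex-pair violations are left
    # to the engine's repair moves, but particle cores must be strict
    l_min = state.params.l
    lm = state.params.l_m
    for _ in range(60):
        dirty = False
        pairs = cKDTree(state.pos).query_pairs(l_min * (1 - 1e-12), output_type="ndarray")
        for a, b in pairs:
            d = state.pos[b] - state.pos[a]
            r = np.linalg.norm(d)
            if r < 1e-12:
                continue
            push = 0.3 * (l_min * (1 + 1e-9) - r)
            state.pos[a] -= push * d / r
            state.pos[b] += push * d / r
            dirty = True
        for i in range(2):
            d = state.pos - state.ppos[i]
            r = np.linalg.norm(d, axis=1)
            bad = r < lm * (1 - 1e-12)
            if bad.any():
                state.pos[bad] = state.ppos[i] + d[bad] * (lm * (1 + 1e-9) / r[bad])[:, None]
                dirty = True
        if not dirty:
            break
    for i in range(2):
        d = np.linalg.norm(state.pos - state.ppos[i], axis=1)
        if d.min() < lm * (1 - 1e-9):
            raise InfeasibleConfigurationError(
                f"particle {i} overlaps membrane after moving to s={separation} D_p")
    state._refresh()


def drag_separation_scan(
    config: SimConfig,
    separations,
    n_replicates: int = 4,
    drag_temperature: float = 0.1,
    drag_step: float = 0.02,
    drag_sweeps: int = 60,
    measure_sweeps: int = 200,
    quench_final_temperature: float = 0.004,
    quench_stages: int = 15,
    quench_sweeps: int = 70,
    bidirectional: bool = True,
    burn_in_sweeps: int = 20000,
) -> SeparationProfile:
    """Quasistatic drag protocol for the excess-energy profile.

    The pair is wrapped once at the largest separation, its adhesion
    topology is frozen (constant degree of wrapping, the regime in which
    the interaction lives in the bending energy alone), and the
    configuration is dragged inwards in small steps (``drag_step`` in D_p,
    ``drag_sweeps`` relaxation sweeps at ``drag_temperature`` per step).
    At each requested separation the state is *forked and quenched*: a
    clone is annealed from the drag temperature to
    ``quench_final_temperature`` and its minimum-energy bending recorded,
    while the scan continues from the un-quenched state.  Because all
    quenches start from one adiabatically transported configuration, the
    frozen wrinkle background is common to all separations and cancels in
    the excess energy, which resolves differences of a few kBT that
    independent annealing runs (scatter of tens of kBT) cannot.

    With ``bidirectional`` (default) the path is retraced outwards and the
    two passes are averaged per separation: residual background drift that
    is linear in simulation time cancels, and the in/out difference doubles
    as a hysteresis check, folded into the reported standard errors.
    """
    separations = np.sort(np.asarray(separations, dtype=float))[::-1]  # outermost first
    n_s = len(separations)
    n_pass = 2 if bidirectional else 1
    bend = np.full((n_s, n_replicates, n_pass), np.nan)
    adhe = np.full((n_s, n_replicates, n_pass), np.nan)
    flags = np.zeros(n_s, dtype=int)

    quench_schedule = AnnealSchedule(drag_temperature, quench_final_temperature,
                                     quench_stages, quench_sweeps)

    def measure(state, i, r, p):
        state.run(measure_sweeps, drag_temperature, config.flip_fraction)
        q = state.clone()
        # transient tether violations from the imposed particle displacement
        # may persist into a cold quench; skip the strict final check here
        stages = anneal(q, quench_schedule, config.flip_fraction, verify_final=False)
        tail = stages.tail(3)
        bend[i, r, p] = float(tail["mean_bending"].mean())
        adhe[i, r, p] = float(tail["mean_adhesion"].mean())

    for r in range(n_replicates):
        seed = (config.seed * 1000003 + r * 101) % (2 ** 31 - 1)
        state = initialize_wrapped_pair(config, float(separations[0]), seed=seed)
        # cool from the wrap-in temperature to the drag temperature, then
        # burn in until the wrinkle background stops relaxing on the scan
        # timescale (its residual drift is cancelled by the two passes)
        anneal(state, AnnealSchedule(1.0, drag_temperature, 15, 60), config.flip_fraction)
        if burn_in_sweeps:
            state.run(burn_in_sweeps, drag_temperature, config.flip_fraction)
        # freeze the adhesion topology: only the currently bound pairs keep
        # interacting, so the degree of wrapping is constant across the scan
        # by construction and the bending energy is directly comparable
        state.adh_mask = (state.adh < -1e-9).astype(np.uint8)
        state._refresh()
        adh_plateau = float(state.acc[3])
        s_now = float(separations[0])

        def drag_to(s_target):
            nonlocal s_now
            step = drag_step if s_target < s_now else -drag_step
            while abs(s_now - s_target) > 1e-9:
                s_now = s_now - step if abs(s_now - s_target) > drag_step else s_target
                _set_pair_separation(state, config, s_now)
                state.run(drag_sweeps, drag_temperature, config.flip_fraction)

        for i, s_target in enumerate(separations):
            drag_to(float(s_target))
            measure(state, i, r, 0)
        if bidirectional:
            for i in range(n_s - 1, -1, -1):
                drag_to(float(separations[i]))
                measure(state, i, r, 1)
        if adhe[:, r, :].max() > (1 - 0.05) * adh_plateau:  # adhesion lost somewhere
            bad = int(np.argmax(np.nanmax(adhe[:, r, :], axis=1)))
            flags[bad] += 1
            warnings.warn(f"replicate {r}: adhesion dropped during drag", RuntimeWarning)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        # average the two passes (cancels drift linear in time), then take
        # per-replicate excess relative to the outermost separation: the
        # common-mode background cancels within a replicate
        bend_rep = np.nanmean(bend, axis=2)
        excess_rep = bend_rep - bend_rep[0]
        mean_excess = np.nanmean(excess_rep, axis=1)
        n_rep = np.sum(np.isfinite(excess_rep), axis=1)
        se_rep = np.nanstd(excess_rep, axis=1, ddof=1) / np.sqrt(np.maximum(n_rep, 1))
        # hysteresis (in-pass vs out-pass spread) folded into the error
        if bidirectional:
            hyst = np.nanstd(bend - bend_rep[:, :, None], axis=(1, 2)) / np.sqrt(n_rep)
            se = np.sqrt(se_rep ** 2 + hyst ** 2)
        else:
            se = se_rep
    order = np.argsort(separations)
    return SeparationProfile(
        separations=separations[order],
        excess_energy=mean_excess[order],
        stderr=se[order],
        bending=np.nanmean(bend, axis=(1, 2))[order],
        adhesion=np.nanmean(adhe, axis=(1, 2))[order],
        n_replicates=n_rep[order],
        flagged=flags[order],
        metadata={
            "kappa": config.kappa,
            "D_p": config.D_p,
            "D_v": config.D_v,
            "epsilon": config.auto_epsilon(),
            "seed": config.seed,
            "vertex_count": config.vertex_count(),
            "protocol": "quasistatic_drag",
            "drag_temperature": drag_temperature,
            "bidirectional": bidirectional,
        },
    )


def run_separation_scan(
    config: SimConfig,
    separations,
    n_replicates: int = 5,
    tail_stages: int = 5,
    unwrap_tol: float = 0.05,
) -> SeparationProfile:
    """Anneal the wrapped pair at each separation; return the excess profile.

    For each separation, ``n_replicates`` independent wrap-in + annealing
    runs are performed (seeds derived from ``config.seed``); the bending
    energy is averaged over the last ``tail_stages`` annealing stages.
    Replicates whose adhesion energy ends more than ``unwrap_tol`` above its
    plateau (particle let go) are excluded and counted in ``flagged``.

    The excess energy at each separation is the mean bending minus the mean
    bending at the largest scanned separation; its standard error combines
    the replicate scatter at both points.
    """
    separations = np.sort(np.asarray(separations, dtype=float))
    if len(separations) < 1:
        raise ValueError("need at least one separation")
    bend = np.full((len(separations), n_replicates), np.nan)
    adhe = np.full((len(separations), n_replicates), np.nan)
    nadh = np.full((len(separations), n_replicates, 2), np.nan)
    flags = np.zeros(len(separations), dtype=int)
    schedule = config.schedule.build()
    for i, s in enumerate(separations):
        for r in range(n_replicates):
            seed = (config.seed * 1000003 + i * 1009 + r * 101) % (2 ** 31 - 1)
            state = initialize_wrapped_pair(config, float(s), seed=seed)
            adh_plateau = float(state.acc[3])
            stages = anneal(state, schedule, config.flip_fraction)
            tail = stages.tail(tail_stages)
            adh_final = float(tail["mean_adhesion"].mean())
            if adh_final > (1 - unwrap_tol) * adh_plateau:  # both negative
                flags[i] += 1
                warnings.warn(
                    f"replicate {r} at s={s} D_p lost adhesion "
                    f"({adh_final:.0f} vs plateau {adh_plateau:.0f}); excluded",
                    RuntimeWarning,
                )
                continue
            bend[i, r] = float(tail["mean_bending"].mean())
            adhe[i, r] = adh_final
            nadh[i, r] = adhering_counts(state)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_bend = np.nanmean(bend, axis=1)
        se_bend = np.nanstd(bend, axis=1) / np.sqrt(np.sum(np.isfinite(bend), axis=1))
    ref = mean_bend[-1]
    excess = mean_bend - ref
    stderr = np.sqrt(se_bend ** 2 + se_bend[-1] ** 2)
    stderr[-1] = se_bend[-1]
    return SeparationProfile(
        separations=separations,
        excess_energy=excess,
        stderr=stderr,
        bending=mean_bend,
        adhesion=np.nanmean(adhe, axis=1),
        n_replicates=np.sum(np.isfinite(bend), axis=1),
        flagged=flags,
        metadata={
            "kappa": config.kappa,
            "D_p": config.D_p,
            "D_v": config.D_v,
            "epsilon": config.auto_epsilon(),
            "seed": config.seed,
            "vertex_count": config.vertex_count(),
            "adhering_counts": nadh,
        },
    )
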