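"""Metropolis Monte Carlo engine with simulated annealing.

Moves are (i) single-vertex displacements, uniform in a cube; (ii) edge
flips, which make the triangulation fluid; (iii) rigid translations of
mobile particles.  Hard constraints (tether bounds, vertex-vertex,
vertex-particle and particle-particle hard cores) are enforced as automatic
rejections.  Proposals are accepted with probability
``min(1, exp(-dE / T))`` where the temperature ``T`` is dimensionless
(energies in k_BT; ``T = 1`` is the physical temperature).

Simulated annealing lowers ``T`` geometrically to suppress membrane
fluctuations and approach the minimum-energy configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels as K
from .energy import EnergyBreakdown, EnergyParams, ParticleState, total_energy
from .errors import CorruptedStateError
from .mesh import TriMesh


@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric cooling schedule.

    ``n_stages`` temperatures from ``initial_temperature`` down to
    ``final_temperature`` (inclusive), ``sweeps_per_stage`` sweeps each.
    """

    initial_temperature: float = 1.0
    final_temperature: float = 0.01
    n_stages: int = 50
    sweeps_per_stage: int = 40

    def __post_init__(self):
        if self.n_stages < 0 or self.sweeps_per_stage < 1:
            raise ValueError("n_stages >= 0 and sweeps_per_stage >= 1 required")
        if not (0 < self.final_temperature <= self.initial_temperature):
            raise ValueError("need 0 < final_temperature <= initial_temperature")

    def temperatures(self) -> np.ndarray:
        if self.n_stages == 0:
            return np.empty(0)
        if self.n_stages == 1:
            return np.array([self.initial_temperature])
        return np.geomspace(self.initial_temperature, self.final_temperature, self.n_stages)

    @property
    def cooling_factor(self) -> float:
        if self.n_stages < 2:
            return 1.0
        return float((self.final_temperature / self.initial_temperature) ** (1.0 / (self.n_stages - 1)))


class McState:
    """Mutable Monte Carlo state: mesh + particles + running energies.

    Construct with :meth:`from_mesh`.  The same seed and the same sequence of
    calls reproduce bit-identical trajectories.
    """

    def __init__(self, pos, faces, face_edges, edge_v, edge_f, vfaces, vnf,
                 ppos, paxis, pmob, pdiam, params: EnergyParams, seed: int,
                 amp_vertex: float, amp_particle: float, box_half: float,
                 n_aspect: int | None = None, amp_aspect: float = 0.01):
        self.pos = pos
        self.faces = faces
        self.face_edges = face_edges
        self.edge_v = edge_v
        self.edge_f = edge_f
        self.vfaces = vfaces
        self.vnf = vnf
        self.ppos = ppos
        self.paxis = paxis
        self.pmob = pmob
        self.pdiam = pdiam
        self.params = params
        self.seed = int(seed)
        self.amp_vertex = float(amp_vertex)
        self.amp_particle = float(amp_particle)
        self.box_half = float(box_half)
        # collective shape moves only make sense without frozen particles
        self.n_aspect = int(n_aspect) if n_aspect is not None else (1 if len(ppos) == 0 else 0)
        self.amp_aspect = float(amp_aspect)
        V, F, E = len(pos), len(faces), len(edge_v)
        self.fnormal = np.empty((F, 3))
        self.farea = np.empty(F)
        self.fvol6 = np.empty(F)
        self.bend_e = np.empty(E)
        self.adh = np.zeros((V, max(len(ppos), 1)))
        #: (V, P) adhesion topology mask; zeroing an entry excludes that
        #: vertex-particle pair from binding (hard cores still apply)
        self.adh_mask = np.ones_like(self.adh, dtype=np.uint8)
        self.acc = np.zeros(4)
        self.counters = np.zeros((4, 2), dtype=np.int64)
        self.ncx = int(np.ceil(2 * self.box_half)) + 1
        self.head = np.full(self.ncx ** 3, -1, dtype=np.int64)
        self.nxt = np.full(V, -1, dtype=np.int64)
        self.vcell = np.zeros(V, dtype=np.int64)
        self._seeder = np.random.Generator(np.random.PCG64(self.seed))
        self._refresh()

    # -- construction ---------------------------------------------------
    @classmethod
    def from_mesh(
        cls,
        mesh: TriMesh,
        particles: Sequence[ParticleState],
        params: EnergyParams,
        seed: int = 0,
        amp_vertex: float = 0.1,
        amp_particle: float = 0.1,
        box_half: float | None = None,
        n_aspect: int | None = None,
        amp_aspect: float = 0.01,
    ) -> "McState":
        mesh = mesh.copy()
        ev, ef = mesh.edges, mesh.edge_faces
        V, F, E = mesh.n_vertices, mesh.n_faces, len(ev)
        # face -> edge incidence
        eidx = {(int(a), int(b)): i for i, (a, b) in enumerate(ev)}
        face_edges = np.empty((F, 3), dtype=np.int64)
        for fi, (a, b, c) in enumerate(mesh.faces):
            for k, (u, v) in enumerate(((a, b), (b, c), (c, a))):
                lo, hi = (int(u), int(v)) if u < v else (int(v), int(u))
                face_edges[fi, k] = eidx[(lo, hi)]
        # vertex -> face incidence (capped at MAXDEG)
        vnf = np.zeros(V, dtype=np.int64)
        vfaces = np.full((V, K.MAXDEG), -1, dtype=np.int64)
        for fi, tri in enumerate(mesh.faces):
            for u in tri:
                u = int(u)
                if vnf[u] >= K.MAXDEG:
                    raise ValueError(f"vertex {u} exceeds max degree {K.MAXDEG}")
                vfaces[u, vnf[u]] = fi
                vnf[u] += 1
        P = len(particles)
        ppos = np.zeros((max(P, 1), 3))
        paxis = np.zeros((max(P, 1), 3))
        paxis[:, 2] = 1.0
        pmob = np.zeros(max(P, 1), dtype=np.uint8)
        pdiam = np.full(max(P, 1), params.D_p)
        for i, p in enumerate(particles):
            ppos[i] = p.centre
            paxis[i] = p.axis
            pmob[i] = 1 if p.mobile else 0
            pdiam[i] = p.diameter
        if P == 0:
            ppos = ppos[:0]
            paxis = paxis[:0]
            pmob = pmob[:0]
            pdiam = pdiam[:0]
        if box_half is None:
            extent = float(np.abs(mesh.vertices).max())
            box_half = 2.0 * extent + params.D_p + 6.0
        return cls(mesh.vertices.copy(), mesh.faces.copy(), face_edges,
                   ev.copy(), ef.copy(), vfaces, vnf, ppos, paxis, pmob, pdiam,
                   params, seed, amp_vertex, amp_particle, box_half,
                   n_aspect, amp_aspect)

    # -- parameter packing ---------------------------------------------
    def _par(self) -> np.ndarray:
        p = self.params
        par = np.zeros(17)
        par[0] = p.l ** 2
        par[1] = p.l_max ** 2
        par[2] = p.kd
        par[3] = p.K_A
        par[4] = p.K_V
        par[5] = p.A_t
        par[6] = p.V_t
        par[7] = p.epsilon
        par[8] = np.cos(p.theta_wr)
        par[9] = p.l_m
        par[10] = p.r_cut
        par[11] = (p.l_m / p.r_cut) ** 6
        par[12] = 1.0 if p.well == "square" else 0.0
        par[13] = p.D_p ** 2
        par[14] = self.amp_vertex
        par[15] = self.amp_particle
        par[16] = self.box_half
        return par

    def _refresh(self) -> None:
        K.rebuild(self.pos, self.faces, self.edge_f, self.fnormal, self.farea,
                  self.fvol6, self.bend_e, self.adh, self.ppos, self.paxis,
                  self.adh_mask, self._par(), self.acc)
        K.build_cells(self.pos, self.box_half, self.ncx, self.head, self.nxt, self.vcell)

    # -- accessors ------------------------------------------------------
    def clone(self) -> "McState":
        """Deep copy (arrays and RNG stream); used for fork-and-quench."""
        import copy

        return copy.deepcopy(self)

    @property
    def n_vertices(self) -> int:
        return len(self.pos)

    def to_mesh(self) -> TriMesh:
        return TriMesh(self.pos.copy(), self.faces.copy())

    @property
    def particles(self) -> list[ParticleState]:
        return [ParticleState(self.ppos[i].copy(), float(self.pdiam[i]),
                              self.paxis[i].copy(), bool(self.pmob[i]))
                for i in range(len(self.ppos))]

    def energy_breakdown(self) -> EnergyBreakdown:
        p = self.params
        area, vol = self.acc[0], self.acc[1]
        return EnergyBreakdown(
            bending=float(self.acc[2]),
            area_constraint=float(p.K_A * (area - p.A_t) ** 2 / p.A_t),
            volume_constraint=float(p.K_V * (vol - p.V_t) ** 2 / p.V_t),
            adhesion=float(self.acc[3]),
        )

    def acceptance_fractions(self) -> dict:
        c = self.counters
        out = {}
        for name, row in zip(("vertex", "flip", "particle", "aspect"), c):
            out[name] = float(row[1] / row[0]) if row[0] > 0 else np.nan
        return out

    def verify(self, rtol: float = 1e-8, atol: float = 1e-6) -> None:
        """Check running totals against a from-scratch recompute.

        Raises :class:`CorruptedStateError` (with the offending mesh attached
        as ``.snapshot``) if the incremental bookkeeping has diverged or the
        mesh is no longer a closed oriented manifold.
        """
        mesh = self.to_mesh()
        try:
            mesh.validate()
        except ValueError as exc:
            err = CorruptedStateError(f"mesh invariant broken: {exc}")
            err.snapshot = mesh
            raise err from exc
        ref = total_energy(mesh, self.particles, self.params)
        got = self.energy_breakdown()
        for name in ("bending", "area_constraint", "volume_constraint", "adhesion"):
            a, b = getattr(ref, name), getattr(got, name)
            if not np.isclose(a, b, rtol=rtol, atol=atol):
                err = CorruptedStateError(
                    f"{name}: running total {b!r} != recomputed {a!r}")
                err.snapshot = mesh
                raise err
        # tether bounds on every edge
        el = np.linalg.norm(self.pos[self.edge_v[:, 1]] - self.pos[self.edge_v[:, 0]], axis=1)
        p = self.params
        if el.min() < p.l * (1 - 1e-9) or el.max() > p.l_max * (1 + 1e-9):
            err = CorruptedStateError(
                f"edge length out of [{p.l}, {p.l_max}]: min {el.min()}, max {el.max()}")
            err.snapshot = mesh
            raise err

    # -- dynamics -------------------------------------------------------
    def _next_seed(self) -> int:
        return int(self._seeder.integers(0, 2 ** 31 - 1))

    def run(self, n_sweeps: int, temperature: float, flip_fraction: float = 0.1) -> pd.DataFrame:
        """Run sweeps at fixed temperature; returns the per-sweep energy trace."""
        if temperature <= 0:
            raise ValueError("temperature must be > 0")
        trace = np.empty((n_sweeps, 4))
        K.run_sweeps(n_sweeps, float(temperature), self._next_seed(),
                     self.pos, self.faces, self.face_edges, self.edge_v,
                     self.edge_f, self.vfaces, self.vnf, self.fnormal,
                     self.farea, self.fvol6, self.bend_e, self.adh,
                     self.ppos, self.paxis, self.pmob, self.adh_mask,
                     self._par(), self.acc,
                     self.box_half, self.ncx, self.head, self.nxt, self.vcell,
                     float(flip_fraction), self.n_aspect, self.amp_aspect,
                     self.counters, trace)
        p = self.params
        df = pd.DataFrame(trace, columns=["area", "volume", "bending", "adhesion"])
        df["area_constraint"] = p.K_A * (df["area"] - p.A_t) ** 2 / p.A_t
        df["volume_constraint"] = p.K_V * (df["volume"] - p.V_t) ** 2 / p.V_t
        df["total"] = df["bending"] + df["adhesion"] + df["area_constraint"] + df["volume_constraint"]
        df["temperature"] = temperature
        return df


def metropolis_sweep(state: McState, temperature: float, flip_fraction: float = 0.1) -> McState:
    """Perform one Metropolis sweep in place and return the state.

    One sweep = V vertex-move attempts, ``flip_fraction * E`` edge-flip
    attempts and one attempt per mobile particle, interleaved at random.
    """
    state.run(1, temperature, flip_fraction)
    return state


def anneal(
    state: McState,
    schedule: AnnealSchedule,
    flip_fraction: float = 0.1,
    verify_every: int | None = None,
    adapt_amplitude: bool = True,
    target_acceptance: float = 0.5,
    verify_final: bool = True,
) -> pd.DataFrame:
    """Simulated annealing over ``schedule``; returns per-stage statistics.

    With ``adapt_amplitude`` (default) the vertex/particle displacement
    amplitude is rescaled after every stage towards ``target_acceptance``
    (clamped to [1e-3, 0.5] l), so cooling does not freeze the dynamics.

    The returned frame has one row per stage with the stage temperature,
    mean energies over the stage's sweeps and acceptance fractions.  The
    state is verified against a from-scratch energy recompute at the end
    (and every ``verify_every`` stages if given); a
    :class:`CorruptedStateError` carries a diagnostic mesh snapshot.
    """
    rows = []
    temps = schedule.temperatures()
    for i, T in enumerate(temps):
        before = state.counters.copy()
        trace = state.run(schedule.sweeps_per_stage, float(T), flip_fraction)
        dc = state.counters - before
        if adapt_amplitude and dc[0, 0] > 0:
            acc_v = dc[0, 1] / dc[0, 0]
            scale = np.clip(np.sqrt((acc_v + 0.02) / target_acceptance), 0.5, 2.0)
            state.amp_vertex = float(np.clip(state.amp_vertex * scale, 1e-3, 0.5))
            state.amp_particle = float(np.clip(state.amp_particle * scale, 1e-3, 0.5))
        row = {
            "stage": i,
            "temperature": float(T),
            "mean_bending": trace["bending"].mean(),
            "mean_adhesion": trace["adhesion"].mean(),
            "mean_area_constraint": trace["area_constraint"].mean(),
            "mean_volume_constraint": trace["volume_constraint"].mean(),
            "mean_total": trace["total"].mean(),
            "mean_area": trace["area"].mean(),
            "mean_volume": trace["volume"].mean(),
            "acc_vertex": dc[0, 1] / dc[0, 0] if dc[0, 0] else np.nan,
            "acc_flip": dc[1, 1] / dc[1, 0] if dc[1, 0] else np.nan,
            "acc_particle": dc[2, 1] / dc[2, 0] if dc[2, 0] else np.nan,
        }
        rows.append(row)
        if verify_every and (i + 1) % verify_every == 0:
            state.verify()
    if len(temps) and verify_final:
        state.verify()
    return pd.DataFrame(rows)
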