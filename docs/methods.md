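# Methods

`memcurv` models how rigid particles that adhere to and become wrapped by a
lipid vesicle interact through the membrane's bending energy, and provides
the statistical machinery to measure such interactions — in simulation
(constrained Monte Carlo of a triangulated vesicle) and from tracking data
(Boltzmann inversion of pair-separation statistics on a sphere).  This note
records the model, the parameter choices, and the numerical decisions,
including the places where the design was genuinely open.

## Units

Lengths are measured in the tether hard-core length `l` (the minimum
vertex-vertex distance of the triangulated membrane), energies in `k_BT`,
and temperature is dimensionless with `T = 1` the physical temperature.
Micron/`k_BT` units appear only at the analysis boundary (the analytic
wrapping model and the trajectory inference), with the experimental
conversions `kappa = 21 k_BT` (DOPC) and `D_p ≈ 1 um`.

## Membrane model

The vesicle is a closed, oriented, dynamically triangulated surface:

* **Geometry.** Icosahedral geodesic spheres of class I (`T = m^2`) and
  class II (`T = 3 m^2`, built by a sqrt(3)-subdivision step), `V = 10T+2`
  vertices.  The production vesicle is `V = 5882` (class II, frequency 14)
  with diameter `D_v = 50 l`; smaller vesicles keep the same areal vertex
  density.  A spring relaxation equalises edge lengths so the initial mesh
  sits inside the tether window.
* **Fluidity.** Edge flips (diagonal exchange of adjacent triangle pairs)
  make the network a fluid rather than a solid shell.  Flips that would
  disconnect a vertex (degree < 3), duplicate an edge, or violate the
  tether bounds are rejected.
* **Self-avoidance.** All vertex pairs carry a hard core of diameter
  `l_min = l`; edges are bounded above by `l_max = sqrt(3) l`.  Together
  these keep the fluid surface impenetrable.
* **Bending energy.** `E_b = (kappa_disc / 2) * sum_edges |n_i - n_j|^2`
  over adjacent-triangle normal vectors.  The discrete-continuum map is
  fixed by requiring a sphere to reproduce the Helfrich value `8 pi kappa`:
  for near-equilateral triangulations `sum_edges (1 - n_i.n_j) ->
  4 pi / sqrt(3)`, hence the default `kappa_disc = 2 sqrt(3) kappa`.
  `calibrate_kappa_disc()` performs the same calibration numerically
  (Richardson extrapolation over refined spheres) and lands within ~1% of
  the closed form.  (A commonly quoted alternative prefactor,
  `sqrt(3) kappa`, underestimates the sphere energy by a factor 1.5 on
  these meshes; the numerical calibration is authoritative here.)
* **Constraints.** Area and volume are maintained softly:
  `u_A = K_A (A - A_t)^2 / A_t`, `u_V = K_V (V - V_t)^2 / V_t` with
  `K_A = 10^3 k_BT/l^2` and `K_V = 4x10^3 k_BT/(D_p l^2)` (converted to
  `k_BT/l^3` internally).  The floppy-vesicle condition is
  `A_t = 1.05 A_0`, `V_t = V_0` of the relaxed sphere: 5% excess area at
  fixed volume, which is (by design) just the membrane needed to wrap two
  particles of the standard size ratio `D_p / D_v = 8/50`.

## Particle adhesion

Particles are rigid spheres of diameter `D_p` with an adhesive ("active")
area covering 90% of the surface — the maximum polar angle of the active
cone is `theta_wr = arccos(-0.8) ≈ 143°`, measured from the cone axis, and
the inactive pole prevents unphysically sharp membrane bends at the neck.
A membrane vertex at centre distance `r` inside the cone contributes
`-epsilon * w(r)` with `w` a truncated-and-shifted `(l_m/r)^6` profile
normalised to `w(l_m) = 1` and `w(r_cut) = 0` (a square well is available).
`l_m = (l + D_p)/2` is the particle-vertex hard-core distance.

**Cut-off.** The adhesion range is `r_cut = 1.2 l_m`.  This realises the
requirement that the attraction do nothing beyond forming a single membrane
coat: the first vertex layer sits at `r ≈ l_m`, the second at
`r ≳ l_m + l`, which lies outside `1.2 l_m` for every particle size of
interest.  Two alternatives were tested and rejected: a razor-thin shell
(`l_m + 0.2 l`) provides no capture gradient and wrapping never nucleates;
an absolute thick shell (`l_m + 1.2 l`) lets a second layer bind, and the
adhering count then grows without bound (membrane crams into the shell).
The factor is configurable (`cutoff_factor`).

**Adhesion strength.** The continuum physics fixes only the threshold:
wrapping requires the areal adhesion `epsilon * rho_v` (with `rho_v` the
areal vertex density) to exceed the bending cost `2 kappa / R_p^2`.  The
default is `epsilon = margin * 2 kappa / (R_p^2 rho_v)` with
`margin = 2.5`, i.e. comfortably wrapped but far from the cramming regime.

## Monte Carlo engine

Metropolis sampling with moves:

* single-vertex displacements, uniform in a cube (default half-side 0.1 l,
  adapted per annealing stage towards ~50% acceptance, clamped to
  [1e-3, 0.5] l);
* edge flips (default `E/10` attempts per sweep);
* rigid particle translations for mobile particles;
* for particle-free systems, one volume-preserving global anisotropic
  scaling per sweep (`e^g` along a random axis, `e^{-g/2}` along the other
  two, `g` symmetric about 0; unit phase-space Jacobian).  This collective
  move is essential: the ellipsoidal shape mode that stores excess membrane
  area is orders of magnitude too slow for single-vertex dynamics, and
  without it the area constraint cannot reach its target at low
  temperature.

Hard constraints are enforced as automatic rejections, with one
deliberate asymmetry: a proposal that *shrinks* an already-existing
violation (possible only after an externally imposed particle displacement
during the separation scan) is allowed, so transient violations heal
instead of locking the dynamics.  On valid states the rule is the plain
hard core.

Energy bookkeeping is incremental (a vertex move touches only its incident
faces and their edges) and is verified against a from-scratch recompute;
running totals are refreshed at the start of every run to keep float drift
out.  All randomness flows from a single seed; identical seeds give
bit-identical traces.

Simulated annealing uses a geometric temperature ladder.  The particle-free
constraint-fidelity experiment starts from a volume-preserving prolate
spheroid whose *mesh* area equals `A_t` (solved to ~1e-4): inflating the
area 5% from a sphere through local moves is a glassy collective process,
while the prolate branch is the actual constrained minimum.  Annealed at
`T: 3e-3 -> 1e-4`, the `D_v = 50 l` vesicle holds `|A - A_t|/A_t` and
`|V - V_t|/V_t` below 1e-4 (the reduced `D_v = 20 l` vesicle cannot: the
equilibrium deviation of the constrained minimum scales as
`(dE_b/dA)/2K_A ~ 1/D_v^2` and sits near 5e-4 there, which is why the
production scale is used for this check).

## Two-particle separation scan

The membrane-mediated interaction is the separation dependence of the
membrane's bending energy with two wrapped particles held at fixed geodesic
separation `s` (reported in units of `D_p`; positions are control
variables, the particles are immobilised).

* **Wrap-in** is two-stage: a widened capture shell (1.2 l above contact)
  at `T = 1` lets the membrane fold around the particles; restoring the
  single-layer cut-off then releases loosely captured vertices and locks
  the contact layer — from here the adhesion energy and adhering count stay
  constant (checked; runs that lose adhesion are flagged and excluded),
  which is the precondition for reading the interaction off the bending
  energy alone.
* **Quasistatic drag.** Independent annealing runs per separation carry
  run-to-run bending scatter of tens of `k_BT` (frozen wrinkle disorder),
  far above the ~3 `k_BT` signal.  Instead one wrapped configuration is
  transported along the separation path: each particle and the vertices in
  its pocket are co-rotated rigidly about the vesicle centre (a smooth
  rotation field decays over 2 l beyond the adhesive shell, so no hard core
  is torn), in steps of 0.02 `D_p` with 60 relaxation sweeps per step at
  `T = 0.1`, after a 20k-sweep burn-in that lets the wrinkle background
  stop relaxing on the scan timescale.
* **Bidirectional averaging.** The path is traversed in and back out and
  the two passes are averaged per separation: background drift linear in
  time cancels, and the in/out spread is a hysteresis estimate folded into
  the reported standard error.  Replicate seeds give the final uncertainty.
* **Coarse-graining floor.** Below ~1.5 `D_p` (production resolution) there
  are no longer two vertex layers between the particles; at the reduced
  test resolution (`D_v = 25 l`, `D_p = 4 l`) the floor is ~1.8 `D_p`
  (pocket shells touch), so scans start above it.

## Analytic wrapping model

The wrapping energy is linear in the membrane-particle contact area with
prefactor `2 kappa / R^2 + sigma - u_ad`; its sign makes wrapping
all-or-nothing.  Consequences implemented and tested: zero-tension
threshold `u_ad* = 2 kappa / R^2` (= 168 `k_BT/um^2` at `kappa = 21 k_BT`,
`R = 0.5 um`); linker efficiency `u_ad* / (E_bond * rho*) ≈ 2%` for 17
`k_BT` bonds at the critical density 513 `um^-2`; and a two-state Boltzmann
occupancy `f = 1 / (1 + e^{dE})`, `dE = (2 kappa/R^2 + sigma - u_ad(rho)) *
A_c`, for the wrapped fraction versus linker density.  The contact area in
the Boltzmann factor is the fully wrapped `A_c = 4 pi R^2` (exposed as a
parameter); with it the bare transition is effectively a step, and the
smooth experimental curve is reproduced by convolving with the measured
batch-to-batch linker-density spread (sigma_rho = 77 `um^-2`, Gauss-Hermite
quadrature).  `f(rho*) = 1/2` exactly at the critical density either way.

## Trajectory inference

Input: per-frame 2-D image coordinates of two particles plus the tracked
vesicle centre and radius.  Pipeline:

1. 3-D reconstruction on the sphere `R + h`, `h = ±D_p/2` by wrapping
   state; the depth sign is unobservable in a single 2-D slice and is taken
   constant per segment.  Geodesic separations are invariant under a joint
   sign flip, so the convention is *exact* while both particles share a
   hemisphere — which is the regime in which frames are assumed recorded
   (segments split where it fails).  Points marginally outside the
   projected disc are clamped to the equator and flagged; larger
   excursions are errors.
2. Geodesic separation between the radial projections (membrane attachment
   points) on the vesicle sphere.
3. Transition counts `C_ij` between separation bins at lag 1 frame
   (configurable; default bin width 0.2 um), pooled over segments by
   summing counts.
4. Stationary distribution after detailed-balance symmetrisation
   `C <- (C + C^T)/2`, restricted to the largest communicating class,
   solved by eigen-decomposition.  Segment-end samples participate in half
   as many ordered pairs as interior samples and receive compensating
   half-weight self-loops (isolated samples full weight); without this the
   stationary vector is biased by the per-bin segment-termination rate —
   on heavily censored data the effect reached ~0.5 `k_BT`.
5. Boltzmann inversion `u(s) = -ln(pi/J) + c` with the geodesic density of
   states `J ∝ sin(s/R) ds` — on a sphere the non-interacting measure is
   not flat in arc length — multiplied, for hemisphere-censored data, by
   the exact visibility factor `1 - theta/pi` (the probability that two
   directions at angle `theta` share a random hemisphere).  Omitting either
   factor fabricates an `O(k_BT)` spurious potential.  The offset `c`
   zeroes the count-weighted mean of the far-field third of visited bins.
6. Uncertainties by block bootstrap over trajectory segments.

On equilibrated data the transition-matrix route and the plain occupancy
histogram agree (tested); the transition route exists for unevenly sampled
trajectories.

## Synthetic data

* **Brownian pair on a sphere**: overdamped Langevin dynamics of two
  particle centres on the tracking sphere under an imposed pair potential
  `u(s)` (membrane-arc coordinates); Euler-Maruyama with radial
  re-projection, 5 integrator substeps per recorded frame (the flat-
  potential stationary measure and the strong-force bias are both checked
  by the suite).  Default conditions mimic video-rate tracking of a
  micron particle: `D = 0.4-1 um^2/s`, `dt = 0.05 s`, vesicle radius a few
  um, `10^4-10^5` frames.  Frames are recorded only while the particles
  share a hemisphere, mirroring the reconstruction's validity regime; the
  generator returns the full ground truth for closed-loop tests.  What it
  does *not* emulate: hydrodynamic coupling, localisation noise, vesicle
  drift/fluctuation — so passing recovery tests demonstrate correctness of
  the inference chain, not robustness to every experimental artefact.
* **Confocal-slice renderer**: Gaussian ring (vesicle equator) plus
  Gaussian particle spots with Poisson-Gaussian noise at prescribed SNR
  (peak signal over noise at the peak); used to validate the contour
  tracker end to end.

## Vesicle tracker

Gaussian pre-smoothing (rms 1 px, toggleable); 180 radial rays (bilinear
interpolation, 1 px steps) from a rough centre; per-ray arg-max; sub-pixel
refinement by straight-line regression on the discrete derivative in a
5-sample window centred on the peak (zero slope or out-of-window crossing
flags the ray); algebraic (Kasa) least-squares circle fit with residual
RMS.  Overlapping particle images are refined by a two-Gaussian-plus-
background nonlinear fit, which removes the centroid-estimator's
towards-each-other bias.  Pixel convention: integer pixel centres, x =
column, y = row.  The 3-D ellipsoid variant is reduced to the in-plane
circle case (no volumetric source in scope).

## Problem sizes and determinism

Production vesicle `V = 5882` (`D_v = 50 l`, `D_p = 8 l`); the suite's
two-particle scan runs the same physics at `V = 1472` (`D_v = 25 l`,
`D_p = 4 l`, identical ratio — the model has no absolute length scale) and
the constraint-fidelity run at full scale, sized so the whole suite stays
within desk-scale runtimes.  Every stochastic component takes an explicit
seed; reruns are bit-identical.

## Known limitations

* The drag protocol quenches to `T ≈ 0.004` from states transported at
  `T = 0.1`; the frozen wrinkle background is common mode and cancels in
  the excess, but its slow non-linear relaxation leaves a noise floor of
  several kBT per point at the reduced test resolution.  Consequently the
  reduced-resolution scan resolves the *absence of long-range repulsion*
  cleanly but leaves the few-kBT attraction near contact within its error
  bars; resolving the well depth requires production resolution and far
  longer annealing than desk scale permits.
* The discrete bending prefactor is calibrated on spheres; fluid,
  defect-carrying triangulations have an effective rigidity a few percent
  different.
* The reduced-resolution scan has a coarse-graining floor of ~1.8 `D_p`,
  so the contact region of the interaction is resolved only at production
  resolution.
* Boltzmann inversion assumes separation-independent drag (as stated for
  the experimental analysis) and equilibrium sampling within segments.
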