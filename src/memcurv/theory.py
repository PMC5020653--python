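"""Two-state particle-wrapping model of an adhesive sphere on a membrane.

For a rigid sphere of radius ``R`` adhering to a membrane with bending
rigidity ``kappa`` and tension ``sigma``, the deformation energy is linear in
the membrane-particle contact area ``A`` with prefactor

    ``2 kappa / R^2 + sigma - u_ad``            [kBT / um^2]

(``u_ad`` = adhesion energy per unit area).  The energy is therefore
minimised by either zero contact (non-wrapped) or maximal contact (fully
wrapped), depending only on the sign of the prefactor — wrapping is
all-or-nothing.  At zero tension the wrapping threshold is
``u_ad = 2 kappa / R^2``; with kappa = 21 kBT and R = 0.5 um this is
168 kBT/um^2.

Adhesion is produced by discrete linkers (avidin-biotin bonds, ~17 kBT
each), so ``u_ad = binding_efficiency * bond_energy * linker_density``.
The observed fraction of wrapped particles as a function of linker density
follows a two-state Boltzmann occupancy of the energy difference between the
wrapped and non-wrapped states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

KBT_PER_UM2_PER_NEWTON_PER_M = 1.0e-12 / 4.11e-21  # sigma [N/m] -> kBT/um^2 at T=298K


@dataclass(frozen=True)
class WrappingModelParams:
    """Parameters of the two-state wrapping model (micron / kBT units)."""

    kappa: float = 21.0          # membrane bending rigidity [kBT]
    R: float = 0.5               # particle radius [um]
    sigma: float = 0.0           # membrane tension [kBT/um^2]
    u_ad: float = 0.0            # adhesion energy per area [kBT/um^2]
    bond_energy: float = 17.0    # energy per linker bond [kBT]
    linker_density: float = 0.0  # [um^-2]
    binding_efficiency: float = 1.0
    contact_area: float | None = None  # defaults to full wrapping, 4 pi R^2

    def __post_init__(self):
        if self.kappa <= 0 or self.R <= 0 or self.bond_energy <= 0:
            raise ValueError("kappa, R and bond_energy must be > 0")
        if not (0 <= self.binding_efficiency <= 1):
            raise ValueError("binding_efficiency must be in [0, 1]")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    @property
    def A_contact(self) -> float:
        return self.contact_area if self.contact_area is not None else 4 * np.pi * self.R ** 2


def sigma_si_to_kbt(sigma_n_per_m: float) -> float:
    """Convert a tension in N/m to kBT/um^2 (room temperature)."""
    return sigma_n_per_m * KBT_PER_UM2_PER_NEWTON_PER_M


def wrapping_prefactor(params: WrappingModelParams) -> float:
    """Energy per contact area, ``2 kappa/R^2 + sigma - u_ad`` [kBT/um^2].

    Negative means wrapping is favoured; positive means the particle stays
    non-wrapped.  Tension enters additively, so a tense membrane suppresses
    wrapping.
    """
    return 2.0 * params.kappa / params.R ** 2 + params.sigma - params.u_ad


def threshold_adhesion(kappa: float, R: float) -> float:
    """Zero-tension wrapping threshold ``2 kappa / R^2`` [kBT/um^2]."""
    if kappa <= 0 or R <= 0:
        raise ValueError("kappa and R must be > 0")
    return 2.0 * kappa / R ** 2


def linker_efficiency(threshold: float, bond_energy: float, critical_density: float) -> float:
    """Fraction of surface linkers that are effectively binding.

    The measured critical linker density marks where the areal adhesion
    energy of the *binding* linkers crosses the wrapping threshold:
    ``efficiency = threshold / (bond_energy * critical_density)``.
    """
    if min(threshold, bond_energy, critical_density) <= 0:
        raise ValueError("all inputs must be > 0")
    return threshold / (bond_energy * critical_density)


def wrapped_fraction_curve(
    densities,
    params: WrappingModelParams,
    density_spread: float = 0.0,
) -> np.ndarray:
    """Two-state wrapped fraction vs linker density, at ``sigma`` = params.sigma.

    The energy difference between wrapped and non-wrapped states is
    ``dE(rho) = (2 kappa/R^2 + sigma - u_ad(rho)) * A_contact`` with
    ``u_ad(rho) = binding_efficiency * bond_energy * rho``; the occupancy of
    the wrapped state is ``f = 1 / (1 + exp(dE))``.  ``f = 1/2`` exactly at
    the critical density and ``f`` is non-decreasing in ``rho``.

    ``density_spread`` (one standard deviation of the per-batch linker
    density, um^-2) optionally convolves the sharp transition with a
    Gaussian, reproducing the smooth experimental curve.
    """
    rho = np.atleast_1d(np.asarray(densities, dtype=float))
    if np.any(rho < 0):
        raise ValueError("densities must be >= 0")

    def f_sharp(r):
        u_ad = params.binding_efficiency * params.bond_energy * r
        dE = (2.0 * params.kappa / params.R ** 2 + params.sigma - u_ad) * params.A_contact
        return 1.0 / (1.0 + np.exp(np.clip(dE, -700, 700)))

    if density_spread <= 0:
        return f_sharp(rho)
    # Gauss-Hermite quadrature of E[f(rho + spread * Z)]
    nodes, weights = np.polynomial.hermite_e.hermegauss(41)
    out = np.zeros_like(rho)
    for z, w in zip(nodes, weights):
        out += w * f_sharp(np.maximum(rho + density_spread * z, 0.0))
    return np.clip(out / np.sqrt(2 * np.pi), 0.0, 1.0)


def critical_density(params: WrappingModelParams) -> float:
    """Linker density at which the wrapped fraction crosses 1/2 [um^-2]."""
    return (2.0 * params.kappa / params.R ** 2 + params.sigma) / (
        params.binding_efficiency * params.bond_energy
    )
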