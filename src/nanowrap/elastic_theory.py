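"""Elastic wrapping energetics of spherical nanoparticles on fluid lipid membranes.

A spherical particle adhering to a fluid bilayer is spontaneously wrapped when
the adhesion energy gained per unit contact area, |W|, outweighs the bending
energy cost set by the membrane bending modulus k.  For a tensionless membrane
the balance defines a critical particle diameter

    d_c = 2 * sqrt(2 k / |W|),

the smallest diameter at which full wrapping is energetically allowed.  Under
a finite lateral tension sigma the membrane must additionally pay a tension
penalty for the area drawn into the wrap, and full wrapping is only reached at
a second, larger critical diameter

    d_c_sigma = 2 * sqrt(2 k / (|W| - sigma)),

which diverges as sigma approaches |W|: particles between the two diameters
remain partially wrapped.

For a particle on a supported bilayer of finite thickness, the effective
per-area contact energy acquires curvature corrections in the wrap radius a
(nominal particle radius plus half a bilayer thickness):

    w_s = -k_w + m / a - 2 * kappa_slb / a**2,

where -k_w is the flat-surface absorption strength and m, kappa_slb are
surface-specific constants fitted to coarse-grained simulation.  The wrap
diameter above which w_s stays negative (adhesive) defines the adhesion
critical diameter; for bare gold the quadratic has no real root and particles
of every size adhere.

Interface convention: lengths are accepted and returned in nm; energies in J;
energies per area (W, sigma, k_w) in N/m (= J/m^2); m in J/m.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .constants import M_TO_NM, NM_TO_M

__all__ = [
    "MembraneSpec",
    "AdhesionSpec",
    "WrappingLabel",
    "WrappingState",
    "critical_diameter_tensionless",
    "critical_diameter_with_tension",
    "contact_energy",
    "adhesion_critical_diameter",
    "classify_wrapping",
]


@dataclass(frozen=True)
class MembraneSpec:
    """Fluid-bilayer elastic parameters.

    bending_modulus : J, > 0. Default 8.4e-20 J (~20 kBT at 298 K, the
        canonical fluid-phosphocholine value).
    tension : N/m, >= 0. Lateral membrane tension.
    thickness : nm. Full bilayer thickness.
    area_per_lipid : A^2. Area per lipid molecule (71 A^2 for DOPC/POPC).
    """

    bending_modulus: float = 8.4e-20
    tension: float = 0.0
    thickness: float = 4.0
    area_per_lipid: float = 71.0

    def __post_init__(self) -> None:
        if self.bending_modulus <= 0:
            raise ValueError("bending_modulus must be > 0")
        if self.tension < 0:
            raise ValueError("tension must be >= 0")
        if self.thickness <= 0:
            raise ValueError("thickness must be > 0")
        if self.area_per_lipid <= 0:
            raise ValueError("area_per_lipid must be > 0")


@dataclass(frozen=True)
class AdhesionSpec:
    """Particle-membrane adhesion parameters.

    adhesion_strength_W : N/m, >= 0. Magnitude |W| of the attractive
        adhesion energy per unit contact area (42 mN/m for bare gold).
    flat_strength_kw : N/m. Flat-surface absorption strength k_w entering
        the curvature-corrected contact energy.
    linear_coeff_m : J/m. Linear curvature-correction coefficient.
    slb_modulus : J. Quadratic curvature-correction coefficient kappa_slb.

    m and kappa_slb are surface-specific fitted constants and have no
    physically meaningful defaults; they must be supplied for contact-energy
    work.
    """

    adhesion_strength_W: float = 0.042
    flat_strength_kw: float = 0.0
    linear_coeff_m: float = 0.0
    slb_modulus: float = 0.0

    def __post_init__(self) -> None:
        if self.adhesion_strength_W < 0:
            raise ValueError("adhesion_strength_W must be >= 0")


class WrappingLabel(enum.Enum):
    ADHERED_UNWRAPPED = "adhered_unwrapped"
    PARTIALLY_WRAPPED = "partially_wrapped"
    FULLY_WRAPPED = "fully_wrapped"


@dataclass(frozen=True)
class WrappingState:
    """Wrapping regime of a particle of diameter d, with both critical diameters."""

    label: WrappingLabel
    dc: float  # nm
    dc_sigma: float  # nm, may be +inf

    def __post_init__(self) -> None:
        if not self.dc <= self.dc_sigma:
            raise ValueError("dc must not exceed dc_sigma")


def _require_adhesion(adhesion: AdhesionSpec) -> float:
    w = adhesion.adhesion_strength_W
    if w <= 0:
        raise ValueError("no adhesion: adhesion_strength_W must be > 0")
    return w


def critical_diameter_tensionless(
    membrane: MembraneSpec, adhesion: AdhesionSpec
) -> float:
    """Tensionless critical diameter d_c = 2*sqrt(2k/|W|), in nm."""
    w = _require_adhesion(adhesion)
    return 2.0 * math.sqrt(2.0 * membrane.bending_modulus / w) * M_TO_NM


def critical_diameter_with_tension(
    membrane: MembraneSpec, adhesion: AdhesionSpec
) -> float:
    """Critical diameter for full wrapping under tension, in nm.

    Returns 2*sqrt(2k/(|W| - sigma)); +inf when sigma >= |W| (full wrapping
    is never reached).
    """
    w = _require_adhesion(adhesion)
    sigma = membrane.tension
    if sigma >= w:
        return math.inf
    return 2.0 * math.sqrt(2.0 * membrane.bending_modulus / (w - sigma)) * M_TO_NM


def contact_energy(wrap_radius_nm: float, adhesion: AdhesionSpec) -> float:
    """Curvature-corrected contact energy w_s = -k_w + m/a - 2*kappa_slb/a^2, in N/m.

    wrap_radius_nm is the wrap radius a (nominal particle radius plus the
    wrap margin) in nm.
    """
    if wrap_radius_nm <= 0:
        raise ValueError("wrap radius must be > 0")
    a = wrap_radius_nm * NM_TO_M
    return (
        -adhesion.flat_strength_kw
        + adhesion.linear_coeff_m / a
        - 2.0 * adhesion.slb_modulus / a**2
    )


def adhesion_critical_diameter(adhesion: AdhesionSpec) -> float:
    """Smallest wrap diameter (nm) above which the contact energy is adhesive.

    Solves k_w*a^2 - m*a + 2*kappa_slb = 0.  A negative discriminant means
    the contact energy is negative at every size (the bare-gold case) and 0
    is returned; otherwise twice the larger root is returned, the wrap
    diameter above which w_s < 0 for all larger sizes.
    """
    kw = adhesion.flat_strength_kw
    if kw <= 0:
        raise ValueError("non-adhesive flat limit: flat_strength_kw must be > 0")
    m = adhesion.linear_coeff_m
    kappa = adhesion.slb_modulus
    disc = m * m - 8.0 * kw * kappa
    if disc < 0:
        return 0.0
    a_larger = (m + math.sqrt(disc)) / (2.0 * kw)
    if a_larger <= 0:
        return 0.0
    return 2.0 * a_larger * M_TO_NM


def classify_wrapping(
    d_nm: float, membrane: MembraneSpec, adhesion: AdhesionSpec
) -> WrappingState:
    """Classify a particle of diameter d (nm) into a wrapping regime.

    ADHERED_UNWRAPPED for d < dc, PARTIALLY_WRAPPED for dc <= d < dc_sigma,
    FULLY_WRAPPED for d >= dc_sigma.
    """
    if d_nm <= 0:
        raise ValueError("diameter must be > 0")
    dc = critical_diameter_tensionless(membrane, adhesion)
    dc_sigma = critical_diameter_with_tension(membrane, adhesion)
    if d_nm < dc:
        label = WrappingLabel.ADHERED_UNWRAPPED
    elif d_nm < dc_sigma:
        label = WrappingLabel.PARTIALLY_WRAPPED
    else:
        label = WrappingLabel.FULLY_WRAPPED
    return WrappingState(label=label, dc=dc, dc_sigma=dc_sigma)
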