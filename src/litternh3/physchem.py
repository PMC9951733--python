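"""Ammonia speciation and flux-chamber physics.

Two quantities connect litter chemistry to air emissions:

* the **generation potential** — the dissolved NH₃-N concentration a litter
  sample can sustain given its total ammoniacal nitrogen (TAN), pH and
  moisture, from the Freundlich-partition speciation balance

      [NH₃-N]ₗ = 1000·TAN / { K_f·10⁻ᵖᴴ/K_d0 + MC·(1 + 10⁻ᵖᴴ/K_d0)/ρ_H₂O }

  with TAN in µg·g⁻¹ dry basis, MC the moisture content (% w/w dry basis)
  and the result in µg·L⁻¹;

* the **SMDAE flux** — the NH₃ mass flux captured by the sponge device
  (Saraz Method for Determination of Ammonia Emissions),
  flux = captured mass / (sponge area × exposure time).

K_f (Freundlich partition coefficient, L·kg⁻¹) and K_d0 (dissociation
constant in water, dimensionless) are litter- and temperature-dependent
constants that must be supplied by the user; the defaults below are
order-of-magnitude placeholders (K_d0 near the ammonium dissociation
constant at ambient temperature), not measured values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: g·kg⁻¹ → µg·g⁻¹ (litter tables store ammoniacal N in g·kg⁻¹).
G_PER_KG_TO_UG_PER_G = 1000.0


@dataclass(frozen=True)
class PhysChemConstants:
    """Speciation constants for the generation-potential balance.

    Attributes
    ----------
    kf : float
        Freundlich partition coefficient, L·kg⁻¹.  Placeholder default 1.0;
        set from sorption measurements for the litter at hand.
    kd0 : float
        NH₄⁺/NH₃ dissociation constant in water, dimensionless.
        Placeholder default 1e-9 (ambient-temperature order of magnitude).
    rho_water : float
        Water density, kg·L⁻¹ (default 1.0).
    """

    kf: float = 1.0
    kd0: float = 1e-9
    rho_water: float = 1.0

    def __post_init__(self):
        if self.kf <= 0 or self.kd0 <= 0 or self.rho_water <= 0:
            raise ValueError("kf, kd0 and rho_water must all be > 0")


@dataclass(frozen=True)
class SMDAEMeasurement:
    """One sponge capture: NH₃ mass (g), sponge diameter (m), exposure time (s).

    Only the lower capture sponge enters the flux; the upper sponge shields
    against ambient contamination and is not modelled.
    """

    nh3_mass: float
    sponge_diameter: float = 0.20  # the standard 20 cm device
    exposure_time: float = 86_400.0  # 24 h

    def __post_init__(self):
        if self.nh3_mass < 0:
            raise ValueError("nh3_mass must be >= 0")
        if self.sponge_diameter <= 0:
            raise ValueError("sponge_diameter must be > 0")
        if self.exposure_time <= 0:
            raise ValueError("exposure_time must be > 0")

    @property
    def sponge_area(self) -> float:
        """Sponge face area, m²."""
        return math.pi * (self.sponge_diameter / 2.0) ** 2


def nh3_generation_potential(tan, ph, mc, constants: PhysChemConstants = PhysChemConstants()):
    """Dissolved-phase NH₃-N concentration (µg·L⁻¹) a litter sample can generate.

    Parameters
    ----------
    tan : array_like
        Total ammoniacal nitrogen, µg·g⁻¹ dry basis (use
        :data:`G_PER_KG_TO_UG_PER_G` to convert from the g·kg⁻¹ of the
        sample tables).
    ph : array_like
        Litter pH (0–14).
    mc : array_like
        Moisture content, % w/w dry basis; must be > 0 unless the sorption
        term K_f·10⁻ᵖᴴ/K_d0 is itself nonzero.
    constants : PhysChemConstants

    The result is homogeneous of degree 1 in TAN and monotone non-decreasing
    in pH (a higher pH shifts the NH₄⁺/NH₃ balance toward free ammonia).
    """
    tan = np.asarray(tan, dtype=float)
    ph = np.asarray(ph, dtype=float)
    mc = np.asarray(mc, dtype=float)
    if np.any(tan < 0):
        raise ValueError("tan must be >= 0")
    if np.any((ph < 0) | (ph > 14)):
        raise ValueError("ph must lie in [0, 14]")
    if np.any(mc < 0):
        raise ValueError("mc must be >= 0")

    h = 10.0 ** (-ph) / constants.kd0
    denom = constants.kf * h + mc * (1.0 + h) / constants.rho_water
    if np.any(denom == 0):
        raise ZeroDivisionError(
            "generation potential undefined: moisture is zero and the sorption "
            "term K_f·10^(-pH)/K_d0 vanishes, so no phase can hold the TAN"
        )
    result = 1000.0 * tan / denom
    return result if result.ndim else float(result)


def smdae_flux(m: SMDAEMeasurement, as_mg: bool = False) -> float:
    """NH₃ mass flux through the capture sponge, g·m⁻²·s⁻¹.

    ``as_mg=True`` returns mg·m⁻²·s⁻¹ instead.
    """
    flux = m.nh3_mass / (m.sponge_area * m.exposure_time)
    return flux * 1000.0 if as_mg else flux
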