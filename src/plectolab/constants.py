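"""Physical constants and unit helpers.

Internal unit system: force in pN, length in nm, time in s, energy in
pN*nm, temperature in K.  Viscosity is accepted in Pa*s and bead radii
in um at API boundaries because that is how instrument parameters are
quoted; the converters below produce drag coefficients in internal
units.
"""

from __future__ import annotations

#: Boltzmann constant in pN*nm/K (1.38e-23 J/K = 0.0138 pN*nm/K).
KB_PN_NM_PER_K = 0.0138

#: Default absolute temperature (K); bead-local temperature in the
#: instrument is elevated above room temperature by NIR absorption.
DEFAULT_TEMPERATURE_K = 310.0

#: Default dynamic viscosity of water near 25 C (Pa*s).
DEFAULT_VISCOSITY_PA_S = 8.9e-4

#: B-DNA helical repeat (bp per turn) and axial rise (nm per bp).
HELICAL_REPEAT_BP = 10.5
RISE_NM_PER_BP = 0.34

#: kcal/mol expressed in pN*nm (per molecule).
KCAL_PER_MOL_PN_NM = 6.9477

# 1 N*s/m -> 1e3 pN*s/nm ; 1 N*m*s -> 1e21 pN*nm*s
_NSM_TO_PNS_PER_NM = 1.0e3
_NMS_TO_PN_NM_S = 1.0e21


def kbt(temperature_K: float = DEFAULT_TEMPERATURE_K) -> float:
    """Thermal energy kB*T in pN*nm."""
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    return KB_PN_NM_PER_K * temperature_K


def drag_translational(bead_radius_um: float,
                       viscosity_Pa_s: float = DEFAULT_VISCOSITY_PA_S) -> float:
    """Stokes drag 6*pi*eta*R for a sphere, in pN*s/nm."""
    if bead_radius_um <= 0 or viscosity_Pa_s <= 0:
        raise ValueError("radius and viscosity must be positive")
    import math
    gamma_si = 6.0 * math.pi * viscosity_Pa_s * bead_radius_um * 1e-6
    return gamma_si * _NSM_TO_PNS_PER_NM


def drag_rotational(bead_radius_um: float,
                    viscosity_Pa_s: float = DEFAULT_VISCOSITY_PA_S) -> float:
    """Rotational drag 8*pi*eta*R^3 for a sphere, in pN*nm*s/rad."""
    if bead_radius_um <= 0 or viscosity_Pa_s <= 0:
        raise ValueError("radius and viscosity must be positive")
    import math
    gamma_si = 8.0 * math.pi * viscosity_Pa_s * (bead_radius_um * 1e-6) ** 3
    return gamma_si * _NMS_TO_PN_NM_S
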