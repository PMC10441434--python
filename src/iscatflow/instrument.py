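"""Closed-form instrument quantities.

Pure arithmetic on the platform's optical, geometric and physico-chemical
parameters: field-of-view size, diffraction-limited packing bounds,
irradiance, effective frame rate, ligand areal densities and
Stokes-Einstein diffusion coefficients.  Everything here is exact and
unit-checked; nothing touches image data.
"""

from __future__ import annotations

import math

AVOGADRO = 6.02214076e23  # 1/mol
BOLTZMANN = 1.380649e-23  # J/K


def fov_side_um(frame_side_px: int = 1024, pixel_pitch_camera_um: float = 6.5,
                magnification: float = 100.0) -> float:
    """Field-of-view side length at the sample plane, in um."""
    if frame_side_px <= 0 or pixel_pitch_camera_um <= 0 or magnification <= 0:
        raise ValueError("all geometry parameters must be positive")
    return frame_side_px * pixel_pitch_camera_um / magnification


def diffraction_packing_limit(resolution_um: float = 0.25) -> float:
    """Upper bound on distinguishable particles per um^2.

    One particle per resolution-limited square: 1/resolution^2, i.e.
    16/um^2 at a 250 nm lateral resolution.
    """
    if resolution_um <= 0:
        raise ValueError("resolution must be positive")
    return 1.0 / resolution_um**2


def packing_headroom(resolution_um: float = 0.25,
                     observed_limit_per_um2: float = 2.0) -> float:
    """Ratio of the diffraction packing bound to the observed density limit."""
    if observed_limit_per_um2 <= 0:
        raise ValueError("observed limit must be positive")
    return diffraction_packing_limit(resolution_um) / observed_limit_per_um2


def irradiance_uW_per_um2(power_mW: float = 1.4,
                          illumination_diameter_um: float = 89.5) -> float:
    """Mean irradiance of a flat-top disc, in uW/um^2."""
    if power_mW <= 0 or illumination_diameter_um <= 0:
        raise ValueError("power and diameter must be positive")
    area = math.pi * (illumination_diameter_um / 2.0) ** 2
    return power_mW * 1e3 / area


def effective_frame_rate_hz(frames_averaged: int = 100,
                            frame_rate_hz: float = 100.0) -> float:
    """Time resolution after on-camera frame averaging, in Hz."""
    if frames_averaged <= 0 or frame_rate_hz <= 0:
        raise ValueError("frame counts and rates must be positive")
    return frame_rate_hz / frames_averaged


def areal_density_pmol_per_cm2(molecules_per_100nm2: float = 1.4) -> float:
    """Convert molecules per 10x10 nm^2 to pmol/cm^2.

    1.4 biotins per 100 nm^2 corresponds to 2.3 pmol/cm^2.
    """
    if molecules_per_100nm2 < 0:
        raise ValueError("density cannot be negative")
    per_cm2 = molecules_per_100nm2 / 100e-14  # 100 nm^2 = 1e-12 cm^2
    return per_cm2 / AVOGADRO * 1e12


def stokes_einstein_D_um2_per_s(diameter_nm: float = 150.0,
                                temperature_K: float = 298.0,
                                viscosity_Pa_s: float = 0.89e-3) -> float:
    """Stokes-Einstein diffusion coefficient of a sphere, in um^2/s.

    A 150 nm vesicle in water at 25 C diffuses at ~3 um^2/s.
    """
    if diameter_nm <= 0 or temperature_K <= 0 or viscosity_Pa_s <= 0:
        raise ValueError("all parameters must be positive")
    radius_m = diameter_nm * 1e-9 / 2.0
    D = BOLTZMANN * temperature_K / (6.0 * math.pi * viscosity_Pa_s * radius_m)
    return D * 1e12  # m^2/s -> um^2/s


def volumetric_concentration_M(areal_density_pmol_per_cm2: float = 0.08,
                               channel_height_um: float = 10.0) -> float:
    """Effective molar concentration of a surface-bound species in a channel.

    Distributes an areal density over the channel height:
    0.08 pmol/cm^2 over 10 um gives 8e-8 M (80 nM).
    """
    if areal_density_pmol_per_cm2 < 0 or channel_height_um <= 0:
        raise ValueError("invalid density or height")
    mol_per_cm2 = areal_density_pmol_per_cm2 * 1e-12
    height_cm = channel_height_um * 1e-4
    mol_per_cm3 = mol_per_cm2 / height_cm
    return mol_per_cm3 * 1e3  # mol/cm^3 -> mol/L
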