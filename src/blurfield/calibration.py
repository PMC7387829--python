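"""Display geometry, unit conversions and image-quality criteria.

All angles are handled in degrees at the API surface, defocus in diopters,
Zernike coefficients in micrometers and lengths in millimeters.  The display
defaults describe a 15 deg square field rendered on a 2160 x 2160 pixel
raster, i.e. one pixel subtends about 0.4 arcmin -- roughly the angular size
of a foveal cone.
"""

from __future__ import annotations

import numpy as np

#: Full visual angle of the projected field, degrees.
DISPLAY_FIELD_DEG = 15.0
#: Linear raster size of the rendered stimulus, pixels.
DISPLAY_SIZE_PX = 2160
#: Radial extent of the blur-profile region, degrees (half the display field).
BLUR_EXTENT_DEG = 7.5
#: Number of annular rings the blur region is split into.
N_RINGS = 20
#: Simulation pupil diameter used for the synthesis PSFs, mm.
PSF_PUPIL_MM = 2.0
#: Monochromatic simulation wavelength, nm.
WAVELENGTH_NM = 550.0
#: Defocus grid for the precomputed PSF set, diopters.
DEFOCUS_MAX_D = 5.0
DEFOCUS_STEP_D = 0.05

ARCMIN_PER_RAD = 60.0 * 180.0 / np.pi


def pixel_scale_arcmin(field_deg: float = DISPLAY_FIELD_DEG,
                       size_px: int = DISPLAY_SIZE_PX) -> float:
    """Angular size of one display pixel in arcmin (15*60/2160 = 0.4167')."""
    if field_deg <= 0 or size_px <= 0:
        raise ValueError("field_deg and size_px must be positive")
    return field_deg * 60.0 / size_px


def ring_width_deg(extent_deg: float = BLUR_EXTENT_DEG,
                   n_rings: int = N_RINGS) -> float:
    """Width of one annular blur ring in degrees (7.5/20 = 0.375)."""
    if extent_deg <= 0 or n_rings <= 0:
        raise ValueError("extent_deg and n_rings must be positive")
    return extent_deg / n_rings


def marechal_rms_um(wavelength_nm: float) -> float:
    """Marechal criterion: the RMS wavefront error (um) of a just
    diffraction-limited system, lambda/14 (0.06 um at 840 nm)."""
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    return wavelength_nm * 1e-3 / 14.0


def arcmin_to_rad(arcmin: float) -> float:
    return arcmin / ARCMIN_PER_RAD


def rad_to_arcmin(rad: float) -> float:
    return rad * ARCMIN_PER_RAD
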