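"""Fourier-optics blur synthesis with annular sigmoid blur profiles.

Defocus point-spread functions are computed from the Zernike defocus mode
only: the pupil function is ``g(u,v) = A(u,v) exp(i 2 pi W(u,v) / lambda)``
with ``W = c20 * Z20``, ``Z20 = sqrt(3) (2 rho^2 - 1)``, and
``PSF = |FT(g)|^2``.  The defocus coefficient relates to the spherical
equivalent ``M`` (diopters) through ``c20 = M r^2 / (4 sqrt(3))`` with ``r``
the simulation pupil radius in mm (c20 in um).  PSFs are synthesised for a
2 mm pupil at 550 nm and precomputed on a 0 to 5 D grid in 0.05 D steps.

Spatially-varying ("global") blur composites 20 concentric annular rings of
0.375 deg width whose defocus follows a normalized sigmoid radial profile
``y(E; K) = E / (1 + K (1 - E))`` scaled by the defocus peak ``a`` at the
largest eccentricity (7.5 deg).  Zonal blur applies a single level inside
one 1.5 deg annulus on a uniform background.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .calibration import (BLUR_EXTENT_DEG, DEFOCUS_MAX_D, DEFOCUS_STEP_D,
                          N_RINGS, PSF_PUPIL_MM, WAVELENGTH_NM,
                          arcmin_to_rad, pixel_scale_arcmin)

__all__ = [
    "DefocusSpec", "PsfKernel", "BlurProfile", "ZonalSpec",
    "c20_from_diopters", "defocus_psf", "psf_for_diopters", "convolve_blur",
    "sigmoid_profile", "blur_volume_fraction", "compose_spatially_varying",
    "zonal_stimulus", "ring_table",
]

_SQRT3 = np.sqrt(3.0)
ZONAL_WIDTH_DEG = 1.5
ZONAL_OUTER_ECCENTRICITIES_DEG = (1.5, 3.0, 4.5, 6.0, 7.5)


def c20_from_diopters(M_diopters: float, pupil_radius_mm: float) -> float:
    """Zernike defocus coefficient (um) for a spherical equivalent in D."""
    if pupil_radius_mm <= 0:
        raise ValueError("pupil radius must be positive")
    return M_diopters * pupil_radius_mm ** 2 / (4.0 * _SQRT3)


@dataclass(frozen=True)
class DefocusSpec:
    """A pure-defocus aberration: spherical equivalent + simulation pupil."""

    M_diopters: float
    pupil_radius_mm: float = PSF_PUPIL_MM / 2.0
    wavelength_nm: float = WAVELENGTH_NM

    @property
    def c20_um(self) -> float:
        return c20_from_diopters(self.M_diopters, self.pupil_radius_mm)


@dataclass
class PsfKernel:
    """Unit-sum defocus PSF sampled at the display pixel scale."""

    intensity: np.ndarray
    pixel_scale_arcmin: float
    source: DefocusSpec

    @property
    def half_width(self) -> int:
        return self.intensity.shape[0] // 2


@dataclass(frozen=True)
class BlurProfile:
    """Sigmoid radial defocus distribution and its ring quantization.

    ``K`` sets the shape (K = 0 is the linear profile, K > 0 concentrates
    blur in the far periphery, -1 < K < 0 spreads it inward); ``peak_a_D``
    is the defocus at the maximum eccentricity.
    """

    K: float
    peak_a_D: float
    extent_deg: float = BLUR_EXTENT_DEG
    n_rings: int = N_RINGS

    def __post_init__(self):
        if self.K <= -1.0:
            raise ValueError("K must be > -1 (sigmoid denominator vanishes)")
        if self.peak_a_D < 0:
            raise ValueError("defocus peak must be >= 0")
        if self.extent_deg <= 0 or self.n_rings <= 0:
            raise ValueError("extent and ring count must be positive")

    @property
    def ring_width_deg(self) -> float:
        return self.extent_deg / self.n_rings

    def ring_outer_deg(self) -> np.ndarray:
        return np.arange(1, self.n_rings + 1) * self.ring_width_deg

    def ring_defocus_D(self, reference: str = "outer") -> np.ndarray:
        """Unquantized defocus of each ring, sampled at its outer edge
        (default) or ring center."""
        e = self.ring_outer_deg()
        if reference == "center":
            e = e - self.ring_width_deg / 2.0
        elif reference != "outer":
            raise ValueError("reference must be 'outer' or 'center'")
        return self.peak_a_D * sigmoid_profile(e / self.extent_deg, self.K)


@dataclass(frozen=True)
class ZonalSpec:
    """One 1.5 deg wide annulus carrying a single blur level."""

    outer_ecc_deg: float
    blur_D: float
    width_deg: float = ZONAL_WIDTH_DEG

    def __post_init__(self):
        if self.outer_ecc_deg <= 0 or self.width_deg <= 0:
            raise ValueError("zone geometry must be positive")
        if self.outer_ecc_deg < self.width_deg:
            raise ValueError("annulus inner edge would be negative")

    @property
    def inner_ecc_deg(self) -> float:
        return self.outer_ecc_deg - self.width_deg


# ---------------------------------------------------------------------------
# sigmoid blur profile


def sigmoid_profile(E_norm, K: float):
    """Normalized sigmoid blur profile y(E; K) = E / (1 + K (1 - E)).

    ``E_norm`` is eccentricity normalized to the profile extent (0..1);
    y(0) = 0 and y(1) = 1 for every admissible K, and K -> 0 gives the
    linear profile y = E.
    """
    if K <= -1.0:
        raise ValueError("K must be > -1")
    E = np.asarray(E_norm, dtype=float)
    if np.any((E < -1e-12) | (E > 1.0 + 1e-12)):
        raise ValueError("normalized eccentricity must lie in [0, 1]")
    out = E / (1.0 + K * (1.0 - E))
    return float(out) if np.isscalar(E_norm) else out


def blur_volume_fraction(K: float) -> float:
    """Area under y(.; K) over [0, 1] as a fraction of the linear profile's.

    Closed form: A(K) = -1/K + (1+K)/K^2 * ln(1+K); the fraction is
    A(K)/A(0) with A(0) = 1/2.  K = 0 returns exactly 1.
    """
    if K <= -1.0:
        raise ValueError("K must be > -1")
    if abs(K) < 1e-8:
        # series: A = 1/2 - K/6 + K^2/12 - ...
        area = 0.5 - K / 6.0 + K ** 2 / 12.0
    else:
        area = -1.0 / K + (1.0 + K) / K ** 2 * np.log1p(K)
    return float(area / 0.5)


# ---------------------------------------------------------------------------
# defocus PSF synthesis


def defocus_psf(spec: DefocusSpec,
                grid_size: int = 1024,
                pixel_scale_arcmin_: float | None = None,
                oversample: int | None = None,
                min_pad_factor: float = 4.0,
                tail_energy: float = 1e-8) -> PsfKernel:
    """Defocus PSF via the squared Fourier transform of the pupil function.

    The pupil is embedded in a fine grid whose FFT samples the PSF at
    ``pixel_scale / oversample``; the fine PSF is then binned ``oversample``-
    fold (bins centered on the peak pixel, preserving the rotational
    symmetry of pure defocus) and cropped to the support holding all but
    ``tail_energy`` of the energy.  The result sums to one.
    """
    scale = pixel_scale_arcmin_ if pixel_scale_arcmin_ is not None \
        else pixel_scale_arcmin()
    if oversample is None:
        # smallest odd oversampling that keeps the pupil embedding >= 4x
        diff_arcmin = (spec.wavelength_nm * 1e-6 / (2 * spec.pupil_radius_mm)) \
            * 60.0 * 180.0 / np.pi
        oversample = int(np.ceil(min_pad_factor * scale / diff_arcmin))
        oversample += 1 - oversample % 2
    if oversample < 1 or oversample % 2 == 0:
        raise ValueError("oversample must be a positive odd integer")
    dtheta_fine = arcmin_to_rad(scale) / oversample
    wl_mm = spec.wavelength_nm * 1e-6
    du = wl_mm / (grid_size * dtheta_fine)          # pupil-plane spacing, mm
    D = 2.0 * spec.pupil_radius_mm
    pad = grid_size * du / D
    if pad < min_pad_factor:
        raise ValueError(
            f"grid embeds the pupil only {pad:.2f}x; need >= {min_pad_factor}x "
            "(increase grid_size or coarsen the pixel scale)")

    c0 = grid_size // 2
    x = (np.arange(grid_size) - c0) * du
    X, Y = np.meshgrid(x, x, indexing="xy")
    rho2 = (X ** 2 + Y ** 2) / spec.pupil_radius_mm ** 2
    mask = rho2 <= 1.0
    w_um = spec.c20_um * _SQRT3 * (2.0 * rho2 - 1.0)
    g = np.where(mask, np.exp(2j * np.pi * w_um / (spec.wavelength_nm * 1e-3)), 0.0)
    psf = np.abs(np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(g)))) ** 2
    total = psf.sum()

    # clipping check: energy in the outermost frame
    border = psf.copy()
    border[oversample:-oversample, oversample:-oversample] = 0.0
    if border.sum() / total > 0.01:
        raise ValueError("PSF support clipped by the grid (>1% energy at the "
                         "border); increase grid_size")

    # crop to an odd multiple of `oversample` centered on c0, keeping the tail
    prof = np.maximum(psf.sum(axis=0), psf.sum(axis=1))
    cum = np.cumsum(prof) / prof.sum()
    m_lo = int(np.searchsorted(cum, tail_energy / 2.0))
    half = max(c0 - m_lo, oversample)
    m = int(np.ceil((half - 1) / oversample))                # coarse half-width
    m = max(1, min(m, (c0 - 1) // oversample - 1))
    K = 2 * m + 1
    half_fine = (K * oversample) // 2
    crop = psf[c0 - half_fine:c0 + half_fine + 1,
               c0 - half_fine:c0 + half_fine + 1]
    coarse = crop.reshape(K, oversample, K, oversample).sum(axis=(1, 3))
    coarse /= coarse.sum()
    return PsfKernel(intensity=coarse, pixel_scale_arcmin=scale, source=spec)


@lru_cache(maxsize=256)
def _cached_psf(M_key: int, pupil_radius_mm: float, wavelength_nm: float,
                scale_arcmin: float, grid_size: int,
                oversample: int | None) -> PsfKernel:
    spec = DefocusSpec(M_key * DEFOCUS_STEP_D, pupil_radius_mm, wavelength_nm)
    return defocus_psf(spec, grid_size=grid_size,
                       pixel_scale_arcmin_=scale_arcmin, oversample=oversample)


def psf_for_diopters(M: float, pupil_radius_mm: float = PSF_PUPIL_MM / 2.0,
                     wavelength_nm: float = WAVELENGTH_NM,
                     scale_arcmin: float | None = None,
                     grid_size: int = 1024,
                     oversample: int | None = None) -> PsfKernel:
    """PSF from the precomputed 0.05 D set (requested defocus rounded to the
    nearest step; 0 to 5 D supported)."""
    if not (0.0 <= M <= DEFOCUS_MAX_D + 1e-9):
        raise ValueError(f"defocus {M} D outside the precomputed 0-{DEFOCUS_MAX_D} D set")
    scale = scale_arcmin if scale_arcmin is not None else pixel_scale_arcmin()
    M_key = int(round(M / DEFOCUS_STEP_D))
    return _cached_psf(M_key, pupil_radius_mm, wavelength_nm, scale,
                       grid_size, oversample)


# ---------------------------------------------------------------------------
# convolution and compositing


def convolve_blur(image: np.ndarray, kernel: PsfKernel,
                  image_scale_arcmin: float | None = None) -> np.ndarray:
    """Linear convolution with mirror-reflected edge padding.

    The kernel and image pixel scales must match; mean luminance is
    preserved to well within 0.1 % because the kernel sums to one.
    """
    scale = image_scale_arcmin if image_scale_arcmin is not None \
        else pixel_scale_arcmin()
    if abs(scale - kernel.pixel_scale_arcmin) > 1e-9 * max(scale, 1.0):
        raise ValueError("kernel pixel scale does not match the image scale")
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    k = kernel.half_width
    if k == 0:
        return img * kernel.intensity.sum()
    padded = np.pad(img, k, mode="reflect")
    out = fftconvolve(padded, kernel.intensity, mode="same")
    return out[k:-k, k:-k]


def _eccentricity_map(shape, scale_arcmin, center=None):
    h, w = shape
    if center is None:
        center = (w / 2.0, h / 2.0)
    ys = (np.arange(h) + 0.5) - center[1]
    xs = (np.arange(w) + 0.5) - center[0]
    E = np.hypot(xs[None, :], ys[:, None]) * scale_arcmin / 60.0
    return E  # degrees


def ring_table(profile: BlurProfile, reference: str = "outer") -> pd.DataFrame:
    """Per-ring geometry and (quantized) defocus for a blur profile."""
    outer = profile.ring_outer_deg()
    d_raw = profile.ring_defocus_D(reference)
    d_q = np.round(d_raw / DEFOCUS_STEP_D) * DEFOCUS_STEP_D
    r_psf = PSF_PUPIL_MM / 2.0
    return pd.DataFrame({
        "ring": np.arange(1, profile.n_rings + 1),
        "inner_deg": outer - profile.ring_width_deg,
        "outer_deg": outer,
        "defocus_D": d_q,
        "c20_um": [c20_from_diopters(d, r_psf) for d in d_q],
    })


def compose_spatially_varying(image: np.ndarray, profile: BlurProfile,
                              scale_arcmin: float | None = None,
                              center=None, reference: str = "outer",
                              psf_grid_size: int = 1024):
    """Spatially-varying blur: annular composite of defocused copies.

    Every pixel is assigned to exactly one ring by its center eccentricity
    (rings exactly partition the field; pixels beyond the profile extent,
    i.e. the display corners, continue the outermost ring).  Each distinct
    quantized ring defocus triggers one full-image convolution; the masked
    copies are summed.  Returns ``(blurred image, ring table)``.
    """
    scale = scale_arcmin if scale_arcmin is not None else pixel_scale_arcmin()
    if profile.peak_a_D > DEFOCUS_MAX_D + 1e-9:
        raise ValueError(f"defocus peak {profile.peak_a_D} D exceeds the "
                         f"precomputed {DEFOCUS_MAX_D} D PSF set")
    half_extent = min(image.shape) * scale / 60.0 / 2.0
    if profile.extent_deg > half_extent + 1e-9:
        raise ValueError("profile extent exceeds the image half-extent")
    img = np.asarray(image, dtype=float)
    table = ring_table(profile, reference)
    E = _eccentricity_map(img.shape, scale, center)
    ring_idx = np.clip(np.ceil(E / profile.ring_width_deg).astype(int),
                       1, profile.n_rings)
    out = np.zeros_like(img)
    for d_q, group in table.groupby("defocus_D"):
        sel = np.isin(ring_idx, group["ring"].to_numpy())
        if d_q < DEFOCUS_STEP_D / 2:
            blurred = img
        else:
            kern = psf_for_diopters(float(d_q), scale_arcmin=scale,
                                    grid_size=psf_grid_size)
            blurred = convolve_blur(img, kern, image_scale_arcmin=scale)
        out[sel] = blurred[sel]
    return out, table


def zonal_stimulus(image: np.ndarray, zone: ZonalSpec,
                   background_level: float,
                   scale_arcmin: float | None = None, center=None,
                   psf_grid_size: int = 1024) -> np.ndarray:
    """Single-level blur inside one annulus, uniform background elsewhere."""
    scale = scale_arcmin if scale_arcmin is not None else pixel_scale_arcmin()
    img = np.asarray(image, dtype=float)
    half_extent = min(img.shape) * scale / 60.0 / 2.0
    if zone.outer_ecc_deg > half_extent + 1e-9:
        raise ValueError("zone lies outside the displayed field")
    if zone.blur_D < DEFOCUS_STEP_D / 2:
        blurred = img
    else:
        kern = psf_for_diopters(zone.blur_D, scale_arcmin=scale,
                                grid_size=psf_grid_size)
        blurred = convolve_blur(img, kern, image_scale_arcmin=scale)
    E = _eccentricity_map(img.shape, scale, center)
    annulus = (E > zone.inner_ecc_deg) & (E <= zone.outer_ecc_deg)
    out = np.full_like(img, float(background_level))
    out[annulus] = blurred[annulus]
    return out
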