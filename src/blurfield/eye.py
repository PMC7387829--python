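"""Wide-field schematic eye and exact sequential ray tracing.

The eye is the unaccommodated wide-angle Navarro model: four conic refracting
surfaces (anterior/posterior cornea, anterior/posterior crystalline lens)
followed by a spherical retina, with homogeneous media (cornea, aqueous,
lens, vitreous) whose indices are interpolated from the published dispersion
table at the requested wavelength.  Rays are traced exactly (closed-form
conic intersection + vector Snell refraction), so oblique field aberrations
are reproduced without paraxial approximation.

Geometry and conventions
------------------------
* Right-handed coordinates, +z into the eye, corneal vertex of the
  unperturbed eye at the origin.
* The limiting aperture is the simulator's artificial pupil, optically
  conjugated to the eye pupil: it is modelled as a disk in the iris plane
  (anterior lens vertex, z = 3.6 mm), *fixed in world coordinates*.
  Collimated beams of the requested field angle are ray-aimed through the
  cornea so that they exactly fill this stop; the chief ray is the ray
  through the stop center.
* Rigid-body misalignment of the eye (fixational tip/tilt about the corneal
  vertex, then transverse decenter) moves the eye behind the fixed stop and
  beam, mimicking fixational eye movements behind a stationary instrument
  pupil.
* On-axis defocus of the aligned eye is nulled once at build time by an
  ideal thin "Badal" lens (a pure quadratic optical-path term at the input
  plane); field curvature and oblique aberrations are left untouched.

The wavefront at a field point is the optical path accumulated from a plane
wavefront in object space to each ray's retinal intersection, referenced to
the chief ray, with piston and tilt removed.  For a focused beam this is
equivalent to the classical exit-pupil reference-sphere OPD (the retinal
sphere and the reference sphere agree to second order within the spot), and
it makes an aberration-free (index-matched, flat-retina) system yield an
identically zero wavefront.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np

from .calibration import ARCMIN_PER_RAD

__all__ = [
    "ConicSurface", "Perturbation", "FieldPoint", "EyeModel", "FieldAnalysis",
    "SpotDiagram", "build_eye", "trace_rays", "field_analysis", "spot_diagram",
    "strehl_batch", "paraxial_back_focal_distance_mm", "strehl_from_wavefront",
    "VignettingError", "ZERO_PERTURBATION",
]

_BRANCH_TOL_MM = 1e-7


class VignettingError(RuntimeError):
    """Raised when too many pupil rays are lost for a meaningful analysis."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ConicSurface:
    """One conic refracting (or image) surface of the eye.

    The surface is the principal cap of the quadric
    ``x^2 + y^2 - 2 R (z - v) + (1 + Q) (z - v)^2 = 0`` with vertex ``v``,
    apical radius of curvature ``R`` (signed, mm) and conic constant ``Q``.
    ``radius_mm = inf`` denotes a plane.
    """

    vertex_mm: float
    radius_mm: float
    conic: float
    index_before: float
    index_after: float
    semi_aperture_mm: float
    name: str = ""

    def __post_init__(self):
        if self.radius_mm == 0:
            raise ValueError("radius_of_curvature must be nonzero (use inf for a plane)")
        if self.semi_aperture_mm <= 0:
            raise ValueError("semi_aperture must be positive")
        # the sag must be real over the full clear aperture
        if np.isfinite(self.radius_mm) and (1.0 + self.conic) > 0:
            h_max2 = self.radius_mm ** 2 / (1.0 + self.conic)
            if self.semi_aperture_mm ** 2 > h_max2:
                raise ValueError("semi_aperture exceeds the conic's real-sag domain")

    def sag(self, h):
        """Axial sag z - vertex at radial height h (mm), principal branch."""
        h2 = np.asarray(h, dtype=float) ** 2
        if np.isinf(self.radius_mm):
            return np.zeros_like(h2)
        R, Q = self.radius_mm, self.conic
        arg = 1.0 - (1.0 + Q) * h2 / R ** 2
        return h2 / (R * (1.0 + np.sqrt(np.maximum(arg, 0.0))))


@dataclass(frozen=True)
class Perturbation:
    """Rigid-body misalignment of the eye relative to the fixed stop.

    The eye is first rotated about the (unperturbed) corneal vertex -- tip
    about the horizontal x-axis, tilt about the vertical y-axis -- and then
    decentered transversally.  Angles in degrees, decenters in mm.
    """

    tip_deg: float = 0.0
    tilt_deg: float = 0.0
    decenter_x_mm: float = 0.0
    decenter_y_mm: float = 0.0

    @property
    def is_zero(self) -> bool:
        return (self.tip_deg == 0 and self.tilt_deg == 0
                and self.decenter_x_mm == 0 and self.decenter_y_mm == 0)

    def mirrored(self) -> "Perturbation":
        """The perturbation seen after a 180 deg rotation of the scene about
        the optical axis (used by the meridian-symmetry property)."""
        return Perturbation(-self.tip_deg, -self.tilt_deg,
                            -self.decenter_x_mm, -self.decenter_y_mm)

    def as_arrays(self):
        return (np.array([self.tip_deg]), np.array([self.tilt_deg]),
                np.array([self.decenter_x_mm]), np.array([self.decenter_y_mm]))


ZERO_PERTURBATION = Perturbation()


@dataclass(frozen=True)
class FieldPoint:
    """Object-space field point: visual eccentricity and meridian (deg)."""

    eccentricity_deg: float
    meridian_deg: float = 0.0

    def __post_init__(self):
        if self.eccentricity_deg < 0:
            raise ValueError("eccentricity must be >= 0")
        if not (0 <= self.meridian_deg < 360):
            object.__setattr__(self, "meridian_deg", self.meridian_deg % 360.0)

    def direction(self) -> np.ndarray:
        """Unit propagation vector of the incoming collimated beam."""
        e = np.deg2rad(self.eccentricity_deg)
        m = np.deg2rad(self.meridian_deg)
        return np.array([np.sin(e) * np.cos(m), np.sin(e) * np.sin(m), np.cos(e)])


@dataclass
class EyeModel:
    """Ordered conic refracting surfaces plus spherical retina."""

    surfaces: tuple[ConicSurface, ...]
    retina: ConicSurface
    wavelength_nm: float
    stop_z_mm: float = 3.6
    stop_diameter_mm: float = 1.35
    badal_diopters: float = 0.0
    name: str = "wide-angle schematic eye"

    def __post_init__(self):
        if len(self.surfaces) != 4:
            raise ValueError("the schematic eye has exactly 4 refracting surfaces")
        verts = [s.vertex_mm for s in self.surfaces] + [self.retina.vertex_mm]
        if not all(a < b for a, b in zip(verts, verts[1:])):
            raise ValueError("surface vertex positions must be strictly increasing")

    @property
    def media_indices(self) -> tuple[float, ...]:
        """Refractive indices of cornea, aqueous, lens, vitreous."""
        return tuple(s.index_after for s in self.surfaces)


@dataclass
class FieldAnalysis:
    """Wavefront / PSF / Strehl / RMS summary for one configuration."""

    field: FieldPoint
    pupil_diameter_mm: float
    perturbation: Perturbation
    wavefront_um: np.ndarray          # (n, n), NaN outside the valid pupil
    pupil_mask: np.ndarray            # (n, n) bool
    pupil_coords_mm: np.ndarray       # 1-D pixel-center stop coordinates
    psf: np.ndarray                   # unit-sum intensity
    psf_scale_arcmin: float
    strehl: float
    rms_wavefront_um: float
    spot_mm: np.ndarray               # (k, 2) retinal intersections re chief
    chief_retina_mm: np.ndarray       # (2,) chief-ray retinal point (eye frame)
    vignetted_fraction: float


@dataclass
class SpotDiagram:
    field: FieldPoint
    pupil_diameter_mm: float
    perturbation: Perturbation
    spot_mm: np.ndarray               # (k, 2) relative to the chief ray
    rms_radius_um: float
    airy_radius_um: float
    chief_retina_mm: np.ndarray


# ---------------------------------------------------------------------------
# model construction


def _load_constants() -> dict:
    with resources.files("blurfield.data").joinpath("navarro_eye.json").open() as fh:
        return json.load(fh)


def _index_at(table: dict, medium: str, wavelength_nm: float) -> float:
    wl = np.asarray(table["wavelengths_nm"], dtype=float)
    nn = np.asarray(table[medium], dtype=float)
    return float(np.interp(wavelength_nm, wl, nn))


def build_eye(wavelength_nm: float = 550.0, *, stop_diameter_mm: float = 1.35,
              correct_on_axis_defocus: bool = True) -> EyeModel:
    """Build the wide-angle schematic eye at the given wavelength.

    Media indices are linearly interpolated from the published dispersion
    table.  The aperture stop sits in the iris plane (anterior lens vertex).
    When ``correct_on_axis_defocus`` is set (default), the residual on-axis
    defocus of the model is nulled by an ideal Badal term stored on the
    model, emulating the subjective on-axis focus adjustment of the
    simulator.
    """
    if not (400.0 <= wavelength_nm <= 900.0):
        raise ValueError(f"wavelength {wavelength_nm} nm outside supported 400-900 nm")
    cst = _load_constants()
    disp = cst["dispersion"]
    surfaces = []
    z = 0.0
    n_before = 1.0
    for spec in cst["surfaces"]:
        n_after = _index_at(disp, spec["medium"], wavelength_nm)
        surfaces.append(ConicSurface(
            vertex_mm=z, radius_mm=spec["radius_mm"], conic=spec["conic"],
            index_before=n_before, index_after=n_after,
            semi_aperture_mm=spec["semi_aperture_mm"], name=spec["name"]))
        z += spec["thickness_mm"]
        n_before = n_after
    ret = cst["retina"]
    retina = ConicSurface(vertex_mm=z, radius_mm=ret["radius_mm"], conic=ret["conic"],
                          index_before=n_before, index_after=n_before,
                          semi_aperture_mm=ret["semi_aperture_mm"], name="retina")
    stop_z = surfaces[2].vertex_mm          # iris plane: anterior lens vertex
    eye = EyeModel(surfaces=tuple(surfaces), retina=retina,
                   wavelength_nm=wavelength_nm, stop_z_mm=stop_z,
                   stop_diameter_mm=stop_diameter_mm, name=cst["name"])
    if correct_on_axis_defocus:
        eye.badal_diopters = _solve_badal(eye)
    return eye


def _solve_badal(eye: EyeModel, pupil_mm: float = 1.0, n_iter: int = 3) -> float:
    """Null the aligned on-axis Zernike defocus with a quadratic input-plane
    optical-path term; returns the Badal power in diopters."""
    badal = 0.0
    for _ in range(n_iter):
        trial = replace(eye) if False else EyeModel(
            surfaces=eye.surfaces, retina=eye.retina,
            wavelength_nm=eye.wavelength_nm, stop_z_mm=eye.stop_z_mm,
            stop_diameter_mm=eye.stop_diameter_mm, badal_diopters=badal,
            name=eye.name)
        fa = field_analysis(trial, FieldPoint(0.0), pupil_mm, pupil_samples=33)
        x = (fa.pupil_coords_mm[None, :] ** 2
             + fa.pupil_coords_mm[:, None] ** 2)[fa.pupil_mask]
        w = fa.wavefront_um[fa.pupil_mask]
        # fit W = a h^2 + c ; residual defocus in diopters is 2 a
        A = np.stack([x, np.ones_like(x)], axis=1)
        coef, *_ = np.linalg.lstsq(A, w, rcond=None)
        badal += 2.0 * coef[0]
        if abs(coef[0]) < 1e-10:
            break
    return badal


# ---------------------------------------------------------------------------
# exact tracing core


def _rotation_matrices(tip_deg, tilt_deg):
    """R = Rx(tip) @ Ry(tilt); accepts scalars or (P,) arrays -> (P, 3, 3)."""
    tip = np.deg2rad(np.atleast_1d(np.asarray(tip_deg, dtype=float)))
    tilt = np.deg2rad(np.atleast_1d(np.asarray(tilt_deg, dtype=float)))
    ct, st = np.cos(tip), np.sin(tip)
    cl, sl = np.cos(tilt), np.sin(tilt)
    R = np.empty(np.broadcast(ct, cl).shape + (3, 3))
    R[..., 0, 0] = cl
    R[..., 0, 1] = 0.0
    R[..., 0, 2] = sl
    R[..., 1, 0] = st * sl
    R[..., 1, 1] = ct
    R[..., 1, 2] = -st * cl
    R[..., 2, 0] = -ct * sl
    R[..., 2, 1] = st
    R[..., 2, 2] = ct * cl
    return R


def _intersect_conic(p, u, surf: ConicSurface):
    """Closed-form ray/quadric intersection on the principal conic branch.

    Returns (t, ok): the ray parameter of the intersection and a validity
    mask (real intersection, forward propagation, inside the clear aperture,
    on the principal branch).
    """
    px, py, pz = p[..., 0], p[..., 1], p[..., 2]
    ux, uy, uz = u[..., 0], u[..., 1], u[..., 2]
    if np.isinf(surf.radius_mm):
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (surf.vertex_mm - pz) / uz
        ok = np.isfinite(t) & (t > -_BRANCH_TOL_MM)
        h2 = (px + t * ux) ** 2 + (py + t * uy) ** 2
        ok &= h2 <= surf.semi_aperture_mm ** 2
        return np.where(ok, t, np.nan), ok

    R, Q = surf.radius_mm, surf.conic
    wz = pz - surf.vertex_mm
    A = ux ** 2 + uy ** 2 + (1.0 + Q) * uz ** 2
    B = 2.0 * (px * ux + py * uy + (1.0 + Q) * wz * uz - R * uz)
    C = px ** 2 + py ** 2 + (1.0 + Q) * wz ** 2 - 2.0 * R * wz
    disc = B ** 2 - 4.0 * A * C
    ok = disc >= 0.0
    sq = np.sqrt(np.maximum(disc, 0.0))
    # numerically stable roots (A -> 0 when 1+Q = 0 and the ray is paraxial)
    q = -0.5 * (B + np.where(B >= 0, 1.0, -1.0) * sq)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(A != 0, q / np.where(A != 0, A, 1.0), np.inf)
        t2 = np.where(q != 0, C / np.where(q != 0, q, 1.0), 0.0)

    def branch_error(t):
        with np.errstate(invalid="ignore"):
            x = px + t * ux
            y = py + t * uy
            z = pz + t * uz
            h2 = x * x + y * y
            inside = h2 <= surf.semi_aperture_mm ** 2
            sag = surf.sag(np.sqrt(h2))
            err = np.abs(z - surf.vertex_mm - sag)
        return np.where(np.isfinite(err), err, np.inf), inside

    e1, in1 = branch_error(t1)
    e2, in2 = branch_error(t2)
    ok1 = ok & (t1 > -_BRANCH_TOL_MM) & (e1 < _BRANCH_TOL_MM) & in1
    ok2 = ok & (t2 > -_BRANCH_TOL_MM) & (e2 < _BRANCH_TOL_MM) & in2
    t = np.where(ok1, t1, np.where(ok2, t2, np.nan))
    return t, ok1 | ok2


def _refract(u, normal, n1, n2):
    """Vector Snell refraction; returns (u_refracted, ok) with TIR flagged."""
    cos_i = -np.sum(u * normal, axis=-1)
    normal = np.where(cos_i[..., None] < 0, -normal, normal)
    cos_i = np.abs(cos_i)
    mu = n1 / n2
    k = 1.0 - mu ** 2 * (1.0 - cos_i ** 2)
    ok = k >= 0.0
    u2 = mu * u + (mu * cos_i - np.sqrt(np.maximum(k, 0.0)))[..., None] * normal
    norm = np.linalg.norm(u2, axis=-1, keepdims=True)
    return u2 / np.where(norm > 0, norm, 1.0), ok


def _surface_normal(p, surf: ConicSurface):
    if np.isinf(surf.radius_mm):
        n = np.zeros_like(p)
        n[..., 2] = -1.0
        return n
    grad = np.empty_like(p)
    grad[..., 0] = 2.0 * p[..., 0]
    grad[..., 1] = 2.0 * p[..., 1]
    grad[..., 2] = (-2.0 * surf.radius_mm
                    + 2.0 * (1.0 + surf.conic) * (p[..., 2] - surf.vertex_mm))
    return grad / np.linalg.norm(grad, axis=-1, keepdims=True)


def _to_eye_frame(origins, d, tip, tilt, dx, dy):
    """World rays -> eye frame for a batch of perturbations.

    Returns (p, u, Rm, tvec) with p, u of shape (P, n, 3).
    """
    origins = np.atleast_2d(np.asarray(origins, dtype=float))
    Rm = _rotation_matrices(tip, tilt)                                  # (P,3,3)
    dxa = np.atleast_1d(np.asarray(dx, dtype=float))
    dya = np.atleast_1d(np.asarray(dy, dtype=float))
    tvec = np.stack([dxa, dya, np.zeros_like(dxa)], axis=-1)            # (P,3)
    if origins.ndim == 2:                                               # (n,3)
        p = np.einsum("pji,nj->pni", Rm, origins)
    else:                                                               # (P,n,3)
        p = np.einsum("pji,pnj->pni", Rm, origins)
    p = p - np.einsum("pji,pj->pi", Rm, tvec)[:, None, :]
    d = np.asarray(d, dtype=float)
    u = np.einsum("pji,j->pi", Rm, d)[:, None, :]
    u = np.broadcast_to(u, p.shape).copy()
    return p, u, Rm, tvec


def _trace_core(eye: EyeModel, p, u, opl, stop_only: bool = False,
                Rm=None, tvec=None):
    """Sequential trace in the eye frame, through the refracting surfaces.

    With ``stop_only`` the trace runs through the cornea only and returns
    the world-frame (x, y) where each ray crosses the fixed stop plane.
    Otherwise traces through all four refracting surfaces and returns
    (p, u, opl, valid) in the vitreous (the retina is intersected
    separately).
    """
    valid = np.ones(p.shape[:-1], dtype=bool)
    n_surf = 2 if stop_only else len(eye.surfaces)
    for surf in eye.surfaces[:n_surf]:
        t, ok = _intersect_conic(p, u, surf)
        valid &= ok
        t = np.where(valid, t, 0.0)
        p = p + t[..., None] * u
        opl = opl + surf.index_before * t
        normal = _surface_normal(p, surf)
        u, ok_r = _refract(u, normal, surf.index_before, surf.index_after)
        valid &= ok_r
    if stop_only:
        # back to world frame, then cross the fixed stop plane z = stop_z
        pw = np.einsum("pij,pnj->pni", Rm, p) + tvec[:, None, :]
        uw = np.einsum("pij,pnj->pni", Rm, u)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (eye.stop_z_mm - pw[..., 2]) / uw[..., 2]
        xy = pw[..., :2] + t[..., None] * uw[..., :2]
        return xy, valid
    return p, u, opl, valid


def _intersect_retina(eye: EyeModel, p, u, opl, valid):
    """Propagate vitreous rays onto the retina; returns (p3, opl, valid)."""
    t, ok = _intersect_conic(p, u, eye.retina)
    valid = valid & ok
    t = np.where(valid, t, 0.0)
    p = p + t[..., None] * u
    opl = opl + eye.retina.index_before * t
    return p, opl, valid


_LAUNCH_BACK_MM = 5.0   # rays start this far upstream so no origin can sit
                        # inside a perturbed cornea


def _input_opl(eye: EyeModel, origins, d):
    """Plane-wave phase at the input plane plus the Badal quadratic (mm).

    ``origins`` are parametrized on the z = 0 plane; the Badal quadratic is
    evaluated there.
    """
    origins = np.asarray(origins, dtype=float)
    opl0 = np.sum(origins * np.asarray(d, dtype=float), axis=-1)
    h2 = origins[..., 0] ** 2 + origins[..., 1] ** 2
    return opl0 - eye.badal_diopters * h2 / 2.0 * 1e-3


def _launch(origins, d):
    """Back the z = 0 parametrized origins upstream along the beam."""
    return np.asarray(origins, dtype=float) - _LAUNCH_BACK_MM * np.asarray(d, dtype=float)


def trace_rays(eye: EyeModel, origins_mm, direction, perturbation=ZERO_PERTURBATION):
    """Trace collimated rays (given input-plane origins) through the eye.

    ``origins_mm``: (n, 3) ray origins on the z = 0 input plane, world frame.
    ``direction``: common unit propagation vector (3,).
    ``perturbation``: a :class:`Perturbation` or arrays (tip, tilt, dx, dy)
    of shape (P,); with arrays, outputs gain a leading P axis.

    Returns a dict with ``opl_mm`` (optical path from the plane wavefront to
    the retina, including the Badal term), ``retina_xy_mm`` (eye frame) and
    ``valid`` (False where a ray was vignetted, missed a surface or suffered
    total internal reflection).  No stop clipping is applied here; callers
    that need a stop-filling bundle should use :func:`aim_pupil`.
    """
    if isinstance(perturbation, Perturbation):
        tip, tilt, dx, dy = perturbation.as_arrays()
        squeeze = True
    else:
        tip, tilt, dx, dy = perturbation
        squeeze = False
    origins = np.atleast_2d(np.asarray(origins_mm, dtype=float))
    opl0 = _input_opl(eye, origins, direction) - _LAUNCH_BACK_MM
    p, u, Rm, tvec = _to_eye_frame(_launch(origins, direction), direction,
                                   tip, tilt, dx, dy)
    opl = np.broadcast_to(opl0, p.shape[:-1]).astype(float).copy()
    p, u, opl, valid = _trace_core(eye, p, u, opl)
    p, opl, valid = _intersect_retina(eye, p, u, opl, valid)
    out = {"opl_mm": np.where(valid, opl, np.nan),
           "retina_xy_mm": np.where(valid[..., None], p[..., :2], np.nan),
           "valid": valid}
    if squeeze:
        out = {k: v[0] for k, v in out.items()}
    return out


def aim_pupil(eye: EyeModel, direction, stop_xy_mm, tip, tilt, dx, dy,
              n_newton: int = 3):
    """Find input-plane ray origins that hit the given stop-plane targets.

    The map from input-plane position to stop-plane crossing (through the
    possibly misaligned cornea) is nearly affine over a few millimeters, so
    a shared-Jacobian Newton iteration converges in 2-3 steps.

    Returns (origins (P, n, 3), jac (P, 2, 2), ok (P, n)); ``jac`` is the
    d(stop)/d(input) map used for entrance-pupil scaling.
    """
    d = np.asarray(direction, dtype=float)
    targets = np.atleast_2d(np.asarray(stop_xy_mm, dtype=float))        # (n,2)
    tip = np.atleast_1d(np.asarray(tip, dtype=float))
    P, n = tip.size, targets.shape[0]

    def stop_xy(origins):
        p, u, Rm, tvec = _to_eye_frame(_launch(origins, d), d, tip, tilt, dx, dy)
        opl = np.zeros(p.shape[:-1])
        return _trace_core(eye, p, u, opl, stop_only=True, Rm=Rm, tvec=tvec)

    # initial guess: launch from the transverse target position at z = 0
    origins = np.broadcast_to(
        np.concatenate([targets, np.zeros((n, 1))], axis=1), (P, n, 3)).copy()
    eps = 1e-3
    probe = np.stack([np.array([0.0, 0.0, 0.0]),
                      np.array([eps, 0.0, 0.0]),
                      np.array([0.0, eps, 0.0])])
    pxy, _ = stop_xy(probe)                                             # (P,3,2)
    jac = np.stack([(pxy[:, 1] - pxy[:, 0]) / eps,
                    (pxy[:, 2] - pxy[:, 0]) / eps], axis=-1)            # (P,2,2)
    jinv = np.linalg.inv(jac)
    ok = np.ones((P, n), dtype=bool)
    for _ in range(n_newton):
        xy, ok_i = stop_xy(origins)
        ok &= ok_i
        err = targets[None, :, :] - xy
        step = np.einsum("pij,pnj->pni", jinv, np.where(ok[..., None], err, 0.0))
        origins[..., :2] += step
    return origins, jac, ok


# ---------------------------------------------------------------------------
# pupil sampling / wavefront assembly


def _pupil_grid(pupil_diameter_mm: float, pupil_samples: int):
    """Square grid of pixel centers (half-integer convention) over the stop."""
    du = pupil_diameter_mm / pupil_samples
    c = (np.arange(pupil_samples) + 0.5 - pupil_samples / 2.0) * du
    X, Y = np.meshgrid(c, c, indexing="xy")
    mask = X ** 2 + Y ** 2 <= (pupil_diameter_mm / 2.0) ** 2
    return c, X, Y, mask, du


def _remove_piston_tilt(w, x, y):
    A = np.stack([np.ones_like(x), x, y], axis=1)
    coef, *_ = np.linalg.lstsq(A, w, rcond=None)
    return w - A @ coef


def strehl_from_wavefront(wavefront_um, mask, wavelength_nm, pad_factor: int = 4):
    """Strehl ratio of an arbitrary pupil-grid wavefront map.

    Peak of |FFT(pupil function)|^2 over the peak of the aberration-free
    pattern on the identical grid.
    """
    n = mask.shape[0]
    w = np.where(mask, wavefront_um, 0.0)
    g = np.where(mask, np.exp(2j * np.pi * w / (wavelength_nm * 1e-3)), 0.0)
    N = pad_factor * n
    amp = np.abs(np.fft.fft2(g, s=(N, N))) ** 2
    return float(amp.max() / mask.sum() ** 2)


def _traced_bundle(eye, field, pupil_diameter_mm, tip, tilt, dx, dy,
                   pupil_samples):
    """Aim and trace a stop-filling bundle plus its chief ray for a batch of
    perturbations; returns everything the analysis layers need."""
    d = field.direction()
    c, X, Y, mask, du = _pupil_grid(pupil_diameter_mm, pupil_samples)
    targets = np.stack([X[mask], Y[mask]], axis=1)
    targets = np.concatenate([np.zeros((1, 2)), targets])   # row 0: chief
    origins, jac, aim_ok = aim_pupil(eye, d, targets, tip, tilt, dx, dy)
    opl0 = _input_opl(eye, origins, d) - _LAUNCH_BACK_MM
    p, u, Rm, tvec = _to_eye_frame(_launch(origins, d), d, tip, tilt, dx, dy)
    opl = opl0.copy()
    p, u, opl, valid = _trace_core(eye, p, u, opl)
    pr, opl_ret, valid = _intersect_retina(eye, p, u, opl, valid & aim_ok)
    chief_ok = valid[:, 0]
    # wavefront: optical path to the image plane through the chief ray's
    # retinal point, perpendicular to the chief ray (avoids the spurious
    # linear term an obliquely tilted image *surface* would inject)
    n_vit = eye.retina.index_before
    u0 = u[:, :1, :]                                  # chief direction
    P3 = pr[:, :1, :]                                 # chief retinal point
    denom = np.sum(u * u0, axis=-1)
    t_pl = np.sum((P3 - p) * u0, axis=-1) / np.where(denom != 0, denom, 1.0)
    opl_pl = opl + n_vit * t_pl
    w_um = (opl_pl[:, 1:] - opl_pl[:, :1]) * 1e3
    xy = pr[..., :2]
    spot = xy[:, 1:, :] - xy[:, :1, :]
    # entrance-pupil spacing: stop spacing mapped back through the cornea
    sv = np.linalg.svd(jac, compute_uv=False)
    du_entrance = du / float(np.mean(np.sqrt(sv[:, 0] * sv[:, 1])))
    return {"c": c, "mask": mask, "du": du, "du_entrance": du_entrance,
            "x": X[mask], "y": Y[mask], "w_um": w_um, "ok": valid[:, 1:],
            "chief_ok": chief_ok, "spot_mm": spot, "chief_xy": xy[:, 0, :]}


def field_analysis(eye: EyeModel, field: FieldPoint, pupil_diameter_mm: float,
                   perturbation: Perturbation = ZERO_PERTURBATION,
                   pupil_samples: int = 64, pad_factor: int = 4,
                   max_vignetted: float = 0.10) -> FieldAnalysis:
    """Full wavefront/PSF/Strehl/RMS analysis of one field configuration.

    A ray-aimed bundle fills the iris stop for the oblique field angle; the
    wavefront is the chief-ray-referenced OPD with piston and tilt removed;
    the PSF is the squared Fourier transform of the pupil function on a
    zero-padded grid; the Strehl ratio is the discrete peak ratio against
    the aberration-free pattern on the identical grid.
    """
    if not (0.5 <= pupil_diameter_mm <= 8.0):
        raise ValueError("pupil diameter must be within [0.5, 8] mm")
    if pupil_samples < 32:
        raise ValueError("need at least 32 samples across the pupil diameter")
    tb = _traced_bundle(eye, field, pupil_diameter_mm,
                        *perturbation.as_arrays(), pupil_samples)
    if not tb["chief_ok"][0]:
        raise VignettingError("chief ray lost: pupil/perturbation outside the model")
    ok = tb["ok"][0]
    vfrac = 1.0 - ok.mean()
    if vfrac > max_vignetted:
        raise VignettingError(
            f"{vfrac:.0%} of pupil rays vignetted (> {max_vignetted:.0%})")

    w_fit = _remove_piston_tilt(tb["w_um"][0][ok], tb["x"][ok], tb["y"][ok])
    mask = tb["mask"]
    wavefront = np.full(mask.shape, np.nan)
    valid_mask = mask.copy()
    valid_mask[mask] = ok
    wavefront[valid_mask] = w_fit

    strehl = strehl_from_wavefront(np.nan_to_num(wavefront), valid_mask,
                                   eye.wavelength_nm, pad_factor)
    rms = float(np.sqrt(np.mean(w_fit ** 2)))

    g = np.where(valid_mask, np.exp(2j * np.pi * np.nan_to_num(wavefront)
                                    / (eye.wavelength_nm * 1e-3)), 0.0)
    N = pad_factor * pupil_samples
    psf = np.abs(np.fft.fftshift(np.fft.fft2(g, s=(N, N)))) ** 2
    psf /= psf.sum()
    dtheta_rad = eye.wavelength_nm * 1e-6 / (N * tb["du_entrance"])

    return FieldAnalysis(
        field=field, pupil_diameter_mm=pupil_diameter_mm, perturbation=perturbation,
        wavefront_um=wavefront, pupil_mask=valid_mask, pupil_coords_mm=tb["c"],
        psf=psf, psf_scale_arcmin=dtheta_rad * ARCMIN_PER_RAD,
        strehl=strehl, rms_wavefront_um=rms, spot_mm=tb["spot_mm"][0][ok],
        chief_retina_mm=tb["chief_xy"][0], vignetted_fraction=float(vfrac))


def strehl_batch(eye: EyeModel, field: FieldPoint, pupil_diameter_mm: float,
                 tips, tilts, dxs, dys, pupil_samples: int = 32,
                 pad_factor: int = 4, chunk: int = 64, compute_rms: bool = True):
    """Vectorized Strehl (and RMS) over a batch of perturbations.

    Returns ``(strehl, rms_um, vignetted_fraction)`` arrays of shape (P,).
    Combinations losing more than 10 % of rays (or the chief ray) score
    Strehl 0 / RMS NaN with a warning, mirroring the per-field contract.
    """
    tips = np.atleast_1d(np.asarray(tips, dtype=float))
    tilts = np.atleast_1d(np.asarray(tilts, dtype=float))
    dxs = np.atleast_1d(np.asarray(dxs, dtype=float))
    dys = np.atleast_1d(np.asarray(dys, dtype=float))
    P = tips.size
    N = pad_factor * pupil_samples
    wl_um = eye.wavelength_nm * 1e-3

    strehls = np.zeros(P)
    rmss = np.full(P, np.nan)
    vfracs = np.ones(P)

    for lo in range(0, P, chunk):
        sl = slice(lo, min(lo + chunk, P))
        tb = _traced_bundle(eye, field, pupil_diameter_mm,
                            tips[sl], tilts[sl], dxs[sl], dys[sl], pupil_samples)
        ok = tb["ok"] & tb["chief_ok"][:, None]
        w = np.where(ok, tb["w_um"], 0.0)
        vf = 1.0 - ok.mean(axis=1)
        vfracs[sl] = vf
        mask = tb["mask"]
        nv = ok.sum(axis=1).astype(float)

        # per-perturbation piston/tilt removal (3x3 weighted normal equations)
        At = np.stack([np.ones_like(tb["x"]), tb["x"], tb["y"]], axis=0)
        wgt = ok.astype(float)
        M = np.einsum("in,jn,pn->pij", At, At, wgt)
        M += 1e-12 * np.eye(3)
        b = np.einsum("in,pn->pi", At, w * wgt)
        coef = np.linalg.solve(M, b[..., None])[..., 0]
        resid = (w - np.einsum("pi,in->pn", coef, At)) * wgt

        g = np.zeros((ok.shape[0],) + mask.shape, dtype=complex)
        g[:, mask] = np.where(ok, np.exp(2j * np.pi * resid / wl_um), 0.0)
        amp = np.abs(np.fft.fft2(g, s=(N, N))) ** 2
        s = amp.reshape(amp.shape[0], -1).max(axis=1) / np.maximum(nv, 1.0) ** 2
        strehls[sl] = np.where(vf <= 0.10, s, 0.0)

        if compute_rms:
            rmss[sl] = np.where(vf <= 0.10,
                                np.sqrt(np.einsum("pn,pn->p", resid, resid)
                                        / np.maximum(nv, 1.0)), np.nan)
    if np.any(vfracs > 0.10):
        warnings.warn("some perturbations vignetted >10% of rays; scored Strehl 0")
    return strehls, rmss, vfracs


# ---------------------------------------------------------------------------
# spot diagrams and paraxial oracle helpers


def retinal_mm_per_deg(eye: EyeModel, eccentricity_deg: float = 0.0) -> float:
    """Local retinal image scale (mm per degree of visual angle) from chief
    rays at neighbouring field angles."""
    e_lo = max(eccentricity_deg - 0.05, 0.0)
    e_hi = eccentricity_deg + 0.05
    xs = []
    for e in (e_lo, e_hi):
        fp = FieldPoint(e)
        org, _, _ = aim_pupil(eye, fp.direction(), np.zeros((1, 2)),
                              *(np.zeros(1),) * 4)
        r = trace_rays(eye, org[0], fp.direction())
        xs.append(r["retina_xy_mm"][0])
    return float(np.linalg.norm(xs[1] - xs[0]) / (e_hi - e_lo))


def airy_radius_um(eye: EyeModel, pupil_diameter_mm: float) -> float:
    """First-minimum Airy radius on the retina for the configured pupil,
    computed from the model's own angular-to-retinal scale.

    The effective aperture is the entrance pupil that corresponds to the
    physical stop diameter.
    """
    # entrance magnification from the aiming Jacobian at the axis
    _, jac, _ = aim_pupil(eye, np.array([0.0, 0.0, 1.0]), np.zeros((1, 2)),
                          *(np.zeros(1),) * 4)
    sv = np.linalg.svd(jac[0], compute_uv=False)
    d_entrance = pupil_diameter_mm / float(np.sqrt(sv[0] * sv[1]))
    scale_mm_per_rad = retinal_mm_per_deg(eye) * 180.0 / np.pi
    theta = 1.22 * eye.wavelength_nm * 1e-6 / d_entrance   # rad
    return theta * scale_mm_per_rad * 1e3


def spot_diagram(eye: EyeModel, field: FieldPoint, pupil_diameter_mm: float,
                 perturbation: Perturbation = ZERO_PERTURBATION,
                 n_rays: int = 500) -> SpotDiagram:
    """Retinal intersection scatter relative to the chief ray."""
    if n_rays < 100:
        raise ValueError("need at least 100 rays for a spot diagram")
    ns = max(32, int(np.ceil(np.sqrt(4.0 * n_rays / np.pi))))
    fa = field_analysis(eye, field, pupil_diameter_mm, perturbation,
                        pupil_samples=ns)
    spot = fa.spot_mm
    rms_radius = float(np.sqrt(np.mean(np.sum(spot ** 2, axis=1)))) * 1e3
    return SpotDiagram(field=field, pupil_diameter_mm=pupil_diameter_mm,
                       perturbation=perturbation, spot_mm=spot,
                       rms_radius_um=rms_radius,
                       airy_radius_um=airy_radius_um(eye, pupil_diameter_mm),
                       chief_retina_mm=fa.chief_retina_mm)


def paraxial_back_focal_distance_mm(eye: EyeModel) -> float:
    """Back focal distance (last refracting vertex to paraxial focus) from
    the ABCD matrix of the surface list; serves as the independent paraxial
    oracle for the exact tracer."""
    M = np.eye(2)
    surfs = eye.surfaces
    for i, s in enumerate(surfs):
        power = (s.index_after - s.index_before) / (s.radius_mm * 1e-3)  # D
        M = np.array([[1.0, 0.0], [-power, 1.0]]) @ M
        if i < len(surfs) - 1:
            t_m = (surfs[i + 1].vertex_mm - s.vertex_mm) * 1e-3
            M = np.array([[1.0, t_m / s.index_after], [0.0, 1.0]]) @ M
    A, C = M[0, 0], M[1, 0]
    n_img = surfs[-1].index_after
    return float(-A * n_img / C * 1e3)
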