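"""Monte-Carlo fixational-misalignment study of wide-field isoplanatism.

Fixational eye movements (drift, microsaccades, tremor) are modelled by
their static displacement envelope: tip/tilt of the eye uniform within
+/-0.35 deg and radial decentration uniform on a disk of 0.75 mm radius.
For every sampled misalignment and every field point of a retinal extent,
the Strehl ratio is evaluated and the worst case extracted; the largest
artificial-pupil diameter that keeps the worst case diffraction-limited
(Strehl >= 0.8) bounds the isoplanatic operating range of the simulator.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .eye import EyeModel, FieldPoint, Perturbation, strehl_batch

__all__ = [
    "PerturbationEnsemble", "WorstCase", "IsoplanatismReport",
    "sample_perturbations", "corner_perturbations", "field_grid",
    "worst_case_quality", "isoplanatic_pupil",
]

#: displacement envelope of fixational eye movements (paper defaults)
TIP_TILT_BOUND_DEG = 0.35
DECENTER_BOUND_MM = 0.75
STREHL_CRITERION = 0.8

#: printed eccentricity grid (deg) and the named retinal extents
ECCENTRICITIES_DEG = (2.5, 4.25, 9.25)
MERIDIANS_DEG = tuple(range(0, 360, 45))
EXTENTS_DEG = {"fovea": 2.5, "parafovea": 4.25, "perifovea": 9.25}


@dataclass
class PerturbationEnsemble:
    """A seeded draw of rigid-body misalignments (zero always appended)."""

    tips: np.ndarray
    tilts: np.ndarray
    dxs: np.ndarray
    dys: np.ndarray
    seed: int | None
    tip_tilt_bound_deg: float
    decenter_bound_mm: float

    @property
    def n(self) -> int:
        return self.tips.size

    def draws(self) -> list[Perturbation]:
        return [Perturbation(t, l, x, y)
                for t, l, x, y in zip(self.tips, self.tilts, self.dxs, self.dys)]

    def extended(self, other: "PerturbationEnsemble") -> "PerturbationEnsemble":
        """Concatenate two ensembles (bounds are the elementwise maxima)."""
        return PerturbationEnsemble(
            np.concatenate([self.tips, other.tips]),
            np.concatenate([self.tilts, other.tilts]),
            np.concatenate([self.dxs, other.dxs]),
            np.concatenate([self.dys, other.dys]),
            self.seed,
            max(self.tip_tilt_bound_deg, other.tip_tilt_bound_deg),
            max(self.decenter_bound_mm, other.decenter_bound_mm))


def sample_perturbations(n: int, tip_tilt_bound_deg: float = TIP_TILT_BOUND_DEG,
                         decenter_bound_mm: float = DECENTER_BOUND_MM,
                         seed: int = 0) -> PerturbationEnsemble:
    """Sample ``n`` misalignments uniformly within the fixational envelope.

    Tip and tilt are i.i.d. uniform on +/-bound; the decentration vector is
    uniform on the disk of the given radius (honouring "radial"
    decentering).  The zero perturbation is always appended so the aligned
    eye is a member of every ensemble.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if tip_tilt_bound_deg < 0 or decenter_bound_mm < 0:
        raise ValueError("bounds must be >= 0")
    rng = np.random.default_rng(seed)
    tips = rng.uniform(-tip_tilt_bound_deg, tip_tilt_bound_deg, n)
    tilts = rng.uniform(-tip_tilt_bound_deg, tip_tilt_bound_deg, n)
    r = decenter_bound_mm * np.sqrt(rng.uniform(0.0, 1.0, n))
    th = rng.uniform(0.0, 2.0 * np.pi, n)
    tips = np.append(tips, 0.0)
    tilts = np.append(tilts, 0.0)
    dxs = np.append(r * np.cos(th), 0.0)
    dys = np.append(r * np.sin(th), 0.0)
    return PerturbationEnsemble(tips, tilts, dxs, dys, seed,
                                tip_tilt_bound_deg, decenter_bound_mm)


def corner_perturbations(tip_tilt_bound_deg: float = TIP_TILT_BOUND_DEG,
                         decenter_bound_mm: float = DECENTER_BOUND_MM
                         ) -> PerturbationEnsemble:
    """The 16 bound-corner probes: tip/tilt at their four sign corners
    crossed with decentration at the four compass points of the disk edge.

    Under box/disk-bounded uniform perturbations the worst case is
    approached at the bounds, so these probes are a cheap sanity oracle for
    the Monte-Carlo minimum.
    """
    tips, tilts, dxs, dys = [], [], [], []
    for tip in (-tip_tilt_bound_deg, tip_tilt_bound_deg):
        for tilt in (-tip_tilt_bound_deg, tip_tilt_bound_deg):
            for dx, dy in ((decenter_bound_mm, 0.0), (-decenter_bound_mm, 0.0),
                           (0.0, decenter_bound_mm), (0.0, -decenter_bound_mm)):
                tips.append(tip)
                tilts.append(tilt)
                dxs.append(dx)
                dys.append(dy)
    return PerturbationEnsemble(np.array(tips), np.array(tilts),
                                np.array(dxs), np.array(dys), None,
                                tip_tilt_bound_deg, decenter_bound_mm)


def field_grid(extent_deg: float,
               eccentricities_deg=ECCENTRICITIES_DEG,
               meridians_deg=MERIDIANS_DEG) -> list[FieldPoint]:
    """On-axis point plus 8 meridians at every printed eccentricity within
    the extent (on-axis counted once)."""
    fields = [FieldPoint(0.0, 0.0)]
    for e in eccentricities_deg:
        if e <= extent_deg + 1e-9:
            fields.extend(FieldPoint(e, m) for m in meridians_deg)
    return fields


@dataclass
class WorstCase:
    strehl: float
    rms_um: float
    argmin_field: FieldPoint
    argmin_perturbation: Perturbation
    argmax_rms_field: FieldPoint
    argmax_rms_perturbation: Perturbation
    records: pd.DataFrame | None = None
    exhaustive: bool = True


@dataclass
class IsoplanatismReport:
    """Per-pupil worst-case image quality over a retinal extent."""

    field_extent_deg: float
    criterion: float
    per_pupil: dict = dc_field(default_factory=dict)   # pupil_mm -> WorstCase
    isoplanatic_pupil_mm: float | None = None
    n_perturbations: int = 0
    seed: int | None = None

    def to_json_dict(self) -> dict:
        return {
            "field_extent_deg": self.field_extent_deg,
            "criterion": self.criterion,
            "isoplanatic_pupil_mm": self.isoplanatic_pupil_mm,
            "n_perturbations": self.n_perturbations,
            "seed": self.seed,
            "per_pupil": {
                str(p): {
                    "worst_strehl": wc.strehl,
                    "worst_rms_um": wc.rms_um,
                    "argmin_field": [wc.argmin_field.eccentricity_deg,
                                     wc.argmin_field.meridian_deg],
                    "argmin_perturbation": [
                        wc.argmin_perturbation.tip_deg,
                        wc.argmin_perturbation.tilt_deg,
                        wc.argmin_perturbation.decenter_x_mm,
                        wc.argmin_perturbation.decenter_y_mm],
                    "exhaustive": wc.exhaustive,
                } for p, wc in self.per_pupil.items()},
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)


def worst_case_quality(eye: EyeModel, fields, pupil_mm: float,
                       ensemble: PerturbationEnsemble,
                       pupil_samples: int = 32, early_stop: float | None = None,
                       keep_records: bool = False) -> WorstCase:
    """Minimum Strehl (and maximum RMS) over fields x ensemble.

    ``early_stop``: abandon the scan once the running minimum falls below
    this value (used by the pupil search, where only the pass/fail decision
    matters); the returned object is then flagged non-exhaustive.
    Combinations failing on vignetting score Strehl 0 with a warning.
    """
    fields = list(fields)
    if not fields:
        raise ValueError("fields must be nonempty")
    best = WorstCase(np.inf, -np.inf, fields[0], Perturbation(),
                     fields[0], Perturbation())
    rows = []
    exhaustive = True
    for fp in fields:
        s, r, v = strehl_batch(eye, fp, pupil_mm, ensemble.tips,
                               ensemble.tilts, ensemble.dxs, ensemble.dys,
                               pupil_samples=pupil_samples)
        i_min = int(np.argmin(s))
        if s[i_min] < best.strehl:
            best.strehl = float(s[i_min])
            best.argmin_field = fp
            best.argmin_perturbation = Perturbation(
                ensemble.tips[i_min], ensemble.tilts[i_min],
                ensemble.dxs[i_min], ensemble.dys[i_min])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            i_max = int(np.nanargmax(r)) if np.any(np.isfinite(r)) else 0
        if np.isfinite(r[i_max]) and r[i_max] > best.rms_um:
            best.rms_um = float(r[i_max])
            best.argmax_rms_field = fp
            best.argmax_rms_perturbation = Perturbation(
                ensemble.tips[i_max], ensemble.tilts[i_max],
                ensemble.dxs[i_max], ensemble.dys[i_max])
        if keep_records:
            rows.append(pd.DataFrame({
                "eccentricity_deg": fp.eccentricity_deg,
                "meridian_deg": fp.meridian_deg,
                "pupil_mm": pupil_mm,
                "tip": ensemble.tips, "tilt": ensemble.tilts,
                "dx": ensemble.dxs, "dy": ensemble.dys,
                "strehl": s, "rms_um": r}))
        if early_stop is not None and best.strehl < early_stop:
            exhaustive = False
            break
    best.exhaustive = exhaustive
    if keep_records:
        best.records = pd.concat(rows, ignore_index=True)
    return best


def isoplanatic_pupil(eye: EyeModel, field_extent_deg: float, pupil_grid,
                      ensemble: PerturbationEnsemble,
                      criterion: float = STREHL_CRITERION,
                      pupil_samples: int = 32, exhaustive: bool = False,
                      eccentricities_deg=ECCENTRICITIES_DEG
                      ) -> IsoplanatismReport:
    """Largest tested pupil whose worst-case Strehl stays at or above the
    diffraction-limit criterion over the field extent.

    The answer is given on the supplied pupil grid only (no interpolation
    between grid points).  Returns a report whose ``isoplanatic_pupil_mm``
    is None when no tested pupil passes.
    """
    pupil_grid = sorted(set(float(p) for p in pupil_grid), reverse=True)
    if not pupil_grid:
        raise ValueError("pupil_grid must be nonempty")
    if not (0.0 < criterion < 1.0):
        raise ValueError("criterion must be in (0, 1)")
    fields = field_grid(field_extent_deg, eccentricities_deg)
    report = IsoplanatismReport(field_extent_deg=field_extent_deg,
                                criterion=criterion,
                                n_perturbations=ensemble.n,
                                seed=ensemble.seed)
    for pupil in pupil_grid:
        wc = worst_case_quality(eye, fields, pupil, ensemble,
                                pupil_samples=pupil_samples,
                                early_stop=None if exhaustive else criterion)
        report.per_pupil[pupil] = wc
        if wc.strehl >= criterion and report.isoplanatic_pupil_mm is None:
            report.isoplanatic_pupil_mm = pupil
            if not exhaustive:
                break
    return report
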