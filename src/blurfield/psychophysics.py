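"""Adaptive-staircase blur psychophysics with simulated observers.

A one-down/one-up staircase (fixed 0.15 D step, converging on the 50 %
point of the response function) controls the blur level of each condition;
conditions -- zonal annulus eccentricities or sigmoid-profile K values --
are randomly interleaved within a session.  Per-condition responses are
fitted with a Gumbel (log-Weibull) psychometric function by maximum
likelihood,

    F(x; alpha, beta) = gamma + (1 - gamma - lambda) *
                        (1 - exp(-10 ** (beta * (x - alpha)))),

whose location parameter ``alpha`` sits at the 1 - 1/e (~63 %) point of the
unscaled core: the bothersome-blur threshold.  Standard errors come from a
seeded parametric bootstrap.  Simulated observers respond Bernoulli
according to a configured psychometric function, which makes the whole
pipeline testable without human subjects.

The model/results split follows the statsmodels convention:
:class:`GumbelPsychometric` is built from trial data and ``fit()`` returns
a :class:`PsychometricFitResults` carrying estimates, bootstrap SEs and a
``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .blur import BlurProfile, sigmoid_profile
from .calibration import BLUR_EXTENT_DEG, DEFOCUS_MAX_D, N_RINGS

__all__ = [
    "Staircase", "TrialRecord", "SimulatedObserver", "GumbelPsychometric",
    "PsychometricFitResults", "FitError", "run_session", "fit_gumbel",
    "bootstrap_se", "compare_zonal_global", "ThresholdComparison",
    "gumbel_function",
]

STEP_D = 0.15
LEVEL_MIN_D = 0.0
LEVEL_MAX_D = DEFOCUS_MAX_D
DEFAULT_START_ZONAL_D = 1.0
DEFAULT_START_GLOBAL_D = 2.0
ZONE_OUTER_DEG = (1.5, 3.0, 4.5, 6.0, 7.5)


class FitError(RuntimeError):
    """Psychometric fit cannot be identified from the data."""


def gumbel_function(x, alpha, beta, gamma=0.0, lam=0.0):
    """Gumbel (log-Weibull) psychometric function with base-10 exponent."""
    x = np.asarray(x, dtype=float)
    expo = np.clip(beta * (x - alpha), -30.0, 30.0)
    core = 1.0 - np.exp(-np.power(10.0, expo))
    out = gamma + (1.0 - gamma - lam) * core
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# staircase


@dataclass
class Staircase:
    """One-down/one-up staircase over defocus level (fixed 0.15 D step).

    "Bothersome" responses lower the level, "not bothersome" raise it; the
    rule's fixed point is the 50 % point of the response function.  Levels
    are clamped to the synthesizable 0-5 D range.
    """

    condition_id: str
    level_D: float
    step_D: float = STEP_D
    level_min_D: float = LEVEL_MIN_D
    level_max_D: float = LEVEL_MAX_D
    history: list = dc_field(default_factory=list)

    def update(self, bothersome) -> "Staircase":
        """Record a response and move the level by one step."""
        if isinstance(bothersome, (bool, np.bool_)):
            resp = bool(bothersome)
        elif bothersome in (0, 1):
            resp = bool(bothersome)
        else:
            raise ValueError("response must be binary (bothersome or not)")
        self.history.append((self.level_D, resp))
        delta = -self.step_D if resp else self.step_D
        self.level_D = float(np.clip(self.level_D + delta,
                                     self.level_min_D, self.level_max_D))
        return self

    def reversals(self) -> list[float]:
        levels = [h[0] for h in self.history]
        resps = [h[1] for h in self.history]
        return [levels[i] for i in range(1, len(resps)) if resps[i] != resps[i - 1]]


@dataclass(frozen=True)
class TrialRecord:
    trial_index: int
    condition_id: str
    level_D: float
    bothersome: bool


@dataclass
class SimulatedObserver:
    """Bernoulli observer with a Gumbel response function per condition."""

    true_alpha_D: dict          # condition_id -> alpha (D)
    true_beta: float = 3.0
    guess: float = 0.0
    lapse: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self._rng = np.random.default_rng(self.seed)

    def p_bothersome(self, condition_id: str, level_D: float) -> float:
        return float(gumbel_function(level_D, self.true_alpha_D[condition_id],
                                     self.true_beta, self.guess, self.lapse))

    def respond(self, condition_id: str, level_D: float) -> bool:
        return bool(self._rng.random() < self.p_bothersome(condition_id, level_D))


def run_session(conditions, observer: SimulatedObserver,
                n_trials_per_condition: int, seed: int = 0,
                start_levels=None) -> list[TrialRecord]:
    """Randomly interleaved staircases, one per condition.

    On each trial a condition with remaining trials is drawn uniformly at
    random (seeded); the observer responds Bernoulli at the presented
    level.  Returns the full trial log.
    """
    conditions = [str(c) for c in conditions]
    if not conditions:
        raise ValueError("need at least one condition")
    if n_trials_per_condition < 0:
        raise ValueError("n_trials_per_condition must be >= 0")
    rng = np.random.default_rng(seed)
    if start_levels is None:
        start_levels = {c: DEFAULT_START_ZONAL_D for c in conditions}
    stairs = {c: Staircase(c, float(start_levels[c])) for c in conditions}
    remaining = {c: n_trials_per_condition for c in conditions}
    records: list[TrialRecord] = []
    idx = 0
    while any(v > 0 for v in remaining.values()):
        live = [c for c in conditions if remaining[c] > 0]
        c = live[int(rng.integers(len(live)))]
        st = stairs[c]
        level = st.level_D
        resp = observer.respond(c, level)
        st.update(resp)
        records.append(TrialRecord(idx, c, level, resp))
        remaining[c] -= 1
        idx += 1
    return records


def trials_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([{"trial": r.trial_index, "condition": r.condition_id,
                          "level_D": r.level_D, "bothersome": r.bothersome}
                         for r in records])


# ---------------------------------------------------------------------------
# Gumbel maximum-likelihood fit (model / results objects)


class GumbelPsychometric:
    """Maximum-likelihood Gumbel psychometric model for one condition.

    Parameters
    ----------
    levels, responses : array-like
        Presented blur levels (D) and binary bothersome judgments.
    gamma, lam : float
        Lower asymptote and lapse rate, fixed (default 0 for the yes/no
        bothersome judgment).  ``free_lapse=True`` in :meth:`fit` estimates
        ``lam`` within [0, 0.05] instead.
    """

    def __init__(self, levels, responses, gamma: float = 0.0, lam: float = 0.0):
        self.levels = np.asarray(levels, dtype=float)
        self.responses = np.asarray(responses).astype(float)
        if self.levels.shape != self.responses.shape or self.levels.ndim != 1:
            raise ValueError("levels and responses must be equal-length 1-D")
        if not np.all(np.isin(self.responses, (0.0, 1.0))):
            raise ValueError("responses must be binary")
        self.gamma = float(gamma)
        self.lam = float(lam)
        # aggregate by level for a fast binomial likelihood
        lv, inv = np.unique(self.levels, return_inverse=True)
        k = np.bincount(inv, weights=self.responses)
        n = np.bincount(inv).astype(float)
        self._lv, self._k, self._n = lv, k, n
        self._validate()

    @classmethod
    def from_trials(cls, records, condition_id: str, **kw) -> "GumbelPsychometric":
        sel = [r for r in records if r.condition_id == str(condition_id)]
        return cls([r.level_D for r in sel], [r.bothersome for r in sel], **kw)

    def _validate(self):
        if self._lv.size < 2:
            raise FitError("need responses at >= 2 distinct levels")
        p_yes = self.responses.mean()
        if p_yes in (0.0, 1.0):
            raise FitError("all responses identical; threshold unidentified")
        # complete separation: every level below some cut all-no, above all-yes
        frac = self._k / self._n
        lo = self._lv[frac < 1.0]
        hi = self._lv[frac > 0.0]
        if lo.size and hi.size and lo.max() < hi.min():
            raise FitError("complete separation between response classes; "
                           "ML slope diverges")

    def _nll(self, params, free_lapse):
        alpha, beta = params[0], params[1]
        lam = params[2] if free_lapse else self.lam
        p = gumbel_function(self._lv, alpha, beta, self.gamma, lam)
        p = np.clip(p, 1e-9, 1.0 - 1e-9)
        return -np.sum(self._k * np.log(p) + (self._n - self._k) * np.log1p(-p))

    def fit(self, start=None, free_lapse: bool = False) -> "PsychometricFitResults":
        if start is None:
            # heuristic: alpha near the empirical 50 % crossing
            frac = self._k / self._n
            alpha0 = float(np.interp(0.5, frac, self._lv)) if np.any(frac > 0.5) \
                else float(self._lv.mean())
            start = (alpha0, 3.0) + ((0.01,) if free_lapse else ())
        bounds = [(self._lv.min() - 5.0, self._lv.max() + 5.0), (1e-2, 50.0)]
        if free_lapse:
            bounds.append((0.0, 0.05))
        res = minimize(self._nll, np.asarray(start, dtype=float),
                       args=(free_lapse,), method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000})
        res2 = minimize(self._nll, res.x, args=(free_lapse,),
                        method="L-BFGS-B", bounds=bounds)
        x = res2.x if res2.fun <= res.fun else res.x
        if not (res.success or res2.success):
            raise FitError(f"ML optimisation failed: {res.message}")
        lam = float(x[2]) if free_lapse else self.lam
        return PsychometricFitResults(
            model=self, alpha_D=float(x[0]), beta=float(x[1]),
            gamma=self.gamma, lam=lam,
            nll=float(min(res.fun, res2.fun)), free_lapse=free_lapse)


@dataclass
class PsychometricFitResults:
    """ML estimates for one condition's Gumbel psychometric function.

    ``threshold_D`` is the level where the unscaled core reaches
    1 - 1/e (~63 %), which is ``alpha`` identically.
    """

    model: GumbelPsychometric
    alpha_D: float
    beta: float
    gamma: float
    lam: float
    nll: float
    free_lapse: bool = False
    se_D: float | None = None
    n_boot: int | None = None
    boot_seed: int | None = None

    @property
    def threshold_D(self) -> float:
        return self.alpha_D

    def predict(self, x):
        return gumbel_function(x, self.alpha_D, self.beta, self.gamma, self.lam)

    def bootstrap_se(self, n_boot: int = 1000, seed: int = 0) -> float:
        """Parametric bootstrap SE of the threshold (stores and returns it).

        ``n_boot`` datasets are simulated from the fitted function at the
        observed levels and trial counts and refitted; the SE is the SD of
        the refitted thresholds.  With more than 20 % failed refits a
        warning is issued and the SE uses the successful ones.
        """
        if n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        m = self.model
        rng = np.random.default_rng(seed)
        p = np.clip(self.predict(m._lv), 1e-9, 1 - 1e-9)
        thresholds = []
        failures = 0
        for _ in range(n_boot):
            k = rng.binomial(m._n.astype(int), p)
            levels = np.repeat(m._lv, m._n.astype(int))
            resp = np.concatenate([
                np.r_[np.ones(int(ki)), np.zeros(int(ni - ki))]
                for ki, ni in zip(k, m._n)])
            try:
                bm = GumbelPsychometric(levels, resp, m.gamma, m.lam)
                bf = bm.fit(start=(self.alpha_D, self.beta)
                            + ((self.lam,) if self.free_lapse else ()),
                            free_lapse=self.free_lapse)
                thresholds.append(bf.threshold_D)
            except FitError:
                failures += 1
        if n_boot == 1:
            warnings.warn("n_boot=1: SE is 0 by convention")
            se = 0.0
        else:
            if failures > 0.2 * n_boot:
                warnings.warn(f"{failures}/{n_boot} bootstrap refits failed; "
                              "SE from the successful ones")
            if len(thresholds) < 2:
                raise FitError("too few successful bootstrap refits for an SE")
            se = float(np.std(thresholds, ddof=1))
        self.se_D = se
        self.n_boot = n_boot
        self.boot_seed = seed
        return se

    def summary(self) -> str:
        lines = [
            "Gumbel psychometric fit (maximum likelihood)",
            "-" * 46,
            f"{'alpha (threshold, D)':<28}{self.alpha_D:>10.4f}",
            f"{'beta (slope, /D)':<28}{self.beta:>10.4f}",
            f"{'gamma (guess)':<28}{self.gamma:>10.4f}",
            f"{'lambda (lapse)':<28}{self.lam:>10.4f}",
            f"{'threshold at 63% point (D)':<28}{self.threshold_D:>10.4f}",
        ]
        if self.se_D is not None:
            lines.append(f"{'bootstrap SE (D)':<28}{self.se_D:>10.4f}"
                         f"   (n_boot={self.n_boot})")
        lines.append(f"{'trials':<28}{int(self.model._n.sum()):>10d}")
        lines.append(f"{'-log likelihood':<28}{self.nll:>10.4f}")
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        return {"alpha_D": self.alpha_D, "beta": self.beta,
                "gamma": self.gamma, "lambda": self.lam,
                "threshold_D": self.threshold_D, "se_D": self.se_D,
                "n_boot": self.n_boot, "boot_seed": self.boot_seed,
                "nll": self.nll}


def fit_gumbel(records, condition_id: str, gamma: float = 0.0,
               lam: float = 0.0, free_lapse: bool = False) -> PsychometricFitResults:
    """Functional wrapper: fit one condition's trials from a session log."""
    return GumbelPsychometric.from_trials(records, condition_id,
                                          gamma=gamma, lam=lam
                                          ).fit(free_lapse=free_lapse)


def bootstrap_se(fit: PsychometricFitResults, n_boot: int = 1000,
                 seed: int = 0) -> float:
    """Functional wrapper around :meth:`PsychometricFitResults.bootstrap_se`."""
    return fit.bootstrap_se(n_boot=n_boot, seed=seed)


# ---------------------------------------------------------------------------
# zonal vs global comparison


@dataclass
class ThresholdComparison:
    """Zonal thresholds vs ring-averaged global-profile thresholds.

    ``differences.loc[zone, K]`` = (mean ring defocus of the fitted global
    profile under that zone) - (zonal threshold at that zone).
    """

    zonal_thresholds: dict               # zone outer ecc (deg) -> D
    global_thresholds: dict              # K -> fitted peak a* (D)
    global_zone_equivalent: pd.DataFrame # zone x K
    differences: pd.DataFrame            # zone x K
    rings_per_zone: dict                 # zone -> list of ring indices
    zone_centers_deg: tuple

    def to_csv(self, path) -> None:
        self.differences.to_csv(path)


def _zone_rings(zone_outer_deg: float, ring_width_deg: float,
                zone_width_deg: float, n_rings: int, mode: int = 4):
    """Ring indices under a zone.  mode=4: rings whose outer edge lies in
    (zone_outer - width, zone_outer]; mode=5 additionally includes the ring
    ending at the zone's inner edge (overlapping aggregation)."""
    outer = np.arange(1, n_rings + 1) * ring_width_deg
    lo = zone_outer_deg - zone_width_deg
    if mode == 4:
        sel = (outer > lo + 1e-9) & (outer <= zone_outer_deg + 1e-9)
    elif mode == 5:
        sel = (outer >= lo - 1e-9) & (outer <= zone_outer_deg + 1e-9)
    else:
        raise ValueError("mode must be 4 or 5")
    return list(np.nonzero(sel)[0] + 1)


def compare_zonal_global(zonal_thresholds: dict, global_thresholds: dict,
                         extent_deg: float = BLUR_EXTENT_DEG,
                         n_rings: int = N_RINGS,
                         zone_width_deg: float = 1.5,
                         rings_mode: int = 4) -> ThresholdComparison:
    """Zonal-equivalent thresholds of fitted global profiles, and their
    difference from the zonal thresholds.

    For each K the fitted peak ``a*`` defines the per-ring defocus table
    ``a* y(E_i; K)``; each zone's global-equivalent threshold is the mean of
    the ring values geometrically inside the zone (4 rings by default for
    1.5 deg zones of 0.375 deg rings; ``rings_mode=5`` adds the shared edge
    ring).  The difference is global-equivalent minus zonal.
    """
    zones = sorted(float(z) for z in zonal_thresholds)
    missing = [z for z in zones if zonal_thresholds[z] is None]
    if missing or not zones or not global_thresholds:
        raise ValueError(f"missing fits for conditions: {missing or 'all'}")
    ring_width = extent_deg / n_rings
    ring_outer = np.arange(1, n_rings + 1) * ring_width
    rings_per_zone = {z: _zone_rings(z, ring_width, zone_width_deg,
                                     n_rings, rings_mode) for z in zones}
    ks = sorted(global_thresholds)
    equiv = pd.DataFrame(index=pd.Index(zones, name="zone_outer_deg"),
                         columns=pd.Index(ks, name="K"), dtype=float)
    for K in ks:
        a_star = float(global_thresholds[K])
        table = a_star * sigmoid_profile(ring_outer / extent_deg, float(K))
        for z in zones:
            idx = np.asarray(rings_per_zone[z]) - 1
            equiv.loc[z, K] = float(table[idx].mean())
    diff = equiv.subtract(pd.Series({z: float(zonal_thresholds[z])
                                     for z in zones}), axis=0)
    centers = tuple(z - zone_width_deg / 2.0 for z in zones)
    return ThresholdComparison(
        zonal_thresholds={z: float(zonal_thresholds[z]) for z in zones},
        global_thresholds={k: float(v) for k, v in global_thresholds.items()},
        global_zone_equivalent=equiv, differences=diff,
        rings_per_zone=rings_per_zone, zone_centers_deg=centers)


def global_condition_profile(K: float, peak_a_D: float,
                             extent_deg: float = BLUR_EXTENT_DEG,
                             n_rings: int = N_RINGS) -> BlurProfile:
    """The blur profile presented when a global staircase sits at peak a."""
    return BlurProfile(K=K, peak_a_D=peak_a_D, extent_deg=extent_deg,
                       n_rings=n_rings)
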