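"""Residue-specific dissociation constants from Gamma2 titration series.

In fast exchange the apparent PRE rate is the population-weighted average of
the free and bound states, giving the single-site saturation isotherm

    Gamma2_app(x) = Gamma2_free + (Gamma2_bound - Gamma2_free) * x / (K_D + x)

with x the molar concentration of the spin-labelled (invisible) species.
Each selected residue is fitted by error-weighted nonlinear least squares
(Levenberg-Marquardt-type trust region), and classified by comparing the
three-parameter isotherm against a two-parameter straight line with a
small-sample-corrected information criterion:

* specific       — saturation model favoured by >= ``margin`` AICc units with
                   K_D interior to its bounds;
* nonspecific    — linear favoured, or K_D / Gamma2_bound pinned at a bound;
* noninteracting — the residue never passed the selection threshold
                   (Gamma2 at the designated titration point <= 15 s^-1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

__all__ = [
    "TitrationSet",
    "SaturationFit",
    "LinearFit",
    "ResidueFit",
    "binding_model",
    "select_fittable_residues",
    "fit_titration",
    "fit_linear",
    "classify_profile",
    "fit_titration_set",
    "group_summary",
]

KD_BOUNDS = (1e-12, 1.0)  # molar
GBOUND_BOUNDS = (0.0, 500.0)  # s^-1
SELECTION_THRESHOLD = 15.0  # s^-1
AICC_MARGIN = 2.0


def binding_model(
    x: np.ndarray | float, gamma2_free: float, gamma2_bound: float, kd: float
) -> np.ndarray | float:
    """Single-site saturation isotherm; monotone nondecreasing in x when
    gamma2_bound >= gamma2_free."""
    if kd <= 0:
        raise ValueError("kd must be positive")
    x = np.asarray(x, dtype=float) if np.ndim(x) else float(x)
    return gamma2_free + (gamma2_bound - gamma2_free) * x / (kd + x)


@dataclass
class TitrationSet:
    """Per-residue Gamma2 across titrant concentrations on a shared x grid."""

    x: np.ndarray  # molar concentration of the spin-labelled species
    gamma2: dict[int, np.ndarray]
    gamma2_error: dict[int, np.ndarray]
    visible_concentration: float
    ratios: np.ndarray
    excluded_points: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, float)
        self.ratios = np.asarray(self.ratios, float)
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x values must be strictly increasing")
        if self.x[0] != 0.0:
            raise ValueError("the x = 0 (no paramagnetic species) point must be present")
        for r, g in self.gamma2.items():
            if len(g) != len(self.x):
                raise ValueError(f"residue {r}: series length does not match the x grid")

    def residues(self) -> list[int]:
        return sorted(self.gamma2)

    def series(self, residue: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.x, self.gamma2[residue], self.gamma2_error[residue]


def select_fittable_residues(
    tset: TitrationSet,
    threshold: float = SELECTION_THRESHOLD,
    point_index: int | None = None,
) -> list[int]:
    """Residues whose Gamma2 at the designated titration point exceeds the
    threshold (strict inequality; default point: highest retained)."""
    if point_index is None:
        point_index = len(tset.x) - 1
    if not (0 <= point_index < len(tset.x)):
        raise ValueError(
            f"point index {point_index} beyond the retained grid of {len(tset.x)} points"
        )
    return [r for r in tset.residues() if tset.gamma2[r][point_index] > threshold]


@dataclass
class SaturationFit:
    gamma2_free: float
    gamma2_bound: float
    kd: float
    gamma2_free_error: float
    gamma2_bound_error: float
    kd_error: float
    kd_low: float  # profile-likelihood interval at delta-chi2 = 1
    kd_high: float
    chi2: float
    n: int
    aicc: float
    converged: bool
    at_bound: bool
    flag: str | None = None


@dataclass
class LinearFit:
    intercept: float
    slope: float
    chi2: float
    n: int
    aicc: float


def _aicc(chi2: float, n: int, k: int) -> float:
    if n - k - 1 <= 0:
        return math.inf
    return chi2 + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _weighted_linear_given_kd(
    x: np.ndarray, y: np.ndarray, w: np.ndarray, kd: float
) -> tuple[float, float, float]:
    """Re-optimise (gamma2_free, gamma2_bound) at fixed kd (model is linear in
    them); returns (gf, gb, chi2)."""
    u = x / (kd + x)
    a = np.column_stack([(1.0 - u) * w, u * w])
    coeff, *_ = np.linalg.lstsq(a, y * w, rcond=None)
    resid = (y - coeff[0] * (1 - u) - coeff[1] * u) * w
    return float(coeff[0]), float(coeff[1]), float(resid @ resid)


def fit_titration(
    x: np.ndarray,
    gamma2: np.ndarray,
    gamma2_error: np.ndarray,
    weighted: bool = True,
    kd_bounds: tuple[float, float] = KD_BOUNDS,
    gbound_bounds: tuple[float, float] = GBOUND_BOUNDS,
) -> SaturationFit:
    """Error-weighted nonlinear least-squares fit of the saturation isotherm.

    Initialisation: gamma2_free from the x = 0 point, gamma2_bound twice the
    maximum observed Gamma2, kd at the median titrant concentration.
    Parameter uncertainties come from the covariance at the optimum scaled by
    the reduced chi-square; the kd interval additionally comes from a
    one-dimensional profile-likelihood scan (kd fixed on a log grid, the two
    linear parameters re-optimised) at delta-chi2 = 1.

    ``weighted=False`` ignores the per-point errors (unit weights).
    """
    x = np.asarray(x, float)
    y = np.asarray(gamma2, float)
    err = np.asarray(gamma2_error, float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 titration points after exclusions")
    if weighted and np.any(err <= 0):
        raise ValueError("gamma2 errors must be positive for a weighted fit")
    w = 1.0 / err if weighted else np.ones_like(y)

    gf0 = float(y[x == 0][0]) if np.any(x == 0) else float(y[0])
    gb0 = float(np.clip(2.0 * np.max(y), gbound_bounds[0] + 1e-9, gbound_bounds[1]))
    kd0 = float(np.clip(np.median(x[x > 0]), *kd_bounds))

    def resid(p: np.ndarray) -> np.ndarray:
        gf, gb, kd = p
        return (y - binding_model(x, gf, gb, kd)) * w

    lower = [-np.inf, gbound_bounds[0], kd_bounds[0]]
    upper = [np.inf, gbound_bounds[1], kd_bounds[1]]
    sol = least_squares(
        resid, x0=[gf0, gb0, kd0], bounds=(lower, upper),
        method="trf", x_scale="jac", ftol=1e-14, xtol=1e-14, gtol=1e-14, max_nfev=5000,
    )
    gf, gb, kd = (float(v) for v in sol.x)
    chi2 = float(2 * sol.cost)
    dof = max(n - 3, 1)

    # covariance from J^T J at the optimum, scaled by reduced chi-square
    try:
        jtj = sol.jac.T @ sol.jac
        cov = np.linalg.inv(jtj) * max(chi2 / dof, 0.0)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(3, np.inf)

    at_bound = (
        kd >= kd_bounds[1] * (1 - 1e-6)
        or kd <= kd_bounds[0] * (1 + 1e-6)
        or gb >= gbound_bounds[1] * (1 - 1e-6)
    )
    flag = None
    if not sol.success:
        flag = "non-convergence"
    elif at_bound:
        flag = "parameter at bound"
    elif abs(gb - gf) < 1e-9 and np.allclose(y, y[0], atol=1e-9):
        flag = "kd unidentifiable (flat profile)"

    kd_low, kd_high = _profile_likelihood_interval(x, y, w, kd, chi2, kd_bounds)
    return SaturationFit(
        gamma2_free=gf, gamma2_bound=gb, kd=kd,
        gamma2_free_error=float(se[0]), gamma2_bound_error=float(se[1]),
        kd_error=float(se[2]), kd_low=kd_low, kd_high=kd_high,
        chi2=chi2, n=n, aicc=_aicc(chi2, n, 3),
        converged=bool(sol.success), at_bound=at_bound, flag=flag,
    )


def _profile_likelihood_interval(
    x: np.ndarray, y: np.ndarray, w: np.ndarray,
    kd_hat: float, chi2_min: float,
    kd_bounds: tuple[float, float],
) -> tuple[float, float]:
    """Delta-chi2 = 1 interval for kd: walk out on a log scale from the
    optimum (re-optimising the two linear parameters at each kd) and bracket
    the crossings by bisection.  An end that never crosses before hitting the
    kd bound is reported as open (the bound itself, or +inf at the top)."""

    def chi2_at(kd: float) -> float:
        return _weighted_linear_given_kd(x, y, w, kd)[2]

    target = min(chi2_min, chi2_at(kd_hat)) + 1.0

    def crossing(direction: int) -> float:
        a, step = kd_hat, 1.25
        for _ in range(300):
            b = a * step if direction > 0 else a / step
            b = min(max(b, kd_bounds[0]), kd_bounds[1])
            if chi2_at(b) > target:
                return float(brentq(lambda k: chi2_at(k) - target,
                                    min(a, b), max(a, b), rtol=1e-6))
            a = b
            if b in kd_bounds:
                break
        return math.inf if direction > 0 and a >= kd_bounds[1] else a

    return crossing(-1), crossing(+1)


def fit_linear(
    x: np.ndarray, gamma2: np.ndarray, gamma2_error: np.ndarray, weighted: bool = True
) -> LinearFit:
    """Weighted straight-line fit Gamma2 = intercept + slope * x (the
    nonspecific candidate model; the intercept mirrors Gamma2_free)."""
    x = np.asarray(x, float)
    y = np.asarray(gamma2, float)
    err = np.asarray(gamma2_error, float)
    w = 1.0 / err if weighted else np.ones_like(y)
    a = np.column_stack([np.ones_like(x) * w, x * w])
    coeff, *_ = np.linalg.lstsq(a, y * w, rcond=None)
    resid = (y - coeff[0] - coeff[1] * x) * w
    chi2 = float(resid @ resid)
    return LinearFit(
        intercept=float(coeff[0]), slope=float(coeff[1]),
        chi2=chi2, n=x.size, aicc=_aicc(chi2, x.size, 2),
    )


@dataclass
class ResidueFit:
    residue_index: int
    classification: str  # specific / nonspecific / noninteracting
    saturation: SaturationFit | None
    linear: LinearFit | None


def classify_profile(
    x: np.ndarray,
    gamma2: np.ndarray,
    gamma2_error: np.ndarray,
    margin: float = AICC_MARGIN,
    weighted: bool = True,
) -> tuple[str, SaturationFit, LinearFit]:
    """Fit both candidate models and classify the titration profile."""
    sat = fit_titration(x, gamma2, gamma2_error, weighted=weighted)
    lin = fit_linear(x, gamma2, gamma2_error, weighted=weighted)
    specific = (
        sat.converged
        and not sat.at_bound
        and sat.flag is None
        and sat.gamma2_bound >= sat.gamma2_free
        and sat.aicc <= lin.aicc - margin
    )
    return ("specific" if specific else "nonspecific"), sat, lin


def fit_titration_set(
    tset: TitrationSet,
    threshold: float = SELECTION_THRESHOLD,
    point_index: int | None = None,
    margin: float = AICC_MARGIN,
    weighted: bool = True,
) -> dict[int, ResidueFit]:
    """Select, fit and classify every residue of a titration set.

    Residues below the selection threshold are reported as noninteracting and
    are not fitted.
    """
    selected = set(select_fittable_residues(tset, threshold, point_index))
    out: dict[int, ResidueFit] = {}
    for r in tset.residues():
        if r not in selected:
            out[r] = ResidueFit(r, "noninteracting", None, None)
            continue
        x, y, e = tset.series(r)
        cls, sat, lin = classify_profile(x, y, e, margin=margin, weighted=weighted)
        out[r] = ResidueFit(r, cls, sat, lin)
    return out


def fits_to_frame(fits: Mapping[int, ResidueFit]) -> pd.DataFrame:
    """Long-format fit report."""
    rows = []
    for r in sorted(fits):
        f = fits[r]
        sat = f.saturation
        rows.append(
            dict(
                residue_index=r,
                classification=f.classification,
                kd=sat.kd if sat and f.classification == "specific" else np.nan,
                kd_low=sat.kd_low if sat and f.classification == "specific" else np.nan,
                kd_high=sat.kd_high if sat and f.classification == "specific" else np.nan,
                gamma2_free=sat.gamma2_free if sat else np.nan,
                gamma2_bound=sat.gamma2_bound if sat else np.nan,
                chi2_saturation=sat.chi2 if sat else np.nan,
                chi2_linear=f.linear.chi2 if f.linear else np.nan,
                aicc_saturation=sat.aicc if sat else np.nan,
                aicc_linear=f.linear.aicc if f.linear else np.nan,
            )
        )
    return pd.DataFrame(rows)


def group_summary(
    fits: Mapping[int, ResidueFit], residues: Iterable[int]
) -> tuple[float, tuple[float, float], int]:
    """Median and min-max range of kd over the specific residues of a group.

    Returns (median_kd, (kd_min, kd_max), n_specific); raises if the group
    contains no specific residue.
    """
    kds = [
        fits[r].saturation.kd
        for r in residues
        if r in fits and fits[r].classification == "specific" and fits[r].saturation
    ]
    if not kds:
        raise ValueError("no residue in the group is classified specific")
    return float(np.median(kds)), (float(np.min(kds)), float(np.max(kds))), len(kds)
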