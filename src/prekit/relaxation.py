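"""Per-residue amide-proton transverse relaxation (R2) from peak-intensity decays.

The pipeline starts from HSQC peak intensities measured across a schedule of
relaxation delays.  Each residue's intensity series is modelled as a
two-parameter mono-exponential decay

    I(t) = I0 * exp(-R2 * t)

and R2 (in s^-1) is estimated by weighted nonlinear least squares, initialised
from the log-linear closed form.  Duplicated delay values in the schedule are
replicate measurements: they enter the fit as independent points and feed a
pooled estimate of the relative intensity noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "PeakSeries",
    "R2Fit",
    "SampleInfo",
    "RelaxationProfile",
    "NoNoiseReplicatesError",
    "estimate_intensity_noise",
    "loglinear_decay",
    "fit_decay",
    "fit_profile",
]

#: delay schedule used throughout the study design (seconds); 12 and 64 ms
#: appear twice on purpose, providing replicate points for error analysis.
DEFAULT_DELAYS = (0.012, 0.032, 0.104, 0.012, 0.124, 0.064, 0.048, 0.094, 0.064, 0.020)


class NoNoiseReplicatesError(ValueError):
    """No duplicated delay anywhere: noise must be supplied by configuration."""


@dataclass(frozen=True)
class SampleInfo:
    """Identity of one NMR sample (one visible/invisible chain combination)."""

    visible_species: str
    invisible_species: str | None = None
    spin_label_site: int | None = None
    arm: str | None = None  # "para" or "dia"
    ratio: float | None = None  # invisible:visible molar ratio

    def matches(self, other: "SampleInfo") -> bool:
        """True if the two samples describe the same titration point (arm aside)."""
        return (
            self.visible_species == other.visible_species
            and self.invisible_species == other.invisible_species
            and self.spin_label_site == other.spin_label_site
            and self.ratio == other.ratio
        )


@dataclass
class PeakSeries:
    """Peak intensities of one residue across the relaxation-delay schedule."""

    residue_index: int
    delays: np.ndarray
    intensities: np.ndarray
    sample_label: str = ""

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.residue_index < 1:
            raise ValueError("residue_index is 1-based and must be >= 1")
        if self.delays.shape != self.intensities.shape:
            raise ValueError("delays and intensities must have equal length")
        if self.delays.size < 3:
            raise ValueError("need at least 3 delay points")
        if np.any(self.delays < 0):
            raise ValueError("delays must be non-negative")
        if np.unique(self.delays).size < 2:
            raise ValueError("need at least two distinct delay values")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    def replicate_groups(self) -> dict[float, np.ndarray]:
        """Intensities grouped by duplicated delay value (groups of size >= 2)."""
        groups: dict[float, np.ndarray] = {}
        for t in np.unique(self.delays):
            idx = np.flatnonzero(self.delays == t)
            if idx.size >= 2:
                groups[float(t)] = self.intensities[idx]
        return groups


@dataclass(frozen=True)
class R2Fit:
    """Mono-exponential fit result for one residue."""

    r2: float
    r2_error: float
    amplitude: float
    fit_quality: float  # reduced chi-square of the weighted fit


@dataclass
class RelaxationProfile:
    """Per-residue R2 with uncertainties for one sample.

    Residues whose fit failed are recorded in ``failures`` (reason strings)
    and are absent from ``residues`` — never silently zero.
    """

    residues: dict[int, R2Fit]
    noise: float
    sample: SampleInfo | None = None
    failures: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for idx, fit in self.residues.items():
            if fit.r2 < 0 or fit.r2_error < 0:
                raise ValueError(f"residue {idx}: fitted r2 and r2_error must be >= 0")

    def __len__(self) -> int:
        return len(self.residues)

    def residue_indices(self) -> list[int]:
        return sorted(self.residues)


def estimate_intensity_noise(series_collection: Iterable[PeakSeries]) -> float:
    """Pooled relative intensity noise from duplicated-delay replicate pairs.

    For every group of replicate intensities (same delay, same residue) the
    unbiased per-measurement relative standard deviation is estimated from the
    replicate spread — for a pair (I1, I2) this is |I1 - I2| / (sqrt(2) * mean) —
    and the estimates are pooled across residues by their degrees of freedom
    (root-mean-square for pairs).  Deterministic for fixed input.

    Raises
    ------
    NoNoiseReplicatesError
        If no residue has a duplicated delay value.
    """
    num = 0.0
    dof = 0
    for series in series_collection:
        for _, vals in series.replicate_groups().items():
            m = float(np.mean(vals))
            if m <= 0:
                continue
            s2 = float(np.var(vals, ddof=1))  # for a pair: (I1-I2)^2 / 2
            num += (len(vals) - 1) * s2 / m**2
            dof += len(vals) - 1
    if dof == 0:
        raise NoNoiseReplicatesError(
            "no duplicated delays found; supply the noise level via configuration"
        )
    return math.sqrt(num / dof)


def loglinear_decay(delays: np.ndarray, intensities: np.ndarray) -> tuple[float, float]:
    """Closed-form (I0, R2) from unweighted linear regression of ln I on t.

    Requires strictly positive intensities.  Serves both as the initialiser of
    the nonlinear fit and as an independent oracle on noiseless data.
    """
    delays = np.asarray(delays, float)
    intensities = np.asarray(intensities, float)
    if np.any(intensities <= 0):
        raise ValueError("log-linear form requires strictly positive intensities")
    slope, intercept = np.polyfit(delays, np.log(intensities), 1)
    return math.exp(intercept), -slope


def _model(t: np.ndarray, i0: float, r2: float) -> np.ndarray:
    return i0 * np.exp(-r2 * t)


def fit_decay(series: PeakSeries, noise: float) -> R2Fit:
    """Weighted nonlinear least-squares mono-exponential fit of one series.

    Parameters
    ----------
    series:
        The intensity decay; replicate delays are fitted as independent points.
    noise:
        Relative (fractional) intensity noise.  Point uncertainties are
        ``noise * I`` and the returned ``r2_error`` comes from the parameter
        covariance under exactly those uncertainties.  With ``noise == 0`` the
        fit is relative-weighted and the covariance is scaled by the reduced
        chi-square (zero for exact data).
    """
    t = series.delays
    y = series.intensities
    n = t.size
    if n < 3:
        raise ValueError("need at least 3 points to fit a decay")

    if np.all(y > 0):
        i0_init, r2_init = loglinear_decay(t, y)
        p0 = (i0_init, r2_init)
        bounds = ((0.0, -np.inf), (np.inf, np.inf))
    else:
        # zero intensities: direct nonlinear fit with positivity bound on I0
        p0 = (max(float(np.max(y)), 1e-12), 1.0)
        bounds = ((0.0, -np.inf), (np.inf, np.inf))

    if noise > 0:
        sigma = noise * np.maximum(y, 1e-12 * max(float(np.max(y)), 1.0))
        absolute = True
    else:
        sigma = np.maximum(y, 1e-12 * max(float(np.max(y)), 1.0))
        absolute = False

    popt, pcov = curve_fit(
        _model, t, y, p0=p0, sigma=sigma, absolute_sigma=absolute,
        bounds=bounds, maxfev=10000, xtol=1e-14, ftol=1e-14,
    )
    i0, r2 = float(popt[0]), float(popt[1])
    resid = (y - _model(t, i0, r2)) / sigma
    dof = max(n - 2, 1)
    red_chi2 = float(resid @ resid) / dof
    var = pcov[1, 1]
    if not absolute:
        # curve_fit already scales by red-chi2 when absolute_sigma=False
        pass
    r2_err = float(math.sqrt(var)) if np.isfinite(var) and var >= 0 else math.inf
    return R2Fit(r2=r2, r2_error=r2_err, amplitude=i0, fit_quality=red_chi2)


def fit_profile(
    tables: Iterable[PeakSeries],
    noise: float | None = None,
    sample: SampleInfo | None = None,
) -> RelaxationProfile:
    """Fit every residue's decay in a sample; record failures explicitly.

    ``noise=None`` pools the replicate-based estimate from the tables
    themselves (requires duplicated delays somewhere).  A residue is marked
    failed on non-convergence, a negative rate at the optimum, or a relative
    rate uncertainty above 100%.
    """
    series_list = list(tables)
    if not series_list:
        raise ValueError("empty collection of peak series")
    seen: set[int] = set()
    for s in series_list:
        if s.residue_index in seen:
            raise ValueError(f"duplicate series for residue {s.residue_index}")
        seen.add(s.residue_index)

    if noise is None:
        noise = estimate_intensity_noise(series_list)

    fitted: dict[int, R2Fit] = {}
    failures: dict[int, str] = {}
    for s in series_list:
        try:
            fit = fit_decay(s, noise)
        except Exception as exc:  # noqa: BLE001 - any fit breakdown is a failure record
            failures[s.residue_index] = f"fit error: {exc}"
            continue
        if not np.isfinite(fit.r2) or not np.isfinite(fit.r2_error):
            failures[s.residue_index] = "non-convergence"
        elif fit.r2 < 0:
            failures[s.residue_index] = "negative rate at optimum"
        elif fit.r2_error > abs(fit.r2) + 1e-8:
            failures[s.residue_index] = "relative rate uncertainty above 100%"
        else:
            fitted[s.residue_index] = fit
    return RelaxationProfile(residues=fitted, noise=noise, sample=sample, failures=failures)


def gamma2_noise_sigma(delays: Iterable[float], noise: float) -> float:
    """Propagated standard deviation of a PRE rate for a given delay schedule.

    With relative intensity noise ``eps``, the slope of ln I against t has
    variance eps^2 / sum((t - tbar)^2); the PRE rate is a difference of two
    such slopes, hence the sqrt(2).
    """
    t = np.asarray(list(delays), float)
    sxx = float(np.sum((t - t.mean()) ** 2))
    return noise * math.sqrt(2.0 / sxx)
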