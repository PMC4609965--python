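"""Synthetic relaxation, PRE and titration data with the statistical structure
the analysis assumes.

The generator emulates a two-state fast-exchange transient dimer: the visible
chain relaxes at a disordered-protein baseline R2; residues inside declared
contact segments gain a bound-state enhancement weighted by the dimer
occupancy set by a dissociation constant.  Peak intensities decay
mono-exponentially with multiplicative Gaussian noise; duplicate delays get
independent noise.  Three default scenarios encode the study conditions:

* ``homo``       — alpha/alpha: N-terminal probes contact both the N-terminal
                   hot-spot neighbourhood 36-44 (nonspecific, K_D far above the
                   sampled concentrations) and the C-terminus 124-140
                   (specific, K_D around 500 uM, range 90-1200 uM);
* ``hetero``     — alpha-labelled / beta-visible: N probes contact the beta
                   C-terminus 105-134 (specific, K_D around 100 uM, range
                   40-350 uM) plus an extremely weak N-N segment 37-41;
* ``beta-beta``  — beta/beta: no contact segments at all.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .pre import RegionMap, alpha_synuclein_regions, beta_synuclein_regions
from .relaxation import DEFAULT_DELAYS, PeakSeries, SampleInfo, gamma2_noise_sigma
from .titration import TitrationSet

__all__ = [
    "ContactSegment",
    "ScenarioConfig",
    "simulate_occupancy",
    "simulate_pre_truth",
    "simulate_peak_tables",
    "simulate_titration",
    "scenario",
    "SCENARIO_NAMES",
]

EDGE_TAPER = 3  # residues over which segment amplitudes ramp linearly


@dataclass(frozen=True)
class ContactSegment:
    """One contact patch on the visible chain, as seen by one spin label.

    ``kd`` is either a single molar constant for the whole segment or a
    per-residue mapping (1-based residue -> molar).
    """

    site: int
    start: int
    end: int
    amplitude: float  # bound-state Gamma2 at the segment core, s^-1
    kd: float | Mapping[int, float]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("segment start must be <= end")
        if self.amplitude < 0:
            raise ValueError("amplitudes must be >= 0")
        kds = self.kd.values() if isinstance(self.kd, Mapping) else [self.kd]
        if any(k <= 0 for k in kds):
            raise ValueError("kd must be positive")

    def kd_at(self, residue: int) -> float:
        if isinstance(self.kd, Mapping):
            return float(self.kd[residue])
        return float(self.kd)

    def multiplier(self, residue: int) -> float:
        """Linear edge taper over EDGE_TAPER residues; 0 outside the segment."""
        if not (self.start <= residue <= self.end):
            return 0.0
        d = min(residue - self.start, self.end - residue)
        return min(1.0, (d + 1) / EDGE_TAPER)


@dataclass
class ScenarioConfig:
    name: str
    visible_species: str
    invisible_species: str
    visible_sequence: str
    invisible_sequence: str
    spin_label_sites: list[int]
    segments: list[ContactSegment]
    visible_concentration: float = 250e-6  # molar
    ratios: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0, 1.5)
    delays: tuple[float, ...] = DEFAULT_DELAYS
    noise: float = 0.035  # relative intensity noise
    seed: int = 0
    occupancy_model: Literal["exact_dimer", "hyperbolic"] = "exact_dimer"
    baseline_r2_range: tuple[float, float] = (10.0, 25.0)  # s^-1, disordered amides
    skip_prolines: bool = True
    titration_site: int = 44

    def __post_init__(self) -> None:
        n = len(self.visible_sequence)
        for seg in self.segments:
            if not (1 <= seg.start <= seg.end <= n):
                raise ValueError(f"segment {seg} outside the visible sequence 1..{n}")
            if seg.site not in self.spin_label_sites:
                raise ValueError(f"segment site {seg.site} is not a declared spin label")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")

    # -- derived, deterministic under the seed ---------------------------------

    def observable_residues(self) -> list[int]:
        """Residues with an observable amide peak (prolines have none)."""
        seq = self.visible_sequence
        return [
            i for i in range(1, len(seq) + 1)
            if not (self.skip_prolines and seq[i - 1] == "P")
        ]

    def baseline_r2(self) -> np.ndarray:
        """Per-residue diamagnetic R2, drawn once from the seed (index i-1)."""
        rng = np.random.default_rng([self.seed, 101])
        lo, hi = self.baseline_r2_range
        return rng.uniform(lo, hi, size=len(self.visible_sequence))

    def gamma2_sigma(self) -> float:
        """Propagated sigma of Gamma2 implied by the intensity noise."""
        return gamma2_noise_sigma(self.delays, self.noise)


def simulate_occupancy(
    c_visible: float,
    c_invisible: float,
    kd: float,
    model: Literal["exact_dimer", "hyperbolic"] = "exact_dimer",
) -> float:
    """Bound fraction of the visible chain for A + B <-> AB.

    ``exact_dimer`` solves the quadratic mass-balance exactly (written in the
    cancellation-free form); ``hyperbolic`` treats the invisible total
    concentration as free ligand, f = c_invisible / (kd + c_invisible) — the
    approximation underlying the fitted isotherm.
    """
    if kd <= 0:
        raise ValueError("kd must be positive")
    if c_visible < 0 or c_invisible < 0:
        raise ValueError("concentrations must be >= 0")
    if model == "hyperbolic":
        return c_invisible / (kd + c_invisible)
    if model == "exact_dimer":
        s = c_visible + c_invisible + kd
        disc = s * s - 4.0 * c_visible * c_invisible
        return 2.0 * c_invisible / (s + math.sqrt(max(disc, 0.0)))
    raise ValueError(f"unknown occupancy model: {model!r}")


def simulate_pre_truth(config: ScenarioConfig, ratio: float) -> dict[int, np.ndarray]:
    """Noise-free Gamma2 per spin-label site (arrays indexed residue-1).

    Gamma2(i) = sum over segments covering i of f(kd_i) * amplitude * taper;
    zero outside all segments.
    """
    n = len(config.visible_sequence)
    x = ratio * config.visible_concentration
    out = {site: np.zeros(n) for site in config.spin_label_sites}
    for seg in config.segments:
        arr = out[seg.site]
        for i in range(seg.start, seg.end + 1):
            mult = seg.multiplier(i)
            f = simulate_occupancy(
                config.visible_concentration, x, seg.kd_at(i), config.occupancy_model
            )
            arr[i - 1] += f * seg.amplitude * mult
    return out


def _rng_for(config: ScenarioConfig, *tags: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, *tags])


_ARM_CODE = {"dia": 0, "para": 1}


def simulate_peak_tables(
    config: ScenarioConfig,
    ratio: float,
    arm: Literal["para", "dia"],
    sites: Iterable[int] | None = None,
) -> dict[int, list[PeakSeries]]:
    """Peak-intensity decay tables for every spin-label site of one arm.

    The diamagnetic arm decays at the baseline R2; the paramagnetic arm at
    baseline + true Gamma2.  Intensities are I0 * exp(-R2 t) with
    multiplicative Gaussian noise; duplicate delays get independent noise.
    Deterministic under a fixed config seed.
    """
    if arm not in _ARM_CODE:
        raise ValueError("arm must be 'para' or 'dia'")
    baseline = config.baseline_r2()
    truth = simulate_pre_truth(config, ratio)
    delays = np.asarray(config.delays, float)
    out: dict[int, list[PeakSeries]] = {}
    for site in sites if sites is not None else config.spin_label_sites:
        rng = _rng_for(config, site, _ARM_CODE[arm], int(round(ratio * 10000)), 7)
        series_list = []
        for i in config.observable_residues():
            r2 = baseline[i - 1] + (truth[site][i - 1] if arm == "para" else 0.0)
            i0 = rng.uniform(600.0, 1400.0)
            clean = i0 * np.exp(-r2 * delays)
            noisy = clean * (1.0 + config.noise * rng.standard_normal(delays.size))
            series_list.append(
                PeakSeries(
                    residue_index=i,
                    delays=delays.copy(),
                    intensities=np.clip(noisy, 0.0, None),
                    sample_label=(
                        f"{config.visible_species}15N/"
                        f"{config.invisible_species}-{site}-MTSL {arm} ratio {ratio:g}"
                    ),
                )
            )
        out[site] = series_list
    return out


def simulate_titration(
    config: ScenarioConfig,
    site: int | None = None,
    path: Literal["fast", "full"] = "fast",
) -> tuple[TitrationSet, pd.DataFrame]:
    """Gamma2 titration series for one spin-label strip, plus the truth record.

    ``fast`` injects Gaussian noise directly on the true Gamma2 with the sigma
    propagated from the intensity noise; ``full`` runs the peak-table ->
    relaxation-fit -> PRE subtraction path for every ratio.  The truth record
    carries the generating kd and core amplitude per contacted residue.
    """
    site = config.titration_site if site is None else site
    if site not in config.spin_label_sites:
        raise ValueError(f"site {site} is not a declared spin label")
    residues = config.observable_residues()
    x = np.array([r * config.visible_concentration for r in config.ratios])
    sigma = config.gamma2_sigma()

    gamma2: dict[int, list[float]] = {i: [] for i in residues}
    errors: dict[int, list[float]] = {i: [] for i in residues}

    if path == "fast":
        rng = _rng_for(config, site, 5, 13)
        for k, ratio in enumerate(config.ratios):
            truth_k = simulate_pre_truth(config, ratio)[site]
            noise_k = sigma * rng.standard_normal(len(residues))
            for j, i in enumerate(residues):
                gamma2[i].append(truth_k[i - 1] + noise_k[j])
                errors[i].append(sigma if sigma > 0 else 1e-6)
    elif path == "full":
        from .pre import compute_pre
        from .relaxation import fit_profile

        for ratio in config.ratios:
            profiles = {}
            for arm in ("para", "dia"):
                tables = simulate_peak_tables(config, ratio, arm, sites=[site])[site]
                profiles[arm] = fit_profile(
                    tables,
                    noise=config.noise if config.noise > 0 else 1e-6,
                    sample=SampleInfo(
                        visible_species=config.visible_species,
                        invisible_species=config.invisible_species,
                        spin_label_site=site,
                        arm=arm,
                        ratio=ratio,
                    ),
                )
            pre = compute_pre(profiles["para"], profiles["dia"])
            for i in residues:
                if i in pre.residues:
                    gamma2[i].append(pre.residues[i].gamma2)
                    errors[i].append(max(pre.residues[i].gamma2_error, 1e-9))
                else:
                    gamma2[i].append(np.nan)
                    errors[i].append(np.nan)
        # drop residues that failed at any ratio (kept on a shared grid)
        bad = [i for i in residues if np.any(np.isnan(gamma2[i]))]
        for i in bad:
            del gamma2[i], errors[i]
    else:
        raise ValueError(f"unknown path: {path!r}")

    tset = TitrationSet(
        x=x,
        gamma2={i: np.array(v) for i, v in gamma2.items()},
        gamma2_error={i: np.array(v) for i, v in errors.items()},
        visible_concentration=config.visible_concentration,
        ratios=np.array(config.ratios),
    )

    rows = []
    for seg in config.segments:
        if seg.site != site:
            continue
        for i in range(seg.start, seg.end + 1):
            if i not in tset.gamma2:
                continue
            rows.append(
                dict(
                    residue_index=i,
                    kd=seg.kd_at(i),
                    amplitude=seg.amplitude * seg.multiplier(i),
                )
            )
    truth = pd.DataFrame(rows, columns=["residue_index", "kd", "amplitude"])
    return tset, truth


# ---------------------------------------------------------------------------
# default scenarios


def _draw_segment_kds(
    rng: np.random.Generator, start: int, end: int,
    median: float, spread: float, clip: tuple[float, float],
) -> dict[int, float]:
    """Per-residue kd draws: lognormal around the reported median, clipped to
    the reported range."""
    kds = median * np.exp(spread * rng.standard_normal(end - start + 1))
    kds = np.clip(kds, *clip)
    return {i: float(k) for i, k in zip(range(start, end + 1), kds)}

HOMO_C_KD = dict(median=500e-6, spread=0.35, clip=(90e-6, 1200e-6))
HETERO_C_KD = dict(median=100e-6, spread=0.35, clip=(40e-6, 350e-6))
NONSPECIFIC_KD = 5e-3  # far above the sampled concentrations -> linear regime


def _homo_alpha(seed: int, noise: float) -> ScenarioConfig:
    regions = alpha_synuclein_regions()
    seq = regions.sequence
    rng = np.random.default_rng([seed, 11])
    segments = []
    for site in (11, 44):
        segments.append(ContactSegment(site, 36, 44, amplitude=400.0, kd=NONSPECIFIC_KD))
        segments.append(
            ContactSegment(site, 124, 140, amplitude=60.0,
                           kd=_draw_segment_kds(rng, 124, 140, **HOMO_C_KD))
        )
    # the symmetric view: the C-terminal probe sees the N-terminal hot spot
    segments.append(
        ContactSegment(132, 36, 44, amplitude=60.0,
                       kd=_draw_segment_kds(rng, 36, 44, **HOMO_C_KD))
    )
    return ScenarioConfig(
        name="homo", visible_species="alpha", invisible_species="alpha",
        visible_sequence=seq, invisible_sequence=seq,
        spin_label_sites=[11, 44, 90, 132], segments=segments,
        ratios=(0.0, 0.25, 0.5, 0.75, 1.0, 1.5), noise=noise, seed=seed,
    )


def _hetero_alpha_beta(seed: int, noise: float) -> ScenarioConfig:
    """Alpha-synuclein spin labels probing the visible beta-synuclein chain."""
    alpha = alpha_synuclein_regions()
    beta = beta_synuclein_regions()
    rng = np.random.default_rng([seed, 11])
    segments = []
    for site in (11, 44):
        segments.append(
            ContactSegment(site, 105, 134, amplitude=50.0,
                           kd=_draw_segment_kds(rng, 105, 134, **HETERO_C_KD))
        )
        segments.append(ContactSegment(site, 37, 41, amplitude=10.0, kd=NONSPECIFIC_KD))
    return ScenarioConfig(
        name="hetero", visible_species="beta", invisible_species="alpha",
        visible_sequence=beta.sequence, invisible_sequence=alpha.sequence,
        spin_label_sites=[11, 44, 90, 132], segments=segments,
        ratios=(0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0), noise=noise, seed=seed,
    )


def _homo_beta(seed: int, noise: float) -> ScenarioConfig:
    beta = beta_synuclein_regions()
    return ScenarioConfig(
        name="beta-beta", visible_species="beta", invisible_species="beta",
        visible_sequence=beta.sequence, invisible_sequence=beta.sequence,
        spin_label_sites=[11, 44, 80, 134], segments=[],
        ratios=(0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0), noise=noise, seed=seed,
    )


_FACTORIES = {"homo": _homo_alpha, "hetero": _hetero_alpha_beta, "beta-beta": _homo_beta}
SCENARIO_NAMES = tuple(_FACTORIES)


def scenario(
    name: str, seed: int = 0, noise: float = 0.035, **overrides
) -> ScenarioConfig:
    """Build a default scenario by name ('homo', 'hetero', 'beta-beta')."""
    try:
        factory = _FACTORIES[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; valid names: {', '.join(SCENARIO_NAMES)}"
        ) from None
    config = factory(seed, noise)
    if overrides:
        config = replace(config, **overrides)
    return config


def visible_region_map(config: ScenarioConfig) -> RegionMap:
    return {"alpha": alpha_synuclein_regions, "beta": beta_synuclein_regions}[
        config.visible_species
    ]()


def invisible_region_map(config: ScenarioConfig) -> RegionMap:
    return {"alpha": alpha_synuclein_regions, "beta": beta_synuclein_regions}[
        config.invisible_species
    ]()
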