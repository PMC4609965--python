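"""Inter-chain PRE rates, significance filtering, contact maps and regions.

The PRE rate Gamma2 of a residue is the difference between its amide-proton
R2 in the paramagnetic sample (spin-labelled invisible chain present) and in
the diamagnetic control (label reduced).  A residue is only considered a
significant contact when three conditions hold simultaneously on its strip:
Gamma2 at least twice the strip mean, above the third quartile, and at least
8 s^-1.  Strips from several spin-label sites assemble into a contact map
over the visible chain, annotated with the N / NAC / C-terminal regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from .relaxation import RelaxationProfile, SampleInfo

__all__ = [
    "PREEntry",
    "PREProfile",
    "RegionMap",
    "ContactMap",
    "compute_pre",
    "significance_mask",
    "significance_filter",
    "build_contact_map",
    "align_sequences",
    "region_summary",
    "alpha_synuclein_regions",
    "beta_synuclein_regions",
    "packaged_sequence",
]

SIGNIFICANCE_FLOOR = 8.0  # s^-1
STRONG_CONTACT = 12.0  # s^-1, saturates the top colour bin


@dataclass(frozen=True)
class PREEntry:
    gamma2: float
    gamma2_error: float
    significant: bool = False


@dataclass
class PREProfile:
    """Per-residue Gamma2 for one (spin-label site, visible chain) strip."""

    residues: dict[int, PREEntry]
    sample: SampleInfo

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def spin_label_site(self) -> int:
        assert self.sample.spin_label_site is not None
        return self.sample.spin_label_site

    def residue_indices(self) -> list[int]:
        return sorted(self.residues)

    def gamma2_vector(self) -> tuple[np.ndarray, np.ndarray]:
        idx = np.array(self.residue_indices(), dtype=int)
        vals = np.array([self.residues[i].gamma2 for i in idx], dtype=float)
        return idx, vals

    def significant_set(self) -> set[int]:
        return {i for i, e in self.residues.items() if e.significant}


def significance_mask(gamma2: np.ndarray, floor: float = SIGNIFICANCE_FLOOR) -> np.ndarray:
    """Three-clause contact filter on one strip's Gamma2 vector.

    A residue passes iff gamma2 >= 2 * mean, gamma2 > Q3 and gamma2 >= floor,
    where mean and Q3 (linear-interpolation quartile) are taken over all
    fitted residues of the strip.
    """
    g = np.asarray(gamma2, dtype=float)
    if g.size < 4:
        raise ValueError("significance filter needs at least 4 residues")
    mean = g.mean()
    q3 = np.percentile(g, 75)
    return (g >= 2.0 * mean) & (g > q3) & (g >= floor)


def significance_filter(profile: PREProfile, floor: float = SIGNIFICANCE_FLOOR) -> dict[int, bool]:
    """Apply :func:`significance_mask` to a profile; returns residue -> passes."""
    idx, vals = profile.gamma2_vector()
    mask = significance_mask(vals, floor=floor)
    return {int(i): bool(m) for i, m in zip(idx, mask)}


def compute_pre(
    para: RelaxationProfile,
    dia: RelaxationProfile,
    floor: float = SIGNIFICANCE_FLOOR,
) -> PREProfile:
    """Gamma2 = R2(para) - R2(dia) residue-wise, with quadrature errors.

    Both profiles must describe the same visible species, spin-label site and
    titration point.  Residues missing from either arm are absent from the
    result.  The significance filter runs automatically when at least four
    residues are shared; with fewer, all residues are marked not significant.
    """
    if para.sample is None or dia.sample is None:
        raise ValueError("both profiles need sample metadata to be paired")
    if not para.sample.matches(dia.sample):
        raise ValueError(
            f"sample metadata mismatch: {para.sample} vs {dia.sample}"
        )
    shared = sorted(set(para.residues) & set(dia.residues))
    if not shared:
        raise ValueError("no residue was fitted in both the para and dia samples")
    entries = {}
    for i in shared:
        p, d = para.residues[i], dia.residues[i]
        entries[i] = PREEntry(
            gamma2=p.r2 - d.r2,
            gamma2_error=float(np.hypot(p.r2_error, d.r2_error)),
        )
    profile = PREProfile(residues=entries, sample=para.sample)
    if len(shared) >= 4:
        sig = significance_filter(profile, floor=floor)
        profile.residues = {
            i: PREEntry(e.gamma2, e.gamma2_error, sig[i]) for i, e in entries.items()
        }
    return profile


# ---------------------------------------------------------------------------
# regions and sequences


@dataclass
class RegionMap:
    """Named 1-based inclusive intervals over the visible-chain sequence."""

    sequence: str
    regions: dict[str, tuple[int, int]]
    hot_spot: tuple[int, int] | None = None
    mtsl_sites: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for name, (a, b) in self.regions.items():
            if not (1 <= a <= b <= n):
                raise ValueError(f"region {name} [{a},{b}] outside sequence 1..{n}")
        core = [self.regions[k] for k in ("N", "NAC", "C") if k in self.regions]
        if len(core) == 3:
            covered = sorted(core)
            spans = []
            for a, b in covered:
                spans.extend(range(a, b + 1))
            if sorted(spans) != list(range(1, n + 1)):
                raise ValueError("N, NAC and C regions must tile the sequence without overlap")
        if self.hot_spot is not None and "N" in self.regions:
            a, b = self.hot_spot
            na, nb = self.regions["N"]
            if not (na <= a <= b <= nb):
                raise ValueError("hot spot must lie inside the N-terminal region")

    def region_of(self, residue: int) -> str | None:
        for name in ("N", "NAC", "C"):
            if name in self.regions:
                a, b = self.regions[name]
                if a <= residue <= b:
                    return name
        return None


def packaged_sequence(species: str) -> str:
    """Canonical human sequence shipped with the package ('alpha' or 'beta')."""
    fname = {"alpha": "alpha_synuclein.fasta", "beta": "beta_synuclein.fasta"}[species]
    with resources.files("prekit.data").joinpath(fname).open() as fh:
        record = next(SeqIO.parse(fh, "fasta"))
    return str(record.seq)


def alpha_synuclein_regions() -> RegionMap:
    """Standard alpha-synuclein boundaries: N 1-60, NAC 61-95, C 96-140."""
    return RegionMap(
        sequence=packaged_sequence("alpha"),
        regions={"N": (1, 60), "NAC": (61, 95), "C": (96, 140)},
        hot_spot=(38, 45),
        mtsl_sites=[11, 44, 90, 132],
    )


def beta_synuclein_regions() -> RegionMap:
    """Standard beta-synuclein boundaries: N 1-60, NAC 61-84, C 85-134."""
    return RegionMap(
        sequence=packaged_sequence("beta"),
        regions={"N": (1, 60), "NAC": (61, 84), "C": (85, 134)},
        mtsl_sites=[11, 44, 80, 134],
    )


REGION_MAPS = {"alpha": alpha_synuclein_regions, "beta": beta_synuclein_regions}


# ---------------------------------------------------------------------------
# contact maps


@dataclass
class ContactMap:
    """Ordered strips of PRE profiles over one visible chain.

    Strips are ordered by spin-label site ascending.  Binned rendering is a
    pure function of the stored Gamma2 values: negatives clamp to zero and
    values above 12 s^-1 saturate the top colour bin.
    """

    strips: list[PREProfile]
    regions: RegionMap

    def __post_init__(self) -> None:
        if not self.strips:
            raise ValueError("a contact map needs at least one strip")
        species = {s.sample.visible_species for s in self.strips}
        if len(species) != 1:
            raise ValueError(f"inconsistent visible species across strips: {species}")
        self.strips = sorted(self.strips, key=lambda s: s.spin_label_site)

    @property
    def sequence_length(self) -> int:
        return len(self.regions.sequence)

    @property
    def sites(self) -> list[int]:
        return [s.spin_label_site for s in self.strips]

    def significant_sets(self) -> dict[int, set[int]]:
        return {s.spin_label_site: s.significant_set() for s in self.strips}

    def matrix(self) -> np.ndarray:
        """Raw Gamma2 matrix (n_strips x sequence_length); absent residues NaN."""
        m = np.full((len(self.strips), self.sequence_length), np.nan)
        for row, strip in enumerate(self.strips):
            for i, e in strip.residues.items():
                m[row, i - 1] = e.gamma2
        return m

    def binned(self, edges: Iterable[float] = (2, 4, 6, 8, 10, 12)) -> np.ndarray:
        """Colour-bin indices: 0 for <= first edge after clamping at 0, top bin
        (len(edges)) for values above the last edge (> 12 s^-1 by default)."""
        edges = np.asarray(list(edges), float)
        m = self.matrix()
        clamped = np.clip(m, 0.0, None)
        out = np.full(m.shape, np.nan)
        ok = np.isfinite(m)
        out[ok] = np.searchsorted(edges, clamped[ok], side="left")
        return out

    def long_table(self) -> pd.DataFrame:
        rows = []
        for strip in self.strips:
            for i in strip.residue_indices():
                e = strip.residues[i]
                rows.append(
                    dict(
                        spin_label_site=strip.spin_label_site,
                        visible_species=strip.sample.visible_species,
                        residue_index=i,
                        gamma2=e.gamma2,
                        gamma2_error=e.gamma2_error,
                        significant=e.significant,
                    )
                )
        return pd.DataFrame(rows)


def build_contact_map(profiles: Iterable[PREProfile], regions: RegionMap) -> ContactMap:
    """Assemble strips (ordered by spin-label site) into a contact map."""
    return ContactMap(strips=list(profiles), regions=regions)


# ---------------------------------------------------------------------------
# sequence alignment


def align_sequences(seq_a: str, seq_b: str) -> dict[int, int]:
    """Global affine-gap alignment; partial 1-based index map a -> b.

    Uses BLOSUM62 with gap open -10 / extend -0.5.  Positions of ``seq_a``
    aligned to a gap are absent from the mapping.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    alignment = aligner.align(seq_a, seq_b)[0]
    mapping: dict[int, int] = {}
    for (a_start, a_end), (b_start, b_end) in zip(*alignment.aligned):
        for offset in range(a_end - a_start):
            mapping[a_start + offset + 1] = b_start + offset + 1
    return mapping


# ---------------------------------------------------------------------------
# per-region summaries and dimer topology


def _has_contiguous_run(residues: set[int], interval: tuple[int, int], min_run: int) -> bool:
    a, b = interval
    run = 0
    for i in range(a, b + 1):
        run = run + 1 if i in residues else 0
        if run >= min_run:
            return True
    return False


def region_summary(
    cmap: ContactMap,
    invisible_regions: RegionMap | None = None,
    min_run: int = 3,
) -> tuple[pd.DataFrame, set[str]]:
    """Per-(strip, region) significant-contact summary and dimer topology.

    A (strip, region) pair counts as interacting when the region contains at
    least ``min_run`` contiguous significant residues (guards against isolated
    single-residue passes).  Topology is read off the N-terminal probes: an
    N-probe contacting the N-terminal region is a head-to-head arrangement;
    an N-probe contacting the C-terminal region is head-to-tail.  The probe's
    region is evaluated on the invisible (spin-labelled) chain, which defaults
    to the visible chain's region map for homo-complexes.
    """
    probe_regions = invisible_regions if invisible_regions is not None else cmap.regions
    rows = []
    topologies: set[str] = set()
    for strip in cmap.strips:
        site = strip.spin_label_site
        sig = strip.significant_set()
        probe_region = probe_regions.region_of(site)
        for name, interval in cmap.regions.regions.items():
            a, b = interval
            in_region = {i for i in sig if a <= i <= b}
            vals = [strip.residues[i].gamma2 for i in in_region]
            interacting = _has_contiguous_run(sig, interval, min_run)
            rows.append(
                dict(
                    spin_label_site=site,
                    probe_region=probe_region,
                    region=name,
                    n_significant=len(in_region),
                    mean_gamma2=float(np.mean(vals)) if vals else 0.0,
                    max_gamma2=float(np.max(vals)) if vals else 0.0,
                    interacting=interacting,
                )
            )
            if interacting and probe_region == "N":
                if name == "N":
                    topologies.add("head-to-head")
                elif name == "C":
                    topologies.add("head-to-tail")
    return pd.DataFrame(rows), topologies
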