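"""Readers and writers for the pipeline's plain-text table formats.

Peak-intensity tables are TSV with one row per residue: a ``residue`` column
followed by one intensity column per delay.  The delay schedule is declared in
a ``# delays_s:`` header line (or passed explicitly).  A Sparky-style
peak-list reader (assignment string parsed to a residue index) is supported as
an alternate dialect, one file per delay.

All residue numbering is 1-based, matching the supplied sequence; missing
residues are absent rows, never sentinel zeros.  Writers use a fixed numeric
format so identical inputs produce byte-identical tables.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO

from .pre import PREEntry, PREProfile
from .relaxation import PeakSeries, R2Fit, RelaxationProfile, SampleInfo

__all__ = [
    "write_peak_table",
    "read_peak_table",
    "read_sparky_peaklist",
    "series_from_sparky",
    "write_relaxation_profile",
    "read_relaxation_profile",
    "write_pre_profile",
    "read_pre_profile",
    "read_fasta",
]

FLOAT_FMT = "%.10g"


def _fmt(v: float) -> str:
    return FLOAT_FMT % v


def write_peak_table(path: str | Path, series: Iterable[PeakSeries]) -> None:
    series = list(series)
    if not series:
        raise ValueError("nothing to write")
    delays = series[0].delays
    lines = ["# delays_s: " + " ".join(_fmt(t) for t in delays)]
    lines.append("residue\t" + "\t".join(f"I{k + 1}" for k in range(delays.size)))
    for s in sorted(series, key=lambda s: s.residue_index):
        if s.delays.shape != delays.shape or np.any(s.delays != delays):
            raise ValueError("all series in one table must share the delay schedule")
        lines.append(str(s.residue_index) + "\t" + "\t".join(_fmt(v) for v in s.intensities))
    Path(path).write_text("\n".join(lines) + "\n")


def read_peak_table(
    path: str | Path, delays: Iterable[float] | None = None, sample_label: str = ""
) -> list[PeakSeries]:
    """Parse a peak-intensity table; malformed rows raise with file and line."""
    path = Path(path)
    text = path.read_text().splitlines()
    header_delays = None
    rows: list[tuple[int, str]] = []
    for lineno, line in enumerate(text, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            m = re.match(r"#\s*delays_s:\s*(.+)", stripped)
            if m:
                header_delays = [float(v) for v in m.group(1).split()]
            continue
        if stripped.lower().startswith("residue"):
            continue
        rows.append((lineno, stripped))
    if delays is None:
        delays = header_delays
    if delays is None:
        raise ValueError(f"{path}: no '# delays_s:' header and no delays supplied")
    delays = np.asarray(list(delays), float)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    series = []
    for lineno, line in rows:
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) != delays.size + 1:
            raise ValueError(
                f"{path}: line {lineno}: expected {delays.size + 1} columns, got {len(fields)}"
            )
        try:
            residue = int(fields[0])
            intensities = np.array([float(v) for v in fields[1:]])
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: non-numeric value ({exc})") from None
        series.append(
            PeakSeries(residue, delays.copy(), intensities, sample_label=sample_label)
        )
    return series


_SPARKY_ASSIGNMENT = re.compile(r"^[A-Za-z]{0,3}(\d+)")


def read_sparky_peaklist(path: str | Path) -> dict[int, float]:
    """Sparky peak-list export: assignment column plus a data-height column.

    Accepts assignments like ``A11N-H``, ``T44HN`` or bare ``44N-H``; the last
    numeric column of each row is taken as the peak height.
    """
    path = Path(path)
    heights: dict[int, float] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.lower().startswith(("assignment", "#")):
            continue
        fields = stripped.split()
        m = _SPARKY_ASSIGNMENT.match(fields[0])
        if m is None:
            raise ValueError(f"{path}: line {lineno}: cannot parse assignment {fields[0]!r}")
        try:
            heights[int(m.group(1))] = float(fields[-1])
        except ValueError:
            raise ValueError(f"{path}: line {lineno}: non-numeric height") from None
    return heights


def series_from_sparky(
    files: Iterable[tuple[float, str | Path]], sample_label: str = ""
) -> list[PeakSeries]:
    """Assemble per-residue decay series from (delay, peak-list path) pairs."""
    files = list(files)
    if not files:
        raise ValueError("no peak-list files supplied")
    per_delay = [(t, read_sparky_peaklist(p)) for t, p in files]
    residues = set.intersection(*(set(h) for _, h in per_delay))
    delays = np.array([t for t, _ in per_delay])
    return [
        PeakSeries(
            r, delays.copy(), np.array([h[r] for _, h in per_delay]), sample_label
        )
        for r in sorted(residues)
    ]


# ---------------------------------------------------------------------------
# fitted profiles

_META_KEYS = ("visible_species", "invisible_species", "spin_label_site", "arm", "ratio")


def _meta_header(sample: SampleInfo | None, noise: float | None = None) -> list[str]:
    lines = []
    if sample is not None:
        for key in _META_KEYS:
            val = getattr(sample, key)
            if val is not None:
                lines.append(f"# {key}: {val}")
    if noise is not None:
        lines.append(f"# noise: {_fmt(noise)}")
    return lines


def _parse_meta(text: list[str]) -> tuple[SampleInfo | None, float | None]:
    meta: dict[str, str] = {}
    for line in text:
        m = re.match(r"#\s*(\w+):\s*(.+)", line)
        if m:
            meta[m.group(1)] = m.group(2).strip()
    noise = float(meta["noise"]) if "noise" in meta else None
    if "visible_species" in meta:
        sample = SampleInfo(
            visible_species=meta["visible_species"],
            invisible_species=meta.get("invisible_species"),
            spin_label_site=int(meta["spin_label_site"]) if "spin_label_site" in meta else None,
            arm=meta.get("arm"),
            ratio=float(meta["ratio"]) if "ratio" in meta else None,
        )
    else:
        sample = None
    return sample, noise


def write_relaxation_profile(path: str | Path, profile: RelaxationProfile) -> None:
    lines = _meta_header(profile.sample, profile.noise)
    lines.append("residue\tr2\tr2_error\tamplitude\tfit_quality")
    for i in profile.residue_indices():
        f = profile.residues[i]
        lines.append(
            "\t".join([str(i), _fmt(f.r2), _fmt(f.r2_error), _fmt(f.amplitude), _fmt(f.fit_quality)])
        )
    for i in sorted(profile.failures):
        lines.append(f"# failed\t{i}\t{profile.failures[i]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_relaxation_profile(path: str | Path) -> RelaxationProfile:
    path = Path(path)
    text = path.read_text().splitlines()
    sample, noise = _parse_meta(text)
    residues: dict[int, R2Fit] = {}
    failures: dict[int, str] = {}
    for lineno, line in enumerate(text, start=1):
        stripped = line.strip()
        if stripped.startswith("# failed"):
            _, idx, reason = stripped.split("\t", 2)
            failures[int(idx)] = reason
            continue
        if not stripped or stripped.startswith(("#", "residue")):
            continue
        fields = stripped.split("\t")
        if len(fields) != 5:
            raise ValueError(f"{path}: line {lineno}: expected 5 columns")
        residues[int(fields[0])] = R2Fit(
            r2=float(fields[1]), r2_error=float(fields[2]),
            amplitude=float(fields[3]), fit_quality=float(fields[4]),
        )
    return RelaxationProfile(
        residues=residues, noise=noise if noise is not None else 0.0,
        sample=sample, failures=failures,
    )


def write_pre_profile(path: str | Path, profile: PREProfile) -> None:
    lines = _meta_header(profile.sample)
    lines.append("residue\tgamma2\tgamma2_error\tsignificant")
    for i in profile.residue_indices():
        e = profile.residues[i]
        lines.append(
            "\t".join([str(i), _fmt(e.gamma2), _fmt(e.gamma2_error), str(int(e.significant))])
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_pre_profile(path: str | Path) -> PREProfile:
    path = Path(path)
    text = path.read_text().splitlines()
    sample, _ = _parse_meta(text)
    if sample is None:
        raise ValueError(f"{path}: missing sample metadata header")
    residues: dict[int, PREEntry] = {}
    for lineno, line in enumerate(text, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith(("#", "residue")):
            continue
        fields = stripped.split("\t")
        if len(fields) != 4:
            raise ValueError(f"{path}: line {lineno}: expected 4 columns")
        residues[int(fields[0])] = PREEntry(
            gamma2=float(fields[1]), gamma2_error=float(fields[2]),
            significant=bool(int(fields[3])),
        )
    return PREProfile(residues=residues, sample=sample)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
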