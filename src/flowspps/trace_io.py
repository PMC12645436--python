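"""Readers and writers for every file format the pipeline touches.

All interchange is plain CSV (UTF-8, ``.``-decimal, explicit dialects —
never sniffed), FASTA for sequences and JSON for ground truth / reports.
Readers validate and reject malformed input instead of coercing it;
every writer→reader round trip is lossless to at least 1e-12 on values.

The UV deprotection channel is recorded at 310 nm (released fluorenyl
chromophore); UHPLC chromatograms at 214 nm (amide backbone).  Residue
labels follow parent-protein numbering as printed (e.g. ``"T86"``,
``"L89"``) while ``cycle_index`` follows synthesis (C→N) order — the two
are decoupled on purpose: the first synthesized residue of a [75–90]
fragment is residue 90.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .exceptions import FormatError, ScheduleError, TraceError

__all__ = [
    "UVTrace",
    "CycleSchedule",
    "CycleWindow",
    "Chromatogram",
    "read_uv_trace",
    "write_uv_trace",
    "read_cycle_schedule",
    "write_cycle_schedule",
    "read_chromatogram",
    "write_chromatogram",
    "read_peak_table",
    "write_peak_table",
    "read_fasta",
    "write_fasta",
]

#: float format used by all CSV writers; 17 significant digits round-trip
#: IEEE doubles exactly.
_FLOAT_FMT = "%.17g"

_MIN_SAMPLES = 10


def _check_axis(time: np.ndarray, values: np.ndarray, what: str) -> None:
    if time.ndim != 1 or values.ndim != 1 or len(time) != len(values):
        raise TraceError(f"{what}: time and absorbance must be 1-D and equal length")
    if len(time) < _MIN_SAMPLES:
        raise TraceError(f"{what} too short: {len(time)} samples < {_MIN_SAMPLES}")
    if not np.all(np.diff(time) > 0):
        raise TraceError("non-monotone time axis")
    if not (np.all(np.isfinite(time)) and np.all(np.isfinite(values))):
        raise TraceError(f"{what}: non-finite values")


@dataclass(frozen=True)
class UVTrace:
    """A sampled absorbance-vs-time series from one synthesis run.

    Parameters
    ----------
    time_s : ndarray
        Strictly increasing sample times in seconds.
    absorbance_au : ndarray
        Absorbance in AU, same length as ``time_s``.
    wavelength_nm : float
        Detection wavelength; 310 nm is the Fmoc-deprotection channel.
    run_id : str
        Free-text run identifier, preserved through CSV round trips.
    """

    time_s: np.ndarray
    absorbance_au: np.ndarray
    wavelength_nm: float = 310.0
    run_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        a = np.asarray(self.absorbance_au, dtype=float)
        _check_axis(t, a, "trace")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "absorbance_au", a)

    def __len__(self) -> int:
        return len(self.time_s)

    def slice(self, start_s: float, end_s: float) -> tuple[np.ndarray, np.ndarray]:
        """Return the (time, absorbance) samples with start_s <= t < end_s."""
        sel = (self.time_s >= start_s) & (self.time_s < end_s)
        return self.time_s[sel], self.absorbance_au[sel]


@dataclass(frozen=True)
class Chromatogram:
    """A UHPLC absorbance trace; time in minutes, default 214 nm."""

    time_min: np.ndarray
    absorbance_au: np.ndarray
    wavelength_nm: float = 214.0
    sample_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, dtype=float)
        a = np.asarray(self.absorbance_au, dtype=float)
        _check_axis(t, a, "chromatogram")
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "absorbance_au", a)

    def __len__(self) -> int:
        return len(self.time_min)


@dataclass(frozen=True)
class CycleWindow:
    residue_label: str
    cycle_index: int
    start_s: float
    end_s: float


@dataclass(frozen=True)
class CycleSchedule:
    """Ordered mapping of trace time windows to residues in synthesis order."""

    windows: tuple[CycleWindow, ...]

    def __post_init__(self) -> None:
        wins = tuple(sorted(self.windows, key=lambda w: w.cycle_index))
        if not wins:
            raise ScheduleError("empty schedule")
        for i, w in enumerate(wins):
            if w.cycle_index != i:
                raise ScheduleError(
                    f"cycle_index not contiguous from 0 (got {w.cycle_index} at position {i})"
                )
            if not w.start_s < w.end_s:
                raise ScheduleError(f"window {w.residue_label}: start >= end")
        for a, b in zip(wins, wins[1:]):
            if b.start_s < a.end_s:
                raise ScheduleError(
                    f"overlapping windows: {a.residue_label} and {b.residue_label}"
                )
        object.__setattr__(self, "windows", wins)

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    @property
    def labels(self) -> list[str]:
        return [w.residue_label for w in self.windows]


def _read_csv(path: str | Path, required: Sequence[str], what: str) -> tuple[pd.DataFrame, dict]:
    """Read a commented CSV; return the frame and ``# key = value`` metadata."""
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise FormatError(f"format error reading {what} {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"format error: {what} {path} missing column(s) {', '.join(missing)}"
        )
    return df, meta


def read_uv_trace(path: str | Path) -> UVTrace:
    """Read a deprotection UV trace CSV (columns ``time_s,absorbance_au``).

    ``#``-prefixed comment lines are allowed; ``# key = value`` comments
    carrying ``run_id`` and ``wavelength_nm`` are restored as metadata.
    Extra columns are ignored.
    """
    df, meta = _read_csv(path, ["time_s", "absorbance_au"], "trace")
    if len(df) < _MIN_SAMPLES:
        raise TraceError(f"trace too short: {len(df)} samples < {_MIN_SAMPLES}")
    return UVTrace(
        time_s=df["time_s"].to_numpy(float),
        absorbance_au=df["absorbance_au"].to_numpy(float),
        wavelength_nm=float(meta.get("wavelength_nm", 310.0)),
        run_id=meta.get("run_id", ""),
    )


def write_uv_trace(trace: UVTrace, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# run_id = {trace.run_id}\n")
        fh.write(f"# wavelength_nm = {_FLOAT_FMT % trace.wavelength_nm}\n")
        pd.DataFrame(
            {"time_s": trace.time_s, "absorbance_au": trace.absorbance_au}
        ).to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_chromatogram(path: str | Path) -> Chromatogram:
    """Read a UHPLC chromatogram CSV (columns ``time_min,absorbance_au``)."""
    df, meta = _read_csv(path, ["time_min", "absorbance_au"], "chromatogram")
    if len(df) < _MIN_SAMPLES:
        raise TraceError(f"chromatogram too short: {len(df)} samples < {_MIN_SAMPLES}")
    return Chromatogram(
        time_min=df["time_min"].to_numpy(float),
        absorbance_au=df["absorbance_au"].to_numpy(float),
        wavelength_nm=float(meta.get("wavelength_nm", 214.0)),
        sample_id=meta.get("sample_id", ""),
    )


def write_chromatogram(chrom: Chromatogram, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# sample_id = {chrom.sample_id}\n")
        fh.write(f"# wavelength_nm = {_FLOAT_FMT % chrom.wavelength_nm}\n")
        pd.DataFrame(
            {"time_min": chrom.time_min, "absorbance_au": chrom.absorbance_au}
        ).to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_cycle_schedule(path: str | Path) -> CycleSchedule:
    """Read a cycle schedule CSV (``residue_label,cycle_index,start_s,end_s``)."""
    df, _ = _read_csv(
        path, ["residue_label", "cycle_index", "start_s", "end_s"], "schedule"
    )
    windows = tuple(
        CycleWindow(
            residue_label=str(r.residue_label),
            cycle_index=int(r.cycle_index),
            start_s=float(r.start_s),
            end_s=float(r.end_s),
        )
        for r in df.itertuples()
    )
    return CycleSchedule(windows)


def write_cycle_schedule(schedule: CycleSchedule, path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(w) for w in schedule.windows]).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


_PEAK_COLUMNS = [
    "residue_label",
    "cycle_index",
    "apex_time_s",
    "height_au",
    "fwhm_s",
    "area_au_s",
    "flags",
]


def write_peak_table(peaks: Iterable, path: str | Path) -> None:
    """Write per-residue :class:`~flowspps.peak_analysis.DeprotectionPeak`
    records to CSV.  Flags are ``;``-joined in a single column."""
    rows = []
    for p in peaks:
        rows.append(
            {
                "residue_label": p.residue_label,
                "cycle_index": p.cycle_index,
                "apex_time_s": p.apex_time_s,
                "height_au": p.height_au,
                "fwhm_s": p.fwhm_s,
                "area_au_s": p.area_au_s,
                "flags": ";".join(sorted(p.flags)),
            }
        )
    pd.DataFrame(rows, columns=_PEAK_COLUMNS).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_peak_table(path: str | Path) -> list:
    from .peak_analysis import DeprotectionPeak

    df, _ = _read_csv(path, _PEAK_COLUMNS, "peak table")
    peaks = []
    for r in df.itertuples():
        flags = frozenset() if pd.isna(r.flags) or r.flags == "" else frozenset(str(r.flags).split(";"))
        peaks.append(
            DeprotectionPeak(
                residue_label=str(r.residue_label),
                cycle_index=int(r.cycle_index),
                apex_time_s=float(r.apex_time_s),
                height_au=float(r.height_au),
                fwhm_s=float(r.fwhm_s),
                area_au_s=float(r.area_au_s),
                flags=flags,
            )
        )
    return peaks


def read_fasta(path: str | Path, c_terminus: str = "acid") -> list:
    """Read peptide sequences from FASTA, validating the canonical alphabet.

    Returns a list of :class:`~flowspps.peptide_mass.PeptideSequence`.
    Non-canonical letters raise a :class:`FormatError` naming the offenders.
    """
    from .peptide_mass import parse_sequence
    from .exceptions import SequenceError

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"format error: no FASTA records in {path}")
    out = []
    for rec in records:
        try:
            out.append(parse_sequence(str(rec.seq), c_terminus=c_terminus, label=rec.id))
        except SequenceError as exc:
            raise FormatError(f"invalid FASTA record {rec.id}: {exc}") from exc
    return out


def write_fasta(sequences: Iterable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for seq in sequences:
            fh.write(f">{seq.label or 'peptide'}\n{seq.residues}\n")
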