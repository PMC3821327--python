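"""Readers and writers for the on-disk dialects used throughout the package.

All formats are plain text (CSV/TSV/JSON) with explicit axis headers, so that
files remain inspectable and diffable.  Readers validate shapes strictly and
raise :class:`FormatError` rather than silently truncating or padding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "FormatError",
    "GroupLabel",
    "FaimsScan",
    "EnoseRecord",
    "GcmsEntry",
    "GcmsPeakTable",
    "ManifestEntry",
    "N_DF_LINES",
    "N_CV_STEPS",
    "N_SENSORS",
    "N_TIME_SAMPLES",
    "default_df_axis",
    "default_cv_axis",
    "read_faims_scan",
    "write_faims_scan",
    "read_enose_record",
    "write_enose_record",
    "read_gcms_table",
    "write_gcms_table",
    "read_manifest",
    "write_manifest",
]

#: instrument geometry: dispersion-field lines per polarity scan
N_DF_LINES = 51
#: instrument geometry: compensation-voltage steps per dispersion-field line
N_CV_STEPS = 512
#: e-nose sensor-array size
N_SENSORS = 18
#: e-nose trace length (1 Hz for 180 s)
N_TIME_SAMPLES = 180

BASE_PEAK_INTENSITY = 999.0


class FormatError(ValueError):
    """Raised when an on-disk file violates its declared dialect."""


class GroupLabel(str, Enum):
    """Study arm of a subject."""

    BAD = "BAD"
    UC = "UC"
    CONTROL = "CONTROL"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def default_df_axis() -> np.ndarray:
    """Dispersion-field axis: 51 equal settings from 0 to 90 %."""
    return np.linspace(0.0, 90.0, N_DF_LINES)


def default_cv_axis() -> np.ndarray:
    """Compensation-voltage axis: +6 V down to -6 V in 512 steps."""
    return np.linspace(6.0, -6.0, N_CV_STEPS)


@dataclass
class FaimsScan:
    """One urine-sample FAIMS measurement: two polarity matrices plus axes.

    Each matrix is indexed ``[df_line, cv_step]`` and holds ion current in
    arbitrary units.
    """

    positive: np.ndarray
    negative: np.ndarray
    df_percent_axis: np.ndarray = field(default_factory=default_df_axis)
    cv_volts_axis: np.ndarray = field(default_factory=default_cv_axis)
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.positive = np.asarray(self.positive, dtype=float)
        self.negative = np.asarray(self.negative, dtype=float)
        self.df_percent_axis = np.asarray(self.df_percent_axis, dtype=float)
        self.cv_volts_axis = np.asarray(self.cv_volts_axis, dtype=float)
        shape = (N_DF_LINES, N_CV_STEPS)
        for name, mat in (("positive", self.positive), ("negative", self.negative)):
            if mat.shape != shape:
                raise FormatError(
                    f"{name} matrix has shape {mat.shape}; expected "
                    f"{N_DF_LINES} x {N_CV_STEPS}"
                )
            if not np.all(np.isfinite(mat)):
                raise FormatError(f"{name} matrix contains non-finite values")
        if self.df_percent_axis.shape != (N_DF_LINES,):
            raise FormatError(f"df axis must have {N_DF_LINES} entries")
        if self.cv_volts_axis.shape != (N_CV_STEPS,):
            raise FormatError(f"cv axis must have {N_CV_STEPS} entries")
        d_df = np.diff(self.df_percent_axis)
        d_cv = np.diff(self.cv_volts_axis)
        if not (np.all(d_df > 0) or np.all(d_df < 0)):
            raise FormatError("df axis must be strictly monotone")
        if not (np.all(d_cv > 0) or np.all(d_cv < 0)):
            raise FormatError("cv axis must be strictly monotone")


@dataclass
class EnoseRecord:
    """One e-nose injection: 18 resistance traces plus pre-injection baselines."""

    resistances: np.ndarray
    baseline: np.ndarray
    sample_id: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        self.resistances = np.asarray(self.resistances, dtype=float)
        self.baseline = np.asarray(self.baseline, dtype=float)
        if self.resistances.shape != (N_SENSORS, N_TIME_SAMPLES):
            raise FormatError(
                f"resistance matrix has shape {self.resistances.shape}; expected "
                f"{N_SENSORS} x {N_TIME_SAMPLES}"
            )
        if self.baseline.shape != (N_SENSORS,):
            raise FormatError(f"baseline must have {N_SENSORS} entries")
        if not np.all(np.isfinite(self.baseline)) or np.any(self.baseline <= 0):
            raise FormatError("baselines must be finite and > 0")
        if not np.all(np.isfinite(self.resistances)):
            raise FormatError("resistance traces contain non-finite values")


@dataclass
class GcmsEntry:
    """One chromatographic peak: retention time plus its mass spectrum."""

    retention_time: float
    spectrum: dict[int, float]
    identification: Optional[str] = None

    def __post_init__(self) -> None:
        if self.retention_time < 0:
            raise FormatError("retention time must be >= 0")
        for mz, intensity in self.spectrum.items():
            if int(mz) <= 0:
                raise FormatError(f"m/z must be a positive integer, got {mz}")
            if intensity < 0:
                raise FormatError(f"intensity must be >= 0, got {intensity} at m/z {mz}")

    def base_peak(self) -> int:
        """m/z of the most intense ion."""
        if not self.spectrum:
            raise ValueError("empty spectrum has no base peak")
        return max(self.spectrum, key=lambda mz: (self.spectrum[mz], -mz))


@dataclass
class GcmsPeakTable:
    """List of GC-MS peaks for one sample, sorted by retention time.

    Spectra are base-peak normalized: the most intense ion of every nonempty
    spectrum reads 999.
    """

    entries: list[GcmsEntry] = field(default_factory=list)
    sample_id: str = ""

    def normalized(self) -> "GcmsPeakTable":
        """Return a copy with every spectrum rescaled so its base peak is 999."""
        out = []
        for e in self.entries:
            if e.spectrum:
                top = max(e.spectrum.values())
                if top <= 0:
                    raise FormatError("spectrum with no positive intensity")
                scale = BASE_PEAK_INTENSITY / top
                spec = {mz: v * scale for mz, v in e.spectrum.items()}
            else:
                spec = {}
            out.append(GcmsEntry(e.retention_time, spec, e.identification))
        out.sort(key=lambda e: e.retention_time)
        return GcmsPeakTable(entries=out, sample_id=self.sample_id)


@dataclass
class ManifestEntry:
    sample_id: str
    group: GroupLabel
    faims_path: Optional[str] = None
    enose_paths: list[str] = field(default_factory=list)
    gcms_path: Optional[str] = None


# ---------------------------------------------------------------------------
# FAIMS scan CSV
# ---------------------------------------------------------------------------

def _fmt_row(values: np.ndarray) -> str:
    # repr round-trips doubles exactly through float()
    return ",".join(repr(float(v)) for v in values)


def _parse_row(line: str, path: Path, lineno: int, expected: int) -> np.ndarray:
    cells = line.split(",")
    if len(cells) != expected:
        raise FormatError(
            f"{path}:{lineno}: row has {len(cells)} columns; expected {expected}"
        )
    out = np.empty(len(cells))
    for j, cell in enumerate(cells):
        try:
            out[j] = float(cell)
        except ValueError:
            raise FormatError(
                f"{path}:{lineno}: non-numeric cell at column {j + 1}: {cell!r}"
            ) from None
    return out


def write_faims_scan(scan: FaimsScan, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# sample_id: {scan.sample_id}\n")
        fh.write(f"# df_axis: {_fmt_row(scan.df_percent_axis)}\n")
        fh.write(f"# cv_axis: {_fmt_row(scan.cv_volts_axis)}\n")
        for name, mat in (("POSITIVE", scan.positive), ("NEGATIVE", scan.negative)):
            fh.write(f"# {name}\n")
            for row in mat:
                fh.write(_fmt_row(row) + "\n")


def read_faims_scan(path: str | Path) -> FaimsScan:
    path = Path(path)
    sample_id = ""
    df_axis = None
    cv_axis = None
    blocks: dict[str, list[np.ndarray]] = {}
    current: Optional[str] = None
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                header = line[1:].strip()
                if header.startswith("sample_id:"):
                    sample_id = header.split(":", 1)[1].strip()
                elif header.startswith("df_axis:"):
                    df_axis = _parse_row(
                        header.split(":", 1)[1].strip(), path, lineno, N_DF_LINES
                    )
                elif header.startswith("cv_axis:"):
                    cv_axis = _parse_row(
                        header.split(":", 1)[1].strip(), path, lineno, N_CV_STEPS
                    )
                elif header in ("POSITIVE", "NEGATIVE"):
                    current = header
                    blocks[current] = []
                else:
                    raise FormatError(f"{path}:{lineno}: unknown header {header!r}")
                continue
            if current is None:
                raise FormatError(f"{path}:{lineno}: data row before a polarity header")
            blocks[current].append(_parse_row(line, path, lineno, N_CV_STEPS))
    for name in ("POSITIVE", "NEGATIVE"):
        if name not in blocks:
            raise FormatError(f"{path}: missing {name} block")
        if len(blocks[name]) != N_DF_LINES:
            raise FormatError(
                f"{path}: {name} block has {len(blocks[name])} rows; expected "
                f"{N_DF_LINES} x {N_CV_STEPS}"
            )
    kwargs = {}
    if df_axis is not None:
        kwargs["df_percent_axis"] = df_axis
    if cv_axis is not None:
        kwargs["cv_volts_axis"] = cv_axis
    return FaimsScan(
        positive=np.vstack(blocks["POSITIVE"]),
        negative=np.vstack(blocks["NEGATIVE"]),
        sample_id=sample_id,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# E-nose record CSV
# ---------------------------------------------------------------------------

def write_enose_record(record: EnoseRecord, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# sample_id: {record.sample_id}\n")
        fh.write(f"# replicate: {record.replicate}\n")
        fh.write(f"# baseline: {_fmt_row(record.baseline)}\n")
        for row in record.resistances:
            fh.write(_fmt_row(row) + "\n")


def read_enose_record(path: str | Path) -> EnoseRecord:
    path = Path(path)
    sample_id = ""
    replicate = 0
    baseline = None
    rows: list[np.ndarray] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                header = line[1:].strip()
                if header.startswith("sample_id:"):
                    sample_id = header.split(":", 1)[1].strip()
                elif header.startswith("replicate:"):
                    replicate = int(header.split(":", 1)[1].strip())
                elif header.startswith("baseline:"):
                    baseline = _parse_row(
                        header.split(":", 1)[1].strip(), path, lineno, N_SENSORS
                    )
                else:
                    raise FormatError(f"{path}:{lineno}: unknown header {header!r}")
                continue
            rows.append(_parse_row(line, path, lineno, N_TIME_SAMPLES))
    if baseline is None:
        raise FormatError(f"{path}: missing baseline header")
    if len(rows) != N_SENSORS:
        raise FormatError(
            f"{path}: found {len(rows)} sensor rows; expected {N_SENSORS} x "
            f"{N_TIME_SAMPLES}"
        )
    return EnoseRecord(
        resistances=np.vstack(rows),
        baseline=baseline,
        sample_id=sample_id,
        replicate=replicate,
    )


# ---------------------------------------------------------------------------
# GC-MS peak table TSV
# ---------------------------------------------------------------------------

def _parse_spectrum(text: str, path: Path, lineno: int) -> dict[int, float]:
    spectrum: dict[int, float] = {}
    text = text.strip()
    if not text:
        return spectrum
    for pair in text.split(";"):
        pair = pair.strip()
        if not pair:
            continue
        try:
            mz_s, intensity_s = pair.split(":")
            mz = int(mz_s)
            intensity = float(intensity_s)
        except ValueError:
            raise FormatError(
                f"{path}:{lineno}: malformed spectrum pair {pair!r}"
            ) from None
        if mz <= 0:
            raise FormatError(f"{path}:{lineno}: m/z must be positive, got {mz}")
        if intensity < 0:
            raise FormatError(
                f"{path}:{lineno}: intensity must be >= 0, got {intensity}"
            )
        spectrum[mz] = intensity
    return spectrum


def read_gcms_table(path: str | Path) -> GcmsPeakTable:
    """Read a TSV peak table; spectra are base-peak renormalized to 999.

    Expected columns (by header name): ``retention_time``, ``spectrum``
    (semicolon-separated ``mz:intensity`` pairs) and optionally
    ``identification``.  Extra columns are ignored.  Entries come back sorted
    by retention time.
    """
    path = Path(path)
    entries: list[GcmsEntry] = []
    with path.open() as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        return GcmsPeakTable(entries=[])
    header = lines[0].split("\t")
    try:
        rt_col = header.index("retention_time")
        spec_col = header.index("spectrum")
    except ValueError:
        raise FormatError(
            f"{path}: header must contain 'retention_time' and 'spectrum' columns"
        ) from None
    id_col = header.index("identification") if "identification" in header else None
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) < len(header):
            cells += [""] * (len(header) - len(cells))
        try:
            rt = float(cells[rt_col])
        except ValueError:
            raise FormatError(
                f"{path}:{lineno}: non-numeric retention time {cells[rt_col]!r}"
            ) from None
        spectrum = _parse_spectrum(cells[spec_col], path, lineno)
        ident = cells[id_col].strip() or None if id_col is not None else None
        entries.append(GcmsEntry(rt, spectrum, ident))
    return GcmsPeakTable(entries=entries).normalized()


def write_gcms_table(table: GcmsPeakTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("retention_time\tspectrum\tidentification\n")
        for e in table.entries:
            spec = ";".join(
                f"{mz}:{e.spectrum[mz]:g}" for mz in sorted(e.spectrum)
            )
            fh.write(f"{e.retention_time!r}\t{spec}\t{e.identification or ''}\n")


# ---------------------------------------------------------------------------
# Cohort manifest JSON
# ---------------------------------------------------------------------------

def write_manifest(entries: list[ManifestEntry], path: str | Path) -> None:
    payload = [
        {
            "sample_id": e.sample_id,
            "group": e.group.value,
            "faims_path": e.faims_path,
            "enose_paths": list(e.enose_paths),
            "gcms_path": e.gcms_path,
        }
        for e in entries
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_manifest(path: str | Path) -> list[ManifestEntry]:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON manifest: {exc}") from None
    entries = []
    seen: set[str] = set()
    for item in payload:
        sid = item["sample_id"]
        if sid in seen:
            raise FormatError(f"{path}: duplicate sample_id {sid!r}")
        seen.add(sid)
        entries.append(
            ManifestEntry(
                sample_id=sid,
                group=GroupLabel(item["group"]),
                faims_path=item.get("faims_path"),
                enose_paths=list(item.get("enose_paths") or []),
                gcms_path=item.get("gcms_path"),
            )
        )
    return entries
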