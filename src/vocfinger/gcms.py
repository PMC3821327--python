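"""GC-MS marker flagging: cosine spectral similarity against a packaged
reference table, gated by a retention-time window.

The reference set is the seven printed spectra (base-peak normalized to 999)
shipped in ``data/reference_spectra.tsv``; the 1.714-min isopropyl-alcohol
and 2.051-min acetamide rows are the BAD-indicating markers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

from .io_formats import FormatError, GcmsPeakTable, read_gcms_table

__all__ = [
    "ReferenceSpectrum",
    "MarkerHit",
    "MarkerReport",
    "BAD_MARKER_NAMES",
    "reference_table_path",
    "load_reference_spectra",
    "spectrum_similarity",
    "detect_markers",
]

DEFAULT_RT_WINDOW = 0.05  # minutes
DEFAULT_MIN_SIMILARITY = 0.8

#: reference names whose presence indicates a BAD sample
BAD_MARKER_NAMES = ("Isopropyl alcohol", "Acetamide")


@dataclass(frozen=True)
class ReferenceSpectrum:
    name: str
    retention_time: float
    spectrum: dict[int, float]
    annotation: Optional[str] = None
    sample_label: Optional[str] = None


@dataclass(frozen=True)
class MarkerHit:
    retention_time: float
    reference_name: str
    similarity: float
    rt_delta: float


@dataclass
class MarkerReport:
    hits: list[MarkerHit] = field(default_factory=list)
    rt_window: float = DEFAULT_RT_WINDOW
    min_similarity: float = DEFAULT_MIN_SIMILARITY

    def hit_names(self) -> set[str]:
        return {h.reference_name for h in self.hits}

    def to_dict(self) -> dict:
        return {
            "rt_window": self.rt_window,
            "min_similarity": self.min_similarity,
            "hits": [
                {
                    "retention_time": h.retention_time,
                    "reference": h.reference_name,
                    "similarity": h.similarity,
                    "rt_delta": h.rt_delta,
                }
                for h in self.hits
            ],
        }


def reference_table_path() -> Path:
    """Filesystem path of the packaged reference TSV."""
    return Path(resources.files("vocfinger").joinpath("data/reference_spectra.tsv"))


def load_reference_spectra(
    path: Optional[str | Path] = None,
) -> list[ReferenceSpectrum]:
    """Load reference spectra from a TSV (packaged table by default).

    The ``name`` column carries the first-listed identification (chemical
    names may themselves contain commas, so splitting the identification
    string is not reliable); the full multi-compound identification string
    is kept as annotation.
    """
    path = Path(path) if path is not None else reference_table_path()
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        return []
    header = lines[0].split("\t")
    try:
        rt_col = header.index("retention_time")
        spec_col = header.index("spectrum")
    except ValueError:
        raise FormatError(
            f"{path}: header must contain 'retention_time' and 'spectrum'"
        ) from None
    id_col = header.index("identification") if "identification" in header else None
    name_col = header.index("name") if "name" in header else None
    sample_col = header.index("sample") if "sample" in header else None
    refs = []
    for line in lines[1:]:
        cells = line.split("\t")
        spectrum = {}
        for pair in cells[spec_col].split(";"):
            mz_s, intensity_s = pair.split(":")
            spectrum[int(mz_s)] = float(intensity_s)
        top = max(spectrum.values())
        if top != 999.0:
            spectrum = {mz: v * 999.0 / top for mz, v in spectrum.items()}
        annotation = cells[id_col].strip() if id_col is not None else None
        if name_col is not None:
            name = cells[name_col].strip()
        elif annotation:
            name = annotation.split(",")[0].strip()
        else:
            name = f"rt={cells[rt_col]}"
        refs.append(
            ReferenceSpectrum(
                name=name,
                retention_time=float(cells[rt_col]),
                spectrum=spectrum,
                annotation=annotation,
                sample_label=cells[sample_col].strip()
                if sample_col is not None
                else None,
            )
        )
    return refs


def spectrum_similarity(a: dict[int, float], b: dict[int, float]) -> float:
    """Cosine similarity over the union of m/z values (missing ions count 0).

    Symmetric and invariant to uniform intensity rescaling of either
    spectrum; disjoint spectra score 0, identical ones 1.
    """
    if not a or not b:
        raise ValueError("cannot compare an empty spectrum")
    dot = sum(v * b.get(mz, 0.0) for mz, v in a.items())
    norm_a = math.sqrt(sum(v * v for v in a.values()))
    norm_b = math.sqrt(sum(v * v for v in b.values()))
    if norm_a == 0.0 or norm_b == 0.0:
        raise ValueError("cannot compare an all-zero spectrum")
    return dot / (norm_a * norm_b)


def detect_markers(
    table: GcmsPeakTable,
    references: Optional[Sequence[ReferenceSpectrum]] = None,
    rt_window: float = DEFAULT_RT_WINDOW,
    min_similarity: float = DEFAULT_MIN_SIMILARITY,
) -> MarkerReport:
    """Flag table entries matching a reference in both time and spectrum.

    An entry hits a reference iff |rt_query - rt_ref| <= rt_window AND
    cosine similarity >= min_similarity.  Hits come back sorted by retention
    time (then reference name).
    """
    if rt_window <= 0:
        raise ValueError("rt_window must be > 0")
    if not 0.0 <= min_similarity <= 1.0:
        raise ValueError("min_similarity must lie in [0, 1]")
    references = (
        list(references) if references is not None else load_reference_spectra()
    )
    hits: list[MarkerHit] = []
    for entry in table.entries:
        if not entry.spectrum:
            continue
        for ref in references:
            delta = entry.retention_time - ref.retention_time
            if abs(delta) > rt_window:
                continue
            sim = spectrum_similarity(entry.spectrum, ref.spectrum)
            if sim >= min_similarity:
                hits.append(
                    MarkerHit(
                        retention_time=entry.retention_time,
                        reference_name=ref.name,
                        similarity=sim,
                        rt_delta=delta,
                    )
                )
    hits.sort(key=lambda h: (h.retention_time, h.reference_name))
    return MarkerReport(
        hits=hits, rt_window=rt_window, min_similarity=min_similarity
    )
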