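"""Synthetic cohort generator emulating the study's three instruments.

FAIMS scans are built from 2-D Gaussian "plumes" on the compensation-voltage
x dispersion-field grid: a set of baseline plumes shared by everyone, plus a
few designated plumes whose amplitude (and, slightly, CV position) depends on
the group, scaled by ``effect_size``.  E-nose records are smooth
rise-and-recovery resistance drops whose amplitudes carry the group signal on
four designated sensors.  GC-MS tables plant the packaged reference spectra,
with the 1.714-min and 2.051-min peaks present only in BAD samples.

Determinism: every generated object is a pure function of
``(config.seed, sample_seed, replicate)``; per-sample seeds are derived from
sample IDs with CRC-32 (stated hash), so cohorts reproduce record by record.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io_formats import (
    N_CV_STEPS,
    N_DF_LINES,
    N_SENSORS,
    N_TIME_SAMPLES,
    EnoseRecord,
    FaimsScan,
    GcmsEntry,
    GcmsPeakTable,
    GroupLabel,
    default_cv_axis,
    default_df_axis,
)

__all__ = [
    "CohortConfig",
    "PlumeSpec",
    "SyntheticCohort",
    "generate_cohort",
    "generate_faims_scan",
    "generate_enose_record",
    "generate_gcms_table",
    "enose_truth_amplitudes",
    "sample_seed_for",
    "DEFAULT_GROUP_SIZES",
]

DEFAULT_GROUP_SIZES: dict[GroupLabel, int] = {
    GroupLabel.BAD: 23,
    GroupLabel.UC: 42,
    GroupLabel.CONTROL: 45,
}

# rng stream tags, so the same sample seed feeds independent streams
_STREAM_FAIMS = 1
_STREAM_ENOSE = 2
_STREAM_GCMS = 3


@dataclass(frozen=True)
class CohortConfig:
    """Knobs of the generator; the seed fully determines the output."""

    n_per_group: dict[GroupLabel, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    effect_size: float = 1.0
    noise_sd: float = 0.5
    biological_sd: float = 0.05
    n_enose_replicates: int = 3
    gcms_rt_jitter: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if any(v < 0 for v in self.n_per_group.values()):
            raise ValueError("group counts must be >= 0")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.biological_sd < 0:
            raise ValueError("biological_sd must be >= 0")
        if self.n_enose_replicates < 1:
            raise ValueError("n_enose_replicates must be >= 1")
        if self.gcms_rt_jitter < 0:
            raise ValueError("gcms_rt_jitter must be >= 0")


@dataclass(frozen=True)
class PlumeSpec:
    """A 2-D Gaussian bump of ion current in (CV, DF) space."""

    center_cv: float  # volts, in [-6, +6]
    center_df_pct: float  # percent, in [0, 90]
    amplitude: float  # arbitrary ion-count units, >= 0
    width_cv: float  # volts, > 0
    width_df: float  # percent, > 0
    polarity: str = "positive"

    def __post_init__(self) -> None:
        if not -6.0 <= self.center_cv <= 6.0:
            raise ValueError("plume CV center must lie in [-6, +6] V")
        if not 0.0 <= self.center_df_pct <= 90.0:
            raise ValueError("plume DF center must lie in [0, 90] %")
        if self.amplitude < 0:
            raise ValueError("plume amplitude must be >= 0")
        if self.width_cv <= 0 or self.width_df <= 0:
            raise ValueError("plume widths must be > 0")
        if self.polarity not in ("positive", "negative"):
            raise ValueError("polarity must be 'positive' or 'negative'")


# Baseline chemistry shared by all groups (reactant-ion-peak-like ridge plus
# a few secondary plumes per polarity).
BASELINE_PLUMES: tuple[PlumeSpec, ...] = (
    PlumeSpec(1.2, 5.0, 80.0, 0.8, 18.0, "positive"),
    PlumeSpec(-0.5, 30.0, 40.0, 1.0, 15.0, "positive"),
    PlumeSpec(2.5, 55.0, 25.0, 1.5, 20.0, "positive"),
    PlumeSpec(0.8, 10.0, 60.0, 0.9, 15.0, "negative"),
    PlumeSpec(-1.5, 40.0, 30.0, 1.2, 18.0, "negative"),
)

# Designated signal plumes; the per-group coefficient multiplies the plume
# amplitude, scaled further by effect_size (all zero signal at effect 0).
_SIGNAL_PLUMES: tuple[PlumeSpec, ...] = (
    PlumeSpec(-2.0, 25.0, 30.0, 0.7, 10.0, "positive"),
    PlumeSpec(3.0, 45.0, 25.0, 0.9, 12.0, "positive"),
    PlumeSpec(-3.5, 60.0, 20.0, 0.8, 12.0, "negative"),
    PlumeSpec(1.8, 70.0, 18.0, 1.0, 14.0, "negative"),
)
_GROUP_PLUME_COEFFS: dict[GroupLabel, tuple[float, float, float, float]] = {
    GroupLabel.BAD: (1.0, 0.0, 0.8, 0.0),
    GroupLabel.UC: (0.25, 1.0, 0.0, 0.4),
    GroupLabel.CONTROL: (0.0, 0.3, 0.4, 1.0),
}
# small group-dependent CV shift of the first signal plume (volts per unit effect)
_GROUP_CV_SHIFT: dict[GroupLabel, float] = {
    GroupLabel.BAD: 0.05,
    GroupLabel.UC: 0.0,
    GroupLabel.CONTROL: -0.05,
}

# E-nose sensor-array constants (ohms).
_ENOSE_BASELINES = 10000.0 + 2000.0 * np.arange(N_SENSORS)
_ENOSE_BASE_AMPLITUDES = 600.0 + 90.0 * np.arange(N_SENSORS)
_ENOSE_TAU = 20.0 + 5.0 * (np.arange(N_SENSORS) % 4)  # response peak time, s
_ENOSE_SIGNAL_SENSORS = np.array([2, 7, 11, 15])
_GROUP_SENSOR_DELTAS: dict[GroupLabel, np.ndarray] = {
    GroupLabel.BAD: np.array([350.0, 0.0, 250.0, 150.0]),
    GroupLabel.UC: np.array([0.0, 300.0, -150.0, 100.0]),
    GroupLabel.CONTROL: np.array([0.0, 0.0, 0.0, 0.0]),
}
_ENOSE_AMP_NOISE_SCALE = 50.0  # ohms of amplitude jitter per unit noise_sd
_ENOSE_TRACE_NOISE_SCALE = 5.0  # ohms of per-sample additive noise per unit
_ENOSE_BIO_SCALE = 100.0  # ohms of per-sample biological jitter per unit

# Which reference spectra (keyed by full annotation) each group's table carries.
_GCMS_SHARED_BAD = ("Acetone, dimethyl diazene", "Cyclopentane, 2-pentene")
_GCMS_SHARED_NONBAD = (
    "Acetone, 1-methylethyl hydroperoxide",
    "Dimethyl disulphide",
    "Dihydro-3-methyl-2,5-furandione, cyclopentane",
)
_GCMS_BAD_ONLY = ("Isopropyl alcohol", "Acetamide")


@dataclass
class SyntheticCohort:
    manifest: list[tuple[str, GroupLabel]]
    faims_scans: dict[str, FaimsScan]
    enose_records: dict[str, list[EnoseRecord]]
    gcms_tables: dict[str, GcmsPeakTable]
    truth: CohortConfig


def sample_seed_for(sample_id: str) -> int:
    """Stated per-sample hash: CRC-32 of the sample ID."""
    return zlib.crc32(sample_id.encode("utf-8"))


def _rng(config: CohortConfig, sample_seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, sample_seed, *stream])


def _render_plumes(
    plumes: list[tuple[PlumeSpec, float, float]],
    cv_axis: np.ndarray,
    df_axis: np.ndarray,
    polarity: str,
) -> np.ndarray:
    """Sum amplitude * exp Gaussian bumps over the (DF, CV) grid.

    ``plumes`` items are (spec, amplitude multiplier, cv shift).
    """
    mat = np.zeros((df_axis.size, cv_axis.size))
    for spec, mult, cv_shift in plumes:
        if spec.polarity != polarity or mult == 0.0:
            continue
        dcv = (cv_axis - (spec.center_cv + cv_shift)) / spec.width_cv
        ddf = (df_axis - spec.center_df_pct) / spec.width_df
        mat += (
            spec.amplitude
            * mult
            * np.exp(-0.5 * (ddf[:, None] ** 2 + dcv[None, :] ** 2))
        )
    return mat


def generate_faims_scan(
    group: GroupLabel, config: CohortConfig, sample_seed: int
) -> FaimsScan:
    """One synthetic dispersion-matrix pair for a sample of the given group."""
    config.validate()
    rng = _rng(config, sample_seed, _STREAM_FAIMS)
    df_axis = default_df_axis()
    cv_axis = default_cv_axis()
    plumes: list[tuple[PlumeSpec, float, float]] = []
    for spec in BASELINE_PLUMES:
        mult = 1.0 + config.biological_sd * rng.standard_normal()
        plumes.append((spec, mult, 0.0))
    coeffs = _GROUP_PLUME_COEFFS[group]
    cv_shift = config.effect_size * _GROUP_CV_SHIFT[group]
    for j, spec in enumerate(_SIGNAL_PLUMES):
        bio = 1.0 + config.biological_sd * rng.standard_normal()
        mult = config.effect_size * coeffs[j] * bio
        plumes.append((spec, mult, cv_shift if j == 0 else 0.0))
    positive = _render_plumes(plumes, cv_axis, df_axis, "positive")
    negative = _render_plumes(plumes, cv_axis, df_axis, "negative")
    if config.noise_sd > 0:
        positive = positive + config.noise_sd * rng.standard_normal(positive.shape)
        negative = negative + config.noise_sd * rng.standard_normal(negative.shape)
    return FaimsScan(
        positive=positive,
        negative=negative,
        df_percent_axis=df_axis,
        cv_volts_axis=cv_axis,
    )


def enose_truth_amplitudes(group: GroupLabel, config: CohortConfig) -> np.ndarray:
    """The generator's ground-truth response amplitude per sensor (ohms)."""
    amps = _ENOSE_BASE_AMPLITUDES.copy()
    amps[_ENOSE_SIGNAL_SENSORS] += config.effect_size * _GROUP_SENSOR_DELTAS[group]
    return amps


def generate_enose_record(
    group: GroupLabel,
    config: CohortConfig,
    sample_seed: int,
    replicate: int = 0,
) -> EnoseRecord:
    """One synthetic 18-sensor injection trace (resistance drop and recovery)."""
    config.validate()
    if not 0 <= replicate < config.n_enose_replicates:
        raise ValueError(
            f"replicate {replicate} out of range [0, {config.n_enose_replicates})"
        )
    sample_rng = _rng(config, sample_seed, _STREAM_ENOSE)
    rep_rng = _rng(config, sample_seed, _STREAM_ENOSE, replicate + 1)
    amps = enose_truth_amplitudes(group, config)
    # per-sample (biological) amplitude jitter, identical across replicates
    amps = amps + config.biological_sd * _ENOSE_BIO_SCALE * sample_rng.standard_normal(
        N_SENSORS
    )
    # per-replicate (technical) amplitude jitter
    amps = amps + config.noise_sd * _ENOSE_AMP_NOISE_SCALE * rep_rng.standard_normal(
        N_SENSORS
    )
    t = np.arange(N_TIME_SAMPLES, dtype=float)
    # smooth rise-and-recovery: peaks at t = tau with unit height
    shape = (t[None, :] / _ENOSE_TAU[:, None]) * np.exp(
        1.0 - t[None, :] / _ENOSE_TAU[:, None]
    )
    resistances = _ENOSE_BASELINES[:, None] - amps[:, None] * shape
    if config.noise_sd > 0:
        resistances = resistances + (
            config.noise_sd
            * _ENOSE_TRACE_NOISE_SCALE
            * rep_rng.standard_normal(resistances.shape)
        )
    return EnoseRecord(
        resistances=resistances,
        baseline=_ENOSE_BASELINES.copy(),
        replicate=replicate,
    )


def generate_gcms_table(
    group: GroupLabel,
    config: CohortConfig,
    sample_seed: int,
    rt_overrides: Optional[dict[str, float]] = None,
) -> GcmsPeakTable:
    """One synthetic peak table; BAD-only markers appear iff group is BAD.

    ``rt_overrides`` maps reference annotations (e.g. ``"Acetamide"``) to
    replacement retention-time centers (e.g. rounded values); jitter of
    ``config.gcms_rt_jitter`` minutes (uniform) is applied to every center.
    """
    from .gcms import load_reference_spectra  # local: avoid cycle

    config.validate()
    rng = _rng(config, sample_seed, _STREAM_GCMS)
    refs = {r.annotation: r for r in load_reference_spectra()}
    if group is GroupLabel.BAD:
        names = _GCMS_SHARED_BAD + _GCMS_BAD_ONLY
    else:
        names = _GCMS_SHARED_NONBAD
    entries = []
    for name in names:
        ref = refs[name]
        center = ref.retention_time
        if rt_overrides and name in rt_overrides:
            center = rt_overrides[name]
        jitter = (
            rng.uniform(-config.gcms_rt_jitter, config.gcms_rt_jitter)
            if config.gcms_rt_jitter > 0
            else 0.0
        )
        entries.append(
            GcmsEntry(
                retention_time=center + jitter,
                spectrum=dict(ref.spectrum),
                identification=None,
            )
        )
    return GcmsPeakTable(entries=entries).normalized()


def generate_cohort(config: Optional[CohortConfig] = None) -> SyntheticCohort:
    """Generate a full cohort: manifest, FAIMS, e-nose replicates, GC-MS.

    Identical config (including seed) yields a bit-identical cohort; with
    ``effect_size = 0`` all groups are drawn from the same distribution.
    """
    config = config or CohortConfig()
    config.validate()
    manifest: list[tuple[str, GroupLabel]] = []
    faims_scans: dict[str, FaimsScan] = {}
    enose_records: dict[str, list[EnoseRecord]] = {}
    gcms_tables: dict[str, GcmsPeakTable] = {}
    for group in GroupLabel:
        count = config.n_per_group.get(group, 0)
        for i in range(count):
            sid = f"{group.value}-{i + 1:03d}"
            manifest.append((sid, group))
            seed = sample_seed_for(sid)
            scan = generate_faims_scan(group, config, seed)
            scan.sample_id = sid
            faims_scans[sid] = scan
            reps = []
            for r in range(config.n_enose_replicates):
                rec = generate_enose_record(group, config, seed, r)
                rec.sample_id = sid
                reps.append(rec)
            enose_records[sid] = reps
            table = generate_gcms_table(group, config, seed)
            table.sample_id = sid
            gcms_tables[sid] = table
    return SyntheticCohort(
        manifest=manifest,
        faims_scans=faims_scans,
        enose_records=enose_records,
        gcms_tables=gcms_tables,
        truth=config,
    )


def small_config(
    n: int = 8,
    effect_size: float = 1.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    **kwargs,
) -> CohortConfig:
    """Convenience: an equal-arm cohort config for tests and calibration."""
    return CohortConfig(
        n_per_group={g: n for g in GroupLabel},
        effect_size=effect_size,
        noise_sd=noise_sd,
        seed=seed,
        **kwargs,
    )
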