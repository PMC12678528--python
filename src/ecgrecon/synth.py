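"""Synthetic 12-lead ECG cohorts with known fiducials and known lead mixing.

The beat model is a sum of truncated Gaussians (ECGSYN-inspired): each beat has
P, Q, R, S and T components; Q+R+S form the QRS source.  The three per-wave
source waveforms have provably disjoint supports, hard-truncated at four
widths, so the generator knows every wave's exact half-open on/off interval.

Each lead is a linear mixture of the three wave sources plus a constant
offset — the single-dipole-region premise made literal.  Two mixing modes:

``global``
    one full-rank leads x waves gain matrix; every lead is then an exact
    linear function of any three independent leads, so plain 3-lead linear
    reconstruction is exact and its true (A, C) is known in closed form.

``per_wave``
    the {I, II} rows share a fixed QRS:T gain ratio and V3's row is an exact
    linear combination of them, while each output lead's row is an in-span
    base row modulated per wave by (1 ± disparity).  Three input leads then
    span only two of the three wave dimensions: the 3-lead model is
    misspecified by construction (more so for larger disparity), while the
    wave-masked 6-channel model remains exact given true fiducials.

Limb leads are rendered from the I and II rows via the Einthoven/Goldberger
identities, so those hold by construction.  Optional white noise is added per
lead at a configured SNR.  Everything is deterministic given the cohort seed
(hierarchical: cohort seed -> patient seed -> record seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .delineate import BeatFiducials, FiducialSet
from .io import CONDITION_NAMES, STANDARD_LEADS, ECGRecord, RecordMetadata

__all__ = [
    "WaveShape",
    "SynthConfig",
    "Mixing",
    "SynthRecordTruth",
    "Cohort",
    "default_morphology",
    "make_mixing",
    "generate_beat",
    "generate_record",
    "generate_cohort",
    "measured_snr_db",
]

WAVES = ("P", "QRS", "T")
_COMPONENTS = ("P", "Q", "R", "S", "T")
_WAVE_OF = {"P": "P", "Q": "QRS", "R": "QRS", "S": "QRS", "T": "T"}

#: truncation of each Gaussian component, in widths
TRUNCATION_SIGMAS = 4.0


@dataclass(frozen=True)
class WaveShape:
    """One Gaussian component: amplitude (mV), center relative to the R peak
    (s), and width sigma (s)."""

    amplitude: float
    center_s: float
    width_s: float

    def __post_init__(self) -> None:
        if self.width_s <= 0:
            raise ValueError("width must be positive")


def default_morphology() -> dict[str, WaveShape]:
    """Typical adult sinus-beat morphology (lead II scale, mV / seconds)."""
    return {
        "P": WaveShape(0.15, -0.150, 0.018),
        "Q": WaveShape(-0.12, -0.022, 0.007),
        "R": WaveShape(1.10, 0.000, 0.010),
        "S": WaveShape(-0.25, 0.028, 0.009),
        "T": WaveShape(0.45, 0.255, 0.030),
    }


@dataclass
class Mixing:
    """Per-wave lead gains (rows follow STANDARD_LEADS, columns P/QRS/T) plus
    per-lead constant offsets.  Limb-lead rows are derived from I and II."""

    gains: np.ndarray  # (12, 3)
    offsets: np.ndarray  # (12,)
    mode: str = "global"
    disparity: float = 0.0

    def __post_init__(self) -> None:
        self.gains = np.asarray(self.gains, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.gains.shape != (12, 3) or self.offsets.shape != (12,):
            raise ValueError("gains must be (12, 3) and offsets (12,)")
        if not np.all(np.isfinite(self.gains)):
            raise ValueError("gains must be finite")

    def row(self, lead: str) -> np.ndarray:
        return self.gains[STANDARD_LEADS.index(lead)]

    def offset(self, lead: str) -> float:
        return float(self.offsets[STANDARD_LEADS.index(lead)])

    def truth_linear_map(
        self, input_leads: Sequence[str], output_leads: Sequence[str]
    ) -> tuple[np.ndarray, np.ndarray]:
        """Exact (A, C) with y = A x + C, defined when the input rows span the
        output rows (always true in global mode with 3 independent inputs)."""
        M_in = np.stack([self.row(l) for l in input_leads])
        M_out = np.stack([self.row(l) for l in output_leads])
        c_in = np.array([self.offset(l) for l in input_leads])
        c_out = np.array([self.offset(l) for l in output_leads])
        A, residual, rank, _ = np.linalg.lstsq(M_in.T, M_out.T, rcond=None)
        A = A.T
        if not np.allclose(A @ M_in, M_out, atol=1e-9):
            raise ValueError(
                f"leads {output_leads} are not exact linear functions of {input_leads} "
                "under this mixing"
            )
        return A, c_out - A @ c_in


# base per-wave gains (P, QRS, T) for the eight independent leads
_BASE_GAINS: Mapping[str, tuple[float, float, float]] = {
    "I": (0.55, 0.60, 0.35),
    "II": (1.00, 1.00, 1.00),
    "V1": (0.20, -0.80, -0.35),
    "V2": (0.35, 0.50, 0.60),
    "V3": (0.50, 1.10, 0.90),
    "V4": (0.45, 1.40, 1.00),
    "V5": (0.40, 1.20, 0.95),
    "V6": (0.35, 0.90, 0.85),
}

# The recording leads I, II, V3 are baseline-corrected (zero DC) — this also
# keeps the zero-masked wave channels pure scaled copies of the wave sources.
# Reconstruction targets carry nonzero constants so the intercept C is
# exercised; limb-lead offsets derive from I and II (hence zero).
_BASE_OFFSETS: Mapping[str, float] = {
    "I": 0.0, "II": 0.0, "V1": 0.05, "V2": -0.02,
    "V3": 0.0, "V4": -0.05, "V5": 0.03, "V6": -0.04,
}

# per-wave modulation signs for per_wave mode (P, QRS, T); QRS/T signs are
# opposite so the disparity shifts each output lead's QRS:T balance away from
# the locked input-lead ratio
_PER_WAVE_SIGNS: Mapping[str, tuple[float, float, float]] = {
    "V1": (+1, +1, -1),
    "V2": (-1, +1, -1),
    "V4": (+1, +1, -1),
    "V5": (-1, +1, -1),
    "V6": (+1, +1, -1),
}

#: QRS:T gain ratio shared by leads I and II in per_wave mode
_PW_T_RATIO = 0.85


def make_mixing(mode: str = "global", disparity: float = 0.2) -> Mixing:
    """Build the cohort mixing for a mode (see module docstring)."""
    if mode not in {"global", "per_wave"}:
        raise ValueError(f"unknown mixing mode {mode!r}")
    rows = {lead: np.array(g, dtype=float) for lead, g in _BASE_GAINS.items()}
    offs = dict(_BASE_OFFSETS)
    if mode == "per_wave":
        rows["I"] = np.array([0.55, 0.60, 0.60 * _PW_T_RATIO])
        rows["II"] = np.array([1.00, 1.00, _PW_T_RATIO])
        span = np.stack([rows["I"], rows["II"]])  # 2 x 3
        for lead in ("V1", "V2", "V3", "V4", "V5", "V6"):
            ab, *_ = np.linalg.lstsq(span.T, np.array(_BASE_GAINS[lead]), rcond=None)
            in_span = ab @ span
            if lead == "V3":
                rows[lead] = in_span  # input lead: exactly inside the span
            else:
                signs = np.array(_PER_WAVE_SIGNS[lead], dtype=float)
                rows[lead] = in_span * (1.0 + disparity * signs)
    gains = np.zeros((12, 3))
    offsets = np.zeros(12)
    for j, lead in enumerate(STANDARD_LEADS):
        if lead in rows:
            gains[j] = rows[lead]
            offsets[j] = offs[lead]
    # limb leads from I and II (Einthoven / Goldberger), offsets included
    i_idx, ii_idx = STANDARD_LEADS.index("I"), STANDARD_LEADS.index("II")
    combos = {"III": (-1.0, 1.0), "aVR": (-0.5, -0.5), "aVL": (1.0, -0.5), "aVF": (-0.5, 1.0)}
    for lead, (a, b) in combos.items():
        j = STANDARD_LEADS.index(lead)
        gains[j] = a * gains[i_idx] + b * gains[ii_idx]
        offsets[j] = a * offsets[i_idx] + b * offsets[ii_idx]
    return Mixing(gains=gains, offsets=offsets, mode=mode, disparity=disparity)


@dataclass
class SynthConfig:
    """Cohort-level generation parameters (the study conditions)."""

    n_patients: int = 10
    records_per_patient: int = 1
    fs: float = 500.0
    duration_s: float = 10.0
    heart_rate_bpm: tuple[float, float] = (50.0, 90.0)
    morphology: dict[str, WaveShape] = field(default_factory=default_morphology)
    mixing_mode: str = "global"
    disparity: float = 0.2
    noise_snr_db: float | None = None
    rr_jitter: float = 0.05
    amp_jitter: float = 0.2
    width_jitter: float = 0.1
    seed: int = 0
    # metadata-injection switches for filter tests
    n_duplicate_patients: int = 0
    n_abnormal: int = 0
    n_blank_leads: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration must be positive")
        lo, hi = self.heart_rate_bpm
        if not 0 < lo <= hi:
            raise ValueError("heart rate range must be positive and ordered")
        if set(self.morphology) != set(_COMPONENTS):
            raise ValueError(f"morphology must define {_COMPONENTS}")


@dataclass
class SynthRecordTruth:
    """A generated record plus everything the generator knows about it."""

    record: ECGRecord
    fiducials: FiducialSet
    mixing: Mixing
    metadata: RecordMetadata
    sources: np.ndarray  # (n_samples, 3) clean P/QRS/T source waveforms


@dataclass
class Cohort:
    items: list[SynthRecordTruth]
    metadata: list[RecordMetadata]
    mixing: Mixing
    config: SynthConfig

    def __len__(self) -> int:
        return len(self.items)


# ---------------------------------------------------------------------------
# beats
# ---------------------------------------------------------------------------

def generate_beat(
    morphology: Mapping[str, WaveShape], fs: float
) -> tuple[dict[str, np.ndarray], dict[str, tuple[int, int]], int]:
    """Render one beat's per-wave source components on a local sample grid.

    Returns ``(components, bounds, r_index)`` where components maps P/QRS/T to
    arrays over the local grid, bounds maps each wave to its half-open
    [on, off) interval (exactly the nonzero support), and r_index is the R
    center.  The local grid starts at the earliest truncated support.
    Raises if the truncated supports of consecutive waves overlap.
    """
    spans = {
        name: (
            shape.center_s - TRUNCATION_SIGMAS * shape.width_s,
            shape.center_s + TRUNCATION_SIGMAS * shape.width_s,
        )
        for name, shape in morphology.items()
    }
    wave_spans = {
        "P": spans["P"],
        "QRS": (
            min(spans[c][0] for c in ("Q", "R", "S")),
            max(spans[c][1] for c in ("Q", "R", "S")),
        ),
        "T": spans["T"],
    }
    if not (wave_spans["P"][1] <= wave_spans["QRS"][0] and wave_spans["QRS"][1] <= wave_spans["T"][0]):
        raise ValueError(f"wave supports overlap for this morphology: {wave_spans}")
    t_start = wave_spans["P"][0]
    # sample index i on the local grid corresponds to time t_start + i / fs
    bounds: dict[str, tuple[int, int]] = {}
    for wave, (lo, hi) in wave_spans.items():
        on = int(math.ceil((lo - t_start) * fs - 1e-9))
        off = int(math.floor((hi - t_start) * fs + 1e-9)) + 1
        bounds[wave] = (on, off)
    n_local = bounds["T"][1]
    t = t_start + np.arange(n_local) / fs
    components = {wave: np.zeros(n_local) for wave in WAVES}
    for comp in _COMPONENTS:
        shape = morphology[comp]
        wave = _WAVE_OF[comp]
        lo, hi = spans[comp]
        on = max(int(math.ceil((lo - t_start) * fs - 1e-9)), bounds[wave][0])
        off = min(int(math.floor((hi - t_start) * fs + 1e-9)) + 1, bounds[wave][1])
        tt = t[on:off]
        components[wave][on:off] += shape.amplitude * np.exp(
            -0.5 * ((tt - shape.center_s) / shape.width_s) ** 2
        )
    r_index = int(round((morphology["R"].center_s - t_start) * fs))
    return components, bounds, r_index


def _jittered_morphology(
    morphology: Mapping[str, WaveShape], rng: np.random.Generator, amp_j: float, width_j: float
) -> dict[str, WaveShape]:
    out = {}
    for name, shape in morphology.items():
        out[name] = WaveShape(
            amplitude=shape.amplitude * (1.0 + amp_j * rng.uniform(-1, 1)),
            center_s=shape.center_s,
            width_s=shape.width_s * (1.0 + width_j * rng.uniform(-1, 1)),
        )
    return out


# ---------------------------------------------------------------------------
# records and cohorts
# ---------------------------------------------------------------------------

def generate_record(
    config: SynthConfig,
    *,
    record_id: str,
    patient_id: str,
    morphology: Mapping[str, WaveShape],
    heart_rate_bpm: float,
    mixing: Mixing,
    rng: np.random.Generator,
    blank_lead: str | None = None,
) -> SynthRecordTruth:
    """Render one record: jittered RR beat train, linear lead mixing, noise."""
    fs, n = config.fs, int(round(config.duration_s * config.fs))
    components, bounds, r_local = generate_beat(morphology, fs)
    n_local = components["T"].size
    rr0 = 60.0 / heart_rate_bpm * fs  # samples
    sources = np.zeros((n, 3))
    beats: list[BeatFiducials] = []
    # first R placed so the P support starts inside the record
    r_pos = float(r_local) + 0.05 * fs
    while True:
        start = int(round(r_pos)) - r_local
        if start < 0:
            r_pos += rr0
            continue
        if start + n_local > n:
            break
        for w, wave in enumerate(WAVES):
            sources[start : start + n_local, w] += components[wave]
        on_p, off_p = bounds["P"]
        on_q, off_q = bounds["QRS"]
        on_t, off_t = bounds["T"]
        beats.append(
            BeatFiducials(
                r_peak=start + r_local,
                p_on=start + on_p, p_off=start + off_p,
                qrs_on=start + on_q, qrs_off=start + off_q,
                t_on=start + on_t, t_off=start + off_t,
            )
        )
        r_pos += rr0 * (1.0 + config.rr_jitter * rng.uniform(-1, 1))
    clean = sources @ mixing.gains.T + mixing.offsets[None, :]
    samples = clean
    if config.noise_snr_db is not None:
        power = clean.var(axis=0)
        sigma = np.sqrt(power * 10.0 ** (-config.noise_snr_db / 10.0))
        samples = clean + rng.standard_normal(clean.shape) * sigma[None, :]
    samples = samples.copy()
    if blank_lead is not None:
        samples[:, STANDARD_LEADS.index(blank_lead)] = 0.0
    record = ECGRecord(
        record_id=record_id,
        patient_id=patient_id,
        fs=fs,
        lead_names=STANDARD_LEADS,
        samples=samples,
    )
    fiducials = FiducialSet(record_id, fs, beats, source="truth")
    fiducials.validate(n)
    metadata = RecordMetadata(
        patient_id=patient_id,
        is_normal=True,
        condition_flags={c: False for c in CONDITION_NAMES},
        has_blank_lead=blank_lead is not None,
    )
    return SynthRecordTruth(record, fiducials, mixing, metadata, sources)


def generate_cohort(config: SynthConfig) -> Cohort:
    """Generate a cohort of patients (records of one patient share morphology
    and heart rate); metadata rows satisfy the selection criteria by default,
    with switches to inject duplicates, abnormals and blank leads."""
    config.validate()
    mixing = make_mixing(config.mixing_mode, config.disparity)
    root = np.random.SeedSequence(config.seed)
    patient_seqs = root.spawn(config.n_patients)
    items: list[SynthRecordTruth] = []
    lo, hi = config.heart_rate_bpm
    for p, pseq in enumerate(patient_seqs):
        prng = np.random.default_rng(pseq)
        morph = _jittered_morphology(
            config.morphology, prng, config.amp_jitter, config.width_jitter
        )
        hr = prng.uniform(lo, hi)
        record_seqs = pseq.spawn(config.records_per_patient)
        for k, rseq in enumerate(record_seqs):
            items.append(
                generate_record(
                    config,
                    record_id=f"rec{p:05d}_{k}",
                    patient_id=f"pat{p:05d}",
                    morphology=morph,
                    heart_rate_bpm=hr,
                    mixing=mixing,
                    rng=np.random.default_rng(rseq),
                )
            )
    # metadata-injection switches (appended rows violating the criteria)
    extra_seq = root.spawn(1)[0]
    erng = np.random.default_rng(extra_seq)
    n_extra = config.n_duplicate_patients + config.n_abnormal + config.n_blank_leads
    for e in range(n_extra):
        kind = (
            "dup" if e < config.n_duplicate_patients
            else "abn" if e < config.n_duplicate_patients + config.n_abnormal
            else "blank"
        )
        pid = items[e % config.n_patients].record.patient_id if kind == "dup" else f"pat_x{e:03d}"
        item = generate_record(
            config,
            record_id=f"rec_x{e:03d}",
            patient_id=pid,
            morphology=_jittered_morphology(
                config.morphology, erng, config.amp_jitter, config.width_jitter
            ),
            heart_rate_bpm=erng.uniform(lo, hi),
            mixing=mixing,
            rng=erng,
            blank_lead="V6" if kind == "blank" else None,
        )
        if kind == "abn":
            item.metadata.is_normal = False
            flag = CONDITION_NAMES[e % len(CONDITION_NAMES)]
            item.metadata.condition_flags[flag] = True
        items.append(item)
    return Cohort(
        items=items,
        metadata=[it.metadata for it in items],
        mixing=mixing,
        config=config,
    )


def measured_snr_db(clean: np.ndarray, noisy: np.ndarray) -> float:
    """Power-ratio SNR of a noisy signal against its known clean version."""
    noise = np.asarray(noisy) - np.asarray(clean)
    return float(10.0 * np.log10(np.var(clean) / np.var(noise)))


# ---------------------------------------------------------------------------
# on-disk export (same dialects the readers consume)
# ---------------------------------------------------------------------------

def write_cohort(
    cohort: Cohort,
    directory: str | Path,
    *,
    format: str = "csv",
) -> Path:
    """Write records + metadata + truth files (fiducial CSVs, mixing JSON)."""
    import json

    from .delineate import export_fiducials
    from .io import write_metadata_csv, write_record_csv, write_record_wfdb, write_records_hdf5

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if format == "csv":
        for it in cohort.items:
            write_record_csv(it.record, directory / f"{it.record.record_id}.csv")
    elif format == "wfdb":
        for it in cohort.items:
            write_record_wfdb(it.record, directory)
    elif format == "hdf5":
        write_records_hdf5([it.record for it in cohort.items], directory / "tracings.h5")
    else:
        raise ValueError(f"unknown format {format!r}")
    write_metadata_csv(cohort.metadata, directory / "metadata.csv")
    truth_dir = directory / "truth"
    truth_dir.mkdir(exist_ok=True)
    for it in cohort.items:
        export_fiducials(it.fiducials, truth_dir / f"{it.record.record_id}_fiducials.csv")
    (truth_dir / "mixing.json").write_text(
        json.dumps(
            {
                "mode": cohort.mixing.mode,
                "disparity": cohort.mixing.disparity,
                "lead_order": list(STANDARD_LEADS),
                "wave_order": list(WAVES),
                "gains": cohort.mixing.gains.tolist(),
                "offsets": cohort.mixing.offsets.tolist(),
            },
            indent=1,
        )
    )
    return directory
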