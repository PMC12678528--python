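"""Reading, selection and conditioning of multichannel ECG records.

Supported on-disk dialects:

* plain CSV — header row of lead names, one row per time sample, amplitudes in mV;
* WFDB record pairs — ``<name>.hea`` text header plus ``<name>.dat`` 16-bit samples
  (a minimal reader/writer for signal format 16, single .dat file, gain in adu/mV);
* HDF5 containers — a ``tracings`` dataset shaped records x time x leads with a
  ``record_id`` id dataset, plus a companion metadata CSV (CODE-15%-style layout).

All records are held in memory as :class:`ECGRecord` with amplitudes in millivolts,
time measured as ``index / fs`` (0-based sample indices).
"""

from __future__ import annotations

import csv as _csv
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "STANDARD_LEADS",
    "CONDITION_NAMES",
    "ECGRecord",
    "RecordMetadata",
    "DenoiseConfig",
    "load_record",
    "write_record_csv",
    "write_record_wfdb",
    "write_records_hdf5",
    "read_metadata_csv",
    "write_metadata_csv",
    "filter_metadata",
    "trim",
    "resample",
    "denoise",
    "is_blank_lead",
]

STANDARD_LEADS = ("I", "II", "III", "aVR", "aVL", "aVF", "V1", "V2", "V3", "V4", "V5", "V6")

#: Rhythm-condition flags carried by the metadata table (CODE-15% naming).
CONDITION_NAMES = ("1dAVb", "RBBB", "LBBB", "SB", "AF", "ST")

# lower-cased alias -> canonical label
_LEAD_ALIASES = {lead.lower(): lead for lead in STANDARD_LEADS}
_LEAD_ALIASES.update({"avr": "aVR", "avl": "aVL", "avf": "aVF", "i": "I", "ii": "II", "iii": "III"})

#: amplitude below which a lead counts as blank (criterion d fallback), in mV
BLANK_LEAD_THRESHOLD_MV = 1e-6


def _canonical_lead(name: str) -> str:
    key = name.strip().lower()
    if key in _LEAD_ALIASES:
        return _LEAD_ALIASES[key]
    warnings.warn(f"unknown lead label {name!r} kept verbatim", stacklevel=3)
    return name.strip()


@dataclass
class ECGRecord:
    """A multichannel ECG trace in millivolts.

    ``samples`` is (n_samples, n_leads); column order follows ``lead_names``.
    """

    record_id: str
    patient_id: str
    fs: float
    lead_names: tuple[str, ...]
    samples: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.lead_names = tuple(self.lead_names)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (time x leads)")
        if len(self.lead_names) != self.samples.shape[1]:
            raise ValueError(
                f"{len(self.lead_names)} lead names but {self.samples.shape[1]} columns"
            )
        if len(set(self.lead_names)) != len(self.lead_names):
            raise ValueError("lead names must be unique")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def has_leads(self, leads: Sequence[str]) -> bool:
        return all(l in self.lead_names for l in leads)

    def lead(self, name: str) -> np.ndarray:
        """Return one lead's samples (a view, column of ``samples``)."""
        try:
            j = self.lead_names.index(name)
        except ValueError:
            raise KeyError(f"record {self.record_id!r} has no lead {name!r}") from None
        return self.samples[:, j]

    def subset(self, leads: Sequence[str]) -> np.ndarray:
        """Matrix of the requested leads in the requested order."""
        return np.column_stack([self.lead(l) for l in leads])


@dataclass
class RecordMetadata:
    """Selection metadata for one record (one row of the cohort table)."""

    patient_id: str
    is_normal: bool
    condition_flags: dict[str, bool]
    has_blank_lead: bool

    def __post_init__(self) -> None:
        if set(self.condition_flags) != set(CONDITION_NAMES):
            raise ValueError(
                f"condition_flags must have exactly the keys {CONDITION_NAMES}"
            )


@dataclass(frozen=True)
class DenoiseConfig:
    """Zero-phase Butterworth conditioning: highpass removes baseline wander,
    lowpass removes high-frequency noise, optional mains notch."""

    highpass_hz: float = 0.3
    lowpass_hz: float = 100.0
    notch_hz: float | None = None
    order: int = 4
    notch_q: float = 30.0


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def load_record(
    path: str | Path,
    format: str = "csv",
    record_id: str | None = None,
    *,
    fs: float = 500.0,
    patient_id: str | None = None,
) -> ECGRecord:
    """Load one ECG record from disk.

    Parameters
    ----------
    path
        File path (CSV / .hea / HDF5 container depending on ``format``).
    format
        One of ``{"csv", "wfdb", "hdf5"}``.
    record_id
        Required for ``hdf5`` (which record of the container); otherwise defaults
        to the file stem.
    fs
        Sampling rate for dialects that do not store one (CSV); ignored for WFDB.
    """
    path = Path(path)
    if format == "csv":
        return _read_csv_record(path, record_id, fs, patient_id)
    if format == "wfdb":
        return _read_wfdb_record(path, record_id, patient_id)
    if format == "hdf5":
        if record_id is None:
            raise ValueError("record_id is required for hdf5 containers")
        return _read_hdf5_record(path, record_id, fs, patient_id)
    raise ValueError(f"unknown format {format!r}")


def _read_csv_record(path: Path, record_id, fs, patient_id) -> ECGRecord:
    try:
        frame = pd.read_csv(path, dtype=float, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - re-raise as a format error
        raise ValueError(f"could not parse {path} as an ECG CSV: {exc}") from exc
    leads = tuple(_canonical_lead(c) for c in frame.columns)
    return ECGRecord(
        record_id=record_id or path.stem,
        patient_id=patient_id or record_id or path.stem,
        fs=fs,
        lead_names=leads,
        samples=frame.to_numpy(dtype=float),
    )


def write_record_csv(record: ECGRecord, path: str | Path) -> None:
    """Write a record in the package CSV dialect (bit-exact round trip)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = _csv.writer(fh)
        writer.writerow(record.lead_names)
        for row in record.samples:
            writer.writerow([repr(float(v)) for v in row])


# -- minimal WFDB (format 16) ------------------------------------------------

_WFDB_GAIN = 1000.0  # adu per mV
_ADC_MAX = 32767


def write_record_wfdb(record: ECGRecord, directory: str | Path, gain: float = _WFDB_GAIN) -> Path:
    """Write ``<record_id>.hea`` + ``<record_id>.dat`` (format 16, little-endian).

    Amplitudes are quantized to 1/gain mV; the header stores the gain so reads
    recover mV within half a quantization step.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = record.record_id
    adc = np.round(record.samples * gain)
    if np.any(np.abs(adc) > _ADC_MAX):
        raise ValueError("amplitude exceeds int16 range at this gain")
    adc = adc.astype("<i2")
    (directory / f"{name}.dat").write_bytes(adc.tobytes())
    lines = [f"{name} {len(record.lead_names)} {record.fs:g} {record.n_samples}"]
    for j, lead in enumerate(record.lead_names):
        first = int(adc[0, j]) if record.n_samples else 0
        lines.append(f"{name}.dat 16 {gain:g}/mV 16 0 {first} 0 0 {lead}")
    (directory / f"{name}.hea").write_text("\n".join(lines) + "\n")
    return directory / f"{name}.hea"


def _read_wfdb_record(path: Path, record_id, patient_id) -> ECGRecord:
    if path.suffix != ".hea":
        path = path.with_suffix(".hea")
    if not path.exists():
        raise FileNotFoundError(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    name, n_sig, fs = head[0], int(head[1]), float(head[2])
    n_samples = int(head[3]) if len(head) > 3 else None
    leads, gains, dat_files = [], [], []
    for ln in lines[1 : 1 + n_sig]:
        parts = ln.split()
        dat_files.append(parts[0])
        if parts[1] not in {"16", "16+0"}:
            raise ValueError(f"unsupported WFDB signal format {parts[1]!r} (only 16)")
        gain_field = parts[2].split("/")[0].split("(")[0]
        gains.append(float(gain_field) if float(gain_field) != 0 else 200.0)
        leads.append(_canonical_lead(parts[-1]))
    if len(set(dat_files)) != 1:
        raise ValueError("multi-file WFDB records are not supported")
    raw = np.frombuffer((path.parent / dat_files[0]).read_bytes(), dtype="<i2")
    if n_samples is None:
        n_samples = raw.size // n_sig
    raw = raw[: n_samples * n_sig].reshape(n_samples, n_sig).astype(float)
    samples = raw / np.asarray(gains)[None, :]
    return ECGRecord(
        record_id=record_id or name,
        patient_id=patient_id or record_id or name,
        fs=fs,
        lead_names=tuple(leads),
        samples=samples,
    )


# -- HDF5 container ----------------------------------------------------------

def write_records_hdf5(
    records: Sequence[ECGRecord],
    path: str | Path,
    *,
    tracings_key: str = "tracings",
    id_key: str = "record_id",
) -> None:
    """Write records into one container: ``tracings`` (N x T x L) + id dataset.

    All records must share fs, length and lead order.
    """
    import h5py

    if not records:
        raise ValueError("no records to write")
    fs = records[0].fs
    leads = records[0].lead_names
    n = records[0].n_samples
    for r in records:
        if r.fs != fs or r.lead_names != leads or r.n_samples != n:
            raise ValueError("records in one container must share fs, leads and length")
    arr = np.stack([r.samples for r in records])
    with h5py.File(path, "w") as fh:
        dset = fh.create_dataset(tracings_key, data=arr)
        dset.attrs["fs"] = fs
        dset.attrs["units"] = "mV"
        dset.attrs["scale"] = 1.0
        dset.attrs["lead_names"] = ",".join(leads)
        fh.create_dataset(id_key, data=np.array([r.record_id for r in records], dtype="S32"))
        fh.create_dataset("patient_id", data=np.array([r.patient_id for r in records], dtype="S32"))


def _read_hdf5_record(path: Path, record_id: str, fs, patient_id) -> ECGRecord:
    import h5py

    with h5py.File(path, "r") as fh:
        key = "tracings" if "tracings" in fh else next(
            (k for k in fh if getattr(fh[k], "ndim", 0) == 3), None
        )
        if key is None:
            raise ValueError(f"{path} has no 3-D tracings dataset")
        id_key = "record_id" if "record_id" in fh else "exam_id"
        if id_key not in fh:
            raise ValueError(f"{path} has no id dataset")
        ids = [i.decode() if isinstance(i, bytes) else str(i) for i in fh[id_key][...]]
        try:
            idx = ids.index(record_id)
        except ValueError:
            raise KeyError(f"record {record_id!r} not found in {path}") from None
        dset = fh[key]
        scale = float(dset.attrs.get("scale", 1.0))
        samples = np.asarray(dset[idx], dtype=float) * scale
        fs = float(dset.attrs.get("fs", fs))
        lead_attr = dset.attrs.get("lead_names")
        if lead_attr is not None:
            if isinstance(lead_attr, bytes):
                lead_attr = lead_attr.decode()
            leads = tuple(_canonical_lead(l) for l in str(lead_attr).split(","))
        else:
            leads = STANDARD_LEADS[: samples.shape[1]]
        pid = patient_id
        if pid is None and "patient_id" in fh:
            raw_pid = fh["patient_id"][idx]
            pid = raw_pid.decode() if isinstance(raw_pid, bytes) else str(raw_pid)
    return ECGRecord(
        record_id=record_id,
        patient_id=pid or record_id,
        fs=fs,
        lead_names=leads,
        samples=samples,
    )


# -- metadata table ----------------------------------------------------------

_DEFAULT_META_COLUMNS: Mapping[str, str] = {
    "patient_id": "patient_id",
    "is_normal": "is_normal",
    "has_blank_lead": "has_blank_lead",
    **{c: c for c in CONDITION_NAMES},
}


def read_metadata_csv(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> list[RecordMetadata]:
    """Read the companion metadata CSV.

    ``column_map`` maps the canonical field names (``patient_id``, ``is_normal``,
    ``has_blank_lead`` and the six condition names) to the file's column names,
    so CODE-15%-style tables with different headers can be adapted.
    """
    cols = dict(_DEFAULT_META_COLUMNS)
    if column_map:
        cols.update(column_map)
    frame = pd.read_csv(path)
    rows = []
    for _, row in frame.iterrows():
        rows.append(
            RecordMetadata(
                patient_id=str(row[cols["patient_id"]]),
                is_normal=bool(row[cols["is_normal"]]),
                condition_flags={c: bool(row[cols[c]]) for c in CONDITION_NAMES},
                has_blank_lead=bool(row[cols["has_blank_lead"]]),
            )
        )
    return rows


def write_metadata_csv(rows: Sequence[RecordMetadata], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "is_normal": r.is_normal,
                **{c: r.condition_flags[c] for c in CONDITION_NAMES},
                "has_blank_lead": r.has_blank_lead,
            }
            for r in rows
        ]
    )
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# selection and conditioning
# ---------------------------------------------------------------------------

def filter_metadata(meta_rows: Sequence[RecordMetadata]) -> list[int]:
    """Indices of rows passing the cohort selection criteria.

    A row survives iff (a) its patient has not appeared in an earlier kept row,
    (b) the record is categorised normal, (c) all six monitored rhythm-condition
    flags are false, and (d) no lead is blank. Order is preserved.
    """
    kept: list[int] = []
    seen: set[str] = set()
    for i, row in enumerate(meta_rows):
        if row.patient_id in seen:
            continue
        if not row.is_normal:
            continue
        if any(row.condition_flags.values()):
            continue
        if row.has_blank_lead:
            continue
        kept.append(i)
        seen.add(row.patient_id)
    return kept


def is_blank_lead(x: np.ndarray, threshold_mv: float = BLANK_LEAD_THRESHOLD_MV) -> bool:
    """A lead is blank iff max|x| stays below the threshold over the record."""
    return bool(np.max(np.abs(x), initial=0.0) < threshold_mv)


def trim(record: ECGRecord, duration_s: float) -> ECGRecord:
    """Keep the first ``round(duration_s * fs)`` samples of every lead."""
    n_keep = int(round(duration_s * record.fs))
    if record.n_samples < n_keep:
        raise ValueError(
            f"record {record.record_id!r} is {record.duration_s:.3f} s, "
            f"shorter than requested {duration_s} s"
        )
    return replace(record, samples=record.samples[:n_keep].copy())


def resample(record: ECGRecord, target_fs: float) -> ECGRecord:
    """Polyphase rational resampling with anti-aliasing."""
    if target_fs <= 0:
        raise ValueError(f"target_fs must be positive, got {target_fs}")
    if target_fs == record.fs:
        return replace(record, samples=record.samples.copy())
    ratio = Fraction(target_fs / record.fs).limit_denominator(10_000)
    up, down = ratio.numerator, ratio.denominator
    out = sps.resample_poly(record.samples, up, down, axis=0, padtype="line")
    n_expect = int(round(record.n_samples * target_fs / record.fs))
    if out.shape[0] > n_expect:
        out = out[:n_expect]
    elif out.shape[0] < n_expect:
        out = np.pad(out, ((0, n_expect - out.shape[0]), (0, 0)), mode="edge")
    return replace(record, fs=float(target_fs), samples=out)


def denoise(record: ECGRecord, config: DenoiseConfig = DenoiseConfig()) -> ECGRecord:
    """Zero-phase band conditioning (no fiducial shift, linear in the signal)."""
    nyq = record.fs / 2.0
    for cut in (config.highpass_hz, config.lowpass_hz):
        if not 0 < cut < nyq:
            raise ValueError(f"cutoff {cut} Hz outside (0, {nyq}) Hz")
    x = record.samples
    sos_hp = sps.butter(config.order, config.highpass_hz, "highpass", fs=record.fs, output="sos")
    x = sps.sosfiltfilt(sos_hp, x, axis=0)
    if config.lowpass_hz < nyq:
        sos_lp = sps.butter(config.order, config.lowpass_hz, "lowpass", fs=record.fs, output="sos")
        x = sps.sosfiltfilt(sos_lp, x, axis=0)
    if config.notch_hz is not None:
        if not 0 < config.notch_hz < nyq:
            raise ValueError(f"notch {config.notch_hz} Hz outside (0, {nyq}) Hz")
        b, a = sps.iirnotch(config.notch_hz, config.notch_q, fs=record.fs)
        x = sps.filtfilt(b, a, x, axis=0)
    return replace(record, samples=np.ascontiguousarray(x))
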