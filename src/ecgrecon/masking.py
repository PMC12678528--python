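"""Wave masking: isolate P, QRS and T waves by zeroing everything else.

A masked wave channel keeps a source lead's samples inside that wave's
delineated segments and is exactly zero outside them.  The augmented input
stack for reconstruction is the fixed 6-channel ordering

    [P-masked, QRS-masked, T-masked, lead I, lead II, lead V3]

with the default wave-to-lead assignment P from lead II, QRS from lead V3 and
T from lead I.  The assignment is configurable; zero is the only padding value
used for masked regions (a hook exists for alternatives).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .delineate import FiducialSet
from .io import ECGRecord

__all__ = [
    "DEFAULT_WAVE_LEADS",
    "CHANNEL_NAMES",
    "MaskedWave",
    "AugmentedInput",
    "mask_wave",
    "build_augmented_input",
    "write_augmented_csv",
]

WAVES = ("P", "QRS", "T")

#: default wave-to-source-lead assignment
DEFAULT_WAVE_LEADS: Mapping[str, str] = {"P": "II", "QRS": "V3", "T": "I"}

#: fixed channel order of the augmented input
CHANNEL_NAMES = ("P_masked", "QRS_masked", "T_masked", "I", "II", "V3")


def mask_wave(
    signal: np.ndarray,
    segments: Sequence[tuple[int, int]],
    *,
    pad_value: float = 0.0,
) -> np.ndarray:
    """Zero (or ``pad_value``-fill) every sample outside the given segments.

    Segments are half-open ``[on, off)`` index intervals; they must lie within
    the signal and be pairwise disjoint.
    """
    signal = np.asarray(signal, dtype=float)
    n = signal.shape[0]
    out = np.full_like(signal, pad_value)
    prev_off = -1
    for on, off in sorted(segments):
        if not (0 <= on < off <= n):
            raise ValueError(f"segment [{on}, {off}) outside [0, {n})")
        if on < prev_off:
            raise ValueError(f"segment [{on}, {off}) overlaps a previous segment")
        out[on:off] = signal[on:off]
        prev_off = off
    return out


@dataclass
class MaskedWave:
    """One wave isolated from one source lead."""

    wave: str
    source_lead: str
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.wave not in WAVES:
            raise ValueError(f"wave must be one of {WAVES}, got {self.wave!r}")


@dataclass
class AugmentedInput:
    """The 6-channel wave-masked input stack for one record."""

    record_id: str
    channels: np.ndarray  # (n_samples, 6)
    channel_names: tuple[str, ...] = CHANNEL_NAMES

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 2 or self.channels.shape[1] != len(self.channel_names):
            raise ValueError(
                f"channels must be (n, {len(self.channel_names)}), got {self.channels.shape}"
            )

    def to_matrix(self) -> np.ndarray:
        return self.channels


def _clipped_segments(fiducials: FiducialSet, wave: str, n: int) -> list[tuple[int, int]]:
    out = []
    for on, off in fiducials.segments(wave):
        on, off = max(on, 0), min(off, n)
        if off > on:
            out.append((on, off))
    return out


def build_augmented_input(
    record: ECGRecord,
    fiducials: FiducialSet,
    wave_leads: Mapping[str, str] = DEFAULT_WAVE_LEADS,
    *,
    pad_value: float = 0.0,
) -> AugmentedInput:
    """Assemble [P-masked, QRS-masked, T-masked, I, II, V3] for one record.

    Beats whose P or T could not be delineated contribute no segment (the
    masked channel stays at the padding value there).  The three raw channels
    are passed through bit-exactly.
    """
    raw_leads = ("I", "II", "V3")
    needed = set(raw_leads) | set(wave_leads.values())
    missing = [l for l in sorted(needed) if l not in record.lead_names]
    if missing:
        raise KeyError(f"record {record.record_id!r} lacks required leads {missing}")
    n = record.n_samples
    upper = max(
        (off for w in WAVES for _, off in fiducials.segments(w)),
        default=0,
    )
    if upper > n:
        raise ValueError(
            f"fiducials extend to sample {upper} but record has {n} samples"
        )
    cols = []
    for wave in WAVES:
        src = record.lead(wave_leads[wave])
        segments = _clipped_segments(fiducials, wave, n)
        cols.append(mask_wave(src, segments, pad_value=pad_value))
    for lead in raw_leads:
        cols.append(record.lead(lead))
    return AugmentedInput(record_id=record.record_id, channels=np.column_stack(cols))


def write_augmented_csv(augmented: AugmentedInput, path: str | Path) -> None:
    """Serialize the augmented stack in the record CSV dialect."""
    import csv as _csv

    with Path(path).open("w", newline="") as fh:
        writer = _csv.writer(fh)
        writer.writerow(augmented.channel_names)
        for row in augmented.channels:
            writer.writerow([repr(float(v)) for v in row])
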