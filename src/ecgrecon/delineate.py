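"""P/QRS/T delineation from a reduced lead set (I, II, V3).

R peaks are detected with a Pan–Tompkins-style detector (band-pass, derivative,
square, moving-window integration, refractory period). Around each R peak, QRS,
P and T boundaries are located by a two-stage outward walk from the wave peak:
a coarse sustained crossing at 5% of the wave's peak amplitude followed by an
extension toward a low return-to-baseline threshold (noise-adaptive floor), so
that on clean signals the boundary lands where the wave genuinely vanishes.

Each of the three leads is delineated independently; per-beat fiducials are
fused by matching beats on R-peak proximity and taking the per-fiducial median
across leads. QRS has priority in overlap repair.

Intervals are half-open ``[on, off)`` in 0-based sample indices.
"""

from __future__ import annotations

import csv as _csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .io import ECGRecord

__all__ = [
    "ABSENT",
    "BeatFiducials",
    "FiducialSet",
    "detect_r_peaks",
    "delineate",
    "import_fiducials",
    "export_fiducials",
]

#: marker for a fiducial that could not be located
ABSENT = None

DEFAULT_INPUT_LEADS = ("I", "II", "V3")

_FIDUCIAL_FIELDS = ("p_on", "p_off", "qrs_on", "qrs_off", "t_on", "t_off")


@dataclass
class BeatFiducials:
    """Sample indices of one beat's wave boundaries (ABSENT when not found)."""

    r_peak: int
    p_on: int | None = ABSENT
    p_off: int | None = ABSENT
    qrs_on: int | None = ABSENT
    qrs_off: int | None = ABSENT
    t_on: int | None = ABSENT
    t_off: int | None = ABSENT

    def validate(self, n_samples: int | None = None) -> None:
        pairs = [("p_on", "p_off"), ("qrs_on", "qrs_off"), ("t_on", "t_off")]
        for on_name, off_name in pairs:
            on, off = getattr(self, on_name), getattr(self, off_name)
            if (on is ABSENT) != (off is ABSENT):
                raise ValueError(f"{on_name}/{off_name} must be both present or both absent")
            if on is not ABSENT and not on < off:
                raise ValueError(f"{on_name}={on} must be < {off_name}={off}")
        seq = [self.p_on, self.p_off, self.qrs_on, self.qrs_off, self.t_on, self.t_off]
        present = [v for v in seq if v is not ABSENT]
        if any(b < a for a, b in zip(present, present[1:])):
            raise ValueError(f"fiducials out of order: {seq}")
        if self.qrs_on is not ABSENT and not self.qrs_on <= self.r_peak < self.qrs_off:
            raise ValueError(
                f"r_peak={self.r_peak} outside QRS [{self.qrs_on}, {self.qrs_off})"
            )
        if n_samples is not None:
            for name in ("r_peak", *_FIDUCIAL_FIELDS):
                v = getattr(self, name)
                if v is not ABSENT and not 0 <= v <= n_samples:
                    raise ValueError(f"{name}={v} outside [0, {n_samples}]")

    def segments(self, wave: str) -> list[tuple[int, int]]:
        on, off = {
            "P": (self.p_on, self.p_off),
            "QRS": (self.qrs_on, self.qrs_off),
            "T": (self.t_on, self.t_off),
        }[wave]
        return [] if on is ABSENT else [(int(on), int(off))]

    @property
    def complete(self) -> bool:
        return all(getattr(self, f) is not ABSENT for f in _FIDUCIAL_FIELDS)


@dataclass
class FiducialSet:
    """All beats' fiducials for one record."""

    record_id: str
    fs: float
    beats: list[BeatFiducials]
    source: str = "internal"  # internal | imported | truth

    def validate(self, n_samples: int | None = None) -> None:
        r = [b.r_peak for b in self.beats]
        if any(b >= a for a, b in zip(r[1:], r)):
            raise ValueError("beats must be ordered by strictly increasing r_peak")
        last_end = -1
        for i, beat in enumerate(self.beats):
            try:
                beat.validate(n_samples)
            except ValueError as exc:
                raise ValueError(f"beat {i}: {exc}") from exc
            start = min(
                (getattr(beat, f) for f in _FIDUCIAL_FIELDS if getattr(beat, f) is not ABSENT),
                default=beat.r_peak,
            )
            if start < last_end:
                raise ValueError(f"beat {i} overlaps the previous beat")
            last_end = max(
                (getattr(beat, f) for f in _FIDUCIAL_FIELDS if getattr(beat, f) is not ABSENT),
                default=beat.r_peak,
            )

    def segments(self, wave: str) -> list[tuple[int, int]]:
        out: list[tuple[int, int]] = []
        for beat in self.beats:
            out.extend(beat.segments(wave))
        return out


# ---------------------------------------------------------------------------
# R-peak detection
# ---------------------------------------------------------------------------

def detect_r_peaks(
    x: np.ndarray,
    fs: float,
    *,
    refractory_s: float = 0.2,
    band: tuple[float, float] = (5.0, 15.0),
) -> list[int]:
    """Pan–Tompkins-style R-peak detection on a single lead.

    Band-pass 5–15 Hz, differentiate, square, integrate over a 150 ms window,
    threshold at a fraction of the integrated envelope's upper percentile, then
    refine each detection to the absolute extremum of the raw signal nearby.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2 * fs:
        raise ValueError("need at least 2 s of signal for R detection")
    if np.ptp(x) == 0:
        warnings.warn("constant signal: no R peaks detectable", stacklevel=2)
        return []
    sos = sps.butter(2, band, "bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    deriv = np.gradient(bp)
    sq = deriv**2
    win = max(1, int(round(0.150 * fs)))
    integ = np.convolve(sq, np.ones(win) / win, mode="same")
    height = 0.2 * np.percentile(integ, 99)
    if height <= 0:
        warnings.warn("flat envelope: no R peaks detectable", stacklevel=2)
        return []
    distance = max(1, int(round(refractory_s * fs)))
    cand, _ = sps.find_peaks(integ, height=height, distance=distance)
    half = max(1, int(round(0.06 * fs)))
    peaks: list[int] = []
    for c in cand:
        lo, hi = max(0, c - half), min(x.size, c + half + 1)
        r = lo + int(np.argmax(np.abs(x[lo:hi])))
        if not peaks or r - peaks[-1] >= distance:
            peaks.append(r)
        elif np.abs(x[r]) > np.abs(x[peaks[-1]]):
            peaks[-1] = r
    return peaks


# ---------------------------------------------------------------------------
# single-lead delineation
# ---------------------------------------------------------------------------

def _estimate_baseline(x: np.ndarray) -> float:
    """Mode-based baseline level: the quiet (isoelectric) segments form the
    tallest cluster of the amplitude histogram, even when waves occupy more
    than half of the record (which biases a plain median)."""
    lo, hi = np.percentile(x, [1.0, 99.0])
    if hi <= lo:
        return float(np.median(x))
    hist, edges = np.histogram(x, bins=101, range=(lo, hi))
    j = int(np.argmax(hist))
    width = edges[1] - edges[0]
    center = 0.5 * (edges[j] + edges[j + 1])
    sel = np.abs(x - center) <= width
    return float(np.median(x[sel])) if np.any(sel) else float(center)


def _noise_floor(x_abs: np.ndarray) -> float:
    """Noise scale from the quietest quarter of the (baseline-removed) record:
    exactly 0 for clean synthetic baselines, roughly the noise sigma otherwise
    (the factor compensates the truncation of the half-normal tail)."""
    q = np.percentile(x_abs, 25.0)
    quiet = x_abs[x_abs <= q]
    return float(quiet.std() * 10.0) if quiet.size else 0.0


def _scan_boundary(
    x_abs: np.ndarray,
    start: int,
    direction: int,
    tol: float,
    run_len: int,
    lo: int,
    hi: int,
) -> int:
    """Walk from ``start`` until ``run_len`` consecutive samples fall below
    ``tol``; return the last above-tolerance index seen (the wave boundary)."""
    i = start
    run = 0
    last_above = start
    while lo <= i < hi:
        if x_abs[i] < tol:
            run += 1
            if run >= run_len:
                return last_above
        else:
            run = 0
            last_above = i
        i += direction
    return last_above


def _walk_boundary(
    seg_abs: np.ndarray,
    peak_idx: int,
    direction: int,
    peak_amp: float,
    noise: float,
    run_len: int,
) -> int:
    """Walk outward from ``peak_idx``; return the boundary index inside seg.

    Coarse stage: first sustained run (>= run_len) below 5% of the peak.
    Fine stage: from there, continue while below the coarse threshold, and
    remember the last position preceding a sustained run below the fine
    (return-to-baseline) threshold.
    """
    coarse = max(0.05 * peak_amp, 2.0 * noise)
    fine = max(5e-4 * peak_amp, 2.0 * noise, 1e-12)
    n = seg_abs.size
    i = peak_idx
    run = 0
    coarse_end = None
    while 0 <= i < n:
        if seg_abs[i] < coarse:
            run += 1
            if run >= run_len:
                coarse_end = i - direction * (run_len - 1)
                break
        else:
            run = 0
        i += direction
    if coarse_end is None:
        return 0 if direction < 0 else n - 1
    # fine extension: keep walking while we stay below the coarse threshold;
    # boundary is just inside the first sustained run below `fine`
    i = coarse_end
    run = 0
    boundary = coarse_end
    while 0 <= i < n and seg_abs[i] < coarse:
        if seg_abs[i] < fine:
            run += 1
            if run >= run_len:
                return i - direction * (run_len - 1) - direction
        else:
            run = 0
            boundary = i
        i += direction
    return boundary


def _delineate_lead(
    x: np.ndarray,
    fs: float,
    r_peaks: Sequence[int],
    *,
    pr_window_s: float = 0.2,
    t_frac_rr: float = 0.6,
    p_min_rel_amp: float = 0.05,
) -> list[BeatFiducials]:
    x = np.asarray(x, dtype=float)
    x = x - _estimate_baseline(x)
    n = x.size
    x_abs = np.abs(x)
    noise = _noise_floor(x_abs)
    run_len = max(1, int(round(0.006 * fs)))
    beats: list[BeatFiducials] = []
    r_peaks = list(r_peaks)
    med_rr = float(np.median(np.diff(r_peaks))) if len(r_peaks) > 1 else 0.8 * fs
    for k, r in enumerate(r_peaks):
        beat = BeatFiducials(r_peak=int(r))
        # QRS bounds: walk outward from R until a sustained quiet run — the
        # isoelectric gaps before Q and after S trigger it, while the brief
        # near-zero dips between Q/R/S (single zero crossings) do not
        qrs_half = int(round(0.20 * fs))
        lo, hi = max(0, r - qrs_half), min(n, r + qrs_half + 1)
        peak_amp = x_abs[r]
        tol = max(5e-4 * peak_amp, 3.0 * noise, 1e-12)
        qrs_run = max(2, int(round(0.008 * fs)))
        beat.qrs_on = int(_scan_boundary(x_abs, r, -1, tol, qrs_run, lo, hi))
        beat.qrs_off = int(_scan_boundary(x_abs, r, +1, tol, qrs_run, lo, hi)) + 1
        # P wave: dominant extremum in the PR window before qrs_on
        p_lo = max(0, beat.qrs_on - int(round(pr_window_s * fs)))
        p_hi = beat.qrs_on
        _find_wave(beat, "p", x, x_abs, p_lo, p_hi, peak_amp, p_min_rel_amp, noise, run_len)
        # T wave: after qrs_off, up to a fraction of the local RR interval
        rr = (r_peaks[k + 1] - r) if k + 1 < len(r_peaks) else med_rr
        t_lo = beat.qrs_off
        t_hi = min(n, beat.qrs_off + int(round(t_frac_rr * rr)))
        _find_wave(beat, "t", x, x_abs, t_lo, t_hi, peak_amp, p_min_rel_amp, noise, run_len)
        beats.append(beat)
    return beats


def _find_wave(beat, prefix, x, x_abs, lo, hi, r_amp, min_rel, noise, run_len) -> None:
    if hi - lo < 2:
        return
    seg = x_abs[lo:hi]
    pk = int(np.argmax(seg))
    amp = seg[pk]
    if amp < max(min_rel * r_amp, 3.0 * noise) or amp <= 0:
        return
    on = lo + _walk_boundary(seg, pk, -1, amp, noise, run_len)
    off = lo + _walk_boundary(seg, pk, +1, amp, noise, run_len)
    if off <= on:
        return
    setattr(beat, f"{prefix}_on", int(on))
    setattr(beat, f"{prefix}_off", int(off) + 1)


# ---------------------------------------------------------------------------
# multi-lead fusion
# ---------------------------------------------------------------------------

def delineate(
    record: ECGRecord,
    input_leads: Sequence[str] = DEFAULT_INPUT_LEADS,
    *,
    match_tol_s: float = 0.15,
) -> FiducialSet:
    """Delineate a record using only ``input_leads`` and fuse per-lead results.

    Beats are anchored on the lead with the most detections; beats in other
    leads are matched by nearest R peak within ``match_tol_s``; each fiducial is
    the median across leads where it was found.
    """
    missing = [l for l in input_leads if l not in record.lead_names]
    if missing:
        raise KeyError(f"record {record.record_id!r} lacks required leads {missing}")
    per_lead: list[list[BeatFiducials]] = []
    for lead in input_leads:
        x = record.lead(lead)
        try:
            r_peaks = detect_r_peaks(x, record.fs)
        except ValueError:
            r_peaks = []
        per_lead.append(_delineate_lead(x, record.fs, r_peaks))
    anchor = max(range(len(per_lead)), key=lambda i: len(per_lead[i]))
    tol = match_tol_s * record.fs
    fused: list[BeatFiducials] = []
    for ref_beat in per_lead[anchor]:
        group = [ref_beat]
        for j, beats in enumerate(per_lead):
            if j == anchor or not beats:
                continue
            nearest = min(beats, key=lambda b: abs(b.r_peak - ref_beat.r_peak))
            if abs(nearest.r_peak - ref_beat.r_peak) <= tol:
                group.append(nearest)
        fused.append(_median_beat(group))
    fused = _repair(fused, record.n_samples)
    fs_set = FiducialSet(record.record_id, record.fs, fused, source="internal")
    fs_set.validate(record.n_samples)
    return fs_set


def _median_beat(group: list[BeatFiducials]) -> BeatFiducials:
    def med(name: str) -> int | None:
        vals = [getattr(b, name) for b in group if getattr(b, name) is not ABSENT]
        return int(round(float(np.median(vals)))) if vals else ABSENT

    return BeatFiducials(
        r_peak=int(round(float(np.median([b.r_peak for b in group])))),
        **{f: med(f) for f in _FIDUCIAL_FIELDS},
    )


def _repair(beats: list[BeatFiducials], n: int) -> list[BeatFiducials]:
    """Clip fused fiducials so the ordering/overlap invariants hold.

    QRS has priority: P offsets are clipped to the QRS onset and T onsets to
    the QRS offset; every fiducial is clamped to the previous beat's trailing
    edge, and intervals emptied by clipping become ABSENT.
    """
    beats = sorted(beats, key=lambda b: b.r_peak)
    out: list[BeatFiducials] = []
    prev_end = 0
    for b in beats:
        if out and b.r_peak <= out[-1].r_peak:
            continue
        if b.r_peak < prev_end or b.r_peak >= n:
            continue  # beat swallowed by the previous beat's waves
        for name in _FIDUCIAL_FIELDS:
            v = getattr(b, name)
            if v is not ABSENT:
                setattr(b, name, int(min(max(v, prev_end), n)))
        if b.qrs_on is not ABSENT:
            b.qrs_on = max(min(b.qrs_on, b.r_peak), prev_end)
            b.qrs_off = min(max(b.qrs_off, b.r_peak + 1), n)
        if b.p_on is not ABSENT and b.qrs_on is not ABSENT:
            b.p_off = min(b.p_off, b.qrs_on)
        if b.t_on is not ABSENT and b.qrs_off is not ABSENT:
            b.t_on = max(b.t_on, b.qrs_off)
            b.t_off = max(b.t_off, b.t_on)
        for on_name, off_name in (("p_on", "p_off"), ("t_on", "t_off")):
            on, off = getattr(b, on_name), getattr(b, off_name)
            if on is not ABSENT and off <= on:
                setattr(b, on_name, ABSENT)
                setattr(b, off_name, ABSENT)
        prev_end = max(
            [getattr(b, f) for f in _FIDUCIAL_FIELDS if getattr(b, f) is not ABSENT]
            + [b.r_peak + 1]
        )
        out.append(b)
    return out


# ---------------------------------------------------------------------------
# external fiducials (CSV dialect)
# ---------------------------------------------------------------------------

_CSV_HEADER = ["beat", "p_on", "p_off", "qrs_on", "qrs_off", "t_on", "t_off", "r_peak"]


def export_fiducials(fiducials: FiducialSet, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = _csv.writer(fh)
        writer.writerow(_CSV_HEADER)
        for i, b in enumerate(fiducials.beats):
            row = [i]
            for name in _FIDUCIAL_FIELDS:
                v = getattr(b, name)
                row.append("" if v is ABSENT else v)
            row.append(b.r_peak)
            writer.writerow(row)


def import_fiducials(path: str | Path, record: ECGRecord) -> FiducialSet:
    """Read externally produced fiducials (e.g. an ECGdeli export) and validate
    them against the record."""
    beats: list[BeatFiducials] = []
    with Path(path).open() as fh:
        reader = _csv.DictReader(fh)
        if reader.fieldnames != _CSV_HEADER:
            raise ValueError(
                f"unexpected fiducial CSV header {reader.fieldnames}, want {_CSV_HEADER}"
            )
        for row in reader:
            def parse(key: str) -> int | None:
                v = row[key].strip()
                return ABSENT if v == "" else int(v)

            beat = BeatFiducials(
                r_peak=int(row["r_peak"]),
                **{f: parse(f) for f in _FIDUCIAL_FIELDS},
            )
            try:
                beat.validate(record.n_samples)
            except ValueError as exc:
                raise ValueError(f"beat {row['beat']}: {exc}") from exc
            beats.append(beat)
    fs_set = FiducialSet(record.record_id, record.fs, beats, source="imported")
    fs_set.validate(record.n_samples)
    return fs_set
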