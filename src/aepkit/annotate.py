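"""Windowed-extremum annotation of AEP waves and the long-format metric table.

Each wave of interest is located as the extremum of the correct polarity
(peaks I, III, V, Pa, Pb are maxima; troughs Na, Nb are minima) inside a
configurable latency window.  Waves are searched greedily left to right in
canonical order, each window truncated to start after the previously found
wave, which enforces the physiological ordering I < III < V and
Na < Pa < Nb < Pb.  A wave is reported as not found when the window
contains no strict local extremum of the correct polarity (flat or
monotone segments never produce an annotation); an equal-valued plateau is
annotated at its earliest sample.

Latency = extremum sample index / fs x 1000 (ms from stimulus onset);
amplitude = the signed signal value at the extremum in µV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .errors import ConfigurationError, IntegrityError
from .records import AEPRecord

#: Default search windows in ms, following the standard physiological
#: ranges (ABR waves within the first 10 ms, AMLR components at ~12-60 ms).
DEFAULT_WINDOWS = {
    "ABR": {"I": (1.0, 2.5), "III": (3.0, 4.8), "V": (4.8, 7.5)},
    "AMLR": {"Na": (12.0, 25.0), "Pa": (25.0, 40.0),
             "Nb": (35.0, 52.0), "Pb": (45.0, 80.0)},
}

#: +1 for peaks (local maxima), -1 for troughs (local minima).
POLARITY = {"I": 1, "III": 1, "V": 1, "Na": -1, "Pa": 1, "Nb": -1, "Pb": 1}

CANONICAL_ORDER = {"ABR": ("I", "III", "V"), "AMLR": ("Na", "Pa", "Nb", "Pb")}


@dataclass(frozen=True)
class WaveAnnotation:
    latency_ms: float
    amplitude_uv: float
    found: bool


@dataclass
class WaveAnnotationSet:
    """Annotations for one record, keyed by wave label."""

    record_id: str
    patient_id: str
    ear: str
    subtype: str
    entries: dict  # label -> WaveAnnotation

    def found_labels(self) -> list[str]:
        return [k for k, v in self.entries.items() if v.found]


def _local_maxima(xp: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima of ``xp``, plateaus at their earliest
    sample.

    An index qualifies when the nearest unequal values on *both* sides are
    strictly smaller; monotone ramps, signal endpoints, and flat segments
    never qualify.
    """
    n = len(xp)
    # collapse plateaus: compare each run of equal values with its flanks
    starts = np.flatnonzero(np.r_[True, xp[1:] != xp[:-1]])
    run_vals = xp[starts]
    out = []
    for k in range(1, len(starts) - 1):
        if run_vals[k] > run_vals[k - 1] and run_vals[k] > run_vals[k + 1]:
            out.append(starts[k])
    return np.asarray(out, dtype=int)


def _find_extremum(x: np.ndarray, lo: int, hi: int, polarity: int):
    """Largest strict local extremum of the given polarity in ``[lo, hi]``.

    Returns the sample index (earliest on exact ties), or None when the
    window holds no strict local extremum of that polarity — the leading
    edge of a later wave entering through the window boundary is a monotone
    ramp there, not an extremum, so it can never masquerade as a wave.
    """
    if hi < lo:
        return None
    xp = polarity * x
    cand = _local_maxima(xp)
    cand = cand[(cand >= lo) & (cand <= hi)]
    if len(cand) == 0:
        return None
    return int(cand[np.argmax(xp[cand])])


def annotate_record(record: AEPRecord, windows: dict | None = None, *,
                    smooth_hz: float | None = None) -> WaveAnnotationSet:
    """Locate this record's waves of interest.

    Parameters
    ----------
    record
        A validated :class:`AEPRecord`.
    windows
        Per-label ``(lo_ms, hi_ms)`` windows; defaults per subtype.
    smooth_hz
        Optional zero-phase low-pass corner applied before detection
        (off by default; annotation never alters the stored waveform).
    """
    windows = windows if windows is not None else DEFAULT_WINDOWS[record.subtype]
    known = set(POLARITY)
    unknown = set(windows) - known
    if unknown:
        raise ConfigurationError(f"unknown wave label(s) {sorted(unknown)}")
    duration = record.duration_ms
    for label, (lo, hi) in windows.items():
        if not (0 <= lo < hi <= duration):
            raise ConfigurationError(
                f"window {label} = ({lo}, {hi}) ms outside the record's "
                f"{duration:.1f} ms analysis time")

    x = record.samples
    if smooth_hz is not None:
        b, a = butter(4, smooth_hz, fs=record.fs_hz)
        x = filtfilt(b, a, x)

    ms_per_sample = 1000.0 / record.fs_hz
    entries: dict[str, WaveAnnotation] = {}
    prev_idx = -1
    for label in CANONICAL_ORDER[record.subtype]:
        if label not in windows:
            continue
        lo_ms, hi_ms = windows[label]
        lo = max(int(np.ceil(lo_ms / ms_per_sample)), prev_idx + 1)
        hi = min(int(np.floor(hi_ms / ms_per_sample)), record.n_samples - 1)
        idx = _find_extremum(x, lo, hi, POLARITY[label])
        if idx is None:
            entries[label] = WaveAnnotation(np.nan, np.nan, False)
        else:
            entries[label] = WaveAnnotation(idx * ms_per_sample,
                                            float(record.samples[idx]), True)
            prev_idx = idx
    return WaveAnnotationSet(record_id=record.record_id,
                             patient_id=record.patient_id, ear=record.ear,
                             subtype=record.subtype, entries=entries)


def annotate_records(records, windows: dict | None = None, **kwargs):
    return [annotate_record(r, windows, **kwargs) for r in records]


def metrics_table(annotations) -> pd.DataFrame:
    """Long-format metric table: one row per (record, wave, metric).

    Columns: record_id, patient_id, ear, subtype, wave, metric, value,
    found.  Metrics are ``latency`` (ms) and ``amplitude`` (µV); a wave
    that was not found carries ``value = NaN`` and ``found = False`` —
    never a zero.
    """
    annotations = list(annotations)
    seen: set[str] = set()
    rows = []
    for ann in annotations:
        if ann.record_id in seen:
            raise IntegrityError(f"duplicate record_id {ann.record_id!r}")
        seen.add(ann.record_id)
        for label in CANONICAL_ORDER[ann.subtype]:
            if label not in ann.entries:
                continue
            e = ann.entries[label]
            for metric, value in (("latency", e.latency_ms),
                                  ("amplitude", e.amplitude_uv)):
                rows.append((ann.record_id, ann.patient_id, ann.ear,
                             ann.subtype, label, metric,
                             value if e.found else np.nan, e.found))
    return pd.DataFrame(rows, columns=["record_id", "patient_id", "ear",
                                       "subtype", "wave", "metric", "value",
                                       "found"])
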