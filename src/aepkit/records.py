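"""Domain types for auditory evoked potential (AEP) recordings.

An :class:`AEPRecord` holds one ear's averaged evoked-potential waveform as a
voltage series in microvolts together with its sampling rate and stimulus
metadata.  Two subtypes are supported:

* ``ABR`` — auditory brainstem response: click stimulus, 30 kHz sampling,
  450 samples (15 ms analysis window), waves I–V.
* ``AMLR`` — auditory middle latency response: 2 kHz tone-burst stimulus,
  3 kHz sampling, 450 samples (150 ms window), waves Na/Pa/Nb/Pb.

Latency conventions used throughout the package: the stimulus occurs at
sample index 0, and the latency of sample ``k`` is ``k / fs_hz * 1000`` ms.
Voltages are stored in µV everywhere (clinical convention — AEP wave
amplitudes are below one microvolt).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

logger = logging.getLogger(__name__)

EARS = ("left", "right")
SUBTYPES = ("ABR", "AMLR")

#: Conventional acquisition defaults per subtype: sampling rate and length.
SUBTYPE_DEFAULTS = {
    "ABR": {"fs_hz": 30000.0, "n_samples": 450},
    "AMLR": {"fs_hz": 3000.0, "n_samples": 450},
}


@dataclass(frozen=True)
class StimulusConfig:
    """Stimulus and acquisition-filter settings for one recording."""

    stimulus_type: str  # "click" or "tone_burst"
    rate_hz: float  # stimuli per second
    intensity_db_nhl: float
    highpass_hz: float
    lowpass_hz: float

    def __post_init__(self) -> None:
        if self.stimulus_type not in ("click", "tone_burst"):
            raise ValidationError(
                f"stimulus_type must be 'click' or 'tone_burst', got {self.stimulus_type!r}"
            )
        if self.rate_hz <= 0:
            raise ValidationError(f"stimulus rate must be positive, got {self.rate_hz}")


#: Standard protocol defaults (click 22/s at 80 dB nHL for ABR; 2 kHz tone
#: burst 6.1/s at 70 dB nHL for AMLR; acquisition band corners as recorded).
DEFAULT_STIMULUS = {
    "ABR": StimulusConfig("click", 22.0, 80.0, 33.0, 1500.0),
    "AMLR": StimulusConfig("tone_burst", 6.1, 70.0, 10.0, 1500.0),
}


@dataclass
class AEPRecord:
    """One ear's evoked-potential waveform with sampling metadata.

    Parameters
    ----------
    record_id, patient_id
        Opaque identifiers.
    ear
        ``"left"`` or ``"right"``.
    subtype
        ``"ABR"`` or ``"AMLR"``.
    fs_hz
        Sampling rate in Hz.
    samples
        Voltage series in µV, stimulus onset at index 0.
    stimulus
        Stimulus/acquisition settings; subtype default when omitted.
    """

    record_id: str
    patient_id: str
    ear: str
    subtype: str
    fs_hz: float
    samples: np.ndarray
    stimulus: StimulusConfig = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.subtype not in SUBTYPES:
            raise ValidationError(
                f"record {self.record_id!r}: subtype must be one of {SUBTYPES}, got {self.subtype!r}"
            )
        if self.ear not in EARS:
            raise ValidationError(
                f"record {self.record_id!r}: ear must be one of {EARS}, got {self.ear!r}"
            )
        if self.stimulus is None:
            self.stimulus = DEFAULT_STIMULUS[self.subtype]
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.validate()
        self._notice_deviation()

    def validate(self) -> None:
        if not np.isfinite(self.fs_hz) or self.fs_hz <= 0:
            raise ValidationError(
                f"record {self.record_id!r}: fs_hz must be positive, got {self.fs_hz}"
            )
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValidationError(
                f"record {self.record_id!r}: samples must be a non-empty 1-D series"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError(
                f"record {self.record_id!r}: samples contain non-finite values"
            )

    def _notice_deviation(self) -> None:
        # Deviations from the subtype's acquisition defaults are allowed but
        # must never pass silently.
        ref = SUBTYPE_DEFAULTS[self.subtype]
        if self.fs_hz != ref["fs_hz"] or self.samples.size != ref["n_samples"]:
            logger.info(
                "record %s: non-default acquisition for %s (fs=%g Hz, %d samples; "
                "default fs=%g Hz, %d samples)",
                self.record_id, self.subtype, self.fs_hz, self.samples.size,
                ref["fs_hz"], ref["n_samples"],
            )

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_ms(self) -> float:
        """Analysis duration in ms (length / fs × 1000)."""
        return self.n_samples / self.fs_hz * 1000.0

    def time_ms(self) -> np.ndarray:
        """Latency of each sample in ms from stimulus onset."""
        return np.arange(self.n_samples) / self.fs_hz * 1000.0

    def truncated(self, n_samples: int) -> "AEPRecord":
        """Copy of this record truncated to its first ``n_samples`` samples.

        Used as an explicit preprocessing step when an analysis requires a
        shorter window than was acquired; the truncation is recorded in the
        log rather than applied silently.
        """
        if not 0 < n_samples <= self.n_samples:
            raise ValidationError(
                f"record {self.record_id!r}: cannot truncate {self.n_samples} "
                f"samples to {n_samples}"
            )
        logger.info("record %s: truncated from %d to %d samples",
                    self.record_id, self.n_samples, n_samples)
        return AEPRecord(
            record_id=self.record_id,
            patient_id=self.patient_id,
            ear=self.ear,
            subtype=self.subtype,
            fs_hz=self.fs_hz,
            samples=self.samples[:n_samples].copy(),
            stimulus=self.stimulus,
        )
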