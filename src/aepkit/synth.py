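"""Synthetic AEP cohorts with controllable group effects.

The generator emulates the statistical structure the downstream analysis
assumes: every patient contributes one ABR and one AMLR waveform per ear;
each waveform is a sum of Gaussian bumps (one per wave) plus additive
noise; a high-distress group (THI >= 48) differs from the low-distress
group by configurable per-wave latency and amplitude shifts and by mean
shifts on selected clinical covariates.

Default wave templates are literature-typical nominal values (the defaults
live in configuration, not in code paths): ABR waves I/III/V at
1.6/3.9/5.6 ms with 0.30/0.30/0.45 µV peaks (plus small unannotated II/IV
bumps), AMLR Na/Pa/Nb/Pb at 18/30/42/55 ms with -0.8/+1.0/-0.7/+0.6 µV.
Default group effects follow the directionality reported for tinnitus
distress: high-distress ABR waves arrive slightly *earlier* with *larger*
amplitudes; high-distress AMLR waves arrive *later* with larger absolute
amplitudes.

Each ear is drawn independently (no patient-level random effect on wave
morphology): ear-level group comparisons are then exactly calibrated
tests, at the cost of not modelling between-ear correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .records import AEPRecord, SUBTYPE_DEFAULTS

WAVES = {"ABR": ("I", "II", "III", "IV", "V"),
         "AMLR": ("Na", "Pa", "Nb", "Pb")}
#: Waves annotated and analysed downstream (II and IV are generated but not
#: scored, mirroring clinical practice of reporting I, III and V).
ANALYSIS_WAVES = {"ABR": ("I", "III", "V"), "AMLR": ("Na", "Pa", "Nb", "Pb")}


@dataclass(frozen=True)
class WaveTemplate:
    """Nominal Gaussian bump for one wave: centre, signed peak, width."""

    label: str
    latency_ms: float
    amplitude_uv: float  # negative for troughs
    width_ms: float      # Gaussian standard deviation

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ConfigurationError(
                f"wave {self.label}: width_ms must be positive, got {self.width_ms}")


DEFAULT_TEMPLATES = {
    "ABR": (
        WaveTemplate("I", 1.6, 0.30, 0.25),
        WaveTemplate("II", 2.8, 0.12, 0.25),
        WaveTemplate("III", 3.9, 0.30, 0.25),
        WaveTemplate("IV", 4.9, 0.12, 0.25),
        WaveTemplate("V", 5.6, 0.45, 0.25),
    ),
    "AMLR": (
        WaveTemplate("Na", 18.0, -0.80, 4.0),
        WaveTemplate("Pa", 30.0, 1.00, 4.0),
        WaveTemplate("Nb", 42.0, -0.70, 4.0),
        WaveTemplate("Pb", 55.0, 0.60, 4.0),
    ),
}

#: Between-ear (biological) variability of wave timing/size, per subtype.
LATENCY_JITTER_MS = {"ABR": 0.10, "AMLR": 1.5}
AMPLITUDE_JITTER_UV = {"ABR": 0.05, "AMLR": 0.15}

#: Default high-minus-low group shifts.  ABR: earlier latencies (waves III
#: and V), larger wave I and V amplitudes.  AMLR: later latencies (Pa, Nb,
#: Pb) and larger absolute amplitudes for all four waves (Na/Nb shifts are
#: negative so the troughs deepen).  Waves without an entry are null
#: metrics.
DEFAULT_LATENCY_SHIFT_MS = {"III": -0.06, "V": -0.06,
                            "Pa": 1.0, "Nb": 1.0, "Pb": 1.0}
DEFAULT_AMPLITUDE_SHIFT_UV = {"I": 0.04, "V": 0.04,
                              "Na": -0.08, "Pa": 0.10, "Nb": -0.07, "Pb": 0.06}

#: Default clinical covariate shifts (high minus low group), in the
#: variable's own units.
DEFAULT_CLINICAL_EFFECTS = {"GUF": 6.0, "Hearing loss": 4.0,
                            "Hearing loss 6000": 5.0, "Age": 3.0,
                            "Minimal masking level": 4.0}

THI_CUTOFF = 48
THI_FLOOR = 18


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters for one synthetic cohort."""

    n_patients: int = 248
    high_distress_fraction: float = 0.46
    latency_shift_ms: dict = field(
        default_factory=lambda: dict(DEFAULT_LATENCY_SHIFT_MS))
    amplitude_shift_uv: dict = field(
        default_factory=lambda: dict(DEFAULT_AMPLITUDE_SHIFT_UV))
    noise_sd_uv: float = 0.05
    noise_model: str = "white"  # "white" or "pink" (1/f)
    seed: int = 0
    clinical_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_CLINICAL_EFFECTS))
    missing_rate: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.high_distress_fraction <= 1:
            raise ConfigurationError(
                f"high_distress_fraction must lie in [0, 1], got "
                f"{self.high_distress_fraction}")
        if self.noise_sd_uv < 0:
            raise ConfigurationError(
                f"noise_sd_uv must be non-negative, got {self.noise_sd_uv}")
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError(
                f"missing_rate must lie in [0, 1), got {self.missing_rate}")
        if self.noise_model not in ("white", "pink"):
            raise ConfigurationError(
                f"noise_model must be 'white' or 'pink', got {self.noise_model!r}")
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be at least 1")
        all_waves = set(WAVES["ABR"]) | set(WAVES["AMLR"])
        for d in (self.latency_shift_ms, self.amplitude_shift_uv):
            unknown = set(d) - all_waves
            if unknown:
                raise ConfigurationError(f"unknown wave label(s) {sorted(unknown)}")


def _noise(n: int, sd: float, model: str, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    white = rng.normal(0.0, 1.0, n)
    if model == "white":
        return sd * white
    # 1/f: shape the spectrum and rescale to unit variance
    spec = np.fft.rfft(white)
    freqs = np.arange(len(spec), dtype=float)
    freqs[0] = 1.0
    pink = np.fft.irfft(spec / np.sqrt(freqs), n)
    return sd * pink / pink.std()


def generate_waveform(templates, subtype: str, fs_hz: float, n_samples: int,
                      noise_sd_uv: float, rng: np.random.Generator, *,
                      noise_model: str = "white", record_id: str = "synthetic",
                      patient_id: str = "synthetic", ear: str = "left") -> AEPRecord:
    """One waveform: the sum of the templates' Gaussian bumps plus noise.

    The deterministic part evaluates
    ``amplitude_uv * exp(-(t - latency_ms)^2 / (2 width_ms^2))`` per wave on
    the sampling grid ``t = k / fs_hz * 1000``.
    """
    duration_ms = n_samples / fs_hz * 1000.0
    t = np.arange(n_samples) / fs_hz * 1000.0
    x = np.zeros(n_samples)
    for tpl in templates:
        if not 0 <= tpl.latency_ms <= duration_ms:
            raise ConfigurationError(
                f"wave {tpl.label}: latency {tpl.latency_ms} ms outside the "
                f"{duration_ms:.1f} ms analysis window")
        x += tpl.amplitude_uv * np.exp(-(t - tpl.latency_ms) ** 2
                                       / (2.0 * tpl.width_ms ** 2))
    x += _noise(n_samples, noise_sd_uv, noise_model, rng)
    return AEPRecord(record_id=record_id, patient_id=patient_id, ear=ear,
                     subtype=subtype, fs_hz=fs_hz, samples=x)


def _truncated_normal(rng: np.random.Generator, sd: float,
                      bound_sigmas: float = 2.5) -> float:
    """Zero-mean normal draw clipped at +/- ``bound_sigmas`` SD.

    Biological wave variability is bounded — an ABR wave III does not occur
    at half the nominal latency — so the jitter distribution is truncated
    rather than Gaussian-tailed, which also keeps every generated wave
    inside its physiological search window.
    """
    return float(np.clip(rng.normal(0.0, sd), -bound_sigmas * sd,
                         bound_sigmas * sd))


def _ear_templates(subtype: str, high: bool, config: CohortConfig,
                   rng: np.random.Generator) -> list[WaveTemplate]:
    """Per-ear realisation of the wave templates (group shift + jitter)."""
    out = []
    for tpl in DEFAULT_TEMPLATES[subtype]:
        lat = tpl.latency_ms + _truncated_normal(rng, LATENCY_JITTER_MS[subtype])
        amp = tpl.amplitude_uv + _truncated_normal(rng, AMPLITUDE_JITTER_UV[subtype])
        if high:
            lat += config.latency_shift_ms.get(tpl.label, 0.0)
            amp += config.amplitude_shift_uv.get(tpl.label, 0.0)
        out.append(replace(tpl, latency_ms=lat, amplitude_uv=amp))
    return out


@dataclass
class Cohort:
    """A generated cohort: waveforms, patient-level clinical data, labels."""

    records: list
    clinical: pd.DataFrame   # one row per patient (see generate_clinical_table)
    labels: pd.Series        # patient_id -> "low" / "high"
    config: CohortConfig

    def records_of(self, subtype: str) -> list:
        return [r for r in self.records if r.subtype == subtype]


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Two records per patient per subtype plus a clinical table.

    Group assignment is Bernoulli(``high_distress_fraction``); THI scores
    are drawn uniformly within the group's range so that the label and
    ``THI >= 48`` coincide and every patient satisfies the THI >= 18
    inclusion floor.  Byte-identical output for identical config (seed
    included).
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    patient_ids = [f"p{i:04d}" for i in range(config.n_patients)]
    high = rng.random(config.n_patients) < config.high_distress_fraction
    thi = np.where(high,
                   rng.integers(THI_CUTOFF, 101, config.n_patients),
                   rng.integers(THI_FLOOR, THI_CUTOFF, config.n_patients))
    labels = pd.Series(np.where(high, "high", "low"), index=patient_ids,
                       name="distress_group")

    records = []
    for subtype in ("ABR", "AMLR"):
        ref = SUBTYPE_DEFAULTS[subtype]
        for pid, is_high in zip(patient_ids, high):
            for ear in ("left", "right"):
                tpls = _ear_templates(subtype, bool(is_high), config, rng)
                rec = generate_waveform(
                    tpls, subtype, ref["fs_hz"], ref["n_samples"],
                    config.noise_sd_uv, rng, noise_model=config.noise_model,
                    record_id=f"{pid}-{ear}-{subtype.lower()}",
                    patient_id=pid, ear=ear)
                records.append(rec)

    clinical = generate_clinical_table(config, labels, thi, rng)
    return Cohort(records=records, clinical=clinical, labels=labels,
                  config=config)


# ------------------------------------------------------------ clinical table

#: The 33 covariates: name -> (kind, generator parameters).  Numeric
#: variables are N(mu, sd) (clipped where noted); categorical variables are
#: integer-coded with the documented levels.  Level maps: binary 0=no 1=yes;
#: Alcohol/Smoking 0=never 1=occasional 2=daily; Education 0=primary
#: 1=secondary 2=tertiary 3=postgraduate; Matching type 0=tone 1=noise
#: 2=mixed; Day pattern 0=constant 1=worse-morning 2=worse-evening;
#: Quality 0=tonal 1=hissing 2=buzzing 3=pulsing; Gender 0=female 1=male.
CLINICAL_SCHEMA: dict[str, tuple] = {
    # the fifteen named covariates
    "Age": ("numeric", 52.0, 12.5, (18, 85)),
    "Height": ("numeric", 172.0, 10.0, (140, 210)),
    "Alcohol": ("categorical", (0.35, 0.45, 0.20)),
    "Hearing loss 6000": ("numeric", 32.0, 16.0, (0, 95)),
    "Hearing loss": ("ear", 25.0, 12.0, (0, 90)),
    "Matching type": ("categorical", (0.55, 0.30, 0.15)),
    "Family history": ("categorical", (0.7, 0.3)),
    "Education": ("categorical", (0.15, 0.40, 0.30, 0.15)),
    "Vertigo": ("categorical", (0.75, 0.25)),
    "Frequency": ("ear", 6.0, 2.5, (0.125, 12.5)),            # kHz, pitch match
    "Day pattern": ("categorical", (0.6, 0.15, 0.25)),
    "Number sounds": ("count", 1.6),
    "Quality": ("categorical", (0.45, 0.30, 0.15, 0.10)),
    "Rhythmic": ("categorical", (0.85, 0.15)),
    "GUF": ("numeric", 18.0, 9.0, (0, 45)),
    # eighteen documented filler covariates
    "Gender": ("categorical", (0.41, 0.59)),
    "Weight": ("numeric", 78.0, 14.0, (40, 160)),
    "Smoking": ("categorical", (0.55, 0.20, 0.25)),
    "Caffeine": ("numeric", 2.3, 1.5, (0, 10)),               # cups/day
    "Sleep quality": ("numeric", 6.0, 2.0, (0, 10)),          # self-rated
    "Stress level": ("numeric", 5.5, 2.2, (0, 10)),
    "Tinnitus duration": ("numeric", 72.0, 60.0, (1, 480)),   # months
    "Loudness": ("numeric", 6.2, 2.1, (0, 10)),               # self-rated
    "Matching loudness": ("ear", 55.0, 12.0, (0, 100)),       # dB
    "Minimal masking level": ("ear", 52.0, 13.0, (0, 100)),   # dB
    "Onset type": ("categorical", (0.65, 0.35)),
    "Noise exposure": ("categorical", (0.6, 0.4)),
    "Headache": ("categorical", (0.7, 0.3)),
    "Hyperacusis": ("categorical", (0.65, 0.35)),
    "Handedness": ("categorical", (0.1, 0.9)),
    "Ear infections": ("categorical", (0.8, 0.2)),
    "Medication count": ("count", 1.1),
    "Physical activity": ("numeric", 3.1, 2.0, (0, 14)),      # h/week
}

#: The four audiological variables recorded per ear and later aggregated to
#: patient level according to tinnitus laterality.
EAR_VARIABLES = ("Hearing loss", "Frequency", "Matching loudness",
                 "Minimal masking level")

#: Octave frequencies (Hz) of the pure-tone audiogram emitted per ear.
AUDIOGRAM_FREQS = (250, 500, 1000, 2000, 4000, 6000, 8000)

CATEGORICAL_COLUMNS = tuple(name for name, spec in CLINICAL_SCHEMA.items()
                            if spec[0] in ("categorical",))


def generate_clinical_table(config: CohortConfig, labels: pd.Series,
                            thi: np.ndarray | None = None,
                            rng: np.random.Generator | None = None) -> pd.DataFrame:
    """One row per patient: 33 covariates plus labels and ear-level columns.

    Besides the 33 feature columns, the frame carries ``thi_score``,
    ``laterality`` (left/right/bilateral/head), per-ear matching flags,
    left/right versions of the four ear-level audiological variables, and a
    per-ear audiogram (columns ``thr_<ear>_<freq>``); the ear-level columns
    feed the laterality aggregation rule downstream.  Covariates named in
    ``clinical_effects`` get their group mean shift; ``missing_rate`` of the
    feature cells are blanked at random.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    unknown = set(config.clinical_effects) - set(CLINICAL_SCHEMA)
    if unknown:
        raise ConfigurationError(
            f"clinical_effects name unknown variable(s): {sorted(unknown)}")
    for name in config.clinical_effects:
        if CLINICAL_SCHEMA[name][0] == "categorical":
            raise ConfigurationError(
                f"clinical_effects: {name!r} is categorical; only numeric "
                f"covariates accept a mean shift")

    n = len(labels)
    is_high = (labels == "high").to_numpy()
    if thi is None:
        thi = np.where(is_high, rng.integers(THI_CUTOFF, 101, n),
                       rng.integers(THI_FLOOR, THI_CUTOFF, n))
    data: dict[str, np.ndarray] = {}
    for name, spec in CLINICAL_SCHEMA.items():
        kind = spec[0]
        shift = config.clinical_effects.get(name, 0.0)
        if kind in ("numeric", "ear"):
            _, mu, sd, (lo, hi) = spec
            if kind == "ear":
                for ear in ("left", "right"):
                    vals = rng.normal(mu, sd, n) + shift * is_high
                    data[f"{name} {ear}"] = np.clip(vals, lo, hi)
            else:
                vals = rng.normal(mu, sd, n) + shift * is_high
                data[name] = np.clip(vals, lo, hi)
        elif kind == "categorical":
            probs = np.asarray(spec[1])
            data[name] = rng.choice(len(probs), size=n, p=probs / probs.sum())
        elif kind == "count":
            data[name] = rng.poisson(spec[1], n) + 1
    df = pd.DataFrame(data, index=labels.index)
    df.index.name = "patient_id"

    # laterality and (for head-derived tinnitus) matched-ear flags
    lat = rng.choice(["left", "right", "bilateral", "head"], size=n,
                     p=[0.25, 0.25, 0.4, 0.1])
    matched_left = np.where(lat == "head", rng.random(n) < 0.6, False)
    matched_right = np.where(lat == "head", rng.random(n) < 0.6, False)

    # per-ear audiogram around the ear's pure-tone average
    for ear in ("left", "right"):
        pta = df[f"Hearing loss {ear}"].to_numpy()
        for f_hz in AUDIOGRAM_FREQS:
            slope = 0.004 * (f_hz - 1000) / 1000.0  # mild high-freq tilt
            data_col = np.clip(pta * (1 + slope) + rng.normal(0, 5.0, n), 0, 110)
            df[f"thr_{ear}_{f_hz}"] = data_col

    # blank missing_rate of the *feature* cells (never the metadata)
    if config.missing_rate > 0:
        feature_cols = [c for c in df.columns if not c.startswith("thr_")]
        mask = rng.random((n, len(feature_cols))) < config.missing_rate
        block = df[feature_cols].to_numpy(dtype=float)
        block[mask] = np.nan
        df[feature_cols] = block

    df["thi_score"] = thi
    df["laterality"] = lat
    df["matched_left"] = matched_left
    df["matched_right"] = matched_right
    return df
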