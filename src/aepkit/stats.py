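"""Group statistics on time-domain wave metrics.

The workflow: split ears into low- and high-distress groups at THI = 48,
test each wave metric (latency and amplitude per wave) for a group
difference, and keep the metrics with p < 0.05 as classifier features.
Variance homogeneity is checked with Levene's test; the pooled-variance
Student t-test is used when Levene's p >= 0.05 and Welch's unequal-variance
t-test otherwise.  Effect sizes are Cohen's d (pooled SD on the Student
branch, the root-mean-square SD analogue on the Welch branch), and the mean
difference carries a 95% CI from the chosen test's degrees of freedom.

No multiple-testing correction is applied by default — the gate is an
uncorrected per-metric p < 0.05, with a Holm option for sensitivity
analysis.  Normality is assessed graphically (QQ-plot export), not by an
automated test, because analytic normality tests at hundreds of waveforms
flag immaterial departures.

Subgroup descriptives stratify ears by gender x hearing class x THI group
(12 strata).  AMLR amplitudes are compared on absolute values (trough
depth), ABR amplitudes on signed values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError, InsufficientDataError, ValidationError

ALPHA = 0.05

GENDERS = ("female", "male")
HEARING_CLASSES = ("normal", "mild_loss", "severe_loss")
THI_GROUPS = ("low", "high")

#: Canonical metric order: subtype, wave (physiological order), then
#: latency before amplitude.
CANONICAL_METRICS = [
    (subtype, wave, metric)
    for subtype, waves in (("ABR", ("I", "III", "V")),
                           ("AMLR", ("Na", "Pa", "Nb", "Pb")))
    for wave in waves
    for metric in ("latency", "amplitude")
]


class Stratum(NamedTuple):
    gender: str
    hearing_class: str
    thi_group: str


@dataclass(frozen=True)
class GroupComparison:
    """Two-group comparison result for one wave metric."""

    metric_id: tuple  # (subtype, wave, metric)
    n_low: int
    n_high: int
    mean_low: float
    sd_low: float
    mean_high: float
    sd_high: float
    levene_p: float
    test_used: str  # "student" or "welch"
    t_stat: float
    df: float
    p_value: float
    ci95: tuple
    cohens_d: float


def hearing_class(thresholds_db_hl: Iterable[float]) -> str:
    """Hearing class from the pure-tone average of the supplied thresholds.

    PTA <= 20 dB HL -> ``normal``; 20 < PTA <= 60 -> ``mild_loss``;
    PTA > 60 -> ``severe_loss``.  (The clinical bins [0-20], [21-60], >61
    leave non-integer averages in (20, 21) and (60, 61) unassigned; the
    contiguous half-open bins used here close those gaps.)
    """
    vals = [v for v in thresholds_db_hl if v is not None and np.isfinite(v)]
    if not vals:
        raise DataError("hearing_class: no thresholds supplied")
    pta = float(np.mean(vals))
    if pta <= 20:
        return "normal"
    if pta <= 60:
        return "mild_loss"
    return "severe_loss"


def compare_metric(values_low, values_high,
                   metric_id: tuple = ("", "", ""), *,
                   levene_center: str = "mean",
                   variance_alpha: float = ALPHA) -> GroupComparison:
    """Student/Welch t-test with a Levene gate, Cohen's d, and a 95% CI.

    The statistic is oriented low-minus-high: a negative ``t_stat`` means
    the high-distress group's mean is larger.  Missing values are dropped
    before testing; fewer than two observations in either group raises
    :class:`InsufficientDataError`.
    """
    low = np.asarray(values_low, dtype=float)
    high = np.asarray(values_high, dtype=float)
    low = low[np.isfinite(low)]
    high = high[np.isfinite(high)]
    n1, n2 = len(low), len(high)
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError(
            f"metric {metric_id}: need >= 2 observations per group, got "
            f"({n1}, {n2})")

    if np.var(low) == 0 and np.var(high) == 0:
        levene_p = 1.0  # no variance anywhere: trivially homogeneous
    else:
        _, levene_p = sps.levene(low, high, center=levene_center)
    equal_var = levene_p >= variance_alpha
    test_used = "student" if equal_var else "welch"

    m1, m2 = low.mean(), high.mean()
    v1, v2 = low.var(ddof=1), high.var(ddof=1)
    t_stat, p_value = sps.ttest_ind(low, high, equal_var=equal_var)
    t_stat, p_value = float(t_stat), float(p_value)

    if equal_var:
        df = float(n1 + n2 - 2)
        sp = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / df)
        se = sp * np.sqrt(1 / n1 + 1 / n2)
        d = (m1 - m2) / sp if sp > 0 else 0.0
    else:
        se2 = v1 / n1 + v2 / n2
        df = float(se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1)
                               + (v2 / n2) ** 2 / (n2 - 1)))
        se = np.sqrt(se2)
        rms_sd = np.sqrt((v1 + v2) / 2)
        d = (m1 - m2) / rms_sd if rms_sd > 0 else 0.0
    if se == 0:  # both samples constant: t-test degenerate
        diff0 = m1 - m2
        t_stat = 0.0 if diff0 == 0 else float(np.sign(diff0) * np.inf)
        p_value = 1.0 if diff0 == 0 else 0.0
    tcrit = sps.t.ppf(0.975, df)
    diff = m1 - m2
    return GroupComparison(
        metric_id=tuple(metric_id), n_low=n1, n_high=n2,
        mean_low=float(m1), sd_low=float(np.sqrt(v1)),
        mean_high=float(m2), sd_high=float(np.sqrt(v2)),
        levene_p=float(levene_p), test_used=test_used, t_stat=t_stat,
        df=df, p_value=p_value,
        ci95=(float(diff - tcrit * se), float(diff + tcrit * se)),
        cohens_d=float(d))


def compare_all_metrics(metrics: pd.DataFrame, thi_group: pd.Series, *,
                        abs_amlr_amplitude: bool = True,
                        min_n: int = 2) -> list[GroupComparison]:
    """One :func:`compare_metric` per canonical wave metric.

    ``metrics`` is the long-format table from
    :func:`aepkit.annotate.metrics_table`; ``thi_group`` maps patient_id to
    ``"low"``/``"high"``.  AMLR amplitudes are compared on absolute values
    by default (trough depth convention).
    """
    df = metrics.copy()
    df["thi_group"] = df["patient_id"].map(thi_group)
    if df["thi_group"].isna().any():
        missing = df.loc[df["thi_group"].isna(), "patient_id"].unique()
        raise DataError(f"no THI group for patient(s) {list(missing)[:5]}")
    out = []
    for metric_id in CANONICAL_METRICS:
        subtype, wave, metric = metric_id
        sel = df[(df["subtype"] == subtype) & (df["wave"] == wave)
                 & (df["metric"] == metric) & df["found"]]
        if sel.empty:
            continue
        values = sel["value"]
        if abs_amlr_amplitude and subtype == "AMLR" and metric == "amplitude":
            values = values.abs()
        low = values[sel["thi_group"] == "low"]
        high = values[sel["thi_group"] == "high"]
        if len(low) < min_n or len(high) < min_n:
            continue
        out.append(compare_metric(low, high, metric_id))
    return out


def select_time_features(comparisons, alpha: float = ALPHA, *,
                         correction: str | None = None) -> list[tuple]:
    """Metric ids with a significant group difference, in canonical order.

    By default the gate is the uncorrected per-metric ``p < alpha``;
    ``correction="holm"`` applies Holm's step-down adjustment first.
    """
    comparisons = list(comparisons)
    pvals = np.array([c.p_value for c in comparisons])
    if correction is None:
        keep = pvals < alpha
    elif correction == "holm":
        from statsmodels.stats.multitest import multipletests
        keep = multipletests(pvals, alpha=alpha, method="holm")[0]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    selected = [c.metric_id for c, k in zip(comparisons, keep) if k]
    rank = {m: i for i, m in enumerate(CANONICAL_METRICS)}
    return sorted(selected, key=lambda m: rank.get(m, len(rank)))


def stratify(ears: pd.DataFrame) -> dict:
    """Partition ears into the 12 gender x hearing x THI strata.

    ``ears`` must be indexed by ear id with columns ``gender``,
    ``hearing_class``, ``thi_group``.  Every one of the 12 strata is
    present in the result, empty strata included; the sets are disjoint
    and exhaustive.
    """
    required = ("gender", "hearing_class", "thi_group")
    for col in required:
        if col not in ears.columns:
            raise ValidationError(f"stratify: missing column {col!r}")
        if ears[col].isna().any():
            bad = ears.index[ears[col].isna()]
            raise ValidationError(
                f"stratify: missing {col} for ear(s) {list(bad)[:5]}")
    for col, levels in (("gender", GENDERS), ("hearing_class", HEARING_CLASSES),
                        ("thi_group", THI_GROUPS)):
        bad = set(ears[col]) - set(levels)
        if bad:
            raise ValidationError(f"stratify: invalid {col} value(s) {bad}")
    out = {Stratum(g, h, t): set()
           for g in GENDERS for h in HEARING_CLASSES for t in THI_GROUPS}
    for ear_id, row in ears.iterrows():
        out[Stratum(row["gender"], row["hearing_class"], row["thi_group"])].add(ear_id)
    return out


def comparisons_frame(comparisons) -> pd.DataFrame:
    """Flatten GroupComparison results into an exportable table."""
    rows = []
    for c in comparisons:
        rows.append({
            "subtype": c.metric_id[0], "wave": c.metric_id[1],
            "metric": c.metric_id[2], "n_low": c.n_low, "n_high": c.n_high,
            "mean_low": c.mean_low, "sd_low": c.sd_low,
            "mean_high": c.mean_high, "sd_high": c.sd_high,
            "levene_p": c.levene_p, "test_used": c.test_used,
            "t_stat": c.t_stat, "df": c.df, "p_value": c.p_value,
            "ci95_low": c.ci95[0], "ci95_high": c.ci95[1],
            "cohens_d": c.cohens_d,
        })
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ plots

def export_qq_plots(metrics: pd.DataFrame, thi_group: pd.Series, outdir) -> list:
    """QQ plot per (metric, group) for graphical normality assessment."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = metrics.copy()
    df["thi_group"] = df["patient_id"].map(thi_group)
    written = []
    for (subtype, wave, metric), grp in df[df["found"]].groupby(
            ["subtype", "wave", "metric"]):
        fig, axes = plt.subplots(1, 2, figsize=(8, 4))
        for ax, side in zip(axes, ("low", "high")):
            vals = grp.loc[grp["thi_group"] == side, "value"].dropna()
            if len(vals) >= 3:
                sps.probplot(vals, dist="norm", plot=ax)
            ax.set_title(f"{subtype} {wave} {metric} — {side} THI")
        fig.tight_layout()
        path = outdir / f"qq_{subtype}_{wave}_{metric}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)
    return written


def export_boxplots(metrics: pd.DataFrame, thi_group: pd.Series, outdir) -> list:
    """Per-subtype boxplots of each metric, split by THI group."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = metrics.copy()
    df["thi_group"] = df["patient_id"].map(thi_group)
    written = []
    for (subtype, metric), grp in df[df["found"]].groupby(["subtype", "metric"]):
        waves = [w for w in ("I", "III", "V", "Na", "Pa", "Nb", "Pb")
                 if w in set(grp["wave"])]
        fig, ax = plt.subplots(figsize=(1.8 * len(waves) + 2, 4))
        data, positions, colors = [], [], []
        for i, wave in enumerate(waves):
            for j, side in enumerate(("low", "high")):
                vals = grp.loc[(grp["wave"] == wave)
                               & (grp["thi_group"] == side), "value"].dropna()
                data.append(vals)
                positions.append(i * 2.5 + j)
                colors.append("tab:blue" if side == "low" else "tab:red")
        bp = ax.boxplot(data, positions=positions, widths=0.8,
                        patch_artist=True)
        for patch, color in zip(bp["boxes"], colors):
            patch.set_facecolor(color)
        ax.set_xticks([i * 2.5 + 0.5 for i in range(len(waves))])
        ax.set_xticklabels(waves)
        unit = "ms" if metric == "latency" else "µV"
        ax.set_ylabel(f"{metric} ({unit})")
        ax.set_title(f"{subtype} {metric} by THI group (blue=low, red=high)")
        fig.tight_layout()
        path = outdir / f"box_{subtype}_{metric}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)
    return written
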