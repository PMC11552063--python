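"""Validation statistics: segmentation agreement, error metrics and
repeated-measurement reproducibility.

Reproducibility works on unregistered repeated image pairs per eye and
reports mean absolute error, Pearson/Spearman correlations, the two-way
mixed single-measure consistency intraclass correlation ICC(3,1) with its
F-based 95% confidence interval, Bland-Altman mean difference and limits of
agreement, and the eye-level measurement-noise statistic lambda: the
standard deviation of an eye's repeated measurements as a percentage of the
between-eye standard deviation (of eye-level means) across the population —
0% is the optimum.  Sample (n-1) standard deviations are used throughout,
matching standard Bland-Altman practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ParameterError, ShapeError


@dataclass
class PairedMeasurements:
    """One metric measured twice per eye across a population."""

    eye_ids: list
    m1: np.ndarray
    m2: np.ndarray
    metric: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.m1 = np.asarray(self.m1, dtype=float)
        self.m2 = np.asarray(self.m2, dtype=float)
        if not (len(self.eye_ids) == len(self.m1) == len(self.m2)):
            raise ShapeError("eye_ids, m1 and m2 must have equal lengths")
        if not (np.all(np.isfinite(self.m1)) and np.all(np.isfinite(self.m2))):
            raise ParameterError("paired measurements must be finite")


@dataclass
class ReproReport:
    metric: str
    units: str
    n_eyes: int
    mae: float
    pearson_r: float
    spearman_rho: float
    icc31: float
    icc31_ci: tuple
    mean_difference: float
    loa_low: float
    loa_high: float
    lambda_per_eye_pct: np.ndarray = field(repr=False, default=None)
    lambda_median_pct: float = float("nan")
    lambda_iqr_pct: tuple = (float("nan"), float("nan"))

    def to_row(self) -> dict:
        return {
            "metric": self.metric,
            "units": self.units,
            "n_eyes": self.n_eyes,
            "MAE": self.mae,
            "pearson_r": self.pearson_r,
            "spearman_rho": self.spearman_rho,
            "ICC31": self.icc31,
            "ICC31_ci_low": self.icc31_ci[0],
            "ICC31_ci_high": self.icc31_ci[1],
            "BA_mean_difference": self.mean_difference,
            "BA_loa_low": self.loa_low,
            "BA_loa_high": self.loa_high,
            "lambda_median_pct": self.lambda_median_pct,
            "lambda_q1_pct": self.lambda_iqr_pct[0],
            "lambda_q3_pct": self.lambda_iqr_pct[1],
        }


# ---------------------------------------------------------------------------
# segmentation agreement
# ---------------------------------------------------------------------------


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity 2|A∩B| / (|A|+|B|); two empty masks are identical,
    so dice(∅, ∅) := 1."""
    a = np.asarray(mask_a, bool)
    b = np.asarray(mask_b, bool)
    if a.shape != b.shape:
        raise ShapeError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def auc(prob_map: np.ndarray, truth_mask: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve over pixels, with
    midranks for ties."""
    p = np.asarray(prob_map, dtype=float).ravel()
    t = np.asarray(truth_mask, bool).ravel()
    if p.shape != t.shape:
        raise ShapeError("probability map and truth mask shapes differ")
    if p.min() < 0 or p.max() > 1:
        raise ParameterError("probability values must lie in [0, 1]")
    n_pos = int(t.sum())
    n_neg = t.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ParameterError("AUC needs both classes present in the truth mask")
    ranks = stats.rankdata(p)  # midranks for ties
    r_pos = ranks[t].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def mae(values_pred, values_true) -> float:
    """Mean absolute error."""
    pred = np.asarray(values_pred, dtype=float)
    true = np.asarray(values_true, dtype=float)
    if pred.shape != true.shape or pred.size == 0:
        raise ShapeError("inputs must be equal-length and non-empty")
    return float(np.mean(np.abs(pred - true)))


def combine_axis_mae(mae_x: float, mae_y: float) -> float:
    """Euclidean (diagonal) combination of per-axis localization MAEs."""
    if mae_x < 0 or mae_y < 0:
        raise ParameterError("axis MAEs must be non-negative")
    return float(np.hypot(mae_x, mae_y))


# ---------------------------------------------------------------------------
# unit conversions
# ---------------------------------------------------------------------------


def px_to_um(value_px: float, scale_um_per_px: float) -> float:
    """Length in pixels to microns."""
    if scale_um_per_px <= 0:
        raise ParameterError("scale must be positive")
    return float(value_px * scale_um_per_px)


def px2_to_mm2(area_px: float, scale_um_per_px: float) -> float:
    """Area in square pixels to square millimeters."""
    if scale_um_per_px <= 0:
        raise ParameterError("scale must be positive")
    return float(area_px * (scale_um_per_px * 1e-3) ** 2)


def field_scale_um_per_px(field_mm: float, pixels: int) -> float:
    """Microns-per-pixel of a field of view ``field_mm`` wide over
    ``pixels`` samples (e.g. the 9 mm / 768 px posterior-pole field)."""
    if field_mm <= 0 or pixels <= 0:
        raise ParameterError("field size and pixel count must be positive")
    return float(field_mm * 1000.0 / pixels)


# ---------------------------------------------------------------------------
# reproducibility
# ---------------------------------------------------------------------------


def bland_altman(pairs: PairedMeasurements) -> tuple[float, float, float]:
    """(mean difference, lower LoA, upper LoA) with LoA = MD ± 1.96 sd(d)."""
    if len(pairs.m1) < 2:
        raise ParameterError("Bland-Altman needs at least 2 pairs")
    d = pairs.m1 - pairs.m2
    md = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return md, md - 1.96 * sd, md + 1.96 * sd


def icc31(pairs: PairedMeasurements, alpha: float = 0.05) -> tuple[float, tuple]:
    """Two-way mixed, single-measure, consistency ICC(3,1) with an F-based
    confidence interval.

    From the eye-by-measurement ANOVA with k = 2 repeats:
    ICC = (BMS - EMS) / (BMS + (k-1) EMS), where BMS and EMS are the
    between-eye and residual mean squares.  A constant offset between the
    two measurements does not reduce consistency ICC.
    """
    n = len(pairs.m1)
    if n < 3:
        raise ParameterError("ICC(3,1) needs at least 3 eyes")
    data = np.column_stack([pairs.m1, pairs.m2])
    k = data.shape[1]
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    bms = k * np.sum((row_means - grand) ** 2) / (n - 1)
    jms = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sst = np.sum((data - grand) ** 2)
    sse = sst - (n - 1) * bms - (k - 1) * jms
    # guard tiny negative residuals from float cancellation
    ems = max(sse, 0.0) / ((n - 1) * (k - 1))
    if bms + (k - 1) * ems <= 0:
        return 1.0, (1.0, 1.0)
    icc = (bms - ems) / (bms + (k - 1) * ems)
    if ems == 0:
        return float(icc), (float(icc), float(icc))
    f_obs = bms / ems
    df1, df2 = n - 1, (n - 1) * (k - 1)
    f_l = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
    f_u = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
    lo = (f_l - 1) / (f_l + k - 1)
    hi = (f_u - 1) / (f_u + k - 1)
    return float(icc), (float(lo), float(hi))


def lambda_noise(pairs: PairedMeasurements) -> np.ndarray:
    """Per-eye measurement-noise percentages.

    For each eye, the sample standard deviation of its repeated measurements
    is expressed as a percentage of the between-eye standard deviation of
    eye-level means across the population.  All-identical repeats give 0%
    for every eye; the statistic is invariant to rescaling all measurements.
    """
    if len(pairs.m1) < 2:
        raise ParameterError("lambda needs at least 2 eyes")
    data = np.column_stack([pairs.m1, pairs.m2])
    within_sd = np.std(data, axis=1, ddof=1)
    between_sd = float(np.std(data.mean(axis=1), ddof=1))
    if between_sd == 0:
        raise ParameterError("between-eye variability is zero; lambda undefined")
    return 100.0 * within_sd / between_sd


def repro_report(pairs: PairedMeasurements) -> ReproReport:
    """Full population + eye-level reproducibility report for one metric."""
    md, lo, hi = bland_altman(pairs)
    icc, ci = icc31(pairs)
    lam = lambda_noise(pairs)
    pearson = stats.pearsonr(pairs.m1, pairs.m2).statistic
    spearman = stats.spearmanr(pairs.m1, pairs.m2).statistic
    q1, med, q3 = np.percentile(lam, [25, 50, 75])
    return ReproReport(
        metric=pairs.metric,
        units=pairs.units,
        n_eyes=len(pairs.m1),
        mae=mae(pairs.m1, pairs.m2),
        pearson_r=float(pearson),
        spearman_rho=float(spearman),
        icc31=icc,
        icc31_ci=ci,
        mean_difference=md,
        loa_low=lo,
        loa_high=hi,
        lambda_per_eye_pct=lam,
        lambda_median_pct=float(med),
        lambda_iqr_pct=(float(q1), float(q3)),
    )


# ---------------------------------------------------------------------------
# optional figures
# ---------------------------------------------------------------------------


def bland_altman_plot(pairs: PairedMeasurements, path) -> None:
    """Save a Bland-Altman scatter with MD and LoA lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    md, lo, hi = bland_altman(pairs)
    means = (pairs.m1 + pairs.m2) / 2.0
    diffs = pairs.m1 - pairs.m2
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(means, diffs, s=12, alpha=0.7)
    for y, style in ((md, "-"), (lo, "--"), (hi, "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel(f"mean of repeats [{pairs.units or 'a.u.'}]")
    ax.set_ylabel("difference (repeat 1 - repeat 2)")
    ax.set_title(pairs.metric or "Bland-Altman")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def lambda_boxplot(lambdas_by_metric: dict, path) -> None:
    """Box plots of per-eye lambda distributions, one box per metric."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(lambdas_by_metric)
    fig, ax = plt.subplots(figsize=(1.2 * max(4, len(names)), 4))
    ax.boxplot([lambdas_by_metric[n] for n in names], tick_labels=names)
    ax.axhline(25.0, color="gray", linestyle="--", linewidth=1)
    ax.set_ylabel("eye-level measurement noise lambda [%]")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
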