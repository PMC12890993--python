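"""Morphine recovery arithmetic and the experiment's statistics.

Covers the measurement chain from instrument response back to mg per
tablet (calibration fit, dilution fold, flask back-calculation), replicate
summaries (mean, n-1 SD, total recovered, recovery efficiency against the
45 mg labelled content), Welch's unequal-variance t-test with
Welch-Satterthwaite degrees of freedom, and one-way fixed-effects ANOVA
for per-bin density comparisons.  Significance stars use strict
thresholds: *** p<0.001, ** p<0.01, * p<0.05.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .conditions import LABEL_CONTENT_MG
from .synthetic import ExtractionMeasurement


@dataclass(frozen=True)
class CalibrationCurve:
    """Least-squares calibration of response ratio on concentration."""

    levels: tuple
    responses: tuple
    slope: float
    intercept: float
    r2: float

    @property
    def range(self) -> tuple:
        return (min(self.levels), max(self.levels))


def fit_calibration(levels: Sequence[float], responses: Sequence[float]) -> CalibrationCurve:
    """Ordinary least squares of instrument response on concentration."""
    levels = [float(x) for x in levels]
    responses = [float(x) for x in responses]
    if len(levels) != len(responses):
        raise ValueError("levels and responses must have equal length")
    if len(set(levels)) < 2:
        raise ValueError("at least two distinct calibration levels are required")
    res = sps.linregress(levels, responses)
    return CalibrationCurve(
        tuple(levels), tuple(responses), float(res.slope), float(res.intercept), float(res.rvalue**2)
    )


@dataclass(frozen=True)
class DilutionChain:
    """One dilution step: an aliquot brought to a final volume.

    ``flask_volume_ml`` is the volumetric flask the original sample was
    collected in (50 ml for the filtrate, 10 ml for the cotton wash).
    """

    aliquot_volume_ul: float
    final_volume_ml: float
    flask_volume_ml: float

    def __post_init__(self) -> None:
        for v in (self.aliquot_volume_ul, self.final_volume_ml, self.flask_volume_ml):
            if not v > 0:
                raise ValueError("all volumes must be > 0")

    @property
    def fold(self) -> float:
        return self.final_volume_ml * 1000.0 / self.aliquot_volume_ul


def dilution_fold(chain: DilutionChain) -> float:
    """Dilution factor of the chain (25 ul into 25 ml -> 1000)."""
    return chain.fold


def back_calculate_mg(
    vial_conc_ug_ml: float,
    chain: DilutionChain,
    calibration: Optional[CalibrationCurve] = None,
) -> float:
    """Morphine mass (mg) in the flask from the measured vial concentration.

    mg = vial concentration (ug/ml) x dilution fold x flask volume (ml)
    / 1000.  Warns when the vial concentration lies outside the calibration
    range.
    """
    if vial_conc_ug_ml < 0:
        raise ValueError("concentration must be >= 0")
    if calibration is not None:
        lo, hi = calibration.range
        if not lo <= vial_conc_ug_ml <= hi:
            warnings.warn(
                f"vial concentration {vial_conc_ug_ml} ug/ml outside calibration range [{lo}, {hi}]",
                stacklevel=2,
            )
    return vial_conc_ug_ml * chain.fold * chain.flask_volume_ml / 1000.0


def recovery_efficiency(
    extracted_mg: float,
    remaining_mg: float,
    label_content_mg: float = LABEL_CONTENT_MG,
    decimals: Optional[int] = 1,
) -> float:
    """Percent of the labelled content recovered (filtrate + cotton wash)."""
    if extracted_mg < 0 or remaining_mg < 0:
        raise ValueError("masses must be >= 0")
    if not label_content_mg > 0:
        raise ValueError("label content must be > 0")
    pct = 100.0 * (extracted_mg + remaining_mg) / label_content_mg
    return round(pct, decimals) if decimals is not None else pct


@dataclass(frozen=True)
class RecoverySummary:
    """Replicate summary for one protocol (means, n-1 SDs, totals)."""

    method: str
    n: int
    mean_extracted_mg: float
    sd_extracted_mg: float
    mean_remaining_mg: float
    sd_remaining_mg: float
    label_content_mg: float = LABEL_CONTENT_MG

    @property
    def sum_mg(self) -> float:
        return self.mean_extracted_mg + self.mean_remaining_mg

    @property
    def efficiency_pct(self) -> float:
        return 100.0 * self.sum_mg / self.label_content_mg


def summarize_method(
    measurements: Sequence[ExtractionMeasurement],
    label_content_mg: float = LABEL_CONTENT_MG,
) -> RecoverySummary:
    """Summarise the replicates of one protocol at full precision.

    SDs use the n-1 denominator and are NaN for a single replicate;
    rounding happens only at report rendering.
    """
    if not measurements:
        raise ValueError("at least one measurement is required")
    methods = {m.method for m in measurements}
    if len(methods) != 1:
        raise ValueError(f"measurements mix methods: {sorted(methods)}")
    ext = np.array([m.extracted_mg for m in measurements], dtype=float)
    rem = np.array([m.remaining_mg for m in measurements], dtype=float)
    n = len(measurements)
    sd = lambda x: float(np.std(x, ddof=1)) if n >= 2 else float("nan")
    return RecoverySummary(
        method=methods.pop(),
        n=n,
        mean_extracted_mg=float(ext.mean()),
        sd_extracted_mg=sd(ext),
        mean_remaining_mg=float(rem.mean()),
        sd_remaining_mg=sd(rem),
        label_content_mg=label_content_mg,
    )


def significance_stars(p: float) -> str:
    """Strict star thresholds: *** <0.001, ** <0.01, * <0.05."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value must be in [0, 1], got {p}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class TestResult:
    statistic: float
    degrees_of_freedom: float
    p_value: float
    stars: str


def welch_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> TestResult:
    """Two-tailed Welch's t-test from summary statistics.

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2) with Welch-Satterthwaite
    degrees of freedom; the p-value comes from the t distribution with
    fractional df.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    v1 = sd1**2 / n1
    v2 = sd2**2 / n2
    se2 = v1 + v2
    if se2 == 0:
        raise ValueError("both variances are zero; the test statistic is undefined")
    t = (mean1 - mean2) / np.sqrt(se2)
    df = se2**2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TestResult(float(t), float(df), p, significance_stars(p))


def anova_oneway(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way fixed-effects ANOVA across condition groups.

    F = between-group mean square / within-group mean square with
    (k-1, N-k) degrees of freedom.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    k = len(groups)
    N = sum(g.size for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, N - k
    if ss_within == 0:
        # all groups internally constant: infinite F unless means also equal
        F = 0.0 if ss_between == 0 else float("inf")
        p = 1.0 if ss_between == 0 else 0.0
    else:
        F = (ss_between / df_b) / (ss_within / df_w)
        p = float(sps.f.sf(F, df_b, df_w))
    return TestResult(float(F), float(df_b), p, significance_stars(p))


def pairwise_welch(summaries: Mapping[str, RecoverySummary], field: str = "sum") -> pd.DataFrame:
    """All pairwise Welch tests between protocols on one summary quantity.

    ``field`` selects 'extracted', 'remaining' or 'sum' (mean of
    extracted+remaining per replicate is approximated from summary stats by
    testing the chosen column's mean/SD).
    """
    rows = []
    for a, b in itertools.combinations(sorted(summaries), 2):
        sa, sb = summaries[a], summaries[b]
        if field == "extracted":
            args = (sa.mean_extracted_mg, sa.sd_extracted_mg, sa.n, sb.mean_extracted_mg, sb.sd_extracted_mg, sb.n)
        elif field == "remaining":
            args = (sa.mean_remaining_mg, sa.sd_remaining_mg, sa.n, sb.mean_remaining_mg, sb.sd_remaining_mg, sb.n)
        elif field == "sum":
            # SD of the per-replicate sum is not derivable from the two
            # marginal SDs without the covariance; use the conservative
            # root-sum-of-squares (independence) approximation.
            sda = np.hypot(sa.sd_extracted_mg, sa.sd_remaining_mg)
            sdb = np.hypot(sb.sd_extracted_mg, sb.sd_remaining_mg)
            args = (sa.sum_mg, sda, sa.n, sb.sum_mg, sdb, sb.n)
        else:
            raise ValueError(f"unknown field {field!r}")
        res = welch_t(*args)
        rows.append(
            {
                "method_1": a,
                "method_2": b,
                "field": field,
                "t": res.statistic,
                "df": res.degrees_of_freedom,
                "p_value": res.p_value,
                "stars": res.stars,
            }
        )
    return pd.DataFrame(rows, columns=["method_1", "method_2", "field", "t", "df", "p_value", "stars"])


def recovery_table(summaries: Mapping[str, RecoverySummary]) -> pd.DataFrame:
    """Render the per-protocol recovery table with one-decimal rounding."""
    rows = []
    for m in sorted(summaries):
        s = summaries[m]
        rows.append(
            {
                "method": m,
                "n": s.n,
                "extracted_mg": round(s.mean_extracted_mg, 1),
                "sd_extracted_mg": round(s.sd_extracted_mg, 1),
                "remaining_mg": round(s.mean_remaining_mg, 1),
                "sd_remaining_mg": round(s.sd_remaining_mg, 1),
                "sum_mg": round(s.sum_mg, 1),
                "efficiency_pct": round(s.efficiency_pct, 1),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "method", "n", "extracted_mg", "sd_extracted_mg", "remaining_mg",
            "sd_remaining_mg", "sum_mg", "efficiency_pct",
        ],
    )


def density_summary(densities: pd.DataFrame) -> pd.DataFrame:
    """Mean density +/- standard error per condition and size bin."""
    grouped = densities.groupby(["condition", "bin"], sort=True)["density_per_mm2"]
    out = grouped.agg(["mean", "sem", "count"]).reset_index()
    return out.rename(columns={"mean": "mean_density", "sem": "sem_density", "count": "n_slides"})


def anova_by_bin(densities: pd.DataFrame, exclude: Sequence[str] = ("blank",)) -> pd.DataFrame:
    """One-way ANOVA across conditions within each size bin."""
    rows = []
    for b, sub in densities.groupby("bin", sort=True):
        groups = [
            g["density_per_mm2"].to_numpy()
            for c, g in sub.groupby("condition")
            if c not in exclude
        ]
        if len(groups) < 2 or any(len(g) < 2 for g in groups):
            continue
        res = anova_oneway(groups)
        rows.append(
            {"bin": b, "F": res.statistic, "df_between": res.degrees_of_freedom,
             "p_value": res.p_value, "stars": res.stars}
        )
    return pd.DataFrame(rows, columns=["bin", "F", "df_between", "p_value", "stars"])


def build_report(
    summaries: Mapping[str, RecoverySummary],
    tests: Optional[pd.DataFrame] = None,
    densities: Optional[pd.DataFrame] = None,
) -> Dict[str, object]:
    """Assemble report tables: recovery, pairwise tests, density summary.

    Returns a dict with DataFrames under 'recovery', 'pairwise', 'density',
    'anova' (where inputs are given) and a plain-text 'markdown' rendering.
    """
    report: Dict[str, object] = {"recovery": recovery_table(summaries)}
    if tests is not None:
        report["pairwise"] = tests
    if densities is not None and len(densities):
        report["density"] = density_summary(densities)
        report["anova"] = anova_by_bin(densities)
    lines = ["## Morphine recovery", ""]
    lines.append(_frame_to_markdown(report["recovery"]))
    if "pairwise" in report and len(report["pairwise"]):
        lines += ["", "## Pairwise Welch tests", "", _frame_to_markdown(report["pairwise"].round(4))]
    if "density" in report:
        lines += ["", "## Particle densities (per mm^2 valid area)", "",
                  _frame_to_markdown(report["density"].round(4))]
    if "anova" in report and len(report["anova"]):
        lines += ["", "## Per-bin ANOVA", "", _frame_to_markdown(report["anova"].round(4))]
    report["markdown"] = "\n".join(lines)
    return report


def _frame_to_markdown(df: pd.DataFrame) -> str:
    cols = list(df.columns)
    header = "| " + " | ".join(str(c) for c in cols) + " |"
    sep = "|" + "|".join("---" for _ in cols) + "|"
    body = ["| " + " | ".join(str(v) for v in row) + " |" for row in df.itertuples(index=False)]
    return "\n".join([header, sep] + body)
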