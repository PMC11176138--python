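"""Repeatability and reproducibility statistics for paired measurements.

Three complementary views of test-retest agreement:

* **Lin's concordance correlation coefficient (CCC)** — combines precision
  (Pearson correlation) and accuracy (bias): 1 is perfect agreement, 0 no
  agreement beyond chance, -1 perfect disagreement.  The 95% CI uses the
  Fisher z-transform with Lin's asymptotic variance.
* **Bland-Altman** — mean paired difference with 95% limits of agreement,
  mean(d) +/- 1.96 * SD(d) (sample SD, n-1), expected to bracket ~95% of
  differences.
* **Coefficient of variation (CoV, %)** — per-subject two-point SD
  (|x - y| / sqrt(2)) divided by the per-subject mean, averaged across
  subjects, classified as excellent (<=5%), good (5-10%], moderate
  (10-20%] or poor (>20%).

Repeatability pairs a reader's first and second acquisition; reproducibility
pairs the two readers on the same acquisition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel
from scipy import stats

from .errors import UndefinedAgreementError

__all__ = [
    "PairedMeasurements",
    "AgreementResult",
    "AgreementReport",
    "DesignConfig",
    "ccc",
    "bland_altman",
    "cov_pairs",
    "classify_cov",
    "agreement_report",
]


@dataclass(frozen=True)
class PairedMeasurements:
    """Two aligned vectors of relaxation times (ms) with their pairing keys."""

    x: np.ndarray
    y: np.ndarray
    pairing: tuple
    label: str = ""

    def __post_init__(self) -> None:
        x = np.asarray(self.x, float)
        y = np.asarray(self.y, float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-D and equally long")
        if x.size < 3:
            raise ValueError("need at least 3 pairs")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("measurements must be finite")
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("relaxation times must be positive")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)


def ccc(x: np.ndarray, y: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Lin's concordance correlation coefficient with 95% CI.

    The point estimate uses 1/n moment estimators,
    ccc = 2*s_xy / (s_x^2 + s_y^2 + (mean(x) - mean(y))^2); the interval is
    the Fisher z-transform with Lin's (1989) asymptotic variance,
    back-transformed.  Degenerate agreement (|ccc| = 1) yields a point CI.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("need two equally long vectors with n >= 3")
    sx2 = np.var(x)  # 1/n moments
    sy2 = np.var(y)
    if sx2 == 0 and sy2 == 0:
        raise UndefinedAgreementError("both vectors are constant; agreement undefined")
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    bias2 = (x.mean() - y.mean()) ** 2
    c = 2.0 * sxy / (sx2 + sy2 + bias2)

    if sx2 == 0 or sy2 == 0:
        return float(c), (float(c), float(c))  # correlation undefined; no asymptotic CI
    r = sxy / np.sqrt(sx2 * sy2)
    if 1.0 - c**2 < 1e-12 or abs(r) < 1e-12:
        return float(c), (float(c), float(c))
    u2 = bias2 / np.sqrt(sx2 * sy2)
    c2 = c * c
    var_z = (
        (1 - r**2) * c2 / ((1 - c2) * r**2)
        + 4 * c**3 * (1 - c) * u2 / (r * (1 - c2) ** 2)
        - 2 * c2 * c2 * u2 * u2 / (r**2 * (1 - c2) ** 2)
    ) / (n - 2)
    se = np.sqrt(max(var_z, 0.0))
    z = np.arctanh(c)
    lo, hi = np.tanh(z - 1.959963984540054 * se), np.tanh(z + 1.959963984540054 * se)
    return float(c), (float(lo), float(hi))


@dataclass(frozen=True)
class BlandAltman:
    mean_diff: float
    loa95: tuple[float, float]
    sd_diff: float
    n: int


def bland_altman(x: np.ndarray, y: np.ndarray) -> BlandAltman:
    """Mean difference (x - y) with 95% limits of agreement mean +/- 1.96*SD."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size != x.size:
        raise ValueError("need two equally long vectors with n >= 2")
    d = x - y
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    half = 1.96 * sd
    return BlandAltman(mean_diff=md, loa95=(md - half, md + half), sd_diff=sd, n=x.size)


def cov_pairs(pairs: PairedMeasurements | None = None, x=None, y=None, agg: str = "mean") -> float:
    """Test-retest coefficient of variation (%) over paired measurements.

    Per subject i: CoV_i = SD(x_i, y_i) / mean(x_i, y_i) * 100 with the
    two-point SD |x_i - y_i| / sqrt(2); the study CoV aggregates per-subject
    CoVs by arithmetic mean (``agg="mean"``) or root-mean-square
    (``agg="rms"``).
    """
    if pairs is not None:
        x, y = pairs.x, pairs.y
    x = np.atleast_1d(np.asarray(x, float))
    y = np.atleast_1d(np.asarray(y, float))
    if x.size < 1 or y.size != x.size:
        raise ValueError("need equally many x and y values, at least one pair")
    means = (x + y) / 2.0
    if np.any(means <= 0):
        raise ValueError("pair means must be positive")
    per_subject = np.abs(x - y) / np.sqrt(2.0) / means * 100.0
    if agg == "mean":
        return float(per_subject.mean())
    if agg == "rms":
        return float(np.sqrt(np.mean(per_subject**2)))
    raise ValueError(f"unknown CoV aggregation {agg!r}")


def classify_cov(cov: float) -> str:
    """Band a CoV percentage: excellent <=5 < good <=10 < moderate <=20 < poor."""
    if cov < 0:
        raise ValueError("CoV must be >= 0")
    if cov <= 5.0:
        return "excellent"
    if cov <= 10.0:
        return "good"
    if cov <= 20.0:
        return "moderate"
    return "poor"


@dataclass(frozen=True)
class AgreementResult:
    """One comparison's agreement statistics (all times in ms)."""

    label: str
    weighting: str
    comparison: str  # "repeatability" | "reproducibility"
    within: str  # reader id (repeatability) or acquisition (reproducibility)
    field_strength: str
    contrast_state: str
    ccc: float
    ccc_ci95: tuple[float, float]
    mean_diff: float
    loa95: tuple[float, float]
    cov_percent: float
    cov_class: str
    n: int
    shapiro_p: float | None = None  # descriptive normality check on the differences


@dataclass
class AgreementReport:
    results: list[AgreementResult] = field(default_factory=list)
    pairs: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append(
                dict(
                    label=r.label, weighting=r.weighting, comparison=r.comparison,
                    within=r.within, field_strength=r.field_strength,
                    contrast_state=r.contrast_state, n=r.n, ccc=r.ccc,
                    ccc_ci_lo=r.ccc_ci95[0], ccc_ci_hi=r.ccc_ci95[1],
                    mean_diff_ms=r.mean_diff, loa_lo_ms=r.loa95[0], loa_hi_ms=r.loa95[1],
                    cov_percent=r.cov_percent, cov_class=r.cov_class, shapiro_p=r.shapiro_p,
                )
            )
        return pd.DataFrame(rows)


class DesignConfig(BaseModel):
    """Which strata are pooled and how CoVs are aggregated.

    ``pool_over`` lists key columns collapsed into the pairing unit
    (default: field strength and contrast state, the granularity of a
    per-parameter summary table); ``cov_agg`` selects mean or rms
    aggregation of per-subject CoVs.
    """

    pool_over: tuple[str, ...] = ("field_strength", "contrast_state")
    cov_agg: str = "mean"


def _comparison_pairs(df: pd.DataFrame, unit_cols: list[str], pivot_col: str, lo, hi):
    """Pivot df to one row per unit with columns for the two compared levels."""
    wide = df.pivot_table(index=unit_cols, columns=pivot_col, values="mean_T", aggfunc="first")
    missing = [lev for lev in (lo, hi) if lev not in wide.columns]
    if missing:
        return None, wide.index.tolist()
    incomplete = wide[[lo, hi]].isna().any(axis=1)
    skipped = wide.index[incomplete].tolist()
    wide = wide.loc[~incomplete]
    return wide[[lo, hi]], skipped


def agreement_report(table: pd.DataFrame, design: DesignConfig | None = None) -> AgreementReport:
    """Compute every repeatability / reproducibility comparison in a table.

    ``table`` is a long-format measurement table (columns: subject_id,
    field_strength, weighting, contrast_state, acquisition_index,
    reader_id, mean_T).  Per weighting (and per unpooled stratum):
    repeatability per reader (acquisition 1 vs 2) and reproducibility per
    acquisition (reader 1 vs reader 2).  Units with incomplete cells are
    warned about and skipped; strata with < 3 complete units are skipped.
    """
    design = design or DesignConfig()
    report = AgreementReport()
    if table is None or len(table) == 0:
        return report

    strat_cols = ["weighting"] + [
        c for c in ("field_strength", "contrast_state") if c not in design.pool_over
    ]
    unit_cols = ["subject_id"] + [c for c in design.pool_over if c in table.columns]

    pair_rows = []
    for strat_key, group in table.groupby(strat_cols, sort=True):
        strat_key = strat_key if isinstance(strat_key, tuple) else (strat_key,)
        strat = dict(zip(strat_cols, strat_key))
        field_s = str(strat.get("field_strength", "pooled"))
        state = str(strat.get("contrast_state", "pooled"))

        comparisons = []
        for reader in sorted(group["reader_id"].unique()):
            comparisons.append(
                ("repeatability", str(reader), group[group["reader_id"] == reader],
                 "acquisition_index", 1, 2)
            )
        readers = sorted(group["reader_id"].unique())
        if len(readers) >= 2:
            for acq in sorted(group["acquisition_index"].unique()):
                comparisons.append(
                    ("reproducibility", f"acq{acq}", group[group["acquisition_index"] == acq],
                     "reader_id", readers[0], readers[1])
                )

        for comparison, within, sub, pivot_col, lo, hi in comparisons:
            wide, skipped = _comparison_pairs(sub, unit_cols, pivot_col, lo, hi)
            if skipped:
                warnings.warn(
                    f"{strat} {comparison}/{within}: skipped incomplete units {skipped[:5]}"
                    + ("..." if len(skipped) > 5 else ""),
                    stacklevel=2,
                )
            if wide is None or len(wide) < 3:
                warnings.warn(
                    f"{strat} {comparison}/{within}: fewer than 3 complete pairs; skipped",
                    stacklevel=2,
                )
                continue
            x = wide[lo].to_numpy(float)
            y = wide[hi].to_numpy(float)
            label = "|".join([strat["weighting"], comparison, within]
                             + ([field_s] if field_s != "pooled" else [])
                             + ([state] if state != "pooled" else []))
            c, ci = ccc(x, y)
            ba = bland_altman(x, y)
            cov = cov_pairs(x=x, y=y, agg=design.cov_agg)
            d = x - y
            shapiro_p = float(stats.shapiro(d).pvalue) if 3 <= d.size <= 5000 and np.ptp(d) > 0 else None
            report.results.append(
                AgreementResult(
                    label=label, weighting=strat["weighting"], comparison=comparison,
                    within=within, field_strength=field_s, contrast_state=state,
                    ccc=c, ccc_ci95=ci, mean_diff=ba.mean_diff, loa95=ba.loa95,
                    cov_percent=cov, cov_class=classify_cov(cov), n=len(x),
                    shapiro_p=shapiro_p,
                )
            )
            for unit, xi, yi in zip(wide.index, x, y):
                unit = unit if isinstance(unit, tuple) else (unit,)
                pair_rows.append(
                    dict(label=label, unit="|".join(str(u) for u in unit),
                         x=xi, y=yi, pair_mean=(xi + yi) / 2.0, pair_diff=xi - yi)
                )
    report.pairs = pd.DataFrame(pair_rows)
    return report
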