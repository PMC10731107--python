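"""Longitudinal cohort statistics.

Percent changes between sessions, monthly rates (percent change divided by
the elapsed months), paired t-tests between time points, one-sample
t-tests of monthly rates against zero, and ordinary-least-squares
bone-muscle regressions.  All tests are two-sided with df = n - 1 and no
multiple-testing correction; p <= 0.05 is flagged as significant.

Readaptation percent change is taken against the postflight baseline,
(followup - postflight) / postflight x 100, and its monthly rate divides
by the readaptation duration (~12 months); dividing by mission duration
instead is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ReportError, ValidationError

__all__ = [
    "StatResult",
    "percent_change",
    "monthly_rate",
    "one_sample_ttest",
    "one_sample_ttest_from_summary",
    "paired_ttest",
    "linear_regression",
    "sample_with_moments",
    "build_report",
    "write_report",
    "METRICS",
]

#: cohort-table metric columns, units mg/cm^3 (bone), mm^2 and HU (muscle)
METRICS = (
    "global_tb_vbmd",
    "rbmd_superior",
    "rbmd_transverse",
    "rbmd_inferior",
    "total_muscle_csa",
    "total_muscle_density",
)

ALPHA = 0.05


@dataclass(frozen=True)
class StatResult:
    estimate: float      # sample mean (one-sample) or mean difference (paired)
    sd: float
    n: int
    t_statistic: float
    df: int
    p_two_sided: float
    comparison: str = ""

    @property
    def significant(self) -> bool:
        return self.p_two_sided <= ALPHA


def percent_change(pre_value: float, post_value: float) -> float:
    """(post - pre) / pre x 100."""
    if pre_value == 0:
        raise ValidationError("pre_value: percent change undefined for a zero baseline")
    return (post_value - pre_value) / pre_value * 100.0


def monthly_rate(pct_change: float, months: float) -> float:
    """Percent change normalised to %/month."""
    if months <= 0:
        raise ValidationError(f"months: must be > 0, got {months}")
    return pct_change / months


def one_sample_ttest(values, comparison: str = "vs 0") -> StatResult:
    """Two-sided one-sample t-test of the mean against zero."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError(f"values: need n >= 2, got n={x.size}")
    sd = float(x.std(ddof=1))
    if sd == 0:
        raise ValidationError("values: zero variance, t-test undefined")
    return one_sample_ttest_from_summary(float(x.mean()), sd, int(x.size), comparison)


def one_sample_ttest_from_summary(mean: float, sd: float, n: int,
                                  comparison: str = "vs 0") -> StatResult:
    """t = mean / (sd / sqrt(n)), df = n - 1, two-sided p."""
    if n < 2:
        raise ValidationError(f"n: need >= 2, got {n}")
    if sd <= 0:
        raise ValidationError(f"sd: must be > 0, got {sd}")
    t = mean / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    return StatResult(mean, sd, n, float(t), df, float(p), comparison)


def paired_ttest(pre_values, post_values, comparison: str = "post vs pre") -> StatResult:
    """Paired t-test on within-subject differences (post - pre).

    Inputs are aligned by position; pairs with a missing value (NaN) are
    dropped pairwise, so n reflects complete pairs only.
    """
    pre = np.asarray(pre_values, dtype=float)
    post = np.asarray(post_values, dtype=float)
    if pre.shape != post.shape:
        raise ValidationError("pre/post: length mismatch")
    ok = np.isfinite(pre) & np.isfinite(post)
    d = post[ok] - pre[ok]
    if d.size < 2:
        raise ValidationError(f"pairs: need >= 2 complete pairs, got {d.size}")
    sd = float(d.std(ddof=1))
    if sd == 0:
        if np.all(d == 0):  # identical pairs: t = 0, p = 1 is well defined
            return StatResult(0.0, 0.0, int(d.size), 0.0, int(d.size) - 1, 1.0, comparison)
        raise ValidationError("pairs: zero variance of differences, t-test undefined")
    t = float(d.mean() / (sd / np.sqrt(d.size)))
    df = int(d.size) - 1
    p = float(2.0 * sps.t.sf(abs(t), df))
    return StatResult(float(d.mean()), sd, int(d.size), t, df, p, comparison)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p: float
    n: int
    comparison: str = ""


def linear_regression(x, y, comparison: str = "") -> RegressionResult:
    """OLS of y on x with r^2 and the two-sided slope p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValidationError(f"x: need n >= 3 finite points, got {x.size}")
    if np.ptp(x) == 0:
        raise ValidationError("x: zero variance, regression undefined")
    if np.ptp(y) == 0:  # constant response: flat line fits exactly, no association
        return RegressionResult(0.0, float(y[0]), 0.0, 1.0, int(x.size), comparison)
    fit = sps.linregress(x, y)
    r2 = float(fit.rvalue**2)
    p = float(fit.pvalue) if np.isfinite(fit.pvalue) else 0.0
    return RegressionResult(float(fit.slope), float(fit.intercept), r2, p,
                            int(x.size), comparison)


def sample_with_moments(mean: float, sd: float, n: int) -> np.ndarray:
    """A deterministic sample with *exactly* the given mean and sd (ddof=1).

    Useful for reproducing summary-statistic tests from printed
    (mean, sd, n) triples.
    """
    if n < 2:
        raise ValidationError(f"n: need >= 2, got {n}")
    base = np.linspace(-1.0, 1.0, n)
    base = (base - base.mean()) / base.std(ddof=1)
    return mean + sd * base


# ---------------------------------------------------------------------------
# cohort report
# ---------------------------------------------------------------------------

def _validate_cohort(df: pd.DataFrame) -> None:
    needed = {"subject_id", "session", "mission_months", "readapt_months", *METRICS}
    missing = needed - set(df.columns)
    if missing:
        raise ReportError(f"cohort table missing columns: {sorted(missing)}")
    dup = df.duplicated(subset=["subject_id", "session"])
    if dup.any():
        raise ReportError(
            f"duplicate subject-session rows: {df.loc[dup, 'subject_id'].tolist()}"
        )
    by_subj = df.groupby("subject_id")["session"].apply(set)
    no_pre = [s for s, sess in by_subj.items() if "preflight" not in sess]
    if no_pre:
        raise ReportError(f"subjects missing preflight session: {no_pre}")


def _wide(df: pd.DataFrame, metric: str) -> pd.DataFrame:
    w = df.pivot(index="subject_id", columns="session", values=metric)
    for s in ("preflight", "postflight", "followup"):
        if s not in w:
            w[s] = np.nan
    return w


def build_report(
    cohort: pd.DataFrame,
    readapt_denominator: str = "readapt_months",
    alpha: float = ALPHA,
) -> dict:
    """Cohort-level summary tables.

    Returns a dict of DataFrames: ``preflight_summary`` (mean +- SD),
    ``percent_change`` (flight and follow-up vs preflight, with paired-test
    p), ``monthly_rates`` (flight and readaptation %/month with one-sample
    p), and ``regressions`` (global trabecular BMD against each muscle
    metric, per session).  ``readapt_denominator`` selects the months used
    for readaptation rates: the readaptation duration (default) or the
    mission duration.
    """
    if readapt_denominator not in ("readapt_months", "mission_months"):
        raise ValidationError(
            "readapt_denominator: must be 'readapt_months' or 'mission_months', "
            f"got {readapt_denominator!r}"
        )
    _validate_cohort(cohort)
    durations = cohort.drop_duplicates("subject_id").set_index("subject_id")

    pre = cohort[cohort.session == "preflight"].set_index("subject_id")
    preflight_summary = pd.DataFrame(
        {
            "metric": METRICS,
            "mean": [pre[m].mean() for m in METRICS],
            "sd": [pre[m].std(ddof=1) for m in METRICS],
            "n": [int(pre[m].notna().sum()) for m in METRICS],
        }
    )

    pc_rows, rate_rows = [], []
    for metric in METRICS:
        w = _wide(cohort, metric)
        mm = durations.loc[w.index, "mission_months"]
        rm = durations.loc[w.index, "readapt_months"]

        for label, post_col, base_col in (
            ("flight", "postflight", "preflight"),
            ("followup", "followup", "preflight"),
        ):
            pc = (w[post_col] - w[base_col]) / w[base_col] * 100.0
            # degenerate samples (one pair, zero variance) yield NaN p
            # rather than aborting the whole report
            try:
                p = paired_ttest(w[base_col], w[post_col]).p_two_sided
            except ValidationError:
                p = float("nan")
            pc_rows.append({
                "metric": metric, "period": label,
                "mean_percent": pc.mean(), "sd_percent": pc.std(ddof=1),
                "n": int(pc.notna().sum()),
                "p_paired": p,
                "significant": bool(p <= alpha) if np.isfinite(p) else False,
            })

        flight_rate = ((w.postflight - w.preflight) / w.preflight * 100.0) / mm
        denom = rm if readapt_denominator == "readapt_months" else mm
        readapt_rate = ((w.followup - w.postflight) / w.postflight * 100.0) / denom
        for label, series in (("flight", flight_rate), ("readapt", readapt_rate)):
            vals = series.dropna()
            try:
                tt = one_sample_ttest(vals, comparison=f"{metric} {label} rate vs 0")
                est, sd, n = tt.estimate, tt.sd, tt.n
                t, p = tt.t_statistic, tt.p_two_sided
            except ValidationError:
                est = float(vals.mean()) if len(vals) else float("nan")
                sd = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
                n, t, p = len(vals), float("nan"), float("nan")
            rate_rows.append({
                "metric": metric, "period": label,
                "mean_rate": est, "sd_rate": sd, "n": n,
                "t": t, "p_vs_zero": p,
                "significant": bool(p <= alpha) if np.isfinite(p) else False,
            })

    reg_rows = []
    for session in ("preflight", "postflight", "followup"):
        sub = cohort[cohort.session == session]
        if len(sub) < 3:
            continue
        for predictor in ("total_muscle_density", "total_muscle_csa"):
            fit = linear_regression(sub[predictor], sub["global_tb_vbmd"],
                                    comparison=f"{session}: bmd ~ {predictor}")
            reg_rows.append({
                "session": session, "predictor": predictor,
                "response": "global_tb_vbmd",
                "slope": fit.slope, "intercept": fit.intercept,
                "r_squared": fit.r_squared, "p": fit.p, "n": fit.n,
                "significant": fit.p <= alpha,
            })

    return {
        "preflight_summary": preflight_summary,
        "percent_change": pd.DataFrame(pc_rows),
        "monthly_rates": pd.DataFrame(rate_rows),
        "regressions": pd.DataFrame(reg_rows),
    }


def write_report(report: dict, out_dir) -> None:
    """Write each report table as CSV plus a combined JSON."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    combined = {}
    for name, table in report.items():
        table.to_csv(out / f"{name}.csv", index=False)
        combined[name] = table.to_dict(orient="records")
    import json

    with open(out / "report.json", "w") as fh:
        json.dump(combined, fh, indent=2, default=float)


def plot_report(cohort: pd.DataFrame, report: dict, out_dir) -> None:
    """Optional figures: percent-change boxplots and bone-muscle scatters."""
    from pathlib import Path

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    pc = report["percent_change"]
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, period in zip(axes, ("flight", "followup")):
        sub = pc[pc.period == period]
        ax.bar(range(len(sub)), sub.mean_percent, yerr=sub.sd_percent, capsize=3)
        ax.set_xticks(range(len(sub)))
        ax.set_xticklabels(sub.metric, rotation=60, ha="right", fontsize=7)
        ax.axhline(0, color="k", lw=0.5)
        ax.set_title(f"% change, {period}")
    axes[0].set_ylabel("% vs preflight")
    fig.tight_layout()
    fig.savefig(out / "percent_change.png", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(1, 3, figsize=(11, 3.5))
    for ax, session in zip(axes, ("preflight", "postflight", "followup")):
        sub = cohort[cohort.session == session]
        ax.scatter(sub.total_muscle_density, sub.global_tb_vbmd, s=12)
        ax.set_title(session)
        ax.set_xlabel("muscle density (HU)")
    axes[0].set_ylabel("global Tb.vBMD (mg/cm$^3$)")
    fig.tight_layout()
    fig.savefig(out / "bone_muscle.png", dpi=120)
    plt.close(fig)
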