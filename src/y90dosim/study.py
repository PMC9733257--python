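"""Cohort replication: deviation and agreement statistics across the four
LSF estimators on an 18-patient table.

The packaged fixture ``table1_lsf.csv`` holds, for each patient, the lung
shunt fraction from the standard whole-body scan (St), from SPECT/CT with
attenuation and scatter correction (AC-SC), from the scatter-corrected
whole-body scan (SC), and from SPECT with scatter correction only
(NoAC-SC), each to three decimals.  This module computes:

* column means/SDs,
* per-patient percent deviations of each method against the St reference
  with integer summaries,
* two-sample significance tests (Welch t and Mann-Whitney U) and the
  squared Pearson correlation between methods,
* the downstream effect on the suggested activity and the lung dose via
  the partition-model closed forms (activity ∝ 1/(1−SF), lung dose ∝
  SF/(1−SF)).

Reporting conventions: column SDs are population SDs; integer deviation
summaries use standard rounding; activity-deviation means are rounded to
one decimal.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .dosimetry import activity_deviation, lung_dose_deviation

__all__ = [
    "LSF_COLUMNS",
    "load_patient_table",
    "column_summary",
    "pairwise_deviation",
    "welch_t",
    "mann_whitney",
    "pearson_r2",
    "reproduce_tables",
    "DeviationSummary",
]

LSF_COLUMNS = ["lsf_wb_st", "lsf_spect_acsc", "lsf_wb_sc", "lsf_spect_noacsc"]
_REQUIRED = ["patient_id"] + LSF_COLUMNS

#: Reference column and the comparison methods, in reporting order.
REFERENCE = "lsf_wb_st"
METHODS = ["lsf_spect_acsc", "lsf_spect_noacsc", "lsf_wb_sc"]
METHOD_LABELS = {
    "lsf_wb_st": "LSFwb(St)",
    "lsf_spect_acsc": "LSFspect(AC-SC)",
    "lsf_spect_noacsc": "LSFspect(NoAC-SC)",
    "lsf_wb_sc": "LSFwb(SC)",
}


@dataclass
class DeviationSummary:
    """Integer-rounded summary of per-patient percent deviations."""

    method: str
    mean_pct: int
    min_pct: int
    max_pct: int
    per_patient_pct: np.ndarray
    p_welch: float | None = None
    p_mannwhitney: float | None = None
    r2: float | None = None


def _round_int(x: float) -> int:
    """Round to the nearest integer for the deviation summaries."""
    return int(np.round(x))


def load_patient_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load and validate the per-patient LSF table.

    ``path=None`` loads the packaged 18-patient fixture.  Requires the five
    named columns and every LSF strictly inside (0, 1).
    """
    if path is None:
        ref = importlib.resources.files("y90dosim").joinpath("data/table1_lsf.csv")
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"patient table missing columns: {missing}")
    if len(df) == 0:
        raise ValueError("patient table is empty")
    vals = df[LSF_COLUMNS].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("patient table contains non-finite LSF values")
    if np.any(vals <= 0) or np.any(vals >= 1):
        raise ValueError("LSF values must lie strictly in (0, 1)")
    return df[_REQUIRED].copy()


def column_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Mean and population SD of each LSF column, rounded to 3 decimals."""
    vals = df[LSF_COLUMNS].to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "column": LSF_COLUMNS,
            "mean": np.round(vals.mean(axis=0), 3),
            "sd": np.round(vals.std(axis=0, ddof=0), 3),
        }
    )


def pairwise_deviation(ref: np.ndarray, alt: np.ndarray, method: str = "") -> DeviationSummary:
    """Per-patient percent deviation of ``alt`` against ``ref``.

    Each patient contributes ``100 * (alt - ref) / ref``; the summary holds
    the mean and the two extremes rounded to integers.
    """
    ref = np.asarray(ref, dtype=float)
    alt = np.asarray(alt, dtype=float)
    if ref.shape != alt.shape:
        raise ValueError("columns must have equal length")
    if np.any(ref == 0):
        raise ZeroDivisionError("reference column contains zeros")
    pct = 100.0 * (alt - ref) / ref
    return DeviationSummary(
        method=method,
        mean_pct=_round_int(pct.mean()),
        min_pct=_round_int(pct.min()),
        max_pct=_round_int(pct.max()),
        per_patient_pct=pct,
    )


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch unequal-variance two-sample t-test (statistic, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two observations per sample")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("both samples are degenerate (zero variance)")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (statistic, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two observations per sample")
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(u), float(p)


def pearson_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation between two columns."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) != len(a):
        raise ValueError("need at least three paired observations")
    if a.var() == 0 or b.var() == 0:
        raise ValueError("zero-variance input: correlation undefined")
    r, _ = stats.pearsonr(a, b)
    return float(r**2)


def reproduce_tables(
    df: pd.DataFrame | None = None, out_dir: str | Path | None = None
) -> dict:
    """Compute the cohort summary, deviation, agreement and dose tables.

    Returns a dict with DataFrames ``summary`` (column mean/SD),
    ``lsf_deviation`` (per method: integer mean/min/max percent deviation vs
    St, Welch and Mann-Whitney p vs St, R² vs AC-SC), and ``dose_deviation``
    (per method: suggested-activity and lung-dose percent-deviation means to
    one decimal with integer ranges), plus a Markdown rendering under
    ``"markdown"``.  When ``out_dir`` is given the tables are written as CSV
    and the Markdown as ``report.md``; output is deterministic given the
    input table.
    """
    if df is None:
        df = load_patient_table()
    st = df[REFERENCE].to_numpy(dtype=float)

    summary = column_summary(df)

    rows = []
    for col in METHODS:
        alt = df[col].to_numpy(dtype=float)
        dev = pairwise_deviation(st, alt, method=METHOD_LABELS[col])
        _, p_w = welch_t(st, alt)
        _, p_m = mann_whitney(st, alt)
        rows.append(
            {
                "method": METHOD_LABELS[col],
                "mean_pct": dev.mean_pct,
                "min_pct": dev.min_pct,
                "max_pct": dev.max_pct,
                "p_welch_vs_st": round(p_w, 4),
                "p_mannwhitney_vs_st": round(p_m, 4),
                "r2_vs_acsc": round(
                    pearson_r2(df["lsf_spect_acsc"].to_numpy(dtype=float), alt), 2
                ),
            }
        )
    lsf_dev = pd.DataFrame(rows)

    rows = []
    for col in METHODS:
        alt = df[col].to_numpy(dtype=float)
        act = 100.0 * np.array([activity_deviation(r, a) for r, a in zip(st, alt)])
        ld = 100.0 * np.array([lung_dose_deviation(r, a) for r, a in zip(st, alt)])
        rows.append(
            {
                "method": METHOD_LABELS[col],
                "activity_mean_pct": round(float(act.mean()), 1),
                "activity_min_pct": _round_int(act.min()),
                "activity_max_pct": _round_int(act.max()),
                "lung_dose_mean_pct": int(np.round(ld.mean())),
                "lung_dose_min_pct": _round_int(ld.min()),
                "lung_dose_max_pct": _round_int(ld.max()),
            }
        )
    dose_dev = pd.DataFrame(rows)

    md = _render_markdown(summary, lsf_dev, dose_dev, n=len(df))
    tables = {
        "summary": summary,
        "lsf_deviation": lsf_dev,
        "dose_deviation": dose_dev,
        "markdown": md,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "lsf_summary.csv", index=False)
        lsf_dev.to_csv(out / "lsf_deviation.csv", index=False)
        dose_dev.to_csv(out / "dose_deviation.csv", index=False)
        (out / "report.md").write_text(md)
    return tables


def _render_markdown(summary, lsf_dev, dose_dev, n: int) -> str:
    lines = [
        f"# LSF method comparison ({n} patients)",
        "",
        "## Column summary (mean / population SD)",
        "",
        summary.to_string(index=False),
        "",
        "## LSF deviation vs LSFwb(St), percent",
        "",
        lsf_dev.to_string(index=False),
        "",
        "## Partition-model consequences (suggested activity, lung dose), percent",
        "",
        dose_dev.to_string(index=False),
        "",
    ]
    return "\n".join(lines)


def plot_agreement(
    df: pd.DataFrame,
    x_col: str = "lsf_wb_sc",
    y_col: str = "lsf_spect_acsc",
    path: str | Path | None = None,
):
    """Scatter plot of two LSF methods with the identity line and R²."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = df[x_col].to_numpy(dtype=float)
    y = df[y_col].to_numpy(dtype=float)
    r2 = pearson_r2(x, y)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(x, y, color="tab:blue")
    lim = max(x.max(), y.max()) * 1.1
    ax.plot([0, lim], [0, lim], "k--", lw=0.8)
    ax.set_xlabel(METHOD_LABELS.get(x_col, x_col))
    ax.set_ylabel(METHOD_LABELS.get(y_col, y_col))
    ax.set_title(f"R² = {r2:.2f}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
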