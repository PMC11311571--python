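"""Statistical protocol on per-volume biomarker medians.

Each volume contributes one median per biomarker; the protocol then:

* tests each feature for normality (Shapiro-Wilk, α = 0.05, on the pooled
  medians) and routes it to a parametric or non-parametric comparison;
* compares paired designs (lesion vs contralateral) with a paired t test
  on differences or the Wilcoxon signed-rank test, and unpaired designs
  (observation vs intervention) with Welch's t test or the Mann-Whitney U
  test, dropping missing values pairwise;
* normalizes lesions to their contralateral (lesion minus contralateral
  median, per patient) for the future-progression analysis;
* offers auxiliary checks: Spearman rank correlation against age,
  Levene's variance-homogeneity test, and a two-sided Grubbs outlier test;
* reports per-group mean-of-medians ± SD tables and bar charts.

p values are reported without correction for multiple comparisons; the
significance threshold is fixed at p < 0.05.

Naming notes (documented deviations from common shorthand): the paired
parametric comparison is the one-sample t test on paired differences (an
unequal-variance correction is undefined for a single difference sample),
and the paired non-parametric comparison is the Wilcoxon signed-rank test
(the rank-sum test ignores pairing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .biomarkers import BIOMARKER_NAMES, BIOMARKER_UNITS

logger = logging.getLogger("oralmark.stats")

ALPHA = 0.05

#: StudyTable columns besides the biomarkers.
TABLE_ID_COLUMNS = (
    "patient_id",
    "role",  # lesion | contralateral
    "diagnosis_group",  # observation | intervention
    "progression",  # progressor | non-progressor | none
    "sex",
    "age",
    "smoking_status",
)

ROLES = ("lesion", "contralateral")
DIAGNOSIS_GROUPS = ("observation", "intervention")


@dataclass
class TestResult:
    """Outcome of one routed two-group comparison."""

    test: str
    statistic: float
    p_value: float
    normal: bool
    n: int


def _clean(values) -> np.ndarray:
    arr = np.asarray(values, dtype=np.float64)
    return arr[np.isfinite(arr)]


def is_normal(values, alpha: float = ALPHA) -> bool:
    """Shapiro-Wilk normality decision on pooled feature values."""
    arr = _clean(values)
    if arr.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 values")
    if np.ptp(arr) == 0:
        return False  # constant input: W undefined; treat as non-normal
    return stats.shapiro(arr).pvalue > alpha


def route_test(x, y, design: str, alpha: float = ALPHA) -> TestResult:
    """Route a two-group comparison through the normality decision.

    ``design`` is ``"paired"`` (rows aligned by patient; missing pairs
    dropped pairwise) or ``"unpaired"``.  The feature's pooled values
    decide parametric vs non-parametric at Shapiro-Wilk α = 0.05.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if design == "paired":
        if x.shape != y.shape:
            raise ValueError("paired groups must be the same length")
        keep = np.isfinite(x) & np.isfinite(y)
        x, y = x[keep], y[keep]
        n = x.size
    elif design == "unpaired":
        x, y = _clean(x), _clean(y)
        n = min(x.size, y.size)
    else:
        raise ValueError(f"unknown design {design!r}")
    if n < 3:
        raise ValueError("need at least 3 values per group")

    normal = is_normal(np.concatenate([x, y]), alpha=alpha)

    if design == "paired":
        diff = x - y
        if np.all(diff == 0):
            # identical paired samples: no evidence of any difference
            name = "paired t" if normal else "wilcoxon signed-rank"
            return TestResult(name, 0.0, 1.0, normal, n)
        if normal:
            res = stats.ttest_rel(x, y)
            return TestResult("paired t", float(res.statistic), float(res.pvalue), True, n)
        res = stats.wilcoxon(x, y)
        return TestResult(
            "wilcoxon signed-rank", float(res.statistic), float(res.pvalue), False, n
        )
    if normal:
        res = stats.ttest_ind(x, y, equal_var=False)
        return TestResult("welch t", float(res.statistic), float(res.pvalue), True, n)
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return TestResult("mann-whitney u", float(res.statistic), float(res.pvalue), False, n)


def normalize_to_contralateral(table: pd.DataFrame) -> pd.DataFrame:
    """Per-patient lesion-minus-contralateral deltas for each biomarker.

    Patients without both a lesion and a contralateral row are excluded
    (logged).  Antisymmetric under swapping the two roles.
    """
    out_rows = []
    for pid, grp in table.groupby("patient_id"):
        lesion = grp[grp["role"] == "lesion"]
        contra = grp[grp["role"] == "contralateral"]
        if len(lesion) == 0 or len(contra) == 0:
            logger.info("patient %s excluded: unmatched lesion/contralateral", pid)
            continue
        row = {"patient_id": pid}
        for col in ("diagnosis_group", "progression", "sex", "age", "smoking_status"):
            if col in grp.columns:
                row[col] = lesion.iloc[0][col]
        for name in BIOMARKER_NAMES:
            row[name] = float(lesion.iloc[0][name]) - float(contra.iloc[0][name])
        out_rows.append(row)
    return pd.DataFrame(out_rows)


def spearman_age(table: pd.DataFrame, biomarker: str) -> tuple[float, float]:
    """Spearman rank correlation of a biomarker against patient age."""
    sub = table[["age", biomarker]].dropna()
    rho, p = stats.spearmanr(sub["age"], sub[biomarker])
    return float(rho), float(p)


def levene_test(x, y) -> tuple[float, float]:
    """Levene's variance-homogeneity test between two groups."""
    res = stats.levene(_clean(x), _clean(y))
    return float(res.statistic), float(res.pvalue)


def grubbs_test(values, alpha: float = ALPHA) -> tuple[int | None, float, float]:
    """Two-sided Grubbs outlier test.

    Returns (index of the flagged outlier or None, G statistic, critical
    value).  The critical value uses the usual t-distribution form at
    significance ``alpha``.
    """
    arr = np.asarray(values, dtype=np.float64)
    if arr.size < 3:
        raise ValueError("Grubbs' test needs at least 3 values")
    sd = arr.std(ddof=1)
    if sd == 0:
        return None, 0.0, np.inf
    dev = np.abs(arr - arr.mean())
    idx = int(np.argmax(dev))
    g = dev[idx] / sd
    n = arr.size
    t2 = stats.t.ppf(1 - alpha / (2 * n), n - 2) ** 2
    g_crit = ((n - 1) / np.sqrt(n)) * np.sqrt(t2 / (n - 2 + t2))
    return (idx if g > g_crit else None), float(g), float(g_crit)


def compare_groups(table: pd.DataFrame, design: str) -> pd.DataFrame:
    """Run the routed comparison for every biomarker.

    ``design="paired"`` compares lesion vs contralateral within patients;
    ``design="unpaired"`` compares observation vs intervention lesions.
    """
    rows = []
    for name in BIOMARKER_NAMES:
        if design == "paired":
            wide = table.pivot_table(
                index="patient_id", columns="role", values=name, aggfunc="first"
            )
            if not {"lesion", "contralateral"} <= set(wide.columns):
                continue
            res = route_test(
                wide["lesion"].to_numpy(), wide["contralateral"].to_numpy(), "paired"
            )
        else:
            lesions = table[table["role"] == "lesion"]
            obs = lesions[lesions["diagnosis_group"] == "observation"][name]
            itv = lesions[lesions["diagnosis_group"] == "intervention"][name]
            res = route_test(obs, itv, "unpaired")
        rows.append(
            {
                "biomarker": name,
                "units": BIOMARKER_UNITS[name],
                "test": res.test,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "normal": res.normal,
                "n": res.n,
                "significant": res.p_value < ALPHA,
            }
        )
    return pd.DataFrame(rows)


def group_summary(table: pd.DataFrame, by: str = "role") -> pd.DataFrame:
    """Mean of per-volume medians ± SD per group for each biomarker."""
    rows = []
    for group, grp in table.groupby(by):
        for name in BIOMARKER_NAMES:
            vals = _clean(grp[name])
            rows.append(
                {
                    by: group,
                    "biomarker": name,
                    "units": BIOMARKER_UNITS[name],
                    "mean_of_medians": vals.mean() if vals.size else np.nan,
                    "sd_of_medians": vals.std(ddof=1) if vals.size > 1 else 0.0,
                    "n": int(vals.size),
                }
            )
    return pd.DataFrame(rows)


def report(table: pd.DataFrame, out_dir: str | Path, design: str = "paired") -> dict:
    """Write summary tables and bar charts for a study table.

    Produces ``group_summary.csv``, ``comparisons.csv`` and one bar chart
    per biomarker (bar height: mean of per-volume medians; error bars: SD
    of the medians; group n annotated; a significance bracket when
    p < 0.05).  Returns the file paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    summary = group_summary(table, by="role")
    comparisons = compare_groups(table, design=design)
    summary_path = out_dir / "group_summary.csv"
    comp_path = out_dir / "comparisons.csv"
    summary.to_csv(summary_path, index=False)
    comparisons.to_csv(comp_path, index=False)

    figures = []
    for name in BIOMARKER_NAMES:
        sub = summary[summary["biomarker"] == name]
        fig, ax = plt.subplots(figsize=(3.2, 3.2))
        xs = np.arange(len(sub))
        ax.bar(
            xs,
            sub["mean_of_medians"],
            yerr=sub["sd_of_medians"],
            capsize=4,
            color=["#7b52a1", "#4878a8"][: len(sub)],
        )
        for xi, (_, r) in zip(xs, sub.iterrows()):
            ax.annotate(f"n={r['n']}", (xi, 0), xytext=(0, 4), textcoords="offset points", ha="center")
        ax.set_xticks(xs)
        ax.set_xticklabels(sub["role"])
        ax.set_ylabel(f"{name} [{BIOMARKER_UNITS[name]}]")
        row = comparisons[comparisons["biomarker"] == name]
        if len(row) and bool(row.iloc[0]["significant"]) and len(sub) == 2:
            top = float((sub["mean_of_medians"] + sub["sd_of_medians"]).max())
            ax.plot([0, 1], [top * 1.08] * 2, color="k", lw=1)
            ax.annotate(
                f"p={row.iloc[0]['p_value']:.3g}",
                (0.5, top * 1.08),
                xytext=(0, 3),
                textcoords="offset points",
                ha="center",
            )
        fig.tight_layout()
        fig_path = out_dir / f"{name}.png"
        fig.savefig(fig_path, dpi=120)
        plt.close(fig)
        figures.append(fig_path)

    return {"summary": summary_path, "comparisons": comp_path, "figures": figures}
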