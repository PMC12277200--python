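"""Cohort summaries and two-population comparison statistics.

Per-drug actionable frequencies are compared between cohorts with a pooled
two-proportion z-test (no continuity correction, so z² equals the
uncorrected chi-square statistic on the same 2×2 table), a 95% Wald
confidence interval on the proportion difference, a cross-product odds
ratio with a Woolf log-scale interval (Haldane–Anscombe 0.5 correction when
any cell is zero), and Benjamini–Hochberg adjustment across the tested
drugs. Two significance tiers are reported: a genome-wide threshold
(default 5e-8) on raw p and a BH tier on adjusted p. p-values are floored
at the smallest positive float rather than reported as exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CohortSummary",
    "CohortComparison",
    "StatsError",
    "summarize_cohort",
    "two_proportion_ztest",
    "odds_ratio",
    "bh_adjust",
    "compare_cohorts",
]

P_FLOOR = np.nextafter(0.0, 1.0)


class StatsError(ValueError):
    """Invalid statistical input (empty cohort, mismatched drug lists, ...)."""


@dataclass
class CohortSummary:
    """Per-drug actionable counts and category histograms for one cohort."""

    label: str
    n: int
    actionable: dict[str, int]
    flagged: dict[str, int] = field(default_factory=dict)
    category_histograms: dict[str, dict[str, int]] = field(default_factory=dict)

    def proportion(self, drug: str) -> float:
        return self.actionable[drug] / self.n

    def percent(self, drug: str) -> float:
        """Percent actionable, rounded to 1 decimal as printed in reports."""
        return round(100.0 * self.proportion(drug), 1)

    def drugs(self) -> list[str]:
        return list(self.actionable)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "drug": drug,
                "cohort": self.label,
                "n": self.n,
                "actionable_count": x,
                "actionable_percent": self.percent(drug),
            }
            for drug, x in self.actionable.items()
        ]
        return pd.DataFrame(rows)


def summarize_cohort(classification: pd.DataFrame, label: str) -> CohortSummary:
    """Aggregate a per-sample per-drug classification into cohort counts.

    Indeterminate-flagged samples are excluded from actionable numerators
    but kept in denominators (n is the full cohort size).
    """
    if classification.empty:
        raise StatsError("empty cohort classification")
    n = classification["sample_id"].nunique()
    actionable: dict[str, int] = {}
    flagged: dict[str, int] = {}
    histograms: dict[str, dict[str, int]] = {}
    for drug, group in classification.groupby("drug", sort=False):
        actionable[drug] = int(group["actionable"].sum())
        flagged[drug] = int((group["flag"] != "").sum())
        cats = group.loc[group["category"] != "", "category"]
        if len(cats):
            histograms[drug] = cats.value_counts().sort_index().to_dict()
    return CohortSummary(
        label=label, n=n, actionable=actionable, flagged=flagged, category_histograms=histograms
    )


def two_proportion_ztest(x1, n1, x2, n2):
    """Pooled-variance two-proportion z-test with a 95% Wald difference CI.

    Accepts scalars or numpy arrays (broadcast). Returns
    ``(z, p, (ci_low, ci_high), degenerate)`` where ``degenerate`` marks
    zero-variance tables (both proportions 0 or both 1), reported as
    z = 0, p = 1.
    """
    x1, n1, x2, n2 = (np.asarray(v, dtype=float) for v in (x1, n1, x2, n2))
    if np.any(n1 <= 0) or np.any(n2 <= 0):
        raise StatsError("sample sizes must be positive")
    if np.any(x1 < 0) or np.any(x2 < 0) or np.any(x1 > n1) or np.any(x2 > n2):
        raise StatsError("counts must satisfy 0 <= x <= n")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    var = pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)
    degenerate = var == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(degenerate, 0.0, (p1 - p2) / np.sqrt(np.where(degenerate, 1.0, var)))
    p = np.where(degenerate, 1.0, 2.0 * stats.norm.sf(np.abs(z)))
    p = np.maximum(p, P_FLOOR)
    se_wald = np.sqrt(p1 * (1.0 - p1) / n1 + p2 * (1.0 - p2) / n2)
    zc = stats.norm.ppf(0.975)
    ci = (p1 - p2 - zc * se_wald, p1 - p2 + zc * se_wald)
    if z.ndim == 0:
        return float(z), float(p), (float(ci[0]), float(ci[1])), bool(degenerate)
    return z, p, ci, degenerate


def odds_ratio(x1, n1, x2, n2) -> tuple[float, tuple[float, float], bool]:
    """Cross-product odds ratio with a 95% Woolf (log-scale) interval.

    Applies the Haldane–Anscombe 0.5 correction to every cell when any cell
    of the 2×2 table is zero; the returned flag records that the correction
    fired.
    """
    a, b = float(x1), float(n1) - float(x1)  # cohort 1: actionable / not
    c, d = float(x2), float(n2) - float(x2)
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    zc = stats.norm.ppf(0.975)
    lo, hi = np.exp(np.log(or_) - zc * se), np.exp(np.log(or_) + zc * se)
    return or_, (float(lo), float(hi)), corrected


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise StatsError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class CohortComparison:
    """Per-drug two-cohort comparison (Table-2-style layout)."""

    label_a: str
    label_b: str
    table: pd.DataFrame

    def significant_drugs(self) -> list[str]:
        return self.table.loc[self.table["significant"], "drug"].tolist()


def compare_cohorts(
    a: CohortSummary,
    b: CohortSummary,
    alpha_genomewide: float = 5e-8,
    alpha_bh: float = 0.05,
    m: int | None = None,
) -> CohortComparison:
    """Compare two cohort summaries drug by drug.

    BH adjustment runs across the shared drug list; ``m`` may force a larger
    correction denominator (p · m/rank) than the list length. The
    ``significant`` flag requires the BH-adjusted p below ``alpha_bh``; the
    genome-wide tier on raw p is reported alongside.
    """
    drugs = a.drugs()
    if drugs != b.drugs():
        raise StatsError(
            f"drug lists differ between cohorts: {sorted(set(drugs) ^ set(b.drugs()))}"
        )
    rows = []
    for drug in drugs:
        x1, x2 = a.actionable[drug], b.actionable[drug]
        z, p, ci, degenerate = two_proportion_ztest(x1, a.n, x2, b.n)
        or_, or_ci, or_corrected = odds_ratio(x1, a.n, x2, b.n)
        rows.append(
            {
                "drug": drug,
                "x1": x1,
                "n1": a.n,
                "p1_percent": round(100 * x1 / a.n, 1),
                "x2": x2,
                "n2": b.n,
                "p2_percent": round(100 * x2 / b.n, 1),
                "z": z,
                "p_raw": p,
                "diff_ci_low": ci[0],
                "diff_ci_high": ci[1],
                "odds_ratio": or_,
                "or_ci_low": or_ci[0],
                "or_ci_high": or_ci[1],
                "flags": ",".join(
                    f
                    for f in (
                        "degenerate" if degenerate else "",
                        "haldane" if or_corrected else "",
                        "p_floored" if p <= P_FLOOR else "",
                    )
                    if f
                ),
            }
        )
    table = pd.DataFrame(rows)
    adjusted = bh_adjust(table["p_raw"].to_numpy())
    if m is not None and m > len(drugs):
        # widen the correction denominator to the configured test count
        scaled = np.minimum(adjusted * m / len(drugs), 1.0)
        adjusted = np.maximum(adjusted, scaled)
    table["p_bh"] = np.maximum(adjusted, table["p_raw"])
    table["genomewide_significant"] = table["p_raw"] < alpha_genomewide
    table["significant"] = table["p_bh"] < alpha_bh
    return CohortComparison(a.label, b.label, table)
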