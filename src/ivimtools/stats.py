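"""Responder grouping, Ki-67 change and the nonparametric cohort battery.

Patients are grouped by Miller-Payne histological grade: grades 4-5 (at or
above 90% reduction in cellularity) are good responders, grades 1-3 poor
responders.  Group comparisons use the Wilcoxon rank-sum (Mann-Whitney)
test, associations use Spearman's rank correlation, and Shapiro-Wilk
normality results are reported for narrative only — the comparisons are
always nonparametric, and no multiple-testing correction is applied (raw
p-values at alpha = 0.05, with the number of tests annotated).

Median/IQR reporting uses linear interpolation between order statistics
(R default, type 7) everywhere.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .roi import RoiSummary

__all__ = [
    "ALPHA",
    "PatientRecord",
    "CohortTable",
    "TestResult",
    "assign_response_group",
    "ki67_percent_change",
    "shapiro_wilk",
    "wilcoxon_rank_sum",
    "spearman_correlation",
    "median_iqr",
    "run_cohort_analysis",
    "CohortReport",
]

ALPHA = 0.05
GOOD, POOR = "good", "poor"

#: Markers analysed per patient, in internal column naming.
MARKERS = ("f", "d", "dstar")
MARKER_LABELS = {"f": "f", "d": "D", "dstar": "D*"}


def assign_response_group(grade: int) -> str:
    """Miller-Payne grade -> responder group (4, 5 good; 1, 2, 3 poor)."""
    if grade not in (1, 2, 3, 4, 5):
        raise ValueError(f"Miller-Payne grade must be in 1..5, got {grade}")
    return GOOD if grade >= 4 else POOR


def ki67_percent_change(biopsy: float, excision: float) -> float:
    """[Ki-67 at excision - Ki-67 at core biopsy] / biopsy * 100."""
    if biopsy <= 0:
        raise ZeroDivisionError("Ki-67 change undefined for non-positive biopsy value")
    return (excision - biopsy) / biopsy * 100.0


@dataclass
class PatientRecord:
    patient_id: str
    miller_payne_grade: int
    ki67_biopsy: float
    ki67_excision: float
    baseline: RoiSummary
    cycle1: Optional[RoiSummary] = None

    def __post_init__(self) -> None:
        if self.miller_payne_grade not in (1, 2, 3, 4, 5):
            raise ValueError(f"invalid Miller-Payne grade {self.miller_payne_grade}")
        for v in (self.ki67_biopsy, self.ki67_excision):
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"Ki-67 must lie in [0, 100], got {v}")

    @property
    def group(self) -> str:
        return assign_response_group(self.miller_payne_grade)


@dataclass
class CohortTable:
    """Per-patient records with derived %change columns."""

    records: List[PatientRecord]

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("patient_ids must be unique")

    def to_frame(self) -> pd.DataFrame:
        from .roi import percent_change

        rows = []
        for r in self.records:
            row = {
                "patient_id": r.patient_id,
                "mp_grade": r.miller_payne_grade,
                "group": r.group,
                "ki67_biopsy": r.ki67_biopsy,
                "ki67_excision": r.ki67_excision,
                "f_baseline": r.baseline.f_median,
                "d_baseline": r.baseline.d_median,
                "dstar_baseline": r.baseline.dstar_median,
            }
            if r.cycle1 is not None:
                pc = percent_change(r.baseline, r.cycle1)
                row.update({
                    "f_cycle1": r.cycle1.f_median,
                    "d_cycle1": r.cycle1.d_median,
                    "dstar_cycle1": r.cycle1.dstar_median,
                    "pct_change_f": pc["f"],
                    "pct_change_d": pc["d"],
                    "pct_change_dstar": pc["d_star"],
                })
            row["pct_change_ki67"] = ki67_percent_change(r.ki67_biopsy, r.ki67_excision)
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: Tuple[int, ...]
    estimate: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def shapiro_wilk(values: Sequence[float]) -> TestResult:
    """Shapiro-Wilk normality test (narrative only; never gates a test)."""
    x = np.asarray(values, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for constant input")
    res = sps.shapiro(x)
    return TestResult(float(res.statistic), float(res.pvalue), "shapiro_wilk",
                      (len(x),), float(res.statistic))


def wilcoxon_rank_sum(group_a: Sequence[float], group_b: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) comparison of two groups.

    The null distribution is exact (full enumeration over rank splits) for
    tie-free samples up to n_a + n_b = 25 — comfortably covering cohort-sized
    groups such as 7 vs 9 — and the normal approximation with tie and
    continuity corrections is used otherwise.  The reported estimate is the
    difference of group medians (a - b).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        # every observation tied: no evidence against the null whatsoever
        return TestResult(len(a) * len(b) / 2.0, 1.0, "wilcoxon_rank_sum_degenerate",
                          (len(a), len(b)), 0.0)
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = (len(a) + len(b) <= 25) and not has_ties
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="exact" if exact else "asymptotic",
                           use_continuity=True)
    return TestResult(
        float(res.statistic), float(min(res.pvalue, 1.0)),
        "wilcoxon_rank_sum_exact" if exact else "wilcoxon_rank_sum_normal",
        (len(a), len(b)),
        float(np.median(a) - np.median(b)),
    )


def _midrank_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    """Product-moment correlation of midranks (Spearman's rho with ties)."""
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        raise ValueError("Spearman's rho undefined for constant input")
    return float(rx @ ry) / denom


def spearman_correlation(x: Sequence[float], y: Sequence[float],
                         exact_max_n: int = 9) -> TestResult:
    """Spearman's rank correlation with a two-sided p-value.

    rho is the product-moment correlation of midranks.  For n <= 9 the
    p-value is exact, from full enumeration of the n! permutations of one
    margin's ranks; larger samples use the t-distribution approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be paired")
    n = len(x)
    if n < 4:
        raise ValueError(f"need at least 4 pairs, got {n}")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _midrank_rho(rx, ry)

    if n <= exact_max_n:
        # Permutation dot products: |rho| ordering equals |S - n*mean^2| ordering.
        rxc = tuple(rx - rx.mean())
        ryc = tuple(ry - ry.mean())
        s_obs = abs(sum(a * b for a, b in zip(rxc, ryc)))
        count = 0
        total = 0
        for perm in itertools.permutations(ryc):
            s = abs(sum(a * b for a, b in zip(rxc, perm)))
            if s >= s_obs - 1e-9:
                count += 1
            total += 1
        p = count / total
        method = "spearman_exact"
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
            p = 2.0 * sps.t.sf(abs(t), df=n - 2)
        method = "spearman_t"
    return TestResult(rho, float(min(p, 1.0)), method, (n,), rho)


def median_iqr(values: Sequence[float]) -> Tuple[float, float, float]:
    """(median, q1, q3) with linear interpolation (R type 7)."""
    x = np.asarray(values, dtype=float)
    return (float(np.quantile(x, 0.5)), float(np.quantile(x, 0.25)),
            float(np.quantile(x, 0.75)))


def _fmt_mi(values) -> str:
    m, q1, q3 = median_iqr(values)
    return f"{m:.2f} ({q1:.2f}–{q3:.2f})"


@dataclass
class CohortReport:
    """Tabular cohort analysis mirroring the published report layout."""

    table: pd.DataFrame
    tests: Dict[str, TestResult]
    normality: Dict[str, TestResult]
    n_tests: int
    skipped: List[str] = field(default_factory=list)

    def to_text(self) -> str:
        lines = ["Cohort analysis: IVIM markers vs response group and Ki-67",
                 "=" * 72]
        lines.append(self.table.to_string(index=False))
        lines.append("")
        lines.append(f"{self.n_tests} hypothesis tests performed; raw p-values, "
                     f"* marks p < {ALPHA} (no multiplicity correction).")
        if self.skipped:
            lines.append("Skipped comparisons: " + "; ".join(self.skipped))
        return "\n".join(lines)


def run_cohort_analysis(cohort: CohortTable | pd.DataFrame) -> CohortReport:
    """Full statistical battery over a two-timepoint cohort.

    Per marker (f, D, D*): baseline median (IQR) for all patients and per
    responder group; %change median (IQR) per group; Wilcoxon good-vs-poor
    at baseline and on %change; Spearman of the baseline value against
    Ki-67 at core biopsy, and of the %change against %change in Ki-67.
    Groups with fewer than 2 patients skip the comparison with a logged
    reason rather than erroring.
    """
    df = cohort.to_frame() if isinstance(cohort, CohortTable) else cohort.copy()
    if df["patient_id"].duplicated().any():
        raise ValueError("patient_ids must be unique")
    if "group" not in df.columns:
        df["group"] = df["mp_grade"].map(assign_response_group)

    good = df[df["group"] == GOOD]
    poor = df[df["group"] == POOR]
    tests: Dict[str, TestResult] = {}
    normality: Dict[str, TestResult] = {}
    skipped: List[str] = []
    rows = []

    def _maybe_wilcoxon(key, a, b):
        if len(a) < 2 or len(b) < 2:
            skipped.append(f"{key}: group sizes {len(a)}/{len(b)} < 2")
            return None
        tests[key] = wilcoxon_rank_sum(a, b)
        return tests[key]

    def _star(t: Optional[TestResult]) -> str:
        if t is None:
            return "n/a"
        return f"{t.p_value:.3f}" + ("*" if t.significant else "")

    for marker in MARKERS:
        base_col = f"{marker}_baseline"
        chg_col = f"pct_change_{marker}"
        base_all = df[base_col].dropna()
        chg = df.dropna(subset=[chg_col]) if chg_col in df else df.iloc[0:0]
        chg_good = chg[chg["group"] == GOOD][chg_col] if len(chg) else pd.Series(dtype=float)
        chg_poor = chg[chg["group"] == POOR][chg_col] if len(chg) else pd.Series(dtype=float)

        try:
            normality[base_col] = shapiro_wilk(base_all)
            if len(chg) >= 3:
                normality[chg_col] = shapiro_wilk(chg[chg_col])
        except ValueError:
            pass

        t_base = _maybe_wilcoxon(f"wilcoxon_baseline_{marker}",
                                 good[base_col].dropna(), poor[base_col].dropna())
        t_chg = _maybe_wilcoxon(f"wilcoxon_change_{marker}", chg_good, chg_poor)

        def _maybe_spearman(key, x, y):
            if len(x) < 4:
                skipped.append(f"{key}: fewer than 4 pairs")
                return None
            try:
                tests[key] = spearman_correlation(x, y)
            except ValueError as e:
                skipped.append(f"{key}: {e}")
                return None
            return tests[key]

        rho_base = _maybe_spearman(f"spearman_baseline_{marker}_ki67",
                                   df[base_col], df["ki67_biopsy"])
        rho_chg = _maybe_spearman(f"spearman_change_{marker}_ki67",
                                  chg[chg_col], chg["pct_change_ki67"]) \
            if len(chg) else None

        rows.append({
            "marker": MARKER_LABELS[marker],
            "baseline_all": _fmt_mi(base_all),
            "baseline_good": _fmt_mi(good[base_col].dropna()),
            "baseline_poor": _fmt_mi(poor[base_col].dropna()),
            "p_baseline": _star(t_base),
            "change_good": _fmt_mi(chg_good) if len(chg_good) else "n/a",
            "change_poor": _fmt_mi(chg_poor) if len(chg_poor) else "n/a",
            "p_change": _star(t_chg),
            "rho_ki67_core": f"{rho_base.estimate:.3f}, {_star(rho_base)}"
            if rho_base else "n/a",
            "rho_ki67_change": f"{rho_chg.estimate:.3f}, {_star(rho_chg)}"
            if rho_chg else "n/a",
        })

    return CohortReport(table=pd.DataFrame(rows), tests=tests,
                        normality=normality, n_tests=len(tests), skipped=skipped)
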