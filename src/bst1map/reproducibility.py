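"""Test-retest reproducibility statistics (Bland-Altman style).

Given per-subject ROI means from two scan sessions, the difference
``d = scan1 - scan2`` feeds:

* ``rMSD = sqrt(sum(d^2) / n)``, the root-mean-square deviation;
* the group 95% CI of the mean difference,
  ``+/- t(0.975, n-1) * std(d) / sqrt(n)`` (Student's t replaces 1.96 for
  moderate cohort sizes);
* the within-subject SD ``wSD = rMSD / sqrt(2)`` and the repeatability
  coefficient ``r = 2.77 * wSD`` (equivalently ``1.96 * rMSD``), the
  maximum difference expected in 95% of paired observations; and
* the coefficient of variation of the two repeats per subject
  (sample SD over mean, reported as cohort mean +/- SD).

Pre-checks delegate to standard routines: Shapiro-Wilk normality of d,
Wilcoxon signed-rank for bias, Kendall's tau between |d| and the
per-subject mean (difference magnitude should not track the mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestRetestSet",
    "ReproReport",
    "rmsd",
    "ci_mean_difference",
    "wsd_and_repeatability",
    "cv_pairs",
    "precheck_tests",
    "repro_report",
    "repro_table",
    "bland_altman_plot",
]


@dataclass
class TestRetestSet:
    """Paired ROI means from two sessions; ``d`` is always recomputed."""

    __test__ = False  # data container, despite the class-name prefix

    subject_ids: np.ndarray
    t1_scan1_ms: np.ndarray
    t1_scan2_ms: np.ndarray
    roi: str = ""
    method: str = ""

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids)
        self.t1_scan1_ms = np.asarray(self.t1_scan1_ms, dtype=float)
        self.t1_scan2_ms = np.asarray(self.t1_scan2_ms, dtype=float)
        if not (len(self.subject_ids) == len(self.t1_scan1_ms) == len(self.t1_scan2_ms)):
            raise ValueError("subject, scan1 and scan2 arrays must align")

    @property
    def d(self) -> np.ndarray:
        """Differences scan1 - scan2, ms (sign convention is immaterial:
        every reported quantity uses |d| or d^2)."""
        return self.t1_scan1_ms - self.t1_scan2_ms

    @property
    def means(self) -> np.ndarray:
        return 0.5 * (self.t1_scan1_ms + self.t1_scan2_ms)

    @property
    def n(self) -> int:
        return len(self.subject_ids)


def rmsd(d) -> float:
    """Root-mean-square deviation ``sqrt(sum(d^2) / n)``."""
    d = np.asarray(d, dtype=float)
    if d.size == 0:
        raise ValueError("empty difference vector")
    return float(np.sqrt(np.mean(d**2)))


def ci_mean_difference(d, n_subjects: int | None = None) -> float:
    """Half-width of the 95% CI of the mean difference, ms.

    ``t(0.975, n-1) * std(d, ddof=1) / sqrt(n)``; the t-quantile is
    computed, not hard-coded (2.131 at n = 16, 2.179 at n = 13).
    """
    d = np.asarray(d, dtype=float)
    n = int(n_subjects) if n_subjects is not None else d.size
    if n < 2:
        raise ValueError("need at least 2 subjects")
    t_mult = float(stats.t.ppf(0.975, n - 1))
    return t_mult * float(np.std(d, ddof=1)) / np.sqrt(n)


def wsd_and_repeatability(d) -> tuple[float, float]:
    """``wSD = rMSD / sqrt(2)`` and repeatability ``r = 2.77 * wSD``."""
    w = rmsd(d) / np.sqrt(2.0)
    return float(w), float(2.77 * w)


def cv_pairs(t1_scan1, t1_scan2) -> tuple[float, float]:
    """Coefficient of variation of the repeated measurements, percent.

    Per subject: sample SD of the two repeats over their mean (for two
    values the SD is ``|d| / sqrt(2)``); reported as the cohort mean and
    SD of the per-subject CVs.
    """
    s1 = np.asarray(t1_scan1, dtype=float)
    s2 = np.asarray(t1_scan2, dtype=float)
    means = 0.5 * (s1 + s2)
    if np.any(means <= 0):
        raise ValueError("per-subject means must be positive")
    cv = 100.0 * (np.abs(s1 - s2) / np.sqrt(2.0)) / means
    sd = float(np.std(cv, ddof=1)) if cv.size > 1 else 0.0
    return float(cv.mean()), sd


def precheck_tests(trs: TestRetestSet) -> dict:
    """Normality, bias and trend pre-checks on the difference vector.

    Returns ``shapiro_p``, ``wilcoxon_p``, ``kendall_tau``, ``kendall_p``.
    Degenerate inputs are handled by convention: all-zero differences give
    Wilcoxon p = 1 (no evidence of bias); a constant |d| gives tau = 0,
    p = 1 (no trend measurable under total ties).
    """
    d = trs.d
    if trs.n < 3:
        raise ValueError("pre-checks need at least 3 subjects")
    shapiro_p = float(stats.shapiro(d).pvalue) if np.ptp(d) > 0 else 1.0
    if np.all(d == 0):
        wilcoxon_p = 1.0
    else:
        wilcoxon_p = float(stats.wilcoxon(d).pvalue)
    abs_d = np.abs(d)
    if np.ptp(abs_d) == 0 or np.ptp(trs.means) == 0:
        tau, tau_p = 0.0, 1.0
    else:
        res = stats.kendalltau(abs_d, trs.means)
        tau, tau_p = float(res.statistic), float(res.pvalue)
        if not np.isfinite(tau):
            tau, tau_p = 0.0, 1.0
    return {
        "shapiro_p": shapiro_p,
        "wilcoxon_p": wilcoxon_p,
        "kendall_tau": tau,
        "kendall_p": tau_p,
    }


@dataclass
class ReproReport:
    """One ROI x method row of the reproducibility table."""

    roi: str
    method: str
    n: int
    mean_ms: float
    mean_abs_diff_ms: float
    ci_ms: float
    ci_pct: float
    wsd_ms: float
    repeatability_ms: float
    cv_mean_pct: float
    cv_sd_pct: float
    shapiro_p: float
    wilcoxon_p: float
    kendall_tau: float
    kendall_p: float

    def __post_init__(self) -> None:
        # r = 2.77 wSD = 1.96 rMSD up to the rounding of the two constants
        if self.wsd_ms > 0 and not np.isclose(
            self.repeatability_ms, 2.77 * self.wsd_ms, rtol=1e-12
        ):
            raise ValueError("repeatability must equal 2.77 * wSD")


def repro_report(trs: TestRetestSet) -> ReproReport:
    """Full reproducibility summary for one ROI x method set."""
    if trs.n < 2:
        raise ValueError("reproducibility undefined for fewer than 2 subjects")
    d = trs.d
    wsd, rep = wsd_and_repeatability(d)
    ci = ci_mean_difference(d, trs.n)
    cohort_mean = float(trs.means.mean())
    cv_mean, cv_sd = cv_pairs(trs.t1_scan1_ms, trs.t1_scan2_ms)
    checks = precheck_tests(trs) if trs.n >= 3 else {
        "shapiro_p": np.nan, "wilcoxon_p": np.nan,
        "kendall_tau": np.nan, "kendall_p": np.nan,
    }
    return ReproReport(
        roi=trs.roi,
        method=trs.method,
        n=trs.n,
        mean_ms=cohort_mean,
        mean_abs_diff_ms=float(np.abs(d).mean()),
        ci_ms=ci,
        ci_pct=100.0 * ci / cohort_mean,
        wsd_ms=wsd,
        repeatability_ms=rep,
        cv_mean_pct=cv_mean,
        cv_sd_pct=cv_sd,
        **checks,
    )


def repro_table(reports) -> pd.DataFrame:
    """Stack ReproReports into the reproducibility table layout."""
    return pd.DataFrame([vars(r) for r in reports])


def bland_altman_plot(trs: TestRetestSet, ax=None):
    """Difference-vs-mean plot with mean-difference, CI and repeatability lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    d = trs.d
    md = float(d.mean())
    ci = ci_mean_difference(d, trs.n)
    _, rep = wsd_and_repeatability(d)
    ax.scatter(trs.means, d, color="k", s=18)
    ax.axhline(md, color="k", label="mean difference")
    for y in (md - ci, md + ci):
        ax.axhline(y, color="tab:blue", ls="--", label="95% CI" if y > md else None)
    for y in (md - rep, md + rep):
        ax.axhline(y, color="tab:red", ls=":", label="repeatability" if y > md else None)
    ax.set_xlabel("mean T1 of repeats (ms)")
    ax.set_ylabel("difference scan1 - scan2 (ms)")
    title = " ".join(x for x in (trs.roi, trs.method) if x)
    if title:
        ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    return ax
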