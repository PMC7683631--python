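"""Two-group separation statistics: t tests, rank-sum tests, ROC/AUC,
logistic regression with an operating cutoff, and the metric-by-correction
results grid.

Conventions: group 0 is the wild-type-grouped class, group 1 the mutant
class; uptake metrics are higher in group 1, and AUC is reported as
P(X1 > X0) + 0.5 P(X1 = X0) via the Mann-Whitney relation, so informative
metrics give AUC > 0.5.  The operating cutoff is the empirical-ROC threshold
maximizing Youden's J = sensitivity + specificity - 1; the logistic fit's
probability-0.5 crossing is reported alongside for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.stats import rankdata

from .corrections import METRIC_FAMILIES
from .rc_model import STATISTICS


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    flagged: bool = False
    note: str = ""


def _check_groups(values0, values1, min_n: int = 2):
    v0 = np.asarray(values0, dtype=float)
    v1 = np.asarray(values1, dtype=float)
    if v0.size < min_n or v1.size < min_n:
        raise ValueError(f"both groups need at least {min_n} observations")
    if not (np.isfinite(v0).all() and np.isfinite(v1).all()):
        raise ValueError("group values must be finite")
    return v0, v1


def t_test(values0, values1, variant: str = "student_pooled") -> TestResult:
    """Two-sided two-sample t test (pooled-variance Student or Welch)."""
    v0, v1 = _check_groups(values0, values1)
    if variant not in ("student_pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    if np.ptp(v0) == 0 and np.ptp(v1) == 0 and v0[0] == v1[0]:
        return TestResult(0.0, 1.0, flagged=True, note="degenerate: all values identical")
    res = sps.ttest_ind(v1, v0, equal_var=(variant == "student_pooled"))
    return TestResult(float(res.statistic), float(res.pvalue))


def t_test_from_summary(
    mean0: float, sd0: float, n0: int, mean1: float, sd1: float, n1: int,
    variant: str = "student_pooled",
) -> TestResult:
    """The same t test from sufficient statistics (mean, SD, n) per group."""
    if n0 < 2 or n1 < 2:
        raise ValueError("each group needs n >= 2")
    if sd0 <= 0 or sd1 <= 0:
        raise ValueError("group SDs must be positive")
    if variant not in ("student_pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    res = sps.ttest_ind_from_stats(
        mean1, sd1, n1, mean0, sd0, n0, equal_var=(variant == "student_pooled")
    )
    return TestResult(float(res.statistic), float(res.pvalue))


def wilcoxon_rank_sum(values0, values1, continuity: bool = True) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test, normal approximation
    with tie correction and optional +/-0.5 continuity correction."""
    v0, v1 = _check_groups(values0, values1)
    pooled = np.concatenate([v0, v1])
    if np.ptp(pooled) == 0:
        return TestResult(0.0, 1.0, flagged=True, note="degenerate: all values tied")
    res = sps.mannwhitneyu(
        v1, v0, alternative="two-sided", method="asymptotic", use_continuity=continuity
    )
    return TestResult(float(res.statistic), float(res.pvalue))


def auc_mann_whitney(values0, values1) -> float:
    """Empirical AUC via the Mann-Whitney relation, ties counted half.

    AUC = [sum of ranks of group-1 values in the pooled ranking
           - n1(n1+1)/2] / (n0 * n1), using midranks for ties.
    """
    v0, v1 = _check_groups(values0, values1, min_n=1)
    n0, n1 = v0.size, v1.size
    ranks = rankdata(np.concatenate([v0, v1]))
    u1 = ranks[n0:].sum() - n1 * (n1 + 1) / 2.0
    return float(u1 / (n0 * n1))


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray  # true-positive rate at value >= threshold
    specificity: np.ndarray
    auc: float

    def youden_cutoff(self) -> tuple[float, float, float]:
        """(cutoff, sensitivity, specificity) maximizing J = sens + spec - 1.

        Ties in J are broken toward the higher-sensitivity operating point.
        """
        j = self.sensitivity + self.specificity - 1.0
        best = np.flatnonzero(j == j.max())
        idx = best[np.argmax(self.sensitivity[best])]
        return float(self.thresholds[idx]), float(self.sensitivity[idx]), float(self.specificity[idx])


def roc(values0, values1) -> RocResult:
    """Empirical ROC over all observed thresholds (decision rule: value >= t)."""
    v0, v1 = _check_groups(values0, values1, min_n=1)
    thr = np.unique(np.concatenate([v0, v1]))[::-1]
    sens = np.array([(v1 >= t).mean() for t in thr])
    spec = np.array([(v0 < t).mean() for t in thr])
    return RocResult(
        thresholds=thr, sensitivity=sens, specificity=spec,
        auc=auc_mann_whitney(v0, v1),
    )


@dataclass
class LogisticCutoffResult:
    intercept: float
    slope: float
    converged: bool
    cutoff: float          # Youden-optimal threshold on the metric scale
    sensitivity: float
    specificity: float
    p50_crossing: float    # metric value where fitted probability = 0.5
    roc: RocResult = field(repr=False)

    def predict(self, x):
        z = self.intercept + self.slope * np.asarray(x, dtype=float)
        return 1.0 / (1.0 + np.exp(-z))


def logistic_cutoff(values0, values1) -> LogisticCutoffResult:
    """Univariate logistic fit (maximum likelihood) plus ROC-based cutoff.

    Under complete separation the ML fit diverges; the result is flagged
    (``converged=False``) and the cutoff is still reported from the ROC.
    """
    v0, v1 = _check_groups(values0, values1, min_n=1)
    x = np.concatenate([v0, v1])
    y = np.concatenate([np.zeros(v0.size), np.ones(v1.size)])
    exog = sm.add_constant(x)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, exog).fit(disp=False, maxiter=200)
            params = fit.params
            converged = bool(fit.mle_retvals.get("converged", True)) and np.all(
                np.isfinite(fit.bse)
            )
        except Exception:
            params = np.array([0.0, 0.0])
            converged = False
    intercept, slope = float(params[0]), float(params[1])
    r = roc(v0, v1)
    cutoff, sens, spec = r.youden_cutoff()
    p50 = -intercept / slope if slope != 0 else np.nan
    return LogisticCutoffResult(
        intercept=intercept, slope=slope, converged=converged,
        cutoff=cutoff, sensitivity=sens, specificity=spec,
        p50_crossing=float(p50), roc=r,
    )


def build_results_grid(
    corrected: pd.DataFrame,
    labels: Sequence[int],
    families: Sequence[str] = METRIC_FAMILIES,
    statistics: Sequence[str] = STATISTICS,
    segmentation_col: str | None = "segmentation",
    subset: np.ndarray | None = None,
    subset_name: str = "",
) -> pd.DataFrame:
    """Evaluate every metric family x statistic (x segmentation) cell.

    ``corrected`` is the wide output of :func:`petquant.corrections.correct_cohort`
    with one row per (lesion, segmentation); ``labels`` the per-row binary
    group labels.  ``subset`` optionally restricts rows (e.g. excluding
    lesions near previously treated tissue, or keeping only biopsy-confirmed
    lesions); an empty group after filtering raises naming the filter.

    Returns a long-format grid with pooled and Welch t p-values, rank-sum
    p-value, AUC, Youden cutoff and its sensitivity/specificity.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size != len(corrected):
        raise ValueError("labels must align with the corrected table rows")
    corrected = corrected.reset_index(drop=True)
    if subset is not None:
        subset = np.asarray(subset, dtype=bool)
        corrected = corrected.loc[subset].reset_index(drop=True)
        labels = labels[subset]
    if segmentation_col is not None and segmentation_col in corrected.columns:
        seg_groups = list(corrected.groupby(segmentation_col, sort=True))
    else:
        seg_groups = [("all", corrected)]

    rows = []
    for seg, sub in seg_groups:
        lab = labels[sub.index.to_numpy()]
        v_mask0, v_mask1 = lab == 0, lab == 1
        if v_mask0.sum() == 0 or v_mask1.sum() == 0:
            name = f" after filter {subset_name!r}" if subset_name else ""
            raise ValueError(
                f"segmentation {seg!r}{name}: one of the groups is empty "
                f"(n0={int(v_mask0.sum())}, n1={int(v_mask1.sum())})"
            )
        for fam in families:
            for stat in statistics:
                col = f"{fam}_{stat}"
                if col not in sub.columns:
                    continue
                x = sub[col].to_numpy(dtype=float)
                g0, g1 = x[v_mask0], x[v_mask1]
                lc = logistic_cutoff(g0, g1)
                rows.append(
                    {
                        "family": fam,
                        "statistic": stat,
                        "segmentation": seg,
                        "n0": int(v_mask0.sum()),
                        "n1": int(v_mask1.sum()),
                        "t_p": t_test(g0, g1, "student_pooled").p_value,
                        "t_p_welch": t_test(g0, g1, "welch").p_value,
                        "wilcoxon_p": wilcoxon_rank_sum(g0, g1).p_value,
                        "auc": lc.roc.auc,
                        "cutoff": lc.cutoff,
                        "sensitivity": lc.sensitivity,
                        "specificity": lc.specificity,
                    }
                )
    return pd.DataFrame(rows)


def grid_to_wide(grid: pd.DataFrame, value: str = "t_p") -> pd.DataFrame:
    """Pivot the long results grid into a family x (statistic, segmentation) table."""
    return grid.pivot_table(
        index="family", columns=["statistic", "segmentation"], values=value, sort=False
    )
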