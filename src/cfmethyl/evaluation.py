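"""Diagnostic-accuracy reporting.

Sensitivity/specificity cells with exact (Clopper-Pearson) binomial
confidence intervals, ROC/AUC, subgroup breakdowns (years before diagnosis,
stage, cancer type, split), and covariate screening of classifier scores
with Kruskal-Wallis plus Mann-Whitney post-hoc tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "AccuracyCell", "CovariateScreen", "clopper_pearson", "confusion_metrics",
    "roc_auc", "subgroup_report", "covariate_screen",
]

CANCER_GROUPS = ("pre_dx", "post_dx")


@dataclass
class AccuracyCell:
    """One sensitivity or specificity cell: k correct calls out of n."""

    label: str
    metric: str          # "sensitivity" or "specificity"
    n: int
    k: int
    point: float | None
    ci_low: float | None
    ci_high: float | None

    @classmethod
    def from_counts(cls, label: str, metric: str, k: int, n: int,
                    conf: float = 0.95) -> "AccuracyCell":
        if n == 0:
            return cls(label, metric, 0, 0, None, None, None)
        lo, hi = clopper_pearson(k, n, conf)
        return cls(label, metric, n, k, k / n, lo, hi)


@dataclass
class CovariateScreen:
    covariate: str
    group: str
    levels: list[str]
    kruskal_H: float
    p: float
    posthoc: list[tuple[str, str, float, float, float]] = field(default_factory=list)
    # posthoc rows: (level_a, level_b, U, p, p_adjusted)


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval for k successes in n.

    Endpoints are beta-distribution quantiles; at the boundaries they reduce
    to the closed forms upper(0, n) = 1 - (alpha/2)^(1/n) and
    lower(n, n) = (alpha/2)^(1/n).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    alpha = 1.0 - conf
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper


def confusion_metrics(calls, truth, conf: float = 0.95,
                      label: str = "") -> tuple[AccuracyCell, AccuracyCell]:
    """Sensitivity over true-cancer samples and specificity over true-healthy.

    ``calls`` and ``truth`` are aligned boolean arrays (True = cancer).  An
    empty class yields an undefined cell (n = 0, point None), never 0.
    """
    calls = np.asarray(calls, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if calls.shape != truth.shape:
        raise ValueError("calls and truth must be aligned")
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    k_tp = int((calls & truth).sum())
    k_tn = int((~calls & ~truth).sum())
    sens = AccuracyCell.from_counts(label, "sensitivity", k_tp, n_pos, conf)
    spec = AccuracyCell.from_counts(label, "specificity", k_tn, n_neg, conf)
    return sens, spec


def roc_auc(scores, truth) -> tuple[pd.DataFrame, float]:
    """ROC curve over all thresholds and the AUC.

    AUC is the probability that a random cancer sample outscores a random
    healthy one, ties counted 1/2 (trapezoidal area under the curve).
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    if len(np.unique(truth)) < 2:
        raise ValueError("ROC requires both classes")
    fpr, tpr, thr = roc_curve(truth, scores)
    auc = float(roc_auc_score(truth, scores))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}), auc


def _cell_rows(cells: list[AccuracyCell]) -> pd.DataFrame:
    return pd.DataFrame([{
        "label": c.label, "metric": c.metric, "n": c.n, "k": c.k,
        "point": c.point, "ci_low": c.ci_low, "ci_high": c.ci_high,
    } for c in cells])


def subgroup_report(score_records: pd.DataFrame, meta: pd.DataFrame,
                    conf: float = 0.95) -> pd.DataFrame:
    """Accuracy table: overall and per-subgroup cells for each split.

    Emits, per split: healthy specificity; pre- and post-diagnosis
    sensitivity; sensitivity per years-before-diagnosis bin, per stage and
    per cancer type.  Empty subgroups appear with n = 0.
    """
    merged = score_records.merge(meta, on="sample_id", how="left")
    merged["is_cancer_call"] = merged["call"] == "cancer"
    cells: list[AccuracyCell] = []

    for split in ("train", "test"):
        sub = merged[merged["split"] == split]

        def sens_cell(mask, label, sub=sub, split=split):
            grp = sub[mask]
            return AccuracyCell.from_counts(
                f"{split}/{label}", "sensitivity",
                int(grp["is_cancer_call"].sum()), len(grp), conf)

        healthy = sub[sub["group"] == "healthy"]
        cells.append(AccuracyCell.from_counts(
            f"{split}/healthy", "specificity",
            int((~healthy["is_cancer_call"]).sum()), len(healthy), conf))
        for grp_name in CANCER_GROUPS:
            cells.append(sens_cell(sub["group"] == grp_name, grp_name))
        for b in ("0-1", "1-2", "2-3", "3-4"):
            cells.append(sens_cell((sub["group"] == "pre_dx")
                                   & (sub["years_to_dx_bin"] == b), f"pre_dx/{b}y"))
        cancer = sub["group"].isin(CANCER_GROUPS)
        for st in ("I", "II", "III", "IV"):
            cells.append(sens_cell(cancer & (sub["stage"] == st), f"stage/{st}"))
        for ct in sorted(sub.loc[cancer, "cancer_type"].dropna().unique()):
            cells.append(sens_cell(cancer & (sub["cancer_type"] == ct), f"type/{ct}"))
    return _cell_rows(cells)


DEFAULT_COVARIATES = ("age", "sex", "collection_date", "collection_site",
                      "smoking", "unique_molecules", "total_dna_ng")


def _bin_covariate(values: pd.Series, name: str) -> pd.Series:
    """Continuous covariates are binned to mirror categorical reporting."""
    if name == "age":
        return ((values // 10) * 10).astype(int).astype(str) + "s"
    if name == "collection_date":
        return pd.to_datetime(values).dt.year.astype(str)
    if name in ("unique_molecules", "total_dna_ng"):
        return pd.qcut(values.astype(float), 4, duplicates="drop").astype(str)
    return values.astype(str)


def covariate_screen(score_records: pd.DataFrame, meta: pd.DataFrame,
                     covariates=DEFAULT_COVARIATES, alpha: float = 0.05,
                     posthoc_correction: str = "bonferroni",
                     groups=("healthy", "pre_dx", "post_dx")) -> list[CovariateScreen]:
    """Kruskal-Wallis screen of final scores across covariate levels.

    Run separately within each sample category.  When the omnibus p < alpha,
    pairwise Mann-Whitney post-hoc tests are run with the configured
    correction (Bonferroni by default).  Untestable covariates (fewer than
    two populated levels, or no score variation) are skipped.
    """
    merged = score_records.merge(meta, on="sample_id", how="left")
    out: list[CovariateScreen] = []
    for grp in groups:
        sub = merged[merged["group"] == grp]
        if len(sub) == 0:
            continue
        for cov in covariates:
            if cov not in sub.columns:
                continue
            levels = _bin_covariate(sub[cov], cov)
            by_level = [(lv, sub.loc[levels == lv, "final_score"].to_numpy())
                        for lv in sorted(levels.unique())]
            by_level = [(lv, v) for lv, v in by_level if len(v) >= 1]
            if len(by_level) < 2:
                continue
            vals = [v for _, v in by_level]
            flat = np.concatenate(vals)
            if np.all(flat == flat[0]):
                # no variation: H = 0, p = 1 by convention
                out.append(CovariateScreen(cov, grp, [lv for lv, _ in by_level], 0.0, 1.0))
                continue
            H, p = stats.kruskal(*vals)
            screen = CovariateScreen(cov, grp, [lv for lv, _ in by_level], float(H), float(p))
            if p < alpha:
                pairs = [(a, b) for i, (a, _) in enumerate(by_level)
                         for b, _ in by_level[i + 1:]]
                m = len(pairs)
                lookup = dict(by_level)
                for a, b in pairs:
                    if len(lookup[a]) == 0 or len(lookup[b]) == 0:
                        continue
                    method = "exact" if max(len(lookup[a]), len(lookup[b])) <= 20 else "asymptotic"
                    try:
                        U, pp = stats.mannwhitneyu(lookup[a], lookup[b],
                                                   alternative="two-sided", method=method)
                    except ValueError:
                        U, pp = stats.mannwhitneyu(lookup[a], lookup[b],
                                                   alternative="two-sided",
                                                   method="asymptotic")
                    p_adj = min(1.0, float(pp) * m) if posthoc_correction == "bonferroni" \
                        else float(pp)
                    screen.posthoc.append((a, b, float(U), float(pp), p_adj))
            out.append(screen)
    return out
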