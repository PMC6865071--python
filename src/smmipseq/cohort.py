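"""Cohort-level statistics: transforms, clustering, differential expression,
mutation association, survival and actionable-marker reporting.

The analysis chain mirrors standard practice for targeted expression panels:

* per-transcript ``z(log10(FPM + 0.01))`` transform (the 0.01 offset keeps
  zero FPM finite at log10 = -2),
* Manhattan distances between sample profiles, group-average (UPGMA)
  agglomeration, cluster labels from a k-cut (default k = 3),
* two-sided Wilcoxon-Mann-Whitney per transcript between groups with
  Benjamini-Hochberg control at FDR < 0.05 (fold changes on raw mean FPM),
* Fisher's exact test of hotspot-by-cluster 2x2 tables at FDR < 0.01,
* Kaplan-Meier product-limit curves with right censoring and the two-group
  Mantel-Haenszel log-rank test,
* per-sample actionable flags: >2-fold expression over the cohort mean,
  EGFRvIII positivity (>= 5 FPM) and the CA12v1 poor-prognosis mark
  (> 50 FPM, strict).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import fisher_exact, mannwhitneyu, spearmanr
from statsmodels.stats.multitest import multipletests

LOG_OFFSET = 0.01
DE_FDR = 0.05
ASSOC_FDR = 0.01
ACTIONABLE_FOLD = 2.0
CA12V1_POOR_PROGNOSIS_FPM = 50.0
EGFRVIII_POSITIVE_FPM = 5.0


class CohortError(ValueError):
    pass


# ---------------------------------------------------------------------------
# transform
# ---------------------------------------------------------------------------


@dataclass
class TransformedMatrix:
    """z-scored log10(FPM + 0.01) per transcript, with constancy flags."""

    values: pd.DataFrame  # samples x transcripts
    constant_transcripts: list[str] = field(default_factory=list)


def preprocess_matrix(expression: pd.DataFrame) -> TransformedMatrix:
    """log10(x + 0.01) then per-transcript z-score across samples.

    Transcripts constant across the cohort carry no clustering information;
    they are set to all-zero and flagged rather than dropped, so the matrix
    shape is stable.  Negative input is an error (FPM cannot be negative).
    """
    if (expression.values < 0).any():
        raise CohortError("expression values must be non-negative FPM")
    logged = np.log10(expression + LOG_OFFSET)
    sd = logged.std(axis=0, ddof=1)
    constant = [c for c in expression.columns if expression[c].nunique() <= 1]
    sd_safe = sd.replace(0, np.nan)
    z = (logged - logged.mean(axis=0)) / sd_safe
    z[constant] = 0.0
    return TransformedMatrix(values=z, constant_transcripts=constant)


# ---------------------------------------------------------------------------
# UPGMA clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    """UPGMA merge tree plus labels for the requested cut."""

    linkage: np.ndarray  # scipy (n-1) x 4 linkage matrix
    labels: pd.Series  # sample_id -> cluster label (1..k)
    order: list[str]  # dendrogram leaf order (cophenetic order)

    def to_json_dict(self) -> dict:
        return {
            "linkage": self.linkage.tolist(),
            "labels": {s: int(v) for s, v in self.labels.items()},
            "order": self.order,
        }


def upgma_cluster(
    transformed: TransformedMatrix | pd.DataFrame,
    k: int | None = 3,
    height: float | None = None,
) -> ClusterResult:
    """Group-average agglomeration on Manhattan distances between samples.

    Labels come from a ``k``-cluster cut (default 3) or, alternatively, from
    a height cut on the merge tree.  UPGMA heights are monotone, so both cuts
    are well defined.
    """
    values = transformed.values if isinstance(transformed, TransformedMatrix) else transformed
    n = values.shape[0]
    if n < 2:
        raise CohortError("clustering needs at least 2 samples")
    if k is not None and k > n:
        raise CohortError(f"cannot cut {n} samples into {k} clusters")
    dist = pdist(values.values, metric="cityblock")
    z = linkage(dist, method="average")
    if height is not None:
        flat = fcluster(z, t=height, criterion="distance")
    else:
        flat = fcluster(z, t=k or 3, criterion="maxclust")
    from scipy.cluster.hierarchy import leaves_list

    order = [values.index[i] for i in leaves_list(z)]
    labels = pd.Series(flat, index=values.index, name="cluster")
    return ClusterResult(linkage=z, labels=labels, order=order)


# ---------------------------------------------------------------------------
# statistical primitives (shared by the tables below)
# ---------------------------------------------------------------------------


def mann_whitney_p(
    x, y, exact_max_n: int = 8
) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U: statistic, p, and the method used.

    Exact null distribution when the smaller group has at most
    ``exact_max_n`` observations and the pooled sample is tie-free;
    otherwise the normal approximation with tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return len(x) * len(y) / 2.0, 1.0, "degenerate"
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(x), len(y)) <= exact_max_n and not ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0)), method


def fisher_exact_p(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table (point-probability rule)."""
    _, p = fisher_exact(np.asarray(table), alternative="two-sided")
    return float(p)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted q-values (monotone in p)."""
    _, q, _, _ = multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")
    return q


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------


def _fold_change(mean_a: float, mean_b: float) -> tuple[float, str]:
    hi, lo = max(mean_a, mean_b), min(mean_a, mean_b)
    direction = "group1" if mean_a >= mean_b else "group2"
    if lo == 0:
        return (math.inf if hi > 0 else 1.0), direction
    return hi / lo, direction


def de_test(
    expression: pd.DataFrame,
    group1: list[str],
    group2: list[str],
    fdr: float = DE_FDR,
    exact_max_n: int = 8,
) -> pd.DataFrame:
    """Per-transcript two-sided Mann-Whitney U with BH correction.

    The exact null distribution is used when the smaller group has at most
    ``exact_max_n`` samples and the pooled values are tie-free; otherwise the
    normal approximation with tie and continuity correction.  Fold changes
    are computed on raw mean FPM (larger mean over smaller, with an
    orientation flag), matching how expression ratios are reported.
    """
    if not group1 or not group2:
        raise CohortError("both groups must be non-empty")
    a = expression.loc[list(group1)]
    b = expression.loc[list(group2)]
    rows = []
    for transcript in expression.columns:
        x, y = a[transcript].values, b[transcript].values
        u, p, _ = mann_whitney_p(x, y, exact_max_n=exact_max_n)
        fc, direction = _fold_change(float(x.mean()), float(y.mean()))
        rows.append(
            {
                "transcript_id": transcript,
                "mean_group1": x.mean(),
                "mean_group2": y.mean(),
                "fold_change": fc,
                "higher_in": direction,
                "U": u,
                "p": p,
            }
        )
    table = pd.DataFrame(rows)
    table["q"] = benjamini_hochberg(table["p"])
    table["significant"] = table["q"] < fdr
    return table.sort_values(["q", "p", "transcript_id"], ignore_index=True)


# ---------------------------------------------------------------------------
# mutation-cluster association
# ---------------------------------------------------------------------------


def mutation_assoc(
    profiles: pd.DataFrame,
    labels: pd.Series,
    fdr: float = ASSOC_FDR,
    status_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Fisher's exact association of each hotspot with each cluster vs rest.

    ``profiles`` carries mut/wt status columns (only passing calls count, by
    construction upstream).  Each hotspot x cluster contrast is a 2x2 table
    (carrier/non-carrier x in-cluster/rest) tested two-sided; BH correction
    runs over all contrasts at the stricter FDR < 0.01 used for mutation
    reporting.
    """
    if status_columns is None:
        status_columns = [
            c
            for c in profiles.columns
            if profiles[c].dtype == object
            and set(profiles[c].unique()) <= {"mut", "wt"}
            and c != "IDH_status"
        ]
    labels = labels.reindex(profiles.index)
    if labels.isna().any():
        raise CohortError("every sample needs a cluster label")
    rows = []
    for col in status_columns:
        carrier = profiles[col] == "mut"
        for cluster in sorted(labels.unique()):
            inside = labels == cluster
            table = [
                [int((carrier & inside).sum()), int((carrier & ~inside).sum())],
                [int((~carrier & inside).sum()), int((~carrier & ~inside).sum())],
            ]
            p = fisher_exact_p(table)
            rows.append(
                {
                    "hotspot": col,
                    "cluster": cluster,
                    "carriers_in": table[0][0],
                    "carriers_out": table[0][1],
                    "noncarriers_in": table[1][0],
                    "noncarriers_out": table[1][1],
                    "p": p,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = benjamini_hochberg(out["p"])
        out["significant"] = out["q"] < fdr
        out = out.sort_values(["q", "p", "hotspot"], ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


@dataclass
class SurvivalComparison:
    """Kaplan-Meier curves per group plus the log-rank comparison."""

    curves: dict[str, pd.DataFrame]  # group -> time, at_risk, events, survival
    medians: dict[str, float]  # np.inf encodes "not reached"
    statistic: float
    p_value: float

    def median_label(self, group: str) -> str:
        m = self.medians[group]
        return "not reached" if math.isinf(m) else f"{m:g}"


def survival_compare(
    survival: pd.DataFrame,
    groups: pd.Series,
) -> SurvivalComparison:
    """Kaplan-Meier estimates per group and the log-rank test across groups.

    ``survival`` needs ``survival_days`` and ``event`` (1 = death observed,
    0 = censored: alive at analysis or lost to follow-up) indexed by sample.
    The two-group case uses the Mantel-Haenszel log-rank; more groups fall
    back to the k-sample extension.  A group whose curve never crosses 0.5
    reports its median as not reached (``inf``).
    """
    groups = groups.reindex(survival.index)
    if groups.isna().any():
        raise CohortError("every subject needs a group label")
    if (survival["survival_days"] < 0).any():
        raise CohortError("survival times must be non-negative")
    curves: dict[str, pd.DataFrame] = {}
    medians: dict[str, float] = {}
    for g in sorted(groups.unique()):
        sub = survival[groups == g]
        if len(sub) == 0:
            raise CohortError(f"group {g} has no subjects")
        km = KaplanMeierFitter()
        km.fit(sub["survival_days"], event_observed=sub["event"])
        ev = km.event_table
        curves[g] = pd.DataFrame(
            {
                "time": ev.index.values,
                "at_risk": ev["at_risk"].values,
                "events": ev["observed"].values,
                "survival": km.survival_function_["KM_estimate"].values,
            }
        )
        medians[g] = float(km.median_survival_time_)
    names = sorted(groups.unique())
    if len(names) == 1:
        stat, p = 0.0, 1.0
    elif len(names) == 2:
        g1 = survival[groups == names[0]]
        g2 = survival[groups == names[1]]
        res = logrank_test(
            g1["survival_days"], g2["survival_days"], g1["event"], g2["event"]
        )
        stat, p = float(res.test_statistic), float(res.p_value)
    else:
        res = multivariate_logrank_test(
            survival["survival_days"], groups, survival["event"]
        )
        stat, p = float(res.test_statistic), float(res.p_value)
    return SurvivalComparison(curves=curves, medians=medians, statistic=stat, p_value=p)


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------


def spearman_corr(values_a, values_b) -> tuple[float, float]:
    """Spearman rank correlation with tie-averaged ranks; two-sided p.

    A constant vector has no rank ordering; rho is reported as NaN.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise CohortError("need two equal-length vectors of at least 3 values")
    if len(np.unique(a)) == 1 or len(np.unique(b)) == 1:
        return float("nan"), float("nan")
    rho, p = spearmanr(a, b)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# actionable-marker report
# ---------------------------------------------------------------------------


def actionable_flags(
    expression: pd.DataFrame,
    isoform_fpm: pd.DataFrame | None = None,
    profiles: pd.DataFrame | None = None,
    targets: list[str] | None = None,
    fold: float = ACTIONABLE_FOLD,
) -> pd.DataFrame:
    """Per-sample actionable report.

    For each target transcript, the sample is flagged when its FPM exceeds
    ``fold`` times the cohort mean (strict >).  EGFRvIII status uses the
    >= 5 FPM rule, the CA12v1 poor-prognosis mark the strict > 50 FPM rule;
    passing hotspot labels are carried over from the profiles.  The
    fold-vs-cohort table itself is returned alongside the flags so it can be
    exported directly.
    """
    targets = list(targets) if targets is not None else list(expression.columns)
    cohort_mean = expression[targets].mean(axis=0)
    fold_vs_cohort = expression[targets].div(cohort_mean.replace(0, np.nan), axis=1)
    report = pd.DataFrame(index=expression.index)
    report["overexpressed_targets"] = [
        ";".join(t for t in targets if fold_vs_cohort.loc[s, t] > fold)
        for s in expression.index
    ]
    if isoform_fpm is not None:
        if "EGFRvIII" in isoform_fpm.columns:
            vals = isoform_fpm["EGFRvIII"].reindex(expression.index).fillna(0.0)
            report["EGFRvIII_fpm"] = vals
            report["EGFRvIII_positive"] = vals >= EGFRVIII_POSITIVE_FPM
        if "CA12v1" in isoform_fpm.columns:
            vals = isoform_fpm["CA12v1"].reindex(expression.index).fillna(0.0)
            report["CA12v1_fpm"] = vals
            report["CA12v1_poor_prognosis"] = vals > CA12V1_POOR_PROGNOSIS_FPM
    if profiles is not None:
        status_cols = [
            c
            for c in profiles.columns
            if profiles[c].dtype == object
            and set(pd.unique(profiles[c])) <= {"mut", "wt"}
            and c != "IDH_status"
        ]
        report["hotspots"] = [
            ";".join(c for c in status_cols if profiles.loc[s, c] == "mut")
            if s in profiles.index
            else ""
            for s in expression.index
        ]
    report.attrs["fold_vs_cohort"] = fold_vs_cohort
    return report
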