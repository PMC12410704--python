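"""ROC statistics with DeLong variance, implemented from first principles.

The AUC is the Mann-Whitney statistic: the mean over all (positive,
negative) pairs of psi(x, y) = 1 if x > y, 1/2 if x == y, 0 otherwise.  It
is computed in O(n log n) with midranks, which handle ties exactly.

DeLong's structural-components estimator gives the sampling variance: with
m positives and n negatives, define the per-positive components
V10_i = mean_j psi(x_i, y_j) and per-negative components
V01_j = mean_i psi(x_i, y_j).  Then

    var(AUC) = S10 / m + S01 / n,

where S10 and S01 are the sample variances (ddof 1) of the components.  For
two models scored on the *same* samples the components are correlated; the
variance of the AUC difference includes the cross-model component
covariances,

    var(A - B) = (S10_aa + S10_bb - 2 S10_ab) / m
               + (S01_aa + S01_bb - 2 S01_ab) / n,

and z = (AUC_a - AUC_b) / sqrt(var) is referred to the standard normal for a
two-sided p-value.  Confidence intervals are normal-approximation intervals
on the AUC scale, clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .model import ClassProbabilities

__all__ = [
    "AucResult",
    "DelongResult",
    "DegenerateLabelsError",
    "cancer_score",
    "binary_auc",
    "delong_variance",
    "auc_ci",
    "delong_paired_test",
    "per_finding_auc",
    "variant_auc",
    "compare_variants",
    "roc_points",
    "metrics_report",
]


class DegenerateLabelsError(ValueError):
    """Fewer than one positive or one negative in the labels."""


@dataclass(frozen=True)
class AucResult:
    auc: float
    variance: float
    ci95: tuple[float, float]
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class DelongResult:
    auc_a: float
    auc_b: float
    var_diff: float
    z: float
    p: float


def cancer_score(p: ClassProbabilities | Sequence[float]) -> float:
    """Reduce 3-class probabilities to the binary cancer score: p_cancer,
    scored against the truth cancer vs {benign, normal}."""
    if isinstance(p, ClassProbabilities):
        return p.p_cancer
    return float(p[0])


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    pos = scores[labels.astype(bool)]
    neg = scores[~labels.astype(bool)]
    if len(pos) == 0 or len(neg) == 0:
        raise DegenerateLabelsError(
            f"need both classes; got {len(pos)} positives, {len(neg)} negatives"
        )
    return pos, neg


def _components(pos: np.ndarray, neg: np.ndarray):
    """Midrank computation of AUC and the DeLong structural components."""
    m, n = len(pos), len(neg)
    tz = rankdata(np.concatenate([pos, neg]))  # midranks over pooled scores
    tx = rankdata(pos)
    ty = rankdata(neg)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    # rank-sum form: the numerator is an exact half-integer, so the AUC is
    # bit-identical to brute-force pairwise enumeration
    auc = float((tz[:m].sum() - m * (m + 1) / 2) / (m * n))
    return auc, v10, v01


def _comp_var(v: np.ndarray) -> float:
    return float(np.var(v, ddof=1)) if len(v) > 1 else 0.0


def _comp_cov(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.cov(a, b, ddof=1)[0, 1]) if len(a) > 1 else 0.0


def binary_auc(scores: Iterable[float], labels: Iterable[int]) -> AucResult:
    """Cancer-vs-rest AUC with midrank tie handling plus DeLong variance and
    95% normal-approximation CI."""
    pos, neg = _split(scores, labels)
    auc, v10, v01 = _components(pos, neg)
    var = _comp_var(v10) / len(pos) + _comp_var(v01) / len(neg)
    res = AucResult(auc=auc, variance=var, ci95=(np.nan, np.nan),
                    n_pos=len(pos), n_neg=len(neg))
    return AucResult(auc=auc, variance=var, ci95=auc_ci(res), n_pos=len(pos), n_neg=len(neg))


def delong_variance(scores: Iterable[float], labels: Iterable[int]) -> float:
    """DeLong sampling variance of the AUC (S10/m + S01/n)."""
    pos, neg = _split(scores, labels)
    _, v10, v01 = _components(pos, neg)
    return _comp_var(v10) / len(pos) + _comp_var(v01) / len(neg)


def auc_ci(result: AucResult, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation interval auc +- z * sqrt(var), clipped to [0,1]."""
    z = norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(max(result.variance, 0.0))
    return (float(max(result.auc - half, 0.0)), float(min(result.auc + half, 1.0)))


def delong_paired_test(
    scores_a: Iterable[float], scores_b: Iterable[float], labels: Iterable[int]
) -> DelongResult:
    """Paired DeLong test for two correlated ROC curves on the same samples."""
    scores_a = np.asarray(scores_a, dtype=np.float64)
    scores_b = np.asarray(scores_b, dtype=np.float64)
    labels = np.asarray(labels)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired score vectors must have equal length")
    pos_a, neg_a = _split(scores_a, labels)
    pos_b, neg_b = _split(scores_b, labels)
    auc_a, v10a, v01a = _components(pos_a, neg_a)
    auc_b, v10b, v01b = _components(pos_b, neg_b)
    m, n = len(pos_a), len(neg_a)
    var_diff = (
        (_comp_var(v10a) + _comp_var(v10b) - 2 * _comp_cov(v10a, v10b)) / m
        + (_comp_var(v01a) + _comp_var(v01b) - 2 * _comp_cov(v01a, v01b)) / n
    )
    var_diff = max(var_diff, 0.0)
    diff = auc_a - auc_b
    if var_diff == 0.0:
        # identical (or perfectly co-varying) scores: no evidence of a
        # difference when the AUCs agree; certainty when they do not
        z = 0.0 if diff == 0.0 else np.inf * np.sign(diff)
        p = 1.0 if diff == 0.0 else 0.0
    else:
        z = diff / np.sqrt(var_diff)
        p = float(2.0 * norm.sf(abs(z)))
    return DelongResult(auc_a=auc_a, auc_b=auc_b, var_diff=float(var_diff),
                        z=float(z), p=float(p))


# ---------------------------------------------------------------------------
# OOF-table front ends


def _scores_and_labels(mean_table: pd.DataFrame, variant: str,
                       positive: str = "cancer") -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    sub = mean_table[mean_table["variant"] == variant].sort_values("image_id")
    if sub.empty:
        raise ValueError(f"variant {variant!r} not present in the table")
    scores = sub["p_cancer"].to_numpy()
    labels = (sub["diagnostic_label"] == positive).astype(int).to_numpy()
    return scores, labels, sub


def variant_auc(mean_table: pd.DataFrame, variant: str) -> AucResult:
    """Overall cancer-vs-rest AUC of one model variant's mean OOF scores."""
    scores, labels, _ = _scores_and_labels(mean_table, variant)
    return binary_auc(scores, labels)


def per_finding_auc(
    mean_table: pd.DataFrame, variant: str, finding: str, include_normals: bool = False
) -> AucResult:
    """Cancer-vs-benign AUC restricted to patches carrying one finding tag.

    Normals carry no finding tags and are excluded by default;
    ``include_normals=True`` adds them to the negative class instead.
    """
    sub = mean_table[mean_table["variant"] == variant]
    has_tag = sub["finding_tags"].fillna("").str.split(";").apply(lambda t: finding in t)
    rows = sub[has_tag]
    if include_normals:
        rows = pd.concat([rows, sub[sub["diagnostic_label"] == "normal"]])
    if rows.empty:
        raise DegenerateLabelsError(f"no patches tagged {finding!r}")
    scores = rows["p_cancer"].to_numpy()
    labels = (rows["diagnostic_label"] == "cancer").astype(int).to_numpy()
    return binary_auc(scores, labels)


def compare_variants(mean_table: pd.DataFrame, variant_a: str, variant_b: str) -> DelongResult:
    """Paired DeLong test between two variants on the integrated OOF set."""
    sa, la, suba = _scores_and_labels(mean_table, variant_a)
    sb, lb, subb = _scores_and_labels(mean_table, variant_b)
    if not np.array_equal(suba["image_id"].to_numpy(), subb["image_id"].to_numpy()):
        raise ValueError("variants are not scored on the same patches")
    return delong_paired_test(sa, sb, la)


def roc_points(scores: Iterable[float], labels: Iterable[int]) -> pd.DataFrame:
    """Empirical ROC curve: one (fpr, tpr, threshold) row per distinct score."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    tps = np.cumsum(y)
    fps = np.cumsum(~y)
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tpr = tps[distinct] / max(tps[-1], 1)
    fpr = fps[distinct] / max(fps[-1], 1)
    return pd.DataFrame(
        {"threshold": np.r_[s[distinct]], "fpr": np.r_[fpr], "tpr": np.r_[tpr]}
    )


def metrics_report(mean_table: pd.DataFrame, findings: Sequence[str] = ("calcification", "mass")) -> dict:
    """JSON-ready report: per-variant overall AUC + CI, pairwise DeLong
    table, per-finding AUCs."""
    variants = sorted(mean_table["variant"].unique())
    report: dict = {"overall": {}, "per_finding": {}, "delong": {}}
    for v in variants:
        res = variant_auc(mean_table, v)
        report["overall"][v] = {
            "auc": res.auc,
            "variance": res.variance,
            "ci95": list(res.ci95),
            "n_pos": res.n_pos,
            "n_neg": res.n_neg,
        }
        report["per_finding"][v] = {}
        for f in findings:
            try:
                r = per_finding_auc(mean_table, v, f)
                report["per_finding"][v][f] = {"auc": r.auc, "ci95": list(r.ci95)}
            except DegenerateLabelsError:
                report["per_finding"][v][f] = None
    for i, a in enumerate(variants):
        for b in variants[i + 1 :]:
            d = compare_variants(mean_table, a, b)
            report["delong"][f"{a}_vs_{b}"] = {
                "auc_a": d.auc_a, "auc_b": d.auc_b, "z": d.z, "p": d.p,
            }
    return report
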