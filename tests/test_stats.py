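"""ROC/AUC and DeLong statistics against independent oracles: brute-force
pairwise enumeration, a sign-flip permutation test, and scikit-learn."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from helpers import brute_auc, brute_components, brute_delong_variance
from morfse.model import ClassProbabilities
from morfse.stats import (
    DegenerateLabelsError,
    AucResult,
    auc_ci,
    binary_auc,
    cancer_score,
    compare_variants,
    delong_paired_test,
    delong_variance,
    metrics_report,
    per_finding_auc,
    roc_points,
)


# ---------------------------------------------------------------------------
# cancer score


def test_cancer_score_is_p_cancer():
    assert cancer_score(ClassProbabilities(0.7, 0.2, 0.1)) == 0.7
    third = 1 / 3
    assert cancer_score(ClassProbabilities(third, third, third)) == pytest.approx(third)


# ---------------------------------------------------------------------------
# AUC


def test_auc_worked_example():
    scores = [0.9, 0.4, 0.5, 0.1]
    labels = [1, 1, 0, 0]
    res = binary_auc(scores, labels)
    assert res.auc == pytest.approx(0.75)  # pairs: 1 + 1 + 0 + 1 = 3/4
    assert res.auc == pytest.approx(brute_auc(scores, labels))
    assert res.n_pos == res.n_neg == 2


def test_auc_boundary_cases():
    perfect = binary_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert perfect.auc == 1.0
    assert perfect.variance == 0.0
    ties = binary_auc([0.5] * 6, [1, 1, 1, 0, 0, 0])
    assert ties.auc == 0.5
    with pytest.raises(DegenerateLabelsError):
        binary_auc([0.1, 0.2], [1, 1])


def test_auc_matches_brute_force_on_random_instances():
    rng = np.random.default_rng(42)
    for _ in range(300):
        n = rng.integers(3, 30)
        scores = rng.choice([0.1, 0.3, 0.5, 0.5, 0.7, 0.9], size=n)
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            continue
        assert binary_auc(scores, labels).auc == brute_auc(scores, labels)


def test_auc_matches_sklearn():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(7)
    scores = rng.normal(size=200) + np.r_[np.ones(100), np.zeros(100)]
    labels = np.r_[np.ones(100), np.zeros(100)]
    assert binary_auc(scores, labels).auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(0, 2**32 - 1), st.floats(0.1, 5.0), st.floats(-3.0, 3.0))
def test_auc_invariant_under_monotone_transform(seed, scale, shift):
    rng = np.random.default_rng(seed)
    scores = rng.normal(size=40)
    labels = np.r_[np.ones(20), np.zeros(20)]
    base = binary_auc(scores, labels).auc
    assert binary_auc(np.exp(scale * scores + shift), labels).auc == pytest.approx(base)


# ---------------------------------------------------------------------------
# DeLong variance


def test_delong_variance_hand_computation():
    scores = [0.9, 0.4, 0.5, 0.1]
    labels = [1, 1, 0, 0]
    # by enumeration: V10 = {1, 0.5}, V01 = {0.5, 1}; variance = S10/2 + S01/2
    v10, v01 = brute_components(scores, labels)
    assert v10.tolist() == [1.0, 0.5]
    assert v01.tolist() == [0.5, 1.0]
    expected = np.var(v10, ddof=1) / 2 + np.var(v01, ddof=1) / 2
    assert delong_variance(scores, labels) == pytest.approx(expected)
    assert delong_variance(scores, labels) == pytest.approx(brute_delong_variance(scores, labels))


def test_delong_variance_zero_when_separated():
    assert delong_variance([0.9, 0.8, 0.2, 0.1, 0.05], [1, 1, 0, 0, 0]) == 0.0


def test_delong_variance_matches_brute_force_with_ties():
    rng = np.random.default_rng(3)
    for _ in range(50):
        n = int(rng.integers(6, 30))
        scores = rng.choice([0.2, 0.4, 0.6, 0.8], size=n)
        labels = np.r_[np.ones(n // 2), np.zeros(n - n // 2)]
        assert delong_variance(scores, labels) == pytest.approx(
            brute_delong_variance(scores, labels), abs=1e-12
        )


# ---------------------------------------------------------------------------
# confidence intervals


def test_ci_worked_example():
    res = AucResult(auc=0.75, variance=0.01, ci95=(0, 0), n_pos=10, n_neg=10)
    lo, hi = auc_ci(res)
    assert (lo, hi) == (pytest.approx(0.554, abs=5e-4), pytest.approx(0.946, abs=5e-4))


def test_ci_degenerate_and_clipped():
    res = AucResult(auc=0.8, variance=0.0, ci95=(0, 0), n_pos=5, n_neg=5)
    assert auc_ci(res) == (0.8, 0.8)
    res = AucResult(auc=0.99, variance=0.25, ci95=(0, 0), n_pos=5, n_neg=5)
    lo, hi = auc_ci(res)
    assert hi == 1.0  # upper limit clipped at 1
    assert lo == pytest.approx(0.99 - 1.959964 * 0.5, abs=1e-6)


# ---------------------------------------------------------------------------
# paired test


def test_identical_scores_give_p_one():
    scores = [0.8, 0.6, 0.4, 0.3]
    labels = [1, 1, 0, 0]
    res = delong_paired_test(scores, scores, labels)
    assert res.p == 1.0
    assert res.z == 0.0


def test_swap_negates_z_keeps_p():
    rng = np.random.default_rng(0)
    labels = np.r_[np.ones(30), np.zeros(30)]
    a = rng.normal(size=60) + labels
    b = rng.normal(size=60) + 0.5 * labels
    ab = delong_paired_test(a, b, labels)
    ba = delong_paired_test(b, a, labels)
    assert ab.z == pytest.approx(-ba.z)
    assert ab.p == pytest.approx(ba.p)
    assert ab.auc_a == ba.auc_b


def test_var_diff_matches_brute_covariances():
    rng = np.random.default_rng(5)
    labels = np.r_[np.ones(15), np.zeros(20)]
    shared = rng.normal(size=35)
    a = shared + 0.5 * rng.normal(size=35) + labels
    b = shared + 0.5 * rng.normal(size=35) + 0.8 * labels
    v10a, v01a = brute_components(a, labels)
    v10b, v01b = brute_components(b, labels)
    expected = (
        np.var(v10a, ddof=1) + np.var(v10b, ddof=1) - 2 * np.cov(v10a, v10b, ddof=1)[0, 1]
    ) / 15 + (
        np.var(v01a, ddof=1) + np.var(v01b, ddof=1) - 2 * np.cov(v01a, v01b, ddof=1)[0, 1]
    ) / 20
    res = delong_paired_test(a, b, labels)
    assert res.var_diff == pytest.approx(expected, abs=1e-12)


def test_paired_p_close_to_permutation_oracle():
    """Sign-flip permutation distribution of the AUC difference as an
    independent check of the asymptotic p-value (n = 60 pairs)."""
    rng = np.random.default_rng(17)
    labels = np.r_[np.ones(30), np.zeros(30)]
    shared = rng.normal(size=60) + 0.8 * labels
    a = shared + 0.6 * rng.normal(size=60)
    b = shared + 0.6 * rng.normal(size=60)
    observed = brute_auc(a, labels) - brute_auc(b, labels)
    flips = rng.random((5000, 60)) < 0.5
    count = 0
    for f in flips:
        pa = np.where(f, b, a)
        pb = np.where(f, a, b)
        if abs(brute_auc(pa, labels) - brute_auc(pb, labels)) >= abs(observed) - 1e-12:
            count += 1
    p_perm = count / 5000
    p_delong = delong_paired_test(a, b, labels).p
    assert abs(p_delong - p_perm) <= 0.03


def test_length_mismatch_raises():
    with pytest.raises(ValueError):
        delong_paired_test([0.1, 0.2], [0.1], [1, 0])


# ---------------------------------------------------------------------------
# OOF-table front ends


def _mean_table():
    rows = []
    entries = [
        ("c1", "cancer", "calcification", 0.9),
        ("c2", "cancer", "calcification", 0.8),
        ("b1", "benign", "calcification", 0.3),
        ("b2", "benign", "calcification", 0.95),
        ("m1", "cancer", "mass", 0.7),
        ("m2", "benign", "mass", 0.2),
        ("x1", "cancer", "calcification;mass", 0.6),
        ("n1", "normal", "", 0.1),
        ("n2", "normal", "", 0.2),
    ]
    for variant in ("morfse", "nognet"):
        for pid, label, tags, p in entries:
            rows.append(
                {
                    "image_id": pid, "variant": variant, "p_cancer": p,
                    "p_benign": (1 - p) / 2, "p_normal": (1 - p) / 2,
                    "wc": 0.5, "diagnostic_label": label, "finding_tags": tags,
                    "fold": 0, "patient_id": pid,
                }
            )
    return pd.DataFrame(rows)


def test_per_finding_auc_excludes_normals():
    table = _mean_table()
    res = per_finding_auc(table, "morfse", "calcification")
    # positives {0.9, 0.8, 0.6}, negatives {0.3, 0.95}: brute enumeration
    scores = [0.9, 0.8, 0.6, 0.3, 0.95]
    labels = [1, 1, 1, 0, 0]
    assert res.auc == pytest.approx(brute_auc(scores, labels))
    assert res.n_pos == 3 and res.n_neg == 2


def test_both_finding_patch_in_both_subsets():
    table = _mean_table()
    calc = per_finding_auc(table, "morfse", "calcification")
    mass = per_finding_auc(table, "morfse", "mass")
    assert calc.n_pos + calc.n_neg == 5
    assert mass.n_pos + mass.n_neg == 3  # m1, m2 and the dual-tagged x1


def test_single_class_finding_raises():
    table = _mean_table()
    only_cancer = table[~table["image_id"].isin(["m2"])]
    with pytest.raises(DegenerateLabelsError):
        per_finding_auc(only_cancer, "morfse", "mass")


def test_compare_variants_and_report():
    table = _mean_table()
    res = compare_variants(table, "morfse", "nognet")
    assert res.p == 1.0  # identical scores by construction
    rep = metrics_report(table)
    assert set(rep["overall"]) == {"morfse", "nognet"}
    assert rep["delong"]["morfse_vs_nognet"]["p"] == 1.0
    assert rep["per_finding"]["morfse"]["calcification"]["auc"] == pytest.approx(
        per_finding_auc(table, "morfse", "calcification").auc
    )


def test_roc_points_monotone():
    rng = np.random.default_rng(1)
    labels = np.r_[np.ones(20), np.zeros(20)]
    scores = rng.normal(size=40) + labels
    pts = roc_points(scores, labels)
    assert (np.diff(pts["fpr"]) >= 0).all()
    assert (np.diff(pts["tpr"]) >= 0).all()
    assert pts["tpr"].iloc[-1] == 1.0 and pts["fpr"].iloc[-1] == 1.0
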