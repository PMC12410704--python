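"""Routing rules, grouped stratified folds, deterministic training, and the
repeated-CV bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from morfse.synth import PatchRecord, SynthConfig, gen_dataset
from morfse.training import (
    ConfigError,
    OofTable,
    StratificationError,
    TrainConfig,
    _stack,
    gate_finding_accuracy,
    make_folds,
    route_training_images,
    run_repeated_cv,
    train_network,
)


def _rec(name, label, tags, patient=None):
    return PatchRecord(
        pixels=np.zeros((32, 32)),
        diagnostic_label=label,
        finding_tags=frozenset(tags),
        patient_id=patient or f"pat-{name}",
        image_id=name,
    )


@pytest.fixture()
def toy_records():
    return [
        _rec("A", "cancer", {"calcification"}),
        _rec("B", "benign", {"mass"}),
        _rec("C", "normal", set()),
        _rec("D", "cancer", {"calcification", "mass"}),
    ]


# ---------------------------------------------------------------------------
# routing


def test_routing_gate_duplicates_multi_tag(toy_records):
    routed = route_training_images(toy_records, "gnet")
    assert [(r.image_id, t) for r, t in routed] == [
        ("A", "calcification"),
        ("B", "mass"),
        ("D", "calcification"),
        ("D", "mass"),
    ]


def test_routing_experts_and_conventional(toy_records):
    cexp = route_training_images(toy_records, "cexp")
    assert {r.image_id for r, _ in cexp} == {"A", "C", "D"}
    assert all(t == r.diagnostic_label for r, t in cexp)
    mexp = route_training_images(toy_records, "mexp")
    assert {r.image_id for r, _ in mexp} == {"B", "C", "D"}
    conv = route_training_images(toy_records, "conventional")
    assert {r.image_id for r, _ in conv} == {"A", "B", "C", "D"}


def test_routing_rejects_empty_subset():
    mass_only = [_rec("B", "benign", {"mass"})]
    with pytest.raises(ConfigError):
        route_training_images(mass_only, "cexp")
    with pytest.raises(ConfigError):
        route_training_images([], "conventional")


# ---------------------------------------------------------------------------
# folds


def _patients(n_per_label):
    recs = []
    for label, n in n_per_label.items():
        tags = set() if label == "normal" else {"mass"}
        for i in range(n):
            recs.append(_rec(f"{label}{i}", label, tags, patient=f"{label}-p{i}"))
    return recs


def test_fold_balance_and_determinism():
    recs = _patients({"cancer": 20, "benign": 15, "normal": 15})
    folds = make_folds(recs, 5, seed=3)
    sizes = np.bincount([folds[r.patient_id] for r in recs], minlength=5)
    assert sizes.sum() == 50
    # per-stratum patient counts differ by at most one
    for label, n in (("cancer", 20), ("benign", 15), ("normal", 15)):
        per = np.bincount(
            [folds[r.patient_id] for r in recs if r.diagnostic_label == label], minlength=5
        )
        assert per.max() - per.min() <= 1
    assert folds == make_folds(recs, 5, seed=3)
    assert folds != make_folds(recs, 5, seed=4)


def test_patient_patches_share_a_fold():
    recs = [_rec(f"x{i}", "cancer", {"mass"}, patient="shared") for i in range(3)]
    recs += _patients({"cancer": 6, "benign": 5, "normal": 5})
    folds = make_folds(recs, 5, seed=0)
    assert len({folds[r.patient_id] for r in recs[:3]}) == 1


def test_small_stratum_raises():
    recs = _patients({"cancer": 5, "benign": 2, "normal": 5})
    with pytest.raises(StratificationError):
        make_folds(recs, 5, seed=0)


def test_patient_spanning_classes_raises():
    recs = [
        _rec("a", "cancer", {"mass"}, patient="p0"),
        _rec("b", "benign", {"mass"}, patient="p0"),
    ]
    with pytest.raises(StratificationError):
        make_folds(recs, 2, seed=0)


# ---------------------------------------------------------------------------
# training determinism and the separable fixture


@pytest.fixture(scope="module")
def separable_calc_records():
    cfg = SynthConfig(
        noise_sd=0.0,
        background_texture_amp=0.0,
        calc_dot_count_benign=(2.0, 0.5),
        calc_dot_count_malignant=(25.0, 2.0),
        calc_cluster_radius_benign=26.0,
        calc_cluster_radius_malignant=6.0,
        n_per_cell={
            "cancer-calcification": 25,
            "cancer-mass": 25,
            "benign-calcification": 13,
            "benign-mass": 13,
            "normal": 25,
        },
    )
    return gen_dataset(cfg)


def test_separable_fixture_trains_above_ninety(separable_calc_records):
    tc = TrainConfig(fast_mode=True, fast_epochs=5, fast_learning_rate=2e-3, batch_size=8)
    subset = route_training_images(separable_calc_records, "cexp")
    net = train_network(subset, tc, seed=1, n_out=3)
    x, y = _stack(subset, 32, 3)
    acc = (net.predict_logits(x).argmax(1) == y).mean()
    assert acc > 0.9


def test_zero_epochs_returns_initialisation(separable_calc_records):
    tc = TrainConfig(fast_mode=True, fast_epochs=0)
    subset = route_training_images(separable_calc_records, "gnet")
    net = train_network(subset, tc, seed=7, n_out=2)
    from morfse.model import BackboneSpec, build_backbone

    init = build_backbone(BackboneSpec(input_side=32, n_out=2), seed=7)
    assert all(np.array_equal(a, b) for a, b in zip(net.params, init.params))
    assert net.loss_history == []


def test_training_is_deterministic(separable_calc_records):
    tc = TrainConfig(fast_mode=True, fast_epochs=3)
    subset = route_training_images(separable_calc_records, "gnet")
    n1 = train_network(subset, tc, seed=11, n_out=2)
    n2 = train_network(subset, tc, seed=11, n_out=2)
    assert n1.loss_history == n2.loss_history
    assert all(np.array_equal(a, b) for a, b in zip(n1.params, n2.params))


# ---------------------------------------------------------------------------
# repeated CV bookkeeping


@pytest.fixture(scope="module")
def small_cv_result():
    records = gen_dataset(SynthConfig(seed=21, n_per_cell=10))
    cfg = TrainConfig(fast_mode=True, fast_epochs=1, repetitions=2, folds=5, master_seed=21)
    return records, cfg, run_repeated_cv(records, cfg)


def test_oof_row_bookkeeping(small_cv_result):
    records, cfg, oof = small_cv_result
    assert len(oof.table) == 50 * 3 * 2
    counts = oof.table.groupby(["image_id", "variant"]).size()
    assert (counts == 2).all()
    mean = oof.mean_table()
    assert len(mean) == 50 * 3
    probs = mean[["p_cancer", "p_benign", "p_normal"]].to_numpy()
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    # mean equals the arithmetic mean of the retained repetition rows
    one = oof.table[(oof.table["image_id"] == records[0].image_id) & (oof.table["variant"] == "morfse")]
    got = mean[(mean["image_id"] == records[0].image_id) & (mean["variant"] == "morfse")]
    assert got["p_cancer"].iloc[0] == pytest.approx(one["p_cancer"].mean())


def test_no_training_leakage(small_cv_result):
    records, cfg, oof = small_cv_result
    fold_of_patch = dict(zip(oof.table["image_id"], oof.table["fold"]))
    for (rep, fold), train_ids in oof.training_ids.items():
        held_out = {pid for pid, f in fold_of_patch.items() if f == fold}
        assert not (held_out & train_ids)
    # and each patch was predicted by the models of its own fold only
    assert set(oof.table["fold"].unique()) == set(range(5))


def test_single_repetition_mean_is_identity():
    records = gen_dataset(SynthConfig(seed=2, n_per_cell=10))
    cfg = TrainConfig(fast_mode=True, fast_epochs=1, repetitions=1, folds=5, master_seed=2)
    oof = run_repeated_cv(records, cfg)
    mean = oof.mean_table().set_index(["image_id", "variant"])
    for _, row in oof.table.iterrows():
        assert mean.loc[(row["image_id"], row["variant"]), "p_cancer"] == pytest.approx(row["p_cancer"])


def test_oof_csv_roundtrip(tmp_path, small_cv_result):
    _, _, oof = small_cv_result
    oof.to_csv(tmp_path / "oof.csv")
    back = OofTable.from_csv(tmp_path / "oof.csv")
    assert back.repetitions == 2
    pd.testing.assert_frame_equal(
        back.mean_table().drop(columns=["wc"]),
        oof.mean_table().drop(columns=["wc"]),
        check_dtype=False,
    )


def test_gate_accuracy_from_known_weights():
    rows = []
    for i, (tags, wc) in enumerate(
        [("calcification", 0.9), ("calcification", 0.2), ("mass", 0.1), ("mass", 0.3)]
    ):
        rows.append(
            {
                "image_id": f"p{i}", "patient_id": f"p{i}", "variant": "morfse",
                "fold": 0, "repetition": 0, "p_cancer": 0.5, "p_benign": 0.25,
                "p_normal": 0.25, "wc": wc, "diagnostic_label": "cancer",
                "finding_tags": tags,
            }
        )
    oof = OofTable(pd.DataFrame(rows), {}, repetitions=1)
    assert gate_finding_accuracy(oof) == pytest.approx(0.75)
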