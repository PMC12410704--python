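"""Training-data routing, grouped stratified folds, and the repeated
cross-validation that produces mean out-of-fold predictions.

Routing rules
-------------
Each of the four networks sees a different training subset:

* gate (gNet): every lesion patch, labelled by its finding type; a patch
  tagged with both findings contributes one training instance per tag;
* calcification expert (cExp): calcification-tagged patches plus all
  normals, labelled by diagnosis;
* mass expert (mExp): mass-tagged patches plus all normals, labelled by
  diagnosis;
* conventional baseline: every patch, labelled by diagnosis.

Cross-validation
----------------
One fixed patient-grouped, diagnosis-stratified K-fold partition is drawn
from the master seed.  The whole K-fold cycle is repeated R times with
different network-initialisation and data-order seeds; each repetition
predicts every held-out patch with all three variants (mixture, equal-weight
ensemble, conventional), and per-patch predictions are averaged over
repetitions.  Repetitions reuse the single partition so that integrating the
out-of-fold predictions over folds is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import (
    CLASS_ORDER,
    GATE_ORDER,
    BackboneSpec,
    build_backbone,
)
from .nn import softmax
from .synth import PatchRecord

__all__ = [
    "TrainConfig",
    "ConfigError",
    "StratificationError",
    "DivergenceError",
    "FoldAssignment",
    "OofTable",
    "route_training_images",
    "make_folds",
    "train_network",
    "run_repeated_cv",
    "gate_finding_accuracy",
]

ROLES = ("gnet", "cexp", "mexp", "conventional")
VARIANTS = ("morfse", "nognet", "conventional")


class ConfigError(ValueError):
    """Invalid configuration or an empty routed training subset."""


class StratificationError(ValueError):
    """A diagnostic stratum has fewer patients than folds."""


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation and evaluation-protocol settings.

    The defaults are the full-scale settings: batch 64, 30 epochs, Adam with
    learning rate 1e-5 and zero weight decay, cross-entropy loss, 5x5-fold
    evaluation.  ``fast_mode`` swaps in desk-scale overrides (fewer epochs, a
    32-pixel input side and a learning rate the tiny network can actually
    learn with over tens of gradient steps).
    """

    batch_size: int = 64
    epochs: int = 30
    learning_rate: float = 1e-5
    weight_decay: float = 0.0
    backbone: BackboneSpec = field(default_factory=BackboneSpec)
    repetitions: int = 5
    folds: int = 5
    master_seed: int = 0
    fast_mode: bool = False
    fast_epochs: int = 20
    fast_learning_rate: float = 1e-3
    fast_input_side: int = 32

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ConfigError("folds must be >= 2")
        if self.repetitions < 1:
            raise ConfigError("repetitions must be >= 1")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ConfigError("epochs must be >= 0")

    def resolved(self) -> "TrainConfig":
        """Apply fast-mode overrides; idempotent."""
        if not self.fast_mode:
            return self
        bb = replace(self.backbone, name="smallcnn", pretrained=False,
                     input_side=self.fast_input_side)
        return replace(
            self,
            epochs=self.fast_epochs,
            learning_rate=self.fast_learning_rate,
            backbone=bb,
            fast_mode=False,
        )


FoldAssignment = dict[str, int]  # patient_id -> fold index


# ---------------------------------------------------------------------------
# routing


def route_training_images(
    records: Sequence[PatchRecord], role: str
) -> list[tuple[PatchRecord, str]]:
    """Select and label the training instances for one network role.

    Returns ``(record, target)`` pairs; targets are finding names for the
    gate and diagnostic labels for everything else.
    """
    if role not in ROLES:
        raise ConfigError(f"unknown role {role!r}")
    out: list[tuple[PatchRecord, str]] = []
    for rec in records:
        if role == "gnet":
            for tag in sorted(rec.finding_tags):
                out.append((rec, tag))
        elif role == "cexp":
            if "calcification" in rec.finding_tags or rec.diagnostic_label == "normal":
                out.append((rec, rec.diagnostic_label))
        elif role == "mexp":
            if "mass" in rec.finding_tags or rec.diagnostic_label == "normal":
                out.append((rec, rec.diagnostic_label))
        else:
            out.append((rec, rec.diagnostic_label))
    if not out:
        raise ConfigError(f"routing for role {role!r} produced an empty subset")
    return out


# ---------------------------------------------------------------------------
# folds


def make_folds(records: Sequence[PatchRecord], k: int, seed: int) -> FoldAssignment:
    """Patient-grouped, diagnosis-stratified fold assignment.

    Patients within each diagnostic stratum are shuffled and dealt
    round-robin, so per-stratum fold sizes (in patients) differ by at most
    one.  A patient whose patches span diagnostic classes is rejected.
    """
    strata: dict[str, dict[str, None]] = {}
    patient_label: dict[str, str] = {}
    for rec in records:
        prev = patient_label.setdefault(rec.patient_id, rec.diagnostic_label)
        if prev != rec.diagnostic_label:
            raise StratificationError(
                f"patient {rec.patient_id} spans diagnostic classes {prev}/{rec.diagnostic_label}"
            )
        strata.setdefault(rec.diagnostic_label, {})[rec.patient_id] = None
    rng = np.random.default_rng(seed)
    assignment: FoldAssignment = {}
    for label in sorted(strata):
        patients = sorted(strata[label])
        if len(patients) < k:
            raise StratificationError(
                f"stratum {label!r} has {len(patients)} patients; needs >= {k}"
            )
        order = rng.permutation(len(patients))
        for pos, idx in enumerate(order):
            assignment[patients[idx]] = pos % k
    return assignment


# ---------------------------------------------------------------------------
# single-network training


def _downsample(images: np.ndarray, side: int) -> np.ndarray:
    """Resize a (N, H, W) stack to (N, side, side); block-mean when the
    sides divide evenly, skimage resize otherwise."""
    n, h, w = images.shape
    if h == side and w == side:
        return images
    if h % side == 0 and w % side == 0:
        fh, fw = h // side, w // side
        return images.reshape(n, side, fh, side, fw).mean(axis=(2, 4))
    from skimage.transform import resize

    return resize(images, (n, side, side), anti_aliasing=True, preserve_range=True)


def _stack(subset: Sequence[tuple[PatchRecord, str]], side: int, n_out: int):
    target_names = GATE_ORDER if n_out == 2 else CLASS_ORDER
    images = _downsample(np.stack([rec.pixels for rec, _ in subset]), side)
    targets = np.array([target_names.index(t) for _, t in subset], dtype=np.int64)
    return images, targets


def train_network(
    subset: Sequence[tuple[PatchRecord, str]],
    cfg: TrainConfig,
    seed: int,
    n_out: int | None = None,
):
    """Train one network on a routed subset.

    Cross-entropy loss, Adam, mini-batches shuffled per epoch from ``seed``.
    Returns the network with ``loss_history`` (per-epoch mean loss) attached.
    With ``epochs=0`` the returned network is its initialisation.
    """
    if not subset:
        raise ConfigError("cannot train on an empty subset")
    cfg = cfg.resolved()
    n_out = n_out if n_out is not None else cfg.backbone.n_out
    spec = replace(cfg.backbone, n_out=n_out)
    net = build_backbone(spec, seed=seed)
    net.configure_optimizer(cfg.learning_rate, cfg.weight_decay)
    images, targets = _stack(subset, spec.input_side, n_out)
    rng = np.random.default_rng(seed)
    history: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(subset))
        losses = []
        for start in range(0, len(subset), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            loss = net.train_batch(images[idx], targets[idx])
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite loss in epoch {epoch}, batch {start // cfg.batch_size}"
                )
            losses.append(loss)
        history.append(float(np.mean(losses)))
    net.loss_history = history
    return net


# ---------------------------------------------------------------------------
# repeated cross-validation


class OofTable:
    """Per-repetition out-of-fold predictions for every patch and variant.

    ``table`` has one row per (patch, variant, repetition) with the 3-class
    probabilities, the gate's calcification weight (mixture rows only), the
    true label, finding tags and fold index.  ``mean_table()`` averages the
    R repetitions.  ``training_ids`` records, for each (repetition, fold),
    the union of patch image_ids any predicting model was trained on — the
    raw material for leakage audits.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        training_ids: dict[tuple[int, int], frozenset[str]],
        repetitions: int,
    ) -> None:
        self.table = table.reset_index(drop=True)
        self.training_ids = training_ids
        self.repetitions = repetitions

    def mean_table(self) -> pd.DataFrame:
        """Mean class probabilities per (patch, variant) over repetitions."""
        counts = self.table.groupby(["image_id", "variant"]).size()
        if not (counts == self.repetitions).all():
            raise ValueError("each patch/variant must have exactly R repetition rows")
        agg = (
            self.table.groupby(["image_id", "variant"], as_index=False)
            .agg(
                p_cancer=("p_cancer", "mean"),
                p_benign=("p_benign", "mean"),
                p_normal=("p_normal", "mean"),
                wc=("wc", "mean"),
                diagnostic_label=("diagnostic_label", "first"),
                finding_tags=("finding_tags", "first"),
                fold=("fold", "first"),
                patient_id=("patient_id", "first"),
            )
        )
        return agg

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "OofTable":
        table = pd.read_csv(path, keep_default_na=False)
        # blank gate weights (non-mixture rows) back to NaN; empty tag
        # strings stay empty
        table["wc"] = pd.to_numeric(table["wc"], errors="coerce")
        reps = int(table.groupby(["image_id", "variant"]).size().max())
        return cls(table, training_ids={}, repetitions=reps)


def _derive_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def run_repeated_cv(
    records: Sequence[PatchRecord], cfg: TrainConfig
) -> OofTable:
    """Run R repetitions of patient-grouped stratified K-fold CV and collect
    out-of-fold predictions for the mixture, the equal-weight ensemble and
    the conventional baseline."""
    cfg_r = cfg.resolved()
    k = cfg.folds
    folds = make_folds(records, k, seed=cfg.master_seed)
    side = cfg_r.backbone.input_side

    all_images = _downsample(np.stack([r.pixels for r in records]), side)
    fold_of = np.array([folds[r.patient_id] for r in records])

    rows: list[dict] = []
    training_ids: dict[tuple[int, int], frozenset[str]] = {}
    for rep in range(cfg.repetitions):
        for fold in range(k):
            train_recs = [r for r, f in zip(records, fold_of) if f != fold]
            val_idx = np.flatnonzero(fold_of == fold)
            nets = {}
            for ri, role in enumerate(ROLES):
                subset = route_training_images(train_recs, role)
                seed = _derive_seed(cfg.master_seed, rep, fold, ri)
                n_out = 2 if role == "gnet" else 3
                nets[role] = train_network(subset, cfg, seed, n_out=n_out)
            training_ids[(rep, fold)] = frozenset(r.image_id for r in train_recs)

            xb = all_images[val_idx]
            gate_p = softmax(nets["gnet"].predict_logits(xb))
            pc = softmax(nets["cexp"].predict_logits(xb))
            pm = softmax(nets["mexp"].predict_logits(xb))
            pv = softmax(nets["conventional"].predict_logits(xb))
            wc = gate_p[:, 0:1]
            preds = {
                "morfse": wc * pc + (1 - wc) * pm,
                "nognet": 0.5 * pc + 0.5 * pm,
                "conventional": pv,
            }
            for j, idx in enumerate(val_idx):
                rec = records[idx]
                for variant in VARIANTS:
                    p = preds[variant][j]
                    rows.append(
                        {
                            "image_id": rec.image_id,
                            "patient_id": rec.patient_id,
                            "variant": variant,
                            "fold": fold,
                            "repetition": rep,
                            "p_cancer": float(p[0]),
                            "p_benign": float(p[1]),
                            "p_normal": float(p[2]),
                            "wc": float(wc[j, 0]) if variant == "morfse" else np.nan,
                            "diagnostic_label": rec.diagnostic_label,
                            "finding_tags": ";".join(sorted(rec.finding_tags)),
                        }
                    )
    return OofTable(pd.DataFrame(rows), training_ids, cfg.repetitions)


def gate_finding_accuracy(oof: OofTable) -> float:
    """Accuracy of the gate's dominant weight against the true finding type,
    over single-finding out-of-fold lesion patches."""
    mean = oof.mean_table()
    lesions = mean[(mean["variant"] == "morfse") & mean["finding_tags"].isin(["calcification", "mass"])]
    if lesions.empty:
        raise ValueError("no single-finding lesion patches in the OOF table")
    predicted = np.where(lesions["wc"] > 0.5, "calcification", "mass")
    return float(np.mean(predicted == lesions["finding_tags"].to_numpy()))
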