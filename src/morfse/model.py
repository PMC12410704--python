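"""The mixture-of-finding-specific-experts model family.

Three independently trained classifiers cooperate on a patch ``x``:

* the gate network (gNet) scores whether the lesion is calcification- or
  mass-dominant and emits weights ``(wc, wm)`` with ``wc + wm = 1``;
* the calcification expert (cExp) and mass expert (mExp) each emit 3-class
  probabilities (cancer, benign, normal);
* the mixture output is the convex combination

      y = wc * cExp(x) + wm * mExp(x).

The constraint ``wc + wm = 1`` is enforced structurally by a two-class
softmax head on the gate, so the mixture is automatically a probability
vector.  Two comparison predictors share the machinery: the equal-weight
ensemble (gate pinned at 0.5/0.5) and a conventional single network trained
on everything.

Backbones are pluggable: the desk-scale default is the NumPy ``smallcnn``
(:class:`morfse.nn.SmallCNN`); a ResNet18 configuration (optionally
ImageNet-pretrained) is available when the optional ``torch`` extra is
installed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .nn import SmallCNN, softmax
from .synth import PatchRecord

__all__ = [
    "CLASS_ORDER",
    "BackboneSpec",
    "GateOutput",
    "ClassProbabilities",
    "build_backbone",
    "gate_forward",
    "expert_forward",
    "conventional_predict",
    "morfse_predict",
    "nognet_predict",
    "save_checkpoint",
    "load_checkpoint",
]

#: on-disk and in-memory class ordering; part of the checkpoint contract
CLASS_ORDER = ("cancer", "benign", "normal")

#: gate class ordering: index 0 = calcification weight, 1 = mass weight
GATE_ORDER = ("calcification", "mass")


@dataclass(frozen=True)
class BackboneSpec:
    """Which network architecture realises a gate or expert."""

    name: str = "smallcnn"
    pretrained: bool = False
    input_side: int = 64
    n_out: int = 3

    def __post_init__(self) -> None:
        if self.name not in ("smallcnn", "resnet18"):
            raise ValueError(f"unknown backbone {self.name!r}")
        if self.n_out not in (2, 3):
            raise ValueError("n_out must be 2 (gate) or 3 (expert)")
        if self.pretrained and self.name != "resnet18":
            raise ValueError("pretrained weights are only available for resnet18")


def build_backbone(spec: BackboneSpec, seed: int = 0):
    """Instantiate a trainable network for ``spec``.

    Returns an object exposing ``predict_logits``, ``loss_and_grads``,
    ``params`` and ``copy_params``.
    """
    if spec.name == "smallcnn":
        return SmallCNN(spec.input_side, spec.n_out, seed=seed)
    try:  # pragma: no cover - exercised only with the optional torch extra
        from ._torch_backbone import TorchResNet18
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "the resnet18 backbone requires the optional 'torch' extra "
            "(pip install morfse[torch])"
        ) from exc
    return TorchResNet18(spec, seed=seed)  # pragma: no cover


@dataclass(frozen=True)
class GateOutput:
    """Finding-type weights emitted by the gate; a 2-point probability."""

    wc: float
    wm: float

    def __post_init__(self) -> None:
        if not (-1e-6 <= self.wc <= 1 + 1e-6 and -1e-6 <= self.wm <= 1 + 1e-6):
            raise ValueError("gate weights must lie in [0, 1]")
        if abs(self.wc + self.wm - 1.0) > 1e-6:
            raise ValueError("gate weights must sum to 1")


@dataclass(frozen=True)
class ClassProbabilities:
    """3-class diagnostic probabilities in the order cancer, benign, normal."""

    p_cancer: float
    p_benign: float
    p_normal: float

    def __post_init__(self) -> None:
        vec = (self.p_cancer, self.p_benign, self.p_normal)
        if any(not (-1e-6 <= p <= 1 + 1e-6) for p in vec):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(vec) - 1.0) > 1e-6:
            raise ValueError("probabilities must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_cancer, self.p_benign, self.p_normal])


def _pixels(patch: PatchRecord | np.ndarray) -> np.ndarray:
    return patch.pixels if isinstance(patch, PatchRecord) else np.asarray(patch)


def gate_forward(gate, patch: PatchRecord | np.ndarray) -> GateOutput:
    """Run the gate on one patch; softmax over its two logits."""
    logits = gate.predict_logits(_pixels(patch)[None] if _pixels(patch).ndim == 2 else _pixels(patch))
    if logits.shape[-1] != 2:
        raise ValueError("gate network must have two outputs")
    w = softmax(logits)[0]
    return GateOutput(wc=float(w[0]), wm=float(w[1]))


def expert_forward(expert, patch: PatchRecord | np.ndarray) -> ClassProbabilities:
    """Run an expert (or the conventional net) on one patch; 3-class softmax."""
    px = _pixels(patch)
    logits = expert.predict_logits(px[None] if px.ndim == 2 else px)
    if logits.shape[-1] != 3:
        raise ValueError("expert network must have three outputs")
    p = softmax(logits)[0]
    return ClassProbabilities(float(p[0]), float(p[1]), float(p[2]))


def conventional_predict(net, patch: PatchRecord | np.ndarray) -> ClassProbabilities:
    """Single-network baseline: identical head to an expert, trained on all
    diagnostic-labelled patches."""
    return expert_forward(net, patch)


def mix(gate_out: GateOutput, pc: ClassProbabilities, pm: ClassProbabilities) -> ClassProbabilities:
    """``y = wc * cExp(x) + wm * mExp(x)``, componentwise."""
    y = gate_out.wc * pc.as_array() + gate_out.wm * pm.as_array()
    return ClassProbabilities(float(y[0]), float(y[1]), float(y[2]))


def morfse_predict(gate, cexp, mexp, patch: PatchRecord | np.ndarray) -> ClassProbabilities:
    """Full mixture prediction: gate-weighted convex combination of the two
    experts' class probabilities."""
    return mix(gate_forward(gate, patch), expert_forward(cexp, patch), expert_forward(mexp, patch))


def nognet_predict(cexp, mexp, patch: PatchRecord | np.ndarray) -> ClassProbabilities:
    """Gate-less ensemble baseline: fixed equal weights wc = wm = 0.5."""
    return mix(GateOutput(0.5, 0.5), expert_forward(cexp, patch), expert_forward(mexp, patch))


# ---------------------------------------------------------------------------
# checkpoints: .npz weights + JSON sidecar with the backbone spec and class order


def save_checkpoint(net, spec: BackboneSpec, path: str | Path, config_hash: str = "") -> None:
    path = Path(path)
    np.savez(path, *net.params)
    sidecar = {
        "backbone": asdict(spec),
        "class_order": list(CLASS_ORDER if spec.n_out == 3 else GATE_ORDER),
        "config_hash": config_hash,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path):
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    spec = BackboneSpec(**sidecar["backbone"])
    net = build_backbone(spec, seed=0)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        loaded = [data[k] for k in data.files]
    if len(loaded) != len(net.params):
        raise ValueError("checkpoint does not match backbone architecture")
    net.params = loaded
    return net, spec
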