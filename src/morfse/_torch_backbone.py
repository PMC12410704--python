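"""Optional ResNet18 backbone (requires the ``torch`` extra).

Reproduces the full-scale configuration: ImageNet-initialised ResNet18 with
the final fully connected layer replaced, grayscale patches replicated to
three channels, resized to 224 and standardised with the ImageNet channel
statistics.  Exposes the same ``predict_logits`` / ``loss_and_grads`` /
``params`` surface as :class:`morfse.nn.SmallCNN` so the training loop is
backbone-agnostic.
"""

from __future__ import annotations

import numpy as np
import torch
import torch.nn.functional as F
from torchvision.models import resnet18

_IMAGENET_MEAN = torch.tensor([0.485, 0.456, 0.406]).view(1, 3, 1, 1)
_IMAGENET_STD = torch.tensor([0.229, 0.224, 0.225]).view(1, 3, 1, 1)


class TorchResNet18:
    def __init__(self, spec, seed: int = 0) -> None:
        torch.manual_seed(seed)
        self.net = resnet18(weights="IMAGENET1K_V1" if spec.pretrained else None)
        self.net.fc = torch.nn.Linear(self.net.fc.in_features, spec.n_out)
        self.in_side = spec.input_side
        self.n_out = spec.n_out
        self.net.eval()

    def _prep(self, images: np.ndarray) -> torch.Tensor:
        x = torch.as_tensor(np.asarray(images, dtype=np.float32))
        if x.ndim == 2:
            x = x[None]
        x = x[:, None].repeat(1, 3, 1, 1)
        if x.shape[-1] != 224:
            x = F.interpolate(x, size=(224, 224), mode="bilinear", align_corners=False)
        return (x - _IMAGENET_MEAN) / _IMAGENET_STD

    @property
    def params(self):
        return [p.detach().cpu().numpy() for p in self.net.parameters()]

    def copy_params(self):
        return [p.copy() for p in self.params]

    def predict_logits(self, images: np.ndarray) -> np.ndarray:
        self.net.eval()
        with torch.no_grad():
            return self.net(self._prep(images)).cpu().numpy().astype(np.float64)

    def configure_optimizer(self, lr: float, weight_decay: float = 0.0) -> None:
        self._opt = torch.optim.Adam(self.net.parameters(), lr=lr, weight_decay=weight_decay)

    def train_batch(self, images: np.ndarray, targets: np.ndarray) -> float:
        self.net.train()
        logits = self.net(self._prep(images))
        loss = F.cross_entropy(logits, torch.as_tensor(targets, dtype=torch.long))
        self._opt.zero_grad()
        loss.backward()
        self._opt.step()
        return float(loss.item())
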