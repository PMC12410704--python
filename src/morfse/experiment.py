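"""Model/Results front end for a full mixture-of-experts evaluation run.

``MorfseExperiment`` is constructed from patch records plus a training
configuration; ``fit()`` runs the repeated grouped-stratified K-fold
cross-validation for all three predictor variants and returns a
``MorfseResults`` carrying the out-of-fold table, AUC estimates with DeLong
uncertainties, pairwise tests and a ``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import stats
from .synth import PatchRecord, SynthConfig, gen_dataset, load_dataset
from .training import (
    OofTable,
    TrainConfig,
    VARIANTS,
    gate_finding_accuracy,
    run_repeated_cv,
)

__all__ = ["MorfseExperiment", "MorfseResults"]


class MorfseExperiment:
    """A planned evaluation of the gated mixture against its baselines.

    Parameters
    ----------
    records : the labelled patches to evaluate on
    config : optimisation and CV-protocol settings
    """

    def __init__(self, records: Sequence[PatchRecord], config: TrainConfig | None = None) -> None:
        if not records:
            raise ValueError("no patch records supplied")
        self.records = list(records)
        self.config = config or TrainConfig()

    @classmethod
    def from_synthetic(cls, synth: SynthConfig, config: TrainConfig | None = None) -> "MorfseExperiment":
        return cls(gen_dataset(synth), config)

    @classmethod
    def from_dataset_dir(cls, path: str | Path, config: TrainConfig | None = None) -> "MorfseExperiment":
        return cls(load_dataset(path), config)

    def fit(self, master_seed: int | None = None) -> "MorfseResults":
        cfg = self.config
        if master_seed is not None:
            cfg = replace(cfg, master_seed=master_seed)
        oof = run_repeated_cv(self.records, cfg)
        return MorfseResults(oof, cfg)


class MorfseResults:
    """Fitted results: the OOF table plus ROC statistics over it."""

    def __init__(self, oof: OofTable, config: TrainConfig) -> None:
        self.oof = oof
        self.config = config
        self.mean_table = oof.mean_table()

    # -- estimates ---------------------------------------------------------

    def auc(self, variant: str = "morfse") -> stats.AucResult:
        return stats.variant_auc(self.mean_table, variant)

    def per_finding_auc(self, variant: str, finding: str, include_normals: bool = False) -> stats.AucResult:
        return stats.per_finding_auc(self.mean_table, variant, finding, include_normals)

    def compare(self, variant_a: str, variant_b: str) -> stats.DelongResult:
        return stats.compare_variants(self.mean_table, variant_a, variant_b)

    def gate_accuracy(self) -> float:
        return gate_finding_accuracy(self.oof)

    def report(self) -> dict:
        rep = stats.metrics_report(self.mean_table)
        rep["gate_finding_accuracy"] = self.gate_accuracy()
        return rep

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        lines = ["Mixture-of-experts evaluation", "=" * 64]
        n = self.mean_table["image_id"].nunique()
        lines.append(
            f"patches: {n}   folds: {self.config.folds}   repetitions: {self.config.repetitions}"
        )
        lines.append(f"{'variant':<14}{'AUC':>8}{'95% CI':>22}{'n+/n-':>12}")
        for v in VARIANTS:
            r = self.auc(v)
            lines.append(
                f"{v:<14}{r.auc:>8.4f}   ({r.ci95[0]:.4f}-{r.ci95[1]:.4f})"
                f"{f'{r.n_pos}/{r.n_neg}':>14}"
            )
        lines.append("-" * 64)
        for a, b in (("morfse", "conventional"), ("morfse", "nognet"), ("conventional", "nognet")):
            d = self.compare(a, b)
            lines.append(f"DeLong {a} vs {b}: z = {d.z:+.3f}, p = {d.p:.4g}")
        try:
            lines.append(f"gate finding accuracy: {self.gate_accuracy():.3f}")
        except ValueError:
            pass
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> None:
        """Persist the per-repetition OOF CSV and the metrics JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.oof.to_csv(outdir / "oof.csv")
        (outdir / "metrics.json").write_text(json.dumps(self.report(), indent=2))

    def plot_roc(self, ax=None):
        """Overlay the three variants' ROC curves (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for v in VARIANTS:
            sub = self.mean_table[self.mean_table["variant"] == v]
            pts = stats.roc_points(
                sub["p_cancer"].to_numpy(),
                (sub["diagnostic_label"] == "cancer").astype(int).to_numpy(),
            )
            ax.plot(pts["fpr"], pts["tpr"], label=f"{v} (AUC {self.auc(v).auc:.3f})")
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend()
        return ax
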