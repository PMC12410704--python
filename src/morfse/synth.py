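"""Synthetic mammographic patch generator.

Renders small grayscale patches of the three diagnostic classes (cancer,
benign, normal) crossed with two radiological finding types (calcification,
mass), with malignancy cues that are *finding-specific by construction*:

* calcifications — malignant clusters contain more, smaller, more
  size-variable and more elongated ("pleomorphic") dots packed into a
  tighter cluster; benign clusters are fewer, larger, rounder and scattered;
* masses — benign masses are smooth ovals with a sharp margin; malignant
  masses have an irregular boundary, radial spicules and a blurred margin.

Because each cue lives on only one finding type, a classifier specialised on
one finding has genuinely distinct signal to exploit — the property a
mixture-of-experts test bed needs.

Patches are stored in ``[0, 1]`` with lesions hyperintense relative to the
background, matching the mammographic appearance of calcifications and dense
masses.  All pixel-valued parameters are expressed at a reference side of 64
pixels and scaled linearly with ``image_size`` so one configuration yields
geometrically similar patches at any resolution.

Randomness is counter-based: each patch draws from its own
``numpy.random.Generator`` seeded by ``(master seed, cell index, patch
index)``, so enlarging ``n_per_cell`` never reshuffles previously generated
patches and dataset generation is a pure function of the configuration.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "SynthConfig",
    "PatchRecord",
    "CELLS",
    "gen_calcification_patch",
    "gen_mass_patch",
    "gen_normal_patch",
    "gen_dataset",
    "proportional_counts",
    "save_dataset",
    "load_dataset",
]

#: reference side at which pixel-valued parameters are stated
_REF_SIDE = 64

#: diagnostic-class mix of the source dataset the generator mirrors
#: (cancer, benign, normal image counts)
_CLASS_MIX = {"cancer": 1462, "benign": 248, "normal": 1054}

#: generation cells: (diagnostic label, finding tag or None)
CELLS: tuple[tuple[str, str | None], ...] = (
    ("cancer", "calcification"),
    ("cancer", "mass"),
    ("benign", "calcification"),
    ("benign", "mass"),
    ("normal", None),
)


@dataclass(frozen=True)
class PatchRecord:
    """One grayscale patch plus its labels and provenance IDs."""

    pixels: np.ndarray
    diagnostic_label: str
    finding_tags: frozenset[str]
    patient_id: str
    image_id: str
    lesion_id: str | None = None

    def __post_init__(self) -> None:
        if self.diagnostic_label not in ("cancer", "benign", "normal"):
            raise ValueError(f"unknown diagnostic label {self.diagnostic_label!r}")
        if not isinstance(self.finding_tags, frozenset):
            object.__setattr__(self, "finding_tags", frozenset(self.finding_tags))
        bad = self.finding_tags - {"calcification", "mass"}
        if bad:
            raise ValueError(f"unknown finding tags {sorted(bad)}")
        if self.diagnostic_label == "normal" and self.finding_tags:
            raise ValueError("normal patches carry no finding tags")
        if self.diagnostic_label != "normal" and not self.finding_tags:
            raise ValueError("lesion patches need at least one finding tag")
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise ValueError("pixel grid must be square and 2-D")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class SynthConfig:
    """Generator knobs.

    Pixel-valued fields (cluster radii, dot sizes, blur widths, spicule
    lengths, texture scale) are stated at a 64-pixel patch side and scaled by
    ``image_size / 64`` at render time.  ``(mean, sd)`` pairs parameterise
    normal draws, ``(lo, hi)`` pairs uniform draws.
    """

    image_size: int = 64
    n_per_cell: int | Mapping[str, int] = 10

    # calcification cues
    calc_dot_count_benign: tuple[float, float] = (4.0, 1.0)
    calc_dot_count_malignant: tuple[float, float] = (13.0, 2.5)
    calc_cluster_radius_benign: float = 22.0
    calc_cluster_radius_malignant: float = 8.0
    calc_dot_size_range_benign: tuple[float, float] = (2.2, 3.2)
    calc_dot_size_range_malignant: tuple[float, float] = (0.8, 2.4)

    # mass cues (margin blur width in pixels; spiculation (count, length))
    mass_margin_sharpness_benign: float = 0.7
    mass_margin_sharpness_malignant: float = 2.8
    mass_spiculation_benign: tuple[int, float] = (0, 0.0)
    mass_spiculation_malignant: tuple[int, float] = (8, 11.0)
    mass_boundary_wobble_benign: float = 0.0
    mass_boundary_wobble_malignant: float = 0.22

    # background fibroglandular texture
    background_texture_scale: float = 6.0
    background_level: float = 0.35
    background_texture_amp: float = 0.35
    noise_sd: float = 0.02

    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        scalars = {
            "calc_cluster_radius_benign": self.calc_cluster_radius_benign,
            "calc_cluster_radius_malignant": self.calc_cluster_radius_malignant,
            "mass_margin_sharpness_benign": self.mass_margin_sharpness_benign,
            "mass_margin_sharpness_malignant": self.mass_margin_sharpness_malignant,
            "mass_boundary_wobble_benign": self.mass_boundary_wobble_benign,
            "mass_boundary_wobble_malignant": self.mass_boundary_wobble_malignant,
            "background_level": self.background_level,
            "background_texture_amp": self.background_texture_amp,
            "noise_sd": self.noise_sd,
        }
        for name, v in scalars.items():
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
        if not (math.isfinite(self.background_texture_scale) or math.isinf(self.background_texture_scale)):
            raise ValueError("background_texture_scale must not be NaN")
        if self.background_texture_scale < 0:
            raise ValueError("background_texture_scale must be non-negative")
        for name, pair in (
            ("calc_dot_count_benign", self.calc_dot_count_benign),
            ("calc_dot_count_malignant", self.calc_dot_count_malignant),
        ):
            m, s = pair
            if not (math.isfinite(m) and math.isfinite(s)) or m < 0 or s < 0:
                raise ValueError(f"{name} mean/sd must be finite and non-negative")
        for name, pair in (
            ("calc_dot_size_range_benign", self.calc_dot_size_range_benign),
            ("calc_dot_size_range_malignant", self.calc_dot_size_range_malignant),
        ):
            lo, hi = pair
            if not (0 < lo <= hi) or not (math.isfinite(lo) and math.isfinite(hi)):
                raise ValueError(f"{name} must satisfy 0 < lo <= hi")
        for name, pair in (
            ("mass_spiculation_benign", self.mass_spiculation_benign),
            ("mass_spiculation_malignant", self.mass_spiculation_malignant),
        ):
            cnt, length = pair
            if cnt < 0 or length < 0 or not math.isfinite(length):
                raise ValueError(f"{name} count/length must be non-negative")

    @property
    def scale(self) -> float:
        return self.image_size / _REF_SIDE

    def cell_count(self, label: str, finding: str | None) -> int:
        if isinstance(self.n_per_cell, Mapping):
            key = label if finding is None else f"{label}-{finding}"
            return int(self.n_per_cell[key])
        return int(self.n_per_cell)


# ---------------------------------------------------------------------------
# rendering


def _background(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Correlated fibroglandular-like texture on a uniform base level."""
    n = cfg.image_size
    img = np.full((n, n), cfg.background_level)
    if cfg.background_texture_amp > 0 and math.isfinite(cfg.background_texture_scale):
        white = rng.standard_normal((n, n))
        smooth = gaussian_filter(white, sigma=cfg.background_texture_scale * cfg.scale, mode="reflect")
        # smoothed white noise: amplitude shrinks with the correlation length,
        # vanishing in the infinite-scale limit (handled by the guard above)
        img = img + cfg.background_texture_amp * smooth
    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, size=(n, n))
    return img


def _finish(img: np.ndarray) -> np.ndarray:
    return np.clip(img, 0.0, 1.0)


def _coords(n: int) -> tuple[np.ndarray, np.ndarray]:
    r = np.arange(n, dtype=np.float64)
    return np.meshgrid(r, r, indexing="ij")


def _render_dot(
    img: np.ndarray,
    cy: float,
    cx: float,
    radius: float,
    ecc: float,
    angle: float,
    amp: float,
) -> None:
    """Add one bright dot with a compact Gaussian-edged profile in place."""
    n = img.shape[0]
    yy, xx = _coords(n)
    dy, dx = yy - cy, xx - cx
    ca, sa = math.cos(angle), math.sin(angle)
    u = ca * dy + sa * dx
    v = -sa * dy + ca * dx
    ry = max(radius * (1.0 + ecc), 0.4)
    rx = max(radius * (1.0 - ecc), 0.4)
    d2 = (u / ry) ** 2 + (v / rx) ** 2
    img += amp * np.exp(-0.5 * d2 * 3.0)  # factor 3: keeps dots compact


def gen_calcification_patch(
    malignant: bool, cfg: SynthConfig, rng: np.random.Generator
) -> PatchRecord:
    """Render a calcification-cluster patch.

    Malignant clusters draw more, smaller, more size-variable and elongated
    dots inside a tighter cluster; benign clusters fewer, larger, round and
    scattered dots.
    """
    s = cfg.scale
    n = cfg.image_size
    img = _background(cfg, rng)

    mean, sd = cfg.calc_dot_count_malignant if malignant else cfg.calc_dot_count_benign
    n_dots = max(0, int(round(rng.normal(mean, sd)))) if mean > 0 or sd > 0 else 0
    if mean > 0:
        n_dots = max(1, n_dots)
    cluster_r = (cfg.calc_cluster_radius_malignant if malignant else cfg.calc_cluster_radius_benign) * s
    lo, hi = cfg.calc_dot_size_range_malignant if malignant else cfg.calc_dot_size_range_benign
    lo, hi = lo * s, hi * s

    cy = n / 2 + rng.uniform(-0.08, 0.08) * n
    cx = n / 2 + rng.uniform(-0.08, 0.08) * n
    for _ in range(n_dots):
        rr = cluster_r * math.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * math.pi)
        dy, dx = cy + rr * math.sin(th), cx + rr * math.cos(th)
        dy = float(np.clip(dy, 2, n - 3))
        dx = float(np.clip(dx, 2, n - 3))
        radius = rng.uniform(lo, hi)
        ecc = rng.uniform(0.25, 0.6) if malignant else rng.uniform(0.0, 0.1)
        _render_dot(img, dy, dx, radius, ecc, rng.uniform(0, math.pi), amp=rng.uniform(0.45, 0.6))

    return PatchRecord(
        pixels=_finish(img),
        diagnostic_label="cancer" if malignant else "benign",
        finding_tags=frozenset({"calcification"}),
        patient_id="",
        image_id="",
        lesion_id=None,
    )


def gen_mass_patch(
    malignant: bool, cfg: SynthConfig, rng: np.random.Generator
) -> PatchRecord:
    """Render a mass patch.

    Benign: smooth oval, sharp margin, no spicules.  Malignant: irregular
    boundary (random low-order radial harmonics), radial spicules, blurred
    margin.
    """
    s = cfg.scale
    n = cfg.image_size
    img = _background(cfg, rng)

    r0 = 0.21 * n * rng.uniform(0.85, 1.15)
    cy = n / 2 + rng.uniform(-0.05, 0.05) * n
    cx = n / 2 + rng.uniform(-0.05, 0.05) * n
    ell = rng.uniform(0.05, 0.18)
    phi = rng.uniform(0, math.pi)
    wobble = cfg.mass_boundary_wobble_malignant if malignant else cfg.mass_boundary_wobble_benign

    yy, xx = _coords(n)
    dy, dx = yy - cy, xx - cx
    rr = np.hypot(dy, dx)
    th = np.arctan2(dy, dx)

    boundary = r0 * (1.0 + ell * np.cos(2 * (th - phi)))
    if wobble > 0:
        for k in (3, 4, 5, 6, 7):
            a = rng.normal(0.0, wobble / math.sqrt(5))
            p = rng.uniform(0, 2 * math.pi)
            boundary = boundary + r0 * a * np.cos(k * th + p)
    boundary = np.maximum(boundary, 1.0)

    mass = np.where(rr <= boundary, 0.5, 0.0)

    spic_count, spic_len = (
        cfg.mass_spiculation_malignant if malignant else cfg.mass_spiculation_benign
    )
    if spic_count > 0 and spic_len > 0:
        for _ in range(int(spic_count)):
            ang = rng.uniform(0, 2 * math.pi)
            length = spic_len * s * rng.uniform(0.7, 1.3)
            base = r0 * (1.0 + ell * math.cos(2 * (ang - phi)))
            for t in np.linspace(0.3, 1.0, max(4, int(length))):
                py = cy + (base + t * length) * math.sin(ang)
                px = cx + (base + t * length) * math.cos(ang)
                if 1 <= py < n - 1 and 1 <= px < n - 1:
                    _render_dot(mass, py, px, 0.9 * s, 0.0, 0.0, amp=0.28 * (1.0 - 0.5 * t))

    blur = (cfg.mass_margin_sharpness_malignant if malignant else cfg.mass_margin_sharpness_benign) * s
    if blur > 0:
        mass = gaussian_filter(mass, sigma=blur, mode="constant")
    img = img + mass

    return PatchRecord(
        pixels=_finish(img),
        diagnostic_label="cancer" if malignant else "benign",
        finding_tags=frozenset({"mass"}),
        patient_id="",
        image_id="",
        lesion_id=None,
    )


def gen_normal_patch(cfg: SynthConfig, rng: np.random.Generator) -> PatchRecord:
    """Render a lesion-free background-texture patch."""
    return PatchRecord(
        pixels=_finish(_background(cfg, rng)),
        diagnostic_label="normal",
        finding_tags=frozenset(),
        patient_id="",
        image_id="",
        lesion_id=None,
    )


# ---------------------------------------------------------------------------
# dataset assembly


def proportional_counts(total: int) -> dict[str, int]:
    """Split ``total`` across cancer/benign/normal in the source dataset's
    proportions using the largest-remainder rounding rule."""
    weights = np.array([_CLASS_MIX[k] for k in ("cancer", "benign", "normal")], dtype=float)
    quota = total * weights / weights.sum()
    base = np.floor(quota).astype(int)
    remainder = quota - base
    for i in np.argsort(-remainder)[: total - base.sum()]:
        base[i] += 1
    return dict(zip(("cancer", "benign", "normal"), (int(c) for c in base)))


def _patch_rng(seed: int, cell_index: int, patch_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, cell_index, patch_index]))


def gen_dataset(cfg: SynthConfig) -> list[PatchRecord]:
    """Generate the full labelled dataset for ``cfg``.

    Deterministic: a pure function of the configuration.  Synthetic patients
    hold two consecutive patches of one generation cell, so no patient ever
    spans diagnostic classes.
    """
    records: list[PatchRecord] = []
    for ci, (label, finding) in enumerate(CELLS):
        count = cfg.cell_count(label, finding)
        cell = label if finding is None else f"{label}-{finding[:4]}"
        for i in range(count):
            rng = _patch_rng(cfg.seed, ci, i)
            if finding == "calcification":
                rec = gen_calcification_patch(label == "cancer", cfg, rng)
            elif finding == "mass":
                rec = gen_mass_patch(label == "cancer", cfg, rng)
            else:
                rec = gen_normal_patch(cfg, rng)
            records.append(
                replace(
                    rec,
                    patient_id=f"P-{cell}-{i // 2:03d}",
                    image_id=f"S-{cell}-{i:04d}",
                    lesion_id=None if finding is None else f"L-{cell}-{i:04d}",
                )
            )
    return records


# ---------------------------------------------------------------------------
# on-disk dialect: 16-bit PNGs + CSV manifest

_MANIFEST_COLUMNS = ["image_id", "patient_id", "lesion_id", "diagnostic_label", "finding_tags", "path"]


def save_dataset(records: Iterable[PatchRecord], outdir: str | Path) -> Path:
    """Write patches as 16-bit PNGs plus a ``manifest.csv``; returns the
    manifest path.  Pixel values are quantised to 16 bits."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.csv"
    with open(manifest, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_MANIFEST_COLUMNS)
        for rec in records:
            fname = f"{rec.image_id}.png"
            arr = np.round(np.clip(rec.pixels, 0, 1) * 65535).astype(np.uint16)
            Image.fromarray(arr).save(outdir / fname)
            writer.writerow(
                [
                    rec.image_id,
                    rec.patient_id,
                    rec.lesion_id or "",
                    rec.diagnostic_label,
                    ";".join(sorted(rec.finding_tags)),
                    fname,
                ]
            )
    return manifest


def load_dataset(path: str | Path) -> list[PatchRecord]:
    """Read a dataset written by :func:`save_dataset` (manifest path or its
    directory)."""
    path = Path(path)
    manifest = path / "manifest.csv" if path.is_dir() else path
    root = manifest.parent
    records: list[PatchRecord] = []
    with open(manifest, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(_MANIFEST_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        for row in reader:
            arr = np.asarray(Image.open(root / row["path"]), dtype=np.float64) / 65535.0
            tags = frozenset(t for t in row["finding_tags"].split(";") if t)
            records.append(
                PatchRecord(
                    pixels=arr,
                    diagnostic_label=row["diagnostic_label"],
                    finding_tags=tags,
                    patient_id=row["patient_id"],
                    image_id=row["image_id"],
                    lesion_id=row["lesion_id"] or None,
                )
            )
    return records
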