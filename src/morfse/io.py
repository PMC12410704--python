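"""Reading mammograms and building labelled patches.

Handles annotation-table-driven patch construction for datasets in the
style of the refined Chinese mammography screening collections: MLO-view
grayscale images with per-lesion segmentation masks and a table giving
malignancy and radiological-finding tags.  The construction rules are:

* lesions are cropped to a fixed window (512 px at full scale) centred on
  the segmentation-mask centroid, shifted inward at image edges;
* each lesion is extracted individually (one patch per annotation);
* ``distortion`` tags are dropped, and annotations left tag-less by that
  are excluded entirely;
* ``FAD`` (focal asymmetric density) is relabelled as ``mass``;
* normal patches are sampled at random within the breast area found by Otsu
  binarisation, accepting windows whose foreground fraction is high enough.

Window coordinates are 0-based and half-open; the centroid is the unweighted
mean of mask pixel coordinates, rounded half-up.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .synth import PatchRecord, save_dataset, load_dataset  # shared on-disk dialect

__all__ = [
    "SourceImage",
    "LesionAnnotation",
    "EXCLUDED",
    "FormatError",
    "AnnotationError",
    "DimensionError",
    "SamplingError",
    "read_source_image",
    "normalize_finding_tags",
    "extract_lesion_patch",
    "split_lesions",
    "sample_normal_patch",
    "build_patches_from_table",
    "save_dataset",
    "load_dataset",
]

KNOWN_TAGS = {"calcification", "mass", "FAD", "distortion"}


class FormatError(ValueError):
    """Unreadable or unsupported image file."""


class AnnotationError(ValueError):
    """Malformed annotation: unknown tags or empty mask."""


class DimensionError(ValueError):
    """Crop larger than the source image."""


class SamplingError(RuntimeError):
    """No acceptable normal window found within the draw cap."""


class _Excluded:
    """Sentinel: annotation removed by the filtering rules."""

    def __repr__(self) -> str:  # pragma: no cover
        return "EXCLUDED"


EXCLUDED = _Excluded()


@dataclass(frozen=True)
class SourceImage:
    pixels: np.ndarray  # rescaled to [0, 1]
    patient_id: str
    image_id: str
    bit_depth: int


@dataclass(frozen=True)
class LesionAnnotation:
    mask: np.ndarray  # boolean, congruent with the image
    malignancy: str  # "cancer" | "benign"
    raw_tags: frozenset[str]
    lesion_id: str

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if not mask.any():
            raise AnnotationError(f"lesion {self.lesion_id}: empty mask")
        if not self.raw_tags:
            raise AnnotationError(f"lesion {self.lesion_id}: no finding tags")
        if self.malignancy not in ("cancer", "benign"):
            raise AnnotationError(f"lesion {self.lesion_id}: malignancy {self.malignancy!r}")
        object.__setattr__(self, "mask", mask)
        if not isinstance(self.raw_tags, frozenset):
            object.__setattr__(self, "raw_tags", frozenset(self.raw_tags))


# ---------------------------------------------------------------------------
# image loading


def read_source_image(path: str | Path, patient_id: str = "", image_id: str = "") -> SourceImage:
    """Load a monochrome DICOM or PNG mammogram, rescaled to [0, 1] by the
    stored bit depth.  IDs default to DICOM tags (PatientID / SOPInstanceUID)
    or, for PNGs, the file stem."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.suffix.lower() in (".dcm", ".dicom"):
        return _read_dicom(path, patient_id, image_id)
    if path.suffix.lower() == ".png":
        return _read_png(path, patient_id, image_id)
    raise FormatError(f"unsupported image format: {path.suffix!r}")


def _read_dicom(path: Path, patient_id: str, image_id: str) -> SourceImage:
    import pydicom

    try:
        ds = pydicom.dcmread(path)
        arr = ds.pixel_array
    except Exception as exc:
        raise FormatError(f"unreadable DICOM {path}: {exc}") from exc
    if arr.ndim != 2:
        raise FormatError(f"{path}: multi-frame or color DICOM is unsupported")
    bits = int(getattr(ds, "BitsStored", arr.dtype.itemsize * 8))
    pixels = arr.astype(np.float64) / (2**bits - 1)
    return SourceImage(
        pixels=np.clip(pixels, 0.0, 1.0),
        patient_id=patient_id or str(getattr(ds, "PatientID", "")),
        image_id=image_id or str(getattr(ds, "SOPInstanceUID", path.stem)),
        bit_depth=bits,
    )


def _read_png(path: Path, patient_id: str, image_id: str) -> SourceImage:
    from PIL import Image, UnidentifiedImageError

    try:
        with Image.open(path) as im:
            im.load()
            arr = np.asarray(im)
    except (UnidentifiedImageError, OSError, SyntaxError) as exc:
        raise FormatError(f"unreadable PNG {path}: {exc}") from exc
    if arr.ndim != 2:
        raise FormatError(f"{path}: color PNG is unsupported")
    bits = 16 if arr.dtype == np.uint16 else 8
    pixels = arr.astype(np.float64) / (2**bits - 1)
    return SourceImage(
        pixels=np.clip(pixels, 0.0, 1.0),
        patient_id=patient_id,
        image_id=image_id or path.stem,
        bit_depth=bits,
    )


# ---------------------------------------------------------------------------
# tag normalization


def normalize_finding_tags(raw_tags: Iterable[str]):
    """Apply the relabelling rules: FAD becomes mass, distortion is dropped,
    and a tag set emptied by that returns :data:`EXCLUDED`."""
    tags = set(raw_tags)
    if not tags:
        raise AnnotationError("raw tag set must be nonempty")
    unknown = tags - KNOWN_TAGS
    if unknown:
        raise AnnotationError(f"unknown finding tags: {sorted(unknown)}")
    tags.discard("distortion")
    if "FAD" in tags:
        tags.discard("FAD")
        tags.add("mass")
    if not tags:
        return EXCLUDED
    return frozenset(tags)


# ---------------------------------------------------------------------------
# patch construction


def _centroid(mask: np.ndarray) -> tuple[int, int]:
    rows, cols = np.nonzero(mask)
    # round half-up, not banker's rounding
    return int(np.floor(rows.mean() + 0.5)), int(np.floor(cols.mean() + 0.5))


def _window_origin(center: int, crop: int, size: int) -> int:
    origin = center - crop // 2
    return int(np.clip(origin, 0, size - crop))


def extract_lesion_patch(
    image: SourceImage, ann: LesionAnnotation, crop: int = 512
):
    """Crop-sized window centred on the mask centroid, shifted inward at
    edges.  Returns a :class:`PatchRecord`, or ``None`` when the annotation's
    tags normalise to :data:`EXCLUDED`."""
    h, w = image.pixels.shape
    if crop > h or crop > w:
        raise DimensionError(f"crop {crop} exceeds image {h}x{w}")
    if ann.mask.shape != image.pixels.shape:
        raise AnnotationError("mask not congruent with its image")
    tags = normalize_finding_tags(ann.raw_tags)
    if tags is EXCLUDED:
        return None
    cy, cx = _centroid(ann.mask)
    r0 = _window_origin(cy, crop, h)
    c0 = _window_origin(cx, crop, w)
    return PatchRecord(
        pixels=image.pixels[r0 : r0 + crop, c0 : c0 + crop].copy(),
        diagnostic_label=ann.malignancy,
        finding_tags=tags,
        patient_id=image.patient_id,
        image_id=f"{image.image_id}:{ann.lesion_id}",
        lesion_id=ann.lesion_id,
    )


def split_lesions(ann: LesionAnnotation) -> list[LesionAnnotation]:
    """Split a mask with several disjoint components into one annotation per
    lesion, so each is extracted individually."""
    from skimage.measure import label as cc_label

    labelled, n = cc_label(ann.mask, return_num=True)
    if n <= 1:
        return [ann]
    return [
        LesionAnnotation(
            mask=labelled == c,
            malignancy=ann.malignancy,
            raw_tags=ann.raw_tags,
            lesion_id=f"{ann.lesion_id}-{c}",
        )
        for c in range(1, n + 1)
    ]


def sample_normal_patch(
    image: SourceImage,
    crop: int,
    rng: np.random.Generator,
    min_foreground: float = 0.9,
    max_draws: int = 1000,
) -> PatchRecord:
    """Rejection-sample a normal-tissue window inside the breast area.

    The breast is separated from background by Otsu's threshold on the full
    image; a window is accepted when at least ``min_foreground`` of its
    pixels are breast."""
    from skimage.filters import threshold_otsu

    h, w = image.pixels.shape
    if crop > h or crop > w:
        raise DimensionError(f"crop {crop} exceeds image {h}x{w}")
    px = image.pixels
    if px.max() == px.min():
        fg = np.ones_like(px, dtype=bool)
    else:
        fg = px > threshold_otsu(px)
    if not fg.any():
        raise SamplingError("no breast foreground after binarization")
    need = min_foreground * crop * crop
    for _ in range(max_draws):
        r0 = int(rng.integers(0, h - crop + 1))
        c0 = int(rng.integers(0, w - crop + 1))
        if fg[r0 : r0 + crop, c0 : c0 + crop].sum() >= need:
            return PatchRecord(
                pixels=px[r0 : r0 + crop, c0 : c0 + crop].copy(),
                diagnostic_label="normal",
                finding_tags=frozenset(),
                patient_id=image.patient_id,
                image_id=f"{image.image_id}:normal-{r0}-{c0}",
                lesion_id=None,
            )
    raise SamplingError(
        f"no window with foreground fraction >= {min_foreground} in {max_draws} draws"
    )


# ---------------------------------------------------------------------------
# annotation-table driver

_TABLE_COLUMNS = ["image_path", "mask_path", "malignancy", "tags", "patient_id"]


def build_patches_from_table(
    table_path: str | Path,
    crop: int = 512,
    normals_per_image: int = 1,
    min_foreground: float = 0.9,
    seed: int = 0,
) -> list[PatchRecord]:
    """Apply the full construction pipeline to a CSV annotation table.

    Columns: ``image_path, mask_path, malignancy, tags, patient_id``; tags
    are semicolon-joined; a row with malignancy ``normal`` (empty mask path)
    yields ``normals_per_image`` sampled normal patches.  Paths are resolved
    relative to the table.
    """
    table_path = Path(table_path)
    root = table_path.parent
    records: list[PatchRecord] = []
    rng = np.random.default_rng(seed)
    with open(table_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(_TABLE_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise AnnotationError(f"annotation table missing columns: {sorted(missing)}")
        for i, row in enumerate(reader):
            image = read_source_image(root / row["image_path"], patient_id=row["patient_id"])
            if row["malignancy"] == "normal":
                for j in range(normals_per_image):
                    records.append(
                        sample_normal_patch(image, crop, rng, min_foreground=min_foreground)
                    )
                continue
            mask_img = read_source_image(root / row["mask_path"])
            ann = LesionAnnotation(
                mask=mask_img.pixels > 0,
                malignancy=row["malignancy"],
                raw_tags=frozenset(t for t in row["tags"].split(";") if t),
                lesion_id=f"lesion-{i:05d}",
            )
            for sub in split_lesions(ann):
                rec = extract_lesion_patch(image, sub, crop=crop)
                if rec is not None:
                    records.append(rec)
    return records
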