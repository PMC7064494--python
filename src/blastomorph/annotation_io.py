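"""Reading and writing micrographs, region annotations and cohort manifests.

Manual region annotations are accepted in two dialects:

* a polygon JSON file with three closed boundaries in pixel coordinates
  (``zp_outer``, ``zp_te``, ``te_inner``), which is rasterized here; or
* a single-channel label-mask PNG (0 background, 1 inner, 2 TE, 3 ZP),
  as written by the phantom generator.

Rasterization convention: pixels are indexed 0-based, the centre of
pixel ``(row, col)`` is the point ``(x=col, y=row)``, and a pixel belongs
to a region when its centre is inside or on the enclosing boundary
polygon (each boundary is owned by the region it encloses).
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .containers import Micrograph, RegionMasks

__all__ = [
    "Micrograph",
    "RegionAnnotation",
    "SampleRecord",
    "BHCG_POSITIVE_THRESHOLD",
    "load_micrograph",
    "write_micrograph",
    "load_mask",
    "write_mask",
    "rasterize_annotation",
    "label_outcome",
    "load_cohort",
    "write_manifest",
]

#: Serum b-hCG concentration (mUI/mL) at or above which the pregnancy
#: test is read as positive.
BHCG_POSITIVE_THRESHOLD = 20.0

BOUNDARY_NAMES = ("zp_outer", "zp_te", "te_inner")

MANIFEST_COLUMNS = [
    "sample_id",
    "image_path",
    "mask_path",
    "age_years",
    "microns_per_pixel",
    "objective",
    "bhcg_mUI_per_mL",
]


@dataclass(frozen=True)
class RegionAnnotation:
    """Three nested closed boundaries in pixel coordinates.

    Each boundary is an (N, 2) array of (x, y) vertices. ``zp_outer``
    is the outer edge of the zona pellucida, ``zp_te`` the ZP/TE
    interface and ``te_inner`` the TE/inner-area interface.
    """

    zp_outer: np.ndarray
    zp_te: np.ndarray
    te_inner: np.ndarray

    def __post_init__(self) -> None:
        for name in BOUNDARY_NAMES:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
                raise ValueError(
                    f"boundary '{name}' must be an (N>=3, 2) vertex array"
                )
            object.__setattr__(self, name, arr)

    @classmethod
    def from_json(cls, path: str | Path) -> "RegionAnnotation":
        data = json.loads(Path(path).read_text())
        missing = [k for k in BOUNDARY_NAMES if k not in data]
        if missing:
            raise ValueError(f"annotation file {path} missing boundaries {missing}")
        return cls(**{k: np.asarray(data[k], dtype=float) for k in BOUNDARY_NAMES})

    def to_json(self, path: str | Path) -> None:
        payload = {k: np.asarray(getattr(self, k)).tolist() for k in BOUNDARY_NAMES}
        Path(path).write_text(json.dumps(payload))


@dataclass(frozen=True)
class SampleRecord:
    """Per-sample metadata from the cohort manifest."""

    sample_id: str
    age_years: float
    microns_per_pixel: float
    objective: Optional[str] = None
    bhcg_mUI_per_mL: Optional[float] = None
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if self.bhcg_mUI_per_mL is None and self.label is None:
            raise ValueError(
                f"sample {self.sample_id}: need b-hCG value or binary label"
            )
        if not 10.0 < self.age_years < 60.0:
            raise ValueError(
                f"sample {self.sample_id}: age {self.age_years} outside (10, 60) years"
            )
        if not self.microns_per_pixel > 0:
            raise ValueError(f"sample {self.sample_id}: non-positive calibration")

    def resolved_label(self) -> int:
        if self.label is not None:
            return int(self.label)
        return label_outcome(self.bhcg_mUI_per_mL)


def load_micrograph(path: str | Path, microns_per_pixel: float,
                    sample_id: str = "") -> Micrograph:
    """Load an image file as a calibrated 8-bit grayscale micrograph.

    RGB(A) inputs are converted to grayscale by luminance; inputs with
    more than 8 bits per channel are rescaled so the maximum pixel maps
    to 255 (acquisition settings vary between microscopes, so only the
    relative intensity scale is meaningful).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    if not microns_per_pixel > 0:
        raise ValueError(f"microns_per_pixel must be positive, got {microns_per_pixel}")
    img = iio.imread(path)
    if img.size == 0:
        raise ValueError(f"zero-size image: {path}")
    eight_bit = img.dtype == np.uint8
    if img.ndim == 3:
        if img.shape[2] == 4:
            img = img[:, :, :3]
        # ITU-R 601 luminance; exact for achromatic pixels
        weights = np.array([0.299, 0.587, 0.114])
        img = np.round(img.astype(float) @ weights)
    if not eight_bit:
        # deeper bit depths: only the relative scale is meaningful
        img = img.astype(float)
        mx = img.max()
        img = np.zeros_like(img) if mx <= 0 else np.round(img * (255.0 / mx))
    return Micrograph(
        pixels=img.astype(np.uint8),
        microns_per_pixel=float(microns_per_pixel),
        sample_id=sample_id,
    )


def write_micrograph(m: Micrograph, path: str | Path) -> None:
    iio.imwrite(Path(path), m.pixels)


def load_mask(path: str | Path) -> RegionMasks:
    """Load a label-mask PNG (0 bg, 1 inner, 2 TE, 3 ZP)."""
    labels = iio.imread(Path(path))
    if labels.ndim == 3:
        labels = labels[:, :, 0]
    return RegionMasks.from_label_image(labels)


def write_mask(masks: RegionMasks, path: str | Path) -> None:
    iio.imwrite(Path(path), masks.to_label_image())


def _as_polygon(vertices: np.ndarray, name: str) -> Polygon:
    poly = Polygon(vertices)
    if not poly.is_valid or not poly.is_simple or poly.area == 0:
        raise ValueError(
            f"boundary '{name}' is not a simple (non-self-intersecting) polygon"
        )
    return poly


def rasterize_annotation(ann: RegionAnnotation,
                         shape: tuple[int, int]) -> RegionMasks:
    """Rasterize three nested boundary polygons into region masks.

    The ZP mask is the set of pixel centres between the ZP outer
    boundary and the ZP/TE interface, the TE mask between ZP/TE and
    TE/inner, and the inner mask everything inside TE/inner. A pixel
    centre lying exactly on a boundary is assigned to the region that
    boundary encloses.
    """
    h, w = shape
    polys = {name: _as_polygon(getattr(ann, name), name)
             for name in BOUNDARY_NAMES}
    if not polys["zp_outer"].contains_properly(polys["zp_te"]):
        raise ValueError(
            "boundary 'zp_te' is not strictly inside 'zp_outer'")
    if not polys["zp_te"].contains_properly(polys["te_inner"]):
        raise ValueError(
            "boundary 'te_inner' is not strictly inside 'zp_te'")
    minx, miny, maxx, maxy = polys["zp_outer"].bounds
    if minx < -0.5 or miny < -0.5 or maxx > w - 0.5 or maxy > h - 0.5:
        raise ValueError(
            f"boundary 'zp_outer' extends outside the {h}x{w} frame")

    ys, xs = np.mgrid[0:h, 0:w]
    xs = xs.ravel().astype(float)
    ys = ys.ravel().astype(float)
    covered = {
        name: shapely.intersects_xy(poly, xs, ys).reshape(h, w)
        for name, poly in polys.items()
    }
    inner = covered["te_inner"]
    te = covered["zp_te"] & ~inner
    zp = covered["zp_outer"] & ~covered["zp_te"]
    masks = RegionMasks(zp=zp, te=te, inner=inner)
    masks.require_nonempty()
    return masks


def label_outcome(bhcg: float) -> int:
    """Binary pregnancy-test outcome from a b-hCG concentration.

    Returns 1 iff ``bhcg`` >= 20 mUI/mL.
    """
    if bhcg is None or not np.isfinite(bhcg):
        raise ValueError(f"b-hCG concentration must be finite, got {bhcg}")
    if bhcg < 0:
        raise ValueError(f"b-hCG concentration must be >= 0, got {bhcg}")
    return int(bhcg >= BHCG_POSITIVE_THRESHOLD)


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest missing columns {missing}")
    manifest.to_csv(path, index=False)


def load_cohort(manifest_path: str | Path
                ) -> list[tuple[Micrograph, RegionMasks, SampleRecord]]:
    """Load a cohort from a manifest CSV.

    Paths in the manifest are resolved relative to the manifest's
    directory. Labels are resolved from the b-hCG column when no
    explicit ``label`` column is present. Validation failures are
    reported with the offending manifest row number (0-based, data rows).
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    required = {"sample_id", "image_path", "mask_path",
                "age_years", "microns_per_pixel"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise ValueError(f"manifest missing required columns {missing}")
    if "bhcg_mUI_per_mL" not in df.columns and "label" not in df.columns:
        raise ValueError("manifest needs a 'bhcg_mUI_per_mL' or 'label' column")
    dupes = df["sample_id"][df["sample_id"].duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate sample ids in manifest: {dupes}")

    base = manifest_path.parent
    out = []
    for i, row in df.iterrows():
        try:
            image_path = base / str(row["image_path"])
            mask_path = base / str(row["mask_path"])
            m = load_micrograph(image_path, float(row["microns_per_pixel"]),
                                sample_id=str(row["sample_id"]))
            if mask_path.suffix.lower() == ".json":
                masks = rasterize_annotation(
                    RegionAnnotation.from_json(mask_path), m.shape)
            else:
                masks = load_mask(mask_path)
            if masks.shape != m.shape:
                raise ValueError(
                    f"mask shape {masks.shape} != image shape {m.shape}")
            bhcg = row.get("bhcg_mUI_per_mL")
            bhcg = None if bhcg is None or pd.isna(bhcg) else float(bhcg)
            label = row.get("label")
            label = None if label is None or pd.isna(label) else int(label)
            rec = SampleRecord(
                sample_id=str(row["sample_id"]),
                age_years=float(row["age_years"]),
                microns_per_pixel=float(row["microns_per_pixel"]),
                objective=str(row["objective"]) if "objective" in df.columns else None,
                bhcg_mUI_per_mL=bhcg,
                label=label,
            )
        except (ValueError, FileNotFoundError, KeyError) as exc:
            raise type(exc)(f"manifest row {i}: {exc}") from exc
        out.append((m, masks, rec))
    return out
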