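"""Core in-memory containers shared across the pipeline.

A :class:`Micrograph` is a calibrated 8-bit grayscale image; a
:class:`RegionMasks` triple labels its pixels as zona pellucida (ZP),
trophectoderm (TE) or inner area (blastocoel + inner cell mass).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

REGION_NAMES = ("zp", "te", "inner")

#: Label-image encoding used on disk: 0 background, then inner-out.
LABEL_CODES = {"inner": 1, "te": 2, "zp": 3}

MIN_IMAGE_SIZE = 32


@dataclass(frozen=True)
class Micrograph:
    """8-bit grayscale micrograph with spatial calibration.

    Parameters
    ----------
    pixels
        2-D uint8 array, row-major, origin at the top-left corner.
    microns_per_pixel
        Physical size of one pixel side in micrometres; must be > 0.
    sample_id
        Optional identifier carried through the pipeline.
    """

    pixels: np.ndarray
    microns_per_pixel: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"micrograph must be 2-D, got shape {px.shape}")
        if px.shape[0] < MIN_IMAGE_SIZE or px.shape[1] < MIN_IMAGE_SIZE:
            raise ValueError(
                f"micrograph must be at least {MIN_IMAGE_SIZE}x{MIN_IMAGE_SIZE}, "
                f"got {px.shape}"
            )
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("pixel intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        if not self.microns_per_pixel > 0:
            raise ValueError(
                f"microns_per_pixel must be positive, got {self.microns_per_pixel}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class RegionMasks:
    """Disjoint boolean masks for the three annotated regions.

    The three regions are concentric in a valid annotation: the inner
    area sits inside the TE annulus, which sits inside the ZP annulus.
    Disjointness is enforced here; nesting is a property of the source
    annotation and is validated where annotations are rasterized.
    """

    zp: np.ndarray
    te: np.ndarray
    inner: np.ndarray

    def __post_init__(self) -> None:
        arrays = {}
        shape = None
        for name in REGION_NAMES:
            m = np.asarray(getattr(self, name), dtype=bool)
            if m.ndim != 2:
                raise ValueError(f"mask '{name}' must be 2-D")
            if shape is None:
                shape = m.shape
            elif m.shape != shape:
                raise ValueError("all region masks must share one shape")
            arrays[name] = m
        if (arrays["zp"] & arrays["te"]).any() or \
           (arrays["zp"] & arrays["inner"]).any() or \
           (arrays["te"] & arrays["inner"]).any():
            raise ValueError("region masks must be pairwise disjoint")
        for name, m in arrays.items():
            object.__setattr__(self, name, m)

    @property
    def shape(self) -> tuple[int, int]:
        return self.zp.shape

    def items(self) -> Iterator[tuple[str, np.ndarray]]:
        for name in REGION_NAMES:
            yield name, getattr(self, name)

    def union(self) -> np.ndarray:
        return self.zp | self.te | self.inner

    def require_nonempty(self) -> None:
        for name, m in self.items():
            if not m.any():
                raise ValueError(f"region '{name}' is empty")

    def to_label_image(self) -> np.ndarray:
        """Encode as a single-channel label image (0 = background)."""
        out = np.zeros(self.shape, dtype=np.uint8)
        for name, code in LABEL_CODES.items():
            out[getattr(self, name)] = code
        return out

    @classmethod
    def from_label_image(cls, labels: np.ndarray) -> "RegionMasks":
        labels = np.asarray(labels)
        known = set(LABEL_CODES.values()) | {0}
        present = set(np.unique(labels).tolist())
        if not present <= known:
            raise ValueError(
                f"label image contains unknown codes {sorted(present - known)}"
            )
        return cls(
            zp=labels == LABEL_CODES["zp"],
            te=labels == LABEL_CODES["te"],
            inner=labels == LABEL_CODES["inner"],
        )
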