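"""Facial region label registry and mask handling.

Masks are uint8 label rasters over a fixed registry. Skin is the union of
the five local skin areas plus residual skin; the three feature areas
(lips, brows, eyes) are excluded from skin. The "surrounding skin" of a
feature is a dilation ring around the feature intersected with skin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage


class RegionError(ValueError):
    """A required region is missing or empty."""


# Fixed uint8 label registry (version 1).
LABELS: dict[str, int] = {
    "background": 0,
    "forehead": 1,
    "cheek": 2,
    "nose": 3,
    "chin": 4,
    "periorbital": 5,
    "lips": 6,
    "brows": 7,
    "eyes": 8,
    "other_skin": 9,
}
LABEL_NAMES = {v: k for k, v in LABELS.items()}

LOCAL_SKIN_REGIONS = ("forehead", "cheek", "nose", "chin", "periorbital")
FEATURE_REGIONS = ("lips", "brows", "eyes")
SKIN_REGIONS = LOCAL_SKIN_REGIONS + ("other_skin",)


def disk_structuring_element(radius: int) -> np.ndarray:
    """Boolean disk of the given pixel radius for morphological dilation."""
    yy, xx = np.ogrid[-radius : radius + 1, -radius : radius + 1]
    return yy * yy + xx * xx <= radius * radius


@dataclass
class RegionMaskSet:
    """A label raster plus derived masks for one face.

    Parameters
    ----------
    labels : ndarray of uint8, shape (H, W)
        Per-pixel region labels from the fixed registry.
    surround_radius : int
        Dilation radius (pixels) defining each feature's surrounding-skin
        ring; default 8 on the 256-px synthetic template.
    """

    labels: np.ndarray
    surround_radius: int = 8

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label raster must be 2-D")
        unknown = set(np.unique(self.labels)) - set(LABELS.values())
        if unknown:
            raise RegionError(f"unregistered labels in mask: {sorted(unknown)}")

    def mask(self, region: str) -> np.ndarray:
        """Boolean mask of one registered region."""
        try:
            lab = LABELS[region]
        except KeyError:
            raise RegionError(f"unknown region name {region!r}") from None
        return self.labels == lab

    def overall_skin(self) -> np.ndarray:
        """Union of all skin labels (local areas + residual skin)."""
        return np.isin(self.labels, [LABELS[r] for r in SKIN_REGIONS])

    def surround(self, feature: str) -> np.ndarray:
        """Skin ring around a feature: dilation of the feature mask minus the
        feature itself, intersected with overall skin."""
        if feature not in FEATURE_REGIONS:
            raise RegionError(f"{feature!r} is not a feature region")
        fmask = self.mask(feature)
        dil = ndimage.binary_dilation(
            fmask, structure=disk_structuring_element(self.surround_radius)
        )
        return dil & ~fmask & self.overall_skin()

    def missing_regions(self) -> list[str]:
        """Registered regions (other than background) with zero pixels."""
        present = set(np.unique(self.labels))
        return [
            name
            for name, lab in LABELS.items()
            if name != "background" and lab not in present
        ]


def rasterize_polygons(spec: dict, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a JSON polygon region file into a label raster.

    ``spec`` maps region names to lists of polygons, each polygon a list of
    (x, y) vertices; later regions overwrite earlier ones. Uses matplotlib's
    point-in-polygon path test.
    """
    from matplotlib.path import Path

    labels = np.zeros(shape, dtype=np.uint8)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    points = np.column_stack([xx.ravel() + 0.5, yy.ravel() + 0.5])
    for region, polys in spec.items():
        if region not in LABELS:
            raise RegionError(f"unknown region name {region!r} in polygon file")
        for poly in polys:
            inside = Path(np.asarray(poly, dtype=float)).contains_points(points)
            labels.ravel()[inside] = LABELS[region]
    return labels


def load_mask(path) -> np.ndarray:
    """Load a label raster from a PNG label image or a JSON polygon file."""
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            payload = json.load(fh)
        return rasterize_polygons(payload["regions"], tuple(payload["shape"]))
    from PIL import Image

    return np.asarray(Image.open(path)).astype(np.uint8)
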