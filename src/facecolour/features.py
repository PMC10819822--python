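"""The 65 facial colour characteristics.

Five categories, computed in CIELAB from an sRGB image and a region label
mask:

* average skin colour — mean over the whole facial skin area (5 values:
  L*, a*, b*, C*, h_ab);
* local skin colour — means over forehead, cheek, nose, chin and
  periorbital skin (5 × 5 = 25);
* feature colour — means over lips, brows and eyes (3 × 5 = 15);
* skin colour variation — mean colour difference from the mean (MCDM) of
  forehead, cheek, nose, chin and the overall skin (5);
* facial colour contrast — adapted Michelson contrast between eyes, brows
  and mouth and their surrounding skin, per coordinate (3 × 5 = 15).

Region C*/h_ab are derived from the region-mean (a*, b*) pair, not by
averaging per-pixel polar coordinates: the circular mean of hue is
ill-defined near the achromatic axis. ``mean_of_pixelwise_polar=True``
switches to per-pixel averaging for sensitivity checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .colourspace import chroma_hue, srgb_to_lab
from .regions import (
    FEATURE_REGIONS,
    LOCAL_SKIN_REGIONS,
    RegionError,
    RegionMaskSet,
    load_mask,
)

COORDS = ("L*", "a*", "b*", "C*", "h_ab")

#: Canonical registry order of the 65 feature names.
FEATURE_NAMES: tuple[str, ...] = (
    tuple(COORDS)
    + tuple(
        f"{r.capitalize()}_{c}" for r in LOCAL_SKIN_REGIONS for c in COORDS
    )
    + tuple(f"{f}_{c}" for f in ("Lip", "Brows", "Eyes") for c in COORDS)
    + ("MCDM_Forehead", "MCDM_Cheek", "MCDM_Nose", "MCDM_Chin", "MCDM")
    + tuple(f"{f}_C_{c}" for f in ("Eyes", "Brows", "Mouth") for c in COORDS)
)

CATEGORY_SIZES = {
    "average_skin": 5,
    "local_skin": 25,
    "feature_colour": 15,
    "skin_variation": 5,
    "colour_contrast": 15,
}

assert len(FEATURE_NAMES) == 65

# contrast name -> feature mask name (mouth contrast uses the lips label)
_CONTRAST_MASKS = {"Eyes": "eyes", "Brows": "brows", "Mouth": "lips"}


@dataclass
class ColourFeatureVector:
    """The 65 named colour characteristics of one face."""

    values: pd.Series
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if list(self.values.index) != list(FEATURE_NAMES):
            raise ValueError("feature vector must follow the canonical registry")

    def __len__(self) -> int:
        return len(self.values)


def region_mean_colour(
    lab: np.ndarray, mask: np.ndarray, *, region: str = "region",
    mean_of_pixelwise_polar: bool = False,
):
    """Mean (L*, a*, b*, C*, h_ab) of the pixels under a boolean mask.

    L*, a*, b* are arithmetic pixel means; C* and h_ab derive from the mean
    (a*, b*) unless ``mean_of_pixelwise_polar`` is set.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise RegionError(f"region {region!r} has no pixels")
    pix = np.asarray(lab, dtype=np.float64)[mask]
    L, a, b = pix.mean(axis=0)
    if mean_of_pixelwise_polar:
        c_pix, h_pix, _ = chroma_hue(pix[:, 1], pix[:, 2])
        return L, a, b, float(np.mean(c_pix)), float(np.mean(h_pix))
    chroma, hue, undef = chroma_hue(a, b)
    if undef:
        warnings.warn(
            f"region {region!r} mean colour is achromatic; hue set to 0",
            stacklevel=2,
        )
    return float(L), float(a), float(b), float(chroma), float(hue)


def mcdm(lab: np.ndarray, mask: np.ndarray, *, region: str = "region") -> float:
    """Mean colour difference from the mean (CIE76) within a region.

    MCDM = (1/N) Σ_p sqrt((L_p − L̄)² + (a_p − ā)² + (b_p − b̄)²); zero iff
    the region is colour-uniform.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise RegionError(f"region {region!r} has no pixels")
    pix = np.asarray(lab, dtype=np.float64)[mask]
    dev = pix - pix.mean(axis=0)
    return float(np.mean(np.sqrt(np.sum(dev * dev, axis=1))))


def feature_contrast(x_skin: float, x_feature: float) -> float:
    """Adapted Michelson contrast (skin − feature) / (skin + feature).

    Positive when the surrounding skin has the larger coordinate value
    (e.g. skin lighter than brows); negative e.g. for a* of lips redder
    than skin. Undefined (NaN) when the denominator is non-positive, which
    can occur for a*.
    """
    denom = x_skin + x_feature
    if denom <= 0:
        return float("nan")
    return (x_skin - x_feature) / denom


def extract_features(
    lab: np.ndarray,
    masks: RegionMaskSet,
    *,
    mean_of_pixelwise_polar: bool = False,
) -> ColourFeatureVector:
    """Compute all 65 colour characteristics of one face.

    Parameters
    ----------
    lab : ndarray (H, W, 3)
        CIELAB raster (see :func:`facecolour.colourspace.srgb_to_lab`).
    masks : RegionMaskSet
        Region labels of the same height/width.

    Raises
    ------
    RegionError
        If any registered region has no pixels, listing the missing labels.
    """
    lab = np.asarray(lab, dtype=np.float64)
    if lab.shape[:2] != masks.labels.shape:
        raise ValueError("image and mask shapes differ")
    missing = masks.missing_regions()
    if missing:
        raise RegionError(f"missing regions in mask: {missing}")

    notes: list[str] = []
    vals: dict[str, float] = {}
    polar = dict(mean_of_pixelwise_polar=mean_of_pixelwise_polar)

    skin = masks.overall_skin()
    for name, v in zip(COORDS, region_mean_colour(lab, skin, region="skin", **polar)):
        vals[name] = v

    for r in LOCAL_SKIN_REGIONS:
        m = region_mean_colour(lab, masks.mask(r), region=r, **polar)
        for name, v in zip(COORDS, m):
            vals[f"{r.capitalize()}_{name}"] = v

    for pretty, r in (("Lip", "lips"), ("Brows", "brows"), ("Eyes", "eyes")):
        m = region_mean_colour(lab, masks.mask(r), region=r, **polar)
        for name, v in zip(COORDS, m):
            vals[f"{pretty}_{name}"] = v

    for r in ("forehead", "cheek", "nose", "chin"):
        vals[f"MCDM_{r.capitalize()}"] = mcdm(lab, masks.mask(r), region=r)
    vals["MCDM"] = mcdm(lab, skin, region="skin")

    for pretty, r in _CONTRAST_MASKS.items():
        ring = masks.surround(r)
        if not ring.any():
            raise RegionError(f"surround of {r!r} has no skin pixels")
        m_feat = region_mean_colour(lab, masks.mask(r), region=r, **polar)
        m_ring = region_mean_colour(lab, ring, region=f"{r}-surround", **polar)
        for i, name in enumerate(COORDS):
            c = feature_contrast(m_ring[i], m_feat[i])
            if np.isnan(c):
                notes.append(
                    f"{pretty}_C_{name}: non-positive denominator, contrast undefined"
                )
            vals[f"{pretty}_C_{name}"] = c

    series = pd.Series([vals[n] for n in FEATURE_NAMES], index=list(FEATURE_NAMES))
    return ColourFeatureVector(series, notes)


def extract_table(
    images: "list[np.ndarray] | dict[str, np.ndarray]",
    masks,
    face_ids=None,
    **kwargs,
) -> pd.DataFrame:
    """Extract features for a batch of faces into a (faces × 65) table."""
    if isinstance(images, dict):
        face_ids = list(images)
        images = [images[k] for k in face_ids]
        masks = [masks[k] for k in face_ids]
    if face_ids is None:
        face_ids = [f"face{i:03d}" for i in range(len(images))]
    rows = {}
    for fid, img, msk in zip(face_ids, images, masks):
        if not isinstance(msk, RegionMaskSet):
            msk = RegionMaskSet(msk)
        lab = srgb_to_lab(img)
        rows[fid] = extract_features(lab, msk, **kwargs).values
    out = pd.DataFrame(rows).T
    out.index.name = "face_id"
    return out


def extract_directory(image_dir, mask_dir, **kwargs) -> pd.DataFrame:
    """Extract features for every image in a directory.

    Masks are matched by stem: ``<stem>.png`` or ``<stem>.json`` in
    ``mask_dir``.
    """
    from PIL import Image

    image_dir, mask_dir = Path(image_dir), Path(mask_dir)
    paths = sorted(
        p for p in image_dir.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
    )
    if not paths:
        raise FileNotFoundError(f"no PNG/TIFF images in {image_dir}")
    images, mask_list, ids = [], [], []
    for p in paths:
        arr = np.asarray(Image.open(p).convert("RGB"))
        for ext in (".png", ".json"):
            mp = mask_dir / (p.stem + ext)
            if mp.exists():
                break
        else:
            raise FileNotFoundError(f"no mask found for {p.stem}")
        images.append(arr)
        mask_list.append(RegionMaskSet(load_mask(mp)))
        ids.append(p.stem)
    return extract_table(images, mask_list, face_ids=ids, **kwargs)
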