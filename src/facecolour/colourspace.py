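"""sRGB ↔ CIELAB conversion and cylindrical coordinates.

The pipeline is the standard one: IEC 61966-2-1 sRGB decoding, the 4-digit
linear-RGB → XYZ matrix (D65, 2° observer), then CIELAB. The reference white
is taken as the image of neutral sRGB under that matrix (the matrix row
sums), so neutral input maps to exactly (L*, 0, 0); with the CIE's
independently-rounded D65 white the residual on neutrals is ~2.6e-3 in
a*/b*, which matters when asserting that grey is grey.
"""

from __future__ import annotations

import numpy as np

__all__ = ["srgb_to_lab", "lab_to_srgb", "chroma_hue", "delta_e"]

# IEC 61966-2-1 linear sRGB -> XYZ (D65, 2 deg observer)
_M_RGB2XYZ = np.array(
    [
        [0.4124, 0.3576, 0.1805],
        [0.2126, 0.7152, 0.0722],
        [0.0193, 0.1192, 0.9505],
    ]
)
_M_XYZ2RGB = np.linalg.inv(_M_RGB2XYZ)
# White point = matrix @ (1, 1, 1): keeps neutrals exactly on the L* axis.
_WHITE = _M_RGB2XYZ.sum(axis=1)

_EPS = (6.0 / 29.0) ** 3
_KAPPA = (29.0 / 3.0) ** 3  # 841/108 * 27... = 903.296...


def _srgb_decode(v: np.ndarray) -> np.ndarray:
    """Electro-optical transfer: 8-bit-normalised sRGB -> linear RGB."""
    return np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)


def _srgb_encode(v: np.ndarray) -> np.ndarray:
    v = np.clip(v, 0.0, 1.0)
    return np.where(v <= 0.0031308, v * 12.92, 1.055 * v ** (1 / 2.4) - 0.055)


def _f(t: np.ndarray) -> np.ndarray:
    return np.where(t > _EPS, np.cbrt(t), (_KAPPA * t + 16.0) / 116.0)


def _f_inv(ft: np.ndarray) -> np.ndarray:
    t = ft**3
    return np.where(t > _EPS, t, (116.0 * ft - 16.0) / _KAPPA)


def srgb_to_lab(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit sRGB raster to CIELAB.

    Parameters
    ----------
    image : ndarray, shape (..., 3)
        8-bit sRGB (uint8, or float already scaled to [0, 1]).

    Returns
    -------
    ndarray, shape (..., 3), float64
        Per-pixel (L*, a*, b*); L* in [0, 100].
    """
    image = np.asarray(image)
    if image.ndim < 1 or image.shape[-1] != 3:
        raise ValueError(
            f"expected a (..., 3) sRGB array, got shape {image.shape}"
        )
    if image.dtype == np.uint8:
        v = image.astype(np.float64) / 255.0
    else:
        v = image.astype(np.float64)
        if v.max(initial=0.0) > 1.0 + 1e-9 or v.min(initial=0.0) < -1e-9:
            raise ValueError("float sRGB input must lie in [0, 1]")
    xyz = _srgb_decode(v) @ _M_RGB2XYZ.T
    fxyz = _f(xyz / _WHITE)
    lab = np.empty_like(fxyz)
    lab[..., 0] = 116.0 * fxyz[..., 1] - 16.0
    lab[..., 1] = 500.0 * (fxyz[..., 0] - fxyz[..., 1])
    lab[..., 2] = 200.0 * (fxyz[..., 1] - fxyz[..., 2])
    return lab


def lab_to_srgb(lab: np.ndarray, *, return_gamut_mask: bool = False):
    """Convert CIELAB to 8-bit sRGB, clipping out-of-gamut values.

    With ``return_gamut_mask=True`` also returns a boolean per-pixel mask of
    the pixels whose linear RGB fell outside [0, 1] before clipping.
    """
    lab = np.asarray(lab, dtype=np.float64)
    fy = (lab[..., 0] + 16.0) / 116.0
    fx = fy + lab[..., 1] / 500.0
    fz = fy - lab[..., 2] / 200.0
    xyz = np.stack([_f_inv(fx), _f_inv(fy), _f_inv(fz)], axis=-1) * _WHITE
    rgb_lin = xyz @ _M_XYZ2RGB.T
    out_of_gamut = np.any((rgb_lin < -1e-9) | (rgb_lin > 1.0 + 1e-9), axis=-1)
    srgb = np.round(_srgb_encode(rgb_lin) * 255.0).astype(np.uint8)
    if return_gamut_mask:
        return srgb, out_of_gamut
    return srgb


def chroma_hue(a, b):
    """Chroma C* = sqrt(a*^2 + b*^2) and hue angle h_ab in degrees [0, 360).

    The achromatic point a* = b* = 0 has no defined hue; by convention the
    pair (C*, h_ab) = (0, 0) is returned there and ``undefined`` flags it.

    Returns
    -------
    (C*, h_ab, undefined) — arrays broadcast over the inputs.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    chroma = np.hypot(a, b)
    undefined = chroma == 0.0
    hue = np.degrees(np.arctan2(b, a))
    hue = np.where(hue < 0.0, hue + 360.0, hue)
    hue = np.where(hue >= 360.0, 0.0, hue)  # -0 degrees wraps to exactly 360
    hue = np.where(undefined, 0.0, hue)
    return chroma, hue, undefined


def delta_e(lab1: np.ndarray, lab2: np.ndarray) -> np.ndarray:
    """CIE76 colour difference ΔE*ab (Euclidean distance in CIELAB)."""
    d = np.asarray(lab1, dtype=np.float64) - np.asarray(lab2, dtype=np.float64)
    return np.sqrt(np.sum(d * d, axis=-1))
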