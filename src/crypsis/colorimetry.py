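"""Specimen colorimetry: balance correction, patch means, total reflectance.

Colour lives on the 8-bit reflectance scale (0-255).  Total reflectance L
uses the ITU-R BT.601 luminance weights, L = 0.299 R + 0.587 G + 0.114 B.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

BT601_WEIGHTS = (0.299, 0.587, 0.114)


def total_reflectance(red: float, green: float, blue: float) -> float:
    """BT.601 total reflectance L = 0.299 R + 0.587 G + 0.114 B."""
    r, g, b = BT601_WEIGHTS
    return r * red + g * green + b * blue


@dataclass
class ColourVector:
    """RGB reflectance on the 0-255 scale, with BT.601 total reflectance."""

    red: float
    green: float
    blue: float

    def __post_init__(self) -> None:
        for name in ("red", "green", "blue"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"non-finite {name} channel")

    @property
    def total_reflectance(self) -> float:
        return total_reflectance(self.red, self.green, self.blue)

    # alias used throughout the analysis tables
    @property
    def L(self) -> float:
        return self.total_reflectance

    def as_array(self) -> np.ndarray:
        return np.array([self.red, self.green, self.blue])


@dataclass
class BalanceReference:
    """Observed white and black ColorChecker swatches used for correction."""

    white_observed: ColourVector
    black_observed: ColourVector

    def __post_init__(self) -> None:
        w, b = self.white_observed.as_array(), self.black_observed.as_array()
        if np.any(w <= b):
            raise ValueError(
                "white reference must exceed black reference in every channel"
            )


def balance_correct(
    pixel: ColourVector, ref: BalanceReference, clip: bool = True
) -> ColourVector:
    """Black/white balance: per-channel linear map black→0, white→255.

    Values outside [0, 255] after the map (specular or deep-shadow pixels)
    are clipped by default.
    """
    w, b = ref.white_observed.as_array(), ref.black_observed.as_array()
    out = (pixel.as_array() - b) / (w - b) * 255.0
    if clip:
        out = np.clip(out, 0.0, 255.0)
    return ColourVector(*out)


def extract_patch_mean(
    image: np.ndarray, region: tuple[int, int, int]
) -> ColourVector:
    """Mean colour over a square patch of an RGB image.

    ``region`` is (row0, col0, side) in 0-based pixel coordinates, half-open.
    A side outside the conventional 40-150 px sampling window triggers a
    warning, not an error.
    """
    import warnings

    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] < 3:
        raise ValueError("image must be an H x W x 3 RGB array")
    row0, col0, side = region
    if side <= 0:
        raise ValueError("empty region")
    if row0 < 0 or col0 < 0 or row0 + side > image.shape[0] or col0 + side > image.shape[1]:
        raise ValueError("region extends outside the image")
    if not 40 <= side <= 150:
        warnings.warn(f"patch side {side} px outside the usual 40-150 px range")
    patch = image[row0 : row0 + side, col0 : col0 + side, :3]
    r, g, b = patch.reshape(-1, 3).mean(axis=0)
    return ColourVector(r, g, b)


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image as float RGB on the 0-255 scale.

    16-bit images are rescaled to 0-255; grayscale promoted to 3 channels.
    """
    from PIL import Image

    with Image.open(path) as im:
        arr = np.asarray(im)
    arr = arr.astype(float)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.max() > 255:
        arr = arr / 65535.0 * 255.0
    return arr


def extract_specimen_colours(manifest: "pd.DataFrame") -> "pd.DataFrame":
    """Batch colour extraction from specimen photographs.

    ``manifest`` needs per specimen: id, path, patch_row0, patch_col0,
    patch_side, and the observed reference swatches white_observed /
    black_observed (scalar per image, as produced by the synthetic patch
    renderer, or per-channel columns *_red/_green/_blue).  Returns a table
    of id, red, green, blue, L after balance correction.
    """
    import pandas as pd

    rows = []
    for _, rec in manifest.iterrows():
        img = read_image(rec["path"])
        raw = extract_patch_mean(
            img, (int(rec["patch_row0"]), int(rec["patch_col0"]), int(rec["patch_side"]))
        )
        if "white_observed_red" in manifest.columns:
            white = ColourVector(
                rec["white_observed_red"],
                rec["white_observed_green"],
                rec["white_observed_blue"],
            )
            black = ColourVector(
                rec["black_observed_red"],
                rec["black_observed_green"],
                rec["black_observed_blue"],
            )
        else:
            white = ColourVector(*[float(rec["white_observed"])] * 3)
            black = ColourVector(*[float(rec["black_observed"])] * 3)
        fixed = balance_correct(raw, BalanceReference(white, black))
        rows.append(
            {
                "id": rec["id"],
                "red": fixed.red,
                "green": fixed.green,
                "blue": fixed.blue,
                "L": fixed.total_reflectance,
            }
        )
    return pd.DataFrame(rows)


def log_standardize(values: np.ndarray) -> np.ndarray:
    """log10 then z-score (sample sd, n-1 denominator).

    Raises on non-positive entries (naming the offending rows) and on zero
    variance after the log transform.
    """
    values = np.asarray(values, dtype=float)
    bad = np.flatnonzero(~(values > 0))
    if bad.size:
        raise ValueError(f"non-positive values at rows {bad.tolist()}")
    logged = np.log10(values)
    sd = logged.std(ddof=1)
    # guard against exact constancy up to float cancellation noise
    if not np.isfinite(sd) or sd <= 1e-12 * max(1.0, float(np.abs(logged).max())):
        raise ValueError("zero variance after log transform")
    return (logged - logged.mean()) / sd
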