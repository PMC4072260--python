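"""Colocalization route: color deconvolution and stain-combination counting.

Stains mix additively in optical-density (OD) space (Beer-Lambert), so a 3x3
matrix of unit stain OD vectors unmixes each pixel's OD triple into per-stain
amounts (Ruifrok-Johnston color deconvolution).  Each pixel is then classified
by which stains exceed their thresholds — one of the eight presence patterns
1, 2, 3, 1+2, 1+3, 2+3, 1+2+3 or none — and fibrosis is the share of tissue
pixels carrying the collagen stain: patterns 3, 2+3 and 1+3.  Tissue is
defined as the non-NONE pixels, i.e. the algorithm's own notion of stained
material.

Thresholds operate on the deconvolved stain amount (OD units), strictly
greater-than; amounts may come out slightly negative under noise and are kept
as-is — they simply fail the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .synthetic_histology import RgbTile, ParameterError


class NoTissueError(ValueError):
    """Raised when an operation needs tissue pixels and the image has none."""


class ConfigurationError(ValueError):
    """Raised for unusable configuration such as a singular stain matrix."""


class StainCombo(IntEnum):
    """Stain-presence pattern; the value is the presence bitmask (1|2|4)."""

    NONE = 0
    S1 = 1
    S2 = 2
    S12 = 3
    S3 = 4
    S13 = 5
    S23 = 6
    S123 = 7


#: Patterns counted as fibrosis: collagen stain alone or with either companion.
FIBROSIS_COMBOS = (StainCombo.S3, StainCombo.S23, StainCombo.S13)

#: Fixed palette for the eight-color markup image (NONE rendered white).
MARKUP_PALETTE: dict[StainCombo, tuple[int, int, int]] = {
    StainCombo.NONE: (255, 255, 255),
    StainCombo.S1: (64, 64, 160),      # hematoxylin only: dark blue-violet
    StainCombo.S2: (220, 60, 60),      # red stain only: red
    StainCombo.S3: (60, 90, 220),      # collagen only: blue
    StainCombo.S12: (200, 60, 200),    # 1+2: magenta
    StainCombo.S13: (60, 180, 220),    # 1+3: cyan
    StainCombo.S23: (120, 200, 90),    # 2+3: green
    StainCombo.S123: (90, 70, 40),     # 1+2+3: brown
}


@dataclass(frozen=True)
class StainMatrix:
    """Unit stain OD vectors (rows) with a cached unmixing inverse."""

    vectors: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vectors, dtype=float)
        if v.shape != (3, 3):
            raise ConfigurationError("stain matrix must be 3x3")
        norms = np.linalg.norm(v, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ConfigurationError("stain matrix rows must be unit OD vectors")
        if np.linalg.cond(v) > 1e12:
            raise ConfigurationError("stain matrix is singular or nearly so")
        object.__setattr__(self, "vectors", v)

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.vectors)


@dataclass(frozen=True)
class ColocalizationResult:
    """Per-category tissue percentages and the fibrosis total."""

    pct_per_category: dict[StainCombo, float]
    fibrosis_pct: float
    tissue_pixel_count: int
    markup: RgbTile


def rgb_to_od(tile: RgbTile | np.ndarray, background_intensity) -> np.ndarray:
    """Convert 8-bit RGB to per-channel optical density.

    ``OD_c = -log10(max(pixel_c, eps) / I0_c)`` with ``eps = 1`` guarding the
    zero-intensity pixel, clamped at 0 for pixels at or brighter than the
    white level I0.
    """
    i0 = np.asarray(background_intensity, dtype=float)
    if np.any(i0 <= 0):
        raise ParameterError("background intensity channels must be positive")
    pixels = tile.pixels if isinstance(tile, RgbTile) else np.asarray(tile)
    p = np.maximum(pixels.astype(float), 1.0)
    return np.maximum(-np.log10(p / i0), 0.0)


def deconvolve(od_image: np.ndarray, matrix: StainMatrix) -> np.ndarray:
    """Unmix per-pixel OD triples into per-stain amounts (OD units).

    Solves ``od = amounts @ V`` per pixel, i.e. ``amounts = od @ V^{-1}``;
    linear and exact on noiseless composed input.
    """
    od = np.asarray(od_image, dtype=float)
    if od.shape[-1] != 3:
        raise ParameterError("od_image must have 3 channels in the last axis")
    return od @ matrix.inverse


def classify_stains(concentrations: np.ndarray, thresholds) -> np.ndarray:
    """Per-pixel stain-presence pattern from deconvolved amounts.

    Stain ``s`` is present iff its amount is strictly greater than
    ``thresholds[s]``; the eight patterns are encoded as the ``StainCombo``
    bitmask, all-absent mapping to NONE.
    """
    thr = np.asarray(thresholds, dtype=float)
    if thr.shape != (3,) or np.any(thr < 0):
        raise ParameterError("thresholds must be 3 nonnegative amounts")
    conc = np.asarray(concentrations, dtype=float)
    present = conc > thr  # (..., 3) strict inequality
    codes = (
        present[..., 0].astype(np.uint8)
        + 2 * present[..., 1].astype(np.uint8)
        + 4 * present[..., 2].astype(np.uint8)
    )
    return codes


def render_markup(combo_map: np.ndarray) -> RgbTile:
    """Eight-color false-color image of the stain-combination map."""
    lut = np.zeros((8, 3), dtype=np.uint8)
    for combo, color in MARKUP_PALETTE.items():
        lut[combo] = color
    return RgbTile(lut[np.asarray(combo_map, dtype=np.uint8)], provenance="markup")


def colocalization_fractions(combo_map: np.ndarray) -> ColocalizationResult:
    """Category percentages over tissue and the fibrosis total.

    The denominator is the count of non-NONE pixels; fibrosis is the sum of
    the collagen-carrying patterns 3, 2+3 and 1+3.
    """
    codes = np.asarray(combo_map, dtype=np.uint8)
    if codes.size == 0:
        raise ParameterError("combination map is empty")
    counts = np.bincount(codes.ravel(), minlength=8)
    tissue = int(counts[1:].sum())
    if tissue == 0:
        raise NoTissueError("no stained (non-NONE) pixels: cannot form tissue fractions")
    pct = {StainCombo(c): 100.0 * counts[c] / tissue for c in range(1, 8)}
    fibrosis_pct = sum(pct[c] for c in FIBROSIS_COMBOS)
    return ColocalizationResult(
        pct_per_category=pct,
        fibrosis_pct=float(fibrosis_pct),
        tissue_pixel_count=tissue,
        markup=render_markup(codes),
    )


def quantify_tile(
    tile: RgbTile,
    matrix: StainMatrix,
    background_intensity,
    thresholds=(0.15, 0.15, 0.15),
) -> ColocalizationResult:
    """Full colocalization pipeline: OD -> unmix -> classify -> fractions."""
    od = rgb_to_od(tile, background_intensity)
    conc = deconvolve(od, matrix)
    return colocalization_fractions(classify_stains(conc, thresholds))
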