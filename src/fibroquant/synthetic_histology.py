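"""Synthetic trichrome-stained myocardium tiles with known ground truth.

Real endomyocardial biopsy slides are Masson's-trichrome stained: collagen
(fibrosis) takes the blue dye, myocardium the red cytoplasmic dye, nuclei the
iron hematoxylin, and the surrounding glass stays near-white.  This module
builds desk-scale stand-ins for such slides: a per-pixel class map
(``TissuePhantom``) with exactly known class fractions, and an RGB rendering
(``RgbTile``) obtained by composing stain optical densities through the
Beer-Lambert law — the exact inverse of the color-deconvolution unmixing the
colocalization route performs.  Because every pixel's class is known, every
downstream estimator can be scored against truth.

Conventions: images are ``(row, col)`` 0-based arrays; regions of interest are
half-open; all randomness flows through an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum
import json
from pathlib import Path

import numpy as np
import imageio.v3 as iio
from scipy import ndimage


class TissueClass(IntEnum):
    """Pixel classes used throughout: the stereology vocabulary.

    OTHER covers inflammation, necrosis and glass-like clearings inside the
    tissue; both area-fraction denominators exclude GLASS and OTHER.
    """

    GLASS = 0
    MYOCARDIUM = 1
    FIBROSIS = 2
    OTHER = 3


#: Classes counted in the fibrosis-fraction denominator.
EFFECTIVE_CLASSES = (TissueClass.MYOCARDIUM, TissueClass.FIBROSIS)


class ParameterError(ValueError):
    """A generator or estimator parameter is out of its documented domain."""


@dataclass(frozen=True)
class TissuePhantom:
    """Ground-truth class map with exact per-class pixel fractions."""

    label_map: np.ndarray  # 2-D uint8 of TissueClass codes
    pixel_size_um: float = 0.5
    true_fractions: dict[TissueClass, float] = field(default_factory=dict)

    def __post_init__(self):
        lm = np.asarray(self.label_map, dtype=np.uint8)
        if lm.ndim != 2 or lm.size < 1:
            raise ParameterError("label_map must be a non-empty 2-D array")
        object.__setattr__(self, "label_map", lm)
        if not self.true_fractions:
            object.__setattr__(self, "true_fractions", self._fractions_from_map())

    def _fractions_from_map(self) -> dict[TissueClass, float]:
        n = self.label_map.size
        return {c: float(np.count_nonzero(self.label_map == c)) / n for c in TissueClass}

    def recompute_fractions(self) -> dict[TissueClass, float]:
        return self._fractions_from_map()

    @property
    def fibrosis_fraction_of_tissue(self) -> float:
        """Fibrosis fraction over MYOCARDIUM+FIBROSIS pixels (GLASS/OTHER excluded)."""
        n_fib = np.count_nonzero(self.label_map == TissueClass.FIBROSIS)
        n_myo = np.count_nonzero(self.label_map == TissueClass.MYOCARDIUM)
        if n_fib + n_myo == 0:
            raise ParameterError("phantom has no effective tissue pixels")
        return n_fib / (n_fib + n_myo)


@dataclass(frozen=True)
class StainModel:
    """Three-stain Beer-Lambert forward model for Masson's trichrome.

    ``od_vectors`` rows are unit optical-density directions for stain 1
    (iron hematoxylin, nuclei), stain 2 (Biebrich scarlet / ponceau-fuchsin,
    cytoplasm red) and stain 3 (aniline blue, collagen).  The paper's slides
    never ship a deconvolution matrix, so these are documented literature-style
    constants, overridable wholesale.
    """

    od_vectors: np.ndarray
    background_intensity: np.ndarray
    mean_od_per_class: dict[TissueClass, np.ndarray]

    def __post_init__(self):
        v = np.asarray(self.od_vectors, dtype=float)
        if v.shape != (3, 3):
            raise ParameterError("od_vectors must be 3x3 (rows = stains)")
        norms = np.linalg.norm(v, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ParameterError("each od_vector must have unit Euclidean norm")
        bg = np.asarray(self.background_intensity, dtype=float)
        if bg.shape != (3,) or np.any(bg <= 0) or np.any(bg > 255):
            raise ParameterError("background_intensity channels must lie in (0, 255]")
        amounts = {
            TissueClass(k): np.asarray(a, dtype=float)
            for k, a in self.mean_od_per_class.items()
        }
        for c, a in amounts.items():
            if a.shape != (3,) or np.any(a < 0):
                raise ParameterError(f"OD amounts for {c.name} must be 3 nonnegative values")
        object.__setattr__(self, "od_vectors", v)
        object.__setattr__(self, "background_intensity", bg)
        object.__setattr__(self, "mean_od_per_class", amounts)


def default_stain_model() -> StainModel:
    """Masson-trichrome stain model used throughout the synthetic study.

    OD directions follow the standard Ruifrok-Johnston style triples for iron
    hematoxylin, a ponceau-fuchsin red and an aniline/methyl blue.  Mean OD
    amounts per class keep per-channel OD below ~1.2 so 8-bit quantization
    stays small; OTHER is rendered at near-zero OD (glass-like clearings).
    """
    v = np.array(
        [
            # stain 1: iron hematoxylin — blue-black, near-neutral absorber
            [0.577, 0.577, 0.577],
            # stain 2: cytoplasm red (ponceau-fuchsin family)
            [0.100, 0.737, 0.668],
            # stain 3: collagen blue (aniline/methyl blue)
            [0.800, 0.591, 0.105],
        ]
    )
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    amounts = {
        TissueClass.GLASS: np.zeros(3),
        TissueClass.MYOCARDIUM: np.array([0.20, 0.70, 0.02]),
        TissueClass.FIBROSIS: np.array([0.05, 0.05, 0.75]),
        TissueClass.OTHER: np.array([0.03, 0.02, 0.02]),
    }
    return StainModel(v, np.array([252.0, 252.0, 252.0]), amounts)


@dataclass(frozen=True)
class RgbTile:
    """An 8-bit RGB image plus a provenance tag (seed or source path)."""

    pixels: np.ndarray  # (H, W, 3) uint8
    provenance: str = ""

    def __post_init__(self):
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3:
            raise ParameterError("pixels must be (H, W, 3)")
        if p.dtype != np.uint8:
            if p.min() < 0 or p.max() > 255:
                raise ParameterError("channel values must lie in [0, 255]")
            p = p.astype(np.uint8)
        object.__setattr__(self, "pixels", p)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class CohortTruth:
    """One synthetic slide: phantom, rendering, and its true fibrosis percent."""

    slide_id: str
    true_fibrosis_pct: float
    phantom: TissuePhantom
    tile: RgbTile

    def __post_init__(self):
        if not 0.0 <= self.true_fibrosis_pct <= 100.0:
            raise ParameterError("true_fibrosis_pct must lie in [0, 100]")


@dataclass(frozen=True)
class MorphologyParams:
    """Spatial texture of the phantom's random fields.

    ``fibrosis_sigma`` is the isotropic smoothing scale (px) of the collagen
    field; ``anisotropy`` > 1 stretches it along columns, giving strand-like
    collagen; ``tissue_fraction`` is the target non-glass share of the tile;
    ``other_fraction`` the share of tissue set aside as OTHER blobs.
    """

    tissue_sigma: float = 24.0
    tissue_fraction: float = 0.75
    fibrosis_sigma: float = 5.0
    anisotropy: float = 3.0
    other_sigma: float = 4.0
    other_fraction: float = 0.02


def _quantile_mask(field: np.ndarray, n_select: int, where: np.ndarray | None = None) -> np.ndarray:
    """Boolean mask selecting the ``n_select`` largest field values (within ``where``)."""
    mask = np.zeros(field.shape, dtype=bool)
    if n_select <= 0:
        return mask
    if where is None:
        flat_idx = np.argpartition(field.ravel(), -n_select)[-n_select:]
        mask.ravel()[flat_idx] = True
    else:
        idx = np.flatnonzero(where)
        if n_select >= idx.size:
            mask.ravel()[idx] = True
        else:
            vals = field.ravel()[idx]
            top = idx[np.argpartition(vals, -n_select)[-n_select:]]
            mask.ravel()[top] = True
    return mask


def generate_phantom(
    height: int,
    width: int,
    target_fibrosis_fraction: float,
    morphology: MorphologyParams | None = None,
    seed: int = 0,
    pixel_size_um: float = 0.5,
) -> TissuePhantom:
    """Generate a labeled tissue phantom with an exact fibrosis fraction.

    A smoothed random field thresholded at a quantile yields the glass/tissue
    split; a second, anisotropically smoothed field is thresholded *by count*
    inside the effective tissue so the fibrosis fraction of MYOCARDIUM+FIBROSIS
    pixels equals ``target_fibrosis_fraction`` to within one pixel.  OTHER is
    laid down as small blobs at a fixed low fraction of the tissue so the
    denominator-exclusion rules downstream are actually exercised.
    """
    if not 0.0 <= target_fibrosis_fraction <= 1.0:
        raise ParameterError("target_fibrosis_fraction must lie in [0, 1]")
    if height < 32 or width < 32:
        raise ParameterError("phantom dimensions must be at least 32x32")
    m = morphology or MorphologyParams()
    rng = np.random.default_rng(seed)

    tissue_field = ndimage.gaussian_filter(
        rng.standard_normal((height, width)), m.tissue_sigma, mode="reflect"
    )
    n_tissue = int(round(m.tissue_fraction * height * width))
    tissue = _quantile_mask(tissue_field, n_tissue)

    other_field = ndimage.gaussian_filter(
        rng.standard_normal((height, width)), m.other_sigma, mode="reflect"
    )
    n_other = int(round(m.other_fraction * n_tissue))
    other = _quantile_mask(other_field, n_other, where=tissue)

    effective = tissue & ~other
    fib_field = ndimage.gaussian_filter(
        rng.standard_normal((height, width)),
        (m.fibrosis_sigma, m.fibrosis_sigma * m.anisotropy),
        mode="reflect",
    )
    n_fib = int(round(target_fibrosis_fraction * np.count_nonzero(effective)))
    fibrosis = _quantile_mask(fib_field, n_fib, where=effective)

    label_map = np.full((height, width), TissueClass.GLASS, dtype=np.uint8)
    label_map[effective] = TissueClass.MYOCARDIUM
    label_map[fibrosis] = TissueClass.FIBROSIS
    label_map[other] = TissueClass.OTHER
    return TissuePhantom(label_map, pixel_size_um=pixel_size_um)


def render_trichrome(
    phantom: TissuePhantom,
    stain_model: StainModel | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> RgbTile:
    """Render a phantom to RGB through the Beer-Lambert law.

    Each pixel's three stain amounts are the class means of ``stain_model``
    plus i.i.d. Gaussian camera/stain noise of SD ``noise_sd`` (OD units,
    clipped at 0); transmitted intensity is ``I0 * 10**(-amounts @ V)``,
    rounded to the nearest integer and clipped to [0, 255].
    """
    if noise_sd < 0:
        raise ParameterError("noise_sd must be nonnegative")
    sm = stain_model or default_stain_model()
    rng = np.random.default_rng(seed)
    h, w = phantom.label_map.shape
    amounts = np.zeros((h, w, 3))
    for c, a in sm.mean_od_per_class.items():
        amounts[phantom.label_map == c] = a
    if noise_sd > 0:
        amounts = np.clip(amounts + rng.normal(0.0, noise_sd, size=amounts.shape), 0.0, None)
    od = amounts @ sm.od_vectors
    intensity = sm.background_intensity * np.power(10.0, -od)
    pixels = np.clip(np.rint(intensity), 0, 255).astype(np.uint8)
    return RgbTile(pixels, provenance=f"synthetic:seed={seed}")


def generate_cohort(
    n_slides: int,
    fibrosis_range: tuple[float, float] = (0.0, 90.0),
    stain_model: StainModel | None = None,
    noise_sd: float = 0.02,
    seed: int = 0,
    tile_shape: tuple[int, int] = (256, 256),
    morphology: MorphologyParams | None = None,
) -> list[CohortTruth]:
    """Generate a cohort of slides whose true fibrosis spans ``fibrosis_range``.

    Target percentages are stratified-uniform: the range is cut into
    ``n_slides`` equal strata and one target drawn uniformly in each, so the
    cohort always covers the full range (mirroring a biopsy series selected to
    provide a full range of fibrosis).  Stored ``true_fibrosis_pct`` is
    recomputed by pixel count from each phantom's label map.
    """
    if n_slides < 1:
        raise ParameterError("n_slides must be >= 1")
    lo, hi = fibrosis_range
    if not (0.0 <= lo <= hi <= 100.0):
        raise ParameterError("fibrosis_range must satisfy 0 <= lo <= hi <= 100")
    sm = stain_model or default_stain_model()
    rng = np.random.default_rng(seed)
    edges = np.linspace(lo, hi, n_slides + 1)
    targets = rng.uniform(edges[:-1], edges[1:]) if hi > lo else np.full(n_slides, lo)
    rng.shuffle(targets)
    cohort = []
    for i, tgt in enumerate(targets):
        sub = int(rng.integers(0, 2**31 - 1))
        phantom = generate_phantom(
            *tile_shape, float(tgt) / 100.0, morphology=morphology, seed=sub
        )
        tile = render_trichrome(phantom, sm, noise_sd=noise_sd, seed=sub + 1)
        cohort.append(
            CohortTruth(
                slide_id=f"S{i + 1:03d}",
                true_fibrosis_pct=100.0 * phantom.fibrosis_fraction_of_tissue,
                phantom=phantom,
                tile=tile,
            )
        )
    return cohort


def simulate_pathologist(
    truths: "list[float] | np.ndarray",
    noise_sd: float = 4.0,
    rounding_step: float = 5.0,
    seed: int = 0,
) -> np.ndarray:
    """Emulate a pathologist's visual fibrosis score.

    The score is the truth plus Gaussian error, rounded to the nearest
    ``rounding_step`` percent (visual scores cluster on multiples of 5) and
    clipped to [0, 100].  Two readings two weeks apart are emulated by calling
    this twice with different seeds.
    """
    if rounding_step <= 0:
        raise ParameterError("rounding_step must be positive")
    rng = np.random.default_rng(seed)
    t = np.asarray(truths, dtype=float)
    noisy = t + rng.normal(0.0, noise_sd, size=t.shape) if noise_sd > 0 else t
    return np.clip(np.round(noisy / rounding_step) * rounding_step, 0.0, 100.0)


# ---------------------------------------------------------------------------
# File interfaces: tiles as PNG/TIFF, phantoms as label PNG + JSON sidecar,
# cohort manifest as CSV.

def save_tile(tile: RgbTile, path: str | Path) -> None:
    iio.imwrite(Path(path), tile.pixels)


def load_tile(path: str | Path) -> RgbTile:
    arr = iio.imread(Path(path))
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return RgbTile(np.asarray(arr, dtype=np.uint8), provenance=str(path))


def save_phantom(phantom: TissuePhantom, path: str | Path) -> None:
    """Write the label map as single-channel PNG plus a ``.json`` sidecar."""
    path = Path(path)
    iio.imwrite(path, phantom.label_map)
    sidecar = {
        "pixel_size_um": phantom.pixel_size_um,
        "true_fractions": {c.name: f for c, f in phantom.true_fractions.items()},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_phantom(path: str | Path) -> TissuePhantom:
    path = Path(path)
    label_map = np.asarray(iio.imread(path), dtype=np.uint8)
    pixel_size = 0.5
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        pixel_size = float(json.loads(sidecar.read_text()).get("pixel_size_um", 0.5))
    return TissuePhantom(label_map, pixel_size_um=pixel_size)


def write_cohort(cohort: list[CohortTruth], out_dir: str | Path) -> Path:
    """Write tiles, phantoms and a manifest CSV; returns the manifest path."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort:
        tile_path = out_dir / f"{s.slide_id}_tile.png"
        label_path = out_dir / f"{s.slide_id}_labels.png"
        save_tile(s.tile, tile_path)
        save_phantom(s.phantom, label_path)
        rows.append(
            {
                "slide_id": s.slide_id,
                "true_fibrosis_pct": f"{s.true_fibrosis_pct:.6f}",
                "tile_path": tile_path.name,
                "label_path": label_path.name,
            }
        )
    manifest = out_dir / "cohort_manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
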