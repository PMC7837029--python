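"""Digital-immunohistochemistry heterogeneity descriptors.

Quantifies how spatially heterogeneous hormone-receptor (DAB, brown)
staining is across a tumor region of a digitized slide. The slide is cut
into square tiles (default 2000 px at 0.5 um/px, i.e. 1 mm^2), each tile
gets a stained ratio (brown pixels / tissue pixels), ratios are ranked into
ten 10%-wide levels, and the rank map yields a co-occurrence matrix whose
Haralick summaries — together with the skewness and kurtosis of the ratio
distribution — form the per-slide feature vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2hed, rgb2hsv

from .texture import CooccurrenceMatrix, haralick_features, pairs_to_matrix

__all__ = [
    "SlideImage",
    "RoiMask",
    "Tile",
    "TileGrid",
    "IhcConfig",
    "IhcFeatureSet",
    "segment_tissue",
    "segment_stain",
    "build_tile_grid",
    "rank_ratio",
    "rank_cooccurrence",
    "distribution_shape",
    "ihc_feature_vector",
]


@dataclass(frozen=True)
class SlideImage:
    """RGB raster of a digitized stained section with physical pixel size."""

    pixels: np.ndarray  # (H, W, 3) uint8
    microns_per_pixel: float = 0.5

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("slide pixels must be an (H, W, 3) RGB array")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("slide must be at least 1x1 pixel")
        if px.dtype != np.uint8:
            raise ValueError("slide pixels must be 8-bit per channel (uint8)")
        if not self.microns_per_pixel > 0:
            raise ValueError("microns_per_pixel must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class RoiMask:
    """Boolean tumor region mask congruent with its slide."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("ROI mask must be 2-D")
        if not m.any():
            raise ValueError("ROI mask selects no pixels")
        object.__setattr__(self, "mask", m)

    @classmethod
    def full(cls, slide: SlideImage) -> "RoiMask":
        return cls(np.ones(slide.shape, dtype=bool))


@dataclass(frozen=True)
class Tile:
    row: int
    col: int
    tissue_fraction: float
    stained_ratio: float | None  # None when the tile fails the tissue filter
    rank: int | None


@dataclass(frozen=True)
class TileGrid:
    """Non-overlapping axis-aligned grid of per-square staining summaries."""

    tile_px: int
    n_rows: int
    n_cols: int
    tiles: tuple[Tile, ...]

    @classmethod
    def from_ratios(cls, ratios: np.ndarray, tile_px: int = 2000) -> "TileGrid":
        """Grid built directly from a 2-D array of stained ratios.

        ``nan`` entries become tiles with no ratio (e.g. outside the ROI).
        Convenient when the per-tile ratios are already known.
        """
        ratios = np.asarray(ratios, dtype=float)
        tiles = []
        for r in range(ratios.shape[0]):
            for c in range(ratios.shape[1]):
                v = ratios[r, c]
                if np.isnan(v):
                    tiles.append(Tile(r, c, 0.0, None, None))
                else:
                    tiles.append(Tile(r, c, 1.0, float(v), rank_ratio(float(v))))
        return cls(tile_px, ratios.shape[0], ratios.shape[1], tuple(tiles))

    def ranked(self) -> list[Tile]:
        return [t for t in self.tiles if t.rank is not None]

    def rank_map(self) -> np.ndarray:
        """Float grid of ranks, ``nan`` where the tile carries no ratio."""
        out = np.full((self.n_rows, self.n_cols), np.nan)
        for t in self.tiles:
            if t.rank is not None:
                out[t.row, t.col] = t.rank
        return out

    def ratios(self) -> np.ndarray:
        return np.array(
            [t.stained_ratio for t in self.tiles if t.stained_ratio is not None]
        )


@dataclass(frozen=True)
class IhcConfig:
    """Tunables of the slide pipeline (defaults give 1 mm^2 tiles at 20x)."""

    tile_px: int = 2000
    min_tissue_fraction: float = 0.05
    dab_od_threshold: float = 0.15  # optical density in the DAB channel
    tissue_value_max: float = 0.92  # HSV value below which a pixel can be tissue
    tissue_saturation_min: float = 0.04
    adjacency: str = "8"  # "4" or "8" neighbor co-occurrence
    shape_on: str = "ratios"  # "ratios" or "ranks"
    stain_method: str = "hed"  # "hed" color deconvolution or "hsv" range


@dataclass(frozen=True)
class IhcFeatureSet:
    contrast: float
    homogeneity: float
    dissimilarity: float
    entropy: float
    energy: float
    correlation: float
    skewness: float
    kurtosis: float
    n_tiles_used: int

    def as_dict(self) -> dict[str, float]:
        return {
            "contrast": self.contrast,
            "homogeneity": self.homogeneity,
            "dissimilarity": self.dissimilarity,
            "entropy": self.entropy,
            "energy": self.energy,
            "correlation": self.correlation,
            "skewness": self.skewness,
            "kurtosis": self.kurtosis,
            "n_tiles_used": self.n_tiles_used,
        }


def segment_tissue(slide: SlideImage, config: IhcConfig = IhcConfig()) -> np.ndarray:
    """Boolean raster of tissue (non-glass) pixels.

    A pixel is tissue iff its HSV value is below ``tissue_value_max`` (it is
    darker than blank glass) and its saturation exceeds
    ``tissue_saturation_min`` (it carries color). Deterministic.
    """
    hsv = rgb2hsv(slide.pixels)
    return (hsv[..., 2] < config.tissue_value_max) & (
        hsv[..., 1] > config.tissue_saturation_min
    )


def segment_stain(slide: SlideImage, config: IhcConfig = IhcConfig()) -> np.ndarray:
    """Boolean raster of DAB-stained (brown) pixels.

    Default classifier: color deconvolution into hematoxylin/eosin/DAB
    optical densities with the standard published stain matrix, thresholding
    the DAB channel at ``dab_od_threshold``. An HSV hue-range fallback is
    available as ``stain_method="hsv"``.
    """
    if config.stain_method == "hed":
        dab = rgb2hed(slide.pixels)[..., 2]
        return dab > config.dab_od_threshold
    if config.stain_method == "hsv":
        hsv = rgb2hsv(slide.pixels)
        # brown: hue in the red-orange band, moderately saturated, not bright
        return (
            (hsv[..., 0] < 0.12)
            & (hsv[..., 1] > 0.3)
            & (hsv[..., 2] < 0.75)
            & (hsv[..., 2] > 0.05)
        )
    raise ValueError(f"unknown stain_method {config.stain_method!r}")


def rank_ratio(ratio: float) -> int:
    """Ten-interval rank of a stained ratio.

    Level 0 covers [0, 0.10]; level k covers (0.10k, 0.10(k+1)] for k=1..9,
    i.e. the upper boundary belongs to the lower level.
    """
    if not 0.0 <= ratio <= 1.0:
        raise ValueError(f"stained ratio {ratio} outside [0, 1]")
    # small slack so 0.3 (stored as 0.30000000000000004) stays in level 2
    level = math.ceil(ratio * 10 - 1e-9) - 1
    return min(9, max(0, level))


def build_tile_grid(
    slide: SlideImage,
    roi: RoiMask,
    tissue: np.ndarray,
    stain: np.ndarray,
    tile_px: int = 2000,
    min_tissue_fraction: float = 0.05,
) -> TileGrid:
    """Cut the slide into squares and compute per-square stained ratios.

    The grid is anchored at the image origin; partial edge tiles are kept.
    Within each square, the ratio is stained / tissue counted over
    tile ∩ ROI ∩ tissue. Squares whose tissue fraction (tissue ∩ ROI pixels
    over tile area) falls below ``min_tissue_fraction`` carry no ratio and
    never enter the rank map.
    """
    h, w = slide.shape
    if roi.mask.shape != (h, w) or tissue.shape != (h, w) or stain.shape != (h, w):
        raise ValueError("ROI / tissue / stain rasters must match the slide shape")
    if tile_px < 1:
        raise ValueError("tile_px must be >= 1")
    if not 0.0 <= min_tissue_fraction <= 1.0:
        raise ValueError("min_tissue_fraction must lie in [0, 1]")

    usable = tissue & roi.mask
    stained = stain & usable
    n_rows = -(-h // tile_px)
    n_cols = -(-w // tile_px)
    tiles: list[Tile] = []
    for r in range(n_rows):
        for c in range(n_cols):
            sl = (slice(r * tile_px, (r + 1) * tile_px),
                  slice(c * tile_px, (c + 1) * tile_px))
            area = usable[sl].size
            n_tissue = int(usable[sl].sum())
            frac = n_tissue / area
            if n_tissue == 0 or frac < min_tissue_fraction:
                tiles.append(Tile(r, c, frac, None, None))
                continue
            ratio = int(stained[sl].sum()) / n_tissue
            tiles.append(Tile(r, c, frac, ratio, rank_ratio(ratio)))
    grid = TileGrid(tile_px, n_rows, n_cols, tuple(tiles))
    if not grid.ranked():
        raise ValueError(
            "empty grid: no square meets the minimum tissue fraction inside the ROI"
        )
    return grid


_OFFSETS = {
    "4": ((0, 1), (1, 0)),
    "8": ((0, 1), (1, 0), (1, 1), (1, -1)),
}


def rank_cooccurrence(
    grid: TileGrid, adjacency: str = "8", symmetric: bool = True
) -> CooccurrenceMatrix:
    """Normalized co-occurrence matrix of tile ranks at offset distance 1.

    Counts every pair of adjacent ranked tiles (4- or 8-neighborhood);
    unranked tiles never contribute. Symmetrized so (i,j) and (j,i) carry
    equal mass, then normalized to sum 1.
    """
    if adjacency not in _OFFSETS:
        raise ValueError("adjacency must be '4' or '8'")
    ranks = grid.rank_map()
    a_list, b_list = [], []
    for dr, dc in _OFFSETS[adjacency]:
        r0 = slice(max(0, -dr), ranks.shape[0] - max(0, dr))
        c0 = slice(max(0, -dc), ranks.shape[1] - max(0, dc))
        r1 = slice(max(0, dr), ranks.shape[0] + min(0, dr))
        c1 = slice(max(0, dc), ranks.shape[1] + min(0, dc))
        a, b = ranks[r0, c0], ranks[r1, c1]
        ok = ~(np.isnan(a) | np.isnan(b))
        a_list.append(a[ok])
        b_list.append(b[ok])
    a = np.concatenate(a_list)
    b = np.concatenate(b_list)
    if a.size == 0:
        raise ValueError("degenerate grid: no adjacent pair of ranked tiles")
    return pairs_to_matrix(a.astype(int), b.astype(int), 10, symmetric=symmetric)


def distribution_shape(values: np.ndarray | list[float]) -> dict[str, float]:
    """Sample skewness and excess kurtosis of the stained-ratio distribution.

    Uses the population central-moment estimators m3/m2^1.5 and m4/m2^2 - 3.
    A zero-variance sample yields ``nan`` for both, not an exception.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("distribution shape requires at least 3 values")
    m = x - x.mean()
    m2 = float((m**2).mean())
    if m2 <= 1e-300:
        return {"skewness": float("nan"), "kurtosis": float("nan")}
    m3 = float((m**3).mean())
    m4 = float((m**4).mean())
    return {"skewness": m3 / m2**1.5, "kurtosis": m4 / m2**2 - 3.0}


def ihc_feature_vector(
    slide: SlideImage, roi: RoiMask, config: IhcConfig = IhcConfig()
) -> IhcFeatureSet:
    """Full slide pipeline: segmentation -> tiling -> ranks -> features."""
    tissue = segment_tissue(slide, config)
    stain = segment_stain(slide, config)
    grid = build_tile_grid(
        slide, roi, tissue, stain, config.tile_px, config.min_tissue_fraction
    )
    matrix = rank_cooccurrence(grid, adjacency=config.adjacency)
    har = haralick_features(matrix)
    if config.shape_on == "ranks":
        shape_input = np.array([t.rank for t in grid.ranked()], dtype=float)
    else:
        shape_input = grid.ratios()
    if shape_input.size >= 3:
        shape = distribution_shape(shape_input)
    else:
        shape = {"skewness": float("nan"), "kurtosis": float("nan")}
    return IhcFeatureSet(
        contrast=har["contrast"],
        homogeneity=har["homogeneity"],
        dissimilarity=har["dissimilarity"],
        entropy=har["entropy"],
        energy=har["energy"],
        correlation=har["correlation"],
        skewness=shape["skewness"],
        kurtosis=shape["kurtosis"],
        n_tiles_used=len(grid.ranked()),
    )
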