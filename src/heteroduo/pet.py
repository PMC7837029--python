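"""PET metabolic-heterogeneity features inside a tumor VOI.

Implements SUVmax, intensity-histogram statistics, gray-level co-occurrence
(GLCM) features and neighborhood gray-level difference (NGLDM) features
under absolute intensity resampling: SUV values are discretized into
fixed-width bins over a fixed range (default 64 bins over [0, 32] SUV,
bin width 0.5), independent of each lesion's own intensity range.
Third-order matrices (GLRLM/GLSZM) are deliberately out of scope.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .texture import (
    CooccurrenceMatrix,
    entropy_bits,
    glcm_matrix_features,
    pairs_to_matrix,
)
from .ihc import distribution_shape

__all__ = [
    "PETVolume",
    "VOIMask",
    "DiscretizedVOI",
    "PetConfig",
    "PetFeatureSet",
    "suv_max",
    "discretize_absolute",
    "histogram_features",
    "glcm_matrices",
    "glcm_features",
    "ngldm_features",
    "pet_feature_vector",
    "GLCM_DIRECTIONS",
]

#: The 13 unique 3-D directions at Chebyshev distance 1 (half of the 26
#: neighbor offsets; the other half are their negations and are covered by
#: symmetrization).
GLCM_DIRECTIONS: tuple[tuple[int, int, int], ...] = tuple(
    d for d in itertools.product((-1, 0, 1), repeat=3) if d > (0, 0, 0)
)

COARSENESS_CAP = 1e6


@dataclass(frozen=True)
class PETVolume:
    """SUV voxel grid with physical spacing in mm."""

    voxels: np.ndarray  # (nx, ny, nz) float, SUV units
    spacing: tuple[float, float, float] = (1.3, 1.3, 1.9)

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels, dtype=float)
        if v.ndim != 3:
            raise ValueError("PET volume must be 3-D")
        if (v < 0).any():
            raise ValueError("SUV values must be nonnegative")
        if not all(s > 0 for s in self.spacing):
            raise ValueError("voxel spacing components must be positive")
        object.__setattr__(self, "voxels", v)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))


@dataclass(frozen=True)
class VOIMask:
    """Binary tumor volume of interest congruent with its PET volume."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 3:
            raise ValueError("VOI mask must be 3-D")
        if int(m.sum()) < 2:
            raise ValueError("VOI must contain at least 2 voxels")
        object.__setattr__(self, "mask", m)

    def check_congruent(self, vol: PETVolume) -> None:
        if self.mask.shape != vol.voxels.shape:
            raise ValueError(
                f"VOI shape {self.mask.shape} does not match volume "
                f"shape {vol.voxels.shape}"
            )


@dataclass(frozen=True)
class DiscretizedVOI:
    """Per-voxel bin indices of the VOI under absolute resampling.

    ``bins`` is an integer grid congruent with the volume; only entries
    where ``voi`` is true are meaningful.
    """

    bins: np.ndarray
    voi: np.ndarray
    n_bins: int
    lo: float
    hi: float

    @property
    def bin_width(self) -> float:
        return (self.hi - self.lo) / self.n_bins

    def voi_bins(self) -> np.ndarray:
        """1-D array of bin indices of the VOI voxels."""
        return self.bins[self.voi]


@dataclass(frozen=True)
class PetConfig:
    n_bins: int = 64
    lo: float = 0.0
    hi: float = 32.0
    min_voi_voxels: int = 64
    glcm_aggregation: str = "feature_mean"  # or "merge_matrices"


@dataclass(frozen=True)
class PetFeatureSet:
    suv_max: float
    histogram: dict[str, float]
    glcm: dict[str, float]
    ngldm: dict[str, float]

    def as_dict(self) -> dict[str, float]:
        out = {"suv_max": self.suv_max}
        out.update({f"{k}_histo": v for k, v in self.histogram.items()})
        out.update({f"{k}_glcm": v for k, v in self.glcm.items()})
        out.update({f"{k}_ngldm": v for k, v in self.ngldm.items()})
        return out


def suv_max(vol: PETVolume, voi: VOIMask) -> float:
    """Maximum SUV over the VOI."""
    voi.check_congruent(vol)
    return float(vol.voxels[voi.mask].max())


def discretize_absolute(
    vol: PETVolume,
    voi: VOIMask,
    n_bins: int = 64,
    lo: float = 0.0,
    hi: float = 32.0,
) -> DiscretizedVOI:
    """Fixed-bin-width discretization: bin = floor((v - lo) / width).

    The value ``hi`` maps to the top bin; values outside [lo, hi] are
    clamped rather than rejected, since data acquired elsewhere may exceed
    the configured maximum SUV.
    """
    voi.check_congruent(vol)
    if not hi > lo:
        raise ValueError("hi must exceed lo")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    width = (hi - lo) / n_bins
    bins = np.floor((vol.voxels - lo) / width).astype(int)
    bins = np.clip(bins, 0, n_bins - 1)
    return DiscretizedVOI(bins=bins, voi=voi.mask, n_bins=n_bins, lo=lo, hi=hi)


def histogram_features(d: DiscretizedVOI) -> dict[str, float]:
    """Intensity-histogram features of the discretized VOI.

    ``entropy`` (bits) and ``uniformity`` are computed over occupied-bin
    occupancy fractions; ``skewness`` and ``kurtosis`` (excess) are the
    central-moment shape statistics of the bin-index sample, ``nan`` when
    the VOI is single-valued.
    """
    idx = d.voi_bins()
    if idx.size < 3:
        raise ValueError("histogram features require at least 3 VOI voxels")
    counts = np.bincount(idx, minlength=d.n_bins).astype(float)
    p = counts[counts > 0] / idx.size
    shape = distribution_shape(idx.astype(float))
    return {
        "skewness": shape["skewness"],
        "kurtosis": shape["kurtosis"],
        "entropy": entropy_bits(p),
        "uniformity": float((p**2).sum()),
    }


def glcm_matrices(
    d: DiscretizedVOI, distance: int = 1
) -> dict[tuple[int, int, int], CooccurrenceMatrix]:
    """Direction-specific co-occurrence matrices over the VOI.

    For each of the 13 unique 3-D directions at Chebyshev distance
    ``distance``, counts ordered voxel pairs with both ends inside the VOI,
    symmetrizes and normalizes. Directions with no in-VOI pair are dropped;
    an error is raised if every direction is empty.
    """
    bins, voi = d.bins, d.voi
    out: dict[tuple[int, int, int], CooccurrenceMatrix] = {}
    for direction in GLCM_DIRECTIONS:
        off = tuple(c * distance for c in direction)
        sl0, sl1 = [], []
        for o, n in zip(off, bins.shape):
            sl0.append(slice(max(0, -o), n - max(0, o)))
            sl1.append(slice(max(0, o), n + min(0, o)))
        sl0, sl1 = tuple(sl0), tuple(sl1)
        ok = voi[sl0] & voi[sl1]
        if not ok.any():
            continue
        out[direction] = pairs_to_matrix(
            bins[sl0][ok], bins[sl1][ok], d.n_bins, symmetric=True
        )
    if not out:
        raise ValueError("no in-VOI voxel pair along any direction")
    return out


def glcm_features(
    mats: dict[tuple[int, int, int], CooccurrenceMatrix] | list[CooccurrenceMatrix],
    aggregation: str = "feature_mean",
) -> dict[str, float]:
    """Aggregate direction matrices into the six scalar GLCM features.

    Default aggregation computes features per direction and averages them
    (unweighted); ``merge_matrices`` instead averages the matrices and
    computes features once. ``correlation`` is averaged over the directions
    where it is defined, and ``nan`` only if undefined in all of them.
    """
    matrices = list(mats.values()) if isinstance(mats, dict) else list(mats)
    if not matrices:
        raise ValueError("glcm_features requires at least one matrix")
    if aggregation == "merge_matrices":
        merged = CooccurrenceMatrix(
            np.mean([m.entries for m in matrices], axis=0),
            matrices[0].levels,
            normalized=True,
        )
        return glcm_matrix_features(merged)
    if aggregation != "feature_mean":
        raise ValueError(f"unknown aggregation {aggregation!r}")
    per_dir = [glcm_matrix_features(m) for m in matrices]
    out: dict[str, float] = {}
    for key in per_dir[0]:
        vals = np.array([f[key] for f in per_dir])
        defined = vals[~np.isnan(vals)]
        out[key] = float(defined.mean()) if defined.size else float("nan")
    return out


def _neighbor_mean_levels(bins: np.ndarray, voi: np.ndarray) -> np.ndarray:
    """Mean level of the in-VOI 26-neighbors of every voxel (nan if none)."""
    padded_b = np.pad(bins.astype(float), 1)
    padded_m = np.pad(voi.astype(float), 1)
    tot = np.zeros(bins.shape)
    cnt = np.zeros(bins.shape)
    for off in itertools.product((-1, 0, 1), repeat=3):
        if off == (0, 0, 0):
            continue
        sl = tuple(slice(1 + o, 1 + o + n) for o, n in zip(off, bins.shape))
        tot += padded_b[sl] * padded_m[sl]
        cnt += padded_m[sl]
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)


def ngldm_features(d: DiscretizedVOI) -> dict[str, float]:
    """Coarseness, contrast and busyness from the neighborhood gray-level
    difference matrix.

    For each occupied level i, with p_i the fraction of VOI voxels at that
    level and s_i the summed absolute difference between each such voxel and
    the mean level of its in-VOI 26-neighbors:

    - coarseness = 1 / sum_i p_i s_i (capped at 1e6 for a uniform VOI)
    - contrast   = [sum_{i,j} p_i p_j (i-j)^2 / (N_g (N_g - 1))] * [sum_i s_i / N_v]
    - busyness   = sum_i p_i s_i / sum_{i != j} |i p_i - j p_j|

    with N_g the number of occupied levels and N_v the VOI voxel count.
    For a single-level VOI, contrast and busyness are ``nan``.
    """
    bins, voi = d.bins, d.voi
    nb_mean = _neighbor_mean_levels(bins, voi)
    has_nb = voi & ~np.isnan(nb_mean)
    if not has_nb.any():
        raise ValueError("no VOI voxel has an in-VOI neighbor")

    n_v = int(voi.sum())
    idx = bins[voi]
    levels, counts = np.unique(idx, return_counts=True)
    p = counts / n_v

    diffs = np.abs(bins[has_nb] - nb_mean[has_nb])
    s = np.zeros(levels.size)
    lev_of = bins[has_nb]
    for k, lev in enumerate(levels):
        s[k] = float(diffs[lev_of == lev].sum())

    ps = float((p * s).sum())
    n_g = levels.size
    coarseness = min(COARSENESS_CAP, 1.0 / ps) if ps > 0 else COARSENESS_CAP
    if n_g < 2:
        return {
            "coarseness": coarseness,
            "contrast": float("nan"),
            "busyness": float("nan"),
        }
    li, lj = np.meshgrid(levels, levels, indexing="ij")
    pi, pj = np.meshgrid(p, p, indexing="ij")
    contrast = float(
        (pi * pj * (li - lj) ** 2).sum() / (n_g * (n_g - 1)) * (s.sum() / n_v)
    )
    ip = levels * p
    denom = float(np.abs(ip[:, None] - ip[None, :]).sum())  # ordered pairs i != j
    busyness = ps / denom if denom > 0 else float("nan")
    return {"coarseness": coarseness, "contrast": contrast, "busyness": busyness}


def pet_feature_vector(
    vol: PETVolume, voi: VOIMask, config: PetConfig = PetConfig()
) -> PetFeatureSet:
    """Full PET pipeline: SUVmax + histogram + GLCM + NGLDM features."""
    voi.check_congruent(vol)
    n_vox = int(voi.mask.sum())
    if n_vox < config.min_voi_voxels:
        raise ValueError(
            f"volume of interest too small to be analyzed: {n_vox} voxels "
            f"< minimum {config.min_voi_voxels}"
        )
    d = discretize_absolute(vol, voi, config.n_bins, config.lo, config.hi)
    return PetFeatureSet(
        suv_max=suv_max(vol, voi),
        histogram=histogram_features(d),
        glcm=glcm_features(glcm_matrices(d), aggregation=config.glcm_aggregation),
        ngldm=ngldm_features(d),
    )
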