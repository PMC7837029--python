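"""Synthetic slides, PET lesions and survival cohorts with known truth.

No public dataset backs this analysis, so every stage is exercised on
simulated inputs that reproduce the statistical structure the methods
assume: spatially correlated stained-ratio fields with a controllable
Beta marginal rendered as brown-on-pink RGB slides, ellipsoidal SUV
lesions with correlated intensity texture, and proportional-hazards
survival cohorts whose hazard depends on a heterogeneity feature.

Every generator is a pure function of its parameter object, including the
seed, and returns the latent ground truth alongside the rendered object so
downstream recovery tests have an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .ihc import SlideImage
from .pet import PETVolume, VOIMask

__all__ = [
    "IhcSimParams",
    "PetSimParams",
    "CohortSimParams",
    "gen_ratio_field",
    "render_slide",
    "gen_pet_lesion",
    "gen_cohort",
    "NOISE_FEATURES",
]

# colors chosen so the default stain/tissue classifiers are genuinely
# exercised: DAB deep brown, tissue pink well below the glass luminance cut
DAB_RGB = (110, 65, 35)
TISSUE_RGB = (220, 170, 195)


@dataclass(frozen=True)
class IhcSimParams:
    """Conditions for a simulated stained slide.

    ``grid_shape`` tiles of ``tile_px`` pixels each; per-tile stained ratios
    follow a Beta(a, b) marginal with spatial correlation length
    ``correlation_length`` (in tiles, Gaussian-kernel sd). ``tissue_fraction``
    of each tile's pixels are tissue; colors carry Gaussian jitter of sd
    ``render_noise`` (8-bit counts).
    """

    grid_shape: tuple[int, int] = (8, 8)
    correlation_length: float = 1.5
    beta_a: float = 2.0
    beta_b: float = 8.0
    microns_per_pixel: float = 0.5
    tile_px: int = 64
    tissue_fraction: float = 0.9
    render_noise: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta_a <= 0 or self.beta_b <= 0:
            raise ValueError("Beta shape parameters must be positive")
        if self.correlation_length < 0:
            raise ValueError("correlation_length must be >= 0")


@dataclass(frozen=True)
class PetSimParams:
    """Conditions for a simulated ellipsoidal FDG-avid lesion.

    SUV = base_suv + texture_amplitude * G where G is a unit-variance
    correlated Gaussian field clipped to +/-3, so suv_max is always at least
    base_suv - 3 * texture_amplitude.
    """

    semi_axes_mm: tuple[float, float, float] = (15.0, 12.0, 10.0)
    spacing: tuple[float, float, float] = (1.3, 1.3, 1.9)
    base_suv: float = 8.0
    texture_amplitude: float = 1.5
    texture_correlation_length_mm: float = 4.0
    background_suv: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_suv <= 0:
            raise ValueError("base_suv must be positive")
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ValueError("lesion semi-axes must be positive")


@dataclass(frozen=True)
class CohortSimParams:
    """Conditions for a simulated event-free-survival cohort.

    Event times are exponential with hazard
    ``baseline_hazard * exp(beta_skew * skewness)`` where the per-patient
    skewness-like feature is standard normal; follow-up is administratively
    censored at ``admin_censor_time``. The defaults give roughly the event
    fraction of a 38-patient luminal cohort with 11 events over 8 years.
    """

    n: int = 40
    baseline_hazard: float = 0.043  # events per year at skewness 0
    beta_skew: float = float(np.log(3.0))  # log hazard ratio per unit skewness
    admin_censor_time: float = 9.0
    horizon: float = 8.0
    age_mean: float = 55.0
    age_sd: float = 12.0
    stage_probs: tuple[float, float, float] = (0.105, 0.579, 0.316)
    n_noise_features: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("cohort size must be >= 2")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")


def _correlated_gaussian(shape: tuple[int, ...], sigma: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian field: blurred white noise, re-standardized."""
    z = rng.standard_normal(shape)
    if sigma > 0:
        z = ndimage.gaussian_filter(z, sigma=sigma, mode="reflect")
        sd = z.std()
        if sd > 0:
            z = (z - z.mean()) / sd
    return z


def gen_ratio_field(p: IhcSimParams) -> np.ndarray:
    """Grid of true stained ratios with a Beta(a, b) marginal.

    A correlated Gaussian field is mapped through a rank-based quantile
    transform, so the marginal is exactly a Beta(a, b) order-statistic
    sample while the spatial ordering (hence the texture) follows the
    Gaussian field.
    """
    rng = np.random.default_rng(p.seed)
    z = _correlated_gaussian(p.grid_shape, p.correlation_length, rng)
    ranks = stats.rankdata(z.ravel(), method="ordinal")
    u = (ranks - 0.5) / ranks.size
    return stats.beta.ppf(u, p.beta_a, p.beta_b).reshape(p.grid_shape)


def render_slide(
    field: np.ndarray, p: IhcSimParams
) -> tuple[SlideImage, dict[str, np.ndarray]]:
    """Render a ratio field as a brown-on-pink RGB slide.

    Each tile gets ``tissue_fraction`` of its pixels as tissue (the rest
    blank glass at pure white); exactly ``round(ratio * n_tissue)`` of the
    tissue pixels are DAB brown. Returns the slide plus ground truth:
    ``tissue_mask``, ``stain_mask`` and the per-tile ``true_ratios``.
    """
    rng = np.random.default_rng(p.seed + 1)  # independent of the field draw
    rows, cols = field.shape
    h, w = rows * p.tile_px, cols * p.tile_px
    img = np.full((h, w, 3), 255.0)
    tissue_mask = np.zeros((h, w), dtype=bool)
    stain_mask = np.zeros((h, w), dtype=bool)
    npx = p.tile_px * p.tile_px
    for r in range(rows):
        for c in range(cols):
            n_tissue = int(round(p.tissue_fraction * npx))
            order = rng.permutation(npx)
            tissue_flat = order[:n_tissue]
            n_stain = int(round(field[r, c] * n_tissue))
            stain_flat = tissue_flat[:n_stain]
            tm = np.zeros(npx, dtype=bool)
            tm[tissue_flat] = True
            sm = np.zeros(npx, dtype=bool)
            sm[stain_flat] = True
            tm = tm.reshape(p.tile_px, p.tile_px)
            sm = sm.reshape(p.tile_px, p.tile_px)
            sl = (slice(r * p.tile_px, (r + 1) * p.tile_px),
                  slice(c * p.tile_px, (c + 1) * p.tile_px))
            tile = np.full((p.tile_px, p.tile_px, 3), 255.0)
            tile[tm] = TISSUE_RGB
            tile[sm] = DAB_RGB
            if p.render_noise > 0:
                noise = rng.normal(0, p.render_noise, tile.shape)
                tile = np.where(tm[..., None], tile + noise, tile)
            img[sl] = tile
            tissue_mask[sl] = tm
            stain_mask[sl] = sm
    slide = SlideImage(
        np.clip(img, 0, 255).astype(np.uint8), microns_per_pixel=p.microns_per_pixel
    )
    truth = {
        "tissue_mask": tissue_mask,
        "stain_mask": stain_mask,
        "true_ratios": field.copy(),
    }
    return slide, truth


def gen_pet_lesion(
    p: PetSimParams, min_voxels: int = 64
) -> tuple[PETVolume, VOIMask, dict[str, float]]:
    """Ellipsoidal lesion on the configured voxel grid.

    The mask is the discrete ellipsoid with the stated semi-axes (mm); SUV
    inside is ``base_suv`` plus a correlated texture field of the stated
    amplitude, clipped at +/-3 sd and floored at 0. Outside the lesion a low
    uniform background uptake is used.
    """
    margin = 3
    shape = tuple(
        2 * (int(np.ceil(a / s)) + margin) + 1
        for a, s in zip(p.semi_axes_mm, p.spacing)
    )
    center = tuple((n - 1) / 2 for n in shape)
    grids = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    r2 = sum(
        ((g - c) * s / a) ** 2
        for g, c, s, a in zip(grids, center, p.spacing, p.semi_axes_mm)
    )
    mask = r2 <= 1.0
    if int(mask.sum()) < min_voxels:
        raise ValueError(
            f"lesion of {int(mask.sum())} voxels is below the minimum "
            f"analyzable VOI of {min_voxels}"
        )
    rng = np.random.default_rng(p.seed)
    sigma_vox = tuple(p.texture_correlation_length_mm / s for s in p.spacing)
    z = rng.standard_normal(shape)
    if p.texture_correlation_length_mm > 0:
        z = ndimage.gaussian_filter(z, sigma=sigma_vox, mode="reflect")
        sd = z.std()
        if sd > 0:
            z = (z - z.mean()) / sd
    z = np.clip(z, -3.0, 3.0)
    suv = np.where(mask, p.base_suv + p.texture_amplitude * z, p.background_suv)
    suv = np.clip(suv, 0.0, None)
    vol = PETVolume(suv, spacing=p.spacing)
    truth = {
        "base_suv": p.base_suv,
        "texture_amplitude": p.texture_amplitude,
        "n_voxels": float(mask.sum()),
    }
    return vol, VOIMask(mask), truth


#: feature columns drawn as pure noise alongside the planted one, named for
#: the quantities the downstream analysis typically carries
NOISE_FEATURES = (
    "kurtosis_er",
    "entropy_er",
    "energy_er",
    "contrast_er",
    "suv_max",
    "entropy_histo",
    "uniformity_histo",
    "busyness_ngldm",
)


def gen_cohort(p: CohortSimParams) -> tuple[pd.DataFrame, dict[str, float]]:
    """Survival cohort with a skewness-linked proportional hazard.

    Returns a per-patient table with id, age, clinical stage, grade,
    histology, molecular subtype, the planted ``skewness_er`` feature,
    ``p.n_noise_features`` independent noise features, follow-up time,
    event flag and the binary event-within-horizon label ``efs8_event``
    (1 = event observed by ``horizon`` years).
    """
    rng = np.random.default_rng(p.seed)
    skew = rng.standard_normal(p.n)
    hazard = p.baseline_hazard * np.exp(p.beta_skew * skew)
    t_event = rng.exponential(1.0 / hazard)
    time = np.minimum(t_event, p.admin_censor_time)
    event = (t_event <= p.admin_censor_time).astype(int)

    age = np.clip(rng.normal(p.age_mean, p.age_sd, p.n), 25, 90)
    stage = rng.choice(["I", "II", "III"], size=p.n, p=p.stage_probs)
    grade = rng.choice(["I", "II", "III"], size=p.n, p=(0.2, 0.5, 0.3))
    histology = rng.choice(
        ["ductal", "lobular", "other"], size=p.n, p=(0.789, 0.132, 0.079)
    )
    subtype = rng.choice(
        ["luminal_A", "luminal_B_HER2neg", "luminal_B_HER2pos"],
        size=p.n,
        p=(0.632, 0.263, 0.105),
    )
    df = pd.DataFrame(
        {
            "id": [f"P{i:03d}" for i in range(p.n)],
            "age": age,
            "clinical_stage": stage,
            "grade": grade,
            "histology": histology,
            "molecular_subtype": subtype,
            "skewness_er": skew,
        }
    )
    noise = rng.standard_normal((p.n, p.n_noise_features))
    for k in range(p.n_noise_features):
        df[NOISE_FEATURES[k % len(NOISE_FEATURES)] if k < len(NOISE_FEATURES)
           else f"noise_{k}"] = noise[:, k]
    df["followup_time"] = np.maximum(time, 1e-6)
    df["event"] = event
    df["efs8_event"] = ((t_event <= p.horizon)).astype(int)
    truth = {
        "beta_skew": p.beta_skew,
        "baseline_hazard": p.baseline_hazard,
        "event_fraction": float(event.mean()),
    }
    return df, truth
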