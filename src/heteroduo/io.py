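"""Reading and writing the file formats the pipeline speaks.

Slides are tiled (or plain) TIFF / PNG read with tifffile and imageio;
PET volumes and 3-D masks are NIfTI read with nibabel. Physical metadata
resolution: an explicit configuration value always wins over file tags.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import tifffile

from .ihc import RoiMask, SlideImage
from .pet import PETVolume, VOIMask

logger = logging.getLogger("heteroduo")

__all__ = [
    "read_slide",
    "write_slide",
    "read_mask_2d",
    "read_volume_mask",
    "write_volume_mask",
]


def _mpp_from_tiff(path: Path) -> float | None:
    """Microns per pixel from TIFF resolution tags, if present and sane."""
    try:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            xres = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            if xres is None:
                return None
            num, den = xres.value
            if num == 0:
                return None
            per_unit = num / den  # pixels per unit
            unit_val = getattr(unit, "value", None)
            unit_um = {2: 25400.0, 3: 10000.0}  # inch, centimeter in um
            if unit_val in (2, 3):
                return unit_um[int(unit_val)] / per_unit
            return None
    except (tifffile.TiffFileError, OSError):
        return None


def read_slide(path: str | Path, microns_per_pixel: float | None = None) -> SlideImage:
    """Load an RGB slide image with a resolved physical pixel size.

    ``microns_per_pixel`` from the caller (configuration) takes precedence
    over TIFF resolution tags; with neither available an error is raised.
    16-bit input is rescaled to 8-bit (max maps to 255) with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"slide file not found: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        pixels = tifffile.imread(path)
        tag_mpp = _mpp_from_tiff(path)
    else:
        import imageio.v3 as iio

        pixels = iio.imread(path)
        tag_mpp = None
    if pixels.ndim == 2:
        pixels = np.stack([pixels] * 3, axis=-1)
    if pixels.shape[-1] == 4:
        pixels = pixels[..., :3]
    if pixels.dtype == np.uint16:
        logger.warning("16-bit slide %s rescaled to 8-bit (max -> 255)", path.name)
        top = pixels.max()
        pixels = (pixels.astype(float) / (top if top else 1) * 255).astype(np.uint8)
    elif pixels.dtype != np.uint8:
        raise ValueError(f"unsupported slide dtype {pixels.dtype} in {path}")
    mpp = microns_per_pixel if microns_per_pixel is not None else tag_mpp
    if mpp is None:
        raise ValueError(
            f"no pixel size for {path}: pass microns_per_pixel or use a TIFF "
            "with resolution tags"
        )
    return SlideImage(pixels, microns_per_pixel=float(mpp))


def write_slide(path: str | Path, slide: SlideImage, tile: int = 256) -> None:
    """Write a slide as a tiled TIFF with resolution tags in pixels/cm."""
    px_per_cm = 10000.0 / slide.microns_per_pixel
    h, w = slide.shape
    tile_opt = (tile, tile) if min(h, w) >= 16 else None
    tifffile.imwrite(
        Path(path),
        slide.pixels,
        tile=tile_opt,
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
        photometric="rgb",
    )


def read_mask_2d(path: str | Path, shape: tuple[int, int] | None = None) -> RoiMask:
    """Binary 2-D ROI mask from PNG/TIFF (any nonzero pixel is inside)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        m = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        m = iio.imread(path)
    if m.ndim == 3:
        m = m[..., 0]
    mask = m > 0
    if shape is not None and mask.shape != shape:
        raise ValueError(f"ROI shape {mask.shape} does not match slide shape {shape}")
    return RoiMask(mask)


def read_volume_mask(
    vol_path: str | Path, mask_path: str | Path
) -> tuple[PETVolume, VOIMask]:
    """Load a NIfTI SUV volume and its congruent binary VOI mask.

    Spacing comes from the volume header; the mask is binarized at > 0.
    Shape or spacing mismatch between the pair raises with both shapes
    named.
    """
    import nibabel as nib

    vimg = nib.load(str(vol_path))
    mimg = nib.load(str(mask_path))
    vdata = np.asarray(vimg.dataobj, dtype=float)
    mdata = np.asarray(mimg.dataobj)
    if vdata.shape != mdata.shape:
        raise ValueError(
            f"volume shape {vdata.shape} does not match mask shape {mdata.shape}"
        )
    spacing = tuple(float(z) for z in vimg.header.get_zooms()[:3])
    mspacing = tuple(float(z) for z in mimg.header.get_zooms()[:3])
    if not np.allclose(spacing, mspacing, atol=1e-6):
        raise ValueError(f"volume spacing {spacing} != mask spacing {mspacing}")
    return PETVolume(vdata, spacing=spacing), VOIMask(mdata > 0)


def write_volume_mask(
    vol_path: str | Path, mask_path: str | Path, vol: PETVolume, voi: VOIMask
) -> None:
    """Write a PET volume and mask as NIfTI with the spacing in the header."""
    import nibabel as nib

    affine = np.diag(list(vol.spacing) + [1.0])
    nib.save(nib.Nifti1Image(vol.voxels.astype(np.float32), affine), str(vol_path))
    nib.save(
        nib.Nifti1Image(voi.mask.astype(np.uint8), affine), str(mask_path)
    )
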