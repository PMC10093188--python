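"""Digital emulation of the micro-CT to clinical ultra-high-resolution CT
(QDCT) resolution gap.

A high-resolution binary phantom stands in for the micro-CT segmentation
(0.05 mm isotropic voxels). The clinical acquisition is emulated as an
anisotropic Gaussian point-spread blur, resampling onto the coarser QDCT
grid (0.25 mm slices; 160 mm field of view on a 1024 matrix, i.e.
0.15625 mm in-plane), and additive Gaussian noise. The output is grayscale:
re-binarization is deliberately left to the caller's thresholding step so
each modality is segmented from its own histogram, as in a real two-scanner
workflow. The true scanner PSF of the clinical reconstruction kernel is not
published; the default FWHM (0.8 mm slice / 0.5 mm in-plane) is a free
parameter calibrated once to reproduce the *direction* of partial-volume
effects (thickness and volume-fraction inflation after re-thresholding),
not their exact magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .binarization import otsu_binarize
from .morphometry import MorphometryRecord, full_record
from .voi import VOILayout, extract_voi
from .volumes import BinaryVolume, ScalarVolume, Triple, resample_volume

__all__ = ["DegradeSpec", "degrade_volume", "nyquist_required_spacing", "paired_modality_run"]

_FWHM_SIGMA = 2.354820045030949

QDCT_SPACING: Triple = (0.25, 0.15625, 0.15625)


@dataclass
class DegradeSpec:
    """Resolution-degradation parameters (defaults: QDCT-like geometry)."""

    psf_fwhm: Triple = (0.8, 0.5, 0.5)  # mm (slice, row, col)
    out_spacing: Triple = QDCT_SPACING  # mm
    noise_sd: float = 0.0  # intensity units (phantom contrast is 0..100)
    seed: int = 0

    def __post_init__(self) -> None:
        self.psf_fwhm = tuple(float(f) for f in self.psf_fwhm)
        self.out_spacing = tuple(float(s) for s in self.out_spacing)
        if any(f < 0 for f in self.psf_fwhm):
            raise ValueError("psf_fwhm components must be >= 0")
        if any(s <= 0 for s in self.out_spacing):
            raise ValueError("out_spacing components must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def degrade_volume(vol: ScalarVolume | BinaryVolume, spec: DegradeSpec) -> ScalarVolume:
    """Blur, downsample and add noise; binary input is cast to 0/100 intensity.

    Refinement (out_spacing finer than the input grid) is refused — there is
    no synthetic super-resolution.
    """
    if isinstance(vol, BinaryVolume):
        vol = vol.to_scalar(fg=100.0, bg=0.0)
    if any(os_ < s * (1 - 1e-9) for os_, s in zip(spec.out_spacing, vol.spacing)):
        raise ValueError(
            f"out_spacing {spec.out_spacing} is finer than the input spacing "
            f"{vol.spacing}; refusing to invent resolution"
        )
    sigma_vox = [f / _FWHM_SIGMA / s for f, s in zip(spec.psf_fwhm, vol.spacing)]
    blurred = (
        vol.data.astype(np.float64)
        if all(s == 0 for s in sigma_vox)
        else ndimage.gaussian_filter(vol.data.astype(np.float64), sigma=sigma_vox)
    )
    out = resample_volume(
        ScalarVolume(blurred, vol.spacing, vol.origin), spec.out_spacing, "linear"
    )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        out = ScalarVolume(
            out.data + rng.normal(0.0, spec.noise_sd, size=out.shape),
            out.spacing,
            out.origin,
        )
    return out


def nyquist_required_spacing(min_feature: float) -> float:
    """Sampling interval (mm) required to resolve a feature of the given size:
    half the feature size, per the Nyquist–Shannon criterion."""
    if min_feature <= 0:
        raise ValueError("min_feature must be positive")
    return min_feature / 2.0


def paired_modality_run(
    phantom: BinaryVolume,
    layout: VOILayout,
    spec: DegradeSpec,
    seed: int = 0,
    star_points: int = 256,
    star_rays: int = 4,
) -> dict[str, dict[tuple[str, str, str], MorphometryRecord]]:
    """Per-VOI morphometry on the hi-res phantom and its degraded twin.

    The hi-res branch measures the phantom directly (unaffected by the
    degradation spec); the degraded branch blurs/downsamples, re-binarizes
    with a discriminant threshold on its own histogram, and measures the
    same physical cylinders mapped into the coarse grid. Returns
    ``{"hires": {label: record}, "degraded": {label: record}}``.
    """
    degraded_gray = degrade_volume(phantom, spec)
    degraded_mask, _ = otsu_binarize(degraded_gray)
    out: dict[str, dict] = {"hires": {}, "degraded": {}}
    for branch, vol in (("hires", phantom), ("degraded", degraded_mask)):
        for voi in layout.vois:
            try:
                ext = extract_voi(vol, voi)
                rec = full_record(
                    ext.mask,
                    ext.indicator,
                    seed=seed,
                    star_points=star_points,
                    star_rays=star_rays,
                )
            except Exception as exc:
                raise RuntimeError(
                    f"morphometry failed in branch {branch!r}, VOI {voi.label}: {exc}"
                ) from exc
            out[branch][voi.label] = rec
    return out
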