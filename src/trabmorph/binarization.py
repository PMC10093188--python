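"""Gradation processing: grayscale volume -> binary bone mask.

Bone is segmented from the marrow cavity by discriminant-analysis
thresholding on the intensity histogram: the threshold that maximizes the
between-class variance sigma_B^2(t) = w0*w1*(mu0 - mu1)^2 (Otsu's criterion).
Binarization itself doubles as the noise-removal step — no pre-filtering is
applied before thresholding.

Conventions chosen for determinism: 256 histogram bins by default, candidate
thresholds are the interior bin edges, and variance ties are broken toward
the smallest threshold. The comparison is inclusive (intensity >= t is bone),
which preserves thin bright trabeculae.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes import BinaryVolume, ScalarVolume

__all__ = [
    "HistogramModel",
    "ThresholdResult",
    "compute_histogram",
    "discriminant_threshold",
    "binarize",
    "otsu_binarize",
]


@dataclass
class HistogramModel:
    """Intensity histogram: ``counts[i]`` covers ``[bin_edges[i], bin_edges[i+1])``."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.float64)
        self.counts = np.asarray(self.counts)
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("len(bin_edges) must equal len(counts) + 1")
        if np.any(np.diff(self.bin_edges) < 0):
            raise ValueError("bin_edges must be monotone non-decreasing")
        if np.any(self.counts < 0) or self.counts.sum() <= 0:
            raise ValueError("counts must be nonnegative with positive total")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class ThresholdResult:
    threshold: float
    between_class_variance: float
    class_fractions: tuple[float, float]  # (marrow, bone)

    def __post_init__(self) -> None:
        if self.between_class_variance < 0:
            raise ValueError("between-class variance must be nonnegative")
        f0, f1 = self.class_fractions
        if not (0 <= f0 <= 1 and 0 <= f1 <= 1):
            raise ValueError("class fractions must lie in [0, 1]")


def compute_histogram(
    vol: ScalarVolume,
    region: BinaryVolume | np.ndarray | None = None,
    n_bins: int = 256,
) -> HistogramModel:
    """Histogram of intensities, optionally restricted to a region mask."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    values = vol.data
    if region is not None:
        region_mask = region.mask if isinstance(region, BinaryVolume) else np.asarray(region, bool)
        if region_mask.shape != vol.shape:
            raise ValueError(
                f"region shape {region_mask.shape} does not match volume shape {vol.shape}"
            )
        if not region_mask.any():
            raise ValueError("region mask is empty")
        values = values[region_mask]
    values = np.asarray(values, dtype=np.float64).ravel()
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        hi = lo + 1.0  # single-valued image: one bin holds all mass
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    return HistogramModel(edges, counts)


def discriminant_threshold(hist: HistogramModel) -> ThresholdResult:
    """Otsu's discriminant threshold on a histogram.

    Evaluates sigma_B^2 at every interior bin edge (class 0 = bins below the
    edge, class 1 = bins at/above it) and returns the smallest edge attaining
    the maximum. Requires at least two nonzero bins, otherwise there are no
    discriminable classes.
    """
    counts = hist.counts.astype(np.float64)
    if np.count_nonzero(counts) < 2:
        raise ValueError("histogram must have at least 2 nonzero bins")
    centers = hist.centers
    total = counts.sum()
    p = counts / total

    w0 = np.cumsum(p)[:-1]  # weight of class 0 for threshold after bin k
    w1 = 1.0 - w0
    cmu = np.cumsum(p * centers)
    mu_total = cmu[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = cmu[:-1] / w0
        mu1 = (mu_total - cmu[:-1]) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.where((w0 > 0) & (w1 > 0), sigma_b, -np.inf)
    # lowest-threshold tie-break, robust to rounding noise in the cumulative
    # formulation: candidates within 1e-12 relative of the maximum are ties
    smax = float(np.max(sigma_b))
    best = int(np.flatnonzero(sigma_b >= smax - abs(smax) * 1e-12)[0])
    t = float(hist.bin_edges[best + 1])
    return ThresholdResult(
        threshold=t,
        between_class_variance=float(sigma_b[best]),
        class_fractions=(float(w0[best]), float(w1[best])),
    )


def binarize(vol: ScalarVolume, t: float) -> BinaryVolume:
    """Threshold: bone = (intensity >= t). Spacing and origin are copied."""
    if not np.isfinite(t):
        raise ValueError("threshold must be finite")
    return BinaryVolume(vol.data >= t, vol.spacing, vol.origin)


def otsu_binarize(
    vol: ScalarVolume,
    region: BinaryVolume | np.ndarray | None = None,
    n_bins: int = 256,
) -> tuple[BinaryVolume, ThresholdResult]:
    """Convenience: histogram -> discriminant threshold -> binarize."""
    hist = compute_histogram(vol, region=region, n_bins=n_bins)
    res = discriminant_threshold(hist)
    return binarize(vol, res.threshold), res
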