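"""Stereological measures: star volume and intercept-based trabecular number.

Star volume V* of a phase is the mean volume visible along straight lines
from random points inside that phase: V* = (pi/3) * <l^3>, where l is the
full intercept length through a uniformly sampled phase point along an
isotropically random direction, traced until the line leaves the phase. For
a convex body the star set from any interior point is the whole body, so V*
equals the body volume — the basis of the Monte-Carlo oracle tests. Applied
to the marrow phase it is the marrow-space star volume (V*m.space); applied
to bone, the trabecular star volume (V*tr). Rays that leave the VOI or grid
before leaving the phase are censored at that boundary and flagged, never
silently dropped.

Trabecular number Tb.N is estimated by line interception: grid lines are
cast along each of the three axes and marrow-to-bone transitions are counted
per unit line length inside the VOI; the estimate is the mean over the three
directions. (The derived alternative (BV/TV)/Tb.Th is computed in the record
aggregator.)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from ..volumes import BinaryVolume

__all__ = ["StarSampleSet", "star_volume", "trabecular_number"]


@dataclass
class StarSampleSet:
    """Per-sample intercept lengths from the star-line algorithm."""

    phase: Literal["bone", "marrow"]
    points: np.ndarray  # (n, 3) mm sample points
    directions: np.ndarray  # (n, 3) unit vectors
    lengths: np.ndarray  # (n,) mm full intercept lengths
    censored: np.ndarray  # (n,) bool — ray reached the VOI/grid boundary
    seed: int

    @property
    def star_volume(self) -> float:
        """V* = (pi/3) * mean(l^3), mm^3 (censored samples included, truncated)."""
        return float(np.pi / 3.0 * np.mean(self.lengths**3))

    @property
    def censored_fraction(self) -> float:
        return float(self.censored.mean())


def _isotropic_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def star_volume(
    mask: BinaryVolume,
    phase: Literal["bone", "marrow"] = "marrow",
    region: np.ndarray | None = None,
    n_points: int = 256,
    n_rays: int = 4,
    seed: int = 0,
) -> tuple[float, StarSampleSet]:
    """Monte-Carlo star volume of the bone or marrow phase, in mm^3.

    Rays are marched at quarter-voxel steps with nearest-voxel phase lookup;
    ``region`` (e.g. a VOI indicator) censors rays at its boundary.
    """
    if n_points < 1 or n_rays < 1:
        raise ValueError("n_points and n_rays must be >= 1")
    phase_only = mask.mask if phase == "bone" else ~mask.mask
    phase_mask = phase_only if region is None else (phase_only & region)
    flat = np.flatnonzero(phase_mask)
    if flat.size == 0:
        raise ValueError(f"{phase} phase is empty")
    spacing = np.asarray(mask.spacing)
    shape = np.asarray(mask.shape)
    rng = np.random.default_rng(seed)

    chosen = rng.choice(flat, size=n_points, replace=True)
    vox = np.stack(np.unravel_index(chosen, mask.shape), axis=1).astype(np.float64)
    # jitter uniformly within each voxel
    pts = (vox + rng.uniform(-0.5, 0.5, size=vox.shape)) * spacing
    pts = np.repeat(pts, n_rays, axis=0)
    n = len(pts)
    dirs = _isotropic_directions(rng, n)

    step = float(spacing.min()) / 4.0
    max_steps = int(np.ceil(np.linalg.norm(shape * spacing) / step)) + 2
    lengths = np.zeros(n)
    censored = np.zeros(n, dtype=bool)

    for sign in (+1.0, -1.0):
        active = np.ones(n, dtype=bool)
        dist = np.zeros(n)
        for k in range(1, max_steps):
            if not active.any():
                break
            p = pts[active] + sign * (k * step) * dirs[active]
            idx = np.rint(p / spacing).astype(int)
            in_grid = np.all((idx >= 0) & (idx < shape), axis=1)
            idxc = np.clip(idx, 0, shape - 1)
            in_phase = phase_only[idxc[:, 0], idxc[:, 1], idxc[:, 2]]
            in_region = in_grid
            if region is not None:
                in_region = in_grid & region[idxc[:, 0], idxc[:, 1], idxc[:, 2]]
            keep_going = in_phase & in_region
            act_idx = np.flatnonzero(active)
            stopped = act_idx[~keep_going]
            # censored: ray still inside the phase but left the grid or VOI
            censored[stopped[(in_phase & ~in_region)[~keep_going]]] = True
            dist[act_idx[keep_going]] = k * step
            active[stopped] = False
        lengths += dist
    sample = StarSampleSet(
        phase=phase, points=pts, directions=dirs, lengths=lengths, censored=censored, seed=seed
    )
    return sample.star_volume, sample


def trabecular_number(
    mask: BinaryVolume,
    voi_indicator: np.ndarray | None = None,
    per_axis: bool = False,
) -> float | tuple[float, tuple[float, float, float]]:
    """Tb.N (1/mm): marrow-to-bone transitions per unit grid-line length,
    averaged over the three axis directions (per-axis rates on request)."""
    inside = (
        np.ones(mask.shape, dtype=bool) if voi_indicator is None else voi_indicator
    )
    if not inside.any():
        raise ValueError("empty VOI")
    bone = mask.mask & inside
    rates = []
    for ax in range(3):
        sl_hi = [slice(None)] * 3
        sl_lo = [slice(None)] * 3
        sl_hi[ax] = slice(1, None)
        sl_lo[ax] = slice(None, -1)
        hi, lo = tuple(sl_hi), tuple(sl_lo)
        transitions = bone[hi] & ~bone[lo] & inside[hi] & inside[lo]
        line_length = inside.sum() * mask.spacing[ax]
        rates.append(transitions.sum() / line_length)
    mean_rate = float(np.mean(rates))
    if per_axis:
        return mean_rate, tuple(float(r) for r in rates)
    return mean_rate
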