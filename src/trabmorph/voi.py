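"""Eight-segment cylindrical volume-of-interest layout.

The measurement geometry divides the cancellous region of a vertebral body
into eight segments: two halves along the craniocaudal (slice) axis, and a
2 x 2 split of the transverse plane into ventral/dorsal and left/right
quadrants. Each segment carries one cylinder (default 16 mm diameter, 12 mm
height) whose axis is craniocaudal. On real anatomy the cylinders sit just
below the endplates inside the cortical shell; here that placement is
abstracted behind the ``bounds`` box the caller supplies (cylinders are
centered in the octants of ``bounds``), which also guarantees the cortical
bone is excluded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .volumes import BinaryVolume, Triple

__all__ = ["CylinderVOI", "VOILayout", "eight_segment_layout", "extract_voi", "VOIExtract"]

Bounds = tuple[tuple[float, float], tuple[float, float], tuple[float, float]]

_AXIS_LABELS = (("cranial", "caudal"), ("ventral", "dorsal"), ("left", "right"))


@dataclass
class CylinderVOI:
    """A cylindrical VOI: ``center`` in mm (slice, row, col), axis a unit vector."""

    center: Triple
    diameter: float
    height: float
    label: tuple[str, str, str]
    axis: Triple = (1.0, 0.0, 0.0)  # craniocaudal by default

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.height <= 0:
            raise ValueError("diameter and height must be positive")
        a = np.asarray(self.axis, dtype=np.float64)
        n = np.linalg.norm(a)
        if n == 0:
            raise ValueError("axis must be a nonzero vector")
        self.axis = tuple(a / n)
        self.center = tuple(float(c) for c in self.center)

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def analytic_volume(self) -> float:
        """pi r^2 h in mm^3."""
        return float(np.pi * self.radius**2 * self.height)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Voxel-center-in-cylinder test for an (..., 3) array of mm points."""
        d = np.asarray(points, dtype=np.float64) - np.asarray(self.center)
        a = np.asarray(self.axis)
        axial = d @ a
        radial2 = np.einsum("...i,...i->...", d, d) - axial**2
        return (np.abs(axial) <= self.height / 2.0) & (radial2 <= self.radius**2)


@dataclass
class VOILayout:
    vois: list[CylinderVOI]
    bounds: Bounds

    def __post_init__(self) -> None:
        if len(self.vois) != 8:
            raise ValueError(f"layout must contain exactly 8 VOIs, got {len(self.vois)}")
        labels = [v.label for v in self.vois]
        if len(set(labels)) != 8:
            raise ValueError("VOI labels must be unique")

    def to_json(self) -> str:
        return json.dumps(
            {
                "bounds": self.bounds,
                "vois": [
                    {
                        "label": list(v.label),
                        "center_mm": list(v.center),
                        "axis": list(v.axis),
                        "diameter_mm": v.diameter,
                        "height_mm": v.height,
                    }
                    for v in self.vois
                ],
                "units": "mm",
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "VOILayout":
        obj = json.loads(text)
        vois = [
            CylinderVOI(
                center=tuple(d["center_mm"]),
                diameter=d["diameter_mm"],
                height=d["height_mm"],
                label=tuple(d["label"]),
                axis=tuple(d["axis"]),
            )
            for d in obj["vois"]
        ]
        bounds = tuple(tuple(b) for b in obj["bounds"])
        return cls(vois, bounds)


def eight_segment_layout(
    bounds: Bounds, diameter: float = 16.0, height: float = 12.0
) -> VOILayout:
    """Place 8 labeled cylinders, one per octant of ``bounds``.

    ``bounds`` is ((zmin, zmax), (ymin, ymax), (xmin, xmax)) in mm; the z axis
    is craniocaudal. Raises if any octant cannot contain its cylinder, naming
    the violated dimension.
    """
    bounds = tuple((float(lo), float(hi)) for lo, hi in bounds)
    spans = [hi - lo for lo, hi in bounds]
    if height > spans[0] / 2.0:
        raise ValueError(
            f"bounds too small along the craniocaudal axis: octant span "
            f"{spans[0] / 2.0:.3f} mm < cylinder height {height} mm"
        )
    for name, span in zip(("anteroposterior (row)", "lateral (col)"), spans[1:]):
        if diameter > span / 2.0:
            raise ValueError(
                f"bounds too small along the {name} axis: octant span "
                f"{span / 2.0:.3f} mm < cylinder diameter {diameter} mm"
            )
    vois = []
    for iz in range(2):
        for iy in range(2):
            for ix in range(2):
                center = tuple(
                    bounds[ax][0] + (2 * idx + 1) * spans[ax] / 4.0
                    for ax, idx in zip(range(3), (iz, iy, ix))
                )
                label = tuple(_AXIS_LABELS[ax][idx] for ax, idx in zip(range(3), (iz, iy, ix)))
                vois.append(CylinderVOI(center=center, diameter=diameter, height=height, label=label))
    return VOILayout(vois, bounds)


@dataclass
class VOIExtract:
    """Axis-aligned crop of a mask around one VOI plus the in-cylinder indicator.

    ``mask`` is the cropped bone mask; ``indicator`` marks voxels whose center
    lies inside the cylinder. The total tissue volume for morphometry is
    ``indicator.sum() * voxel volume``.
    """

    mask: BinaryVolume
    indicator: np.ndarray
    voi: CylinderVOI
    offset_index: tuple[int, int, int] = (0, 0, 0)

    @property
    def tissue_volume(self) -> float:
        return float(self.indicator.sum()) * self.mask.voxel_volume


def extract_voi(mask: BinaryVolume, voi: CylinderVOI) -> VOIExtract:
    """Crop ``mask`` to the VOI bounding box and rasterize the cylinder.

    Raster rule: a voxel belongs to the cylinder iff its center does. Raises
    if the cylinder does not intersect the volume grid.
    """
    spacing = np.asarray(mask.spacing)
    origin = np.asarray(mask.origin)
    center = np.asarray(voi.center)
    # conservative bounding half-size: radius in every direction plus height along axis
    half = voi.radius + voi.height / 2.0
    lo_idx = np.maximum(0, np.floor((center - half - origin) / spacing).astype(int))
    hi_idx = np.minimum(mask.shape, np.ceil((center + half - origin) / spacing).astype(int) + 1)
    if np.any(lo_idx >= hi_idx):
        raise ValueError(f"VOI {voi.label} lies entirely outside the volume")
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo_idx, hi_idx))
    crop = mask.mask[sl]
    grids = [
        origin[ax] + (np.arange(lo_idx[ax], hi_idx[ax])) * spacing[ax] for ax in range(3)
    ]
    pts = np.stack(np.meshgrid(*grids, indexing="ij"), axis=-1)
    indicator = voi.contains(pts)
    if not indicator.any():
        raise ValueError(f"VOI {voi.label} contains no voxel centers")
    sub = BinaryVolume(
        crop.copy(),
        mask.spacing,
        tuple(origin + lo_idx * spacing),
        meta=dict(mask.meta),
    )
    return VOIExtract(mask=sub, indicator=indicator, voi=voi, offset_index=tuple(int(i) for i in lo_idx))
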