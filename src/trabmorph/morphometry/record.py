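"""Aggregation of the 14 cancellous-bone morphometric parameters per VOI.

Units follow the conventional reporting: volumes in mm^3, surfaces in mm^2,
BV/TV in percent, Conn.D in 1/mm^3, TSL in mm, Tb.Th and Tb.Sp in
micrometres, Tb.N and TBPf in 1/mm, FD and SMI dimensionless, star volumes
in mm^3. Parameters whose preconditions fail on a degenerate VOI (e.g. an
all-marrow cylinder has no bone thickness) are recorded as NaN with the
failure noted in ``errors`` rather than aborting the whole record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np

from ..volumes import BinaryVolume
from .fractal import fractal_dimension
from .skeleton import (
    connectivity_density,
    euler_connectivity_density,
    skeleton_analysis,
    total_strut_length,
)
from .stereology import star_volume, trabecular_number
from .surface import smi, tbpf, volumes_and_surface
from .thickness import local_thickness

__all__ = ["MorphometryRecord", "full_record", "PARAMETER_COLUMNS"]

# column order used in CSV outputs (name, unit) as conventionally tabulated
PARAMETER_COLUMNS = [
    ("TV", "mm^3"),
    ("BV", "mm^3"),
    ("BS", "mm^2"),
    ("BVTV", "%"),
    ("ConnD", "1/mm^3"),
    ("TSL", "mm"),
    ("TbTh", "um"),
    ("TbN", "1/mm"),
    ("TbSp", "um"),
    ("FD", ""),
    ("TBPf", "1/mm"),
    ("SMI", ""),
    ("VmSpace", "mm^3"),
    ("Vtr", "mm^3"),
]


@dataclass
class MorphometryRecord:
    TV: float = math.nan
    BV: float = math.nan
    BS: float = math.nan
    BVTV: float = math.nan
    ConnD: float = math.nan
    TSL: float = math.nan
    TbTh: float = math.nan
    TbN: float = math.nan
    TbSp: float = math.nan
    FD: float = math.nan
    TBPf: float = math.nan
    SMI: float = math.nan
    VmSpace: float = math.nan
    Vtr: float = math.nan
    # secondary/diagnostic outputs, never substituted for the primary ones
    TbN_derived: float = math.nan  # (BV/TV) / Tb.Th, 1/mm
    ConnD_euler: float = math.nan  # (1 - chi)/TV, 1/mm^3
    star_censored_marrow: float = math.nan
    star_censored_bone: float = math.nan
    errors: dict = field(default_factory=dict)

    def primary_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name, _ in PARAMETER_COLUMNS}

    def as_dict(self) -> dict[str, float]:
        out = {}
        for f in fields(self):
            if f.name == "errors":
                continue
            out[f.name] = getattr(self, f.name)
        return out

    def validate(self) -> None:
        if not math.isnan(self.TV) and not math.isnan(self.BV):
            if self.BV > self.TV + 1e-9 or self.BV < 0:
                raise ValueError(f"invariant violated: need TV >= BV >= 0, got TV={self.TV}, BV={self.BV}")


def full_record(
    mask: BinaryVolume,
    voi_indicator: np.ndarray | None = None,
    seed: int = 0,
    star_points: int = 256,
    star_rays: int = 4,
) -> MorphometryRecord:
    """Compute all 14 parameters on one (VOI-restricted) binary volume.

    Sub-operations share intermediates where possible; failures of individual
    parameters on degenerate inputs are recorded per parameter.
    """
    rec = MorphometryRecord()

    def run(names, fn):
        try:
            fn()
        except Exception as exc:  # degenerate-input errors recorded per parameter
            for nm in names:
                rec.errors[nm] = f"{type(exc).__name__}: {exc}"

    def _vs():
        out = volumes_and_surface(mask, voi_indicator)
        rec.TV, rec.BV, rec.BS, rec.BVTV = out["TV"], out["BV"], out["BS"], out["BVTV"]

    run(["TV", "BV", "BS", "BVTV"], _vs)

    bone_in = mask.mask if voi_indicator is None else (mask.mask & voi_indicator)
    bone_sub = BinaryVolume(bone_in, mask.spacing, mask.origin)

    def _skel():
        graph = skeleton_analysis(bone_sub)
        rec.TSL = total_strut_length(graph)
        rec.ConnD = connectivity_density(graph, rec.TV)
        rec.ConnD_euler = euler_connectivity_density(bone_sub, rec.TV)

    run(["TSL", "ConnD"], _skel)

    def _thick():
        rec.TbTh = 1000.0 * local_thickness(mask, "bone", region=voi_indicator).mean

    run(["TbTh"], _thick)

    def _sep():
        rec.TbSp = 1000.0 * local_thickness(mask, "marrow", region=voi_indicator).mean

    run(["TbSp"], _sep)

    def _tbn():
        rec.TbN = trabecular_number(mask, voi_indicator)
        if rec.TbTh > 0:
            rec.TbN_derived = (rec.BVTV / 100.0) / (rec.TbTh / 1000.0)

    run(["TbN"], _tbn)

    run(["FD"], lambda: setattr(rec, "FD", fractal_dimension(bone_sub)))

    def _tbpf():
        rec.TBPf = tbpf(mask, voi_indicator)[0]

    run(["TBPf"], _tbpf)

    def _smi():
        rec.SMI = smi(mask, voi_indicator)[0]

    run(["SMI"], _smi)

    def _star_marrow():
        v, samples = star_volume(
            mask, "marrow", region=voi_indicator,
            n_points=star_points, n_rays=star_rays, seed=seed,
        )
        rec.VmSpace = v
        rec.star_censored_marrow = samples.censored_fraction

    run(["VmSpace"], _star_marrow)

    def _star_bone():
        v, samples = star_volume(
            mask, "bone", region=voi_indicator,
            n_points=star_points, n_rays=star_rays, seed=seed + 1,
        )
        rec.Vtr = v
        rec.star_censored_bone = samples.censored_fraction

    run(["Vtr"], _star_bone)

    rec.validate()
    return rec
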