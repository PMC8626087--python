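"""Region-of-interest definitions for the attention and default-mode networks.

Seeds are spheres in Talairach space.  The dorsal-ventral attention network
(DVAN) set holds the ten published group-mean centroids (bilateral IPS, hMT+,
FEF, TPJ, VFC).  The default-mode network (DMN) control set ships with
*placeholder* centroids: the study defined those regions only by name and
literature citation, so the coordinates below are synthetic stand-ins chosen
to be anatomically plausible and well separated from the DVAN spheres.  Both
sets are overridable from TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

DVAN = "DVAN"
DMN = "DMN"

ROI_TSV_COLUMNS = ["name", "hemisphere", "x", "y", "z", "radius_mm"]


@dataclass(frozen=True)
class RoiSpec:
    """A named spherical seed region.

    Parameters
    ----------
    name : str
        Region label, e.g. ``"IPS_L"``.
    hemisphere : str
        ``"L"``, ``"R"`` or ``"M"`` (midline).
    center : tuple of float
        (x, y, z) centroid in Talairach mm.
    radius_mm : float
        Sphere radius in mm (default 6).
    """

    name: str
    hemisphere: str
    center: tuple[float, float, float]
    radius_mm: float = 6.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError(f"ROI {self.name!r}: radius must be positive")
        if len(self.center) != 3:
            raise ValueError(f"ROI {self.name!r}: center must be (x, y, z)")


def _mk(name: str, hemi: str, x: float, y: float, z: float) -> RoiSpec:
    return RoiSpec(name=name, hemisphere=hemi, center=(float(x), float(y), float(z)))


# Published group-mean Talairach centroids of the attention-network seeds.
DVAN_ROIS: list[RoiSpec] = [
    _mk("IPS_L", "L", -26, -63, 48),
    _mk("IPS_R", "R", 25, -60, 48),
    _mk("hMT_L", "L", -44, -67, 3),
    _mk("hMT_R", "R", 44, -71, 6),
    _mk("FEF_L", "L", -30, -5, 48),
    _mk("FEF_R", "R", 30, -5, 48),
    _mk("TPJ_L", "L", -48, -54, 26),
    _mk("TPJ_R", "R", 48, -54, 21),
    _mk("VFC_L", "L", -42, 12, -1),
    _mk("VFC_R", "R", 40, 17, 4),
]

# Synthetic placeholder centroids for the ten DMN control seeds (the source
# study names these regions without printing coordinates).  Values approximate
# common literature locations; override from TSV for real analyses.
DMN_ROIS: list[RoiSpec] = [
    _mk("vmPFC", "M", -1, 47, -4),
    _mk("dPFC", "M", 0, 52, 26),
    _mk("PCC_L", "L", -5, -49, 40),
    _mk("LatTemp_L", "L", -60, -24, -12),
    _mk("IPL_L", "L", -47, -62, 33),
    _mk("IPL_R", "R", 47, -58, 33),
    _mk("PHC_L", "L", -26, -32, -18),
    _mk("PHC_R", "R", 26, -30, -18),
    _mk("HF_L", "L", -25, -22, -14),
    _mk("HF_R", "R", 25, -20, -14),
]

DEFAULT_ROI_SETS: dict[str, list[RoiSpec]] = {DVAN: DVAN_ROIS, DMN: DMN_ROIS}


def roi_set_to_frame(rois: list[RoiSpec]) -> pd.DataFrame:
    """Tabulate an ROI set with the standard TSV columns."""
    rows = [
        {
            "name": r.name,
            "hemisphere": r.hemisphere,
            "x": r.center[0],
            "y": r.center[1],
            "z": r.center[2],
            "radius_mm": r.radius_mm,
        }
        for r in rois
    ]
    return pd.DataFrame(rows, columns=ROI_TSV_COLUMNS)


def save_roi_set(rois: list[RoiSpec], path) -> None:
    roi_set_to_frame(rois).to_csv(path, sep="\t", index=False)


def load_roi_set(path) -> list[RoiSpec]:
    """Read an ROI set from TSV (columns: name, hemisphere, x, y, z, radius_mm)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(ROI_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ROI table missing columns: {sorted(missing)}")
    return [
        RoiSpec(
            name=str(row["name"]),
            hemisphere=str(row["hemisphere"]),
            center=(float(row["x"]), float(row["y"]), float(row["z"])),
            radius_mm=float(row["radius_mm"]),
        )
        for _, row in df.iterrows()
    ]


def roi_names(rois: list[RoiSpec]) -> list[str]:
    return [r.name for r in rois]
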