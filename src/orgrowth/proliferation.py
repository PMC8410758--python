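"""BrdU/Ki67 labeling index, cell-cycle length, and absolute cell counts.

The labeling index is the fraction of cycling (Ki67+) cells that
incorporated BrdU during a pulse; for a fixed S-phase length Ts it is
inversely proportional to the cell-cycle length via Tc = Ts / LI. Because
Ts cancels in ratios, genotype comparisons can be made Ts-free with
:func:`relative_cell_cycle`. Absolute cell numbers come from isotropic
fractionation: nuclei counted in a hemocytometer chamber scaled by
dilution and suspension volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CellCycleEstimate",
    "labeling_index",
    "cell_cycle_length",
    "relative_cell_cycle",
    "total_cells",
    "absolute_marker_count",
]

_LEVELS = ("section", "organoid", "line")


def labeling_index(sections: pd.DataFrame, level: str = "line") -> pd.Series:
    """BrdU+Ki67+ / Ki67+ fraction at the requested aggregation level.

    Counts are pooled (summed) across sections within an organoid because
    sections have unequal denominators; organoid-level values are then
    averaged within a line. Units with zero Ki67+ cells are dropped with a
    warning.

    Returns a Series indexed by section / organoid / line id.
    """
    if level not in _LEVELS:
        raise ValueError(f"level must be one of {_LEVELS}")
    required = {"line_id", "organoid_id", "n_ki67", "n_double"}
    missing = required - set(sections.columns)
    if missing:
        raise ValueError(f"section table lacks columns {sorted(missing)}")

    if level == "section":
        zero = sections["n_ki67"] == 0
        if zero.any():
            warnings.warn(f"{int(zero.sum())} sections with zero Ki67+ cells dropped")
        s = sections.loc[~zero]
        out = s["n_double"] / s["n_ki67"]
        out.index = pd.MultiIndex.from_frame(
            s[["organoid_id", "section_idx"]]
            if "section_idx" in s.columns
            else s[["organoid_id"]]
        )
        return out.rename("labeling_index")

    pooled = sections.groupby(["line_id", "organoid_id"])[["n_double", "n_ki67"]].sum()
    zero = pooled["n_ki67"] == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} organoids with zero Ki67+ cells dropped")
    pooled = pooled.loc[~zero]
    per_org = (pooled["n_double"] / pooled["n_ki67"]).rename("labeling_index")
    if level == "organoid":
        return per_org.droplevel("line_id")
    return per_org.groupby("line_id").mean()


@dataclass(frozen=True)
class CellCycleEstimate:
    """Cell-cycle length Tc derived from Tc = Ts / labeling index (hours)."""

    labeling_index: float
    t_s: float
    t_c: float


def cell_cycle_length(t_s: float, li: float) -> CellCycleEstimate:
    """Cell-cycle length from S-phase length Ts and labeling index."""
    if not 0.0 < li <= 1.0:
        raise ValueError(f"labeling index must be in (0, 1], got {li}")
    if t_s <= 0:
        raise ValueError("Ts must be positive")
    return CellCycleEstimate(labeling_index=float(li), t_s=float(t_s), t_c=float(t_s) / float(li))


def relative_cell_cycle(t_c_reference: float, li_fold: float) -> float:
    """Cell-cycle length implied by a fold-change in labeling index.

    Exact and Ts-free: Tc_other = Tc_reference / li_fold, because Ts
    cancels in the ratio of two Tc = Ts / LI estimates.
    """
    if li_fold <= 0:
        raise ValueError("labeling-index fold must be positive")
    if t_c_reference <= 0:
        raise ValueError("reference Tc must be positive")
    return float(t_c_reference) / float(li_fold)


def total_cells(
    chamber_count: float,
    chamber_volume_ml: float,
    dilution_factor: float = 1.0,
    suspension_volume_ml: float = 1.0,
) -> float:
    """Total cells in a homogenized organoid from a hemocytometer count.

    chamber_count / chamber_volume * dilution * suspension volume.
    """
    if chamber_volume_ml <= 0:
        raise ValueError("chamber volume must be positive")
    if chamber_count < 0 or dilution_factor <= 0 or suspension_volume_ml <= 0:
        raise ValueError("counts must be >= 0 and factors/volumes > 0")
    return chamber_count / chamber_volume_ml * dilution_factor * suspension_volume_ml


def absolute_marker_count(total: float, fraction: float) -> int:
    """Absolute marker-positive cell number: total * fraction, rounded to
    the nearest integer (ties to even)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    if total < 0:
        raise ValueError("total must be >= 0")
    return int(np.rint(total * fraction))
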