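"""Morphological endpoints paired with the fluorescence phenotyping:
specific leaf area (SLA) and aboveground dry-mass summaries.

SLA = leaf area / leaf dry mass (cm² g⁻¹); aboveground biomass is reported
per compartment (leaf, stem, pod dry mass) as cell means ± SD per
(maturity group, treatment level).  Pod mass may legitimately be zero —
severe heat aborts pods entirely.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DesignError, DomainError, FormatError, ValidationError
from .transients import TreatmentDesign

HARVEST_COLUMNS = (
    "leaf_area_cm2", "leaf_dry_g", "stem_dry_g", "pod_dry_g",
    "maturity_group", "day_length_h", "temp_day_c", "temp_night_c",
    "replicate",
)


@dataclass(frozen=True)
class PlantHarvest:
    """One plant's harvest record: leaf area (cm²) and dry masses (g)."""

    leaf_area_cm2: float
    leaf_dry_g: float
    stem_dry_g: float
    pod_dry_g: float
    meta: TreatmentDesign

    def __post_init__(self) -> None:
        for name in ("leaf_area_cm2", "leaf_dry_g", "stem_dry_g", "pod_dry_g"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {v}")


def specific_leaf_area(h: PlantHarvest) -> float:
    """SLA in cm² per g of leaf dry mass."""
    if h.leaf_dry_g <= 0:
        raise DomainError("leaf_dry_g must be > 0 to compute SLA")
    return h.leaf_area_cm2 / h.leaf_dry_g


def harvest_frame(harvests: Sequence[PlantHarvest]) -> pd.DataFrame:
    """Tidy per-plant table (one row per harvest) with SLA attached."""
    rows = []
    for h in harvests:
        m = h.meta
        rows.append(
            {
                "maturity_group": m.maturity_group,
                "day_length_h": m.day_length_h,
                "temp_day_c": m.temperature_day_c,
                "temp_night_c": m.temperature_night_c,
                "temperature": m.temperature_label,
                "replicate": m.replicate,
                "leaf_area_cm2": h.leaf_area_cm2,
                "leaf_dry_g": h.leaf_dry_g,
                "stem_dry_g": h.stem_dry_g,
                "pod_dry_g": h.pod_dry_g,
                "total_dry_g": h.leaf_dry_g + h.stem_dry_g + h.pod_dry_g,
                "sla_cm2_g": (h.leaf_area_cm2 / h.leaf_dry_g
                              if h.leaf_dry_g > 0 else np.nan),
            }
        )
    return pd.DataFrame(rows)


def read_harvest_table(path: str | Path) -> list[PlantHarvest]:
    """Read per-plant harvests from a CSV/TSV with the documented columns."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in HARVEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    out = []
    for _, r in df.iterrows():
        out.append(
            PlantHarvest(
                leaf_area_cm2=float(r["leaf_area_cm2"]),
                leaf_dry_g=float(r["leaf_dry_g"]),
                stem_dry_g=float(r["stem_dry_g"]),
                pod_dry_g=float(r["pod_dry_g"]),
                meta=TreatmentDesign(
                    maturity_group=str(r["maturity_group"]),
                    day_length_h=float(r["day_length_h"]),
                    temperature_day_c=float(r["temp_day_c"]),
                    temperature_night_c=float(r["temp_night_c"]),
                    replicate=int(r["replicate"]),
                ),
            )
        )
    return out


def biomass_summary(
    harvests: Sequence[PlantHarvest],
    axis: str = "temperature",
) -> pd.DataFrame:
    """Cell means ± SD of dry masses and SLA per (maturity group, level).

    ``axis`` is ``"temperature"`` or ``"day_length"``.  Cells with a single
    harvest report SD as missing; an empty cell (no harvest at all for a
    crossed level) raises :class:`DesignError` naming the cell.
    """
    if not harvests:
        raise DesignError("no harvests supplied")
    df = harvest_frame(harvests)
    level_col = "temperature" if axis == "temperature" else "day_length_h"
    measures = ["leaf_dry_g", "stem_dry_g", "pod_dry_g", "total_dry_g",
                "sla_cm2_g"]
    grouped = df.groupby(["maturity_group", level_col], sort=False)
    # crossed design check: every group must appear at every level
    groups = df["maturity_group"].unique()
    levels = df[level_col].unique()
    seen = set(grouped.groups)
    for g in groups:
        for lv in levels:
            if (g, lv) not in seen:
                raise DesignError(f"empty cell: maturity group {g}, level {lv}")
    out = grouped[measures].agg(["mean", "std", "count"])
    out.columns = [f"{m}_{stat}" for m, stat in out.columns]
    return out.reset_index()
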