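"""Well-lattice heatmaps, region assignment and region statistics.

The array pixelates a tissue section into 300 µm wells, so results are
naturally displayed on the well lattice: one heatmap cell per well per probe.
Tissue regions (tumor nodules, normal adjacent tissue) are supplied as
polygons in array µm coordinates — typically drawn on an H&E stain of a
proximal section and transferred by the user — and a well belongs to the
region containing its center.  Region summaries treat each well under a
region as one sample.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .geometry import ArrayLayout
from .qc import coefficient_of_variation

__all__ = [
    "RegionMask",
    "HeatmapGrid",
    "build_heatmap",
    "assign_wells_to_regions",
    "region_summary",
    "cross_section_cv",
]


@dataclass(frozen=True)
class RegionMask:
    """Labeled polygons in array µm coordinates (x right, y down)."""

    regions: tuple[tuple[str, tuple[tuple[float, float], ...]], ...]

    def __post_init__(self) -> None:
        labels = [label for label, _ in self.regions]
        if len(labels) != len(set(labels)):
            raise ValueError("region labels must be unique")
        for label, poly in self.regions:
            if not Polygon(poly).is_valid:
                raise ValueError(f"region {label!r} polygon is malformed")

    @classmethod
    def from_geojson(cls, obj: dict | str) -> "RegionMask":
        """Parse a GeoJSON FeatureCollection of labeled polygons."""
        if isinstance(obj, str):
            obj = json.loads(obj)
        regions = []
        for feat in obj["features"]:
            label = feat["properties"]["label"]
            ring = feat["geometry"]["coordinates"][0]
            regions.append((label, tuple((float(x), float(y)) for x, y in ring)))
        return cls(regions=tuple(regions))

    def to_geojson(self) -> dict:
        return {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "properties": {"label": label},
                    "geometry": {"type": "Polygon", "coordinates": [list(map(list, poly))]},
                }
                for label, poly in self.regions
            ],
        }


@dataclass(frozen=True)
class HeatmapGrid:
    """Per-well quantities for one probe on the well lattice (NaN = filtered)."""

    probe: str
    values: np.ndarray


def build_heatmap(
    wq: pd.DataFrame,
    probe: str,
    layout: ArrayLayout,
    value_col: str = "amount_amol",
) -> HeatmapGrid:
    """Arrange one probe's per-well quantities on the well grid.

    Cells of wells absent from the table (filtered, missing) stay NaN.
    ``value_col`` selects calibrated amounts or net AFU.
    """
    sub = wq[wq["probe"] == probe]
    if sub.empty:
        raise KeyError(f"probe {probe!r} not present")
    grid = np.full((layout.n_well_rows, layout.n_well_cols), np.nan)
    for rec in sub.itertuples(index=False):
        grid[rec.well_row, rec.well_col] = getattr(rec, value_col)
    return HeatmapGrid(probe=probe, values=grid)


def assign_wells_to_regions(
    layout: ArrayLayout, mask: RegionMask
) -> pd.DataFrame:
    """Region label per well: the region whose polygon contains the well center.

    Overlap ties resolve to the first-listed region (warned once); wells in
    no region are unassigned (label NaN).
    """
    polys = [(label, Polygon(poly)) for label, poly in mask.regions]
    rows = []
    warned = False
    for r in range(layout.n_well_rows):
        for c in range(layout.n_well_cols):
            center = Point(*layout.well_center_um(r, c))
            hits = [label for label, poly in polys if poly.contains(center)]
            if len(hits) > 1 and not warned:
                warnings.warn(
                    "overlapping region polygons; ties assigned to the first "
                    "listed region",
                    stacklevel=2,
                )
                warned = True
            rows.append(
                {
                    "well_row": r,
                    "well_col": c,
                    "region": hits[0] if hits else np.nan,
                }
            )
    return pd.DataFrame(rows)


def region_summary(
    wq: pd.DataFrame,
    assignment: pd.DataFrame,
    probe: str,
    value_col: str = "amount_amol",
) -> pd.DataFrame:
    """Sample statistics of one probe's well values per region.

    ``n`` counts the unfiltered wells under each region; mean and sd are the
    sample statistics of those wells.  Regions with no retained wells are
    omitted with a warning.  ``values`` keeps the per-well samples for
    plotting and for feeding the pairwise tests.
    """
    sub = wq[(wq["probe"] == probe) & wq[value_col].notna()]
    merged = sub.merge(assignment, on=["well_row", "well_col"], how="left")
    merged = merged[merged["region"].notna()]
    rows = []
    for label in [lab for lab, _ in _ordered_regions(assignment)]:
        vals = merged.loc[merged["region"] == label, value_col].to_numpy()
        if vals.size == 0:
            warnings.warn(f"region {label!r} has no retained wells; omitted",
                          stacklevel=2)
            continue
        rows.append(
            {
                "region": label,
                "n": int(vals.size),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "values": vals,
            }
        )
    return pd.DataFrame(rows)


def _ordered_regions(assignment: pd.DataFrame) -> list[tuple[str, int]]:
    labels = assignment["region"].dropna()
    order = labels.drop_duplicates().tolist()
    counts = labels.value_counts()
    return [(lab, int(counts[lab])) for lab in order]


def cross_section_cv(
    summaries: Mapping[str, Mapping[str, Mapping[str, float]]],
) -> tuple[dict[str, dict[str, float]], float]:
    """Coefficient of variation of region means across serial sections.

    ``summaries`` maps section → region → probe → mean.  Returns the CV (%)
    per (region, probe) across sections, and the grand average (unweighted
    mean of those CVs) — the single reproducibility number quoted for a
    serial-section experiment.
    """
    sections = list(summaries)
    if len(sections) < 2:
        raise ValueError("need >= 2 sections")
    first = summaries[sections[0]]
    region_probes = [(r, p) for r in first for p in first[r]]
    for s in sections[1:]:
        other = [(r, p) for r in summaries[s] for p in summaries[s][r]]
        if set(other) != set(region_probes):
            raise ValueError(f"section {s!r} has mismatched region/probe labels")
    cvs: dict[str, dict[str, float]] = {}
    flat = []
    for r, p in region_probes:
        series = [summaries[s][r][p] for s in sections]
        cv = coefficient_of_variation(series)
        cvs.setdefault(r, {})[p] = cv
        flat.append(cv)
    return cvs, float(np.mean(flat))
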