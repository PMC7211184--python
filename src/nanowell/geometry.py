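"""Physical geometry of nanoliter well arrays and assay-design arithmetic.

The device quantified by this package is a glass slide carrying a rectangular
grid of square nanoliter wells molded in optical adhesive.  Each well holds a
small square grid of photopolymerized hydrogel posts; each post carries one
DNA probe species and reports, through its mean fluorescence after labeling,
the amount of the complementary miRNA captured from the ~300 µm tissue patch
sealed above the well.

This module describes that geometry in physical units (µm) and implements the
design calculations used to size an assay: how many wells fit under a tissue
section of a given extent, the well volume, how many posts pack into a well
at a given pitch, and whether the expected amount of analyte per well clears
the assay's limit of detection.  All lengths are in µm; the single conversion
to image pixels is isolated in :attr:`ArrayLayout.pixel_size_um`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

__all__ = [
    "ArrayLayout",
    "PlexEntry",
    "PlexMap",
    "Role",
    "wells_per_area",
    "well_volume_nl",
    "posts_per_well",
    "expected_amount_per_well",
    "detectability_ratio",
    "post_loss_percent",
]

Role = Literal["target", "negative_control", "blank"]

#: µm³ in one nanoliter.
UM3_PER_NL = 1.0e6


@dataclass(frozen=True)
class ArrayLayout:
    """Physical description of a well array.

    Defaults reproduce the fabricated device: 300 µm square wells, 39 µm
    deep, separated by 50 µm, in a 28 × 28 grid covering 1 cm × 1 cm; each
    well holds a 3 × 3 grid of 40 µm posts at 100 µm center-to-center pitch;
    the slide scanner samples at 5 µm per pixel.
    """

    well_side_um: float = 300.0
    well_depth_um: float = 39.0
    well_spacing_um: float = 50.0
    n_well_rows: int = 28
    n_well_cols: int = 28
    post_side_um: float = 40.0
    post_grid_rows: int = 3
    post_grid_cols: int = 3
    post_pitch_um: float = 100.0
    pixel_size_um: float = 5.0

    def __post_init__(self) -> None:
        lengths = {
            "well_side_um": self.well_side_um,
            "well_depth_um": self.well_depth_um,
            "post_side_um": self.post_side_um,
            "post_pitch_um": self.post_pitch_um,
            "pixel_size_um": self.pixel_size_um,
        }
        for name, value in lengths.items():
            if not value > 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        if self.well_spacing_um < 0:
            raise ValueError("well_spacing_um must be >= 0")
        counts = {
            "n_well_rows": self.n_well_rows,
            "n_well_cols": self.n_well_cols,
            "post_grid_rows": self.post_grid_rows,
            "post_grid_cols": self.post_grid_cols,
        }
        for name, value in counts.items():
            if not (isinstance(value, int) and value >= 1):
                raise ValueError(f"{name} must be an integer >= 1, got {value!r}")
        for axis, n in (("cols", self.post_grid_cols), ("rows", self.post_grid_rows)):
            extent = (n - 1) * self.post_pitch_um + self.post_side_um
            if extent > self.well_side_um:
                raise ValueError(
                    f"post grid {axis} extent {extent} µm exceeds well side "
                    f"{self.well_side_um} µm"
                )

    # -- derived quantities ------------------------------------------------

    @property
    def well_pitch_um(self) -> float:
        """Center-to-center well spacing: well side plus gap."""
        return self.well_side_um + self.well_spacing_um

    @property
    def post_grid_extent_um(self) -> tuple[float, float]:
        """(height, width) of the post grid within a well."""
        h = (self.post_grid_rows - 1) * self.post_pitch_um + self.post_side_um
        w = (self.post_grid_cols - 1) * self.post_pitch_um + self.post_side_um
        return h, w

    @property
    def post_margin_um(self) -> tuple[float, float]:
        """(top, left) margin that centers the post grid in the well."""
        h, w = self.post_grid_extent_um
        return (self.well_side_um - h) / 2.0, (self.well_side_um - w) / 2.0

    def well_origin_um(self, row: int, col: int) -> tuple[float, float]:
        """Upper-left corner (x, y) of a well, array origin at (0, 0)."""
        return col * self.well_pitch_um, row * self.well_pitch_um

    def well_center_um(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.well_origin_um(row, col)
        return x0 + self.well_side_um / 2.0, y0 + self.well_side_um / 2.0

    def post_origin_um(
        self, well_row: int, well_col: int, post_row: int, post_col: int
    ) -> tuple[float, float]:
        """Upper-left corner (x, y) of a post in array coordinates."""
        x0, y0 = self.well_origin_um(well_row, well_col)
        top, left = self.post_margin_um
        return (
            x0 + left + post_col * self.post_pitch_um,
            y0 + top + post_row * self.post_pitch_um,
        )

    @property
    def array_extent_um(self) -> tuple[float, float]:
        """(width, height) spanned by the wells, without outer margin."""
        w = (self.n_well_cols - 1) * self.well_pitch_um + self.well_side_um
        h = (self.n_well_rows - 1) * self.well_pitch_um + self.well_side_um
        return w, h

    @property
    def post_side_px(self) -> int:
        return int(round(self.post_side_um / self.pixel_size_um))

    @property
    def post_footprint_px(self) -> int:
        """Pixel count covered by one post; the size cutoff for dust removal."""
        return self.post_side_px**2


@dataclass(frozen=True)
class PlexEntry:
    """Probe identity and role of one post position within every well."""

    probe: str
    role: Role

    def __post_init__(self) -> None:
        if self.role not in ("target", "negative_control", "blank"):
            raise ValueError(f"unknown role {self.role!r}")


@dataclass(frozen=True)
class PlexMap:
    """Assignment of each post position (row, col within a well) to a probe.

    The same map applies to every well: post (r, c) of every well carries the
    same probe.  Exactly one ``negative_control`` probe may be designated as
    the subtraction control (the off-target spike-in; the blank post is kept
    as a separate QC reading, not the subtrahend).
    """

    entries: Mapping[tuple[int, int], PlexEntry]
    control_probe: str | None = field(default=None)

    def __post_init__(self) -> None:
        controls = {e.probe for e in self.entries.values() if e.role == "negative_control"}
        if self.control_probe is None and len(controls) == 1:
            object.__setattr__(self, "control_probe", next(iter(controls)))
        elif self.control_probe is None and len(controls) > 1:
            raise ValueError(
                "multiple negative_control probes; designate control_probe explicitly"
            )
        if self.control_probe is not None and self.control_probe not in controls:
            raise ValueError(
                f"control_probe {self.control_probe!r} is not a negative_control entry"
            )

    def validate_against(self, layout: ArrayLayout) -> None:
        """Require exactly one entry per post position of the layout."""
        expected = {
            (r, c)
            for r in range(layout.post_grid_rows)
            for c in range(layout.post_grid_cols)
        }
        got = set(self.entries)
        if got != expected:
            missing = expected - got
            extra = got - expected
            raise ValueError(
                f"plex map does not cover the post grid: missing {sorted(missing)}, "
                f"extra {sorted(extra)}"
            )

    @property
    def target_probes(self) -> list[str]:
        return [e.probe for e in self.entries.values() if e.role == "target"]

    def probe_position(self, probe: str) -> tuple[int, int]:
        for pos, e in self.entries.items():
            if e.probe == probe:
                return pos
        raise KeyError(probe)


# -- design calculations ----------------------------------------------------


def wells_per_area(
    width_um: float, height_um: float, layout: ArrayLayout
) -> tuple[int, int, int]:
    """Number of wells fitting under a ``width × height`` µm footprint.

    The trailing inter-well spacer is credited (an array of *n* wells spans
    ``n·pitch − spacing``), so ``floor((extent + spacing) / pitch)`` wells fit
    per axis.  Returns ``(rows, cols, total)``.
    """
    if width_um <= 0 or height_um <= 0:
        raise ValueError("area dimensions must be positive")
    pitch = layout.well_pitch_um
    rows = math.floor((height_um + layout.well_spacing_um) / pitch)
    cols = math.floor((width_um + layout.well_spacing_um) / pitch)
    return rows, cols, rows * cols


def well_volume_nl(layout: ArrayLayout) -> float:
    """Volume of a single well in nanoliters (side² × depth)."""
    return layout.well_side_um**2 * layout.well_depth_um / UM3_PER_NL


def posts_per_well(
    well_side_um: float, post_side_um: float, post_pitch_um: float
) -> int:
    """Square posts fitting in a square well on a grid at the given pitch.

    Per axis, ``floor((well − post) / pitch) + 1`` posts fit: the grid extent
    ``(n − 1)·pitch + post`` never exceeds the well side.  The count is the
    square of the per-axis count.
    """
    if post_side_um > well_side_um:
        raise ValueError("post larger than well")
    if not (post_side_um <= post_pitch_um <= well_side_um):
        raise ValueError("require post_side <= pitch <= well_side")
    n_axis = math.floor((well_side_um - post_side_um) / post_pitch_um) + 1
    return n_axis**2


def expected_amount_per_well(
    areal_density_amol_per_mm2: float, layout: ArrayLayout
) -> float:
    """Expected captured amount (amol) given a tissue areal density.

    The tissue patch above each well is digested into that well, so the
    captured amount is the areal density times the well footprint in mm².
    """
    if areal_density_amol_per_mm2 < 0:
        raise ValueError("areal density must be >= 0")
    footprint_mm2 = (layout.well_side_um / 1000.0) ** 2
    return areal_density_amol_per_mm2 * footprint_mm2


def detectability_ratio(expected_amol: float, lod_amol: float) -> float:
    """Ratio of expected captured amount to the limit of detection.

    A ratio above 1 means the design is expected to detect the analyte.
    """
    if lod_amol <= 0:
        raise ValueError("lod_amol must be > 0")
    if expected_amol < 0:
        raise ValueError("expected_amol must be >= 0")
    return expected_amol / lod_amol


def post_loss_percent(n_lost: int, n_total: int) -> float:
    """Percentage of posts lost during fabrication (fabrication QC)."""
    if n_total <= 0 or n_lost < 0 or n_lost > n_total:
        raise ValueError("require 0 <= n_lost <= n_total, n_total > 0")
    return 100.0 * n_lost / n_total
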