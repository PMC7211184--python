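"""Ground-truthed synthetic array images.

Real slide-scanner images of sealed tissue assays are not distributable, so
every downstream stage of this package is exercised against synthetic renders
with known truth.  The generator emulates the data-generating process of the
assay at the level the analysis sees it:

* the array geometry (wells, posts, pixel scale) from :class:`ArrayLayout`;
* a linear signal model — the noiseless mean fluorescence of a post is
  ``background + gain × captured_amount``, optionally capped at a saturation
  level.  The captured amount per well is the tissue areal density times the
  well footprint: signal tracks the *amount* of miRNA in a well, not its
  concentration, because hybridization runs long enough for the well content
  to be fully captured;
* independent Gaussian pixel noise;
* bright dust artifacts (axis-aligned squares larger than a post);
* randomly missing posts (fabrication losses).  A missing post exposes the
  well floor, which reads the darker slide level (``slide_afu``), well below
  the hydrogel's baseline fluorescence (``background_afu``) — this contrast
  is what lets a missing target post be recognized downstream by its strongly
  negative control-subtracted signal;
* spatial expression fields given as labeled polygons (tumor regions, normal
  adjacent tissue) with per-probe areal densities.

Negative-control and blank posts always receive a true amount of zero.
Generation is bit-identical for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, box as shapely_box

from .geometry import ArrayLayout, PlexEntry, PlexMap, expected_amount_per_well

__all__ = [
    "Region",
    "DustModel",
    "SyntheticScenario",
    "GroundTruth",
    "render_array_image",
    "generate_calibration_series",
    "generate_null_scenario",
    "generate_serial_sections",
    "demo_plex",
    "demo_scenario",
    "CalibrationImage",
]


@dataclass(frozen=True)
class Region:
    """A labeled tissue region with per-probe areal densities (amol/mm²)."""

    label: str
    polygon: tuple[tuple[float, float], ...]
    amounts: Mapping[str, float]

    def shapely(self) -> Polygon:
        poly = Polygon(self.polygon)
        if not poly.is_valid:
            raise ValueError(f"region {self.label!r} polygon is not simple/valid")
        return poly


@dataclass(frozen=True)
class DustModel:
    """Bright square artifacts: how many, how large (µm), how bright (AFU)."""

    count: int = 0
    side_um: tuple[float, float] = (60.0, 120.0)
    intensity_afu: tuple[float, float] = (40000.0, 60000.0)

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("dust count must be >= 0")
        for name, (lo, hi) in (
            ("side_um", self.side_um),
            ("intensity_afu", self.intensity_afu),
        ):
            if not (0 < lo <= hi):
                raise ValueError(f"dust {name} range must satisfy 0 < lo <= hi")


@dataclass(frozen=True)
class SyntheticScenario:
    """Complete description of one synthetic assay condition."""

    layout: ArrayLayout
    plex: PlexMap
    regions: tuple[Region, ...] = ()
    gain_afu_per_amol: float = 1000.0
    background_afu: float = 1500.0
    slide_afu: float = 100.0
    pixel_noise_sd_afu: float = 50.0
    saturation_afu: float = 65535.0
    dust: DustModel = field(default_factory=DustModel)
    missing_post_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gain_afu_per_amol < 0 or self.background_afu < 0:
            raise ValueError("gain and background must be >= 0")
        if not 0 <= self.slide_afu <= self.background_afu:
            raise ValueError("slide_afu must be in [0, background_afu]")
        if not 0.0 <= self.missing_post_prob <= 1.0:
            raise ValueError("missing_post_prob must be in [0, 1]")
        if self.pixel_noise_sd_afu < 0:
            raise ValueError("pixel_noise_sd_afu must be >= 0")
        if self.saturation_afu <= self.background_afu:
            raise ValueError("saturation must exceed background")
        self.plex.validate_against(self.layout)


class GroundTruth(NamedTuple):
    """Per-post truth table plus the per-well region assignment.

    ``posts`` has one row per (well, post) with the true amount (amol), the
    noiseless post mean (AFU), the missing flag, probe, role and region.
    """

    posts: pd.DataFrame

    def well_amounts(self, probe: str) -> pd.DataFrame:
        sub = self.posts[self.posts["probe"] == probe]
        if sub.empty:
            raise KeyError(probe)
        return sub[["well_row", "well_col", "amount_amol", "missing", "region"]]


def _assign_regions(
    layout: ArrayLayout, regions: Sequence[Region]
) -> dict[tuple[int, int], str | None]:
    """Region label per well by point-in-polygon on the well center.

    Overlapping polygons resolve to the first-listed region (with a warning);
    wells under no region carry no tissue.
    """
    polys = [(r.label, r.shapely()) for r in regions]
    w_um, h_um = layout.array_extent_um
    array_box = shapely_box(0, 0, w_um, h_um)
    for label, poly in polys:
        if not poly.within(array_box):
            warnings.warn(
                f"region {label!r} extends outside the array; clipped to array extent",
                stacklevel=3,
            )
    assignment: dict[tuple[int, int], str | None] = {}
    warned_overlap = False
    for r in range(layout.n_well_rows):
        for c in range(layout.n_well_cols):
            center = Point(*layout.well_center_um(r, c))
            hits = [label for label, poly in polys if poly.contains(center)]
            if len(hits) > 1 and not warned_overlap:
                warnings.warn(
                    f"well ({r}, {c}) center lies in {len(hits)} regions; "
                    "assigned to the first listed",
                    stacklevel=3,
                )
                warned_overlap = True
            assignment[(r, c)] = hits[0] if hits else None
    return assignment


def render_array_image(
    scenario: SyntheticScenario, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, GroundTruth]:
    """Render one array image and its ground truth.

    Returns a float64 image in AFU (convert with
    :func:`nanowell.pipeline.write_image` for a 16-bit TIFF) and the truth
    table.  Present posts are drawn at their noiseless mean plus independent
    pixel noise; missing posts are left at the slide level (the well floor);
    dust squares overwrite whatever lies beneath them.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    layout = scenario.layout
    px = layout.pixel_size_um
    w_um, h_um = layout.array_extent_um
    width = int(round(w_um / px))
    height = int(round(h_um / px))
    image = np.full((height, width), scenario.slide_afu, dtype=np.float64)

    region_amounts = {r.label: r.amounts for r in scenario.regions}
    assignment = _assign_regions(layout, scenario.regions)

    rows: list[dict] = []
    side_px = layout.post_side_px
    for wr in range(layout.n_well_rows):
        for wc in range(layout.n_well_cols):
            region = assignment[(wr, wc)]
            densities = region_amounts.get(region, {}) if region else {}
            for (pr, pc), entry in sorted(scenario.plex.entries.items()):
                if entry.role == "target" and entry.probe in densities:
                    amount = expected_amount_per_well(densities[entry.probe], layout)
                else:
                    amount = 0.0
                mean = min(
                    scenario.background_afu + scenario.gain_afu_per_amol * amount,
                    scenario.saturation_afu,
                )
                missing = bool(rng.random() < scenario.missing_post_prob)
                x_um, y_um = layout.post_origin_um(wr, wc, pr, pc)
                x0, y0 = int(round(x_um / px)), int(round(y_um / px))
                if not missing:
                    image[y0 : y0 + side_px, x0 : x0 + side_px] = mean
                rows.append(
                    {
                        "well_row": wr,
                        "well_col": wc,
                        "post_row": pr,
                        "post_col": pc,
                        "probe": entry.probe,
                        "role": entry.role,
                        "region": region,
                        "amount_amol": amount,
                        "mean_afu": mean,
                        "missing": missing,
                    }
                )

    if scenario.pixel_noise_sd_afu > 0:
        image += rng.normal(0.0, scenario.pixel_noise_sd_afu, size=image.shape)

    for _ in range(scenario.dust.count):
        side = int(round(rng.uniform(*scenario.dust.side_um) / px))
        side = max(side, 1)
        intensity = rng.uniform(*scenario.dust.intensity_afu)
        x0 = int(rng.integers(0, max(width - side, 1)))
        y0 = int(rng.integers(0, max(height - side, 1)))
        image[y0 : y0 + side, x0 : x0 + side] = intensity

    np.clip(image, 0.0, scenario.saturation_afu, out=image)
    truth = GroundTruth(posts=pd.DataFrame(rows))
    return image, truth


class CalibrationImage(NamedTuple):
    amount_amol: float
    replicate: int
    image: np.ndarray
    truth: GroundTruth


def generate_calibration_series(
    amounts: Sequence[float],
    replicates: int,
    scenario: SyntheticScenario,
) -> list[CalibrationImage]:
    """Render a dilution series: every well spiked with the same amount.

    Emulates a calibration experiment where synthetic targets are added to
    all wells at known per-well amounts (amol).  One image per amount per
    replicate; seeds derive deterministically from ``scenario.seed``.
    """
    amounts = list(amounts)
    if not amounts:
        raise ValueError("amounts must be non-empty")
    if any(a < 0 for a in amounts):
        raise ValueError("amounts must be >= 0")
    if 0.0 not in amounts:
        raise ValueError("amounts must include 0 (blank)")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")

    layout = scenario.layout
    w_um, h_um = layout.array_extent_um
    footprint_mm2 = (layout.well_side_um / 1000.0) ** 2
    images: list[CalibrationImage] = []
    streams = np.random.SeedSequence(scenario.seed).spawn(len(amounts) * replicates)
    i = 0
    for amount in amounts:
        density = amount / footprint_mm2  # so captured amount == `amount`
        region = Region(
            label="spike",
            polygon=((0, 0), (w_um, 0), (w_um, h_um), (0, h_um)),
            amounts={p: density for p in scenario.plex.target_probes},
        )
        cal_scenario = dataclasses.replace(scenario, regions=(region,))
        for rep in range(replicates):
            rng = np.random.default_rng(streams[i])
            i += 1
            image, truth = render_array_image(cal_scenario, rng=rng)
            images.append(CalibrationImage(amount, rep, image, truth))
    return images


def generate_null_scenario(base: SyntheticScenario) -> SyntheticScenario:
    """Equalize all regions to the first region's densities.

    Under the null every region shares the same expression field, so any
    region comparison downstream should reject only at its nominal rate.
    """
    if not base.regions:
        return base
    ref = base.regions[0].amounts
    regions = tuple(dataclasses.replace(r, amounts=dict(ref)) for r in base.regions)
    return dataclasses.replace(base, regions=regions)


def generate_serial_sections(
    scenario: SyntheticScenario,
    n_sections: int,
    section_cv: float,
    render: bool = True,
) -> list[tuple[np.ndarray | None, GroundTruth]]:
    """Emulate serial tissue sections with section-to-section variability.

    Each section multiplies every region density by one independent positive
    factor with unit mean and coefficient of variation ``section_cv`` (gamma
    distributed), emulating the biological and assay variability between
    adjacent 5 µm sections of the same block.  With ``render=False`` only the
    truth tables are produced (image is ``None``), which is sufficient for
    studying the statistics of section-level summaries.
    """
    if n_sections < 2:
        raise ValueError("n_sections must be >= 2")
    if section_cv < 0:
        raise ValueError("section_cv must be >= 0")
    master = np.random.default_rng(scenario.seed)
    if section_cv > 0:
        shape = 1.0 / section_cv**2
        factors = master.gamma(shape, scale=1.0 / shape, size=n_sections)
    else:
        factors = np.ones(n_sections)
    streams = np.random.SeedSequence(scenario.seed).spawn(n_sections)
    out: list[tuple[np.ndarray | None, GroundTruth]] = []
    for s in range(n_sections):
        regions = tuple(
            dataclasses.replace(
                r, amounts={p: d * factors[s] for p, d in r.amounts.items()}
            )
            for r in scenario.regions
        )
        section = dataclasses.replace(scenario, regions=regions)
        rng = np.random.default_rng(streams[s])
        if render:
            image, truth = render_array_image(section, rng=rng)
        else:
            image = None
            _, truth = render_array_image(
                dataclasses.replace(section, pixel_noise_sd_afu=0.0,
                                    dust=DustModel(count=0)),
                rng=rng,
            )
        out.append((image, truth))
    return out


# -- packaged demo ------------------------------------------------------------


def demo_plex() -> PlexMap:
    """The 9-post plex used throughout the examples.

    Seven target miRNAs, one off-target negative control (cel-miR-54, a
    C. elegans miRNA absent from mouse tissue) and one blank post.
    """
    probes = [
        ("miR-21", "target"),
        ("let-7a", "target"),
        ("miR-16", "target"),
        ("miR-19b", "target"),
        ("miR-210", "target"),
        ("miR-20a", "target"),
        ("miR-15b", "target"),
        ("cel-miR-54", "negative_control"),
        ("blank", "blank"),
    ]
    entries = {
        (i // 3, i % 3): PlexEntry(probe=p, role=r) for i, (p, r) in enumerate(probes)
    }
    return PlexMap(entries=entries)


def demo_scenario(
    n_well_rows: int = 12,
    n_well_cols: int = 14,
    seed: int = 7,
    **overrides,
) -> SyntheticScenario:
    """A tumor/NAT tissue scenario on a modest array.

    Two tumor nodules with elevated miR-21/miR-19b sit inside a larger patch
    of normal adjacent tissue (NAT).  Densities are on the scale of a few
    amol/mm², matching the expected tissue loading of abundant miRNAs.
    """
    layout = ArrayLayout(n_well_rows=n_well_rows, n_well_cols=n_well_cols)
    w_um, h_um = layout.array_extent_um

    def rect(x0, y0, x1, y1):
        return ((x0, y0), (x1, y0), (x1, y1), (x0, y1))

    base = {"miR-21": 5.0, "let-7a": 4.0, "miR-16": 6.0, "miR-19b": 2.0,
            "miR-210": 1.0, "miR-20a": 1.5, "miR-15b": 2.5}
    tumor1 = {**base, "miR-21": 15.0, "let-7a": 8.0, "miR-19b": 4.0}
    tumor2 = {**base, "miR-21": 25.0, "let-7a": 8.0, "miR-19b": 10.0}
    # Tumor polygons are listed first so they win the overlap with NAT.
    regions = (
        Region("Tumor 1", rect(0.18 * w_um, 0.15 * h_um, 0.45 * w_um, 0.5 * h_um),
               tumor1),
        Region("Tumor 2", rect(0.55 * w_um, 0.45 * h_um, 0.9 * w_um, 0.85 * h_um),
               tumor2),
        Region("NAT", rect(0.05 * w_um, 0.05 * h_um, 0.95 * w_um, 0.95 * h_um), base),
    )
    params = dict(
        layout=layout,
        plex=demo_plex(),
        regions=regions,
        gain_afu_per_amol=1000.0,
        background_afu=1500.0,
        slide_afu=100.0,
        pixel_noise_sd_afu=50.0,
        saturation_afu=65535.0,
        dust=DustModel(count=4),
        missing_post_prob=0.005,
        seed=seed,
    )
    params.update(overrides)
    return SyntheticScenario(**params)
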