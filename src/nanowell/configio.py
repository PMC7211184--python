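"""YAML configuration for layouts, plex maps and synthetic scenarios.

One structured document describes a run.  Sections:

``layout``
    Physical geometry; keys mirror :class:`ArrayLayout` fields.  Defaults are
    the fabricated device (300 µm wells, 50 µm spacing, 39 µm depth, 3×3 grid
    of 40 µm posts at 100 µm pitch, 5 µm pixels).
``plex``
    ``control`` names the subtraction control; ``posts`` lists
    ``{row, col, probe, role}`` for every post position.
``scenario``
    Synthetic-generation parameters: signal model (gain, background,
    saturation), pixel noise, dust, missing-post probability, seed, and
    ``regions`` (label, polygon in µm, per-probe areal densities in amol/mm²).
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import yaml

from .geometry import ArrayLayout, PlexEntry, PlexMap
from .synthetic import DustModel, Region, SyntheticScenario

__all__ = [
    "load_config",
    "layout_from_dict",
    "plex_from_dict",
    "scenario_from_dict",
    "scenario_to_dict",
    "save_scenario",
]


def load_config(path: str | Path) -> dict[str, Any]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def layout_from_dict(cfg: dict[str, Any] | None) -> ArrayLayout:
    return ArrayLayout(**(cfg or {}))


def plex_from_dict(cfg: dict[str, Any]) -> PlexMap:
    entries = {
        (int(p["row"]), int(p["col"])): PlexEntry(probe=p["probe"], role=p["role"])
        for p in cfg["posts"]
    }
    return PlexMap(entries=entries, control_probe=cfg.get("control"))


def scenario_from_dict(cfg: dict[str, Any]) -> SyntheticScenario:
    layout = layout_from_dict(cfg.get("layout"))
    plex = plex_from_dict(cfg["plex"])
    sc = dict(cfg.get("scenario", {}))
    regions = tuple(
        Region(
            label=r["label"],
            polygon=tuple((float(x), float(y)) for x, y in r["polygon"]),
            amounts={k: float(v) for k, v in r.get("amounts", {}).items()},
        )
        for r in sc.pop("regions", [])
    )
    dust_cfg = sc.pop("dust", None)
    dust = (
        DustModel(
            count=int(dust_cfg.get("count", 0)),
            side_um=tuple(dust_cfg.get("side_um", (60.0, 120.0))),
            intensity_afu=tuple(dust_cfg.get("intensity_afu", (40000.0, 60000.0))),
        )
        if dust_cfg
        else DustModel()
    )
    return SyntheticScenario(layout=layout, plex=plex, regions=regions, dust=dust, **sc)


def scenario_to_dict(scenario: SyntheticScenario) -> dict[str, Any]:
    layout = scenario.layout
    return {
        "layout": {
            f: getattr(layout, f) for f in layout.__dataclass_fields__  # type: ignore[attr-defined]
        },
        "plex": {
            "control": scenario.plex.control_probe,
            "posts": [
                {"row": r, "col": c, "probe": e.probe, "role": e.role}
                for (r, c), e in sorted(scenario.plex.entries.items())
            ],
        },
        "scenario": {
            "gain_afu_per_amol": scenario.gain_afu_per_amol,
            "background_afu": scenario.background_afu,
            "slide_afu": scenario.slide_afu,
            "pixel_noise_sd_afu": scenario.pixel_noise_sd_afu,
            "saturation_afu": scenario.saturation_afu,
            "missing_post_prob": scenario.missing_post_prob,
            "seed": scenario.seed,
            "dust": {
                "count": scenario.dust.count,
                "side_um": list(scenario.dust.side_um),
                "intensity_afu": list(scenario.dust.intensity_afu),
            },
            "regions": [
                {
                    "label": r.label,
                    "polygon": [list(p) for p in r.polygon],
                    "amounts": dict(r.amounts),
                }
                for r in scenario.regions
            ],
        },
    }


def save_scenario(scenario: SyntheticScenario, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(scenario), fh, sort_keys=False)
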