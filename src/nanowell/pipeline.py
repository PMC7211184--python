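"""End-to-end runs: simulate, quantify, calibrate, report.

These functions chain the module-level operations in the fixed assay order —
dust removal → grid registration → post extraction → (optional) analysis
window → control subtraction → missing-post filter — write their outputs as
CSV/TIFF/PNG under an output directory, and record a manifest (config
snapshot, seed, file checksums) sufficient to reproduce deterministic stages
bit for bit.  Every removal or flag is counted in the returned summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .configio import scenario_to_dict
from .geometry import ArrayLayout, PlexMap
from .imaging import Anchor, extract_post_means, register_grid, remove_dust, select_window
from .qc import QcConfig, flag_missing_posts, tukey_hsd
from .quantify import CalibrationCurve, apply_calibration, fit_calibration, net_signal
from .spatial import RegionMask, assign_wells_to_regions, build_heatmap, region_summary
from .synthetic import SyntheticScenario, generate_calibration_series, render_array_image

logger = logging.getLogger("nanowell")

__all__ = [
    "RunConfig",
    "write_image",
    "read_image",
    "truth_anchors",
    "run_simulate",
    "run_quantify",
    "run_calibrate",
    "run_report",
    "curves_to_csv",
    "curves_from_csv",
]


@dataclass
class RunConfig:
    """Paths and knobs shared by the pipeline stages."""

    out_dir: Path
    anchors: tuple[Anchor, Anchor] | None = None
    qc: QcConfig = field(default_factory=QcConfig)
    dust_threshold_afu: float | None = 30000.0
    window: tuple[int, int] | None = None
    seed: int = 0


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Save an AFU image as 16-bit grayscale TIFF (rounded, clipped)."""
    data = np.clip(np.round(image), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), data)


def read_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.float64)


def truth_anchors(layout: ArrayLayout, wells: tuple[tuple[int, int], tuple[int, int]] | None = None) -> tuple[Anchor, Anchor]:
    """Anchors at the true post positions of two wells of a synthetic render.

    Default wells: the array's first and last well, maximizing the baseline
    for pitch inference.
    """
    if wells is None:
        wells = ((0, 0), (layout.n_well_rows - 1, layout.n_well_cols - 1))
    anchors = []
    for r, c in wells:
        x_um, y_um = layout.post_origin_um(r, c, 0, 0)
        px = layout.pixel_size_um
        anchors.append(Anchor(well_index=(r, c),
                              pixel=(round(x_um / px), round(y_um / px))))
    return anchors[0], anchors[1]


def _manifest(out_dir: Path, extra: dict) -> None:
    files = sorted(p for p in out_dir.rglob("*") if p.is_file() and p.name != "manifest.json")
    entry = {
        "nanowell_version": __version__,
        **extra,
        "files": {
            str(p.relative_to(out_dir)): hashlib.sha256(p.read_bytes()).hexdigest()
            for p in files
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(entry, indent=2, sort_keys=True))


def run_simulate(scenario: SyntheticScenario, out_dir: str | Path) -> dict:
    """Render one scenario to disk: TIFF image, truth CSV, manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    image, truth = render_array_image(scenario)
    write_image(image, out / "array.tiff")
    truth.posts.to_csv(out / "truth_posts.csv", index=False)
    _manifest(out, {"seed": scenario.seed, "scenario": scenario_to_dict(scenario)})
    logger.info("simulated %d wells -> %s", scenario.layout.n_well_rows
                * scenario.layout.n_well_cols, out)
    return {"image": out / "array.tiff", "truth": out / "truth_posts.csv"}


def run_quantify(
    image: np.ndarray,
    layout: ArrayLayout,
    plex: PlexMap,
    config: RunConfig,
    out_dir: str | Path | None = None,
) -> dict:
    """Image → post means → net signals, with stage-level accounting.

    Returns the post measurement table, the well quantification after the
    missing-post filter, and counts of everything removed or flagged.
    """
    if config.anchors is None:
        raise ValueError("registration anchors are required")
    if plex.control_probe is None:
        raise ValueError("plex map designates no negative-control probe")
    counts: dict[str, int] = {}
    if config.dust_threshold_afu is not None:
        image, removed = remove_dust(image, config.dust_threshold_afu, layout)
        counts["dust_components_removed"] = len(removed)
        logger.info("dust removal: %d components", len(removed))
    grid = register_grid(config.anchors[0], config.anchors[1], layout)
    table = extract_post_means(image, grid, plex)
    counts["posts_extracted"] = len(table)
    counts["posts_out_of_frame"] = int((table["flags"] == "out_of_frame").sum())
    if config.window is not None:
        table = select_window(table, *config.window)
        counts["posts_in_window"] = len(table)
    wq = net_signal(table, plex.control_probe)
    wq, flagged = flag_missing_posts(wq, config.qc)
    counts["missing_posts_flagged"] = len(flagged)
    logger.info("missing-post filter: %d data points removed (< %g AFU)",
                len(flagged), config.qc.missing_post_threshold_afu)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "post_means.csv", index=False)
        wq.to_csv(out / "well_quantification.csv", index=False)
        flagged.to_csv(out / "flagged_missing_posts.csv", index=False)
        (out / "quantify_counts.json").write_text(json.dumps(counts, indent=2))
    return {"post_means": table, "wells": wq, "flagged": flagged, "counts": counts}


def run_calibrate(
    amounts: list[float],
    replicates: int,
    scenario: SyntheticScenario,
    config: RunConfig,
    window: tuple[int, int] | None = None,
) -> dict[str, CalibrationCurve]:
    """Simulate a dilution series and fit per-probe calibration curves.

    Each (amount, replicate) image is quantified with the standard pipeline;
    each calibration point is the mean net signal over the wells of the
    analysis window, mirroring a calibration experiment where every data
    point summarizes one array.
    """
    series = generate_calibration_series(amounts, replicates, scenario)
    layout, plex = scenario.layout, scenario.plex
    anchors = truth_anchors(layout)
    cfg = RunConfig(out_dir=config.out_dir, anchors=anchors, qc=config.qc,
                    dust_threshold_afu=config.dust_threshold_afu, window=window)
    records: dict[str, list[tuple[float, float]]] = {p: [] for p in plex.target_probes}
    for cal in series:
        res = run_quantify(cal.image, layout, plex, cfg)
        wells = res["wells"]
        for probe in plex.target_probes:
            nets = wells.loc[wells["probe"] == probe, "net_afu"].dropna()
            if len(nets):
                records[probe].append((cal.amount_amol, float(nets.mean())))
    curves = {}
    for probe, pts in records.items():
        a = np.array([x for x, _ in pts])
        n = np.array([y for _, y in pts])
        curves[probe] = fit_calibration(a, n, probe=probe)
    return curves


def curves_to_csv(curves: dict[str, CalibrationCurve], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "probe": c.probe,
                "slope": c.slope,
                "intercept": c.intercept,
                "residual_sd": c.residual_sd,
                "blank_sd": c.blank_sd,
                "lod_amol": c.lod_amol,
                "n_points": c.n_points,
            }
            for c in curves.values()
        ]
    ).to_csv(path, index=False)


def curves_from_csv(path: str | Path) -> dict[str, CalibrationCurve]:
    df = pd.read_csv(path)
    return {
        r.probe: CalibrationCurve(
            probe=r.probe, slope=r.slope, intercept=r.intercept,
            residual_sd=r.residual_sd, blank_sd=r.blank_sd,
            lod_amol=r.lod_amol, n_points=int(r.n_points),
        )
        for r in df.itertuples(index=False)
    }


def run_report(
    wq: pd.DataFrame,
    layout: ArrayLayout,
    out_dir: str | Path,
    mask: RegionMask | None = None,
    curves: dict[str, CalibrationCurve] | None = None,
    qc: QcConfig = QcConfig(),
    value_col: str | None = None,
) -> dict:
    """Heatmaps, region statistics and pairwise tests from quantified wells.

    With calibration curves, wells are converted to attomoles and heatmaps
    show amounts; otherwise they show net AFU.  With a region mask, per-region
    summaries and Tukey HSD tables (with star labels) are produced per probe.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if curves:
        wq = apply_calibration(wq, curves)
    if value_col is None:
        value_col = "amount_amol" if curves else "net_afu"
    probes = sorted(wq["probe"].unique())

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    heatmaps = {}
    for probe in probes:
        hm = build_heatmap(wq, probe, layout, value_col=value_col)
        heatmaps[probe] = hm
        safe = probe.replace("/", "_")
        np.savetxt(out / f"heatmap_{safe}.csv", hm.values, delimiter=",")
        fig, ax = plt.subplots(figsize=(4, 4))
        im = ax.imshow(hm.values, cmap="viridis")
        ax.set_title(f"{probe} ({'amol/well' if value_col == 'amount_amol' else 'net AFU'})")
        fig.colorbar(im, ax=ax, shrink=0.8)
        fig.savefig(out / f"heatmap_{safe}.png", dpi=120, bbox_inches="tight")
        plt.close(fig)

    results: dict = {"heatmaps": heatmaps}
    if mask is not None:
        assignment = assign_wells_to_regions(layout, mask)
        summaries, tukey_tables = {}, {}
        for probe in probes:
            summ = region_summary(wq, assignment, probe, value_col=value_col)
            summaries[probe] = summ
            summ.drop(columns="values").to_csv(
                out / f"region_summary_{probe.replace('/', '_')}.csv", index=False
            )
            if len(summ) >= 2 and (summ["n"] >= 2).all():
                groups = {r.region: r.values for r in summ.itertuples(index=False)}
                tk = tukey_hsd(groups, alpha=qc.tukey_alpha)
                tukey_tables[probe] = tk
                tk.to_csv(out / f"tukey_{probe.replace('/', '_')}.csv", index=False)
        results["assignment"] = assignment
        results["summaries"] = summaries
        results["tukey"] = tukey_tables
    return results
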