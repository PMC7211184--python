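"""Raw array image → per-post mean-intensity table.

The slide scanner produces a 16-bit grayscale TIFF of the whole array.  Four
steps turn it into a tidy measurement table:

1. :func:`remove_dust` — bright connected components larger than a post are
   set to the background level (dust and fibers deposited on the array);
2. :func:`register_grid` — an axis-aligned grid model is fit from two anchor
   wells (the pixel of the upper-left corner of each well's upper-left post),
   giving a pixel box for every post of every well;
3. :func:`extract_post_means` — the mean intensity over each box;
4. :func:`select_window` — optionally restrict to a centered block of wells
   to avoid array edges and cracks.

Pixel coordinates are 0-based with x = column and y = row, origin at the
image's top-left; boxes are half-open ``[x0, x0+w) × [y0, y0+h)``.  The grid
model has no rotation term: the two anchors determine per-axis pitch and
offset only, so visibly rotated slides are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label

from .geometry import ArrayLayout, PlexMap

__all__ = [
    "Anchor",
    "PostGrid",
    "remove_dust",
    "register_grid",
    "extract_post_means",
    "select_window",
]


@dataclass(frozen=True)
class Anchor:
    """A registration landmark.

    ``pixel`` is the (x, y) of the upper-left corner of the upper-left post
    of well ``well_index = (row, col)``.
    """

    well_index: tuple[int, int]
    pixel: tuple[float, float]


@dataclass(frozen=True)
class PostGrid:
    """Pixel boxes for every (well, post) position.

    ``boxes`` has columns well_row, well_col, post_row, post_col, x0, y0,
    width, height.  Boxes may extend beyond a particular image; extraction
    flags those rows as out-of-frame rather than failing.
    """

    boxes: pd.DataFrame
    pitch_x_px: float
    pitch_y_px: float


def remove_dust(
    image: np.ndarray, intensity_threshold_afu: float, layout: ArrayLayout
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Replace bright connected areas larger than a post with background.

    Connected components (8-connectivity) of pixels strictly above the
    threshold whose pixel count exceeds the post footprint are set to the
    background level, defined as the median of all pixels at or below the
    threshold.  Posts themselves occupy exactly the footprint, so they are
    never removed.  Returns the cleaned image and the removed components as
    ``(N, 2)`` arrays of (row, col) pixel indices.
    """
    if intensity_threshold_afu <= 0:
        raise ValueError("intensity threshold must be > 0")
    below = image <= intensity_threshold_afu
    if not below.any():
        raise ValueError(
            "entire image is above the dust threshold; background undefined"
        )
    labels = cc_label(image > intensity_threshold_afu, connectivity=2)
    background = float(np.median(image[below]))
    cleaned = image.copy()
    removed: list[np.ndarray] = []
    if labels.max() == 0:
        return cleaned, removed
    sizes = np.bincount(labels.ravel())
    cutoff = layout.post_footprint_px
    for comp in np.flatnonzero(sizes > cutoff):
        if comp == 0:
            continue
        mask = labels == comp
        cleaned[mask] = background
        removed.append(np.argwhere(mask))
    return cleaned, removed


def register_grid(
    anchor_a: Anchor, anchor_b: Anchor, layout: ArrayLayout
) -> PostGrid:
    """Fit the axis-aligned post grid from two anchor wells.

    Per axis, the well pitch in pixels is the anchor displacement divided by
    the well-index offset; where the anchors share a row (or column) the
    nominal pitch ``well_pitch_um / pixel_size_um`` is used for that axis.
    Post boxes are placed at the anchor plus whole-well offsets plus the
    within-well post offsets from the layout.
    """
    (ra, ca), (xa, ya) = anchor_a.well_index, anchor_a.pixel
    (rb, cb), (xb, yb) = anchor_b.well_index, anchor_b.pixel
    if (ra, ca) == (rb, cb):
        raise ValueError("anchors must name distinct wells")
    nominal = layout.well_pitch_um / layout.pixel_size_um
    if cb != ca:
        pitch_x = (xb - xa) / (cb - ca)
    else:
        if xb != xa:
            raise ValueError(
                "anchors share a well column but differ in x; grid model is "
                "axis-aligned"
            )
        pitch_x = nominal
    if rb != ra:
        pitch_y = (yb - ya) / (rb - ra)
    else:
        if yb != ya:
            raise ValueError(
                "anchors share a well row but differ in y; grid model is "
                "axis-aligned"
            )
        pitch_y = nominal
    if pitch_x <= 0 or pitch_y <= 0:
        raise ValueError(f"non-positive inferred pitch ({pitch_x}, {pitch_y})")
    for name, pitch in (("x", pitch_x), ("y", pitch_y)):
        if abs(pitch - nominal) / nominal > 0.10:
            warnings.warn(
                f"inferred {name}-pitch {pitch:.2f} px deviates >10% from the "
                f"nominal {nominal:.2f} px",
                stacklevel=2,
            )

    px = layout.pixel_size_um
    side = layout.post_side_px
    post_pitch_px = layout.post_pitch_um / px
    rows = []
    for wr in range(layout.n_well_rows):
        for wc in range(layout.n_well_cols):
            bx = xa + (wc - ca) * pitch_x
            by = ya + (wr - ra) * pitch_y
            for pr in range(layout.post_grid_rows):
                for pc in range(layout.post_grid_cols):
                    rows.append(
                        {
                            "well_row": wr,
                            "well_col": wc,
                            "post_row": pr,
                            "post_col": pc,
                            "x0": int(round(bx + pc * post_pitch_px)),
                            "y0": int(round(by + pr * post_pitch_px)),
                            "width": side,
                            "height": side,
                        }
                    )
    return PostGrid(boxes=pd.DataFrame(rows), pitch_x_px=pitch_x, pitch_y_px=pitch_y)


def extract_post_means(
    image: np.ndarray, grid: PostGrid, plex: PlexMap
) -> pd.DataFrame:
    """Mean intensity of every post box.

    Returns one row per (well, post): well/post indices, probe, role, mean
    AFU over the box, pixel count and flags.  Boxes not fully inside the
    image are flagged ``out_of_frame`` with an undefined mean.
    """
    if grid.boxes.empty:
        raise ValueError("empty post grid")
    h, w = image.shape
    rows = []
    for rec in grid.boxes.itertuples(index=False):
        entry = plex.entries[(rec.post_row, rec.post_col)]
        x0, y0 = rec.x0, rec.y0
        x1, y1 = x0 + rec.width, y0 + rec.height
        if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
            mean, n_pixels, flags = np.nan, 0, "out_of_frame"
        else:
            patch = image[y0:y1, x0:x1]
            mean, n_pixels, flags = float(patch.mean()), patch.size, ""
        rows.append(
            {
                "well_row": rec.well_row,
                "well_col": rec.well_col,
                "post_row": rec.post_row,
                "post_col": rec.post_col,
                "probe": entry.probe,
                "role": entry.role,
                "mean_afu": mean,
                "n_pixels": n_pixels,
                "flags": flags,
            }
        )
    return pd.DataFrame(rows)


def select_window(table: pd.DataFrame, rows: int = 9, cols: int = 11) -> pd.DataFrame:
    """Restrict the table to a centered ``rows × cols`` block of wells.

    The analysis window avoids array edges and cracks; centering uses the
    integer floor of the margin on each axis.
    """
    if rows < 1 or cols < 1:
        raise ValueError("window dimensions must be >= 1")
    rmin, rmax = int(table["well_row"].min()), int(table["well_row"].max())
    cmin, cmax = int(table["well_col"].min()), int(table["well_col"].max())
    n_rows = rmax - rmin + 1
    n_cols = cmax - cmin + 1
    if rows > n_rows or cols > n_cols:
        raise ValueError(
            f"window {rows}x{cols} larger than the {n_rows}x{n_cols} well grid"
        )
    r0 = rmin + (n_rows - rows) // 2
    c0 = cmin + (n_cols - cols) // 2
    keep = (
        (table["well_row"] >= r0)
        & (table["well_row"] < r0 + rows)
        & (table["well_col"] >= c0)
        & (table["well_col"] < c0 + cols)
    )
    return table[keep].reset_index(drop=True)
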