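"""Image pipeline: dust removal, two-anchor registration, extraction, window."""

from collections import deque

import numpy as np
import pandas as pd
import pytest

from nanowell import (
    Anchor,
    ArrayLayout,
    extract_post_means,
    register_grid,
    remove_dust,
    render_array_image,
    select_window,
)
from nanowell.imaging import PostGrid

from conftest import make_scenario


def flood_fill_clean(image, threshold, footprint_px):
    """Brute-force oracle: BFS connected components (8-neighborhood) of
    above-threshold pixels; those larger than the post footprint are set to
    the median of at-or-below-threshold pixels."""
    h, w = image.shape
    above = image > threshold
    background = np.median(image[~above])
    seen = np.zeros_like(above, dtype=bool)
    out = image.copy()
    for sy in range(h):
        for sx in range(w):
            if not above[sy, sx] or seen[sy, sx]:
                continue
            comp = []
            queue = deque([(sy, sx)])
            seen[sy, sx] = True
            while queue:
                y, x = queue.popleft()
                comp.append((y, x))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = y + dy, x + dx
                        if (0 <= ny < h and 0 <= nx < w and above[ny, nx]
                                and not seen[ny, nx]):
                            seen[ny, nx] = True
                            queue.append((ny, nx))
            if len(comp) > footprint_px:
                for y, x in comp:
                    out[y, x] = background
    return out


class TestRemoveDust:
    def setup_method(self):
        self.layout = ArrayLayout()  # post footprint 8x8 px = 64 px

    def test_large_blob_replaced_by_background(self):
        image = np.full((50, 50), 100.0)
        image[10:22, 10:22] = 60000.0  # 12x12 blob > 64 px footprint
        cleaned, removed = remove_dust(image, 30000.0, self.layout)
        assert len(removed) == 1
        assert np.all(cleaned == 100.0)

    def test_post_sized_blob_preserved(self):
        image = np.full((50, 50), 100.0)
        image[10:16, 10:16] = 60000.0  # 6x6 = 36 px <= footprint
        cleaned, removed = remove_dust(image, 30000.0, self.layout)
        assert removed == []
        assert np.array_equal(cleaned, image)

    def test_matches_flood_fill_oracle_on_random_images(self, rng):
        threshold = 30000.0
        for _ in range(10):
            image = rng.uniform(0, 5000, size=(120, 120))
            for _ in range(rng.integers(1, 5)):
                side = int(rng.integers(3, 20))
                y, x = rng.integers(0, 120 - side, size=2)
                image[y : y + side, x : x + side] = rng.uniform(40000, 60000)
            cleaned, _ = remove_dust(image, threshold, self.layout)
            oracle = flood_fill_clean(image, threshold, self.layout.post_footprint_px)
            assert np.array_equal(cleaned, oracle)

    def test_idempotent_and_local(self, rng):
        image = rng.uniform(0, 5000, size=(100, 100))
        image[20:40, 20:40] = 50000.0
        cleaned, removed = remove_dust(image, 30000.0, self.layout)
        mask = np.zeros_like(image, dtype=bool)
        for comp in removed:
            mask[comp[:, 0], comp[:, 1]] = True
        assert np.array_equal(cleaned[~mask], image[~mask])
        again, removed2 = remove_dust(cleaned, 30000.0, self.layout)
        assert removed2 == []
        assert np.array_equal(again, cleaned)

    def test_all_above_threshold_is_an_error(self):
        with pytest.raises(ValueError, match="background"):
            remove_dust(np.full((10, 10), 50000.0), 30000.0, self.layout)

    def test_dusty_render_restored_to_dust_free(self, small_layout, plex):
        from nanowell import DustModel
        import dataclasses
        sc = make_scenario(small_layout, plex, {"miR-21": 5.0})
        dusty = dataclasses.replace(
            sc, dust=DustModel(count=3, side_um=(80, 150),
                               intensity_afu=(40000, 60000)))
        img_clean, _ = render_array_image(sc)
        img_dusty, _ = render_array_image(dusty)
        cleaned, removed = remove_dust(img_dusty, 30000.0, small_layout)
        assert len(removed) >= 1
        # every post pixel is restored to its dust-free value unless the
        # blob landed on it (then it reads the background level)
        diff = cleaned != img_clean
        assert np.all(np.unique(cleaned[diff]) == np.median(img_clean))


class TestRegisterGrid:
    def test_pitch_arithmetic_from_two_anchors(self, layout):
        a = Anchor(well_index=(0, 0), pixel=(100, 100))
        b = Anchor(well_index=(0, 10), pixel=(800, 100))
        grid = register_grid(a, b, layout)
        assert grid.pitch_x_px == pytest.approx(70.0)
        assert grid.pitch_y_px == pytest.approx(70.0)  # nominal fallback
        box = grid.boxes.query(
            "well_row == 0 and well_col == 0 and post_row == 0 and post_col == 0"
        ).iloc[0]
        assert (box.x0, box.y0) == (100, 100)
        assert (box.width, box.height) == (8, 8)

    def test_boxes_match_generator_truth(self, small_layout, plex):
        sc = make_scenario(small_layout, plex, {"miR-21": 5.0})
        px = small_layout.pixel_size_um
        anchors = []
        for (r, c) in [(0, 0), (5, 5)]:
            x_um, y_um = small_layout.post_origin_um(r, c, 0, 0)
            anchors.append(Anchor((r, c), (x_um / px, y_um / px)))
        grid = register_grid(anchors[0], anchors[1], small_layout)
        for rec in grid.boxes.itertuples(index=False):
            x_um, y_um = small_layout.post_origin_um(
                rec.well_row, rec.well_col, rec.post_row, rec.post_col)
            assert rec.x0 == int(round(x_um / px))
            assert rec.y0 == int(round(y_um / px))

    def test_identical_wells_rejected(self, layout):
        a = Anchor((0, 0), (10, 10))
        with pytest.raises(ValueError, match="distinct"):
            register_grid(a, Anchor((0, 0), (50, 50)), layout)

    def test_negative_pitch_rejected(self, layout):
        a = Anchor((0, 0), (800, 100))
        b = Anchor((0, 10), (100, 100))
        with pytest.raises(ValueError, match="pitch"):
            register_grid(a, b, layout)

    def test_pitch_deviation_warns(self, layout):
        a = Anchor((0, 0), (0, 0))
        b = Anchor((0, 10), (900, 0))  # 90 px vs nominal 70 px
        with pytest.warns(UserWarning, match="deviates"):
            register_grid(a, b, layout)

    def test_axis_misalignment_rejected(self, layout):
        a = Anchor((0, 0), (100, 100))
        b = Anchor((0, 10), (800, 130))  # same well row, y shifted
        with pytest.raises(ValueError, match="axis-aligned"):
            register_grid(a, b, layout)


class TestExtractPostMeans:
    def test_mean_of_known_boxes(self, plex):
        image = np.zeros((20, 30))
        image[0:8, 0:8] = 500.0
        image[0:8, 10:14] = 0.0
        image[0:8, 14:18] = 1000.0
        boxes = pd.DataFrame([
            {"well_row": 0, "well_col": 0, "post_row": 0, "post_col": 0,
             "x0": 0, "y0": 0, "width": 8, "height": 8},
            {"well_row": 0, "well_col": 1, "post_row": 0, "post_col": 0,
             "x0": 10, "y0": 0, "width": 8, "height": 8},
            {"well_row": 0, "well_col": 2, "post_row": 0, "post_col": 0,
             "x0": 25, "y0": 0, "width": 8, "height": 8},  # out of frame
        ])
        grid = PostGrid(boxes=boxes, pitch_x_px=70, pitch_y_px=70)
        table = extract_post_means(image, grid, plex)
        assert table.loc[0, "mean_afu"] == 500.0
        assert table.loc[1, "mean_afu"] == 500.0  # half 0 / half 1000
        assert table.loc[2, "flags"] == "out_of_frame"
        assert np.isnan(table.loc[2, "mean_afu"])
        assert (table.loc[:1, "n_pixels"] == 64).all()

    def test_matches_direct_summation(self, rng, plex):
        image = rng.uniform(0, 1000, size=(64, 64))
        boxes = pd.DataFrame([
            {"well_row": 0, "well_col": 0, "post_row": 0, "post_col": 0,
             "x0": 3, "y0": 5, "width": 8, "height": 8},
        ])
        grid = PostGrid(boxes=boxes, pitch_x_px=70, pitch_y_px=70)
        table = extract_post_means(image, grid, plex)
        patch = image[5:13, 3:11]
        assert table.loc[0, "mean_afu"] == pytest.approx(
            patch.sum() / patch.size, rel=1e-12)

    def test_empty_grid_rejected(self, plex):
        grid = PostGrid(boxes=pd.DataFrame(), pitch_x_px=70, pitch_y_px=70)
        with pytest.raises(ValueError, match="empty"):
            extract_post_means(np.zeros((10, 10)), grid, plex)

    def test_one_row_per_post_no_duplicates(self, small_layout, plex):
        sc = make_scenario(small_layout, plex)
        image, _ = render_array_image(sc)
        px = small_layout.pixel_size_um
        a = Anchor((0, 0), tuple(v / px for v in small_layout.post_origin_um(0, 0, 0, 0)))
        b = Anchor((5, 5), tuple(v / px for v in small_layout.post_origin_um(5, 5, 0, 0)))
        table = extract_post_means(image, register_grid(a, b, small_layout), plex)
        n_posts = 36 * 9
        assert len(table) == n_posts
        keys = table[["well_row", "well_col", "post_row", "post_col"]]
        assert not keys.duplicated().any()


class TestSelectWindow:
    def _table(self, rows, cols):
        idx = [(r, c) for r in range(rows) for c in range(cols)]
        return pd.DataFrame(idx, columns=["well_row", "well_col"])

    def test_9x11_window_keeps_99_wells(self):
        out = select_window(self._table(28, 28), 9, 11)
        assert len(out) == 99
        assert out["well_row"].min() == (28 - 9) // 2
        assert out["well_col"].min() == (28 - 11) // 2

    def test_full_window_is_identity(self):
        table = self._table(6, 6)
        out = select_window(table, 6, 6)
        pd.testing.assert_frame_equal(out, table)

    def test_window_larger_than_array_rejected(self):
        with pytest.raises(ValueError, match="larger"):
            select_window(self._table(8, 20), 9, 11)
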