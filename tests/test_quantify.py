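"""Net signal, calibration fitting, LOD and fold-change utilities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanowell import (
    CalibrationCurve,
    afu_to_amol,
    apply_calibration,
    ddct_fold_change,
    estimate_lod,
    fit_calibration,
    net_signal,
    normalize_to_reference,
)


def table_from_wells(wells):
    """wells: {(r, c): {probe: (role, mean_afu)}} -> measurement table."""
    rows = []
    for (r, c), posts in wells.items():
        for i, (probe, (role, mean)) in enumerate(posts.items()):
            rows.append({"well_row": r, "well_col": c, "post_row": i // 3,
                         "post_col": i % 3, "probe": probe, "role": role,
                         "mean_afu": mean, "n_pixels": 64, "flags": ""})
    return pd.DataFrame(rows)


class TestNetSignal:
    def test_control_subtraction(self):
        table = table_from_wells({(0, 0): {
            "miR-21": ("target", 2000.0),
            "cel-miR-54": ("negative_control", 500.0),
        }})
        wq = net_signal(table, "cel-miR-54")
        assert wq.loc[0, "net_afu"] == 1500.0

    def test_target_equal_control_gives_zero(self):
        table = table_from_wells({(0, 0): {
            "miR-21": ("target", 500.0),
            "cel-miR-54": ("negative_control", 500.0),
        }})
        assert net_signal(table, "cel-miR-54").loc[0, "net_afu"] == 0.0

    def test_lost_post_yields_strongly_negative_net(self):
        # missing target post reads the slide; bright control drives net < -1000
        table = table_from_wells({(0, 0): {
            "miR-21": ("target", 0.0),
            "cel-miR-54": ("negative_control", 1500.0),
        }})
        assert net_signal(table, "cel-miR-54").loc[0, "net_afu"] == -1500.0

    def test_constant_well_offset_cancels(self):
        base = {"miR-21": ("target", 2000.0),
                "cel-miR-54": ("negative_control", 500.0)}
        shifted = {p: (r, m + 300.0) for p, (r, m) in base.items()}
        wq1 = net_signal(table_from_wells({(0, 0): base}), "cel-miR-54")
        wq2 = net_signal(table_from_wells({(0, 0): shifted}), "cel-miR-54")
        assert wq1.loc[0, "net_afu"] == wq2.loc[0, "net_afu"]

    def test_flagged_control_gives_undefined_net(self):
        table = table_from_wells({(0, 0): {
            "miR-21": ("target", 2000.0),
            "cel-miR-54": ("negative_control", 500.0),
        }})
        table.loc[table["probe"] == "cel-miR-54", "flags"] = "out_of_frame"
        wq = net_signal(table, "cel-miR-54")
        assert np.isnan(wq.loc[0, "net_afu"])
        assert wq.loc[0, "flags"] == "no_control"

    def test_unknown_control_probe_rejected(self):
        table = table_from_wells({(0, 0): {"miR-21": ("target", 2000.0)}})
        with pytest.raises(KeyError):
            net_signal(table, "cel-miR-54")


class TestFitCalibration:
    def test_noiseless_line(self):
        amounts = np.array([0.0, 0.0, 1.0, 2.0])
        with pytest.warns(UserWarning):
            # two identical blanks give blank_sd 0 -> degenerate-LOD warning
            curve = fit_calibration(amounts, 1000.0 * amounts)
        assert curve.slope == pytest.approx(1000.0)
        assert curve.intercept == pytest.approx(0.0, abs=1e-9)
        assert curve.residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_offset_moves_intercept_only(self):
        amounts = np.array([0.0, 0.0, 1.0, 2.0])
        with pytest.warns(UserWarning):
            c0 = fit_calibration(amounts, 1000.0 * amounts)
            c1 = fit_calibration(amounts, 1000.0 * amounts + 200.0)
        assert c1.slope == pytest.approx(c0.slope)
        assert c1.intercept == pytest.approx(c0.intercept + 200.0)

    def test_noisy_slope_recovery_within_3_se(self, rng):
        gain = 1000.0
        amounts = np.repeat([0.0, 0.01, 0.03, 0.1, 0.3, 1.0], 30)
        nets = gain * amounts + rng.normal(0, 20.0, amounts.size)
        curve = fit_calibration(amounts, nets)
        sxx = np.sum((amounts - amounts.mean()) ** 2)
        se = 20.0 / np.sqrt(sxx)
        assert abs(curve.slope - gain) < 3 * se

    @pytest.mark.parametrize("amounts", [[1.0, 1.0, 1.0], [0.0, 1.0], [0.1, 0.5, 1.0]])
    def test_degenerate_designs_rejected(self, amounts):
        with pytest.raises(ValueError):
            fit_calibration(amounts, [1.0] * len(amounts))


class TestLod:
    def _curve(self, slope, blank_sd):
        return CalibrationCurve("p", slope, 0.0, 0.0, blank_sd, np.nan, 10)

    def test_three_sigma_rule(self):
        assert estimate_lod(self._curve(1000.0, 10.0)) == pytest.approx(0.03)

    def test_zero_blank_sd_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert estimate_lod(self._curve(1000.0, 0.0)) == 0.0

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            estimate_lod(self._curve(0.0, 10.0))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(slope=st.floats(1, 1e5), sd=st.floats(0.01, 1e3), k=st.floats(1.5, 10))
    def test_scaling_laws(self, slope, sd, k):
        base = estimate_lod(self._curve(slope, sd))
        assert estimate_lod(self._curve(slope * k, sd)) == pytest.approx(base / k)
        assert estimate_lod(self._curve(slope, sd * k)) == pytest.approx(base * k)


class TestAfuToAmol:
    def test_inverts_the_line(self):
        curve = CalibrationCurve("p", 1000.0, 200.0, 0.0, 5.0, 0.015, 10)
        assert afu_to_amol(200.0, curve) == 0.0
        assert afu_to_amol(1200.0, curve) == pytest.approx(1.0)
        x = np.linspace(-1, 5, 13)
        assert np.allclose(afu_to_amol(1000.0 * x + 200.0, curve), x)

    def test_apply_calibration_flags_below_zero(self):
        wq = pd.DataFrame({
            "well_row": [0, 0], "well_col": [0, 1],
            "probe": ["miR-21", "miR-21"],
            "net_afu": [1200.0, -300.0],
            "amount_amol": [np.nan, np.nan],
            "flags": ["", ""],
        })
        curve = CalibrationCurve("miR-21", 1000.0, 0.0, 0.0, 5.0, 0.015, 10)
        out = apply_calibration(wq, {"miR-21": curve})
        assert out.loc[0, "amount_amol"] == pytest.approx(1.2)
        assert out.loc[1, "amount_amol"] == pytest.approx(-0.3)  # preserved
        assert out.loc[1, "flags"] == "below_zero"
        assert out.loc[0, "flags"] == ""


class TestFoldChanges:
    def test_reference_region_is_unity_and_scale_invariant(self):
        values = {"NAT": 10.0, "T1": 40.0}
        cells = {"NAT": 100.0, "T1": 200.0}
        folds = normalize_to_reference(values, cells, "NAT")
        assert folds["NAT"] == 1.0
        assert folds["T1"] == pytest.approx(2.0)
        doubled = normalize_to_reference(
            {k: 2 * v for k, v in values.items()},
            {k: 2 * v for k, v in cells.items()}, "NAT")
        assert doubled == pytest.approx(folds)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_reference({"NAT": 0.0, "T1": 1.0},
                                   {"NAT": 10, "T1": 10}, "NAT")

    def test_ddct_definition(self):
        ct_t = {"NAT": 25.0, "T1": 24.0, "T2": 28.3219}
        ct_e = {"NAT": 20.0, "T1": 20.0, "T2": 20.0}
        folds = ddct_fold_change(ct_t, ct_e, "NAT")
        assert folds["NAT"] == 1.0
        assert folds["T1"] == pytest.approx(2.0)       # ddCt = -1
        assert folds["T2"] == pytest.approx(0.1, rel=1e-4)  # ddCt = log2(10)

    def test_missing_region_rejected(self):
        with pytest.raises(KeyError):
            ddct_fold_change({"NAT": 25.0}, {}, "NAT")
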