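"""Post intensities → net signals and attomole amounts.

Each well carries one post per probe.  The net signal of a target probe in a
well is its mean post fluorescence minus the mean fluorescence of the same
well's negative-control post (a probe against an off-target miRNA, absent
from the sample).  A calibration dilution series of known spiked amounts
gives, per probe, an ordinary least-squares line ``net = slope·amount +
intercept``; inverting it converts net AFU to attomoles, and the limit of
detection is the standard 3·σ_blank / slope.  Negative estimated amounts are
preserved (only flagged), so downstream region statistics stay unbiased.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "net_signal",
    "fit_calibration",
    "estimate_lod",
    "afu_to_amol",
    "apply_calibration",
    "normalize_to_reference",
    "ddct_fold_change",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Per-probe linear response: slope (AFU/amol), intercept (AFU), LOD."""

    probe: str
    slope: float
    intercept: float
    residual_sd: float
    blank_sd: float
    lod_amol: float
    n_points: int


def net_signal(table: pd.DataFrame, control_probe: str) -> pd.DataFrame:
    """Control-subtracted signal per well and target probe.

    For every well, ``net = target post mean − negative-control post mean``.
    Wells whose control post is flagged (out of frame, dust) yield an
    undefined net with flag ``no_control``.  The blank post's mean is carried
    along as a QC column where present.
    """
    if control_probe not in set(table["probe"]):
        raise KeyError(f"control probe {control_probe!r} not in measurement table")
    rows = []
    for (wr, wc), well in table.groupby(["well_row", "well_col"], sort=True):
        ctrl = well[(well["probe"] == control_probe) & (well["flags"] == "")]
        ctrl_afu = float(ctrl["mean_afu"].iloc[0]) if len(ctrl) else np.nan
        blank = well[well["role"] == "blank"]
        blank_afu = float(blank["mean_afu"].iloc[0]) if len(blank) else np.nan
        for rec in well[well["role"] == "target"].itertuples(index=False):
            flags = rec.flags
            if rec.flags:
                net = np.nan
            elif np.isnan(ctrl_afu):
                net, flags = np.nan, "no_control"
            else:
                net = rec.mean_afu - ctrl_afu
            rows.append(
                {
                    "well_row": wr,
                    "well_col": wc,
                    "probe": rec.probe,
                    "target_afu": rec.mean_afu,
                    "control_afu": ctrl_afu,
                    "blank_afu": blank_afu,
                    "net_afu": net,
                    "amount_amol": np.nan,
                    "flags": flags,
                }
            )
    return pd.DataFrame(rows)


def fit_calibration(
    amounts: np.ndarray | list[float],
    nets: np.ndarray | list[float],
    probe: str = "",
) -> CalibrationCurve:
    """Ordinary least-squares calibration line with blank statistics.

    Requires at least three distinct spike amounts including blanks
    (amount 0).  ``blank_sd`` is the sample standard deviation of the blank
    nets; ``residual_sd`` comes from the fit residuals (n − 2 dof).
    """
    amounts = np.asarray(amounts, dtype=float)
    nets = np.asarray(nets, dtype=float)
    if amounts.shape != nets.shape or amounts.ndim != 1:
        raise ValueError("amounts and nets must be matched 1-D sequences")
    distinct = np.unique(amounts)
    if distinct.size < 3:
        raise ValueError("need >= 3 distinct amounts")
    if 0.0 not in distinct:
        raise ValueError("calibration requires blanks (amount 0)")
    fit = stats.linregress(amounts, nets)
    slope, intercept = float(fit.slope), float(fit.intercept)
    resid = nets - (slope * amounts + intercept)
    n = amounts.size
    residual_sd = float(np.sqrt(np.sum(resid**2) / (n - 2))) if n > 2 else 0.0
    blanks = nets[amounts == 0.0]
    if blanks.size >= 2:
        blank_sd = float(np.std(blanks, ddof=1))
    else:
        warnings.warn("single blank; blank_sd set to 0", stacklevel=2)
        blank_sd = 0.0
    curve = CalibrationCurve(
        probe=probe,
        slope=slope,
        intercept=intercept,
        residual_sd=residual_sd,
        blank_sd=blank_sd,
        lod_amol=np.nan,
        n_points=n,
    )
    lod = estimate_lod(curve)
    return CalibrationCurve(
        probe=probe,
        slope=slope,
        intercept=intercept,
        residual_sd=residual_sd,
        blank_sd=blank_sd,
        lod_amol=lod,
        n_points=n,
    )


def estimate_lod(curve: CalibrationCurve) -> float:
    """Limit of detection: 3·σ_blank / slope (amol)."""
    if curve.slope <= 0:
        raise ValueError(f"probe {curve.probe!r}: non-positive slope, not quantifiable")
    if curve.blank_sd == 0:
        warnings.warn(
            f"probe {curve.probe!r}: zero blank sd gives a degenerate LOD of 0",
            stacklevel=2,
        )
    return 3.0 * curve.blank_sd / curve.slope


def afu_to_amol(net, curve: CalibrationCurve):
    """Invert the calibration line: amount = (net − intercept) / slope.

    Negative results are preserved, not clipped; flag them downstream.
    Accepts scalars or arrays.
    """
    if curve.slope <= 0:
        raise ValueError(f"probe {curve.probe!r}: unusable calibration slope")
    return (np.asarray(net, dtype=float) - curve.intercept) / curve.slope


def apply_calibration(
    wq: pd.DataFrame, curves: Mapping[str, CalibrationCurve]
) -> pd.DataFrame:
    """Fill ``amount_amol`` for every probe with a calibration curve.

    Probes without a curve keep an undefined amount.  Estimated amounts below
    zero receive the ``below_zero`` flag.
    """
    out = wq.copy()
    for probe, curve in curves.items():
        sel = (out["probe"] == probe) & out["net_afu"].notna()
        amounts = afu_to_amol(out.loc[sel, "net_afu"].to_numpy(), curve)
        out.loc[sel, "amount_amol"] = amounts
        neg = sel.copy()
        neg.loc[sel] = amounts < 0
        out.loc[neg, "flags"] = out.loc[neg, "flags"].apply(
            lambda f: f + (";" if f else "") + "below_zero"
        )
    return out


def normalize_to_reference(
    region_values: Mapping[str, float],
    cell_counts: Mapping[str, float],
    reference: str,
) -> dict[str, float]:
    """Per-cell fold change relative to a reference region.

    ``fold(r) = (value_r / cells_r) / (value_ref / cells_ref)`` — used to put
    array measurements on the same footing as expression assays normalized by
    an endogenous (per-cell) control.
    """
    if reference not in region_values:
        raise KeyError(f"reference region {reference!r} missing from values")
    for r in region_values:
        if r not in cell_counts:
            raise KeyError(f"no cell count for region {r!r}")
        if cell_counts[r] <= 0:
            raise ValueError(f"cell count for region {r!r} must be > 0")
    ref_per_cell = region_values[reference] / cell_counts[reference]
    if ref_per_cell == 0:
        raise ValueError("reference region has zero signal")
    return {
        r: (v / cell_counts[r]) / ref_per_cell for r, v in region_values.items()
    }


def ddct_fold_change(
    ct_target: Mapping[str, float],
    ct_endogenous: Mapping[str, float],
    reference: str,
) -> dict[str, float]:
    """RT-PCR ΔΔCt fold change relative to a reference region.

    ``fold(r) = 2^−((Ct_target,r − Ct_endo,r) − (Ct_target,ref − Ct_endo,ref))``
    with an endogenous-control miRNA as the per-sample normalizer.
    """
    if reference not in ct_target:
        raise KeyError(f"reference region {reference!r} missing")
    for r in ct_target:
        if r not in ct_endogenous:
            raise KeyError(f"region {r!r} missing from endogenous Cts")
        if not (np.isfinite(ct_target[r]) and np.isfinite(ct_endogenous[r])):
            raise ValueError(f"non-finite Ct for region {r!r}")
    ref_dct = ct_target[reference] - ct_endogenous[reference]
    return {
        r: float(2.0 ** -((ct - ct_endogenous[r]) - ref_dct))
        for r, ct in ct_target.items()
    }
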