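"""Routine assay quantifications: ΔΔCt relative expression, dual-luciferase
normalization, and densitometry ratios including myosin heavy-chain isoform
distributions from gel band densities."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "ddct",
    "luciferase_ratio",
    "reporter_summary",
    "densitometry_ratio",
    "densitometry_summary",
    "mhc_distribution",
]


def ddct(table: pd.DataFrame, efficiency: float = 2.0) -> pd.DataFrame:
    """Relative expression by the ΔΔCt method.

    ΔCt = target_ct − ref_ct per sample; ΔΔCt subtracts the mean calibrator
    ΔCt; fold = efficiency^(−ΔΔCt) with the standard assumption of
    amplification efficiency 2.  Rows with the same sample name are treated
    as replicates and aggregated by the geometric mean of their folds in
    the returned summary columns.
    """
    required = {"sample", "target_ct", "ref_ct", "group"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    if not (table["group"] == "calibrator").any():
        raise ValueError("no calibrator group present")
    ct = table.copy()
    if not np.isfinite(ct[["target_ct", "ref_ct"]].to_numpy()).all():
        raise ValueError("Ct values must be finite")
    ct["dct"] = ct["target_ct"] - ct["ref_ct"]
    cal_dct = ct.loc[ct["group"] == "calibrator", "dct"].mean()
    ct["ddct"] = ct["dct"] - cal_dct
    ct["fold"] = np.power(float(efficiency), -ct["ddct"])
    geo = (
        ct.groupby("sample", sort=False)["fold"]
        .apply(lambda f: float(np.exp(np.mean(np.log(f)))))
        .rename("fold_geomean")
    )
    return ct.merge(geo, on="sample")


def luciferase_ratio(firefly: float, renilla: float) -> float:
    """Transfection-normalized reporter activity: firefly/Renilla."""
    if renilla <= 0:
        raise ValueError("renilla must be positive")
    return firefly / renilla


def reporter_summary(table: pd.DataFrame, control: str) -> pd.DataFrame:
    """Per-condition mean firefly/Renilla ratios, expressed relative to the
    named control condition (the control maps to 1.0)."""
    required = {"condition", "firefly", "renilla"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if (table["renilla"] <= 0).any():
        raise ValueError("renilla must be positive")
    df = table.copy()
    df["ratio"] = df["firefly"] / df["renilla"]
    means = df.groupby("condition", sort=False)["ratio"].mean().rename("mean_ratio")
    out = means.reset_index()
    if control not in set(out["condition"]):
        raise ValueError(f"control condition {control!r} not present")
    ctrl = float(out.loc[out["condition"] == control, "mean_ratio"].iloc[0])
    out["relative_to_control"] = out["mean_ratio"] / ctrl
    return out


def densitometry_ratio(band: float, loading_control: float) -> float:
    """Band density normalized to its lane's loading control."""
    if loading_control <= 0:
        raise ValueError("loading control must be positive")
    return band / loading_control


def densitometry_summary(table: pd.DataFrame, control_group: str) -> pd.DataFrame:
    """Per-lane loading-control-normalized densities with group means and
    fold change vs a control group."""
    required = {"group", "band", "loading_control"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if (table["loading_control"] <= 0).any():
        raise ValueError("loading controls must be positive")
    df = table.copy()
    df["normalized"] = df["band"] / df["loading_control"]
    means = df.groupby("group", sort=False)["normalized"].mean().rename("group_mean")
    out = means.reset_index()
    if control_group not in set(out["group"]):
        raise ValueError(f"control group {control_group!r} not present")
    ctrl = float(out.loc[out["group"] == control_group, "group_mean"].iloc[0])
    out["fold_vs_control"] = out["group_mean"] / ctrl
    return out


def mhc_distribution(band_densities) -> np.ndarray:
    """Myosin heavy-chain isoform distribution (percent of total) from gel
    band densities; sums to 100 for any non-degenerate input."""
    d = np.asarray(band_densities, dtype=float)
    if np.any(d < 0):
        raise ValueError("band densities must be non-negative")
    total = d.sum()
    if total == 0:
        raise ValueError("all band densities are zero")
    return 100.0 * d / total
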