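"""Quantification of image-derived measurements.

Z-line width at the base of averaged electron-micrograph density profiles,
fibre cross-sectional-area and fibre-number summaries by fibre type,
myotube width, fusion index, and EdU proliferation fraction.  The module
consumes already-extracted measurement tables; image segmentation is
upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ZlineWidth",
    "zline_width",
    "summarize_fibres",
    "fusion_index",
    "count_fused_nuclei",
    "edu_fraction",
    "myotube_width_summary",
]


@dataclass
class ZlineWidth:
    width_nm: float
    background: float
    peak: float
    threshold: float
    threshold_frac: float
    left_nm: float
    right_nm: float


def zline_width(
    position_nm,
    intensity,
    threshold_frac: float = 0.05,
    outer_frac: float = 0.2,
) -> ZlineWidth:
    """Width at the base of a single dominant peak in a density profile.

    The background is the median intensity over the outer ``outer_frac`` of
    positions (half on each side); the base is the contiguous region around
    the peak where intensity exceeds background + ``threshold_frac``·(peak −
    background), with the edges refined by linear interpolation to the
    threshold level.  The measurement is invariant to adding a constant to
    all intensities.
    """
    pos = np.asarray(position_nm, dtype=float)
    inten = np.asarray(intensity, dtype=float)
    if pos.size < 10:
        raise ValueError("profile too short")
    if np.any(np.diff(pos) <= 0):
        raise ValueError("positions must be strictly increasing")
    n_outer = max(2, int(round(outer_frac * pos.size / 2)))
    background = float(np.median(np.concatenate([inten[:n_outer], inten[-n_outer:]])))
    peak = float(inten.max())
    if peak <= background:
        raise ValueError("no peak above background")
    thr = background + threshold_frac * (peak - background)

    above = inten > thr
    i_peak = int(np.argmax(inten))
    if not above[i_peak]:
        raise ValueError("no region exceeds the threshold")
    left = i_peak
    while left > 0 and above[left - 1]:
        left -= 1
    right = i_peak
    while right < pos.size - 1 and above[right + 1]:
        right += 1

    if left > 0:
        x0, x1 = pos[left - 1], pos[left]
        y0, y1 = inten[left - 1], inten[left]
        left_nm = x0 + (thr - y0) / (y1 - y0) * (x1 - x0)
    else:
        left_nm = float(pos[0])
    if right < pos.size - 1:
        x0, x1 = pos[right], pos[right + 1]
        y0, y1 = inten[right], inten[right + 1]
        right_nm = x0 + (thr - y0) / (y1 - y0) * (x1 - x0)
    else:
        right_nm = float(pos[-1])
    return ZlineWidth(
        width_nm=float(right_nm - left_nm), background=background, peak=peak,
        threshold=thr, threshold_frac=threshold_frac,
        left_nm=float(left_nm), right_nm=float(right_nm),
    )


def summarize_fibres(
    pop: pd.DataFrame,
    control: str = "WT",
    test: str = "MKO",
) -> pd.DataFrame:
    """Per-(muscle, fibre type) mean CSA and fibre counts for each genotype
    with the percent CSA reduction of ``test`` vs ``control``.

    Cells present in one genotype only are kept with NaN differences and
    flagged, never dropped silently.  Counts sum to the input row count.
    """
    required = {"csa_um2", "fibre_type", "muscle", "genotype"}
    missing = required - set(pop.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if (pop["csa_um2"] <= 0).any():
        raise ValueError("csa_um2 must be positive")
    grouped = (
        pop.groupby(["muscle", "fibre_type", "genotype"], observed=True)["csa_um2"]
        .agg(["mean", "count"])
        .unstack("genotype")
    )
    out = pd.DataFrame(index=grouped.index)
    for geno in (control, test):
        if ("mean", geno) in grouped.columns:
            out[f"mean_csa_{geno}"] = grouped[("mean", geno)]
            out[f"n_{geno}"] = grouped[("count", geno)].fillna(0).astype(int)
        else:
            out[f"mean_csa_{geno}"] = np.nan
            out[f"n_{geno}"] = 0
    out["percent_reduction"] = 100.0 * (
        1.0 - out[f"mean_csa_{test}"] / out[f"mean_csa_{control}"]
    )
    out["incomplete"] = out[[f"mean_csa_{control}", f"mean_csa_{test}"]].isna().any(axis=1)
    return out.reset_index()


def count_fused_nuclei(myotube_nucleus_counts, min_nuclei: int = 3) -> int:
    """Nuclei residing in myotubes with at least ``min_nuclei`` nuclei."""
    counts = np.asarray(myotube_nucleus_counts, dtype=int)
    return int(counts[counts >= min_nuclei].sum())


def fusion_index(nuclei_in_myotubes_ge3: int, nuclei_total: int) -> float:
    """Percentage of nuclei inside myotubes containing three or more nuclei
    relative to all nuclei in the field."""
    if nuclei_total <= 0:
        raise ValueError("nuclei_total must be positive")
    if nuclei_in_myotubes_ge3 > nuclei_total:
        raise ValueError("fused nuclei cannot exceed the total")
    return 100.0 * nuclei_in_myotubes_ge3 / nuclei_total


def edu_fraction(edu_positive: int, hoechst_total: int) -> float:
    """EdU-positive nuclei as a percentage of all counted nuclei."""
    if hoechst_total <= 0:
        raise ValueError("hoechst_total must be positive")
    if edu_positive > hoechst_total:
        raise ValueError("positive nuclei cannot exceed the total")
    return 100.0 * edu_positive / hoechst_total


def myotube_width_summary(widths_control, widths_test) -> dict:
    """Mean, SD and percent reduction of test vs control myotube widths."""
    c = np.asarray(widths_control, dtype=float)
    t = np.asarray(widths_test, dtype=float)
    if c.size == 0 or t.size == 0:
        raise ValueError("width samples must be non-empty")
    return {
        "mean_control": float(c.mean()),
        "sd_control": float(c.std(ddof=1)) if c.size > 1 else 0.0,
        "mean_test": float(t.mean()),
        "sd_test": float(t.std(ddof=1)) if t.size > 1 else 0.0,
        "n_control": int(c.size),
        "n_test": int(t.size),
        "percent_reduction": 100.0 * (1.0 - float(t.mean()) / float(c.mean())),
    }
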