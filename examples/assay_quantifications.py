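"""Small assay quantifications: ddCt fold changes, dual-luciferase
normalization, densitometry and MHC isoform distribution."""

import pandas as pd

from fibractin import (
    ddct,
    densitometry_summary,
    edu_fraction,
    fusion_index,
    mhc_distribution,
    paper_fixtures,
    reporter_summary,
)

ct = paper_fixtures(seed=0)["ddct_2p5fold"].files["ct"]
out = ddct(ct)
fold = out.loc[out["group"] == "test", "fold_geomean"].iloc[0]
print(f"ddCt fold change (differentiating vs proliferating): {fold:.2f}x")

rep = reporter_summary(
    pd.DataFrame({
        "condition": ["lacz", "lacz", "srf", "srf"],
        "firefly": [220.0, 180.0, 930.0, 1010.0],
        "renilla": [110.0, 95.0, 105.0, 118.0],
    }),
    control="lacz",
)
srf = rep.loc[rep["condition"] == "srf", "relative_to_control"].iloc[0]
print(f"SRF reporter activity vs control: {srf:.1f}x (Renilla-normalized)")

dens = densitometry_summary(
    pd.DataFrame({
        "group": ["wt", "wt", "mko", "mko"],
        "band": [8.2, 7.8, 5.1, 4.9],
        "loading_control": [4.0, 3.9, 4.1, 4.0],
    }),
    control_group="wt",
)
mko = dens.loc[dens["group"] == "mko", "fold_vs_control"].iloc[0]
print(f"puromycin incorporation, knockout vs wild type: {mko:.2f}x")

print("MHC isoform distribution (%):", [f"{p:.0f}" for p in mhc_distribution([30, 50, 20])])
print(f"fusion index: {fusion_index(430, 1500):.1f}%  "
      f"EdU fraction: {edu_fraction(310, 2400):.1f}%")
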