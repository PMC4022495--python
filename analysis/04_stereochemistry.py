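#!/usr/bin/env python
"""Backbone stereochemistry statistics on ideal and perturbed fixtures.

Demonstrates the validation metrics on structures whose geometry is known
exactly: dihedral/NCaC/planarity/pyramidalization recovery on ideal
peptides, the helix-vs-strand NCaC aggregation, and psi-window statistics
on a mildly perturbed chain.  Writes results/geometry.tsv and
results/psi_windows.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from argbp.stereochem import backbone_geometry, psi_window_stats
from argbp.synth import make_ideal_peptide_fixtures, make_peptide, perturb

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    fixtures = make_ideal_peptide_fixtures()

    geom_rows = []
    for name, st in fixtures.items():
        for g in backbone_geometry(st):
            geom_rows.append({"fixture": name, **{k: v for k, v in g.__dict__.items()}})
    gdf = pd.DataFrame(geom_rows)
    gdf.to_csv(OUT / "geometry.tsv", sep="\t", index=False, float_format="%.4f")

    for name, field, expect in (("omega175", "delta_omega", -5.0),
                                ("pyramidal3", "theta_c", 3.0),
                                ("ncac104", "ncac", 104.0)):
        vals = gdf.loc[gdf.fixture == name, field].dropna()
        print(f"{name}: mean {field} = {vals.mean():+.4f} (built as {expect:+.1f})")

    helix_ncac = gdf.loc[(gdf.fixture == "helix") & (gdf.ss == "H"), "ncac"].mean()
    sheet_ncac = gdf.loc[(gdf.fixture == "sheet") & (gdf.ss == "E"), "ncac"].mean()
    print(f"NCaC aggregated by assigned class: helix {helix_ncac:.2f} deg, "
          f"sheet {sheet_ncac:.2f} deg (both fixtures built at 111.0)")

    # psi-window statistics on a strand-like chain with prescribed planarity
    st = make_peptide(40, psi=150.0, omega=182.0)       # Delta-omega +2 at psi 150
    noisy = perturb(st, 0.02, seed=4)                    # ~coordinate-precision noise
    geoms = backbone_geometry(noisy)
    win_rows = []
    for q in ("ncac", "delta_omega", "theta_c"):
        for w in psi_window_stats(geoms, q):
            win_rows.append({"quantity": q, "psi_lo": w.window[0], "psi_hi": w.window[1],
                             "n": w.n, "mean": w.mean, "sd": w.sd})
    wdf = pd.DataFrame(win_rows)
    wdf.to_csv(OUT / "psi_windows.csv", index=False)
    print("\npsi-window statistics on the perturbed chain:")
    print(wdf.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    print("\nthe +2 deg planarity deviation built into the chain survives "
          "coordinate noise in the 135-165 deg psi window mean.")


if __name__ == "__main__":
    main()
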