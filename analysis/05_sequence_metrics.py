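#!/usr/bin/env python
"""Sequence-derived thermostability and oligomer-state metrics.

Runs the composition / theoretical-mass / stoichiometry calculators: the
published weight-average light-scattering masses (50.3 and 49.6 kDa) are
interpreted against the published theoretical monomer mass (25267 Da), and
the hinge-motif check is demonstrated on a sequence carrying the KKSPY
swap-hinge.  Writes results/sequence_metrics.csv.
"""

from pathlib import Path

import pandas as pd

from argbp.seqcomp import (
    SequenceRecord,
    composition,
    hinge_motif_check,
    stoichiometry,
    theoretical_mass,
)

OUT = Path(__file__).resolve().parent.parent / "results"

MONOMER_DA = 25267.0            # theoretical construct mass, used as input
MALS_KDA = {"holo": 50.3, "apo": 49.6}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for label, kda in MALS_KDA.items():
        ratio, n, ok = stoichiometry(kda, MONOMER_DA)
        rows.append({"metric": f"stoichiometry_{label}", "value": round(ratio, 3),
                     "assigned_n": n, "unambiguous": ok})
        print(f"{label}: {kda} kDa / {MONOMER_DA/1000:.3f} kDa = {ratio:.2f} -> n = {n}")

    # composition on demonstration sequences spanning the charged/polar axis
    for name, seq in (
        ("charged_rich", "KKEEDDRRKEDRAAAALLLVVIIGG"),
        ("polar_rich", "NNSSQQTTNSQTAAAALLLVVIIGG"),
    ):
        rep = composition(seq)
        rows.append({"metric": f"pct_charged_{name}", "value": rep.pct_charged})
        rows.append({"metric": f"pct_polar_{name}", "value": rep.pct_polar})
        print(f"{name}: {rep.pct_charged}% charged (K/R/E/D), {rep.pct_polar}% polar (N/S/Q/T)")

    demo = ["A"] * 227
    for off, ch in zip(range(232 - 20, 237 - 20), "KKSPY"):
        demo[off] = ch
    rec = SequenceRecord("".join(demo), first_number=20)
    hinge = hinge_motif_check(rec, (232, 236))
    rows.append({"metric": "hinge_sequence", "value": hinge["sequence"]})
    rows.append({"metric": "hinge_contains_proline", "value": hinge["contains_proline"]})
    rows.append({"metric": "demo_sequence_mass_da", "value": round(theoretical_mass(rec))})
    print(f"hinge 232-236: {hinge['sequence']} (Pro present: {hinge['contains_proline']})")

    pd.DataFrame(rows).to_csv(OUT / "sequence_metrics.csv", index=False)
    print("\nboth light-scattering masses resolve unambiguously to a dimer "
          "(ratios 1.99 and 1.96), and the swap hinge carries the Pro that "
          "restrains the monomeric closed state.")


if __name__ == "__main__":
    main()
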