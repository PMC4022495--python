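#!/usr/bin/env python
"""Quantify the open -> closed conformational change of the bilobed monomer.

Measures what a Venus-flytrap closure looks like through the superposition
module: whole-chain RMSD is large while per-lobe RMSDs stay ~0, and the
two-stage closure analysis recovers the applied inter-lobe rotation and its
axis.  Writes results/closure.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from argbp.superpose import closure_analysis, rmsd
from argbp.synth import ToySpec, apply_domain_rotation, make_two_lobe_monomer
from argbp.structure import DomainDefinition

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    mono, dom = make_two_lobe_monomer(ToySpec(seed=SEED))
    pivot = mono.chains[0].residue(dom["linker"].ranges[0][1]).atom("CA").pos
    axis = np.array([0.0, 0.0, 1.0])
    full = DomainDefinition("full", [("A", 1, len(mono.chains[0].residues))])

    rows = []
    for angle in (5.0, 20.0, 30.0, 84.0, 120.0):
        closed = apply_domain_rotation(mono, dom["lobe2"], axis, angle, pivot)
        motion = closure_analysis(mono, closed, dom["lobe1"], dom["lobe2"])
        rows.append({
            "applied_deg": angle,
            "recovered_deg": motion.angle,
            "axis_alignment": abs(float(motion.axis @ axis)),
            "rmsd_full_ca_A": rmsd(mono, closed, full),
            "rmsd_lobe1_ca_A": rmsd(mono, closed, dom["lobe1"]),
            "rmsd_lobe2_ca_A": rmsd(mono, closed, dom["lobe2"]),
        })

    df = pd.DataFrame(rows)
    df.to_csv(OUT / "closure.csv", index=False)
    print(df.to_string(index=False, float_format=lambda v: f"{v:.6g}"))
    print("\nwhole-chain RMSD grows with the applied closure while per-lobe "
          "RMSDs stay at zero: the motion is a rigid inter-lobe rotation, "
          "recovered exactly by the two-stage fit.")


if __name__ == "__main__":
    main()
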