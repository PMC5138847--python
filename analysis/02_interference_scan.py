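#!/usr/bin/env python
"""Quantify the HIU spectral interference and the Urah:Uox ratio scan.

Two experiments on the simulator:
(1) the apparent initial-velocity ratio with/without equimolar Urah as the
    HIU product-inhibition constant K_p varies (the spectral-interference
    floor is a factor 2 when eps_HIU = 0.5 eps_urate); and
(2) apparent v0 against the Urah:Uox molar ratio, locating the plateau.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from uricolysis import (
    AssayConditions,
    EnzymeSpec,
    KineticParameters,
    interference_ratio,
    plateau_ratio,
)
from uricolysis.synthetic import GeneratorConfig, default_true_spectra, gen_ratio_scan

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

spectra = default_true_spectra()
rows = []
for kp in [None, 10.0, 2.0, 1.0, 0.5]:
    p = KineticParameters(K_M=11.0, k_cat=3.95, K_p=kp)
    cond = AssayConditions(
        substrate_0=100.0,
        enzymes=(
            EnzymeSpec("Uox", 0.9, parameters=p),
            EnzymeSpec("Urah", 0.9, first_order_efficiency=30.0),
        ),
    )
    rows.append(
        {"K_p_uM": np.inf if kp is None else kp,
         "v0_ratio": interference_ratio(cond, p, spectra, 292.0)}
    )
interference = pd.DataFrame(rows)
interference.to_csv(OUT / "interference_vs_kp.csv", index=False)

ratios = [0.0, 0.25, 0.5, 1.0, 2.0, 5.0, 10.0]
scan = gen_ratio_scan(GeneratorConfig(seed=4), ratios)
r_plateau, v0 = plateau_ratio(scan, 12.2, tol=0.05)
pd.DataFrame({"urah_uox_ratio": ratios, "v0_uM_s": v0}).to_csv(
    OUT / "ratio_scan_v0.csv", index=False
)

print(interference.to_string(index=False))
print(
    f"\nspectral interference alone halves the apparent v0 (ratio 2); the "
    f"KP calibration (K_p = 1 uM) raises the ratio to "
    f"{interference.loc[3, 'v0_ratio']:.2f}"
)
print(
    f"ratio scan: v0 plateaus by Urah:Uox = {r_plateau:g} "
    f"(v0 at 1:1 is {100 * v0[3] / v0[-1]:.1f}% of 10:1)"
)
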