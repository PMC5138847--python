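#!/usr/bin/env python
"""Simulate the coupled uricolysis assay with and without HIU hydrolase.

Integrates the four-species network (urate -> HIU -> OHCU -> allantoin) for
the wild-type enzyme in KP buffer, with and without equimolar Urah, and
writes both concentration series.  The run reports when HIU peaks without
Urah and how completely an equimolar Urah quenches it.
"""

from pathlib import Path

import numpy as np

from uricolysis import simulate_uricolysis, scenario
from uricolysis.io import write_series

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

sc = scenario("wt-KP-292", None)
t = np.linspace(0.0, 400.0, 2001)

with_urah = simulate_uricolysis(sc.conditions, sc.params, t)
no_urah_cond = sc.conditions.with_enzymes(
    [e for e in sc.conditions.enzymes if e.name != "Urah"]
)
without_urah = simulate_uricolysis(no_urah_cond, sc.params, t)

write_series(with_urah, OUT / "series_wt_with_urah.csv")
write_series(without_urah, OUT / "series_wt_without_urah.csv")

i_peak = int(np.argmax(without_urah.hiu))
print(f"wrote concentration series to {OUT}")
print(
    f"without Urah, HIU peaks at {without_urah.hiu[i_peak]:.1f} uM "
    f"(t = {t[i_peak]:.1f} s) before decaying at k_HIU = {sc.conditions.k_HIU} 1/s"
)
print(
    f"with equimolar Urah, HIU never exceeds {with_urah.hiu.max():.2f} uM: "
    "the intermediate is quenched and 292 nm reports urate alone"
)
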