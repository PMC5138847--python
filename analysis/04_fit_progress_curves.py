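#!/usr/bin/env python
"""Progress-curve analysis: closed form with Urah, ODE model without.

The +Urah trace at 292 nm follows the integrated Michaelis-Menten law
(Lambert-W closed form) and returns the true constants.  The -Urah trace
is slowed by HIU product inhibition: a closed-form fit inflates the
apparent K_M, while the ODE model with a free K_p recovers the generating
constants.
"""

import json
from pathlib import Path

import numpy as np

from uricolysis import (
    AbsorbanceTrace,
    absorbance_project,
    fit_progress_curve,
    simulate_uricolysis,
    scenario,
)
from uricolysis.io import write_trace
from uricolysis.synthetic import GeneratorConfig, default_true_spectra, gen_progress_curves

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

# with Urah: clean trace, closed form
cfg = GeneratorConfig(seed=5, scenario="wt-KP-292")
trace_plus = gen_progress_curves(cfg, n_curves=1)[0]
write_trace(trace_plus, OUT / "trace_wt_with_urah.csv")
fit_plus = fit_progress_curve(trace_plus, 12.2, 0.9, model="closed_form")

# without Urah: urate observable only, product inhibition active
sc = scenario("wt-KP-292", None)
cond_minus = sc.conditions.with_enzymes(
    [e for e in sc.conditions.enzymes if e.name != "Urah"]
)
t = np.linspace(0.0, 400.0, 401)
series = simulate_uricolysis(cond_minus, sc.params, t)
urate_only = [s for s in default_true_spectra() if s.species == "urate"]
trace_minus = absorbance_project(series, urate_only, 292.0)
rng = np.random.default_rng(5)
trace_minus = AbsorbanceTrace(
    292.0, 1.0, t, trace_minus.absorbance + 0.002 * rng.standard_normal(t.shape)
)
write_trace(trace_minus, OUT / "trace_wt_without_urah.csv")

fit_closed = fit_progress_curve(trace_minus, 12.2, 0.9, model="closed_form")
fit_ode = fit_progress_curve(
    trace_minus, 12.2, 0.9, model="ode_product_inhibition", conditions=cond_minus
)

report = {
    "with_urah_closed_form": fit_plus.estimates,
    "without_urah_closed_form": fit_closed.estimates,
    "without_urah_ode_free_Kp": fit_ode.estimates,
}
(OUT / "progress_curve_fits.json").write_text(json.dumps(report, indent=2))

print(f"+Urah closed form:  K_M = {fit_plus.estimates['K_M']:.1f} uM, "
      f"Vmax = {fit_plus.estimates['Vmax']:.2f} uM/s")
km_app = fit_closed.estimates["K_M"]
print(f"-Urah closed form:  apparent K_M = {km_app:.3g} uM -- product "
      "inhibition with K_p << K_M drives the curve toward first-order decay, "
      "so the simple model sees an enormously inflated, weakly determined K_M")
print(f"-Urah ODE model:    K_M = {fit_ode.estimates['K_M']:.1f} uM, "
      f"K_p = {fit_ode.estimates['K_p']:.2f} uM "
      f"(generating values 11 uM and 1 uM)")
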