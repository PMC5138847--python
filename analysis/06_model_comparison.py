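#!/usr/bin/env python
"""Likelihood-ratio comparisons: dN/dS rate models and shared-Vmax kinetics.

(1) Applies the LRT to the published log-likelihoods of nested dN/dS rate
    models for the urate oxidase gene across primates (printed table values
    as inputs) and reproduces the printed p column.
(2) On synthetic competitive-inhibition data, tests the shared-Vmax
    (competitive) model against a per-xanthine-level free-Vmax alternative:
    the relaxation brings no significant improvement, the kinetic
    signature of purely competitive inhibition.
"""

from pathlib import Path

import pandas as pd

from uricolysis import ModelFit, fit_competitive_global, likelihood_ratio_test
from uricolysis.synthetic import GeneratorConfig, gen_rate_dataset

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

# published log-likelihoods of the nested dN/dS rate models (input data)
models = [
    ("1-rate", -2881.94, 1),
    ("2-rates", -2856.90, 2),
    ("3-rates", -2854.75, 3),
    ("4-rates", -2854.69, 4),
    ("7-rates", -2854.25, 7),
]
rows = []
for (name0, ll0, k0), (name1, ll1, k1) in zip(models, models[1:]):
    res = likelihood_ratio_test(ModelFit(name0, ll0, k0), ModelFit(name1, ll1, k1))
    rows.append({"comparison": f"{name1} vs {name0}", "statistic": res.statistic,
                 "df": res.df, "p": res.p_value})
lrt_table = pd.DataFrame(rows)
lrt_table.to_csv(OUT / "dnds_lrt.csv", index=False)
print(lrt_table.to_string(index=False))
print("-> only the hominoid rate shift (2-rates vs 1-rate) is decisive; "
      "finer splits add little\n")

ds = gen_rate_dataset(GeneratorConfig(seed=21, scenario="wt-KP-292"))
shared = fit_competitive_global(ds)
unshared = fit_competitive_global(ds, share_vmax=False)
res = likelihood_ratio_test(
    shared.as_model_fit("shared-Vmax"), unshared.as_model_fit("free-Vmax")
)
pd.DataFrame([{"statistic": res.statistic, "df": res.df, "p": res.p_value}]).to_csv(
    OUT / "vmax_invariance_lrt.csv", index=False
)
print(f"shared-Vmax vs free-Vmax on competitive data: p = {res.p_value:.3f} "
      "(no significant gain: xanthine changes the apparent K_M, not Vmax)")
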