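# uricolysis

Simulation and kinetic analysis of the coupled urate oxidase UV assay.

Urate oxidase (Uox) catalyses the first step of uricolysis, the pathway
that converts poorly soluble urate into (S)-allantoin:

    urate --Uox--> HIU --Urah--> OHCU --Urad--> allantoin

Measuring Uox activity by the decay of the urate band at 292 nm is
complicated by its own product: 5-hydroxyisourate (HIU) is unstable,
absorbs at 292 nm with roughly half the molar absorptivity of urate, and
inhibits the enzyme. Adding HIU hydrolase (Urah) to the assay removes the
intermediate and makes the progress curve obey the integrated
Michaelis–Menten law. This package provides the machinery to simulate and
analyse that assay end to end, for anyone fitting enzyme kinetics from UV
progress curves with unstable, absorbing intermediates:

- **kinetics** — Michaelis–Menten rate laws with competitive xanthine and
  HIU product inhibition; the Schell–Mendoza closed form
  `S(t) = K_M · W0((S0/K_M) e^{(S0−Vmax t)/K_M})` built on an internal
  Lambert-W kernel; a stiff-capable ODE simulator of the four-species
  network; k_cat/K_M reporting.
- **spectroscopy** — Beer–Lambert projection of species time courses,
  initial-velocity extraction, and quantification of the HIU interference
  (apparent v0 with vs without Urah).
- **fitting** — steady-state MM fits, global competitive-inhibition fits
  with shared Vmax, progress-curve fits (closed form or full ODE with free
  K_p), variable-projection deconvolution of time-resolved spectra into
  intermediate spectra, and likelihood-ratio tests of nested models.
- **synthetic** — seeded generators for every input (rate datasets,
  progress curves, time×wavelength matrices, Urah:Uox ratio scans) with
  scenario presets for the wild-type and F216S enzymes.
- **cli / io** — a `uricolysis` command-line tool and CSV/JSON round-trip
  I/O.

## Worked example

```python
import numpy as np
from uricolysis import (GeneratorConfig, fit_competitive_global,
                        catalytic_efficiency, round_sig)
from uricolysis.synthetic import gen_rate_dataset

# noiseless initial-velocity data at the wild-type preset
cfg = GeneratorConfig(seed=1, noise_sd_rate=0.0, scenario="wt-KP-292")
fit = fit_competitive_global(gen_rate_dataset(cfg))
print(fit.estimates)
print(round_sig(catalytic_efficiency(fit.estimates["k_cat"],
                                     fit.estimates["K_M"]), 2))
```

prints

```
{'K_M': 11.000000000001602, 'k_cat': 3.950000000000005, 'K_i': 4.300000000000687}
360000.0
```

i.e. the generator→fitter round trip returns the generating constants —
K_M = 11 μM, k_cat = 3.95 s⁻¹, xanthine K_i = 4.3 μM — and a catalytic
efficiency of 3.6×10⁵ M⁻¹ s⁻¹. The F216S preset (`"F216S-KP-292"`)
returns K_M = 284 μM and K_i = 59.2 μM at the same k_cat: the mutation
weakens substrate and inhibitor binding ~25-fold without touching
turnover.

The numbered scripts under `analysis/` run the full story — assay
simulation, interference quantification, steady-state and progress-curve
fits, spectral deconvolution, and model comparison — and write their
tables under `results/`:

```sh
python analysis/01_simulate_assay.py
python analysis/02_interference_scan.py
...
```

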