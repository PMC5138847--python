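#!/usr/bin/env python
"""Resolve the HIU and OHCU spectra from time-resolved absorbance matrices.

Generates noisy (sigma = 0.002 AU) time x wavelength matrices for the two
quench schemes and deconvolves them by variable projection: Uox+Urad
resolves urate and the accumulating HIU; Uox+Urah resolves urate and OHCU.
The key diagnostic is the HIU/urate absorptivity ratio at 292 nm (~0.5),
the origin of the assay interference.
"""

from pathlib import Path

from uricolysis import deconvolve_sequential_spectra
from uricolysis.io import write_fit_result, write_spectrum
from uricolysis.synthetic import GeneratorConfig, gen_time_resolved_spectra

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

for scheme, decay in [("Uox+Urad", "k_HIU"), ("Uox+Urah", "k_OHCU")]:
    truth = gen_time_resolved_spectra(
        GeneratorConfig(seed=7, noise_sd_abs=0.002), scheme
    )
    res, spectra = deconvolve_sequential_spectra(
        truth.matrix, scheme,
        init={"Vmax": 3.0, "K_M": 10.0, decay: 0.005, "S0": 100.0},
    )
    tag = scheme.replace("+", "_")
    write_fit_result(res, OUT / f"deconv_{tag}_rates.json")
    for s in spectra:
        write_spectrum(s, OUT / f"deconv_{tag}_{s.species}.csv")
    print(f"{scheme}: rates {({k: round(v, 4) for k, v in res.estimates.items()})}")
    if scheme == "Uox+Urad":
        ratio = spectra[1].at(292.0) / spectra[0].at(292.0)
        print(f"  eps_HIU(292)/eps_urate(292) = {ratio:.3f} "
              "(truth 0.500: HIU absorbs half as strongly as urate, hence "
              "the 292 nm interference)")
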