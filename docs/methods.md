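# Methods

## The reaction network

Oxidative uricolysis degrades urate in three steps:

    urate --Uox--> 5-hydroxyisourate (HIU) --Urah | spontaneous--> OHCU --Urad | spontaneous--> (S)-allantoin

Urate oxidase (Uox) is rate limiting and follows Michaelis–Menten kinetics.
The two intermediates are unstable: HIU decays spontaneously with a
buffer-dependent first-order rate `k_HIU`, OHCU with `k_OHCU`; the
downstream enzymes HIU hydrolase (Urah) and OHCU decarboxylase (Urad)
remove them enzymatically. The simulator integrates

    dU/dt = -v_Uox(U; I, H)
    dH/dt =  v_Uox - k_HIU·H - v_Urah(H)
    dO/dt =  k_HIU·H + v_Urah(H) - k_OHCU·O - v_Urad(O)
    dA/dt =  k_OHCU·O + v_Urad(O)

with the Uox rate law

    v_Uox = k_cat·E·U / ( K_M·(1 + I/K_i + H/K_p) + U )

Xanthine (I, held at its loading concentration) is a competitive dead-end
inhibitor; HIU product inhibition is modelled as a competitive term
`H/K_p` in the K_M bracket, the simplest scheme consistent with an
apparent K_M increase at unchanged maximal velocity. Either term is
omitted when its constant is absent. Urah and Urad operate far below
their Michaelis constants for the trace intermediates, so by default they
are described by a first-order catalytic efficiency (k_cat/K_M,
μM⁻¹ s⁻¹); a full Michaelis–Menten description is accepted when
parameters are supplied.

Units are fixed package-wide: concentrations μM, time s, path length cm,
molar absorptivity mM⁻¹ cm⁻¹. The only conversion is in
`catalytic_efficiency`, which reports k_cat/K_M in M⁻¹ s⁻¹ (factor 10⁶).

## Closed-form progress curve and the Lambert-W kernel

Without inhibition the integrated Michaelis–Menten law has the closed form

    S(t) = K_M · W0( (S0/K_M) · exp((S0 - Vmax·t)/K_M) )

with W0 the principal Lambert-W branch. W0 is computed internally by
Halley iteration from a branch-point series (x near −1/e) or logarithmic
asymptotic (large x) initial guess, to an absolute residual
|W e^W − x| ≤ 10⁻¹²·max(1, |x|); the closed form is evaluated through
W0(e^y) in logarithmic form so that strongly saturating curves
(S0/K_M up to 10⁶) do not overflow. The kernel is cross-checked in the
test suite against `scipy.special.lambertw` and, for the progress curve,
against adaptive ODE integration (10⁻⁶ relative over 100 random
parameter triples).

A useful exact identity used in the tests: with competitive product
inhibition and P = S0 − S, the rate law is again Michaelis–Menten-shaped
with apparent constants K_M,app = K_M(1 + S0/K_p)/α and
Vmax,app = Vmax/α, α = 1 − K_M/K_p. For weak inhibition (K_p ≫ K_M) a
closed-form fit of a product-inhibited curve therefore returns an
inflated K_M at nearly unchanged Vmax; for K_p < K_M the curve degenerates
toward first-order decay and the apparent K_M is unbounded.

## Observation model

Beer–Lambert projection: A(t) = path · Σ_i ε_i(λ)·c_i(t)/1000 (c in μM,
ε in mM⁻¹ cm⁻¹). Named observation wavelengths: 292 nm (urate peak),
302 nm (used with xanthine to reduce its interference), 320 nm (HIU
formation/decay). Out-of-range wavelengths are an error, never an
extrapolation.

Initial velocities are ordinary least-squares slopes over an early
window, converted by v0 = −slope·1000/(Δε·path). The default window is
the earliest span in which ≤10% of the total absorbance change has
occurred, refined iteratively from the fitted slope, never fewer than
5 points. The interference ratio simulates paired assays (± equimolar
Urah), projects both at the same wavelength and applies the same Δε
(urate minus the final product of the +Urah scheme) and the same window
(chosen on the +Urah trace) to both.

## Fitting contract

All fitters use derivative-based least squares
(`scipy.optimize.least_squares`, trf, positive bounds) with ≥5 multistart
initial guesses drawn log-uniformly around data-driven heuristics
(K_M init = substrate at half-maximal observed rate; Vmax init = 1.1 ×
max rate). The best-residual solution wins and all restarts are logged.
If two restarts tie in rss to 10⁻⁸ relative but differ in parameters by
more than 1%, the fit is flagged non-identifiable. Standard errors come
from the Gaussian-error Jacobian approximation at the optimum; parameters
with SE larger than the estimate are listed as poorly determined. A
profiled-common-variance Gaussian log-likelihood,
lnL = −n/2·(ln(2π·rss/n) + 1), makes nested kinetic models comparable by
likelihood-ratio test (statistic 2ΔlnL against a χ² upper tail).

The global competitive fit shares (K_M, k_cat, K_i) across all inhibitor
series — the unchanged maximal velocity is the signature of competitive
inhibition — and offers a relaxed per-level-Vmax alternative for LRT.

Spectral deconvolution uses variable projection: for each trial of the
nonlinear rate parameters, concentration profiles come from the network
simulator and component spectra are solved per wavelength by linear least
squares, non-negative by default (physical ε ≥ 0; an unconstrained mode
exists for parity with classical global analysis). Scheme presets:
`Uox+Urad` resolves urate + HIU (OHCU quenched), `Uox+Urah` resolves
urate + OHCU (HIU quenched). A rank check on the trial concentration
matrix (condition number < 10¹⁰) rejects schemes with indistinguishable
or absent species. The variable-projection optimum is verified in the
tests to coincide with brute-force joint least squares.

## Numerical choices

- ODE integration: LSODA (stiff-capable, adaptive), rtol 10⁻⁸, atol
  10⁻¹⁰ μM. Derivatives are evaluated on the raw solver state; negative
  excursions are clipped to zero only in the reported series.
- Progress-curve identifiability: a warning is issued when the trace
  covers <50% substrate conversion.
- Deconvolution optimizer tolerances are tightened to 10⁻¹⁴ so that
  noiseless round trips recover spectra to ≤10⁻⁶.
- S0 floats by default in progress-curve fits (fixing it to the nominal
  loading is possible by removing it from the free set of the ODE model).

## Synthetic data: what it emulates, and what it does not

The generators emulate the study conditions: 0.1 mM urate, 0.9 μM Uox,
equimolar Urah, 100 mM potassium phosphate pH 7.6 at 25 °C, 1 cm path,
observation at 292/302/320 nm. Wild-type and F216S generation constants
are the reference values (K_M 11 / 284 μM, k_cat 3.95 / 3.99 s⁻¹,
K_i 4.3 / 59.2 μM). Randomness comes from a counter-based generator
(numpy Philox); per-curve substreams derive from
`SeedSequence(seed, spawn_key=(i,))`, so adding curves never perturbs
earlier ones and identical configurations are bit-identical.

Constants that no table provides are package calibration values, chosen
once from the qualitative constraints and held fixed:

| constant | default | basis |
|---|---|---|
| k_HIU (KP pH 7.6) | 0.006 s⁻¹ | HIU decays over minutes in phosphate |
| k_HIU (borate pH 9.2) | 0.03 s⁻¹ | decay is several-fold faster in borate |
| k_OHCU | 0.004 s⁻¹ | OHCU is comparably unstable |
| K_p (HIU on Uox) | 1 μM | chosen so the simulated −Urah assay is suppressed several-fold beyond the factor-2 pure spectral interference, as observed |
| Urah/Urad efficiency | 30 μM⁻¹ s⁻¹ | Urah's specific activity (~230 μmol min⁻¹ mg⁻¹, ~14.5 kDa subunit) implies k_cat ≈ 55 s⁻¹; with a low-μM K_M this gives ~3×10⁷ M⁻¹ s⁻¹ and a >10-fold unit excess at a 1:1 molar ratio |
| ε(292): urate 12.2, HIU 6.1, OHCU 0.3 mM⁻¹ cm⁻¹ | — | HIU at 50% of urate; OHCU nearly transparent; the absolute urate value is a literature-typical calibration |
| noise | 0.002 AU; 3% on rates | synthetic choice: recovery nontrivial but stable |

The full-band spectra in `default_true_spectra` are synthetic Gaussian
shapes anchored to the 292 nm values above; they stand in for
experimentally derived spectra that are not tabulated anywhere. The
time-resolved-spectra scenarios generate under the plain sequential model
(no product inhibition, instantaneous quench enzyme) because that is the
model the deconvolution fits; their round trips test the estimator, not
the full assay physics.

Consequently, passing tests demonstrate correct estimation under the
package's own error model (additive Gaussian absorbance noise,
multiplicative rate noise, no baseline drift, no inner-filter or
scattering effects, no xanthine absorbance in the projection, no thermal
inactivation). They do not certify the calibration constants against
real instruments, and quantities that depend on the unprinted constants —
the absolute interference ratio (~7-fold observed experimentally; ≈2.7
simulated under this calibration) and the exact ratio-scan plateau — are
reproduced
qualitatively (ratio > 2, monotone in 1/K_p, plateau by 1:1), not
numerically.

## Known limitations

- Product inhibition is strictly competitive by assumption; mixed schemes
  are not implemented.
- Xanthine is treated as a non-consumed dead-end inhibitor and as
  spectrally silent.
- pH and temperature enter only as labels; rate constants do not depend
  on them.
- The deconvolution presets resolve exactly two species; richer schemes
  require more informative kinetics than the sequential model provides
  (the rank check fails loudly when a species never accumulates).
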