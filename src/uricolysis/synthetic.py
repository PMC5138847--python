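"""Seeded generators for every input the analysis consumes.

The generators emulate the study's assay conditions: 0.1 mM urate in 100 mM
potassium phosphate at pH 7.6 and 25 C, ~1 uM enzyme, 1 cm path, observation
at 292/302/320 nm, Gaussian absorbance noise, and synthetic UV spectra for
the unstable intermediates with the HIU molar absorptivity at 292 nm equal
to half of urate's.  Scenario presets encode the standard assay designs
(wild type vs F216S, KP vs borate buffer, xanthine series, HIU formation
at 320 nm, and the two time-resolved-spectra schemes).

Randomness is drawn from a named counter-based generator (numpy Philox).
Per-curve substreams are derived from the configuration seed through
``SeedSequence(seed, spawn_key=(index,))``, so adding curves never perturbs
earlier ones and identical configurations give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .kinetics import (
    DEFAULT_K_P,
    DEFAULT_QUENCH_EFFICIENCY,
    AssayConditions,
    EnzymeSpec,
    KineticParameters,
    simulate_uricolysis,
)
from .spectroscopy import (
    EPSILON_292,
    AbsorbanceTrace,
    AbsorptionSpectrum,
    SpectraMatrix,
    absorbance_project,
    initial_velocity,
)
from .fitting import RateDataset

__all__ = [
    "GeneratorConfig",
    "Scenario",
    "SCENARIOS",
    "scenario",
    "default_true_spectra",
    "gen_rate_dataset",
    "gen_progress_curves",
    "gen_time_resolved_spectra",
    "gen_ratio_scan",
    "plateau_ratio",
    "SpectraTruth",
]

#: default noise levels; synthetic choices (the source does not state its
#: replicate error model): 0.002 AU additive on absorbance, 3% relative on
#: initial velocities — enough to make recovery nontrivial but stable.
DEFAULT_NOISE_SD_ABS = 0.002
DEFAULT_NOISE_SD_RATE = 0.03


@dataclass(frozen=True)
class GeneratorConfig:
    """Reproducible generator settings.

    ``overrides`` may set any KineticParameters or AssayConditions field of
    the chosen scenario (e.g. ``{"K_M": 20, "substrate_0": 50}``) or the
    observation ``wavelength``.
    """

    seed: int = 0
    noise_sd_abs: float = DEFAULT_NOISE_SD_ABS
    noise_sd_rate: float = DEFAULT_NOISE_SD_RATE
    scenario: Optional[str] = None
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.noise_sd_abs < 0 or self.noise_sd_rate < 0:
            raise ValueError("noise parameters must be >= 0")

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Philox substream ``stream`` of this configuration's seed."""
        ss = np.random.SeedSequence(self.seed, spawn_key=(stream,))
        return np.random.Generator(np.random.Philox(ss))


@dataclass(frozen=True)
class Scenario:
    """A named assay condition: kinetics, composition, observation."""

    name: str
    params: KineticParameters
    conditions: AssayConditions
    wavelength: float
    substrate_grid: tuple
    inhibitor_levels: tuple


def _uox(conc: float, params: KineticParameters) -> EnzymeSpec:
    return EnzymeSpec("Uox", conc, parameters=params)


def _urah(conc: float) -> EnzymeSpec:
    return EnzymeSpec("Urah", conc, first_order_efficiency=DEFAULT_QUENCH_EFFICIENCY)


def _urad(conc: float) -> EnzymeSpec:
    return EnzymeSpec("Urad", conc, first_order_efficiency=DEFAULT_QUENCH_EFFICIENCY)


#: wild-type and F216S kinetic constants used for generation (uM, s^-1)
WT_PARAMS = KineticParameters(K_M=11.0, k_cat=3.95, K_i=4.3, K_p=DEFAULT_K_P)
F216S_PARAMS = KineticParameters(K_M=284.0, k_cat=3.99, K_i=59.2, K_p=DEFAULT_K_P)
#: wild-type kinetics under the plain sequential scheme used for
#: time-resolved spectra (the deconvolution model carries no product
#: inhibition, so its generator must not either)
WT_SEQ_PARAMS = KineticParameters(K_M=11.0, k_cat=3.95)

_E_UOX = 0.9  # uM, the assay's Uox concentration
_S0 = 100.0  # uM, 0.1 mM urate

_KP_KWARGS = dict(k_HIU=0.006, k_OHCU=0.004, buffer_label="KP pH 7.6")
_BORATE_KWARGS = dict(k_HIU=0.03, k_OHCU=0.004, buffer_label="borate pH 9.2")


def _build_scenarios() -> dict:
    wt_cond = AssayConditions(
        substrate_0=_S0, enzymes=(_uox(_E_UOX, WT_PARAMS), _urah(_E_UOX)), **_KP_KWARGS
    )
    f216s_cond = AssayConditions(
        substrate_0=_S0, enzymes=(_uox(_E_UOX, F216S_PARAMS), _urah(_E_UOX)), **_KP_KWARGS
    )
    wt_borate = AssayConditions(
        substrate_0=_S0, enzymes=(_uox(_E_UOX, WT_PARAMS),), **_BORATE_KWARGS
    )
    hiu_cond = AssayConditions(
        substrate_0=_S0, enzymes=(_uox(_E_UOX, WT_PARAMS),), **_KP_KWARGS
    )
    # time-resolved-spectra schemes generate under the plain sequential
    # model (no product inhibition, quenching enzyme effectively
    # instantaneous), matching the deconvolution analysis assumptions
    trs_urad = AssayConditions(
        substrate_0=_S0,
        enzymes=(_uox(_E_UOX, WT_SEQ_PARAMS), EnzymeSpec("Urad", _E_UOX, first_order_efficiency=1e6)),
        k_HIU=0.006, k_OHCU=0.0, buffer_label="KP pH 7.6",
    )
    trs_urah = AssayConditions(
        substrate_0=_S0,
        enzymes=(_uox(_E_UOX, WT_SEQ_PARAMS), EnzymeSpec("Urah", _E_UOX, first_order_efficiency=1e6)),
        k_HIU=0.0, k_OHCU=0.004, buffer_label="KP pH 7.6",
    )
    wt_S = tuple(11.0 * np.array([0.25, 0.5, 1, 2, 4, 8, 16, 32]))
    f216s_S = (25.0, 50.0, 100.0, 200.0, 300.0, 400.0, 600.0, 800.0)
    return {
        "wt-KP-292": Scenario(
            "wt-KP-292", WT_PARAMS, wt_cond, 292.0, wt_S, (0.0, 4.3, 12.9, 43.0)
        ),
        "F216S-KP-292": Scenario(
            "F216S-KP-292", F216S_PARAMS, f216s_cond, 292.0, f216s_S,
            (0.0, 59.2, 177.6, 592.0),
        ),
        "wt-borate-292": Scenario(
            "wt-borate-292", WT_PARAMS, wt_borate, 292.0, wt_S, (0.0,)
        ),
        "F216S-xanthine-302": Scenario(
            "F216S-xanthine-302", F216S_PARAMS, f216s_cond, 302.0, f216s_S,
            (0.0, 30.0, 60.0, 120.0),
        ),
        "HIU-320": Scenario("HIU-320", WT_PARAMS, hiu_cond, 320.0, wt_S, (0.0,)),
        "TRS-UoxUrad": Scenario(
            "TRS-UoxUrad", WT_SEQ_PARAMS, trs_urad, 292.0, wt_S, (0.0,)
        ),
        "TRS-UoxUrah": Scenario(
            "TRS-UoxUrah", WT_SEQ_PARAMS, trs_urah, 292.0, wt_S, (0.0,)
        ),
    }


SCENARIOS = _build_scenarios()

_PARAM_FIELDS = {f.name for f in fields(KineticParameters)}
_COND_FIELDS = {f.name for f in fields(AssayConditions)}


def scenario(cfg_or_name, overrides: Optional[dict] = None) -> Scenario:
    """Resolve a scenario by name or from a GeneratorConfig, with overrides.

    Unknown override keys are rejected.
    """
    if isinstance(cfg_or_name, GeneratorConfig):
        name = cfg_or_name.scenario
        overrides = {**cfg_or_name.overrides, **(overrides or {})}
        if name is None:
            raise ValueError("GeneratorConfig has no scenario set")
    else:
        name = cfg_or_name
        overrides = dict(overrides or {})
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    sc = SCENARIOS[name]

    unknown = set(overrides) - _PARAM_FIELDS - _COND_FIELDS - {"wavelength"}
    if unknown:
        raise ValueError(f"unknown override keys {sorted(unknown)}")

    param_over = {k: v for k, v in overrides.items() if k in _PARAM_FIELDS}
    cond_over = {k: v for k, v in overrides.items() if k in _COND_FIELDS}
    params = replace(sc.params, **param_over) if param_over else sc.params
    cond = replace(sc.conditions, **cond_over) if cond_over else sc.conditions
    if param_over:
        # keep the Uox enzyme entry in sync with the overridden kinetics
        enzymes = tuple(
            _uox(e.concentration, params) if e.name == "Uox" else e for e in cond.enzymes
        )
        cond = cond.with_enzymes(enzymes)
    wl = float(overrides.get("wavelength", sc.wavelength))
    return replace(sc, params=params, conditions=cond, wavelength=wl)


# ---------------------------------------------------------------------------
# synthetic reference spectra
# ---------------------------------------------------------------------------


def default_true_spectra(wavelengths: Optional[np.ndarray] = None) -> list:
    """Synthetic UV spectra of the four species on [220, 340] nm.

    Gaussian band shapes anchored so that the 292 nm molar absorptivities
    equal the package calibration values (urate 12.2, HIU 6.1 = 50% of
    urate, OHCU 0.3 mM^-1 cm^-1, allantoin transparent).  The shapes are
    synthetic stand-ins for the experimentally derived spectra, which are
    not tabulated anywhere in the source.
    """
    if wavelengths is None:
        wavelengths = np.arange(220.0, 341.0, 2.0)
    wl = np.asarray(wavelengths, dtype=float)

    def anchored(shape_fn, at=292.0, value=1.0):
        ref = shape_fn(np.array([at]))[0]
        return value / ref * shape_fn(wl)

    def _urate_shape(w):
        return (np.exp(-0.5 * ((w - 292.0) / 16.0) ** 2)
                + 0.9 * np.exp(-0.5 * ((w - 235.0) / 11.0) ** 2))

    def _hiu_shape(w):
        return (np.exp(-0.5 * ((w - 300.0) / 20.0) ** 2)
                + 0.5 * np.exp(-0.5 * ((w - 240.0) / 14.0) ** 2))

    def _ohcu_shape(w):
        return np.exp(-0.5 * ((w - 255.0) / 20.0) ** 2)

    urate = anchored(_urate_shape, value=EPSILON_292["urate"])
    hiu = anchored(_hiu_shape, value=EPSILON_292["hiu"])
    ohcu = anchored(_ohcu_shape, value=EPSILON_292["ohcu"])
    allantoin = np.zeros_like(wl)
    return [
        AbsorptionSpectrum("urate", wl, urate),
        AbsorptionSpectrum("hiu", wl, hiu),
        AbsorptionSpectrum("ohcu", wl, ohcu),
        AbsorptionSpectrum("allantoin", wl, allantoin),
    ]


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _vmax(cond: AssayConditions) -> float:
    uox = cond.enzyme("Uox")
    return uox.parameters.k_cat * uox.concentration


def _default_grid(cond: AssayConditions, n: int = 1201) -> np.ndarray:
    """Time grid long enough for near-complete conversion."""
    t_total = 6.0 * cond.substrate_0 / _vmax(cond)
    return np.linspace(0.0, t_total, n)


def gen_rate_dataset(
    cfg: GeneratorConfig,
    params: Optional[KineticParameters] = None,
    substrate_grid: Optional[Sequence[float]] = None,
    inhibitor_levels: Optional[Sequence[float]] = None,
    enzyme_conc: Optional[float] = None,
    stream: int = 0,
) -> RateDataset:
    """Initial-velocity dataset over a substrate x inhibitor grid.

    True rates come from the competitive-inhibition rate law (no HIU term:
    the assay is run with Urah, so HIU never accumulates during the
    initial-velocity measurement); noise is multiplicative Gaussian with
    relative sd ``cfg.noise_sd_rate``.
    """
    sc = scenario(cfg) if cfg.scenario else None
    if params is None:
        params = sc.params
    if substrate_grid is None:
        substrate_grid = sc.substrate_grid
    if inhibitor_levels is None:
        inhibitor_levels = sc.inhibitor_levels if sc else (0.0,)
    if enzyme_conc is None:
        enzyme_conc = sc.conditions.enzyme("Uox").concentration if sc else _E_UOX

    S = np.asarray(substrate_grid, dtype=float)
    if S.size == 0 or len(inhibitor_levels) == 0:
        raise ValueError("grids must be non-empty")
    SS = np.tile(S, len(inhibitor_levels))
    II = np.repeat(np.asarray(inhibitor_levels, dtype=float), len(S))
    bracket = 1.0 + (II / params.K_i if params.K_i is not None else 0.0)
    v = params.k_cat * enzyme_conc * SS / (params.K_M * bracket + SS)
    if cfg.noise_sd_rate > 0:
        z = cfg.rng(stream).standard_normal(v.shape)
        v = np.clip(v * (1.0 + cfg.noise_sd_rate * z), 0.0, None)
    return RateDataset(substrate=SS, velocity=v, inhibitor=II, enzyme_conc=enzyme_conc)


def gen_progress_curves(
    cfg: GeneratorConfig,
    params: Optional[KineticParameters] = None,
    cond: Optional[AssayConditions] = None,
    n_curves: int = 1,
    wavelength: Optional[float] = None,
    spectra: Optional[list] = None,
    t_grid: Optional[np.ndarray] = None,
    path: float = 1.0,
) -> list:
    """Simulated absorbance progress curves with additive Gaussian noise.

    The noiseless trace is simulated once (reaction network then
    Beer-Lambert projection); each returned curve adds independent noise
    from its own deterministic substream of ``cfg.seed``.
    """
    if n_curves < 1:
        raise ValueError("n_curves must be >= 1")
    sc = scenario(cfg) if cfg.scenario else None
    if params is None:
        params = sc.params
    if cond is None:
        cond = sc.conditions
    if wavelength is None:
        wavelength = sc.wavelength if sc else 292.0
    if spectra is None:
        spectra = default_true_spectra()
    if t_grid is None:
        t_grid = _default_grid(cond)

    series = simulate_uricolysis(cond, params, t_grid)
    clean = absorbance_project(series, spectra, wavelength, path)
    out = []
    for i in range(n_curves):
        A = clean.absorbance
        if cfg.noise_sd_abs > 0:
            A = A + cfg.noise_sd_abs * cfg.rng(i).standard_normal(A.shape)
        out.append(AbsorbanceTrace(wavelength, path, t_grid, A))
    return out


class SpectraTruth(NamedTuple):
    matrix: SpectraMatrix
    spectra: list
    params: KineticParameters
    conditions: AssayConditions


def gen_time_resolved_spectra(
    cfg: GeneratorConfig,
    scheme: str = "Uox+Urad",
    spectra_truth: Optional[list] = None,
    cond: Optional[AssayConditions] = None,
    params: Optional[KineticParameters] = None,
    t_grid: Optional[np.ndarray] = None,
    path: float = 1.0,
    stream: int = 0,
) -> SpectraTruth:
    """Time x wavelength absorbance matrix with stored generating truth.

    ``scheme`` is "Uox+Urad" (HIU accumulates; OHCU quenched) or
    "Uox+Urah" (OHCU accumulates; HIU quenched).  The matrix is the
    Beer-Lambert combination of all species' truth spectra plus additive
    Gaussian noise of sd ``cfg.noise_sd_abs``.
    """
    preset = {"Uox+Urad": "TRS-UoxUrad", "Uox+Urah": "TRS-UoxUrah"}
    if scheme not in preset:
        raise ValueError(f"unknown scheme {scheme!r}")
    sc = scenario(cfg) if cfg.scenario else scenario(preset[scheme], None)
    if params is None:
        params = sc.params
    if cond is None:
        cond = scenario(preset[scheme], None).conditions
    if spectra_truth is None:
        spectra_truth = default_true_spectra()
    if t_grid is None:
        t_grid = _default_grid(cond, n=301)

    series = simulate_uricolysis(cond, params, t_grid)
    wl = spectra_truth[0].wavelengths
    for s in spectra_truth:
        if not np.array_equal(s.wavelengths, wl):
            raise ValueError("all truth spectra must share one wavelength grid")
    eps = np.vstack([s.epsilon for s in spectra_truth])  # (n_species, n_wl)
    C = np.column_stack([series.concentration(s.species) for s in spectra_truth])
    A = path * C @ eps / 1000.0
    if cfg.noise_sd_abs > 0:
        A = A + cfg.noise_sd_abs * cfg.rng(stream).standard_normal(A.shape)
    matrix = SpectraMatrix(times=t_grid, wavelengths=wl, absorbance=A, path_length=path)
    return SpectraTruth(matrix=matrix, spectra=spectra_truth, params=params, conditions=cond)


def gen_ratio_scan(
    cfg: GeneratorConfig,
    ratios: Sequence[float],
    params: Optional[KineticParameters] = None,
    cond: Optional[AssayConditions] = None,
    wavelength: float = 292.0,
    spectra: Optional[list] = None,
    noiseless: bool = True,
) -> list:
    """Paired assays at different Urah:Uox molar ratios.

    Returns ``[(ratio, AbsorbanceTrace), ...]``; ratio 0 is the assay
    without Urah.  The apparent initial velocity is non-decreasing in the
    ratio (more quenching never slows the apparent rate) and plateaus once
    Urah is in excess.
    """
    if any(r < 0 for r in ratios):
        raise ValueError("ratios must be >= 0")
    sc = scenario(cfg) if cfg.scenario else scenario("wt-KP-292", None)
    if params is None:
        params = sc.params
    if cond is None:
        cond = sc.conditions
    if spectra is None:
        spectra = default_true_spectra()
    uox = cond.enzyme("Uox")
    if uox is None:
        raise ValueError("conditions must include Uox")
    base = tuple(e for e in cond.enzymes if e.name != "Urah")
    t_grid = _default_grid(cond)

    out = []
    for i, r in enumerate(ratios):
        enz = base if r == 0 else base + (_urah(r * uox.concentration),)
        series = simulate_uricolysis(cond.with_enzymes(enz), params, t_grid)
        trace = absorbance_project(series, spectra, wavelength, 1.0)
        if not noiseless and cfg.noise_sd_abs > 0:
            A = trace.absorbance + cfg.noise_sd_abs * cfg.rng(i).standard_normal(
                trace.absorbance.shape
            )
            trace = AbsorbanceTrace(wavelength, 1.0, t_grid, A)
        out.append((float(r), trace))
    return out


def plateau_ratio(
    scan: Sequence[tuple],
    delta_eps: float,
    tol: float = 0.05,
) -> tuple[float, np.ndarray]:
    """Smallest Urah:Uox ratio whose apparent v0 is within ``tol`` of the max.

    Returns ``(ratio, v0_array)`` with v0 per scan entry.
    """
    v0 = np.array([initial_velocity(tr, delta_eps) for _r, tr in scan])
    vmax = v0.max()
    for (r, _tr), v in zip(scan, v0):
        if v >= (1.0 - tol) * vmax:
            return float(r), v0
    return float(scan[-1][0]), v0
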