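"""Reaction-network kinetics of oxidative uricolysis.

Uricolysis converts urate into (S)-allantoin in three steps:

    urate --Uox--> HIU --(Urah | spontaneous)--> OHCU --(Urad | spontaneous)--> allantoin

Urate oxidase (Uox) is the rate-limiting enzyme and follows Michaelis-Menten
kinetics with competitive inhibition by xanthine and, when the first
intermediate 5-hydroxyisourate (HIU) accumulates, competitive product
inhibition.  HIU and OHCU are unstable: each decays spontaneously with a
buffer-dependent first-order rate and can also be removed enzymatically by
HIU hydrolase (Urah) and OHCU decarboxylase (Urad).

This module provides

* an internal principal-branch Lambert-W kernel (Halley iteration),
* the closed-form integrated Michaelis-Menten substrate time course
  (Schell-Mendoza form, built on Lambert W),
* the pointwise Michaelis-Menten rate law with competitive inhibition terms,
* a stiff-capable ODE simulator of the full four-species network, and
* the catalytic-efficiency helper k_cat/K_M.

Units are fixed package-wide: concentrations in uM, time in s, path length
in cm, molar absorptivities in mM^-1 cm^-1.  The only unit conversion in the
package is in :func:`catalytic_efficiency`, which reports M^-1 s^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "KineticParameters",
    "EnzymeSpec",
    "AssayConditions",
    "ConcentrationSeries",
    "SolverError",
    "lambert_w0",
    "integrated_mm_substrate",
    "mm_rate",
    "simulate_uricolysis",
    "catalytic_efficiency",
    "round_sig",
]

#: branch point of the principal Lambert-W branch, -1/e
_NEG_INV_E = -math.exp(-1.0)

SPECIES = ("urate", "hiu", "ohcu", "allantoin")

#: calibration first-order catalytic efficiency (uM^-1 s^-1, i.e. k_cat/K_M)
#: assigned to the quenching enzymes Urah/Urad when only a molar ratio is
#: specified.  Urah's measured specific activity (~230 umol min^-1 mg^-1,
#: ~14.5 kDa subunit) implies k_cat ~ 55 s^-1; with a low-micromolar K_M for
#: HIU this puts k_cat/K_M at ~3e7 M^-1 s^-1 = 30 uM^-1 s^-1, and makes a
#: 1:1 Urah:Uox molar ratio a >10-fold excess of enzyme units.
DEFAULT_QUENCH_EFFICIENCY = 30.0

#: calibration competitive product-inhibition constant of HIU on Uox (uM).
#: Not directly measurable from single-wavelength data; chosen so that the
#: simulated no-Urah assay is suppressed
#: several-fold beyond pure spectral interference, the direction and rough
#: magnitude of the reported observation.
DEFAULT_K_P = 1.0


class SolverError(RuntimeError):
    """ODE integration failed; the message carries the diagnostic state."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KineticParameters:
    """Michaelis-Menten parameters of an enzyme.

    Parameters
    ----------
    K_M : float
        Michaelis constant for the substrate (uM).
    k_cat : float
        Turnover number (s^-1).
    K_i : float, optional
        Competitive inhibition constant for a dead-end inhibitor
        (xanthine for Uox), uM.  ``None`` means no inhibitor term.
    K_p : float, optional
        Competitive product-inhibition constant for HIU (uM).
        ``None`` means no product inhibition.
    """

    K_M: float
    k_cat: float
    K_i: Optional[float] = None
    K_p: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("K_M", "k_cat"):
            v = getattr(self, name)
            if not (v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        for name in ("K_i", "K_p"):
            v = getattr(self, name)
            if v is not None and not (v > 0):
                raise ValueError(f"{name} must be strictly positive when given, got {v!r}")


@dataclass(frozen=True)
class EnzymeSpec:
    """One enzyme in the assay mix.

    Urah and Urad typically operate far below their Michaelis constants for
    HIU/OHCU, so they may be described by a first-order catalytic efficiency
    (``first_order_efficiency``, uM^-1 s^-1, i.e. k_cat/K_M in package
    units); the effective removal rate constant is then
    ``first_order_efficiency * concentration``.  Exactly one of
    ``parameters`` and ``first_order_efficiency`` must be given.
    """

    name: str
    concentration: float
    parameters: Optional[KineticParameters] = None
    first_order_efficiency: Optional[float] = None

    def __post_init__(self) -> None:
        if self.name not in ("Uox", "Urah", "Urad"):
            raise ValueError(f"unknown enzyme name {self.name!r}")
        if self.concentration < 0:
            raise ValueError("enzyme concentration must be >= 0")
        n_desc = (self.parameters is not None) + (self.first_order_efficiency is not None)
        if n_desc != 1:
            raise ValueError(
                "exactly one kinetic description (parameters or "
                "first_order_efficiency) must be present"
            )
        if self.first_order_efficiency is not None and self.first_order_efficiency < 0:
            raise ValueError("first_order_efficiency must be >= 0")

    def first_order_rate(self) -> Optional[float]:
        """Effective first-order rate constant (s^-1), if first-order."""
        if self.first_order_efficiency is None:
            return None
        return self.first_order_efficiency * self.concentration


@dataclass(frozen=True)
class AssayConditions:
    """Composition and buffer of one uricolysis assay.

    ``k_HIU`` and ``k_OHCU`` are the spontaneous (non-enzymatic) first-order
    decay rates of the two intermediates; both are buffer dependent (HIU
    decays several-fold faster in borate at high pH than in potassium
    phosphate at pH 7.6).
    """

    substrate_0: float
    enzymes: tuple[EnzymeSpec, ...] = ()
    inhibitor_0: float = 0.0
    k_HIU: float = 0.006
    k_OHCU: float = 0.004
    buffer_label: str = "KP pH 7.6"
    temperature_label: str = "25 C"

    def __post_init__(self) -> None:
        if not (self.substrate_0 > 0):
            raise ValueError("substrate_0 must be strictly positive")
        if self.inhibitor_0 < 0:
            raise ValueError("inhibitor_0 must be >= 0")
        if self.k_HIU < 0 or self.k_OHCU < 0:
            raise ValueError("decay rates must be >= 0")
        object.__setattr__(self, "enzymes", tuple(self.enzymes))

    def enzyme(self, name: str) -> Optional[EnzymeSpec]:
        for e in self.enzymes:
            if e.name == name:
                return e
        return None

    def with_enzymes(self, enzymes: Sequence[EnzymeSpec]) -> "AssayConditions":
        return replace(self, enzymes=tuple(enzymes))


@dataclass
class ConcentrationSeries:
    """Time courses of the four uricolysis species (uM).

    Mass is conserved: urate + HIU + OHCU + allantoin equals the initial
    substrate at every time, within solver tolerance.  Tiny negative solver
    excursions are clipped to zero on construction (reporting only).
    """

    times: np.ndarray
    urate: np.ndarray
    hiu: np.ndarray
    ohcu: np.ndarray
    allantoin: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValueError("times must be a 1-D array with >= 2 points")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        for name in SPECIES:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.times.shape:
                raise ValueError(f"{name} must match times in shape")
            setattr(self, name, np.clip(arr, 0.0, None))

    def concentration(self, species: str) -> np.ndarray:
        if species not in SPECIES:
            raise KeyError(species)
        return getattr(self, species)

    def as_matrix(self) -> np.ndarray:
        """(n_times, 4) matrix in the canonical species order."""
        return np.column_stack([getattr(self, s) for s in SPECIES])

    def total(self) -> np.ndarray:
        return self.as_matrix().sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "urate_uM": self.urate,
                "hiu_uM": self.hiu,
                "ohcu_uM": self.ohcu,
                "allantoin_uM": self.allantoin,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ConcentrationSeries":
        return cls(
            times=df["time_s"].to_numpy(),
            urate=df["urate_uM"].to_numpy(),
            hiu=df["hiu_uM"].to_numpy(),
            ohcu=df["ohcu_uM"].to_numpy(),
            allantoin=df["allantoin_uM"].to_numpy(),
        )


# ---------------------------------------------------------------------------
# Lambert W
# ---------------------------------------------------------------------------


def _halley_refine(w: np.ndarray, x: np.ndarray, tol: float = 0.5e-12) -> np.ndarray:
    """Halley iteration on f(w) = w*exp(w) - x from a good initial guess."""
    w = np.array(w, dtype=float)
    x = np.asarray(x, dtype=float)
    scale = np.maximum(1.0, np.abs(x))
    for _ in range(100):
        ew = np.exp(w)
        f = w * ew - x
        active = np.abs(f) > tol * scale
        if not np.any(active):
            break
        fp = ew * (w + 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = (w + 2.0) * f / (2.0 * w + 2.0)
            corr = np.where(np.isfinite(corr), corr, 0.0)
            denom = fp - corr
            step = f / denom
        # step only where active and well-defined; at the branch point
        # (w = -1, f = 0) the entry is already converged and stays put
        step = np.where(active & np.isfinite(step), step, 0.0)
        w = w - step
    return w


def lambert_w0(x):
    """Principal branch W0 of the Lambert W function.

    Solves ``w * exp(w) = x`` for ``w >= -1``, defined for ``x >= -1/e``.
    Computed by Halley iteration from a branch-point series (near -1/e) or
    logarithmic asymptotic (large x) initial guess, to an absolute residual
    ``|w e^w - x| <= 1e-12 * max(1, |x|)``.

    Accepts scalars or arrays; returns the same shape.

    Raises
    ------
    ValueError
        If any ``x < -1/e`` (beyond floating-point rounding of the branch
        point itself).
    """
    x_arr = np.asarray(x, dtype=float)
    scalar = x_arr.ndim == 0
    x_arr = np.atleast_1d(x_arr).copy()

    below = x_arr < _NEG_INV_E
    if np.any(below):
        if np.any(_NEG_INV_E - x_arr[below] > 1e-12):
            bad = float(x_arr[below].min())
            raise ValueError(f"lambert_w0 domain error: x = {bad} < -1/e")
        x_arr[below] = _NEG_INV_E  # rounding-level clamp onto the branch point

    w = np.empty_like(x_arr)

    # branch-point series in p = sqrt(2 (e x + 1)) for x close to -1/e
    near = x_arr < -0.32
    if np.any(near):
        p = np.sqrt(2.0 * (math.e * x_arr[near] + 1.0))
        w[near] = -1.0 + p - p**2 / 3.0 + 11.0 * p**3 / 72.0 - 43.0 * p**4 / 540.0

    # moderate arguments: log1p is exact at 0 and a serviceable guess
    mid = (~near) & (x_arr < 3.0)
    if np.any(mid):
        w[mid] = np.log1p(x_arr[mid])

    # large arguments: w ~ ln x - ln ln x
    big = x_arr >= 3.0
    if np.any(big):
        lx = np.log(x_arr[big])
        w[big] = lx - np.log(lx)

    w = _halley_refine(w, x_arr)
    return float(w[0]) if scalar else w


def _lambert_w0_of_exp(y):
    """W0(exp(y)) computed without overflow for large y.

    For y <= 300, exp(y) is representable and :func:`lambert_w0` is used.
    For larger y the defining relation is solved in logarithmic form,
    w + ln w = y, by Newton iteration from w0 = y - ln y.  For very
    negative y, W0(e^y) ~ e^y to double precision.
    """
    y_arr = np.atleast_1d(np.asarray(y, dtype=float))
    scalar = np.asarray(y, dtype=float).ndim == 0
    w = np.empty_like(y_arr)

    tiny = y_arr < -36.0
    w[tiny] = np.exp(y_arr[tiny])

    mid = (~tiny) & (y_arr <= 300.0)
    if np.any(mid):
        w[mid] = lambert_w0(np.exp(y_arr[mid]))

    big = y_arr > 300.0
    if np.any(big):
        yb = y_arr[big]
        wb = yb - np.log(yb)
        for _ in range(50):
            g = wb + np.log(wb) - yb
            if np.all(np.abs(g) <= 1e-14 * np.maximum(1.0, yb)):
                break
            wb = wb - g / (1.0 + 1.0 / wb)
        w[big] = wb

    return float(w[0]) if scalar else w


# ---------------------------------------------------------------------------
# rate laws and closed form
# ---------------------------------------------------------------------------


def integrated_mm_substrate(t, S0: float, Vmax: float, K_M: float):
    """Substrate time course of the integrated Michaelis-Menten rate law.

    Closed-form solution of ``dS/dt = -Vmax*S/(K_M+S)`` with ``S(0) = S0``::

        S(t) = K_M * W0( (S0/K_M) * exp((S0 - Vmax*t)/K_M) )

    evaluated through the principal Lambert-W branch in a logarithmic form
    that does not overflow when ``S0 >> K_M``.

    Parameters are in package units (uM, s); ``t`` may be a scalar or array
    of times >= 0.
    """
    for name, v in (("S0", S0), ("Vmax", Vmax), ("K_M", K_M)):
        if not (v > 0):
            raise ValueError(f"{name} must be strictly positive, got {v!r}")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    y = math.log(S0 / K_M) + (S0 - Vmax * t_arr) / K_M
    return K_M * _lambert_w0_of_exp(y)


def mm_rate(S, I=0.0, H=0.0, E=1.0, p: KineticParameters = None):
    """Michaelis-Menten rate with optional competitive inhibition terms.

    ::

        v = k_cat * E * S / ( K_M * (1 + I/K_i + H/K_p) + S )

    where the xanthine term ``I/K_i`` and HIU product term ``H/K_p`` are
    omitted when the corresponding constant is absent from ``p``.
    The rate never exceeds ``k_cat * E``; infinite ``S`` returns exactly
    that saturating value.
    """
    if p is None:
        raise ValueError("KineticParameters p is required")
    S_arr = np.asarray(S, dtype=float)
    I_arr = np.asarray(I, dtype=float)
    H_arr = np.asarray(H, dtype=float)
    if np.any(S_arr < 0) or np.any(I_arr < 0) or np.any(H_arr < 0) or E < 0:
        raise ValueError("concentrations must be >= 0")
    shape = np.broadcast_shapes(S_arr.shape, I_arr.shape, H_arr.shape)
    bracket = np.ones(shape, dtype=float)
    if p.K_i is not None:
        bracket = bracket + I_arr / p.K_i
    if p.K_p is not None:
        bracket = bracket + H_arr / p.K_p
    vmax = p.k_cat * E
    with np.errstate(invalid="ignore"):
        v = np.where(
            np.isinf(S_arr),
            vmax,
            vmax * S_arr / (p.K_M * bracket + S_arr),
        )
    return float(v) if v.ndim == 0 else v


def _removal_rate(spec: Optional[EnzymeSpec], substrate: float) -> float:
    """Enzymatic removal rate (uM/s) of an intermediate by Urah or Urad."""
    if spec is None or spec.concentration == 0.0:
        return 0.0
    k1 = spec.first_order_rate()
    if k1 is not None:
        return k1 * substrate
    q = spec.parameters
    return q.k_cat * spec.concentration * substrate / (q.K_M + substrate)


def simulate_uricolysis(
    cond: AssayConditions,
    uox: KineticParameters,
    t_grid: Sequence[float],
) -> ConcentrationSeries:
    """Integrate the four-species uricolysis network on a time grid.

    The network is::

        dU/dt = -v_Uox(U; I0, H)
        dH/dt =  v_Uox - k_HIU*H - v_Urah(H)
        dO/dt =  k_HIU*H + v_Urah(H) - k_OHCU*O - v_Urad(O)
        dA/dt =  k_OHCU*O + v_Urad(O)

    with v_Uox the competitive-inhibition rate law of :func:`mm_rate`
    (xanthine at the fixed initial concentration ``cond.inhibitor_0``; HIU
    product inhibition active only when ``uox.K_p`` is set).  The Uox
    concentration is taken from the "Uox" entry of ``cond.enzymes`` (zero if
    absent).  Integration is adaptive and stiff-capable (LSODA, rtol 1e-8,
    atol 1e-10 uM); derivatives are evaluated on the raw state, and only the
    reported series is clipped at zero.

    Raises
    ------
    SolverError
        If the integrator fails; the message reports the solver status and
        the time and state reached.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or len(t) < 2:
        raise ValueError("t_grid must be 1-D with >= 2 points")
    if t[0] != 0.0:
        raise ValueError("t_grid must start at 0")
    if not np.all(np.diff(t) > 0):
        raise ValueError("t_grid must be strictly increasing")

    uox_spec = cond.enzyme("Uox")
    E_uox = uox_spec.concentration if uox_spec is not None else 0.0
    urah = cond.enzyme("Urah")
    urad = cond.enzyme("Urad")
    I0 = cond.inhibitor_0
    k_hiu, k_ohcu = cond.k_HIU, cond.k_OHCU

    kcat_E = uox.k_cat * E_uox
    base_bracket = 1.0 + (I0 / uox.K_i if uox.K_i is not None else 0.0)
    inv_Kp = 1.0 / uox.K_p if uox.K_p is not None else 0.0

    def rhs(_t, y):
        # raw solver state on purpose: tiny negative excursions self-correct
        # through the rate law and are clipped only in the reported series
        U, H, O, _A = y
        v_uox = kcat_E * U / (uox.K_M * (base_bracket + H * inv_Kp) + U) if E_uox > 0 else 0.0
        v_urah = _removal_rate(urah, H)
        v_urad = _removal_rate(urad, O)
        dU = -v_uox
        dH = v_uox - k_hiu * H - v_urah
        dO = k_hiu * H + v_urah - k_ohcu * O - v_urad
        dA = k_ohcu * O + v_urad
        return (dU, dH, dO, dA)

    y0 = (cond.substrate_0, 0.0, 0.0, 0.0)
    sol = solve_ivp(
        rhs,
        (t[0], t[-1]),
        y0,
        method="LSODA",
        t_eval=t,
        rtol=1e-8,
        atol=1e-10,
    )
    if not sol.success:
        reached = sol.t[-1] if len(sol.t) else t[0]
        state = sol.y[:, -1] if sol.y.size else y0
        raise SolverError(
            f"uricolysis ODE integration failed (status {sol.status}: "
            f"{sol.message}) at t = {reached:.6g} s, state = {np.asarray(state)}"
        )
    U, H, O, A = sol.y
    return ConcentrationSeries(times=t, urate=U, hiu=H, ohcu=O, allantoin=A)


def catalytic_efficiency(k_cat: float, K_M: float) -> float:
    """Catalytic efficiency k_cat/K_M in M^-1 s^-1.

    ``k_cat`` in s^-1 and ``K_M`` in uM; the factor 1e-6 converts uM to M.
    This is the only place in the package where units leave the native
    uM/s system.  Use :func:`round_sig` to present at 2 significant figures.
    """
    if not (k_cat > 0) or not (K_M > 0):
        raise ValueError("k_cat and K_M must be strictly positive")
    return k_cat / (K_M * 1e-6)


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (used for reporting k_cat/K_M)."""
    if x == 0:
        return 0.0
    if not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))
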