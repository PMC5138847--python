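"""CSV and JSON round-trip I/O for all pipeline objects.

Dialect: comma-separated, ``.`` decimal, UTF-8, ``#`` comment lines.
Column headers carry unit suffixes (``time_s``, ``urate_uM``, ...) so unit
mismatches fail loudly.  Trace and matrix metadata (wavelength, path
length) travel in ``#``-prefixed header lines and survive the round trip.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .fitting import FitResult, RateDataset
from .kinetics import ConcentrationSeries
from .spectroscopy import AbsorbanceTrace, AbsorptionSpectrum, SpectraMatrix

__all__ = [
    "ParseError",
    "read_trace", "write_trace",
    "read_matrix", "write_matrix",
    "read_rates", "write_rates",
    "read_series", "write_series",
    "read_spectrum", "write_spectrum",
    "read_fit_result", "write_fit_result",
]

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line or column."""


def _read_csv(path: PathLike, required: list) -> tuple[pd.DataFrame, dict]:
    """Read a dialect CSV, returning the frame and `# key: value` metadata."""
    path = Path(path)
    meta = {}
    body = []
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise ParseError(f"{path}: cannot read file ({exc})") from exc
    for line in text.splitlines():
        if line.startswith("#"):
            stripped = line[1:].strip()
            if ":" in stripped:
                k, v = stripped.split(":", 1)
                meta[k.strip()] = v.strip()
        elif line.strip():
            body.append(line)
    if not body:
        raise ParseError(f"{path}: no data rows")
    try:
        df = pd.read_csv(_io.StringIO("\n".join(body)))
    except Exception as exc:
        raise ParseError(f"{path}: malformed CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(
            f"{path}: missing required columns {missing} (found {list(df.columns)}; "
            "check the unit suffixes)"
        )
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax())
        raise ParseError(f"{path}: non-numeric or empty value in data row {row}")
    return df, meta


def _check_monotone(path: PathLike, values: np.ndarray, label: str) -> None:
    d = np.diff(values)
    if np.any(d <= 0):
        row = int(np.argmax(d <= 0)) + 1
        raise ParseError(f"{path}: {label} not strictly increasing at data row {row}")


# -- ConcentrationSeries -----------------------------------------------------

_SERIES_COLS = ["time_s", "urate_uM", "hiu_uM", "ohcu_uM", "allantoin_uM"]


def write_series(series: ConcentrationSeries, path: PathLike) -> None:
    series.to_frame().to_csv(path, index=False)


def read_series(path: PathLike) -> ConcentrationSeries:
    df, _ = _read_csv(path, _SERIES_COLS)
    _check_monotone(path, df["time_s"].to_numpy(), "time_s")
    return ConcentrationSeries.from_frame(df)


# -- AbsorbanceTrace ---------------------------------------------------------


def write_trace(trace: AbsorbanceTrace, path: PathLike) -> None:
    header = (
        f"# wavelength_nm: {trace.wavelength:g}\n"
        f"# path_length_cm: {trace.path_length:g}\n"
    )
    Path(path).write_text(header + trace.to_frame().to_csv(index=False), encoding="utf-8")


def read_trace(path: PathLike) -> AbsorbanceTrace:
    df, meta = _read_csv(path, ["time_s", "absorbance"])
    _check_monotone(path, df["time_s"].to_numpy(), "time_s")
    try:
        wavelength = float(meta.get("wavelength_nm", "nan"))
        path_length = float(meta.get("path_length_cm", 1.0))
    except ValueError as exc:
        raise ParseError(f"{path}: bad metadata header ({exc})") from exc
    return AbsorbanceTrace(
        wavelength=wavelength,
        path_length=path_length,
        times=df["time_s"].to_numpy(),
        absorbance=df["absorbance"].to_numpy(),
    )


# -- SpectraMatrix -----------------------------------------------------------


def write_matrix(matrix: SpectraMatrix, path: PathLike) -> None:
    header = f"# path_length_cm: {matrix.path_length:g}\n"
    Path(path).write_text(header + matrix.to_frame().to_csv(index=False), encoding="utf-8")


def read_matrix(path: PathLike) -> SpectraMatrix:
    df, meta = _read_csv(path, ["time_s"])
    _check_monotone(path, df["time_s"].to_numpy(), "time_s")
    wl_cols = [c for c in df.columns if c != "time_s"]
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise ParseError(
            f"{path}: wavelength column labels must be numeric nm values ({exc})"
        ) from exc
    _check_monotone(path, wavelengths, "wavelength columns")
    return SpectraMatrix(
        times=df["time_s"].to_numpy(),
        wavelengths=wavelengths,
        absorbance=df[wl_cols].to_numpy(dtype=float),
        path_length=float(meta.get("path_length_cm", 1.0)),
    )


# -- RateDataset -------------------------------------------------------------

_RATE_COLS = ["substrate_uM", "inhibitor_uM", "velocity_uM_s"]


def write_rates(data: RateDataset, path: PathLike) -> None:
    header = f"# enzyme_conc_uM: {data.enzyme_conc:g}\n"
    df = pd.DataFrame(
        {
            "substrate_uM": data.substrate,
            "inhibitor_uM": data.inhibitor,
            "velocity_uM_s": data.velocity,
        }
    )
    Path(path).write_text(header + df.to_csv(index=False), encoding="utf-8")


def read_rates(path: PathLike, enzyme_conc: float = None) -> RateDataset:
    df, meta = _read_csv(path, _RATE_COLS)
    if enzyme_conc is None:
        enzyme_conc = float(meta.get("enzyme_conc_uM", 1.0))
    try:
        return RateDataset(
            substrate=df["substrate_uM"].to_numpy(),
            inhibitor=df["inhibitor_uM"].to_numpy(),
            velocity=df["velocity_uM_s"].to_numpy(),
            enzyme_conc=enzyme_conc,
        )
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


# -- AbsorptionSpectrum ------------------------------------------------------


def write_spectrum(spectrum: AbsorptionSpectrum, path: PathLike) -> None:
    header = f"# species: {spectrum.species}\n"
    Path(path).write_text(
        header + spectrum.to_frame().to_csv(index=False), encoding="utf-8"
    )


def read_spectrum(path: PathLike) -> AbsorptionSpectrum:
    df, meta = _read_csv(path, ["wavelength_nm", "epsilon_mM_cm"])
    _check_monotone(path, df["wavelength_nm"].to_numpy(), "wavelength_nm")
    return AbsorptionSpectrum(
        species=meta.get("species", "unknown"),
        wavelengths=df["wavelength_nm"].to_numpy(),
        epsilon=df["epsilon_mM_cm"].to_numpy(),
    )


# -- FitResult ---------------------------------------------------------------


def write_fit_result(result: FitResult, path: PathLike) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=2), encoding="utf-8")


def read_fit_result(path: PathLike) -> FitResult:
    try:
        d = json.loads(Path(path).read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return FitResult(
        estimates=d["estimates"],
        standard_errors=d["standard_errors"],
        rss=d["rss"],
        n_obs=d["n_obs"],
        n_params=d["n_params"],
        log_likelihood=d["log_likelihood"],
        converged=d["converged"],
        restarts=d.get("restarts", []),
        non_identifiable=d.get("non_identifiable", False),
        poorly_determined=tuple(d.get("poorly_determined", ())),
        seed=d.get("seed"),
    )
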