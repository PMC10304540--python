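"""Readers and writers for the plain-text formats the pipeline touches.

Time series travel as two-column whitespace text in the XVG dialect: lines
starting with ``@`` are plotting directives (ignored), lines starting with
``#`` are comments, and ``# key = value`` comments are parsed as metadata.
Profiles travel as TSV with a commented header recording units, the reference
convention and the temperature; values are printed with 17 significant digits
so a write→read round trip is bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import T_DEFAULT
from .diffusion import DepthProfile, WindowForceSeries
from .pmf import FreeEnergyProfile, UmbrellaWindow


class TimeSeriesParseError(ValueError):
    """A data row could not be parsed; carries the 1-based line number."""


@dataclass(frozen=True)
class TimeSeriesData:
    dt: float
    values: np.ndarray
    meta: dict


def read_timeseries(path) -> TimeSeriesData:
    """Read an XVG-dialect two-column (time ps, value) file.

    Times must be strictly increasing and uniformly spaced to within 1e-6
    relative; ``# key = value`` header comments are returned as metadata
    (floats where possible).
    """
    path = Path(path)
    times, values, meta = [], [], {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("@"):
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    key, val = key.strip(), val.strip()
                    if key:
                        try:
                            meta[key] = float(val)
                        except ValueError:
                            meta[key] = val
                continue
            parts = line.split()
            if len(parts) != 2:
                raise TimeSeriesParseError(
                    f"{path}:{lineno}: expected two columns, got {len(parts)}"
                )
            try:
                t, v = float(parts[0]), float(parts[1])
            except ValueError:
                raise TimeSeriesParseError(
                    f"{path}:{lineno}: non-numeric row {line!r}"
                ) from None
            times.append(t)
            values.append(v)
    if not times:
        raise TimeSeriesParseError(f"{path}: no data rows")
    times = np.asarray(times)
    values = np.asarray(values)
    if times.size == 1:
        dt = float(meta.get("dt", 1.0))
    else:
        steps = np.diff(times)
        if np.any(steps <= 0):
            raise TimeSeriesParseError(f"{path}: times are not strictly increasing")
        dt = float(steps.mean())
        if np.max(np.abs(steps - dt)) > 1e-6 * max(abs(dt), 1.0):
            raise TimeSeriesParseError(
                f"{path}: non-uniform time step (max deviation "
                f"{np.max(np.abs(steps - dt)):.3e} ps)"
            )
    return TimeSeriesData(dt=dt, values=values, meta=meta)


def write_timeseries(path, dt: float, values, meta: dict | None = None) -> None:
    """Write a two-column XVG-dialect file with ``# key = value`` metadata."""
    path = Path(path)
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("refusing to write an empty time series")
    with path.open("w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key} = {val}\n")
        fh.write("@ xaxis label \"time (ps)\"\n")
        for i, v in enumerate(values):
            fh.write(f"{i * dt:.10g} {v:.17g}\n")


def read_window(path) -> UmbrellaWindow:
    """Read a ``window_<z0>.xvg`` file into an UmbrellaWindow."""
    ts = read_timeseries(path)
    try:
        z0 = ts.meta["z0"]
        k = ts.meta["k"]
    except KeyError as exc:
        raise TimeSeriesParseError(f"{path}: missing metadata key {exc}") from None
    return UmbrellaWindow(z0=z0, k=k, dt=ts.dt, samples=ts.values)


def read_force_series(path) -> WindowForceSeries:
    """Read a ``force_<z0>.xvg`` file into a WindowForceSeries."""
    ts = read_timeseries(path)
    try:
        z0 = ts.meta["z0"]
    except KeyError:
        raise TimeSeriesParseError(f"{path}: missing metadata key 'z0'") from None
    return WindowForceSeries(z0=z0, dt=ts.dt, F=ts.values)


_PROFILE_COLUMNS = {
    "free_energy": ("z_nm", "G_kJmol"),
    "diffusion": ("z_nm", "D_nm2_per_ps"),
    "partition": ("z_nm", "K"),
    "resistance_density": ("z_nm", "rho_ps_per_nm2"),
    "cumulative_resistance": ("z_nm", "cumR_ps_per_nm"),
}


def write_profile(profile, path) -> None:
    """Write a FreeEnergyProfile or DepthProfile as commented-header TSV."""
    path = Path(path)
    if isinstance(profile, FreeEnergyProfile):
        kind = "free_energy"
        header = {
            "type": kind,
            "reference": profile.reference,
            "temperature_K": profile.T,
        }
        cols = {"z_nm": profile.z, "G_kJmol": profile.G}
        if profile.uncertainty is not None:
            cols["err_kJmol"] = profile.uncertainty
    elif isinstance(profile, DepthProfile):
        kind = profile.quantity
        header = {"type": kind}
        if "T" in profile.meta:
            header["temperature_K"] = profile.meta["T"]
        if "reference" in profile.meta:
            header["reference"] = profile.meta["reference"]
        zcol, vcol = _PROFILE_COLUMNS[kind]
        cols = {zcol: profile.z, vcol: profile.values}
    else:
        raise TypeError(f"cannot write profile of type {type(profile).__name__}")
    if len(next(iter(cols.values()))) == 0:
        raise ValueError("refusing to write an empty profile")
    df = pd.DataFrame(cols)
    with path.open("w") as fh:
        for key, val in header.items():
            fh.write(f"# {key} = {val}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_profile(path):
    """Read a profile TSV back into its in-memory type (round-trip inverse)."""
    path = Path(path)
    header = {}
    with path.open() as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            body = line.lstrip("#").strip()
            key, _, val = body.partition("=")
            header[key.strip()] = val.strip()
            pos = fh.tell()
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    kind = header.get("type")
    if kind == "free_energy":
        return FreeEnergyProfile(
            z=df["z_nm"].to_numpy(),
            G=df["G_kJmol"].to_numpy(),
            reference=header.get("reference", "bilayer_center"),
            T=float(header.get("temperature_K", T_DEFAULT)),
            uncertainty=df["err_kJmol"].to_numpy() if "err_kJmol" in df else None,
        )
    if kind == "diffusion_table":
        meta = {}
        if "cutoff_ps" in df:
            meta["cutoff_ps"] = df["cutoff_ps"].to_numpy()
        if "D_cm2_per_s" in df:
            meta["D_cm2_per_s"] = df["D_cm2_per_s"].to_numpy()
        return DepthProfile(
            z=df["z_nm"].to_numpy(),
            values=df["D_nm2_per_ps"].to_numpy(),
            quantity="diffusion",
            meta=meta,
        )
    if kind in _PROFILE_COLUMNS:
        zcol, vcol = _PROFILE_COLUMNS[kind]
        meta = {}
        if "temperature_K" in header:
            meta["T"] = float(header["temperature_K"])
        if "reference" in header:
            meta["reference"] = header["reference"]
        return DepthProfile(
            z=df[zcol].to_numpy(), values=df[vcol].to_numpy(), quantity=kind, meta=meta
        )
    raise ValueError(f"{path}: unknown or missing profile type {kind!r}")


def write_diffusion_table(profile: DepthProfile, path) -> None:
    """Diffusion profile TSV with both unit systems and per-window cutoffs."""
    if profile.quantity != "diffusion":
        raise ValueError("expected a diffusion profile")
    df = pd.DataFrame(
        {
            "z_nm": profile.z,
            "D_nm2_per_ps": profile.values,
            "D_cm2_per_s": profile.meta.get("D_cm2_per_s", profile.values * 1e-2),
            "cutoff_ps": profile.meta.get("cutoff_ps", np.full(profile.z.size, np.nan)),
        }
    )
    with Path(path).open("w") as fh:
        fh.write("# type = diffusion_table\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")
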