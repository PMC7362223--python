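"""Reading and writing delimited-text rheometry tables.

Rheometer export formats vary (comma/semicolon/tab separators, decimal
commas in European locales, vendor-specific headers), so ingestion
auto-detects the delimiter and resolves headers through an explicit
``column_map`` supplied by the user rather than guessing synonyms.
"""

from __future__ import annotations

import csv
import io as _io
import math
from os import PathLike
from typing import Mapping

import numpy as np
import pandas as pd

from .sweeps import FrequencySweep, StrutSeries, SweepValidationError

__all__ = ["read_sweep", "write_sweep", "read_strut_series", "IngestionError"]

# canonical column roles for a frequency sweep
_FREQ = "frequency"
_GP = "g_prime"
_GPP = "g_double_prime"
_AMP = "strain_amplitude"


class IngestionError(ValueError):
    """Raised when a delimited-text table cannot be mapped to a sweep."""


def _read_table(source, decimal_comma: bool = False) -> pd.DataFrame:
    """Load a delimited table, sniffing comma/semicolon/tab separators."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "r", encoding="utf-8-sig") as fh:
            text = fh.read()
    try:
        dialect = csv.Sniffer().sniff(text.splitlines()[0], delimiters=",;\t")
        sep = dialect.delimiter
    except (csv.Error, IndexError):
        sep = ","
    decimal = "," if decimal_comma else "."
    if decimal_comma and sep == ",":
        raise IngestionError(
            "decimal-comma tables must use semicolon or tab separators"
        )
    df = pd.read_csv(_io.StringIO(text), sep=sep, decimal=decimal)
    df.columns = [str(c).strip() for c in df.columns]
    return df


def _resolve(df: pd.DataFrame, column_map: Mapping[str, str] | None, role: str,
             required: bool = True) -> str | None:
    """Find the source column for a canonical role.

    ``column_map`` maps source header -> canonical role.  When absent, a
    column whose header already equals the canonical role name is used.
    """
    if column_map:
        for src, dst in column_map.items():
            if dst == role:
                if src not in df.columns:
                    raise IngestionError(
                        f"column {src!r} (mapped to {role}) not found in table; "
                        f"available: {list(df.columns)}"
                    )
                return src
    if role in df.columns:
        return role
    if required:
        raise IngestionError(
            f"no column found for {role!r}; available: {list(df.columns)}; "
            "supply a column_map entry"
        )
    return None


def read_sweep(
    source: str | PathLike | _io.TextIOBase,
    column_map: Mapping[str, str] | None = None,
    frequency_unit: str = "rad_per_s",
    strain_amplitude: float | None = None,
    decimal_comma: bool = False,
    metadata: Mapping[str, str] | None = None,
) -> FrequencySweep:
    """Read a frequency sweep from a delimited-text table.

    Parameters
    ----------
    source
        Path or open text handle of a CSV/TSV/semicolon table.
    column_map
        Mapping from source header to canonical role, e.g.
        ``{"w": "frequency", "storage": "g_prime", "loss": "g_double_prime"}``.
        Columns whose headers already equal the canonical names need no map.
    frequency_unit
        ``"rad_per_s"`` (angular frequency, the default) or ``"hz"``;
        ordinary frequencies are converted by ω = 2πf.
    strain_amplitude
        Global deformation amplitude ε̃.  Taken from a mapped
        ``strain_amplitude`` column if present (must be constant), else from
        this argument, else defaults to 1.
    decimal_comma
        Accept European decimal commas (requires ; or tab separation).

    Returns
    -------
    FrequencySweep sorted by ascending ω.  Duplicate frequencies are a hard
    error: they inflate the sample size without adding information.
    """
    if frequency_unit not in ("rad_per_s", "hz"):
        raise IngestionError(f"unknown frequency unit {frequency_unit!r}")
    df = _read_table(source, decimal_comma=decimal_comma)
    fcol = _resolve(df, column_map, _FREQ)
    gpcol = _resolve(df, column_map, _GP)
    gppcol = _resolve(df, column_map, _GPP)
    ampcol = _resolve(df, column_map, _AMP, required=False)

    freq = df[fcol].to_numpy(dtype=float)
    omega = freq * (2.0 * math.pi) if frequency_unit == "hz" else freq
    gp = df[gpcol].to_numpy(dtype=float)
    gpp = df[gppcol].to_numpy(dtype=float)

    bad = np.flatnonzero((gp < 0) | (gpp < 0))
    if bad.size:
        raise IngestionError(f"negative modulus in row {bad[0]}")
    if np.unique(omega).size != omega.size:
        raise IngestionError("duplicate frequency values in table")

    order = np.argsort(omega)
    amp = 1.0
    if ampcol is not None:
        amps = df[ampcol].to_numpy(dtype=float)
        if not np.allclose(amps, amps[0]):
            raise IngestionError(
                "strain_amplitude column is not constant; a single global "
                "amplitude is required"
            )
        amp = float(amps[0])
    elif strain_amplitude is not None:
        amp = float(strain_amplitude)

    try:
        return FrequencySweep(
            omega=omega[order],
            g_prime=gp[order],
            g_double_prime=gpp[order],
            strain_amplitude=amp,
            metadata=dict(metadata or {}),
        )
    except SweepValidationError as exc:
        raise IngestionError(str(exc)) from exc


def write_sweep(sweep: FrequencySweep, path: str | PathLike) -> None:
    """Write a sweep as a canonical CSV (frequency in rad/s).

    ``read_sweep(write_sweep(s))`` is the identity on valid sweeps.
    """
    df = pd.DataFrame(
        {
            _FREQ: sweep.omega,
            _GP: sweep.g_prime,
            _GPP: sweep.g_double_prime,
            _AMP: np.full(sweep.n_points, sweep.strain_amplitude),
        }
    )
    df.to_csv(path, index=False)


def read_strut_series(
    source: str | PathLike | _io.TextIOBase,
    column_map: Mapping[str, str] | None = None,
    decimal_comma: bool = False,
) -> list[StrutSeries]:
    """Read strut-diameter time series (columns time, diameter, optional
    replicate) from a delimited table; one series per replicate id."""
    df = _read_table(source, decimal_comma=decimal_comma)
    tcol = _resolve(df, column_map, "time")
    dcol = _resolve(df, column_map, "diameter")
    rcol = _resolve(df, column_map, "replicate", required=False)
    if rcol is None:
        groups = [("", df)]
    else:
        groups = [(str(k), g) for k, g in df.groupby(rcol, sort=True)]
    series = []
    for rep, g in groups:
        g = g.sort_values(tcol)
        try:
            series.append(
                StrutSeries(
                    time=g[tcol].to_numpy(dtype=float),
                    diameter=g[dcol].to_numpy(dtype=float),
                    replicate_id=rep,
                )
            )
        except SweepValidationError as exc:
            raise IngestionError(f"replicate {rep!r}: {exc}") from exc
    return series
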