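"""Domain types and I/O for FRAP/FLAP time–intensity data.

A FRAP or FLAP experiment yields, per replicate, a series of fluorescence
intensities sampled at (typically 10-s) intervals inside a region of interest.
This module holds the in-memory containers (:class:`IntensityTrace`,
:class:`TraceSet`), reads/writes delimited trace tables, and performs the
intensity normalization that puts traces on the 0–1 scale the kinetic model
works with.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Modality",
    "IntensityTrace",
    "TraceSet",
    "TotalConcentration",
    "TraceError",
    "read_traces",
    "normalize_trace",
    "default_reference",
    "write_traces",
    "write_rates_table",
    "read_rates_table",
]

#: Minimum number of (time, intensity) pairs needed to fit the 3-parameter model.
MIN_POINTS = 4

#: Tolerance around [0, 1] allowed for normalized intensities (noise headroom).
NORMALIZED_LO = -0.1
NORMALIZED_HI = 1.5


class TraceError(ValueError):
    """Raised for malformed or inconsistent trace data."""


class Modality(enum.Enum):
    """Photobleaching/photoactivation experiment type.

    FRAP traces recover from ~0 toward a plateau; FLAP traces decay from the
    photoactivated maximum toward a plateau.
    """

    FRAP = "frap"
    FLAP = "flap"

    @classmethod
    def coerce(cls, value: "Modality | str") -> "Modality":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise TraceError(f"unknown modality {value!r}; expected 'frap' or 'flap'") from None


@dataclass(frozen=True)
class IntensityTrace:
    """One replicate's time/intensity series.

    Parameters
    ----------
    times
        Sample times in seconds, strictly increasing.
    intensities
        Fluorescence values (raw or normalized), same length as ``times``.
    modality
        FRAP or FLAP.
    label
        Free-text replicate/protein identifier.
    """

    times: np.ndarray
    intensities: np.ndarray
    modality: Modality
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if t.ndim != 1 or y.ndim != 1 or t.size != y.size:
            raise TraceError("times and intensities must be 1-D arrays of equal length")
        if t.size < MIN_POINTS:
            raise TraceError(f"trace {self.label!r} has {t.size} points; need >= {MIN_POINTS}")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(y)):
            raise TraceError(f"trace {self.label!r} contains non-finite values")
        if np.any(np.diff(t) <= 0):
            raise TraceError(f"trace {self.label!r} has a non-monotone time column")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)
        object.__setattr__(self, "modality", Modality.coerce(self.modality))

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def is_normalized(self) -> bool:
        """Heuristic: all intensities within the tolerant normalized band."""
        y = self.intensities
        return bool(np.all((y >= NORMALIZED_LO) & (y <= NORMALIZED_HI)))


@dataclass(frozen=True)
class TraceSet:
    """A group of replicate traces for one protein, sharing modality."""

    traces: tuple[IntensityTrace, ...]
    protein: str = ""

    def __post_init__(self) -> None:
        traces = tuple(self.traces)
        if not traces:
            raise TraceError("TraceSet requires at least one trace")
        modalities = {tr.modality for tr in traces}
        if len(modalities) > 1:
            raise TraceError(f"mixed modalities in TraceSet: {sorted(m.value for m in modalities)}")
        object.__setattr__(self, "traces", traces)

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)

    def __getitem__(self, i):
        return self.traces[i]

    @property
    def modality(self) -> Modality:
        return self.traces[0].modality


@dataclass(frozen=True)
class TotalConcentration:
    """Conserved total (interior + exterior) protein concentration.

    After normalization the total is fixed at 1.0; raw-count workflows may
    carry another positive value. ``n_tot = n_in + n_out`` holds at all times.
    """

    n_tot: float = 1.0

    def __post_init__(self) -> None:
        if not (self.n_tot > 0):
            raise TraceError(f"n_tot must be positive, got {self.n_tot}")


# ---------------------------------------------------------------------------
# Reading trace tables


def _looks_numeric(token: str) -> bool:
    token = token.strip().replace(",", ".")
    if token == "" or token.lower() in {"nan", "na", ""}:
        return True
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_traces(
    path: str | Path,
    modality: Modality | str,
    *,
    decimal: str = ".",
    protein: str = "",
) -> TraceSet:
    """Read a delimited table of traces (first column time, rest replicates).

    The delimiter (comma or tab) is auto-detected, a header row is optional
    (the first row is treated as a header when any of its cells is
    non-numeric), and lines starting with ``#`` are ignored. Cells missing in
    one replicate drop that (time, intensity) pair from that replicate only.
    """
    modality = Modality.coerce(modality)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise TraceError(f"{path}: empty trace file")
    sep = "\t" if lines[0].count("\t") >= lines[0].count(",") and "\t" in lines[0] else ","
    first_fields = lines[0].split(sep)
    has_header = not all(_looks_numeric(f) for f in first_fields)
    df = pd.read_csv(
        io.StringIO("\n".join(lines)),
        sep=sep,
        header=0 if has_header else None,
        decimal=decimal,
    )
    if df.shape[1] < 2:
        raise TraceError(f"{path}: need a time column plus at least one intensity column")
    times = pd.to_numeric(df.iloc[:, 0], errors="coerce").to_numpy(dtype=float)
    traces = []
    for j in range(1, df.shape[1]):
        y = pd.to_numeric(df.iloc[:, j], errors="coerce").to_numpy(dtype=float)
        keep = np.isfinite(times) & np.isfinite(y)
        if keep.sum() < MIN_POINTS:
            raise TraceError(
                f"{path}: column {df.columns[j]!r} has {int(keep.sum())} valid points; "
                f"need >= {MIN_POINTS}"
            )
        label = str(df.columns[j]) if has_header else f"{protein or path.stem}-{j}"
        traces.append(IntensityTrace(times[keep], y[keep], modality, label=label))
    return TraceSet(tuple(traces), protein=protein or path.stem)


def write_traces(traceset: TraceSet, path: str | Path, *, header_lines: Sequence[str] = ()) -> Path:
    """Write a TraceSet as a CSV on its common time grid (``#`` comment header)."""
    path = Path(path)
    n = min(len(tr) for tr in traceset)
    grid = traceset[0].times[:n]
    for tr in traceset:
        if not np.allclose(tr.times[:n], grid, rtol=0, atol=1e-9):
            raise TraceError("traces do not share a common time grid; cannot tabulate")
    cols = {"time_s": grid}
    for tr in traceset:
        cols[tr.label or "trace"] = tr.intensities[:n]
    with path.open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        pd.DataFrame(cols).to_csv(fh, index=False, float_format="%.12g")
    return path


# ---------------------------------------------------------------------------
# Normalization


def default_reference(trace: IntensityTrace) -> float:
    """Default normalization reference for a raw trace.

    Mean of pre-bleach samples (t < 0) when present, else the maximum
    intensity. The underlying experiments only state that data are normalized;
    both conventions are exposed (pass an explicit reference to override).
    """
    pre = trace.intensities[trace.times < 0]
    ref = float(pre.mean()) if pre.size else float(trace.intensities.max())
    if ref <= 0:
        raise TraceError("cannot infer a positive normalization reference")
    return ref


def normalize_trace(trace: IntensityTrace, reference: float) -> IntensityTrace:
    """Divide intensities by a positive reference (pre-bleach or total signal)."""
    if not (reference > 0):
        raise TraceError(f"normalization reference must be > 0, got {reference}")
    return replace(trace, intensities=trace.intensities / float(reference))


# ---------------------------------------------------------------------------
# Rates table I/O (layout mirrors the per-protein dynamic-rates summary:
# protein, kT, kIn, kOut, n̄, each with its uncertainty)

_RATE_COLUMNS = [
    "protein",
    "k_t_per_s",
    "sigma_k_t_per_s",
    "k_in_per_s",
    "sigma_k_in_per_s",
    "k_out_per_s",
    "sigma_k_out_per_s",
    "n_in_bar",
    "sigma_n_in_bar",
]


def write_rates_table(rates: Sequence, path: str | Path, *, header_lines: Sequence[str] = ()) -> Path:
    """Write DynamicRates records as a TSV, round-trippable at 12 significant digits."""
    rates = list(rates)
    if not rates:
        raise TraceError("write_rates_table requires a nonempty list")
    rows = [
        {
            "protein": r.protein,
            "k_t_per_s": r.k_t,
            "sigma_k_t_per_s": r.sigma_k_t,
            "k_in_per_s": r.k_in,
            "sigma_k_in_per_s": r.sigma_k_in,
            "k_out_per_s": r.k_out,
            "sigma_k_out_per_s": r.sigma_k_out,
            "n_in_bar": r.n_in_bar,
            "sigma_n_in_bar": r.sigma_n_in_bar,
        }
        for r in rates
    ]
    path = Path(path)
    with path.open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        pd.DataFrame(rows, columns=_RATE_COLUMNS).to_csv(fh, sep="\t", index=False, float_format="%.12g")
    return path


def read_rates_table(path: str | Path) -> list:
    """Read back a rates TSV written by :func:`write_rates_table`."""
    from .cme import DynamicRates  # local import: cme does not depend on traces

    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for _, row in df.iterrows():
        out.append(
            DynamicRates(
                k_t=float(row["k_t_per_s"]),
                k_in=float(row["k_in_per_s"]),
                k_out=float(row["k_out_per_s"]),
                n_in_bar=float(row["n_in_bar"]),
                sigma_k_t=float(row["sigma_k_t_per_s"]),
                sigma_k_in=float(row["sigma_k_in_per_s"]),
                sigma_k_out=float(row["sigma_k_out_per_s"]),
                sigma_n_in_bar=float(row["sigma_n_in_bar"]),
                protein=str(row["protein"]),
            )
        )
    return out
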