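"""Closed-form chemical-master-equation machinery for ROI exchange kinetics.

The interior protein count of a region of interest (ROI, here a focal
adhesion) exchanging with the cytosolic pool is a one-dimensional linear
birth–death process. Its mean obeys a single-exponential relaxation with rate
``k_t = k_in + k_out`` toward the stationary interior fraction
``n_in_bar = k_out / k_t`` (the parameterization in which the published
dynamic-rate tables are internally consistent; see docs/methods.md for the
labeling convention). Given the two quantities a FRAP/FLAP fit provides —
the turnover rate ``k_t`` and the plateau ``n_in_bar`` — the entry/exit pair
is recovered exactly:

    k_out = n_in_bar * k_t,      k_in = k_t - k_out.

This module implements that inversion, the closed-form mean trajectory, the
FRAP/FLAP curve predictions, and first-order uncertainty propagation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CMEError",
    "DynamicRates",
    "InitialState",
    "invert_rates",
    "stationary_fraction",
    "propagate_uncertainty",
    "dynamic_rates",
    "analytic_trace",
    "predict_frap",
    "predict_flap",
    "DEFAULT_GRID",
]

#: Default prediction grid: 10-s sampling up to 300 s, matching acquisition.
DEFAULT_GRID = np.arange(0.0, 300.0 + 1e-9, 10.0)

_REL_TOL = 1e-9  # internal consistency tolerance (survives 12-digit round trips)


class CMEError(ValueError):
    """Raised for invalid kinetic parameters or initial states."""


@dataclass(frozen=True)
class DynamicRates:
    """Entry/exit decomposition of a protein's ROI turnover.

    All rates are in /s; ``n_in_bar`` is the stationary interior fraction of
    the (normalized, conserved) total. Invariants ``k_in + k_out == k_t`` and
    ``n_in_bar == k_out / k_t`` are enforced at construction.
    """

    k_t: float
    k_in: float
    k_out: float
    n_in_bar: float
    sigma_k_t: float = 0.0
    sigma_k_in: float = 0.0
    sigma_k_out: float = 0.0
    sigma_n_in_bar: float = 0.0
    protein: str = ""

    def __post_init__(self) -> None:
        if not (self.k_t > 0):
            raise CMEError(f"k_t must be positive, got {self.k_t}")
        if self.k_in < 0 or self.k_out < 0:
            raise CMEError(f"rates must be nonnegative: k_in={self.k_in}, k_out={self.k_out}")
        if abs(self.k_in + self.k_out - self.k_t) > _REL_TOL * self.k_t:
            raise CMEError(
                f"k_in + k_out = {self.k_in + self.k_out} inconsistent with k_t = {self.k_t}"
            )
        if abs(self.n_in_bar - self.k_out / self.k_t) > _REL_TOL:
            raise CMEError(
                f"n_in_bar = {self.n_in_bar} inconsistent with k_out/k_t = {self.k_out / self.k_t}"
            )
        for name in ("sigma_k_t", "sigma_k_in", "sigma_k_out", "sigma_n_in_bar"):
            if getattr(self, name) < 0:
                raise CMEError(f"{name} must be nonnegative")

    def display_milli(self) -> dict[str, float]:
        """Rates in the conventional display unit 10⁻³/s (display only)."""
        return {
            "k_t": 1e3 * self.k_t,
            "k_in": 1e3 * self.k_in,
            "k_out": 1e3 * self.k_out,
            "sigma_k_t": 1e3 * self.sigma_k_t,
            "sigma_k_in": 1e3 * self.sigma_k_in,
            "sigma_k_out": 1e3 * self.sigma_k_out,
        }


@dataclass(frozen=True)
class InitialState:
    """Interior/exterior concentrations at the start of the observation.

    ``n_in_0 + n_out_0`` is the conserved total (1.0 for normalized data).
    """

    n_in_0: float
    n_out_0: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.n_in_0 < 0 or self.n_out_0 < 0:
            raise CMEError("initial concentrations must be nonnegative")

    @property
    def n_tot(self) -> float:
        return self.n_in_0 + self.n_out_0


def invert_rates(k_t: float, n_in_bar: float) -> tuple[float, float]:
    """Invert (turnover rate, stationary fraction) into (k_in, k_out).

    Parameters
    ----------
    k_t
        Turnover rate |R0| from the exponential fit, /s. Must be positive.
    n_in_bar
        Stationary interior fraction (plateau), in [0, 1].

    Returns
    -------
    (k_in, k_out)
        Entry and exit rates in /s; ``k_in + k_out == k_t`` exactly.
    """
    if not (k_t > 0):
        raise CMEError(f"k_t must be positive, got {k_t}")
    if not (0.0 <= n_in_bar <= 1.0):
        raise CMEError(f"n_in_bar must lie in [0, 1], got {n_in_bar}")
    k_out = n_in_bar * k_t
    k_in = k_t - k_out
    return k_in, k_out


def stationary_fraction(k_in: float, k_out: float) -> float:
    """Stationary interior fraction ``k_out / (k_in + k_out)``."""
    if k_in < 0 or k_out < 0:
        raise CMEError("rates must be nonnegative")
    total = k_in + k_out
    if total <= 0:
        raise CMEError("k_in + k_out must be positive")
    return k_out / total


def propagate_uncertainty(
    k_t: float, sigma_k_t: float, n_in_bar: float, sigma_n_in_bar: float
) -> tuple[float, float]:
    """First-order (independent, Gaussian) propagation onto (k_in, k_out).

    With k_out = n̄·kT and k_in = (1−n̄)·kT:

        σ_out = sqrt((n̄·σ_kT)² + (kT·σ_n̄)²)
        σ_in  = sqrt(((1−n̄)·σ_kT)² + (kT·σ_n̄)²)
    """
    if sigma_k_t < 0 or sigma_n_in_bar < 0:
        raise CMEError("uncertainties must be nonnegative")
    sigma_k_out = math.hypot(n_in_bar * sigma_k_t, k_t * sigma_n_in_bar)
    sigma_k_in = math.hypot((1.0 - n_in_bar) * sigma_k_t, k_t * sigma_n_in_bar)
    return sigma_k_in, sigma_k_out


def dynamic_rates(
    k_t: float,
    n_in_bar: float,
    sigma_k_t: float = 0.0,
    sigma_n_in_bar: float = 0.0,
    protein: str = "",
) -> DynamicRates:
    """Build a full :class:`DynamicRates` record from fitted (kT, n̄)."""
    k_in, k_out = invert_rates(k_t, n_in_bar)
    sigma_k_in, sigma_k_out = propagate_uncertainty(k_t, sigma_k_t, n_in_bar, sigma_n_in_bar)
    return DynamicRates(
        k_t=k_t,
        k_in=k_in,
        k_out=k_out,
        n_in_bar=n_in_bar,
        sigma_k_t=sigma_k_t,
        sigma_k_in=sigma_k_in,
        sigma_k_out=sigma_k_out,
        sigma_n_in_bar=sigma_n_in_bar,
        protein=protein,
    )


def analytic_trace(rates: DynamicRates, init: InitialState, times: np.ndarray) -> np.ndarray:
    """Closed-form mean interior concentration of the birth–death CME.

    n_in(t) = [n_in(t0)·(k_out + k_in·e^{−kT·(t−t0)})
               + n_out(t0)·k_out·(1 − e^{−kT·(t−t0)})] / kT

    Monotone between ``n_in(t0)`` and the stationary value
    ``n_tot · k_out / k_t``; exactly ``n_in(t0)`` at ``t = t0``.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < init.t0 - 1e-12):
        raise CMEError("times must not precede the initial time t0")
    decay = np.exp(-rates.k_t * (t - init.t0))
    n_in = (
        init.n_in_0 * (rates.k_out + rates.k_in * decay)
        + init.n_out_0 * rates.k_out * (1.0 - decay)
    ) / rates.k_t
    return n_in


def predict_frap(
    rates: DynamicRates, times: np.ndarray | None = None, n_tot: float = 1.0
) -> np.ndarray:
    """Predicted FRAP recovery: interior starts empty, recovers to n̄·n_tot."""
    t = DEFAULT_GRID if times is None else np.asarray(times, dtype=float)
    t0 = float(t[0]) if t.size else 0.0
    return analytic_trace(rates, InitialState(0.0, n_tot, t0=t0), t)


def predict_flap(
    rates: DynamicRates, times: np.ndarray | None = None, n_tot: float = 1.0
) -> np.ndarray:
    """Predicted FLAP interior decay: starts fully labeled, decays to n̄·n_tot."""
    t = DEFAULT_GRID if times is None else np.asarray(times, dtype=float)
    t0 = float(t[0]) if t.size else 0.0
    return analytic_trace(rates, InitialState(n_tot, 0.0, t0=t0), t)
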