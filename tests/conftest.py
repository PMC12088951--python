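"""Shared fixtures: published rate table, RK4 oracle, hypothesis profile."""

from __future__ import annotations

import numpy as np
import pytest

import frapcme as f

try:
    from hypothesis import HealthCheck, settings

    settings.register_profile(
        "frapcme",
        deadline=None,
        derandomize=True,
        suppress_health_check=[HealthCheck.too_slow],
    )
    settings.load_profile("frapcme")
except ImportError:  # pragma: no cover
    pass


#: Published dynamic-rates table for the 12 focal-adhesion proteins, kept as
#: printed strings (units 10^-3 /s for rates) so tests can reason about the
#: printed precision. Columns: kT, σkT, kIn, σkIn, kOut, σkOut, n̄, σn̄.
PUBLISHED_RATES = [
    ("Tensin1",      "11.29", "0.32", "4.94", "0.20", "6.35", "0.23", "0.562", "0.013"),
    ("Talin1",       "15.0",  "0.6",  "7.8",  "0.5",  "7.2",  "0.5",  "0.481", "0.030"),
    ("Vinculin",     "17.7",  "0.7",  "5.2",  "0.4",  "12.5", "0.6",  "0.706", "0.021"),
    ("alpha-Actinin","25.7",  "1.4",  "6.1",  "0.6",  "19.6", "1.2",  "0.761", "0.020"),
    ("ILK",          "23.4",  "1.2",  "9.3",  "0.6",  "14.1", "0.8",  "0.603", "0.017"),
    ("alpha-Parvin", "26.1",  "1.5",  "10.7", "0.8",  "15.4", "1.0",  "0.590", "0.018"),
    ("Kindlin2",     "28.8",  "1.8",  "10.6", "0.9",  "18.1", "1.3",  "0.630", "0.022"),
    ("Paxillin",     "37.3",  "2.5",  "14.2", "1.5",  "23.1", "1.9",  "0.619", "0.031"),
    ("p130Cas",      "45.0",  "3.1",  "12.5", "1.4",  "32.6", "2.5",  "0.724", "0.026"),
    ("VASP",         "86",    "7",    "19.2", "3.4",  "66",   "6",    "0.78",  "0.04"),
    ("FAK",          "83",    "6",    "29.1", "3.0",  "54",   "5",    "0.649", "0.024"),
    ("Zyxin",        "87",    "6",    "14.9", "2.2",  "72",   "6",    "0.829", "0.021"),
]


def ulp(printed: str) -> float:
    """One unit in the last printed digit of a decimal string."""
    if "." in printed:
        return 10.0 ** -(len(printed) - printed.index(".") - 1)
    return 1.0


def rk4(rhs, y0: float, times: np.ndarray, max_step: float = 0.05) -> np.ndarray:
    """Classical fixed-step RK4 integration of dy/dt = rhs(t, y).

    Independent numerical oracle for the closed-form trajectories; hits each
    requested time exactly by subdividing the spans.
    """
    times = np.asarray(times, dtype=float)
    out = np.empty_like(times)
    t, y = float(times[0]), float(y0)
    out[0] = y
    for i in range(1, times.size):
        span = times[i] - t
        n_steps = max(int(np.ceil(span / max_step)), 1)
        h = span / n_steps
        for _ in range(n_steps):
            k1 = rhs(t, y)
            k2 = rhs(t + h / 2, y + h * k1 / 2)
            k3 = rhs(t + h / 2, y + h * k2 / 2)
            k4 = rhs(t + h, y + h * k3)
            y += h * (k1 + 2 * k2 + 2 * k3 + k4) / 6
            t += h
        out[i] = y
    return out


@pytest.fixture(scope="session")
def tensin_rates() -> f.DynamicRates:
    return f.dynamic_rates(11.29e-3, 0.562, 0.32e-3, 0.013, protein="Tensin1")


@pytest.fixture(scope="session")
def talin_rates() -> f.DynamicRates:
    # from the printed entry/exit pair: kT = 15.0e-3, n̄ = 7.2/15
    return f.dynamic_rates(15.0e-3, 7.2 / 15.0, 0.6e-3, 0.030, protein="Talin1")
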