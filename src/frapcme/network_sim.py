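"""Gillespie simulation of interaction-perturbed ROI exchange kinetics.

The base model is the two-channel birth–death process whose mean is the
closed-form relaxation of :mod:`frapcme.cme` (interior-gain propensity
``k_out * n_out``, interior-loss propensity ``k_in * n_in``, stationary
interior fraction ``k_out / k_t`` — see docs/methods.md on the rate-labeling
convention). Interaction partners enter through extra channels proportional
to the interior count: a destabilizing partner (loss of the vinculin
interaction for talin) adds an interior-loss channel ``k_v * n_in``; a
retention partner (constitutive actomyosin engagement, via the α-actinin
entry rate) adds an interior-gain channel ``k_a * n_in``, capped so the
interior never exceeds the conserved total. None of the perturbed models has
a closed-form CME solution, so the stochastic simulation algorithm (SSA) is
used, with the linear mean-field ODE as the analytic reference for the
ensemble mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cme import DynamicRates

__all__ = [
    "NetworkError",
    "NetworkModel",
    "Trajectory",
    "EnsembleResult",
    "build_base",
    "build_vinculin_loss",
    "build_actin_gain",
    "build_three_protein",
    "gillespie_run",
    "ensemble",
    "mean_field_solution",
]


class NetworkError(ValueError):
    """Raised for invalid or unstable network specifications."""


@dataclass(frozen=True)
class NetworkModel:
    """Propensity specification for the (possibly perturbed) interior CME.

    Channels, for interior count ``n`` out of a conserved total ``n_tot``:

    - gain from the exterior pool: ``gain_out * (n_tot − n)``
    - partner-mediated interior gain (capped at ``n < n_tot``): ``gain_in * n``
    - interior loss: ``(loss_in + extra_loss_in) * n``

    Stability requires a positive mean-field relaxation rate
    ``gain_out + loss_in + extra_loss_in − gain_in``.
    """

    focal_protein: str
    gain_out: float
    loss_in: float
    gain_in: float = 0.0
    extra_loss_in: float = 0.0
    n_tot: int = 1000

    def __post_init__(self) -> None:
        for name in ("gain_out", "loss_in", "gain_in", "extra_loss_in"):
            if getattr(self, name) < 0:
                raise NetworkError(f"{name} must be nonnegative")
        if self.n_tot < 1:
            raise NetworkError(f"n_tot must be >= 1, got {self.n_tot}")
        if self.relaxation_rate <= 0:
            raise NetworkError(
                "unstable model: partner gain rate "
                f"{self.gain_in} >= turnover {self.gain_out + self.loss_in + self.extra_loss_in}"
            )

    @property
    def relaxation_rate(self) -> float:
        """Effective exponential relaxation rate of the mean (per second)."""
        return self.gain_out + self.loss_in + self.extra_loss_in - self.gain_in

    @property
    def stationary_fraction(self) -> float:
        """Mean-field fixed point of the interior fraction."""
        return self.gain_out / self.relaxation_rate


@dataclass(frozen=True)
class Trajectory:
    """One SSA realization: piecewise-constant interior counts between events."""

    event_times: np.ndarray
    states: np.ndarray

    def sample(self, grid: np.ndarray) -> np.ndarray:
        """Last-observation-carried-forward sampling onto a time grid."""
        idx = np.searchsorted(self.event_times, np.asarray(grid, dtype=float), side="right") - 1
        return self.states[np.clip(idx, 0, self.states.size - 1)]


@dataclass(frozen=True)
class EnsembleResult:
    """Grid-wise mean ± standard error of repeated SSA runs (as fractions)."""

    grid_times: np.ndarray
    mean: np.ndarray
    stderr: np.ndarray
    n_runs: int


# ---------------------------------------------------------------------------
# Model builders


def build_base(rates: DynamicRates, n_tot: int = 1000) -> NetworkModel:
    """Two-channel birth–death model whose mean is the closed-form trace.

    The interior-gain constant is ``rates.k_out`` and the interior-loss
    constant is ``rates.k_in``, so the stationary interior fraction is
    ``k_out / k_t = n_in_bar``, matching the inversion convention.
    """
    return NetworkModel(
        focal_protein=rates.protein or "protein",
        gain_out=rates.k_out,
        loss_in=rates.k_in,
        n_tot=n_tot,
    )


def build_vinculin_loss(
    talin_rates: DynamicRates, k_in_vinculin: float, n_tot: int = 1000
) -> NetworkModel:
    """Talin model with the vinculin interaction removed.

    The lost stabilization appears as an extra interior-loss channel
    ``k_in_vinculin * n_in``: turnover accelerates and the stationary interior
    fraction drops to ``k_out / (k_t + k_in_vinculin)``.
    """
    if k_in_vinculin < 0:
        raise NetworkError("k_in_vinculin must be nonnegative")
    base = build_base(talin_rates, n_tot)
    return NetworkModel(
        focal_protein=f"{base.focal_protein}-vinculin-loss",
        gain_out=base.gain_out,
        loss_in=base.loss_in,
        extra_loss_in=k_in_vinculin,
        n_tot=n_tot,
    )


def build_actin_gain(
    talin_rates: DynamicRates, k_in_alpha_actinin: float, n_tot: int = 1000
) -> NetworkModel:
    """Talin model with constitutive actomyosin engagement.

    Retention appears as an interior-gain channel ``k_in_alpha_actinin * n_in``
    (capped at the conserved total); the stationary interior fraction rises to
    ``k_out / (k_t − k_in_alpha_actinin)``. Construction fails when the
    partner gain reaches the turnover rate (unstable mean dynamics).
    """
    if k_in_alpha_actinin < 0:
        raise NetworkError("k_in_alpha_actinin must be nonnegative")
    base = build_base(talin_rates, n_tot)
    return NetworkModel(
        focal_protein=f"{base.focal_protein}-actin-gain",
        gain_out=base.gain_out,
        loss_in=base.loss_in,
        gain_in=k_in_alpha_actinin,
        n_tot=n_tot,
    )


def build_three_protein(
    p1_rates: DynamicRates, p2_k_in: float, p3_k_in: float, n_tot: int = 1000
) -> NetworkModel:
    """Focal protein with two recruiting partners.

    Both partners contribute interior-gain propensity proportional to the
    focal protein's interior count; by linearity this is equivalent to a
    single partner with the summed rate.
    """
    if p2_k_in < 0 or p3_k_in < 0:
        raise NetworkError("partner rates must be nonnegative")
    base = build_base(p1_rates, n_tot)
    return NetworkModel(
        focal_protein=f"{base.focal_protein}-network",
        gain_out=base.gain_out,
        loss_in=base.loss_in,
        gain_in=p2_k_in + p3_k_in,
        n_tot=n_tot,
    )


# ---------------------------------------------------------------------------
# Stochastic simulation


def gillespie_run(
    model: NetworkModel,
    t_max: float,
    init_fraction: float = 1.0,
    seed: int | np.random.SeedSequence | None = None,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Exact SSA realization of the interior count up to ``t_max`` seconds.

    At each step the waiting time is exponential with the total propensity and
    the channel is chosen proportionally; states change by ±1. An absorbing
    state (total propensity zero) ends the walk early; :meth:`Trajectory.sample`
    carries the last state forward. Reproducible given ``seed``.
    """
    if not (t_max > 0):
        raise NetworkError(f"t_max must be positive, got {t_max}")
    if not (0.0 <= init_fraction <= 1.0):
        raise NetworkError(f"init_fraction must lie in [0, 1], got {init_fraction}")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_tot = model.n_tot
    n = int(round(init_fraction * n_tot))
    gain_out = model.gain_out
    gain_in = model.gain_in
    loss = model.loss_in + model.extra_loss_in
    times = [0.0]
    states = [n]
    t = 0.0
    block = 4096
    exp_buf = rng.standard_exponential(block)
    u_buf = rng.random(block)
    i = 0
    while True:
        birth = gain_out * (n_tot - n)
        if n < n_tot:
            birth += gain_in * n
        a0 = birth + loss * n
        if a0 <= 0.0:
            break  # absorbing state
        if i >= block:
            exp_buf = rng.standard_exponential(block)
            u_buf = rng.random(block)
            i = 0
        t += exp_buf[i] / a0
        if t > t_max:
            break
        n += 1 if u_buf[i] * a0 < birth else -1
        i += 1
        times.append(t)
        states.append(n)
    return Trajectory(np.asarray(times), np.asarray(states, dtype=np.int64))


def ensemble(
    model: NetworkModel,
    n_runs: int = 1000,
    t_max: float = 300.0,
    grid_dt: float = 10.0,
    init_fraction: float = 1.0,
    seed: int | np.random.SeedSequence = 0,
) -> EnsembleResult:
    """Ensemble mean ± standard error of ``n_runs`` SSA realizations.

    Trajectories are sampled onto the regular grid (last value carried
    forward), normalized by ``n_tot``; independent sub-streams are spawned per
    run from ``seed``, so results are reproducible and runs are uncorrelated.
    """
    if n_runs < 2:
        raise NetworkError(f"n_runs must be >= 2, got {n_runs}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    grid = np.arange(0.0, t_max + grid_dt * 0.5, grid_dt)
    samples = np.empty((n_runs, grid.size))
    for row, child in enumerate(ss.spawn(n_runs)):
        traj = gillespie_run(model, t_max, init_fraction, rng=np.random.default_rng(child))
        samples[row] = traj.sample(grid) / model.n_tot
    mean = samples.mean(axis=0)
    stderr = samples.std(axis=0, ddof=1) / np.sqrt(n_runs)
    return EnsembleResult(grid_times=grid, mean=mean, stderr=stderr, n_runs=n_runs)


def mean_field_solution(
    model: NetworkModel, times: np.ndarray, init_fraction: float = 1.0
) -> np.ndarray:
    """Deterministic mean of the (uncapped) linear jump process, as a fraction.

    Solves dn/dt = gain_out·(n_tot − n) + gain_in·n − (loss_in + extra)·n in
    closed form: exponential relaxation toward the fixed point
    ``gain_out / relaxation_rate`` at rate :attr:`NetworkModel.relaxation_rate`.
    """
    t = np.asarray(times, dtype=float)
    fp = model.stationary_fraction
    lam = model.relaxation_rate
    return fp + (init_fraction - fp) * np.exp(-lam * (t - t[0] if t.size else 0.0))
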