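"""Single-exponential fitting of recovery/loss curves and replicate pooling.

Every FRAP recovery and FLAP loss curve is fitted with

    y(t) = y0 + A * exp(R0 * t)

by deterministic nonlinear least squares. The turnover rate is ``k_t = |R0|``
and the plateau gives the stationary mobile fraction. Replicates are screened
with the Tukey interquartile-range fence on their fitted ``R0`` values, then
pooled into one average curve per protein, which is what gets fitted for the
reported rates (per-replicate fits serve outlier detection only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from . import cme
from .traces import IntensityTrace, Modality, TraceSet

__all__ = [
    "FitError",
    "FitWarning",
    "ExpFit",
    "OutlierBounds",
    "fit_exponential",
    "turnover_rate",
    "stationary_concentration",
    "remove_outliers",
    "average_trace",
    "plateau_estimate",
    "FitReport",
    "analyze_traceset",
]


class FitError(RuntimeError):
    """Raised when the exponential fit cannot be performed or is degenerate."""


class FitWarning(UserWarning):
    """Emitted when a converged fit violates the modality sign convention."""


@dataclass(frozen=True)
class ExpFit:
    """Result of fitting y = y0 + A·exp(R0·t).

    Sign convention: the exponential term must decay (R0 < 0); FRAP recovery
    has A < 0, FLAP loss has A > 0.
    """

    y0: float
    A: float
    R0: float
    residual_sse: float
    n_points: int
    converged: bool = True
    sigma_y0: float = float("nan")
    sigma_A: float = float("nan")
    sigma_R0: float = float("nan")
    label: str = ""

    def predict(self, times: np.ndarray) -> np.ndarray:
        return _model(np.asarray(times, dtype=float), self.y0, self.A, self.R0)


@dataclass(frozen=True)
class OutlierBounds:
    """Tukey fences on a sample of fitted R0 values.

    ``ucl = q3 + 1.5·iqr`` and ``lcl = q1 − 1.5·iqr`` (standard fence; the
    lower limit uses the minus sign).
    """

    q1: float
    q3: float
    iqr: float
    ucl: float
    lcl: float


def _model(t: np.ndarray, y0: float, A: float, R0: float) -> np.ndarray:
    # clip the exponent so a wandering optimizer step cannot overflow
    return y0 + A * np.exp(np.clip(R0 * t, -700.0, 700.0))


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Deterministic start: y0 from the tail, A from the span, R0 from a log-slope."""
    y0 = float(y[-1])
    A = float(y[0] - y[-1])
    half = max(t.size // 2, 3)
    resid = y[:half] - y0
    mask = np.abs(resid) > 1e-12
    R0 = -0.01
    if mask.sum() >= 2 and A != 0.0:
        # slope of log|y - y0| is R0 for the noiseless model
        slope = np.polyfit(t[:half][mask], np.log(np.abs(resid[mask])), 1)[0]
        if np.isfinite(slope) and slope < 0:
            R0 = float(slope)
    return y0, A, R0


#: Deterministic restart schedule: multiplicative perturbations of the R0 guess.
_RESTART_FACTORS = (1.0, 0.5, 2.0, 0.25, 4.0)


def fit_exponential(trace: IntensityTrace) -> ExpFit:
    """Least-squares fit of the single-exponential model to one trace.

    Deterministic: fixed initialization, up to five restarts that perturb the
    initial R0, plus two growth-oriented starts; the converged candidate with
    the lowest SSE wins.

    Raises
    ------
    FitError
        For a constant trace, non-convergence of every restart, or a best fit
        whose exponential term does not decay (R0 >= 0).
    """
    t = trace.times
    y = trace.intensities
    if np.ptp(y) == 0.0:
        raise FitError(f"trace {trace.label!r} is constant; exponential fit is degenerate")
    y0g, Ag, R0g = _initial_guess(t, y)
    starts = [(y0g, Ag if Ag != 0.0 else float(np.ptp(y)), R0g * factor)
              for factor in _RESTART_FACTORS]
    # growth-oriented starts: if the signal diverges from a past asymptote the
    # least-squares optimum has R0 > 0 and must be found to be rejected
    starts += [(float(y[0]), float(y[-1] - y[0]) or float(np.ptp(y)), abs(R0g)),
               (float(y[0]), float(y[-1] - y[0]) or float(np.ptp(y)), 0.01)]
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for p0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(_model, t, y, p0=p0, maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((y - _model(t, *popt)) ** 2))
        if np.isfinite(sse) and (best is None or sse < best[0]):
            best = (sse, popt, pcov)
    if best is None:
        raise FitError(f"exponential fit did not converge for trace {trace.label!r}")
    sse, popt, pcov = best
    y0, A, R0 = (float(v) for v in popt)
    if R0 >= 0:
        raise FitError(
            f"trace {trace.label!r}: fitted R0 = {R0:.3g} >= 0 but the modality "
            f"({trace.modality.value}) demands a decaying exponential term"
        )
    expected_A_sign = -1.0 if trace.modality is Modality.FRAP else 1.0
    if A * expected_A_sign < 0:
        warnings.warn(
            f"trace {trace.label!r}: amplitude sign {np.sign(A):+.0f} violates the "
            f"{trace.modality.value} convention",
            FitWarning,
            stacklevel=2,
        )
    sigmas = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf)) if np.all(np.isfinite(pcov)) else [np.nan] * 3
    return ExpFit(
        y0=y0,
        A=A,
        R0=R0,
        residual_sse=sse,
        n_points=len(trace),
        converged=True,
        sigma_y0=float(sigmas[0]),
        sigma_A=float(sigmas[1]),
        sigma_R0=float(sigmas[2]),
        label=trace.label,
    )


def turnover_rate(fit: ExpFit) -> float:
    """Turnover rate ``k_t = |R0|`` in /s."""
    if fit.R0 == 0.0:
        raise FitError("R0 is zero; turnover rate undefined")
    return abs(fit.R0)


def stationary_concentration(
    trace: IntensityTrace,
    m: int = 1,
    *,
    n_tot: float = 1.0,
    exterior_plateau: bool | None = None,
) -> float:
    """Stationary interior fraction n̄ from the tail of a normalized trace.

    FRAP: the mean of the last ``m`` intensities is n̄ directly. FLAP: by
    default the plateau is read as the stationary *exterior* value and
    ``n̄ = n_tot − plateau`` by conservation of the total; pass
    ``exterior_plateau=False`` to read the plateau as the interior value
    (appropriate when the FLAP signal is the interior decay of the labeled
    pool, which relaxes to n̄ itself).
    """
    if not (1 <= m <= len(trace)):
        raise ValueError(f"m must be in [1, {len(trace)}], got {m}")
    plateau = float(trace.intensities[-m:].mean())
    if exterior_plateau is None:
        exterior_plateau = trace.modality is Modality.FLAP
    value = n_tot - plateau if exterior_plateau else plateau
    if not (-0.1 <= value <= n_tot + 0.1):
        raise ValueError(
            f"stationary concentration {value:.4g} outside [0, {n_tot}] beyond tolerance 0.1; "
            "is the trace normalized?"
        )
    return value


def remove_outliers(fits: list[ExpFit]) -> tuple[list[ExpFit], OutlierBounds]:
    """Drop fits whose R0 falls outside the Tukey IQR fence.

    Quartiles use linear interpolation between order statistics (type 7).
    Input order is preserved among the kept fits.
    """
    if len(fits) < 4:
        raise ValueError(f"need at least 4 fits for outlier screening, got {len(fits)}")
    r0 = np.array([f.R0 for f in fits], dtype=float)
    q1, q3 = np.percentile(r0, [25.0, 75.0])  # default 'linear' = type 7
    iqr = q3 - q1
    bounds = OutlierBounds(q1=float(q1), q3=float(q3), iqr=float(iqr),
                           ucl=float(q3 + 1.5 * iqr), lcl=float(q1 - 1.5 * iqr))
    kept = [f for f in fits if bounds.lcl <= f.R0 <= bounds.ucl]
    return kept, bounds


def average_trace(traceset: TraceSet) -> IntensityTrace:
    """Pointwise mean curve of replicates sharing a time grid.

    Grids may be truncated to the shortest common length; they must agree on
    that common prefix.
    """
    n = min(len(tr) for tr in traceset)
    grid = traceset[0].times[:n]
    for tr in traceset:
        if not np.allclose(tr.times[:n], grid, rtol=0.0, atol=1e-9):
            raise ValueError("replicate time grids are incompatible (no common prefix)")
    mean = np.mean([tr.intensities[:n] for tr in traceset], axis=0)
    label = f"{traceset.protein or 'mean'}-average"
    return IntensityTrace(grid, mean, traceset.modality, label=label)


# ---------------------------------------------------------------------------
# Per-protein analysis pipeline (per-replicate fits -> IQR screen -> average
# curve fit -> rate inversion), shared by the CLI and the validation module.


@dataclass(frozen=True)
class FitReport:
    """Everything the per-protein pipeline produced."""

    replicate_fits: list[ExpFit]
    kept_fits: list[ExpFit]
    removed_labels: list[str]
    bounds: OutlierBounds | None
    average: IntensityTrace
    average_fit: ExpFit
    rates: "cme.DynamicRates"


def plateau_estimate(
    fit: ExpFit,
    trace: IntensityTrace,
    *,
    plateau: str = "fit",
    m: int = 1,
    n_tot: float = 1.0,
    exterior_plateau: bool | None = None,
) -> tuple[float, float]:
    """Stationary fraction n̄ and its uncertainty from a fitted trace.

    ``plateau="fit"`` (default) uses the fitted asymptote ``y0`` (exact for a
    decaying exponential, unbiased even when the acquisition ends before the
    plateau is reached), with σ from the least-squares covariance.
    ``plateau="tail"`` is the literal read-off of the last ``m`` samples via
    :func:`stationary_concentration`, with σ taken as the fit's residual
    standard deviation over sqrt(m). The FLAP exterior-plateau complement
    applies in either mode (see :func:`stationary_concentration`).
    """
    if exterior_plateau is None:
        exterior_plateau = trace.modality is Modality.FLAP
    if plateau == "fit":
        value = n_tot - fit.y0 if exterior_plateau else fit.y0
        sigma = fit.sigma_y0 if np.isfinite(fit.sigma_y0) else 0.0
        if not (-0.1 <= value <= n_tot + 0.1):
            raise ValueError(
                f"fitted plateau gives stationary concentration {value:.4g} outside "
                f"[0, {n_tot}] beyond tolerance 0.1; is the trace normalized?"
            )
    elif plateau == "tail":
        value = stationary_concentration(trace, m=m, n_tot=n_tot,
                                         exterior_plateau=exterior_plateau)
        resid_sd = float(np.sqrt(fit.residual_sse / max(fit.n_points - 3, 1)))
        sigma = resid_sd / np.sqrt(m)
    else:
        raise ValueError(f"plateau must be 'fit' or 'tail', got {plateau!r}")
    return float(np.clip(value, 0.0, n_tot)), float(sigma)


def analyze_traceset(
    traceset: TraceSet,
    m: int = 1,
    *,
    screen_outliers: bool = True,
    plateau: str = "fit",
    exterior_plateau: bool | None = None,
) -> FitReport:
    """Run the full single-protein workflow on a set of replicate traces.

    Fits each replicate, removes IQR outliers (when there are >= 4 replicates
    and ``screen_outliers``), averages the surviving traces, refits the
    average curve, and inverts (kT, n̄) into (k_in, k_out) with first-order
    uncertainty propagation. σ(kT) comes from the least-squares covariance of
    the average-curve fit; n̄ and σ(n̄) come from :func:`plateau_estimate`.
    """
    fits = [fit_exponential(tr) for tr in traceset]
    bounds = None
    kept_idx = list(range(len(fits)))
    if screen_outliers and len(fits) >= 4:
        _, bounds = remove_outliers(fits)
        kept_idx = [i for i, f in enumerate(fits) if bounds.lcl <= f.R0 <= bounds.ucl]
    kept_fits = [fits[i] for i in kept_idx]
    removed = [fits[i].label for i in range(len(fits)) if i not in kept_idx]
    pooled = TraceSet(tuple(traceset[i] for i in kept_idx), protein=traceset.protein)
    avg = average_trace(pooled)
    avg_fit = fit_exponential(avg)
    k_t = turnover_rate(avg_fit)
    n_in_bar, sigma_n = plateau_estimate(
        avg_fit, avg, plateau=plateau, m=m, exterior_plateau=exterior_plateau
    )
    rates = cme.dynamic_rates(
        k_t=k_t,
        n_in_bar=n_in_bar,
        sigma_k_t=avg_fit.sigma_R0 if np.isfinite(avg_fit.sigma_R0) else 0.0,
        sigma_n_in_bar=sigma_n,
        protein=traceset.protein,
    )
    return FitReport(
        replicate_fits=fits,
        kept_fits=kept_fits,
        removed_labels=removed,
        bounds=bounds,
        average=avg,
        average_fit=avg_fit,
        rates=rates,
    )
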