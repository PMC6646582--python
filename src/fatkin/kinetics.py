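"""Exponential fatigue kinetics: per-series model fitting and prediction.

The fatigue model describes the decline of a normalized neuromuscular
variable (IMVC, VA or Q_tw, each expressed in percent of its pre-fatigue
baseline) with accumulated contraction time ``t``::

    DV(t) = A + (100 - A) * exp(-t / tau)

``A`` is the asymptote (the stable state the variable converges to, in
percent of baseline) and ``tau`` the curvature constant in seconds; 95 %
of the total decline ``100 - A`` is completed by ``t ~= 3 tau``.

Each subject x condition x variable time course is fitted independently
by bounded nonlinear least squares; no pooling across subjects is done.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "FatigueSeries",
    "ExpFit",
    "exp_decay",
    "fit_exponential",
    "predict",
    "time_to_fraction",
]

CONDITIONS = ("HF", "LF")
VARIABLES = ("IMVC", "VA", "QTW")

#: Parameter bounds for the fit: asymptote in percent, time constant in s.
A_BOUNDS = (0.0, 100.0)
TAU_BOUNDS = (1e-6, 1e4)


@dataclass(frozen=True)
class FatigueSeries:
    """One subject x condition x variable fatigue time course.

    ``times`` are accumulated contraction seconds starting at 0 and
    ``values`` are percent of the pre-fatigue baseline; the t = 0 point is
    the baseline itself and therefore equals 100 by construction.
    """

    subject_id: str
    condition: str
    variable: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if self.variable not in VARIABLES:
            raise ValueError(f"variable must be one of {VARIABLES}, got {self.variable!r}")
        if times.ndim != 1 or times.shape != values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if times.size == 0 or times[0] != 0.0:
            raise ValueError("times must start at 0 (the baseline test)")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")
        if abs(values[0] - 100.0) > 1e-6:
            raise ValueError("the t=0 value must equal 100 (percent of baseline)")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class ExpFit:
    """Fitted exponential fatigue model for one series."""

    A: float
    tau: float
    r_squared: float
    p_value: float
    n_points: int
    residual_sse: float
    converged: bool
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (A_BOUNDS[0] - 1e-9 <= self.A <= A_BOUNDS[1] + 1e-9):
            raise ValueError(f"asymptote out of [0, 100]: {self.A}")
        if self.tau <= 0:
            raise ValueError(f"curvature constant must be positive: {self.tau}")


def exp_decay(t, A: float, tau: float):
    """Evaluate ``A + (100 - A) * exp(-t / tau)`` elementwise."""
    t = np.asarray(t, dtype=float)
    out = A + (100.0 - A) * np.exp(-t / tau)
    return out if out.ndim else float(out)


def _initial_guesses(times: np.ndarray, values: np.ndarray, n_starts: int) -> list[tuple[float, float]]:
    """Heuristic start plus deterministic +/-50 % jittered restarts."""
    a0 = float(np.clip(values.min(), *A_BOUNDS))
    # time at which the decline has covered ~63 % of (100 - a0): the
    # first observation below a0 + (100 - a0)/e, else the median time.
    target = a0 + (100.0 - a0) / np.e
    below = times[values < target]
    tau0 = float(below[0]) if below.size and below[0] > 0 else float(np.median(times))
    tau0 = float(np.clip(tau0, 1.0, TAU_BOUNDS[1]))
    guesses = [(a0, tau0)]
    rng = np.random.default_rng(12345)
    while len(guesses) < n_starts:
        fa, ft = rng.uniform(0.5, 1.5, size=2)
        guesses.append(
            (float(np.clip(a0 * fa, *A_BOUNDS)), float(np.clip(tau0 * ft, *TAU_BOUNDS)))
        )
    return guesses


def fit_exponential(
    series: FatigueSeries,
    include_t0: bool = True,
    n_starts: int = 5,
) -> ExpFit:
    """Fit (A, tau) to one series by bounded least squares.

    Minimizes the sum of squared errors between the model and the
    observed percent-of-baseline values with ``A`` in [0, 100] and
    ``tau`` in (0, 1e4], using a heuristic start and jittered restarts.
    ``r_squared`` is 1 - SSE/SST about the series mean and ``p_value``
    comes from the F-test of the fitted model against the constant-mean
    model (1 and n - 2 degrees of freedom).

    With ``include_t0=False`` the structural t = 0 point is dropped and
    only the post-baseline tests are fitted.
    """
    times, values = series.times, series.values
    if not include_t0:
        times, values = times[1:], values[1:]
    n = times.size
    if n < 4:
        raise ValueError(f"need at least 4 points to fit, got {n}")

    def residuals(p):
        return exp_decay(times, p[0], p[1]) - values

    lo = (A_BOUNDS[0], TAU_BOUNDS[0])
    hi = (A_BOUNDS[1], TAU_BOUNDS[1])
    best = None
    any_success = False
    for guess in _initial_guesses(times, values, n_starts):
        try:
            res = optimize.least_squares(residuals, guess, bounds=(lo, hi), method="trf")
        except Exception:  # pragma: no cover - defensive
            continue
        any_success = any_success or res.success
        sse = float(2.0 * res.cost)
        if best is None or sse < best[0] - 1e-12:
            best = (sse, res)
    if best is None:
        raise RuntimeError("least-squares optimization failed for all starts")

    sse, res = best
    A_hat, tau_hat = float(res.x[0]), float(res.x[1])
    sst = float(np.sum((values - values.mean()) ** 2))
    degenerate = sst <= 1e-12 or A_hat >= A_BOUNDS[1] - 1e-9
    if sst <= 1e-12:
        # constant series (no decline): the model is pinned at A = 100
        r2 = 1.0 if sse <= 1e-12 else 0.0
        p = float("nan")
    else:
        r2 = 1.0 - sse / sst
        r2 = float(np.clip(r2, 0.0, 1.0))
        dof = n - 2
        if sse <= 1e-12 * max(sst, 1.0):
            p = 0.0
        else:
            f_stat = (sst - sse) / 1.0 / (sse / dof)
            p = float(stats.f.sf(max(f_stat, 0.0), 1, dof))
    return ExpFit(
        A=A_hat,
        tau=tau_hat,
        r_squared=r2,
        p_value=p,
        n_points=n,
        residual_sse=sse,
        converged=bool(any_success),
        degenerate=bool(degenerate),
    )


def predict(fit: ExpFit, t):
    """Model prediction ``A + (100 - A) exp(-t/tau)`` at time(s) ``t >= 0``."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    return exp_decay(t, fit.A, fit.tau)


def time_to_fraction(fit: ExpFit, fraction: float) -> float:
    """Time at which ``fraction`` of the total decline (100 - A) is completed.

    Closed form ``tau * ln(1 / (1 - fraction))``; for fraction = 0.95 this
    is ~2.996 tau, the usual "95 % of the loss by 3 tau" rule.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    if fit.A >= 100.0:
        raise ValueError("A = 100 means no decline: time-to-fraction undefined")
    return float(fit.tau * np.log(1.0 / (1.0 - fraction)))
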