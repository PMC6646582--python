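"""Synthetic cohorts, fatigue time series and raw 2 kHz torque traces.

The study's raw dynamometer recordings are not deposited, so this module
emulates them with known ground truth: (i) per-subject latent (A, tau)
parameters for IMVC, VA and Q_tw in both force conditions, drawn from a
correlated multivariate normal whose defaults mirror the published
cohort summary; (ii) noisy percent-of-baseline time series on the
0, 20, ..., 160 s accumulated-contraction-time schedule (a neuromuscular
test every twenty 1-s contractions); (iii) raw isometric torque traces
of a single neuromuscular test — rise to an IMVC plateau, a superimposed
doublet twitch, relaxation, and a resting potentiated doublet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import CONDITIONS, VARIABLES, FatigueSeries, exp_decay
from .nm_extraction import NMTestMetrics, TorqueTrace, compute_voluntary_activation

__all__ = [
    "PARAM_COLUMNS",
    "COHORT_MEANS",
    "COHORT_SDS",
    "CohortConfig",
    "TraceConfig",
    "default_correlation",
    "nearest_psd",
    "generate_cohort_parameters",
    "generate_observations",
    "generate_nm_trace",
]

#: Canonical order of the 12 latent parameters: (A, tau) x variable x condition.
PARAM_COLUMNS = tuple(
    f"{p}_{v}_{c}" for c in CONDITIONS for v in VARIABLES for p in ("A", "tau")
)

# Cohort means and SDs (percent for A, seconds for tau) of the published
# 13-subject summary; these are the generator defaults.
COHORT_MEANS = {
    "A_IMVC_HF": 64.0, "tau_IMVC_HF": 31.0,
    "A_VA_HF": 82.0, "tau_VA_HF": 43.0,
    "A_QTW_HF": 71.0, "tau_QTW_HF": 49.0,
    "A_IMVC_LF": 53.0, "tau_IMVC_LF": 50.0,
    "A_VA_LF": 74.0, "tau_VA_LF": 90.0,
    "A_QTW_LF": 63.0, "tau_QTW_LF": 44.0,
}
COHORT_SDS = {
    "A_IMVC_HF": 9.0, "tau_IMVC_HF": 14.0,
    "A_VA_HF": 11.0, "tau_VA_HF": 30.0,
    "A_QTW_HF": 10.0, "tau_QTW_HF": 21.0,
    "A_IMVC_LF": 11.0, "tau_IMVC_LF": 30.0,
    "A_VA_LF": 13.0, "tau_VA_LF": 45.0,
    "A_QTW_LF": 11.0, "tau_QTW_LF": 27.0,
}

#: Default additive noise SD on the percent scale, calibrated once so that
#: individual exponential fits on default cohorts yield R-squared ~= 0.9,
#: matching the spread of fit quality in the published per-subject table.
DEFAULT_NOISE_SD = 3.0

DEFAULT_TIMES = tuple(float(t) for t in range(0, 161, 20))


def default_correlation() -> np.ndarray:
    """Default correlation over the 12 latent parameters.

    Within each condition the VA and Q_tw asymptotes are negatively
    correlated (-0.70) and the Q_tw asymptotes of the two conditions are
    positively correlated (+0.67), so that synthetic cohorts reproduce
    the qualitative individual-level structure of the real one; all other
    cross-correlations are zero.  The resulting matrix is slightly
    indefinite and is repaired to the nearest PSD correlation matrix at
    sampling time.
    """
    idx = {name: i for i, name in enumerate(PARAM_COLUMNS)}
    R = np.eye(len(PARAM_COLUMNS))

    def set_corr(a: str, b: str, rho: float) -> None:
        R[idx[a], idx[b]] = R[idx[b], idx[a]] = rho

    set_corr("A_VA_HF", "A_QTW_HF", -0.70)
    set_corr("A_VA_LF", "A_QTW_LF", -0.70)
    set_corr("A_QTW_HF", "A_QTW_LF", 0.67)
    return R


def nearest_psd(corr: np.ndarray, repair_tol: float = 0.15) -> np.ndarray:
    """Repair a symmetric correlation matrix to the nearest PSD one.

    Negative eigenvalues are clipped to zero, the matrix reconstructed
    and rescaled back to unit diagonal.  If any entry moves by more than
    ``repair_tol`` the input is considered structurally invalid and a
    ``ValueError`` is raised rather than silently changing the model.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
        raise ValueError("correlation matrix must have unit diagonal")
    w, V = np.linalg.eigh(corr)
    if w.min() >= -1e-12:
        return corr
    w_clipped = np.clip(w, 0.0, None)
    repaired = (V * w_clipped) @ V.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    repaired = (repaired + repaired.T) / 2.0
    np.fill_diagonal(repaired, 1.0)
    if np.max(np.abs(repaired - corr)) > repair_tol:
        raise ValueError(
            "correlation matrix is too far from positive semi-definite "
            f"(max repair {np.max(np.abs(repaired - corr)):.3f} > {repair_tol})"
        )
    return repaired


@dataclass
class CohortConfig:
    """Configuration of the latent-parameter cohort generator."""

    n_subjects: int = 13
    means: dict = field(default_factory=lambda: dict(COHORT_MEANS))
    sds: dict = field(default_factory=lambda: dict(COHORT_SDS))
    correlation: np.ndarray = field(default_factory=default_correlation)
    noise_sd: float = DEFAULT_NOISE_SD
    times: tuple = DEFAULT_TIMES
    seed: int = 0
    repair_tol: float = 0.15

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        missing = [c for c in PARAM_COLUMNS if c not in self.means or c not in self.sds]
        if missing:
            raise ValueError(f"means/sds missing parameters: {missing}")
        if any(self.sds[c] < 0 for c in PARAM_COLUMNS):
            raise ValueError("all SDs must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        times = tuple(float(t) for t in self.times)
        if times[0] != 0.0 or any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("times must be strictly increasing and start at 0")
        self.times = times
        self.correlation = nearest_psd(np.asarray(self.correlation, float), self.repair_tol)


def generate_cohort_parameters(config: CohortConfig) -> pd.DataFrame:
    """Draw per-subject true (A, tau) for every variable x condition.

    Latent parameters come from a truncated multivariate normal with the
    configured means, SDs and correlation; rows violating the physical
    ranges A in (0, 100] and tau > 0 are redrawn, which preserves the
    configured correlation approximately.  Returns one row per subject
    with columns :data:`PARAM_COLUMNS` and a ``subject_id`` index column.
    """
    rng = np.random.default_rng(config.seed)
    mu = np.array([config.means[c] for c in PARAM_COLUMNS])
    sd = np.array([config.sds[c] for c in PARAM_COLUMNS])
    cov = config.correlation * np.outer(sd, sd)
    is_a = np.array([c.startswith("A_") for c in PARAM_COLUMNS])

    def valid(rows: np.ndarray) -> np.ndarray:
        ok_a = np.all((rows[:, is_a] > 0.0) & (rows[:, is_a] <= 100.0), axis=1)
        ok_tau = np.all(rows[:, ~is_a] > 0.0, axis=1)
        return ok_a & ok_tau

    draws = rng.multivariate_normal(mu, cov, size=config.n_subjects, method="svd")
    bad = ~valid(draws)
    for _ in range(1000):
        if not bad.any():
            break
        draws[bad] = rng.multivariate_normal(mu, cov, size=int(bad.sum()), method="svd")
        bad = ~valid(draws)
    else:
        raise RuntimeError("could not draw parameters inside physical ranges")

    df = pd.DataFrame(draws, columns=list(PARAM_COLUMNS))
    df.insert(0, "subject_id", [f"{i + 1:02d}" for i in range(config.n_subjects)])
    return df


def generate_observations(
    true_params: pd.DataFrame,
    times=DEFAULT_TIMES,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
) -> list[FatigueSeries]:
    """Simulate noisy fatigue time series from true parameters.

    Each series is the exponential model evaluated at ``times`` plus
    independent homoscedastic Gaussian noise on the percent scale.  The
    t = 0 point is fixed to exactly 100 regardless of noise, because the
    baseline test defines the normalization.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    times = np.asarray(times, dtype=float)
    if times.size == 0 or times[0] != 0.0:
        raise ValueError("times must include 0 as the first element")
    rng = np.random.default_rng(seed)
    out: list[FatigueSeries] = []
    for _, row in true_params.iterrows():
        for cond in CONDITIONS:
            for var in VARIABLES:
                a, tau = row[f"A_{var}_{cond}"], row[f"tau_{var}_{cond}"]
                values = exp_decay(times, a, tau)
                if noise_sd > 0:
                    values = values + rng.normal(0.0, noise_sd, size=times.size)
                values[0] = 100.0
                out.append(
                    FatigueSeries(
                        subject_id=str(row["subject_id"]),
                        condition=cond,
                        variable=var,
                        times=times,
                        values=values,
                    )
                )
    return out


@dataclass
class TraceConfig:
    """Shape of one simulated isometric neuromuscular-test torque trace.

    The trace is a linear rise to a maximal-effort plateau, a 100 Hz
    doublet twitch superimposed on the plateau at ``stim_times[0]``,
    continued effort for ~1 s, relaxation, and a resting potentiated
    doublet at ``stim_times[1]``.  The doublet transient uses the
    single-peak shape ``amp * (s/Tc) * exp(1 - s/Tc)`` which is zero at
    onset and peaks at exactly ``amp`` after ``Tc`` seconds.
    """

    sampling_rate: float = 2000.0
    plateau_torque: float = 250.0
    rise_time: float = 1.0
    twitch_amplitude: float = 10.0          # superimposed doublet, N.m
    resting_twitch_amplitude: float = 96.0  # potentiated resting doublet, N.m
    twitch_contraction_time: float = 0.06   # time to twitch peak Tc, s
    stim_times: tuple = (2.5, 4.5)
    effort_after_stim: float = 1.0          # maximal effort held past the stimulus, s
    relax_tau: float = 0.08                 # voluntary relaxation time constant, s
    duration: float = 6.0
    baseline_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.twitch_contraction_time <= 0:
            raise ValueError("twitch_contraction_time must be positive")
        if len(self.stim_times) != 2:
            raise ValueError("exactly two stimulus times are required")
        t1, t2 = self.stim_times
        if not t1 < t2:
            raise ValueError("stim_times must be strictly increasing")
        if t2 - t1 < self.effort_after_stim + 8 * self.twitch_contraction_time:
            raise ValueError("stimulus transients overlap: stimuli too close")
        if not (0 < t1 and t2 + 10 * self.twitch_contraction_time < self.duration):
            raise ValueError("stim_times must lie inside the trace duration")
        if self.rise_time <= 0 or self.rise_time >= t1:
            raise ValueError("rise must complete before the first stimulus")
        if self.baseline_noise_sd < 0:
            raise ValueError("baseline_noise_sd must be non-negative")


def _twitch(t: np.ndarray, onset: float, amp: float, tc: float) -> np.ndarray:
    s = np.maximum(t - onset, 0.0)
    return amp * (s / tc) * np.exp(1.0 - s / tc)


def generate_nm_trace(config: TraceConfig) -> tuple[TorqueTrace, NMTestMetrics]:
    """Build one neuromuscular-test torque trace with exact ground truth.

    Returns the trace (with stimulus markers set at the two stimulation
    onsets) and the metrics used in its construction: the IMVC plateau,
    maximal pre-stimulus torque, torque at stimulation, superimposed
    twitch, resting potentiated twitch and the resulting voluntary
    activation.
    """
    fs = config.sampling_rate
    n = int(round(config.duration * fs)) + 1
    t = np.arange(n) / fs
    t_sup, t_rest = (float(s) for s in config.stim_times)

    # voluntary torque envelope: linear rise, plateau, exponential relaxation
    relax_start = t_sup + config.effort_after_stim
    envelope = np.where(
        t < config.rise_time,
        config.plateau_torque * t / config.rise_time,
        config.plateau_torque,
    )
    after = t >= relax_start
    envelope[after] = config.plateau_torque * np.exp(-(t[after] - relax_start) / config.relax_tau)

    torque = (
        envelope
        + _twitch(t, t_sup, config.twitch_amplitude, config.twitch_contraction_time)
        + _twitch(t, t_rest, config.resting_twitch_amplitude, config.twitch_contraction_time)
    )
    if config.baseline_noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        torque = torque + rng.normal(0.0, config.baseline_noise_sd, size=n)

    trace = TorqueTrace(
        time=t,
        torque=torque,
        stim_markers=(t_sup, t_rest),
        sampling_rate=fs,
    )
    t_max = t_stim = plateau = config.plateau_torque
    st = config.twitch_amplitude
    q_tw = config.resting_twitch_amplitude
    va = compute_voluntary_activation(st, t_stim, t_max, q_tw)
    truth = NMTestMetrics(
        t_stim_super=t_sup,
        T_max=t_max,
        T_stim=t_stim,
        ST=st,
        Q_tw=q_tw,
        imvc_plateau=plateau,
        VA=va,
        ST_raw=st,
        VA_raw=va,
    )
    return trace, truth
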