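"""Neuromuscular-test metrics from a raw isometric torque trace.

One test comprises a maximal isometric contraction with a superimposed
100 Hz doublet delivered at the torque plateau, followed ~2 s later by a
second doublet on the relaxed, potentiated muscle.  From the trace this
module extracts the IMVC plateau (mean torque over the 500 ms before the
superimposed stimulus), the maximal pre-stimulus torque T_max, the
torque at stimulation T_stim, the superimposed twitch ST, the resting
potentiated twitch Q_tw, and voluntary activation by twitch
interpolation with correction for stimuli delivered off the true peak::

    VA = (1 - (ST * (T_stim / T_max)) / Q_tw) * 100
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "TorqueTrace",
    "NMTestMetrics",
    "BaselineCheck",
    "detect_stimulus_times",
    "compute_imvc_plateau",
    "extract_superimposed_twitch",
    "extract_resting_twitch",
    "compute_voluntary_activation",
    "check_baseline",
    "normalize_to_baseline",
    "extract_nm_metrics",
]

#: Post-stimulus search windows (s): the doublet twitch peaks well within
#: these at 100 Hz; both are configurable per call.
SUPERIMPOSED_WINDOW = 0.3
RESTING_WINDOW = 0.5
PLATEAU_WINDOW = 0.5
RESTING_BASELINE_WINDOW = 0.1


@dataclass(frozen=True)
class TorqueTrace:
    """Raw sampled torque of one neuromuscular test.

    ``time`` must be a uniform grid (within 1 ppm) in seconds, ``torque``
    in N.m; ``stim_markers`` carries the 0-2 known stimulus onset times
    when the acquisition recorded them.
    """

    time: np.ndarray
    torque: np.ndarray
    stim_markers: tuple = ()
    sampling_rate: float = 2000.0

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        torque = np.asarray(self.torque, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "torque", torque)
        object.__setattr__(self, "stim_markers", tuple(float(s) for s in self.stim_markers))
        if time.ndim != 1 or time.shape != torque.shape or time.size < 2:
            raise ValueError("time and torque must be 1-D arrays of equal length >= 2")
        dt = np.diff(time)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if np.ptp(dt) > 1e-6 * dt.mean():
            raise ValueError("time grid must be uniform within 1 ppm")
        if not np.all(np.isfinite(torque)):
            raise ValueError("torque must be finite")
        if len(self.stim_markers) > 2:
            raise ValueError("at most 2 stimulus markers per test window")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def index_at(self, t: float) -> int:
        """Index of the grid sample nearest to time ``t``."""
        i = int(round((t - self.time[0]) / self.dt))
        if not 0 <= i < self.time.size:
            raise ValueError(f"time {t} s outside the trace")
        return i


@dataclass(frozen=True)
class NMTestMetrics:
    """Extracted metrics of one neuromuscular test.

    ``ST_raw`` and ``VA_raw`` keep the unclamped values for audit when
    noise drives ST below 0 or VA outside [0, 100].
    """

    t_stim_super: float
    T_max: float
    T_stim: float
    ST: float
    Q_tw: float
    imvc_plateau: float
    VA: float
    ST_raw: float = float("nan")
    VA_raw: float = float("nan")

    @property
    def va_clamped(self) -> bool:
        return self.VA != self.VA_raw


@dataclass(frozen=True)
class BaselineCheck:
    """Result of the pre-test plateau quality gate (>= 95 % of control)."""

    plateau: float
    control_imvc: float
    ratio: float
    passed: bool


def detect_stimulus_times(trace: TorqueTrace) -> list[float]:
    """Stimulus onset times, from markers or torque-derivative transients.

    When the trace carries stimulus markers they are returned as-is.
    Otherwise the two largest positive torque-derivative transients
    separated by at least 1 s are located (each doublet onset produces a
    sharp positive derivative spike).
    """
    if trace.stim_markers:
        return sorted(trace.stim_markers)
    deriv = np.gradient(trace.torque, trace.dt)
    peaks, props = signal.find_peaks(deriv, height=0.0)
    if peaks.size == 0:
        raise ValueError("stimuli not found: no positive derivative transients")
    order = peaks[np.argsort(props["peak_heights"])[::-1]]
    min_sep = int(round(1.0 * trace.sampling_rate))
    chosen: list[int] = []
    for idx in order:
        if all(abs(idx - c) >= min_sep for c in chosen):
            chosen.append(int(idx))
        if len(chosen) == 2:
            break
    if len(chosen) < 2:
        raise ValueError("stimuli not found: fewer than 2 separated transients")
    return sorted(float(trace.time[i]) for i in chosen)


def compute_imvc_plateau(
    trace: TorqueTrace, t_stim_super: float, window: float = PLATEAU_WINDOW
) -> float:
    """Mean torque over the ``window`` seconds before the superimposed stimulus.

    The window is [t_stim - window, t_stim), end-exclusive so the
    stimulus sample itself is never averaged in.
    """
    i_stim = trace.index_at(t_stim_super)
    n_win = int(round(window * trace.sampling_rate))
    if i_stim - n_win < 0:
        raise ValueError("plateau window extends before the start of the trace")
    return float(trace.torque[i_stim - n_win : i_stim].mean())


def _contraction_start(trace: TorqueTrace, i_stim: int) -> int:
    """First index of the contiguous contraction containing the stimulus."""
    threshold = 0.1 * trace.torque[i_stim]
    below = np.nonzero(trace.torque[:i_stim] < threshold)[0]
    return int(below[-1] + 1) if below.size else 0


def extract_superimposed_twitch(
    trace: TorqueTrace,
    t_stim_super: float,
    window: float = SUPERIMPOSED_WINDOW,
    clamp: bool = True,
) -> tuple[float, float, float]:
    """(T_max, T_stim, ST) around the superimposed stimulus.

    T_max is the maximal torque produced during the current contraction
    before the stimulation (not over the whole trace), T_stim the torque
    at the stimulation instant, and ST the superimposed twitch: the
    maximal torque within ``window`` after the stimulus minus T_stim,
    clamped at 0 when relaxation already started.
    """
    i_stim = trace.index_at(t_stim_super)
    n_win = int(round(window * trace.sampling_rate))
    if i_stim + n_win >= trace.time.size:
        raise ValueError("post-stimulus window truncated by the end of the trace")
    i0 = _contraction_start(trace, i_stim)
    if i0 >= i_stim:
        raise ValueError("no voluntary contraction found before the stimulus")
    t_max = float(trace.torque[i0:i_stim].max())
    t_stim = float(trace.torque[i_stim])
    # "maximal torque attained after the stimulation": the stimulus sample
    # itself is excluded, so noise or relaxation can make the raw ST negative
    st_raw = float(trace.torque[i_stim + 1 : i_stim + n_win + 1].max() - t_stim)
    if st_raw < 0 and clamp:
        logger.warning("superimposed twitch %.3f N.m clamped to 0", st_raw)
    return t_max, t_stim, max(st_raw, 0.0) if clamp else st_raw


def extract_resting_twitch(
    trace: TorqueTrace,
    t_stim_rest: float,
    window: float = RESTING_WINDOW,
    baseline_window: float = RESTING_BASELINE_WINDOW,
    rest_fraction: float = 0.1,
) -> float:
    """Potentiated resting twitch amplitude Q_tw.

    The muscle must be relaxed at the stimulus (torque below
    ``rest_fraction`` of the trace maximum); the twitch amplitude is the
    post-stimulus maximum within ``window`` minus the mean torque over
    the ``baseline_window`` before the stimulus (dynamometer zero drifts,
    so an absolute zero is not assumed).
    """
    i_stim = trace.index_at(t_stim_rest)
    n_win = int(round(window * trace.sampling_rate))
    n_base = int(round(baseline_window * trace.sampling_rate))
    if i_stim - n_base < 0 or i_stim + n_win >= trace.time.size:
        raise ValueError("resting-twitch windows extend outside the trace")
    if trace.torque[i_stim] >= rest_fraction * trace.torque.max():
        raise ValueError("not at rest: torque above baseline at the resting stimulus")
    baseline = float(trace.torque[i_stim - n_base : i_stim].mean())
    return float(trace.torque[i_stim : i_stim + n_win + 1].max() - baseline)


def compute_voluntary_activation(
    ST: float, T_stim: float, T_max: float, Q_tw: float
) -> float:
    """Voluntary activation (%) by corrected twitch interpolation.

    ``VA = (1 - (ST * (T_stim / T_max)) / Q_tw) * 100``, clamped to
    [0, 100] with a warning; the T_stim/T_max factor corrects for
    stimuli delivered slightly off the true torque peak.
    """
    if Q_tw <= 0:
        raise ValueError("Q_tw must be positive")
    if T_max <= 0:
        raise ValueError("T_max must be positive")
    if not 0 < T_stim <= T_max + 1e-9:
        raise ValueError("require 0 < T_stim <= T_max")
    va = (1.0 - (ST * (T_stim / T_max)) / Q_tw) * 100.0
    if not 0.0 <= va <= 100.0:
        logger.warning("voluntary activation %.2f%% clamped to [0, 100]", va)
    return float(np.clip(va, 0.0, 100.0))


def check_baseline(plateau: float, control_imvc: float) -> BaselineCheck:
    """Gate a baseline test: the plateau must reach 95 % of the control IMVC."""
    if control_imvc <= 0:
        raise ValueError("control IMVC must be positive")
    ratio = plateau / control_imvc
    return BaselineCheck(
        plateau=float(plateau),
        control_imvc=float(control_imvc),
        ratio=float(ratio),
        passed=bool(ratio >= 0.95 - 1e-12),
    )


def normalize_to_baseline(raw_values, baseline_value: float) -> np.ndarray:
    """Express values in percent of the pre-fatigue baseline (baseline -> 100)."""
    if baseline_value <= 0:
        raise ValueError("baseline value must be positive")
    return np.asarray(raw_values, dtype=float) * 100.0 / baseline_value


def extract_nm_metrics(trace: TorqueTrace) -> NMTestMetrics:
    """Full extraction for one test: stimuli, plateau, ST, Q_tw and VA."""
    t_sup, t_rest = detect_stimulus_times(trace)
    plateau = compute_imvc_plateau(trace, t_sup)
    t_max, t_stim, st_raw = extract_superimposed_twitch(trace, t_sup, clamp=False)
    st = max(st_raw, 0.0)
    if st_raw < 0:
        logger.warning("superimposed twitch %.3f N.m clamped to 0", st_raw)
    q_tw = extract_resting_twitch(trace, t_rest)
    va = compute_voluntary_activation(st, t_stim, t_max, q_tw)
    va_raw = (1.0 - (st_raw * (t_stim / t_max)) / q_tw) * 100.0
    return NMTestMetrics(
        t_stim_super=t_sup,
        T_max=t_max,
        T_stim=t_stim,
        ST=st,
        Q_tw=q_tw,
        imvc_plateau=plateau,
        VA=va,
        ST_raw=st_raw,
        VA_raw=va_raw,
    )
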