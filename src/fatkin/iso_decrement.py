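"""VA and Q_tw expressed as closed-form functions of IMVC decline.

Because IMVC, VA and Q_tw all follow the same exponential time course,
time can be eliminated between the fitted models.  Inverting the IMVC
model gives the accumulated contraction time at which IMVC reaches a
given level::

    t = -tau_IMVC * ln((IMVC - A_IMVC) / (100 - A_IMVC))

and substituting into the model of another variable DV (VA or Q_tw)
gives the closed form::

    DV = A_DV + (100 - A_DV) * ((IMVC - A_IMVC) / (100 - A_IMVC)) ** (tau_IMVC / tau_DV)

used to estimate, per subject, the VA and Q_tw reached at 10, 20 and
30 % IMVC decrease.  Levels at or below a subject's IMVC asymptote are
unreachable (the model never gets there) and are flagged, not estimated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import ExpFit, predict

logger = logging.getLogger(__name__)

__all__ = [
    "DecrementEstimate",
    "invert_imvc",
    "dv_at_imvc",
    "estimate_decrements",
]

DEFAULT_LEVELS = (10.0, 20.0, 30.0)


@dataclass(frozen=True)
class DecrementEstimate:
    """Model-based VA or Q_tw at one IMVC decrement for one subject."""

    subject_id: str
    condition: str
    variable: str
    imvc_decrease: float   # percent points of the normalized scale
    dv_value: float        # percent of baseline; NaN when unreachable
    reachable: bool


def invert_imvc(fit_imvc: ExpFit, imvc_level: float) -> float:
    """Accumulated contraction time at which fitted IMVC equals ``imvc_level``.

    Defined only for levels strictly above the asymptote (and at most
    100); levels at or below ``A`` are never reached by the model.
    """
    if imvc_level > 100.0:
        raise ValueError("IMVC level cannot exceed 100 % of baseline")
    if imvc_level <= fit_imvc.A:
        raise ValueError(
            f"IMVC level {imvc_level} is at or below the asymptote "
            f"{fit_imvc.A:.1f} (unreachable)"
        )
    ratio = (imvc_level - fit_imvc.A) / (100.0 - fit_imvc.A)
    return float(-fit_imvc.tau * np.log(ratio))


def dv_at_imvc(fit_dv: ExpFit, fit_imvc: ExpFit, imvc_level: float) -> float:
    """VA or Q_tw predicted at the time IMVC reaches ``imvc_level``.

    Closed-form composition of the inverted IMVC model with the DV
    model; algebraically identical to
    ``predict(fit_dv, invert_imvc(fit_imvc, imvc_level))``.
    """
    if imvc_level > 100.0:
        raise ValueError("IMVC level cannot exceed 100 % of baseline")
    if imvc_level <= fit_imvc.A:
        raise ValueError(
            f"IMVC level {imvc_level} is at or below the asymptote "
            f"{fit_imvc.A:.1f} (unreachable)"
        )
    ratio = (imvc_level - fit_imvc.A) / (100.0 - fit_imvc.A)
    return float(fit_dv.A + (100.0 - fit_dv.A) * ratio ** (fit_imvc.tau / fit_dv.tau))


def estimate_decrements(
    fits: pd.DataFrame,
    levels=DEFAULT_LEVELS,
    variables=("VA", "QTW"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject VA/Q_tw estimates at each IMVC decrement.

    ``fits`` is a long fitted-parameter table with columns
    ``subject_id, condition, variable, A_pct, tau_s``.  Returns the
    per-subject estimate table (one row per subject x condition x
    variable x level, with reachability flags) and the cohort means over
    reachable subjects per condition x variable x level.
    """
    rows: list[DecrementEstimate] = []
    n_unreachable = 0
    for (subject, cond), grp in fits.groupby(["subject_id", "condition"], sort=True):
        by_var = {v: g.iloc[0] for v, g in grp.groupby("variable")}
        if "IMVC" not in by_var:
            logger.warning("subject %s %s: no IMVC fit, skipped", subject, cond)
            continue
        r = by_var["IMVC"]
        fit_imvc = ExpFit(r.A_pct, r.tau_s, 1.0, 0.0, 9, 0.0, True)
        for var in variables:
            if var not in by_var:
                logger.warning("subject %s %s: no %s fit, skipped", subject, cond, var)
                continue
            r = by_var[var]
            fit_dv = ExpFit(r.A_pct, r.tau_s, 1.0, 0.0, 9, 0.0, True)
            for level in levels:
                target = 100.0 - level
                reachable = target > fit_imvc.A
                if reachable:
                    value = dv_at_imvc(fit_dv, fit_imvc, target)
                else:
                    value = float("nan")
                    n_unreachable += 1
                rows.append(
                    DecrementEstimate(str(subject), cond, var, float(level), value, reachable)
                )
    if n_unreachable:
        logger.info("%d subject x level decrements unreachable (below asymptote)", n_unreachable)
    est = pd.DataFrame([vars(r) for r in rows])
    means = (
        est[est.reachable]
        .groupby(["condition", "variable", "imvc_decrease"], sort=True)["dv_value"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    return est, means
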