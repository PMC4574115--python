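"""Quantifying reversal of senescence-associated methylation.

After p16 knockdown, deeply senescent (DS) cultures transiently return
toward the early-proliferating (EP) state.  Per senDMP the residual distance
from EP is |mean over timepoint replicates − mean over EP replicates|; a
site counts as reverted below a threshold t when its residual is strictly
less than t (0.3 = below the calling threshold, 0.1 = essentially complete
reversal).  Residual drift of sites called only in the other experiment is
tested for directionality against that experiment's EP→DS deltas with
Kendall's tau-b plus a simple sign-concordance fraction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import BetaMatrix

logger = logging.getLogger("senesig")

DEFAULT_THRESHOLDS = (0.3, 0.1)


@dataclass
class ReversalReport:
    """Per-group reversal fractions and per-site residuals.

    ``fractions`` has one row per (group, threshold) with columns n_below,
    n_total, fraction; ``residuals`` maps group → Series of per-probe
    |timepoint mean − EP mean|.
    """

    fractions: pd.DataFrame
    residuals: dict


@dataclass
class DirectionalityResult:
    tau: float
    p: float
    concordance: float
    n: int
    message: str = ""


def _group_members(signature_groups) -> dict[str, list]:
    """Accept a SignatureGroups instance or a mapping group → probe ids."""
    if hasattr(signature_groups, "agree"):
        return {
            g: sorted(getattr(signature_groups, g))
            for g in ("exp1_only", "exp2_only", "agree", "disagree")
            if len(getattr(signature_groups, g)) > 0
        }
    return {g: sorted(ps) for g, ps in dict(signature_groups).items()}


def reversal_fractions(
    beta_timepoint: BetaMatrix,
    beta_ep: BetaMatrix,
    signature_groups,
    thresholds=DEFAULT_THRESHOLDS,
) -> ReversalReport:
    """Fraction of each signature group's sites within each threshold of EP.

    Both matrices may contain replicates; per probe the replicate means are
    compared.  Every signature probe must be present in both matrices.
    """
    groups = _group_members(signature_groups)
    wanted = sorted({p for ps in groups.values() for p in ps})
    missing = [
        p for p in wanted
        if p not in beta_timepoint.values.index or p not in beta_ep.values.index
    ]
    if missing:
        raise ValueError(
            f"{len(missing)} signature probes absent from a matrix, "
            f"e.g. {missing[:5]}"
        )
    tp_mean = beta_timepoint.values.loc[wanted].mean(axis=1, skipna=True)
    ep_mean = beta_ep.values.loc[wanted].mean(axis=1, skipna=True)
    residual = (tp_mean - ep_mean).abs()

    rows = []
    residuals = {}
    for g, probes in groups.items():
        res = residual.loc[probes]
        residuals[g] = res
        for t in thresholds:
            n_below = int((res < t).sum())
            rows.append(
                {
                    "group": g,
                    "threshold": float(t),
                    "n_below": n_below,
                    "n_total": len(probes),
                    "fraction": n_below / len(probes) if probes else math.nan,
                }
            )
    report = ReversalReport(pd.DataFrame(rows), residuals)
    for _, r in report.fractions.iterrows():
        logger.info(
            "reversal %s: %.1f%% (%d/%d) below %.2g",
            r["group"], 100 * r["fraction"], r["n_below"], r["n_total"],
            r["threshold"],
        )
    return report


def reversal_directionality(
    delta_timepoint, delta_reference, probes
) -> DirectionalityResult:
    """Directionality of residual drift at sites called only elsewhere.

    ``delta_timepoint`` maps probe → (timepoint mean − DS mean) and
    ``delta_reference`` maps probe → the reference experiment's DS − EP
    delta.  Returns Kendall tau-b between the two vectors over ``probes``,
    plus the fraction of probes whose deltas share a sign.
    """
    probes = sorted(probes)
    if len(probes) < 3:
        raise ValueError("need >=3 probes")
    dt = pd.Series(delta_timepoint, dtype=float)
    dr = pd.Series(delta_reference, dtype=float)
    missing = [p for p in probes if p not in dt.index or p not in dr.index]
    if missing:
        raise ValueError(f"delta maps do not cover probes, e.g. {missing[:5]}")
    x = dt.loc[probes].to_numpy()
    y = dr.loc[probes].to_numpy()
    concordance = float((np.sign(x) == np.sign(y)).mean())
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        msg = "a delta vector is constant; correlation undefined"
        logger.warning("reversal_directionality: %s", msg)
        return DirectionalityResult(
            math.nan, math.nan, concordance, len(probes), message=msg
        )
    tau, p = stats.kendalltau(x, y)
    return DirectionalityResult(float(tau), float(p), concordance, len(probes))
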