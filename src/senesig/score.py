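"""The per-sample senDMP score and cohort-level statistics built on it.

For a sample k the score is

    S_k = mean beta over hyper-senDMPs − mean beta over hypo-senDMPs + c

with offset c = 0.35 by default, chosen so that the lowest score in a
reference cohort sits near zero.  A higher S means a more DS-like (deeply
senescent) methylome: higher methylation at hyper-senDMPs and lower at
hypo-senDMPs.

Rank correlations use Kendall's tau-b (tie-corrected); two-group comparisons
use the Welch unequal-variance t-test with the sign convention
t = (mean_a − mean_b)/SE, so comparing normals (a) against tumors (b) with
higher tumor scores yields a negative t.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import BetaMatrix
from .signature import SenescenceSignature

logger = logging.getLogger("senesig")

DEFAULT_OFFSET = 0.35


@dataclass
class ScoreResult:
    """Per-sample senDMP scores and their hyper/hypo components.

    ``table`` is indexed by sample id with columns hyper_mean, hypo_mean, S,
    n_hyper_used, n_hypo_used.  ``coverage_hyper``/``coverage_hypo`` report
    the fraction of signature probes present in the scored matrix.
    """

    table: pd.DataFrame
    offset: float
    coverage_hyper: float
    coverage_hypo: float

    @property
    def scores(self) -> pd.Series:
        return self.table["S"]


@dataclass
class KendallResult:
    tau: float
    p: float
    n: int
    message: str = ""


@dataclass
class WelchResult:
    t: float
    p: float
    df: float
    degenerate: bool = False


def senescence_score(
    beta_cohort: BetaMatrix,
    signature: SenescenceSignature,
    offset: float = DEFAULT_OFFSET,
    min_coverage: float = 0.5,
) -> ScoreResult:
    """Compute the senDMP score for every sample of a cohort matrix.

    Means are taken over signature probes present in the matrix and
    non-missing for the sample.  If fewer than ``min_coverage`` of either
    probe list is present, scoring refuses rather than silently degrade.
    """
    present_hyper = [p for p in signature.hyper_probes if p in beta_cohort.values.index]
    present_hypo = [p for p in signature.hypo_probes if p in beta_cohort.values.index]
    cov_hyper = len(present_hyper) / signature.n_hyper
    cov_hypo = len(present_hypo) / signature.n_hypo
    for name, cov in (("hyper", cov_hyper), ("hypo", cov_hypo)):
        if cov < min_coverage:
            raise ValueError(
                f"only {cov:.1%} of {name}-senDMP probes present in the "
                f"cohort matrix (minimum {min_coverage:.0%})"
            )
    hyper = beta_cohort.values.loc[present_hyper]
    hypo = beta_cohort.values.loc[present_hypo]
    n_hyper_used = hyper.notna().sum(axis=0)
    n_hypo_used = hypo.notna().sum(axis=0)
    if (n_hyper_used == 0).any() or (n_hypo_used == 0).any():
        bad = list(
            n_hyper_used.index[(n_hyper_used == 0) | (n_hypo_used == 0)]
        )
        raise ValueError(f"zero usable signature probes for samples {bad[:5]}")
    hyper_mean = hyper.mean(axis=0, skipna=True)
    hypo_mean = hypo.mean(axis=0, skipna=True)
    table = pd.DataFrame(
        {
            "hyper_mean": hyper_mean,
            "hypo_mean": hypo_mean,
            "S": hyper_mean - hypo_mean + offset,
            "n_hyper_used": n_hyper_used,
            "n_hypo_used": n_hypo_used,
        }
    )
    logger.info(
        "senescence_score: %d samples, coverage hyper=%.1f%% hypo=%.1f%%",
        table.shape[0], 100 * cov_hyper, 100 * cov_hypo,
    )
    return ScoreResult(table, offset, cov_hyper, cov_hypo)


def _kendall(x, y, what: str) -> KendallResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError(f"{what}: need >=3 complete pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        msg = f"{what}: a vector is constant; correlation undefined"
        logger.warning(msg)
        return KendallResult(math.nan, math.nan, int(x.size), message=msg)
    tau, p = stats.kendalltau(x, y)  # tau-b with normal-approximation p
    return KendallResult(float(tau), float(p), int(x.size))


def hyper_hypo_correlation(
    beta_cohort: BetaMatrix, signature: SenescenceSignature
) -> KendallResult:
    """Kendall tau-b between per-sample hyper-senDMP and hypo-senDMP means.

    A negative tau means samples with high methylation at hyper-senDMPs show
    low methylation at hypo-senDMPs — the hallmark of a shared senescence
    burden across the signature.
    """
    res = senescence_score(beta_cohort, signature)
    return _kendall(
        res.table["hyper_mean"], res.table["hypo_mean"], "hyper_hypo_correlation"
    )


def score_covariate_association(scores, covariate) -> KendallResult:
    """Kendall tau-b between senDMP scores and a per-sample covariate (e.g. age).

    Pairs with a missing covariate are dropped; fewer than 3 complete pairs
    is an error.
    """
    scores = pd.Series(scores, dtype=float)
    covariate = pd.Series(covariate, dtype=float)
    joined = pd.concat([scores, covariate], axis=1, join="inner")
    return _kendall(
        joined.iloc[:, 0], joined.iloc[:, 1], "score_covariate_association"
    )


def compare_tumor_normal(scores_a, scores_b) -> WelchResult:
    """Welch two-sample t-test, t = (mean_a − mean_b)/SE.

    Zero variance in both arms with equal means gives t = 0, p = 1; zero
    variance with unequal means is flagged degenerate (infinite t).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each arm needs >=2 samples")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return WelchResult(0.0, 1.0, float(a.size + b.size - 2))
        t = math.inf if a.mean() > b.mean() else -math.inf
        return WelchResult(t, 0.0, float("nan"), degenerate=True)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    se2 = va / a.size + vb / b.size
    df = se2**2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    return WelchResult(float(t), float(p), float(df))
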