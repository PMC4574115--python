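"""Differential methylation position (DMP) calling.

Per-probe one-way ANOVA (F-test) between sample groups on beta values,
Benjamini–Hochberg false-discovery control, and effect-size thresholding.
A senDMP is a probe with q < 0.01 and an absolute beta difference > 0.3
between deeply senescent (DS) and early-proliferating (EP) cultures; both
inequalities are strict.

The tests run directly on beta values rather than M-values, because the
effect-size filter is defined on the beta scale.  No variance moderation is
applied: each probe is tested on its own replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import BetaMatrix, ProbeAnnotation, SampleTable, SEX_CHROMOSOMES

logger = logging.getLogger("senesig")

#: Smallest positive double; reported when within-group variance is zero but
#: group means differ (the F statistic is infinite).
TINY_P = np.nextafter(0.0, 1.0)
_ZERO_SS = 1e-24


@dataclass(frozen=True)
class DMPRecord:
    """One called differentially methylated position."""

    probe_id: str
    F: float
    p: float
    q: float
    delta: float  # mean(group B) - mean(group A)
    direction: str  # "hyper" if delta > 0 else "hypo"
    degenerate: bool = False


def anova_table(values: pd.DataFrame, labels: pd.Series, order=None) -> pd.DataFrame:
    """Vectorized per-row one-way ANOVA.

    Parameters
    ----------
    values
        features × samples numeric frame (NaN allowed = missing).
    labels
        sample → group label; only samples present in ``labels`` are used.
    order
        optional (group_a, group_b) pair fixing the sign of ``delta`` =
        mean(group_b) − mean(group_a).  With more than two groups ``delta``
        is NaN unless an order pair is given.

    Returns
    -------
    DataFrame indexed like ``values`` (rows failing the ≥2-per-group rule are
    dropped and logged) with columns F, p, delta, degenerate.

    Rows where all group means are equal get F = 0, p = 1.  Rows with zero
    within-group variance but unequal means get p = smallest positive double
    and ``degenerate`` = True.
    """
    labels = pd.Series(labels)
    samples = [s for s in values.columns if s in labels.index]
    if not samples:
        raise ValueError("no overlap between value columns and labelled samples")
    values = values[samples]
    labels = labels.loc[samples]
    groups = list(dict.fromkeys(labels))
    if len(groups) < 2:
        raise ValueError(f"need >=2 groups, got {groups}")

    X = values.to_numpy(dtype=float)
    present = ~np.isnan(X)
    k = len(groups)
    n_g = np.empty((k, X.shape[0]))
    sum_g = np.empty((k, X.shape[0]))
    ssw = np.zeros(X.shape[0])
    means = {}
    for gi, g in enumerate(groups):
        cols = (labels == g).to_numpy()
        Xg = X[:, cols]
        pg = present[:, cols]
        n_g[gi] = pg.sum(axis=1)
        sum_g[gi] = np.nansum(np.where(pg, Xg, 0.0), axis=1)
        with np.errstate(invalid="ignore"):
            mg = sum_g[gi] / n_g[gi]
        means[g] = mg
        ssw += np.nansum((Xg - mg[:, None]) ** 2, axis=1)

    usable = (n_g >= 2).all(axis=0)
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info(
            "anova: dropped %d probes with <2 non-missing samples in a group",
            n_dropped,
        )

    n_tot = n_g.sum(axis=0)
    grand = sum_g.sum(axis=0) / np.maximum(n_tot, 1)
    ssb = np.zeros(X.shape[0])
    for gi in range(k):
        with np.errstate(invalid="ignore"):
            ssb += n_g[gi] * (sum_g[gi] / np.maximum(n_g[gi], 1) - grand) ** 2

    df1 = k - 1
    df2 = n_tot - k
    F = np.zeros(X.shape[0])
    p = np.ones(X.shape[0])
    degenerate = np.zeros(X.shape[0], dtype=bool)

    null_rows = ssb <= _ZERO_SS
    degen_rows = (~null_rows) & (ssw <= _ZERO_SS)
    normal_rows = (~null_rows) & (~degen_rows)
    with np.errstate(divide="ignore", invalid="ignore"):
        F[normal_rows] = (ssb[normal_rows] / df1) / (ssw[normal_rows] / df2[normal_rows])
    p[normal_rows] = stats.f.sf(F[normal_rows], df1, df2[normal_rows])
    # p from the continuous F tail can underflow to 0; keep it positive
    p[normal_rows] = np.maximum(p[normal_rows], TINY_P)
    F[degen_rows] = np.inf
    p[degen_rows] = TINY_P
    degenerate[degen_rows] = True

    if order is not None:
        a, b = order
        if a not in means or b not in means:
            raise ValueError(f"order groups {order} not among labels {groups}")
        delta = means[b] - means[a]
    elif k == 2:
        delta = means[groups[1]] - means[groups[0]]
    else:
        delta = np.full(X.shape[0], np.nan)

    out = pd.DataFrame(
        {"F": F, "p": p, "delta": delta, "degenerate": degenerate},
        index=values.index,
    )
    return out[usable]


def f_test(beta: BetaMatrix, groups, order=None) -> pd.DataFrame:
    """Per-probe one-way F-test between sample groups of a beta matrix.

    ``groups`` maps sample id → group label.  See :func:`anova_table` for the
    returned columns and degenerate-case conventions.
    """
    return anova_table(beta.values, pd.Series(groups), order=order)


def bh_qvalues(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_dmps(
    beta: BetaMatrix,
    samples: SampleTable,
    group_a: str,
    group_b: str,
    *,
    experiment: str | None = None,
    q_thresh: float = 0.01,
    delta_thresh: float = 0.3,
) -> list[DMPRecord]:
    """Call DMPs between two sample groups.

    Returns exactly the probes with q < ``q_thresh`` AND |delta| >
    ``delta_thresh`` (both strict), where delta = mean(group_b) −
    mean(group_a), sorted by |delta| descending with ties broken by probe id.
    BH correction is applied across all probes tested in this contrast.
    """
    sel_a = samples.samples_in(group_a, experiment)
    sel_b = samples.samples_in(group_b, experiment)
    if len(sel_a) < 2 or len(sel_b) < 2:
        raise ValueError(
            f"each group needs >=2 samples: {group_a}={len(sel_a)}, "
            f"{group_b}={len(sel_b)}"
        )
    labels = pd.Series(
        {**{s: group_a for s in sel_a}, **{s: group_b for s in sel_b}}
    )
    table = anova_table(beta.values, labels, order=(group_a, group_b))
    table = table.copy()
    table["q"] = bh_qvalues(table["p"].to_numpy())
    hits = table[(table["q"] < q_thresh) & (table["delta"].abs() > delta_thresh)]
    # |delta| descending, ties by probe id
    ordix = sorted(hits.index, key=lambda pid: (-abs(hits.at[pid, "delta"]), pid))
    records = [
        DMPRecord(
            probe_id=pid,
            F=float(hits.at[pid, "F"]),
            p=float(hits.at[pid, "p"]),
            q=float(hits.at[pid, "q"]),
            delta=float(hits.at[pid, "delta"]),
            direction="hyper" if hits.at[pid, "delta"] > 0 else "hypo",
            degenerate=bool(hits.at[pid, "degenerate"]),
        )
        for pid in ordix
    ]
    logger.info(
        "call_dmps %s vs %s: %d/%d probes pass q<%g and |delta|>%g",
        group_a, group_b, len(records), len(table), q_thresh, delta_thresh,
    )
    return records


def dmp_table(records: list[DMPRecord]) -> pd.DataFrame:
    """DMP records as a DataFrame indexed by probe id (call order preserved)."""
    if not records:
        return pd.DataFrame(
            columns=["F", "p", "q", "delta", "direction", "degenerate"]
        )
    return pd.DataFrame(
        [
            {
                "probe_id": r.probe_id, "F": r.F, "p": r.p, "q": r.q,
                "delta": r.delta, "direction": r.direction,
                "degenerate": r.degenerate,
            }
            for r in records
        ]
    ).set_index("probe_id")


@dataclass
class FilterPolicy:
    """Which probe classes to remove before analysis."""

    drop_sex_chromosomes: bool = True
    drop_multimapping: bool = True
    drop_low_detection: bool = True


def filter_probes(
    beta: BetaMatrix, annotation: ProbeAnnotation, policy: FilterPolicy | None = None
) -> BetaMatrix:
    """Remove flagged probes (and, per policy, sex-chromosome probes).

    Every probe of the matrix must be annotated; removal counts are logged
    per reason.  A probe matching several removal reasons is removed once.
    """
    policy = policy or FilterPolicy()
    missing = annotation.covers(beta.probe_ids)
    if missing:
        raise ValueError(
            f"{len(missing)} probes missing from annotation, e.g. {missing[:5]}"
        )
    t = annotation.table.loc[beta.probe_ids]
    drop = pd.Series(False, index=t.index)
    reasons = {}
    if policy.drop_multimapping:
        m = t["flags"].map(lambda fs: "multimapping" in fs)
        reasons["multimapping"] = int(m.sum())
        drop |= m
    if policy.drop_low_detection:
        m = t["flags"].map(lambda fs: "low_detection" in fs)
        reasons["low_detection"] = int(m.sum())
        drop |= m
    if policy.drop_sex_chromosomes:
        m = t["chrom"].isin(SEX_CHROMOSOMES) | t["flags"].map(
            lambda fs: "sex_chromosome" in fs
        )
        reasons["sex_chromosome"] = int(m.sum())
        drop |= m
    for reason, n in reasons.items():
        logger.info("filter_probes: %d probes flagged %s", n, reason)
    kept = beta.values.loc[~drop.to_numpy()]
    logger.info("filter_probes: %d -> %d probes", len(drop), len(kept))
    return BetaMatrix(kept)
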