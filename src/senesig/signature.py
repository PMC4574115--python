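"""Senescence signature construction and set-level statistics.

Combines the DMP calls of two replicated experiments into the three senDMP
signature groups ("experiment 1 only", "experiment 2 only", "agree"), the
four-category partition of cross-experiment DS discordance, resampling-based
overlap enrichment, and the co-methylation profile of called probes with
their nearest genomic neighbors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dmp import DMPRecord
from .io import ProbeAnnotation

logger = logging.getLogger("senesig")


# ---------------------------------------------------------------------------
# Signature groups
# ---------------------------------------------------------------------------


@dataclass
class SenescenceSignature:
    """Hyper- and hypo-senDMP probe lists for one signature group."""

    hyper_probes: tuple
    hypo_probes: tuple
    source_group: str = ""

    def __post_init__(self) -> None:
        self.hyper_probes = tuple(self.hyper_probes)
        self.hypo_probes = tuple(self.hypo_probes)
        if set(self.hyper_probes) & set(self.hypo_probes):
            raise ValueError("hyper and hypo probe lists overlap")
        if self.n_hyper + self.n_hypo < 1:
            raise ValueError("signature must contain at least one probe")

    @property
    def n_hyper(self) -> int:
        return len(self.hyper_probes)

    @property
    def n_hypo(self) -> int:
        return len(self.hypo_probes)

    def directions(self) -> dict[str, str]:
        d = {p: "hyper" for p in self.hyper_probes}
        d.update({p: "hypo" for p in self.hypo_probes})
        return d


@dataclass
class SignatureGroups:
    """The five disjoint outcomes of combining two experiments' senDMP calls.

    Each of ``exp1_only``, ``exp2_only``, ``agree``, ``disagree`` maps
    probe id → direction ("hyper"/"hypo"; for ``disagree`` the direction in
    experiment 1).  ``unclassified`` holds probes called in one experiment
    whose beta difference in the other is at least the minor threshold
    without the probe being called there.
    """

    exp1_only: dict
    exp2_only: dict
    agree: dict
    disagree: dict
    unclassified: set

    def signature(self, group: str) -> SenescenceSignature:
        members = getattr(self, group)
        return SenescenceSignature(
            hyper_probes=tuple(sorted(p for p, d in members.items() if d == "hyper")),
            hypo_probes=tuple(sorted(p for p, d in members.items() if d == "hypo")),
            source_group=group,
        )

    def counts(self) -> dict[str, int]:
        return {
            "exp1_only": len(self.exp1_only),
            "exp2_only": len(self.exp2_only),
            "agree": len(self.agree),
            "disagree": len(self.disagree),
            "unclassified": len(self.unclassified),
        }


def _direction(delta: float) -> str:
    return "hyper" if delta > 0 else "hypo"


def classify_signature_groups(
    dmps1: list[DMPRecord],
    dmps2: list[DMPRecord],
    delta1,
    delta2,
    minor_thresh: float = 0.1,
) -> SignatureGroups:
    """Partition the union of two experiments' senDMP calls.

    A probe called in both experiments lands in ``agree`` (same delta sign)
    or ``disagree`` (opposite sign).  A probe called only in experiment 1
    lands in ``exp1_only`` when |delta in experiment 2| < ``minor_thresh``,
    otherwise in ``unclassified`` (symmetric for experiment 2).  ``delta1``
    and ``delta2`` map probe → beta difference and must cover every called
    probe.
    """
    called1 = {r.probe_id: r.delta for r in dmps1}
    called2 = {r.probe_id: r.delta for r in dmps2}
    union = set(called1) | set(called2)
    missing = [p for p in union if p not in delta1 or p not in delta2]
    if missing:
        raise ValueError(
            f"{len(missing)} called probes absent from a delta map, "
            f"e.g. {sorted(missing)[:5]}"
        )
    groups = SignatureGroups({}, {}, {}, {}, set())
    for p in union:
        in1, in2 = p in called1, p in called2
        if in1 and in2:
            if np.sign(called1[p]) == np.sign(called2[p]):
                groups.agree[p] = _direction(called1[p])
            else:
                groups.disagree[p] = _direction(called1[p])
        elif in1:
            if abs(delta2[p]) < minor_thresh:
                groups.exp1_only[p] = _direction(called1[p])
            else:
                groups.unclassified.add(p)
        else:
            if abs(delta1[p]) < minor_thresh:
                groups.exp2_only[p] = _direction(called2[p])
            else:
                groups.unclassified.add(p)
    logger.info("classify_signature_groups: %s", groups.counts())
    return groups


# ---------------------------------------------------------------------------
# Four-category DS-discordance partition
# ---------------------------------------------------------------------------

FOUR_CATEGORIES = (
    "batch_effect",
    "unique_change",
    "common_same_direction",
    "common_opposite_direction",
)


def classify_ds_differences(
    ds_diff_probes, delta1, delta2, change_thresh: float = 0.1
) -> dict[str, str]:
    """Partition probes that differ between the two experiments' DS states.

    With t = ``change_thresh`` and d1/d2 the EP→DS beta differences within
    each experiment: ``batch_effect`` iff |d1| < t and |d2| < t;
    ``unique_change`` iff exactly one of |d1|, |d2| ≥ t;
    ``common_same_direction`` / ``common_opposite_direction`` iff both ≥ t
    with equal / opposite sign.  The ≥ on the "change" side makes the four
    categories exhaustive.
    """
    ds_diff_probes = list(ds_diff_probes)
    missing = [p for p in ds_diff_probes if p not in delta1 or p not in delta2]
    if missing:
        raise ValueError(
            f"{len(missing)} probes absent from a delta map, e.g. {missing[:5]}"
        )
    out = {}
    t = change_thresh
    for p in ds_diff_probes:
        d1, d2 = delta1[p], delta2[p]
        big1, big2 = abs(d1) >= t, abs(d2) >= t
        if not big1 and not big2:
            out[p] = "batch_effect"
        elif big1 != big2:
            out[p] = "unique_change"
        elif np.sign(d1) == np.sign(d2):
            out[p] = "common_same_direction"
        else:
            out[p] = "common_opposite_direction"
    return out


# ---------------------------------------------------------------------------
# Overlap enrichment with a resampled background
# ---------------------------------------------------------------------------


@dataclass
class OverlapEnrichment:
    """Observed overlap of two probe/gene sets against a resampled background."""

    observed: int
    n_a: int
    n_b: int
    n_universe: int
    mean_resampled: float
    fold_empirical: float  # NaN when undefined, inf when background overlap is 0
    fold_analytic: float
    empirical_p: float
    n_resamples: int
    message: str = ""


def overlap_enrichment(
    set_a, set_b, universe, n_resamples: int = 1000, seed=None, rng=None
) -> OverlapEnrichment:
    """Fold enrichment of |A∩B| against random same-size draws from the universe.

    ``fold_empirical`` divides the observed overlap by the mean overlap of
    ``n_resamples`` uniform without-replacement draws of |A| elements;
    ``fold_analytic`` divides by the hypergeometric expectation |A||B|/|U|.
    ``empirical_p`` uses the add-one estimator (1 + #{resample ≥ observed}) /
    (1 + n_resamples) and therefore never reaches zero.
    """
    universe = pd.Index(sorted(set(universe)))
    a = set(set_a)
    b = set(set_b)
    if not a <= set(universe) or not b <= set(universe):
        raise ValueError("set_a and set_b must be subsets of the universe")
    if rng is None:
        rng = np.random.default_rng(seed)
    if len(a) == 0 or len(b) == 0:
        return OverlapEnrichment(
            0, len(a), len(b), len(universe), np.nan, np.nan, np.nan,
            np.nan, n_resamples, message="fold undefined for an empty set",
        )
    observed = len(a & b)
    b_mask = universe.isin(b).astype(bool)
    uni_n = len(universe)
    overlaps = np.empty(n_resamples, dtype=np.int64)
    for i in range(n_resamples):
        idx = rng.choice(uni_n, size=len(a), replace=False)
        overlaps[i] = int(b_mask[idx].sum())
    mean_res = float(overlaps.mean())
    fold_analytic = observed / (len(a) * len(b) / uni_n)
    if mean_res == 0.0:
        fold_empirical = np.inf
        msg = "mean resampled overlap is 0; empirical fold infinite"
    else:
        fold_empirical = observed / mean_res
        msg = ""
    empirical_p = (1 + int((overlaps >= observed).sum())) / (1 + n_resamples)
    return OverlapEnrichment(
        observed, len(a), len(b), uni_n, mean_res,
        float(fold_empirical), float(fold_analytic), float(empirical_p),
        n_resamples, message=msg,
    )


# ---------------------------------------------------------------------------
# Co-methylation of index DMPs with their nearest neighbors
# ---------------------------------------------------------------------------


@dataclass
class CoMethylationProfile:
    """Nearest-neighbor co-methylation of index DMPs.

    ``pairs`` has one row per retained index probe (columns index_probe,
    neighbor_probe, distance, index_delta, neighbor_delta); ``rho`` is the
    Spearman correlation of the two delta columns with its p-value ``p``;
    ``background`` collects the same statistic over random probe sets of
    equal size; ``excluded`` lists index probes without a same-chromosome
    neighbor or with none within the distance cap.
    """

    pairs: pd.DataFrame
    rho: float
    p: float
    background: np.ndarray
    excluded: list


def nearest_neighbors(annotation: ProbeAnnotation, probes=None) -> pd.DataFrame:
    """Nearest other probe on the same chromosome for every (or given) probe.

    Distance is |pos_i − pos_j|; equidistant flanks resolve to the upstream
    (lower-position) probe.  Probes alone on their chromosome are omitted.
    """
    t = annotation.table
    rows = []
    for _, sub in t.groupby("chrom", sort=False):
        if len(sub) < 2:
            continue
        sub = sub.sort_index().sort_values("pos", kind="mergesort")
        pos = sub["pos"].to_numpy()
        ids = sub.index.to_numpy()
        left = np.r_[np.inf, np.diff(pos)]
        right = np.r_[np.diff(pos), np.inf]
        take_left = left <= right  # tie -> upstream
        nb = np.where(take_left, np.r_[ids[:1], ids[:-1]], np.r_[ids[1:], ids[-1:]])
        dist = np.where(take_left, left, right)
        rows.append(pd.DataFrame({"neighbor": nb, "distance": dist}, index=ids))
    if not rows:
        return pd.DataFrame(columns=["neighbor", "distance"])
    out = pd.concat(rows)
    if probes is not None:
        out = out.reindex([p for p in probes if p in out.index])
    out["distance"] = out["distance"].astype(float)
    return out


def comethylation_profile(
    index_dmps,
    annotation: ProbeAnnotation,
    delta_map,
    max_dist: float = 500,
    n_resamples: int = 1000,
    seed=None,
) -> CoMethylationProfile:
    """Correlate index-DMP beta differences with those of their nearest probes.

    For each index DMP the nearest other probe on the same chromosome is
    found; pairs farther apart than ``max_dist`` bp are excluded.  Neighbor
    probes that are themselves index DMPs are retained — removing them would
    bias the correlation downward.  The background repeats the procedure on
    ``n_resamples`` uniformly drawn probe sets of the same size.
    """
    index_probes = [r.probe_id if isinstance(r, DMPRecord) else r for r in index_dmps]
    delta_map = pd.Series(delta_map, dtype=float)
    missing = annotation.covers(delta_map.index)
    if missing:
        raise ValueError(
            f"annotation does not cover the delta universe: {missing[:5]}"
        )
    universe = [p for p in annotation.probe_ids if p in delta_map.index]
    nn = nearest_neighbors(
        ProbeAnnotation(annotation.table.loc[universe].copy())
    )

    def pairs_for(probes):
        got = nn.reindex([p for p in probes if p in nn.index])
        got = got.dropna()
        got = got[got["distance"] <= max_dist]
        return got

    got = pairs_for(index_probes)
    excluded = [p for p in index_probes if p not in got.index]
    if excluded:
        logger.info(
            "comethylation: excluded %d index probes without a neighbor "
            "within %g bp", len(excluded), max_dist,
        )
    pairs = pd.DataFrame(
        {
            "index_probe": got.index,
            "neighbor_probe": got["neighbor"].to_numpy(),
            "distance": got["distance"].to_numpy(),
            "index_delta": delta_map.reindex(got.index).to_numpy(),
            "neighbor_delta": delta_map.reindex(got["neighbor"]).to_numpy(),
        }
    ).reset_index(drop=True)
    if len(pairs) >= 2:
        rho, p = stats.spearmanr(pairs["index_delta"], pairs["neighbor_delta"])
    else:
        rho, p = np.nan, np.nan

    rng = np.random.default_rng(seed)
    uni_arr = np.asarray(universe)
    background = np.full(n_resamples, np.nan)
    for i in range(n_resamples):
        draw = rng.choice(uni_arr, size=len(index_probes), replace=False)
        g = pairs_for(draw)
        if len(g) >= 2:
            background[i] = stats.spearmanr(
                delta_map.reindex(g.index), delta_map.reindex(g["neighbor"])
            )[0]
    return CoMethylationProfile(pairs, float(rho), float(p), background, excluded)
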