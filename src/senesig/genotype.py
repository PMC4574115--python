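"""Genotype–senDMP directional association.

For each GWAS-catalogue SNP, risk-allele dosage (0/1/2) is correlated
(Pearson) with methylation at every senDMP across the cohort individuals.
senDMPs with |r| above a noise threshold (default 0.15) are binned by their
senescence direction (hyper/hypo) and correlation sign; a risk allele whose
carriers look DS-like (hyper-senDMPs up, hypo-senDMPs down) contributes
concordant counts, an EP-like pattern discordant counts.  The summary
statistic is a 1-df goodness-of-fit chi-squared of the concordant/discordant
split against 50:50, signed positive when the risk allele is DS-like — its
magnitude is (concordant − discordant)²/n and is bounded by the number of
informative senDMPs.  Significance is calibrated with an empirical
permutation null that redraws random probe sets of the same hyper/hypo
sizes from the probe universe (or, alternatively, shuffles the hyper/hypo
labels on the fixed senDMP set).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import BetaMatrix, GenotypeMatrix
from .signature import SenescenceSignature

logger = logging.getLogger("senesig")

DEFAULT_R_THRESH = 0.15


@dataclass
class SNPAssociationResult:
    """Directional chi-squared summary for one SNP.

    Counts: a = hyper & r > +thr, b = hyper & r < −thr, c = hypo & r > +thr,
    d = hypo & r < −thr.  Concordant (DS-like) = a + d, discordant = b + c.
    """

    snp_id: str
    a: int
    b: int
    c: int
    d: int
    statistic: float
    sign: int
    max_abs_r: float
    perm_p: float | None = None
    flag: str = ""

    @property
    def n_pass(self) -> int:
        return self.a + self.b + self.c + self.d


def genotype_dmp_correlations(
    genotypes: GenotypeMatrix,
    beta_cohort: BetaMatrix,
    probes,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """SNP × probe grid of Pearson r over pairwise-complete individuals.

    Individuals are matched by id between the two matrices (≥3 shared
    required).  Cells with a constant dosage or beta vector, or fewer than
    ``min_pairs`` complete pairs, are NaN.
    """
    probes = [p for p in probes if p in beta_cohort.values.index]
    shared = [s for s in genotypes.individual_ids if s in beta_cohort.values.columns]
    if len(shared) < 3:
        raise ValueError(f"need >=3 shared individuals, got {len(shared)}")
    G = genotypes.dosages[shared].to_numpy(dtype=float)  # S × n
    B = beta_cohort.values.loc[probes, shared].to_numpy(dtype=float)  # P × n
    n = len(shared)

    if not np.isnan(G).any() and not np.isnan(B).any():
        R = _corr_complete(G, B)
    else:
        R = np.full((G.shape[0], B.shape[0]), np.nan)
        n_sparse = 0
        for si in range(G.shape[0]):
            g = G[si]
            for pi in range(B.shape[0]):
                b = B[pi]
                keep = ~(np.isnan(g) | np.isnan(b))
                if keep.sum() < min_pairs:
                    n_sparse += 1
                    continue
                gs, bs = g[keep], b[keep]
                if np.ptp(gs) == 0 or np.ptp(bs) == 0:
                    continue
                R[si, pi] = np.corrcoef(gs, bs)[0, 1]
        if n_sparse:
            logger.info(
                "genotype_dmp_correlations: %d cells with <%d complete pairs",
                n_sparse, min_pairs,
            )
    return pd.DataFrame(R, index=genotypes.snp_ids, columns=probes)


def _corr_complete(G: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson r between every row of G and every row of B (no missing)."""
    def standardize(X):
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            Z = (X - mu) / sd
        Z[np.repeat(sd == 0, X.shape[1], axis=1)] = np.nan
        return Z

    Zg = standardize(G)
    Zb = standardize(B)
    return Zg @ Zb.T / G.shape[1]


def directional_chisq(
    r_row,
    directions,
    r_thresh: float = DEFAULT_R_THRESH,
    snp_id: str = "",
    variant: str = "gof",
) -> SNPAssociationResult:
    """Signed chi-squared of one SNP's correlations against senDMP directions.

    Only senDMPs with |r| > ``r_thresh`` (strict) are informative.  With the
    default ``variant="gof"`` the magnitude is the 1-df goodness-of-fit of
    the concordant/discordant split against 50:50, i.e.
    (concordant − discordant)²/n_pass; ``variant="independence"`` instead
    uses the uncorrected chi-squared of the 2×2 direction × sign table.
    The sign is +1 when concordant > discordant (risk allele DS-like), −1
    when discordant dominates, 0 on a tie.
    """
    r = pd.Series(r_row, dtype=float)
    directions = pd.Series(directions)
    missing = [p for p in r.index if p not in directions.index]
    if missing:
        raise ValueError(f"directions do not cover probes, e.g. {missing[:5]}")
    d = directions.loc[r.index]
    hyper = (d == "hyper").to_numpy()
    hypo = (d == "hypo").to_numpy()
    rv = r.to_numpy()
    pos = rv > r_thresh
    neg = rv < -r_thresh
    a = int((hyper & pos).sum())
    b = int((hyper & neg).sum())
    c = int((hypo & pos).sum())
    dd = int((hypo & neg).sum())
    n = a + b + c + dd
    finite = np.abs(rv[~np.isnan(rv)])
    max_abs_r = float(finite.max()) if finite.size else float("nan")

    if n == 0:
        return SNPAssociationResult(
            snp_id, 0, 0, 0, 0, 0.0, 0, max_abs_r,
            flag="no informative senDMPs",
        )
    conc = a + dd
    disc = b + c
    sign = 0 if conc == disc else (1 if conc > disc else -1)
    if variant == "gof":
        magnitude = (conc - disc) ** 2 / n
    elif variant == "independence":
        table = np.array([[a, b], [c, dd]], dtype=float)
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            magnitude = 0.0
        else:
            magnitude = float(
                stats.chi2_contingency(table, correction=False)[0]
            )
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return SNPAssociationResult(
        snp_id, a, b, c, dd, float(sign * magnitude), sign, max_abs_r
    )


def _stat_magnitudes(
    R: np.ndarray, hyper_mask: np.ndarray, hypo_mask: np.ndarray, r_thresh: float
) -> np.ndarray:
    """|statistic| for every SNP (row of R) given direction masks over columns."""
    pos = R > r_thresh
    neg = R < -r_thresh
    conc = (pos & hyper_mask).sum(axis=1) + (neg & hypo_mask).sum(axis=1)
    disc = (neg & hyper_mask).sum(axis=1) + (pos & hypo_mask).sum(axis=1)
    n = conc + disc
    with np.errstate(divide="ignore", invalid="ignore"):
        mag = np.where(n > 0, (conc - disc) ** 2 / np.maximum(n, 1), 0.0)
    return mag.astype(float)


def snp_permutation_test(
    genotypes: GenotypeMatrix,
    beta_cohort: BetaMatrix,
    signature: SenescenceSignature,
    universe,
    n_perm: int = 1000,
    seed=None,
    mode: str = "resample_probes",
    r_thresh: float = DEFAULT_R_THRESH,
    min_minor_count: int = 3,
) -> pd.DataFrame:
    """Permutation calibration of the directional chi-squared for every SNP.

    ``mode="resample_probes"`` draws random probe sets of the same
    hyper/hypo sizes from ``universe`` and recomputes correlations and
    statistics; ``mode="shuffle_directions"`` permutes the hyper/hypo labels
    on the fixed senDMP set.  perm_p = (1 + #{|permuted| ≥ |observed|}) /
    (1 + n_perm).  SNPs with fewer than ``min_minor_count`` minor-allele
    carriers among the shared individuals are skipped (perm_p NaN, flagged).

    Returns a DataFrame indexed by snp_id with the contingency counts,
    statistic, sign, max_abs_r and perm_p.
    """
    universe = sorted(set(universe))
    sig_probes = list(signature.hyper_probes) + list(signature.hypo_probes)
    if not set(sig_probes) <= set(universe):
        raise ValueError("universe must contain every signature probe")
    universe = [p for p in universe if p in beta_cohort.values.index]
    if not set(sig_probes) <= set(universe):
        raise ValueError("cohort matrix does not cover the signature probes")

    rng = np.random.default_rng(seed)
    R_all = genotype_dmp_correlations(genotypes, beta_cohort, universe)
    uni_index = {p: i for i, p in enumerate(R_all.columns)}
    Rv = np.nan_to_num(R_all.to_numpy(), nan=0.0)  # NaN r never passes |r|>thr

    dosages = genotypes.dosages[
        [s for s in genotypes.individual_ids if s in beta_cohort.values.columns]
    ]
    dos = dosages.to_numpy(dtype=float)
    minor = np.minimum(np.nansum(dos, axis=1), np.nansum(2 - dos, axis=1))
    skipped = minor < min_minor_count
    if skipped.any():
        logger.info(
            "snp_permutation_test: skipping %d SNPs with minor-allele count "
            "< %d", int(skipped.sum()), min_minor_count,
        )

    directions = signature.directions()
    obs = []
    for snp_id in R_all.index:
        res = directional_chisq(
            R_all.loc[snp_id, sig_probes], directions,
            r_thresh=r_thresh, snp_id=snp_id,
        )
        obs.append(res)
    obs_mag = np.array([abs(r.statistic) for r in obs])

    n_hyper, n_hypo = signature.n_hyper, signature.n_hypo
    n_sig = n_hyper + n_hypo
    exceed = np.zeros(len(obs), dtype=np.int64)
    if mode == "resample_probes":
        uni_arr = np.arange(len(universe))
        hyper_mask = np.zeros(n_sig, dtype=bool)
        hyper_mask[:n_hyper] = True
        hypo_mask = ~hyper_mask
        for _ in range(n_perm):
            idx = rng.choice(uni_arr, size=n_sig, replace=False)
            mags = _stat_magnitudes(Rv[:, idx], hyper_mask, hypo_mask, r_thresh)
            exceed += mags >= obs_mag
    elif mode == "shuffle_directions":
        cols = np.array([uni_index[p] for p in sig_probes])
        R_sig = Rv[:, cols]
        base_hyper = np.zeros(n_sig, dtype=bool)
        base_hyper[:n_hyper] = True
        for _ in range(n_perm):
            perm = rng.permutation(n_sig)
            hyper_mask = base_hyper[perm]
            mags = _stat_magnitudes(R_sig, hyper_mask, ~hyper_mask, r_thresh)
            exceed += mags >= obs_mag
    else:
        raise ValueError(f"unknown mode {mode!r}")

    perm_p = (1 + exceed) / (1 + n_perm)
    out = pd.DataFrame(
        {
            "a": [r.a for r in obs],
            "b": [r.b for r in obs],
            "c": [r.c for r in obs],
            "d": [r.d for r in obs],
            "n_pass": [r.n_pass for r in obs],
            "statistic": [r.statistic for r in obs],
            "sign": [r.sign for r in obs],
            "max_abs_r": [r.max_abs_r for r in obs],
            "perm_p": perm_p,
            "flag": [r.flag for r in obs],
        },
        index=R_all.index,
    )
    out.loc[skipped, "perm_p"] = np.nan
    out.loc[skipped, "flag"] = "minor-allele count below threshold"
    return out


def rank_snp_results(results, snp_meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Rank SNP association results by |statistic| descending, ties by snp_id.

    ``results`` may be a list of :class:`SNPAssociationResult` or the frame
    returned by :func:`snp_permutation_test`; ``snp_meta`` (indexed by
    snp_id, e.g. ``GenotypeMatrix.snps``) contributes chrom/pos/risk
    allele/trait columns when given.
    """
    if isinstance(results, pd.DataFrame):
        table = results.copy()
    else:
        table = pd.DataFrame(
            {
                "statistic": [r.statistic for r in results],
                "n_pass": [r.n_pass for r in results],
                "max_abs_r": [r.max_abs_r for r in results],
                "perm_p": [r.perm_p for r in results],
            },
            index=pd.Index([r.snp_id for r in results], name="snp_id"),
        )
    if table.empty:
        return table
    if snp_meta is not None:
        meta_cols = [c for c in ("chrom", "pos", "gene", "risk_allele", "trait")
                     if c in snp_meta.columns]
        table = snp_meta.loc[table.index, meta_cols].join(table)
    order = sorted(
        table.index, key=lambda sid: (-abs(table.at[sid, "statistic"]), sid)
    )
    return table.loc[order]
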