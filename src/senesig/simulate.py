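"""Synthetic methylation-array data with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* a bimodal baseline methylome (most CpGs near 0 or near 1, a minority
  intermediate), observed through Beta-distributed replicate noise with
  concentration ``nu`` around the per-group mean — draws stay in [0, 1] and
  the variance shrinks toward the boundaries, mimicking array beta values;
* two replicated culture experiments (EP vs DS, three replicates each) with
  planted hyper-/hypo-senDMPs of effect |Δβ| drawn from ``delta_range``,
  split between experiment-exclusive, shared-same-direction and
  shared-opposite-direction sites;
* a cohort of individuals whose latent senescence burden b ∈ [0, 1] scales
  the planted deltas multiplicatively (β = base + dir·δ·b), so a fully
  senescent sample reproduces the in-vitro DS shift; tumors carry an extra
  burden shift, and age increases linearly with burden plus noise;
* Hardy–Weinberg genotypes at uniform random MAF, with causal SNPs adding
  η·dosage·direction to the signature-probe means;
* expression with planted DE genes, a configurable fraction of which are
  genes annotated to signature probes;
* a post-knockdown reversal timecourse where each site returns a fraction
  r ∈ [0, 1] of the way from its DS mean back to its EP mean.

One global seed drives independent named substreams per output block, so
generating an extra block never perturbs earlier draws.  The returned
:class:`SimTruth` records everything planted and serves as the oracle for
the test suite.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    BetaMatrix,
    ExpressionMatrix,
    GenotypeMatrix,
    ProbeAnnotation,
    SampleTable,
)

logger = logging.getLogger("senesig")

AUTOSOMES = [f"chr{i}" for i in range(1, 23)]
TRAITS = [
    "Type 2 diabetes", "Breast cancer", "Ischaemic stroke",
    "Lentiform nucleus volume", "Fasting glucose-related traits",
    "Obesity-related traits", "IgG glycosylation", "Height",
]

# substream indices off the master seed; append-only so adding a block
# never reshuffles earlier draws
_STREAMS = {
    "layout": 0,
    "experiment_noise": 1,
    "cohort_layout": 2,
    "cohort_burden": 3,
    "genotypes": 4,
    "cohort_noise": 5,
    "expression": 6,
    "reversal_r": 7,
    "reversal_noise": 8,
}


class ParameterError(ValueError):
    """Simulation parameters are inconsistent or infeasible."""


@dataclass
class SimParams:
    """Generator parameters (defaults are the study conditions being emulated)."""

    # two-experiment design: 2 experiments x {EP, DS} x replicates
    n_probes: int = 20_000
    n_replicates: int = 3
    fraction_hyper: float = 0.025   # 500 hyper-senDMPs per experiment at 20k probes
    fraction_hypo: float = 0.025
    share_agree: float = 0.4        # of each experiment's planted sites
    share_disagree: float = 0.1
    delta_range: tuple = (0.3, 0.5)
    nu: float = 50.0                # Beta concentration of replicate noise
    # probe layout
    neighbor_fraction: float = 0.15
    neighbor_max_dist: int = 500
    neighbor_noise_sd: float = 0.1
    frac_sex_probes: float = 0.01
    frac_multimapping: float = 0.005
    frac_low_detection: float = 0.005
    # cohort
    n_individuals: int = 73
    include_tumors: bool = True
    burden_range: tuple = (0.0, 1.0)
    tumor_burden_shift: float = 0.3
    n_cohort_hyper: int = 500
    n_cohort_hypo: int = 500
    # genotypes
    n_snps: int = 200
    n_causal_snps: int = 1
    snp_eta: float = 0.15           # per-risk-allele beta shift
    causal_affected_fraction: float = 0.2   # of the signature probes
    maf_range: tuple = (0.05, 0.5)
    # age model: age = intercept + slope * burden + N(0, noise)
    age_intercept: float = 30.0
    age_slope: float = 40.0
    age_noise_sd: float = 8.0
    # expression
    n_genes: int = 2000
    n_de_genes: int = 150
    de_overlap_fraction: float = 0.3
    de_effect: float = 2.0
    expr_noise_sd: float = 0.5
    # reversal: Beta(a, b) of per-site completeness r, per timepoint
    reversal_r_d2: tuple = (6.0, 2.0)
    reversal_r_d5: tuple = (3.0, 2.0)
    exp2_drift_d2: tuple = (1.0, 3.0)   # Beta(a, b) of drift toward exp2 delta
    exp2_drift_d5: tuple = (1.5, 2.5)
    seed: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.fraction_hyper <= 1 and 0 <= self.fraction_hypo <= 1):
            raise ParameterError("planted fractions must lie in [0, 1]")
        if self.fraction_hyper + self.fraction_hypo >= 1:
            raise ParameterError("planted fractions must sum to < 1")
        if self.nu is not None and not self.nu > 0:
            raise ParameterError("nu must be positive (or None for noise-free)")
        lo, hi = self.delta_range
        if not (0 < lo <= hi < 1):
            raise ParameterError("delta_range must be an interval within (0, 1)")
        if hi > 0.9:
            raise ParameterError(
                "delta_range upper bound > 0.9 leaves no feasible baselines"
            )
        mlo, mhi = self.maf_range
        if not (0 < mlo <= mhi <= 0.5):
            raise ParameterError("maf_range must lie within (0, 0.5]")
        if self.share_agree + self.share_disagree > 1:
            raise ParameterError("share_agree + share_disagree must be <= 1")

    def rng(self, stream: str) -> np.random.Generator:
        ss = np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        return np.random.default_rng(ss)


@dataclass
class SimTruth:
    """Ground truth of a simulation; the oracle for every downstream test.

    ``probes``: per-probe baseline mean, signed delta per experiment (or the
    cohort delta), and role (null / planted / neighbor).  ``samples``:
    per-individual latent burden, age, tumor flag.  ``snps``: causal flag,
    effect eta, MAF.  ``genes``: DE flag and senDMP-gene flag.
    ``reversal``: per-site completeness r per timepoint (and exp2 drift).
    ``meta`` carries auxiliary objects (signature lists, annotation).
    """

    probes: pd.DataFrame | None = None
    samples: pd.DataFrame | None = None
    snps: pd.DataFrame | None = None
    genes: pd.DataFrame | None = None
    reversal: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    # -- oracle accessors ---------------------------------------------------

    def planted(self, experiment: str = "exp1") -> dict:
        """Probe → direction for sites planted in the given experiment."""
        col = {"exp1": "delta_exp1", "exp2": "delta_exp2", "cohort": "delta"}[
            experiment
        ]
        d = self.probes[col]
        out = {}
        for p, v in d.items():
            if v > 0:
                out[p] = "hyper"
            elif v < 0:
                out[p] = "hypo"
        return out

    def signature_probes(self) -> tuple[list, list]:
        """(hyper, hypo) probe lists of the cohort signature."""
        sig = self.meta.get("signature")
        if sig is None:
            raise ValueError("truth has no cohort signature")
        return list(sig["hyper"]), list(sig["hypo"])

    def to_json(self, path) -> None:
        payload = {}
        for name in ("probes", "samples", "snps", "genes", "reversal"):
            df = getattr(self, name)
            if df is not None:
                payload[name] = json.loads(df.to_json(orient="index"))
        payload["meta"] = {
            k: v for k, v in self.meta.items() if _json_safe(v)
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def _draw_beta_noise(
    means: np.ndarray, nu, rng: np.random.Generator
) -> np.ndarray:
    """Observed betas around per-cell means with concentration nu."""
    if nu is None or np.isinf(nu):
        return means.copy()
    m = np.clip(means, 1e-9, 1 - 1e-9)
    return np.clip(rng.beta(m * nu, (1 - m) * nu), 0.0, 1.0)


def _bimodal_baseline(n: int, rng: np.random.Generator) -> np.ndarray:
    comp = rng.random(n)
    out = np.empty(n)
    low = comp < 0.45
    high = (comp >= 0.45) & (comp < 0.9)
    mid = comp >= 0.9
    out[low] = rng.beta(1, 10, low.sum())
    out[high] = rng.beta(10, 1, high.sum())
    out[mid] = rng.beta(2, 2, mid.sum())
    return np.clip(out, 0.01, 0.99)


def _probe_ids(n: int) -> list[str]:
    return [f"cg{i:08d}" for i in range(n)]


def simulate_two_experiment_senescence(
    params: SimParams,
) -> tuple[BetaMatrix, SampleTable, ProbeAnnotation, SimTruth]:
    """Two replicated EP-vs-DS experiments with planted senDMPs.

    Returns the observed beta matrix (2 experiments × {EP, DS} ×
    ``n_replicates`` samples), sample metadata, probe annotation and the
    truth record.  EP means equal the baseline in both experiments (the EP
    state is the reproducible one); DS means are baseline + the planted
    signed delta of that experiment, clipped into [0.01, 0.99].
    """
    rng = params.rng("layout")
    n = params.n_probes
    ids = np.array(_probe_ids(n))

    n_h = int(round(n * params.fraction_hyper))
    n_o = int(round(n * params.fraction_hypo))
    agree_h = int(round(params.share_agree * n_h))
    agree_o = int(round(params.share_agree * n_o))
    dis_h = int(round(params.share_disagree * n_h / 2))  # hyper in exp1, hypo in exp2
    dis_o = int(round(params.share_disagree * n_o / 2))  # hypo in exp1, hyper in exp2
    e1h = n_h - agree_h - dis_h
    e2h = n_h - agree_h - dis_o
    e1o = n_o - agree_o - dis_o
    e2o = n_o - agree_o - dis_h
    if min(e1h, e2h, e1o, e2o) < 0:
        raise ParameterError("share_agree/share_disagree exceed planted quota")
    blocks = {
        "agree_h": agree_h, "agree_o": agree_o,
        "dis_h": dis_h, "dis_o": dis_o,
        "e1h": e1h, "e1o": e1o, "e2h": e2h, "e2o": e2o,
    }
    total_planted = sum(blocks.values())
    if total_planted > n:
        raise ParameterError("planted sites exceed probe count")

    perm = rng.permutation(n)
    cursor = 0
    block_idx = {}
    for name, size in blocks.items():
        block_idx[name] = perm[cursor:cursor + size]
        cursor += size
    planted_idx = perm[:cursor]
    null_idx = perm[cursor:]

    baseline = _bimodal_baseline(n, rng)
    dmin, dmax = params.delta_range
    dis_max = min(dmax, 0.42)
    if (dis_h or dis_o) and dmin > dis_max:
        raise ParameterError(
            "delta_range lower bound too large for opposite-direction sites"
        )

    d1 = np.zeros(n)
    d2 = np.zeros(n)
    for name, idx in block_idx.items():
        if len(idx) == 0:
            continue
        if name in ("agree_h", "e1h", "e2h"):
            baseline[idx] = rng.uniform(0.05, 0.45, len(idx))
        elif name in ("agree_o", "e1o", "e2o"):
            baseline[idx] = rng.uniform(0.55, 0.95, len(idx))
        else:  # disagree blocks sit mid-range so both directions fit
            baseline[idx] = rng.uniform(0.45, 0.55, len(idx))
        if name == "agree_h":
            d1[idx] = rng.uniform(dmin, dmax, len(idx))
            d2[idx] = rng.uniform(dmin, dmax, len(idx))
        elif name == "agree_o":
            d1[idx] = -rng.uniform(dmin, dmax, len(idx))
            d2[idx] = -rng.uniform(dmin, dmax, len(idx))
        elif name == "dis_h":
            d1[idx] = rng.uniform(dmin, dis_max, len(idx))
            d2[idx] = -rng.uniform(dmin, dis_max, len(idx))
        elif name == "dis_o":
            d1[idx] = -rng.uniform(dmin, dis_max, len(idx))
            d2[idx] = rng.uniform(dmin, dis_max, len(idx))
        elif name == "e1h":
            d1[idx] = rng.uniform(dmin, dmax, len(idx))
        elif name == "e1o":
            d1[idx] = -rng.uniform(dmin, dmax, len(idx))
        elif name == "e2h":
            d2[idx] = rng.uniform(dmin, dmax, len(idx))
        elif name == "e2o":
            d2[idx] = -rng.uniform(dmin, dmax, len(idx))

    role = np.array(["null"] * n, dtype=object)
    role[planted_idx] = "planted"

    # co-methylation partners: a fraction of planted sites donate a
    # correlated delta to a neighboring null probe (placed <= max_dist away)
    n_partner = int(round(params.neighbor_fraction * total_planted))
    n_partner = min(n_partner, len(null_idx))
    partner_of = {}
    if n_partner > 0:
        donors = rng.choice(planted_idx, size=n_partner, replace=False)
        partners = null_idx[:n_partner]
        for donor, partner in zip(donors, partners):
            baseline[partner] = baseline[donor]
            for dvec in (d1, d2):
                if dvec[donor] != 0.0:
                    dvec[partner] = dvec[donor] + rng.normal(
                        0, params.neighbor_noise_sd
                    )
            role[partner] = "neighbor"
            partner_of[partner] = donor

    # flagged / sex-chromosome probes drawn from the remaining null pool
    free = null_idx[n_partner:]
    n_sex = int(round(params.frac_sex_probes * n))
    n_multi = int(round(params.frac_multimapping * n))
    n_lowdet = int(round(params.frac_low_detection * n))
    if n_sex + n_multi + n_lowdet > len(free):
        raise ParameterError("too few null probes left for flagged probes")
    sex_idx = set(free[:n_sex].tolist())
    multi_idx = set(free[n_sex:n_sex + n_multi].tolist())
    lowdet_idx = set(free[n_sex + n_multi:n_sex + n_multi + n_lowdet].tolist())

    # genomic layout: non-partner probes spaced well beyond max_dist,
    # partners placed within max_dist of their donor
    chrom = np.empty(n, dtype=object)
    pos = np.zeros(n, dtype=int)
    non_partner = np.array([i for i in range(n) if i not in partner_of])
    chrom_assign = rng.integers(0, len(AUTOSOMES), len(non_partner))
    for ci, cname in enumerate(AUTOSOMES):
        members = non_partner[chrom_assign == ci]
        gaps = rng.integers(2 * params.neighbor_max_dist + 100, 20_000, len(members))
        chrom[members] = cname
        pos[members] = 10_000 + np.cumsum(gaps)
    for partner, donor in partner_of.items():
        chrom[partner] = chrom[donor]
        pos[partner] = pos[donor] + int(rng.integers(10, params.neighbor_max_dist))
    for i in sex_idx:
        chrom[i] = "chrX"

    gene_pool = np.array([f"G{i:05d}" for i in range(params.n_genes)])
    fc_draw = rng.random(n)
    feature_class = np.where(
        fc_draw < 0.25, "promoter", np.where(fc_draw < 0.6, "gene_body", "intergenic")
    )
    gene = np.where(
        feature_class == "intergenic", "", gene_pool[rng.integers(0, len(gene_pool), n)]
    )

    flags = []
    for i in range(n):
        fs = set()
        if i in sex_idx:
            fs.add("sex_chromosome")
        if i in multi_idx:
            fs.add("multimapping")
        if i in lowdet_idx:
            fs.add("low_detection")
        flags.append(frozenset(fs))
    annotation = ProbeAnnotation(
        pd.DataFrame(
            {
                "chrom": chrom, "pos": pos, "gene": gene,
                "feature_class": feature_class, "flags": flags,
            },
            index=pd.Index(ids, name="probe_id"),
        )
    )

    # realized deltas after clipping the DS mean into [0.01, 0.99]
    ds1 = np.clip(baseline + d1, 0.01, 0.99)
    ds2 = np.clip(baseline + d2, 0.01, 0.99)
    d1 = ds1 - baseline
    d2 = ds2 - baseline

    noise_rng = params.rng("experiment_noise")
    columns, sample_rows, data = [], [], []
    for e, ds_mean in (("exp1", ds1), ("exp2", ds2)):
        for grp, mean in (("EP", baseline), ("DS", ds_mean)):
            for r in range(1, params.n_replicates + 1):
                sid = f"{e}_{grp}_r{r}"
                columns.append(sid)
                sample_rows.append(
                    {
                        "sample_id": sid, "group": grp, "experiment": e,
                        "replicate": r, "age": np.nan, "paired_with": "",
                    }
                )
                data.append(_draw_beta_noise(mean, params.nu, noise_rng))
    beta = BetaMatrix(
        pd.DataFrame(
            np.column_stack(data), index=pd.Index(ids, name="probe_id"),
            columns=columns,
        )
    )
    samples = SampleTable(pd.DataFrame(sample_rows).set_index("sample_id"))

    truth = SimTruth(
        probes=pd.DataFrame(
            {
                "baseline": baseline, "delta_exp1": d1, "delta_exp2": d2,
                "role": role,
            },
            index=pd.Index(ids, name="probe_id"),
        ),
        meta={
            "design": "two_experiment",
            "partner_of": {ids[k]: ids[v] for k, v in partner_of.items()},
            "gene_by_probe": dict(zip(ids, gene)),
        },
    )
    logger.info(
        "simulated two-experiment design: %d probes (%d planted, %d neighbor), "
        "%d samples", n, total_planted, n_partner, len(columns),
    )
    return beta, samples, annotation, truth


def simulate_cohort(
    params: SimParams, truth: SimTruth | None = None
) -> tuple[BetaMatrix, SampleTable, GenotypeMatrix, ExpressionMatrix, SimTruth]:
    """Cohort of individuals with burden-driven senDMP methylation.

    When ``truth`` from :func:`simulate_two_experiment_senescence` is given,
    the cohort reuses its probe universe and takes the shared-same-direction
    planted sites as the signature; otherwise a standalone universe with
    ``n_cohort_hyper`` + ``n_cohort_hypo`` signature probes is planted.

    Each normal individual k draws burden b_k ~ Uniform(burden_range); a
    signature probe's mean is baseline + direction·δ_p·b_k (clipped).
    Tumors add ``tumor_burden_shift`` to their burden.  Causal SNPs add
    η·dosage·direction on top.  Ages follow the linear burden model.
    """
    if params.n_individuals < 3:
        raise ParameterError("n_individuals must be >= 3")
    rng = params.rng("cohort_layout")
    dmin, dmax = params.delta_range

    if truth is not None and truth.probes is not None:
        probes = truth.probes
        ids = np.array(probes.index)
        baseline = probes["baseline"].to_numpy().copy()
        same_sign = (
            (probes["delta_exp1"] * probes["delta_exp2"] > 0)
            & (probes["role"] == "planted")
        )
        hyper = list(probes.index[same_sign & (probes["delta_exp1"] > 0)])
        hypo = list(probes.index[same_sign & (probes["delta_exp1"] < 0)])
        if not hyper or not hypo:
            raise ParameterError(
                "two-experiment truth has no shared-direction planted sites"
            )
        delta = np.zeros(len(ids))
        loc = {p: i for i, p in enumerate(ids)}
        for p in hyper + hypo:
            delta[loc[p]] = 0.5 * (
                probes.at[p, "delta_exp1"] + probes.at[p, "delta_exp2"]
            )
        gene = truth.meta.get("gene_by_probe")
    else:
        n = params.n_probes
        ids = np.array(_probe_ids(n))
        baseline = _bimodal_baseline(n, rng)
        n_hy, n_ho = params.n_cohort_hyper, params.n_cohort_hypo
        if n_hy + n_ho > n:
            raise ParameterError("signature larger than probe universe")
        perm = rng.permutation(n)
        hyper_idx = perm[:n_hy]
        hypo_idx = perm[n_hy:n_hy + n_ho]
        baseline[hyper_idx] = rng.uniform(0.05, 0.45, n_hy)
        baseline[hypo_idx] = rng.uniform(0.55, 0.95, n_ho)
        delta = np.zeros(n)
        delta[hyper_idx] = rng.uniform(dmin, dmax, n_hy)
        delta[hypo_idx] = -rng.uniform(dmin, dmax, n_ho)
        hyper = [ids[i] for i in hyper_idx]
        hypo = [ids[i] for i in hypo_idx]
        gene = None

    n_probes = len(ids)
    if gene is None:
        gene_pool = np.array([f"G{i:05d}" for i in range(params.n_genes)])
        has_gene = rng.random(n_probes) < 0.6
        gene_arr = np.where(
            has_gene, gene_pool[rng.integers(0, len(gene_pool), n_probes)], ""
        )
        gene = dict(zip(ids, gene_arr))

    # individuals ------------------------------------------------------------
    brng = params.rng("cohort_burden")
    blo, bhi = params.burden_range
    normals = [f"ind{k:03d}" for k in range(1, params.n_individuals + 1)]
    burden_n = brng.uniform(blo, bhi, params.n_individuals)
    individuals = list(normals)
    burden = list(burden_n)
    tumor_flag = [False] * params.n_individuals
    if params.include_tumors:
        tumors = [f"tum{k:03d}" for k in range(1, params.n_individuals + 1)]
        burden_t = brng.uniform(blo, bhi, params.n_individuals) + params.tumor_burden_shift
        individuals += tumors
        burden += list(burden_t)
        tumor_flag += [True] * params.n_individuals
    burden = np.array(burden)
    age = np.maximum(
        params.age_intercept
        + params.age_slope * burden
        + brng.normal(0, params.age_noise_sd, len(burden)),
        0.0,
    )

    # genotypes ---------------------------------------------------------------
    grng = params.rng("genotypes")
    mafs = grng.uniform(*params.maf_range, params.n_snps)
    dosages = grng.binomial(2, mafs[:, None], (params.n_snps, len(individuals)))
    snp_ids = [f"rs{100000 + i}" for i in range(params.n_snps)]
    causal = np.zeros(params.n_snps, dtype=bool)
    if params.n_causal_snps > 0:
        causal_pick = grng.choice(
            params.n_snps, size=min(params.n_causal_snps, params.n_snps),
            replace=False,
        )
        causal[causal_pick] = True
    eta = np.where(causal, params.snp_eta, 0.0)
    snps = pd.DataFrame(
        {
            "chrom": grng.choice(AUTOSOMES, params.n_snps),
            "pos": grng.integers(10_000, 100_000_000, params.n_snps),
            "risk_allele": grng.choice(list("ACGT"), params.n_snps),
            "trait": grng.choice(TRAITS, params.n_snps),
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )
    genotypes = GenotypeMatrix(
        snps,
        pd.DataFrame(
            dosages.astype(float), index=pd.Index(snp_ids, name="snp_id"),
            columns=individuals,
        ),
    )

    # signature probes affected by each causal SNP
    sig_all = list(hyper) + list(hypo)
    n_aff = int(round(params.causal_affected_fraction * len(sig_all)))
    affected = {}
    for si in np.flatnonzero(causal):
        affected[snp_ids[si]] = sorted(
            grng.choice(sig_all, size=n_aff, replace=False)
        )

    # mean methylation and observed betas ------------------------------------
    loc = {p: i for i, p in enumerate(ids)}
    direction = np.zeros(n_probes)
    direction[delta > 0] = 1.0
    direction[delta < 0] = -1.0
    means = np.tile(baseline[:, None], (1, len(individuals)))
    means += np.abs(delta)[:, None] * direction[:, None] * burden[None, :]
    for si in np.flatnonzero(causal):
        rows = np.array([loc[p] for p in affected[snp_ids[si]]])
        means[rows] += (
            eta[si] * direction[rows][:, None] * dosages[si][None, :]
        )
    means = np.clip(means, 0.01, 0.99)
    crng = params.rng("cohort_noise")
    beta = BetaMatrix(
        pd.DataFrame(
            _draw_beta_noise(means, params.nu, crng),
            index=pd.Index(ids, name="probe_id"), columns=individuals,
        )
    )
    samples = SampleTable(
        pd.DataFrame(
            {
                "group": ["tumor" if t else "normal" for t in tumor_flag],
                "experiment": "cohort",
                "replicate": 1,
                "age": age,
                "paired_with": "",
            },
            index=pd.Index(individuals, name="sample_id"),
        )
    )

    # expression --------------------------------------------------------------
    erng = params.rng("expression")
    gene_pool = sorted({g for g in gene.values() if g})
    dmp_genes = sorted({gene[p] for p in sig_all if gene.get(p)})
    n_de = min(params.n_de_genes, len(gene_pool))
    n_from_dmp = min(int(round(params.de_overlap_fraction * n_de)), len(dmp_genes))
    de_genes = set(
        erng.choice(dmp_genes, size=n_from_dmp, replace=False)
    ) if n_from_dmp else set()
    others = [g for g in gene_pool if g not in de_genes]
    de_genes |= set(erng.choice(others, size=n_de - len(de_genes), replace=False))
    base_expr = erng.normal(8.0, 1.0, len(gene_pool))
    expr = np.tile(base_expr[:, None], (1, len(individuals)))
    de_mask = np.array([g in de_genes for g in gene_pool])
    expr[np.ix_(de_mask, np.array(tumor_flag))] += params.de_effect
    expr += erng.normal(0, params.expr_noise_sd, expr.shape)
    expression = ExpressionMatrix(
        pd.DataFrame(
            expr, index=pd.Index(gene_pool, name="gene_id"), columns=individuals
        )
    )

    cohort_truth = SimTruth(
        probes=pd.DataFrame(
            {
                "baseline": baseline, "delta": delta,
                "direction": np.where(
                    delta > 0, "hyper", np.where(delta < 0, "hypo", "null")
                ),
            },
            index=pd.Index(ids, name="probe_id"),
        ),
        samples=pd.DataFrame(
            {"burden": burden, "age": age, "tumor": tumor_flag},
            index=pd.Index(individuals, name="sample_id"),
        ),
        snps=pd.DataFrame(
            {"causal": causal, "eta": eta, "maf": mafs},
            index=pd.Index(snp_ids, name="snp_id"),
        ),
        genes=pd.DataFrame(
            {
                "is_de": [g in de_genes for g in gene_pool],
                "is_dmp_gene": [g in set(dmp_genes) for g in gene_pool],
            },
            index=pd.Index(gene_pool, name="gene_id"),
        ),
        meta={
            "design": "cohort",
            "signature": {"hyper": sorted(hyper), "hypo": sorted(hypo)},
            "gene_by_probe": dict(gene),
            "affected_probes": affected,
        },
    )
    logger.info(
        "simulated cohort: %d probes, %d individuals (%d tumors), %d SNPs "
        "(%d causal), %d genes (%d DE)",
        n_probes, len(individuals), int(np.sum(tumor_flag)), params.n_snps,
        int(causal.sum()), len(gene_pool), len(de_genes),
    )
    return beta, samples, genotypes, expression, cohort_truth


def completeness_for_fractions(
    abs_delta: pd.Series, targets: dict
) -> pd.Series:
    """Per-site reversal completeness r hitting exact fraction-below targets.

    ``targets`` maps threshold → desired fraction of sites whose noise-free
    residual |timepoint − EP| falls strictly below that threshold (e.g.
    ``{0.3: 0.90, 0.1: 0.18}``).  Requires every |Δβ| to be at least the
    largest threshold so that r = 0 leaves the residual above it.
    """
    thresholds = sorted(targets)
    abs_delta = abs_delta.astype(float)
    n = len(abs_delta)
    if (abs_delta < max(thresholds)).any():
        raise ParameterError(
            "all planted |delta| must be >= the largest threshold"
        )
    counts = [int(round(targets[t] * n)) for t in thresholds]
    if counts != sorted(counts):
        raise ParameterError("fractions must be non-decreasing in threshold")
    r = pd.Series(0.0, index=abs_delta.index)
    prev = 0
    lower = 0.0
    for t, c in zip(thresholds, counts):
        block = abs_delta.index[prev:c]
        # residual placed at the midpoint of [lower, t)
        target_resid = 0.5 * (lower + t)
        r.loc[block] = 1.0 - target_resid / abs_delta.loc[block]
        prev = c
        lower = t
    return r.clip(0.0, 1.0)


def simulate_reversal(
    params: SimParams,
    truth: SimTruth,
    r_d2=None,
    r_d5=None,
) -> tuple[BetaMatrix, SampleTable, SimTruth]:
    """Post-knockdown timecourse betas for DS cultures derived from exp1.

    Per probe the day-2/day-5 mean is DS₁ + r·(EP − DS₁) with per-site
    completeness r drawn from the configured Beta distributions (or supplied
    explicitly via ``r_d2``/``r_d5``, mappings or Series over probe ids).
    Sites planted only in experiment 2 additionally drift toward their
    experiment-2 delta by a Beta-distributed fraction.  Updates and returns
    ``truth`` with the reversal record.
    """
    if truth.probes is None or "delta_exp1" not in truth.probes:
        raise ValueError("simulate_reversal needs two-experiment truth")
    probes = truth.probes
    ids = np.array(probes.index)
    baseline = probes["baseline"].to_numpy()
    d1 = probes["delta_exp1"].to_numpy()
    d2x = probes["delta_exp2"].to_numpy()
    ds1 = np.clip(baseline + d1, 0.01, 0.99)

    rrng = params.rng("reversal_r")
    planted1 = d1 != 0.0
    exp2_only = (np.abs(d1) < 0.1) & (np.abs(d2x) >= 0.3)

    def completeness(override, beta_ab):
        r = np.ones(len(ids))
        r[planted1] = rrng.beta(*beta_ab, int(planted1.sum()))
        if override is not None:
            ov = pd.Series(override, dtype=float)
            if ((ov < 0) | (ov > 1)).any():
                raise ParameterError("reversal completeness must lie in [0, 1]")
            pos = {p: i for i, p in enumerate(ids)}
            for p, v in ov.items():
                r[pos[p]] = v
        return r

    def drift(beta_ab):
        dr = np.zeros(len(ids))
        dr[exp2_only] = rrng.beta(*beta_ab, int(exp2_only.sum()))
        return dr

    r2 = completeness(r_d2, params.reversal_r_d2)
    r5 = completeness(r_d5, params.reversal_r_d5)
    drift2 = drift(params.exp2_drift_d2)
    drift5 = drift(params.exp2_drift_d5)

    mean_d2 = np.clip(ds1 + r2 * (baseline - ds1) + drift2 * d2x, 0.01, 0.99)
    mean_d5 = np.clip(ds1 + r5 * (baseline - ds1) + drift5 * d2x, 0.01, 0.99)

    nrng = params.rng("reversal_noise")
    columns, rows, data = [], [], []
    for grp, mean in (("DS_p16_d2", mean_d2), ("DS_p16_d5", mean_d5)):
        for rep in range(1, params.n_replicates + 1):
            sid = f"{grp}_r{rep}"
            columns.append(sid)
            rows.append(
                {
                    "sample_id": sid, "group": grp, "experiment": "exp1",
                    "replicate": rep, "age": np.nan, "paired_with": "",
                }
            )
            data.append(_draw_beta_noise(mean, params.nu, nrng))
    beta = BetaMatrix(
        pd.DataFrame(
            np.column_stack(data), index=pd.Index(ids, name="probe_id"),
            columns=columns,
        )
    )
    samples = SampleTable(pd.DataFrame(rows).set_index("sample_id"))
    truth.reversal = pd.DataFrame(
        {"r_d2": r2, "r_d5": r5, "drift_d2": drift2, "drift_d5": drift5},
        index=pd.Index(ids, name="probe_id"),
    )
    logger.info("simulated reversal timecourse: %d samples", len(columns))
    return beta, samples, truth
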