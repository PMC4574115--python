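"""End-to-end pipeline: simulate → call → signature → score → SNP → reversal
→ expression enrichment, driven by one config with a single seed.

Every stage writes machine-readable outputs under the configured output
directory with fixed filenames, and ``summary.json`` records thresholds,
per-stage counts and the software version.  Rerunning with the same config
and seed is byte-identical except for the log (the only place timestamps
live).  A failed run leaves a ``FAILED`` marker file naming the stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .dmp import call_dmps, dmp_table
from .expression import call_de_genes, dmp_genes, methylation_expression_enrichment
from .genotype import rank_snp_results, snp_permutation_test
from .io import (
    read_beta_matrix,
    read_expression,
    read_genotypes,
    read_probe_annotation,
    read_samples,
    write_beta_matrix,
    write_expression,
    write_genotypes,
    write_probe_annotation,
    write_samples,
)
from .reversal import reversal_directionality, reversal_fractions
from .score import (
    compare_tumor_normal,
    hyper_hypo_correlation,
    score_covariate_association,
    senescence_score,
)
from .signature import classify_signature_groups, overlap_enrichment
from .simulate import SimParams, simulate_cohort, simulate_reversal, \
    simulate_two_experiment_senescence

logger = logging.getLogger("senesig")

STAGES = (
    "simulate", "call_dmps", "signature", "score", "snp", "reversal",
    "expression",
)


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (YAML-mirrorable)."""

    outdir: str = "senesig_out"
    seed: int = 1
    q_thresh: float = 0.01
    delta_thresh: float = 0.3
    minor_thresh: float = 0.1
    r_thresh: float = 0.15
    max_dist: int = 500
    n_resamples: int = 1000
    n_perm: int = 1000
    score_group: str = "agree"
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    sim: SimParams = field(default_factory=lambda: SimParams(nu=500.0))
    inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("q_thresh", 0.0, 1.0), ("delta_thresh", 0.0, 1.0),
            ("minor_thresh", 0.0, 1.0), ("r_thresh", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"config field {name}={v} outside [{lo}, {hi}]")
        if self.n_resamples < 1 or self.n_perm < 1:
            raise ValueError("n_resamples and n_perm must be >= 1")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        for s in STAGES:
            self.stages.setdefault(s, True)
        if isinstance(self.sim, dict):
            self.sim = SimParams(**self.sim)
        self._check_dependencies()
        if not self.stages["simulate"]:
            self._check_inputs()

    def _check_dependencies(self) -> None:
        s = self.stages
        needs = {
            "signature": ["call_dmps"],
            "score": ["signature"],
            "snp": ["signature"],
            "reversal": ["signature"],
            "expression": ["signature"],
        }
        for stage, deps in needs.items():
            if s.get(stage):
                for d in deps:
                    if not s.get(d):
                        raise ValueError(
                            f"stage {stage!r} requires stage {d!r} to be enabled"
                        )

    def _check_inputs(self) -> None:
        if not any(self.stages[s] for s in STAGES if s != "simulate"):
            return
        required = ["beta", "samples", "annotation"]
        if self.stages["score"] or self.stages["snp"]:
            required.append("cohort_beta")
            required.append("cohort_samples")
        if self.stages["snp"]:
            required.append("genotypes")
        if self.stages["reversal"]:
            required.append("reversal_beta")
        if self.stages["expression"]:
            required.append("expression")
        for key in required:
            path = self.inputs.get(key)
            if not path:
                raise ValueError(
                    f"simulation disabled but input {key!r} not configured"
                )
            if not Path(path).exists():
                raise ValueError(f"input file {path!r} ({key}) does not exist")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _seed_for(config: PipelineConfig, stage: str) -> int:
    """Per-stage deterministic 31-bit substream seed."""
    ss = np.random.SeedSequence(config.seed, spawn_key=(STAGES.index(stage),))
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages; returns the summary dict written to disk."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "FAILED"
    if marker.exists():
        marker.unlink()
    try:
        summary = _run(config, out)
    except Exception as exc:
        marker.write_text(f"pipeline failed: {exc}\n")
        raise
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return summary


def _run(config: PipelineConfig, out: Path) -> dict:
    summary = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "q": config.q_thresh, "delta": config.delta_thresh,
            "minor": config.minor_thresh, "r": config.r_thresh,
            "max_dist": config.max_dist,
        },
        "stages": {},
    }
    enabled = [s for s in STAGES if config.stages[s]]
    if not enabled:
        return summary

    annotation = truth = None
    beta = samples = cohort_beta = cohort_samples = None
    genotypes = expression = None
    reversal_beta = reversal_samples = None

    if config.stages["simulate"]:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        beta, samples, annotation, truth = simulate_two_experiment_senescence(sim)
        write_beta_matrix(beta, out / "beta_experiments.tsv")
        write_samples(samples, out / "samples_experiments.tsv")
        write_probe_annotation(annotation, out / "probes.bed")
        counts = {"n_probes": len(beta.probe_ids), "n_samples": len(beta.sample_ids)}
        if config.stages["score"] or config.stages["snp"] or config.stages["expression"]:
            cohort_beta, cohort_samples, genotypes, expression, cohort_truth = \
                simulate_cohort(sim, truth)
            write_beta_matrix(cohort_beta, out / "beta_cohort.tsv")
            write_samples(cohort_samples, out / "samples_cohort.tsv")
            write_genotypes(genotypes, out / "genotypes.tsv")
            write_expression(expression, out / "expression.tsv")
            counts["n_individuals"] = len(cohort_beta.sample_ids)
        if config.stages["reversal"]:
            reversal_beta, reversal_samples, truth = simulate_reversal(sim, truth)
            write_beta_matrix(reversal_beta, out / "beta_reversal.tsv")
            write_samples(reversal_samples, out / "samples_reversal.tsv")
        truth.to_json(out / "truth.json")
        summary["stages"]["simulate"] = counts
    else:
        beta = read_beta_matrix(config.inputs["beta"])
        samples = read_samples(config.inputs["samples"])
        annotation = read_probe_annotation(config.inputs["annotation"])
        if "cohort_beta" in config.inputs:
            cohort_beta = read_beta_matrix(config.inputs["cohort_beta"])
            cohort_samples = read_samples(config.inputs["cohort_samples"])
        if "genotypes" in config.inputs:
            genotypes = read_genotypes(config.inputs["genotypes"])
        if "expression" in config.inputs:
            expression = read_expression(config.inputs["expression"])
        if "reversal_beta" in config.inputs:
            reversal_beta = read_beta_matrix(config.inputs["reversal_beta"])

    groups = None
    dmps = {}
    deltas = {}
    if config.stages["call_dmps"]:
        experiments = sorted(set(samples.table["experiment"]))
        for e in experiments:
            recs = call_dmps(
                beta, samples, "EP", "DS", experiment=e,
                q_thresh=config.q_thresh, delta_thresh=config.delta_thresh,
            )
            dmps[e] = recs
            dmp_table(recs).to_csv(out / f"dmps_{e}.tsv", sep="\t")
            # full delta map for cross-experiment classification
            ep = samples.samples_in("EP", e)
            ds = samples.samples_in("DS", e)
            deltas[e] = (
                beta.values[ds].mean(axis=1) - beta.values[ep].mean(axis=1)
            )
        summary["stages"]["call_dmps"] = {e: len(r) for e, r in dmps.items()}

    signature = None
    if config.stages["signature"]:
        e1, e2 = sorted(dmps)[:2] if len(dmps) >= 2 else (None, None)
        if e2 is None:
            raise ValueError("signature stage needs two experiments of calls")
        groups = classify_signature_groups(
            dmps[e1], dmps[e2], deltas[e1].to_dict(), deltas[e2].to_dict(),
            minor_thresh=config.minor_thresh,
        )
        sig_json = {
            g: {
                "hyper": sorted(p for p, d in getattr(groups, g).items() if d == "hyper"),
                "hypo": sorted(p for p, d in getattr(groups, g).items() if d == "hypo"),
            }
            for g in ("exp1_only", "exp2_only", "agree", "disagree")
        }
        with open(out / "signature.json", "w") as fh:
            json.dump(sig_json, fh, indent=1, sort_keys=True)
        universe = sorted(set(beta.probe_ids))
        called1 = {r.probe_id for r in dmps[e1]}
        called2 = {r.probe_id for r in dmps[e2]}
        enr = overlap_enrichment(
            called1, called2, universe, n_resamples=config.n_resamples,
            seed=_seed_for(config, "signature"),
        )
        summary["stages"]["signature"] = {
            **groups.counts(),
            "overlap_fold_analytic": _round(enr.fold_analytic),
            "overlap_fold_empirical": _round(enr.fold_empirical),
            "overlap_empirical_p": _round(enr.empirical_p),
        }
        signature = (
            groups.signature(config.score_group)
            if len(getattr(groups, config.score_group)) > 0
            else None
        )

    if config.stages["score"]:
        if signature is None:
            raise ValueError(
                f"score stage: signature group {config.score_group!r} is empty"
            )
        sres = senescence_score(cohort_beta, signature)
        sres.table.round(6).to_csv(out / "scores.tsv", sep="\t")
        stats_out = {}
        hh = hyper_hypo_correlation(cohort_beta, signature)
        stats_out["hyper_hypo_tau"] = _round(hh.tau)
        stats_out["hyper_hypo_p"] = _round(hh.p)
        ages = cohort_samples.table["age"]
        if ages.notna().sum() >= 3:
            ka = score_covariate_association(sres.scores, ages)
            stats_out["age_tau"] = _round(ka.tau)
            stats_out["age_p"] = _round(ka.p)
        normals = cohort_samples.samples_in("normal")
        tumors = cohort_samples.samples_in("tumor")
        if len(normals) >= 2 and len(tumors) >= 2:
            w = compare_tumor_normal(
                sres.scores.loc[normals], sres.scores.loc[tumors]
            )
            stats_out["tumor_normal_t"] = _round(w.t)
            stats_out["tumor_normal_p"] = _round(w.p)
        with open(out / "score_stats.json", "w") as fh:
            json.dump(stats_out, fh, indent=1, sort_keys=True)
        summary["stages"]["score"] = {
            "n_scored": int(len(sres.table)), **stats_out,
        }

    if config.stages["snp"]:
        if signature is None:
            raise ValueError(
                f"snp stage: signature group {config.score_group!r} is empty"
            )
        universe = sorted(set(cohort_beta.probe_ids))
        snp_res = snp_permutation_test(
            genotypes, cohort_beta, signature, universe,
            n_perm=config.n_perm, seed=_seed_for(config, "snp"),
            r_thresh=config.r_thresh,
        )
        ranked = rank_snp_results(snp_res, genotypes.snps)
        ranked.round(6).to_csv(out / "snp_results.tsv", sep="\t")
        top = ranked.index[0] if len(ranked) else None
        summary["stages"]["snp"] = {
            "n_snps": int(len(ranked)),
            "top_snp": top,
            "top_statistic": _round(float(ranked["statistic"].iloc[0]))
            if top else None,
            "top_perm_p": _round(float(ranked["perm_p"].iloc[0])) if top else None,
        }

    if config.stages["reversal"]:
        ep_samples = samples.samples_in("EP", "exp1")
        beta_ep = beta.subset_samples(ep_samples)
        rev_out = {}
        for tp in ("DS_p16_d2", "DS_p16_d5"):
            if reversal_samples is not None:
                cols = reversal_samples.samples_in(tp)
            else:
                cols = [s for s in reversal_beta.sample_ids if s.startswith(tp)]
            if not cols:
                continue
            rep = reversal_fractions(
                reversal_beta.subset_samples(cols), beta_ep, groups,
            )
            rev_out[tp] = [
                {k: _round(v) if isinstance(v, float) else v for k, v in row.items()}
                for row in rep.fractions.to_dict(orient="records")
            ]
        with open(out / "reversal.json", "w") as fh:
            json.dump(rev_out, fh, indent=1, sort_keys=True)
        summary["stages"]["reversal"] = {
            tp: len(rows) for tp, rows in rev_out.items()
        }

    if config.stages["expression"]:
        if signature is None:
            raise ValueError(
                f"expression stage: signature group {config.score_group!r} is empty"
            )
        de, de_tab = call_de_genes(
            expression, cohort_samples, "normal", "tumor",
            q_thresh=config.q_thresh,
        )
        sig_genes = dmp_genes(
            list(signature.hyper_probes) + list(signature.hypo_probes),
            annotation,
        )
        gene_universe = sorted(
            {g for g in annotation.table["gene"] if g} | set(expression.gene_ids)
        )
        enr = methylation_expression_enrichment(
            sig_genes, de, gene_universe, n_resamples=config.n_resamples,
            seed=_seed_for(config, "expression"),
        )
        payload = {
            "n_de_genes": len(de),
            "n_dmp_genes": len(sig_genes),
            "observed_overlap": enr.observed,
            "fold_analytic": _round(enr.fold_analytic),
            "fold_empirical": _round(enr.fold_empirical),
            "empirical_p": _round(enr.empirical_p),
        }
        with open(out / "enrichment.json", "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
        summary["stages"]["expression"] = payload

    return summary


def _round(v, nd: int = 6):
    if v is None:
        return None
    try:
        f = float(v)
    except (TypeError, ValueError):
        return v
    if np.isnan(f):
        return None
    if np.isinf(f):
        return "inf" if f > 0 else "-inf"
    return round(f, nd)
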