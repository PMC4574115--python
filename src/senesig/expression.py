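"""Differential expression and its enrichment among senDMP-annotated genes.

Genes differentially expressed between two sample groups are called with the
same per-feature F-test + Benjamini–Hochberg machinery used for methylation
(direction is ignored downstream, no fold-change filter by default).  The
gene sets annotated to senDMPs (promoter or gene-body probes) are then
tested for enrichment among the DE genes against a resampled background of
random gene sets, sharing the overlap-enrichment implementation used for
probe sets.
"""

from __future__ import annotations

import logging

import pandas as pd

from .dmp import DMPRecord, anova_table, bh_qvalues
from .io import ExpressionMatrix, ProbeAnnotation, SampleTable
from .signature import OverlapEnrichment, overlap_enrichment

logger = logging.getLogger("senesig")

DEFAULT_GENE_CLASSES = frozenset({"promoter", "gene_body"})


def call_de_genes(
    expr: ExpressionMatrix,
    samples: SampleTable,
    group_a: str,
    group_b: str,
    q_thresh: float = 0.01,
) -> tuple[set, pd.DataFrame]:
    """Call differentially expressed genes between two groups.

    Per-gene two-group F-test (the square of the pooled t) on normalized
    expression with BH correction; returns (genes with q < ``q_thresh``,
    full per-gene table with F, p, q, delta).
    """
    sel_a = samples.samples_in(group_a)
    sel_b = samples.samples_in(group_b)
    if len(sel_a) < 2 or len(sel_b) < 2:
        raise ValueError(
            f"each group needs >=2 samples: {group_a}={len(sel_a)}, "
            f"{group_b}={len(sel_b)}"
        )
    labels = pd.Series(
        {**{s: group_a for s in sel_a}, **{s: group_b for s in sel_b}}
    )
    table = anova_table(expr.values, labels, order=(group_a, group_b)).copy()
    table["q"] = bh_qvalues(table["p"].to_numpy())
    de = set(table.index[table["q"] < q_thresh])
    logger.info(
        "call_de_genes %s vs %s: %d/%d genes at q<%g",
        group_a, group_b, len(de), len(table), q_thresh,
    )
    return de, table


def dmp_genes(
    dmps, annotation: ProbeAnnotation, classes=DEFAULT_GENE_CLASSES
) -> set:
    """Unique gene symbols of DMP probes in the given feature classes.

    Intergenic probes and probes with an empty gene field contribute
    nothing.
    """
    probe_ids = [r.probe_id if isinstance(r, DMPRecord) else r for r in dmps]
    missing = annotation.covers(probe_ids)
    if missing:
        raise ValueError(
            f"annotation does not cover DMP probes, e.g. {missing[:5]}"
        )
    t = annotation.table.loc[probe_ids]
    keep = t["feature_class"].isin(set(classes)) & (t["gene"] != "")
    return set(t.loc[keep, "gene"])


def methylation_expression_enrichment(
    dmp_gene_set,
    de_gene_set,
    gene_universe,
    n_resamples: int = 1000,
    seed=None,
) -> OverlapEnrichment:
    """Enrichment of DE genes among senDMP-annotated genes.

    Identical machinery to probe-set overlap enrichment applied at the gene
    level: the observed overlap is compared with random gene sets of size
    |dmp genes| drawn from the universe.
    """
    return overlap_enrichment(
        dmp_gene_set, de_gene_set, gene_universe,
        n_resamples=n_resamples, seed=seed,
    )
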