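"""Core data model and TSV/BED-like readers and writers.

All downstream stages operate on five in-memory containers built on pandas:

* :class:`BetaMatrix` — probes × samples methylation fractions (beta values)
  in [0, 1], ``NaN`` marking missing cells.
* :class:`ProbeAnnotation` — per-probe genomic coordinates (BED convention,
  0-based; the probe position is the interval start), gene symbol, feature
  class and QC flags.
* :class:`SampleTable` — sample metadata: biological group, experiment label,
  replicate number, age, pairing.
* :class:`GenotypeMatrix` — a GWAS-catalogue-style SNP table plus a
  SNP × individuals grid of risk-allele dosages in {0, 1, 2}.
* :class:`ExpressionMatrix` — genes × samples normalized expression.

On-disk formats are plain TSV (beta, samples, genotypes, expression; missing
values written as the literal ``NA``) and a headerless 7-column BED-like file
for probe annotation.  Beta and expression values are written to 6 decimal
places; write∘read is the identity at that precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("senesig")

SAMPLE_GROUPS = frozenset(
    {"EP", "DS", "DS_p16_d2", "DS_p16_d5", "normal", "tumor", "other"}
)
FEATURE_CLASSES = frozenset({"promoter", "gene_body", "intergenic"})
PROBE_FLAGS = frozenset({"sex_chromosome", "multimapping", "low_detection"})
SEX_CHROMOSOMES = frozenset({"chrX", "chrY", "X", "Y"})

#: Missing-value marker used in every TSV dialect.
NA_TOKEN = "NA"
#: Decimal places used when writing fractional values.
FLOAT_DECIMALS = 6


class ValidationError(ValueError):
    """A container or file violated one of the data-model invariants."""


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what}: {dups}")


# ---------------------------------------------------------------------------
# BetaMatrix
# ---------------------------------------------------------------------------


@dataclass
class BetaMatrix:
    """Probes × samples beta values in [0, 1]; NaN = missing."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        self.values = self.values.astype(float)
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)
        _check_unique(self.values.index, "probe id")
        _check_unique(self.values.columns, "sample id")
        arr = self.values.to_numpy()
        bad = (arr < 0.0) | (arr > 1.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value {arr[i, j]!r} outside [0,1] at probe "
                f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_probes(self, probes) -> "BetaMatrix":
        probes = [p for p in probes if p in self.values.index]
        return BetaMatrix(self.values.loc[probes])

    def subset_samples(self, samples) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[:, list(samples)])


def read_beta_matrix(path) -> BetaMatrix:
    """Read a beta-value TSV (header row of sample ids, first column probe ids)."""
    df = _read_numeric_tsv(path, kind="beta")
    bm = BetaMatrix(df)
    logger.info("read beta matrix %s: %d probes x %d samples", path, *bm.shape)
    return bm


def write_beta_matrix(bm: BetaMatrix, path) -> None:
    out = bm.values.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", na_rep=NA_TOKEN, float_format=f"%.{FLOAT_DECIMALS}f")


def _read_numeric_tsv(path, kind: str) -> pd.DataFrame:
    """Strict TSV reader: ragged rows, duplicate ids and bad cells are errors."""
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            index_col=0,
            dtype=str,
            na_values=[NA_TOKEN],
            keep_default_na=False,
        )
    except pd.errors.ParserError as exc:  # ragged row and friends
        raise ValidationError(f"malformed {kind} TSV {path}: {exc}") from exc
    if df.isna().all(axis=1).any() and df.shape[1] == 0:
        raise ValidationError(f"{kind} TSV {path} has no data columns")
    df.index = df.index.astype(str)
    _check_unique(df.index, f"{kind} row id")
    _check_unique(df.columns, f"{kind} column id")
    num = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        try:
            num[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ValidationError(
                f"non-numeric value in {kind} TSV {path}, column {col!r}: {exc}"
            ) from exc
    return num


# ---------------------------------------------------------------------------
# ProbeAnnotation
# ---------------------------------------------------------------------------


@dataclass
class ProbeAnnotation:
    """Per-probe genomic annotation.

    ``table`` is indexed by probe_id with columns ``chrom`` (str), ``pos``
    (int, 0-based coordinate of the interrogated cytosine = BED start),
    ``gene`` (symbol or empty string), ``feature_class`` (promoter /
    gene_body / intergenic) and ``flags`` (frozenset ⊆
    {sex_chromosome, multimapping, low_detection}).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"chrom", "pos", "gene", "feature_class", "flags"}
        missing = required - set(t.columns)
        if missing:
            raise ValidationError(f"annotation missing columns {sorted(missing)}")
        t.index = t.index.astype(str)
        _check_unique(t.index, "probe id")
        if (t["pos"].astype(int) < 0).any():
            bad = t.index[t["pos"].astype(int) < 0][0]
            raise ValidationError(f"negative position for probe {bad!r}")
        t["pos"] = t["pos"].astype(int)
        bad_fc = set(t["feature_class"]) - FEATURE_CLASSES
        if bad_fc:
            raise ValidationError(f"unknown feature_class values {sorted(bad_fc)}")
        t["flags"] = t["flags"].map(_as_flagset)
        t["gene"] = t["gene"].fillna("").astype(str)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table.index)

    def covers(self, probes) -> list[str]:
        """Return probes from ``probes`` missing from this annotation."""
        return [p for p in probes if p not in self.table.index]


def _as_flagset(flags) -> frozenset:
    if isinstance(flags, frozenset):
        fs = flags
    elif isinstance(flags, (set, list, tuple)):
        fs = frozenset(flags)
    elif flags is None or (isinstance(flags, float) and np.isnan(flags)):
        fs = frozenset()
    else:
        s = str(flags).strip()
        fs = frozenset() if s in {"", "."} else frozenset(s.split(","))
    bad = fs - PROBE_FLAGS
    if bad:
        raise ValidationError(f"unknown probe flags {sorted(bad)}")
    return fs


def read_probe_annotation(path) -> ProbeAnnotation:
    """Read 7-column BED-like annotation.

    Columns: chrom, start, end, probe_id, gene, feature_class, flags
    (comma-joined or "." for none).  A "." gene means no associated gene.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "probe_id", "gene", "feature_class", "flags"],
            dtype=str,
            na_values=[],
            keep_default_na=False,
        )
    except pd.errors.ParserError as exc:
        raise ValidationError(f"malformed annotation BED {path}: {exc}") from exc
    if df.shape[1] != 7:
        raise ValidationError(f"annotation BED {path} must have 7 columns")
    try:
        start = df["start"].astype(int)
    except ValueError as exc:
        raise ValidationError(f"non-integer start in {path}: {exc}") from exc
    gene = df["gene"].replace(".", "")
    table = pd.DataFrame(
        {
            "chrom": df["chrom"].to_numpy(),
            "pos": start.to_numpy(),
            "gene": gene.to_numpy(),
            "feature_class": df["feature_class"].to_numpy(),
            "flags": df["flags"].to_numpy(),
        },
        index=pd.Index(df["probe_id"].astype(str), name="probe_id"),
    )
    ann = ProbeAnnotation(table)
    logger.info("read probe annotation %s: %d probes", path, len(table))
    return ann


def write_probe_annotation(ann: ProbeAnnotation, path) -> None:
    t = ann.table
    out = pd.DataFrame(
        {
            "chrom": t["chrom"],
            "start": t["pos"],
            "end": t["pos"] + 1,
            "probe_id": t.index,
            "gene": t["gene"].replace("", "."),
            "feature_class": t["feature_class"],
            "flags": t["flags"].map(lambda fs: ",".join(sorted(fs)) if fs else "."),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# SampleTable
# ---------------------------------------------------------------------------


@dataclass
class SampleTable:
    """Sample metadata indexed by sample_id.

    Columns: ``group`` (closed set), ``experiment`` (free label), ``replicate``
    (int), ``age`` (years, NaN if unknown), ``paired_with`` (sample id or "").
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"group", "experiment", "replicate", "age", "paired_with"}
        missing = required - set(t.columns)
        if missing:
            raise ValidationError(f"sample table missing columns {sorted(missing)}")
        t.index = t.index.astype(str)
        _check_unique(t.index, "sample id")
        bad = set(t["group"]) - SAMPLE_GROUPS
        if bad:
            raise ValidationError(f"unknown sample groups {sorted(bad)}")
        t["replicate"] = t["replicate"].astype(int)
        t["age"] = pd.to_numeric(t["age"], errors="raise")
        if (t["age"].dropna() < 0).any():
            raise ValidationError("negative age in sample table")
        t["paired_with"] = t["paired_with"].fillna("").astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def samples_in(self, group: str, experiment: str | None = None) -> list[str]:
        t = self.table
        mask = t["group"] == group
        if experiment is not None:
            mask &= t["experiment"] == experiment
        return list(t.index[mask])

    def group_map(self, samples=None) -> dict[str, str]:
        t = self.table if samples is None else self.table.loc[list(samples)]
        return dict(t["group"])


def read_samples(path) -> SampleTable:
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, dtype=str,
            na_values=[NA_TOKEN], keep_default_na=False,
        )
    except pd.errors.ParserError as exc:
        raise ValidationError(f"malformed sample TSV {path}: {exc}") from exc
    st = SampleTable(df)
    logger.info("read sample table %s: %d samples", path, len(df))
    return st


def write_samples(st: SampleTable, path) -> None:
    out = st.table.copy()
    out.index.name = "sample_id"
    out["paired_with"] = out["paired_with"].replace("", NA_TOKEN)
    out.to_csv(path, sep="\t", na_rep=NA_TOKEN)


# ---------------------------------------------------------------------------
# GenotypeMatrix
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """SNP metadata plus SNP × individuals risk-allele dosage grid.

    ``snps`` is indexed by snp_id with columns chrom, pos, risk_allele, trait;
    ``dosages`` shares the snp_id index, one column per individual, values in
    {0, 1, 2} or NaN.
    """

    snps: pd.DataFrame
    dosages: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "risk_allele", "trait"}
        missing = required - set(self.snps.columns)
        if missing:
            raise ValidationError(f"snp table missing columns {sorted(missing)}")
        self.snps.index = self.snps.index.astype(str)
        _check_unique(self.snps.index, "snp id")
        self.snps["pos"] = self.snps["pos"].astype(int)
        if (self.snps["pos"] < 0).any():
            raise ValidationError("negative SNP position")
        self.dosages = self.dosages.astype(float)
        self.dosages.index = self.dosages.index.astype(str)
        if list(self.dosages.index) != list(self.snps.index):
            raise ValidationError("snp table and dosage grid indices differ")
        arr = self.dosages.to_numpy()
        ok = np.isnan(arr) | (arr == 0) | (arr == 1) | (arr == 2)
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise ValidationError(
                f"dosage {arr[i, j]!r} outside {{0,1,2}} at SNP "
                f"{self.dosages.index[i]!r}, individual {self.dosages.columns[j]!r}"
            )

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snps.index)

    @property
    def individual_ids(self) -> list[str]:
        return list(self.dosages.columns)


def read_genotypes(path) -> GenotypeMatrix:
    """Read genotype TSV: snp_id, chrom, pos, risk_allele, trait, then dosages."""
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, dtype=str,
            na_values=[NA_TOKEN], keep_default_na=False,
        )
    except pd.errors.ParserError as exc:
        raise ValidationError(f"malformed genotype TSV {path}: {exc}") from exc
    meta_cols = ["chrom", "pos", "risk_allele", "trait"]
    missing = set(meta_cols) - set(df.columns)
    if missing:
        raise ValidationError(f"genotype TSV missing columns {sorted(missing)}")
    snps = df[meta_cols].copy()
    dosage_cols = [c for c in df.columns if c not in meta_cols]
    dos = pd.DataFrame(index=df.index, columns=dosage_cols, dtype=float)
    for col in dosage_cols:
        try:
            dos[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ValidationError(
                f"non-numeric dosage in {path}, individual {col!r}: {exc}"
            ) from exc
    gm = GenotypeMatrix(snps, dos)
    logger.info(
        "read genotypes %s: %d SNPs x %d individuals", path, *gm.dosages.shape
    )
    return gm


def write_genotypes(gm: GenotypeMatrix, path) -> None:
    dos = gm.dosages.copy()
    # integral dosages are written without a decimal point
    out = pd.concat([gm.snps, dos], axis=1)
    out.index.name = "snp_id"
    with pd.option_context("display.float_format", None):
        out.to_csv(
            path, sep="\t", na_rep=NA_TOKEN,
            float_format=lambda v: f"{v:.0f}",
        )


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes × samples normalized expression (arbitrary log-scale units)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)
        _check_unique(self.values.index, "gene id")
        _check_unique(self.values.columns, "sample id")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def read_expression(path) -> ExpressionMatrix:
    df = _read_numeric_tsv(path, kind="expression")
    em = ExpressionMatrix(df)
    logger.info("read expression %s: %d genes x %d samples", path, *df.shape)
    return em


def write_expression(em: ExpressionMatrix, path) -> None:
    out = em.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", na_rep=NA_TOKEN, float_format=f"%.{FLOAT_DECIMALS}f")
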