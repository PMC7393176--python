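"""Cohort input/output.

Reads and validates the two inputs of the analysis — a bulk expression matrix
(RSEM-style relative abundances, genes in rows) and a somatic mutation table
(MAF) — applies the log transform used throughout the package, and implements
the two gene pre-filters (top-variance genes for the expression metric, and
prevalence + nonsynonymous/total-ratio selection of test genes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: MAF Variant_Classification values treated as protein-altering.
NONSYNONYMOUS_CLASSES = frozenset({
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "Splice_Site",
    "Nonstop_Mutation",
    "Translation_Start_Site",
    "In_Frame_Del",
    "In_Frame_Ins",
})

MAF_REQUIRED_COLUMNS = ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification")


def transform_rsem(x):
    """Transform RSEM relative abundances: ``r = log2(1 + 1e6 * x)``.

    Accepts scalars or arrays; negative or missing input raises ``ValueError``.
    The transform is strictly increasing with ``transform_rsem(0) == 0``, so
    transformed values are always nonnegative.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(np.isnan(arr)):
        raise ValueError("expression values contain missing entries")
    if np.any(arr < 0):
        raise ValueError("RSEM relative abundances must be nonnegative")
    out = np.log2(1.0 + 1e6 * arr)
    if arr.ndim == 0:
        return float(out)
    return out


@dataclass
class ExpressionMatrix:
    """Transformed expression values, samples x genes.

    ``data`` is a pandas DataFrame indexed by sample id with gene ids as
    columns, on the transformed (log2) scale.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if self.data.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        self.data = self.data.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(samples)])

    def write_tsv(self, path) -> None:
        """Write genes-in-rows TSV of transformed values."""
        self.data.T.to_csv(path, sep="\t", index_label="gene_id")


def read_expression(path, already_transformed: bool = False) -> ExpressionMatrix:
    """Read a genes-in-rows TSV (first column gene id, header sample ids).

    Values are transformed with :func:`transform_rsem` unless
    ``already_transformed``. Duplicate gene rows keep the first occurrence
    (logged); a duplicated sample column is an error.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise ValueError(f"empty expression file: {path}")
    sample_cols = header.rstrip("\n").split("\t")[1:]
    if len(sample_cols) != len(set(sample_cols)):
        dupes = sorted({s for s in sample_cols if sample_cols.count(s) > 1})
        raise ValueError(f"duplicate sample id(s) in expression header: {dupes}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"expression file has no data rows: {path}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValueError(
                f"non-numeric expression value in sample column {col!r} "
                f"(first offending gene: {bad.index[0]!r})"
            )
    if df.index.has_duplicates:
        n = int(df.index.duplicated().sum())
        logger.warning("%d duplicated gene id(s); keeping first occurrence", n)
        df = df[~df.index.duplicated(keep="first")]
    mat = df.T  # samples x genes
    if not already_transformed:
        mat = pd.DataFrame(
            transform_rsem(mat.to_numpy()), index=mat.index, columns=mat.columns
        )
    return ExpressionMatrix(mat)


@dataclass
class MutationTable:
    """Somatic mutation records over a fixed sample universe.

    ``records`` has columns sample_id, gene_id, variant_class,
    is_nonsynonymous. A sample's burden is its total record count (all
    variant classes); silent/non-coding records are retained because the
    test-gene filter ranks genes by their nonsynonymous/total ratio.
    """

    records: pd.DataFrame
    sample_universe: list[str]

    REQUIRED = ("sample_id", "gene_id", "variant_class", "is_nonsynonymous")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"mutation records missing column(s): {missing}")
        if len(self.sample_universe) != len(set(self.sample_universe)):
            raise ValueError("duplicate sample ids in sample universe")
        universe = set(self.sample_universe)
        unknown = set(self.records["sample_id"]) - universe
        if unknown:
            raise ValueError(
                f"mutation records reference samples outside the universe: "
                f"{sorted(unknown)[:5]}"
            )
        self.records = self.records.reset_index(drop=True)

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.records["gene_id"].unique())

    def burdens(self) -> pd.Series:
        """Total mutation count (all classes) per sample, 0 for unmutated."""
        counts = self.records["sample_id"].value_counts()
        return counts.reindex(self.sample_universe, fill_value=0).astype(int)

    def nonsyn_indicator(self, genes: Sequence[str], samples: Sequence[str] | None = None) -> pd.DataFrame:
        """Boolean samples x genes matrix: >=1 nonsynonymous mutation."""
        samples = list(samples) if samples is not None else list(self.sample_universe)
        sub = self.records[self.records["is_nonsynonymous"]]
        sub = sub[sub["gene_id"].isin(set(genes))]
        ind = pd.DataFrame(False, index=samples, columns=list(genes))
        sset = set(samples)
        for s, g in zip(sub["sample_id"], sub["gene_id"]):
            if s in sset:
                ind.at[s, g] = True
        return ind

    def prevalence(self, genes: Sequence[str] | None = None) -> pd.Series:
        """Fraction of universe samples with >=1 nonsynonymous mutation per gene."""
        sub = self.records[self.records["is_nonsynonymous"]]
        n = len(self.sample_universe)
        counts = sub.drop_duplicates(["sample_id", "gene_id"])["gene_id"].value_counts()
        if genes is None:
            genes = sorted(counts.index)
        return counts.reindex(list(genes), fill_value=0) / n

    def subset_samples(self, samples: Sequence[str]) -> "MutationTable":
        keep = set(samples)
        rec = self.records[self.records["sample_id"].isin(keep)]
        return MutationTable(rec.copy(), list(samples))

    def write_maf(self, path) -> None:
        out = pd.DataFrame(
            {
                "Hugo_Symbol": self.records["gene_id"],
                "Tumor_Sample_Barcode": self.records["sample_id"],
                "Variant_Classification": self.records["variant_class"],
            }
        )
        out.to_csv(path, sep="\t", index=False)


def read_maf(path, sample_universe: Sequence[str] | None = None) -> MutationTable:
    """Read a tab-delimited MAF.

    Needs at least Hugo_Symbol, Tumor_Sample_Barcode and
    Variant_Classification. Records in :data:`NONSYNONYMOUS_CLASSES` are
    flagged protein-altering; Silent and non-coding classes are retained with
    ``is_nonsynonymous=False``. The sample universe defaults to the samples
    present in the file.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, low_memory=False)
    for col in MAF_REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"MAF is missing required column {col!r}")
    records = pd.DataFrame(
        {
            "sample_id": df["Tumor_Sample_Barcode"],
            "gene_id": df["Hugo_Symbol"],
            "variant_class": df["Variant_Classification"],
        }
    )
    records["is_nonsynonymous"] = records["variant_class"].isin(NONSYNONYMOUS_CLASSES)
    if sample_universe is None:
        sample_universe = sorted(records["sample_id"].unique())
    return MutationTable(records, list(sample_universe))


def read_batches(path) -> pd.Series:
    """Two-column TSV (sample_id, batch) -> Series indexed by sample."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("batch file needs two columns: sample_id, batch")
    s = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="batch")
    if s.index.has_duplicates:
        raise ValueError("duplicate sample ids in batch file")
    return s


def align_cohort(expression: ExpressionMatrix, mutations: MutationTable) -> tuple[ExpressionMatrix, MutationTable]:
    """Keep samples present in both inputs (dropped counts are logged)."""
    mut_samples = set(mutations.sample_universe)
    shared = [s for s in expression.sample_ids if s in mut_samples]
    if len(shared) < 2:
        raise ValueError("fewer than 2 samples shared between expression and mutation data")
    n_expr_drop = expression.n_samples - len(shared)
    n_mut_drop = len(mutations.sample_universe) - len(shared)
    if n_expr_drop or n_mut_drop:
        logger.info(
            "aligning cohort: dropped %d expression-only and %d mutation-only samples",
            n_expr_drop, n_mut_drop,
        )
    return expression.subset_samples(shared), mutations.subset_samples(shared)


@dataclass
class AnalysisConfig:
    """Tunable parameters of the analysis.

    ``prevalence_min`` is deliberately required: the minimum cohort prevalence
    for a gene to enter the test set is a per-cohort choice with no universal
    default. Remaining defaults follow the standard protocol: 350 test genes
    ranked by nonsynonymous/total ratio, 4500 top-variance genes for the
    expression metric, k=30 neighbors, 1e4 permutations, q<0.15 significance,
    2000 permutations and a 0.8 median-q cut for the Jensen-Shannon filter.
    """

    prevalence_min: float
    max_test_genes: int = 350
    n_variable_genes: int = 4500
    k_neighbors: int = 30
    n_permutations: int = 10_000
    q_threshold: float = 0.15
    js_removal_q: float = 0.8
    js_n_permutations: int = 2000
    js_mode: str = "anticorrelation"  # or "literal"
    burden_threshold: float | str = "auto"
    burden_alpha: float = 0.05
    batch_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence_min <= 1.0:
            raise ValueError("prevalence_min must be in [0, 1]")
        for name in ("max_test_genes", "n_variable_genes", "k_neighbors",
                     "n_permutations", "js_n_permutations"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be a positive integer")
        for name in ("q_threshold", "js_removal_q", "burden_alpha", "batch_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be a fraction in (0, 1)")
        if self.js_mode not in ("anticorrelation", "literal"):
            raise ValueError("js_mode must be 'anticorrelation' or 'literal'")
        if self.burden_threshold != "auto" and float(self.burden_threshold) <= 0:
            raise ValueError("burden_threshold must be positive or 'auto'")

    def resolved_burden_threshold(self) -> float:
        """'auto' resolves to 10**2.5 total mutations."""
        if self.burden_threshold == "auto":
            return 10.0 ** 2.5
        return float(self.burden_threshold)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def replace(self, **kw) -> "AnalysisConfig":
        return replace(self, **kw)


def select_variable_genes(expression: ExpressionMatrix, n: int) -> list[str]:
    """Gene ids with the ``n`` highest (unbiased) variances across samples.

    Ties are broken lexicographically by gene id so the selection is
    deterministic.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    var = expression.data.var(axis=0, ddof=1)
    order = sorted(var.index, key=lambda g: (-var[g], g))
    return order[: min(n, len(order))]


def filter_test_genes(mutations: MutationTable, cfg: AnalysisConfig) -> list[str]:
    """Select genes to test for localization.

    Keeps genes whose nonsynonymous prevalence is at least
    ``cfg.prevalence_min``, ranks them by descending nonsynonymous/total
    mutation-count ratio (ties: higher prevalence, then gene id), and
    truncates to ``cfg.max_test_genes``.
    """
    rec = mutations.records
    totals = rec["gene_id"].value_counts()
    nonsyn = rec[rec["is_nonsynonymous"]]["gene_id"].value_counts()
    prev = mutations.prevalence(list(totals.index))
    rows = []
    for g in totals.index:
        if prev[g] < cfg.prevalence_min:
            continue
        ratio = float(nonsyn.get(g, 0)) / float(totals[g])
        rows.append((g, ratio, float(prev[g])))
    rows.sort(key=lambda r: (-r[1], -r[2], r[0]))
    genes = [g for g, _, _ in rows[: cfg.max_test_genes]]
    if not genes:
        logger.warning("no genes pass the prevalence filter (prevalence_min=%g)",
                       cfg.prevalence_min)
    return genes
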