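"""Resolution x gain parameter scan and aggregation.

A single Mapper representation depends on two cover parameters with no
canonical value, so the analysis is repeated over a grid (coarse default:
resolution 10-80 in steps of 10, gain 1.5-8.5 in steps of 1), a stable
sub-region is selected (many significant genes, no unresolved confounds),
optionally refined at steps of 5 and 0.5, and per-gene significance is
aggregated as the median q across grid cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .confounds import (
    CohortExcludedError,
    ConfoundReport,
    batch_control,
    batch_sample_mask,
    burden_localization,
    js_permutation_filter,
    subsample_hypermutators,
)
from .io import AnalysisConfig, ExpressionMatrix, MutationTable
from .localization import localize_all
from .mapper import MapperConfig, TopologicalRepresentation, build_representation, correlation_distance, filter_embedding

logger = logging.getLogger(__name__)

DEFAULT_RESOLUTIONS = tuple(range(10, 81, 10))
DEFAULT_GAINS = tuple(1.5 + i for i in range(8))  # 1.5 .. 8.5


def coarse_grid(resolutions: Sequence[int] | None = None,
                gains: Sequence[float] | None = None,
                k_neighbors: int = 30,
                filter_kind: str = "geodesic_mds") -> list[MapperConfig]:
    """Cartesian product of the coarse resolution/gain ranges (default
    8 x 8 = 64 configurations)."""
    resolutions = tuple(resolutions) if resolutions is not None else DEFAULT_RESOLUTIONS
    gains = tuple(gains) if gains is not None else DEFAULT_GAINS
    return [MapperConfig(resolution=int(r), gain=float(g), k_neighbors=k_neighbors,
                         filter_kind=filter_kind)
            for r in resolutions for g in gains]


def fine_grid(region: dict, resolution_step: int = 5, gain_step: float = 0.5,
              k_neighbors: int = 30, filter_kind: str = "geodesic_mds") -> list[MapperConfig]:
    """Grid over ``region`` (keys resolution_min/max, gain_min/max) at the
    fine steps (5 in resolution, 0.5 in gain), endpoints inclusive."""
    r0, r1 = int(region["resolution_min"]), int(region["resolution_max"])
    g0, g1 = float(region["gain_min"]), float(region["gain_max"])
    if r1 < r0 or g1 < g0:
        raise ValueError("empty fine-scan region")
    resolutions = np.arange(r0, r1 + resolution_step / 2, resolution_step)
    gains = np.arange(g0, g1 + gain_step / 2, gain_step)
    return [MapperConfig(resolution=int(r), gain=float(g), k_neighbors=k_neighbors,
                         filter_kind=filter_kind)
            for r in resolutions for g in gains]


@dataclass
class CellResult:
    """One grid cell: representation, per-gene results, confound report."""

    config: MapperConfig
    representation: TopologicalRepresentation
    results: pd.DataFrame
    confounds: ConfoundReport
    passed: bool  # burden control resolved (possibly after subsampling)

    @property
    def n_significant(self) -> int:
        if self.results.empty:
            return 0
        return int(self.results["significant"].sum())


@dataclass
class ScanResult:
    grid: list[CellResult]
    genes: list[str]
    js_removed: set[str] = field(default_factory=set)
    js_table: pd.DataFrame | None = None
    config: AnalysisConfig | None = None

    @property
    def passing_cells(self) -> list[CellResult]:
        return [c for c in self.grid if c.passed]


def run_scan(expression: ExpressionMatrix, mutations: MutationTable,
             genes: Sequence[str], mapper_configs: Sequence[MapperConfig],
             cfg: AnalysisConfig, batches: pd.Series | None = None,
             variable_genes: Sequence[str] | None = None,
             n_perm: int | None = None, js_n_perm: int | None = None,
             js_filter: bool = True,
             override_burden_exclusion: bool = False) -> ScanResult:
    """Run the full per-cell analysis across ``mapper_configs``.

    Stages per cell: representation (distance matrix and filter embedding are
    shared across cells with the same k and filter kind); burden control with
    hypermutator subsampling when triggered; batch control; then, across all
    cells jointly, the Jensen-Shannon anticorrelation filter; finally
    localization with BH adjustment over the retained genes. Cells whose
    burden stays localized after subsampling carry no gene results; if every
    cell fails, the cohort is excluded (``CohortExcludedError``) unless
    ``override_burden_exclusion``.
    """
    genes = list(genes)
    variable_genes = list(variable_genes) if variable_genes is not None else expression.gene_ids
    D = correlation_distance(expression, variable_genes)
    coords_cache: dict[tuple, np.ndarray] = {}
    reps: list[TopologicalRepresentation] = []
    for mc in mapper_configs:
        key = (mc.k_neighbors, mc.filter_kind)
        if key not in coords_cache:
            coords_cache[key] = filter_embedding(D, mc, expression=expression,
                                                 genes=variable_genes)
        reps.append(build_representation(expression, mc, genes=variable_genes,
                                         distance=D, coords=coords_cache[key]))

    # burden control; the subsampled table depends only on (table, threshold,
    # seed) so it is computed once and shared by every triggered cell
    threshold = cfg.resolved_burden_threshold()
    subsampled_cache: tuple[MutationTable, list[str]] | None = None
    cell_tables: list[MutationTable] = []
    reports: list[ConfoundReport] = []
    passed: list[bool] = []
    burden_perm = min(int(n_perm or cfg.n_permutations), 2000)
    for mc, rep in zip(mapper_configs, reps):
        report = ConfoundReport(burden_threshold=threshold)
        _, p0 = burden_localization(rep, mutations, n_perm=burden_perm, seed=cfg.seed)
        report.burden_p_initial = p0
        table = mutations
        ok = True
        if p0 < cfg.burden_alpha:
            if subsampled_cache is None:
                subsampled_cache = subsample_hypermutators(mutations, threshold,
                                                           seed=cfg.seed)
            table, hyper = subsampled_cache
            report.hypermutated_samples = list(hyper)
            report.subsampled = True
            _, p1 = burden_localization(rep, table, n_perm=burden_perm, seed=cfg.seed)
            report.burden_p_final = p1
            if p1 < cfg.burden_alpha:
                ok = False
        else:
            report.burden_p_final = p0
        cell_tables.append(table)
        reports.append(report)
        passed.append(ok)

    if not any(passed):
        if not override_burden_exclusion:
            raise CohortExcludedError(
                "mutational burden remains localized after subsampling in every "
                "grid cell; the cohort should be excluded "
                "(pass override_burden_exclusion=True to force)"
            )
        logger.warning("burden control failed everywhere; proceeding under override")
        passed = [True] * len(passed)

    # batch control per cell
    masks: list[np.ndarray | None] = []
    for rep, report in zip(reps, reports):
        if batches is not None:
            flagged, p_by_batch = batch_control(rep, batches, n_perm=burden_perm,
                                                seed=cfg.seed, alpha=cfg.batch_alpha)
            report.batch_p = p_by_batch
            report.batches_flagged = flagged
            masks.append(batch_sample_mask(rep, batches, flagged))
        else:
            masks.append(None)

    # Jensen-Shannon anticorrelation filter across the passing cells
    active = [i for i, ok in enumerate(passed) if ok]
    js_removed: set[str] = set()
    js_table = None
    if js_filter and active and genes:
        # when any cell triggered subsampling, the subsampled table is the
        # conservative choice for the gene-level filter everywhere
        js_mut = subsampled_cache[0] if subsampled_cache is not None else mutations
        js_removed, js_table = js_permutation_filter(
            [reps[i] for i in active], expression, js_mut, genes,
            cfg, n_perm=js_n_perm, sample_masks=[masks[i] for i in active],
        )
        for i in active:
            reports[i].js_removed = {
                g: float(js_table.set_index("gene").loc[g, "median_q_anti"])
                for g in js_removed
            }
    retained = [g for g in genes if g not in js_removed]

    cells = []
    for i, (mc, rep) in enumerate(zip(mapper_configs, reps)):
        if passed[i]:
            results = localize_all(rep, cell_tables[i], retained, cfg,
                                   n_perm=n_perm, sample_mask=masks[i])
        else:
            results = pd.DataFrame(columns=["gene", "prevalence", "C", "p", "q",
                                            "significant", "n_permutations"])
        cells.append(CellResult(mc, rep, results, reports[i], passed[i]))
    return ScanResult(cells, retained, js_removed, js_table, cfg)


def aggregate_significance(scan: ScanResult, q_threshold: float | None = None) -> pd.DataFrame:
    """Per-gene median and quartiles of q across the passing cells.

    A gene absent from some passing cell (dropped there) counts as q = 1 in
    that cell. Significant means median q below the threshold.
    """
    cells = scan.passing_cells
    if not cells:
        raise ValueError("no passing cells to aggregate")
    q_threshold = q_threshold if q_threshold is not None else (
        scan.config.q_threshold if scan.config else 0.15)
    genes = scan.genes
    Q = np.ones((len(genes), len(cells)))
    Cmat = np.zeros((len(genes), len(cells)))
    gene_pos = {g: i for i, g in enumerate(genes)}
    imputed = 0
    for j, cell in enumerate(cells):
        present = set(cell.results["gene"]) if not cell.results.empty else set()
        imputed += len(genes) - len(present & set(genes))
        for _, row in cell.results.iterrows():
            i = gene_pos.get(row["gene"])
            if i is not None:
                Q[i, j] = row["q"]
                Cmat[i, j] = row["C"]
    if imputed:
        logger.info("imputed q=1 for %d (gene, cell) pairs missing from results", imputed)
    df = pd.DataFrame(
        {
            "gene": genes,
            "median_q": np.median(Q, axis=1),
            "q25": np.percentile(Q, 25, axis=1),
            "q75": np.percentile(Q, 75, axis=1),
            "median_C": np.median(Cmat, axis=1),
            "n_cells": len(cells),
        }
    )
    df["significant"] = df["median_q"] < q_threshold
    return df.sort_values(["median_q", "gene"]).reset_index(drop=True)


def select_region(scan: ScanResult, window: tuple[int, int] = (3, 3),
                  q_threshold: float | None = None) -> dict:
    """Select a contiguous resolution x gain window for the fine scan.

    Eligible windows contain only cells that passed the confound checks; the
    winner maximizes the mean count of significant genes, with ties broken
    toward smaller resolution, then smaller gain.
    """
    cells = scan.grid
    resolutions = sorted({c.config.resolution for c in cells})
    gains = sorted({c.config.gain for c in cells})
    by_key = {(c.config.resolution, c.config.gain): c for c in cells}
    wr, wg = window
    wr = min(wr, len(resolutions))
    wg = min(wg, len(gains))
    best = None
    for i in range(len(resolutions) - wr + 1):
        for j in range(len(gains) - wg + 1):
            block = []
            ok = True
            for r in resolutions[i:i + wr]:
                for g in gains[j:j + wg]:
                    cell = by_key.get((r, g))
                    if cell is None or not cell.passed:
                        ok = False
                        break
                    block.append(cell)
                if not ok:
                    break
            if not ok:
                continue
            score = float(np.mean([c.n_significant for c in block]))
            key = (-score, resolutions[i], gains[j])
            if best is None or key < best[0]:
                best = (key, {
                    "resolution_min": resolutions[i],
                    "resolution_max": resolutions[i + wr - 1],
                    "gain_min": gains[j],
                    "gain_max": gains[j + wg - 1],
                    "mean_significant": score,
                })
    if best is None:
        raise CohortExcludedError(
            "no parameter-space window passes the confound checks; "
            "the cohort should be excluded"
        )
    return best[1]


def stability_correlation(scan: ScanResult) -> tuple[np.ndarray, float]:
    """Pairwise Pearson correlation of per-gene C vectors across cells.

    Uses the genes present in every passing cell; returns the correlation
    matrix and the median off-diagonal r.
    """
    cells = scan.passing_cells
    if len(cells) < 2:
        raise ValueError("stability needs at least 2 passing cells")
    common = set(scan.genes)
    for c in cells:
        common &= set(c.results["gene"])
    common = sorted(common)
    if len(common) < 2:
        raise ValueError("fewer than 2 genes shared across cells")
    V = np.column_stack([
        c.results.set_index("gene").loc[common, "C"].to_numpy() for c in cells
    ])
    if np.any(V.std(axis=0) == 0):
        raise ValueError("a cell has a zero-variance C vector")
    R = np.corrcoef(V.T)
    off = R[np.triu_indices_from(R, k=1)]
    return R, float(np.median(off))
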