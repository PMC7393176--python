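"""Model/results interface to the integrative topological analysis.

:class:`DriverLocalization` is constructed from a cohort (expression +
somatic mutations, optional batch labels) and an :class:`AnalysisConfig`;
``fit`` runs the analysis on a single Mapper representation and returns a
:class:`DriverLocalizationResults`, while ``fit_scan`` runs the resolution x
gain scan and returns a :class:`ScanResults` with per-gene aggregated
significance. Both results objects expose a ``summary()`` table and
persistence helpers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import scan as scan_mod
from .confounds import ConfoundReport
from .io import (
    AnalysisConfig,
    ExpressionMatrix,
    MutationTable,
    align_cohort,
    filter_test_genes,
    read_batches,
    read_expression,
    read_maf,
    select_variable_genes,
)
from .mapper import MapperConfig, TopologicalRepresentation, correlation_distance, filter_embedding

logger = logging.getLogger(__name__)


class DriverLocalization:
    """Localization analysis of mutated genes in a cohort expression space.

    Parameters
    ----------
    expression:
        :class:`ExpressionMatrix` or samples x genes DataFrame on the
        transformed scale.
    mutations:
        :class:`MutationTable`.
    config:
        :class:`AnalysisConfig`; required because the prevalence threshold
        is a per-cohort choice.
    batches:
        optional Series mapping sample id to processing batch.
    """

    def __init__(self, expression, mutations: MutationTable,
                 config: AnalysisConfig, batches: pd.Series | None = None) -> None:
        if isinstance(expression, pd.DataFrame):
            expression = ExpressionMatrix(expression)
        if config is None:
            raise ValueError("an AnalysisConfig (with prevalence_min) is required")
        self.expression, self.mutations = align_cohort(expression, mutations)
        self.config = config
        self.batches = batches
        self.variable_genes = select_variable_genes(self.expression,
                                                    config.n_variable_genes)
        self.test_genes = filter_test_genes(self.mutations, config)
        self._distance: np.ndarray | None = None
        self._coords: dict[tuple, np.ndarray] = {}

    @classmethod
    def from_files(cls, expression_path, maf_path, config: AnalysisConfig,
                   batches_path=None, already_transformed: bool = False) -> "DriverLocalization":
        E = read_expression(expression_path, already_transformed=already_transformed)
        M = read_maf(maf_path)
        B = read_batches(batches_path) if batches_path else None
        return cls(E, M, config, batches=B)

    # ------------------------------------------------------------------
    @property
    def distance(self) -> np.ndarray:
        if self._distance is None:
            self._distance = correlation_distance(self.expression, self.variable_genes)
        return self._distance

    def _coords_for(self, mapper_cfg: MapperConfig) -> np.ndarray:
        key = (mapper_cfg.k_neighbors, mapper_cfg.filter_kind)
        if key not in self._coords:
            self._coords[key] = filter_embedding(self.distance, mapper_cfg,
                                                 expression=self.expression,
                                                 genes=self.variable_genes)
        return self._coords[key]

    # ------------------------------------------------------------------
    def fit(self, resolution: int = 30, gain: float = 3.5,
            filter_kind: str = "geodesic_mds", n_perm: int | None = None,
            js_n_perm: int | None = None,
            override_burden_exclusion: bool = False) -> "DriverLocalizationResults":
        """Run the analysis on one Mapper representation."""
        mc = MapperConfig(resolution=resolution, gain=gain,
                          k_neighbors=self.config.k_neighbors,
                          filter_kind=filter_kind)
        scan = self._run([mc], n_perm=n_perm, js_n_perm=js_n_perm,
                         override_burden_exclusion=override_burden_exclusion)
        cell = scan.grid[0]
        return DriverLocalizationResults(model=self, cell=cell, scan=scan)

    def fit_scan(self, resolutions=None, gains=None,
                 filter_kind: str = "geodesic_mds", n_perm: int | None = None,
                 js_n_perm: int | None = None, fine: bool = False,
                 window: tuple[int, int] = (3, 3),
                 override_burden_exclusion: bool = False) -> "ScanResults":
        """Run the coarse scan (and optionally a fine scan over the selected
        region) and aggregate per-gene significance."""
        configs = scan_mod.coarse_grid(resolutions, gains,
                                       k_neighbors=self.config.k_neighbors,
                                       filter_kind=filter_kind)
        # the JS filter medians its removal decision across the whole
        # parameter space, and region selection counts significant genes
        # net of it, so it runs on the coarse scan; the fine scan inherits
        # the retained gene set
        coarse = self._run(configs, n_perm=n_perm, js_n_perm=js_n_perm,
                           override_burden_exclusion=override_burden_exclusion)
        region = None
        result_scan = coarse
        if fine:
            region = scan_mod.select_region(coarse, window=window)
            fine_cfgs = scan_mod.fine_grid(region,
                                           k_neighbors=self.config.k_neighbors,
                                           filter_kind=filter_kind)
            result_scan = self._run(fine_cfgs, n_perm=n_perm, js_n_perm=js_n_perm,
                                    genes=coarse.genes, js_filter=False,
                                    override_burden_exclusion=override_burden_exclusion)
            result_scan.js_removed = coarse.js_removed
            result_scan.js_table = coarse.js_table
        table = scan_mod.aggregate_significance(result_scan)
        return ScanResults(model=self, coarse=coarse, scan=result_scan,
                           region=region, gene_table=table)

    def _run(self, configs, n_perm=None, js_n_perm=None, js_filter=True,
             genes=None, override_burden_exclusion=False) -> scan_mod.ScanResult:
        return scan_mod.run_scan(
            self.expression, self.mutations,
            genes if genes is not None else self.test_genes, configs,
            self.config, batches=self.batches,
            variable_genes=self.variable_genes, n_perm=n_perm,
            js_n_perm=js_n_perm, js_filter=js_filter,
            override_burden_exclusion=override_burden_exclusion,
        )


def _format_summary(title: str, info: list[tuple[str, str]],
                    table: pd.DataFrame, max_rows: int = 20) -> str:
    width = 72
    lines = [title.center(width), "=" * width]
    for k, v in info:
        lines.append(f"{k:<38}{v:>34}")
    lines.append("-" * width)
    with pd.option_context("display.width", 120, "display.max_rows", max_rows + 2):
        lines.append(table.head(max_rows).to_string(index=False,
                                                    float_format=lambda x: f"{x:.4g}"))
    lines.append("=" * width)
    return "\n".join(lines)


@dataclass
class DriverLocalizationResults:
    """Per-gene localization results on a single representation."""

    model: DriverLocalization
    cell: scan_mod.CellResult
    scan: scan_mod.ScanResult

    @property
    def table(self) -> pd.DataFrame:
        return self.cell.results

    @property
    def representation(self) -> TopologicalRepresentation:
        return self.cell.representation

    @property
    def confounds(self) -> ConfoundReport:
        return self.cell.confounds

    @property
    def significant_genes(self) -> list[str]:
        t = self.table
        if t.empty:
            return []
        sig = t[t["significant"]].sort_values(["q", "gene"])
        return list(sig["gene"])

    def summary(self) -> str:
        mc = self.cell.config
        info = [
            ("No. samples", str(self.model.expression.n_samples)),
            ("No. tested genes", str(len(self.scan.genes))),
            ("Removed by JS filter", str(len(self.scan.js_removed))),
            ("Mapper resolution / gain", f"{mc.resolution} / {mc.gain:g}"),
            ("Nodes in representation", str(self.representation.n_nodes)),
            ("Burden control p (initial/final)",
             f"{self.confounds.burden_p_initial:.3g} / {self.confounds.burden_p_final:.3g}"),
            ("Hypermutators subsampled", str(self.confounds.subsampled)),
            ("Significant genes (q < %.2f)" % self.model.config.q_threshold,
             str(self.cell.n_significant)),
        ]
        t = self.table.sort_values(["q", "gene"]) if not self.table.empty else self.table
        return _format_summary("Topological Mutation Localization", info, t)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(directory / "results.tsv", sep="\t", index=False)
        self.confounds.to_json(directory / "confounds.json")
        self.representation.write_graphml(directory / "network.graphml")
        self.representation.write_node_link_json(directory / "network.json")


@dataclass
class ScanResults:
    """Aggregated results of a resolution x gain scan."""

    model: DriverLocalization
    coarse: scan_mod.ScanResult
    scan: scan_mod.ScanResult
    region: dict | None
    gene_table: pd.DataFrame

    @property
    def significant_genes(self) -> list[str]:
        sig = self.gene_table[self.gene_table["significant"]]
        return list(sig["gene"])

    def stability(self) -> float:
        _, med = scan_mod.stability_correlation(self.scan)
        return med

    def select_region(self, window: tuple[int, int] = (3, 3)) -> dict:
        return scan_mod.select_region(self.coarse, window=window)

    def summary(self) -> str:
        info = [
            ("No. samples", str(self.model.expression.n_samples)),
            ("No. tested genes", str(len(self.scan.genes))),
            ("Removed by JS filter", str(len(self.scan.js_removed))),
            ("Grid cells (passing/total)",
             f"{len(self.scan.passing_cells)} / {len(self.scan.grid)}"),
            ("Fine-scan region", str(self.region) if self.region else "-"),
            ("Significant genes (median q < %.2f)" % self.model.config.q_threshold,
             str(len(self.significant_genes))),
        ]
        return _format_summary("Topological Mutation Localization - Parameter Scan",
                               info, self.gene_table)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.gene_table.to_csv(directory / "scan_summary.tsv", sep="\t", index=False)
        if self.scan.js_table is not None:
            self.scan.js_table.to_csv(directory / "js_filter.tsv", sep="\t", index=False)
        for i, cell in enumerate(self.scan.grid):
            cell.confounds.to_json(directory / f"confounds_cell{i:03d}.json")
        cells = pd.DataFrame(
            [
                {
                    "resolution": c.config.resolution,
                    "gain": c.config.gain,
                    "passed": c.passed,
                    "n_nodes": c.representation.n_nodes,
                    "n_significant": c.n_significant,
                }
                for c in self.scan.grid
            ]
        )
        cells.to_csv(directory / "cells.tsv", sep="\t", index=False)
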