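"""Synthetic tumor cohorts with known ground truth.

The generator emulates the statistical structure the method relies on:
expression profiles clustered into molecular subtypes (Gaussian noise around
subtype mean vectors on the transformed log scale); driver mutations
concentrated within a subtype at low cohort prevalence (1-15%); passenger
mutations scattered uniformly (with a silent fraction, so the
nonsynonymous/total ratio filter has something to rank); a few hypermutated
samples with multiplied passenger rates, optionally confined to one subtype;
genes whose mutation probability is coupled - positively or negatively - to
their own expression, emulating e.g. transcription-coupled repair; and batch
labels, random or aligned with a subtype. Everything is reproducible from
the mandatory seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, MutationTable

_MISSENSE = "Missense_Mutation"
_SILENT = "Silent"


@dataclass
class CohortConfig:
    """Parameters of a synthetic cohort. ``seed`` is mandatory."""

    seed: int
    n_samples: int = 300
    n_genes: int = 1000
    n_subtypes: int = 3
    subtype_separation: float = 3.0   # between-cluster mean shift, in noise s.d.
    marker_fraction: float = 0.10     # fraction of genes shifted per subtype
    noise_sd: float = 1.0
    n_drivers: int = 5
    driver_prevalence: tuple[float, float] = (0.03, 0.15)
    driver_subtypes: tuple[int, ...] | None = None  # default: round robin
    driver_cis_shift: float = 2.0  # expression change of the mutated gene in
    # its carriers (in noise s.d.); driver mutations being accompanied by
    # expression changes is the premise of expression-based driver discovery
    n_passengers: int = 200
    passenger_rate: float = 8.0       # expected passenger mutations per sample
    silent_fraction: float = 0.30
    n_hypermutators: int = 2
    hypermutator_burden_multiplier: float = 50.0
    hypermutator_placement: str = "clustered"  # or "random"
    hypermutator_signature_genes: int = 200  # hypermutated tumors carry a
    # broad expression phenotype (MSI/POLE-like); the signature is what
    # makes their excess passenger load localize in expression space, so
    # the burden control can detect and correct it
    n_coupled: int = 0
    coupling_sign: int = -1           # -1 mutation rate anticorrelated with expression
    coupling_strength: float = 3.0
    coupled_prevalence: float = 0.05
    batch_structure: str | None = None  # None | "random" | "cluster_aligned"
    n_batches: int = 2

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_samples", "n_genes", "n_subtypes"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.driver_prevalence
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("driver_prevalence bounds must satisfy 0 < lo <= hi < 1")
        if self.driver_subtypes is not None:
            if any(t < 0 or t >= self.n_subtypes for t in self.driver_subtypes):
                raise ValueError("driver_subtypes out of range")
            if len(self.driver_subtypes) != self.n_drivers:
                raise ValueError("driver_subtypes length must equal n_drivers")
        if self.hypermutator_placement not in ("clustered", "random"):
            raise ValueError("hypermutator_placement must be 'clustered' or 'random'")
        if self.coupling_sign not in (-1, 1):
            raise ValueError("coupling_sign must be -1 or +1")
        n_mutated = self.n_drivers + self.n_passengers + self.n_coupled
        if n_mutated > self.n_genes:
            raise ValueError("drivers + passengers + coupled genes exceed n_genes")
        if not (0.0 < self.coupled_prevalence < 1.0):
            raise ValueError("coupled_prevalence must be in (0, 1)")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort."""

    drivers: dict[str, int]            # gene -> subtype
    passengers: list[str]
    coupled: list[str]
    hypermutators: list[str]
    subtype_of: dict[str, int]         # sample -> subtype
    batch_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.drivers) & set(self.passengers):
            raise ValueError("driver and passenger gene sets must be disjoint")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _gene_names(cfg: CohortConfig) -> tuple[list[str], list[str], list[str], list[str]]:
    drivers = [f"DRV{i + 1:02d}" for i in range(cfg.n_drivers)]
    passengers = [f"PSG{i + 1:03d}" for i in range(cfg.n_passengers)]
    coupled = [f"CPL{i + 1:02d}" for i in range(cfg.n_coupled)]
    n_rest = cfg.n_genes - len(drivers) - len(passengers) - len(coupled)
    rest = [f"GEN{i + 1:04d}" for i in range(n_rest)]
    return drivers, passengers, coupled, rest


def simulate_cohort(cfg: CohortConfig) -> tuple[ExpressionMatrix, MutationTable, SyntheticTruth]:
    """Generate (expression, mutations, truth) for the configured cohort.

    Expression is on the transformed (log2) scale, clipped at zero. Driver
    genes are mutated nonsynonymously in samples drawn from their assigned
    subtype; passengers fall uniformly; coupled genes are mutated in samples
    chosen with probability exponential in (sign x strength x z-scored own
    expression). Identical configs produce byte-identical outputs.
    """
    rng = np.random.default_rng(cfg.seed)
    drivers, passengers, coupled, rest = _gene_names(cfg)
    genes = drivers + passengers + coupled + rest
    samples = [f"S{i + 1:04d}" for i in range(cfg.n_samples)]

    # subtype assignment: contiguous, near-equal blocks
    sizes = np.full(cfg.n_subtypes, cfg.n_samples // cfg.n_subtypes)
    sizes[: cfg.n_samples % cfg.n_subtypes] += 1
    subtype = np.repeat(np.arange(cfg.n_subtypes), sizes)

    # expression: gene baselines + per-subtype marker shifts + noise
    base = rng.uniform(2.0, 10.0, size=cfg.n_genes)
    means = np.tile(base, (cfg.n_subtypes, 1))
    n_markers = max(1, int(round(cfg.marker_fraction * cfg.n_genes)))
    # subtype markers come from the unmutated filler genes, so the mutated
    # test genes carry only their designed expression couplings
    n_mutated = len(drivers) + len(passengers) + len(coupled)
    filler_idx = np.arange(n_mutated, cfg.n_genes)
    if filler_idx.size < cfg.n_subtypes * n_markers:
        raise ValueError(
            "not enough unmutated genes to carry the subtype markers; "
            "increase n_genes or reduce marker_fraction"
        )
    marker_pool = rng.permutation(filler_idx)
    for t in range(cfg.n_subtypes):
        markers = marker_pool[t * n_markers:(t + 1) * n_markers]
        means[t, markers] += cfg.subtype_separation * cfg.noise_sd
    # coupled genes must vary across the cohort structure for the coupling
    # to act at network scale: give each one a subtype-marker shift
    gene_index = {g: i for i, g in enumerate(genes)}
    for j, g in enumerate(coupled):
        t = j % cfg.n_subtypes
        means[t, gene_index[g]] += cfg.subtype_separation * cfg.noise_sd
    X = means[subtype] + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_samples, cfg.n_genes))

    # hypermutators (drawn before their expression signature is applied)
    if cfg.n_hypermutators > 0:
        pool = (np.flatnonzero(subtype == 0) if cfg.hypermutator_placement == "clustered"
                else np.arange(cfg.n_samples))
        hyper_idx = rng.choice(pool, size=min(cfg.n_hypermutators, pool.size),
                               replace=False)
        if cfg.hypermutator_signature_genes > 0:
            sig = rng.choice(cfg.n_genes, size=min(cfg.hypermutator_signature_genes,
                                                   cfg.n_genes), replace=False)
            X[np.ix_(hyper_idx, sig)] += cfg.subtype_separation * cfg.noise_sd
    else:
        hyper_idx = np.array([], dtype=int)
    hyper_set = set(hyper_idx.tolist())

    records: list[tuple[str, str, str, bool]] = []

    # drivers: nonsynonymous, confined to the assigned subtype, with a cis
    # expression effect of the mutation on the mutated gene itself
    driver_subtypes = (list(cfg.driver_subtypes) if cfg.driver_subtypes is not None
                       else [i % cfg.n_subtypes for i in range(cfg.n_drivers)])
    truth_drivers = {}
    for g, t in zip(drivers, driver_subtypes):
        members = np.flatnonzero(subtype == t)
        prev = rng.uniform(*cfg.driver_prevalence)
        n_mut = min(members.size, max(1, int(round(prev * cfg.n_samples))))
        chosen = rng.choice(members, size=n_mut, replace=False)
        for s in chosen:
            records.append((samples[s], g, _MISSENSE, True))
        X[chosen, gene_index[g]] += cfg.driver_cis_shift * cfg.noise_sd
        truth_drivers[g] = t

    X = np.clip(X, 0.0, None)
    expression = ExpressionMatrix(pd.DataFrame(X, index=samples, columns=genes))

    # passengers: uniform scatter, Poisson counts per sample
    if cfg.n_passengers > 0:
        for s in range(cfg.n_samples):
            rate = cfg.passenger_rate * (cfg.hypermutator_burden_multiplier
                                         if s in hyper_set else 1.0)
            n_ev = rng.poisson(rate)
            if n_ev == 0:
                continue
            gs = rng.integers(0, cfg.n_passengers, size=n_ev)
            silent = rng.random(n_ev) < cfg.silent_fraction
            for gi, sil in zip(gs, silent):
                records.append((samples[s], passengers[gi],
                                _SILENT if sil else _MISSENSE, not sil))

    # expression-coupled genes
    for g in coupled:
        expr = X[:, gene_index[g]]
        z = (expr - expr.mean()) / (expr.std() + 1e-12)
        w = np.exp(cfg.coupling_sign * cfg.coupling_strength * z)
        w /= w.sum()
        n_mut = max(1, int(round(cfg.coupled_prevalence * cfg.n_samples)))
        chosen = rng.choice(cfg.n_samples, size=n_mut, replace=False, p=w)
        for s in chosen:
            records.append((samples[s], g, _MISSENSE, True))

    rec = pd.DataFrame(records, columns=["sample_id", "gene_id", "variant_class",
                                         "is_nonsynonymous"])
    mutations = MutationTable(rec, samples)

    # batches
    batch_of: dict[str, str] = {}
    if cfg.batch_structure == "random":
        assign = rng.integers(0, cfg.n_batches, size=cfg.n_samples)
        batch_of = {samples[i]: f"B{assign[i] + 1}" for i in range(cfg.n_samples)}
    elif cfg.batch_structure == "cluster_aligned":
        batch_of = {samples[i]: ("B1" if subtype[i] == 0 else "B2")
                    for i in range(cfg.n_samples)}
    elif cfg.batch_structure is not None:
        raise ValueError(f"unknown batch_structure {cfg.batch_structure!r}")

    truth = SyntheticTruth(
        drivers=truth_drivers,
        passengers=list(passengers),
        coupled=list(coupled),
        hypermutators=[samples[i] for i in sorted(hyper_set)],
        subtype_of={samples[i]: int(subtype[i]) for i in range(cfg.n_samples)},
        batch_of=batch_of,
    )
    return expression, mutations, truth


def write_fixture(directory, expression: ExpressionMatrix,
                  mutations: MutationTable, truth: SyntheticTruth) -> dict[str, Path]:
    """Write a cohort in the exact dialects the readers consume.

    Emits expression.tsv (genes in rows, already-transformed values),
    mutations.maf, truth.json and, when batches exist, batches.tsv. Returns
    the paths keyed by kind.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expression.tsv",
        "maf": directory / "mutations.maf",
        "truth": directory / "truth.json",
    }
    expression.write_tsv(paths["expression"])
    mutations.write_maf(paths["maf"])
    truth.to_json(paths["truth"])
    if truth.batch_of:
        paths["batches"] = directory / "batches.tsv"
        pd.DataFrame(
            {"sample_id": list(truth.batch_of), "batch": list(truth.batch_of.values())}
        ).to_csv(paths["batches"], sep="\t", index=False)
    return paths
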