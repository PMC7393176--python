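"""Localization of node features on the topological representation.

The statistic is

    C = N/(N-1) * sum_{i,j} e_i A_ij e_j / (sum_k e_k)^2

over the N nodes of the representation, where e_i is a nonnegative feature
of node i (for a mutated gene, the fraction of member samples carrying at
least one nonsynonymous mutation in it) and A the binary, zero-diagonal
adjacency. The double sum runs over ordered node pairs, so each undirected
edge contributes twice; C is invariant under rescaling of e. Significance
comes from a permutation null: the per-sample labels of the feature are
shuffled while the representation stays fixed, and the add-one estimate
p = (1 + #{C_perm >= C_obs}) / (1 + n_perm) is adjusted across the tested
genes with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import AnalysisConfig, MutationTable
from .mapper import TopologicalRepresentation

logger = logging.getLogger(__name__)

#: relative tolerance when counting null scores at least as large as the
#: observed one, so permutation-invariant (constant) features give p = 1
#: despite float summation-order noise.
_TIE_RTOL = 1e-9


@dataclass
class NodeFeature:
    """A nonnegative per-node feature e_i and the kind of signal it carries."""

    values: np.ndarray
    kind: str = "binary_mutation_fraction"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("node feature values must be nonnegative")


def localization_score(representation, feature) -> float:
    """Evaluate the localization score C literally.

    Accepts a :class:`TopologicalRepresentation` or a raw adjacency matrix,
    and a :class:`NodeFeature` or array. The implementation is the
    definitional ordered double loop; the vectorized engine used inside the
    permutation test is validated against it.
    """
    A = representation.adjacency if isinstance(representation, TopologicalRepresentation) else np.asarray(representation)
    e = feature.values if isinstance(feature, NodeFeature) else np.asarray(feature, dtype=float)
    N = e.shape[0]
    if N < 2:
        raise ValueError("localization score needs at least 2 nodes")
    if A.shape != (N, N):
        raise ValueError("feature length does not match the adjacency")
    if np.any(e < 0):
        raise ValueError("feature values must be nonnegative")
    total = e.sum()
    if total <= 0:
        raise ValueError("feature is identically zero; the score is undefined")
    num = 0.0
    for i in range(N):
        ei = e[i]
        if ei == 0.0:
            continue  # zero terms cannot move the accumulator
        row = A[i]
        for j in range(N):
            if row[j]:
                num += ei * e[j]
    return (N / (N - 1.0)) * num / (total * total)


def gene_seed(base_seed: int, gene_id: str) -> int:
    """Deterministic per-gene sub-seed, independent of gene order."""
    return (int(base_seed) * 1_000_003 + zlib.crc32(gene_id.encode())) % (2**31 - 1)


class LocalizationEngine:
    """Vectorized scoring and permutation machinery for one representation.

    Precomputes the sample-level quadratic form M = W^T A W (W the
    row-normalized membership matrix restricted to the kept samples), so a
    permutation of a binary feature reduces to summing an index submatrix of
    M. ``sample_mask`` (boolean over the representation's samples) excludes
    samples - e.g. members of localized batches - from all feature
    statistics; node membership itself is never altered.
    """

    def __init__(self, representation: TopologicalRepresentation,
                 sample_mask: np.ndarray | None = None) -> None:
        self.representation = representation
        B = representation.membership
        n_samples = B.shape[1]
        if sample_mask is None:
            sample_mask = np.ones(n_samples, dtype=bool)
        sample_mask = np.asarray(sample_mask, dtype=bool)
        self.kept = np.flatnonzero(sample_mask)
        if self.kept.size < 2:
            raise ValueError("fewer than 2 samples retained for localization")
        Bk = B[:, self.kept].astype(float)
        sizes = Bk.sum(axis=1)
        W = np.divide(Bk, sizes[:, None], out=np.zeros_like(Bk), where=sizes[:, None] > 0)
        A = representation.adjacency.astype(float)
        self.W = W
        self.M = W.T @ (A @ W)
        self.w = W.sum(axis=0)  # per-sample total node weight
        self.N = representation.n_nodes
        self.sample_index = {s: i for i, s in enumerate(representation.sample_ids)}

    def restrict(self, values_by_sample: np.ndarray) -> np.ndarray:
        """Project a per-sample vector (over representation.sample_ids) onto
        the kept samples."""
        return np.asarray(values_by_sample, dtype=float)[self.kept]

    def node_profile(self, v_kept: np.ndarray) -> np.ndarray:
        """e_i = mean of the sample values over each node's kept members."""
        return self.W @ np.asarray(v_kept, dtype=float)

    def score(self, v_kept: np.ndarray) -> float:
        v = np.asarray(v_kept, dtype=float)
        den = float(self.w @ v)
        if den <= 0:
            raise ValueError("feature is identically zero on the kept samples")
        num = float(v @ (self.M @ v))
        return (self.N / (self.N - 1.0)) * num / (den * den)

    def _pvalue(self, c_obs: float, c_perm: np.ndarray) -> float:
        thr = c_obs - _TIE_RTOL * max(1.0, abs(c_obs))
        n_perm = c_perm.shape[0]
        return (1.0 + float(np.sum(c_perm >= thr))) / (1.0 + n_perm)

    def perm_pvalue_binary(self, v_kept: np.ndarray, n_perm: int, seed: int) -> tuple[float, float]:
        """(C_obs, p) for a 0/1 feature; permutations are uniform random
        subsets of the kept samples of the same size."""
        v = np.asarray(v_kept, dtype=float)
        k = int(v.sum())
        if k == 0:
            raise ValueError("feature is identically zero on the kept samples")
        c_obs = self.score(v)
        n = v.shape[0]
        if k == n:
            return c_obs, 1.0
        rng = np.random.default_rng(seed)
        idx = np.argpartition(rng.random((n_perm, n)), k - 1, axis=1)[:, :k]
        num = self.M[idx[:, :, None], idx[:, None, :]].sum(axis=(1, 2))
        den = self.w[idx].sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            c_perm = np.where(den > 0, (self.N / (self.N - 1.0)) * num / den**2, 0.0)
        return c_obs, self._pvalue(c_obs, c_perm)

    def perm_pvalue_general(self, v_kept: np.ndarray, n_perm: int, seed: int) -> tuple[float, float]:
        """(C_obs, p) for an arbitrary nonnegative feature; permutations
        shuffle the sample values over the kept samples."""
        v = np.asarray(v_kept, dtype=float)
        if v.sum() <= 0:
            raise ValueError("feature is identically zero on the kept samples")
        c_obs = self.score(v)
        n = v.shape[0]
        rng = np.random.default_rng(seed)
        perm = np.argsort(rng.random((n_perm, n)), axis=1)
        V = v[perm]  # n_perm x n
        num = np.einsum("ps,ps->p", V @ self.M, V)
        den = V @ self.w
        with np.errstate(divide="ignore", invalid="ignore"):
            c_perm = np.where(den > 0, (self.N / (self.N - 1.0)) * num / den**2, 0.0)
        return c_obs, self._pvalue(c_obs, c_perm)


def mutation_node_profile(representation: TopologicalRepresentation,
                          mutations: MutationTable, gene: str) -> NodeFeature:
    """Per-node fraction of member samples with >=1 nonsynonymous mutation
    in ``gene``. Samples appearing in several nodes contribute to each."""
    if gene not in set(mutations.records["gene_id"]):
        raise ValueError(f"gene {gene!r} not present in the mutation table")
    ind = mutations.nonsyn_indicator([gene], representation.sample_ids)[gene]
    engine = LocalizationEngine(representation)
    return NodeFeature(engine.node_profile(ind.to_numpy(dtype=float)),
                       kind="binary_mutation_fraction")


def permutation_pvalue(representation: TopologicalRepresentation,
                       values_by_sample: np.ndarray, n_perm: int, seed: int,
                       binary: bool | None = None,
                       sample_mask: np.ndarray | None = None) -> tuple[float, float]:
    """Permutation test of a per-sample feature's localization.

    Returns (C_obs, p). ``binary=None`` autodetects 0/1 vectors, which use
    the faster subset formulation; both paths compute the identical
    statistic.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    engine = LocalizationEngine(representation, sample_mask)
    v = engine.restrict(values_by_sample)
    if binary is None:
        binary = bool(np.isin(v, (0.0, 1.0)).all())
    if binary:
        return engine.perm_pvalue_binary(v, n_perm, seed)
    return engine.perm_pvalue_general(v, n_perm, seed)


def bh_qvalues(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def localize_all(representation: TopologicalRepresentation,
                 mutations: MutationTable, genes, cfg: AnalysisConfig,
                 n_perm: int | None = None,
                 sample_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Score, permutation p and BH q for every tested gene on one
    representation.

    q-values are computed over exactly the supplied gene set. Genes with no
    nonsynonymous mutation among the kept samples (possible after burden
    subsampling or batch exclusion) are dropped with a logged warning.
    """
    genes = list(genes)
    n_perm = int(n_perm if n_perm is not None else cfg.n_permutations)
    if not genes:
        return pd.DataFrame(columns=["gene", "prevalence", "C", "p", "q",
                                     "significant", "n_permutations"])
    engine = LocalizationEngine(representation, sample_mask)
    ind = mutations.nonsyn_indicator(genes, representation.sample_ids)
    prev = mutations.prevalence(genes)
    rows = []
    dropped = []
    for g in genes:
        v = engine.restrict(ind[g].to_numpy(dtype=float))
        if v.sum() == 0:
            dropped.append(g)
            continue
        c_obs, p = engine.perm_pvalue_binary(v, n_perm, gene_seed(cfg.seed, g))
        rows.append((g, float(prev[g]), c_obs, p))
    if dropped:
        logger.warning("dropped %d gene(s) with no mutations among kept samples", len(dropped))
    if not rows:
        return pd.DataFrame(columns=["gene", "prevalence", "C", "p", "q",
                                     "significant", "n_permutations"])
    df = pd.DataFrame(rows, columns=["gene", "prevalence", "C", "p"])
    df["q"] = bh_qvalues(df["p"].to_numpy())
    df["significant"] = df["q"] < cfg.q_threshold
    df["n_permutations"] = n_perm
    return df
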