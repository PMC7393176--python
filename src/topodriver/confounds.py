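"""Controls for spurious mutation-expression associations.

Three effects can make a passenger gene look localized in expression space:

1. Globally hypermutated tumors with a distinctive expression signature
   concentrate passengers in one region. Detected by scoring the
   localization of the mutational burden (total mutation count, all variant
   classes) itself; if significant, hypermutated tumors are subsampled until
   their median burden matches that of the rest of the cohort, and a cohort
   that stays significant after subsampling is excluded.
2. Per-gene coupling between expression and mutation rate (e.g.
   transcription-coupled repair) produces network-scale anticorrelation
   between a gene's expression and mutation profiles. Detected by a
   permutation test of the Jensen-Shannon divergence between the two
   normalized node profiles.
3. Batch effects from mutation calling centers. Detected by scoring the
   localization of each batch's membership fraction; samples from localized
   batches are excluded from the mutation-side statistics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .io import AnalysisConfig, ExpressionMatrix, MutationTable
from .localization import LocalizationEngine, bh_qvalues, gene_seed, permutation_pvalue
from .mapper import TopologicalRepresentation

logger = logging.getLogger(__name__)


class CohortExcludedError(RuntimeError):
    """Mutational burden stayed localized after subsampling; gene-level
    results would be unreliable for this cohort."""


@dataclass
class ConfoundReport:
    """Summary of the confound controls applied to one analysis."""

    burden_p_initial: float | None = None
    burden_p_final: float | None = None
    burden_threshold: float | None = None
    hypermutated_samples: list[str] = field(default_factory=list)
    subsampled: bool = False
    js_removed: dict[str, float] = field(default_factory=dict)  # gene -> median q
    batch_p: dict[str, float] = field(default_factory=dict)
    batches_flagged: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def burden_localization(representation: TopologicalRepresentation,
                        mutations: MutationTable, n_perm: int = 1000,
                        seed: int = 0) -> tuple[float, float]:
    """(C, p) for the localization of the mutational tumor burden.

    The node feature is the mean total mutation count - all variant classes,
    not only nonsynonymous - over each node's members.
    """
    burdens = mutations.burdens().reindex(representation.sample_ids).to_numpy(dtype=float)
    return permutation_pvalue(representation, burdens, n_perm=n_perm, seed=seed,
                              binary=False)


def subsample_hypermutators(mutations: MutationTable, threshold: float,
                            seed: int = 0) -> tuple[MutationTable, list[str]]:
    """Downsample each hypermutated sample's records to the median burden of
    the nonhypermutated samples.

    Hypermutated means burden > ``threshold``. Records of other samples are
    untouched; the subsample is drawn without replacement and is fully
    determined by ``seed``. Returns the new table and the hypermutated
    sample ids.

    When the nonhypermutated median is a half-integer, per-sample targets
    alternate between its floor and ceiling so the hypermutated median can
    match it exactly; with an odd number of hypermutated samples that
    median is necessarily an integer and may sit half a mutation away
    (logged).
    """
    burdens = mutations.burdens()
    hyper = sorted(burdens.index[burdens > threshold])
    if not hyper:
        return mutations, []
    nonhyper = burdens.drop(hyper)
    if nonhyper.empty:
        raise ValueError("no nonhypermutated samples below the burden threshold")
    med = float(nonhyper.median())
    lo, hi = int(np.floor(med)), int(np.ceil(med))
    # split low/high targets evenly so the median of the targets equals med
    targets = [lo if i < (len(hyper) + 1) // 2 else hi
               for i in range(len(hyper))]
    rng = np.random.default_rng(seed)
    rec = mutations.records
    keep_idx = list(rec.index[~rec["sample_id"].isin(hyper)])
    for s, target in zip(hyper, targets):
        idx = rec.index[rec["sample_id"] == s].to_numpy()
        if idx.size > target:
            idx = rng.choice(idx, size=target, replace=False)
        keep_idx.extend(idx.tolist())
    out = MutationTable(rec.loc[sorted(keep_idx)].copy(), list(mutations.sample_universe))
    new_burdens = out.burdens()
    med_h = float(new_burdens[hyper].median())
    med_n = float(new_burdens.drop(hyper).median())
    if med_h != med_n:
        logger.warning(
            "post-subsampling medians differ (hyper %.1f vs nonhyper %.1f); "
            "some hypermutated samples had fewer than the target records",
            med_h, med_n,
        )
    return out, hyper


def normalize_profiles(e_raw: np.ndarray, r_raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalize two nonnegative node profiles to sum to one."""
    e = np.asarray(e_raw, dtype=float)
    r = np.asarray(r_raw, dtype=float)
    if e.shape != r.shape:
        raise ValueError("profiles must have the same length")
    if np.any(e < 0) or np.any(r < 0):
        raise ValueError("profiles must be nonnegative")
    se, sr = e.sum(), r.sum()
    if se <= 0 or sr <= 0:
        raise ValueError("cannot normalize an identically-zero profile")
    return e / se, r / sr


def _xlogx(a: np.ndarray) -> np.ndarray:
    out = np.zeros_like(a)
    pos = a > 0
    out[pos] = a[pos] * np.log(a[pos])
    return out


def js_divergence(e_tilde: np.ndarray, r_tilde: np.ndarray) -> float:
    """Jensen-Shannon divergence between two normalized node profiles.

    Natural log; 0*log 0 = 0; symmetric; bounded by log 2, reached at
    disjoint supports. Inputs must each sum to 1 within 1e-9.
    """
    e = np.asarray(e_tilde, dtype=float)
    r = np.asarray(r_tilde, dtype=float)
    if e.shape != r.shape:
        raise ValueError("profiles must have the same length")
    if abs(e.sum() - 1.0) > 1e-9 or abs(r.sum() - 1.0) > 1e-9:
        raise ValueError("profiles must each sum to 1 (use normalize_profiles)")
    m = e + r
    val = 0.5 * float(np.sum(-_xlogx(m) + m * np.log(2.0) + _xlogx(e) + _xlogx(r)))
    return max(val, 0.0)


def _js_columns(E_cols: np.ndarray, r_tilde: np.ndarray) -> np.ndarray:
    """JS divergence of each column of ``E_cols`` (already normalized)
    against the fixed profile ``r_tilde``."""
    R = r_tilde[:, None]
    m = E_cols + R
    with np.errstate(divide="ignore", invalid="ignore"):
        term_m = np.where(m > 0, m * np.log(m), 0.0)
        term_e = np.where(E_cols > 0, E_cols * np.log(E_cols), 0.0)
    term_r = _xlogx(r_tilde)[:, None]
    vals = 0.5 * np.sum(-term_m + m * np.log(2.0) + term_e + term_r, axis=0)
    return np.clip(vals, 0.0, None)


def js_permutation_filter(representations, expression: ExpressionMatrix,
                          mutations: MutationTable, genes: Sequence[str],
                          cfg: AnalysisConfig, n_perm: int | None = None,
                          sample_masks=None) -> tuple[set[str], pd.DataFrame]:
    """Flag genes whose mutation profile anticorrelates with their own
    expression profile across the network.

    Per representation and gene, the mutation profile (fraction of member
    samples mutated) and expression profile (mean expression of the gene
    over member samples) are normalized to sum to one and their JS
    divergence J is compared with ``n_perm`` permutations of the sample
    labels of the mutation data. The lower-tail estimate
    p = (1 + #{J_perm < J_obs})/(1 + n_perm) is small for correlated genes
    and large for anticorrelated ones.

    Node expression is averaged on the abundance scale (the transformed
    values are inverted through x = 2**r - 1): on the log scale per-node
    mean expression is nearly flat for every gene, and a profile that
    cannot vary cannot register as aligned or misaligned with the mutation
    profile.

    Two removal modes (``cfg.js_mode``):

    - ``anticorrelation`` (default): the upper tail is tested directly,
      p_anti = (1 + #{J_perm >= J_obs})/(1 + n_perm), BH-adjusted across the
      tested genes within each representation; a gene is removed when its
      median adjusted value across representations falls below
      1 - cfg.js_removal_q AND the median Pearson correlation between its
      mutation profile and its log-scale expression profile is negative.
      The sign guard is needed because J is an unsigned divergence: a
      strongly localized gene's mutation profile is spikier than any
      permuted scattering, so its J lands in the upper tail regardless of
      how its expression covaries, and without the guard the filter would
      strip genuine drivers, whose profile alignment is positive. The
      guard uses the log scale because expression effects of mutations are
      additive there, so the alignment signal does not depend on the
      gene's baseline abundance.
    - ``literal``: BH-adjust the lower-tail p and remove when the median
      adjusted value exceeds cfg.js_removal_q, with no sign guard. Under a
      complete null, BH adjustment pushes most values toward 1, so this
      mode removes a large fraction of neutral genes; it is kept for
      comparability only.

    Genes whose mutation or expression profile cannot be normalized are
    skipped (never removed). Returns (removed genes, per-gene table).
    """
    if not isinstance(representations, (list, tuple)):
        representations = [representations]
    genes = list(genes)
    n_perm = int(n_perm if n_perm is not None else cfg.js_n_permutations)
    if sample_masks is None:
        sample_masks = [None] * len(representations)
    per_rep_q_corr: list[pd.Series] = []
    per_rep_q_anti: list[pd.Series] = []
    per_rep_corr: list[pd.Series] = []
    for rep, mask in zip(representations, sample_masks):
        engine = LocalizationEngine(rep, mask)
        ind = mutations.nonsyn_indicator(genes, rep.sample_ids)
        expr = expression.data.reindex(index=rep.sample_ids)
        p_corr, p_anti, corrs, tested = [], [], [], []
        for g in genes:
            v = engine.restrict(ind[g].to_numpy(dtype=float))
            k = int(v.sum())
            if k == 0:
                continue
            x_log = expr[g].to_numpy(dtype=float)
            x_lin = np.exp2(x_log) - 1.0  # abundance scale
            r_raw = engine.node_profile(engine.restrict(x_lin))
            r_log = engine.node_profile(engine.restrict(x_log))
            e_raw = engine.node_profile(v)
            if r_raw.sum() <= 0 or e_raw.sum() <= 0:
                continue
            r_t = r_raw / r_raw.sum()
            e_t = e_raw / e_raw.sum()
            j_obs = js_divergence(e_t, r_t)
            rng = np.random.default_rng(gene_seed(cfg.seed + 77, g))
            n = v.shape[0]
            # permute the sample labels of the mutation data, as in the
            # localization test
            idx = np.argpartition(rng.random((n_perm, n)), k - 1, axis=1)[:, :k]
            # node profiles of each permuted subset, chunked to bound memory
            n_nodes = engine.W.shape[0]
            chunk = max(1, int(2e7) // max(1, n_nodes * k))
            j_parts = []
            for start in range(0, n_perm, chunk):
                sub = idx[start:start + chunk]
                E = engine.W[:, sub].sum(axis=2)  # nodes x chunk
                col = E.sum(axis=0)
                E = np.divide(E, col[None, :], out=np.zeros_like(E),
                              where=col[None, :] > 0)
                j_parts.append(_js_columns(E, r_t))
            j_perm = np.concatenate(j_parts)
            tol = 1e-12
            n_less = int(np.sum(j_perm < j_obs - tol))
            p_corr.append((1.0 + n_less) / (1.0 + n_perm))
            p_anti.append((1.0 + (n_perm - n_less)) / (1.0 + n_perm))
            if e_t.std() > 0 and r_log.std() > 0:
                corrs.append(float(np.corrcoef(e_t, r_log)[0, 1]))
            else:
                corrs.append(0.0)
            tested.append(g)
        if tested:
            per_rep_q_corr.append(pd.Series(bh_qvalues(p_corr), index=tested))
            per_rep_q_anti.append(pd.Series(bh_qvalues(p_anti), index=tested))
            per_rep_corr.append(pd.Series(corrs, index=tested))
    if not per_rep_q_corr:
        return set(), pd.DataFrame(columns=["gene", "median_q_corr", "median_q_anti",
                                            "median_profile_corr", "removed"])
    q_corr = pd.concat(per_rep_q_corr, axis=1).median(axis=1)
    q_anti = pd.concat(per_rep_q_anti, axis=1).median(axis=1)
    corr = pd.concat(per_rep_corr, axis=1).median(axis=1)
    if cfg.js_mode == "literal":
        removed = set(q_corr.index[q_corr > cfg.js_removal_q])
    else:
        removed = set(q_anti.index[(q_anti < 1.0 - cfg.js_removal_q) & (corr < 0)])
    table = pd.DataFrame(
        {
            "gene": q_corr.index,
            "median_q_corr": q_corr.values,
            "median_q_anti": q_anti.values,
            "median_profile_corr": corr.values,
            "removed": [g in removed for g in q_corr.index],
        }
    ).reset_index(drop=True)
    return removed, table


def batch_control(representation: TopologicalRepresentation,
                  batch_labels: pd.Series, n_perm: int = 1000, seed: int = 0,
                  alpha: float = 0.05) -> tuple[list[str], dict[str, float]]:
    """Flag batches that localize on the representation.

    The feature for a batch is the fraction of each node's members processed
    by it. Samples without a label get their own singleton batch (logged).
    Returns (flagged batches, p per batch); a batch covering the whole
    cohort is permutation-invariant and can never be flagged.
    """
    labels = batch_labels.reindex(representation.sample_ids)
    unlabeled = labels.index[labels.isna()]
    if len(unlabeled):
        logger.warning("%d sample(s) missing a batch label; assigning singleton batches",
                       len(unlabeled))
        labels = labels.copy()
        for s in unlabeled:
            labels[s] = f"_singleton_{s}"
    flagged, p_by_batch = [], {}
    for batch in sorted(labels.unique()):
        v = (labels == batch).to_numpy(dtype=float)
        _, p = permutation_pvalue(representation, v, n_perm=n_perm,
                                  seed=gene_seed(seed + 131, str(batch)), binary=True)
        p_by_batch[str(batch)] = p
        if p < alpha:
            flagged.append(str(batch))
    return flagged, p_by_batch


def batch_sample_mask(representation: TopologicalRepresentation,
                      batch_labels: pd.Series | None,
                      flagged: Sequence[str]) -> np.ndarray | None:
    """Boolean keep-mask over the representation's samples excluding flagged
    batches; None when nothing is excluded."""
    if batch_labels is None or not flagged:
        return None
    labels = batch_labels.reindex(representation.sample_ids)
    mask = ~labels.isin(set(flagged)).to_numpy()
    if not mask.any():
        raise ValueError("all samples belong to flagged batches")
    return mask
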