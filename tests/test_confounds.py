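import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import jensenshannon

from topodriver import (
    AnalysisConfig,
    MutationTable,
    batch_control,
    burden_localization,
    js_divergence,
    js_permutation_filter,
    normalize_profiles,
    subsample_hypermutators,
)


class TestJSDivergence:
    def test_equal_profiles_zero(self):
        p = np.array([0.2, 0.3, 0.5])
        assert js_divergence(p, p) == pytest.approx(0.0, abs=1e-15)

    def test_disjoint_supports_log_two(self):
        assert js_divergence([1.0, 0.0], [0.0, 1.0]) == pytest.approx(np.log(2))

    def test_half_overlap_worked_value(self):
        # JSD = H(mean) - mean(H), natural log
        assert js_divergence([1.0, 0.0], [0.5, 0.5]) == pytest.approx(0.2158, abs=1e-4)

    def test_matches_entropy_decomposition_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(2, 12))
            p = rng.random(n)
            q = rng.random(n)
            if rng.random() < 0.3:
                p[rng.integers(0, n)] = 0.0  # exercise 0*log0
            p, q = normalize_profiles(p, q)
            expected = jensenshannon(p, q, base=np.e) ** 2
            assert js_divergence(p, q) == pytest.approx(expected, abs=1e-12)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            p, q = normalize_profiles(rng.random(6), rng.random(6))
            j = js_divergence(p, q)
            assert 0.0 <= j <= np.log(2) + 1e-12
            assert j == pytest.approx(js_divergence(q, p), abs=1e-14)

    def test_zero_iff_equal(self):
        rng = np.random.default_rng(2)
        p, q = normalize_profiles(rng.random(5), rng.random(5))
        assert js_divergence(p, q) > 1e-12

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            js_divergence([0.5, 0.6], [0.5, 0.5])


def _table(burden_by_sample, gene="g"):
    rows = []
    for s, n in burden_by_sample.items():
        for k in range(n):
            rows.append((s, f"{gene}{k}", "Missense_Mutation", True))
    rec = pd.DataFrame(rows, columns=["sample_id", "gene_id", "variant_class",
                                      "is_nonsynonymous"])
    return MutationTable(rec, list(burden_by_sample))


class TestSubsampling:
    def test_no_hypermutators_unchanged(self):
        M = _table({"a": 5, "b": 7, "c": 6})
        out, hyper = subsample_hypermutators(M, threshold=100, seed=0)
        assert hyper == []
        assert len(out.records) == len(M.records)

    def test_worked_example_medians_equalized(self):
        burdens = {f"n{i}": b for i, b in enumerate([100, 120, 140])}
        burdens.update({"h1": 500, "h2": 800})
        M = _table(burdens)
        out, hyper = subsample_hypermutators(M, threshold=300, seed=1)
        nb = out.burdens()
        assert sorted(hyper) == ["h1", "h2"]
        assert nb["h1"] == 120 and nb["h2"] == 120
        assert float(nb[["h1", "h2"]].median()) == float(nb[["n0", "n1", "n2"]].median())

    def test_nonhypermutated_records_untouched(self):
        M = _table({"a": 10, "b": 12, "h": 400})
        out, _ = subsample_hypermutators(M, threshold=100, seed=0)
        for s in ("a", "b"):
            before = M.records[M.records["sample_id"] == s]
            after = out.records[out.records["sample_id"] == s]
            assert sorted(before["gene_id"]) == sorted(after["gene_id"])

    def test_same_seed_identical_subsample(self):
        M = _table({"a": 10, "b": 12, "h": 400})
        o1, _ = subsample_hypermutators(M, threshold=100, seed=7)
        o2, _ = subsample_hypermutators(M, threshold=100, seed=7)
        pd.testing.assert_frame_equal(o1.records, o2.records)

    def test_medians_equal_on_random_cohorts(self):
        rng = np.random.default_rng(42)
        for rep in range(20):
            # odd nonhypermutated count -> integer median, so exact
            # equality is always achievable
            n = 2 * int(rng.integers(5, 15)) + 1
            burdens = {f"s{i}": int(rng.integers(5, 60)) for i in range(n)}
            n_hyper = int(rng.integers(1, 4))
            for h in range(n_hyper):
                burdens[f"h{h}"] = int(rng.integers(300, 900))
            M = _table(burdens)
            out, hyper = subsample_hypermutators(M, threshold=200, seed=rep)
            nb = out.burdens()
            med_h = float(nb[hyper].median())
            med_n = float(nb.drop(hyper).median())
            assert med_h == med_n

    def test_all_hypermutated_rejected(self):
        M = _table({"h1": 400, "h2": 500})
        with pytest.raises(ValueError):
            subsample_hypermutators(M, threshold=100, seed=0)


class TestBurdenControl:
    def test_burden_counts_all_variant_classes(self, small_representation):
        samples = small_representation.sample_ids
        rows = [(samples[0], "g1", "Silent", False),
                (samples[0], "g2", "Missense_Mutation", True),
                (samples[1], "g1", "Missense_Mutation", True)]
        rec = pd.DataFrame(rows, columns=["sample_id", "gene_id", "variant_class",
                                          "is_nonsynonymous"])
        M = MutationTable(rec, list(samples))
        assert M.burdens()[samples[0]] == 2  # the silent record counts

    def test_identical_burdens_never_significant(self, small_representation):
        samples = small_representation.sample_ids
        M = _table({s: 3 for s in samples})
        _, p = burden_localization(small_representation, M, n_perm=100, seed=0)
        assert p == 1.0

    def test_clustered_hypermutators_detected(self):
        """Hypermutated samples with a shared expression signature localize."""
        from topodriver import (CohortConfig, MapperConfig,
                                build_representation, select_variable_genes,
                                simulate_cohort)
        cfg = CohortConfig(seed=21, n_samples=150, n_genes=400, n_drivers=0,
                           n_passengers=60, passenger_rate=8.0,
                           n_hypermutators=4, hypermutator_burden_multiplier=60,
                           hypermutator_signature_genes=80)
        E, M, truth = simulate_cohort(cfg)
        var = select_variable_genes(E, 400)
        rep = build_representation(E, MapperConfig(resolution=10, gain=4.0),
                                   genes=var)
        _, p = burden_localization(rep, M, n_perm=500, seed=0)
        assert p < 0.05
        # subsampling resolves it
        M2, hyper = subsample_hypermutators(M, 10 ** 2.5, seed=0)
        assert sorted(hyper) == sorted(truth.hypermutators)
        _, p2 = burden_localization(rep, M2, n_perm=500, seed=0)
        assert p2 >= 0.05


class TestBatchControl:
    def test_single_batch_never_flagged(self, small_representation):
        samples = small_representation.sample_ids
        batches = pd.Series("B1", index=samples)
        flagged, pvals = batch_control(small_representation, batches,
                                       n_perm=100, seed=0)
        assert flagged == []
        assert pvals["B1"] == 1.0

    def test_cluster_aligned_batch_flagged(self):
        from topodriver import (CohortConfig, MapperConfig,
                                build_representation, select_variable_genes,
                                simulate_cohort)
        cfg = CohortConfig(seed=13, n_samples=150, n_genes=400, n_subtypes=2,
                           n_drivers=0, n_passengers=40, n_hypermutators=0,
                           batch_structure="cluster_aligned")
        E, M, truth = simulate_cohort(cfg)
        var = select_variable_genes(E, 400)
        rep = build_representation(E, MapperConfig(resolution=8, gain=3.0),
                                   genes=var)
        batches = pd.Series(truth.batch_of)
        flagged, pvals = batch_control(rep, batches, n_perm=500, seed=0)
        assert set(flagged) == {"B1", "B2"}

    def test_random_batches_rarely_flagged(self, small_representation):
        """Two interleaved batches with no structure stay unflagged in at
        least 90% of draws."""
        samples = small_representation.sample_ids
        rng = np.random.default_rng(3)
        clean = 0
        n_reps = 10
        for r in range(n_reps):
            assign = rng.integers(0, 2, size=len(samples))
            batches = pd.Series([f"B{a}" for a in assign], index=samples)
            flagged, _ = batch_control(small_representation, batches,
                                       n_perm=200, seed=r)
            clean += not flagged
        assert clean >= int(0.9 * n_reps)

    def test_unlabeled_samples_get_singleton_batches(self, small_representation):
        samples = small_representation.sample_ids
        batches = pd.Series("B1", index=samples[: len(samples) // 2])
        flagged, pvals = batch_control(small_representation, batches,
                                       n_perm=50, seed=0)
        assert any(k.startswith("_singleton_") for k in pvals)


class TestJSFilter:
    def test_correlated_gene_retained_anticorrelated_removed(self):
        from topodriver import (CohortConfig, MapperConfig,
                                build_representation, select_variable_genes,
                                simulate_cohort)
        cfg = CohortConfig(seed=5, n_samples=200, n_genes=400, n_subtypes=2,
                           n_drivers=2, driver_prevalence=(0.08, 0.12),
                           n_passengers=40, n_hypermutators=0,
                           n_coupled=5, coupling_sign=-1)
        E, M, truth = simulate_cohort(cfg)
        acfg = AnalysisConfig(prevalence_min=0.01, seed=5)
        var = select_variable_genes(E, 400)
        rep = build_representation(E, MapperConfig(resolution=10, gain=4.0),
                                   genes=var)
        genes = sorted(truth.drivers) + truth.passengers + truth.coupled
        removed, table = js_permutation_filter([rep], E, M, genes, acfg,
                                               n_perm=500)
        assert not (removed & set(truth.drivers))
        assert len(removed & set(truth.coupled)) >= 3

    def test_default_permutation_count(self):
        assert AnalysisConfig(prevalence_min=0.02).js_n_permutations == 2000

    def test_literal_mode_uses_printed_rule(self, small_cohort, small_representation):
        """The paper-literal mode removes exactly the genes whose median BH
        q on the lower-tail p exceeds the 0.8 cut."""
        E, M, truth = small_cohort
        acfg = AnalysisConfig(prevalence_min=0.02, seed=1, js_mode="literal")
        genes = truth.passengers[:30]
        removed, table = js_permutation_filter([small_representation], E, M,
                                               genes, acfg, n_perm=200)
        expected = set(table.loc[table["median_q_corr"] > 0.8, "gene"])
        assert removed == expected
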