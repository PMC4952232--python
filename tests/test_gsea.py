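from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from remsig import (
    CohortDesign,
    ExpressionMatrix,
    GseaParams,
    RankedList,
    enrichment_score,
    generate_cohort,
    leading_edge,
    nominal_p,
    normalize_and_fdr,
    permutation_null,
    run_gsea,
    signal_to_noise,
)
from remsig.containers import GeneSet, GeneSetCollection
from remsig.gsea import DIRECTION_NONREM_UP, DIRECTION_REM_UP


def _matrix(arr, genes=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i:03d}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples))


def ks_es_oracle(ranked_genes, members):
    """Classic (unweighted) KS deviation via two ECDFs, independent of the
    running-sum implementation."""
    members = set(members)
    hits = np.array([g in members for g in ranked_genes])
    n_hit, n_miss = hits.sum(), (~hits).sum()
    ecdf_hit = np.cumsum(hits) / n_hit
    ecdf_miss = np.cumsum(~hits) / n_miss
    diff = ecdf_hit - ecdf_miss
    return diff.max(), diff.min()


class TestSignalToNoise:
    def test_hand_oracle_with_sd_floor(self):
        # one gene: NON-REM values {3,5}, REM values {1,1}
        m = _matrix([[3, 5, 1, 1]])
        labels = ["NON-REM", "NON-REM", "REM", "REM"]
        ranked = signal_to_noise(m, labels, log_transform=False)
        sd_a = np.std([3, 5], ddof=1)
        expected = (4.0 - 1.0) / (sd_a + 0.2)  # REM SD 0 floored at 0.2
        assert ranked.metric[0] == pytest.approx(expected)

    def test_equal_class_means_give_zero(self):
        m = _matrix([[1, 3, 2, 2]])
        s = signal_to_noise(m, ["NON-REM", "NON-REM", "REM", "REM"], log_transform=False)
        assert s.metric[0] == 0.0

    def test_negating_values_flips_every_sign(self, rng):
        arr = rng.normal(0, 2, (20, 10))
        labels = ["NON-REM"] * 5 + ["REM"] * 5
        a = signal_to_noise(_matrix(arr), labels, log_transform=False)
        b = signal_to_noise(_matrix(-arr), labels, log_transform=False)
        by_gene_a = dict(zip(a.genes, a.metric))
        by_gene_b = dict(zip(b.genes, b.metric))
        for g in by_gene_a:
            assert by_gene_b[g] == pytest.approx(-by_gene_a[g])

    def test_requires_two_samples_per_class(self):
        m = _matrix(np.ones((3, 3)))
        with pytest.raises(ValueError):
            signal_to_noise(m, ["NON-REM", "REM", "REM"])

    def test_metric_sorted_descending_with_lexicographic_ties(self):
        m = _matrix(np.ones((4, 4)), genes=["gz", "ga", "gm", "gb"])
        ranked = signal_to_noise(m, ["NON-REM"] * 2 + ["REM"] * 2, log_transform=False)
        assert ranked.genes == ["ga", "gb", "gm", "gz"]  # all metrics tie at 0


class TestEnrichmentScore:
    def test_single_gene_set_at_rank_one_unweighted(self):
        ranked = RankedList([f"g{i}" for i in range(10)], np.arange(9, -1, -1.0))
        prof = enrichment_score(ranked, ["g0"], p=0)
        assert prof.es == pytest.approx(1.0)

    def test_top_three_weighted_walk(self):
        # metrics 9..0 and set = ranks 1-3: running peaks at exactly 1.0
        ranked = RankedList([f"g{i}" for i in range(10)], np.arange(9, -1, -1.0))
        prof = enrichment_score(ranked, ["g0", "g1", "g2"], p=1)
        assert prof.es == pytest.approx(1.0)
        np.testing.assert_allclose(prof.running[:3], [9 / 24, 17 / 24, 1.0])

    def test_ten_gene_hand_fixture(self):
        # set at ranks 1, 4, 8 (metrics 9, 6, 2), p=1: hand-computed walk
        # peaks after the second hit at 9/17 - 2/7 + 6/17 = 71/119
        ranked = RankedList([f"g{i}" for i in range(10)], np.arange(9, -1, -1.0))
        prof = enrichment_score(ranked, ["g0", "g3", "g7"], p=1)
        assert prof.es == pytest.approx(71 / 119)
        core = leading_edge(prof, ranked)
        assert core == ["g0", "g3"]

    def test_unweighted_matches_two_ecdf_oracle_on_random_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 51))
            metric = np.sort(rng.normal(0, 1, n))[::-1]
            genes = [f"g{i}" for i in range(n)]
            k = int(rng.integers(1, n))
            members = list(rng.choice(genes, size=k, replace=False))
            ranked = RankedList(genes, metric)
            es = enrichment_score(ranked, members, p=0).es
            d_max, d_min = ks_es_oracle(genes, members)
            if d_max > -d_min + 1e-9:
                assert es == pytest.approx(d_max)
            elif -d_min > d_max + 1e-9:
                assert es == pytest.approx(d_min)
            else:  # exact tie between the two extremes: either sign is valid
                assert abs(es) == pytest.approx(d_max)

    def test_es_bounded_and_reversal_negates(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 40))
            metric = np.sort(rng.normal(0, 1, n))[::-1]
            genes = [f"g{i}" for i in range(n)]
            members = list(rng.choice(genes, size=int(rng.integers(1, n - 1)), replace=False))
            ranked = RankedList(genes, metric)
            es = enrichment_score(ranked, members, p=1).es
            assert -1.0 <= es <= 1.0
            reversed_list = RankedList(genes[::-1], -metric[::-1])
            es_rev = enrichment_score(reversed_list, members, p=1).es
            assert es_rev == pytest.approx(-es)

    def test_empty_intersection_errors(self):
        ranked = RankedList(["g0", "g1"], np.array([1.0, 0.0]))
        with pytest.raises(ValueError, match="intersection"):
            enrichment_score(ranked, ["absent"])


class TestLeadingEdge:
    def test_single_member_positive_es(self):
        ranked = RankedList([f"g{i}" for i in range(10)], np.arange(9, -1, -1.0))
        prof = enrichment_score(ranked, ["g0"], p=1)
        assert leading_edge(prof, ranked) == ["g0"]

    def test_set_entirely_before_peak_is_whole_set(self):
        ranked = RankedList([f"g{i}" for i in range(10)], np.arange(9, -1, -1.0))
        prof = enrichment_score(ranked, ["g0", "g1", "g2"], p=1)
        assert leading_edge(prof, ranked) == ["g0", "g1", "g2"]

    def test_negative_es_takes_members_after_trough(self):
        ranked = RankedList([f"g{i}" for i in range(10)], np.arange(9, -1, -1.0))
        prof = enrichment_score(ranked, ["g7", "g8", "g9"], p=0)
        assert prof.es < 0
        assert leading_edge(prof, ranked) == ["g7", "g8", "g9"]

    def test_zero_es_empty_core(self):
        prof_running = np.zeros(4)
        from remsig.gsea import EnrichmentProfile

        prof = EnrichmentProfile(es=0.0, running=prof_running, hit_positions=np.array([0]))
        ranked = RankedList(["a", "b", "c", "d"], np.zeros(4))
        assert leading_edge(prof, ranked) == []


class _IdentityRng:
    """Stub generator whose permutation is always the identity."""

    def permutation(self, n):
        return np.arange(n)


class TestPermutationNull:
    def test_identity_permutation_reproduces_observed(self):
        rng = np.random.default_rng(0)
        arr = rng.normal(8, 1, (20, 8))
        # NON-REM samples first, so the identity permutation recovers the labels
        labels = ["NON-REM"] * 4 + ["REM"] * 4
        m = _matrix(arr)
        genes = list(m.gene_ids[:6])
        params = GseaParams(n_perm=1, min_size=1, seed=0, log_transform=False)
        null = permutation_null(m, labels, [genes], params, rng=_IdentityRng())
        ranked = signal_to_noise(m, labels, log_transform=False)
        observed = enrichment_score(ranked, genes, p=1).es
        assert null[0, 0] == pytest.approx(observed)

    def test_three_vs_three_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(42)
        arr = rng.normal(0, 1, (25, 6))
        m = _matrix(arr)
        genes = list(np.array(m.gene_ids)[rng.choice(25, 8, replace=False)])
        labels = np.array(["NON-REM"] * 3 + ["REM"] * 3, dtype=object)

        # exhaustive null: all 20 assignments of 3 NON-REM among 6 samples
        exact_null = []
        for idx in combinations(range(6), 3):
            lab = np.array(["REM"] * 6, dtype=object)
            lab[list(idx)] = "NON-REM"
            ranked = signal_to_noise(m, lab, log_transform=False)
            exact_null.append(enrichment_score(ranked, genes, p=1).es)
        exact_null = np.array(exact_null)

        ranked_obs = signal_to_noise(m, labels, log_transform=False)
        observed = enrichment_score(ranked_obs, genes, p=1).es
        p_exact, _ = nominal_p(observed, exact_null)

        n_perm = 4000
        params = GseaParams(n_perm=n_perm, min_size=1, seed=11, log_transform=False)
        sampled = permutation_null(m, labels, [genes], params)[0]
        p_sampled, _ = nominal_p(observed, sampled)
        se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(p_sampled - p_exact) <= 3 * se + 1e-12

    def test_same_seed_identical_null(self, small_cohort):
        _, (matrix, clinical, coll) = small_cohort
        from remsig import assign_outcome

        samples = clinical.arm_samples("TCZ")
        labels = assign_outcome(clinical)["label"].loc[samples]
        sub = matrix.subset_samples(samples)
        params = GseaParams(n_perm=50, seed=9)
        sets = [list(coll[n].genes) for n in coll.names]
        a = permutation_null(sub, labels, sets, params)
        b = permutation_null(sub, labels, sets, params)
        np.testing.assert_array_equal(a, b)


class TestNominalP:
    def test_observed_beyond_all_nulls_is_flagged_floor(self):
        null = np.concatenate([np.linspace(0.1, 0.5, 80), -np.linspace(0.1, 0.5, 20)])
        p, flag = nominal_p(0.9, null)
        assert flag and p == pytest.approx(1 / 80)

    def test_observed_at_null_median_is_half(self):
        null = np.linspace(0.01, 1.0, 100)
        p, flag = nominal_p(null[49], null)
        assert not flag
        assert p == pytest.approx(0.51, abs=0.02)

    def test_enumeration_tail_fraction_exact(self):
        null = np.array([0.1, 0.2, 0.3, 0.4, -0.5, -0.1])
        p, flag = nominal_p(0.25, null)
        assert p == pytest.approx(2 / 4) and not flag


class TestNormalizeAndFdr:
    def test_nes_one_when_es_equals_mean_positive_null(self):
        null = np.concatenate([np.full(50, 0.4), -np.full(50, 0.4)])
        nes, q = normalize_and_fdr(np.array([0.4]), null[None, :])
        assert nes[0] == pytest.approx(1.0)

    def test_q_values_clipped_to_unit_interval(self, rng):
        observed = rng.normal(0, 0.5, 10)
        null = rng.normal(0, 0.5, (10, 200))
        _, q = normalize_and_fdr(observed, null)
        assert np.all((q[np.isfinite(q)] >= 0) & (q[np.isfinite(q)] <= 1))

    def test_two_set_toy_hand_ratio(self):
        # set 1 observed at the 90th percentile of its positive null,
        # fully enumerated two-sided nulls shared by both sets
        null = np.array(
            [np.concatenate([np.linspace(0.1, 1.0, 10), -np.linspace(0.1, 1.0, 10)])] * 2
        )
        observed = np.array([0.95, 0.15])
        nes, q = normalize_and_fdr(observed, null)
        # NES = ES / mean(positive nulls) = ES / 0.55
        np.testing.assert_allclose(nes, observed / 0.55)
        # pooled positive null NES beyond 0.95/0.55: 2 of 20 (one per set);
        # observed NES beyond: 1 of 2
        assert q[0] == pytest.approx((2 / 20) / (1 / 2))
        # less extreme set: 18 of 20 positive nulls qualify, both observed qualify
        assert q[1] == pytest.approx((18 / 20) / (2 / 2))

    def test_q_monotone_within_sign(self, rng):
        observed = np.abs(rng.normal(0.3, 0.2, 8))
        null = rng.normal(0, 0.3, (8, 500))
        nes, q = normalize_and_fdr(observed, null)
        order = np.argsort(-np.abs(nes))
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestRunGsea:
    def test_size_filters_exclude_small_sets(self, small_cohort):
        from remsig import assign_outcome

        _, (matrix, clinical, coll) = small_cohort
        samples = clinical.arm_samples("IFX")
        labels = assign_outcome(clinical)["label"].loc[samples]
        sub = matrix.subset_samples(samples)
        small = GeneSetCollection(
            [GeneSet("TOO_SMALL", "", tuple(matrix.gene_ids[:14])),
             GeneSet("OK", "", tuple(matrix.gene_ids[:20]))]
        )
        res = run_gsea(sub, labels, small, GseaParams(n_perm=10, seed=0))
        assert [r.set_name for r in res] == ["OK"]

    def test_empty_surviving_collection_errors(self, small_cohort):
        from remsig import assign_outcome

        _, (matrix, clinical, coll) = small_cohort
        samples = clinical.arm_samples("IFX")
        labels = assign_outcome(clinical)["label"].loc[samples]
        tiny = GeneSetCollection([GeneSet("S", "", ("nope1", "nope2"))])
        with pytest.raises(ValueError, match="size filters|survives"):
            run_gsea(matrix.subset_samples(samples), labels, tiny, GseaParams(n_perm=5))

    def test_direction_matches_es_sign(self, small_cohort):
        from remsig import assign_outcome

        _, (matrix, clinical, coll) = small_cohort
        for arm, planted, expected in [
            ("IFX", "INFLAMMASOME_LIKE", DIRECTION_NONREM_UP),
            ("TCZ", "CD19_LIKE", DIRECTION_REM_UP),
        ]:
            samples = clinical.arm_samples(arm)
            labels = assign_outcome(clinical)["label"].loc[samples]
            res = run_gsea(
                matrix.subset_samples(samples), labels, coll, GseaParams(n_perm=100, seed=1)
            )
            by_name = {r.set_name: r for r in res}
            assert by_name[planted].direction == expected
            assert by_name[planted].significant

    def test_full_run_deterministic(self, small_cohort):
        from remsig import assign_outcome

        _, (matrix, clinical, coll) = small_cohort
        samples = clinical.arm_samples("ABT")
        labels = assign_outcome(clinical)["label"].loc[samples]
        sub = matrix.subset_samples(samples)
        params = GseaParams(n_perm=50, seed=21)
        a = run_gsea(sub, labels, coll, params)
        b = run_gsea(sub, labels, coll, params)
        assert [(r.set_name, r.es, r.nes, r.p_nominal, r.q_fdr, tuple(r.core_genes))
                for r in a] == [
            (r.set_name, r.es, r.nes, r.p_nominal, r.q_fdr, tuple(r.core_genes))
            for r in b
        ]

    def test_nominal_p_uniform_under_null(self):
        # decoy-only cohort with no planted signal: permutation p values
        # across decoy sets should look uniform
        design = CohortDesign(
            n_genes=500, n_per_arm=(50,), arms=("IFX",),
            remission_rate_per_arm=(0.3,), n_decoy_sets=30,
            insufficient_effect_per_arm=(0,), adverse_event_per_arm=(0,), seed=17,
        )
        matrix, clinical, coll = generate_cohort(design)
        from remsig import assign_outcome

        labels = assign_outcome(clinical)["label"]
        res = run_gsea(matrix, labels, coll, GseaParams(n_perm=200, min_size=15, seed=5))
        pvals = np.array([r.p_nominal for r in res])
        stat = stats.kstest(pvals, "uniform")
        assert stat.pvalue > 0.01
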