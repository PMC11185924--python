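import numpy as np
import pandas as pd
import pytest
from scipy import stats

from drugsense import scoring
from drugsense.scoring import (
    combine_brown,
    combine_fisher,
    combine_g_score,
    empirical_p,
    enrichment_score,
    four_way_gsea,
    null_es_distribution,
    rank_profile,
    score_sample,
)
from drugsense.types import DGCP, ScoringParams


def es_bruteforce(ranked, members, weight=0.0, values=None):
    """Step-by-step running-sum enumeration, independent of the main path."""
    members = set(members)
    hits = [g in members for g in ranked]
    n, nh = len(ranked), sum(hits)
    if weight == 0:
        w = [1.0] * n
    else:
        w = [abs(v) ** weight for v in values]
    w_hit = sum(wi for wi, h in zip(w, hits) if h)
    run, best = 0.0, 0.0
    for i in range(n):
        if hits[i]:
            run += w[i] / w_hit
        else:
            run -= 1.0 / (n - nh)
        if abs(run) > abs(best):
            best = run
    return best


class TestEnrichmentScore:
    def test_matches_bruteforce_on_random_instances(self, rng):
        genes = [f"g{i}" for i in range(80)]
        for _ in range(100):
            members = rng.choice(genes, size=rng.integers(1, 20), replace=False)
            values = np.sort(rng.standard_normal(80))[::-1]
            for weight in (0.0, 1.0):
                got = enrichment_score(genes, members, weight=weight, ranking_values=values)
                want = es_bruteforce(genes, members, weight=weight, values=values)
                assert got == pytest.approx(want, abs=1e-12)

    def test_set_at_top_gives_plus_one(self):
        genes = [f"g{i}" for i in range(50)]
        assert enrichment_score(genes, genes[:7]) == pytest.approx(1.0)

    def test_set_at_bottom_gives_minus_one(self):
        genes = [f"g{i}" for i in range(50)]
        assert enrichment_score(genes, genes[-7:]) == pytest.approx(-1.0)

    def test_small_hand_case(self):
        # 10 genes, hits at 1-based positions {2, 5, 9}, weight 0
        genes = [f"g{i}" for i in range(10)]
        members = [genes[1], genes[4], genes[8]]
        assert enrichment_score(genes, members) == pytest.approx(
            es_bruteforce(genes, members), abs=1e-15
        )

    def test_disjoint_set_errors(self):
        with pytest.raises(ValueError, match="overlap"):
            enrichment_score(["a", "b"], ["z"])

    def test_full_list_set_errors(self):
        with pytest.raises(ValueError, match="misses"):
            enrichment_score(["a", "b"], ["a", "b"])


class TestEmpiricalP:
    def test_hand_counted_case(self):
        assert empirical_p(0.25, np.array([0.1, 0.2, 0.3, 0.4]), "greater") == pytest.approx(0.6)

    def test_floor_rule(self):
        null = np.linspace(-0.5, 0.5, 10_000)
        assert empirical_p(0.9, null, "greater") == pytest.approx(1 / 10_001)

    def test_median_observation_near_half(self):
        null = np.linspace(-1, 1, 999)
        assert empirical_p(0.0, null, "greater") == pytest.approx(0.5, abs=0.01)

    def test_monotone_in_observation(self, rng):
        null = rng.standard_normal(500)
        ps = [empirical_p(x, null, "greater") for x in (-1.0, 0.0, 1.0)]
        assert ps[0] >= ps[1] >= ps[2]


class TestRankProfile:
    def test_sorts_by_value_then_gene_id(self):
        s = pd.Series([3.0, 1.0, 2.0, 2.0, 0.0], index=["e", "d", "c", "a", "b"], name="s1")
        prof = rank_profile(s, ["a", "b", "c", "d", "e"])
        assert list(prof.genes) == ["e", "a", "c", "d", "b"]

    def test_universe_filter(self):
        s = pd.Series([3.0, 1.0, 2.0], index=["a", "b", "c"], name="s1")
        prof = rank_profile(s, ["a", "c"])
        assert list(prof.genes) == ["a", "c"]

    def test_all_equal_values_lexicographic(self, caplog):
        s = pd.Series([1.0, 1.0, 1.0], index=["c", "a", "b"], name="s1")
        prof = rank_profile(s, ["c", "a", "b"])
        assert list(prof.genes) == ["a", "b", "c"]

    def test_insufficient_overlap_errors(self):
        s = pd.Series([1.0], index=["a"], name="s1")
        with pytest.raises(ValueError, match="overlap"):
            rank_profile(s, ["a", "b"], min_genes=2)


def _toy_dgcp(n=400, seed=0):
    rng = np.random.default_rng(seed)
    genes = np.array([f"g{i:04d}" for i in range(n)], dtype=object)
    pcc = np.sort(rng.uniform(-1, 1, n))[::-1]
    return DGCP("drug", genes, pcc, 30)


def test_constructed_extreme_tumor_hits_the_floor(rng):
    """A tumor whose top-expressed genes are exactly the DGCP bottom genes
    drives test 1 to ES = -1 at the minimal attainable p-value."""
    dgcp = _toy_dgcp()
    n, m = len(dgcp), 50
    values = np.linspace(5, -5, n)
    # most-expressed genes = DGCP bottom block, least-expressed = DGCP top block
    order = np.concatenate([np.arange(n - m, n), np.arange(m, n - m), np.arange(m)])
    sample = pd.Series(values, index=dgcp.genes[order], name="t")
    profile = rank_profile(sample, list(dgcp.genes))
    params = ScoringParams(set_size=m, n_perm=200)
    fp = four_way_gsea(profile, dgcp, params, rng=rng)
    assert fp.es[0] == pytest.approx(-1.0)
    assert fp.p_top_expr_vs_sensitivity == pytest.approx(1 / 201)
    assert fp.es[1] == pytest.approx(1.0)
    assert fp.p_bottom_expr_vs_resistance == pytest.approx(1 / 201)
    assert fp.p_sens_biomarkers_up == pytest.approx(1 / 201)
    assert fp.p_res_biomarkers_down == pytest.approx(1 / 201)


def test_null_ensemble_full_shuffle_centers_random_set(rng):
    dgcp = _toy_dgcp()
    sample = pd.Series(rng.standard_normal(len(dgcp)), index=dgcp.genes, name="t")
    profile = rank_profile(sample, list(dgcp.genes))
    gene_set = rng.choice(profile.genes, size=40, replace=False)
    params = ScoringParams(set_size=40, n_perm=300, shuffle_fraction=1.0)
    null = null_es_distribution(profile, gene_set, params, rng)
    assert abs(float(np.mean(null))) < 0.05


def test_single_permutation_reproducible(rng):
    dgcp = _toy_dgcp()
    sample = pd.Series(np.arange(float(len(dgcp))), index=dgcp.genes, name="t")
    profile = rank_profile(sample, list(dgcp.genes))
    gene_set = list(dgcp.genes[:30])
    params = ScoringParams(set_size=30, n_perm=1)
    a = null_es_distribution(profile, gene_set, params, np.random.default_rng(7))
    b = null_es_distribution(profile, gene_set, params, np.random.default_rng(7))
    np.testing.assert_array_equal(a, b)


def test_top_set_beats_null_quantile(rng):
    dgcp = _toy_dgcp()
    sample = pd.Series(np.linspace(3, -3, len(dgcp)), index=dgcp.genes, name="t")
    profile = rank_profile(sample, list(dgcp.genes))
    gene_set = list(profile.genes[:40])  # set at the top of the ranking
    params = ScoringParams(set_size=40, n_perm=1000)
    observed = enrichment_score(profile.genes, gene_set)
    null = null_es_distribution(profile, gene_set, params, rng)
    assert observed > np.quantile(null, 0.99)


class TestGScore:
    def test_idempotent_on_equal_ps(self):
        assert combine_g_score([0.1, 0.1, 0.1, 0.1]) == pytest.approx(0.1, abs=1e-12)

    def test_closed_form(self):
        assert combine_g_score([0.01, 0.1, 0.1, 1.0]) == pytest.approx(0.1, abs=1e-12)

    def test_permutation_invariant(self, rng):
        p = rng.uniform(0.001, 1, 4)
        vals = {combine_g_score(p[perm]) for perm in map(list, __import__("itertools").permutations(range(4)))}
        assert len({round(v, 15) for v in vals}) == 1

    def test_monotone_in_each_p(self):
        base = combine_g_score([0.2, 0.3, 0.4, 0.5])
        assert combine_g_score([0.1, 0.3, 0.4, 0.5]) < base

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            combine_g_score([0.0, 0.1, 0.1, 0.1])


class TestBrown:
    def test_zero_covariance_equals_fisher(self, rng):
        p = rng.uniform(0.01, 1, 4)
        got = combine_brown(p, np.zeros((4, 4)))
        assert got == pytest.approx(combine_fisher(p), rel=1e-12)

    def test_full_dependence_recovers_single_p(self):
        # four copies of one test: cov of -2 ln p is 4 off-diagonal
        cov = np.full((4, 4), 4.0)
        for single_p in (0.01, 0.2, 0.7):
            got = combine_brown([single_p] * 4, cov)
            assert got == pytest.approx(single_p, rel=1e-9)

    def test_degenerate_covariance_falls_back_to_fisher(self):
        p = [0.1, 0.2, 0.3, 0.4]
        bad = np.full((4, 4), -100.0)
        with pytest.warns(UserWarning, match="degenerate"):
            got = combine_brown(p, bad)
        assert got == pytest.approx(combine_fisher(p), rel=1e-12)


class TestScoreSample:
    def test_single_drug_rank_one(self, small_library, small_cohort):
        drug = small_library.drug_ids[0]
        from drugsense.types import DGCPLibrary

        lib1 = DGCPLibrary(
            "one", {drug: small_library.dgcps[drug]}, small_library.gene_universe
        )
        out = score_sample(
            small_cohort.expression.iloc[:, 0],
            lib1,
            ScoringParams(set_size=50, n_perm=50),
            seed=0,
        )
        assert len(out) == 1 and out.loc[0, "rank"] == 1

    def test_identical_samples_identical_rankings(self, small_library, small_cohort):
        expr = small_cohort.expression.iloc[:, [0]].copy()
        expr["twin"] = expr.iloc[:, 0]
        scored = scoring.score_cohort(expr, small_library, ScoringParams(set_size=50, n_perm=100), seed=3)
        a = scored[scored.sample_id == expr.columns[0]].set_index("drug_id")
        b = scored[scored.sample_id == "twin"].set_index("drug_id")
        pd.testing.assert_series_equal(a["rank"], b["rank"], check_names=False)
        np.testing.assert_array_equal(a["g_score"], b["g_score"])

    def test_bit_for_bit_reproducible(self, small_library, small_cohort):
        params = ScoringParams(set_size=50, n_perm=100)
        a = score_sample(small_cohort.expression.iloc[:, 1], small_library, params, seed=11)
        b = score_sample(small_cohort.expression.iloc[:, 1], small_library, params, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_sensitive_tumor_scores_lower_than_neutral(self, small_benchmark, small_library):
        """Planted up-regulation of a drug's sensitivity biomarkers lowers
        that drug's G-score relative to a background tumor."""
        from drugsense import synthetic

        drug = small_library.drug_ids[0]
        rng = np.random.default_rng(40)
        genes = small_benchmark.expression.index
        neutral = pd.Series(rng.standard_normal(len(genes)), index=genes, name="neutral")
        sensitive = neutral.copy()
        sensitive.name = "sensitive"
        sensitive[small_benchmark.truth_biomarkers[drug]["sensitivity"]] += 2.0
        sensitive[small_benchmark.truth_biomarkers[drug]["resistance"]] -= 2.0
        params = ScoringParams(set_size=50, n_perm=200)
        g_neutral = score_sample(neutral, small_library, params, seed=1).set_index("drug_id").g_score[drug]
        g_sens = score_sample(sensitive, small_library, params, seed=1).set_index("drug_id").g_score[drug]
        assert g_sens < g_neutral


def test_brown_and_gmean_rankings_agree(small_library, small_cohort):
    params = ScoringParams(set_size=50, n_perm=300, combine_method="brown")
    out = score_sample(small_cohort.expression.iloc[:, 0], small_library, params, seed=5)
    rho = stats.spearmanr(out["g_score"], out["brown_p"]).statistic
    assert rho >= 0.95


from hypothesis import given, settings, strategies as st


@settings(deadline=None, derandomize=True, max_examples=60)
@given(st.lists(st.booleans(), min_size=3, max_size=60).filter(lambda h: 0 < sum(h) < len(h)))
def test_es_bounded_and_matches_oracle_on_arbitrary_hit_patterns(hits):
    """The running-sum statistic stays in [-1, 1] and agrees with the
    brute-force enumeration for any hit/miss pattern."""
    genes = [f"g{i:02d}" for i in range(len(hits))]
    members = [g for g, h in zip(genes, hits) if h]
    es = enrichment_score(genes, members)
    assert -1.0 <= es <= 1.0
    assert es == pytest.approx(es_bruteforce(genes, members), abs=1e-12)
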