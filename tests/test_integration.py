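"""Integration stage: group tests, correlations, seed matching, stability."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pcafe
from pcafe.matrix import ExpressionMatrix


class TestDesign:
    def test_default_design_valid_and_unpaired_flagged(self):
        design = pcafe.ConditionDesign(pcafe.default_design(4))
        assert design.unpaired == ["T1-1d", "T3-1d"]
        assert len(design.pair_ids) == 5

    def test_incomplete_pair_rejected(self):
        tab = pcafe.default_design(2)
        tab = tab[tab["condition"] != "C2-1d"]  # orphan the 2-1d pair
        with pytest.raises(ValueError, match="2-1d"):
            pcafe.ConditionDesign(tab)


class TestGroupPvalues:
    def test_identical_groups_give_half(self, fixture_data):
        mrna = fixture_data["mrna"]
        design = fixture_data["design"]
        treat = design.samples_of("T2-1d")
        vals = mrna.values.copy()
        cols = {s: j for j, s in enumerate(mrna.sample_ids)}
        for st, sc in zip(treat, design.samples_of("C2-1d")):
            vals[:, cols[sc]] = vals[:, cols[st]]
        em = ExpressionMatrix(vals, mrna.feature_ids, mrna.sample_ids, mrna.labels)
        p = pcafe.per_feature_group_pvalues(em, design, "2-1d", alternative="greater")
        np.testing.assert_allclose(p, 0.5, atol=1e-12)

    def test_one_sided_orientations_sum_to_one(self, fixture_data):
        mrna, design = fixture_data["mrna"], fixture_data["design"]
        pg = pcafe.per_feature_group_pvalues(mrna, design, "5-1d", "greater")
        pl = pcafe.per_feature_group_pvalues(mrna, design, "5-1d", "less")
        np.testing.assert_allclose(pg + pl, 1.0, atol=1e-9)

    def test_planted_regulation_detected_directionally(self, fixture_data):
        # planted mRNAs are suppressed under treatment -> small "less" P-values
        mrna, design, spec = fixture_data["mrna"], fixture_data["design"], fixture_data["spec"]
        p_less = pcafe.per_feature_group_pvalues(mrna, design, "10-42d", "less")
        planted = p_less[: spec.n_planted_pairs]
        assert np.median(planted) < 0.5
        # and the paired miRNA probes are upregulated
        mirna = fixture_data["mirna"]
        p_gt = pcafe.per_feature_group_pvalues(mirna, design, "10-42d", "greater")
        assert np.median(p_gt[: spec.n_planted_pairs * 2]) < 0.5

    def test_missing_condition_rejected(self, fixture_data):
        with pytest.raises(ValueError):
            pcafe.per_feature_group_pvalues(
                fixture_data["mrna"], fixture_data["design"], ("T99-1d", "C2-1d")
            )


class TestSelectedVsOthers:
    def test_null_selection_is_not_significant(self, rng):
        ps = []
        for _ in range(30):
            log_p = rng.normal(0, 1, 200)
            sel = rng.choice(200, 20, replace=False)
            ps.append(pcafe.selected_vs_others_test(log_p, sel).p_less)
        # near-uniform: no pile-up at the significant end
        assert np.mean(np.array(ps) < 0.05) < 0.25
        assert 0.2 < np.median(ps) < 0.8

    def test_shifted_selection_detected(self, rng):
        log_p = rng.normal(0, 1, 100)
        sel = np.arange(10)
        log_p[sel] -= 10.0
        res = pcafe.selected_vs_others_test(log_p, sel)
        assert res.p_less < 1e-6
        assert res.p_greater + res.p_less == pytest.approx(1.0, abs=1e-9)

    def test_empty_group_rejected(self, rng):
        with pytest.raises(ValueError):
            pcafe.selected_vs_others_test(rng.normal(0, 1, 10), [])


class TestLogRatio:
    def test_identical_conditions_give_half(self, fixture_data):
        mrna, design = fixture_data["mrna"], fixture_data["design"]
        res = pcafe.log_ratio_group_test(mrna, design, ("T2-1d", "T2-1d"), range(8))
        assert res.p_greater == pytest.approx(0.5, abs=1e-9)

    def test_suppressed_selection_has_small_down_pvalue(self, fixture_data):
        mrna, design, spec = fixture_data["mrna"], fixture_data["design"], fixture_data["spec"]
        res = pcafe.log_ratio_group_test(mrna, design, "10-42d", range(spec.n_planted_pairs))
        assert res.p_less < 0.05

    def test_swapping_conditions_swaps_pvalues(self, fixture_data):
        mrna, design = fixture_data["mrna"], fixture_data["design"]
        fwd = pcafe.log_ratio_group_test(mrna, design, ("T5-1d", "C5-1d"), range(8))
        rev = pcafe.log_ratio_group_test(mrna, design, ("C5-1d", "T5-1d"), range(8))
        assert fwd.p_greater == pytest.approx(rev.p_less, abs=1e-9)

    def test_nonpositive_expression_rejected(self, fixture_data):
        mrna, design = fixture_data["mrna"], fixture_data["design"]
        bad = ExpressionMatrix(
            mrna.values - mrna.values.max(), mrna.feature_ids, mrna.sample_ids, mrna.labels
        )
        with pytest.raises(ValueError, match="positive"):
            pcafe.log_ratio_group_test(bad, design, "2-1d", range(8))


class TestLoadingCorrelation:
    def test_self_correlation_is_one(self, fixture_data):
        emb = pcafe.pca_embed(fixture_data["mrna"], center="feature")
        r, p = pcafe.loading_correlation(emb, emb)
        assert r == pytest.approx(1.0)

    def test_planted_programs_anticorrelated(self, fixture_data):
        """The shared program couples the two embeddings strongly; once each
        component is oriented by its planted features' scores (the package's
        deterministic sign convention is otherwise arbitrary for cross-omics
        comparison), the miRNA and mRNA programs are anticorrelated."""
        spec = fixture_data["spec"]
        ea = pcafe.pca_embed(fixture_data["mirna"], center="feature")
        eb = pcafe.pca_embed(fixture_data["mrna"], center="feature")
        r, p = pcafe.loading_correlation(ea, eb)
        assert abs(r) > 0.5 and p < 0.01
        sign_a = np.sign(ea.feature_scores[: spec.n_planted_pairs * 2, 0].mean())
        sign_b = np.sign(eb.feature_scores[: spec.n_planted_pairs, 0].mean())
        assert sign_a * sign_b * r < 0

    def test_by_condition_averages(self, fixture_data):
        ea = pcafe.pca_embed(fixture_data["mirna"], center="feature")
        eb = pcafe.pca_embed(fixture_data["mrna"], center="feature")
        r, p = pcafe.loading_correlation(ea, eb, by_condition=True, design=fixture_data["design"])
        assert -1 <= r <= 1

    def test_sample_mismatch_rejected(self, fixture_data, rng):
        ea = pcafe.pca_embed(fixture_data["mirna"], center="feature")
        other = pcafe.pca_embed(rng.normal(0, 1, (5, 10)), center="none")
        with pytest.raises(ValueError):
            pcafe.loading_correlation(ea, other)


class TestCorrelationSignificance:
    def test_zero_correlation(self):
        t, p = pcafe.correlation_significance(0.0, 48)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_against_t_cdf_oracle(self):
        t, p = pcafe.correlation_significance(0.5, 48)
        t_oracle = 0.5 * np.sqrt(46) / np.sqrt(0.75)
        assert t == pytest.approx(t_oracle)
        assert p == pytest.approx(2 * (1 - stats.t.cdf(t_oracle, 46)), rel=1e-9)

    def test_antisymmetric_t_symmetric_p(self):
        tp, pp = pcafe.correlation_significance(0.4, 30)
        tn, pn = pcafe.correlation_significance(-0.4, 30)
        assert tp == pytest.approx(-tn)
        assert pp == pytest.approx(pn)

    def test_perfect_correlation_limit(self):
        t, p = pcafe.correlation_significance(1.0, 10)
        assert p == 0.0

    def test_batch_flags_significance(self):
        out = pcafe.correlation_significance_batch([-0.9, 0.01, 0.85], 48)
        assert out.significant.tolist() == [True, False, True]


def _bh_stepup_oracle(p):
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


class TestBhAdjust:
    def test_single_pvalue_unchanged(self):
        assert pcafe.bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_stepup_arithmetic(self):
        np.testing.assert_allclose(
            pcafe.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_matches_stepup_oracle_on_random_vectors(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 1, rng.integers(1, 50))
            np.testing.assert_allclose(pcafe.bh_adjust(p), _bh_stepup_oracle(p), atol=1e-12)

    def test_monotone_and_capped(self, rng):
        p = rng.uniform(0, 1, 100)
        adj = pcafe.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()
        assert (adj <= 1).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pcafe.bh_adjust([0.5, 1.5])


def _seed_match_bruteforce(mirna, utr):
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    m = mirna.upper().replace("U", "T")
    u = utr.upper().replace("U", "T")
    site = "".join(comp[b] for b in reversed(m[1:8]))
    return [i for i in range(len(u) - 6) if u[i : i + 7] == site]


class TestSeedMatch:
    def test_constructed_site_found_at_offset(self):
        mirna = "UAGCUUAUCAGACUGAUGUUGA"
        site = _seed_match_bruteforce(mirna, "A" * 7)  # just build the site string
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        site_str = "".join(comp[b] for b in reversed(mirna.replace("U", "T")[1:8]))
        utr = "GGGGG" + site_str + "GGGGG"
        matches = pcafe.seed_match_7mer_m8(mirna, utr)
        assert [m.utr_offset for m in matches] == [5]
        assert matches[0].matched_site == site_str

    def test_incompatible_alphabet_means_no_match(self):
        assert pcafe.seed_match_7mer_m8("UAGCUUAUCAGACUGAUGUUGA", "A" * 50) == []

    def test_matches_sliding_window_oracle(self, rng):
        bases = np.array(list("ACGU"))
        for _ in range(20):
            mirna = "".join(rng.choice(bases, 22))
            utr = "".join(rng.choice(np.array(list("ACGT")), 1000))
            got = [m.utr_offset for m in pcafe.seed_match_7mer_m8(mirna, utr)]
            assert got == _seed_match_bruteforce(mirna, utr)

    def test_u_t_alphabet_equivalence(self):
        mirna_rna = "UAGCUUAUCAGACUGAUGUUGA"
        mirna_dna = mirna_rna.replace("U", "T")
        utr = "CTGATAAGCTA" * 30
        a = pcafe.seed_match_7mer_m8(mirna_rna, utr)
        b = pcafe.seed_match_7mer_m8(mirna_dna, utr)
        assert [m.utr_offset for m in a] == [m.utr_offset for m in b]

    def test_ambiguous_bases_never_match(self):
        mirna = "UNGCUUAUCAGACUGAUGUUGA"  # N lands in the seed
        assert pcafe.seed_match_7mer_m8(mirna, "ACGT" * 100) == []

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError):
            pcafe.seed_match_7mer_m8("ACGUACG", "ACGT" * 10)


class TestPairTable:
    def test_planted_pairs_significant_negative_with_seed_sites(self, fixture_data):
        d = fixture_data
        spec = d["spec"]
        sel_mi = [f"mir-{i + 1}" for i in range(spec.n_planted_pairs)]
        sel_mr = [f"gene_{i + 1}" for i in range(spec.n_planted_pairs)]
        tab = pcafe.mirna_mrna_pairs(
            d["mirna"], d["mrna"], sel_mi, sel_mr,
            probe_map=d["truth"]["probe_map"],
            mirna_seqs=d["mirna_seqs"], utr_seqs=d["utr_seqs"],
        )
        planted = tab[tab.mirna_id.str[4:] == tab.mrna_id.str[5:]]
        assert len(planted) == spec.n_planted_pairs
        assert (planted.r < 0).all()
        assert planted.significant.all()
        assert planted.seed_match.all()

    def test_unknown_ids_rejected(self, fixture_data):
        with pytest.raises(ValueError):
            pcafe.mirna_mrna_pairs(
                fixture_data["mirna"], fixture_data["mrna"], ["mir-999"], ["gene_1"]
            )


class TestCvStability:
    def test_constant_method_gives_all_or_nothing_frequencies(self, fixture_data):
        mrna, design = fixture_data["mrna"], fixture_data["design"]
        freq, n_eff, failures = pcafe.cv_stability(
            mrna, design, lambda sub: [0, 5, 9], n_samplings=10, seed=0
        )
        assert failures == 0 and n_eff == 10
        assert set(freq.tolist()) == {0, 10}
        assert freq[[0, 5, 9]].tolist() == [10, 10, 10]

    def test_failures_are_skipped_and_counted(self, fixture_data):
        mrna, design = fixture_data["mrna"], fixture_data["design"]
        calls = {"n": 0}

        def flaky(sub):
            calls["n"] += 1
            if calls["n"] % 2:
                raise RuntimeError("boom")
            return [1]

        freq, n_eff, failures = pcafe.cv_stability(mrna, design, flaky, n_samplings=6, seed=0)
        assert failures == 3 and n_eff == 3
        assert freq[1] == 3

    def test_unsupervised_frequencies_ignore_role_labels(self, fixture_data):
        """Permuting the role column leaves an unsupervised method's
        stability frequencies unchanged (labels are never consulted)."""
        mrna = fixture_data["mrna"]
        design = fixture_data["design"]
        shuffled = design.table.copy()
        shuffled["role"] = np.random.default_rng(1).permutation(shuffled["role"].to_numpy())
        shuffled["pair_id"] = ""

        def fe(sub):
            emb = pcafe.pca_embed(sub, center="feature")
            return pcafe.cpcafe_select(emb, n_top=8).selected

        f1, *_ = pcafe.cv_stability(mrna, design, fe, n_samplings=15, seed=4)
        f2, *_ = pcafe.cv_stability(
            mrna, pcafe.ConditionDesign(shuffled), fe, n_samplings=15, seed=4
        )
        np.testing.assert_array_equal(f1, f2)

    def test_strong_signal_is_bimodally_stable(self, fixture_data):
        """Planted features are (nearly) always selected, background
        (nearly) never — the stability signature of unsupervised FE."""
        mrna = fixture_data["mrna"]
        design = fixture_data["design"]
        spec = fixture_data["spec"]

        def fe(sub):
            emb = pcafe.pca_embed(sub, center="feature")
            return pcafe.cpcafe_select(emb, n_top=spec.n_planted_pairs).selected

        freq, n_eff, _ = pcafe.cv_stability(mrna, design, fe, n_samplings=30, seed=2)
        assert n_eff == 30
        extreme = (freq <= 3) | (freq >= 27)
        assert extreme.mean() > 0.9
        assert np.median(freq[: spec.n_planted_pairs]) >= 27
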