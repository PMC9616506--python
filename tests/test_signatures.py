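"""Signature scoring, variable-gene selection, log-rank filtering, FDR."""

import numpy as np
import pandas as pd
import pytest

from clonepulse.signatures import (
    DegenerateSplitError,
    GeneSignature,
    SurvivalCohort,
    bh_fdr,
    integrate_signature,
    logrank_median_split,
    merge_signatures,
    top_variable_genes,
    zscore_matrix,
    zscore_signature_score,
)
from clonepulse.simulate import (
    beta_for_halves_hazard_ratio,
    simulate_expression_cohort,
)


def expr_frame(data, genes=None, samples=None):
    data = np.asarray(data, dtype=float)
    genes = genes or [f"g{i}" for i in range(data.shape[0])]
    samples = samples or [f"s{j}" for j in range(data.shape[1])]
    return pd.DataFrame(data, index=genes, columns=samples)


class TestZScoreScoring:
    def test_zscored_rows_are_standardized(self):
        rng = np.random.default_rng(1)
        expr = expr_frame(rng.normal(2, 3, size=(10, 8)))
        z = zscore_matrix(expr)
        assert np.allclose(z.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(z.std(axis=1, ddof=0), 1, atol=1e-9)

    def test_sample_at_plus_one_on_both_genes_scores_one(self):
        # two genes, sample s1 exactly one sd above the mean on both
        expr = expr_frame([[0, 2], [5, 7]])
        sig = GeneSignature.from_genes("sig", ["g0", "g1"])
        scores, used = zscore_signature_score(expr, sig)
        assert used == 2
        assert scores["s1"] == pytest.approx(1.0)

    def test_invariant_to_gene_and_sample_order(self):
        rng = np.random.default_rng(2)
        expr = expr_frame(rng.normal(size=(6, 9)))
        sig = GeneSignature.from_genes("sig", ["g1", "g3", "g5"])
        base, _ = zscore_signature_score(expr, sig)
        permuted = expr.iloc[::-1, ::-1]
        sig_rev = GeneSignature.from_genes("sig", ["g5", "g1", "g3"])
        again, _ = zscore_signature_score(permuted, sig_rev)
        assert np.allclose(base.sort_index(), again.sort_index())

    def test_constant_genes_dropped_no_overlap_errors(self):
        expr = expr_frame([[1, 1, 1], [0, 1, 2]])
        sig = GeneSignature.from_genes("sig", ["g0", "g1"])
        scores, used = zscore_signature_score(expr, sig)
        assert used == 1
        with pytest.raises(ValueError):
            zscore_signature_score(expr, GeneSignature.from_genes("x", ["nope"]))

    def test_planted_group_shift_separates_scores(self):
        diffs = []
        for seed in range(30):
            sim = simulate_expression_cohort(
                seed=seed, n_genes=200, n_samples=20, n_patients=4,
                n_signature_genes=15, group_shift=1.0, censoring_rate=0.0,
            )
            sig = GeneSignature.from_genes(
                "planted", sim["truth"]["signature_genes"])
            scores, _ = zscore_signature_score(sim["expression"], sig)
            groups = sim["groups"]
            diffs.append(scores[groups == "B"].mean()
                         - scores[groups == "A"].mean())
        # shift of 1.0 on unit-variance genes: z-score gap ~ 1/sqrt(1+shift var)
        assert 0.5 < np.mean(diffs) < 1.2


class TestTopVariableGenes:
    def test_exact_count_from_oversized_matrix(self):
        rng = np.random.default_rng(3)
        expr = expr_frame(rng.normal(size=(5000, 12)))
        assert len(top_variable_genes(expr, 1000)) == 1000

    def test_saturation_returns_all_with_warning(self, caplog):
        rng = np.random.default_rng(4)
        expr = expr_frame(rng.normal(size=(10, 5)))
        with caplog.at_level("WARNING"):
            genes = top_variable_genes(expr, 1000)
        assert len(genes) == 10 and "only 10" in caplog.text

    def test_ranking_and_lexicographic_tie_break(self):
        expr = expr_frame(
            [[0, 0, 0], [0, 4, 8], [8, 4, 0], [0, 1, 2]],
            genes=["flat", "zb", "za", "small"],
        )
        # zb and za tie at the top; za wins the tie lexicographically
        assert top_variable_genes(expr, 1)[0] == "za"
        assert top_variable_genes(expr, 3) == ["za", "zb", "small"]


class TestMergeSignatures:
    def test_union_with_provenance(self):
        a = GeneSignature.from_genes("A", ["g1", "g2"])
        b = GeneSignature.from_genes("B", ["g2", "g3"])
        merged = merge_signatures([a, b])
        assert sorted(merged.members) == ["g1", "g2", "g3"]
        assert merged.genes["g2"] == ["A", "B"]

    def test_majority_keeps_gene_tie_drops_it(self):
        adr = [GeneSignature.from_genes(f"adr{i}", ["shared", f"a{i}"])
               for i in range(3)]
        mes = [GeneSignature.from_genes("mes1", ["shared", "tied", "m1"]),
               ]
        adr[0].genes["tied"] = ["adr0"]
        merged = merge_signatures(adr, opposing=mes)
        assert "shared" in merged.genes      # 3 ADR sources vs 1 MES
        assert "tied" not in merged.genes    # 1 vs 1: dropped
        assert "tied" in merged.dropped


class TestLogrankMedianSplit:
    @staticmethod
    def _random_cohort(seed, n=80, effect=0.0):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=n)
        hazard = 0.01 * np.exp(effect * values)
        t_event = rng.exponential(1 / hazard)
        t_cens = rng.exponential(1 / 0.004, size=n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        return time, event, values

    def test_identical_arms_give_zero_statistic(self):
        time = np.array([5.0, 9, 13, 20, 5, 9, 13, 20])
        event = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        values = np.array([0.0, 0, 0, 0, 1, 1, 1, 1])
        stat, p, direction = logrank_median_split(time, event, values)
        assert stat == 0.0 and p == 1.0 and direction == "none"

    def test_matches_lifelines_on_random_cohorts(self):
        from lifelines.statistics import logrank_test

        for seed in range(10):
            time, event, values = self._random_cohort(seed, effect=0.4)
            stat, p, _ = logrank_median_split(time, event, values)
            high = values > np.median(values)
            ref = logrank_test(time[high], time[~high],
                               event[high], event[~high])
            assert stat == pytest.approx(ref.test_statistic, rel=1e-6)
            assert p == pytest.approx(ref.p_value, rel=1e-6)

    def test_direction_reports_worse_arm(self):
        # high expression strongly increases hazard
        time, event, values = self._random_cohort(3, n=200, effect=2.0)
        _, _, direction = logrank_median_split(time, event, values)
        assert direction == "high_worse"

    def test_tiny_cohort_is_degenerate(self):
        with pytest.raises(DegenerateSplitError):
            logrank_median_split(
                np.array([1.0, 2, 3]), np.array([1, 1, 1]),
                np.array([0.1, 0.2, 0.3]),
            )


class TestBhFdr:
    def test_step_up_hand_example(self):
        # hand-applied BH: q_i = min over j>=i of p_(j)*m/j
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_identity_cases(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_monotone_and_never_below_raw(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=50)
        q = bh_fdr(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.5])


class TestIntegrateSignature:
    def test_threshold_one_keeps_all_present_genes(self):
        sim = simulate_expression_cohort(seed=9, n_genes=60, n_patients=60,
                                         n_signature_genes=10)
        genes = sim["truth"]["signature_genes"] + ["not_in_cohort"]
        sig = GeneSignature.from_genes("sig", genes)
        filtered, result = integrate_signature(
            sig, sim["cohort"], fdr_threshold=1.0 + 1e-9,
            direction_filter=False,
        )
        assert sorted(filtered.members) == sorted(sim["truth"]["signature_genes"])
        assert (result["q"] >= result["p"] - 1e-12).all()

    def test_planted_hazard_genes_are_retained(self):
        beta = beta_for_halves_hazard_ratio(2.5)
        sim = simulate_expression_cohort(
            seed=13, n_genes=80, n_patients=300, n_signature_genes=20,
            beta=beta,
        )
        planted = sim["truth"]["signature_genes"]
        nulls = [g for g in sim["cohort"].expression.index
                 if g not in planted][:20]
        sig = GeneSignature.from_genes("mixed", planted + nulls)
        filtered, result = integrate_signature(
            sig, sim["cohort"], direction_filter=False)
        kept = set(filtered.members)
        assert len(kept & set(planted)) >= 0.8 * len(planted)
        assert len(kept & set(nulls)) <= 0.1 * len(nulls)

    def test_direction_filter_respects_declared_prognosis(self):
        beta = beta_for_halves_hazard_ratio(2.5)  # high score -> worse survival
        sim = simulate_expression_cohort(
            seed=17, n_genes=60, n_patients=250, n_signature_genes=15,
            beta=beta,
        )
        planted = sim["truth"]["signature_genes"]
        adverse = GeneSignature.from_genes("mes", planted, prognosis="adverse")
        favorable = GeneSignature.from_genes("adr", planted,
                                             prognosis="favorable")
        kept_adverse, _ = integrate_signature(adverse, sim["cohort"])
        kept_favorable, _ = integrate_signature(favorable, sim["cohort"])
        assert len(kept_adverse) >= 0.8 * len(planted)
        assert len(kept_favorable) == 0

    def test_empty_overlap_errors(self):
        sim = simulate_expression_cohort(seed=19, n_genes=20, n_patients=40)
        with pytest.raises(ValueError):
            integrate_signature(GeneSignature.from_genes("x", ["absent"]),
                                sim["cohort"])
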