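"""Synthetic-data generators: determinism, structure, forward-model audits."""

import math

import numpy as np
import pytest
from scipy import stats

from clonepulse.bulk import filter_segments, msf_from_log2r, segment_msf
from clonepulse.response import classify_response
from clonepulse.simulate import (
    ARCHETYPES,
    beta_for_halves_hazard_ratio,
    random_clone_frequencies,
    simulate_bulk_segments,
    simulate_cell_matrix,
    simulate_clone_tree,
    simulate_expression_cohort,
    simulate_volume_series,
    sweep_frequencies,
)

from conftest import SMALL_GENOME


class TestCloneTree:
    def test_single_clone_tree(self):
        tree = simulate_clone_tree(seed=1, n_clones=1,
                                   genome_model=SMALL_GENOME)
        assert tree.clones == ["C0"]
        assert tree.event_set("C0") == tree.stem_events

    def test_same_seed_is_bit_identical(self):
        a = simulate_clone_tree(seed=5, n_clones=5, genome_model=SMALL_GENOME)
        b = simulate_clone_tree(seed=5, n_clones=5, genome_model=SMALL_GENOME)
        assert a == b

    def test_event_sets_nest_along_every_lineage(self):
        for seed in range(100):
            tree = simulate_clone_tree(seed=seed, n_clones=5,
                                       events_per_branch=1,
                                       genome_model=SMALL_GENOME)
            for clone, parent in tree.parents.items():
                if parent is not None:
                    assert tree.event_set(parent) <= tree.event_set(clone)

    def test_no_overlap_within_lineage(self):
        for seed in range(30):
            tree = simulate_clone_tree(seed=seed, n_clones=4,
                                       events_per_branch=2,
                                       genome_model=SMALL_GENOME)
            for clone in tree.clones:
                events = sorted(tree.event_set(clone))
                for a, b in zip(events, events[1:]):
                    if a.chrom == b.chrom:
                        assert a.end_bin < b.start_bin or b.end_bin < a.start_bin

    def test_infeasible_event_load_errors(self):
        with pytest.raises(ValueError):
            simulate_clone_tree(seed=1, n_clones=4, events_per_branch=30,
                                genome_model={"chr1": 40})

    def test_stem_wgd_doubles_baseline(self):
        tree = simulate_clone_tree(seed=2, n_clones=2, stem_wgd=True,
                                   genome_model=SMALL_GENOME)
        assert tree.baseline_ploidy == 4

    def test_sweep_rescales_toward_winner(self):
        freqs = {"C0": 0.5, "C1": 0.3, "C2": 0.2}
        swept = sweep_frequencies(freqs, "C1", 0.8)
        assert swept["C1"] == pytest.approx(0.3 * 0.2 + 0.8)
        assert sum(swept.values()) == pytest.approx(1.0)


class TestBulkForwardModel:
    def test_noise_free_clonal_gain_in_pure_sample(self):
        tree = simulate_clone_tree(seed=3, n_clones=1, events_per_branch=1,
                                   genome_model=SMALL_GENOME,
                                   event_delta_choices=(1,))
        segs, truth = simulate_bulk_segments(
            tree, {"C0": 1.0}, purity=1.0, sigma_log2r=0.0, sigma_baf=0.0,
            seed=4,
        )
        assert segs[0].log2r == pytest.approx(math.log2(1.5))
        assert truth["msf_true"].iloc[0] == 1.0

    def test_forward_model_is_exact_inverse_at_zero_noise(self):
        for seed in range(10):
            tree = simulate_clone_tree(seed=seed, n_clones=3,
                                       genome_model=SMALL_GENOME)
            freqs = random_clone_frequencies(tree, seed=seed + 50)
            segs, truth = simulate_bulk_segments(
                tree, freqs, purity=0.8, sigma_log2r=0.0, sigma_baf=0.0,
                seed=seed,
            )
            for seg, msf_true in zip(segs, truth["msf_true"]):
                msf, flagged = segment_msf(seg)
                assert not flagged
                assert msf == pytest.approx(msf_true, abs=1e-9)
                # the mBAF route agrees with the intensity route
                from clonepulse.bulk import msf_from_mbaf
                assert msf_from_mbaf(seg.mbaf, seg.n_minor, seg.n_major) \
                    == pytest.approx(msf_true, abs=1e-9)

    def test_noisy_recovery_is_unbiased_and_calibrated(self):
        """At sigma_log2r = 0.02 the MSF inversion is unbiased and its
        error matches the propagated per-segment precision
        sd = N_p * ln2 * 2^log2R * sigma / |N_t - N_p| (95% coverage)."""
        tree = simulate_clone_tree(seed=23, n_clones=3,
                                   genome_model=SMALL_GENOME)
        freqs = random_clone_frequencies(tree, seed=24)
        sigma = 0.02
        errors, bounds = [], []
        for rep in range(150):
            segs, truth = simulate_bulk_segments(
                tree, freqs, purity=0.8, sigma_log2r=sigma, seed=300 + rep)
            for seg, msf_true in zip(segs, truth["msf_true"]):
                msf, _ = msf_from_log2r(seg.log2r, seg.n_total,
                                        seg.background_ploidy,
                                        with_flag=True)
                errors.append(msf - msf_true)
                sd = (seg.background_ploidy * math.log(2) * 2 ** seg.log2r
                      * sigma / abs(seg.n_total - seg.background_ploidy))
                bounds.append(1.96 * sd)
        errors = np.asarray(errors)
        bounds = np.asarray(bounds)
        assert len(errors) >= 900
        assert abs(errors.mean()) < 0.01  # unbiased
        coverage = (np.abs(errors) <= bounds).mean()
        assert 0.92 <= coverage

    def test_planted_decoys_fail_the_curation_filter(self):
        tree = simulate_clone_tree(seed=25, n_clones=2,
                                   genome_model=SMALL_GENOME)
        segs, truth = simulate_bulk_segments(
            tree, {"C0": 0.5, "C1": 0.5}, purity=0.9, seed=26,
            fail_filter_fraction=1.0,
        )
        kept = filter_segments(segs)
        assert len(kept) == int((~truth["below_filter"]).sum())


class TestCellMatrix:
    def test_same_seed_identical_matrix(self):
        tree = simulate_clone_tree(seed=6, n_clones=3,
                                   genome_model=SMALL_GENOME)
        mix = {"C0": 0.5, "C1": 0.3, "C2": 0.2}
        m1, t1 = simulate_cell_matrix(tree, 30, mix, seed=7)
        m2, t2 = simulate_cell_matrix(tree, 30, mix, seed=7)
        assert np.array_equal(m1.copy_state, m2.copy_state)
        assert t1.cell_to_clone == t2.cell_to_clone

    def test_mixture_counts_within_binomial_bounds(self):
        tree = simulate_clone_tree(seed=8, n_clones=3,
                                   genome_model=SMALL_GENOME)
        mix = {"C0": 0.5, "C1": 0.3, "C2": 0.2}
        _, truth = simulate_cell_matrix(tree, 100, mix, seed=9)
        counts = {}
        for clone in truth.clones:
            counts[clone] = truth.clone_sizes[clone]
        for clone, p in mix.items():
            lo = stats.binom.ppf(0.005, 100, p)
            hi = stats.binom.ppf(0.995, 100, p)
            label = clone if clone in counts else "baseline"
            assert lo <= counts.get(label, 0) <= hi

    def test_invalid_inputs_error(self):
        tree = simulate_clone_tree(seed=10, n_clones=2,
                                   genome_model=SMALL_GENOME)
        with pytest.raises(ValueError):
            simulate_cell_matrix(tree, 0, {"C0": 1.0})
        with pytest.raises(ValueError):
            simulate_cell_matrix(tree, 5, {"C0": 0.7})


class TestExpressionCohort:
    def test_deterministic_per_seed(self):
        a = simulate_expression_cohort(seed=11, n_genes=50, n_patients=30)
        b = simulate_expression_cohort(seed=11, n_genes=50, n_patients=30)
        assert a["expression"].equals(b["expression"])
        assert np.array_equal(a["cohort"].time, b["cohort"].time)

    def test_null_beta_gives_uniform_logrank_p(self):
        from clonepulse.signatures import logrank_median_split

        pvals = []
        for seed in range(300):
            sim = simulate_expression_cohort(
                seed=seed, n_genes=1, n_patients=60, n_signature_genes=1,
                beta=0.0,
            )
            _, p, _ = logrank_median_split(
                sim["cohort"].time, sim["cohort"].event, sim["score"])
            pvals.append(p)
        d = stats.kstest(pvals, "uniform").statistic
        assert d < 0.08

    def test_censoring_rate_close_to_requested(self):
        sim = simulate_expression_cohort(seed=12, n_genes=5, n_patients=2000,
                                         n_signature_genes=2,
                                         censoring_rate=0.3)
        assert 1 - sim["cohort"].event.mean() == pytest.approx(0.3, abs=0.05)

    def test_beta_for_hazard_ratio_helper(self):
        assert beta_for_halves_hazard_ratio(1.0) == 0.0
        assert beta_for_halves_hazard_ratio(2.5) == pytest.approx(
            math.log(2.5) / (2 * math.sqrt(2 / math.pi)))


class TestVolumeArchetypes:
    @pytest.mark.parametrize("archetype", ARCHETYPES)
    def test_noise_free_round_trip(self, archetype):
        s, truth = simulate_volume_series(seed=1, archetype=archetype,
                                          noise=0.0)
        call = classify_response(s)
        assert call.response == truth["expected_response"]
        assert call.relapse == truth["expected_relapse"]

    def test_unknown_archetype_errors(self):
        with pytest.raises(ValueError):
            simulate_volume_series(seed=1, archetype="bogus")

    def test_deterministic_per_seed(self):
        a, _ = simulate_volume_series(seed=2, archetype="PR")
        b, _ = simulate_volume_series(seed=2, archetype="PR")
        assert a.volumes == b.volumes
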