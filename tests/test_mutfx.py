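"""Transforms, tests, candidate selection, models, permutation, sweeps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from cpgdm import mutfx, synthio
from cpgdm.mutfx import (
    candidate_mutations,
    chromatin_state_scan,
    classify_density,
    gene_interval,
    interaction_anova,
    invnorm,
    fit_within_class_model,
    permutation_calibration,
    sweep_density_threshold,
    sweep_transcript_filter,
    welch_t,
)


class TestInvnorm:
    def test_closed_form_three_values(self):
        expect = stats.norm.ppf([1 / 6, 3 / 6, 5 / 6])
        np.testing.assert_allclose(invnorm([1, 2, 3]), expect, atol=1e-12)
        np.testing.assert_allclose(expect, [-0.9674216, 0.0, 0.9674216], atol=1e-6)

    def test_missing_values_kept_in_place(self):
        got = invnorm([5, np.nan, 7])
        assert np.isnan(got[1])
        np.testing.assert_allclose(got[[0, 2]], stats.norm.ppf([0.25, 0.75]))

    def test_ties_get_average_ranks(self):
        got = invnorm([1, 1, 2])
        # tied values share rank 1.5 -> (1.5 - 0.5)/3 = 1/3
        np.testing.assert_allclose(got[:2], stats.norm.ppf([1 / 3, 1 / 3]))

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            invnorm([np.nan, np.nan])

    @given(
        values=st.lists(
            st.floats(-1e6, 1e6, allow_nan=False), min_size=3, max_size=40, unique=True
        )
    )
    def test_monotone_rank_preserving_and_centred(self, values):
        x = np.array(values)
        y = invnorm(x)
        order = np.argsort(x)
        assert (np.diff(y[order]) > 0).all()
        assert abs(y.mean()) < 1e-6

    def test_odd_length_strictly_increasing_middle_is_zero(self):
        assert invnorm([10, 20, 30, 40, 50])[2] == pytest.approx(0.0, abs=1e-12)


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_t([1.0, 2, 3], [1.0, 2, 3])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_equal_sizes_equal_variances_matches_pooled_t(self):
        a = np.array([1.0, 2, 3, 4, 5])
        b = a + 1.5
        t, df, p = welch_t(a, b)
        sp2 = (a.var(ddof=1) + b.var(ddof=1)) / 2
        pooled = (a.mean() - b.mean()) / np.sqrt(sp2 * 2 / 5)
        assert t == pytest.approx(pooled)
        assert df == pytest.approx(8.0)

    def test_matches_textbook_formula_on_fixed_fixture(self):
        a = np.array([2.1, 3.4, 1.9, 4.0, 2.8])
        b = np.array([5.2, 4.1, 6.3, 5.8, 4.9])
        va, vb = a.var(ddof=1) / 5, b.var(ddof=1) / 5
        t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_hand = (va + vb) ** 2 / (va**2 / 4 + vb**2 / 4)
        p_hand = 2 * stats.t.sf(abs(t_hand), df_hand)
        t, df, p = welch_t(a, b)
        assert t == pytest.approx(t_hand)
        assert df == pytest.approx(df_hand)
        assert p == pytest.approx(p_hand)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])


class TestClassifyDensityAndGeneInterval:
    def test_strictly_above_threshold_is_high(self):
        assert classify_density(40.5)
        assert not classify_density(40.0)  # boundary is low

    def test_threshold_configurable(self):
        assert classify_density(39, threshold=38)

    def test_gene_interval_flanks_and_clamping(self):
        assert gene_interval(10_000, 20_000) == (8_000, 22_000)
        assert gene_interval(500, 3_000) == (0, 5_000)
        assert gene_interval(500, 3_000, flank=0) == (500, 3_000)
        assert gene_interval(500, 3_000, chrom_length=4_000) == (0, 4_000)


def _candidate_fixture():
    sites = pd.DataFrame(
        {
            "chrom": ["chr1"] * 4,
            "pos": [100, 300, 500, 700],
            "b6.call": [1.0, 1.0, 0.0, 1.0],
        }
    )
    variants = pd.DataFrame(
        {
            "chrom": ["chr1"] * 4,
            "pos": [100, 300, 500, 700],
            "ref": ["C"] * 4,
            "b6": ["C"] * 4,
            # T at a methylated site (keep), G (wrong allele), A at an
            # unmethylated site (reject), A at a methylated site (keep)
            "d2": ["T", "G", "A", "A"],
        }
    )
    segments = pd.DataFrame(
        {
            "chrom": ["chr1"], "start": [0], "end": [2000], "seg_id": [0],
            "partial": [False], "density": [50.0], "density_bin": [50],
        }
    )
    genes = pd.DataFrame(
        {
            "gene_id": ["g1"], "chrom": ["chr1"], "strand": ["+"],
            "txStart": [0], "txEnd": [1000],
        }
    )
    return sites, variants, segments, genes


class TestCandidateMutations:
    def test_selection_rules(self):
        sites, variants, segments, genes = _candidate_fixture()
        cand, counts = candidate_mutations(
            sites, variants, segments, genes,
            focal_strain="d2", reference_strain="b6",
        )
        assert sorted(cand["pos"]) == [100, 700]
        assert counts["excluded_allele"] == 1     # the G at pos 300
        assert counts["excluded_unmethylated"] == 1  # pos 500
        assert cand["high"].all()  # density 50 > 40
        assert set(cand["gene_id"]) == {"g1"}

    def test_row_order_invariance(self):
        sites, variants, segments, genes = _candidate_fixture()
        shuffled = variants.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a, _ = candidate_mutations(
            sites, variants, segments, genes, "d2", "b6"
        )
        b, _ = candidate_mutations(
            sites, shuffled, segments, genes, "d2", "b6"
        )
        key = ["chrom", "pos", "gene_id"]
        pd.testing.assert_frame_equal(
            a.sort_values(key).reset_index(drop=True),
            b.sort_values(key).reset_index(drop=True),
        )

    def test_focal_methylated_direction_swaps_roles(self):
        sites, variants, segments, genes = _candidate_fixture()
        sites["d2.call"] = [1.0, 0.0, 1.0, 1.0]
        variants["b6"] = ["T", "C", "C", "C"]
        variants["d2"] = ["C"] * 4
        cand, _ = candidate_mutations(
            sites, variants, segments, genes, "d2", "b6",
            direction="focal_methylated",
        )
        assert sorted(cand["pos"]) == [100]

    def test_mutation_in_two_gene_intervals_yields_two_records(self):
        sites, variants, segments, genes = _candidate_fixture()
        genes = pd.concat(
            [genes, pd.DataFrame({
                "gene_id": ["g2"], "chrom": ["chr1"], "strand": ["-"],
                "txStart": [600], "txEnd": [1500],
            })],
            ignore_index=True,
        )
        cand, _ = candidate_mutations(
            sites, variants, segments, genes, "d2", "b6"
        )
        assert len(cand[cand["pos"] == 700]) == 2


class TestModels:
    def test_constant_response_gives_zero_slopes(self):
        t = synthio.sample_analysis_table(300, seed=0)
        t["log2fold"] = 0.0
        fit = fit_within_class_model(t, "high", normalize=False)
        assert fit.params["mutation"] == pytest.approx(0.0, abs=1e-10)

    def test_zero_variance_predictor_dropped(self):
        t = synthio.sample_analysis_table(300, seed=1)
        t["mutation"] = False
        fit = fit_within_class_model(t, "high")
        assert "mutation" in fit.dropped_terms

    def test_single_class_design_rejected(self):
        t = synthio.sample_analysis_table(300, seed=2)
        t["high"] = True
        with pytest.raises(ValueError, match="degenerate"):
            interaction_anova(t, covariates=False)

    def test_interaction_detected_when_effect_is_high_only(self):
        t = synthio.sample_analysis_table(
            4000, seed=3, beta_high=0.3, beta_low=0.0
        )
        fit = interaction_anova(t, covariates=False)
        assert fit.fpvalue < 1e-3
        assert fit.params["high:mutation"] > 0

    def test_covariate_design_includes_states_and_chromosome(self):
        t = synthio.sample_analysis_table(500, seed=4, with_states=True)
        fit = interaction_anova(t)
        assert any(name.startswith("state_") for name in fit.params.index)
        assert any(name.startswith("chrom_") for name in fit.params.index)


class TestChromatinStateScan:
    def test_percent_mutated_hand_count(self):
        n = 1000
        t = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "log2fold": np.random.default_rng(0).normal(size=n),
                "high": [True] * n,
                "mutation": [True] * 10 + [False] * 990,
                "state": ["Quiescent"] * n,
            }
        )
        scan = chromatin_state_scan(t)
        row = scan[(scan["state"] == "Quiescent") & (scan["density_class"] == "high")]
        assert float(row["pct_mutated"].iloc[0]) == pytest.approx(1.0)
        assert int(row["n_mutation"].iloc[0]) == 10

    def test_state_with_no_mutations_has_missing_p(self):
        t = synthio.sample_analysis_table(400, seed=5, with_states=True)
        t.loc[t["state"] == "Quiescent", "mutation"] = False
        scan = chromatin_state_scan(t)
        rows = scan[scan["state"] == "Quiescent"]
        assert rows["p"].isna().all()
        assert not rows["significant_bonferroni"].any()

    def test_empty_state_track_degenerates_to_unstratified(self):
        t = synthio.sample_analysis_table(400, seed=6)  # no state column
        scan = chromatin_state_scan(t)
        assert set(scan["state"]) == {"(all)"}
        assert len(scan) == 2  # high and low


class TestPermutation:
    def test_same_seed_identical_stream(self):
        t = synthio.sample_analysis_table(300, seed=7)
        r1 = permutation_calibration(t, n_perm=20, seed=9)
        r2 = permutation_calibration(t, n_perm=20, seed=9)
        np.testing.assert_array_equal(r1.perm_stats, r2.perm_stats)
        assert r1.empirical_p == r2.empirical_p

    def test_add_one_convention(self):
        t = synthio.sample_analysis_table(
            1200, seed=8, beta_high=1.5, mean_sites=3.0
        )
        r = permutation_calibration(t, n_perm=30, seed=1)
        # a strong true effect beats every permutation
        assert r.empirical_p == pytest.approx(1 / 31)

    def test_zero_permutations_rejected(self):
        t = synthio.sample_analysis_table(100, seed=9)
        with pytest.raises(ValueError):
            permutation_calibration(t, n_perm=0, seed=0)


class TestSweeps:
    def test_single_threshold_equals_direct_interaction(self):
        t = synthio.sample_analysis_table(800, seed=10, beta_high=0.3)
        sweep = sweep_density_threshold(t, [40], covariates=False)
        direct = interaction_anova(t, covariates=False)
        assert len(sweep) == 1
        assert sweep.loc[0, "beta_interaction"] == pytest.approx(
            float(direct.params["high:mutation"])
        )
        assert sweep.loc[0, "p"] == pytest.approx(direct.fpvalue)

    def test_thresholds_outside_range_flagged_inestimable(self):
        t = synthio.sample_analysis_table(200, seed=11)
        sweep = sweep_density_threshold(t, [1, 500], covariates=False)
        assert not sweep["estimable"].any()

    def test_identity_filter_equals_unfiltered(self):
        t = synthio.sample_analysis_table(600, seed=12, beta_high=0.3)
        sweep = sweep_transcript_filter(t, [np.inf])
        direct = interaction_anova(t, covariates=False)
        assert sweep.loc[0, "beta_interaction"] == pytest.approx(
            float(direct.params["high:mutation"])
        )

    def test_retained_gene_count_monotone_in_threshold(self):
        t = synthio.sample_analysis_table(600, seed=13, struct_fraction=0.1)
        sweep = sweep_transcript_filter(t, [0.2, 0.5, 1, 2, 4, 8])
        counts = sweep["n_genes_small"].to_numpy()
        assert (np.diff(counts) >= 0).all()

    def test_large_effect_subset_shows_negative_mutation_term(self):
        t = synthio.sample_analysis_table(
            3000, seed=14, beta_high=0.16,
            struct_fraction=0.15, struct_offset=-3.0, struct_mut_beta=-0.8,
        )
        sweep = sweep_transcript_filter(t, [2.0])
        assert sweep.loc[0, "beta_mutation_large"] < 0
        assert sweep.loc[0, "p_mutation_large"] < 0.05
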