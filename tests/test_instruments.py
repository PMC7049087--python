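"""Harmonization, wGRS construction and quartile assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lpamr.instruments import (GRSVector, assign_quartiles, build_wgrs, harmonize,
                               load_example_weights)
from lpamr.mr import ivw_estimate
from lpamr.synthetic import CohortConfig, SummaryStatsConfig, generate_cohort, \
    generate_summary_stats

from conftest import make_stat_set


def _table(rows):
    return pd.DataFrame(rows, columns=["rsid", "effect_allele", "other_allele",
                                       "eaf", "beta", "se"])


class TestHarmonize:
    def test_swapped_alleles_flip_outcome_sign(self):
        exposure = _table([["rs1", "A", "G", 0.3, 10.0, 1.0]])
        outcome = _table([["rs1", "G", "A", 0.7, 0.05, 0.01]])
        s = harmonize(exposure, outcome)
        snp = s.snps.iloc[0]
        assert snp["effect_allele"] == "A"
        assert snp["beta_exp"] == 10.0
        assert snp["beta_out"] == -0.05

    def test_double_flip_is_identity(self):
        """Swapping alleles in both tables leaves the harmonized set unchanged."""
        exposure = _table([["rs1", "A", "G", 0.3, 10.0, 1.0]])
        outcome = _table([["rs1", "A", "G", 0.3, 0.05, 0.01]])
        flipped_exp = _table([["rs1", "G", "A", 0.7, -10.0, 1.0]])
        flipped_out = _table([["rs1", "G", "A", 0.7, -0.05, 0.01]])
        a = harmonize(exposure, outcome).snps
        b = harmonize(flipped_exp, flipped_out).snps
        pd.testing.assert_frame_equal(a, b)

    def test_identical_allele_columns_noop(self):
        exposure = _table([["rs1", "A", "G", 0.3, 10.0, 1.0],
                           ["rs2", "T", "C", 0.2, 5.0, 0.8]])
        outcome = _table([["rs1", "A", "G", 0.3, 0.05, 0.01],
                          ["rs2", "T", "C", 0.2, -0.02, 0.01]])
        s = harmonize(exposure, outcome)
        assert list(s.snps["beta_out"]) == [0.05, -0.02]
        assert list(s.snps["beta_exp"]) == [10.0, 5.0]

    def test_flip_invariance_of_ivw(self):
        """IVW is identical whether or not outcome rows arrive allele-flipped."""
        cfg = dict(n_snps=40, seed=13)
        s_flipped = make_stat_set(flip_fraction=0.3, **cfg)
        s_clean = make_stat_set(flip_fraction=0.0, **cfg)
        a, b = ivw_estimate(s_flipped), ivw_estimate(s_clean)
        assert a.slope == pytest.approx(b.slope, rel=1e-12)
        assert a.slope_sd == pytest.approx(b.slope_sd, rel=1e-12)

    def test_idempotence(self, default_stat_set):
        exp, out = default_stat_set.to_tables()
        again = harmonize(exp, out)
        pd.testing.assert_frame_equal(default_stat_set.snps, again.snps)

    def test_palindromic_ambiguous_dropped(self, caplog):
        exposure = _table([["rs1", "A", "T", 0.50, 10.0, 1.0],
                           ["rs2", "A", "G", 0.30, 5.0, 0.8]])
        outcome = _table([["rs1", "A", "T", 0.50, 0.05, 0.01],
                          ["rs2", "A", "G", 0.30, 0.02, 0.01]])
        s = harmonize(exposure, outcome)
        assert list(s.snps["rsid"]) == ["rs2"]

    def test_irreconcilable_alleles_dropped(self):
        exposure = _table([["rs1", "A", "G", 0.3, 10.0, 1.0],
                           ["rs2", "A", "G", 0.3, 5.0, 0.8]])
        outcome = _table([["rs1", "A", "C", 0.3, 0.05, 0.01],
                          ["rs2", "A", "G", 0.3, 0.02, 0.01]])
        s = harmonize(exposure, outcome)
        assert list(s.snps["rsid"]) == ["rs2"]

    def test_empty_intersection_fails_naming_inputs(self):
        exposure = _table([["rs1", "A", "G", 0.3, 10.0, 1.0]])
        outcome = _table([["rs9", "A", "G", 0.3, 0.05, 0.01]])
        with pytest.raises(ValueError, match="exposure.*outcome"):
            harmonize(exposure, outcome, exposure_label="exposure",
                      outcome_label="outcome")

    def test_orientation_nonnegative(self):
        exposure = _table([["rs1", "A", "G", 0.3, -10.0, 1.0]])
        outcome = _table([["rs1", "A", "G", 0.3, 0.05, 0.01]])
        s = harmonize(exposure, outcome)
        snp = s.snps.iloc[0]
        assert snp["beta_exp"] == 10.0 and snp["beta_out"] == -0.05
        assert snp["effect_allele"] == "G"


class TestWGRS:
    def test_all_zero_dosages_zero_scores(self, default_stat_set):
        n_snps = len(default_stat_set)
        dosages = pd.DataFrame(np.zeros((5, n_snps)),
                               columns=default_stat_set.snps["rsid"])
        grs = build_wgrs(dosages, default_stat_set)
        assert np.all(grs.score == 0)

    def test_single_snp_linearity(self):
        weights = pd.DataFrame({"rsid": ["rs1"], "maf": [0.2], "beta": [10.0]})
        dosages = pd.DataFrame({"rs1": [0.0, 1.0, 2.0]})
        grs = build_wgrs(dosages, weights)
        assert list(grs.score) == [0.0, 10.0, 20.0]

    def test_score_is_exact_weighted_dosage_sum(self, default_stat_set):
        rng = np.random.default_rng(0)
        rsids = list(default_stat_set.snps["rsid"])
        G = rng.integers(0, 3, size=(50, len(rsids))).astype(float)
        grs = build_wgrs(pd.DataFrame(G, columns=rsids), default_stat_set)
        expected = G @ default_stat_set.snps["beta_exp"].to_numpy()
        np.testing.assert_array_equal(grs.score, expected)

    def test_missing_imputed_to_2maf_and_cap_flags(self):
        weights = pd.DataFrame({"rsid": ["rs1", "rs2"], "maf": [0.2, 0.4],
                                "beta": [10.0, 5.0]})
        dosages = pd.DataFrame({"rs1": [np.nan, np.nan, 1.0],
                                "rs2": [1.0, np.nan, 1.0]})
        grs = build_wgrs(dosages, weights, max_missing_frac=0.5)
        # subject 0: rs1 imputed to 0.4 -> 4.0 + 5.0
        assert grs.score[0] == pytest.approx(9.0)
        # subject 1: both missing, exceeds 50% cap -> absent, not zero
        assert np.isnan(grs.score[1])
        assert grs.n_flagged == 1
        assert grs.score[2] == pytest.approx(15.0)

    def test_maf_standardize_rescales_weights(self):
        weights = pd.DataFrame({"rsid": ["rs1"], "maf": [0.5], "beta": [10.0]})
        dosages = pd.DataFrame({"rs1": [2.0]})
        plain = build_wgrs(dosages, weights)
        scaled = build_wgrs(dosages, weights, maf_standardize=True)
        # sqrt(2 * 0.5 * 0.5) = sqrt(0.5)
        assert scaled.score[0] == pytest.approx(plain.score[0] * np.sqrt(0.5))

    def test_out_of_range_dosage_rejected(self):
        weights = pd.DataFrame({"rsid": ["rs1"], "maf": [0.2], "beta": [10.0]})
        with pytest.raises(ValueError, match=r"\[0, 2\]"):
            build_wgrs(pd.DataFrame({"rs1": [3.0]}), weights)

    def test_construction_oracle_correlation(self, default_stat_set, default_weights):
        """wGRS correlates > 0.99 with the true genetic contribution to Lp(a)."""
        cohort = generate_cohort(CohortConfig(n_subjects=2000, seed=8),
                                 default_weights)
        dosages = cohort[list(default_weights["rsid"])]
        grs = build_wgrs(dosages, default_stat_set)
        truth = dosages.to_numpy() @ default_weights["beta"].to_numpy()
        assert np.corrcoef(grs.score, truth)[0, 1] > 0.99


class TestQuartiles:
    def test_eight_scores(self):
        q = assign_quartiles(np.arange(1.0, 9.0))
        assert list(q) == [1, 1, 2, 2, 3, 3, 4, 4]

    def test_degenerate_fails(self):
        with pytest.raises(ValueError, match="distinct"):
            assign_quartiles(np.full(10, 2.5))

    def test_balanced_partition_without_ties(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=20_000)
        q = assign_quartiles(scores)
        counts = np.bincount(q)[1:]
        assert np.all(np.abs(counts - 5000) <= 1)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=8, max_size=200))
    def test_partition_and_tie_properties(self, xs):
        xs = np.asarray(xs)
        if np.unique(xs).size < 4:
            return
        q = assign_quartiles(xs)
        assert set(np.unique(q)) <= {1, 2, 3, 4}
        # monotone in score, and equal scores share a quartile
        order = np.argsort(xs, kind="stable")
        assert np.all(np.diff(q[order]) >= 0)
        for v in np.unique(xs):
            assert np.unique(q[xs == v]).size == 1


def test_bundled_example_weights_load():
    for source, n_expected in (("burgess-style", 26), ("mack-style", 22),
                               ("mack-style-isoform-adjusted", 22)):
        w = load_example_weights(source)
        assert len(w) == n_expected
        assert {"rsid", "effect_allele", "other_allele", "eaf", "beta"} <= set(w.columns)
    with pytest.raises(ValueError):
        load_example_weights("nope")
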