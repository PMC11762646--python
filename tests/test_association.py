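"""Mutual information, resampling inference, correlations, k-mer spacing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirgold.association import (correlation_table, expected_kmer_count,
                                 kmer_chance_spacing, mutual_information,
                                 pearson, relative_mi, resample_mi)
from mirgold.synth import plant_utr_table

from _oracles import mi_direct, pearson_direct


class TestMutualInformation:
    def test_identity_on_balanced_binary_is_ln2(self):
        x = np.array([0.0, 1.0] * 50)
        assert mutual_information(x, x, 2, 2) == pytest.approx(math.log(2),
                                                               abs=1e-12)

    def test_constant_x_gives_zero(self):
        y = np.arange(50.0)
        assert mutual_information(np.ones(50), y) == 0.0

    def test_matches_direct_summation_on_2x2_joint(self):
        # joint counts [[2,1],[1,2]] realized as paired binary data
        x = np.array([0, 0, 0, 1, 1, 1] * 5, dtype=float)
        y = np.array([0, 0, 1, 0, 1, 1] * 5, dtype=float)
        expected = mi_direct([[2, 1], [1, 2]])
        assert mutual_information(x, y, 2, 2) == pytest.approx(expected,
                                                               abs=1e-12)
        assert expected == pytest.approx(
            (2 / 3) * math.log(4 / 3) + (1 / 3) * math.log(2 / 3), abs=1e-12)

    def test_length_mismatch_and_bad_bins(self):
        with pytest.raises(ValueError, match="length"):
            mutual_information([1.0] * 10, [1.0] * 11)
        with pytest.raises(ValueError, match="bins"):
            mutual_information([1.0] * 10, [1.0] * 10, bins_x=1)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.random(200), rng.random(200)
        assert mutual_information(x, y, 4, 7) == pytest.approx(
            mutual_information(y, x, 7, 4), abs=1e-12)

    def test_two_bin_result_equals_mi_of_coarsened_data(self):
        rng = np.random.default_rng(1)
        x, y = rng.random(500), rng.random(500)
        # coarsen explicitly to halves of the range, then treat as discrete
        cx = (x >= (x.min() + x.max()) / 2).astype(float)
        cy = (y >= (y.min() + y.max()) / 2).astype(float)
        assert mutual_information(x, y, 2, 2) == pytest.approx(
            mutual_information(cx, cy, 2, 2), abs=1e-12)


class TestRelativeMI:
    def test_self_information_is_one(self):
        rng = np.random.default_rng(2)
        x = rng.random(300)
        assert relative_mi(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_constant_vector_convention_zero(self):
        assert relative_mi(np.ones(50), np.arange(50.0)) == 0.0

    def test_independent_uniform_near_zero(self):
        rng = np.random.default_rng(3)
        x, y = rng.random(10_000), rng.random(10_000)
        assert relative_mi(x, y) < 0.02


class TestResampleMI:
    def test_identity_is_significant(self):
        rng = np.random.default_rng(4)
        x = rng.random(200)
        res = resample_mi(x, x, n_boot=200, n_perm=499, seed=5)
        assert res.p_perm <= 0.01
        assert res.rmi == pytest.approx(1.0, abs=1e-12)

    def test_point_estimate_inside_ci_on_dependent_fixture(self):
        rng = np.random.default_rng(6)
        x = rng.random(400)
        y = x + 0.2 * rng.random(400)
        res = resample_mi(x, y, n_boot=300, n_perm=100, seed=7)
        assert res.ci_low <= res.mi_nats <= res.ci_high
        assert res.ci_low <= res.ci_high

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(8)
        x, y = rng.random(100), rng.random(100)
        a = resample_mi(x, y, n_boot=100, n_perm=100, seed=9)
        b = resample_mi(x, y, n_boot=100, n_perm=100, seed=9)
        assert a == b

    def test_small_resamples_warn_but_run(self, caplog):
        rng = np.random.default_rng(10)
        x, y = rng.random(50), rng.random(50)
        with caplog.at_level("WARNING"):
            res = resample_mi(x, y, n_boot=50, n_perm=50, seed=11)
        assert "below 100" in caplog.text
        assert res.n_boot == 50

    def test_null_rejection_rate_calibrated(self):
        # independent x, y: permutation p <= 0.05 should be rare
        rejections = 0
        runs = 50
        for rep in range(runs):
            rng = np.random.default_rng(100 + rep)
            x, y = rng.random(150), rng.random(150)
            res = resample_mi(x, y, n_boot=100, n_perm=199, seed=rep)
            rejections += res.p_perm <= 0.05
        assert rejections <= runs * 0.10  # > 90% non-rejections


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1).r == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(10.0)
        assert pearson(x, -x).r == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        x, y = [1.0, 2, 3, 4], [1.0, 3, 2, 4]
        assert pearson(x, y).r == pytest.approx(0.8, abs=1e-12)
        assert pearson_direct(x, y) == pytest.approx(0.8, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson([1.0, 1, 1], [1.0, 2, 3])

    @given(st.floats(min_value=0.1, max_value=50),
           st.floats(min_value=-100, max_value=100))
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_invariant_under_positive_affine_transform(self, a, b):
        rng = np.random.default_rng(12)
        x, y = rng.random(60), rng.random(60)
        r0 = pearson(x, y).r
        assert pearson(a * x + b, y).r == pytest.approx(r0, abs=1e-12)


class TestCorrelationTable:
    def test_exact_linear_relation_and_unit_diagonal(self):
        import pandas as pd

        n = 50
        rng = np.random.default_rng(13)
        utr = rng.uniform(200, 5000, n)
        df = pd.DataFrame({
            "utr3_length": utr, "transcript_length": utr + 1500,
            "n_verified": rng.poisson(5, n).astype(float),
            "n_pred_A": utr / 100, "n_pred_B": rng.poisson(50, n).astype(float),
        })
        ct = correlation_table(df)
        assert ct.cell("utr3_length", "n_pred_A").r == pytest.approx(1.0)
        assert np.allclose(np.diag(ct.r), 1.0)
        assert np.allclose(ct.r, ct.r.T, equal_nan=True)

    def test_planted_correlations_recovered(self):
        df = plant_utr_table(500, 0.7, 0.3, seed=14)
        ct = correlation_table(df)
        assert ct.cell("utr3_length", "n_pred_A").r == pytest.approx(0.7, abs=0.1)
        assert ct.cell("utr3_length", "n_pred_B").r == pytest.approx(0.7, abs=0.1)
        assert ct.cell("utr3_length", "n_verified").r == pytest.approx(0.3, abs=0.1)

    def test_too_few_complete_rows_flagged(self):
        import pandas as pd

        df = pd.DataFrame({
            "utr3_length": [1.0, 2, 3, 4],
            "transcript_length": [2.0, 3, 4, 5],
            "n_verified": [np.nan, np.nan, 1.0, 2.0],
            "n_pred_A": [1.0, 2, np.nan, np.nan],
            "n_pred_B": [1.0, 2, 3, 4],
        })
        ct = correlation_table(df)
        assert np.isnan(ct.cell("n_verified", "n_pred_A").r)  # 0 complete rows
        assert ct.cell("utr3_length", "n_pred_B").n == 4

    def test_missing_column_is_error(self):
        import pandas as pd

        with pytest.raises(ValueError, match="missing columns"):
            correlation_table(pd.DataFrame({"utr3_length": [1.0, 2, 3]}))


class TestKmerSpacing:
    @pytest.mark.parametrize("k,expected", [(6, 4096), (1, 4), (7, 16384)])
    def test_expected_spacing(self, k, expected):
        assert kmer_chance_spacing(k) == expected

    def test_out_of_range(self):
        for k in (0, 16):
            with pytest.raises(ValueError):
                kmer_chance_spacing(k)

    def test_expected_count_in_sequence(self):
        # a 6-mer in a 4101-nt sequence is expected about once
        assert expected_kmer_count(4101, 6) == pytest.approx(1.0)
        assert expected_kmer_count(5, 6) == 0.0
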