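"""The W statistic, its contingency machinery and chi-squared calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wepistasis import (
    bootstrap_null_samples,
    build_pair_categories,
    estimate_hf,
    raw_statistic,
    tabulate_cells,
    wtest_pvalue,
)
from wepistasis.wtest import CalibrationTable, ContingencyTable

SETTINGS = dict(derandomize=True, deadline=None, max_examples=100)


def oracle_s(case_counts, control_counts):
    """Independent cell-by-cell arithmetic for the raw statistic.

    Pure-Python re-derivation: per retained category, collapse to the
    2x2 (category vs rest) x (case vs control) table, add 0.5 to all four
    entries if any is zero, and accumulate (log OR / SE)^2.
    """
    n1, n0 = sum(case_counts), sum(control_counts)
    s = 0.0
    for n1i, n0i in zip(case_counts, control_counts):
        a, b, c, d = n1i, n1 - n1i, n0i, n0 - n0i
        if 0 in (a, b, c, d):
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        log_or = math.log((a / b) / (c / d))
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        s += (log_or / se) ** 2
    return s


def make_table(case_counts, control_counts):
    case_counts = np.asarray(case_counts)
    control_counts = np.asarray(control_counts)
    n1, n0 = int(case_counts.sum()), int(control_counts.sum())
    corr = (
        (case_counts == 0) | (control_counts == 0)
        | (case_counts == n1) | (control_counts == n0)
    )
    return ContingencyTable(
        k=len(case_counts),
        case_counts=case_counts,
        control_counts=control_counts,
        n1=n1,
        n0=n0,
        category_labels=[(0, 0)] * len(case_counts),
        cell_corrected=corr,
    )


class TestBuildPairCategories:
    def test_enumeration_order(self):
        cats = build_pair_categories([0, 1, 2], [0, 1, 0])
        np.testing.assert_array_equal(cats, [0, 3, 4])

    def test_all_reference_category(self):
        np.testing.assert_array_equal(build_pair_categories([0, 0], [0, 0]), [0, 0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            build_pair_categories([0], [0, 1])


class TestTabulateCells:
    def test_counts_per_category(self):
        tab = tabulate_cells([0, 0, 3, 3], [1, 0, 1, 0])
        assert tab.k == 2
        np.testing.assert_array_equal(tab.case_counts, [1, 1])
        np.testing.assert_array_equal(tab.control_counts, [1, 1])
        assert tab.category_labels == [(0, 0), (1, 1)]

    def test_categories_empty_in_both_groups_dropped(self):
        tab = tabulate_cells([0, 0, 1, 1, 4, 4], [1, 0, 1, 0, 1, 0])
        assert tab.k == 3
        assert (2, 1) not in tab.category_labels  # index 5 never observed

    def test_zero_cell_sets_correction_flag(self):
        # category 1 holds cases only
        tab = tabulate_cells([0, 0, 1, 1, 1], [0, 1, 1, 1, 1])
        assert tab.correction_applied

    def test_single_class_phenotype_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            tabulate_cells([0, 1], [1, 1])


class TestRawStatistic:
    def test_balanced_two_cell_example(self):
        """Frozen from the independent oracle: 60/40 vs 40/60 of 100 each."""
        tab = make_table([60, 40], [40, 60])
        s, cells = raw_statistic(tab)
        assert s == pytest.approx(oracle_s([60, 40], [40, 60]), abs=1e-12)
        assert s == pytest.approx(15.782588, abs=1e-6)
        assert cells[0].log_or == pytest.approx(math.log(2.25), abs=1e-9)
        assert cells[1].log_or == pytest.approx(-math.log(2.25), abs=1e-9)
        assert cells[0].se == pytest.approx(0.2886751, abs=1e-7)

    def test_identical_distributions_give_zero(self):
        s, _ = raw_statistic(make_table([30, 20, 10], [30, 20, 10]))
        assert s == pytest.approx(0.0, abs=1e-12)

    def test_case_control_swap_symmetry(self):
        a, b = [5, 9, 2, 4], [7, 3, 6, 4]
        s1, _ = raw_statistic(make_table(a, b))
        s2, _ = raw_statistic(make_table(b, a))
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_degenerate_single_category_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            raw_statistic(make_table([10], [10]))

    def test_transferring_case_mass_increases_s(self):
        """With margins fixed, widening every |log OR| never shrinks S."""
        prev = -1.0
        for d in range(0, 41, 5):
            s, _ = raw_statistic(make_table([50 + d, 50 - d], [50, 50]))
            assert s >= prev - 1e-12
            prev = s

    @given(
        st.integers(2, 6),
        st.integers(0, 2**31 - 1),
    )
    @settings(**SETTINGS)
    def test_agrees_with_oracle_on_random_tables(self, k, seed):
        rng = np.random.default_rng(seed)
        n1, n0 = int(rng.integers(k, 31)), int(rng.integers(k, 31))
        case = rng.multinomial(n1, np.ones(k) / k)
        ctrl = rng.multinomial(n0, np.ones(k) / k)
        if (case + ctrl == 0).any():
            keep = case + ctrl > 0
            case, ctrl = case[keep], ctrl[keep]
        if len(case) < 2:
            return
        s, _ = raw_statistic(make_table(case, ctrl))
        assert s == pytest.approx(oracle_s(case.tolist(), ctrl.tolist()), abs=1e-10)


class TestCalibration:
    @pytest.mark.parametrize(
        "m,v,h,f",
        [(1.0, 2.0, 1.0, 1.0), (2.0, 4.0, 1.0, 2.0), (4.0, 16.0, 0.5, 2.0)],
    )
    def test_moment_matching_algebra(self, m, v, h, f):
        # two-point sample {m-d, m+d} has mean m, unbiased variance 2d^2
        d = math.sqrt(v / 2)
        cal = estimate_hf({6: np.array([m - d, m + d])}, floor=2)
        assert cal.entries[6].h == pytest.approx(h, abs=1e-12)
        assert cal.entries[6].f == pytest.approx(f, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(**SETTINGS)
    def test_calibration_identities_hold_exactly(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.chisquare(4, size=60)
        cal = estimate_hf({5: s}, floor=50)
        e = cal.entries[5]
        assert e.h * e.m_boot == pytest.approx(e.f, rel=1e-12)
        assert e.h**2 * e.v_boot == pytest.approx(2 * e.f, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            estimate_hf({4: np.array([3.0, 3.0, 3.0])})

    def test_small_groups_fall_back_to_pooled(self, rng):
        big = rng.chisquare(5, 500)
        small = rng.chisquare(3, 5)
        cal = estimate_hf({6: big, 3: small}, floor=50)
        assert cal.entries[3].pooled_fallback
        assert cal.entries[3].h == cal.pooled.h
        assert not cal.entries[6].pooled_fallback

    def test_estimated_f_tracks_category_count(self, rng):
        """On balanced null tables, f lands near k-1 (wide band [k-2, k])."""
        for k in (4, 5, 6):
            samples = []
            for _ in range(2000):
                case = rng.multinomial(1000, np.ones(k) / k)
                ctrl = rng.multinomial(1000, np.ones(k) / k)
                samples.append(raw_statistic(make_table(case, ctrl))[0])
            f = estimate_hf({k: np.array(samples)}).entries[k].f
            assert k - 2 <= f <= k

    def test_tsv_round_trip(self, tmp_path, rng):
        cal = estimate_hf({5: rng.chisquare(4, 100), 6: rng.chisquare(5, 100)}, floor=50)
        path = tmp_path / "cal.tsv"
        cal.to_tsv(path)
        back = CalibrationTable.from_tsv(path)
        for k in (5, 6):
            assert back.entries[k].h == pytest.approx(cal.entries[k].h, rel=1e-9)
            assert back.entries[k].f == pytest.approx(cal.entries[k].f, rel=1e-9)
        assert back.pooled.f == pytest.approx(cal.pooled.f, rel=1e-9)


class TestWtestPvalue:
    def _cal(self, h, f):
        from wepistasis.wtest import CalibrationEntry

        entry = CalibrationEntry(h=h, f=f, m_boot=f / h, v_boot=2 * f / h**2, n_samples=100)
        return CalibrationTable(entries={6: entry}, pooled=entry)

    def test_zero_statistic_gives_p_one(self):
        res = wtest_pvalue(0.0, self._cal(1.0, 1.0), 6)
        assert res.W == 0.0
        assert res.p_value == 1.0

    def test_chi2_1df_95th_percentile(self):
        res = wtest_pvalue(3.841459, self._cal(1.0, 1.0), 6)
        assert res.p_value == pytest.approx(0.0500, abs=1e-4)

    def test_chi2_2df_closed_form_tail(self):
        res = wtest_pvalue(10.0, self._cal(0.5, 2.0), 6)
        assert res.W == pytest.approx(5.0)
        assert res.p_value == pytest.approx(math.exp(-2.5), rel=1e-9)

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            wtest_pvalue(-1.0, self._cal(1.0, 1.0), 6)


class TestBootstrapNullSamples:
    @pytest.fixture
    def cohort_arrays(self, rng):
        n = 120
        codes = rng.integers(0, 3, size=(n, 3)).astype(float)
        labels = rng.integers(0, 2, size=(n, 3)).astype(np.int8)
        y = rng.integers(0, 2, size=n).astype(np.int8)
        return codes, labels, y

    def test_same_seed_reproduces_samples(self, cohort_arrays):
        codes, labels, y = cohort_arrays
        pairs = [(0, 0), (1, 2)]
        a = bootstrap_null_samples(codes, labels, y, pairs, B=150, seed=42)
        b = bootstrap_null_samples(codes, labels, y, pairs, B=150, seed=42)
        assert a.keys() == b.keys()
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])

    def test_group_sizes_sum_to_b(self, cohort_arrays):
        codes, labels, y = cohort_arrays
        out = bootstrap_null_samples(codes, labels, y, [(0, 0)], B=200, seed=1)
        assert sum(len(v) for v in out.values()) == 200

    def test_invalid_b_rejected(self, cohort_arrays):
        codes, labels, y = cohort_arrays
        with pytest.raises(ValueError, match="B must be"):
            bootstrap_null_samples(codes, labels, y, [(0, 0)], B=0, seed=1)

    def test_no_candidate_pairs_rejected(self, cohort_arrays):
        codes, labels, y = cohort_arrays
        with pytest.raises(ValueError, match="no candidate pairs"):
            bootstrap_null_samples(codes, labels, y, [], B=100, seed=1)

    def test_oversized_subsample_rejected(self, cohort_arrays):
        codes, labels, y = cohort_arrays
        with pytest.raises(ValueError, match="subsample_size"):
            bootstrap_null_samples(codes, labels, y, [(0, 0)], B=100,
                                   subsample_size=500, seed=1)
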