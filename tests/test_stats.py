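"""Audic-Claverie statistic, adjustment, and the DEG calling rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln

from tagdge import DegThresholds, ac_pvalue, adjust, call_degs, tpm
from tagdge.mapping import GeneCountTable

from conftest import ac_oracle


class TestTpm:
    @pytest.mark.parametrize(
        "count,total,expected",
        [
            (10, 1_000_000, 10.0),
            (0, 12345, 0.0),
            (23, 9_212_390, 23 / 9_212_390 * 1e6),
        ],
    )
    def test_definition(self, count, total, expected):
        assert tpm(count, total) == pytest.approx(expected, rel=1e-12)

    def test_rejects_zero_total(self):
        with pytest.raises(ValueError):
            tpm(1, 0)


def _point_mass(x, y, n1, n2):
    r = n2 / n1
    return float(
        np.exp(
            y * np.log(r)
            + gammaln(x + y + 1)
            - gammaln(x + 1)
            - gammaln(y + 1)
            - (x + y + 1) * np.log1p(r)
        )
    )


class TestAcPvalue:
    def test_balanced_equal_counts_give_pvalue_one(self):
        assert ac_pvalue(5, 5, 10**6, 10**6) == 1.0

    def test_extreme_imbalance_is_significant(self):
        p = ac_pvalue(0, 20, 10**6, 10**6)
        assert p == pytest.approx(ac_oracle(0, 20, 10**6, 10**6), rel=1e-10)
        assert p < 1e-4

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            ac_pvalue(-1, 3, 10, 10)

    @pytest.mark.parametrize("ratio", [0.5, 1.0, 2.0])
    def test_matches_exact_summation_oracle_on_grid(self, ratio):
        n1 = 10**6
        n2 = int(n1 * ratio)
        for x in range(0, 201, 13):
            for y in range(0, 201, 13):
                expected = ac_oracle(x, y, n1, n2)
                assert ac_pvalue(x, y, n1, n2) == pytest.approx(expected, rel=1e-10)

    def test_stable_for_large_counts(self):
        # counts up to 1e6 against totals up to 1e8: finite, in [0, 1],
        # and a moderate imbalance keeps a representable non-degenerate p
        p = ac_pvalue(10**6, 998_000, 10**8, 10**8)
        assert 0.0 < p < 1.0 and np.isfinite(p)
        assert p == pytest.approx(ac_oracle(10**6, 998_000, 10**8, 10**8), rel=1e-8)
        extreme = ac_pvalue(10**6, 10**4, 10**8, 10**8)
        assert np.isfinite(extreme) and 0.0 <= extreme < p

    @given(
        x=st.integers(0, 150),
        y=st.integers(0, 150),
        n1=st.integers(10**4, 10**7),
        n2=st.integers(10**4, 10**7),
    )
    @settings(max_examples=200, deadline=None)
    def test_orientation_swap_agrees_within_point_mass(self, x, y, n1, n2):
        """The doubled-min-tail p is symmetric up to the observed point's mass.

        Each orientation includes the observed table in both of its tails, so
        the two orientations' minimal tails differ by at most that table's
        point mass; exact equality holds in the balanced diagonal case.
        """
        a = ac_pvalue(x, y, n1, n2)
        b = ac_pvalue(y, x, n2, n1)
        bound = 2 * max(_point_mass(x, y, n1, n2), _point_mass(y, x, n2, n1))
        assert abs(a - b) <= bound + 1e-12
        if x == y and n1 == n2:
            assert a == pytest.approx(b, rel=1e-12)


class TestAdjust:
    @pytest.mark.parametrize(
        "pvals,method,expected",
        [
            ([0.01], "bonferroni", [0.01]),
            ([0.01, 0.02], "bonferroni", [0.02, 0.04]),
            ([0.01, 0.02, 0.03, 0.04], "bh", [0.04, 0.04, 0.04, 0.04]),
            # hand-computed step-up: m*p/rank then enforce monotonicity
            ([0.01, 0.04, 0.03, 0.005], "bh", [0.02, 0.04, 0.04, 0.02]),
        ],
    )
    def test_known_adjustments(self, pvals, method, expected):
        assert adjust(pvals, method) == pytest.approx(expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            adjust([0.5, 1.5], "bh")

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_qvalues_dominate_pvalues(self, pvals):
        for method in ("bonferroni", "bh"):
            q = adjust(pvals, method)
            assert np.all(q >= np.asarray(pvals) - 1e-12)
            assert np.all(q <= 1.0 + 1e-12)


def _table(counts, total, sample_id="s"):
    return GeneCountTable(
        sample_id=sample_id,
        counts=counts,
        clean_tag_total=total,
        unmapped_count=total - sum(counts.values()),
    )


class TestCallDegs:
    def test_low_tpm_in_both_libraries_is_excluded(self):
        n = 10**6
        control = _table({"g": 5, "ref": n - 100}, n)  # 5 TPM
        treatment = _table({"g": 8, "ref": n - 100}, n)  # 8 TPM
        records = {r.gene_id: r for r in call_degs(control, treatment)}
        assert "g" not in records
        assert "ref" in records  # high in at least one library

    def test_zero_count_defaults_to_one_and_calls_tier2_down(self):
        n = 10**6
        control = _table({"g": 100, "ref": 10**5}, n)
        treatment = _table({"g": 0, "ref": 10**5}, n)
        record = {r.gene_id: r for r in call_degs(control, treatment)}["g"]
        assert record.log2_ratio == pytest.approx(np.log2(1 / 100), abs=1e-9)
        assert record.p_value == pytest.approx(ac_oracle(100, 0, n, n), rel=1e-9)
        assert record.call == "down" and record.tier == "tier2"

    def test_small_fold_change_stays_unchanged_despite_significance(self):
        n = 10**6
        control = _table({"g": 100_000, "ref": 200}, n)
        treatment = _table({"g": 60_000, "ref": 200}, n)
        record = {r.gene_id: r for r in call_degs(control, treatment)}["g"]
        assert abs(record.log2_ratio) < 1
        assert record.p_value < 1e-4  # hugely significant, but below the fold floor
        assert record.call == "unchanged" and record.tier == "none"

    def test_permissive_thresholds_record_every_gene(self):
        n = 1000
        counts_c = {f"g{i}": i for i in range(6)}
        counts_t = {f"g{i}": 5 - i for i in range(6)}
        thresholds = DegThresholds(
            min_tpm=1e-9, log2_tier1=1e-9, log2_tier2=1e-9, fdr_max=1.0, p_max=1.0
        )
        records = call_degs(_table(counts_c, n), _table(counts_t, n), thresholds)
        assert len(records) == 6

    def test_mismatched_universes_rejected(self):
        with pytest.raises(ValueError):
            call_degs(_table({"a": 1}, 10), _table({"b": 1}, 10))

    def test_pvalue_threshold_is_conjoint_with_fdr(self):
        # a gene can pass FDR yet fail the raw-p ceiling; it must stay unchanged
        n = 10**4
        control = _table({"g": 40, "ref": 5000}, n)
        treatment = _table({"g": 15, "ref": 5000}, n)
        loose = DegThresholds(fdr_max=0.9, p_max=1e-4)
        record = {r.gene_id: r for r in call_degs(control, treatment, loose)}["g"]
        assert record.p_value > 1e-4
        assert record.call == "unchanged"
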