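import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pleioconj.cfdr import (compute_cfdr, conditional_fdr, conjunctional_fdr,
                            enforce_monotone, select_loci)
from pleioconj.sumstats import PairedStats

from _oracles import cfdr_bruteforce


def _make_paired(p1, p2):
    n = len(p1)
    return PairedStats(df=pd.DataFrame({
        "variant_id": [f"rs{i}" for i in range(n)], "chrom": "1",
        "pos": 1000 + 5000 * np.arange(n), "z1": 0.0, "z2": 0.0,
        "p1": p1, "p2": p2}))


class TestConditional:
    def test_all_inclusive_conditioning_stratum(self, random_paired):
        p1 = np.array([0.001] + [0.5] * 9)
        paired = random_paired(10, p1=p1, p2=np.ones(10))
        vals = conditional_fdr(paired, 1)
        assert vals[0] == pytest.approx(0.001 * 10 / 1, rel=1e-12)

    def test_worked_five_snp_values(self, worked_five):
        c12 = conditional_fdr(worked_five, 1)
        # A: 0.001 * 1/1; B: 0.01 * 4/2 (hand-counted dominance sets)
        assert c12[0] == pytest.approx(0.001, rel=1e-12)
        assert c12[1] == pytest.approx(0.02, rel=1e-12)

    def test_direction_two_swaps_the_roles(self, worked_five):
        c21 = conditional_fdr(worked_five, 2)
        assert c21[1] == pytest.approx(0.5, rel=1e-12)  # B: 0.5 * 2/2

    def test_capped_at_one(self, random_paired):
        paired = random_paired(20, p1=np.full(20, 1.0), p2=np.full(20, 1.0))
        assert (conditional_fdr(paired, 1) <= 1.0).all()

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(2, 200), st.booleans())
    def test_equals_bruteforce_oracle(self, seed, n, with_ties):
        rng = np.random.default_rng(seed)
        p1 = rng.uniform(size=n)
        p2 = rng.uniform(size=n)
        if with_ties:
            p1 = np.round(p1, 2).clip(0.01, 1)
            p2 = np.round(p2, 1).clip(0.1, 1)
        paired = _make_paired(p1, p2)
        for direction, (prim, cond) in ((1, (p1, p2)), (2, (p2, p1))):
            np.testing.assert_allclose(conditional_fdr(paired, direction),
                                       cfdr_bruteforce(prim, cond), rtol=0,
                                       atol=1e-12)

    def test_degenerate_conditioning_reduces_to_bh(self, random_paired):
        """With identical p2, cFDR(p1|p2) = p1 * n / rank(p1)."""
        rng = np.random.default_rng(3)
        n = 500
        p1 = rng.uniform(size=n)
        paired = random_paired(n, p1=p1, p2=np.full(n, 0.7))
        vals = conditional_fdr(paired, 1)
        rank = np.searchsorted(np.sort(p1), p1, side="right")
        np.testing.assert_allclose(vals, np.minimum(p1 * n / rank, 1.0),
                                   rtol=0, atol=1e-12)


class TestMonotone:
    def _paired(self, p1, p2):
        n = len(p1)
        return PairedStats(df=pd.DataFrame({
            "variant_id": [f"r{i}" for i in range(n)], "chrom": "1",
            "pos": np.arange(n), "z1": 0.0, "z2": 0.0, "p1": p1, "p2": p2}))

    def test_min_from_right_within_band(self):
        paired = self._paired([0.1, 0.2, 0.3], [0.5, 0.5, 0.5])
        out = enforce_monotone(np.array([0.01, 0.005, 0.02]), paired, 1,
                               n_bands=1)
        np.testing.assert_allclose(out, [0.005, 0.005, 0.02], atol=0)

    def test_monotone_input_is_fixed_point(self):
        paired = self._paired([0.1, 0.2, 0.3], [0.5, 0.5, 0.5])
        vals = np.array([0.01, 0.02, 0.03])
        np.testing.assert_allclose(enforce_monotone(vals, paired, 1, 1), vals)

    def test_constant_input_unchanged(self):
        paired = self._paired([0.1, 0.2, 0.3], [0.5, 0.5, 0.5])
        vals = np.full(3, 0.02)
        np.testing.assert_allclose(enforce_monotone(vals, paired, 1, 1), vals)

    def test_bands_separate_conditioning_levels(self):
        # two bands: the small-p2 half must not borrow minima from the other
        paired = self._paired([0.1, 0.2, 0.1, 0.2],
                              [0.01, 0.01, 0.9, 0.9])
        raw = np.array([0.5, 0.4, 0.05, 0.01])
        out = enforce_monotone(raw, paired, 1, n_bands=2)
        np.testing.assert_allclose(out, [0.4, 0.4, 0.01, 0.01], atol=0)


class TestConjunctionAndSelection:
    def test_conjunction_is_elementwise_max(self, worked_five):
        c12 = conditional_fdr(worked_five, 1)
        c21 = conditional_fdr(worked_five, 2)
        conj = conjunctional_fdr(c12, c21)
        assert conj[1] == pytest.approx(0.5)  # B: max(0.02, 0.5)
        assert (conj >= c12).all() and (conj >= c21).all()
        np.testing.assert_allclose(conjunctional_fdr(c12, c12), c12)

    def test_mismatched_sets_rejected(self):
        with pytest.raises(ValueError):
            conjunctional_fdr(np.ones(3), np.ones(4))

    def test_boundary_value_not_selected(self):
        rec = pd.DataFrame({"SNP": ["a"], "CHR": ["1"], "BP": [1],
                            "P1": [0.1], "P2": [0.1], "CFDR12": [0.5],
                            "CFDR21": [0.5], "CONJFDR": [0.05]})
        assert len(select_loci(rec, "conjunctional", 0.05)) == 0

    def test_conditional_default_threshold_filters(self):
        rec = pd.DataFrame({"SNP": ["a", "b"], "CHR": "1", "BP": [1, 2],
                            "P1": [0.1, 0.1], "P2": [0.1, 0.1],
                            "CFDR12": [0.002, 0.02], "CFDR21": [0.5, 0.5],
                            "CONJFDR": [0.5, 0.5]})
        sel = select_loci(rec, "conditional")
        assert list(sel["SNP"]) == ["a"]
        assert sel["threshold"].iloc[0] == 0.01

    def test_selection_monotone_in_threshold(self, random_paired):
        records = compute_cfdr(random_paired(400, seed=7))
        low = set(select_loci(records, "conjunctional", 0.2)["SNP"])
        high = set(select_loci(records, "conjunctional", 0.4)["SNP"])
        assert low.issubset(high)

    def test_exclude_region_removes_snps(self):
        rec = pd.DataFrame({"SNP": ["a", "b"], "CHR": ["6", "7"],
                            "BP": [26_000_000, 26_000_000],
                            "P1": [0.1, 0.1], "P2": [0.1, 0.1],
                            "CFDR12": [0.001, 0.001], "CFDR21": [0.001, 0.001],
                            "CONJFDR": [0.001, 0.001]})
        sel = select_loci(rec, "conjunctional",
                          exclude_region=("6", 25e6, 34e6))
        assert list(sel["SNP"]) == ["b"]


class TestComputeTable:
    def test_columns_and_definitional_invariants(self, random_paired):
        records = compute_cfdr(random_paired(300, seed=5))
        assert list(records.columns) == ["SNP", "CHR", "BP", "P1", "P2",
                                         "CFDR12", "CFDR21", "CONJFDR"]
        np.testing.assert_allclose(
            records["CONJFDR"],
            np.maximum(records["CFDR12"], records["CFDR21"]), atol=0)
        for col in ("CFDR12", "CFDR21", "CONJFDR"):
            assert (records[col] > 0).all() and (records[col] <= 1).all()

    def test_monotone_only_lowers_values(self, random_paired):
        paired = random_paired(300, seed=6)
        raw = compute_cfdr(paired, monotone=False)
        mono = compute_cfdr(paired, monotone=True)
        assert (mono["CFDR12"] <= raw["CFDR12"] + 1e-15).all()
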