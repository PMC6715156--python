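"""Trait preparation: CMM filter, agglomeration, CSS, RINT,
internal-standard normalization and log2."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pleioscan.preprocess import (
    agglomerate,
    cmm_filter,
    css_normalize,
    internal_standard_normalize,
    log2_metabolites,
    rank_inverse_normal,
)


def table(rows, columns=None, index=None):
    return pd.DataFrame(rows, columns=columns, index=index)


class TestCmmFilter:
    def test_inclusive_boundary(self):
        counts = table({"f": [5, 0, 0, 0, 0]})  # present in 1 of 5 = 0.20
        assert list(cmm_filter(counts, 0.20).columns) == ["f"]

    def test_prevalence_counting(self):
        counts = table({"a": [1, 1, 0, 0, 0], "b": [2, 3, 1, 1, 0], "c": [0] * 5})
        kept = cmm_filter(counts, 0.20)
        assert list(kept.columns) == ["a", "b"]

    def test_idempotent(self):
        counts = table({"a": [1, 0, 0, 0, 0], "b": [1, 1, 1, 1, 1]})
        once = cmm_filter(counts, 0.2)
        pd.testing.assert_frame_equal(cmm_filter(once, 0.2), once)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cmm_filter(pd.DataFrame())


class TestAgglomerate:
    TAX = pd.Series(
        {
            "e1": "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Lachnospiraceae;g__Blautia;s__",
            "e2": "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Lachnospiraceae;g__Blautia;s__x",
            "e3": "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Lachnospiraceae;g__Roseburia;s__",
            "e4": "k__Bacteria;p__Bacteroidetes;c__Bacteroidia;o__Bacteroidales;f__S24-7;g__;s__",
            "e5": "k__Bacteria;p__Bacteroidetes;c__Bacteroidia;o__Bacteroidales;f__S24-7;g__;s__",
        }
    )

    def test_same_genus_sums(self):
        counts = table({"e1": [3], "e2": [4]})
        agg, _ = agglomerate(counts, self.TAX, "genus")
        assert agg.shape[1] == 1
        assert agg.iloc[0, 0] == 7

    def test_unassigned_bucketed_under_parent(self):
        counts = table({"e1": [1], "e4": [2]})
        agg, groups = agglomerate(counts, self.TAX, "genus")
        assert "unclassified-f__S24-7" in agg.columns
        assert groups["e4"] == "unclassified-f__S24-7"

    def test_family_collapse_conserves_totals(self):
        counts = table({f"e{i}": np.random.default_rng(i).integers(0, 9, 4) for i in range(1, 6)})
        agg, _ = agglomerate(counts, self.TAX, "family")
        assert agg.shape[1] == 2
        np.testing.assert_array_equal(agg.sum(axis=1), counts.sum(axis=1))

    def test_phylum_collapse_conserves_totals(self):
        counts = table({f"e{i}": [i, 2 * i] for i in range(1, 6)})
        agg, _ = agglomerate(counts, self.TAX, "phylum")
        np.testing.assert_array_equal(agg.sum(axis=1), counts.sum(axis=1))

    def test_malformed_lineage_names_feature(self):
        tax = pd.Series({"bad": "k__A;x__oops"})
        with pytest.raises(ValueError, match="bad"):
            agglomerate(table({"bad": [1]}), tax, "phylum")


class TestCssNormalize:
    def test_hand_case(self):
        counts = table({"a": [10], "b": [10], "c": [10], "d": [10]})
        out = css_normalize(counts, quantile_l=0.5, scale_constant=1000)
        np.testing.assert_allclose(out.to_numpy(), 250.0)

    def test_scale_invariance_single_sample(self):
        rng = np.random.default_rng(4)
        base = rng.integers(0, 50, size=(3, 12))
        base[:, 0] += 1  # keep every sample non-empty
        counts = pd.DataFrame(base)
        scaled = counts.copy()
        scaled.iloc[1] *= 7
        out1, out2 = css_normalize(counts), css_normalize(scaled)
        np.testing.assert_allclose(out1.iloc[1], out2.iloc[1], rtol=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 6), st.integers(3, 15))
    def test_library_size_invariance_property(self, seed, n, m):
        rng = np.random.default_rng(seed)
        counts = pd.DataFrame(rng.integers(0, 30, size=(n, m)) + (rng.random((n, m)) < 0.3))
        counts.iloc[:, 0] += 1
        factors = rng.integers(1, 100, size=n)
        scaled = counts.mul(factors, axis=0)
        np.testing.assert_allclose(
            css_normalize(counts).to_numpy(), css_normalize(scaled).to_numpy(), rtol=1e-9
        )

    def test_all_zero_sample_named(self):
        counts = table({"a": [1, 0], "b": [2, 0]}, index=["s1", "s2"])
        with pytest.raises(ValueError, match="s2"):
            css_normalize(counts)


class TestRankInverseNormal:
    def test_middle_of_three_is_zero(self):
        out = rank_inverse_normal(np.array([5.0, 1.0, 9.0]))
        assert out[0] == pytest.approx(0.0, abs=1e-12)

    def test_blom_offset_smallest_of_three(self):
        out = rank_inverse_normal(np.array([5.0, 1.0, 9.0]), offset_c=3 / 8)
        expected = stats.norm.ppf((1 - 3 / 8) / (3 - 2 * 3 / 8 + 1))
        assert out[1] == pytest.approx(expected, abs=1e-6)
        assert out[1] == pytest.approx(-0.8694, abs=5e-4)

    def test_ties_get_identical_outputs(self):
        out = rank_inverse_normal(np.array([2.0, 2.0, 1.0, 5.0]))
        assert out[0] == out[1]

    def test_mean_near_zero_and_monotone(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=101)
        out = rank_inverse_normal(x)
        assert abs(out.mean()) < 1e-6
        order = np.argsort(x)
        assert np.all(np.diff(out[order]) >= 0)

    def test_missing_stays_missing(self):
        x = pd.Series([1.0, np.nan, 3.0, 2.0])
        out = rank_inverse_normal(x)
        assert np.isnan(out.iloc[1]) and np.isfinite(out.drop(index=1)).all()

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            rank_inverse_normal(np.array([2.0, 2.0, 2.0]))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            rank_inverse_normal(np.array([1.0, 2.0]))


class TestInternalStandardNormalize:
    def test_hand_case(self):
        df = table({"met": [100.0, 200.0], "IS_d4CDCA": [10.0, 20.0]})
        out = internal_standard_normalize(df)
        np.testing.assert_allclose(out["met"], [150.0, 150.0])

    def test_equal_is_areas_identity(self):
        df = table({"met": [3.0, 8.0, 1.0], "IS_d4CDCA": [7.0, 7.0, 7.0]})
        out = internal_standard_normalize(df)
        np.testing.assert_allclose(out["met"], df["met"])

    def test_single_sample_identity(self):
        df = table({"met": [42.0], "IS_d4CDCA": [5.0]})
        np.testing.assert_allclose(internal_standard_normalize(df)["met"], [42.0])

    def test_zeros_preserved(self):
        df = table({"met": [0.0, 10.0], "IS_d4CDCA": [2.0, 4.0]})
        assert internal_standard_normalize(df)["met"].iloc[0] == 0.0

    def test_idempotent_with_constant_is(self):
        df = table({"met": [100.0, 200.0], "IS_d4CDCA": [10.0, 20.0]})
        out = internal_standard_normalize(df)
        out["IS_d4CDCA"] = 15.0  # the mean of the consumed IS channel
        out2 = internal_standard_normalize(out)
        np.testing.assert_allclose(out2["met"], [150.0, 150.0])

    def test_zero_is_names_sample(self):
        df = table({"met": [1.0, 2.0], "IS_d4CDCA": [3.0, 0.0]}, index=["s1", "s2"])
        with pytest.raises(ValueError, match="s2"):
            internal_standard_normalize(df)


class TestTraitTable:
    def test_transform_transitions_enforced(self):
        from pleioscan.preprocess import TraitTable

        t = TraitTable(pd.DataFrame({"m": [1.0, 2.0]}))
        t.set_transform("m", "css")
        t.set_transform("m", "rint")
        with pytest.raises(ValueError, match="transition"):
            t.set_transform("m", "log2")  # rint -> log2 is not a valid chain


class TestLog2Metabolites:
    def test_examples(self):
        assert log2_metabolites(table({"m": [8.0]})).iloc[0, 0] == pytest.approx(3.0)
        assert log2_metabolites(table({"m": [0.0]}), pseudo=1).iloc[0, 0] == pytest.approx(0.0)

    def test_doubling_adds_one(self):
        df = table({"m": [1.0, 4.0, 32.0]})
        np.testing.assert_allclose(
            log2_metabolites(2 * df).to_numpy(), log2_metabolites(df).to_numpy() + 1.0
        )

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            log2_metabolites(table({"m": [-1.0]}))
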