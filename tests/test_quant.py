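"""Loading normalization, abundance indexing, categories, contaminants."""

import numpy as np
import pandas as pd
import pytest

from chromatophore.digest import DigestParams, ProteinRecord, expected_peptide_count
from chromatophore.quant import (
    ContaminantRules,
    abundance_index,
    abundance_table,
    category_percentages,
    contaminant_filter,
    loading_factors,
    normalize_loading,
)


def table_from(data, samples):
    return pd.DataFrame(data, columns=samples, index=[f"P{i}" for i in range(len(data))])


class TestLoadingFactors:
    def test_ratios_by_construction(self):
        t = table_from([[1000, 2200, 1800]], ["A", "B", "C"])
        lf = loading_factors(t, reference="A")
        assert lf.factors == {"A": 1.0, "B": 2.2, "C": 1.8}

    def test_equal_totals_give_unit_factors(self):
        t = table_from([[5, 5, 5]], ["A", "B", "C"])
        assert set(loading_factors(t).factors.values()) == {1.0}

    def test_min_total_reference_yields_factors_ge_one(self):
        t = table_from([[10, 22, 18]], ["y", "r", "b"])
        lf = loading_factors(t)  # default min-total
        assert lf.reference == "y"
        assert all(f >= 1.0 for f in lf.factors.values())

    def test_unknown_reference_rejected(self):
        t = table_from([[1, 2]], ["A", "B"])
        with pytest.raises(KeyError):
            loading_factors(t, reference="Z")

    def test_zero_total_reference_rejected(self):
        t = table_from([[0, 2]], ["A", "B"])
        with pytest.raises(ValueError):
            loading_factors(t, reference="A")


class TestNormalizeLoading:
    def test_division_by_factor(self):
        t = table_from([[10, 22]], ["A", "B"])
        lf = loading_factors(t, reference="A")
        norm = normalize_loading(t, lf)
        assert norm.loc["P0", "B"] == pytest.approx(10.0)
        assert norm.loc["P0", "A"] == 10  # reference unchanged

    def test_sample_mismatch_rejected(self):
        t = table_from([[10, 22]], ["A", "B"])
        lf = loading_factors(t, reference="A")
        with pytest.raises(ValueError, match="mismatch"):
            normalize_loading(t.rename(columns={"B": "C"}), lf)

    def test_scale_invariance(self):
        """Scaling one sample's counts scales its factor and leaves the
        normalized column unchanged."""
        t = table_from([[10, 22], [5, 11]], ["A", "B"])
        lf = loading_factors(t, reference="A")
        t2 = t.copy()
        t2["B"] = t2["B"] * 7
        lf2 = loading_factors(t2, reference="A")
        assert lf2["B"] == pytest.approx(7 * lf["B"])
        pd.testing.assert_frame_equal(
            normalize_loading(t, lf), normalize_loading(t2, lf2)
        )


class TestAbundanceIndex:
    def test_arithmetic(self):
        assert abundance_index(10, 20, 65.5) == pytest.approx(32.75)

    def test_identity_when_kp_equals_kbar(self):
        assert abundance_index(7.0, 4, 4.0) == pytest.approx(7.0)

    def test_zero_count_gives_zero(self):
        assert abundance_index(0, 13, 65.5) == 0.0

    def test_zero_kp_rejected(self):
        with pytest.raises(ValueError):
            abundance_index(1, 0, 65.5)


class TestAbundanceTable:
    def test_single_protein_identity_case(self):
        prot = [ProteinRecord("P0", "MKTAYR")]  # k_p = 2, k_bar = 2
        t = table_from([[5]], ["y"])
        res = abundance_table(t, prot)
        assert res.values.loc["P0", "y"] == pytest.approx(5.0)

    def test_matches_step_by_step_hand_computation(self, small_proteome):
        t = pd.DataFrame(
            {"y": [10, 5, 2], "r": [22, 11, 0], "b": [18, 9, 9]},
            index=["P1", "P2", "P3"],
        )
        res = abundance_table(t, small_proteome, reference="y")
        # independent composition of the three steps
        totals = t.sum(axis=0)
        factors = totals / totals["y"]
        norm = t / factors
        k_p = {p.id: expected_peptide_count(p) for p in small_proteome}
        k_bar = np.mean(list(k_p.values()))
        for pid in t.index:
            for s in t.columns:
                expect = norm.loc[pid, s] / k_p[pid] * k_bar
                assert res.values.loc[pid, s] == pytest.approx(expect)

    def test_rank_preservation_within_sample(self, small_proteome):
        t = pd.DataFrame({"y": [40, 10, 3]}, index=["P1", "P2", "P3"])
        res = abundance_table(t, small_proteome)
        k_p = res.k_p
        raw_ratio = (t["y"] / k_p).rank()
        assert (res.values["y"].rank() == raw_ratio).all()

    def test_integer_view_rounds_half_away_from_zero(self, small_proteome):
        t = pd.DataFrame({"y": [1, 1, 1]}, index=["P1", "P2", "P3"])
        res = abundance_table(t, small_proteome)
        expect = np.sign(res.values) * np.floor(np.abs(res.values) + 0.5)
        assert (res.integer.to_numpy() == expect.to_numpy().astype(int)).all()

    def test_granule_mode_skips_loading_normalization(self, small_proteome):
        t = pd.DataFrame({"y": [10, 5, 2], "r": [100, 50, 20]},
                         index=["P1", "P2", "P3"])
        res = abundance_table(t, small_proteome, loading_normalize=False)
        assert res.factors is None
        # columns scale with raw counts, not equalized totals
        ratio = res.values["r"] / res.values["y"]
        assert np.allclose(ratio, 10.0)

    def test_missing_sequence_lists_ids(self, small_proteome):
        t = pd.DataFrame({"y": [1, 1]}, index=["P1", "PX"])
        with pytest.raises(KeyError, match="PX"):
            abundance_table(t, small_proteome)


class TestCategoryPercentages:
    def test_single_category_is_all(self):
        t = table_from([[3], [7]], ["y"])
        pct = category_percentages(t, {"P0": "opt", "P1": "opt"})
        assert pct.loc["opt", "y"] == pytest.approx(100.0)

    @pytest.mark.parametrize(
        "counts, cats, expected",
        [
            ([[30], [70]], {"P0": "a", "P1": "b"}, {"a": 30.0, "b": 70.0}),
            ([[1], [1], [2]], {"P0": "a", "P1": "b", "P2": "c"},
             {"a": 25.0, "b": 25.0, "c": 50.0}),
        ],
    )
    def test_hand_arithmetic(self, counts, cats, expected):
        pct = category_percentages(table_from(counts, ["y"]), cats)
        for cat, val in expected.items():
            assert pct.loc[cat, "y"] == pytest.approx(val)
        assert pct["y"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_unmapped_proteins_fall_into_uncharacterized(self):
        t = table_from([[1], [3]], ["y"])
        pct = category_percentages(t, {"P0": "a"})
        assert pct.loc["uncharacterized", "y"] == pytest.approx(75.0)

    def test_zero_sample_total_rejected(self):
        t = table_from([[0], [0]], ["y"])
        with pytest.raises(ValueError):
            category_percentages(t, {})


class TestContaminantFilter:
    def test_bacterial_ribosomal_protein_removed(self):
        rec = ProteinRecord("c1", "MKTAYR", "30S ribosomal protein S4, Vibrio")
        kept, removed = contaminant_filter([rec])
        assert kept == [] and removed[0][0] is rec
        assert "ribosomal" in removed[0][1]

    def test_crystallin_kept(self):
        rec = ProteinRecord("c2", "MKTAYR", "Omega-crystallin")
        kept, removed = contaminant_filter([rec])
        assert kept == [rec] and removed == []

    def test_empty_rules_are_identity(self):
        rec = ProteinRecord("c1", "MKTAYR", "Trypsin precursor")
        kept, removed = contaminant_filter([rec], ContaminantRules.none())
        assert kept == [rec]

    def test_partition_is_conservative(self, rng):
        descs = ["trypsin", "papain-like", "crystallin", "reflectin A2",
                 "50S ribosomal protein L2", "collagenase", "unknown"]
        recs = [ProteinRecord(f"r{i}", "MK", d) for i, d in enumerate(descs)]
        kept, removed = contaminant_filter(recs)
        assert len(kept) + len(removed) == len(recs)
        assert {r.id for r in kept}.isdisjoint({r.id for r, _ in removed})

    def test_id_blocklist(self):
        rec = ProteinRecord("BAD1", "MK", "fine description")
        kept, removed = contaminant_filter(
            [rec], ContaminantRules(keywords=[], id_blocklist=["BAD1"])
        )
        assert not kept and "blocklisted" in removed[0][1]

    def test_malformed_regex_is_config_error(self):
        with pytest.raises(ValueError, match="malformed"):
            contaminant_filter(
                [ProteinRecord("a", "MK", "x")],
                ContaminantRules(keywords=[], patterns=["[unclosed"]),
            )
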