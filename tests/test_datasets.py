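import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from eipdt.datasets import (
    FossilRecord,
    ModernDataset,
    PollenMatrix,
    SchemaError,
    SiteMeta,
    harmonize_taxa,
    read_table,
    to_percentages,
    write_table,
)


def make_pm(values, taxa=None, ids=None, basis="counts"):
    values = np.asarray(values, dtype=float)
    taxa = taxa or [f"T{j}" for j in range(values.shape[1])]
    ids = ids or [f"s{i}" for i in range(values.shape[0])]
    return PollenMatrix(tuple(ids), tuple(taxa), values, basis)


class TestPollenMatrixValidation:
    def test_negative_values_rejected(self):
        with pytest.raises(SchemaError, match="negative"):
            make_pm([[1, -2], [3, 4]])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(SchemaError, match="duplicate sample_ids"):
            make_pm([[1, 2], [3, 4]], ids=["a", "a"])

    def test_duplicate_taxa_rejected(self):
        with pytest.raises(SchemaError, match="duplicate taxon"):
            make_pm([[1, 2], [3, 4]], taxa=["A", "A"])

    def test_percentage_rows_must_close(self):
        with pytest.raises(SchemaError, match="sums to"):
            make_pm([[60, 30]], basis="percentages")


class TestSiteMetaValidation:
    def test_hii_above_64_rejected(self):
        with pytest.raises(SchemaError, match=r"HII outside \[0, 64\]"):
            SiteMeta(("a",), [0.0], [0.0], [10.0], [500.0], [65.0])

    def test_negative_precipitation_rejected(self):
        with pytest.raises(SchemaError, match="precipitation"):
            SiteMeta(("a",), [0.0], [0.0], [10.0], [-5.0], [10.0])

    def test_misaligned_dataset_rejected(self):
        pm = make_pm([[1, 2]], ids=["a"])
        meta = SiteMeta(("b",), [0.0], [0.0], [10.0], [500.0], [10.0])
        with pytest.raises(SchemaError, match="aligned"):
            ModernDataset(pm, meta)


class TestFossilValidation:
    def test_nonmonotone_depth_rejected(self):
        pm = make_pm([[1, 2], [3, 4]])
        with pytest.raises(SchemaError, match="strictly increasing"):
            FossilRecord(pm, depth=[10.0, 5.0], age=[100.0, 200.0])

    def test_decreasing_age_rejected(self):
        pm = make_pm([[1, 2], [3, 4]])
        with pytest.raises(SchemaError, match="nondecreasing"):
            FossilRecord(pm, depth=[5.0, 10.0], age=[200.0, 100.0])


class TestRoundTrip:
    def test_pollen_round_trip(self, tmp_path):
        pm = make_pm([[10, 0], [0, 10]], taxa=["A", "B"])
        path = tmp_path / "pollen.tsv"
        write_table(pm, path)
        back = read_table(path, "pollen")
        assert back.taxa == pm.taxa
        assert back.basis == "counts"
        np.testing.assert_allclose(back.values, pm.values, atol=1e-9)

    def test_meta_round_trip_with_optional_columns(self, tmp_path):
        meta = SiteMeta(
            ("a", "b"), [100.0, 101.0], [30.0, 31.0], [10.0, 12.0],
            [800.0, 900.0], [5.0, 40.0], elev=[10.0, 20.0], veg_label=("forest", "city"),
        )
        path = tmp_path / "meta.tsv"
        write_table(meta, path)
        back = read_table(path, "meta")
        np.testing.assert_allclose(back.hii, meta.hii, atol=1e-9)
        assert back.veg_label == meta.veg_label

    def test_fossil_round_trip(self, tmp_path):
        rec = FossilRecord(make_pm([[3, 7], [5, 5]]), [1.0, 2.0], [100.0, 250.0])
        path = tmp_path / "fossil.tsv"
        write_table(rec, path)
        back = read_table(path, "fossil")
        np.testing.assert_allclose(back.age, rec.age, atol=1e-9)
        np.testing.assert_allclose(back.pollen.values, rec.pollen.values, atol=1e-9)

    def test_comma_dialect_sniffed(self, tmp_path):
        path = tmp_path / "pollen.csv"
        path.write_text("sample_id,A,B\ns1,4,6\n")
        pm = read_table(path, "pollen")
        np.testing.assert_allclose(pm.values, [[4, 6]])

    def test_missing_meta_column_named(self, tmp_path):
        path = tmp_path / "meta.tsv"
        path.write_text("sample_id\tlon\tlat\ns1\t0\t0\n")
        with pytest.raises(SchemaError, match="mat_c"):
            read_table(path, "meta")

    def test_non_numeric_cell_located(self, tmp_path):
        path = tmp_path / "pollen.tsv"
        path.write_text("sample_id\tA\tB\ns1\t3\toops\n")
        with pytest.raises(SchemaError, match="B"):
            read_table(path, "pollen")


class TestToPercentages:
    @pytest.mark.parametrize(
        "counts, expected",
        [([[30, 70]], [[30, 70]]), ([[1, 3]], [[25, 75]])],
    )
    def test_simple_conversion(self, counts, expected):
        out = to_percentages(make_pm(counts))
        assert out.basis == "percentages"
        np.testing.assert_allclose(out.values, expected)

    def test_zero_sum_row_names_samples(self):
        with pytest.raises(ValueError, match="s1"):
            to_percentages(make_pm([[1, 1], [0, 0]], ids=["s0", "s1"]))

    def test_idempotent_on_percentages(self):
        pct = to_percentages(make_pm([[20, 80]]))
        assert to_percentages(pct) is pct

    def test_subset_pollen_sum(self):
        pm = make_pm([[50, 50, 100]], taxa=["A", "B", "X"])
        out = to_percentages(pm, sum_taxa=["A", "B"])
        # A and B close to 100; X reported as percent of the A+B sum
        np.testing.assert_allclose(out.values, [[50, 50, 100]])
        assert out.sum_taxa == ("A", "B")

    @given(
        arrays(
            np.float64,
            st.tuples(st.integers(1, 6), st.integers(1, 5)),
            elements=st.floats(0, 1000),
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_rows_close_to_100(self, counts):
        if (counts.sum(axis=1) <= 0).any():
            return
        out = to_percentages(make_pm(counts))
        np.testing.assert_allclose(out.values.sum(axis=1), 100.0, atol=1e-6)


class TestHarmonize:
    def test_intersection_and_reclosure(self):
        modern = to_percentages(make_pm([[20, 30, 50]], taxa=["A", "B", "C"]))
        fossil = to_percentages(make_pm([[10, 40, 50]], taxa=["B", "C", "D"]))
        m, f, report = harmonize_taxa(modern, fossil)
        assert m.taxa == ("B", "C")
        np.testing.assert_allclose(m.values.sum(axis=1), 100, atol=1e-6)
        np.testing.assert_allclose(m.values, [[37.5, 62.5]])
        assert report["dropped_modern"] == ["A"]
        assert report["dropped_fossil"] == ["D"]
        np.testing.assert_allclose(report["dropped_mass_modern"]["s0"], 20.0)

    def test_identical_taxa_is_identity(self):
        a = to_percentages(make_pm([[25, 75]], taxa=["A", "B"]))
        b = to_percentages(make_pm([[60, 40]], taxa=["A", "B"]))
        m, f, _ = harmonize_taxa(a, b)
        np.testing.assert_allclose(m.values, a.values)
        np.testing.assert_allclose(f.values, b.values)

    def test_empty_intersection_raises(self):
        a = to_percentages(make_pm([[100]], taxa=["A"]))
        b = to_percentages(make_pm([[100]], taxa=["B"]))
        with pytest.raises(ValueError, match="no taxa shared"):
            harmonize_taxa(a, b)

    def test_case_folding_matches(self):
        a = to_percentages(make_pm([[50, 50]], taxa=["Pinus ", "quercus"]))
        b = to_percentages(make_pm([[50, 50]], taxa=["pinus", "Quercus"]))
        m, f, _ = harmonize_taxa(a, b)
        assert len(m.taxa) == 2

    def test_reharmonizing_is_identity(self):
        modern = to_percentages(make_pm([[20, 30, 50], [10, 60, 30]], taxa=["A", "B", "C"]))
        fossil = to_percentages(make_pm([[10, 40, 50]], taxa=["B", "C", "D"]))
        m1, f1, _ = harmonize_taxa(modern, fossil)
        m2, f2, _ = harmonize_taxa(m1, f1)
        np.testing.assert_allclose(m1.values, m2.values, atol=1e-9)
        np.testing.assert_allclose(f1.values, f2.values, atol=1e-9)
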