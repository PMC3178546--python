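import numpy as np
import pytest

from gextemplates.expression_io import (
    ExpressionMatrix,
    MatrixFormatError,
    SampleMetadata,
    align_genes,
    ensure_log2,
    metadata_index,
    read_matrix,
    read_metadata,
    write_matrix,
    write_metadata,
)


def make_matrix(genes, samples, values):
    return ExpressionMatrix(tuple(genes), tuple(samples), np.asarray(values, float))


class TestExpressionMatrix:
    def test_shape_and_ids(self):
        m = make_matrix(["a", "b"], ["s1", "s2", "s3"], np.zeros((2, 3)))
        assert m.shape == (2, 3)
        assert m.n_genes == 2 and m.n_samples == 3

    def test_rejects_duplicate_gene_ids(self):
        with pytest.raises(MatrixFormatError, match="duplicate gene"):
            make_matrix(["a", "a"], ["s1"], np.zeros((2, 1)))

    def test_rejects_duplicate_sample_ids(self):
        with pytest.raises(MatrixFormatError, match="duplicate sample"):
            make_matrix(["a"], ["s1", "s1"], np.zeros((1, 2)))

    def test_rejects_nan(self):
        with pytest.raises(MatrixFormatError, match="non-finite"):
            make_matrix(["a"], ["s1"], [[np.nan]])

    def test_rejects_shape_mismatch(self):
        with pytest.raises(MatrixFormatError, match="shape"):
            make_matrix(["a", "b"], ["s1"], np.zeros((1, 1)))

    def test_subset_genes_preserves_order(self):
        m = make_matrix(["a", "b", "c"], ["s"], [[1.0], [2.0], [3.0]])
        sub = m.subset_genes(["c", "a"])
        assert sub.gene_ids == ("c", "a")
        assert sub.values[:, 0].tolist() == [3.0, 1.0]


class TestReadMatrix:
    def test_tsv_round_trip_identity(self, tmp_path):
        m = make_matrix(
            ["g1", "g2", "g3"], ["s1", "s2"],
            [[1.5, 2.5], [3.25, 4.0], [0.1, 9.9]],
        )
        path = tmp_path / "m.tsv"
        write_matrix(m, path)
        back = read_matrix(path)
        assert back.gene_ids == m.gene_ids
        assert back.sample_ids == m.sample_ids
        np.testing.assert_array_equal(back.values, m.values)

    def test_tsv_3x2_shape(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text(
            "gene_id\ts1\ts2\ng1\t1\t2\ng2\t3\t4\ng3\t5\t6\n"
        )
        m = read_matrix(path)
        assert m.shape == (3, 2)
        assert m.gene_ids == ("g1", "g2", "g3")
        assert m.sample_ids == ("s1", "s2")

    def test_duplicate_rows_collapse_mean(self, tmp_path):
        # elementwise mean of the two g1 rows: (1+3)/2, (2+4)/2
        path = tmp_path / "m.tsv"
        path.write_text("gene_id\ts1\ts2\ng1\t1\t2\ng1\t3\t4\n")
        m = read_matrix(path, collapse="mean")
        assert m.gene_ids == ("g1",)
        np.testing.assert_array_equal(m.values, [[2.0, 3.0]])

    def test_duplicate_rows_collapse_max_mean_row(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("gene_id\ts1\ts2\ng1\t1\t2\ng1\t30\t40\ng2\t5\t5\n")
        m = read_matrix(path)  # default max-mean-row
        assert m.gene_ids == ("g1", "g2")
        np.testing.assert_array_equal(m.values[0], [30.0, 40.0])

    def test_duplicate_rows_error_policy(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("gene_id\ts1\ng1\t1\ng1\t2\n")
        with pytest.raises(MatrixFormatError, match="duplicate gene rows"):
            read_matrix(path, collapse="error")

    def test_series_matrix_dialect(self, tmp_path):
        lines = [
            "!Series_title\t\"toy\"",
            "!Series_platform\t\"GPLX\"",
            "!Sample_count\t3",
            "!extra_meta\tfoo",
            "!another_meta\tbar",
            "!series_matrix_table_begin",
            '"ID_REF"\t"s1"\t"s2"\t"s3"',
            '"g1"\t1\t2\t3',
            '"g2"\t4\t5\t6',
            '"g3"\t7\t8\t9',
            '"g4"\t10\t11\t12',
            "!series_matrix_table_end",
        ]
        path = tmp_path / "series.txt"
        path.write_text("\n".join(lines))
        m = read_matrix(path, format="series_matrix")
        assert m.shape == (4, 3)
        assert m.sample_ids == ("s1", "s2", "s3")
        np.testing.assert_array_equal(m.values[0], [1, 2, 3])

    def test_non_numeric_cell_names_coordinates(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("gene_id\ts1\ts2\ng1\t1\toops\n")
        with pytest.raises(MatrixFormatError, match="'g1'.*'s2'"):
            read_matrix(path)

    def test_duplicate_sample_ids_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("gene_id\ts1\ts1\ng1\t1\t2\n")
        with pytest.raises(MatrixFormatError, match="duplicate sample"):
            read_matrix(path)

    def test_ragged_row_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("gene_id\ts1\ts2\ng1\t1\n")
        with pytest.raises(MatrixFormatError, match="line 2"):
            read_matrix(path)

    def test_missing_value_rejected_by_default(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("gene_id\ts1\ts2\ng1\t1\tNA\n")
        with pytest.raises(MatrixFormatError, match="missing value"):
            read_matrix(path)

    def test_missing_value_imputed_with_row_mean(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("gene_id\ts1\ts2\ts3\ng1\t1\tNA\t3\n")
        m = read_matrix(path, missing="impute-mean")
        np.testing.assert_array_equal(m.values, [[1.0, 2.0, 3.0]])

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_matrix(tmp_path / "nope.tsv")


class TestEnsureLog2:
    def test_auto_leaves_log_scale_untouched(self):
        m = make_matrix(["g"], ["s1", "s2"], [[5.0, 19.9]])
        out = ensure_log2(m, mode="auto")
        np.testing.assert_array_equal(out.values, m.values)

    def test_force_log2_identity(self):
        m = make_matrix(["g"], ["s"], [[1024.0]])
        out = ensure_log2(m, mode="force", epsilon=0.0)
        assert out.values[0, 0] == 10.0

    def test_auto_fires_on_linear_scale(self):
        # max 20000 > 50 -> transform applied; spot-check every cell
        vals = np.array([[20000.0, 128.0], [7.0, 1000.0]])
        m = make_matrix(["g1", "g2"], ["s1", "s2"], vals)
        out = ensure_log2(m, mode="auto", epsilon=1.0)
        np.testing.assert_allclose(out.values, np.log2(vals + 1.0))

    def test_skip(self):
        m = make_matrix(["g"], ["s"], [[20000.0]])
        out = ensure_log2(m, mode="skip")
        assert out.values[0, 0] == 20000.0

    def test_negative_value_under_force_errors(self):
        m = make_matrix(["g"], ["s"], [[-1.0]])
        with pytest.raises(ValueError, match="negative"):
            ensure_log2(m, mode="force")

    def test_force_is_monotone(self, rng):
        vals = rng.uniform(0, 5000, size=(20, 5))
        m = make_matrix([f"g{i}" for i in range(20)], [f"s{j}" for j in range(5)], vals)
        out = ensure_log2(m, mode="force")
        flat_in = vals.ravel()
        flat_out = out.values.ravel()
        order = np.argsort(flat_in)
        assert np.all(np.diff(flat_out[order]) >= 0)


class TestAlignGenes:
    def test_intersection(self):
        m1 = make_matrix(["A", "B", "C"], ["s1"], [[1], [2], [3]])
        m2 = make_matrix(["B", "C", "D"], ["t1"], [[4], [5], [6]])
        a1, a2 = align_genes([m1, m2])
        assert a1.gene_ids == a2.gene_ids == ("B", "C")
        assert a1.values[:, 0].tolist() == [2, 3]
        assert a2.values[:, 0].tolist() == [4, 5]

    def test_idempotence_up_to_row_order(self):
        m = make_matrix(["b", "a"], ["s1"], [[1], [2]])
        a1, a2 = align_genes([m, m])
        assert a1.gene_ids == ("a", "b")
        assert a1.values[:, 0].tolist() == [2, 1]
        np.testing.assert_array_equal(a1.values, a2.values)

    def test_three_inputs_single_shared_gene(self):
        # brute-force: set intersection of the three id sets has exactly one member
        sets = [["A", "X"], ["A", "Y"], ["A", "Z"]]
        expected = set(sets[0]) & set(sets[1]) & set(sets[2])
        assert expected == {"A"}
        ms = [make_matrix(g, [f"s{i}"], [[1], [2]]) for i, g in enumerate(sets)]
        out = align_genes(ms)
        assert all(m.gene_ids == ("A",) for m in out)

    def test_empty_intersection_errors(self):
        m1 = make_matrix(["A"], ["s1"], [[1]])
        m2 = make_matrix(["B"], ["t1"], [[1]])
        with pytest.raises(ValueError, match="empty"):
            align_genes([m1, m2])

    def test_requires_two_matrices(self):
        m = make_matrix(["A"], ["s1"], [[1]])
        with pytest.raises(ValueError):
            align_genes([m])

    def test_output_genes_subset_of_every_input(self, rng):
        all_genes = [f"g{i}" for i in range(30)]
        ms = []
        for i in range(4):
            genes = sorted(rng.choice(all_genes, size=20, replace=False))
            ms.append(make_matrix(genes, [f"s{i}"], rng.normal(size=(20, 1))))
        out = align_genes(ms)
        shared = out[0].gene_ids
        for m_in, m_out in zip(ms, out):
            assert m_out.gene_ids == shared
            assert set(shared) <= set(m_in.gene_ids)


class TestMetadata:
    def test_round_trip(self, tmp_path):
        metas = [
            SampleMetadata("s1", "liver", "ds1", time=3.5, condition="normal"),
            SampleMetadata("s2", "lung", "ds2"),
        ]
        path = tmp_path / "meta.tsv"
        write_metadata(metas, path)
        back = read_metadata(path)
        assert back[0].sample_id == "s1"
        assert back[0].time == 3.5
        assert back[0].condition == "normal"
        assert back[1].time is None

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            SampleMetadata("s", "liver", "ds", time=-1.0)

    def test_index_rejects_duplicates(self):
        metas = [
            SampleMetadata("s1", "liver", "ds1"),
            SampleMetadata("s1", "lung", "ds1"),
        ]
        with pytest.raises(ValueError, match="duplicate"):
            metadata_index(metas)
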