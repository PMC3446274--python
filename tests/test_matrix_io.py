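"""Containers, scale conversions and file round trips."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evora import io
from evora.matrix import (
    MethylationMatrix,
    SampleAnnotation,
    beta_to_m,
    beta_to_r,
    clip_beta,
    convert_scale,
    m_to_beta,
    r_to_beta,
)


class TestMethylationMatrix:
    def test_shape_and_mask(self):
        beta = np.array([[0.1, 0.9], [0.5, np.nan], [0.3, 0.4]])
        m = MethylationMatrix(beta, ["a", "b", "c"], ["s1", "s2"])
        assert (m.n_cpgs, m.n_samples) == (3, 2)
        assert m.missing_mask.sum() == 1

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate CpG.*dup"):
            MethylationMatrix(np.full((2, 1), 0.5), ["dup", "dup"], ["s1"])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="strictly inside"):
            MethylationMatrix(np.array([[0.0], [0.5]]), ["a", "b"], ["s1"])

    def test_select_preserves_order(self, tiny_matrix):
        sub = tiny_matrix.select_cpgs(["cg3", "cg1"])
        assert list(sub.cpg_ids) == ["cg3", "cg1"]
        np.testing.assert_array_equal(sub.beta[0], tiny_matrix.beta[3])

    def test_drop_high_missing(self):
        beta = np.array([[0.1, np.nan, np.nan, np.nan], [0.2, 0.3, 0.4, 0.5]])
        m = MethylationMatrix(beta, ["a", "b"], list("wxyz"))
        kept = m.drop_high_missing_cpgs(0.5)
        assert list(kept.cpg_ids) == ["b"]


class TestScales:
    @pytest.mark.parametrize(
        "beta,expected_r,expected_m",
        [(0.5, 1.0, 0.0), (0.8, 4.0, 2.0), (0.2, 0.25, -2.0)],
    )
    def test_known_conversions(self, beta, expected_r, expected_m):
        assert beta_to_r(beta) == pytest.approx(expected_r, abs=1e-12)
        assert beta_to_m(beta) == pytest.approx(expected_m, abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(min_value=1e-6, max_value=1 - 1e-6))
    def test_round_trips_are_inverse(self, b):
        assert m_to_beta(beta_to_m(b)) == pytest.approx(b, abs=1e-12)
        assert r_to_beta(beta_to_r(b)) == pytest.approx(b, abs=1e-12)

    def test_round_trip_bulk(self):
        rng = np.random.default_rng(0)
        b = rng.uniform(1e-6, 1 - 1e-6, 1000)
        np.testing.assert_allclose(m_to_beta(beta_to_m(b)), b, atol=1e-12)

    def test_monotone_in_beta(self):
        b = np.linspace(0.01, 0.99, 500)
        assert (np.diff(beta_to_r(b)) > 0).all()
        assert (np.diff(beta_to_m(b)) > 0).all()

    def test_boundary_errors(self):
        for bad in (0.0, 1.0):
            with pytest.raises(ValueError, match="clip"):
                convert_scale(np.array([bad]), "m")

    def test_clip_identity_inside_band(self):
        vals = np.array([0.2, 0.5, 0.9])
        np.testing.assert_array_equal(clip_beta(vals, 1e-6), vals)
        assert clip_beta(np.array([1.0]), 1e-6)[0] == 1 - 1e-6


class TestBetaMatrixIO:
    def test_round_trip_and_na(self, tmp_path):
        path = tmp_path / "beta.tsv"
        path.write_text("cpg_id\ts1\ts2\ncgA\t0.1\t0.9\ncgB\tNA\t0.25\ncgC\t0.4\t0.6\n")
        m = io.read_beta_matrix(path)
        assert m.beta.shape == (3, 2)
        assert m.missing_mask.sum() == 1
        out = tmp_path / "out.tsv"
        io.write_beta_matrix(m, out)
        m2 = io.read_beta_matrix(out)
        np.testing.assert_allclose(
            m.beta[np.isfinite(m.beta)], m2.beta[np.isfinite(m2.beta)], rtol=1e-6
        )

    def test_boundary_value_clipped(self, tmp_path):
        path = tmp_path / "beta.tsv"
        path.write_text("cpg_id\ts1\ncgA\t1.0\ncgB\t0.0\n")
        m = io.read_beta_matrix(path, clip_epsilon=1e-6)
        assert m.beta[0, 0] == 1 - 1e-6
        assert m.beta[1, 0] == 1e-6

    def test_duplicate_row_id_named(self, tmp_path):
        path = tmp_path / "beta.tsv"
        path.write_text("cpg_id\ts1\ncgA\t0.5\ncgA\t0.6\n")
        with pytest.raises(ValueError, match="cgA"):
            io.read_beta_matrix(path)

    def test_non_numeric_cell_located(self, tmp_path):
        path = tmp_path / "beta.tsv"
        path.write_text("cpg_id\ts1\ts2\ncgA\t0.5\tbogus\n")
        with pytest.raises(ValueError, match="cgA.*s2"):
            io.read_beta_matrix(path)

    def test_out_of_unit_range_rejected(self, tmp_path):
        path = tmp_path / "beta.tsv"
        path.write_text("cpg_id\ts1\ncgA\t1.5\n")
        with pytest.raises(ValueError, match="outside"):
            io.read_beta_matrix(path)


class TestAnnotationIO:
    def test_sample_annotation_parsing(self, tmp_path):
        path = tmp_path / "samples.csv"
        path.write_text("sample_id,status,age,hpv\ns1,case,34,positive\ns2,control,40,\n")
        ann = io.read_sample_annotation(path)
        assert list(ann.status) == ["case", "control"]
        assert ann.hpv[1] == "unknown"
        assert ann.age[0] == 34.0

    def test_bad_status_lists_allowed(self, tmp_path):
        path = tmp_path / "samples.csv"
        path.write_text("sample_id,status,age,hpv\ns2,tumour,34,\n")
        with pytest.raises(ValueError, match="case.*control"):
            io.read_sample_annotation(path)

    def test_non_numeric_age_rejected(self):
        with pytest.raises(ValueError, match="age"):
            SampleAnnotation(
                pd.DataFrame({"sample_id": ["a"], "status": ["case"], "age": ["old"]})
            )

    def test_cpg_annotation_defaults(self, tmp_path):
        path = tmp_path / "cpgs.csv"
        path.write_text("cpg_id,entrez_id,gene_symbol,pcgt\ncgA,1,G1,1\ncgB,2,G2,0\n")
        ann = io.read_cpg_annotation(path)
        assert ann.pcgt_set() == {"cgA"}


class TestTables:
    def test_dvc_table_column_order(self, tmp_path):
        table = pd.DataFrame({"cpg_id": ["a"], "p_bartlett": [0.1], "var_ratio": [2.0]})
        path = tmp_path / "dvc.tsv"
        io.write_dvc_table(table, path)
        header = path.read_text().splitlines()[0].split("\t")
        assert header == io.DVC_COLUMNS

    def test_empty_table_writes_header_only(self, tmp_path):
        path = tmp_path / "dvc.tsv"
        io.write_dvc_table(pd.DataFrame(columns=["cpg_id"]), path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1

    def test_category_file_grouped_by_set(self, tmp_path):
        path = tmp_path / "sets.tsv"
        path.write_text("cgA\tpcgt\ncgB\tpcgt\ncgC\tother\n")
        sets = io.read_category_file(path)
        assert sets == {"pcgt": {"cgA", "cgB"}, "other": {"cgC"}}

    def test_scores_schema_enforced(self, tmp_path):
        with pytest.raises(ValueError, match="missing columns"):
            io.write_scores(pd.DataFrame({"sample_id": ["s"]}), tmp_path / "x.tsv")


class TestModelIO:
    def test_save_load_round_trip_scores(self, tmp_path, small_cohort):
        from evora.model import score_samples, train_evora

        matrix, annotation, _, _ = small_cohort
        model = train_evora(matrix, annotation, seed=3)
        before = score_samples(model, matrix)
        path = tmp_path / "model.json"
        io.save_model(model, path)
        loaded = io.load_model(path)
        after = score_samples(loaded, matrix)
        pd.testing.assert_frame_equal(before, after)

    def test_schema_version_mismatch(self, tmp_path):
        path = tmp_path / "model.json"
        path.write_text(json.dumps({"schema_version": 99}))
        with pytest.raises(ValueError, match="99"):
            io.load_model(path)
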