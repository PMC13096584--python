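import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from liverspatial.core_io import (CountMatrix, FormatError, QCConfig,
                                  normalize_log1p, qc_filter, read_counts,
                                  read_obs_meta, write_counts, write_obs_meta)


class TestReadWriteCounts:
    def test_dense_tsv_round_trip_bit_exact(self, tiny_counts, tmp_path):
        path = tmp_path / "counts.tsv"
        write_counts(tiny_counts, path, format="dense_tsv")
        back = read_counts(path, format="dense_tsv")
        assert list(back.obs_ids) == list(tiny_counts.obs_ids)
        assert list(back.gene_ids) == list(tiny_counts.gene_ids)
        np.testing.assert_array_equal(back.counts, tiny_counts.counts)

    def test_mtx_triplet_round_trip_bit_exact(self, tiny_counts, tmp_path):
        path = tmp_path / "m" / "counts.mtx"
        write_counts(tiny_counts, path, format="mtx_triplet")
        back = read_counts(path, format="mtx_triplet")
        assert list(back.obs_ids) == list(tiny_counts.obs_ids)
        np.testing.assert_array_equal(back.counts, tiny_counts.counts)

    def test_dense_tsv_parses_expected_entries(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text("obs_id\tgA\tgB\no1\t1\t0\no2\t2\t3\no3\t0\t5\n")
        cm = read_counts(path, format="dense_tsv")
        np.testing.assert_array_equal(cm.counts, [[1, 0], [2, 3], [0, 5]])

    def test_sparse_triplet_fills_missing_entries_with_zero(self, tmp_path):
        d = tmp_path
        (d / "counts.mtx").write_text(
            "%%MatrixMarket matrix coordinate integer general\n2 2 1\n1 1 4\n")
        (d / "barcodes.tsv").write_text("obs1\nobs2\n")
        (d / "genes.tsv").write_text("geneA\ngeneB\n")
        cm = read_counts(d / "counts.mtx", format="mtx_triplet")
        np.testing.assert_array_equal(cm.counts, [[4, 0], [0, 0]])

    def test_negative_entry_reports_location(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text("obs_id\tgA\no1\t-1\n")
        with pytest.raises(FormatError, match="negative"):
            read_counts(path, format="dense_tsv")

    def test_non_integer_entry_reports_row(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text("obs_id\tgA\no1\t1.5\n")
        with pytest.raises(FormatError, match="row 2"):
            read_counts(path, format="dense_tsv")

    def test_missing_label_file_is_an_error(self, tmp_path):
        (tmp_path / "counts.mtx").write_text(
            "%%MatrixMarket matrix coordinate integer general\n1 1 1\n1 1 1\n")
        with pytest.raises(FormatError, match="barcodes"):
            read_counts(tmp_path / "counts.mtx", format="mtx_triplet")

    def test_duplicate_ids_rejected(self):
        with pytest.raises(FormatError, match="duplicate"):
            CountMatrix(["a", "a"], ["g"], np.zeros((2, 1), dtype=int))

    def test_obs_meta_round_trip(self, tiny_meta, tmp_path):
        path = tmp_path / "meta.tsv"
        write_obs_meta(tiny_meta, path)
        back = read_obs_meta(path)
        pd.testing.assert_frame_equal(back, tiny_meta)


class TestQCFilter:
    def _matrix(self, rows, genes):
        return CountMatrix([f"c{i}" for i in range(len(rows))], genes,
                           np.array(rows))

    def test_high_mito_cell_removed(self):
        # 12% mito against a 10% ceiling
        cm = self._matrix([[12, 88], [5, 95]], ["mt-Nd1", "geneA"])
        kept, rep = qc_filter(cm, QCConfig(max_mito_fraction=0.10, min_genes=0,
                                           max_genes=None))
        assert list(kept.obs_ids) == ["c1"]
        assert rep.n_removed_mito == 1

    def test_cell_exactly_at_thresholds_is_retained(self):
        # exactly 10% mito and exactly min_genes detected genes survive
        genes = ["mt-Nd1"] + [f"g{i}" for i in range(499)]
        row = [10] + [1] * 90 + [0] * 409  # 100 UMIs, 10 mito, 91 detected genes
        cm = self._matrix([row], genes)
        kept, _ = qc_filter(cm, QCConfig(max_mito_fraction=0.10, min_genes=91,
                                         max_genes=None))
        assert kept.shape[0] == 1

    def test_low_gene_spot_removed_under_spot_config(self):
        genes = [f"g{i}" for i in range(300)]
        low = [1] * 150 + [0] * 150
        ok = [1] * 250 + [0] * 50
        cm = self._matrix([low, ok], genes)
        kept, rep = qc_filter(cm, QCConfig(max_mito_fraction=0.05, min_genes=200,
                                           max_genes=None))
        assert list(kept.obs_ids) == ["c1"]
        assert rep.n_removed_min_genes == 1

    def test_doublet_flag_via_max_genes(self):
        genes = [f"g{i}" for i in range(10)]
        cm = self._matrix([[1] * 10, [1] * 5 + [0] * 5], genes)
        kept, rep = qc_filter(cm, QCConfig(max_mito_fraction=1.0, min_genes=0,
                                           max_genes=8))
        assert list(kept.obs_ids) == ["c1"]
        assert rep.n_removed_max_genes == 1

    def test_idempotent(self, spatial_data):
        _, counts, *_ = spatial_data
        cfg = QCConfig(max_mito_fraction=0.10, min_genes=50, max_genes=None)
        with pytest.warns(UserWarning):  # synthetic genes carry no mito prefix
            once, _ = qc_filter(counts, cfg)
            twice, rep = qc_filter(once, cfg)
        assert twice.shape == once.shape
        assert rep.n_kept == rep.n_input

    def test_missing_mito_genes_warns_and_skips_rule(self):
        cm = self._matrix([[5, 5]], ["geneA", "geneB"])
        with pytest.warns(UserWarning, match="mito"):
            kept, rep = qc_filter(cm, QCConfig(max_mito_fraction=0.0, min_genes=0,
                                               max_genes=None))
        assert kept.shape[0] == 1
        assert rep.warnings

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            QCConfig(max_mito_fraction=1.5)
        with pytest.raises(ValueError):
            QCConfig(min_genes=500, max_genes=400)


class TestNormalize:
    def test_closed_form_value(self):
        cm = CountMatrix(["o1"], [f"g{i}" for i in range(10)],
                         np.full((1, 10), 10))
        norm = normalize_log1p(cm, scale=10000)
        np.testing.assert_allclose(norm.values, np.log(1 + 1000.0))

    def test_zero_total_row_stays_zero(self):
        cm = CountMatrix(["o1", "o2"], ["g1", "g2"], np.array([[0, 0], [1, 1]]))
        norm = normalize_log1p(cm)
        np.testing.assert_array_equal(norm.values[0], [0.0, 0.0])
        assert np.all(norm.values[1] > 0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(base=arrays(np.int64, (4, 12), elements=st.integers(0, 50)),
           factor=st.integers(1, 1000))
    def test_per_observation_rescaling_invariance(self, base, factor):
        cm1 = CountMatrix([f"o{i}" for i in range(4)],
                          [f"g{i}" for i in range(12)], base)
        cm2 = CountMatrix(cm1.obs_ids, cm1.gene_ids, base * factor)
        np.testing.assert_allclose(normalize_log1p(cm1).values,
                                   normalize_log1p(cm2).values, atol=1e-9)
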