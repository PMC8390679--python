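"""Triplet I/O, QC filter semantics, ambient estimation and correction."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from amniograph.ingest_qc import (
    QcThresholds,
    UmiCountMatrix,
    apply_qc_filters,
    correct_ambient,
    estimate_ambient_fraction,
    read_tenx_triplet,
    write_tenx_triplet,
)


def _matrix(dense, genes=None, barcodes=None, meta=None):
    dense = np.asarray(dense)
    genes = genes or [f"g{i}" for i in range(dense.shape[0])]
    barcodes = barcodes or [f"c{i}" for i in range(dense.shape[1])]
    return UmiCountMatrix(sp.csr_matrix(dense), np.array(genes), np.array(barcodes), meta)


class TestContainer:
    def test_rejects_negative_and_fractional(self):
        with pytest.raises(ValueError):
            _matrix([[-1, 0], [0, 2]])
        with pytest.raises(ValueError):
            UmiCountMatrix(
                sp.csr_matrix(np.array([[0.5, 0.0]])), np.array(["g"]), np.array(["a", "b"])
            )

    def test_rejects_duplicate_ids(self):
        with pytest.raises(ValueError):
            _matrix([[1, 2]], genes=["g"], barcodes=["a", "a"])

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            _matrix([[1, 2], [3, 4]], genes=["g0"])


class TestTripletIO:
    def test_round_trip(self, tmp_path, small_sim):
        _, m, _ = small_sim
        write_tenx_triplet(m, tmp_path / "out")
        back = read_tenx_triplet(tmp_path / "out")
        assert (m.values != back.values).nnz == 0
        assert list(m.gene_ids) == list(back.gene_ids)
        assert list(m.barcodes) == list(back.barcodes)
        assert list(back.cell_meta["condition"]) == list(m.cell_meta["condition"])

    def test_second_write_is_byte_identical(self, tmp_path):
        m = _matrix([[5, 0], [0, 0], [0, 2]])
        d1 = write_tenx_triplet(m, tmp_path / "a")
        back = read_tenx_triplet(d1)
        d2 = write_tenx_triplet(back, tmp_path / "b")
        for name in ("matrix.mtx", "features.tsv", "barcodes.tsv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_hand_written_mtx(self, tmp_path):
        d = tmp_path / "t"
        d.mkdir()
        (d / "matrix.mtx").write_text(
            "%%MatrixMarket matrix coordinate integer general\n3 2 2\n1 1 5\n3 2 2\n"
        )
        (d / "features.tsv").write_text("gA\ngB\ngC\n")
        (d / "barcodes.tsv").write_text("c1\nc2\n")
        m = read_tenx_triplet(d)
        np.testing.assert_array_equal(m.to_dense(), [[5, 0], [0, 0], [0, 2]])

    def test_single_entry_body_line(self, tmp_path):
        m = _matrix([[7]])
        d = write_tenx_triplet(m, tmp_path / "one")
        body = [
            line
            for line in (d / "matrix.mtx").read_text().splitlines()
            if not line.startswith("%")
        ]
        assert body[-1].split() == ["1", "1", "7"]

    def test_feature_count_mismatch_errors(self, tmp_path):
        d = tmp_path / "bad"
        d.mkdir()
        (d / "matrix.mtx").write_text(
            "%%MatrixMarket matrix coordinate integer general\n3 2 1\n1 1 5\n"
        )
        (d / "features.tsv").write_text("gA\ngB\ngC\ngD\n")
        (d / "barcodes.tsv").write_text("c1\nc2\n")
        with pytest.raises(ValueError):
            read_tenx_triplet(d)

    def test_empty_matrix_round_trip(self, tmp_path):
        m = UmiCountMatrix(sp.csr_matrix((2, 0), dtype=np.int64), np.array(["g0", "g1"]), np.array([], dtype=str))
        d = write_tenx_triplet(m, tmp_path / "empty")
        back = read_tenx_triplet(d)
        assert back.n_cells == 0 and back.n_genes == 2


class TestQcFilters:
    def _qc_matrix(self):
        # 4 cells x 3 genes (one mito); designed mito fractions
        #   c0: 80/1000 = 0.080 (dropped), c1: 74/1000 = 0.074 (kept)
        #   c2, c3: low mito, kept
        dense = np.array(
            [
                [80, 74, 10, 10],  # MT-1
                [900, 920, 980, 990],  # g1
                [20, 6, 10, 0],  # g2
            ]
        )
        return _matrix(dense, genes=["MT-1", "g1", "g2"])

    def test_mito_boundary_is_strict(self):
        m = self._qc_matrix()
        thr = QcThresholds(max_mito_fraction=0.075, min_cells_per_gene=1, min_genes_per_cell=1)
        filtered, table = apply_qc_filters(m, thr, ["MT-1"])
        assert not table.loc["c0", "kept"] and table.loc["c0", "reason"] == "mito_fraction"
        assert table.loc["c1", "kept"]
        assert filtered.n_cells == 3

    def test_gene_min_cells_boundary(self):
        # after dropping c0, g2 is expressed in exactly 2 remaining cells
        m = self._qc_matrix()
        thr = QcThresholds(max_mito_fraction=0.075, min_cells_per_gene=3, min_genes_per_cell=1)
        filtered, _ = apply_qc_filters(m, thr, ["MT-1"])
        assert "g2" not in filtered.gene_ids  # 2 < 3 cells
        assert "g1" in filtered.gene_ids  # 3 >= 3 cells

    def test_min_genes_per_cell(self):
        m = self._qc_matrix()
        thr = QcThresholds(max_mito_fraction=0.9, min_cells_per_gene=1, min_genes_per_cell=3)
        _, table = apply_qc_filters(m, thr, ["MT-1"])
        assert not table.loc["c3", "kept"] and "few_genes" in table.loc["c3", "reason"]

    def test_idempotent_on_simulated_data(self, small_sim):
        _, m, truth = small_sim
        thr = QcThresholds(max_mito_fraction=0.075, min_cells_per_gene=3, min_genes_per_cell=100)
        once, _ = apply_qc_filters(m, thr, truth.mito_genes)
        mito_left = [g for g in truth.mito_genes if g in set(once.gene_ids)]
        twice, table2 = apply_qc_filters(once, thr, mito_left)
        assert (once.values != twice.values).nnz == 0
        assert table2["kept"].all()

    def test_unknown_mito_gene_errors(self):
        with pytest.raises(ValueError):
            apply_qc_filters(self._qc_matrix(), QcThresholds(), ["NOPE"])


class TestAmbient:
    def test_closed_form_rho(self):
        # 2 reporter-population cells, N=1000 each, 5 reporter counts each;
        # one producer cell tuned so the aggregate reporter share is 0.05
        # -> rho_hat = 10 / (2000 * 0.05) = 0.10
        dense = np.array(
            [
                [5, 5, 120],  # reporter gene R
                [995, 995, 480],  # filler
            ]
        )
        m = _matrix(dense, genes=["R", "F"], barcodes=["a", "b", "prod"])
        est = estimate_ambient_fraction(m, ["R"], ["a", "b"])
        assert est.ambient_profile[0] == pytest.approx(0.05)
        assert est.rho == pytest.approx(0.10)
        assert "prod" in est.producer_population

    def test_zero_reporter_counts_gives_zero(self):
        dense = np.array([[0, 0, 50], [100, 100, 50]])
        m = _matrix(dense, genes=["R", "F"], barcodes=["a", "b", "prod"])
        est = estimate_ambient_fraction(m, ["R"], ["a", "b"])
        assert est.rho == 0.0

    def test_rho_clamped_to_one(self):
        dense = np.array([[90, 90, 5], [10, 10, 95]])
        m = _matrix(dense, genes=["R", "F"], barcodes=["a", "b", "c"])
        est = estimate_ambient_fraction(m, ["R"], ["a", "b"])
        assert est.rho == 1.0

    def test_errors(self):
        m = _matrix([[0, 0], [5, 5]], genes=["R", "F"])
        with pytest.raises(ValueError):
            estimate_ambient_fraction(m, ["R"], [])  # empty population
        with pytest.raises(ValueError):
            estimate_ambient_fraction(m, ["R"], ["c0"])  # reporters absent in aggregate

    def test_correction_arithmetic(self):
        # x=5, rho=0.1, N=1000, b=0.004 -> 5 - 0.4 rounds back to 5
        # with b=0.04 -> 5 - 4 = 1;  x=1 with expected 3 clamps to 0
        from amniograph.ingest_qc import AmbientEstimate

        dense = np.array([[5], [5], [1], [989]])
        m = _matrix(dense, genes=["gA", "gB", "gC", "gD"], barcodes=["c"])
        b = np.array([0.004, 0.04, 0.03, 0.926])
        est = AmbientEstimate(
            rho=0.1, ambient_profile=b, gene_ids=m.gene_ids,
            reporter_genes=("gA",), reporter_population=("c",), producer_population=(),
        )
        out = correct_ambient(m, est)
        col = out.to_dense()[:, 0]
        assert col[0] == 5 and col[1] == 1 and col[2] == 0

    def test_zero_rho_is_identity(self, small_sim):
        _, m, truth = small_sim
        from amniograph.ingest_qc import AmbientEstimate

        est = AmbientEstimate(
            rho=0.0,
            ambient_profile=truth.ambient_profile["wt"],
            gene_ids=m.gene_ids,
            reporter_genes=tuple(truth.reporter_genes),
            reporter_population=("x",),
            producer_population=(),
        )
        out = correct_ambient(m, est)
        assert (out.values != m.values).nnz == 0

    def test_correction_removes_most_reporter_signal(self, default_sim):
        _, m, truth = default_sim
        pop = list(truth.cell_type.index[truth.cell_type == "Epi"])
        est = estimate_ambient_fraction(m, truth.reporter_genes, pop)
        out = correct_ambient(m, est)
        ridx = m.gene_index(truth.reporter_genes)
        pidx = m.barcode_index(pop)
        before = m.values[np.ix_(ridx, pidx)].mean()
        after = out.values[np.ix_(ridx, pidx)].mean()
        assert out.cell_totals().sum() <= m.cell_totals().sum()
        assert after <= 0.2 * before
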