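"""Prefilter rule, recovery-curve AUC vs brute force, dip test, binarization."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from amniograph import regulons as R
from amniograph.ingest_qc import UmiCountMatrix


def _matrix(dense, genes=None, barcodes=None):
    dense = np.asarray(dense)
    genes = genes or [f"g{i}" for i in range(dense.shape[0])]
    barcodes = barcodes or [f"c{i}" for i in range(dense.shape[1])]
    return UmiCountMatrix(sp.csr_matrix(dense), np.array(genes), np.array(barcodes))


class TestPrefilter:
    def test_threshold_arithmetic(self):
        assert R.prefilter_thresholds(1300) == (39, 13)
        assert R.prefilter_thresholds(100) == (3, 1)

    def test_boundary_gene_at_1300_cells(self):
        n_cells = 1300
        X = np.zeros((3, n_cells), dtype=int)
        X[0, :13] = 3  # 39 counts in 13 cells: kept
        X[1, :13] = [3] * 12 + [2]  # 38 counts in 13 cells: dropped
        X[2, :12] = 4  # 48 counts but only 12 cells: dropped
        kept = R.prefilter_genes(_matrix(X))
        assert kept == ["g0"]


def brute_force_auc(counts, member_idx, k):
    """Enumerate the recovery curve explicitly (counts must be tie-free)."""
    order = sorted(range(len(counts)), key=lambda i: -counts[i])
    members = set(member_idx)
    hits, raw = 0, 0
    for x, gene in enumerate(order[:k], start=1):
        if gene in members:
            hits += 1
        raw += hits
    max_raw = sum(min(x, len(members)) for x in range(1, k + 1))
    return raw / max_raw


class TestAucScore:
    def test_full_recovery_and_zero_recovery(self):
        counts = np.arange(100, 0, -1)[:, None]  # distinct, gene 0 highest
        m = _matrix(counts)
        top5 = {"r": [f"g{i}" for i in range(5)]}
        out = R.auc_score(m, top5, k=50, seed=0)
        assert out.values.iloc[0, 0] == pytest.approx(1.0)
        bottom = {"r": [f"g{i}" for i in range(95, 100)]}
        out = R.auc_score(m, bottom, k=50, seed=0)
        assert out.values.iloc[0, 0] == pytest.approx(0.0)

    def test_worked_example_ranks_2_and_4(self):
        # 10 genes; regulon occupies ranks 2 and 4; k=5
        # hits = (0,1,1,2,2) -> raw 6; max = 1+2+2+2+2 = 9 -> 2/3
        counts = np.array([100, 90, 80, 70, 60, 50, 40, 30, 20, 10])[:, None]
        m = _matrix(counts)
        out = R.auc_score(m, {"r": ["g1", "g3"]}, k=5, seed=0)
        assert out.values.iloc[0, 0] == pytest.approx(2.0 / 3.0)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        for trial in range(100):
            n_genes = 20
            k = int(rng.integers(1, 11))
            counts = rng.choice(1000, size=n_genes, replace=False)  # tie-free
            members = rng.choice(n_genes, size=rng.integers(1, 8), replace=False)
            m = _matrix(counts[:, None])
            got = R.auc_score(m, {"r": [f"g{i}" for i in members]}, k=k, seed=trial).values.iloc[0, 0]
            assert got == pytest.approx(brute_force_auc(counts, members, k), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(5, size=(50, 8))
        m1 = _matrix(counts)
        m2 = _matrix(counts**2)  # strictly monotone on nonnegative ints
        reg = {"r": [f"g{i}" for i in range(0, 50, 7)]}
        a1 = R.auc_score(m1, reg, k=10, seed=4).values
        a2 = R.auc_score(m2, reg, k=10, seed=4).values
        pd.testing.assert_frame_equal(a1, a2)

    def test_missing_regulon_flagged_nan(self):
        m = _matrix(np.arange(12)[:, None])
        with pytest.warns(UserWarning):
            out = R.auc_score(m, {"ghost": ["NOPE"]}, k=3, seed=0)
        assert np.isnan(out.values.iloc[0, 0])

    def test_k_larger_than_genes_errors(self):
        m = _matrix(np.arange(5)[:, None])
        with pytest.raises(ValueError):
            R.auc_score(m, {"r": ["g0"]}, k=6, seed=0)


class TestDipStatistic:
    def test_two_atom_closed_form(self):
        # nearest unimodal CDF reproduces the larger jump as a mode atom and
        # halves the smaller jump: dip = min(w, 1-w)/2
        assert R.dip_statistic([0, 0, 1, 1]) == pytest.approx(0.25)
        assert R.dip_statistic([0, 1, 1, 1]) == pytest.approx(0.125)
        assert R.dip_statistic([0, 0, 0, 1, 1, 1, 1, 1]) == pytest.approx(3 / 16)
        assert R.dip_statistic([0, 0, 0, 0, 0, 0, 0, 1, 1, 1]) == pytest.approx(3 / 20)

    def test_equally_spaced_sample_attains_minimum(self):
        for n in (4, 10, 51):
            assert R.dip_statistic(np.arange(n)) == pytest.approx(1 / (2 * n))

    def test_permutation_and_affine_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        d = R.dip_statistic(x)
        assert R.dip_statistic(rng.permutation(x)) == pytest.approx(d)
        assert R.dip_statistic(3.5 * x - 2.0) == pytest.approx(d)

    def test_bimodal_exceeds_unimodal(self):
        rng = np.random.default_rng(1)
        uni = rng.normal(size=500)
        bi = np.concatenate([rng.normal(0.2, 0.02, 250), rng.normal(0.6, 0.02, 250)])
        assert R.dip_statistic(bi) > 5 * R.dip_statistic(uni)


class TestDipTest:
    def test_errors_for_degenerate_input(self):
        with pytest.raises(ValueError):
            R.dip_test([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            R.dip_test([2.0] * 10)

    def test_classifies_single_runs(self):
        rng = np.random.default_rng(2)
        _, p_uni = R.dip_test(rng.normal(size=500), n_boot=300, seed=0)
        mix = np.concatenate([rng.normal(0.2, 0.02, 250), rng.normal(0.6, 0.02, 250)])
        _, p_bi = R.dip_test(mix, n_boot=300, seed=0)
        assert p_uni >= 0.05
        assert p_bi < 0.05


class TestBinarizeRegulon:
    def test_unimodal_rule_is_exact(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.20, 0.05, size=1000)
        tau, rule, active = R.binarize_regulon(x, dip_result=(0.01, 0.5))
        assert rule == "mean+2sd"
        assert tau == pytest.approx(x.mean() + 2 * x.std(ddof=0), abs=1e-15)
        np.testing.assert_array_equal(active, x > tau)

    def test_mixture_trough_near_midpoint(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(0.2, 0.02, 500), rng.normal(0.6, 0.02, 500)])
        D, p = R.dip_test(x, n_boot=200, seed=0)
        tau, rule, active = R.binarize_regulon(x, (D, p))
        assert rule == "kde-trough"
        assert 0.35 <= tau <= 0.45
        assert 0.2 < tau < 0.6  # strictly between component means

    def test_constant_values_degenerate(self):
        x = np.full(50, 0.3)
        tau, rule, active = R.binarize_regulon(x, (0.0, 1.0))
        assert tau == pytest.approx(0.3)
        assert not active.any()  # strict inequality

    def test_bimodal_call_without_two_peaks_falls_back(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0.5, 0.05, 400)  # unimodal data but a forced bimodal call
        with pytest.warns(UserWarning):
            tau, rule, _ = R.binarize_regulon(x, (0.1, 0.0))
        assert rule == "mean+2sd"


class TestBinarizeMatrix:
    def _auc(self, rows: dict):
        cells = [f"c{i}" for i in range(len(next(iter(rows.values()))))]
        df = pd.DataFrame(rows, index=cells).T
        return R.AucMatrix(values=df, k=10, seed=0)

    def test_low_activity_regulon_dropped(self):
        rng = np.random.default_rng(6)
        n = 1000
        silent = rng.normal(0.1, 0.01, n)
        silent[:3] = 0.5  # ~0.3% of cells beyond any sane threshold
        active = np.concatenate([rng.normal(0.1, 0.01, n // 2), rng.normal(0.6, 0.01, n // 2)])
        report, bam = R.binarize_matrix(
            self._auc({"silent": silent, "busy": active}), n_boot=200, seed=0
        )
        assert report.loc["silent", "active_fraction"] < 0.01
        assert "silent" not in bam.values.index
        assert "busy" in bam.values.index

    def test_all_zero_auc_yields_empty_warning(self):
        with pytest.warns(UserWarning):
            report, bam = R.binarize_matrix(self._auc({"r1": np.zeros(100)}), n_boot=50)
        assert bam.values.shape[0] == 0
        assert report.loc["r1", "modality"] == "degenerate"

    def test_isl1_regulon_recovers_wt_amnion(self, small_sim):
        cfg, m, truth = small_sim
        wt_cells = list(truth.condition.index[truth.condition == "wt"])
        m_wt = m.subset_cells_by_barcode(wt_cells)
        kept = R.prefilter_genes(m_wt)
        m_pre = m_wt.subset_genes(m_wt.gene_index(kept))
        auc = R.auc_score(m_pre, truth.regulon, seed=0)
        report, bam = R.binarize_matrix(auc, n_boot=300, seed=0)
        tf = cfg.regulon_tf
        assert tf in bam.values.index
        assert report.loc[tf, "modality"] == "bimodal"
        active = bam.values.loc[tf]
        is_am = truth.cell_type.reindex(active.index).isin(["AM-1", "AM-2"])
        sens = active[is_am.values].mean()
        spec = 1.0 - active[~is_am.values].mean()
        assert sens >= 0.95 and spec >= 0.95
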