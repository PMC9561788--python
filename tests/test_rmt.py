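"""Spearman matrices, spectral unfolding, NNSD tests, threshold selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pmenet import (AbundanceTable, CorrelationMatrix, nnsd_poisson_test,
                    scan_thresholds, select_threshold, spacing_gof,
                    spearman_matrix, threshold_matrix, unfold_spectrum)
from pmenet.rmt import ThresholdScan


def table_from_rows(rows: np.ndarray) -> AbundanceTable:
    rows = np.asarray(rows)
    n = rows.shape[1]
    counts = pd.DataFrame(rows, index=[f"A{i}" for i in range(len(rows))],
                          columns=[f"S{j}" for j in range(n)])
    meta = pd.DataFrame({"group": ["aeration"] * n, "layer": ["top"] * n,
                         "week": [1] * n, "replicate": range(n)},
                        index=counts.columns)
    tax = pd.Series({a: "B;P" for a in counts.index})
    return AbundanceTable(counts=counts, taxonomy=tax, metadata=meta)


def rank_pearson(x, y):
    """Independent Spearman oracle (scipy's pairwise implementation)."""
    return stats.spearmanr(x, y).statistic


class TestSpearman:
    def test_perfect_antimonotone(self):
        corr = spearman_matrix(table_from_rows([[1, 2, 3], [3, 2, 1]]))
        assert corr.values[0, 1] == pytest.approx(-1.0)

    def test_printed_formula_no_ties(self):
        # d^2 = (0,0,0,1,1): 1 - 6*2/(5*24) = 0.9
        corr = spearman_matrix(table_from_rows([[1, 2, 3, 4, 5],
                                                [1, 2, 3, 5, 4]]))
        assert corr.values[0, 1] == pytest.approx(0.9)

    def test_monotone_transform_invariance(self):
        x = np.array([3, 1, 4, 1, 5, 9, 2, 6])
        y = np.array([2, 7, 1, 8, 2, 8, 1, 8])
        a = spearman_matrix(table_from_rows([x, y])).values[0, 1]
        b = spearman_matrix(table_from_rows([x**2, y])).values[0, 1]
        assert a == pytest.approx(b, abs=1e-12)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            x = rng.integers(0, 50, size=10)
            y = rng.integers(0, 50, size=10)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            got = spearman_matrix(table_from_rows([x, y])).values[0, 1]
            assert got == pytest.approx(rank_pearson(x, y), abs=1e-12)

    def test_zero_variance_asv_gets_zero(self, caplog):
        corr = spearman_matrix(table_from_rows([[1, 2, 3, 4],
                                                [5, 5, 5, 5],
                                                [4, 3, 2, 1]]))
        assert corr.values[0, 1] == 0.0 and corr.values[1, 2] == 0.0
        assert corr.values[0, 2] == pytest.approx(-1.0)

    def test_symmetry_unit_diagonal(self):
        rng = np.random.default_rng(1)
        corr = spearman_matrix(table_from_rows(rng.integers(0, 100, (8, 12))))
        assert np.array_equal(corr.values, corr.values.T)
        assert np.all(np.diag(corr.values) == 1.0)


class TestThresholdMatrix:
    def make(self, off):
        v = np.eye(3)
        v[0, 1] = v[1, 0] = off[0]
        v[0, 2] = v[2, 0] = off[1]
        v[1, 2] = v[2, 1] = off[2]
        return CorrelationMatrix(values=v, asv_ids=["a", "b", "c"], n_obs=10)

    def test_absolute_value_rule(self):
        sub = threshold_matrix(self.make([0.9, -0.85, 0.5]), 0.83)
        off = sub.off_diagonal()
        assert sorted(np.round(off[off != 0], 2)) == [-0.85, 0.9]

    def test_above_max_gives_empty(self):
        sub = threshold_matrix(self.make([0.3, 0.2, 0.1]), 0.5)
        assert sub.size == 0

    def test_node_count_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        v = rng.uniform(-1, 1, (30, 30))
        v = np.triu(v, 1) + np.triu(v, 1).T
        np.fill_diagonal(v, 1.0)
        corr = CorrelationMatrix(values=v, asv_ids=[f"a{i}" for i in range(30)],
                                 n_obs=10)
        sizes = [threshold_matrix(corr, t).size for t in (0.5, 0.6, 0.7)]
        assert sizes == sorted(sizes, reverse=True)


class TestUnfolding:
    def test_equispaced_spectrum_unit_spacings(self):
        s = unfold_spectrum(np.arange(1.0, 101.0))
        assert np.allclose(s.spacings, 1.0, atol=1e-6)
        assert s.mean == pytest.approx(1.0, abs=1e-9)

    def test_goe_matches_wigner_not_poisson(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((500, 500))
        s = unfold_spectrum(np.linalg.eigvalsh((x + x.T) / np.sqrt(2)))
        assert s.mean == pytest.approx(1.0, abs=0.05)
        assert spacing_gof(s, "wigner", n_bins=20).p_value >= 0.01
        assert nnsd_poisson_test(s).p_value < 0.05

    def test_iid_levels_match_poisson(self):
        rng = np.random.default_rng(8)
        s = unfold_spectrum(rng.uniform(0, 1, 500))
        assert nnsd_poisson_test(s).p_value >= 0.01

    def test_too_small_spectrum_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            unfold_spectrum(np.arange(10.0))


class TestPoissonGof:
    def test_exponential_null_accepts(self):
        accept = sum(
            nnsd_poisson_test(
                np.random.default_rng(s).exponential(1, 1000)).p_value >= 0.05
            for s in range(20)
        )
        assert accept >= 17

    def test_wigner_alternative_rejects(self):
        reject = 0
        for s in range(20):
            u = np.random.default_rng(s).uniform(size=1000)
            w = np.sqrt(-4 * np.log1p(-u) / np.pi)  # Wigner surmise draws
            reject += nnsd_poisson_test(w).p_value < 0.05
        assert reject >= 17

    def test_degenerate_spacings_reject(self):
        res = nnsd_poisson_test(np.ones(200))
        assert res.p_value < 1e-10


class TestScanSelect:
    def test_identity_plus_noise_untestable_above_noise(self):
        rng = np.random.default_rng(3)
        v = rng.uniform(-0.19, 0.19, (40, 40))
        v = np.triu(v, 1) + np.triu(v, 1).T
        np.fill_diagonal(v, 1.0)
        corr = CorrelationMatrix(values=v, asv_ids=[f"a{i}" for i in range(40)],
                                 n_obs=10)
        scan = scan_thresholds(corr, t_min=0.2, t_max=0.9, step=0.1)
        assert not scan.table["testable"].any()

    def test_default_grid_has_95_rows(self):
        rng = np.random.default_rng(4)
        v = rng.uniform(-0.9, 0.9, (25, 25))
        v = np.triu(v, 1) + np.triu(v, 1).T
        np.fill_diagonal(v, 1.0)
        corr = CorrelationMatrix(values=v, asv_ids=[f"a{i}" for i in range(25)],
                                 n_obs=10)
        scan = scan_thresholds(corr)
        assert len(scan.table) == 95
        assert scan.table["threshold"].iloc[0] == pytest.approx(0.01)
        assert scan.table["threshold"].iloc[-1] == pytest.approx(0.95)

    @staticmethod
    def scan_from_pattern(pattern, t0=0.28):
        rows = []
        for i, ok in enumerate(pattern):
            rows.append({"threshold": round(t0 + 0.01 * i, 2), "n_nodes": 50 - i,
                         "n_eigenvalues": 50 - i, "chi2": 1.0, "dof": 5,
                         "p_value": 0.5 if ok else 0.001, "poisson_ok": ok,
                         "testable": True})
        return ThresholdScan(table=pd.DataFrame(rows), alpha=0.05)

    def test_two_consecutive_rule(self):
        scan = self.scan_from_pattern([False, False, True, True, True])
        assert select_threshold(scan, "auto") == pytest.approx(0.30)

    def test_flicker_skipped(self):
        scan = self.scan_from_pattern([False, True, False, True, True],
                                      t0=0.01)
        assert select_threshold(scan, "auto") == pytest.approx(0.04)

    def test_fixed_mode_verbatim(self):
        scan = self.scan_from_pattern([False, False])
        assert select_threshold(scan, "fixed", fixed_t=0.83) == 0.83

    def test_auto_without_acceptance_raises_with_table(self):
        scan = self.scan_from_pattern([False, True, False])
        with pytest.raises(ValueError, match="threshold"):
            select_threshold(scan, "auto")
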