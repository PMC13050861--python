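"""Structure covariates, kinship, GLM/MLM scans and FDR control."""

import numpy as np
import pandas as pd
import pytest

from conftest import band_matrix_from_array
from popkit.association import (
    KinshipMatrix,
    _reml_delta,
    fdr_adjust,
    glm_scan,
    kinship,
    marker_pcs,
    mlm_scan,
    qq_data,
    report_associations,
    records_to_frame,
)
from popkit.genotypes import BandMatrix
from popkit.simulate import SimulationConfig, simulate_dataset


class TestMarkerPCs:
    def test_separates_two_populations(self, small_dataset):
        matrix, _, truth = small_dataset
        pcs = marker_pcs(matrix)
        pc1 = pcs["PC1"].to_numpy()
        labels = truth.pop_assignment.astype(float)
        r = np.corrcoef(pc1, labels)[0, 1]
        assert abs(r) > 0.95

    def test_rank_one_matrix(self):
        col = np.array([1, 1, 1, 0, 0, 0])
        arr = np.column_stack([col, col, 1 - col])
        m = band_matrix_from_array(arr)
        with pytest.warns(UserWarning, match="rank"):
            pcs = marker_pcs(m, n_pc=5)
        total_var = np.var(pcs.to_numpy(), axis=0).sum()
        assert np.var(pcs["PC1"]) / total_var == pytest.approx(1.0)

    def test_bit_identical_repeats(self, study_dataset):
        matrix, _, _ = study_dataset
        a = marker_pcs(matrix)
        b = marker_pcs(matrix)
        assert a.equals(b)

    def test_q_matrix_covariates_usable(self, small_dataset):
        from popkit.association import q_covariates

        matrix, traits, truth = small_dataset
        q = pd.DataFrame(
            truth.true_Q, index=matrix.accession_ids,
            columns=[f"Q{k}" for k in range(truth.true_Q.shape[1])],
        )
        cov = q_covariates(q)
        assert cov.shape[1] == truth.true_Q.shape[1] - 1
        recs = glm_scan(traits.values["AC"], matrix, cov)
        assert sum(not np.isnan(r.p_raw) for r in recs) > 100


class TestKinship:
    def test_duplicated_accessions_maximal(self):
        rng = np.random.default_rng(0)
        row = (rng.random(50) < 0.5).astype(int)
        arr = np.vstack([row, row] + [(rng.random(50) < 0.5).astype(int) for _ in range(8)])
        kin = kinship(band_matrix_from_array(arr))
        assert kin.K[0, 1] == pytest.approx(kin.K[0, 0], abs=1e-9)

    def test_panmictic_off_diagonal_near_zero(self):
        cfg = SimulationConfig(
            n_accessions=60, n_markers=80, n_pops=1, missing_rate=0.0, seed=13
        )
        matrix, _, _ = simulate_dataset(cfg)
        kin = kinship(matrix)
        off = kin.K[~np.eye(len(kin.K), dtype=bool)]
        assert abs(off.mean()) < 0.05

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetric_psd(self, seed):
        rng = np.random.default_rng(seed)
        arr = (rng.random((12, 30)) < rng.random(30)).astype(int)
        arr[rng.random(arr.shape) < 0.05] = -9
        kin = kinship(band_matrix_from_array(arr))
        assert np.allclose(kin.K, kin.K.T, atol=1e-10)
        assert np.linalg.eigvalsh(kin.K).min() > -1e-8
        assert np.mean(np.diag(kin.K)) == pytest.approx(1.0)


class TestGLM:
    def test_perfect_signal(self, small_dataset):
        matrix, _, _ = small_dataset
        band = next(
            b for b in matrix.band_ids if matrix.values[b].nunique() == 2
            and 5 <= matrix.values[b].sum() <= 35
        )
        y = pd.Series(
            matrix.values[band].to_numpy(float), index=matrix.accession_ids, name="y"
        )
        cov = marker_pcs(matrix)
        recs = glm_scan(y, matrix, cov)
        rec = next(r for r in recs if r.band_id == band)
        assert rec.p_raw < 1e-12

    def test_f_statistic_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        n = 12
        arr = (rng.random((n, 8)) < 0.5).astype(int)
        arr[:, 0] = [0, 1] * 6  # ensure polymorphic target band
        m = band_matrix_from_array(arr)
        y = pd.Series(rng.normal(size=n), index=m.accession_ids, name="y")
        cov = pd.DataFrame(
            rng.normal(size=(n, 2)), index=m.accession_ids, columns=["c1", "c2"]
        )
        recs = glm_scan(y, m, cov)
        for rec in recs:
            if np.isnan(rec.p_raw):
                continue
            x = m.values[rec.band_id].to_numpy(float)
            X = sm.add_constant(np.column_stack([cov.to_numpy(), x]))
            fit = sm.OLS(y.to_numpy(), X).fit()
            t = fit.tvalues[-1]
            assert rec.statistic == pytest.approx(t**2, rel=1e-8)
            assert rec.p_raw == pytest.approx(fit.pvalues[-1], rel=1e-8)

    def test_constant_band_flagged(self):
        arr = np.array([[1, 1], [1, 0], [1, 1], [1, 0]])
        m = band_matrix_from_array(arr)
        y = pd.Series([1.0, 2.0, 3.0, 4.0], index=m.accession_ids, name="y")
        cov = pd.DataFrame(index=m.accession_ids)
        recs = glm_scan(y, m, cov)
        assert recs[0].flag == "constant_band"
        assert np.isnan(recs[0].p_raw)

    def test_trait_affine_invariance(self, small_dataset):
        matrix, traits, _ = small_dataset
        cov = marker_pcs(matrix)
        y = traits.values["AC"]
        p1 = [r.p_raw for r in glm_scan(y, matrix, cov)]
        p2 = [r.p_raw for r in glm_scan(3.7 * y + 11.0, matrix, cov)]
        assert np.allclose(p1, p2, rtol=1e-8, equal_nan=True)


class TestMLM:
    def test_identity_kinship_reduces_to_glm(self, small_dataset):
        matrix, traits, _ = small_dataset
        cov = marker_pcs(matrix)
        y = traits.values["AC"]
        kin = KinshipMatrix(matrix.accession_ids, np.eye(matrix.n_accessions))
        glm_p = np.array([r.p_raw for r in glm_scan(y, matrix, cov)])
        mlm_p = np.array([r.p_raw for r in mlm_scan(y, matrix, cov, kin)])
        assert np.allclose(glm_p, mlm_p, atol=1e-6, equal_nan=True)

    def test_reml_delta_recovery(self):
        """Known delta = 1 (ln delta = 0) recovered within 0.3 on ln scale."""
        cfg = SimulationConfig(
            n_accessions=200, n_markers=80, n_pops=1, missing_rate=0.0, seed=17
        )
        matrix, _, _ = simulate_dataset(cfg)
        kin = kinship(matrix)
        vals, vecs = np.linalg.eigh(kin.K)
        vals = np.clip(vals, 0, None)
        root = vecs @ np.diag(np.sqrt(vals)) @ vecs.T
        n = 200
        X = np.ones((n, 1))
        errs = []
        rng = np.random.default_rng(3)
        for _ in range(10):
            u = root @ rng.normal(size=n)
            y = X[:, 0] * 0.5 + u + rng.normal(size=n)  # sigma_g = sigma_e = 1
            delta, *_ = _reml_delta(y, X, kin.K)
            errs.append(np.log(delta))
        assert abs(np.mean(errs)) < 0.3

    def test_mlm_deflates_structured_inflation(self, study_dataset):
        """Polygenic trait on structured panel: MLM lambda closer to 1."""
        from scipy import stats

        matrix, _, truth = study_dataset
        cov = marker_pcs(matrix)
        kin = kinship(matrix)
        x = matrix.values.to_numpy().astype(float)
        x[x == -9] = np.nan
        xm = np.nan_to_num(x - np.nanmean(x, axis=0))
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            beta = rng.normal(0, 1, size=xm.shape[1])
            g = xm @ beta
            g *= np.sqrt(2.0) / g.std()
            y = pd.Series(
                g + rng.normal(size=len(g)), index=matrix.accession_ids, name="poly"
            )

            def lam(recs):
                p = np.array([r.p_raw for r in recs])
                p = p[~np.isnan(p)]
                chi = stats.chi2.isf(p, 1)
                return np.median(chi) / stats.chi2.ppf(0.5, 1)

            l_glm = lam(glm_scan(y, matrix, cov))
            l_mlm = lam(mlm_scan(y, matrix, cov, kin))
            if abs(l_mlm - 1) < abs(l_glm - 1):
                wins += 1
        assert wins >= 8


class TestFDR:
    def test_hand_bh(self):
        q = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert fdr_adjust([0.2])[0] == pytest.approx(0.2)

    def test_order_invariance_and_na(self):
        p = [0.04, np.nan, 0.001, 0.2]
        q = fdr_adjust(p)
        q_sorted_in = fdr_adjust([0.001, 0.04, 0.2, np.nan])
        assert np.isnan(q[1]) and np.isnan(q_sorted_in[3])
        assert sorted(q[~np.isnan(q)]) == sorted(q_sorted_in[:3])

    def test_q_dominates_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        q = fdr_adjust(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestReporting:
    def test_no_discoveries_when_all_p_one(self):
        df = pd.DataFrame(
            {"band": ["b1"], "marker": ["m1"], "trait": ["t"], "model": ["GLM"],
             "effect": [0.0], "statistic": [0.0], "p_raw": [1.0], "q_fdr": [1.0],
             "flag": [""]}
        )
        assert len(report_associations(df)) == 0

    def test_qq_expected_quantiles(self):
        df = qq_data([0.5, 0.1, 0.9, 0.01])
        m = 4
        expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
        assert np.allclose(df["expected"], expected)
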