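"""Marker-trait association for dominant markers: GLM (Q) and MLM (Q+K).

Population structure is captured by the top principal components of the
column-centred band matrix (5 by default, the usual "Q" covariates) or,
optionally, by admixture proportions.  The GLM tests each band with a
1-df F-test of y ~ covariates + band against y ~ covariates.  The MLM adds
a polygenic random effect u ~ N(0, sigma2_g K) with K a marker-derived
kinship matrix; variance components are estimated once per trait by REML on
the null model (EMMA eigendecomposition, 1-D profile over
delta = sigma2_e/sigma2_g) and reused for every marker test (the
P3D/EMMAX approximation).  Raw p-values are corrected by Benjamini-Hochberg
FDR within each trait x model family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests

from .genotypes import MISSING, BandMatrix
from .traits import TraitTable

__all__ = [
    "KinshipMatrix",
    "AssociationRecord",
    "marker_pcs",
    "q_covariates",
    "kinship",
    "glm_scan",
    "mlm_scan",
    "fdr_adjust",
    "association_study",
    "report_associations",
    "qq_data",
    "manhattan_data",
]


def _imputed_centered(matrix: BandMatrix) -> np.ndarray:
    """0/1 matrix with missing cells mean-imputed per band, then centred."""
    x = matrix.values.to_numpy().astype(float)
    x[x == MISSING] = np.nan
    col_mean = np.nanmean(x, axis=0)
    nan_idx = np.where(np.isnan(x))
    x[nan_idx] = np.take(col_mean, nan_idx[1])
    return x - x.mean(axis=0)


def marker_pcs(matrix: BandMatrix, n_pc: int = 5) -> pd.DataFrame:
    """Top principal-component scores of the band matrix (structure covariates).

    Scores are left singular vectors scaled by singular values; each
    component's sign is fixed so its largest-magnitude loading is positive,
    making repeated runs bit-identical.
    """
    W = _imputed_centered(matrix)
    U, s, Vt = np.linalg.svd(W, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
    k = min(n_pc, rank)
    if k < n_pc:
        warnings.warn(f"matrix rank {rank} < requested {n_pc} PCs; returning {k}")
    for j in range(k):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    scores = U[:, :k] * s[:k]
    return pd.DataFrame(
        scores, index=matrix.accession_ids, columns=[f"PC{i + 1}" for i in range(k)]
    )


def q_covariates(q_frame: pd.DataFrame) -> pd.DataFrame:
    """Admixture proportions as structure covariates.

    Drops the last cluster column (rows of Q sum to 1, so the full matrix is
    collinear with the intercept).  Alternative to :func:`marker_pcs`.
    """
    return q_frame.iloc[:, :-1]


@dataclass
class KinshipMatrix:
    ids: list[str]
    K: np.ndarray
    construction: str = "marker_vanraden"

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        if not np.allclose(self.K, self.K.T, atol=1e-10):
            raise ValueError("kinship must be symmetric")


def kinship(matrix: BandMatrix) -> KinshipMatrix:
    """Marker-based realized relationship matrix K = W W'/L.

    W is the centred (mean-imputed) band matrix.  K is rescaled so its mean
    diagonal is 1 and eigenvalue-clamped to positive semidefinite.
    """
    W = _imputed_centered(matrix)
    K = W @ W.T / W.shape[1]
    K /= np.mean(np.diag(K))
    vals, vecs = np.linalg.eigh(K)
    if vals.min() < -1e-8:
        vals = np.clip(vals, 0.0, None)
        K = vecs @ np.diag(vals) @ vecs.T
        K /= np.mean(np.diag(K))
    return KinshipMatrix(matrix.accession_ids, K)


@dataclass
class AssociationRecord:
    band_id: str
    marker_id: str
    trait: str
    model: str
    effect: float
    statistic: float
    df: tuple[int, int]
    p_raw: float
    q_fdr: float = np.nan
    sigma2_g: float | None = None
    sigma2_e: float | None = None
    flag: str = ""


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _f_test(rss0: float, rss1: float, df_resid: int) -> tuple[float, float]:
    if df_resid <= 0 or rss1 <= 0:
        return np.inf, 0.0
    F = (rss0 - rss1) / (rss1 / df_resid)
    F = max(F, 0.0)
    p = float(stats.f.sf(F, 1, df_resid))
    return F, max(p, np.finfo(float).tiny)


def glm_scan(
    trait: pd.Series, matrix: BandMatrix, covariates: pd.DataFrame
) -> list[AssociationRecord]:
    """Per-band OLS F-tests of y ~ 1 + covariates + band."""
    y_all = trait.reindex(matrix.accession_ids).to_numpy(float)
    C = covariates.reindex(matrix.accession_ids).to_numpy(float)
    X0_all = np.column_stack([np.ones(len(y_all)), C])
    records = []
    geno = matrix.values.to_numpy()
    for j, band in enumerate(matrix.band_ids):
        x = geno[:, j].astype(float)
        keep = (x != MISSING) & ~np.isnan(y_all)
        xs, ys, X0 = x[keep], y_all[keep], X0_all[keep]
        marker = matrix.marker_of_band[band]
        if xs.size == 0 or np.all(xs == xs[0]):
            records.append(
                AssociationRecord(band, marker, trait.name, "GLM", np.nan, np.nan,
                                  (0, 0), np.nan, flag="constant_band")
            )
            continue
        X1 = np.column_stack([X0, xs])
        rss0 = _ols_rss(X0, ys)
        rss1 = _ols_rss(X1, ys)
        df_resid = len(ys) - X1.shape[1]
        F, p = _f_test(rss0, rss1, df_resid)
        beta = np.linalg.lstsq(X1, ys, rcond=None)[0][-1]
        records.append(
            AssociationRecord(band, marker, trait.name, "GLM", float(beta), F,
                              (1, df_resid), p)
        )
    return records


def _reml_delta(y: np.ndarray, X: np.ndarray, K: np.ndarray) -> tuple[float, float, float, str]:
    """EMMA REML: profile the likelihood over log-delta in [-10, 10].

    Returns (delta_hat, sigma2_g, sigma2_e, flag).
    """
    n, p = X.shape
    # residual-space eigendecomposition of S K S
    Q, _ = np.linalg.qr(X)
    S = np.eye(n) - Q @ Q.T
    vals, vecs = np.linalg.eigh(S @ K @ S)
    order = np.argsort(vals)[::-1]
    xi = vals[order][: n - p]
    U = vecs[:, order][:, : n - p]
    eta = U.T @ y
    xi = np.clip(xi, 0.0, None)

    def neg_reml(log_delta: float) -> float:
        delta = np.exp(log_delta)
        denom = xi + delta
        return float(
            (n - p) * np.log(np.sum(eta**2 / denom)) + np.sum(np.log(denom))
        )

    res = minimize_scalar(neg_reml, bounds=(-10.0, 10.0), method="bounded")
    ld = float(res.x)
    flag = "delta_boundary" if abs(ld) > 9.99 else ""
    delta = float(np.exp(ld))
    sigma2_g = float(np.sum(eta**2 / (xi + delta)) / (n - p))
    sigma2_e = delta * sigma2_g
    return delta, sigma2_g, sigma2_e, flag


def mlm_scan(
    trait: pd.Series,
    matrix: BandMatrix,
    covariates: pd.DataFrame,
    kin: KinshipMatrix,
) -> list[AssociationRecord]:
    """EMMAX-style mixed-model scan (P3D: null-model variance components).

    Per marker, generalized least squares under V = sigma2_g (K + delta I)
    with listwise deletion of missing genotypes; the marker coefficient is
    tested with a 1-df F (squared Wald) test.
    """
    ids = matrix.accession_ids
    if kin.ids != ids:
        raise ValueError("kinship ids must match the band matrix")
    y_all = trait.reindex(ids).to_numpy(float)
    C = covariates.reindex(ids).to_numpy(float)
    X0_all = np.column_stack([np.ones(len(y_all)), C])
    Kfull = kin.K
    if np.linalg.eigvalsh(Kfull).min() < -1e-8:
        raise ValueError("kinship matrix is not positive semidefinite")
    ok = ~np.isnan(y_all)
    delta, s2g, s2e, flag0 = _reml_delta(y_all[ok], X0_all[ok], Kfull[np.ix_(ok, ok)])
    records = []
    geno = matrix.values.to_numpy()
    chol_cache: dict[bytes, np.ndarray] = {}
    for j, band in enumerate(matrix.band_ids):
        x = geno[:, j].astype(float)
        keep = (x != MISSING) & ok
        marker = matrix.marker_of_band[band]
        xs = x[keep]
        if xs.size == 0 or np.all(xs == xs[0]):
            records.append(
                AssociationRecord(band, marker, trait.name, "MLM", np.nan, np.nan,
                                  (0, 0), np.nan, s2g, s2e, flag="constant_band")
            )
            continue
        key = keep.tobytes()
        Lc = chol_cache.get(key)
        if Lc is None:
            V = Kfull[np.ix_(keep, keep)] + delta * np.eye(int(keep.sum()))
            Lc = np.linalg.cholesky(V)
            chol_cache[key] = Lc
        X1 = np.column_stack([X0_all[keep], xs])
        yt = solve_triangular(Lc, y_all[keep], lower=True)
        Xt = solve_triangular(Lc, X1, lower=True)
        X0t = solve_triangular(Lc, X0_all[keep], lower=True)
        rss0 = _ols_rss(X0t, yt)
        rss1 = _ols_rss(Xt, yt)
        df_resid = len(yt) - X1.shape[1]
        F, p = _f_test(rss0, rss1, df_resid)
        beta = np.linalg.lstsq(Xt, yt, rcond=None)[0][-1]
        records.append(
            AssociationRecord(band, marker, trait.name, "MLM", float(beta), F,
                              (1, df_resid), p, s2g, s2e, flag=flag0)
        )
    return records


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaNs pass through unchanged."""
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def records_to_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "band": r.band_id,
                "marker": r.marker_id,
                "trait": r.trait,
                "model": r.model,
                "effect": r.effect,
                "statistic": r.statistic,
                "p_raw": r.p_raw,
                "q_fdr": r.q_fdr,
                "flag": r.flag,
            }
            for r in records
        ]
    )


def association_study(
    traits: TraitTable,
    matrix: BandMatrix,
    models: tuple[str, ...] = ("GLM", "MLM"),
    n_pc: int = 5,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Scan every trait with the requested models; FDR within trait x model."""
    if covariates is None:
        covariates = marker_pcs(matrix, n_pc)
    kin = kinship(matrix) if "MLM" in models else None
    all_records: list[AssociationRecord] = []
    for t in traits.trait_names:
        y = traits.values[t]
        for model in models:
            recs = (
                glm_scan(y, matrix, covariates)
                if model == "GLM"
                else mlm_scan(y, matrix, covariates, kin)
            )
            qs = fdr_adjust([r.p_raw for r in recs])
            for r, q in zip(recs, qs):
                r.q_fdr = float(q)
            all_records.extend(recs)
    return records_to_frame(all_records)


def report_associations(
    results: pd.DataFrame, p_threshold: float = 0.05, fdr_level: float = 0.05
) -> pd.DataFrame:
    """Significant records: p <= threshold screen, then q below the FDR line."""
    sig = results[(results["p_raw"] <= p_threshold) & (results["q_fdr"] <= fdr_level)]
    return sig.sort_values(["trait", "model", "p_raw"]).reset_index(drop=True)


def qq_data(p_values) -> pd.DataFrame:
    """Expected vs observed -log10 p for a QQ plot."""
    p = np.sort(np.asarray([v for v in p_values if not np.isnan(v)]))
    m = len(p)
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    return pd.DataFrame({"expected": expected, "observed": -np.log10(p)})


def manhattan_data(results: pd.DataFrame, p_threshold: float = 0.05) -> pd.DataFrame:
    """Marker index vs -log10 p, with the significance line attached."""
    df = results.reset_index(drop=True).copy()
    df["index"] = np.arange(len(df))
    df["neg_log10_p"] = -np.log10(df["p_raw"])
    df.attrs["threshold_line"] = -np.log10(p_threshold)
    return df[["index", "band", "marker", "trait", "model", "neg_log10_p"]]
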