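"""Phenotype analytics: descriptive statistics, mixed PCA, correlations.

A trait table holds one column per trait over the accession panel.  Traits
are either quantitative (continuous measurements, e.g. plant height in cm)
or qualitative (integer class codes, e.g. leaf colour categories).  The
standard germplasm-characterisation summary is computed per trait: mean,
sample SD, coefficient of variation CV = SD/mean x 100%, and the
Shannon-Wiener index H' = -sum_c p_c ln p_c over the frequency distribution
of distinct observed values.

Mixed PCA follows the PCAmix construction: quantitative columns are
z-scored; each qualitative trait is expanded into centred category
indicators weighted by 1/sqrt(p_category) (the MCA metric), and the combined
matrix is factored by SVD.  With only quantitative traits this reduces
exactly to correlation-matrix PCA.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

# the 18 study traits: 10 quantitative, 8 qualitative (coded)
QUANTITATIVE_TRAITS = ["PH", "PW", "LL", "LW", "PL", "PD", "NL", "RCL", "AC", "FSL"]
QUALITATIVE_TRAITS = ["LC", "LS", "LA", "LP", "PC", "RC", "FS", "FSS"]

__all__ = [
    "TraitTable",
    "read_trait_table",
    "write_trait_table",
    "trait_summary",
    "mixed_pca",
    "trait_correlations",
    "QUANTITATIVE_TRAITS",
    "QUALITATIVE_TRAITS",
]


@dataclass
class TraitTable:
    """Accessions x traits table with a set of qualitative column names."""

    values: pd.DataFrame
    qualitative: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        unknown = self.qualitative - set(self.values.columns)
        if unknown:
            raise ValueError(f"qualitative traits not in table: {sorted(unknown)}")
        for t in self.qualitative:
            col = self.values[t].dropna()
            if ((col != col.round()) | (col <= 0)).any():
                raise ValueError(f"qualitative trait {t!r} must hold positive integer codes")

    @property
    def accession_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def trait_names(self) -> list[str]:
        return list(self.values.columns)

    def is_qualitative(self, trait: str) -> bool:
        return trait in self.qualitative


def write_trait_table(table: TraitTable, path: str | Path) -> None:
    path = Path(path)
    table.values.to_csv(path, sep="\t", index_label="accession")
    sidecar = path.with_suffix(path.suffix + ".types.json")
    sidecar.write_text(json.dumps({"qualitative": sorted(table.qualitative)}))


def read_trait_table(path: str | Path, qualitative: list[str] | None = None) -> TraitTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if qualitative is None:
        sidecar = path.with_suffix(path.suffix + ".types.json")
        qualitative = (
            json.loads(sidecar.read_text())["qualitative"] if sidecar.exists() else []
        )
    return TraitTable(df, set(qualitative))


def _shannon_wiener(values: pd.Series) -> float:
    counts = values.value_counts().to_numpy(dtype=float)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log(p)))


def trait_summary(table: TraitTable) -> pd.DataFrame:
    """Per-trait mean, SD, CV (%) and Shannon-Wiener H' (nats).

    H' uses the distinct observed values as classes (qualitative codes are
    classes by definition; for quantitative traits distinct measured values
    are used unbinned).  CV is NaN when the mean is zero.
    """
    rows = []
    for t in table.trait_names:
        col = table.values[t].dropna()
        if len(col) < 2:
            raise ValueError(f"trait {t!r} has fewer than 2 non-missing values")
        mean = float(col.mean())
        sd = float(col.std(ddof=1))
        cv = sd / mean * 100.0 if mean != 0 else np.nan
        rows.append(
            {
                "trait": t,
                "type": "qualitative" if table.is_qualitative(t) else "quantitative",
                "mean": mean,
                "sd": sd,
                "cv_percent": cv,
                "shannon_wiener": _shannon_wiener(col),
            }
        )
    return pd.DataFrame(rows).set_index("trait")


@dataclass
class MixedPCAResult:
    scores: pd.DataFrame          # accessions x components
    loadings: pd.DataFrame        # expanded columns x components
    trait_contributions: pd.DataFrame  # original traits x components (sum of sq loadings)
    percent_variance: np.ndarray


def _impute(col: pd.Series, qualitative: bool) -> pd.Series:
    if not col.isna().any():
        return col
    fill = col.mode().iloc[0] if qualitative else col.mean()
    return col.fillna(fill)


def mixed_pca(table: TraitTable, n_components: int | None = None) -> MixedPCAResult:
    """PCAmix-style PCA over mixed quantitative/qualitative traits."""
    n = len(table.values)
    blocks: list[np.ndarray] = []
    col_names: list[str] = []
    col_trait: list[str] = []
    dropped: list[str] = []
    for t in table.trait_names:
        col = _impute(table.values[t], table.is_qualitative(t))
        if table.is_qualitative(t):
            codes = col.astype(int)
            cats = sorted(codes.unique())
            if len(cats) < 2:
                dropped.append(t)
                continue
            for c in cats:
                ind = (codes == c).to_numpy(float)
                p = ind.mean()
                blocks.append((ind - p) / np.sqrt(p))
                col_names.append(f"{t}={c}")
                col_trait.append(t)
        else:
            x = col.to_numpy(float)
            sd = x.std(ddof=1)
            if sd == 0:
                dropped.append(t)
                continue
            blocks.append((x - x.mean()) / sd)
            col_names.append(t)
            col_trait.append(t)
    if len(blocks) < 2:
        raise ValueError("need at least 2 usable trait columns")
    Z = np.column_stack(blocks) / np.sqrt(n - 1)
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    # deterministic sign: largest-|loading| entry positive per component
    for j in range(len(s)):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    var = s**2
    pct = var / var.sum() * 100.0
    k = n_components or len(s)
    comp_names = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(
        U[:, :k] * s[:k] * np.sqrt(n - 1), index=table.values.index, columns=comp_names
    )
    loadings = pd.DataFrame(Vt[:k].T, index=col_names, columns=comp_names)
    contrib = (loadings**2).groupby(pd.Index(col_trait, name="trait")).sum()
    res = MixedPCAResult(scores, loadings, contrib, pct[:k])
    res.dropped = dropped  # type: ignore[attr-defined]
    return res


def trait_correlations(table: TraitTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations with significance flags.

    Returns (r matrix, flag matrix) where flags are ``**`` for p < 0.01,
    ``*`` for p < 0.05, ``""`` otherwise (diagonal flagged ``""``).
    Qualitative codes are correlated on their integer values — a linear
    approximation, flagged as such in the documentation.
    """
    names = table.trait_names
    m = len(names)
    r = pd.DataFrame(np.eye(m), index=names, columns=names)
    flags = pd.DataFrame("", index=names, columns=names)
    for i in range(m):
        for j in range(i + 1, m):
            a = table.values[names[i]]
            b = table.values[names[j]]
            mask = a.notna() & b.notna()
            if mask.sum() < 3 or a[mask].std() == 0 or b[mask].std() == 0:
                r.iloc[i, j] = r.iloc[j, i] = np.nan
                continue
            rr, p = stats.pearsonr(a[mask], b[mask])
            r.iloc[i, j] = r.iloc[j, i] = rr
            flag = "**" if p < 0.01 else "*" if p < 0.05 else ""
            flags.iloc[i, j] = flags.iloc[j, i] = flag
    return r, flags
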