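"""Distance-based AMOVA and Wright's Fst from variance components.

One-level analysis of molecular variance on a matrix of pairwise genetic
distances (here squared Jaccard distances between band profiles):

    SS_total  = (1/N) sum_{i<j} d_ij^2
    SS_within = sum_g (1/n_g) sum_{i<j in g} d_ij^2
    SS_among  = SS_total - SS_within

with df_among = G-1, df_within = N-G, average sample-size coefficient
n0 = (N - sum n_g^2 / N)/(G-1), variance components sigma2_w = MS_within and
sigma2_a = (MS_among - MS_within)/n0, and the Phi-statistic

    Fst = sigma2_a / (sigma2_a + sigma2_w)

Significance is assessed by permuting group labels and recomputing Fst,
with the +1-corrected p-value p = (1 + #{perm >= obs})/(n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distance import DistanceMatrix

__all__ = ["AMOVAResult", "amova", "fst_from_components", "pairwise_fst"]


@dataclass
class AMOVAResult:
    df_among: int
    df_within: int
    SS_among: float
    SS_within: float
    SS_total: float
    MS_among: float
    MS_within: float
    n0: float
    sigma2_among: float
    sigma2_within: float
    Fst: float
    percent_among: float
    percent_within: float
    p_perm: float | None
    n_perm: int
    clamped: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "source": "among populations",
                    "df": self.df_among,
                    "SS": self.SS_among,
                    "MS": self.MS_among,
                    "variance_component": self.sigma2_among,
                    "percent": self.percent_among,
                },
                {
                    "source": "within populations",
                    "df": self.df_within,
                    "SS": self.SS_within,
                    "MS": self.MS_within,
                    "variance_component": self.sigma2_within,
                    "percent": self.percent_within,
                },
            ]
        )


def fst_from_components(sigma2_among: float, sigma2_within: float) -> float:
    """Fst = sigma2_a / (sigma2_a + sigma2_w); error if both are zero."""
    if sigma2_among < 0 or sigma2_within <= 0:
        if sigma2_among == 0 and sigma2_within == 0:
            raise ValueError("Fst undefined: both variance components zero")
        if sigma2_within <= 0:
            raise ValueError("within-population component must be positive")
    return sigma2_among / (sigma2_among + sigma2_within)


def _ss_decomposition(d2: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    n = d2.shape[0]
    iu = np.triu_indices(n, 1)
    ss_total = float(d2[iu].sum()) / n
    ss_within = 0.0
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += float(sub[np.triu_indices(len(idx), 1)].sum()) / len(idx)
    return ss_total, ss_within


def _components(d2: np.ndarray, groups: np.ndarray) -> tuple[float, float, dict]:
    n = d2.shape[0]
    labels, counts = np.unique(groups, return_counts=True)
    G = len(labels)
    ss_total, ss_within = _ss_decomposition(d2, groups)
    ss_among = ss_total - ss_within
    df_a, df_w = G - 1, n - G
    ms_a, ms_w = ss_among / df_a, ss_within / df_w
    n0 = (n - float(np.sum(counts**2)) / n) / df_a
    s2_w = ms_w
    s2_a = (ms_a - ms_w) / n0
    extras = {
        "ss_total": ss_total,
        "ss_within": ss_within,
        "ss_among": ss_among,
        "ms_a": ms_a,
        "ms_w": ms_w,
        "n0": n0,
        "df_a": df_a,
        "df_w": df_w,
    }
    return s2_a, s2_w, extras


def amova(
    D: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int = 0,
) -> AMOVAResult:
    """One-level AMOVA with Fst permutation test (labels shuffled)."""
    groups = np.asarray(groups)
    if len(groups) != len(D.ids):
        raise ValueError("groups length must match distance matrix")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if counts.min() < 2:
        raise ValueError("singleton group not allowed")
    d2 = D.d**2
    s2_a, s2_w, ex = _components(d2, groups)
    clamped = s2_a < 0
    s2_a_c = max(s2_a, 0.0)
    if s2_w <= 0.0:
        # zero within-group variance: complete differentiation (if any
        # among-group variance exists)
        fst = 1.0 if s2_a_c > 0 else 0.0
        s2_w = max(s2_w, 0.0)
    else:
        fst = fst_from_components(s2_a_c, s2_w)
    p = None
    if n_perm > 0:
        # permutation statistic: the unclamped among-population component
        # (monotone surrogate of Fst that stays continuous under the null,
        # so p-values do not pile up at 1 when sigma2_a clamps to 0)
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(groups)
            pa, _, _ = _components(d2, perm)
            if pa >= s2_a:
                count += 1
        p = (1 + count) / (n_perm + 1)
    tot = s2_a_c + s2_w
    if tot == 0.0:
        tot = np.nan
    return AMOVAResult(
        df_among=ex["df_a"],
        df_within=ex["df_w"],
        SS_among=ex["ss_among"],
        SS_within=ex["ss_within"],
        SS_total=ex["ss_total"],
        MS_among=ex["ms_a"],
        MS_within=ex["ms_w"],
        n0=ex["n0"],
        sigma2_among=s2_a_c,
        sigma2_within=s2_w,
        Fst=fst,
        percent_among=100.0 * s2_a_c / tot,
        percent_within=100.0 * s2_w / tot,
        p_perm=p,
        n_perm=n_perm,
        clamped=clamped,
    )


def pairwise_fst(
    D: DistanceMatrix, groups, n_perm: int = 0, seed: int = 0
) -> pd.DataFrame:
    """G x G table of pairwise Fst from AMOVA on each pair's submatrix."""
    groups = np.asarray(groups)
    labels = np.unique(groups)
    out = pd.DataFrame(0.0, index=labels, columns=labels)
    for a_i in range(len(labels)):
        for b_i in range(a_i + 1, len(labels)):
            a, b = labels[a_i], labels[b_i]
            idx = np.flatnonzero((groups == a) | (groups == b))
            sub = DistanceMatrix(
                [D.ids[i] for i in idx], D.d[np.ix_(idx, idx)], D.method
            )
            res = amova(sub, groups[idx], n_perm=n_perm, seed=seed)
            out.loc[a, b] = out.loc[b, a] = res.Fst
    return out
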