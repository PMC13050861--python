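"""Bayesian admixture inference for dominant (binary band) markers.

A STRUCTURE-style admixture model reduced to two-state loci: individual i
carries admixture proportions q_i (Dirichlet(alpha) prior), cluster k has a
band frequency f_kl per band-locus l (Beta(lambda, lambda) prior), and each
observed band x_il is Bernoulli(f_{z_il, l}) with latent origin
z_il ~ Categorical(q_i).  A collapsed-free Gibbs sampler alternates

    z_il  ~  P(z=k) propto q_ik f_kl^x (1-f_kl)^(1-x)
    f_kl  ~  Beta(lambda + n1_kl, lambda + n0_kl)
    q_i   ~  Dirichlet(alpha + m_i)

Missing cells (-9) contribute no likelihood.  The model-evidence proxy
LnP(D) is STRUCTURE's estimator mean(lnL) - var(lnL)/2 over post-burn-in
samples; across a K sweep it feeds the Evanno delta-K statistic

    dK(K) = |L(K+1) - 2 L(K) + L(K-1)| / sd_runs(L(K))

whose peak over interior K indicates the supported number of clusters.
Replicate runs are aligned CLUMPP-style (column permutation maximizing the
dot product with the first run) before averaging.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import linear_sum_assignment

from .genotypes import BandMatrix

__all__ = [
    "QMatrix",
    "StructureSweep",
    "gibbs_admixture",
    "align_runs",
    "structure_sweep",
    "evanno_delta_k",
]


_KERNEL_CACHE: dict[int, object] = {}


def _make_gibbs_kernel(K: int):
    """Compile a Gibbs kernel specialized for a fixed K.

    K is captured as a compile-time constant so numba unrolls the short
    per-cluster loops.  The per-cell categorical draws use an inlined
    xorshift128+ generator (seeded from the run seed, warmed up 20 rounds);
    the Beta/Dirichlet draws use numba's Mersenne Twister.  Both streams are
    fully determined by the seed.
    """
    if K in _KERNEL_CACHE:
        return _KERNEL_CACHE[K]

    @njit(fastmath=True)
    def kernel(x, alpha, lam, burnin, iters, thin, seed):  # pragma: no cover - numba
        np.random.seed(seed)
        s0 = np.uint64(seed * 2685821657736338717 + 1442695040888963407)
        s1 = np.uint64(seed * 6364136223846793005 + 1141592653589793239)
        for _ in range(20):
            t = s0 ^ (s0 << np.uint64(23))
            s0, s1 = s1, (t ^ s1 ^ (t >> np.uint64(17)) ^ (s1 >> np.uint64(26)))
        inv64 = 1.0 / 18446744073709551616.0
        n, L = x.shape
        q = np.full((n, K), 1.0 / K)
        # fb holds f in columns [0, K) and 1-f in [K, 2K) so the emission
        # for x=0 is an offset lookup instead of a subtraction
        fb = np.empty((L, 2 * K))
        for l in range(L):
            for k in range(K):
                fk = np.random.beta(lam, lam)
                fb[l, k] = fk
                fb[l, K + k] = 1.0 - fk
        q_sum = np.zeros((n, K))
        lnp = np.empty(iters // thin + 1)
        n_samples = 0
        m = np.zeros((n, K))
        n1 = np.zeros((L, K))
        n0 = np.zeros((L, K))
        for sweep in range(burnin + iters):
            record = sweep >= burnin and (sweep - burnin) % thin == 0
            ll = 0.0
            m[:, :] = 0.0
            n1[:, :] = 0.0
            n0[:, :] = 0.0
            for i in range(n):
                for l in range(L):
                    xv = x[i, l]
                    if xv < 0:
                        continue
                    off = 0 if xv == 1 else K
                    tot = 0.0
                    for k in range(K):
                        tot += q[i, k] * fb[l, off + k]
                    if record:
                        ll += np.log(tot)
                    t = s0 ^ (s0 << np.uint64(23))
                    s0, s1 = s1, (t ^ s1 ^ (t >> np.uint64(17)) ^ (s1 >> np.uint64(26)))
                    u = float(s0 + s1) * inv64 * tot
                    acc = 0.0
                    z = K - 1
                    for k in range(K):
                        acc += q[i, k] * fb[l, off + k]
                        if u < acc:
                            z = k
                            break
                    m[i, z] += 1.0
                    if xv == 1:
                        n1[l, z] += 1.0
                    else:
                        n0[l, z] += 1.0
            if record:
                # likelihood and q taken at the state entering this sweep
                q_sum += q
                lnp[n_samples] = ll
                n_samples += 1
            for l in range(L):
                for k in range(K):
                    fk = np.random.beta(lam + n1[l, k], lam + n0[l, k])
                    fb[l, k] = fk
                    fb[l, K + k] = 1.0 - fk
            for i in range(n):
                s = 0.0
                for k in range(K):
                    g = np.random.gamma(alpha + m[i, k], 1.0)
                    q[i, k] = g
                    s += g
                for k in range(K):
                    q[i, k] /= s
        return q_sum / n_samples, lnp[:n_samples]

    _KERNEL_CACHE[K] = kernel
    return kernel


def log_likelihood(matrix: BandMatrix, q: np.ndarray, f: np.ndarray) -> float:
    """Data log-likelihood sum log(sum_k q_ik f_kl^x (1-f_kl)^(1-x)).

    Missing cells contribute nothing.  Invariant under any simultaneous
    permutation of the columns of q and rows of f (label switching).
    """
    x = matrix.values.to_numpy()
    obs = x >= 0
    p1 = q @ f  # n x L presence probability
    with np.errstate(divide="ignore"):
        ll = np.where(x == 1, np.log(p1), np.log1p(-p1))
    return float(ll[obs].sum())


@dataclass
class QMatrix:
    ids: list[str]
    q: np.ndarray  # n x K, rows sum to 1
    provenance: str = ""

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if not np.allclose(self.q.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("Q rows must sum to 1")

    @property
    def K(self) -> int:
        return self.q.shape[1]

    def assignments(self) -> np.ndarray:
        return self.q.argmax(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.q, index=self.ids, columns=[f"Q{k + 1}" for k in range(self.K)]
        )


def gibbs_admixture(
    matrix: BandMatrix,
    K: int,
    burnin: int = 10_000,
    iters: int = 100_000,
    seed: int = 0,
    alpha: float = 1.0,
    lam: float = 1.0,
    thin: int = 10,
) -> tuple[QMatrix, float]:
    """One MCMC run; returns the posterior-mean Q and LnP(D).

    Defaults mirror common STRUCTURE practice (burn-in 10,000, chain
    100,000, alpha = lambda = 1, every 10th sweep stored); reduced settings
    are appropriate for desk-scale panels and are what the test profile uses.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > matrix.n_accessions:
        raise ValueError("K exceeds the number of accessions")
    matrix.validate_qc()
    x = matrix.values.to_numpy().astype(np.int8)
    kernel = _make_gibbs_kernel(int(K))
    q_mean, lnps = kernel(
        x, float(alpha), float(lam), int(burnin), int(iters), int(thin), int(seed) & 0x7FFFFFFF
    )
    q_mean = q_mean / q_mean.sum(axis=1, keepdims=True)
    lnpd = float(np.mean(lnps) - np.var(lnps, ddof=1) / 2.0) if len(lnps) > 1 else float(lnps[0])
    return QMatrix(matrix.accession_ids, q_mean, f"K={K} seed={seed}"), lnpd


def _best_permutation(q_ref: np.ndarray, q_run: np.ndarray) -> tuple[int, ...]:
    """Column permutation of q_run maximizing sum_ik q_run[i, perm[k]] q_ref[i, k]."""
    K = q_ref.shape[1]
    cost = q_run.T @ q_ref  # cost[a, k]: run column a against ref column k
    if K <= 8:
        best, best_val = None, -np.inf
        for perm in itertools.permutations(range(K)):
            val = sum(cost[perm[k], k] for k in range(K))
            if val > best_val:
                best, best_val = perm, val
        return best
    rows, cols = linear_sum_assignment(-cost)
    perm = [0] * K
    for a, k in zip(rows, cols):
        perm[k] = a
    return tuple(perm)


def align_runs(runs: list[QMatrix]) -> QMatrix:
    """CLUMPP-style alignment of replicate runs to the first, then average."""
    if not runs:
        raise ValueError("no runs")
    ref = runs[0]
    for r in runs[1:]:
        if r.q.shape != ref.q.shape or r.ids != ref.ids:
            raise ValueError("runs disagree in shape or ids")
    acc = np.array(ref.q)
    for r in runs[1:]:
        perm = _best_permutation(ref.q, r.q)
        acc += r.q[:, list(perm)]
    avg = acc / len(runs)
    avg /= avg.sum(axis=1, keepdims=True)
    return QMatrix(ref.ids, avg, f"aligned mean of {len(runs)} runs")


@dataclass
class StructureSweep:
    """Per-(K, run) LnP(D) table plus the aligned Q matrix for each K."""

    table: pd.DataFrame  # columns: K, run, lnpd
    q_by_k: dict[int, QMatrix] = field(default_factory=dict)


def structure_sweep(
    matrix: BandMatrix,
    k_range: range | list[int],
    n_runs: int = 20,
    burnin: int = 10_000,
    iters: int = 100_000,
    seed: int = 0,
    **kwargs,
) -> StructureSweep:
    """Independent runs for each K; per-K runs aligned and averaged."""
    ss = np.random.SeedSequence(seed)
    rows = []
    q_by_k: dict[int, QMatrix] = {}
    ks = list(k_range)
    child_seeds = iter(ss.generate_state(len(ks) * n_runs) & 0x7FFFFFFF)
    for K in ks:
        runs = []
        for r in range(n_runs):
            qm, lnpd = gibbs_admixture(
                matrix, K, burnin=burnin, iters=iters, seed=int(next(child_seeds)), **kwargs
            )
            runs.append(qm)
            rows.append({"K": K, "run": r, "lnpd": lnpd})
        q_by_k[K] = align_runs(runs)
    return StructureSweep(pd.DataFrame(rows), q_by_k)


def evanno_delta_k(sweep: StructureSweep) -> tuple[pd.DataFrame, int]:
    """Evanno table (mean L, sd, L', |L''|, dK) and the selected K*.

    |L''| is computed from across-run mean L(K); dK = |L''(K)| / sd(L(K))
    with the sample (n-1) standard deviation.  dK is defined only for
    interior K; zero-sd entries are flagged NaN.
    """
    g = sweep.table.groupby("K")["lnpd"]
    ks = np.array(sorted(g.groups))
    if len(ks) < 3 or np.any(np.diff(ks) != 1):
        raise ValueError("need a contiguous K range of length >= 3")
    if (g.count() < 2).any():
        raise ValueError("need >= 2 runs per K")
    mean = g.mean().reindex(ks).to_numpy()
    sd = g.std(ddof=1).reindex(ks).to_numpy()
    lp = np.full(len(ks), np.nan)
    lpp = np.full(len(ks), np.nan)
    dk = np.full(len(ks), np.nan)
    lp[1:] = np.diff(mean)
    for i in range(1, len(ks) - 1):
        lpp[i] = abs(mean[i + 1] - 2 * mean[i] + mean[i - 1])
        if sd[i] > 0:
            dk[i] = lpp[i] / sd[i]
        else:
            # zero spread across runs: no curvature -> dK 0, else undefined
            dk[i] = 0.0 if lpp[i] == 0 else np.nan
    table = pd.DataFrame(
        {"K": ks, "mean_L": mean, "sd_L": sd, "L_prime": lp, "abs_L_pp": lpp, "delta_K": dk}
    ).set_index("K")
    if np.all(np.isnan(dk)):
        raise ValueError("delta K undefined everywhere (zero sd)")
    k_star = int(ks[int(np.nanargmax(dk))])
    return table, k_star
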