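"""Synthetic dominant-marker panels with known admixture and trait truth.

The generator emulates the statistical structure of a germplasm association
panel scored with dominant SSR markers: 82 accessions, 59 markers averaging
6.7 bands each, three strongly differentiated subpopulations with admixed
membership, missing-data codes, and traits driven by a few causal bands plus
population and residual effects.

Population band frequencies follow the Balding-Nichols construction: an
ancestral frequency p0 per band-locus is drawn Uniform(0.05, 0.95) and each
population's frequency is Beta(p0(1-F)/F, (1-p0)(1-F)/F), so F acts as an
Fst-like differentiation parameter.  Individual admixture proportions are
Dirichlet(alpha_sim, ..., alpha_sim); small alpha_sim gives near-pure
membership.  Band presence is Bernoulli(sum_k q_ik f_kl).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, BandMatrix
from .traits import QUALITATIVE_TRAITS, QUANTITATIVE_TRAITS, TraitTable

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_band_freqs",
    "simulate_genotypes",
    "simulate_traits",
    "simulate_dataset",
]


@dataclass
class SimulationConfig:
    """Study-scale defaults; one seed drives every stage deterministically."""

    n_accessions: int = 82
    n_markers: int = 59
    mean_bands_per_marker: float = 6.7
    n_pops: int = 3
    differentiation: float = 0.7      # Balding-Nichols F
    admixture_concentration: float = 0.05  # Dirichlet alpha_sim
    missing_rate: float = 0.02
    n_causal_bands: int = 3
    effect_sizes: list[float] = field(default_factory=lambda: [3.0, 2.0, 1.5])
    pop_effect_sd: float = 1.0
    trait_noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_accessions, self.n_markers, self.n_pops) < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 < self.differentiation < 1.0:
            raise ValueError("differentiation must lie strictly in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.mean_bands_per_marker < 2.0:
            raise ValueError("mean_bands_per_marker must be >= 2 (markers need >= 2 bands)")
        if self.admixture_concentration <= 0 or self.trait_noise_sd <= 0:
            raise ValueError("concentration and noise SD must be positive")
        if len(self.effect_sizes) != self.n_causal_bands:
            raise ValueError("effect_sizes length must equal n_causal_bands")


@dataclass
class SyntheticTruth:
    true_Q: np.ndarray              # n x K, rows sum to 1
    true_band_freqs: np.ndarray     # K x L in [0, 1]
    band_ids: list[str]
    marker_of_band: dict[str, str]
    causal_band_ids: list[str] = field(default_factory=list)
    true_effects: list[float] = field(default_factory=list)

    @property
    def pop_assignment(self) -> np.ndarray:
        return self.true_Q.argmax(axis=1)


def _marker_sizes(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Bands per marker: 2 + Poisson(mean - 2), so every marker has >= 2 bands."""
    lam = config.mean_bands_per_marker - 2.0
    return 2 + rng.poisson(lam, size=config.n_markers)


def simulate_band_freqs(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, list[str], dict[str, str]]:
    """Balding-Nichols K x L population band-frequency matrix.

    Returns (freqs, band_ids, marker_of_band); band ids are
    ``M<number>_<band index>``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sizes = _marker_sizes(config, rng)
    band_ids: list[str] = []
    marker_of_band: dict[str, str] = {}
    for m, size in enumerate(sizes, start=1):
        marker = f"M{m:03d}"
        for b in range(1, size + 1):
            band = f"{marker}_{b}"
            band_ids.append(band)
            marker_of_band[band] = marker
    L = len(band_ids)
    F = config.differentiation
    p0 = rng.uniform(0.05, 0.95, size=L)
    a = p0 * (1.0 - F) / F
    b = (1.0 - p0) * (1.0 - F) / F
    freqs = rng.beta(a, b, size=(config.n_pops, L))
    return freqs, band_ids, marker_of_band


def simulate_genotypes(
    truth: SyntheticTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> BandMatrix:
    """Bernoulli band calls under the admixture model, with missing codes."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n, K = truth.true_Q.shape
    if truth.true_band_freqs.shape[0] != K:
        raise ValueError("true_Q and true_band_freqs disagree on K")
    probs = truth.true_Q @ truth.true_band_freqs  # n x L
    x = (rng.random(probs.shape) < probs).astype(np.int64)
    if config.missing_rate > 0:
        miss = rng.random(x.shape) < config.missing_rate
        x[miss] = MISSING
    ids = [f"A{i + 1:03d}" for i in range(n)]
    df = pd.DataFrame(x, index=ids, columns=truth.band_ids)
    return BandMatrix(df, dict(truth.marker_of_band))


def simulate_traits(
    genotypes: BandMatrix,
    truth: SyntheticTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> TraitTable:
    """Quantitative + coded qualitative traits over the simulated panel.

    The focal quantitative trait (``AC``) carries the additive causal-band
    effects: y_i = sum_c beta_c x_ic + pop_effect(pop_i) + eps_i.  The other
    quantitative traits are population effect + noise; qualitative traits are
    latent quantitative variables thresholded into integer codes at their
    within-panel quantiles.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    for band in truth.causal_band_ids:
        if band not in genotypes.band_ids:
            raise ValueError(f"causal band {band!r} absent from the matrix")
    n = genotypes.n_accessions
    pops = truth.pop_assignment
    K = truth.true_Q.shape[1]

    def latent() -> np.ndarray:
        pop_eff = rng.normal(0.0, config.pop_effect_sd, size=K)
        return pop_eff[pops] + rng.normal(0.0, config.trait_noise_sd, size=n)

    cols: dict[str, np.ndarray] = {}
    for t in QUANTITATIVE_TRAITS:
        y = latent()
        if t == "AC" and truth.causal_band_ids:
            x = genotypes.values[truth.causal_band_ids].to_numpy(float)
            x[x == MISSING] = 0.0  # unreadable bands contribute no effect
            y = y + x @ np.asarray(truth.true_effects, dtype=float)
        cols[t] = y
    n_classes = 3
    for t in QUALITATIVE_TRAITS:
        z = latent()
        edges = np.quantile(z, np.linspace(0, 1, n_classes + 1)[1:-1])
        cols[t] = (np.digitize(z, edges) + 1).astype(float)
    df = pd.DataFrame(cols, index=genotypes.accession_ids)
    return TraitTable(df, set(QUALITATIVE_TRAITS))


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[BandMatrix, TraitTable, SyntheticTruth]:
    """Full generator: frequencies -> admixture -> genotypes -> traits.

    A single seed drives one Generator consumed in this documented order:
    marker sizes, ancestral/population frequencies, Q, genotype draws,
    missingness, causal-band choice, trait effects.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    freqs, band_ids, marker_of_band = simulate_band_freqs(config, rng)
    q = rng.dirichlet(
        np.full(config.n_pops, config.admixture_concentration), size=config.n_accessions
    )
    truth = SyntheticTruth(q, freqs, band_ids, marker_of_band)
    genotypes = simulate_genotypes(truth, config, rng)
    n_causal = min(config.n_causal_bands, len(band_ids))
    causal = rng.choice(len(band_ids), size=n_causal, replace=False)
    truth.causal_band_ids = [band_ids[i] for i in sorted(causal)]
    truth.true_effects = list(config.effect_sizes[:n_causal])
    trait_table = simulate_traits(genotypes, truth, config, rng)
    return genotypes, trait_table, truth
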