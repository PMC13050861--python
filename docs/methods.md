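# Methods

`popkit` implements the analysis chain used for dominant (presence/absence)
EST-SSR marker panels in germplasm characterisation: SSR mining from
transcript sequences, band-matrix diversity statistics, distance-based
clustering, Bayesian admixture inference, AMOVA-based differentiation, and
marker–trait association — together with a synthetic-data generator that
provides ground truth for every stage. This note records the models, the
parameters that matter, and the numerical choices made where the design was
genuinely open.

## Synthetic panels

The generator emulates a germplasm association panel: by default 82
accessions scored at 59 markers averaging 6.7 bands each (≈396 band-loci),
drawn from 3 subpopulations with admixed membership.

* **Population band frequencies** follow the Balding–Nichols construction:
  an ancestral frequency `p0 ~ Uniform(0.05, 0.95)` per band-locus and a
  per-population frequency `Beta(p0(1−F)/F, (1−p0)(1−F)/F)`. `F` is an
  Fst-like differentiation parameter (default 0.7, matching the strongly
  differentiated panels this kind of study reports). This is the simplest
  generator with a tunable differentiation dial; the variance of the
  per-population frequency is exactly `F·p0(1−p0)`.
* **Admixture proportions** are `Dirichlet(α_sim, …, α_sim)` rows (default
  `α_sim = 0.05`, near-pure membership with occasional admixed
  individuals). Band presence is `Bernoulli(Σ_k q_ik f_kℓ)`; missing cells
  (−9) are inserted uniformly at random (default rate 0.02).
* **Bands per marker** are `2 + Poisson(mean − 2)` so every marker retains
  at least two bands; only the mean (6.7) is constrained by the emulated
  design.
* **Traits.** The focal quantitative trait (`AC`) is
  `y_i = Σ_c β_c x_ic + pop_effect(pop_i) + ε_i` with `ε ~ N(0, σ²)`
  (defaults: 3 causal bands with effects 3.0/2.0/1.5, population effects
  `N(0, 1)`, σ = 1). Remaining quantitative traits carry population and
  residual effects only; qualitative traits are latent quantitative
  variables thresholded at their within-panel tertiles into integer codes.
  Missing causal genotypes contribute no effect.
* **Determinism.** One seed drives a single `numpy` Generator consumed in a
  documented order (marker sizes → frequencies → Q → genotypes →
  missingness → causal choice → traits); identical seeds give bit-identical
  outputs.

What the generator does **not** emulate: tetraploid allele dosage, gel
scoring artifacts, linkage between bands of one marker (bands are
independent Bernoulli draws given ancestry), or non-additive trait
architecture. Tests passing on these panels therefore demonstrate
correctness of the estimators under the stated model, not robustness to
those real-data complications.

## SSR mining

Maximal perfect tandem repeats with unit length 1–6 bp are detected at the
usual EST-SSR thresholds (mono ≥ 10 repeats, di ≥ 6, tri–hexa ≥ 5). A run
is reported once, at its smallest period: motifs must be primitive (not
themselves a repetition of a shorter unit), and of the up-to-`u−1`
phase-shifted descriptions of a run only the leftmost is kept. Non-ACGT
characters break runs rather than aborting the scan. Only perfect repeats
are mined; imperfect/compound repeat detection would require interruption
parameters that have no canonical values and is out of scope.

Motifs are grouped into strand- and phase-invariant classes: the class
representative is the lexicographic minimum over all cyclic rotations of
the motif and of its reverse complement (e.g. `TA → AT`, `ATT → AAT`; the
60 primitive trinucleotides collapse to 10 classes). Report percentages are
rounded half-up to two decimals.

Primer screening applies the standard constraints (length 18–27 bp, GC
40–80 %, Tm 58–65 °C, pair ΔTm ≤ 2 °C, product 100–300 bp). Tm is
nearest-neighbor thermodynamics (unified parameters, 50 mM monovalent
salt, 0.25 µM oligo) via Biopython; the formula is a single swappable
function, chosen because bit-stable filtering needs one stated convention.
In-silico PCR declares a primer pair unique iff exactly one productive
site (forward match … reverse-complement match, product within bounds)
exists in the whole sequence set. Full thermodynamic primer *design* is not
re-implemented; candidates are enumerated from flank substrings.

## Diversity statistics

Each marker is treated as one multi-allelic locus whose allele frequencies
are its normalized band presence counts (`p̂_b = n_b / Σ n_b'`, missing
cells excluded per band; never-present bands dropped). On that vector:
`Na = #alleles`, `Ne = 1/Σp̂²`, `H = 1 − Σp̂²`, `I = −Σ p̂ ln p̂`, and
Botstein's `PIC = 1 − Σp̂² − Σ_{i<j} 2 p̂_i² p̂_j²`. The multi-allele (not
dominant `2p(1−p)`) PIC form is used because band counts per marker behave
as allele counts in this framing and the dominant form cannot exceed 0.5.
Reports classify markers as high/moderate/low polymorphism at PIC > 0.5 /
0.25–0.5 / < 0.25. Note that `H = 1 − Σp̂²` is bounded above by 1; published
tables that print H above 1 must use a different (unstated) formula, so
printed H values are not reproduced.

## Distances and clustering

For binary profiles with missing codes, both coefficients use
pairwise-complete positions and ignore shared absences: Jaccard
`d = 1 − a/(a+b+c)` (fed to AMOVA) and Nei–Li/Dice `d = 1 − 2a/(2a+b+c)`
(fed to clustering — the field convention for "Nei's distance" on
individual band data, since Nei's standard distance needs population
frequencies). UPGMA merges the closest pair, breaking ties on the
lexicographically smallest pair of cluster representatives for
platform-stable output; the new cluster's distances are size-weighted
means and the merge height is half the merge distance (ultrametric).
Trees serialize to Newick with branch lengths; cutting the k−1 highest
merges yields k groups numbered by first-seen leaf.

## Admixture model

A STRUCTURE-style admixture model reduced to two-state loci: cluster k has
band frequency `f_kℓ ~ Beta(λ, λ)`, individual i has proportions
`q_i ~ Dirichlet(α1_K)`, each cell's latent origin `z_iℓ ~ Cat(q_i)` and
`x_iℓ ~ Bernoulli(f_{z_iℓ,ℓ})`; missing cells contribute no likelihood.
Gibbs sweeps update z, f, q from their exact conditionals. Defaults:
`α = 1` fixed (no Metropolis update — keeps runs fast and deterministic;
exposed in the API), `λ = 1`, burn-in 10,000 / chain 100,000 / K 1–10 / 20
runs for production presets, every 10th sweep stored. The model-evidence
proxy is `LnP(D) = mean(lnL) − var(lnL)/2` over stored samples, with the
likelihood evaluated at the state entering the sweep. Replicate runs are
aligned by the column permutation maximizing `Σ q·q_ref` (exact search for
K ≤ 8, Hungarian assignment otherwise) and averaged; Evanno's
`ΔK = |L(K+1) − 2L(K) + L(K−1)| / sd_runs(L(K))` (means in the numerator,
sample SD in the denominator) selects K at its interior maximum. When the
across-run SD is zero, ΔK is 0 if the curvature is also zero and flagged
undefined otherwise.

Performance: the sweep kernel is compiled with numba, specialized per K.
The per-cell categorical draws use an inlined xorshift128+ generator
(seeded from the run seed, 20 warm-up rounds) because the library
generator call dominated sweep cost; Beta/Dirichlet draws use numba's
Mersenne Twister. Both streams are fully determined by the seed, so fixed
seeds reproduce Q to the last bit. Test and acceptance profiles use a
reduced sweep (K 1–5, 5 runs, burn-in 1,000, chain 5,000) — at the default
panel size the posterior is concentrated enough that this reliably
recovers the simulated K.

Not implemented: linkage model, correlated-frequencies prior, location
priors, CLUMPP's Greedy/LargeKGreedy modes.

## AMOVA and Fst

One-level AMOVA on squared distances: `SS_total = (1/N) Σ_{i<j} d²`,
`SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d²`, `SS_among` by difference;
`n0 = (N − Σn_g²/N)/(G−1)`, `σ²_w = MS_within`,
`σ²_a = (MS_among − MS_within)/n0`, `Fst = σ²_a/(σ²_a + σ²_w)` with
negative `σ²_a` clamped to zero (flagged). Raw squared Jaccard distances
are used without Euclidean correction, as is standard for
distance-AMOVA on binary marker data. Significance comes from permuting
group labels; the permutation statistic is the *unclamped* `σ²_a` (a
monotone surrogate of Fst that remains continuous under the null — the
clamped statistic would send half of all null datasets to p = 1), with the
`(1 + #{≥ obs})/(n_perm + 1)` correction so p is never 0. Pairwise Fst runs
the same machinery on each group pair's submatrix. Group labels come from
the UPGMA cut by default, or from admixture assignments; the choice is
explicit in the configuration because the two can disagree for admixed
accessions.

## Association

Structure covariates are the top 5 principal components of the
column-centred band matrix (missing cells mean-imputed per band for the
SVD only), with a deterministic sign convention (largest-magnitude loading
positive). Admixture Q columns (dropping one to avoid collinearity) are an
alternative covariate source. GLM: per band, a 1-df F-test of
`y ~ 1 + PCs + band` against the covariate-only null under OLS, with
listwise deletion of missing genotypes; constant bands are flagged NA.

MLM adds a polygenic effect `u ~ N(0, σ²_g K)` with `K = WW'/L` from the
centred band matrix, rescaled to mean diagonal 1 and eigenvalue-clamped to
PSD. Variance components are estimated once per trait by REML on the null
model — eigendecomposition of `S K S` restricted to the residual space, 1-D
bounded profile over `ln δ ∈ [−10, 10]`, `δ = σ²_e/σ²_g`, boundary hits
flagged — and reused for every marker test (the P3D/EMMAX approximation,
indistinguishable from exact per-marker REML at this marker count). Each
marker is then tested by GLS under `V = σ²_g(K + δI)` on the
non-missing subset (Cholesky per missing pattern, cached). With `K = I`
the MLM reduces exactly to the GLM.

Qualitative traits are analysed on their integer codes — a linear
approximation, acceptable for screening but not for effect interpretation.
Benjamini–Hochberg FDR is applied within each trait × model family
(matching how per-trait, per-model discovery counts are reported);
significant records must pass both the raw `p ≤ 0.05` screen and the FDR
line. QQ and Manhattan data are exported as tables.

## Phenotype analytics

Per-trait summaries: mean, sample SD (n−1), `CV = SD/mean × 100 %` (NA for
zero mean), and Shannon–Wiener `H' = −Σ p_c ln p_c` over the frequency
distribution of *distinct observed values* (unbinned; with all-distinct
values over n accessions this equals `ln n`, which is the regime
germplasm studies report for continuous growth traits). Mixed PCA follows
the PCAmix construction — z-scored quantitative columns, centred category
indicators weighted `1/√p_c` — factored by SVD; with only quantitative
traits this is exactly correlation-matrix PCA. Per-trait contributions
aggregate indicator loadings by sum of squares. Correlations are Pearson on
numeric values/codes with two-sided t tests (n−2 df), flagged `*` at 0.05
and `**` at 0.01.

## Problem sizes in the test suite

The suite exercises the full default panel (82 × ~396) everywhere except
the MCMC, which uses the reduced sweep above; the SSR oracle runs on 50-kb
planted-repeat sequences; AMOVA null calibration uses 200 datasets of 16
individuals at 99 permutations; association calibration pools 20 null
panels and 20 planted-effect panels. These sizes were chosen to make every
statistical check decisive at desk scale while the whole suite stays quick
to run.

## Known limitations

* Bands are modelled as independent loci throughout; within-marker
  dependence (bands of one marker are mutually exclusive alleles on a gel)
  is ignored, consistent with treating the 0/1 matrix as the substrate.
* The admixture sampler reports non-convergence only through across-run
  spread; no within-chain diagnostics (e.g. Gelman–Rubin) are computed.
* Only one-level AMOVA (among/within populations) is provided.
* Exact per-marker REML is available behind the P3D default only via the
  null-model path; genomic prediction, epistasis and haplotype tests are
  out of scope.
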