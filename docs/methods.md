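# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `evotherm`. It describes what the code computes and why
the defaults are what they are; every empirical statement here is one the
test suite or the acceptance script computes itself.

## Alignment preparation

Alignments are parsed from FASTA, A2M or Stockholm. A2M/Stockholm insert
states (lowercase letters and `.`) are removed per sequence so all rows
align on match columns; columns in which the focus (wild-type) sequence is
gapped are dropped, and every retained column is mapped to a 1-based
position on the ungapped focus sequence. Non-canonical residue codes
(B, Z, X, J, U, O, `*`) are mapped to the gap state with a logged count —
a deterministic, conservative policy.

Filtering is order-fixed: sequences with more than 50% gaps are removed
first (the focus sequence is exempt), then columns gapped in more than 30%
of the surviving rows. These thresholds are the standard DCA
post-processing defaults and are exposed as parameters. Filtering is
idempotent by construction.

Redundancy reweighting gives sequence s the weight
1 / |{t : identity(s, t) ≥ 1 − θ}| with θ = 0.2 (80% identity clusters),
the common DCA convention; the effective sample size n_eff is the sum of
weights. Identity counts gap positions like any other state. Weighted
single and pairwise frequencies can be mixed with a uniform pseudocount
fraction λ (default 0): f = (1 − λ) f_emp + λ/q (singles) and λ/q²
(pairs), so the pair table marginalizes exactly to the single table at
λ = 0. Inference regularizes at the objective level instead of
pseudocounting frequencies, so λ defaults to 0 throughout the pipeline.

## Potts model and pseudo-likelihood inference

The model is E(σ) = Σ_i h_i(σ_i) + Σ_{i<j} J_ij(σ_i, σ_j) with
p(σ) ∝ exp E(σ); the sign convention makes higher energies more favorable,
so beneficial variants have positive ΔE. The alphabet includes the gap as
a modeled state (q = 21 for proteins; smaller alphabets are supported for
synthetic systems); substitutions to or from gap are never proposed as
variants.

Inference maximizes the weighted, L2-penalized pseudo-likelihood: for each
site i the conditional distribution of σ_i given the rest of the sequence
is a multinomial logistic regression with parameters h_i and the coupling
rows J_i·, fitted independently per site with analytic gradients
(L-BFGS-B, gradient-infinity-norm tolerance 1e-5, at most 500 iterations
per site). The per-site objective is

    O_i = Σ_s w_s NLL_s(i) + λ_h ||h_i||² + λ_e Σ_{j≠i} ||J_ij||²

with absolute (unnormalized) λ's, the plmc convention. Consequences of
this scaling, both tested:

* duplicating the alignment and recomputing identity weights leaves the
  fit unchanged (n_eff is unchanged);
* doubling every weight reproduces the fit exactly when both λ's are
  doubled too — λ's are specified per campaign, consistent with n_eff.

The two asymmetric estimates of each coupling block are symmetrized by
averaging (J_ij ← (J_ij + J_jiᵀ)/2) and the model is converted to the
zero-sum gauge (every h_i and every row/column of every J_ij block sums to
zero). Gauge fixing changes energies only by a sequence-independent
constant, so all ΔE values are preserved; this is asserted to 1e-8.

Defaults λ_h = 0.01 and λ_e = 0.2 (L − 1) follow the published campaign
(L = number of modeled sites; 294 sites give λ_e = 58.6). The "auto"
coupling penalty grows with L, not with n_eff; for the tiny synthetic
systems in the test suite the null-recovery test states its own
λ_e = 0.2 n_eff, chosen a priori from ridge-shrinkage arithmetic so that a
zero-coupling truth yields pair Frobenius norms below 0.05 at
n_eff ≥ 2000. Optimizer initialization is zeros, so fitting is
deterministic; the seed parameter is recorded for provenance (and reserved
for stochastic restarts).

Model files are `.npz` containers with a JSON metadata header carrying a
format tag (`evotherm-potts-1`), alphabet, λ's and gauge; loading
validates the tag and fails loudly on corruption. Per-pair coupling
Frobenius norms export as plain TSV for inspection.

## Variant scoring and enumeration

Variants are parsed from protein-engineering strings ("Q289G",
"S180T/Q289G"), validated against the focus sequence (the stated wild-type
residue must match; substituted positions must be modeled — a filtered
column raises an explicit "unmodeled position" error). ΔE is computed
incrementally from the terms touching substituted positions and equals the
full energy difference exactly (tested against a brute-force oracle).

Enumeration covers all single substitutions and all 19×19 amino-acid
combinations over all unordered position pairs. Scoring is fully
vectorized per position pair, and only the per-pair top-k candidates are
retained before the global sort, keeping memory at O(pairs × top_k).
Sorting is by ΔE descending with deterministic tie-breaking by (position,
mutant residue); ranks are dense. For a double, the decomposition

    ΔE(ab) = ΔE(a) + ΔE(b) + [J_ij(a',b') − J_ij(a',b) − J_ij(a,b') + J_ij(a,b)]

holds exactly; the bracketed coupling gap is the model-level epistasis.

ΔΔG tables from structure-based predictors arrive as (variant, run_index,
ddg) rows; the package aggregates mean and SEM (sample SD / √runs) per
variant, sorts ascending (most stabilizing first, ties by name), and
offers the negative-mean filter used to pick stabilizing candidates. The
underlying force-field computation is upstream of this package.

## Thermal-resistance analysis

**Plate normalization.** Long-form plate tables (variant, condition,
replicate, signal, is_background) are background-subtracted with the mean
empty-vector signal per condition; a variant's fold-change is its mean net
signal over the wild type's, with SEM from the variant's replicate scatter.
The wild type's own uncertainty is excluded by default — matching error
bars computed per variant from biological replicates — with a
`propagate_wt` option that adds it in quadrature. Variants whose
replicates never exceed background are flagged inactive with fold 0.
Normalization is scale-invariant.

**Classification.** A variant is improved/similar/reduced versus wild type
by z = (x − x_wt)/√(SEM² + SEM_wt²) against a threshold (default z = 2).
The rule is symmetric (swapping roles maps improved ↔ reduced). The
published melting-temperature split for the sequence-arm singles (12
similar / 4 up / 4 down) is not reproduced by this or any symmetric
combined-SEM rule applied to the printed Tm table; the package reports its
own counts under the stated rule and does not assert that split. Hit rate
is simply 100 × improved / tested.

**Melting temperature.** The default extractor smooths the scan with a
Savitzky–Golay filter (window 9, cubic) and takes the first-derivative
maximum — the nanoDSF convention — refined to sub-grid precision by a
quadratic vertex fitted over the derivative's half-maximum neighborhood
(two-state derivative peaks are locally symmetric, so the vertex is
unbiased on symmetric sampling). Falling transitions are handled by
mirroring. A derivative maximum at the scan edge, or one not prominent
above the baseline derivative level (4 robust SDs over the median), means
no transition: the fit is flagged instead of reporting a Tm, so monotone
drift never yields a spurious melting point. A two-state sigmoid fit with
linear pre-/post-transition baselines serves as a cross-check; the two
agree within 0.5 °C on clean curves. On the default 20–95 °C grid at 1 °C
steps with 1%-of-amplitude noise, at least 95 of 100 generated curves are
recovered within 0.3 °C.

**Kinetic stability.** Residual-activity time courses are fitted to
first-order deactivation A(t) = A₀ e^(−kt) by nonlinear least squares on
replicate means (initialized from a log-linear regression), giving
t₁/₂ = ln 2 / k with a delta-method standard error
(SE(t₁/₂) = ln 2 · SE(k)/k²). The single-exponential form is the standard
pairing of a reported half-life with a deactivation constant. A fitted
k ≤ 0 (non-decaying series) is flagged "no measurable decay".

**Correlation.** Stability–activity tradeoffs use Spearman's ρ with
average ranks for ties and a two-sided t-approximation p-value on n − 2
degrees of freedom (scipy's implementation; the tests cross-check against
an independent rank-then-Pearson computation). Constant inputs are
rejected as undefined.

**Experimental epistasis.** For measured quantities the deviation of a
double from its singles is computed additively
((ab − wt) − [(a − wt) + (b − wt)], natural for Tm and half-life) or
multiplicatively (fold_ab − fold_a · fold_b, natural for fold-changes);
the sign labels positive/negative epistasis. Both operationalizations are
provided because published statements of epistasis may refer to either
level; neither is asserted as "the" definition.

**Rounding policy** for reported tables: one decimal for temperatures,
whole minutes for half-lives, matching the precision of the published
tables.

## Synthetic data and ground truth

Every generator returns its data together with a `SyntheticTruth` record
(generator name, full parameters, seed) that serializes to JSON next to
the data; identical parameters and seed regenerate bit-identical output.
Analysis stages never read the truth — recovery tests do.

* **MSAs** are drawn from a known Potts model by single-site Gibbs
  sampling (exact conditional distributions are available from the model,
  which is why Gibbs rather than Metropolis). Chains are independent per
  sequence (uniform random initialization, 50-sweep default burn-in), so
  rows are i.i.d. draws; on a 3-position, 3-state model the sampled pair
  frequencies match exhaustive Boltzmann enumeration within 0.02.
* **Melting curves** are two-state logistics between linear pre/post
  baselines with additive Gaussian noise (instrument-like).
* **Decay series** are first-order exponentials with multiplicative
  (CV-style) replicate noise, clipped at zero.
* **Assay plates** place each variant at background + fold × (WT −
  background) with multiplicative noise on every well, including wild-type
  and empty-vector wells.

Generator defaults mirror the study conditions: 0–150 min sampled every
15 min with 3 replicates and 5% noise for decay; 20–95 °C at 1 °C for
melting; 3 replicates and 5% noise for plates. What the generators do
*not* emulate: phylogenetic correlation between homologs (rows are
independent given the model), alignment errors, plate positional effects,
or substrate-depletion kinetics. Passing recovery tests therefore
demonstrates estimator correctness under the stated noise model, not
robustness to those real-data artifacts.

The published benchmark tables (top-20 singles per prediction arm with
ΔΔG/ΔE, all melting temperatures, top-20 doubles) ship as machine-readable
fixtures at printed precision. A companion toy Potts model encodes the
printed single ΔE values in its fields and the printed double ΔE values in
its couplings (all unlisted substitutions pushed to a large negative
field), so enumeration and ranking can be exercised against published
numbers; it is a synthetic construction, not the campaign's inferred
model, which would require the original UniRef100-scale alignment.

## Statistical design of the recovery tests

With three replicates an SEM is estimated at 2 degrees of freedom, so a
nominal 2-SEM interval covers the truth roughly 90–95% of the time per
variant. Single-draw recovery checks (one seeded dataset, estimate within
2 SE of truth) are therefore used where one quantity is estimated;
multi-variant panel recovery is asserted as an ensemble property instead
(bias near zero and ≥ 85% empirical 2-SEM coverage over 100 seeded
panels), which is the claim a fixed-seed panel check approximates.

## Known limitations

* Pseudo-likelihood with absolute λ's means regularization strength must
  be chosen relative to the campaign's n_eff; the "auto" coupling penalty
  follows the published formula (a function of L) and is not adaptive.
* The dense coupling tensor (L² q² doubles) is comfortable up to a few
  hundred positions but is not engineered for genome-scale models; there
  is no GPU path.
* Contact prediction and average-product correction of coupling norms are
  out of scope; the norm export is for inspection and synthetic-recovery
  tests only.
* The Tm extractor assumes a single two-state transition; multi-domain
  unfolding with two peaks will return the dominant one.
* Deactivation is modeled as single-exponential; biphasic inactivation is
  flagged only insofar as the fit quality degrades.
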