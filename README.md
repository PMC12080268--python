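# evotherm

Sequence-statistics-guided enzyme engineering, end to end: infer a Potts
(direct coupling analysis) model from a multiple sequence alignment of
homologs, rank candidate variants by evolutionary statistical energy, and
quantify the thermal resistance of characterized variants — activity
fold-changes after heat stress, melting temperatures, deactivation
half-lives, hit rates, and stability–activity correlations.

It is written for protein engineers and computational biologists who want
the selection logic of a DCA-based campaign (the kind used to thermostabilize
an endoglucanase, GH5 cellulase EGLII) as a tested, reusable library with a
thin CLI, including synthetic-data generators with known ground truth for
validating every stage.

## The model

A Potts model assigns every aligned sequence σ a statistical energy

```
E(σ) = Σ_i h_i(σ_i) + Σ_{i<j} J_ij(σ_i, σ_j),        p(σ) ∝ exp E(σ)
```

with local biases `h_i` and pairwise couplings `J_ij` over a 21-state
alphabet (20 amino acids + gap). Parameters are inferred from a gap-filtered,
identity-reweighted alignment by L2-regularized **pseudo-likelihood
maximization** (per-site conditional likelihoods, asymmetric coupling
estimates symmetrized by averaging, zero-sum gauge). Defaults follow the
plmc conventions: λ_h = 0.01, λ_e = 0.2 (L − 1), sequence reweighting at
θ = 0.2 (80% identity clusters).

A variant is scored by its statistical-energy difference

```
ΔE(σ, σ_wt) = E(σ) − E(σ_wt)
```

(positive = evolutionarily favored). Singles and all double substitutions
are enumerated exhaustively and ranked by ΔE; for a double, ΔE decomposes
exactly into the two single effects plus a coupling gap, the model-level
epistasis. Structure-based ΔΔG predictions (negative = predicted
stabilizing) are ingested from per-run tables and run-averaged for the
comparison arm.

The thermal-analysis stages fit a two-state melting curve (Tm from the
smoothed-derivative maximum, sigmoid fit as cross-check), a first-order
deactivation model A(t) = A₀ e^(−kt) with t₁/₂ = ln 2 / k, normalize plate
activities to wild type, classify variants on a combined-SEM z score, and
correlate stability with activity via Spearman's ρ.

## Worked example

The package ships the published EGLII benchmark tables (`evotherm.fixtures`)
and a toy Potts model whose ΔE values reproduce them exactly:

```python
from evotherm import enumerate_and_rank, epistasis_decompose, fit_decay, parse_variant
from evotherm.fixtures import table_model, paper_report
from evotherm.simulate import make_decay_series

model = table_model()
for s in enumerate_and_rank(model, order="double", top_k=3):
    print(f"rank {s.rank}: {s.variant.name}  dE = {s.delta_e:.2f}")

rec = epistasis_decompose(model, parse_variant("S180T/Q289G"))
print(f"epistasis gap for {rec.double.name}: {rec.coupling_gap:+.2f}")

series, truth = make_decay_series(t_half=104.0, n_replicates=3, noise_frac=0.05, seed=2)
fit = fit_decay(series)
print(f"fitted half-life: {fit.half_life:.0f} +/- {fit.se_half_life:.0f} min "
      f"(truth {truth.parameters['t_half']:.0f})")

report = paper_report()
print(f"hit rates: singles {report['hit_rate_single_pct']:.0f}%, "
      f"doubles {report['hit_rate_double_pct']:.0f}%")
```

prints

```
rank 1: V226I/Q289G  dE = 5.83
rank 2: P111I/Q289G  dE = 5.47
rank 3: D164A/Q289G  dE = 5.41
epistasis gap for S180T/Q289G: +0.04
fitted half-life: 105 +/- 3 min (truth 104)
hit rates: singles 50%, doubles 80%
```

The top-ranked double (V226I/Q289G, ΔE 5.83) and the near-additive
S180T/Q289G decomposition match the published tables; the half-life fit
recovers the generating truth (the best single variant's 104 min) within
its standard error; the hit rates are the fraction of characterized
variants with improved activity after one hour at 75 °C.

The same operations are available from the shell, e.g.

```
evotherm simulate decay --t-half 40 --seed 1 --out decay.csv
evotherm fit-decay decay.csv
evotherm report
evotherm run-all homologs.fasta --focus MY_ENZYME --seed 1 --out-dir run/
```

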