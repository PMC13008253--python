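# kineflux

Predicting genome-scale steady-state flux distributions that are compatible
with metabolite concentration effects, using quantitative proteomics alone.

Intracellular fluxes are shaped jointly by enzyme abundances and metabolite
concentrations, but matched metabolomic data are expensive to obtain. This
package implements a hybrid approach for systems biologists working with
constraint-based metabolic models: from a training set of matched fluxomic
(e.g. ¹³C-MFA-constrained pFBA) and proteomic data it derives, per reaction
and condition, the *metabolite concentration effect*

    η^C = v^C / (E^C · k_app^max) ∈ (0, 1],

the fraction of maximal catalytic capacity realized in vivo (with
`k_app^max = max_C v^C/E^C` the apparent-catalytic-rate proxy for the in
vivo turnover number). It then learns, per reaction, a logit regression

    η = 1 / (1 + exp(−(β + Σ_k α_k φ_k)))

predicting η from metabolite flux-sums `φ = S⁺v` (production turnover as a
concentration proxy), with the reaction's substrates always included and up
to three additional metabolites chosen by exhaustive subset search under
grouped five-fold cross-validation (replicates never straddle folds,
selection by adjusted R²). Finally, for a new condition with proteomics
only, it predicts fluxes by solving

    min_v Σ_{j∈P} (v_j − E_j·k_app^max_j·η̂_j(v))² + w·Σ_i v_i
    s.t.  S v = 0,   v_l ≤ E_l·k_app^max_l (l∈Q),   v_lb ≤ v ≤ v_ub

with `w = 10⁻²`, P the reactions with cross-validated models (adjusted
R² > 0.6) and Q all reactions with abundance and `k_app^max`. The selected
extra metabolites (plus flux-sum-correlated alternates at Pearson > 0.8)
double as candidate regulators.

See `docs/methods.md` for the full model description, estimator and solver
details, and the synthetic-study design.

## Worked example

Every stage runs on synthetic networks with known kinetic ground truth, so
the whole pipeline can be exercised — and audited — without any download:

```python
from kineflux import generate_bundle, end_to_end_recovery

# 25-reaction branched network, 30 conditions in 15 replicate groups,
# noiseless observations; ground truth: v = kcat * E * eta with eta an
# exact logistic in metabolite flux-sums
bundle = generate_bundle(seed=1)

# train on ~70% of replicate groups, predict held-out fluxes from
# abundances alone, score against the generator's true fluxes
report = end_to_end_recovery(bundle, seed=1)

print(f"models selected          : {report['n_models']}")
print(f"mean CV adjusted R^2     : {report['cv_adj_r2_mean']:.4f}")
print(f"k_app^max rel. error     : {report['kappmax_rel_err_max']:.2e}")
print(f"feature sets recovered   : {report['feature_set_match_frac']:.0%}")
print(f"held-out flux Pearson    : median {report['heldout_pearson_median']:.5f}")
```

prints

```
models selected          : 7
mean CV adjusted R^2     : 1.0000
k_app^max rel. error     : 1.00e-09
feature sets recovered   : 100%
held-out flux Pearson    : median 0.99999
```

i.e. on noiseless data the apparent catalytic rates recover the true
turnover numbers, feature-subset selection finds exactly the generating
metabolite sets (here e.g. reaction `ENZ02` gets its substrate `S02` plus
the planted effector `S01`, coefficients α = {S02: −4.672, S01: −0.667},
β = 26.233), and fluxes predicted for unseen conditions from proteomics
alone correlate with the true fluxes at r ≈ 1 per reaction.

Real data enter through plain files: a model (SBML L3+FBC or a small JSON
dialect), wide TSV tables of per-reaction abundances and flux bounds, and a
condition manifest with replicate groups. The same pipeline is scriptable
from the shell:

```bash
kineflux simulate --seed 1 --out fixture/          # synthetic study + truth
kineflux solve --model fixture/model.json --eta-models models.json \
    --abundance abundance.tsv --kappmax kappmax.tsv --out pred/
kineflux evaluate --pred pred/flux.tsv --est est_flux.tsv \
    --model fixture/model.json --out eval/
```

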