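# seedlingfit

Growth-curve fitting and genetic-hypothesis selection for seed and
seedling phenotypes.

## The problem

When a large-seeded and a small-seeded bean accession are crossed
reciprocally, the two F1 hybrids carry the same nuclear genotype but
inherit contrasting seed sizes from their maternal parents. Comparing the
early, cotyledon-fueled growth of the four lines (two selfed parents, two
reciprocal F1s) separates what the seedling's own genotype controls from
what the maternal seed phenotype controls. `seedlingfit` implements the
statistical machinery for that comparison:

* **Trajectory models.** Total root length and branch counts follow an
  expolinear curve Y(t) = (Cm/Rm)·ln(1 + e^{Rm(t−tb)}) — exponential
  growth turning linear with slope Cm at x-intercept tb. Primary/basal
  root length, leaf area and seedling dry weight follow a Gompertz sigmoid
  Y(t) = Wf·e^{−e^{−k(t−TT)}} with asymptote Wf and maximum relative rate
  k at time TT (where Y = Wf/e). Cotyledon dry weight follows a logistic
  decay Y(t) = Min + (Max−Min)/(1 + e^{t−TT}) as reserves are remobilized.
* **Correlated, heteroskedastic errors.** Repeated measurements on the
  same plant are fitted by generalized non-linear least squares (full ML)
  with within-plant AR1 correlation ρ and a variance function of the
  measurement day — exponential e^{δ·day}, or one free ratio per harvest
  for destructive traits.
* **Five genetic hypotheses.** The four lines are partitioned into
  parameter levels under GEN4 (all distinct), GEN3 (F1s share), MAPHE
  (maternal seed-size classes), MAHY (parents share) and UNI (all share);
  candidates are ranked by AICc = −2logL + 2k + 2k(k+1)/(n−k−1) with
  Akaike weights w_i = e^{−Δ_i/2}/Σe^{−Δ_j/2} and evidence ratios
  e^{Δ/2}.
* **End-point traits and derived statistics.** Tukey-HSD compact letter
  displays for per-plant traits, seed circularity 4πA/P², organ length
  per gram of seed, and remobilization efficiency (seedling Wf over
  cotyledon Max).

Because the original raw measurements were never deposited, the package
ships a synthetic-data generator that emulates the study design (plants
measured every other day up to day 12, or harvested destructively) with
the published estimates as generating truth, and the whole analysis is
validated by parameter-recovery, coverage and selection-consistency
simulations.

## Worked example

```python
import seedlingfit as sf

cfg = sf.default_config("TRL", plants_per_line=14, seed=11)
data = sf.simulate_trajectories(cfg)
fits = sf.fit_schemes(data, "TRL", "expolinear", sf.CovarianceSpec())
print(sf.compare_fits(fits))
```

prints the selection table

```
scheme  df  logL  AICc  dAICc     wAICc        ER support
 MAPHE   9 -1505  3028      0    0.9958         1  strong
  GEN4  15 -1504  3039  10.94  0.004196     237.3 discard
  MAHY  12 -1585  3194  166.2 8.012e-37 1.243e+36 discard
  GEN3  12 -1587  3198  170.6 9.064e-38 1.099e+37 discard
   UNI   6 -1626  3264  236.5 4.387e-52  2.27e+51 discard
```

The data were simulated under the maternal seed-size hypothesis (MAPHE),
and MAPHE wins with essentially all the Akaike weight; its only
competitor is GEN4, the four-level refinement that nests it and pays a
6-parameter penalty. Fitting the winning model directly,

```python
spec = sf.ModelSpec("TRL", "expolinear", cfg.scheme, sf.CovarianceSpec())
fit = sf.fit_gnls(spec, data)
print(fit.estimates_table())
```

returns per-class estimates with asymptotic 95% intervals — e.g. for the
large-seed class Cm ≈ 154.1 cm/d (CI 145.4–162.9) against the generating
value 149.52 cm/d — plus the nuisance estimates (ρ̂ ≈ 0.58, δ̂ ≈ 0.195/d
here, truth 0.5 and 0.2). The scripts in `examples/` walk through each
capability: curve evaluation, simulate-and-refit, model selection, seed
trait comparison with Tukey letters, and the end-to-end multi-trait
pipeline (`run_full_analysis` + `render_report`).

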