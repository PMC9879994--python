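# reefmass

Bayesian size–weight modelling and belt-transect standing-biomass
estimation for harvested aquarium corals.

## The problem

Coral harvest fisheries (Queensland, Western Australia, Northern Territory)
report their catch of large-polyp stony (LPS) corals by weight, but field
surveys record colony counts and sizes. To judge whether a weight-based
quota is ecologically meaningful you need the *standing biomass* of each
target species — grams of harvestable coral per square metre of habitat.
`reefmass` bridges that gap for species such as *Catalaphyllia jardinei*,
*Duncanopsammia axifuga*, *Euphyllia glabrescens*, *Homophyllia* cf.
*australis*, *Micromussa lordhowensis* and *Trachyphyllia geoffroyi*:

1. **Size–weight model.** Per species, weight follows a two-parameter power
   law in maximum colony diameter,

       W_i ~ N(μ_i, σ),   μ_i = a · D_i^b

   (or, on the variance-stabilised scale, log W_i ~ N(log a + b·log D_i, σ)),
   fitted by MCMC with weakly informative priors. The exponent prior is
   centred on isometry (b = 3); posterior draws of b feed a direct test of
   allometric growth, P(b < 3).
2. **Model screening.** Linear (a + bD) and exponential (a·e^{bD})
   alternatives are compared with the power law by PSIS-LOO
   cross-validation (elpd_loo, elpd_diff ± se_diff, Pareto-k̂ diagnostics),
   with an exact leave-one-out refit oracle for small n.
3. **Group comparisons.** Robust (Student-t) Bayesian pairwise comparisons
   of weight, diameter and density between groups, and a lognormal
   ANCOVA-type model with a per-species offset `c` whose pairwise contrasts
   exp(c_s − c_t) say whether two species share a size–weight relationship.
4. **Transect biomass.** Belt-transect (50 × 1 m) frame measurements
   (pixels against a 1 m scale bar) convert to cm; each coral's weight is
   predicted from its species' fitted curve; per-transect totals divide by
   area to give g·m⁻², summarised as mean ± SE / median / min / max per
   species and state.

Because the underlying fishery specimen data are commercially restricted,
the package includes a calibrated synthetic-data generator
(`reefmass.simulate`) reproducing the published per-species size ranges,
sample sizes, power-law structure, and the patchy, outlier-heavy transect
occupancy of real surveys — so the entire pipeline is testable end to end
against known ground truth.

## Worked example

```python
import numpy as np
from reefmass import SizeWeightRegressor, allometry_test, generate_specimens
from reefmass.simulate import SPECIES_DEFAULTS

cfg = SPECIES_DEFAULTS["Catalaphyllia jardinei"]
recs = generate_specimens(cfg, n=300, seed=42)
x = np.array([r.max_diameter_cm for r in recs])
y = np.array([r.weight_g for r in recs])

reg = SizeWeightRegressor(likelihood="lognormal", random_state=1).fit(x, y)
b = reg.summary_.params["b"]
print(f"b = {b['mean']:.2f} ± {b['se']:.2f} "
      f"(95% HDI {b['hdi_low']:.2f}–{b['hdi_high']:.2f}), "
      f"R² = {reg.summary_.bayes_r2:.2f}")
print(f"P(b < 3) = {allometry_test(reg.draws_).prob_b_lt_3:.2f}")
print(f"predicted weight at 10 cm: {reg.predict([[10.0]])[0]:.1f} g")
```

prints

```
b = 2.68 ± 0.08 (95% HDI 2.53–2.83), R² = 0.80
P(b < 3) = 1.00
predicted weight at 10 cm: 358.8 g
```

The generating exponent here is 2.73; the 95% HDI covers it, every
posterior draw lies below 3 (clear allometry — weight grows more slowly
than the cube of diameter), and the fitted curve predicts a 10 cm colony
at about 359 g. `SizeWeightRegressor` is a scikit-learn estimator, so it
composes with `clone`, pipelines and model selection.

The same workflow runs from the shell:

```bash
reefmass simulate --out data --seed 1
reefmass fit --specimens data/specimens.csv \
    --species "Trachyphyllia geoffroyi" --likelihood lognormal --seed 2
reefmass compare --specimens data/specimens.csv \
    --species "Trachyphyllia geoffroyi"
reefmass pipeline --config config.yaml --seed 1 --out results
```

`reefmass pipeline` writes specimen/transect tables, per-species fit
summaries (`fits.json`), a model-comparison table, species contrasts,
per-transect densities and Table-style density summaries, plus a run log —
deterministically for a given config and seed.

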