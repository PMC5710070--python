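# rrfi — random-regression residual feed intake

Feed efficiency drives the economics of pig production, and residual feed
intake (RFI) — the feed an animal eats beyond what its maintenance, growth
and fat deposition predict — is the classical selection criterion for it.
`rrfi` implements a random-regression extension of RFI in which the needs
themselves are animal-specific: weekly feed intake is regressed on
standardized metabolic body weight (MW = BW^0.75), body-weight gain (WG)
and backfat gain (FG), with the regression intercepts *and slopes* carrying
additive-genetic and permanent-environmental variation per animal,

    y = BA_jk + MW·β1j + WG·β2j + FG·β3j + b_l + MW·γ1jk + WG·γ2jk + FG·γ3jk
      + (a_1i + MW·a_2i + WG·a_3i + FG·a_4i) + (p_1i + MW·p_2i + …) + e,

with genetic covariance G0 ⊗ A over the pedigree and permanent covariance
P0 ⊗ I. Eight nested models (intercepts only, up to all three slopes) are
compared by DIC. The package is aimed at quantitative geneticists working
with longitudinal feed-intake data: it covers the full path from raw daily
feeder records to genetic parameters and predicted selection responses.

What it provides:

* **pedigree** — numerator relationship matrix (tabular method), inbreeding
  (Meuwissen–Luo), sparse A⁻¹ by Henderson's inbreeding-corrected rules;
* **phenoprep** — daily intake imputation and weight/backfat interpolation
  via animal-nested three-coefficient Legendre polynomials, weekly record
  derivation, filtering, within week×batch standardization;
* **model** — the eight nested random-regression designs;
* **inference / reml** — Gibbs sampling with flat variance priors (numba
  sweeps), posterior summaries (mean/median/sd/95% HPD/Pr>0/ESS), DIC;
  EM-REML and BLUP on sparse mixed-model equations (PCG for large systems);
* **params** — heritabilities, slope variance ratios, genetic correlations,
  conditional h² along a covariate, variance partitions;
* **simulate** — a stochastic 120-sow/30-boar selection nucleus comparing
  six feed-efficiency selection indexes (FI, tRFI, RFI, FI/MW, FI/WG,
  FI/FG);
* **synth** — synthetic datasets with known truth, from weekly records down
  to raw daily-intake and measurement files.

## Worked example

```python
import numpy as np
from rrfi.synth import FixtureConfig, generate_weekly_dataset
from rrfi.model import build_design_system, model_from_code
from rrfi.inference import ChainConfig, gibbs_sample
from rrfi.params import derived_draws

ds = generate_weekly_dataset(FixtureConfig(n_batches=2, animals_per_batch=160, seed=11))
system = build_design_system(ds.records, ds.pedigree, model_from_code(8))
samples = gibbs_sample(system, ChainConfig(n_iterations=50_000, burn_in=10_000,
                                           thinning=10, n_chains=2, seed=12))
d = derived_draws(samples, system.spec)
for k in ("h2_rfi", "slope_ratio_mw", "slope_ratio_wg", "slope_ratio_fg"):
    print(k, round(float(np.mean(d[k])), 3))
```

prints (about two minutes on one core):

```
h2_rfi 0.143
slope_ratio_mw 0.421
slope_ratio_wg 0.415
slope_ratio_fg 0.491
```

The fixture was generated with an intercept heritability of 0.12 and slope
additive shares of 0.44/0.39/0.55 (MW/WG/FG); the posterior means recover
them within their posterior uncertainty — the FG slope is the most weakly
identified component (its variance is a few hundred (g/d)² against a
~31,000 (g/d)² residual), so its ratio shrinks toward ½ at this population
size.

The same pipeline is available from the shell:

```bash
rrfi fixture --out fx --seed 3
rrfi prep --daily fx/daily_intake.csv --events fx/measurements.csv \
          --penmap fx/penmap.csv --out prep
rrfi fit --records prep/weekly_records.csv --pedigree fx/pedigree.csv \
         --model 8 --out fit
rrfi simulate --scenario RFI --replicates 50 --out sim
```

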