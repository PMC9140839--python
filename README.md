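# aquarisk

Human health risk assessment of heavy metals in river drinking-water
sources, with PCA source apportionment and Monte Carlo uncertainty
propagation.

The package targets the standard survey design for a large-river transect:
per-site concentrations of seven metals (Cr, As, Cd, Pb, Cu, Zn, Ni in
μg/L) sampled along both banks from upstream to downstream — 55 sites per
bank, 110 samples in total in the reference design. It provides:

- **Deterministic risk (`risk_core`)** — the US-EPA two-pathway exposure
  model for adult and child receptors:

  - ingestion dose `Q_ing = C_w · IR · ABS_GI · EF · ED / (BW · AT)`
  - dermal dose `Q_derm = C_w · K_P · SA · ET · EF · ED / (BW · AT)`
    (with the contacted volume converted cm³ → L)
  - hazard quotient `HQ = Q_ing/RfD_oral + Q_derm/RfD_dermal`, hazard
    index `HI = Σ HQ`, and cancer risk
    `CR = Q_ing·CSF_oral + Q_derm·CSF_dermal` for the carcinogens
    (Cr, As, Cd), classified against the 10⁻⁶ / 5×10⁻⁵ / 10⁻⁴ benchmarks.

- **Descriptive screening (`descriptive_stats`)** — per-metal range,
  mean ± SD, median, CV, Tukey 1.5×IQR outlier counts, and compliance of
  the observed maxima against GB 5749-2006, GB 3838-2002 Class I, WHO and
  US EPA MCL guideline limits.

- **Source apportionment (`source_apportionment`)** — KMO sampling
  adequacy, Bartlett's sphericity test, PCA on the Pearson correlation
  matrix, Kaiser (eigenvalue > 1) retention and varimax rotation with
  Kaiser normalization, reported as a loadings × components table with
  variance contributions.

- **Monte Carlo uncertainty (`uncertainty_mc`)** — maximum-likelihood
  fitting of candidate distributions (normal, lognormal, gamma, Weibull,
  triangular, uniform, Gumbel, beta-on-range) to the stochastic inputs
  (concentration, ingestion rate, body weight), selection by the
  Anderson–Darling statistic with KS and χ² diagnostics, propagation of
  10 000 joint draws through the risk equations, and a simulated-versus-
  calculated comparison report.

- **Synthetic transect generator (`synthetic_data`)** — a seedable
  generator of concentration tables with right-skewed moment-matched
  lognormal marginals, left/right-bank asymmetries, qualitative downstream
  trends, and a Gaussian-copula correlation structure with two source
  blocks ({Cr, Ni, Cu} and {Zn, Cd, Pb}) plus a largely independent As
  factor, standing in for unreleased survey data.

## Worked example

```bash
aquarisk simulate-data --seed 1 --out conc.csv
aquarisk pca conc.csv --out loadings.csv
aquarisk report --table conc.csv --out-dir report --seed 1 --draws 2000
```

The `pca` step prints

```
KMO 0.390 | Bartlett chi2 310.8 (df 21, p 2.00e-53)
3 components, cumulative contribution 78.2%
```

i.e. for this draw the correlation matrix is decidedly non-spherical,
three components pass the Kaiser criterion and together explain 78% of the
variance. `report/headline.json` then collects the headline numbers; for
seed 1 the dominant-loading assignment recovers the planted structure
exactly —

```json
"dominant": {"Cr": "PC1", "Ni": "PC1", "Cu": "PC1",
             "Zn": "PC2", "Cd": "PC2", "Pb": "PC2", "As": "PC3"},
"hi_max":   {"adult": 0.516, "kid": 0.731},
"cr_total_mean": {"adult": 5.31e-4, "kid": 7.51e-4}
```

— no site exceeds the non-carcinogenic concern level HI = 1, but the mean
total carcinogenic risk sits above the 10⁻⁴ benchmark for both receptors,
and every child risk exceeds the adult one.

From Python, the deterministic single-site calculation at the reference
survey's As maximum (8.52 μg/L):

```python
>>> import aquarisk as aq
>>> tox = aq.DEFAULT_TOXICITY["As"]
>>> q_ing = aq.daily_dose_ingestion(8.52, aq.KID)
>>> q_derm = aq.daily_dose_dermal(8.52, aq.KID)
>>> round(aq.hazard_quotient(q_ing, q_derm, tox), 2)
1.37
>>> aq.classify_risk(1.37).noncarcinogenic
'concern'
```

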