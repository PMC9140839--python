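# Methods

This note documents the models implemented in `aquarisk`, the defaults and
their rationale, what the synthetic generator does and does not emulate,
and the numerical choices a maintainer would want to know.

## Exposure and risk model

Risk is evaluated for two receptors (adult, child) and two pathways
(direct ingestion of untreated river water, dermal contact). Average daily
doses in mg/(kg·d) are

    Q_ing  = (C_w/1000) · IR · ABS_GI · EF · ED / (BW · AT)
    Q_derm = (C_w/1000) · K_P · SA · ET · EF · ED / (BW · AT) / 1000

with `C_w` carried in μg/L and converted to mg/L inside the equations.
The second /1000 in the dermal dose converts the contacted water volume
(`K_P·SA·ET` accumulates in cm³) to litres; only with both conversions do
the equations reproduce the reference endpoint values (e.g. an adult As
hazard quotient of 0.9690 at 8.52 μg/L).

Receptor parameters (packaged in `data/exposure.yaml`, editable):

| parameter | unit | adult | child |
|---|---|---|---|
| BW body weight | kg | 62.4 | 20.08 |
| AT averaging time | d | 10 950 | 4 380 |
| EF exposure frequency | d/a | 350 | 350 |
| IR ingestion rate | L/d | 2.2 | 1.0 |
| ABS_GI gastrointestinal absorption | – | 1 | 1 |
| ED exposure duration | a | 30 | 12 |
| K_P dermal permeability | cm/h | 0.001 | 0.001 |
| ET exposure time | h/d | 0.5 | 0.5 |
| SA surface area | cm² | 16 600 | 9 500 |

Two consequences of these values are exact model invariants used in the
tests: the child/adult ingestion-dose ratio is 1.41253 and the dermal
ratio 1.77842, for every concentration.

Deliberate modelling choices:

- **AT = ED × 365 for carcinogens too.** Standard EPA practice averages
  cancer risk over a 70-year lifetime; the reference parameterization uses
  the exposure-duration averaging time for both endpoints, and the
  published cancer-risk values are reproducible only that way. The profile
  is editable if a lifetime AT is preferred.
- **Dermal toxicity values are taken from the toxicity table, not derived
  via RfD·ABS_GI.** The packaged dermal RfDs encode effective absorption
  fractions (e.g. As 0.000123 = 0.0003 × 0.41) that are inconsistent with
  the nominal ABS_GI = 1 of the exposure profiles; the table values are
  the ones that reproduce the published risks. `rfd_dermal_from_drinking`
  implements the conversion for completeness.
- **Missing CSF = non-carcinogen.** Ni, Pb, Cu and Zn carry no slope
  factors; their cancer risk is *absent*, not zero, and total CR sums over
  the carcinogens Cd, As, Cr only.
- **"Exceeds 1" is strict.** HI or HQ exactly 1.0 is classified
  acceptable. Cancer risk is compared separately against the three
  conventional benchmarks 10⁻⁶ (contaminated-site guideline),
  5×10⁻⁵ (ICRP) and 10⁻⁴ (Dutch limit).
- Report tables are rendered with the conventional power-of-ten row scales
  and two decimals; internal computation is never rounded.

## Synthetic transect generator

No raw per-site data were released for the reference survey, so the
generator emulates its published structure; its defaults *are* the study
conditions the rest of the pipeline is tested under.

- **Marginals.** Lognormal, moment-matched per metal:
  σ² = ln(1 + sd²/mean²), μ = ln(mean) − σ²/2, with (mean, sd) and clip
  ranges taken from the published summary table (n = 110). Lognormality
  reflects that every metal's mean exceeds its median and all boxplot
  outliers are high-side. Values falling outside the published range are
  redrawn (≤100 attempts, then truncated) rather than clipped, to avoid
  probability spikes at the range ends.
- **Banks.** 55 sites per bank; the left bank is enriched for Zn, As, Cd,
  Pb and the right bank for Cu, Ni, Cr (multiplicative factors 1 ± b/2).
  The published source quantifies direction only; the default magnitude is
  b = 0.4·CV per metal (15–38%), chosen once so the asymmetry is
  detectable (~2 SE of the bank-mean difference) at 55 sites per bank and
  consistent with the 14–54% per-bank differences the published bank
  averages display. A uniform ±10% shift was rejected: for the high-CV
  metals it is statistically invisible at this sample size.
- **Downstream trends.** Multiplicative mean-one positive factors over the
  ordinal position 1..55: linear upward for Ni, Cu, Cr; linear upward plus
  a Gaussian bump at 85% of the transect for Pb, Cd, Zn; a bump at 10% for
  As. Amplitude defaults to 20% of the mean; the source describes shapes
  only, so amplitudes are conventions.
- **Correlation.** A Gaussian copula with within-block correlation 0.7 for
  {Cr, Ni, Cu} and {Zn, Cd, Pb}, 0.25 between the blocks, and 0.45 between
  As and one member of each block (Zn, Cr). The lognormal transform
  attenuates these (realized Pearson ≈ 0.6 / 0.2 / 0.3). The As couplings
  matter: with As fully independent, the As factor's population eigenvalue
  is exactly 1 and Kaiser retention of a third component degenerates to a
  coin flip at n = 110; the weak couplings mirror the secondary loadings
  real source profiles display and lift that eigenvalue to ~1.15, making
  the planted three-factor structure recoverable in >90% of seeds.
- **What is not emulated.** No geostatistics (position is ordinal, not
  coordinates), no measurement error or censoring at detection limits, no
  seasonal or hydrological covariates, and independence of sites along the
  transect (real transects are spatially autocorrelated). Passing tests
  therefore demonstrate that the pipeline recovers structure *of this
  kind*, not that it would from any particular real river.

## Descriptive statistics

Sample SD (n−1), CV = sd/mean·100, medians by linear interpolation between
order statistics, and Tukey fences Q1 − 1.5·IQR / Q3 + 1.5·IQR with
quartiles by the same interpolation rule (the common statistical-software
default; the reference does not define its boxplot rule, so published
outlier counts guide the generator but are not asserted). Guideline
screening compares the observed maximum against each standard's limit;
standards without a limit for a metal are reported `not-assessed`.
Published CVs are not exactly sd/mean of the rounded printed moments
(e.g. 0.24/0.35 = 68.6% vs a printed 69.00%); the implementation computes
CV from the data and does not force agreement.

## Source apportionment

Pearson-correlation PCA (scale-invariant, appropriate for concentrations
spanning two orders of magnitude), with an optional log-transform flag for
strongly skewed inputs. KMO uses the anti-image partial correlations from
the inverted correlation matrix and is reported as NaN for an exactly
diagonal correlation matrix (0/0). Bartlett's statistic is
−(n−1−(2p+5)/6)·ln|R| on p(p−1)/2 degrees of freedom. Loadings are
eigenvectors scaled by √eigenvalue; retention is Kaiser (eigenvalue > 1)
by default with a fixed-count override; rotation is varimax with Kaiser
row normalization (the SPSS default), iterated until the criterion change
falls below 10⁻⁸, and validated in the tests against R's `stats::varimax`.
Components are ordered by explained variance and sign-flipped so each
dominant loading is positive. Adequacy failures warn rather than block,
since PCA remains algebraically defined.

Design trade-off: with seven variables in a 3+3+1 factor layout, sampling
adequacy and a stably retained third factor pull in opposite directions —
diffuse weak correlations raise KMO but absorb the As factor's variance
into the block components and collapse its eigenvalue toward 1. The
defaults favour recoverability: KMO exceeds 0.5 in roughly 80% of seeds
(median above 0.5) rather than near-always, while the three-component
block pattern is recovered in 92–96% of seeds. The same tension is visible
in the reference survey itself, which reports KMO 0.724 alongside a third
eigenvalue of 1.007.

## Monte Carlo uncertainty

The stochastic "assumption" inputs are the concentration (per metal and
bank), the ingestion rate and the body weight; all other exposure
parameters stay fixed. Candidate families are fitted by maximum likelihood
(location pinned at zero for the positive-support families; beta fitted on
the slightly widened observed range). The reported diagnostics are the
Anderson–Darling A² statistic (computed against the fitted CDF), the KS
statistic and p-value (approximate, as parameters are estimated), and a
χ² test on ~√n equiprobable bins with df reduced by the parameter count.
Selection is by smallest A², ties by larger KS p, then fewer parameters;
A² < 1.5 is surfaced as an advisory flag only, because the conventional
triplet of pass thresholds is not a coherent acceptance rule for all three
tests. The reference never states which family won per variable, so the
pipeline records its choice instead of hard-coding one.

Draws (default 10 000, matching the reference) are independent across
inputs — no joint structure is published — with negative draws rejected
and redrawn. Each draw is pushed through the deterministic dose/risk
equations, and summaries report mean, SD, the 2.5/5/50/95/97.5 percentiles
and exceedance probabilities against HQ = 1 and the CR benchmarks.
Point-mass inputs reproduce the deterministic results exactly; with
concentration-only stochasticity the model is linear in C_w, so the
simulated mean matches the deterministic value at the mean concentration
to Monte Carlo error (<2% at 10⁴ draws); with stochastic body weight the
simulated mean exceeds the deterministic value (Jensen's inequality for
1/BW). Exact published simulation outputs depend on the unreleased
per-bank samples and are treated as structural references, not targets.

## Problem sizes in the test suite

Fixed-seed (derandomized) simulations throughout: 100 seeds for the
structure-recovery rate, 40–60 seeds for generator calibration properties,
10⁴ draws for Monte Carlo consistency, 2×10⁴ for the Jensen check. These
sizes keep the whole suite around half a minute while leaving the binomial
/ Monte Carlo margins well clear of the asserted thresholds.

## Known limitations

- Exposure via food, inhalation, or treated tap water is out of scope, as
  is any toxicokinetic or mixture (antagonism/synergy) modelling; risks
  for a drinking-water scenario based on raw river concentrations are
  conservative.
- The KS p-value after parameter estimation is optimistic (no
  Lilliefors-type correction); it is used only as a tie-breaker.
- KMO of the default synthetic data is moderate by design (see above);
  analyses requiring KMO > 0.7 should use real data or a denser factor
  layout.
- The CLI loads packaged parameter defaults; site-specific assessments
  should supply their own exposure/toxicity YAML files.
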