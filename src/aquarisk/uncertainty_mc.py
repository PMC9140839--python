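"""Monte Carlo uncertainty propagation for HQ and CR.

Mirrors the spreadsheet-Monte-Carlo workflow: the measured concentration,
the daily water ingestion rate and the body weight are treated as stochastic
"assumption" inputs, each assigned the best-fitting parametric distribution
from a candidate set (selected by the Anderson-Darling statistic, with
Kolmogorov-Smirnov and chi-square diagnostics reported alongside); the
hazard quotient and cancer risk are the "prediction" outputs, evaluated
through the deterministic dose equations draw by draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, DomainError
from .risk_core import ExposureProfile, ToxicityProfile

#: Candidate family name -> (scipy distribution, fixed fit kwargs).
#: Location is pinned at zero for the positive-support families so the
#: fitted laws remain physically meaningful for concentrations and weights.
CANDIDATE_FAMILIES: dict[str, tuple[stats.rv_continuous, dict]] = {
    "normal": (stats.norm, {}),
    "lognormal": (stats.lognorm, {"floc": 0.0}),
    "gamma": (stats.gamma, {"floc": 0.0}),
    "weibull": (stats.weibull_min, {"floc": 0.0}),
    "triangular": (stats.triang, {}),
    "uniform": (stats.uniform, {}),
    "gumbel": (stats.gumbel_r, {}),
    "beta": (stats.beta, {}),  # fitted on the observed range, see _fit_one
}

_N_PARAMS = {"normal": 2, "lognormal": 2, "gamma": 2, "weibull": 2,
             "triangular": 3, "uniform": 2, "gumbel": 2, "beta": 4}


@dataclass
class FittedInput:
    """A stochastic model-input variable with its fitted distribution.

    ``family == "point_mass"`` marks a degenerate (constant) input; its
    single parameter is the constant value.
    """

    name: str
    family: str
    params: tuple[float, ...]
    diagnostics: Mapping[str, float] = field(default_factory=dict)
    ad_ok: bool | None = None  # advisory: Anderson-Darling statistic < 1.5

    def frozen(self):
        if self.family == "point_mass":
            raise ConfigurationError("point mass has no scipy frozen form")
        dist, _ = CANDIDATE_FAMILIES[self.family]
        return dist(*self.params)

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "point_mass":
            return np.full(size, self.params[0])
        return self.frozen().rvs(size=size, random_state=rng)

    @classmethod
    def point_mass(cls, name: str, value: float) -> "FittedInput":
        return cls(name=name, family="point_mass", params=(float(value),))


def anderson_darling_statistic(values: np.ndarray, cdf) -> float:
    """A^2 statistic of a sample against an arbitrary fitted CDF."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    u = np.clip(cdf(x), 1e-12, 1 - 1e-12)
    i = np.arange(1, n + 1)
    return float(-n - np.mean((2 * i - 1) * (np.log(u) + np.log(1 - u[::-1]))))


def _chi_square_gof(values: np.ndarray, frozen, n_params: int) -> tuple[float, float]:
    """Chi-square GOF on equiprobable bins; df = bins - 1 - n_params."""
    n = values.size
    n_bins = max(5, min(30, int(np.sqrt(n))))
    edges = frozen.ppf(np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    observed, _ = np.histogram(values, bins=edges)
    expected = n / n_bins
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    df = max(1, n_bins - 1 - n_params)
    return chi2, float(stats.chi2.sf(chi2, df))


def _fit_one(values: np.ndarray, family: str):
    dist, fit_kwargs = CANDIDATE_FAMILIES[family]
    if family == "beta":
        # beta on the observed range, slightly widened so endpoints are interior
        lo, hi = values.min(), values.max()
        pad = 1e-6 * (hi - lo)
        fit_kwargs = {"floc": lo - pad, "fscale": (hi - lo) + 2 * pad}
    with np.errstate(all="ignore"):
        params = dist.fit(values, **fit_kwargs)
    frozen = dist(*params)
    if not np.isfinite(frozen.mean()):
        raise ValueError("fitted distribution has non-finite mean")
    return params, frozen


def fit_distribution(
    values: Sequence[float],
    candidates: Sequence[str] | None = None,
    name: str = "input",
) -> FittedInput:
    """Fit every candidate family by maximum likelihood and select the best.

    Selection: smallest Anderson-Darling statistic; ties (within 1e-9)
    broken by larger KS p-value, then by fewer parameters.  Reports AD, KS
    (statistic and p) and chi-square (statistic and p) diagnostics for the
    winner, plus an advisory ``ad_ok`` flag (AD < 1.5).  A constant sample
    returns a point-mass pseudo-family.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 20:
        raise DomainError(f"distribution fitting needs >= 20 values, got {x.size}")
    if np.ptp(x) == 0:
        return FittedInput.point_mass(name, x[0])
    if candidates is None:
        candidates = list(CANDIDATE_FAMILIES)
    unknown = set(candidates) - set(CANDIDATE_FAMILIES)
    if unknown:
        raise ConfigurationError(f"unknown candidate families: {sorted(unknown)}")

    results = []
    failures = {}
    for family in candidates:
        try:
            params, frozen = _fit_one(x, family)
            ad = anderson_darling_statistic(x, frozen.cdf)
            ks = stats.kstest(x, frozen.cdf)
            chi2_stat, chi2_p = _chi_square_gof(x, frozen, _N_PARAMS[family])
            if not np.isfinite(ad):
                raise ValueError("non-finite AD statistic")
            results.append((family, params, {
                "ad_stat": ad,
                "ks_stat": float(ks.statistic), "ks_p": float(ks.pvalue),
                "chi2_stat": chi2_stat, "chi2_p": chi2_p,
            }))
        except Exception as err:  # fit failures are collected, not fatal
            failures[family] = str(err)
    if not results:
        raise DomainError(f"all candidate fits failed: {failures}")

    results.sort(key=lambda r: (round(r[2]["ad_stat"] / 1e-9) * 1e-9,
                                -r[2]["ks_p"], _N_PARAMS[r[0]]))
    family, params, diag = results[0]
    return FittedInput(name=name, family=family, params=tuple(params),
                       diagnostics=diag, ad_ok=diag["ad_stat"] < 1.5)


@dataclass(frozen=True)
class MCResult:
    """Monte Carlo prediction summary for one (quantity, metal, receptor)."""

    prediction: str              # "HQ" or "CR"
    metal: str
    receptor: str
    n_draws: int
    seed: int | None
    mean: float
    sd: float
    percentiles: Mapping[float, float]   # keys 2.5, 5, 50, 95, 97.5
    exceedance: Mapping[float, float]    # threshold -> P(value > threshold)
    draws: np.ndarray | None = None

    def as_row(self) -> dict:
        row = {"prediction": self.prediction, "metal": self.metal,
               "receptor": self.receptor, "n_draws": self.n_draws,
               "seed": self.seed, "mean": self.mean, "sd": self.sd}
        row.update({f"p{q:g}": v for q, v in self.percentiles.items()})
        row.update({f"P_gt_{t:g}": v for t, v in self.exceedance.items()})
        return row


_PCTS = (2.5, 5.0, 50.0, 95.0, 97.5)


def _draw_positive(inp: FittedInput, n: int, rng: np.random.Generator,
                   max_rounds: int = 100) -> np.ndarray:
    """Draw n values, rejecting and redrawing negatives."""
    out = inp.rvs(n, rng)
    for _ in range(max_rounds):
        bad = out < 0
        if not bad.any():
            return out
        out[bad] = inp.rvs(int(bad.sum()), rng)
    raise DomainError(f"{inp.name}: could not obtain non-negative draws "
                      f"(family {inp.family} has too much negative mass)")


def simulate_risk(
    concentration: FittedInput,
    tox: ToxicityProfile,
    profile: ExposureProfile,
    ingestion_rate: FittedInput | None = None,
    body_weight: FittedInput | None = None,
    n_draws: int = 10_000,
    seed: int | None = None,
) -> dict[str, MCResult]:
    """Propagate input uncertainty through the dose/risk equations.

    Concentration (ug/L), ingestion rate IR (L/day) and body weight BW (kg)
    are stochastic; IR and BW default to point masses at the profile's
    values.  All other exposure parameters are fixed.  Inputs are drawn
    independently; negative draws are rejected and redrawn.  Returns
    ``{"HQ": MCResult, "CR": MCResult}`` (CR present only for carcinogens).
    Deterministic for a fixed seed.
    """
    if n_draws < 1:
        raise ConfigurationError(f"n_draws must be >= 1, got {n_draws}")
    if ingestion_rate is None:
        ingestion_rate = FittedInput.point_mass("IR", profile.IR)
    if body_weight is None:
        body_weight = FittedInput.point_mass("BW", profile.BW)
    rng = np.random.default_rng(seed)

    cw = _draw_positive(concentration, n_draws, rng)
    ir = _draw_positive(ingestion_rate, n_draws, rng)
    bw = _draw_positive(body_weight, n_draws, rng)
    bw = np.where(bw <= 0, profile.BW, bw)  # guard 1/BW against zero draws

    q_ing = (cw / 1000.0) * ir * profile.ABS_GI * profile.EF * profile.ED / (bw * profile.AT)
    q_derm = ((cw / 1000.0) * profile.KP * profile.SA * profile.EF * profile.ED
              * profile.ET / (bw * profile.AT) / 1000.0)

    def _summarize(pred: str, draws: np.ndarray, thresholds: tuple[float, ...]) -> MCResult:
        return MCResult(
            prediction=pred, metal=tox.metal, receptor=profile.receptor_label,
            n_draws=n_draws, seed=seed,
            mean=float(draws.mean()),
            sd=float(draws.std(ddof=1)) if n_draws > 1 else 0.0,
            percentiles={q: float(np.percentile(draws, q)) for q in _PCTS},
            exceedance={t: float((draws > t).mean()) for t in thresholds},
            draws=draws,
        )

    hq = q_ing / tox.rfd_drinking + q_derm / tox.rfd_dermal
    out = {"HQ": _summarize("HQ", hq, (1.0,))}
    if tox.is_carcinogen:
        cr = q_ing * tox.csf_drinking + q_derm * tox.csf_dermal
        out["CR"] = _summarize("CR", cr, (1e-6, 5e-5, 1e-4))
    return out


def compare_simulated_vs_calculated(
    mc_results: Mapping[str, Mapping[str, MCResult]],
    deterministic: Mapping[str, Mapping[str, float]],
) -> pd.DataFrame:
    """Simulated means against deterministic point calculations.

    Both arguments are nested ``{key: {prediction: value}}`` mappings with
    matching keys (e.g. key = "As/adult/left").  Returns a long frame with
    the simulated mean, the calculated value and their relative difference.
    """
    if set(mc_results) != set(deterministic):
        raise ConfigurationError(
            f"key mismatch: simulated {sorted(mc_results)} vs calculated {sorted(deterministic)}"
        )
    rows = []
    for key in mc_results:
        sims, calcs = mc_results[key], deterministic[key]
        if set(sims) != set(calcs):
            raise ConfigurationError(f"{key}: prediction mismatch {sorted(sims)} vs {sorted(calcs)}")
        for pred, mc in sims.items():
            calc = calcs[pred]
            rel = (mc.mean - calc) / calc if calc != 0 else np.nan
            rows.append({"key": key, "prediction": pred, "simulated_mean": mc.mean,
                         "calculated": calc, "relative_difference": rel})
    return pd.DataFrame(rows)
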