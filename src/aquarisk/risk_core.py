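"""Deterministic drinking-water exposure and health-risk computation.

Implements the US-EPA-style two-pathway exposure model (direct ingestion of
water and dermal contact) for heavy metals, producing average daily doses,
hazard quotients (HQ), hazard indices (HI) and incremental lifetime cancer
risks (CR) for adult and child receptors.

Units convention
----------------
Concentrations are carried in ug/L everywhere outside the dose equations and
converted to mg/L (/1000) inside them.  In the dermal dose the product
``KP * SA * ET`` has units cm^3 per hour-ish aggregate; a second /1000
converts cm^3 of contacted water to litres so the same mg/L concentration
applies.  Doses are mg per kg body weight per day.

The averaging time AT equals ED x 365 for both the non-carcinogenic and the
carcinogenic endpoint (the standard 70-year carcinogenic AT is deliberately
not used; see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DomainError, ParameterError

#: The seven metals the survey quantifies, in reporting order.
METALS: tuple[str, ...] = ("Cr", "As", "Cd", "Pb", "Cu", "Zn", "Ni")

#: Regulatory benchmarks for incremental lifetime cancer risk, most to least
#: stringent: contaminated-site guideline 1e-6, ICRP 5e-5, Dutch limit 1e-4.
CR_BENCHMARKS: tuple[float, ...] = (1e-6, 5e-5, 1e-4)


@dataclass(frozen=True)
class ExposureProfile:
    """Receptor-specific exposure parameters.

    Attributes
    ----------
    receptor_label : str
        Receptor name, e.g. ``"adult"`` or ``"kid"``.
    BW : float
        Body weight, kg.
    AT : float
        Averaging time, days.
    EF : float
        Exposure frequency, days/year (<= 365).
    IR : float
        Water ingestion rate, L/day.
    ABS_GI : float
        Gastrointestinal absorption factor, dimensionless.
    ED : float
        Exposure duration, years.
    KP : float
        Dermal permeability coefficient, cm/h.
    ET : float
        Dermal exposure time, h/day.
    SA : float
        Exposed body surface area, cm^2.
    """

    receptor_label: str
    BW: float
    AT: float
    EF: float
    IR: float
    ABS_GI: float
    ED: float
    KP: float
    ET: float
    SA: float

    def __post_init__(self) -> None:
        for name in ("BW", "AT", "EF", "IR", "ABS_GI", "ED", "KP", "ET", "SA"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ParameterError(
                    f"exposure parameter {name} must be a positive finite number, got {value!r}"
                )
        if self.EF > 365:
            raise ParameterError(f"EF must not exceed 365 days/year, got {self.EF}")


@dataclass(frozen=True)
class ToxicityProfile:
    """Per-metal toxicity reference values.

    ``rfd_*`` are non-carcinogenic reference doses (mg kg-1 d-1) for the
    drinking and dermal pathways; ``csf_*`` are cancer slope factors
    ((mg kg-1 d-1)-1), ``None`` for non-carcinogens.
    """

    metal: str
    rfd_drinking: float
    rfd_dermal: float
    csf_drinking: float | None = None
    csf_dermal: float | None = None

    def __post_init__(self) -> None:
        for name in ("rfd_drinking", "rfd_dermal"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{self.metal}: {name} must be > 0")
        if (self.csf_drinking is None) != (self.csf_dermal is None):
            raise ParameterError(
                f"{self.metal}: drinking and dermal CSF must be both present or both absent"
            )
        if self.csf_drinking is not None and (self.csf_drinking <= 0 or self.csf_dermal <= 0):
            raise ParameterError(f"{self.metal}: CSF values must be > 0 when present")

    @property
    def is_carcinogen(self) -> bool:
        return self.csf_drinking is not None


# Receptor parameters: adult and child ("kid") defaults used throughout.
ADULT = ExposureProfile(
    receptor_label="adult",
    BW=62.4, AT=10950.0, EF=350.0, IR=2.2, ABS_GI=1.0,
    ED=30.0, KP=0.001, ET=0.5, SA=16600.0,
)
KID = ExposureProfile(
    receptor_label="kid",
    BW=20.08, AT=4380.0, EF=350.0, IR=1.0, ABS_GI=1.0,
    ED=12.0, KP=0.001, ET=0.5, SA=9500.0,
)
DEFAULT_PROFILES: dict[str, ExposureProfile] = {"adult": ADULT, "kid": KID}

# Toxicity reference values.  Cr, As and Cd are the carcinogens (IARC);
# Ni, Pb, Cu and Zn carry only non-carcinogenic endpoints.
DEFAULT_TOXICITY: dict[str, ToxicityProfile] = {
    "As": ToxicityProfile("As", 0.0003, 0.000123, 1.5, 3.66),
    "Cd": ToxicityProfile("Cd", 0.0005, 0.000005, 0.38, 6.1),
    "Cr": ToxicityProfile("Cr", 0.003, 0.00006, 41.0, 41.0),
    "Ni": ToxicityProfile("Ni", 0.02, 0.02),
    "Pb": ToxicityProfile("Pb", 0.0014, 0.0014),
    "Cu": ToxicityProfile("Cu", 0.005, 0.005),
    "Zn": ToxicityProfile("Zn", 0.3, 0.06),
}


def validate_concentration_table(df: pd.DataFrame, metals: Sequence[str] = METALS) -> pd.DataFrame:
    """Validate a per-site concentration table.

    Requires columns ``site_id``, ``bank`` (left/right), ``position`` and one
    column per metal (ug/L, >= 0); site ids must be unique.  Returns the
    (unmodified) frame for chaining.
    """
    required = ["site_id", "bank", "position", *metals]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DomainError(f"concentration table missing columns: {missing}")
    bad_banks = set(df["bank"].unique()) - {"left", "right"}
    if bad_banks:
        raise DomainError(f"bank values must be 'left' or 'right', got {sorted(bad_banks)}")
    if df["site_id"].duplicated().any():
        dupes = df.loc[df["site_id"].duplicated(), "site_id"].tolist()
        raise DomainError(f"duplicate site_id values: {dupes}")
    values = df[list(metals)].to_numpy(dtype=float)
    if (values < 0).any() or not np.isfinite(values).all():
        bad = df.index[(values < 0).any(axis=1) | ~np.isfinite(values).all(axis=1)].tolist()
        raise DomainError(f"negative or non-finite concentrations at rows {bad}")
    return df


# ---------------------------------------------------------------------------
# Dose equations
# ---------------------------------------------------------------------------

def daily_dose_ingestion(cw_ug_per_L: float, exp: ExposureProfile) -> float:
    """Average daily dose via direct water ingestion, mg/(kg d).

    ``Q_ing = (C_w/1000) * IR * ABS_GI * EF * ED / (BW * AT)`` with C_w in
    ug/L converted to mg/L.  Linear in concentration.
    """
    cw = np.asarray(cw_ug_per_L, dtype=float)
    if (cw < 0).any():
        raise DomainError(f"concentration must be >= 0, got {cw_ug_per_L!r}")
    out = (cw / 1000.0) * exp.IR * exp.ABS_GI * exp.EF * exp.ED / (exp.BW * exp.AT)
    return out.item() if np.isscalar(cw_ug_per_L) else out


def daily_dose_dermal(cw_ug_per_L: float, exp: ExposureProfile) -> float:
    """Average daily dose via dermal contact, mg/(kg d).

    ``Q_derm = (C_w/1000) * KP * SA * EF * ED * ET / (BW * AT) / 1000``;
    the trailing /1000 converts the contacted water volume from cm^3 to L.
    """
    cw = np.asarray(cw_ug_per_L, dtype=float)
    if (cw < 0).any():
        raise DomainError(f"concentration must be >= 0, got {cw_ug_per_L!r}")
    out = (
        (cw / 1000.0) * exp.KP * exp.SA * exp.EF * exp.ED * exp.ET
        / (exp.BW * exp.AT) / 1000.0
    )
    return out.item() if np.isscalar(cw_ug_per_L) else out


def rfd_dermal_from_drinking(rfd: float, abs_gi: float) -> float:
    """Derive a dermal reference dose from the oral one: ``RfD_dermal = RfD * ABS_GI``.

    Provided for completeness; the pipeline default reads dermal RfDs
    directly from the toxicity table, whose values encode effective
    gastrointestinal absorption fractions differing from the exposure
    profile's nominal ABS_GI.
    """
    if rfd <= 0:
        raise ParameterError(f"RfD must be > 0, got {rfd}")
    return rfd * abs_gi


def hazard_quotient(q_ing: float, q_derm: float, tox: ToxicityProfile) -> float:
    """Non-carcinogenic hazard quotient: pathway dose/RfD ratios, summed."""
    if q_ing < 0 or q_derm < 0:
        raise DomainError("doses must be >= 0")
    return q_ing / tox.rfd_drinking + q_derm / tox.rfd_dermal


def hazard_index(hqs: Iterable[float]) -> float:
    """Hazard index: the sum of hazard quotients over metals/pathways."""
    values = list(hqs)
    if not values:
        raise DomainError("hazard_index requires at least one HQ")
    if any(v < 0 for v in values):
        raise DomainError("HQ values must be >= 0")
    return float(sum(values))


def cancer_risk(q_ing: float, q_derm: float, tox: ToxicityProfile) -> float | None:
    """Incremental lifetime cancer risk, or ``None`` for non-carcinogens.

    ``CR = Q_ing * CSF_drinking + Q_derm * CSF_dermal``.
    """
    if q_ing < 0 or q_derm < 0:
        raise DomainError("doses must be >= 0")
    if not tox.is_carcinogen:
        return None
    return q_ing * tox.csf_drinking + q_derm * tox.csf_dermal


@dataclass(frozen=True)
class RiskLabels:
    """Classification of a receptor's risk against the standard benchmarks."""

    noncarcinogenic: str  # "acceptable" (<= 1) or "concern" (> 1)
    carcinogenic: Mapping[float, str] = field(default_factory=dict)  # benchmark -> below/above


def classify_risk(hi_or_hq: float, cr: float | None = None) -> RiskLabels:
    """Label a hazard index/quotient and (optionally) a cancer risk.

    The non-carcinogenic threshold is strict: exactly 1 is still acceptable.
    The cancer risk is compared separately against each benchmark in
    :data:`CR_BENCHMARKS`.
    """
    if hi_or_hq < 0 or (cr is not None and cr < 0):
        raise DomainError("risk values must be >= 0")
    nc = "concern" if hi_or_hq > 1 else "acceptable"
    car: dict[float, str] = {}
    if cr is not None:
        for bench in CR_BENCHMARKS:
            car[bench] = "above" if cr > bench else "below"
    return RiskLabels(noncarcinogenic=nc, carcinogenic=car)


# ---------------------------------------------------------------------------
# Vectorized risk table
# ---------------------------------------------------------------------------

@dataclass
class RiskTable:
    """Per-site risk results.

    ``long``: one row per (site, receptor, metal) with doses, HQ and CR
    (CR is NaN for non-carcinogens).  ``summary``: one row per
    (site, receptor) with HI, total CR and classification labels.
    """

    long: pd.DataFrame
    summary: pd.DataFrame

    def bank_summary(self) -> pd.DataFrame:
        """Min/mean/max of HQ and CR per (receptor, bank, metal), plus HI and
        total CR rows — the survey-report layout."""
        if self.long.empty:
            return pd.DataFrame(
                columns=["receptor", "bank", "quantity", "metal", "min", "mean", "max"]
            )
        rows = []
        for (receptor, bank, metal), grp in self.long.groupby(["receptor", "bank", "metal"]):
            rows.append((receptor, bank, "HQ", metal,
                         grp["hq"].min(), grp["hq"].mean(), grp["hq"].max()))
            if grp["cr"].notna().any():
                rows.append((receptor, bank, "CR", metal,
                             grp["cr"].min(), grp["cr"].mean(), grp["cr"].max()))
        for (receptor, bank), grp in self.summary.groupby(["receptor", "bank"]):
            rows.append((receptor, bank, "HI", "all",
                         grp["hi"].min(), grp["hi"].mean(), grp["hi"].max()))
            rows.append((receptor, bank, "CR_total", "all",
                         grp["cr_total"].min(), grp["cr_total"].mean(), grp["cr_total"].max()))
        return pd.DataFrame(rows, columns=["receptor", "bank", "quantity", "metal",
                                           "min", "mean", "max"])


def compute_risk_table(
    conc: pd.DataFrame,
    profiles: Mapping[str, ExposureProfile] | None = None,
    toxicity: Mapping[str, ToxicityProfile] | None = None,
    metals: Sequence[str] | None = None,
) -> RiskTable:
    """Evaluate the dose/HQ/HI/CR model for every site, metal and receptor.

    Parameters
    ----------
    conc : pandas.DataFrame
        Concentration table (``site_id``, ``bank``, ``position`` + metal
        columns in ug/L).
    profiles : mapping, optional
        Receptor label -> :class:`ExposureProfile`; defaults to adult + kid.
    toxicity : mapping, optional
        Metal -> :class:`ToxicityProfile`; defaults to the packaged values.
    metals : sequence, optional
        Metal columns to evaluate; defaults to the intersection of
        :data:`METALS` with the table's columns.
    """
    profiles = dict(profiles) if profiles is not None else dict(DEFAULT_PROFILES)
    toxicity = dict(toxicity) if toxicity is not None else dict(DEFAULT_TOXICITY)
    if metals is None:
        metals = [m for m in METALS if m in conc.columns]
    missing_tox = [m for m in metals if m not in toxicity]
    if missing_tox:
        raise ConfigurationError(f"no toxicity profile for metals: {missing_tox}")

    long_cols = ["site_id", "bank", "receptor", "metal", "q_ingestion", "q_dermal", "hq", "cr"]
    if conc.empty:
        return RiskTable(
            long=pd.DataFrame(columns=long_cols),
            summary=pd.DataFrame(columns=["site_id", "bank", "receptor", "hi", "cr_total",
                                          "nc_label", "cr_vs_1e-06", "cr_vs_5e-05", "cr_vs_0.0001"]),
        )
    validate_concentration_table(conc, metals)

    frames = []
    for label, prof in profiles.items():
        for metal in metals:
            cw = conc[metal].to_numpy(dtype=float)
            q_ing = daily_dose_ingestion(cw, prof)
            q_derm = daily_dose_dermal(cw, prof)
            tox = toxicity[metal]
            hq = q_ing / tox.rfd_drinking + q_derm / tox.rfd_dermal
            if tox.is_carcinogen:
                cr = q_ing * tox.csf_drinking + q_derm * tox.csf_dermal
            else:
                cr = np.full_like(hq, np.nan)
            frames.append(pd.DataFrame({
                "site_id": conc["site_id"].to_numpy(),
                "bank": conc["bank"].to_numpy(),
                "receptor": label,
                "metal": metal,
                "q_ingestion": q_ing,
                "q_dermal": q_derm,
                "hq": hq,
                "cr": cr,
            }))
    long = pd.concat(frames, ignore_index=True)[long_cols]

    grouped = long.groupby(["site_id", "bank", "receptor"], sort=False)
    summary = grouped.agg(hi=("hq", "sum"), cr_total=("cr", lambda s: s.sum(min_count=0))).reset_index()
    summary["cr_total"] = summary["cr_total"].fillna(0.0)
    summary["nc_label"] = np.where(summary["hi"] > 1, "concern", "acceptable")
    for bench in CR_BENCHMARKS:
        summary[f"cr_vs_{bench:g}"] = np.where(summary["cr_total"] > bench, "above", "below")
    return RiskTable(long=long, summary=summary)


# Scale factors used when rendering report tables the way survey papers print
# them (value x 10^-k with two decimals); computation itself is never rounded.
REPORT_SCALES: dict[tuple[str, str], float] = {
    ("HQ", "Ni"): 1e-4, ("HQ", "Zn"): 1e-4, ("HQ", "Cu"): 1e-3, ("HQ", "Pb"): 1e-3,
    ("HQ", "Cd"): 1e-3, ("HQ", "As"): 1e-2, ("HQ", "Cr"): 1e-3,
    ("CR", "Cd"): 1e-7, ("CR", "As"): 1e-5, ("CR", "Cr"): 1e-4,
    ("HI", "all"): 1.0, ("CR_total", "all"): 1e-4,
}


def render_bank_summary(table: RiskTable) -> pd.DataFrame:
    """Bank summary with each row rescaled by its conventional power of ten."""
    out = table.bank_summary()
    if out.empty:
        return out
    scales = [REPORT_SCALES.get((q, m), 1.0) for q, m in zip(out["quantity"], out["metal"])]
    out = out.assign(scale=scales)
    for col in ("min", "mean", "max"):
        out[col + "_scaled"] = (out[col] / out["scale"]).round(2)
    return out
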