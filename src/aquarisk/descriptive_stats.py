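"""Summary statistics, boxplot outlier screening and guideline compliance.

Per-metal descriptive summaries (range, mean +/- SD, median, coefficient of
variation), Tukey 1.5 x IQR outlier counts, and screening of the observed
maxima against named drinking-water / surface-water guideline sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError
from .risk_core import METALS

#: Guideline limits in ug/L; ``None`` marks a standard that sets no limit
#: for that metal.  GB5749-2006 is China's drinking-water standard,
#: GB3838-2002 Class I the surface-water quality class I standard.
DEFAULT_GUIDELINES: dict[str, dict[str, float | None]] = {
    "GB5749-2006": {"Cr": 50, "As": 10, "Cd": 5, "Pb": 10, "Cu": 1000, "Zn": 1000, "Ni": 20},
    "GB3838-2002 Class I": {"Cr": 10, "As": 50, "Cd": 1, "Pb": 10, "Cu": 10, "Zn": 50, "Ni": None},
    "WHO": {"Cr": 50, "As": 10, "Cd": 3, "Pb": 10, "Cu": 2000, "Zn": None, "Ni": 70},
    "US EPA MCL": {"Cr": 100, "As": 10, "Cd": 5, "Pb": 15, "Cu": 1300, "Zn": None, "Ni": None},
}


@dataclass(frozen=True)
class OutlierReport:
    """Boxplot-rule outlier screen for one sample of concentrations."""

    flagged: np.ndarray          # the outlying values
    mask: np.ndarray             # boolean mask into the input
    lower_fence: float
    upper_fence: float
    count: int
    percent: float


def detect_outliers(values: Sequence[float]) -> OutlierReport:
    """Flag values outside the Tukey fences Q1 - 1.5 IQR, Q3 + 1.5 IQR.

    Quartiles use linear interpolation between order statistics.  Requires
    at least 4 values.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        raise DomainError(f"outlier detection needs >= 4 values, got {arr.size}")
    q1, q3 = np.percentile(arr, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    mask = (arr < lo) | (arr > hi)
    count = int(mask.sum())
    return OutlierReport(
        flagged=arr[mask], mask=mask, lower_fence=float(lo), upper_fence=float(hi),
        count=count, percent=100.0 * count / arr.size,
    )


def summarize(conc: pd.DataFrame, metals: Sequence[str] | None = None) -> pd.DataFrame:
    """One summary row per metal: n, min/max, mean, sample SD, median, CV (%),
    and boxplot outlier count/percent.

    SD uses the n-1 denominator; CV = SD/mean x 100.
    """
    if metals is None:
        metals = [m for m in METALS if m in conc.columns]
    if len(conc) < 2:
        raise DomainError("summarize requires at least 2 records")
    rows = []
    for metal in metals:
        x = conc[metal].to_numpy(dtype=float)
        mean = x.mean()
        sd = x.std(ddof=1)
        out = detect_outliers(x) if x.size >= 4 else None
        rows.append({
            "metal": metal,
            "n": x.size,
            "min": x.min(),
            "max": x.max(),
            "mean": mean,
            "sd": sd,
            "median": float(np.median(x)),
            "cv": 100.0 * sd / mean if mean > 0 else np.nan,
            "outlier_count": out.count if out else 0,
            "outlier_percent": out.percent if out else 0.0,
        })
    return pd.DataFrame(rows)


def mean_concentration_order(summary: pd.DataFrame) -> list[str]:
    """Metals sorted by ascending mean concentration."""
    return summary.sort_values("mean")["metal"].tolist()


def screen_against_guidelines(
    summary: pd.DataFrame,
    guidelines: Mapping[str, Mapping[str, float | None]] | None = None,
) -> pd.DataFrame:
    """Compare each metal's observed maximum against each guideline limit.

    Returns one row per metal x standard with the limit, the observed max
    and a status: ``pass`` (max <= limit), ``fail`` (max > limit) or
    ``not-assessed`` where the standard sets no limit.
    """
    if guidelines is None:
        guidelines = DEFAULT_GUIDELINES
    rows = []
    maxima = summary.set_index("metal")["max"]
    for standard, limits in guidelines.items():
        for metal in summary["metal"]:
            limit = limits.get(metal)
            if limit is None:
                status = "not-assessed"
            else:
                status = "pass" if maxima[metal] <= limit else "fail"
            rows.append({
                "metal": metal, "standard": standard,
                "limit_ug_L": limit if limit is not None else np.nan,
                "max_ug_L": maxima[metal], "status": status,
            })
    return pd.DataFrame(rows)


def guidelines_frame(guidelines: Mapping[str, Mapping[str, float | None]] | None = None) -> pd.DataFrame:
    """Guideline set as a metals x standards DataFrame (NaN = no limit)."""
    if guidelines is None:
        guidelines = DEFAULT_GUIDELINES
    return pd.DataFrame(
        {std: {m: (v if v is not None else np.nan) for m, v in limits.items()}
         for std, limits in guidelines.items()}
    ).reindex(list(METALS))
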