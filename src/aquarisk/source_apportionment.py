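"""PCA-based source apportionment with sampling-adequacy diagnostics.

Reproduces the SPSS-style workflow used for heavy-metal source
identification: Kaiser-Meyer-Olkin sampling adequacy, Bartlett's test of
sphericity, principal component extraction from the Pearson correlation
matrix, Kaiser eigenvalue-greater-than-one retention, and varimax rotation
with Kaiser row normalization.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DomainError
from .risk_core import METALS


@dataclass(frozen=True)
class AdequacyReport:
    """KMO and Bartlett sphericity diagnostics for a data matrix.

    ``kmo`` is NaN when indeterminate (all off-diagonal correlations and
    partials zero, e.g. an exactly diagonal correlation matrix).
    """

    kmo: float
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float


@dataclass(frozen=True)
class SourceModel:
    """Retained-component PCA model after varimax rotation."""

    eigenvalues: np.ndarray              # all p eigenvalues, descending
    n_retained: int
    loadings: pd.DataFrame               # unrotated, metals x components
    rotated_loadings: pd.DataFrame       # varimax-rotated, metals x components
    rotation: np.ndarray                 # orthogonal rotation matrix
    variance_contribution: np.ndarray    # % per retained component (post-rotation)
    cumulative_contribution: np.ndarray  # non-decreasing cumulative %
    unrotated_contribution: np.ndarray   # eigenvalue / p * 100 per retained comp.

    @property
    def communalities(self) -> pd.Series:
        return (self.rotated_loadings ** 2).sum(axis=1)


def _data_matrix(data: pd.DataFrame, metals=None) -> tuple[np.ndarray, list[str]]:
    if metals is None:
        metals = [m for m in METALS if m in data.columns]
        if not metals:
            metals = [c for c in data.columns if pd.api.types.is_numeric_dtype(data[c])
                      and c != "position"]
    x = data[list(metals)].to_numpy(dtype=float)
    return x, list(metals)


def _correlation(x: np.ndarray) -> np.ndarray:
    if np.any(x.std(axis=0) == 0):
        raise DomainError("constant columns have no defined correlation")
    return np.corrcoef(x, rowvar=False)


def kmo_statistic(data: pd.DataFrame, metals=None) -> float:
    """Overall Kaiser-Meyer-Olkin measure of sampling adequacy.

    KMO = sum r_ij^2 / (sum r_ij^2 + sum a_ij^2) over i != j, where r are
    Pearson correlations and a the anti-image partial correlations obtained
    from the inverse correlation matrix.  Values above ~0.7 indicate the
    correlation structure is suitable for factor extraction.  Returns NaN
    for an exactly diagonal correlation matrix (0/0).
    """
    x, metals = _data_matrix(data, metals)
    r = _correlation(x)
    try:
        rinv = np.linalg.inv(r)
    except np.linalg.LinAlgError as err:
        cols = [metals[i] for i in range(len(metals))]
        raise DomainError(f"singular correlation matrix; check collinear columns {cols}") from err
    d = np.sqrt(np.diag(rinv))
    partial = -rinv / np.outer(d, d)
    off = ~np.eye(len(metals), dtype=bool)
    r2 = (r[off] ** 2).sum()
    a2 = (partial[off] ** 2).sum()
    if r2 + a2 < 1e-12:  # exactly diagonal R up to float noise: 0/0
        return float("nan")
    return float(r2 / (r2 + a2))


def bartlett_sphericity(data: pd.DataFrame, metals=None) -> tuple[float, int, float]:
    """Bartlett's test that the correlation matrix is the identity.

    chi2 = -(n - 1 - (2p + 5)/6) * ln|R| with df = p(p-1)/2.  Returns
    (statistic, df, p-value).
    """
    x, metals = _data_matrix(data, metals)
    n, p = x.shape
    if n <= p:
        raise DomainError(f"need n > p for Bartlett's test (n={n}, p={p})")
    r = _correlation(x)
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        cond = np.linalg.cond(r)
        raise DomainError(f"|R| <= 0 (condition number {cond:.3g}); Bartlett statistic undefined")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), pval


def adequacy_report(data: pd.DataFrame, metals=None) -> AdequacyReport:
    chi2, df, p = bartlett_sphericity(data, metals)
    return AdequacyReport(kmo=kmo_statistic(data, metals),
                          bartlett_chi2=chi2, bartlett_df=df, bartlett_p=p)


def varimax(loadings: np.ndarray, normalize: bool = True,
            tol: float = 1e-8, max_iter: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation of a loading matrix.

    Iterative SVD-based maximization of the varimax criterion; with
    ``normalize`` (Kaiser normalization) rows are scaled to unit communality
    during rotation, the SPSS convention.  Returns (rotated loadings,
    orthogonal rotation matrix).
    """
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    if k < 2:
        return L, np.eye(k)
    if normalize:
        h = np.sqrt((L ** 2).sum(axis=1))
        h[h == 0] = 1.0
        L = L / h[:, None]
    rot = np.eye(k)
    crit = 0.0
    for _ in range(max_iter):
        lr = L @ rot
        u, s, vt = np.linalg.svd(
            L.T @ (lr ** 3 - lr @ np.diag((lr ** 2).sum(axis=0)) / p)
        )
        rot = u @ vt
        new_crit = s.sum()
        if new_crit < crit * (1 + tol):
            break
        crit = new_crit
    L = L @ rot
    if normalize:
        L = L * h[:, None]
    return L, rot


def pca_varimax(
    data: pd.DataFrame,
    retention: str | int = "kaiser",
    metals=None,
    log_transform: bool = False,
    check_adequacy: bool = True,
) -> SourceModel:
    """Correlation-matrix PCA with Kaiser retention and varimax rotation.

    Parameters
    ----------
    data : pandas.DataFrame
        Concentration table; metal columns are z-scored internally (the
        correlation matrix is used, so raw scales do not matter).
    retention : "kaiser" or int
        Retain eigenvalues > 1 (default) or a fixed component count.
    log_transform : bool
        Apply ``log`` to concentrations before correlation, for strongly
        skewed data.
    check_adequacy : bool
        Run KMO/Bartlett first and warn (not fail) when KMO < 0.5 or the
        Bartlett p-value exceeds 0.05.

    Components are sign-flipped so each column's largest-magnitude loading
    is positive, and ordered by decreasing explained variance.
    """
    x, metals = _data_matrix(data, metals)
    if log_transform:
        if (x <= 0).any():
            raise DomainError("log transform requires strictly positive concentrations")
        x = np.log(x)
    p = len(metals)

    if check_adequacy:
        try:
            rep = adequacy_report(data if not log_transform else
                                  pd.DataFrame(x, columns=metals), metals)
            if not math.isnan(rep.kmo) and rep.kmo < 0.5:
                warnings.warn(f"KMO = {rep.kmo:.3f} < 0.5: sampling adequacy is poor",
                              stacklevel=2)
            if rep.bartlett_p > 0.05:
                warnings.warn(f"Bartlett p = {rep.bartlett_p:.3g}: correlations may be spurious",
                              stacklevel=2)
        except DomainError as err:
            warnings.warn(f"adequacy diagnostics unavailable: {err}", stacklevel=2)

    r = _correlation(x)
    eigval, eigvec = np.linalg.eigh(r)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)

    if retention == "kaiser":
        n_keep = int((eigval > 1.0).sum())
    else:
        n_keep = int(retention)
    if n_keep < 1:
        raise DomainError("component retention selected 0 components")

    load = eigvec[:, :n_keep] * np.sqrt(eigval[:n_keep])
    rotated, rot = varimax(load)

    # order rotated components by explained variance, dominant loading positive
    ss = (rotated ** 2).sum(axis=0)
    order2 = np.argsort(ss)[::-1]
    rotated, rot, ss = rotated[:, order2], rot[:, order2], ss[order2]
    signs = np.sign(rotated[np.abs(rotated).argmax(axis=0), np.arange(n_keep)])
    signs[signs == 0] = 1.0
    rotated = rotated * signs
    rot = rot * signs

    comp_names = [f"PC{i + 1}" for i in range(n_keep)]
    contrib = ss / p * 100.0
    return SourceModel(
        eigenvalues=eigval,
        n_retained=n_keep,
        loadings=pd.DataFrame(load, index=metals, columns=comp_names),
        rotated_loadings=pd.DataFrame(rotated, index=metals, columns=comp_names),
        rotation=rot,
        variance_contribution=contrib,
        cumulative_contribution=np.cumsum(contrib),
        unrotated_contribution=eigval[:n_keep] / p * 100.0,
    )


def dominant_component(model: SourceModel) -> dict[str, str]:
    """Map each variable to the retained component with its largest |loading|."""
    L = model.rotated_loadings
    return {metal: L.columns[np.abs(L.loc[metal].to_numpy()).argmax()] for metal in L.index}


def loadings_table(model: SourceModel) -> pd.DataFrame:
    """Rotated loadings plus eigenvalue / contribution footer rows."""
    out = model.rotated_loadings.copy()
    out.loc["Eigenvalues"] = model.eigenvalues[: model.n_retained]
    out.loc["Variance contribution (%)"] = model.variance_contribution
    out.loc["Cumulative contribution (%)"] = model.cumulative_contribution
    return out
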