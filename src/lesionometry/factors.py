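"""Per-bundle reduction of microstructure metrics to principal-component factors.

Seven bundle-averaged metrics (FA, MD, RD, AFD, RISH0, RISH2, NuFO) are
z-scored and decomposed via the correlation matrix; components with
eigenvalue > 1 are retained and loadings below 0.3 in absolute value are
suppressed for reporting (scores always use the full loadings). The first
component's standardized scores are the factor, with its sign oriented so
that RISH0 loads positively ("higher = healthier"). Sampling adequacy is
checked with the Kaiser-Meyer-Olkin statistic (flagged below 0.7) and
Bartlett's test of sphericity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["FactorModel", "kmo", "bartlett_sphericity", "build_factor"]


def _as_matrix(data) -> np.ndarray:
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be a 2-D (subjects x variables) matrix")
    return X


def _corr(X: np.ndarray) -> np.ndarray:
    if np.any(X.std(axis=0) == 0):
        raise ValueError("zero-variance variable in data matrix")
    return np.corrcoef(X, rowvar=False)


def kmo(data) -> float:
    """Kaiser-Meyer-Olkin measure of sampling adequacy.

    KMO = sum r^2 / (sum r^2 + sum q^2) over the off-diagonal simple
    correlations r and anti-image partial correlations q, where
    q_ij = -Rinv_ij / sqrt(Rinv_ii * Rinv_jj).
    """
    X = _as_matrix(data)
    if X.shape[1] < 3:
        raise ValueError("KMO needs at least 3 variables")
    R = _corr(X)
    if np.linalg.cond(R) > 1e12:
        raise np.linalg.LinAlgError("correlation matrix is singular")
    Rinv = np.linalg.inv(R)
    d = np.sqrt(np.diag(Rinv))
    Q = -Rinv / np.outer(d, d)
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = (R[off] ** 2).sum()
    q2 = (Q[off] ** 2).sum()
    return float(r2 / (r2 + q2))


def bartlett_sphericity(data) -> tuple[float, int, float]:
    """Bartlett's test of sphericity (H0: correlation matrix is identity).

    chi2 = -(n - 1 - (2p + 5) / 6) * ln det(R), df = p (p - 1) / 2.
    """
    X = _as_matrix(data)
    n, p = X.shape
    if n <= p:
        raise ValueError("Bartlett's test requires more subjects than variables")
    R = _corr(X)
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("correlation matrix is not positive definite")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), pval


@dataclass
class FactorModel:
    """PCA factor for one bundle: loadings, eigenvalues, standardized scores
    and the adequacy diagnostics that qualify them."""

    metrics: list
    eigenvalues: np.ndarray
    loadings: np.ndarray            # (p, k) for the k retained components
    suppressed: np.ndarray          # bool (p, k): |loading| < suppress threshold
    scores: np.ndarray              # (n,) standardized first-component scores, NaN where incomplete
    kmo: float
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    n_used: int
    bundle: str | None = None
    complete_case: np.ndarray | None = None
    notes: list = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def reported_loadings(self) -> np.ndarray:
        """Loadings with small coefficients suppressed (NaN) for reporting."""
        out = self.loadings.copy()
        out[self.suppressed] = np.nan
        return out


def build_factor(
    data: pd.DataFrame,
    eigen_threshold: float = 1.0,
    suppress: float = 0.3,
    orient_metric: str = "rish0",
    kmo_min: float = 0.7,
    bartlett_alpha: float = 0.0005,
    bundle: str | None = None,
) -> FactorModel:
    """Build one Tractometry/lesionometry factor from a subjects x metrics table.

    Rows with any missing metric are dropped (complete case; their scores are
    NaN). Adequacy failures (KMO below ``kmo_min``, Bartlett p at or above
    ``bartlett_alpha``) and a second eigenvalue above the retention threshold
    are recorded as warnings, not errors.
    """
    if not isinstance(data, pd.DataFrame):
        data = pd.DataFrame(np.asarray(data, dtype=float))
    metrics = [str(c) for c in data.columns]
    X_all = data.to_numpy(dtype=float)
    complete = np.isfinite(X_all).all(axis=1)
    X = X_all[complete]
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 complete subjects for a factor")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance metric in factor input")
    Z = (X - X.mean(axis=0)) / sd

    notes: list[str] = []
    try:
        kmo_val = kmo(X)
        chi2, df, bart_p = bartlett_sphericity(X)
    except (np.linalg.LinAlgError, ValueError):
        # perfectly collinear metrics: PCA is still defined, adequacy is not
        kmo_val, chi2, df, bart_p = np.nan, np.nan, 0, np.nan
        notes.append("singular correlation matrix: adequacy diagnostics undefined")
        warnings.warn(notes[-1], stacklevel=2)
    if kmo_val < kmo_min:
        notes.append(f"KMO {kmo_val:.3f} below adequacy threshold {kmo_min}")
        warnings.warn(notes[-1], stacklevel=2)
    if bart_p >= bartlett_alpha:
        notes.append(f"Bartlett p {bart_p:.4g} not below {bartlett_alpha}")
        warnings.warn(notes[-1], stacklevel=2)

    R = np.corrcoef(Z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    n_keep = int((eigval > eigen_threshold).sum())
    if n_keep == 0:
        notes.append("no eigenvalue exceeds the retention threshold; keeping component 1")
        warnings.warn(notes[-1], stacklevel=2)
        n_keep = 1
    if n_keep > 1:
        notes.append(
            f"{n_keep} eigenvalues exceed {eigen_threshold}; scores use component 1 only"
        )
        warnings.warn(notes[-1], stacklevel=2)

    vecs = eigvec[:, :n_keep].copy()
    # orientation: the named metric loads positively on each component
    if orient_metric in metrics:
        oi = metrics.index(orient_metric)
    else:
        oi = None
    for k in range(n_keep):
        ref = vecs[oi, k] if oi is not None else vecs[np.abs(vecs[:, k]).argmax(), k]
        if ref < 0:
            vecs[:, k] *= -1
    loadings = vecs * np.sqrt(eigval[:n_keep])
    suppressed = np.abs(loadings) < suppress

    raw = Z @ vecs[:, 0]
    raw = (raw - raw.mean()) / raw.std(ddof=1)
    scores = np.full(len(X_all), np.nan)
    scores[complete] = raw

    return FactorModel(
        metrics=metrics,
        eigenvalues=eigval,
        loadings=loadings,
        suppressed=suppressed,
        scores=scores,
        kmo=kmo_val,
        bartlett_chi2=chi2,
        bartlett_df=df,
        bartlett_p=bart_p,
        n_used=n,
        bundle=bundle,
        complete_case=complete,
        notes=notes,
    )
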