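"""ACE twin variance decomposition for standardized abundance features.

The classical twin design splits trait variance into additive genetic
(A), common/shared environment (C), and unique environment (E) fractions
using the expected twin-pair correlations

    r_MZ = a2 + c2        r_DZ = 0.5 * a2 + c2

(monozygotic co-twins share all segregating additive variance, dizygotic
co-twins half of it; the shared environment is common to every pair).
Features are pre-residualized against covariates (sex, age, phenotype) by
ordinary least squares, then fit by constrained maximum likelihood under a
bivariate normal with unit variances; Falconer's method-of-moments
estimator (clipped to the simplex) serves as starting point and fallback.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "ACEEstimate",
    "residualize",
    "intraclass_correlation",
    "falconer",
    "ace_fit",
    "ace_table",
]


@dataclass
class ACEEstimate:
    feature_id: str
    a2: float
    c2: float
    e2: float
    method: str  # "ml" or "falconer"
    n_mz_pairs: int
    n_dz_pairs: int
    boundary: bool = False  # clipped to the simplex edge


def residualize(values: pd.Series, covariates: pd.DataFrame) -> pd.Series:
    """OLS residuals of a feature against covariates, re-standardized.

    Categorical covariates are dummy-coded; rank-deficient (collinear)
    designs are handled by least squares with a warning. A feature fully
    explained by the covariates degenerates to a zero residual vector,
    returned as zeros with a warning.
    """
    covariates = covariates.loc[values.index]
    X = pd.get_dummies(covariates, drop_first=True, dtype=float)
    X.insert(0, "_intercept", 1.0)
    Xm = X.to_numpy(dtype=float)
    y = values.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        warnings.warn("collinear covariates; using minimum-norm least squares")
    beta, *_ = np.linalg.lstsq(Xm, y, rcond=None)
    resid = y - Xm @ beta
    sd = resid.std(ddof=1)
    if sd <= 1e-12 * max(1.0, np.abs(y).std()):
        warnings.warn(
            f"feature {values.name!r} is fully explained by covariates; "
            "residuals are zero"
        )
        return pd.Series(np.zeros_like(resid), index=values.index, name=values.name)
    resid = (resid - resid.mean()) / sd
    return pd.Series(resid, index=values.index, name=values.name)


def intraclass_correlation(pairs: np.ndarray) -> float:
    """Pairwise (double-entry) intraclass correlation of an (n, 2) array."""
    pairs = np.asarray(pairs, dtype=float)
    x = np.concatenate([pairs[:, 0], pairs[:, 1]])
    y = np.concatenate([pairs[:, 1], pairs[:, 0]])
    vx = x.std()
    if vx == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def falconer(r_mz: float, r_dz: float) -> tuple[float, float, float, bool]:
    """Falconer moments: a2 = 2(r_MZ - r_DZ), c2 = r_MZ - a2, e2 = 1 - r_MZ,
    clipped to the 2-simplex; returns (a2, c2, e2, clipped)."""
    a2 = 2.0 * (r_mz - r_dz)
    c2 = r_mz - a2
    e2 = 1.0 - r_mz
    clipped = a2 < 0 or c2 < 0 or e2 < 0
    a2, c2, e2 = max(a2, 0.0), max(c2, 0.0), max(e2, 0.0)
    total = a2 + c2 + e2
    if total == 0:
        return 0.0, 0.0, 1.0, True
    return a2 / total, c2 / total, e2 / total, clipped


def _pair_nll(params: np.ndarray, mz: np.ndarray, dz: np.ndarray) -> float:
    a2, c2 = params
    nll = 0.0
    for pairs, r in ((mz, a2 + c2), (dz, 0.5 * a2 + c2)):
        r = min(max(r, -0.9999), 0.9999)
        x, y = pairs[:, 0], pairs[:, 1]
        q = (x**2 - 2 * r * x * y + y**2) / (1 - r**2)
        nll += 0.5 * len(pairs) * math.log(1 - r**2) + 0.5 * q.sum()
    return float(nll)


def ace_fit(
    mz_pairs: np.ndarray,
    dz_pairs: np.ndarray,
    feature_id: str = "",
    method: str = "ml",
) -> ACEEstimate:
    """Fit (a2, c2, e2) from standardized MZ and DZ co-twin value pairs.

    ``method='ml'`` maximizes the bivariate-normal likelihood with unit
    variances under the constraints a2, c2 >= 0, a2 + c2 <= 1, falling
    back to clipped Falconer moments if the optimizer fails.
    """
    mz = np.asarray(mz_pairs, dtype=float)
    dz = np.asarray(dz_pairs, dtype=float)
    if mz.ndim != 2 or dz.ndim != 2 or mz.shape[1] != 2 or dz.shape[1] != 2:
        raise ValueError("pair arrays must have shape (n, 2)")
    if len(mz) < 2 or len(dz) < 2:
        raise ValueError("need at least 2 complete pairs of each zygosity")

    r_mz = intraclass_correlation(mz)
    r_dz = intraclass_correlation(dz)
    fa2, fc2, fe2, clipped = falconer(r_mz, r_dz)

    if method == "falconer":
        return ACEEstimate(feature_id, fa2, fc2, fe2, "falconer", len(mz), len(dz), clipped)

    x0 = np.clip([fa2, fc2], 1e-6, 1 - 1e-6)
    if x0.sum() > 1 - 1e-6:
        x0 = x0 / (x0.sum() + 1e-3)
    try:
        res = optimize.minimize(
            _pair_nll,
            x0,
            args=(mz, dz),
            method="SLSQP",
            bounds=[(0.0, 1.0), (0.0, 1.0)],
            constraints=[{"type": "ineq", "fun": lambda p: 1.0 - p[0] - p[1]}],
            options={"maxiter": 200, "ftol": 1e-12},
        )
        ok = res.success and np.isfinite(res.fun)
    except (ValueError, FloatingPointError):
        ok = False
    if not ok:
        warnings.warn(f"ML fit failed for {feature_id!r}; using Falconer moments")
        return ACEEstimate(feature_id, fa2, fc2, fe2, "falconer", len(mz), len(dz), clipped)
    a2, c2 = float(res.x[0]), float(res.x[1])
    a2, c2 = max(a2, 0.0), max(c2, 0.0)
    e2 = max(1.0 - a2 - c2, 0.0)
    total = a2 + c2 + e2
    a2, c2, e2 = a2 / total, c2 / total, e2 / total
    boundary = min(a2, c2, e2) < 1e-9
    return ACEEstimate(feature_id, a2, c2, e2, "ml", len(mz), len(dz), boundary)


def _pair_arrays(
    values: pd.Series, metadata: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    mz, dz = [], []
    for pair_id, grp in metadata.groupby("pair_id"):
        if len(grp) != 2:
            continue
        v = values.loc[grp.index].to_numpy()
        if np.isnan(v).any():
            continue
        (mz if grp["zygosity"].iloc[0] == "MZ" else dz).append(v)
    return np.asarray(mz, dtype=float), np.asarray(dz, dtype=float)


def ace_table(
    standardized: pd.DataFrame,
    metadata: pd.DataFrame,
    covariates: tuple[str, ...] = ("sex", "age", "caries"),
    method: str = "ml",
) -> pd.DataFrame:
    """Per-feature ACE estimates for a standardized subjects x features
    matrix, controlling for the listed metadata covariates."""
    meta = metadata.loc[standardized.index]
    cov = meta[list(covariates)] if covariates else None
    rows = []
    for feat in standardized.columns:
        vals = standardized[feat]
        if cov is not None:
            vals = residualize(vals, cov)
        mz, dz = _pair_arrays(vals, meta)
        est = ace_fit(mz, dz, feature_id=feat, method=method)
        rows.append(
            {
                "feature_id": est.feature_id,
                "A": est.a2,
                "C": est.c2,
                "E": est.e2,
                "method": est.method,
                "n_mz_pairs": est.n_mz_pairs,
                "n_dz_pairs": est.n_dz_pairs,
                "boundary": est.boundary,
            }
        )
    return pd.DataFrame(rows).set_index("feature_id")
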