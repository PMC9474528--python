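"""Per-training-fold unsupervised dimensionality reduction.

z-scaling -> Spearman redundancy filtering (|rho| >= 0.95) -> orthogonally
rotated common-factor analysis (maximum likelihood, principal-axis
fallback) on the filtered correlation matrix, with the Kaiser-Meyer-Olkin
sampling-adequacy measure reported. Factor count follows the
one-factor-per-ten-training-subjects rule. Test lesions are projected with
regression (Thomson) scores using training parameters only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "DimredConfig",
    "Scaler",
    "KmoResult",
    "FactorModel",
    "fit_scaler",
    "apply_scaler",
    "redundancy_filter",
    "kmo",
    "fit_factors",
    "factor_scores",
    "label_factors",
    "fit_dimred",
    "transform",
    "n_factors_rule",
]


@dataclass(frozen=True)
class DimredConfig:
    spearman_threshold: float = 0.95
    subjects_per_factor: int = 10
    kmo_min: float = 0.9
    rotation: str = "varimax"
    method: str = "ml"          # 'ml' with principal-axis fallback, or 'pa'

    def __post_init__(self) -> None:
        if not 0 < self.spearman_threshold <= 1:
            raise ValueError("spearman_threshold must be in (0, 1]")
        if self.subjects_per_factor < 1:
            raise ValueError("subjects_per_factor must be >= 1")


def n_factors_rule(n_train: int, subjects_per_factor: int = 10) -> int:
    """floor(n_train / subjects_per_factor), clamped to at least 1."""
    return max(n_train // subjects_per_factor, 1)


# ---------------------------------------------------------------- scaling

@dataclass
class Scaler:
    """Per-feature training mean and population sd (ddof=0).

    With the population denominator the scaled training columns have
    variance exactly 1 ("centred around 0, variance of 1").
    """

    features: list[str]
    mean: np.ndarray
    sd: np.ndarray
    dropped: list[str] = field(default_factory=list)


def fit_scaler(train: pd.DataFrame) -> Scaler:
    """Fit z-scaling on the training fold; zero-variance columns are dropped."""
    if len(train) < 2:
        raise ValueError("need at least 2 training samples")
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    keep = sd > 0
    dropped = list(train.columns[~keep])
    if dropped:
        logger.warning("dropping %d zero-variance feature(s): %s", len(dropped), dropped[:5])
    cols = list(train.columns[keep])
    return Scaler(cols, mean[keep].to_numpy(), sd[keep].to_numpy(), dropped)


def apply_scaler(scaler: Scaler, data: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in scaler.features if c not in data.columns]
    if missing:
        raise KeyError(f"missing features: {missing[:5]}")
    x = data[scaler.features].to_numpy(dtype=np.float64)
    return pd.DataFrame((x - scaler.mean) / scaler.sd, index=data.index, columns=scaler.features)


# ------------------------------------------------------- redundancy filter

def redundancy_filter(scaled: pd.DataFrame, rho: float = 0.95) -> list[str]:
    """Iteratively drop the feature with the most |Spearman| >= rho partners.

    Ties break to the larger mean absolute correlation, then to the lower
    column position. The surviving set has no pair at or above `rho`.
    """
    cols = list(scaled.columns)
    if len(cols) < 2:
        return cols
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns yield NaN rho
        corr, _ = stats.spearmanr(scaled.to_numpy())
    corr = np.atleast_2d(np.abs(np.nan_to_num(corr)))
    np.fill_diagonal(corr, 0.0)
    alive = np.ones(len(cols), dtype=bool)
    while True:
        sub = corr[np.ix_(alive, alive)]
        over = sub >= rho
        if not over.any():
            break
        counts = over.sum(axis=1)
        mean_abs = sub.mean(axis=1)
        alive_idx = np.flatnonzero(alive)
        order = sorted(
            range(len(alive_idx)),
            key=lambda t: (-counts[t], -mean_abs[t], alive_idx[t]),
        )
        alive[alive_idx[order[0]]] = False
    return [c for c, a in zip(cols, alive) if a]


# ------------------------------------------------------------------- KMO

@dataclass(frozen=True)
class KmoResult:
    value: float
    defined: bool = True


def kmo(corr: np.ndarray, ridge_eps: float = 1e-8) -> KmoResult:
    """Kaiser-Meyer-Olkin measure from raw and anti-image partial correlations.

    A diagonal correlation matrix has no off-diagonal correlation at all;
    the measure is then 0/0 and reported as undefined.
    """
    R = np.asarray(corr, dtype=np.float64)
    p = R.shape[0]
    if R.shape != (p, p):
        raise ValueError("correlation matrix must be square")
    off = ~np.eye(p, dtype=bool)
    r2 = float(np.sum(R[off] ** 2))
    if r2 == 0.0:
        return KmoResult(float("nan"), defined=False)
    Rinv = _robust_inverse(R, ridge_eps)
    d = np.sqrt(np.diag(Rinv))
    Q = -Rinv / np.outer(d, d)
    q2 = float(np.sum(Q[off] ** 2))
    return KmoResult(r2 / (r2 + q2), defined=True)


def _robust_inverse(R: np.ndarray, eps: float) -> np.ndarray:
    try:
        return np.linalg.inv(R)
    except np.linalg.LinAlgError:
        logger.warning("correlation matrix singular; ridge-regularising")
        ridge = eps
        for _ in range(40):
            try:
                return np.linalg.inv(R + ridge * np.eye(R.shape[0]))
            except np.linalg.LinAlgError:
                ridge *= 10
        raise np.linalg.LinAlgError("correlation matrix not invertible after ridge")


def _regularise_correlation(R: np.ndarray, min_eig: float = 1e-4) -> tuple[np.ndarray, float]:
    """Shrink toward identity until comfortably positive definite."""
    gamma = 0.0
    lo = float(np.linalg.eigvalsh(R).min())
    while lo < min_eig and gamma < 0.95:
        gamma = 0.05 if gamma == 0.0 else gamma * 1.6
        Rs = (1 - gamma) * R + gamma * np.eye(R.shape[0])
        lo = float(np.linalg.eigvalsh(Rs).min())
    if gamma > 0:
        logger.info("correlation matrix shrunk toward identity (gamma=%.3f)", gamma)
        return (1 - gamma) * R + gamma * np.eye(R.shape[0]), gamma
    return R, 0.0


# --------------------------------------------------------- factor analysis

@dataclass
class FactorModel:
    scaler: Scaler
    retained: list[str]
    loadings: np.ndarray          # len(retained) x m, rotated
    m: int
    kmo: KmoResult
    factor_labels: list[str]
    score_weights: np.ndarray     # len(retained) x m, regression-score weights
    corr: np.ndarray              # (regularised) training correlation matrix
    ridge_gamma: float = 0.0
    method: str = "ml"


def _ml_uniquenesses(R: np.ndarray, m: int) -> np.ndarray:
    """Maximum-likelihood uniquenesses via the concentrated objective.

    F(psi) = sum_{j>m} (lambda_j - ln lambda_j - 1) of Psi^-1/2 R Psi^-1/2,
    with analytic gradient dF/d(ln psi_i) = -sum_{j>m} (lambda_j - 1) w_ij^2.
    """
    p = R.shape[0]
    smc = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    psi0 = np.clip(1.0 - smc, 0.05, 0.95)

    def fg(theta: np.ndarray):
        psi = np.exp(theta)
        s = 1.0 / np.sqrt(psi)
        sstar = R * np.outer(s, s)
        lam, W = np.linalg.eigh(sstar)
        lam_t, W_t = lam[: p - m], W[:, : p - m]   # smallest p-m eigenvalues
        lam_t = np.maximum(lam_t, 1e-12)
        f = float(np.sum(lam_t - np.log(lam_t) - 1.0))
        g = -np.sum((lam_t - 1.0) * W_t**2, axis=1)
        return f, g

    res = optimize.minimize(
        fg,
        np.log(psi0),
        jac=True,
        method="L-BFGS-B",
        bounds=[(np.log(5e-3), np.log(1.0))] * p,
        options={"maxiter": 200, "ftol": 1e-10},
    )
    if not res.success and res.status != 1:  # status 1 = maxiter reached, still usable
        raise RuntimeError(f"ML factor estimation failed: {res.message}")
    return np.exp(res.x)


def _loadings_from_uniquenesses(R: np.ndarray, psi: np.ndarray, m: int) -> np.ndarray:
    s = 1.0 / np.sqrt(psi)
    sstar = R * np.outer(s, s)
    lam, W = np.linalg.eigh(sstar)
    idx = np.argsort(lam)[::-1][:m]
    lam_m = np.maximum(lam[idx] - 1.0, 0.0)
    return np.sqrt(psi)[:, None] * W[:, idx] * np.sqrt(lam_m)[None, :]


def _principal_axis(R: np.ndarray, m: int, n_iter: int = 100, tol: float = 1e-6) -> np.ndarray:
    smc = 1.0 - 1.0 / np.diag(_robust_inverse(R, 1e-8))
    h2 = np.clip(smc, 0.0, 1.0)
    L = None
    for _ in range(n_iter):
        Ra = R.copy()
        np.fill_diagonal(Ra, h2)
        lam, W = np.linalg.eigh(Ra)
        idx = np.argsort(lam)[::-1][:m]
        L = W[:, idx] * np.sqrt(np.maximum(lam[idx], 0.0))[None, :]
        h2_new = np.clip((L**2).sum(axis=1), 0.0, 1.0)
        if np.max(np.abs(h2_new - h2)) < tol:
            h2 = h2_new
            break
        h2 = h2_new
    return L


def varimax(L: np.ndarray, max_iter: int = 200, tol: float = 1e-10) -> np.ndarray:
    """Varimax rotation with Kaiser row normalisation."""
    p, m = L.shape
    if m == 1:
        return L.copy()
    h = np.sqrt((L**2).sum(axis=1))
    h[h == 0] = 1.0
    A = L / h[:, None]
    Rot = np.eye(m)
    d = 0.0
    for _ in range(max_iter):
        B = A @ Rot
        u, s, vt = np.linalg.svd(A.T @ (B**3 - B @ np.diag((B**2).sum(axis=0)) / p))
        Rot = u @ vt
        d_new = s.sum()
        if d_new <= d * (1.0 + tol):
            break
        d = d_new
    return (A @ Rot) * h[:, None]


def _order_and_sign(L: np.ndarray) -> np.ndarray:
    """Columns by explained variance descending; largest |loading| positive."""
    order = np.argsort(-(L**2).sum(axis=0), kind="stable")
    L = L[:, order]
    for j in range(L.shape[1]):
        k = int(np.argmax(np.abs(L[:, j])))
        if L[k, j] < 0:
            L[:, j] = -L[:, j]
    return L


def fit_factors(
    scaled: pd.DataFrame,
    m: int,
    method: str = "ml",
    rotation: str = "varimax",
) -> tuple[np.ndarray, np.ndarray, float]:
    """Fit the common-factor model on the correlation matrix of `scaled`.

    Returns ``(rotated loadings, regularised correlation matrix, gamma)``.
    """
    p = scaled.shape[1]
    if m < 1:
        raise ValueError("need at least one factor")
    if p == 1:
        return np.ones((1, 1)), np.ones((1, 1)), 0.0
    m = min(m, p - 1)
    R = np.corrcoef(scaled.to_numpy(), rowvar=False)
    R, gamma = _regularise_correlation(R)
    L = None
    if method == "ml":
        try:
            psi = _ml_uniquenesses(R, m)
            L = _loadings_from_uniquenesses(R, psi, m)
        except (RuntimeError, np.linalg.LinAlgError) as exc:
            logger.warning("ML factor fit failed (%s); falling back to principal axis", exc)
    if L is None:
        L = _principal_axis(R, m)
    if rotation == "varimax":
        L = varimax(L)
    elif rotation not in (None, "none"):
        raise ValueError(f"unknown rotation {rotation!r}")
    return _order_and_sign(L), R, gamma


def factor_scores(model: "FactorModel", scaled: pd.DataFrame) -> pd.DataFrame:
    """Regression (Thomson) scores: S = Z R^-1 Lambda, train and test alike."""
    missing = [c for c in model.retained if c not in scaled.columns]
    if missing:
        raise KeyError(f"missing features: {missing[:5]}")
    Z = scaled[model.retained].to_numpy(dtype=np.float64)
    S = Z @ model.score_weights
    cols = [f"factor{j + 1}" for j in range(model.m)]
    return pd.DataFrame(S, index=scaled.index, columns=cols)


def label_factors(retained: list[str], loadings: np.ndarray) -> list[str]:
    """Per factor, the feature with the largest |loading| (ties: first)."""
    return [retained[int(np.argmax(np.abs(loadings[:, j])))] for j in range(loadings.shape[1])]


def fit_dimred(train: pd.DataFrame, config: DimredConfig | None = None) -> FactorModel:
    """Scale -> filter -> factor-analyse one training fold."""
    config = config or DimredConfig()
    scaler = fit_scaler(train)
    z = apply_scaler(scaler, train)
    retained = redundancy_filter(z, config.spearman_threshold)
    m = n_factors_rule(len(train), config.subjects_per_factor)
    zr = z[retained]
    L, R, gamma = fit_factors(zr, m, config.method, config.rotation)
    m_eff = L.shape[1]
    kmo_res = kmo(R)
    if kmo_res.defined and kmo_res.value < config.kmo_min:
        logger.warning("KMO %.3f below %.2f", kmo_res.value, config.kmo_min)
    weights = _robust_inverse(R, 1e-8) @ L
    return FactorModel(
        scaler=scaler,
        retained=retained,
        loadings=L,
        m=m_eff,
        kmo=kmo_res,
        factor_labels=label_factors(retained, L),
        score_weights=weights,
        corr=R,
        ridge_gamma=gamma,
        method=config.method,
    )


def transform(model: FactorModel, data: pd.DataFrame) -> pd.DataFrame:
    """Project (training or test) lesions onto the training factors."""
    return factor_scores(model, apply_scaler(model.scaler, data))
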