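"""Linear mixed model machinery: REML, BLUP and association scans.

The model is y = Xb + Z u + e with u ~ N(0, K sigma_g^2) and
e ~ N(0, I sigma_e^2).  Variance components are estimated by restricted
maximum likelihood, profiled down to a one-dimensional search over the
heritability h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2) after a single
eigendecomposition of the kinship block of the phenotyped individuals
(the EMMA device): in the rotated basis V is diagonal with weights
h2 * d_i + (1 - h2), so each likelihood evaluation is O(n p).

Genetic values for all individuals, phenotyped or not, follow from the
conditional mean

    u_hat = sigma_g^2 K Z' V^-1 (y - X b),      b = (X'V^-1X)^-1 X'V^-1 y

and, when pseudo-QTN covariates Q are fitted, the predicted genetic value
adds the fixed part: u* = Q q + sigma_g^2 K_w Z' V^-1 (y - Xb - Qq).

Association scans: the GLM scan is per-marker ordinary least squares of y
on [intercept | covariates | dosage] with a two-sided t-test; the MLM
scan whitens by the null-model V (variance components estimated once and
reused for every marker — the P3D shortcut) and reports per-marker Wald
chi-square p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .kinship import KinshipMatrix

__all__ = [
    "VarianceComponents",
    "GwasResult",
    "KinshipEig",
    "fit_variance_components",
    "blup_predict",
    "BlupResult",
    "glm_scan",
    "mlm_scan",
]

H2_BOUNDS = (1e-5, 1.0 - 1e-5)
_PSD_TOL = 1e-6


@dataclass
class VarianceComponents:
    """REML estimates of the genetic and residual variances."""

    sigma_g2: float
    sigma_e2: float
    log_likelihood: float

    @property
    def h2(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else 0.0


@dataclass
class GwasResult:
    """Per-marker association-scan output."""

    p_values: np.ndarray
    effects: np.ndarray
    se: np.ndarray
    kind: str  # "GLM" | "MLM"
    degenerate: np.ndarray = field(default=None)  # type: ignore[assignment]
    fold: tuple[int, int] | None = None  # (repeat, fold) metadata

    def __post_init__(self) -> None:
        self.p_values = np.asarray(self.p_values, dtype=float)
        if self.degenerate is None:
            self.degenerate = np.zeros(self.p_values.size, dtype=bool)
        bad = (self.p_values <= 0) | (self.p_values > 1) | np.isnan(self.p_values)
        if bad.any():
            # keep p-values in (0, 1] — exact zeros break downstream logs
            tiny = np.finfo(float).tiny
            self.p_values = np.clip(np.nan_to_num(self.p_values, nan=1.0), tiny, 1.0)

    def to_frame(self, markers: pd.DataFrame | None = None) -> pd.DataFrame:
        out = pd.DataFrame({"effect": self.effects, "se": self.se, "p": self.p_values})
        if markers is not None:
            out = pd.concat(
                [markers[["id", "chrom", "pos"]].reset_index(drop=True), out], axis=1
            )
        return out


class KinshipEig:
    """Cached eigendecomposition of one kinship block.

    REML fits, BLUP solves and MLM whitening for the same set of
    phenotyped individuals all reuse it, which keeps repeated
    cross-validation fits cheap and numerically consistent.
    """

    def __init__(self, K: np.ndarray):
        K = np.asarray(K, dtype=float)
        if np.abs(K - K.T).max() > 1e-8:
            raise ValueError("kinship block not symmetric")
        d, U = np.linalg.eigh(K)
        scale = max(1.0, float(d.max(initial=0.0)))
        if d.min(initial=0.0) < -_PSD_TOL * scale:
            raise ValueError(
                f"kinship not positive semidefinite (min eigenvalue {d.min():.3e})"
            )
        self.d = np.clip(d, 0.0, None)
        self.U = U

    @property
    def n(self) -> int:
        return self.d.size


def _as_matrix(K) -> np.ndarray:
    return K.values if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)


def _with_intercept(X: np.ndarray | None, n: int) -> np.ndarray:
    if X is None:
        return np.ones((n, 1))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != n:
        X = X.T
    ones = np.ones((n, 1))
    Xf = np.hstack([ones, X])
    # drop columns that duplicate earlier ones (keeps full column rank)
    q, r = np.linalg.qr(Xf)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
    return Xf[:, keep]


def _reml_neg_ll(h2: float, d: np.ndarray, ys: np.ndarray, Xs: np.ndarray, ldXX: float) -> float:
    w = h2 * d + (1.0 - h2)
    Xw = Xs / w[:, None]
    XtWX = Xs.T @ Xw
    sign, ldXWX = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return np.inf
    b = np.linalg.solve(XtWX, Xw.T @ ys)
    r = ys - Xs @ b
    rss = float(np.sum(r * r / w))
    nf = d.size - Xs.shape[1]
    if rss <= 0:
        return np.inf
    sigma_p2 = rss / nf
    ll = -0.5 * (
        nf * np.log(2.0 * np.pi * sigma_p2)
        + nf
        + float(np.sum(np.log(w)))
        + ldXWX
        - ldXX
    )
    return -ll


def fit_variance_components(
    y: np.ndarray,
    K: KinshipMatrix | np.ndarray,
    X: np.ndarray | None = None,
    eig: KinshipEig | None = None,
    grid_points: int = 64,
) -> VarianceComponents:
    """REML variance components by 1-D search over h2.

    ``y`` must be complete and aligned to the rows of ``K``.  A coarse
    grid over h2 brackets the optimum, then bounded Brent refinement; the
    result is deterministic.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 phenotyped individuals for REML")
    if np.isnan(y).any():
        raise ValueError("y must be complete (drop missing records first)")
    if np.ptp(y) == 0:
        raise ValueError("zero phenotypic variance")
    Xf = _with_intercept(X, n)
    if eig is None:
        eig = KinshipEig(_as_matrix(K))
    if eig.n != n:
        raise ValueError("eigendecomposition size does not match y")
    ys = eig.U.T @ y
    Xs = eig.U.T @ Xf
    _, ldXX = np.linalg.slogdet(Xf.T @ Xf)

    # degenerate: y (numerically) in the column space of X
    b_ols, *_ = np.linalg.lstsq(Xf, y, rcond=None)
    rss_ols = float(np.sum((y - Xf @ b_ols) ** 2))
    if rss_ols <= 1e-12 * float(np.sum((y - y.mean()) ** 2) + 1e-300):
        warnings.warn("phenotype lies in the fixed-effect column space; variances ~ 0")
        return VarianceComponents(0.0, 0.0, 0.0)

    grid = np.linspace(H2_BOUNDS[0], H2_BOUNDS[1], grid_points)
    vals = np.array([_reml_neg_ll(h, eig.d, ys, Xs, ldXX) for h in grid])
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid_points - 1)]
    res = optimize.minimize_scalar(
        _reml_neg_ll,
        bounds=(lo, hi),
        args=(eig.d, ys, Xs, ldXX),
        method="bounded",
        options={"xatol": 1e-8},
    )
    h2 = float(res.x) if res.fun <= vals[i] else float(grid[i])
    neg_ll = min(float(res.fun), float(vals[i]))

    w = h2 * eig.d + (1.0 - h2)
    Xw = Xs / w[:, None]
    b = np.linalg.solve(Xs.T @ Xw, Xw.T @ ys)
    r = ys - Xs @ b
    sigma_p2 = float(np.sum(r * r / w)) / (n - Xs.shape[1])
    return VarianceComponents(h2 * sigma_p2, (1.0 - h2) * sigma_p2, -neg_ll)


@dataclass
class BlupResult:
    """BLUP solution: genetic values for every kinship individual."""

    mu: np.ndarray  # predicted genetic value per kinship row (incl. Qq part)
    b: np.ndarray  # fixed-effect estimates for X columns
    q: np.ndarray  # pseudo-QTN effect estimates (empty when no Q)
    random_part: np.ndarray  # K Z' V^-1 residual component alone


def blup_predict(
    y: np.ndarray,
    K: KinshipMatrix | np.ndarray,
    obs_idx: np.ndarray,
    vc: VarianceComponents,
    X: np.ndarray | None = None,
    Q: np.ndarray | None = None,
    eig: KinshipEig | None = None,
) -> BlupResult:
    """Solve for fixed effects and genetic values of all kinship individuals.

    ``y`` holds the phenotypes of rows ``obs_idx`` of ``K`` (the Z
    incidence); ``X`` and ``Q`` are given for *all* kinship rows so that
    the fixed pseudo-QTN part can be predicted for unphenotyped
    individuals too.
    """
    Km = _as_matrix(K)
    n_all = Km.shape[0]
    obs_idx = np.asarray(obs_idx)
    if obs_idx.dtype == bool:
        obs_idx = np.flatnonzero(obs_idx)
    y = np.asarray(y, dtype=float).ravel()
    if y.size != obs_idx.size:
        raise ValueError("y length must match obs_idx")

    X_all = _with_intercept(X, n_all)
    n_q = 0 if Q is None else np.atleast_2d(np.asarray(Q, float)).reshape(n_all, -1).shape[1]
    Q_all = None if Q is None else np.asarray(Q, float).reshape(n_all, n_q)
    F_all = X_all if Q_all is None else np.hstack([X_all, Q_all])
    F_obs = F_all[obs_idx]

    Koo = Km[np.ix_(obs_idx, obs_idx)]
    if eig is None:
        eig = KinshipEig(Koo)
    w = vc.sigma_g2 * eig.d + vc.sigma_e2
    if w.min() <= 0:
        raise np.linalg.LinAlgError(
            f"singular V (condition number ~ {w.max() / max(w.min(), 1e-300):.2e})"
        )

    def v_solve(mat: np.ndarray) -> np.ndarray:
        return eig.U @ ((eig.U.T @ mat) / w[:, None] if mat.ndim == 2 else (eig.U.T @ mat) / w)

    FtVi = F_obs.T @ v_solve(F_obs)
    coef = np.linalg.solve(FtVi, F_obs.T @ v_solve(y))
    resid = y - F_obs @ coef
    random_part = vc.sigma_g2 * (Km[:, obs_idx] @ v_solve(resid))
    b = coef[: F_all.shape[1] - n_q]
    q = coef[F_all.shape[1] - n_q :]
    mu = random_part if Q_all is None else Q_all @ q + random_part
    return BlupResult(mu=mu, b=b, q=q, random_part=random_part)


# ---------------------------------------------------------------------------
# Association scans


def _project_out(X0: np.ndarray, *mats: np.ndarray) -> tuple[np.ndarray, ...]:
    """Residualise each matrix/vector on the column space of X0."""
    Qx, _ = np.linalg.qr(X0)
    return tuple(m - Qx @ (Qx.T @ m) for m in mats)


def glm_scan(
    y: np.ndarray,
    G: np.ndarray,
    covariates: np.ndarray | None = None,
) -> GwasResult:
    """Per-marker OLS of y on [intercept | covariates | dosage], t-test p-values.

    Vectorised across markers through the Frisch-Waugh projection: after
    residualising y and each dosage column on the nuisance design, the
    marker coefficient and its t statistic coincide with those of the
    full OLS fit.
    """
    y = np.asarray(y, dtype=float).ravel()
    G = np.asarray(G, dtype=float)
    n, m = G.shape
    if y.size != n:
        raise ValueError("y length must match genotype rows")
    X0 = _with_intercept(covariates, n)
    p0 = X0.shape[1]
    ry, rG = _project_out(X0, y, G)
    gss = np.einsum("ij,ij->j", rG, rG)
    orig_ss = np.einsum("ij,ij->j", G - G.mean(axis=0), G - G.mean(axis=0))
    degenerate = gss <= 1e-12 * np.maximum(orig_ss, 1.0)
    gss_safe = np.where(degenerate, 1.0, gss)
    beta = (rG.T @ ry) / gss_safe
    df = n - p0 - 1
    rss = np.maximum(float(ry @ ry) - beta**2 * gss_safe, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / df / gss_safe)
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    pvals[degenerate] = 1.0
    beta[degenerate] = 0.0
    se[degenerate] = np.inf
    return GwasResult(pvals, beta, se, kind="GLM", degenerate=degenerate)


def mlm_scan(
    y: np.ndarray,
    G: np.ndarray,
    K: KinshipMatrix | np.ndarray,
    covariates: np.ndarray | None = None,
    vc: VarianceComponents | None = None,
    eig: KinshipEig | None = None,
) -> GwasResult:
    """Mixed-model scan with variance components fixed from the null model.

    Variance components are estimated once without any marker (the P3D
    shortcut), the data are whitened by V^-1/2 in the eigenbasis of K,
    and each marker is tested by a Wald chi-square on its generalised
    least-squares coefficient.
    """
    y = np.asarray(y, dtype=float).ravel()
    G = np.asarray(G, dtype=float)
    n, m = G.shape
    X0 = _with_intercept(covariates, n)
    if eig is None:
        eig = KinshipEig(_as_matrix(K))
    if vc is None:
        vc = fit_variance_components(y, K, X=X0[:, 1:] if X0.shape[1] > 1 else None, eig=eig)
    h2 = vc.h2
    w = h2 * eig.d + (1.0 - h2)
    sw = np.sqrt(w)
    yt = (eig.U.T @ y) / sw
    Xt = (eig.U.T @ X0) / sw[:, None]
    Gt = (eig.U.T @ G) / sw[:, None]
    ry, rG = _project_out(Xt, yt, Gt)
    gss = np.einsum("ij,ij->j", rG, rG)
    orig_ss = np.einsum("ij,ij->j", G - G.mean(axis=0), G - G.mean(axis=0))
    degenerate = (gss <= 1e-12 * np.maximum(orig_ss, 1.0)) | (orig_ss <= 0)
    gss_safe = np.where(degenerate, 1.0, gss)
    beta = (rG.T @ ry) / gss_safe
    sigma_p2 = vc.sigma_g2 + vc.sigma_e2
    if sigma_p2 <= 0:
        raise ValueError("null model has zero total variance")
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma_p2 / gss_safe)
        chi2 = beta**2 * gss_safe / sigma_p2
    pvals = stats.chi2.sf(chi2, df=1)
    pvals[degenerate] = 1.0
    beta[degenerate] = 0.0
    se[degenerate] = np.inf
    return GwasResult(pvals, beta, se, kind="MLM", degenerate=degenerate)
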