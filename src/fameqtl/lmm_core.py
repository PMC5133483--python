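"""REML linear mixed model with a kinship random effect.

Model:  y = X beta + g + eps,   g ~ N(0, sigma_g^2 K),  eps ~ N(0, sigma_e^2 I)

with K = 2*Phi the additive relationship matrix.  Because K is block
diagonal by family it is eigendecomposed once per sample set (one small
symmetric eigenproblem per family) and every response and design column is
rotated into the eigenbasis, where the covariance becomes diagonal:
sigma_e^2 * (gamma * lambda + 1) with gamma = sigma_g^2 / sigma_e^2.  The
REML log-likelihood then profiles out beta (GLS) and sigma_e^2 in closed
form, leaving a one-dimensional optimisation over log(gamma) done by
bounded Brent search.  The rotation is computed once and reused across all
probes, SNPs and permutations — the decisive performance property for the
permutation stage.

Heritability is reported as h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2)
= gamma / (1 + gamma), the narrow-sense fraction of variance attributable
to the polygenic component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar

from .io_formats import ExpressionMatrix, get_logger
from .relatedness import KinshipMatrix

# search range for the variance ratio gamma = sigma_g^2 / sigma_e^2
GAMMA_LO = 1e-6
GAMMA_HI = 1e6
BRENT_XATOL = 1e-8
_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class KinshipEigen:
    """Per-family eigendecomposition of K = 2*Phi, assembled sample-wise.

    ``lam`` concatenates the block eigenvalues; ``rotate`` applies the
    block-diagonal U^T without ever forming the full n x n matrix.
    """

    lam: np.ndarray
    blocks: list[tuple[int, int]]
    U: list[np.ndarray]  # one orthogonal matrix per block

    def rotate(self, M: np.ndarray) -> np.ndarray:
        """U^T @ M, block by block.  M is (n,) or (n, k)."""
        M2 = M[:, None] if M.ndim == 1 else M
        out = np.empty(M2.shape, dtype=float)
        for (a, b), u in zip(self.blocks, self.U):
            out[a:b] = u.T @ M2[a:b]
        return out[:, 0] if M.ndim == 1 else out


def eigen_kinship(kinship: KinshipMatrix) -> KinshipEigen:
    """Eigendecompose K = 2*Phi family block by family block."""
    K = kinship.additive_relationship()
    lam_parts, Us = [], []
    for a, b in kinship.family_blocks:
        w, u = np.linalg.eigh(K[a:b, a:b])
        if w.min() < -1e-8:
            raise ValueError(f"kinship block [{a}:{b}] is not PSD "
                             f"(min eigenvalue {w.min():.3g})")
        lam_parts.append(np.maximum(w, 0.0))
        Us.append(u)
    return KinshipEigen(np.concatenate(lam_parts), list(kinship.family_blocks), Us)


@dataclass
class LmmFit:
    """A single REML fit: fixed effects, variance components, REML loglik."""

    beta: np.ndarray
    se: np.ndarray
    names: list[str]
    sigma_g2: float
    sigma_e2: float
    loglik_reml: float
    converged: bool
    boundary: bool = False

    def coef(self, name: str) -> tuple[float, float]:
        if name not in self.names:
            raise KeyError(f"no coefficient {name!r}; have {self.names}")
        k = self.names.index(name)
        return float(self.beta[k]), float(self.se[k])

    @property
    def h2(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return float(self.sigma_g2 / tot) if tot > 0 else 0.0


def _neg2_reml(log_gamma: float, lam: np.ndarray, Xr: np.ndarray,
               yr: np.ndarray) -> float:
    """-2 * REML log-likelihood profiled over beta and sigma_e^2."""
    gamma = np.exp(log_gamma)
    n, p = Xr.shape
    w = 1.0 / (gamma * lam + 1.0)
    Xw = Xr * w[:, None]
    A = Xr.T @ Xw
    b = Xw.T @ yr
    beta = np.linalg.solve(A, b)
    rss = float(yr @ (w * yr) - b @ beta)
    rss = max(rss, 1e-300)
    sig_e2 = rss / (n - p)
    sign, logdet_A = np.linalg.slogdet(A)
    return ((n - p) * (np.log(sig_e2) + _LOG2PI + 1.0)
            + float(np.sum(np.log(gamma * lam + 1.0))) + logdet_A)


def _gls_at(gamma: float, lam: np.ndarray, Xr: np.ndarray, yr: np.ndarray,
            ) -> tuple[np.ndarray, np.ndarray, float]:
    """GLS beta, se and sigma_e^2 at a fixed variance ratio."""
    n, p = Xr.shape
    w = 1.0 / (gamma * lam + 1.0)
    Xw = Xr * w[:, None]
    A = Xr.T @ Xw
    b = Xw.T @ yr
    Ainv = np.linalg.inv(A)
    beta = Ainv @ b
    rss = float(yr @ (w * yr) - b @ beta)
    sig_e2 = max(rss, 1e-300) / (n - p)
    se = np.sqrt(np.maximum(np.diag(Ainv), 0.0) * sig_e2)
    return beta, se, sig_e2


DEFAULT_NAMES = ["intercept", "age", "sex", "smoking", "pc1", "pc2", "snp"]


def fit_rotated_fast(yr: np.ndarray, Xr: np.ndarray, lam: np.ndarray,
                     ) -> tuple[float, float, float]:
    """Minimal REML fit on pre-rotated data for inner scan loops.

    Skips design validation and name bookkeeping; returns
    (beta_last, se_last, gamma) for the last design column — the SNP (or
    other focal) coefficient.  Identical optimisation to :func:`reml_fit`.
    """
    res = minimize_scalar(_neg2_reml, bounds=(np.log(GAMMA_LO), np.log(GAMMA_HI)),
                          args=(lam, Xr, yr), method="bounded",
                          options={"xatol": BRENT_XATOL})
    gamma = float(np.exp(res.x))
    beta, se, _ = _gls_at(gamma, lam, Xr, yr)
    return float(beta[-1]), float(se[-1]), gamma


def reml_fit(y: np.ndarray, X: np.ndarray, K: KinshipMatrix | None = None,
             eig: KinshipEigen | None = None,
             names: list[str] | None = None,
             rotated: bool = False) -> LmmFit:
    """Fit the mixed model by REML.

    Either a :class:`KinshipMatrix` or a precomputed :class:`KinshipEigen`
    must be given.  With ``rotated=True``, ``y`` and ``X`` are already in
    the eigenbasis and are used as-is.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != y.shape[0]:
        raise ValueError("y and X row counts differ")
    if eig is None:
        if K is None:
            raise ValueError("provide K or eig")
        eig = eigen_kinship(K)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the collinear columns for the error message
        nm = names or [f"x{k}" for k in range(X.shape[1])]
        _, r = np.linalg.qr(X)
        bad = [nm[k] for k in range(X.shape[1]) if abs(r[k, k]) < 1e-10]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")

    yr = y if rotated else eig.rotate(y)
    Xr = X if rotated else eig.rotate(X)
    lam = eig.lam

    res = minimize_scalar(_neg2_reml, bounds=(np.log(GAMMA_LO), np.log(GAMMA_HI)),
                          args=(lam, Xr, yr), method="bounded",
                          options={"xatol": BRENT_XATOL})
    gamma = float(np.exp(res.x))
    boundary = (res.x <= np.log(GAMMA_LO) + 1e-6 or
                res.x >= np.log(GAMMA_HI) - 1e-6)
    beta, se, sig_e2 = _gls_at(gamma, lam, Xr, yr)
    nm = names if names is not None else (
        DEFAULT_NAMES[:X.shape[1]] if X.shape[1] <= len(DEFAULT_NAMES)
        else [f"x{k}" for k in range(X.shape[1])])
    return LmmFit(beta=beta, se=se, names=list(nm),
                  sigma_g2=gamma * sig_e2, sigma_e2=sig_e2,
                  loglik_reml=-0.5 * float(res.fun), converged=bool(res.success),
                  boundary=boundary)


def wald_p(fit: LmmFit, coefficient: str = "snp") -> float:
    """Two-sided Wald p-value: (beta/se)^2 against chi-square(1)."""
    if not fit.converged:
        return float("nan")
    beta, se = fit.coef(coefficient)
    if se <= 0:
        return float("nan")
    return float(stats.chi2.sf((beta / se) ** 2, df=1))


def estimate_h2(y: np.ndarray, X_null: np.ndarray,
                K: KinshipMatrix | None = None,
                eig: KinshipEigen | None = None,
                rotated: bool = False) -> float:
    """Narrow-sense heritability from the SNP-free (covariates-only) model."""
    fit = reml_fit(y, X_null, K=K, eig=eig, rotated=rotated)
    return fit.h2


def pca_covariates(expr: ExpressionMatrix, k: int = 2) -> np.ndarray:
    """Sample scores of the top-k expression principal components.

    The probes x samples matrix is centered per probe and decomposed by SVD;
    scores are the per-sample coordinates on the top-k components.  The sign
    of each component is fixed by making its largest-magnitude probe loading
    positive.  Used as batch-effect covariates (Pc1, Pc2).
    """
    Y = np.asarray(expr.values, float)
    if Y.shape[1] < k + 1:
        raise ValueError(f"need at least {k + 1} samples for {k} components")
    Yc = Y - Y.mean(axis=1, keepdims=True)
    if np.allclose(Yc, 0):
        raise ValueError("expression matrix is constant; PCA undefined")
    U, s, Vt = np.linalg.svd(Yc, full_matrices=False)
    scores = (s[:k, None] * Vt[:k]).T  # samples x k
    for j in range(k):
        lead = np.argmax(np.abs(U[:, j]))
        if U[lead, j] < 0:
            scores[:, j] = -scores[:, j]
    return scores


def normality_scan(expr: ExpressionMatrix, alpha: float = 0.05,
                   ) -> "pd.DataFrame":
    """Shapiro-Wilk normality p per probe with a Bonferroni-significant flag.

    Constant probes are flagged non-testable and excluded from the
    Bonferroni denominator.  Returns a table with columns probe_id,
    shapiro_p, testable, bonferroni_significant.
    """
    import pandas as pd

    Y = np.asarray(expr.values, float)
    if Y.shape[1] < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 samples")
    testable = Y.std(axis=1) > 0
    n_test = int(testable.sum())
    n_const = Y.shape[0] - n_test
    if n_const:
        get_logger().info("normality_scan: %d constant probes not testable", n_const)
    pvals = np.full(Y.shape[0], np.nan)
    for j in np.where(testable)[0]:
        pvals[j] = stats.shapiro(Y[j]).pvalue
    thresh = alpha / max(n_test, 1)
    flags = np.where(testable, pvals < thresh, False)
    return pd.DataFrame({"probe_id": expr.probe_ids, "shapiro_p": pvals,
                         "testable": testable, "bonferroni_significant": flags})
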