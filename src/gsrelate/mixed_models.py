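"""Single-trait animal-model mixed-model equations and REML.

The model is y = Xb + Zg + e with var(g) = K sigma_g^2 (K a genomic or
pedigree relationship matrix over reference *and* test animals) and
var(e) = I sigma_e^2.  Henderson's mixed-model equations

    [ X'X      X'Z           ] [b]   [X'y]
    [ Z'X      Z'Z + K^-1 l  ] [g] = [Z'y],    l = sigma_e^2 / sigma_g^2,

are solved by dense Cholesky factorization; the diagonal of the inverse
coefficient matrix supplies per-animal prediction error variances
PEV_i = sigma_e^2 * C_ii.  Animals without records obtain predictions
purely through their relationships in K.

Variance components are estimated by maximizing the exact restricted
likelihood of the one-random-effect model, profiled to a single variance
ratio via the eigendecomposition of the projected relationship matrix
(the standard spectral trick for one-component REML).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

from ._util import ParameterError
from .relatedness import RelationshipMatrix


@dataclass
class MixedModelSpec:
    """Inputs of one MME solve.

    ``z_indices[r]`` maps record ``r`` to its row in ``K`` (this is the
    incidence matrix Z in index form; test animals simply never appear).
    """

    y: np.ndarray
    X: np.ndarray
    z_indices: np.ndarray
    K: RelationshipMatrix | np.ndarray
    sigma_g2: float
    sigma_e2: float
    ridge: float = 1e-6

    @property
    def K_values(self) -> np.ndarray:
        return self.K.values if isinstance(self.K, RelationshipMatrix) else self.K

    @property
    def K_ids(self) -> np.ndarray:
        if isinstance(self.K, RelationshipMatrix):
            return self.K.ids
        return np.arange(1, self.K_values.shape[0] + 1)

    def dense_Z(self) -> np.ndarray:
        Z = np.zeros((self.y.size, self.K_values.shape[0]))
        Z[np.arange(self.y.size), self.z_indices] = 1.0
        return Z

    def validate(self) -> None:
        y = np.asarray(self.y, float)
        X = np.asarray(self.X, float)
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ParameterError("X must have one row per record")
        if np.asarray(self.z_indices).shape != (y.size,):
            raise ParameterError("z_indices must have one entry per record")
        if self.sigma_g2 <= 0 or self.sigma_e2 <= 0:
            raise ParameterError("variance components must be positive")


@dataclass
class MixedModelFit:
    """MME solutions plus the inverse-coefficient-matrix diagonal."""

    ids: np.ndarray
    b_hat: np.ndarray
    g_hat: np.ndarray
    c_diag: np.ndarray          # genetic block of diag(C^-1)
    lambda_: float
    sigma_g2: float
    sigma_e2: float

    def pev(self) -> np.ndarray:
        return self.sigma_e2 * self.c_diag

    def ebv_of(self, ids) -> np.ndarray:
        lookup = {int(a): i for i, a in enumerate(self.ids)}
        return self.g_hat[[lookup[int(a)] for a in np.asarray(ids).ravel()]]

    def c_diag_of(self, ids) -> np.ndarray:
        lookup = {int(a): i for i, a in enumerate(self.ids)}
        return self.c_diag[[lookup[int(a)] for a in np.asarray(ids).ravel()]]


def solve_mme(spec: MixedModelSpec) -> MixedModelFit:
    """Solve the mixed-model equations exactly (dense).

    Returns fixed-effect solutions, breeding values for every animal in K
    (with or without records) and the exact diagonal of the genetic block
    of the inverse coefficient matrix.
    """
    spec.validate()
    y = np.asarray(spec.y, float)
    X = np.asarray(spec.X, float)
    zi = np.asarray(spec.z_indices, np.int64)
    Kv = spec.K_values
    q = Kv.shape[0]
    p = X.shape[1]
    lam = spec.sigma_e2 / spec.sigma_g2

    Kr = Kv + spec.ridge * np.eye(q)
    try:
        cho = linalg.cho_factor(Kr, lower=True, check_finite=False)
        Kinv = linalg.cho_solve(cho, np.eye(q), check_finite=False)
    except linalg.LinAlgError as e:
        raise linalg.LinAlgError(f"relationship matrix K not positive definite: {e}")

    C = np.empty((p + q, p + q))
    C[:p, :p] = X.T @ X
    XtZ = np.zeros((p, q))
    np.add.at(XtZ.T, zi, X)
    C[:p, p:] = XtZ
    C[p:, :p] = XtZ.T
    ZtZ = np.bincount(zi, minlength=q).astype(float)
    C[p:, p:] = lam * Kinv
    C[p + np.arange(q), p + np.arange(q)] += ZtZ

    rhs = np.empty(p + q)
    rhs[:p] = X.T @ y
    rhs[p:] = np.bincount(zi, weights=y, minlength=q)

    try:
        choC = linalg.cho_factor(C, lower=True, check_finite=False)
    except linalg.LinAlgError as e:
        raise linalg.LinAlgError(f"MME coefficient matrix singular "
                                 f"(fixed-effect block rank-deficient?): {e}")
    sol = linalg.cho_solve(choC, rhs, check_finite=False)
    Cinv = linalg.cho_solve(choC, np.eye(p + q), check_finite=False)
    c_diag = np.diag(Cinv)[p:].copy()

    return MixedModelFit(ids=spec.K_ids, b_hat=sol[:p], g_hat=sol[p:],
                         c_diag=c_diag, lambda_=lam,
                         sigma_g2=spec.sigma_g2, sigma_e2=spec.sigma_e2)


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    loglik: float
    converged: bool
    n_evaluations: int

    @property
    def h2(self) -> float:
        return self.sigma_g2 / (self.sigma_g2 + self.sigma_e2)

    @property
    def lambda_(self) -> float:
        return self.sigma_e2 / self.sigma_g2


def reml_loglik(gamma: float, xi: np.ndarray, eta2: np.ndarray) -> float:
    """Profiled restricted log-likelihood at variance ratio
    gamma = sigma_g^2 / sigma_e^2 (constants dropped)."""
    w = gamma * xi + 1.0
    nq = xi.size
    s2 = float(np.sum(eta2 / w)) / nq
    return -0.5 * (np.sum(np.log(w)) + nq * np.log(s2))


def estimate_variance_components(y: np.ndarray, X: np.ndarray,
                                 K_obs: np.ndarray | RelationshipMatrix,
                                 tol: float = 1e-6,
                                 max_evaluations: int = 200) -> VarianceComponents:
    """REML for y = Xb + g + e with var(g) = K_obs sigma_g^2 over the
    phenotyped animals only.

    The restricted likelihood is profiled to the ratio
    gamma = sigma_g^2/sigma_e^2 using the spectral decomposition of
    S K S (S the projector orthogonal to the fixed effects), then
    maximized over log gamma by a bounded scalar search.  A flat
    likelihood (e.g. K = I, where only the total variance is identified)
    is reported with ``converged=False``.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != y.size:
        X = X.T
    n, p = X.shape
    if n - p < 2:
        raise ParameterError("too few records for REML")
    Kv = K_obs.values if isinstance(K_obs, RelationshipMatrix) else np.asarray(K_obs)
    if Kv.shape != (n, n):
        raise ParameterError("K_obs must match the number of records")

    Q, _ = np.linalg.qr(X)
    S = np.eye(n) - Q @ Q.T
    M = S @ Kv @ S
    M = (M + M.T) / 2.0
    xi_all, U = np.linalg.eigh(M)
    # keep the n-p eigenvectors spanning the complement of col(X)
    keep = np.argsort(xi_all)[p:]
    xi = np.clip(xi_all[keep], 0.0, None)
    eta = U[:, keep].T @ y
    eta2 = eta**2

    lo, hi = -14.0, 14.0
    grid = np.linspace(lo, hi, 57)
    vals = np.array([reml_loglik(np.exp(g), xi, eta2) for g in grid])
    j = int(np.argmax(vals))
    a = grid[max(j - 1, 0)]
    b = grid[min(j + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda lg: -reml_loglik(np.exp(lg), xi, eta2),
        bounds=(a, b), method="bounded",
        options={"xatol": tol, "maxiter": max_evaluations})
    gamma = float(np.exp(res.x))
    ll = reml_loglik(gamma, xi, eta2)

    sigma_e2 = float(np.sum(eta2 / (gamma * xi + 1.0)) / (n - p))
    sigma_g2 = gamma * sigma_e2

    spread = float(vals.max() - vals.min())
    flat = spread < 1e-8 * max(1.0, abs(vals.max()))
    boundary = j in (0, grid.size - 1) and not flat
    if flat or boundary:
        warnings.warn("restricted likelihood flat or maximized at the search "
                      "boundary; variance ratio poorly identified")
    return VarianceComponents(sigma_g2=max(sigma_g2, 1e-12 * sigma_e2),
                              sigma_e2=sigma_e2, loglik=ll,
                              converged=bool(res.success and not flat and not boundary),
                              n_evaluations=int(res.nfev) + grid.size)
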