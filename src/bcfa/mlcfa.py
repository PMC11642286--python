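"""Maximum-likelihood CFA by direct minimisation of the Wishart fit function.

This estimator is fully independent of the Gibbs sampler (different
algorithm, different code path) and serves as a frequentist cross-check: in
the diffuse-prior / moderate-n regime the Bayesian posterior means should
agree closely with the ML estimates.

The model is the plain confirmatory structure (majors only, diagonal
residual covariance, Phi a correlation matrix) and the criterion is

    F_ML(S, Sigma) = ln|Sigma| - ln|S| + tr(S Sigma^-1) - p,

whose n-multiple is the familiar likelihood-ratio chi-square statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .exceptions import MatrixValidityError
from .model import ModelSpec


def ml_fit_function(s: np.ndarray, sigma: np.ndarray) -> float:
    """Evaluate F_ML(S, Sigma) (covariance part, no mean term)."""
    s = np.asarray(s, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    p = s.shape[0]
    sign_s, logdet_s = np.linalg.slogdet(s)
    sign_m, logdet_m = np.linalg.slogdet(sigma)
    if sign_s <= 0 or sign_m <= 0:
        raise MatrixValidityError("S and Sigma must be positive definite")
    return float(logdet_m - logdet_s + np.trace(np.linalg.solve(sigma, s)) - p)


@dataclass
class MlCfaResult:
    loadings: np.ndarray  # (p, m) with zeros off the pattern
    phi: np.ndarray  # (m, m) correlation matrix
    theta_diag: np.ndarray  # (p,)
    fmin: float
    chi_square: float
    n_obs: int
    converged: bool

    def implied_covariance(self) -> np.ndarray:
        sig = self.loadings @ self.phi @ self.loadings.T + np.diag(self.theta_diag)
        return (sig + sig.T) / 2.0


def _unpack(x: np.ndarray, major: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    p, m = major.shape
    n_load = p
    lam = np.zeros((p, m))
    lam[major] = x[:n_load]
    ntri = m * (m - 1) // 2
    l = np.eye(m)
    l[np.tril_indices(m, k=-1)] = x[n_load : n_load + ntri]
    l /= np.linalg.norm(l, axis=1, keepdims=True)
    phi = l @ l.T
    theta = np.exp(x[n_load + ntri :])
    return lam, phi, theta


def fit_ml_cfa(
    s: np.ndarray,
    major: np.ndarray,
    n_obs: int,
    n_starts: int = 3,
    seed: int = 0,
) -> MlCfaResult:
    """Fit a CFA to a sample covariance ``s`` by quasi-Newton minimisation.

    ``major`` is the (p, m) boolean major-loading pattern; factor variances
    are fixed at 1 with Phi parameterised through normalised Cholesky rows,
    and residual variances through their logs.  A few jittered restarts
    guard against local minima.
    """
    s = np.asarray(s, dtype=float)
    major = np.asarray(major, dtype=bool)
    p, m = major.shape
    if s.shape != (p, p):
        raise MatrixValidityError("covariance dimension does not match pattern")
    ntri = m * (m - 1) // 2

    def objective(x: np.ndarray) -> float:
        lam, phi, theta = _unpack(x, major)
        sigma = lam @ phi @ lam.T + np.diag(theta)
        try:
            return ml_fit_function(s, sigma)
        except (MatrixValidityError, np.linalg.LinAlgError):
            return 1e10

    rng = np.random.default_rng(seed)
    x0_base = np.concatenate(
        [np.full(p, 0.7), np.zeros(ntri), np.log(np.full(p, 0.5))]
    )
    best = None
    for start in range(n_starts):
        x0 = x0_base if start == 0 else x0_base + 0.1 * rng.standard_normal(x0_base.size)
        res = minimize(objective, x0, method="L-BFGS-B",
                       options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    lam, phi, theta = _unpack(best.x, major)
    # align signs: summed major loadings positive per factor
    for k in range(m):
        if lam[major[:, k], k].sum() < 0:
            lam[:, k] *= -1
            phi[k, :] *= -1
            phi[:, k] *= -1
            phi[k, k] = 1.0
    return MlCfaResult(
        loadings=lam,
        phi=phi,
        theta_diag=theta,
        fmin=float(best.fun),
        chi_square=float(n_obs * best.fun),
        n_obs=n_obs,
        converged=bool(best.success),
    )


def fit_ml_cfa_spec(data_values: np.ndarray, spec: ModelSpec, seed: int = 0) -> MlCfaResult:
    """Convenience wrapper fitting the spec's major pattern to raw data."""
    y = np.asarray(data_values, dtype=float)
    n = y.shape[0]
    yc = y - y.mean(axis=0)
    s = yc.T @ yc / n
    return fit_ml_cfa(s, spec.pattern.major, n_obs=n, seed=seed)
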