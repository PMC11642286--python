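"""Blocked Gibbs sampler for Bayesian confirmatory factor models.

Updates per iteration, each from its exact full conditional:

1. factor scores eta_i | rest  ~  multivariate normal;
2. intercepts and loadings (free entries of the coefficient matrix) | rest
   ~  joint normal combining the likelihood with the Normal priors;
3. residual covariance Theta | rest  ~  Inverse-Wishart (full Theta) or
   independent inverse-gamma variances (diagonal Theta);
4. factor correlation matrix Phi | rest via an exact parameter-expanded
   Gibbs step (marginal data augmentation): expand Phi to an unconstrained
   covariance W = D Phi D with the scale draw D taken from its conditional
   under W ~ IW(I, m+1), update W conjugately given the rescaled factor
   scores, and project back to a correlation matrix.  The induced prior on
   Phi is the marginally-uniform projected Inverse-Wishart.

Identification: factor variances are fixed at 1 (Phi is a correlation
matrix) and, after every iteration, each factor's loadings/scores are sign-
aligned so the summed major loadings are positive — a relabelling that
leaves the likelihood invariant.

Convergence is monitored with the classic Gelman-Rubin potential scale
reduction (PSR) on the retained second half of each chain; sampling extends
past the minimum iteration count until PSR < 1.1 or the maximum is reached.
A single integer seed determines all chains exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular

from .data import StandardizedMatrix
from .exceptions import InsufficientDataError, ValidationError
from .model import ModelSpec, ResidualIWPrior

logger = logging.getLogger(__name__)

PSR_THRESHOLD = 1.1


# ---------------------------------------------------------------------------
# convergence diagnostics


def potential_scale_reduction(traces: np.ndarray) -> np.ndarray:
    """Classic Gelman-Rubin PSR for multi-chain scalar traces.

    ``traces`` has shape (chains, T) or (chains, T, K).  With W the mean
    within-chain variance and B = T * var(chain means), the pooled variance
    estimate is  var+ = (T-1)/T * W + B/T  and  PSR = sqrt(var+ / W).
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim == 2:
        traces = traces[:, :, None]
        squeeze = True
    else:
        squeeze = False
    c, t = traces.shape[:2]
    if c < 2:
        raise ValidationError("PSR requires at least two chains")
    if t < 2:
        raise ValidationError("PSR requires at least two iterations per chain")
    chain_means = traces.mean(axis=1)  # (C, K)
    w = traces.var(axis=1, ddof=1).mean(axis=0)  # (K,)
    b = t * chain_means.var(axis=0, ddof=1)  # (K,)
    varplus = (t - 1) / t * w + b / t
    with np.errstate(divide="ignore", invalid="ignore"):
        psr = np.sqrt(varplus / w)
    # degenerate traces: no spread within or between chains -> PSR 1
    psr = np.where(w <= 0, np.where(b <= 0, 1.0, np.inf), psr)
    # the (T-1)/T finite-length bias can push the ratio below 1; floor it so
    # identical chains report exactly 1
    psr = np.maximum(psr, 1.0)
    return psr[0] if squeeze and psr.shape == (1,) else psr


@dataclass
class ConvergenceReport:
    converged: bool
    threshold: float
    worst: list[tuple[str, float]]

    @property
    def max_psr(self) -> float:
        return self.worst[0][1] if self.worst else float("nan")


def check_convergence(
    psr: Mapping[str, float] | np.ndarray,
    threshold: float = PSR_THRESHOLD,
    k: int = 5,
) -> ConvergenceReport:
    """True iff every PSR is below ``threshold``; reports the k worst."""
    if isinstance(psr, Mapping):
        items = list(psr.items())
    else:
        arr = np.asarray(psr, dtype=float).ravel()
        items = [(f"param{i}", v) for i, v in enumerate(arr)]
    if not items:
        raise ValidationError("empty PSR set")
    items.sort(key=lambda kv: -kv[1])
    return ConvergenceReport(
        converged=bool(items[0][1] < threshold),
        threshold=threshold,
        worst=items[:k],
    )


# ---------------------------------------------------------------------------
# draw container


@dataclass
class PosteriorDraws:
    """Retained (post burn-in) multi-chain draws of Lambda, Phi, Theta, nu."""

    lam: np.ndarray  # (chains, T, p, m)
    nu: np.ndarray  # (chains, T, p)
    phi: np.ndarray  # (chains, T, m, m)
    theta: np.ndarray  # (chains, T, p, p)
    spec: ModelSpec
    seed: int | None
    n_iterations: int  # total iterations per chain (incl. burn-in)
    psr: dict[str, float]
    converged: bool
    n_obs: int
    prior_only: bool = False

    @property
    def n_chains(self) -> int:
        return self.lam.shape[0]

    @property
    def n_retained(self) -> int:
        return self.lam.shape[1]

    @property
    def n_draws(self) -> int:
        return self.n_chains * self.n_retained

    def flat(self, name: str) -> np.ndarray:
        """Draws of one block pooled across chains: (n_draws, ...)."""
        arr = getattr(self, name)
        return arr.reshape((-1,) + arr.shape[2:])

    def posterior_mean(self) -> dict[str, np.ndarray]:
        return {
            name: self.flat(name).mean(axis=0)
            for name in ("lam", "nu", "phi", "theta")
        }

    def to_frame(self):
        """Pooled draws as a DataFrame with lambda[item,factor]-style columns."""
        import pandas as pd

        names, traces = _monitored_traces(
            self.lam, self.nu, self.phi, self.theta, self.spec
        )
        flat = traces.reshape(-1, traces.shape[-1])
        return pd.DataFrame(flat, columns=names)


def _monitor_names(spec: ModelSpec) -> list[str]:
    items, factors = spec.item_labels, spec.factor_labels
    names: list[str] = []
    mask = spec.free_loading_mask()
    for i in range(spec.p):
        for k in range(spec.m):
            if mask[i, k]:
                names.append(f"lambda[{items[i]},{factors[k]}]")
    names += [f"nu[{it}]" for it in items]
    for j in range(spec.m):
        for k in range(j + 1, spec.m):
            names.append(f"phi[{factors[j]},{factors[k]}]")
    if spec.full_theta:
        for i in range(spec.p):
            for j in range(i, spec.p):
                names.append(f"theta[{items[i]},{items[j]}]")
    else:
        names += [f"theta[{it},{it}]" for it in items]
    return names


def _monitored_traces(
    lam: np.ndarray, nu: np.ndarray, phi: np.ndarray, theta: np.ndarray, spec: ModelSpec
) -> tuple[list[str], np.ndarray]:
    """Stack the free parameters into a (chains, T, K) monitor array."""
    mask = spec.free_loading_mask()
    iu_phi = np.triu_indices(spec.m, k=1)
    blocks = [lam[..., mask], nu]
    if spec.m > 1:
        blocks.append(phi[..., iu_phi[0], iu_phi[1]])
    if spec.full_theta:
        iu_t = np.triu_indices(spec.p, k=0)
        blocks.append(theta[..., iu_t[0], iu_t[1]])
    else:
        di = np.arange(spec.p)
        blocks.append(theta[..., di, di])
    names = _monitor_names(spec)
    if spec.m <= 1:
        names = [n for n in names if not n.startswith("phi[")]
    traces = np.concatenate(blocks, axis=-1)
    assert traces.shape[-1] == len(names)
    return names, traces


# ---------------------------------------------------------------------------
# sampler internals


def _invwishart_rvs(df: float, scale: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """IW(scale, df) draw via the Bartlett decomposition (mean scale/(df-p-1))."""
    p = scale.shape[0]
    # X ~ Wishart(df, scale^-1)  =>  X^-1 ~ IW(scale, df)
    l_inv = solve_triangular(cholesky(scale, lower=True), np.eye(p), lower=True)
    a = np.zeros((p, p))
    idx = np.tril_indices(p, k=-1)
    a[idx] = rng.standard_normal(idx[0].size)
    a[np.arange(p), np.arange(p)] = np.sqrt(rng.chisquare(df - np.arange(p)))
    # chol of Wishart draw: (L_inv' a) with scale^-1 = L_inv' L_inv
    f = l_inv.T @ a
    w = f @ f.T
    cf = cho_factor(w, lower=True)
    out = cho_solve(cf, np.eye(p))
    return (out + out.T) / 2.0


class _ChainState:
    __slots__ = ("lam", "nu", "theta", "phi", "eta", "rng")

    def __init__(self, spec: ModelSpec, n: int, rng: np.random.Generator):
        p, m = spec.p, spec.m
        self.rng = rng
        self.lam = np.zeros((p, m))
        # overdispersed starts so PSR is an honest diagnostic
        self.lam[spec.pattern.major] = 0.7 + 0.4 * rng.uniform(-1, 1, size=p)
        self.nu = 0.1 * rng.standard_normal(p)
        self.theta = np.diag(np.exp(rng.uniform(-1.0, 0.2, size=p)))
        self.phi = np.eye(m)
        self.eta = np.zeros((n, m))


class _GibbsKernel:
    """Precomputed constants + one-iteration transition for a given spec."""

    def __init__(self, spec: ModelSpec, y: np.ndarray):
        self.spec = spec
        self.y = y
        self.n, self.p = y.shape
        self.m = spec.m
        self.q = 1 + self.m
        mask_c = np.zeros((self.q, self.p), dtype=bool)
        mask_c[0, :] = True
        mask_c[1:, :] = spec.free_loading_mask().T
        self.free_idx = np.flatnonzero(mask_c.ravel(order="F"))
        prior_prec = np.zeros((self.q, self.p))
        prior_prec[0, :] = 1.0 / spec.priors.intercept_prior_variance
        lam_prec = np.zeros((self.p, self.m))
        lam_prec[spec.pattern.major] = 1.0 / spec.priors.major_loading_prior_variance
        if spec.estimates_cross:
            v = spec.priors.crossloading_variance
            lam_prec[~spec.pattern.major] = 1.0 / v
        prior_prec[1:, :] = lam_prec.T
        self.prior_prec_free = prior_prec.ravel(order="F")[self.free_idx]
        rp = spec.priors.residual_prior
        if isinstance(rp, ResidualIWPrior):
            self.iw_scale = rp.scale_matrix
            self.iw_df = rp.d
        else:
            self.iw_scale = None
            self.ig_shape = spec.priors.residual_ig_shape
            self.ig_scale = spec.priors.residual_ig_scale

    def step(self, s: _ChainState) -> None:
        n, p, m, q = self.n, self.p, self.m, self.q
        rng = s.rng
        theta_cf = cho_factor(s.theta, lower=True)
        theta_inv = cho_solve(theta_cf, np.eye(p))

        # (1) factor scores
        if n > 0 and m > 0:
            phi_inv = cho_solve(cho_factor(s.phi, lower=True), np.eye(m))
            lt_ti = s.lam.T @ theta_inv  # (m, p)
            prec = phi_inv + lt_ti @ s.lam
            prec = (prec + prec.T) / 2.0
            cov = cho_solve(cho_factor(prec, lower=True), np.eye(m))
            cov = (cov + cov.T) / 2.0
            mean = (self.y - s.nu) @ (cov @ lt_ti).T
            s.eta = mean + rng.standard_normal((n, m)) @ cholesky(cov, lower=True).T

        # (2) intercepts + loadings, joint normal over free entries
        x = np.concatenate([np.ones((n, 1)), s.eta], axis=1)  # (n, q)
        xtx = x.T @ x
        xty = x.T @ self.y
        p_full = np.kron(theta_inv, xtx)
        prec_c = p_full[np.ix_(self.free_idx, self.free_idx)]
        prec_c[np.arange(self.free_idx.size), np.arange(self.free_idx.size)] += (
            self.prior_prec_free
        )
        b = (xty @ theta_inv).ravel(order="F")[self.free_idx]
        lc = cholesky((prec_c + prec_c.T) / 2.0, lower=True)
        mean_c = cho_solve((lc, True), b)
        draw = mean_c + solve_triangular(
            lc.T, rng.standard_normal(self.free_idx.size), lower=False
        )
        cf = np.zeros(q * p)
        cf[self.free_idx] = draw
        c = cf.reshape(q, p, order="F")
        s.nu = c[0].copy()
        s.lam = c[1:].T.copy()

        # (3) residual covariance
        e = self.y - x @ c
        if self.iw_scale is not None:
            scale = self.iw_scale + e.T @ e
            s.theta = _invwishart_rvs(self.iw_df + n, scale, rng)
        else:
            sse = np.einsum("ij,ij->j", e, e)
            shape = self.ig_shape + 0.5 * n
            rate = self.ig_scale + 0.5 * sse
            s.theta = np.diag(rate / rng.gamma(shape, 1.0, size=p))

        # (4) factor correlations via exact parameter expansion
        if m > 1:
            phi_inv = cho_solve(cho_factor(s.phi, lower=True), np.eye(m))
            d2 = np.diag(phi_inv) / (2.0 * rng.gamma((m + 1) / 2.0, 1.0, size=m))
            d = np.sqrt(d2)
            xi = s.eta * d
            w = _invwishart_rvs(m + 1 + n, np.eye(m) + xi.T @ xi, rng)
            sd = np.sqrt(np.diag(w))
            s.phi = w / np.outer(sd, sd)
            np.fill_diagonal(s.phi, 1.0)
            if n > 0:
                s.eta = xi / sd

        # (5) sign alignment: summed major loadings positive per factor
        major = self.spec.pattern.major
        for k in range(m):
            if s.lam[major[:, k], k].sum() < 0:
                s.lam[:, k] *= -1
                s.phi[k, :] *= -1
                s.phi[:, k] *= -1
                s.phi[k, k] = 1.0
                if n > 0:
                    s.eta[:, k] *= -1


# ---------------------------------------------------------------------------
# driver


def run_mcmc(
    spec: ModelSpec,
    data: StandardizedMatrix | None,
    chains: int = 8,
    min_iterations: int = 15000,
    max_iterations: int = 100000,
    seed: int | None = None,
    check_every: int = 1000,
    psr_threshold: float = PSR_THRESHOLD,
    prior_only: bool = False,
) -> PosteriorDraws:
    """Estimate ``spec`` on standardized data by multi-chain blocked Gibbs.

    Chains run for ``min_iterations`` and extend in ``check_every`` blocks
    until every monitored parameter's PSR falls below ``psr_threshold`` or
    ``max_iterations`` is reached; the first half of each chain is discarded
    as burn-in (the diagnostic and the returned draws use the second half).
    Failure to converge is reported via the ``converged`` flag, never an
    exception.  With ``prior_only`` the data terms are switched off and the
    retained draws sample the prior itself.
    """
    if chains < 1:
        raise ValidationError("need at least one chain")
    if min_iterations < 2 or max_iterations < min_iterations:
        raise ValidationError("invalid iteration bounds")
    if prior_only:
        y = np.zeros((0, spec.p))
    else:
        if data is None:
            raise ValidationError("data required unless prior_only")
        y = data.values
        if y.shape[0] < 2:
            raise InsufficientDataError("need at least 2 subjects")
        if y.shape[1] != spec.p:
            raise ValidationError(
                f"data has {y.shape[1]} items but spec expects {spec.p}"
            )
    kernel = _GibbsKernel(spec, y)
    ss = np.random.SeedSequence(seed)
    states = [
        _ChainState(spec, y.shape[0], np.random.default_rng(child))
        for child in ss.spawn(chains)
    ]
    p, m = spec.p, spec.m
    per_chain: list[dict[str, list[np.ndarray]]] = [
        {"lam": [], "nu": [], "phi": [], "theta": []} for _ in range(chains)
    ]

    total = 0
    converged = False
    psr_dict: dict[str, float] = {}
    while True:
        seg = (
            min_iterations
            if total == 0
            else min(check_every, max_iterations - total)
        )
        for c, state in enumerate(states):
            lam_c = np.empty((seg, p, m))
            nu_c = np.empty((seg, p))
            phi_c = np.empty((seg, m, m))
            theta_c = np.empty((seg, p, p))
            for t in range(seg):
                kernel.step(state)
                lam_c[t] = state.lam
                nu_c[t] = state.nu
                phi_c[t] = state.phi
                theta_c[t] = state.theta
            pc = per_chain[c]
            pc["lam"].append(lam_c)
            pc["nu"].append(nu_c)
            pc["phi"].append(phi_c)
            pc["theta"].append(theta_c)
        total += seg

        arrays = {
            name: np.stack([np.concatenate(pc[name]) for pc in per_chain])
            for name in ("lam", "nu", "phi", "theta")
        }
        retained = slice(total // 2, total)
        if chains >= 2:
            names, traces = _monitored_traces(
                arrays["lam"][:, retained],
                arrays["nu"][:, retained],
                arrays["phi"][:, retained],
                arrays["theta"][:, retained],
                spec,
            )
            psr = potential_scale_reduction(traces)
            psr_dict = dict(zip(names, np.atleast_1d(psr)))
            converged = bool(np.max(list(psr_dict.values())) < psr_threshold)
        else:
            converged = False
        if converged or total >= max_iterations:
            break
    if chains >= 2 and not converged and not prior_only:
        logger.warning(
            "PSR did not fall below %.3g after %d iterations (max PSR %.3g)",
            psr_threshold,
            total,
            max(psr_dict.values()) if psr_dict else float("nan"),
        )
    retained = slice(total // 2, total)
    return PosteriorDraws(
        lam=arrays["lam"][:, retained].copy(),
        nu=arrays["nu"][:, retained].copy(),
        phi=arrays["phi"][:, retained].copy(),
        theta=arrays["theta"][:, retained].copy(),
        spec=spec,
        seed=seed,
        n_iterations=total,
        psr=psr_dict,
        # a single chain cannot be diagnosed; only prior sampling is exempt
        converged=converged if chains >= 2 else prior_only,
        n_obs=y.shape[0],
        prior_only=prior_only,
    )


def sample_prior(
    spec: ModelSpec, draws: int = 2000, seed: int | None = None, chains: int = 1
) -> PosteriorDraws:
    """Sample the prior by running the Gibbs kernel with no data.

    The retained draws are exact prior draws: with n = 0 every full
    conditional collapses to the corresponding prior.
    """
    return run_mcmc(
        spec,
        data=None,
        chains=chains,
        min_iterations=2 * draws,
        max_iterations=2 * draws,
        seed=seed,
        prior_only=True,
    )
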