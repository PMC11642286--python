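"""McDonald's omega subscale reliability and standardized-solution reporting.

Omega for a congeneric subscale with loadings lambda_i and residual
variances theta_i is

    omega = (sum lambda)^2 / [ (sum lambda)^2 + sum theta ],

computed from major loadings and item residual variances only (residual
covariances are excluded from the denominator by default; ``include_residual_
covariances`` switches to the omega-total variant for sensitivity checks).
Posterior draws of omega give equal-tailed 95% credible intervals, and
values between 0.70 and 0.95 (inclusive) are labelled good internal
consistency for health questionnaires.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .exceptions import ValidationError
from .gibbs import PosteriorDraws

logger = logging.getLogger(__name__)

OMEGA_GOOD_LOWER = 0.70
OMEGA_GOOD_UPPER = 0.95


def mcdonald_omega(
    loadings: Sequence[float],
    residual_variances: Sequence[float],
    residual_covariance_sum: float = 0.0,
) -> float:
    """Omega from one subscale's major loadings and residual variances."""
    lam = np.asarray(loadings, dtype=float)
    theta = np.asarray(residual_variances, dtype=float)
    if lam.size < 2:
        raise ValidationError("omega needs at least two items")
    if lam.size != theta.size:
        raise ValidationError("one residual variance per loading required")
    if np.any(theta <= 0):
        raise ValidationError("residual variances must be positive")
    common = lam.sum() ** 2
    return float(common / (common + theta.sum() + 2.0 * residual_covariance_sum))


def classify_omega(value: float) -> str:
    """Band label: 'below' (<0.70), 'good' (0.70-0.95 inclusive), 'above'."""
    if value < OMEGA_GOOD_LOWER:
        return "below"
    if value > OMEGA_GOOD_UPPER:
        return "above"
    return "good"


@dataclass
class OmegaEstimate:
    subscale: str
    point: float  # posterior mean
    lower: float  # 2.5th percentile
    upper: float  # 97.5th percentile
    classification: str
    point_estimate: str = "posterior mean"

    def to_dict(self) -> dict:
        return {
            "subscale": self.subscale,
            "omega": self.point,
            "ci95": [self.lower, self.upper],
            "classification": self.classification,
            "point_estimate": self.point_estimate,
        }


def omega_posterior(
    draws: PosteriorDraws,
    subscale_map: Mapping[str, str] | None = None,
    include_residual_covariances: bool = False,
) -> dict[str, OmegaEstimate]:
    """Per-subscale omega posterior mean and equal-tailed 95% interval.

    ``subscale_map`` defaults to grouping items by their major-loading
    factor from the spec.  Each retained draw contributes one omega value
    per subscale.
    """
    spec = draws.spec
    items = list(spec.item_labels)
    if subscale_map is None:
        factor_of_item = {
            items[i]: spec.factor_labels[int(np.argmax(spec.pattern.major[i]))]
            for i in range(spec.p)
        }
    else:
        missing = [it for it in items if it not in subscale_map]
        if missing:
            raise ValidationError(f"items missing from subscale map: {missing}")
        factor_of_item = dict(subscale_map)
    lam = draws.flat("lam")  # (T, p, m)
    theta = draws.flat("theta")  # (T, p, p)
    out: dict[str, OmegaEstimate] = {}
    for k, factor in enumerate(spec.factor_labels):
        rows = [i for i, it in enumerate(items) if factor_of_item[it] == factor]
        if len(rows) < 2:
            raise ValidationError(f"subscale {factor!r} has fewer than two items")
        lam_sub = lam[:, rows, k]  # (T, |rows|)
        theta_diag = theta[:, rows, :][:, :, rows]
        common = lam_sub.sum(axis=1) ** 2
        resid = np.einsum("tii->t", theta_diag)
        if include_residual_covariances:
            resid = theta_diag.sum(axis=(1, 2))
        omegas = common / (common + resid)
        lo, hi = np.percentile(omegas, [2.5, 97.5])
        point = float(omegas.mean())
        out[factor] = OmegaEstimate(
            subscale=factor,
            point=point,
            lower=float(lo),
            upper=float(hi),
            classification=classify_omega(point),
        )
    return out


@dataclass
class StandardizedSolution:
    """Posterior-mean standardized loadings / correlations with 95% CI flags."""

    loadings: np.ndarray  # (p, m) posterior means, standardized
    loadings_lower: np.ndarray
    loadings_upper: np.ndarray
    loading_significant: np.ndarray  # bool, 95% CI excludes zero
    phi: np.ndarray  # (m, m) posterior mean factor correlations
    phi_significant: np.ndarray
    item_labels: tuple[str, ...]
    factor_labels: tuple[str, ...]
    n_skipped_draws: int

    def to_frame(self):
        import pandas as pd

        cols = list(self.factor_labels)
        df = pd.DataFrame(self.loadings, index=list(self.item_labels), columns=cols)
        return df


def standardized_solution(draws: PosteriorDraws) -> StandardizedSolution:
    """Standardize each draw's loadings by its implied indicator variances.

    lambda*_ij = lambda_ij / sqrt((Lambda Phi Lambda' + Theta)_ii); factor
    correlations pass through from Phi.  A parameter is flagged significant
    when its 95% equal-tailed credible interval excludes zero.  Draws with a
    non-positive implied variance (possible far out in a poorly mixing
    chain) are skipped and counted.
    """
    spec = draws.spec
    lam = draws.flat("lam")
    phi = draws.flat("phi")
    theta = draws.flat("theta")
    t_total = lam.shape[0]
    implied_var = (
        np.einsum("tij,tjk,tik->ti", lam, phi, lam)
        + np.einsum("tii->ti", theta)
    )
    ok = np.all(implied_var > 0, axis=1)
    n_skipped = int(t_total - ok.sum())
    if n_skipped:
        logger.info("skipped %d draws with non-PD implied covariance", n_skipped)
    lam_std = lam[ok] / np.sqrt(implied_var[ok])[:, :, None]
    lo, hi = np.percentile(lam_std, [2.5, 97.5], axis=0)
    phi_lo, phi_hi = np.percentile(phi[ok], [2.5, 97.5], axis=0)
    return StandardizedSolution(
        loadings=lam_std.mean(axis=0),
        loadings_lower=lo,
        loadings_upper=hi,
        loading_significant=(lo > 0) | (hi < 0),
        phi=phi[ok].mean(axis=0),
        phi_significant=(phi_lo > 0) | (phi_hi < 0),
        item_labels=spec.item_labels,
        factor_labels=spec.factor_labels,
        n_skipped_draws=n_skipped,
    )
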