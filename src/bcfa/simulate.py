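"""Synthetic Likert/continuous response generation under a linear factor model.

Data are drawn from y = nu + Lambda eta + eps with eta ~ N(0, Phi) and
eps ~ N(0, Theta).  Two presets reproduce the published standardized
solutions of the 12-item PIH validation: the plain four-factor CFA solution
and the BSEM solution with small nonzero cross-loadings.  In both presets
Theta is diagonal with theta_ii = 1 - (Lambda Phi Lambda')_ii so every
indicator has unit implied variance, matching the standardized reporting
scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .data import DEFAULT_ITEM_LABELS, DEFAULT_SUBSCALE_MAP, ResponseMatrix
from .exceptions import MatrixValidityError, ValidationError

FACTOR_LABELS = ("Knowledge", "Partnership", "Management", "Coping")

# Published standardized BSEM solution (cross-loading prior N(0, 0.005),
# residual covariances IW(200 D, 200)); columns K, P, M, C.
LAMBDA_BSEM = np.array(
    [
        [0.831, -0.019, 0.037, 0.013],
        [0.869, 0.024, -0.020, -0.011],
        [-0.040, 0.538, 0.065, -0.060],
        [0.057, 0.772, -0.036, 0.012],
        [0.022, 0.854, -0.072, 0.012],
        [-0.063, 0.604, 0.082, 0.017],
        [0.024, 0.008, 0.906, -0.023],
        [-0.003, 0.009, 0.850, 0.045],
        [0.014, 0.024, 0.067, 0.622],
        [-0.001, -0.026, -0.070, 0.971],
        [-0.003, 0.010, -0.019, 0.915],
        [-0.020, 0.001, 0.101, 0.414],
    ]
)

PHI_BSEM = np.array(
    [
        [1.0, 0.641, 0.409, 0.576],
        [0.641, 1.0, 0.662, 0.641],
        [0.409, 0.662, 1.0, 0.597],
        [0.576, 0.641, 0.597, 1.0],
    ]
)

# Published standardized four-factor CFA solution (exact-zero cross-loadings).
LAMBDA_CFA = np.array(
    [
        [0.916, 0.0, 0.0, 0.0],
        [0.918, 0.0, 0.0, 0.0],
        [0.0, 0.915, 0.0, 0.0],
        [0.0, 0.517, 0.0, 0.0],
        [0.0, 0.551, 0.0, 0.0],
        [0.0, 0.836, 0.0, 0.0],
        [0.0, 0.0, 0.860, 0.0],
        [0.0, 0.0, 0.885, 0.0],
        [0.0, 0.0, 0.0, 0.761],
        [0.0, 0.0, 0.0, 0.950],
        [0.0, 0.0, 0.0, 0.964],
        [0.0, 0.0, 0.0, 0.523],
    ]
)

PHI_CFA = np.array(
    [
        [1.0, 0.275, 0.350, 0.540],
        [0.275, 1.0, 0.842, 0.358],
        [0.350, 0.842, 1.0, 0.609],
        [0.540, 0.358, 0.609, 1.0],
    ]
)


def _check_spd(mat: np.ndarray, name: str, unit_diag: bool = False) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise MatrixValidityError(f"{name} must be square")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise MatrixValidityError(f"{name} must be symmetric")
    if unit_diag and not np.allclose(np.diag(mat), 1.0, atol=1e-10):
        raise MatrixValidityError(f"{name} must have unit diagonal")
    if np.linalg.eigvalsh(mat).min() <= 1e-12:
        raise MatrixValidityError(f"{name} must be positive definite")
    return mat


@dataclass
class GeneratingModel:
    """Population factor model (nu, Lambda, Phi, Theta) used for simulation."""

    nu: np.ndarray
    Lambda: np.ndarray
    Phi: np.ndarray
    Theta: np.ndarray
    item_labels: tuple[str, ...] = DEFAULT_ITEM_LABELS
    factor_labels: tuple[str, ...] = FACTOR_LABELS

    def __post_init__(self) -> None:
        self.nu = np.asarray(self.nu, dtype=float)
        self.Lambda = np.asarray(self.Lambda, dtype=float)
        p, m = self.Lambda.shape
        if self.nu.shape != (p,):
            raise MatrixValidityError("nu must have one intercept per item")
        self.Phi = _check_spd(self.Phi, "Phi", unit_diag=True)
        self.Theta = _check_spd(self.Theta, "Theta")
        if self.Phi.shape != (m, m) or self.Theta.shape != (p, p):
            raise MatrixValidityError("Phi/Theta dimensions inconsistent with Lambda")
        _check_spd(self.implied_covariance(), "implied covariance")

    @property
    def n_items(self) -> int:
        return self.Lambda.shape[0]

    @property
    def n_factors(self) -> int:
        return self.Lambda.shape[1]

    def implied_covariance(self) -> np.ndarray:
        """Sigma = Lambda Phi Lambda' + Theta."""
        sig = self.Lambda @ self.Phi @ self.Lambda.T + self.Theta
        return (sig + sig.T) / 2.0

    @classmethod
    def from_standardized(
        cls,
        Lambda: np.ndarray,
        Phi: np.ndarray,
        Theta: np.ndarray | None = None,
        item_labels: Sequence[str] = DEFAULT_ITEM_LABELS,
        factor_labels: Sequence[str] = FACTOR_LABELS,
    ) -> "GeneratingModel":
        """Build a unit-implied-variance model from standardized loadings.

        When ``Theta`` is omitted it is set diagonal with
        theta_ii = 1 - (Lambda Phi Lambda')_ii.
        """
        Lambda = np.asarray(Lambda, dtype=float)
        common = np.diag(Lambda @ np.asarray(Phi, float) @ Lambda.T)
        if Theta is None:
            resid = 1.0 - common
            if np.any(resid <= 0):
                raise MatrixValidityError(
                    "communality >= 1 for some item; cannot build diagonal Theta"
                )
            Theta = np.diag(resid)
        return cls(
            nu=np.zeros(Lambda.shape[0]),
            Lambda=Lambda,
            Phi=np.asarray(Phi, float),
            Theta=np.asarray(Theta, float),
            item_labels=tuple(item_labels),
            factor_labels=tuple(factor_labels),
        )

    def to_dict(self) -> dict:
        return {
            "nu": self.nu.tolist(),
            "Lambda": self.Lambda.tolist(),
            "Phi": self.Phi.tolist(),
            "Theta": self.Theta.tolist(),
            "item_labels": list(self.item_labels),
            "factor_labels": list(self.factor_labels),
        }


def bsem_generating_model(theta: np.ndarray | None = None) -> GeneratingModel:
    """Preset parameterised from the published BSEM standardized solution.

    Majors and small cross-loadings plus the BSEM factor correlations;
    diagonal Theta completes each indicator to unit implied variance.  An
    explicit ``theta`` (e.g. with small off-diagonals) may be supplied to
    exercise the residual-covariance machinery.
    """
    return GeneratingModel.from_standardized(LAMBDA_BSEM, PHI_BSEM, Theta=theta)


def cfa_generating_model(theta: np.ndarray | None = None) -> GeneratingModel:
    """Preset from the published plain-CFA standardized solution (zero crosses)."""
    return GeneratingModel.from_standardized(LAMBDA_CFA, PHI_CFA, Theta=theta)


def generate_continuous(
    model: GeneratingModel, n: int, seed: int | np.random.SeedSequence
) -> ResponseMatrix:
    """Draw ``n`` independent rows y = nu + Lambda eta + eps.

    The same seed always reproduces the same matrix.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    p, m = model.Lambda.shape
    l_phi = np.linalg.cholesky(model.Phi)
    l_theta = np.linalg.cholesky(model.Theta)
    eta = rng.standard_normal((n, m)) @ l_phi.T
    eps = rng.standard_normal((n, p)) @ l_theta.T
    y = model.nu + eta @ model.Lambda.T + eps
    subscale_map = (
        dict(DEFAULT_SUBSCALE_MAP)
        if tuple(model.item_labels) == DEFAULT_ITEM_LABELS
        else {it: model.factor_labels[int(np.argmax(np.abs(model.Lambda[i])))]
              for i, it in enumerate(model.item_labels)}
    )
    return ResponseMatrix(
        values=y,
        item_labels=model.item_labels,
        subscale_map=subscale_map,
        likert=False,
    )


def discretize_to_likert(
    data: ResponseMatrix,
    categories: int = 8,
    thresholds: str | np.ndarray = "equal-probability",
) -> ResponseMatrix:
    """Map continuous responses to ordered codes 1..categories.

    ``thresholds`` is either ``"equal-probability"`` (per-item empirical
    quantiles at k/categories, so each category holds ~1/categories of the
    sample) or an ``(n_items, categories-1)`` array of strictly increasing
    cut points.
    """
    if categories < 2:
        raise ValidationError("categories must be >= 2")
    y = data.values
    n, p = y.shape
    if isinstance(thresholds, str):
        if thresholds != "equal-probability":
            raise ValidationError(f"unknown threshold rule {thresholds!r}")
        qs = np.arange(1, categories) / categories
        cuts = np.quantile(y, qs, axis=0).T  # (p, categories-1)
    else:
        cuts = np.asarray(thresholds, dtype=float)
        if cuts.shape != (p, categories - 1):
            raise ValidationError(
                f"thresholds must have shape ({p}, {categories - 1})"
            )
    if np.any(np.diff(cuts, axis=1) < 0):
        raise ValidationError("thresholds must be non-decreasing per item")
    codes = np.empty_like(y)
    for j in range(p):
        codes[:, j] = np.searchsorted(cuts[j], y[:, j], side="left") + 1
    return ResponseMatrix(
        values=codes,
        item_labels=data.item_labels,
        scale_min=1,
        scale_max=categories,
        subscale_map=dict(data.subscale_map),
        likert=True,
    )


def write_simulation(
    outdir: str | Path,
    model: GeneratingModel,
    data: ResponseMatrix,
    stem: str = "synthetic",
) -> tuple[Path, Path]:
    """Write the response CSV plus a YAML sidecar of generating parameters."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / f"{stem}.csv"
    data.to_csv(csv_path)
    sidecar = outdir / f"{stem}_params.yaml"
    with open(sidecar, "w") as fh:
        yaml.safe_dump(model.to_dict(), fh, sort_keys=False)
    return csv_path, sidecar
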