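"""Model specification: loading pattern, identification convention, priors.

A spec fixes which loadings are estimated and under which priors:

* major loadings (the hypothesized pattern) get a diffuse Normal(0, 10);
* cross-loadings are either exact zeros (plain CFA) or estimated under an
  informative small-variance Normal(0, v);
* residual covariance Theta is either diagonal (independent inverse-gamma
  variances) or a full matrix under an Inverse-Wishart IW(d*D, d) prior with
  D a diagonal matrix of residual variances from a previously fitted model;
* factors are identified by fixing their variances to 1, so Phi is a
  correlation matrix and reported solutions are on the standardized scale.

Free parameters are counted the way the original software reports them:
majors + estimated crosses + intercepts + residual entries + m(m-1)/2
factor correlations (42 / 78 / 144 for the 12-item, 4-factor ladder).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .data import DEFAULT_ITEM_LABELS, DEFAULT_SUBSCALE_MAP
from .exceptions import PatternError, PriorError
from .simulate import FACTOR_LABELS


@dataclass(frozen=True)
class LoadingPattern:
    """Indicator of hypothesized major loadings (one per item)."""

    major: np.ndarray  # (p, m) boolean
    estimate_cross: bool = False

    def __post_init__(self) -> None:
        major = np.asarray(self.major, dtype=bool)
        object.__setattr__(self, "major", major)
        if major.ndim != 2:
            raise PatternError("pattern must be a 2-D item-by-factor indicator")
        counts = major.sum(axis=1)
        if np.any(counts == 0):
            rows = np.flatnonzero(counts == 0).tolist()
            raise PatternError(f"items with no major loading: {rows}")
        if np.any(counts > 1):
            rows = np.flatnonzero(counts > 1).tolist()
            raise PatternError(f"items with multiple major loadings: {rows}")

    @property
    def p(self) -> int:
        return self.major.shape[0]

    @property
    def m(self) -> int:
        return self.major.shape[1]


def pih_pattern() -> LoadingPattern:
    """The 12-item / 4-factor PIH major-loading pattern."""
    major = np.zeros((12, 4), dtype=bool)
    for i, item in enumerate(DEFAULT_ITEM_LABELS):
        major[i, FACTOR_LABELS.index(DEFAULT_SUBSCALE_MAP[item])] = True
    return LoadingPattern(major=major)


@dataclass(frozen=True)
class ResidualIWPrior:
    """Inverse-Wishart prior IW(d*D, d) on the full residual covariance."""

    d: float
    D: np.ndarray  # diagonal entries (length p)

    def __post_init__(self) -> None:
        object.__setattr__(self, "D", np.asarray(self.D, dtype=float))
        if self.D.ndim != 1 or np.any(self.D <= 0):
            raise PriorError("D must be a positive diagonal (1-D array)")

    @property
    def scale_matrix(self) -> np.ndarray:
        return self.d * np.diag(self.D)

    def prior_mean(self) -> np.ndarray:
        """E[Theta] = d*D / (d - p - 1), finite only when d > p + 1."""
        p = self.D.size
        return self.scale_matrix / (self.d - p - 1)


@dataclass(frozen=True)
class PriorConfig:
    """Prior settings for one model specification.

    ``crossloading_variance`` is ``None`` for exact-zero cross-loadings.
    ``residual_prior`` is ``"diagonal"`` or a :class:`ResidualIWPrior`.
    """

    crossloading_variance: float | None = None
    residual_prior: str | ResidualIWPrior = "diagonal"
    major_loading_prior_variance: float = 10.0
    intercept_prior_variance: float = 10.0
    # weakly-informative IG(shape, scale) on each residual variance when
    # Theta is diagonal (prior mean 0.5 on standardized indicators)
    residual_ig_shape: float = 2.0
    residual_ig_scale: float = 0.5

    def __post_init__(self) -> None:
        if self.crossloading_variance is not None and self.crossloading_variance <= 0:
            raise PriorError("cross-loading prior variance must be positive")
        if self.major_loading_prior_variance <= 0 or self.intercept_prior_variance <= 0:
            raise PriorError("prior variances must be positive")


@dataclass(frozen=True)
class ModelSpec:
    """Loading pattern + priors + identification, ready for estimation."""

    pattern: LoadingPattern
    priors: PriorConfig = field(default_factory=PriorConfig)
    item_labels: tuple[str, ...] = ()
    factor_labels: tuple[str, ...] = ()
    label: str = "CFA"

    def __post_init__(self) -> None:
        p, m = self.pattern.p, self.pattern.m
        items = self.item_labels or tuple(f"item{i}" for i in range(1, p + 1))
        factors = self.factor_labels or tuple(f"factor{k}" for k in range(1, m + 1))
        object.__setattr__(self, "item_labels", tuple(items))
        object.__setattr__(self, "factor_labels", tuple(factors))
        if len(self.item_labels) != p or len(self.factor_labels) != m:
            raise PatternError("label lengths inconsistent with pattern shape")
        rp = self.priors.residual_prior
        if isinstance(rp, ResidualIWPrior):
            if rp.D.size != p:
                raise PriorError("IW diagonal D must have one entry per item")
            if rp.d <= p + 1:
                raise PriorError(
                    f"IW degrees of freedom d={rp.d} must exceed p+1={p + 1} "
                    "for a finite prior mean"
                )
        elif rp != "diagonal":
            raise PriorError(f"unknown residual prior {rp!r}")

    @property
    def p(self) -> int:
        return self.pattern.p

    @property
    def m(self) -> int:
        return self.pattern.m

    @property
    def estimates_cross(self) -> bool:
        return self.pattern.estimate_cross

    @property
    def full_theta(self) -> bool:
        return isinstance(self.priors.residual_prior, ResidualIWPrior)

    def free_loading_mask(self) -> np.ndarray:
        """(p, m) boolean: which loadings are estimated."""
        if self.estimates_cross:
            return np.ones((self.p, self.m), dtype=bool)
        return self.pattern.major.copy()


def build_cfa_spec(
    pattern: LoadingPattern,
    item_labels: Sequence[str] = (),
    factor_labels: Sequence[str] = (),
    label: str = "CFA",
) -> ModelSpec:
    """Plain confirmatory spec: exact-zero crosses, diagonal residuals."""
    pattern = LoadingPattern(major=pattern.major, estimate_cross=False)
    return ModelSpec(
        pattern=pattern,
        priors=PriorConfig(),
        item_labels=tuple(item_labels),
        factor_labels=tuple(factor_labels),
        label=label,
    )


def pih_cfa_spec() -> ModelSpec:
    """CFA spec for the 12-item PIH scale."""
    return build_cfa_spec(
        pih_pattern(), item_labels=DEFAULT_ITEM_LABELS, factor_labels=FACTOR_LABELS
    )


def with_crossloading_priors(spec: ModelSpec, variance: float) -> ModelSpec:
    """Estimate every non-major loading under Normal(0, variance).

    Applying this twice replaces (does not stack) the prior variance.
    """
    if variance <= 0:
        raise PriorError("cross-loading prior variance must be positive")
    pattern = LoadingPattern(major=spec.pattern.major, estimate_cross=True)
    priors = replace(spec.priors, crossloading_variance=float(variance))
    return replace(
        spec, pattern=pattern, priors=priors, label=f"xload N(0, {variance:g})"
    )


def with_residual_covariance_prior(
    spec: ModelSpec, d: float, D: np.ndarray
) -> ModelSpec:
    """Model the full residual covariance under IW(d*D, d)."""
    priors = replace(spec.priors, residual_prior=ResidualIWPrior(d=float(d), D=D))
    return replace(spec, priors=priors, label=f"{spec.label} res corr (d = {d:g})")


def count_free_parameters(spec: ModelSpec) -> int:
    """Free parameters: loadings + intercepts + residuals + factor correlations."""
    p, m = spec.p, spec.m
    n_loadings = int(spec.free_loading_mask().sum())
    n_intercepts = p
    n_residual = p * (p + 1) // 2 if spec.full_theta else p
    n_phi = m * (m - 1) // 2
    return n_loadings + n_intercepts + n_residual + n_phi


def spec_to_dict(spec: ModelSpec) -> dict:
    """Serializable description of a spec (round-trips via spec_from_dict)."""
    rp = spec.priors.residual_prior
    return {
        "major": spec.pattern.major.astype(int).tolist(),
        "estimate_cross": spec.pattern.estimate_cross,
        "crossloading_variance": spec.priors.crossloading_variance,
        "residual_prior": (
            {"d": rp.d, "D": rp.D.tolist()}
            if isinstance(rp, ResidualIWPrior)
            else "diagonal"
        ),
        "major_loading_prior_variance": spec.priors.major_loading_prior_variance,
        "intercept_prior_variance": spec.priors.intercept_prior_variance,
        "residual_ig_shape": spec.priors.residual_ig_shape,
        "residual_ig_scale": spec.priors.residual_ig_scale,
        "item_labels": list(spec.item_labels),
        "factor_labels": list(spec.factor_labels),
        "label": spec.label,
    }


def spec_from_dict(payload: dict) -> ModelSpec:
    rp = payload["residual_prior"]
    residual = (
        "diagonal" if rp == "diagonal" else ResidualIWPrior(d=rp["d"], D=np.array(rp["D"]))
    )
    return ModelSpec(
        pattern=LoadingPattern(
            major=np.array(payload["major"], dtype=bool),
            estimate_cross=payload["estimate_cross"],
        ),
        priors=PriorConfig(
            crossloading_variance=payload["crossloading_variance"],
            residual_prior=residual,
            major_loading_prior_variance=payload["major_loading_prior_variance"],
            intercept_prior_variance=payload["intercept_prior_variance"],
            residual_ig_shape=payload["residual_ig_shape"],
            residual_ig_scale=payload["residual_ig_scale"],
        ),
        item_labels=tuple(payload["item_labels"]),
        factor_labels=tuple(payload["factor_labels"]),
        label=payload["label"],
    )
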