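"""Analytic light-response curve families and their closed-form derived quantities.

Two families are implemented for leaf-level light responses of net CO2
assimilation (A_n) and of PSII electron transport (J, and its carboxylation /
oxygenation components J_C, J_O):

* the nonasymptotic rational ("Ye") curve

      y(I) = alpha * (1 - beta*I) / (1 + gamma*I) * I - r_d

  whose photoinhibition coefficient ``beta`` and light-saturation coefficient
  ``gamma`` give a finite interior maximum and an explicit saturation
  irradiance, and

* the non-rectangular hyperbola ("NH") — the lower root of

      theta*y**2 - (alpha*I + y_max)*y + alpha*I*y_max = 0,   minus r_d,

  which approaches its maximum only asymptotically, so no saturation
  irradiance exists.

All functions are pure, vectorised over irradiance, and keep the closed forms
valid for negative ``gamma`` (observed in field fits) as long as
``beta + gamma > 0`` and the denominator ``1 + gamma*I`` stays positive over
the measured light range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import (
    DomainError,
    InvalidParameterError,
    NoCompensationPointError,
)

__all__ = [
    "YeParams",
    "NHParams",
    "DerivedQuantities",
    "ye_predict",
    "nh_predict",
    "ye_derived",
    "ye_light_compensation",
    "nh_light_compensation",
    "nh_asymptote_gap",
]

# switch thresholds below which the analytic gamma->0 / theta->0 limits are
# used instead of the raw closed forms (cancellation guard)
GAMMA_EPS = 1e-10
THETA_EPS = 1e-10
BETA_EPS = 1e-10


@dataclass(frozen=True)
class YeParams:
    """Coefficients of the nonasymptotic rational curve.

    Parameters
    ----------
    alpha : float
        Initial slope (μmol μmol⁻¹ photons), > 0.
    beta : float
        Photoinhibition coefficient (m² s μmol⁻¹), >= 0.
    gamma : float
        Light-saturation coefficient (m² s μmol⁻¹); may be negative provided
        ``beta + gamma > 0`` and ``1 + gamma*I > 0`` over the light range.
    r_d : float
        Dark respiration rate (μmol m⁻² s⁻¹), >= 0. Zero for electron-flow
        curves (J, J_C, J_O), which carry no offset term.
    """

    alpha: float
    beta: float
    gamma: float
    r_d: float = 0.0

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise InvalidParameterError(f"alpha must be > 0, got {self.alpha}")
        if self.beta < 0:
            raise InvalidParameterError(f"beta must be >= 0, got {self.beta}")
        if not self.beta + self.gamma > 0:
            raise InvalidParameterError(
                f"beta + gamma must be > 0 for a finite interior maximum, "
                f"got {self.beta + self.gamma}"
            )
        if self.r_d < 0:
            raise InvalidParameterError(f"r_d must be >= 0, got {self.r_d}")

    @property
    def domain_limit(self) -> float:
        """Largest irradiance at which the curve is defined (-1/gamma for gamma<0)."""
        return math.inf if self.gamma >= 0 else -1.0 / self.gamma


@dataclass(frozen=True)
class NHParams:
    """Coefficients of the non-rectangular hyperbola.

    ``y_max`` is the asymptote of the *gross* response; the net curve
    approaches ``y_max - r_d``. ``theta`` in (0, 1] is the convexity:
    theta=1 gives the Blackman limiting form min(alpha*I, y_max), theta->0 the
    rectangular hyperbola.
    """

    alpha: float
    theta: float
    y_max: float
    r_d: float = 0.0

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise InvalidParameterError(f"alpha must be > 0, got {self.alpha}")
        if not (0 < self.theta <= 1):
            raise InvalidParameterError(f"theta must be in (0, 1], got {self.theta}")
        if not self.y_max > 0:
            raise InvalidParameterError(f"y_max must be > 0, got {self.y_max}")
        if self.r_d < 0:
            raise InvalidParameterError(f"r_d must be >= 0, got {self.r_d}")


@dataclass(frozen=True)
class DerivedQuantities:
    """Closed-form quantities derived from fitted curve parameters.

    Attributes
    ----------
    y_max : float
        Maximum of the (net) response. For the NH family this is the
        asymptote minus r_d, flagged ``asymptotic`` because it is attained
        only in the I -> inf limit.
    i_sat : float or None
        Saturation irradiance at which the maximum is reached; ``None`` when
        no interior maximum exists (NH family, or Ye with beta = 0).
    i_c : float or None
        Light compensation point; populated only for net-photosynthesis
        curves with r_d > 0.
    asymptotic : bool
        True when ``y_max`` is an asymptote rather than an attained maximum.
    """

    y_max: float
    i_sat: float | None = None
    i_c: float | None = None
    asymptotic: bool = False


def _as_irradiance(i):
    arr = np.asarray(i, dtype=float)
    if np.any(arr < 0):
        raise DomainError("irradiance must be non-negative")
    return arr


def ye_predict(params: YeParams, i) -> np.ndarray | float:
    """Evaluate the nonasymptotic curve alpha*(1-beta*I)*I/(1+gamma*I) - r_d.

    Raises :class:`DomainError` where ``1 + gamma*i <= 0`` (beyond the curve's
    validity window ``I < -1/gamma`` for negative gamma).
    """
    arr = _as_irradiance(i)
    denom = 1.0 + params.gamma * arr
    if np.any(denom <= 0):
        raise DomainError(
            f"curve undefined: 1 + gamma*I <= 0 at some irradiance "
            f"(validity requires I < {params.domain_limit:.6g})"
        )
    out = params.alpha * (1.0 - params.beta * arr) * arr / denom - params.r_d
    return out if out.ndim else float(out)


def nh_predict(params: NHParams, i) -> np.ndarray | float:
    """Evaluate the non-rectangular hyperbola (lower quadratic root) minus r_d.

    The lower root is computed in the cancellation-free product form
    ``2*alpha*I*y_max / (b + sqrt(b^2 - 4*alpha*theta*y_max*I))`` with
    ``b = alpha*I + y_max``, which is exact for theta = 1 (Blackman) and
    remains stable as theta -> 0; below ``THETA_EPS`` the explicit
    rectangular-hyperbola limit is used.
    """
    arr = _as_irradiance(i)
    a, th, ym = params.alpha, params.theta, params.y_max
    if th < THETA_EPS:
        out = a * arr * ym / (a * arr + ym) - params.r_d
        return out if out.ndim else float(out)
    if th == 1.0:
        # Blackman limiting form, exact: roots are alpha*I and y_max
        out = np.minimum(a * arr, ym) - params.r_d
        return out if out.ndim else float(out)
    b = a * arr + ym
    disc = b * b - 4.0 * a * th * ym * arr
    # disc >= (alpha*I - y_max)^2 >= 0 for theta <= 1; clamp tiny negatives
    root = np.sqrt(np.maximum(disc, 0.0))
    out = 2.0 * a * arr * ym / (b + root) - params.r_d
    return out if out.ndim else float(out)


def ye_derived(params: YeParams) -> DerivedQuantities:
    """Closed-form maximum and saturation irradiance of the nonasymptotic curve.

    General case (beta > 0, gamma != 0)::

        i_sat = (sqrt((beta+gamma)/beta) - 1) / gamma
        y_max = alpha * ((sqrt(beta+gamma) - sqrt(beta)) / gamma)**2 - r_d

    Limits: gamma -> 0 gives the parabola values i_sat = 1/(2 beta),
    y_max = alpha/(4 beta) - r_d; beta = 0 (with gamma > 0) gives a saturating
    curve with asymptote alpha/gamma - r_d and no finite i_sat.
    """
    a, b, g, rd = params.alpha, params.beta, params.gamma, params.r_d
    if b + g <= 0:
        raise InvalidParameterError("beta + gamma must be > 0")
    i_c: float | None = None
    if b < BETA_EPS:
        # no photoinhibition: monotone saturating curve, maximum is the asymptote
        derived = DerivedQuantities(
            y_max=a / g - rd, i_sat=None, asymptotic=True
        )
    elif abs(g) < GAMMA_EPS:
        derived = DerivedQuantities(y_max=a / (4.0 * b) - rd, i_sat=1.0 / (2.0 * b))
    else:
        i_sat = (math.sqrt((b + g) / b) - 1.0) / g
        y_max = a * ((math.sqrt(b + g) - math.sqrt(b)) / g) ** 2 - rd
        derived = DerivedQuantities(y_max=y_max, i_sat=i_sat)
    if rd > 0:
        try:
            i_c = ye_light_compensation(params)
        except NoCompensationPointError:
            i_c = None
        derived = DerivedQuantities(
            y_max=derived.y_max,
            i_sat=derived.i_sat,
            i_c=i_c,
            asymptotic=derived.asymptotic,
        )
    return derived


def ye_light_compensation(params: YeParams) -> float:
    """Light compensation point of the net nonasymptotic curve.

    Solves alpha*(1-beta*I)*I/(1+gamma*I) = r_d, i.e. the quadratic
    ``alpha*beta*I^2 - (alpha - r_d*gamma)*I + r_d = 0``, returning the smaller
    positive root (the crossing below saturation). For beta = 0 the equation
    is linear-fractional with solution r_d / (alpha - r_d*gamma).
    """
    a, b, g, rd = params.alpha, params.beta, params.gamma, params.r_d
    if rd <= 0:
        raise DomainError("light compensation point requires r_d > 0")
    lin = a - rd * g
    if b < BETA_EPS:
        if lin <= 0:
            raise NoCompensationPointError(
                "respiration exceeds attainable assimilation (no zero crossing)"
            )
        return rd / lin
    disc = lin * lin - 4.0 * a * b * rd
    if disc < 0 or lin <= 0:
        raise NoCompensationPointError(
            "respiration exceeds attainable assimilation (no positive root)"
        )
    # smaller positive root, product form avoids cancellation: roots multiply
    # to rd/(a*b) and sum to lin/(a*b), both positive here
    return 2.0 * rd / (lin + math.sqrt(disc))


def nh_light_compensation(params: NHParams) -> float:
    """Light compensation point of the net non-rectangular hyperbola.

    Setting the gross lower root equal to r_d gives

        I_c = r_d * (y_max - theta*r_d) / (alpha * (y_max - r_d)),

    valid when y_max > r_d (otherwise the net curve never reaches zero).
    """
    a, th, ym, rd = params.alpha, params.theta, params.y_max, params.r_d
    if rd <= 0:
        raise DomainError("light compensation point requires r_d > 0")
    if ym <= rd:
        raise NoCompensationPointError(
            "asymptote does not exceed respiration (net curve never positive)"
        )
    return rd * (ym - th * rd) / (a * (ym - rd))


def nh_asymptote_gap(params: NHParams, i_max: float) -> float:
    """Gap between the NH asymptote and the gross model value at ``i_max``.

    Quantifies how far the asymptotic maximum exceeds anything the curve
    reaches over the measured range; strictly positive for theta < 1, the
    mechanism by which the NH family overestimates attainable maxima.
    """
    if not i_max > 0:
        raise DomainError("i_max must be > 0")
    gross = nh_predict(params, i_max) + params.r_d
    return params.y_max - float(gross)
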