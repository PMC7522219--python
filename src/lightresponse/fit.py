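"""Per-replicate nonlinear least-squares fitting of light-response curves.

The API follows the model/results convention of statistical modelling
packages: a model object is constructed from one replicate's curve
(:class:`YeModel` or :class:`NHModel`, optionally via ``from_dataframe``),
and ``.fit()`` returns a :class:`FitResult` carrying the coefficient
estimates, asymptotic standard errors, closed-form derived quantities,
goodness of fit and residuals, with ``summary()``, ``predict()`` and
``plot()`` attached. Thin functional wrappers :func:`fit_ye`,
:func:`fit_nh` and :func:`fit_all_replicates` cover scripted use.

Estimation is ordinary (unweighted) least squares via bounded trust-region
``scipy.optimize.least_squares`` with a small deterministic multi-start grid:
both curve families have shallow valleys in (beta, gamma) and (theta, y_max)
respectively, and a single start is not reliable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

from .exceptions import (
    DegenerateVarianceError,
    InsufficientDataError,
    InvalidParameterError,
)
from .models import (
    DerivedQuantities,
    NHParams,
    YeParams,
    NoCompensationPointError,
    nh_light_compensation,
    nh_predict,
    ye_derived,
    ye_predict,
)

__all__ = [
    "LightResponseCurve",
    "FitResult",
    "YeModel",
    "NHModel",
    "fit_ye",
    "fit_nh",
    "goodness_of_fit",
    "fit_all_replicates",
]

ResponseKind = Literal["a_n", "j", "j_c", "j_o"]
RESPONSE_KINDS = ("a_n", "j", "j_c", "j_o")

# optimizer settings: cheap problems, favour reproducibility
_TOL = 1e-10
_MAX_NFEV = 10_000
_MIN_LEVELS = 5


@dataclass(frozen=True)
class LightResponseCurve:
    """Ordered (irradiance, response) measurements for one replicate.

    ``response_kind`` selects the fitted family variant: net photosynthesis
    ("a_n") carries a free (or pinned) respiration offset; the electron-flow
    kinds ("j", "j_c", "j_o") are fitted through the origin with r_d = 0.
    """

    replicate_id: str
    response_kind: ResponseKind
    i: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        i = np.asarray(self.i, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "i", i)
        object.__setattr__(self, "y", y)
        if self.response_kind not in RESPONSE_KINDS:
            raise InvalidParameterError(
                f"response_kind must be one of {RESPONSE_KINDS}, got {self.response_kind!r}"
            )
        if i.shape != y.shape or i.ndim != 1:
            raise InvalidParameterError("i and y must be 1-d arrays of equal length")
        if np.any(i < 0):
            raise InvalidParameterError("irradiances must be non-negative")
        if np.unique(i).size != i.size:
            raise InvalidParameterError("irradiances must be unique")
        if i.size < _MIN_LEVELS:
            raise InsufficientDataError(
                f"need at least {_MIN_LEVELS} distinct irradiance levels, got {i.size}"
            )

    @property
    def n_obs(self) -> int:
        return int(self.i.size)

    def sorted(self) -> "LightResponseCurve":
        """Copy with steps in ascending irradiance."""
        order = np.argsort(self.i)
        return LightResponseCurve(
            self.replicate_id, self.response_kind, self.i[order], self.y[order]
        )


def goodness_of_fit(observed, predicted) -> tuple[float, float, float]:
    """Return (r_squared, sse, sst) with R² = 1 - SSE/SST."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or obs.size < 2:
        raise InsufficientDataError("observed/predicted must be equal-length 1-d, n >= 2")
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0:
        raise DegenerateVarianceError("all observed values are equal; SST = 0")
    sse = float(np.sum((obs - pred) ** 2))
    return 1.0 - sse / sst, sse, sst


@dataclass
class FitResult:
    """Estimates and diagnostics from fitting one replicate curve.

    ``params`` is a :class:`YeParams` or :class:`NHParams`; ``derived`` the
    closed-form maxima / saturation irradiance / compensation point;
    ``param_se`` asymptotic standard errors from the Gauss-Newton
    approximation (None for parameters pinned during fitting, or when the
    information matrix is singular).
    """

    model: Literal["ye", "nh"]
    curve: LightResponseCurve
    params: YeParams | NHParams | None
    derived: DerivedQuantities | None
    r_squared: float = np.nan
    sse: float = np.nan
    sst: float = np.nan
    residuals: np.ndarray | None = None
    converged: bool = False
    n_obs: int = 0
    param_se: dict[str, float] | None = None
    error: str | None = None
    n_starts: int = 0

    @property
    def ok(self) -> bool:
        return self.error is None and self.params is not None

    def predict(self, i) -> np.ndarray | float:
        if self.params is None:
            raise InvalidParameterError("fit failed; no parameters available")
        if self.model == "ye":
            return ye_predict(self.params, i)
        return nh_predict(self.params, i)

    def summary(self) -> str:
        """Plain-text summary table of estimates, SEs and derived quantities."""
        lines = []
        title = f"{'Nonasymptotic (Ye)' if self.model == 'ye' else 'Non-rectangular hyperbola (NH)'} fit"
        lines.append(title)
        lines.append("=" * 58)
        lines.append(
            f"replicate: {self.curve.replicate_id:<12s} response: {self.curve.response_kind}"
        )
        lines.append(
            f"n_obs: {self.n_obs:<4d} converged: {self.converged}   starts: {self.n_starts}"
        )
        if self.error is not None:
            lines.append(f"fit error: {self.error}")
            return "\n".join(lines)
        lines.append("-" * 58)
        lines.append(f"{'coef':>8s} {'estimate':>14s} {'std err':>12s}")
        names = (
            ("alpha", "beta", "gamma", "r_d")
            if self.model == "ye"
            else ("alpha", "theta", "y_max", "r_d")
        )
        for name in names:
            val = getattr(self.params, name)
            se = (self.param_se or {}).get(name)
            se_s = f"{se:12.5g}" if se is not None else f"{'(fixed)':>12s}"
            lines.append(f"{name:>8s} {val:14.6g} {se_s}")
        lines.append("-" * 58)
        d = self.derived
        if d is not None:
            y_tag = "asymptotic max" if d.asymptotic else "maximum"
            lines.append(f"{y_tag:>14s}: {d.y_max:10.4f}")
            if d.i_sat is not None:
                lines.append(f"{'I_sat':>14s}: {d.i_sat:10.2f}")
            if d.i_c is not None:
                lines.append(f"{'I_c':>14s}: {d.i_c:10.2f}")
        lines.append(f"{'R^2':>14s}: {self.r_squared:10.6f}")
        lines.append(f"{'SSE':>14s}: {self.sse:10.5g}")
        return "\n".join(lines)

    def plot(self, ax=None, n_grid: int = 200):
        """Diagnostic plot of data and fitted curve; returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.curve
        ax.plot(c.i, c.y, "o", label="observed")
        grid = np.linspace(0, c.i.max(), n_grid)
        ax.plot(grid, self.predict(grid), "-", label=f"{self.model} fit")
        ax.set_xlabel("irradiance (μmol m$^{-2}$ s$^{-1}$)")
        ax.set_ylabel(c.response_kind)
        ax.legend()
        return ax

    def check_consistency(self) -> float:
        """Recompute R² from stored residuals; returns |difference|."""
        sse = float(np.sum(np.asarray(self.residuals) ** 2))
        return abs(self.r_squared - (1.0 - sse / self.sst))


def _alpha0(curve: LightResponseCurve) -> float:
    """Initial slope from the two lowest-irradiance points."""
    order = np.argsort(curve.i)
    i0, i1 = curve.i[order[0]], curve.i[order[1]]
    y0, y1 = curve.y[order[0]], curve.y[order[1]]
    slope = (y1 - y0) / (i1 - i0)
    return float(np.clip(slope, 1e-4, 1.0))


def _se_from_jac(res, free_names: list[str], n: int) -> dict[str, float] | None:
    p = len(free_names)
    if n <= p:
        return None
    try:
        jtj = res.jac.T @ res.jac
        cov = np.linalg.inv(jtj) * (2.0 * res.cost) / (n - p)
    except np.linalg.LinAlgError:
        return None
    diag = np.diag(cov)
    if np.any(diag < 0):
        return None
    return dict(zip(free_names, np.sqrt(diag)))


class _CurveModel:
    """Shared machinery for the two curve-family models."""

    model_name: Literal["ye", "nh"]

    def __init__(self, curve: LightResponseCurve):
        self.curve = curve

    @classmethod
    def from_dataframe(
        cls,
        df,
        *,
        irradiance: str = "i",
        response: str = "a_n",
        response_kind: ResponseKind | None = None,
        replicate_id: str = "r1",
    ) -> "_CurveModel":
        """Build the model from a tidy per-step DataFrame."""
        kind = response_kind if response_kind is not None else response
        curve = LightResponseCurve(
            replicate_id=replicate_id,
            response_kind=kind,  # type: ignore[arg-type]
            i=df[irradiance].to_numpy(dtype=float),
            y=df[response].to_numpy(dtype=float),
        )
        return cls(curve)

    def fit(self, fix_rd: float | None = None) -> FitResult:
        raise NotImplementedError

    def _minimize(self, residual, starts, lower, upper, free_names):
        best = None
        n_starts = 0
        for x0 in starts:
            x0 = np.clip(x0, lower + 1e-12, upper - 1e-12 * np.abs(upper))
            n_starts += 1
            try:
                res = least_squares(
                    residual,
                    x0,
                    bounds=(lower, upper),
                    method="trf",
                    xtol=_TOL,
                    ftol=_TOL,
                    gtol=_TOL,
                    max_nfev=_MAX_NFEV,
                )
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
        return best, n_starts

    def _finalize(self, params, best, free_names, n_starts) -> FitResult:
        curve = self.curve
        pred = (
            ye_predict(params, curve.i)
            if self.model_name == "ye"
            else nh_predict(params, curve.i)
        )
        r2, sse, sst = goodness_of_fit(curve.y, pred)
        if self.model_name == "ye":
            derived = ye_derived(params)
        else:
            i_c = None
            if params.r_d > 0:
                try:
                    i_c = nh_light_compensation(params)
                except NoCompensationPointError:
                    i_c = None
            derived = DerivedQuantities(
                y_max=params.y_max - params.r_d, i_sat=None, i_c=i_c, asymptotic=True
            )
        return FitResult(
            model=self.model_name,
            curve=curve,
            params=params,
            derived=derived,
            r_squared=r2,
            sse=sse,
            sst=sst,
            residuals=np.asarray(curve.y - pred),
            converged=bool(best.status > 0),
            n_obs=curve.n_obs,
            param_se=_se_from_jac(best, free_names, curve.n_obs),
            n_starts=n_starts,
        )


class YeModel(_CurveModel):
    """Nonasymptotic rational light-response model for one replicate curve.

    For net-photosynthesis curves the respiration offset r_d is a free
    parameter unless pinned with ``fit(fix_rd=...)`` (e.g. to the measured
    gas exchange at I = 0); electron-flow curves are fitted with r_d = 0.
    """

    model_name = "ye"

    # deterministic multi-start grid over the shallow (beta, gamma) valley
    GAMMA_STARTS = (-1e-4, 1e-5, 5e-4, 2e-3)
    BETA_START = 1e-4

    def fit(self, fix_rd: float | None = None) -> FitResult:
        curve = self.curve
        i, y = curve.i, curve.y
        i_max = float(i.max())
        free_rd = curve.response_kind == "a_n" and fix_rd is None
        rd_fixed = 0.0 if curve.response_kind != "a_n" else (fix_rd or 0.0)

        gamma_lo = -1.0 / (1.05 * i_max)  # keeps 1 + gamma*I > 0 over the data
        a0 = _alpha0(curve)
        rd0 = 1.0
        if curve.response_kind == "a_n":
            at_zero = y[i == 0]
            rd0 = float(np.clip(-at_zero[0], 0.01, 19.9)) if at_zero.size else 1.0

        if free_rd:
            lower = np.array([1e-8, 0.0, gamma_lo, 0.0])
            upper = np.array([1.0, 0.02, 0.05, 20.0])
            free_names = ["alpha", "beta", "gamma", "r_d"]
        else:
            lower = np.array([1e-8, 0.0, gamma_lo])
            upper = np.array([1.0, 0.02, 0.05])
            free_names = ["alpha", "beta", "gamma"]

        def residual(x):
            if free_rd:
                a, b, g, rd = x
            else:
                a, b, g = x
                rd = rd_fixed
            denom = 1.0 + g * i
            return a * (1.0 - b * i) * i / denom - rd - y

        starts = []
        for g0 in self.GAMMA_STARTS:
            if not (gamma_lo < g0 < 0.05):
                continue
            x0 = [a0, self.BETA_START, g0] + ([rd0] if free_rd else [])
            starts.append(np.asarray(x0))

        best, n_starts = self._minimize(residual, starts, lower, upper, free_names)
        if best is None:
            return FitResult(
                model="ye", curve=curve, params=None, derived=None,
                n_obs=curve.n_obs, error="all optimizer starts failed",
            )
        if free_rd:
            a, b, g, rd = best.x
        else:
            (a, b, g), rd = best.x, rd_fixed
        # keep the parameter set valid: beta+gamma must stay positive
        b = max(b, 0.0)
        if b + g <= 0:
            g = -b + 1e-12
        try:
            params = YeParams(alpha=float(a), beta=float(b), gamma=float(g), r_d=float(rd))
        except InvalidParameterError as exc:
            return FitResult(
                model="ye", curve=curve, params=None, derived=None,
                n_obs=curve.n_obs, error=f"optimum violates parameter invariants: {exc}",
            )
        return self._finalize(params, best, free_names, n_starts)


class NHModel(_CurveModel):
    """Non-rectangular hyperbola model for one replicate curve.

    ``y_max`` is estimated as the gross asymptote; the reported maximum in
    ``FitResult.derived`` is the net asymptote ``y_max - r_d``. No saturation
    irradiance is reported — the asymptote is never attained.
    """

    model_name = "nh"

    THETA_STARTS = (0.5, 0.9)

    def fit(self, fix_rd: float | None = None) -> FitResult:
        curve = self.curve
        i, y = curve.i, curve.y
        free_rd = curve.response_kind == "a_n" and fix_rd is None
        rd_fixed = 0.0 if curve.response_kind != "a_n" else (fix_rd or 0.0)

        a0 = _alpha0(curve)
        rd0 = 1.0
        if curve.response_kind == "a_n":
            at_zero = y[i == 0]
            rd0 = float(np.clip(-at_zero[0], 0.01, 19.9)) if at_zero.size else 1.0
        y_obs_max = float(y.max())
        ym_hi = 10.0 * max(y_obs_max, 1.0) + 20.0  # gross headroom incl. r_d
        ym0 = 1.05 * max(y_obs_max, 1.0) + (rd0 if (free_rd or rd_fixed > 0) else 0.0)

        if free_rd:
            lower = np.array([1e-8, 1e-6, 1e-8, 0.0])
            upper = np.array([1.0, 1.0, ym_hi, 20.0])
            free_names = ["alpha", "theta", "y_max", "r_d"]
        else:
            lower = np.array([1e-8, 1e-6, 1e-8])
            upper = np.array([1.0, 1.0, ym_hi])
            free_names = ["alpha", "theta", "y_max"]

        def residual(x):
            if free_rd:
                a, th, ym, rd = x
            else:
                (a, th, ym), rd = x, rd_fixed
            b = a * i + ym
            disc = np.maximum(b * b - 4.0 * a * th * ym * i, 0.0)
            return 2.0 * a * i * ym / (b + np.sqrt(disc)) - rd - y

        starts = []
        for th0 in self.THETA_STARTS:
            x0 = [a0, th0, ym0] + ([rd0] if free_rd else [])
            starts.append(np.asarray(x0))

        best, n_starts = self._minimize(residual, starts, lower, upper, free_names)
        if best is None:
            return FitResult(
                model="nh", curve=curve, params=None, derived=None,
                n_obs=curve.n_obs, error="all optimizer starts failed",
            )
        if free_rd:
            a, th, ym, rd = best.x
        else:
            (a, th, ym), rd = best.x, rd_fixed
        try:
            params = NHParams(
                alpha=float(a), theta=float(min(th, 1.0)), y_max=float(ym), r_d=float(rd)
            )
        except InvalidParameterError as exc:
            return FitResult(
                model="nh", curve=curve, params=None, derived=None,
                n_obs=curve.n_obs, error=f"optimum violates parameter invariants: {exc}",
            )
        return self._finalize(params, best, free_names, n_starts)


def fit_ye(curve: LightResponseCurve, fix_rd: float | None = None) -> FitResult:
    """Least-squares fit of the nonasymptotic curve to one replicate."""
    return YeModel(curve).fit(fix_rd=fix_rd)


def fit_nh(curve: LightResponseCurve, fix_rd: float | None = None) -> FitResult:
    """Least-squares fit of the non-rectangular hyperbola to one replicate."""
    return NHModel(curve).fit(fix_rd=fix_rd)


def fit_all_replicates(
    curves: Sequence[LightResponseCurve],
    model: Literal["ye", "nh"] = "ye",
    fix_rd: float | None = None,
) -> list[FitResult]:
    """Fit every replicate independently, preserving order.

    Per-curve failures are returned as :class:`FitResult` records with
    ``error`` set rather than raised, so one bad replicate does not sink
    the batch.
    """
    if len(curves) == 0:
        raise InsufficientDataError("no curves to fit")
    if model not in ("ye", "nh"):
        raise InvalidParameterError(f"model must be 'ye' or 'nh', got {model!r}")
    cls = YeModel if model == "ye" else NHModel
    results: list[FitResult] = []
    for curve in curves:
        try:
            results.append(cls(curve).fit(fix_rd=fix_rd))
        except Exception as exc:  # record, don't raise
            results.append(
                FitResult(
                    model=model, curve=curve, params=None, derived=None,
                    n_obs=getattr(curve, "n_obs", 0), error=str(exc),
                )
            )
    return results
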