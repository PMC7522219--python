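"""Replicate summaries, observed extrema, and model-vs-observation testing.

Mirrors the intercomparison layout used for leaf light-response studies: for
each derived quantity (maximum, saturation irradiance, compensation point,
respiration, residual sum of squares) the per-replicate values fitted by the
nonasymptotic (Ye) model, by the non-rectangular hyperbola (NH), and taken
directly from the measurements (Obs) form three groups that are compared by
one-way ANOVA with Tukey HSD homogeneous-subset letters at alpha = 0.05.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateVarianceError,
    InsufficientDataError,
    InvalidParameterError,
)
from .fit import FitResult, LightResponseCurve, fit_all_replicates

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "ObservedExtrema",
    "observed_extrema",
    "one_way_anova",
    "compare_models",
    "ComparisonTable",
]


@dataclass(frozen=True)
class GroupSummary:
    """Per-replicate values of one quantity under one label (Ye/NH/Obs)."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values)) if self.n else math.nan

    @property
    def se(self) -> float:
        """Standard error of the mean, sd/sqrt(n); nan for n < 2."""
        if self.n < 2:
            return math.nan
        return float(np.std(self.values, ddof=1) / math.sqrt(self.n))


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA across groups with Tukey-HSD letter display."""

    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    groups: tuple[GroupSummary, ...]
    letters: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class ObservedExtrema:
    """Directly measured curve characteristics for one replicate."""

    y_max: float
    i_at_max: float
    i_c: float | None = None
    r_d: float | None = None


def observed_extrema(curve: LightResponseCurve) -> ObservedExtrema:
    """Extract the measured maximum, its irradiance, and (for A_n curves)
    the measured dark exchange and interpolated light compensation point.

    The observed compensation point is the linear interpolation of the zero
    crossing between the two steps bracketing A_n = 0 (lowest-irradiance
    crossing); absent with a warning when the response never changes sign.
    """
    c = curve.sorted()
    idx = int(np.argmax(c.y))
    y_max = float(c.y[idx])
    i_at_max = float(c.i[idx])
    i_c = None
    r_d = None
    if curve.response_kind == "a_n":
        at_zero = c.y[c.i == 0]
        if at_zero.size:
            r_d = float(-at_zero[0])
        sign = np.sign(c.y)
        crossing = np.where((sign[:-1] <= 0) & (sign[1:] > 0))[0]
        if crossing.size:
            k = int(crossing[0])
            i0, i1 = c.i[k], c.i[k + 1]
            y0, y1 = c.y[k], c.y[k + 1]
            i_c = float(i0) if y0 == 0 else float(i0 + (0.0 - y0) * (i1 - i0) / (y1 - y0))
        else:
            warnings.warn(
                f"replicate {curve.replicate_id}: no A_n sign change; "
                "observed compensation point unavailable",
                UserWarning,
                stacklevel=2,
            )
    return ObservedExtrema(y_max=y_max, i_at_max=i_at_max, i_c=i_c, r_d=r_d)


def _tukey_nsd_pairs(groups: Sequence[GroupSummary], alpha: float) -> set[frozenset[str]]:
    """Pairs of labels NOT significantly different by Tukey HSD."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate([g.values for g in groups])
    labels = np.concatenate([[g.label] * g.n for g in groups])
    if np.ptp(values) == 0:
        return {frozenset((a.label, b.label)) for a, b in itertools.combinations(groups, 2)}
    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    nsd: set[frozenset[str]] = set()
    table = res.summary().data[1:]
    for row, reject in zip(table, res.reject):
        if not reject:
            nsd.add(frozenset((str(row[0]), str(row[1]))))
    return nsd


def _letters_from_nsd(
    groups: Sequence[GroupSummary], nsd: set[frozenset[str]]
) -> dict[str, str]:
    """Compact letter display: maximal cliques of the not-different graph,
    ordered by descending group mean, lettered a, b, c, ..."""
    labels = [g.label for g in groups]
    means = {g.label: g.mean for g in groups}

    def compatible(subset: tuple[str, ...]) -> bool:
        return all(
            frozenset((a, b)) in nsd for a, b in itertools.combinations(subset, 2)
        )

    cliques: list[tuple[str, ...]] = []
    for r in range(len(labels), 0, -1):
        for subset in itertools.combinations(labels, r):
            if compatible(subset) and not any(
                set(subset) <= set(c) for c in cliques
            ):
                cliques.append(subset)
    cliques.sort(key=lambda c: -max(means[l] for l in c))
    letters: dict[str, list[str]] = {l: [] for l in labels}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for l in clique:
            letters[l].append(letter)
    return {l: "".join(sorted(v)) for l, v in letters.items()}


def one_way_anova(groups: Sequence[GroupSummary], alpha: float = 0.05) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA across >= 2 groups.

    F and p are computed from explicit between/within sums of squares (so an
    independent routine can serve as a cross-check); homogeneous-subset
    letters come from pairwise Tukey HSD at the given alpha.
    """
    if len(groups) < 2:
        raise InsufficientDataError("ANOVA needs at least two groups")
    for g in groups:
        if g.n < 2:
            raise InsufficientDataError(f"group {g.label!r} has n < 2")
    values = np.concatenate([g.values for g in groups])
    if np.ptp(values) == 0:
        raise DegenerateVarianceError("total variance is zero")
    k = len(groups)
    n_total = int(values.size)
    grand = float(values.mean())
    ss_between = float(sum(g.n * (g.mean - grand) ** 2 for g in groups))
    ss_within = float(sum(np.sum((g.values - g.mean) ** 2) for g in groups))
    df_b, df_w = k - 1, n_total - k
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0:
        f_stat = math.inf if ms_b > 0 else 0.0
        p = 0.0 if ms_b > 0 else 1.0
    else:
        from scipy.stats import f as f_dist

        f_stat = ms_b / ms_w
        p = float(f_dist.sf(f_stat, df_b, df_w))
    nsd = _tukey_nsd_pairs(groups, alpha)
    letters = _letters_from_nsd(groups, nsd)
    return AnovaResult(
        f_statistic=f_stat,
        df_between=df_b,
        df_within=df_w,
        p_value=p,
        groups=tuple(groups),
        letters=letters,
    )


@dataclass
class ComparisonTable:
    """Model-vs-observation intercomparison, one row block per quantity."""

    response_kind: str
    rows: list[dict] = field(default_factory=list)
    anova: dict[str, AnovaResult | None] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_json_obj(self) -> dict:
        out: dict = {"response_kind": self.response_kind, "quantities": {}}
        for row in self.rows:
            q = out["quantities"].setdefault(row["quantity"], {})
            q[row["group"]] = {
                "mean": row["mean"],
                "se": None if row["se"] != row["se"] else row["se"],
                "n": row["n"],
                "letter": row["letter"],
            }
        for qty, an in self.anova.items():
            if an is not None:
                out["quantities"].setdefault(qty, {})["anova"] = {
                    "F": an.f_statistic,
                    "df": [an.df_between, an.df_within],
                    "p": an.p_value,
                }
        return out


_QUANTITIES = ("y_max", "i_sat", "i_c", "r_d", "residual_ss")


def _finite(values: list[float | None]) -> np.ndarray:
    return np.asarray([v for v in values if v is not None and np.isfinite(v)], float)


def compare_models(
    curves: Sequence[LightResponseCurve],
    resp=None,
    models: Sequence[str] = ("ye", "nh"),
    alpha: float = 0.05,
    fix_rd: float | None = None,
) -> ComparisonTable:
    """Fit the requested models to every replicate and compare against the
    observations, quantity by quantity.

    For each applicable quantity the per-replicate fitted values (one group
    per model) and measured values (Obs) are summarised as mean ± SE and, when
    at least two groups have n >= 2, tested by one-way ANOVA with Tukey
    letters. NH saturation-irradiance cells stay empty: the hyperbola has no
    attainable maximum. ``resp`` (a RespirationSpec) is accepted for pipeline
    symmetry and recorded but not needed once the curves are assembled.
    """
    if len(curves) < 2:
        raise InsufficientDataError("model comparison needs >= 2 replicates")
    kinds = {c.response_kind for c in curves}
    if len(kinds) != 1:
        raise InvalidParameterError("all curves must share one response_kind")
    kind = kinds.pop()
    models = tuple(models)
    for m in models:
        if m not in ("ye", "nh"):
            raise InvalidParameterError(f"unknown model {m!r}")

    fits: dict[str, list[FitResult]] = {
        m: fit_all_replicates(curves, model=m, fix_rd=fix_rd) for m in models
    }
    obs = [observed_extrema(c) for c in curves]

    def collect(quantity: str) -> dict[str, np.ndarray]:
        groups: dict[str, np.ndarray] = {}
        for m in models:
            label = "Ye" if m == "ye" else "NH"
            vals: list[float | None] = []
            for r in fits[m]:
                if not r.ok:
                    vals.append(None)
                elif quantity == "y_max":
                    vals.append(r.derived.y_max)
                elif quantity == "i_sat":
                    vals.append(r.derived.i_sat if m == "ye" else None)
                elif quantity == "i_c":
                    vals.append(r.derived.i_c)
                elif quantity == "r_d":
                    vals.append(r.params.r_d)
                elif quantity == "residual_ss":
                    vals.append(r.sse)
            arr = _finite(vals)
            if arr.size:
                groups[label] = arr
        obs_vals: list[float | None] = []
        for o, c in zip(obs, curves):
            if quantity == "y_max":
                obs_vals.append(o.y_max)
            elif quantity == "i_sat":
                obs_vals.append(o.i_at_max)
            elif quantity == "i_c":
                obs_vals.append(o.i_c)
            elif quantity == "r_d":
                obs_vals.append(o.r_d)
            else:
                obs_vals.append(None)
        arr = _finite(obs_vals)
        if arr.size:
            groups["Obs"] = arr
        return groups

    table = ComparisonTable(response_kind=kind)
    for quantity in _QUANTITIES:
        if quantity in ("i_c", "r_d") and kind != "a_n":
            continue
        raw_groups = collect(quantity)
        if not raw_groups:
            continue
        summaries = [GroupSummary(label, vals) for label, vals in raw_groups.items()]
        anova: AnovaResult | None = None
        testable = [g for g in summaries if g.n >= 2]
        if len(testable) >= 2:
            try:
                anova = one_way_anova(testable, alpha=alpha)
            except DegenerateVarianceError:
                anova = None
        table.anova[quantity] = anova
        for g in summaries:
            letter = anova.letters.get(g.label, "") if anova is not None else ""
            table.rows.append(
                {
                    "quantity": quantity,
                    "group": g.label,
                    "mean": g.mean,
                    "se": g.se,
                    "n": g.n,
                    "letter": letter,
                }
            )
    return table
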