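"""PSII electron flow from fluorescence and its carboxylation/oxygenation split.

Total linear electron transport through PSII is estimated from the effective
PSII quantum yield as ``J = Phi_PSII * I * f_PSII * absorptance`` with the
standard leaf values f_PSII = 0.5 (fraction of absorbed quanta reaching PSII)
and absorptance = 0.84. With alternative electron sinks ignored or constant,
J splits between RuBP carboxylation and oxygenation as

    J_C = (1/3) * (J + 8*(A_n + R_day))
    J_O = (2/3) * (J - 4*(A_n + R_day))

which sum to J identically. Day respiration defaults to the common convention
R_day = 0.5 * R_d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .exceptions import DomainError, InsufficientDataError, PartitionWarning

__all__ = [
    "LightStep",
    "RespirationSpec",
    "compute_j",
    "partition_j",
    "partition_curve",
]

PSII_FRACTION = 0.5
ABSORPTANCE = 0.84


@dataclass(frozen=True)
class LightStep:
    """Steady-state measurements at one irradiance step for one replicate.

    Units: irradiance in μmol photons m⁻² s⁻¹, A_n in μmol CO2 m⁻² s⁻¹,
    electron flows in μmol e⁻ m⁻² s⁻¹; phi_psii dimensionless in [0, 1].
    """

    i: float
    a_n: float
    phi_psii: float | None = None
    j: float | None = None
    j_c: float | None = None
    j_o: float | None = None

    def __post_init__(self) -> None:
        if self.i < 0:
            raise DomainError(f"irradiance must be >= 0, got {self.i}")
        if self.phi_psii is not None and not (0 <= self.phi_psii <= 1):
            raise DomainError(f"phi_psii must be in [0, 1], got {self.phi_psii}")
        if self.j is not None and self.j < 0:
            raise DomainError(f"j must be >= 0, got {self.j}")


@dataclass(frozen=True)
class RespirationSpec:
    """Dark and day respiration; r_day defaults to 0.5 * r_d."""

    r_d: float
    r_day: float | None = None

    def __post_init__(self) -> None:
        if self.r_d < 0:
            raise DomainError(f"r_d must be >= 0, got {self.r_d}")
        if self.r_day is None:
            object.__setattr__(self, "r_day", 0.5 * self.r_d)
        elif self.r_day < 0:
            raise DomainError(f"r_day must be >= 0, got {self.r_day}")


def compute_j(
    phi_psii,
    i,
    psii_fraction: float = PSII_FRACTION,
    absorptance: float = ABSORPTANCE,
):
    """Total PSII electron transport rate J = Phi_PSII * I * f_PSII * absorptance."""
    phi = np.asarray(phi_psii, dtype=float)
    irr = np.asarray(i, dtype=float)
    if np.any((phi < 0) | (phi > 1)):
        raise DomainError("phi_psii must be within [0, 1]")
    if np.any(irr < 0):
        raise DomainError("irradiance must be non-negative")
    if not (0 < psii_fraction <= 1):
        raise DomainError(f"psii_fraction must be in (0, 1], got {psii_fraction}")
    if not (0 < absorptance <= 1):
        raise DomainError(f"absorptance must be in (0, 1], got {absorptance}")
    out = phi * irr * psii_fraction * absorptance
    return out if out.ndim else float(out)


def partition_j(j, a_n, resp: RespirationSpec):
    """Split total electron flow into (J_C, J_O).

    Negative J_O values (J < 4*(A_n + R_day)) are returned as-is but flagged
    with a :class:`PartitionWarning` — they indicate inconsistent inputs or a
    non-negligible alternative electron sink, not a numerical fault.
    """
    jj = np.asarray(j, dtype=float)
    an = np.asarray(a_n, dtype=float)
    if np.any(jj < 0):
        raise DomainError("j must be non-negative")
    bracket = an + resp.r_day
    j_c = (jj + 8.0 * bracket) / 3.0
    j_o = 2.0 / 3.0 * (jj - 4.0 * bracket)
    if np.any(j_o < 0):
        warnings.warn(
            "negative J_O produced (J < 4*(A_n + R_day)): inputs inconsistent "
            "with carboxylation/oxygenation-only electron allocation",
            PartitionWarning,
            stacklevel=2,
        )
    if np.any(j_c < 0):
        warnings.warn(
            "negative J_C produced (strongly negative A_n relative to J)",
            PartitionWarning,
            stacklevel=2,
        )
    if jj.ndim == 0:
        return float(j_c), float(j_o)
    return j_c, j_o


def partition_curve(
    steps: Sequence[LightStep],
    resp: RespirationSpec,
    psii_fraction: float = PSII_FRACTION,
    absorptance: float = ABSORPTANCE,
) -> list[LightStep]:
    """Populate j, j_c, j_o on each step of a measured curve.

    Steps providing neither ``phi_psii`` nor ``j`` are passed through
    unchanged with a warning.
    """
    if len(steps) == 0:
        raise InsufficientDataError("cannot partition an empty curve")
    out: list[LightStep] = []
    n_skipped = 0
    for step in steps:
        if step.j is not None:
            j = step.j
        elif step.phi_psii is not None:
            j = compute_j(step.phi_psii, step.i, psii_fraction, absorptance)
        else:
            n_skipped += 1
            out.append(step)
            continue
        j_c, j_o = partition_j(j, step.a_n, resp)
        out.append(replace(step, j=j, j_c=j_c, j_o=j_o))
    if n_skipped:
        warnings.warn(
            f"{n_skipped} step(s) lacked both phi_psii and j; passed through "
            "without partitioning",
            PartitionWarning,
            stacklevel=2,
        )
    return out
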