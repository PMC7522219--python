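"""Synthetic gas-exchange / fluorescence data with the structure of field
light-response measurements.

The generator emulates the measurement design used for field-grown C3 crops:
descending light steps (2000...0 μmol m⁻² s⁻¹ for the soybean design, capped
at 1800 for the wheat design), three leaf replicates, curves with a linear
initial rise, saturation, and a mild post-saturation decline. Measurement
error is additive Gaussian, homoscedastic, with standard deviation expressed
relative to the noiseless curve maximum by default (2%). Between-replicate
biological variation, when requested, is multiplicative lognormal jitter on
the truth parameters, which keeps them inside their validity region almost
surely (invalid draws are redrawn).

:func:`fixture_table1` provides a catalog of ground-truth parameter sets for
each response family of both species, taken from published replicate-mean
fits, and is used throughout the test suite. The wheat J–I entry is omitted:
its published photoinhibition coefficient is internally inconsistent with the
published maximum (off by roughly an order of magnitude, a likely misprint).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError, SimulationWarning
from .models import NHParams, YeParams, nh_predict, ye_predict
from .partition import ABSORPTANCE, PSII_FRACTION, RespirationSpec

__all__ = [
    "SOYBEAN_STEPS",
    "WHEAT_STEPS",
    "SimulationSpec",
    "simulate_an_curves",
    "simulate_fluorescence",
    "fixture_table1",
]

SOYBEAN_STEPS = (
    2000.0, 1800.0, 1600.0, 1400.0, 1200.0, 1000.0, 800.0, 600.0,
    400.0, 200.0, 150.0, 100.0, 80.0, 50.0, 0.0,
)
WHEAT_STEPS = SOYBEAN_STEPS[1:]


@dataclass(frozen=True)
class SimulationSpec:
    """Design of one synthetic experiment.

    ``noise_sd`` is interpreted relative to the max |noiseless response| when
    ``noise_relative`` is True (default), otherwise as an absolute standard
    deviation in response units. ``replicate_jitter`` is the lognormal sigma
    of the multiplicative per-replicate parameter perturbation (0 = replicates
    share the truth exactly).
    """

    truth: YeParams | NHParams
    response_kind: str = "a_n"
    light_steps: tuple[float, ...] = SOYBEAN_STEPS
    n_replicates: int = 3
    noise_sd: float = 0.02
    noise_relative: bool = True
    replicate_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        steps = tuple(float(s) for s in self.light_steps)
        object.__setattr__(self, "light_steps", steps)
        if len(set(steps)) != len(steps):
            raise InvalidParameterError("light steps must be unique")
        if any(s < 0 for s in steps):
            raise InvalidParameterError("light steps must be non-negative")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if self.replicate_jitter < 0:
            raise InvalidParameterError("replicate_jitter must be >= 0")
        if self.n_replicates < 1:
            raise InvalidParameterError("n_replicates must be >= 1")


def _predict(truth, i):
    return ye_predict(truth, i) if isinstance(truth, YeParams) else nh_predict(truth, i)


def _jitter_params(truth, sigma: float, rng: np.random.Generator, i_max: float):
    """Multiplicative lognormal jitter; redraw until the perturbed set is valid."""
    if sigma == 0:
        return truth
    cls = type(truth)
    names = (
        ("alpha", "beta", "gamma", "r_d")
        if isinstance(truth, YeParams)
        else ("alpha", "theta", "y_max", "r_d")
    )
    for _ in range(100):
        factors = np.exp(rng.normal(0.0, sigma, size=len(names)))
        kwargs = {n: getattr(truth, n) * f for n, f in zip(names, factors)}
        if isinstance(truth, NHParams):
            kwargs["theta"] = min(kwargs["theta"], 1.0)
        try:
            cand = cls(**kwargs)
        except InvalidParameterError:
            continue
        if isinstance(cand, YeParams) and cand.domain_limit <= i_max:
            continue
        return cand
    raise InvalidParameterError(
        "could not draw valid jittered parameters in 100 attempts"
    )


def _replicate_rngs(seed: int, n: int, stream: int) -> list[np.random.Generator]:
    """Independent, reproducible per-replicate streams.

    ``stream`` separates the gas-exchange and fluorescence stages so each
    stage has its own substream family under one experiment seed.
    """
    ss = np.random.SeedSequence([int(seed), int(stream)])
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def simulate_an_curves(spec: SimulationSpec) -> "Dataset":
    """Simulate per-replicate response curves from the spec's truth.

    Despite the name (the net-photosynthesis case is the common entry point),
    any response family simulates the same way: jitter the truth per
    replicate, evaluate its curve at the light steps, add Gaussian noise.
    """
    from .io import Dataset

    i = np.asarray(spec.light_steps, dtype=float)
    col = "a_n" if spec.response_kind == "a_n" else spec.response_kind
    rngs = _replicate_rngs(spec.seed, spec.n_replicates, stream=0)
    replicates: dict[str, pd.DataFrame] = {}
    for r, rng in enumerate(rngs, start=1):
        truth_r = _jitter_params(spec.truth, spec.replicate_jitter, rng, float(i.max()))
        clean = np.asarray(_predict(truth_r, i), dtype=float)
        sd = spec.noise_sd * np.max(np.abs(clean)) if spec.noise_relative else spec.noise_sd
        noisy = clean + rng.normal(0.0, sd, size=clean.shape) if sd > 0 else clean.copy()
        replicates[f"r{r}"] = pd.DataFrame({"i": i, col: noisy})
    return Dataset(
        species_label="synthetic",
        replicates=replicates,
        metadata={
            "truth": spec.truth,
            "response_kind": spec.response_kind,
            "seed": spec.seed,
            "noise_sd": spec.noise_sd,
            "replicate_jitter": spec.replicate_jitter,
        },
    )


def simulate_fluorescence(
    spec: SimulationSpec,
    an_dataset: "Dataset",
    resp: RespirationSpec | None = None,
    psii_fraction: float = PSII_FRACTION,
    absorptance: float = ABSORPTANCE,
) -> "Dataset":
    """Add an effective PSII quantum-yield column to a gas-exchange dataset.

    Two truth conventions are supported through ``spec.response_kind``:

    * ``"j"`` (default usage): the total electron flow follows its own
      nonasymptotic truth; Phi_PSII is the inversion
      ``J / (psii_fraction * absorptance * I)`` for I > 0, with the I = 0 step
      assigned the yield of the smallest positive step (a dark value cannot be
      inferred from J = 0).
    * ``"j_c"``: the *carboxylation* stream follows the truth, and Phi_PSII is
      built so that partitioning the generated data returns that truth exactly
      at every positive irradiance (J = 3*J_C - 8*(A_n + R_day), requires
      ``resp``). This carboxylation-consistent mode gives the pipeline an
      exact closed loop for validation.

    Yields are clipped to [0, 1]; a clipping rate above 10% raises a loud
    warning because it means truth and light design are inconsistent.
    Gaussian noise (relative to the maximum yield) is then applied.
    """
    from .io import Dataset

    if spec.response_kind not in ("j", "j_c"):
        raise InvalidParameterError(
            "fluorescence truth must have response_kind 'j' or 'j_c'"
        )
    if spec.response_kind == "j_c" and resp is None:
        raise InvalidParameterError("carboxylation-consistent mode requires resp")
    scale = psii_fraction * absorptance
    rngs = _replicate_rngs(spec.seed, len(an_dataset.replicates), stream=1)
    replicates: dict[str, pd.DataFrame] = {}
    n_clipped = 0
    n_total = 0
    for (rep_id, df), rng in zip(an_dataset.replicates.items(), rngs):
        i = df["i"].to_numpy(dtype=float)
        i_max = float(i.max())
        truth_r = _jitter_params(spec.truth, spec.replicate_jitter, rng, i_max)
        if spec.response_kind == "j":
            j = np.asarray(_predict(truth_r, i), dtype=float)
        else:
            j_c = np.asarray(_predict(truth_r, i), dtype=float)
            j = 3.0 * j_c - 8.0 * (df["a_n"].to_numpy(dtype=float) + resp.r_day)
        pos = i > 0
        phi = np.empty_like(i)
        phi[pos] = j[pos] / (scale * i[pos])
        if np.any(pos):
            smallest = np.argmin(np.where(pos, i, np.inf))
            phi[~pos] = phi[smallest]
        clipped = (phi < 0) | (phi > 1)
        n_clipped += int(clipped.sum())
        n_total += int(phi.size)
        phi = np.clip(phi, 0.0, 1.0)
        sd = spec.noise_sd * float(np.max(phi)) if spec.noise_relative else spec.noise_sd
        if sd > 0:
            phi = np.clip(phi + rng.normal(0.0, sd, size=phi.shape), 0.0, 1.0)
        out = df.copy()
        out["phi_psii"] = phi
        replicates[rep_id] = out
    if n_total and n_clipped / n_total > 0.10:
        warnings.warn(
            f"{n_clipped}/{n_total} quantum yields clipped to [0, 1]: "
            "fluorescence truth and light-step design are inconsistent",
            SimulationWarning,
            stacklevel=2,
        )
    elif n_clipped:
        warnings.warn(
            f"{n_clipped} quantum yield value(s) clipped to [0, 1]",
            SimulationWarning,
            stacklevel=2,
        )
    meta = dict(an_dataset.metadata)
    meta["fluorescence_truth"] = spec.truth
    meta["fluorescence_kind"] = spec.response_kind
    return Dataset(
        species_label=an_dataset.species_label, replicates=replicates, metadata=meta
    )


def fixture_table1() -> dict[str, SimulationSpec]:
    """Catalog of ground-truth simulation specs per species and response family.

    Parameter values are published replicate-mean nonasymptotic-model fits for
    field-grown winter wheat (taes_*) and soybean (gmax_*). The wheat J–I set
    is excluded (published beta_e inconsistent with the published J_max; see
    module docstring).
    """
    cat = {
        "taes_an": SimulationSpec(
            truth=YeParams(0.077, 1.31e-4, 1.02e-3, 3.60),
            response_kind="a_n", light_steps=WHEAT_STEPS,
        ),
        "taes_jc": SimulationSpec(
            truth=YeParams(0.266, 2.07e-4, 3.75e-4, 0.0),
            response_kind="j_c", light_steps=WHEAT_STEPS,
        ),
        "taes_jo": SimulationSpec(
            truth=YeParams(0.062, 3.45e-4, -1.98e-4, 0.0),
            response_kind="j_o", light_steps=WHEAT_STEPS,
        ),
        "gmax_an": SimulationSpec(
            truth=YeParams(0.059, 1.40e-4, 5.76e-4, 3.76),
            response_kind="a_n", light_steps=SOYBEAN_STEPS,
        ),
        "gmax_j": SimulationSpec(
            truth=YeParams(0.299, 3.07e-4, -1.50e-4, 0.0),
            response_kind="j", light_steps=SOYBEAN_STEPS,
        ),
        "gmax_jc": SimulationSpec(
            truth=YeParams(0.221, 2.54e-4, 1.67e-5, 0.0),
            response_kind="j_c", light_steps=SOYBEAN_STEPS,
        ),
        "gmax_jo": SimulationSpec(
            truth=YeParams(0.087, 4.12e-4, -3.71e-4, 0.0),
            response_kind="j_o", light_steps=SOYBEAN_STEPS,
        ),
    }
    return cat
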