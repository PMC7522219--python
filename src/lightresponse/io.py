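"""Reading measured step tables and writing results.

The input contract is a plain delimited text file (CSV or TSV) with a header
row; one row per (replicate, irradiance step). Header names are matched
case-insensitively against common gas-exchange synonyms (PARi/Qin for
irradiance, Photo/A for net photosynthesis, PhiPS2 for the PSII yield), or
mapped explicitly via ``column_map``. Units are assumed μmol-based throughout,
as produced by standard leaf gas-exchange systems; no unit conversion is
attempted. Instrument-native file dialects are not parsed — export to CSV
first.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError, MissingColumnError
from .fit import FitResult, LightResponseCurve

__all__ = ["Dataset", "read_steps", "write_results", "COLUMN_SYNONYMS"]

logger = logging.getLogger("lightresponse")

COLUMN_SYNONYMS: dict[str, tuple[str, ...]] = {
    "i": ("i", "irradiance", "par", "pari", "qin", "q", "ppfd", "light", "parleaf"),
    "a_n": ("a_n", "an", "a", "photo", "anet", "assimilation"),
    "phi_psii": ("phi_psii", "phips2", "phipsii", "phi2", "phipsii_yield", "yield"),
    "j": ("j", "etr"),
    "j_c": ("j_c", "jc"),
    "j_o": ("j_o", "jo"),
    "replicate": ("replicate", "rep", "replicate_id", "leaf", "curve", "plant"),
}

_FLOAT_FMT = "%.6g"


@dataclass
class Dataset:
    """Per-replicate step tables plus experiment metadata.

    ``replicates`` maps replicate id to a tidy DataFrame with column ``i``
    and whichever response columns the file provided (a_n, phi_psii, j, ...).
    """

    species_label: str
    replicates: dict[str, pd.DataFrame]
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for rep_id, df in self.replicates.items():
            f = df.copy()
            f.insert(0, "replicate", rep_id)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def curves(
        self, response_kind: str, column: str | None = None, include_zero: bool = True
    ) -> list[LightResponseCurve]:
        """Extract one :class:`LightResponseCurve` per replicate.

        ``include_zero=False`` drops the I = 0 step — used for partitioned
        electron-flow curves, where the dark step carries only the respiration
        bookkeeping term, not electron flow.
        """
        col = column or ("a_n" if response_kind == "a_n" else response_kind)
        out = []
        for rep_id, df in self.replicates.items():
            if col not in df.columns:
                raise MissingColumnError(
                    f"replicate {rep_id!r} lacks column {col!r} required for "
                    f"{response_kind} analysis"
                )
            sub = df if include_zero else df[df["i"] > 0]
            out.append(
                LightResponseCurve(
                    replicate_id=rep_id,
                    response_kind=response_kind,  # type: ignore[arg-type]
                    i=sub["i"].to_numpy(dtype=float),
                    y=sub[col].to_numpy(dtype=float),
                )
            )
        return out

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)
        return path


def _canonical_columns(columns, column_map: dict[str, str] | None) -> dict[str, str]:
    """Map file headers to canonical names via column_map then synonyms."""
    mapping: dict[str, str] = {}
    cmap = {k.lower(): v for k, v in (column_map or {}).items()}
    for col in columns:
        low = str(col).strip().lower()
        if low in cmap:
            mapping[col] = cmap[low]
            continue
        for canonical, synonyms in COLUMN_SYNONYMS.items():
            if low in synonyms:
                mapping[col] = canonical
                break
    return mapping


def read_steps(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    species_label: str | None = None,
) -> Dataset:
    """Parse a delimited step table into a :class:`Dataset`.

    Rows whose irradiance (or every response value) fails numeric parsing are
    dropped with a logged count. A file without a replicate column is treated
    as a single replicate ``r1``.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        raw = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise InsufficientDataError(f"empty input file: {path}") from exc
    if raw.empty:
        raise InsufficientDataError(f"no data rows in {path}")
    mapping = _canonical_columns(raw.columns, column_map)
    df = raw.rename(columns=mapping)
    df = df[[c for c in df.columns if c in COLUMN_SYNONYMS]]
    if "i" not in df.columns:
        raise MissingColumnError(
            f"no irradiance column found in {path.name}; headers seen: "
            f"{list(raw.columns)}"
        )
    value_cols = [c for c in df.columns if c not in ("replicate",)]
    for col in value_cols:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    n_before = len(df)
    df = df.dropna(subset=["i"])
    response_cols = [c for c in value_cols if c != "i"]
    if not response_cols:
        raise MissingColumnError(
            f"no response column (a_n / phi_psii / j / j_c / j_o) found in {path.name}"
        )
    df = df.dropna(subset=response_cols, how="all")
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.info("read_steps: dropped %d unparseable row(s) from %s", n_dropped, path.name)
    if df.empty:
        raise InsufficientDataError(f"no parseable data rows in {path}")
    if "replicate" in df.columns:
        groups = {str(k): v.drop(columns=["replicate"]).reset_index(drop=True)
                  for k, v in df.groupby("replicate", sort=True)}
    else:
        groups = {"r1": df.reset_index(drop=True)}
    return Dataset(
        species_label=species_label or path.stem,
        replicates=groups,
        metadata={"source": str(path), "n_dropped_rows": n_dropped},
    )


def _round_sig(x):
    """Round floats through the 6-significant-digit text representation so the
    JSON and CSV writers agree and round-trips are lossless."""
    if isinstance(x, float):
        return float(_FLOAT_FMT % x) if np.isfinite(x) else None
    return x


def _fitresult_record(r: FitResult) -> dict:
    rec: dict = {
        "model": r.model,
        "replicate": r.curve.replicate_id,
        "response_kind": r.curve.response_kind,
        "converged": bool(r.converged),
        "n_obs": int(r.n_obs),
        "error": r.error,
    }
    if r.params is not None:
        rec.update({k: v for k, v in dataclasses.asdict(r.params).items()})
        rec["r_squared"] = r.r_squared
        rec["sse"] = r.sse
        d = r.derived
        rec["y_max"] = d.y_max
        rec["i_sat"] = d.i_sat
        rec["i_c"] = d.i_c
        rec["asymptotic"] = d.asymptotic
    return {k: _round_sig(v) for k, v in rec.items()}


def write_results(results, path: str | Path, fmt: str = "csv") -> Path:
    """Serialise fit results, comparison tables or step datasets.

    Column order is deterministic and floats are written at 6 significant
    digits; JSON output round-trips losslessly through :func:`json.load`.
    """
    from .compare import ComparisonTable

    path = Path(path)
    if results is None:
        raise InsufficientDataError("nothing to write")
    if isinstance(results, ComparisonTable):
        if not results.rows:
            raise InsufficientDataError("comparison table is empty")
        if fmt == "json":
            payload = json.loads(
                json.dumps(results.to_json_obj()), parse_float=float
            )
            payload = _deep_round(payload)
            path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
        else:
            results.to_dataframe().to_csv(path, index=False, float_format=_FLOAT_FMT)
        return path
    if isinstance(results, Dataset):
        if not results.replicates:
            raise InsufficientDataError("dataset is empty")
        if fmt == "json":
            payload = _deep_round(
                {rep: df.to_dict(orient="list") for rep, df in results.replicates.items()}
            )
            path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
        else:
            results.write(path)
        return path
    if isinstance(results, FitResult):
        results = [results]
    if isinstance(results, (list, tuple)):
        if len(results) == 0:
            raise InsufficientDataError("no results to write")
        records = [_fitresult_record(r) for r in results]
        if fmt == "json":
            path.write_text(json.dumps(records, indent=1, sort_keys=True) + "\n")
        else:
            pd.DataFrame(records).to_csv(path, index=False, float_format=_FLOAT_FMT)
        return path
    raise TypeError(f"cannot serialise results of type {type(results).__name__}")


def _deep_round(obj):
    if isinstance(obj, dict):
        return {k: _deep_round(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_deep_round(v) for v in obj]
    return _round_sig(obj)
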