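"""Trial-table interchange, validation, and run manifests.

The on-disk trial table is UTF-8 delimited text with a header row, one row
per TOJ trial, SOA in milliseconds with the convention that a negative SOA
means the probe led.  Unknown columns are preserved on read but ignored by
the analysis.  Every simulated or fitted artifact is accompanied by a JSON
manifest recording the generating configuration, seed and package versions,
making each output reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_trials", "write_trials", "validate_trials", "write_manifest",
           "read_manifest", "ValidationError", "RunConfig", "load_run_config",
           "save_fit", "load_posterior"]


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """One end-to-end run: experiment layout, model, population, windows.

    Every field is JSON-serializable (via the manifest writer); defaults are
    the documented defaults of the underlying dataclasses.
    """

    experiment: str
    seed: int
    outdir: Path
    model: object  # ModelSpec
    population: object  # PopulationConfig
    window: object | None = None  # WindowSpec

REQUIRED_COLUMNS = ("participant_id", "session", "trial_index", "condition",
                    "soa", "response_probe_first")
OPTIONAL_COLUMNS = ("sequence_length", "repetition_index", "position_in_run",
                    "has_distractor_pair")
SOA_LIMIT_MS = 1000.0
_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False,
             True: True, False: False, 1: True, 0: False}


class ValidationError(ValueError):
    """A trial table violated the schema; the message names the offender."""


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Schema-check a trial table; returns a normalized copy.

    Raises :class:`ValidationError` naming the offending column (and first
    offending row) on: missing columns, unknown conditions, non-boolean
    responses, SOAs outside +/-1000 ms, negative indices, or a repetition
    index at or beyond its sequence length.
    """
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"missing required column {col!r}")
    out = df.copy()

    bad = ~out["condition"].isin(("assertion", "negation"))
    if bad.any():
        i = out.index[bad][0]
        raise ValidationError(
            f"column 'condition', row {i}: {out.loc[i, 'condition']!r} "
            "is not 'assertion' or 'negation'")

    resp = out["response_probe_first"]
    if resp.dtype != bool:
        mapped = resp.map(lambda v: _BOOL_MAP.get(
            v.strip().lower() if isinstance(v, str) else v))
        if mapped.isna().any():
            i = out.index[mapped.isna()][0]
            raise ValidationError(
                f"column 'response_probe_first', row {i}: {resp[i]!r} is not boolean")
        out["response_probe_first"] = mapped.astype(bool)

    soa = pd.to_numeric(out["soa"], errors="coerce")
    bad = soa.isna() | (soa.abs() > SOA_LIMIT_MS)
    if bad.any():
        i = out.index[bad][0]
        raise ValidationError(
            f"column 'soa', row {i}: {out.loc[i, 'soa']!r} outside +/-{SOA_LIMIT_MS:.0f} ms")
    out["soa"] = soa.astype(float)

    for col, minimum in (("session", 1), ("trial_index", 0)):
        vals = pd.to_numeric(out[col], errors="coerce")
        bad = vals.isna() | (vals < minimum) | (vals != vals.round())
        if bad.any():
            i = out.index[bad][0]
            raise ValidationError(
                f"column {col!r}, row {i}: {out.loc[i, col]!r} must be an "
                f"integer >= {minimum}")
        out[col] = vals.astype(int)

    if "repetition_index" in out.columns and "sequence_length" in out.columns:
        bad = out["repetition_index"] >= out["sequence_length"]
        if bad.any():
            i = out.index[bad][0]
            raise ValidationError(
                f"column 'repetition_index', row {i}: index "
                f"{out.loc[i, 'repetition_index']} >= sequence length "
                f"{out.loc[i, 'sequence_length']}")
    return out


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial table (CSV/TSV inferred from the extension)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    return validate_trials(df)


def write_trials(df: pd.DataFrame, path) -> None:
    """Validate and write a trial table as delimited text."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    validate_trials(df).to_csv(path, sep=sep, index=False)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def write_manifest(path, *, seed: int, config=None, extra: dict | None = None) -> None:
    """Record the configuration, seed and versions next to an artifact."""
    import arviz, scipy  # versions only

    manifest = {
        "seed": int(seed),
        "config": _jsonable(config) if config is not None else None,
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "arviz": arviz.__version__,
        },
    }
    if extra:
        manifest.update(_jsonable(extra))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2))


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


def load_run_config(path) -> "RunConfig":
    """Read a TOML run configuration.

    Recognized tables: top-level ``experiment`` (exp1|exp2|exp3), ``seed``,
    ``outdir``; ``[population]`` (PopulationConfig fields), ``[model]``
    (ModelSpec fields, with ``[model.sampler]`` and ``[model.priors]``),
    ``[window]`` (width/step).  Omitted fields take the documented defaults.
    """
    import tomllib

    from .inference import ModelSpec
    from .sequence import WindowSpec
    from .simulate import PopulationConfig

    raw = tomllib.loads(Path(path).read_text())
    seed = int(raw.get("seed", 0))
    pop_kwargs = raw.get("population", {})
    pop_kwargs.setdefault("seed", seed)
    window = raw.get("window")
    return RunConfig(
        experiment=raw.get("experiment", "exp2"),
        seed=seed,
        outdir=Path(raw.get("outdir", "results/run")),
        model=ModelSpec(**raw.get("model", {})),
        population=PopulationConfig(**pop_kwargs),
        window=WindowSpec(**window) if window else None,
    )


def save_fit(fit_result, outdir) -> None:
    """Persist a fit: posterior draws as NetCDF, summaries as CSV, manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fit_result.idata.to_netcdf(str(outdir / "posterior.nc"))
    fit_result.summary_table().to_csv(outdir / "summaries.csv", index=False)
    write_manifest(outdir / "manifest.json", seed=fit_result.seed,
                   config=fit_result.spec,
                   extra={"warnings": list(fit_result.warnings),
                          "n_cells": len(fit_result.model.cells)})


def load_posterior(path):
    """Read back a persisted posterior as an arviz InferenceData."""
    import arviz as az

    return az.from_netcdf(str(path))
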