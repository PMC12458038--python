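"""Readers and writers for the package's documented plain-text schemas.

All tabular formats are CSV with mandatory headers; traces and curves carry
a JSON metadata sidecar (``<file>.meta.json``). Config files are YAML with
unit-suffixed field names (``c_nM``, ``D_um2_per_s``, ``bin_width_ms`` ...)
that are converted to SI on load; unknown unit suffixes are rejected. See
docs/FORMATS.md for the full schema catalog.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .correlate import CorrelationCurve
from .fcsmodels import CorrFitResult
from .geometry import ConfocalGeometry
from .simulate import BindingSystem, FluorSpecies, IntensityTrace

SCHEMA_VERSION = 1

__all__ = [
    "write_trace",
    "read_trace",
    "write_curve",
    "read_curve",
    "read_table",
    "write_table",
    "fit_result_to_json",
    "fit_result_from_json",
    "load_config",
    "system_from_config",
]

# ---------------------------------------------------------------------------
# unit-suffix handling
# ---------------------------------------------------------------------------

#: SI conversion factor per recognised unit suffix
UNIT_SUFFIXES: dict[str, float] = {
    # concentration -> M
    "M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9, "pM": 1e-12,
    # time -> s
    "s": 1.0, "ms": 1e-3, "us": 1e-6, "min": 60.0, "h": 3600.0,
    # length -> m
    "m": 1.0, "um": 1e-6, "nm": 1e-9,
    # diffusion -> m^2/s
    "m2_per_s": 1.0, "um2_per_s": 1e-12,
    # rates
    "per_s": 1.0, "per_M_per_s": 1.0,
    # brightness -> counts/s
    "cps": 1.0, "kcps": 1e3,
}

#: fields that need no unit suffix
PLAIN_FIELDS = frozenset(
    {"name", "label", "seed", "f_ov", "s", "n_red_labels", "mode", "design",
     "schema_version", "kind", "m", "levels", "n_segments"}
)


def _parse_unit_field(key: str, value):
    """Return (base_name, SI value) for a unit-suffixed config field."""
    if key in PLAIN_FIELDS:
        return key, value
    base, sep, suffix = key.rpartition("_")
    if not sep:
        raise ValueError(f"config field {key!r}: missing unit suffix")
    # compound suffixes like um2_per_s span several underscores
    for known in sorted(UNIT_SUFFIXES, key=len, reverse=True):
        if key.endswith("_" + known):
            return key[: -len(known) - 1], float(value) * UNIT_SUFFIXES[known]
    raise ValueError(
        f"config field {key!r}: unknown unit suffix {suffix!r} "
        f"(known: {sorted(UNIT_SUFFIXES)})"
    )


def _convert_block(block: dict) -> dict:
    out = {}
    for key, value in block.items():
        base, si = _parse_unit_field(key, value)
        out[base] = si
    return out


def load_config(path) -> dict:
    """Load a YAML experiment config, converting unit-suffixed fields to SI.

    Expected blocks: ``geometry``, ``species`` (list), ``kinetics``,
    ``simulation``; every quantity field must carry a recognised unit
    suffix.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cfg = {}
    for block, content in raw.items():
        if isinstance(content, list):
            cfg[block] = [_convert_block(item) for item in content]
        elif isinstance(content, dict):
            cfg[block] = _convert_block(content)
        else:
            cfg[block] = content
    return cfg


def system_from_config(cfg: dict) -> BindingSystem:
    """Build a BindingSystem from a loaded (SI-converted) config."""
    g = cfg["geometry"]
    geometry = ConfocalGeometry(
        w_xy=g["w_xy"], w_z=g["w_z"], f_ov=g.get("f_ov", 0.6)
    )
    species = {}
    for sp in cfg["species"]:
        species[sp["name"]] = FluorSpecies(
            sp["name"], sp["D"], sp["c"],
            q_green=sp.get("q_green", 0.0), q_red=sp.get("q_red", 0.0),
        )
    missing = {"NP", "L", "NP.L"} - set(species)
    if missing:
        raise ValueError(f"config species must include NP, L and NP.L; missing {sorted(missing)}")
    kin = cfg.get("kinetics", {})
    return BindingSystem(
        species["NP"], species["L"], species["NP.L"], geometry,
        k_on=kin.get("k_on", 0.0), k_off=kin.get("k_off", 0.0),
    )


# ---------------------------------------------------------------------------
# traces and curves
# ---------------------------------------------------------------------------

def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_trace(trace: IntensityTrace, path) -> Path:
    """Write a two-channel trace as ``time_s,green_counts,red_counts`` CSV."""
    path = Path(path)
    df = pd.DataFrame(
        {"time_s": trace.times, "green_counts": trace.counts_green,
         "red_counts": trace.counts_red}
    )
    df.to_csv(path, index=False)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "bin_width_s": trace.bin_width,
        "duration_s": trace.duration,
        "seed": trace.seed,
        "config": trace.meta,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1, default=str))
    return path


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{what}: missing required column {col!r}")


def read_trace(path) -> IntensityTrace:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ("time_s", "green_counts", "red_counts"), f"trace {path}")
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
        bin_width = meta["bin_width_s"]
        seed = meta.get("seed", -1)
        config = meta.get("config", {})
    else:
        t = df["time_s"].to_numpy()
        bin_width = float(t[1] - t[0]) if t.size > 1 else 1.0
        seed, config = -1, {}
    return IntensityTrace(
        bin_width,
        df["green_counts"].to_numpy(dtype=np.int64),
        df["red_counts"].to_numpy(dtype=np.int64),
        seed,
        config,
    )


def write_curve(curve: CorrelationCurve, path) -> Path:
    """Write a correlation curve as ``lag_s,G,G_err`` CSV plus sidecar."""
    path = Path(path)
    err = curve.G_err if curve.G_err is not None else np.full_like(curve.G, np.nan)
    pd.DataFrame({"lag_s": curve.lags, "G": curve.G, "G_err": err}).to_csv(
        path, index=False, float_format="%.17g"
    )
    _sidecar(path).write_text(
        json.dumps({"schema_version": SCHEMA_VERSION, "kind": curve.kind,
                    **curve.meta}, indent=1, default=str)
    )
    return path


def read_curve(path) -> CorrelationCurve:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ("lag_s", "G"), f"curve {path}")
    err = df["G_err"].to_numpy() if "G_err" in df else None
    if err is not None and np.all(np.isnan(err)):
        err = None
    kind, meta = "auto_green", {}
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
        kind = meta.pop("kind", kind)
        meta.pop("schema_version", None)
    return CorrelationCurve(df["lag_s"].to_numpy(), df["G"].to_numpy(),
                            G_err=err, kind=kind, meta=meta)


# ---------------------------------------------------------------------------
# CCP tables and fit results
# ---------------------------------------------------------------------------

TABLE_SCHEMAS = {
    "timecourse": ("t_s", "ccp"),
    "titration": ("L_conc_M", "ccp"),
    "decay": ("t_s", "ccp"),
}


def read_table(path, kind: str) -> pd.DataFrame:
    """Read a CCP table (``timecourse``, ``titration`` or ``decay``)."""
    if kind not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}; known: {sorted(TABLE_SCHEMAS)}")
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, TABLE_SCHEMAS[kind], f"{kind} table {path}")
    return df


def write_table(df: pd.DataFrame, path, kind: str) -> Path:
    if kind not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    _require_columns(df, TABLE_SCHEMAS[kind], f"{kind} table")
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def fit_result_to_json(result, path=None) -> str:
    """Serialise a fit result (CorrFitResult or KineticResults) to JSON."""
    if isinstance(result, CorrFitResult):
        payload = dataclasses.asdict(result)
        payload["cov"] = np.asarray(payload["cov"]).tolist()
        payload["type"] = "CorrFitResult"
    else:  # KineticResults
        payload = {
            "type": "KineticResults",
            "model_name": result.model_name,
            "equation": result.equation,
            "params": result.params.to_dict(),
            "bse": result.bse.to_dict(),
            "cov_params": result.cov_params.to_numpy().tolist(),
            "nobs": int(result.nobs),
            "ssr": None if result.ssr is None or not np.isfinite(result.ssr) else float(result.ssr),
            "converged": bool(result.converged),
            "flags": list(result.flags),
        }
    payload["schema_version"] = SCHEMA_VERSION
    text = json.dumps(payload, indent=1, default=float)
    if path is not None:
        Path(path).write_text(text)
    return text


def fit_result_from_json(path) -> dict:
    """Load a fit-result JSON into a plain dict (round-trip inspection)."""
    payload = json.loads(Path(path).read_text())
    if "type" not in payload:
        raise ValueError(f"not a fit-result file: {path}")
    return payload
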