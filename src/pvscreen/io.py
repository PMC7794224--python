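"""Cohort CSV serialization, cohort-spec config files, and the JSON report.

The cohort CSV schema is fixed: columns exactly
``id,sex,age,hb,htc,wbc,neutrophils,platelets,mcv,rdw,mch,mchc,
jak2_positive,known_mpn,dna_ok`` with booleans as 0/1, decimal points and no
thousands separators.  Units are fixed by the schema (g/dL, %, x10^9/L, fL,
pg); plausibility bounds are validated on read and fail loudly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import COHORT_COLUMNS, MARKERS, CohortSpec, MarkerDistribution

__all__ = [
    "write_cohort_csv",
    "read_cohort_csv",
    "spec_to_dict",
    "spec_from_dict",
    "save_spec",
    "load_spec",
    "jsonify",
    "write_report",
    "validate_report",
]

log = logging.getLogger("pvscreen")

_BOOL_COLUMNS = ("jak2_positive", "known_mpn", "dna_ok")
_BOOL_DEFAULTS = {"jak2_positive": False, "known_mpn": False, "dna_ok": True}

# Plausibility bounds per marker in schema units; malformed magnitudes
# (e.g. Hb reported in g/L) must fail loudly rather than flow through.
_BOUNDS = {
    "age": (0.0, 120.0), "hb": (0.0, 25.0), "htc": (0.0, 100.0),
    "wbc": (0.0, 500.0), "neutrophils": (0.0, 300.0), "platelets": (0.0, 3000.0),
    "mcv": (30.0, 160.0), "rdw": (5.0, 50.0), "mch": (10.0, 60.0),
    "mchc": (15.0, 60.0),
}


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """Write a cohort in the canonical schema (booleans as 0/1)."""
    out = cohort[list(COHORT_COLUMNS)].copy()
    for c in _BOOL_COLUMNS:
        out[c] = out[c].astype(int)
    out.to_csv(path, index=False)


def read_cohort_csv(path, validate_bounds: bool = True) -> pd.DataFrame:
    """Read a cohort CSV, tolerating missing optional columns and extras.

    Missing flag columns get their documented defaults with a logged
    warning; unrecognized columns are dropped with a warning; a malformed
    row fails with its line number; unknown sex tokens fail.
    """
    df = pd.read_csv(path, dtype={"id": str, "sex": str})
    extra = [c for c in df.columns if c not in COHORT_COLUMNS]
    if extra:
        log.warning("ignoring unrecognized column(s): %s", extra)
        df = df.drop(columns=extra)
    required = ("id", "sex") + MARKERS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV is missing required column(s): {missing}")
    for c in _BOOL_COLUMNS:
        if c not in df.columns:
            log.warning("column %r absent; defaulting to %s", c, _BOOL_DEFAULTS[c])
            df[c] = _BOOL_DEFAULTS[c]
        df[c] = df[c].astype(bool)
    bad_sex = ~df["sex"].isin(("male", "female"))
    if bad_sex.any():
        line = int(df.index[bad_sex][0]) + 2  # header + 1-based
        raise ValueError(
            f"unknown sex token {df.loc[bad_sex, 'sex'].iloc[0]!r} at line {line}")
    for m in MARKERS:
        vals = pd.to_numeric(df[m], errors="coerce")
        if vals.isna().any():
            line = int(df.index[vals.isna()][0]) + 2
            raise ValueError(f"malformed value in column {m!r} at line {line}")
        df[m] = vals.astype(float)
        if validate_bounds:
            lo, hi = _BOUNDS[m]
            out = ~df[m].between(lo, hi)
            if out.any():
                line = int(df.index[out][0]) + 2
                raise ValueError(
                    f"value {df.loc[out, m].iloc[0]} in column {m!r} at line "
                    f"{line} is outside the plausible range [{lo}, {hi}]")
    return df[list(COHORT_COLUMNS)]


# ------------------------------------------------------------- spec config

def _dist_to_dict(d: MarkerDistribution) -> dict:
    out = {"family": d.family, "location": d.location, "scale": d.scale}
    if d.truncation is not None:
        out["truncation"] = list(d.truncation)
    return out


def _dist_from_dict(d: dict) -> MarkerDistribution:
    trunc = tuple(d["truncation"]) if d.get("truncation") else None
    return MarkerDistribution(d["family"], float(d["location"]),
                              float(d["scale"]), trunc)


def spec_to_dict(spec: CohortSpec) -> dict:
    return {
        "n": spec.n,
        "sex_fraction_male": spec.sex_fraction_male,
        "jak2_prevalence": spec.jak2_prevalence,
        "known_mpn_fraction": spec.known_mpn_fraction,
        "dna_failure_rate": spec.dna_failure_rate,
        "seed": spec.seed,
        "markers": {
            f"{group}/{sex}": {m: _dist_to_dict(d) for m, d in dists.items()}
            for (group, sex), dists in spec.markers.items()
        },
        "correlation": {
            "markers": list(spec.correlation.columns),
            "matrix": np.asarray(spec.correlation, dtype=float).tolist(),
        },
    }


def spec_from_dict(d: dict) -> CohortSpec:
    markers = {}
    for key, dists in d["markers"].items():
        group, sex = key.split("/")
        markers[(group, sex)] = {m: _dist_from_dict(v) for m, v in dists.items()}
    corr = pd.DataFrame(d["correlation"]["matrix"],
                        index=d["correlation"]["markers"],
                        columns=d["correlation"]["markers"])
    return CohortSpec(
        n=int(d["n"]),
        sex_fraction_male=float(d["sex_fraction_male"]),
        jak2_prevalence=float(d["jak2_prevalence"]),
        known_mpn_fraction=float(d["known_mpn_fraction"]),
        dna_failure_rate=float(d["dna_failure_rate"]),
        markers=markers,
        correlation=corr,
        seed=int(d.get("seed", 0)),
    )


def save_spec(spec: CohortSpec, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(jsonify(spec_to_dict(spec)), sort_keys=False))


def load_spec(path) -> CohortSpec:
    return spec_from_dict(yaml.safe_load(Path(path).read_text()))


# ------------------------------------------------------------- JSON report

def jsonify(obj):
    """Recursively convert numpy/dataclass values into JSON-safe types."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return jsonify(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [jsonify(v) for v in obj]
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    return obj


def write_report(report: dict, path) -> None:
    data = jsonify(report)
    validate_report(data)
    Path(path).write_text(json.dumps(data, indent=2) + "\n")


def _schema() -> dict:
    return json.loads(
        resources.files("pvscreen").joinpath("report.schema.json").read_text())


_TYPES = {"object": dict, "array": list, "string": str,
          "number": (int, float), "integer": int, "boolean": bool}


def validate_report(report: dict, schema: dict | None = None,
                    _path: str = "report") -> None:
    """Structural validation against the shipped schema (required keys and
    primitive types; a deliberately small checker)."""
    node = schema if schema is not None else _schema()
    expected = node.get("type")
    if expected and not (report is None and node.get("nullable")):
        if not isinstance(report, _TYPES[expected]) or isinstance(report, bool) \
                and expected not in ("boolean",):
            raise ValueError(
                f"{_path}: expected {expected}, got {type(report).__name__}")
    if expected == "object":
        for key in node.get("required", []):
            if key not in report:
                raise ValueError(f"{_path}: missing required key {key!r}")
        for key, sub in node.get("properties", {}).items():
            if key in report:
                validate_report(report[key], sub, f"{_path}.{key}")
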