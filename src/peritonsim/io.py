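"""Readers/writers and provenance plumbing.

File formats:

* RPM records: comma-separated UTF-8 with header
  ``patient_id,day,phase,cycle_index,infused_ml,drained_ml,fluid_label``;
  metadata sidecar ``patient_id,regimen,diuresis_ml[,residual_volume_ml]``.
  Volumes are mL (integers where the cycler reports integers).
* Tissue profiles: delimited table (x_cm, theta, P_mmHg, C_glu_mmol_per_ml, t_min).
* Session results: JSON with a provenance block (config hash, parameter
  version, seed).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .constitutive import ModelParameters
from .session import SessionResult, DayResult
from .stats import RPMDataset, RECORD_COLUMNS, PHASES
from .tissue import TissueState, pressure_from_hydration

__all__ = ["read_rpm_csv", "write_rpm_csv", "export_profiles",
           "export_session", "import_session", "provenance_block"]

_DTYPES = {"patient_id": str, "day": int, "phase": str, "cycle_index": int,
           "infused_ml": float, "drained_ml": float, "fluid_label": str}


class SchemaError(ValueError):
    """A file does not conform to the expected column schema."""


def read_rpm_csv(path: str | Path, meta_path: str | Path | None = None) -> RPMDataset:
    """Read an RPM record CSV (plus metadata sidecar) into an RPMDataset.

    Schema violations raise :class:`SchemaError` naming the column (and row
    where identifiable).  If ``meta_path`` is None, ``<stem>.meta.csv`` next
    to the records file is used.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing} in header")
    for col, typ in _DTYPES.items():
        try:
            df[col] = df[col].astype(typ)
        except (ValueError, TypeError) as e:
            raise SchemaError(f"{path}: column {col!r} not convertible: {e}") from e
    bad = ~df["phase"].isin(PHASES)
    if bad.any():
        raise SchemaError(f"{path}: invalid phase at row {int(df.index[bad][0]) + 2} "
                          f"(expected one of {PHASES})")
    neg = (df["infused_ml"] < 0) | (df["drained_ml"] < 0)
    if neg.any():
        raise SchemaError(f"{path}: negative volume at row {int(df.index[neg][0]) + 2}")
    if meta_path is None:
        meta_path = path.parent / (path.stem + ".meta.csv")
    meta = pd.read_csv(meta_path, comment="#")
    for col in ("patient_id", "regimen"):
        if col not in meta.columns:
            raise SchemaError(f"{meta_path}: missing column {col!r}")
    meta["patient_id"] = meta["patient_id"].astype(str)
    return RPMDataset(df[RECORD_COLUMNS].copy(), meta)


def write_rpm_csv(ds: RPMDataset, path: str | Path,
                  meta_path: str | Path | None = None,
                  header_comment: str | None = None) -> None:
    """Write an RPMDataset as records CSV + metadata sidecar (lossless)."""
    path = Path(path)
    if meta_path is None:
        meta_path = path.parent / (path.stem + ".meta.csv")
    out = ds.records[RECORD_COLUMNS].copy()
    for col in ("infused_ml", "drained_ml"):
        v = out[col].to_numpy()
        if np.allclose(v, np.round(v)):
            out[col] = np.round(v).astype(int)
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out.to_csv(fh, index=False)
    with open(meta_path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        ds.meta.to_csv(fh, index=False)


def export_profiles(states: Iterable[TissueState], params: ModelParameters,
                    path: str | Path, labels: Iterable[str] | None = None) -> None:
    """Write hydration/pressure/glucose depth profiles as a delimited table.

    Deterministic serialization, fixed column order, units in the header.
    An empty state list produces a header-only file.
    """
    states = list(states)
    labels = list(labels) if labels is not None else [str(i) for i in range(len(states))]
    rows = []
    for lab, s in zip(labels, states):
        P = pressure_from_hydration(s.theta, params)
        for i in range(s.n_cells):
            rows.append((lab, s.t, s.x_centers[i], s.theta[i], P[i], s.C_glu[i]))
    df = pd.DataFrame(rows, columns=["label", "t_min", "x_cm", "theta",
                                     "P_mmHg", "C_glu_mmol_per_ml"])
    try:
        df.to_csv(path, index=False, float_format="%.8g")
    except OSError as e:
        raise OSError(f"cannot write profiles to {path}: {e}") from e


def _session_dict(res: SessionResult) -> dict:
    return {
        "initial_drained_ml": res.initial_drained,
        "cycles": [{"infused_ml": c.infused, "drained_ml": c.drained,
                    "net_uf_ml": c.net_uf,
                    "tissue_water_delta_ml": c.tissue_water_delta}
                   for c in res.cycles],
        "session_uf_ml": res.session_uf,
        "per_cycle_uf_ml": res.per_cycle_uf,
        "mean_uf_c3plus_ml": res.mean_uf_c3plus,
        "t_series_min": list(res.t_series),
        "V_series_ml": list(res.V_series),
    }


def provenance_block(params: ModelParameters, seed: int | None = None,
                     extra: dict | None = None) -> dict:
    """Config hash + parameter version + seed, embedded in every output."""
    cfg = json.dumps(params.to_dict(), sort_keys=True)
    block = {
        "parameter_version": params.version,
        "config_sha256": hashlib.sha256(cfg.encode()).hexdigest()[:16],
        "seed": seed,
    }
    if extra:
        block.update(extra)
    return block


def export_session(result: SessionResult | list[DayResult], path: str | Path,
                   params: ModelParameters | None = None,
                   seed: int | None = None) -> None:
    """Serialize a session (or a multi-day run) to JSON with provenance."""
    if isinstance(result, SessionResult):
        payload: dict = {"kind": "session", "session": _session_dict(result)}
    else:
        payload = {"kind": "days", "days": [
            {"session": _session_dict(d.session),
             "day_infused_ml": d.day_infused,
             "day_drained_ml": d.day_drained,
             "day_net_uf_ml": d.day_net_uf} for d in result]}
    if params is not None:
        payload["provenance"] = provenance_block(params, seed)
    try:
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
    except OSError as e:
        raise OSError(f"cannot write session JSON to {path}: {e}") from e


def import_session(path: str | Path) -> dict:
    """Load an exported session JSON back into plain dictionaries."""
    with open(path) as fh:
        return json.load(fh)
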