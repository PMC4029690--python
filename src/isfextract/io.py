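"""CSV session tables, calibration files, and simulation configs.

The interchange format is a flat CSV with one row per measurement time point
and a fixed header::

    session_id,mode,time_min,r_ab_kohm,r_bc_kohm,r_ac_kohm,cs_mmol_per_l,cb_ref_mmol_per_l,x_true_ul,ci_true_mmol_per_l

The last three columns hold the reference meter reading and the synthetic
ground truth; their cells are empty for real measurements.  Rows belonging to
one session are contiguous; static sessions have two rows (before/after) and
dynamic sessions five.

Calibration state (C1 and the extraction constants it was derived under) is
a small YAML key-value file so prediction runs do not re-derive it.  The
simulation config is a YAML file with one block per parameter group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .extraction import ExtractionConfig, ExtractionSession, SkinPermeability
from .network import PairwiseResistances, estimate_rb
from .simulate import DriftParams, NoiseParams

__all__ = [
    "SESSIONS_COLUMNS",
    "SessionTableError",
    "read_sessions",
    "write_sessions",
    "cohort_to_table",
    "reduce_sessions",
    "read_calibration",
    "write_calibration",
    "SimulationConfig",
    "load_config",
]

SESSIONS_COLUMNS = [
    "session_id", "mode", "time_min",
    "r_ab_kohm", "r_bc_kohm", "r_ac_kohm",
    "cs_mmol_per_l", "cb_ref_mmol_per_l", "x_true_ul", "ci_true_mmol_per_l",
]

_ROWS_PER_MODE = {"static": 2, "dynamic": 5}
_RESISTANCE_COLS = ["r_ab_kohm", "r_bc_kohm", "r_ac_kohm"]
_OPTIONAL_COLS = ["cb_ref_mmol_per_l", "x_true_ul", "ci_true_mmol_per_l"]


class SessionTableError(ValueError):
    """Malformed session CSV (schema, values, or group structure)."""


def read_sessions(path: str | Path) -> pd.DataFrame:
    """Read and validate a sessions CSV.

    Raises :class:`SessionTableError` naming the offending column or the
    1-based file line of the offending row.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SESSIONS_COLUMNS if c not in raw.columns]
    if missing:
        raise SessionTableError(f"missing required column(s): {', '.join(missing)}")
    extra = [c for c in raw.columns if c not in SESSIONS_COLUMNS]
    if extra:
        raise SessionTableError(f"unexpected column(s): {', '.join(extra)}")

    df = raw.copy()
    numeric_cols = ["time_min", *_RESISTANCE_COLS, "cs_mmol_per_l", *_OPTIONAL_COLS]
    for col in numeric_cols:
        optional = col in _OPTIONAL_COLS
        converted = pd.to_numeric(df[col].mask(df[col] == ""), errors="coerce")
        bad = converted.isna() & (df[col] != "" if optional else True)
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 1-based
            raise SessionTableError(f"non-numeric value {df[col][bad.idxmax()]!r} "
                                    f"in column {col} at line {line}")
        df[col] = converted

    for col in _RESISTANCE_COLS:
        bad = ~(df[col] > 0)
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise SessionTableError(f"non-positive resistance in column {col} at line {line}")

    bad_mode = ~df["mode"].isin(_ROWS_PER_MODE)
    if bad_mode.any():
        line = int(bad_mode.idxmax()) + 2
        raise SessionTableError(f"unknown mode {df['mode'][bad_mode.idxmax()]!r} at line {line}")

    # contiguity: each session_id must form one uninterrupted block
    ids = df["session_id"].tolist()
    seen: set[str] = set()
    prev = None
    for i, sid in enumerate(ids):
        if sid != prev and sid in seen:
            raise SessionTableError(f"session {sid!r} rows are not contiguous (line {i + 2})")
        seen.add(sid)
        prev = sid
    for sid, group in df.groupby("session_id", sort=False):
        modes = group["mode"].unique()
        if len(modes) != 1:
            raise SessionTableError(f"session {sid!r} mixes measurement modes")
        expected = _ROWS_PER_MODE[modes[0]]
        if len(group) != expected:
            raise SessionTableError(
                f"session {sid!r}: {modes[0]} mode requires {expected} rows, got {len(group)}"
            )
    return df


def write_sessions(table: pd.DataFrame, path: str | Path) -> None:
    """Write a sessions table with the canonical header; floats at 12 s.f."""
    missing = [c for c in SESSIONS_COLUMNS if c not in table.columns]
    if missing:
        raise SessionTableError(f"missing required column(s): {', '.join(missing)}")
    table.to_csv(path, index=False, columns=SESSIONS_COLUMNS, float_format="%.12g")


def cohort_to_table(sessions: Iterable[ExtractionSession], *,
                    include_truth: bool = True) -> pd.DataFrame:
    """Flatten simulated sessions into the canonical row-per-timepoint table."""
    rows = []
    for s in sessions:
        series = s.series
        if series is None:
            raise ValueError(f"session {s.session_id!r} carries no measurement series")
        for t, triple in zip(series.times, series.triples):
            rows.append({
                "session_id": s.session_id,
                "mode": s.mode,
                "time_min": t,
                "r_ab_kohm": triple.r_ab,
                "r_bc_kohm": triple.r_bc,
                "r_ac_kohm": triple.r_ac,
                "cs_mmol_per_l": s.cs,
                "cb_ref_mmol_per_l": s.cb_true if include_truth else np.nan,
                "x_true_ul": s.x_isf if include_truth else np.nan,
                "ci_true_mmol_per_l": s.ci if include_truth else np.nan,
            })
    return pd.DataFrame(rows, columns=SESSIONS_COLUMNS)


def reduce_sessions(table: pd.DataFrame) -> pd.DataFrame:
    """Reduce each session's triples to one longitudinal resistance.

    Applies the pairwise inversion per row, drops flagged non-positive
    estimates, and averages the rest per the session's protocol.  Returns a
    per-session frame with columns ``session_id, mode, r_b_kohm, n_invalid,
    valid, cs_mmol_per_l, cb_ref_mmol_per_l``.
    """
    out = []
    for sid, group in table.groupby("session_id", sort=False):
        estimates = [
            estimate_rb(PairwiseResistances(row.r_ab_kohm, row.r_bc_kohm, row.r_ac_kohm))
            for row in group.itertuples()
        ]
        usable = [e.r_b_hat for e in estimates if e.valid]
        out.append({
            "session_id": sid,
            "mode": group["mode"].iloc[0],
            "r_b_kohm": float(np.mean(usable)) if usable else np.nan,
            "n_invalid": len(estimates) - len(usable),
            "valid": bool(usable),
            "cs_mmol_per_l": float(group["cs_mmol_per_l"].iloc[0]),
            "cb_ref_mmol_per_l": float(group["cb_ref_mmol_per_l"].iloc[0]),
        })
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# calibration files

_CALIBRATION_KEYS = ["c1_ul_kohm", "k", "v_buffer_ul", "t_extract_min", "area_cm2"]


def write_calibration(path: str | Path, c1: float, cfg: ExtractionConfig, *,
                      timestamp: str | None = None) -> None:
    """Persist a calibration (C1 plus the constants it was derived under)."""
    payload = {
        "c1_ul_kohm": float(c1),
        "k": float(cfg.k),
        "v_buffer_ul": float(cfg.v_buffer),
        "t_extract_min": float(cfg.t_extract),
        "area_cm2": float(cfg.area),
    }
    if timestamp is not None:
        payload["timestamp"] = timestamp
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_calibration(path: str | Path) -> tuple[float, ExtractionConfig]:
    """Load a calibration file; returns (C1, extraction constants)."""
    payload = yaml.safe_load(Path(path).read_text())
    if not isinstance(payload, dict):
        raise ValueError(f"{path}: not a key-value calibration file")
    missing = [k for k in _CALIBRATION_KEYS if k not in payload]
    if missing:
        raise ValueError(f"{path}: missing calibration key(s): {', '.join(missing)}")
    cfg = ExtractionConfig(v_buffer=float(payload["v_buffer_ul"]),
                           t_extract=float(payload["t_extract_min"]),
                           area=float(payload["area_cm2"]),
                           k=float(payload["k"]))
    c1 = float(payload["c1_ul_kohm"])
    if not (math.isfinite(c1) and c1 > 0):
        raise ValueError(f"{path}: c1_ul_kohm must be positive, got {c1!r}")
    return c1, cfg


# ---------------------------------------------------------------------------
# simulation config

@dataclass(frozen=True)
class SimulationConfig:
    """Fully resolved parameter blocks for cohort simulation."""

    extraction: ExtractionConfig
    skin: SkinPermeability
    noise: NoiseParams
    drift: DriftParams | None
    n_sessions: int
    mode: str
    rb_median: float
    rb_sigma_log: float
    recovery_factor: float
    cb_true_range: tuple[float, float]

    def resolved(self) -> dict:
        """Plain-dict echo of every resolved parameter, for run logs."""
        return {
            "extraction": {"v_buffer_ul": self.extraction.v_buffer,
                           "t_extract_min": self.extraction.t_extract,
                           "area_cm2": self.extraction.area,
                           "k": self.extraction.k},
            "skin": {"c1_ul_kohm": self.skin.c1},
            "noise": {"sigma_rel": self.noise.sigma_rel},
            "drift": (None if self.drift is None else
                      {"r_start_kohm": self.drift.r_start,
                       "r_floor_kohm": self.drift.r_floor,
                       "tau_min": self.drift.tau}),
            "cohort": {"n_sessions": self.n_sessions, "mode": self.mode,
                       "rb_median_kohm": self.rb_median,
                       "rb_sigma_log": self.rb_sigma_log,
                       "recovery_factor": self.recovery_factor,
                       "cb_true_range_mmol_per_l": list(self.cb_true_range)},
        }


def load_config(path: str | Path) -> SimulationConfig:
    """Load a YAML simulation config; absent blocks fall back to defaults."""
    payload = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(payload, dict):
        raise ValueError(f"{path}: config must be a mapping of parameter blocks")

    ext = payload.get("extraction", {})
    cfg = ExtractionConfig(v_buffer=float(ext.get("v_buffer_ul", 50.0)),
                           t_extract=float(ext.get("t_extract_min", 10.0)),
                           area=float(ext.get("area_cm2", 0.785)),
                           k=float(ext.get("k", 1.0)))
    skin = SkinPermeability(c1=float(payload.get("skin", {}).get("c1_ul_kohm", 500.0)))
    noise = NoiseParams(sigma_rel=float(payload.get("noise", {}).get("sigma_rel", 0.0)))
    drift_block = payload.get("drift")
    drift = None
    if drift_block is not None:
        drift = DriftParams(r_start=float(drift_block["r_start_kohm"]),
                            r_floor=float(drift_block["r_floor_kohm"]),
                            tau=float(drift_block["tau_min"]))
    cohort = payload.get("cohort", {})
    cb_range = cohort.get("cb_true_range_mmol_per_l", [4.0, 10.0])
    return SimulationConfig(
        extraction=cfg, skin=skin, noise=noise, drift=drift,
        n_sessions=int(cohort.get("n_sessions", 10)),
        mode=str(cohort.get("mode", "static")),
        rb_median=float(cohort.get("rb_median_kohm", 100.0)),
        rb_sigma_log=float(cohort.get("rb_sigma_log", 0.25)),
        recovery_factor=float(cohort.get("recovery_factor", 1.0)),
        cb_true_range=(float(cb_range[0]), float(cb_range[1])),
    )
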