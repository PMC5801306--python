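"""Trial-table CSV schema, config parsing, run manifests and logging.

The on-disk trial table is comma-separated UTF-8 with LF line endings,
one row per trial, a fixed header, and missing RT (an omission) encoded
as an empty field.  RT is stored in seconds at millisecond precision.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import (
    CONDITIONS,
    TRIAL_TYPES,
    ConfigError,
    GenerativeGrid,
    SessionConfig,
    study_grid,
)
from .ddm import DDMParams

log = logging.getLogger("switchddm")

#: Fixed column order of the trial-table CSV.
COLUMNS = ["subject_id", "condition", "block_index", "block_phase",
           "trial_index", "trial_type", "block_start", "correct", "rt",
           "coins", "iti", "lapse_flag"]

_BOOL_COLS = ["block_start", "correct", "lapse_flag"]
_INT_COLS = ["block_index", "trial_index", "coins"]


class TrialTableError(ValueError):
    """Schema violation in a trial table file."""


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table in the canonical schema (lossless round-trip
    with :func:`read_trials`)."""
    df = trials.loc[:, COLUMNS].copy()
    df["rt"] = df["rt"].map(lambda x: "" if pd.isna(x) else f"{x:.3f}")
    df["iti"] = df["iti"].map(lambda x: "" if pd.isna(x) else f"{x:.3f}")
    for c in _BOOL_COLS:
        df[c] = df[c].map({True: "true", False: "false"})
    df.to_csv(path, index=False, lineterminator="\n")


def read_trials(path, deadline: float = 2.0) -> pd.DataFrame:
    """Read and validate a trial table.

    Raises :class:`TrialTableError` naming unknown/missing columns, or
    reporting the count and first row number of malformed rows (bad
    enumeration values, RT outside (0, deadline])."""
    try:
        df = pd.read_csv(path, dtype={"subject_id": str, "rt": float,
                                      "iti": float})
    except pd.errors.EmptyDataError:
        raise TrialTableError(f"{path}: empty trial table file") from None
    unknown = [c for c in df.columns if c not in COLUMNS]
    missing = [c for c in COLUMNS if c not in df.columns]
    if unknown:
        raise TrialTableError(f"{path}: unknown columns {unknown}")
    if missing:
        raise TrialTableError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise TrialTableError(f"{path}: empty trial table (header only)")
    for c in _BOOL_COLS:
        vals = df[c].astype(str).str.lower()
        bad = ~vals.isin(["true", "false"])
        if bad.any():
            raise TrialTableError(
                f"{path}: column {c}: {int(bad.sum())} non-boolean rows, "
                f"first at row {int(np.flatnonzero(bad)[0]) + 2}")
        df[c] = vals == "true"
    bad = ~df["trial_type"].isin(TRIAL_TYPES)
    if bad.any():
        raise TrialTableError(
            f"{path}: {int(bad.sum())} rows with unknown trial_type, "
            f"first at row {int(np.flatnonzero(bad)[0]) + 2}")
    bad = ~df["condition"].isin(CONDITIONS)
    if bad.any():
        raise TrialTableError(
            f"{path}: {int(bad.sum())} rows with unknown condition, "
            f"first at row {int(np.flatnonzero(bad)[0]) + 2}")
    rt = df["rt"]
    bad = rt.notna() & ~((rt > 0) & (rt <= deadline))
    if bad.any():
        raise TrialTableError(
            f"{path}: {int(bad.sum())} rows with rt outside (0, {deadline}], "
            f"first at row {int(np.flatnonzero(bad)[0]) + 2}")
    for c in _INT_COLS:
        df[c] = df[c].astype(int)
    return df.loc[:, COLUMNS]


# ---------------------------------------------------------------------------
# config documents

def load_config(source) -> tuple[SessionConfig, GenerativeGrid]:
    """Parse a YAML config document (path, text, or mapping).

    An empty document yields the full default study design.  All
    violations are collected and reported together."""
    if isinstance(source, dict):
        raw = source
    else:
        text = source
        try:
            if hasattr(source, "read"):
                text = source.read()
            elif isinstance(source, str) and "\n" not in source and (
                    source.endswith((".yml", ".yaml")) or "/" in source):
                with open(source, "r", encoding="utf-8") as fh:
                    text = fh.read()
        except FileNotFoundError:
            raise ConfigError([f"config file not found: {source}"]) from None
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError(["config document must be a mapping"])
    return validate_config(raw)


def validate_config(raw: dict) -> tuple[SessionConfig, GenerativeGrid]:
    """Fill defaults from the study design constants and validate;
    reports every violation, not just the first."""
    problems: list[str] = []
    known = {"session", "grid"}
    for key in raw:
        if key not in known:
            problems.append(f"unknown top-level key {key!r}")
    sess_raw = dict(raw.get("session") or {})
    valid_fields = set(SessionConfig.__dataclass_fields__)
    for key in list(sess_raw):
        if key not in valid_fields:
            problems.append(f"session: unknown field {key!r}")
            sess_raw.pop(key)
    if "iti_range" in sess_raw:
        sess_raw["iti_range"] = tuple(sess_raw["iti_range"])
    config = None
    try:
        config = SessionConfig(**sess_raw)
        problems.extend(config.violations())
    except TypeError as exc:
        problems.append(f"session: {exc}")

    grid_raw = dict(raw.get("grid") or {})
    grid = None
    try:
        grid = _build_grid(grid_raw, config or SessionConfig(), problems)
    except ConfigError as exc:
        problems.extend(exc.violations)
    if problems:
        raise ConfigError(problems)
    return config, grid


def _param_cell(d: dict, defaults: dict, where: str, problems: list) -> DDMParams | None:
    merged = {**defaults, **d}
    for key in d:
        if key not in ("v", "a", "t0", "lapse"):
            problems.append(f"{where}: unknown parameter {key!r}")
    try:
        p = DDMParams(**{k: float(merged[k]) for k in ("v", "a", "t0", "lapse")})
    except (KeyError, ValueError) as exc:
        problems.append(f"{where}: {exc}")
        return None
    if not 0.0 <= p.lapse <= 1.0:
        problems.append(f"{where}: lapse out of range")
    return p


def _build_grid(grid_raw: dict, config: SessionConfig, problems: list) -> GenerativeGrid:
    dispersion = dict(grid_raw.get("dispersion") or {})
    for key, val in dispersion.items():
        if key not in ("v", "a", "t0"):
            problems.append(f"grid.dispersion: unknown parameter {key!r}")
        elif val < 0:
            problems.append(f"grid.dispersion.{key} must be >= 0 (got {val})")
    if not grid_raw or set(grid_raw) <= {"dispersion"}:
        return study_grid(config, dispersion=dispersion or None)
    defaults = {"t0": 0.3, "lapse": 0.10}
    if "default" in grid_raw:
        base = dict(grid_raw["default"])
        defaults.update(base)
        if "v" in defaults and "a" in defaults:
            p = _param_cell({}, defaults, "grid.default", problems)
            grid = GenerativeGrid.constant(p, config,
                                           dispersion=dispersion or None) \
                if p else None
        else:
            problems.append("grid.default must give at least v and a")
            grid = None
    else:
        grid = study_grid(config, dispersion=dispersion or None)
    cells = grid_raw.get("cells") or {}
    if grid is None and cells:
        return study_grid(config)
    params = dict(grid.params) if grid else {}
    for tt, by_block in cells.items():
        if tt not in TRIAL_TYPES:
            problems.append(f"grid.cells: unknown trial type {tt!r}")
            continue
        for blk, cell in (by_block or {}).items():
            try:
                b = int(blk)
            except (TypeError, ValueError):
                problems.append(f"grid.cells.{tt}: bad block index {blk!r}")
                continue
            base = params.get((tt, b))
            cell_defaults = {**defaults}
            if base is not None:
                cell_defaults.update(v=base.v, a=base.a, t0=base.t0,
                                     lapse=base.lapse)
            p = _param_cell(dict(cell or {}), cell_defaults,
                            f"grid.cells.{tt}.{blk}", problems)
            if p is not None:
                params[(tt, b)] = p
    return GenerativeGrid(params, dispersion or
                          {"v": 0.0, "a": 0.0, "t0": 0.0})


def config_hash(config: SessionConfig, grid: GenerativeGrid | None = None) -> str:
    """Stable digest of a configuration (and grid), for manifests."""
    doc = {"session": {k: getattr(config, k)
                       for k in sorted(SessionConfig.__dataclass_fields__)}}
    if grid is not None:
        doc["grid"] = {f"{tt}/{b}": [p.v, p.a, p.t0, p.lapse]
                       for (tt, b), p in sorted(grid.params.items())}
        doc["dispersion"] = dict(sorted(grid.dispersion.items()))
    blob = json.dumps(doc, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------------------
# run manifests

def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record emitted once per CLI run."""

    stage: str
    master_seed: int | None
    config_hash: str | None = None
    package_version: str = __version__
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    timestamp: str = ""

    def add_input(self, path) -> None:
        self.inputs[str(path)] = file_digest(path)

    def add_output(self, path) -> None:
        self.outputs[str(path)] = file_digest(path)

    def write(self, path) -> None:
        self.timestamp = self.timestamp or time.strftime(
            "%Y-%m-%dT%H:%M:%S", time.gmtime())
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s")
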