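"""CSV and config readers/writers shared by the CLI and analysis stages.

All tables are UTF-8, comma-separated, dot-decimal CSV; units are encoded
in column names (``conc_kgm3``, ``tmp_bar``).  Feed concentrations are
expected in kg m^-3 — a ``brix`` column triggers a warning because °Bx
values must be converted by the user before loading.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .calibration import FluxCurve
from .core import Composition, SolutePair
from .design import DesignTable, FactorLevels, PILOT_LEVELS
from .dynamics import FluxModelParams, UFSystemSpec

__all__ = [
    "load_design_csv",
    "write_design_csv",
    "load_composition_csv",
    "load_flux_curve_csv",
    "load_profiles_csv",
    "load_scenario",
    "write_manifest",
]

logger = logging.getLogger(__name__)

_DESIGN_REQUIRED = ["run_id", "t_c", "tmp_bar", "conc_kgm3"]


def _read_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if frame.empty:
        raise ValueError(f"{path}: table has a header but no rows")
    if any("brix" in c.lower() for c in frame.columns):
        warnings.warn(f"{path}: 'brix' column detected — concentrations must be "
                      "converted to kg m^-3 before loading", stacklevel=3)
    return frame


def load_design_csv(path: str | Path, levels: FactorLevels = PILOT_LEVELS) -> DesignTable:
    """Read a design table; derives coded columns when absent.

    Validates numeric cells and, when possible, the Box-Behnken structure
    (a non-BBD run table loads with a warning, since the regression
    machinery does not require the design pattern).
    """
    frame = _read_csv(path)
    missing = [c for c in _DESIGN_REQUIRED if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    numeric_cols = [c for c in frame.columns if c != "run_id"]
    coerced = frame[numeric_cols].apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & frame[numeric_cols].notna()
    if bad.any().any():
        cells = [(frame.loc[i, "run_id"], c) for c in numeric_cols for i in bad.index[bad[c]]]
        raise ValueError(f"{path}: non-numeric cells at (run_id, column) {cells}")
    frame[numeric_cols] = coerced
    table = DesignTable(frame, levels)
    if not table.is_box_behnken():
        warnings.warn(f"{path}: run table is not a 3-factor Box-Behnken design",
                      stacklevel=2)
    return table


def write_design_csv(table: DesignTable, path: str | Path) -> None:
    table.frame.to_csv(path, index=False)


def load_composition_csv(path: str | Path) -> pd.DataFrame:
    """Read a batch-composition table (batch_id, pct_fc, pct_fos, pct_md).

    Returns the frame with an added ``composition`` column of
    :class:`~fructanuf.core.Composition` objects (validated to sum to 100%).
    """
    frame = _read_csv(path)
    required = ["batch_id", "pct_fc", "pct_fos", "pct_md"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    frame["composition"] = [
        Composition.from_percent(fc=r.pct_fc, fos=r.pct_fos, md=r.pct_md)
        for r in frame.itertuples()
    ]
    return frame


def load_flux_curve_csv(path: str | Path) -> FluxCurve:
    """Read a flux curve (columns ``conc_kgm3`` and ``flux_m_s`` or ``flux_kghm2``)."""
    frame = _read_csv(path)
    if "conc_kgm3" not in frame.columns:
        raise ValueError(f"{path}: missing 'conc_kgm3' column")
    if "flux_m_s" in frame.columns:
        return FluxCurve(conc=tuple(frame["conc_kgm3"]), flux=tuple(frame["flux_m_s"]),
                         flux_unit="m_s")
    if "flux_kghm2" in frame.columns:
        return FluxCurve(conc=tuple(frame["conc_kgm3"]), flux=tuple(frame["flux_kghm2"]),
                         flux_unit="kg_h_m2")
    raise ValueError(f"{path}: need a 'flux_m_s' or 'flux_kghm2' column")


def load_profiles_csv(path: str | Path) -> pd.DataFrame:
    """Read a tidy observed-concentration table (time_s, stream, solute, conc_kgm3)."""
    frame = _read_csv(path)
    required = {"time_s", "stream", "solute", "conc_kgm3"}
    if not required <= set(frame.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(frame.columns))}")
    return frame


_SCENARIO_DEFAULTS: dict[str, Any] = {
    "driving_solute": "fc",
    "t_end_s": 3600.0,
    "v_min_frac": 0.05,
    "rtol": 1e-8,
    "atol": 1e-10,
}


def load_scenario(path: str | Path) -> tuple[UFSystemSpec, dict[str, Any]]:
    """Read a batch-run scenario from a YAML key-value file.

    Required keys: area_m2, v0_m3, c0_fc, c0_fos, ro_fc, ro_fos, k, c_lim.
    Optional: driving_solute, t_end_s, v_min_frac, rtol, atol.  Returns
    the system spec and the solver keyword arguments; every defaulted key
    is logged so runs are auditable.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    required = ["area_m2", "v0_m3", "c0_fc", "c0_fos", "ro_fc", "ro_fos", "k", "c_lim"]
    missing = [k for k in required if k not in cfg]
    if missing:
        raise ValueError(f"{path}: scenario missing keys {missing}")
    for key, default in _SCENARIO_DEFAULTS.items():
        if key not in cfg:
            logger.info("scenario %s: using default %s = %r", path, key, default)
            cfg[key] = default
    spec = UFSystemSpec(
        area=float(cfg["area_m2"]),
        v0=float(cfg["v0_m3"]),
        c0=SolutePair(fc=float(cfg["c0_fc"]), fos=float(cfg["c0_fos"])),
        ro=SolutePair(fc=float(cfg["ro_fc"]), fos=float(cfg["ro_fos"])),
        flux_params=FluxModelParams(k=float(cfg["k"]), c_lim=float(cfg["c_lim"]),
                                    driving_solute=cfg["driving_solute"]),
    )
    solver = {k: float(cfg[k]) for k in ("t_end_s", "v_min_frac", "rtol", "atol")}
    return spec, solver


def write_manifest(out_dir: str | Path, command: str, config: dict[str, Any],
                   seed: int | None = None) -> Path:
    """Write a JSON run manifest next to a command's outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "command": command,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "config": config,
        "seed": seed,
        "package_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / f"manifest_{command.replace(' ', '_')}.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
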