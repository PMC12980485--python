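"""CSV/JSON containers for titrations, echo trains, and analysis reports.

Dialects:

* titration CSV — columns ``lipid_mM,r2_obs_s-1,sigma_s-1`` (header required,
  UTF-8, '.' decimal); the sigma column may be absent, in which case sigmas
  default to 0 and a warning is logged;
* echo-train CSV — columns ``index,real,imag`` with a JSON sidecar holding
  the :class:`~memrelax.cpmg.CPMGConfig`;
* results — plain JSON with field names matching the dataclasses.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .binding import TitrationSeries
from .cpmg import CPMGConfig

__all__ = [
    "read_titration_csv",
    "write_titration_csv",
    "read_echo_train_csv",
    "write_echo_train_csv",
    "read_cpmg_config",
    "write_cpmg_config",
    "write_json",
    "write_report",
]

logger = logging.getLogger("memrelax")

TITRATION_COLUMNS = ("lipid_mM", "r2_obs_s-1", "sigma_s-1")


class ParseError(ValueError):
    """Malformed input file; message names the offending row/column."""


def _numeric_column(df: pd.DataFrame, col: str, path: Path) -> np.ndarray:
    values = pd.to_numeric(df[col], errors="coerce")
    bad = values.isna() & df[col].notna()
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ParseError(
            f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
            f"{col!r}, data row {row + 1}"
        )
    if values.isna().any():
        row = int(np.flatnonzero(values.isna())[0])
        raise ParseError(f"{path}: missing value in column {col!r}, data row {row + 1}")
    return values.to_numpy(dtype=float)


def read_titration_csv(path: str | Path) -> TitrationSeries:
    """Read a titration series; a missing sigma column defaults to zeros."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, encoding="utf-8")
    required = TITRATION_COLUMNS[:2]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    vt = _numeric_column(df, "lipid_mM", path)
    r2 = _numeric_column(df, "r2_obs_s-1", path)
    if "sigma_s-1" in df.columns:
        sigma = _numeric_column(df, "sigma_s-1", path)
    else:
        logger.warning("%s: no sigma column; uncertainties default to 0", path)
        sigma = np.zeros(vt.size)
    return TitrationSeries(Vt=tuple(vt), r2_obs=tuple(r2), sigma=tuple(sigma))


def write_titration_csv(series: TitrationSeries, path: str | Path) -> None:
    pd.DataFrame(
        {
            "lipid_mM": series.Vt,
            "r2_obs_s-1": series.r2_obs,
            "sigma_s-1": series.sigma,
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_echo_train_csv(path: str | Path) -> np.ndarray:
    """Read raw complex samples from an ``index,real,imag`` CSV."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, encoding="utf-8")
    for col in ("real", "imag"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    real = _numeric_column(df, "real", path)
    imag = _numeric_column(df, "imag", path)
    return real + 1j * imag


def write_echo_train_csv(raw: np.ndarray, path: str | Path) -> None:
    raw = np.asarray(raw, dtype=complex).reshape(-1)
    pd.DataFrame(
        {"index": np.arange(raw.size), "real": raw.real, "imag": raw.imag}
    ).to_csv(path, index=False, float_format="%.17g")


def read_cpmg_config(path: str | Path) -> CPMGConfig:
    with open(path, encoding="utf-8") as fh:
        return CPMGConfig.from_dict(json.load(fh))


def write_cpmg_config(cfg: CPMGConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(cfg.to_dict(), indent=1) + "\n")


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def _markdown_section(title: str, payload: dict) -> str:
    lines = [f"## {title}", "", "| quantity | value |", "| --- | --- |"]
    for key, value in payload.items():
        if isinstance(value, float):
            lines.append(f"| {key} | {value:.6g} |")
        else:
            lines.append(f"| {key} | {value} |")
    lines.append("")
    return "\n".join(lines)


def write_report(report: dict, out_dir: str | Path) -> tuple[Path, Path]:
    """Serialize an analysis report as JSON plus a Markdown summary.

    Every section of ``report`` whose value is a flat dict becomes a table in
    the Markdown file; the JSON file holds the full nested structure
    (including the provenance block of pinned constants).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    json_path = out / "report.json"
    write_json(report, json_path)
    md = ["# memrelax analysis report", ""]
    for title, payload in report.items():
        if isinstance(payload, dict) and all(
            not isinstance(v, (dict, list)) for v in payload.values()
        ):
            md.append(_markdown_section(title, payload))
        else:
            md.append(f"## {title}\n\n```json\n{json.dumps(payload, indent=1)}\n```\n")
    md_path = out / "report.md"
    md_path.write_text("\n".join(md))
    return json_path, md_path
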