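"""Plain-text interchange: titration CSV, cluster/isotherm export, configs.

CSV is the interchange format (no domain-standard wire format exists for
titration tables): required columns ``L_total`` and ``signal``, optional
``L_free`` and ``nu``, concentrations in µM.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .titration import TitrationDataset

__all__ = ["read_titration_csv", "write_titration_csv", "read_config", "write_report"]


def read_titration_csv(path, A_total: float, metadata: dict | None = None) -> TitrationDataset:
    """Read a titration table; strictly increasing L_total, >= 5 rows."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("L_total", "signal"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if len(df) < 5:
        raise ValueError(f"{path}: need >= 5 rows, got {len(df)}")
    L = df["L_total"].to_numpy(dtype=float)
    bad = np.flatnonzero(L < 0)
    if bad.size:
        raise ValueError(f"{path}: negative L_total at row {bad[0] + 1}")
    step_bad = np.flatnonzero(np.diff(L) <= 0)
    if step_bad.size:
        raise ValueError(
            f"{path}: L_total not strictly increasing at row {step_bad[0] + 2}"
        )
    return TitrationDataset(
        L_total=L,
        signal=df["signal"].to_numpy(dtype=float),
        A_total=A_total,
        L_free=df["L_free"].to_numpy(dtype=float) if "L_free" in df else None,
        nu=df["nu"].to_numpy(dtype=float) if "nu" in df else None,
        metadata=dict(metadata or {}),
    )


def write_titration_csv(dataset: TitrationDataset, path) -> None:
    """Write a dataset back to CSV (full float precision round trip)."""
    cols = {"L_total": dataset.L_total, "signal": dataset.signal}
    if dataset.L_free is not None:
        cols["L_free"] = dataset.L_free
    if dataset.nu is not None:
        cols["nu"] = dataset.nu
    # repr() is the shortest exact round-trip representation of a double
    lines = [",".join(cols)]
    for row in zip(*cols.values()):
        lines.append(",".join(repr(float(v)) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path) -> dict:
    """YAML or JSON run configuration."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def write_report(report: dict, path) -> None:
    """JSON report (fits, validation summaries, run logs)."""
    Path(path).write_text(json.dumps(report, indent=2, default=float) + "\n")
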