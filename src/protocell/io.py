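"""Result writers and readers: CSV for tables, JSON for single records.

Machine outputs keep full float precision (round-trips are exact); the
human-facing table printed by the CLI formats times with two decimals and
large counts in scientific notation.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable

import pandas as pd

from .balances import SolutionState
from .limits import LimitReport
from .solver import SweepResult


def write_state_json(state: SolutionState, path: str | Path) -> None:
    Path(path).write_text(json.dumps(state.to_dict(), indent=2, allow_nan=True))


def read_state_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def sweep_to_csv(result: SweepResult, path: str | Path) -> None:
    # 17 significant digits: binary64 round-trips exactly
    result.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_sweep_csv(path: str | Path) -> pd.DataFrame:
    # correctly rounded float parsing so written values read back exactly
    return pd.read_csv(path, float_precision="round_trip")


def limits_to_frame(reports: Iterable[LimitReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in reports])


def limits_to_csv(reports: Iterable[LimitReport], path: str | Path) -> None:
    limits_to_frame(reports).to_csv(path, index=False)


def limits_to_json(reports: Iterable[LimitReport], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([r.to_dict() for r in reports], indent=2)
    )


def format_count(x: float) -> str:
    """Human formatting: plain below 1e6, scientific above, inf as unbounded."""
    if math.isinf(x):
        return "unlimited"
    if x >= 1e6:
        return f"{x:.3e}"
    if x >= 100:
        return f"{x:,.0f}".replace(",", "")
    return f"{x:.2f}"


def format_time_s(x: float) -> str:
    return f"{x:.2f}"
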