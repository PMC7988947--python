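"""Report rendering: period-summary tables, funnel exports, reference pairs.

Deviations are displayed rounded half-away-from-zero to 1 decimal and MAPE
to 2 decimals (registry-table convention); all internal computation is done
unrounded.
"""
from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .validation import ValidationReport

__all__ = [
    "round_half_away",
    "load_printed_pairs",
    "render_summary",
    "write_with_metadata",
    "config_hash",
]


def round_half_away(x, ndigits: int = 0):
    """Round half away from zero (1.25 -> 1.3 at 1 digit, -1.25 -> -1.3)."""
    x = np.asarray(x, dtype=float)
    factor = 10.0**ndigits
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    return float(out) if out.ndim == 0 else out


def load_printed_pairs(kind: str = "period") -> pd.DataFrame:
    """Bundled reference pairs of observed and expected incident cases from
    the Granada registry back-validation exercise (2004-2013).

    kind="period": per sex and site, period totals with the published
    deviation, MAPE and best-scenario code.
    kind="yearly": all-sites yearly pairs per sex.

    These printed integers exercise the deviation/MAPE arithmetic
    independently of any model fitting.
    """
    name = {"period": "printed_pairs_period.csv", "yearly": "printed_pairs_yearly.csv"}[kind]
    with resources.files("imrest.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def render_summary(report: ValidationReport) -> pd.DataFrame:
    """Summary table per sex and site: observed, expected, period deviation
    (1 decimal), best-scenario MAPE (2 decimals) and the scenario code."""
    summ = report.summary().copy()
    summ["relative_deviation"] = [round_half_away(v, 1) for v in summ["relative_deviation"]]
    summ["mape"] = [round_half_away(v, 2) for v in summ["mape"]]
    summ["observed"] = summ["observed"].round().astype(int)
    summ["expected"] = summ["expected"].round().astype(int)
    return summ


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def write_with_metadata(
    df: pd.DataFrame, path: str | Path, seed: int | None = None,
    config: dict | None = None, extra: Iterable[str] = (),
) -> None:
    """Write a CSV with a commented metadata header (version, config hash,
    seed) so any output can be rerun exactly."""
    from . import __version__

    lines = [f"imrest version={__version__}"]
    if config is not None:
        lines.append(f"config_hash={config_hash(config)}")
    if seed is not None:
        lines.append(f"seed={seed}")
    lines.extend(extra)
    with open(path, "w") as fh:
        for line in lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
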