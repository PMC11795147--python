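"""Particle-table readers and report writers.

Particle tables are CSV or TSV with header columns ``length_um`` and
``width_um`` (required) plus optional ``mineral_class``, ``density``,
``dataset_id`` and ``habit``.  Dimensions are micrometres end-to-end; no
unit conversion happens downstream.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import CLASS_DEFAULT_DENSITY, MineralClass

logger = logging.getLogger("empdcc")

__all__ = ["read_particles", "write_report", "FormatError"]

REQUIRED_COLUMNS = ("length_um", "width_um")
REPORT_SCHEMA_VERSION = 1


class FormatError(ValueError):
    pass


def _sniff_sep(path: Path) -> str:
    head = path.read_text().splitlines()[0] if path.stat().st_size else ""
    return "\t" if head.count("\t") >= head.count(",") and "\t" in head else ","


def read_particles(path, dialect: str | None = None) -> dict[str, pd.DataFrame]:
    """Read a particle table, grouped by ``dataset_id``.

    ``dialect`` may be "csv" or "tsv"; by default the delimiter is sniffed
    from the header line.  Rows with missing or non-positive dimensions are
    rejected and logged with their line numbers.  Unknown mineral classes
    fall back to ``other_nonserpentine`` with a warning.
    """
    path = Path(path)
    sep = {"csv": ",", "tsv": "\t", None: _sniff_sep(path)}[dialect]
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required columns: {', '.join(missing)}")
    for col in REQUIRED_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df["length_um"].isna() | df["width_um"].isna() | (df["length_um"] <= 0) | (df["width_um"] <= 0)
    if bad.any():
        for idx in df.index[bad]:
            logger.warning("%s: rejected malformed particle row at line %d", path.name, idx + 2)
        df = df.loc[~bad]
    if "mineral_class" not in df.columns:
        df["mineral_class"] = MineralClass.OTHER_NONSERPENTINE.value
    else:
        known = {c.value for c in MineralClass}
        unknown = ~df["mineral_class"].isin(known)
        if unknown.any():
            logger.warning(
                "%s: %d rows with unknown mineral_class defaulted to other_nonserpentine",
                path.name, int(unknown.sum()),
            )
            df.loc[unknown, "mineral_class"] = MineralClass.OTHER_NONSERPENTINE.value
    if "density" not in df.columns:
        df["density"] = [
            CLASS_DEFAULT_DENSITY[MineralClass(c)] for c in df["mineral_class"]
        ]
    if "dataset_id" not in df.columns:
        df["dataset_id"] = path.stem
    return {str(k): g.reset_index(drop=True) for k, g in df.groupby("dataset_id", sort=False)}


def write_report(summaries, path, calls=None, potencies=None, fmt: str = "tsv") -> Path:
    """Write a per-dataset report as TSV or JSON.

    ``summaries`` is a list of DatasetSummary; ``calls`` and ``potencies``
    are optional dicts keyed by dataset_id (HabitCall / potency dicts).
    Numbers are serialised at full precision.
    """
    path = Path(path)
    calls = calls or {}
    potencies = potencies or {}
    for mapping, label in ((calls, "habit call"), (potencies, "potency")):
        stray = set(mapping) - {s.dataset_id for s in summaries}
        if stray:
            raise ValueError(f"{label} for unknown dataset ids: {sorted(stray)}")
    rows = []
    for s in summaries:
        row = s.as_dict()
        call = calls.get(s.dataset_id)
        if call is not None:
            row.update(
                habit_call=call.label.value,
                rule_fired=call.rule_fired,
                boundary_margin=call.boundary_margin,
            )
        row.update(potencies.get(s.dataset_id, {}))
        rows.append(row)
    if fmt == "tsv":
        cols = list(rows[0]) if rows else [
            "dataset_id", "n_particles", "criteria_fraction", "empa", "pearson_index"
        ]
        pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        path.write_text(
            json.dumps({"schema_version": REPORT_SCHEMA_VERSION, "datasets": rows}, indent=2)
        )
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    return path
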