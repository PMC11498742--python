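"""File formats: model YAML, condition/measurement TSV tables, report output.

The measurement and condition tables follow PEtab column naming
(observableId, simulationConditionId, preequilibrationConditionId, time,
measurement), restricted to the subset this package supports. ``time = inf``
marks steady-state (post-equilibration) rows. Full PEtab (SBML models,
noiseFormula overrides, observableParameters) is out of scope and rejected
with a clear message.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError, ValidationError
from .model import Condition, OdeModel, parse_model

__all__ = [
    "Dataset",
    "read_model",
    "model_to_document",
    "write_model",
    "read_conditions",
    "write_conditions",
    "read_measurements",
    "write_measurements",
    "build_dataset",
    "write_report",
    "read_report",
]

MEASUREMENT_COLUMNS = ("observableId", "simulationConditionId", "time", "measurement")
_UNSUPPORTED_PETAB = ("observableParameters", "noiseParameters", "noiseFormula", "datasetId")


@dataclass
class Dataset:
    """Conditions plus a normalized measurement table.

    ``tasks()`` yields one simulation task per (condition, pre-equilibration
    condition) combination with its measurement rows, in a deterministic
    order.
    """

    conditions: dict
    measurements: pd.DataFrame

    def tasks(self):
        df = self.measurements
        keys = []
        for _, row in df.iterrows():
            key = (row["simulationConditionId"], row.get("preequilibrationConditionId"))
            if key not in keys:
                keys.append(key)
        for cond_id, preeq_id in keys:
            mask = (df["simulationConditionId"] == cond_id) & (
                df["preequilibrationConditionId"].map(lambda v: v == preeq_id)
            )
            rows = df[mask].copy()
            cond = self.conditions[cond_id]
            preeq = self.conditions[preeq_id] if preeq_id else None
            yield cond, preeq, rows

    @property
    def requires_posteq(self) -> bool:
        return bool(np.isinf(self.measurements["time"]).any())


def read_model(path) -> OdeModel:
    """Load a model from a YAML file."""
    return parse_model(Path(path).read_text())


def model_to_document(model: OdeModel) -> dict:
    """Serialize a model back to the YAML dialect (expressions as strings)."""
    return {
        "name": model.name,
        "states": [
            {"name": s, "init": str(e)}
            for s, e in zip(model.state_names, model.init_exprs)
        ],
        "parameters": [
            {"name": p.name, "lower": p.lower, "upper": p.upper, "scale": p.scale}
            for p in model.parameters
        ],
        "inputs": list(model.input_names),
        "rates": {s: str(e) for s, e in zip(model.state_names, model.rhs_exprs)},
        "observables": [
            {
                "name": o.name,
                "formula": str(o.formula),
                "noise_formula": str(o.noise_formula),
            }
            for o in model.observables
        ],
    }


def write_model(model: OdeModel, path):
    Path(path).write_text(yaml.safe_dump(model_to_document(model), sort_keys=False))


def read_conditions(path) -> dict:
    """Read a condition table (TSV): conditionId, one column per input, and an
    optional preequilibrationConditionId column."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "conditionId" not in df.columns:
        raise SchemaError("condition table must have a 'conditionId' column")
    input_cols = [
        c
        for c in df.columns
        if c not in ("conditionId", "preequilibrationConditionId")
    ]
    conditions = {}
    for _, row in df.iterrows():
        cid = row["conditionId"]
        preeq = row.get("preequilibrationConditionId")
        if isinstance(preeq, float) and math.isnan(preeq):
            preeq = None
        preeq = preeq if preeq else None
        conditions[cid] = Condition(
            condition_id=cid,
            input_values={c: float(row[c]) for c in input_cols},
            preeq_condition_id=preeq,
        )
    return conditions


def write_conditions(conditions: dict, path, input_names=None):
    rows = []
    has_preeq = any(c.preeq_condition_id for c in conditions.values())
    for cid, cond in conditions.items():
        row = {"conditionId": cid}
        names = input_names if input_names is not None else sorted(cond.input_values)
        for n in names:
            row[n] = repr(float(cond.input_values[n]))
        if has_preeq:
            row["preequilibrationConditionId"] = cond.preeq_condition_id or ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _parse_time(value, row_number: int) -> float:
    if isinstance(value, str):
        v = value.strip().lower()
        if v in ("inf", "+inf", "infinity"):
            return math.inf
        value = float(value)
    t = float(value)
    if math.isnan(t):
        raise SchemaError(f"row {row_number}: time must be a number or 'inf'")
    if t < 0 and not math.isinf(t):
        raise SchemaError(f"row {row_number}: negative measurement time {t}")
    if math.isinf(t) and t < 0:
        raise SchemaError(f"row {row_number}: negative measurement time {t}")
    return t


def read_measurements(path) -> pd.DataFrame:
    """Read a measurement table (TSV) into the normalized in-memory form.

    Columns: observableId, simulationConditionId, optional
    preequilibrationConditionId (empty allowed), time (float or literal
    ``inf``, mapped to the steady-state marker), measurement. Rows are sorted
    per condition by time.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    unsupported = [c for c in df.columns if c in _UNSUPPORTED_PETAB]
    if unsupported:
        raise SchemaError(
            f"column(s) {unsupported} belong to full PEtab, which this package "
            "does not support; remove them or preprocess the table"
        )
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"measurement table misses column(s) {missing}")
    out = pd.DataFrame(
        {
            "observableId": df["observableId"].astype(str),
            "simulationConditionId": df["simulationConditionId"].astype(str),
            "preequilibrationConditionId": [
                (v if isinstance(v, str) and v.strip() else None)
                for v in df.get(
                    "preequilibrationConditionId", pd.Series([None] * len(df))
                )
            ],
            "time": [
                _parse_time(v, i + 2)  # +2: header line + 1-based file rows
                for i, v in enumerate(df["time"])
            ],
            "measurement": df["measurement"].astype(float),
        }
    )
    out = out.sort_values(
        ["simulationConditionId", "time"], kind="stable"
    ).reset_index(drop=True)
    return out


def write_measurements(measurements: pd.DataFrame, path):
    df = measurements.copy()
    df["time"] = [("inf" if math.isinf(t) else repr(float(t))) for t in df["time"]]
    df["measurement"] = [repr(float(v)) for v in df["measurement"]]
    df["preequilibrationConditionId"] = [
        (v if v else "") for v in df["preequilibrationConditionId"]
    ]
    df.to_csv(path, sep="\t", index=False)


def build_dataset(model: OdeModel, conditions: dict, measurements: pd.DataFrame) -> Dataset:
    """Validate ids and assemble a Dataset.

    The preequilibrationConditionId of a measurement row takes precedence
    over the default stored on its condition; pre-equilibration references
    must resolve and must not themselves require pre-equilibration (acyclic).
    """
    df = measurements.copy()
    if "preequilibrationConditionId" not in df.columns:
        df["preequilibrationConditionId"] = None
    known_obs = set(model.observable_names)
    for i, row in df.iterrows():
        if row["observableId"] not in known_obs:
            raise SchemaError(
                f"row {i}: unknown observable id {row['observableId']!r}"
            )
        cid = row["simulationConditionId"]
        if cid not in conditions:
            raise SchemaError(f"row {i}: unknown condition id {cid!r}")
        preeq = row["preequilibrationConditionId"]
        if preeq is None:
            preeq = conditions[cid].preeq_condition_id
            df.at[i, "preequilibrationConditionId"] = preeq
        if preeq is not None:
            if preeq not in conditions:
                raise SchemaError(
                    f"row {i}: unknown pre-equilibration condition id {preeq!r}"
                )
            if conditions[preeq].preeq_condition_id:
                raise ValidationError(
                    f"pre-equilibration condition {preeq!r} must not itself "
                    "reference a pre-equilibration condition"
                )
    for cond in conditions.values():
        model.condition_inputs(cond)  # all declared inputs assigned
    return Dataset(conditions=conditions, measurements=df)


# -- benchmark report serialization ---------------------------------------


def write_report(report, out_dir):
    """Write a BenchmarkReport as JSON (full) plus CSV summaries.

    Files: report.json, failure_rates.csv (percent per pair and category),
    gradient_agreement.csv, timings.csv. Numeric fields round-trip losslessly
    through the JSON file.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    d = report.to_dict()
    (out / "report.json").write_text(json.dumps(d, indent=2))

    rows = []
    for pair in report.pair_names:
        counts = report.failure_counts.get(pair, {})
        n_failed = sum(counts.values())
        row = {
            "pair": pair,
            "n_samples": report.n_samples,
            "failure_rate_percent": (
                100.0 * n_failed / report.n_samples if report.n_samples else 0.0
            ),
        }
        for cat, cnt in sorted(counts.items()):
            row[cat] = cnt
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "failure_rates.csv", index=False)

    rows = []
    for key, entry in report.agreement.items():
        rows.append({"pairs": key, **entry})
    pd.DataFrame(rows).to_csv(out / "gradient_agreement.csv", index=False)

    rows = []
    for pair, t in report.timings.items():
        rows.append({"pair": pair, **t})
    pd.DataFrame(rows).to_csv(out / "timings.csv", index=False)
    return out


def read_report(path):
    """Round-trip a report back from its JSON file."""
    from .bench import BenchmarkReport

    return BenchmarkReport.from_dict(json.loads(Path(path).read_text()))
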