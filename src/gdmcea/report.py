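"""Result tables and run manifests.

Exports are deterministic for a fixed input: fixed row/column order, full
numeric precision, plus a rounded presentation variant of the comparison
table. Timestamps live only in the run manifest.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .health_economics import ComparisonResult
from .model_inputs import ModelConfig
from .uncertainty import PsaSummary, TornadoEntry

__all__ = ["RunManifest", "comparison_table", "export_tables", "write_manifest"]

_OUTCOME_ROWS = [
    ("cases_gdm", "Cases of GDM"),
    ("cases_t2dm", "Cases of type 2 diabetes"),
    ("years_of_life_disc", "Years of life (discounted)"),
    ("years_with_t2dm_disc", "Years of life with T2DM (discounted)"),
    ("qalys_disc", "QALYs (discounted)"),
    ("nicu_scn_admissions", "NICU/SCN admissions"),
]
_COST_ROWS = [
    ("intervention", "Intervention cost"),
    ("pregnancy", "Pregnancy costs"),
    ("t2dm_management", "Type 2 diabetes management"),
    ("nicu_scn", "NICU/SCN costs"),
    ("societal_addons", "Societal add-on costs"),
]


@dataclass
class RunManifest:
    config: ModelConfig
    seed: int
    provenance: dict[str, str] = field(default_factory=dict)
    command: str = ""
    version: str = __version__
    timestamp: str = ""

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["config"] = dataclasses.asdict(self.config)
        return d


def write_manifest(manifest: RunManifest, outdir: str, name: str = "manifest") -> str:
    if not manifest.timestamp:
        manifest.timestamp = datetime.datetime.now(datetime.timezone.utc).isoformat()
    path = os.path.join(outdir, f"{name}.json")
    with open(path, "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path


def comparison_table(results: dict[str, ComparisonResult]) -> pd.DataFrame:
    """Table of usual-care totals and per-subgroup incremental results.

    Rows: health outcomes, cost categories, per-woman increments, ICER, ROI.
    Columns: 'usual_care' (from the first result) then one per subgroup.
    """
    first = next(iter(results.values()))
    uc = first.arms["usual_care"]
    rows: dict[str, dict] = {}

    def put(row, col, value):
        rows.setdefault(row, {})[col] = value

    for attr, label in _OUTCOME_ROWS:
        put(label, "usual_care", getattr(uc.outcomes, attr))
    for attr, label in _COST_ROWS:
        put(label, "usual_care", getattr(uc.costs, attr))
    put("Total healthcare costs", "usual_care", uc.costs.total_healthcare)

    for sg, res in results.items():
        put("Cases of GDM", sg, res.delta_cases_gdm)
        put("Cases of type 2 diabetes", sg, res.delta_cases_t2dm)
        put("Years of life (discounted)", sg, res.delta_years_of_life_disc)
        put("Years of life with T2DM (discounted)", sg, res.delta_years_with_t2dm_disc)
        put("QALYs (discounted)", sg, res.delta_qalys)
        put("NICU/SCN admissions", sg, res.delta_nicu_admissions)
        for attr, label in _COST_ROWS:
            put(label, sg, getattr(res.delta, attr))
        put("Total healthcare costs", sg, res.delta.total_healthcare)
        put("Incremental QALYs per woman", sg, res.delta_qalys_per_woman)
        put("Incremental cost per woman", sg, res.delta_cost_per_woman)
        put("ICER", sg, res.icer)
        put("ROI ratio", sg, res.roi)

    order = ([label for _, label in _OUTCOME_ROWS]
             + [label for _, label in _COST_ROWS]
             + ["Total healthcare costs", "Incremental QALYs per woman",
                "Incremental cost per woman", "ICER", "ROI ratio"])
    cols = ["usual_care"] + list(results)
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(order)[cols]
    df.index.name = "outcome"
    return df


def _rounded(df: pd.DataFrame) -> pd.DataFrame:
    def fmt(x):
        if isinstance(x, str) or x is None:
            return x
        if isinstance(x, float) and np.isnan(x):
            return ""
        if abs(x) >= 1000:
            return f"{x:,.0f}"
        return f"{x:,.3g}"
    return df.map(fmt)


def export_tables(obj, outdir: str, name: str) -> list[str]:
    """Write ``obj`` (comparison table, PSA summary or tornado list) to CSV + JSON."""
    os.makedirs(outdir, exist_ok=True)
    written = []

    if isinstance(obj, dict) and obj and isinstance(next(iter(obj.values())), ComparisonResult):
        df = comparison_table(obj)
        csv_path = os.path.join(outdir, f"{name}.csv")
        df.to_csv(csv_path)
        written.append(csv_path)
        rounded_path = os.path.join(outdir, f"{name}_rounded.csv")
        _rounded(df).to_csv(rounded_path)
        written.append(rounded_path)
        json_path = os.path.join(outdir, f"{name}.json")
        with open(json_path, "w") as fh:
            json.dump(json.loads(df.to_json(orient="index")), fh, indent=1, sort_keys=True)
            fh.write("\n")
        written.append(json_path)
        return written

    if isinstance(obj, PsaSummary):
        df = pd.DataFrame({"delta_cost_per_woman": obj.delta_cost_per_woman,
                           "delta_qalys_per_woman": obj.delta_qalys_per_woman,
                           "roi": obj.roi})
        csv_path = os.path.join(outdir, f"{name}_iterations.csv")
        df.to_csv(csv_path, index_label="iteration")
        written.append(csv_path)
        summary = {
            "n_iterations": obj.n_iterations, "seed": obj.seed,
            "n_resampled": obj.n_resampled,
            "quadrant_fractions": obj.quadrant_fractions, "ci95": obj.ci95,
            "mean_delta_cost_per_woman": obj.mean_delta_cost_per_woman,
            "mean_delta_qalys_per_woman": obj.mean_delta_qalys_per_woman,
            "mean_roi": float(obj.roi.mean()),
        }
        json_path = os.path.join(outdir, f"{name}.json")
        with open(json_path, "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
            fh.write("\n")
        written.append(json_path)
        return written

    if isinstance(obj, list) and obj and isinstance(obj[0], TornadoEntry):
        recs = []
        for e in obj:
            recs.append({"parameter": e.parameter, "low_input": e.low_input,
                         "high_input": e.high_input,
                         "delta_cost_pw_low": e.low_result["delta_cost_per_woman"],
                         "delta_cost_pw_high": e.high_result["delta_cost_per_woman"],
                         "delta_qalys_pw_low": e.low_result["delta_qalys_per_woman"],
                         "delta_qalys_pw_high": e.high_result["delta_qalys_per_woman"],
                         "icer_low": e.low_result["icer"], "icer_high": e.high_result["icer"],
                         "span": e.span})
        df = pd.DataFrame.from_records(recs)
        csv_path = os.path.join(outdir, f"{name}.csv")
        df.to_csv(csv_path, index=False)
        written.append(csv_path)
        json_path = os.path.join(outdir, f"{name}.json")
        with open(json_path, "w") as fh:
            json.dump(recs, fh, indent=1, sort_keys=True, default=str)
            fh.write("\n")
        written.append(json_path)
        return written

    raise TypeError(f"don't know how to export {type(obj)!r}")
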