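"""File formats: count-data CSVs, design/parameter configs, result tables.

Counts are exchanged as two CSV tables (comma-separated, header row, UTF-8,
1-based indices matching the (k, t) notation):

* marks: ``period,occasion,count`` -- individuals first marked per occasion;
* recaptures: ``mark_period,recap_period,occasion,count`` -- recaptures of
  period-``k`` cohorts per occasion.

Missing rows read as zero; structural-zero cells (``recap_period <
mark_period`` or same period with ``occasion = 1``) must be absent.  The
study design and true/initial parameters travel as JSON or YAML mappings.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import StudyDesign
from .matrices import CountData, count_index
from .parameters import ParameterSet


def _load_mapping(path):
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def read_design(path) -> StudyDesign:
    return StudyDesign.from_dict(_load_mapping(path))


def write_design(design: StudyDesign, path):
    Path(path).write_text(json.dumps(design.to_dict(), indent=1) + "\n")


def read_theta(path, design: StudyDesign) -> ParameterSet:
    d = _load_mapping(path)
    return ParameterSet(N=float(d["N"]), p=np.asarray(d["p"], float),
                        phi=np.asarray(d.get("phi", []), float),
                        beta=np.asarray(d["beta"], float)
                        ).validate_against(design)


def read_count_data(design_path, marks_path, recaptures_path) -> CountData:
    """Read and validate a batch-mark dataset from its three files."""
    design = read_design(design_path)
    marks = pd.read_csv(marks_path)
    recaps = pd.read_csv(recaptures_path)

    need_m = {"period", "occasion", "count"}
    if not need_m.issubset(marks.columns):
        raise ValueError(
            f"marks table needs columns {sorted(need_m)}; per-occasion data "
            f"are required (per-period aggregates are not accepted)")
    need_n = {"mark_period", "recap_period", "occasion", "count"}
    if not need_n.issubset(recaps.columns):
        raise ValueError(
            f"recaptures table needs columns {sorted(need_n)}; per-occasion "
            f"data are required (per-period aggregates are not accepted)")

    m_index, n_index = count_index(design)
    m = np.zeros(len(m_index), dtype=np.int64)
    pos_m = {kt: i for i, kt in enumerate(m_index)}
    seen = set()
    for row in marks.itertuples(index=False):
        key = (int(row.period), int(row.occasion))
        if key in seen:
            raise ValueError(f"duplicate marks row for (period, occasion)={key}")
        seen.add(key)
        if key not in pos_m:
            raise ValueError(f"marks row {key} outside the study design")
        m[pos_m[key]] = int(row.count)

    n = np.zeros(len(n_index), dtype=np.int64)
    pos_n = {kjt: i for i, kjt in enumerate(n_index)}
    seen = set()
    for row in recaps.itertuples(index=False):
        key = (int(row.mark_period), int(row.recap_period), int(row.occasion))
        if key in seen:
            raise ValueError(f"duplicate recaptures row for (k, j, t)={key}")
        seen.add(key)
        k, j, t = key
        if j < k or (j == k and t == 1):
            raise ValueError(
                f"recaptures row (k, j, t)={key} is a structural zero: "
                f"recaptures require j > k, or j = k with t >= 2")
        if key not in pos_n:
            raise ValueError(f"recaptures row {key} outside the study design")
        n[pos_n[key]] = int(row.count)
    return CountData(design=design, m=m, n=n)


def write_count_data(data: CountData, out_dir):
    """Write the design + marks + recaptures files; returns the three paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design_path = out / "design.json"
    write_design(data.design, design_path)
    m_index, n_index = count_index(data.design)
    marks = pd.DataFrame([(k, t, v) for (k, t), v in zip(m_index, data.m)],
                         columns=["period", "occasion", "count"])
    recaps = pd.DataFrame([(k, j, t, v)
                           for (k, j, t), v in zip(n_index, data.n)],
                          columns=["mark_period", "recap_period",
                                   "occasion", "count"])
    marks_path = out / "marks.csv"
    recaps_path = out / "recaptures.csv"
    marks.to_csv(marks_path, index=False)
    recaps.to_csv(recaps_path, index=False)
    return design_path, marks_path, recaps_path


def read_period_summary(path) -> pd.DataFrame:
    """Read a per-period study summary table (tab-separated).

    Layout: one row per marking period with a ``Marks`` column and one column
    per recapture period; blank cells are structural zeros.  This aggregated
    format summarizes a study but is NOT sufficient to fit the model (use the
    per-occasion CSVs for that).
    """
    df = pd.read_csv(path, sep="\t")
    if "Marks" not in df.columns:
        raise ValueError("period summary needs a 'Marks' column")
    return df


def summary_totals(df: pd.DataFrame):
    """Total individuals marked and total recaptures in a period summary."""
    recap_cols = [c for c in df.columns if c not in ("Period", "Marks")]
    marked = int(df["Marks"].sum())
    recaptured = int(np.nansum(df[recap_cols].to_numpy(dtype=float)))
    return marked, recaptured


def write_fit_result(fit, out_prefix):
    """Serialize a fit to ``<prefix>.json`` and a flat ``<prefix>.tsv``."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    json_path = out_prefix.with_suffix(".json")
    json_path.write_text(json.dumps(fit.to_dict(), indent=1, default=float)
                         + "\n")
    tab = pd.concat([fit.params_table(), fit.derived_abundance()],
                    ignore_index=True)
    tsv_path = out_prefix.with_suffix(".tsv")
    tab.to_csv(tsv_path, sep="\t", index=False)
    return json_path, tsv_path


def write_study_summary(summary, path):
    """Study summary as TSV: Parameter, True, Mean/RMSE/CIC%/CIW per variant."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    summary.to_frame().to_csv(path, sep="\t", index=False)
    return path


def write_selection_table(table: pd.DataFrame, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)
    return path
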