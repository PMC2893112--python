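"""Readers, writers and run configuration.

File formats are deliberately plain:

* **Trace files** — one trace per file, two-column CSV
  ``data_point_index,intensity`` with a header line.
* **Manifest** — TSV with columns ``sample_id``, ``locus_id``,
  ``trace_path``, ``reference_path`` mapping samples to trace files.
* **CohortTable** — TSV (or CSV), one row per patient, columns
  ``patient_id``, ``set``, ``time_months``, ``event``, the clinical
  covariates, and one score column per locus; missing = empty cell.  A
  ``supplementary-xls`` dialect reads a spreadsheet through a small
  column-mapping file instead of hard-coded headers, since supplementary
  spreadsheets rarely share a layout.
* **Reports** — every analysis is written twice: a TSV with the field's
  table conventions (p-values to 4 decimals, hazard ratios and AUCs to 2)
  and a JSON with full precision that round-trips exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import EmptyTable, IOFailure, MissingRequiredColumn
from .screen import ScreenConfig, ScreenReport
from .survival import CoxFit, KMCurve, TdROC
from .traces import AmpliconSpec, Trace, TraceConfig, TraceScorer

logger = logging.getLogger("methylscreen")

REQUIRED_COHORT_COLUMNS = ("patient_id", "set", "time_months", "event")

# TSV rendering conventions: p-values to 4 decimals, hazard ratios and
# their CI bounds to 1 (3.7, not 3.68), AUC to 2
_P_COLS = {"logrank_p", "adjusted_p", "wald_p", "lrt_p", "p_value"}
_ONE_DEC_COLS = {"hr", "hazard_ratio", "ci_lower", "ci_upper"}
_TWO_DEC_COLS = {"auc"}


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """Flat, file-serializable configuration of a pipeline run."""

    horizon: float = 60.0
    alpha: float = 0.05
    auc_threshold: float = 0.6
    stage1_theta: float = 0.2
    stage1_stat: str = "range"
    adjusted_alpha: float = 0.05
    roc_method: str = "km"
    ties: str = "efron"
    seed: int = 0

    def screen_config(self) -> ScreenConfig:
        return ScreenConfig(horizon=self.horizon, alpha=self.alpha,
                            auc_threshold=self.auc_threshold,
                            stage1_theta=self.stage1_theta,
                            stage1_stat=self.stage1_stat,
                            adjusted_alpha=self.adjusted_alpha,
                            roc_method=self.roc_method)

    def to_file(self, path) -> None:
        path = Path(path)
        payload = dataclasses.asdict(self)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(payload, sort_keys=True))
        else:
            path.write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        payload = (yaml.safe_load(text) if path.suffix in (".yaml", ".yml")
                   else json.loads(text))
        return cls(**payload)


# ---------------------------------------------------------------------------
# Traces
# ---------------------------------------------------------------------------

def write_trace_csv(trace: Trace, path) -> None:
    df = pd.DataFrame({"data_point_index": np.arange(len(trace)),
                       "intensity": trace.intensities})
    df.to_csv(path, index=False)


def read_trace_csv(path, sample_id=None, locus_id="", is_reference=False) -> Trace:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise IOFailure(f"{path}: expected two columns (index, intensity)")
    y = df.iloc[:, 1].to_numpy(float)
    if sample_id is None:
        sample_id = Path(path).stem
    return Trace(sample_id=str(sample_id), locus_id=str(locus_id),
                 intensities=y, is_reference=is_reference)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    needed = {"sample_id", "locus_id", "trace_path", "reference_path"}
    missing = needed - set(df.columns)
    if missing:
        raise MissingRequiredColumn(f"manifest lacks columns {sorted(missing)}")
    return df


def score_manifest(manifest: pd.DataFrame, specs: dict[str, AmpliconSpec],
                   config: TraceConfig = TraceConfig(),
                   base_dir=None) -> pd.DataFrame:
    """Score every sample trace listed in a manifest.

    One :class:`TraceScorer` is built per (locus, reference) pair so the
    reference is processed once.  Returns a table of
    (sample_id, locus_id, score, n_sites_used, shift_applied, tag_area).
    """
    base = Path(base_dir) if base_dir is not None else Path(".")
    scorers: dict[tuple[str, str], TraceScorer] = {}
    rows = []
    for rec in manifest.itertuples(index=False):
        locus = str(rec.locus_id)
        key = (locus, str(rec.reference_path))
        if key not in scorers:
            ref = read_trace_csv(base / rec.reference_path, locus_id=locus,
                                 is_reference=True)
            scorers[key] = TraceScorer(ref, specs[locus], config)
        trace = read_trace_csv(base / rec.trace_path, sample_id=rec.sample_id,
                               locus_id=locus)
        score = scorers[key].score(trace)
        rows.append({"sample_id": score.sample_id, "locus_id": score.locus_id,
                     "score": score.score, "n_sites_used": score.n_sites_used,
                     "shift_applied": score.shift_applied,
                     "tag_area": score.tag_area})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

def read_cohort_table(path, dialect="tsv", mapping=None) -> pd.DataFrame:
    """Read and validate a cohort table.

    ``dialect`` is ``tsv``, ``csv`` or ``supplementary-xls`` (a
    spreadsheet read through ``mapping``: a dict, or path to a YAML/JSON
    file, sending canonical column names to the spreadsheet's headers).
    Unparseable numeric cells become missing, with a logged warning count.
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
    elif dialect == "csv":
        df = pd.read_csv(path)
    elif dialect == "supplementary-xls":
        df = pd.read_excel(path)
        if mapping is not None:
            if not isinstance(mapping, dict):
                mpath = Path(mapping)
                text = mpath.read_text()
                mapping = (yaml.safe_load(text) if mpath.suffix in (".yaml", ".yml")
                           else json.loads(text))
            df = df.rename(columns={v: k for k, v in mapping.items()})
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise MissingRequiredColumn(f"cohort table lacks columns {missing}")
    if df.shape[0] == 0:
        raise EmptyTable(f"{path}: no patient rows")

    n_bad = 0
    numeric_cols = [c for c in df.columns if c not in ("patient_id", "set")]
    for col in numeric_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        n_bad += int((coerced.isna() & df[col].notna()).sum())
        df[col] = coerced
    if n_bad:
        logger.warning("cohort table %s: %d unparseable cells set to missing",
                       path, n_bad)
    return df


def write_cohort_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _render_tsv_frame(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if col in _P_COLS:
            out[col] = out[col].map(
                lambda v: "" if pd.isna(v) else f"{v:.4f}")
        elif col in _ONE_DEC_COLS:
            out[col] = out[col].map(
                lambda v: "" if pd.isna(v) else f"{v:.1f}")
        elif col in _TWO_DEC_COLS:
            out[col] = out[col].map(
                lambda v: "" if pd.isna(v) else f"{v:.2f}")
    return out


def _report_frames(report) -> dict[str, pd.DataFrame]:
    if isinstance(report, ScreenReport):
        return {"stage1": report.stage1, "stage2": report.stage2,
                "stage3": report.stage3}
    if isinstance(report, CoxFit):
        df = report.summary()
        df["lrt_stat"] = report.lrt_statistic
        df["lrt_p"] = report.lrt_p
        return {"cox": df}
    if isinstance(report, TdROC):
        df = pd.DataFrame({"cutpoint": report.cutpoints,
                           "sensitivity": report.sensitivity,
                           "specificity": report.specificity})
        df["auc"] = report.auc
        df["horizon"] = report.horizon
        return {"tdroc": df}
    if isinstance(report, KMCurve):
        return {"km": pd.DataFrame({"time": report.event_times,
                                    "at_risk": report.at_risk,
                                    "n_events": report.n_events,
                                    "survival": report.survival})}
    raise IOFailure(f"cannot serialize object of type {type(report).__name__}")


def _json_payload(report):
    if isinstance(report, ScreenReport):
        return json.loads(report.to_json())
    frames = _report_frames(report)
    payload = {name: df.to_dict(orient="records") for name, df in frames.items()}
    if isinstance(report, CoxFit):
        payload["meta"] = {"ties": report.ties, "n_used": report.n_used,
                           "n_events": report.n_events,
                           "lrt_statistic": report.lrt_statistic,
                           "lrt_p": report.lrt_p,
                           "log_likelihood": report.log_likelihood}
    return payload


def write_report(report, path_base) -> dict[str, Path]:
    """Write a report as TSV (table conventions) and JSON (full precision).

    ``path_base`` is the stem; one ``<stem>_<section>.tsv`` per section
    plus ``<stem>.json``.  Returns the written paths.
    """
    base = Path(path_base)
    base.parent.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    try:
        for name, df in _report_frames(report).items():
            p = base.parent / f"{base.name}_{name}.tsv"
            _render_tsv_frame(df).to_csv(p, sep="\t", index=False)
            written[name] = p
        jp = base.parent / f"{base.name}.json"
        jp.write_text(json.dumps(_json_payload(report), indent=2,
                                 sort_keys=True, default=float))
        written["json"] = jp
    except OSError as exc:
        raise IOFailure(str(exc)) from exc
    return written
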