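"""Three-stage methylation-biomarker screening cascade.

Candidate loci are filtered in three stages of increasing cost and
stringency:

1. **Pilot differential filter** — loci whose methylation scores show no
   apparent spread across a small pilot panel (default: 12 samples) are
   dropped.  "Apparent differential methylation" is quantified here as
   the range (or optionally the standard deviation) of the pilot scores
   reaching a threshold theta; theta is a package parameter with no
   single field-standard value, and every report flags it as such.
2. **Training screen** — in the training cohort (which contains the pilot
   samples), each surviving locus is dichotomized at the *training*
   median, tested by log-rank, and its continuous score evaluated by
   time-dependent ROC at the configured horizon.  Candidates must have
   log-rank p < alpha AND AUC > the AUC threshold, both strict.
3. **Independent validation** — candidates are re-tested in a disjoint
   validation cohort, dichotomizing at the *validation* cohort's own
   median, with Bonferroni adjustment for the number of stage-2
   candidates.  The final call requires adjusted p < alpha.

Stage results are monotone by construction: validated loci are a subset
of stage-2 candidates, which are a subset of stage-1 survivors.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    CohortOverlap,
    DegenerateCutpoint,
    InsufficientPilotData,
    InvalidP,
)
from .simulate import LOCUS_PREFIX, RESERVED_COLUMNS
from .survival import dichotomize_at_median, logrank_test, td_roc


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and settings of the cascade.

    ``horizon`` is the ROC evaluation time in months.  ``stage1_theta``
    (dispersion threshold on the normalized score scale) has no
    field-standard value; reports carry a flag saying so.
    """

    horizon: float = 60.0
    alpha: float = 0.05
    auc_threshold: float = 0.6
    stage1_theta: float = 0.2
    stage1_stat: str = "range"      # or "sd"
    adjusted_alpha: float = 0.05
    roc_method: str = "km"          # or "nne"

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1 and 0 < self.adjusted_alpha < 1):
            raise ValueError("alpha thresholds must lie in (0, 1)")
        if not (0 <= self.auc_threshold <= 1):
            raise ValueError("auc_threshold must lie in [0, 1]")
        if self.stage1_stat not in ("range", "sd"):
            raise ValueError("stage1_stat must be 'range' or 'sd'")


@dataclass
class ScreenReport:
    """Per-locus statistics and pass/fail decisions of the whole cascade."""

    config: ScreenConfig
    stage1: pd.DataFrame
    stage2: pd.DataFrame
    stage3: pd.DataFrame
    counts: dict[str, int]
    notes: tuple[str, ...] = (
        "stage1_theta is a package parameter, not a field-standard value",
    )

    def validated_loci(self) -> list[str]:
        if self.stage3.empty:
            return []
        return list(self.stage3.loc[self.stage3["final_call"], "locus"])

    def to_json(self, indent: int = 2) -> str:
        payload = {
            "config": asdict(self.config),
            "counts": self.counts,
            "notes": list(self.notes),
            "stage1": self.stage1.to_dict(orient="records"),
            "stage2": self.stage2.to_dict(orient="records"),
            "stage3": self.stage3.to_dict(orient="records"),
        }
        return json.dumps(payload, indent=indent, sort_keys=True,
                          default=float)


def locus_columns(table: pd.DataFrame) -> list[str]:
    """Score columns of a cohort table (by the ``locus_`` naming convention,
    falling back to every non-reserved column)."""
    by_prefix = [c for c in table.columns if c.startswith(LOCUS_PREFIX)]
    if by_prefix:
        return by_prefix
    return [c for c in table.columns if c not in RESERVED_COLUMNS]


def stage1_differential_filter(pilot_scores: pd.DataFrame,
                               theta: float = 0.2,
                               stat: str = "range") -> pd.DataFrame:
    """Pass/fail per locus on pilot-panel score dispersion.

    ``pilot_scores`` holds one column per locus over the pilot samples.
    A locus passes iff its dispersion statistic is >= theta (boundary
    inclusive).  Raises :class:`InsufficientPilotData` if any locus has
    fewer than two non-missing pilot scores.
    """
    rows = []
    for locus in pilot_scores.columns:
        values = pilot_scores[locus].dropna().to_numpy(float)
        if values.size < 2:
            raise InsufficientPilotData(
                f"locus {locus}: {values.size} non-missing pilot scores")
        disp = float(np.ptp(values)) if stat == "range" else float(np.std(values, ddof=1))
        rows.append({"locus": locus, "dispersion": disp,
                     "statistic": stat, "stage1_pass": disp >= theta})
    return pd.DataFrame(rows)


def _locus_survival_stats(cohort: pd.DataFrame, locus: str, horizon: float,
                          roc_method: str, cutpoint_scores=None) -> dict:
    """Median-split log-rank p and continuous-score AUC for one locus."""
    sub = cohort[["time_months", "event", locus]].dropna()
    t = sub["time_months"].to_numpy(float)
    e = sub["event"].to_numpy(float)
    x = sub[locus].to_numpy(float)
    high, cut = dichotomize_at_median(x, cutpoint_scores)
    lr = logrank_test(t[~high], e[~high], t[high], e[high])
    roc = td_roc(t, e, x, horizon, method=roc_method)
    return {"locus": locus, "n_used": int(sub.shape[0]), "cutpoint": cut,
            "logrank_p": lr.p_value, "logrank_stat": lr.statistic,
            "auc": roc.auc}


def stage2_training_screen(training: pd.DataFrame, loci,
                           config: ScreenConfig = ScreenConfig()) -> pd.DataFrame:
    """Training-cohort screen of the stage-1 survivors.

    Dichotomizes at the training cohort's own median, applies the log-rank
    test, and computes the time-dependent AUC of the continuous score at
    ``config.horizon``.  Candidate iff p < alpha and AUC > auc_threshold
    (strict inequalities).  A degenerate median split fails the locus with
    its reason instead of aborting the screen.
    """
    rows = []
    for locus in loci:
        try:
            entry = _locus_survival_stats(training, locus, config.horizon,
                                          config.roc_method)
            entry["candidate"] = (entry["logrank_p"] < config.alpha
                                  and entry["auc"] > config.auc_threshold)
            entry["reason"] = ""
        except DegenerateCutpoint as exc:
            entry = {"locus": locus, "n_used": 0, "cutpoint": np.nan,
                     "logrank_p": np.nan, "logrank_stat": np.nan,
                     "auc": np.nan, "candidate": False,
                     "reason": f"degenerate cutpoint: {exc}"}
        rows.append(entry)
    return pd.DataFrame(rows)


def bonferroni_adjust(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, m * p)."""
    if not (0 <= p <= 1):
        raise InvalidP(f"p-value {p} outside [0, 1]")
    if m < 1:
        raise InvalidP(f"number of tests {m} must be >= 1")
    return min(1.0, m * p)


def stage3_validate(validation: pd.DataFrame, candidates,
                    config: ScreenConfig = ScreenConfig(),
                    training_ids=None) -> pd.DataFrame:
    """Independent validation of the stage-2 candidates.

    Uses the validation cohort's own median as the cut point and adjusts
    the log-rank p by Bonferroni with m = number of candidates.  With zero
    candidates the result is an empty table, not an error.

    Raises :class:`CohortOverlap` if ``training_ids`` is given and shares
    a patient with the validation cohort.
    """
    candidates = list(candidates)
    if training_ids is not None and "patient_id" in validation.columns:
        overlap = set(training_ids) & set(validation["patient_id"])
        if overlap:
            raise CohortOverlap(f"patients in both sets: {sorted(overlap)[:5]}")
    m = len(candidates)
    rows = []
    for locus in candidates:
        entry = _locus_survival_stats(validation, locus, config.horizon,
                                      config.roc_method)
        entry["m_tests"] = m
        entry["adjusted_p"] = bonferroni_adjust(entry["logrank_p"], m)
        entry["final_call"] = entry["adjusted_p"] < config.adjusted_alpha
        rows.append(entry)
    columns = ["locus", "n_used", "cutpoint", "logrank_p", "logrank_stat",
               "auc", "m_tests", "adjusted_p", "final_call"]
    return pd.DataFrame(rows, columns=columns)


def run_screen(cohort: pd.DataFrame, config: ScreenConfig = ScreenConfig(),
               loci=None) -> ScreenReport:
    """Execute the full cascade on a labelled cohort table.

    The ``set`` column must label every patient pilot, training or
    validation; training-set analyses pool the pilot and training rows
    (the pilot samples are part of the training cohort by design).
    Deterministic given the table and config.
    """
    if loci is None:
        loci = locus_columns(cohort)
    sets = cohort["set"]
    pilot = cohort.loc[sets == "pilot"]
    training = cohort.loc[sets.isin(["pilot", "training"])]
    validation = cohort.loc[sets == "validation"]

    stage1 = stage1_differential_filter(pilot[list(loci)], config.stage1_theta,
                                        config.stage1_stat)
    survivors = list(stage1.loc[stage1["stage1_pass"], "locus"])
    stage2 = stage2_training_screen(training, survivors, config)
    candidates = (list(stage2.loc[stage2["candidate"], "locus"])
                  if not stage2.empty else [])
    stage3 = stage3_validate(validation, candidates, config,
                             training_ids=training["patient_id"])
    counts = {
        "loci_in": len(list(loci)),
        "stage1_pass": len(survivors),
        "stage2_candidates": len(candidates),
        "validated": int(stage3["final_call"].sum()) if not stage3.empty else 0,
        "n_pilot": int(pilot.shape[0]),
        "n_training": int(training.shape[0]),
        "n_validation": int(validation.shape[0]),
    }
    return ScreenReport(config=config, stage1=stage1, stage2=stage2,
                        stage3=stage3, counts=counts)
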