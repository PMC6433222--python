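"""End-to-end analysis chain: simulate/ingest -> calibrate -> DIF/split ->
equate -> trajectories -> practice-effect report.

This is the programmatic equivalent of running the numbered analysis
scripts in sequence, packaged so tests and replication runs can execute
the whole chain on one cohort with one call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import dif_split, fit_battery, gbta, practice_effect, rasch_engine
from .dif_split import calibrate_with_collapse
from .rasch_engine import CalibrationResult, calibrate
from .synthetic_cohort import CohortSpec, FormPlan, ItemBank

__all__ = ["PipelineResult", "run_pipeline", "equated_total_scores"]


@dataclass
class PipelineResult:
    responses: pd.DataFrame
    calibration: CalibrationResult
    dif: dif_split.DIFResult
    audit: list[str]
    split_calibration: CalibrationResult
    equating: pd.DataFrame | None
    totals: pd.DataFrame
    model: gbta.TrajectoryModel
    selection_table: pd.DataFrame | None
    criterion: float
    ba: practice_effect.BlandAltman
    report: practice_effect.PracticeEffectReport


def equated_total_scores(
    calib: CalibrationResult,
    session_to_form: dict[int, str],
    occasions_months: dict[int, float],
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Equate each person-session raw total onto the reference-form scale.

    Builds per-form raw-to-reference tables from the split calibration and
    maps every person-session through its form's table.  If the
    calibration contains no split (form-varying) items, raw totals are
    used unchanged and the equating table is None.
    """
    bank = dif_split.split_bank_with_forms(calib, session_to_form)
    persons = calib.persons
    if bank.forms:
        tables = rasch_engine.equate_forms(bank)
        eq = rasch_engine.apply_equating(persons, tables, session_to_form)
        score = eq["equated"]
    else:
        tables = None
        eq = persons.copy()
        score = eq["raw_total"].astype(float)
    totals = pd.DataFrame(
        {
            "person_id": eq["person_id"],
            "session": eq["session"],
            "month": [occasions_months[int(s)] for s in eq["session"]],
            "score": score,
        }
    )
    return totals, tables


def run_pipeline(
    responses: pd.DataFrame,
    spec: CohortSpec,
    plan: FormPlan,
    *,
    n_groups: int | None = None,
    k_range: tuple[int, ...] = (1, 2, 3, 4),
    n_intervals: int = 5,
    n_starts: int = 5,
    dif_action: str = "split",
    seed: int = 0,
) -> PipelineResult:
    """Run the full analysis on one long-format response table.

    With ``n_groups=None`` (default) the number of trajectory groups is
    chosen by BIC over ``k_range``; pass an integer to fix it.
    """
    occasions_months = {
        s: float(m) for s, m in zip(
            sorted(plan.session_to_form), spec.occasions
        )
    }
    audit: list[str] = []

    calib, collapse_log = calibrate_with_collapse(responses, calibrate)
    audit += collapse_log

    dif = dif_split.dif_anova(calib, n_intervals=n_intervals)
    split_table, dif_log = dif_split.resolve_dif(responses, dif, action=dif_action)
    audit += dif_log
    if dif.flagged_items:
        split_calib, collapse_log = calibrate_with_collapse(split_table, calibrate)
        audit += collapse_log
    else:
        split_calib = calib

    totals, equating = equated_total_scores(
        split_calib, plan.session_to_form, occasions_months
    )

    if n_groups is None:
        model, selection_table = gbta.select_model(
            totals, K_range=k_range, n_starts=n_starts, seed=seed
        )
    else:
        model = gbta.fit_gbta(
            totals, K=n_groups, order=1, n_starts=n_starts, seed=seed
        )
        selection_table = None

    first_session = min(occasions_months)
    last_session = max(occasions_months)
    wide = totals.pivot_table(index="person_id", columns="session", values="score")
    baseline = wide[first_session].dropna()
    criterion = practice_effect.half_sd_criterion(baseline.to_numpy())
    paired = wide[[first_session, last_session]].dropna()
    ba = practice_effect.bland_altman(
        paired[first_session].to_numpy(),
        paired[last_session].to_numpy(),
        person_ids=list(paired.index),
    )
    overall = practice_effect.overall_first_last_test(
        paired[first_session].to_numpy(), paired[last_session].to_numpy()
    )
    months = occasions_months[last_session] - occasions_months[first_session]
    report = practice_effect.adjudicate(
        model, criterion, ba, period_months=months, overall=overall
    )
    return PipelineResult(
        responses=responses,
        calibration=calib,
        dif=dif,
        audit=audit,
        split_calibration=split_calib,
        equating=equating,
        totals=totals,
        model=model,
        selection_table=selection_table,
        criterion=criterion,
        ba=ba,
        report=report,
    )
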