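"""Differential item functioning by testing session, and item splitting.

An item functions differentially by session when, conditional on ability,
its residuals shift across sessions -- here a practice or alternate-form
effect.  Following standard Rasch practice the test is a two-way ANOVA of
standardized residuals on session and ability class interval: the session
main effect indicates uniform DIF, the session x interval interaction
non-uniform DIF, with Bonferroni adjustment across items.

The remedy for a flagged item is *splitting*: the item is replaced by one
pseudo-item per session, each observed only at its session, so every form
gets its own difficulty while per-person raw totals are conserved.
Deletion is available as an alternative resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

from .fit_battery import assign_class_intervals, DEFAULT_INTERVALS
from .rasch_engine import CalibrationResult, CategoryUseError, Item, ItemBank

__all__ = [
    "DIFResult",
    "dif_anova",
    "split_item_by_session",
    "resolve_dif",
    "collapse_categories",
    "split_bank_with_forms",
    "pseudo_item_id",
    "parse_pseudo_item",
]

SPLIT_SEP = "::s"


def pseudo_item_id(item_id: str, session: int) -> str:
    return f"{item_id}{SPLIT_SEP}{session}"


def parse_pseudo_item(pseudo: str) -> tuple[str, int | None]:
    """Return (base item id, session) -- session None if not a pseudo-item."""
    if SPLIT_SEP in pseudo:
        base, s = pseudo.rsplit(SPLIT_SEP, 1)
        try:
            return base, int(s)
        except ValueError:
            return pseudo, None
    return pseudo, None


@dataclass
class DIFResult:
    """Two-way ANOVA results per item, with Bonferroni-adjusted flags."""

    table: pd.DataFrame
    alpha: float = 0.05

    @property
    def flagged_items(self) -> list[str]:
        t = self.table
        return list(t.loc[t["uniform_flag"] | t["nonuniform_flag"], "item_id"])


def dif_anova(
    calib: CalibrationResult,
    n_intervals: int = DEFAULT_INTERVALS,
    alpha: float = 0.05,
) -> DIFResult:
    """Two-way ANOVA of residuals on session x class interval, per item.

    Requires a calibration pooled across at least two sessions.  Empty
    session-by-interval cells are simply absent from that item's design;
    a warning notes them.  F and p are reported for the session main
    effect (uniform DIF) and the interaction (non-uniform DIF), with
    Bonferroni-adjusted flags across items.
    """
    persons = calib.persons
    sessions = persons["session"].unique()
    if sessions.size < 2:
        raise ValueError("DIF by session needs at least 2 sessions")
    intervals = assign_class_intervals(persons["theta"].to_numpy(), n_intervals)

    z = calib.residuals
    n_items = len(calib.item_ids)
    rows = []
    for item in calib.item_ids:
        d = pd.DataFrame(
            {
                "z": z[item].to_numpy(),
                "session": persons["session"].to_numpy(),
                "interval": intervals,
            }
        ).dropna()
        if d["session"].nunique() < 2:
            rows.append(
                {"item_id": item, "f_session": np.nan, "p_session": np.nan,
                 "f_interaction": np.nan, "p_interaction": np.nan,
                 "p_session_bonf": np.nan, "p_interaction_bonf": np.nan,
                 "uniform_flag": False, "nonuniform_flag": False}
            )
            continue
        cells = d.groupby(["session", "interval"]).size()
        expected_cells = d["session"].nunique() * d["interval"].nunique()
        if len(cells) < expected_cells:
            warnings.warn(
                f"item {item!r}: {expected_cells - len(cells)} empty "
                "session-by-interval cell(s) dropped from the DIF test",
                stacklevel=2,
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = ols("z ~ C(session) * C(interval)", data=d).fit()
            tab = anova_lm(fit, typ=2)
        f_s = float(tab.loc["C(session)", "F"])
        p_s = float(tab.loc["C(session)", "PR(>F)"])
        key = "C(session):C(interval)"
        f_i = float(tab.loc[key, "F"]) if key in tab.index else np.nan
        p_i = float(tab.loc[key, "PR(>F)"]) if key in tab.index else np.nan
        p_s_b = min(1.0, p_s * n_items) if np.isfinite(p_s) else np.nan
        p_i_b = min(1.0, p_i * n_items) if np.isfinite(p_i) else np.nan
        rows.append(
            {
                "item_id": item,
                "f_session": f_s, "p_session": p_s,
                "f_interaction": f_i, "p_interaction": p_i,
                "p_session_bonf": p_s_b, "p_interaction_bonf": p_i_b,
                "uniform_flag": bool(np.isfinite(p_s_b) and p_s_b < alpha),
                "nonuniform_flag": bool(np.isfinite(p_i_b) and p_i_b < alpha),
            }
        )
    return DIFResult(table=pd.DataFrame(rows), alpha=alpha)


def split_item_by_session(table: pd.DataFrame, item_id: str) -> pd.DataFrame:
    """Replace an item by one session-specific pseudo-item per session.

    Each pseudo-item is observed only at its session and missing
    elsewhere; per-person raw totals are unchanged because responses are
    relabelled, never altered.
    """
    if item_id not in set(table["item_id"]):
        raise KeyError(f"unknown item {item_id!r}")
    sub = table["item_id"] == item_id
    if table.loc[sub, "session"].nunique() < 2:
        raise ValueError(f"item {item_id!r} present at fewer than 2 sessions")
    out = table.copy()
    out.loc[sub, "item_id"] = [
        pseudo_item_id(item_id, int(s)) for s in out.loc[sub, "session"]
    ]
    return out


def resolve_dif(
    table: pd.DataFrame,
    dif: DIFResult,
    action: str = "split",
) -> tuple[pd.DataFrame, list[str]]:
    """Apply the configured remedy to every flagged item; log each action.

    ``action='split'`` (default) splits flagged items by session;
    ``action='delete'`` removes them.  Returns the transformed table and
    an audit log.  Intended use is one pass: split, recalibrate, retest.
    """
    if action not in {"split", "delete"}:
        raise ValueError("action must be 'split' or 'delete'")
    audit: list[str] = []
    out = table
    for item in dif.flagged_items:
        row = dif.table.set_index("item_id").loc[item]
        kind = "uniform" if row["uniform_flag"] else "non-uniform"
        if action == "split":
            out = split_item_by_session(out, item)
            audit.append(f"split item {item!r} by session ({kind} DIF)")
        else:
            out = out.loc[out["item_id"] != item].reset_index(drop=True)
            audit.append(f"deleted item {item!r} ({kind} DIF)")
    if not audit:
        audit.append("no items flagged; table unchanged")
        out = out.copy()
    return out, audit


def collapse_categories(table: pd.DataFrame, item_id: str) -> pd.DataFrame:
    """Re-code an item's responses to consecutive observed categories.

    The deliberate remedy for never-used categories: observed response
    values are ranked and mapped to 0..k-1, preserving order.  The item's
    maximum (and so the raw-total ceiling) shrinks accordingly.
    """
    sub = table["item_id"] == item_id
    if not sub.any():
        raise KeyError(f"unknown item {item_id!r}")
    observed = np.sort(table.loc[sub, "response"].unique())
    remap = {int(v): r for r, v in enumerate(observed)}
    out = table.copy()
    out.loc[sub, "response"] = [int(remap[int(v)]) for v in out.loc[sub, "response"]]
    return out


def calibrate_with_collapse(table: pd.DataFrame, calibrate_fn, max_passes: int = 12):
    """Calibrate, collapsing categories of offending items on demand.

    Retries calibration after each :class:`CategoryUseError`, re-coding the
    named item's categories, and returns ``(result, audit)``.
    """
    audit: list[str] = []
    current = table
    for _ in range(max_passes):
        try:
            return calibrate_fn(current), audit
        except CategoryUseError as err:
            current = collapse_categories(current, err.item_id)
            audit.append(
                f"collapsed categories of {err.item_id!r} "
                f"(category {err.category} never used)"
            )
    raise RuntimeError("category collapse did not stabilize; inspect the data")


def split_bank_with_forms(
    calib: CalibrationResult,
    session_to_form: dict[int, str],
) -> ItemBank:
    """Rebuild an ItemBank with per-form variants from a split calibration.

    Pseudo-items ``item::sK`` become form variants of their base item under
    the form in effect at session K; unsplit items keep one threshold
    vector for all forms.  This is the bank :func:`raschtraj.rasch_engine.
    equate_forms` consumes to build the scoring-correction tables.
    """
    base_items: dict[str, dict] = {}
    for pid in calib.item_ids:
        base, session = parse_pseudo_item(pid)
        entry = base_items.setdefault(base, {"common": None, "variants": {}})
        if session is None:
            entry["common"] = calib.thresholds[pid]
        else:
            form = session_to_form[session]
            entry["variants"][form] = calib.thresholds[pid]
    forms = sorted(set(session_to_form.values()))
    items = []
    for base, entry in base_items.items():
        if entry["variants"]:
            variants = dict(entry["variants"])
            missing = [f for f in forms if f not in variants]
            if entry["common"] is not None:
                for f in missing:
                    variants[f] = entry["common"]
            elif missing:
                # anchor absent forms at the mean of the observed variants
                mean_len = min(len(v) for v in variants.values())
                stack = np.mean(
                    [np.asarray(v)[:mean_len] for v in variants.values()], axis=0
                )
                for f in missing:
                    variants[f] = stack
            ref = variants[forms[0]]
            items.append(Item(base, ref, True, variants))
        else:
            items.append(Item(base, entry["common"], False))
    return ItemBank(items)
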