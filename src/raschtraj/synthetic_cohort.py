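"""Synthetic cohorts for a 6-task cognitive battery scored 0-24.

The generator emulates the statistical structure the downstream analyses
assume: a brief computerized battery (B-CAM-style) of six polytomous tasks
whose maximum categories sum to 24, administered at months 0/3/6 with three
alternate forms; two verbal tasks (letter fluency, word-list recall) whose
difficulty shifts by form; three latent trajectory groups of the total
score with small positive linear slopes; and monotone attrition unrelated
to ability.

Latent trajectories are generated directly on the observed 0-24 total-score
scale (that is the scale the trajectory model operates on); each
person-occasion expected total is mapped to a latent logit ability by
inverting the bank's test characteristic curve, and item responses are then
sampled from partial-credit probabilities under the form in effect at that
session.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .rasch_engine import Item, ItemBank, _probs_matrix, invert_tcc

__all__ = [
    "CohortSpec",
    "FormPlan",
    "default_cohort_spec",
    "make_default_item_bank",
    "default_form_plan",
    "simulate_abilities",
    "simulate_responses",
    "apply_dropout",
    "simulate_cohort",
    "load_config",
]

SCORE_MAX = 24.0


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters for one synthetic cohort.

    Defaults are the observed study conditions: 102 persons, three
    trajectory groups with intercepts 9.2/14.9/18.7 total-score points and
    per-month slopes 0.36/0.24/0.47, membership shares 36.1/49.2/14.6 %
    (normalized), sessions at months 0/3/6, and ~15/102 attrition.
    """

    n_persons: int = 102
    group_weights: tuple[float, ...] = (0.361361361361361, 0.492492492492492, 0.146146146146146)
    group_intercepts: tuple[float, ...] = (9.2, 14.9, 18.7)
    group_slopes: tuple[float, ...] = (0.36, 0.24, 0.47)
    occasions: tuple[float, ...] = (0.0, 3.0, 6.0)
    # latent-scale noise; calibrated so the *observed* baseline total-score
    # SD is ~4.4 once the response layer adds its ~2 points of measurement
    # error on top
    residual_sd: float = 1.6
    dropout_rate: float = 15.0 / 102.0
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.group_weights, dtype=float)
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("group_weights must sum to 1 within 1e-12")
        k = w.size
        if len(self.group_intercepts) != k or len(self.group_slopes) != k:
            raise ValueError("intercepts/slopes must match group_weights length")
        if any(not (0.0 <= b <= SCORE_MAX) for b in self.group_intercepts):
            raise ValueError("intercepts must lie in [0, 24]")
        occ = np.asarray(self.occasions, dtype=float)
        if occ.size < 1 or np.any(np.diff(occ) <= 0):
            raise ValueError("occasions must be strictly increasing")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")
        if not (0.0 <= self.dropout_rate <= 1.0):
            raise ValueError("dropout_rate must be in [0, 1]")
        if self.n_persons < k:
            raise ValueError("need at least as many persons as groups")

    @property
    def n_groups(self) -> int:
        return len(self.group_weights)


def default_cohort_spec(**overrides) -> CohortSpec:
    """The study conditions as a spec; keyword overrides for experiments."""
    return CohortSpec(**overrides)


def make_default_item_bank() -> ItemBank:
    """Six polytomous tasks whose maximum categories sum to 24.

    Per-item maxima are (3, 3, 4, 2, 4, 8) for Corsi block forward/backward
    span, flanker reaction time (binned), mini trail-making, letter fluency
    (binned) and recall of an 8-word list -- recall naturally scores 0-8,
    the others are ordinal bins covering the remaining range.  Thresholds
    are equally spaced around each item's location; locations are centred
    so the bank mean is exactly zero.  Fluency and recall are flagged as
    form-varying (their alternate versions differ in difficulty).
    """
    layout = [
        # (item_id, max score, location, threshold spacing, form varying)
        ("corsi_forward", 3, -1.0, 0.8, False),
        ("corsi_backward", 3, 0.5, 0.8, False),
        ("flanker", 4, -0.2, 0.7, False),
        ("mini_trails", 2, -0.8, 0.9, False),
        ("fluency", 4, 0.5, 0.7, True),
        ("word_recall", 8, 1.0, 0.35, True),
    ]
    items = []
    for item_id, m, loc, spacing, varying in layout:
        j = np.arange(1, m + 1, dtype=float)
        tau = loc + spacing * (j - (m + 1) / 2.0)
        items.append(Item(item_id, tau, form_varying=varying))
    return ItemBank(items).center()


@dataclass(frozen=True)
class FormPlan:
    """Which alternate form each session uses, and the form difficulty shifts.

    ``dif_shifts`` maps (item_id, form) to a logit offset added to that
    item's thresholds under that form; negative = easier.  Defaults:
    the session-2 fluency list is easier by 0.8 logits, and the recall
    lists differ by +/-0.4 logits across forms.
    """

    session_to_form: dict[int, str] = field(
        default_factory=lambda: {1: "A", 2: "B", 3: "C"}
    )
    dif_items: tuple[str, ...] = ("fluency", "word_recall")
    dif_shifts: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("fluency", "A"): 0.0,
            ("fluency", "B"): -0.8,
            ("fluency", "C"): 0.0,
            ("word_recall", "A"): 0.0,
            ("word_recall", "B"): 0.4,
            ("word_recall", "C"): -0.4,
        }
    )

    def __post_init__(self) -> None:
        forms = set(self.session_to_form.values())
        for item in self.dif_items:
            for form in forms:
                if (item, form) not in self.dif_shifts:
                    raise ValueError(
                        f"dif_shifts missing entry for ({item!r}, {form!r})"
                    )

    @property
    def forms(self) -> list[str]:
        return sorted(set(self.session_to_form.values()))

    def shift(self, item_id: str, form: str) -> float:
        return self.dif_shifts.get((item_id, form), 0.0)

    def form_thresholds(self, bank: ItemBank, form: str) -> list[np.ndarray]:
        return [
            it.thresholds + self.shift(it.item_id, form) for it in bank
        ]

    def bank_with_variants(self, bank: ItemBank) -> ItemBank:
        """Attach per-form threshold variants to the dif items of a bank."""
        items = []
        for it in bank:
            if it.item_id in self.dif_items:
                variants = {
                    f: it.thresholds + self.shift(it.item_id, f)
                    for f in self.forms
                }
                items.append(Item(it.item_id, it.thresholds, True, variants))
            else:
                items.append(Item(it.item_id, it.thresholds, it.form_varying))
        return ItemBank(items)


def default_form_plan() -> FormPlan:
    return FormPlan()


def simulate_abilities(spec: CohortSpec) -> pd.DataFrame:
    """Latent total-score trajectories plus true group labels.

    Each person draws a group from ``group_weights``; the expected score at
    month t is intercept_k + slope_k * t, plus Gaussian noise with
    ``residual_sd``, clamped to [0, 24].  Deterministic given ``spec.seed``.
    Columns: person_id, group (1-based truth label), session, month, latent.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.n_groups
    groups = rng.choice(k, size=spec.n_persons, p=np.asarray(spec.group_weights))
    width = len(str(spec.n_persons))
    ids = [f"p{j + 1:0{width}d}" for j in range(spec.n_persons)]
    rows = []
    for s_idx, month in enumerate(spec.occasions, start=1):
        mean = (
            np.asarray(spec.group_intercepts)[groups]
            + np.asarray(spec.group_slopes)[groups] * month
        )
        latent = mean + rng.normal(0.0, spec.residual_sd, size=spec.n_persons)
        latent = np.clip(latent, 0.0, SCORE_MAX)
        for pid, g, val in zip(ids, groups, latent):
            rows.append(
                {"person_id": pid, "group": int(g) + 1, "session": s_idx,
                 "month": float(month), "latent": float(val)}
            )
    return pd.DataFrame(rows)


def simulate_responses(
    abilities: pd.DataFrame,
    bank: ItemBank,
    plan: FormPlan,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample item responses from the PCM given latent total-score targets.

    Each person-occasion latent score (0-24 scale) is converted to a logit
    ability by inverting the test characteristic curve of the form in
    effect at that session, then each item's category is drawn from its
    partial-credit probabilities (with the form's difficulty shifts
    applied).  Long-format rows: person_id, session, month, form, item_id,
    response.
    """
    lat = abilities["latent"].to_numpy(dtype=float)
    if np.any(lat < 0.0) or np.any(lat > SCORE_MAX):
        raise ValueError("latent scores must lie in [0, 24]")
    rng = np.random.default_rng(seed)
    out = []
    for session, sub in abilities.groupby("session", sort=True):
        form = plan.session_to_form[int(session)]
        ths = plan.form_thresholds(bank, form)
        max_total = sum(len(t) for t in ths)
        targets = np.clip(sub["latent"].to_numpy(float), 0.25, max_total - 0.25)
        theta = invert_tcc(targets, ths)
        month = sub["month"].to_numpy(float)
        pids = sub["person_id"].to_numpy()
        for it, tau in zip(bank, ths):
            p = _probs_matrix(theta, tau)
            u = rng.random(theta.size)
            resp = (u[:, None] > np.cumsum(p, axis=1)[:, :-1]).sum(axis=1)
            for pid, mo, r in zip(pids, month, resp):
                out.append(
                    {"person_id": pid, "session": int(session),
                     "month": float(mo), "form": form,
                     "item_id": it.item_id, "response": int(r)}
                )
    return pd.DataFrame(out)


def apply_dropout(table: pd.DataFrame, rate: float, seed: int = 0) -> pd.DataFrame:
    """Monotone, ability-unrelated attrition.

    Each person is independently selected with probability ``rate``;
    selected persons lose every row after a cutoff session drawn uniformly
    from the non-final sessions, so nobody loses session 1 and everybody
    stays in the table.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must be in [0, 1]")
    if rate == 0.0:
        return table.copy()
    rng = np.random.default_rng(seed)
    sessions = np.sort(table["session"].unique())
    if sessions.size < 2:
        return table.copy()
    persons = table["person_id"].unique()
    selected = rng.random(persons.size) < rate
    cutoffs = rng.integers(1, sessions.size, size=persons.size)  # 1..S-1
    cut = {
        pid: int(sessions[c - 1]) if sel else int(sessions[-1])
        for pid, sel, c in zip(persons, selected, cutoffs)
    }
    keep = table["session"] <= table["person_id"].map(cut)
    return table.loc[keep].reset_index(drop=True)


def simulate_cohort(
    spec: CohortSpec,
    bank: ItemBank | None = None,
    plan: FormPlan | None = None,
):
    """Full generator: abilities -> responses -> dropout.

    Returns ``(responses, abilities)``; ``abilities`` is the truth sidecar
    (group labels and latent scores).  Sub-stage seeds are derived from
    ``spec.seed`` so the whole cohort is reproducible from one integer.
    """
    bank = bank if bank is not None else make_default_item_bank()
    plan = plan if plan is not None else default_form_plan()
    abilities = simulate_abilities(spec)
    responses = simulate_responses(
        abilities, bank, plan, seed=spec.seed + 1_000_003
    )
    responses = apply_dropout(
        responses, spec.dropout_rate, seed=spec.seed + 2_000_003
    )
    return responses, abilities


def load_config(path) -> tuple[CohortSpec, FormPlan]:
    """Read a YAML/JSON config mirroring CohortSpec + FormPlan fields."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    spec_kwargs = dict(cfg.get("cohort", {}))
    for key in ("group_weights", "group_intercepts", "group_slopes", "occasions"):
        if key in spec_kwargs:
            spec_kwargs[key] = tuple(spec_kwargs[key])
    spec = CohortSpec(**spec_kwargs)
    plan_cfg = cfg.get("forms", None)
    if plan_cfg is None:
        plan = default_form_plan()
    else:
        shifts = {
            (d["item"], d["form"]): float(d["shift"])
            for d in plan_cfg.get("dif_shifts", [])
        }
        plan = FormPlan(
            session_to_form={int(k): v for k, v in plan_cfg["session_to_form"].items()},
            dif_items=tuple(plan_cfg.get("dif_items", ())),
            dif_shifts=shifts,
        )
    return spec, plan
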