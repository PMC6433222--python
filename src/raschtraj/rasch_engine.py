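"""Partial-credit Rasch model: probabilities, joint calibration, form equating.

The partial credit model (PCM) gives the probability that a person at
ability ``theta`` (logits) responds in category ``k`` of an item whose m
ordered thresholds are ``tau_1..tau_m``::

    P(X = k) ∝ exp( sum_{j<=k} (theta - tau_j) ),   k = 0..m

with the empty sum equal to zero for k = 0.  A threshold is the logit
location where adjacent categories are equally probable; an item with m+1
response options has m thresholds.

Item thresholds are estimated by conditional maximum likelihood: the
person parameters are eliminated by conditioning each response vector on
its raw total, leaving a likelihood over elementary symmetric functions of
the item category parameters.  CML is consistent in the number of persons
regardless of how few items there are and assumes nothing about the person
distribution.  Persons at floor or ceiling raw totals contribute nothing
to the conditional likelihood (their conditional probability is 1) and are
flagged ``extreme``.  Item locations (threshold means) are centred to zero
for identifiability.  Person abilities use the weighted-likelihood (WLE)
correction, which stays finite at extreme totals; standard errors come
from the observed test information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize

__all__ = [
    "pcm_category_probs",
    "pcm_expected_score",
    "pcm_score_variance",
    "Item",
    "ItemBank",
    "CategoryUseError",
    "CalibrationResult",
    "calibrate",
    "equate_forms",
    "apply_equating",
    "tcc",
    "invert_tcc",
]

THETA_BOUND = 12.0


# ---------------------------------------------------------------------------
# PCM primitives
# ---------------------------------------------------------------------------

def _probs_matrix(theta: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Category probabilities for a vector of abilities; shape (n, m+1)."""
    theta = np.asarray(theta, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    steps = theta[:, None] - thresholds[None, :]
    logits = np.concatenate(
        [np.zeros((theta.size, 1)), np.cumsum(steps, axis=1)], axis=1
    )
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    return p


def pcm_category_probs(theta, thresholds) -> np.ndarray:
    """PCM category probabilities P(X = 0..m) at ability ``theta``.

    ``theta`` may be a scalar (returns a length m+1 vector) or a 1-d array
    (returns an (n, m+1) matrix).  Probabilities sum to one.
    """
    th = np.asarray(theta, dtype=float)
    if th.ndim == 0:
        return _probs_matrix(th[None], thresholds)[0]
    return _probs_matrix(th, thresholds)


def _item_moments(theta: np.ndarray, thresholds: np.ndarray):
    """Expected score, score variance and third central moment per person."""
    p = _probs_matrix(theta, thresholds)
    k = np.arange(p.shape[1], dtype=float)
    e1 = p @ k
    e2 = p @ k**2
    e3 = p @ k**3
    var = e2 - e1**2
    mu3 = e3 - 3.0 * e1 * e2 + 2.0 * e1**3
    return e1, var, mu3


def pcm_expected_score(theta, thresholds) -> float | np.ndarray:
    """Model-expected category, sum_k k P(X=k); strictly increasing in theta."""
    th = np.asarray(theta, dtype=float)
    scalar = th.ndim == 0
    e1, _, _ = _item_moments(np.atleast_1d(th), np.asarray(thresholds, float))
    return float(e1[0]) if scalar else e1


def pcm_score_variance(theta, thresholds) -> float | np.ndarray:
    """Model score variance, the item information about theta."""
    th = np.asarray(theta, dtype=float)
    scalar = th.ndim == 0
    _, v, _ = _item_moments(np.atleast_1d(th), np.asarray(thresholds, float))
    return float(v[0]) if scalar else v


def tcc(theta, thresholds_list) -> np.ndarray:
    """Test characteristic curve: expected raw total across a set of items."""
    th = np.atleast_1d(np.asarray(theta, dtype=float))
    total = np.zeros_like(th)
    for tau in thresholds_list:
        total += pcm_expected_score(th, tau)
    return total


def invert_tcc(targets, thresholds_list, *, bound: float = 30.0) -> np.ndarray:
    """Map expected raw totals back to theta by inverting the (monotone) TCC.

    Targets must lie strictly inside (0, max_total).  A coarse grid lookup
    is refined with Newton steps using the exact TCC slope (the test
    information), giving machine-level inversion accuracy.
    """
    targets = np.atleast_1d(np.asarray(targets, dtype=float))
    max_total = sum(len(tau) for tau in thresholds_list)
    if np.any(targets <= 0.0) or np.any(targets >= max_total):
        raise ValueError("targets must lie strictly inside (0, max_total)")
    grid = np.linspace(-bound, bound, 2401)
    tcc_grid = tcc(grid, thresholds_list)
    theta = np.interp(targets, tcc_grid, grid)
    for _ in range(50):
        resid = tcc(theta, thresholds_list) - targets
        slope = np.zeros_like(theta)
        for tau in thresholds_list:
            slope += pcm_score_variance(theta, tau)
        step = resid / np.maximum(slope, 1e-12)
        theta -= np.clip(step, -2.0, 2.0)
        if np.max(np.abs(step)) < 1e-10:
            break
    return theta


# ---------------------------------------------------------------------------
# Item bank
# ---------------------------------------------------------------------------

@dataclass
class Item:
    """One polytomous item: ordered thresholds, optional per-form variants."""

    item_id: str
    thresholds: np.ndarray
    form_varying: bool = False
    form_variants: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.thresholds.ndim != 1 or self.thresholds.size < 1:
            raise ValueError(f"{self.item_id}: thresholds must be a 1-d vector")
        if not np.all(np.isfinite(self.thresholds)):
            raise ValueError(f"{self.item_id}: thresholds must be finite")

    @property
    def n_categories(self) -> int:
        return self.thresholds.size + 1

    @property
    def max_score(self) -> int:
        return self.thresholds.size

    @property
    def location(self) -> float:
        return float(np.mean(self.thresholds))

    def thresholds_for(self, form: str | None = None) -> np.ndarray:
        if form is not None and self.form_variants and form in self.form_variants:
            return np.asarray(self.form_variants[form], dtype=float)
        return self.thresholds


@dataclass
class ItemBank:
    """An ordered collection of items sharing one logit scale."""

    items: list[Item]

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate item ids in bank")

    def __iter__(self):
        return iter(self.items)

    def __len__(self) -> int:
        return len(self.items)

    def __getitem__(self, item_id: str) -> Item:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def max_total(self) -> int:
        return sum(it.max_score for it in self.items)

    @property
    def locations(self) -> pd.Series:
        return pd.Series({it.item_id: it.location for it in self.items})

    @property
    def forms(self) -> list[str]:
        seen: set[str] = set()
        for it in self.items:
            if it.form_variants:
                seen.update(it.form_variants)
        return sorted(seen)

    def thresholds_list(self, form: str | None = None) -> list[np.ndarray]:
        return [it.thresholds_for(form) for it in self.items]

    def center(self) -> "ItemBank":
        """Return a copy with the grand mean of item locations set to zero."""
        c = float(np.mean([it.location for it in self.items]))
        items = []
        for it in self.items:
            variants = None
            if it.form_variants:
                variants = {f: np.asarray(v, float) - c for f, v in it.form_variants.items()}
            items.append(
                Item(it.item_id, it.thresholds - c, it.form_varying, variants)
            )
        return ItemBank(items)


# ---------------------------------------------------------------------------
# Weighted-likelihood person estimation
# ---------------------------------------------------------------------------

def _wle_equation(theta: float, totals: float, taus: list[np.ndarray]) -> float:
    t = np.array([theta])
    e = v = j = 0.0
    for tau in taus:
        e1, var, mu3 = _item_moments(t, tau)
        e += e1[0]
        v += var[0]
        j += mu3[0]
    return (totals - e) + j / (2.0 * max(v, 1e-300))


def wle_abilities(X: np.ndarray, observed: np.ndarray, thresholds: list[np.ndarray]):
    """Weighted-likelihood ability estimates and SEs for a response matrix.

    ``X`` is persons x items with NaN for missing; ``observed`` the boolean
    mask.  The WLE solves sum_i (x_i - E_i) + J/(2I) = 0 where I is the test
    information and J its derivative; it is finite at floor/ceiling totals.
    The solution depends only on the set of observed items and the raw
    total, so estimates are memoized over that pattern.
    """
    n = X.shape[0]
    theta = np.full(n, np.nan)
    se = np.full(n, np.nan)
    totals = np.nansum(np.where(observed, X, 0.0), axis=1)
    cache: dict[tuple, tuple[float, float]] = {}
    for p in range(n):
        idx = tuple(np.flatnonzero(observed[p]))
        if not idx:
            continue
        key = (idx, totals[p])
        if key not in cache:
            taus = [thresholds[i] for i in idx]
            f = lambda t: _wle_equation(t, totals[p], taus)  # noqa: E731
            lo, hi = -THETA_BOUND * 2, THETA_BOUND * 2
            flo, fhi = f(lo), f(hi)
            while flo < 0 and lo > -200:
                lo *= 2
                flo = f(lo)
            while fhi > 0 and hi < 200:
                hi *= 2
                fhi = f(hi)
            t_hat = brentq(f, lo, hi, xtol=1e-10)
            info = 0.0
            for tau in taus:
                info += pcm_score_variance(t_hat, tau)
            cache[key] = (t_hat, 1.0 / np.sqrt(max(info, 1e-300)))
        theta[p], se[p] = cache[key]
    return theta, se


# ---------------------------------------------------------------------------
# Conditional maximum-likelihood calibration
# ---------------------------------------------------------------------------

class CategoryUseError(ValueError):
    """A response category was never observed; collapse categories first."""

    def __init__(self, item_id: str, category: int, message: str):
        super().__init__(message)
        self.item_id = item_id
        self.category = category


@dataclass
class CalibrationResult:
    """Estimated thresholds, person abilities with SEs, and residuals."""

    item_ids: list[str]
    thresholds: dict[str, np.ndarray]
    persons: pd.DataFrame
    observed: pd.DataFrame
    expected: pd.DataFrame
    variance: pd.DataFrame
    residuals: pd.DataFrame
    loglik_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    threshold_cov: pd.DataFrame | None = None

    @property
    def item_locations(self) -> pd.Series:
        return pd.Series({i: float(np.mean(t)) for i, t in self.thresholds.items()})

    def location_contrast_se(self, plus: list[str], minus: list[str]) -> float:
        """SE of mean(location of ``plus`` items) - mean(location of
        ``minus`` items), from the threshold covariance (requires
        ``calibrate(..., compute_se=True)``)."""
        if self.threshold_cov is None:
            raise ValueError("calibration was run without compute_se=True")
        names = list(self.threshold_cov.columns)
        a = np.zeros(len(names))
        for sign, group in ((1.0, plus), (-1.0, minus)):
            for item in group:
                taus = [j for j, nm in enumerate(names) if nm.startswith(f"{item}.tau")]
                for j in taus:
                    a[j] += sign / (len(taus) * len(group))
        var = float(a @ self.threshold_cov.to_numpy() @ a)
        return float(np.sqrt(max(var, 0.0)))

    def thresholds_list(self) -> list[np.ndarray]:
        return [self.thresholds[i] for i in self.item_ids]

    def to_bank(self) -> ItemBank:
        return ItemBank([Item(i, self.thresholds[i]) for i in self.item_ids])


def _log_conv(la: np.ndarray, lb: np.ndarray) -> np.ndarray:
    """Log of the convolution of exp(la) and exp(lb), with rescaling."""
    ma, mb = la.max(), lb.max()
    c = np.convolve(np.exp(la - ma), np.exp(lb - mb))
    return np.log(np.maximum(c, 1e-300)) + ma + mb


def _pattern_gammas(log_eps: list[np.ndarray], idx: tuple[int, ...]):
    """Full and leave-one-out log elementary symmetric functions.

    ``log_eps[i][k]`` is -delta_ik, the log category coefficient of item i.
    Returns (log gamma over all items of the pattern, {i: log gamma
    without item i}).
    """
    mats = [log_eps[i] for i in idx]
    k = len(mats)
    prefix = [np.array([0.0])]
    for a in mats:
        prefix.append(_log_conv(prefix[-1], a))
    suffix = [np.array([0.0])]
    for a in reversed(mats):
        suffix.append(_log_conv(suffix[-1], a))
    suffix = suffix[::-1]
    full = prefix[-1]
    loo = {idx[j]: _log_conv(prefix[j], suffix[j + 1]) for j in range(k)}
    return full, loo


def calibrate(
    table: pd.DataFrame,
    *,
    tol: float = 1e-5,
    max_iter: int = 200,
    compute_se: bool = False,
) -> CalibrationResult:
    """Conditional ML calibration of a long-format response table.

    ``table`` needs columns ``person_id``, ``session``, ``item_id``,
    ``response`` (``month``/``form`` are carried through to the person table
    when present).  Each person-session is estimated as its own ability
    ("stacked" calibration), which is what lets session act as a grouping
    factor in downstream DIF testing.

    Raises :class:`CategoryUseError` if any category 0..max(observed) of an
    item is never used, naming the offending item -- collapse categories
    deliberately (see :func:`raschtraj.dif_split.collapse_categories`) and
    re-run.
    """
    required = {"person_id", "session", "item_id", "response"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table missing columns: {sorted(missing)}")

    wide = table.pivot_table(
        index=["person_id", "session"], columns="item_id", values="response",
        aggfunc="first",
    )
    item_ids = list(wide.columns)
    if len(item_ids) < 2:
        raise ValueError("calibration needs at least 2 items")

    X = wide.to_numpy(dtype=float)
    observed = ~np.isnan(X)
    n, I = X.shape

    # category-use audit: every code 0..max must occur at least once
    m = np.zeros(I, dtype=int)
    for i, item in enumerate(item_ids):
        vals = X[observed[:, i], i].astype(int)
        mi = int(vals.max()) if vals.size else 0
        counts = np.bincount(vals, minlength=mi + 1)
        if mi < 1:
            raise CategoryUseError(
                item, 1,
                f"item {item!r} has a single observed category; collapse or "
                "drop the item before calibration",
            )
        never = np.flatnonzero(counts == 0)
        if never.size:
            raise CategoryUseError(
                item, int(never[0]),
                f"item {item!r}: category {int(never[0])} is never used; "
                "group the response categories before calibration",
            )
        m[i] = mi

    totals = np.where(observed, X, 0.0).sum(axis=1)
    max_totals = (observed * m[None, :]).sum(axis=1)
    if np.unique(totals).size < 2:
        raise ValueError("calibration needs at least 2 distinct raw totals")
    extreme = (totals <= 0) | (totals >= max_totals)

    # --- conditional likelihood over response patterns ------------------
    # rows sharing an observed-item set share the elementary symmetric
    # functions; extreme totals have conditional probability 1 and drop out
    pattern_rows: dict[tuple[int, ...], list[int]] = {}
    for p in range(n):
        pattern_rows.setdefault(tuple(np.flatnonzero(observed[p])), []).append(p)
    pattern_counts = {}
    for key, rows in pattern_rows.items():
        mtot = int(sum(m[i] for i in key))
        c = np.zeros(mtot + 1)
        for p in rows:
            c[int(totals[p])] += 1.0
        pattern_counts[key] = c

    # per-item category counts n_ik (sufficient statistics)
    cat_counts = [
        np.bincount(X[observed[:, i], i].astype(int), minlength=m[i] + 1).astype(float)
        for i in range(I)
    ]

    offsets = np.concatenate([[0], np.cumsum(m)])
    names = [f"{item_ids[i]}.tau{j + 1}" for i in range(I) for j in range(m[i])]

    def unpack(x: np.ndarray) -> list[np.ndarray]:
        return [x[offsets[i]:offsets[i + 1]] for i in range(I)]

    def nll_grad(x: np.ndarray):
        taus = unpack(x)
        deltas = [np.concatenate([[0.0], np.cumsum(t)]) for t in taus]
        log_eps = [-d for d in deltas]
        val = sum(float(cat_counts[i] @ deltas[i]) for i in range(I))
        g_delta = [cat_counts[i][1:].copy() for i in range(I)]
        for key, c in pattern_counts.items():
            full, loo = _pattern_gammas(log_eps, key)
            r_obs = np.flatnonzero(c)
            val += float(c[r_obs] @ full[r_obs])
            for i in key:
                li = loo[i]
                for k in range(1, m[i] + 1):
                    rk = r_obs - k
                    ok = (rk >= 0) & (rk < li.size)
                    if not ok.any():
                        continue
                    pi_k = np.exp(
                        log_eps[i][k] + li[rk[ok]] - full[r_obs[ok]]
                    )
                    g_delta[i][k - 1] -= float(c[r_obs[ok]] @ pi_k)
        # chain rule delta_ik = sum_{j<=k} tau_ij : d/d tau_ij = sum_{k>=j}
        grad = np.concatenate(
            [np.cumsum(g[::-1])[::-1] for g in g_delta]
        )
        return val, grad

    x0 = np.empty(offsets[-1])
    for i in range(I):
        counts = cat_counts[i]
        tau = np.log(np.maximum(counts[:-1], 0.5) / np.maximum(counts[1:], 0.5))
        x0[offsets[i]:offsets[i + 1]] = tau - tau.mean()

    trace: list[float] = []

    def record(xk: np.ndarray) -> None:
        trace.append(-nll_grad(xk)[0])

    res = minimize(
        nll_grad, x0, jac=True, method="L-BFGS-B", callback=record,
        options={"maxiter": max_iter, "ftol": 1e-13, "gtol": tol * 1e-1},
    )
    _, grad_final = nll_grad(res.x)
    converged = bool(res.success) or float(np.max(np.abs(grad_final))) < tol * max(n, 1)
    if not converged:
        worst = int(np.argmax(np.abs(grad_final)))
        raise RuntimeError(
            f"calibration did not converge in {max_iter} iterations; "
            f"worst-moving parameter {names[worst]} "
            f"(gradient {grad_final[worst]:.2e}); trace tail "
            f"{[round(v, 3) for v in trace[-3:]]}"
        )
    thresholds = unpack(res.x)
    # identifiability: centre the grand mean of item locations at zero
    c = float(np.mean([np.mean(t) for t in thresholds]))
    thresholds = [np.asarray(t, dtype=float) - c for t in thresholds]
    it = int(res.nit)

    threshold_cov = None
    if compute_se:
        # observed information via central differences of the analytic
        # gradient; pseudo-inverse because the grand-shift direction is flat
        p = res.x.size
        hess = np.empty((p, p))
        step = 1e-5
        for j in range(p):
            e = np.zeros(p)
            e[j] = step
            gp = nll_grad(res.x + e)[1]
            gm = nll_grad(res.x - e)[1]
            hess[:, j] = (gp - gm) / (2.0 * step)
        hess = 0.5 * (hess + hess.T)
        threshold_cov = pd.DataFrame(
            np.linalg.pinv(hess), index=names, columns=names
        )

    # --- final person estimates: weighted likelihood, finite at extremes -
    theta_wle, se_wle = wle_abilities(X, observed, thresholds)

    e_mat = np.full_like(X, np.nan)
    v_mat = np.full_like(X, np.nan)
    for i in range(I):
        msk = observed[:, i]
        e1, var, _ = _item_moments(theta_wle, thresholds[i])
        e_mat[msk, i] = e1[msk]
        v_mat[msk, i] = var[msk]
    z = (X - e_mat) / np.sqrt(np.maximum(v_mat, 1e-12))

    persons = pd.DataFrame(
        {
            "person_id": wide.index.get_level_values("person_id"),
            "session": wide.index.get_level_values("session"),
            "raw_total": totals,
            "max_total": max_totals,
            "extreme": extreme,
            "theta": theta_wle,
            "se": se_wle,
        }
    )
    for extra in ("month", "form"):
        if extra in table.columns:
            lookup = (
                table.groupby(["person_id", "session"])[extra].first()
            )
            persons[extra] = lookup.reindex(wide.index).to_numpy()

    def as_frame(mat):
        return pd.DataFrame(mat, index=wide.index, columns=item_ids)

    return CalibrationResult(
        item_ids=item_ids,
        thresholds={item_ids[i]: thresholds[i] for i in range(I)},
        persons=persons,
        observed=as_frame(X),
        expected=as_frame(e_mat),
        variance=as_frame(v_mat),
        residuals=as_frame(z),
        loglik_trace=trace,
        n_iter=it,
        converged=converged,
        threshold_cov=threshold_cov,
    )


# ---------------------------------------------------------------------------
# Form equating
# ---------------------------------------------------------------------------

def equate_forms(bank: ItemBank, ref_form: str | None = None) -> pd.DataFrame:
    """Raw-score -> theta -> reference-form equivalent-score tables per form.

    For each form, every raw total 0..max maps to the theta at which the
    form's test characteristic curve equals that total (extreme totals are
    anchored at a conventional 0.25-point offset into the scale), and then
    to the expected total on the reference form at that theta.  Raw 0 and
    the maximum map to themselves on every form; both maps are monotone.
    """
    forms = bank.forms
    if not forms:
        raise ValueError("bank has no form variants; nothing to equate")
    ref = ref_form if ref_form is not None else forms[0]
    if ref not in forms:
        raise KeyError(f"undefined form ID {ref!r}")
    ref_ths = bank.thresholds_list(ref)
    rows = []
    for f in forms:
        ths = bank.thresholds_list(f)
        max_total = sum(len(t) for t in ths)
        raw = np.arange(max_total + 1, dtype=float)
        targets = np.clip(raw, 0.25, max_total - 0.25)
        theta = invert_tcc(targets, ths)
        ref_score = tcc(theta, ref_ths)
        ref_score[0] = 0.0
        ref_score[-1] = float(sum(len(t) for t in ref_ths))
        for r, t, s in zip(raw, theta, ref_score):
            rows.append(
                {"form": f, "raw": int(r), "theta": float(t),
                 "ref_score": float(s)}
            )
    return pd.DataFrame(rows)


def apply_equating(
    persons: pd.DataFrame,
    tables: pd.DataFrame,
    session_to_form: dict,
) -> pd.DataFrame:
    """Attach form-equated total scores to a person-session table.

    ``persons`` needs ``person_id``, ``session``, ``raw_total`` (and
    optionally ``month``); ``tables`` is the output of
    :func:`equate_forms`.  Returns a copy with an ``equated`` column on the
    reference-form scale.
    """
    out = persons.copy()
    lut = {
        (row.form, row.raw): row.ref_score for row in tables.itertuples()
    }
    eq = []
    for row in out.itertuples():
        form = session_to_form[row.session]
        key = (form, int(round(row.raw_total)))
        if key not in lut:
            raise KeyError(f"no equating entry for form {form!r} raw {key[1]}")
        eq.append(lut[key])
    out["equated"] = eq
    return out
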