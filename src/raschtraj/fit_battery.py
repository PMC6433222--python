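"""Model-fit diagnostics for a calibrated partial-credit scale.

Implements the standard Rasch quality-control battery: threshold ordering,
item and person fit residuals with class-interval chi-square tests,
unidimensionality via principal components of the standardized residuals
(with a paired subset t-test and binomial CI), pairwise response
dependency, targeting, and the person separation index (PSI).

Conventional decision constants are exposed as module defaults: fit
residuals acceptable within +/-2.5; at most 5% of subset t values outside
+/-1.96; residual correlations above 0.3 flag dependency; PSI above 0.7
supports group comparison and above 0.9 within-person change; the intended
construct range is -4..+4 logits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .rasch_engine import CalibrationResult, wle_abilities

__all__ = [
    "assign_class_intervals",
    "item_fit",
    "person_fit",
    "unidimensionality_test",
    "response_dependency",
    "targeting_summary",
    "person_separation_index",
    "full_fit_report",
    "FitReport",
]

FIT_RESIDUAL_LIMIT = 2.5
T_PROPORTION_LIMIT = 0.05
DEPENDENCY_R = 0.3
PSI_GROUP = 0.7
PSI_INDIVIDUAL = 0.9
CONSTRUCT_RANGE = (-4.0, 4.0)
DEFAULT_INTERVALS = 5


def assign_class_intervals(theta: np.ndarray, n_intervals: int = DEFAULT_INTERVALS) -> np.ndarray:
    """Partition person-sessions into ability strata of near-equal size.

    Persons are ordered by theta (ties broken by stable input order) and
    cut into ``n_intervals`` contiguous groups; when sizes cannot be equal
    the extra members go to the lower intervals.  Returns 0-based labels
    aligned with the input.
    """
    theta = np.asarray(theta, dtype=float)
    n = theta.size
    if n < n_intervals:
        raise ValueError(
            f"{n} persons cannot fill {n_intervals} class intervals; "
            "use fewer intervals"
        )
    if np.unique(theta).size < n_intervals:
        raise ValueError(
            "fewer distinct ability values than intervals; use fewer intervals"
        )
    order = np.argsort(theta, kind="stable")
    base, extra = divmod(n, n_intervals)
    sizes = [base + 1 if g < extra else base for g in range(n_intervals)]
    labels = np.empty(n, dtype=int)
    start = 0
    for g, size in enumerate(sizes):
        labels[order[start:start + size]] = g
        start += size
    return labels


def item_fit(
    calib: CalibrationResult,
    intervals: np.ndarray | None = None,
    n_intervals: int = DEFAULT_INTERVALS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-item fit residuals and class-interval chi-square tests.

    The item fit residual standardizes the sum of squared person residuals
    ((sum z^2 - n)/sqrt(2n)); values above +2.5 indicate misfit to the
    latent trait, below -2.5 overfit (the item may be redundant).  Because
    person abilities are estimated from the same responses, each squared
    residual is deflated by roughly the item's share of the person's test
    information; squared residuals are rescaled by 1/(1 - h) with h that
    information share before aggregation (no kurtosis correction).  The
    chi-square compares observed and expected interval mean scores with
    df = intervals - 1; p-values carry a Bonferroni flag across items.
    """
    z = calib.residuals.to_numpy()
    x = calib.observed.to_numpy()
    e = calib.expected.to_numpy()
    v = calib.variance.to_numpy()
    theta = calib.persons["theta"].to_numpy()
    if intervals is None:
        intervals = assign_class_intervals(theta, n_intervals)
    n_items = len(calib.item_ids)
    # hat values: the item's share of each person's test information
    info_total = np.nansum(v, axis=1, keepdims=True)
    hat = v / np.maximum(info_total, 1e-12)
    rows = []
    for i, item in enumerate(calib.item_ids):
        obs = ~np.isnan(z[:, i])
        zi = z[obs, i]
        n = zi.size
        z2 = zi**2 / np.clip(1.0 - hat[obs, i], 0.05, 1.0)
        fit_resid = (np.sum(z2) - n) / np.sqrt(2.0 * n)
        chi2 = 0.0
        used = 0
        for g in np.unique(intervals):
            msk = obs & (intervals == g)
            if not msk.any():
                continue
            num = np.sum(x[msk, i] - e[msk, i]) ** 2
            den = np.sum(v[msk, i])
            chi2 += num / max(den, 1e-12)
            used += 1
        df = max(used - 1, 1)
        p = float(stats.chi2.sf(chi2, df))
        rows.append(
            {
                "item_id": item,
                "n": n,
                "fit_residual": float(fit_resid),
                "chi2": float(chi2),
                "df": df,
                "p": p,
                "p_bonferroni": min(1.0, p * n_items),
                "misfit": bool(fit_resid > FIT_RESIDUAL_LIMIT),
                "overfit": bool(fit_resid < -FIT_RESIDUAL_LIMIT),
                "chi2_flag": bool(min(1.0, p * n_items) < alpha),
            }
        )
    return pd.DataFrame(rows)


def person_fit(calib: CalibrationResult) -> pd.DataFrame:
    """Per person-session fit residual over the observed items."""
    z = calib.residuals.to_numpy()
    obs = ~np.isnan(z)
    k = obs.sum(axis=1)
    ssq = np.nansum(z**2, axis=1)
    resid = (ssq - k) / np.sqrt(np.maximum(2.0 * k, 1.0))
    out = calib.persons[["person_id", "session"]].copy()
    out["fit_residual"] = resid
    out["n_items"] = k
    return out


@dataclass
class UnidimResult:
    proportion: float
    n_tested: int
    n_outside: int
    ci_low: float
    ci_high: float
    verdict: str
    loadings: pd.Series | None = None
    positive_items: list[str] = field(default_factory=list)
    negative_items: list[str] = field(default_factory=list)
    t_values: np.ndarray | None = None


def unidimensionality_test(calib: CalibrationResult) -> UnidimResult:
    """PCA-of-residuals test that one latent trait drives the items.

    The first principal component of the standardized-residual correlation
    matrix splits items into positively- and negatively-loading subsets;
    each person's ability is re-estimated from each subset and compared
    with an independent-samples style t.  The scale counts as
    unidimensional when fewer than 5% of |t| exceed 1.96, or when 5% falls
    inside the binomial 95% CI of the observed proportion.
    """
    zd = calib.residuals
    corr = zd.corr().to_numpy()
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    evals, evecs = np.linalg.eigh(corr)
    loading = evecs[:, -1]
    # sign convention: orient the component toward its largest loading
    if loading[np.argmax(np.abs(loading))] < 0:
        loading = -loading
    items = list(zd.columns)
    pos = [items[i] for i in range(len(items)) if loading[i] > 0]
    neg = [items[i] for i in range(len(items)) if loading[i] < 0]
    loadings = pd.Series(loading, index=items)
    if not pos or not neg:
        return UnidimResult(
            proportion=np.nan, n_tested=0, n_outside=0,
            ci_low=np.nan, ci_high=np.nan, verdict="not assessable",
            loadings=loadings, positive_items=pos, negative_items=neg,
        )

    x = calib.observed.to_numpy()
    obs = ~np.isnan(x)
    ths = calib.thresholds_list()
    idx_pos = [items.index(i) for i in pos]
    idx_neg = [items.index(i) for i in neg]

    def subset_estimates(idx):
        cols = np.zeros_like(obs)
        cols[:, idx] = obs[:, idx]
        return wle_abilities(x, cols, ths)

    th_p, se_p = subset_estimates(idx_pos)
    th_n, se_n = subset_estimates(idx_neg)
    ok = np.isfinite(th_p) & np.isfinite(th_n)
    t = (th_p[ok] - th_n[ok]) / np.sqrt(se_p[ok] ** 2 + se_n[ok] ** 2)
    n_tested = int(ok.sum())
    n_outside = int(np.sum(np.abs(t) > 1.96))
    prop = n_outside / n_tested if n_tested else np.nan
    lo, hi = proportion_confint(n_outside, n_tested, alpha=0.05, method="normal")
    if prop < T_PROPORTION_LIMIT or (lo <= T_PROPORTION_LIMIT <= hi):
        verdict = "unidimensional"
    else:
        verdict = "violated"
    return UnidimResult(
        proportion=float(prop), n_tested=n_tested, n_outside=n_outside,
        ci_low=float(lo), ci_high=float(hi), verdict=verdict,
        loadings=loadings, positive_items=pos, negative_items=neg,
        t_values=t,
    )


def response_dependency(
    calib: CalibrationResult, threshold: float = DEPENDENCY_R
) -> pd.DataFrame:
    """Pairwise residual correlations; r above the threshold flags a pair."""
    corr = calib.residuals.corr()
    items = list(corr.columns)
    rows = []
    for a in range(len(items)):
        for b in range(a + 1, len(items)):
            r = float(corr.iloc[a, b])
            rows.append(
                {"item_a": items[a], "item_b": items[b], "r": r,
                 "flagged": bool(np.isfinite(r) and r > threshold)}
            )
    return pd.DataFrame(rows)


@dataclass
class TargetingSummary:
    item_min: float
    item_max: float
    person_mean: float
    person_sd: float
    person_p2_5: float
    person_p97_5: float
    covered: bool


def targeting_summary(calib: CalibrationResult) -> TargetingSummary:
    """Do the item thresholds span where the persons actually are?

    Coverage is true when the threshold range contains the central 95% of
    the (non-extreme) person ability distribution.  Well-targeted scales
    also place the person mean near 0 on the item-centred metric.
    """
    ths = np.concatenate(calib.thresholds_list())
    persons = calib.persons.loc[~calib.persons["extreme"], "theta"].to_numpy()
    lo, hi = np.percentile(persons, [2.5, 97.5])
    return TargetingSummary(
        item_min=float(ths.min()),
        item_max=float(ths.max()),
        person_mean=float(persons.mean()),
        person_sd=float(persons.std(ddof=1)),
        person_p2_5=float(lo),
        person_p97_5=float(hi),
        covered=bool(ths.min() <= lo and ths.max() >= hi),
    )


def person_separation_index(persons: pd.DataFrame) -> tuple[float, str]:
    """PSI = (Var(theta) - mean(SE^2)) / Var(theta), floored at zero.

    A reliability-like index of how well the scale separates persons;
    above 0.7 supports group comparison, above 0.9 within-person change.
    Computed over non-extreme persons.
    """
    sub = persons.loc[~persons["extreme"]] if "extreme" in persons else persons
    if len(sub) < 2:
        raise ValueError("PSI needs at least 2 non-extreme persons")
    var = float(sub["theta"].var(ddof=1))
    if var <= 0:
        raise ValueError("zero ability variance; PSI undefined")
    mse = float(np.mean(sub["se"].to_numpy() ** 2))
    psi = max(0.0, (var - mse) / var)
    if psi > PSI_INDIVIDUAL:
        note = f"PSI {psi:.3f} > {PSI_INDIVIDUAL}: suitable for within-person change"
    elif psi > PSI_GROUP:
        note = f"PSI {psi:.3f} > {PSI_GROUP}: suitable for group differences"
    else:
        note = f"PSI {psi:.3f} <= {PSI_GROUP}: limited discrimination"
    return psi, note


@dataclass
class FitReport:
    """All diagnostics for one calibration, in conventional row order."""

    threshold_order: pd.DataFrame
    item_fit: pd.DataFrame
    person_fit: pd.DataFrame
    unidimensionality: UnidimResult
    dependency: pd.DataFrame
    targeting: TargetingSummary
    psi: float
    psi_note: str

    def to_text(self) -> str:
        lines = ["Rasch fit battery", "=" * 17, ""]
        dis = self.threshold_order.loc[~self.threshold_order["ordered"], "item_id"]
        lines.append("Threshold order: " + (
            "all items ordered" if dis.empty else
            "DISORDERED: " + ", ".join(dis)
        ))
        lines.append("")
        lines.append("Fit to the model (fit residual within +/-2.5, chi-square):")
        for r in self.item_fit.itertuples():
            flag = " MISFIT" if r.misfit else (" OVERFIT" if r.overfit else "")
            lines.append(
                f"  {r.item_id:<16s} fit {r.fit_residual:+6.2f}  "
                f"chi2 {r.chi2:7.2f} (df {r.df}) p {r.p:.3f}"
                f" adj {r.p_bonferroni:.3f}{flag}"
            )
        u = self.unidimensionality
        lines.append("")
        lines.append(
            f"Unidimensionality: {u.verdict} "
            f"({u.n_outside}/{u.n_tested} = {u.proportion:.1%} of t outside "
            f"+/-1.96; 95% CI {u.ci_low:.3f}-{u.ci_high:.3f})"
        )
        flagged = self.dependency.loc[self.dependency["flagged"]]
        lines.append(
            "Response dependency: " + (
                "no residual correlation > 0.3" if flagged.empty else
                "; ".join(f"{r.item_a}~{r.item_b} r={r.r:.2f}" for r in flagged.itertuples())
            )
        )
        t = self.targeting
        lines.append(
            f"Targeting: items {t.item_min:+.2f}..{t.item_max:+.2f} logits; "
            f"persons mean {t.person_mean:+.2f} SD {t.person_sd:.2f}; "
            f"coverage {'yes' if t.covered else 'NO'}"
        )
        lines.append(f"Person separation: {self.psi_note}")
        return "\n".join(lines)


def full_fit_report(
    calib: CalibrationResult, n_intervals: int = DEFAULT_INTERVALS
) -> FitReport:
    order = pd.DataFrame(
        {
            "item_id": calib.item_ids,
            "ordered": [
                bool(np.all(np.diff(calib.thresholds[i]) > 0))
                for i in calib.item_ids
            ],
        }
    )
    psi, note = person_separation_index(calib.persons)
    return FitReport(
        threshold_order=order,
        item_fit=item_fit(calib, n_intervals=n_intervals),
        person_fit=person_fit(calib),
        unidimensionality=unidimensionality_test(calib),
        dependency=response_dependency(calib),
        targeting=targeting_summary(calib),
        psi=psi,
        psi_note=note,
    )
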