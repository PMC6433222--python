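"""Group-based trajectory analysis of repeated total scores.

A finite mixture of polynomial mean trajectories with shared Gaussian
residual variance: person i in latent group k has

    y_it ~ Normal( x_t' beta_k , sigma^2 ),   x_t = (1, t, t^2, ...)

with time coded in months so a linear slope is in score units per month.
The likelihood for a person is the product over their *observed* occasions
only, so persons with missing sessions still contribute to the
trajectories.  Estimation is EM with multiple starts (a baseline-quantile
start plus seeded random perturbations); groups are reported in ascending
order of intercept.  Standard errors come from the observed information
(numerical Hessian of the mixture log-likelihood at the optimum).  Model
selection across group counts and polynomial orders is by BIC, with a
flag when any group's average posterior membership probability falls
below 0.7 (the conventional adequacy bar).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "TrajectoryModel",
    "fit_gbta",
    "select_model",
    "posterior_assignment",
]

MIN_SIGMA2 = 1e-12
AVG_POSTERIOR_BAR = 0.7


@dataclass
class TrajectoryModel:
    """A fitted trajectory mixture in ascending-intercept order."""

    K: int
    order: int
    pi: np.ndarray                    # mixture weights, sum 1
    beta: np.ndarray                  # (K, order+1) score-scale coefficients
    beta_se: np.ndarray               # same shape; NaN when not estimable
    sigma: float                      # shared residual SD (score units)
    posterior: np.ndarray             # (n_persons, K), rows sum to 1
    person_ids: list
    loglik: float
    n_params: int
    bic: float
    loglik_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = True

    @property
    def intercepts(self) -> np.ndarray:
        return self.beta[:, 0]

    @property
    def slopes(self) -> np.ndarray:
        return self.beta[:, 1] if self.beta.shape[1] > 1 else np.zeros(self.K)

    @property
    def labels(self) -> np.ndarray:
        """Hard assignment; exact ties go to the lower-intercept group."""
        return np.argmax(self.posterior, axis=1)

    @property
    def avg_posterior(self) -> np.ndarray:
        """Mean posterior probability among each group's assigned members."""
        lab = self.labels
        out = np.full(self.K, np.nan)
        for k in range(self.K):
            msk = lab == k
            if msk.any():
                out[k] = float(self.posterior[msk, k].mean())
        return out

    @property
    def group_shares(self) -> np.ndarray:
        """Hard-assignment membership proportions (vs the model weights pi)."""
        lab = self.labels
        return np.array([(lab == k).mean() for k in range(self.K)])


def _prepare(scores: pd.DataFrame):
    """Long (person_id, month, score) -> stacked arrays with person index."""
    d = scores.dropna(subset=["score"]).sort_values(["person_id", "month"])
    persons = list(dict.fromkeys(d["person_id"]))
    index = {p: i for i, p in enumerate(persons)}
    idx = d["person_id"].map(index).to_numpy()
    t = d["month"].to_numpy(dtype=float)
    y = d["score"].to_numpy(dtype=float)
    n_obs = np.bincount(idx, minlength=len(persons)).astype(float)
    return persons, idx, t, y, n_obs


def _design(t: np.ndarray, order: int) -> np.ndarray:
    return np.vander(t, order + 1, increasing=True)


def _mixture_loglik(pi, beta, sigma2, X, y, idx, n_persons, n_obs):
    K = pi.size
    logdens = np.zeros((n_persons, K))
    for k in range(K):
        r2 = (y - X @ beta[k]) ** 2
        per = np.zeros(n_persons)
        np.add.at(per, idx, r2)
        logdens[:, k] = (
            -0.5 * n_obs * np.log(2.0 * np.pi * sigma2) - 0.5 * per / sigma2
        )
    logw = np.log(np.maximum(pi, 1e-300))[None, :] + logdens
    ll = float(np.sum(logsumexp(logw, axis=1)))
    return ll, logw


def _em(pi, beta, sigma2, X, y, idx, n_persons, n_obs, tol, max_iter):
    trace = []
    prev = -np.inf
    resp = None
    for it in range(1, max_iter + 1):
        ll, logw = _mixture_loglik(pi, beta, sigma2, X, y, idx, n_persons, n_obs)
        trace.append(ll)
        resp = np.exp(logw - logsumexp(logw, axis=1, keepdims=True))
        if np.isfinite(prev) and abs(ll - prev) < tol * (1.0 + abs(ll)):
            break
        prev = ll
        # M-step
        pi = resp.mean(axis=0)
        pi = np.maximum(pi, 1e-12)
        pi /= pi.sum()
        K = pi.size
        rss = 0.0
        wtot = 0.0
        new_beta = beta.copy()
        for k in range(K):
            w = resp[idx, k]
            Xw = X * w[:, None]
            A = Xw.T @ X
            b = Xw.T @ y
            try:
                new_beta[k] = np.linalg.solve(A, b)
            except np.linalg.LinAlgError:
                new_beta[k] = np.linalg.lstsq(A, b, rcond=None)[0]
            r2 = (y - X @ new_beta[k]) ** 2
            rss += float(np.sum(w * r2))
            wtot += float(np.sum(w))
        beta = new_beta
        sigma2 = max(rss / max(wtot, 1.0), MIN_SIGMA2)
    return pi, beta, sigma2, trace, it, resp


def _order_groups(pi, beta, resp):
    order = np.argsort(beta[:, 0], kind="stable")
    return pi[order], beta[order], resp[:, order]


def _neg_loglik_packed(params, K, order, X, y, idx, n_persons, n_obs):
    p = order + 1
    alpha = params[: K - 1]
    beta = params[K - 1: K - 1 + K * p].reshape(K, p)
    log_sigma = params[-1]
    logits = np.concatenate([[0.0], alpha])
    pi = np.exp(logits - logsumexp(logits))
    sigma2 = np.exp(2.0 * log_sigma)
    ll, _ = _mixture_loglik(pi, beta, sigma2, X, y, idx, n_persons, n_obs)
    return -ll


def _beta_standard_errors(pi, beta, sigma, X, y, idx, n_persons, n_obs):
    """Observed-information SEs for the trajectory coefficients."""
    K, p = beta.shape
    if sigma < 1e-6:  # degenerate (noiseless) fit; information unbounded
        return np.zeros_like(beta)
    logits = np.log(np.maximum(pi, 1e-300))
    alpha = logits[1:] - logits[0]
    params = np.concatenate([alpha, beta.ravel(), [np.log(sigma)]])
    m = params.size
    h = 1e-4 * (1.0 + np.abs(params))
    f = lambda q: _neg_loglik_packed(q, K, p - 1, X, y, idx, n_persons, n_obs)  # noqa: E731
    hess = np.empty((m, m))
    for a in range(m):
        for b in range(a, m):
            ea = np.zeros(m); ea[a] = h[a]
            eb = np.zeros(m); eb[b] = h[b]
            val = (
                f(params + ea + eb) - f(params + ea - eb)
                - f(params - ea + eb) + f(params - ea - eb)
            ) / (4.0 * h[a] * h[b])
            hess[a, b] = hess[b, a] = val
    try:
        cov = np.linalg.pinv(hess)
        var = np.diag(cov)[K - 1: K - 1 + K * p]
        var = np.where(var > 0, var, np.nan)
        return np.sqrt(var).reshape(K, p)
    except np.linalg.LinAlgError:
        return np.full_like(beta, np.nan)


def fit_gbta(
    scores: pd.DataFrame,
    K: int,
    order: int = 1,
    n_starts: int = 20,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
    compute_se: bool = True,
) -> TrajectoryModel:
    """Fit a K-group trajectory mixture to long-format total scores.

    ``scores`` needs columns ``person_id``, ``month``, ``score``; persons
    may have any non-empty subset of occasions observed.  The first start
    slices persons into K groups by baseline score quantile; the remaining
    ``n_starts - 1`` starts perturb group assignment at random (seeded).
    The best log-likelihood wins.  K = 1 reduces to ordinary polynomial
    least squares.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    persons, idx, t, y, n_obs = _prepare(scores)
    n_persons = len(persons)
    if n_persons == 0:
        raise ValueError("no observed scores")
    profiles = {
        (tuple(np.round(t[idx == i], 9)), tuple(np.round(y[idx == i], 9)))
        for i in range(n_persons)
    }
    if K > len(profiles):
        raise ValueError(
            f"K={K} exceeds the {len(profiles)} distinct response profiles"
        )
    X = _design(t, order)
    rng = np.random.default_rng(seed)

    # baseline = first observed score per person
    first_pos = np.full(n_persons, -1, dtype=int)
    for row, i in enumerate(idx):
        if first_pos[i] < 0:
            first_pos[i] = row
    baseline = y[first_pos]

    best = None
    for start in range(max(1, n_starts)):
        if start == 0:
            ranks = np.argsort(np.argsort(baseline, kind="stable"))
            hard = np.minimum((ranks * K) // n_persons, K - 1)
        else:
            hard = rng.integers(0, K, size=n_persons)
        resp0 = np.full((n_persons, K), 0.05 / max(K - 1, 1))
        resp0[np.arange(n_persons), hard] = 0.95
        if K == 1:
            resp0 = np.ones((n_persons, 1))
        # M-step from the initial responsibilities
        pi = resp0.mean(axis=0)
        pi = np.maximum(pi, 1e-12); pi /= pi.sum()
        beta = np.zeros((K, order + 1))
        rss = 0.0; wtot = 0.0
        for k in range(K):
            w = resp0[idx, k]
            Xw = X * w[:, None]
            try:
                beta[k] = np.linalg.solve(Xw.T @ X, Xw.T @ y)
            except np.linalg.LinAlgError:
                beta[k] = np.linalg.lstsq(Xw.T @ X, Xw.T @ y, rcond=None)[0]
            rss += float(np.sum(w * (y - X @ beta[k]) ** 2))
            wtot += float(np.sum(w))
        sigma2 = max(rss / max(wtot, 1.0), MIN_SIGMA2)

        pi, beta, sigma2, trace, n_iter, resp = _em(
            pi, beta, sigma2, X, y, idx, n_persons, n_obs, tol, max_iter
        )
        ll = trace[-1]
        if best is None or ll > best[0] + 1e-10:
            best = (ll, pi, beta, sigma2, trace, n_iter, resp)

    ll, pi, beta, sigma2, trace, n_iter, resp = best
    pi, beta, resp = _order_groups(pi, beta, resp)
    sigma = float(np.sqrt(sigma2))
    n_params = (K - 1) + K * (order + 1) + 1
    bic = -2.0 * ll + n_params * np.log(n_persons)
    beta_se = (
        _beta_standard_errors(pi, beta, sigma, X, y, idx, n_persons, n_obs)
        if compute_se else np.full_like(beta, np.nan)
    )
    return TrajectoryModel(
        K=K, order=order, pi=pi, beta=beta, beta_se=beta_se, sigma=sigma,
        posterior=resp, person_ids=persons, loglik=float(ll),
        n_params=n_params, bic=float(bic), loglik_trace=trace,
        n_iter=n_iter, converged=n_iter < max_iter,
    )


def select_model(
    scores: pd.DataFrame,
    K_range=(1, 2, 3, 4),
    order_range=(1,),
    n_starts: int = 10,
    seed: int = 0,
) -> tuple[TrajectoryModel, pd.DataFrame]:
    """Fit a grid of (K, order) models and rank by BIC (lower is better).

    The selection table records log-likelihood, parameter count, BIC and
    the minimum average posterior membership probability, flagging models
    below the 0.7 adequacy bar.  Returns the BIC-best model and the table.
    """
    rows = []
    models = {}
    for order in order_range:
        for K in K_range:
            try:
                m = fit_gbta(
                    scores, K, order=order, n_starts=n_starts, seed=seed,
                    compute_se=False,
                )
            except ValueError as err:
                rows.append(
                    {"K": K, "order": order, "loglik": np.nan,
                     "n_params": np.nan, "bic": np.nan,
                     "min_avg_posterior": np.nan, "adequate_posterior": False,
                     "note": str(err)}
                )
                continue
            minpp = float(np.nanmin(m.avg_posterior))
            models[(K, order)] = m
            rows.append(
                {"K": K, "order": order, "loglik": m.loglik,
                 "n_params": m.n_params, "bic": m.bic,
                 "min_avg_posterior": minpp,
                 "adequate_posterior": bool(minpp >= AVG_POSTERIOR_BAR),
                 "note": ""}
            )
    table = pd.DataFrame(rows)
    if not models:
        raise ValueError("no model in the grid could be fitted")
    valid = table.dropna(subset=["bic"])
    best_row = valid.loc[valid["bic"].idxmin()]
    best = models[(int(best_row["K"]), int(best_row["order"]))]
    best_se = fit_gbta(
        scores, best.K, order=best.order, n_starts=n_starts, seed=seed,
        compute_se=True,
    )
    return best_se, table


def posterior_assignment(model: TrajectoryModel) -> tuple[np.ndarray, np.ndarray]:
    """Hard labels (ties to the lower-intercept group) and avg posteriors."""
    return model.labels, model.avg_posterior
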