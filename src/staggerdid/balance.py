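"""Covariate balancing: entropy balancing, logistic propensity scores
and nearest-neighbor matching.

Entropy balancing reweights control units so their covariate moments
match the treated group's exactly, while staying as close as possible
(in Kullback–Leibler divergence) to the base weights.  The problem is
solved through its dual: with centered constraint columns c_i the dual
objective is log sum_i q_i exp(c_i' lambda), minimized by a safeguarded
Newton iteration; at the optimum the weights take the exponential-
tilting form w_i proportional to q_i exp(c_i' lambda) and the gradient
equals the residual moment imbalance, so the convergence tolerance *is*
the constraint violation.

Propensity scores are fit by iteratively reweighted least squares
(Newton scoring for the logistic likelihood) implemented here, with
explicit separation detection; matching is greedy nearest-neighbor
within a caliper.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BalanceProblem", "BalanceWeights", "entropy_balance", "entropy_balance_panel",
    "balance_table", "PropensityResult", "fit_propensity",
    "nearest_neighbor_match", "PerfectSeparationError",
]


@dataclass(frozen=True)
class BalanceProblem:
    """Treated/control covariate matrices plus solver settings.

    ``moment_order`` 1 matches means; 2 additionally matches second raw
    moments (hence variances, given matched means).  Base weights
    default to uniform.
    """

    treated: np.ndarray
    control: np.ndarray
    moment_order: int = 1
    base_weights: np.ndarray | None = None
    tolerance: float = 1e-8
    max_iterations: int = 200

    def __post_init__(self) -> None:
        treated = np.atleast_2d(np.asarray(self.treated, dtype=float))
        control = np.atleast_2d(np.asarray(self.control, dtype=float))
        object.__setattr__(self, "treated", treated)
        object.__setattr__(self, "control", control)
        if treated.shape[1] != control.shape[1]:
            raise ValueError("treated and control must share columns")
        if self.moment_order not in (1, 2):
            raise ValueError("moment_order must be 1 or 2")
        if self.base_weights is not None:
            bw = np.asarray(self.base_weights, dtype=float)
            if bw.shape != (control.shape[0],) or (bw <= 0).any():
                raise ValueError("base weights must be positive, one per control unit")
            object.__setattr__(self, "base_weights", bw)


@dataclass
class BalanceWeights:
    """Solved control-unit weights (summing to the number of treated
    units) with convergence diagnostics."""

    weights: np.ndarray
    converged: bool
    iterations: int
    max_violation: float
    lambdas: np.ndarray = field(repr=False, default=None)


def _expand(mat: np.ndarray, order: int) -> np.ndarray:
    if order == 1:
        return mat
    return np.column_stack([mat, mat**2])


def entropy_balance(problem: BalanceProblem) -> BalanceWeights:
    """Solve the entropy-balancing dual by safeguarded Newton iteration.

    Raises on infeasible targets (a treated moment outside the convex
    hull of control contributions, named in the message) and on
    non-convergence within ``max_iterations``.
    """
    ct = _expand(problem.treated, problem.moment_order)
    cc = _expand(problem.control, problem.moment_order)
    n_c = cc.shape[0]
    target = ct.mean(axis=0)

    names = [f"m{j+1}" for j in range(problem.treated.shape[1])]
    if problem.moment_order == 2:
        names += [f"m{j+1}^2" for j in range(problem.treated.shape[1])]
    # feasibility: target must lie inside [min, max] of control values
    for j, name in enumerate(names):
        lo, hi = cc[:, j].min(), cc[:, j].max()
        if not (lo <= target[j] <= hi):
            raise ValueError(
                f"infeasible balance target for moment {name}: treated "
                f"{target[j]:.6g} outside control range [{lo:.6g}, {hi:.6g}]"
            )

    q = (problem.base_weights if problem.base_weights is not None
         else np.ones(n_c))
    q = q / q.sum()

    # center and scale constraint columns for conditioning
    c = cc - target
    scale = np.where(c.std(axis=0) > 0, c.std(axis=0), 1.0)
    c = c / scale

    lam = np.zeros(c.shape[1])
    logq = np.log(q)

    def dual(l_):
        a = logq + c @ l_
        amax = a.max()
        return amax + np.log(np.exp(a - amax).sum())

    def probs(l_):
        a = logq + c @ l_
        a -= a.max()
        p = np.exp(a)
        return p / p.sum()

    converged = False
    it = 0
    f_old = dual(lam)
    for it in range(1, problem.max_iterations + 1):
        p = probs(lam)
        grad = c.T @ p
        # gradient on the raw moment scale is the constraint violation
        if np.abs(grad * scale).max() <= problem.tolerance:
            converged = True
            break
        hess = (c * p[:, None]).T @ c - np.outer(grad, grad)
        try:
            step = np.linalg.solve(hess + 1e-12 * np.eye(len(lam)), grad)
        except np.linalg.LinAlgError:
            step = grad
        # step halving on dual increase
        t = 1.0
        for _ in range(40):
            cand = lam - t * step
            if dual(cand) < f_old + 1e-14:
                break
            t *= 0.5
        lam = lam - t * step
        f_old = dual(lam)
    p = probs(lam)
    # raw-scale constraint violation
    w = p * ct.shape[0]  # control weights summing to n_treated
    raw_viol = float(np.abs((cc * p[:, None]).sum(axis=0) - target).max())
    if not converged:
        raise RuntimeError(
            f"entropy balancing did not converge in {problem.max_iterations} "
            f"iterations (final max violation {raw_viol:.3g})"
        )
    return BalanceWeights(weights=w, converged=True, iterations=it,
                          max_violation=raw_viol, lambdas=lam)


def entropy_balance_panel(panel: pd.DataFrame, covariates: Sequence[str],
                          treated_column: str = "treated",
                          moment_order: int = 1) -> pd.Series:
    """Entropy-balance a panel's control records toward its treated
    records; returns per-record weights (treated records weight 1)."""
    t_mask = panel[treated_column].astype(bool).to_numpy()
    prob = BalanceProblem(
        treated=panel.loc[t_mask, list(covariates)].to_numpy(dtype=float),
        control=panel.loc[~t_mask, list(covariates)].to_numpy(dtype=float),
        moment_order=moment_order,
    )
    bw = entropy_balance(prob)
    weights = np.ones(len(panel))
    # scale control weights to average 1 so WLS keeps comparable scale
    weights[~t_mask] = bw.weights * (~t_mask).sum() / t_mask.sum()
    return pd.Series(weights, index=panel.index, name="weight")


def balance_table(panel: pd.DataFrame, weights: pd.Series | np.ndarray,
                  covariates: Sequence[str],
                  treated_column: str = "treated") -> pd.DataFrame:
    """Raw and weighted standardized mean differences per covariate.

    SMD = (treated mean - control mean) / pooled SD, with the pooled SD
    from the unweighted groups in both columns so the weighting's effect
    is isolated in the numerator.
    """
    t_mask = panel[treated_column].astype(bool).to_numpy()
    w = np.asarray(weights, dtype=float)
    rows = []
    for cov in covariates:
        x = panel[cov].to_numpy(dtype=float)
        xt, xc = x[t_mask], x[~t_mask]
        pooled = np.sqrt((xt.var(ddof=1) + xc.var(ddof=1)) / 2)
        pooled = pooled if pooled > 0 else 1.0
        wc = w[~t_mask]
        weighted_mean_c = float(np.average(xc, weights=wc))
        rows.append({
            "covariate": cov,
            "treated_mean": xt.mean(),
            "control_mean": xc.mean(),
            "smd_raw": (xt.mean() - xc.mean()) / pooled,
            "weighted_control_mean": weighted_mean_c,
            "smd_weighted": (xt.mean() - weighted_mean_c) / pooled,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# propensity scores and matching

class PerfectSeparationError(RuntimeError):
    """Raised when the logistic likelihood has no finite maximizer."""


@dataclass
class PropensityResult:
    """Logistic propensity model: coefficients and per-unit scores."""

    params: pd.Series
    scores: pd.Series
    n_iter: int
    dropped: list[str] = field(default_factory=list)


def fit_propensity(panel: pd.DataFrame, covariates: Sequence[str],
                   treated_column: str = "treated",
                   max_iter: int = 100, tol: float = 1e-10) -> PropensityResult:
    """Logistic regression of treatment on covariates via IRLS.

    Deterministic (cold start at zero).  Zero-variance covariates are
    dropped with a log message; perfect separation raises.
    """
    y = panel[treated_column].astype(float).to_numpy()
    if y.min() == y.max():
        raise ValueError("both treated and control units must be present")
    kept, dropped = [], []
    for cov in covariates:
        if panel[cov].nunique() <= 1:
            dropped.append(cov)
        else:
            kept.append(cov)
    if dropped:
        logger.info("fit_propensity dropped zero-variance covariates: %s", dropped)
    X = np.column_stack([np.ones(len(panel))] +
                        [panel[c].to_numpy(dtype=float) for c in kept])
    names = ["_cons"] + kept
    beta = np.zeros(X.shape[1])
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        w = np.clip(p * (1 - p), 1e-12, None)
        z = eta + (y - p) / w
        xtw = X.T * w
        try:
            beta_new = np.linalg.solve(xtw @ X, xtw @ z)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular IRLS system (collinear covariates?): {exc}")
        delta = np.abs(beta_new - beta).max()
        beta = beta_new
        if np.abs(X @ beta).max() > 30 and delta > 1:
            raise PerfectSeparationError(
                "propensity model diverging: data are (quasi-)separated")
        if delta < tol:
            break
    else:
        raise PerfectSeparationError(
            f"IRLS failed to converge in {max_iter} iterations")
    eta = X @ beta
    scores = 1.0 / (1.0 + np.exp(-eta))
    return PropensityResult(
        params=pd.Series(beta, index=names),
        scores=pd.Series(scores, index=panel.index, name="propensity"),
        n_iter=it, dropped=dropped)


def nearest_neighbor_match(scores: pd.Series, treated: pd.Series,
                           caliper: float = 0.05, scale: str = "logit",
                           with_replacement: bool = False) -> pd.DataFrame:
    """Greedy 1:1 nearest-neighbor matching on the propensity score.

    Treated units are processed in descending score order (ties broken
    by unit identifier); each is matched to the nearest control within
    the caliper, measured on the logit scale by default.  Returns a
    frame of (treated_id, control_id, distance); unmatched treated units
    appear with a missing control.
    """
    s = scores.astype(float)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if scale == "logit":
        eps = 1e-12
        s = np.log(np.clip(s, eps, 1 - eps) / np.clip(1 - s, eps, 1 - eps))
    elif scale != "probability":
        raise ValueError("scale must be 'logit' or 'probability'")
    t_mask = treated.astype(bool)
    t_units = sorted(s[t_mask].items(), key=lambda kv: (-kv[1], str(kv[0])))
    c_items = sorted(s[~t_mask].items(), key=lambda kv: (kv[1], str(kv[0])))
    c_vals = np.array([v for _, v in c_items])
    c_ids = [k for k, _ in c_items]
    used = np.zeros(len(c_vals), dtype=bool)
    rows = []
    for unit, sv in t_units:
        pos = int(np.searchsorted(c_vals, sv))
        # nearest unused neighbor: scan outward from the insertion point
        left, right = pos - 1, pos
        while left >= 0 and used[left]:
            left -= 1
        while right < len(c_vals) and used[right]:
            right += 1
        dl = sv - c_vals[left] if left >= 0 else np.inf
        dr = c_vals[right] - sv if right < len(c_vals) else np.inf
        best, best_d = None, np.inf
        if np.isfinite(dl) or np.isfinite(dr):
            if dl < dr:
                best, best_d = left, dl
            elif dr < dl:
                best, best_d = right, dr
            else:  # exact tie: smaller identifier wins
                best = min(left, right, key=lambda i: str(c_ids[i]))
                best_d = dl
        if best is not None and best_d <= caliper:
            rows.append({"treated_id": unit, "control_id": c_ids[best],
                         "distance": float(best_d)})
            if not with_replacement:
                used[best] = True
        else:
            rows.append({"treated_id": unit, "control_id": None, "distance": np.nan})
    matched = pd.DataFrame(rows, columns=["treated_id", "control_id", "distance"])
    n_un = int(matched["control_id"].isna().sum())
    if n_un:
        logger.info("%d treated units unmatched within caliper", n_un)
    return matched
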