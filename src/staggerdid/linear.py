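"""Shared linear-model engine: design construction, OLS/WLS fits and
cluster-robust inference.

All regression designs in the pipeline (staggered DID, event study,
moderation, subgroup fits) reduce to an ordinary least-squares fit of a
per-1,000 linear probability model with wave (and optionally region)
fixed effects absorbed by dummy expansion.  Inference defaults to the
cluster-robust sandwich at the region level with the standard
small-sample factor G/(G-1) * (N-1)/(N-K) and t critical values on G-1
degrees of freedom; the policy varies at region level, so that is the
natural clustering unit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
import statsmodels.api as sm

__all__ = ["ModelSpec", "FitResult", "fit_linear", "wald_interval", "build_design"]


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one linear probability model run.

    Parameters
    ----------
    outcome
        Name of the 0/1000-coded outcome column.
    treatment_terms
        Interaction / focal columns listed first in output tables
        (e.g. the treat x post indicator, event-time dummies).
    covariates
        Individual-level control columns.
    include_treated_main
        Add the ever-treated group dummy as a main effect.  Required for
        the two-period two-group fit to reduce to the classic
        difference-in-means DID; on by default.
    time_fe / region_fe
        Factor columns absorbed via dummy expansion (first level in sort
        order dropped as the reference).  Time fixed effects default to
        the survey wave; region fixed effects are off by default.
    cluster
        Column defining the cluster-robust variance groups, or ``None``
        for classical OLS standard errors.
    cov_method
        Cluster covariance flavour. ``"cr2"`` (default) is the
        Bell–McCaffrey bias-reduced sandwich with per-coefficient
        Satterthwaite degrees of freedom — calibrated even when few
        clusters carry the treatment, as with a handful of pilot
        regions.  ``"cr1"`` is the textbook sandwich with small-sample
        factor G/(G-1) * (N-1)/(N-K) and t inference on G-1 degrees of
        freedom.
    weight
        Optional positive observation-weight column (WLS).
    level
        Confidence level for reported intervals.
    """

    outcome: str = "cancer"
    treatment_terms: tuple[str, ...] = ("cetp_post",)
    covariates: tuple[str, ...] = ()
    include_treated_main: bool = True
    treated_column: str = "treated"
    time_fe: str | None = "wave"
    region_fe: str | None = None
    cluster: str | None = "region_id"
    cov_method: str = "cr2"
    weight: str | None = None
    level: float = 0.95

    def replace(self, **kw) -> "ModelSpec":
        return replace(self, **kw)


def _dummies(series: pd.Series, prefix: str) -> pd.DataFrame:
    levels = sorted(series.unique())
    # first level in sort order is the dropped reference
    cols = {}
    for lv in levels[1:]:
        cols[f"{prefix}[{lv}]"] = (series == lv).astype(float)
    return pd.DataFrame(cols, index=series.index)


def build_design(panel: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Return (y, X) for a spec; X columns ordered const, treatment terms,
    treated main effect, covariates, fixed-effect dummies."""
    missing = [c for c in (spec.outcome, *spec.treatment_terms, *spec.covariates)
               if c not in panel.columns]
    if spec.include_treated_main and spec.treated_column not in panel.columns:
        missing.append(spec.treated_column)
    if missing:
        raise ValueError(f"panel missing model columns: {missing}")
    y = panel[spec.outcome].to_numpy(dtype=float)
    parts: list[pd.DataFrame] = [
        pd.DataFrame({"_cons": np.ones(len(panel))}, index=panel.index)
    ]
    parts.append(panel[list(spec.treatment_terms)].astype(float))
    if spec.include_treated_main:
        parts.append(panel[[spec.treated_column]].astype(float))
    if spec.covariates:
        parts.append(panel[list(spec.covariates)].astype(float))
    for fe in (spec.time_fe, spec.region_fe):
        if fe is not None:
            parts.append(_dummies(panel[fe], fe))
    X = pd.concat(parts, axis=1)
    return y, X


def _check_rank(X: pd.DataFrame) -> None:
    # rank of X equals rank of the (k x k) Gram matrix; avoids an SVD of
    # the full n x k design on large panels
    arr = X.to_numpy(dtype=float)
    gram = arr.T @ arr
    scale = np.sqrt(np.diag(gram))
    scale[scale == 0] = 1.0
    gram = gram / np.outer(scale, scale)
    rank = np.linalg.matrix_rank(gram, tol=1e-10)
    if rank < arr.shape[1]:
        _, _, piv = scipy.linalg.qr(gram, pivoting=True)
        bad = [X.columns[i] for i in piv[rank:]]
        raise ValueError(
            f"design matrix rank deficient ({rank}/{arr.shape[1]}); "
            f"collinear columns: {bad}"
        )


@dataclass
class FitResult:
    """Estimates and cluster-robust inference for one linear model run.

    Mirrors the reporting layout of policy-evaluation tables:
    coefficient, 95% CI, p-value per term, with R^2 and N as footers.
    """

    params: pd.Series
    cov: pd.DataFrame
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    level: float
    nobs: int
    n_clusters: int | None
    df_inference: "float | pd.Series"
    rsquared: float
    rss: float
    spec: ModelSpec
    notes: list[str] = field(default_factory=list)

    @property
    def coef_names(self) -> list[str]:
        return list(self.params.index)

    def treatment_effect(self) -> float:
        return float(self.params[self.spec.treatment_terms[0]])

    def term_df(self, term: str) -> float:
        """Inference degrees of freedom for one term (per-term under
        Satterthwaite, shared otherwise)."""
        if isinstance(self.df_inference, pd.Series):
            return float(self.df_inference[term])
        return float(self.df_inference)

    def wald_interval(self, term: str, level: float | None = None) -> tuple[float, float]:
        """Estimate +/- t-quantile x SE at the given confidence level."""
        if term not in self.params.index:
            raise ValueError(f"unknown term {term!r}; have {list(self.params.index)}")
        level = self.level if level is None else float(level)
        if not 0 < level < 1:
            raise ValueError("level must be in (0, 1)")
        crit = scipy.stats.t.ppf(0.5 + level / 2, self.term_df(term))
        est, se = float(self.params[term]), float(self.bse[term])
        return est - crit * se, est + crit * se

    def _display_order(self, show_fe: bool = False) -> list[str]:
        spec = self.spec
        order = [t for t in spec.treatment_terms]
        if spec.include_treated_main:
            order.append(spec.treated_column)
        order += [c for c in spec.covariates]
        if show_fe:
            order += [c for c in self.params.index
                      if c.startswith(f"{spec.time_fe}[") or
                      (spec.region_fe and c.startswith(f"{spec.region_fe}["))]
        order.append("_cons")
        return [c for c in order if c in self.params.index]

    def to_frame(self, show_fe: bool = False) -> pd.DataFrame:
        rows = self._display_order(show_fe)
        return pd.DataFrame(
            {
                "coef": self.params[rows],
                "ci_low": self.conf_int.loc[rows, "low"],
                "ci_high": self.conf_int.loc[rows, "high"],
                "se": self.bse[rows],
                "t": self.tvalues[rows],
                "p": self.pvalues[rows],
            }
        )

    def summary(self, show_fe: bool = False, title: str | None = None) -> str:
        """Human-readable table: term, coef [95% CI], p; R^2 and N footer."""
        lines = []
        if title:
            lines.append(title)
        lines.append(f"{'term':<24}{'coef [' + format(self.level, '.0%') + ' CI]':<40}{'p':>8}")
        lines.append("-" * 72)
        frame = self.to_frame(show_fe)
        for name, row in frame.iterrows():
            ci = f"{row.coef:.3f} [{row.ci_low:.3f}, {row.ci_high:.3f}]"
            lines.append(f"{name:<24}{ci:<40}{row.p:>8.3f}")
        lines.append("-" * 72)
        lines.append(f"r2    {self.rsquared:.4f}")
        lines.append(f"N     {self.nobs}")
        if self.n_clusters is not None:
            lines.append(f"clusters ({self.spec.cluster})  {self.n_clusters}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "pvalues": self.pvalues.to_dict(),
            "conf_int": {k: [float(v["low"]), float(v["high"])]
                         for k, v in self.conf_int.iterrows()},
            "level": self.level,
            "nobs": int(self.nobs),
            "n_clusters": self.n_clusters,
            "df_inference": (self.df_inference.to_dict()
                             if isinstance(self.df_inference, pd.Series)
                             else float(self.df_inference)),
            "rsquared": float(self.rsquared),
            "rss": float(self.rss),
            "notes": list(self.notes),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _cr2_covariance(X: np.ndarray, u: np.ndarray, codes: np.ndarray,
                    n_groups: int) -> tuple[np.ndarray, np.ndarray]:
    """Bell–McCaffrey bias-reduced cluster covariance with per-coefficient
    Satterthwaite degrees of freedom.

    Each cluster's residuals are pre-multiplied by (I - H_gg)^(-1/2)
    before entering the sandwich, undoing the downward bias of the plain
    estimator when few clusters carry a regressor.  All cluster-level
    algebra is reduced to k x k operations via the eigendecomposition of
    M^(1/2) X_g'X_g M^(1/2), so clusters of any size are cheap.
    """
    n, k = X.shape
    M = np.linalg.inv(X.T @ X)
    lam_m, Q_m = np.linalg.eigh(M)
    Msqrt = (Q_m * np.sqrt(np.clip(lam_m, 0, None))) @ Q_m.T

    order = np.argsort(codes, kind="stable")
    Xs, us, cs = X[order], u[order], codes[order]
    bounds = np.flatnonzero(np.r_[True, cs[1:] != cs[:-1], True])

    S_list, K_list, s_list = [], [], []
    meat = np.zeros((k, k))
    for g in range(n_groups):
        sl = slice(bounds[g], bounds[g + 1])
        Xg, ug = Xs[sl], us[sl]
        S = Xg.T @ Xg
        B = Msqrt @ S @ Msqrt
        lam, Q = np.linalg.eigh(B)
        lam = np.clip(lam, 0.0, 1.0 - 1e-10)
        gfun = np.where(lam > 1e-12,
                        (1.0 / np.sqrt(1.0 - lam) - 1.0) / np.where(lam > 1e-12, lam, 1.0),
                        0.0)
        K = Msqrt @ (Q * gfun) @ Q.T @ Msqrt
        Ug = Xg.T @ ug
        s = Ug + S @ (K @ Ug)
        meat += np.outer(s, s)
        S_list.append(S)
        K_list.append(K)
        s_list.append(s)
    cov = M @ meat @ M

    # Satterthwaite df per coefficient: under the working iid model the
    # variance estimate is a quadratic form with df = (tr O)^2 / tr(O^2)
    dfs = np.empty(k)
    for j in range(k):
        m = M[:, j]
        aa = np.empty(n_groups)
        V = np.empty((n_groups, k))
        for g in range(n_groups):
            S, K = S_list[g], K_list[g]
            r = m + K @ (S @ m)
            aa[g] = r @ S @ r
            V[g] = S @ r
        C = V @ M @ V.T
        diag = np.diag(C)
        tr = float(np.sum(aa - diag))
        tr2 = float((C * C).sum() - np.sum(diag**2) + np.sum((aa - diag) ** 2))
        dfs[j] = tr * tr / tr2 if tr2 > 0 else n - k
    return cov, dfs


def fit_linear(panel: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Fit the spec by (weighted) least squares with the requested variance.

    With a cluster factor the covariance defaults to the bias-reduced
    CR2 sandwich with Satterthwaite t inference (``cov_method="cr2"``);
    ``"cr1"`` selects the textbook cluster sandwich with small-sample
    factor G/(G-1) * (N-1)/(N-K) and t inference on G-1 degrees of
    freedom.  Without clustering, classical OLS on N-K degrees of
    freedom.
    """
    y, X = build_design(panel, spec)
    _check_rank(X)
    if spec.weight is not None:
        w = panel[spec.weight].to_numpy(dtype=float)
        if (w <= 0).any():
            raise ValueError("weights must be positive")
        model = sm.WLS(y, X, weights=w)
    else:
        w = None
        model = sm.OLS(y, X)
    n_clusters: int | None = None
    df_inf: float | pd.Series
    if spec.cluster is not None:
        groups = panel[spec.cluster].to_numpy()
        codes, uniques = pd.factorize(groups)
        n_clusters = len(uniques)
        if n_clusters < 2:
            raise ValueError(
                f"cluster-robust variance needs >= 2 clusters, got {n_clusters}"
            )
        if spec.cov_method == "cr1":
            res = model.fit(method="qr", cov_type="cluster",
                            cov_kwds={"groups": groups}, use_t=True)
            cov = np.asarray(res.cov_params())
            df_inf = float(n_clusters - 1)
        elif spec.cov_method == "cr2":
            res = model.fit(method="qr")
            Xa = X.to_numpy(dtype=float)
            ua = np.asarray(res.resid)
            if w is not None:
                sw = np.sqrt(w)
                Xa, ua = Xa * sw[:, None], ua * sw
            cov, dfs = _cr2_covariance(Xa, ua, codes, n_clusters)
            df_inf = pd.Series(dfs, index=X.columns)
        else:
            raise ValueError(f"unknown cov_method {spec.cov_method!r}")
    else:
        res = model.fit(method="qr", use_t=True)
        cov = np.asarray(res.cov_params())
        df_inf = float(res.df_resid)

    params = pd.Series(res.params, index=X.columns)
    bse = pd.Series(np.sqrt(np.clip(np.diag(cov), 0, None)), index=X.columns)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = params / bse
    df_arr = (df_inf.to_numpy() if isinstance(df_inf, pd.Series)
              else np.full(len(params), df_inf))
    pvals = 2 * scipy.stats.t.sf(np.abs(tvals.to_numpy()), df_arr)
    crit = scipy.stats.t.ppf(0.5 + spec.level / 2, df_arr)
    ci = pd.DataFrame({"low": params - crit * bse, "high": params + crit * bse},
                      index=X.columns)
    with np.errstate(divide="ignore"):
        rsq = float(res.rsquared)
    if not np.isfinite(rsq):
        rsq = 0.0  # constant outcome: zero explainable variation
    return FitResult(
        params=params,
        cov=pd.DataFrame(cov, index=X.columns, columns=X.columns),
        bse=bse,
        tvalues=tvals,
        pvalues=pd.Series(pvals, index=X.columns),
        conf_int=ci,
        level=spec.level,
        nobs=int(res.nobs),
        n_clusters=n_clusters,
        df_inference=df_inf,
        rsquared=rsq,
        rss=float(res.ssr),
        spec=spec,
    )


def wald_interval(fit: FitResult, term: str, level: float = 0.95) -> tuple[float, float]:
    """Confidence interval estimate +/- t_{df} quantile x SE for one term."""
    return fit.wald_interval(term, level)
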