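"""Regression designs for the staggered policy evaluation.

Three designs share the linear engine:

* **Staggered DID** — outcome on treat x post with wave fixed effects
  (plus the ever-treated main effect); the treatment coefficient is the
  average post-adoption outcome shift per 1,000 persons.
* **Event study** — relative-time dummies around each region's adoption
  wave probe pre-adoption trend differences (the parallel-trends check)
  and trace the post-adoption dynamic response.
* **Moderation** — the treatment indicator interacted with a numeric
  moderator (pollution index or depression score) asks whether the
  policy effect is stronger where the moderator is high.

Subgroup fits with Chow F-tests, the per-outcome regression loop and
the pan-cancer composite outcome round out the design set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .linear import FitResult, ModelSpec, build_design, fit_linear
from .panel import PolicySchedule, build_treatment_indicator

__all__ = [
    "StaggeredDID", "estimate_did",
    "EventStudy", "EventStudyCurve", "estimate_event_study",
    "ModerationSpec", "ModeratedDID", "estimate_moderation",
    "build_pan_cancer_outcome", "estimate_per_outcome", "forest_frame",
    "SubgroupComparison", "subgroup_analysis", "chow_test",
]


def _prepare(panel: pd.DataFrame, schedule: PolicySchedule, spec: ModelSpec) -> pd.DataFrame:
    if spec.treatment_terms[0] not in panel.columns:
        panel = build_treatment_indicator(
            panel, schedule, name=spec.treatment_terms[0],
            treated_name=spec.treated_column,
        )
    return panel


class StaggeredDID:
    """Staggered difference-in-differences model.

    Parameters
    ----------
    panel : long-format individual-by-wave DataFrame
    schedule : region -> adoption-year policy schedule
    spec : model specification (outcome, covariates, fixed effects,
        clustering); defaults to the wave-fixed-effect spec clustered at
        region level.
    """

    def __init__(self, panel: pd.DataFrame, schedule: PolicySchedule,
                 spec: ModelSpec | None = None):
        self.spec = spec or ModelSpec()
        self.schedule = schedule
        self.panel = _prepare(panel, schedule, self.spec)
        if self.panel[self.spec.treatment_terms[0]].sum() == 0:
            raise ValueError("no treated observations under this schedule")

    def fit(self) -> FitResult:
        return fit_linear(self.panel, self.spec)


def estimate_did(panel: pd.DataFrame, schedule: PolicySchedule,
                 spec: ModelSpec | None = None) -> FitResult:
    """Fit the staggered DID; the first treatment term is the policy effect."""
    return StaggeredDID(panel, schedule, spec).fit()


# ---------------------------------------------------------------------------
# event study

@dataclass
class EventStudyCurve:
    """Relative-period coefficients with confidence bands.

    The reference period has coefficient identically 0 with a zero-width
    interval; periods are sorted ascending.
    """

    periods: list[int]
    coefs: list[float]
    ci_low: list[float]
    ci_high: list[float]
    reference: int
    level: float = 0.95
    fit: FitResult | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "period": self.periods, "coef": self.coefs,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "is_reference": [p == self.reference for p in self.periods],
        })

    def pre_periods(self) -> pd.DataFrame:
        frame = self.to_frame()
        return frame[(frame["period"] < 0) & ~frame["is_reference"]]

    def post_periods(self) -> pd.DataFrame:
        frame = self.to_frame()
        return frame[(frame["period"] >= 0) & ~frame["is_reference"]]

    def plot(self, ax=None, title: str = "Event-study coefficients"):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        frame = self.to_frame()
        yerr = np.array([frame["coef"] - frame["ci_low"],
                         frame["ci_high"] - frame["coef"]])
        ax.errorbar(frame["period"], frame["coef"], yerr=yerr,
                    fmt="o", capsize=3, color="tab:blue")
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.axvline(-0.5, color="grey", lw=0.8, ls="--")
        ax.set_xlabel("waves relative to adoption")
        ax.set_ylabel("effect per 1,000 persons")
        ax.set_title(title)
        return ax


def _relative_periods(panel: pd.DataFrame, schedule: PolicySchedule,
                      pre: int, post: int) -> tuple[pd.Series, pd.Series]:
    """Binned wave-relative event time for treated records (NaN otherwise)."""
    waves = sorted(panel["wave"].unique())
    wave_pos = {w: i for i, w in enumerate(waves)}
    adoption = panel["region_id"].map(schedule.adoption)
    treated = adoption.notna()

    def adopt_idx(year: float) -> int:
        for i, w in enumerate(waves):
            if w >= year:
                return i
        return len(waves)

    rel = pd.Series(np.nan, index=panel.index)
    idx = panel.loc[treated, "wave"].map(wave_pos)
    aidx = adoption[treated].map(adopt_idx)
    rel.loc[treated] = np.clip(idx - aidx, -pre, post)
    return rel, treated.astype(int)


class EventStudy:
    """Relative-time (event-study) design around staggered adoption.

    Treated records get a dummy for their wave-relative period, binned
    into [-pre_periods, post_periods]; the ``reference`` period (default
    -1, the wave before adoption) is omitted, and never-treated regions
    anchor the counterfactual trend.
    """

    def __init__(self, panel: pd.DataFrame, schedule: PolicySchedule,
                 spec: ModelSpec | None = None, pre_periods: int = 2,
                 post_periods: int = 3, reference: int = -1):
        if not -pre_periods <= reference <= post_periods:
            raise ValueError(
                f"reference period {reference} outside window "
                f"[{-pre_periods}, {post_periods}]"
            )
        self.spec = spec or ModelSpec()
        self.schedule = schedule
        self.pre_periods, self.post_periods = int(pre_periods), int(post_periods)
        self.reference = int(reference)
        panel = panel.copy()
        rel, treated = _relative_periods(panel, schedule, pre_periods, post_periods)
        panel[self.spec.treated_column] = treated
        present = sorted(int(p) for p in rel.dropna().unique())
        if self.reference not in present:
            raise ValueError(
                f"reference period {self.reference} has no treated observations"
            )
        self.periods = present
        dummy_cols = []
        for p in present:
            if p == self.reference:
                continue
            col = f"rel[{p}]"
            panel[col] = (rel == p).astype(float)
            dummy_cols.append(col)
        self.dummy_cols = dummy_cols
        self.panel = panel
        self._spec = self.spec.replace(treatment_terms=tuple(dummy_cols))

    def fit(self) -> EventStudyCurve:
        res = fit_linear(self.panel, self._spec)
        periods, coefs, lo, hi = [], [], [], []
        for p in self.periods:
            periods.append(p)
            if p == self.reference:
                coefs.append(0.0)
                lo.append(0.0)
                hi.append(0.0)
            else:
                col = f"rel[{p}]"
                coefs.append(float(res.params[col]))
                a, b = res.wald_interval(col)
                lo.append(a)
                hi.append(b)
        return EventStudyCurve(periods=periods, coefs=coefs, ci_low=lo,
                               ci_high=hi, reference=self.reference,
                               level=self.spec.level, fit=res)


def estimate_event_study(panel: pd.DataFrame, schedule: PolicySchedule,
                         spec: ModelSpec | None = None, pre_periods: int = 2,
                         post_periods: int = 3, reference: int = -1) -> EventStudyCurve:
    """Fit the parallel-trends event study and return the coefficient curve."""
    return EventStudy(panel, schedule, spec, pre_periods, post_periods,
                      reference).fit()


# ---------------------------------------------------------------------------
# moderation

@dataclass(frozen=True)
class ModerationSpec:
    """Moderator column plus the base model specification."""

    moderator: str
    base: ModelSpec = field(default_factory=ModelSpec)


class ModeratedDID:
    """Triple-interaction design: outcome on moderator, treat x post and
    moderator x treat x post (plus controls and fixed effects).

    A negative triple-interaction coefficient means the policy effect is
    stronger (more protective) where the moderator is high.  An
    identically-zero moderator degenerates to the plain DID (the
    moderator columns vanish and are dropped with a note); any other
    constant moderator is collinear with treat x post and raises.
    """

    def __init__(self, panel: pd.DataFrame, schedule: PolicySchedule,
                 mspec: ModerationSpec):
        self.mspec = mspec
        spec = mspec.base
        panel = _prepare(panel, schedule, spec)
        mod = mspec.moderator
        if mod not in panel.columns:
            raise ValueError(f"moderator column {mod!r} not in panel")
        m = panel[mod].to_numpy(dtype=float)
        if not np.all(np.isfinite(m)):
            raise ValueError(f"moderator {mod!r} has non-finite values")
        self._degenerate = False
        if np.ptp(m) == 0.0:
            if m[0] == 0.0:
                # all-zero interaction columns carry no information
                self._degenerate = True
            else:
                raise ValueError(
                    f"moderator {mod!r} is constant ({m[0]}); the triple "
                    "interaction is collinear with treat x post"
                )
        d = panel[spec.treatment_terms[0]]
        inter = f"{spec.treatment_terms[0]}:{mod}"
        panel = panel.copy()
        panel[inter] = d * panel[mod]
        self.interaction_term = inter
        self.panel = panel
        if self._degenerate:
            self.spec = spec.replace(
                covariates=tuple(c for c in spec.covariates if c != mod)
            )
        else:
            covs = tuple(c for c in spec.covariates if c != mod) + (mod,)
            self.spec = spec.replace(
                treatment_terms=(spec.treatment_terms[0], inter),
                covariates=covs,
            )

    def fit(self) -> FitResult:
        res = fit_linear(self.panel, self.spec)
        if self._degenerate:
            res.notes.append(
                f"moderator {self.mspec.moderator!r} identically zero; "
                "interaction dropped, estimates equal the plain DID"
            )
        return res


def estimate_moderation(panel: pd.DataFrame, schedule: PolicySchedule,
                        mspec: ModerationSpec) -> FitResult:
    """Fit the moderated DID; the ``<treat>:<moderator>`` term is the
    triple-interaction coefficient."""
    return ModeratedDID(panel, schedule, mspec).fit()


# ---------------------------------------------------------------------------
# per-outcome loop and pan-cancer composite

def build_pan_cancer_outcome(panel: pd.DataFrame, cancer_columns: Sequence[str],
                             name: str = "pan_cancer") -> pd.DataFrame:
    """Composite event outcome: 1000 if any listed site event occurred."""
    cancer_columns = list(cancer_columns)
    if not cancer_columns:
        raise ValueError("cancer_columns must be non-empty")
    missing = [c for c in cancer_columns if c not in panel.columns]
    if missing:
        raise ValueError(f"panel missing outcome columns: {missing}")
    panel = panel.copy()
    panel[name] = (panel[cancer_columns].to_numpy() > 0).any(axis=1).astype(int) * 1000
    return panel


def estimate_per_outcome(panel: pd.DataFrame, schedule: PolicySchedule,
                         spec: ModelSpec, outcomes: Sequence[str],
                         bh_correct: bool = False) -> list[FitResult]:
    """One DID fit per outcome column, in input order.

    ``bh_correct`` optionally appends Benjamini-Hochberg adjusted
    p-values for the treatment term (off by default; the primary
    analysis reports unadjusted per-site tests).
    """
    panel = _prepare(panel, schedule, spec)
    results = [fit_linear(panel, spec.replace(outcome=out)) for out in outcomes]
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        term = spec.treatment_terms[0]
        pvals = [r.pvalues[term] for r in results]
        _, adj, _, _ = multipletests(pvals, method="fdr_bh")
        for r, q in zip(results, adj):
            r.notes.append(f"bh_adjusted_p={q:.6g}")
    return results


def forest_frame(results: Sequence[FitResult],
                 outcomes: Sequence[str]) -> pd.DataFrame:
    """Treatment coefficient, CI and p per outcome (forest-plot table)."""
    rows = []
    for out, res in zip(outcomes, results):
        term = res.spec.treatment_terms[0]
        lo, hi = res.conf_int.loc[term, "low"], res.conf_int.loc[term, "high"]
        rows.append({"outcome": out, "coef": res.params[term],
                     "ci_low": lo, "ci_high": hi, "p": res.pvalues[term],
                     "n": res.nobs})
    return pd.DataFrame(rows)


def plot_forest(frame: pd.DataFrame, ax=None, title: str = "Policy effect by outcome"):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.3 * len(frame) + 2))
    ypos = np.arange(len(frame))[::-1]
    err = np.array([frame["coef"] - frame["ci_low"],
                    frame["ci_high"] - frame["coef"]])
    ax.errorbar(frame["coef"], ypos, xerr=err, fmt="o", capsize=2,
                color="tab:blue")
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_yticks(ypos)
    ax.set_yticklabels(frame["outcome"])
    ax.set_xlabel("effect per 1,000 persons")
    ax.set_title(title)
    return ax


# ---------------------------------------------------------------------------
# subgroups and Chow test

def chow_test(panel: pd.DataFrame, spec: ModelSpec, grouping: str) -> tuple[float, float]:
    """Chow F-test of coefficient equality across subsamples.

    F = [(RSS_pooled - sum RSS_g) / ((G-1) k)] / [sum RSS_g / (N - G k)]
    with k model parameters, against F_{(G-1)k, N-Gk}.  Group fits use
    the pooled design columns so k is common across groups.
    """
    y, X = build_design(panel, spec)
    arr = X.to_numpy(dtype=float)
    k = arr.shape[1]
    groups = panel[grouping]
    labels = [g for g in pd.unique(groups) if pd.notna(g)]
    if len(labels) < 2:
        raise ValueError(f"grouping {grouping!r} yields fewer than 2 groups")
    n = len(y)
    g = len(labels)
    df_den = n - g * k
    if df_den < 1:
        raise ValueError("insufficient residual degrees of freedom for Chow test")

    def rss(a: np.ndarray, b: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(a, b, rcond=None)
        resid = b - a @ beta
        return float(resid @ resid)

    rss_pooled = rss(arr, y)
    rss_groups = 0.0
    for lab in labels:
        mask = (groups == lab).to_numpy()
        rss_groups += rss(arr[mask], y[mask])
    df_num = (g - 1) * k
    num = max(rss_pooled - rss_groups, 0.0) / df_num
    den = rss_groups / df_den
    if den == 0.0:
        return 0.0, 1.0
    f_stat = num / den
    p = float(scipy.stats.f.sf(f_stat, df_num, df_den))
    return float(f_stat), p


def _group_labels(values: pd.Series, cutpoints: Sequence[float] | None) -> pd.Series:
    if cutpoints is None:
        return values.astype(str)
    cuts = sorted(float(c) for c in cutpoints)
    labels = [f"<{cuts[0]:g}"]
    labels += [f"{a:g}-{b:g}" for a, b in zip(cuts, cuts[1:])]
    labels += [f">={cuts[-1]:g}"]
    idx = np.digitize(values.to_numpy(dtype=float), cuts)
    return pd.Series([labels[i] for i in idx], index=values.index)


@dataclass
class SubgroupComparison:
    """Per-group DID fits plus the Chow test of coefficient equality."""

    grouping: str
    fits: dict[str, FitResult | None]
    chow_f: float
    chow_p: float
    skipped: dict[str, str] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        rows = []
        for label, res in self.fits.items():
            if res is None:
                rows.append({"group": label, "coef": np.nan, "ci_low": np.nan,
                             "ci_high": np.nan, "p": np.nan, "n": 0,
                             "note": self.skipped.get(label, "")})
                continue
            term = res.spec.treatment_terms[0]
            rows.append({
                "group": label, "coef": res.params[term],
                "ci_low": res.conf_int.loc[term, "low"],
                "ci_high": res.conf_int.loc[term, "high"],
                "p": res.pvalues[term], "n": res.nobs, "note": "",
            })
        out = pd.DataFrame(rows)
        out.attrs["chow_f"] = self.chow_f
        out.attrs["chow_p"] = self.chow_p
        return out


def subgroup_analysis(panel: pd.DataFrame, schedule: PolicySchedule,
                      spec: ModelSpec, grouping: str,
                      cutpoints: Sequence[float] | None = None) -> SubgroupComparison:
    """Stratified DID fits with a Chow test across estimable groups.

    Continuous grouping variables are cut at ``cutpoints`` into labeled
    bins (e.g. BMI at 18.5 and 25 -> "<18.5", "18.5-25", ">=25").  The
    grouping variable is dropped from the subgroup covariate sets.  A
    group with no treated observations is flagged and excluded from the
    Chow comparison.
    """
    panel = _prepare(panel, schedule, spec)
    labels = _group_labels(panel[grouping], cutpoints)
    panel = panel.copy()
    panel["_group"] = labels
    sub_spec = spec.replace(
        covariates=tuple(c for c in spec.covariates if c != grouping)
    )
    fits: dict[str, FitResult | None] = {}
    skipped: dict[str, str] = {}
    estimable: list[str] = []
    uniq = sorted(labels.unique())
    if len(uniq) < 2:
        raise ValueError(f"grouping {grouping!r} yields fewer than 2 non-empty groups")
    for lab in uniq:
        sub = panel[panel["_group"] == lab]
        if sub[spec.treatment_terms[0]].sum() == 0:
            fits[lab] = None
            skipped[lab] = "no treated observations"
            continue
        try:
            fits[lab] = fit_linear(sub, sub_spec)
            estimable.append(lab)
        except ValueError as exc:
            fits[lab] = None
            skipped[lab] = str(exc)
    if len(estimable) >= 2:
        mask = panel["_group"].isin(estimable)
        chow_f, chow_p = chow_test(panel[mask], sub_spec, "_group")
    else:
        chow_f, chow_p = np.nan, np.nan
    return SubgroupComparison(grouping=grouping, fits=fits, chow_f=chow_f,
                              chow_p=chow_p, skipped=skipped)
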