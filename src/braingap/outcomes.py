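"""BAG-outcome association suite.

Tertile stratification of the corrected brain-age gap, Cox proportional
hazards models for mortality (all participants, cognitively-normal only,
and a cause-specific competing-risk sensitivity analysis), least-squares
mean contrasts of BAG across cognitive-status groups, and covariate-adjusted
per-phenotype linear regressions with BAG as the outcome.

Conventions mirror the study design this package emulates: the *highest*
BAG tertile (oldest-looking brains) is the survival reference, tertile
boundary ties go down at the first cut and up at the second, Cox ties use
the Efron approximation, and every model is complete-case with the number
of excluded rows recorded on the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy import stats

__all__ = [
    "CoxResult",
    "LsMeansResult",
    "assign_tertiles",
    "fit_cox",
    "fit_competing_risk_cox",
    "lsmeans_by_group",
    "phenotype_assoc",
]

TERTILE_NAMES = {1: "lowest", 2: "middle", 3: "highest"}


def assign_tertiles(values: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Split values into tertiles by the empirical 1/3 and 2/3 quantiles.

    Label 1 (lowest) for v <= q1, 3 (highest) for v >= q2, else 2 — values
    sitting exactly on a boundary go to the outer groups, matching the
    convention t1 <= q1 < t2 < q2 <= t3.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3 or not np.all(np.isfinite(values)):
        raise ValueError("need >= 3 finite values")
    # order-statistic boundaries keep all three groups within 1 of n/3:
    # q1 is the round(n/3)-th smallest, q2 the round(n/3)-th largest value
    srt = np.sort(values)
    k = max(int(round(values.size / 3.0)), 1)
    q1 = float(srt[k - 1])
    q2 = float(srt[values.size - k])
    labels = np.full(values.shape, 2, dtype=int)
    labels[values <= q1] = 1
    labels[values >= q2] = 3
    counts = np.bincount(labels, minlength=4)[1:]
    if (counts == 0).any():
        raise ValueError(
            f"tertile boundaries collide (q1={q1:.6g}, q2={q2:.6g}); "
            "heavy ties leave a group empty"
        )
    return labels, (float(q1), float(q2))


@dataclass
class CoxResult:
    """Tertile hazard ratios vs the reference, with Wald 95% CIs."""

    table: pd.DataFrame               # index: term; HR, ci_low, ci_high, p
    n: int
    n_events: int
    n_competing: int = 0
    n_excluded: int = 0
    reference: int = 3
    fitter: CoxPHFitter | None = field(default=None, repr=False)

    def summary(self) -> str:
        lines = [f"Cox PH (Efron ties): n={self.n}, events={self.n_events}"
                 + (f", competing events={self.n_competing}"
                    if self.n_competing else "")]
        for term, row in self.table.iterrows():
            lines.append(
                f"  {term}: HR {row['hazard_ratio']:.2f} "
                f"({row['ci_low']:.2f}-{row['ci_high']:.2f}) p={row['p_value']:.2g}"
            )
        lines.append(f"  {TERTILE_NAMES[self.reference]} tertile: HR 1.00 (reference)")
        return "\n".join(lines)


def _encode_covariates(df: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Numeric covariates pass through; categoricals become drop-first dummies."""
    parts = []
    for cov in covariates:
        col = df[cov]
        if col.dtype.kind in "biufc":
            parts.append(col.astype(float).rename(cov))
        else:
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            parts.append(dummies)
    if not parts:
        return pd.DataFrame(index=df.index)
    return pd.concat(parts, axis=1)


def _prepare_cox_frame(df: pd.DataFrame, tertile_col: str, covariates: list[str],
                       duration_col: str, event_col: str, reference: int):
    cols = [duration_col, event_col, tertile_col] + list(covariates)
    work = df[cols].copy()
    n_before = len(work)
    work = work.dropna()
    n_excluded = n_before - len(work)
    tert = work[tertile_col].astype(int)
    frame = pd.DataFrame({
        duration_col: work[duration_col].astype(float),
        event_col: work[event_col].astype(int),
    })
    for level in (1, 2, 3):
        if level != reference:
            frame[f"tertile_{TERTILE_NAMES[level]}"] = (tert == level).astype(float)
    enc = _encode_covariates(work, list(covariates))
    frame = pd.concat([frame, enc], axis=1)
    return frame, n_excluded


def fit_cox(df: pd.DataFrame, tertile_col: str = "tertile",
            covariates: list[str] | None = None, duration_col: str = "time",
            event_col: str = "event", reference: int = 3) -> CoxResult:
    """Cox PH of mortality on BAG-tertile dummies plus covariates.

    The reference tertile (default 3, the highest/oldest-looking) is fixed at
    HR 1; ties are handled by the Efron approximation (lifelines default).
    """
    covariates = list(covariates or [])
    frame, n_excluded = _prepare_cox_frame(df, tertile_col, covariates,
                                           duration_col, event_col, reference)
    cph = CoxPHFitter()
    cph.fit(frame, duration_col=duration_col, event_col=event_col,
            fit_options={"precision": 1e-9, "max_steps": 500})
    summ = cph.summary
    terms = [c for c in frame.columns if c.startswith("tertile_")]
    table = pd.DataFrame({
        "hazard_ratio": np.exp(summ.loc[terms, "coef"]),
        "ci_low": np.exp(summ.loc[terms, "coef lower 95%"]),
        "ci_high": np.exp(summ.loc[terms, "coef upper 95%"]),
        "p_value": summ.loc[terms, "p"],
    })
    return CoxResult(table=table, n=len(frame),
                     n_events=int(frame[event_col].sum()),
                     n_excluded=n_excluded, reference=reference, fitter=cph)


def fit_competing_risk_cox(df: pd.DataFrame, tertile_col: str = "tertile",
                           covariates: list[str] | None = None,
                           duration_col: str = "time", event_col: str = "event",
                           cause_col: str = "cause", event_cause: str = "nonCNS",
                           reference: int = 3) -> CoxResult:
    """Cause-specific Cox: deaths from the competing cause are censored.

    Only deaths with ``cause == event_cause`` count as events; competing-cause
    deaths keep their event time but contribute as censored observations.
    With zero competing events this reduces exactly to :func:`fit_cox`.
    """
    work = df.copy()
    is_event = work[event_col].astype(int) == 1
    competing = is_event & (work[cause_col] != event_cause)
    work[event_col] = (is_event & (work[cause_col] == event_cause)).astype(int)
    result = fit_cox(work, tertile_col=tertile_col, covariates=covariates,
                     duration_col=duration_col, event_col=event_col,
                     reference=reference)
    result.n_competing = int(competing.sum())
    return result


@dataclass
class LsMeansResult:
    """Adjusted (least-squares) group means and all pairwise contrasts."""

    group_table: pd.DataFrame         # group, n, lsmean, stderr, ci_low, ci_high
    contrast_table: pd.DataFrame      # group_1, group_2, difference, stderr, p
    ols_result: object = field(default=None, repr=False)

    def summary(self) -> str:
        lines = ["LS means"]
        for _, r in self.group_table.iterrows():
            lines.append(f"  {r['group']}: {r['lsmean']:.2f} "
                         f"(SE {r['stderr']:.2f}, n={int(r['n'])})")
        lines.append("Pairwise contrasts")
        for _, r in self.contrast_table.iterrows():
            lines.append(f"  {r['group_1']} vs {r['group_2']}: "
                         f"{r['difference']:.2f} (SE {r['stderr']:.2f}) "
                         f"p={r['p_value']:.2g}")
        return "\n".join(lines)


def _group_levels(series: pd.Series) -> list:
    if isinstance(series.dtype, pd.CategoricalDtype):
        return [g for g in series.cat.categories if (series == g).any()]
    return sorted(series.dropna().unique())


def lsmeans_by_group(df: pd.DataFrame, outcome: str, group: str,
                     covariates: list[str] | None = None) -> LsMeansResult:
    """LS means of ``outcome`` per level of ``group``, adjusted for covariates.

    The linear model outcome ~ group + covariates is evaluated per group at
    the covariates' sample means (categorical covariates at their observed
    proportions). With no covariates the LS means equal raw group means.
    """
    covariates = list(covariates or [])
    work = df[[outcome, group] + covariates].dropna()
    levels = _group_levels(work[group])
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    for g in levels:
        if (work[group] == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")

    y = work[outcome].to_numpy(dtype=float)
    group_dummies = pd.DataFrame(
        {f"{group}[{g}]": (work[group] == g).astype(float) for g in levels[1:]},
        index=work.index,
    )
    cov_design = _encode_covariates(work, covariates)
    X = pd.concat([pd.Series(1.0, index=work.index, name="Intercept"),
                   group_dummies, cov_design], axis=1)
    Xv = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(Xv)
    if rank < Xv.shape[1]:
        # name aliased columns via the QR diagonal
        _, r = np.linalg.qr(Xv)
        aliased = [X.columns[j] for j in range(Xv.shape[1])
                   if abs(r[j, j]) < 1e-8 * abs(r[0, 0])]
        raise ValueError(f"design is rank deficient; aliased terms: {aliased}")
    fit = sm.OLS(y, Xv).fit()
    beta = fit.params
    cov_beta = fit.cov_params()
    dfree = fit.df_resid

    cov_means = cov_design.mean(axis=0).to_numpy() if len(covariates) else np.empty(0)
    L = {}
    for g in levels:
        row = np.concatenate([[1.0],
                              [1.0 if g == h else 0.0 for h in levels[1:]],
                              cov_means])
        L[g] = row

    tcrit = stats.t.ppf(0.975, dfree)
    grows = []
    for g in levels:
        est = float(L[g] @ beta)
        se = float(np.sqrt(L[g] @ cov_beta @ L[g]))
        grows.append({"group": g, "n": int((work[group] == g).sum()),
                      "lsmean": est, "stderr": se,
                      "ci_low": est - tcrit * se, "ci_high": est + tcrit * se})
    crows = []
    for g, h in combinations(levels, 2):
        c = L[g] - L[h]
        est = float(c @ beta)
        se = float(np.sqrt(c @ cov_beta @ c))
        tval = est / se
        p = 2 * stats.t.sf(abs(tval), dfree)
        crows.append({"group_1": g, "group_2": h, "difference": est,
                      "stderr": se, "p_value": float(p)})
    return LsMeansResult(group_table=pd.DataFrame(grows),
                         contrast_table=pd.DataFrame(crows), ols_result=fit)


def phenotype_assoc(df: pd.DataFrame, bag_col: str, phenotypes: list[str],
                    covariates: list[str] | None = None) -> pd.DataFrame:
    """One linear model per phenotype with BAG as the outcome.

    Returns one row per phenotype: coefficient (BAG-years per unit or vs the
    reference level), Wald 95% CI, p-value, and complete-case n.
    """
    covariates = list(covariates or [])
    rows = []
    for pheno in phenotypes:
        work = df[[bag_col, pheno] + covariates].dropna()
        col = work[pheno]
        if col.dtype.kind in "biufc":
            x = col.astype(float)
            if x.nunique() < 2:
                raise ValueError(f"phenotype {pheno!r} is constant")
            xdf = x.to_frame(pheno)
        else:
            xdf = pd.get_dummies(col, prefix=pheno, drop_first=True, dtype=float)
            if xdf.shape[1] != 1:
                raise ValueError(f"phenotype {pheno!r} must be binary or continuous")
        X = pd.concat([pd.Series(1.0, index=work.index, name="Intercept"),
                       xdf, _encode_covariates(work, covariates)], axis=1)
        fit = sm.OLS(work[bag_col].to_numpy(dtype=float),
                     X.to_numpy(dtype=float)).fit()
        j = 1  # phenotype column sits right after the intercept
        ci = fit.conf_int()[j]
        rows.append({"phenotype": pheno, "coefficient": float(fit.params[j]),
                     "ci_low": float(ci[0]), "ci_high": float(ci[1]),
                     "p_value": float(fit.pvalues[j]), "n": int(len(work))})
    return pd.DataFrame(rows)
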