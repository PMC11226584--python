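"""Proteome-wide association scan of the brain-age gap.

For every analyte that passes quality control, an ordinary-least-squares
model is fitted with BAG as the outcome and the (standardized) analyte plus
covariates as predictors. Multiplicity is controlled two ways on the same
p-values: Bonferroni at alpha/m (m = analytes actually tested) and the
Benjamini-Hochberg step-up FDR at alpha. Bonferroni rejections are always a
subset of the BH rejections at equal alpha.

The per-analyte fits are computed in one pass by the Frisch-Waugh-Lovell
decomposition (residualize outcome and analyte on the covariates, then a
simple regression with the covariate-adjusted degrees of freedom), which is
algebraically identical to fitting each full OLS model separately; analytes
with missing values fall back to a per-column complete-case fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ProteomicsMatrix",
    "PwasResult",
    "qc_filter",
    "run_pwas",
    "bh_stepup",
    "pwas_report",
]


@dataclass
class ProteomicsMatrix:
    """Subjects x analytes relative concentrations with QC-pass flags."""

    values: pd.DataFrame              # index: subject_id, columns: analyte_id
    qc_pass: pd.Series                # bool per analyte
    transform: str = "raw"            # marker: raw | log2 | rank

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("analyte IDs must be unique")
        if not self.qc_pass.index.equals(self.values.columns):
            self.qc_pass = self.qc_pass.reindex(self.values.columns)
            if self.qc_pass.isna().any():
                raise ValueError("qc_pass flags do not cover all analytes")
        self.qc_pass = self.qc_pass.astype(bool)

    @property
    def n_analytes(self) -> int:
        return self.values.shape[1]

    @property
    def analyte_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_csv(self, values_path: str | Path, qc_path: str | Path) -> None:
        self.values.to_csv(values_path, index_label="subject_id")
        self.qc_pass.rename("qc_pass").to_csv(qc_path, index_label="analyte_id")

    @classmethod
    def from_csv(cls, values_path: str | Path,
                 qc_path: str | Path | None = None) -> "ProteomicsMatrix":
        values = pd.read_csv(values_path, index_col="subject_id")
        if qc_path is not None:
            qc = pd.read_csv(qc_path, index_col="analyte_id")["qc_pass"]
        else:
            qc = pd.Series(True, index=values.columns)
        return cls(values=values, qc_pass=qc)


def qc_filter(matrix: ProteomicsMatrix) -> ProteomicsMatrix:
    """Keep only analytes whose QC flag is set; error if none survive."""
    keep = matrix.qc_pass[matrix.qc_pass].index
    if len(keep) == 0:
        raise ValueError("no analytes pass quality control")
    return ProteomicsMatrix(
        values=matrix.values[keep].copy(),
        qc_pass=matrix.qc_pass.loc[keep].copy(),
        transform=matrix.transform,
    )


def bh_stepup(p_values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejections at level alpha.

    Reject H_(1..k*) where k* is the largest k with p_(k) <= k*alpha/m.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    thresh = alpha * (np.arange(1, m + 1)) / m
    below = p[order] <= thresh
    reject = np.zeros(m, dtype=bool)
    if below.any():
        k_star = int(np.max(np.nonzero(below)[0]))
        reject[order[: k_star + 1]] = True
    return reject


@dataclass
class PwasResult:
    """Per-analyte scan results plus the multiplicity bookkeeping."""

    table: pd.DataFrame               # analyte, beta, stderr, p_value, flags, n_used
    alpha: float
    m_tested: int
    transform: str
    skipped: list[str] = field(default_factory=list)

    @property
    def bonferroni_threshold(self) -> float:
        return self.alpha / self.m_tested

    def significant(self, method: str = "bonferroni") -> pd.DataFrame:
        col = {"bonferroni": "bonferroni_significant",
               "fdr": "fdr_significant"}[method]
        return self.table[self.table[col]].sort_values("p_value")

    def summary(self) -> str:
        nb = int(self.table["bonferroni_significant"].sum())
        nf = int(self.table["fdr_significant"].sum())
        return (f"PWAS: {self.m_tested} analytes tested "
                f"(transform: {self.transform}); "
                f"{nb} Bonferroni-significant, {nf} FDR-significant "
                f"at alpha={self.alpha}")


def _transform_analytes(values: pd.DataFrame, transform: str) -> pd.DataFrame:
    if transform == "raw":
        return values
    if transform == "log2":
        if (values <= 0).any().any():
            raise ValueError("log2 transform requires strictly positive analytes")
        return np.log2(values)
    if transform == "rank":
        ranked = values.rank(axis=0)
        return pd.DataFrame(
            stats.norm.ppf(ranked / (len(values) + 1)),
            index=values.index, columns=values.columns,
        )
    raise ValueError(f"unknown transform {transform!r}")


def run_pwas(bag: pd.Series, matrix: ProteomicsMatrix,
             covariates: pd.DataFrame | None = None, alpha: float = 0.05,
             transform: str = "raw", qc: bool = True) -> PwasResult:
    """Scan every analyte for association with BAG.

    Parameters
    ----------
    bag : Series indexed by subject_id (the corrected gap, years).
    matrix : the analyte panel; QC-failing analytes are dropped first
        unless ``qc=False``.
    covariates : optional DataFrame indexed by subject_id; categoricals are
        dummy-encoded. Subjects are aligned by index across all three inputs.
    transform : "raw" | "log2" | "rank" applied before per-analyte
        standardization, so betas are BAG-years per SD of (transformed) analyte.
    """
    if qc:
        matrix = qc_filter(matrix)
    values = matrix.values
    common = bag.index.intersection(values.index)
    missing = bag.index.difference(values.index)
    if len(common) == 0:
        raise ValueError("subject IDs do not align between BAG and panel; "
                         f"unmatched (first 5): {list(missing)[:5]}")
    if covariates is not None:
        common = common.intersection(covariates.index)
        cov = covariates.loc[common]
        from .outcomes import _encode_covariates
        C = _encode_covariates(cov, list(cov.columns)).to_numpy(dtype=float)
        C = np.column_stack([np.ones(len(common)), C])
    else:
        C = np.ones((len(common), 1))
    y = bag.loc[common].to_numpy(dtype=float)
    Z = _transform_analytes(values.loc[common], transform)
    n, q = C.shape
    if n < q + 10:
        raise ValueError(f"need >= {q + 10} subjects for {q} covariate "
                         f"parameters; have {n}")

    # standardize analytes; drop (skip) constant columns
    Zv = Z.to_numpy(dtype=float)
    analyte_ids = np.array(Z.columns)
    sd = np.nanstd(Zv, axis=0)
    skipped = [str(a) for a in analyte_ids[sd == 0]]
    keep = sd > 0
    Zv, analyte_ids, sd = Zv[:, keep], analyte_ids[keep], sd[keep]
    Zv = (Zv - np.nanmean(Zv, axis=0)) / sd

    # FWL in one pass for complete columns; per-column fallback otherwise
    Cpinv = np.linalg.pinv(C)
    ey = y - C @ (Cpinv @ y)
    df_resid = n - q - 1
    has_nan = np.isnan(Zv).any(axis=0)
    beta = np.full(Zv.shape[1], np.nan)
    se = np.full(Zv.shape[1], np.nan)
    n_used = np.full(Zv.shape[1], n)
    comp = ~has_nan
    if comp.any():
        E = Zv[:, comp] - C @ (Cpinv @ Zv[:, comp])
        denom = np.einsum("ij,ij->j", E, E)
        num = E.T @ ey
        b = num / denom
        rss = ey @ ey - b * num
        s2 = rss / df_resid
        beta[comp] = b
        se[comp] = np.sqrt(s2 / denom)
    for j in np.nonzero(has_nan)[0]:
        rows = ~np.isnan(Zv[:, j])
        nj = int(rows.sum())
        if nj < q + 3:
            skipped.append(str(analyte_ids[j]))
            continue
        Cj = C[rows]
        zj = Zv[rows, j]
        yj = y[rows]
        Cjp = np.linalg.pinv(Cj)
        eyj = yj - Cj @ (Cjp @ yj)
        ez = zj - Cj @ (Cjp @ zj)
        denom = ez @ ez
        bj = (ez @ eyj) / denom
        rss = eyj @ eyj - bj * (ez @ eyj)
        beta[j] = bj
        se[j] = np.sqrt(rss / (nj - q - 1) / denom)
        n_used[j] = nj

    ok = np.isfinite(beta)
    analyte_ids, beta, se, n_used = (analyte_ids[ok], beta[ok], se[ok],
                                     n_used[ok])
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals),
                           np.where(n_used == n, df_resid, n_used - q - 1))
    m = beta.size
    bonf = pvals <= alpha / m
    fdr = bh_stepup(pvals, alpha)
    table = pd.DataFrame({
        "analyte": analyte_ids,
        "beta": beta,
        "stderr": se,
        "p_value": pvals,
        "bonferroni_significant": bonf,
        "fdr_significant": fdr,
        "n_used": n_used,
    })
    return PwasResult(table=table, alpha=alpha, m_tested=m,
                      transform=transform, skipped=skipped)


def pwas_report(result: PwasResult, out_dir: str | Path | None = None,
                plot: bool = False):
    """Tidy table sorted by p plus volcano coordinates and threshold lines.

    Returns (sorted table, volcano DataFrame with beta and -log10 p, dict of
    threshold lines). Optionally writes ``pwas.csv``/``volcano.png``.
    """
    if result.table.empty:
        raise ValueError("empty PWAS result")
    table = result.table.sort_values("p_value").reset_index(drop=True)
    volcano = pd.DataFrame({
        "analyte": table["analyte"],
        "beta": table["beta"],
        "neg_log10_p": -np.log10(np.clip(table["p_value"], 1e-300, None)),
    })
    rejected = table.loc[table["fdr_significant"], "p_value"]
    bh_line = float(rejected.max()) if len(rejected) else np.nan
    lines = {
        "bonferroni_p": result.bonferroni_threshold,
        "bh_p": bh_line,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "pwas.csv", index=False)
        if plot:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(figsize=(7, 5))
            ax.scatter(volcano["beta"], volcano["neg_log10_p"], s=6,
                       c=np.where(table["bonferroni_significant"], "crimson",
                                  np.where(table["fdr_significant"],
                                           "seagreen", "grey")))
            ax.axhline(-np.log10(lines["bonferroni_p"]), color="red", lw=1,
                       label="Bonferroni")
            if np.isfinite(bh_line):
                ax.axhline(-np.log10(bh_line), color="green", lw=1, label="FDR")
            ax.set_xlabel("beta (BAG years per analyte SD)")
            ax.set_ylabel("-log10 p")
            ax.legend(loc="upper right", fontsize=8)
            fig.tight_layout()
            fig.savefig(out / "volcano.png", dpi=120)
            plt.close(fig)
    return table, volcano, lines
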