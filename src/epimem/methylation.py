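"""Global DNA methylation percentage (%mC) and the genotype-by-environment
statistics: replicate aggregation, two-way ANOVA with Tukey post hoc, and
normality-gated correlation analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd


class MethylationError(ValueError):
    pass


def percent_mC(C_amount: float, mC_amount: float) -> float:
    """%mC = mC / (C + mC) * 100."""
    if C_amount < 0 or mC_amount < 0:
        raise MethylationError("nucleoside amounts must be >= 0")
    total = C_amount + mC_amount
    if total <= 0:
        raise MethylationError("%mC undefined when C + mC is zero")
    return mC_amount / total * 100.0


def aggregate_replicates(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average technical replicates per individual, then summarize cells.

    ``records`` needs columns (genotype, condition, individual, C_amount,
    mC_amount); hydrolysis/run replicates are averaged unweighted per
    individual. Returns ``(per_individual, per_cell)`` where per_cell
    carries genotype-by-condition mean %mC, SE over individuals, and n.
    With a single individual the SE is reported as missing.
    """
    df = records.copy()
    df["pct_mC"] = [percent_mC(c, m) for c, m in zip(df["C_amount"], df["mC_amount"])]
    per_individual = (df.groupby(["genotype", "condition", "individual"], sort=True)
                        ["pct_mC"].mean().reset_index())
    grouped = per_individual.groupby(["genotype", "condition"], sort=True)["pct_mC"]
    per_cell = grouped.agg(mean_pct="mean", n="count",
                           se=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan
                           ).reset_index()
    per_cell["n"] = per_cell["n"].astype(int)
    return per_individual, per_cell


@dataclass
class GxeResult:
    anova: pd.DataFrame            # F and p for genotype, condition, interaction
    tukey: dict[str, pd.DataFrame]  # per-condition pairwise genotype comparisons
    shapiro_p: float               # Shapiro-Wilk on ANOVA residuals
    degenerate: bool = False       # zero residual variance; F undefined

    @property
    def interaction_p(self) -> float:
        return float(self.anova.loc["genotype:condition", "PR(>F)"])


def anova_gxe(per_individual: pd.DataFrame) -> GxeResult:
    """Two-way type-II ANOVA of %mC on genotype x condition with Tukey HSD
    on genotypes within each condition and Shapiro-Wilk on residuals.

    Requires >= 2 genotypes, >= 2 conditions, and >= 2 individuals in
    every genotype-by-condition cell; empty cells are named in the error.
    """
    df = per_individual.rename(columns={"pct_mC": "pct"})
    if df["genotype"].nunique() < 2 or df["condition"].nunique() < 2:
        raise MethylationError("need >= 2 genotypes and >= 2 conditions")
    cells = df.groupby(["genotype", "condition"]).size()
    full = pd.MultiIndex.from_product([df["genotype"].unique(), df["condition"].unique()])
    missing = [t for t in full if t not in cells.index or cells[t] < 2]
    if missing:
        raise MethylationError(f"cells with < 2 individuals: {missing[:10]}")

    model = smf.ols("pct ~ C(genotype) * C(condition)", data=df).fit()
    resid = model.resid.to_numpy()
    degenerate = float(np.var(resid)) < 1e-20
    if degenerate:
        anova = pd.DataFrame(
            {"sum_sq": np.nan, "df": np.nan, "F": np.nan, "PR(>F)": np.nan},
            index=["genotype", "condition", "genotype:condition", "Residual"])
        shapiro_p = float("nan")
    else:
        anova = sm.stats.anova_lm(model, typ=2)
        anova.index = ["genotype", "condition", "genotype:condition", "Residual"]
        shapiro_p = float(stats.shapiro(resid).pvalue)

    tukey: dict[str, pd.DataFrame] = {}
    for condition, group in df.groupby("condition", sort=True):
        if group["genotype"].nunique() < 2 or degenerate:
            continue
        res = pairwise_tukeyhsd(group["pct"], group["genotype"])
        tukey[condition] = pd.DataFrame(res.summary().data[1:],
                                        columns=res.summary().data[0])
    return GxeResult(anova=anova, tukey=tukey, shapiro_p=shapiro_p, degenerate=degenerate)


@dataclass
class CorrelationResult:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    shapiro_p_x: float
    shapiro_p_y: float
    n: int

    @property
    def pearson_valid(self) -> bool:
        """Pearson is reported only when both variables pass normality."""
        return self.shapiro_p_x > 0.05 and self.shapiro_p_y > 0.05


def correlate(x, y) -> CorrelationResult:
    """Pearson r and Spearman rho with two-sided p-values, plus per-variable
    Shapiro-Wilk normality checks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise MethylationError("need >= 3 paired finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise MethylationError("zero variance in a correlated variable")
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return CorrelationResult(
        pearson_r=float(pr.statistic), pearson_p=float(pr.pvalue),
        spearman_rho=float(sr.statistic), spearman_p=float(sr.pvalue),
        shapiro_p_x=float(stats.shapiro(x).pvalue),
        shapiro_p_y=float(stats.shapiro(y).pvalue),
        n=int(x.size))


def methylation_biomass_correlations(per_cell: pd.DataFrame,
                                     biomass: pd.DataFrame) -> pd.DataFrame:
    """Per-condition correlation of genotype-mean %mC against biomass."""
    rows = []
    for condition, group in per_cell.groupby("condition", sort=True):
        merged = group.merge(biomass[biomass["condition"] == condition],
                             on=["genotype", "condition"])
        res = correlate(merged["mean_pct"], merged["biomass"])
        rows.append({"condition": condition, "n": res.n,
                     "pearson_r": res.pearson_r, "pearson_p": res.pearson_p,
                     "spearman_rho": res.spearman_rho, "spearman_p": res.spearman_p,
                     "shapiro_p_mC": res.shapiro_p_x, "shapiro_p_biomass": res.shapiro_p_y,
                     "pearson_valid": res.pearson_valid})
    return pd.DataFrame(rows)
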