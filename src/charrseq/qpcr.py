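"""Relative qPCR quantification by the 2^-ddCt method.

Target Ct values are normalized against the arithmetic mean of the
reference-gene Cts (algebraically identical to geometric-mean normalization
of the 2^-Ct quantities under the perfect-doubling model), referenced to a
calibrator group, and reported as fold changes with SE-propagated bounds
2^-(ddCt +/- SE). Group comparisons use a fixed-effects two-way ANOVA with
interaction on the dCt values and Tukey's HSD post hoc test.

The exponential model assumes efficiency 2 per cycle; measured efficiencies
are carried as metadata and a warning is emitted below 1.9, where fold
estimates become unreliable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

EFFICIENCY_WARN = 1.9


@dataclass(frozen=True)
class QpcrRecord:
    gene: str
    morph: str
    timepoint: float
    replicate: str
    ct: float
    is_reference: bool = False
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        if self.ct <= 0:
            raise ValueError(f"{self.gene}: Ct must be positive")
        if not 1 < self.efficiency <= 2:
            raise ValueError(f"{self.gene}: efficiency must be in (1, 2]")


@dataclass(frozen=True)
class RelativeExpression:
    gene: str
    morph: str
    timepoint: float
    delta_ct: float
    ddct: float
    rq: float
    rq_min: float
    rq_max: float
    se: float


def records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    return pd.DataFrame([vars(r) for r in records])


def normalize_delta_ct(records, reference_genes: list[str]) -> pd.DataFrame:
    """dCt = Ct_target - mean(reference Cts) per (gene, morph, time, replicate).

    Technical duplicates (repeated Cts within a cell) are averaged first.
    Every reference gene must be measured in every (morph, time, replicate)
    cell that carries a target measurement.
    """
    df = records_frame(records)
    low = df.loc[df["efficiency"] < EFFICIENCY_WARN, "gene"].unique()
    if len(low):
        warnings.warn(
            f"amplification efficiency below {EFFICIENCY_WARN} for {sorted(low)}; "
            "fold estimates for these genes may be weak",
            stacklevel=2,
        )
    cell = ["morph", "timepoint", "replicate"]
    mean_ct = df.groupby(["gene"] + cell, as_index=False)["ct"].mean()
    refs = mean_ct[mean_ct["gene"].isin(reference_genes)]
    targets = mean_ct[~mean_ct["gene"].isin(reference_genes)]
    ref_means = refs.groupby(cell)["ct"].agg(["mean", "count"])
    rows = []
    for row in targets.itertuples():
        key = (row.morph, row.timepoint, row.replicate)
        if key not in ref_means.index or ref_means.loc[key, "count"] < len(reference_genes):
            raise ValueError(
                f"missing reference measurement in cell morph={row.morph}, "
                f"timepoint={row.timepoint}, replicate={row.replicate}"
            )
        rows.append(
            {
                "gene": row.gene,
                "morph": row.morph,
                "timepoint": row.timepoint,
                "replicate": row.replicate,
                "delta_ct": row.ct - ref_means.loc[key, "mean"],
            }
        )
    return pd.DataFrame(rows)


def relative_expression(
    delta_cts: pd.DataFrame, calibrator: tuple[str, float]
) -> list[RelativeExpression]:
    """Fold change per (gene, morph, timepoint) group relative to the
    calibrator group, with 2^-(ddCt +/- SE) bounds.

    SE is the standard error of the dCt replicates within the group; the
    calibrator group has rq = 1 exactly by construction.
    """
    cal_morph, cal_time = calibrator
    out: list[RelativeExpression] = []
    for gene, sub in delta_cts.groupby("gene"):
        cal = sub[(sub["morph"] == cal_morph) & (sub["timepoint"] == cal_time)]
        if cal.empty:
            raise ValueError(f"calibrator group {calibrator} absent for gene {gene}")
        cal_mean = cal["delta_ct"].mean()
        for (morph, time), grp in sub.groupby(["morph", "timepoint"]):
            d = grp["delta_ct"]
            ddct = d.mean() - cal_mean
            n = len(d)
            se = float(d.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            out.append(
                RelativeExpression(
                    gene=gene,
                    morph=morph,
                    timepoint=time,
                    delta_ct=float(d.mean()),
                    ddct=float(ddct),
                    rq=float(2.0 ** -ddct),
                    rq_min=float(2.0 ** -(ddct + se)),
                    rq_max=float(2.0 ** -(ddct - se)),
                    se=se,
                )
            )
    return out


def anova_delta_ct(delta_cts: pd.DataFrame) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA, dCt ~ morph + time + morph:time,
    sequential (type I) sums of squares.

    Cells without replication make the interaction inestimable; it is then
    dropped with a warning. An all-constant response returns the F = 0,
    p = 1 convention.
    """
    df = delta_cts.copy()
    if df["delta_ct"].nunique() <= 1:
        terms = ["C(morph)", "C(time_f)", "C(morph):C(time_f)", "Residual"]
        return pd.DataFrame(
            {"sum_sq": 0.0, "df": np.nan, "F": 0.0, "PR(>F)": 1.0}, index=terms
        )
    df["time_f"] = df["timepoint"].astype(str)
    cell_sizes = df.groupby(["morph", "time_f"]).size()
    formula = "delta_ct ~ C(morph) + C(time_f) + C(morph):C(time_f)"
    if (cell_sizes < 2).any():
        warnings.warn("cells without replication; interaction term dropped", stacklevel=2)
        formula = "delta_ct ~ C(morph) + C(time_f)"
    fit = smf.ols(formula, data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = anova_lm(fit, typ=1)
    # descriptive residual-normality check (not a gatekeeper)
    resid = fit.resid
    if len(resid) >= 3 and resid.std() > 0:
        from scipy.stats import shapiro

        table.attrs["shapiro_p"] = float(shapiro(resid.values).pvalue)
    return table


def tukey_hsd(delta_cts: pd.DataFrame, factor: str = "morph") -> pd.DataFrame:
    """Tukey HSD adjusted p-values for all pairs of ``factor`` levels.

    Pairs involving a single-observation group are flagged NA (the
    within-group variance contribution is undefined for them).
    """
    df = delta_cts.copy()
    groups = df.groupby(factor)["delta_ct"]
    sizes = groups.size()
    if len(sizes) < 2:
        raise ValueError("need at least two groups")
    singletons = set(sizes.index[sizes < 2])
    ok = df[~df[factor].isin(singletons)]
    res = None
    if ok[factor].nunique() >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = pairwise_tukeyhsd(ok["delta_ct"].values, ok[factor].values)
    pvals: dict[frozenset, float] = {}
    if res is not None:
        uniq = list(res.groupsunique)
        k = 0
        for i in range(len(uniq)):
            for j in range(i + 1, len(uniq)):
                pvals[frozenset((uniq[i], uniq[j]))] = float(res.pvalues[k])
                k += 1
    rows = []
    levels = sorted(sizes.index)
    for i, g1 in enumerate(levels):
        for g2 in levels[i + 1 :]:
            p = (
                np.nan
                if g1 in singletons or g2 in singletons
                else pvals[frozenset((g1, g2))]
            )
            rows.append({"group1": g1, "group2": g2, "p_adj": p})
    return pd.DataFrame(rows)
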