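"""Paralog-group expression analysis.

Salmonids carry an extra whole-genome duplication, so many genes exist as
ohnolog pairs assembled into separate reference contigs. Contigs sharing an
annotation are pooled into paralog groups before testing, trading
paralog-specific resolution for statistical power. Differential expression
between morphs across developmental time is assessed with a negative
binomial GLM, counts ~ morph + time (log link, additive model; with one
pooled library per morph x time cell the interaction is not estimable), and
likelihood-ratio tests of each factor against the model without it.

Dispersion is a single common estimate shared across groups, obtained by
calibrating the Pearson chi-square statistic of the full-model fits to its
residual degrees of freedom (a method-of-moments / pseudo-likelihood
estimate); a per-group moment estimate is available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.cluster import hierarchy
from scipy.optimize import brentq
from statsmodels.stats.multitest import multipletests

from .data_io import CountMatrix, SampleMeta

LOG_CPM_PRIOR = 0.25  # added before log2 to keep zero counts finite


@dataclass
class ParalogGroup:
    label: str
    contig_ids: list[str]
    counts: pd.Series  # per-sample pooled integer counts

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def pool_paralog_groups(matrix: CountMatrix) -> list[ParalogGroup]:
    """Sum counts of contigs sharing an annotation; per-sample totals are
    conserved exactly."""
    pooled = matrix.counts.groupby(matrix.annotation).sum()
    members = {
        label: list(idx)
        for label, idx in matrix.counts.groupby(matrix.annotation).groups.items()
    }
    return [
        ParalogGroup(label=str(label), contig_ids=members[label], counts=row)
        for label, row in pooled.iterrows()
    ]


def groups_frame(groups: Sequence[ParalogGroup]) -> pd.DataFrame:
    return pd.DataFrame({g.label: g.counts for g in groups}).T


def filter_min_total(
    groups: Sequence[ParalogGroup], min_total: int = 800
) -> list[ParalogGroup]:
    """Drop groups with fewer than ``min_total`` reads over the whole dataset."""
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    return [g for g in groups if g.total >= min_total]


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million within each sample (column)."""
    libsize = counts.sum(axis=0)
    if (libsize <= 0).any():
        bad = list(libsize.index[libsize <= 0])
        raise ValueError(f"zero library size for samples {bad}")
    return counts / libsize * 1e6


def log_cpm(counts: pd.DataFrame, prior: float = LOG_CPM_PRIOR) -> pd.DataFrame:
    return np.log2(cpm(counts) + prior)


def bh_fdr(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values; NaN inputs stay NaN."""
    p = np.asarray(list(pvalues), dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# NB-GLM differential expression


def _design(samples: Sequence[SampleMeta]) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list[str], str]:
    """Full (morph + time), time-only and morph-only design matrices.

    Baselines are the lexicographically/numerically smallest levels; the
    morph contrast is (second morph) - (baseline morph) on the log scale.
    """
    morphs = sorted({s.morph for s in samples})
    times = sorted({s.timepoint for s in samples})
    if len(morphs) < 2 or len(times) < 2:
        raise ValueError("need >=2 morphs and >=2 timepoints")
    idx = [s.sample_id for s in samples]
    X = pd.DataFrame({"Intercept": 1.0}, index=idx)
    morph_cols = []
    for m in morphs[1:]:
        col = f"morph[{m}]"
        X[col] = [1.0 if s.morph == m else 0.0 for s in samples]
        morph_cols.append(col)
    time_cols = []
    for t in times[1:]:
        col = f"time[{t:g}]"
        X[col] = [1.0 if s.timepoint == t else 0.0 for s in samples]
        time_cols.append(col)
    full = X
    time_only = X[["Intercept"] + time_cols]
    morph_only = X[["Intercept"] + morph_cols]
    if np.linalg.matrix_rank(full.values) < full.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return full, time_only, morph_only, time_cols, morph_cols[0]


def _nb_family(alpha: float):
    if alpha <= 1e-8:
        return sm.families.Poisson()
    return sm.families.NegativeBinomial(alpha=alpha)


def estimate_common_dispersion(
    counts: pd.DataFrame, samples: Sequence[SampleMeta]
) -> float:
    """Common NB dispersion alpha with Var(Y) = mu + alpha * mu^2.

    Fits each group with a Poisson GLM under the full design, then solves
    for the alpha that makes the pooled Pearson chi-square equal its pooled
    residual degrees of freedom.
    """
    full, _, _, _, _ = _design(samples)
    X = full.values
    resid_df = X.shape[0] - X.shape[1]
    if resid_df <= 0:
        raise ValueError("no residual degrees of freedom in the design")
    mus, ys = [], []
    for _, y in counts.iterrows():
        y = y.values.astype(float)
        if y.sum() == 0:
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mu = sm.GLM(y, X, family=sm.families.Poisson()).fit().mu
        except Exception:
            continue
        mus.append(mu)
        ys.append(y)
    if not mus:
        return 0.0
    mu = np.concatenate(mus)
    y = np.concatenate(ys)
    target = len(ys) * resid_df

    def pearson(alpha: float) -> float:
        return float(np.sum((y - mu) ** 2 / (mu + alpha * mu**2)) - target)

    if pearson(0.0) <= 0:  # under-dispersed relative to Poisson
        return 0.0
    hi = 1.0
    while pearson(hi) > 0 and hi < 1e4:
        hi *= 10
    return float(brentq(pearson, 0.0, hi, xtol=1e-8))


def fit_de(
    groups: Sequence[ParalogGroup] | pd.DataFrame,
    samples: Sequence[SampleMeta],
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Per-group NB-GLM fits with likelihood-ratio tests.

    The morph effect is tested against the time-only model (1 df) and the
    time effect against the morph-only model. Fold changes are reported in
    base 2. Returns one row per group; groups whose fits fail to converge
    get NA statistics.
    """
    counts = groups if isinstance(groups, pd.DataFrame) else groups_frame(groups)
    counts = counts[[s.sample_id for s in samples]]
    full, time_only, morph_only, time_cols, morph_col = _design(samples)
    if dispersion is None:
        dispersion = estimate_common_dispersion(counts, samples)
    family = _nb_family(dispersion)
    n_contigs = (
        {g.label: len(g.contig_ids) for g in groups}
        if not isinstance(groups, pd.DataFrame)
        else {}
    )
    lib = counts.sum(axis=0)
    log_cpm_mean = np.log2(
        (counts / lib * 1e6).mean(axis=1) + LOG_CPM_PRIOR
    )

    rows = []
    for label, y in counts.iterrows():
        row: dict = {
            "label": label,
            "n_contigs": n_contigs.get(label, np.nan),
            "logCPM": float(log_cpm_mean.loc[label]),
            "logFC_morph": np.nan,
            "p_morph": np.nan,
            "p_time": np.nan,
        }
        for col in time_cols:
            row[f"logFC_T{col[5:-1]}"] = np.nan
        yv = y.values.astype(float)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit_full = sm.GLM(yv, full.values, family=family).fit()
                fit_time = sm.GLM(yv, time_only.values, family=family).fit()
                fit_morph = sm.GLM(yv, morph_only.values, family=family).fit()
            params = dict(zip(full.columns, fit_full.params))
            row["logFC_morph"] = params[morph_col] / np.log(2)
            for col in time_cols:
                row[f"logFC_T{col[5:-1]}"] = params[col] / np.log(2)
            lr_morph = max(0.0, 2 * (fit_full.llf - fit_time.llf))
            lr_time = max(0.0, 2 * (fit_full.llf - fit_morph.llf))
            row["p_morph"] = float(stats.chi2.sf(lr_morph, df=1))
            row["p_time"] = float(stats.chi2.sf(lr_time, df=len(time_cols)))
        except Exception:
            pass  # leave NA statistics for non-convergent groups
        rows.append(row)
    out = pd.DataFrame(rows).set_index("label", drop=False)
    out["FDR_morph"] = bh_fdr(out["p_morph"])
    out["FDR_time"] = bh_fdr(out["p_time"])
    out.attrs["dispersion"] = dispersion
    return out


# ---------------------------------------------------------------------------
# clustering and enrichment


def cluster_profiles(log_cpm_rows: pd.DataFrame, k: int = 4) -> pd.Series:
    """Cut a complete-linkage euclidean tree of z-scored profiles into k groups.

    Rows with zero standard deviation carry no profile shape and are
    excluded with a warning (their label is NA in the result).
    """
    sd = log_cpm_rows.std(axis=1, ddof=1)
    usable = log_cpm_rows.loc[sd > 0]
    if len(usable) < len(log_cpm_rows):
        warnings.warn(
            f"excluded {len(log_cpm_rows) - len(usable)} zero-variance profiles",
            stacklevel=2,
        )
    if len(usable) < k:
        raise ValueError(f"need at least k={k} usable rows, got {len(usable)}")
    z = usable.sub(usable.mean(axis=1), axis=0).div(sd.loc[usable.index], axis=0)
    link = hierarchy.linkage(z.values, method="complete", metric="euclidean")
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    out = pd.Series(np.nan, index=log_cpm_rows.index, dtype="Int64", name="cluster")
    out.loc[usable.index] = labels
    return out


def hypergeom_enrich(
    hits: set[str], universe: set[str], categories: Mapping[str, str]
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each category among the hits.

    p = P(X >= k) with X ~ Hypergeom(M=|universe|, K=category size,
    n=|hits|); BH adjustment across categories.
    """
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    M, n = len(universe), len(hits)
    by_cat: dict[str, set[str]] = {}
    for label, cat in categories.items():
        by_cat.setdefault(cat, set()).add(label)
    rows = []
    for cat, members in sorted(by_cat.items()):
        in_universe = members & universe
        if not in_universe:
            warnings.warn(f"category {cat!r} absent from universe; skipped", stacklevel=2)
            continue
        K = len(in_universe)
        k = len(in_universe & hits)
        p = float(stats.hypergeom.sf(k - 1, M, K, n))
        rows.append({"category": cat, "K": K, "k": k, "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["FDR"] = bh_fdr(df["p"])
    return df
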