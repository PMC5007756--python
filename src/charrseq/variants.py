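"""SNP-candidate filtering cascade for pooled transcriptome data.

In a genome-duplicated salmonid, reads from diverged paralogs co-mapping to
one reference contig produce apparent SNPs. Because each sequenced sample is
a pool of only a few individuals, genuine segregating SNPs are unlikely to
sit at the same allele frequency in every pool, whereas a fixed difference
between co-expressed paralogs yields a near-constant alt frequency across
samples (proportional to the paralogs' expression ratio). The cascade
exploits that signature:

1. interspecific: alt frequency >= 0.90 in *every* covered sample means the
   study species simply differs from the cross-species reference contig;
   the site is not a within-species polymorphism.
2. coverage: sites with <= 5 reads in at least 3 of a morph's 4 samples
   carry too little information and are dropped.
3. homogeneity: between-sample Fisher exact tests; sites whose samples do
   NOT differ significantly (minimum pairwise p >= alpha, no multiple
   testing correction) are flagged as paralog artifacts and removed.
4. morph comparison: reads summed over each morph's samples; a 2x2 Fisher
   test between the pooled morph counts must reach p < alpha, and the
   surviving sites are binned by delta (absolute pooled alt-frequency
   difference) tiers 0.5 / 0.75 / 0.95.

Derived-allele polarity is assigned against an outgroup base (the allele
differing from the outgroup is derived); the funnel report stratifies tier
counts by the morph carrying the higher derived-allele frequency, and by
UNI/REP mapping stratum throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import SampleMeta, SiteCounts, validate_samples


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the cascade; defaults reproduce the published rules."""

    interspecific_min_freq: float = 0.90
    low_cov_reads: int = 5
    low_cov_min_samples_per_morph: int = 3
    homogeneity_alpha: float = 0.05
    morph_alpha: float = 0.05
    delta_tiers: tuple[float, ...] = (0.5, 0.75, 0.95)
    homogeneity_mode: str = "pairwise"  # or "chisq" (2 x k contingency)
    low_cov_morph_rule: str = "either"  # or "both"

    def __post_init__(self) -> None:
        for v in (self.interspecific_min_freq, self.homogeneity_alpha, self.morph_alpha):
            if not 0 < v <= 1:
                raise ValueError("frequencies and alphas must be in (0, 1]")
        if tuple(sorted(self.delta_tiers)) != tuple(self.delta_tiers):
            raise ValueError("delta_tiers must be sorted ascending")
        if self.homogeneity_mode not in ("pairwise", "chisq"):
            raise ValueError("homogeneity_mode must be 'pairwise' or 'chisq'")
        if self.low_cov_morph_rule not in ("either", "both"):
            raise ValueError("low_cov_morph_rule must be 'either' or 'both'")


@dataclass
class MorphAlleleSummary:
    """Pooled per-morph allele counts and the derived comparison statistics."""

    pooled: dict[str, tuple[int, int]]  # morph -> (ref, alt)
    freq: dict[str, float]  # morph -> alt frequency
    delta: float
    morph_p: float
    derived_allele: str | None  # "ref" | "alt" | None (unpolarized)
    derived_high_morph: str | None

    def derived_freq(self, morph: str) -> float | None:
        if self.derived_allele == "alt":
            return self.freq[morph]
        if self.derived_allele == "ref":
            return 1.0 - self.freq[morph]
        return None


@dataclass
class FilterTrace:
    """Per-site record of the cascade outcome.

    Exactly the first failing filter (in cascade order) is flagged;
    ``retained`` is true iff no flag is set.
    """

    site: SiteCounts
    removed_interspecific: bool = False
    removed_low_coverage: bool = False
    removed_homogeneous: bool = False
    removed_morph_test: bool = False
    homogeneity_p: float | None = None
    summary: MorphAlleleSummary | None = None
    retained: bool = False
    tier: float | None = None

    @property
    def removal_flags(self) -> tuple[bool, bool, bool, bool]:
        return (
            self.removed_interspecific,
            self.removed_low_coverage,
            self.removed_homogeneous,
            self.removed_morph_test,
        )


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table of non-negative counts.

    With the margins fixed, the first cell follows a hypergeometric
    distribution; the p-value sums the probabilities of all tables at most
    as probable as the observed one. Probabilities are compared as exact
    integer weights C(r1, x) * C(r2, c1 - x), so ties at the observed
    probability are handled without floating-point tolerance. An all-zero
    table has no information; p = 1 is returned with a warning.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be non-negative")
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        warnings.warn("all-zero 2x2 table; returning p = 1", stacklevel=2)
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    w_obs = comb(r1, a) * comb(r2, c)
    num = 0
    for x in range(lo, hi + 1):
        w = comb(r1, x) * comb(r2, c1 - x)
        if w <= w_obs:
            num += w
    return num / comb(n, c1)  # exact big-int division, correctly rounded


def filter_interspecific(site: SiteCounts, cfg: FilterConfig = FilterConfig()) -> bool:
    """Remove iff alt frequency >= threshold in every covered sample.

    Samples with zero coverage at the site are skipped for this rule.
    """
    freqs = [f for sid in site.counts if (f := site.alt_frequency(sid)) is not None]
    if not freqs:
        return False
    return all(f >= cfg.interspecific_min_freq for f in freqs)


def _morph_groups(samples: Sequence[SampleMeta]) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    for s in samples:
        groups.setdefault(s.morph, []).append(s.sample_id)
    if any(len(v) < 1 for v in groups.values()) or len(groups) < 2:
        raise ValueError("need >=2 morphs with >=1 sample each")
    return groups


def filter_low_coverage(
    site: SiteCounts, samples: Sequence[SampleMeta], cfg: FilterConfig = FilterConfig()
) -> bool:
    """Remove iff, within either morph (configurable to both), at least
    ``low_cov_min_samples_per_morph`` samples have total reads <= ``low_cov_reads``."""
    groups = _morph_groups(samples)
    hits = []
    for sids in groups.values():
        n_low = sum(site.coverage(sid) <= cfg.low_cov_reads for sid in sids)
        hits.append(n_low >= cfg.low_cov_min_samples_per_morph)
    return any(hits) if cfg.low_cov_morph_rule == "either" else all(hits)


def homogeneity_test(
    site: SiteCounts, samples: Sequence[SampleMeta], cfg: FilterConfig = FilterConfig()
) -> tuple[float, bool]:
    """Between-sample heterogeneity screen for paralog artifacts.

    Returns ``(p, remove)``. In the default pairwise mode p is the minimum
    two-sided Fisher exact p over all covered sample pairs' (ref, alt)
    tables, compared to alpha without multiple-testing correction; sites
    *not* significantly heterogeneous are removed as paralog artifacts.
    Mode "chisq" instead uses a single 2 x k chi-square over covered samples.
    """
    covered = [s.sample_id for s in samples if site.coverage(s.sample_id) > 0]
    if len(covered) < 2:
        return 1.0, True
    if cfg.homogeneity_mode == "chisq":
        tab = np.array([site.counts[sid] for sid in covered]).T
        # drop an all-zero allele row (monomorphic across samples): no heterogeneity
        tab = tab[tab.sum(axis=1) > 0]
        if tab.shape[0] < 2:
            return 1.0, True
        p = float(stats.chi2_contingency(tab, correction=False)[1])
    else:
        p = 1.0
        for s1, s2 in combinations(covered, 2):
            p = min(p, fisher_exact_2x2([site.counts[s1], site.counts[s2]]))
    return p, p >= cfg.homogeneity_alpha


def summarize_morphs(
    site: SiteCounts,
    samples: Sequence[SampleMeta],
    outgroup_base: str | None = None,
    cfg: FilterConfig = FilterConfig(),
) -> MorphAlleleSummary:
    """Pool read counts over each morph's samples and compare the two pools.

    delta is the absolute difference in pooled alt frequency; morph_p the
    two-sided Fisher exact p of the pooled 2x2 table. The derived allele is
    the one differing from the outgroup base; if the outgroup base is
    unknown or matches neither allele (tri-allelic across species) the site
    is left unpolarized.
    """
    groups = _morph_groups(samples)
    pooled: dict[str, tuple[int, int]] = {}
    freq: dict[str, float] = {}
    for morph, sids in groups.items():
        r = sum(site.counts[sid][0] for sid in sids)
        a = sum(site.counts[sid][1] for sid in sids)
        pooled[morph] = (r, a)
        freq[morph] = a / (r + a) if r + a else float("nan")
    morphs = list(groups)
    if len(morphs) != 2:
        raise ValueError("morph summary is defined for exactly two morphs")
    m1, m2 = morphs
    delta = abs(freq[m1] - freq[m2])
    morph_p = fisher_exact_2x2([pooled[m1], pooled[m2]])

    derived_allele: str | None = None
    if outgroup_base == site.ref_base:
        derived_allele = "alt"
    elif outgroup_base == site.alt_base:
        derived_allele = "ref"
    summary = MorphAlleleSummary(
        pooled=pooled, freq=freq, delta=delta, morph_p=morph_p,
        derived_allele=derived_allele, derived_high_morph=None,
    )
    if derived_allele is not None:
        d1, d2 = summary.derived_freq(m1), summary.derived_freq(m2)
        if d1 != d2:
            summary.derived_high_morph = m1 if d1 > d2 else m2
    return summary


def assign_tier(delta: float, tiers: Sequence[float]) -> float | None:
    """Highest tier with delta strictly above it, or None."""
    passed = [t for t in tiers if delta > t]
    return max(passed) if passed else None


def apply_cascade_site(
    site: SiteCounts,
    samples: Sequence[SampleMeta],
    outgroup_base: str | None,
    cfg: FilterConfig,
) -> FilterTrace:
    """Run the ordered cascade on one site; only the first failing stage flags."""
    trace = FilterTrace(site=site)
    if filter_interspecific(site, cfg):
        trace.removed_interspecific = True
        return trace
    if filter_low_coverage(site, samples, cfg):
        trace.removed_low_coverage = True
        return trace
    p, remove = homogeneity_test(site, samples, cfg)
    trace.homogeneity_p = p
    if remove:
        trace.removed_homogeneous = True
        return trace
    trace.summary = summarize_morphs(site, samples, outgroup_base, cfg)
    if not trace.summary.morph_p < cfg.morph_alpha:
        trace.removed_morph_test = True
        return trace
    trace.retained = True
    trace.tier = assign_tier(trace.summary.delta, cfg.delta_tiers)
    return trace


def run_cascade(
    sites: Sequence[SiteCounts],
    samples: Sequence[SampleMeta],
    outgroups: Mapping[tuple[str, int], str] | None = None,
    cfg: FilterConfig = FilterConfig(),
) -> tuple[list[FilterTrace], pd.DataFrame]:
    """Apply the cascade to every site and build the funnel report.

    ``outgroups`` maps (contig_id, position) to the outgroup base used for
    polarization; sites absent from the map stay unpolarized.

    The funnel counts, per UNI/REP stratum and in total, the sites
    surviving each stage, then the retained sites per delta tier split by
    the morph carrying the higher derived-allele frequency (rows
    ``delta>0.5/<morph>`` etc.; unpolarized or tier-less sites appear only
    in the stage rows).
    """
    validate_samples(samples)
    outgroups = outgroups or {}
    traces = [
        apply_cascade_site(s, samples, outgroups.get((s.contig_id, s.position)), cfg)
        for s in sites
    ]
    return traces, funnel_report(traces, samples, cfg)


def frequency_table_recount(
    table: pd.DataFrame, tier: float = 0.95
) -> dict[str, int]:
    """Re-apply the delta tier rule to a table of per-morph derived-allele
    frequencies (columns freq_ac, freq_sb, stratum).

    Returns counts of sites with delta strictly above ``tier``, overall and
    stratified by UNI/REP and by the morph with the higher derived
    frequency within the UNI stratum.
    """
    delta = (table["freq_ac"] - table["freq_sb"]).abs()
    kept = table[delta > tier]
    uni = kept[kept["stratum"] == "UNI"]
    return {
        "total": int(len(kept)),
        "uni": int((kept["stratum"] == "UNI").sum()),
        "rep": int((kept["stratum"] == "REP").sum()),
        "uni_high_ac": int((uni["freq_ac"] > uni["freq_sb"]).sum()),
        "uni_high_sb": int((uni["freq_sb"] > uni["freq_ac"]).sum()),
    }


def funnel_report(
    traces: Sequence[FilterTrace],
    samples: Sequence[SampleMeta],
    cfg: FilterConfig = FilterConfig(),
) -> pd.DataFrame:
    morphs = list(_morph_groups(samples)) if traces or samples else []
    strata = ["UNI", "REP"]

    def count(pred) -> dict[str, int]:
        row = {st: sum(pred(t) and t.site.stratum == st for t in traces) for st in strata}
        row["Total"] = sum(row.values())
        return row

    rows: dict[str, dict[str, int]] = {}
    rows["total"] = count(lambda t: True)
    rows["pass_interspecific"] = count(lambda t: not t.removed_interspecific)
    rows["pass_coverage"] = count(
        lambda t: not (t.removed_interspecific or t.removed_low_coverage)
    )
    rows["diff_between_samples"] = count(
        lambda t: not any(t.removal_flags[:3])
    )
    rows["diff_between_morphs"] = count(lambda t: t.retained)
    for tier in cfg.delta_tiers:
        for morph in morphs:
            rows[f"delta>{tier:g}/{morph}"] = count(
                lambda t, tier=tier, morph=morph: t.retained
                and t.tier is not None
                and t.summary is not None
                and t.summary.delta > tier
                and t.summary.derived_high_morph == morph
            )
    return pd.DataFrame(rows).T[strata + ["Total"]]
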