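"""Synthetic data generation for every pipeline input.

The generators emulate the study design: two morphs x four developmental
timepoints, one pooled library per cell, each pool holding ~6 diploid
individuals. Site classes follow the generative models the filter cascade
is built to separate:

* true_snp — each sample's pool allele count is Binomial(ploidy x pool_size,
  q_morph), so sampling few individuals makes the realized frequency vary
  between pools; reads are then Binomial(coverage, pool_freq) with a small
  symmetric sequencing-error flip.
* paralog_artifact — a fixed difference between co-mapping paralogs whose
  apparent alt frequency equals the paralogs' (steady) expression share r
  in every sample: reads are Binomial(coverage, r) with no pool sampling.
* interspecific — the study species is fixed for the non-reference base;
  reads are Binomial(coverage, 1 - e).

Coverage is negative binomial per sample. Expression counts are NB with
log-linear morph/time effects; qPCR Cts follow the perfect-doubling model
with Gaussian replicate noise; genotype tables are binomial draws from
stated population frequencies (with a deterministic rounding mode so that
small worked examples come out exactly).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_io import SampleMeta, SiteCounts
from .qpcr import QpcrRecord
from .verification import AlignmentColumnProfile, GenotypeTable

SITE_CLASSES = ("true_snp", "paralog_artifact", "interspecific")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for all generators; defaults match the design they
    emulate (8 pools of ~6 diploid individuals, NB coverage around 100x)."""

    seed: int = 0
    # site simulation
    n_sites: int = 1000
    class_mix: tuple[float, float, float] = (0.4, 0.4, 0.2)  # true/artifact/interspecific
    pool_size: int = 6
    ploidy: int = 2
    coverage_mean: float = 100.0
    coverage_size: float = 5.0
    seq_error: float = 0.005
    rep_fraction: float = 0.4  # share of candidates from multiply mapped reads
    planted_deltas: tuple[float, ...] = (0.0, 0.5, 0.75, 0.95)
    planted_delta_weights: tuple[float, ...] = (0.4, 0.2, 0.2, 0.2)
    artifact_share_range: tuple[float, float] = (0.15, 0.85)
    family_mode: bool = False
    # expression simulation
    n_genes: int = 2000
    expr_mean: float = 500.0
    expr_dispersion: float = 0.1
    expr_n_de: int = 0
    expr_logfc: float = 2.0  # planted morph effect, base 2
    expr_time_logfc_sd: float = 0.0
    # qPCR simulation
    qpcr_baseline_ct: float = 24.0
    qpcr_ref_cts: tuple[float, ...] = (20.0, 22.0, 24.0)
    qpcr_morph_log2fc: float = 1.0
    qpcr_time_log2fc: float = 0.0
    qpcr_sigma: float = 0.1
    qpcr_replicates: int = 2
    # genotype / alignment simulation
    geno_freqs: dict = field(
        default_factory=lambda: {"PL": 0.0, "LB": 0.125, "SB": 0.625}
    )
    geno_n: int = 8
    geno_deterministic: bool = False
    align_n_species: int = 100
    align_ref_base: str = "C"
    align_var_base: str = "T"
    align_n_mismatch: int = 1

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix proportions must sum to 1")
        if abs(sum(self.planted_delta_weights) - 1.0) > 1e-9:
            raise ValueError("planted_delta_weights must sum to 1")
        for v in (self.seq_error, self.rep_fraction):
            if not 0 <= v <= 1:
                raise ValueError("rates must be in [0, 1]")


MORPHS = ("AC", "SB")
TIMEPOINTS = (141.0, 163.0, 200.0, 433.0)


def make_default_samples(cfg: SimConfig = SimConfig()) -> list[SampleMeta]:
    """The 2 morphs x 4 timepoints pooled-library layout."""
    return [
        SampleMeta(
            sample_id=f"{m}_{t:g}", morph=m, timepoint=t,
            pool_size=cfg.pool_size, ploidy=cfg.ploidy,
        )
        for m in MORPHS
        for t in TIMEPOINTS
    ]


_BASES = np.array(list("ACGT"))


def _read_alt_count(rng, coverage: int, freq: float, e: float) -> int:
    p = freq * (1 - e) + (1 - freq) * e
    return int(rng.binomial(coverage, p)) if coverage > 0 else 0


def simulate_site_counts(
    cfg: SimConfig = SimConfig(),
) -> tuple[list[SiteCounts], pd.DataFrame, dict[tuple[str, int], str]]:
    """Generate labeled candidate sites.

    Returns (sites, truth, outgroups): truth holds one row per site with
    its class, per-morph true frequencies, planted delta and per-sample
    realized pool frequencies; outgroups maps (contig, pos) to the
    cross-species reference base (always the ref allele here, so the alt
    allele is derived).
    """
    rng = np.random.default_rng(cfg.seed)
    samples = make_default_samples(cfg)
    chrom = cfg.ploidy * cfg.pool_size
    sites: list[SiteCounts] = []
    truth_rows = []
    outgroups: dict[tuple[str, int], str] = {}
    classes = rng.choice(len(SITE_CLASSES), size=cfg.n_sites, p=list(cfg.class_mix))
    for i in range(cfg.n_sites):
        cls = SITE_CLASSES[classes[i]]
        contig = f"sim{i:06d}"
        pos = int(rng.integers(1, 1501))
        ref, alt = rng.choice(4, size=2, replace=False)
        ref_base, alt_base = str(_BASES[ref]), str(_BASES[alt])
        stratum = "REP" if rng.random() < cfg.rep_fraction else "UNI"
        coverage = rng.negative_binomial(
            cfg.coverage_size,
            cfg.coverage_size / (cfg.coverage_size + cfg.coverage_mean),
            size=len(samples),
        )

        q = {m: np.nan for m in MORPHS}
        planted_delta = np.nan
        pool_freqs = {}
        counts: dict[str, tuple[int, int]] = {}
        if cls == "true_snp":
            d_idx = rng.choice(len(cfg.planted_deltas), p=list(cfg.planted_delta_weights))
            planted_delta = cfg.planted_deltas[d_idx]
            if planted_delta == 0:
                q0 = rng.uniform(0.1, 0.9)
                q = {m: q0 for m in MORPHS}
            else:
                lo, hi = (1 - planted_delta) / 2, (1 + planted_delta) / 2
                high_morph = MORPHS[int(rng.integers(2))]
                q = {m: (hi if m == high_morph else lo) for m in MORPHS}
            for s, cov in zip(samples, coverage):
                qm = q[s.morph]
                if cfg.family_mode:
                    # draw the parents' allele pool first: few spawners per
                    # family inflate between-sample variance further
                    parent_freq = rng.binomial(2 * cfg.pool_size, qm) / (2 * cfg.pool_size)
                    pool_count = rng.binomial(chrom, parent_freq)
                else:
                    pool_count = rng.binomial(chrom, qm)
                pf = pool_count / chrom
                pool_freqs[s.sample_id] = pf
                a = _read_alt_count(rng, int(cov), pf, cfg.seq_error)
                counts[s.sample_id] = (int(cov) - a, a)
        elif cls == "paralog_artifact":
            r = rng.uniform(*cfg.artifact_share_range)
            q = {m: r for m in MORPHS}
            for s, cov in zip(samples, coverage):
                pool_freqs[s.sample_id] = r
                a = int(rng.binomial(int(cov), r)) if cov > 0 else 0
                counts[s.sample_id] = (int(cov) - a, a)
        else:  # interspecific
            q = {m: 1.0 for m in MORPHS}
            for s, cov in zip(samples, coverage):
                pool_freqs[s.sample_id] = 1.0
                a = _read_alt_count(rng, int(cov), 1.0, cfg.seq_error)
                counts[s.sample_id] = (int(cov) - a, a)

        sites.append(
            SiteCounts(
                contig_id=contig, position=pos, ref_base=ref_base,
                alt_base=alt_base, stratum=stratum, counts=counts,
            )
        )
        outgroups[(contig, pos)] = ref_base
        row = {
            "contig": contig, "pos": pos, "site_class": cls,
            "planted_delta": planted_delta,
            **{f"q_{m}": q[m] for m in MORPHS},
            **{f"pool_freq_{sid}": pool_freqs[sid] for sid in pool_freqs},
        }
        truth_rows.append(row)
    return sites, pd.DataFrame(truth_rows), outgroups


def simulate_expression(
    cfg: SimConfig = SimConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NB count matrix (genes x 8 samples) with optional planted effects.

    The first ``expr_n_de`` genes carry a morph effect of ``expr_logfc``
    (base 2, higher in the second morph); per-gene time effects are drawn
    Normal(0, expr_time_logfc_sd) per non-baseline timepoint.
    """
    rng = np.random.default_rng(cfg.seed)
    samples = make_default_samples(cfg)
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    logfc = np.zeros(cfg.n_genes)
    logfc[: cfg.expr_n_de] = cfg.expr_logfc
    time_fx = rng.normal(0.0, cfg.expr_time_logfc_sd, size=(cfg.n_genes, len(TIMEPOINTS)))
    time_fx[:, 0] = 0.0
    alpha = cfg.expr_dispersion
    data = np.zeros((cfg.n_genes, len(samples)), dtype=int)
    for j, s in enumerate(samples):
        t_idx = TIMEPOINTS.index(s.timepoint)
        mu = cfg.expr_mean * 2.0 ** (
            logfc * (s.morph == MORPHS[1]) + time_fx[:, t_idx]
        )
        if alpha > 0:
            n = 1.0 / alpha
            data[:, j] = rng.negative_binomial(n, n / (n + mu))
        else:
            data[:, j] = rng.poisson(mu)
    counts = pd.DataFrame(data, index=genes, columns=[s.sample_id for s in samples])
    truth = pd.DataFrame({"gene": genes, "true_logfc_morph": logfc}).set_index("gene")
    return counts, truth


def simulate_qpcr(
    cfg: SimConfig = SimConfig(),
) -> tuple[list[QpcrRecord], dict]:
    """Ct table for one target gene plus reference genes.

    Ct = baseline - log2(relative expression) + Normal(0, sigma); the
    planted relative expression doubles per unit of ``qpcr_morph_log2fc``
    in the second morph. Timepoints 161 and 200 with the configured number
    of biological replicates per cell.
    """
    rng = np.random.default_rng(cfg.seed)
    times = (161.0, 200.0)
    records: list[QpcrRecord] = []
    for m in MORPHS:
        for t in times:
            for rep in range(1, cfg.qpcr_replicates + 1):
                log2rel = cfg.qpcr_morph_log2fc * (m == MORPHS[1]) + (
                    cfg.qpcr_time_log2fc * (t == times[1])
                )
                for k, ref_ct in enumerate(cfg.qpcr_ref_cts):
                    records.append(
                        QpcrRecord(
                            gene=f"ref{k + 1}", morph=m, timepoint=t,
                            replicate=str(rep),
                            ct=float(ref_ct + rng.normal(0, cfg.qpcr_sigma)),
                            is_reference=True,
                        )
                    )
                records.append(
                    QpcrRecord(
                        gene="target", morph=m, timepoint=t, replicate=str(rep),
                        ct=float(
                            cfg.qpcr_baseline_ct - log2rel + rng.normal(0, cfg.qpcr_sigma)
                        ),
                    )
                )
    truth = {
        "morph_log2fc": cfg.qpcr_morph_log2fc,
        "time_log2fc": cfg.qpcr_time_log2fc,
        "reference_genes": [f"ref{k + 1}" for k in range(len(cfg.qpcr_ref_cts))],
        "calibrator": (MORPHS[0], times[0]),
    }
    return records, truth


def simulate_genotypes(cfg: SimConfig = SimConfig(), variant_id: str = "sim") -> GenotypeTable:
    """Genotype table from stated population frequencies.

    In deterministic-rounding mode the carrier counts are round(freq * n)
    exactly; otherwise they are Binomial(n, freq) draws.
    """
    rng = np.random.default_rng(cfg.seed)
    n_variant = {}
    for pop, f in cfg.geno_freqs.items():
        if cfg.geno_deterministic:
            n_variant[pop] = int(round(f * cfg.geno_n))
        else:
            n_variant[pop] = int(rng.binomial(cfg.geno_n, f))
    return GenotypeTable(
        variant_id=variant_id,
        n_variant=n_variant,
        n_total={pop: cfg.geno_n for pop in cfg.geno_freqs},
    )


def simulate_alignment_column(
    cfg: SimConfig = SimConfig(), variant_id: str = "sim"
) -> AlignmentColumnProfile:
    """A deeply conserved column with a stated number of mismatching species."""
    rng = np.random.default_rng(cfg.seed)
    species = [f"sp{i:03d}" for i in range(cfg.align_n_species)]
    mismatched = set(
        rng.choice(cfg.align_n_species, size=cfg.align_n_mismatch, replace=False)
    )
    bases = {
        sp: (cfg.align_var_base if i in mismatched else cfg.align_ref_base)
        for i, sp in enumerate(species)
    }
    return AlignmentColumnProfile(variant_id=variant_id, bases=bases)


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    return replace(cfg, seed=seed)
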