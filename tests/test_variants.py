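import numpy as np
import pytest
from scipy.stats import fisher_exact as scipy_fisher

import charrseq
from charrseq import variants
from charrseq.variants import (
    FilterConfig,
    assign_tier,
    fisher_exact_2x2,
    filter_interspecific,
    filter_low_coverage,
    frequency_table_recount,
    homogeneity_test,
    run_cascade,
    summarize_morphs,
)


class TestFisherExact:
    def test_perfect_separation_matches_enumeration(self):
        # 2 of the 11 tables with margins (10,10,10) are as extreme: p = 2/C(20,10)
        assert fisher_exact_2x2([[10, 0], [0, 10]]) == pytest.approx(2 / 184756)

    @pytest.mark.parametrize("table", [[[5, 5], [5, 5]], [[3, 7], [3, 7]]])
    def test_proportional_rows_give_p_one(self, table):
        assert fisher_exact_2x2(table) == 1.0

    def test_all_zero_table_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="all-zero"):
            assert fisher_exact_2x2([[0, 0], [0, 0]]) == 1.0

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [0, 2]])

    def test_agrees_with_scipy_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 120, size=4)
            if a + b + c + d == 0:
                continue
            assert fisher_exact_2x2([[a, b], [c, d]]) == pytest.approx(
                scipy_fisher([[a, b], [c, d]])[1], abs=1e-9
            )


class TestInterspecificFilter:
    def test_fixed_alt_in_all_samples_removed(self, make_site):
        assert filter_interspecific(make_site([(0, 50)] * 8))

    def test_one_intermediate_sample_rescues(self, make_site):
        pairs = [(5, 95)] * 7 + [(50, 50)]
        assert not filter_interspecific(make_site(pairs))

    def test_strict_boundary_at_090(self, make_site):
        assert not filter_interspecific(make_site([(11, 89)] * 8))
        assert filter_interspecific(make_site([(10, 90)] * 8))

    def test_zero_coverage_samples_skipped(self, make_site):
        pairs = [(0, 0)] * 4 + [(0, 50)] * 4
        assert filter_interspecific(make_site(pairs))


class TestLowCoverageFilter:
    def test_three_low_samples_in_one_morph_removed(self, make_site, samples8):
        pairs = [(1, 2), (2, 2), (3, 2), (50, 50)] + [(40, 10)] * 4
        assert filter_low_coverage(make_site(pairs), samples8)

    def test_uniform_good_coverage_kept(self, make_site, samples8):
        assert not filter_low_coverage(make_site([(25, 25)] * 8), samples8)

    def test_single_low_sample_kept(self, make_site, samples8):
        pairs = [(3, 2), (3, 3), (3, 3), (3, 3)] + [(40, 10)] * 4
        assert not filter_low_coverage(make_site(pairs), samples8)

    def test_both_mode_requires_both_morphs_low(self, make_site, samples8):
        cfg = FilterConfig(low_cov_morph_rule="both")
        pairs = [(1, 1)] * 4 + [(40, 10)] * 4
        assert not filter_low_coverage(make_site(pairs), samples8, cfg)
        assert filter_low_coverage(make_site([(1, 1)] * 8), samples8, cfg)


class TestHomogeneityTest:
    def test_constant_frequency_is_paralog_artifact(self, make_site, samples8):
        p, remove = homogeneity_test(make_site([(50, 50)] * 8), samples8)
        assert p == 1.0 and remove

    def test_fixed_difference_between_samples_retained(self, make_site, samples8):
        pairs = [(100, 0)] * 4 + [(0, 100)] * 4
        p, remove = homogeneity_test(make_site(pairs), samples8)
        assert p < 1e-10 and not remove

    def test_single_covered_sample_removed(self, make_site, samples8):
        pairs = [(50, 50)] + [(0, 0)] * 7
        _, remove = homogeneity_test(make_site(pairs), samples8)
        assert remove

    def test_null_retention_rate_bounded(self, make_site, samples8):
        # constant-p binomial read noise only: the min-pairwise-p screen is
        # anti-conservative but must still drop most artifact-like sites
        rng = np.random.default_rng(1)
        retained = 0
        n_sites = 1000
        for _ in range(n_sites):
            pairs = [(100 - a, a) for a in rng.binomial(100, 0.5, size=8)]
            _, remove = homogeneity_test(make_site(pairs), samples8)
            retained += not remove
        # measured null level of the min-pairwise-p screen is ~0.43 here:
        # inflated well above a single test's alpha, but far below the
        # retention of genuinely heterogeneous pooled SNPs (~1.0)
        assert 0 < retained / n_sites <= 0.50

    def test_chisq_mode_agrees_on_extremes(self, make_site, samples8):
        cfg = FilterConfig(homogeneity_mode="chisq")
        _, remove_const = homogeneity_test(make_site([(50, 50)] * 8), samples8, cfg)
        _, remove_fixed = homogeneity_test(
            make_site([(100, 0)] * 4 + [(0, 100)] * 4), samples8, cfg
        )
        assert remove_const and not remove_fixed


class TestMorphSummary:
    def test_delta_arithmetic(self, make_site, samples8):
        pairs = [(50, 0)] * 4 + [(2, 47), (3, 48), (2, 47), (3, 48)]
        s = summarize_morphs(make_site(pairs), samples8)
        assert s.pooled["AC"] == (200, 0)
        assert s.pooled["SB"] == (10, 190)
        assert s.delta == pytest.approx(0.95)

    def test_published_csad_site_delta_and_polarity(self, make_site, samples8):
        # pooled frequencies 0.961 (AC) vs 0.000 (SB) at a G>T site with the
        # outgroup carrying the reference G: derived allele is alt, high in AC
        pairs = [(39, 961), (0, 0), (0, 0), (0, 0), (1000, 0), (0, 0), (0, 0), (0, 0)]
        site = make_site(pairs, ref="G", alt="T")
        s = summarize_morphs(site, samples8, outgroup_base="G")
        assert s.freq["AC"] == pytest.approx(0.961)
        assert s.delta == pytest.approx(0.961)
        assert s.derived_allele == "alt"
        assert s.derived_high_morph == "AC"

    def test_equal_pools_give_zero_delta_p_one(self, make_site, samples8):
        s = summarize_morphs(make_site([(30, 30)] * 8), samples8)
        assert s.delta == 0.0
        assert s.morph_p == 1.0

    def test_triallelic_outgroup_left_unpolarized(self, make_site, samples8):
        site = make_site([(10, 10)] * 8, ref="A", alt="T")
        s = summarize_morphs(site, samples8, outgroup_base="C")
        assert s.derived_allele is None
        assert s.derived_high_morph is None


def test_tier_assignment_strict_inequality():
    tiers = (0.5, 0.75, 0.95)
    assert assign_tier(0.5, tiers) is None
    assert assign_tier(0.51, tiers) == 0.5
    assert assign_tier(0.96, tiers) == 0.95


# ---------------------------------------------------------------------------
# cascade


def _reference_cascade_site(site, samples, outgroup, cfg):
    """Independent per-site re-derivation of the cascade verdict."""
    covered = [sid for sid in site.counts if site.coverage(sid) > 0]
    freqs = [site.counts[sid][1] / site.coverage(sid) for sid in covered]
    if covered and min(freqs) >= cfg.interspecific_min_freq:
        return "interspecific"
    by_morph = {}
    for s in samples:
        by_morph.setdefault(s.morph, []).append(site.coverage(s.sample_id))
    if any(
        sum(c <= cfg.low_cov_reads for c in covs) >= cfg.low_cov_min_samples_per_morph
        for covs in by_morph.values()
    ):
        return "coverage"
    if len(covered) < 2:
        return "homogeneous"
    pmin = min(
        scipy_fisher([site.counts[s1], site.counts[s2]])[1]
        for i, s1 in enumerate(covered)
        for s2 in covered[i + 1 :]
    )
    if pmin >= cfg.homogeneity_alpha:
        return "homogeneous"
    pooled = {}
    for s in samples:
        r, a = site.counts[s.sample_id]
        pr, pa = pooled.get(s.morph, (0, 0))
        pooled[s.morph] = (pr + r, pa + a)
    m1, m2 = list(pooled)
    if not scipy_fisher([pooled[m1], pooled[m2]])[1] < cfg.morph_alpha:
        return "morph"
    return "retained"


def test_cascade_counts_match_independent_reference(samples8):
    from charrseq import synthetic

    cfg = synthetic.SimConfig(seed=7, n_sites=100)
    sites, _, outgroups = synthetic.simulate_site_counts(cfg)
    fcfg = FilterConfig()
    traces, funnel = run_cascade(sites, samples8, outgroups, fcfg)
    verdicts = [
        _reference_cascade_site(s, samples8, outgroups.get((s.contig_id, s.position)), fcfg)
        for s in sites
    ]
    assert funnel.loc["total", "Total"] == 100
    assert funnel.loc["pass_interspecific", "Total"] == sum(
        v != "interspecific" for v in verdicts
    )
    assert funnel.loc["pass_coverage", "Total"] == sum(
        v not in ("interspecific", "coverage") for v in verdicts
    )
    assert funnel.loc["diff_between_samples", "Total"] == sum(
        v in ("morph", "retained") for v in verdicts
    )
    assert funnel.loc["diff_between_morphs", "Total"] == sum(
        v == "retained" for v in verdicts
    )
    for t, v in zip(traces, verdicts):
        assert t.retained == (v == "retained")


def test_cascade_flags_first_failing_stage_only(samples8, make_site):
    traces, _ = run_cascade([make_site([(0, 50)] * 8)], samples8)
    (t,) = traces
    assert t.removed_interspecific
    assert sum(t.removal_flags) == 1
    assert not t.retained


def test_empty_input_gives_empty_funnel(samples8):
    traces, funnel = run_cascade([], samples8)
    assert traces == []
    assert (funnel["Total"] == 0).all()


def test_cascade_idempotent_on_retained_sites(samples8):
    from charrseq import synthetic

    cfg = synthetic.SimConfig(seed=3, n_sites=200)
    sites, _, outgroups = synthetic.simulate_site_counts(cfg)
    traces, _ = run_cascade(sites, samples8, outgroups)
    kept = [t.site for t in traces if t.retained]
    traces2, _ = run_cascade(kept, samples8, outgroups)
    assert all(not (t.removed_interspecific or t.removed_low_coverage) for t in traces2)


def test_morph_relabeling_flips_polarity_not_retention(make_site, samples8):
    pairs = [(40, 10)] * 4 + [(5, 45)] * 4
    site = make_site(pairs)
    swapped = [
        type(s)(
            sample_id=s.sample_id,
            morph={"AC": "SB", "SB": "AC"}[s.morph],
            timepoint=s.timepoint, pool_size=s.pool_size, ploidy=s.ploidy,
        )
        for s in samples8
    ]
    s1 = summarize_morphs(site, samples8, outgroup_base="A")
    s2 = summarize_morphs(site, swapped, outgroup_base="A")
    assert s1.delta == s2.delta
    assert s1.morph_p == s2.morph_p
    assert s1.derived_high_morph != s2.derived_high_morph
    assert {s1.derived_high_morph, s2.derived_high_morph} <= {"AC", "SB"}


def test_published_frequency_table_recount():
    df = charrseq.load_nearly_fixed_snps()
    counts = frequency_table_recount(df, tier=0.95)
    assert counts == {
        "total": 60, "uni": 46, "rep": 14, "uni_high_ac": 17, "uni_high_sb": 29
    }
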