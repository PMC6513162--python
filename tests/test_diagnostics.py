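"""Homolog Z-score, exact-binomial agreement, a constructed paralog-collapse
locus, and ploidy-model recovery."""

import math

import numpy as np
import pytest

from gbscall.caller import SiteGenotype, VariantCall, call_population, CallerParams
from gbscall.diagnostics import (
    allele_ratio_distribution,
    exact_binomial_flag,
    filter_homologs,
    homolog_z,
    infer_ploidy,
)


def _variant(het_ads, position=10, extra=()):
    """Variant with given het (ad_ref, ad_alt) pairs plus optional other GTs."""
    gts = [SiteGenotype(f"h{i}", "het", r, a, r + a)
           for i, (r, a) in enumerate(het_ads)]
    gts += [SiteGenotype(f"o{i}", gt, r, a, r + a)
            for i, (gt, r, a) in enumerate(extra)]
    return VariantCall("C0", position, "SNP", "A", "C", gts,
                       len(gts), len(het_ads), 0.3)


class TestHomologZ:
    def test_perfect_balance_zero(self):
        st = homolog_z(_variant([(10, 10), (15, 15)]))
        assert st.z == 0.0 and st.ratio == 0.5

    @pytest.mark.parametrize("x,n,expected", [(70, 100, 4.0), (27, 36, 3.0)])
    def test_known_values(self, x, n, expected):
        st = homolog_z(_variant([(x, n - x)]))
        assert st.z == pytest.approx(expected)

    def test_symmetry_swapping_alleles_negates(self):
        a = homolog_z(_variant([(30, 12), (25, 14)]))
        b = homolog_z(_variant([(12, 30), (14, 25)]))
        assert a.z == pytest.approx(-b.z)

    def test_no_hets_not_evaluable_never_culled(self):
        v = _variant([], extra=[("homRef", 25, 0), ("homAlt", 0, 25)])
        st = homolog_z(v)
        assert not st.evaluable and math.isnan(st.z)
        retained, culled, _ = filter_homologs([v])
        assert retained == [v] and culled == []

    def test_hom_and_missing_excluded_from_pooling(self):
        v = _variant([(10, 10)], extra=[("homRef", 25, 0), ("missing", 0, 0)])
        st = homolog_z(v)
        assert (st.x, st.n) == (10, 20)

    def test_mean_method_agrees_on_balanced_depths(self):
        v = _variant([(30, 10), (30, 10), (30, 10)])
        zp = homolog_z(v, "pooled").z
        zm = homolog_z(v, "mean").z
        assert np.sign(zp) == np.sign(zm)
        assert zp == pytest.approx(zm, rel=1e-9)  # equal depths: identical


class TestFilter:
    def test_boundary_strict_inequality(self):
        # pooled n=400, x such that z just below/above 5
        n = 400
        x_below = int(n / 2 + 4.99 * math.sqrt(n / 4) // 1)  # z ~ 4.9
        v1 = _variant([(x_below, n - x_below)])
        retained, culled, _ = filter_homologs([v1], 5.0)
        assert v1 in retained

    def test_negative_z_culled_by_absolute_value(self):
        v = _variant([(10, 53)])  # z = (10 - 31.5)/sqrt(15.75) ~ -5.4
        retained, culled, _ = filter_homologs([v], 5.0)
        assert v in culled

    def test_partition(self):
        vs = [_variant([(10, 10)]), _variant([(60, 10)]), _variant([(10, 60)])]
        retained, culled, _ = filter_homologs(vs, 5.0)
        assert sorted(map(id, retained + culled)) == sorted(map(id, vs))


class TestExactBinomialAgreement:
    def test_agrees_with_normal_classification_on_fixtures(self, rng):
        """|z|>5 and the exact two-sided binomial tail (at the equivalent
        probability cutoff) classify identically for pooled n >= 100."""
        for _ in range(300):
            n = int(rng.integers(100, 1200))
            # mix of null and shifted sites
            p = rng.choice([0.5, 0.5, 0.75, 0.25])
            x = int(rng.binomial(n, p))
            z = (x - n / 2) / math.sqrt(n / 4)
            assert (abs(z) > 5.0) == exact_binomial_flag(x, n, 5.0)

    def test_null_calibration(self, rng):
        """Fraction of well-behaved variants flagged at |z|>5 is < 0.1%."""
        n_flag = 0
        trials = 20_000
        for _ in range(trials):
            depths = rng.integers(20, 31, size=12)  # 12 hets at 20-30x
            x = rng.binomial(depths, 0.5).sum()
            n = int(depths.sum())
            z = (x - n / 2) / math.sqrt(n / 4)
            n_flag += abs(z) > 5
        assert n_flag / trials < 0.001


class TestParalogCollapse:
    def test_collapsed_paralog_locus_is_culled(self, rng):
        """Two fragments merged 1:1 with a variant segregating on one of
        them: every individual looks heterozygous but with a ~3:1 depth
        ratio, so |Z| blows past 5 while a true het site stays near 1:1."""
        from gbscall.align import Pileup, align_batch, build_index
        from gbscall.mockref import build_mock_reference
        from gbscall.sim import ReadBatch, decode, encode

        frag = rng.integers(0, 4, 240).astype(np.uint8)
        site = 60
        alt_code = (frag[site] + 1) % 4
        hapA_ref = frag.copy()
        hapA_alt = frag.copy()
        hapA_alt[site] = alt_code
        # paralog B: same locus sequence (collapses at 0.99 identity) with
        # the ref-like base at the variant site and one fixed difference
        fixed_diff = 100
        hapB = frag.copy()
        hapB[fixed_diff] = (hapB[fixed_diff] + 2) % 4
        n_ind = 12
        inds = [f"i{k:02d}" for k in range(n_ind)]
        batches = {}
        for ind in inds:
            rows = []
            # every individual het at the A locus: 6 ref + 6 alt reads,
            # plus 12 reads from collapsed paralog B (ref base at the site)
            rows += [hapA_ref[:150]] * 6 + [hapA_alt[:150]] * 6 + [hapB[:150]] * 12
            mat = np.vstack(rows).astype(np.uint8)
            batches[ind] = ReadBatch(ind, mat, [f"{ind}:r{i}" for i in range(len(rows))],
                                     [""] * len(rows))
        reads0 = [decode(r) for r in batches[inds[0]].codes]
        mr = build_mock_reference({inds[0]: reads0})
        assert len(mr) == 1  # the paralogs collapse into one centroid
        idx = build_index(mr, 20)
        pile = Pileup(mr, inds)
        for ind in inds:
            align_batch(batches[ind], idx, pile)
        calls = call_population(pile, CallerParams())
        by_pos = {c.position - 1: c for c in calls}
        assert site in by_pos
        retained, culled, stats = filter_homologs(calls, 5.0)
        culled_pos = {c.position - 1 for c in culled}
        assert site in culled_pos  # pooled 18:6 per ind -> |Z| >> 5
        st = {s.position - 1: s for s in stats}[site]
        assert abs(st.z) > 5
        # the fixed difference between the paralogs is balanced 1:1 in every
        # individual, so the Z-score alone does not cull it
        if fixed_diff in by_pos:
            assert fixed_diff in {c.position - 1 for c in retained}


class TestPloidy:
    def test_insufficient_data(self):
        rep = infer_ploidy(np.full(10, 0.5))
        assert rep.insufficient_data and rep.best_model is None

    def test_histogram_accounts_for_all_sites(self, rng):
        ratios = rng.uniform(0.05, 0.95, 200)
        rep = infer_ploidy(ratios)
        assert rep.histogram.sum() == rep.n_het_sites == 200

    def test_diploid_recovery_rate(self):
        ok = 0
        for s in range(100):
            r = np.random.default_rng(s)
            ratios = r.binomial(25, 0.5, size=200) / 25
            rep = infer_ploidy(ratios)
            ok += rep.best_model == "diploid"
        assert ok >= 95

    def test_tetraploid_recovery_rate(self):
        ok = 0
        for s in range(100):
            r = np.random.default_rng(1000 + s)
            parts = [r.binomial(28, p, size=67) / 28 for p in (0.25, 0.5, 0.75)]
            rep = infer_ploidy(np.concatenate(parts))
            ok += rep.best_model == "tetraploid"
        assert ok >= 95

    def test_allele_ratio_distribution_filters(self):
        v = _variant([(10, 12)], extra=[("homRef", 25, 0)])
        v.genotypes[0].individual_id = "h0"
        assert len(allele_ratio_distribution("h0", [v], min_depth=10)) == 1
        assert len(allele_ratio_distribution("h0", [v], min_depth=50)) == 0
        assert len(allele_ratio_distribution("nobody", [v])) == 0
        assert allele_ratio_distribution("h0", [v], 10)[0] == pytest.approx(12 / 22)

    def test_diploid_simulation_ratio_mean(self, tiny_run, tiny_sim):
        """Het allele-balance in a diploid simulation centres on 0.5.

        The mock-reference individual is excluded: at its own het sites the
        consensus picks its majority haplotype, so the VCF ALT is its
        minority allele and its ratios are selection-biased low (~0.42 at
        25x), a real property of de novo references rather than a defect.
        """
        _cfg, res = tiny_run
        from gbscall.caller import read_vcf

        mr_ind = sorted(tiny_sim.read_counts,
                        key=lambda i: (-tiny_sim.read_counts[i], i))[0]
        calls, individuals = read_vcf(res.out_dir / "variants.retained.vcf")
        pooled = []
        for ind in individuals:
            if ind != mr_ind:
                pooled.extend(allele_ratio_distribution(ind, calls, 10))
        pooled = np.asarray(pooled)
        assert len(pooled) > 80
        # bound sized to the pool: 3 standard errors of the mean (the toy
        # run yields <~150 ratios; larger pools tighten this towards 0.02)
        bound = max(0.02, 3 * pooled.std() / np.sqrt(len(pooled)))
        assert abs(float(pooled.mean()) - 0.5) <= bound
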