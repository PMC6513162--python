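"""Simulator unit and property tests: fragment space, variant induction,
Hardy-Weinberg genotypes and read generation."""

import numpy as np
import pytest

from gbscall.errors import ConfigError
from gbscall.sim import (
    SimConfig,
    apply_variant,
    encode,
    individual_ids,
    induce_variants,
    make_fragments,
    sample_population_genotypes,
    simulate,
)


def _cfg(**kw):
    base = dict(n_fragments=50, n_snps=10, n_indels=5, n_individuals=4,
                depth_range=(5, 8), error_rate=0.0, seed=1)
    base.update(kw)
    return SimConfig(**base)


class TestFragments:
    def test_counts_lengths_uniqueness(self, rng):
        cfg = _cfg(n_fragments=300)
        frags = make_fragments(cfg, rng)
        assert len(frags) == 300
        seqs = {f.sequence for f in frags}
        assert len(seqs) == 300
        lo, hi = cfg.fragment_length_range
        assert all(lo <= len(f.sequence) <= hi for f in frags)
        assert len({f.fragment_id for f in frags}) == 300

    def test_single_fragment(self, rng):
        frags = make_fragments(_cfg(n_fragments=1, n_snps=0, n_indels=0), rng)
        assert len(frags) == 1

    def test_deterministic_given_seed(self):
        a = make_fragments(_cfg(), np.random.default_rng(99))
        b = make_fragments(_cfg(), np.random.default_rng(99))
        assert [f.sequence for f in a] == [f.sequence for f in b]

    @pytest.mark.parametrize("kw", [
        dict(n_snps=40, n_indels=20),              # more variants than fragments
        dict(depth_range=(0, 5)),                  # depth floor
        dict(error_rate=1.0),                      # error rate bound
        dict(fragment_length_range=(100, 120)),    # shorter than read length
        dict(maf_range=(0.0, 0.5)),                # maf must be > 0
    ])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ConfigError):
            _cfg(**kw).validate()


class TestInduceVariants:
    def test_counts_and_one_per_fragment(self, rng):
        frags = make_fragments(_cfg(n_fragments=500), rng)
        vs = induce_variants(frags, 100, 40, 10, rng)
        assert sum(v.vtype == "SNP" for v in vs) == 100
        assert sum(v.vtype in ("INS", "DEL") for v in vs) == 40
        assert len({v.fragment_id for v in vs}) == 140

    def test_indels_left_anchored_within_window(self, rng):
        frags = make_fragments(_cfg(n_fragments=400), rng)
        vs = induce_variants(frags, 0, 120, 10, rng, read_length=150, margin=10)
        by_id = {f.fragment_id: f.sequence for f in frags}
        for v in vs:
            assert v.ref_allele[0] == v.alt_allele[0]  # shared anchor base
            ilen = abs(len(v.ref_allele) - len(v.alt_allele))
            assert 1 <= ilen <= 10
            assert v.offset >= 10
            assert v.offset + len(v.ref_allele) <= 140
            # alleles are real fragment content
            frag = by_id[v.fragment_id]
            assert frag[v.offset : v.offset + len(v.ref_allele)] == v.ref_allele

    def test_empty_and_overfull(self, rng):
        frags = make_fragments(_cfg(n_fragments=10, n_snps=0, n_indels=0), rng)
        assert induce_variants(frags, 0, 0, 10, rng) == []
        with pytest.raises(ConfigError):
            induce_variants(frags[:5], 6, 0, 10, rng)


class TestGenotypes:
    def test_hwe_het_fraction_at_half(self, rng):
        frags = make_fragments(_cfg(n_fragments=1, n_snps=1, n_indels=0), rng)
        vs = induce_variants(frags, 1, 0, 10, rng, maf_range=(0.5, 0.5))
        gt = sample_population_genotypes(vs, 10_000, (0.5, 0.5), rng)
        het = (gt.genotype == "het").mean()
        assert het == pytest.approx(0.5, abs=0.015)

    def test_every_variant_has_a_carrier(self, rng):
        frags = make_fragments(_cfg(n_fragments=200), rng)
        vs = induce_variants(frags, 50, 0, 10, rng, maf_range=(0.1, 0.15))
        gt = sample_population_genotypes(vs, 5, (0.1, 0.15), rng)
        carriers = gt[gt.genotype != "homRef"].groupby("fragment_id").size()
        assert set(carriers.index) == {v.fragment_id for v in vs}

    def test_single_individual(self, rng):
        frags = make_fragments(_cfg(), rng)
        vs = induce_variants(frags, 5, 2, 10, rng)
        gt = sample_population_genotypes(vs, 1, (0.1, 0.5), rng)
        assert len(gt) == len(vs)

    def test_empty_truth(self, rng):
        gt = sample_population_genotypes([], 5, (0.1, 0.5), rng)
        assert len(gt) == 0


class TestReads:
    def test_zero_error_reads_are_haplotype_prefixes(self, clean_sim):
        frag_by_id = {f.fragment_id: f for f in clean_sim.fragments}
        var_by_frag = {v.fragment_id: v for v in clean_sim.variants}
        batch = clean_sim.batches["ind01"]
        for row, fid in zip(batch.codes[:500], batch.fragment_ids[:500]):
            fc = encode(frag_by_id[fid].sequence)
            candidates = [fc[:150]]
            if fid in var_by_frag:
                candidates.append(apply_variant(fc, var_by_frag[fid])[:150])
            assert any(np.array_equal(row, c) for c in candidates)

    def test_observed_error_rate(self, tiny_sim):
        """Mismatch fraction vs the source haplotype = 1.1% +/- 0.1%."""
        frag_by_id = {f.fragment_id: f for f in tiny_sim.fragments}
        var_by_frag = {v.fragment_id: v for v in tiny_sim.variants}
        mism = tot = 0
        for ind in ("ind01", "ind02"):
            batch = tiny_sim.batches[ind]
            for row, fid in zip(batch.codes, batch.fragment_ids):
                fc = encode(frag_by_id[fid].sequence)
                candidates = [fc[:150]]
                if fid in var_by_frag:
                    candidates.append(apply_variant(fc, var_by_frag[fid])[:150])
                d = min(int((row != c).sum()) for c in candidates)
                mism += d
                tot += 150
        assert tot >= 100_000
        assert mism / tot == pytest.approx(0.011, abs=0.001)

    def test_depth_within_range(self, tiny_sim):
        batch = tiny_sim.batches["ind03"]
        import collections

        depth = collections.Counter(batch.fragment_ids)
        assert set(depth) == {f.fragment_id for f in tiny_sim.fragments}
        assert all(20 <= d <= 30 for d in depth.values())

    def test_truth_completeness_zero_error(self, clean_sim):
        """Every alt allele appears in at least one read."""
        frag_by_id = {f.fragment_id: f for f in clean_sim.fragments}
        seen_alt = set()
        alt_reads = {}
        for v in clean_sim.variants:
            fc = encode(frag_by_id[v.fragment_id].sequence)
            alt_reads[v.fragment_id] = apply_variant(fc, v)[:150]
        for batch in clean_sim.batches.values():
            for row, fid in zip(batch.codes, batch.fragment_ids):
                if fid in alt_reads and np.array_equal(row, alt_reads[fid]):
                    seen_alt.add(fid)
        assert seen_alt == {v.fragment_id for v in clean_sim.variants}

    def test_het_allele_balance(self, clean_sim):
        """Pooled over het individuals, alt-read fraction is ~0.5."""
        frag_by_id = {f.fragment_id: f for f in clean_sim.fragments}
        alt_reads = {
            v.fragment_id: apply_variant(
                encode(frag_by_id[v.fragment_id].sequence), v)[:150]
            for v in clean_sim.variants
        }
        hets = clean_sim.genotypes.query("genotype == 'het'")
        het_keys = set(zip(hets.individual_id, hets.fragment_id))
        n_alt = n_tot = 0
        for ind, batch in clean_sim.batches.items():
            for row, fid in zip(batch.codes, batch.fragment_ids):
                if (ind, fid) in het_keys:
                    n_tot += 1
                    n_alt += int(np.array_equal(row, alt_reads[fid]))
        assert n_tot > 2000
        assert n_alt / n_tot == pytest.approx(0.5, abs=0.02)


class TestDeterminismAndConservation:
    def test_byte_identical_outputs(self, tmp_path):
        cfg = _cfg(error_rate=0.01)
        a, b = tmp_path / "a", tmp_path / "b"
        simulate(cfg, out_dir=a)
        simulate(cfg, out_dir=b)
        for name in ["fragments.fasta", "truth_variants.tsv", "truth_genotypes.tsv",
                     "ind01.R1.fastq", "ind04.R1.fastq", "manifest.tsv"]:
            assert (a / name).read_bytes() == (b / name).read_bytes()

    def test_read_counts_conserved(self, tiny_sim):
        for ind in individual_ids(tiny_sim.config.n_individuals):
            assert tiny_sim.read_counts[ind] == len(tiny_sim.batches[ind])
        assert tiny_sim.total_reads == sum(
            len(b) for b in tiny_sim.batches.values())
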