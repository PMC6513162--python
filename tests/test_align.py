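"""Aligner tests: k-mer index, banded affine DP versus an unbanded
dynamic-programming oracle, mapping policies and pileup bookkeeping."""

import numpy as np
import pytest

from gbscall.align import (
    KmerIndex,
    Pileup,
    align_read,
    banded_align,
    build_index,
    make_pileup,
)
from gbscall.mockref import MockReference
from gbscall.seqio import SimRead
from gbscall.sim import decode, encode

NEG = -(10 ** 7)


def _mr(*seqs):
    return MockReference([(f"C{i}", s, 1) for i, s in enumerate(seqs)])


def _rand_seq(rng, n):
    return "".join("ACGT"[c] for c in rng.integers(0, 4, n))


# ---------------------------------------------------------------------------
# oracle: full (unbanded) affine-gap DP, free target ends, read global
# ---------------------------------------------------------------------------

def oracle_affine_score(read: str, target: str) -> int:
    """Plain O(L*T) affine DP: match +1, mismatch -1, gap of length g costs
    2 + (g-1); leading/trailing target overhang free; read fully aligned."""
    L, T = len(read), len(target)
    M = np.full((L + 1, T + 1), NEG, dtype=np.int64)
    I = np.full((L + 1, T + 1), NEG, dtype=np.int64)
    D = np.full((L + 1, T + 1), NEG, dtype=np.int64)
    M[0, :] = 0
    for i in range(1, L + 1):
        for j in range(0, T + 1):
            if j >= 1:
                s = 1 if read[i - 1] == target[j - 1] else -1
                M[i, j] = max(M[i - 1, j - 1], I[i - 1, j - 1], D[i - 1, j - 1]) + s
                D[i, j] = max(M[i, j - 1] - 2, D[i, j - 1] - 1, I[i, j - 1] - 2)
            I[i, j] = max(M[i - 1, j] - 2, I[i - 1, j] - 1, D[i - 1, j] - 2)
    return int(max(M[L].max(), I[L].max(), D[L].max()))


def _mutate(rng, codes, n_sub=0, ins=None, dele=None):
    out = codes.copy()
    for _ in range(n_sub):
        p = rng.integers(10, len(out) - 10)
        out[p] = (out[p] + rng.integers(1, 4)) % 4
    if ins is not None:
        p, ln = ins
        out = np.concatenate([out[:p], rng.integers(0, 4, ln).astype(np.uint8), out[p:]])
    if dele is not None:
        p, ln = dele
        out = np.concatenate([out[:p], out[p + ln:]])
    return out


class TestBandedDP:
    @pytest.mark.parametrize("case", range(30))
    def test_matches_unbanded_oracle(self, case):
        """Banded score equals the full DP score whenever the true edit
        distance is below the band width."""
        rng = np.random.default_rng(1000 + case)
        target = rng.integers(0, 4, 170).astype(np.uint8)
        kind = case % 3
        if kind == 0:
            read = _mutate(rng, target[:150], n_sub=int(rng.integers(0, 6)))
        elif kind == 1:
            read = _mutate(rng, target[:150], n_sub=2,
                           ins=(int(rng.integers(20, 120)), int(rng.integers(1, 9))))[:150]
        else:
            read = _mutate(rng, target[:155], n_sub=2,
                           dele=(int(rng.integers(20, 120)), int(rng.integers(1, 9))))[:150]
        score, start, ops, edit = banded_align(read, target, 0, 12)
        assert edit < 12
        assert score == oracle_affine_score(decode(read), decode(target))

    def test_exact_read(self):
        rng = np.random.default_rng(5)
        t = rng.integers(0, 4, 200).astype(np.uint8)
        score, start, ops, edit = banded_align(t[30:180].copy(), t, 30, 12)
        assert (score, start, edit) == (150, 30, 0)
        assert ops == [("M", 150)]

    def test_cigar_lengths_account_for_read(self):
        rng = np.random.default_rng(6)
        t = rng.integers(0, 4, 160).astype(np.uint8)
        read = _mutate(rng, t[:155], dele=(50, 5))[:150]
        _s, _p, ops, _e = banded_align(read, t, 0, 12)
        consumed = sum(ln for op, ln in ops if op in "MIS")
        assert consumed == 150
        assert any(op == "D" for op, _ln in ops)


class TestIndexAndMapping:
    def test_index_position_counts(self):
        idx = build_index(_mr("ACGTACGT"), k=4)
        assert sum(len(v) for v in idx.table.values()) == 5  # L - k + 1
        idx2 = build_index(_mr("ACGTACGT"), k=8)
        assert sum(len(v) for v in idx2.table.values()) == 1

    def test_identical_centroids_listed_twice(self):
        idx = build_index(_mr("ACGTAAGGTTCC", "ACGTAAGGTTCC"), k=6)
        for hits in idx.table.values():
            assert len(hits) == 2

    def test_exact_prefix_read(self, rng):
        cent = _rand_seq(rng, 200)
        idx = build_index(_mr(cent), k=20)
        rec = align_read(cent[:150], idx)
        assert rec.mapped and rec.position == 0
        assert rec.cigar == "150M" and rec.edit_distance == 0

    def test_two_substitutions(self, rng):
        cent = _rand_seq(rng, 180)
        read = list(cent[:150])
        for p in (40, 90):
            read[p] = "ACGT"[("ACGT".index(read[p]) + 1) % 4]
        rec = align_read("".join(read), build_index(_mr(cent), k=20),
                         max_mismatch_frac=0.1)
        assert rec.mapped and rec.edit_distance == 2

    def test_ambiguous_between_identical_centroids_unmapped(self, rng):
        cent = _rand_seq(rng, 180)
        rec = align_read(cent[:150], build_index(_mr(cent, cent), k=20))
        assert not rec.mapped
        assert "ambiguous" in rec.reason

    def test_read_shorter_than_seed_unmapped(self, rng):
        idx = build_index(_mr(_rand_seq(rng, 180)), k=20)
        rec = align_read("ACGTACGTAC", idx)
        assert not rec.mapped and "shorter" in rec.reason

    def test_strand_closure(self, rng):
        cent = _rand_seq(rng, 200)
        idx = build_index(_mr(cent), k=20)
        fwd = align_read(cent[20:170], idx)
        rc = decode((3 - encode(cent[20:170])[::-1]).astype(np.uint8))
        rev = align_read(rc, idx)
        assert rev.mapped and rev.strand == "-"
        assert (rev.centroid_id, rev.position, rev.edit_distance) == (
            fwd.centroid_id, fwd.position, fwd.edit_distance)

    def test_too_many_errors_unmapped(self, rng):
        cent = _rand_seq(rng, 180)
        read = encode(cent[:150])
        read[:40] = (read[:40] + 1) % 4  # 40 mismatches > 15 allowed
        rec = align_read(decode(read), build_index(_mr(cent), k=20),
                         max_mismatch_frac=0.1)
        assert not rec.mapped


class TestPileup:
    def _reads(self, seqs, ind="indA"):
        return [SimRead(f"r{i}", ind, "", "none", s, "I" * len(s))
                for i, s in enumerate(seqs)]

    def test_single_perfect_read_columns(self, rng):
        cent = _rand_seq(rng, 160)
        mr = _mr(cent)
        idx = build_index(mr, k=20)
        reads = self._reads([cent[:150]])
        recs = [align_read(r, idx) for r in reads]
        pile = make_pileup(recs, {r.read_id: r.sequence for r in reads}, mr,
                           ["indA"])
        depth = pile.depth("C0")
        assert depth[0, :150].tolist() == [1] * 150
        assert depth[0, 150:].sum() == 0
        cc = encode(cent)
        bc = pile.base_counts["C0"][0]
        assert all(bc[j, cc[j]] == 1 for j in range(150))

    def test_per_individual_depth_conservation(self, rng):
        cent = _rand_seq(rng, 170)
        mr = _mr(cent)
        idx = build_index(mr, k=20)
        reads = (self._reads([cent[:150]] * 20, "indA")
                 + self._reads([cent[10:160]] * 30, "indB"))
        recs = [align_read(r, idx) for r in reads]
        pile = make_pileup(recs, {r.read_id: r.sequence for r in reads}, mr,
                           ["indA", "indB"])
        depth = pile.depth("C0")
        assert depth[0].sum() == 20 * 150
        assert depth[1].sum() == 30 * 150
        assert depth[0, 20] == 20 and depth[1, 20] == 30

    def test_deletion_counted_once_at_anchor(self, rng):
        cent = _rand_seq(rng, 170)
        cc = encode(cent)
        read = decode(np.concatenate([cc[:10], cc[12:152]]))  # 2 bp deletion
        mr = _mr(cent)
        idx = build_index(mr, k=20)
        reads = self._reads([read])
        recs = [align_read(r, idx) for r in reads]
        assert recs[0].mapped and "D" in recs[0].cigar
        pile = make_pileup(recs, {r.read_id: r.sequence for r in reads}, mr,
                           ["indA"])
        keys = list(pile.indels["C0"])
        assert len(keys) == 1
        pos, ref, alt = keys[0]
        assert len(ref) - len(alt) == 2
        assert pile.indels["C0"][keys[0]][0] == 1
        # deletion-spanning columns contribute depth but no base
        dspan = pile.del_span["C0"][0]
        assert dspan.sum() == 2

    def test_mapped_unmapped_accounting(self, tiny_sim):
        """Aligning one individual's simulated reads reconciles counts."""
        from gbscall.align import align_batch
        from gbscall.mockref import build_mock_reference

        ind = "ind01"
        reads = [decode(row) for row in tiny_sim.batches[ind].codes]
        mr = build_mock_reference({ind: reads})
        idx = build_index(mr, 20)
        pile = Pileup(mr, [ind])
        st = align_batch(tiny_sim.batches[ind], idx, pile)
        assert st["mapped"] + st["unmapped"] == len(reads)
        assert st["mapped"] == pile.n_mapped
        assert st["mapped"] / len(reads) > 0.95
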