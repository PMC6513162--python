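"""K-mer seeded, banded, gap-aware read alignment against the mock
reference, and per-individual pileup accumulation.

Candidate centroids are gathered from exact k-mer seed hits of the read and
its reverse complement; each candidate is scored with a banded affine
dynamic program (match +1, mismatch -1, gap open -2, gap extend -1, band
centred on the seed diagonal). A read is reported only if its best
alignment's edit distance is within ``max_mismatch_frac`` of the read
length, and is marked unmapped when two centroids tie for best (unique-
mapping policy). Indels observed in alignments are left-normalised against
the centroid before being counted in the pileup, so the caller and the
truth-matcher share one normal form.

Coordinates are 0-based half-open internally; 1-based only at SAM/VCF
emission.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from numba import njit

from gbscall.errors import ConfigError, DataError
from gbscall.mockref import MockReference
from gbscall.sim import ReadBatch, _left_normalize, decode, encode

log = logging.getLogger(__name__)

NEG = -(10 ** 7)


# ---------------------------------------------------------------------------
# banded affine-gap dynamic program (numba)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _banded_affine(read, target, diag, band):  # pragma: no cover - jitted
    """Banded semi-global alignment of ``read`` against ``target``.

    The read is aligned end-to-end (trailing bases may be soft-clipped only
    when the alignment runs off the target's 3' end); the target's leading
    and trailing overhangs are free. ``diag`` anchors the band: read
    position i explores target positions i+diag-band .. i+diag+band.

    Returns (score, start_j, n_ops, ops, lens, n_clip_tail) where ops/lens
    describe the alignment path (0=M, 1=I, 2=D) from start_j on the target.
    A length-g gap costs 2 + (g - 1).
    """
    L = read.shape[0]
    T = target.shape[0]
    W = 2 * band + 1
    M = np.full((L + 1, W), NEG, dtype=np.int32)
    I = np.full((L + 1, W), NEG, dtype=np.int32)
    D = np.full((L + 1, W), NEG, dtype=np.int32)
    # predecessor state per (state, i, w): 0=M 1=I 2=D 9=alignment start
    PM = np.full((L + 1, W), 9, dtype=np.uint8)
    PI = np.full((L + 1, W), 9, dtype=np.uint8)
    PD = np.full((L + 1, W), 9, dtype=np.uint8)

    for w in range(W):
        j = diag + w - band
        if 0 <= j <= T:
            M[0, w] = 0
    for i in range(1, L + 1):
        for w in range(W):
            j = i + diag + w - band
            if j < 0 or j > T:
                continue
            if j >= 1:
                s = 1 if read[i - 1] == target[j - 1] else -1
                best = M[i - 1, w]
                ptr = 0
                if I[i - 1, w] > best:
                    best = I[i - 1, w]
                    ptr = 1
                if D[i - 1, w] > best:
                    best = D[i - 1, w]
                    ptr = 2
                if best > NEG:
                    M[i, w] = best + s
                    PM[i, w] = ptr
            if w + 1 < W:
                best = M[i - 1, w + 1] - 2
                ptr = 0
                if I[i - 1, w + 1] - 1 > best:
                    best = I[i - 1, w + 1] - 1
                    ptr = 1
                if D[i - 1, w + 1] - 2 > best:
                    best = D[i - 1, w + 1] - 2
                    ptr = 2
                if best > NEG:
                    I[i, w] = best
                    PI[i, w] = ptr
            if w >= 1 and j >= 1:
                best = M[i, w - 1] - 2
                ptr = 0
                if D[i, w - 1] - 1 > best:
                    best = D[i, w - 1] - 1
                    ptr = 2
                if I[i, w - 1] - 2 > best:
                    best = I[i, w - 1] - 2
                    ptr = 1
                if best > NEG:
                    D[i, w] = best
                    PD[i, w] = ptr

    # best end: full read consumed (free trailing target), or target 3' end
    # reached with the remaining read bases soft-clipped (no penalty).
    best_score = NEG
    bi = -1
    bw = -1
    bs = 0
    for w in range(W):
        j = L + diag + w - band
        if 0 <= j <= T:
            for st in range(3):
                sc = M[L, w] if st == 0 else (I[L, w] if st == 1 else D[L, w])
                if sc > best_score:
                    best_score = sc
                    bi = L
                    bw = w
                    bs = st
    for i in range(1, L):
        w = T - i - diag + band
        if 0 <= w < W:
            for st in range(3):
                sc = M[i, w] if st == 0 else (I[i, w] if st == 1 else D[i, w])
                if sc > best_score:
                    best_score = sc
                    bi = i
                    bw = w
                    bs = st
    ops = np.zeros(2 * (L + 1), dtype=np.int32)
    lens = np.zeros(2 * (L + 1), dtype=np.int32)
    if best_score <= NEG or bi < 0:
        return NEG, -1, 0, ops, lens, 0

    n_clip_tail = L - bi
    # traceback
    n = 0
    i = bi
    w = bw
    st = bs
    while i > 0 or st != 0:
        if st == 0:
            ptr = PM[i, w]
            if ptr == 9 and i == 0:
                break
            op = 0
            i -= 1
        elif st == 1:
            ptr = PI[i, w]
            op = 1
            i -= 1
            w += 1
        else:
            ptr = PD[i, w]
            op = 2
            w -= 1
        if n > 0 and ops[n - 1] == op:
            lens[n - 1] += 1
        else:
            ops[n] = op
            lens[n] = 1
            n += 1
        if ptr == 9:
            break
        st = ptr
    start_j = 0 + diag + w - band  # i is 0 here
    # reverse op runs in place
    for a in range(n // 2):
        b = n - 1 - a
        ops[a], ops[b] = ops[b], ops[a]
        lens[a], lens[b] = lens[b], lens[a]
    return best_score, start_j, n, ops, lens, n_clip_tail


def banded_align(read_codes: np.ndarray, target_codes: np.ndarray,
                 diag: int, band: int):
    """Python-facing wrapper; returns (score, start, ops, edit_distance).

    ``ops`` is a list of (op_char, length) over {M, I, D, S}; ``edit`` counts
    mismatches plus inserted plus deleted bases over the aligned span
    (soft-clipped bases excluded).
    """
    score, start, n, ops_a, lens_a, clip = _banded_affine(
        np.ascontiguousarray(read_codes), np.ascontiguousarray(target_codes),
        diag, band,
    )
    if start < 0:
        return NEG, -1, [], 10 ** 9
    ops: list[tuple[str, int]] = []
    edit = 0
    qi, tj = 0, start
    for x in range(n):
        op, ln = int(ops_a[x]), int(lens_a[x])
        if op == 0:
            edit += int(
                np.count_nonzero(read_codes[qi:qi + ln] != target_codes[tj:tj + ln])
            )
            qi += ln
            tj += ln
            ops.append(("M", ln))
        elif op == 1:
            edit += ln
            qi += ln
            ops.append(("I", ln))
        else:
            edit += ln
            tj += ln
            ops.append(("D", ln))
    if clip:
        ops.append(("S", clip))
    return int(score), int(start), ops, edit


# ---------------------------------------------------------------------------
# k-mer index
# ---------------------------------------------------------------------------

@dataclass
class KmerIndex:
    k: int
    centroid_ids: list[str]
    seqs: list[str]
    codes: list[np.ndarray]
    table: dict  # kmer bytes -> list of (centroid_index, offset)

    def lookup(self, kmer: bytes):
        return self.table.get(kmer)


def build_index(mr: MockReference, k: int = 20) -> KmerIndex:
    """Index every k-mer occurrence of every centroid.

    Centroids shorter than ``k`` are skipped with a warning.
    """
    ids: list[str] = []
    seqs: list[str] = []
    codes: list[np.ndarray] = []
    table: dict[bytes, list[tuple[int, int]]] = {}
    n_skipped = 0
    for cid, seq, _size in mr.records:
        if len(seq) < k:
            n_skipped += 1
            continue
        ci = len(ids)
        ids.append(cid)
        seqs.append(seq)
        arr = encode(seq)
        codes.append(arr)
        raw = arr.tobytes()
        for off in range(len(seq) - k + 1):
            table.setdefault(raw[off : off + k], []).append((ci, off))
    if n_skipped:
        log.warning("build_index: %d centroid(s) shorter than k=%d skipped",
                    n_skipped, k)
    if not ids:
        raise ConfigError(f"no centroid of length >= k={k} to index")
    return KmerIndex(k, ids, seqs, codes, table)


# ---------------------------------------------------------------------------
# read alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignmentRecord:
    read_id: str
    individual_id: str
    centroid_id: str | None  # None = unmapped
    position: int  # 0-based leftmost on centroid
    cigar: str
    strand: str  # '+' or '-'
    edit_distance: int
    reason: str = ""  # why unmapped, when unmapped
    ops: list = None  # [(op_char, length)] kept for pileup use

    @property
    def mapped(self) -> bool:
        return self.centroid_id is not None


def _seed_offsets(L: int, k: int) -> list[int]:
    if L <= k:
        return [0]
    return sorted({0, (L - k) // 2, L - k})


def _gather_candidates(codes: np.ndarray, index: KmerIndex):
    """Seed both orientations; yield (strand, centroid_idx, diag, votes)."""
    k = index.k
    L = codes.shape[0]
    out: dict[tuple[str, int], list[tuple[int, int]]] = {}
    for strand, arr in (("+", codes), ("-", (3 - codes[::-1]).astype(np.uint8))):
        raw = arr.tobytes()
        for q in _seed_offsets(L, k):
            hits = index.lookup(raw[q : q + k])
            if not hits:
                continue
            for ci, p in hits:
                out.setdefault((strand, ci), []).append((q, p))
    cands = []
    for (strand, ci), hits in out.items():
        hits.sort()
        q0, p0 = hits[0]
        cands.append((strand, ci, p0 - q0, len(hits)))
    return cands


def align_codes(
    codes: np.ndarray,
    index: KmerIndex,
    max_mismatch_frac: float = 0.1,
    band: int = 12,
):
    """Core alignment of one encoded read.

    Returns (centroid_idx, start, strand, ops, edit, reason); centroid_idx
    is -1 when unmapped. A candidate whose gap-free (Hamming) alignment has
    <= 2 mismatches is accepted without the DP: under this scoring a gapped
    alignment cannot beat a <=2-mismatch ungapped one over the same span.
    """
    L = codes.shape[0]
    if L < index.k:
        return -1, -1, "+", [], 0, "read shorter than seed length"
    cands = _gather_candidates(codes, index)
    if not cands:
        return -1, -1, "+", [], 0, "no seed hits"
    max_edit = int(np.floor(max_mismatch_frac * L))
    scored = []
    for strand, ci, diag, votes in cands:
        tgt = index.codes[ci]
        arr = codes if strand == "+" else (3 - codes[::-1]).astype(np.uint8)
        start = None
        if 0 <= diag and diag + L <= tgt.shape[0]:
            mism = int(np.count_nonzero(arr != tgt[diag : diag + L]))
            if mism <= 2:
                scored.append(
                    (L - 2 * mism, mism, -votes, index.centroid_ids[ci], diag,
                     strand, ci, [("M", L)])
                )
                continue
        if diag < -band:
            diag = -band
        score, start, ops, edit = banded_align(arr, tgt, diag, band)
        if start < 0:
            continue
        scored.append(
            (score, edit, -votes, index.centroid_ids[ci], start, strand, ci, ops)
        )
    if not scored:
        return -1, -1, "+", [], 0, "no alignment within band"
    scored.sort(key=lambda t: (-t[0], t[1], t[2], t[3], t[4]))
    best = scored[0]
    if len(scored) > 1:
        second = scored[1]
        if (best[0], best[1], best[2]) == (second[0], second[1], second[2]) \
                and best[6] != second[6]:
            return -1, -1, "+", [], 0, "ambiguous: equally-best on >1 centroid"
    score, edit, _nv, _cid, start, strand, ci, ops = best
    if edit > max_edit:
        return -1, -1, "+", [], 0, f"edit distance {edit} > {max_edit}"
    return ci, start, strand, ops, edit, ""


def align_read(
    read,
    index: KmerIndex,
    max_mismatch_frac: float = 0.1,
    band: int = 12,
) -> AlignmentRecord:
    """Align one read (a SimRead or DNA string) to the mock reference."""
    if hasattr(read, "sequence"):
        seq, rid, ind = read.sequence, read.read_id, read.individual_id
    else:
        seq, rid, ind = str(read), "read", ""
    codes = encode(seq)
    ci, start, strand, ops, edit, reason = align_codes(
        codes, index, max_mismatch_frac, band
    )
    if ci < 0:
        return AlignmentRecord(rid, ind, None, -1, "*", "+", 0, reason, [])
    cigar = "".join(f"{ln}{op}" for op, ln in ops)
    return AlignmentRecord(
        rid, ind, index.centroid_ids[ci], start, cigar, strand, edit, "", ops
    )


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------

class Pileup:
    """Per-centroid, per-individual allele depth counts.

    ``base_counts[cid]`` has shape (n_individuals, centroid_len, 4);
    ``del_span[cid]`` counts reads whose deletion spans a column (they
    contribute depth but no base there); ``indels[cid]`` maps a
    left-anchored (position, ref, alt) allele pair to a per-individual
    count vector. Per individual and column, total depth = sum of base
    counts + deletion-spanning count.
    """

    def __init__(self, mr: MockReference, individuals: Sequence[str]):
        self.individuals = list(individuals)
        self.ind_index = {ind: i for i, ind in enumerate(self.individuals)}
        n = len(self.individuals)
        self.centroid_ids = [cid for cid, _s, _z in mr.records]
        self.seqs = {cid: seq for cid, seq, _z in mr.records}
        self.base_counts = {
            cid: np.zeros((n, len(seq), 4), dtype=np.uint16)
            for cid, seq, _z in mr.records
        }
        self.del_span = {
            cid: np.zeros((n, len(seq)), dtype=np.uint16) for cid, seq, _z in mr.records
        }
        self.indels: dict[str, dict[tuple[int, str, str], np.ndarray]] = {
            cid: {} for cid, _s, _z in mr.records
        }
        self.n_mapped = 0
        self.n_unmapped = 0
        self.n_rejected = 0

    def depth(self, cid: str) -> np.ndarray:
        """(n_individuals, L) total depth per column."""
        return self.base_counts[cid].sum(axis=2, dtype=np.int64) + self.del_span[cid]

    def add(self, cid: str, ind: str, start: int, ops, oriented_codes: np.ndarray):
        """Accumulate one mapped read given its alignment path."""
        bc = self.base_counts[cid]
        L = bc.shape[1]
        span = sum(ln for op, ln in ops if op in "MD")
        if start < 0 or start + span > L:
            self.n_rejected += 1
            log.warning("alignment overruns centroid %s (start %d span %d); rejected",
                        cid, start, span)
            return
        ii = self.ind_index[ind]
        seq = self.seqs[cid]
        qi, tj = 0, start
        for op, ln in ops:
            if op == "M":
                bc[ii, tj : tj + ln, :][np.arange(ln), oriented_codes[qi : qi + ln]] += 1
                qi += ln
                tj += ln
            elif op == "S":
                qi += ln
            elif op == "I":
                if tj > 0:
                    ins = decode(oriented_codes[qi : qi + ln])
                    ref = seq[tj - 1]
                    pos, nref, nalt = _left_normalize(seq, tj - 1, ref, ref + ins)
                    key = (pos, nref, nalt)
                    d = self.indels[cid].setdefault(
                        key, np.zeros(len(self.individuals), dtype=np.uint32)
                    )
                    d[ii] += 1
                qi += ln
            elif op == "D":
                self.del_span[cid][ii, tj : tj + ln] += 1
                if tj > 0:
                    ref = seq[tj - 1 : tj + ln]
                    pos, nref, nalt = _left_normalize(seq, tj - 1, ref, seq[tj - 1])
                    key = (pos, nref, nalt)
                    d = self.indels[cid].setdefault(
                        key, np.zeros(len(self.individuals), dtype=np.uint32)
                    )
                    d[ii] += 1
                tj += ln
        self.n_mapped += 1

    def save_npz(self, path) -> None:
        """Persist the pileup (internal cache format for CLI chaining)."""
        import json

        payload = {
            "individuals": np.array(self.individuals),
            "centroid_ids": np.array(self.centroid_ids),
        }
        for i, cid in enumerate(self.centroid_ids):
            payload[f"bc_{i}"] = self.base_counts[cid]
            payload[f"ds_{i}"] = self.del_span[cid]
        indels = {
            cid: {f"{p}|{r}|{a}": v.tolist() for (p, r, a), v in d.items()}
            for cid, d in self.indels.items()
        }
        payload["indels_json"] = np.array(json.dumps(indels))
        np.savez_compressed(str(path), **payload)

    @classmethod
    def load_npz(cls, path, mr: "MockReference") -> "Pileup":
        import json

        with np.load(str(path), allow_pickle=False) as z:
            individuals = [str(x) for x in z["individuals"]]
            pile = cls(mr, individuals)
            cids = [str(x) for x in z["centroid_ids"]]
            for i, cid in enumerate(cids):
                pile.base_counts[cid] = z[f"bc_{i}"]
                pile.del_span[cid] = z[f"ds_{i}"]
            indels = json.loads(str(z["indels_json"]))
        for cid, d in indels.items():
            for key, counts in d.items():
                p, r, a = key.split("|")
                pile.indels[cid][(int(p), r, a)] = np.array(counts, dtype=np.uint32)
        return pile

    def dump_tsv(self, path) -> None:
        """Debugging dump: one row per (centroid, position, individual)."""
        with open(path, "w") as out:
            out.write("centroid_id\tpos\tindividual\tA\tC\tG\tT\tdel_span\n")
            for cid in self.centroid_ids:
                bc = self.base_counts[cid]
                ds = self.del_span[cid]
                tot = bc.sum(axis=2) + ds
                for ii, ind in enumerate(self.individuals):
                    for j in np.nonzero(tot[ii])[0]:
                        a, c, g, t = bc[ii, j]
                        out.write(
                            f"{cid}\t{j}\t{ind}\t{a}\t{c}\t{g}\t{t}\t{ds[ii, j]}\n"
                        )


def make_pileup(
    alignments: Iterable[AlignmentRecord],
    reads: Mapping[str, str],
    mr: MockReference,
    individuals: Sequence[str] | None = None,
) -> Pileup:
    """Build a pileup from alignment records and a read_id -> sequence map."""
    alignments = list(alignments)
    if individuals is None:
        individuals = sorted({a.individual_id for a in alignments})
    pile = Pileup(mr, individuals)
    for rec in alignments:
        if not rec.mapped:
            pile.n_unmapped += 1
            continue
        if rec.centroid_id not in pile.base_counts:
            raise DataError(f"alignment references unknown centroid {rec.centroid_id}")
        codes = encode(reads[rec.read_id])
        if rec.strand == "-":
            codes = (3 - codes[::-1]).astype(np.uint8)
        pile.add(rec.centroid_id, rec.individual_id, rec.position, rec.ops, codes)
    return pile


def align_batch(
    batch: ReadBatch,
    index: KmerIndex,
    pileup: Pileup,
    max_mismatch_frac: float = 0.1,
    band: int = 12,
    sam_writer=None,
) -> dict:
    """Align one individual's reads and accumulate them into ``pileup``.

    This is the streaming fast path used by the pipeline; results are
    identical to calling :func:`align_read` + :meth:`Pileup.add` per read.
    """
    n_mapped = n_unmapped = 0
    ind = batch.individual_id
    for row, rid in zip(batch.codes, batch.read_ids):
        ci, start, strand, ops, edit, reason = align_codes(
            row, index, max_mismatch_frac, band
        )
        if ci < 0:
            n_unmapped += 1
            if sam_writer is not None:
                sam_writer.write_unmapped(rid, ind, decode(row))
            continue
        oriented = row if strand == "+" else (3 - row[::-1]).astype(np.uint8)
        cid = index.centroid_ids[ci]
        pileup.add(cid, ind, start, ops, oriented)
        n_mapped += 1
        if sam_writer is not None:
            sam_writer.write_mapped(rid, ind, cid, start, ops, strand, edit,
                                    decode(oriented))
    pileup.n_unmapped += n_unmapped
    log.info("%s: %d mapped, %d unmapped", ind, n_mapped, n_unmapped)
    return {"individual": ind, "mapped": n_mapped, "unmapped": n_unmapped}


# ---------------------------------------------------------------------------
# SAM emission
# ---------------------------------------------------------------------------

class SamWriter:
    """Minimal SAM 1.x writer over pysam with one read group per individual."""

    def __init__(self, path, mr: MockReference, individuals: Sequence[str]):
        import pysam

        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": cid, "LN": len(seq)} for cid, seq, _z in mr.records],
            "RG": [{"ID": ind, "SM": ind} for ind in individuals],
        }
        self._f = pysam.AlignmentFile(str(path), "w", header=header)
        self._tid = {cid: i for i, (cid, _s, _z) in enumerate(mr.records)}
        self._ids = [cid for cid, _s, _z in mr.records]

    def write_mapped(self, rid, ind, cid, start, ops, strand, edit, seq):
        import pysam

        a = pysam.AlignedSegment(self._f.header)
        a.query_name = rid
        a.query_sequence = seq
        a.flag = 16 if strand == "-" else 0
        a.reference_id = self._tid[cid]
        a.reference_start = start
        a.mapping_quality = 60
        a.cigarstring = "".join(f"{ln}{op}" for op, ln in ops)
        a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
        a.set_tag("NM", edit)
        a.set_tag("RG", ind)
        self._f.write(a)

    def write_unmapped(self, rid, ind, seq):
        import pysam

        a = pysam.AlignedSegment(self._f.header)
        a.query_name = rid
        a.query_sequence = seq
        a.flag = 4
        a.reference_id = -1
        a.reference_start = -1
        a.mapping_quality = 0
        a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
        a.set_tag("RG", ind)
        self._f.write(a)

    def close(self):
        self._f.close()
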