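"""Mock Reference construction by greedy identity clustering of GBS reads.

Without a genome, reads are dereplicated, clustered at a sequence-identity
threshold, and each cluster's members are aligned back to its centroid to
emit one consensus "fragment" per cluster. The resulting FASTA (the mock
reference) stands in for a genome in downstream alignment and calling.

Identity between two sequences is 1 - edit_distance/max(lengths) with
unit-cost edits (computed with edlib). Clustering is greedy in descending
(length, abundance, lexicographic) order: a sequence joins the first
existing centroid it matches at or above the threshold, else founds a new
cluster. A candidate prefilter based on the q-gram lemma keeps this exact
while scaling to ~1e5 unique sequences.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np

from gbscall.errors import ConfigError
from gbscall.seqio import write_fasta

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class UniqueSeq:
    sequence: str
    count: int


@dataclass
class Cluster:
    centroid_id: str
    centroid_seq: str
    members: list[tuple[UniqueSeq, float]] = field(default_factory=list)

    @property
    def size(self) -> int:
        """Total supporting reads (sum of member counts)."""
        return sum(u.count for u, _ in self.members)


@dataclass
class MockReference:
    """Ordered (centroid_id, consensus sequence, cluster size) records."""

    records: list[tuple[str, str, int]]

    def __len__(self) -> int:
        return len(self.records)

    def sequences(self) -> dict[str, str]:
        return {cid: seq for cid, seq, _ in self.records}

    def write(self, path) -> None:
        write_fasta(
            ((f"{cid} size={size}", seq) for cid, seq, size in self.records), path
        )

    @classmethod
    def from_fasta(cls, path) -> "MockReference":
        from gbscall.seqio import read_fasta

        recs = []
        for name, seq in read_fasta(path):
            recs.append((name.split()[0], seq, 0))
        return cls(recs)


def dereplicate(reads: Iterable[str]) -> list[UniqueSeq]:
    """Collapse exact duplicate sequences, conserving counts."""
    counts: dict[str, int] = {}
    for seq in reads:
        counts[seq] = counts.get(seq, 0) + 1
    return [UniqueSeq(s, c) for s, c in counts.items()]


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: 1 - edit_distance(a, b) / max(|a|, |b|)."""
    if not a or not b:
        raise ConfigError("pairwise_identity requires non-empty sequences")
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def _sort_key(u: UniqueSeq):
    # descending length, descending count, ascending lexicographic
    return (-len(u.sequence), -u.count, u.sequence)


def greedy_cluster(
    uniques: Sequence[UniqueSeq],
    identity_threshold: float = 0.93,
    min_count: int = 1,
) -> list[Cluster]:
    """Greedy centroid clustering.

    Sequences are processed in descending (length, count) order with a
    lexicographic tie-break; each joins the *first-founded* centroid whose
    identity is >= ``identity_threshold``, else founds a new cluster.
    Sequences with count < ``min_count`` may join clusters but never found
    one (suppresses error-only centroids); such sequences that match no
    centroid are left unassigned and reported in the log.
    """
    if not (0.0 < identity_threshold <= 1.0):
        raise ConfigError("identity_threshold must be in (0, 1]")
    order = sorted(uniques, key=_sort_key)
    clusters: list[Cluster] = []
    cent_seqs: list[str] = []
    n_unassigned = 0

    # q-gram lemma: sequences within E edits of a (length-Lmin) sequence share
    # an exact k-mer whenever (Lmin - k + 1) - k*E >= 1. Using the most
    # permissive E over the batch keeps the prefilter exact.
    kmer_index: dict[str, list[int]] | None = None
    if order:
        lmin = min(len(u.sequence) for u in order)
        lmax = max(len(u.sequence) for u in order)
        # epsilon guards the boundary: identity exactly at threshold must pass
        emax = int(np.floor((1.0 - identity_threshold) * lmax + 1e-9))
        k = lmin // (emax + 1) if emax >= 0 else lmin
        k = min(k, 16)
        if k >= 5:
            kmer_index = {}
        else:
            log.debug("greedy_cluster: prefilter disabled (k=%d too small)", k)

    def _candidates(seq: str) -> Iterable[int]:
        if kmer_index is None:
            return range(len(clusters))
        hits: set[int] = set()
        for i in range(0, len(seq) - k + 1):
            lst = kmer_index.get(seq[i : i + k])
            if lst:
                hits.update(lst)
        return sorted(hits)  # founding order = "first" semantics

    for u in order:
        assigned = False
        for ci in _candidates(u.sequence):
            cent = cent_seqs[ci]
            lim = int(np.floor((1.0 - identity_threshold)
                               * max(len(u.sequence), len(cent)) + 1e-9))
            res = edlib.align(u.sequence, cent, mode="NW", task="distance", k=lim)
            d = res["editDistance"]
            if d != -1:
                ident = 1.0 - d / max(len(u.sequence), len(cent))
                clusters[ci].members.append((u, ident))
                assigned = True
                break
        if not assigned:
            if u.count >= min_count:
                ci = len(clusters)
                cid = f"MR{ci:06d}"
                clusters.append(Cluster(cid, u.sequence, [(u, 1.0)]))
                cent_seqs.append(u.sequence)
                if kmer_index is not None:
                    s = u.sequence
                    for i in range(0, len(s) - k + 1):
                        kmer_index.setdefault(s[i : i + k], []).append(ci)
            else:
                n_unassigned += 1
    if n_unassigned:
        log.info(
            "greedy_cluster: %d low-abundance sequence(s) matched no centroid "
            "and were left unclustered", n_unassigned,
        )
    return clusters


def consensus(cluster: Cluster) -> str:
    """Count-weighted majority consensus over centroid columns.

    Members are globally aligned to the centroid (edlib path). Per centroid
    column the majority base wins, weighted by member read counts; ties go
    to the centroid's own base; member insertions (columns absent from the
    centroid) are ignored; a column deleted in every member is dropped.
    """
    if not cluster.members:
        raise ConfigError("consensus of an empty cluster")
    cent = cluster.centroid_seq
    L = len(cent)
    from gbscall.sim import encode

    counts = np.zeros((L, 4), dtype=np.int64)
    covered = np.zeros(L, dtype=np.int64)
    cent_codes = encode(cent)
    cols = np.arange(L)
    for u, _ident in cluster.members:
        mem = encode(u.sequence)
        if u.sequence == cent:
            counts[cols, cent_codes] += u.count
            covered += u.count
            continue
        res = edlib.align(u.sequence, cent, mode="NW", task="path")
        qi = 0
        tj = 0
        for ln, op in _parse_cigar(res["cigar"]):
            if op in "=XM":
                idx = cols[tj : tj + ln]
                counts[idx, mem[qi : qi + ln]] += u.count
                covered[idx] += u.count
                qi += ln
                tj += ln
            elif op == "I":  # member has extra bases: no centroid column
                qi += ln
            elif op == "D":  # member gap over centroid columns
                tj += ln
    out = []
    for j in range(L):
        if covered[j] == 0:
            continue  # all members gapped here
        best = int(np.argmax(counts[j]))
        if counts[j, cent_codes[j]] == counts[j, best]:
            best = int(cent_codes[j])  # tie (or outright win) goes to centroid
        out.append("ACGT"[best])
    return "".join(out)


def _parse_cigar(cig: str):
    num = ""
    for ch in cig:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def select_individuals(
    read_counts: Mapping[str, int], selection: str | int | Sequence[str]
) -> list[str]:
    """Resolve an individual selection: 'best' (single most read-abundant
    individual), an integer N (top-N by read count), or explicit IDs."""
    if not read_counts:
        raise ConfigError("no read sets available for selection")
    ranked = sorted(read_counts, key=lambda i: (-read_counts[i], i))
    if selection == "best":
        return [ranked[0]]
    if isinstance(selection, int):
        if selection < 1:
            raise ConfigError("selection count must be >= 1")
        return ranked[:selection]
    sel = list(selection)
    if not sel:
        raise ConfigError("empty individual selection")
    missing = [s for s in sel if s not in read_counts]
    if missing:
        raise ConfigError(f"unknown individual(s) in selection: {missing}")
    return sel


def build_mock_reference(
    readsets: Mapping[str, Sequence[str]],
    selection: str | int | Sequence[str] = "best",
    identity_threshold: float = 0.93,
    min_count: int = 2,
) -> MockReference:
    """Dereplicate -> cluster -> consensus over the pooled reads of the
    selected individuals (default: the single most read-abundant one, the
    recommended practice for mock-reference assembly)."""
    chosen = select_individuals(
        {ind: len(reads) for ind, reads in readsets.items()}, selection
    )
    log.info("mock reference from %d individual(s): %s", len(chosen), ",".join(chosen))
    pooled: list[str] = []
    for ind in chosen:
        pooled.extend(readsets[ind])
    uniques = dereplicate(pooled)
    clusters = greedy_cluster(uniques, identity_threshold, min_count)
    records = [(c.centroid_id, consensus(c), c.size) for c in clusters]
    log.info(
        "mock reference: %d reads -> %d unique -> %d centroids",
        len(pooled), len(uniques), len(records),
    )
    return MockReference(records)


def write_cluster_table(clusters: Sequence[Cluster], path) -> None:
    """TSV: centroid_id, member sequence sha1, count, identity-to-centroid."""
    with open(path, "w") as out:
        out.write("centroid_id\tmember_sha1\tcount\tidentity\n")
        for c in clusters:
            for u, ident in c.members:
                h = hashlib.sha1(u.sequence.encode()).hexdigest()[:12]
                out.write(f"{c.centroid_id}\t{h}\t{u.count}\t{ident:.4f}\n")
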