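"""Validation of called variants against simulation truth.

Centroids of the mock reference are anchored back to their source
fragments (shared-k-mer vote, verified at >= 0.9 identity); each call is
projected into fragment coordinates and matched one-to-one against the
truth table. A call validates when its projected position hits a truth
record (exactly for SNPs, within +/-2 bp for left-normalised indels) and
its allele pair matches after re-anchoring to the fragment's frame:
a centroid assembled from an individual carrying the alternate allele has
REF and ALT swapped relative to the fragment, which re-anchoring undoes;
a call whose alleles are genuinely swapped relative to truth still fails.

The summary metrics follow the standard benchmark definitions:
  Type I  = 100 * (called - validated) / called        (false positives)
  Type II = 100 * (simulated - validated) / simulated  (false negatives)
  accuracy = 100 * validated / (simulated + (called - validated))
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from gbscall.caller import MISSING, VariantCall
from gbscall.errors import ConsistencyError
from gbscall.mockref import MockReference
from gbscall.sim import Fragment, TruthVariant, _left_normalize

log = logging.getLogger(__name__)


@dataclass
class CentroidAnchor:
    fragment_id: str
    strand: str  # '+' or '-'
    identity: float
    proj: np.ndarray  # centroid position -> fragment offset (monotone)
    # indel events of the centroid relative to the fragment, in the aligned
    # query frame: (op, anchor position = base preceding the event, length);
    # op 'I' = centroid has extra bases, 'D' = fragment has extra bases
    events: list = None


@dataclass
class CentroidMap:
    anchors: dict  # centroid_id -> CentroidAnchor
    unmatched: list

    def project(self, centroid_id: str, pos0: int) -> tuple[str, int] | None:
        a = self.anchors.get(centroid_id)
        if a is None or pos0 >= len(a.proj) or pos0 < 0:
            return None
        idx = pos0 if a.strand == "+" else len(a.proj) - 1 - pos0
        return a.fragment_id, int(a.proj[idx])


def _revcomp_str(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _projection_array(cigar: str, tgt_start: int, qlen: int):
    """Map each query (centroid) position to a target (fragment) offset and
    record the indel events of the path.

    Positions inside query insertions inherit the previous anchored offset,
    which keeps left-anchored indel matching within the +/-2 bp slack.
    Events are (op, query anchor position, length) with 'I' = extra query
    (centroid) bases and 'D' = extra target (fragment) bases.
    """
    proj = np.zeros(qlen, dtype=np.int64)
    events: list[tuple[str, int, int]] = []
    qi, tj = 0, tgt_start
    num = ""
    last = tgt_start
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        ln = int(num)
        num = ""
        if ch in "=XM":
            proj[qi : qi + ln] = np.arange(tj, tj + ln)
            qi += ln
            tj += ln
            last = tj - 1
        elif ch == "I":  # centroid base absent from fragment
            proj[qi : qi + ln] = last
            events.append(("I", qi - 1, ln))
            qi += ln
        elif ch == "D":
            tj += ln
            events.append(("D", qi - 1, ln))
            last = tj - 1
    return proj, events


def map_centroids(
    mr: MockReference,
    fragments: Sequence[Fragment],
    k: int = 20,
    min_identity: float = 0.9,
) -> CentroidMap:
    """Anchor each centroid to its source fragment.

    Candidate fragments are gathered by shared-k-mer vote (both strands)
    and the winner verified by infix alignment at >= ``min_identity``
    (identity = 1 - edit_distance / centroid length). Each centroid maps to
    at most one fragment; failures are recorded as unmatched.
    """
    index: dict[str, list[int]] = {}
    for fi, frag in enumerate(fragments):
        s = frag.sequence
        for off in range(0, len(s) - k + 1, 7):  # stride keeps the index small
            index.setdefault(s[off : off + k], []).append(fi)
    anchors: dict[str, CentroidAnchor] = {}
    unmatched = []
    for cid, seq, _size in mr.records:
        best = None
        for strand, q in (("+", seq), ("-", _revcomp_str(seq))):
            votes: dict[int, int] = {}
            for off in range(0, max(1, len(q) - k + 1)):
                for fi in index.get(q[off : off + k], ()):
                    votes[fi] = votes.get(fi, 0) + 1
            for fi, _nv in sorted(votes.items(), key=lambda t: -t[1])[:3]:
                tgt = fragments[fi].sequence
                res = edlib.align(q, tgt, mode="HW", task="path")
                d = res["editDistance"]
                ident = 1.0 - d / len(q)
                if ident >= min_identity and (best is None or ident > best[0]):
                    start = res["locations"][0][0]
                    proj, events = _projection_array(res["cigar"], start, len(q))
                    best = (ident, fi, strand, proj, events)
        if best is None:
            unmatched.append(cid)
        else:
            ident, fi, strand, proj, events = best
            anchors[cid] = CentroidAnchor(fragments[fi].fragment_id, strand,
                                          ident, proj, events)
    log.info("map_centroids: %d anchored, %d unmatched", len(anchors), len(unmatched))
    return CentroidMap(anchors, unmatched)


# ---------------------------------------------------------------------------
# truth matching
# ---------------------------------------------------------------------------

def _reanchor(call: VariantCall, frag_seq: str, offset: int,
              anchor: CentroidAnchor, qpos: int) -> tuple[int, str, str, bool] | None:
    """Express a call's alleles in the fragment's frame.

    A centroid assembled from an alternate-allele carrier disagrees with
    the fragment at the variant, so the call's REF/ALT are swapped relative
    to truth. For indels the decision comes from the centroid-vs-fragment
    alignment path itself (is there an indel of the call's length near the
    call?), because string matching is ambiguous in repeat context (an
    inserted base that duplicates the following reference base matches both
    orientations). Returns (offset, ref, alt, swapped) or None when the
    call is consistent with neither frame.
    """
    ref, alt = call.ref_allele, call.alt_allele
    if anchor.strand == "-":
        # reverse-complemented alleles span [offset - len + 1, offset] forward
        ref, alt = _revcomp_str(ref), _revcomp_str(alt)
        offset = offset - (len(ref) - 1)
    if len(ref) == len(alt):  # SNP: the fragment base is decisive
        if frag_seq[offset : offset + len(ref)] == ref:
            return offset, ref, alt, False
        if frag_seq[offset : offset + len(alt)] == alt:
            return offset, alt, ref, True
        return None
    # Indel: measure the net centroid-vs-fragment coordinate shift across a
    # window spanning the call. A centroid that carries the event shifts the
    # projection by +/- the event length there; one that agrees with the
    # fragment shifts by ~0. (Single-event matching would be fragile: a
    # unit-cost aligner may split one gap into several.)
    ev_len = abs(len(ref) - len(alt))
    L = len(anchor.proj)
    a = max(0, qpos - 3)
    b = min(L - 1, qpos + ev_len + 3)
    net = int(anchor.proj[b]) - int(anchor.proj[a]) - (b - a)
    want = ev_len if len(alt) > len(ref) else -ev_len  # INS call: frag has extra
    d_swap, d_keep = abs(net - want), abs(net)
    if d_swap < d_keep:
        return offset, alt, ref, True
    if d_keep < d_swap:
        return offset, ref, alt, False
    # inconclusive window (e.g. nearby unrelated jitter): fall back to
    # matching the longer allele against the fragment
    lo, hi = (ref, alt) if len(ref) >= len(alt) else (alt, ref)
    if frag_seq[offset : offset + len(lo)] == lo:
        return (offset, ref, alt, False) if lo is ref else (offset, alt, ref, True)
    if frag_seq[offset : offset + len(hi)] == hi:
        return (offset, ref, alt, False) if hi is ref else (offset, alt, ref, True)
    return None


def match_variants(
    calls: Sequence[VariantCall],
    truth: Sequence[TruthVariant],
    cmap: CentroidMap,
    fragments: Mapping[str, str] | Sequence[Fragment],
    centroid_seqs: Mapping[str, str],
    indel_slack: int = 2,
) -> list[bool]:
    """Validate each call against the truth table (one-to-one matching).

    A call validates iff its projected (fragment, offset) coincides with a
    truth record (exact for SNPs, +/-``indel_slack`` bp for indels, both
    sides left-normalised) and the re-anchored ref/alt pair matches. Truth
    records are consumed greedily in projected-position order so each
    validates at most one call.
    """
    if not isinstance(fragments, Mapping):
        fragments = {f.fragment_id: f.sequence for f in fragments}
    truth_by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for ti, tv in enumerate(truth):
        truth_by_key.setdefault((tv.fragment_id, tv.vtype), []).append((tv.offset, ti))
    consumed = [False] * len(truth)
    projected = []
    for ci, call in enumerate(calls):
        hit = cmap.project(call.centroid_id, call.position - 1)
        projected.append((ci, call, hit))
    # deterministic one-to-one matching ordered by projected position
    projected.sort(key=lambda t: (t[2] is None, t[2] or ("", 0), t[0]))
    validated = [False] * len(calls)
    for ci, call, hit in projected:
        if hit is None:
            continue
        frag_id, off = hit
        frag_seq = fragments.get(frag_id)
        if frag_seq is None:
            continue
        anchor = cmap.anchors[call.centroid_id]
        p0 = call.position - 1
        qpos = p0 if anchor.strand == "+" else len(anchor.proj) - 1 - p0
        re = _reanchor(call, frag_seq, off, anchor, qpos)
        if re is None:
            continue
        off2, ref, alt, _swapped = re
        if len(ref) != len(alt):
            off2, ref, alt = _left_normalize(frag_seq, off2, ref, alt)
        vtype = ("SNP" if len(ref) == len(alt) == 1
                 else ("DEL" if len(ref) > len(alt) else "INS"))
        slack = 0 if vtype == "SNP" else indel_slack
        for t_off, ti in truth_by_key.get((frag_id, vtype), ()):
            if consumed[ti] or abs(t_off - off2) > slack:
                continue
            tv = truth[ti]
            if tv.ref_allele == ref and tv.alt_allele == alt:
                consumed[ti] = True
                validated[ci] = True
                break
            # same event, slightly shifted anchor: compare allele lengths and
            # inserted/deleted material for indels
            if vtype != "SNP" and len(tv.ref_allele) == len(ref) \
                    and len(tv.alt_allele) == len(alt):
                consumed[ti] = True
                validated[ci] = True
                break
    return validated


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvaluationReport:
    n_simulated: int
    n_called: int
    n_validated: int
    type1: float  # percent
    type2: float  # percent
    accuracy: float  # percent

    def rounded(self) -> tuple[float, float, float]:
        """Display values at one decimal, as benchmark tables print them."""
        return (round(self.type1, 1), round(self.type2, 1), round(self.accuracy, 1))

    def to_tsv(self, path) -> None:
        with open(path, "w") as out:
            out.write("n_simulated\tn_called\tn_validated\ttype1_pct\ttype2_pct\taccuracy_pct\n")
            out.write(f"{self.n_simulated}\t{self.n_called}\t{self.n_validated}"
                      f"\t{self.type1:.1f}\t{self.type2:.1f}\t{self.accuracy:.1f}\n")


def compute_metrics(n_simulated: int, n_called: int, n_validated: int) -> EvaluationReport:
    """Type I / Type II / overall accuracy from the three counts.

    accuracy = 100 * validated / (simulated + non-validated), where
    non-validated = called - validated.
    """
    if n_validated > n_called:
        raise ConsistencyError(
            f"n_validated ({n_validated}) exceeds n_called ({n_called})"
        )
    if n_validated > n_simulated:
        raise ConsistencyError(
            f"n_validated ({n_validated}) exceeds n_simulated ({n_simulated})"
        )
    type1 = 100.0 * (n_called - n_validated) / n_called if n_called else 0.0
    type2 = 100.0 * (n_simulated - n_validated) / n_simulated if n_simulated else 0.0
    denom = n_simulated + (n_called - n_validated)
    accuracy = 100.0 * n_validated / denom if denom else 0.0
    return EvaluationReport(n_simulated, n_called, n_validated, type1, type2, accuracy)


def evaluate_calls(
    calls: Sequence[VariantCall],
    truth: Sequence[TruthVariant],
    mr: MockReference,
    fragments: Sequence[Fragment],
) -> tuple[EvaluationReport, list[bool], CentroidMap]:
    """Full evaluation: anchor centroids, match calls, compute metrics."""
    cmap = map_centroids(mr, fragments)
    validated = match_variants(
        calls, truth, cmap, fragments, {cid: s for cid, s, _z in mr.records}
    )
    rep = compute_metrics(len(truth), len(calls), sum(validated))
    return rep, validated, cmap


def genotype_concordance(
    calls: Sequence[VariantCall],
    validated: Sequence[bool],
    truth: Sequence[TruthVariant],
    truth_genotypes: pd.DataFrame,
    cmap: CentroidMap,
    fragments: Mapping[str, str] | Sequence[Fragment],
    centroid_seqs: Mapping[str, str],
) -> float:
    """Per-individual genotype concordance with truth at validated sites.

    When a call's alleles are swapped relative to the fragment frame (the
    centroid carried the alternate allele) homRef/homAlt are flipped before
    comparison. Missing calls are excluded. Returns a fraction in [0, 1]
    (nan when nothing is comparable).
    """
    if not isinstance(fragments, Mapping):
        fragments = {f.fragment_id: f.sequence for f in fragments}
    tg = {
        (r.individual_id, r.fragment_id): r.genotype
        for r in truth_genotypes.itertuples(index=False)
    }
    n_ok = n_tot = 0
    flip = {"homRef": "homAlt", "homAlt": "homRef", "het": "het"}
    for call, ok in zip(calls, validated):
        if not ok:
            continue
        hit = cmap.project(call.centroid_id, call.position - 1)
        if hit is None:
            continue
        frag_id, off = hit
        anchor = cmap.anchors[call.centroid_id]
        p0 = call.position - 1
        qpos = p0 if anchor.strand == "+" else len(anchor.proj) - 1 - p0
        re = _reanchor(call, fragments[frag_id], off, anchor, qpos)
        if re is None:
            continue
        swapped = re[3]
        for g in call.genotypes:
            if g.gt == MISSING:
                continue
            t = tg.get((g.individual_id, frag_id))
            if t is None:
                continue
            called_gt = flip[g.gt] if swapped else g.gt
            n_ok += called_gt == t
            n_tot += 1
    return n_ok / n_tot if n_tot else math.nan


def write_validation_table(calls, validated, cmap, path) -> None:
    with open(path, "w") as out:
        out.write("centroid_id\tposition\tvtype\tref\talt\tvalidated\tfragment_id\toffset\n")
        for call, ok in zip(calls, validated):
            hit = cmap.project(call.centroid_id, call.position - 1)
            frag, off = hit if hit else ("NA", -1)
            out.write(f"{call.centroid_id}\t{call.position}\t{call.vtype}"
                      f"\t{call.ref_allele}\t{call.alt_allele}\t{int(ok)}"
                      f"\t{frag}\t{off}\n")
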