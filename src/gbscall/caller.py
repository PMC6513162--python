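"""Bi-allelic SNP and indel calling from mock-reference pileups.

Calling combines within-individual depth criteria (minimum depth to
genotype, minimum minor-allele depth and fraction for a heterozygote,
maximum minor fraction for a homozygote — individuals between the two are
set missing, not forced) with across-population criteria (call rate,
minimum alternate-allele carriers, strict bi-allelism with a pooled noise
floor for third alleles). The genotype matrix, the VCF and the variant
description table carry the same content; VCF conversion is purely a
format change.

Threshold defaults are conservative for 20-30x GBS depth and are fully
configurable; they are not canonical values of any published pipeline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from gbscall.align import Pileup
from gbscall.errors import ConfigError, DataError
from gbscall.mockref import MockReference
from gbscall.sim import encode

log = logging.getLogger(__name__)

MISSING = "missing"
GT_ORDER = ("homRef", "het", "homAlt", MISSING)


@dataclass(frozen=True)
class CallerParams:
    min_depth_call: int = 6
    min_minor_depth_het: int = 3
    min_minor_frac_het: float = 0.20
    max_minor_frac_hom: float = 0.10
    min_call_rate: float = 0.75
    min_alt_carriers: int = 1
    # third-allele noise floor: max(noise_floor_reads, noise_floor_frac * pooled depth)
    noise_floor_reads: int = 2
    noise_floor_frac: float = 0.05

    def validate(self) -> None:
        for f in ("min_minor_frac_het", "max_minor_frac_hom", "min_call_rate",
                  "noise_floor_frac"):
            v = getattr(self, f)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{f} must be in [0, 1], got {v}")
        for f in ("min_depth_call", "min_minor_depth_het", "min_alt_carriers",
                  "noise_floor_reads"):
            if getattr(self, f) < 0:
                raise ConfigError(f"{f} must be >= 0")


@dataclass
class SiteGenotype:
    individual_id: str
    gt: str  # homRef | het | homAlt | missing
    ad_ref: int
    ad_alt: int
    dp: int


@dataclass
class VariantCall:
    centroid_id: str
    position: int  # 1-based anchor position on the centroid
    vtype: str  # SNP | INS | DEL
    ref_allele: str
    alt_allele: str
    genotypes: list[SiteGenotype]
    n_called: int
    n_het: int
    alt_frequency: float
    zscore: float = math.nan  # filled by depth_diagnostics

    @property
    def key(self) -> tuple[str, int]:
        return (self.centroid_id, self.position)


def genotype_individual(
    ad_ref: int,
    ad_alt: int,
    params: CallerParams,
    dp: int | None = None,
    individual_id: str = "",
) -> SiteGenotype:
    """Genotype one individual at a bi-allelic site from allele depths.

    With primary depth p = max(ad_ref, ad_alt) and secondary s = min:
    below ``min_depth_call`` total depth the call is missing; a het needs
    s >= min_minor_depth_het and s/(p+s) >= min_minor_frac_het; a
    homozygote (for the primary allele) needs s/(p+s) <= max_minor_frac_hom;
    anything in between is ambiguous and set missing.
    """
    if ad_ref < 0 or ad_alt < 0:
        raise DataError("negative allele depth")
    if dp is None:
        dp = ad_ref + ad_alt
    g = SiteGenotype(individual_id, MISSING, ad_ref, ad_alt, dp)
    if dp < params.min_depth_call:
        return g
    p, s = max(ad_ref, ad_alt), min(ad_ref, ad_alt)
    # the two site alleles must themselves carry the depth floor; depth made
    # of reads supporting neither allele (e.g. spanning deletions) does not
    # license a genotype
    if p + s < params.min_depth_call:
        return g
    frac = s / (p + s)
    if s >= params.min_minor_depth_het and frac >= params.min_minor_frac_het:
        g.gt = "het"
    elif frac <= params.max_minor_frac_hom:
        g.gt = "homAlt" if ad_alt > ad_ref else "homRef"
    return g


@dataclass
class _Column:
    """One pileup column handed to call_site (0-based position)."""

    centroid_id: str
    position: int
    ref_base: str
    individuals: list[str]
    base_counts: np.ndarray  # (n_ind, 4)
    del_span: np.ndarray  # (n_ind,)
    indel_alleles: dict = field(default_factory=dict)  # (ref, alt) -> (n_ind,) counts


def column_from_pileup(pile: Pileup, cid: str, pos: int) -> _Column:
    seq = pile.seqs[cid]
    ind = {
        (r, a): v for (p, r, a), v in pile.indels[cid].items() if p == pos
    }
    return _Column(
        cid, pos, seq[pos], pile.individuals,
        pile.base_counts[cid][:, pos, :].astype(np.int64),
        pile.del_span[cid][:, pos].astype(np.int64), ind,
    )


_BASES = "ACGT"


def call_site(col: _Column, params: CallerParams) -> VariantCall | None:
    """Call one column: pick the population-wide top alternate allele,
    enforce bi-allelism against the noise floor, genotype every individual
    and apply the across-population retention filters."""
    n_ind = len(col.individuals)
    ref_code = _BASES.index(col.ref_base)
    pooled_bases = col.base_counts.sum(axis=0)
    dp_ind = col.base_counts.sum(axis=1) + col.del_span
    pooled_depth = int(dp_ind.sum())
    if pooled_depth == 0:
        return None

    # candidate alternate alleles: non-reference bases and anchored indels
    alts: list[tuple[int, str, object]] = []  # (pooled count, kind, payload)
    for b in range(4):
        if b != ref_code and pooled_bases[b] > 0:
            alts.append((int(pooled_bases[b]), "SNP", b))
    for (ref_a, alt_a), vec in col.indel_alleles.items():
        tot = int(vec.sum())
        if tot > 0:
            alts.append((tot, "INDEL", (ref_a, alt_a, vec)))
    if not alts:
        return None  # monomorphic
    alts.sort(key=lambda t: (-t[0], t[1], str(t[2])))
    top_count, top_kind, top_payload = alts[0]

    noise_floor = max(params.noise_floor_reads, params.noise_floor_frac * pooled_depth)
    if len(alts) > 1 and alts[1][0] > noise_floor:
        return None  # multi-allelic above the noise floor
    # reads whose deletion (anchored elsewhere) spans this column support
    # neither site allele; treat them as conflicting-allele evidence
    if int(col.del_span.sum()) > noise_floor:
        return None

    if top_kind == "SNP":
        alt_code = top_payload
        vtype, ref_allele, alt_allele = "SNP", col.ref_base, _BASES[alt_code]
        ad_alt = col.base_counts[:, alt_code]
        ad_ref = col.base_counts[:, ref_code]
    else:
        ref_allele, alt_allele, vec = top_payload
        vtype = "DEL" if len(ref_allele) > len(alt_allele) else "INS"
        ad_alt = vec.astype(np.int64)
        # anchor-base reads minus those carrying the indel support the ref
        ad_ref = np.maximum(col.base_counts[:, ref_code] - ad_alt, 0)

    genotypes = [
        genotype_individual(int(ad_ref[i]), int(ad_alt[i]), params,
                            dp=int(dp_ind[i]), individual_id=col.individuals[i])
        for i in range(n_ind)
    ]
    called = [g for g in genotypes if g.gt != MISSING]
    n_called = len(called)
    if n_called == 0 or n_called / n_ind < params.min_call_rate:
        return None
    carriers = sum(1 for g in called if g.gt in ("het", "homAlt"))
    if carriers < params.min_alt_carriers:
        return None
    if int(ad_alt.sum()) < 1 or int(ad_ref.sum()) < 1:
        return None  # both alleles must be observed population-wide
    n_het = sum(1 for g in called if g.gt == "het")
    alt_alleles = sum(2 if g.gt == "homAlt" else (1 if g.gt == "het" else 0)
                      for g in called)
    return VariantCall(
        col.centroid_id, col.position + 1, vtype, ref_allele, alt_allele,
        genotypes, n_called, n_het, alt_alleles / (2 * n_called),
    )


def call_population(
    pileup: Pileup, params: CallerParams | None = None
) -> list[VariantCall]:
    """Apply :func:`call_site` across all columns of all centroids.

    A vectorised pooled screen skips columns that cannot possibly yield a
    call (no alternate allele reaches ``min_minor_depth_het`` pooled and no
    indel is anchored there); the per-column rules are unchanged.
    """
    params = params or CallerParams()
    params.validate()
    calls: list[VariantCall] = []
    for cid in pileup.centroid_ids:
        bc = pileup.base_counts[cid]
        if bc.size == 0:
            continue
        pooled = bc.sum(axis=0, dtype=np.int64)  # (L, 4)
        ref_codes = encode(pileup.seqs[cid])
        masked = pooled.copy()
        masked[np.arange(len(ref_codes)), ref_codes] = -1
        cand = set(np.nonzero(masked.max(axis=1) >= params.min_minor_depth_het)[0])
        cand.update(p for (p, _r, _a) in pileup.indels[cid])
        for pos in sorted(cand):
            vc = call_site(column_from_pileup(pileup, cid, int(pos)), params)
            if vc is not None:
                calls.append(vc)
    calls.sort(key=lambda v: (v.centroid_id, v.position))
    log.info("caller: %d variant(s) retained", len(calls))
    return calls


# ---------------------------------------------------------------------------
# output formats
# ---------------------------------------------------------------------------

_GT_FIELD = {"homRef": "0/0", "het": "0/1", "homAlt": "1/1", MISSING: "./."}


def genotype_matrix(calls: Sequence[VariantCall],
                    individuals: Sequence[str]) -> pd.DataFrame:
    """One variant per row; GT/AD/DP column triplet per individual."""
    cols: dict[str, list] = {
        "centroid_id": [], "position": [], "vtype": [], "ref": [], "alt": [],
        "zscore": [],
    }
    for ind in individuals:
        cols[f"{ind}.GT"] = []
        cols[f"{ind}.AD"] = []
        cols[f"{ind}.DP"] = []
    for v in calls:
        cols["centroid_id"].append(v.centroid_id)
        cols["position"].append(v.position)
        cols["vtype"].append(v.vtype)
        cols["ref"].append(v.ref_allele)
        cols["alt"].append(v.alt_allele)
        cols["zscore"].append(round(v.zscore, 4) if v.zscore == v.zscore else "NA")
        by_id = {g.individual_id: g for g in v.genotypes}
        for ind in individuals:
            g = by_id.get(ind)
            cols[f"{ind}.GT"].append(_GT_FIELD[g.gt] if g else "./.")
            cols[f"{ind}.AD"].append(f"{g.ad_ref},{g.ad_alt}" if g else "0,0")
            cols[f"{ind}.DP"].append(g.dp if g else 0)
    return pd.DataFrame(cols)


def write_matrix(calls, individuals, path) -> None:
    genotype_matrix(calls, individuals).to_csv(path, sep="\t", index=False)


def write_vcf(calls: Sequence[VariantCall], mr: MockReference, path,
              individuals: Sequence[str] | None = None) -> None:
    """Emit VCF 4.2 (CHROM = centroid id, 1-based POS, left-anchored indel
    alleles, FORMAT GT:AD:DP, INFO NS/AF/ZSCORE, contig headers from the
    mock reference)."""
    import pysam

    if individuals is None:
        inds: list[str] = []
        for v in calls:
            for g in v.genotypes:
                if g.individual_id not in inds:
                    inds.append(g.individual_id)
        individuals = inds
    header = pysam.VariantHeader()
    header.add_line('##source=gbscall')
    for cid, seq, _z in mr.records:
        header.contigs.add(cid, length=len(seq))
    header.info.add("NS", 1, "Integer", "Number of individuals with a genotype call")
    header.info.add("AF", "A", "Float", "Alternate allele frequency over called genotypes")
    header.info.add("ZSCORE", 1, "Float",
                    "Homolog Z-score: pooled heterozygote allele-depth deviation from 1:1")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allele depths (ref, alt)")
    header.formats.add("DP", 1, "Integer", "Total read depth")
    for ind in individuals:
        header.add_sample(ind)
    gt_codes = {"homRef": (0, 0), "het": (0, 1), "homAlt": (1, 1),
                MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in calls:
            rec = out.new_record(
                contig=v.centroid_id, start=v.position - 1,
                alleles=(v.ref_allele, v.alt_allele),
            )
            rec.info["NS"] = v.n_called
            rec.info["AF"] = (float(v.alt_frequency),)
            if v.zscore == v.zscore:
                rec.info["ZSCORE"] = float(v.zscore)
            by_id = {g.individual_id: g for g in v.genotypes}
            for ind in individuals:
                g = by_id.get(ind)
                s = rec.samples[ind]
                if g is None:
                    s["GT"] = (None, None)
                    s["AD"] = (0, 0)
                    s["DP"] = 0
                else:
                    s["GT"] = gt_codes[g.gt]
                    s["AD"] = (g.ad_ref, g.ad_alt)
                    s["DP"] = g.dp
            out.write(rec)


def read_vcf(path) -> tuple[list[VariantCall], list[str]]:
    """Read a gbscall VCF back into VariantCall objects."""
    import pysam

    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as f:
        individuals = list(f.header.samples)
        for rec in f:
            if len(rec.alts or ()) != 1:
                raise DataError(f"{path}: record at {rec.chrom}:{rec.pos} not bi-allelic")
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) == len(alt) == 1:
                vtype = "SNP"
            elif len(ref) > len(alt):
                vtype = "DEL"
            else:
                vtype = "INS"
            genotypes = []
            for ind in individuals:
                s = rec.samples[ind]
                gt = s.get("GT")
                ad = s.get("AD") or (0, 0)
                dp = s.get("DP") or 0
                if gt is None or gt[0] is None:
                    name = MISSING
                elif gt == (0, 0):
                    name = "homRef"
                elif gt == (1, 1):
                    name = "homAlt"
                else:
                    name = "het"
                genotypes.append(SiteGenotype(ind, name, int(ad[0]), int(ad[1] if len(ad) > 1 else 0), int(dp)))
            called = [g for g in genotypes if g.gt != MISSING]
            n_het = sum(1 for g in called if g.gt == "het")
            alt_alleles = sum(2 if g.gt == "homAlt" else (1 if g.gt == "het" else 0)
                              for g in called)
            z = float(rec.info["ZSCORE"]) if "ZSCORE" in rec.info else math.nan
            calls.append(VariantCall(
                rec.chrom, rec.pos, vtype, ref, alt, genotypes, len(called),
                n_het, alt_alleles / (2 * len(called)) if called else 0.0, z,
            ))
    return calls, individuals


def matrix_to_calls(path) -> tuple[list[VariantCall], list[str]]:
    """Parse a genotype matrix TSV back into VariantCall objects.

    The matrix mirrors the VCF content one-to-one, so matrix -> VCF is a
    pure format conversion.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    fixed = {"centroid_id", "position", "vtype", "ref", "alt", "zscore"}
    individuals: list[str] = []
    for c in df.columns:
        if c not in fixed and c.endswith(".GT"):
            individuals.append(c[:-3])
    rev_gt = {v: k for k, v in _GT_FIELD.items()}
    calls: list[VariantCall] = []
    for d in df.to_dict("records"):
        genotypes = []
        for ind in individuals:
            gt = rev_gt.get(d[f"{ind}.GT"], MISSING)
            ad = str(d[f"{ind}.AD"]).split(",")
            genotypes.append(SiteGenotype(
                ind, gt, int(ad[0]), int(ad[1]) if len(ad) > 1 else 0,
                int(d[f"{ind}.DP"]),
            ))
        called = [g for g in genotypes if g.gt != MISSING]
        n_het = sum(1 for g in called if g.gt == "het")
        alt_alleles = sum(2 if g.gt == "homAlt" else (1 if g.gt == "het" else 0)
                          for g in called)
        z = d.get("zscore", "NA")
        calls.append(VariantCall(
            d["centroid_id"], int(d["position"]), d["vtype"], d["ref"], d["alt"],
            genotypes, len(called), n_het,
            alt_alleles / (2 * len(called)) if called else 0.0,
            float(z) if z not in ("NA", None, "") else math.nan,
        ))
    return calls, individuals


def write_description(calls: Sequence[VariantCall], path) -> pd.DataFrame:
    """Comprehensive per-variant description table for downstream filtering."""
    rows = []
    for v in calls:
        called = [g for g in v.genotypes if g.gt != MISSING]
        hets = [g for g in called if g.gt == "het"]
        mean_dp = float(np.mean([g.dp for g in called])) if called else 0.0
        rows.append({
            "centroid_id": v.centroid_id,
            "position": v.position,
            "vtype": v.vtype,
            "ref": v.ref_allele,
            "alt": v.alt_allele,
            "n_called": v.n_called,
            "n_het": v.n_het,
            "alt_frequency": round(v.alt_frequency, 4),
            "mean_depth": round(mean_dp, 2),
            "het_ref_depth": sum(g.ad_ref for g in hets),
            "het_alt_depth": sum(g.ad_alt for g in hets),
            "zscore": round(v.zscore, 4) if v.zscore == v.zscore else "NA",
        })
    df = pd.DataFrame(rows, columns=[
        "centroid_id", "position", "vtype", "ref", "alt", "n_called", "n_het",
        "alt_frequency", "mean_depth", "het_ref_depth", "het_alt_depth", "zscore",
    ])
    df.to_csv(path, sep="\t", index=False)
    return df
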