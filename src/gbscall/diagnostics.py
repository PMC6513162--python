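"""Allele-depth diagnostics: homolog-variant Z-score filtering and ploidy
inference.

Homolog (paralog/duplicated-locus) variants arise when reads from two
related but non-allelic loci collapse onto one mock-reference centroid.
At such a site heterozygotes show a systematic departure of the
reference:alternate depth ratio from the 1:1 expected of a true diploid
het. Pooling ref and total depths over all heterozygous individuals, the
deviation is standardised against binomial(n, 0.5):

    z = (x - n/2) / sqrt(n/4)

where x is the pooled reference depth and n the pooled total. Variants
with |z| above a conservative threshold (default 5) are flagged as likely
homologs and culled. Sites with no heterozygotes carry no evidence either
way and are never culled.

Ploidy is inferred per individual from the distribution of alternate-
allele fractions at its heterozygous calls: fixed-mean Gaussian mixtures
at {1/2} (diploid), {1/3, 2/3} (triploid) and {1/4, 1/2, 3/4} (tetraploid)
with free weights and a shared variance are fit by EM, and the best model
is selected by BIC (the mean sets are nested, so raw likelihood alone
cannot prefer the simpler model; the full log-likelihood table is
reported).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from gbscall.caller import VariantCall
from gbscall.errors import DataError

log = logging.getLogger(__name__)


@dataclass
class HomologStat:
    centroid_id: str
    position: int
    n_het: int
    x: int  # pooled reference-allele depth over hets
    n: int  # pooled total (ref+alt) depth over hets
    ratio: float  # x/n, nan when not evaluable
    z: float  # nan when not evaluable
    evaluable: bool


def homolog_z(variant: VariantCall, method: str = "pooled") -> HomologStat:
    """Compute the homolog Z-score for one called variant.

    ``method='pooled'`` (default) sums ref and total depths over all
    heterozygous individuals and standardises against binomial(n, 1/2).
    ``method='mean'`` averages the per-heterozygote ref fraction and
    standardises the mean using the binomial variance of each ratio
    (1/(4*d_i)); both read the same 1:1 expectation.
    """
    hets = [g for g in variant.genotypes
            if g.gt == "het" and (g.ad_ref + g.ad_alt) > 0]
    for g in hets:
        if g.ad_ref < 0 or g.ad_alt < 0:
            raise DataError("negative allele depth in variant genotypes")
    x = sum(g.ad_ref for g in hets)
    n = sum(g.ad_ref + g.ad_alt for g in hets)
    if not hets or n == 0:
        return HomologStat(variant.centroid_id, variant.position, 0, 0, 0,
                           math.nan, math.nan, False)
    if method == "pooled":
        z = (x - n / 2) / math.sqrt(n / 4)
        ratio = x / n
    elif method == "mean":
        fracs = np.array([g.ad_ref / (g.ad_ref + g.ad_alt) for g in hets])
        depths = np.array([g.ad_ref + g.ad_alt for g in hets], dtype=float)
        ratio = float(fracs.mean())
        se = math.sqrt(float((1.0 / (4.0 * depths)).sum())) / len(hets)
        z = (ratio - 0.5) / se
    else:
        raise DataError(f"unknown homolog method {method!r}")
    return HomologStat(variant.centroid_id, variant.position, len(hets),
                       x, n, ratio, z, True)


def annotate_zscores(variants: Sequence[VariantCall],
                     method: str = "pooled") -> list[HomologStat]:
    """Fill each variant's ``zscore`` field in place; returns the stats."""
    stats_out = []
    for v in variants:
        st = homolog_z(v, method)
        v.zscore = st.z
        stats_out.append(st)
    return stats_out


def exact_binomial_flag(x: int, n: int, z_threshold: float = 5.0) -> bool:
    """Exact-binomial analogue of the |z| > threshold classification.

    Flags when the two-sided binomial(n, 1/2) tail probability of the
    pooled reference depth falls below the normal-tail probability
    equivalent to the Z threshold.
    """
    if n == 0:
        return False
    p_cut = 2.0 * stats.norm.sf(z_threshold)
    lo, hi = min(x, n - x), max(x, n - x)
    p = stats.binom.cdf(lo, n, 0.5) + stats.binom.sf(hi - 1, n, 0.5)
    return min(p, 1.0) < p_cut


def filter_homologs(
    variants: Sequence[VariantCall],
    z_threshold: float = 5.0,
    method: str = "pooled",
) -> tuple[list[VariantCall], list[VariantCall], list[HomologStat]]:
    """Split calls into (retained, culled) by |z| > z_threshold (strict).

    Variants with no heterozygous evidence are retained. The union of the
    two sets is the input, order preserved within each.
    """
    if z_threshold <= 0:
        raise DataError("z_threshold must be positive")
    stats_out = annotate_zscores(variants, method)
    retained, culled = [], []
    for v, st in zip(variants, stats_out):
        if st.evaluable and abs(st.z) > z_threshold:
            culled.append(v)
        else:
            retained.append(v)
    log.info("homolog filter: %d retained, %d culled (|Z| > %g)",
             len(retained), len(culled), z_threshold)
    return retained, culled, stats_out


def write_homolog_stats(stats_out: Sequence[HomologStat], culled_keys, path) -> None:
    with open(path, "w") as out:
        out.write("centroid_id\tposition\tn_het\tx\tn\tratio\tz\tculled\n")
        for st in stats_out:
            culled = int((st.centroid_id, st.position) in culled_keys)
            r = f"{st.ratio:.4f}" if st.ratio == st.ratio else "NA"
            z = f"{st.z:.4f}" if st.z == st.z else "NA"
            out.write(f"{st.centroid_id}\t{st.position}\t{st.n_het}\t{st.x}"
                      f"\t{st.n}\t{r}\t{z}\t{culled}\n")


# ---------------------------------------------------------------------------
# ploidy inference
# ---------------------------------------------------------------------------

PLOIDY_MEANS = {
    "diploid": (0.5,),
    "triploid": (1 / 3, 2 / 3),
    "tetraploid": (0.25, 0.5, 0.75),
}


@dataclass
class PloidyReport:
    individual_id: str
    n_het_sites: int
    ratios: np.ndarray
    histogram: np.ndarray  # 20 bins over [0, 1]
    log_likelihood: dict = field(default_factory=dict)
    bic: dict = field(default_factory=dict)
    best_model: str | None = None
    insufficient_data: bool = False


def allele_ratio_distribution(
    individual_id: str,
    variants: Sequence[VariantCall],
    min_depth: int = 10,
) -> np.ndarray:
    """Alt-fraction alt/(ref+alt) at this individual's het calls with
    dp >= min_depth."""
    out = []
    for v in variants:
        for g in v.genotypes:
            if (g.individual_id == individual_id and g.gt == "het"
                    and g.dp >= min_depth and (g.ad_ref + g.ad_alt) > 0):
                out.append(g.ad_alt / (g.ad_ref + g.ad_alt))
    return np.asarray(out, dtype=float)


def _em_fixed_means(ratios: np.ndarray, means: Sequence[float],
                    n_iter: int = 200, tol: float = 1e-8) -> tuple[float, int]:
    """EM for a Gaussian mixture with fixed means, free weights and one
    shared variance. Returns (log-likelihood, n free parameters)."""
    r = np.asarray(ratios, dtype=float)
    mu = np.asarray(means, dtype=float)
    k = len(mu)
    w = np.full(k, 1.0 / k)
    var = max(float(np.var(r - np.mean(mu))), 1e-4)
    var = min(max(var, 1e-4), 0.25)
    ll_old = -np.inf
    for _ in range(n_iter):
        d2 = (r[:, None] - mu[None, :]) ** 2
        logp = -0.5 * d2 / var - 0.5 * math.log(2 * math.pi * var)
        logw = np.log(np.maximum(w, 1e-300))
        joint = logp + logw[None, :]
        m = joint.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(joint - m).sum(axis=1))
        ll = float(lse.sum())
        gamma = np.exp(joint - lse[:, None])
        w = gamma.mean(axis=0)
        var = float((gamma * d2).sum() / max(gamma.sum(), 1e-12))
        var = min(max(var, 1e-6), 0.25)
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    return ll, k  # free params: (k-1) weights + 1 shared variance = k

def infer_ploidy(ratios: np.ndarray, individual_id: str = "",
                 min_sites: int = 30) -> PloidyReport:
    """Score the diploid/triploid/tetraploid allele-balance models.

    Requires at least ``min_sites`` ratios; otherwise an insufficient-data
    report is returned with no best_model.
    """
    r = np.asarray(ratios, dtype=float)
    r = r[(r > 0) & (r < 1)]
    hist, _edges = np.histogram(r, bins=20, range=(0.0, 1.0))
    rep = PloidyReport(individual_id, len(r), r, hist)
    if len(r) < min_sites:
        rep.insufficient_data = True
        return rep
    for name, means in PLOIDY_MEANS.items():
        ll, n_par = _em_fixed_means(r, means)
        rep.log_likelihood[name] = ll
        rep.bic[name] = n_par * math.log(len(r)) - 2.0 * ll
    rep.best_model = min(rep.bic, key=rep.bic.get)
    return rep


def ploidy_reports(
    variants: Sequence[VariantCall],
    individuals: Sequence[str],
    min_depth: int = 10,
) -> list[PloidyReport]:
    return [
        infer_ploidy(allele_ratio_distribution(ind, variants, min_depth), ind)
        for ind in individuals
    ]


def write_ploidy_report(reports: Sequence[PloidyReport], path) -> None:
    with open(path, "w") as out:
        out.write("individual_id\tn_het_sites\tbest_model\t"
                  "ll_diploid\tll_triploid\tll_tetraploid\t"
                  "bic_diploid\tbic_triploid\tbic_tetraploid\n")
        for r in reports:
            if r.insufficient_data:
                out.write(f"{r.individual_id}\t{r.n_het_sites}\tinsufficient_data"
                          "\tNA\tNA\tNA\tNA\tNA\tNA\n")
            else:
                ll = [f"{r.log_likelihood[m]:.3f}" for m in PLOIDY_MEANS]
                bic = [f"{r.bic[m]:.3f}" for m in PLOIDY_MEANS]
                out.write(f"{r.individual_id}\t{r.n_het_sites}\t{r.best_model}\t"
                          + "\t".join(ll) + "\t" + "\t".join(bic) + "\n")
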