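"""GBS read simulator with recorded truth.

Emulates a reduced-representation (GBS) experiment: a "genomic space" of
unique restriction fragments, at most one induced variant (SNP or short
indel) per fragment, Hardy-Weinberg genotypes for a small population, and
per-individual single-end (or paired-end) reads sampled uniformly at a
target depth with an independent per-base substitution error. Every induced
polymorphism and every assigned genotype is recorded so downstream calls can
be validated against truth.

Default parameters mirror a desk-scale version of the published benchmark
design: 150 bp single-end reads, 20-30x depth per fragment per individual,
1.1% per-base error, 25 individuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from gbscall.errors import ConfigError
from gbscall.seqio import SimRead, write_fasta

log = logging.getLogger(__name__)

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_LUT = np.frombuffer(BASES.encode(), dtype=np.uint8)
_DECODE = np.full(256, 255, dtype=np.uint8)
for _b, _i in _CODE.items():
    _DECODE[ord(_b)] = _i

HOM_REF, HET, HOM_ALT = "homRef", "het", "homAlt"
_GT_NAMES = (HOM_REF, HET, HOM_ALT)


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 code array (A=0 C=1 G=2 T=3)."""
    arr = _DECODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr > 3).any():
        raise ConfigError(f"non-ACGT character in sequence {seq[:40]!r}")
    return arr


def decode(codes: np.ndarray) -> str:
    """uint8 code array -> DNA string."""
    return _LUT[codes].tobytes().decode()


@dataclass(frozen=True)
class SimConfig:
    """Study design for one simulation run.

    ``depth_range`` is reads per fragment per individual (inclusive bounds);
    ``error_rate`` is the per-base substitution probability; ``maf_range``
    bounds the uniform minor-allele-frequency draw per variant.
    """

    n_fragments: int = 4_000
    fragment_length_range: tuple[int, int] = (240, 400)
    n_snps: int = 1_000
    n_indels: int = 400
    max_indel_len: int = 10
    n_individuals: int = 25
    depth_range: tuple[int, int] = (20, 30)
    error_rate: float = 0.011
    read_length: int = 150
    read_mode: str = "single"
    maf_range: tuple[float, float] = (0.1, 0.5)
    seed: int = 1

    # reads must cover a variant with flank on both sides
    edge_margin: int = 10

    def validate(self) -> None:
        if self.n_fragments < 1:
            raise ConfigError("n_fragments must be >= 1")
        if self.n_snps + self.n_indels > self.n_fragments:
            raise ConfigError(
                f"n_snps + n_indels ({self.n_snps + self.n_indels}) exceeds "
                f"n_fragments ({self.n_fragments}): at most one variant per fragment"
            )
        lo, hi = self.fragment_length_range
        if lo > hi or lo < self.read_length:
            raise ConfigError(
                "fragment_length_range invalid: min must be <= max and >= read_length"
            )
        if self.depth_range[0] < 1 or self.depth_range[0] > self.depth_range[1]:
            raise ConfigError("depth_range must satisfy 1 <= min <= max")
        if not (0.0 <= self.error_rate < 1.0):
            raise ConfigError("error_rate must be in [0, 1)")
        if self.read_mode not in ("single", "paired"):
            raise ConfigError("read_mode must be 'single' or 'paired'")
        if not (0.0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ConfigError("maf_range must lie in (0, 0.5]")
        if self.max_indel_len < 1:
            raise ConfigError("max_indel_len must be >= 1")
        if self.n_individuals < 1:
            raise ConfigError("n_individuals must be >= 1")


@dataclass(frozen=True)
class Fragment:
    fragment_id: str
    sequence: str


@dataclass(frozen=True)
class TruthVariant:
    """One induced polymorphism, VCF-style left-anchored for indels."""

    fragment_id: str
    offset: int  # 0-based on the fragment; anchor base for indels
    vtype: str  # SNP | INS | DEL
    ref_allele: str
    alt_allele: str
    maf: float


@dataclass
class ReadBatch:
    """One individual's reads as a dense code matrix (rows = reads)."""

    individual_id: str
    codes: np.ndarray  # (n_reads, read_length) uint8
    read_ids: list[str]
    fragment_ids: list[str]

    def __len__(self) -> int:
        return self.codes.shape[0]

    def to_simreads(self, qual_char: str = "I") -> list[SimRead]:
        qual = qual_char * self.codes.shape[1]
        return [
            SimRead(rid, self.individual_id, fid, "none", decode(row), qual)
            for rid, fid, row in zip(self.read_ids, self.fragment_ids, self.codes)
        ]


# ---------------------------------------------------------------------------
# stage 1: fragment space
# ---------------------------------------------------------------------------

def make_fragments(config: SimConfig, rng: np.random.Generator) -> list[Fragment]:
    """Simulate ``n_fragments`` pairwise-distinct uniform-random fragments."""
    config.validate()
    lo, hi = config.fragment_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_fragments)
    width = max(6, len(str(config.n_fragments)))
    seen: set[bytes] = set()
    frags: list[Fragment] = []
    for i, L in enumerate(lengths):
        codes = rng.integers(0, 4, size=int(L)).astype(np.uint8)
        key = codes.tobytes()
        # uniform >=240-mers collide with negligible probability; regenerate if so
        while key in seen:
            codes = rng.integers(0, 4, size=int(L)).astype(np.uint8)
            key = codes.tobytes()
        seen.add(key)
        frags.append(Fragment(f"frag{i:0{width}d}", decode(codes)))
    return frags


# ---------------------------------------------------------------------------
# stage 2: variant induction
# ---------------------------------------------------------------------------

def _left_normalize(frag: str, pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Shift an indel to its leftmost VCF representation on ``frag``."""
    ref, alt = list(ref), list(alt)
    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref.pop()
            alt.pop()
            continue
        if (len(ref) == 1 or len(alt) == 1) and ref[-1] == alt[-1] and pos > 0:
            pos -= 1
            prev = frag[pos]
            ref.pop()
            alt.pop()
            ref.insert(0, prev)
            alt.insert(0, prev)
            # re-grow: the trimmed tail base is the shared anchor moving left;
            # rebuild full alleles
            continue
        break
    return pos, "".join(ref), "".join(alt)


def induce_variants(
    fragments: Sequence[Fragment],
    n_snps: int,
    n_indels: int,
    max_indel_len: int,
    rng: np.random.Generator,
    *,
    maf_range: tuple[float, float] = (0.1, 0.5),
    read_length: int = 150,
    margin: int = 10,
) -> list[TruthVariant]:
    """Induce ``n_snps`` SNPs and ``n_indels`` bi-allelic indels, at most one
    per fragment, placed so a read-length prefix covers them with flank.

    Indels are emitted in left-anchored VCF convention (first base shared);
    positions are resampled if left-normalisation would push an indel out of
    the allowed window.
    """
    if n_snps + n_indels > len(fragments):
        raise ConfigError(
            f"{n_snps}+{n_indels} variants requested for {len(fragments)} fragments"
        )
    chosen = rng.choice(len(fragments), size=n_snps + n_indels, replace=False)
    mafs = rng.uniform(maf_range[0], maf_range[1], size=n_snps + n_indels)
    variants: list[TruthVariant] = []
    for k, fi in enumerate(chosen):
        frag = fragments[int(fi)].sequence
        maf = float(mafs[k])
        if k < n_snps:
            off = int(rng.integers(margin, read_length - margin + 1))
            ref = frag[off]
            alt = BASES[(_CODE[ref] + int(rng.integers(1, 4))) % 4]
            variants.append(
                TruthVariant(fragments[int(fi)].fragment_id, off, "SNP", ref, alt, maf)
            )
        else:
            for _attempt in range(100):
                ilen = int(rng.integers(1, max_indel_len + 1))
                is_del = bool(rng.integers(0, 2))
                hi_anchor = read_length - margin - (ilen + 1)
                off = int(rng.integers(margin, max(margin + 1, hi_anchor)))
                if is_del:
                    ref = frag[off : off + ilen + 1]
                    alt = frag[off]
                else:
                    ins = decode(rng.integers(0, 4, size=ilen).astype(np.uint8))
                    ref = frag[off]
                    alt = frag[off] + ins
                npos, nref, nalt = _left_normalize(frag, off, ref, alt)
                if npos >= margin and npos + len(nref) <= read_length - margin:
                    variants.append(
                        TruthVariant(
                            fragments[int(fi)].fragment_id,
                            npos,
                            "DEL" if is_del else "INS",
                            nref,
                            nalt,
                            maf,
                        )
                    )
                    break
            else:  # pragma: no cover - would need pathological fragment
                raise ConfigError("could not place indel within read window")
    return variants


# ---------------------------------------------------------------------------
# stage 3: population genotypes
# ---------------------------------------------------------------------------

def individual_ids(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"ind{i:0{width}d}" for i in range(1, n + 1)]


def sample_population_genotypes(
    truth: Sequence[TruthVariant],
    n_individuals: int,
    maf_range: tuple[float, float],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Assign Hardy-Weinberg genotypes per variant and individual.

    Genotype frequencies are (1-p)^2 / 2p(1-p) / p^2 for homRef/het/homAlt
    with p the variant's minor-allele frequency (drawn uniform over
    ``maf_range`` if the variant carries none). A variant left with zero
    alt carriers is resampled so every truth record is discoverable.

    Returns a table with columns individual_id, fragment_id, genotype.
    """
    if n_individuals < 1:
        raise ConfigError("n_individuals must be >= 1")
    inds = individual_ids(n_individuals)
    rows_ind: list[str] = []
    rows_frag: list[str] = []
    rows_gt: list[str] = []
    for v in truth:
        p = v.maf if v.maf == v.maf and v.maf > 0 else float(rng.uniform(*maf_range))
        thr_alt, thr_het = p * p, p * p + 2 * p * (1 - p)
        while True:
            u = rng.random(n_individuals)
            gt = np.where(u < thr_alt, 2, np.where(u < thr_het, 1, 0))
            if (gt > 0).any():
                break
        rows_ind.extend(inds)
        rows_frag.extend([v.fragment_id] * n_individuals)
        rows_gt.extend(_GT_NAMES[g] for g in gt)
    return pd.DataFrame(
        {"individual_id": rows_ind, "fragment_id": rows_frag, "genotype": rows_gt}
    )


# ---------------------------------------------------------------------------
# stage 4: reads
# ---------------------------------------------------------------------------

def apply_variant(frag_codes: np.ndarray, v: TruthVariant) -> np.ndarray:
    """Return the alternate haplotype of a fragment."""
    o = v.offset
    if v.vtype == "SNP":
        hap = frag_codes.copy()
        hap[o] = _CODE[v.alt_allele]
        return hap
    if v.vtype == "INS":
        ins = encode(v.alt_allele[len(v.ref_allele):])
        return np.concatenate([frag_codes[: o + len(v.ref_allele)], ins,
                               frag_codes[o + len(v.ref_allele):]])
    if v.vtype == "DEL":
        dlen = len(v.ref_allele) - len(v.alt_allele)
        return np.concatenate([frag_codes[: o + 1], frag_codes[o + 1 + dlen:]])
    raise ConfigError(f"unknown vtype {v.vtype}")


def _revcomp(codes: np.ndarray) -> np.ndarray:
    return (3 - codes[::-1]).astype(np.uint8)


def generate_reads_for_individual(
    individual_id: str,
    gt_codes: dict[str, int],
    fragments: Sequence[Fragment],
    variants_by_frag: dict[str, TruthVariant],
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[ReadBatch, ReadBatch | None]:
    """Sample reads for one individual.

    Per fragment, depth ~ uniform integer over ``depth_range``; each read
    comes from one of the two haplotypes (het: coin flip per read); single
    mode takes the first ``read_length`` bases, paired mode additionally
    emits R2 as the reverse complement of the last ``read_length`` bases.
    Substitution errors are injected independently per base, changing to a
    uniformly chosen different base.
    """
    L = config.read_length
    rows: list[np.ndarray] = []
    rows2: list[np.ndarray] = []
    read_ids: list[str] = []
    frag_ids: list[str] = []
    paired = config.read_mode == "paired"
    for frag in fragments:
        fc = encode(frag.sequence)
        v = variants_by_frag.get(frag.fragment_id)
        gt = gt_codes.get(frag.fragment_id, 0) if v is not None else 0
        d = int(rng.integers(config.depth_range[0], config.depth_range[1] + 1))
        haps = [fc]
        if v is not None and gt > 0:
            alt_hap = apply_variant(fc, v)
            haps = [alt_hap] if gt == 2 else [fc, alt_hap]
        if gt == 1:
            pick = (rng.random(d) < 0.5).astype(np.int8)  # 1 -> alt haplotype
        else:
            pick = np.zeros(d, dtype=np.int8)
        skipped = 0
        for s in range(d):
            hap = haps[pick[s]] if len(haps) == 2 else haps[0]
            if len(hap) < L:
                skipped += 1
                continue
            rows.append(hap[:L])
            if paired:
                rows2.append(_revcomp(hap[-L:]))
            read_ids.append(f"{individual_id}:{frag.fragment_id}:{s}")
            frag_ids.append(frag.fragment_id)
        if skipped:
            log.warning(
                "%s/%s: haplotype shorter than read length; %d read(s) skipped",
                individual_id, frag.fragment_id, skipped,
            )
    mat = np.vstack(rows) if rows else np.empty((0, L), dtype=np.uint8)
    if config.error_rate > 0 and mat.size:
        mask = rng.random(mat.shape) < config.error_rate
        shift = rng.integers(1, 4, size=mat.shape).astype(np.uint8)
        mat = np.where(mask, (mat + shift) % 4, mat).astype(np.uint8)
    r1 = ReadBatch(individual_id, mat, read_ids, frag_ids)
    r2 = None
    if paired:
        mat2 = np.vstack(rows2) if rows2 else np.empty((0, L), dtype=np.uint8)
        if config.error_rate > 0 and mat2.size:
            mask = rng.random(mat2.shape) < config.error_rate
            shift = rng.integers(1, 4, size=mat2.shape).astype(np.uint8)
            mat2 = np.where(mask, (mat2 + shift) % 4, mat2).astype(np.uint8)
        r2 = ReadBatch(
            individual_id, mat2,
            [i + "/2" for i in read_ids], list(frag_ids),
        )
        r1 = ReadBatch(individual_id, mat, [i + "/1" for i in read_ids], frag_ids)
    return r1, r2


def _stage_rngs(seed: int, n_individuals: int):
    """Fan a single seed out to independent per-stage streams.

    Stream order: fragments, variants, genotypes, then one stream per
    individual's reads (so per-individual read generation is independently
    re-runnable).
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(3 + n_individuals)
    rngs = [np.random.Generator(np.random.PCG64(c)) for c in children]
    return rngs[0], rngs[1], rngs[2], rngs[3:]


@dataclass
class SimResult:
    config: SimConfig
    fragments: list[Fragment]
    variants: list[TruthVariant]
    genotypes: pd.DataFrame
    read_counts: dict[str, int] = field(default_factory=dict)
    out_dir: Path | None = None
    batches: dict[str, ReadBatch] | None = None  # populated when kept in memory

    @property
    def total_reads(self) -> int:
        return sum(self.read_counts.values())


def _write_batch_fastq(batch: ReadBatch, path: Path, read_length: int) -> None:
    qual = b"I" * read_length
    with open(path, "wb") as out:
        for rid, row in zip(batch.read_ids, batch.codes):
            out.write(b"@" + rid.encode() + b"\n" + _LUT[row].tobytes()
                      + b"\n+\n" + qual + b"\n")


def simulate(config: SimConfig, out_dir=None, keep_in_memory: bool | None = None) -> SimResult:
    """Run the full simulation.

    With ``out_dir`` set, writes fragments.fasta, truth_variants.tsv,
    truth_genotypes.tsv, per-individual FASTQ files and manifest.tsv.
    ``keep_in_memory`` (default: True when out_dir is None) retains the read
    batches on the result object.
    """
    config.validate()
    if keep_in_memory is None:
        keep_in_memory = out_dir is None
    rng_frag, rng_var, rng_gt, rng_reads = _stage_rngs(config.seed, config.n_individuals)
    fragments = make_fragments(config, rng_frag)
    variants = induce_variants(
        fragments, config.n_snps, config.n_indels, config.max_indel_len, rng_var,
        maf_range=config.maf_range, read_length=config.read_length,
        margin=config.edge_margin,
    )
    genotypes = sample_population_genotypes(
        variants, config.n_individuals, config.maf_range, rng_gt
    )
    variants_by_frag = {v.fragment_id: v for v in variants}
    gt_code = {HOM_REF: 0, HET: 1, HOM_ALT: 2}
    gt_by_ind: dict[str, dict[str, int]] = {}
    for ind, frag, g in genotypes.itertuples(index=False):
        gt_by_ind.setdefault(ind, {})[frag] = gt_code[g]

    result = SimResult(config, fragments, variants, genotypes)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(((f.fragment_id, f.sequence) for f in fragments),
                    out_dir / "fragments.fasta")
        pd.DataFrame(
            [
                (v.fragment_id, v.offset, v.vtype, v.ref_allele, v.alt_allele,
                 round(v.maf, 6))
                for v in variants
            ],
            columns=["fragment_id", "offset", "vtype", "ref", "alt", "maf"],
        ).to_csv(out_dir / "truth_variants.tsv", sep="\t", index=False)
        genotypes.to_csv(out_dir / "truth_genotypes.tsv", sep="\t", index=False)
        result.out_dir = out_dir
    if keep_in_memory:
        result.batches = {}

    for ind, rng in zip(individual_ids(config.n_individuals), rng_reads):
        r1, r2 = generate_reads_for_individual(
            ind, gt_by_ind.get(ind, {}), fragments, variants_by_frag, config, rng
        )
        result.read_counts[ind] = len(r1) * (2 if r2 is not None else 1)
        if out_dir is not None:
            _write_batch_fastq(r1, out_dir / f"{ind}.R1.fastq", config.read_length)
            if r2 is not None:
                _write_batch_fastq(r2, out_dir / f"{ind}.R2.fastq", config.read_length)
        if keep_in_memory:
            result.batches[ind] = r1
        log.info("%s: %d reads simulated", ind, result.read_counts[ind])

    if out_dir is not None:
        with open(out_dir / "manifest.tsv", "w") as out:
            out.write("# simulation manifest\n")
            for k, v in vars(config).items():
                out.write(f"# config.{k} = {v}\n")
            out.write("individual_id\tn_reads\n")
            for ind, n in result.read_counts.items():
                out.write(f"{ind}\t{n}\n")
    return result


def load_truth(truth_dir) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read truth_variants.tsv and truth_genotypes.tsv back."""
    truth_dir = Path(truth_dir)
    tv = pd.read_csv(truth_dir / "truth_variants.tsv", sep="\t")
    tg = pd.read_csv(truth_dir / "truth_genotypes.tsv", sep="\t")
    return tv, tg
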