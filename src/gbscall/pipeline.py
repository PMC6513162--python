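"""End-to-end orchestration: simulate -> mock reference -> align -> call ->
homolog filter -> ploidy -> evaluate, with every stage's artifacts on disk
and single-seed reproducibility (per-stage streams are derived from the one
seed; re-running a config reproduces all outputs byte-identically).
"""

from __future__ import annotations

import configparser
import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from gbscall import caller as caller_mod
from gbscall import diagnostics as diag_mod
from gbscall.align import Pileup, SamWriter, align_batch, build_index
from gbscall.caller import CallerParams
from gbscall.errors import ConfigError
from gbscall.evaluate import (
    EvaluationReport,
    evaluate_calls,
    genotype_concordance,
    write_validation_table,
)
from gbscall.mockref import build_mock_reference
from gbscall.sim import (
    ReadBatch,
    SimConfig,
    _DECODE,
    individual_ids,
    simulate,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters for a full pipeline run, round-trippable through INI."""

    sim: SimConfig = field(default_factory=SimConfig)
    mr_selection: str = "best"  # 'best' | 'N' | comma-separated ids
    mr_identity: float = 0.93
    mr_min_count: int = 2
    aln_k: int = 20
    aln_band: int = 12
    aln_max_mismatch_frac: float = 0.1
    write_sam: bool = False
    caller: CallerParams = field(default_factory=CallerParams)
    z_threshold: float = 5.0
    homolog_method: str = "pooled"
    ploidy_min_depth: int = 10
    out_dir: str = "gbscall_run"
    log_level: str = "INFO"

    # ------------------------------------------------------------------
    def to_file(self, path) -> None:
        cp = configparser.ConfigParser()
        cp["simulate"] = {
            k: _fmt(v) for k, v in dataclasses.asdict(self.sim).items()
        }
        cp["mockref"] = {
            "selection": self.mr_selection,
            "identity": _fmt(self.mr_identity),
            "min_count": _fmt(self.mr_min_count),
        }
        cp["align"] = {
            "k": _fmt(self.aln_k),
            "band": _fmt(self.aln_band),
            "max_mismatch_frac": _fmt(self.aln_max_mismatch_frac),
            "write_sam": _fmt(self.write_sam),
        }
        cp["call"] = {k: _fmt(v) for k, v in dataclasses.asdict(self.caller).items()}
        cp["filter"] = {
            "z_threshold": _fmt(self.z_threshold),
            "method": self.homolog_method,
        }
        cp["ploidy"] = {"min_depth": _fmt(self.ploidy_min_depth)}
        cp["run"] = {"out_dir": self.out_dir, "log_level": self.log_level}
        with open(path, "w") as out:
            cp.write(out)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        cp = configparser.ConfigParser()
        if not Path(path).exists():
            raise ConfigError(f"config file not found: {path}")
        cp.read(path)
        cfg = cls()
        known = {
            "simulate": dataclasses.asdict(cfg.sim),
            "mockref": {"selection": 0, "identity": 0, "min_count": 0},
            "align": {"k": 0, "band": 0, "max_mismatch_frac": 0, "write_sam": 0},
            "call": dataclasses.asdict(cfg.caller),
            "filter": {"z_threshold": 0, "method": 0},
            "ploidy": {"min_depth": 0},
            "run": {"out_dir": 0, "log_level": 0},
        }
        for sec in cp.sections():
            if sec not in known:
                raise ConfigError(f"unknown config section [{sec}]")
            for key in cp[sec]:
                if key not in known[sec]:
                    raise ConfigError(f"unknown config key [{sec}] {key}")
        sim_kwargs = {}
        for k, v in cp["simulate"].items() if "simulate" in cp else []:
            default = getattr(cfg.sim, k)
            sim_kwargs[k] = _parse(v, default)
        if sim_kwargs:
            cfg.sim = SimConfig(**{**dataclasses.asdict(cfg.sim), **sim_kwargs})
        if "mockref" in cp:
            s = cp["mockref"]
            cfg.mr_selection = s.get("selection", cfg.mr_selection)
            cfg.mr_identity = s.getfloat("identity", cfg.mr_identity)
            cfg.mr_min_count = s.getint("min_count", cfg.mr_min_count)
        if "align" in cp:
            s = cp["align"]
            cfg.aln_k = s.getint("k", cfg.aln_k)
            cfg.aln_band = s.getint("band", cfg.aln_band)
            cfg.aln_max_mismatch_frac = s.getfloat(
                "max_mismatch_frac", cfg.aln_max_mismatch_frac)
            cfg.write_sam = s.getboolean("write_sam", cfg.write_sam)
        if "call" in cp:
            kwargs = {}
            for k, v in cp["call"].items():
                kwargs[k] = _parse(v, getattr(cfg.caller, k))
            cfg.caller = CallerParams(**kwargs)
        if "filter" in cp:
            cfg.z_threshold = cp["filter"].getfloat("z_threshold", cfg.z_threshold)
            cfg.homolog_method = cp["filter"].get("method", cfg.homolog_method)
        if "ploidy" in cp:
            cfg.ploidy_min_depth = cp["ploidy"].getint("min_depth", cfg.ploidy_min_depth)
        if "run" in cp:
            cfg.out_dir = cp["run"].get("out_dir", cfg.out_dir)
            cfg.log_level = cp["run"].get("log_level", cfg.log_level)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "sim": dataclasses.asdict(self.sim),
                "mockref": [self.mr_selection, self.mr_identity, self.mr_min_count],
                "align": [self.aln_k, self.aln_band, self.aln_max_mismatch_frac],
                "call": dataclasses.asdict(self.caller),
                "filter": [self.z_threshold, self.homolog_method],
                "ploidy": self.ploidy_min_depth,
            },
            sort_keys=True,
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _fmt(v) -> str:
    if isinstance(v, (tuple, list)):
        return ",".join(str(x) for x in v)
    return str(v)


def _parse(text: str, default):
    if isinstance(default, bool):
        return text.strip().lower() in ("1", "true", "yes", "on")
    if isinstance(default, int):
        return int(text)
    if isinstance(default, float):
        return float(text)
    if isinstance(default, tuple):
        parts = [p for p in text.split(",") if p.strip()]
        elem = default[0] if default else 0
        conv = int if isinstance(elem, int) else float
        return tuple(conv(p) for p in parts)
    return text


# ---------------------------------------------------------------------------

def load_batch(fastq_path, individual_id: str, read_length: int) -> ReadBatch:
    """Read one individual's FASTQ into a dense code matrix."""
    import pysam

    seqs: list[str] = []
    ids: list[str] = []
    frags: list[str] = []
    with pysam.FastxFile(str(fastq_path)) as fh:
        for rec in fh:
            seqs.append(rec.sequence)
            ids.append(rec.name)
            parts = rec.name.split(":")
            frags.append(parts[1] if len(parts) == 3 else "")
    if not seqs:
        return ReadBatch(individual_id,
                         np.empty((0, read_length), dtype=np.uint8), [], [])
    raw = "".join(seqs).encode()
    mat = _DECODE[np.frombuffer(raw, dtype=np.uint8)].reshape(len(seqs), read_length)
    return ReadBatch(individual_id, mat, ids, frags)


@dataclass
class PipelineResult:
    out_dir: Path
    report: EvaluationReport
    n_centroids: int
    n_calls: int
    n_retained: int
    n_culled: int
    concordance: float
    ploidy_best: dict
    timings: dict


def run_pipeline(config: RunConfig, out_dir=None) -> PipelineResult:
    """Execute the whole pipeline; see module docstring for stage order."""
    out_dir = Path(out_dir if out_dir is not None else config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    t0 = time.time()

    # stage 1: simulation (truth + reads on disk)
    sim_dir = out_dir / "sim"
    sim = simulate(config.sim, out_dir=sim_dir, keep_in_memory=False)
    inds = individual_ids(config.sim.n_individuals)
    timings["simulate"] = time.time() - t0

    # stage 2: mock reference from the selected individual(s)
    t = time.time()
    sel: object = config.mr_selection
    if isinstance(sel, str) and sel != "best":
        sel = int(sel) if sel.isdigit() else [s for s in sel.split(",") if s]
    ranked = sorted(inds, key=lambda i: (-sim.read_counts[i], i))
    if sel == "best":
        chosen = [ranked[0]]
    elif isinstance(sel, int):
        chosen = ranked[:sel]
    else:
        chosen = list(sel)
    readsets = {}
    batches: dict[str, ReadBatch] = {}
    for ind in chosen:
        b = load_batch(sim_dir / f"{ind}.R1.fastq", ind, config.sim.read_length)
        batches[ind] = b
        readsets[ind] = list(_decode_rows(b.codes))
    mr = build_mock_reference(
        readsets, selection=chosen, identity_threshold=config.mr_identity,
        min_count=config.mr_min_count,
    )
    mr.write(out_dir / "mockref.fasta")
    del readsets
    timings["mockref"] = time.time() - t

    # stage 3: alignment + pileup (per-individual, independently runnable)
    t = time.time()
    index = build_index(mr, config.aln_k)
    pile = Pileup(mr, inds)
    sam = SamWriter(out_dir / "alignments.sam", mr, inds) if config.write_sam else None
    aln_stats = []
    for ind in inds:
        b = batches.pop(ind, None)
        if b is None:
            b = load_batch(sim_dir / f"{ind}.R1.fastq", ind, config.sim.read_length)
        aln_stats.append(
            align_batch(b, index, pile, config.aln_max_mismatch_frac,
                        config.aln_band, sam_writer=sam)
        )
    if sam is not None:
        sam.close()
    timings["align"] = time.time() - t

    # stage 4: calling
    t = time.time()
    calls = caller_mod.call_population(pile, config.caller)
    timings["call"] = time.time() - t

    # stage 5: homolog filter + ploidy
    t = time.time()
    retained, culled, hstats = diag_mod.filter_homologs(
        calls, config.z_threshold, config.homolog_method
    )
    caller_mod.write_vcf(calls, mr, out_dir / "variants.vcf", inds)
    caller_mod.write_matrix(calls, inds, out_dir / "genotype_matrix.tsv")
    caller_mod.write_description(calls, out_dir / "variant_description.tsv")
    caller_mod.write_vcf(retained, mr, out_dir / "variants.retained.vcf", inds)
    caller_mod.write_vcf(culled, mr, out_dir / "variants.culled.vcf", inds)
    diag_mod.write_homolog_stats(
        hstats, {(v.centroid_id, v.position) for v in culled},
        out_dir / "homolog_stats.tsv",
    )
    preports = diag_mod.ploidy_reports(retained, inds, config.ploidy_min_depth)
    diag_mod.write_ploidy_report(preports, out_dir / "ploidy_report.tsv")
    timings["diagnostics"] = time.time() - t

    # stage 6: evaluation against truth
    t = time.time()
    report, validated, cmap = evaluate_calls(
        retained, sim.variants, mr, sim.fragments
    )
    report.to_tsv(out_dir / "evaluation_report.tsv")
    write_validation_table(retained, validated, cmap, out_dir / "validation.tsv")
    conc = genotype_concordance(
        retained, validated, sim.variants, sim.genotypes, cmap,
        sim.fragments, mr.sequences(),
    )
    timings["evaluate"] = time.time() - t

    with open(out_dir / "run_manifest.txt", "w") as out:
        import gbscall

        out.write(f"gbscall_version\t{gbscall.__version__}\n")
        out.write(f"config_hash\t{config.config_hash()}\n")
        out.write(f"seed\t{config.sim.seed}\n")
        out.write(f"total_reads\t{sim.total_reads}\n")
        out.write(f"n_centroids\t{len(mr)}\n")
        out.write(f"n_calls\t{len(calls)}\n")
        out.write(f"n_retained\t{len(retained)}\n")
        for st in aln_stats:
            out.write(f"mapped\t{st['individual']}\t{st['mapped']}\t{st['unmapped']}\n")
        for k, v in timings.items():
            out.write(f"time_{k}_s\t{v:.1f}\n")
    config.to_file(out_dir / "config.ini")

    ploidy_best = {r.individual_id: (r.best_model or "insufficient_data")
                   for r in preports}
    log.info(
        "pipeline: %d centroids, %d calls (%d retained), accuracy %.1f%%",
        len(mr), len(calls), len(retained), report.accuracy,
    )
    return PipelineResult(
        out_dir, report, len(mr), len(calls), len(retained), len(culled),
        conc, ploidy_best, timings,
    )


def _decode_rows(mat: np.ndarray):
    from gbscall.sim import _LUT

    for row in mat:
        yield _LUT[row].tobytes().decode()
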