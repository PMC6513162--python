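"""FASTA/FASTQ readers and writers.

Reading goes through :class:`pysam.FastxFile` (C parser, transparent gzip);
records are normalised to uppercase. Writing is plain text formatting —
FASTQ is always emitted 4-line, FASTA wrapped at 70 columns.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pysam

from gbscall.errors import DataError

log = logging.getLogger(__name__)

_VALID_BASES = set("ACGTN")


@dataclass(frozen=True)
class SimRead:
    """A single sequencing read.

    ``read_id`` encodes (individual, fragment, serial) when produced by the
    simulator; ``mate`` is ``R1``/``R2`` for paired data, ``none`` otherwise.
    """

    read_id: str
    individual_id: str
    fragment_id: str
    mate: str
    sequence: str
    qualities: str

    def __post_init__(self):
        if len(self.sequence) != len(self.qualities):
            raise DataError(
                f"read {self.read_id}: sequence/quality length mismatch "
                f"({len(self.sequence)} vs {len(self.qualities)})"
            )


def read_fasta(path) -> Iterator[tuple[str, str]]:
    """Yield (id, uppercased sequence) from a FASTA file (.gz accepted)."""
    path = str(path)
    n_lower = 0
    try:
        with pysam.FastxFile(path) as fh:
            for rec in fh:
                seq = rec.sequence or ""
                if not seq:
                    raise DataError(f"{path}: record '{rec.name}' has empty sequence")
                if not seq.isupper():
                    n_lower += 1
                    seq = seq.upper()
                bad = set(seq) - _VALID_BASES
                if bad:
                    raise DataError(
                        f"{path}: record '{rec.name}' contains non-DNA characters {sorted(bad)}"
                    )
                yield rec.name, seq
    except (OSError, ValueError) as exc:
        raise DataError(f"cannot parse FASTA {path}: {exc}") from exc
    if n_lower:
        log.info("%s: normalised %d lowercase record(s) to uppercase", path, n_lower)


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 70) -> int:
    """Write (id, seq) records as FASTA; returns record count."""
    n = 0
    with open(path, "w") as out:
        for name, seq in records:
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")
            n += 1
    return n


def read_fastq(path, individual_id: str | None = None) -> Iterator[SimRead]:
    """Yield :class:`SimRead` from a FASTQ file (.gz accepted).

    Individual/fragment/mate fields are recovered from simulator-style read
    names (``<ind>:<frag>:<serial>[/1|/2]``) when present, else left blank.
    """
    path = str(path)
    try:
        with pysam.FastxFile(path) as fh:
            for rec in fh:
                seq = (rec.sequence or "").upper()
                qual = rec.quality
                if qual is None or len(qual) != len(seq):
                    raise DataError(
                        f"{path}: record '{rec.name}' sequence/quality length mismatch"
                    )
                name = rec.name
                mate = "none"
                if name.endswith("/1"):
                    mate, name = "R1", name[:-2]
                elif name.endswith("/2"):
                    mate, name = "R2", name[:-2]
                parts = name.split(":")
                ind = individual_id or (parts[0] if len(parts) == 3 else "")
                frag = parts[1] if len(parts) == 3 else ""
                yield SimRead(rec.name, ind, frag, mate, seq, qual)
    except (OSError, ValueError) as exc:
        raise DataError(f"cannot parse FASTQ {path}: {exc}") from exc


def write_fastq(reads: Iterable[SimRead], path) -> int:
    """Write reads as 4-line FASTQ (gzip if path ends with .gz)."""
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    n = 0
    with opener(path, "wt") as out:
        for r in reads:
            out.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.qualities}\n")
            n += 1
    return n


def fastq_paths(in_dir, individual_id: str, mate: str = "R1") -> Path:
    """Canonical on-disk location of one individual's reads."""
    base = Path(in_dir) / f"{individual_id}.{mate}.fastq"
    if base.exists():
        return base
    gz = base.with_suffix(".fastq.gz")
    if gz.exists():
        return gz
    return base
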