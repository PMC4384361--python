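"""Aligned single-molecule kinetics: containers, file formats, track building.

The interchange format is a plain TSV with header

    read_id  ref_name  ref_pos  strand  base  ipd_s  inserts

one row per synthesized position, rows of a read contiguous and in
synthesis order (5'->3' of the nascent strand).  ``ref_pos`` is the
0-based position on the *forward* reference axis, so it increases along a
forward-strand read and decreases along a reverse-strand read, whose
``bases`` are the reverse complement of the forward reference slice.
``ipd_s`` is the interpulse duration in seconds — the waiting time before
the base was incorporated; long IPDs indicate polymerase pausing.
``inserts`` counts inserted (non-reference) base calls immediately
following the position.

For the multi-scale correlation analysis, reads are length-filtered,
concatenated in input order, and trimmed from the tail to a power of two,
alongside 0/1 indicator tracks for each nucleotide.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from os import PathLike

import numpy as np
import pandas as pd
from Bio import SeqIO

from .exceptions import ValidationError

__all__ = [
    "KineticRead",
    "Reference",
    "ConcatenatedTracks",
    "load_reference",
    "load_kinetics",
    "write_kinetics",
    "filter_by_length",
    "encode_indicators",
    "concatenate_and_trim",
    "KINETICS_COLUMNS",
    "reverse_complement",
]

KINETICS_COLUMNS = ("read_id", "ref_name", "ref_pos", "strand", "base", "ipd_s", "inserts")

_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Reference:
    """A named reference sequence, canonically uppercase."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValidationError("reference sequence is empty")
        bad = set(self.sequence) - _BASES
        if bad:
            raise ValidationError(f"reference contains non-ACGTN symbols: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class KineticRead:
    """One aligned single-molecule read, arrays in synthesis order."""

    read_id: str
    reference_name: str
    reference_start: int  # 0-based leftmost forward-reference position covered
    strand: str  # "+" or "-"
    bases: str
    ipd_seconds: np.ndarray
    insert_count: np.ndarray

    def __post_init__(self) -> None:
        self.ipd_seconds = np.asarray(self.ipd_seconds, dtype=np.float64)
        self.insert_count = np.asarray(self.insert_count, dtype=np.int64)
        n = len(self.bases)
        if not (self.ipd_seconds.size == self.insert_count.size == n):
            raise ValidationError(
                f"read {self.read_id!r}: bases/ipd/inserts lengths differ "
                f"({n}/{self.ipd_seconds.size}/{self.insert_count.size})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"read {self.read_id!r}: unknown strand {self.strand!r}")
        bad = set(self.bases) - _BASES
        if bad:
            raise ValidationError(f"read {self.read_id!r}: invalid bases {sorted(bad)}")
        if not np.all(np.isfinite(self.ipd_seconds)) or np.any(self.ipd_seconds < 0):
            raise ValidationError(f"read {self.read_id!r}: IPDs must be finite and >= 0")
        if np.any(self.insert_count < 0):
            raise ValidationError(f"read {self.read_id!r}: insert counts must be >= 0")
        if self.reference_start < 0:
            raise ValidationError(f"read {self.read_id!r}: negative reference_start")

    def __len__(self) -> int:
        return len(self.bases)

    def reference_positions(self) -> np.ndarray:
        """Forward-reference position of each array index, in synthesis order."""
        idx = np.arange(len(self))
        if self.strand == "+":
            return self.reference_start + idx
        return self.reference_start + len(self) - 1 - idx


def load_reference(fasta: str | PathLike, name: str | None = None) -> Reference:
    """Load one record from a FASTA file (the first, or the named one)."""
    records = SeqIO.parse(str(fasta), "fasta")
    if name is None:
        first = next(records, None)
        if first is None:
            raise ValidationError(f"no FASTA records in {fasta}")
        return Reference(name=first.id, sequence=str(first.seq))
    for rec in records:
        if rec.id == name:
            return Reference(name=rec.id, sequence=str(rec.seq))
    raise ValidationError(f"record {name!r} not found in {fasta}")


def load_kinetics(tsv: str | PathLike) -> list[KineticRead]:
    """Parse a kinetics TSV into reads, in file order.

    Rows for one read must be contiguous; validation errors report the
    offending 1-based data row number.
    """
    df = pd.read_csv(
        tsv,
        sep="\t",
        dtype={
            "read_id": str,
            "ref_name": str,
            "ref_pos": np.int64,
            "strand": str,
            "base": str,
            "ipd_s": np.float64,
            "inserts": np.int64,
        },
    )
    missing = set(KINETICS_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"kinetics file missing columns: {sorted(missing)}")

    reads: list[KineticRead] = []
    seen: set[str] = set()
    row0 = 0
    for read_id, grp in itertools.groupby(
        df.itertuples(index=True), key=lambda r: r.read_id
    ):
        rows = list(grp)
        if read_id in seen:
            raise ValidationError(
                f"row {rows[0].Index + 1}: rows for read {read_id!r} are not contiguous"
            )
        seen.add(read_id)
        row0 = rows[0].Index + 1
        strand = rows[0].strand
        ref_name = rows[0].ref_name
        for r in rows:
            if r.strand not in ("+", "-"):
                raise ValidationError(f"row {r.Index + 1}: unknown strand symbol {r.strand!r}")
            if r.strand != strand or r.ref_name != ref_name:
                raise ValidationError(
                    f"row {r.Index + 1}: read {read_id!r} mixes strands or references"
                )
            if not np.isfinite(r.ipd_s) or r.ipd_s < 0:
                raise ValidationError(f"row {r.Index + 1}: negative or non-finite ipd_s")
            if r.inserts < 0:
                raise ValidationError(f"row {r.Index + 1}: negative insert count")
        pos = np.array([r.ref_pos for r in rows])
        step = 1 if strand == "+" else -1
        if pos.size > 1 and not np.all(np.diff(pos) == step):
            raise ValidationError(
                f"row {row0}: read {read_id!r} positions are not consecutive in "
                f"synthesis order (ragged read)"
            )
        reads.append(
            KineticRead(
                read_id=read_id,
                reference_name=ref_name,
                reference_start=int(pos.min()),
                strand=strand,
                bases="".join(r.base for r in rows).upper(),
                ipd_seconds=np.array([r.ipd_s for r in rows]),
                insert_count=np.array([r.inserts for r in rows]),
            )
        )
    return reads


def write_kinetics(reads: list[KineticRead], tsv: str | PathLike) -> None:
    """Write reads to the kinetics TSV (IPD at 6 significant digits)."""
    with open(tsv, "w") as fh:
        fh.write("\t".join(KINETICS_COLUMNS) + "\n")
        for read in reads:
            positions = read.reference_positions()
            for t in range(len(read)):
                fh.write(
                    f"{read.read_id}\t{read.reference_name}\t{positions[t]}\t"
                    f"{read.strand}\t{read.bases[t]}\t{read.ipd_seconds[t]:.6g}\t"
                    f"{read.insert_count[t]}\n"
                )


def filter_by_length(reads: list[KineticRead], min_exclusive: int = 1000) -> list[KineticRead]:
    """Keep reads strictly longer than ``min_exclusive`` positions, order preserved.

    The default drops reads of <= 1000 nucleotides, limiting the number of
    read-boundary discontinuities in the concatenated tracks.
    """
    return [r for r in reads if len(r) > min_exclusive]


def encode_indicators(bases: str) -> dict[str, np.ndarray]:
    """0/1 occupancy vector per nucleotide; N positions are 0 in all four."""
    bad = set(bases) - _BASES
    if bad:
        raise ValidationError(f"invalid bases for indicator encoding: {sorted(bad)}")
    arr = np.frombuffer(bases.encode("ascii"), dtype=np.uint8)
    return {nt: (arr == ord(nt)).astype(np.float64) for nt in "ACGT"}


@dataclass
class ConcatenatedTracks:
    """Six aligned power-of-two-length vectors built from concatenated reads.

    At every position the four indicators sum to 1 except at N positions
    (all zero).  ``read_boundaries`` are the offsets where each retained
    read begins; coefficients spanning them are few and are not masked by
    default downstream.
    """

    ipd: np.ndarray = field(repr=False)
    inserts: np.ndarray = field(repr=False)
    indicator_a: np.ndarray = field(repr=False)
    indicator_c: np.ndarray = field(repr=False)
    indicator_g: np.ndarray = field(repr=False)
    indicator_t: np.ndarray = field(repr=False)
    read_boundaries: list[int] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.ipd.size

    def track(self, label: str) -> np.ndarray:
        return {
            "A": self.indicator_a,
            "C": self.indicator_c,
            "G": self.indicator_g,
            "T": self.indicator_t,
            "IPD": self.ipd,
            "inserts": self.inserts,
        }[label]


def concatenate_and_trim(
    reads: list[KineticRead], max_length: int = 2 ** 23
) -> ConcatenatedTracks:
    """Concatenate reads in input order and trim the tail to a power of two.

    The result length is the largest power of two <= min(total length,
    ``max_length``).  Trimming removes the tail, never the head, so
    earlier reads are preserved intact.
    """
    if not reads:
        raise ValidationError("no reads to concatenate")
    total = sum(len(r) for r in reads)
    if total < 2:
        raise ValidationError(f"total length {total} is too short to analyze")
    length = 1 << int(np.floor(np.log2(min(total, max_length))))

    boundaries: list[int] = []
    offset = 0
    for r in reads:
        if offset < length:
            boundaries.append(offset)
        offset += len(r)

    ipd = np.concatenate([r.ipd_seconds for r in reads])[:length]
    inserts = np.concatenate([r.insert_count for r in reads])[:length].astype(np.float64)
    bases = "".join(r.bases for r in reads)[:length]
    ind = encode_indicators(bases)
    return ConcatenatedTracks(
        ipd=ipd,
        inserts=inserts,
        indicator_a=ind["A"],
        indicator_c=ind["C"],
        indicator_g=ind["G"],
        indicator_t=ind["T"],
        read_boundaries=boundaries,
    )
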