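"""Readers and writers for the formats the pipeline touches.

Sequences are plain FASTA (case is significant: lowercase and ``N`` mark
repeat-masked bases).  Photon traces are TSV with columns ``time_ms``,
``green``, ``red`` and integral counts.  Assay plates are CSV with columns
``condition``, ``conc``, ``signal``, ``replicate``.  Coordinates in all
interval outputs follow the BED convention (0-based, half-open).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


_SEQ_ALPHABET = set("ACGTNacgtn")


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence; lowercase or ``N`` bases are masked."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record has an empty id")
        if not self.sequence:
            raise FormatError(f"sequence record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - _SEQ_ALPHABET
        if bad:
            raise FormatError(
                f"sequence record {self.id!r} contains non-DNA characters: "
                f"{sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(self.id, str(Seq(self.sequence).reverse_complement()))


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into a list of records, preserving masking case.

    Raises
    ------
    FormatError
        On duplicate ids, empty sequences, or non-DNA characters; the error
        names the offending record.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq)))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA; round-trips bit-identically through read_fasta."""
    seq_records = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seq_records, str(path), "fasta-2line")


@dataclass
class TraceTable:
    """Two-channel photon counts per time bin.

    Attributes
    ----------
    bin_width_ms : float
        Width of each time bin in milliseconds (> 0).
    green, red : ndarray of int
        Photon counts per bin, non-negative.
    """

    bin_width_ms: float
    green: np.ndarray
    red: np.ndarray
    saturated: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.green = np.asarray(self.green)
        self.red = np.asarray(self.red)
        if self.bin_width_ms <= 0:
            raise FormatError("bin_width_ms must be positive")
        if self.green.shape != self.red.shape or self.green.ndim != 1:
            raise FormatError("green and red must be 1-D arrays of equal length")
        for name, arr in (("green", self.green), ("red", self.red)):
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.all(np.mod(arr, 1) == 0):
                    raise FormatError(f"{name} counts must be integers (photon counting)")
                arr = arr.astype(np.int64)
            if np.any(arr < 0):
                raise FormatError(f"{name} counts must be non-negative")
        self.green = self.green.astype(np.int64)
        self.red = self.red.astype(np.int64)

    @property
    def n_bins(self) -> int:
        return int(self.green.size)

    @property
    def duration_s(self) -> float:
        return self.n_bins * self.bin_width_ms / 1000.0

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.bin_width_ms


def read_trace(path: str | Path) -> TraceTable:
    """Read a photon-trace TSV (columns time_ms, green, red).

    The bin width is inferred from the first two time stamps and validated as
    constant across the whole file.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"time_ms", "green", "red"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"trace file {path} must have columns time_ms, green, red "
            f"(found {list(df.columns)})"
        )
    if len(df) < 2:
        raise FormatError(f"trace file {path} must contain at least two bins")
    t = df["time_ms"].to_numpy(dtype=float)
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-9) or dt[0] <= 0:
        raise FormatError(f"non-uniform or non-increasing bin spacing in {path}")
    for col in ("green", "red"):
        vals = df[col].to_numpy()
        if not np.all(np.mod(vals, 1) == 0):
            raise FormatError(f"non-integer photon count in column {col} of {path}")
        if np.any(vals < 0):
            raise FormatError(f"negative photon count in column {col} of {path}")
    return TraceTable(float(dt[0]), df["green"].to_numpy(np.int64), df["red"].to_numpy(np.int64))


def write_trace(trace: TraceTable, path: str | Path) -> None:
    df = pd.DataFrame(
        {"time_ms": trace.times_ms, "green": trace.green, "red": trace.red}
    )
    df.to_csv(path, sep="\t", index=False)


PLATE_COLUMNS = ["condition", "conc", "signal", "replicate"]


def read_plate(path: str | Path) -> pd.DataFrame:
    """Read a generic assay-plate CSV (condition, conc, signal, replicate)."""
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"plate file {path} is missing columns {missing}")
    if not np.all(np.isfinite(df["conc"].to_numpy(dtype=float))):
        raise FormatError(f"non-finite concentration in {path}")
    if np.any(df["conc"].to_numpy(dtype=float) < 0):
        raise FormatError(f"negative concentration in {path}")
    if np.any(df["replicate"].to_numpy(dtype=int) < 1):
        raise FormatError(f"replicate indices must be >= 1 in {path}")
    return df[PLATE_COLUMNS + [c for c in df.columns if c not in PLATE_COLUMNS]]


def write_plate(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"plate table is missing columns {missing}")
    df.to_csv(path, index=False)


# The three 37-bp inverted-repeat probes (positive strands), in the order the
# assay designed them: spacers of 10, 5 and 1 bp between the SOX half-site
# AACAAT and its reverse complement ATTGTT.  GC-rich flanks/spacers avoid
# off-site protein-DNA binding.
_PROBES = (
    ("IR10", "cgccagtAACAATagggcggcttATTGTTccgggggc"),
    ("IR5", "cgccagtaggAACAATgcggcATTGTTttccgggggc"),
    ("IR1", "cgccagtagggcAACAATgATTGTTgcttccgggggc"),
)


def builtin_probes() -> dict[str, SequenceRecord]:
    """Return the three built-in inverted-repeat probe sequences.

    Keys are ``IR10``, ``IR5``, ``IR1`` (insertion order matches the probe
    design table); each value is the 37-bp positive strand.
    """
    return {name: SequenceRecord(name, seq) for name, seq in _PROBES}


def write_bed6(intervals: Sequence[tuple[str, int, int, str, float, str]],
               path: str | Path) -> None:
    """Write (chrom, start, end, name, score, strand) rows as BED6."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score:g}\t{strand}\n")
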