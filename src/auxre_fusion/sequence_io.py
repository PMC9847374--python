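"""Sequence and report I/O, and the upstream coordinate convention.

Upstream (promoter) sequences are indexed with negative positions: the
base immediately 5' of the retrieval anchor is position -1, and a base at
0-based string index ``i`` in a sequence of length ``L`` sits at position
``i - L``.  There is no position 0, and motif spans are inclusive on both
ends, so a 6-bp core spans ``end - start + 1 == 6``.

The anchor itself (transcription start vs. translation start) is whatever
the input FASTA was cut at; this module preserves the frame, it does not
decide it.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")

#: Columns of the occurrence report, in file order.
TABLE1_COLUMNS = ["gene", "repeats", "start", "end", "matching_seq"]
FULL_COLUMNS = TABLE1_COLUMNS + ["bel", "pl", "betp", "label"]


@dataclass(frozen=True)
class UpstreamSequence:
    """A promoter/upstream sequence with its gene id.

    ``seq`` is uppercase DNA over {A, C, G, T, N}; the final base is at
    upstream position -1.
    """

    gene_id: str
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"empty sequence for gene {self.gene_id!r}")
        for i, base in enumerate(self.seq):
            if base not in _VALID_BASES:
                raise ValueError(
                    f"invalid base {base!r} at index {i} in record {self.gene_id!r}"
                )

    @property
    def length(self) -> int:
        return len(self.seq)


def index_to_position(i: int, length: int) -> int:
    """Convert a 0-based string index into a negative upstream position.

    The last base (index ``length - 1``) is position -1; the first base is
    position ``-length``.
    """
    if not 0 <= i < length:
        raise IndexError(f"index {i} out of range for length {length}")
    return i - length


def position_to_index(p: int, length: int) -> int:
    """Inverse of :func:`index_to_position`: negative position to 0-based index."""
    if not -length <= p <= -1:
        raise IndexError(f"position {p} out of range for length {length}")
    return p + length


@dataclass(frozen=True)
class ReportRow:
    """One predicted AuxRE occurrence in the final report."""

    gene_id: str
    repeats: int
    start: int
    end: int
    matching_seq: str
    bel: float | None = None
    pl: float | None = None
    betp: float | None = None
    label: str | None = None


@dataclass
class OccurrenceReport:
    """Ordered collection of report rows (by gene, then ascending start)."""

    rows: list[ReportRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts: dict[str, int] = {}
        for row in self.rows:
            counts[row.gene_id] = counts.get(row.gene_id, 0) + 1
        for row in self.rows:
            if not row.start < row.end < 0:
                raise ValueError(f"bad span {row.start}..{row.end} for {row.gene_id}")
            if row.repeats != counts[row.gene_id]:
                raise ValueError(
                    f"repeats={row.repeats} for {row.gene_id} but "
                    f"{counts[row.gene_id]} rows share that gene"
                )
            if row.bel is not None:
                if not row.bel <= row.betp + 1e-12:
                    raise ValueError("bel must not exceed betp")
                if not row.betp <= row.pl + 1e-12:
                    raise ValueError("betp must not exceed pl")

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[ReportRow]:
        return iter(self.rows)


def _open_maybe_gzip(path: Path):
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path) -> list[UpstreamSequence]:
    """Read upstream sequences from a plain or gzipped FASTA file.

    The header token before the first whitespace is the gene id; sequences
    are uppercased and RNA ``U`` is converted to ``T``.  Duplicate gene ids
    and non-IUPAC characters are errors.
    """
    path = Path(path)
    records: list[UpstreamSequence] = []
    seen: set[str] = set()
    with _open_maybe_gzip(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            gene_id = rec.id
            if gene_id in seen:
                raise ValueError(f"duplicate gene_id {gene_id!r} in {path}")
            seen.add(gene_id)
            seq = str(rec.seq).upper().replace("U", "T")
            records.append(UpstreamSequence(gene_id, seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[UpstreamSequence], path: str | Path) -> None:
    """Write upstream sequences as FASTA (60-column wrap)."""
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.gene_id}\n")
            for i in range(0, rec.length, 60):
                out.write(rec.seq[i : i + 60] + "\n")


def write_report(
    report: OccurrenceReport, path: str | Path, table1_mode: bool = False
) -> None:
    """Write the occurrence report as TSV.

    ``table1_mode`` emits only the five columns gene / repeats / start /
    end / matching_seq; full mode appends bel, pl, betp and label.
    Coordinates are printed as plain ASCII negative integers.
    """
    cols = TABLE1_COLUMNS if table1_mode else FULL_COLUMNS
    data: dict[str, list] = {c: [] for c in cols}
    for row in report:
        data["gene"].append(row.gene_id)
        data["repeats"].append(row.repeats)
        data["start"].append(row.start)
        data["end"].append(row.end)
        data["matching_seq"].append(row.matching_seq)
        if not table1_mode:
            data["bel"].append("" if row.bel is None else f"{row.bel:.6f}")
            data["pl"].append("" if row.pl is None else f"{row.pl:.6f}")
            data["betp"].append("" if row.betp is None else f"{row.betp:.6f}")
            data["label"].append("" if row.label is None else row.label)
    pd.DataFrame(data, columns=cols).to_csv(path, sep="\t", index=False)


def read_report(path: str | Path) -> OccurrenceReport:
    """Read a report TSV back into an :class:`OccurrenceReport`."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "matching_seq": str})
    full = "bel" in df.columns
    rows = []
    for rec in df.itertuples(index=False):
        rows.append(
            ReportRow(
                gene_id=rec.gene,
                repeats=int(rec.repeats),
                start=int(rec.start),
                end=int(rec.end),
                matching_seq=rec.matching_seq,
                bel=float(rec.bel) if full else None,
                pl=float(rec.pl) if full else None,
                betp=float(rec.betp) if full else None,
                label=rec.label if full else None,
            )
        )
    return OccurrenceReport(rows)
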