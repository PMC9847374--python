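"""Exact scanning for candidate AuxRE core motifs and 14-bp context extraction.

The canonical auxin-response element core is the hexamer TGTCTC; known
variants (TGTCCC, TGTCGG, TGTCAC) can be added to the motif set.  Matches
are exact and may overlap; the scan is forward-strand by default, with
reverse-complement scanning as an opt-in (reverse hits are reported in
forward coordinates on strand '-').
"""

from __future__ import annotations

from dataclasses import dataclass

from .sequence_io import UpstreamSequence, index_to_position, position_to_index

DEFAULT_MOTIF = "TGTCTC"
#: Core variants reported as ARF binding sites; only the first is on by default.
KNOWN_MOTIFS = ("TGTCTC", "TGTCCC", "TGTCGG", "TGTCAC")

CORE_LENGTH = 6
CONTEXT_FLANK = 4

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifOccurrence:
    """One core-motif hit with inclusive negative coordinates.

    ``context`` is the 14-char string of 4-bp lowercase flanks around the
    uppercase 6-bp core, padded with '.' where a flank runs off an end.
    """

    gene_id: str
    core: str
    start: int
    end: int
    strand: str
    context: str

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != CORE_LENGTH:
            raise ValueError(f"core span must be {CORE_LENGTH} bp")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.context[CONTEXT_FLANK : CONTEXT_FLANK + CORE_LENGTH].upper() != (
            self.core if self.strand == "+" else reverse_complement(self.core)
        ):
            raise ValueError("context core does not match occurrence core")


def _validate_motif(motif: str) -> None:
    if len(motif) != CORE_LENGTH or any(b not in "ACGT" for b in motif):
        raise ValueError(
            f"motif {motif!r} must be a {CORE_LENGTH}-mer over A/C/G/T"
        )


def _exact_hits(seq: str, word: str) -> list[int]:
    """All (possibly overlapping) start indices of word in seq."""
    hits = []
    i = seq.find(word)
    while i != -1:
        hits.append(i)
        i = seq.find(word, i + 1)
    return hits


def _context_at(seq: UpstreamSequence, idx: int, flank: int) -> str:
    left = seq.seq[max(0, idx - flank) : idx].lower()
    left = "." * (flank - len(left)) + left
    core = seq.seq[idx : idx + CORE_LENGTH].upper()
    right = seq.seq[idx + CORE_LENGTH : idx + CORE_LENGTH + flank].lower()
    right = right + "." * (flank - len(right))
    return left + core + right


def extract_context(
    seq: UpstreamSequence, occ: MotifOccurrence, flank: int = CONTEXT_FLANK
) -> str:
    """Extract the flanked context string for an occurrence within ``seq``.

    Flank bases are lowercase, the core uppercase; '.' pads where a flank
    extends past either end of the sequence.
    """
    idx = position_to_index(occ.start, seq.length)
    return _context_at(seq, idx, flank)


def find_core_matches(
    seq: UpstreamSequence,
    motif_set: set[str] | None = None,
    scan_reverse: bool = False,
) -> list[MotifOccurrence]:
    """Find every exact core-motif match in an upstream sequence.

    Returns occurrences ordered by ascending start position.  With
    ``scan_reverse``, matches of each motif's reverse complement are also
    reported, on strand '-' but in forward coordinates (the context string
    then shows the forward-strand letters).  N never matches.
    """
    motifs = sorted(motif_set) if motif_set else [DEFAULT_MOTIF]
    for m in motifs:
        _validate_motif(m)

    raw: list[tuple[int, str, str]] = []  # (index, core, strand)
    for motif in motifs:
        for i in _exact_hits(seq.seq, motif):
            raw.append((i, motif, "+"))
        if scan_reverse:
            rc = reverse_complement(motif)
            if rc == motif:
                continue  # palindromic core already counted on '+'
            for i in _exact_hits(seq.seq, rc):
                raw.append((i, motif, "-"))
    raw.sort()

    occs = []
    for i, core, strand in raw:
        start = index_to_position(i, seq.length)
        context = _context_at(seq, i, CONTEXT_FLANK)
        occs.append(
            MotifOccurrence(
                gene_id=seq.gene_id,
                core=core,
                start=start,
                end=start + CORE_LENGTH - 1,
                strand=strand,
                context=context,
            )
        )
    return occs


def count_word(seq: UpstreamSequence, word: str) -> int:
    """Forward-strand overlapping occurrence count of a hexamer word."""
    _validate_motif(word)
    return len(_exact_hits(seq.seq, word))
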