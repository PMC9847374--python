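"""Generators for every input the pipeline consumes.

Three generators cover the three input files: fixture promoters that embed
canonical TGTCTC AuxREs of six maize genes at their published upstream
coordinates, labelled training motifs with a controlled degree of class
separation, and an expression table with a planted set of auxin-induced
genes.  Everything is deterministic for a given seed, so the whole test
suite runs without any downloads.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np

from .features import LABEL_NEG, LABEL_POS, TrainingMotif
from .motif_scan import CORE_LENGTH, DEFAULT_MOTIF, find_core_matches
from .sequence_io import UpstreamSequence, position_to_index, write_fasta

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

#: Published canonical AuxRE sites in the upstream sequences of six
#: auxin-induced maize genes: gene id -> list of (core start position,
#: 14-char flanked context).  Starts are inclusive negative upstream
#: coordinates of the TGTCTC core; contexts show 4-bp lowercase flanks.
REFERENCE_SITES: dict[str, list[tuple[int, str]]] = {
    "Zm00001d002678": [(-274, "ccttTGTCTCctct"), (-104, "tcccTGTCTCtagt")],
    "Zm00001d016948": [
        (-969, "aacaTGTCTCcgta"),
        (-440, "tccgTGTCTCctca"),
        (-238, "tcgaTGTCTCtaca"),
    ],
    "Zm00001d015217": [
        (-530, "ctcgTGTCTCgcgc"),
        (-479, "ctcgTGTCTCgtgg"),
        (-408, "ctcgTGTCTCgtgc"),
        (-92, "acgcTGTCTCataa"),
    ],
    "Zm00001d017591": [(-521, "tcgcTGTCTCccgg"), (-394, "cttgTGTCTCgtgc")],
    "Zm00001d020429": [(-528, "ctatTGTCTCcttg"), (-368, "tccgTGTCTCttgg")],
    "Zm00001d048709": [(-941, "ttgtTGTCTCtggg"), (-100, "cgctTGTCTCgaat")],
}

#: Flank base composition of planted positive contexts, by separation level.
_FLANK_BIAS = {
    "high": {"A": 0.05, "C": 0.45, "G": 0.05, "T": 0.45},
    "low": {"A": 0.23, "C": 0.27, "G": 0.23, "T": 0.27},
}
#: Fraction of negatives that are TGTC-prefixed decoys.
_DECOY_FRACTION = {"high": 0.3, "low": 0.9}
#: Probability that a decoy core is the canonical hexamer itself (the
#: rest keep the TGTC prefix but differ in the final bases).  Scan
#: candidates always carry a canonical core, so training needs some
#: canonical-core negatives for flank context to be learnable; at low
#: separation every decoy is canonical and the classes differ only in a
#: weak flank bias, putting accuracy near chance.
_DECOY_CANONICAL_P = {"high": 0.5, "low": 1.0}

_MAX_DRAWS = 1000


def _random_dna(rng: np.random.Generator, n: int, probs=None) -> str:
    return "".join(rng.choice(_BASES, size=n, p=probs))


def make_fixture_promoters(
    length: int = 1000, seed: int = 0
) -> list[UpstreamSequence]:
    """Six fixture promoters embedding the reference AuxRE sites.

    Backgrounds are uniform-random DNA, rejection-resampled until free of
    the canonical core; each reference 14-mer is then written so its core
    occupies exactly the published coordinates.  After embedding, the
    scan is re-run and must return exactly the published hits, otherwise
    the background is redrawn (a boundary between flank and background
    could otherwise spell out a spurious core).
    """
    deepest = min(s for sites in REFERENCE_SITES.values() for s, _ in sites)
    if length < -deepest + 4:
        raise ValueError(
            f"length must be at least {-deepest + 4} bp to hold the deepest "
            f"site ({deepest}) and its upstream flank"
        )
    rng = np.random.default_rng(seed)
    promoters = []
    for gene_id, sites in REFERENCE_SITES.items():
        spans = sorted(
            (position_to_index(start, length) - 4, position_to_index(start, length) + 10)
            for start, _ in sites
        )
        for (a0, b0), (a1, _) in zip(spans, spans[1:]):
            if a1 < b0:
                raise ValueError(f"overlapping embedded sites for {gene_id}")
        expected = sorted(start for start, _ in sites)
        for _ in range(_MAX_DRAWS):
            bg = _random_dna(rng, length)
            if DEFAULT_MOTIF in bg:
                continue
            chars = list(bg)
            for start, context in sites:
                idx = position_to_index(start, length)
                chars[idx - 4 : idx + 10] = context.upper()
            candidate = UpstreamSequence(gene_id, "".join(chars))
            found = [occ.start for occ in find_core_matches(candidate)]
            if found == expected:
                promoters.append(candidate)
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError(f"could not build a clean background for {gene_id}")
    return promoters


def _random_core(rng: np.random.Generator) -> str:
    while True:
        core = _random_dna(rng, CORE_LENGTH)
        if core != DEFAULT_MOTIF:
            return core


def _decoy_core(rng: np.random.Generator, p_canonical: float) -> str:
    if rng.random() < p_canonical:
        return DEFAULT_MOTIF
    while True:
        core = DEFAULT_MOTIF[:4] + _random_dna(rng, 2)
        if core != DEFAULT_MOTIF:
            return core


def make_training_set(
    n_pos: int,
    n_neg: int,
    separation: str = "high",
    seed: int = 0,
) -> list[TrainingMotif]:
    """Labelled 14-mer contexts with a planted, tunable class contrast.

    Positives carry the canonical TGTCTC core with flanks drawn from a
    C/T-rich composition whose bias strength is set by ``separation``.
    Negatives mix random non-canonical hexamer cores with TGTC-prefixed
    decoys (some carrying the canonical core itself), all with uniform
    flanks.  At high separation the classes differ strongly in both core
    and flank composition; at low separation most negatives are
    canonical-core decoys and the flank bias is weak, so the classes are
    nearly indistinguishable.
    """
    if n_pos < 5 or n_neg < 5:
        raise ValueError("need at least 5 examples per class")
    if separation not in _FLANK_BIAS:
        raise ValueError(f"separation must be one of {sorted(_FLANK_BIAS)}")
    rng = np.random.default_rng(seed)
    bias = np.array([_FLANK_BIAS[separation][b] for b in "ACGT"])
    decoy_frac = _DECOY_FRACTION[separation]

    motifs = []
    for _ in range(n_pos):
        left = _random_dna(rng, 4, bias).lower()
        right = _random_dna(rng, 4, bias).lower()
        motifs.append(TrainingMotif(left + DEFAULT_MOTIF + right, LABEL_POS))
    p_canonical = _DECOY_CANONICAL_P[separation]
    for _ in range(n_neg):
        if rng.random() < decoy_frac:
            core = _decoy_core(rng, p_canonical)
        else:
            core = _random_core(rng)
        left = _random_dna(rng, 4).lower()
        right = _random_dna(rng, 4).lower()
        motifs.append(TrainingMotif(left + core + right, LABEL_NEG))
    return motifs


def make_expression_table(
    n_genes: int,
    n_above_threshold: int,
    threshold: float = 3.0,
    seed: int = 0,
) -> list[tuple[str, float]]:
    """Expression records (gene_id, fold_change) with a planted induced set.

    Exactly ``n_above_threshold`` genes get fold changes uniform on
    (threshold, 10]; the rest are uniform on (0.1, threshold].  No gene
    lands exactly at the threshold, so strict-inequality selection
    recovers the planted set exactly.
    """
    if n_above_threshold > n_genes:
        raise ValueError("n_above_threshold cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    records = []
    for g in range(n_genes):
        gene_id = f"gene{g:04d}"
        if g < n_above_threshold:
            fc = float(rng.uniform(threshold, 10.0))
            while fc <= threshold:  # open at the threshold
                fc = float(rng.uniform(threshold, 10.0))
        else:
            fc = float(rng.uniform(0.1, threshold))
        records.append((gene_id, fc))
    return records


def make_planted_promoters(
    n_pos: int = 20,
    n_neg: int = 20,
    length: int = 600,
    seed: int = 0,
) -> tuple[list[UpstreamSequence], dict[str, str]]:
    """Promoters for end-to-end recovery checks, with ground truth.

    Each promoter embeds one canonical core at its centre: "pos" promoters
    use a high-separation positive context (C/T-biased flanks), "neg"
    promoters a decoy context with uniform flanks.  Backgrounds are kept
    free of extra canonical cores.  Returns the promoters and a map from
    gene id to its true class ("pos" or "neg").
    """
    rng = np.random.default_rng(seed)
    bias = np.array([_FLANK_BIAS["high"][b] for b in "ACGT"])
    promoters = []
    truth = {}
    mid = length // 2
    for k in range(n_pos + n_neg):
        is_pos = k < n_pos
        gene_id = f"{'pos' if is_pos else 'neg'}{k:03d}"
        flank_probs = bias if is_pos else None
        left = _random_dna(rng, 4, flank_probs)
        right = _random_dna(rng, 4, flank_probs)
        insert = left + DEFAULT_MOTIF + right
        for _ in range(_MAX_DRAWS):
            bg = _random_dna(rng, length)
            if DEFAULT_MOTIF in bg:
                continue
            chars = list(bg)
            chars[mid - 4 : mid + 10] = insert
            candidate = UpstreamSequence(gene_id, "".join(chars))
            hits = find_core_matches(candidate)
            if len(hits) == 1:
                promoters.append(candidate)
                truth[gene_id] = "pos" if is_pos else "neg"
                break
        else:  # pragma: no cover
            raise RuntimeError(f"could not build a clean background for {gene_id}")
    return promoters, truth


def write_training_tsv(motifs: Sequence[TrainingMotif], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("context\tlabel\n")
        for m in motifs:
            out.write(f"{m.context}\t{m.label}\n")


def write_expression_tsv(
    records: Sequence[tuple[str, float]], path: str | Path
) -> None:
    with open(path, "w") as out:
        out.write("gene_id\tfold_change\n")
        for gene_id, fc in records:
            out.write(f"{gene_id}\t{fc:.6f}\n")


def write_fixture_bundle(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the full fixture bundle (FASTA + training TSV + expression TSV)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out_dir / "promoters.fasta",
        "training": out_dir / "training.tsv",
        "expression": out_dir / "expression.tsv",
    }
    write_fasta(make_fixture_promoters(seed=seed), paths["fasta"])
    write_training_tsv(
        make_training_set(200, 200, separation="high", seed=seed + 1),
        paths["training"],
    )
    write_expression_tsv(
        make_expression_table(100, 10, seed=seed + 2), paths["expression"]
    )
    logger.info("fixture bundle written to %s", out_dir)
    return paths
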