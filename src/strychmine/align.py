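"""Global protein alignment, percent identity and reciprocal-best-hit orthology.

Orthologue identity claims (e.g. a producer enzyme sharing 92% amino-acid
identity with its non-producer counterpart) are reproduced here with global
Needleman-Wunsch alignment under BLOSUM62 and affine gap penalties, since the
comparisons are between full-length orthologues.  Reciprocal best hits (RBH)
between two proteomes are the standard orthologue proxy: a pair is RBH when
each sequence is the other's unique top-scoring partner.

The dynamic programming itself is delegated to Biopython's PairwiseAligner;
this module owns the scoring conventions, identity bookkeeping and RBH logic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring conventions for global protein alignment.

    A gap of length k costs gap_open + gap_extend * k (BLAST-style protein
    defaults 11/1).  ``identity_denominator`` selects what percent identity is
    divided by: alignment columns (terminal gap overhangs excluded), or the
    shorter/longer ungapped sequence length.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    identity_denominator: str = "alignment_columns"

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")
        if self.identity_denominator not in (
            "alignment_columns",
            "shorter_sequence",
            "longer_sequence",
        ):
            raise ValueError(f"unknown identity denominator {self.identity_denominator!r}")


@dataclass
class OrthologPair:
    """A scored global alignment of two proteins, optionally flagged as RBH."""

    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float
    percent_identity: float
    rbh: bool = False


def _aligner(params: AlignmentParams) -> PairwiseAligner:
    matrix = substitution_matrices.load(params.matrix_name).copy()
    # X (unknown residue) is tolerated but carries no evidence either way
    if "X" in matrix.alphabet:
        for aa in matrix.alphabet:
            matrix["X", aa] = 0.0
            matrix[aa, "X"] = 0.0
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    # first gap position costs open + extend so a length-k gap totals open + k*extend
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def _check_sequence(label: str, seq: str) -> None:
    if not seq:
        raise ValueError(f"sequence {label} is empty")
    bad = sorted(set(seq) - VALID_RESIDUES)
    if bad:
        raise ValueError(f"illegal residue(s) in {label}: {bad}")


def global_align(
    a: str,
    b: str,
    params: AlignmentParams = AlignmentParams(),
    id_a: str = "a",
    id_b: str = "b",
) -> OrthologPair:
    """Optimal global alignment of two protein sequences.

    The optimum is unique in score; among co-optimal tracebacks the aligner's
    first (deterministic) one is reported.
    """
    _check_sequence(id_a, a)
    _check_sequence(id_b, b)
    alignment = _aligner(params).align(a, b)[0]
    aligned_a, aligned_b = str(alignment[0]), str(alignment[1])
    pair = OrthologPair(
        id_a=id_a,
        id_b=id_b,
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(alignment.score),
        percent_identity=0.0,
    )
    pair.percent_identity = percent_identity(pair, params)
    return pair


def align_score(a: str, b: str, params: AlignmentParams = AlignmentParams()) -> float:
    """Optimal global alignment score only (skips traceback; used for RBH scans)."""
    _check_sequence("a", a)
    _check_sequence("b", b)
    return float(_aligner(params).score(a, b))


def _core_columns(aligned_a: str, aligned_b: str) -> range:
    """Column range excluding terminal gap overhangs of either sequence."""
    n = len(aligned_a)
    lead_a = n - len(aligned_a.lstrip("-"))
    lead_b = n - len(aligned_b.lstrip("-"))
    tail_a = n - len(aligned_a.rstrip("-"))
    tail_b = n - len(aligned_b.rstrip("-"))
    start = max(lead_a, lead_b)
    stop = n - max(tail_a, tail_b)
    return range(start, max(start, stop))


def percent_identity(pair: OrthologPair, params: AlignmentParams = AlignmentParams()) -> float:
    """100 x identical residue columns / denominator.

    Identical positions are counted only where both columns hold residues.
    The default denominator is the number of alignment columns between the
    terminal gap overhangs (internal gaps count, overhangs do not).
    """
    a, b = pair.aligned_a, pair.aligned_b
    if len(a) != len(b):
        raise ValueError("aligned strings must have equal length")
    matches = sum(
        1 for x, y in zip(a, b) if x == y and x != "-"
    )
    if params.identity_denominator == "alignment_columns":
        denom = len(_core_columns(a, b))
    elif params.identity_denominator == "shorter_sequence":
        denom = min(len(a.replace("-", "")), len(b.replace("-", "")))
    else:
        denom = max(len(a.replace("-", "")), len(b.replace("-", "")))
    if denom == 0:
        return 0.0
    return 100.0 * matches / denom


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into an id -> sequence mapping (order preserved)."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return records


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def reciprocal_best_hits(
    proteome_a: dict[str, str],
    proteome_b: dict[str, str],
    params: AlignmentParams = AlignmentParams(),
) -> list[OrthologPair]:
    """Orthologue pairs where each sequence is the other's unique best hit.

    All-vs-all global alignment scores are computed; a gene whose top score is
    tied between several partners gets no RBH (logged).  Returned pairs carry
    the full alignment and percent identity of the RBH partners.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")
    ids_a, ids_b = list(proteome_a), list(proteome_b)
    scores = np.empty((len(ids_a), len(ids_b)))
    for i, ida in enumerate(ids_a):
        for j, idb in enumerate(ids_b):
            scores[i, j] = align_score(proteome_a[ida], proteome_b[idb], params)

    def unique_argmax(row: np.ndarray) -> int | None:
        top = row.max()
        hits = np.flatnonzero(row == top)
        return int(hits[0]) if hits.size == 1 else None

    best_in_b = [unique_argmax(scores[i]) for i in range(len(ids_a))]
    best_in_a = [unique_argmax(scores[:, j]) for j in range(len(ids_b))]

    pairs: list[OrthologPair] = []
    for i, j in enumerate(best_in_b):
        if j is None:
            logger.info("no unique best hit in B for %s (tied top score)", ids_a[i])
            continue
        if best_in_a[j] == i:
            pair = global_align(
                proteome_a[ids_a[i]], proteome_b[ids_b[j]], params, ids_a[i], ids_b[j]
            )
            pairs.append(replace(pair, rbh=True))
    return pairs
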