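"""Pairwise protein alignment with BLAST-style summary statistics.

Local (Smith–Waterman) alignment under a named substitution matrix with
affine gaps; each hit reports raw score, percent identity, percent
similarity (positive-scoring residue pairs, BLAST's "Positives") over the
alignment columns, and a Karlin–Altschul e-value

    E = K * m * n * exp(-lambda * S)

with ``m``, ``n`` the full sequence lengths.  The gapped-BLOSUM62
constants are defaults; they are configurable because exact e-values are
search-tool dependent.

The affine gap convention is Biopython's: a gap of length ``k`` costs
``gap_open + (k - 1) * gap_extend``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
import math

from Bio.Align import PairwiseAligner, substitution_matrices

from .records import PROTEIN_ALPHABET, ProteinRecord


class AlignmentError(ValueError):
    """Invalid alignment input."""


@dataclass(frozen=True)
class SearchParams:
    """Scoring and significance parameters for protein homology search.

    Parameters
    ----------
    substitution_matrix : str
        Name of a substitution matrix shipped with Biopython.
    gap_open, gap_extend : float
        Positive gap penalties; a length-k gap costs
        ``gap_open + (k - 1) * gap_extend``.
    evalue_cutoff : float
        Hits with larger e-value are treated as "no hit".
    karlin_lambda, karlin_k : float
        Karlin–Altschul statistics constants for the chosen scoring
        (defaults: standard gapped BLOSUM62, open 11 / extend 1).
    """

    substitution_matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    evalue_cutoff: float = 1e-10
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041

    def __post_init__(self) -> None:
        if self.evalue_cutoff <= 0:
            raise AlignmentError("evalue_cutoff must be > 0")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise AlignmentError("gap penalties must be > 0")


@dataclass(frozen=True)
class AlignmentHit:
    """Best local alignment between a query and a subject protein."""

    query_id: str
    subject_id: str
    raw_score: float
    percent_identity: float
    percent_similarity: float
    aligned_length: int
    e_value: float

    def __post_init__(self) -> None:
        if self.aligned_length < 1:
            raise AlignmentError("aligned_length must be >= 1")
        if self.percent_identity > self.percent_similarity + 1e-9:
            raise AlignmentError("identity cannot exceed similarity")


@lru_cache(maxsize=8)
def load_matrix(name: str):
    return substitution_matrices.load(name)


@lru_cache(maxsize=32)
def make_aligner(params: SearchParams, mode: str = "local") -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = load_matrix(params.substitution_matrix)
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def _check_sequence(seq: str, label: str) -> None:
    if not seq:
        raise AlignmentError(f"{label}: empty sequence")
    bad = set(seq) - PROTEIN_ALPHABET
    if bad:
        raise AlignmentError(f"{label}: unknown residue characters {sorted(bad)}")


def e_value(score: float, m: int, n: int, params: SearchParams) -> float:
    """Karlin–Altschul e-value for a raw score on an m x n search space."""
    return params.karlin_k * m * n * math.exp(-params.karlin_lambda * score)


def alignment_identity_similarity(alignment, matrix) -> tuple[int, int, int]:
    """Count (identities, positives, columns) of a Biopython alignment.

    Columns include internal gap columns of the local alignment, matching
    BLAST's alignment-length convention.
    """
    target, query = alignment.sequences
    identities = 0
    positives = 0
    columns = 0
    blocks = alignment.aligned
    prev_t_end = prev_q_end = None
    for (t0, t1), (q0, q1) in zip(blocks[0], blocks[1]):
        if prev_t_end is not None:  # gap columns between aligned blocks
            columns += (t0 - prev_t_end) + (q0 - prev_q_end)
        for i in range(t1 - t0):
            a, b = target[t0 + i], query[q0 + i]
            columns += 1
            if a == b:
                identities += 1
            try:
                if matrix[a, b] > 0:
                    positives += 1
            except KeyError:
                pass
        prev_t_end, prev_q_end = t1, q1
    return identities, positives, columns


def align_protein_pair(
    a: ProteinRecord, b: ProteinRecord, params: SearchParams | None = None
) -> AlignmentHit:
    """Optimal local alignment of two proteins.

    Percent identity and percent similarity are taken over the alignment
    columns of the best-scoring local alignment; the e-value uses the full
    sequence lengths as the search-space dimensions.
    """
    params = params or SearchParams()
    _check_sequence(a.residues, a.id)
    _check_sequence(b.residues, b.id)
    aligner = make_aligner(params)
    alignment = next(iter(aligner.align(a.residues, b.residues)))
    matrix = load_matrix(params.substitution_matrix)
    identities, positives, columns = alignment_identity_similarity(
        alignment, matrix
    )
    if columns == 0:
        # best local alignment is empty (all-negative scoring); report a
        # zero-similarity single-column hit
        return AlignmentHit(a.id, b.id, 0.0, 0.0, 0.0, 1, e_value(0.0, len(a), len(b), params))
    return AlignmentHit(
        query_id=a.id,
        subject_id=b.id,
        raw_score=float(alignment.score),
        percent_identity=100.0 * identities / columns,
        percent_similarity=100.0 * positives / columns,
        aligned_length=columns,
        e_value=e_value(float(alignment.score), len(a), len(b), params),
    )


def global_align(a: str, b: str, params: SearchParams | None = None):
    """Global (Needleman–Wunsch) alignment; returns the aligned strings."""
    params = params or SearchParams()
    _check_sequence(a, "sequence a")
    _check_sequence(b, "sequence b")
    aligner = make_aligner(params, mode="global")
    alignment = next(iter(aligner.align(a, b)))
    t_aln = []
    q_aln = []
    ti = qi = 0
    for (t0, t1), (q0, q1) in zip(alignment.aligned[0], alignment.aligned[1]):
        while ti < t0:
            t_aln.append(a[ti])
            q_aln.append("-")
            ti += 1
        while qi < q0:
            t_aln.append("-")
            q_aln.append(b[qi])
            qi += 1
        t_aln.append(a[t0:t1])
        q_aln.append(b[q0:q1])
        ti, qi = t1, q1
    while ti < len(a):
        t_aln.append(a[ti])
        q_aln.append("-")
        ti += 1
    while qi < len(b):
        t_aln.append("-")
        q_aln.append(b[qi])
        qi += 1
    return "".join(t_aln), "".join(q_aln), float(alignment.score)
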