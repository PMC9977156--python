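"""Affine-gap local protein alignment used throughout the pipeline.

The aligner wraps :class:`Bio.Align.PairwiseAligner` in local mode with
BLOSUM62 scoring.  Gap costs follow the BLAST convention: a gap of length
``k`` costs ``gap_open + k * gap_extend`` (default 11/1), which maps onto
biopython's open/extend scores as ``-(gap_open + gap_extend)`` for the
first gapped residue and ``-gap_extend`` thereafter.

Percent identity is computed over aligned columns only (columns where both
sequences have a residue), matching the convention used for the >70%
reciprocal-identity classification rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = ["AlignmentResult", "local_align", "make_aligner", "blosum62"]


@lru_cache(maxsize=None)
def blosum62():
    return substitution_matrices.load("BLOSUM62")


@lru_cache(maxsize=8)
def make_aligner(gap_open: int = 11, gap_extend: int = 1) -> PairwiseAligner:
    """Local BLOSUM62 aligner with BLAST-convention affine gap costs."""
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = blosum62()
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


@dataclass(frozen=True)
class AlignmentResult:
    """Best local alignment of a query against a target."""

    score: float
    identity_pct: float
    query_aln: str
    target_aln: str
    # 0-based half-open spans of the aligned region on each sequence.
    query_span: tuple[int, int]
    target_span: tuple[int, int]

    @property
    def empty(self) -> bool:
        return self.score <= 0.0


_EMPTY = AlignmentResult(0.0, 0.0, "", "", (0, 0), (0, 0))


def _identity_from_alignment(aln) -> tuple[float, int, int]:
    counts = aln.counts()
    comparable = counts.identities + counts.mismatches
    if comparable == 0:
        return 0.0, 0, 0
    return 100.0 * counts.identities / comparable, counts.identities, comparable


def local_align(
    query_aa: str,
    target_aa: str,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> AlignmentResult:
    """Optimal affine-gap local alignment of two protein sequences.

    Returns an :class:`AlignmentResult`; a pair with no positive-scoring
    local alignment yields score 0 and an empty alignment.
    """
    if not query_aa or not target_aa:
        raise ValueError("local_align requires non-empty sequences")
    aligner = make_aligner(gap_open, gap_extend)
    alignments = aligner.align(target_aa, query_aa)
    if alignments.score <= 0 or len(alignments) == 0:
        return _EMPTY
    best = alignments[0]
    identity, _, _ = _identity_from_alignment(best)
    tblocks, qblocks = best.aligned
    tspan = (int(tblocks[0][0]), int(tblocks[-1][1]))
    qspan = (int(qblocks[0][0]), int(qblocks[-1][1]))
    q_aln, t_aln = _gapped_strings(query_aa, target_aa, qblocks, tblocks)
    return AlignmentResult(
        score=float(alignments.score),
        identity_pct=identity,
        query_aln=q_aln,
        target_aln=t_aln,
        query_span=qspan,
        target_span=tspan,
    )


def _gapped_strings(query, target, qblocks, tblocks) -> tuple[str, str]:
    q_parts: list[str] = []
    t_parts: list[str] = []
    prev_q = qblocks[0][0]
    prev_t = tblocks[0][0]
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        if qs > prev_q:  # insertion in query relative to target
            q_parts.append(query[prev_q:qs])
            t_parts.append("-" * (qs - prev_q))
        if ts > prev_t:
            q_parts.append("-" * (ts - prev_t))
            t_parts.append(target[prev_t:ts])
        q_parts.append(query[qs:qe])
        t_parts.append(target[ts:te])
        prev_q, prev_t = qe, te
    return "".join(q_parts), "".join(t_parts)


def align_score(query_aa: str, target_aa: str,
                gap_open: int = 11, gap_extend: int = 1) -> float:
    """Score-only local alignment (no traceback); faster than
    :func:`local_align` when only the score is needed."""
    aligner = make_aligner(gap_open, gap_extend)
    return float(aligner.score(target_aa, query_aa))
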