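"""Candidate homeobox locus detection in genomic DNA.

The scan emulates a translated homology search (TBLASTN-style): each
contig is translated in all six reading frames, exact amino-acid k-mer
seeds shared with the reference homeodomains gate a full affine-gap local
alignment, and hit significance is assessed with Karlin-Altschul E-values
using fixed gapped BLOSUM62 constants (lambda = 0.267, K = 0.041).

Overlapping hits (from any query, either strand) are then collapsed so
that each homeobox locus is reported once, represented by its longest
alignment; finally a permissive rescan of 1-kb flanks around each locus
recovers tandem neighbors that the strict first pass missed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

from .align import AlignmentResult, local_align, make_aligner
from .catalog import ReferenceSet

__all__ = [
    "RawHit",
    "Locus",
    "ScanParams",
    "translate_six_frames",
    "scan_genome",
    "scan_sequences",
    "merge_overlapping_hits",
    "rescan_flanks",
    "find_loci",
    "read_genome",
]

logger = logging.getLogger(__name__)

# Gapped BLOSUM62 Karlin-Altschul parameters (11/1 gap costs).
KA_LAMBDA = 0.267
KA_K = 0.041

DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
VALID_DNA = set("ACGTN")


@dataclass(frozen=True)
class RawHit:
    """One translated local-alignment hit in genomic coordinates.

    ``start``/``end`` are 0-based half-open positions on the forward
    strand of ``contig``; ``frame`` is the 0-2 reading-frame offset on the
    strand given by ``strand``.
    """

    contig: str
    start: int
    end: int
    strand: str
    frame: int
    query_id: str
    score: float
    bitscore: float
    evalue: float
    identity_pct: float
    aligned_query_span: tuple[int, int]
    target_aa: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Locus:
    """A candidate homeobox locus: one merged group of overlapping hits.

    ``representative_hit`` (the longest aligned span) fixes the locus
    interval and translated sequence; ``best_hit`` (the highest-scoring
    supporting hit) carries the best forward query, which downstream
    classification compares against the reciprocal search.
    """

    contig: str
    start: int
    end: int
    strand: str
    representative_hit: RawHit
    supporting_hits: int
    dna: str = ""
    aa: str = ""
    best_hit: RawHit | None = None

    def __post_init__(self) -> None:
        if self.best_hit is None:
            self.best_hit = self.representative_hit


@dataclass(frozen=True)
class ScanParams:
    """Tunable parameters of the translated scan."""

    evalue_max: float = 1e-5
    word_size: int = 5
    gap_open: int = 11
    gap_extend: int = 1
    window_pad: int = 12
    exhaustive: bool = False  # force full DP on every frame, no seeding
    flank: int = 1000
    flank_evalue_max: float = 1e-3


# ---------------------------------------------------------------------------
# Translation


def _validate_dna(dna: str) -> str:
    dna = dna.upper()
    bad = set(dna) - VALID_DNA
    if bad:
        raise ValueError(f"non-IUPAC nucleotide characters: {sorted(bad)}")
    return dna


@dataclass(frozen=True)
class Frame:
    """One translated reading frame with its genomic coordinate map."""

    strand: str
    offset: int  # 0-2 shift on the translated strand
    aa: str
    seq_len: int  # length of the source nucleotide sequence

    def codon_interval(self, aa_start: int, aa_end: int) -> tuple[int, int]:
        """Forward-strand nucleotide interval covered by aa [start, end)."""
        nt_start = self.offset + 3 * aa_start
        nt_end = self.offset + 3 * aa_end
        if self.strand == "+":
            return nt_start, nt_end
        return self.seq_len - nt_end, self.seq_len - nt_start


def translate_six_frames(dna: str) -> list[Frame]:
    """Translate a nucleotide sequence in all six reading frames.

    Codons containing N translate to X.  Each frame records how residue
    indices map back to forward-strand codon positions.
    """
    dna = _validate_dna(dna)
    if len(dna) < 3:
        raise ValueError("sequence shorter than one codon")
    frames: list[Frame] = []
    fwd = Seq(dna)
    rev = fwd.reverse_complement()
    for strand, seq in (("+", fwd), ("-", rev)):
        for offset in range(3):
            sub = seq[offset : offset + 3 * ((len(seq) - offset) // 3)]
            aa = str(sub.translate())
            frames.append(Frame(strand=strand, offset=offset, aa=aa,
                                seq_len=len(dna)))
    return frames


# ---------------------------------------------------------------------------
# Seeding

_AA_CODE_BASE = 27  # A-Z plus one sentinel for anything else


def _encode_aa(aa: str) -> np.ndarray:
    codes = np.frombuffer(aa.encode("ascii"), dtype=np.uint8).astype(np.int64)
    codes = codes - ord("A")
    # stops ('*'), gaps, or out-of-range bytes -> sentinel 26; X stays its
    # own letter code but query k-mers containing X are never indexed.
    codes[(codes < 0) | (codes > 25)] = 26
    return codes


def _kmer_hashes(codes: np.ndarray, k: int) -> np.ndarray:
    if len(codes) < k:
        return np.empty(0, dtype=np.int64)
    h = np.zeros(len(codes) - k + 1, dtype=np.int64)
    for j in range(k):
        h += codes[j : len(codes) - k + 1 + j] * (_AA_CODE_BASE ** (k - 1 - j))
    return h


class _SeedIndex:
    """Exact amino-acid k-mer index over the reference queries."""

    def __init__(self, refset: ReferenceSet, k: int):
        self.k = k
        self.table: dict[int, list[tuple[int, int]]] = {}
        self.queries = list(refset.entries)
        x_code = ord("X") - ord("A")
        for qi, entry in enumerate(self.queries):
            codes = _encode_aa(entry.sequence)
            hashes = _kmer_hashes(codes, k)
            for off, h in enumerate(hashes):
                window = codes[off : off + k]
                if np.any(window == 26) or np.any(window == x_code):
                    continue
                self.table.setdefault(int(h), []).append((qi, off))
        self.hash_array = np.fromiter(self.table.keys(), dtype=np.int64,
                                      count=len(self.table))
        self.hash_array.sort()

    def candidate_windows(self, frame_codes: np.ndarray) -> dict[int, list[int]]:
        """Map query index -> candidate target aa start positions."""
        hashes = _kmer_hashes(frame_codes, self.k)
        if hashes.size == 0:
            return {}
        mask = np.isin(hashes, self.hash_array, assume_unique=False)
        positions = np.nonzero(mask)[0]
        out: dict[int, list[int]] = {}
        for pos in positions:
            for qi, off in self.table[int(hashes[pos])]:
                out.setdefault(qi, []).append(int(pos) - off)
        return out


def _merge_starts(starts: list[int], span: int) -> list[tuple[int, int]]:
    """Collapse candidate alignment start positions into [start, end) aa
    windows, merging windows that overlap."""
    starts = sorted(set(starts))
    windows: list[tuple[int, int]] = []
    for s in starts:
        lo, hi = s, s + span
        if windows and lo <= windows[-1][1]:
            windows[-1] = (windows[-1][0], max(windows[-1][1], hi))
        else:
            windows.append((lo, hi))
    return windows


# ---------------------------------------------------------------------------
# E-values


def bitscore_from_raw(raw: float) -> float:
    return (KA_LAMBDA * raw - math.log(KA_K)) / math.log(2.0)


def evalue_from_bitscore(bitscore: float, search_space: float) -> float:
    return search_space * 2.0 ** (-bitscore)


def min_raw_score(evalue_max: float, search_space: float) -> float:
    """Smallest raw alignment score that can reach ``evalue_max``."""
    bits = math.log2(search_space / evalue_max)
    return (bits * math.log(2.0) + math.log(KA_K)) / KA_LAMBDA


# ---------------------------------------------------------------------------
# Scan


def read_genome(path: str | Path) -> dict[str, str]:
    """Read a genome FASTA into a dict of upper-case contig sequences."""
    genome = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(path), "fasta")
    }
    return genome


def scan_genome(
    genome: str | Path | dict[str, str],
    refset: ReferenceSet,
    params: ScanParams = ScanParams(),
) -> list[RawHit]:
    """Scan a genome (FASTA path or contig dict) for homeodomain hits.

    Every reported hit satisfies ``evalue <= params.evalue_max`` with the
    E-value computed over search space = total genome length x query
    length.  An empty genome yields an empty list with a warning.
    """
    if not isinstance(genome, dict):
        genome = read_genome(genome)
    if not genome:
        logger.warning("empty genome: no contigs to scan")
        return []
    if len(refset) == 0:
        raise ValueError("empty reference set")
    total_len = sum(len(s) for s in genome.values())
    return scan_sequences(genome, refset, params, search_len=total_len,
                          evalue_max=params.evalue_max)


def scan_sequences(
    contigs: dict[str, str],
    refset: ReferenceSet,
    params: ScanParams,
    search_len: int,
    evalue_max: float,
    offsets: dict[str, int] | None = None,
) -> list[RawHit]:
    """Core scan over explicit sequences.

    ``search_len`` fixes the nucleotide component of the E-value search
    space (the full genome length, even when rescanning subregions);
    ``offsets`` shifts reported coordinates (used by the flank rescan,
    where sequences are excised subregions of a larger contig).
    """
    index = _SeedIndex(refset, params.word_size)
    aligner = make_aligner(params.gap_open, params.gap_extend)
    hits: list[RawHit] = []
    for contig, seq in contigs.items():
        if len(seq) < 3:
            continue
        shift = (offsets or {}).get(contig, 0)
        for frame in translate_six_frames(seq):
            codes = _encode_aa(frame.aa)
            if params.exhaustive:
                candidates = {
                    qi: [0] for qi in range(len(index.queries))
                }
                full = True
            else:
                candidates = index.candidate_windows(codes)
                full = False
            for qi, starts in candidates.items():
                entry = index.queries[qi]
                qlen = len(entry.sequence)
                cutoff = min_raw_score(evalue_max, search_len * qlen)
                if full:
                    windows = [(0, len(frame.aa))]
                else:
                    span = qlen + params.window_pad
                    windows = [
                        (max(0, lo - params.window_pad),
                         min(len(frame.aa), hi))
                        for lo, hi in _merge_starts(starts, span)
                    ]
                for lo, hi in windows:
                    target = frame.aa[lo:hi]
                    if not target:
                        continue
                    score = aligner.score(target, entry.sequence)
                    if score < cutoff:
                        continue
                    res = local_align(entry.sequence, target,
                                      params.gap_open, params.gap_extend)
                    if res.empty:
                        continue
                    bits = bitscore_from_raw(res.score)
                    ev = evalue_from_bitscore(bits, search_len * qlen)
                    if ev > evalue_max:
                        continue
                    ts, te = res.target_span
                    g_start, g_end = frame.codon_interval(lo + ts, lo + te)
                    hits.append(RawHit(
                        contig=contig,
                        start=g_start + shift,
                        end=g_end + shift,
                        strand=frame.strand,
                        frame=frame.offset,
                        query_id=entry.id,
                        score=res.score,
                        bitscore=bits,
                        evalue=ev,
                        identity_pct=res.identity_pct,
                        aligned_query_span=res.query_span,
                        target_aa=res.target_aln.replace("-", ""),
                    ))
    hits.sort(key=lambda h: (h.contig, h.start, h.end, h.query_id))
    return hits


# ---------------------------------------------------------------------------
# Merging


def merge_overlapping_hits(
    hits: Sequence[RawHit],
    genome: dict[str, str] | None = None,
) -> list[Locus]:
    """Collapse hits whose genomic intervals overlap (>= 1 bp, either
    strand, transitively) into one locus each.

    The representative is the hit with the longest aligned genomic span,
    ties broken by higher score then lexicographically smaller query id;
    the locus takes the representative's interval, so loci from distinct
    overlap groups never overlap.
    """
    loci: list[Locus] = []
    ordered = sorted(hits, key=lambda h: (h.contig, h.start, h.end))
    group: list[RawHit] = []
    group_end = -1

    def close_group() -> None:
        if not group:
            return
        rep = min(group, key=lambda h: (-h.length, -h.score, h.query_id))
        best = min(group, key=lambda h: (-h.score, -h.length, h.query_id))
        locus = Locus(
            contig=rep.contig,
            start=rep.start,
            end=rep.end,
            strand=rep.strand,
            representative_hit=rep,
            supporting_hits=len(group),
            aa=rep.target_aa,
            best_hit=best,
        )
        if genome is not None and rep.contig in genome:
            dna = genome[rep.contig][rep.start:rep.end]
            if rep.strand == "-":
                dna = dna.translate(DNA_COMPLEMENT)[::-1]
            locus.dna = dna
        loci.append(locus)

    current_contig = None
    for hit in ordered:
        if hit.contig != current_contig or hit.start >= group_end:
            close_group()
            group = [hit]
            group_end = hit.end
            current_contig = hit.contig
        else:
            group.append(hit)
            group_end = max(group_end, hit.end)
    close_group()
    return loci


# ---------------------------------------------------------------------------
# Flank rescan


def rescan_flanks(
    genome: dict[str, str],
    loci: Sequence[Locus],
    refset: ReferenceSet,
    params: ScanParams = ScanParams(),
) -> list[RawHit]:
    """Permissively re-align the reference set against each locus extended
    by ``params.flank`` bp on both sides (clamped at contig ends).

    Returns newly found hits that do not overlap any existing locus; the
    caller merges them together with the original hits in a second round.
    """
    total_len = sum(len(s) for s in genome.values())
    regions: dict[str, str] = {}
    offsets: dict[str, int] = {}
    region_spans: list[tuple[str, int, int]] = []
    for i, locus in enumerate(loci):
        seq = genome.get(locus.contig)
        if seq is None:
            continue
        lo = max(0, locus.start - params.flank)
        hi = min(len(seq), locus.end + params.flank)
        key = f"__region{i}__{locus.contig}"
        regions[key] = seq[lo:hi]
        offsets[key] = lo
        region_spans.append((key, lo, hi))
    if not regions:
        return []
    raw = scan_sequences(regions, refset, params, search_len=total_len,
                         evalue_max=params.flank_evalue_max,
                         offsets=offsets)
    # restore real contig names and drop hits overlapping existing loci
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for locus in loci:
        by_contig.setdefault(locus.contig, []).append((locus.start, locus.end))
    new_hits: list[RawHit] = []
    seen: set[tuple] = set()
    for hit in raw:
        contig = hit.contig.split("__", 2)[2]
        hit = replace(hit, contig=contig)
        if any(hit.start < e and s < hit.end
               for s, e in by_contig.get(contig, [])):
            continue
        key = (contig, hit.start, hit.end, hit.strand, hit.query_id)
        if key in seen:  # same flank found from two adjacent loci
            continue
        seen.add(key)
        new_hits.append(hit)
    new_hits.sort(key=lambda h: (h.contig, h.start, h.end, h.query_id))
    return new_hits


# ---------------------------------------------------------------------------
# Pipeline convenience


def find_loci(
    genome: str | Path | dict[str, str],
    refset: ReferenceSet,
    params: ScanParams = ScanParams(),
) -> tuple[list[Locus], list[RawHit]]:
    """Full detection pipeline: scan, merge, flank rescan, merge again.

    Returns the final locus list and all retained raw hits.
    """
    if not isinstance(genome, dict):
        genome = read_genome(genome)
    hits = scan_genome(genome, refset, params)
    loci = merge_overlapping_hits(hits, genome)
    extra = rescan_flanks(genome, loci, refset, params)
    if extra:
        hits = sorted(hits + extra,
                      key=lambda h: (h.contig, h.start, h.end, h.query_id))
        loci = merge_overlapping_hits(hits, genome)
    return loci, hits
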