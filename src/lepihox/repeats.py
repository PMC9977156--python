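"""Transposable-element density and Shx-region enrichment testing.

Repeat annotations (BED or RepeatMasker ``.out``) are reduced to the four
major TE classes (LINE, SINE, LTR, DNA; everything else is "other") and
elements shorter than 50 bp are dropped at load time.  Densities are the
fraction of bases covered per 5-kb window; enrichment of each class in
the Shx gene region relative to the remaining Hox cluster (lab excluded)
is tested with a two-sided Wilcoxon rank-sum test, Bonferroni-corrected
across the four classes, with a direction gate requiring the Shx-region
median to exceed the rest-of-cluster median.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import mannwhitneyu

from .clusters import ClusterArchitecture, shx_copy_table

__all__ = [
    "RepeatAnnotation",
    "EnrichmentResult",
    "TE_CLASSES",
    "load_repeats",
    "window_density",
    "wilcoxon_rank_sum",
    "shx_enrichment",
    "region_enrichment",
]

logger = logging.getLogger(__name__)

TE_CLASSES = ("LINE", "SINE", "LTR", "DNA")
MIN_REPEAT_LEN = 50
WINDOW = 5000
MIN_TERMINAL_WINDOW = 2500
ALPHA = 0.05
BONFERRONI_M = 4


def classify_te(family_field: str) -> str:
    """Map a repeat class/family string (e.g. ``LINE/CR1``) to a broad TE
    class; unrecognized prefixes (Simple_repeat, Low_complexity, ...) map
    to ``other``."""
    prefix = family_field.split("/", 1)[0].strip()
    return prefix if prefix in TE_CLASSES else "other"


@dataclass
class RepeatInterval:
    contig: str
    start: int
    end: int
    te_class: str
    name: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RepeatAnnotation:
    intervals: list[RepeatInterval]
    dropped_short: int = 0

    def by_class(self, contig: str, te_class: str) -> np.ndarray:
        """(n, 2) array of [start, end) intervals of one class on one
        contig, sorted by start."""
        ivs = sorted(
            (iv.start, iv.end)
            for iv in self.intervals
            if iv.contig == contig and iv.te_class == te_class
        )
        return np.array(ivs, dtype=np.int64).reshape(-1, 2)


def _looks_like_rm_out(lines: list[str]) -> bool:
    head = " ".join(lines[:3])
    return "SW" in head and "perc" in head


def load_repeats(path: str | Path) -> RepeatAnnotation:
    """Load repeats from BED (contig, start, end, class[/family]) or
    RepeatMasker ``.out`` format, auto-detected from the header.

    Intervals shorter than 50 bp are dropped; the drop count is logged
    and recorded on the returned annotation.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    non_empty = [l for l in lines if l.strip()]
    if not non_empty:
        return RepeatAnnotation([], 0)
    intervals: list[RepeatInterval] = []
    dropped = 0
    if _looks_like_rm_out(non_empty):
        for line in non_empty:
            fields = line.split()
            if not fields or not fields[0].isdigit():
                continue  # header / separator lines
            if len(fields) < 11:
                raise ValueError(f"malformed RepeatMasker row: {line!r}")
            contig = fields[4]
            start = int(fields[5]) - 1  # .out is 1-based inclusive
            end = int(fields[6])
            name = fields[9]
            te_class = classify_te(fields[10])
            if end - start < MIN_REPEAT_LEN:
                dropped += 1
                continue
            intervals.append(RepeatInterval(contig, start, end, te_class, name))
    elif non_empty[0].count("\t") >= 2 or len(non_empty[0].split()) >= 3:
        for line in non_empty:
            if line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            contig, start, end = fields[0], int(fields[1]), int(fields[2])
            label = fields[3] if len(fields) > 3 else "other"
            te_class = classify_te(label)
            if end - start < MIN_REPEAT_LEN:
                dropped += 1
                continue
            intervals.append(RepeatInterval(contig, start, end, te_class, label))
    else:
        raise ValueError(f"unrecognized repeat annotation format: {path}")
    if dropped:
        logger.info("dropped %d repeat intervals < %d bp", dropped,
                    MIN_REPEAT_LEN)
    return RepeatAnnotation(intervals, dropped)


def merged_coverage(intervals: np.ndarray, lo: int, hi: int) -> int:
    """Total bases of [lo, hi) covered by the union of intervals."""
    if intervals.size == 0:
        return 0
    starts = np.clip(intervals[:, 0], lo, hi)
    ends = np.clip(intervals[:, 1], lo, hi)
    keep = ends > starts
    if not keep.any():
        return 0
    starts, ends = starts[keep], ends[keep]
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    total = 0
    cur_s, cur_e = int(starts[0]), int(ends[0])
    for s, e in zip(starts[1:], ends[1:]):
        if s <= cur_e:
            cur_e = max(cur_e, int(e))
        else:
            total += cur_e - cur_s
            cur_s, cur_e = int(s), int(e)
    total += cur_e - cur_s
    return total


def _windows(start: int, end: int, window: int) -> list[tuple[int, int]]:
    """Non-overlapping tiling from ``start``; terminal partial window kept
    iff >= MIN_TERMINAL_WINDOW bp."""
    out = []
    pos = start
    while pos + window <= end:
        out.append((pos, pos + window))
        pos += window
    if end - pos >= MIN_TERMINAL_WINDOW:
        out.append((pos, end))
    return out


def window_density(
    repeats: RepeatAnnotation,
    region: tuple[str, int, int],
    te_class: str,
    window: int = WINDOW,
) -> np.ndarray:
    """Per-window fraction-of-bases density of one TE class over a region.

    Windows tile the region from its start; a terminal partial window is
    kept only when at least 2,500 bp wide, with the actual width as
    denominator.
    """
    contig, start, end = region
    if end - start < MIN_TERMINAL_WINDOW:
        raise ValueError(
            f"region shorter than {MIN_TERMINAL_WINDOW} bp: {end - start}"
        )
    intervals = repeats.by_class(contig, te_class)
    densities = [
        merged_coverage(intervals, lo, hi) / (hi - lo)
        for lo, hi in _windows(start, end, window)
    ]
    return np.array(densities, dtype=float)


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when the combined sample is small
    (n + m <= 20) and tie-free, otherwise the normal approximation with
    tie and continuity corrections.  Returns (U statistic of x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    tie_free = len(np.unique(combined)) == len(combined)
    method = "exact" if (len(combined) <= 20 and tie_free) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method,
                       use_continuity=True)
    return float(res.statistic), float(res.pvalue)


@dataclass
class EnrichmentResult:
    te_class: str
    shx_densities: np.ndarray
    rest_densities: np.ndarray
    U: float
    p_raw: float
    p_bonferroni: float
    enriched: bool

    @property
    def median_shx(self) -> float:
        return float(np.median(self.shx_densities))

    @property
    def median_rest(self) -> float:
        return float(np.median(self.rest_densities))


def region_enrichment(
    repeats: RepeatAnnotation,
    contig: str,
    cluster_region: tuple[int, int],
    shx_region: tuple[int, int],
    window: int = WINDOW,
    alpha: float = ALPHA,
    m: int = BONFERRONI_M,
) -> list[EnrichmentResult]:
    """Test each TE class for enriched density in the Shx region versus
    the remaining cluster.

    The Shx region and each remaining cluster segment (the stretches on
    either side of the Shx region) are tiled independently from their own
    edges.  ``enriched`` requires Bonferroni-corrected p < alpha AND a
    higher Shx-region median (direction gate: the test is for increased
    density, not any difference).
    """
    c_lo, c_hi = cluster_region
    s_lo, s_hi = shx_region
    if not (c_lo <= s_lo < s_hi <= c_hi):
        raise ValueError("shx_region must lie within cluster_region")
    rest_segments = []
    if s_lo - c_lo >= MIN_TERMINAL_WINDOW:
        rest_segments.append((c_lo, s_lo))
    if c_hi - s_hi >= MIN_TERMINAL_WINDOW:
        rest_segments.append((s_hi, c_hi))
    if not rest_segments:
        raise ValueError("no cluster sequence outside the Shx region")
    results = []
    for te_class in TE_CLASSES:
        shx_d = window_density(repeats, (contig, s_lo, s_hi), te_class, window)
        rest_d = np.concatenate([
            window_density(repeats, (contig, lo, hi), te_class, window)
            for lo, hi in rest_segments
        ])
        U, p = wilcoxon_rank_sum(shx_d, rest_d)
        p_bonf = min(1.0, p * m)
        enriched = bool(
            p_bonf < alpha and np.median(shx_d) > np.median(rest_d)
        )
        results.append(EnrichmentResult(
            te_class=te_class,
            shx_densities=shx_d,
            rest_densities=rest_d,
            U=U,
            p_raw=p,
            p_bonferroni=p_bonf,
            enriched=enriched,
        ))
    return results


def shx_enrichment(
    repeats: RepeatAnnotation,
    arch: ClusterArchitecture,
    window: int = WINDOW,
    alpha: float = ALPHA,
    m: int = BONFERRONI_M,
) -> list[EnrichmentResult]:
    """Fig-5-style enrichment test on a built Hox architecture.

    The cluster region runs from the outermost member coordinates (lab is
    never a member, so it is excluded by construction); the Shx region is
    the first-to-last Shx locus interval and must be defined.
    """
    if arch.cluster_name != "HOX" or not arch.members:
        raise ValueError("requires a non-empty HOX architecture")
    table = shx_copy_table(arch)
    if table.shx_region is None:
        raise ValueError("shx_region undefined: no Shx loci in cluster")
    cluster_region = (
        min(m_.start for m_ in arch.members),
        max(m_.end for m_ in arch.members),
    )
    return region_enrichment(
        repeats, arch.contig, cluster_region, table.shx_region,
        window=window, alpha=alpha, m=m,
    )
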