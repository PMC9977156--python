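"""Family assignment of candidate homeobox loci.

Each locus is classified by a reciprocal search: the translated locus
sequence is locally aligned back against the full homeodomain reference
set, and the locus is ASSIGNED to a family only when the best reverse hit
belongs to the same family as the forward query that discovered the locus
AND the reverse alignment identity is strictly greater than 70%.
Everything else is flagged DIVERGENT_UNCLASSIFIED and exported for
external phylogenetic placement.

Reciprocity is evaluated at the family level (the reference set holds
several species per family, so requiring the exact same sequence would be
overly strict).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .align import local_align, make_aligner
from .catalog import CATALOG, SHX_FAMILIES, ReferenceSet
from .scan import Locus

__all__ = [
    "ClassifiedLocus",
    "CensusResult",
    "IDENTITY_THRESHOLD",
    "reciprocal_classify",
    "classify_all",
    "export_divergent",
    "census",
]

logger = logging.getLogger(__name__)

IDENTITY_THRESHOLD = 70.0  # strict ">": exactly 70.0 stays divergent

ASSIGNED = "ASSIGNED"
DIVERGENT = "DIVERGENT_UNCLASSIFIED"


@dataclass
class ClassifiedLocus:
    """A locus plus its family-assignment outcome."""

    locus: Locus
    forward_family: str
    reverse_family: str
    identity_pct: float
    status: str
    family: str | None

    @property
    def is_assigned(self) -> bool:
        return self.status == ASSIGNED


def _family_of(query_id: str) -> str:
    return query_id.split("|", 1)[0]


def reciprocal_classify(
    locus: Locus,
    refset: ReferenceSet,
    identity_threshold: float = IDENTITY_THRESHOLD,
) -> ClassifiedLocus:
    """Classify one locus by reverse local alignment against the full
    reference set.

    The best reverse hit is chosen by score, ties broken by reference id,
    so classification is deterministic and independent of input order.
    """
    if len(refset) == 0:
        raise ValueError("empty reference set")
    if not locus.aa:
        raise ValueError("locus has no translated sequence")
    aligner = make_aligner()
    best_entry = None
    best_score = float("-inf")
    for entry in refset.entries:
        score = aligner.score(entry.sequence, locus.aa)
        if score > best_score or (
            score == best_score
            and best_entry is not None
            and entry.id < best_entry.id
        ):
            best_score = score
            best_entry = entry
    assert best_entry is not None
    res = local_align(locus.aa, best_entry.sequence)
    forward = locus.best_hit or locus.representative_hit
    forward_family = _family_of(forward.query_id)
    reverse_family = best_entry.family
    assigned = (
        forward_family == reverse_family
        and res.identity_pct > identity_threshold
    )
    return ClassifiedLocus(
        locus=locus,
        forward_family=forward_family,
        reverse_family=reverse_family,
        identity_pct=res.identity_pct,
        status=ASSIGNED if assigned else DIVERGENT,
        family=forward_family if assigned else None,
    )


def classify_all(
    loci: Sequence[Locus],
    refset: ReferenceSet,
    identity_threshold: float = IDENTITY_THRESHOLD,
) -> list[ClassifiedLocus]:
    return [reciprocal_classify(l, refset, identity_threshold) for l in loci]


def export_divergent(
    classified: Iterable[ClassifiedLocus], path: str | Path
) -> int:
    """Write DIVERGENT_UNCLASSIFIED locus proteins to FASTA for external
    tree building; headers carry ``contig:start-end`` provenance.

    Returns the number of records written (zero divergent loci yields an
    empty file)."""
    n = 0
    with open(path, "w") as fh:
        for cl in classified:
            if cl.status != DIVERGENT:
                continue
            loc = cl.locus
            fh.write(
                f">{loc.contig}:{loc.start}-{loc.end}({loc.strand}) "
                f"forward={cl.forward_family} reverse={cl.reverse_family} "
                f"identity={cl.identity_pct:.1f}\n{loc.aa}\n"
            )
            n += 1
    return n


@dataclass
class CensusResult:
    """Per-family, per-class, and aggregate homeobox locus counts."""

    per_family: pd.Series
    per_class: pd.Series
    total: int
    shx_total: int
    zen_shx_total: int
    divergent: int

    def to_frame(self) -> pd.DataFrame:
        df = self.per_family.rename("count").to_frame()
        df["hclass"] = [CATALOG[f].hclass for f in df.index]
        return df


def census(classified: Sequence[ClassifiedLocus]) -> CensusResult:
    """Count assigned loci per family and per class.

    The census counts loci exactly as detected: functional genes, partial
    genes, and pseudogenes are not distinguished.  Divergent loci are
    tallied separately and excluded from family counts.
    """
    family_counts = {name: 0 for name in CATALOG}
    divergent = 0
    for cl in classified:
        if cl.is_assigned:
            family_counts[cl.family] += 1
        else:
            divergent += 1
    per_family = pd.Series(family_counts, name="count")
    hclass = pd.Series({name: fam.hclass for name, fam in CATALOG.items()})
    per_class = per_family.groupby(hclass).sum()
    shx_total = int(sum(family_counts[f] for f in SHX_FAMILIES))
    return CensusResult(
        per_family=per_family,
        per_class=per_class,
        total=int(per_family.sum()),
        shx_total=shx_total,
        zen_shx_total=shx_total + family_counts["zen"],
        divergent=divergent,
    )
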