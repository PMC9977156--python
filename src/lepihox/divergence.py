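"""Pairwise homeodomain identity contrasts between a focal clade and
background species.

For each gene family, every focal-versus-background species pair identity
is compared against every background-versus-background pair identity with
a two-sided Wilcoxon rank-sum test.  A significantly lower focal identity
distribution indicates accelerated homeodomain sequence evolution in the
focal clade (the pattern seen for ShxA-C after ShxD loss in Lycaenidae).

Alignments are taken as input (pre-aligned, equal-length protein strings,
``-`` for gaps); identity is computed over columns where both sequences
have a residue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations, product
from pathlib import Path

from Bio import SeqIO

from .repeats import wilcoxon_rank_sum

__all__ = [
    "IdentityContrast",
    "pairwise_identity",
    "clade_contrast",
    "contrast_all",
    "load_alignment_fasta",
    "load_species_groups",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity between two aligned sequences over the columns
    where both carry a residue (gap-gap and residue-gap columns are not
    comparable)."""
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"aligned sequences differ in length: {len(seq_a)} vs {len(seq_b)}"
        )
    identical = 0
    comparable = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a == "-" or b == "-":
            continue
        comparable += 1
        if a == b:
            identical += 1
    if comparable == 0:
        return 0.0
    return 100.0 * identical / comparable


@dataclass
class IdentityContrast:
    family: str
    focal_pairs: list[float]
    background_pairs: list[float]
    U: float
    p_raw: float
    significant: bool


def clade_contrast(
    alignment: dict[str, str],
    focal_species: set[str],
    family: str = "",
    alpha: float = ALPHA,
) -> IdentityContrast:
    """Contrast focal-vs-background pair identities against
    background-vs-background pair identities.

    ``alignment`` maps species tag to aligned sequence.  Requires at
    least two focal and two background species (otherwise one of the pair
    sets is degenerate).
    """
    focal = sorted(s for s in alignment if s in focal_species)
    background = sorted(s for s in alignment if s not in focal_species)
    if len(focal) < 2 or len(background) < 2:
        raise ValueError(
            f"need >=2 focal and >=2 background species "
            f"(got {len(focal)} and {len(background)})"
        )
    focal_pairs = [
        pairwise_identity(alignment[a], alignment[b])
        for a, b in product(focal, background)
    ]
    background_pairs = [
        pairwise_identity(alignment[a], alignment[b])
        for a, b in combinations(background, 2)
    ]
    U, p = wilcoxon_rank_sum(focal_pairs, background_pairs)
    return IdentityContrast(
        family=family,
        focal_pairs=focal_pairs,
        background_pairs=background_pairs,
        U=U,
        p_raw=p,
        significant=bool(p < alpha),
    )


def contrast_all(
    alignments: dict[str, dict[str, str]],
    focal_species: set[str],
    alpha: float = ALPHA,
) -> list[IdentityContrast]:
    """Run the contrast for every family alignment.

    Species missing a family (absent from its alignment) are simply not
    part of that family's pair sets; a warning records the drop.
    """
    all_species = set().union(*(a.keys() for a in alignments.values()))
    results = []
    for family, alignment in sorted(alignments.items()):
        missing = all_species - set(alignment)
        if missing:
            logger.warning(
                "family %s: species without sequence dropped: %s",
                family, ", ".join(sorted(missing)),
            )
        results.append(
            clade_contrast(alignment, focal_species, family, alpha)
        )
    return results


def load_alignment_fasta(path: str | Path) -> dict[str, str]:
    """Load an aligned protein FASTA keyed by species.

    Headers may be plain species tags or the pipe-delimited
    ``family|species|id`` convention (the species field is used).
    """
    alignment: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        species = parts[1] if len(parts) == 3 else rec.id
        if species in alignment:
            raise ValueError(f"duplicate species in alignment: {species!r}")
        alignment[species] = str(rec.seq).upper()
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) > 1:
        raise ValueError("alignment sequences differ in length")
    return alignment


def load_species_groups(path: str | Path) -> set[str]:
    """Read a two-column TSV (species, group) and return the focal set
    (rows whose group is ``focal``)."""
    focal = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed species-group row: {line!r}")
            if fields[1].strip().lower() == "focal":
                focal.add(fields[0].strip())
    return focal
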