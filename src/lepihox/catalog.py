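"""Homeodomain gene-family catalog and labeled reference sets.

The catalog is a static taxonomy of the homeobox gene families found in
lepidopteran genomes, each tagged with its homeodomain class (ANTP, PRD,
LIM, POU, SINE, TALE, CUT, PROS, ZF, CERS), whether it belongs to the Hox
gene cluster, and whether it is one of the Lepidoptera-specific Shx genes
(tandem *zen*-derived "special homeobox" genes ShxA-ShxD).

A :class:`ReferenceSet` holds labeled ~60-residue homeodomain protein
sequences used as queries for the genome scan and as subjects for the
reciprocal classification step.  Reference FASTA files carry pipe-delimited
headers ``family|species|id``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneFamily",
    "HomeodomainReference",
    "ReferenceSet",
    "CATALOG",
    "HOX_CLUSTER_FAMILIES",
    "SHX_FAMILIES",
    "get_family",
    "load_reference",
    "write_reference",
    "canonical_orders",
    "export_catalog_tsv",
]

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

# Minimum reference length: partial homeodomains are tolerated down to half
# the canonical 60 residues.
MIN_REFERENCE_LEN = 30


@dataclass(frozen=True)
class GeneFamily:
    """One homeobox gene family (e.g. ``Antp``, ``ShxA``, ``Rx``)."""

    name: str
    hclass: str
    is_hox_cluster_member: bool = False
    is_shx: bool = False


@dataclass(frozen=True)
class HomeodomainReference:
    """A labeled homeodomain protein sequence from the reference set."""

    id: str
    family: str
    species_tag: str
    sequence: str


# Family names per homeodomain class.  The ANTP class contains the Hox and
# Hox-derived genes (including the four Shx families), the NK genes, and
# several dispersed genes such as rough (ro) which sits next to pb in the
# lepidopteran Hox cluster without being Hox-derived itself.
_CLASS_FAMILIES: dict[str, list[str]] = {
    "ANTP": [
        "lab", "Abd-B", "abd-A", "Ubx", "Antp", "ftz", "Scr", "Dfd", "zen",
        "ShxA", "ShxB", "ShxC", "ShxD", "pb", "ind", "cad", "exex", "eve",
        "unpg", "btn", "Tlx", "Msx", "NK4", "NK3", "Lbx", "NK1", "Hmx",
        "Emx", "Hhex", "NK7", "NK6", "Nedx", "Dlx", "En", "NK2.1", "Msxlx",
        "Hlx", "NK2.2", "Barhl", "Bari", "Bsx", "Dbx", "Abox", "Noto", "ro",
    ],
    "PRD": [
        "Uncx", "Gsc", "Pitx", "Otp", "Rx", "Hbn", "Repo", "Prrx", "Shox",
        "Arx", "Pax4/6", "Phox", "Prop", "Vsx", "CG11294", "Pax3/7", "Drgx",
        "Otx",
    ],
    "LIM": ["Lhx6/8", "Lmx", "Lhx2/9", "Lhx3/4", "Lhx1/5", "Isl"],
    "POU": ["Pou2", "Pou3", "Pou4", "Pou6"],
    "SINE": ["Six3/6", "Six1/2", "Six4/5"],
    "TALE": ["Meis", "Irx", "Mkx", "Pbx", "Tgif"],
    "CUT": ["Onecut", "Cux", "Cmp"],
    "PROS": ["Prox"],
    "ZF": ["Zfhx"],
    "CERS": ["Cers"],
}

# The 14 Hox / Hox-derived families of the lepidopteran cluster.  ro is
# adjacent to pb in the cluster but is not Hox-derived, so it is excluded.
HOX_CLUSTER_FAMILIES: tuple[str, ...] = (
    "lab", "pb", "zen", "ShxA", "ShxB", "ShxC", "ShxD", "Dfd", "Scr",
    "Antp", "ftz", "Ubx", "abd-A", "Abd-B",
)

SHX_FAMILIES: tuple[str, ...] = ("ShxA", "ShxB", "ShxC", "ShxD")


def _build_catalog() -> dict[str, GeneFamily]:
    catalog: dict[str, GeneFamily] = {}
    hox = set(HOX_CLUSTER_FAMILIES)
    shx = set(SHX_FAMILIES)
    for hclass, names in _CLASS_FAMILIES.items():
        for name in names:
            if name in catalog:
                raise ValueError(f"duplicate family name in catalog: {name}")
            catalog[name] = GeneFamily(
                name=name,
                hclass=hclass,
                is_hox_cluster_member=name in hox,
                is_shx=name in shx,
            )
    return catalog


CATALOG: dict[str, GeneFamily] = _build_catalog()


def get_family(name: str) -> GeneFamily:
    """Look up a family by name; raises ``KeyError`` for unknown names."""
    return CATALOG[name]


def canonical_orders() -> dict[str, tuple[str, ...]]:
    """Canonical ordered family lists for the three analyzed clusters.

    ``LEP_HOX`` is the lepidopteran Hox cluster order from the ro-side edge
    to Abd-B; lab is not part of this order because it has been relocated
    beyond Abd-B.  ``NK`` is the canonical NK cluster order (with two Msx
    copies), and ``PRD_TRIO`` is the conserved hbn-Rx-otp neuronal cluster.
    """
    return {
        "LEP_HOX": (
            "ro", "pb", "ShxA", "ShxB", "ShxC", "ShxD", "zen", "Dfd", "Scr",
            "Antp", "ftz", "Ubx", "abd-A", "Abd-B",
        ),
        "NK": ("Tlx", "Msx", "Msx", "NK4", "NK3", "Lbx", "NK1", "Hmx", "Emx"),
        "PRD_TRIO": ("Hbn", "Rx", "Otp"),
    }


class ReferenceError_(ValueError):
    """Raised for malformed or inconsistent reference input."""


@dataclass
class ReferenceSet:
    """A validated, indexed collection of homeodomain references."""

    entries: list[HomeodomainReference] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.by_family: dict[str, list[HomeodomainReference]] = {}
        self.by_id: dict[str, HomeodomainReference] = {}
        for entry in self.entries:
            self._validate(entry)
            if entry.id in self.by_id:
                raise ReferenceError_(f"duplicate reference id: {entry.id!r}")
            self.by_id[entry.id] = entry
            self.by_family.setdefault(entry.family, []).append(entry)

    @staticmethod
    def _validate(entry: HomeodomainReference) -> None:
        if entry.family not in CATALOG:
            raise ReferenceError_(
                f"record {entry.id!r}: unknown family {entry.family!r}"
            )
        if not entry.sequence:
            raise ReferenceError_(f"record {entry.id!r}: empty sequence")
        bad = set(entry.sequence.upper()) - AA_ALPHABET
        if bad:
            raise ReferenceError_(
                f"record {entry.id!r}: invalid residues {sorted(bad)}"
            )
        if len(entry.sequence) < MIN_REFERENCE_LEN:
            raise ReferenceError_(
                f"record {entry.id!r}: sequence shorter than "
                f"{MIN_REFERENCE_LEN} aa"
            )

    def __len__(self) -> int:
        return len(self.entries)

    def families(self) -> list[str]:
        return sorted(self.by_family)


def load_reference(path: str | Path) -> ReferenceSet:
    """Load a reference set from a protein FASTA with ``family|species|id``
    headers.

    Raises :class:`ReferenceError_` naming the offending record for
    malformed headers, unknown family names, duplicate ids, or invalid
    residues; an empty file is an error.
    """
    path = Path(path)
    entries: list[HomeodomainReference] = []
    for record in SeqIO.parse(str(path), "fasta"):
        parts = record.id.split("|")
        if len(parts) != 3 or not all(parts):
            raise ReferenceError_(
                f"record {record.id!r}: header must be 'family|species|id'"
            )
        family, species, rid = parts
        entries.append(
            HomeodomainReference(
                id=record.id,
                family=family,
                species_tag=species,
                sequence=str(record.seq).upper(),
            )
        )
    if not entries:
        raise ReferenceError_(f"no FASTA records found in {path}")
    return ReferenceSet(entries)


def write_reference(refset: ReferenceSet, path: str | Path) -> None:
    """Write a reference set back to pipe-header protein FASTA."""
    records = [
        SeqRecord(Seq(e.sequence), id=e.id, description="")
        for e in refset.entries
    ]
    SeqIO.write(records, str(path), "fasta")


def export_catalog_tsv(path: str | Path) -> None:
    """Export the family taxonomy as TSV (family, class, flags)."""
    with open(path, "w") as fh:
        fh.write("family\thclass\tis_hox_cluster_member\tis_shx\n")
        for fam in CATALOG.values():
            fh.write(
                f"{fam.name}\t{fam.hclass}\t"
                f"{int(fam.is_hox_cluster_member)}\t{int(fam.is_shx)}\n"
            )
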