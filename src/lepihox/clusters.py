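"""Gene-cluster architecture reconstruction and rearrangement detection.

Builds ordered, oriented cluster layouts (Hox, NK, hbn-Rx-otp) from
classified loci and compares them against the canonical lepidopteran
orders.  Cluster membership is defined by family identity plus the modal
contig (the contig carrying most member loci); no distance gating is
applied because lepidopteran Hox clusters span up to several megabases.

For the Hox cluster, lab is handled specially: in Lepidoptera it has been
relocated far beyond Abd-B, so it is reported among the external members
and excluded from span computations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .catalog import HOX_CLUSTER_FAMILIES, SHX_FAMILIES, canonical_orders
from .classify import ClassifiedLocus

__all__ = [
    "ClusterMember",
    "ClusterArchitecture",
    "RearrangementReport",
    "build_cluster",
    "hox_span",
    "shx_copy_table",
    "detect_rearrangements",
    "prd_trio",
    "CLUSTER_FAMILIES",
]

logger = logging.getLogger(__name__)

# Families considered members of each cluster when found on the modal contig.
CLUSTER_FAMILIES: dict[str, tuple[str, ...]] = {
    # 13 in-cluster Hox families (lab excluded) plus ro
    "HOX": tuple(f for f in HOX_CLUSTER_FAMILIES if f != "lab") + ("ro",),
    "NK": ("Tlx", "Msx", "NK4", "NK3", "Lbx", "NK1", "Hmx", "Emx"),
    "PRD_TRIO": ("Hbn", "Rx", "Otp"),
}

_CANONICAL_KEY = {"HOX": "LEP_HOX", "NK": "NK", "PRD_TRIO": "PRD_TRIO"}


@dataclass(frozen=True)
class ClusterMember:
    family: str
    start: int
    end: int
    strand: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ClusterArchitecture:
    cluster_name: str
    contig: str | None
    members: list[ClusterMember]
    span_bp: int
    intergenic_bp: list[int]
    external_members: list[tuple[str, str, int, int]]  # family, contig, s, e

    @property
    def family_order(self) -> list[str]:
        return [m.family for m in self.members]


@dataclass
class RearrangementReport:
    broken_adjacencies: list[tuple[str, str]]
    orientation_flips: list[str]
    translocated: list[str]
    shx_region: tuple[int, int] | None


def _empty_architecture(cluster_name: str) -> ClusterArchitecture:
    logger.warning("no member loci for cluster %s", cluster_name)
    return ClusterArchitecture(cluster_name, None, [], 0, [], [])


def build_cluster(
    classified: Sequence[ClassifiedLocus], cluster_name: str
) -> ClusterArchitecture:
    """Assemble one cluster's architecture from classified loci.

    Members are ASSIGNED loci of the cluster's families located on the
    modal contig, sorted by start coordinate.  Member-family loci on other
    contigs are listed as external.  For HOX, lab loci are always external
    unless they fall between ro and Abd-B on the modal contig.
    """
    if cluster_name not in CLUSTER_FAMILIES:
        raise ValueError(f"unknown cluster {cluster_name!r}")
    families = set(CLUSTER_FAMILIES[cluster_name])
    candidates = [
        cl for cl in classified if cl.is_assigned and cl.family in families
    ]
    lab_loci = (
        [cl for cl in classified if cl.is_assigned and cl.family == "lab"]
        if cluster_name == "HOX"
        else []
    )
    if not candidates:
        return _empty_architecture(cluster_name)

    contig_counts: dict[str, int] = {}
    for cl in candidates:
        contig_counts[cl.locus.contig] = contig_counts.get(cl.locus.contig, 0) + 1
    modal_contig = max(sorted(contig_counts), key=lambda c: contig_counts[c])

    members = sorted(
        (
            ClusterMember(cl.family, cl.locus.start, cl.locus.end,
                          cl.locus.strand)
            for cl in candidates
            if cl.locus.contig == modal_contig
        ),
        key=lambda m: (m.start, m.end),
    )
    external = [
        (cl.family, cl.locus.contig, cl.locus.start, cl.locus.end)
        for cl in candidates
        if cl.locus.contig != modal_contig
    ]

    # lab placement: internal only if it lies between ro and Abd-B on the
    # modal contig, otherwise external (the lepidopteran norm).
    for cl in lab_loci:
        loc = cl.locus
        internal = False
        if loc.contig == modal_contig:
            fams = {m.family: m for m in members}
            if "ro" in fams and "Abd-B" in fams:
                lo = min(fams["ro"].start, fams["Abd-B"].start)
                hi = max(fams["ro"].end, fams["Abd-B"].end)
                internal = lo <= loc.start and loc.end <= hi
        if internal:
            members.append(
                ClusterMember("lab", loc.start, loc.end, loc.strand)
            )
            members.sort(key=lambda m: (m.start, m.end))
        else:
            external.append(("lab", loc.contig, loc.start, loc.end))

    span = max(m.end for m in members) - min(m.start for m in members)
    intergenic = [
        members[i + 1].start - members[i].end for i in range(len(members) - 1)
    ]
    return ClusterArchitecture(
        cluster_name=cluster_name,
        contig=modal_contig,
        members=members,
        span_bp=span,
        intergenic_bp=intergenic,
        external_members=sorted(external),
    )


def hox_span(arch: ClusterArchitecture) -> int:
    """Span of the main Hox cluster from Abd-B to ro, inclusive of both
    gene bodies (orientation-invariant)."""
    coords = {}
    for m in arch.members:
        coords.setdefault(m.family, []).append(m)
    for endpoint in ("ro", "Abd-B"):
        if endpoint not in coords:
            raise ValueError(f"endpoint family {endpoint} missing")
    pts = coords["ro"] + coords["Abd-B"]
    return max(m.end for m in pts) - min(m.start for m in pts)


@dataclass
class ShxCopyTable:
    counts: dict[str, int]
    runs: list[tuple[str, int, int, int]]  # family, n_copies, start, end
    shx_region: tuple[int, int] | None

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def shx_copy_table(arch: ClusterArchitecture) -> ShxCopyTable:
    """Per-family Shx copy counts plus maximal tandem-array runs.

    The Shx region is the interval from the first to the last Shx locus
    on the cluster contig; it is undefined when no Shx locus is present
    (as in non-ditrysian lineages that lack Shx genes).
    """
    shx_members = [m for m in arch.members if m.family in SHX_FAMILIES]
    counts = {f: 0 for f in SHX_FAMILIES}
    for m in shx_members:
        counts[m.family] += 1
    counts = {f: c for f, c in counts.items() if c > 0}
    runs: list[tuple[str, int, int, int]] = []
    i = 0
    # runs are maximal stretches of consecutive cluster members of the
    # same Shx family (an intervening non-Shx gene breaks a run)
    order = arch.members
    while i < len(order):
        fam = order[i].family
        if fam not in SHX_FAMILIES:
            i += 1
            continue
        j = i
        while j + 1 < len(order) and order[j + 1].family == fam:
            j += 1
        runs.append((fam, j - i + 1, order[i].start, order[j].end))
        i = j + 1
    region = None
    if shx_members:
        region = (min(m.start for m in shx_members),
                  max(m.end for m in shx_members))
    return ShxCopyTable(counts=counts, runs=runs, shx_region=region)


def _collapse_blocks(order: Sequence[str]) -> list[str]:
    """Collapse tandem runs of the same family to one block, then keep
    only the first remaining occurrence of any family that still repeats
    (multi-copy families anchored at their first block)."""
    collapsed: list[str] = []
    for fam in order:
        if not collapsed or collapsed[-1] != fam:
            collapsed.append(fam)
    seen: set[str] = set()
    out: list[str] = []
    for fam in collapsed:
        if fam in seen:
            continue
        seen.add(fam)
        out.append(fam)
    return out


def _adjacency_set(order: Sequence[str]) -> set[frozenset]:
    return {
        frozenset((order[i], order[i + 1]))
        for i in range(len(order) - 1)
        if order[i] != order[i + 1]
    }


def detect_rearrangements(
    arch: ClusterArchitecture,
    canonical: Sequence[str] | None = None,
) -> RearrangementReport:
    """Compare observed family order against the canonical order.

    Multi-copy families are collapsed to a single block; the canonical
    order is contracted to the families actually observed, and canonical
    neighbor pairs that are no longer adjacent are reported as broken
    adjacencies.  Orientation flips are genes on the minority strand.
    No minimal rearrangement scenario is inferred.
    """
    if canonical is None:
        canonical = canonical_orders()[_CANONICAL_KEY[arch.cluster_name]]
    observed = _collapse_blocks(arch.family_order)
    canon = _collapse_blocks(canonical)
    present = set(observed)
    canon_present = [f for f in canon if f in present]
    broken = []
    obs_adj = _adjacency_set(observed)
    for i in range(len(canon_present) - 1):
        pair = (canon_present[i], canon_present[i + 1])
        if frozenset(pair) not in obs_adj:
            broken.append(pair)

    strands = [m.strand for m in arch.members]
    flips: list[str] = []
    if strands:
        majority = max(sorted(set(strands)), key=strands.count)
        flips = sorted({
            m.family for m in arch.members if m.strand != majority
        })

    # translocation = member family on another contig; same-contig
    # displacement (the lepidopteran lab) is external but not translocated
    translocated = sorted({
        fam for fam, contig, *_ in arch.external_members
        if contig != arch.contig
    })
    shx_region = None
    if arch.cluster_name == "HOX":
        shx_region = shx_copy_table(arch).shx_region
    return RearrangementReport(
        broken_adjacencies=broken,
        orientation_flips=flips,
        translocated=translocated,
        shx_region=shx_region,
    )


def prd_trio(classified: Sequence[ClassifiedLocus]) -> tuple[
    ClusterArchitecture, bool
]:
    """Architecture of the hbn-Rx-otp cluster plus a canonical-order flag.

    The order is canonical when it matches Hbn-Rx-Otp or its exact mirror;
    transcriptional orientation is free to vary (as observed across
    Lepidoptera).
    """
    arch = build_cluster(classified, "PRD_TRIO")
    order = arch.family_order
    canon = list(canonical_orders()["PRD_TRIO"])
    is_canonical = order == canon or order == canon[::-1]
    return arch, is_canonical
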