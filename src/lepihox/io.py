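"""Tabular and annotation output writers.

All genomic TSV/BED outputs use 0-based half-open coordinates and say so
in a header comment; GFF3 outputs are 1-based closed per the format.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence
from urllib.parse import quote

from .classify import ClassifiedLocus
from .clusters import ClusterArchitecture, RearrangementReport
from .repeats import EnrichmentResult
from .divergence import IdentityContrast
from .scan import Locus, RawHit

COORD_HEADER = "# coordinates: 0-based, half-open\n"


def write_hits_tsv(hits: Sequence[RawHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(COORD_HEADER)
        fh.write("contig\tstart\tend\tstrand\tframe\tquery\tscore\t"
                 "bitscore\tevalue\tidentity_pct\n")
        for h in hits:
            fh.write(
                f"{h.contig}\t{h.start}\t{h.end}\t{h.strand}\t{h.frame}\t"
                f"{h.query_id}\t{h.score:.1f}\t{h.bitscore:.2f}\t"
                f"{h.evalue:.3g}\t{h.identity_pct:.2f}\n"
            )


def _gff3_attr(value: str) -> str:
    return quote(str(value), safe=" |_.-/")


def write_loci_gff3(loci: Sequence[Locus], path: str | Path,
                    feature_type: str = "homeobox_candidate") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write("# coordinates: 1-based, closed (GFF3)\n")
        for i, loc in enumerate(loci):
            attrs = (
                f"ID=locus{i};query={_gff3_attr(loc.representative_hit.query_id)};"
                f"supporting_hits={loc.supporting_hits}"
            )
            fh.write(
                f"{loc.contig}\tlepihox\t{feature_type}\t{loc.start + 1}\t"
                f"{loc.end}\t{loc.representative_hit.score:.0f}\t{loc.strand}"
                f"\t.\t{attrs}\n"
            )


def write_classification_tsv(classified: Sequence[ClassifiedLocus],
                             path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(COORD_HEADER)
        fh.write("contig\tstart\tend\tstrand\tstatus\tfamily\t"
                 "identity_pct\tforward_family\treverse_family\n")
        for cl in classified:
            loc = cl.locus
            fh.write(
                f"{loc.contig}\t{loc.start}\t{loc.end}\t{loc.strand}\t"
                f"{cl.status}\t{cl.family or '.'}\t{cl.identity_pct:.2f}\t"
                f"{cl.forward_family}\t{cl.reverse_family}\n"
            )


def write_architecture_tsv(arch: ClusterArchitecture,
                           path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(COORD_HEADER)
        fh.write(f"# cluster={arch.cluster_name} contig={arch.contig} "
                 f"span_bp={arch.span_bp}\n")
        fh.write("family\tstart\tend\tstrand\tplacement\n")
        for m in arch.members:
            fh.write(f"{m.family}\t{m.start}\t{m.end}\t{m.strand}\tmember\n")
        for fam, contig, s, e in arch.external_members:
            fh.write(f"{fam}\t{s}\t{e}\t.\texternal:{contig}\n")


def write_rearrangements_tsv(reports: dict[str, RearrangementReport],
                             path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster\tkind\tdetail\n")
        for name, rep in reports.items():
            for a, b in rep.broken_adjacencies:
                fh.write(f"{name}\tbroken_adjacency\t{a}--{b}\n")
            for fam in rep.orientation_flips:
                fh.write(f"{name}\torientation_flip\t{fam}\n")
            for fam in rep.translocated:
                fh.write(f"{name}\ttranslocated\t{fam}\n")
            if rep.shx_region:
                fh.write(f"{name}\tshx_region\t"
                         f"{rep.shx_region[0]}-{rep.shx_region[1]}\n")


def write_enrichment_tsv(results: Sequence[EnrichmentResult],
                         path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("te_class\tn_shx_windows\tn_rest_windows\tmedian_shx\t"
                 "median_rest\tU\tp_raw\tp_bonferroni\tenriched\n")
        for r in results:
            fh.write(
                f"{r.te_class}\t{len(r.shx_densities)}\t"
                f"{len(r.rest_densities)}\t{r.median_shx:.4f}\t"
                f"{r.median_rest:.4f}\t{r.U:.1f}\t{r.p_raw:.4g}\t"
                f"{r.p_bonferroni:.4g}\t{int(r.enriched)}\n"
            )


def write_density_bed(contig: str, windows: Sequence[tuple[int, int]],
                      densities: Sequence[float], te_class: str,
                      path: str | Path, append: bool = False) -> None:
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        if not append:
            fh.write(COORD_HEADER)
        for (lo, hi), d in zip(windows, densities):
            fh.write(f"{contig}\t{lo}\t{hi}\t{te_class}\t{d:.4f}\n")


def write_contrasts_tsv(contrasts: Sequence[IdentityContrast],
                        path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("family\tn_focal_pairs\tn_background_pairs\t"
                 "median_focal\tmedian_background\tU\tp_raw\tsignificant\n")
        for c in contrasts:
            import numpy as np
            fh.write(
                f"{c.family}\t{len(c.focal_pairs)}\t"
                f"{len(c.background_pairs)}\t"
                f"{float(np.median(c.focal_pairs)):.2f}\t"
                f"{float(np.median(c.background_pairs)):.2f}\t"
                f"{c.U:.1f}\t{c.p_raw:.4g}\t{int(c.significant)}\n"
            )


def write_manifest(path: str | Path, **fields) -> None:
    """JSON run manifest: inputs, thresholds, package version, seed."""
    from . import __version__

    payload = {"lepihox_version": __version__, **fields}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Stage round-tripping: stages couple through files, so loci and
# classifications must reload losslessly enough for downstream stages.


def write_loci_tsv(loci: Sequence[Locus], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(COORD_HEADER)
        fh.write("contig\tstart\tend\tstrand\tquery\tscore\tevalue\t"
                 "identity_pct\tsupporting_hits\tbest_query\tbest_score\t"
                 "aa\n")
        for loc in loci:
            rep = loc.representative_hit
            best = loc.best_hit or rep
            fh.write(
                f"{loc.contig}\t{loc.start}\t{loc.end}\t{loc.strand}\t"
                f"{rep.query_id}\t{rep.score:.1f}\t{rep.evalue:.3g}\t"
                f"{rep.identity_pct:.2f}\t{loc.supporting_hits}\t"
                f"{best.query_id}\t{best.score:.1f}\t{loc.aa}\n"
            )


def read_loci_tsv(path: str | Path) -> list[Locus]:
    loci: list[Locus] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("contig\t"):
                continue
            f = line.rstrip("\n").split("\t")
            hit = RawHit(
                contig=f[0], start=int(f[1]), end=int(f[2]), strand=f[3],
                frame=0, query_id=f[4], score=float(f[5]), bitscore=0.0,
                evalue=float(f[6]), identity_pct=float(f[7]),
                aligned_query_span=(0, 0), target_aa=f[11],
            )
            best = RawHit(
                contig=f[0], start=int(f[1]), end=int(f[2]), strand=f[3],
                frame=0, query_id=f[9], score=float(f[10]), bitscore=0.0,
                evalue=float(f[6]), identity_pct=float(f[7]),
                aligned_query_span=(0, 0), target_aa=f[11],
            )
            loci.append(Locus(
                contig=f[0], start=int(f[1]), end=int(f[2]), strand=f[3],
                representative_hit=hit, supporting_hits=int(f[8]),
                aa=f[11], best_hit=best,
            ))
    return loci


def read_classification_tsv(path: str | Path) -> list[ClassifiedLocus]:
    out: list[ClassifiedLocus] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("contig\t"):
                continue
            f = line.rstrip("\n").split("\t")
            contig, start, end, strand = f[0], int(f[1]), int(f[2]), f[3]
            status, family, identity = f[4], f[5], float(f[6])
            forward, reverse = f[7], f[8]
            hit = RawHit(
                contig=contig, start=start, end=end, strand=strand, frame=0,
                query_id=f"{forward}|NA|NA", score=0.0, bitscore=0.0,
                evalue=0.0, identity_pct=identity,
                aligned_query_span=(0, 0),
            )
            locus = Locus(contig=contig, start=start, end=end, strand=strand,
                          representative_hit=hit, supporting_hits=1)
            out.append(ClassifiedLocus(
                locus=locus, forward_family=forward, reverse_family=reverse,
                identity_pct=identity, status=status,
                family=None if family == "." else family,
            ))
    return out
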