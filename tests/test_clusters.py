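"""Cluster architecture, spans, Shx copy tables, rearrangement calls."""

import numpy as np
import pytest

from lepihox.catalog import canonical_orders
from lepihox.classify import ASSIGNED, ClassifiedLocus
from lepihox.clusters import (
    build_cluster,
    detect_rearrangements,
    hox_span,
    prd_trio,
    shx_copy_table,
)
from lepihox.scan import Locus, RawHit
from oracles import exact_ranksum_p  # noqa: F401  (shared import path check)

LEP_HOX = list(canonical_orders()["LEP_HOX"])


def make_cl(family, contig="chr1", start=0, end=None, strand="+"):
    end = end if end is not None else start + 180
    hit = RawHit(contig=contig, start=start, end=end, strand=strand, frame=0,
                 query_id=f"{family}|DM|x", score=250.0, bitscore=100.0,
                 evalue=1e-20, identity_pct=95.0, aligned_query_span=(0, 60))
    locus = Locus(contig=contig, start=start, end=end, strand=strand,
                  representative_hit=hit, supporting_hits=1, aa="M" * 60)
    return ClassifiedLocus(locus=locus, forward_family=family,
                           reverse_family=family, identity_pct=95.0,
                           status=ASSIGNED, family=family)


def canonical_hox(gap=50_000, start=100_000, lab_offset=7_000_000,
                  contig="chr1"):
    classified = []
    pos = start
    for fam in LEP_HOX:
        classified.append(make_cl(fam, contig=contig, start=pos))
        pos += 180 + gap
    abdb_end = pos - gap
    classified.append(make_cl("lab", contig=contig,
                              start=abdb_end + lab_offset))
    return classified


class TestBuildCluster:
    def test_canonical_order_and_lab_external(self):
        classified = canonical_hox()
        arch = build_cluster(classified, "HOX")
        assert arch.family_order == LEP_HOX
        assert [e[0] for e in arch.external_members] == ["lab"]
        abdb = next(m for m in arch.members if m.family == "Abd-B")
        lab = arch.external_members[0]
        assert lab[2] - abdb.end == 7_000_000
        # span excludes lab
        assert arch.span_bp == max(m.end for m in arch.members) - \
            min(m.start for m in arch.members)

    def test_modal_contig_selection(self):
        classified = canonical_hox()
        # move abd-A, Abd-B, ftz to another contig
        moved = []
        for cl in classified:
            if cl.family in {"abd-A", "Abd-B", "ftz"}:
                moved.append(make_cl(cl.family, contig="chr9",
                                     start=cl.locus.start))
            else:
                moved.append(cl)
        arch = build_cluster(moved, "HOX")
        assert arch.contig == "chr1"
        assert sorted(e[0] for e in arch.external_members
                      if e[0] != "lab") == ["Abd-B", "abd-A", "ftz"]

    def test_single_member_cluster(self):
        arch = build_cluster([make_cl("Antp", start=500, end=680)], "HOX")
        assert arch.span_bp == 180
        assert arch.intergenic_bp == []

    def test_no_members_yields_empty_architecture(self):
        arch = build_cluster([], "HOX")
        assert arch.members == []
        assert arch.contig is None

    def test_span_decomposition_and_shift_invariance(self):
        classified = canonical_hox(gap=10_000, start=50_000)
        arch = build_cluster(classified, "HOX")
        gene_total = sum(m.length for m in arch.members)
        assert gene_total + sum(arch.intergenic_bp) == arch.span_bp
        shifted = canonical_hox(gap=10_000, start=250_000)
        arch2 = build_cluster(shifted, "HOX")
        assert arch2.span_bp == arch.span_bp
        assert arch2.intergenic_bp == arch.intergenic_bp

    def test_mirror_invariance(self):
        classified = canonical_hox(gap=10_000)
        L = 20_000_000
        mirrored = []
        for cl in classified:
            loc = cl.locus
            mirrored.append(make_cl(cl.family, start=L - loc.end,
                                    end=L - loc.start,
                                    strand="-" if loc.strand == "+" else "+"))
        a = build_cluster(classified, "HOX")
        b = build_cluster(mirrored, "HOX")
        assert b.span_bp == a.span_bp
        assert b.intergenic_bp == a.intergenic_bp[::-1]
        assert b.family_order == a.family_order[::-1]
        assert detect_rearrangements(b).broken_adjacencies == []


class TestHoxSpan:
    def test_arithmetic(self):
        classified = [make_cl("ro", start=0, end=1000),
                      make_cl("Abd-B", start=1_219_000, end=1_220_000)]
        arch = build_cluster(classified, "HOX")
        assert hox_span(arch) == 1_220_000

    def test_orientation_invariant(self):
        classified = [make_cl("Abd-B", start=0, end=1000, strand="-"),
                      make_cl("ro", start=1_219_000, end=1_220_000,
                              strand="-")]
        assert hox_span(build_cluster(classified, "HOX")) == 1_220_000

    def test_missing_endpoint_named(self):
        arch = build_cluster([make_cl("Abd-B", start=0, end=1000)], "HOX")
        with pytest.raises(ValueError, match="ro"):
            hox_span(arch)


class TestShxCopyTable:
    def test_four_distinct_shx(self):
        arch = build_cluster(canonical_hox(), "HOX")
        table = shx_copy_table(arch)
        assert table.counts == {"ShxA": 1, "ShxB": 1, "ShxC": 1, "ShxD": 1}
        assert all(run[1] == 1 for run in table.runs)
        assert table.shx_region is not None

    def test_tandem_array_reported_as_one_run(self):
        classified = [make_cl("pb", start=0)]
        pos = 10_000
        for _ in range(25):
            classified.append(make_cl("ShxA", start=pos))
            pos += 2_000
        classified.append(make_cl("zen", start=pos + 10_000))
        arch = build_cluster(classified, "HOX")
        table = shx_copy_table(arch)
        assert table.counts == {"ShxA": 25}
        assert table.total == 25
        (run,) = table.runs
        assert run[0] == "ShxA" and run[1] == 25
        assert table.shx_region == (10_000, 10_000 + 24 * 2_000 + 180)

    def test_no_shx_means_undefined_region(self):
        classified = [make_cl(f, start=i * 10_000)
                      for i, f in enumerate(["ro", "pb", "zen", "Abd-B"])]
        table = shx_copy_table(build_cluster(classified, "HOX"))
        assert table.counts == {}
        assert table.shx_region is None
        assert table.runs == []


class TestRearrangements:
    def test_canonical_order_reports_nothing_broken(self):
        arch = build_cluster(canonical_hox(), "HOX")
        rep = detect_rearrangements(arch)
        assert rep.broken_adjacencies == []
        assert rep.orientation_flips == []
        assert rep.translocated == []  # lab is displaced, not translocated

    def test_ro_relocation_breaks_ro_pb(self):
        classified = []
        pos = 100_000
        for fam in LEP_HOX:
            if fam == "ro":
                continue
            classified.append(make_cl(fam, start=pos))
            pos += 20_180
        classified.append(make_cl("ro", start=pos + 300_000))
        classified.append(make_cl("lab", start=pos + 7_000_000))
        arch = build_cluster(classified, "HOX")
        rep = detect_rearrangements(arch)
        assert rep.broken_adjacencies == [("ro", "pb")]

    def test_nk_block_translocation_breakpoint(self):
        # slou(NK1)/Hmx/ems(Emx) block moved to the Tlx end
        observed = ["NK1", "Hmx", "Emx", "Tlx", "Msx", "NK4", "NK3", "Lbx"]
        classified = [make_cl(f, start=i * 50_000)
                      for i, f in enumerate(observed)]
        rep = detect_rearrangements(build_cluster(classified, "NK"))
        assert ("Lbx", "NK1") in rep.broken_adjacencies

    def test_adjacent_transpositions_bounded_by_oracle(self):
        rng = np.random.default_rng(17)
        base = [f for f in LEP_HOX]
        for k in (1, 2, 3):
            for _ in range(10):
                order = base[:]
                for _ in range(k):
                    i = int(rng.integers(0, len(order) - 1))
                    order[i], order[i + 1] = order[i + 1], order[i]
                classified = [make_cl(f, start=j * 20_000)
                              for j, f in enumerate(order)]
                rep = detect_rearrangements(build_cluster(classified, "HOX"))
                n_broken = len(rep.broken_adjacencies)
                if order == base:
                    assert n_broken == 0
                else:
                    assert 1 <= n_broken <= 2 * k

    def test_orientation_flip_detected(self):
        classified = canonical_hox()
        flipped = [
            make_cl(cl.family, start=cl.locus.start, strand="-")
            if cl.family == "zen" else cl
            for cl in classified
        ]
        rep = detect_rearrangements(build_cluster(flipped, "HOX"))
        assert rep.orientation_flips == ["zen"]


class TestPrdTrio:
    def test_canonical_span(self):
        classified = [make_cl("Hbn", contig="p", start=0, end=2_000),
                      make_cl("Rx", contig="p", start=170_000, end=172_000),
                      make_cl("Otp", contig="p", start=346_000, end=348_000)]
        arch, canonical = prd_trio(classified)
        assert canonical
        assert arch.span_bp == 348_000

    def test_reverse_order_is_canonical(self):
        classified = [make_cl("Otp", start=0), make_cl("Rx", start=100_000),
                      make_cl("Hbn", start=200_000)]
        _, canonical = prd_trio(classified)
        assert canonical

    def test_scrambled_order_flagged(self):
        classified = [make_cl("Hbn", start=0), make_cl("Otp", start=100_000),
                      make_cl("Rx", start=200_000)]
        _, canonical = prd_trio(classified)
        assert not canonical
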