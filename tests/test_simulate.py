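"""Synthetic-genome generator: determinism, truth fidelity, coverage."""

import numpy as np
import pytest

from lepihox.repeats import merged_coverage
from lepihox.simulate import (
    SimulationConfig,
    family_prototype,
    generate,
    mutate_domain,
    reverse_translate,
    synthetic_reference_set,
)


class TestMutateDomain:
    def test_zero_fraction_is_identity(self):
        aa = family_prototype("zen")
        assert mutate_domain(aa, 0.0, 1) == aa

    def test_exact_substitution_count(self):
        aa = family_prototype("Antp")
        mutated = mutate_domain(aa, 0.2, 3)
        diffs = sum(a != b for a, b in zip(aa, mutated))
        assert diffs == 12  # round(0.2 * 60)

    def test_seeds_give_different_mutation_sets(self):
        aa = family_prototype("pb")
        m1, m2 = mutate_domain(aa, 0.2, 1), mutate_domain(aa, 0.2, 2)
        assert m1 != m2
        assert sum(a != b for a, b in zip(aa, m1)) == \
            sum(a != b for a, b in zip(aa, m2)) == 12

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(ValueError):
            mutate_domain(family_prototype("zen"), 0.6, 1)


class TestReverseTranslate:
    def test_translation_round_trip(self):
        from Bio.Seq import Seq

        aa = family_prototype("Scr")
        rng = np.random.default_rng(0)
        dna = reverse_translate(aa, 0.35, rng)
        assert len(dna) == 3 * len(aa)
        assert str(Seq(dna).translate()) == aa

    def test_gc_weighting_shifts_composition(self):
        aa = family_prototype("Dfd") * 5
        rng = np.random.default_rng(0)
        low = reverse_translate(aa, 0.25, rng)
        high = reverse_translate(aa, 0.65, rng)
        gc = lambda s: (s.count("G") + s.count("C")) / len(s)
        assert gc(high) > gc(low)


class TestReferencePanel:
    def test_covers_all_families_with_three_species(self, refset):
        from lepihox.catalog import CATALOG

        assert sorted(refset.by_family) == sorted(CATALOG)
        assert all(len(v) == 3 for v in refset.by_family.values())

    def test_family_prototypes_are_separated(self):
        # families must be far further apart than planted within-family
        # divergence for classification to be well-posed
        fams = ["zen", "ShxA", "ShxB", "pb", "Antp", "ro", "Hbn"]
        for i, a in enumerate(fams):
            for b in fams[i + 1:]:
                pa, pb_ = family_prototype(a), family_prototype(b)
                ident = np.mean([x == y for x, y in zip(pa, pb_)])
                assert ident < 0.65, (a, b, ident)


class TestGenerate:
    def test_deterministic_byte_identical(self):
        cfg = dict(seed=5, intergenic_median_bp=5_000, lab_offset_bp=50_000,
                   include_nk=False, include_prd=False, end_margin=20_000)
        s1 = generate(SimulationConfig(**cfg))
        s2 = generate(SimulationConfig(**cfg))
        assert s1.contigs == s2.contigs
        assert s1.genes == s2.genes
        assert s1.repeats == s2.repeats

    def test_default_hox_plan_has_fifteen_genes(self):
        cfg = SimulationConfig(seed=1, include_nk=False, include_prd=False,
                               intergenic_median_bp=5_000,
                               lab_offset_bp=100_000, end_margin=20_000)
        sim = generate(cfg)
        assert len(sim.genes) == 15
        fams = [g.family for g in sim.genes]
        assert fams.count("lab") == 1
        lab = next(g for g in sim.genes if g.family == "lab")
        abdb = next(g for g in sim.genes if g.family == "Abd-B")
        assert lab.start - abdb.end == 100_000

    def test_truth_gff3_round_trip(self, tmp_path):
        cfg = SimulationConfig(seed=2, include_nk=False, include_prd=False,
                               intergenic_median_bp=5_000,
                               lab_offset_bp=50_000, end_margin=20_000)
        sim = generate(cfg)
        path = tmp_path / "truth.gff3"
        sim.write_truth_gff3(path)
        rows = [l for l in path.read_text().splitlines()
                if l and not l.startswith("#")]
        assert len(rows) == len(sim.genes)
        first = rows[0].split("\t")
        assert int(first[3]) == sim.genes[0].start + 1  # 1-based closed
        assert int(first[4]) == sim.genes[0].end

    def test_shx_array_with_interleaved_lines(self):
        cfg = SimulationConfig(
            seed=3, shx_copies={"ShxA": 25, "ShxB": 1, "ShxC": 1, "ShxD": 1},
            line_interleave=True, include_nk=False, include_prd=False,
            intergenic_median_bp=5_000, lab_offset_bp=50_000,
            end_margin=20_000,
        )
        sim = generate(cfg)
        shxa = [g for g in sim.genes if g.family == "ShxA"]
        assert len(shxa) == 25
        interleaved = [r for r in sim.repeats if "array" in r.name]
        assert len(interleaved) >= 24
        assert all(r.strand == "+" for r in interleaved)
        assert all(r.te_class == "LINE" for r in interleaved)
        # interleaved elements sit strictly between consecutive copies
        starts = sorted(g.start for g in shxa)
        for r in interleaved[: len(starts) - 1]:
            assert starts[0] < r.start < starts[-1] + 180

    def test_realized_repeat_coverage_near_configured(self):
        cfg = SimulationConfig(seed=4, include_nk=False, include_prd=False,
                               lab_offset_bp=300_000)
        sim = generate(cfg)
        cluster = [g for g in sim.genes if g.family != "lab"]
        lo = min(g.start for g in cluster)
        hi = max(g.end for g in cluster)
        shx_lo, shx_hi = sim.shx_region()
        # background LINE coverage measured outside the multiplied region
        iv = np.array(sorted(
            (r.start, r.end) for r in sim.repeats
            if r.te_class == "LINE" and r.contig == "hox_chr"
        ))
        cov = merged_coverage(iv, lo, shx_lo) + merged_coverage(iv, shx_hi, hi)
        frac = cov / ((shx_lo - lo) + (hi - shx_hi))
        target = cfg.repeat_background["LINE"]
        assert abs(frac - target) / target < 0.20
        # tripled coverage inside the Shx region (wide tolerance: the
        # region is short, so the realization is noisy)
        shx_cov = merged_coverage(iv, shx_lo, shx_hi) / (shx_hi - shx_lo)
        assert shx_cov > frac

    def test_layout_exceeding_fixed_contig_rejected(self):
        cfg = SimulationConfig(seed=0, hox_contig_len=500_000)
        with pytest.raises(ValueError, match="exceeds"):
            generate(cfg)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="gc"):
            generate(SimulationConfig(gc=1.5))
        with pytest.raises(ValueError, match="divergence"):
            generate(SimulationConfig(shx_divergence=0.9))
        with pytest.raises(ValueError, match=">= 0"):
            generate(SimulationConfig(shx_copies={"ShxA": -1}))

    def test_relocated_ro_leaves_cluster_interior(self):
        cfg = SimulationConfig(seed=6, relocate_ro=True, include_nk=False,
                               include_prd=False, intergenic_median_bp=5_000,
                               lab_offset_bp=200_000, ro_offset_bp=80_000,
                               end_margin=20_000)
        sim = generate(cfg)
        ro = next(g for g in sim.genes if g.family == "ro")
        abdb = next(g for g in sim.genes if g.family == "Abd-B")
        lab = next(g for g in sim.genes if g.family == "lab")
        assert abdb.end < ro.start < lab.start


class TestEndToEndRecovery:
    def test_pipeline_reproduces_truth_counts_and_mirror(self, refset):
        from lepihox.classify import classify_all
        from lepihox.scan import find_loci

        cfg = SimulationConfig(seed=8, include_nk=False, include_prd=False,
                               intergenic_median_bp=3_000,
                               intergenic_sigma=0.4, lab_offset_bp=40_000,
                               end_margin=20_000, hox_divergence=0.15,
                               shx_divergence=0.15)
        sim = generate(cfg)

        def check(intervals, truth_genes):
            # every planted gene matched by exactly one assigned locus of
            # its family with >= 90% interval overlap (terminal residue
            # trimming by the local aligner shaves a few bp at most)
            assert len(intervals) == len(truth_genes)
            for g in truth_genes:
                matches = [
                    (s, e) for s, e, fam in intervals
                    if fam == g.family and s < g.end and g.start < e
                ]
                assert len(matches) == 1, g
                s, e = matches[0]
                overlap = min(e, g.end) - max(s, g.start)
                assert overlap / (g.end - g.start) >= 0.90, g

        loci, _ = find_loci(sim.contigs, refset)
        classified = classify_all(loci, refset)
        got = [(c.locus.start, c.locus.end, c.family)
               for c in classified if c.is_assigned]
        check(got, sim.genes)
        # mirror: reverse-complement the genome, rerun, expect mirrored loci
        comp = str.maketrans("ACGT", "TGCA")
        name = "hox_chr"
        L = len(sim.contigs[name])
        mirrored = {name: sim.contigs[name].translate(comp)[::-1]}
        loci_m, _ = find_loci(mirrored, refset)
        got_m = [
            (L - c.locus.end, L - c.locus.start, c.family)
            for c in classify_all(loci_m, refset) if c.is_assigned
        ]
        check(got_m, sim.genes)
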