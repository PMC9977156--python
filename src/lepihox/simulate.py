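"""Seeded synthetic genomes with planted homeobox gene clusters.

The generator emulates the genomic structure the downstream analyses
assume: a Hox chromosome carrying the lepidopteran cluster order (ro, pb,
ShxA-D, zen, Dfd, Scr, Antp, ftz, Ubx, abd-A, Abd-B) with lab relocated
megabases beyond Abd-B; configurable tandem Shx arrays, optionally with
same-orientation LINE/CR1-style elements interleaved between copies; an
NK cluster and the hbn-Rx-otp trio on separate contigs; and a Poisson
repeat landscape per TE class with a density multiplier inside the Shx
region.  Every planted feature is recorded in a ground-truth set (GFF3
for genes, BED for repeats).

Planted genes are intron-free 180-bp homeodomains: family prototype
protein sequences are diverged at the amino-acid level and then
reverse-translated with GC-weighted synonymous codon choice.  Family
prototypes derive deterministically from a single consensus homeodomain,
so the matching synthetic reference set (`synthetic_reference_set`) and
the generator agree on what each family looks like.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .catalog import (
    CATALOG,
    SHX_FAMILIES,
    HomeodomainReference,
    ReferenceSet,
    canonical_orders,
)

__all__ = [
    "CONSENSUS_HOMEODOMAIN",
    "SimulationConfig",
    "PlantedGene",
    "PlantedRepeat",
    "SimResult",
    "mutate_domain",
    "family_prototype",
    "synthetic_reference_set",
    "reverse_translate",
    "generate",
    "simulate_family_alignment",
]

# The canonical 60-residue Antennapedia-type homeodomain used as the seed
# for all synthetic family prototypes.
CONSENSUS_HOMEODOMAIN = (
    "RKRGRQTYTRYQTLELEKEFHFNRYLTRRRRIEIAHALCLTERQIKIWFQNRRMKWKKEN"
)
assert len(CONSENSUS_HOMEODOMAIN) == 60

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# Standard codon table restricted to the 20 amino acids.
_CODONS: dict[str, list[str]] = {}
_BASES = "TCAG"
_STANDARD = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, _aa in enumerate(_STANDARD):
    if _aa == "*":
        continue
    _codon = _BASES[_i // 16] + _BASES[(_i // 4) % 4] + _BASES[_i % 4]
    _CODONS.setdefault(_aa, []).append(_codon)


def mutate_domain(aa: str, fraction: float, seed) -> str:
    """Substitute exactly ``round(fraction * len)`` residues of ``aa`` to
    different residues; positions and replacements are drawn from the
    given seed (an int or a ``numpy.random.Generator``)."""
    if not 0.0 <= fraction <= 0.5:
        raise ValueError(f"divergence fraction out of [0, 0.5]: {fraction}")
    rng = seed if isinstance(seed, np.random.Generator) else (
        np.random.default_rng(seed)
    )
    n = round(fraction * len(aa))
    if n == 0:
        return aa
    positions = rng.choice(len(aa), size=n, replace=False)
    out = list(aa)
    for pos in positions:
        choices = [r for r in AA20 if r != out[pos]]
        out[pos] = choices[rng.integers(len(choices))]
    return "".join(out)


def _family_seed(family: str, salt: int = 0) -> int:
    return (zlib.crc32(f"{salt}:{family}".encode()) & 0x7FFFFFFF)


def family_prototype(family: str, divergence: float = 0.40) -> str:
    """Deterministic prototype homeodomain for a family: the consensus
    diverged by a fixed fraction with a seed derived from the family name
    alone, so prototypes are stable across runs and seeds."""
    if family not in CATALOG:
        raise KeyError(f"unknown family {family!r}")
    return mutate_domain(CONSENSUS_HOMEODOMAIN, divergence,
                         _family_seed(family))


def synthetic_reference_set(
    seed: int = 0,
    species: tuple[str, ...] = ("DM", "TC", "AM"),
    species_divergence: float = 0.04,
    families: tuple[str, ...] | None = None,
) -> ReferenceSet:
    """A labeled synthetic homeodomain reference set covering the whole
    family catalog, with one diverged variant per species tag (emulating
    a three-insect reference panel)."""
    entries = []
    fams = families if families is not None else tuple(CATALOG)
    for family in fams:
        proto = family_prototype(family)
        for sp in species:
            rng = np.random.default_rng(
                (seed, _family_seed(family), zlib.crc32(sp.encode()))
            )
            seq = mutate_domain(proto, species_divergence, rng)
            entries.append(HomeodomainReference(
                id=f"{family}|{sp}|hd{_family_seed(family) % 10000}",
                family=family,
                species_tag=sp,
                sequence=seq,
            ))
    return ReferenceSet(entries)


def reverse_translate(aa: str, gc: float, rng: np.random.Generator) -> str:
    """Reverse-translate a protein with synonymous codon choice weighted
    toward the target GC content."""
    codons = []
    for residue in aa:
        options = _CODONS[residue]
        weights = np.array([
            np.prod([gc / 2 if b in "GC" else (1 - gc) / 2 for b in codon])
            for codon in options
        ])
        weights = weights / weights.sum()
        codons.append(options[rng.choice(len(options), p=weights)])
    return "".join(codons)


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic genome.

    Defaults emulate the typical ditrysian architecture: a ~1.2-Mb Hox
    cluster (intergenic gaps lognormal, median 50 kb), four single-copy
    Shx genes between pb and zen, lab 7 Mb beyond Abd-B, an NK cluster
    and PRD trio on their own contigs, and a background repeat landscape
    with LINE density tripled inside the Shx region.
    """

    seed: int = 0
    gc: float = 0.35
    gene_len: int = 180
    # Hox chromosome layout
    cluster_start: int = 200_000
    intergenic_median_bp: float = 50_000.0
    intergenic_sigma: float = 1.0
    shx_spacing_median_bp: float = 4_000.0
    shx_spacing_sigma: float = 0.3
    shx_copies: dict = field(
        default_factory=lambda: {"ShxA": 1, "ShxB": 1, "ShxC": 1, "ShxD": 1}
    )
    shx_divergence: float = 0.05
    hox_divergence: float = 0.05
    lab_offset_bp: int = 7_000_000
    relocate_ro: bool = False
    ro_offset_bp: int = 300_000
    end_margin: int = 200_000
    hox_contig_len: int | None = None  # None: auto-size to fit the layout
    # additional clusters
    include_nk: bool = True
    include_prd: bool = True
    nk_gap_median_bp: float = 50_000.0
    nk_gap_sigma: float = 0.6
    prd_gap_median_bp: float = 170_000.0
    prd_gap_sigma: float = 0.25
    # repeat landscape (fraction-of-bases coverage per TE class)
    repeat_background: dict = field(
        default_factory=lambda: {"LINE": 0.05, "SINE": 0.02,
                                 "LTR": 0.02, "DNA": 0.03}
    )
    shx_repeat_multiplier: dict = field(
        default_factory=lambda: {"LINE": 3.0}
    )
    repeat_len_median: float = 400.0
    repeat_len_sigma: float = 0.7
    line_interleave: bool = False  # plant same-orientation LINEs in arrays

    def validate(self) -> None:
        if not 0.0 < self.gc < 1.0:
            raise ValueError(f"gc out of (0,1): {self.gc}")
        for name, frac in (("shx_divergence", self.shx_divergence),
                           ("hox_divergence", self.hox_divergence)):
            if not 0.0 <= frac <= 0.5:
                raise ValueError(f"{name} out of [0, 0.5]: {frac}")
        if any(n < 0 for n in self.shx_copies.values()):
            raise ValueError("shx_copies must be >= 0")
        unknown = set(self.shx_copies) - set(SHX_FAMILIES)
        if unknown:
            raise ValueError(f"unknown Shx families: {sorted(unknown)}")
        if self.relocate_ro and self.ro_offset_bp >= self.lab_offset_bp:
            raise ValueError(
                "relocated ro must lie between Abd-B and lab "
                "(ro_offset_bp < lab_offset_bp)"
            )


@dataclass(frozen=True)
class PlantedGene:
    family: str
    contig: str
    start: int
    end: int
    strand: str
    divergence: float
    aa: str


@dataclass(frozen=True)
class PlantedRepeat:
    te_class: str
    name: str
    contig: str
    start: int
    end: int
    strand: str


@dataclass
class SimResult:
    config: SimulationConfig
    contigs: dict[str, str]
    genes: list[PlantedGene]
    repeats: list[PlantedRepeat]

    # ---- truth helpers -------------------------------------------------
    def genes_by_family(self) -> dict[str, list[PlantedGene]]:
        out: dict[str, list[PlantedGene]] = {}
        for g in self.genes:
            out.setdefault(g.family, []).append(g)
        return out

    def shx_region(self) -> tuple[int, int] | None:
        shx = [g for g in self.genes if g.family in SHX_FAMILIES]
        if not shx:
            return None
        return min(g.start for g in shx), max(g.end for g in shx)

    # ---- writers -------------------------------------------------------
    def write_fasta(self, path: str | Path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_truth_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write("# coordinates: 1-based, closed (GFF3)\n")
            for i, g in enumerate(self.genes):
                attrs = (
                    f"ID=planted{i};family={g.family};"
                    f"divergence={g.divergence:.3f}"
                )
                fh.write(
                    f"{g.contig}\tlepihox-sim\tgene\t{g.start + 1}\t{g.end}"
                    f"\t.\t{g.strand}\t.\t{attrs}\n"
                )

    def write_repeat_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.repeats:
                fh.write(
                    f"{r.contig}\t{r.start}\t{r.end}\t{r.name}\t0\t{r.strand}\n"
                )

    def write_config_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self.config), fh, indent=2, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Generation


def _lognormal(rng: np.random.Generator, median: float, sigma: float) -> int:
    return max(200, int(rng.lognormal(np.log(median), sigma)))


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length,
                      p=probs)


_COMPLEMENT = bytes.maketrans(b"ACGT", b"TGCA")


def _plant(seq: np.ndarray, pos: int, dna: str, strand: str) -> None:
    payload = dna.encode()
    if strand == "-":
        payload = payload.translate(_COMPLEMENT)[::-1]
    seq[pos : pos + len(payload)] = np.frombuffer(payload, dtype=np.uint8)


def _layout_hox(config: SimulationConfig,
                rng: np.random.Generator) -> list[tuple[str, int, float]]:
    """Plan (family, start, divergence) placements along the Hox contig."""
    order = canonical_orders()["LEP_HOX"]
    plan: list[tuple[str, int, float]] = []
    cursor = config.cluster_start
    prev_family: str | None = None
    for family in order:
        if family == "ro" and config.relocate_ro:
            continue
        copies = config.shx_copies.get(family, 1) if family in SHX_FAMILIES \
            else 1
        div = config.shx_divergence if family in SHX_FAMILIES \
            else config.hox_divergence
        for _ in range(copies):
            if prev_family is not None:
                if prev_family == family:
                    gap = _lognormal(rng, config.shx_spacing_median_bp,
                                     config.shx_spacing_sigma)
                else:
                    gap = _lognormal(rng, config.intergenic_median_bp,
                                     config.intergenic_sigma)
                cursor += gap
            plan.append((family, cursor, div))
            cursor += config.gene_len
            prev_family = family
    cluster_end = cursor
    if config.relocate_ro:
        plan.append(("ro", cluster_end + config.ro_offset_bp,
                     config.hox_divergence))
    plan.append(("lab", cluster_end + config.lab_offset_bp,
                 config.hox_divergence))
    return plan


def _sample_repeats(
    rng: np.random.Generator,
    config: SimulationConfig,
    contig: str,
    region: tuple[int, int],
    coverage: dict[str, float],
    tag: str,
) -> list[PlantedRepeat]:
    out: list[PlantedRepeat] = []
    lo, hi = region
    length = hi - lo
    mean_len = np.exp(np.log(config.repeat_len_median)
                      + config.repeat_len_sigma ** 2 / 2)
    names = {"LINE": "LINE/CR1", "SINE": "SINE/tRNA",
             "LTR": "LTR/Gypsy", "DNA": "DNA/TcMar"}
    for te_class in sorted(coverage):
        cov = coverage[te_class]
        if cov <= 0:
            continue
        # a Poisson interval process with per-base intensity c has union
        # coverage 1 - exp(-c): invert so the configured coverage is the
        # expected realized (merged) coverage
        lam = -np.log1p(-cov)
        # element starts extend one mean length left of the region so
        # coverage is stationary across the region edge
        n = rng.poisson(lam * (length + mean_len) / mean_len)
        for i in range(n):
            rep_len = int(np.clip(
                rng.lognormal(np.log(config.repeat_len_median),
                              config.repeat_len_sigma), 60, 5000))
            start = int(rng.integers(lo - rep_len + 1, hi))
            strand = "+" if rng.random() < 0.5 else "-"
            out.append(PlantedRepeat(
                te_class=te_class,
                name=f"{names[te_class]}_{tag}{i}",
                contig=contig,
                start=max(0, start),
                end=start + rep_len,
                strand=strand,
            ))
    return out


def generate(config: SimulationConfig) -> SimResult:
    """Generate a synthetic genome with ground truth per the config.

    Deterministic: the same config and seed yield byte-identical output.
    Raises if the planted layout exceeds a fixed ``hox_contig_len``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes: list[PlantedGene] = []
    repeats: list[PlantedRepeat] = []
    contigs: dict[str, str] = {}

    # --- Hox chromosome -------------------------------------------------
    plan = _layout_hox(config, rng)
    layout_end = max(start for _, start, _ in plan) + config.gene_len
    contig_len = layout_end + config.end_margin
    if config.hox_contig_len is not None:
        if layout_end + 1000 > config.hox_contig_len:
            raise ValueError(
                f"planted content ({layout_end} bp) exceeds hox contig "
                f"length {config.hox_contig_len}"
            )
        contig_len = config.hox_contig_len
    seq = _random_dna(rng, contig_len, config.gc)
    contig = "hox_chr"
    for family, start, div in plan:
        proto = family_prototype(family)
        aa = mutate_domain(proto, div, rng)
        dna = reverse_translate(aa, config.gc, rng)
        _plant(seq, start, dna, "+")
        genes.append(PlantedGene(
            family=family, contig=contig, start=start,
            end=start + config.gene_len, strand="+", divergence=div, aa=aa,
        ))

    # repeat landscape over the cluster and flanks
    cluster_genes = [g for g in genes
                     if g.family != "lab"
                     and not (config.relocate_ro and g.family == "ro")]
    cluster_lo = min(g.start for g in cluster_genes)
    cluster_hi = max(g.end for g in cluster_genes)
    pad = 100_000
    rep_region = (max(0, cluster_lo - pad), min(contig_len, cluster_hi + pad))
    repeats += _sample_repeats(rng, config, contig, rep_region,
                               config.repeat_background, "bg")
    shx = [g for g in genes if g.family in SHX_FAMILIES]
    if shx:
        s_lo = min(g.start for g in shx)
        s_hi = max(g.end for g in shx)
        # extra coverage whose Poisson intensity adds to the background's
        # to yield the multiplied target coverage inside the Shx region
        extra = {}
        for cls, mult in config.shx_repeat_multiplier.items():
            bg = config.repeat_background.get(cls, 0.0)
            if mult > 1.0 and bg > 0.0:
                target = min(0.999, bg * mult)
                extra[cls] = 1.0 - (1.0 - target) / (1.0 - bg)
        if extra and s_hi - s_lo > 500:
            repeats += _sample_repeats(rng, config, contig, (s_lo, s_hi),
                                       extra, "shx")
    if config.line_interleave:
        ordered = sorted(shx, key=lambda g: g.start)
        for k in range(len(ordered) - 1):
            a, b = ordered[k], ordered[k + 1]
            if a.family != b.family:
                continue
            gap_lo, gap_hi = a.end, b.start
            if gap_hi - gap_lo < 200:
                continue
            rep_len = min(600, gap_hi - gap_lo - 100)
            mid = (gap_lo + gap_hi) // 2
            start = mid - rep_len // 2
            repeats.append(PlantedRepeat(
                te_class="LINE", name=f"LINE/CR1_array{k}", contig=contig,
                start=start, end=start + rep_len, strand="+",
            ))
    contigs[contig] = seq.tobytes().decode("ascii")

    # --- NK chromosome --------------------------------------------------
    if config.include_nk:
        nk_contig = "nk_chr"
        cursor = 100_000
        nk_genes: list[PlantedGene] = []
        for family in canonical_orders()["NK"]:
            aa = mutate_domain(family_prototype(family),
                               config.hox_divergence, rng)
            nk_genes.append(PlantedGene(
                family=family, contig=nk_contig, start=cursor,
                end=cursor + config.gene_len, strand="+",
                divergence=config.hox_divergence, aa=aa,
            ))
            cursor += config.gene_len + _lognormal(
                rng, config.nk_gap_median_bp, config.nk_gap_sigma)
        nk_len = cursor + 100_000
        nk_seq = _random_dna(rng, nk_len, config.gc)
        for g in nk_genes:
            dna = reverse_translate(g.aa, config.gc, rng)
            _plant(nk_seq, g.start, dna, g.strand)
        genes += nk_genes
        contigs[nk_contig] = nk_seq.tobytes().decode("ascii")

    # --- PRD trio chromosome --------------------------------------------
    if config.include_prd:
        prd_contig = "prd_chr"
        cursor = 100_000
        prd_genes: list[PlantedGene] = []
        for family in canonical_orders()["PRD_TRIO"]:
            strand = "+" if rng.random() < 0.5 else "-"
            aa = mutate_domain(family_prototype(family),
                               config.hox_divergence, rng)
            prd_genes.append(PlantedGene(
                family=family, contig=prd_contig, start=cursor,
                end=cursor + config.gene_len, strand=strand,
                divergence=config.hox_divergence, aa=aa,
            ))
            cursor += config.gene_len + _lognormal(
                rng, config.prd_gap_median_bp, config.prd_gap_sigma)
        prd_len = cursor + 100_000
        prd_seq = _random_dna(rng, prd_len, config.gc)
        for g in prd_genes:
            dna = reverse_translate(g.aa, config.gc, rng)
            _plant(prd_seq, g.start, dna, g.strand)
        genes += prd_genes
        contigs[prd_contig] = prd_seq.tobytes().decode("ascii")

    genes.sort(key=lambda g: (g.contig, g.start))
    repeats.sort(key=lambda r: (r.contig, r.start, r.end, r.name))
    return SimResult(config=config, contigs=contigs, genes=genes,
                     repeats=repeats)


# ---------------------------------------------------------------------------
# Alignment simulation for the identity-contrast analysis


def simulate_family_alignment(
    n_focal: int,
    n_background: int,
    extra_subs: int,
    seed: int,
    base_divergence: float = 0.08,
) -> tuple[dict[str, str], set[str]]:
    """Synthetic gapless homeodomain alignment with an optional clade
    effect.

    Every species starts from the consensus homeodomain with independent
    background substitutions (``base_divergence`` fraction).  Focal
    species additionally carry ``extra_subs`` substitutions at positions
    (and to residues) shared across the clade, emulating divergence
    accumulated on the clade's ancestral branch.
    """
    rng = np.random.default_rng(seed)
    base = CONSENSUS_HOMEODOMAIN
    alignment: dict[str, str] = {}
    focal: set[str] = set()
    shift_positions = rng.choice(len(base), size=extra_subs, replace=False) \
        if extra_subs else np.empty(0, dtype=int)
    shift_residues = {}
    for pos in shift_positions:
        choices = [r for r in AA20 if r != base[pos]]
        shift_residues[int(pos)] = choices[rng.integers(len(choices))]
    for i in range(n_focal + n_background):
        name = f"sp{i:02d}"
        seq = mutate_domain(base, base_divergence, rng)
        if i < n_focal:
            focal.add(name)
            chars = list(seq)
            for pos, res in shift_residues.items():
                chars[pos] = res
            seq = "".join(chars)
        alignment[name] = seq
    return alignment, focal
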