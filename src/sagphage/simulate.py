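"""Seeded generator for every input the pipeline consumes.

The generator emulates the statistical structure of single-cell assemblies
from an oxygen-minimum-zone bacterial population and the viruses that
infect it:

* host contigs carry mostly characterized genes arranged in operon blocks
  (runs of co-oriented genes), so their strand-change ratio is roughly the
  inverse of the mean block length;
* viral genomes carry a high fraction of uncharacterized genes, strong
  strand coherence, and hallmark virion genes (capsid, terminase, portal,
  tail) — tailed dsDNA phages are 15-60 kb and linear, small ssDNA phages
  are 4.5-6.5 kb and circular;
* infections are planted per SAG: current infections add intact viral
  contigs; past infections leave defective prophages (a viral gene block
  inside a host contig, optionally conserved in a second SAG) or CRISPR
  arrays with one spacer copied from a past virus;
* metagenomes are substitution-only read sets drawn from hosts and
  viruses at controlled copy numbers and nucleotide/amino-acid identities
  to the references.

Every planted feature is recorded in a machine-readable ground truth, so
pipeline output can be scored without ambiguity. Identical configuration
(including the seed) reproduces byte-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .models import Contig, ContigRole, Gene, HallmarkCategory, reverse_complement
from .orfs import STOP_CODONS, translate

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]
_CODON_AA = {c: translate(c, allow_internal_stop=True) for c in _CODONS}
_AA_TO_CODONS: dict[str, list[str]] = {}
for _c, _a in _CODON_AA.items():
    _AA_TO_CODONS.setdefault(_a, []).append(_c)

HOST_PRODUCTS = [
    "ABC transporter ATP-binding protein",
    "DNA polymerase III subunit alpha",
    "50S ribosomal protein L3",
    "cytochrome c oxidase subunit II",
    "dissimilatory sulfite reductase subunit A",
    "elongation factor Tu",
    "sulfur oxidation protein SoxB",
    "RuBisCO large subunit",
    "NADH-quinone oxidoreductase subunit B",
    "two-component sensor histidine kinase",
]

VIRAL_HALLMARK_PRODUCTS = {
    HallmarkCategory.CAPSID: "major capsid protein",
    HallmarkCategory.TERMINASE: "terminase large subunit",
    HallmarkCategory.PORTAL: "portal protein",
    HallmarkCategory.TAIL: "tail fiber protein",
    HallmarkCategory.VIRION_STRUCTURE: "virion structure protein",
}

VIRAL_OTHER_PRODUCTS = [
    "DNA primase",
    "single-stranded DNA-binding protein",
    "replication initiation protein",
    "endolysin",
]

UNCHARACTERIZED_PRODUCT = "hypothetical protein"


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class HostParams:
    contigs_per_sag: int = 2
    genes_per_contig: int = 60
    gene_len_meanlog: float = float(np.log(800.0))
    gene_len_sdlog: float = 0.25
    characterized_fraction: float = 0.7
    mean_operon_len: float = 5.0
    intergenic_len: int = 30


@dataclass
class ViralParams:
    caudo_length_range: tuple[int, int] = (15_000, 60_000)
    micro_length_range: tuple[int, int] = (4_500, 6_500)
    gene_len_meanlog: float = float(np.log(600.0))
    #: ssDNA microviruses pack short, dense genes into tiny genomes
    micro_gene_len_meanlog: float = float(np.log(450.0))
    gene_len_sdlog: float = 0.25
    uncharacterized_fraction: float = 0.7
    strand_coherence: float = 0.95  # probability a gene keeps the strand
    #: minimum genes per genome (a complete phage genome is gene-dense)
    min_genes: int = 8


@dataclass
class InfectionParams:
    #: probability of current infection per SAG at each depth (m)
    p_current_by_depth: dict[int, float] = field(
        default_factory=lambda: {100: 0.08, 150: 0.28, 185: 0.47}
    )
    #: microviridae-infected SAGs also carry the linked podovirus w.p. this
    p_coinfection_link: float = 0.9
    #: extra background podovirus probability for uninfected SAGs (off by
    #: default so infection frequency follows p_current_by_depth exactly)
    p_podo_background: float = 0.0
    #: fraction of current infections (at 150/185 m) that are microviridae
    p_microviridae: float = 0.4
    p_prophage: float = 0.15
    p_crispr: float = 0.2
    #: plant one CRISPR spacer from a *current* virus (overlap scenario)
    plant_past_current_overlap: bool = False


@dataclass
class MetagenomeParams:
    read_length: int = 250
    error_rate: float = 0.005
    linker_amplified: bool = False


@dataclass
class ScenarioConfig:
    seed: int = 0
    sags_per_depth: int = 10
    depths: tuple[int, ...] = (100, 150, 185)
    host: HostParams = field(default_factory=HostParams)
    viral: ViralParams = field(default_factory=ViralParams)
    infection: InfectionParams = field(default_factory=InfectionParams)
    metagenome: MetagenomeParams = field(default_factory=MetagenomeParams)


@dataclass
class GroundTruth:
    """Exact record of everything the generator planted."""

    contig_label: dict[str, str] = field(default_factory=dict)  # microbial|viral
    viral_taxon: dict[str, str] = field(default_factory=dict)
    infections: dict[str, set[str]] = field(default_factory=dict)  # sag -> taxa
    prophages: list[dict] = field(default_factory=list)
    crisprs: list[dict] = field(default_factory=list)
    realized_identity: dict[str, float] = field(default_factory=dict)
    copy_numbers: dict[str, float] = field(default_factory=dict)
    read_provenance: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Sequence-level helpers


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _random_coding(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_CODONS), size=n_codons)
    return "".join(_CODONS[i] for i in idx)


@dataclass
class _GeneSpec:
    n_codons: int
    strand: str
    characterized: bool
    annotation: str
    hallmark: HallmarkCategory = HallmarkCategory.NONE


def _assemble_contig(
    contig_id: str,
    source_id: str,
    specs: Sequence[_GeneSpec],
    rng: np.random.Generator,
    *,
    intergenic_len: int,
    role: ContigRole = ContigRole.SAG_ASSEMBLY,
    circular: bool = False,
) -> tuple[Contig, list[Gene]]:
    """Lay genes head-to-tail with random intergenic spacers.

    A '+' gene occupies ``ATG + codons`` followed by a stop codon just
    outside its interval; a '-' gene is the reverse complement, with the
    stop complement preceding the interval.
    """
    parts: list[str] = []
    genes: list[Gene] = []
    pos = 0
    for i, spec in enumerate(specs, 1):
        gap = int(rng.integers(max(3, intergenic_len // 2), intergenic_len * 2))
        parts.append(random_dna(rng, gap))
        pos += gap
        coding = "ATG" + _random_coding(rng, spec.n_codons - 1)
        stop = STOP_CODONS[int(rng.integers(0, 3))]
        if spec.strand == "+":
            parts.append(coding + stop)
            start, end = pos + 1, pos + len(coding)
        else:
            parts.append(reverse_complement(coding + stop))
            start, end = pos + 4, pos + 3 + len(coding)
        pos += len(coding) + 3
        genes.append(
            Gene(
                id=f"{contig_id}_g{i}",
                contig_id=contig_id,
                start=start,
                end=end,
                strand=spec.strand,
                protein=translate(coding),
                characterized=spec.characterized,
                annotation_text=spec.annotation,
                hallmark_category=spec.hallmark,
            )
        )
    parts.append(random_dna(rng, int(rng.integers(10, 30))))
    contig = Contig(
        id=contig_id,
        source_id=source_id,
        sequence="".join(parts),
        role=role,
        circular=circular,
    )
    return contig, genes


def _gene_lengths(
    rng: np.random.Generator, n: int, meanlog: float, sdlog: float
) -> list[int]:
    lengths = np.exp(rng.normal(meanlog, sdlog, size=n))
    return [max(90, 3 * int(x // 3)) for x in lengths]


# ---------------------------------------------------------------------------
# Host and viral genome generation


def generate_host_genome(
    config: HostParams,
    rng: np.random.Generator,
    *,
    sag_id: str,
) -> tuple[list[Contig], list[Gene]]:
    """Host contigs with operon-structured, mostly characterized genes.

    Strand blocks alternate, so the expected strand-change ratio is the
    inverse of the mean operon length.
    """
    contigs: list[Contig] = []
    genes: list[Gene] = []
    for ci in range(1, config.contigs_per_sag + 1):
        specs: list[_GeneSpec] = []
        lengths = _gene_lengths(
            rng, config.genes_per_contig, config.gene_len_meanlog, config.gene_len_sdlog
        )
        strand = "+" if rng.random() < 0.5 else "-"
        block_left = int(rng.geometric(1.0 / config.mean_operon_len))
        for glen in lengths:
            if block_left == 0:
                strand = "+" if strand == "-" else "-"
                block_left = int(rng.geometric(1.0 / config.mean_operon_len))
            block_left -= 1
            characterized = bool(rng.random() < config.characterized_fraction)
            annotation = (
                HOST_PRODUCTS[int(rng.integers(0, len(HOST_PRODUCTS)))]
                if characterized
                else UNCHARACTERIZED_PRODUCT
            )
            specs.append(_GeneSpec(glen // 3, strand, characterized, annotation))
        contig, contig_genes = _assemble_contig(
            f"{sag_id}_c{ci}",
            sag_id,
            specs,
            rng,
            intergenic_len=config.intergenic_len,
        )
        contigs.append(contig)
        genes.extend(contig_genes)
    return contigs, genes


def generate_viral_genome(
    config: ViralParams,
    rng: np.random.Generator,
    *,
    kind: str,
    genome_id: str,
    length: int | None = None,
) -> tuple[Contig, list[Gene]]:
    """One viral genome: 'caudovirales' (linear dsDNA) or 'microviridae'
    (small circular ssDNA).

    Hallmark genes are always annotated with their keyword products; the
    remaining genes are mostly uncharacterized, and strand flips are rare
    so the genome is strand-coherent.
    """
    if kind == "caudovirales":
        lo, hi = config.caudo_length_range
        circular = False
        hallmarks = [
            HallmarkCategory.CAPSID,
            HallmarkCategory.TERMINASE,
            HallmarkCategory.PORTAL,
        ]
    elif kind == "microviridae":
        lo, hi = config.micro_length_range
        circular = True
        hallmarks = [HallmarkCategory.CAPSID]
    else:
        raise ValueError(f"unknown viral kind {kind!r}")
    target_len = length if length is not None else int(rng.integers(lo, hi + 1))

    meanlog = (
        config.micro_gene_len_meanlog if kind == "microviridae" else config.gene_len_meanlog
    )
    # small circular ssDNA phages encode essentially everything on one
    # strand; strand flips are a dsDNA-phage feature here
    coherence = 1.0 if kind == "microviridae" else config.strand_coherence
    specs: list[_GeneSpec] = []
    total = 0
    strand = "+"
    while total < target_len - 400 or len(specs) < config.min_genes:
        glen = _gene_lengths(rng, 1, meanlog, config.gene_len_sdlog)[0]
        if rng.random() > coherence:
            strand = "+" if strand == "-" else "-"
        uncharacterized = rng.random() < config.uncharacterized_fraction
        if uncharacterized:
            annotation, characterized = UNCHARACTERIZED_PRODUCT, False
            hallmark = HallmarkCategory.NONE
        else:
            annotation = VIRAL_OTHER_PRODUCTS[
                int(rng.integers(0, len(VIRAL_OTHER_PRODUCTS)))
            ]
            characterized, hallmark = True, HallmarkCategory.NONE
        specs.append(_GeneSpec(glen // 3, strand, characterized, annotation, hallmark))
        total += glen + 40
    # guarantee the hallmark complement at random positions
    positions = rng.choice(len(specs), size=min(len(hallmarks), len(specs)), replace=False)
    for pos, category in zip(sorted(int(p) for p in positions), hallmarks):
        specs[pos] = replace(
            specs[pos],
            characterized=True,
            annotation=VIRAL_HALLMARK_PRODUCTS[category],
            hallmark=category,
        )
    contig, genes = _assemble_contig(
        genome_id,
        genome_id,
        specs,
        rng,
        intergenic_len=25,
        role=ContigRole.VIRAL_REFERENCE,
        circular=circular,
    )
    return contig, genes


def mask_annotations(genes: Iterable[Gene]) -> list[Gene]:
    """Strip annotations, emulating a genome absent from every database."""
    return [
        replace(
            g,
            annotation_text=UNCHARACTERIZED_PRODUCT,
            characterized=False,
            hallmark_category=HallmarkCategory.NONE,
        )
        for g in genes
    ]


# ---------------------------------------------------------------------------
# Mutation at controlled identity


def mutate_to_identity(
    sequence: str,
    target_identity: float,
    *,
    level: str = "nucleotide",
    rng: np.random.Generator,
) -> tuple[str, float]:
    """Mutate a sequence to a target percent identity.

    Nucleotide level substitutes individual bases; amino-acid level
    substitutes whole codons non-synonymously (never creating a stop), so
    nucleotide and protein identities stay jointly consistent. Returns
    (mutated sequence, realized identity) — realized is exact, within one
    point of the target by construction.
    """
    if not 30.0 <= target_identity <= 100.0:
        raise ValueError("target identity must be in [30, 100]")
    if level == "nucleotide":
        n = len(sequence)
        if n == 0:
            raise ValueError("cannot mutate an empty sequence")
        k = int(round(n * (1 - target_identity / 100)))
        positions = rng.choice(n, size=k, replace=False)
        seq = list(sequence)
        for p in positions:
            choices = [b for b in "ACGT" if b != seq[p]]
            seq[p] = choices[int(rng.integers(0, 3))]
        return "".join(seq), 100.0 * (n - k) / n
    if level == "amino_acid":
        if len(sequence) % 3 != 0 or not sequence:
            raise ValueError("amino-acid mutation requires an in-frame sequence")
        codons = [sequence[i : i + 3] for i in range(0, len(sequence), 3)]
        n = len(codons)
        k = int(round(n * (1 - target_identity / 100)))
        positions = rng.choice(n, size=k, replace=False)
        for p in positions:
            aa = _CODON_AA.get(codons[p])
            choices = [c for c in _CODONS if _CODON_AA[c] != aa]
            codons[p] = choices[int(rng.integers(0, len(choices)))]
        return "".join(codons), 100.0 * (n - k) / n
    raise ValueError(f"unknown mutation level {level!r}")


def mutate_genome_genes(
    contig: Contig,
    genes: Sequence[Gene],
    target_identity: float,
    *,
    level: str = "amino_acid",
    rng: np.random.Generator,
) -> tuple[Contig, list[Gene], dict[str, float]]:
    """Mutate every gene of a genome to a target identity.

    Intergenic sequence is left untouched. Returns the mutated contig,
    updated genes (with re-translated proteins) and the realized identity
    per gene.
    """
    seq = list(contig.sequence)
    new_genes: list[Gene] = []
    realized: dict[str, float] = {}
    for gene in sorted(genes, key=lambda g: g.start):
        coding = gene.nucleotide_sequence(contig)
        mutated, ident = mutate_to_identity(
            coding, target_identity, level=level, rng=rng
        )
        realized[gene.id] = ident
        insert = mutated if gene.strand == "+" else reverse_complement(mutated)
        seq[gene.start - 1 : gene.end] = list(insert)
        new_genes.append(replace(gene, protein=translate(mutated)))
    new_contig = replace(contig, sequence="".join(seq))
    return new_contig, new_genes, realized


# ---------------------------------------------------------------------------
# Planting infections into SAG assemblies


@dataclass
class SAGAssembly:
    id: str
    depth: int
    contigs: list[Contig]
    genes: list[Gene]

    def contig_genes(self) -> dict[str, list[Gene]]:
        out: dict[str, list[Gene]] = {c.id: [] for c in self.contigs}
        for g in self.genes:
            out[g.contig_id].append(g)
        for lst in out.values():
            lst.sort(key=lambda g: g.start)
        return out


def _insert_segment(
    sag: SAGAssembly,
    contig: Contig,
    gene_index: int,
    segment: str,
    segment_genes: Sequence[Gene],
) -> tuple[int, int]:
    """Insert `segment` between genes `gene_index-1` and `gene_index`.

    `segment_genes` carry coordinates relative to the segment (1-based);
    they are shifted into place, and downstream host genes move right.
    Returns the 1-based nucleotide interval the segment occupies.
    """
    contig_genes = [g for g in sag.genes if g.contig_id == contig.id]
    contig_genes.sort(key=lambda g: g.start)
    left = contig_genes[gene_index - 1]
    right = contig_genes[gene_index]
    pos0 = left.end + (right.start - left.end) // 2  # insert after this base
    new_seq = contig.sequence[:pos0] + segment + contig.sequence[pos0:]
    shift = len(segment)
    new_genes: list[Gene] = []
    for g in sag.genes:
        if g.contig_id != contig.id or g.end <= pos0:
            new_genes.append(g)
        else:
            new_genes.append(replace(g, start=g.start + shift, end=g.end + shift))
    for g in segment_genes:
        new_genes.append(
            replace(g, contig_id=contig.id, start=g.start + pos0, end=g.end + pos0)
        )
    sag.genes = sorted(new_genes, key=lambda g: (g.contig_id, g.start))
    for i, c in enumerate(sag.contigs):
        if c.id == contig.id:
            sag.contigs[i] = replace(c, sequence=new_seq)
    return pos0 + 1, pos0 + shift


def plant_infection(
    sag: SAGAssembly,
    virus: tuple[Contig, Sequence[Gene]],
    mode: str,
    rng: np.random.Generator,
    truth: GroundTruth,
    *,
    taxon: str = "",
    conserve_in: SAGAssembly | None = None,
    n_fragments: int = 1,
) -> None:
    """Plant a current infection, a defective prophage, or a CRISPR spacer.

    current: the viral genome is added as its own contig(s) (optionally
    fragmented). prophage: a block of consecutive viral genes (with
    annotations masked — remnants are not in reference databases) is
    inserted inside a host contig with host genes flanking; when
    `conserve_in` is given the same block is copied into that SAG too.
    crispr_spacer: a repeat-spacer array with one spacer copied from the
    virus is inserted into a host contig.
    """
    vcontig, vgenes = virus
    taxon = taxon or vcontig.id
    if mode == "current":
        n_fragments = max(1, n_fragments)
        bounds = np.linspace(0, vcontig.length, n_fragments + 1).astype(int)
        order = sorted(vgenes, key=lambda g: g.start)
        for fi in range(n_fragments):
            lo, hi = int(bounds[fi]), int(bounds[fi + 1])
            cid = f"{sag.id}_{taxon}" + (f"_f{fi + 1}" if n_fragments > 1 else "")
            frag = replace(
                vcontig,
                id=cid,
                source_id=sag.id,
                sequence=vcontig.sequence[lo:hi],
                role=ContigRole.SAG_ASSEMBLY,
            )
            frag_genes = [
                replace(
                    g,
                    id=f"{cid}_g{i}",
                    contig_id=cid,
                    start=g.start - lo,
                    end=g.end - lo,
                )
                for i, g in enumerate(
                    (g for g in order if g.start > lo and g.end <= hi), 1
                )
            ]
            sag.contigs.append(frag)
            sag.genes.extend(frag_genes)
            truth.contig_label[cid] = "viral"
            truth.viral_taxon[cid] = taxon
        truth.infections.setdefault(sag.id, set()).add(taxon)
        return

    if mode == "prophage":
        if len(vgenes) < 10:
            raise ValueError("virus too small to donate a prophage block")
        order = sorted(vgenes, key=lambda g: g.start)
        m = int(rng.integers(8, min(13, len(order))))
        start_i = int(rng.integers(0, len(order) - m + 1))
        block = order[start_i : start_i + m]
        seg_start, seg_end = block[0].start, block[-1].end
        segment = vcontig.sequence[seg_start - 1 : seg_end]
        for target, is_primary in ((sag, True), (conserve_in, False)):
            if target is None:
                continue
            host_choices = [
                c for c in target.contigs
                if truth.contig_label.get(c.id, "microbial") == "microbial"
            ]
            host_contig = host_choices[int(rng.integers(0, len(host_choices)))]
            contig_genes = [g for g in target.genes if g.contig_id == host_contig.id]
            gene_index = int(rng.integers(2, len(contig_genes) - 2))
            seg_genes = mask_annotations(
                [
                    replace(
                        g,
                        id=f"{target.id}_pro_g{i}",
                        start=g.start - seg_start + 1,
                        end=g.end - seg_start + 1,
                    )
                    for i, g in enumerate(block, 1)
                ]
            )
            nt_lo, nt_hi = _insert_segment(
                target, host_contig, gene_index, segment, seg_genes
            )
            truth.prophages.append(
                {
                    "sag": target.id,
                    "contig": host_contig.id,
                    "gene_region": (gene_index, gene_index + m),
                    "nt_region": (nt_lo, nt_hi),
                    "source_virus": taxon,
                    "conserved": conserve_in is not None,
                    "primary": is_primary,
                }
            )
        return

    if mode == "crispr_spacer":
        if vcontig.length < 60:
            raise ValueError("virus too small to donate a spacer")
        segment, meta = _make_crispr_segment(vcontig, rng)
        host_choices = [
            c for c in sag.contigs
            if truth.contig_label.get(c.id, "microbial") == "microbial"
        ]
        host_contig = host_choices[int(rng.integers(0, len(host_choices)))]
        contig_genes = [g for g in sag.genes if g.contig_id == host_contig.id]
        gene_index = int(rng.integers(1, len(contig_genes)))
        nt_lo, _ = _insert_segment(sag, host_contig, gene_index, segment, [])
        # meta intervals are 1-based within the segment (flank included)
        offset = nt_lo - 1
        truth.crisprs.append(
            {
                "sag": sag.id,
                "contig": host_contig.id,
                "repeats": [(a + offset, b + offset) for a, b in meta["repeats"]],
                "spacers": [(a + offset, b + offset) for a, b in meta["spacers"]],
                "source_virus": taxon,
                "virus_spacer_index": meta["virus_spacer_index"],
            }
        )
        return

    raise ValueError(f"unknown infection mode {mode!r}")


def _make_crispr_segment(
    virus: Contig, rng: np.random.Generator, *, flank: int = 5
) -> tuple[str, dict]:
    """Build a repeat-spacer array with one virus-derived spacer.

    Spacers and flanks are rejection-sampled so the columns immediately
    outside each repeat copy are heterogeneous: exact-repeat extension
    then stops exactly at the planted boundaries, making the array
    boundary-unambiguous.
    """
    repeat_len = int(rng.integers(23, 48))
    n_repeats = int(rng.integers(3, 7))
    repeat = random_dna(rng, repeat_len)
    v_idx = int(rng.integers(0, n_repeats - 1))
    for _attempt in range(100):
        spacers: list[str] = []
        for si in range(n_repeats - 1):
            if si == v_idx:
                slen = int(rng.integers(25, 46))
                start = int(rng.integers(0, virus.length - slen))
                spacers.append(virus.sequence[start : start + slen])
            else:
                spacers.append(random_dna(rng, int(rng.integers(20, 61))))
        left_flank = random_dna(rng, flank)
        right_flank = random_dna(rng, flank)
        after = [s[0] for s in spacers] + [right_flank[0]]
        before = [s[-1] for s in spacers] + [left_flank[-1]]
        if len(set(after)) > 1 and len(set(before)) > 1:
            break
    else:  # pragma: no cover - rejection virtually always succeeds
        raise RuntimeError("failed to build a boundary-unambiguous array")
    parts = [left_flank]
    repeats: list[tuple[int, int]] = []
    spacer_pos: list[tuple[int, int]] = []
    pos = flank
    for i in range(n_repeats):
        repeats.append((pos + 1, pos + repeat_len))
        parts.append(repeat)
        pos += repeat_len
        if i < n_repeats - 1:
            spacer_pos.append((pos + 1, pos + len(spacers[i])))
            parts.append(spacers[i])
            pos += len(spacers[i])
    parts.append(right_flank)
    return "".join(parts), {
        "flank": flank,
        "repeats": repeats,
        "spacers": spacer_pos,
        "virus_spacer_index": v_idx,
    }


# ---------------------------------------------------------------------------
# Metagenome simulation


@dataclass
class Metagenome:
    id: str
    reads: dict[str, str]
    total_bases: int
    linker_amplified: bool = False


def simulate_metagenome(
    community: Sequence[tuple[Contig, float]],
    *,
    n_reads: int,
    read_length: int,
    error_rate: float,
    rng: np.random.Generator,
    metagenome_id: str = "metagenome",
    linker_amplified: bool = False,
    truth: GroundTruth | None = None,
) -> Metagenome:
    """Substitution-only shotgun reads from a community.

    The source genome of each read is drawn with probability proportional
    to genome length times copy number; start positions are uniform, and
    circular genomes wrap. Linear genomes shorter than the read length
    are skipped with a warning.
    """
    usable = [
        (c, copy) for c, copy in community if c.circular or c.length >= read_length
    ]
    for c, _ in community:
        if not c.circular and c.length < read_length:
            logger.warning(
                "genome %s shorter than read length; skipped", c.id
            )
    if not usable:
        raise ValueError("no genome long enough to sample reads from")
    weights = np.array([c.length * copy for c, copy in usable], dtype=float)
    weights /= weights.sum()
    choices = rng.choice(len(usable), size=n_reads, p=weights)
    reads: dict[str, str] = {}
    for i, gi in enumerate(choices, 1):
        contig, _ = usable[int(gi)]
        if contig.circular:
            start = int(rng.integers(0, contig.length))
            doubled = contig.sequence + contig.sequence
            read = doubled[start : start + read_length]
        else:
            start = int(rng.integers(0, contig.length - read_length + 1))
            read = contig.sequence[start : start + read_length]
        if error_rate > 0:
            n_err = rng.binomial(read_length, error_rate)
            if n_err:
                seq = list(read)
                for p in rng.choice(read_length, size=n_err, replace=False):
                    choicesb = [b for b in "ACGT" if b != seq[p]]
                    seq[p] = choicesb[int(rng.integers(0, 3))]
                read = "".join(seq)
        if rng.random() < 0.5:
            read = reverse_complement(read)
        read_id = f"{metagenome_id}_r{i}"
        reads[read_id] = read
        if truth is not None:
            truth.read_provenance[read_id] = contig.id
    mg = Metagenome(
        id=metagenome_id,
        reads=reads,
        total_bases=sum(len(r) for r in reads.values()),
        linker_amplified=linker_amplified,
    )
    if truth is not None:
        for c, copy in community:
            truth.copy_numbers[c.id] = copy
    return mg


def sample_protein_fragments(
    genes: Sequence[Gene],
    *,
    coverage: float,
    fragment_aa: int = 80,
    rng: np.random.Generator,
    prefix: str = "frag",
) -> dict[str, str]:
    """Protein fragments emulating predicted genes from a metagenome.

    Each reference gene contributes enough uniformly-placed `fragment_aa`
    peptides for roughly `coverage`-fold amino-acid coverage. This is the
    short-read route, where recruitment compares predicted metagenome
    proteins to reference proteins.
    """
    fragments: dict[str, str] = {}
    i = 0
    for gene in genes:
        prot = gene.protein
        if len(prot) <= fragment_aa:
            n = max(1, int(round(coverage)))
            for _ in range(n):
                i += 1
                fragments[f"{prefix}_{i}"] = prot
            continue
        n = max(1, int(round(coverage * len(prot) / fragment_aa)))
        starts = rng.integers(0, len(prot) - fragment_aa + 1, size=n)
        for s in starts:
            i += 1
            fragments[f"{prefix}_{i}"] = prot[int(s) : int(s) + fragment_aa]
    return fragments


# ---------------------------------------------------------------------------
# Full scenario


@dataclass
class Scenario:
    config: ScenarioConfig
    sags: list[SAGAssembly]
    current_viruses: dict[str, tuple[Contig, list[Gene]]]
    past_viruses: dict[str, tuple[Contig, list[Gene]]]
    truth: GroundTruth

    def all_contigs(self) -> list[Contig]:
        return [c for sag in self.sags for c in sag.contigs]

    def contig_genes(self) -> dict[str, list[Gene]]:
        out: dict[str, list[Gene]] = {}
        for sag in self.sags:
            out.update(sag.contig_genes())
        return out


#: taxa making up the default community
CURRENT_TAXA = ("podoviridae_A", "podoviridae_B", "siphoviridae_A", "microviridae_A")
PAST_TAXA = ("past_caudo_A", "past_caudo_B")


def build_scenario(config: ScenarioConfig | None = None) -> Scenario:
    """The default end-to-end study: SAGs across a depth gradient.

    Infection frequency rises with depth; microviridae infections are
    linked to podovirus co-infection; past infections (defective
    prophages, CRISPR spacers) derive from viruses distinct from every
    current one, unless the overlap scenario is requested.
    """
    config = config or ScenarioConfig()
    rng = np.random.default_rng(config.seed)
    inf = config.infection
    truth = GroundTruth()

    current: dict[str, tuple[Contig, list[Gene]]] = {}
    caudo_kinds = {
        "podoviridae_A": "caudovirales",
        "podoviridae_B": "caudovirales",
        "siphoviridae_A": "caudovirales",
        "microviridae_A": "microviridae",
    }
    for taxon in CURRENT_TAXA:
        contig, genes = generate_viral_genome(
            config.viral, rng, kind=caudo_kinds[taxon], genome_id=taxon
        )
        current[taxon] = (contig, genes)
    past: dict[str, tuple[Contig, list[Gene]]] = {}
    for taxon in PAST_TAXA:
        contig, genes = generate_viral_genome(
            config.viral, rng, kind="caudovirales", genome_id=taxon
        )
        past[taxon] = (contig, genes)

    sags: list[SAGAssembly] = []
    for depth in config.depths:
        for si in range(1, config.sags_per_depth + 1):
            sag_id = f"sag_{depth}m_{si:02d}"
            contigs, genes = generate_host_genome(config.host, rng, sag_id=sag_id)
            for c in contigs:
                truth.contig_label[c.id] = "microbial"
            sag = SAGAssembly(id=sag_id, depth=depth, contigs=contigs, genes=genes)
            truth.infections[sag_id] = set()
            sags.append(sag)

    # current infections with depth-dependent frequency and linked co-infection
    caudo_pool = [t for t in CURRENT_TAXA if t != "microviridae_A"]
    for sag in sags:
        p = inf.p_current_by_depth.get(sag.depth, 0.0)
        if rng.random() < p:
            micro_ok = sag.depth >= 150
            if micro_ok and rng.random() < inf.p_microviridae:
                plant_infection(
                    sag, current["microviridae_A"], "current", rng, truth,
                    taxon="microviridae_A",
                )
                if rng.random() < inf.p_coinfection_link:
                    plant_infection(
                        sag, current["podoviridae_A"], "current", rng, truth,
                        taxon="podoviridae_A",
                    )
            else:
                taxon = caudo_pool[int(rng.integers(0, len(caudo_pool)))]
                plant_infection(sag, current[taxon], "current", rng, truth, taxon=taxon)
        elif rng.random() < inf.p_podo_background:
            plant_infection(
                sag, current["podoviridae_A"], "current", rng, truth,
                taxon="podoviridae_A",
            )

    # past infections: defective prophages (conserved pairwise) and CRISPRs
    for i, sag in enumerate(sags):
        if rng.random() < inf.p_prophage:
            partner = sags[(i + 1) % len(sags)]
            taxon = PAST_TAXA[int(rng.integers(0, len(PAST_TAXA)))]
            plant_infection(
                sag, past[taxon], "prophage", rng, truth,
                taxon=taxon, conserve_in=partner,
            )
        if rng.random() < inf.p_crispr:
            if inf.plant_past_current_overlap:
                source, taxon = current["podoviridae_A"], "podoviridae_A"
                inf = replace(inf, plant_past_current_overlap=False)
            else:
                taxon = PAST_TAXA[int(rng.integers(0, len(PAST_TAXA)))]
                source = past[taxon]
            plant_infection(
                sag, source, "crispr_spacer", rng, truth, taxon=taxon
            )

    return Scenario(
        config=config,
        sags=sags,
        current_viruses=current,
        past_viruses=past,
        truth=truth,
    )
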