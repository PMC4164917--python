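"""Fragment recruitment of metagenome sequences to viral and host references.

Viral references are tracked at the protein level (metagenome reads are
six-frame translated, or predicted proteins used directly) with the
pipeline's standard qualifying thresholds (e-value <= 1e-3, bit >= 50).
Host contig sets are tracked at the nucleotide level with a
mummer-style anchor-and-chain mapper (maximal exact matches >= 20 bp,
chained co-linearly with gaps <= 500 bp, clusters of < 100 anchored bp
discarded, identity from an end-to-end gap-filled alignment).

Presence is called per reference and metagenome from the fraction of
reference genes detected and the identity at which they were detected;
abundances are recruited bases normalised by reference length and
metagenome size, and a virus-to-host ratio compares the two for the same
SAG.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np

from .align import (
    DEFAULT_THRESHOLDS,
    _DEFAULT_ALIGNER,
    HitThresholds,
    _cigar_columns,
    align_proteins,
    _kmer_set,
)
from .models import Contig, Gene, SimilarityHit, reverse_complement
from .orfs import translate

logger = logging.getLogger(__name__)


def _raw_score(a: str, b: str) -> float:
    return float(_DEFAULT_ALIGNER.score(a, b))


@dataclass
class RecruitmentProfile:
    """Recruitment of one metagenome against one reference (set)."""

    reference_id: str
    metagenome_id: str
    n_reference_genes: int
    per_gene_best_identity: dict[str, float] = field(default_factory=dict)
    recruited_bases: int = 0
    #: nucleotide mode: recruited bases split by reference contig
    recruited_bases_per_contig: dict[str, int] = field(default_factory=dict)
    coverage: dict[str, np.ndarray] = field(default_factory=dict)
    #: nucleotide mode only: (covered genes, length-weighted mean identity)
    covered_genes: set[str] = field(default_factory=set)
    mean_cluster_identity: float = float("nan")
    cluster_identities: list[tuple[float, int]] = field(default_factory=list)


@dataclass
class PresenceCall:
    state: str  # present | related | absent | inconclusive
    frac_genes_high: float
    frac_genes_mid: float


# ---------------------------------------------------------------------------
# Protein-level recruitment (viral references)


def six_frame_peptides(read: str, *, min_aa: int = 10) -> list[str]:
    """Stop-free peptides from all six reading frames of a read."""
    peptides: list[str] = []
    for seq in (read, reverse_complement(read)):
        for frame in range(3):
            sub = seq[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            if not sub:
                continue
            prot = translate(sub, allow_internal_stop=True)
            peptides.extend(p for p in prot.split("*") if len(p) >= min_aa)
    return peptides


def recruit_protein(
    metagenome_sequences: Mapping[str, str],
    reference_genes: Sequence[Gene],
    *,
    reference_id: str,
    metagenome_id: str,
    reference_length: int | None = None,
    input_type: str = "protein",
    thresholds: HitThresholds = DEFAULT_THRESHOLDS,
    seed_k: int = 5,
) -> RecruitmentProfile:
    """Recruit metagenome reads or predicted proteins to reference genes.

    Each metagenome sequence is assigned to at most one reference gene
    (best bit score; ties to the gene with the lowest start coordinate).
    ``recruited_bases`` sums the nucleotide lengths of recruited sequences
    (3x the amino-acid length for protein input).

    `input_type` is ``"protein"`` (predicted proteins, the short-read
    assembly route) or ``"nucleotide"`` (raw reads, six-frame translated
    internally — the long-read route).
    """
    if not reference_genes:
        raise ValueError("empty reference gene set")
    genes = sorted(reference_genes, key=lambda g: g.start)
    index: dict[str, set[int]] = {}
    for gi, g in enumerate(genes):
        for kmer in _kmer_set(g.protein, seed_k):
            index.setdefault(kmer, set()).add(gi)
    total_subject = sum(len(g.protein) for g in genes)

    ref_len = reference_length or max(g.end for g in genes)
    profile = RecruitmentProfile(
        reference_id=reference_id,
        metagenome_id=metagenome_id,
        n_reference_genes=len(genes),
    )
    cov = np.zeros(ref_len, dtype=np.int64)

    for seq_id, seq in metagenome_sequences.items():
        if input_type == "nucleotide":
            peptides = six_frame_peptides(seq)
            nt_len = len(seq)
        elif input_type == "protein":
            peptides = [seq]
            nt_len = 3 * len(seq)
        else:
            raise ValueError(f"unknown input_type {input_type!r}")
        # cheap raw-score pass over seeded candidates; the full alignment
        # (identity, coordinates) is computed once, for the best pair only
        best_raw, best_gi, best_pep = 0.0, -1, ""
        for pep in peptides:
            candidates: set[int] = set()
            for kmer in _kmer_set(pep, seed_k):
                candidates |= index.get(kmer, set())
            for gi in sorted(candidates):
                raw = _raw_score(pep, genes[gi].protein)
                if raw > best_raw or (
                    raw == best_raw and best_gi >= 0 and genes[gi].start < genes[best_gi].start
                ):
                    best_raw, best_gi, best_pep = raw, gi, pep
        if best_gi < 0:
            continue
        best = align_proteins(
            best_pep,
            genes[best_gi].protein,
            query_id=seq_id,
            subject_id=genes[best_gi].id,
            search_space=len(best_pep) * max(total_subject, 1),
        )
        if best is None or not thresholds.passes(best):
            continue
        gene = genes[best_gi]
        prev = profile.per_gene_best_identity.get(gene.id, -1.0)
        profile.per_gene_best_identity[gene.id] = max(prev, best.identity)
        profile.recruited_bases += nt_len
        # map subject (aa) coordinates onto reference nucleotides
        if gene.strand == "+":
            nt_s = gene.start + 3 * (best.s_start - 1)
            nt_e = gene.start + 3 * best.s_end - 1
        else:
            nt_e = gene.end - 3 * (best.s_start - 1)
            nt_s = gene.end - 3 * best.s_end + 1
        cov[max(nt_s - 1, 0) : min(nt_e, ref_len)] += 1
    profile.coverage[reference_id] = cov
    return profile


def classify_presence(
    profile: RecruitmentProfile,
    *,
    ssdna: bool = False,
    linker_amplified: bool = False,
    high_identity: float = 80.0,
    mid_identity: float = 60.0,
    min_fraction: float = 0.75,
) -> PresenceCall:
    """Presence of a viral reference in a metagenome.

    present: > 75 % of genes detected at > 80 % identity; related: > 75 %
    of genes detected at 60-80 % identity (inclusive of the present
    class's support); otherwise absent — except that an absent call for an
    ssDNA reference in a linker-amplified metagenome is inconclusive,
    because that library chemistry selects against ssDNA templates (a
    positive detection still counts as presence).
    """
    n = profile.n_reference_genes
    idents = list(profile.per_gene_best_identity.values())
    f_high = sum(1 for x in idents if x > high_identity) / n
    f_mid = sum(1 for x in idents if x >= mid_identity) / n
    if f_high > min_fraction:
        state = "present"
    elif f_mid > min_fraction:
        state = "related"
    else:
        state = "absent"
        if ssdna and linker_amplified:
            state = "inconclusive"
    return PresenceCall(state=state, frac_genes_high=f_high, frac_genes_mid=f_mid)


# ---------------------------------------------------------------------------
# Nucleotide-level recruitment (host contig sets)

_ANCHOR_K = 20


def _merge_anchors(hits: list[tuple[int, int]], k: int) -> list[tuple[int, int, int]]:
    """Merge seed hits on the same diagonal into maximal exact matches.

    `hits` are (qpos, rpos) of exact k-mers; returns (qpos, rpos, length).
    """
    by_diag: dict[int, list[int]] = {}
    for q, r in hits:
        by_diag.setdefault(r - q, []).append(q)
    mems: list[tuple[int, int, int]] = []
    for diag, qs in by_diag.items():
        qs.sort()
        start = prev = qs[0]
        for q in qs[1:]:
            if q == prev + 1:
                prev = q
            else:
                mems.append((start, start + diag, prev - start + k))
                start = prev = q
        mems.append((start, start + diag, prev - start + k))
    return mems


def _chain_clusters(
    mems: list[tuple[int, int, int]], max_gap: int
) -> list[list[tuple[int, int, int]]]:
    """Greedy co-linear chaining of MEMs with bounded gaps."""
    mems = sorted(mems, key=lambda m: (m[1], m[0]))
    clusters: list[list[tuple[int, int, int]]] = []
    for mem in mems:
        placed = False
        for cluster in clusters:
            last = cluster[-1]
            gap_r = mem[1] - (last[1] + last[2])
            gap_q = mem[0] - (last[0] + last[2])
            if -_ANCHOR_K < gap_r <= max_gap and -_ANCHOR_K < gap_q <= max_gap and mem[0] >= last[0]:
                cluster.append(mem)
                placed = True
                break
        if not placed:
            clusters.append([mem])
    return clusters


def recruit_nucleotide(
    metagenome_reads: Mapping[str, str],
    microbial_contigs: Sequence[Contig],
    contig_genes: Mapping[str, Sequence[Gene]],
    *,
    reference_id: str,
    metagenome_id: str,
    min_cluster: int = 100,
    max_gap: int = 500,
    min_anchor: int = _ANCHOR_K,
) -> RecruitmentProfile:
    """Map reads onto a (set of) microbial contig(s), mummer-style.

    Exact `min_anchor`-mers are merged into maximal exact matches,
    chained co-linearly (gap <= `max_gap`), and chains whose summed
    anchor length is below `min_cluster` are discarded. Accepted clusters
    get an identity from an end-to-end alignment of the spanned read and
    reference segments. A gene counts as covered when >= 50 % of its span
    lies under accepted clusters; the profile's ANI is the length-weighted
    mean cluster identity. Each read is counted once (its best cluster).
    """
    if not microbial_contigs:
        raise ValueError("empty reference contig set")
    k = min_anchor
    index: dict[str, list[tuple[int, int]]] = {}
    for ci, contig in enumerate(microbial_contigs):
        seq = contig.sequence
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append((ci, i))

    profile = RecruitmentProfile(
        reference_id=reference_id,
        metagenome_id=metagenome_id,
        n_reference_genes=sum(len(v) for v in contig_genes.values()),
    )
    cov = {
        c.id: np.zeros(c.length, dtype=np.int64) for c in microbial_contigs
    }
    covered_intervals: dict[str, list[tuple[int, int]]] = {
        c.id: [] for c in microbial_contigs
    }

    for read_id, read in metagenome_reads.items():
        best_cluster = None  # (anchored_len, identity, ci, r_lo, r_hi)
        for strand_seq in (read, reverse_complement(read)):
            hits_by_contig: dict[int, list[tuple[int, int]]] = {}
            for i in range(len(strand_seq) - k + 1):
                for ci, rpos in index.get(strand_seq[i : i + k], ()):
                    hits_by_contig.setdefault(ci, []).append((i, rpos))
            for ci, hits in hits_by_contig.items():
                mems = _merge_anchors(hits, k)
                for cluster in _chain_clusters(mems, max_gap):
                    anchored = sum(m[2] for m in cluster)
                    if anchored < min_cluster:
                        continue
                    q_lo = cluster[0][0]
                    q_hi = cluster[-1][0] + cluster[-1][2]
                    r_lo = cluster[0][1]
                    r_hi = cluster[-1][1] + cluster[-1][2]
                    ref_seq = microbial_contigs[ci].sequence[r_lo:r_hi]
                    ident = _segment_identity(strand_seq[q_lo:q_hi], ref_seq)
                    if best_cluster is None or anchored > best_cluster[0]:
                        best_cluster = (anchored, ident, ci, r_lo, r_hi)
        if best_cluster is None:
            continue
        _, ident, ci, r_lo, r_hi = best_cluster
        contig = microbial_contigs[ci]
        profile.recruited_bases += len(read)
        profile.recruited_bases_per_contig[contig.id] = (
            profile.recruited_bases_per_contig.get(contig.id, 0) + len(read)
        )
        profile.cluster_identities.append((ident, r_hi - r_lo))
        cov[contig.id][r_lo:r_hi] += 1
        covered_intervals[contig.id].append((r_lo, r_hi))

    profile.coverage = cov
    for contig in microbial_contigs:
        for gene in contig_genes.get(contig.id, ()):  # genes are 1-based
            span = gene.end - gene.start + 1
            covered = int(np.count_nonzero(cov[contig.id][gene.start - 1 : gene.end]))
            if covered >= 0.5 * span:
                profile.covered_genes.add(gene.id)
    if profile.cluster_identities:
        idents = np.array([i for i, _ in profile.cluster_identities])
        weights = np.array([w for _, w in profile.cluster_identities])
        profile.mean_cluster_identity = float(np.average(idents, weights=weights))
    return profile


def _segment_identity(a: str, b: str) -> float:
    res = edlib.align(a, b, mode="NW", task="path")
    cols = _cigar_columns(res["cigar"])
    return 100.0 * (cols - res["editDistance"]) / cols


def host_presence(
    profile: RecruitmentProfile,
    *,
    min_gene_fraction: float = 0.75,
    min_ani: float = 95.0,
) -> PresenceCall:
    """Host present iff > 75 % of genes covered at ANI > 95 %."""
    n = profile.n_reference_genes
    frac = len(profile.covered_genes) / n if n else 0.0
    ani = profile.mean_cluster_identity
    present = frac > min_gene_fraction and ani > min_ani
    return PresenceCall(
        state="present" if present else "absent",
        frac_genes_high=frac,
        frac_genes_mid=frac,
    )


# ---------------------------------------------------------------------------
# Abundance


def relative_abundance(
    profile: RecruitmentProfile,
    reference_length_bp: int,
    metagenome_length_bases: int,
) -> float:
    """Recruited bases per reference bp per Mb of metagenome."""
    if reference_length_bp <= 0 or metagenome_length_bases <= 0:
        raise ValueError("reference and metagenome lengths must be positive")
    return (
        profile.recruited_bases
        / reference_length_bp
        / (metagenome_length_bases / 1e6)
    )


def virus_host_ratio(viral_ra: float, host_ra: float) -> float | None:
    """Viral over host relative abundance; None (missing) when host is 0."""
    if host_ra == 0:
        warnings.warn("host relative abundance is zero; ratio undefined")
        return None
    return viral_ra / host_ra


def identity_distribution(
    identities: Iterable[float], *, min_identity: float = 80.0
) -> dict:
    """Box summary (type-7 quartiles, Tukey outlier rule) of hit identities.

    Only values >= `min_identity` enter the summary, matching how
    population-variability distributions are drawn from qualifying
    recruitment hits.
    """
    values = np.array([v for v in identities if v >= min_identity], dtype=float)
    if values.size == 0:
        raise ValueError("no qualifying identities")
    hinge_lo, median, hinge_hi = np.percentile(values, [25, 50, 75])
    iqr = hinge_hi - hinge_lo
    lo, hi = hinge_lo - 1.5 * iqr, hinge_hi + 1.5 * iqr
    outliers = values[(values < lo) | (values > hi)]
    return {
        "median": float(median),
        "hinge_lo": float(hinge_lo),
        "hinge_hi": float(hinge_hi),
        "outliers": sorted(float(v) for v in outliers),
        "n": int(values.size),
    }


def coverage_profile(
    profile: RecruitmentProfile, window_bp: int, *, contig_id: str | None = None
) -> np.ndarray:
    """Mean per-position coverage in non-overlapping windows."""
    if window_bp < 100:
        raise ValueError("window_bp must be >= 100")
    key = contig_id or profile.reference_id
    cov = profile.coverage[key]
    n_windows = max(1, -(-len(cov) // window_bp))
    out = np.empty(n_windows)
    for w in range(n_windows):
        chunk = cov[w * window_bp : (w + 1) * window_bp]
        out[w] = chunk.mean() if chunk.size else 0.0
    return out
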