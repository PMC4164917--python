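"""Naive ORF calling and translation for synthetic genomes.

Real assemblies normally come with external gene calls (GFF3); this module
exists so that purely synthetic sequence can be pushed through the same
pipeline. ORFs are scanned on all six frames; a reported interval runs from
the start codon (ATG/GTG/TTG) through the last sense codon before a stop
(TAA/TAG/TGA), so a stop codon is required but sits outside the interval.
"""

from __future__ import annotations

from Bio.Seq import Seq

from .models import Contig, Gene, reverse_complement

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")


def translate(dna: str, *, allow_internal_stop: bool = False) -> str:
    """Translate an in-frame coding sequence with the bacterial code.

    A trailing stop is dropped. Codons containing ambiguity (N) translate
    to ``X``. Internal stops raise unless `allow_internal_stop` is set.
    """
    if len(dna) % 3 != 0:
        raise ValueError(f"sequence length {len(dna)} not divisible by 3")
    prot = str(Seq(dna).translate(table=11))
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot and not allow_internal_stop:
        raise ValueError(f"internal stop codon at codon {prot.index('*') + 1}")
    return prot


def _scan_frame(seq: str, frame: int, min_len_nt: int) -> list[tuple[int, int]]:
    """ORFs on the forward strand of `seq` in one frame (0-based half-open)."""
    orfs: list[tuple[int, int]] = []
    start: int | None = None
    for pos in range(frame, len(seq) - 2, 3):
        codon = seq[pos : pos + 3]
        if codon in STOP_CODONS:
            if start is not None and pos - start >= min_len_nt:
                orfs.append((start, pos))
            start = None
        elif start is None and codon in START_CODONS:
            start = pos
    # ORFs running off the contig end have no stop codon and are dropped.
    return orfs


def call_orfs(contig: Contig, min_len_nt: int = 90) -> list[Gene]:
    """Maximal open reading frames on all six frames, greedily deduplicated.

    Within each stop-to-stop segment the first start codon defines the
    (maximal) ORF. Overlapping ORFs across frames/strands are resolved
    greedily by descending length (ties: leftmost, then '+' strand), so the
    reported genes never overlap each other.
    """
    if min_len_nt < 30 or min_len_nt % 3 != 0:
        raise ValueError("min_len_nt must be >= 30 and divisible by 3")
    seq = contig.sequence
    n = len(seq)
    candidates: list[tuple[int, int, str]] = []  # (start0, end0 half-open, strand)
    for frame in range(3):
        for s, e in _scan_frame(seq, frame, min_len_nt):
            candidates.append((s, e, "+"))
    rc = reverse_complement(seq)
    for frame in range(3):
        for s, e in _scan_frame(rc, frame, min_len_nt):
            candidates.append((n - e, n - s, "-"))

    candidates.sort(key=lambda t: (-(t[1] - t[0]), t[0], t[2]))
    chosen: list[tuple[int, int, str]] = []
    for s, e, strand in candidates:
        if all(e <= cs or s >= ce for cs, ce, _ in chosen):
            chosen.append((s, e, strand))
    chosen.sort(key=lambda t: t[0])

    genes = []
    for i, (s, e, strand) in enumerate(chosen, 1):
        coding = seq[s:e] if strand == "+" else reverse_complement(seq[s:e])
        genes.append(
            Gene(
                id=f"{contig.id}_orf{i}",
                contig_id=contig.id,
                start=s + 1,
                end=e,
                strand=strand,
                protein=translate(coding),
            )
        )
    return genes
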