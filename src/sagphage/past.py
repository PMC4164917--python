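"""Remnants of past viral infection: CRISPR arrays and defective prophages.

CRISPR detection follows the classic repeat-recognition recipe: short
exact k-mer seeds recurring at array-like periods are chained, extended to
maximal repeats, and kept when the resulting array satisfies repeat/spacer
length bounds, strict repeat-spacer alternation and a minimum repeat-to-
consensus identity. Spacers are then searched against all contigs to link
arrays to the viruses that left them behind. Candidate prophage regions
(architecture-based sub-contig calls embedded in microbial contigs) are
promoted to defective prophages when they are flanked by microbial genes
and conserved in a microbial contig of a *different* SAG — an explicit,
reproducible stand-in for manual curation of conserved viral-like regions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib

from .align import best_infix_match, nucleotide_identity
from .detection import ViralCall
from .models import Contig, Gene, SimilarityHit

# CRT-like defaults; the tool this emulates does not publish one canonical
# parameter set, so these bounds are exposed as keyword arguments.
MIN_REPEATS = 3
REPEAT_LEN_RANGE = (19, 48)
SPACER_LEN_RANGE = (20, 60)
MIN_REPEAT_CONSENSUS_IDENTITY = 85.0
_SEED_K = 8
_PERIOD_RANGE = (39, 108)  # repeat+spacer length bounds


@dataclass
class CRISPRArray:
    """A repeat-spacer array on one contig (1-based inclusive intervals)."""

    contig_id: str
    repeat_consensus: str
    repeat_positions: list[tuple[int, int]]
    spacers: list[tuple[tuple[int, int], str]]

    @property
    def span(self) -> tuple[int, int]:
        return self.repeat_positions[0][0], self.repeat_positions[-1][1]

    @property
    def n_repeats(self) -> int:
        return len(self.repeat_positions)


@dataclass
class ProphageCall:
    """A viral-like region inside a microbial contig, conserved elsewhere."""

    contig_id: str
    region: tuple[int, int]  # 1-based nucleotide interval
    gene_region: tuple[int, int]  # gene-index range (0-based, end exclusive)
    conserved_in: list[str]
    status: str = "putative_defective_prophage"


def _consensus(strings: Sequence[str]) -> str:
    length = min(len(s) for s in strings)
    return "".join(
        Counter(s[i] for s in strings).most_common(1)[0][0] for i in range(length)
    )


def _repeat_identity(repeat: str, consensus: str) -> float:
    n = min(len(repeat), len(consensus))
    matches = sum(1 for a, b in zip(repeat, consensus) if a == b)
    return 100.0 * matches / max(len(repeat), len(consensus), 1)


def _extend_chain(seq: str, starts: list[int]) -> tuple[list[tuple[int, int]], str] | None:
    """Extend seed positions to maximal repeats agreeing across all copies."""
    left = 0
    while all(s - left - 1 >= 0 for s in starts) and len(
        {seq[s - left - 1] for s in starts}
    ) == 1:
        left += 1
    right = _SEED_K
    while all(s + right < len(seq) for s in starts) and len(
        {seq[s + right] for s in starts}
    ) == 1:
        right += 1
    begin = [s - left for s in starts]
    length = left + right
    # repeats must not run into each other
    for a, b in zip(begin, begin[1:]):
        if a + length > b:
            return None
    repeats = [(b, b + length) for b in begin]
    consensus = _consensus([seq[a:b] for a, b in repeats])
    return repeats, consensus


def find_crispr_arrays(
    contig: Contig,
    *,
    min_repeats: int = MIN_REPEATS,
    repeat_len_range: tuple[int, int] = REPEAT_LEN_RANGE,
    spacer_len_range: tuple[int, int] = SPACER_LEN_RANGE,
    min_consensus_identity: float = MIN_REPEAT_CONSENSUS_IDENTITY,
) -> list[CRISPRArray]:
    """Detect CRISPR repeat-spacer arrays on one contig.

    Overlapping candidate arrays are resolved in favour of the one with
    the most repeats, ties broken by longer total span.
    """
    if contig.length < 200:
        return []
    seq = contig.sequence
    occurrences: dict[str, list[int]] = {}
    for i in range(len(seq) - _SEED_K + 1):
        occurrences.setdefault(seq[i : i + _SEED_K], []).append(i)

    lo, hi = _PERIOD_RANGE
    candidates: list[CRISPRArray] = []
    seen_chains: set[tuple[int, ...]] = set()
    for kmer, positions in occurrences.items():
        if len(positions) < min_repeats:
            continue
        pos_set = positions
        for start_idx, p0 in enumerate(pos_set):
            chain = [p0]
            while True:
                nxt = next(
                    (q for q in pos_set if chain[-1] + lo <= q <= chain[-1] + hi),
                    None,
                )
                if nxt is None:
                    break
                chain.append(nxt)
            if len(chain) < min_repeats:
                continue
            key = tuple(chain)
            if key in seen_chains:
                continue
            seen_chains.add(key)
            extended = _extend_chain(seq, chain)
            if extended is None:
                continue
            repeats0, consensus = extended
            rlen = repeats0[0][1] - repeats0[0][0]
            if not repeat_len_range[0] <= rlen <= repeat_len_range[1]:
                continue
            spacers0 = [
                (repeats0[i][1], repeats0[i + 1][0])
                for i in range(len(repeats0) - 1)
            ]
            if not all(
                spacer_len_range[0] <= (b - a) <= spacer_len_range[1]
                for a, b in spacers0
            ):
                continue
            if any(
                _repeat_identity(seq[a:b], consensus) < min_consensus_identity
                for a, b in repeats0
            ):
                continue
            candidates.append(
                CRISPRArray(
                    contig_id=contig.id,
                    repeat_consensus=consensus,
                    repeat_positions=[(a + 1, b) for a, b in repeats0],
                    spacers=[((a + 1, b), seq[a:b]) for a, b in spacers0],
                )
            )

    # resolve overlaps: most repeats, ties by longer span
    candidates.sort(
        key=lambda arr: (-arr.n_repeats, -(arr.span[1] - arr.span[0]), arr.span)
    )
    accepted: list[CRISPRArray] = []
    for arr in candidates:
        s, e = arr.span
        if all(e < a.span[0] or s > a.span[1] for a in accepted):
            accepted.append(arr)
    accepted.sort(key=lambda a: a.span)
    return accepted


def match_spacers(
    arrays: Iterable[CRISPRArray],
    contigs: Sequence[Contig],
    *,
    min_identity: float = 95.0,
    min_coverage: float = 0.95,
) -> list[SimilarityHit]:
    """Search every spacer against every contig (both strands).

    The footprint of the spacer's own array is excluded, so an array never
    "matches" itself. A hit requires >= `min_identity` % identity over
    >= `min_coverage` of the spacer length.
    """
    hits: list[SimilarityHit] = []
    for arr in arrays:
        arr_start, arr_end = arr.span
        for idx, ((s_start, s_end), spacer) in enumerate(arr.spacers):
            spacer_id = f"{arr.contig_id}:spacer{idx + 1}"
            # combined identity+coverage budget expressed as edit distance
            max_ed = int(len(spacer) * (1 - min_identity / 100 * min_coverage))
            for contig in contigs:
                if contig.id == arr.contig_id:
                    # mask the array footprint to enforce self-exclusion
                    seq = (
                        contig.sequence[: arr_start - 1]
                        + "N" * (arr_end - arr_start + 1)
                        + contig.sequence[arr_end:]
                    )
                else:
                    seq = contig.sequence
                found = best_infix_match(spacer, seq, max_distance=max_ed)
                if found is None or found[2] < min_identity:
                    continue
                start0, end0, ident = found
                if (end0 - start0) < min_coverage * len(spacer):
                    continue
                hits.append(
                    SimilarityHit(
                        query_id=spacer_id,
                        subject_id=contig.id,
                        kind="nucleotide",
                        identity=ident,
                        aln_length=end0 - start0,
                        bit_score=0.0,
                        evalue=0.0,
                        q_start=1,
                        q_end=len(spacer),
                        s_start=start0 + 1,
                        s_end=end0,
                    )
                )
    return hits


def _region_nt_span(genes: Sequence[Gene], gene_region: tuple[int, int]) -> tuple[int, int]:
    block = genes[gene_region[0] : gene_region[1]]
    return block[0].start, block[-1].end


def _conserved_core(
    region_seq: str,
    contig: Contig,
    *,
    min_identity: float,
    chunk: int = 500,
) -> tuple[int, int] | None:
    """Longest conserved stretch of `region_seq` present in `contig`.

    The region is tiled into `chunk`-bp pieces, each placed end-to-end
    (infix) in the contig at >= `min_identity` % identity; the longest
    run of consecutive matching pieces is returned as a 0-based interval
    on the region (None when nothing matches).
    """
    n = len(region_seq)
    offsets = list(range(0, n, chunk))
    matched: list[bool] = []
    for off in offsets:
        piece = region_seq[off : off + chunk]
        if len(piece) < 100:
            matched.append(False)
            continue
        max_ed = int(len(piece) * (1 - min_identity / 100))
        found = best_infix_match(piece, contig.sequence, max_distance=max_ed)
        matched.append(found is not None and found[2] >= min_identity)
    best: tuple[int, int] | None = None
    run_start: int | None = None
    for i, ok in enumerate(matched + [False]):
        if ok and run_start is None:
            run_start = i
        elif not ok and run_start is not None:
            lo = offsets[run_start]
            hi = min(offsets[i - 1] + chunk, n)
            if best is None or hi - lo > best[1] - best[0]:
                best = (lo, hi)
            run_start = None
    return best


def _anchor_index(
    contigs: Sequence[Contig], *, k: int = 20, stride: int = 4
) -> dict[str, set[str]]:
    """Sampled exact k-mer membership index over a contig set."""
    index: dict[str, set[str]] = {}
    for contig in contigs:
        seq = contig.sequence
        for i in range(0, len(seq) - k + 1, stride):
            index.setdefault(seq[i : i + k], set()).add(contig.id)
    return index


def flag_defective_prophages(
    microbial_contigs: Sequence[Contig],
    contig_genes: Mapping[str, Sequence[Gene]],
    embedded_region_calls: Iterable[ViralCall],
    *,
    min_identity: float = 95.0,
    min_coverage: float = 0.5,
    min_conserved_bp: int = 2000,
) -> list[ProphageCall]:
    """Promote embedded viral-like regions to defective-prophage calls.

    The architecture scan over-reaches by design (it unions every
    qualifying window), so each candidate region is first refined to the
    viral remnant it contains: characterized genes at the edges are
    trimmed, then the longest stretch conserved at >= `min_identity` %
    identity in a microbial contig of a *different* SAG (located via
    exact 20-mer anchors, then chunk alignment) becomes the prophage
    core, provided it spans >= `min_conserved_bp` and >= `min_coverage`
    of the refined region, and microbial genes flank the core on both
    sides. This automates, with explicit thresholds, what was originally
    a manual check that viral-like regions recur between closely related
    bacterial contigs.
    """
    contig_list = list(microbial_contigs)
    by_id = {c.id: c for c in contig_list}
    anchors = _anchor_index(contig_list)
    k = 20
    calls: list[ProphageCall] = []
    for call in embedded_region_calls:
        if call.method != "region_metric":
            continue
        contig = by_id.get(call.contig_id)
        if contig is None:
            continue
        genes = sorted(contig_genes[call.contig_id], key=lambda g: g.start)
        gi, gj = call.region
        while gi < gj and genes[gi].characterized:
            gi += 1
        while gj > gi and genes[gj - 1].characterized:
            gj -= 1
        if gi >= gj:
            continue
        nt_start, nt_end = _region_nt_span(genes, (gi, gj))
        region_seq = contig.sequence[nt_start - 1 : nt_end]

        # anchor prefilter: which other-SAG contigs share exact sequence?
        # (probe step is coprime to the index stride so the sampling
        # grids cannot phase-lock)
        candidate_ids: dict[str, int] = {}
        for off in range(0, len(region_seq) - k + 1, 17):
            for cid in anchors.get(region_seq[off : off + k], ()):  # noqa: B905
                if by_id[cid].source_id != contig.source_id:
                    candidate_ids[cid] = candidate_ids.get(cid, 0) + 1
        supporters: list[str] = []
        best_core: tuple[int, int] | None = None
        for cid, count in sorted(candidate_ids.items()):
            if count < 5:
                continue
            core = _conserved_core(region_seq, by_id[cid], min_identity=min_identity)
            if core is None:
                continue
            lo, hi = core
            if hi - lo < min_conserved_bp:
                continue
            supporters.append(cid)
            if best_core is None or hi - lo > best_core[1] - best_core[0]:
                best_core = core
        if not supporters or best_core is None:
            continue

        core_start = nt_start + best_core[0]
        core_end = nt_start + best_core[1] - 1
        core_genes = [
            i for i, g in enumerate(genes)
            if g.start >= core_start and g.end <= core_end
        ]
        if not core_genes:
            continue
        cgi, cgj = core_genes[0], core_genes[-1] + 1
        if cgi < 1 or cgj > len(genes) - 1:
            continue  # no flanking microbial gene on one side
        region_nt = _region_nt_span(genes, (cgi, cgj))
        if (best_core[1] - best_core[0]) < min_coverage * (region_nt[1] - region_nt[0] + 1):
            continue
        calls.append(
            ProphageCall(
                contig_id=call.contig_id,
                region=region_nt,
                gene_region=(cgi, cgj),
                conserved_in=sorted(supporters),
            )
        )
    return calls


@dataclass
class PastSequence:
    """A past-infection sequence: a CRISPR spacer or a prophage region."""

    id: str
    kind: str  # "spacer" | "prophage"
    sequence: str


def collect_past_sequences(
    arrays: Iterable[CRISPRArray],
    prophages: Iterable[ProphageCall],
    contigs: Sequence[Contig],
) -> list[PastSequence]:
    by_id = {c.id: c for c in contigs}
    out: list[PastSequence] = []
    for arr in arrays:
        for idx, (_, spacer) in enumerate(arr.spacers):
            out.append(
                PastSequence(f"{arr.contig_id}:spacer{idx + 1}", "spacer", spacer)
            )
    for p in prophages:
        seq = by_id[p.contig_id].sequence[p.region[0] - 1 : p.region[1]]
        out.append(PastSequence(f"{p.contig_id}:prophage", "prophage", seq))
    return out


def check_past_vs_current(
    past_sequences: Sequence[PastSequence],
    current_viral_contigs: Sequence[Contig],
    *,
    spacer_min_identity: float = 95.0,
    spacer_min_coverage: float = 0.95,
    prophage_min_identity: float = 80.0,
    prophage_min_length: int = 500,
) -> list[tuple[str, str]]:
    """Nucleotide overlap between past- and current-infection sequences.

    Spacers are compared with the spacer-match thresholds; prophage
    regions require >= `prophage_min_identity` % identity over
    >= `prophage_min_length` bp (tested by tiling the region into
    `prophage_min_length`-bp chunks). An empty list means the two records
    of infection are disjoint.
    """
    if not past_sequences or not current_viral_contigs:
        raise ValueError("nothing to compare: past or current set is empty")
    pairs: set[tuple[str, str]] = set()
    for past in past_sequences:
        for contig in current_viral_contigs:
            if past.kind == "spacer":
                max_ed = int(
                    len(past.sequence)
                    * (1 - spacer_min_identity / 100 * spacer_min_coverage)
                )
                found = best_infix_match(
                    past.sequence, contig.sequence, max_distance=max_ed
                )
                if found is not None and found[2] >= spacer_min_identity:
                    pairs.add((past.id, contig.id))
            else:
                step = prophage_min_length // 2
                for off in range(0, max(1, len(past.sequence) - prophage_min_length + 1), step):
                    chunk = past.sequence[off : off + prophage_min_length]
                    if len(chunk) < prophage_min_length:
                        break
                    max_ed = int(len(chunk) * (1 - prophage_min_identity / 100))
                    found = best_infix_match(
                        chunk, contig.sequence, max_distance=max_ed
                    )
                    if found is not None and found[2] >= prophage_min_identity:
                        pairs.add((past.id, contig.id))
                        break
    return sorted(pairs)
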