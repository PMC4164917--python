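"""Viral-contig detection: metrics, hallmark keywords, association
fixpoint, virome support, and the architecture scan vs a brute-force
all-window oracle."""

import numpy as np
import pytest

from sagphage import (
    Gene,
    SimilarityHit,
    classify_contigs,
    compute_metrics,
    detect_by_virome_support,
    detect_hallmark,
    expand_by_association,
    scan_unknown_regions,
)
from sagphage.detection import LABEL_HALLMARK, LABEL_MICROBIAL, LABEL_PUTATIVE

from conftest import make_gene


# ---------------------------------------------------------------------------
# metrics


def genes_from(sizes=None, strands=None, characterized=None, contig="c1"):
    n = max(len(x) for x in (sizes, strands, characterized) if x is not None)
    sizes = sizes or [300] * n
    strands = strands or ["+"] * n
    characterized = characterized if characterized is not None else [False] * n
    genes, pos = [], 1
    for i in range(n):
        genes.append(
            make_gene(
                i + 1, contig=contig, start=pos, end=pos + sizes[i] - 1,
                strand=strands[i], characterized=characterized[i],
            )
        )
        pos += sizes[i] + 20
    return genes


def test_avg_gene_size_is_arithmetic_mean():
    m = compute_metrics(genes_from(sizes=[300, 600, 900]))
    assert m.avg_gene_size == 600.0


def test_strand_change_ratio_uses_total_gene_count():
    # changes at positions 2->3 and 4->5, divided by 5 genes
    m = compute_metrics(genes_from(strands=list("++--+")))
    assert m.strand_change_ratio == pytest.approx(0.4)


def test_uncharacterized_ratio():
    m = compute_metrics(genes_from(characterized=[True, False, False, True]))
    assert m.uncharacterized_ratio == 0.5


def test_metrics_require_genes():
    with pytest.raises(ValueError):
        compute_metrics([])


# ---------------------------------------------------------------------------
# hallmark


def test_hallmark_keyword_detection():
    genes = [
        make_gene(1, annotation="portal protein gp6", characterized=True),
        make_gene(2, annotation="hypothetical protein"),
    ]
    (call,) = detect_hallmark(genes)
    assert call.contig_id == "c1"
    assert call.evidence["hallmark_genes"] == ["c1_g1"]
    assert genes[0].hallmark_category.value == "portal"


def test_hallmark_requires_a_keyword():
    genes = [make_gene(1), make_gene(2)]
    assert detect_hallmark(genes) == []


def test_hallmark_case_insensitive_and_stoplist():
    genes = [make_gene(1, annotation="Terminase large subunit", characterized=True)]
    assert len(detect_hallmark(genes)) == 1
    genes = [make_gene(1, annotation="tailless particle protein", characterized=True)]
    assert detect_hallmark(genes) == []


# ---------------------------------------------------------------------------
# association


def hit(q, s, bit=100.0, evalue=1e-10):
    return SimilarityHit(
        query_id=q, subject_id=s, kind="protein", identity=80.0,
        aln_length=100, bit_score=bit, evalue=evalue,
    )


def contig_genes(contig, n):
    return [make_gene(i + 1, contig=contig) for i in range(n)]


def test_association_requires_half_the_genes():
    candidates = {
        "v": contig_genes("v", 4),
        "a": contig_genes("a", 6),
        "b": contig_genes("b", 6),
    }
    hits = [hit("a_g1", "v_g1"), hit("a_g2", "v_g2"), hit("a_g3", "v_g3"),
            hit("b_g1", "v_g1"), hit("b_g2", "v_g2")]
    calls = expand_by_association(candidates, ["v"], hits)
    assert [c.contig_id for c in calls] == ["a"]  # 3/6 flagged, 2/6 not
    assert calls[0].evidence["reference"] == "v"


def test_association_ignores_weak_hits():
    candidates = {"v": contig_genes("v", 4), "a": contig_genes("a", 4)}
    hits = [hit("a_g1", "v_g1", bit=40), hit("a_g2", "v_g2", evalue=0.1)]
    assert expand_by_association(candidates, ["v"], hits) == []


def test_association_iterates_to_fixpoint():
    """Chain A<-B<-C: B qualifies only via A, C only via B."""
    candidates = {
        "a": contig_genes("a", 4),
        "b": contig_genes("b", 4),
        "c": contig_genes("c", 4),
    }
    hits = [hit(f"b_g{i}", f"a_g{i}") for i in range(1, 3)] + [
        hit(f"c_g{i}", f"b_g{i}") for i in range(1, 3)
    ]
    calls = expand_by_association(candidates, ["a"], hits)
    assert {c.contig_id for c in calls} == {"b", "c"}

    # oracle: repeated single passes until stable gives the same set
    viral = {"a"}
    while True:
        new = set(viral)
        for cid, genes in candidates.items():
            if cid in new:
                continue
            for ref in viral:
                shared = {
                    h.query_id
                    for h in hits
                    if h.query_id.startswith(cid) and h.subject_id.startswith(ref)
                }
                if len(shared) / len(genes) >= 0.5:
                    new.add(cid)
        if new == viral:
            break
        viral = new
    assert {c.contig_id for c in calls} == viral - {"a"}


def test_association_monotone_in_hits():
    candidates = {"v": contig_genes("v", 4), "a": contig_genes("a", 4)}
    base = [hit("a_g1", "v_g1"), hit("a_g2", "v_g2")]
    flagged_before = {c.contig_id for c in expand_by_association(candidates, ["v"], base)}
    more = base + [hit("a_g3", "v_g3")]
    flagged_after = {c.contig_id for c in expand_by_association(candidates, ["v"], more)}
    assert flagged_before <= flagged_after


def test_association_unknown_gene_rejected():
    candidates = {"v": contig_genes("v", 4)}
    with pytest.raises(ValueError, match="unknown gene"):
        expand_by_association(candidates, ["v"], [hit("zzz", "v_g1")])


# ---------------------------------------------------------------------------
# virome support


def vhit(gene, identity):
    return SimilarityHit(
        query_id="read1", subject_id=gene, kind="protein", identity=identity,
        aln_length=60, bit_score=80, evalue=1e-9,
    )


@pytest.mark.parametrize(
    "identities,flagged",
    [
        ([91, 95, 90], True),
        ([99, 99], False),
        ([89, 95, 95], False),
    ],
)
def test_virome_support_rule(identities, flagged):
    candidates = {"x": contig_genes("x", 6)}
    hits = [vhit(f"x_g{i + 1}", ident) for i, ident in enumerate(identities)]
    calls = detect_by_virome_support(candidates, hits)
    assert bool(calls) is flagged


# ---------------------------------------------------------------------------
# architecture scan vs exhaustive window oracle


def oracle_regions(genes, min_genes, min_unchar=0.5, min_strand=0.8,
                   over_unchar=False):
    """Union of all qualifying windows, written independently."""
    n = len(genes)
    windows = []
    for i in range(n):
        for j in range(i + min_genes, n + 1):
            w = genes[i:j]
            unchar = [g for g in w if not g.characterized]
            if len(unchar) < min_unchar * len(w):
                continue
            pool = unchar if over_unchar else w
            if not pool:
                continue
            plus = sum(g.strand == "+" for g in pool)
            if max(plus, len(pool) - plus) < min_strand * len(pool):
                continue
            windows.append((i, j))
    covered = sorted({k for i, j in windows for k in range(i, j)})
    regions, cur = [], None
    for i, j in sorted(windows):
        if cur is None:
            cur = [i, j]
        elif i < cur[1]:
            cur[1] = max(cur[1], j)
        else:
            regions.append(tuple(cur))
            cur = [i, j]
    if cur:
        regions.append(tuple(cur))
    return regions


def random_contig_genes(rng, n, contig="c1"):
    strands = rng.choice(["+", "-"], size=n)
    chars = rng.random(n) < rng.uniform(0.2, 0.8)
    return genes_from(
        strands=list(strands), characterized=list(chars), contig=contig
    )


def test_scan_matches_oracle_on_random_contigs(rng):
    for _ in range(200):
        n = int(rng.integers(1, 31))
        genes = random_contig_genes(rng, n)
        for min_genes in (4, 8):
            got = [c.region for c in scan_unknown_regions(genes, min_genes)]
            assert got == oracle_regions(genes, min_genes)


def test_scan_whole_contig_region():
    # 10 genes, all '+', 6 uncharacterized -> one region covering genes 1-10
    chars = [True, False, False, True, False, False, True, False, False, True]
    genes = genes_from(strands=["+"] * 10, characterized=chars)
    (call,) = scan_unknown_regions(genes, 8)
    assert call.region == (0, 10)


def test_scan_alternating_strands_blocked_by_coherence():
    genes = genes_from(strands=["+", "-"] * 5, characterized=[False] * 10)
    assert scan_unknown_regions(genes, 8) == []


def test_scan_finds_embedded_block_and_matches_oracle():
    """Characterized mixed-strand prefix, then a coherent uncharacterized
    block: the reported region must contain the block and agree exactly
    with the exhaustive oracle."""
    strands = ["+", "-"] * 5 + ["+"] * 10
    chars = [True] * 10 + [True, False, False, False, True, False, False, False, False, True]
    genes = genes_from(strands=strands, characterized=chars)
    calls = scan_unknown_regions(genes, 8)
    assert len(calls) == 1
    s, e = calls[0].region
    assert s <= 10 and e == 20  # contains the planted block (genes 11-20)
    assert [c.region for c in calls] == oracle_regions(genes, 8)


def test_scan_minimum_region_size_enforced():
    with pytest.raises(ValueError):
        scan_unknown_regions(genes_from(strands=["+"] * 10), 3)


# ---------------------------------------------------------------------------
# classification


def test_classification_precedence_and_embedded_regions():
    from sagphage.detection import ViralCall

    cg = {
        "h": contig_genes("h", 10),
        "p": contig_genes("p", 10),
        "m": contig_genes("m", 40),
        "plain": contig_genes("plain", 5),
    }
    calls = [
        ViralCall("h", (0, 10), "hallmark", {}),
        ViralCall("h", (0, 10), "region_metric", {}),
        ViralCall("p", (0, 10), "region_metric", {}),
        ViralCall("m", (10, 18), "region_metric", {}),
    ]
    out = classify_contigs(cg, calls)
    assert out["h"]["label"] == LABEL_HALLMARK
    assert out["p"]["label"] == LABEL_PUTATIVE
    assert out["m"]["label"] == LABEL_MICROBIAL
    assert [c.region for c in out["m"]["embedded_regions"]] == [(10, 18)]
    assert out["plain"]["label"] == LABEL_MICROBIAL
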