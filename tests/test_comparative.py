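"""Shared-gene fractions, genus clustering, clonality and Fisher exact."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from sagphage import (
    ContingencyTable2x2,
    SimilarityHit,
    clonality,
    cluster_genera,
    cooccurrence_table,
    fisher_exact_2x2,
    shared_gene_fraction,
)
from sagphage.models import reverse_complement
from sagphage.simulate import random_dna

from conftest import make_gene


def hit(q, s, bit=100.0, evalue=1e-10):
    return SimilarityHit(
        query_id=q, subject_id=s, kind="protein", identity=80.0,
        aln_length=100, bit_score=bit, evalue=evalue,
    )


def genome(prefix, n):
    return [make_gene(i + 1, contig=prefix) for i in range(n)]


# ---------------------------------------------------------------------------
# shared-gene fraction and genus clustering


def test_identical_genomes_share_everything():
    a, b = genome("a", 10), genome("b", 10)
    hits = [hit(f"a_g{i}", f"b_g{i}") for i in range(1, 11)]
    assert shared_gene_fraction(a, b, hits) == 1.0


def test_directed_fractions_are_averaged():
    a, b = genome("a", 10), genome("b", 20)
    hits = [hit(f"a_g{i}", f"b_g{i}") for i in range(1, 6)]
    assert shared_gene_fraction(a, b, hits) == pytest.approx((0.5 + 0.25) / 2)


def test_no_hits_no_sharing():
    assert shared_gene_fraction(genome("a", 5), genome("b", 5), []) == 0.0
    with pytest.raises(ValueError):
        shared_gene_fraction([], genome("b", 5), [])


def test_single_linkage_transitivity():
    ids = ["A", "B", "C"]
    fm = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.45], [0.2, 0.45, 1.0]])
    (cluster,) = cluster_genera(ids, fm)
    assert cluster.members == ["A", "B", "C"]


def test_all_distant_genomes_are_singletons():
    ids = ["A", "B", "C"]
    fm = np.full((3, 3), 0.1)
    np.fill_diagonal(fm, 1.0)
    clusters = cluster_genera(ids, fm)
    assert [c.members for c in clusters] == [["A"], ["B"], ["C"]]


def test_threshold_is_inclusive():
    ids = ["A", "B"]
    fm = np.array([[1.0, 0.40], [0.40, 1.0]])
    (cluster,) = cluster_genera(ids, fm)
    assert cluster.members == ["A", "B"]


def test_clustering_invariant_to_order():
    rng = np.random.default_rng(3)
    ids = [f"g{i}" for i in range(6)]
    fm = rng.uniform(0, 0.8, size=(6, 6))
    fm = (fm + fm.T) / 2
    np.fill_diagonal(fm, 1.0)
    ref = [c.members for c in cluster_genera(ids, fm)]
    perm = rng.permutation(6)
    shuffled = [c.members for c in cluster_genera(
        [ids[i] for i in perm], fm[np.ix_(perm, perm)]
    )]
    assert ref == shuffled


# ---------------------------------------------------------------------------
# clonality


def test_identical_sequences_are_clonal(rng):
    seq = random_dna(rng, 5000)
    out = clonality({f"m{i}": seq for i in range(8)})
    assert out["clonal"] and out["min_identity"] == 100.0


def test_rotation_normalisation(rng):
    seq = random_dna(rng, 5000)
    rotated = seq[1000:] + seq[:1000]
    out = clonality({"a": seq, "b": rotated}, circular=True)
    assert out["min_identity"] == 100.0 and out["clonal"]
    flipped = reverse_complement(rotated)
    out2 = clonality({"a": seq, "b": flipped}, circular=True)
    assert out2["min_identity"] == 100.0


def test_single_substitution_breaks_clonality(rng):
    seq = random_dna(rng, 5000)
    mutated = list(seq)
    mutated[2500] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[2500]]
    out = clonality({"a": seq, "b": "".join(mutated)}, circular=False)
    assert out["min_identity"] == pytest.approx(100 * 4999 / 5000)
    assert not out["clonal"]


def test_clonality_needs_two_sequences(rng):
    with pytest.raises(ValueError):
        clonality({"a": random_dna(rng, 100)})


# ---------------------------------------------------------------------------
# co-occurrence table


def test_cooccurrence_cells():
    calls = {"s1": {"A", "B"}, "s2": {"A"}, "s3": set(), "s4": {"B"}}
    t = cooccurrence_table(calls, "A", "B")
    assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)


def test_cooccurrence_validation():
    calls = {"s1": {"A"}, "s2": {"B"}}
    with pytest.raises(ValueError, match="unknown viral group"):
        cooccurrence_table(calls, "A", "Z")
    with pytest.raises(ValueError, match="empty"):
        cooccurrence_table(calls, "A", "B", sag_subset=[])


# ---------------------------------------------------------------------------
# Fisher exact


def oracle_fisher(a, b, c, d, rel_tol=1e-7):
    """Exact-rational enumeration oracle (integer arithmetic)."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    denom = comb(n, c1)
    k_min, k_max = max(0, c1 - (n - r1)), min(r1, c1)
    nums = {k: comb(r1, k) * comb(n - r1, c1 - k) for k in range(k_min, k_max + 1)}
    scale = 10 ** 9
    obs = nums[a]
    total = sum(v for v in nums.values() if v * scale <= obs * (scale + int(scale * rel_tol)))
    return float(Fraction(total, denom))


@pytest.mark.parametrize(
    "table,expected",
    [
        ((3, 1, 1, 3), 34 / 70),     # full enumeration over margins (4,4,4,4)
        ((5, 0, 0, 5), 2 / 252),     # margins (5,5,5,5)
        ((2, 2, 2, 2), 1.0),         # symmetric table
    ],
)
def test_fisher_derived_examples(table, expected):
    p = fisher_exact_2x2(ContingencyTable2x2(*table))
    assert p == pytest.approx(expected, abs=1e-12)


def test_fisher_matches_scipy_on_random_tables(rng):
    for _ in range(200):
        a, b, c, d = (int(x) for x in rng.integers(0, 30, size=4))
        if a + b + c + d == 0:
            continue
        ours = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
        theirs = scipy_fisher([[a, b], [c, d]]).pvalue
        assert ours == pytest.approx(theirs, abs=1e-9)


def test_fisher_matches_exact_oracle_on_random_tables(rng):
    for _ in range(300):
        a, b, c, d = (int(x) for x in rng.integers(0, 25, size=4))
        if a + b + c + d == 0:
            continue
        ours = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
        assert ours == pytest.approx(oracle_fisher(a, b, c, d), abs=1e-10)


def test_fisher_rejects_empty_table():
    with pytest.raises(ValueError):
        fisher_exact_2x2(ContingencyTable2x2(0, 0, 0, 0))
    with pytest.raises(ValueError):
        ContingencyTable2x2(-1, 0, 0, 1)
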