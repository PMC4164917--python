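"""Genus-level comparison of phage genomes and co-infection statistics.

Phage genera are defined operationally by shared gene content: two
genomes sharing >= 40 % of their genes (qualifying protein hits, mean of
the two directed fractions) belong to the same genus, and genera are the
single-linkage connected components of that relation. Clonality between
genome copies is assessed by global nucleotide identity, normalising over
rotations and strands for circular genomes. Co-infection between two
viral groups across a SAG collection is summarised in a 2x2 contingency
table and tested with the two-sided Fisher exact test (probability-mass
method, computed by hypergeometric enumeration).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
from scipy.stats import hypergeom

from .align import DEFAULT_THRESHOLDS, HitThresholds, _cigar_columns
from .models import Gene, SimilarityHit, reverse_complement


@dataclass
class GenusCluster:
    members: list[str]
    pairwise_shared_fraction: np.ndarray  # symmetric, unit diagonal


@dataclass
class ContingencyTable2x2:
    """Rows: infected / not by virus group A; columns: by group B."""

    a: int  # both
    b: int  # A only
    c: int  # B only
    d: int  # neither

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")


def shared_gene_fraction(
    genome_a_genes: Sequence[Gene],
    genome_b_genes: Sequence[Gene],
    protein_hits: Iterable[SimilarityHit],
    *,
    thresholds: HitThresholds = DEFAULT_THRESHOLDS,
    denominator: str = "mean",
) -> float:
    """Fraction of genes shared between two genomes.

    A gene is shared when it has a qualifying hit to any gene of the other
    genome (hits are read symmetrically). The two directed fractions
    |A shared|/|A| and |B shared|/|B| are combined by their mean
    (`denominator="mean"`) or by the smaller genome (`"min"`), since the
    genus criterion leaves the denominator open.
    """
    if not genome_a_genes or not genome_b_genes:
        raise ValueError("empty genome")
    ids_a = {g.id for g in genome_a_genes}
    ids_b = {g.id for g in genome_b_genes}
    shared_a: set[str] = set()
    shared_b: set[str] = set()
    for hit in protein_hits:
        if not thresholds.passes(hit):
            continue
        q, s = hit.query_id, hit.subject_id
        if q in ids_a and s in ids_b:
            shared_a.add(q)
            shared_b.add(s)
        elif q in ids_b and s in ids_a:
            shared_b.add(q)
            shared_a.add(s)
    f_ab = len(shared_a) / len(ids_a)
    f_ba = len(shared_b) / len(ids_b)
    if denominator == "mean":
        return (f_ab + f_ba) / 2
    if denominator == "min":
        return max(f_ab, f_ba) if len(ids_a) == len(ids_b) else (
            f_ab if len(ids_a) < len(ids_b) else f_ba
        )
    raise ValueError(f"unknown denominator mode {denominator!r}")


def shared_fraction_matrix(
    genomes: Mapping[str, Sequence[Gene]],
    protein_hits: Iterable[SimilarityHit],
    *,
    thresholds: HitThresholds = DEFAULT_THRESHOLDS,
    denominator: str = "mean",
) -> tuple[list[str], np.ndarray]:
    """Symmetric shared-gene-fraction matrix over a set of genomes."""
    ids = sorted(genomes)
    hits = [h for h in protein_hits if thresholds.passes(h)]
    n = len(ids)
    fm = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            f = shared_gene_fraction(
                genomes[ids[i]],
                genomes[ids[j]],
                hits,
                thresholds=thresholds,
                denominator=denominator,
            )
            fm[i, j] = fm[j, i] = f
    return ids, fm


def cluster_genera(
    genome_ids: Sequence[str],
    fraction_matrix: np.ndarray,
    threshold: float = 0.40,
) -> list[GenusCluster]:
    """Single-linkage connected components over shared-fraction >= threshold.

    Genomes sharing fewer genes than the threshold with every cluster
    member found so far seed their own genus. Output is invariant to the
    input order (clusters and members are sorted by id).
    """
    fm = np.asarray(fraction_matrix, dtype=float)
    n = len(genome_ids)
    if fm.shape != (n, n):
        raise ValueError("fraction matrix shape does not match genome ids")
    if not np.allclose(fm, fm.T):
        raise ValueError("fraction matrix must be symmetric")
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if fm[i, j] >= threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    clusters = []
    for members in groups.values():
        order = sorted(members, key=lambda i: genome_ids[i])
        sub = fm[np.ix_(order, order)].copy()
        np.fill_diagonal(sub, 1.0)
        clusters.append(
            GenusCluster(
                members=[genome_ids[i] for i in order],
                pairwise_shared_fraction=sub,
            )
        )
    clusters.sort(key=lambda c: c.members[0])
    return clusters


def _pair_identity(a: str, b: str, circular: bool) -> float:
    """Best global nucleotide identity over strands (and rotations if circular)."""
    best = 0.0
    if circular:
        # infix alignment of a against the doubled subject finds the best
        # rotation without enumerating start points explicitly
        for subject in (b + b, reverse_complement(b) + reverse_complement(b)):
            res = edlib.align(a, subject, mode="HW", task="path")
            cols = _cigar_columns(res["cigar"])
            best = max(best, 100.0 * (cols - res["editDistance"]) / cols)
    else:
        for subject in (b, reverse_complement(b)):
            res = edlib.align(a, subject, mode="NW", task="path")
            cols = _cigar_columns(res["cigar"])
            best = max(best, 100.0 * (cols - res["editDistance"]) / cols)
    return best


def clonality(
    genome_sequences: Mapping[str, str],
    *,
    circular: bool = True,
) -> dict:
    """Pairwise nucleotide identity summary for a set of genome copies.

    The set is clonal iff the minimum pairwise identity is exactly 100.
    For circular genomes the comparison is rotation- and strand-
    normalised.
    """
    ids = sorted(genome_sequences)
    if len(ids) < 2:
        raise ValueError("need at least two sequences")
    pairwise: dict[tuple[str, str], float] = {}
    for x, y in itertools.combinations(ids, 2):
        ident = _pair_identity(
            genome_sequences[x], genome_sequences[y], circular
        )
        pairwise[(x, y)] = ident
    min_identity = min(pairwise.values())
    return {
        "pairwise": pairwise,
        "min_identity": min_identity,
        "clonal": min_identity == 100.0,
    }


def cooccurrence_table(
    per_sag_calls: Mapping[str, set[str]],
    group_a: str,
    group_b: str,
    sag_subset: Sequence[str] | None = None,
) -> ContingencyTable2x2:
    """2x2 co-infection table over a SAG collection.

    `per_sag_calls` maps each SAG to the set of viral group labels
    detected in it. Unknown group labels (appearing in no SAG) raise.
    """
    known = set().union(*per_sag_calls.values()) if per_sag_calls else set()
    for label in (group_a, group_b):
        if label not in known:
            raise ValueError(f"unknown viral group label {label!r}")
    sags = list(per_sag_calls) if sag_subset is None else list(sag_subset)
    if not sags:
        raise ValueError("empty SAG subset")
    a = b = c = d = 0
    for sag in sags:
        calls = per_sag_calls.get(sag, set())
        has_a, has_b = group_a in calls, group_b in calls
        if has_a and has_b:
            a += 1
        elif has_a:
            b += 1
        elif has_b:
            c += 1
        else:
            d += 1
    return ContingencyTable2x2(a, b, c, d)


def fisher_exact_2x2(
    table: ContingencyTable2x2, *, rel_tol: float = 1e-7
) -> float:
    """Two-sided Fisher exact p-value by hypergeometric enumeration.

    Sums the probabilities of every table with the observed margins whose
    probability does not exceed that of the observed table (probability-
    mass method), with a relative tolerance on the comparison to absorb
    floating-point ties.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    if n == 0:
        raise ValueError("all-zero contingency table")
    r1, c1 = a + b, a + c
    k_min = max(0, c1 - (n - r1))
    k_max = min(r1, c1)
    ks = np.arange(k_min, k_max + 1)
    pmf = hypergeom.pmf(ks, n, r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    p = float(pmf[pmf <= p_obs * (1 + rel_tol)].sum())
    return min(p, 1.0)
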