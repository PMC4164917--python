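"""Fragment recruitment, presence classification, abundance arithmetic,
identity distributions and coverage profiles."""

import numpy as np
import pytest

from sagphage import (
    Contig,
    classify_presence,
    coverage_profile,
    generate_viral_genome,
    host_presence,
    identity_distribution,
    recruit_nucleotide,
    recruit_protein,
    relative_abundance,
    virus_host_ratio,
)
from sagphage.recruitment import RecruitmentProfile
from sagphage.simulate import (
    HostParams,
    ViralParams,
    generate_host_genome,
    mutate_to_identity,
    random_dna,
    sample_protein_fragments,
)


@pytest.fixture(scope="module")
def reference():
    rng = np.random.default_rng(11)
    contig, genes = generate_viral_genome(
        ViralParams(caudo_length_range=(15_000, 16_000)), rng,
        kind="caudovirales", genome_id="ref",
    )
    return contig, genes


# ---------------------------------------------------------------------------
# protein recruitment


def test_exact_fragments_recruit_at_100(reference, rng):
    contig, genes = reference
    frags = sample_protein_fragments(genes, coverage=3, rng=rng)
    profile = recruit_protein(
        frags, genes, reference_id="ref", metagenome_id="m",
        reference_length=contig.length,
    )
    assert set(profile.per_gene_best_identity) == {g.id for g in genes}
    assert all(v == 100.0 for v in profile.per_gene_best_identity.values())
    assert profile.recruited_bases == 3 * sum(len(s) for s in frags.values())


def test_unrelated_fragments_rarely_recruit(reference, rng):
    contig, genes = reference
    frags = {f"r{i}": "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=80))
             for i in range(200)}
    profile = recruit_protein(
        frags, genes, reference_id="ref", metagenome_id="m",
        reference_length=contig.length,
    )
    high = [g for g, v in profile.per_gene_best_identity.items() if v >= 60]
    assert len(high) <= 0.01 * len(genes)


def test_zero_reads_gives_empty_profile(reference):
    contig, genes = reference
    profile = recruit_protein(
        {}, genes, reference_id="ref", metagenome_id="m",
        reference_length=contig.length,
    )
    assert profile.per_gene_best_identity == {} and profile.recruited_bases == 0
    assert classify_presence(profile).state == "absent"


def test_empty_reference_rejected():
    with pytest.raises(ValueError):
        recruit_protein({}, [], reference_id="r", metagenome_id="m")


# ---------------------------------------------------------------------------
# presence classification


def profile_with(identities, n=20):
    p = RecruitmentProfile(reference_id="r", metagenome_id="m", n_reference_genes=n)
    p.per_gene_best_identity = {f"g{i}": v for i, v in enumerate(identities)}
    return p


def test_present_when_over_75pct_genes_above_80():
    idents = list(np.linspace(85, 95, 16))
    assert classify_presence(profile_with(idents)).state == "present"


def test_related_when_mid_identity():
    assert classify_presence(profile_with([70.0] * 16)).state == "related"


def test_exact_75pct_boundary_is_absent():
    assert classify_presence(profile_with([90.0] * 15)).state == "absent"


def test_ssdna_linker_amplified_absent_is_inconclusive():
    p = profile_with([95.0, 95.0])
    assert classify_presence(p, ssdna=True, linker_amplified=True).state == "inconclusive"
    # a positive detection is never downgraded
    q = profile_with([95.0] * 16)
    assert classify_presence(q, ssdna=True, linker_amplified=True).state == "present"


def test_presence_monotone_in_identity(rng):
    order = {"absent": 0, "inconclusive": 0, "related": 1, "present": 2}
    for _ in range(50):
        idents = list(rng.uniform(40, 100, size=12))
        base = classify_presence(profile_with(idents, n=12)).state
        i = int(rng.integers(0, 12))
        idents[i] = min(100.0, idents[i] + rng.uniform(0, 30))
        raised = classify_presence(profile_with(idents, n=12)).state
        assert order[raised] >= order[base]


# ---------------------------------------------------------------------------
# nucleotide recruitment


@pytest.fixture(scope="module")
def host():
    rng = np.random.default_rng(5)
    contigs, genes = generate_host_genome(
        HostParams(contigs_per_sag=1, genes_per_contig=30), rng, sag_id="h"
    )
    cg = {contigs[0].id: [g for g in genes]}
    return contigs, cg


def reads_from(contig, n, length, rng, identity=100.0):
    reads = {}
    for i in range(n):
        s = int(rng.integers(0, contig.length - length + 1))
        read = contig.sequence[s : s + length]
        if identity < 100:
            read, _ = mutate_to_identity(read, identity, level="nucleotide", rng=rng)
        reads[f"r{i}"] = read
    return reads


def test_identical_reads_cover_all_genes_at_ani_100(host, rng):
    contigs, cg = host
    reads = reads_from(contigs[0], 600, 250, rng)
    profile = recruit_nucleotide(
        reads, contigs, cg, reference_id="h", metagenome_id="m"
    )
    assert profile.mean_cluster_identity == 100.0
    assert profile.covered_genes == {g.id for genes in cg.values() for g in genes}
    assert host_presence(profile).state == "present"


def test_90pct_reads_recover_realized_identity(host, rng):
    contigs, cg = host
    reads = reads_from(contigs[0], 150, 500, rng, identity=90.0)
    profile = recruit_nucleotide(
        reads, contigs, cg, reference_id="h", metagenome_id="m"
    )
    assert profile.mean_cluster_identity == pytest.approx(90.0, abs=1.0)
    assert host_presence(profile).state == "absent"  # ANI < 95


def test_unrelated_reads_not_recruited(host, rng):
    contigs, cg = host
    reads = {f"r{i}": random_dna(rng, 250) for i in range(100)}
    profile = recruit_nucleotide(
        reads, contigs, cg, reference_id="h", metagenome_id="m"
    )
    assert profile.recruited_bases == 0


def test_cluster_gap_rule(rng):
    """Anchors 80 bp apart are chained; 600 bp apart are split."""
    from sagphage.recruitment import _chain_clusters

    near = [(0, 1000, 40), (120, 1120, 40)]  # reference gap 80
    assert len(_chain_clusters(near, max_gap=500)) == 1
    far = [(0, 1000, 40), (640, 1640, 40)]  # reference gap 600
    assert len(_chain_clusters(far, max_gap=500)) == 2


# ---------------------------------------------------------------------------
# abundance


def test_relative_abundance_formula():
    p = RecruitmentProfile("r", "m", 1, recruited_bases=200_000)
    assert relative_abundance(p, 20_000, 10_000_000) == pytest.approx(1.0)
    p0 = RecruitmentProfile("r", "m", 1, recruited_bases=0)
    assert relative_abundance(p0, 20_000, 10_000_000) == 0.0
    assert relative_abundance(p, 20_000, 20_000_000) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        relative_abundance(p, 0, 1)


def test_virus_host_ratio_contract():
    assert virus_host_ratio(0.3, 1.0) == pytest.approx(0.3)
    assert virus_host_ratio(0.0, 2.0) == 0.0
    with pytest.warns(UserWarning):
        assert virus_host_ratio(0.5, 0.0) is None


# ---------------------------------------------------------------------------
# identity distribution and coverage profile


def test_identity_distribution_order_statistics():
    d = identity_distribution([80, 85, 90, 95, 100])
    assert (d["median"], d["hinge_lo"], d["hinge_hi"]) == (90, 85, 95)
    assert d["outliers"] == []


def test_identity_distribution_constant_values():
    d = identity_distribution([88.0] * 10)
    assert d["median"] == d["hinge_lo"] == d["hinge_hi"] == 88.0
    assert d["outliers"] == []


def test_identity_distribution_outlier_rule():
    d = identity_distribution([80.0] * 19 + [100.0])
    assert d["hinge_lo"] == d["hinge_hi"] == 80.0
    assert d["outliers"] == [100.0]


def test_identity_distribution_filters_below_80():
    d = identity_distribution([50.0, 85.0, 90.0])
    assert d["n"] == 2
    with pytest.raises(ValueError):
        identity_distribution([50.0])


def test_coverage_profile_windows_and_planted_gap():
    p = RecruitmentProfile("r", "m", 1)
    cov = np.full(10_000, 10, dtype=np.int64)
    cov[3_000:4_000] = 0  # planted gap
    p.coverage["r"] = cov
    prof = coverage_profile(p, 1_000)
    assert prof.shape == (10,)
    assert prof[3] == 0.0 and all(prof[i] == 10.0 for i in range(10) if i != 3)
    single = coverage_profile(p, 20_000)
    assert single.shape == (1,)
    with pytest.raises(ValueError):
        coverage_profile(p, 50)
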