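"""Generator properties: determinism, architecture statistics, controlled
identities, abundance-weighted read sampling, ground-truth completeness."""

import numpy as np
import pytest

from sagphage import (
    ScenarioConfig,
    build_scenario,
    compute_metrics,
    generate_host_genome,
    generate_viral_genome,
    mutate_to_identity,
    simulate_metagenome,
    translate,
)
from sagphage.simulate import (
    GroundTruth,
    HostParams,
    ViralParams,
    mutate_genome_genes,
    random_dna,
)
from sagphage.models import Contig


def test_same_seed_byte_identical():
    a = build_scenario(ScenarioConfig(seed=42))
    b = build_scenario(ScenarioConfig(seed=42))
    assert [c.sequence for c in a.all_contigs()] == [c.sequence for c in b.all_contigs()]
    assert a.truth.prophages == b.truth.prophages
    assert a.truth.crisprs == b.truth.crisprs
    assert a.truth.infections == b.truth.infections


def test_host_strand_change_matches_operon_length(rng):
    contigs, genes = generate_host_genome(
        HostParams(contigs_per_sag=5, genes_per_contig=200, mean_operon_len=5.0),
        rng, sag_id="s",
    )
    ratios = [
        compute_metrics([g for g in genes if g.contig_id == c.id]).strand_change_ratio
        for c in contigs
    ]
    assert np.mean(ratios) == pytest.approx(0.2, abs=0.05)


def test_fully_characterized_host(rng):
    _, genes = generate_host_genome(
        HostParams(contigs_per_sag=1, genes_per_contig=50, characterized_fraction=1.0),
        rng, sag_id="s",
    )
    assert compute_metrics(genes).uncharacterized_ratio == 0.0


def test_gene_sequences_translate_to_recorded_proteins(rng):
    contigs, genes = generate_host_genome(
        HostParams(contigs_per_sag=1, genes_per_contig=20), rng, sag_id="s"
    )
    contig = contigs[0]
    for g in genes:
        assert translate(g.nucleotide_sequence(contig)) == g.protein
        assert len(g.protein) == g.length // 3


def test_viral_genome_architecture(rng):
    contig, genes = generate_viral_genome(
        ViralParams(), rng, kind="caudovirales", genome_id="v"
    )
    assert 15_000 <= contig.length <= 61_000 and not contig.circular
    m = compute_metrics(genes)
    assert m.uncharacterized_ratio >= 0.5
    categories = {g.hallmark_category.value for g in genes}
    assert {"capsid", "terminase"} <= categories

    micro, mgenes = generate_viral_genome(
        ViralParams(), rng, kind="microviridae", genome_id="mv"
    )
    assert micro.circular and 4_000 <= micro.length <= 7_000
    assert any(g.hallmark_category.value == "capsid" for g in mgenes)


@pytest.mark.parametrize("target", [100.0, 85.0])
def test_mutate_to_identity_nucleotide(rng, target):
    seq = random_dna(rng, 10_000)
    mutated, realized = mutate_to_identity(seq, target, level="nucleotide", rng=rng)
    hamming = 100.0 * sum(a == b for a, b in zip(seq, mutated)) / len(seq)
    assert realized == pytest.approx(target, abs=1.0)
    assert hamming == pytest.approx(realized, abs=1e-9)
    if target == 100.0:
        assert mutated == seq


def test_mutate_to_identity_amino_acid_changes_protein(rng):
    seq = "ATG" + "".join(
        np.random.default_rng(1).choice(["GCT", "GGA", "CTG", "AAA", "TCC"], size=99)
    )
    mutated, realized = mutate_to_identity(seq, 70.0, level="amino_acid", rng=rng)
    p0, p1 = translate(seq), translate(mutated, allow_internal_stop=True)
    aa_ident = 100.0 * sum(a == b for a, b in zip(p0, p1)) / len(p0)
    assert "*" not in p1
    assert aa_ident == pytest.approx(realized, abs=1e-9)
    assert realized == pytest.approx(70.0, abs=1.0)


def test_mutate_same_seed_identical():
    seq = random_dna(np.random.default_rng(0), 1000)
    m1, _ = mutate_to_identity(seq, 90, rng=np.random.default_rng(4))
    m2, _ = mutate_to_identity(seq, 90, rng=np.random.default_rng(4))
    assert m1 == m2


def test_mutate_genome_genes_only_touches_genes(rng):
    contigs, genes = generate_host_genome(
        HostParams(contigs_per_sag=1, genes_per_contig=10), rng, sag_id="s"
    )
    contig = contigs[0]
    new_contig, new_genes, realized = mutate_genome_genes(
        contig, genes, 80.0, rng=rng
    )
    in_gene = np.zeros(contig.length, dtype=bool)
    for g in genes:
        in_gene[g.start - 1 : g.end] = True
    for i, (a, b) in enumerate(zip(contig.sequence, new_contig.sequence)):
        if a != b:
            assert in_gene[i]
    assert all(abs(v - 80.0) <= 1.0 for v in realized.values())


def test_metagenome_exact_reads_without_errors(rng):
    genome = Contig(id="g", source_id="g", sequence=random_dna(rng, 5000))
    mg = simulate_metagenome(
        [(genome, 1.0)], n_reads=50, read_length=200, error_rate=0.0, rng=rng
    )
    from sagphage.models import reverse_complement

    for read in mg.reads.values():
        assert read in genome.sequence or reverse_complement(read) in genome.sequence


def test_metagenome_copy_number_ratio(rng):
    g1 = Contig(id="g1", source_id="g1", sequence=random_dna(rng, 8000))
    g2 = Contig(id="g2", source_id="g2", sequence=random_dna(rng, 8000))
    truth = GroundTruth()
    mg = simulate_metagenome(
        [(g1, 9.0), (g2, 1.0)], n_reads=4000, read_length=150,
        error_rate=0.0, rng=rng, truth=truth,
    )
    n1 = sum(1 for v in truth.read_provenance.values() if v == "g1")
    frac = n1 / 4000
    # binomial 99.9% interval around 0.9 at n=4000
    assert abs(frac - 0.9) < 3.3 * np.sqrt(0.9 * 0.1 / 4000)


def test_metagenome_skips_short_linear_genomes(rng, caplog):
    short = Contig(id="s", source_id="s", sequence=random_dna(rng, 100))
    ok = Contig(id="ok", source_id="ok", sequence=random_dna(rng, 2000))
    with caplog.at_level("WARNING"):
        mg = simulate_metagenome(
            [(short, 1.0), (ok, 1.0)], n_reads=10, read_length=200,
            error_rate=0.0, rng=rng, truth=(t := GroundTruth()),
        )
    assert "skipped" in caplog.text
    assert set(t.read_provenance.values()) == {"ok"}


def test_circular_reads_wrap(rng):
    genome = Contig(id="c", source_id="c", sequence=random_dna(rng, 1000), circular=True)
    mg = simulate_metagenome(
        [(genome, 1.0)], n_reads=200, read_length=300, error_rate=0.0, rng=rng
    )
    doubled = genome.sequence * 2
    from sagphage.models import reverse_complement

    assert all(
        r in doubled or reverse_complement(r) in doubled for r in mg.reads.values()
    )
    assert all(len(r) == 300 for r in mg.reads.values())


def test_ground_truth_complete_and_consistent(default_scenario):
    sc = default_scenario
    truth = sc.truth
    contig_ids = {c.id for c in sc.all_contigs()}
    # every contig is labelled, every label refers to a contig
    assert set(truth.contig_label) == contig_ids
    # viral labels carry a taxon
    for cid, label in truth.contig_label.items():
        if label == "viral":
            assert cid in truth.viral_taxon
    # infections reference planted viral contigs
    for sag in sc.sags:
        taxa = {truth.viral_taxon[c.id] for c in sag.contigs
                if truth.contig_label[c.id] == "viral"}
        assert taxa == truth.infections[sag.id]
    # planted intervals lie within their contigs
    genes = sc.contig_genes()
    lengths = {c.id: c.length for c in sc.all_contigs()}
    for p in truth.prophages:
        lo, hi = p["nt_region"]
        assert 1 <= lo < hi <= lengths[p["contig"]]
        gi, gj = p["gene_region"]
        assert 0 < gi < gj < len(genes[p["contig"]])
    for cr in truth.crisprs:
        for a, b in cr["repeats"] + cr["spacers"]:
            assert 1 <= a < b <= lengths[cr["contig"]]


def test_depth_gradient_in_default_scenario(default_scenario):
    sc = default_scenario
    freq = {}
    for depth in sc.config.depths:
        sags = [s for s in sc.sags if s.depth == depth]
        freq[depth] = sum(1 for s in sags if sc.truth.infections[s.id]) / len(sags)
    assert freq[100] <= freq[150] <= freq[185]
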