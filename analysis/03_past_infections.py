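#!/usr/bin/env python
"""Annotate remnants of past infections and check them against current ones.

Finds CRISPR repeat-spacer arrays, links spacers back to viral sequence,
promotes conserved embedded regions to defective-prophage calls, and
verifies that no past-infection sequence matches a current-infection
viral contig. Writes the annotations and the overlap report to results/.
"""

import argparse
from pathlib import Path

import pandas as pd

import sagphage as sp

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    args = ap.parse_args()

    sc = sp.build_scenario(sp.ScenarioConfig(seed=args.seed))
    truth = sc.truth
    contigs = sc.all_contigs()
    contig_genes = sc.contig_genes()

    arrays = [a for c in contigs for a in sp.find_crispr_arrays(c)]
    spacer_hits = sp.match_spacers(arrays, contigs)

    scan = [
        c for genes in contig_genes.values() if genes
        for c in sp.scan_unknown_regions(genes)
    ]
    labels = sp.classify_contigs(contig_genes, scan)
    embedded = [c for v in labels.values() for c in v["embedded_regions"]]
    microbial = [c for c in contigs if truth.contig_label[c.id] == "microbial"]
    prophages = sp.flag_defective_prophages(microbial, contig_genes, embedded)

    past = sp.collect_past_sequences(arrays, prophages, contigs)
    current = [c for c in contigs if truth.contig_label[c.id] == "viral"]
    overlaps = sp.check_past_vs_current(past, current) if past else []

    outdir = ROOT / "results"
    outdir.mkdir(exist_ok=True)
    pd.DataFrame(
        [
            {
                "contig_id": a.contig_id,
                "span_start": a.span[0],
                "span_end": a.span[1],
                "n_repeats": a.n_repeats,
                "repeat_len": len(a.repeat_consensus),
                "n_spacers": len(a.spacers),
            }
            for a in arrays
        ]
    ).to_csv(outdir / "crispr_arrays.csv", index=False)
    pd.DataFrame(
        [
            {
                "contig_id": p.contig_id,
                "nt_start": p.region[0],
                "nt_end": p.region[1],
                "conserved_in": ";".join(p.conserved_in),
                "status": p.status,
            }
            for p in prophages
        ]
    ).to_csv(outdir / "prophage_calls.csv", index=False)
    pd.DataFrame(overlaps, columns=["past_id", "current_contig"]).to_csv(
        outdir / "past_current_overlap.csv", index=False
    )

    print("CRISPR arrays found: %d (planted: %d)" % (len(arrays), len(truth.crisprs)))
    print("Spacer-to-contig links: %d" % len(spacer_hits))
    print("Defective prophages flagged: %d on %d contigs (planted: %d)" % (
        len(prophages), len({p.contig_id for p in prophages}), len(truth.prophages)))
    if overlaps:
        print("WARNING: past/current overlap pairs:", overlaps)
    else:
        print("No past-infection sequence matches any current viral contig "
              "(empty overlap report).")
    print("Wrote results/crispr_arrays.csv, prophage_calls.csv, "
          "past_current_overlap.csv.")


if __name__ == "__main__":
    main()
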