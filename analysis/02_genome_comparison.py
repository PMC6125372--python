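#!/usr/bin/env python
"""Run the genome comparison on the simulated set and score it against
truth.

Stages: exact local alignment of all candidate protein pairs per genome
pair, 35%/60%/1e-5 hit filtering, reciprocal best hits with
conserved-region (synteny) weighting of tied assignments, ortholog
families, the binary presence/absence matrix over reference genes, group
core genomes, sharing-pattern calls and locus completeness.

Reads results/synthetic/ (from 01_simulate_genomes.py); writes the full
report bundle to results/compare/ and prints recovery statistics.
"""

import argparse
import os
import sys

import pandas as pd

ROOT = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))

from orthocore.core_genome import locus_completeness
from orthocore.model import LocusDefinition
from orthocore.pipeline import RunConfig, run_compare


def co_membership(assignment):
    buckets = {}
    for gene, fam in assignment.items():
        buckets.setdefault(fam, []).append(gene)
    pairs = set()
    for genes in buckets.values():
        genes.sort()
        for i, a in enumerate(genes):
            for b in genes[i + 1:]:
                pairs.add((a, b))
    return pairs


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", default=os.path.join(ROOT, "results",
                                                       "synthetic"))
    parser.add_argument("--out", default=os.path.join(ROOT, "results",
                                                      "compare"))
    args = parser.parse_args()

    genome_ids = sorted(
        f[:-5] for f in os.listdir(args.data) if f.endswith(".gff3"))
    config = RunConfig(
        genome_files=[{"genome_id": gid,
                       "gff3": os.path.join(args.data, f"{gid}.gff3"),
                       "fasta": os.path.join(args.data, f"{gid}.faa")}
                      for gid in genome_ids],
        group_table=os.path.join(args.data, "groups.tsv"),
        reference_genome_id="G1S1",
        locus_definitions=os.path.join(args.data, "loci.tsv"),
        output_dir=args.out)
    result = run_compare(config)

    print(f"{len(result['rbh'])} RBH pairs, "
          f"{len(result['families'])} families, presence matrix "
          f"{result['matrix'].presence.shape[0]} genes x "
          f"{result['matrix'].presence.shape[1]} genomes -> {args.out}")

    truth_path = os.path.join(args.data, "truth_families.tsv")
    if os.path.exists(truth_path):
        truth = pd.read_csv(truth_path, sep="\t", index_col=0)["family_id"]
        predicted = {g: f.family_id for f in result["families"]
                     for g in f.members}
        tp_pairs = co_membership(truth.to_dict())
        pr_pairs = co_membership(predicted)
        tp = len(tp_pairs & pr_pairs)
        print(f"family recovery vs truth: precision "
              f"{tp / len(pr_pairs):.4f}, recall {tp / len(tp_pairs):.4f}")

    calls = {c.gene_id: c.category for c in result["calls"]}
    matrix = result["matrix"]
    groups = result["groups"]
    in_group = sorted(groups.groups[groups.reference_group_id])
    for locus in (result["completeness"]["locus_id"].unique()):
        loci_path = os.path.join(args.data, "loci.tsv")
        defs = pd.read_csv(loci_path, sep="\t")
        gene_ids = list(defs[defs["locus_id"] == locus]["gene_id"])
        cats = {calls[g] for g in gene_ids}
        obj = LocusDefinition(locus, gene_ids)
        fr_in = min(locus_completeness(obj, matrix, m)[0]
                    for m in in_group)
        fr_out = max(locus_completeness(obj, matrix, m)[0]
                     for m in matrix.genome_ids if m not in in_group)
        print(f"locus {locus}: categories {sorted(cats)}, "
              f"in-group completeness >= {fr_in:.2f}, "
              f"out-group <= {fr_out:.2f}")

    counts = pd.Series(list(calls.values())).value_counts()
    print("sharing categories:",
          ", ".join(f"{k}={v}" for k, v in counts.items()))
    return 0


if __name__ == "__main__":
    sys.exit(main())
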