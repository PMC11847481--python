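#!/usr/bin/env python
"""Exon/isoform architecture and polyadenylation elements.

Tabulates exons and isoforms per gene/transcript by biotype, identifies
the extreme genes, assigns annotated polyA signals/sites to genes,
measures signal->site spacing, and tests polyA presence against
subcellular localization with Fisher's exact test. Writes tables under
results/.
"""

import argparse
from pathlib import Path

from lnckaryotype import gene_architecture as ga, io_formats, sequence_profile as sp
from lnckaryotype.model import genes_to_frame, transcripts_to_frame


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    bundle_dir = args.results / "bundle"

    ann = io_formats.read_gene_annotation(bundle_dir / "genes.gtf")
    genes = genes_to_frame(ann.genes)
    transcripts = transcripts_to_frame(ann.transcripts)
    features = io_formats.read_polya_annotation(bundle_dir / "polya.gtf")

    arch = ga.architecture_summary(genes, transcripts)
    print(arch.to_string(index=False))
    ext = ga.extremes(genes, transcripts)
    print(f"longest gene: {ext['longest_gene']['gene_id']} "
          f"({ext['longest_gene']['length']:,} nt); most isoforms: "
          f"{ext['max_isoform_gene']['gene_id']} ({ext['max_isoform_gene']['n_transcripts']})")

    assignments = ga.assign_polya(genes, features)
    flags = ga.polya_gene_flags(genes, assignments)
    pairs = ga.pair_site_signal(assignments)
    spacing = ga.mean_spacing_by_biotype(pairs)
    print(spacing.to_string(index=False))
    for biotype, sub in flags.groupby("biotype"):
        print(f"{biotype}: {100 * sub['has_polyA'].mean():.1f}% of genes carry a polyA element")

    # polyA presence vs localization (2x2 Fisher)
    records, _ = io_formats.read_localization_table(bundle_dir / "localization.tsv")
    loc = sp.classify_localization(records)
    name_to_gene = dict(zip(genes["gene_name"], genes["gene_id"]))
    has_polya = dict(zip(flags["gene_id"], flags["has_polyA"]))
    table = [[0, 0], [0, 0]]
    for name, cls in loc.items():
        gid = name_to_gene.get(name)
        if gid is None or cls not in ("nuclear", "cytoplasmic"):
            continue
        table[0 if cls == "nuclear" else 1][0 if has_polya.get(gid) else 1] += 1
    if min(sum(r) for r in table) > 0:
        odds, p = ga.fisher_exact_2x2(table)
        print(f"polyA presence vs localization: table {table}, Fisher p={p:.3f}")

    io_formats.write_tables(
        {"architecture_summary": arch, "polya_pairs": pairs,
         "polya_gene_flags": flags, "polya_spacing": spacing},
        args.results,
    )


if __name__ == "__main__":
    main()
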