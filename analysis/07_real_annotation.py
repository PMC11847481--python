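#!/usr/bin/env python
"""Run the full virtual-karyotype pipeline on real annotation releases.

Intended for the GENCODE human annotation (lncRNA and comprehensive gene
GTFs, transcript FASTA, polyA feature GTF) and Ensembl clinically
associated VCFs, which the user supplies as local files; nothing is
downloaded. The same stages run as on the synthetic bundle, writing all
tables and report.json under --out.

Example:
    python analysis/07_real_annotation.py \
        --lnc-gtf gencode.v46.long_noncoding_RNAs.gtf \
        --coding-gtf gencode.v46.annotation.gtf \
        --transcript-fasta gencode.v46.lncRNA_transcripts.fa \
        --polya-gtf gencode.v46.polyAs.gtf \
        --variant-vcf homo_sapiens_clinically_associated.vcf \
        --out results/real
"""

import argparse
from pathlib import Path

from lnckaryotype.pipeline import PipelineConfig, run


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__,
                                 formatter_class=argparse.RawDescriptionHelpFormatter)
    ap.add_argument("--lnc-gtf", type=Path)
    ap.add_argument("--coding-gtf", type=Path)
    ap.add_argument("--transcript-fasta", type=Path)
    ap.add_argument("--polya-gtf", type=Path)
    ap.add_argument("--variant-vcf", type=Path)
    ap.add_argument("--localization-tsv", type=Path)
    ap.add_argument("--validated-tsv", type=Path)
    ap.add_argument("--out", type=Path, default=Path("results/real"))
    ap.add_argument("--monoexonic-mode", default="all_isoforms",
                    choices=["all_isoforms", "any_isoform"])
    args = ap.parse_args()

    config = PipelineConfig(
        lnc_gtf=args.lnc_gtf,
        coding_gtf=args.coding_gtf,
        transcript_fasta=args.transcript_fasta,
        polya_gtf=args.polya_gtf,
        variant_vcf=args.variant_vcf,
        localization_tsv=args.localization_tsv,
        validated_tsv=args.validated_tsv,
        monoexonic_mode=args.monoexonic_mode,
        out_dir=args.out,
    )
    report = run(config)
    for stage, payload in report["stages"].items():
        print(f"[{stage}] {payload}")


if __name__ == "__main__":
    main()
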