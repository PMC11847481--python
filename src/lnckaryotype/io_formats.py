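"""Readers and writers for every standard format the pipeline touches.

GTF (GENCODE dialect) via pyranges, FASTA via Biopython, VCF via cyvcf2,
plus plain-TSV snapshots for localization and validated-variant tables.
All in-memory coordinates stay 1-based inclusive; BED export converts to
0-based half-open at the boundary and nowhere else.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import pyranges as pr
from Bio import SeqIO
from cyvcf2 import VCF

from .model import (
    CLINICAL_FLAGS,
    ExonRecord,
    GeneRecord,
    GenomeAssembly,
    LocalizationRecord,
    ModelError,
    PolyAFeature,
    TranscriptRecord,
    VariantRecord,
)

logger = logging.getLogger(__name__)

# GENCODE's polyA GTF uses "polyA_signal_sequence"; we normalize the label.
_POLYA_FEATURE_MAP = {
    "polyA_site": "polyA_site",
    "polyA_signal": "polyA_signal",
    "polyA_signal_sequence": "polyA_signal",
}


class FormatError(ValueError):
    """A file cannot be interpreted in its declared format."""


@dataclass
class AnnotationBundle:
    """Linked gene/transcript/exon collections from one GTF."""

    genes: list[GeneRecord]
    transcripts: list[TranscriptRecord]
    exons: list[ExonRecord]
    rejected: dict[str, int] = field(default_factory=dict)

    @property
    def n_rejected(self) -> int:
        return sum(self.rejected.values())


def read_gene_annotation(
    path: str | Path,
    biotype: Optional[str] = None,
    assembly: Optional[GenomeAssembly] = None,
    default_biotype: Optional[str] = None,
) -> AnnotationBundle:
    """Read a GENCODE-dialect GTF into linked gene/transcript/exon records.

    Parameters
    ----------
    biotype:
        If given, keep only genes whose ``gene_type`` equals it (transcripts
        and exons of dropped genes are dropped with them).
    assembly:
        If given, chromosome labels are normalized against it and records on
        unknown sequences (scaffolds, patches) are rejected and counted.
    default_biotype:
        Biotype assigned when the GTF has no ``gene_type`` attribute — e.g.
        the dedicated lncRNA-only annotation, where every gene is lncRNA.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"annotation file not found: {path}")
    try:
        df = pr.read_gtf(str(path)).df
    except Exception as exc:  # noqa: BLE001 - surfaced as a format error
        raise FormatError(f"could not parse GTF {path}: {exc}") from exc
    if df.empty:
        return AnnotationBundle([], [], [])
    # pyranges stores 0-based half-open; restore GTF 1-based inclusive.
    df["start1"] = df["Start"].astype(int) + 1
    df["end1"] = df["End"].astype(int)
    for col in ("gene_type", "gene_name", "transcript_id", "exon_number"):
        if col not in df.columns:
            df[col] = None

    rejected: dict[str, int] = {}

    def _reject(reason: str) -> None:
        rejected[reason] = rejected.get(reason, 0) + 1

    def _chrom(label: str) -> Optional[str]:
        if assembly is None:
            return label
        return assembly.normalize(label)

    genes: list[GeneRecord] = []
    transcripts_raw: list[dict] = []
    exons: list[ExonRecord] = []
    exon_spans: dict[str, list[tuple[int, int]]] = {}

    for row in df.itertuples(index=False):
        feature = row.Feature
        if feature not in ("gene", "transcript", "exon"):
            continue
        chrom = _chrom(str(row.Chromosome))
        if chrom is None:
            _reject("unknown_chromosome")
            continue
        gene_type = row.gene_type if isinstance(row.gene_type, str) and row.gene_type else default_biotype
        if feature == "gene":
            if biotype is not None and gene_type != biotype:
                _reject("biotype_filtered")
                continue
            name = row.gene_name if isinstance(row.gene_name, str) and row.gene_name else None
            try:
                genes.append(
                    GeneRecord(
                        gene_id=str(row.gene_id),
                        gene_name=name,
                        chrom=chrom,
                        start=int(row.start1),
                        end=int(row.end1),
                        strand=str(row.Strand),
                        biotype=gene_type or "lncRNA",
                    )
                )
            except ModelError:
                _reject("invalid_gene")
        elif feature == "transcript":
            transcripts_raw.append(
                dict(
                    transcript_id=str(row.transcript_id),
                    gene_id=str(row.gene_id),
                    chrom=chrom,
                    start=int(row.start1),
                    end=int(row.end1),
                    strand=str(row.Strand),
                )
            )
        else:  # exon
            tid = str(row.transcript_id)
            spans = exon_spans.setdefault(tid, [])
            spans.append((int(row.start1), int(row.end1)))

    kept_gene_ids = {g.gene_id for g in genes}
    transcripts: list[TranscriptRecord] = []
    for t in transcripts_raw:
        if t["gene_id"] not in kept_gene_ids:
            _reject("orphan_transcript")
            continue
        spans = sorted(exon_spans.get(t["transcript_id"], []))
        if not spans:
            # GTF with transcript lines but no exon lines: treat the
            # transcript span as a single exon.
            spans = [(t["start"], t["end"])]
        try:
            transcripts.append(
                TranscriptRecord(
                    exon_count=len(spans),
                    mature_length=sum(e - s + 1 for s, e in spans),
                    **t,
                )
            )
        except ModelError:
            _reject("invalid_transcript")
            continue
        for rank, (s, e) in enumerate(spans, start=1):
            exons.append(ExonRecord(transcript_id=t["transcript_id"], start=s, end=e, rank=rank))

    if rejected:
        logger.info("GTF %s: rejected records %s", path.name, rejected)
    return AnnotationBundle(genes, transcripts, exons, rejected)


def write_gene_annotation(
    genes: Sequence[GeneRecord],
    transcripts: Sequence[TranscriptRecord],
    exons: Sequence[ExonRecord],
    path: str | Path,
    source: str = "lnckaryotype",
) -> None:
    """Emit a GENCODE-dialect GTF (deterministic record order)."""
    exons_by_tx: dict[str, list[ExonRecord]] = {}
    for e in exons:
        exons_by_tx.setdefault(e.transcript_id, []).append(e)
    tx_by_gene: dict[str, list[TranscriptRecord]] = {}
    for t in transcripts:
        tx_by_gene.setdefault(t.gene_id, []).append(t)

    def attr(pairs: list[tuple[str, str]]) -> str:
        return " ".join(f'{k} "{v}";' for k, v in pairs)

    lines = []
    for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
        gene_attrs = [("gene_id", g.gene_id), ("gene_type", g.biotype)]
        if g.gene_name:
            gene_attrs.append(("gene_name", g.gene_name))
        lines.append(
            f"{g.chrom}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attr(gene_attrs)}"
        )
        for t in sorted(tx_by_gene.get(g.gene_id, []), key=lambda t: t.transcript_id):
            t_attrs = gene_attrs + [("transcript_id", t.transcript_id)]
            lines.append(
                f"{t.chrom}\t{source}\ttranscript\t{t.start}\t{t.end}\t.\t{t.strand}\t.\t{attr(t_attrs)}"
            )
            for e in sorted(exons_by_tx.get(t.transcript_id, []), key=lambda e: e.rank):
                e_attrs = t_attrs + [("exon_number", str(e.rank))]
                lines.append(
                    f"{t.chrom}\t{source}\texon\t{e.start}\t{e.end}\t.\t{t.strand}\t.\t{attr(e_attrs)}"
                )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


class SequenceStore:
    """Transcript sequences keyed by accession, version-insensitive on lookup."""

    def __init__(self) -> None:
        self._seqs: dict[str, str] = {}
        self._unversioned: dict[str, str] = {}

    def add(self, transcript_id: str, seq: str) -> None:
        if not seq:
            raise FormatError(f"empty sequence for {transcript_id}")
        if transcript_id in self._seqs:
            raise FormatError(f"duplicate transcript id {transcript_id}")
        self._seqs[transcript_id] = seq.upper()
        self._unversioned[transcript_id.split(".")[0]] = transcript_id

    def __getitem__(self, transcript_id: str) -> str:
        if transcript_id in self._seqs:
            return self._seqs[transcript_id]
        versioned = self._unversioned.get(transcript_id.split(".")[0])
        if versioned is None:
            raise KeyError(transcript_id)
        return self._seqs[versioned]

    def __contains__(self, transcript_id: str) -> bool:
        return (
            transcript_id in self._seqs
            or transcript_id.split(".")[0] in self._unversioned
        )

    def __len__(self) -> int:
        return len(self._seqs)

    def items(self):
        return self._seqs.items()

    def keys(self):
        return self._seqs.keys()


def read_transcript_sequences(path: str | Path) -> SequenceStore:
    """Read a transcript FASTA; GENCODE pipe-delimited headers are trimmed to
    the leading transcript accession."""
    store = SequenceStore()
    for record in SeqIO.parse(str(path), "fasta"):
        transcript_id = record.id.split("|")[0]
        store.add(transcript_id, str(record.seq))
    return store


def write_transcript_sequences(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for tid in sorted(seqs):
            fh.write(f">{tid}\n")
            s = seqs[tid]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_polya_annotation(path: str | Path) -> list[PolyAFeature]:
    """Read a polyA feature GTF into site/signal records."""
    df = pr.read_gtf(str(path)).df
    features: list[PolyAFeature] = []
    if df.empty:
        return features
    has_tid = "transcript_id" in df.columns
    for row in df.itertuples(index=False):
        kind = _POLYA_FEATURE_MAP.get(row.Feature)
        if kind is None:
            continue
        linked = getattr(row, "transcript_id", None) if has_tid else None
        features.append(
            PolyAFeature(
                kind=kind,
                chrom=str(row.Chromosome),
                start=int(row.Start) + 1,
                end=int(row.End),
                strand=str(row.Strand),
                linked_id=linked if isinstance(linked, str) and linked else None,
            )
        )
    return features


def write_polya_annotation(features: Sequence[PolyAFeature], path: str | Path) -> None:
    lines = []
    order = sorted(features, key=lambda f: (f.chrom, f.start, f.kind))
    for f in order:
        attrs = f'feature_kind "{f.kind}";'
        if f.linked_id:
            attrs += f' transcript_id "{f.linked_id}";'
        lines.append(
            f"{f.chrom}\tlnckaryotype\t{f.kind}\t{f.start}\t{f.end}\t.\t{f.strand}\t.\t{attrs}"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_variants(
    path: str | Path,
    region: Optional[str] = None,
) -> list[VariantRecord]:
    """Read a VCF into variant records.

    Clinical-significance flags are taken from INFO keys matching the five
    canonical labels; absent keys default to false. Multi-allelic lines yield
    a single record carrying the full alt list.
    """
    variants: list[VariantRecord] = []
    vcf = VCF(str(path))
    iterator = vcf(region) if region else vcf
    for v in iterator:
        flags = frozenset(
            flag for flag in CLINICAL_FLAGS if v.INFO.get(flag) not in (None, False)
        )
        variants.append(
            VariantRecord(
                chrom=v.CHROM,
                pos=v.POS,
                variant_id=v.ID or f"{v.CHROM}:{v.POS}",
                ref=v.REF,
                alts=tuple(v.ALT),
                clinical_flags=flags,
            )
        )
    vcf.close()
    return variants


def write_variants(variants: Sequence[VariantRecord], path: str | Path, contigs: Optional[Mapping[str, int]] = None) -> None:
    """Write a minimal VCF v4.1 with the five clinical flags as INFO flags."""
    lines = ["##fileformat=VCFv4.1"]
    if contigs:
        for name in contigs:
            lines.append(f"##contig=<ID={name},length={contigs[name]}>")
    for flag in CLINICAL_FLAGS:
        lines.append(
            f'##INFO=<ID={flag},Number=0,Type=Flag,Description="Clinical significance: {flag}">'
        )
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.variant_id)):
        info = ";".join(flag for flag in CLINICAL_FLAGS if flag in v.clinical_flags) or "."
        lines.append(
            f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.ref}\t{','.join(v.alts)}\t.\t.\t{info}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_localization_table(path: str | Path) -> tuple[list[LocalizationRecord], int]:
    """Read a two-column (name, compartment) TSV snapshot.

    Returns the records plus the count of rejected rows (blank name or
    compartment). Duplicate names are preserved: one molecule may carry
    several compartment annotations.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError(f"localization table {path} needs >= 2 columns")
    name_col, comp_col = df.columns[0], df.columns[1]
    records: list[LocalizationRecord] = []
    rejected = 0
    for name, comp in zip(df[name_col], df[comp_col]):
        if not name.strip() or not comp.strip():
            rejected += 1
            continue
        records.append(LocalizationRecord(name=name.strip(), compartment=comp.strip()))
    if rejected:
        logger.info("localization table %s: rejected %d blank rows", path, rejected)
    return records, rejected


def write_localization_table(records: Sequence[LocalizationRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.name, r.compartment) for r in records], columns=["name", "compartment"]
    )
    df.to_csv(path, sep="\t", index=False)


def read_validated_table(path: str | Path) -> pd.DataFrame:
    """Read a validated-variant coordinate TSV (chrom, start, end[, id])."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "start": int, "end": int})
    missing = {"chrom", "start", "end"} - set(df.columns)
    if missing:
        raise FormatError(f"validated table {path} lacks columns {sorted(missing)}")
    return df


def write_validated_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Result export

def write_tables(results: Mapping[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write each result frame as ``<name>.tsv`` with a fixed column order.

    Output is deterministic: the same frames produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(results):
        p = out / f"{name}.tsv"
        results[name].to_csv(p, sep="\t", index=False, float_format="%.6g")
        written.append(p)
    return written


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Export 1-based inclusive intervals as BED (0-based half-open).

    Expects columns chrom, start, end and optionally name and score.
    """
    bed = pd.DataFrame(
        {
            "chrom": intervals["chrom"],
            "start": intervals["start"].astype(int) - 1,
            "end": intervals["end"].astype(int),
        }
    )
    if "name" in intervals.columns:
        bed["name"] = intervals["name"]
    if "score" in intervals.columns:
        bed["score"] = intervals["score"]
    bed.to_csv(path, sep="\t", index=False, header=False)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
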