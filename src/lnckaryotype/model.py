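"""Shared data model for the virtual-karyotype pipeline.

All genomic coordinates are 1-based inclusive (GTF/VCF native); conversion
to 0-based half-open happens only at BED export.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

#: Clinical-significance flags in descending priority order.
CLINICAL_FLAGS = ("Pathogenic", "Likely_pathogenic", "VUS", "Likely_benign", "Benign")

BIOTYPES = ("lncRNA", "protein_coding")


class ModelError(ValueError):
    """An input record violates a data-model invariant."""


@dataclass(frozen=True)
class GenomeAssembly:
    """Ordered chromosome names and their lengths in base pairs.

    Chromosome labels are matched leniently: ``chr1`` and ``1`` refer to the
    same sequence regardless of which convention the assembly itself uses.
    """

    names: tuple[str, ...]
    lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ModelError("duplicate chromosome names in assembly")
        for name in self.names:
            if name not in self.lengths:
                raise ModelError(f"no length for chromosome {name!r}")
            if self.lengths[name] <= 0:
                raise ModelError(f"non-positive length for chromosome {name!r}")

    def normalize(self, chrom: str) -> Optional[str]:
        """Map a chromosome label onto this assembly's naming, or None."""
        if chrom in self.lengths:
            return chrom
        alt = chrom[3:] if chrom.startswith("chr") else "chr" + chrom
        if alt in self.lengths:
            return alt
        return None

    def length_of(self, chrom: str) -> int:
        norm = self.normalize(chrom)
        if norm is None:
            raise ModelError(f"unknown chromosome {chrom!r}")
        return self.lengths[norm]


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    gene_name: Optional[str]
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ModelError(f"{self.gene_id}: start > end")
        if self.start < 1:
            raise ModelError(f"{self.gene_id}: start < 1")
        if self.strand not in ("+", "-"):
            raise ModelError(f"{self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        """Genomic span in nt (end - start + 1)."""
        return self.end - self.start + 1


@dataclass(frozen=True)
class TranscriptRecord:
    transcript_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exon_count: int
    mature_length: int

    def __post_init__(self) -> None:
        if self.exon_count < 1:
            raise ModelError(f"{self.transcript_id}: exon_count < 1")
        if self.start > self.end:
            raise ModelError(f"{self.transcript_id}: start > end")


@dataclass(frozen=True)
class ExonRecord:
    transcript_id: str
    start: int
    end: int
    rank: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ModelError(f"exon of {self.transcript_id}: start > end")
        if self.rank < 1:
            raise ModelError(f"exon of {self.transcript_id}: rank < 1")


POLYA_KINDS = ("polyA_site", "polyA_signal")


@dataclass(frozen=True)
class PolyAFeature:
    kind: str
    chrom: str
    start: int
    end: int
    strand: str
    linked_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in POLYA_KINDS:
            raise ModelError(f"bad polyA kind {self.kind!r}")
        if self.start > self.end:
            raise ModelError("polyA feature: start > end")


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int
    variant_id: str
    ref: str
    alts: tuple[str, ...]
    clinical_flags: frozenset[str] = frozenset()
    validated: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ModelError(f"{self.variant_id}: pos < 1")
        if not self.ref or not all(self.alts):
            raise ModelError(f"{self.variant_id}: empty allele")
        unknown = set(self.clinical_flags) - set(CLINICAL_FLAGS)
        if unknown:
            raise ModelError(f"{self.variant_id}: unknown clinical flags {unknown}")


@dataclass(frozen=True)
class LocalizationRecord:
    name: str
    compartment: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ModelError("localization record without a molecule name")


# ---------------------------------------------------------------------------
# DataFrame views: downstream statistics work on tidy frames.

def genes_to_frame(genes: Iterable[GeneRecord]) -> pd.DataFrame:
    rows = [
        (g.gene_id, g.gene_name, g.chrom, g.start, g.end, g.strand, g.biotype, g.length)
        for g in genes
    ]
    return pd.DataFrame(
        rows,
        columns=["gene_id", "gene_name", "chrom", "start", "end", "strand", "biotype", "length"],
    )


def transcripts_to_frame(transcripts: Iterable[TranscriptRecord]) -> pd.DataFrame:
    rows = [
        (t.transcript_id, t.gene_id, t.chrom, t.start, t.end, t.strand, t.exon_count, t.mature_length)
        for t in transcripts
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "gene_id", "chrom", "start", "end",
            "strand", "exon_count", "mature_length",
        ],
    )


def exons_to_frame(exons: Iterable[ExonRecord]) -> pd.DataFrame:
    rows = [(e.transcript_id, e.start, e.end, e.rank) for e in exons]
    return pd.DataFrame(rows, columns=["transcript_id", "start", "end", "rank"])


def variants_to_frame(variants: Iterable[VariantRecord]) -> pd.DataFrame:
    rows = [
        (v.chrom, v.pos, v.variant_id, v.ref, ",".join(v.alts),
         *(flag in v.clinical_flags for flag in CLINICAL_FLAGS), v.validated)
        for v in variants
    ]
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "variant_id", "ref", "alts", *CLINICAL_FLAGS, "validated"],
    )
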