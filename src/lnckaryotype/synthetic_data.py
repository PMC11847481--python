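"""Seeded generator of a complete toy input bundle with known ground truth.

Emits the exact formats the readers consume — gene GTF, transcript FASTA,
polyA GTF, VCF, localization TSV and validated-variant TSV — for a small
multi-chromosome genome, together with per-gene and per-variant truth
tables. The statistical structure mirrors the real annotation: log-normal
gene lengths, a configurable monoexonic fraction and exon/isoform count
distributions, name-encoded lncRNA subtypes at the genome-wide proportions
of the human catalog, injected 1-Mb density hotspots, a linear 5'→3' GC
gradient in mature transcript sequences, signal→site polyadenylation pairs
at a configured mean spacing, and variants with a configured
transition:transversion ratio and clinical-flag probabilities.

It does not emulate realistic human sequence composition (repeats, CpG
islands, splice-site motifs): only the aggregate statistics the pipeline
measures are built in.

Determinism: one root seed, split hierarchically (per chromosome, then per
stage), so identical configurations produce byte-identical bundles.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import io_formats
from .model import (
    CLINICAL_FLAGS,
    ExonRecord,
    GeneRecord,
    GenomeAssembly,
    LocalizationRecord,
    PolyAFeature,
    TranscriptRecord,
    VariantRecord,
)
from .sequence_profile import CYTOPLASMIC_TERMS, NUCLEAR_TERMS
from .subtype_classifier import SUBTYPES
from .variant_analysis import classify_substitution, resolve_clinical

#: Genome-wide subtype mix of the human lncRNA catalog (name-rule classes).
DEFAULT_SUBTYPE_MIX = {
    "novel": 14320 / 20310,
    "name_assigned": 1040 / 20310,
    "antisense": 1848 / 20310,
    "divergent": 600 / 20310,
    "intergenic": 2274 / 20310,
    "intronic": 127 / 20310,
    "mirna_host": 86 / 20310,
    "overlapping": 15 / 20310,
}

_TRANSITION_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS_OF = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass(frozen=True)
class Hotspot:
    chrom: str
    window_index: int
    extra_genes: int


@dataclass
class SimConfig:
    """Configuration of one synthetic bundle. Defaults are the study
    conditions the package's synthetic experiments run under."""

    seed: int = 0
    chrom_names: tuple[str, ...] = ("chr1", "chr2", "chr3")
    chrom_length: int = 10_000_000
    window: int = 1_000_000
    lnc_per_chrom: int = 100
    pcg_per_chrom: int = 80
    # gene span lengths: log-normal, truncated to [200, chrom_length/10]
    lnc_length_logmu: float = float(np.log(10_000))
    lnc_length_logsigma: float = 1.2
    pcg_length_logmu: float = float(np.log(30_000))
    pcg_length_logsigma: float = 1.0
    # isoforms per gene: 1 + geometric
    lnc_tx_mean: float = 3.1
    pcg_tx_mean: float = 8.5
    # exon counts: monoexonic with the stated fraction, else 1 + geometric
    lnc_monoexonic_fraction: float = 0.156
    pcg_monoexonic_fraction: float = 0.045
    lnc_exon_p: float = 0.30
    pcg_exon_p: float = 0.133
    hotspots: tuple[Hotspot, ...] = (Hotspot("chr1", 3, 30),)
    # linear GC gradient (5' target, 3' target) of mature sequences
    gc_gradient_lnc: tuple[float, float] = (0.60, 0.36)
    gc_gradient_pcg: tuple[float, float] = (0.64, 0.44)
    polya_fraction: float = 0.28
    polya_spacing_mean: float = 20.0
    subtype_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SUBTYPE_MIX))
    variant_count: int = 30_000
    variant_in_gene_fraction: float = 0.5
    transition_fraction: float = 2 / 3
    clinical_flag_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "Pathogenic": 0.06,
            "Likely_pathogenic": 0.05,
            "VUS": 0.04,
            "Likely_benign": 0.02,
            "Benign": 0.02,
        }
    )
    validated_fraction: float = 0.3
    n_localization: int = 120

    def __post_init__(self) -> None:
        for p in (
            self.lnc_monoexonic_fraction,
            self.pcg_monoexonic_fraction,
            self.polya_fraction,
            self.transition_fraction,
            self.validated_fraction,
            self.variant_in_gene_fraction,
            *self.clinical_flag_probs.values(),
            *self.subtype_mix.values(),
        ):
            if not 0 <= p <= 1:
                raise ValueError(f"probability out of [0,1]: {p}")
        for g in (*self.gc_gradient_lnc, *self.gc_gradient_pcg):
            if not 0 < g < 1:
                raise ValueError(f"GC target out of (0,1): {g}")
        if self.lnc_per_chrom < 0 or self.pcg_per_chrom < 0 or self.variant_count < 0:
            raise ValueError("counts must be >= 0")
        if set(self.subtype_mix) != set(SUBTYPES):
            raise ValueError("subtype_mix must cover exactly the 8 subtypes")
        n_windows = (self.chrom_length + self.window - 1) // self.window
        for h in self.hotspots:
            if h.chrom not in self.chrom_names:
                raise ValueError(f"hotspot on unknown chromosome {h.chrom}")
            if not 0 <= h.window_index < n_windows:
                raise ValueError(f"hotspot window {h.window_index} outside chromosome")
            if h.extra_genes < 0:
                raise ValueError("hotspot extra_genes must be >= 0")
        # feasibility: genes need at least minimal spans
        capacity = self.chrom_length // 200
        if self.lnc_per_chrom + self.pcg_per_chrom > capacity:
            raise ValueError("gene counts exceed chromosome capacity")

    @property
    def assembly(self) -> GenomeAssembly:
        return GenomeAssembly(
            names=tuple(self.chrom_names),
            lengths={c: self.chrom_length for c in self.chrom_names},
        )

    @property
    def max_gene_length(self) -> int:
        return max(200, self.chrom_length // 10)


@dataclass
class SimResult:
    """Everything one simulation emitted: file paths, in-memory collections
    and the truth tables."""

    config: SimConfig
    out_dir: Path
    paths: dict[str, Path]
    genes: list[GeneRecord]
    transcripts: list[TranscriptRecord]
    exons: list[ExonRecord]
    sequences: dict[str, str]
    polya_features: list[PolyAFeature]
    variants: list[VariantRecord]
    truth_genes: pd.DataFrame
    truth_variants: pd.DataFrame


def _trunc_lognormal(rng: np.random.Generator, mu: float, sigma: float, lo: int, hi: int, n: int) -> np.ndarray:
    out = np.empty(n, dtype=int)
    todo = np.arange(n)
    while len(todo):
        draw = rng.lognormal(mu, sigma, size=len(todo)).astype(int)
        ok = (draw >= lo) & (draw <= hi)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def _subtype_name(subtype: str, gene_id: str, serial: int, rng: np.random.Generator) -> Optional[str]:
    base = f"GN{serial:05d}"
    if subtype == "novel":
        return gene_id  # no curated symbol: the GTF repeats the accession
    if subtype == "name_assigned":
        return base
    if subtype == "intergenic":
        return f"LINC{serial:05d}"
    suffix = {
        "antisense": "-AS",
        "divergent": "-DT",
        "intronic": "-IT",
        "mirna_host": "-HG",
        "overlapping": "-OT",
    }[subtype]
    # about half the symbols carry a serial digit after the suffix
    digit = str(rng.integers(1, 3)) if rng.random() < 0.5 else ""
    return f"{base}{suffix}{digit}"


def inject_hotspot(
    genes: Sequence[GeneRecord],
    chrom: str,
    window_index: int,
    k: int,
    rng: np.random.Generator,
    config: SimConfig,
    id_offset: int = 0,
) -> tuple[list[GeneRecord], list[str]]:
    """Add k lncRNA genes with start coordinates uniform inside one 1-Mb
    window. Returns the augmented list plus the injected gene ids."""
    if k < 0:
        raise ValueError("k must be >= 0")
    lo = window_index * config.window + 1
    hi = min((window_index + 1) * config.window, config.chrom_length)
    if lo > config.chrom_length:
        raise ValueError("hotspot window outside chromosome")
    added: list[GeneRecord] = []
    subtype_labels, probs = zip(*sorted(config.subtype_mix.items()))
    for i in range(k):
        serial = id_offset + i
        gene_id = f"ENSGS{serial:08d}"
        subtype = rng.choice(subtype_labels, p=probs)
        length = int(
            _trunc_lognormal(
                rng, config.lnc_length_logmu, config.lnc_length_logsigma, 200, config.max_gene_length, 1
            )[0]
        )
        start = int(rng.integers(lo, hi + 1))
        end = min(start + length - 1, config.chrom_length)
        added.append(
            GeneRecord(
                gene_id=gene_id,
                gene_name=_subtype_name(subtype, gene_id, serial, rng),
                chrom=chrom,
                start=start,
                end=end,
                strand="+" if rng.random() < 0.5 else "-",
                biotype="lncRNA",
            )
        )
    return list(genes) + added, [g.gene_id for g in added]


def _make_genes(config: SimConfig, root: np.random.SeedSequence) -> tuple[list[GeneRecord], dict[str, dict]]:
    """Background genes plus hotspot genes; returns records and per-gene truth."""
    genes: list[GeneRecord] = []
    truth: dict[str, dict] = {}
    subtype_labels, probs = zip(*sorted(config.subtype_mix.items()))
    chrom_seeds = root.spawn(len(config.chrom_names))
    serial = 0
    for chrom, seedseq in zip(config.chrom_names, chrom_seeds):
        rng = np.random.default_rng(seedseq)
        for biotype, count in (("lncRNA", config.lnc_per_chrom), ("protein_coding", config.pcg_per_chrom)):
            if biotype == "lncRNA":
                mu, sigma = config.lnc_length_logmu, config.lnc_length_logsigma
            else:
                mu, sigma = config.pcg_length_logmu, config.pcg_length_logsigma
            lengths = _trunc_lognormal(rng, mu, sigma, 200, config.max_gene_length, count)
            for length in lengths:
                if biotype == "lncRNA":
                    gene_id = f"ENSGS{serial:08d}"
                    subtype = str(rng.choice(subtype_labels, p=probs))
                    name = _subtype_name(subtype, gene_id, serial, rng)
                else:
                    gene_id = f"ENSGP{serial:08d}"
                    subtype = ""
                    name = f"PCG{serial:05d}"
                start = int(rng.integers(1, max(config.chrom_length - int(length), 1) + 1))
                end = min(start + int(length) - 1, config.chrom_length)
                rec = GeneRecord(
                    gene_id=gene_id,
                    gene_name=name,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand="+" if rng.random() < 0.5 else "-",
                    biotype=biotype,
                )
                genes.append(rec)
                truth[gene_id] = {"subtype": subtype, "hotspot": False}
                serial += 1
        for h in config.hotspots:
            if h.chrom != chrom:
                continue
            genes, added = inject_hotspot(
                genes, chrom, h.window_index, h.extra_genes, rng, config, id_offset=serial
            )
            for gid in added:
                truth[gid] = {"subtype": "", "hotspot": True}
            serial += h.extra_genes
    # hotspot gene subtypes come from the classifier's own name rules
    by_id = {g.gene_id: g for g in genes}
    from .subtype_classifier import classify

    for gid, t in truth.items():
        g = by_id[gid]
        if g.biotype == "lncRNA":
            t["subtype"] = classify(g.gene_name, gid)
    return genes, truth


def _make_transcripts(
    config: SimConfig, genes: Sequence[GeneRecord], root: np.random.SeedSequence
) -> tuple[list[TranscriptRecord], list[ExonRecord], dict[str, str]]:
    rng = np.random.default_rng(root)
    transcripts: list[TranscriptRecord] = []
    exons: list[ExonRecord] = []
    sequences: dict[str, str] = {}
    for g in genes:
        lnc = g.biotype == "lncRNA"
        tx_mean = config.lnc_tx_mean if lnc else config.pcg_tx_mean
        mono_frac = config.lnc_monoexonic_fraction if lnc else config.pcg_monoexonic_fraction
        exon_p = config.lnc_exon_p if lnc else config.pcg_exon_p
        gc5, gc3 = config.gc_gradient_lnc if lnc else config.gc_gradient_pcg
        n_tx = 1 + int(rng.geometric(1.0 / (tx_mean - 1.0 + 1e-12))) if tx_mean > 1 else 1
        # monoexonic is a gene-level property: all isoforms single-exon
        gene_mono = rng.random() < mono_frac
        for j in range(n_tx):
            tid = f"ENSTS{g.gene_id[5:]}T{j + 1}"
            if gene_mono:
                exon_lengths = [int(rng.integers(200, 2001))]
            else:
                k = max(2, 1 + int(rng.geometric(exon_p)))
                exon_lengths = [int(x) for x in rng.integers(100, 501, size=k)]
            span = g.end - g.start + 1
            total = sum(exon_lengths)
            if total + len(exon_lengths) - 1 > span:
                # shrink to fit tiny genes, preserving exon count
                scale = (span - (len(exon_lengths) - 1)) / total
                exon_lengths = [max(10, int(l * scale)) for l in exon_lengths]
                total = sum(exon_lengths)
                if total + len(exon_lengths) - 1 > span:
                    exon_lengths = [max(10, span // (2 * len(exon_lengths)))] * len(exon_lengths)
                    total = sum(exon_lengths)
            slack = span - total
            k = len(exon_lengths)
            if k == 1:
                offset = int(rng.integers(0, slack + 1))
                starts = [g.start + offset]
            else:
                # place the chain from the gene start with random gaps,
                # clipped so the chain stays inside the gene span
                starts = []
                cursor = g.start
                remaining = slack
                for idx, length in enumerate(exon_lengths):
                    starts.append(cursor)
                    if idx < k - 1:
                        gap = 1 + int(rng.integers(0, max(remaining // (k - 1 - idx), 1)))
                        gap = min(gap, remaining)
                        cursor += length + gap
                        remaining -= gap
                    else:
                        cursor += length
            spans = [(s, s + l - 1) for s, l in zip(starts, exon_lengths)]
            t_start, t_end = spans[0][0], spans[-1][1]
            mature = sum(e - s + 1 for s, e in spans)
            transcripts.append(
                TranscriptRecord(
                    transcript_id=tid,
                    gene_id=g.gene_id,
                    chrom=g.chrom,
                    start=t_start,
                    end=t_end,
                    strand=g.strand,
                    exon_count=k,
                    mature_length=mature,
                )
            )
            for rank, (s, e) in enumerate(spans, start=1):
                exons.append(ExonRecord(transcript_id=tid, start=s, end=e, rank=rank))
            sequences[tid] = _gradient_sequence(rng, mature, gc5, gc3)
    return transcripts, exons, sequences


def _gradient_sequence(rng: np.random.Generator, length: int, gc5: float, gc3: float) -> str:
    """Mature 5'→3' sequence with P(G or C) interpolated linearly from gc5
    to gc3 along the transcript."""
    pos = np.arange(length)
    p_gc = gc5 + (gc3 - gc5) * (pos / max(length - 1, 1))
    is_gc = rng.random(length) < p_gc
    pick = rng.random(length) < 0.5
    bases = np.where(is_gc, np.where(pick, ord("G"), ord("C")), np.where(pick, ord("A"), ord("T")))
    return bases.astype(np.uint8).tobytes().decode()


def _make_polya(
    config: SimConfig, genes: Sequence[GeneRecord], root: np.random.SeedSequence
) -> tuple[list[PolyAFeature], dict[str, float]]:
    rng = np.random.default_rng(root)
    features: list[PolyAFeature] = []
    spacing_truth: dict[str, float] = {}
    for g in genes:
        if rng.random() >= config.polya_fraction:
            continue
        if g.end - g.start + 1 < 200:
            continue
        spacing = int(rng.poisson(config.polya_spacing_mean))
        if g.strand == "+":
            site_start = g.end - 50
            site = (site_start, site_start + 1)
            signal_end = site_start - spacing - 1
            signal = (signal_end - 5, signal_end)
        else:
            site_end = g.start + 50
            site = (site_end - 1, site_end)
            signal_start = site_end + spacing + 1
            signal = (signal_start, signal_start + 5)
        if signal[0] < g.start or signal[1] > g.end:
            continue
        features.append(
            PolyAFeature("polyA_signal", g.chrom, signal[0], signal[1], g.strand, linked_id=g.gene_id)
        )
        features.append(
            PolyAFeature("polyA_site", g.chrom, site[0], site[1], g.strand, linked_id=g.gene_id)
        )
        spacing_truth[g.gene_id] = float(spacing)
    return features, spacing_truth


def _make_variants(
    config: SimConfig, genes: Sequence[GeneRecord], root: np.random.SeedSequence
) -> tuple[list[VariantRecord], pd.DataFrame]:
    rng = np.random.default_rng(root)
    lnc_genes = [g for g in genes if g.biotype == "lncRNA"]
    variants: list[VariantRecord] = []
    truth_rows = []
    bases = "ACGT"
    for i in range(config.variant_count):
        if lnc_genes and rng.random() < config.variant_in_gene_fraction:
            g = lnc_genes[int(rng.integers(0, len(lnc_genes)))]
            chrom = g.chrom
            pos = int(rng.integers(g.start, g.end + 1))
        else:
            chrom = config.chrom_names[int(rng.integers(0, len(config.chrom_names)))]
            pos = int(rng.integers(1, config.chrom_length + 1))
        ref = bases[int(rng.integers(0, 4))]
        is_ti = rng.random() < config.transition_fraction
        if is_ti:
            alt = _TRANSITION_OF[ref]
        else:
            alt = _TRANSVERSIONS_OF[ref][int(rng.integers(0, 2))]
        flags = frozenset(
            flag for flag, p in config.clinical_flag_probs.items() if rng.random() < p
        )
        validated = rng.random() < config.validated_fraction
        vid = f"rs{i + 1:07d}"
        variants.append(
            VariantRecord(
                chrom=chrom,
                pos=pos,
                variant_id=vid,
                ref=ref,
                alts=(alt,),
                clinical_flags=flags,
                validated=validated,
            )
        )
        truth_rows.append(
            {
                "variant_id": vid,
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "substitution": classify_substitution(ref, alt),
                "clinical_class": resolve_clinical(flags),
                "validated": validated,
            }
        )
    columns = ["variant_id", "chrom", "pos", "ref", "alt", "substitution", "clinical_class", "validated"]
    return variants, pd.DataFrame(truth_rows, columns=columns)


def _make_localization(
    config: SimConfig, genes: Sequence[GeneRecord], root: np.random.SeedSequence
) -> list[LocalizationRecord]:
    rng = np.random.default_rng(root)
    named = [g for g in genes if g.biotype == "lncRNA" and g.gene_name and g.gene_name != g.gene_id]
    records: list[LocalizationRecord] = []
    nuclear = sorted(NUCLEAR_TERMS)
    cyto = sorted(CYTOPLASMIC_TERMS)
    n = min(config.n_localization, len(named))
    for g in named[:n]:
        side = nuclear if rng.random() < 0.5 else cyto
        records.append(LocalizationRecord(g.gene_name, side[int(rng.integers(0, len(side)))]))
        if rng.random() < 0.15:  # some molecules carry a second annotation
            side2 = nuclear if rng.random() < 0.5 else cyto
            records.append(LocalizationRecord(g.gene_name, side2[int(rng.integers(0, len(side2)))]))
    return records


def simulate(config: SimConfig, out_dir: str | Path) -> SimResult:
    """Generate the full bundle and write it under ``out_dir``.

    With a fixed configuration (seed included) the emitted files are
    byte-identical across runs; a manifest JSON records the configuration
    and per-file checksums.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    genes_seed, tx_seed, polya_seed, var_seed, loc_seed = root.spawn(5)

    genes, gene_truth = _make_genes(config, genes_seed)
    transcripts, exons, sequences = _make_transcripts(config, genes, tx_seed)
    polya, spacing_truth = _make_polya(config, genes, polya_seed)
    variants, truth_variants = _make_variants(config, genes, var_seed)
    localization = _make_localization(config, genes, loc_seed)

    paths = {
        "genes_gtf": out / "genes.gtf",
        "transcripts_fasta": out / "transcripts.fa",
        "polya_gtf": out / "polya.gtf",
        "variants_vcf": out / "variants.vcf",
        "localization_tsv": out / "localization.tsv",
        "validated_tsv": out / "validated.tsv",
        "truth_genes": out / "truth_genes.tsv",
        "truth_variants": out / "truth_variants.tsv",
        "manifest": out / "manifest.json",
    }
    io_formats.write_gene_annotation(genes, transcripts, exons, paths["genes_gtf"])
    io_formats.write_transcript_sequences(sequences, paths["transcripts_fasta"])
    io_formats.write_polya_annotation(polya, paths["polya_gtf"])
    io_formats.write_variants(
        variants, paths["variants_vcf"], contigs={c: config.chrom_length for c in config.chrom_names}
    )
    io_formats.write_localization_table(localization, paths["localization_tsv"])
    validated_df = (
        truth_variants.loc[truth_variants["validated"], ["chrom", "pos", "variant_id"]]
        .rename(columns={"pos": "start"})
        .assign(end=lambda d: d["start"])
        .loc[:, ["chrom", "start", "end", "variant_id"]]
        .sort_values(["chrom", "start", "variant_id"])
        .reset_index(drop=True)
    )
    io_formats.write_validated_table(validated_df, paths["validated_tsv"])

    truth_genes = pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "gene_name": g.gene_name,
                "biotype": g.biotype,
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "subtype": gene_truth[g.gene_id]["subtype"],
                "hotspot": gene_truth[g.gene_id]["hotspot"],
                "polya_spacing": spacing_truth.get(g.gene_id, np.nan),
            }
            for g in sorted(genes, key=lambda g: g.gene_id)
        ]
    )
    truth_genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    truth_variants = truth_variants.sort_values("variant_id").reset_index(drop=True)
    truth_variants.to_csv(paths["truth_variants"], sep="\t", index=False)

    manifest = {
        "config": _config_dict(config),
        "checksums": {
            name: hashlib.sha256(p.read_bytes()).hexdigest()
            for name, p in sorted(paths.items())
            if name != "manifest" and p.exists()
        },
    }
    io_formats.write_json(manifest, paths["manifest"])

    return SimResult(
        config=config,
        out_dir=out,
        paths=paths,
        genes=genes,
        transcripts=transcripts,
        exons=exons,
        sequences=sequences,
        polya_features=polya,
        variants=variants,
        truth_genes=truth_genes,
        truth_variants=truth_variants,
    )


def _config_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["hotspots"] = [asdict(h) for h in config.hotspots]
    d["subtype_mix"] = dict(config.subtype_mix)
    d["clinical_flag_probs"] = dict(config.clinical_flag_probs)
    return d
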