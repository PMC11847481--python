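"""End-to-end orchestration: read the input bundle, run every analysis
stage, write plotting-ready tables and a machine-readable report.

Stages are skipped gracefully when their inputs are absent; identical
configuration and inputs yield an identical report (and byte-identical
tables on disk).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import (
    gene_architecture,
    io_formats,
    karyotype_density,
    sequence_profile,
    subtype_classifier,
    variant_analysis,
)
from .model import GenomeAssembly, genes_to_frame, transcripts_to_frame, variants_to_frame
from .synthetic_data import SimConfig, SimResult, simulate

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One virtual-karyotype run. All inputs are optional except at least
    one gene annotation; stages without inputs are skipped with a notice."""

    lnc_gtf: Optional[Path] = None
    coding_gtf: Optional[Path] = None
    transcript_fasta: Optional[Path] = None
    polya_gtf: Optional[Path] = None
    variant_vcf: Optional[Path] = None
    localization_tsv: Optional[Path] = None
    validated_tsv: Optional[Path] = None
    assembly: Optional[GenomeAssembly] = None
    window: int = 1_000_000
    peak_quantile: float = 0.95
    n_chunks: int = 20
    gc_window: int = 10
    rule_file: Optional[Path] = None
    chisq_weight_mode: str = "gene_counts"
    monoexonic_mode: str = "all_isoforms"
    out_dir: Path = Path("karyotype_out")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lnc_gtf is None and self.coding_gtf is None:
            raise ValueError("at least one gene annotation GTF is required")
        if not 0 < self.peak_quantile < 1:
            raise ValueError("peak quantile must be in (0, 1)")
        if self.window < 1000:
            raise ValueError("window must be >= 1 kb")


def _derive_assembly(genes: pd.DataFrame, window: int) -> GenomeAssembly:
    """Fallback assembly when none is supplied: chromosome length = last
    gene end rounded up to a whole window."""
    lengths = {}
    for chrom, sub in genes.groupby("chrom", observed=True):
        end = int(sub["end"].max())
        lengths[str(chrom)] = ((end + window - 1) // window) * window
    names = tuple(sorted(lengths))
    return GenomeAssembly(names=names, lengths=lengths)


def run(config: PipelineConfig) -> dict:
    """Execute all stages and return the karyotype report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "provenance": _provenance(config)}
    tables: dict[str, pd.DataFrame] = {}

    rules = (
        subtype_classifier.load_rules(config.rule_file)
        if config.rule_file
        else subtype_classifier.DEFAULT_RULES
    )

    # --- annotation ---------------------------------------------------
    bundles = []
    if config.lnc_gtf:
        bundles.append(
            io_formats.read_gene_annotation(config.lnc_gtf, default_biotype="lncRNA")
        )
    if config.coding_gtf:
        bundles.append(
            io_formats.read_gene_annotation(config.coding_gtf, default_biotype="protein_coding")
        )
    genes = genes_to_frame(g for b in bundles for g in b.genes)
    transcripts = transcripts_to_frame(t for b in bundles for t in b.transcripts)
    exon_records = [e for b in bundles for e in b.exons]
    report["stages"]["annotation"] = {
        "n_genes": len(genes),
        "n_transcripts": len(transcripts),
        "n_exons": len(exon_records),
        "n_rejected": sum(b.n_rejected for b in bundles),
    }
    logger.info("annotation: %s", report["stages"]["annotation"])

    assembly = config.assembly or _derive_assembly(genes, config.window)

    # --- subtype classification ---------------------------------------
    lnc_genes = genes[genes["biotype"] == "lncRNA"].copy()
    classified = subtype_classifier.classify_genes(lnc_genes, rules)
    subtype_tabs = subtype_classifier.subtype_summary(classified)
    tables["subtypes"] = classified[["gene_id", "gene_name", "chrom", "subtype"]]
    tables["subtype_totals"] = subtype_tabs["totals"]
    tables["subtype_by_chromosome"] = subtype_tabs["by_chromosome"]
    tables["subtype_length_stats"] = subtype_tabs["length_stats"]
    report["stages"]["subtypes"] = {
        "n_classified": len(classified),
        "fractions": dict(
            zip(subtype_tabs["totals"]["subtype"], subtype_tabs["totals"]["fraction"].round(6))
        ),
    }

    # --- karyotype density --------------------------------------------
    chrom_summary = karyotype_density.count_by_chromosome(genes, assembly)
    track = karyotype_density.windowed_density(genes, assembly, window=config.window)
    peaks = karyotype_density.call_peaks(track, q=config.peak_quantile)
    tables["chromosome_summary"] = chrom_summary
    tables["density_track"] = peaks
    tables["intergene_distances"] = karyotype_density.inter_gene_distances(genes)
    true_peaks = peaks[peaks["is_true_peak"]]
    io_formats.write_bed(
        true_peaks.rename(columns={"window_start": "start", "window_end": "end"})[
            ["chrom", "start", "end"]
        ].assign(name=true_peaks["biotype"].to_numpy()),
        out / "true_peaks.bed",
    )
    karyo: dict = {"peak_summary": karyotype_density.peak_summary(peaks).to_dict("records")}
    wide = chrom_summary.pivot(index="chrom", columns="biotype", values="count")
    if {"lncRNA", "protein_coding"} <= set(wide.columns) and len(wide) >= 3:
        try:
            karyo["r_lnc_vs_pcg"] = karyotype_density.pearson_r(
                wide["lncRNA"], wide["protein_coding"]
            )
        except karyotype_density.DegenerateInputError:
            karyo["r_lnc_vs_pcg"] = None
        lengths = chrom_summary.drop_duplicates("chrom").set_index("chrom")["length_bp"]
        try:
            karyo["r_lnc_vs_length"] = karyotype_density.pearson_r(
                wide["lncRNA"], lengths.reindex(wide.index)
            )
        except karyotype_density.DegenerateInputError:
            karyo["r_lnc_vs_length"] = None
    report["stages"]["karyotype"] = karyo

    # --- lengths -------------------------------------------------------
    length_rows = []
    for biotype, sub in genes.groupby("biotype", observed=True):
        length_rows.append(sequence_profile.length_summary(sub["length"], label=f"gene_{biotype}"))
    if len(transcripts):
        for biotype in sorted(genes["biotype"].unique()):
            tx = transcripts.merge(genes[["gene_id", "biotype"]], on="gene_id")
            sub = tx[tx["biotype"] == biotype]
            if len(sub):
                summary = sequence_profile.length_summary(
                    sub["mature_length"], detect_modes=len(sub) >= 10, label=f"transcript_{biotype}"
                )
                summary["modes"] = ";".join(f"{m:.0f}" for m in summary.get("modes", []))
                length_rows.append(summary)
    tables["length_summary"] = pd.DataFrame(length_rows)
    report["stages"]["lengths"] = {
        r["group"]: {"n": r["n"], "mean": r["mean"], "median": r["median"]} for r in length_rows
    }

    # --- GC profiles ---------------------------------------------------
    if config.transcript_fasta:
        store = io_formats.read_transcript_sequences(config.transcript_fasta)
        seqs = dict(store.items())
        tx_biotype = dict(
            zip(
                transcripts["transcript_id"],
                transcripts["gene_id"].map(genes.set_index("gene_id")["biotype"]),
            )
        )
        gc_values = {tid: sequence_profile.gc_fraction(s) for tid, s in seqs.items()}
        tables["transcript_gc"] = pd.DataFrame(
            {
                "transcript_id": list(gc_values),
                "gc": list(gc_values.values()),
                "biotype": [tx_biotype.get(t, "") for t in gc_values],
            }
        ).sort_values("transcript_id").reset_index(drop=True)
        biotype_profiles = sequence_profile.group_profile(
            seqs, tx_biotype, window=config.gc_window, n_chunks=config.n_chunks
        )
        tables["gc_profile_by_biotype"] = biotype_profiles
        tx_subtype = dict(
            zip(
                transcripts["transcript_id"],
                transcripts["gene_id"].map(classified.set_index("gene_id")["subtype"]),
            )
        )
        tx_subtype = {t: s for t, s in tx_subtype.items() if isinstance(s, str)}
        if tx_subtype:
            tables["gc_profile_by_subtype"] = sequence_profile.group_profile(
                seqs,
                tx_subtype,
                window=config.gc_window,
                n_chunks=config.n_chunks,
                exclude_groups=("novel", "name_assigned"),
                pool_excluded_as="Others",
            )
        report["stages"]["gc"] = {
            "n_sequences": len(seqs),
            "mean_gc": float(np.mean(list(gc_values.values()))) if gc_values else None,
        }

        # localization comparison needs both FASTA and the table
        if config.localization_tsv:
            records, _ = io_formats.read_localization_table(config.localization_tsv)
            loc_class = sequence_profile.classify_localization(records)
            name_to_gene = dict(zip(genes["gene_name"], genes["gene_id"]))
            gene_gc: dict[str, list[float]] = {}
            for tid, gc in gc_values.items():
                gid = transcripts.loc[transcripts["transcript_id"] == tid, "gene_id"]
                if len(gid):
                    gene_gc.setdefault(gid.iloc[0], []).append(gc)
            groups: dict[str, list[float]] = {"nuclear": [], "cytoplasmic": []}
            for name, cls in loc_class.items():
                if cls not in groups:
                    continue
                gid = name_to_gene.get(name)
                if gid and gid in gene_gc:
                    groups[cls].append(float(np.mean(gene_gc[gid])))
            if all(len(v) >= 2 for v in groups.values()):
                anova = sequence_profile.compare_gc_by_group(groups)
                report["stages"]["localization"] = {
                    "n_nuclear": len(groups["nuclear"]),
                    "n_cytoplasmic": len(groups["cytoplasmic"]),
                    "mean_gc_nuclear": float(np.mean(groups["nuclear"])),
                    "mean_gc_cytoplasmic": float(np.mean(groups["cytoplasmic"])),
                    "anova_F": anova["F"],
                    "anova_p": anova["p"],
                }
            else:
                report["stages"]["localization"] = {"skipped": "too few localized molecules"}
    else:
        logger.info("no transcript FASTA: GC stage skipped")

    # --- architecture & polyA ------------------------------------------
    if len(transcripts):
        arch = gene_architecture.architecture_summary(
            genes, transcripts, monoexonic_mode=config.monoexonic_mode
        )
        tables["architecture_summary"] = arch
        report["stages"]["architecture"] = arch.set_index("biotype").to_dict("index")
        report["stages"]["extremes"] = gene_architecture.extremes(genes, transcripts)
    if config.polya_gtf:
        features = io_formats.read_polya_annotation(config.polya_gtf)
        assignments = gene_architecture.assign_polya(genes, features)
        flags = gene_architecture.polya_gene_flags(genes, assignments)
        pairs = gene_architecture.pair_site_signal(assignments)
        tables["polya_pairs"] = pairs
        tables["polya_gene_flags"] = flags
        spacing = gene_architecture.mean_spacing_by_biotype(pairs)
        tables["polya_spacing"] = spacing
        report["stages"]["polya"] = {
            "n_features": len(features),
            "gene_fraction_with_polya": {
                str(b): float(sub["has_polyA"].mean())
                for b, sub in flags.groupby("biotype", observed=True)
            },
            "mean_spacing": {
                str(r["biotype"]): float(r["mean_spacing"]) for _, r in spacing.iterrows()
            },
        }

    # --- variants -------------------------------------------------------
    if config.variant_vcf:
        variants = io_formats.read_variants(config.variant_vcf)
        vdf = variants_to_frame(variants)
        vdf = variant_analysis.add_clinical_class(vdf)
        classes = variant_analysis.substitution_classes(vdf)
        titv = variant_analysis.titv_shares(classes)
        clin_vdf = vdf[vdf["clinical_class"] != "unclassified"]
        titv_clinical = (
            variant_analysis.titv_shares(variant_analysis.substitution_classes(clin_vdf))
            if len(clin_vdf)
            else None
        )
        hits = variant_analysis.intersect(vdf, classified, assembly=assembly)
        if config.validated_tsv is not None and len(hits):
            validated = io_formats.read_validated_table(config.validated_tsv)
            hits = variant_analysis.crossref_validated(hits, validated)
        tables["variant_hits"] = hits
        dist = variant_analysis.distribution_tables(hits) if len(hits) else {}
        for name, frame in dist.items():
            tables[f"variant_{name}"] = frame
        chisq = (
            variant_analysis.subtype_chisq_by_chromosome(
                hits, classified, weight_mode=config.chisq_weight_mode
            )
            if len(hits)
            else pd.DataFrame()
        )
        tables["variant_chisq"] = chisq
        report["stages"]["variants"] = {
            "n_variants": len(vdf),
            "titv": titv,
            "titv_clinical": titv_clinical,
            "n_lncG_hits": int(hits["variant_id"].nunique()) if len(hits) else 0,
            "n_validated_hits": int(hits["validated"].sum()) if "validated" in hits else 0,
            "chisq_all_p_below_1e4": bool((chisq["p"] < 1e-4).all()) if len(chisq) else None,
            "chisq_weight_mode": config.chisq_weight_mode,
        }
    else:
        logger.info("no VCF: variant stage skipped")

    io_formats.write_tables(tables, out)
    io_formats.write_json(report, out / "report.json")
    return report


def _provenance(config: PipelineConfig) -> dict:
    prov = {"seed": config.seed, "window": config.window, "peak_quantile": config.peak_quantile}
    checksums = {}
    for name in (
        "lnc_gtf",
        "coding_gtf",
        "transcript_fasta",
        "polya_gtf",
        "variant_vcf",
        "localization_tsv",
        "validated_tsv",
    ):
        p = getattr(config, name)
        if p and Path(p).exists():
            checksums[name] = hashlib.sha256(Path(p).read_bytes()).hexdigest()
    prov["input_checksums"] = checksums
    return prov


def simulate_and_run(
    sim_config: SimConfig,
    out_dir: str | Path,
    pipeline_kwargs: Optional[dict] = None,
) -> tuple[dict, dict, SimResult]:
    """Simulate a bundle, run the pipeline on it and score recovery against
    the generator's truth tables.

    Returns (report, scorecard, sim_result). The scorecard reports subtype
    agreement, hotspot detection, transition-fraction error and polyA
    spacing error.
    """
    out = Path(out_dir)
    sim = simulate(sim_config, out / "bundle")
    config = PipelineConfig(
        lnc_gtf=sim.paths["genes_gtf"],
        transcript_fasta=sim.paths["transcripts_fasta"],
        polya_gtf=sim.paths["polya_gtf"],
        variant_vcf=sim.paths["variants_vcf"],
        localization_tsv=sim.paths["localization_tsv"],
        validated_tsv=sim.paths["validated_tsv"],
        assembly=sim_config.assembly,
        out_dir=out / "results",
        seed=sim_config.seed,
        **(pipeline_kwargs or {}),
    )
    report = run(config)
    scorecard = score_recovery(sim, report, config)
    io_formats.write_json(scorecard, out / "scorecard.json")
    return report, scorecard, sim


def score_recovery(sim: SimResult, report: dict, config: PipelineConfig) -> dict:
    """Compare pipeline output with generator truth."""
    from .subtype_classifier import classify_genes

    card: dict = {}

    truth = sim.truth_genes
    lnc_truth = truth[truth["biotype"] == "lncRNA"]
    predicted = classify_genes(genes_to_frame(g for g in sim.genes if g.biotype == "lncRNA"))
    merged = lnc_truth.merge(predicted[["gene_id", "subtype"]], on="gene_id", suffixes=("_true", "_pred"))
    card["subtype_agreement"] = float((merged["subtype_true"] == merged["subtype_pred"]).mean())

    # hotspot recovery: every hotspot window flagged TRUE in the lncRNA track
    track = pd.read_csv(Path(config.out_dir) / "density_track.tsv", sep="\t")
    lnc_track = track[track["biotype"] == "lncRNA"]
    hits = []
    for h in sim.config.hotspots:
        row = lnc_track[
            (lnc_track["chrom"] == h.chrom) & (lnc_track["window_index"] == h.window_index)
        ]
        hits.append(bool(row["is_true_peak"].iloc[0]) if len(row) else False)
    card["hotspot_recall"] = float(np.mean(hits)) if hits else None

    titv = report["stages"].get("variants", {}).get("titv")
    if titv and titv["n_substitutions"]:
        card["transition_share_observed"] = titv["transition_share"]
        card["transition_share_configured"] = sim.config.transition_fraction
        card["transition_share_error"] = abs(
            titv["transition_share"] - sim.config.transition_fraction
        )
    else:
        card["transition_share_observed"] = None

    spacing_truth = sim.truth_genes["polya_spacing"].dropna()
    mean_spacing = report["stages"].get("polya", {}).get("mean_spacing", {})
    if len(spacing_truth) and mean_spacing:
        observed = float(np.mean(list(mean_spacing.values())))
        card["polya_spacing_truth_mean"] = float(spacing_truth.mean())
        card["polya_spacing_observed_mean"] = observed
        card["polya_spacing_error"] = abs(observed - float(spacing_truth.mean()))
    return card
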