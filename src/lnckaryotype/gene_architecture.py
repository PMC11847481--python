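"""Exon/isoform architecture, polyadenylation element assignment and
site–signal spacing, plus the small exact tests used alongside them.

Exons-per-gene aggregates exon records across all isoforms of a gene
without deduplicating shared exons, the convention under which a gene with
8–9 isoforms of ~8 exons each averages ~70 exons. A monoexonic gene is one
all of whose isoforms consist of a single exon.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from math import comb
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import GeneRecord, PolyAFeature

logger = logging.getLogger(__name__)

PAIRING_WINDOW_NT = 100
SIGNAL_MOTIF = "AATAAA"
SITE_MOTIF = "CA"


def architecture_summary(
    genes: pd.DataFrame,
    transcripts: pd.DataFrame,
    monoexonic_mode: str = "all_isoforms",
) -> pd.DataFrame:
    """Per-biotype exon/isoform statistics.

    monoexonic_mode: "all_isoforms" counts a gene as monoexonic when every
    isoform has exactly one exon; "any_isoform" when at least one does.
    """
    if monoexonic_mode not in ("all_isoforms", "any_isoform"):
        raise ValueError("monoexonic_mode must be 'all_isoforms' or 'any_isoform'")
    tx = transcripts.merge(genes[["gene_id", "biotype"]], on="gene_id", how="left")
    orphans = tx["biotype"].isna()
    if orphans.any():
        logger.info("architecture_summary: %d orphan transcripts excluded", int(orphans.sum()))
        tx = tx[~orphans]
    rows = []
    for biotype, sub in tx.groupby("biotype", observed=True):
        per_gene = sub.groupby("gene_id").agg(
            n_tx=("transcript_id", "nunique"),
            exons_total=("exon_count", "sum"),
            all_mono=("exon_count", lambda e: bool((e == 1).all())),
            any_mono=("exon_count", lambda e: bool((e == 1).any())),
        )
        mono = per_gene["all_mono"] if monoexonic_mode == "all_isoforms" else per_gene["any_mono"]
        rows.append(
            {
                "biotype": biotype,
                "n_genes": len(per_gene),
                "n_transcripts": int(per_gene["n_tx"].sum()),
                "mean_exons_per_gene": float(per_gene["exons_total"].mean()),
                "median_exons_per_gene": float(per_gene["exons_total"].median()),
                "mean_exons_per_transcript": float(sub["exon_count"].mean()),
                "median_exons_per_transcript": float(sub["exon_count"].median()),
                "n_monoexonic_genes": int(mono.sum()),
                "monoexonic_fraction": float(mono.mean()),
                "mean_transcripts_per_gene": float(per_gene["n_tx"].mean()),
                "median_transcripts_per_gene": float(per_gene["n_tx"].median()),
            }
        )
    return pd.DataFrame(rows).sort_values("biotype").reset_index(drop=True)


def extremes(genes: pd.DataFrame, transcripts: pd.DataFrame) -> dict:
    """Longest gene, gene with most isoforms, and transcript(s) with the
    largest exon count. Ties break on lexicographically smallest id."""
    if genes.empty:
        raise ValueError("empty gene collection")
    g = genes.sort_values(["length", "gene_id"], ascending=[False, True]).iloc[0]
    out = {
        "longest_gene": {
            "gene_id": g["gene_id"],
            "gene_name": g["gene_name"],
            "length": int(g["length"]),
        }
    }
    if not transcripts.empty:
        iso = (
            transcripts.groupby("gene_id")["transcript_id"]
            .nunique()
            .sort_values(ascending=False)
        )
        top_n = iso.max()
        top_gene = min(iso[iso == top_n].index)
        out["max_isoform_gene"] = {"gene_id": top_gene, "n_transcripts": int(top_n)}
        emax = transcripts["exon_count"].max()
        tx_ids = sorted(transcripts.loc[transcripts["exon_count"] == emax, "transcript_id"])
        out["max_exon_transcripts"] = {"exon_count": int(emax), "transcript_ids": tx_ids}
    return out


def assign_polya(
    genes: Iterable[GeneRecord] | pd.DataFrame,
    features: Sequence[PolyAFeature],
    mode: str = "span",
) -> pd.DataFrame:
    """Assign polyA features to genes.

    mode "span" (default): a feature goes to every same-strand gene whose
    span it overlaps. mode "linked": a feature goes to the gene whose id
    (or whose transcript's id prefix) matches the feature's annotated link;
    unlinked features are dropped. Returns one row per (gene, feature).
    """
    if mode not in ("span", "linked"):
        raise ValueError("mode must be 'span' or 'linked'")
    if isinstance(genes, pd.DataFrame):
        gdf = genes
    else:
        from .model import genes_to_frame

        gdf = genes_to_frame(genes)
    rows = []
    if mode == "linked":
        by_id = {g.gene_id: g for g in gdf.itertuples(index=False)}
        for f in features:
            g = by_id.get(f.linked_id) if f.linked_id else None
            if g is not None and g.strand == f.strand:
                rows.append(
                    {
                        "gene_id": g.gene_id,
                        "biotype": g.biotype,
                        "strand": g.strand,
                        "kind": f.kind,
                        "feature_start": f.start,
                        "feature_end": f.end,
                    }
                )
    else:
        by_chrom: dict[tuple[str, str], list[PolyAFeature]] = {}
        for f in features:
            by_chrom.setdefault((f.chrom, f.strand), []).append(f)
        for g in gdf.itertuples(index=False):
            for f in by_chrom.get((g.chrom, g.strand), []):
                if f.start <= g.end and f.end >= g.start:
                    rows.append(
                        {
                            "gene_id": g.gene_id,
                            "biotype": g.biotype,
                            "strand": g.strand,
                            "kind": f.kind,
                            "feature_start": f.start,
                            "feature_end": f.end,
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "biotype", "strand", "kind", "feature_start", "feature_end"],
    )


def polya_gene_flags(genes: pd.DataFrame, assignments: pd.DataFrame) -> pd.DataFrame:
    """has_polyA per gene: at least one assigned site or signal."""
    flagged = set(assignments["gene_id"]) if len(assignments) else set()
    out = genes[["gene_id", "biotype"]].copy()
    out["has_polyA"] = out["gene_id"].isin(flagged)
    return out


def pair_site_signal(
    assignments: pd.DataFrame,
    max_gap: int = PAIRING_WINDOW_NT,
) -> pd.DataFrame:
    """Pair each polyA site with its nearest upstream signal in the same
    gene, strand-aware, within ``max_gap`` nt.

    Spacing on + is (site 5' coordinate − signal 3' coordinate − 1); on −
    the mirror (signal 5' coordinate − site 3' coordinate − 1). Sites with
    no upstream signal in range are left unpaired and excluded from means.
    """
    pairs = []
    if assignments.empty:
        return pd.DataFrame(columns=["gene_id", "biotype", "signal_start", "signal_end", "site_start", "site_end", "spacing"])
    for (gene_id, strand), sub in assignments.groupby(["gene_id", "strand"]):
        sites = sub[sub["kind"] == "polyA_site"]
        signals = sub[sub["kind"] == "polyA_signal"]
        if sites.empty or signals.empty:
            continue
        biotype = sub["biotype"].iloc[0]
        for site in sites.itertuples(index=False):
            best = None
            for sig in signals.itertuples(index=False):
                if strand == "+":
                    spacing = site.feature_start - sig.feature_end - 1
                else:
                    spacing = sig.feature_start - site.feature_end - 1
                if 0 <= spacing <= max_gap and (best is None or spacing < best[0]):
                    best = (spacing, sig)
            if best is not None:
                spacing, sig = best
                pairs.append(
                    {
                        "gene_id": gene_id,
                        "biotype": biotype,
                        "signal_start": sig.feature_start,
                        "signal_end": sig.feature_end,
                        "site_start": site.feature_start,
                        "site_end": site.feature_end,
                        "spacing": spacing,
                    }
                )
    return pd.DataFrame(
        pairs,
        columns=["gene_id", "biotype", "signal_start", "signal_end", "site_start", "site_end", "spacing"],
    )


def mean_spacing_by_biotype(pairs: pd.DataFrame) -> pd.DataFrame:
    if pairs.empty:
        return pd.DataFrame(columns=["biotype", "n_pairs", "mean_spacing"])
    return (
        pairs.groupby("biotype", observed=True)["spacing"]
        .agg(n_pairs="size", mean_spacing="mean")
        .reset_index()
    )


def scan_motifs(seq: str) -> dict[str, list[int]]:
    """1-based start positions of every (possibly overlapping) occurrence of
    the canonical polyA signal (AATAAA) and site (CA) motifs."""
    s = seq.upper()
    return {
        "polyA_signal": [m.start() + 1 for m in re.finditer(f"(?={SIGNAL_MOTIF})", s)],
        "polyA_site": [m.start() + 1 for m in re.finditer(f"(?={SITE_MOTIF})", s)],
    }


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 count table.

    Returns (odds_ratio, p). The two-sided p sums, over all tables with the
    observed margins, the probabilities no larger than the observed one.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if t.sum(axis=0).min() == 0 and t.sum() == 0:
        raise ValueError("empty margins")
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return float(odds), float(p)
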