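"""Single-nucleotide variant analysis over gene bodies: interval
intersection, transition/transversion classification, clinical-significance
priority resolution, distribution tables and goodness-of-fit testing.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import CLINICAL_FLAGS, GenomeAssembly, VariantRecord, variants_to_frame

#: Pathogenicity classes in descending priority; a multi-flagged variant
#: resolves to the highest-priority true flag.
CLINICAL_CLASSES = ("pathogenic", "likely_pathogenic", "VUS", "likely_benign", "benign")
_FLAG_TO_CLASS = dict(zip(CLINICAL_FLAGS, CLINICAL_CLASSES))

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_BASES = frozenset("ACGT")


def intersect(
    variants: Iterable[VariantRecord] | pd.DataFrame,
    genes: pd.DataFrame,
    assembly: Optional[GenomeAssembly] = None,
) -> pd.DataFrame:
    """All (variant, gene) hits: variant position inside the gene span,
    inclusive bounds, strand-ignored. A variant inside k genes yields k
    rows; per-chromosome totals should deduplicate on variant_id."""
    vdf = variants if isinstance(variants, pd.DataFrame) else variants_to_frame(variants)
    if assembly is not None:
        vdf = vdf.copy()
        vdf["chrom"] = [assembly.normalize(c) for c in vdf["chrom"]]
        if vdf["chrom"].isna().any():
            bad = vdf.loc[vdf["chrom"].isna(), "variant_id"].head(3).tolist()
            raise ValueError(f"variants on unknown chromosomes, e.g. {bad}")
    rows = []
    cols = [c for c in vdf.columns if c not in ("chrom", "pos")]
    for chrom, vsub in vdf.groupby("chrom", observed=True):
        gsub = genes[genes["chrom"] == chrom]
        if gsub.empty:
            continue
        starts = gsub["start"].to_numpy()
        ends = gsub["end"].to_numpy()
        pos = vsub["pos"].to_numpy()
        # pairwise containment; collections are modest after per-chrom split
        inside = (pos[:, None] >= starts[None, :]) & (pos[:, None] <= ends[None, :])
        vi, gi = np.nonzero(inside)
        for v_idx, g_idx in zip(vi, gi):
            row = {"chrom": chrom, "pos": int(pos[v_idx])}
            for c in cols:
                row[c] = vsub.iloc[v_idx][c]
            grow = gsub.iloc[g_idx]
            row["gene_id"] = grow["gene_id"]
            row["biotype"] = grow["biotype"]
            if "subtype" in gsub.columns:
                row["subtype"] = grow["subtype"]
            rows.append(row)
    base_cols = ["chrom", "pos", *cols, "gene_id", "biotype"]
    if "subtype" in genes.columns:
        base_cols.append("subtype")
    return pd.DataFrame(rows, columns=base_cols)


def classify_substitution(ref: str, alt: str) -> str:
    """transition / transversion / other for one ref→alt allele pair.

    Transitions are the purine↔purine and pyrimidine↔pyrimidine exchanges
    (A↔G, C↔T); any other single-base exchange is a transversion; indels and
    multi-nucleotide alleles are "other"."""
    r, a = ref.upper(), alt.upper()
    if len(r) != 1 or len(a) != 1 or r not in _BASES or a not in _BASES or r == a:
        return "other"
    return "transition" if (r, a) in _TRANSITIONS else "transversion"


def substitution_classes(variants: pd.DataFrame) -> pd.DataFrame:
    """One classification per alt allele of every variant."""
    rows = []
    for v in variants.itertuples(index=False):
        for alt in str(v.alts).split(","):
            rows.append(
                {
                    "variant_id": v.variant_id,
                    "chrom": v.chrom,
                    "ref": v.ref,
                    "alt": alt,
                    "substitution": classify_substitution(v.ref, alt),
                }
            )
    return pd.DataFrame(rows, columns=["variant_id", "chrom", "ref", "alt", "substitution"])


def titv_shares(classes: pd.DataFrame) -> dict:
    """Transition/transversion shares over classified substitutions (indels
    and MNVs excluded from the denominator)."""
    sub = classes[classes["substitution"].isin(["transition", "transversion"])]
    n = len(sub)
    ti = int((sub["substitution"] == "transition").sum())
    return {
        "n_substitutions": n,
        "n_transitions": ti,
        "n_transversions": n - ti,
        "transition_share": ti / n if n else float("nan"),
        "transversion_share": (n - ti) / n if n else float("nan"),
    }


def resolve_clinical(flags: Iterable[str]) -> str:
    """Highest-priority true clinical flag; no flags → unclassified."""
    present = set(flags)
    for flag in CLINICAL_FLAGS:  # already in priority order
        if flag in present:
            return _FLAG_TO_CLASS[flag]
    return "unclassified"


def add_clinical_class(variants: pd.DataFrame) -> pd.DataFrame:
    out = variants.copy()
    out["clinical_class"] = [
        resolve_clinical(f for f in CLINICAL_FLAGS if row[f])
        for row in variants[list(CLINICAL_FLAGS)].to_dict("records")
    ]
    return out


def distribution_tables(hits: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-chromosome subtype counts, pathogenicity fractions and variant
    totals from a hit table carrying subtype and clinical_class columns."""
    tables: dict[str, pd.DataFrame] = {}
    dedup = hits.drop_duplicates("variant_id")
    tables["per_chromosome_totals"] = (
        dedup.groupby("chrom", observed=True)["variant_id"].nunique().rename("n_variants").reset_index()
    )
    if "subtype" in hits.columns:
        tables["subtype_by_chromosome"] = (
            hits.groupby(["chrom", "subtype"], observed=True)["variant_id"]
            .nunique()
            .unstack(fill_value=0)
            .reset_index()
        )
    if "clinical_class" in hits.columns:
        clin = dedup[dedup["clinical_class"] != "unclassified"]
        counts = (
            clin.groupby(["chrom", "clinical_class"], observed=True)["variant_id"]
            .nunique()
            .unstack(fill_value=0)
            .reindex(columns=CLINICAL_CLASSES, fill_value=0)
        )
        frac = counts.div(counts.sum(axis=1).replace(0, np.nan), axis=0)
        tables["pathogenicity_counts"] = counts.reset_index()
        tables["pathogenicity_fractions"] = frac.reset_index()
    return tables


def chisq_observed_expected(
    observed: Sequence[float],
    expected_weights: Sequence[float],
) -> dict:
    """Goodness-of-fit chi-square of observed counts against expected
    weights (rescaled to the observed total). df = k − 1."""
    obs = np.asarray(observed, dtype=float)
    w = np.asarray(expected_weights, dtype=float)
    if len(obs) != len(w) or len(obs) < 2:
        raise ValueError("need k >= 2 matched categories")
    if (w <= 0).any():
        raise ValueError("expected weights must be positive")
    exp = w / w.sum() * obs.sum()
    x2 = float(((obs - exp) ** 2 / exp).sum())
    df = len(obs) - 1
    return {"X2": x2, "df": df, "p": float(stats.chi2.sf(x2, df)), "expected": exp.tolist()}


def subtype_chisq_by_chromosome(
    hits: pd.DataFrame,
    classified_genes: pd.DataFrame,
    weight_mode: str = "gene_counts",
) -> pd.DataFrame:
    """Per-chromosome chi-square of observed SNP counts across subtypes
    against expected weights.

    weight_mode: "gene_counts" (per-subtype gene counts on that chromosome),
    "gene_bp" (per-subtype genomic bp) or "genome_share" (genome-wide
    subtype shares). Subtypes with zero weight on a chromosome are excluded
    from that chromosome's test.
    """
    if weight_mode not in ("gene_counts", "gene_bp", "genome_share"):
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    rows = []
    genome_counts = classified_genes.groupby("subtype", observed=True).size()
    for chrom, sub in hits.groupby("chrom", observed=True):
        obs = sub.groupby("subtype", observed=True)["variant_id"].nunique()
        gsub = classified_genes[classified_genes["chrom"] == chrom]
        if weight_mode == "gene_counts":
            w = gsub.groupby("subtype", observed=True).size()
        elif weight_mode == "gene_bp":
            w = gsub.groupby("subtype", observed=True)["length"].sum()
        else:
            w = genome_counts
        cats = [s for s in w.index if w[s] > 0]
        if len(cats) < 2:
            continue
        obs_v = [int(obs.get(s, 0)) for s in cats]
        res = chisq_observed_expected(obs_v, [float(w[s]) for s in cats])
        rows.append(
            {
                "chrom": chrom,
                "k": len(cats),
                "X2": res["X2"],
                "df": res["df"],
                "p": res["p"],
                "weight_mode": weight_mode,
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "k", "X2", "df", "p", "weight_mode"])


def crossref_validated(hits: pd.DataFrame, validated: pd.DataFrame) -> pd.DataFrame:
    """Flag hits whose (chrom, position) exactly matches a validated-variant
    coordinate row; duplicate validated rows collapse to one."""
    keys = set(
        zip(validated["chrom"].astype(str), validated["start"].astype(int))
    )
    out = hits.copy()
    out["validated"] = [
        (str(c), int(p)) in keys for c, p in zip(out["chrom"], out["pos"])
    ]
    return out
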