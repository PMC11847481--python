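"""Nomenclature-based classification of lncRNA genes into eight subtypes.

Human lncRNA gene symbols encode a coarse positional taxonomy: ``LINC``
prefixes mark long intergenic lncRNAs; hyphenated suffixes mark antisense
(``-AS1``), divergent (``-DT``), intronic (``-IT1``), microRNA-hosting
(``-HG1``) and overlapping (``-OT1``) transcripts. Genes with no symbol
beyond their accession are "novel"; everything else carries an arbitrary,
curated name ("name-assigned"). Classification is purely lexical — no
coordinate comparison against protein-coding genes is attempted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .model import GeneRecord

SUBTYPES = (
    "novel",
    "name_assigned",
    "antisense",
    "divergent",
    "intergenic",
    "intronic",
    "mirna_host",
    "overlapping",
)


@dataclass(frozen=True)
class Rule:
    """One ordered classification rule.

    kind: "prefix" matches names starting with the pattern; "suffix_digits"
    matches names ending with the pattern followed by optional digits.
    """

    kind: str
    pattern: str
    subtype: str

    def matches(self, name: str) -> bool:
        if self.kind == "prefix":
            return name.startswith(self.pattern)
        if self.kind == "suffix_digits":
            return re.search(re.escape(self.pattern) + r"\d*$", name) is not None
        raise ValueError(f"unknown rule kind {self.kind!r}")


#: Rule precedence is fixed: novel handling first (built into classify),
#: then LINC, then the hyphenated suffixes, with name_assigned as fallback.
DEFAULT_RULES: tuple[Rule, ...] = (
    Rule("prefix", "LINC", "intergenic"),
    Rule("suffix_digits", "-AS", "antisense"),
    Rule("suffix_digits", "-DT", "divergent"),
    Rule("suffix_digits", "-IT", "intronic"),
    Rule("suffix_digits", "-HG", "mirna_host"),
    Rule("suffix_digits", "-OT", "overlapping"),
)

#: Optional extension: capture host genes named without a hyphen, e.g.
#: MIR17HG. Off by default — the hyphenated rule is the documented one.
UNHYPHENATED_HG_RULE = Rule("suffix_digits", "HG", "mirna_host")


def classify(
    gene_name: Optional[str],
    gene_id: str,
    rules: Sequence[Rule] = DEFAULT_RULES,
) -> str:
    """Assign one subtype from (name, accession). Pure and total.

    A missing name, a name equal to the accession, or a name that itself
    starts with "ENSG" all mean the gene has no curated symbol → novel.
    Matching is case-sensitive on the conventional uppercase symbols.
    """
    if not gene_name or gene_name == gene_id or gene_name.startswith("ENSG"):
        return "novel"
    for rule in rules:
        if rule.matches(gene_name):
            return rule.subtype
    return "name_assigned"


def load_rules(path: str | Path) -> tuple[Rule, ...]:
    """Load an ordered rule set from a 3-column TSV: kind, pattern, subtype."""
    rules = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        kind, pattern, subtype = line.split("\t")
        if subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {subtype!r} in rule file")
        rules.append(Rule(kind, pattern, subtype))
    if not rules:
        raise ValueError(f"no rules in {path}")
    return tuple(rules)


def classify_genes(
    genes: Iterable[GeneRecord] | pd.DataFrame,
    rules: Sequence[Rule] = DEFAULT_RULES,
) -> pd.DataFrame:
    """Classify a gene collection; returns gene_id, gene_name, subtype (+
    chrom and length when available)."""
    if isinstance(genes, pd.DataFrame):
        df = genes.copy()
    else:
        from .model import genes_to_frame

        df = genes_to_frame(genes)
    df["subtype"] = [
        classify(name if isinstance(name, str) else None, gid, rules)
        for name, gid in zip(df["gene_name"], df["gene_id"])
    ]
    return df


def subtype_summary(classified: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-subtype counts/fractions, per-chromosome distribution and length
    statistics for a classified gene frame."""
    counts = (
        classified["subtype"].value_counts().reindex(SUBTYPES, fill_value=0).rename("count")
    )
    totals = pd.DataFrame(counts)
    totals["fraction"] = totals["count"] / max(totals["count"].sum(), 1)
    totals = totals.reset_index(names="subtype")

    by_chrom = (
        classified.groupby(["chrom", "subtype"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=SUBTYPES, fill_value=0)
        .reset_index()
    )

    if "length" in classified.columns:
        grp = classified.groupby("subtype", observed=True)["length"]
        lengths = pd.DataFrame(
            {
                "n": grp.size(),
                "mean_length": grp.mean(),
                "sem_length": grp.sem(ddof=1),
            }
        ).reindex(SUBTYPES)
        lengths = lengths.fillna({"n": 0}).reset_index(names="subtype")
    else:
        lengths = pd.DataFrame(columns=["subtype", "n", "mean_length", "sem_length"])

    return {"totals": totals, "by_chromosome": by_chrom, "length_stats": lengths}
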