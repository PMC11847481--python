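"""Transcript sequence statistics: GC content, positional GC profiles in 20
length-proportional chunks, length summaries and localization comparison.

The positional profile slides a 10-nt window along the mature transcript
(step 1), then averages window values into 20 chunks proportional to the
transcript length, giving comparable 5'→3' profiles for transcripts of any
length. Profiles in the literature are sometimes labelled "GC skew"; the
quantity computed here is positional GC *content*, (G+C)/total per window.
True strand skew (G−C)/(G+C) is available separately.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

N_CHUNKS = 20
GC_WINDOW = 10

_UNAMBIGUOUS = frozenset("ACGT")

#: Compartment vocabularies for nuclear/cytoplasmic calls (matched
#: case-insensitively on the exact terms).
NUCLEAR_TERMS = frozenset(
    t.lower()
    for t in (
        "Nucleoplasm",
        "Nucleus",
        "Chromatin",
        "Nuclear",
        "Nuclear speckle",
        "Paraspeckles in the nucleus",
    )
)
CYTOPLASMIC_TERMS = frozenset(
    t.lower()
    for t in (
        "Cytosol",
        "Cytoplasm",
        "Ribosome",
        "Ribosome-free cytosol",
        "Mitochondrion",
        "Endoplasmic reticulum",
    )
)


class EmptySequenceError(ValueError):
    """GC content undefined: no unambiguous bases."""


def gc_fraction(seq: str) -> float:
    """(G+C) / (A+C+G+T); ambiguity codes are excluded from the denominator."""
    if not seq:
        raise EmptySequenceError("empty sequence")
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        raise EmptySequenceError("no unambiguous bases in sequence")
    return gc / (gc + at)


def strand_skew(seq: str) -> float:
    """True GC skew, (G−C)/(G+C) — kept separate from the positional GC
    content profile."""
    s = seq.upper()
    g, c = s.count("G"), s.count("C")
    if g + c == 0:
        raise EmptySequenceError("no G or C bases")
    return (g - c) / (g + c)


def sliding_gc(seq: str, window: int = GC_WINDOW, step: int = 1) -> np.ndarray:
    """GC content in sliding windows along the sequence, 5'→3'.

    Window i (0-based) covers positions [i, i+window). Sequences shorter
    than the window yield one whole-sequence value. Windows containing only
    ambiguity codes propagate NaN.
    """
    if not seq:
        raise EmptySequenceError("empty sequence")
    s = seq.upper()
    if len(s) < window:
        return np.array([gc_fraction(s)])
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    is_gc = np.isin(arr, np.frombuffer(b"GC", dtype=np.uint8)).astype(float)
    is_acgt = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8)).astype(float)
    # cumulative sums give O(1) window counts
    cgc = np.concatenate([[0.0], np.cumsum(is_gc)])
    cun = np.concatenate([[0.0], np.cumsum(is_acgt)])
    starts = np.arange(0, len(s) - window + 1, step)
    gc_counts = cgc[starts + window] - cgc[starts]
    un_counts = cun[starts + window] - cun[starts]
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(un_counts > 0, gc_counts / np.maximum(un_counts, 1), np.nan)


def chunk_profile(series: Sequence[float] | np.ndarray, n_chunks: int = N_CHUNKS) -> pd.DataFrame:
    """Average an ordered window series into length-proportional chunks.

    Window i of m is assigned to chunk floor(i*n/m). With fewer windows than
    chunks some chunks receive no window; those are reported with
    ``n_windows`` 0 and NaN mean, and are excluded from group aggregation.
    """
    values = np.asarray(series, dtype=float)
    m = len(values)
    if m == 0:
        raise ValueError("empty window series")
    assignment = (np.arange(m) * n_chunks) // m
    means = np.full(n_chunks, np.nan)
    counts = np.zeros(n_chunks, dtype=int)
    for chunk in range(n_chunks):
        mask = assignment == chunk
        vals = values[mask]
        vals = vals[~np.isnan(vals)]
        counts[chunk] = len(vals)
        if len(vals):
            means[chunk] = vals.mean()
    return pd.DataFrame({"chunk": np.arange(1, n_chunks + 1), "gc_mean": means, "n_windows": counts})


def transcript_profile(seq: str, window: int = GC_WINDOW, n_chunks: int = N_CHUNKS) -> pd.DataFrame:
    return chunk_profile(sliding_gc(seq, window=window), n_chunks=n_chunks)


def group_profile(
    sequences: Mapping[str, str],
    groups: Mapping[str, str],
    window: int = GC_WINDOW,
    n_chunks: int = N_CHUNKS,
    exclude_groups: Sequence[str] = (),
    pool_excluded_as: Optional[str] = None,
) -> pd.DataFrame:
    """Chunk-wise mean GC profile per group.

    ``groups`` maps subject id → group label (e.g. biotype or lncRNA
    subtype). The mean for a chunk is taken across members that contribute
    at least one window to it. Groups listed in ``exclude_groups`` are
    dropped, or pooled under ``pool_excluded_as`` when given — used to keep
    ambiguous taxonomy classes (novel, name-assigned) out of subtype
    profiles.
    """
    per_member: dict[str, list[np.ndarray]] = {}
    for subject, seq in sequences.items():
        label = groups.get(subject)
        if label is None:
            continue
        if label in exclude_groups:
            if pool_excluded_as is None:
                continue
            label = pool_excluded_as
        prof = transcript_profile(seq, window=window, n_chunks=n_chunks)
        per_member.setdefault(label, []).append(prof["gc_mean"].to_numpy())
    if not per_member:
        raise ValueError("no members in any group")
    rows = []
    for label in sorted(per_member):
        stacked = np.vstack(per_member[label])
        contributing = (~np.isnan(stacked)).sum(axis=0)
        sums = np.nansum(stacked, axis=0)
        means = np.where(contributing > 0, sums / np.maximum(contributing, 1), np.nan)
        for chunk in range(n_chunks):
            rows.append(
                {
                    "group": label,
                    "chunk": chunk + 1,
                    "gc_mean": means[chunk],
                    "n_members": int(contributing[chunk]),
                }
            )
    return pd.DataFrame(rows)


def profile_slope(profile: pd.DataFrame, value_col: str = "gc_mean") -> float:
    """Least-squares slope of a chunk profile over the full 5'→3' extent.

    The slope is expressed per unit of relative position (chunk 1 → 0,
    chunk n → 1), so it is directly comparable with (gc_3' − gc_5')."""
    y = profile[value_col].to_numpy(dtype=float)
    x = (profile["chunk"].to_numpy(dtype=float) - 1) / max(len(y) - 1, 1)
    ok = ~np.isnan(y)
    if ok.sum() < 2:
        raise ValueError("need >= 2 non-empty chunks for a slope")
    res = stats.linregress(x[ok], y[ok])
    return float(res.slope)


def classify_localization(records) -> dict[str, str]:
    """Collapse free-text compartment annotations to nuclear / cytoplasmic /
    other per molecule.

    A molecule with at least one nuclear term and no cytoplasmic term is
    nuclear (and vice versa); conflicting or unmatched molecules fall into
    "other" and are excluded from two-group comparisons.
    """
    seen: dict[str, set[str]] = {}
    for rec in records:
        hits = seen.setdefault(rec.name, set())
        term = rec.compartment.strip().lower()
        if term in NUCLEAR_TERMS:
            hits.add("nuclear")
        elif term in CYTOPLASMIC_TERMS:
            hits.add("cytoplasmic")
    out = {}
    for name, hits in seen.items():
        if hits == {"nuclear"}:
            out[name] = "nuclear"
        elif hits == {"cytoplasmic"}:
            out[name] = "cytoplasmic"
        else:
            out[name] = "other"
    return out


def compare_gc_by_group(values_by_group: Mapping[str, Sequence[float]]) -> dict:
    """One-way analysis of variance across groups of GC values.

    Returns the F statistic and p-value; with more than two groups, pairwise
    follow-up p-values are Benjamini–Hochberg adjusted. For exactly two
    groups the raw ANOVA p is the reported p.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for k, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} has fewer than 2 observations")
    f, p = stats.f_oneway(*groups.values())
    result = {"F": float(f), "p": float(p), "groups": {k: len(v) for k, v in groups.items()}}
    if len(groups) > 2:
        labels = sorted(groups)
        raw = []
        pairs = []
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                fp, pp = stats.f_oneway(groups[a], groups[b])
                raw.append(pp)
                pairs.append((a, b))
        adj = _benjamini_hochberg(np.array(raw))
        result["pairwise"] = [
            {"a": a, "b": b, "p_raw": float(pr_), "p_adj": float(pa)}
            for (a, b), pr_, pa in zip(pairs, raw, adj)
        ]
    return result


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def length_summary(lengths: Sequence[float], detect_modes: bool = False, label: str = "") -> dict:
    """Mean/median/standard-error of a length sample, optionally with the
    locations of density modes (local maxima of a Gaussian KDE with
    Silverman bandwidth)."""
    arr = np.asarray(lengths, dtype=float)
    if len(arr) == 0:
        raise ValueError("empty length sample")
    out = {
        "group": label,
        "n": int(len(arr)),
        "mean": float(arr.mean()),
        "median": float(np.median(arr)),
        "sem": float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0,
    }
    if detect_modes:
        if len(arr) < 10:
            out["modes"] = []
        else:
            kde = stats.gaussian_kde(arr, bw_method="silverman")
            grid = np.linspace(arr.min(), arr.max(), 2048)
            dens = kde(grid)
            interior = np.where((dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:]))[0] + 1
            out["modes"] = [float(grid[i]) for i in interior]
    return out
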