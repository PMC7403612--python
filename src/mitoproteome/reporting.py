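"""Category-level summaries and cross-species ortholog-group counting.

Functional categories follow the 16-name custom vocabulary used for manual
annotation of organellar proteomes (roughly KEGG-pathway based); proteins
without an assigned function carry the reserved label ``"unknown"``.
Category-level enrichment is summarised by the geometric mean of the finite
Mt/Cp ratios (ratios are multiplicative), with members whose chloroplast
signal is zero tallied separately as "infinite".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

#: The closed category vocabulary (16 names); "unknown" is the reserved
#: out-of-vocabulary label.  Configurable via ``load_categories``.
FUNCTIONAL_CATEGORIES: tuple[str, ...] = (
    "core metabolic pathways",
    "ribosome, aminoacyl-tRNA biosynthesis and translation",
    "protein transport, folding, processing and degradation",
    "oxidative phosphorylation and electron transport",
    "RNA processing",
    "transcription",
    "DNA replication and repair",
    "amino acid metabolism",
    "fatty acid metabolism",
    "carbohydrate metabolism",
    "nucleotide metabolism",
    "Fe-S cluster biosynthesis",
    "sulfate assimilation",
    "membrane transport",
    "redox homeostasis and stress response",
    "signaling",
)

UNKNOWN_CATEGORY = "unknown"


class CategoryError(ValueError):
    """Raised on a category label outside the closed vocabulary."""


def load_categories(path) -> tuple[str, ...]:
    """Read a custom category vocabulary, one name per line."""
    with open(path) as fh:
        names = [line.strip() for line in fh if line.strip()]
    return tuple(names)


def percent_round(numerator: float, denominator: float) -> int:
    """Integer percent, rounding half away from zero (998/1786 -> 56)."""
    if denominator == 0:
        raise ZeroDivisionError("percent of empty set")
    x = 100.0 * numerator / denominator
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def log10_ratio_bin(log10_value: float | None, any_infinite: bool = False) -> str | None:
    """Bin a log10 Mt/Cp value: "0-1" (1-10x), "1-2" (10-100x), ">2", "<=0".

    ``None`` with ``any_infinite`` set yields "infinite" (all members had no
    chloroplast signal); ``None`` otherwise means the bin is undefined.
    """
    if log10_value is None:
        return "infinite" if any_infinite else None
    if log10_value <= 0:
        return "<=0"
    if log10_value <= 1:
        return "0-1"
    if log10_value <= 2:
        return "1-2"
    return ">2"


@dataclass(frozen=True)
class CategorySummary:
    category: str
    count: int
    n_infinite: int
    geometric_mean_ratio: float | None
    log10_bin: str | None


@dataclass(frozen=True)
class CrossSpeciesComparison:
    n_transcripts: int
    n_groups: int
    n_uncategorized: int


def category_summary(
    categories: Mapping[str, str],
    ratios: Mapping[str, float] | None = None,
    vocabulary: Iterable[str] = FUNCTIONAL_CATEGORIES,
) -> tuple[list[CategorySummary], int, int]:
    """Summarise the final proteome by functional category.

    ``categories`` maps protein id -> category label (closed vocabulary plus
    "unknown"); ``ratios`` maps protein id -> Mt/Cp ratio (``math.inf``
    allowed).  Returns the per-category summaries (vocabulary order, all
    categories included), the unknown-function count, and the rounded
    unknown-function percent of the whole proteome.
    """
    vocab = tuple(vocabulary)
    allowed = set(vocab) | {UNKNOWN_CATEGORY}
    bad = set(categories.values()) - allowed
    if bad:
        raise CategoryError(f"labels outside the closed vocabulary: {sorted(bad)}")
    ratios = ratios or {}

    summaries = []
    for cat in vocab:
        members = [pid for pid, c in categories.items() if c == cat]
        finite = [
            ratios[p]
            for p in members
            if p in ratios and math.isfinite(ratios[p]) and ratios[p] > 0
        ]
        n_inf = sum(1 for p in members if p in ratios and math.isinf(ratios[p]))
        if finite:
            log_g = sum(math.log10(r) for r in finite) / len(finite)
            geo = 10.0 ** log_g
            bin_label = log10_ratio_bin(log_g)
        else:
            geo = None
            bin_label = log10_ratio_bin(None, any_infinite=n_inf > 0)
        summaries.append(
            CategorySummary(cat, len(members), n_inf, geo, bin_label)
        )
    n_unknown = sum(1 for c in categories.values() if c == UNKNOWN_CATEGORY)
    pct = percent_round(n_unknown, len(categories)) if categories else 0
    return summaries, n_unknown, pct


def category_summary_table(summaries: list[CategorySummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "category": s.category,
                "count": s.count,
                "n_infinite": s.n_infinite,
                "geometric_mean_mt_cp": s.geometric_mean_ratio,
                "log10_bin": s.log10_bin if s.log10_bin is not None else "",
            }
            for s in summaries
        ]
    )


def cross_species_counts(
    orthogroups: pd.DataFrame,
    focal_column: str,
    other_column: str,
    focal_proteome: Iterable[str],
    focal_categories: Mapping[str, str] | None = None,
) -> CrossSpeciesComparison:
    """Count other-species transcripts orthologous to the focal proteome.

    ``orthogroups`` is an OrthoFinder-style table: one row per ortholog group
    with comma-separated gene lists in the per-species columns.  A transcript
    of the other species counts if its group contains at least one member of
    ``focal_proteome``; distinct such groups are counted as well.  When
    ``focal_categories`` is given, transcripts whose in-proteome co-members
    are all functionally uncategorized are tallied separately.
    """
    focal = set(focal_proteome)
    n_transcripts = 0
    n_uncat = 0
    groups = set()
    for idx, row in orthogroups.iterrows():
        focal_genes = _split(row[focal_column])
        other_genes = _split(row[other_column])
        shared = [g for g in focal_genes if g in focal]
        if not shared or not other_genes:
            continue
        groups.add(row["Orthogroup"] if "Orthogroup" in row.index else idx)
        n_transcripts += len(other_genes)
        if focal_categories is not None and all(
            focal_categories.get(g, UNKNOWN_CATEGORY) == UNKNOWN_CATEGORY
            for g in shared
        ):
            n_uncat += len(other_genes)
    return CrossSpeciesComparison(n_transcripts, len(groups), n_uncat)


def _split(cell) -> list[str]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return []
    return [g.strip() for g in str(cell).split(",") if g.strip()]
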