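"""Group-level quantification: enrichment ratios, volcano statistics, masses.

Per-sample group intensity is the sum of the intensities of the peptides
unique to the group (razor and redundant peptides never contribute).
Enrichment ratios compare the mean mitochondrial-fraction intensity with the
mean chloroplast-fraction (Mt/Cp) and whole-cell (Mt/WC) intensities; a group
is *enriched* when both ratios exceed 1.  A zero denominator with positive
numerator is the explicit INFINITE category, not a sentinel number.
Confidence bins follow the log10 Mt/Cp value: (0, 1] means a 1-10x greater
mitochondrial amount, >1 means more than 10x, infinite means no chloroplast
signal at all.

P-values are from Welch's unequal-variance two-sample t-test on log10
intensities, as in standard volcano-plot analyses of fraction enrichment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _pt_mass
from scipy import stats

from .inference import PeptideMatch, ProteinGroup
from .synthetic import validate_sequence

#: smallest representable positive double; returned when a zero-variance
#: comparison has unequal means (p approaches 0)
MIN_PVALUE = math.nextafter(0.0, 1.0)


class ConfidenceBin(str, Enum):
    INFINITE = "infinite"
    GT_ONE = ">1.0"
    ZERO_TO_ONE = "0.0-1.0"
    NOT_ENRICHED = "not_enriched"


class IntensityError(ValueError):
    """Raised on negative intensities."""


@dataclass
class EnrichmentResult:
    """Per-group fraction intensities, enrichment ratios and confidence bin."""

    group_id: str
    mt: tuple[float, ...]
    cp: tuple[float, ...]
    wc: tuple[float, ...]
    ratio_mt_cp: float
    ratio_mt_wc: float
    log10_mt_cp: float
    enriched: bool
    confidence_bin: ConfidenceBin
    p_value: float | None = None


def unique_peptides_of_group(
    group: ProteinGroup, matches: Sequence[PeptideMatch]
) -> list[PeptideMatch]:
    """Peptides mapping only to members of this group."""
    members = set(group.members)
    return [m for m in matches if m.proteins <= members]


def aggregate_group_intensity(
    group: ProteinGroup, matches: Sequence[PeptideMatch]
) -> tuple[dict[str, float], bool]:
    """Sum unique-peptide intensities per sample.

    Returns ``(intensities, quantifiable)``; a group without unique peptides
    is flagged unquantifiable (empty intensities, flag False) rather than
    raising.  Missing observations contribute 0.
    """
    unique = unique_peptides_of_group(group, matches)
    if not unique:
        return {}, False
    totals: dict[str, float] = {}
    for m in unique:
        for sample, value in m.intensities.items():
            totals[sample] = totals.get(sample, 0.0) + value
    return totals, True


def _ratio(numerator: float, denominator: float) -> float:
    if denominator > 0:
        return numerator / denominator
    if numerator > 0:
        return math.inf
    return math.nan


def _exceeds_one(ratio: float) -> bool:
    return math.isinf(ratio) or (not math.isnan(ratio) and ratio > 1.0)


def enrichment_ratios(
    mt: Sequence[float],
    cp: Sequence[float],
    wc: Sequence[float],
    group_id: str = "",
) -> EnrichmentResult:
    """Compute Mt/Cp and Mt/WC enrichment from per-replicate intensities.

    Ratios use replicate means with no pseudocount.  A group is enriched iff
    both ratios exceed 1 (INFINITE counts as greater than 1).  Requires at
    least one mitochondrial replicate; negative intensities are rejected.
    """
    for name, values in (("mt", mt), ("cp", cp), ("wc", wc)):
        if any(v < 0 for v in values):
            raise IntensityError(f"negative intensity in {name} replicates")
    if len(mt) == 0:
        raise IntensityError("need at least one mitochondrial replicate")
    mean_mt = float(np.mean(mt))
    mean_cp = float(np.mean(cp)) if len(cp) else 0.0
    mean_wc = float(np.mean(wc)) if len(wc) else 0.0
    r_cp = _ratio(mean_mt, mean_cp)
    r_wc = _ratio(mean_mt, mean_wc)
    if math.isnan(r_cp):
        log_cp = math.nan
    elif r_cp == 0:
        log_cp = -math.inf
    else:
        log_cp = math.log10(r_cp)  # +inf maps to +inf
    enriched = _exceeds_one(r_cp) and _exceeds_one(r_wc)
    if not enriched:
        bin_ = ConfidenceBin.NOT_ENRICHED
    elif math.isinf(r_cp):
        bin_ = ConfidenceBin.INFINITE
    elif log_cp > 1.0:
        bin_ = ConfidenceBin.GT_ONE
    else:  # enriched implies 0 < log10 <= 1 here (interval closed on the right)
        bin_ = ConfidenceBin.ZERO_TO_ONE
    return EnrichmentResult(
        group_id=group_id,
        mt=tuple(mt),
        cp=tuple(cp),
        wc=tuple(wc),
        ratio_mt_cp=r_cp,
        ratio_mt_wc=r_wc,
        log10_mt_cp=log_cp,
        enriched=enriched,
        confidence_bin=bin_,
    )


def volcano_stats(
    mt_log: Sequence[float], other_log: Sequence[float]
) -> tuple[float, float | None]:
    """Welch two-sample t-test on log-intensities.

    Returns ``(difference of means, two-sided p)``.  With fewer than two
    replicates on either side the p-value is undefined (None).  Zero variance
    on both sides yields p = 1 for equal means and the smallest representable
    positive double for unequal means.
    """
    a = np.asarray(mt_log, dtype=float)
    b = np.asarray(other_log, dtype=float)
    lfc = float(a.mean() - b.mean()) if a.size and b.size else math.nan
    if a.size < 2 or b.size < 2:
        return lfc, None
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        return lfc, 1.0 if a.mean() == b.mean() else MIN_PVALUE
    p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return lfc, p


def molecular_weight(sequence: str) -> float:
    """Average (not monoisotopic) molecular mass of the peptide chain in kDa."""
    validate_sequence(sequence)
    if not sequence:
        raise ValueError("empty sequence")
    return _pt_mass.calculate_mass(sequence=sequence, average=True) / 1000.0


def split_sample(sample: str) -> tuple[str, int]:
    fraction, _, replicate = sample.rpartition("_")
    return fraction, int(replicate)


def replicate_vector(
    intensities: Mapping[str, float], fraction: str, n_replicates: int
) -> list[float]:
    """Per-replicate intensities for one fraction; absent observations are 0."""
    return [
        float(intensities.get(f"{fraction}_{rep}", 0.0))
        for rep in range(1, n_replicates + 1)
    ]


def quantify_groups(
    groups: Sequence[ProteinGroup],
    matches: Sequence[PeptideMatch],
    n_replicates: int = 3,
    sequences: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Full quantification table for a list of protein groups.

    Columns: ``group_id``, per-sample LFQ intensities
    (``lfq_{fraction}_{replicate}``), ratios, log10 Mt/Cp, Welch p-value
    (Mt vs Cp on log10 intensities of replicates observed on both sides),
    confidence bin, quantifiable flag, and molecular weight in kDa when the
    leader sequence is supplied.
    """
    rows = []
    for g in groups:
        intensities, quantifiable = aggregate_group_intensity(g, matches)
        row: dict[str, object] = {"group_id": g.group_id, "quantifiable": quantifiable}
        for fraction in ("mt", "cp", "wc"):
            for rep in range(1, n_replicates + 1):
                row[f"lfq_{fraction}_{rep}"] = float(
                    intensities.get(f"{fraction}_{rep}", 0.0)
                )
        if quantifiable:
            mt = replicate_vector(intensities, "mt", n_replicates)
            cp = replicate_vector(intensities, "cp", n_replicates)
            wc = replicate_vector(intensities, "wc", n_replicates)
            res = enrichment_ratios(mt, cp, wc, group_id=g.group_id)
            mt_pos = [math.log10(v) for v in mt if v > 0]
            cp_pos = [math.log10(v) for v in cp if v > 0]
            _, p = volcano_stats(mt_pos, cp_pos)
            row.update(
                ratio_mt_cp=res.ratio_mt_cp,
                ratio_mt_wc=res.ratio_mt_wc,
                log10_mt_cp=res.log10_mt_cp,
                enriched=res.enriched,
                confidence_bin=res.confidence_bin.value,
                p_value=p,
            )
        else:
            row.update(
                ratio_mt_cp=math.nan,
                ratio_mt_wc=math.nan,
                log10_mt_cp=math.nan,
                enriched=False,
                confidence_bin=ConfidenceBin.NOT_ENRICHED.value,
                p_value=None,
            )
        if sequences and g.leader in sequences:
            row["mw_kda"] = round(molecular_weight(sequences[g.leader]), 2)
        rows.append(row)
    return pd.DataFrame(rows)
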