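"""Strategy union, curation and assembly of the verified proteome.

A candidate protein enters the proteome if at least one of the three
strategies supports it (ortholog in a reference mitoproteome, mitochondrial
enrichment, targeting consensus).  Curation then

* removes union members whose functional annotation shows a clear
  non-mitochondrial role AND that lack an ortholog in any reference
  mitoproteome (both conditions required), and
* reintegrates candidates that failed all strategies — in practice failed
  enrichment — when the in-silico predicted mitoproteome contains them AND
  their functional annotation is clearly mitochondrial.

The final proteome is ACCEPTED ∪ REINTEGRATED, and the summary always
satisfies ``final = union − removed + reintegrated``.  Union (≥1 strategy) is
the primary rule; a strict 2-of-3 majority mode is available for sensitivity
analysis.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .evidence import EvidenceProfile

STRATEGIES = ("ORTHOLOG", "ENRICHED", "TARGETING")


class Status(Enum):
    ACCEPTED = "accepted"
    REMOVED_CONTAMINANT = "removed_contaminant"
    REINTEGRATED = "reintegrated"
    REJECTED = "rejected"


class IntegrationError(ValueError):
    pass


class ConsistencyError(RuntimeError):
    """Raised when the summary invariant final = union - removed + reintegrated fails."""


@dataclass(frozen=True)
class MembershipDecision:
    identifier: str
    strategies: frozenset[str]
    status: Status
    rationale: str


@dataclass(frozen=True)
class ProteomeSummary:
    candidate_count: int
    n_ortholog: int
    n_enriched: int
    n_targeting: int
    union_count: int
    removed_count: int
    reintegrated_count: int
    final_count: int
    chloroplast_greater_retained: int

    def as_dict(self) -> dict:
        return asdict(self)


def _profile_strategies(profile: EvidenceProfile) -> frozenset[str]:
    flags = set()
    if profile.ortholog_member:
        flags.add("ORTHOLOG")
    if profile.enriched:
        flags.add("ENRICHED")
    if profile.targeting_consensus:
        flags.add("TARGETING")
    return frozenset(flags)


def strategy_union(
    profiles: Sequence[EvidenceProfile], majority: bool = False
) -> dict[str, frozenset[str]]:
    """Accepted set with per-protein strategy flags.

    With ``majority=False`` (the primary rule) a protein is accepted when at
    least one strategy supports it; with ``majority=True`` at least two of
    the three strategies are required.
    """
    seen: set[str] = set()
    accepted: dict[str, frozenset[str]] = {}
    for p in profiles:
        if p.protein_id in seen:
            raise IntegrationError(f"duplicate identifier {p.protein_id!r}")
        seen.add(p.protein_id)
        flags = _profile_strategies(p)
        threshold = 2 if majority else 1
        if len(flags) >= threshold:
            accepted[p.protein_id] = flags
    return accepted


def curate(
    union: Mapping[str, frozenset[str]], profiles: Sequence[EvidenceProfile]
) -> list[MembershipDecision]:
    """Apply contaminant removal and reintegration to the candidate list.

    Every profile receives exactly one decision with a rationale string;
    running curate on its own output decisions is stable (the rules depend
    only on the profiles and the union, both unchanged).
    """
    decisions = []
    for p in sorted(profiles, key=lambda q: q.protein_id):
        flags = union.get(p.protein_id, frozenset())
        if p.protein_id in union:
            if p.annotation_clear_nonmito and not p.ortholog_member:
                decisions.append(
                    MembershipDecision(
                        p.protein_id,
                        flags,
                        Status.REMOVED_CONTAMINANT,
                        "clear non-mitochondrial annotation and no ortholog "
                        "in any reference mitoproteome",
                    )
                )
            else:
                supported = ", ".join(sorted(flags))
                decisions.append(
                    MembershipDecision(
                        p.protein_id,
                        flags,
                        Status.ACCEPTED,
                        f"supported by: {supported}",
                    )
                )
        else:
            if p.predicted_mito and p.annotation_mito_function:
                decisions.append(
                    MembershipDecision(
                        p.protein_id,
                        frozenset(),
                        Status.REINTEGRATED,
                        "failed enrichment but present in the predicted "
                        "mitoproteome with mitochondrial functional annotation",
                    )
                )
            else:
                decisions.append(
                    MembershipDecision(
                        p.protein_id,
                        frozenset(),
                        Status.REJECTED,
                        "no supporting strategy",
                    )
                )
    return decisions


def assemble(
    decisions: Sequence[MembershipDecision],
    profiles: Sequence[EvidenceProfile] | None = None,
) -> tuple[list[str], ProteomeSummary]:
    """Final proteome (sorted identifiers) plus the bookkeeping summary.

    Verifies ``final = union − removed + reintegrated``; a violation raises
    :class:`ConsistencyError`.  When profiles are given, members with greater
    chloroplast than mitochondrial enrichment (Mt/Cp < 1) that were retained
    through orthology or targeting are counted.
    """
    final = sorted(
        d.identifier
        for d in decisions
        if d.status in (Status.ACCEPTED, Status.REINTEGRATED)
    )
    union_count = sum(
        1
        for d in decisions
        if d.status in (Status.ACCEPTED, Status.REMOVED_CONTAMINANT)
    )
    removed = sum(1 for d in decisions if d.status is Status.REMOVED_CONTAMINANT)
    reintegrated = sum(1 for d in decisions if d.status is Status.REINTEGRATED)
    if len(final) != union_count - removed + reintegrated:
        raise ConsistencyError(
            f"final={len(final)} != union({union_count}) - removed({removed})"
            f" + reintegrated({reintegrated})"
        )
    cp_greater = 0
    if profiles is not None:
        final_set = set(final)
        for p in profiles:
            if (
                p.protein_id in final_set
                and p.ratio_mt_cp is not None
                and p.ratio_mt_cp < 1.0
                and (p.ortholog_member or p.targeting_consensus)
            ):
                cp_greater += 1
    summary = ProteomeSummary(
        candidate_count=len(decisions),
        n_ortholog=sum(1 for d in decisions if "ORTHOLOG" in d.strategies),
        n_enriched=sum(1 for d in decisions if "ENRICHED" in d.strategies),
        n_targeting=sum(1 for d in decisions if "TARGETING" in d.strategies),
        union_count=union_count,
        removed_count=removed,
        reintegrated_count=reintegrated,
        final_count=len(final),
        chloroplast_greater_retained=cp_greater,
    )
    return final, summary


def expected_total(
    experimental: Iterable[str], predicted: Iterable[str]
) -> tuple[int, int]:
    """Combined (experimental ∪ in-silico predicted) proteome size and overlap."""
    exp = set(experimental)
    pred = set(predicted)
    return len(exp | pred), len(exp & pred)


def decisions_table(decisions: Sequence[MembershipDecision]) -> pd.DataFrame:
    final = {
        d.identifier
        for d in decisions
        if d.status in (Status.ACCEPTED, Status.REINTEGRATED)
    }
    return pd.DataFrame(
        [
            {
                "id": d.identifier,
                "strategies": ";".join(sorted(d.strategies)),
                "status": d.status.value,
                "rationale": d.rationale,
                "final_member": d.identifier in final,
            }
            for d in decisions
        ]
    )


def write_summary_json(summary: ProteomeSummary, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary.as_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
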