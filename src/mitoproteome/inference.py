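"""Protein inference: peptide canonicalisation, grouping, unique counts, FDR.

Peptides are canonicalised by collapsing isoleucine onto leucine (the two are
isobaric and indistinguishable by standard MS) and dropping peptides shorter
than six residues.  Proteins whose identified peptide set is contained in the
peptide set of another protein are merged into that protein's group
(subsumption through the leading protein: B ⊆ A and C ⊆ A puts A, B, C in one
group even when B and C are incomparable).  A peptide is *unique* to a group
if it maps only to members of that group; peptides shared across groups are
razor peptides and excluded from unique counts and from quantification.

Identification confidence is controlled by the classical target-decoy
estimator: the accepted set is the largest score prefix whose
decoys/targets ratio does not exceed the requested FDR level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .synthetic import SequenceError, validate_sequence

DECOY_PREFIX = "REV__"
CANONICAL_IL = "L"


def collapse_and_filter(
    peptides: Iterable[str], min_length: int = 6
) -> list[str]:
    """Collapse I onto L and drop peptides shorter than ``min_length``.

    Order-preserving and idempotent.  Raises :class:`SequenceError` on
    residues outside the amino-acid alphabet.
    """
    out = []
    for pep in peptides:
        validate_sequence(pep)
        canonical = pep.replace("I", CANONICAL_IL)
        if len(canonical) >= min_length:
            out.append(canonical)
    return out


@dataclass
class PeptideMatch:
    """A canonical peptide with its matched proteins and per-sample intensities."""

    peptide: str
    proteins: frozenset[str]
    intensities: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.proteins:
            raise ValueError(f"peptide {self.peptide!r} matches no protein")


@dataclass
class ProteinGroup:
    """Group of proteins indistinguishable by peptide-set subsumption.

    ``leader`` owns the largest peptide set (ties broken lexicographically by
    identifier); every member's peptide set is a subset of the leader's.
    """

    leader: str
    members: tuple[str, ...]
    peptides: frozenset[str]
    unique_peptides: int = 0
    razor_peptides: int = 0

    @property
    def group_id(self) -> str:
        return self.leader


def build_matches(
    observations: pd.DataFrame, min_length: int = 6
) -> list[PeptideMatch]:
    """Collapse a peptide-observation table into per-peptide matches.

    Input columns: ``peptide, protein_ids, fraction, replicate, intensity``.
    Sample keys are ``"{fraction}_{replicate}"``; intensities for the same
    (peptide, sample) are summed.  Output is sorted by peptide.
    """
    matches: dict[str, PeptideMatch] = {}
    for row in observations.itertuples(index=False):
        validate_sequence(row.peptide)
        canonical = row.peptide.replace("I", CANONICAL_IL)
        if len(canonical) < min_length:
            continue
        proteins = frozenset(str(row.protein_ids).split(";"))
        sample = f"{row.fraction}_{row.replicate}"
        m = matches.get(canonical)
        if m is None:
            matches[canonical] = PeptideMatch(canonical, proteins, {sample: float(row.intensity)})
        else:
            m.proteins = m.proteins | proteins
            m.intensities[sample] = m.intensities.get(sample, 0.0) + float(row.intensity)
    return [matches[k] for k in sorted(matches)]


def group_proteins(matches: Sequence[PeptideMatch]) -> list[ProteinGroup]:
    """Form protein groups by peptide-set subsumption.

    A protein joins the group of the protein with the largest peptide set
    containing its own (ties by lexicographic identifier); proteins with
    identical sets are co-members.  Every protein lands in exactly one group;
    output groups are ordered by leader identifier.
    """
    peptide_sets: dict[str, set[str]] = {}
    for m in matches:
        for prot in m.proteins:
            peptide_sets.setdefault(prot, set()).add(m.peptide)
    if not peptide_sets:
        return []

    order = sorted(peptide_sets, key=lambda p: (-len(peptide_sets[p]), p))
    groups: list[dict] = []
    by_peptide: dict[str, list[int]] = {}
    for prot in order:
        pset = peptide_sets[prot]
        anchor = next(iter(pset))
        assigned = None
        for gi in by_peptide.get(anchor, ()):
            if pset <= groups[gi]["peptides"]:
                assigned = gi
                break
        if assigned is None:
            gi = len(groups)
            groups.append({"leader": prot, "peptides": pset, "members": [prot]})
            for pep in pset:
                by_peptide.setdefault(pep, []).append(gi)
        else:
            groups[assigned]["members"].append(prot)

    out = [
        ProteinGroup(
            leader=g["leader"],
            members=tuple(sorted(g["members"])),
            peptides=frozenset(g["peptides"]),
        )
        for g in groups
    ]
    out.sort(key=lambda g: g.leader)
    return out


def count_unique_peptides(
    groups: Sequence[ProteinGroup], matches: Sequence[PeptideMatch]
) -> tuple[dict[str, int], dict[str, int]]:
    """Count unique peptides per group; razor peptides count for no group.

    Returns ``(counts, partition)`` where ``counts`` maps group id (leader) to
    its unique-peptide count and ``partition`` gives the group tally with
    more than one unique peptide, exactly one, and none.  Groups are updated
    in place with their unique and razor counts.
    """
    leader_of: dict[str, str] = {}
    for g in groups:
        for member in g.members:
            leader_of[member] = g.leader
    counts = {g.leader: 0 for g in groups}
    razor = {g.leader: 0 for g in groups}
    for m in matches:
        touched = {leader_of[p] for p in m.proteins if p in leader_of}
        if len(touched) == 1:
            counts[next(iter(touched))] += 1
        else:
            for gid in touched:
                razor[gid] += 1
    for g in groups:
        g.unique_peptides = counts[g.leader]
        g.razor_peptides = razor[g.leader]
    partition = {
        ">1": sum(1 for c in counts.values() if c > 1),
        "1": sum(1 for c in counts.values() if c == 1),
        "0": sum(1 for c in counts.values() if c == 0),
    }
    return counts, partition


@dataclass(frozen=True)
class FdrResult:
    """Score threshold and acceptance counts of a target-decoy filter."""

    threshold: float
    n_targets: int
    n_decoys: int
    fdr: float


def decoy_fdr_threshold(
    scored: Iterable[tuple[float, bool]], level: float = 0.01
) -> FdrResult:
    """Most permissive score threshold whose decoys/targets ratio ≤ level.

    ``scored`` is an iterable of ``(score, is_decoy)``.  Acceptance means
    ``score >= threshold``; ties share the fate of their score.  The FDR of a
    candidate set is ``decoys / targets`` (the count of reversed-database
    hits over target hits).  If no threshold admits at least one target at
    the requested level, the acceptance is empty with FDR defined as 0.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    entries = sorted(scored, key=lambda e: -e[0])
    best: FdrResult | None = None
    targets = decoys = 0
    i = 0
    n = len(entries)
    while i < n:
        score = entries[i][0]
        while i < n and entries[i][0] == score:
            if entries[i][1]:
                decoys += 1
            else:
                targets += 1
            i += 1
        if targets > 0 and decoys / targets <= level:
            # keep the prefix admitting the most targets; a lower threshold
            # that only adds decoys is never preferred
            if best is None or targets > best.n_targets:
                best = FdrResult(score, targets, decoys, decoys / targets)
    if best is None:
        return FdrResult(math.inf, 0, 0, 0.0)
    return best


def apply_fdr(
    scored: Sequence[tuple[float, bool]], level: float = 0.01
) -> tuple[FdrResult, list[tuple[float, bool]]]:
    """Return the threshold plus the accepted entries sorted by score descending."""
    result = decoy_fdr_threshold(scored, level)
    accepted = sorted(
        (e for e in scored if e[0] >= result.threshold), key=lambda e: -e[0]
    )
    return result, accepted


# ---------------------------------------------------------------------------
# MaxQuant-flavoured tables


def is_decoy_id(protein_id: str) -> bool:
    return protein_id.startswith(DECOY_PREFIX)


def sample_columns(matches: Sequence[PeptideMatch]) -> list[str]:
    samples: set[str] = set()
    for m in matches:
        samples.update(m.intensities)
    return sorted(samples)


def write_peptides_table(
    matches: Sequence[PeptideMatch], path
) -> pd.DataFrame:
    """Write a peptides table (Sequence, Proteins, Intensity <sample> ...)."""
    samples = sample_columns(matches)
    rows = []
    for m in matches:
        row = {"Sequence": m.peptide, "Proteins": ";".join(sorted(m.proteins))}
        for s in samples:
            row[f"Intensity {s}"] = m.intensities.get(s, 0.0)
        rows.append(row)
    table = pd.DataFrame(rows, columns=["Sequence", "Proteins"] + [f"Intensity {s}" for s in samples])
    table.to_csv(path, sep="\t", index=False)
    return table


def read_peptides_table(path) -> list[PeptideMatch]:
    table = pd.read_csv(path, sep="\t")
    required = {"Sequence", "Proteins"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"peptides table missing columns: {sorted(missing)}")
    intensity_cols = [c for c in table.columns if c.startswith("Intensity ")]
    matches = []
    for _, row in table.iterrows():
        intensities = {
            c[len("Intensity "):]: float(row[c]) for c in intensity_cols
        }
        intensities = {k: v for k, v in intensities.items() if v != 0.0}
        matches.append(
            PeptideMatch(
                peptide=str(row["Sequence"]),
                proteins=frozenset(str(row["Proteins"]).split(";")),
                intensities=intensities,
            )
        )
    return matches


def write_protein_groups_table(
    groups: Sequence[ProteinGroup],
    path,
    lfq: Mapping[str, Mapping[str, float]] | None = None,
) -> pd.DataFrame:
    """Write a proteinGroups table; ``lfq`` maps group id -> sample -> intensity."""
    lfq = lfq or {}
    samples = sorted({s for per in lfq.values() for s in per})
    rows = []
    for g in groups:
        row = {
            "Protein IDs": ";".join(g.members),
            "Majority protein IDs": g.leader,
            "Unique peptides": g.unique_peptides,
            "Razor peptides": g.razor_peptides,
        }
        for s in samples:
            row[f"LFQ intensity {s}"] = lfq.get(g.leader, {}).get(s, 0.0)
        rows.append(row)
    cols = ["Protein IDs", "Majority protein IDs", "Unique peptides", "Razor peptides"]
    table = pd.DataFrame(rows, columns=cols + [f"LFQ intensity {s}" for s in samples])
    table.to_csv(path, sep="\t", index=False)
    return table


def read_protein_groups_table(path) -> list[ProteinGroup]:
    table = pd.read_csv(path, sep="\t")
    required = {"Protein IDs", "Majority protein IDs", "Unique peptides"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"proteinGroups table missing columns: {sorted(missing)}")
    groups = []
    for row in table.iterrows():
        r = row[1]
        groups.append(
            ProteinGroup(
                leader=str(r["Majority protein IDs"]),
                members=tuple(str(r["Protein IDs"]).split(";")),
                peptides=frozenset(),
                unique_peptides=int(r["Unique peptides"]),
                razor_peptides=int(r.get("Razor peptides", 0)),
            )
        )
    return groups
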