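"""Membership evidence layers: orthology, targeting consensus, homology hits.

Three strategies support mitochondrial membership of a candidate protein:

* orthology — an ortholog in at least one reference mitoproteome;
* enrichment — Mt/Cp and Mt/WC ratios both above 1 (from quantification);
* targeting consensus — a majority of the surveyed transcriptome variants
  predict mitochondrial import for an ORF that starts with methionine.

The majority denominator is the number of transcriptomes surveyed (3), not
the number that contain the transcript: a transcript present in one of three
variants cannot reach two votes and fails, which is the conservative reading.
Homology searches against the transcriptome are filtered at E ≤ 1e-3 (BLAST,
boundary inclusive) and E ≤ 1e-3 with bias < 1 (HMM, bias boundary strict).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

BLAST_EVALUE_MAX = 1e-3
HMM_EVALUE_MAX = 1e-3
HMM_BIAS_MAX = 1.0  # strict: bias must be lower than 1
N_TRANSCRIPTOMES = 3
MITO_LOCATION = "M"


class EvidenceInputError(ValueError):
    pass


@dataclass
class EvidenceProfile:
    """Per-protein evidence flags feeding the membership decision."""

    protein_id: str
    ortholog_member: bool = False
    ortholog_species: tuple[str, ...] = ()
    enriched: bool = False
    targeting_consensus: bool = False
    targeting_votes: int = 0
    predicted_mito: bool = False
    annotation_mito_function: bool = False
    annotation_clear_nonmito: bool = False
    ratio_mt_cp: float | None = None


@dataclass(frozen=True)
class HomologyHit:
    query: str
    target: str
    e_value: float
    tool: str  # "blast" or "hmm"
    bias: float | None = None

    def __post_init__(self) -> None:
        if self.e_value <= 0:
            raise EvidenceInputError("e_value must be positive")
        if self.tool not in ("blast", "hmm"):
            raise EvidenceInputError(f"unknown tool {self.tool!r}")


class PresenceStatus(Enum):
    PROTEOMIC = "proteomic"
    IN_SILICO = "in_silico"
    ABSENT = "absent"
    PUTATIVE = "putative"


def ortholog_membership(
    protein_id: str,
    ortholog_table: pd.DataFrame,
    reference_species: Sequence[str],
) -> tuple[bool, list[str]]:
    """Member iff an ortholog exists in at least one reference mitoproteome."""
    known = set(reference_species)
    species_in_table = set(ortholog_table["reference_species"].unique())
    unknown = species_in_table - known
    if unknown:
        raise EvidenceInputError(
            f"unknown reference species in ortholog table: {sorted(unknown)}"
        )
    hits = ortholog_table.loc[
        ortholog_table["protein_id"] == protein_id, "reference_species"
    ]
    species = sorted(set(hits))
    return bool(species), species


def targeting_consensus(
    predictions: Sequence[tuple[str, bool]],
    n_transcriptomes: int = N_TRANSCRIPTOMES,
) -> tuple[bool, int]:
    """Majority vote for mitochondrial targeting across transcriptome variants.

    Each prediction is ``(location, start_met)``; a prediction votes only if
    the ORF starts with methionine and the predicted location is
    mitochondrial.  Consensus requires strictly more than half of all
    surveyed transcriptomes (2 of 3), absent transcripts included in the
    denominator.
    """
    if len(predictions) > n_transcriptomes:
        raise EvidenceInputError("more predictions than surveyed transcriptomes")
    votes = sum(
        1 for loc, start_met in predictions if start_met and loc == MITO_LOCATION
    )
    return votes > n_transcriptomes / 2, votes


def filter_homology_hits(hits: Iterable[HomologyHit]) -> list[HomologyHit]:
    """Keep BLAST hits with E ≤ 1e-3 and HMM hits with E ≤ 1e-3 and bias < 1."""
    accepted = []
    for hit in hits:
        if hit.tool == "blast":
            if hit.e_value <= BLAST_EVALUE_MAX:
                accepted.append(hit)
        else:
            if hit.bias is None:
                raise EvidenceInputError(
                    f"hmm hit {hit.query}->{hit.target} lacks a bias score"
                )
            if hit.e_value <= HMM_EVALUE_MAX and hit.bias < HMM_BIAS_MAX:
                accepted.append(hit)
    return accepted


def presence_status(
    in_proteome: bool, in_transcriptome: bool, weak_homology_only: bool = False
) -> PresenceStatus:
    """Four-way pathway-component call.

    Proteomically confirmed entities with only weak homology support are
    "putative"; transcriptome-only entities are "in silico"; the rest are
    absent.
    """
    if in_proteome:
        return PresenceStatus.PUTATIVE if weak_homology_only else PresenceStatus.PROTEOMIC
    if in_transcriptome:
        return PresenceStatus.IN_SILICO
    return PresenceStatus.ABSENT


def consensus_from_tables(
    targeting_tables: Mapping[str, pd.DataFrame],
    protein_ids: Iterable[str],
    n_transcriptomes: int = N_TRANSCRIPTOMES,
) -> dict[str, tuple[bool, int]]:
    """Vectorised targeting consensus for many proteins over variant tables."""
    per_protein: dict[str, list[tuple[str, bool]]] = {p: [] for p in protein_ids}
    for table in targeting_tables.values():
        for row in table.itertuples(index=False):
            entry = per_protein.get(str(row.name))
            if entry is not None:
                entry.append((str(row.loc), bool(row.start_met)))
    return {
        pid: targeting_consensus(preds, n_transcriptomes)
        for pid, preds in per_protein.items()
    }


def build_profiles(
    candidates: Iterable[str],
    ortholog_table: pd.DataFrame,
    reference_species: Sequence[str],
    targeting_tables: Mapping[str, pd.DataFrame],
    enrichment: Mapping[str, tuple[bool, float]],
    annotations: pd.DataFrame,
) -> list[EvidenceProfile]:
    """Assemble per-protein evidence profiles for the candidate list.

    ``enrichment`` maps protein id -> (enriched flag, Mt/Cp ratio) from its
    protein group; ``annotations`` carries the input columns
    ``protein_id, predicted_mito, annotation_mito_function,
    is_contaminant_annotation`` (annotation flags are inputs to curation, not
    computed here).
    """
    candidates = sorted(set(candidates))
    known = set(reference_species)
    bad = set(ortholog_table["reference_species"].unique()) - known
    if bad:
        raise EvidenceInputError(
            f"unknown reference species in ortholog table: {sorted(bad)}"
        )
    ortho_map: dict[str, list[str]] = {}
    for row in ortholog_table.itertuples(index=False):
        ortho_map.setdefault(str(row.protein_id), []).append(str(row.reference_species))
    consensus = consensus_from_tables(targeting_tables, candidates)
    ann = annotations.set_index("protein_id")

    profiles = []
    for pid in candidates:
        species = sorted(set(ortho_map.get(pid, [])))
        cons, votes = consensus.get(pid, (False, 0))
        enr, ratio = enrichment.get(pid, (False, None))
        a = ann.loc[pid] if pid in ann.index else None
        profiles.append(
            EvidenceProfile(
                protein_id=pid,
                ortholog_member=bool(species),
                ortholog_species=tuple(species),
                enriched=bool(enr),
                targeting_consensus=cons,
                targeting_votes=votes,
                predicted_mito=bool(a["predicted_mito"]) if a is not None else False,
                annotation_mito_function=(
                    bool(a["annotation_mito_function"]) if a is not None else False
                ),
                annotation_clear_nonmito=(
                    bool(a["is_contaminant_annotation"]) if a is not None else False
                ),
                ratio_mt_cp=ratio,
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# readers for external search-tool outputs


def read_blast_tabular(path) -> list[HomologyHit]:
    """Read BLAST outfmt-6-like tabular output (qseqid sseqid ... evalue bitscore)."""
    hits = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise EvidenceInputError("blast tabular line has fewer than 12 fields")
            hits.append(
                HomologyHit(
                    query=fields[0],
                    target=fields[1],
                    e_value=float(fields[10]),
                    tool="blast",
                )
            )
    return hits


def read_hmmer_tblout(path) -> list[HomologyHit]:
    """Read HMMER tblout-like output (target, query, full-seq E-value, bias)."""
    hits = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise EvidenceInputError("hmmer tblout line has fewer than 6 fields")
            hits.append(
                HomologyHit(
                    query=fields[2],
                    target=fields[0],
                    e_value=float(fields[4]),
                    bias=float(fields[5]),
                    tool="hmm",
                )
            )
    return hits


def read_targetp(path) -> pd.DataFrame:
    """Read a TargetP-1.1-like TSV (name, loc, RC, start_met)."""
    table = pd.read_csv(path, sep="\t")
    missing = {"name", "loc", "RC", "start_met"} - set(table.columns)
    if missing:
        raise EvidenceInputError(f"targeting table missing columns: {sorted(missing)}")
    table["start_met"] = table["start_met"].astype(bool)
    return table


def read_ortholog_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = {"protein_id", "reference_species", "reference_protein"} - set(
        table.columns
    )
    if missing:
        raise EvidenceInputError(f"ortholog table missing columns: {sorted(missing)}")
    return table


def read_orthogroups(path) -> pd.DataFrame:
    """Read an OrthoFinder Orthogroups.tsv-like table (Orthogroup + species columns)."""
    table = pd.read_csv(path, sep="\t")
    if "Orthogroup" not in table.columns:
        raise EvidenceInputError("orthogroups table missing 'Orthogroup' column")
    return table
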