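"""Synthetic ground truth and input tables for organellar fractionation proteomics.

This module emulates the data a sucrose-gradient fractionation / LC-MS-MS
experiment on a photosynthetic protist produces: a proteome with known
subcellular localizations, per-fraction label-free peptide observations
(mitochondrial, chloroplast, whole-cell; replicated), TargetP-style
localization predictions for three transcriptome variants with 5'-truncation,
ortholog tables against a panel of reference mitoproteomes, and target/decoy
identification scores.  Every downstream module of the package can therefore
be exercised without any external download.

The intensity model is multiplicative: a protein's observed peptide intensity
in fraction ``F`` is ``base * effect(protein, F) * 10**eps`` with
``eps ~ Normal(0, intensity_log_sd)``.  Residents of an organellar fraction
(mitochondrial proteins in the mitochondrial fraction, chloroplast proteins in
the chloroplast fraction, dually localized proteins in both) carry
``effect = enrichment_fold``; every other protein is present at the base level
(``effect = 1``), so at zero noise the Mt/Cp ratio of a mitochondrial protein
equals the configured fold exactly.  The whole-cell fraction is an
abundance-weighted mixture of the compartments with weights equal to the
localization proportions.  Annotated contaminants leak into the mitochondrial
fraction at ``contaminant_leak * enrichment_fold`` instead of 1, placing them
just below the enrichment boundary so that curation has real work to do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reporting import FUNCTIONAL_CATEGORIES

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
LOCALIZATIONS = ("mito", "chloroplast", "cytosol", "dual")
#: localizations whose proteins genuinely reside in the mitochondrion
TRUE_MITO = frozenset({"mito", "dual"})
FRACTIONS = ("mt", "cp", "wc")
TRANSCRIPTOME_VARIANTS = ("v1", "v2", "v3")
REFERENCE_SPECIES = ("A_thaliana", "M_musculus", "S_cerevisiae", "T_brucei")

TRUTH_COLUMNS = [
    "protein_id",
    "sequence",
    "localization",
    "has_targeting_signal",
    "is_contaminant_annotation",
    "category",
    "annotation_mito_function",
    "predicted_mito",
]

# distinct substream ids so each generator draws from an independent stream
# derived from the same user-facing seed
_STREAM_PROTEOME = 11
_STREAM_OBSERVATIONS = 12
_STREAM_TARGETING = 13
_STREAM_ORTHOLOGS = 14
_STREAM_DECOYS = 15


class ConfigurationError(ValueError):
    """Raised when a SimulationConfig violates its invariants."""


class SequenceError(ValueError):
    """Raised on residues outside the 20-letter amino-acid alphabet."""


def _default_proportions() -> dict[str, float]:
    # Mirrors the composition of the mitochondrial-fraction candidate list in
    # the motivating study (~2/3 of candidates end up accepted as mitochondrial).
    return {"mito": 0.55, "chloroplast": 0.25, "cytosol": 0.15, "dual": 0.05}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the simulated fractionation experiment.

    Probabilities are in [0, 1]; folds are strictly positive; the log-normal
    noise sd may be 0, which is the exact zero-noise limit used by several
    invariants.
    """

    n_proteins: int = 2000
    localization_proportions: Mapping[str, float] = field(
        default_factory=_default_proportions
    )
    enrichment_fold: float = 8.0
    intensity_log_sd: float = 0.2
    n_replicates_per_fraction: int = 3
    missing_rate: float = 0.1
    detectability: float = 0.6
    truncation_prob: float = 0.85
    reference_coverage: float = 0.2
    n_reference_proteomes: int = 4
    seed: int = 0
    # secondary knobs
    missed_cleavages: int = 0
    min_peptide_length: int = 6
    contaminant_rate: float = 0.05
    contaminant_leak: float = 0.1
    annotated_fraction: float = 0.44
    predicted_coverage: float = 0.6
    mean_log10_base_intensity: float = 6.0
    base_log10_sd: float = 0.5
    min_protein_length: int = 120
    max_protein_length: int = 600

    def __post_init__(self) -> None:
        if self.n_proteins < 0:
            raise ConfigurationError("n_proteins must be nonnegative")
        props = dict(self.localization_proportions)
        unknown = set(props) - set(LOCALIZATIONS)
        if unknown:
            raise ConfigurationError(f"unknown localizations: {sorted(unknown)}")
        if any(p < 0 for p in props.values()):
            raise ConfigurationError("localization proportions must be nonnegative")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ConfigurationError("localization proportions must sum to 1")
        for name in (
            "missing_rate",
            "detectability",
            "truncation_prob",
            "reference_coverage",
            "contaminant_rate",
            "contaminant_leak",
            "annotated_fraction",
            "predicted_coverage",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.enrichment_fold <= 0:
            raise ConfigurationError("enrichment_fold must be strictly positive")
        if self.intensity_log_sd < 0 or self.base_log10_sd < 0:
            raise ConfigurationError("noise sd must be nonnegative")
        if self.n_replicates_per_fraction < 1:
            raise ConfigurationError("need at least one replicate per fraction")
        if not 0 <= self.missed_cleavages <= 2:
            raise ConfigurationError("missed_cleavages must be 0, 1 or 2")
        if self.n_reference_proteomes < 0:
            raise ConfigurationError("n_reference_proteomes must be nonnegative")
        if not 0 < self.min_protein_length <= self.max_protein_length:
            raise ConfigurationError("invalid protein length range")

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    @property
    def proportions(self) -> dict[str, float]:
        return {loc: dict(self.localization_proportions).get(loc, 0.0) for loc in LOCALIZATIONS}

    @property
    def reference_species(self) -> tuple[str, ...]:
        named = REFERENCE_SPECIES[: self.n_reference_proteomes]
        extra = tuple(
            f"reference_{i}" for i in range(len(named), self.n_reference_proteomes)
        )
        return named + extra


def _rng(stream: int, seed: int) -> np.random.Generator:
    return np.random.default_rng([stream, seed])


def _apportion(n: int, proportions: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n items over the localization classes."""
    keys = [k for k in LOCALIZATIONS if proportions.get(k, 0.0) > 0]
    raw = {k: n * proportions[k] for k in keys}
    counts = {k: int(math.floor(raw[k])) for k in keys}
    remainder = n - sum(counts.values())
    by_frac = sorted(keys, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in by_frac[:remainder]:
        counts[k] += 1
    return counts


def validate_sequence(sequence: str) -> str:
    bad = set(sequence) - set(AMINO_ACIDS)
    if bad:
        raise SequenceError(f"invalid residues {sorted(bad)} in sequence")
    return sequence


def generate_proteome(config: SimulationConfig) -> pd.DataFrame:
    """Generate the ground-truth proteome table.

    Returns a DataFrame with one row per protein: identifier, residue
    sequence, true localization, targeting-signal flag, contaminant-annotation
    flag, functional category (one of the 16-name vocabulary or "unknown"),
    plus the two annotation-layer flags downstream curation consumes
    (mito-function annotation, in-silico predicted membership).
    Deterministic given ``config.seed``.
    """
    rng = _rng(_STREAM_PROTEOME, config.seed)
    n = config.n_proteins
    if n == 0:
        return pd.DataFrame(columns=TRUTH_COLUMNS)

    counts = _apportion(n, config.proportions)
    localizations = np.concatenate(
        [np.repeat(loc, c) for loc, c in counts.items()]
    )
    rng.shuffle(localizations)

    lengths = rng.integers(config.min_protein_length, config.max_protein_length + 1, n)
    aa = np.array(list(AMINO_ACIDS))
    sequences = ["".join(rng.choice(aa, size=int(L))) for L in lengths]

    is_mito = np.isin(localizations, list(TRUE_MITO))
    has_signal = is_mito.copy()
    contaminant = (~is_mito) & (rng.random(n) < config.contaminant_rate)
    annotated = rng.random(n) < config.annotated_fraction
    cats = np.where(
        annotated, rng.choice(FUNCTIONAL_CATEGORIES, size=n), "unknown"
    )
    predicted = is_mito & (rng.random(n) < config.predicted_coverage)

    width = max(4, len(str(n)))
    ids = [f"SYN_{i:0{width}d}" for i in range(1, n + 1)]
    return pd.DataFrame(
        {
            "protein_id": ids,
            "sequence": sequences,
            "localization": localizations,
            "has_targeting_signal": has_signal,
            "is_contaminant_annotation": contaminant,
            "category": cats,
            "annotation_mito_function": is_mito & annotated,
            "predicted_mito": predicted,
        }
    )


def digest_tryptic(
    sequence: str, min_length: int = 6, missed_cleavages: int = 0
) -> list[str]:
    """In-silico tryptic digest: cleave C-terminal to K/R unless followed by P.

    Peptides shorter than ``min_length`` are dropped.  With
    ``missed_cleavages = 0`` the concatenation of the peptides before length
    filtering equals the input sequence; with ``missed_cleavages`` in {1, 2}
    all windows of up to that many skipped sites are returned as well,
    ordered by start position then length.
    """
    validate_sequence(sequence)
    if not sequence:
        return []
    fragments: list[str] = []
    start = 0
    for i, res in enumerate(sequence):
        if res in "KR" and (i + 1 == len(sequence) or sequence[i + 1] != "P"):
            fragments.append(sequence[start : i + 1])
            start = i + 1
    if start < len(sequence):
        fragments.append(sequence[start:])

    peptides: list[str] = []
    for i in range(len(fragments)):
        for span in range(1, missed_cleavages + 2):
            if i + span > len(fragments):
                break
            pep = "".join(fragments[i : i + span])
            if len(pep) >= min_length:
                peptides.append(pep)
    return peptides


def _fraction_effects(truth: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Per-protein multiplicative fraction effects (columns mt, cp, wc)."""
    loc = truth["localization"].to_numpy()
    fold = config.enrichment_fold
    mt = np.where(np.isin(loc, list(TRUE_MITO)), fold, 1.0)
    leak = truth["is_contaminant_annotation"].to_numpy(dtype=bool)
    mt = np.where(leak, config.contaminant_leak * fold, mt)
    cp = np.where(np.isin(loc, ["chloroplast", "dual"]), fold, 1.0)
    props = config.proportions
    w_rest = props["cytosol"] + props["dual"]
    wc = props["mito"] * mt + props["chloroplast"] * cp + w_rest * 1.0
    return pd.DataFrame({"mt": mt, "cp": cp, "wc": wc}, index=truth["protein_id"])


def simulate_observations(
    truth: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Simulate the peptide-observation table.

    One row per (peptide, fraction, replicate) that survives the per-peptide
    detectability draw and the per-observation missingness draw.  Columns:
    ``peptide, protein_ids, fraction, replicate, intensity``; ``protein_ids``
    is a ";"-joined list of every protein whose digest contains the peptide
    (I/L treated as indistinguishable when matching).
    """
    rng = _rng(_STREAM_OBSERVATIONS, config.seed)
    columns = ["peptide", "protein_ids", "fraction", "replicate", "intensity"]
    if truth.empty:
        return pd.DataFrame(columns=columns)

    base = 10.0 ** rng.normal(
        config.mean_log10_base_intensity, config.base_log10_sd, len(truth)
    )
    effects = _fraction_effects(truth, config)

    # peptide key = I/L-collapsed sequence; record the raw peptide as observed
    peptide_map: dict[str, dict] = {}
    for idx, (pid, seq) in enumerate(zip(truth["protein_id"], truth["sequence"])):
        for pep in digest_tryptic(
            seq, config.min_peptide_length, config.missed_cleavages
        ):
            key = pep.replace("I", "L")
            entry = peptide_map.setdefault(
                key, {"raw": pep, "proteins": [], "rows": []}
            )
            if pid not in entry["proteins"]:
                entry["proteins"].append(pid)
                entry["rows"].append(idx)

    n_rep = config.n_replicates_per_fraction
    rows: dict[str, list] = {c: [] for c in columns}
    for key, entry in peptide_map.items():
        if rng.random() >= config.detectability:
            continue
        prot_ids = ";".join(sorted(entry["proteins"]))
        idxs = entry["rows"]
        for fraction in FRACTIONS:
            expected = float(
                sum(base[i] * effects[fraction].iloc[i] for i in idxs)
            )
            for rep in range(1, n_rep + 1):
                noise = (
                    10.0 ** rng.normal(0.0, config.intensity_log_sd)
                    if config.intensity_log_sd > 0
                    else 1.0
                )
                missing = rng.random() < config.missing_rate
                if missing:
                    continue
                rows["peptide"].append(entry["raw"])
                rows["protein_ids"].append(prot_ids)
                rows["fraction"].append(fraction)
                rows["replicate"].append(rep)
                rows["intensity"].append(expected * noise)
    return pd.DataFrame(rows, columns=columns)


def simulate_targeting_tables(
    truth: pd.DataFrame, config: SimulationConfig
) -> dict[str, pd.DataFrame]:
    """TargetP-1.1-like prediction tables for three transcriptome variants.

    Each table has columns ``name, loc, RC, start_met``.  A transcript is
    5'-truncated with probability ``truncation_prob`` independently per
    variant; truncation loses both the start methionine and any N-terminal
    targeting signal (predicted location "_").
    """
    rng = _rng(_STREAM_TARGETING, config.seed)
    tables: dict[str, pd.DataFrame] = {}
    n = len(truth)
    for variant in TRANSCRIPTOME_VARIANTS:
        if n == 0:
            tables[variant] = pd.DataFrame(columns=["name", "loc", "RC", "start_met"])
            continue
        truncated = rng.random(n) < config.truncation_prob
        rc = rng.integers(1, 6, n)
        intact_loc = np.where(
            truth["has_targeting_signal"].to_numpy(dtype=bool),
            "M",
            np.where(truth["localization"].to_numpy() == "chloroplast", "C", "S"),
        )
        tables[variant] = pd.DataFrame(
            {
                "name": truth["protein_id"],
                "loc": np.where(truncated, "_", intact_loc),
                "RC": rc,
                "start_met": ~truncated,
            }
        )
    return tables


def simulate_ortholog_tables(
    truth: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Ortholog table linking proteins to reference mitoproteomes.

    True mitochondrial proteins carry an ortholog in each reference
    independently with probability ``reference_coverage``; other proteins have
    no rows.  Columns: ``protein_id, reference_species, reference_protein``.
    """
    rng = _rng(_STREAM_ORTHOLOGS, config.seed)
    cols = ["protein_id", "reference_species", "reference_protein"]
    rows: list[tuple[str, str, str]] = []
    mito = truth[truth["localization"].isin(TRUE_MITO)]
    for pid in mito["protein_id"]:
        for species in config.reference_species:
            if rng.random() < config.reference_coverage:
                rows.append((pid, species, f"{species}|{pid}_ort"))
    return pd.DataFrame(rows, columns=cols)


def simulate_decoy_scores(
    n_targets: int,
    n_decoys: int,
    separation: float,
    seed: int,
    false_target_fraction: float = 0.1,
) -> pd.DataFrame:
    """Scored identification list for target-decoy FDR exercises.

    Correct targets score ``Normal(separation, 1)``; incorrect targets (a
    ``false_target_fraction`` share of the target list) and decoys score
    ``Normal(0, 1)``.  Columns: ``score, is_decoy, is_correct`` — the truth
    label is preserved so realized false-discovery proportions can be
    measured against the decoy-based estimate.
    """
    if not 0.0 <= false_target_fraction <= 1.0:
        raise ConfigurationError("false_target_fraction must be in [0, 1]")
    rng = _rng(_STREAM_DECOYS, seed)
    n_false = int(round(false_target_fraction * n_targets))
    n_true = n_targets - n_false
    scores = np.concatenate(
        [
            rng.normal(separation, 1.0, n_true),
            rng.normal(0.0, 1.0, n_false),
            rng.normal(0.0, 1.0, n_decoys),
        ]
    )
    is_decoy = np.concatenate(
        [np.zeros(n_targets, dtype=bool), np.ones(n_decoys, dtype=bool)]
    )
    is_correct = np.concatenate(
        [
            np.ones(n_true, dtype=bool),
            np.zeros(n_false + n_decoys, dtype=bool),
        ]
    )
    return pd.DataFrame(
        {"score": scores, "is_decoy": is_decoy, "is_correct": is_correct}
    )


# ---------------------------------------------------------------------------
# writers


def write_fasta(truth: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    records = [
        SeqRecord(Seq(row.sequence), id=row.protein_id, description=row.localization)
        for row in truth.itertuples()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    return path


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False)
    return path


def generate_all(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write every synthetic input artifact into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = generate_proteome(config)
    paths = {
        "truth": write_table(truth, out / "truth.tsv"),
        "fasta": write_fasta(truth, out / "proteins.fasta"),
        "observations": write_table(
            simulate_observations(truth, config), out / "observations.tsv"
        ),
        "orthologs": write_table(
            simulate_ortholog_tables(truth, config), out / "orthologs.tsv"
        ),
    }
    for variant, table in simulate_targeting_tables(truth, config).items():
        paths[f"targeting_{variant}"] = write_table(
            table, out / f"targeting_{variant}.tsv"
        )
    return paths
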