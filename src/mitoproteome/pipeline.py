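"""End-to-end pipeline: simulate → infer → quantify → evidence → integrate → report.

Each stage reads and writes plain-text artifacts in a working directory so the
stages can also be driven individually from the command line.  The candidate
list mirrors the experimental design: proteins identified by at least one
peptide observation in the mitochondrial fraction.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import evidence as ev
from . import inference, integration, quantification, reporting, synthetic

LOG = logging.getLogger("mitoproteome")

REQUIRED_OBSERVATION_COLUMNS = [
    "peptide",
    "protein_ids",
    "fraction",
    "replicate",
    "intensity",
]


class SchemaError(ValueError):
    pass


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"required input file not found: {path}")
    return path


def read_observations(path) -> pd.DataFrame:
    table = pd.read_csv(_require(Path(path)), sep="\t")
    missing = set(REQUIRED_OBSERVATION_COLUMNS) - set(table.columns)
    if missing:
        raise SchemaError(
            f"observation table {path} missing columns: {sorted(missing)}"
        )
    return table


def read_truth(path) -> pd.DataFrame:
    table = pd.read_csv(_require(Path(path)), sep="\t")
    missing = set(synthetic.TRUTH_COLUMNS) - set(table.columns)
    if missing:
        raise SchemaError(f"truth table {path} missing columns: {sorted(missing)}")
    return table


def load_config(path) -> synthetic.SimulationConfig:
    """Load a pipeline configuration (YAML, a ``synthetic:`` section)."""
    with open(_require(Path(path))) as fh:
        raw = yaml.safe_load(fh) or {}
    section = raw.get("synthetic", raw)
    return synthetic.SimulationConfig(**section)


def stage_simulate(config: synthetic.SimulationConfig, work_dir) -> dict[str, Path]:
    LOG.info("simulating synthetic data: n=%d seed=%d", config.n_proteins, config.seed)
    return synthetic.generate_all(config, work_dir)


def stage_infer(work_dir, min_peptide_length: int = 6):
    """Build peptide matches and protein groups from the observation table."""
    wd = Path(work_dir)
    observations = read_observations(wd / "observations.tsv")
    matches = inference.build_matches(observations, min_peptide_length)
    groups = inference.group_proteins(matches)
    inference.count_unique_peptides(groups, matches)
    inference.write_peptides_table(matches, wd / "peptides.tsv")
    inference.write_protein_groups_table(groups, wd / "protein_groups.tsv")
    LOG.info("inference: %d peptides, %d protein groups", len(matches), len(groups))
    return matches, groups


def stage_quantify(work_dir, matches=None, groups=None, n_replicates=3) -> pd.DataFrame:
    wd = Path(work_dir)
    if matches is None or groups is None:
        observations = read_observations(wd / "observations.tsv")
        matches = inference.build_matches(observations)
        groups = inference.group_proteins(matches)
        inference.count_unique_peptides(groups, matches)
    sequences = None
    truth_path = wd / "truth.tsv"
    if truth_path.exists():
        truth = read_truth(truth_path)
        sequences = dict(zip(truth["protein_id"], truth["sequence"]))
    quant = quantification.quantify_groups(groups, matches, n_replicates, sequences)
    quant.to_csv(wd / "quantification.tsv", sep="\t", index=False)
    LOG.info("quantification: %d groups (%d quantifiable)",
             len(quant), int(quant["quantifiable"].sum()) if len(quant) else 0)
    return quant


def _candidates_from_matches(matches) -> set[str]:
    """Proteins identified in the mitochondrial fraction."""
    candidates: set[str] = set()
    for m in matches:
        if any(s.startswith("mt_") for s in m.intensities):
            candidates.update(m.proteins)
    return candidates


def stage_evidence(
    work_dir,
    config: synthetic.SimulationConfig,
    matches=None,
    groups=None,
    quant: pd.DataFrame | None = None,
) -> list[ev.EvidenceProfile]:
    wd = Path(work_dir)
    if matches is None or groups is None:
        observations = read_observations(wd / "observations.tsv")
        matches = inference.build_matches(observations)
        groups = inference.group_proteins(matches)
        inference.count_unique_peptides(groups, matches)
    if quant is None:
        quant = stage_quantify(wd, matches, groups, config.n_replicates_per_fraction)

    targeting_tables = {
        v: ev.read_targetp(_require(wd / f"targeting_{v}.tsv"))
        for v in synthetic.TRANSCRIPTOME_VARIANTS
    }
    ortholog_table = ev.read_ortholog_table(_require(wd / "orthologs.tsv"))
    annotations = read_truth(wd / "truth.tsv")[
        [
            "protein_id",
            "predicted_mito",
            "annotation_mito_function",
            "is_contaminant_annotation",
        ]
    ]

    # map group-level enrichment onto member proteins
    enrichment: dict[str, tuple[bool, float]] = {}
    quant_by_group = quant.set_index("group_id") if len(quant) else pd.DataFrame()
    for g in groups:
        if g.group_id in getattr(quant_by_group, "index", []):
            row = quant_by_group.loc[g.group_id]
            for member in g.members:
                enrichment[member] = (bool(row["enriched"]), float(row["ratio_mt_cp"]))

    candidates = _candidates_from_matches(matches)
    profiles = ev.build_profiles(
        candidates,
        ortholog_table,
        config.reference_species,
        targeting_tables,
        enrichment,
        annotations,
    )
    table = pd.DataFrame(
        [
            {
                "protein_id": p.protein_id,
                "ortholog_member": p.ortholog_member,
                "ortholog_species": ";".join(p.ortholog_species),
                "enriched": p.enriched,
                "targeting_consensus": p.targeting_consensus,
                "targeting_votes": p.targeting_votes,
                "predicted_mito": p.predicted_mito,
                "annotation_mito_function": p.annotation_mito_function,
                "annotation_clear_nonmito": p.annotation_clear_nonmito,
                "ratio_mt_cp": p.ratio_mt_cp,
            }
            for p in profiles
        ],
        columns=[
            "protein_id", "ortholog_member", "ortholog_species", "enriched",
            "targeting_consensus", "targeting_votes", "predicted_mito",
            "annotation_mito_function", "annotation_clear_nonmito", "ratio_mt_cp",
        ],
    )
    table.to_csv(wd / "evidence.tsv", sep="\t", index=False)
    LOG.info("evidence: %d candidate profiles", len(profiles))
    return profiles


def stage_integrate(work_dir, profiles, majority: bool = False):
    wd = Path(work_dir)
    union = integration.strategy_union(profiles, majority=majority)
    decisions = integration.curate(union, profiles)
    final, summary = integration.assemble(decisions, profiles)
    integration.decisions_table(decisions).to_csv(
        wd / "decisions.tsv", sep="\t", index=False
    )
    integration.write_summary_json(summary, wd / "summary.json")
    for d in decisions:
        if d.status is not integration.Status.REJECTED:
            LOG.debug("%s: %s (%s)", d.identifier, d.status.value, d.rationale)
    LOG.info(
        "integration: union=%d removed=%d reintegrated=%d final=%d",
        summary.union_count, summary.removed_count,
        summary.reintegrated_count, summary.final_count,
    )
    return final, summary, decisions


def stage_report(work_dir, final, quant: pd.DataFrame | None = None) -> pd.DataFrame:
    wd = Path(work_dir)
    truth = read_truth(wd / "truth.tsv")
    categories = dict(zip(truth["protein_id"], truth["category"]))
    final_categories = {p: categories.get(p, reporting.UNKNOWN_CATEGORY) for p in final}
    ratios: dict[str, float] = {}
    if quant is None and (wd / "quantification.tsv").exists():
        quant = pd.read_csv(wd / "quantification.tsv", sep="\t")
    if quant is not None and len(quant):
        for row in quant.itertuples(index=False):
            ratios[str(row.group_id)] = float(row.ratio_mt_cp)
    summaries, n_unknown, pct_unknown = reporting.category_summary(
        final_categories, {p: r for p, r in ratios.items() if p in final_categories}
    )
    table = reporting.category_summary_table(summaries)
    table.to_csv(wd / "category_summary.tsv", sep="\t", index=False)
    LOG.info("report: %d unknown-function (%d%%)", n_unknown, pct_unknown)
    return table


def run_pipeline(
    config: synthetic.SimulationConfig | str | Path | Mapping,
    work_dir,
    majority: bool = False,
) -> dict:
    """Run every stage; returns the summary (also written to summary.json).

    ``config`` may be a :class:`SimulationConfig`, a mapping of its fields, or
    a path to a YAML configuration file.
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    elif isinstance(config, Mapping):
        config = synthetic.SimulationConfig(**config)

    wd = Path(work_dir)
    wd.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(wd / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    LOG.addHandler(handler)
    LOG.setLevel(logging.INFO)
    try:
        stage_simulate(config, wd)
        matches, groups = stage_infer(wd, config.min_peptide_length)
        quant = stage_quantify(wd, matches, groups, config.n_replicates_per_fraction)
        profiles = stage_evidence(wd, config, matches, groups, quant)
        final, summary, _ = stage_integrate(wd, profiles, majority=majority)
        stage_report(wd, final, quant)

        truth = read_truth(wd / "truth.tsv")
        metrics = evaluate_against_truth(final, truth)
        out = {"summary": summary.as_dict(), "metrics": metrics}
        with open(wd / "summary.json", "w") as fh:
            json.dump(out, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return out
    finally:
        LOG.removeHandler(handler)
        handler.close()


def evaluate_against_truth(final, truth: pd.DataFrame) -> dict:
    """Recall/precision of the final membership call against true localization."""
    final_set = set(final)
    true_mito = set(
        truth.loc[truth["localization"].isin(synthetic.TRUE_MITO), "protein_id"]
    )
    tp = len(final_set & true_mito)
    fp = len(final_set - true_mito)
    fn = len(true_mito - final_set)
    return {
        "true_positives": tp,
        "false_positives": fp,
        "false_negatives": fn,
        "recall": tp / (tp + fn) if (tp + fn) else 1.0,
        "precision": tp / (tp + fp) if (tp + fp) else 1.0,
    }
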