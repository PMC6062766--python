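"""End-to-end orchestration of the OBP analysis stages.

A :class:`RunConfig` (YAML-serialisable) names the inputs, the stages to run
and every stage parameter; :func:`run_pipeline` executes the stages in
dependency order, writes human-readable tables plus one machine-readable
JSON report, and serialises the config next to the results so any run is
reproducible from config + inputs.  All randomness flows from the single
top-level seed, fanned out deterministically per stage.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .expression_stats import time_course_table, tissue_profile_table
from .gene_architecture import (
    intergenic_distances,
    locus_summary,
    locus_table,
    parse_gene_models,
)
from .phase_behavior import (
    DEFAULT_PHASE_MODEL,
    BehaviorSummary,
    PhaseModel,
    knockdown_report,
    score_table,
)
from .phylogeny import (
    bootstrap_supports,
    consensus_collapse,
    read_alignment_fasta,
    write_newick,
)
from .sequence_motifs import classify_fasta
from .synthetic_data import (
    PRESETS,
    write_alignment_fasta,
    write_fasta,
    write_gff3,
    write_sp_table,
)

__all__ = ["RunConfig", "PipelineInputError", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = ("classify", "loci", "tree", "express", "timecourse", "behave")


class PipelineInputError(ValueError):
    """Missing inputs for enabled stages, listed all at once."""


@dataclass
class RunConfig:
    outdir: str = "obpkit_run"
    seed: int = 0
    #: synthetic preset generating the inputs; None = use explicit paths
    preset: Optional[str] = None
    stages: tuple[str, ...] = ALL_STAGES
    # explicit input paths (ignored where the preset provides the input)
    fasta: Optional[str] = None
    annotations: Optional[str] = None
    gff: Optional[str] = None
    alignment: Optional[str] = None
    tissue_ct: Optional[str] = None
    timecourse_ct: Optional[str] = None
    behavior: Optional[str] = None
    # stage parameters
    alpha: float = 0.05
    bootstrap_reps: int = 500
    support_cutoff: float = 0.5
    long_intron_bp: int = 5000
    ref_gene: str = "rp49"
    atypical_min_length: int = 200
    control_group: str = "dsGFP"
    phase_model: tuple[float, float, float, float] = (
        DEFAULT_PHASE_MODEL.intercept,
        DEFAULT_PHASE_MODEL.coef_attraction,
        DEFAULT_PHASE_MODEL.coef_distance,
        DEFAULT_PHASE_MODEL.coef_duration,
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        cfg.stages = tuple(cfg.stages)
        cfg.phase_model = tuple(cfg.phase_model)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["stages"] = list(self.stages)
        data["phase_model"] = list(self.phase_model)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def _stage_seed(seed: int, index: int) -> int:
    return (seed * 1000003 + 7919 * (index + 1)) % (2**31 - 1)


# which input attribute each stage reads
_STAGE_INPUT = {
    "classify": "fasta",
    "loci": "gff",
    "tree": "alignment",
    "express": "tissue_ct",
    "timecourse": "timecourse_ct",
    "behave": "behavior",
}

# presets only provide some of the inputs
_PRESET_PROVIDES = {
    "table1": {"fasta", "annotations", "gff", "alignment"},
    "figure2": {"tissue_ct"},
    "figure4": {"timecourse_ct"},
    "figure5": {"behavior"},
}


def _materialise_preset(config: RunConfig, outdir: Path) -> dict[str, str]:
    """Generate the preset's inputs under ``outdir/inputs`` and return paths."""
    inputs_dir = outdir / "inputs"
    inputs_dir.mkdir(parents=True, exist_ok=True)
    artifacts = PRESETS[config.preset](seed=_stage_seed(config.seed, 0))
    paths: dict[str, str] = {}
    if "records" in artifacts:
        fasta = inputs_dir / "proteins.fasta"
        sp = inputs_dir / "signal_peptides.tsv"
        write_fasta(artifacts["records"], fasta)
        write_sp_table(artifacts["records"], sp)
        artifacts["protein_truth"].to_csv(
            inputs_dir / "protein_truth.tsv", sep="\t", index=False
        )
        paths["fasta"], paths["annotations"] = str(fasta), str(sp)
    if "gene_models" in artifacts:
        gff = inputs_dir / "genes.gff3"
        write_gff3(artifacts["gene_models"], gff)
        artifacts["gene_truth"].to_csv(
            inputs_dir / "gene_truth.tsv", sep="\t", index=False
        )
        paths["gff"] = str(gff)
    if "alignment" in artifacts:
        aln = inputs_dir / "alignment.fasta"
        write_alignment_fasta(artifacts["alignment"], aln)
        paths["alignment"] = str(aln)
    if "ct" in artifacts:
        ct_path = inputs_dir / "ct_table.csv"
        artifacts["ct"].to_csv(ct_path, index=False)
        artifacts["truth"].to_csv(inputs_dir / "ct_truth.tsv", sep="\t", index=False)
        key = "timecourse_ct" if "process" in artifacts["ct"].columns else "tissue_ct"
        paths[key] = str(ct_path)
    if "cohorts" in artifacts:
        b = inputs_dir / "behavior.csv"
        artifacts["cohorts"].to_csv(b, index=False)
        artifacts["truth"].to_csv(
            inputs_dir / "behavior_truth.tsv", sep="\t", index=False
        )
        paths["behavior"] = str(b)
    return paths


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; return (and write) the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.preset is not None:
        if config.preset not in PRESETS:
            raise PipelineInputError(
                f"unknown preset {config.preset!r}; choose from {sorted(PRESETS)}"
            )
        generated = _materialise_preset(config, outdir)
        for key, path in generated.items():
            setattr(config, key, path)
        provided = _PRESET_PROVIDES[config.preset]
        stages = tuple(s for s in config.stages if _STAGE_INPUT[s] in provided)
    else:
        stages = config.stages

    problems = []
    for stage in stages:
        if stage not in ALL_STAGES:
            problems.append(f"unknown stage {stage!r}")
            continue
        path = getattr(config, _STAGE_INPUT[stage])
        if path is None:
            problems.append(f"stage {stage!r}: no {_STAGE_INPUT[stage]} input configured")
        elif not Path(path).is_file():
            problems.append(f"stage {stage!r}: input {path} not found")
    if problems:
        raise PipelineInputError("; ".join(problems))

    report: dict = {
        "obpkit_version": __version__,
        "seed": config.seed,
        "preset": config.preset,
        "stages": list(stages),
        "parameters": {
            "alpha": config.alpha,
            "bootstrap_reps": config.bootstrap_reps,
            "support_cutoff": config.support_cutoff,
            "long_intron_bp": config.long_intron_bp,
            "ref_gene": config.ref_gene,
            "atypical_min_length": config.atypical_min_length,
        },
    }

    for stage in stages:
        runner = globals()[f"_run_{stage}"]
        report[stage] = runner(config, outdir)

    config.to_yaml(outdir / "config.yaml")
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _run_classify(config: RunConfig, outdir: Path) -> dict:
    table = classify_fasta(
        config.fasta,
        annotations=config.annotations,
        atypical_min_length=config.atypical_min_length,
    )
    table.to_csv(outdir / "subtypes.tsv", sep="\t", index=False)
    census = table["subtype"].value_counts().to_dict()
    return {
        "n_records": int(len(table)),
        "census": {k: int(v) for k, v in census.items()},
        "length_range": [int(table["length"].min()), int(table["length"].max())]
        if len(table)
        else None,
        "n_with_signal_peptide": int((table["signal_peptide_len"] > 0).sum()),
    }


def _run_loci(config: RunConfig, outdir: Path) -> dict:
    models = parse_gene_models(config.gff)
    locus_table(models, config.long_intron_bp).to_csv(
        outdir / "loci.tsv", sep="\t", index=False
    )
    pairs = intergenic_distances(models)
    pairs.to_csv(outdir / "intergenic.tsv", sep="\t", index=False)
    summary = locus_summary(models, config.long_intron_bp)
    return {**summary, "n_same_scaffold_pairs": int(len(pairs))}


def _run_tree(config: RunConfig, outdir: Path) -> dict:
    block = read_alignment_fasta(config.alignment)
    result = bootstrap_supports(
        block,
        n_reps=config.bootstrap_reps,
        seed=_stage_seed(config.seed, 3),
    )
    write_newick(result.tree, outdir / "tree.nwk")
    consensus = consensus_collapse(
        result.tree, result.supports, cutoff=config.support_cutoff
    )
    write_newick(consensus, outdir / "consensus.nwk")
    supports = sorted(result.supports.values())
    return {
        "n_taxa": block.n_rows,
        "n_columns": block.n_cols,
        "n_reps": result.n_reps,
        "n_redrawn": result.n_redrawn,
        "support_min": supports[0] if supports else None,
        "support_max": supports[-1] if supports else None,
        "n_internal_edges": len(result.supports),
        "n_collapsed": sum(
            1 for s in result.supports.values() if s < config.support_cutoff
        ),
    }


def _run_express(config: RunConfig, outdir: Path) -> dict:
    ct = pd.read_csv(config.tissue_ct)
    table = tissue_profile_table(ct, ref_gene=config.ref_gene, alpha=config.alpha)
    table.to_csv(outdir / "tissue_patterns.tsv", sep="\t", index=False)
    return {
        "n_genes": int(len(table)),
        "pattern_counts": {
            k: int(v) for k, v in table["pattern"].value_counts().to_dict().items()
        },
    }


def _run_timecourse(config: RunConfig, outdir: Path) -> dict:
    ct = pd.read_csv(config.timecourse_ct)
    table = time_course_table(ct, ref_gene=config.ref_gene, alpha=config.alpha)
    table.to_csv(outdir / "time_course.tsv", sep="\t", index=False)
    return {
        "n_genes": int(len(table)),
        "responders": sorted(table.loc[table["class"] == "responder", "gene_id"]),
    }


def _run_behave(config: RunConfig, outdir: Path) -> dict:
    df = pd.read_csv(config.behavior)
    model = PhaseModel(*config.phase_model)
    individuals = [
        BehaviorSummary(
            individual_id=str(r.individual_id),
            attraction_index=float(r.attraction_index),
            total_distance=float(r.total_distance),
            total_duration=float(r.total_duration),
            group=str(r.group),
        )
        for r in df.itertuples()
    ]
    scores = score_table(individuals, model)
    scores.to_csv(outdir / "phase_scores.csv", index=False)
    control = [b for b in individuals if b.group == config.control_group]
    if not control:
        raise PipelineInputError(
            f"behave: control group {config.control_group!r} absent from data"
        )
    medians = {
        group: float(sub["p_greg"].median())
        for group, sub in scores.groupby("group")
    }
    comparisons = {}
    tables = []
    for group in sorted(set(b.group for b in individuals) - {config.control_group}):
        treated = [b for b in individuals if b.group == group]
        rep = knockdown_report(treated, control, model)
        rep.insert(0, "treated_group", group)
        tables.append(rep)
        comparisons[group] = {
            row["measure"]: {
                "percent_of_control": None
                if pd.isna(row["percent_of_control"])
                else float(row["percent_of_control"]),
                "U": float(row["U"]),
                "p_value": float(row["p_value"]),
            }
            for _, row in rep.iterrows()
        }
    if tables:
        pd.concat(tables).to_csv(outdir / "knockdown.tsv", sep="\t", index=False)
    return {
        "groups": {g: int((scores["group"] == g).sum()) for g in medians},
        "median_p_greg": medians,
        "comparisons": comparisons,
    }
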