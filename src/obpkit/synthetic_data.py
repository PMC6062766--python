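"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator is a pure function of its spec and a seed, and returns the
artifact together with a first-class truth table so downstream tests recover
planted structure instead of re-inferring it.  Defaults emulate the study
conditions of the locust OBP family: a 17-member catalog of planted cysteine
architectures, 17 gene models scattered over 16 scaffolds with one
co-located pair and heavy-tailed introns, Ct tables with tissue/phase and
time-course effects at four biological replicates, and behavioral cohorts
with log-normal (right-skewed) covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import LOCUST_OBP_CATALOG
from .gene_architecture import GeneModel
from .phylogeny import AlignedBlock
from .sequence_motifs import (
    DEFAULT_GAPS,
    SUBTYPE_ATYPICAL,
    SUBTYPE_CLASSIC,
    SUBTYPE_PLUS_C_A,
    SUBTYPE_PLUS_C_B,
    GapConfig,
    ProteinRecord,
    classify_record,
)

__all__ = [
    "SpecError",
    "ProteinEntry",
    "catalog_entries",
    "random_protein_entries",
    "gen_proteins",
    "write_fasta",
    "write_sp_table",
    "GeneLayoutSpec",
    "gen_gene_models",
    "write_gff3",
    "TissueCtSpec",
    "gen_tissue_ct",
    "TimeCourseCtSpec",
    "gen_timecourse_ct",
    "BehaviorCohortSpec",
    "gen_behavior_cohorts",
    "AlignmentSpec",
    "gen_alignment",
    "write_alignment_fasta",
    "preset_table1",
    "preset_figure2",
    "preset_figure4",
    "preset_figure5",
    "PRESETS",
]

_NON_C = "ADEFGHIKLMNPQRSTVWY"  # flanks avoid cysteine so planted C's are all C's


class SpecError(ValueError):
    """A generator spec is infeasible (e.g. motif does not fit the length)."""


# ---------------------------------------------------------------------------
# Proteins with planted cysteine architectures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinEntry:
    name: str
    subtype: str
    protein_length: int
    signal_peptide_len: int = 0


def catalog_entries() -> list[ProteinEntry]:
    """One entry per published locust OBP (printed lengths and subtypes)."""
    return [
        ProteinEntry(e.name, e.subtype, e.protein_length, e.signal_peptide_len)
        for e in LOCUST_OBP_CATALOG
    ]


def random_protein_entries(
    counts: dict[str, int],
    seed: Optional[int] = None,
    length_range: tuple[int, int] = (124, 180),
    atypical_length_range: tuple[int, int] = (210, 280),
    sp_len_range: tuple[int, int] = (16, 30),
    sp_prob: float = 0.6,
) -> list[ProteinEntry]:
    """Random entries per subtype, with realistic lengths and signal peptides."""
    rng = np.random.default_rng(seed)
    entries = []
    for subtype, n in counts.items():
        lo, hi = (
            atypical_length_range if subtype == SUBTYPE_ATYPICAL else length_range
        )
        for i in range(n):
            length = int(rng.integers(lo, hi + 1))
            sp = (
                int(rng.integers(*sp_len_range))
                if rng.random() < sp_prob
                else 0
            )
            entries.append(ProteinEntry(f"{subtype}_{i+1:03d}", subtype, length, sp))
    return entries


def _sample_gaps(
    subtype: str, mature_len: int, config: GapConfig, rng: np.random.Generator
) -> tuple[int, ...]:
    """Planted inter-cysteine gaps respecting the config and the length budget.

    The two diagnostic gaps are fixed by the config; the free gaps are drawn
    uniformly for core-only subtypes and pinned to range midpoints for the
    plus-C subtypes (where deterministic geometry keeps the planted core the
    best-scoring assignment despite the extra cysteines).
    """
    ranges = config.ranges()
    min_span = 6 + sum(lo for lo, _ in ranges)
    reserve = 13 if subtype == SUBTYPE_PLUS_C_B else 0
    if min_span + reserve > mature_len:
        raise SpecError(
            f"mature length {mature_len} cannot hold the motif "
            f"(minimum span {min_span + reserve})"
        )
    if subtype in (SUBTYPE_PLUS_C_A, SUBTYPE_PLUS_C_B):
        mids = tuple(int((lo + hi) // 2) for lo, hi in ranges)
        g3_floor = max(ranges[2][0], 22) if subtype == SUBTYPE_PLUS_C_A else ranges[2][0]
        # keep the C1-C2 gap at its midpoint (so a flanking extra can never
        # out-score the planted C1); shrink only C3-C4 / C4-C5 when tight
        shrunk = (mids[0], mids[1], g3_floor, ranges[3][0], mids[4])
        for gaps in (mids, shrunk):
            if gaps[2] >= g3_floor and 6 + sum(gaps) + reserve <= mature_len:
                return gaps
        raise SpecError(
            f"mature length {mature_len} too short for a planted {subtype} motif"
        )
    for _ in range(200):
        gaps = tuple(int(rng.integers(lo, hi + 1)) for lo, hi in ranges)
        if 6 + sum(gaps) <= mature_len:
            return gaps
    return tuple(lo for lo, _ in ranges)


def _plant_sequence(
    entry: ProteinEntry, config: GapConfig, rng: np.random.Generator
) -> tuple[str, tuple[int, ...]]:
    """Full-length sequence (signal peptide included) with a planted core.

    Returns the residues and the planted C1-C6 positions in mature
    coordinates.
    """
    mature_len = entry.protein_length - entry.signal_peptide_len
    if mature_len < 1:
        raise SpecError(f"{entry.name}: signal peptide covers the sequence")
    gaps = _sample_gaps(entry.subtype, mature_len, config, rng)
    span = 6 + sum(gaps)
    leftover = mature_len - span
    if entry.subtype == SUBTYPE_PLUS_C_B:
        if leftover < 13:
            raise SpecError(f"{entry.name}: no room for flanking cysteines")
        n_pre = int(rng.integers(6, leftover - 6))
    else:
        n_pre = int(rng.integers(0, leftover + 1))

    seq = list(rng.choice(list(_NON_C), size=mature_len))
    core = []
    pos = n_pre
    core.append(pos)
    for g in gaps:
        pos += g + 1
        core.append(pos)
    for p in core:
        seq[p] = "C"
    c1, _, c3, _, _, c6 = core
    if entry.subtype == SUBTYPE_PLUS_C_A:
        # offsets into the C3-C4 gap chosen so no spurious pair is 4 or 9
        # residues apart (which would admit an alternative core assignment)
        for k in (6, 13, 21):
            seq[c3 + k] = "C"
    elif entry.subtype == SUBTYPE_PLUS_C_B:
        seq[c1 - 6] = "C"
        seq[c6 + 6] = "C"

    sp = list(rng.choice(list(_NON_C), size=entry.signal_peptide_len))
    if sp:
        sp[0] = "M"
    elif seq[0] != "C":
        seq[0] = "M"
    return "".join(sp) + "".join(seq), tuple(core)


def gen_proteins(
    entries: Sequence[ProteinEntry],
    seed: Optional[int] = None,
    config: GapConfig = DEFAULT_GAPS,
    validate: bool = True,
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Protein records with planted subtypes plus their truth table.

    With ``validate`` each sequence is checked to classify back to its
    planted subtype under the same gap config (a generator self-check, not a
    substitute for the round-trip tests).
    """
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    rows = []
    for entry in entries:
        residues, core = _plant_sequence(entry, config, rng)
        record = ProteinRecord(entry.name, residues, entry.signal_peptide_len)
        if validate:
            call = classify_record(record, config)
            if call.subtype != entry.subtype:
                raise SpecError(
                    f"{entry.name}: planted {entry.subtype} classifies as "
                    f"{call.subtype} under this gap config"
                )
        records.append(record)
        rows.append(
            {
                "id": entry.name,
                "subtype": entry.subtype,
                "protein_length": entry.protein_length,
                "signal_peptide_len": entry.signal_peptide_len,
                "c_positions": ",".join(map(str, core)),
            }
        )
    return records, pd.DataFrame(rows)


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.residues}\n")


def write_sp_table(records: Sequence[ProteinRecord], path: str | Path) -> None:
    """Signal-peptide annotation TSV consumed by the classifier."""
    pd.DataFrame(
        {
            "id": [r.id for r in records],
            "signal_peptide_len": [r.signal_peptide_len for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneLayoutSpec:
    """Scaffold layout and exon/intron geometry of the synthetic gene set.

    The intron log-normal defaults put the median near 6 kb so roughly 55%
    of introns exceed the 5 kb long-intron threshold, within the printed
    83-58448 bp range; exons are uniform on the printed 20-210 bp range.
    """

    n_genes: int = 17
    n_scaffolds: int = 16
    n_seven_exon: int = 5
    exon_len_range: tuple[int, int] = (20, 210)
    intron_lognorm_mu: float = 8.706  # ln(5000) + 0.1257 * sigma -> ~55% > 5 kb
    intron_lognorm_sigma: float = 1.5
    intron_len_range: tuple[int, int] = (83, 58448)
    intergenic_bp: int = 32000
    gene_ids: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_scaffolds < 1:
            raise SpecError("need at least one gene and one scaffold")
        if self.n_scaffolds > self.n_genes:
            raise SpecError("more scaffolds than genes")
        if self.n_seven_exon > self.n_genes:
            raise SpecError("more seven-exon genes than genes")


def gen_gene_models(
    spec: GeneLayoutSpec = GeneLayoutSpec(), seed: Optional[int] = None
) -> tuple[list[GeneModel], pd.DataFrame]:
    """Gene models on scaffolds plus the truth table of spans and lengths."""
    rng = np.random.default_rng(seed)
    ids = spec.gene_ids or tuple(
        f"gene{i+1:02d}" for i in range(spec.n_genes)
    )
    if len(ids) != spec.n_genes:
        raise SpecError("gene_ids length does not match n_genes")
    seven = set(rng.choice(spec.n_genes, size=spec.n_seven_exon, replace=False))

    # first n_scaffolds genes get their own scaffold; the remainder co-locate
    # after the resident gene at the configured intergenic gap
    scaffold_of = [min(i, spec.n_scaffolds - 1) if i < spec.n_scaffolds else i - spec.n_scaffolds
                   for i in range(spec.n_genes)]
    last_end: dict[int, int] = {}
    models: list[GeneModel] = []
    rows = []
    for i, gene_id in enumerate(ids):
        n_exons = 7 if i in seven else 6
        exon_lens = rng.integers(
            spec.exon_len_range[0], spec.exon_len_range[1] + 1, size=n_exons
        )
        intron_lens = np.clip(
            np.round(
                rng.lognormal(
                    spec.intron_lognorm_mu, spec.intron_lognorm_sigma, size=n_exons - 1
                )
            ),
            *spec.intron_len_range,
        ).astype(int)
        sc = scaffold_of[i]
        start = last_end.get(sc, int(rng.integers(1000, 5001)))
        if sc in last_end:
            start += spec.intergenic_bp
        exons = []
        pos = start
        for k in range(n_exons):
            exons.append((pos, pos + int(exon_lens[k])))
            pos += int(exon_lens[k])
            if k < n_exons - 1:
                pos += int(intron_lens[k])
        model = GeneModel(
            gene_id=gene_id,
            scaffold_id=f"scaffold{sc+1:02d}",
            strand=str(rng.choice(["+", "-"])),
            exons=tuple(exons),
        )
        last_end[sc] = model.span[1]
        models.append(model)
        rows.append(
            {
                "gene_id": gene_id,
                "scaffold_id": model.scaffold_id,
                "strand": model.strand,
                "gene_span": model.span[1] - model.span[0],
                "n_exons": n_exons,
                "exon_lengths": ",".join(map(str, exon_lens.tolist())),
                "intron_lengths": ",".join(map(str, intron_lens.tolist())),
            }
        )
    return models, pd.DataFrame(rows)


def write_gff3(models: Sequence[GeneModel], path: str | Path) -> None:
    """Serialise gene models to GFF3 (1-based closed coordinates)."""
    scaffold_len: dict[str, int] = {}
    for m in models:
        scaffold_len[m.scaffold_id] = max(
            scaffold_len.get(m.scaffold_id, 0), m.span[1] + 1000
        )
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for sc in sorted(scaffold_len):
            fh.write(f"##sequence-region {sc} 1 {scaffold_len[sc]}\n")
        for m in models:
            g0, g1 = m.span
            fh.write(
                f"{m.scaffold_id}\tobpkit\tgene\t{g0+1}\t{g1}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}\n"
            )
            mrna = f"{m.gene_id}.t1"
            fh.write(
                f"{m.scaffold_id}\tobpkit\tmRNA\t{g0+1}\t{g1}\t.\t{m.strand}\t.\t"
                f"ID={mrna};Parent={m.gene_id}\n"
            )
            for k, (s, e) in enumerate(m.exons, start=1):
                fh.write(
                    f"{m.scaffold_id}\tobpkit\texon\t{s+1}\t{e}\t.\t{m.strand}\t.\t"
                    f"ID={mrna}.exon{k};Parent={mrna}\n"
                )


# ---------------------------------------------------------------------------
# Ct tables
# ---------------------------------------------------------------------------

_RICH_SETS = {
    "antenna-rich": frozenset({"antenna"}),
    "labial-palp-rich": frozenset({"labial_palp"}),
    "antenna-and-labial-palp-rich": frozenset({"antenna", "labial_palp"}),
    "brain-rich": frozenset({"brain"}),
    "multi-tissue": frozenset(),
}

_TISSUES = ("antenna", "labial_palp", "brain", "wing", "hind_leg")
_PHASES = ("gregarious", "solitarious")
_TIMES = (0, 4, 8, 16)


def _ln_sigma(cv: float) -> float:
    """Log-scale sd of a log-normal with the given coefficient of variation."""
    return float(np.sqrt(np.log1p(cv**2)))


@dataclass(frozen=True)
class TissueCtSpec:
    """Tissue x phase qPCR design with planted expression patterns.

    ``genes`` maps gene id to one of the five pattern names; tissues in the
    pattern's rich set are elevated ``fold``-fold over the base expression.
    Four biological replicates per cell and 10% replicate CV by default.
    """

    genes: dict[str, str] = field(
        default_factory=lambda: {"gene_antenna": "antenna-rich"}
    )
    fold: float = 8.0
    base_expr: float = 0.01
    n_reps: int = 4
    cv: float = 0.10
    ref_gene: str = "rp49"
    ref_ct: float = 16.0
    ref_noise_sd: float = 0.05


def gen_tissue_ct(
    spec: TissueCtSpec = TissueCtSpec(), seed: Optional[int] = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format Ct table for the tissue/phase design plus its truth table."""
    for gene, pattern in spec.genes.items():
        if pattern not in _RICH_SETS:
            raise SpecError(f"{gene}: unknown pattern {pattern!r}")
    rng = np.random.default_rng(seed)
    sigma = _ln_sigma(spec.cv)
    rows = []
    for phase in _PHASES:
        for tissue in _TISSUES:
            for rep in range(1, spec.n_reps + 1):
                sample = f"{phase}_{tissue}_r{rep}"
                ref_ct = spec.ref_ct + rng.normal(0.0, spec.ref_noise_sd)
                rows.append(
                    {
                        "sample_id": sample,
                        "gene_id": spec.ref_gene,
                        "tissue": tissue,
                        "phase": phase,
                        "replicate": rep,
                        "ct": ref_ct,
                    }
                )
                for gene, pattern in spec.genes.items():
                    rich = _RICH_SETS[pattern]
                    mean = spec.base_expr * (spec.fold if tissue in rich else 1.0)
                    expr = mean * np.exp(rng.normal(0.0, sigma))
                    rows.append(
                        {
                            "sample_id": sample,
                            "gene_id": gene,
                            "tissue": tissue,
                            "phase": phase,
                            "replicate": rep,
                            "ct": ref_ct - np.log2(expr),
                        }
                    )
    truth = pd.DataFrame(
        {
            "gene_id": list(spec.genes),
            "pattern": [spec.genes[g] for g in spec.genes],
            "fold": spec.fold,
        }
    )
    return pd.DataFrame(rows), truth


@dataclass(frozen=True)
class TimeCourseCtSpec:
    """IG/CS time-course design (0/4/8/16 h, four replicates).

    Responder genes decline ``fold``-fold (log-linear) across the IG series
    and rise ``fold``-fold across CS; flat genes keep the base expression in
    both processes.
    """

    responders: tuple[str, ...] = ("gene_resp",)
    flats: tuple[str, ...] = ("gene_flat",)
    fold: float = 2.0
    base_expr: float = 0.01
    n_reps: int = 4
    cv: float = 0.10
    ref_gene: str = "rp49"
    ref_ct: float = 16.0
    ref_noise_sd: float = 0.05


def gen_timecourse_ct(
    spec: TimeCourseCtSpec = TimeCourseCtSpec(), seed: Optional[int] = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format Ct table for the time-course design plus its truth table."""
    rng = np.random.default_rng(seed)
    sigma = _ln_sigma(spec.cv)
    t_max = max(_TIMES)
    rows = []
    for process in ("IG", "CS"):
        for t in _TIMES:
            for rep in range(1, spec.n_reps + 1):
                sample = f"{process}_t{t:02d}_r{rep}"
                ref_ct = spec.ref_ct + rng.normal(0.0, spec.ref_noise_sd)
                rows.append(
                    {
                        "sample_id": sample,
                        "gene_id": spec.ref_gene,
                        "process": process,
                        "time_h": t,
                        "replicate": rep,
                        "ct": ref_ct,
                    }
                )
                for gene in spec.responders + spec.flats:
                    if gene in spec.responders:
                        sign = -1.0 if process == "IG" else 1.0
                        mean = spec.base_expr * spec.fold ** (sign * t / t_max)
                    else:
                        mean = spec.base_expr
                    expr = mean * np.exp(rng.normal(0.0, sigma))
                    rows.append(
                        {
                            "sample_id": sample,
                            "gene_id": gene,
                            "process": process,
                            "time_h": t,
                            "replicate": rep,
                            "ct": ref_ct - np.log2(expr),
                        }
                    )
    truth = pd.DataFrame(
        {
            "gene_id": list(spec.responders) + list(spec.flats),
            "class": ["responder"] * len(spec.responders)
            + ["non-responder"] * len(spec.flats),
        }
    )
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# Behavioral cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BehaviorCohortSpec:
    """Arena-assay cohorts with log-normal covariates.

    Control medians are set so the control cohort's median phase score is
    ~0.995 under the default logistic model; treated cohorts scale each
    covariate by the configured reduction factors (defaults: the printed
    28.7/60.3/70.9% knockdown effect on attraction index, distance moved and
    movement duration).
    """

    n_per_group: int = 30
    control_group: str = "dsGFP"
    control_medians: tuple[float, float, float] = (100.0, 300.0, 220.0)
    cv: float = 0.30
    treatments: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "dsLmigOBP4": (0.287, 0.603, 0.709),
            "dsLmigOBP2": (1.0, 1.0, 1.0),
        }
    )


def gen_behavior_cohorts(
    spec: BehaviorCohortSpec = BehaviorCohortSpec(), seed: Optional[int] = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-individual behavior summaries (CSV-ready) plus the truth table."""
    rng = np.random.default_rng(seed)
    sigma = _ln_sigma(spec.cv)
    rows = []
    truth_rows = []
    groups = {spec.control_group: (1.0, 1.0, 1.0), **spec.treatments}
    for group, factors in groups.items():
        medians = tuple(m * f for m, f in zip(spec.control_medians, factors))
        truth_rows.append(
            {
                "group": group,
                "factor_attraction": factors[0],
                "factor_distance": factors[1],
                "factor_duration": factors[2],
                "median_attraction": medians[0],
                "median_distance": medians[1],
                "median_duration": medians[2],
            }
        )
        for i in range(spec.n_per_group):
            draws = [m * np.exp(rng.normal(0.0, sigma)) for m in medians]
            rows.append(
                {
                    "individual_id": f"{group}_{i+1:03d}",
                    "group": group,
                    "attraction_index": draws[0],
                    "total_distance": draws[1],
                    "total_duration": draws[2],
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Aligned blocks with planted cluster structure
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignmentSpec:
    """Gap-free aligned block with planted clusters.

    Each cluster descends from its own ancestor (mutated from a common root
    at ``between_p`` per site); leaves mutate from the cluster ancestor at
    ``within_p`` per site.  Clusters of size 2..n-2 are planted bipartitions
    that a correct tree must contain with high support.
    """

    clusters: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "left": ("A1", "A2", "A3"),
            "right": ("B1", "B2", "B3"),
        }
    )
    n_cols: int = 200
    within_p: float = 0.05
    between_p: float = 0.4


def gen_alignment(
    spec: AlignmentSpec = AlignmentSpec(), seed: Optional[int] = None
) -> tuple[AlignedBlock, dict[str, frozenset[str]]]:
    """Aligned block plus the planted non-trivial cluster bipartitions."""
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

    def mutate(seq: np.ndarray, p: float) -> np.ndarray:
        out = seq.copy()
        hits = rng.random(seq.size) < p
        # draw replacements different from the current residue
        for idx in np.flatnonzero(hits):
            choices = alphabet[alphabet != out[idx]]
            out[idx] = choices[rng.integers(choices.size)]
        return out

    root = alphabet[rng.integers(alphabet.size, size=spec.n_cols)]
    ids: list[str] = []
    rows: list[str] = []
    for cluster in spec.clusters.values():
        ancestor = mutate(root, spec.between_p)
        for taxon in cluster:
            ids.append(taxon)
            rows.append("".join(mutate(ancestor, spec.within_p)))
    block = AlignedBlock(tuple(ids), tuple(rows))
    n = len(ids)
    truth = {
        name: frozenset(members)
        for name, members in spec.clusters.items()
        if 2 <= len(members) <= n - 2
    }
    return block, truth


def write_alignment_fasta(block: AlignedBlock, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(block.ids, block.rows):
            fh.write(f">{rid}\n{row}\n")


# ---------------------------------------------------------------------------
# Presets emulating the study's datasets
# ---------------------------------------------------------------------------

_CLADES = {
    "clade1": ("LmigOBP5", "LmigOBP10", "LmigOBP13", "LmigOBP8", "LmigOBP12",
               "LmigOBP15", "LmigOBP17"),
    "clade2": ("LmigOBP1", "LmigOBP9", "LmigOBP14"),
    "clade3": ("LmigOBP2", "LmigOBP3", "LmigOBP4", "LmigOBP7", "LmigOBP11"),
    "clade4": ("LmigOBP6", "LmigOBP16"),
}

_FIGURE2_PATTERNS = {
    "LmigOBP1": "antenna-rich",
    "LmigOBP2": "antenna-rich",
    "LmigOBP4": "antenna-rich",
    "LmigOBP5": "antenna-rich",
    "LmigOBP9": "antenna-rich",
    "LmigOBP10": "antenna-rich",
    "LmigOBP13": "antenna-rich",
    "LmigOBP14": "antenna-rich",
    "LmigOBP7": "labial-palp-rich",
    "LmigOBP11": "labial-palp-rich",
    "LmigOBP12": "labial-palp-rich",
    "LmigOBP15": "labial-palp-rich",
    "LmigOBP17": "labial-palp-rich",
    "LmigOBP3": "antenna-and-labial-palp-rich",
    "LmigOBP16": "antenna-and-labial-palp-rich",
    "LmigOBP8": "brain-rich",
    "LmigOBP6": "multi-tissue",
}


def preset_table1(seed: Optional[int] = None) -> dict:
    """Synthetic 17-member OBP family: sequences, gene models, alignment."""
    records, protein_truth = gen_proteins(catalog_entries(), seed=seed)
    layout = GeneLayoutSpec(gene_ids=tuple(e.name for e in LOCUST_OBP_CATALOG))
    models, gene_truth = gen_gene_models(layout, seed=None if seed is None else seed + 1)
    block, clade_truth = gen_alignment(
        AlignmentSpec(clusters=_CLADES), seed=None if seed is None else seed + 2
    )
    return {
        "records": records,
        "protein_truth": protein_truth,
        "gene_models": models,
        "gene_truth": gene_truth,
        "alignment": block,
        "alignment_truth": clade_truth,
    }


def preset_figure2(seed: Optional[int] = None) -> dict:
    """Tissue/phase Ct design with the published five-pattern layout."""
    ct, truth = gen_tissue_ct(TissueCtSpec(genes=dict(_FIGURE2_PATTERNS)), seed=seed)
    return {"ct": ct, "truth": truth}


def preset_figure4(seed: Optional[int] = None) -> dict:
    """Time-course Ct design: two reverse-pattern responders, five flats."""
    spec = TimeCourseCtSpec(
        responders=("LmigOBP2", "LmigOBP4"),
        flats=("LmigOBP1", "LmigOBP5", "LmigOBP9", "LmigOBP14", "LmigOBP16"),
    )
    ct, truth = gen_timecourse_ct(spec, seed=seed)
    return {"ct": ct, "truth": truth}


def preset_figure5(seed: Optional[int] = None) -> dict:
    """RNAi behavioral cohorts: dsGFP control, effective and null knockdowns."""
    cohorts, truth = gen_behavior_cohorts(BehaviorCohortSpec(), seed=seed)
    return {"cohorts": cohorts, "truth": truth}


PRESETS = {
    "table1": preset_table1,
    "figure2": preset_figure2,
    "figure4": preset_figure4,
    "figure5": preset_figure5,
}
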