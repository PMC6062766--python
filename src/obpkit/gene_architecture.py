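"""Genomic-locus statistics for multi-exon gene models.

Computes per-gene span, exon/intron counts and lengths, the fraction of long
introns (default threshold 5 kb) and same-scaffold intergenic distances from
GFF3 gene models.  Internal coordinates are 0-based half-open; conversion
from the GFF3 1-based closed convention happens only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import gffutils
import pandas as pd

__all__ = [
    "GeneModel",
    "LocusStats",
    "MalformedModelError",
    "parse_gene_models",
    "locus_stats",
    "locus_table",
    "locus_summary",
    "intergenic_distances",
    "DEFAULT_LONG_INTRON_BP",
]

DEFAULT_LONG_INTRON_BP = 5000


class MalformedModelError(ValueError):
    """A gene model violates the single-scaffold / single-strand contract."""


@dataclass(frozen=True)
class GeneModel:
    """A gene on one scaffold with ordered, non-overlapping exon intervals.

    Exons are 0-based half-open ``[start, end)`` intervals sorted by start.
    """

    gene_id: str
    scaffold_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise MalformedModelError(f"{self.gene_id}: strand must be + or -")
        if not self.exons:
            raise MalformedModelError(f"{self.gene_id}: no exons")
        prev_end: Optional[int] = None
        for start, end in self.exons:
            if end <= start or start < 0:
                raise MalformedModelError(
                    f"{self.gene_id}: empty or negative exon [{start}, {end})"
                )
            if prev_end is not None and start < prev_end:
                raise MalformedModelError(
                    f"{self.gene_id}: exons overlap or are unsorted at [{start}, {end})"
                )
            prev_end = end

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])


@dataclass(frozen=True)
class LocusStats:
    gene_id: str
    gene_span: int
    n_exons: int
    exon_lengths: tuple[int, ...]
    intron_lengths: tuple[int, ...]
    #: proportion of introns longer than the threshold; None for 1-exon genes
    long_intron_fraction: Optional[float]


def _exons_of(db: gffutils.FeatureDB, parent_id: str) -> list[gffutils.Feature]:
    return list(db.children(parent_id, featuretype="exon", order_by="start"))


def parse_gene_models(gff_path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3; one model per gene.

    Genes with several mRNAs contribute the transcript with the largest total
    exon length.  Exons spread over multiple scaffolds or mixed strands raise
    :class:`MalformedModelError`.
    """
    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        mrnas = list(db.children(gene.id, featuretype="mRNA", order_by="start"))
        if mrnas:
            exon_sets = [(_exons_of(db, m.id), m.id) for m in mrnas]
            exon_sets = [(ex, mid) for ex, mid in exon_sets if ex]
            if not exon_sets:
                raise MalformedModelError(f"{gene.id}: mRNA(s) without exons")
            exons, _ = max(
                exon_sets, key=lambda p: (sum(e.end - e.start + 1 for e in p[0]), p[1])
            )
        else:
            exons = _exons_of(db, gene.id)
            if not exons:
                raise MalformedModelError(f"{gene.id}: no exons")
        scaffolds = {e.seqid for e in exons}
        strands = {e.strand for e in exons}
        if len(scaffolds) > 1:
            raise MalformedModelError(
                f"{gene.id}: exons on multiple scaffolds {sorted(scaffolds)}"
            )
        if len(strands) > 1:
            raise MalformedModelError(f"{gene.id}: exons on mixed strands")
        # GFF3 is 1-based closed; internal representation 0-based half-open.
        intervals = tuple(sorted((e.start - 1, e.end) for e in exons))
        models.append(
            GeneModel(
                gene_id=gene.id,
                scaffold_id=exons[0].seqid,
                strand=exons[0].strand,
                exons=intervals,
            )
        )
    return models


def locus_stats(
    model: GeneModel, long_intron_threshold: int = DEFAULT_LONG_INTRON_BP
) -> LocusStats:
    """Span, exon/intron lengths and long-intron fraction of one gene."""
    exon_lengths = tuple(end - start for start, end in model.exons)
    intron_lengths = tuple(
        model.exons[i + 1][0] - model.exons[i][1] for i in range(len(model.exons) - 1)
    )
    span = model.exons[-1][1] - model.exons[0][0]
    if intron_lengths:
        frac = sum(1 for n in intron_lengths if n > long_intron_threshold) / len(
            intron_lengths
        )
    else:
        frac = None
    return LocusStats(
        gene_id=model.gene_id,
        gene_span=span,
        n_exons=len(model.exons),
        exon_lengths=exon_lengths,
        intron_lengths=intron_lengths,
        long_intron_fraction=frac,
    )


def locus_table(
    models: Sequence[GeneModel], long_intron_threshold: int = DEFAULT_LONG_INTRON_BP
) -> pd.DataFrame:
    """Per-gene locus statistics as a DataFrame (lists comma-joined)."""
    rows = []
    for model in models:
        st = locus_stats(model, long_intron_threshold)
        rows.append(
            {
                "gene_id": st.gene_id,
                "scaffold_id": model.scaffold_id,
                "strand": model.strand,
                "gene_span": st.gene_span,
                "n_exons": st.n_exons,
                "exon_lengths": ",".join(map(str, st.exon_lengths)),
                "intron_lengths": ",".join(map(str, st.intron_lengths)),
                "long_intron_fraction": st.long_intron_fraction,
            }
        )
    return pd.DataFrame(rows)


def locus_summary(
    models: Sequence[GeneModel], long_intron_threshold: int = DEFAULT_LONG_INTRON_BP
) -> dict:
    """Family-level ranges and the pooled long-intron fraction."""
    stats = [locus_stats(m, long_intron_threshold) for m in models]
    exon_lengths = [n for s in stats for n in s.exon_lengths]
    intron_lengths = [n for s in stats for n in s.intron_lengths]
    spans = [s.gene_span for s in stats]
    n_long = sum(1 for n in intron_lengths if n > long_intron_threshold)
    return {
        "n_genes": len(models),
        "n_scaffolds": len({m.scaffold_id for m in models}),
        "gene_span_range": (min(spans), max(spans)) if spans else None,
        "exon_length_range": (min(exon_lengths), max(exon_lengths))
        if exon_lengths
        else None,
        "intron_length_range": (min(intron_lengths), max(intron_lengths))
        if intron_lengths
        else None,
        "long_intron_fraction": (n_long / len(intron_lengths))
        if intron_lengths
        else None,
        "long_intron_threshold": long_intron_threshold,
    }


def intergenic_distances(models: Sequence[GeneModel]) -> pd.DataFrame:
    """Gap (bp) between adjacent gene spans on each shared scaffold.

    Adjacency is by span start, unstranded.  Overlapping spans report a gap
    of 0 with ``overlap`` set.  Scaffolds holding a single gene contribute
    no rows.
    """
    if not models:
        raise ValueError("need at least one gene model")
    by_scaffold: dict[str, list[GeneModel]] = {}
    for m in models:
        by_scaffold.setdefault(m.scaffold_id, []).append(m)
    rows = []
    for scaffold in sorted(by_scaffold):
        genes = sorted(by_scaffold[scaffold], key=lambda m: m.span)
        for left, right in zip(genes, genes[1:]):
            gap = right.span[0] - left.span[1]
            rows.append(
                {
                    "scaffold_id": scaffold,
                    "gene_a": left.gene_id,
                    "gene_b": right.gene_id,
                    "gap_bp": max(gap, 0),
                    "overlap": gap < 0,
                }
            )
    return pd.DataFrame(
        rows, columns=["scaffold_id", "gene_a", "gene_b", "gap_bp", "overlap"]
    )
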