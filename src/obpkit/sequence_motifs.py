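"""Cysteine-architecture detection and OBP subtype classification.

Insect odorant-binding proteins (OBPs) are defined by a conserved core of six
cysteine residues (C1-C6) in the mature (signal-peptide-free) protein.  In the
locust OBP family the spacing of two of the inter-cysteine gaps is diagnostic:
exactly three residues between C2 and C3 and exactly eight residues between C5
and C6.  Subtypes are read off the cysteine content around a valid core:

* classic          -- the six-cysteine core and nothing else;
* plus-C type-A    -- three additional cysteines (C3', C4', C5') between C3
                      and C6;
* plus-C type-B    -- one additional cysteine before C1 and one after C6;
* atypical         -- an unusually long protein (default >= 200 residues)
                      carrying a valid core.

"Gap" throughout means the number of residues *strictly between* two
cysteines, so a C2-C3 gap of 3 is the pattern ``C-x-x-x-C``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "AMINO_ACIDS",
    "GapConfig",
    "DEFAULT_GAPS",
    "ProteinRecord",
    "CysteineArchitecture",
    "SubtypeCall",
    "InvalidAnnotationError",
    "SequenceParseError",
    "mature_sequence",
    "find_cysteine_architecture",
    "classify_subtype",
    "classify_record",
    "classify_fasta",
]

#: The 20 canonical amino acids; X is additionally accepted as "unknown".
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = frozenset(AMINO_ACIDS) | {"X"}

SUBTYPE_CLASSIC = "classic"
SUBTYPE_PLUS_C_A = "plus-C-type-A"
SUBTYPE_PLUS_C_B = "plus-C-type-B"
SUBTYPE_ATYPICAL = "atypical"
SUBTYPE_NON_OBP = "non-OBP"

SUBTYPES = (
    SUBTYPE_CLASSIC,
    SUBTYPE_PLUS_C_A,
    SUBTYPE_PLUS_C_B,
    SUBTYPE_ATYPICAL,
    SUBTYPE_NON_OBP,
)


class InvalidAnnotationError(ValueError):
    """A signal-peptide annotation is inconsistent with the sequence."""


class SequenceParseError(ValueError):
    """A FASTA record contains characters outside the amino-acid alphabet."""


@dataclass(frozen=True)
class GapConfig:
    """Allowed residue counts strictly between consecutive core cysteines.

    The two diagnostic gaps (C2-C3 and C5-C6) default to exact values; the
    remaining three are unconstrained by the motif definition and default to
    permissive ranges bracketing the family's alignment geometry.
    """

    c1_c2: tuple[int, int] = (15, 50)
    c2_c3: tuple[int, int] = (3, 3)
    c3_c4: tuple[int, int] = (20, 60)
    c4_c5: tuple[int, int] = (8, 30)
    c5_c6: tuple[int, int] = (8, 8)

    def ranges(self) -> tuple[tuple[int, int], ...]:
        return (self.c1_c2, self.c2_c3, self.c3_c4, self.c4_c5, self.c5_c6)

    def midpoints(self) -> tuple[float, ...]:
        return tuple((lo + hi) / 2.0 for lo, hi in self.ranges())

    def __post_init__(self) -> None:
        for lo, hi in self.ranges():
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid gap range ({lo}, {hi})")


DEFAULT_GAPS = GapConfig()

#: Protein length at and above which a valid core is called atypical.
DEFAULT_ATYPICAL_MIN_LENGTH = 200


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence with an annotated signal-peptide length."""

    id: str
    residues: str
    signal_peptide_len: int = 0

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            raise SequenceParseError(
                f"record {self.id!r}: invalid residue(s) {sorted(bad)}"
            )
        if self.signal_peptide_len < 0:
            raise InvalidAnnotationError(
                f"record {self.id!r}: negative signal-peptide length"
            )
        if self.signal_peptide_len >= len(self.residues):
            raise InvalidAnnotationError(
                f"record {self.id!r}: signal peptide ({self.signal_peptide_len}) "
                f"covers the whole sequence ({len(self.residues)} aa)"
            )

    def __len__(self) -> int:
        return len(self.residues)


def mature_sequence(record: ProteinRecord) -> str:
    """Residues with the annotated signal peptide removed from the N-terminus."""
    return record.residues[record.signal_peptide_len:]


@dataclass(frozen=True)
class CysteineArchitecture:
    """Positions (0-based, mature coordinates) of the cysteine landmarks.

    ``c_positions`` are the six core landmarks C1..C6.  Cysteines present in
    the mature sequence but not assigned to the core are reported as
    ``extra_internal`` (strictly between C3 and C6, the candidate C3'-C5'),
    ``extra_flanking`` (the nearest cysteine before C1 and after C6, if any)
    or ``extra_other`` (anything else, e.g. between C1 and C3 or additional
    flanking cysteines beyond the nearest).
    """

    c_positions: tuple[int, int, int, int, int, int]
    extra_internal: tuple[int, ...] = ()
    extra_flanking: tuple[Optional[int], Optional[int]] = (None, None)
    extra_other: tuple[int, ...] = ()

    @property
    def gaps(self) -> tuple[int, int, int, int, int]:
        """Residue counts strictly between consecutive core cysteines."""
        c = self.c_positions
        return tuple(c[i + 1] - c[i] - 1 for i in range(5))  # type: ignore[return-value]

    def n_extras(self) -> int:
        flanks = sum(1 for f in self.extra_flanking if f is not None)
        return len(self.extra_internal) + flanks + len(self.extra_other)


def _candidate_assignments(
    cys: Sequence[int], config: GapConfig
) -> Iterable[tuple[int, ...]]:
    """Yield all 6-tuples of cysteine positions satisfying the gap ranges.

    Nested loops with range pruning; equivalent to filtering all 6-subsets.
    """
    (g1, g2, g3, g4, g5) = config.ranges()

    def ok(lo_hi: tuple[int, int], a: int, b: int) -> bool:
        gap = b - a - 1
        return lo_hi[0] <= gap <= lo_hi[1]

    for c2, c3 in itertools.combinations(cys, 2):
        if not ok(g2, c2, c3):
            continue
        for c1 in cys:
            if c1 >= c2 or not ok(g1, c1, c2):
                continue
            for c4 in cys:
                if c4 <= c3 or not ok(g3, c3, c4):
                    continue
                for c5 in cys:
                    if c5 <= c4 or not ok(g4, c4, c5):
                        continue
                    for c6 in cys:
                        if c6 <= c5 or not ok(g5, c5, c6):
                            continue
                        yield (c1, c2, c3, c4, c5, c6)


def _assignment_score(core: Sequence[int], config: GapConfig) -> float:
    """Total absolute deviation of non-fixed gaps from their range midpoints."""
    mids = config.midpoints()
    score = 0.0
    for i, (lo, hi) in enumerate(config.ranges()):
        if lo == hi:
            continue  # fixed gap carries no preference
        gap = core[i + 1] - core[i] - 1
        score += abs(gap - mids[i])
    return score


def find_cysteine_architecture(
    mature: str, config: GapConfig = DEFAULT_GAPS
) -> Optional[CysteineArchitecture]:
    """Best assignment of six cysteines to the C1-C6 landmarks, or ``None``.

    Among all assignments satisfying the gap constraints the one minimising
    the total deviation of the unconstrained gaps from their range midpoints
    is chosen; ties break to the leftmost C1, then lexicographically.
    """
    if not mature:
        raise ValueError("empty mature sequence")
    cys = [i for i, aa in enumerate(mature) if aa == "C"]
    if len(cys) < 6:
        return None

    best: Optional[tuple[int, ...]] = None
    best_key: Optional[tuple[float, tuple[int, ...]]] = None
    for core in _candidate_assignments(cys, config):
        key = (_assignment_score(core, config), core)
        if best_key is None or key < best_key:
            best_key = key
            best = core
    if best is None:
        return None

    assigned = set(best)
    c1, c3, c6 = best[0], best[2], best[5]
    unassigned = [p for p in cys if p not in assigned]
    internal = tuple(p for p in unassigned if c3 < p < c6)
    before = [p for p in unassigned if p < c1]
    after = [p for p in unassigned if p > c6]
    flank_before = max(before) if before else None
    flank_after = min(after) if after else None
    claimed = set(internal) | {flank_before, flank_after}
    other = tuple(p for p in unassigned if p not in claimed)
    return CysteineArchitecture(
        c_positions=best,  # type: ignore[arg-type]
        extra_internal=internal,
        extra_flanking=(flank_before, flank_after),
        extra_other=other,
    )


@dataclass(frozen=True)
class SubtypeCall:
    """A subtype assignment together with the rules that produced it."""

    subtype: str
    architecture: Optional[CysteineArchitecture]
    rationale: str

    def __post_init__(self) -> None:
        if (self.subtype == SUBTYPE_NON_OBP) != (self.architecture is None):
            raise ValueError("non-OBP call must (only) lack an architecture")


def classify_subtype(
    record: ProteinRecord,
    architecture: Optional[CysteineArchitecture],
    atypical_min_length: int = DEFAULT_ATYPICAL_MIN_LENGTH,
) -> SubtypeCall:
    """Assign an OBP subtype from a detected cysteine architecture.

    Precedence on a valid core: atypical (protein length at or above the
    threshold, regardless of extras) > plus-C type-A (exactly three internal
    extras) > plus-C type-B (both flanking extras, no internal ones) >
    classic.  Extra-cysteine patterns matching none of these fall through to
    classic, with the unmatched extras noted in the rationale.
    """
    if architecture is None:
        return SubtypeCall(SUBTYPE_NON_OBP, None, "no C1-C6 architecture found")

    length = len(record.residues)
    flank_before, flank_after = architecture.extra_flanking
    n_internal = len(architecture.extra_internal)

    if length >= atypical_min_length:
        return SubtypeCall(
            SUBTYPE_ATYPICAL,
            architecture,
            f"valid core and protein length {length} >= {atypical_min_length}",
        )
    if n_internal == 3:
        return SubtypeCall(
            SUBTYPE_PLUS_C_A,
            architecture,
            "valid core with three internal extra cysteines (C3', C4', C5')",
        )
    if flank_before is not None and flank_after is not None and n_internal == 0:
        return SubtypeCall(
            SUBTYPE_PLUS_C_B,
            architecture,
            "valid core with one extra cysteine before C1 and one after C6",
        )
    if architecture.n_extras() == 0:
        return SubtypeCall(
            SUBTYPE_CLASSIC, architecture, "valid six-cysteine core, no extras"
        )
    return SubtypeCall(
        SUBTYPE_CLASSIC,
        architecture,
        "valid core; extra cysteines match no plus-C pattern "
        f"(internal={n_internal}, flanking={architecture.extra_flanking}, "
        f"other={len(architecture.extra_other)}) -- classified classic by precedence",
    )


def classify_record(
    record: ProteinRecord,
    config: GapConfig = DEFAULT_GAPS,
    atypical_min_length: int = DEFAULT_ATYPICAL_MIN_LENGTH,
) -> SubtypeCall:
    """Convenience: mature sequence -> architecture -> subtype in one step."""
    arch = find_cysteine_architecture(mature_sequence(record), config)
    return classify_subtype(record, arch, atypical_min_length)


def read_signal_peptide_table(path: str | Path) -> dict[str, int]:
    """Read a TSV of (id, signal_peptide_len) annotations."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if not {"id", "signal_peptide_len"} <= set(df.columns):
        raise ValueError(
            f"{path}: annotation table needs columns 'id' and 'signal_peptide_len'"
        )
    return dict(zip(df["id"], df["signal_peptide_len"].astype(int)))


def classify_fasta(
    path: str | Path,
    annotations: Optional[Mapping[str, int] | str | Path] = None,
    config: GapConfig = DEFAULT_GAPS,
    atypical_min_length: int = DEFAULT_ATYPICAL_MIN_LENGTH,
) -> pd.DataFrame:
    """Classify every record of a protein FASTA; one row per record, in order.

    ``annotations`` maps record id to signal-peptide length (ids absent from
    the table default to 0).  Raises :class:`SequenceParseError` naming the
    offending record on non-amino-acid characters.
    """
    if annotations is None:
        sp_table: Mapping[str, int] = {}
    elif isinstance(annotations, (str, Path)):
        sp_table = read_signal_peptide_table(annotations)
    else:
        sp_table = annotations

    rows = []
    for seqrec in SeqIO.parse(str(path), "fasta"):
        record = ProteinRecord(
            id=seqrec.id,
            residues=str(seqrec.seq).upper(),
            signal_peptide_len=int(sp_table.get(seqrec.id, 0)),
        )
        call = classify_record(record, config, atypical_min_length)
        cpos = (
            ",".join(str(p) for p in call.architecture.c_positions)
            if call.architecture
            else ""
        )
        rows.append(
            {
                "id": record.id,
                "length": len(record.residues),
                "signal_peptide_len": record.signal_peptide_len,
                "subtype": call.subtype,
                "c_positions": cpos,
                "rationale": call.rationale,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "id",
            "length",
            "signal_peptide_len",
            "subtype",
            "c_positions",
            "rationale",
        ],
    )
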