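"""Published catalog of the 17 Locusta migratoria OBPs.

Per-protein attributes of the locust OBP family as reported for the
L. migratoria genome: protein length (aa), predicted signal-peptide length
(aa; 0 = none predicted) and cysteine-architecture subtype.  These printed
values parameterise the synthetic sequence generator and serve as the
reference census for the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

from .sequence_motifs import (
    SUBTYPE_ATYPICAL,
    SUBTYPE_CLASSIC,
    SUBTYPE_PLUS_C_A,
    SUBTYPE_PLUS_C_B,
)

__all__ = ["CatalogEntry", "LOCUST_OBP_CATALOG", "catalog_census"]


@dataclass(frozen=True)
class CatalogEntry:
    name: str
    protein_length: int
    signal_peptide_len: int
    subtype: str


LOCUST_OBP_CATALOG: tuple[CatalogEntry, ...] = (
    CatalogEntry("LmigOBP1", 152, 21, SUBTYPE_CLASSIC),
    CatalogEntry("LmigOBP2", 124, 0, SUBTYPE_CLASSIC),
    CatalogEntry("LmigOBP3", 133, 0, SUBTYPE_PLUS_C_A),
    CatalogEntry("LmigOBP4", 154, 18, SUBTYPE_PLUS_C_A),
    CatalogEntry("LmigOBP5", 151, 25, SUBTYPE_CLASSIC),
    CatalogEntry("LmigOBP6", 166, 16, SUBTYPE_PLUS_C_B),
    CatalogEntry("LmigOBP7", 134, 0, SUBTYPE_PLUS_C_A),
    CatalogEntry("LmigOBP8", 157, 21, SUBTYPE_CLASSIC),
    CatalogEntry("LmigOBP9", 145, 24, SUBTYPE_CLASSIC),
    CatalogEntry("LmigOBP10", 133, 0, SUBTYPE_CLASSIC),
    CatalogEntry("LmigOBP11", 134, 23, SUBTYPE_PLUS_C_A),
    CatalogEntry("LmigOBP12", 159, 18, SUBTYPE_CLASSIC),
    CatalogEntry("LmigOBP13", 158, 34, SUBTYPE_CLASSIC),
    CatalogEntry("LmigOBP14", 138, 25, SUBTYPE_CLASSIC),
    CatalogEntry("LmigOBP15", 138, 23, SUBTYPE_CLASSIC),
    CatalogEntry("LmigOBP16", 271, 22, SUBTYPE_ATYPICAL),
    CatalogEntry("LmigOBP17", 138, 19, SUBTYPE_CLASSIC),
)


def catalog_census() -> dict[str, int]:
    """Subtype counts over the published catalog."""
    census: dict[str, int] = {}
    for entry in LOCUST_OBP_CATALOG:
        census[entry.subtype] = census.get(entry.subtype, 0) + 1
    return census
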