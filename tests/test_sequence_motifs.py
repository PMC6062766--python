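"""Cysteine-architecture detection and subtype classification."""

import numpy as np
import pytest

from obpkit.sequence_motifs import (
    DEFAULT_GAPS,
    SUBTYPE_ATYPICAL,
    SUBTYPE_CLASSIC,
    SUBTYPE_NON_OBP,
    SUBTYPE_PLUS_C_A,
    SUBTYPE_PLUS_C_B,
    GapConfig,
    InvalidAnnotationError,
    ProteinRecord,
    SequenceParseError,
    classify_fasta,
    classify_record,
    classify_subtype,
    find_cysteine_architecture,
    mature_sequence,
)
from obpkit.synthetic_data import (
    ProteinEntry,
    catalog_entries,
    gen_proteins,
    random_protein_entries,
    write_fasta,
    write_sp_table,
)

from _oracles import brute_force_core

#: permissive ranges for hand-built short sequences
LOOSE = GapConfig(c1_c2=(0, 60), c3_c4=(0, 60), c4_c5=(0, 60))


def motif(gaps, pre="", post=""):
    """Sequence with six cysteines separated by the given gap sizes."""
    out = pre + "C"
    for g in gaps:
        out += "A" * g + "C"
    return out + post


class TestMatureSequence:
    def test_no_signal_peptide_is_identity(self):
        rec = ProteinRecord("p", "MKLAVLA", 0)
        assert mature_sequence(rec) == "MKLAVLA"

    def test_removes_annotated_prefix(self):
        # 152-residue protein with a 21-residue signal peptide -> 131 mature
        rec = ProteinRecord("p", "M" + "A" * 151, 21)
        assert len(mature_sequence(rec)) == 131
        assert mature_sequence(rec) == "A" * 131

    def test_signal_peptide_covering_sequence_rejected(self):
        with pytest.raises(InvalidAnnotationError):
            ProteinRecord("p", "MKLA", 4)

    def test_invalid_residue_rejected(self):
        with pytest.raises(SequenceParseError):
            ProteinRecord("p", "MK1A")


class TestFindArchitecture:
    def test_planted_motif_found_with_diagnostic_gaps(self):
        seq = "AA" + motif([2, 3, 5, 2, 8]) + "AA"
        arch = find_cysteine_architecture(seq, LOOSE)
        assert arch is not None
        assert arch.gaps == (2, 3, 5, 2, 8)
        assert arch.n_extras() == 0

    def test_five_cysteines_is_no_architecture(self):
        seq = motif([2, 3, 5, 2, 8]).replace("C", "A", 1)
        assert find_cysteine_architecture(seq, LOOSE) is None

    def test_wrong_diagnostic_gap_is_no_architecture(self):
        # C2-C3 gap of 4 instead of the required 3
        seq = motif([2, 4, 5, 2, 8])
        assert find_cysteine_architecture(seq, LOOSE) is None

    def test_extra_internal_cysteines_reported(self):
        # classic core with gaps (2,3,12,2,8); three extra C's in the C3-C4 gap
        seq = list(motif([2, 3, 12, 2, 8]))
        c3 = seq.index("C", seq.index("C", seq.index("C") + 1) + 1)
        # place extras avoiding spacings of 4 or 9 to any landmark
        for off in (2, 5, 7):
            assert seq[c3 + off] == "A"
            seq[c3 + off] = "C"
        arch = find_cysteine_architecture("".join(seq), LOOSE)
        assert arch is not None
        assert len(arch.extra_internal) == 3
        assert arch.gaps[1] == 3 and arch.gaps[4] == 8

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_exhaustive_subset_search(self, seed):
        """On short sequences the search equals brute force over 6-subsets."""
        rng = np.random.default_rng(seed)
        length = int(rng.integers(30, 61))
        seq = "".join(rng.choice(list("AC"), size=length, p=[0.72, 0.28]))
        arch = find_cysteine_architecture(seq, LOOSE)
        expected = brute_force_core(seq, LOOSE.ranges(), LOOSE.midpoints())
        if expected is None:
            assert arch is None
        else:
            assert arch is not None and arch.c_positions == expected


class TestClassifySubtype:
    def _call(self, record, config=DEFAULT_GAPS):
        arch = find_cysteine_architecture(mature_sequence(record), config)
        return classify_subtype(record, arch)

    def test_four_planted_subtypes(self):
        entries = [
            ProteinEntry("classic", SUBTYPE_CLASSIC, 124, 0),
            ProteinEntry("plusA", SUBTYPE_PLUS_C_A, 154, 18),
            ProteinEntry("plusB", SUBTYPE_PLUS_C_B, 166, 16),
            ProteinEntry("atypical", SUBTYPE_ATYPICAL, 271, 22),
        ]
        records, _ = gen_proteins(entries, seed=0, validate=False)
        for record, entry in zip(records, entries):
            assert self._call(record).subtype == entry.subtype

    def test_no_architecture_is_non_obp(self):
        rec = ProteinRecord("p", "MKLAVLAGLLAVSEA")
        call = self._call(rec)
        assert call.subtype == SUBTYPE_NON_OBP
        assert call.architecture is None

    def test_atypical_takes_precedence_over_extras(self):
        # long protein whose extras would otherwise mean plus-C type-A
        entry = ProteinEntry("x", SUBTYPE_PLUS_C_A, 260, 0)
        (rec,), _ = gen_proteins([entry], seed=1, validate=False)
        assert self._call(rec).subtype == SUBTYPE_ATYPICAL

    def test_removing_any_landmark_cysteine_gives_non_obp(self):
        (rec,), truth = gen_proteins(
            [ProteinEntry("c", SUBTYPE_CLASSIC, 140, 0)], seed=2
        )
        core = [int(p) for p in truth.loc[0, "c_positions"].split(",")]
        for pos in core:
            residues = rec.residues[:pos] + "A" + rec.residues[pos + 1:]
            mutant = ProteinRecord("c", residues)
            assert self._call(mutant).subtype == SUBTYPE_NON_OBP

    def test_invariant_to_non_cysteine_substitutions(self):
        rng = np.random.default_rng(3)
        entries = random_protein_entries(
            {SUBTYPE_CLASSIC: 3, SUBTYPE_PLUS_C_A: 3}, seed=4
        )
        records, _ = gen_proteins(entries, seed=5)
        for rec in records:
            before = classify_record(rec).subtype
            residues = list(rec.residues)
            non_c = [i for i, aa in enumerate(residues) if aa != "C"]
            for i in rng.choice(non_c, size=20, replace=False):
                choices = [aa for aa in "ADEFGHIKLMNPQRSTVWY" if aa != residues[i]]
                residues[i] = choices[int(rng.integers(len(choices)))]
            mutant = ProteinRecord(rec.id, "".join(residues), rec.signal_peptide_len)
            assert classify_record(mutant).subtype == before


class TestPlantedRoundTrip:
    def test_all_subtypes_recovered_exactly(self):
        """100 planted sequences per subtype classify back to their subtype."""
        counts = {
            SUBTYPE_CLASSIC: 100,
            SUBTYPE_PLUS_C_A: 100,
            SUBTYPE_PLUS_C_B: 100,
            SUBTYPE_ATYPICAL: 100,
        }
        entries = random_protein_entries(counts, seed=10)
        records, _ = gen_proteins(entries, seed=11, validate=False)
        hits = sum(
            classify_record(r).subtype == e.subtype
            for r, e in zip(records, entries)
        )
        assert hits == len(entries)


class TestClassifyFasta:
    def test_catalog_fasta_round_trip(self, tmp_path):
        records, truth = gen_proteins(catalog_entries(), seed=6)
        fasta = tmp_path / "p.fasta"
        sp = tmp_path / "sp.tsv"
        write_fasta(records, fasta)
        write_sp_table(records, sp)
        table = classify_fasta(fasta, sp)
        assert list(table["id"]) == list(truth["id"])  # input order preserved
        assert list(table["subtype"]) == list(truth["subtype"])
        assert list(table["signal_peptide_len"]) == list(
            truth["signal_peptide_len"]
        )

    def test_empty_fasta_gives_empty_table(self, tmp_path):
        fasta = tmp_path / "empty.fasta"
        fasta.write_text("")
        table = classify_fasta(fasta)
        assert len(table) == 0

    def test_bad_residue_names_the_record(self, tmp_path):
        fasta = tmp_path / "bad.fasta"
        fasta.write_text(">ok\nMKLA\n>broken\nMK1A\n")
        with pytest.raises(SequenceParseError, match="broken"):
            classify_fasta(fasta)
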