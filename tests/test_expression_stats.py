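"""qPCR normalization, letter displays, pattern and responder calls."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from obpkit.expression_stats import (
    InsufficientReplicationError,
    MissingReferenceError,
    assign_tissue_pattern,
    classify_time_course,
    compact_letter_display,
    phase_ttests,
    relative_expression,
    time_course_table,
    tissue_anova_letters,
    tissue_profile_table,
)
from obpkit.synthetic_data import (
    TimeCourseCtSpec,
    TissueCtSpec,
    gen_timecourse_ct,
    gen_tissue_ct,
)

from _oracles import clique_letter_columns


def ct_row(sample, gene, ct, **meta):
    return {"sample_id": sample, "gene_id": gene, "ct": ct, **meta}


class TestRelativeExpression:
    def test_equal_ct_gives_unity(self):
        df = pd.DataFrame([ct_row("s1", "rp49", 16.0), ct_row("s1", "g", 16.0)])
        out = relative_expression(df)
        assert out.loc[out["gene_id"] == "g", "rel_expr"].item() == 1.0

    def test_one_cycle_doubles(self):
        df = pd.DataFrame([ct_row("s1", "rp49", 16.0), ct_row("s1", "g", 15.0)])
        out = relative_expression(df)
        assert out.loc[out["gene_id"] == "g", "rel_expr"].item() == 2.0

    def test_reference_maps_to_one_in_every_sample(self):
        ct, _ = gen_tissue_ct(TissueCtSpec(), seed=1)
        out = relative_expression(ct)
        ref = out[out["gene_id"] == "rp49"]["rel_expr"]
        assert np.allclose(ref, 1.0)

    def test_missing_reference_names_the_sample(self):
        df = pd.DataFrame([ct_row("s1", "rp49", 16.0), ct_row("s2", "g", 15.0)])
        with pytest.raises(MissingReferenceError, match="s2"):
            relative_expression(df)

    def test_planted_fold_change_recovered(self):
        spec = TissueCtSpec(genes={"g": "antenna-rich"}, fold=8.0, cv=0.05)
        ct, _ = gen_tissue_ct(spec, seed=2)
        out = relative_expression(ct)
        g = out[(out["gene_id"] == "g") & (out["phase"] == "gregarious")]
        ant = g[g["tissue"] == "antenna"]["rel_expr"].mean()
        wing = g[g["tissue"] == "wing"]["rel_expr"].mean()
        assert ant / wing == pytest.approx(8.0, rel=0.25)


class TestCompactLetterDisplay:
    def test_no_significance_is_single_letter(self):
        letters = compact_letter_display(list("ABCDE"), set())
        assert set(letters.values()) == {"a"}

    def test_one_group_fully_separated(self):
        groups = list("ABCDE")
        sig = {frozenset({"A", g}) for g in "BCDE"}
        letters = compact_letter_display(groups, sig)
        assert letters["A"] == "a"
        assert all("a" not in letters[g] for g in "BCDE")
        assert len({letters[g] for g in "BCDE"}) == 1

    def test_every_five_group_pattern_satisfies_sharing_rule(self):
        """Exhaustive oracle: over all 1024 significance graphs on 5 groups,
        two groups share a letter iff their comparison is not significant,
        and each letter column is a clique of the non-significance graph."""
        groups = list("ABCDE")
        pairs = list(itertools.combinations(groups, 2))
        for mask in range(1 << len(pairs)):
            sig = {
                frozenset(p) for k, p in enumerate(pairs) if mask & (1 << k)
            }
            letters = compact_letter_display(groups, sig)
            for g1, g2 in pairs:
                shares = bool(set(letters[g1]) & set(letters[g2]))
                assert shares == (frozenset({g1, g2}) not in sig), (mask, letters)
            cliques = clique_letter_columns(groups, sig)
            for ch in set("".join(letters.values())):
                column = frozenset(g for g in groups if ch in letters[g])
                assert any(column <= c for c in cliques)


class TestTissueAnova:
    def _frame(self, data):
        rows = []
        for tissue, values in data.items():
            for v in values:
                rows.append({"tissue": tissue, "rel_expr": v})
        return pd.DataFrame(rows)

    def test_one_elevated_tissue_holds_top_letter_alone(self):
        rng = np.random.default_rng(3)
        data = {"antenna": 10 + 0.1 * rng.standard_normal(4)}
        for t in ("labial_palp", "brain", "wing", "hind_leg"):
            data[t] = 1 + 0.1 * rng.standard_normal(4)
        disp = tissue_anova_letters(self._frame(data))
        assert disp.letters["antenna"] == "a"
        assert all("a" not in disp.letters[t] for t in disp.groups[1:])

    def test_zero_variance_gives_shared_letter_with_note(self):
        data = {t: [2.0, 2.0] for t in ("a", "b", "c")}
        disp = tissue_anova_letters(self._frame(data))
        assert set(disp.letters.values()) == {"a"}
        assert "degenerate" in disp.note

    def test_single_replicate_rejected(self):
        data = {"a": [1.0], "b": [1.0, 2.0]}
        with pytest.raises(InsufficientReplicationError):
            tissue_anova_letters(self._frame(data))


class TestPhaseTtests:
    def _frame(self, g, s):
        rows = [{"phase": "gregarious", "rel_expr": v} for v in g]
        rows += [{"phase": "solitarious", "rel_expr": v} for v in s]
        return pd.DataFrame(rows)

    def test_identical_groups_give_null_result(self):
        t, p = phase_ttests(self._frame([1, 2, 3, 4], [1, 2, 3, 4]))
        assert t == 0.0 and p == 1.0

    def test_large_shift_is_significant(self):
        t, p = phase_ttests(self._frame([1, 2, 3, 4], [11, 12, 13, 14]))
        assert p < 0.01

    def test_matches_permutation_reference(self):
        """The t statistic's two-sided p agrees with an exhaustive
        permutation test at the resolution the permutation null allows."""
        x = [1.0, 3.0, 4.5, 6.0]
        y = [2.0, 7.0, 8.0, 9.0]
        t_obs, _ = phase_ttests(self._frame(x, y))
        pooled = np.array(x + y)
        count = 0
        total = 0
        for idx in itertools.combinations(range(8), 4):
            a = pooled[list(idx)]
            b = pooled[[i for i in range(8) if i not in idx]]
            t, _ = stats.ttest_ind(a, b)
            total += 1
            if abs(t) >= abs(t_obs) - 1e-12:
                count += 1
        _, p_model = phase_ttests(self._frame(x, y))
        assert abs(p_model - count / total) < 0.15


class TestTissuePatterns:
    @pytest.mark.parametrize(
        "pattern",
        [
            "antenna-rich",
            "labial-palp-rich",
            "antenna-and-labial-palp-rich",
            "brain-rich",
            "multi-tissue",
        ],
    )
    def test_planted_pattern_recovered(self, pattern):
        ct, _ = gen_tissue_ct(TissueCtSpec(genes={"g": pattern}), seed=4)
        table = tissue_profile_table(ct)
        assert table.loc[0, "pattern"] == pattern

    def test_conflicting_phases_logged(self):
        disp = {}
        for phase, rich in (("gregarious", "antenna"), ("solitarious", "labial_palp")):
            rng = np.random.default_rng(5)
            data = []
            for t in ("antenna", "labial_palp", "brain", "wing", "hind_leg"):
                mean = 10.0 if t == rich else 1.0
                for v in mean + 0.1 * rng.standard_normal(4):
                    data.append({"tissue": t, "rel_expr": v})
            disp[phase] = tissue_anova_letters(pd.DataFrame(data))
        call = assign_tissue_pattern("g", disp)
        assert call.pattern == "antenna-and-labial-palp-rich"
        assert "conflict" in call.note


class TestTimeCourse:
    def test_planted_reverse_pattern_is_responder(self):
        spec = TimeCourseCtSpec(responders=("g",), flats=())
        ct, _ = gen_timecourse_ct(spec, seed=6)
        table = time_course_table(ct)
        assert table.loc[0, "class"] == "responder"
        assert table.loc[0, "direction_IG"] == -1
        assert table.loc[0, "direction_CS"] == 1

    def test_flat_series_is_non_responder(self):
        spec = TimeCourseCtSpec(responders=(), flats=("g",))
        ct, _ = gen_timecourse_ct(spec, seed=7)
        table = time_course_table(ct)
        assert table.loc[0, "class"] == "non-responder"

    def test_single_process_significance_is_not_enough(self):
        rng = np.random.default_rng(1)
        rows = []
        for process in ("IG", "CS"):
            for t in (0, 4, 8, 16):
                mean = 1.0 + (t / 16.0 if process == "CS" else 0.0)
                for rep, v in enumerate(mean + 0.02 * rng.standard_normal(4)):
                    rows.append(
                        {"process": process, "time_h": t, "rel_expr": v}
                    )
        cls = classify_time_course("g", pd.DataFrame(rows))
        assert cls.p_values["CS"] < 0.05 <= cls.p_values["IG"]
        assert not cls.responder

    def test_missing_time_point_rejected(self):
        rows = [
            {"process": p, "time_h": t, "rel_expr": v}
            for p in ("IG", "CS")
            for t in (0, 4, 8)
            for v in (1.0, 1.1, 0.9, 1.05)
        ]
        with pytest.raises(InsufficientReplicationError):
            classify_time_course("g", pd.DataFrame(rows))
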