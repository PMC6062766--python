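"""qRT-PCR expression normalization and expression-pattern classification.

Replicate-level Ct measurements are normalized to a reference gene (ribosomal
protein 49 by default) with the delta-Ct method, ``expr = 2^(Ct_ref - Ct)``.
Downstream, two classifications reproduce the family-level readouts:

* **tissue patterns** -- one-way ANOVA across five tissues followed by all-
  pairs Tukey HSD and a compact letter display per phase; a gene is called
  "rich" in the tissue set that exclusively carries the top letter in both
  phases (antenna-rich, labial-palp-rich, antenna-and-labial-palp-rich,
  brain-rich, otherwise multi-tissue);
* **time-course responders** -- one-way ANOVA over the 0/4/8/16 h time
  points within each of the two phase-change processes (IG: isolation of
  gregarious; CS: crowding of solitarious); a responder must be significant
  in *both* processes with opposite directions of change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "TISSUES",
    "PATTERNS",
    "relative_expression",
    "compact_letter_display",
    "tissue_anova_letters",
    "LetterDisplay",
    "phase_ttests",
    "assign_tissue_pattern",
    "TissuePattern",
    "classify_time_course",
    "TimeCourseClass",
    "tissue_profile_table",
    "time_course_table",
    "InsufficientReplicationError",
    "MissingReferenceError",
]

TISSUES = ("antenna", "labial_palp", "brain", "wing", "hind_leg")
PHASES = ("gregarious", "solitarious")
PROCESSES = ("IG", "CS")
TIME_POINTS = (0, 4, 8, 16)

PATTERN_ANTENNA = "antenna-rich"
PATTERN_PALP = "labial-palp-rich"
PATTERN_ANTENNA_PALP = "antenna-and-labial-palp-rich"
PATTERN_BRAIN = "brain-rich"
PATTERN_MULTI = "multi-tissue"
PATTERNS = (
    PATTERN_ANTENNA,
    PATTERN_PALP,
    PATTERN_ANTENNA_PALP,
    PATTERN_BRAIN,
    PATTERN_MULTI,
)

_NAMED_SETS = {
    frozenset({"antenna"}): PATTERN_ANTENNA,
    frozenset({"labial_palp"}): PATTERN_PALP,
    frozenset({"antenna", "labial_palp"}): PATTERN_ANTENNA_PALP,
    frozenset({"brain"}): PATTERN_BRAIN,
}


class MissingReferenceError(ValueError):
    """A sample lacks the reference-gene Ct needed for normalization."""


class InsufficientReplicationError(ValueError):
    """Fewer replicates than the test requires."""


def relative_expression(ct: pd.DataFrame, ref_gene: str = "rp49") -> pd.DataFrame:
    """Delta-Ct normalization: ``rel_expr = 2^(Ct_ref - Ct)`` per sample.

    ``ct`` is long-format with at least ``sample_id``, ``gene_id`` and ``ct``
    columns; metadata columns are carried through.  The reference gene maps
    to exactly 1 in every sample.
    """
    required = {"sample_id", "gene_id", "ct"}
    if not required <= set(ct.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    dup = ct.duplicated(subset=["sample_id", "gene_id"])
    if dup.any():
        pair = ct.loc[dup, ["sample_id", "gene_id"]].iloc[0]
        raise ValueError(
            f"duplicate (sample, gene) measurement: {tuple(pair)}"
        )
    ref = ct[ct["gene_id"] == ref_gene].set_index("sample_id")["ct"]
    missing = sorted(set(ct["sample_id"]) - set(ref.index))
    if missing:
        raise MissingReferenceError(
            f"reference gene {ref_gene!r} missing in sample(s): {missing}"
        )
    out = ct.copy()
    out["rel_expr"] = np.exp2(
        out["sample_id"].map(ref).to_numpy() - out["ct"].to_numpy()
    )
    return out


# ---------------------------------------------------------------------------
# Compact letter display
# ---------------------------------------------------------------------------


def compact_letter_display(
    groups: Sequence[str], significant_pairs: set[frozenset[str]]
) -> dict[str, str]:
    """Letters such that two groups share a letter iff not significantly different.

    ``groups`` must be ordered by decreasing mean so that the top group
    carries letter ``a``.  Insert-and-absorb algorithm: start from one column
    holding all groups; each significant pair splits every column containing
    both; columns that become subsets of others are absorbed.
    """
    columns: list[set[str]] = [set(groups)]
    for pair in sorted(significant_pairs, key=lambda p: sorted(p)):
        g1, g2 = sorted(pair)
        for col in [c for c in columns if g1 in c and g2 in c]:
            columns.remove(col)
            columns.extend((col - {g1}, col - {g2}))
        # absorb columns contained in another
        columns = [
            c
            for i, c in enumerate(columns)
            if c
            and not any(c < d or (c == d and i > j) for j, d in enumerate(columns))
        ]
    # order letters by the best-ranked group each column contains
    rank = {g: i for i, g in enumerate(groups)}
    columns.sort(key=lambda c: (min(rank[g] for g in c), sorted(rank[g] for g in c)))
    letters = {g: "" for g in groups}
    for i, col in enumerate(columns):
        ch = chr(ord("a") + i)
        for g in groups:
            if g in col:
                letters[g] += ch
    return letters


@dataclass(frozen=True)
class LetterDisplay:
    """Per-group letters with the ANOVA behind them, groups by mean desc."""

    groups: tuple[str, ...]
    means: dict[str, float]
    letters: dict[str, str]
    f_statistic: float
    p_value: float
    note: str = ""


def tissue_anova_letters(
    expr: pd.DataFrame,
    value_col: str = "rel_expr",
    group_col: str = "tissue",
    alpha: float = 0.05,
) -> LetterDisplay:
    """One-way ANOVA across groups, Tukey HSD all pairs, compact letters.

    Requires >= 2 replicates per group.  With zero variance everywhere the
    groups share a single letter and the display carries a degenerate-data
    note.
    """
    samples = {
        g: sub[value_col].to_numpy(dtype=float)
        for g, sub in expr.groupby(group_col, sort=False)
    }
    for g, x in samples.items():
        if len(x) < 2:
            raise InsufficientReplicationError(
                f"group {g!r} has {len(x)} replicate(s); need >= 2"
            )
    means = {g: float(np.mean(x)) for g, x in samples.items()}
    order = tuple(sorted(samples, key=lambda g: -means[g]))
    values = np.concatenate([samples[g] for g in order])

    if np.allclose(values, values[0]):
        return LetterDisplay(
            groups=order,
            means=means,
            letters={g: "a" for g in order},
            f_statistic=float("nan"),
            p_value=float("nan"),
            note="degenerate data: zero variance in every group",
        )

    f_stat, p_val = stats.f_oneway(*(samples[g] for g in order))
    labels = np.concatenate([[g] * len(samples[g]) for g in order])
    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    g1s, g2s = _tukey_pairs(tukey)
    sig_pairs: set[frozenset[str]] = set()
    for g1, g2, reject in zip(g1s, g2s, tukey.reject):
        if reject:
            sig_pairs.add(frozenset({g1, g2}))
    letters = compact_letter_display(order, sig_pairs)
    return LetterDisplay(
        groups=order,
        means=means,
        letters=letters,
        f_statistic=float(f_stat),
        p_value=float(p_val),
    )


def _tukey_pairs(tukey) -> tuple[list[str], list[str]]:
    """Group-name pairs of a statsmodels Tukey result, in result order."""
    frame = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    return list(frame["group1"]), list(frame["group2"])


def phase_ttests(
    expr: pd.DataFrame,
    group_col: str = "phase",
    value_col: str = "rel_expr",
    welch: bool = False,
) -> tuple[float, float]:
    """Two-sample two-sided t-test between the two phase groups.

    Classical Student's t (pooled variance) by default; Welch behind a flag.
    """
    groups = [sub[value_col].to_numpy(dtype=float) for _, sub in expr.groupby(group_col)]
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups in {group_col!r}")
    if min(len(g) for g in groups) < 2:
        raise InsufficientReplicationError("need >= 2 replicates per phase")
    if np.allclose(np.concatenate(groups), groups[0][0]):
        return 0.0, 1.0
    t, p = stats.ttest_ind(groups[0], groups[1], equal_var=not welch)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# Tissue-pattern assignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TissuePattern:
    gene_id: str
    pattern: str
    top_sets: dict[str, frozenset[str]]
    note: str = ""


def _top_letter_set(display: LetterDisplay) -> frozenset[str]:
    """Tissues carrying the letter of the highest-mean tissue ('a')."""
    return frozenset(g for g in display.groups if "a" in display.letters[g])


def assign_tissue_pattern(
    gene_id: str, displays: dict[str, LetterDisplay]
) -> TissuePattern:
    """Reconcile per-phase top-letter separation into one of five patterns.

    Per phase, the "top set" is the set of tissues statistically tied with
    the highest mean (those carrying letter ``a``).  If no tissue separates
    (the top set is all tissues) in either phase the gene is multi-tissue.
    Matching top sets map directly to a named pattern; conflicting phases
    fall back to the union of the two top sets (the largest phase-consistent
    set), logged in the note.
    """
    top = {phase: _top_letter_set(d) for phase, d in displays.items()}
    n_tissues = {phase: len(d.groups) for phase, d in displays.items()}
    sets = list(top.values())
    if any(len(s) == n_tissues[ph] for ph, s in top.items()):
        return TissuePattern(gene_id, PATTERN_MULTI, top,
                             "no tissue separates from the rest in >=1 phase")
    if all(s == sets[0] for s in sets):
        pattern = _NAMED_SETS.get(sets[0], PATTERN_MULTI)
        note = "" if sets[0] in _NAMED_SETS else f"unnamed rich set {sorted(sets[0])}"
        return TissuePattern(gene_id, pattern, top, note)
    union = frozenset().union(*sets)
    pattern = _NAMED_SETS.get(union, PATTERN_MULTI)
    return TissuePattern(
        gene_id,
        pattern,
        top,
        f"phases conflict ({ {k: sorted(v) for k, v in top.items()} }); "
        f"used union {sorted(union)}",
    )


# ---------------------------------------------------------------------------
# Time-course responder classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimeCourseClass:
    gene_id: str
    responder: bool
    f_statistics: dict[str, float]
    p_values: dict[str, float]
    directions: dict[str, int]  # sign of mean(16 h) - mean(0 h) per process
    note: str = ""


def classify_time_course(
    gene_id: str,
    expr: pd.DataFrame,
    alpha: float = 0.05,
    value_col: str = "rel_expr",
    time_points: Sequence[int] = TIME_POINTS,
) -> TimeCourseClass:
    """Responder call from the two phase-change time courses.

    ``expr`` holds one gene's replicates with ``process`` (IG/CS), ``time_h``
    and expression columns.  A responder is significant (one-way ANOVA over
    time, p < alpha) in *both* processes with opposite signs of the 0->16 h
    change; anything else is a non-responder.
    """
    f_stats: dict[str, float] = {}
    p_vals: dict[str, float] = {}
    directions: dict[str, int] = {}
    for process in PROCESSES:
        sub = expr[expr["process"] == process]
        series = []
        for t in time_points:
            x = sub.loc[sub["time_h"] == t, value_col].to_numpy(dtype=float)
            if len(x) < 2:
                raise InsufficientReplicationError(
                    f"{gene_id}: process {process}, time {t} h has {len(x)} "
                    "replicate(s); need >= 2"
                )
            series.append(x)
        if np.allclose(np.concatenate(series), series[0][0]):
            f_stats[process], p_vals[process] = 0.0, 1.0
        else:
            f, p = stats.f_oneway(*series)
            f_stats[process], p_vals[process] = float(f), float(p)
        directions[process] = int(np.sign(np.mean(series[-1]) - np.mean(series[0])))
    both_sig = all(p_vals[pr] < alpha for pr in PROCESSES)
    opposite = directions["IG"] * directions["CS"] < 0
    responder = both_sig and opposite
    note = ""
    if both_sig and not opposite:
        note = "significant in both processes but directions do not reverse"
    return TimeCourseClass(gene_id, responder, f_stats, p_vals, directions, note)


# ---------------------------------------------------------------------------
# Whole-table drivers
# ---------------------------------------------------------------------------


def tissue_profile_table(
    ct: pd.DataFrame,
    ref_gene: str = "rp49",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pattern call, per-phase letters and antenna phase t-test per gene."""
    expr = relative_expression(ct, ref_gene)
    expr = expr[expr["gene_id"] != ref_gene]
    rows = []
    for gene_id, gsub in expr.groupby("gene_id", sort=False):
        displays = {}
        for phase in PHASES:
            psub = gsub[gsub["phase"] == phase]
            displays[phase] = tissue_anova_letters(psub, alpha=alpha)
        pattern = assign_tissue_pattern(gene_id, displays)
        antenna = gsub[gsub["tissue"] == "antenna"]
        t, p = phase_ttests(antenna)
        rows.append(
            {
                "gene_id": gene_id,
                "pattern": pattern.pattern,
                "letters_gregarious": ";".join(
                    f"{g}={displays['gregarious'].letters[g]}"
                    for g in displays["gregarious"].groups
                ),
                "letters_solitarious": ";".join(
                    f"{g}={displays['solitarious'].letters[g]}"
                    for g in displays["solitarious"].groups
                ),
                "antenna_t": t,
                "antenna_p": p,
                "note": pattern.note,
            }
        )
    return pd.DataFrame(rows)


def time_course_table(
    ct: pd.DataFrame,
    ref_gene: str = "rp49",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Responder classification for every gene of a time-course Ct table."""
    expr = relative_expression(ct, ref_gene)
    expr = expr[expr["gene_id"] != ref_gene]
    rows = []
    for gene_id, gsub in expr.groupby("gene_id", sort=False):
        cls = classify_time_course(gene_id, gsub, alpha=alpha)
        rows.append(
            {
                "gene_id": gene_id,
                "class": "responder" if cls.responder else "non-responder",
                "F_IG": cls.f_statistics["IG"],
                "p_IG": cls.p_values["IG"],
                "F_CS": cls.f_statistics["CS"],
                "p_CS": cls.p_values["CS"],
                "direction_IG": cls.directions["IG"],
                "direction_CS": cls.directions["CS"],
                "note": cls.note,
            }
        )
    return pd.DataFrame(rows)
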