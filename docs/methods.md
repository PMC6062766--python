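# Methods

This note documents the models and procedures obpkit implements, the
parameter choices that matter, what the synthetic-data generators emulate,
and the numerical conventions behind the results. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Cysteine-architecture detection and subtyping

The mature protein is the annotated sequence with the first
`signal_peptide_len` residues removed; no signal-peptide predictor is
bundled — lengths are consumed from an annotation table and default to 0.

A candidate architecture assigns six cysteines to the landmarks C1–C6
subject to gap constraints, where a *gap* is the number of residues strictly
between two cysteines (so a C2–C3 gap of 3 is `C-x-x-x-C`). This strict
between-count convention is stated prominently because prose descriptions of
"intervals" are ambiguous; it matches the standard motif notation for OBPs.
Defaults:

| gap | range | note |
| --- | --- | --- |
| C1–C2 | 15–50 | permissive; brackets the family alignment geometry |
| C2–C3 | exactly 3 | diagnostic |
| C3–C4 | 20–60 | permissive |
| C4–C5 | 8–30 | permissive |
| C5–C6 | exactly 8 | diagnostic |

All ranges are configurable (`GapConfig`). When several assignments satisfy
the constraints, the one minimising the total absolute deviation of the
non-fixed gaps from their range midpoints wins; ties break to the leftmost
C1 and then lexicographically, so output is deterministic. The search prunes
by gap ranges but is equivalent to filtering all 6-subsets of cysteine
positions (the test suite checks this equivalence by brute force on short
sequences).

Subtype precedence on a valid core: **atypical** (protein length ≥ 200 aa,
regardless of extra cysteines) > **plus-C type-A** (exactly three extra
cysteines strictly between C3 and C6) > **plus-C type-B** (one extra
cysteine before C1 and one after C6, none internal) > **classic** (no
extras). The atypical threshold of 200 aa sits between the longest
non-atypical catalog member (166 aa) and the single atypical one (271 aa)
and is exposed in the configuration. Atypical-first precedence mirrors the
family catalog, where the long member is atypical irrespective of its
extra-cysteine content. Extra-cysteine patterns matching none of the plus-C
definitions fall through to classic with the unmatched extras recorded in
the call's rationale. The exact positions of C3′–C5′ within the core are
not constrained beyond being internal extras between C3 and C6, since the
family definition fixes only their number and region.

## Genomic loci

Internal coordinates are 0-based half-open; GFF3 I/O converts from the
standard's 1-based closed convention at the boundary, which removes any
off-by-one ambiguity from the length formulas: exon length = end − start,
intron length = next start − previous end, gene span = last end − first
start, and span = Σexons + Σintrons identically. Genes with several mRNAs
contribute the transcript with the largest total exon length (one structure
per gene). Intergenic distance is measured between gene spans (not CDS),
unstranded, for adjacent genes on the same scaffold only; overlapping spans
report a gap of 0 with an overlap flag. The long-intron threshold defaults
to 5 kb.

## Distance phylogenetics

*p*-distance is the fraction of differing residues among comparable sites.
Complete deletion (drop any column gapped in *any* row of the block) is the
default, matching the common default of distance-matrix phylogenetics
software; pairwise deletion is available by flag — the choice is exposed
because published analyses often leave it unstated. Poisson correction
converts *p* to substitutions per site, *d* = −ln(1 − *p*); *p* = 1 is a
saturation error. Rates are uniform across sites (no gamma option).

Neighbor joining is the standard Q-criterion agglomeration. Ties in Q break
to the pair whose clusters have the lexicographically smallest
(smallest-leaf-label) keys. Negative branch-length estimates are clamped to
zero with the deficit moved to the sibling edge, preserving leaf-to-leaf
path lengths — on additive matrices the patristic distances reproduce the
input exactly (tested to 1e-9).

Bootstrap replicates resample alignment columns with replacement to the
original length (500 replicates and a 50% cutoff by default); replicates
with an undefined or saturated distance are redrawn and counted. Supports
are the fraction of replicates containing each bipartition of the
*full-data* tree, and the consensus operation collapses full-data edges
below the cutoff — the behavior of common tree software when asked for a
bootstrap consensus with a cutoff. A true majority-rule consensus rebuilt
from the replicates is provided as an alternative
(`majority_rule_consensus`). All replicate indices come from one seeded
generator in a fixed order, so supports are bit-reproducible.

## Expression statistics

Relative expression is per-sample ΔCt against the reference gene,
`2^(Ct_ref − Ct)`. No calibrator sample is designated (a ΔΔCt variant would
rescale every value by a shared constant and leave all downstream tests
unchanged), so the simpler ratio-to-reference form is used.

Tissue profiling runs a one-way ANOVA across the five tissues within each
phase, Tukey HSD on all pairs at α = 0.05, and a compact letter display via
the insert-and-absorb algorithm (two groups share a letter iff their Tukey
comparison is not significant; verified exhaustively against a
maximal-clique oracle for all 1024 five-group significance patterns). The
"rich" tissue set of a phase is the set of tissues carrying the top letter
(statistically tied with the highest mean). Matching rich sets in both
phases map to the named patterns; if no tissue separates in either phase the
gene is multi-tissue; conflicting phases fall back to the union of the two
rich sets, with the conflict logged. This top-letter operationalization of
the prose pattern definitions is a design choice and is configurable in the
sense that single-phase displays can be inspected directly.

Phase comparisons use the classical (pooled-variance) Student's *t* by
default, Welch behind a flag. α = 0.05, two-sided, everywhere; no
multiple-testing correction is applied across genes — a deliberate match to
the source analysis style and a known limitation.

The time-course responder call fits a one-way ANOVA over the 0/4/8/16 h
time points within each process (IG and CS) and requires (i) p < α in
*both* processes and (ii) opposite signs of the 16 h − 0 h mean change
between processes. The both-process requirement compounds the per-process
error rate, so the null responder rate is ≲ α²/2; the acceptance suite
measures ≤ 0.01 on 2,000 flat genes and ≥ 90% power on planted reverse
2-fold patterns at four replicates and 10% CV.

## Behavioral phase scoring

The logistic model's coefficients (−2.110; 0.005; 0.012; 0.015) are fixed
from prior work and ship as defaults of `PhaseModel`; they presume the
original video tracker's exported units, making the model unit-fragile by
construction — rescaling any covariate requires refitting, which is out of
scope. The logistic transform is overflow-safe (`expit`), saturating to
exactly 0/1 for |η| beyond floating-point range.

Mann–Whitney U is computed from rank sums with midranks for ties. In auto
mode the two-sided p is exact — the null distribution of U is built by
dynamic programming (the Gaussian-binomial count of partitions in an n×m
box) and the p-value is the null mass at least as far from nm/2 as
observed — whenever max(n, m) ≤ 10 and the pooled data are tie-free;
otherwise a normal approximation with tie correction and continuity
correction is used. The tie-exact permutation distribution is not
implemented (expensive and rarely needed at these sample sizes); forcing
`mode="exact"` on tied data is an error rather than a silent approximation.

Knockdown reports give percent-of-control as the ratio of group means
(the conventional reading of "reduced to X% of control"); a median-ratio
variant is available by flag. A zero control mean flags the percent as
undefined rather than dividing.

## Synthetic-data generators

Every generator is a pure function of (spec, seed); identical inputs give
bit-identical outputs, and truth tables are first-class outputs.

- **Proteins.** Cores are planted with the diagnostic gaps fixed and free
  gaps drawn uniformly within their ranges (core-only subtypes) or pinned
  to range midpoints (plus-C subtypes, where the fixed geometry of the
  extra cysteines — offsets chosen so no spurious cysteine pair mimics a
  diagnostic spacing — keeps the planted core the best-scoring assignment).
  Flanking residues are random non-cysteines, so the planted architecture
  is the only one present. Signal peptides are random prefixes. The
  17-entry catalog preset uses the published per-protein lengths,
  signal-peptide lengths and subtypes.
- **Gene models.** Defaults: 17 genes on 16 scaffolds with one co-located
  pair (32 kb intergenic gap), five 7-exon and twelve 6-exon genes, exon
  lengths uniform on 20–210 bp, intron lengths log-normal (μ = 8.706,
  σ = 1.5, clipped to 83–58448 bp) so that roughly 55% of introns exceed
  5 kb — the published family geometry.
- **Ct tables.** Planted relative expressions (base 0.01; rich tissues
  elevated 8-fold; time-course responders moving 2-fold log-linearly,
  downward in IG and upward in CS) are converted to Ct as
  `Ct = Ct_ref − log2(expr)` with log-normal replicate noise at 10% CV and
  a nearly constant reference gene; four biological replicates per cell.
- **Behavior cohorts.** Covariates are log-normal (non-negative,
  right-skewed — the reason the downstream tests are nonparametric) with
  control medians (100, 300, 220) chosen so the control median P_greg is
  ≈ 0.995 under the default model; treated cohorts scale the covariate
  medians by (0.287, 0.603, 0.709) — the published knockdown effect — and a
  null treatment uses factors of 1. Thirty individuals per group, 30% CV.
- **Alignments.** Gap-free blocks with planted clusters: each cluster's
  ancestor mutates from a common root at 0.4 per site and leaves mutate
  from their ancestor at 0.05 per site over 200 columns, giving clean,
  strongly supported clades.

What the generators do **not** emulate: real protein evolution (no
substitution-model site heterogeneity, no indels — planted alignments are
gap-free, so gap-handling modes are exercised only by hand-built cases),
primer efficiency or plate effects in qPCR (the replicate-pairing plate
structure is recorded in sample ids but no batch term exists), and any
correlation between an individual's three behavioral covariates (drawn
independently, whereas real tracker covariates co-vary). Passing round-trip
tests therefore demonstrates correctness of the statistical machinery under
the stated noise models, not robustness to the full messiness of wet-lab
data.

## Problem sizes used by the test and acceptance suites

The suites run at sizes chosen to make the brute-force oracles exhaustive
while keeping the whole run desk-scale: NJ-vs-exhaustive-search on 200
additive matrices of 4–8 taxa (the 8-taxon search spans 10,395 topologies);
exact Mann–Whitney against full enumeration for 500 cases with samples of
≤ 8; letter displays against all 1,024 five-group significance patterns;
responder operating characteristics on 2,000 null and 1,000 planted genes;
and end-to-end preset pipelines with 100 bootstrap replicates (the CLI
default remains 500).

## Known limitations

- The subtype rules are rule-based reconstructions of a published catalog;
  proteins violating the diagnostic gaps are non-OBP by definition here,
  even though real families contain divergent members.
- No multiple-testing correction across genes in the expression module.
- The Mann–Whitney exact path covers tie-free data only.
- NJ is O(n³) pure Python/NumPy; fine for family-scale trees (tens of
  taxa), not for thousands.
- The behavioral model cannot be refit; it is a fixed scoring rule.
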