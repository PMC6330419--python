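# Methods

This note documents the model, the numerical choices and the limits of what
the test suite demonstrates. It states no empirical number that the tests or
`scripts/acceptance.py` do not themselves compute.

## The detection model

The detector treats an MSA as observations from a profile HMM and asks, for
each sequence, where that sequence stops looking like a draw from the
profile. The profile is an explicit star-model assumption: every sequence is
scored against a single position-specific consensus, with no tree structure.
This is what makes single-sequence errors stand out — an erroneous segment
disagrees with *all* other sequences at once, while genuine divergence is
usually shared by a clade.

Each ungapped residue gets one of four match categories (`U`, `L`, `P`,
`B`; see the README). Categories, not posterior probabilities, drive
scoring: the category depends only on the local match quality, whereas a
posterior also reflects alignment uncertainty around the site.

The cumulative similarity trace starts at 1 and adds c(symbol) per residue,
clamped to [0, 1]. A segment requires the trace to *reach exactly zero*:
sub-1 excursions that never hit zero are tolerated divergence. Boundaries:
the segment starts after the last score of 1 (sequence start if the trace
begins below 1) and ends at the last zero of the run — unless the run
reaches the sequence end without recovering to 1, in which case the segment
extends to the end (terminal errors rarely recover). An alternative
convention treats the whole sub-1 run as the segment; the last-zero rule is
the more precise one and is what `detect_segments` implements.

### Scoring matrices

| preset | c1 (`B`) | c2 (`P`) | c3 (`L`) | c4 (`U`) |
|---|---|---|---|---|
| default | −0.150 | −0.080 | 0.150 | 0.450 |
| species_rich | −0.175 | −0.175 | 0.150 | 0.400 |
| high_specificity | −0.125 | −0.125 | 0.175 | 0.400 |
| species_rich_high_specificity | −0.125 | −0.125 | 0.150 | 0.400 |
| v1_8 (legacy) | −0.300 | −0.100 | 0.200 | 0.500 |

All scores are dimensionless increments on the unit similarity scale. The
blank penalty sets the analytic detection floor: with the default matrix a
run of ⌈1/0.15⌉ = 7 blanks is needed to reach zero from a full score, so
errors shorter than 7 aa are undetectable wherever the trace sits at 1.

### Exact score lattice

Every preset and every grid value has three-decimal precision, so traces
are accumulated in integer milliunits (score × 1000) with clamping to
[0, 1000]. This makes the `score == 0` predicate exact — no float
accumulation can produce a spurious 1e-17 that misses the zero test — and
custom matrices are quantized to three decimals on construction. The test
suite checks the trace against an exact rational (Fraction) accumulator;
agreement is exact, not approximate.

## Annotation engines

**Internal (default).** Match columns are alignment columns with gap
fraction ≤ 0.5 over the profile-building set (configurable). Per match
column, emission frequencies use a Laplace +1 prior:
e(a) = (count(a) + 1) / (n_residues + 20). The consensus is the argmax
(ties break alphabetically). A residue equal to the consensus is `U` when
e > 0.5, else `L`; otherwise `P` when log(e(r)/f(r)) > 0 against the
background f, else `B`. Insert columns and unknown (`X`) residues are `B`.
The background is the Robinson & Robinson (1991) amino-acid composition
(a uniform table is selectable). Sequence weighting is uniform. This rule
is a documented approximation of HMMER's display categories, not asserted
to be identical; on high-identity fixtures the two engines agree on the
match/mismatch dichotomy at ≥ 99% of residues (tested at a ≥ 90% gate).

Note a consequence of the +1 prior: the consensus emission (n+1)/(n+20)
only exceeds 0.5 for n ≥ 19 sequences, so small alignments of identical
sequences annotate as `L`, not `U`. This is faithful to the stated rule.

**External.** `pyhmmer` (the HMMER codebase in-process) builds the profile
with `prior_scheme="laplace"` and `fragthresh=0` and searches each ungapped
sequence; categories are read off the per-domain alignment midline
(letter case → `U`/`L`, `+` → `P`, blank → `B`). Residues outside every
envelope are `B`; overlapping envelopes resolve in favor of the non-blank
symbol from the higher-scoring domain. Sequences with no reported hit are
annotated all-`B` (with a warning, not an error).

Leave-one-out builds one profile per sequence (n profiles); complete builds
one. Leave-one-out is more sensitive but the profile shift at category
boundaries makes it slightly less specific, and it costs n× more; complete
is the default.

## The simulator

Errors are introduced into the ungapped CDS of a codon alignment, at an
anchor drawn uniformly over interior codon starts (never the first or last
codon):

* **frameshift** — one nucleotide deleted (or inserted; direction chosen by
  the RNG) at the anchor boundary, with the opposite event after L
  out-of-frame codons; the inserted base is uniform on {A,C,G,T}. Total
  length is conserved and exactly L residues are out of frame.
* **scramble** — the 3L nucleotides of the window are uniformly permuted.
* **insertion** — a shuffled copy of a randomly chosen same-length window
  of the *same* sequence is inserted at the anchor, preserving local
  composition.

Translation uses the standard genetic code; in-frame STOPs become `X` and
never truncate. Realignment is either MAFFT L-INS-i (external, for fidelity
experiments) or the built-in deterministic **gap-transfer** path (default):
length-conserving errors re-use the original gap skeleton, and insertions
open a fresh gap block in all other sequences at the anchor column. The
gap-transfer path is exact for the truth bookkeeping (residue order never
changes through alignment, so true spans are lifted by residue index) and
keeps the whole harness binary-free and bit-reproducible.

### Fixture generator

`generate_fixture_msa` evolves n sequences independently from a random
sense-codon root (star tree): each nucleotide substitutes with probability
*divergence* (uniformly to one of the other three bases) and each codon
deletes with probability *indel_rate*, rendered as `---` so the output is
aligned by construction. Defaults — 25 sequences, 200 codons, divergence
0.05, indel rate 0.01 — model the study conditions: 25-sequence subsets of
conserved single-copy orthologs of ≥ ~100–200 aa, with an expected pairwise
nucleotide identity of (1−d)² + d²/3 ≈ 0.90 per site (≈ 74% amino-acid
identity). What it does **not** model: tree structure (no clades — which
flatters the star-model assumption of the detector), insertions shared by
subsets of sequences, rate heterogeneity across sites, and real alignment
uncertainty (gaps are placed by construction, not inferred). Passing the
recovery tests on these fixtures therefore demonstrates the machinery is
correct under the model's own assumptions, at reduced realism; it does not
by itself bound performance on deep, indel-rich empirical alignments, where
specificity is known to degrade with divergence.

The short-error floor experiment (1–6 aa errors never detected) uses
divergence-0 fixtures: the floor is an analytic statement about regions
where the trace sits at 1, and in divergent context a chance blank adjacent
to the error can legitimately extend the run to seven.

## Evaluation

Scoring is per residue, gaps excluded, and per sequence: a truth span in
one sequence never matches a detection in another. Sensitivity =
tp/(tp+fn), specificity = tn/(tn+fp), reported as undefined when a
denominator is zero. Pooled (micro) rates sum counts across replicates;
per-alignment (macro) means are also available, since "mean sensitivity"
can be read either way.

Columns are classified UAR/AAR by a built-in entropy/gap rule: AAR iff the
smoothed normalized Shannon entropy (base-20 normalization, X excluded,
centered moving average of window 3, shrinking at the edges) exceeds the
entropy cutoff, or the raw gap frequency exceeds the gap cutoff. The three
named settings are strict (0.4, 0.05), medium (0.5, 0.2) and loose
(0.6, 0.4). This mirrors the stringency conventions of block-filtering
practice; an external block filter can be substituted for fidelity work.
The per-column substitution-rate proxy is the mean pairwise difference
among non-gap residues — labelled a proxy because no particular rate
estimator is implied.

Detected segments are characterized by the gap fraction of their column
span across all sequences (≥ 70% flags the segment as linked to an
insertion event) and by mean pairwise identity, where a pair is computable
only when ≥ 10% of the segment residues face a residue in the other
sequence, and the mean is reported only when ≥ 10% of pairs are computable.

## Optimization

The search grid is materialized from integer milliunit steps (9 × 7 × 9 × 5
= 2835 matrices; c1 −0.05…−0.25 by 0.025, c2 −0.02…−0.08 by 0.01, c3
0.05…0.25 by 0.025, c4 0.4…0.6 by 0.05). Annotation is matrix-independent,
so each simulated alignment is annotated once and all 2835 matrices are
evaluated on the cached annotations. The bi-objective (mean sensitivity,
mean specificity) has no canonical scalarization; `sum` is the default and
`min` and `product` are reported alongside so either convention can be
reproduced.

## Problem sizes used by the shipped experiments

The acceptance benchmark runs 30 replicates of 25-sequence × 200-codon
fixtures with one 30-aa scrambled error each; the monotonicity experiment
runs 30 paired replicates over error lengths {5, 10, 20, 40}; the
short-error floor uses 5 replicates per length 1–6. These sizes give stable
pooled rates (≈ 150k assessed residues in the benchmark) while keeping any
single experiment in the seconds-to-minutes range. The full published-scale
designs (640,000 simulations / 4,960,000 errors; 80,000 optimization MSAs)
are represented by exact design enumerators and are not executed.

## Known limitations

* The internal engine approximates HMMER's category display; agreement is
  high on conserved alignments but unverified on deep divergence.
* The gap-transfer aligner sidesteps alignment noise entirely; MAFFT-based
  runs are the fidelity path and are not bit-reproducible across versions.
* No support for Phylip/Stockholm/Nexus, DNA profiles, or column (block)
  filtering; `X` is the only ambiguity code carried through translation.
* A trace that starts below 1 anchors its segment at residue 1 — the
  "after the last score of 1" rule has no antecedent there.
* Segments are reported per sequence, merging across disjoint envelopes.
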