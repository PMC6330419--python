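"""Cumulative similarity scoring, low-similarity-segment detection, masking.

The similarity trace walks the four-category annotation of a sequence from
left to right.  It starts at the maximal value 1 (a perfect fit to the
profile), adds a signed elemental score per residue (c1 for 'B', c2 for 'P',
c3 for 'L', c4 for 'U'), and clamps to [0, 1] at every step.  A
low-similarity segment is a maximal run of sub-1 scores containing at least
one exact zero: it starts after the last position where the score was 1 and
ends at the last zero of the run (or at the sequence end when the run never
returns to 1 before the sequence ends).

Scores live on an exact 0.001 lattice: every published preset and every
optimization-grid value has three-decimal precision, so traces are
accumulated in integer milliunits and the "score reaches zero" predicate is
exact rather than subject to float rounding.  Custom elemental scores are
quantized to three decimals on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .msa_io import GAP, Alignment, translate_alignment
from .profile_annotation import MatchAnnotation, ProfileSpec, annotate_alignment

_SCALE = 1000


@dataclass(frozen=True)
class ScoringMatrix:
    """The four elemental scores: c1 ('B') and c2 ('P') negative, c3 ('L')
    and c4 ('U') positive."""

    c1: float
    c2: float
    c3: float
    c4: float
    name: str = "custom"

    def __post_init__(self):
        for attr in ("c1", "c2", "c3", "c4"):
            object.__setattr__(
                self, attr, round(float(getattr(self, attr)), 3)
            )
        if not (self.c1 < 0 and self.c2 < 0):
            raise ValueError("c1 and c2 must be negative")
        if not (self.c3 > 0 and self.c4 > 0):
            raise ValueError("c3 and c4 must be positive")

    def milli(self) -> dict[str, int]:
        return {
            "B": round(self.c1 * _SCALE),
            "P": round(self.c2 * _SCALE),
            "L": round(self.c3 * _SCALE),
            "U": round(self.c4 * _SCALE),
        }

    def min_detectable_run(self) -> int:
        """Smallest all-'B' run driving the trace from 1 to 0."""
        step = -round(self.c1 * _SCALE)
        return -(-_SCALE // step)  # ceil(1000 / |c1 milli|)


#: The five published presets (tool versions 2 and 1.8).
PRESETS: dict[str, ScoringMatrix] = {
    "default": ScoringMatrix(-0.15, -0.08, 0.15, 0.45, name="default"),
    "species_rich": ScoringMatrix(-0.175, -0.175, 0.15, 0.40, name="species_rich"),
    "high_specificity": ScoringMatrix(
        -0.125, -0.125, 0.175, 0.40, name="high_specificity"
    ),
    "species_rich_high_specificity": ScoringMatrix(
        -0.125, -0.125, 0.15, 0.40, name="species_rich_high_specificity"
    ),
    "v1_8": ScoringMatrix(-0.30, -0.10, 0.20, 0.50, name="v1_8"),
}


@dataclass(frozen=True)
class SimilarityTrace:
    seq_id: str
    scores: np.ndarray  # one value per ungapped residue, in [0, 1]
    milli: np.ndarray  # the exact integer-lattice scores (scores * 1000)


@dataclass(frozen=True)
class LowSimilaritySegment:
    """A detected residue interval (1-based inclusive) and its column span."""

    seq_id: str
    start_res: int
    end_res: int
    start_col: int | None = None
    end_col: int | None = None

    @property
    def length(self) -> int:
        return self.end_res - self.start_res + 1


def similarity_trace(ann: MatchAnnotation, m: ScoringMatrix) -> SimilarityTrace:
    """Accumulate the clamped cumulative similarity score along a sequence."""
    if len(ann.symbols) == 0:
        raise ValueError("empty annotation")
    costs = m.milli()
    milli = np.empty(len(ann.symbols), dtype=np.int64)
    score = _SCALE
    for k, sym in enumerate(ann.symbols):
        score += costs[sym]
        if score > _SCALE:
            score = _SCALE
        elif score < 0:
            score = 0
        milli[k] = score
    return SimilarityTrace(ann.seq_id, scores=milli / _SCALE, milli=milli)


def detect_segments(trace: SimilarityTrace) -> list[LowSimilaritySegment]:
    """Locate low-similarity segments in one trace.

    For each maximal run of positions with score < 1 containing at least one
    zero: the segment starts after the last position where the score was 1
    (or at residue 1 when the trace begins below 1) and ends at the last zero
    of the run, unless the run extends to the sequence end without returning
    to 1, in which case it ends at the final position.
    """
    milli = trace.milli
    n = len(milli)
    segments: list[LowSimilaritySegment] = []
    i = 0
    while i < n:
        if milli[i] == _SCALE:
            i += 1
            continue
        run_start = i  # first sub-1 position of the run
        while i < n and milli[i] < _SCALE:
            i += 1
        run_end = i - 1  # last sub-1 position
        zeros = np.nonzero(milli[run_start : run_end + 1] == 0)[0]
        if len(zeros) == 0:
            continue
        end_res = n if run_end == n - 1 else run_start + int(zeros[-1]) + 1
        segments.append(
            LowSimilaritySegment(
                seq_id=trace.seq_id, start_res=run_start + 1, end_res=end_res
            )
        )
    return segments


def _with_columns(
    seg: LowSimilaritySegment, aln: Alignment
) -> LowSimilaritySegment:
    cmap = aln.coord_map(seg.seq_id)
    return replace(
        seg,
        start_col=cmap.col_of(seg.start_res),
        end_col=cmap.col_of(seg.end_res),
    )


def clean(
    aln: Alignment,
    spec: ProfileSpec | None = None,
    matrix: ScoringMatrix | None = None,
    mask_char: str = GAP,
    annotations: list[MatchAnnotation] | None = None,
) -> tuple[Alignment, list[LowSimilaritySegment]]:
    """Detect and mask low-similarity segments in a protein alignment.

    Masked residues are replaced by *mask_char* in their own sequence only;
    the column count never changes.  Pre-computed *annotations* may be passed
    to reuse profile evaluation across several scoring matrices.

    Returns the cleaned alignment and the detected segments (with both
    residue and alignment-column coordinates).
    """
    matrix = matrix or PRESETS["default"]
    if annotations is None:
        annotations = annotate_alignment(aln, spec)
    segments: list[LowSimilaritySegment] = []
    cleaned = aln
    for ann in annotations:
        if len(ann) == 0:  # all-gap row: nothing to score
            continue
        segs = detect_segments(similarity_trace(ann, matrix))
        if not segs:
            continue
        cmap = aln.coord_map(ann.seq_id)
        gapped = list(aln.seq(ann.seq_id))
        for seg in segs:
            seg = _with_columns(seg, aln)
            segments.append(seg)
            for res in range(seg.start_res, seg.end_res + 1):
                gapped[cmap.col_of(res) - 1] = mask_char
        cleaned = cleaned.replace_seq(ann.seq_id, "".join(gapped))
    return cleaned, segments


def clean_nt(
    nt_aln: Alignment,
    spec: ProfileSpec | None = None,
    matrix: ScoringMatrix | None = None,
) -> tuple[Alignment, list[LowSimilaritySegment]]:
    """Clean a codon-phased nucleotide alignment.

    Segments are detected on the translated protein alignment; each masked
    amino acid masks its whole codon (``---``).  The returned segments carry
    protein-alignment coordinates.
    """
    aa_aln = translate_alignment(nt_aln)
    _, segments = clean(aa_aln, spec=spec, matrix=matrix)
    cleaned = nt_aln
    for seg in segments:
        cmap = nt_aln.coord_map(seg.seq_id)
        gapped = list(nt_aln.seq(seg.seq_id))
        # aa residue k occupies ungapped nt 3(k-1)+1 .. 3k
        for res in range(seg.start_res, seg.end_res + 1):
            for nt_res in range(3 * (res - 1) + 1, 3 * res + 1):
                gapped[cmap.col_of(nt_res) - 1] = GAP
        cleaned = cleaned.replace_seq(seg.seq_id, "".join(gapped))
    return cleaned, segments
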