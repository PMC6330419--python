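"""Residue-level scoring of a filter against simulated truth, alignment
region classification, positional context, and the benchmark harness.

Sensitivity is the fraction of truly erroneous residues that were detected
and specificity the fraction of correct residues left untouched, both at
residue level with gaps excluded.  Columns are partitioned into
unambiguously (UAR) and ambiguously (AAR) aligned regions with a built-in
entropy/gap classifier mirroring the three stringency settings of standard
block-filtering practice (strict 0.4/0.05, medium 0.5/0.2, loose 0.6/0.4).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cleaner import LowSimilaritySegment, PRESETS, ScoringMatrix, clean
from .msa_io import GAP, Alignment
from .profile_annotation import ProfileSpec
from .simulator import ErrorSpec, SimulatedError, build_erroneous_msa, generate_fixture_msa


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def specificity(self) -> float | None:
        d = self.tn + self.fp
        return self.tn / d if d else None

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )


@dataclass(frozen=True)
class RegionSettings:
    name: str
    entropy_cutoff: float
    gap_cutoff: float


#: The three stringency settings for UAR/AAR classification.
REGION_SETTINGS: dict[str, RegionSettings] = {
    "strict": RegionSettings("strict", 0.4, 0.05),
    "medium": RegionSettings("medium", 0.5, 0.2),
    "loose": RegionSettings("loose", 0.6, 0.4),
}


class CoordinateError(ValueError):
    """A span refers to residues outside its sequence."""


def _residue_masks(
    aln: Alignment,
    detected: list[LowSimilaritySegment],
    truth: list[SimulatedError],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per sequence: boolean (is_truth, is_called) over ungapped residues."""
    masks = {}
    for sid in aln.ids:
        n = aln.coord_map(sid).n_residues
        masks[sid] = (np.zeros(n, dtype=bool), np.zeros(n, dtype=bool))
    for t in truth:
        is_t, _ = masks[t.seq_id]
        if not 1 <= t.start_res <= t.end_res <= len(is_t):
            raise CoordinateError(
                f"truth span {t.start_res}-{t.end_res} outside {t.seq_id!r}"
            )
        is_t[t.start_res - 1 : t.end_res] = True
    for d in detected:
        _, is_c = masks[d.seq_id]
        if not 1 <= d.start_res <= d.end_res <= len(is_c):
            raise CoordinateError(
                f"detected span {d.start_res}-{d.end_res} outside {d.seq_id!r}"
            )
        is_c[d.start_res - 1 : d.end_res] = True
    return masks


def confusion(
    detected: list[LowSimilaritySegment],
    truth: list[SimulatedError],
    aln: Alignment,
    column_mask: np.ndarray | None = None,
) -> ConfusionCounts:
    """Residue-level confusion counts over all residues of all sequences.

    A residue is positive-truth iff inside a true error span *of its own
    sequence*, positive-call iff inside a detected segment of its own
    sequence.  *column_mask* (boolean per alignment column) restricts the
    assessment to a column subset (e.g. the UARs).
    """
    masks = _residue_masks(aln, detected, truth)
    tp = fp = fn = tn = 0
    for sid in aln.ids:
        is_t, is_c = masks[sid]
        if column_mask is not None:
            cols = aln.coord_map(sid).res_to_col - 1
            keep = column_mask[cols]
            is_t, is_c = is_t[keep], is_c[keep]
        tp += int((is_t & is_c).sum())
        fp += int((~is_t & is_c).sum())
        fn += int((is_t & ~is_c).sum())
        tn += int((~is_t & ~is_c).sum())
    return ConfusionCounts(tp, fp, fn, tn)


# -- column classification and context ----------------------------------

_LN20 = math.log(20.0)


def _column_stats(aln: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """Per column: gap frequency and normalized Shannon entropy (X excluded
    from the residue distribution)."""
    n_cols = aln.n_cols
    counts = np.zeros((20, n_cols), dtype=np.int64)
    gap_counts = np.zeros(n_cols, dtype=np.int64)
    from .msa_io import AA_LETTERS

    lut = {a: i for i, a in enumerate(AA_LETTERS)}
    for _, seq in aln.records:
        for c, ch in enumerate(seq):
            if ch == GAP:
                gap_counts[c] += 1
            elif ch in lut:
                counts[lut[ch], c] += 1
    gap_freq = gap_counts / aln.n_seqs
    tot = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / np.where(tot == 0, 1, tot)
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    entropy = -plogp.sum(axis=0) / _LN20
    entropy[tot == 0] = 0.0
    return gap_freq, entropy


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with an odd window, shrinking at the edges."""
    if window <= 1:
        return values
    half = window // 2
    out = np.empty_like(values, dtype=float)
    for i in range(len(values)):
        lo, hi = max(0, i - half), min(len(values), i + half + 1)
        out[i] = values[lo:hi].mean()
    return out


def classify_columns(
    aln: Alignment,
    settings: RegionSettings | str = "medium",
    smooth_window: int = 3,
) -> np.ndarray:
    """Label every column UAR or AAR.

    A column is AAR iff its (window-smoothed) normalized entropy exceeds the
    entropy cutoff or its (unsmoothed) gap frequency exceeds the gap cutoff.
    """
    if isinstance(settings, str):
        settings = REGION_SETTINGS[settings]
    if aln.alphabet != "aa":
        raise ValueError("column classification expects a protein alignment")
    gap_freq, entropy = _column_stats(aln)
    smoothed = _smooth(entropy, smooth_window)
    aar = (smoothed > settings.entropy_cutoff) | (gap_freq > settings.gap_cutoff)
    return np.where(aar, "AAR", "UAR")


def column_context(aln: Alignment) -> pd.DataFrame:
    """Per-column context: gap frequency, substitution-rate proxy, and the
    region class at the three stringency settings.

    The substitution-rate proxy is the mean pairwise difference among the
    non-gap residues of the column (a proxy; no rate estimator is implied).
    """
    gap_freq, _ = _column_stats(aln)
    n_cols = aln.n_cols
    rate = np.zeros(n_cols)
    cols = np.array([list(seq) for _, seq in aln.records])
    for c in range(n_cols):
        residues = cols[:, c]
        residues = residues[residues != GAP]
        n = len(residues)
        if n < 2:
            rate[c] = 0.0
            continue
        _, cnt = np.unique(residues, return_counts=True)
        same = (cnt * (cnt - 1) // 2).sum()
        pairs = n * (n - 1) // 2
        rate[c] = (pairs - same) / pairs
    data = {"column": np.arange(1, n_cols + 1), "gap_frequency": gap_freq,
            "substitution_rate_proxy": rate}
    for name in REGION_SETTINGS:
        data[f"region_{name}"] = classify_columns(aln, name)
    return pd.DataFrame(data)


# -- detected-segment characterization ----------------------------------


@dataclass(frozen=True)
class SegmentCharacter:
    segment: LowSimilaritySegment
    region_gap_frequency: float
    insertion_linked: bool
    mean_pairwise_identity: float | None


def characterize_segment(
    seg: LowSimilaritySegment, aln: Alignment
) -> SegmentCharacter:
    """Gap context and mean pairwise identity of a detected segment.

    Segments sitting in regions with >= 70% gaps are flagged as linked to
    insertion events.  Pairwise identity against another sequence is
    computable only when >= 10% of the segment residues face a residue (not
    a gap) in that sequence; the mean is reported only when >= 10% of the
    pairs are computable.
    """
    if seg.start_col is None or seg.end_col is None:
        cmap = aln.coord_map(seg.seq_id)
        start_col, end_col = cmap.col_of(seg.start_res), cmap.col_of(seg.end_res)
    else:
        start_col, end_col = seg.start_col, seg.end_col
    span = slice(start_col - 1, end_col)
    block = [seq[span] for _, seq in aln.records]
    n_chars = sum(len(b) for b in block)
    n_gaps = sum(b.count(GAP) for b in block)
    gap_freq = n_gaps / n_chars if n_chars else 0.0

    focal = aln.seq(seg.seq_id)[span]
    focal_res = [i for i, ch in enumerate(focal) if ch != GAP]
    identities = []
    n_pairs = 0
    for sid, seq in aln.records:
        if sid == seg.seq_id:
            continue
        n_pairs += 1
        other = seq[span]
        facing = [i for i in focal_res if other[i] != GAP]
        if not focal_res or len(facing) / len(focal_res) < 0.10:
            continue  # pair not computable
        same = sum(1 for i in facing if other[i] == focal[i])
        identities.append(same / len(facing))
    mean_id: float | None
    if n_pairs == 0 or len(identities) / n_pairs < 0.10:
        mean_id = None
    else:
        mean_id = float(np.mean(identities))
    return SegmentCharacter(
        segment=seg,
        region_gap_frequency=gap_freq,
        insertion_linked=gap_freq >= 0.70,
        mean_pairwise_identity=mean_id,
    )


# -- experiment designs and the benchmark harness -----------------------


@dataclass(frozen=True)
class CharacterizationDesign:
    """The error length x error count characterization experiment."""

    error_lengths: tuple[int, ...] = (10, 33, 66, 100)
    error_counts: tuple[int, ...] = (1, 5, 10, 15)
    simulations_per_cell: int = 100
    msas_per_lineage: int = 100
    n_lineages: int = 4
    subset_size: int = 25

    @property
    def n_simulations(self) -> int:
        return (
            len(self.error_lengths)
            * len(self.error_counts)
            * self.simulations_per_cell
            * self.msas_per_lineage
            * self.n_lineages
        )

    @property
    def n_errors(self) -> int:
        return (
            len(self.error_lengths)
            * sum(self.error_counts)
            * self.simulations_per_cell
            * self.msas_per_lineage
            * self.n_lineages
        )


@dataclass(frozen=True)
class OptimizationDesign:
    """The scoring-matrix optimization experiment (MSA arithmetic only)."""

    n_lineages: int = 2
    msas_per_lineage: int = 100
    subset_sizes: tuple[int, ...] = (5, 10, 25, 50)
    draws_per_size: int = 100

    @property
    def n_msas(self) -> int:
        return (
            self.n_lineages
            * self.msas_per_lineage
            * len(self.subset_sizes)
            * self.draws_per_size
        )


def run_benchmark(
    error_lengths: tuple[int, ...] = (10, 33, 66, 100),
    error_counts: tuple[int, ...] = (1, 5, 10, 15),
    replicates: int = 3,
    n_seqs: int = 25,
    n_codons: int = 200,
    divergence: float = 0.05,
    indel_rate: float = 0.01,
    error_type: str = "frameshift",
    matrix: ScoringMatrix | None = None,
    spec: ProfileSpec | None = None,
    rng_seed: int = 0,
    region_setting: str = "medium",
) -> pd.DataFrame:
    """Simulate -> clean -> score over an error-length x error-count grid.

    Each replicate generates a fresh star-tree fixture alignment, introduces
    the requested number of errors, cleans the translated alignment and
    scores the detections.  The tidy result has one row per cell x replicate
    x partition (all / UAR / AAR, under *region_setting*).
    """
    matrix = matrix or PRESETS["default"]
    rng = np.random.default_rng(rng_seed)
    rows = []
    for length, count in itertools.product(error_lengths, error_counts):
        if count > n_seqs:
            raise ValueError("more errors than sequences")
        for rep in range(replicates):
            nt = generate_fixture_msa(
                n_seqs=n_seqs,
                n_codons=n_codons,
                divergence=divergence,
                indel_rate=indel_rate,
                rng_seed=rng,
            )
            target_ids = [
                nt.ids[i]
                for i in rng.choice(n_seqs, size=count, replace=False)
            ]
            specs = [
                ErrorSpec(error_type, sid, length_codons=length)
                for sid in target_ids
            ]
            aa_aln, truth = build_erroneous_msa(nt, specs, rng)
            _, detected = clean(aa_aln, spec=spec, matrix=matrix)
            regions = classify_columns(aa_aln, region_setting)
            parts = {
                "all": None,
                "UAR": regions == "UAR",
                "AAR": regions == "AAR",
            }
            for part, mask in parts.items():
                cc = confusion(detected, truth, aa_aln, column_mask=mask)
                rows.append(
                    {
                        "error_length": length,
                        "n_errors": count,
                        "replicate": rep,
                        "partition": part,
                        "tp": cc.tp,
                        "fp": cc.fp,
                        "fn": cc.fn,
                        "tn": cc.tn,
                        "sensitivity": cc.sensitivity,
                        "specificity": cc.specificity,
                    }
                )
    return pd.DataFrame(rows)


def pooled_rates(table: pd.DataFrame, partition: str = "all") -> tuple[float | None, float | None]:
    """Micro-averaged (count-pooled) sensitivity and specificity."""
    sub = table[table["partition"] == partition]
    cc = ConfusionCounts(
        int(sub["tp"].sum()), int(sub["fp"].sum()),
        int(sub["fn"].sum()), int(sub["tn"].sum()),
    )
    return cc.sensitivity, cc.specificity
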