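"""Grid search over the four elemental scores of the scoring matrix.

The published search grid spans 9 x 7 x 9 x 5 = 2835 combinations:
c1 from -0.05 to -0.25 by 0.025, c2 from -0.02 to -0.08 by 0.01, c3 from
0.05 to 0.25 by 0.025 and c4 from 0.4 to 0.6 by 0.05.  Because profile
annotation does not depend on the scoring matrix, each simulated alignment
is annotated once and the whole grid is evaluated on the cached
annotations, which makes the search cheap.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cleaner import ScoringMatrix, clean
from .evaluation import ConfusionCounts, confusion
from .msa_io import Alignment
from .profile_annotation import ProfileSpec, annotate_alignment
from .simulator import ErrorSpec, build_erroneous_msa


def _axis(start_milli: int, step_milli: int, n: int) -> tuple[float, ...]:
    # integer milliunit generation: exact 3-decimal values, no float drift
    return tuple((start_milli + k * step_milli) / 1000 for k in range(n))


@dataclass(frozen=True)
class ParameterGrid:
    c1_values: tuple[float, ...] = _axis(-50, -25, 9)  # -0.05 .. -0.25
    c2_values: tuple[float, ...] = _axis(-20, -10, 7)  # -0.02 .. -0.08
    c3_values: tuple[float, ...] = _axis(50, 25, 9)  # 0.05 .. 0.25
    c4_values: tuple[float, ...] = _axis(400, 50, 5)  # 0.40 .. 0.60

    @property
    def cardinality(self) -> int:
        return (
            len(self.c1_values)
            * len(self.c2_values)
            * len(self.c3_values)
            * len(self.c4_values)
        )


def enumerate_grid(grid: ParameterGrid | None = None) -> list[ScoringMatrix]:
    """Cartesian product in deterministic order (c1 outer, c4 inner)."""
    grid = grid or ParameterGrid()
    return [
        ScoringMatrix(c1, c2, c3, c4)
        for c1, c2, c3, c4 in itertools.product(
            grid.c1_values, grid.c2_values, grid.c3_values, grid.c4_values
        )
    ]


_OBJECTIVES = {
    "sum": lambda sens, spec: sens + spec,
    "min": min,
    "product": lambda sens, spec: sens * spec,
}


def optimize(
    msa_set: list[Alignment],
    grid: ParameterGrid | None = None,
    error_length: int = 30,
    n_errors: int = 1,
    error_type: str = "frameshift",
    spec: ProfileSpec | None = None,
    rng_seed: int = 0,
    objective: str = "sum",
) -> pd.DataFrame:
    """Rank every grid matrix by benchmark performance on *msa_set*.

    Each input codon alignment receives one simulated-error replicate; the
    profile annotation of each erroneous alignment is computed once and
    shared by all matrices.  The result table carries micro- (count-pooled)
    and macro- (per-alignment mean) averaged sensitivity and specificity,
    plus all three scalarizations of the two means, sorted by the requested
    *objective* on the macro means.
    """
    if not msa_set:
        raise ValueError("msa_set must not be empty")
    if objective not in _OBJECTIVES:
        raise ValueError(f"unknown objective {objective!r}")
    matrices = enumerate_grid(grid)
    rng = np.random.default_rng(rng_seed)

    # simulate + annotate once per alignment
    prepared = []
    for nt in msa_set:
        target_ids = [
            nt.ids[i] for i in rng.choice(nt.n_seqs, size=n_errors, replace=False)
        ]
        specs = [
            ErrorSpec(error_type, sid, length_codons=error_length)
            for sid in target_ids
        ]
        aa_aln, truth = build_erroneous_msa(nt, specs, rng)
        anns = annotate_alignment(aa_aln, spec)
        prepared.append((aa_aln, truth, anns))

    rows = []
    for m in matrices:
        pooled = ConfusionCounts(0, 0, 0, 0)
        sens_list, spec_list = [], []
        for aa_aln, truth, anns in prepared:
            _, detected = clean(aa_aln, matrix=m, annotations=anns)
            cc = confusion(detected, truth, aa_aln)
            pooled = pooled + cc
            if cc.sensitivity is not None:
                sens_list.append(cc.sensitivity)
            if cc.specificity is not None:
                spec_list.append(cc.specificity)
        mean_sens = float(np.mean(sens_list)) if sens_list else float("nan")
        mean_spec = float(np.mean(spec_list)) if spec_list else float("nan")
        row = {
            "c1": m.c1,
            "c2": m.c2,
            "c3": m.c3,
            "c4": m.c4,
            "mean_sensitivity": mean_sens,
            "mean_specificity": mean_spec,
            "micro_sensitivity": pooled.sensitivity,
            "micro_specificity": pooled.specificity,
        }
        for name, fn in _OBJECTIVES.items():
            row[f"objective_{name}"] = fn(mean_sens, mean_spec)
        rows.append(row)
    table = pd.DataFrame(rows)
    return table.sort_values(
        f"objective_{objective}", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
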