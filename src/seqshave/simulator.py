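"""Ground-truthed primary-sequence-error simulation on codon alignments.

Three error types are introduced into the ungapped CDS of a chosen sequence:

* ``frameshift`` — delete (or insert) one nucleotide at a codon boundary and
  apply the opposite, compensatory event after a set number of out-of-frame
  codons, conserving total length while garbling exactly that codon window;
* ``scramble`` — uniformly permute the nucleotides of a codon window;
* ``insertion`` — insert a shuffled copy of a randomly chosen same-length
  window of the same sequence at the anchor.

After error injection the sequences are translated (STOP codons become
``X``, never truncating) and re-assembled into a protein alignment; the true
error span is tracked through both steps in residue coordinates (alignment
only moves gaps, never residues) and reported with its alignment-column
footprint.

A star-tree fixture generator provides synthetic codon alignments so the
whole benchmark harness runs without any external data.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .msa_io import GAP, Alignment, CodonPhaseError, read_fasta, translate

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

_PLACEMENT_RETRIES = 100


class PlacementError(RuntimeError):
    """No valid anchor could be drawn for the requested error."""


@dataclass(frozen=True)
class ErrorSpec:
    """A requested primary sequence error."""

    error_type: str  # frameshift | scramble | insertion
    seq_id: str
    length_codons: int
    anchor: int | str = "random"  # 1-based codon index in the ungapped CDS

    def __post_init__(self):
        if self.error_type not in ("frameshift", "scramble", "insertion"):
            raise ValueError(f"unknown error type {self.error_type!r}")
        if self.length_codons < 1:
            raise ValueError("length_codons must be >= 1")


@dataclass(frozen=True)
class SimulatedError:
    """Ground truth for one introduced error, in post-error coordinates."""

    error_type: str
    seq_id: str
    length_codons: int
    anchor: int
    start_res: int
    end_res: int
    start_col: int | None = None
    end_col: int | None = None


def _draw_anchor(
    n_codons: int, length: int, rng: np.random.Generator, needs_room: bool
) -> int:
    """Anchor uniform over codon starts, avoiding the first and last codon."""
    lo, hi = 2, n_codons - length if needs_room else n_codons - 1
    if hi < lo:
        raise PlacementError(
            f"error of {length} codons does not fit in {n_codons} codons"
        )
    return int(rng.integers(lo, hi + 1))


def introduce_error(
    nt_aln: Alignment, spec: ErrorSpec, rng: np.random.Generator
) -> tuple[str, SimulatedError]:
    """Apply one error to the ungapped CDS of spec.seq_id.

    Returns the modified ungapped CDS and the ground-truth record (residue
    span only; columns are filled in after realignment).  Anchors are drawn
    uniformly over interior codon starts; ``anchor='random'`` redraws are not
    needed here because errors operate on the ungapped CDS, but explicit
    anchors are validated.
    """
    cds = nt_aln.ungapped(spec.seq_id)
    if len(cds) % 3 != 0:
        raise CodonPhaseError(f"{spec.seq_id!r}: CDS not codon-phased")
    n_codons = len(cds) // 3
    L = spec.length_codons
    needs_room = spec.error_type != "insertion"
    if spec.anchor == "random":
        anchor = _draw_anchor(n_codons, L, rng, needs_room)
    else:
        anchor = int(spec.anchor)
        hi = n_codons - L if needs_room else n_codons - 1
        if not 2 <= anchor <= hi:
            raise PlacementError(f"anchor {anchor} out of range [2, {hi}]")
    p0 = 3 * (anchor - 1)

    if spec.error_type == "frameshift":
        # one nt deleted (or inserted) at the anchor boundary, the opposite
        # event after L out-of-frame codons; total length conserved.
        ins = "ACGT"[rng.integers(4)]
        if rng.integers(2) == 0:  # deletion first
            mutated = cds[:p0] + cds[p0 + 1 : p0 + 3 * L] + ins + cds[p0 + 3 * L :]
        else:  # insertion first
            mutated = cds[:p0] + ins + cds[p0 : p0 + 3 * L - 1] + cds[p0 + 3 * L :]
    elif spec.error_type == "scramble":
        window = np.frombuffer(cds[p0 : p0 + 3 * L].encode(), dtype="S1")
        shuffled = window[rng.permutation(3 * L)]
        mutated = cds[:p0] + b"".join(shuffled).decode() + cds[p0 + 3 * L :]
    else:  # insertion
        src = _draw_anchor(n_codons, L, rng, needs_room=True)
        q0 = 3 * (src - 1)
        window = np.frombuffer(cds[q0 : q0 + 3 * L].encode(), dtype="S1")
        shuffled = b"".join(window[rng.permutation(3 * L)]).decode()
        mutated = cds[:p0] + shuffled + cds[p0:]

    truth = SimulatedError(
        error_type=spec.error_type,
        seq_id=spec.seq_id,
        length_codons=L,
        anchor=anchor,
        start_res=anchor,
        end_res=anchor + L - 1,
    )
    return mutated, truth


# -- realignment --------------------------------------------------------


def _gap_transfer_align(
    nt_aln: Alignment, mutated: dict[str, str], truths: list[SimulatedError]
) -> Alignment:
    """Deterministic built-in aligner: reuse the original gap pattern.

    Length-conserving errors (frameshift, scramble) drop straight into the
    original gap skeleton of their sequence; each insertion opens a fresh
    gap block in every other sequence at its anchor column.
    """
    rows = {sid: list(seq) for sid, seq in nt_aln.records}
    # apply length-conserving replacements in place
    for sid, cds in mutated.items():
        orig = nt_aln.seq(sid)
        if len(cds) == len(orig) - orig.count(GAP):
            it = iter(cds)
            rows[sid] = [next(it) if ch != GAP else GAP for ch in orig]
    # insertions: open a gap block at the anchor column, widest first so
    # earlier column indices stay valid for later (sorted descending) edits
    ins_truths = [t for t in truths if t.error_type == "insertion"]
    for t in sorted(ins_truths, key=lambda t: -nt_aln.coord_map(t.seq_id).col_of(
        min(3 * (t.anchor - 1) + 1, nt_aln.coord_map(t.seq_id).n_residues)
    )):
        cmap = nt_aln.coord_map(t.seq_id)
        nt_pos = 3 * (t.anchor - 1) + 1  # first ungapped nt of the anchor codon
        col = cmap.col_of(nt_pos) - 1  # 0-based insertion point
        block = 3 * t.length_codons
        inserted = mutated[t.seq_id][3 * (t.anchor - 1) : 3 * (t.anchor - 1) + block]
        for sid in rows:
            if sid == t.seq_id:
                rows[sid][col:col] = list(inserted)
            else:
                rows[sid][col:col] = [GAP] * block
    return Alignment(tuple((sid, "".join(rows[sid])) for sid in nt_aln.ids), "nt")


def _mafft_align(aa_seqs: dict[str, str]) -> Alignment:
    """Align translated sequences with MAFFT L-INS-i (5000 iterations)."""
    exe = shutil.which("mafft")
    if exe is None:
        raise RuntimeError(
            "MAFFT executable not found on PATH; use aligner='gap-transfer' "
            "or install MAFFT"
        )
    with tempfile.TemporaryDirectory() as tmp:
        infile = Path(tmp) / "in.fasta"
        with open(infile, "w") as fh:
            for sid, s in aa_seqs.items():
                fh.write(f">{sid}\n{s}\n")
        proc = subprocess.run(
            [exe, "--localpair", "--maxiterate", "5000", "--quiet", str(infile)],
            capture_output=True,
            text=True,
            check=True,
        )
        outfile = Path(tmp) / "out.fasta"
        outfile.write_text(proc.stdout)
        return read_fasta(outfile, alphabet="aa")


def build_erroneous_msa(
    nt_aln: Alignment,
    specs: list[ErrorSpec],
    rng: np.random.Generator | int,
    aligner: str = "gap-transfer",
) -> tuple[Alignment, list[SimulatedError]]:
    """Inject errors, translate, realign, and lift the truth to columns.

    At most one error per sequence.  *aligner* is ``gap-transfer`` (built-in,
    deterministic) or ``mafft`` (external L-INS-i, for fidelity runs).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    ids = [s.seq_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("at most one error per sequence")
    mutated: dict[str, str] = {}
    truths: list[SimulatedError] = []
    for spec in specs:
        cds, truth = introduce_error(nt_aln, spec, rng)
        mutated[spec.seq_id] = cds
        truths.append(truth)

    if aligner == "gap-transfer":
        nt_out = _gap_transfer_align(nt_aln, mutated, truths)
        aa_aln = Alignment(
            tuple((sid, translate(seq)) for sid, seq in nt_out.records), "aa"
        )
    elif aligner == "mafft":
        aa_seqs = {
            sid: translate(mutated.get(sid, nt_aln.ungapped(sid)))
            for sid in nt_aln.ids
        }
        aa_aln = _mafft_align(aa_seqs)
    else:
        raise ValueError(f"unknown aligner {aligner!r}")

    lifted = []
    for t in truths:
        cmap = aa_aln.coord_map(t.seq_id)
        lifted.append(
            SimulatedError(
                error_type=t.error_type,
                seq_id=t.seq_id,
                length_codons=t.length_codons,
                anchor=t.anchor,
                start_res=t.start_res,
                end_res=t.end_res,
                start_col=cmap.col_of(t.start_res),
                end_col=cmap.col_of(t.end_res),
            )
        )
    return aa_aln, lifted


# -- synthetic fixture alignments ---------------------------------------


def generate_fixture_msa(
    n_seqs: int = 25,
    n_codons: int = 200,
    divergence: float = 0.05,
    indel_rate: float = 0.01,
    rng_seed: int | np.random.Generator = 0,
) -> Alignment:
    """Star-tree codon alignment from a random root CDS.

    Each leaf substitutes every nucleotide independently with probability
    *divergence* (uniformly to one of the other three bases) and deletes
    whole codons with probability *indel_rate* (rendered as ``---``, so the
    output is aligned by construction).  Deterministic under *rng_seed*.
    """
    if n_seqs < 2:
        raise ValueError("need at least 2 sequences")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(int(rng_seed))
    )
    root = "".join(
        _SENSE_CODONS[i] for i in rng.integers(len(_SENSE_CODONS), size=n_codons)
    )
    root_arr = np.frombuffer(root.encode(), dtype=np.uint8)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    base_idx = np.full(128, -1, dtype=np.int64)
    for i, b in enumerate(bases):
        base_idx[b] = i
    records = []
    for s in range(n_seqs):
        seq = root_arr.copy()
        if divergence > 0:
            hit = rng.random(seq.size) < divergence
            shift = rng.integers(1, 4, size=int(hit.sum()))
            seq[hit] = bases[(base_idx[seq[hit]] + shift) % 4]
        row = seq.tobytes().decode()
        if indel_rate > 0:
            codons = [row[i : i + 3] for i in range(0, len(row), 3)]
            dele = rng.random(n_codons) < indel_rate
            codons = ["---" if d else c for c, d in zip(codons, dele)]
            row = "".join(codons)
        records.append((f"seq{s + 1:03d}", row))
    return Alignment(tuple(records), "nt")
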