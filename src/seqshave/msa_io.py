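"""Gapped FASTA alignment container and codon/protein coordinate plumbing.

The central object is :class:`Alignment`, an immutable rectangular block of
gapped sequences (protein or nucleotide) with per-sequence maps between
ungapped residue indices and alignment columns.  All externally visible
coordinates are 1-based inclusive.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
_AA_ALLOWED = frozenset(AA_LETTERS + "X" + GAP)
_NT_ALLOWED = frozenset("ACGTN" + GAP)

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
_FORWARD = dict(_CODON_TABLE.forward_table)
_STOPS = frozenset(_CODON_TABLE.stop_codons)


class AlignmentError(ValueError):
    """Malformed alignment: ragged rows, duplicate ids or illegal characters."""


class CodonPhaseError(ValueError):
    """Nucleotide sequence is not in codon phase (length or gap placement)."""


@dataclass(frozen=True)
class CoordMap:
    """Bijection between 1-based ungapped residue index and alignment column."""

    res_to_col: np.ndarray  # res_to_col[k-1] = column of residue k (1-based)
    col_to_res: np.ndarray  # col_to_res[c-1] = residue at column c, 0 if gap

    @classmethod
    def from_gapped(cls, gapped: str) -> "CoordMap":
        arr = np.frombuffer(gapped.encode(), dtype="S1")
        is_res = arr != GAP.encode()
        cols = np.nonzero(is_res)[0] + 1
        col_to_res = np.where(is_res, np.cumsum(is_res), 0)
        return cls(res_to_col=cols, col_to_res=col_to_res)

    @property
    def n_residues(self) -> int:
        return int(len(self.res_to_col))

    def col_of(self, residue_index: int) -> int:
        if not 1 <= residue_index <= self.n_residues:
            raise IndexError(f"residue index {residue_index} out of range")
        return int(self.res_to_col[residue_index - 1])

    def res_of(self, column: int) -> int:
        """Residue index at a column (0 means the column is a gap here)."""
        return int(self.col_to_res[column - 1])


def _normalize(seq: str) -> str:
    return seq.upper().replace(".", GAP)


@dataclass(frozen=True)
class Alignment:
    """A rectangular gapped alignment over an amino-acid or nucleotide alphabet."""

    records: tuple[tuple[str, str], ...]
    alphabet: str  # "aa" | "nt"
    _maps: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if not self.records:
            raise AlignmentError("empty alignment")
        if self.alphabet not in ("aa", "nt"):
            raise AlignmentError(f"unknown alphabet {self.alphabet!r}")
        lengths = {len(s) for _, s in self.records}
        if len(lengths) != 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        ids = [i for i, _ in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dupes}")
        allowed = _AA_ALLOWED if self.alphabet == "aa" else _NT_ALLOWED
        for sid, seq in self.records:
            bad = set(seq) - allowed
            if bad:
                raise AlignmentError(
                    f"illegal characters {sorted(bad)} in sequence {sid!r} "
                    f"for alphabet {self.alphabet!r}"
                )

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]], alphabet: str) -> "Alignment":
        return cls(tuple((i, _normalize(s)) for i, s in pairs), alphabet)

    # -- basic accessors -------------------------------------------------

    @property
    def n_cols(self) -> int:
        return len(self.records[0][1])

    @property
    def n_seqs(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.records]

    def seq(self, seq_id: str) -> str:
        for i, s in self.records:
            if i == seq_id:
                return s
        raise KeyError(seq_id)

    def ungapped(self, seq_id: str) -> str:
        return self.seq(seq_id).replace(GAP, "")

    def coord_map(self, seq_id: str) -> CoordMap:
        if seq_id not in self._maps:
            self._maps[seq_id] = CoordMap.from_gapped(self.seq(seq_id))
        return self._maps[seq_id]

    def residue_count(self) -> int:
        return sum(len(s) - s.count(GAP) for _, s in self.records)

    def replace_seq(self, seq_id: str, new_gapped: str) -> "Alignment":
        if len(new_gapped) != self.n_cols:
            raise AlignmentError("replacement sequence has wrong length")
        recs = tuple(
            (i, new_gapped if i == seq_id else s) for i, s in self.records
        )
        return Alignment(recs, self.alphabet)


# -- FASTA I/O ----------------------------------------------------------


def read_fasta(path, alphabet: str | None = None) -> Alignment:
    """Read a gapped FASTA alignment.

    The alphabet is auto-detected (nucleotide iff every character is in
    ``ACGTN-``) unless given explicitly.  ``.`` gaps are normalized to ``-``
    and sequences are uppercased.
    """
    pairs = [(rec.id, _normalize(str(rec.seq))) for rec in SeqIO.parse(str(path), "fasta")]
    if not pairs:
        raise AlignmentError(f"no FASTA records in {path}")
    if alphabet is None:
        chars = set().union(*(set(s) for _, s in pairs))
        alphabet = "nt" if chars <= _NT_ALLOWED else "aa"
    return Alignment(tuple(pairs), alphabet)


def write_fasta(aln: Alignment, path) -> None:
    """Write 60-column wrapped FASTA atomically (temp file + rename)."""
    records = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in aln.records
    ]
    directory = os.path.dirname(os.path.abspath(str(path))) or "."
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".fasta.tmp")
    try:
        with os.fdopen(fd, "w") as handle:
            SeqIO.write(records, handle, "fasta")
        os.replace(tmp, str(path))
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# -- protein/codon plumbing ---------------------------------------------


def transfer_gaps(protein_aln: Alignment, cds_seqs: Mapping[str, str]) -> Alignment:
    """Expand a protein alignment's gap pattern onto ungapped CDS sequences.

    Each amino-acid gap becomes ``---``; codon content is untouched.  Every
    protein id must be present in *cds_seqs* with exactly 3x the ungapped
    protein length.
    """
    if protein_aln.alphabet != "aa":
        raise AlignmentError("transfer_gaps expects a protein alignment")
    out = []
    for sid, gapped in protein_aln.records:
        try:
            cds = _normalize(cds_seqs[sid]).replace(GAP, "")
        except KeyError:
            raise CodonPhaseError(f"no CDS provided for {sid!r}") from None
        n_res = len(gapped) - gapped.count(GAP)
        if len(cds) != 3 * n_res:
            raise CodonPhaseError(
                f"{sid!r}: CDS length {len(cds)} != 3 x {n_res} residues"
            )
        chunks = []
        k = 0
        for ch in gapped:
            if ch == GAP:
                chunks.append("---")
            else:
                chunks.append(cds[3 * k : 3 * k + 3])
                k += 1
        out.append((sid, "".join(chunks)))
    return Alignment(tuple(out), "nt")


def translate(nt_seq: str) -> str:
    """Translate a codon-phased (possibly gapped) nucleotide sequence.

    Standard genetic code; STOP codons become ``X`` (kept, never truncating);
    ``---`` becomes ``-``; codons containing ``N`` become ``X``.
    """
    seq = _normalize(nt_seq)
    if len(seq) % 3 != 0:
        raise CodonPhaseError(f"sequence length {len(seq)} not divisible by 3")
    out = []
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if codon == "---":
            out.append(GAP)
        elif GAP in codon:
            raise CodonPhaseError(f"broken gap triplet {codon!r} at nt {i + 1}")
        elif codon in _STOPS or "N" in codon:
            out.append("X")
        else:
            out.append(_FORWARD[codon])
    return "".join(out)


def translate_alignment(nt_aln: Alignment) -> Alignment:
    if nt_aln.alphabet != "nt":
        raise AlignmentError("translate_alignment expects a nucleotide alignment")
    return Alignment(
        tuple((sid, translate(seq)) for sid, seq in nt_aln.records), "aa"
    )
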