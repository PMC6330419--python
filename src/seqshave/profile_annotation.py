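"""Profile construction and four-category match/mismatch annotation.

Every ungapped residue of every sequence is labelled with one of four
symbols describing how well it fits a profile built from the alignment:

* ``U`` — equals the profile consensus, consensus emission probability > 50%
* ``L`` — equals the profile consensus, consensus emission probability < 50%
* ``P`` — differs from the consensus but has a positive log-odds emission
  score against the background (a conservative substitution)
* ``B`` — blank: negative log-odds score, or not covered by any profile
  match (insert columns, residues outside every search envelope)

Two engines produce these annotations.  The *internal* engine is a small,
deterministic, dependency-free reference: per match column it computes
Laplace(+1) emission frequencies from the profile-building set and applies
the category rule directly.  The *external* engine drives HMMER (via
pyhmmer): it builds the profile with a Laplace +1 prior and fragment
threshold 0, searches each sequence, and reads the categories off the
per-domain alignment midline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .msa_io import AA_LETTERS, GAP, Alignment

# Robinson & Robinson (1991) amino-acid background frequencies, the standard
# composition table used by profile search tools; normalized at import.
ROBINSON_FREQS = {
    "A": 0.07805, "C": 0.01925, "D": 0.05364, "E": 0.06295, "F": 0.03856,
    "G": 0.07377, "H": 0.02199, "I": 0.05142, "K": 0.05744, "L": 0.09019,
    "M": 0.02243, "N": 0.04487, "P": 0.05203, "Q": 0.04264, "R": 0.05129,
    "S": 0.07120, "T": 0.05841, "V": 0.06441, "W": 0.01330, "Y": 0.03216,
}

_AA_INDEX = {a: i for i, a in enumerate(AA_LETTERS)}
N_AA = len(AA_LETTERS)


def background_array(name: str = "robinson") -> np.ndarray:
    """Background frequencies over the 20 amino acids, in AA_LETTERS order."""
    if name == "robinson":
        v = np.array([ROBINSON_FREQS[a] for a in AA_LETTERS])
    elif name == "uniform":
        v = np.full(N_AA, 1.0)
    else:
        raise ValueError(f"unknown background table {name!r}")
    return v / v.sum()


class EngineError(RuntimeError):
    """The annotation engine failed or produced unusable output."""


@dataclass(frozen=True)
class MatchAnnotation:
    """Per-sequence category string, one symbol per ungapped residue."""

    seq_id: str
    symbols: str

    def __post_init__(self):
        bad = set(self.symbols) - set("BPLU")
        if bad:
            raise ValueError(f"illegal annotation symbols {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class ProfileSpec:
    """How to build the profile and annotate against it.

    match_column_rule is the maximum gap fraction for an alignment column to
    be treated as a profile match state (internal engine only; the external
    engine delegates this to HMMER's own architecture rule).
    """

    strategy: str = "complete"  # complete | leave_one_out
    engine: str = "internal"  # internal | external
    match_column_rule: float = 0.5
    background: str = "robinson"  # robinson | uniform
    prior: str = "laplace_plus_one"

    def __post_init__(self):
        if self.strategy not in ("complete", "leave_one_out"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.engine not in ("internal", "external"):
            raise ValueError(f"unknown engine {self.engine!r}")
        if not 0.0 <= self.match_column_rule <= 1.0:
            raise ValueError("match_column_rule must be in [0, 1]")
        if self.prior != "laplace_plus_one":
            raise ValueError(f"unsupported prior {self.prior!r}")


def annotate_alignment(aln: Alignment, spec: ProfileSpec | None = None) -> list[MatchAnnotation]:
    """Annotate every sequence of a protein alignment.

    Under the leave-one-out strategy the profile scoring sequence *i* is
    built from all sequences except *i*; under the complete strategy a single
    profile from the whole alignment is reused for every sequence.
    """
    spec = spec or ProfileSpec()
    if aln.alphabet != "aa":
        raise ValueError("annotation requires a protein alignment")
    if aln.n_seqs < 2:
        raise ValueError("annotation requires at least 2 sequences")
    if spec.engine == "internal":
        return [
            internal_engine_annotate(aln, spec, i) for i in range(aln.n_seqs)
        ]
    return external_engine_annotate(aln, spec)


# -- internal reference engine ------------------------------------------


def _encode(aln: Alignment) -> np.ndarray:
    """Integer matrix: 0..19 residues, 20 gap, 21 unknown (X)."""
    mat = np.empty((aln.n_seqs, aln.n_cols), dtype=np.int8)
    lut = np.full(128, 21, dtype=np.int8)
    for a, i in _AA_INDEX.items():
        lut[ord(a)] = i
    lut[ord(GAP)] = 20
    for r, (_, seq) in enumerate(aln.records):
        mat[r] = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
    return mat


def _column_profile(mat: np.ndarray, exclude: int | None):
    """Laplace(+1) emission frequencies and match-column gap fractions."""
    rows = np.ones(mat.shape[0], dtype=bool)
    if exclude is not None:
        rows[exclude] = False
    sub = mat[rows]
    counts = np.zeros((N_AA, mat.shape[1]), dtype=np.int64)
    for a in range(N_AA):
        counts[a] = (sub == a).sum(axis=0)
    gap_frac = (sub == 20).mean(axis=0)
    n_res = counts.sum(axis=0)  # X excluded from emission counting
    emis = (counts + 1.0) / (n_res + N_AA)
    return emis, gap_frac


def internal_engine_annotate(
    aln: Alignment, spec: ProfileSpec, seq_index: int
) -> MatchAnnotation:
    """Annotate one sequence with the deterministic reference rule.

    Match columns are alignment columns whose gap fraction over the
    profile-building set is <= spec.match_column_rule.  For a residue r in a
    match column with Laplace emission e and consensus argmax(e):
    r == consensus -> 'U' if e(r) > 0.5 else 'L'; else 'P' if
    log(e(r)/background(r)) > 0 else 'B'.  Residues in insert columns, and
    unknown ('X') residues, are 'B'.
    """
    mat = _encode(aln)
    exclude = seq_index if spec.strategy == "leave_one_out" else None
    emis, gap_frac = _column_profile(mat, exclude)
    is_match = gap_frac <= spec.match_column_rule
    bg = background_array(spec.background)
    # consensus: argmax emission; np.argmax ties break to the lowest index,
    # i.e. alphabetically first residue — deterministic.
    consensus = emis.argmax(axis=0)
    cons_emis = emis[consensus, np.arange(mat.shape[1])]

    row = mat[seq_index]
    out = []
    for c in range(mat.shape[1]):
        r = row[c]
        if r == 20:
            continue  # gap: no symbol
        if r == 21 or not is_match[c]:
            out.append("B")
        elif r == consensus[c]:
            out.append("U" if cons_emis[c] > 0.5 else "L")
        elif emis[r, c] > bg[r]:
            out.append("P")
        else:
            out.append("B")
    sid = aln.records[seq_index][0]
    return MatchAnnotation(seq_id=sid, symbols="".join(out))


# -- external engine (HMMER via pyhmmer) --------------------------------


def _pyhmmer():
    try:
        import pyhmmer  # noqa: F401

        return pyhmmer
    except ImportError as exc:  # pragma: no cover - present in supported envs
        raise EngineError(
            "the external engine requires the 'pyhmmer' package "
            "(pip install pyhmmer), or use engine='internal'"
        ) from exc


def _midline_category(ch: str) -> str:
    if ch.isalpha():
        return "U" if ch.isupper() else "L"
    if ch == "+":
        return "P"
    return "B"


def _annotate_with_profile(pyhmmer, hmm, background, targets, lengths):
    """Search digitized targets against one profile; return symbol lists."""
    from pyhmmer.easel import DigitalSequenceBlock

    pipeline = pyhmmer.plan7.Pipeline(hmm.alphabet, background=background)
    block = DigitalSequenceBlock(hmm.alphabet, targets)
    hits = pipeline.search_hmm(hmm, block)
    symbols = {name: ["B"] * n for name, n in lengths.items()}
    for hit in hits:
        name = hit.name.decode() if isinstance(hit.name, bytes) else hit.name
        if name not in symbols:  # pragma: no cover - defensive
            continue
        syms = symbols[name]
        # lower-scoring envelopes first so higher-scoring ones win overlaps
        domains = sorted(hit.domains.included, key=lambda d: d.score)
        for dom in domains:
            ali = dom.alignment
            res = ali.target_from  # 1-based first residue of the envelope
            for tch, mch in zip(ali.target_sequence, ali.identity_sequence):
                if tch == "-":
                    continue  # deletion relative to the profile
                cat = _midline_category(mch)
                if cat != "B" or syms[res - 1] == "B":
                    syms[res - 1] = cat
                res += 1
    return symbols


def external_engine_annotate(
    aln: Alignment, spec: ProfileSpec | None = None
) -> list[MatchAnnotation]:
    """Annotate all sequences by building and searching a HMMER profile.

    The profile is built with a Laplace +1 prior and fragment threshold 0
    (every sequence weighted as full-length), then each ungapped sequence is
    searched against it; the per-domain alignment midline supplies the
    categories.  Sequences with no reported envelope are annotated all-'B'.
    """
    spec = spec or ProfileSpec(engine="external")
    if aln.alphabet != "aa":
        raise ValueError("annotation requires a protein alignment")
    if aln.n_seqs < 2:
        raise ValueError("annotation requires at least 2 sequences")
    pyhmmer = _pyhmmer()
    from pyhmmer.easel import Alphabet, TextMSA, TextSequence

    abc = Alphabet.amino()
    builder = pyhmmer.plan7.Builder(abc, prior_scheme="laplace", fragthresh=0.0)
    bg = pyhmmer.plan7.Background(abc)

    def build(indices):
        msa = TextMSA(
            name=b"profile",
            sequences=[
                TextSequence(
                    name=aln.records[i][0].encode(), sequence=aln.records[i][1]
                )
                for i in indices
            ],
        )
        try:
            hmm, _, _ = builder.build_msa(msa.digitize(abc), bg)
        except Exception as exc:
            raise EngineError(f"profile construction failed: {exc}") from exc
        return hmm

    targets = {
        sid: TextSequence(name=sid.encode(), sequence=aln.ungapped(sid)).digitize(abc)
        for sid in aln.ids
    }
    lengths = {sid: len(aln.ungapped(sid)) for sid in aln.ids}

    if spec.strategy == "complete":
        hmm = build(range(aln.n_seqs))
        symbols = _annotate_with_profile(
            pyhmmer, hmm, bg, list(targets.values()), lengths
        )
    else:
        symbols = {}
        for i, sid in enumerate(aln.ids):
            hmm = build([j for j in range(aln.n_seqs) if j != i])
            got = _annotate_with_profile(
                pyhmmer, hmm, bg, [targets[sid]], {sid: lengths[sid]}
            )
            symbols[sid] = got[sid]
    return [MatchAnnotation(sid, "".join(symbols[sid])) for sid in aln.ids]
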