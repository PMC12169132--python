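"""Pairwise global alignment and MSA column conservation with BLOSUM62.

Alignment is affine-gap Needleman–Wunsch (gap open 10, extend 0.5 by
default) over the standard BLOSUM62 matrix, delegated to Biopython's
``PairwiseAligner``; scores involving the unknown-residue letter X are
set to 0.  Conservation classing of an alignment column against a
reference residue follows the log-odds sign: identical column →
*conserved*; every substitution scoring ≥ 0 → *conservative*; any
negative-scoring substitution (or a gap) → *non-conservative*.  The raw
minimum score is always reported so a looser reading (e.g. treating −1
substitutions between similar small residues as benign) stays available
to the user.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

__all__ = [
    "AlignmentResult",
    "ConservationReport",
    "blosum62",
    "global_align",
    "conservation_profile",
    "read_fasta",
]


def blosum62():
    """BLOSUM62 with all X-involving scores set to 0."""
    matrix = substitution_matrices.load("BLOSUM62")
    alphabet = matrix.alphabet
    if "X" in alphabet:
        xi = alphabet.index("X")
        matrix[xi, :] = 0.0
        matrix[:, xi] = 0.0
    return matrix


_MATRIX = blosum62()
_ALPHABET = set(_MATRIX.alphabet)


@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    position_map: dict  # 1-based ungapped A position -> B position or None

    def recomputed_score(self, gap_open: float = 10.0, gap_extend: float = 0.5) -> float:
        """Re-derive the score from the aligned strings (consistency check)."""
        score, in_gap_a, in_gap_b = 0.0, False, False
        for ca, cb in zip(self.aligned_a, self.aligned_b):
            if ca == "-":
                score -= gap_extend if in_gap_a else gap_open
                in_gap_a, in_gap_b = True, False
            elif cb == "-":
                score -= gap_extend if in_gap_b else gap_open
                in_gap_b, in_gap_a = True, False
            else:
                score += float(_MATRIX[ca, cb])
                in_gap_a = in_gap_b = False
        return score


@dataclass
class ConservationReport:
    positions: list      # queried reference positions (1-based, ungapped)
    rows: list           # dicts: position, reference, column, identity, min_score, class


def _validate(seq: str, label: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _ALPHABET
    if bad:
        raise ValueError(f"sequence {label} contains letters outside the "
                         f"substitution alphabet: {sorted(bad)}")
    return seq


def global_align(seq_a: str, seq_b: str, gap_open: float = 10.0,
                 gap_extend: float = 0.5) -> AlignmentResult:
    """Affine-gap global alignment; a gap of length L costs
    ``gap_open + (L − 1)·gap_extend``.  Deterministic: of co-optimal
    alignments the aligner's first (diagonal-preferring) traceback is kept.
    """
    seq_a, seq_b = _validate(seq_a, "A"), _validate(seq_b, "B")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _MATRIX
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    if not seq_a or not seq_b:
        # degenerate: one pure gap run (or an empty-vs-empty zero alignment)
        n = max(len(seq_a), len(seq_b))
        score = 0.0 if n == 0 else -(gap_open + (n - 1) * gap_extend)
        aligned_a = seq_a if seq_a else "-" * n
        aligned_b = seq_b if seq_b else "-" * n
        pmap = {i + 1: None for i in range(len(seq_a))}
        return AlignmentResult(aligned_a, aligned_b, score, pmap)
    alignment = aligner.align(seq_a, seq_b)[0]
    aligned_a, aligned_b = str(alignment[0]), str(alignment[1])
    pmap, ia, ib = {}, 0, 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca != "-" and cb != "-":
            ia, ib = ia + 1, ib + 1
            pmap[ia] = ib
        elif ca != "-":
            ia += 1
            pmap[ia] = None
        else:
            ib += 1
    return AlignmentResult(aligned_a, aligned_b, float(alignment.score), pmap)


def conservation_profile(msa, reference_id: str, positions) -> ConservationReport:
    """Column conservation of queried reference positions in an aligned MSA.

    ``msa`` is a list of ``(id, aligned_sequence)`` pairs of equal length;
    ``positions`` are 1-based ungapped positions in the reference row and
    are mapped through its gaps.  Identity is the fraction of rows whose
    column residue equals the reference residue (gaps never match).
    """
    msa = [(str(i), str(s).upper()) for i, s in msa]
    lengths = {len(s) for _, s in msa}
    if len(lengths) != 1:
        raise ValueError("MSA rows have unequal lengths")
    ref_rows = [s for i, s in msa if i == reference_id]
    if not ref_rows:
        raise ValueError(f"reference row {reference_id!r} not found")
    ref = ref_rows[0]
    # ungapped reference position -> alignment column
    col_of = {}
    pos = 0
    for col, c in enumerate(ref):
        if c != "-":
            pos += 1
            col_of[pos] = col
    rows = []
    for p in positions:
        if p not in col_of:
            raise ValueError(f"position {p} beyond the reference length {pos}")
        col = col_of[p]
        ref_res = ref[col]
        column = [s[col] for _, s in msa]
        identity = float(np.mean([c == ref_res for c in column]))
        scores = []
        has_gap = False
        for c in column:
            if c == "-":
                has_gap = True
            elif c != ref_res:
                scores.append(float(_MATRIX[ref_res, c]))
        min_score = min(scores) if scores else float(_MATRIX[ref_res, ref_res])
        if identity == 1.0:
            klass = "conserved"
        elif not has_gap and all(s >= 0 for s in scores):
            klass = "conservative"
        else:
            klass = "non-conservative"
        rows.append({
            "position": int(p), "reference": ref_res, "column": column,
            "identity": identity, "min_score": min_score, "class": klass,
        })
    return ConservationReport(positions=[int(p) for p in positions], rows=rows)


def read_fasta(path):
    """Read sequences (or an aligned MSA) as a list of (id, sequence) pairs."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
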