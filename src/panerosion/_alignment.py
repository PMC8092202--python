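"""Shared pairwise/multiple alignment primitives.

All pairwise alignments are delegated to :class:`Bio.Align.PairwiseAligner`
with fixed, deterministic scoring schemes:

* proteins — BLOSUM62, affine gaps (open -11, extend -1);
* nucleotides — match +2 / mismatch -3, affine gaps (open -5, extend -2).

The multiple aligner is a center-star progressive alignment: the center is
the sequence maximising the summed pairwise global score against all other
members, every other sequence is aligned to the center pairwise, and the
pairwise alignments are merged in the center's coordinate system
("once a gap, always a gap").
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices

PROTEIN_GAP_OPEN = -11.0
PROTEIN_GAP_EXTEND = -1.0
NT_MATCH = 2.0
NT_MISMATCH = -3.0
NT_GAP_OPEN = -5.0
NT_GAP_EXTEND = -2.0


@lru_cache(maxsize=None)
def protein_aligner(mode: str = "global") -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = PROTEIN_GAP_OPEN
    aligner.extend_gap_score = PROTEIN_GAP_EXTEND
    return aligner


@lru_cache(maxsize=None)
def nucleotide_aligner(mode: str = "global") -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = NT_MATCH
    aligner.mismatch_score = NT_MISMATCH
    aligner.open_gap_score = NT_GAP_OPEN
    aligner.extend_gap_score = NT_GAP_EXTEND
    return aligner


def global_protein_pair(a: str, b: str) -> tuple[str, str]:
    """Globally align two protein sequences; return the gapped strings."""
    alignment = protein_aligner("global").align(a, b)[0]
    return alignment[0], alignment[1]


def global_nucleotide_pair(a: str, b: str) -> tuple[str, str]:
    """Globally align two nucleotide sequences; return the gapped strings."""
    alignment = nucleotide_aligner("global").align(a, b)[0]
    return alignment[0], alignment[1]


def local_protein_score(query: str, subject: str) -> float:
    return protein_aligner("local").score(query, subject)


def local_protein_identity(query: str, subject: str) -> tuple[float, float]:
    """Best local alignment of two proteins.

    Returns ``(score, identity_pct)`` where identity is the percentage of
    identical residue pairs over the aligned columns (gap columns included).
    """
    alignments = protein_aligner("local").align(query, subject)
    try:
        alignment = alignments[0]
    except IndexError:  # no positive-scoring local alignment exists
        return 0.0, 0.0
    rows = (alignment[0], alignment[1])
    ncols = len(rows[0])
    if ncols == 0:
        return alignment.score, 0.0
    matches = sum(1 for x, y in zip(*rows) if x == y and x != "-")
    return alignment.score, 100.0 * matches / ncols


def _slot_decompose(gapped_center: str, gapped_other: str, center_len: int):
    """Split a center-vs-other pairwise alignment into the center's slots.

    Slot ``j`` holds the residues of *other* inserted between center
    positions ``j-1`` and ``j``; ``pos_chars[j]`` is the other's character
    (possibly ``-``) aligned to center position ``j``.
    """
    slot_frags: list[list[str]] = [[] for _ in range(center_len + 1)]
    pos_chars: list[str] = [""] * center_len
    j = 0
    for c_center, c_other in zip(gapped_center, gapped_other):
        if c_center == "-":
            slot_frags[j].append(c_other)
        else:
            pos_chars[j] = c_other
            j += 1
    return slot_frags, pos_chars


def center_star_align(seqs: dict[str, str], center: str | None = None) -> dict[str, str]:
    """Center-star progressive multiple alignment.

    Parameters
    ----------
    seqs
        Mapping sequence id -> ungapped protein sequence.
    center
        Optional center id. By default the center is the longest sequence
        maximising the summed pairwise global score: the center acts as
        the alignment scaffold, and a truncated member used as scaffold
        fragments the alignment of the full-length members.

    Returns
    -------
    dict
        Mapping sequence id -> gapped row; all rows have equal length and
        ungapping each row recovers the input sequence.
    """
    if not seqs:
        raise ValueError("no sequences to align")
    ids = sorted(seqs)
    if len(ids) == 1:
        return {ids[0]: seqs[ids[0]]}

    if center is None:
        aligner = protein_aligner("global")
        max_len = max(len(seqs[i]) for i in ids)
        candidates = [i for i in ids if len(seqs[i]) == max_len]
        score_sum = {i: 0.0 for i in candidates}
        for a in candidates:
            for b in ids:
                if b != a:
                    score_sum[a] += aligner.score(seqs[a], seqs[b])
        # ties broken by sequence id for determinism
        center = max(candidates, key=lambda i: (score_sum[i], i))
    elif center not in seqs:
        raise ValueError(f"center {center!r} not among the sequences")
    center_seq = seqs[center]
    length = len(center_seq)

    others = [i for i in ids if i != center]
    decomposed = {}
    for other in others:
        gc, go = global_protein_pair(center_seq, seqs[other])
        decomposed[other] = _slot_decompose(gc, go, length)

    slot_width = [0] * (length + 1)
    for frags, _ in decomposed.values():
        for j, frag in enumerate(frags):
            slot_width[j] = max(slot_width[j], len(frag))

    rows: dict[str, str] = {}
    center_parts = []
    for j in range(length):
        center_parts.append("-" * slot_width[j] + center_seq[j])
    center_parts.append("-" * slot_width[length])
    rows[center] = "".join(center_parts)

    for other in others:
        frags, pos_chars = decomposed[other]
        parts = []
        for j in range(length):
            frag = "".join(frags[j])
            parts.append(frag + "-" * (slot_width[j] - len(frag)) + pos_chars[j])
        frag = "".join(frags[length])
        parts.append(frag + "-" * (slot_width[length] - len(frag)))
        rows[other] = "".join(parts)

    assert len({len(r) for r in rows.values()}) == 1
    return rows
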