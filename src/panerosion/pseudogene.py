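"""Codon-aware pseudogene classification within gene families.

For each orthologous group the member proteins are aligned (center-star
progressive alignment, or an externally supplied alignment used verbatim),
the protein alignment is back-translated into a codon-based nucleotide
alignment, and each member is scored on three pieces of evidence:

* internal stop codons (bacterial code, table 11) in its codon row;
* frameshifts — maximal indel runs of length not divisible by 3 in a
  global nucleotide alignment against the group's reference (the longest
  frame-consistent, stop-free member);
* the fraction of gap characters in its row of the nucleotide alignment.

The decision rule has two modes. In the default ``literal`` mode a member
is a pseudogene iff it has at least one internal stop AND at least one
frameshift, OR more than 30% of its alignment row is gaps. The ``any``
mode instead ORs all three criteria. The gap threshold is strict:
exactly 30% does not fire.

Members whose CDS length (terminal stop stripped) is not three times their
protein length are frame-inconsistent: they bypass back-translation and are
analysed directly against the reference CDS, with the frameshift alignment
also used to frame-correct the sequence before stop counting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from ._alignment import center_star_align, global_nucleotide_pair
from .orthology import OrthoGroup

logger = logging.getLogger(__name__)

GAP_THRESHOLD = 0.30
STOP_CODONS = {"TAA", "TAG", "TGA"}
MODES = ("literal", "any")


@dataclass
class CodonAlignment:
    group_id: str
    rows: dict[str, str]  # gene_id -> gapped nucleotide row
    aa_rows: dict[str, str]  # gene_id -> gapped protein row
    length: int  # nucleotide columns


@dataclass
class PseudoCall:
    gene_id: str
    group_id: str
    n_internal_stops: int
    n_frameshifts: int
    gap_fraction: float
    criteria_fired: frozenset
    is_pseudogene: bool
    mode: str


def strip_terminal_stop(cds: str) -> str:
    """Remove the terminal stop codon when the CDS is in frame and ends in one."""
    if len(cds) >= 3 and len(cds) % 3 == 0 and cds[-3:].upper() in STOP_CODONS:
        return cds[:-3]
    return cds


def align_family(aa_seqs: dict[str, str]) -> dict[str, str]:
    """Protein multiple alignment of a family (center-star progressive).

    A single sequence is returned unaligned as a one-row MSA.
    """
    if not aa_seqs:
        raise ValueError("empty family")
    if len(aa_seqs) == 1:
        return dict(aa_seqs)
    return center_star_align(aa_seqs)


def backtranslate(
    protein_msa: dict[str, str], nt_seqs: dict[str, str], group_id: str = ""
) -> tuple[CodonAlignment, list[str]]:
    """Expand a protein MSA to a codon-based nucleotide alignment.

    Each residue column becomes the corresponding codon; protein gaps
    expand to ``---``. Rows whose CDS (terminal stop stripped) is not
    exactly 3x the ungapped protein length are frame-inconsistent: they
    are excluded from the codon alignment and returned separately for
    direct frameshift analysis.
    """
    rows: dict[str, str] = {}
    inconsistent: list[str] = []
    for gid, aa_row in protein_msa.items():
        cds = strip_terminal_stop(nt_seqs[gid])
        n_res = sum(1 for c in aa_row if c != "-")
        if len(cds) != 3 * n_res:
            inconsistent.append(gid)
            continue
        parts = []
        k = 0
        for c in aa_row:
            if c == "-":
                parts.append("---")
            else:
                parts.append(cds[3 * k : 3 * k + 3])
                k += 1
        rows[gid] = "".join(parts)
    length = len(next(iter(rows.values()))) if rows else 0
    aa_rows = {gid: protein_msa[gid] for gid in rows}
    return CodonAlignment(group_id=group_id, rows=rows, aa_rows=aa_rows, length=length), inconsistent


def detect_internal_stops(codon_row: str) -> int:
    """Count stop codons strictly before the final non-gap codon of a row.

    Gap codons are skipped; codons containing N are not counted (logged).
    """
    if len(codon_row) % 3 != 0:
        raise ValueError("codon row length must be a multiple of 3")
    codons = [codon_row[i : i + 3].upper() for i in range(0, len(codon_row), 3)]
    non_gap = [i for i, c in enumerate(codons) if "-" not in c]
    if not non_gap:
        return 0
    last = non_gap[-1]
    count = 0
    for i in non_gap:
        if i >= last:
            break
        codon = codons[i]
        if "N" in codon:
            logger.debug("codon with N skipped at position %d", i)
            continue
        if codon in STOP_CODONS:
            count += 1
    return count


def _indel_runs(row_a: str, row_b: str) -> list[int]:
    """Lengths of maximal single-row gap runs, terminal overhangs excluded."""
    n = len(row_a)
    start = 0
    while start < n and (row_a[start] == "-" or row_b[start] == "-"):
        start += 1
    end = n
    while end > start and (row_a[end - 1] == "-" or row_b[end - 1] == "-"):
        end -= 1
    runs = []
    current_row = None
    run_len = 0
    for i in range(start, end):
        gap_row = "a" if row_a[i] == "-" else ("b" if row_b[i] == "-" else None)
        if gap_row == current_row:
            if gap_row is not None:
                run_len += 1
            continue
        if current_row is not None:
            runs.append(run_len)
        current_row = gap_row
        run_len = 1 if gap_row is not None else 0
    if current_row is not None:
        runs.append(run_len)
    return runs


def detect_frameshifts(cds: str, reference_cds: str) -> int:
    """Frameshifts of ``cds`` relative to the reference CDS.

    The two sequences are globally aligned at the nucleotide level and the
    maximal indel runs whose length is not a multiple of 3 are counted;
    terminal overhangs are excluded.
    """
    if cds == reference_cds:
        return 0
    ref_row, cds_row = global_nucleotide_pair(reference_cds, cds)
    return sum(1 for ell in _indel_runs(ref_row, cds_row) if ell % 3 != 0)


def frame_correct(cds: str, reference_cds: str) -> str:
    """Project ``cds`` onto the reference frame.

    Bases inserted relative to the reference are removed and deleted
    positions are padded with N, restoring the reference reading frame so
    that internal stops can be counted on a frame-inconsistent sequence.
    """
    ref_row, cds_row = global_nucleotide_pair(reference_cds, cds)
    out = []
    for r, c in zip(ref_row, cds_row):
        if r == "-":
            continue
        out.append(c if c != "-" else "N")
    return "".join(out)


def gap_fraction(aligned_row: str) -> float:
    """Fraction of gap characters over the full row of the nucleotide alignment."""
    if not aligned_row:
        raise ValueError("zero-length alignment row")
    return aligned_row.count("-") / len(aligned_row)


def classify(
    gene_id: str,
    group_id: str,
    n_internal_stops: int,
    n_frameshifts: int,
    gap_frac: float,
    mode: str = "literal",
) -> PseudoCall:
    """Apply the pseudogene decision rule to the three evidence counts.

    ``literal``: (stops >= 1 AND frameshifts >= 1) OR gap fraction > 0.30.
    ``any``: OR over all three criteria. ``criteria_fired`` lists every
    satisfied criterion regardless of mode.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    fired = set()
    if n_internal_stops >= 1:
        fired.add("stop")
    if n_frameshifts >= 1:
        fired.add("frameshift")
    if gap_frac > GAP_THRESHOLD:
        fired.add("gap")
    if mode == "literal":
        is_pseudo = ({"stop", "frameshift"} <= fired) or ("gap" in fired)
    else:
        is_pseudo = bool(fired)
    return PseudoCall(
        gene_id=gene_id,
        group_id=group_id,
        n_internal_stops=n_internal_stops,
        n_frameshifts=n_frameshifts,
        gap_fraction=gap_frac,
        criteria_fired=frozenset(fired),
        is_pseudogene=is_pseudo,
        mode=mode,
    )


def _reference_member(cds: dict[str, str]) -> str:
    """Longest in-frame member with zero internal stops; longest overall otherwise."""
    candidates = [
        gid
        for gid, seq in cds.items()
        if len(seq) % 3 == 0 and detect_internal_stops(seq) == 0
    ]
    if not candidates:
        logger.warning("no stop-free in-frame member; using longest member as reference")
        candidates = list(cds)
    return max(candidates, key=lambda g: (len(cds[g]), g))


def analyze_group(
    group_id: str,
    nt_seqs: dict[str, str],
    aa_seqs: dict[str, str],
    mode: str = "literal",
    external_alignment: dict[str, str] | None = None,
) -> list[PseudoCall]:
    """Full classification of one gene family.

    Frame-consistent members are scored on the codon alignment
    (stops + gap fraction) and on a global nucleotide alignment against
    the reference member (frameshifts). Frame-inconsistent members are
    scored entirely against the reference: indel runs give the frameshift
    count, the frame-corrected sequence gives the stop count, and their
    gap fraction is the fraction of deleted columns in that pairwise
    alignment.
    """
    cds = {gid: strip_terminal_stop(seq) for gid, seq in nt_seqs.items()}
    if external_alignment is not None:
        msa = external_alignment
    else:
        # frame-inconsistent members are kept out of the protein MSA: their
        # translation is off-frame downstream of the lesion and would
        # corrupt the alignment scaffold for everyone else
        consistent_aa = {
            gid: aa
            for gid, aa in aa_seqs.items()
            if len(cds[gid]) == 3 * len(aa)
        }
        msa = align_family(consistent_aa) if consistent_aa else {}
    codon_aln, inconsistent = backtranslate(msa, nt_seqs, group_id=group_id)
    ref = _reference_member(cds)
    ref_cds = cds[ref]

    calls = []
    for gid in sorted(nt_seqs):
        if gid in codon_aln.rows:
            row = codon_aln.rows[gid]
            n_stops = detect_internal_stops(row)
            gapf = gap_fraction(row)
            n_fs = detect_frameshifts(cds[gid], ref_cds)
        else:
            ref_row, gene_row = global_nucleotide_pair(ref_cds, cds[gid])
            n_fs = sum(1 for ell in _indel_runs(ref_row, gene_row) if ell % 3 != 0)
            # the frame inconsistency itself (CDS length not 3x protein
            # length) is frameshift evidence even when the optimal
            # alignment hides the indel inside a terminal overhang
            n_fs = max(n_fs, 1)
            corrected = "".join(
                (c if c != "-" else "N") for r, c in zip(ref_row, gene_row) if r != "-"
            )
            # stops are counted both on the frame-corrected sequence and on
            # the raw annotated frame: near a frameshift the optimal
            # nucleotide alignment can trade a stop codon's mismatches for
            # gap pairs, hiding it from the corrected frame, while upstream
            # of the first indel the annotated frame is unambiguous
            raw = cds[gid]
            raw_frame1 = raw[: len(raw) // 3 * 3]
            n_stops = max(detect_internal_stops(corrected), detect_internal_stops(raw_frame1))
            gapf = gene_row.count("-") / len(gene_row)
        calls.append(classify(gid, group_id, n_stops, n_fs, gapf, mode=mode))
    return calls


def classify_groups(groups: list[OrthoGroup], mode: str = "literal") -> pd.DataFrame:
    """Classify every member of every group; updates ``GeneRecord.status``.

    Returns the calls table (one row per gene).
    """
    rows = []
    for group in sorted(groups, key=lambda g: g.group_id):
        nt = {m.gene_id: m.nt_seq for m in group.members}
        aa = {m.gene_id: m.aa_seq for m in group.members}
        by_gene = {m.gene_id: m for m in group.members}
        for call in analyze_group(group.group_id, nt, aa, mode=mode):
            by_gene[call.gene_id].status = "pseudogene" if call.is_pseudogene else "intact"
            rows.append(
                (
                    call.gene_id,
                    by_gene[call.gene_id].genome_id,
                    call.group_id,
                    call.n_internal_stops,
                    call.n_frameshifts,
                    call.gap_fraction,
                    ",".join(sorted(call.criteria_fired)),
                    call.is_pseudogene,
                    call.mode,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "genome_id",
            "group_id",
            "n_internal_stops",
            "n_frameshifts",
            "gap_fraction",
            "criteria_fired",
            "is_pseudogene",
            "mode",
        ],
    )
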