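"""Flank extraction and pairwise conservation alignment.

For cross-species reports the regulatory module plus 200 bp of flanking
sequence on either side is aligned globally (affine gap penalties) and
summarized as percent identity plus maximal conserved blocks.  Two
identity figures are reported: over all alignment columns (gap columns
count against identity) and over aligned-residue columns only, since
published identity numbers rarely state which denominator was used.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align


@dataclass(frozen=True)
class FlankedModule:
    """A module core with its genomic flanks.

    ``left_flank + core + right_flank`` reconstructs the contiguous
    genomic slice; truncation at a contig end is recorded.
    """

    left_flank: str
    core: str
    right_flank: str
    flank_bp: int
    slice_start: int
    slice_end: int
    truncated_left: bool = False
    truncated_right: bool = False

    @property
    def sequence(self) -> str:
        return self.left_flank + self.core + self.right_flank


@dataclass(frozen=True)
class PairwiseConservation:
    """Summary of one global alignment.

    ``percent_identity`` uses all alignment columns as denominator;
    ``percent_identity_ungapped`` excludes gap columns.  Conserved
    blocks are maximal runs of >= k identical columns, reported in
    sequence-a coordinates (half-open).
    """

    aligned_a: str
    aligned_b: str
    score: float
    matches: int
    alignment_length: int
    percent_identity: float
    percent_identity_ungapped: float
    conserved_blocks: tuple[tuple[int, int], ...]


#: Default affine-gap scoring: a gap of length L costs open + (L-1)*extend.
DEFAULT_SCORING = {
    "match": 1.0,
    "mismatch": -1.0,
    "gap_open": -5.0,
    "gap_extend": -1.0,
}


def extract_flanks(
    module_start: int,
    module_end: int,
    contig_seq: str,
    flank_bp: int = 200,
) -> FlankedModule:
    """Slice a module core plus ``flank_bp`` bases on either side.

    Flanks are truncated only at contig ends and the truncation is
    flagged; a module outside the contig is rejected.
    """
    n = len(contig_seq)
    if not (0 <= module_start <= module_end <= n):
        raise ValueError(
            f"module [{module_start},{module_end}) outside contig of {n} bp"
        )
    ls = max(0, module_start - flank_bp)
    re_ = min(n, module_end + flank_bp)
    return FlankedModule(
        left_flank=contig_seq[ls:module_start],
        core=contig_seq[module_start:module_end],
        right_flank=contig_seq[module_end:re_],
        flank_bp=flank_bp,
        slice_start=ls,
        slice_end=re_,
        truncated_left=module_start - ls < flank_bp,
        truncated_right=re_ - module_end < flank_bp,
    )


def _make_aligner(scoring: dict | None) -> Align.PairwiseAligner:
    sc = dict(DEFAULT_SCORING)
    if scoring:
        sc.update(scoring)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = sc["match"]
    aligner.mismatch_score = sc["mismatch"]
    aligner.open_gap_score = sc["gap_open"]
    aligner.extend_gap_score = sc["gap_extend"]
    return aligner


def conserved_blocks_from_columns(
    aligned_a: str, aligned_b: str, k: int = 10
) -> tuple[tuple[int, int], ...]:
    """Maximal runs of >= k identical columns, in sequence-a coordinates."""
    blocks: list[tuple[int, int]] = []
    a_pos = 0
    run_start = None  # a-coordinate where the current identical run began
    run_len = 0
    for ca, cb in zip(aligned_a, aligned_b):
        identical = ca != "-" and ca == cb
        if identical:
            if run_len == 0:
                run_start = a_pos
            run_len += 1
        else:
            if run_len >= k:
                blocks.append((run_start, run_start + run_len))
            run_len = 0
        if ca != "-":
            a_pos += 1
    if run_len >= k:
        blocks.append((run_start, run_start + run_len))
    return tuple(blocks)


def global_align(
    a: str,
    b: str,
    scoring: dict | None = None,
    block_min: int = 10,
) -> PairwiseConservation:
    """Optimal global alignment of two sequences with affine gaps.

    Among co-optimal alignments the aligner's first is reported (the
    score, matches and identity of that alignment are deterministic for
    fixed inputs).  ``scoring`` may override any of
    ``match/mismatch/gap_open/gap_extend``.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = _make_aligner(scoring)
    aln = aligner.align(a.upper(), b.upper())[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    length = len(row_a)
    matches = sum(
        1 for ca, cb in zip(row_a, row_b) if ca != "-" and ca == cb
    )
    ungapped_cols = sum(
        1 for ca, cb in zip(row_a, row_b) if ca != "-" and cb != "-"
    )
    return PairwiseConservation(
        aligned_a=row_a,
        aligned_b=row_b,
        score=float(aln.score),
        matches=matches,
        alignment_length=length,
        percent_identity=100.0 * matches / length,
        percent_identity_ungapped=(
            100.0 * matches / ungapped_cols if ungapped_cols else 0.0
        ),
        conserved_blocks=conserved_blocks_from_columns(row_a, row_b, block_min),
    )


def format_alignment(
    cons: PairwiseConservation, name_a: str = "a", name_b: str = "b", width: int = 60
) -> str:
    """CLUSTAL-like text block with a '|' midline on identical columns."""
    mid = "".join(
        "|" if ca != "-" and ca == cb else " "
        for ca, cb in zip(cons.aligned_a, cons.aligned_b)
    )
    w = max(len(name_a), len(name_b), 4)
    out = [
        f"# score={cons.score:g} identity={cons.percent_identity:.1f}% "
        f"(ungapped {cons.percent_identity_ungapped:.1f}%) "
        f"columns={cons.alignment_length}"
    ]
    for i in range(0, cons.alignment_length, width):
        out.append(f"{name_a:<{w}s} {cons.aligned_a[i:i + width]}")
        out.append(f"{'':<{w}s} {mid[i:i + width]}")
        out.append(f"{name_b:<{w}s} {cons.aligned_b[i:i + width]}")
        out.append("")
    return "\n".join(out)
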