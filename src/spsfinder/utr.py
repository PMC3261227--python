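"""3' UTR regulatory-box profiling and cross-species organization
comparison.

The Brd, GY and K boxes are mRNA-level elements targeted by miRNAs, so
scanning is sense-strand only.  Conservation of organization between two
orthologs is judged on the ordered string of box types (longest common
subsequence), ignoring offsets: two UTRs are "identical" when their box
strings are equal and non-empty, "identical-empty" when both are empty,
"none" when they share no common subsequence, and "partial" otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

from .iupac import DegeneratePattern, compile_pattern, DEFAULT_MOTIFS

UTR_BOX_TYPES = ("Brd", "GY", "K")

_BOX_LETTER = {"Brd": "B", "GY": "G", "K": "K"}
_LETTER_BOX = {v: k for k, v in _BOX_LETTER.items()}


def default_box_patterns() -> dict[str, DegeneratePattern]:
    return {
        name: compile_pattern(DEFAULT_MOTIFS[name], name) for name in UTR_BOX_TYPES
    }


@dataclass(frozen=True)
class UTRBoxProfile:
    """Ordered Brd/GY/K boxes found in one gene's 3' UTR window.

    ``boxes`` holds (box_type, offset-from-UTR-start) sorted by offset;
    ``source`` records whether the window came from a transcript or the
    stop-codon+1000 fallback; ``truncated`` flags windows shorter than
    requested (contig edge or short EST), where absence of downstream
    boxes is weak evidence.
    """

    gene_id: str
    species: str
    boxes: tuple[tuple[str, int], ...]
    window_length: int
    source: str = "stop+1000"
    truncated: bool = False

    @property
    def box_string(self) -> str:
        """Compact type string, e.g. 'BGK' for Brd,GY,K."""
        return "".join(_BOX_LETTER[b] for b, _ in self.boxes)


@dataclass(frozen=True)
class OrganizationComparison:
    profile_a: UTRBoxProfile
    profile_b: UTRBoxProfile
    matched_pairs: tuple[tuple[int, int], ...]  # index pairs into a/b box lists
    conservation_class: str  # identical | partial | none | identical-empty


def scan_utr(
    window_seq: str,
    gene_id: str = "",
    species: str = "",
    patterns: dict[str, DegeneratePattern] | None = None,
    source: str = "stop+1000",
    truncated: bool = False,
) -> UTRBoxProfile:
    """Scan a gene-oriented UTR window for the three boxes (sense only).

    Overlapping boxes of different types are all reported; the merged
    list is ordered by offset (ties by box type).
    """
    patterns = patterns or default_box_patterns()
    found: list[tuple[str, int]] = []
    for name, pat in patterns.items():
        for m in pat.regex.finditer(window_seq):
            found.append((name, m.start()))
    found.sort(key=lambda t: (t[1], t[0]))
    return UTRBoxProfile(
        gene_id=gene_id,
        species=species,
        boxes=tuple(found),
        window_length=len(window_seq),
        source=source,
        truncated=truncated,
    )


def _lcs_pairs(a: str, b: str) -> list[tuple[int, int]]:
    """Index pairs of one longest common subsequence (standard DP)."""
    n, m = len(a), len(b)
    L = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            L[i][j] = (
                1 + L[i + 1][j + 1]
                if a[i] == b[j]
                else max(L[i + 1][j], L[i][j + 1])
            )
    pairs: list[tuple[int, int]] = []
    i = j = 0
    while i < n and j < m:
        if a[i] == b[j]:
            pairs.append((i, j))
            i += 1
            j += 1
        elif L[i + 1][j] >= L[i][j + 1]:
            i += 1
        else:
            j += 1
    return pairs


def compare_organization(
    a: UTRBoxProfile, b: UTRBoxProfile
) -> OrganizationComparison:
    """Compare two orthologs' UTR box organization.

    The matching is a longest common subsequence over the box-type
    strings; the classification is symmetric in a and b.
    """
    sa, sb = a.box_string, b.box_string
    pairs = _lcs_pairs(sa, sb)
    if not sa and not sb:
        cls = "identical-empty"
    elif sa == sb:
        cls = "identical"
    elif not pairs:
        cls = "none"
    else:
        cls = "partial"
    return OrganizationComparison(
        profile_a=a, profile_b=b,
        matched_pairs=tuple(pairs),
        conservation_class=cls,
    )


_GLYPH = {"Brd": "[B]", "GY": "(G)", "K": "<K>"}


def organization_diagram(cmp: OrganizationComparison) -> str:
    """Plain-text two-line diagram of a compared ortholog pair.

    Conserved (LCS-matched) boxes are marked with '*', mirroring the
    shaded-shape convention of published UTR organization figures.
    """
    ia = {i for i, _ in cmp.matched_pairs}
    ib = {j for _, j in cmp.matched_pairs}

    def line(profile: UTRBoxProfile, matched: set) -> str:
        toks = [
            _GLYPH[t] + ("*" if k in matched else " ")
            for k, (t, _) in enumerate(profile.boxes)
        ]
        label = f"{profile.species or '?'}:{profile.gene_id or '?'}"
        body = " ".join(toks) if toks else "(no boxes)"
        trunc = "  [truncated window]" if profile.truncated else ""
        return f"{label:<24s} {body}{trunc}"

    return "\n".join(
        [
            line(cmp.profile_a, ia),
            line(cmp.profile_b, ib),
            f"{'class':<24s} {cmp.conservation_class}",
        ]
    )
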