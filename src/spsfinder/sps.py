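"""Paired Su(H) site (SPS) architecture: inverted-pair building, A-box
association and Y-position typing.

An SPS is an inverted pair of Su(H) sites; the canonical geometry has 17
intervening bases.  With a proneural A box in close proximity the module
is the SPS+A class.  The "Y" position is the first (C/T-degenerate) base
of the Su(H) consensus; canonically T in the gene-upstream site and C in
the gene-downstream site.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .iupac import MotifHit

CANONICAL_SPACER = 17


@dataclass(frozen=True)
class SPSPair:
    """An inverted (opposite-strand, non-overlapping) pair of Su(H) hits.

    ``spacer_bp`` counts the bases strictly between the two site
    intervals, so "separated by 17 bp" means 17 intervening bases.
    Orientation is ``convergent`` when the left site is on the plus
    strand (sites point toward each other), ``divergent`` otherwise.
    """

    site_left: MotifHit
    site_right: MotifHit
    spacer_bp: int
    orientation: str
    canonical: bool
    variant_label: str | None = None

    @property
    def start(self) -> int:
        return self.site_left.start

    @property
    def end(self) -> int:
        return self.site_right.end


@dataclass(frozen=True)
class SPSAModule:
    """An SPS pair plus any associated A boxes and Y-position typing.

    ``module_class`` is "SPS+A" iff at least one A box is attached.
    ``y_upstream``/``y_downstream`` are filled only once the module is
    oriented relative to its regulated gene (see
    :func:`assign_y_positions`); ``y_canonical`` is True for the T/C
    arrangement.
    """

    pair: SPSPair
    a_boxes: tuple[tuple[MotifHit, int], ...] = ()
    module_class: str = "SPS"
    y_upstream: str | None = None
    y_downstream: str | None = None
    y_canonical: bool | None = None

    @property
    def start(self) -> int:
        return self.pair.start

    @property
    def end(self) -> int:
        return self.pair.end


def find_inverted_pairs(
    hits: list[MotifHit],
    spacer_min: int = 0,
    spacer_max: int = 30,
) -> list[SPSPair]:
    """Build inverted Su(H) pairs from a hit list of one contig.

    Every opposite-strand, non-overlapping pair with ``spacer_min <=
    spacer <= spacer_max`` is a candidate.  When a site participates in
    several candidates, a greedy pass keeps the pair whose spacer is
    closest to the canonical 17 bp (ties broken toward the smaller
    spacer, then the leftmost pair) and discards alternatives sharing a
    site.  Output is sorted by left-site start.
    """
    if spacer_min < 0 or spacer_max < spacer_min:
        raise ValueError("require 0 <= spacer_min <= spacer_max")
    candidates: list[SPSPair] = []
    ordered = sorted(hits, key=lambda h: (h.start, h.strand))
    for i, left in enumerate(ordered):
        for right in ordered[i + 1:]:
            spacer = right.start - left.end
            if spacer > spacer_max:
                break
            if spacer < spacer_min or left.strand == right.strand:
                continue
            orientation = "convergent" if left.strand == "+" else "divergent"
            candidates.append(
                SPSPair(
                    site_left=left,
                    site_right=right,
                    spacer_bp=spacer,
                    orientation=orientation,
                    canonical=spacer == CANONICAL_SPACER,
                    variant_label=None if spacer == CANONICAL_SPACER else str(spacer),
                )
            )
    # Greedy dedup: one pair per site, closest-to-canonical spacer wins.
    candidates.sort(
        key=lambda p: (abs(p.spacer_bp - CANONICAL_SPACER), p.spacer_bp, p.start)
    )
    used: set[tuple[int, int, str]] = set()
    kept: list[SPSPair] = []
    for pair in candidates:
        keys = [
            (pair.site_left.start, pair.site_left.end, pair.site_left.strand),
            (pair.site_right.start, pair.site_right.end, pair.site_right.strand),
        ]
        if any(k in used for k in keys):
            continue
        used.update(keys)
        kept.append(pair)
    kept.sort(key=lambda p: p.start)
    return kept


def _gap_to_pair(hit: MotifHit, pair: SPSPair) -> int:
    """Bases between an A-box hit and the nearest edge of the pair span
    (0 when the box overlaps the span, e.g. sits in the spacer)."""
    if hit.end <= pair.start:
        return pair.start - hit.end
    if hit.start >= pair.end:
        return hit.start - pair.end
    return 0


def associate_aboxes(
    pair: SPSPair,
    abox_hits: list[MotifHit],
    max_dist: int = 500,
    region: tuple[int, int] | None = None,
) -> SPSAModule:
    """Attach nearby A boxes to a pair and classify SPS vs SPS+A.

    A boxes within ``max_dist`` bases of either pair edge and (when a
    ``region`` — the non-coding interval containing the pair — is given)
    fully inside that region are attached with their distances.  An
    empty attachment yields class "SPS".
    """
    if region is not None:
        lo, hi = region
        if not (lo <= pair.start and pair.end <= hi):
            raise ValueError(
                f"pair [{pair.start},{pair.end}) outside region [{lo},{hi})"
            )
    attached: list[tuple[MotifHit, int]] = []
    for hit in abox_hits:
        if region is not None and not (region[0] <= hit.start and hit.end <= region[1]):
            continue
        d = _gap_to_pair(hit, pair)
        if d <= max_dist:
            attached.append((hit, d))
    attached.sort(key=lambda t: (t[1], t[0].start))
    return SPSAModule(
        pair=pair,
        a_boxes=tuple(attached),
        module_class="SPS+A" if attached else "SPS",
    )


def assign_y_positions(module: SPSAModule, gene_strand: str | None) -> SPSAModule:
    """Fill Y-position characters once the regulated gene is known.

    The gene-upstream S site is the one 5'-most in the gene's reading
    orientation: the left site for a plus-strand gene, the right site
    for a minus-strand gene.  The Y character is the first base of each
    motif-oriented site sequence; canonical means T upstream / C
    downstream.  With no gene context the fields stay unassigned.
    """
    if gene_strand not in ("+", "-"):
        return module
    if gene_strand == "+":
        up, down = module.pair.site_left, module.pair.site_right
    else:
        up, down = module.pair.site_right, module.pair.site_left
    y_up = up.site_seq[0]
    y_down = down.site_seq[0]
    return replace(
        module,
        y_upstream=y_up,
        y_downstream=y_down,
        y_canonical=(y_up == "T" and y_down == "C"),
    )


def abox_distance_sensitivity(
    pairs: list[SPSPair],
    abox_hits: list[MotifHit],
    max_dists: list[int],
    regions: dict[int, tuple[int, int]] | None = None,
) -> list[tuple[int, int, int]]:
    """Report how the SPS+A vs bare-SPS split moves with the A-box
    proximity threshold.

    Returns ``(max_dist, n_sps_plus_a, n_sps)`` per threshold.  The
    SPS+A count is non-decreasing in ``max_dist``; useful for judging
    how robust a census split is to the proximity rule.
    """
    out = []
    for d in sorted(max_dists):
        n_a = 0
        for i, pair in enumerate(pairs):
            region = regions.get(i) if regions else None
            mod = associate_aboxes(pair, abox_hits, max_dist=d, region=region)
            if mod.module_class == "SPS+A":
                n_a += 1
        out.append((d, n_a, len(pairs) - n_a))
    return out
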