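"""Gene-model geometry: non-coding masking, module-to-gene assignment,
upstream distances and 3' UTR windows.

"Non-coding" here means non-CDS: introns and intergenic DNA are both
searchable.  All coordinates are 0-based half-open on the plus strand.
For a minus-strand gene, ``start_codon_pos`` is the genomic coordinate
of the first base of the start codon in gene orientation (its rightmost
base), and ``stop_codon_end`` is the coordinate just past the stop codon
in gene orientation (the leftmost genomic coordinate of the stop codon).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gffutils
from Bio import SeqIO


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    contig_id: str
    strand: str
    cds_intervals: tuple[tuple[int, int], ...]
    start_codon_pos: int
    stop_codon_end: int

    def __post_init__(self):
        ivs = sorted(self.cds_intervals)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: overlapping CDS intervals")
        for s, e in ivs:
            if s >= e:
                raise ValueError(f"{self.gene_id}: malformed interval [{s},{e})")
        object.__setattr__(self, "cds_intervals", tuple(ivs))

    @property
    def span(self) -> tuple[int, int]:
        return (self.cds_intervals[0][0], self.cds_intervals[-1][1])

    @classmethod
    def from_cds(cls, gene_id, contig_id, strand, cds_intervals) -> "GeneModel":
        """Build a model assuming the CDS includes start and stop codons."""
        ivs = sorted(tuple(map(tuple, cds_intervals)))
        if strand == "+":
            start_codon = ivs[0][0]
            stop_end = ivs[-1][1]
        else:
            start_codon = ivs[-1][1] - 1
            stop_end = ivs[0][0]
        return cls(gene_id, contig_id, strand, tuple(ivs), start_codon, stop_end)


@dataclass(frozen=True)
class RegionAssignment:
    """Placement of a module relative to its assigned gene.

    ``distance_bp`` counts the bases strictly between the module edge
    nearest the start codon and the first base of the start codon.
    ``candidates`` lists every gene the module is upstream of (nearest
    first) with signed context, so a module between two divergently
    transcribed genes reports both.
    """

    gene_id: str | None
    distance_bp: int | None
    side: str | None  # upstream | downstream | internal
    candidates: tuple[tuple[str, int], ...] = ()


def noncoding_regions(
    contig_length: int, genes: list[GeneModel]
) -> list[tuple[int, int]]:
    """Complement of the union of CDS intervals over [0, contig_length).

    Intronic and intergenic sequence are both retained; overlapping
    genes are allowed.
    """
    ivs = []
    for g in genes:
        for s, e in g.cds_intervals:
            if s < 0 or e > contig_length:
                raise ValueError(
                    f"{g.gene_id}: CDS [{s},{e}) outside contig of {contig_length} bp"
                )
            ivs.append((s, e))
    ivs.sort()
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    out = []
    prev = 0
    for s, e in merged:
        if s > prev:
            out.append((prev, s))
        prev = e
    if prev < contig_length:
        out.append((prev, contig_length))
    return out


def containing_region(
    regions: list[tuple[int, int]], start: int, end: int
) -> tuple[int, int] | None:
    """The region fully containing [start, end), if any."""
    for s, e in regions:
        if s <= start and end <= e:
            return (s, e)
    return None


def _upstream_distance(gene: GeneModel, mstart: int, mend: int) -> int | None:
    """Bases between the module and the start codon when the module is
    upstream of the gene in its reading orientation, else None."""
    if gene.strand == "+":
        if mend <= gene.start_codon_pos:
            return gene.start_codon_pos - mend
    else:
        if mstart >= gene.start_codon_pos + 1:
            return mstart - (gene.start_codon_pos + 1)
    return None


def assign_module_to_gene(
    module_start: int, module_end: int, genes: list[GeneModel]
) -> RegionAssignment:
    """Assign a module to the gene it is upstream of.

    The winner is the gene whose start codon is nearest downstream of
    the module in that gene's reading orientation; all upstream
    candidates are reported nearest-first.  A module overlapping a
    gene's CDS span (e.g. in an intron) is ``internal``; failing both,
    the nearest gene in genomic distance is reported as ``downstream``.
    """
    if not genes:
        return RegionAssignment(None, None, None)
    upstream: list[tuple[str, int]] = []
    for g in genes:
        d = _upstream_distance(g, module_start, module_end)
        if d is not None:
            upstream.append((g.gene_id, d))
    upstream.sort(key=lambda t: t[1])
    if upstream:
        return RegionAssignment(
            gene_id=upstream[0][0],
            distance_bp=upstream[0][1],
            side="upstream",
            candidates=tuple(upstream),
        )
    for g in genes:
        s, e = g.span
        if module_start < e and s < module_end:
            d = (
                abs(g.start_codon_pos - module_end)
                if g.strand == "+"
                else abs(module_start - g.start_codon_pos - 1)
            )
            return RegionAssignment(g.gene_id, d, "internal", ((g.gene_id, d),))
    # Downstream of everything: nearest gene by genomic gap.
    def gap(g: GeneModel) -> int:
        s, e = g.span
        return max(s - module_end, module_start - e, 0)

    g = min(genes, key=gap)
    return RegionAssignment(g.gene_id, gap(g), "downstream", ((g.gene_id, gap(g)),))


def utr_window(
    gene: GeneModel,
    contig_length: int,
    window_bp: int = 1000,
    transcript_interval: tuple[int, int] | None = None,
) -> tuple[int, int]:
    """Genomic interval of the 3' UTR search window.

    When a transcript defines the UTR, that interval is returned
    verbatim; otherwise the ``window_bp`` bases immediately 3' of the
    stop codon in gene orientation, truncated at contig ends.
    """
    if transcript_interval is not None:
        return transcript_interval
    if gene.strand == "+":
        return (gene.stop_codon_end, min(contig_length, gene.stop_codon_end + window_bp))
    return (max(0, gene.stop_codon_end - window_bp), gene.stop_codon_end)


def utr_window_seq(gene: GeneModel, contig_seq: str, window_bp: int = 1000) -> str:
    """The UTR window sequence in gene (sense) orientation."""
    from .iupac import reverse_complement

    s, e = utr_window(gene, len(contig_seq), window_bp)
    seq = contig_seq[s:e]
    return seq if gene.strand == "+" else reverse_complement(seq)


# ---------------------------------------------------------------------------
# Annotation readers


def load_genes_gff3(path: str | Path, contig_id: str | None = None) -> list[GeneModel]:
    """Read gene models (CDS geometry) from a GFF3 file via gffutils.

    CDS features are grouped by Parent (falling back to ID/gene_id).
    The CDS is assumed to include start and stop codons.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True,
        merge_strategy="create_unique", keep_order=True,
    )
    grouped: dict[tuple[str, str], dict] = {}
    for cds in db.features_of_type("CDS"):
        if contig_id is not None and cds.seqid != contig_id:
            continue
        parent = (
            cds.attributes.get("Parent")
            or cds.attributes.get("gene_id")
            or cds.attributes.get("ID")
            or [f"gene_at_{cds.start}"]
        )[0]
        key = (cds.seqid, parent)
        entry = grouped.setdefault(key, {"strand": cds.strand, "ivs": []})
        entry["ivs"].append((cds.start - 1, cds.end))  # GFF3 is 1-based inclusive
    genes = [
        GeneModel.from_cds(parent, seqid, entry["strand"], entry["ivs"])
        for (seqid, parent), entry in grouped.items()
    ]
    genes.sort(key=lambda g: g.span)
    return genes


def load_genes_genbank(path: str | Path) -> tuple[list, list[GeneModel]]:
    """Read contigs and embedded CDS features from a GenBank flat file.

    Returns (SeqRecords, GeneModels).  Compound (joined) CDS locations
    become multi-interval models.
    """
    records = list(SeqIO.parse(str(path), "genbank"))
    if not records:
        raise ValueError(f"no records in {path}")
    genes: list[GeneModel] = []
    for rec in records:
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            name = (
                feat.qualifiers.get("gene")
                or feat.qualifiers.get("locus_tag")
                or [f"cds_at_{int(feat.location.start)}"]
            )[0]
            ivs = [(int(p.start), int(p.end)) for p in feat.location.parts]
            strand = "+" if feat.location.strand != -1 else "-"
            genes.append(GeneModel.from_cds(name, rec.id, strand, ivs))
    genes.sort(key=lambda g: g.span)
    return records, genes


def write_genes_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (1-based inclusive)."""
    lines = ["##gff-version 3"]
    for g in genes:
        s, e = g.span
        lines.append(
            f"{g.contig_id}\tspsfinder\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
            f"ID={g.gene_id}"
        )
        for i, (cs, ce) in enumerate(g.cds_intervals):
            lines.append(
                f"{g.contig_id}\tspsfinder\tCDS\t{cs + 1}\t{ce}\t.\t{g.strand}\t0\t"
                f"ID={g.gene_id}.cds{i};Parent={g.gene_id}"
            )
    Path(path).write_text("\n".join(lines) + "\n")
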