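"""Synthetic annotated contigs with planted regulatory architectures.

The generator emulates a multi-gene fly contig: CDS on both strands over
i.i.d. background of configurable GC, paired Su(H) modules planted at
controlled spacers/orientations/Y characters and upstream distances,
A boxes at controlled offsets, and Brd/GY/K box strings in the 3' UTRs.
Ground truth (exact coordinates, strands and classifications of every
planted element) is recorded so recall and false-positive rates of the
whole pipeline are measurable.

In clean-background mode a rejection pass redraws background windows
that accidentally create unplanted motif matches, so any module the
scanner reports beyond the truth is a genuine false positive of the
method, not of the simulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .iupac import (
    DEFAULT_MOTIFS,
    compile_pattern,
    reverse_complement,
    scan_both_strands,
)
from .genes import GeneModel

_SITE_LEN = len(DEFAULT_MOTIFS["SuH"])
_ABOX_LEN = len(DEFAULT_MOTIFS["Abox"])
_BOX_MOTIF = {"Brd": "AGCTTTA", "GY": "GTCTTCC", "K": "TGTGAT"}

# Literal sequences planted for each element class.  The Su(H) site is
# planted with R=A; the A box with R=A, S=C.  Only the Y position varies
# (per module plan), matching the degenerate consensus either way.
_SUH_TAIL = "GTGAGAA"
_ABOX_LITERAL = "ACAGCTG"


@dataclass(frozen=True)
class GenePlan:
    gene_id: str
    strand: str
    cds: tuple[tuple[int, int], ...]
    utr_boxes: tuple[tuple[str, int], ...] = ()  # (type, offset from UTR start)


@dataclass(frozen=True)
class ModulePlan:
    """One planted SPS / SPS+A module.

    ``upstream_distance`` is the gap between the module edge nearest
    the target gene's start codon and the first base of that codon.
    ``aboxes`` holds signed gaps: negative = left of the pair span,
    positive/zero = right of it, |value| intervening bases.
    """

    name: str
    gene: str
    upstream_distance: int
    spacer: int
    orientation: str = "convergent"
    y_upstream: str = "T"
    y_downstream: str = "C"
    aboxes: tuple[int, ...] = ()

    @property
    def length(self) -> int:
        return 2 * _SITE_LEN + self.spacer


@dataclass(frozen=True)
class PlantSpec:
    contig_id: str
    length: int
    genes: tuple[GenePlan, ...]
    modules: tuple[ModulePlan, ...]
    gc: float = 0.40
    species: str = ""
    clean_background: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "PlantSpec":
        genes = tuple(
            GenePlan(
                gene_id=g["gene_id"],
                strand=g["strand"],
                cds=tuple((int(s), int(e)) for s, e in g["cds"]),
                utr_boxes=tuple((t, int(o)) for t, o in g.get("utr_boxes", [])),
            )
            for g in d["genes"]
        )
        modules = tuple(
            ModulePlan(
                name=m["name"],
                gene=m["gene"],
                upstream_distance=int(m["upstream_distance"]),
                spacer=int(m["spacer"]),
                orientation=m.get("orientation", "convergent"),
                y_upstream=m.get("y_upstream", "T"),
                y_downstream=m.get("y_downstream", "C"),
                aboxes=tuple(int(a) for a in m.get("aboxes", [])),
            )
            for m in d["modules"]
        )
        return cls(
            contig_id=d["contig_id"],
            length=int(d["length"]),
            genes=genes,
            modules=modules,
            gc=float(d.get("gc", 0.40)),
            species=d.get("species", ""),
            clean_background=bool(d.get("clean_background", True)),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class PlantedTruth:
    """Ground-truth record serialized alongside generated contigs."""

    contig_id: str
    length: int
    seed: int
    sites: list[dict] = field(default_factory=list)
    pairs: list[dict] = field(default_factory=list)
    aboxes: list[dict] = field(default_factory=list)
    utr_boxes: list[dict] = field(default_factory=list)
    genes: list[dict] = field(default_factory=list)
    protected: bool = True

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        return cls(**json.loads(Path(path).read_text()))

    def pair_keys(self) -> set[tuple[int, int, int, str]]:
        """(start, end, spacer, class) of every planted pair."""
        return {
            (p["start"], p["end"], p["spacer"], p["module_class"])
            for p in self.pairs
        }


class PackingError(ValueError):
    """Raised when a PlantSpec cannot be placed on its contig."""


def _gene_start_codon(plan: GenePlan) -> int:
    ivs = sorted(plan.cds)
    return ivs[0][0] if plan.strand == "+" else ivs[-1][1] - 1


def _gene_utr_origin(plan: GenePlan) -> int:
    ivs = sorted(plan.cds)
    return ivs[-1][1] if plan.strand == "+" else ivs[0][0]


def _module_interval(plan: ModulePlan, gene: GenePlan) -> tuple[int, int]:
    s_codon = _gene_start_codon(gene)
    if gene.strand == "+":
        end = s_codon - plan.upstream_distance
        return end - plan.length, end
    start = s_codon + 1 + plan.upstream_distance
    return start, start + plan.length


def _abox_interval(offset: int, mstart: int, mend: int) -> tuple[int, int]:
    if offset < 0:
        end = mstart + offset  # offset is the negated gap
        return end - _ABOX_LEN, end
    return mend + offset, mend + offset + _ABOX_LEN


def _plant(seq: list, start: int, text: str, footprints: list) -> None:
    if start < 0 or start + len(text) > len(seq):
        raise PackingError(f"element [{start},{start + len(text)}) out of bounds")
    for (s, e) in footprints:
        if start < e and s < start + len(text):
            raise PackingError(
                f"element [{start},{start + len(text)}) overlaps planted [{s},{e})"
            )
    seq[start:start + len(text)] = list(text)
    footprints.append((start, start + len(text)))


def _background(rng: np.random.Generator, n: int, gc: float) -> list:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return list(rng.choice(np.array(list("ACGT")), size=n, p=p))


def generate_contig(
    spec: PlantSpec, seed: int, max_clean_iter: int = 500
) -> tuple[SeqRecord, list[GeneModel], PlantedTruth]:
    """Generate one contig from a PlantSpec; deterministic given seed.

    Returns the sequence record, the gene models, and the ground truth.
    With ``spec.clean_background`` a rejection pass re-draws background
    bases inside any unplanted Su(H)/A-box/UTR-box match until none
    remain (planted bases are never touched).
    """
    rng = np.random.default_rng(seed)
    seq = _background(rng, spec.length, spec.gc)
    footprints: list[tuple[int, int]] = []
    truth = PlantedTruth(contig_id=spec.contig_id, length=spec.length, seed=seed)
    # (pattern_name, start, strand) triples the clean pass must keep.
    whitelist: set[tuple[str, int, str]] = set()
    gene_by_id = {g.gene_id: g for g in spec.genes}

    gene_models: list[GeneModel] = []
    for g in spec.genes:
        model = GeneModel.from_cds(g.gene_id, spec.contig_id, g.strand, g.cds)
        gene_models.append(model)
        # Start and stop codons are planted so annotation geometry is real.
        if g.strand == "+":
            _plant(seq, model.start_codon_pos, "ATG", footprints)
            _plant(seq, model.stop_codon_end - 3, "TAA", footprints)
        else:
            _plant(seq, model.start_codon_pos - 2, "CAT", footprints)
            _plant(seq, model.stop_codon_end, "TTA", footprints)
        truth.genes.append(
            dict(
                gene_id=g.gene_id, strand=g.strand,
                cds=[list(iv) for iv in sorted(g.cds)],
                start_codon_pos=model.start_codon_pos,
                stop_codon_end=model.stop_codon_end,
            )
        )
        utr0 = _gene_utr_origin(g)
        for box_type, offset in g.utr_boxes:
            motif = _BOX_MOTIF[box_type]
            if g.strand == "+":
                bstart = utr0 + offset
                text = motif
            else:
                bstart = utr0 - offset - len(motif)
                text = reverse_complement(motif)
            _plant(seq, bstart, text, footprints)
            whitelist.add((box_type, bstart, g.strand))
            truth.utr_boxes.append(
                dict(
                    gene_id=g.gene_id, box_type=box_type, offset=offset,
                    start=bstart, end=bstart + len(motif), strand=g.strand,
                )
            )

    cds_ivs = sorted(iv for g in spec.genes for iv in g.cds)

    def _check_noncoding(s: int, e: int, what: str) -> None:
        for cs, ce in cds_ivs:
            if s < ce and cs < e:
                raise PackingError(
                    f"{what} [{s},{e}) overlaps CDS [{cs},{ce}); regulatory "
                    "elements must be planted in non-coding DNA"
                )

    for plan in spec.modules:
        gene = gene_by_id[plan.gene]
        mstart, mend = _module_interval(plan, gene)
        _check_noncoding(mstart, mend, f"module {plan.name}")
        for offset in plan.aboxes:
            _check_noncoding(*_abox_interval(offset, mstart, mend),
                             f"A box of {plan.name}")
        up_seq = plan.y_upstream + _SUH_TAIL
        down_seq = plan.y_downstream + _SUH_TAIL
        if gene.strand == "+":
            left_site, right_site = up_seq, down_seq
        else:
            left_site, right_site = down_seq, up_seq
        if plan.orientation == "convergent":
            left_strand, right_strand = "+", "-"
        else:
            left_strand, right_strand = "-", "+"
        left_text = left_site if left_strand == "+" else reverse_complement(left_site)
        right_text = (
            right_site if right_strand == "+" else reverse_complement(right_site)
        )
        _plant(seq, mstart, left_text, footprints)
        _plant(seq, mend - _SITE_LEN, right_text, footprints)
        whitelist.add(("SuH", mstart, left_strand))
        whitelist.add(("SuH", mend - _SITE_LEN, right_strand))
        site_ids = []
        for sid, (s0, strand, site) in enumerate(
            [(mstart, left_strand, left_site), (mend - _SITE_LEN, right_strand, right_site)]
        ):
            site_id = f"{plan.name}.S{sid}"
            site_ids.append(site_id)
            truth.sites.append(
                dict(
                    id=site_id, pattern="SuH", start=s0, end=s0 + _SITE_LEN,
                    strand=strand, site_seq=site, module=plan.name,
                )
            )
        abox_records = []
        for offset in plan.aboxes:
            astart, aend = _abox_interval(offset, mstart, mend)
            _plant(seq, astart, _ABOX_LITERAL, footprints)
            whitelist.add(("Abox", astart, "+"))
            rec = dict(
                start=astart, end=aend, strand="+",
                distance=abs(offset), module=plan.name,
            )
            abox_records.append(rec)
            truth.aboxes.append(rec)
        truth.pairs.append(
            dict(
                module=plan.name, gene=plan.gene,
                left_site=site_ids[0], right_site=site_ids[1],
                start=mstart, end=mend, spacer=plan.spacer,
                orientation=plan.orientation,
                module_class="SPS+A" if plan.aboxes else "SPS",
                y_upstream=plan.y_upstream, y_downstream=plan.y_downstream,
                y_canonical=(plan.y_upstream == "T" and plan.y_downstream == "C"),
                upstream_distance=plan.upstream_distance,
                aboxes=abox_records,
            )
        )

    if spec.clean_background:
        _reject_spurious(seq, whitelist, footprints, rng, spec.gc, max_clean_iter)

    record = SeqRecord(Seq("".join(seq)), id=spec.contig_id, description="")
    return record, gene_models, truth


def _reject_spurious(
    seq: list,
    whitelist: set,
    footprints: list,
    rng: np.random.Generator,
    gc: float,
    max_iter: int,
) -> None:
    patterns = [compile_pattern(iu, name) for name, iu in DEFAULT_MOTIFS.items()]
    protected = np.zeros(len(seq), dtype=bool)
    for s, e in footprints:
        protected[s:e] = True
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.array(list("ACGT"))
    for _ in range(max_iter):
        text = "".join(seq)
        bad: set[int] = set()
        for pat in patterns:
            for hit in scan_both_strands(text, pat):
                if (pat.name, hit.start, hit.strand) in whitelist:
                    continue
                mutable = [
                    i for i in range(hit.start, hit.end) if not protected[i]
                ]
                if not mutable:
                    raise PackingError(
                        f"spurious {pat.name} match at {hit.start} lies entirely "
                        "inside planted elements; spec infeasible in clean mode"
                    )
                bad.update(mutable)
        if not bad:
            return
        for i in sorted(bad):
            seq[i] = str(rng.choice(bases, p=p))
    raise PackingError("clean-background rejection did not converge")


# ---------------------------------------------------------------------------
# Targeted degradation of planted sites


def degrade_site(
    seq: str, truth: PlantedTruth, site_id: str, edit: tuple
) -> tuple[str, PlantedTruth]:
    """Apply an edit to one planted Su(H) site and update the truth.

    ``edit`` is ``("delete", offset)`` or ``("substitute", offset, base)``
    with offset/base in motif orientation.  A deletion must leave the
    site no longer matching the consensus (otherwise rejected); a
    substitution that still matches just rewrites the recorded site
    (and the pair's Y character when offset is 0).  A no-op edit is
    rejected.  Deletion shifts all downstream truth coordinates by -1.
    """
    site = next((s for s in truth.sites if s["id"] == site_id), None)
    if site is None:
        raise ValueError(f"unknown site {site_id!r}")
    pat = compile_pattern(DEFAULT_MOTIFS["SuH"], "SuH")
    start, end, strand = site["start"], site["end"], site["strand"]
    kind = edit[0]
    offset = edit[1]
    if not (0 <= offset < end - start):
        raise ValueError("offset outside site")
    pos = start + offset if strand == "+" else end - 1 - offset

    new_truth = PlantedTruth(**json.loads(truth.to_json()))
    if kind == "substitute":
        base = edit[2].upper()
        planted = base if strand == "+" else reverse_complement(base)
        if seq[pos] == planted:
            raise ValueError("no-op edit: base already present")
        new_seq = seq[:pos] + planted + seq[pos + 1:]
        window = new_seq[start:end]
        new_site = window if strand == "+" else reverse_complement(window)
        if pat.matches(new_site):
            for s in new_truth.sites:
                if s["id"] == site_id:
                    s["site_seq"] = new_site
            for p in new_truth.pairs:
                if site_id in (p["left_site"], p["right_site"]) and offset == 0:
                    which = "y_upstream" if _is_upstream_site(p, site_id, new_truth) else "y_downstream"
                    p[which] = base
                    p["y_canonical"] = (
                        p["y_upstream"] == "T" and p["y_downstream"] == "C"
                    )
        else:
            _drop_site(new_truth, site_id)
        return new_seq, new_truth

    if kind == "delete":
        new_seq = seq[:pos] + seq[pos + 1:]
        window = new_seq[start:start + (end - start)]
        oriented = window if strand == "+" else reverse_complement(window)
        if len(oriented) == end - start and pat.matches(oriented):
            raise ValueError("edit leaves the site still matching the consensus")
        _drop_site(new_truth, site_id)
        _shift_coords(new_truth, pos)
        new_truth.length -= 1
        return new_seq, new_truth

    raise ValueError(f"unknown edit kind {kind!r}")


def _is_upstream_site(pair: dict, site_id: str, truth: PlantedTruth) -> bool:
    gene = next(g for g in truth.genes if g["gene_id"] == pair["gene"])
    left_is_up = gene["strand"] == "+"
    return (pair["left_site"] == site_id) == left_is_up


def _drop_site(truth: PlantedTruth, site_id: str) -> None:
    truth.sites = [s for s in truth.sites if s["id"] != site_id]
    gone = [
        p for p in truth.pairs if site_id in (p["left_site"], p["right_site"])
    ]
    for p in gone:
        truth.aboxes = [a for a in truth.aboxes if a["module"] != p["module"]]
    truth.pairs = [p for p in truth.pairs if p not in gone]


def _shift_coords(truth: PlantedTruth, deleted_pos: int) -> None:
    def sh(x: int) -> int:
        return x - 1 if x > deleted_pos else x

    for s in truth.sites:
        s["start"], s["end"] = sh(s["start"]), sh(s["end"])
    for p in truth.pairs:
        p["start"], p["end"] = sh(p["start"]), sh(p["end"])
        for a in p["aboxes"]:
            a["start"], a["end"] = sh(a["start"]), sh(a["end"])
    for a in truth.aboxes:
        a["start"], a["end"] = sh(a["start"]), sh(a["end"])
    for b in truth.utr_boxes:
        b["start"], b["end"] = sh(b["start"]), sh(b["end"])
    for g in truth.genes:
        g["cds"] = [[sh(s), sh(e)] for s, e in g["cds"]]
        g["start_codon_pos"] = sh(g["start_codon_pos"])
        g["stop_codon_end"] = sh(g["stop_codon_end"])


# ---------------------------------------------------------------------------
# Ortholog-pair simulation


def generate_ortholog_pair(
    spec: PlantSpec,
    divergence: float,
    seed: int,
    indel_rate: float = 0.0,
    indel_mean_len: float = 3.0,
    protect_planted: bool = True,
):
    """Derive a diverged ortholog contig from a generated one.

    Contig b is produced from contig a by i.i.d. substitutions at
    per-base probability ``divergence`` and (optionally) geometric-length
    indels at per-base rate ``indel_rate``; with ``protect_planted``
    every planted footprint is left untouched, so planted modules and
    boxes are expected to be fully conserved.  Returns
    ``(rec_a, genes_a, truth_a, rec_b, genes_b, truth_b)``.
    """
    if not (0 <= divergence < 1):
        raise ValueError("divergence must be in [0, 1)")
    rec_a, genes_a, truth_a = generate_contig(spec, seed)
    rng = np.random.default_rng(seed + 1_000_003)
    a = str(rec_a.seq)
    protected = np.zeros(len(a), dtype=bool)
    if protect_planted:
        # whole pair spans (sites + spacer) are protected so planted
        # geometry, including spacer length, is conserved in b
        for coll in (truth_a.pairs, truth_a.aboxes, truth_a.utr_boxes):
            for item in coll:
                protected[item["start"]:item["end"]] = True
        for g in truth_a.genes:
            # keep codons intact so gene geometry survives
            if g["strand"] == "+":
                protected[g["start_codon_pos"]:g["start_codon_pos"] + 3] = True
                protected[g["stop_codon_end"] - 3:g["stop_codon_end"]] = True
            else:
                protected[g["start_codon_pos"] - 2:g["start_codon_pos"] + 1] = True
                protected[g["stop_codon_end"]:g["stop_codon_end"] + 3] = True

    others = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}
    out: list[str] = []
    newpos = np.full(len(a), -1, dtype=np.int64)
    gc = spec.gc
    p_bg = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.array(list("ACGT"))
    i = 0
    while i < len(a):
        if not protected[i] and indel_rate > 0 and rng.random() < indel_rate:
            ln = 1 + rng.geometric(1.0 / indel_mean_len)
            if rng.random() < 0.5:  # deletion of background run
                j = i
                while j < len(a) and j - i < ln and not protected[j]:
                    j += 1
                i = j
                continue
            out.extend(rng.choice(bases, size=ln, p=p_bg))  # insertion
        ch = a[i]
        if not protected[i] and rng.random() < divergence:
            ch = others[ch][rng.integers(3)]
        newpos[i] = len(out)
        out.append(ch)
        i += 1

    b = "".join(out)

    def map_start(x: int) -> int:
        j = x
        while j < len(a) and newpos[j] < 0:
            j += 1
        return int(newpos[j]) if j < len(a) else len(b)

    def map_end(x: int) -> int:
        j = x - 1
        while j >= 0 and newpos[j] < 0:
            j -= 1
        return int(newpos[j]) + 1 if j >= 0 else 0

    truth_b = PlantedTruth(**json.loads(truth_a.to_json()))
    truth_b.length = len(b)
    truth_b.protected = protect_planted
    for s in truth_b.sites:
        s["start"], s["end"] = map_start(s["start"]), map_end(s["end"])
    site_by_id = {s["id"]: s for s in truth_b.sites}
    for p in truth_b.pairs:
        left, right = site_by_id[p["left_site"]], site_by_id[p["right_site"]]
        p["start"], p["end"] = left["start"], right["end"]
        p["spacer"] = right["start"] - left["end"]
        for ab in p["aboxes"]:
            ab["start"], ab["end"] = map_start(ab["start"]), map_end(ab["end"])
    for ab in truth_b.aboxes:
        ab["start"], ab["end"] = map_start(ab["start"]), map_end(ab["end"])
    for bx in truth_b.utr_boxes:
        bx["start"], bx["end"] = map_start(bx["start"]), map_end(bx["end"])
    genes_b = []
    for g in truth_b.genes:
        g["cds"] = [[map_start(s), map_end(e)] for s, e in g["cds"]]
        model = GeneModel.from_cds(
            g["gene_id"], spec.contig_id + "_b", g["strand"], g["cds"]
        )
        g["start_codon_pos"] = model.start_codon_pos
        g["stop_codon_end"] = model.stop_codon_end
        genes_b.append(model)
    rec_b = SeqRecord(Seq(b), id=spec.contig_id + "_b", description="")
    return rec_a, genes_a, truth_a, rec_b, genes_b, truth_b


# ---------------------------------------------------------------------------
# Random specs for property testing and the shipped census fixtures


def random_plant_spec(
    rng: np.random.Generator,
    n_genes: int | None = None,
    contig_id: str = "synth",
    gc: float = 0.40,
) -> PlantSpec:
    """A random valid PlantSpec on a slotted layout.

    Each gene occupies a 2.4 kb slot: a 600 bp CDS with its module
    planted 40-250 bp upstream (0-2 A boxes within 150 bp) and 0-4 UTR
    boxes within 250 bp of the stop codon.  Strands, spacers (0-30),
    orientations and Y characters are drawn at random.
    """
    if n_genes is None:
        n_genes = int(rng.integers(1, 4))
    slot = 2400
    length = n_genes * slot + 1200
    genes, modules = [], []
    for k in range(n_genes):
        base = 600 + k * slot
        strand = "+" if rng.random() < 0.7 else "-"
        cds = ((base + 900, base + 1500),)
        n_boxes = int(rng.integers(0, 5))
        offs = sorted(rng.choice(np.arange(10, 250, 12), size=n_boxes, replace=False))
        box_types = [str(rng.choice(["Brd", "GY", "K"])) for _ in range(n_boxes)]
        gene = GenePlan(
            gene_id=f"g{k}", strand=strand, cds=cds,
            utr_boxes=tuple(zip(box_types, (int(o) for o in offs))),
        )
        genes.append(gene)
        if rng.random() < 0.9:  # most genes get a module
            spacer = int(rng.integers(0, 31))
            dist = int(rng.integers(40, 250))
            n_a = int(rng.integers(0, 3))
            # the gene-facing side is bounded by the upstream gap so the
            # A box stays in non-coding DNA; +1 faces the gene for '+'
            toward = 1 if strand == "+" else -1
            sides = [-toward, toward]
            rng.shuffle(sides)
            aboxes = []
            for j in range(n_a):
                side = sides[j]
                hi = min(150, dist - 9) if side == toward else 150
                aboxes.append(int(side * rng.integers(4, hi)))
            modules.append(
                ModulePlan(
                    name=f"mod{k}", gene=gene.gene_id,
                    upstream_distance=dist,
                    spacer=spacer,
                    orientation=str(rng.choice(["convergent", "divergent"])),
                    y_upstream=str(rng.choice(["T", "C"])),
                    y_downstream=str(rng.choice(["T", "C"])),
                    aboxes=tuple(aboxes),
                )
            )
    return PlantSpec(
        contig_id=contig_id, length=length,
        genes=tuple(genes), modules=tuple(modules), gc=gc,
    )


def census_specs() -> tuple[PlantSpec, PlantSpec]:
    """The shipped synthetic census pair.

    Two PlantSpecs encoding the regulatory architecture of the 11-gene
    Enhancer-of-split complex as reported for the stalk-eyed fly and for
    D. melanogaster: 7 SPS+A modules and 4 bare SPS pairs (one with the
    15 bp spacer variant) on the first contig, and UTR box strings such
    that 6 of 11 ortholog pairs have identical organization (one of them
    the empty-empty case).  Both are synthetic stand-ins built from the
    published census structure, not real genomic sequence.
    """
    data = Path(__file__).parent / "data"
    return (
        PlantSpec.from_json(data / "synthetic_census_teleopsis.json"),
        PlantSpec.from_json(data / "synthetic_census_drosophila.json"),
    )


def evaluate_recovery(truth: PlantedTruth, modules) -> dict:
    """Recall / false-positive tally of pipeline output against truth.

    A planted pair is recovered when some reported module matches its
    (start, end, spacer) exactly and carries the planted class.
    """
    found = {
        (m.pair.start, m.pair.end, m.pair.spacer_bp, m.module_class)
        for m in modules
    }
    planted = truth.pair_keys()
    return {
        "n_planted": len(planted),
        "n_found": len(found),
        "n_recovered": len(planted & found),
        "recall": len(planted & found) / len(planted) if planted else 1.0,
        "n_false": len(found - planted),
    }
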