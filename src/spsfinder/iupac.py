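"""Degenerate (IUPAC) DNA pattern compilation and both-strand scanning.

The scanner is exhaustive: every offset on both strands is reported,
including overlapping and nested matches.  Coordinates are 0-based
half-open on the plus strand throughout the library; user-facing writers
convert to 1-based inclusive (GFF3 convention).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

# IUPAC nucleotide codes -> set of literal bases.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)

#: The five motifs used throughout: the Su(H) transcription-factor binding
#: consensus, the proneural bHLH activator box, and the three 3' UTR
#: miRNA-targeted boxes.
DEFAULT_MOTIFS: dict[str, str] = {
    "SuH": "YGTGRGAA",
    "Abox": "RCAGSTG",
    "Brd": "AGCTTTA",
    "GY": "GTCTTCC",
    "K": "TGTGAT",
}


def reverse_complement(seq: str) -> str:
    """Reverse-complement a DNA string, degenerate codes included.

    An involution: ``reverse_complement(reverse_complement(x)) == x``.
    Raises :class:`ValueError` on any non-IUPAC character.
    """
    for i, ch in enumerate(seq):
        if ch.upper() not in IUPAC_CODES:
            raise ValueError(f"invalid IUPAC character {ch!r} at position {i}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DegeneratePattern:
    """A compiled degenerate DNA motif.

    ``degeneracy`` is the number of literal expansions (product of
    per-position code sizes); ``regex``/``regex_rc`` match the motif on
    the plus strand in forward and reverse-complement orientation, each
    wrapped in a capturing lookahead so overlapping matches are found.
    """

    name: str
    iupac: str
    regex: re.Pattern = field(repr=False, compare=False)
    regex_rc: re.Pattern = field(repr=False, compare=False)

    @property
    def length(self) -> int:
        return len(self.iupac)

    @property
    def degeneracy(self) -> int:
        n = 1
        for ch in self.iupac:
            n *= len(IUPAC_CODES[ch])
        return n

    def expansions(self) -> list[str]:
        """All literal ACGT strings the motif accepts (lexicographic)."""
        return [
            "".join(p)
            for p in itertools.product(*(IUPAC_CODES[c] for c in self.iupac))
        ]

    def matches(self, site: str) -> bool:
        """Whether ``site`` (motif-oriented) matches the motif literally."""
        if len(site) != self.length:
            return False
        return all(
            b.upper() in IUPAC_CODES[c] for b, c in zip(site, self.iupac)
        )


def _char_class(code: str) -> str:
    bases = IUPAC_CODES[code]
    return "[" + bases + bases.lower() + "]"


def compile_pattern(iupac: str, name: str = "") -> DegeneratePattern:
    """Compile an IUPAC string into a :class:`DegeneratePattern`.

    Case-insensitive on the scanned sequence; ambiguity codes in the
    *sequence* (e.g. N runs in background) never match, because each
    pattern position compiles to the explicit base class of its code.
    """
    if not iupac:
        raise ValueError("empty pattern")
    for i, ch in enumerate(iupac):
        if ch.upper() not in IUPAC_CODES:
            raise ValueError(
                f"invalid IUPAC character {ch!r} at position {i} of {iupac!r}"
            )
    iupac = iupac.upper()
    fwd = "(?=(" + "".join(_char_class(c) for c in iupac) + "))"
    rc = reverse_complement(iupac)
    rev = "(?=(" + "".join(_char_class(c) for c in rc) + "))"
    return DegeneratePattern(
        name=name or iupac,
        iupac=iupac,
        regex=re.compile(fwd),
        regex_rc=re.compile(rev),
    )


@dataclass(frozen=True)
class MotifHit:
    """One strand-aware match of a pattern on a contig.

    ``matched_seq`` is the plus-strand slice ``contig[start:end]``;
    ``site_seq`` is the motif-oriented sequence (its reverse complement
    when ``strand == '-'``).
    """

    pattern_name: str
    contig_id: str
    start: int
    end: int
    strand: str
    matched_seq: str
    site_seq: str

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def overlaps(self, other: "MotifHit") -> bool:
        return self.start < other.end and other.start < self.end


def scan_both_strands(
    seq: str,
    pattern: DegeneratePattern,
    contig_id: str = "",
    exclude_softmasked: bool = False,
) -> list[MotifHit]:
    """Exhaustively scan both strands of ``seq`` for ``pattern``.

    Every offset is tested; overlapping and nested matches are all
    reported, and a position matching on both strands yields two hits.
    Hits are sorted by start, plus strand first at ties.  With
    ``exclude_softmasked`` any hit containing a lowercase base is dropped.
    """
    hits: list[MotifHit] = []
    n = pattern.length
    for strand, rx in (("+", pattern.regex), ("-", pattern.regex_rc)):
        for m in rx.finditer(seq):
            start = m.start()
            slice_ = m.group(1)
            if exclude_softmasked and not slice_.isupper():
                continue
            site = slice_.upper()
            if strand == "-":
                site = reverse_complement(site)
            hits.append(
                MotifHit(
                    pattern_name=pattern.name,
                    contig_id=contig_id,
                    start=start,
                    end=start + n,
                    strand=strand,
                    matched_seq=slice_.upper(),
                    site_seq=site,
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_record(
    record,
    pattern: DegeneratePattern,
    exclude_softmasked: bool = False,
) -> list[MotifHit]:
    """Scan a Bio.SeqRecord (or any object with .id and .seq)."""
    return scan_both_strands(
        str(record.seq), pattern, contig_id=record.id,
        exclude_softmasked=exclude_softmasked,
    )


def read_fasta(path: str | Path) -> list:
    """Read all records of a FASTA file; error on an empty file."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return records


def load_motif_config(path: str | Path | None = None) -> dict[str, DegeneratePattern]:
    """Load a motif set from a two-column text file (name, IUPAC string).

    Lines starting with '#' and blank lines are ignored.  Without a path
    the shipped default set (Su(H), A box, Brd, GY, K) is returned.
    """
    if path is None:
        raw: Iterable[tuple[str, str]] = DEFAULT_MOTIFS.items()
    else:
        raw = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'name IUPAC'")
            raw.append((parts[0], parts[1]))
    return {name: compile_pattern(iupac, name) for name, iupac in raw}
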