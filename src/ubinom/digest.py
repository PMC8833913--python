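"""In-silico tryptic digestion and diGly-remnant site mapping.

Ubiquitinated lysines survive tryptic digestion as a Gly-Gly stub
(K-ε-GG).  This module parses the modified-peptide strings that search
engines emit, simulates trypsin digestion of a protein database, and maps
observed peptidoforms back onto protein coordinates so that a modified
lysine can be reported in the familiar ``K676`` notation.

All coordinates are 1-based and inclusive, in protein residue space.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ProteinRecord",
    "Peptidoform",
    "SiteAnnotation",
    "PeptidoformParseError",
    "DIGLY_TAG",
    "parse_peptidoform",
    "render_peptidoform",
    "tryptic_digest",
    "map_peptide_to_protein",
    "peptide_length_summary",
    "read_fasta",
    "write_fasta",
]

logger = logging.getLogger(__name__)

#: canonical label for the diGly (K-ε-GG) ubiquitin remnant
DIGLY_TAG = "GlyGly"

_AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWYX")

# Dialect table: how each upstream tool writes a diGly-modified K.
# Keys are the literal tag text inside the delimiter; unknown tags raise.
_BRACKET_TAGS = {"gg": DIGLY_TAG, "gl": DIGLY_TAG}
_CARET_TAGS = {"ub": DIGLY_TAG}


class PeptidoformParseError(ValueError):
    """Malformed or chemically invalid modified-peptide string."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identifier plus its amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - _AMINO_ACIDS
        if bad:
            raise ValueError(
                f"protein {self.id!r}: invalid residues {sorted(bad)!r} "
                "(uppercase 20-letter alphabet plus X expected)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Peptidoform:
    """A bare peptide sequence with 1-based modified-K positions.

    Two peptidoforms are equal iff bare sequence *and* the exact set of
    modified positions agree: site isomers of one sequence are distinct
    observations.
    """

    bare_sequence: str
    mod_positions: tuple[int, ...] = ()
    mod_tag: str = DIGLY_TAG

    def __post_init__(self) -> None:
        if not self.bare_sequence:
            raise ValueError("empty peptide sequence")
        object.__setattr__(self, "mod_positions", tuple(self.mod_positions))
        prev = 0
        for pos in self.mod_positions:
            if not 1 <= pos <= len(self.bare_sequence):
                raise ValueError(
                    f"modified position {pos} outside peptide of length "
                    f"{len(self.bare_sequence)}"
                )
            if pos <= prev:
                raise ValueError("modified positions must be strictly increasing")
            if self.bare_sequence[pos - 1] != "K":
                raise PeptidoformParseError(
                    f"modification at position {pos} attached to "
                    f"{self.bare_sequence[pos - 1]!r}, not K"
                )
            prev = pos

    @property
    def key(self) -> str:
        """Normalized identity string: bare sequence + site positions."""
        if not self.mod_positions:
            return self.bare_sequence
        return self.bare_sequence + "|" + ",".join(map(str, self.mod_positions))


@dataclass(frozen=True)
class SiteAnnotation:
    """A peptidoform located on a protein, with site coordinates.

    ``site_positions[i] = peptide_start + mod_position[i] - 1``; every
    site points at a K residue of the parent protein.
    """

    protein_id: str
    peptide_start: int
    site_positions: tuple[int, ...]
    peptide: str
    ambiguous: bool = False


def parse_peptidoform(text: str) -> Peptidoform:
    """Parse a modified-peptide string in any supported dialect.

    Supported dialects: ``K[gg]``, ``K(gl)``, ``K^ub^``.  All dialects of
    the same peptidoform normalize to the same :class:`Peptidoform`.
    Unknown tags and unbalanced delimiters raise
    :class:`PeptidoformParseError`; a modification attached to a non-K
    residue raises with the offending position named.
    """
    if not text:
        raise PeptidoformParseError("empty peptidoform string")
    bare: list[str] = []
    mods: list[int] = []
    i = 0
    n = len(text)
    while i < n:
        c = text[i]
        if c in "[(^":
            closer = {"[": "]", "(": ")", "^": "^"}[c]
            end = text.find(closer, i + 1)
            if end < 0:
                raise PeptidoformParseError(
                    f"unbalanced {c!r} at offset {i} in {text!r}"
                )
            tag = text[i + 1 : end].lower()
            table = _CARET_TAGS if c == "^" else _BRACKET_TAGS
            if tag not in table:
                raise PeptidoformParseError(f"unknown modification tag {tag!r}")
            if not bare:
                raise PeptidoformParseError(
                    f"modification tag at offset {i} precedes any residue"
                )
            pos = len(bare)
            if bare[-1] != "K":
                raise PeptidoformParseError(
                    f"modification at peptide position {pos} attached to "
                    f"{bare[-1]!r}, not K"
                )
            mods.append(pos)
            i = end + 1
        elif c in "])":
            raise PeptidoformParseError(f"unbalanced {c!r} at offset {i} in {text!r}")
        else:
            if c.upper() not in _AMINO_ACIDS:
                raise PeptidoformParseError(f"invalid residue {c!r} in {text!r}")
            bare.append(c.upper())
            i += 1
    return Peptidoform("".join(bare), tuple(mods))


def render_peptidoform(pf: Peptidoform, dialect: str = "gg") -> str:
    """Write *pf* back out in one of the supported dialects."""
    markers = {"gg": "[gg]", "gl": "(gl)", "ub": "^ub^"}
    try:
        marker = markers[dialect]
    except KeyError:
        raise ValueError(f"unknown dialect {dialect!r}") from None
    out = []
    modset = set(pf.mod_positions)
    for i, aa in enumerate(pf.bare_sequence, start=1):
        out.append(aa)
        if i in modset:
            out.append(marker)
    return "".join(out)


def tryptic_digest(
    protein: ProteinRecord,
    max_missed: int = 1,
    blocked_positions: Iterable[int] = (),
) -> list[tuple[str, int, int]]:
    """Digest *protein* with trypsin, emitting (peptide, start, missed).

    Trypsin cleaves C-terminal to K or R, except when the next residue is
    P or when the position is blocked (a diGly-modified K is not cleaved).
    All peptides with 0..*max_missed* missed cleavages are emitted; start
    positions are 1-based.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be non-negative")
    seq = protein.sequence
    blocked = set(blocked_positions)
    for pos in blocked:
        if not (1 <= pos <= len(seq)) or seq[pos - 1] != "K":
            raise ValueError(
                f"blocked position {pos} is not a K residue of {protein.id!r}"
            )
    # 1-based residue positions after which a cut occurs
    cuts = [
        i
        for i in range(1, len(seq))
        if seq[i - 1] in "KR" and seq[i] != "P" and i not in blocked
    ]
    bounds = [0, *cuts, len(seq)]  # segment i spans bounds[i]+1 .. bounds[i+1]
    n_seg = len(bounds) - 1
    peptides: list[tuple[str, int, int]] = []
    for i in range(n_seg):
        for m in range(min(max_missed, n_seg - 1 - i) + 1):
            start, stop = bounds[i], bounds[i + m + 1]
            peptides.append((seq[start:stop], start + 1, m))
    peptides.sort(key=lambda t: (t[1], t[2]))
    return peptides


def map_peptide_to_protein(
    pf: Peptidoform, proteome: Sequence[ProteinRecord]
) -> list[SiteAnnotation]:
    """Locate *pf* in *proteome* by exact substring search.

    Returns one :class:`SiteAnnotation` per match locus (all loci in all
    proteins, overlapping matches included); the ``ambiguous`` flag is set
    on every annotation when the total number of loci exceeds one.  An
    unmatched peptide yields an empty list (logged, not an error).
    """
    if not proteome:
        raise ValueError("proteome must be non-empty")
    hits: list[tuple[str, int]] = []
    needle = pf.bare_sequence
    for prot in proteome:
        offset = prot.sequence.find(needle)
        while offset >= 0:
            hits.append((prot.id, offset + 1))
            offset = prot.sequence.find(needle, offset + 1)
    ambiguous = len(hits) > 1
    if not hits:
        logger.info("peptide %s not found in proteome", needle)
    return [
        SiteAnnotation(
            protein_id=pid,
            peptide_start=start,
            site_positions=tuple(start + p - 1 for p in pf.mod_positions),
            peptide=needle,
            ambiguous=ambiguous,
        )
        for pid, start in hits
    ]


def peptide_length_summary(pfs: Iterable[Peptidoform]) -> dict:
    """Histogram of bare-peptide lengths with min/max.

    Returns ``{"counts": {length: n}, "min": .., "max": ..}``; an empty
    input yields an empty histogram with ``min``/``max`` of ``None``.
    """
    counts = Counter(len(pf.bare_sequence) for pf in pfs)
    if not counts:
        return {"counts": {}, "min": None, "max": None}
    return {
        "counts": dict(sorted(counts.items())),
        "min": min(counts),
        "max": max(counts),
    }


def read_fasta(path) -> list[ProteinRecord]:
    """Read a protein FASTA; the ID is the first whitespace-delimited token."""
    return [
        ProteinRecord(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )
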