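"""Gene models and coding-DNA (c.) coordinates.

All user-facing coordinates are 1-based closed intervals in the HGVS style:
negative positions count backward through the 5' UTR from the first base of
the start codon, plain positions count through the reading frame (the stop
codon included), asterisked positions count forward through the 3' UTR, and
``a+m`` / ``a-m`` address intronic bases by their offset from the nearest
exonic anchor. Internally everything is 0-based half-open; the conversion
lives in this module only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator

from Bio.Data.CodonTable import standard_dna_table
from Bio.SeqUtils import seq3

__all__ = [
    "Region",
    "CodingPosition",
    "GeneModel",
    "CoordinateError",
    "LabelParseError",
    "parse_coding_label",
    "coding_to_transcript",
    "transcript_to_coding",
    "codon_index",
    "protein_effect",
    "ProteinEffect",
    "EffectKind",
]

_VALID_BASES = frozenset("ACGTN")


class CoordinateError(ValueError):
    """A position cannot be addressed in the given gene model."""


class LabelParseError(ValueError):
    """A coding-coordinate label does not match the grammar."""


class Region(str, Enum):
    UTR5 = "UTR5"
    CDS = "CDS"
    UTR3 = "UTR3"
    INTRON = "INTRON"


@dataclass(frozen=True, order=True)
class CodingPosition:
    """One addressable base in coding-DNA coordinates.

    ``anchor`` is always a positive integer: the distance back from the
    start codon (UTR5), the position within the reading frame counting the
    A of ATG as 1 (CDS), or the position past the stop codon (UTR3). For
    intronic positions the anchor is the nearest reading-frame base and
    ``intron_offset`` is the signed HGVS offset.
    """

    region: Region
    anchor: int
    intron_offset: int = 0

    def __post_init__(self) -> None:
        if self.anchor < 1:
            raise ValueError(f"anchor must be >= 1, got {self.anchor}")
        if (self.intron_offset != 0) != (self.region is Region.INTRON):
            raise ValueError("intron_offset must be nonzero iff region is INTRON")

    def __str__(self) -> str:
        if self.region is Region.UTR5:
            return f"-{self.anchor}"
        if self.region is Region.UTR3:
            return f"*{self.anchor}"
        if self.region is Region.INTRON:
            return f"{self.anchor}{self.intron_offset:+d}"
        return str(self.anchor)

    @property
    def label(self) -> str:
        return f"c.{self}"

    @property
    def sort_key(self) -> tuple[int, int, int]:
        """Orders positions 5' to 3' along the transcript (UTR5 before CDS
        before UTR3; intron positions sort with their anchor)."""
        if self.region is Region.UTR5:
            return (0, -self.anchor, 0)
        if self.region is Region.CDS:
            return (1, self.anchor, 0)
        if self.region is Region.INTRON:
            return (1, self.anchor, self.intron_offset)
        return (2, self.anchor, 0)


_LABEL_RE = re.compile(
    r"""^(?:c\.)?
        (?:
            (?P<utr5>-(?P<utr5_n>\d+))
          | (?P<utr3>\*(?P<utr3_n>\d+))
          | (?P<intron>(?P<anchor>\d+)(?P<sign>[+-])(?P<offset>\d+))
          | (?P<cds>\d+)
        )$""",
    re.VERBOSE,
)


def parse_coding_label(label: str) -> CodingPosition:
    """Parse a coding-coordinate label such as ``c.-212``, ``c.759``,
    ``c.*543`` or ``c.502-64`` into a :class:`CodingPosition`.

    Raises :class:`LabelParseError` on anything outside the grammar.
    """
    m = _LABEL_RE.match(label.strip())
    if m is None:
        raise LabelParseError(f"malformed coding-coordinate label: {label!r}")
    if m.group("utr5"):
        return CodingPosition(Region.UTR5, int(m.group("utr5_n")))
    if m.group("utr3"):
        return CodingPosition(Region.UTR3, int(m.group("utr3_n")))
    if m.group("intron"):
        off = int(m.group("offset"))
        if off == 0:
            raise LabelParseError(f"intron offset must be nonzero in {label!r}")
        if m.group("sign") == "-":
            off = -off
        return CodingPosition(Region.INTRON, int(m.group("anchor")), off)
    return CodingPosition(Region.CDS, int(m.group("cds")))


@dataclass
class GeneModel:
    """A single-transcript gene anchored on its transcribed-strand sequence.

    ``sequence`` is the genomic sequence of the transcribed strand with
    introns included; ``exons`` are 1-based closed intervals on it, sorted
    and non-overlapping; ``cds_start``/``cds_end`` delimit the reading
    frame (stop codon included) in spliced-transcript coordinates.
    """

    name: str
    sequence: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    _exon_offsets: list[int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(f"invalid bases in sequence: {sorted(bad)}")
        if not self.exons:
            raise ValueError("gene model needs at least one exon")
        self.exons = [(int(s), int(e)) for s, e in self.exons]
        prev_end = 0
        for s, e in self.exons:
            if not (1 <= s <= e <= len(self.sequence)):
                raise ValueError(f"exon ({s}, {e}) outside sequence of length {len(self.sequence)}")
            if s <= prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = e
        # cumulative spliced length before each exon
        offsets, total = [], 0
        for s, e in self.exons:
            offsets.append(total)
            total += e - s + 1
        self._exon_offsets = offsets
        if not (1 <= self.cds_start < self.cds_end <= total):
            raise ValueError("CDS interval outside spliced transcript")
        cds_len = self.cds_end - self.cds_start + 1
        if cds_len % 3 != 0 or cds_len < 6:
            raise ValueError(f"CDS length {cds_len} must be a positive multiple of 3 and >= 6")

    # -- derived anatomy ---------------------------------------------------

    @property
    def spliced_length(self) -> int:
        return self._exon_offsets[-1] + (self.exons[-1][1] - self.exons[-1][0] + 1)

    @property
    def spliced_sequence(self) -> str:
        return "".join(self.sequence[s - 1 : e] for s, e in self.exons)

    @property
    def cds_sequence(self) -> str:
        return self.spliced_sequence[self.cds_start - 1 : self.cds_end]

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start + 1

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Genomic 1-based closed intron intervals, 5' to 3'."""
        return [
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        ]

    # -- coordinate plumbing ----------------------------------------------

    def transcript_to_genomic(self, t: int) -> int:
        """Map a spliced-transcript position to its genomic position."""
        if not 1 <= t <= self.spliced_length:
            raise CoordinateError(f"transcript position {t} outside [1, {self.spliced_length}]")
        for (s, e), off in zip(self.exons, self._exon_offsets):
            if t <= off + (e - s + 1):
                return s + (t - off - 1)
        raise AssertionError("unreachable")

    def genomic_to_transcript(self, g: int) -> int | None:
        """Map a genomic position to spliced coordinates; None if intronic
        or outside all exons."""
        for (s, e), off in zip(self.exons, self._exon_offsets):
            if s <= g <= e:
                return off + (g - s) + 1
        return None

    def iter_coding_positions(self) -> Iterator[CodingPosition]:
        """Every addressable position of the model, exonic then intronic."""
        for t in range(1, self.spliced_length + 1):
            yield transcript_to_coding(t, self)
        for istart, iend in self.introns:
            for g in range(istart, iend + 1):
                yield self.genomic_to_coding_intronic(g)

    def genomic_to_coding_intronic(self, g: int) -> CodingPosition:
        """Coding position of a genomic base that lies inside an intron."""
        for istart, iend in self.introns:
            if istart <= g <= iend:
                mid = istart + (iend - istart) // 2
                if g <= mid:
                    anchor_t = self.genomic_to_transcript(istart - 1)
                    assert anchor_t is not None
                    return CodingPosition(
                        Region.INTRON, self._cds_anchor(anchor_t), g - (istart - 1)
                    )
                anchor_t = self.genomic_to_transcript(iend + 1)
                assert anchor_t is not None
                return CodingPosition(
                    Region.INTRON, self._cds_anchor(anchor_t), g - (iend + 1)
                )
        raise CoordinateError(f"genomic position {g} is not intronic")

    def _cds_anchor(self, t: int) -> int:
        """Reading-frame number used to anchor intron offsets.

        Intron anchors are expressed in reading-frame numbering even when
        the flanking exonic base is in a UTR (the common case in practice
        has introns inside the CDS; UTR-anchored introns clamp to the
        nearest frame edge, which keeps the label well-formed).
        """
        if t < self.cds_start:
            return 1
        if t > self.cds_end:
            return self.cds_length
        return t - self.cds_start + 1


def transcript_to_coding(t: int, model: GeneModel) -> CodingPosition:
    """Coding position of spliced-transcript position ``t``."""
    if not 1 <= t <= model.spliced_length:
        raise CoordinateError(f"transcript position {t} outside [1, {model.spliced_length}]")
    if t < model.cds_start:
        return CodingPosition(Region.UTR5, model.cds_start - t)
    if t <= model.cds_end:
        return CodingPosition(Region.CDS, t - model.cds_start + 1)
    return CodingPosition(Region.UTR3, t - model.cds_end)


def coding_to_transcript(pos: CodingPosition, model: GeneModel) -> int:
    """Spliced-transcript index of an exonic coding position, or the
    genomic index when the position is intronic."""
    if pos.region is Region.UTR5:
        t = model.cds_start - pos.anchor
        if t < 1:
            raise CoordinateError(f"{pos.label} precedes the transcript start")
        return t
    if pos.region is Region.CDS:
        if pos.anchor > model.cds_length:
            raise CoordinateError(f"{pos.label} beyond CDS of length {model.cds_length}")
        return model.cds_start + pos.anchor - 1
    if pos.region is Region.UTR3:
        t = model.cds_end + pos.anchor
        if t > model.spliced_length:
            raise CoordinateError(f"{pos.label} beyond the transcript end")
        return t
    # intron: resolve the exonic anchor genomically and step into the intron
    anchor_t = model.cds_start + pos.anchor - 1
    if not 1 <= anchor_t <= model.spliced_length:
        raise CoordinateError(f"intron anchor of {pos.label} outside the transcript")
    g = model.transcript_to_genomic(anchor_t) + pos.intron_offset
    if model.genomic_to_transcript(g) is not None or not 1 <= g <= len(model.sequence):
        raise CoordinateError(f"{pos.label} does not land in an intron")
    return g


def codon_index(cds_pos: int, cds_length: int | None = None) -> tuple[int, int]:
    """Map a reading-frame position to ``(codon, frame)``, both 1-based.

    ``frame`` is the base's position within its codon (1-3).
    """
    if cds_pos < 1:
        raise CoordinateError(f"reading-frame position must be >= 1, got {cds_pos}")
    if cds_length is not None and cds_pos > cds_length:
        raise CoordinateError(f"reading-frame position {cds_pos} beyond CDS length {cds_length}")
    return (cds_pos - 1) // 3 + 1, (cds_pos - 1) % 3 + 1


class EffectKind(str, Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    FRAMESHIFT = "frameshift"
    STOP_AFFECTING = "stop_affecting"
    IN_FRAME_INDEL = "in_frame_indel"
    NONCODING = "noncoding"


@dataclass(frozen=True)
class ProteinEffect:
    kind: EffectKind
    aa_from: str | None = None  # three-letter residue codes
    aa_to: str | None = None
    codon: int | None = None

    def __str__(self) -> str:
        if self.kind is EffectKind.MISSENSE:
            return f"p.{self.aa_from}{self.codon}{self.aa_to}"
        return self.kind.value


_CODON_TO_AA = dict(standard_dna_table.forward_table)


def _translate_codon(codon: str) -> str:
    if codon in standard_dna_table.stop_codons:
        return "*"
    try:
        return _CODON_TO_AA[codon]
    except KeyError:
        raise CoordinateError(f"codon {codon!r} contains ambiguous bases") from None


def protein_effect(variant, cds_sequence: str) -> ProteinEffect:
    """Coarse protein-level consequence of a variant given the reading
    frame (stop codon included).

    Substitutions must be single-base. Indels inside the reading frame are
    frameshifts when their length is not a multiple of 3. Variants outside
    the reading frame are noncoding.
    """
    from .pairalign import Variant, VariantKind  # local import avoids a cycle

    if not isinstance(variant, Variant):
        raise TypeError("protein_effect expects a pairalign.Variant")
    cds_sequence = cds_sequence.upper()
    pos = variant.position
    if pos.region is not Region.CDS:
        return ProteinEffect(EffectKind.NONCODING)
    if variant.kind is VariantKind.SUBSTITUTION:
        if len(variant.ancestral) != 1 or len(variant.derived) != 1:
            raise ValueError("substitutions must be single-base")
        if pos.anchor > len(cds_sequence):
            raise CoordinateError(f"position {pos.label} beyond supplied reading frame")
        codon_no, frame = codon_index(pos.anchor, len(cds_sequence))
        start = (codon_no - 1) * 3
        codon = cds_sequence[start : start + 3]
        if codon[frame - 1] != variant.ancestral:
            raise ValueError(
                f"reading frame has {codon[frame - 1]} at {pos.label}, "
                f"variant claims ancestral {variant.ancestral}"
            )
        alt = codon[: frame - 1] + variant.derived + codon[frame:]
        aa_from, aa_to = _translate_codon(codon), _translate_codon(alt)
        if aa_from == aa_to:
            return ProteinEffect(EffectKind.SYNONYMOUS, codon=codon_no)
        if aa_from == "*" or aa_to == "*":
            return ProteinEffect(
                EffectKind.STOP_AFFECTING, seq3(aa_from) if aa_from != "*" else "Ter",
                seq3(aa_to) if aa_to != "*" else "Ter", codon_no,
            )
        return ProteinEffect(EffectKind.MISSENSE, seq3(aa_from), seq3(aa_to), codon_no)
    if variant.kind in (VariantKind.DELETION, VariantKind.INSERTION):
        length = len(variant.ancestral) if variant.kind is VariantKind.DELETION else len(variant.derived)
        codon_no, _ = codon_index(pos.anchor, len(cds_sequence))
        if length % 3 != 0:
            return ProteinEffect(EffectKind.FRAMESHIFT, codon=codon_no)
        return ProteinEffect(EffectKind.IN_FRAME_INDEL, codon=codon_no)
    # repeat-length variants sit in UTR tracts in practice; inside the CDS
    # treat them like indels of the implied length difference
    return ProteinEffect(EffectKind.NONCODING)
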