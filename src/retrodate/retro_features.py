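"""Hallmarks of a retrocopy insertion: target-site duplication, poly(A)
remnant, intron loss, orientation relative to a host element, and
strand-aware IUPAC motif occurrences.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

from .gene_coords import GeneModel
from .paralog_reads import reverse_complement

__all__ = [
    "detect_tsd",
    "detect_polya",
    "verify_intron_loss",
    "motif_scan",
    "orientation_of",
    "JunctionStatus",
    "MotifHit",
    "RetrocopyAnnotation",
    "MIN_TSD_LEN",
]

MIN_TSD_LEN = 6


class JunctionStatus(str, Enum):
    LOST = "lost"
    RETAINED = "retained"
    UNKNOWN = "unknown"


class Orientation(str, Enum):
    FORWARD = "forward"
    REVERSE = "reverse"


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence; ``start``/``end`` are anchored coordinates
    (1-based downstream of the anchor, -1 immediately upstream, no zero)."""

    start: int
    end: int
    orientation: Orientation
    matched: str


@dataclass
class RetrocopyAnnotation:
    tsd: tuple[str, int]
    polya_length: int
    junctions: list[JunctionStatus]
    orientation: Orientation
    motif_hits: list[MotifHit] = field(default_factory=list)


def detect_tsd(
    locus: str,
    element_interval: tuple[int, int],
    max_len: int = 30,
    max_mismatch: int = 0,
    min_len: int = MIN_TSD_LEN,
) -> tuple[str, int]:
    """Longest duplication between the sequence immediately 5' of an
    inserted element and the sequence immediately 3' of it.

    ``element_interval`` is 0-based half-open on ``locus``. Candidate
    lengths are scanned outward from the boundaries, longest first; a
    candidate tolerates up to ``max_mismatch`` mismatches. Returns
    ``("", 0)`` when no duplication of at least ``min_len`` exists.
    """
    locus = locus.upper()
    start, end = element_interval
    if not (0 <= start < end <= len(locus)):
        raise ValueError("element interval outside the locus")
    if start < max_len or len(locus) - end < max_len:
        raise ValueError(f"flanks shorter than max_len={max_len} on one side")
    for length in range(max_len, min_len - 1, -1):
        left = locus[start - length : start]
        right = locus[end : end + length]
        mism = sum(1 for a, b in zip(left, right) if a != b)
        if mism <= max_mismatch:
            return left, length
    return "", 0


def detect_polya(
    seq: str,
    search_window: int = 50,
    min_len: int = 8,
    min_purity: float = 0.8,
) -> int:
    """Length of the best A-rich tract within the 3'-terminal window: the
    longest A-bounded stretch of length >= ``min_len`` whose fraction of A
    is >= ``min_purity``; 0 when none qualifies."""
    seq = seq.upper()
    window = seq[-search_window:] if search_window < len(seq) else seq
    n = len(window)
    best = 0
    for i in range(n):
        if window[i] != "A":
            continue
        a_count = 0
        for j in range(i, n):
            if window[j] == "A":
                a_count += 1
            length = j - i + 1
            if (
                window[j] == "A"
                and length >= min_len
                and a_count / length >= min_purity
                and length > best
            ):
                best = length
    return best


def verify_intron_loss(
    retrocopy: str, parent: GeneModel, k: int = 18
) -> list[JunctionStatus]:
    """Per parent intron: ``lost`` when the fused exon-exon junction 2k-mer
    occurs in the retrocopy while neither exon-intron junction 2k-mer
    does; ``retained`` for the reverse; ``unknown`` otherwise."""
    if len(parent.exons) < 2:
        raise ValueError("parent model has no introns")
    retrocopy = retrocopy.upper()
    statuses: list[JunctionStatus] = []
    for idx in range(len(parent.exons) - 1):
        (s1, e1), (s2, e2) = parent.exons[idx], parent.exons[idx + 1]
        if e1 - s1 + 1 < k or e2 - s2 + 1 < k:
            raise ValueError(f"k={k} exceeds an exon flanking junction {idx + 1}")
        exon_left = parent.sequence[e1 - k : e1]
        exon_right = parent.sequence[s2 - 1 : s2 - 1 + k]
        intron = parent.sequence[e1 : s2 - 1]
        fused = exon_left + exon_right
        fused_hit = fused in retrocopy
        retained_hit = False
        if len(intron) >= k:
            donor = exon_left + intron[:k]
            acceptor = intron[-k:] + exon_right
            retained_hit = donor in retrocopy and acceptor in retrocopy
        elif intron:
            retained_hit = (exon_left + intron + exon_right) in retrocopy
        if fused_hit and not retained_hit:
            statuses.append(JunctionStatus.LOST)
        elif retained_hit and not fused_hit:
            statuses.append(JunctionStatus.RETAINED)
        else:
            statuses.append(JunctionStatus.UNKNOWN)
    return statuses


_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


def _iupac_regex(motif: str) -> re.Pattern[str]:
    try:
        return re.compile("".join(_IUPAC[b] for b in motif.upper()))
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code {exc.args[0]!r} in motif") from None


def _anchored(pos0: int, anchor0: int) -> int:
    """0-based sequence index -> anchored coordinate where the anchor base
    is +1 and the base before it is -1 (no zero)."""
    return pos0 - anchor0 + 1 if pos0 >= anchor0 else pos0 - anchor0


def motif_scan(
    seq: str,
    motif: str,
    both_strands: bool = True,
    anchor: int = 0,
) -> list[MotifHit]:
    """All exact IUPAC matches of ``motif`` on ``seq`` (and on its reverse
    complement when ``both_strands``), positions reported relative to the
    0-based ``anchor`` index (e.g. the first base of the start codon)."""
    if len(motif) < 4:
        raise ValueError("motif must be at least 4 nt")
    seq = seq.upper()
    pattern = _iupac_regex(motif)
    hits: list[MotifHit] = []
    for m in _overlapping(pattern, seq):
        hits.append(
            MotifHit(
                _anchored(m.start(), anchor),
                _anchored(m.end() - 1, anchor),
                Orientation.FORWARD,
                m.group(0),
            )
        )
    if both_strands:
        rc_pattern = _iupac_regex(reverse_complement(motif))
        for m in _overlapping(rc_pattern, seq):
            hits.append(
                MotifHit(
                    _anchored(m.start(), anchor),
                    _anchored(m.end() - 1, anchor),
                    Orientation.REVERSE,
                    m.group(0),
                )
            )
    hits.sort(key=lambda h: (h.start, h.orientation.value))
    return hits


def _overlapping(pattern: re.Pattern[str], seq: str):
    pos = 0
    while True:
        m = pattern.search(seq, pos)
        if m is None:
            return
        yield m
        pos = m.start() + 1


def orientation_of(retro_locus_segment: str, spliced_parent: str) -> Orientation:
    """Strand of the retrocopy relative to its host: the orientation whose
    alignment to the spliced parent transcript scores best (shared-k-mer
    count; cheap and adequate for >90% identity)."""
    k = 12
    ref = {spliced_parent[i : i + k] for i in range(len(spliced_parent) - k + 1)}
    fwd = sum(
        1
        for i in range(len(retro_locus_segment) - k + 1)
        if retro_locus_segment[i : i + k] in ref
    )
    rc = reverse_complement(retro_locus_segment)
    rev = sum(1 for i in range(len(rc) - k + 1) if rc[i : i + k] in ref)
    return Orientation.FORWARD if fwd >= rev else Orientation.REVERSE
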