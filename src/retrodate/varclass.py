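"""Classification of variants: polymorphic vs. fixed within each paralog,
ancestral vs. derived against outgroups, reconstruction of the parent
allele, and counting of fixed differences over a comparison region.

Fixation is always relative to the observed panel: every call carries the
panel sizes it was made from, so "fixed" stays evidence-qualified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .gene_coords import CodingPosition, parse_coding_label

__all__ = [
    "SitePanel",
    "FixationStatus",
    "FixationCall",
    "AncestralCall",
    "ReconstructionResult",
    "classify_fixation",
    "assign_ancestral",
    "reconstruct_parent",
    "count_fixed_differences",
    "panels_from_frame",
    "panels_to_frame",
    "calls_to_frame",
]

_ALLELE_OK_SINGLE = frozenset("ACGT")


def _check_allele(allele: str) -> str:
    allele = allele.strip()
    if allele in ("del", "=") or allele in _ALLELE_OK_SINGLE:
        return allele
    if allele.startswith("repeat:"):
        int(allele.split(":", 1)[1])  # validates
        return allele
    if allele == "N":
        return allele
    raise ValueError(f"unrecognized allele {allele!r}")


@dataclass
class SitePanel:
    """Observed alleles at one site of one paralog across a panel.

    ``observations`` maps an individual or source name to its allele;
    ``source_class`` records whether each observation came from a
    reference assembly or a panel sequence. ``N`` observations are kept
    but never counted as alleles.
    """

    paralog: str
    position: CodingPosition
    observations: dict[str, str]
    source_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.observations:
            raise ValueError("a site panel needs at least one observation")
        self.observations = {k: _check_allele(v) for k, v in self.observations.items()}

    @property
    def alleles(self) -> set[str]:
        """Distinct non-missing alleles observed."""
        return {a for a in self.observations.values() if a != "N"}

    @property
    def size(self) -> int:
        return sum(1 for a in self.observations.values() if a != "N")

    @property
    def is_polymorphic(self) -> bool:
        return len(self.alleles) >= 2

    @property
    def is_repeat_site(self) -> bool:
        return any(a.startswith("repeat:") for a in self.alleles)


class FixationStatus(str, Enum):
    FIXED_DIFFERENCE = "fixed_difference"
    POLYMORPHIC_IN_PARENT = "polymorphic_in_parent"
    POLYMORPHIC_IN_RETROCOPY = "polymorphic_in_retrocopy"
    POLYMORPHIC_IN_BOTH = "polymorphic_in_both"
    SHARED_INVARIANT = "shared_invariant"
    UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class FixationCall:
    position: CodingPosition
    status: FixationStatus
    parent_alleles: frozenset[str] = frozenset()
    retro_alleles: frozenset[str] = frozenset()
    parent_n: int = 0
    retro_n: int = 0

    def __post_init__(self) -> None:
        if self.status is FixationStatus.FIXED_DIFFERENCE:
            if len(self.parent_alleles) != 1 or len(self.retro_alleles) != 1:
                raise ValueError("fixed_difference requires both paralogs monomorphic")
            if self.parent_alleles == self.retro_alleles:
                raise ValueError("fixed_difference requires differing alleles")


@dataclass(frozen=True)
class AncestralCall:
    """Outgroup-parsimony polarity at one site: the unanimous outgroup
    state, or ``ambiguous``/``unresolved``."""

    position: CodingPosition
    state: str  # nucleotide, "del", "ambiguous", or "unresolved"
    basis: tuple[tuple[str, str], ...] = ()  # (taxon, observed state)

    def __post_init__(self) -> None:
        if self.state not in ("ambiguous", "unresolved"):
            informative = {s for _, s in self.basis if s != "N"}
            if informative and informative != {self.state}:
                raise ValueError("non-ambiguous call conflicts with its basis")


def classify_fixation(
    parent_panel: list[SitePanel], retro_panel: list[SitePanel]
) -> list[FixationCall]:
    """Classify every site observed in either paralog's panel.

    A site is polymorphic in a paralog iff >= 2 distinct alleles are
    observed there; a fixed difference requires each paralog monomorphic
    with differing alleles. Sites observed in only one paralog are
    unresolved.
    """
    if not parent_panel and not retro_panel:
        raise ValueError("both panels are empty")
    parents = {p.position: p for p in parent_panel}
    retros = {p.position: p for p in retro_panel}
    calls: list[FixationCall] = []
    for pos in sorted(set(parents) | set(retros), key=lambda p: p.sort_key):
        pp, rp = parents.get(pos), retros.get(pos)
        if pp is None or rp is None:
            side = pp or rp
            calls.append(
                FixationCall(
                    pos,
                    FixationStatus.UNRESOLVED,
                    frozenset(pp.alleles) if pp else frozenset(),
                    frozenset(rp.alleles) if rp else frozenset(),
                    pp.size if pp else 0,
                    rp.size if rp else 0,
                )
            )
            continue
        p_poly, r_poly = pp.is_polymorphic, rp.is_polymorphic
        if p_poly and r_poly:
            status = FixationStatus.POLYMORPHIC_IN_BOTH
        elif p_poly:
            status = FixationStatus.POLYMORPHIC_IN_PARENT
        elif r_poly:
            status = FixationStatus.POLYMORPHIC_IN_RETROCOPY
        elif not pp.alleles or not rp.alleles:
            status = FixationStatus.UNRESOLVED
        elif pp.alleles == rp.alleles:
            status = FixationStatus.SHARED_INVARIANT
        else:
            status = FixationStatus.FIXED_DIFFERENCE
        calls.append(
            FixationCall(
                pos, status,
                frozenset(pp.alleles), frozenset(rp.alleles), pp.size, rp.size,
            )
        )
    return calls


def assign_ancestral(
    position: CodingPosition,
    focal_states: set[str],
    outgroups: dict[str, str | None],
) -> AncestralCall:
    """Polarize one site with outgroup states.

    Unanimity among non-missing outgroups sets the ancestral state;
    disagreement yields ``ambiguous``; repeat-length sites are always
    ambiguous; all-missing outgroups yield ``unresolved``.
    """
    basis = tuple(sorted((t, s if s is not None else "N") for t, s in outgroups.items()))
    if any(s.startswith("repeat:") for s in focal_states) or any(
        s.startswith("repeat:") for _, s in basis
    ):
        return AncestralCall(position, "ambiguous", basis)
    informative = {s for _, s in basis if s != "N"}
    if not informative:
        return AncestralCall(position, "unresolved", basis)
    if len(informative) > 1:
        return AncestralCall(position, "ambiguous", basis)
    return AncestralCall(position, next(iter(informative)), basis)


@dataclass
class ReconstructionResult:
    """Merged parent sequence plus the bookkeeping of what could not be
    resolved. ``sequence`` equals both references at concordant positions
    and the ancestral state where they disagree; ambiguous positions are
    N. Positions are 1-based on the primary reference."""

    sequence: str
    ambiguous_positions: list[int]
    excluded_regions: list[tuple[int, int]]

    @property
    def n_ambiguous(self) -> int:
        return len(self.ambiguous_positions)


def reconstruct_parent(
    ref_primary: str,
    ref_alternate: str,
    ancestral_calls: dict[int, AncestralCall],
) -> ReconstructionResult:
    """Merge two references of the parent gene into the inferred ancestral
    allele.

    ``ancestral_calls`` is keyed by 1-based position on the primary
    reference; a call is required wherever the references substitute.
    Length differences (indel discordance) are not merged: the references
    must be pre-aligned to equal length with ``-`` padding, and discordant
    indel columns are excluded (primary's state kept, region recorded).
    """
    if len(ref_primary) != len(ref_alternate):
        raise ValueError(
            "references must be pre-aligned to equal length (pad indels with '-')"
        )
    out: list[str] = []
    ambiguous: list[int] = []
    excluded: list[tuple[int, int]] = []
    pos = 0  # 1-based position on primary (non-gap columns)
    in_excl_start: int | None = None
    for a, b in zip(ref_primary.upper(), ref_alternate.upper()):
        if a != "-":
            pos += 1
        if a == "-" or b == "-":
            if a != "-":
                out.append(a)
            if in_excl_start is None:
                in_excl_start = max(pos, 1)
            continue
        if in_excl_start is not None:
            excluded.append((in_excl_start, max(pos - 1, in_excl_start)))
            in_excl_start = None
        if a == b:
            out.append(a)
            continue
        call = ancestral_calls.get(pos)
        if call is None or call.state in ("ambiguous", "unresolved"):
            out.append("N")
            ambiguous.append(pos)
        elif call.state == a:
            out.append(a)
        elif call.state == b:
            out.append(b)
        else:
            # outgroups carry a third state: neither reference is ancestral
            out.append("N")
            ambiguous.append(pos)
    if in_excl_start is not None:
        excluded.append((in_excl_start, pos))
    return ReconstructionResult("".join(out), ambiguous, excluded)


def count_fixed_differences(
    calls: list[FixationCall],
    region_mask: set[CodingPosition],
) -> tuple[int, int]:
    """Count ``k`` fixed-difference substitution calls inside the mask and
    report ``L`` as the mask size.

    The mask is the set of compared positions; repeat tracts and indel
    columns are excluded by constructing the mask without them. Indel
    fixed differences (``del`` alleles) are not substitutions and do not
    count toward ``k``.
    """
    k = 0
    for call in calls:
        if call.status is not FixationStatus.FIXED_DIFFERENCE:
            continue
        if call.position not in region_mask:
            continue
        alleles = call.parent_alleles | call.retro_alleles
        if alleles <= _ALLELE_OK_SINGLE:
            k += 1
    return k, len(region_mask)


# -- TSV round-tripping ----------------------------------------------------

def panels_to_frame(panels: list[SitePanel]) -> pd.DataFrame:
    rows = [
        {
            "paralog": p.paralog,
            "position": str(p.position),
            "individual": ind,
            "allele": allele,
            "source": p.source_class.get(ind, "panel_sequence"),
        }
        for p in panels
        for ind, allele in p.observations.items()
    ]
    return pd.DataFrame(rows, columns=["paralog", "position", "individual", "allele", "source"])


def panels_from_frame(frame: pd.DataFrame) -> list[SitePanel]:
    panels: list[SitePanel] = []
    for (paralog, pos_label), grp in frame.groupby(["paralog", "position"], sort=False):
        panels.append(
            SitePanel(
                paralog=str(paralog),
                position=parse_coding_label(str(pos_label)),
                observations=dict(zip(grp["individual"], grp["allele"])),
                source_class=dict(zip(grp["individual"], grp["source"])),
            )
        )
    return panels


def calls_to_frame(calls: list[FixationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "position": str(c.position),
                "status": c.status.value,
                "parent_alleles": "/".join(sorted(c.parent_alleles)),
                "retro_alleles": "/".join(sorted(c.retro_alleles)),
                "parent_n": c.parent_n,
                "retro_n": c.retro_n,
            }
            for c in calls
        ],
        columns=["position", "status", "parent_alleles", "retro_alleles", "parent_n", "retro_n"],
    )
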