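"""Diagnostic sites among near-identical paralogs and conclusive
assignment of short reads.

Reads are placed gaplessly (minimum Hamming distance over every offset,
both orientations) against each ungapped member of a pre-aligned paralog
family; a read is conclusively assigned when a single member attains the
minimum distance with a configurable margin over the runner-up. ``N`` in a
read matches nothing, so it adds one mismatch against every member —
conservative toward a tie.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

__all__ = [
    "ParalogSet",
    "ReadAssignment",
    "Verdict",
    "find_diagnostic_sites",
    "assign_read",
    "spans_junction",
    "reverse_complement",
    "MIN_READ_LENGTH",
]

MIN_READ_LENGTH = 20

_COMP = str.maketrans("ACGTNacgtn-", "TGCANtgcan-")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class ParalogSet:
    """A family of paralogous sequences pre-aligned over a common frame
    (gap-padded with ``-``), one of which is the focal member."""

    members: dict[str, str]
    focal: str

    def __post_init__(self) -> None:
        if self.focal not in self.members:
            raise ValueError(f"focal member {self.focal!r} not in the set")
        lengths = {len(s) for s in self.members.values()}
        if len(lengths) > 1:
            raise ValueError("all aligned rows must have equal length")
        self.members = {k: v.upper() for k, v in self.members.items()}

    @property
    def aligned_length(self) -> int:
        return len(self.members[self.focal])

    def ungapped(self, name: str) -> str:
        return self.members[name].replace("-", "")


class Verdict(str, Enum):
    UNIQUE = "unique"
    TIED = "tied"
    UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    per_member_mismatches: dict[str, int] = field(hash=False)
    verdict: Verdict = Verdict.UNASSIGNED
    best_member: str | None = None
    tied_members: frozenset[str] = frozenset()


def find_diagnostic_sites(pset: ParalogSet) -> list[tuple[int, str]]:
    """Aligned columns (0-based) where the focal member's allele differs
    from every other member's; gaps count as alleles."""
    if len(pset.members) < 2:
        raise ValueError("need at least 2 members to find diagnostic sites")
    focal_row = pset.members[pset.focal]
    other_rows = [row for name, row in pset.members.items() if name != pset.focal]
    return [
        (col, focal_row[col])
        for col in range(pset.aligned_length)
        if all(row[col] != focal_row[col] for row in other_rows)
    ]


def _best_hamming(read: str, target: str) -> int:
    """Minimum Hamming distance of ``read`` over all gapless placements on
    ``target`` (one orientation). A read longer than the target counts the
    overhang as mismatches."""
    n, m = len(read), len(target)
    if n > m:
        return _best_hamming(read[:m], target) + (n - m)
    best = n
    for off in range(m - n + 1):
        d = 0
        window = target[off : off + n]
        for a, b in zip(read, window):
            if a != b or a == "N":
                d += 1
                if d >= best:
                    break
        if d < best:
            best = d
            if best == 0:
                break
    return best


def assign_read(
    read: str,
    pset: ParalogSet,
    margin: int = 1,
    read_id: str = "read",
    edit_distance: bool = False,
) -> ReadAssignment:
    """Assign a short read among the family members.

    For each member, the read's best gapless placement (both orientations)
    is scored by Hamming distance; ``edit_distance=True`` switches to a
    full Levenshtein placement. The verdict is ``unique`` iff exactly one
    member attains the minimum and the runner-up is at least ``margin``
    mismatches worse.
    """
    read = read.upper()
    if len(read) < MIN_READ_LENGTH:
        raise ValueError(f"read shorter than {MIN_READ_LENGTH} nt")
    if len(read) > pset.aligned_length:
        raise ValueError("read longer than the aligned family")
    if margin < 1:
        raise ValueError("margin must be >= 1")
    rc = reverse_complement(read)
    scorer = _best_edit if edit_distance else _best_hamming
    dists = {
        name: min(scorer(read, pset.ungapped(name)), scorer(rc, pset.ungapped(name)))
        for name in pset.members
    }
    ranked = sorted(dists.items(), key=lambda kv: (kv[1], kv[0]))
    best_name, best_d = ranked[0]
    ties = frozenset(n for n, d in dists.items() if d == best_d)
    if len(ties) > 1:
        return ReadAssignment(read_id, dists, Verdict.TIED, None, ties)
    if len(ranked) > 1 and ranked[1][1] - best_d < margin:
        return ReadAssignment(read_id, dists, Verdict.UNASSIGNED, None, frozenset())
    return ReadAssignment(read_id, dists, Verdict.UNIQUE, best_name, frozenset([best_name]))


def _best_edit(read: str, target: str) -> int:
    """Minimum edit distance of an infix placement of ``read`` on
    ``target`` (free ends on the target, all of the read consumed)."""
    n, m = len(read), len(target)
    prev = [0] * (m + 1)  # free start anywhere on target
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        ri = read[i - 1]
        for j in range(1, m + 1):
            sub = prev[j - 1] + (0 if (ri == target[j - 1] and ri != "N") else 1)
            cur[j] = min(sub, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return min(prev)


def _mismatch_profile(read: str, target: str):
    """Mismatch count of every gapless placement of ``read`` on ``target``
    (vectorized). N in the read mismatches everything."""
    import numpy as np

    r = np.frombuffer(read.encode(), dtype=np.uint8)
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    n, m = r.size, t.size
    if n > m:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(t, n)
    mism = (windows != r).sum(axis=1)
    n_count = int((r == ord("N")).sum())
    if n_count:
        # N never matches, including N-vs-N columns the comparison missed
        mism = mism + (windows[:, r == ord("N")] == ord("N")).sum(axis=1)
    return mism


@dataclass(frozen=True)
class JunctionPlacement:
    spans: bool
    offset: int | None  # 0-based best placement start on the reference
    mismatches: int | None
    left_overhang: int = 0
    right_overhang: int = 0


def spans_junction(
    read: str,
    reference: str,
    junction: int,
    min_overhang: int = 10,
) -> JunctionPlacement:
    """Does the read's best gapless placement cover at least
    ``min_overhang`` bases on each side of the 0-based cut index
    ``junction``? Both orientations are tried."""
    read = read.upper()
    reference = reference.upper()
    if not 0 <= junction <= len(reference):
        raise ValueError("junction outside the reference")
    best: tuple[int, int, str] | None = None  # (dist, offset, oriented read)

    def covers(off: int, n: int) -> bool:
        return junction - off >= min_overhang and off + n - junction >= min_overhang

    # exact occurrences are globally optimal; prefer one that spans
    for oriented in (read, reverse_complement(read)):
        if "N" in oriented:
            continue
        off = reference.find(oriented)
        while off != -1:
            if best is None or best[0] > 0 or (
                covers(off, len(oriented)) and not covers(best[1], len(best[2]))
            ):
                best = (0, off, oriented)
            if covers(off, len(oriented)):
                break
            off = reference.find(oriented, off + 1)
        if best is not None and covers(best[1], len(best[2])):
            break
    if best is None:  # no exact hit: vectorized Hamming scan
        for oriented in (read, reverse_complement(read)):
            d_arr = _mismatch_profile(oriented, reference)
            if d_arr.size == 0:
                continue
            off = int(d_arr.argmin())
            if best is None or d_arr[off] < best[0]:
                best = (int(d_arr[off]), off, oriented)
    if best is None:
        return JunctionPlacement(False, None, None)
    d, off, oriented = best
    left = junction - off
    right = off + len(oriented) - junction
    spans = left >= min_overhang and right >= min_overhang
    return JunctionPlacement(spans, off, d, max(left, 0), max(right, 0))
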