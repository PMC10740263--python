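"""IMGT unique numbering: labels, comparator, regions, gap filling.

The IMGT scheme assigns every residue of an antibody variable domain a
position from 1 to 128, with fixed anchors (Cys 23, Trp 41, Cys 104,
Trp/Phe 118).  Positions missing from a short domain are simply absent;
domains longer than the scheme receive insertion codes.  Almost all
insertion happens in CDR3, where extra residues beyond the 13 canonical
positions 105-117 are numbered 111.1, 111.2, ... ascending and then
112.k, ..., 112.2, 112.1 descending into position 112.  The comparator
therefore orders

    111 < 111.1 < 111.2 < ... < 112.2 < 112.1 < 112

Insertions anywhere else follow the ordinary rule p < p.1 < p.2 < p+1.
"""

from __future__ import annotations

from typing import NamedTuple

#: Inclusive IMGT position bounds of the seven regions, in domain order.
REGION_BOUNDS: dict[str, tuple[int, int]] = {
    "FR1": (1, 26),
    "CDR1": (27, 38),
    "FR2": (39, 55),
    "CDR2": (56, 65),
    "FR3": (66, 104),
    "CDR3": (105, 117),
    "FR4": (118, 128),
}

REGION_ORDER = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")

#: Conserved anchor positions and the residue class expected there.
ANCHORS: dict[int, str] = {23: "C", 41: "W", 104: "C", 118: "WF"}


class ImgtLabel(NamedTuple):
    """One IMGT position, possibly an insertion code (e.g. 111.2)."""

    position: int
    insert: int = 0

    def key(self) -> tuple[int, int]:
        """Sort key implementing the IMGT comparator.

        Insertions at 112 precede 112 itself (descending); everywhere
        else insertions follow their base position.
        """
        if self.position == 112:
            return (112, -self.insert)
        return (self.position, self.insert)

    def __str__(self) -> str:
        if self.insert:
            return f"{self.position}.{self.insert}"
        return str(self.position)

    @classmethod
    def parse(cls, text: str) -> "ImgtLabel":
        if "." in text:
            pos, ins = text.split(".", 1)
            return cls(int(pos), int(ins))
        return cls(int(text), 0)


def label_sorted(labels: list[ImgtLabel]) -> list[ImgtLabel]:
    return sorted(labels, key=ImgtLabel.key)


def is_increasing(labels: list[ImgtLabel]) -> bool:
    """True if labels are strictly increasing under the IMGT comparator."""
    keys = [lab.key() for lab in labels]
    return all(a < b for a, b in zip(keys, keys[1:]))


def region_of(label: ImgtLabel) -> str:
    """Region name for a label; insertion codes follow their base position."""
    pos = label.position
    for region, (lo, hi) in REGION_BOUNDS.items():
        if lo <= pos <= hi:
            return region
    raise ValueError(f"IMGT position {pos} outside 1..128")


def short_loop_labels(lo: int, hi: int, n: int) -> list[ImgtLabel]:
    """IMGT labels for a loop of ``n`` residues numbered over [lo, hi].

    Shorter-than-canonical loops keep the two ends and lose positions at
    the top (middle): the first ceil(n/2) residues take lo, lo+1, ...,
    the remaining floor(n/2) take ..., hi-1, hi.  Requires
    n <= hi - lo + 1.
    """
    width = hi - lo + 1
    if n > width:
        raise ValueError(f"{n} residues cannot fit in IMGT {lo}..{hi}")
    n_front = (n + 1) // 2
    n_back = n - n_front
    front = [ImgtLabel(lo + i) for i in range(n_front)]
    back = [ImgtLabel(hi - n_back + 1 + i) for i in range(n_back)]
    return front + back


def gap_labels(prev: ImgtLabel, nxt: ImgtLabel, n: int) -> list[ImgtLabel]:
    """Labels for ``n`` residues lying strictly between ``prev`` and ``nxt``.

    Used when a stretch of query residues carries no model position:
    insert runs inside one alignment, or the unmatched span between two
    merged partial alignments.  Integer positions available between the
    flanks are used first, ends inward (middle omitted when too few
    residues).  When the span overflows the available integers — the
    ultralong-CDR3 case — the overflow receives insertion codes by the
    IMGT rule: 111.1, 111.2, ... then ..., 112.2, 112.1, added
    alternately starting at 112.1 (so position 112's side gets the extra
    residue when the overflow is odd).

    The returned labels are strictly between prev and nxt under the IMGT
    comparator and strictly increasing.
    """
    if n <= 0:
        return []
    lo = prev.position + 1
    hi = nxt.position - 1
    if prev.insert and prev.position != 112:
        # continuing after an insertion code: integer lo is still fine
        pass
    available = max(0, hi - lo + 1)
    if n <= available:
        labels = short_loop_labels(lo, hi, n)
    elif lo <= 111 and hi >= 112:
        # overflow with the CDR3 apex in range: insertion codes at 111/112
        extra = n - available
        n112 = (extra + 1) // 2
        n111 = extra - n112
        labels = (
            [ImgtLabel(p) for p in range(lo, 112)]
            + [ImgtLabel(111, i + 1) for i in range(n111)]
            + [ImgtLabel(112, n112 - i) for i in range(n112)]
            + [ImgtLabel(p) for p in range(112, hi + 1)]
        )
    else:
        # overflow outside the CDR3 apex: ascending insertions on the
        # last integer position (or on prev itself when none is free)
        labels = [ImgtLabel(p) for p in range(lo, hi + 1)]
        base = hi if available else prev.position
        start = prev.insert + 1 if not available else 1
        if base == 112:
            # cannot insert after 112 (codes there sort backwards);
            # fall back to the next position's predecessor
            base = nxt.position - 1 if nxt.position - 1 > 112 else 113
            start = 1
        labels += [ImgtLabel(base, start + i) for i in range(n - available)]
    assert len(labels) == n
    return labels
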