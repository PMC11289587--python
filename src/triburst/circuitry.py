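"""Multilevel synchrony: circuitry bursts (CB) and intermediate circuitry
bursts (ICB) from per-compartment network-burst lists.

A CB is a maximal interval during which all three compartments have an
ongoing network burst simultaneously (full three-way temporal
intersection, zero assumed inter-compartment delay).  An ICB is a maximal
pairwise intersection between exactly two compartments that does not touch
any CB — candidates overlapping a CB are excluded entirely so circuit-wide
events are not double counted as pairwise ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .bursts import NetworkBurst

__all__ = [
    "CircuitryEvent",
    "intersect_interval_lists",
    "detect_cb",
    "detect_icb",
    "classify_synchrony",
    "detect_circuitry",
]

Interval = tuple[float, float]


@dataclass
class CircuitryEvent:
    """A CB (three compartments) or ICB (two compartments) interval."""

    kind: str  # "CB" or "ICB"
    compartments: frozenset[str]
    start: float
    end: float
    member_nbs: dict[str, int] = field(default_factory=dict)  # compartment -> NB index

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def pair_label(self) -> str:
        return "".join(sorted(self.compartments))

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "compartments": sorted(self.compartments),
            "start": self.start,
            "end": self.end,
            "member_nbs": dict(self.member_nbs),
        }


def _as_intervals(nbs: list) -> list[Interval]:
    out = []
    for nb in nbs:
        if isinstance(nb, NetworkBurst):
            out.append((nb.start, nb.end))
        else:
            out.append((float(nb[0]), float(nb[1])))
    return out


def intersect_interval_lists(a: list[Interval], b: list[Interval]) -> list[tuple[float, float, int, int]]:
    """Pairwise positive-measure intersections of two disjoint ordered lists.

    Returns (start, end, index_in_a, index_in_b) via a linear sweep;
    point contacts (zero measure) are discarded.
    """
    out: list[tuple[float, float, int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            out.append((s, e, i, j))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def detect_cb(
    nbs_by_compartment: dict[str, list],
) -> list[CircuitryEvent]:
    """Maximal intervals where every compartment has an ongoing NB."""
    comps = sorted(nbs_by_compartment)
    if len(comps) < 3:
        raise ValueError("CB detection requires three compartments")
    ivs = {c: _as_intervals(nbs_by_compartment[c]) for c in comps}
    c0, c1, c2 = comps
    ab = intersect_interval_lists(ivs[c0], ivs[c1])
    abc: list[CircuitryEvent] = []
    # intersect the AB segments with C's intervals
    pair_ints = intersect_interval_lists([(s, e) for s, e, _, _ in ab], ivs[c2])
    for s, e, k, j2 in pair_ints:
        _, _, i0, i1 = ab[k]
        abc.append(
            CircuitryEvent(
                kind="CB",
                compartments=frozenset(comps),
                start=s,
                end=e,
                member_nbs={c0: i0, c1: i1, c2: j2},
            )
        )
    return abc


def detect_icb(
    nbs_by_compartment: dict[str, list],
    cbs: list[CircuitryEvent] | None = None,
    trim_instead_of_exclude: bool = False,
) -> list[CircuitryEvent]:
    """Two-compartment intersections not associated with any CB.

    A pairwise candidate overlapping a CB (positive measure) is excluded
    entirely by default; with ``trim_instead_of_exclude`` the CB-covered
    parts are cut out and positive-length remainders kept.
    """
    if cbs is None:
        cbs = detect_cb(nbs_by_compartment)
    cb_ivs = [(cb.start, cb.end) for cb in cbs]
    out: list[CircuitryEvent] = []
    for ca, cb_label in combinations(sorted(nbs_by_compartment), 2):
        a = _as_intervals(nbs_by_compartment[ca])
        b = _as_intervals(nbs_by_compartment[cb_label])
        for s, e, ia, ib in intersect_interval_lists(a, b):
            overlaps = [iv for iv in cb_ivs if min(e, iv[1]) > max(s, iv[0])]
            if overlaps and not trim_instead_of_exclude:
                continue
            segments = [(s, e)]
            if overlaps:
                segments = _subtract(s, e, overlaps)
            for ss, ee in segments:
                out.append(
                    CircuitryEvent(
                        kind="ICB",
                        compartments=frozenset((ca, cb_label)),
                        start=ss,
                        end=ee,
                        member_nbs={ca: ia, cb_label: ib},
                    )
                )
    out.sort(key=lambda ev: (ev.start, ev.pair_label))
    return out


def _subtract(s: float, e: float, holes: list[Interval]) -> list[Interval]:
    """[s, e] minus the union of holes; positive-length pieces only."""
    pieces: list[Interval] = []
    cur = s
    for hs, he in sorted(holes):
        if hs > cur:
            pieces.append((cur, min(hs, e)))
        cur = max(cur, he)
        if cur >= e:
            break
    if cur < e:
        pieces.append((cur, e))
    return [(a, b) for a, b in pieces if b > a]


def classify_synchrony(
    nbs_by_compartment: dict[str, list],
    cbs: list[CircuitryEvent],
    icbs: list[CircuitryEvent],
) -> set[str]:
    """Plate-level labels from one recording's NB/ICB/CB structure.

    ``full_synchrony``: every NB in every compartment overlaps some CB
    (all local activity is part of circuit-wide events).  ``no_icb``: no
    intermediate (two-compartment) events remain.  ``mixed`` otherwise.
    """
    cb_ivs = [(cb.start, cb.end) for cb in cbs]
    full = True
    for nbs in nbs_by_compartment.values():
        for s, e in _as_intervals(nbs):
            if not any(min(e, ce) > max(s, cs) for cs, ce in cb_ivs):
                full = False
                break
        if not full:
            break
    labels: set[str] = set()
    if full and cbs:
        labels.add("full_synchrony")
    if not icbs:
        labels.add("no_icb")
    if not labels:
        labels.add("mixed")
    return labels


def detect_circuitry(
    nbs_by_compartment: dict[str, list],
    trim_instead_of_exclude: bool = False,
) -> tuple[list[CircuitryEvent], list[CircuitryEvent], set[str]]:
    """Convenience wrapper: CBs, ICBs and plate synchrony labels."""
    cbs = detect_cb(nbs_by_compartment)
    icbs = detect_icb(nbs_by_compartment, cbs, trim_instead_of_exclude)
    labels = classify_synchrony(nbs_by_compartment, cbs, icbs)
    return cbs, icbs, labels
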