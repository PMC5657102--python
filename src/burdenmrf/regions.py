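"""Four-gamete-compatible interval partitioning of the site axis.

Under an infinite-sites, no-recombination model two sites are incompatible
iff all four joint carrier configurations (0,0), (0,1), (1,0), (1,1) occur
in the sample.  The partition pipeline mirrors a maximal-K-cover scan:
greedy left-to-right and right-to-left scans produce two K-interval sets,
their index-wise intersections form cores, candidate maximal compatible
intervals are grown around each core, and a dynamic program selects the
disjoint chain of candidates covering the most sites.  Uncovered sites are
appended as singletons so the final interval set is a partition.

Compatibility within an interval is *pairwise-all* (every pair of member
sites must pass the four-gamete test), which is stricter than adjacent-only
and makes the greedy scans well defined.  Coordinates are 0-based,
half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "IntervalSet",
    "four_gamete_compatible",
    "scan_left_right",
    "scan_right_left",
    "merge_cores",
    "uber_scan_and_cover",
    "partition_sites",
]


@dataclass
class IntervalSet:
    """List of [start, end) site-index intervals with scan provenance."""

    intervals: list[tuple[int, int]]
    provenance: str = "final"  # lr | rl | core | final

    def __post_init__(self) -> None:
        self.intervals = [(int(a), int(b)) for a, b in self.intervals]
        for a, b in self.intervals:
            if a >= b:
                raise ValueError(f"empty interval [{a}, {b})")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def covered(self) -> int:
        return sum(b - a for a, b in self.intervals)


def four_gamete_compatible(col_a: np.ndarray, col_b: np.ndarray) -> bool:
    """True unless all four joint carrier configurations occur."""
    a = np.asarray(col_a).astype(bool)
    b = np.asarray(col_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("columns must have equal length")
    n11 = np.any(a & b)
    n10 = np.any(a & ~b)
    n01 = np.any(~a & b)
    n00 = np.any(~a & ~b)
    return not (n11 and n10 and n01 and n00)


def _compatible_with_all(carriers: np.ndarray, members: list[int],
                         s: int) -> bool:
    """Pairwise-all test of site ``s`` against every member column."""
    b = carriers[:, s]
    sub = carriers[:, members]
    n11 = (sub & b[:, None]).any(axis=0)
    n10 = (sub & ~b[:, None]).any(axis=0)
    n01 = (~sub & b[:, None]).any(axis=0)
    n00 = (~sub & ~b[:, None]).any(axis=0)
    return not np.any(n11 & n10 & n01 & n00)


def _case_carriers(carriers: np.ndarray, labels: np.ndarray | None,
                   all_samples: bool) -> np.ndarray:
    carriers = np.asarray(carriers).astype(bool)
    if all_samples or labels is None:
        return carriers
    labels = np.asarray(labels).astype(bool)
    return carriers[labels]


def scan_left_right(carriers: np.ndarray,
                    labels: np.ndarray | None = None,
                    all_samples: bool = False) -> IntervalSet:
    """Greedy maximal compatible intervals scanning left to right.

    The scan runs on the case half of the matrix unless ``all_samples``;
    an interval extends until the first site incompatible with any site
    already inside, then restarts from that site.
    """
    g = _case_carriers(carriers, labels, all_samples)
    m = g.shape[1]
    out, start, members = [], 0, [0]
    for s in range(1, m):
        if _compatible_with_all(g, members, s):
            members.append(s)
        else:
            out.append((start, s))
            start, members = s, [s]
    out.append((start, m))
    return IntervalSet(out, provenance="lr")


def scan_right_left(carriers: np.ndarray,
                    labels: np.ndarray | None = None,
                    all_samples: bool = False) -> IntervalSet:
    """Mirror of :func:`scan_left_right` (scan from the right edge)."""
    g = _case_carriers(carriers, labels, all_samples)
    m = g.shape[1]
    rev = scan_left_right(g[:, ::-1], None, all_samples=True)
    out = sorted((m - b, m - a) for a, b in rev.intervals)
    return IntervalSet(out, provenance="rl")


def merge_cores(i_lr: IntervalSet, i_rl: IntervalSet,
                strict: bool = True) -> IntervalSet:
    """Index-wise intersections of the two scans; empty cores are dropped.

    With pairwise-all compatibility the two greedy scans can occasionally
    disagree on K.  ``strict=True`` raises then; ``strict=False`` falls back
    to pairing each left-to-right interval with the right-to-left interval
    it overlaps most.
    """
    if len(i_lr) == 0 or len(i_rl) == 0:
        raise ValueError("scan interval sets must be nonempty")
    if len(i_lr) != len(i_rl):
        if strict:
            raise ValueError("left-right and right-left scans disagree on K")
        pairs = []
        for a1, b1 in i_lr:
            best = max(i_rl, key=lambda ab: min(b1, ab[1]) - max(a1, ab[0]))
            pairs.append(((a1, b1), best))
    else:
        pairs = list(zip(i_lr, i_rl))
    cores = []
    for (a1, b1), (a2, b2) in pairs:
        lo, hi = max(a1, a2), min(b1, b2)
        if lo < hi:
            cores.append((lo, hi))
    if not cores:  # degenerate fallback: every site its own core
        m = max(b for _, b in i_lr)
        cores = [(s, s + 1) for s in range(m)]
    return IntervalSet(cores, provenance="core")


def _grow_maximal(g: np.ndarray, start: int, end: int) -> tuple[int, int]:
    """Extend [start, end) as far as possible on both sides (left first)."""
    m = g.shape[1]
    members = list(range(start, end))
    while start > 0 and _compatible_with_all(g, members, start - 1):
        start -= 1
        members.append(start)
    while end < m and _compatible_with_all(g, members, end):
        members.append(end)
        end += 1
    return start, end


def _max_reach(g: np.ndarray) -> np.ndarray:
    """reach[a] = largest b such that [a, b) is pairwise-all compatible.

    Pairwise-all compatibility is closed under taking sub-intervals and
    extendable one site at a time, so the compatible intervals starting at
    ``a`` are exactly [a, x) for x <= reach[a].
    """
    m = g.shape[1]
    reach = np.empty(m, dtype=int)
    for a in range(m):
        members = [a]
        b = a + 1
        while b < m and _compatible_with_all(g, members, b):
            members.append(b)
            b += 1
        reach[a] = b
    return reach


def uber_scan_and_cover(carriers: np.ndarray, cores: IntervalSet,
                        labels: np.ndarray | None = None,
                        all_samples: bool = False) -> IntervalSet:
    """Candidate maximal intervals around each core + exact coverage DP.

    Every core is grown to the maximal compatible candidates containing it
    (the K+m candidate list).  A dynamic program over the per-start maximal
    reach then selects the disjoint chain of compatible intervals covering
    the most sites — candidates may enter truncated, which is what makes
    the cover provably optimal (compatibility is sub-interval closed).
    Uncovered sites become singletons so the result partitions [0, M).
    """
    g = _case_carriers(carriers, labels, all_samples)
    m = g.shape[1]
    # candidate list retained for provenance: grown around each core
    cands: set[tuple[int, int]] = set()
    for a, b in cores:
        cands.add(_grow_maximal(g, a, b))
    reach = _max_reach(g)

    # best[e] = max sites covered by multi-site intervals within [0, e)
    best = np.zeros(m + 1, dtype=int)
    take: list[tuple[int, int] | None] = [None] * (m + 1)
    for e in range(1, m + 1):
        best[e] = best[e - 1]
        take[e] = None
        for a in range(e - 2, -1, -1):  # only multi-site intervals count
            if reach[a] < e:  # reach is monotone: smaller a cannot work
                break
            cand = best[a] + (e - a)
            if cand >= best[e]:  # ties prefer the longer (earlier) start
                best[e] = cand
                take[e] = (a, e)
    chosen = []
    e = m
    while e > 0:
        if take[e] is None:
            e -= 1
        else:
            a, b = take[e]
            chosen.append((a, b))
            e = a
    chosen.sort()

    final, cursor = [], 0
    for a, b in chosen:
        final.extend((s, s + 1) for s in range(cursor, a))
        final.append((a, b))
        cursor = b
    final.extend((s, s + 1) for s in range(cursor, m))
    return IntervalSet(final, provenance="final")


def partition_sites(carriers: np.ndarray,
                    labels: np.ndarray | None = None,
                    all_samples: bool = False) -> IntervalSet:
    """Full pipeline: scans -> cores -> maximal cover partition."""
    i_lr = scan_left_right(carriers, labels, all_samples)
    i_rl = scan_right_left(carriers, labels, all_samples)
    cores = merge_cores(i_lr, i_rl, strict=False)
    return uber_scan_and_cover(carriers, cores, labels, all_samples)
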