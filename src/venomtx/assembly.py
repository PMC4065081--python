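"""Greedy exact-overlap read assembly.

Reads are merged only on perfect identity: either one read is a verbatim
substring of another (containment), or the suffix of one read equals the
prefix of another over at least ``min_overlap`` nucleotides (default 50).
This mirrors high-stringency EST assembly; approximate overlaps are
deliberately rejected.

The merge schedule is greedy longest-overlap-first with a deterministic
tie-break (lexicographically smaller merged sequence, then smaller unit id),
so a fixed input yields a fixed output.  Reverse-complement overlaps are
considered; each contig is reported in the orientation of its first-merged
read.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .sequences import NucSequence, reverse_complement

__all__ = ["AssemblyParams", "Contig", "assemble"]


@dataclass(frozen=True)
class AssemblyParams:
    min_overlap: int = 50
    identity: float = 1.0

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self.identity != 1.0:
            raise ValueError("only exact assembly (identity = 1.0) is implemented")


@dataclass
class Contig:
    contig_id: str
    bases: str
    member_read_ids: list[str] = field(default_factory=list)

    @property
    def read_count(self) -> int:
        return len(self.member_read_ids)


class _Node:
    """A live assembly unit: a sequence plus its member reads."""

    __slots__ = ("uid", "bases", "members", "alive")

    def __init__(self, uid: int, bases: str, members: list[str]):
        self.uid = uid
        self.bases = bases
        self.members = members
        self.alive = True


def _best_overlap(a: str, b: str, min_ov: int) -> int:
    """Longest L >= min_ov with suffix(a, L) == prefix(b, L); 0 if none.

    Seeded on occurrences of b's leading ``min_ov``-mer inside a, scanning
    left to right so the first verified hit is the longest overlap.
    """
    if len(b) < min_ov:
        return 0
    key = b[:min_ov]
    start = max(0, len(a) - len(b))  # the overlap cannot exceed len(b)
    p = a.find(key, start)
    while p != -1:
        L = len(a) - p
        if L >= min_ov and a[p:] == b[:L]:
            return L
        p = a.find(key, p + 1)
    return 0


def _pair_candidates(a: "_Node", b: "_Node", min_ov: int):
    """Yield (overlap_len, merged_bases) for all exact joins of two nodes,
    considering both orientations of ``b``.

    Containment yields the containing sequence with overlap = contained
    length (counts as full-length overlap)."""
    for b_bases in (b.bases, reverse_complement(b.bases)):
        if len(b_bases) <= len(a.bases):
            if b_bases in a.bases:
                yield len(b_bases), a.bases
        elif a.bases in b_bases:
            yield len(a.bases), b_bases
        L = _best_overlap(a.bases, b_bases, min_ov)
        if L and L < min(len(a.bases), len(b_bases)):
            yield L, a.bases + b_bases[L:]
        L = _best_overlap(b_bases, a.bases, min_ov)
        if L and L < min(len(a.bases), len(b_bases)):
            yield L, b_bases + a.bases[L:]


def _best_join(a: "_Node", b: "_Node", min_ov: int) -> tuple[int, str] | None:
    best = None
    for L, merged in _pair_candidates(a, b, min_ov):
        key = (-L, merged)
        if best is None or key < best:
            best = key
    return best


def assemble(
    reads: Sequence[NucSequence],
    params: AssemblyParams = AssemblyParams(),
) -> tuple[list[Contig], list[Contig]]:
    """Assemble reads into contigs; returns ``(contigs, singletons)``.

    Contigs carry >= 2 member reads; singletons are unmerged reads wrapped in
    single-member contigs.  Output is sorted by read count descending, then
    sequence length descending, then sequence.  Every input read id appears
    in exactly one output record, and every member read (or its reverse
    complement) occurs verbatim in its contig.  The result is a fixed point:
    no two output sequences share an exact overlap of ``min_overlap`` or
    more.
    """
    if not reads:
        raise ValueError("reads must be non-empty")
    min_ov = params.min_overlap
    # collapse exact duplicates (same bases up to reverse complement) first:
    # these are containment merges of maximal overlap, so the greedy
    # longest-first schedule is unchanged.
    groups: dict[str, list[NucSequence]] = {}
    for r in sorted(reads, key=lambda r: r.id):
        canon = min(r.bases, reverse_complement(r.bases))
        groups.setdefault(canon, []).append(r)
    nodes: dict[int, _Node] = {}
    for uid, grp in enumerate(groups[k] for k in sorted(groups)):
        nodes[uid] = _Node(uid, grp[0].bases, [r.id for r in grp])
    next_uid = len(nodes)

    # prefix index: leading min_ov-mer of each orientation -> node uids
    index: dict[str, set[int]] = {}

    def _index_node(node: _Node) -> None:
        for bases in (node.bases, reverse_complement(node.bases)):
            if len(bases) >= min_ov:
                index.setdefault(bases[:min_ov], set()).add(node.uid)

    for node in nodes.values():
        _index_node(node)

    def _candidates_for(node: _Node) -> set[int]:
        """Nodes whose prefix (either orientation) occurs inside ``node``:
        suffix-prefix and containment partners in every orientation, by the
        reverse-complement symmetry of overlap."""
        out: set[int] = set()
        for bases in (node.bases, reverse_complement(node.bases)):
            for i in range(0, len(bases) - min_ov + 1):
                hit = index.get(bases[i : i + min_ov])
                if hit:
                    out |= hit
        out.discard(node.uid)
        return out

    heap: list[tuple[int, str, int, int]] = []

    def _push_overlaps(node: _Node) -> None:
        for uid in _candidates_for(node):
            other = nodes.get(uid)
            if other is None or not other.alive:
                continue
            best = _best_join(node, other, min_ov)
            if best is not None:
                a, b = sorted((node.uid, uid))
                heapq.heappush(heap, (best[0], best[1], a, b))

    for node in list(nodes.values()):
        _push_overlaps(node)

    def _drain() -> None:
        nonlocal next_uid
        while heap:
            negL, merged, ua, ub = heapq.heappop(heap)
            a, b = nodes.get(ua), nodes.get(ub)
            if a is None or b is None or not (a.alive and b.alive):
                continue
            best = _best_join(a, b, min_ov)  # stale-entry check
            if best is None:
                continue
            if best != (negL, merged):
                heapq.heappush(heap, (best[0], best[1], ua, ub))
                continue
            a.alive = b.alive = False
            node = _Node(next_uid, merged, a.members + b.members)
            next_uid += 1
            nodes[node.uid] = node
            _index_node(node)
            _push_overlaps(node)

    _drain()
    # completeness sweep: the prefix index can miss a freshly merged contig
    # that is itself contained in an older one; verify all live pairs until
    # no exact overlap >= min_ov remains (idempotence guarantee)
    while True:
        live = [n for n in nodes.values() if n.alive]
        found = False
        for x in range(len(live)):
            for y in range(x + 1, len(live)):
                best = _best_join(live[x], live[y], min_ov)
                if best is not None:
                    a, b = sorted((live[x].uid, live[y].uid))
                    heapq.heappush(heap, (best[0], best[1], a, b))
                    found = True
        if not found:
            break
        _drain()

    live = sorted(
        (n for n in nodes.values() if n.alive),
        key=lambda n: (-len(n.members), -len(n.bases), n.bases),
    )
    contigs: list[Contig] = []
    singletons: list[Contig] = []
    for n in live:
        if len(n.members) > 1:
            cid = f"contig{len(contigs) + 1:05d}"
            contigs.append(Contig(cid, n.bases, sorted(n.members)))
        else:
            singletons.append(Contig(n.members[0], n.bases, list(n.members)))
    return contigs, singletons
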