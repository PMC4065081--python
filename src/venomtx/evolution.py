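"""Molecular-evolution analysis: original Nei-Gojobori dN/dS with
Jukes-Cantor correction, Fisher's exact test for positive selection,
selection-zone classification, and neighbor-joining trees with bootstrap.

The Nei-Gojobori (1986) method counts synonymous (S) and nonsynonymous (N)
*sites* per codon as the fraction of the three possible changes at each
position that preserve the encoded amino acid (changes to stop codons count
as nonsynonymous), averaged between the two sequences; *differences* between
codons differing at several positions are averaged with equal weight over
all minimal substitution pathways, excluding pathways that pass through a
stop codon.  Proportions p = d/sites are corrected to distances with the
Jukes-Cantor formula d = -(3/4) ln(1 - (4/3) p).

Selection zones follow the conventional thresholds: dN/dS > 1 positive
(diversifying) selection, 0.27 < dN/dS <= 1 lack of constraints,
dN/dS <= 0.27 purifying selection (boundary ratios fall in the lower zone).
"""

from __future__ import annotations

import itertools
import math
import random
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.stats import fisher_exact

from .sequences import translate

__all__ = [
    "NgCounts",
    "DnDsResult",
    "ng_counts",
    "dnds",
    "classify_selection",
    "fisher_positive_selection",
    "TreeNode",
    "nj_tree",
    "tree_distances",
    "bipartitions",
    "p_distance_matrix",
    "bootstrap_support",
]

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"


@dataclass(frozen=True)
class NgCounts:
    """Nei-Gojobori site and difference counts for one aligned pair."""

    N: float  # nonsynonymous sites
    S: float  # synonymous sites
    Nd: float  # nonsynonymous differences
    Sd: float  # synonymous differences
    codons_compared: int


@dataclass(frozen=True)
class DnDsResult:
    pN: float
    pS: float
    Dn: float | None  # None when the Jukes-Cantor correction is undefined
    Ds: float | None
    ratio: float | None  # None when Ds is 0 or either distance undefined


@lru_cache(maxsize=None)
def _syn_fraction(codon: str) -> float:
    """Synonymous sites of a codon: per position, the fraction of the three
    alternative bases that preserve the amino acid.  Changes to stop codons
    are nonsynonymous."""
    aa = translate(codon)
    total = 0.0
    for pos in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in _STOPS and translate(alt) == aa:
                syn += 1
        total += syn / 3.0
    return total


@lru_cache(maxsize=None)
def _pathway_diffs(c1: str, c2: str) -> tuple[float, float] | None:
    """(nonsynonymous, synonymous) differences between two sense codons,
    averaged with equal weights over all minimal substitution pathways that
    avoid stop codons.  None when every pathway passes through a stop
    (the codon pair is then skipped: pairwise deletion)."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    valid = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        nd = sd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                ok = False
                break
            if translate(cur) == translate(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            valid.append((nd, sd))
    if not valid:
        return None
    nd = sum(v[0] for v in valid) / len(valid)
    sd = sum(v[1] for v in valid) / len(valid)
    return nd, sd


def ng_counts(cds1: str, cds2: str) -> NgCounts:
    """Site and difference counts over an aligned codon pair of sequences.

    Sequences must have equal length divisible by three.  Codons containing
    gaps or N in either sequence, stop codons, and codon pairs whose every
    substitution pathway passes through a stop are skipped pairwise.
    """
    if len(cds1) != len(cds2):
        raise ValueError("aligned sequences must have equal length")
    if len(cds1) % 3 != 0:
        raise ValueError("aligned length must be a multiple of 3")
    c1u, c2u = cds1.upper(), cds2.upper()
    N = S = Nd = Sd = 0.0
    compared = 0
    for i in range(0, len(c1u), 3):
        a, b = c1u[i : i + 3], c2u[i : i + 3]
        if any(ch not in _BASES for ch in a + b):
            continue  # gap or N: pairwise deletion
        if a in _STOPS or b in _STOPS:
            continue
        diffs = _pathway_diffs(a, b)
        if diffs is None:
            continue
        compared += 1
        S += (_syn_fraction(a) + _syn_fraction(b)) / 2.0
        N += 3.0 - (_syn_fraction(a) + _syn_fraction(b)) / 2.0
        Nd += diffs[0]
        Sd += diffs[1]
    return NgCounts(N=N, S=S, Nd=Nd, Sd=Sd, codons_compared=compared)


def _jukes_cantor(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def dnds(counts: NgCounts) -> DnDsResult:
    """Jukes-Cantor-corrected Dn, Ds and their ratio from NG counts."""
    if counts.N <= 0 or counts.S <= 0:
        raise ValueError("need N > 0 and S > 0")
    pn, ps = counts.Nd / counts.N, counts.Sd / counts.S
    dn, ds = _jukes_cantor(pn), _jukes_cantor(ps)
    ratio = None
    if dn is not None and ds is not None and ds > 0:
        ratio = dn / ds
    return DnDsResult(pN=pn, pS=ps, Dn=dn, Ds=ds, ratio=ratio)


def classify_selection(result: DnDsResult) -> str:
    """Selection zone from the Dn/Ds ratio; boundary ratios (exactly 1 or
    0.27) are assigned to the lower zone; undefined ratios are 'undefined'."""
    if result.ratio is None:
        return "undefined"
    if result.ratio > 1.0:
        return "positive"
    if result.ratio > 0.27:
        return "lack_of_constraints"
    return "purifying"


def fisher_positive_selection(counts: NgCounts) -> float:
    """One-sided Fisher's exact test that nonsynonymous differences are
    enriched relative to synonymous ones.

    The 2x2 table {Nd, N-Nd; Sd, S-Sd} uses nearest-integer rounding of the
    fractional NG counts (ties to even).  Degenerate margins give p = 1.
    """
    nd, n = round(counts.Nd), round(counts.N)
    sd, s = round(counts.Sd), round(counts.S)
    table = [[nd, max(n - nd, 0)], [sd, max(s - sd, 0)]]
    if nd + sd == 0 or n + s == 0:
        return 1.0
    return float(fisher_exact(table, alternative="greater")[1])


# ---------------------------------------------------------------------------
# neighbor joining


@dataclass
class TreeNode:
    """A node of an (unrooted, stored rooted at the final join) NJ tree."""

    name: str | None = None
    length: float = 0.0  # branch length to parent (may be negative internally)
    support: float | None = None  # bootstrap support of the edge above, in %
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [leaf for ch in self.children for leaf in ch.leaves()]

    def newick(self, with_support: bool = True) -> str:
        return self._newick(with_support) + ";"

    def _newick(self, with_support: bool) -> str:
        length = max(self.length, 0.0)  # negatives clamped on output
        if self.is_leaf:
            return f"{self.name}:{length:.6f}"
        inner = ",".join(ch._newick(with_support) for ch in self.children)
        label = ""
        if with_support and self.support is not None:
            label = f"{self.support:.0f}"
        return f"({inner}){label}:{length:.6f}"


def nj_tree(matrix: np.ndarray | Sequence[Sequence[float]], taxa: Sequence[str]) -> TreeNode:
    """Saitou-Nei neighbor joining with a deterministic tie-break (the
    smallest row-index pair attaining the minimal Q value).

    Requires a symmetric matrix with zero diagonal over >= 3 taxa.  Branch
    lengths may come out negative on noisy input; they are preserved
    internally and clamped to zero when serialised.
    """
    d = np.asarray(matrix, dtype=float).copy()
    n = d.shape[0]
    if n != d.shape[1] or n != len(taxa):
        raise ValueError("matrix shape must match the number of taxa")
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if not np.allclose(d, d.T, atol=1e-9) or not np.allclose(np.diag(d), 0.0, atol=1e-9):
        raise ValueError("matrix must be symmetric with zero diagonal")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in taxa]
    active = list(range(n))
    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest Q; ties resolved by smallest (i, j) row-index pair
        qmin = q.min()
        ii, jj = min(
            (int(i), int(j))
            for i, j in zip(*np.where(np.isclose(q, qmin, rtol=0, atol=1e-12)))
            if i < j
        )
        a, b = active[ii], active[jj]
        dij = d[a, b]
        la = 0.5 * dij + (r[ii] - r[jj]) / (2.0 * (m - 2))
        lb = dij - la
        nodes[a].length = la
        nodes[b].length = lb
        parent = TreeNode(children=[nodes[a], nodes[b]])
        # distances from the new node to the remaining taxa
        new_row = np.zeros(d.shape[0] + 1)
        for k in active:
            if k in (a, b):
                continue
            new_row[k] = 0.5 * (d[a, k] + d[b, k] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (a, b)] + [len(nodes) - 1]
    a, b = active
    # final join: attach one remaining node to the other (unrooted tree
    # serialised with a trifurcating or bifurcating root)
    nodes[a].length = 0.0
    nodes[b].length = d[a, b]
    if nodes[a].is_leaf:
        root = TreeNode(children=[nodes[a], nodes[b]])
    else:
        root = nodes[a]
        root.children.append(nodes[b])
    return root


def tree_distances(root: TreeNode) -> tuple[list[str], np.ndarray]:
    """Leaf-to-leaf path-length matrix induced by the tree."""
    leaves = root.leaves()
    names = [leaf.name for leaf in leaves]
    idx = {id(leaf): i for i, leaf in enumerate(leaves)}
    n = len(leaves)
    dist = np.zeros((n, n))

    def walk(node: TreeNode) -> dict[int, float]:
        if node.is_leaf:
            return {idx[id(node)]: 0.0}
        below: list[dict[int, float]] = []
        for ch in node.children:
            sub = {k: v + ch.length for k, v in walk(ch).items()}
            below.append(sub)
        for x in range(len(below)):
            for y in range(x + 1, len(below)):
                for i, di in below[x].items():
                    for j, dj in below[y].items():
                        dist[i, j] = dist[j, i] = di + dj
        merged: dict[int, float] = {}
        for sub in below:
            merged.update(sub)
        return merged

    walk(root)
    return names, dist


def bipartitions(root: TreeNode) -> set[frozenset[str]]:
    """Non-trivial leaf bipartitions (each given as the smaller side, ties by
    sorted order) of the unrooted tree."""
    all_leaves = frozenset(leaf.name for leaf in root.leaves())
    out: set[frozenset[str]] = set()

    def walk(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(walk(ch) for ch in node.children))
        if node is not root and 1 < len(below) < len(all_leaves) - 1:
            other = all_leaves - below
            side = min(below, other, key=lambda s: (len(s), tuple(sorted(s))))
            out.add(side)
        return below

    walk(root)
    return out


def p_distance_matrix(seqs: Sequence[str], columns: Sequence[int] | None = None) -> np.ndarray:
    """Pairwise p-distances over alignment columns (gap/N pairs skipped)."""
    arr = np.array([list(s.upper()) for s in seqs])
    if columns is not None:
        arr = arr[:, list(columns)]
    n = arr.shape[0]
    valid = np.isin(arr, list("ACGT"))
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = valid[i] & valid[j]
            total = int(ok.sum())
            if total == 0:
                continue
            diff = int((arr[i][ok] != arr[j][ok]).sum())
            d[i, j] = d[j, i] = diff / total
    return d


def bootstrap_support(
    aligned: Sequence[str],
    taxa: Sequence[str],
    replicates: int = 500,
    seed: int = 0,
) -> TreeNode:
    """NJ tree of an alignment with bootstrap supports on internal edges.

    Columns are resampled with replacement ``replicates`` times (seeded);
    each internal edge of the reference tree gets the percentage of
    replicate trees containing the same leaf bipartition.
    """
    if len(aligned) != len(taxa):
        raise ValueError("need one taxon label per sequence")
    L = len(aligned[0])
    if any(len(s) != L for s in aligned):
        raise ValueError("sequences must be aligned to equal length")
    ref = nj_tree(p_distance_matrix(aligned), taxa)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in bipartitions(ref)}
    rng = random.Random(seed)
    for _ in range(replicates):
        cols = [rng.randrange(L) for _ in range(L)]
        rep = nj_tree(p_distance_matrix(aligned, cols), taxa)
        for bp in bipartitions(rep):
            if bp in counts:
                counts[bp] += 1

    all_leaves = frozenset(taxa)

    def annotate(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(annotate(ch) for ch in node.children))
        if node is not ref and 1 < len(below) < len(all_leaves) - 1:
            side = min(below, all_leaves - below, key=lambda s: (len(s), tuple(sorted(s))))
            node.support = 100.0 * counts.get(side, 0) / replicates
        return below

    annotate(ref)
    return ref
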