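"""Nei-Gojobori counting, selection classification, Fisher's exact test and
neighbor joining."""

import itertools
import math
import random

import numpy as np
import pytest
from Bio.Seq import Seq

from venomtx.evolution import (
    DnDsResult,
    NgCounts,
    bipartitions,
    bootstrap_support,
    classify_selection,
    dnds,
    fisher_positive_selection,
    ng_counts,
    nj_tree,
    p_distance_matrix,
    tree_distances,
)

STOPS = {"TAA", "TAG", "TGA"}
SENSE = [
    "".join(c) for c in itertools.product("TCAG", repeat=3) if "".join(c) not in STOPS
]
_AA = {c: str(Seq(c).translate()) for c in ("".join(p) for p in itertools.product("TCAG", repeat=3))}


def oracle_pair(c1: str, c2: str):
    """Independent Nei-Gojobori oracle for one codon pair: per-position
    synonymous site fractions (changes to stops excluded from the synonymous
    tally) and difference counts averaged over stop-free minimal pathways."""

    def sites(codon):
        s = 0.0
        for i in range(3):
            for b in "TCAG":
                if b != codon[i]:
                    alt = codon[:i] + b + codon[i + 1 :]
                    if alt not in STOPS and _AA[alt] == _AA[codon]:
                        s += 1 / 3
        return s

    diff = [i for i in range(3) if c1[i] != c2[i]]
    paths = []

    def walk(cur, remaining, nd, sd):
        if not remaining:
            paths.append((nd, sd))
            return
        for p in remaining:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if nxt in STOPS:
                continue
            syn = _AA[cur] == _AA[nxt]
            walk(nxt, [q for q in remaining if q != p], nd + (not syn), sd + syn)

    walk(c1, diff, 0, 0)
    if not paths:
        return None
    nd = sum(p[0] for p in paths) / len(paths)
    sd = sum(p[1] for p in paths) / len(paths)
    return (sites(c1) + sites(c2)) / 2, nd, sd


def test_worked_pair_ttt_ctt():
    c = ng_counts("TTT", "CTT")
    assert c.S == pytest.approx(2 / 3, abs=1e-12)
    assert c.N == pytest.approx(7 / 3, abs=1e-12)
    assert c.Nd == 1 and c.Sd == 0
    r = dnds(c)
    assert r.pN == pytest.approx(3 / 7, abs=1e-12)
    assert r.Dn == pytest.approx(-0.75 * math.log(3 / 7), abs=1e-9)
    assert r.Ds == pytest.approx(0.0, abs=1e-12)
    assert r.ratio is None


def test_identical_cds_zero_differences():
    cds = "ATGAAATGCCTG"
    c = ng_counts(cds, cds)
    assert c.Nd == 0 and c.Sd == 0
    assert c.N + c.S == pytest.approx(3 * c.codons_compared, abs=1e-9)


def test_two_difference_codon_averages_orderings():
    s, nd, sd = oracle_pair("TTT", "GTA")
    c = ng_counts("TTT", "GTA")
    assert c.Nd == pytest.approx(nd, abs=1e-12)
    assert c.Sd == pytest.approx(sd, abs=1e-12)
    assert (c.N, c.S) == (pytest.approx(3 - s, abs=1e-12), pytest.approx(s, abs=1e-12))


def test_gap_and_n_codons_are_skipped_pairwise():
    c = ng_counts("ATG---TGC", "ATGAAATGC")
    assert c.codons_compared == 2
    c2 = ng_counts("ATGANATGC", "ATGAAATGC")
    assert c2.codons_compared == 2
    with pytest.raises(ValueError):
        ng_counts("ATGA", "ATGA")
    with pytest.raises(ValueError):
        ng_counts("ATG", "ATGATG")


def test_site_conservation_on_random_codon_pairs(rng):
    for _ in range(500):
        n = rng.randint(1, 20)
        a = "".join(rng.choice(SENSE) for _ in range(n))
        b = "".join(rng.choice(SENSE) for _ in range(n))
        c = ng_counts(a, b)
        assert c.N + c.S == pytest.approx(3 * c.codons_compared, abs=1e-9)


def test_dnds_symmetry(rng):
    for _ in range(50):
        a = "".join(rng.choice(SENSE) for _ in range(12))
        b = "".join(rng.choice(SENSE) for _ in range(12))
        ca, cb = ng_counts(a, b), ng_counts(b, a)
        assert ca.Nd == pytest.approx(cb.Nd, abs=1e-12)
        assert ca.Sd == pytest.approx(cb.Sd, abs=1e-12)
        assert ca.N == pytest.approx(cb.N, abs=1e-12)


def test_jukes_cantor_small_p_limit():
    """As pN -> 0 the correction approaches identity: Dn/pN -> 1."""
    for p in (1e-3, 1e-5, 1e-7):
        counts = NgCounts(N=1000.0, S=500.0, Nd=1000.0 * p, Sd=0.0, codons_compared=500)
        r = dnds(counts)
        assert r.Dn / p == pytest.approx(1.0, rel=1e-2 if p > 1e-4 else 1e-4)


def test_dnds_undefined_beyond_three_quarters():
    counts = NgCounts(N=10.0, S=10.0, Nd=8.0, Sd=1.0, codons_compared=7)
    r = dnds(counts)
    assert r.Dn is None and r.ratio is None
    with pytest.raises(ValueError):
        dnds(NgCounts(N=0.0, S=1.0, Nd=0.0, Sd=0.0, codons_compared=0))


@pytest.mark.parametrize(
    "dn,ds,zone",
    [
        (0.5, 0.25, "positive"),
        (0.25, 0.5, "lack_of_constraints"),
        (0.027, 0.27, "purifying"),
        (0.27, 1.0, "purifying"),  # exactly 0.27: assigned to the lower zone
        (0.5, 0.5, "lack_of_constraints"),  # exactly 1: lower zone
    ],
)
def test_selection_zones(dn, ds, zone):
    res = DnDsResult(pN=0.0, pS=0.0, Dn=dn, Ds=ds, ratio=dn / ds)
    assert classify_selection(res) == zone


def test_selection_undefined():
    res = DnDsResult(pN=0.0, pS=0.0, Dn=0.0, Ds=0.0, ratio=None)
    assert classify_selection(res) == "undefined"


# ---------------------------------------------------------------------------
# Fisher's exact test


def _hypergeom_tail(table):
    """P(X >= a) for the 2x2 table under fixed margins, by enumeration."""
    a, b = table[0]
    c, d = table[1]
    row1, col1, n = a + b, a + c, a + b + c + d
    total = 0.0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        total_x = (
            math.comb(col1, x) * math.comb(n - col1, row1 - x) / math.comb(n, row1)
        )
        if x >= a:
            total += total_x
    return total


def test_fisher_matches_hypergeometric_enumeration():
    counts = NgCounts(N=10.0, S=10.0, Nd=8.0, Sd=1.0, codons_compared=7)
    p = fisher_positive_selection(counts)
    assert p == pytest.approx(_hypergeom_tail([[8, 2], [1, 9]]), abs=1e-12)


def test_fisher_degenerate_and_bounds(rng):
    assert fisher_positive_selection(NgCounts(10.0, 5.0, 0.0, 0.0, 5)) == 1.0
    for _ in range(100):
        n, s = rng.uniform(3, 60), rng.uniform(3, 60)
        nd, sd = rng.uniform(0, n), rng.uniform(0, s)
        p = fisher_positive_selection(NgCounts(n, s, nd, sd, 10))
        assert 0.0 <= p <= 1.0


# ---------------------------------------------------------------------------
# neighbor joining


def test_three_taxa_closed_form():
    d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
    tree = nj_tree(d, ["A", "B", "C"])
    names, dm = tree_distances(tree)
    idx = {n: i for i, n in enumerate(names)}
    assert dm[idx["A"], idx["B"]] == pytest.approx(5.0)
    assert dm[idx["A"], idx["C"]] == pytest.approx(9.0)
    assert dm[idx["B"], idx["C"]] == pytest.approx(10.0)


def test_four_taxa_additive_matrix_recovered_exactly():
    d = np.array(
        [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
    )
    tree = nj_tree(d, ["A", "B", "C", "D"])
    assert bipartitions(tree) == {frozenset({"A", "B"})}
    names, dm = tree_distances(tree)
    idx = {n: i for i, n in enumerate(names)}
    for (i, a), (j, b) in itertools.combinations(enumerate("ABCD"), 2):
        assert dm[idx[a], idx[b]] == pytest.approx(d[i, j], abs=1e-9)


def test_nj_input_validation():
    with pytest.raises(ValueError):
        nj_tree(np.zeros((2, 2)), ["A", "B"])
    bad = np.array([[0, 1, 2], [1, 0, 3], [9, 3, 0]], float)
    with pytest.raises(ValueError):
        nj_tree(bad, ["A", "B", "C"])


def leaf_distance_matrix(rng, n_taxa):
    """Generate a random additive tree and its exact leaf distance matrix."""
    leaves = [f"t{i}" for i in range(n_taxa)]
    # start with each leaf as a cluster carrying distances to its leaves
    clusters = [({leaf: 0.0}, {leaf}) for leaf in leaves]
    cross: dict[tuple[str, str], float] = {}
    bips = set()
    while len(clusters) > 1:
        i, j = sorted(rng.sample(range(len(clusters)), 2))
        (da, sa), (db, sb) = clusters[i], clusters[j]
        la, lb = rng.uniform(0.1, 1.0), rng.uniform(0.1, 1.0)
        da = {k: v + la for k, v in da.items()}
        db = {k: v + lb for k, v in db.items()}
        for x, dx in da.items():
            for y, dy in db.items():
                cross[tuple(sorted((x, y)))] = dx + dy
        merged_set = sa | sb
        if 1 < len(merged_set) < n_taxa - 1:
            bips.add(frozenset(merged_set))
        merged = dict(da)
        merged.update(db)
        clusters = [clusters[k] for k in range(len(clusters)) if k not in (i, j)]
        clusters.append((merged, merged_set))
    d = np.zeros((n_taxa, n_taxa))
    for a in range(n_taxa):
        for b in range(a + 1, n_taxa):
            d[a, b] = d[b, a] = cross[tuple(sorted((leaves[a], leaves[b])))]
    return leaves, d, bips


def _canon(bips, all_taxa):
    out = set()
    for bp in bips:
        other = frozenset(all_taxa) - bp
        out.add(min(bp, other, key=lambda s: (len(s), tuple(sorted(s)))))
    return out


def test_nj_recovers_random_additive_trees():
    rng = random.Random(2024)
    for trial in range(30):
        n = rng.randint(5, 8)
        taxa, d, true_bips = leaf_distance_matrix(rng, n)
        tree = nj_tree(d, taxa)
        assert bipartitions(tree) == _canon(true_bips, taxa), f"trial {trial}"
        names, dm = tree_distances(tree)
        idx = {t: i for i, t in enumerate(names)}
        for a in range(n):
            for b in range(a + 1, n):
                assert dm[idx[taxa[a]], idx[taxa[b]]] == pytest.approx(
                    d[a, b], abs=1e-9
                ), f"trial {trial}"


def test_nj_agrees_with_scikit_bio_on_additive_matrix():
    """Independent cross-check: scikit-bio's NJ induces the same leaf
    distances on an additive matrix."""
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj

    rng = random.Random(7)
    taxa, d, _ = leaf_distance_matrix(rng, 6)
    sk_tree = skbio_nj(DistanceMatrix(d, ids=taxa))
    mine = nj_tree(d, taxa)
    names, dm = tree_distances(mine)
    idx = {t: i for i, t in enumerate(names)}
    for a in range(len(taxa)):
        for b in range(a + 1, len(taxa)):
            sk_dist = sk_tree.find(taxa[a]).distance(sk_tree.find(taxa[b]))
            assert dm[idx[taxa[a]], idx[taxa[b]]] == pytest.approx(sk_dist, abs=1e-6)


def test_bootstrap_conserved_alignment_full_support():
    aligned = ["ATGAAATGCCTGGGG", "ATGAAATGCCTGGGG", "ATGAAATGCCTGGGC", "ATGAAATGCCTCGGC"]
    taxa = ["a", "b", "c", "d"]
    tree = bootstrap_support(aligned, taxa, replicates=50, seed=1)
    supports = [
        n.support
        for n in _iter_nodes(tree)
        if n.support is not None
    ]
    # a perfectly conserved alignment: resampling cannot change the matrix
    conserved = ["ATGAAATGC"] * 4
    t2 = bootstrap_support(conserved, taxa, replicates=50, seed=2)
    assert all(
        n.support == pytest.approx(100.0) for n in _iter_nodes(t2) if n.support is not None
    )
    assert tree.newick().count(";") == 1


def _iter_nodes(node):
    yield node
    for ch in node.children:
        yield from _iter_nodes(ch)


def test_p_distance_skips_gap_and_n_columns():
    d = p_distance_matrix(["ATG-A", "ATGCA", "ATNCA"])
    assert d[0, 1] == 0.0  # gap column skipped
    assert d[1, 2] == 0.0  # N column skipped
    d2 = p_distance_matrix(["ATGA", "ATCA"])
    assert d2[0, 1] == pytest.approx(0.25)
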