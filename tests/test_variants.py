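"""Variant-mechanism classification and expression tiers."""

import pytest

from venomtx.annotate import segment_precursor
from venomtx.simulate import codon_table
from venomtx.variants import (
    assign_tier,
    choose_reference,
    classify_variant_events,
    codon_alignment,
    global_align_nt,
    left_normalize_indel,
)


# ---------------------------------------------------------------------------
# tiers


@pytest.mark.parametrize(
    "count,tier",
    [(1, "rare"), (2, "low"), (10, "low"), (11, "high"), (100, "high")],
)
def test_tier_assignment(count, tier):
    assert assign_tier(count).tier == tier


def test_tier_breakpoints_and_errors():
    """The tier function is total on counts >= 1 and changes exactly at the
    1/2 and 10/11 boundaries."""
    tiers = [assign_tier(c).tier for c in range(1, 30)]
    changes = [c for c in range(2, 30) if tiers[c - 1] != tiers[c - 2]]
    assert changes == [2, 11]
    with pytest.raises(ValueError):
        assign_tier(0)


# ---------------------------------------------------------------------------
# global nt alignment


def test_identical_sequences_align_without_gaps():
    aln = global_align_nt("ATGAAACCC", "ATGAAACCC")
    c = aln.counts()
    assert c.gaps == 0 and c.mismatches == 0


def test_three_nt_deletion_yields_single_gap():
    ref = "ATGAAACCCGGGTTTAGCTGTACCTGA"
    var = ref[:9] + ref[12:]
    aln = global_align_nt(var, ref)
    c = aln.counts()
    assert c.gaps == 3 and c.mismatches == 0
    assert str(aln[0]).count("-") == 3


def _oracle_global(a: str, b: str) -> float:
    """Exhaustive global alignment score, affine gaps (open -12 on the first
    gapped base, -0.5 each additional), match +5 / mismatch -4.  Enumerates
    every monotone alignment path, pruned only by the admissible all-match
    bound (which cannot exclude an optimal path)."""
    best = [float("-inf")]

    def walk(i, j, score, in_gap):
        if score + 5 * min(len(a) - i, len(b) - j) < best[0] - 1e-9:
            return  # even matching everything left cannot beat the best
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, score + (5 if a[i] == b[j] else -4), None)
        if i < len(a):
            walk(i + 1, j, score - (0.5 if in_gap == "a" else 12), "a")
        if j < len(b):
            walk(i, j + 1, score - (0.5 if in_gap == "b" else 12), "b")

    walk(0, 0, 0.0, None)
    return best[0]


def test_global_alignment_matches_bruteforce_on_toy_pair():
    a, b = "ATGAAACCCTTT", "ATGAACCCTTTG"
    aln = global_align_nt(a, b)
    assert aln.score == pytest.approx(_oracle_global(a, b))
    with pytest.raises(ValueError):
        global_align_nt("", "A")


def test_left_normalize_indel():
    #       123456789
    ref = "ATGAAACCC"
    # deleting the third A (pos 6) is equivalent to deleting the first (pos 4)
    assert left_normalize_indel(ref, 6, "A", False) == (4, "A")
    # inserting "A" before pos 7 in the A-run normalises to before pos 4
    assert left_normalize_indel(ref, 7, "A", True) == (4, "A")
    # non-repetitive context does not move
    assert left_normalize_indel(ref, 8, "C", False)[0] == 7  # CCC run start


# ---------------------------------------------------------------------------
# event classification


def _toy_reference():
    codons = codon_table()
    signal = "MKASMFLAFAGLVLLFVVCYA"
    propep = "SELEEESQLMEVGMPDTELEAVDEER"
    mature = "AFGHIKTGECKGFGKSTGVPGKNETGCSGYATGNSRDKWTGKVLLAGSTV"
    mature = mature.replace("TG", "CG", 3)  # sprinkle cysteines upstream? keep simple
    aa = signal + propep + mature
    cds = "".join(codons[c] for c in aa) + codons["*"]
    return aa, cds


def test_cysteine_loss_from_tgc_to_ggc(catalog):
    codons = codon_table()
    signal = "MKASMFLAFAGLVLLFVVCYA"
    mature = "AFGHIKLECKGFGKSCVPGKNECCSGYACNSRDKWCKVLL"
    aa = signal + mature
    ref = "".join(codons[c] for c in aa) + codons["*"]
    ann = segment_precursor(aa, catalog, "ref")
    # first mature cysteine: TGC -> GGC (C -> G), nonsynonymous
    ci = aa.index("C", len(signal))
    pos = 3 * ci + 1
    var = ref[: pos - 1] + "G" + ref[pos:]
    call = classify_variant_events(var, ref, ann)
    assert [e.kind for e in call.events] == ["cysteine_loss"]
    assert call.events[0].nt_position == pos


def test_synonymous_point_substitution(catalog):
    codons = codon_table()
    aa = "MKASMFLAFAGLVLLFVVCYA" + "AFGHIKLECKGFGKSCVPGKNECCSGYACNSRDKWCKVLL"
    ref = "".join(codons[c] for c in aa) + codons["*"]
    # GCC -> GCT (Ala -> Ala) at the first mature alanine
    ci = len("MKASMFLAFAGLVLLFVVCYA")
    pos = 3 * ci + 3
    var = ref[: pos - 1] + "T" + ref[pos:]
    call = classify_variant_events(var, ref)
    assert [e.kind for e in call.events] == ["point_synonymous"]
    assert call.events[0].nt_position == pos


def test_premature_stop_caa_to_taa():
    codons = codon_table()
    aa = "M" + "Q" * 60 + "AFGHIKLECKGFGKSCVPGKNECC"
    ref = "".join(codons[c] for c in aa) + codons["*"]
    k = 45  # codon index mutated to TAA (CAG codons here: use direct stop swap)
    var_full = ref[: 3 * k] + "TAA" + ref[3 * k + 3 :]
    # the observable variant CDS ends at the premature stop
    var = var_full[: 3 * k + 3]
    call = classify_variant_events(var, ref)
    kinds = [e.kind for e in call.events]
    assert "premature_stop" in kinds
    stop_ev = next(e for e in call.events if e.kind == "premature_stop")
    assert stop_ev.nt_position == 3 * k + 1


def test_frameshift_collapses_downstream_differences():
    codons = codon_table()
    aa = "M" + "ADEFGHIKLNPQRSTVWY" * 4
    ref = "".join(codons[c] for c in aa) + codons["*"]
    pos = 100
    var = ref[: pos - 1] + ref[pos:]  # single-base deletion
    # re-derive the variant ORF (translation runs to a new or no stop)
    call = classify_variant_events(var, ref)
    fs = [e for e in call.events if e.kind == "frameshift"]
    assert len(fs) == 1
    assert all(e.kind == "frameshift" or e.nt_position < fs[0].nt_position for e in call.events)


def test_stop_loss_elongation():
    codons = codon_table()
    aa = "M" + "ADEFGHIKLNPQRSTVWY" * 3
    ref = "".join(codons[c] for c in aa) + "TGA"
    readthrough = "".join(codons[c] for c in "AGLST") + "TAA"
    var = ref[:-3] + "TGG" + readthrough
    call = classify_variant_events(var, ref)
    kinds = [e.kind for e in call.events]
    assert kinds == ["stop_loss_elongation"]
    assert call.events[0].nt_position == len(ref) - 2


def test_unalignable_pair_is_flagged():
    call = classify_variant_events("ATAT" * 30, "GCGC" * 30, min_identity=0.30)
    assert call.flagged_unalignable and call.events == []


def test_cysteine_loss_count_matches_mature_cys_difference(catalog):
    """With only point events, cysteine_loss count equals the drop in mature
    cysteine count."""
    codons = codon_table()
    signal = "MKASMFLAFAGLVLLFVVCYA"
    mature = "AFGHIKLECKGFGKSCVPGKNECCSGYACNSRDKWCKVLL"
    aa = signal + mature
    ref = "".join(codons[c] for c in aa) + codons["*"]
    ann = segment_precursor(aa, catalog, "ref")
    # knock out cysteines 2 and 4 of the mature region
    cys_idx = [i for i, c in enumerate(aa) if c == "C" and i >= len(signal)]
    var = ref
    for ci in (cys_idx[1], cys_idx[3]):
        pos = 3 * ci + 1
        var = var[: pos - 1] + "G" + var[pos:]
    call = classify_variant_events(var, ref, ann)
    losses = [e for e in call.events if e.kind == "cysteine_loss"]
    from venomtx.sequences import translate

    var_mature_cys = translate(var).rstrip("*")[len(signal):].count("C")
    assert len(losses) == mature.count("C") - var_mature_cys == 2


def test_choose_reference_tiebreaks():
    members = [("b", "ATG" * 30, 5), ("a", "ATG" * 30, 5), ("c", "ATG" * 40, 3)]
    assert choose_reference(members)[0] == "a"  # max count, then lexicographic
    members2 = [("b", "ATG" * 40, 5), ("a", "ATG" * 30, 5)]
    assert choose_reference(members2)[0] == "b"  # longer CDS wins the tie


def test_codon_alignment_produces_frame_compatible_pair():
    codons = codon_table()
    aa = "MKASMFLAFAGLVLLFVVCYA"
    ref = "".join(codons[c] for c in aa) + codons["*"]
    var = ref[:9] + ref[12:]  # in-frame codon deletion
    ca, cb = codon_alignment(var, ref)
    assert len(ca) == len(cb)
    assert len(ca) % 3 == 0
    assert cb.replace("-", "") == ref
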