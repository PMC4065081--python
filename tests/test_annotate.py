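"""Similarity search, classification, segmentation and frameworks."""

import random

import pytest
from Bio.Align import substitution_matrices
from hypothesis import given, settings
from hypothesis import strategies as st

from venomtx.annotate import (
    AnnotationParams,
    classify_transcript,
    extract_framework,
    local_align,
    search_best,
    segment_precursor,
)
from venomtx.catalog import FRAMEWORK_SCAFFOLDS
from venomtx.sequences import NucSequence, find_orfs

BLOSUM62 = substitution_matrices.load("BLOSUM62")


# ---------------------------------------------------------------------------
# local alignment


def test_self_alignment_scores_diagonal_sum():
    seq = "MKASMFLAFAGLVLLFVVCY"  # 20 residues
    hit = local_align(seq, seq)
    assert hit.score == sum(BLOSUM62[a, a] for a in seq)
    assert hit.query_span == (1, 20) and hit.subject_span == (1, 20)


def test_disjoint_residues_score_zero():
    # W/F against acidic residues: all pairwise substitution scores negative
    hit = local_align("WWWWWW", "DEDEDE")
    assert hit.score == 0
    assert not hit.significant()


def _oracle_local(a: str, b: str, open_run: float, extend: float) -> float:
    """Exhaustive local alignment: best affine-gap alignment over all
    substring pairs, enumerated recursively.  Independent of the DP path."""
    best = 0.0

    def walk(i, j, score, in_gap):
        nonlocal best
        best = max(best, score)  # local: may end anywhere
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, score + BLOSUM62[a[i], b[j]], None)
        if i < len(a):
            cost = extend if in_gap == "a" else open_run
            walk(i + 1, j, score - cost, "a")
        if j < len(b):
            cost = extend if in_gap == "b" else open_run
            walk(i, j + 1, score - cost, "b")

    for i0 in range(len(a)):
        for j0 in range(len(b)):
            walk(i0, j0, 0.0, None)  # local: may start anywhere
    return best


def test_local_alignment_matches_bruteforce_oracle():
    params = AnnotationParams()
    a, b = "MKCYAS", "MKACYASE"
    expected = _oracle_local(a, b, params.gap_open + params.gap_extend, params.gap_extend)
    assert local_align(a, b, params).score == pytest.approx(expected)


def test_significance_uses_both_gates():
    params = AnnotationParams()
    long_match = "MKASMFLAFAGLVLLFVVCYASELEEESQLMEVGMPDTELEAVDEER"
    hit = local_align(long_match, long_match, params)
    assert hit.evalue_like <= params.max_evalue and hit.bits > params.min_bits
    assert hit.significant(params)
    short = local_align("MKAS", "MKAS", params)  # strong identity, tiny score
    assert not short.significant(params)


def test_search_best_and_empty_inputs():
    db = [("a", "MKASMFLAFAGLVLLFVVCYA"), ("b", "WWWWWWWWWW")]
    hit = search_best("MKASMFLAFAGLVLLFVVCYA", db)
    assert hit.subject_id == "a"
    with pytest.raises(ValueError):
        local_align("", "MKA")


# ---------------------------------------------------------------------------
# segmentation


def test_segment_superfamily_one_worked_example(catalog):
    signal = "MKASMFLAFAGLVLLFVVCYA"
    propep = "SELEEESQLMEVGMPDTELEAVDEER"
    mature = "AFAGHIKLECKGFGKSCVPGKNECCSGYACNSRDKWCKVLL"
    ann = segment_precursor(signal + propep + mature, catalog, "wk")
    assert ann.signal == signal
    assert ann.propeptide == propep and ann.propeptide.endswith("EER")
    assert ann.mature == mature
    assert ann.signal_evidence == "catalog_match"
    assert "CYASE" in ann.cleavage_motifs
    assert any(m.endswith("EER") for m in ann.cleavage_motifs)


def test_segment_no_pqm_gives_empty_propeptide(catalog):
    signal = "MKVVLLVCLVWMMAMMELVSC"  # superfamily XIV: no propeptide
    mature = "AFGHIKCLNPQCSTVWCCYAFGCHIKLC"
    ann = segment_precursor(signal + mature, catalog, "x")
    assert ann.signal == signal
    assert ann.propeptide == ""
    assert ann.mature == mature


def test_segment_fallback_missing_evidence(catalog):
    # hydrophilic start: no catalog match, heuristic fails
    aa = "MDEDEDEDKRKRKEDEDEDKRKRHHHHQQQQNNNNDEDEDEDKRKRK"
    ann = segment_precursor(aa, catalog, "f")
    assert ann.signal_evidence == "missing"
    assert ann.signal == "" and ann.mature == aa


def test_segment_signal_less_superfamily_via_propeptide(catalog):
    prop = "MTREETQSLGEHEKDEEVTGSEER"
    mature = "AFGHIKCLNPQCSTVWCCYAFGCHIKC"
    ann = segment_precursor(prop + mature, catalog, "xxv")
    assert ann.signal == ""
    assert ann.propeptide == prop
    assert ann.mature == mature
    assert ann.matched_superfamily == "XXV"


def test_segment_tolerates_two_mismatches(catalog):
    signal = "MKASMFLAFAGLVLLFVVCYA"
    mutated = "MQASMFLAFAGLVLLFVVCYA"  # one substitution
    mature = "AAGHIKCLNPQCSTVWCCYAFGCHIKC"
    ann = segment_precursor(mutated + mature, catalog, "m")
    assert ann.signal == mutated
    assert ann.matched_superfamily == "I"


def test_segmentation_conservation_on_all_templates(catalog, templates):
    for tpl in templates:
        ann = segment_precursor(tpl.precursor, catalog, tpl.template_id)
        assert ann.signal + ann.propeptide + ann.mature == tpl.precursor
        assert ann.mature


# ---------------------------------------------------------------------------
# cysteine frameworks


def test_framework_worked_examples():
    fw = extract_framework("ACAACAACCAACAACA")
    assert (fw.scaffold, fw.n_cys, fw.pattern_class) == ("-C-C-CC-C-C-", 6, "I")
    fw9 = extract_framework("AACAACAAACAAACAA")
    assert (fw9.scaffold, fw9.pattern_class) == ("-C-C-C-C-", "IX")
    # C,C,CC,C,C,C,C,CC,C,C with non-cysteine spacers
    vii = "xCxCxCCxCxCxCxCxCCxCxCx".replace("x", "AG")
    fw7 = extract_framework(vii)
    assert fw7.pattern_class == "VII" and fw7.n_cys == 12


def test_framework_edges():
    fw0 = extract_framework("AAAA")
    assert (fw0.scaffold, fw0.n_cys, fw0.pattern_class) == ("-", 0, "NOVEL")
    fw1 = extract_framework("C")
    assert fw1.scaffold == "-C-" and fw1.parity == "odd"
    with pytest.raises(ValueError):
        extract_framework("")


@given(st.data())
@settings(max_examples=60, derandomize=True, deadline=None)
def test_framework_invariant_under_non_cysteine_substitution(data):
    """Replacing any non-cysteine residue by another non-cysteine leaves the
    scaffold and class unchanged."""
    rng = random.Random(data.draw(st.integers(0, 10_000)))
    mature = "".join(rng.choices("ACDEFGHIKLMNPQRSTVWY", k=rng.randint(5, 60)))
    fw = extract_framework(mature)
    pos = data.draw(st.integers(0, len(mature) - 1))
    if mature[pos] == "C":
        return
    repl = data.draw(st.sampled_from("ADEFGHIKLMNPQRSTVWY"))
    mutated = mature[:pos] + repl + mature[pos + 1 :]
    fw2 = extract_framework(mutated)
    assert fw.scaffold == fw2.scaffold and fw.pattern_class == fw2.pattern_class


def test_all_catalog_scaffolds_classify_to_their_label(rng):
    for label, scaffold in FRAMEWORK_SCAFFOLDS.items():
        mature = "".join(
            "C" if ch == "C" else "".join(rng.choices("AGLSTV", k=rng.randint(1, 6)))
            for ch in scaffold
        )
        fw = extract_framework(mature)
        assert fw.scaffold == scaffold
        assert fw.pattern_class == label


# ---------------------------------------------------------------------------
# classification


def test_classify_template_transcript_toxin_like(catalog, templates):
    tpl = templates[0]
    t = NucSequence("t", tpl.cdna())
    orfs = find_orfs(t, min_aa=40)
    toxin_db = [(x.template_id, x.precursor) for x in templates]
    from venomtx.annotate import search_best

    hit = max(
        (search_best(o.aa, toxin_db) for o in orfs), key=lambda h: h.score if h else -1
    )
    assert classify_transcript(orfs, hit, None, None, catalog) == "Toxin_like"


def test_classify_random_sequence_no_hit(catalog, rng):
    from venomtx.simulate import _no_orf_random

    t = NucSequence("r", _no_orf_random(rng))
    orfs = find_orfs(t, min_aa=40)
    assert classify_transcript(orfs, None, None, None, catalog) == "No_Hit"


def test_classify_cysteine_rich_orphan_is_putative_toxin(catalog):
    # 45-aa ORF with 6 cysteines and no catalog hit
    aa = "M" + "AGLST" * 3 + "C" + "AGLT" + "C" + "AGLT" + "C" + "AGLT" + "C" + "AGT" + "CC" + "AGLSTV"
    from venomtx.simulate import codon_table

    codons = codon_table()
    nt = "".join(codons[ch] for ch in aa) + "TAA"
    orfs = find_orfs(NucSequence("p", nt), min_aa=30)
    assert orfs
    assert classify_transcript(orfs, None, None, None, catalog) == "Putative_toxin"


def test_classification_is_total_and_single(catalog, templates):
    from venomtx.annotate import annotate_transcripts
    from venomtx.simulate import (
        cellular_reference,
        generate_background,
        unannotated_reference,
    )

    bg, _ = generate_background(12, seed=3)
    toxin_db = [(t.template_id, t.precursor) for t in templates]
    anns = annotate_transcripts(
        bg, catalog, toxin_db, cellular_reference(), unannotated_reference()
    )
    cats = {
        "Toxin_like",
        "Putative_toxin",
        "Cellular_Proteins",
        "Unknown_function",
        "No_Hit",
    }
    assert len(anns) == 12
    assert all(a.category in cats for a in anns)
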