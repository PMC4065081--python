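"""Similarity search, transcript classification, precursor segmentation and
cysteine-framework extraction.

The similarity search is Smith-Waterman local alignment with affine gaps
(BLOSUM62, open 11 / extend 1) with a Karlin-Altschul-style significance
calibration: ``evalue_like = K * m * n * exp(-lambda * S)`` with fixed,
versioned constants.  A hit is significant when ``evalue_like <= 1e-5`` and
the bit-equivalent score exceeds 40 — both gates apply.

Transcript categories follow a fixed rule order: a significant hit against
the toxin catalog wins, then the cellular reference, then the unannotated
reference; cysteine-rich orphan ORFs become putative toxins; everything else
is a no-hit.

Precursor segmentation: the signal peptide is located by matching the 16
catalogued signal peptides (<= 2 mismatches over the catalog signal length),
with a hydrophobicity heuristic as fallback; the propeptide ends at the
rightmost processing-quadruplet-motif (PQM, ``X[ED][ED]R`` — e.g. GEER or
SEER) occurring after the signal and before the first cysteine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .catalog import SCAFFOLD_TO_CLASS, ReferenceCatalog
from .sequences import NucSequence, OpenReadingFrame, find_orfs

__all__ = [
    "AnnotationParams",
    "SimilarityHit",
    "PrecursorAnnotation",
    "CysteineFramework",
    "local_align",
    "search_best",
    "classify_transcript",
    "segment_precursor",
    "extract_framework",
    "TranscriptAnnotation",
    "annotate_transcripts",
]

CATEGORIES = ("Toxin_like", "Putative_toxin", "Cellular_Proteins", "Unknown_function", "No_Hit")


@dataclass(frozen=True)
class AnnotationParams:
    """Significance and scoring calibration (fixed, versioned: cal-1)."""

    max_evalue: float = 1e-5
    min_bits: float = 40.0
    lambda_: float = 0.267  # BLOSUM62 gapped (11/1) scale
    k: float = 0.041
    gap_open: float = 11.0
    gap_extend: float = 1.0
    matrix: str = "BLOSUM62"
    min_orf_aa: int = 40
    # cysteine-richness rule for Putative_toxin
    rich_min_aa: int = 30
    rich_max_aa: int = 130
    rich_min_cys: int = 4
    rich_min_fraction: float = 0.06


@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: float, gap_extend: float, mode: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.substitution_matrix = substitution_matrices.load(matrix)
    al.open_gap_score = -(gap_open + gap_extend)
    al.extend_gap_score = -gap_extend
    al.mode = mode
    return al


@dataclass(frozen=True)
class SimilarityHit:
    query_id: str
    subject_id: str
    score: float  # raw Smith-Waterman score
    bits: float
    evalue_like: float
    query_span: tuple[int, int]  # 1-based inclusive on query
    subject_span: tuple[int, int]

    def significant(self, params: AnnotationParams = AnnotationParams()) -> bool:
        return self.evalue_like <= params.max_evalue and self.bits > params.min_bits


def local_align(
    query: str,
    subject: str,
    params: AnnotationParams = AnnotationParams(),
    query_id: str = "query",
    subject_id: str = "subject",
) -> SimilarityHit:
    """Optimal local alignment of two amino-acid strings.

    Returns the hit with raw score, bit-equivalent score and e-value-like
    statistic.  A score of zero (nothing aligns favourably) yields spans
    ``(0, 0)``.
    """
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    al = _aligner(params.matrix, params.gap_open, params.gap_extend, "local")
    score = al.score(query, subject)
    if score <= 0:
        qspan = sspan = (0, 0)
        score = 0.0
    else:
        aln = al.align(query, subject)[0]
        qs, ss = aln.aligned
        qspan = (int(qs[0][0]) + 1, int(qs[-1][1]))
        sspan = (int(ss[0][0]) + 1, int(ss[-1][1]))
    import math

    bits = (params.lambda_ * score - math.log(params.k)) / math.log(2.0)
    evalue = params.k * len(query) * len(subject) * math.exp(-params.lambda_ * score)
    return SimilarityHit(query_id, subject_id, float(score), bits, evalue, qspan, sspan)


def search_best(
    query: str,
    db: Sequence[tuple[str, str]],
    params: AnnotationParams = AnnotationParams(),
    query_id: str = "query",
) -> SimilarityHit | None:
    """Best-scoring hit of ``query`` against a (subject_id, sequence) db."""
    if not db:
        return None
    al = _aligner(params.matrix, params.gap_open, params.gap_extend, "local")
    best_sid, best_score = None, -1.0
    for sid, subject in db:
        s = al.score(query, subject)
        if s > best_score:
            best_sid, best_score, best_subject = sid, s, subject
    return local_align(query, best_subject, params, query_id, best_sid)


def select_precursor_orf(
    orfs: Sequence[OpenReadingFrame],
    start_bonus: int = 40,
    stop_bonus: int = 20,
) -> OpenReadingFrame | None:
    """Pick the ORF most plausibly encoding the precursor.

    Ranked by translated length plus anchoring bonuses for an ATG start and
    a stop codon: frame anchors are strong evidence of the true reading
    frame, while unanchored stop-free spans (e.g. an off-frame walk across a
    whole cDNA) can be long without being coding.  Ties resolve to the
    ``find_orfs`` sort order.
    """
    if not orfs:
        return None
    return max(
        orfs,
        key=lambda o: len(o.aa)
        + (0 if o.missing_start else start_bonus)
        + (0 if o.missing_stop else stop_bonus),
    )


# ---------------------------------------------------------------------------
# segmentation

_HYDROPHOBIC = set("AVLIMFWC")
_SMALL = set("AGSC")


@dataclass(frozen=True)
class PrecursorAnnotation:
    """Signal | propeptide | mature segmentation with motif evidence.

    The three spans are contiguous and cover the full precursor:
    ``signal + propeptide + mature == precursor``.
    """

    precursor_id: str
    signal: str
    propeptide: str
    mature: str
    signal_evidence: str  # catalog_match | heuristic | missing
    cleavage_motifs: tuple[str, ...] = ()
    matched_superfamily: str | None = None  # catalog entry behind the match

    def __post_init__(self) -> None:
        if not self.mature:
            raise ValueError("mature span must be non-empty")

    @property
    def precursor(self) -> str:
        return self.signal + self.propeptide + self.mature


def _match_catalog_signal(aa: str, catalog: ReferenceCatalog) -> tuple[str, str] | None:
    """Best (superfamily, signal) whose full length matches the precursor
    N-terminus with <= 2 mismatches; ties: fewer mismatches, longer signal,
    catalog order."""
    best = None
    for sf, sig in catalog.signals():
        if len(aa) <= len(sig):
            continue
        mm = sum(a != b for a, b in zip(aa, sig))
        if mm <= 2:
            key = (mm, -len(sig))
            if best is None or key < best[0]:
                best = (key, sf, sig)
    if best is None:
        return None
    return best[1], best[2]


def _heuristic_signal_end(aa: str) -> int | None:
    """Fallback signal predictor: the longest 15-30 aa N-terminal window with
    >= 50% hydrophobic residues and a small residue (A/G/S/C) within its
    last five positions."""
    best = None
    for L in range(15, 31):
        if L >= len(aa):
            break
        w = aa[:L]
        if sum(c in _HYDROPHOBIC for c in w) / L >= 0.5 and any(
            c in _SMALL for c in w[-5:]
        ):
            best = L
    return best


def _rightmost_pqm(aa: str, start: int, limit: int) -> int | None:
    """End index (exclusive) of the rightmost X[ED][ED]R motif whose span
    lies in [start, limit)."""
    for i in range(limit - 4, start - 1, -1):
        if aa[i + 1] in "ED" and aa[i + 2] in "ED" and aa[i + 3] == "R":
            return i + 4
    return None


def segment_precursor(
    aa: str,
    catalog: ReferenceCatalog,
    precursor_id: str = "precursor",
    missing_start: bool = False,
) -> PrecursorAnnotation:
    """Segment a precursor into signal | propeptide | mature.

    Signal evidence order: catalog signal match (<= 2 mismatches), catalog
    propeptide key (signal-less superfamilies, e.g. XXV), hydrophobicity
    heuristic, then ``missing`` (5'-partial ORFs, or no signal found).  The
    propeptide ends at the rightmost PQM after the signal and before the
    first cysteine; without a PQM the propeptide is empty.
    """
    if not aa:
        raise ValueError("empty precursor")
    if not aa.startswith("M") and not missing_start:
        # tolerated, but only with evidence downgraded to missing
        missing_start = True
    signal_end = 0
    evidence = "missing"
    matched_sf: str | None = None
    motifs: list[str] = []
    if not missing_start:
        hit = _match_catalog_signal(aa, catalog)
        if hit is not None:
            matched_sf, sig = hit
            signal_end = len(sig)
            evidence = "catalog_match"
        else:
            for sf, prop in catalog.propeptide_keys():
                if len(aa) > len(prop):
                    mm = sum(a != b for a, b in zip(aa, prop))
                    if mm <= 2:
                        matched_sf, evidence = sf, "catalog_match"
                        signal_end = 0
                        break
            else:
                L = _heuristic_signal_end(aa)
                if L is not None:
                    signal_end = L
                    evidence = "heuristic"
    # cleavage motif bookkeeping
    if signal_end and "CYASE" in aa[max(0, signal_end - 4) : signal_end + 4]:
        motifs.append("CYASE")
    first_c = aa.find("C", signal_end)
    limit = first_c if first_c != -1 else len(aa)
    pqm_end = _rightmost_pqm(aa, signal_end, limit) if limit - signal_end >= 4 else None
    if pqm_end is not None and pqm_end < len(aa):
        propeptide = aa[signal_end:pqm_end]
        mature = aa[pqm_end:]
        motifs.append(aa[pqm_end - 4 : pqm_end])
    else:
        propeptide = ""
        mature = aa[signal_end:]
    return PrecursorAnnotation(
        precursor_id=precursor_id,
        signal=aa[:signal_end],
        propeptide=propeptide,
        mature=mature,
        signal_evidence=evidence,
        cleavage_motifs=tuple(motifs),
        matched_superfamily=matched_sf,
    )


# ---------------------------------------------------------------------------
# cysteine frameworks


@dataclass(frozen=True)
class CysteineFramework:
    scaffold: str  # e.g. "-C-C-CC-C-C-"
    n_cys: int
    pattern_class: str  # I..XI or NOVEL
    parity: str  # even | odd

    def __post_init__(self) -> None:
        if self.scaffold.count("C") != self.n_cys:
            raise ValueError("n_cys inconsistent with scaffold")


def extract_framework(mature: str) -> CysteineFramework:
    """Render the cysteine scaffold of a mature peptide and classify it.

    Adjacent cysteines render as ``CC``; isolated runs of non-cysteine
    residues render as single ``-``; leading/trailing non-cysteines flank the
    scaffold with ``-``.  The pattern class is the Table-style lookup (I-XI),
    ``NOVEL`` otherwise.
    """
    if not mature:
        raise ValueError("mature peptide must be non-empty")
    out: list[str] = []
    prev_c = None
    for ch in mature:
        is_c = ch == "C"
        if is_c:
            out.append("C")
        elif prev_c is not False:  # first residue or transition from C
            out.append("-")
        prev_c = is_c
    if prev_c:
        out.append("")
    scaffold = "".join(out)
    if not scaffold.startswith("-"):
        scaffold = "-" + scaffold
    if not scaffold.endswith("-"):
        scaffold = scaffold + "-"
    n_cys = scaffold.count("C")
    cls = SCAFFOLD_TO_CLASS.get(scaffold, "NOVEL")
    return CysteineFramework(scaffold, n_cys, cls, "even" if n_cys % 2 == 0 else "odd")


# ---------------------------------------------------------------------------
# transcript classification


def _cysteine_rich(orf: OpenReadingFrame, catalog: ReferenceCatalog, params: AnnotationParams) -> bool:
    aa = orf.aa
    if not params.rich_min_aa <= len(aa) <= params.rich_max_aa:
        return False
    ann = segment_precursor(aa, catalog, missing_start=orf.missing_start)
    region = ann.propeptide + ann.mature
    if not region:
        return False
    n_cys = region.count("C")
    return n_cys >= params.rich_min_cys and n_cys / len(region) >= params.rich_min_fraction


def classify_transcript(
    orfs: Sequence[OpenReadingFrame],
    toxin_hit: SimilarityHit | None,
    cellular_hit: SimilarityHit | None,
    unannotated_hit: SimilarityHit | None,
    catalog: ReferenceCatalog,
    params: AnnotationParams = AnnotationParams(),
) -> str:
    """Five-category rule classifier (first matching rule wins)."""
    if toxin_hit is not None and toxin_hit.significant(params):
        return "Toxin_like"
    if cellular_hit is not None and cellular_hit.significant(params):
        return "Cellular_Proteins"
    if unannotated_hit is not None and unannotated_hit.significant(params):
        return "Unknown_function"
    for orf in orfs:
        if _cysteine_rich(orf, catalog, params):
            return "Putative_toxin"
    return "No_Hit"


@dataclass
class TranscriptAnnotation:
    transcript_id: str
    category: str
    best_hit: SimilarityHit | None
    orf: OpenReadingFrame | None
    precursor: PrecursorAnnotation | None
    framework: CysteineFramework | None


def annotate_transcripts(
    transcripts: Sequence[NucSequence],
    catalog: ReferenceCatalog,
    toxin_db: Sequence[tuple[str, str]],
    cellular_db: Sequence[tuple[str, str]] | None = None,
    unannotated_db: Sequence[tuple[str, str]] | None = None,
    params: AnnotationParams = AnnotationParams(),
) -> list[TranscriptAnnotation]:
    """Run search + classification + segmentation over transcripts.

    For toxin-like and putative-toxin transcripts the reported ORF is the one
    with the best toxin hit (longest otherwise), and its precursor is
    segmented and framework-extracted.
    """
    out = []
    for t in transcripts:
        orfs = find_orfs(t, min_aa=params.min_orf_aa)
        best: dict[str, SimilarityHit | None] = {"tox": None, "cel": None, "unk": None}
        best_orf = select_precursor_orf(orfs)
        tox_orf = None
        # complete ORFs first so score ties resolve to the ATG-anchored frame
        for orf in sorted(orfs, key=lambda o: (o.missing_start, -len(o.aa))):
            th = search_best(orf.aa, toxin_db, params, query_id=t.id) if toxin_db else None
            if th and (best["tox"] is None or th.score > best["tox"].score):
                best["tox"], tox_orf = th, orf
            ch = (
                search_best(orf.aa, cellular_db, params, query_id=t.id)
                if cellular_db
                else None
            )
            if ch and (best["cel"] is None or ch.score > best["cel"].score):
                best["cel"] = ch
            uh = (
                search_best(orf.aa, unannotated_db, params, query_id=t.id)
                if unannotated_db
                else None
            )
            if uh and (best["unk"] is None or uh.score > best["unk"].score):
                best["unk"] = uh
        category = classify_transcript(
            orfs, best["tox"], best["cel"], best["unk"], catalog, params
        )
        precursor = framework = None
        orf = None
        if category in ("Toxin_like", "Putative_toxin"):
            orf = tox_orf if (category == "Toxin_like" and tox_orf is not None) else best_orf
            if orf is not None:
                precursor = segment_precursor(
                    orf.aa, catalog, precursor_id=t.id, missing_start=orf.missing_start
                )
                framework = extract_framework(precursor.mature)
        hit = best["tox"] or best["cel"] or best["unk"]
        out.append(TranscriptAnnotation(t.id, category, hit, orf, precursor, framework))
    return out
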