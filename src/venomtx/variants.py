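"""Variant-mechanism calls and expression tiers.

Low-abundance isoforms are globally aligned to their family reference (the
member with the highest read support) and every difference is mapped to a
mutational event: synonymous / nonsynonymous point substitutions (with
cysteine loss or gain flagged in the mature region), in-frame insertions and
deletions, frameshifts (indel length not divisible by three; all apparent
downstream substitutions collapse into the single frameshift event),
premature stop codons, and stop-loss read-through elongation.

Expression tiers follow the read-support convention: high > 10 reads,
low 2-10 reads, rare = a single read.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

from Bio import Align

from .annotate import PrecursorAnnotation
from .sequences import translate

__all__ = [
    "VariantEvent",
    "ExpressionTier",
    "VariantCall",
    "global_align_nt",
    "classify_variant_events",
    "assign_tier",
    "left_normalize_indel",
    "choose_reference",
]

EVENT_KINDS = (
    "point_synonymous",
    "point_nonsynonymous",
    "cysteine_loss",
    "cysteine_gain",
    "inframe_insertion",
    "inframe_deletion",
    "frameshift",
    "premature_stop",
    "stop_loss_elongation",
)

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class VariantEvent:
    kind: str
    nt_position: int  # 1-based on the reference CDS
    detail: str = ""

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass(frozen=True)
class ExpressionTier:
    tier: str
    read_count: int


def assign_tier(read_count: int) -> ExpressionTier:
    """high: > 10 reads; low: 2-10 reads; rare: exactly 1 read."""
    if read_count < 1:
        raise ValueError("read count must be >= 1")
    if read_count > 10:
        tier = "high"
    elif read_count >= 2:
        tier = "low"
    else:
        tier = "rare"
    return ExpressionTier(tier, read_count)


@lru_cache(maxsize=2)
def _nt_aligner() -> Align.PairwiseAligner:
    # mismatch preferred over gap for isolated differences; long gaps cheap
    # to extend so a single indel stays one gap
    al = Align.PairwiseAligner()
    al.match_score = 5.0
    al.mismatch_score = -4.0
    al.open_gap_score = -12.0
    al.extend_gap_score = -0.5
    al.mode = "global"
    return al


def global_align_nt(variant_cds: str, reference_cds: str):
    """Optimal global nucleotide alignment (first optimal alignment under a
    fixed deterministic scoring, so results are reproducible)."""
    if not variant_cds or not reference_cds:
        raise ValueError("sequences must be non-empty")
    return _nt_aligner().align(variant_cds, reference_cds)[0]


@lru_cache(maxsize=2)
def _free_end_aligner() -> Align.PairwiseAligner:
    """Same scoring as the global aligner but with free end gaps, so 5'/3'
    truncation or extension hangs off the ends instead of being forced into
    internal gaps."""
    al = Align.PairwiseAligner()
    al.match_score = 5.0
    al.mismatch_score = -4.0
    al.open_gap_score = -12.0
    al.extend_gap_score = -0.5
    al.end_gap_score = 0.0
    al.mode = "global"
    return al


def left_normalize_indel(ref: str, pos: int, seq: str, is_insertion: bool) -> tuple[int, str]:
    """Shift an indel to its leftmost equivalent placement.

    ``pos`` is the 1-based reference position of the first deleted base
    (deletions) or the base before which the payload is inserted
    (insertions).  Returns the normalised ``(pos, seq)``.
    """
    p = pos
    s = seq
    if is_insertion:
        while p > 1 and s and s[-1] == ref[p - 2]:
            s = ref[p - 2] + s[:-1]
            p -= 1
    else:
        L = len(s)
        while p > 1 and ref[p - 2] == ref[p + L - 2]:
            p -= 1
            s = ref[p - 1 : p - 1 + L]
    return p, s


def _aligned_columns(aln) -> list[tuple[str, str]]:
    """(variant_char, reference_char) per alignment column; '-' for gaps."""
    v, r = str(aln[0]), str(aln[1])
    return list(zip(v, r))


@dataclass
class VariantCall:
    variant_id: str
    reference_id: str
    events: list[VariantEvent]
    identity: float
    flagged_unalignable: bool = False


def classify_variant_events(
    variant_cds: str,
    reference_cds: str,
    reference_annotation: PrecursorAnnotation | None = None,
    variant_id: str = "variant",
    reference_id: str = "reference",
    min_identity: float = 0.30,
) -> VariantCall:
    """Map every alignment difference to a mutational event.

    Both inputs should include their stop codon when present.  Analysis runs
    in reference-codon coordinates; once a frameshift is seen, downstream
    differences are suppressed into that single event; once the variant hits
    a premature stop, downstream differences are unreachable by translation
    and likewise suppressed.  If the reference stop codon aligns to a sense
    codon, a stop-loss elongation is reported.
    """
    aln = _free_end_aligner().align(variant_cds, reference_cds)[0]
    counts = aln.counts()
    identity = counts.identities / aln.length
    if identity < min_identity:
        return VariantCall(variant_id, reference_id, [], identity, flagged_unalignable=True)
    cols = _aligned_columns(aln)

    # mature span on the reference CDS, for cysteine-loss/gain calls
    mature_nt = None
    if reference_annotation is not None:
        pre = reference_annotation.precursor
        m0 = len(pre) - len(reference_annotation.mature)
        mature_nt = (3 * m0 + 1, 3 * len(pre))

    events: list[VariantEvent] = []
    ref_stop_start = len(reference_cds) - 2 if reference_cds[-3:] in _STOPS else None

    # gather gap runs and per-column substitutions in reference coordinates;
    # blocks touching either alignment end are truncation/extension context
    # (5'/3'-partial ORFs, read-through tails), not indel events
    rpos = 0  # last consumed reference position (1-based)
    vpos = 0
    ref_pos_of_var: list[int | None] = [None] * len(variant_cds)
    i = 0
    frameshift_seen = False
    trailing_ins = 0  # variant bases hanging past the reference 3' end
    subs: list[tuple[int, str, str]] = []  # (ref pos, ref base, var base)
    n = len(cols)
    while i < n:
        v, r = cols[i]
        if v != "-" and r != "-":
            rpos += 1
            vpos += 1
            ref_pos_of_var[vpos - 1] = rpos
            if v != r:
                subs.append((rpos, r, v))
            i += 1
            continue
        # a gap run: collect its full extent (insertion or deletion)
        j = i
        ins, dele = [], []
        while j < n and (cols[j][0] == "-" or cols[j][1] == "-"):
            if cols[j][1] == "-":
                ins.append(cols[j][0])
                vpos += 1
            else:
                dele.append(cols[j][1])
                rpos += 1
            j += 1
        leading, trailing = i == 0, j == n
        if leading or frameshift_seen:
            i = j
            continue
        if trailing:
            if ins and not dele:
                trailing_ins += len(ins)
            i = j
            continue
        if ins and not dele:
            p0 = rpos + 1  # inserted before this reference position
            if ref_stop_start is not None and p0 > ref_stop_start:
                trailing_ins += len(ins)  # read-through: handled after the scan
                i = j
                continue
            p, s = left_normalize_indel(reference_cds, p0, "".join(ins), True)
            if len(ins) % 3 == 0:
                events.append(VariantEvent("inframe_insertion", p, f"+{s}"))
            else:
                events.append(VariantEvent("frameshift", p, f"+{len(ins)}nt"))
                frameshift_seen = True
        elif dele and not ins:
            p0 = rpos - len(dele) + 1
            p, s = left_normalize_indel(reference_cds, p0, "".join(dele), False)
            if len(dele) % 3 == 0:
                events.append(VariantEvent("inframe_deletion", p, f"-{s}"))
            else:
                events.append(VariantEvent("frameshift", p, f"-{len(dele)}nt"))
                frameshift_seen = True
        else:
            # mixed gap block: net frame change decides
            net = len(ins) - len(dele)
            p0 = rpos - len(dele) + 1
            if net % 3 != 0:
                events.append(VariantEvent("frameshift", p0, f"{net:+d}nt net"))
                frameshift_seen = True
            else:
                events.append(
                    VariantEvent(
                        "inframe_insertion" if net > 0 else "inframe_deletion",
                        p0,
                        f"{net:+d}nt net",
                    )
                )
        i = j
    # substitution events, codon by codon, truncated at frameshift/stop
    fs_pos = next((e.nt_position for e in events if e.kind == "frameshift"), None)
    var_map = _variant_codons(cols, reference_cds)
    emitted_stop = False
    for codon_start in sorted({(p - 1) // 3 * 3 + 1 for p, _, _ in subs}):
        if fs_pos is not None and codon_start >= fs_pos:
            continue
        if emitted_stop:
            break
        ref_codon = reference_cds[codon_start - 1 : codon_start + 2]
        var_codon = var_map.get(codon_start)
        codon_subs = [s for s in subs if codon_start <= s[0] <= codon_start + 2]
        if var_codon is None or len(var_codon) != 3:
            continue
        if ref_codon in _STOPS:
            if var_codon not in _STOPS:
                extra = len(variant_cds) - len(reference_cds)
                events.append(
                    VariantEvent(
                        "stop_loss_elongation",
                        codon_start,
                        f"{ref_codon}->{var_codon}; +{max(extra, 0)}nt readthrough",
                    )
                )
            continue
        if var_codon in _STOPS:
            events.append(
                VariantEvent("premature_stop", codon_start, f"{ref_codon}->{var_codon}")
            )
            emitted_stop = True
            continue
        ref_aa = translate(ref_codon) if "N" not in ref_codon else "X"
        var_aa = translate(var_codon) if "N" not in var_codon else "X"
        for p, rb, vb in codon_subs:
            detail = f"{rb}->{vb} ({ref_codon}->{var_codon}, {ref_aa}->{var_aa})"
            if ref_aa == var_aa:
                events.append(VariantEvent("point_synonymous", p, detail))
            else:
                kind = "point_nonsynonymous"
                if mature_nt and mature_nt[0] <= codon_start <= mature_nt[1]:
                    if ref_aa == "C" and var_aa != "C":
                        kind = "cysteine_loss"
                    elif ref_aa != "C" and var_aa == "C":
                        kind = "cysteine_gain"
                events.append(VariantEvent(kind, p, detail))
    # structural premature stop: the variant ends in a stop codon aligned
    # upstream of the reference stop (the reference 3' tail hangs unaligned)
    if (
        ref_stop_start is not None
        and not frameshift_seen
        and variant_cds[-3:] in _STOPS
        and not any(e.kind == "premature_stop" for e in events)
    ):
        rp = ref_pos_of_var[len(variant_cds) - 3]
        if rp is not None and rp < ref_stop_start:
            codon_start = (rp - 1) // 3 * 3 + 1
            events.append(
                VariantEvent(
                    "premature_stop",
                    codon_start,
                    f"variant stop {variant_cds[-3:]} at reference codon "
                    f"{(codon_start - 1) // 3 + 1}",
                )
            )
    # read-through elongation that the aligner rendered as an insertion at or
    # past the reference stop codon rather than a stop-codon substitution
    if (
        ref_stop_start is not None
        and trailing_ins > 0
        and not frameshift_seen
        and not any(e.kind in ("stop_loss_elongation", "premature_stop") for e in events)
        and len(variant_cds) > len(reference_cds)
    ):
        events.append(
            VariantEvent(
                "stop_loss_elongation",
                ref_stop_start,
                f"+{trailing_ins}nt readthrough",
            )
        )
    events.sort(key=lambda e: (e.nt_position, EVENT_KINDS.index(e.kind)))
    return VariantCall(variant_id, reference_id, events, identity)


def _variant_codons(cols: list[tuple[str, str]], reference_cds: str) -> dict[int, str]:
    """Variant bases grouped by reference codon (codon start -> variant
    string at the three reference positions, gaps dropped)."""
    out: dict[int, list[str]] = {}
    rpos = 0
    for v, r in cols:
        if r == "-":
            continue
        rpos += 1
        start = (rpos - 1) // 3 * 3 + 1
        if v != "-":
            out.setdefault(start, []).append(v)
        else:
            out.setdefault(start, [])
    return {k: "".join(v) for k, v in out.items()}


def codon_alignment(cds_a: str, cds_b: str) -> tuple[str, str]:
    """Codon-wise pairwise alignment in the frame of ``cds_b``.

    Globally aligns the two CDSs, then walks reference codons: codons where
    the query contributes exactly three aligned bases are emitted as aligned
    codon pairs; codons touched by gaps are emitted gap-filled so downstream
    site counting can skip them pairwise.  Output strings have equal length
    divisible by three.
    """
    aln = global_align_nt(cds_a, cds_b)
    cols = _aligned_columns(aln)
    out_a: list[str] = []
    out_b: list[str] = []
    rpos = 0
    cur_a: list[str] = []
    cur_b: list[str] = []
    for v, r in cols:
        if r == "-":
            if cur_b:  # insertion inside a codon: poison it
                cur_a.append("-")
            continue
        rpos += 1
        cur_a.append(v)
        cur_b.append(r)
        if rpos % 3 == 0:
            a = "".join(cur_a)
            out_a.append(a if len(a) == 3 and "-" not in a else "---")
            out_b.append("".join(cur_b))
            cur_a, cur_b = [], []
    return "".join(out_a), "".join(out_b)


def project_onto_reference(member_cds: str, reference_cds: str) -> str:
    """Member bases at each reference position (insertions relative to the
    reference dropped, deletions as '-').  All members projected this way
    form a star multiple alignment of length ``len(reference_cds)``."""
    aln = global_align_nt(member_cds, reference_cds)
    out: list[str] = []
    for v, r in _aligned_columns(aln):
        if r == "-":
            continue
        out.append(v)
    return "".join(out)


def choose_reference(
    members: Sequence[tuple[str, str, int]]
) -> tuple[str, str]:
    """Family reference: the member with the highest read count, ties by
    longest CDS then lexicographic id.  ``members`` — (id, cds, read_count)."""
    if not members:
        raise ValueError("members must be non-empty")
    best = max(members, key=lambda m: (m[2], len(m[1]), ReversedStr(m[0])))
    return best[0], best[1]


class ReversedStr(str):
    """Orders lexicographically *smaller* strings as larger (for use inside
    ``max``-based selection with ascending tie-breaks)."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)
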