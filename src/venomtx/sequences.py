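"""Sequence records, FASTA/FASTQ I/O, translation and ORF discovery.

Conventions used throughout the package:

* coordinates are 1-based and inclusive, always on the forward strand;
* bases are uppercase over the alphabet ``{A, C, G, T, N}``;
* stop codons translate to ``'*'`` and any codon containing ``N``
  translates to ``'X'`` (``X`` never matches in motif searches);
* only ``ATG`` is accepted as a start codon — every signal peptide in the
  bundled reference catalog begins with methionine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "NucSequence",
    "OpenReadingFrame",
    "reverse_complement",
    "translate",
    "find_orfs",
    "read_fasta",
    "read_fastq",
    "write_fasta",
    "orf_table",
]

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    _CODON_TO_AA[_stop] = "*"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class NucSequence:
    """A nucleotide sequence record (uppercase, A/C/G/T/N)."""

    id: str
    bases: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"sequence {self.id!r} is empty")
        up = self.bases.upper()
        bad = set(up) - set("ACGTN")
        if bad:
            raise ValueError(f"sequence {self.id!r} has invalid symbols {sorted(bad)}")
        object.__setattr__(self, "bases", up)

    def __len__(self) -> int:
        return len(self.bases)

    def reverse_complement(self) -> "NucSequence":
        return NucSequence(self.id, reverse_complement(self.bases), self.description)


@dataclass(frozen=True)
class OpenReadingFrame:
    """An open reading frame located on a parent nucleotide sequence.

    ``start``/``end`` are 1-based inclusive coordinates on the parent's
    forward strand regardless of ``frame`` sign.  ``aa`` excludes the stop.
    """

    parent_id: str
    frame: int
    start: int
    end: int
    aa: str
    missing_start: bool = False
    missing_stop: bool = False

    @property
    def partial(self) -> bool:
        return self.missing_start or self.missing_stop


def reverse_complement(bases: str) -> str:
    return bases.translate(_COMPLEMENT)[::-1]


def translate(nt: str, frame: int = 1) -> str:
    """Translate ``nt`` in the given frame under the standard genetic code.

    Stops render as ``'*'``; codons containing ``N`` render as ``'X'``.
    Trailing bases that do not fill a codon are ignored.
    """
    if not nt:
        raise ValueError("cannot translate an empty sequence")
    if frame not in FRAMES:
        raise ValueError(f"frame must be one of {FRAMES}, got {frame}")
    seq = nt.upper()
    if frame < 0:
        seq = reverse_complement(seq)
    offset = abs(frame) - 1
    seq = seq[offset:]
    if len(seq) < 3:
        raise ValueError("fewer than 3 bases after frame offset")
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        if "N" in codon:
            out.append("X")
        else:
            out.append(_CODON_TO_AA[codon])
    return "".join(out)


def _frame_coords(frame: int, i0: int, i1: int, n: int) -> tuple[int, int]:
    """Map codon-walk offsets [i0, i1) on the (possibly RC'd) working strand
    back to 1-based inclusive forward-strand coordinates."""
    if frame > 0:
        return i0 + 1, i1
    # offsets are on the reverse complement; flip
    return n - i1 + 1, n - i0


def find_orfs(seq: NucSequence, min_aa: int = 40) -> list[OpenReadingFrame]:
    """Six-frame ORF scan.

    Complete ORFs run ATG→stop.  The leading stop-free span of each frame is
    additionally reported as a 5'-partial ORF (``missing_start``) when it does
    not itself begin with ATG — reads truncated inside a coding region surface
    this way.  Spans that reach the 3' end without a stop carry
    ``missing_stop``.  Results are sorted by amino-acid length descending,
    ties by (frame, start).

    ``min_aa`` filters on translated length (default 40: the shortest toxin
    precursors are ~60 residues, and partial reads may carry less).
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    n = len(seq)
    found: dict[tuple[int, int, int], OpenReadingFrame] = {}
    for frame in FRAMES:
        working = seq.bases if frame > 0 else reverse_complement(seq.bases)
        offset = abs(frame) - 1
        codon_starts = range(offset, len(working) - 2, 3)
        # split the frame into stop-delimited segments
        seg_start = offset
        segments: list[tuple[int, int, bool]] = []  # (start, end_excl, has_stop)
        for i in codon_starts:
            codon = working[i : i + 3]
            if "N" not in codon and _CODON_TO_AA[codon] == "*":
                segments.append((seg_start, i + 3, True))
                seg_start = i + 3
        tail_end = offset + ((len(working) - offset) // 3) * 3
        if seg_start < tail_end:
            segments.append((seg_start, tail_end, False))
        for k, (s0, s1, has_stop) in enumerate(segments):
            coding_end = s1 - 3 if has_stop else s1
            # complete (or 3'-partial) ORF from the first ATG
            atg = working.find("ATG", s0, coding_end)
            while atg != -1 and (atg - offset) % 3 != 0:
                atg = working.find("ATG", atg + 1, coding_end)
            candidates: list[tuple[int, bool]] = []
            if atg != -1:
                candidates.append((atg, False))
            if k == 0 and (atg == -1 or atg != s0):
                # leading stop-free span: 5'-partial
                candidates.append((s0, True))
            for cstart, is_partial in candidates:
                aa = "".join(
                    "X" if "N" in working[i : i + 3] else _CODON_TO_AA[working[i : i + 3]]
                    for i in range(cstart, coding_end, 3)
                )
                if len(aa) < min_aa:
                    continue
                start, end = _frame_coords(frame, cstart, s1 if has_stop else coding_end, n)
                orf = OpenReadingFrame(
                    parent_id=seq.id,
                    frame=frame,
                    start=start,
                    end=end,
                    aa=aa,
                    missing_start=is_partial,
                    missing_stop=not has_stop,
                )
                found.setdefault((frame, start, end), orf)
    frame_order = {f: i for i, f in enumerate(FRAMES)}
    return sorted(
        found.values(),
        key=lambda o: (-len(o.aa), frame_order[o.frame], o.start),
    )


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path) -> list[NucSequence]:
    return [
        NucSequence(rec.id, str(rec.seq), rec.description.partition(" ")[2])
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_fastq(path: str | Path) -> list[NucSequence]:
    """Read FASTQ; quality strings are ignored."""
    return [
        NucSequence(rec.id, str(rec.seq), rec.description.partition(" ")[2])
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_fasta(seqs: Iterable[NucSequence], path: str | Path, wrap: int = 60) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            header = f">{s.id}" + (f" {s.description}" if s.description else "")
            fh.write(header + "\n")
            for i in range(0, len(s.bases), wrap):
                fh.write(s.bases[i : i + wrap] + "\n")


def orf_table(orfs: Iterable[OpenReadingFrame]) -> Iterator[str]:
    """TSV lines for an ORF list (header first)."""
    yield "parent_id\tframe\tstart\tend\taa_len\tmissing_start\tmissing_stop\taa"
    for o in orfs:
        yield (
            f"{o.parent_id}\t{o.frame:+d}\t{o.start}\t{o.end}\t{len(o.aa)}"
            f"\t{int(o.missing_start)}\t{int(o.missing_stop)}\t{o.aa}"
        )
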