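"""Bundled reference catalog of toxin superfamilies.

The catalog transcribes the published signal peptides and cysteine-framework
labels of the 16 *Ornithoctonus huwena* toxin gene superfamilies (I, II, X,
XI, XIII-XVIII, XX-XXV).  Superfamily XXV has no signal peptide and is
recognised by its propeptide instead.  Mature-peptide sequences are not part
of the published catalog; synthetic template matures are built by
:mod:`venomtx.simulate`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = [
    "CatalogEntry",
    "ReferenceCatalog",
    "FRAMEWORK_SCAFFOLDS",
    "SCAFFOLD_TO_CLASS",
    "NO_PROPEPTIDE_SUPERFAMILIES",
    "load_catalog",
]

#: Cysteine-framework classes I-XI: scaffold strings with "C" for a cysteine,
#: "CC" for adjacent cysteines and "-" for any run of non-cysteine residues.
FRAMEWORK_SCAFFOLDS: dict[str, str] = {
    "I": "-C-C-CC-C-C-",
    "II": "-C-C-C-C-C-C-",
    "III": "-C-C-CC-C-C-C-C-",
    "IV": "-C-C-C-CC-C-C-C-",
    "V": "-C-C-C-C-C-C-C-C-",
    "VI": "-C-C-CC-C-C-C-C-C-C-",
    "VII": "-C-C-CC-C-C-C-C-CC-C-C-",
    "VIII": "-C-C-C-C-C-",
    "IX": "-C-C-C-C-",
    "X": "-C-C-C-C-C-C-C-",
    "XI": "-C-C-C-CC-C-C-",
}

SCAFFOLD_TO_CLASS: dict[str, str] = {v: k for k, v in FRAMEWORK_SCAFFOLDS.items()}

#: Superfamilies whose precursors carry no propeptide region.
NO_PROPEPTIDE_SUPERFAMILIES = frozenset({"XI", "XIV", "XXIII", "XXIV"})


@dataclass(frozen=True)
class CatalogEntry:
    superfamily_id: str
    signal_peptide: str  # empty for superfamily XXV
    propeptide: str  # known propeptide, empty if not catalogued
    framework: str  # pattern label I..XI
    families: tuple[str, ...]


@dataclass(frozen=True)
class ReferenceCatalog:
    entries: tuple[CatalogEntry, ...]

    def __post_init__(self) -> None:
        if len(self.entries) != len({e.superfamily_id for e in self.entries}):
            raise ValueError("duplicate superfamily ids in catalog")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def entry(self, superfamily_id: str) -> CatalogEntry:
        for e in self.entries:
            if e.superfamily_id == superfamily_id:
                return e
        raise KeyError(superfamily_id)

    def signals(self) -> list[tuple[str, str]]:
        """(superfamily_id, signal peptide) pairs for entries with a signal."""
        return [(e.superfamily_id, e.signal_peptide) for e in self.entries if e.signal_peptide]

    def propeptide_keys(self) -> list[tuple[str, str]]:
        """(superfamily_id, propeptide) for signal-less entries (e.g. XXV)."""
        return [
            (e.superfamily_id, e.propeptide)
            for e in self.entries
            if not e.signal_peptide and e.propeptide
        ]


def load_catalog(path: str | Path | None = None) -> ReferenceCatalog:
    """Load the bundled superfamily catalog (or a user-supplied TSV)."""
    if path is None:
        src = resources.files("venomtx.data") / "catalog.tsv"
        text = src.read_text()
    else:
        text = Path(path).read_text()
    entries = []
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        fw = row["framework"].strip()
        if fw not in FRAMEWORK_SCAFFOLDS:
            raise ValueError(f"unknown framework label {fw!r}")
        entries.append(
            CatalogEntry(
                superfamily_id=row["superfamily"].strip(),
                signal_peptide=row["signal_peptide"].strip(),
                propeptide=row["propeptide"].strip(),
                framework=fw,
                families=tuple(f.strip() for f in row["families"].split(",") if f.strip()),
            )
        )
    return ReferenceCatalog(tuple(entries))
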