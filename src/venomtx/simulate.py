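"""Ground-truthed synthetic venom-gland transcriptome generator.

Emulates the statistical structure the downstream analysis assumes, so every
stage is testable without sequencing data:

* precursor architecture signal + (optional) propeptide + mature, with the
  published signal peptides and cysteine scaffolds of the 16 superfamilies;
* conserved cleavage motifs (the processing quadruplet motif ``X[ED][ED]R``,
  e.g. GEER/SEER, closing every propeptide);
* mutation classes observed among low-abundance isoforms: point
  substitutions (including cysteine loss), in-frame and frameshift indels,
  premature stops and stop-loss read-through elongation;
* a Zipf-like per-precursor read abundance with a long tail of single-read
  variants, and pyrosequencing-style read lengths (mean ~327 nt, 40-836 nt).

Reads are error-free substrings of their source cDNA: the downstream
assembler demands 100% identity, and sequencing-error simulation is out of
scope.  Identical seeds and configs yield byte-identical output.
"""

from __future__ import annotations

import json
import random
from bisect import bisect_left
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

from .catalog import (
    FRAMEWORK_SCAFFOLDS,
    NO_PROPEPTIDE_SUPERFAMILIES,
    ReferenceCatalog,
    load_catalog,
)
from .sequences import NucSequence, reverse_complement, translate

__all__ = [
    "ToxinTemplate",
    "MutationSpec",
    "VariantRecord",
    "BackgroundRecord",
    "SyntheticTruth",
    "ReadModel",
    "default_templates",
    "generate_variants",
    "generate_reads",
    "generate_background",
    "codon_table",
]

_MUTATION_KINDS = ("point", "insertion", "deletion", "premature_stop", "stop_loss")
_BACKGROUND_CATEGORIES = ("cellular", "no_hit", "unknown", "toxin_like_decoy")

# internal seed fixing the synthetic template set (catalog version v1)
_TEMPLATE_SEED = 7140


def codon_table() -> dict[str, str]:
    """The bundled fixed reverse-translation codon table (versioned)."""
    src = resources.files("venomtx.data") / "codon_table.json"
    return json.loads(src.read_text())["codons"]


@dataclass(frozen=True)
class ToxinTemplate:
    """A ground-truth precursor gene: signal + propeptide + mature."""

    template_id: str
    superfamily_id: str
    signal_peptide: str
    propeptide: str
    mature_peptide: str
    framework_pattern: str
    utr5: str = ""
    utr3: str = ""

    def __post_init__(self) -> None:
        if self.framework_pattern in FRAMEWORK_SCAFFOLDS:
            n_cys = self.mature_peptide.count("C")
            if not 4 <= n_cys <= 12:
                raise ValueError(
                    f"template {self.template_id}: {n_cys} cysteines outside 4-12"
                )
        if self.propeptide and not _ends_with_pqm(self.propeptide):
            raise ValueError(
                f"template {self.template_id}: propeptide does not end in a PQM"
            )

    @property
    def precursor(self) -> str:
        return self.signal_peptide + self.propeptide + self.mature_peptide

    def cds(self, codons: dict[str, str] | None = None) -> str:
        codons = codons or codon_table()
        return "".join(codons[a] for a in self.precursor) + codons["*"]

    def cdna(self, codons: dict[str, str] | None = None) -> str:
        return self.utr5 + self.cds(codons) + self.utr3


def _ends_with_pqm(propeptide: str) -> bool:
    if len(propeptide) < 4:
        return False
    tail = propeptide[-4:]
    return tail[1] in "ED" and tail[2] in "ED" and tail[3] == "R"


@dataclass(frozen=True)
class MutationSpec:
    """One mutational event applied to a template CDS.

    ``position`` is a 1-based nucleotide offset on the *template* CDS.  For
    insertions the payload is inserted before ``position``; for
    ``premature_stop`` the payload replaces the codon starting at
    ``position``; for ``stop_loss`` it replaces the stop codon.
    """

    kind: str
    position: int
    payload: str = ""
    length: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _MUTATION_KINDS:
            raise ValueError(f"unknown mutation kind {self.kind!r}")
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if self.kind == "point" and len(self.payload) != 1:
            raise ValueError("point payload must be a single base")
        if self.kind == "deletion" and self.length < 1:
            raise ValueError("deletion length must be >= 1")

    def compact(self) -> str:
        return f"{self.kind}@{self.position}:{self.payload or self.length}"

    @classmethod
    def from_compact(cls, text: str) -> "MutationSpec":
        kind, _, rest = text.partition("@")
        pos, _, tail = rest.partition(":")
        if kind == "deletion":
            return cls(kind, int(pos), "", int(tail))
        return cls(kind, int(pos), tail, len(tail) if kind == "insertion" else 0)


@dataclass
class VariantRecord:
    variant_id: str
    template_id: str
    mutations: tuple[MutationSpec, ...]
    read_count: int | None = None
    tier: str | None = None


@dataclass
class BackgroundRecord:
    seq_id: str
    category: str


@dataclass
class SyntheticTruth:
    """Ground-truth ledger for recovery tests."""

    variants: list[VariantRecord] = field(default_factory=list)
    background: list[BackgroundRecord] = field(default_factory=list)

    def record(self, variant_id: str) -> VariantRecord:
        for rec in self.variants:
            if rec.variant_id == variant_id:
                return rec
        raise KeyError(variant_id)

    def total_toxin_reads(self) -> int:
        return sum(r.read_count or 0 for r in self.variants)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("variant_id\ttemplate_id\tmutations\tread_count\ttier\n")
            for r in self.variants:
                muts = ";".join(m.compact() for m in r.mutations) or "."
                fh.write(
                    f"{r.variant_id}\t{r.template_id}\t{muts}"
                    f"\t{r.read_count if r.read_count is not None else '.'}"
                    f"\t{r.tier or '.'}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SyntheticTruth":
        truth = cls()
        with open(path) as fh:
            header = fh.readline()
            assert header.startswith("variant_id")
            for line in fh:
                vid, tid, muts, count, tier = line.rstrip("\n").split("\t")
                specs = (
                    tuple(MutationSpec.from_compact(m) for m in muts.split(";"))
                    if muts != "."
                    else ()
                )
                truth.variants.append(
                    VariantRecord(
                        vid,
                        tid,
                        specs,
                        None if count == "." else int(count),
                        None if tier == "." else tier,
                    )
                )
        return truth


@dataclass(frozen=True)
class ReadModel:
    """Pyrosequencing-style read length and abundance model.

    Lengths are drawn from a normal distribution (``mean_length``,
    ``length_sd``), clipped to ``[min_length, max_length]`` and to the source
    cDNA length.  Per-variant read counts mix a singleton mass
    (``singleton_fraction``) with a truncated Zipf body on
    ``[2, max_count]`` with exponent ``abundance_exponent``: a long tail of
    single-read variants over a heavy-tailed abundance body.
    """

    mean_length: int = 327
    min_length: int = 40
    max_length: int = 836
    length_sd: float = 60.0
    abundance_exponent: float = 1.5
    singleton_fraction: float = 0.66
    max_count: int = 3000
    both_strands: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.min_length <= self.mean_length <= self.max_length:
            raise ValueError("require min_length <= mean_length <= max_length")
        if not 0.0 <= self.singleton_fraction <= 1.0:
            raise ValueError("singleton_fraction must be in [0, 1]")
        if self.abundance_exponent <= 0 or self.max_count < 2:
            raise ValueError("invalid abundance model")

    def sample_length(self, rng: random.Random) -> int:
        L = round(rng.gauss(self.mean_length, self.length_sd))
        return max(self.min_length, min(self.max_length, L))

    def sample_count(self, rng: random.Random) -> int:
        if rng.random() < self.singleton_fraction:
            return 1
        # truncated Zipf on [2, max_count] by inverse CDF
        cum = _zipf_cumweights(self.abundance_exponent, self.max_count)
        u = rng.random() * cum[-1]
        return 2 + bisect_left(cum, u)


_zipf_cache: dict[tuple[float, int], list[float]] = {}


def _zipf_cumweights(a: float, kmax: int) -> list[float]:
    key = (a, kmax)
    if key not in _zipf_cache:
        total, cum = 0.0, []
        for k in range(2, kmax + 1):
            total += k**-a
            cum.append(total)
        _zipf_cache[key] = cum
    return _zipf_cache[key]


# ---------------------------------------------------------------------------
# templates

_HYDROPHOBIC_FILL = "AFGHIKLNPQSTVWY"  # no C, and no D/E/R (avoids spurious PQMs)
_GAP_FILL = "ADEFGHIKLNPQRSTVWY"  # any residue but C and M


def _synthetic_mature(scaffold: str, rng: random.Random) -> str:
    """Expand a framework scaffold into a concrete mature peptide.

    The N-terminal spacer avoids D/E/R so that no spurious processing motif
    precedes the first cysteine.
    """
    out: list[str] = []
    first_gap = True
    for sym in scaffold:
        if sym == "C":
            out.append("C")
            first_gap = False
        else:
            if first_gap:
                out.append("".join(rng.choices(_HYDROPHOBIC_FILL, k=rng.randint(3, 7))))
            else:
                out.append("".join(rng.choices(_GAP_FILL, k=rng.randint(2, 8))))
    return "".join(out)


def _synthetic_propeptide(rng: random.Random) -> str:
    body = "".join(rng.choices("ADEGLNPQSTV", k=rng.randint(12, 20)))
    return body + rng.choice(("GEER", "SEER", "EEER", "ADER"))


def _synthetic_utrs(rng: random.Random, codons: dict[str, str]) -> tuple[str, str]:
    """Short UTRs; the 3' UTR carries an in-frame stop so read-through
    elongation terminates within the transcript."""
    while True:
        utr5 = "".join(rng.choices("ACGT", k=24))
        if "ATG" not in utr5:  # no upstream start in any frame
            break
    sense = [c for c in codons.values() if c not in ("TAA", "TAG", "TGA")]
    utr3 = "".join(rng.choice(sense) for _ in range(4)) + "TAA"
    utr3 += "".join(rng.choices("ACGT", k=18))
    return utr5, utr3


def default_templates(
    catalog: ReferenceCatalog | None = None, seed: int = _TEMPLATE_SEED
) -> list[ToxinTemplate]:
    """One synthetic template per catalogued superfamily.

    Signal peptides (and the XXV propeptide) are the published catalog
    entries; propeptides, mature peptides and UTRs are synthetic, fixed by
    ``seed`` (versioned default)."""
    catalog = catalog or load_catalog()
    codons = codon_table()
    templates = []
    for entry in catalog:
        # str seeds hash via sha512 inside random.seed: stable across processes
        rng = random.Random(f"{seed}:{entry.superfamily_id}")
        if entry.propeptide:
            prop = entry.propeptide
        elif entry.superfamily_id in NO_PROPEPTIDE_SUPERFAMILIES:
            prop = ""
        else:
            prop = _synthetic_propeptide(rng)
        mature = _synthetic_mature(FRAMEWORK_SCAFFOLDS[entry.framework], rng)
        utr5, utr3 = _synthetic_utrs(rng, codons)
        templates.append(
            ToxinTemplate(
                template_id=entry.families[0],
                superfamily_id=entry.superfamily_id,
                signal_peptide=entry.signal_peptide,
                propeptide=prop if entry.signal_peptide else entry.propeptide,
                mature_peptide=mature,
                framework_pattern=entry.framework,
                utr5=utr5,
                utr3=utr3,
            )
        )
    return templates


# ---------------------------------------------------------------------------
# variants

_STOPS = ("TAA", "TAG", "TGA")


def _codon_at(cds: str, codon_index: int) -> str:
    return cds[3 * codon_index : 3 * codon_index + 3]


def _draw_point(cds: str, rng: random.Random) -> MutationSpec:
    n_codons = len(cds) // 3
    for _ in range(200):
        ci = rng.randint(1, n_codons - 2)  # skip ATG and stop
        off = rng.randint(0, 2)
        pos = 3 * ci + off  # 0-based
        ref = cds[pos]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        codon = _codon_at(cds, ci)
        new = codon[:off] + alt + codon[off + 1 :]
        if new not in _STOPS:
            return MutationSpec("point", pos + 1, alt)
    raise RuntimeError("could not place point mutation")


# truncating mutations (frameshifts, premature stops) are placed at or after
# this codon so the truncated isoform keeps an ORF long enough to be
# recovered by annotation: the analysis models the truncated isoforms the
# study could observe, all of which retained a detectable reading frame
_MIN_TRUNCATION_CODON = 45


def _frameshift_observable(cds: str, spec: MutationSpec) -> bool:
    """A frameshift indel is observable as such only if translation runs at
    least a few shifted codons past the indel before terminating; one that
    terminates immediately is indistinguishable from a nonsense mutation."""
    from .sequences import translate as _translate

    mutated = apply_mutations(cds, [spec])
    aa = _translate(mutated)
    stop_idx = aa.find("*")
    orf_nt = (stop_idx + 1) * 3 if stop_idx != -1 else len(mutated)
    return orf_nt - spec.position >= 12


def _draw_insertion(cds: str, rng: random.Random) -> MutationSpec:
    codons = codon_table()
    sense = [c for c in codons.values() if c not in _STOPS]
    n_codons = len(cds) // 3
    if rng.random() < 0.5:  # in-frame, at a codon boundary
        ci = rng.randint(2, n_codons - 3)
        payload = "".join(rng.choice(sense) for _ in range(rng.choice((1, 2))))
        return MutationSpec("insertion", 3 * ci + 1, payload)
    lo = min(3 * _MIN_TRUNCATION_CODON + 1, len(cds) - 12)
    for _ in range(100):
        pos = rng.randint(lo, len(cds) - 9)
        payload = "".join(rng.choices("ACGT", k=rng.choice((1, 2))))
        spec = MutationSpec("insertion", pos, payload)
        if _frameshift_observable(cds, spec):
            return spec
    return spec


def _draw_deletion(cds: str, rng: random.Random) -> MutationSpec:
    n_codons = len(cds) // 3
    if rng.random() < 0.5:  # in-frame: whole codons
        length = rng.choice((3, 6))
        ci = rng.randint(2, n_codons - 3 - length // 3)
        return MutationSpec("deletion", 3 * ci + 1, "", length)
    length = rng.choice((1, 2))
    lo = min(3 * _MIN_TRUNCATION_CODON + 1, len(cds) - 12 - length)
    for _ in range(100):
        pos = rng.randint(lo, len(cds) - 9 - length)
        spec = MutationSpec("deletion", pos, "", length)
        if _frameshift_observable(cds, spec):
            return spec
    return spec


def _draw_premature_stop(cds: str, rng: random.Random) -> MutationSpec:
    """Nonsense mutation: a single-base change turning a sense codon into a
    stop (codons without a one-substitution stop neighbour are not drawn)."""
    n_codons = len(cds) // 3
    lo = min(_MIN_TRUNCATION_CODON, n_codons - 4)
    candidates = []
    for ci in range(lo, n_codons - 3):
        codon = _codon_at(cds, ci)
        stops = sorted(
            s for s in _STOPS if sum(a != b for a, b in zip(s, codon)) == 1
        )
        if stops:
            candidates.append((ci, stops))
    if not candidates:  # fall back to the nearest-stop replacement
        ci = rng.randint(lo, n_codons - 4)
        codon = _codon_at(cds, ci)
        stop = min(_STOPS, key=lambda s: (sum(a != b for a, b in zip(s, codon)), s))
        return MutationSpec("premature_stop", 3 * ci + 1, stop)
    ci, stops = candidates[rng.randrange(len(candidates))]
    return MutationSpec("premature_stop", 3 * ci + 1, rng.choice(stops))


def _draw_stop_loss(cds: str, rng: random.Random) -> MutationSpec:
    return MutationSpec("stop_loss", len(cds) - 2, "TGG")


_DRAWERS = {
    "point": _draw_point,
    "insertion": _draw_insertion,
    "deletion": _draw_deletion,
    "premature_stop": _draw_premature_stop,
    "stop_loss": _draw_stop_loss,
}

#: Relative superfamily sizes (precursor counts) observed in the study:
#: isoform diversity is strongly skewed toward a few large superfamilies.
PUBLISHED_SUPERFAMILY_SIZES: dict[str, int] = {
    "I": 199, "II": 133, "XVIII": 113, "XVI": 66, "XIV": 40, "X": 14,
    "XXV": 10, "XI": 9, "XXIV": 9, "XVII": 7, "XV": 6, "XX": 6,
    "XXI": 5, "XXIII": 4, "XXII": 2, "XIII": 1,
}


def profile_variant_counts(
    templates: Sequence[ToxinTemplate], total: int
) -> dict[str, int]:
    """Per-template variant counts proportional to the published superfamily
    size profile, scaled to ``total`` (largest-remainder rounding, minimum
    one variant per template)."""
    weights = [
        PUBLISHED_SUPERFAMILY_SIZES.get(t.superfamily_id, 1) for t in templates
    ]
    wsum = sum(weights)
    raw = [total * w / wsum for w in weights]
    counts = [max(1, int(r)) for r in raw]
    remainders = sorted(
        range(len(templates)), key=lambda i: raw[i] - int(raw[i]), reverse=True
    )
    k = 0
    while sum(counts) < total and k < len(remainders):
        counts[remainders[k]] += 1
        k += 1
    return {t.template_id: c for t, c in zip(templates, counts)}

DEFAULT_MUTATION_RATES: dict[str, float] = {
    "point": 0.55,
    "insertion": 0.08,
    "deletion": 0.08,
    "premature_stop": 0.05,
    "stop_loss": 0.03,
}


def apply_mutations(cds: str, specs: Sequence[MutationSpec]) -> str:
    """Apply specs to a CDS (positions refer to the unmutated CDS)."""
    out = cds
    for spec in sorted(specs, key=lambda s: -s.position):
        p = spec.position - 1
        if spec.kind == "point":
            out = out[:p] + spec.payload + out[p + 1 :]
        elif spec.kind == "insertion":
            out = out[:p] + spec.payload + out[p:]
        elif spec.kind == "deletion":
            out = out[:p] + out[p + spec.length :]
        elif spec.kind in ("premature_stop", "stop_loss"):
            out = out[:p] + spec.payload + out[p + 3 :]
    return out


def generate_variants(
    templates: Sequence[ToxinTemplate],
    n_variants_per_template: int | dict[str, int],
    mutation_rates: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[list[NucSequence], SyntheticTruth]:
    """Generate mutated isoform cDNAs plus their ground-truth ledger.

    Each variant derives from its template CDS by an independently drawn set
    of mutation specs (one Bernoulli trial per mutation class); variants with
    no drawn mutation reproduce the template exactly (canonical isoforms).
    Mutations are spaced at least six nucleotides apart.

    ``n_variants_per_template`` is either a single count applied to every
    template or a per-template-id mapping (see
    :func:`profile_variant_counts` for the published skewed size profile).
    """
    if not templates:
        raise ValueError("templates must be non-empty")
    rates = dict(DEFAULT_MUTATION_RATES if mutation_rates is None else mutation_rates)
    for kind, rate in rates.items():
        if kind not in _MUTATION_KINDS:
            raise ValueError(f"unknown mutation kind {kind!r}")
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate for {kind!r} outside [0, 1]")
    rng = random.Random(seed)
    codons = codon_table()
    out: list[NucSequence] = []
    truth = SyntheticTruth()
    for tpl in templates:
        cds = tpl.cds(codons)
        if isinstance(n_variants_per_template, dict):
            n_this = n_variants_per_template.get(tpl.template_id, 0)
        else:
            n_this = n_variants_per_template
        for i in range(n_this):
            specs: list[MutationSpec] = []
            for kind in _MUTATION_KINDS:
                if rng.random() < rates.get(kind, 0.0):
                    for _ in range(50):
                        spec = _DRAWERS[kind](cds, rng)
                        if all(abs(spec.position - s.position) >= 6 for s in specs):
                            specs.append(spec)
                            break
            vid = f"{tpl.template_id}_v{i + 1}"
            mutated = apply_mutations(cds, specs)
            out.append(
                NucSequence(vid, tpl.utr5 + mutated + tpl.utr3, f"template={tpl.template_id}")
            )
            truth.variants.append(VariantRecord(vid, tpl.template_id, tuple(specs)))
    return out, truth


# ---------------------------------------------------------------------------
# reads


def generate_reads(
    variants: Sequence[NucSequence],
    truth: SyntheticTruth,
    model: ReadModel,
) -> list[NucSequence]:
    """Emit error-free substring reads; records counts and tiers in ``truth``.

    Read count per variant follows the abundance model; every read is an
    exact substring of its source cDNA (reverse-complemented with
    probability 1/2 when ``model.both_strands``); lengths are clipped to
    ``[min_length, max_length]`` and to the cDNA length.
    """
    if not variants:
        raise ValueError("variant set must be non-empty")
    from .variants import assign_tier  # tier thresholds live with the variants module

    rng = random.Random(model.seed)
    reads: list[NucSequence] = []
    for var in variants:
        rec = truth.record(var.id)
        count = model.sample_count(rng)
        rec.read_count = count
        rec.tier = assign_tier(count).tier
        for j in range(count):
            L = min(model.sample_length(rng), len(var.bases))
            start = rng.randint(0, len(var.bases) - L)
            sub = var.bases[start : start + L]
            if model.both_strands and rng.random() < 0.5:
                sub = reverse_complement(sub)
            reads.append(NucSequence(f"{var.id}_r{j + 1}", sub, f"source={var.id}"))
    return reads


# ---------------------------------------------------------------------------
# background transcripts

_DEFAULT_MIX = {"cellular": 0.44, "no_hit": 0.20, "unknown": 0.07, "toxin_like_decoy": 0.29}


def _load_reference_proteins(name: str) -> list[tuple[str, str]]:
    src = resources.files("venomtx.data") / name
    seqs, sid, buf = [], None, []
    for line in src.read_text().splitlines():
        if line.startswith(">"):
            if sid:
                seqs.append((sid, "".join(buf)))
            sid, buf = line[1:].split()[0], []
        else:
            buf.append(line.strip())
    if sid:
        seqs.append((sid, "".join(buf)))
    return seqs


def cellular_reference() -> list[tuple[str, str]]:
    """Bundled synthetic housekeeping-style proteins (cellular search db)."""
    return _load_reference_proteins("cellular_reference.synthetic.fasta")


def unannotated_reference() -> list[tuple[str, str]]:
    """Bundled synthetic proteins of unknown function (unannotated db)."""
    return _load_reference_proteins("unannotated_reference.synthetic.fasta")


def _cellular_like(rng: random.Random, codons: dict[str, str]) -> str:
    """Block-shuffled housekeeping ORF: 20-codon blocks of a bundled cellular
    protein in permuted order.  Retains local similarity to the cellular
    reference db while guaranteeing no toxin-catalog hit (no cysteine-rich
    region exists to begin with)."""
    _, prot = rng.choice(cellular_reference())
    cds = "".join(codons[a] for a in prot)
    blocks = [cds[i : i + 60] for i in range(0, len(cds), 60)]
    rng.shuffle(blocks)
    return "ATG" + "".join(blocks) + "TAA"


def _no_orf_random(rng: random.Random, min_aa: int = 40) -> str:
    """Random-composition sequence with no ORF (complete or partial) of
    ``min_aa`` codons in any frame."""
    from .sequences import find_orfs

    while True:
        seq = "".join(rng.choices("ACGT", k=rng.randint(150, 400)))
        if not find_orfs(NucSequence("x", seq), min_aa=min_aa):
            return seq


def _unknown_like(rng: random.Random, codons: dict[str, str]) -> str:
    _, prot = rng.choice(unannotated_reference())
    cds = list("".join(codons[a] for a in prot))
    for i in range(3, len(cds) - 3):  # ~2% point noise
        if rng.random() < 0.02:
            cds[i] = rng.choice("ACGT")
    return "ATG" + "".join(cds[3:]) + "TAA"


def _decoy_like(rng: random.Random, codons: dict[str, str]) -> str:
    """Cysteine-rich ORF with no catalog signal: a putative-toxin decoy."""
    n_cys = rng.randint(4, 8)
    aa = ["M"] + list("".join(rng.choices(_GAP_FILL, k=rng.randint(4, 8))))
    for _ in range(n_cys):
        aa.append("C")
        aa.extend(rng.choices(_GAP_FILL, k=rng.randint(2, 6)))
    prot = "".join(aa)
    return "".join(codons[a] for a in prot) + "TAA"


def generate_background(
    n: int,
    category_mix: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[list[NucSequence], list[BackgroundRecord]]:
    """Generate non-toxin background transcripts with per-sequence truth.

    Default mix mirrors the study's EST classification shape: 44%
    cellular-like, 20% no-hit-like, 7% unknown-like, remainder cysteine-rich
    decoys.  Categories are drawn i.i.d. from the mix.
    """
    mix = dict(_DEFAULT_MIX if category_mix is None else category_mix)
    for cat, p in mix.items():
        if cat not in _BACKGROUND_CATEGORIES:
            raise ValueError(f"unknown background category {cat!r}")
        if p < 0:
            raise ValueError(f"negative proportion for {cat!r}")
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("category proportions must sum to 1")
    rng = random.Random(seed)
    codons = codon_table()
    cats = sorted(mix)
    weights = [mix[c] for c in cats]
    makers = {
        "cellular": _cellular_like,
        "unknown": _unknown_like,
        "toxin_like_decoy": _decoy_like,
    }
    seqs: list[NucSequence] = []
    records: list[BackgroundRecord] = []
    for i in range(n):
        cat = rng.choices(cats, weights=weights)[0]
        if cat == "no_hit":
            bases = _no_orf_random(rng)
        else:
            bases = makers[cat](rng, codons)
        sid = f"BG{i + 1:05d}"
        seqs.append(NucSequence(sid, bases, f"category={cat}"))
        records.append(BackgroundRecord(sid, cat))
    return seqs, records
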