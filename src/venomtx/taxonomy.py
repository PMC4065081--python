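"""Superfamily / family / subfamily taxonomy of toxin precursors.

Superfamilies are defined by signal-peptide similarity: a precursor whose
signal reaches the identity threshold (default 0.70) against a catalogued
signal joins that superfamily; the remainder are clustered into NEW-k
superfamilies by single linkage at the same threshold.  Signal-less
catalogue entries (superfamily XXV) are recognised by their propeptide.
Precursors without any signal evidence are deferred to a mature-peptide
nearest-neighbour assignment and flagged.

Within a superfamily, families are single-linkage clusters of full-precursor
identity (default 0.60) and subfamilies of mature-peptide identity (default
0.90).  Identity is matches / alignment-length under global alignment with
the same substitution matrix and gap costs as the similarity search.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .annotate import AnnotationParams, PrecursorAnnotation, _aligner
from .catalog import ReferenceCatalog

__all__ = [
    "TaxonomyThresholds",
    "TaxonomyAssignment",
    "global_identity",
    "assign_superfamilies",
    "cluster_families",
    "assign_taxonomy",
]


@dataclass(frozen=True)
class TaxonomyThresholds:
    superfamily: float = 0.70
    family: float = 0.60
    subfamily: float = 0.90

    def __post_init__(self) -> None:
        for v in (self.superfamily, self.family, self.subfamily):
            if not 0.0 < v <= 1.0:
                raise ValueError("thresholds must lie in (0, 1]")


@dataclass
class TaxonomyAssignment:
    precursor_id: str
    superfamily_id: str
    family_id: str = ""
    subfamily_id: str = ""
    identity_to_nearest: float = 0.0
    flagged: bool = False  # assigned via mature nearest-neighbour


def global_identity(a: str, b: str, params: AnnotationParams = AnnotationParams()) -> float:
    """Identity = matches / alignment length under global alignment."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    al = _aligner(params.matrix, params.gap_open, params.gap_extend, "global")
    aln = al.align(a, b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def _single_linkage_components(
    n: int, pairs: list[tuple[int, int]]
) -> list[list[int]]:
    """Connected components of the threshold graph, each sorted; component
    order follows the smallest member index (input order)."""
    if n == 0:
        return []
    rows = [p[0] for p in pairs] + [p[1] for p in pairs]
    cols = [p[1] for p in pairs] + [p[0] for p in pairs]
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    comps: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        comps.setdefault(int(lab), []).append(i)
    return sorted(comps.values(), key=lambda c: c[0])


def assign_superfamilies(
    annotations: Sequence[PrecursorAnnotation],
    catalog: ReferenceCatalog,
    threshold: float = 0.70,
    template_matures: Sequence[tuple[str, str]] | None = None,
    params: AnnotationParams = AnnotationParams(),
) -> list[TaxonomyAssignment]:
    """Superfamily-level assignment for segmented precursors.

    ``template_matures`` — (superfamily_id, mature peptide) references used
    for the nearest-neighbour fallback when the signal is missing.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    out: list[TaxonomyAssignment | None] = [None] * len(annotations)
    unassigned: list[int] = []
    deferred: list[int] = []
    for i, ann in enumerate(annotations):
        if ann.signal:
            best_sf, best_ident = None, -1.0
            for sf, sig in catalog.signals():
                ident = global_identity(ann.signal, sig, params)
                if ident > best_ident:
                    best_sf, best_ident = sf, ident
            if best_ident >= threshold:
                out[i] = TaxonomyAssignment(ann.precursor_id, best_sf, identity_to_nearest=best_ident)
            else:
                unassigned.append(i)
        elif ann.matched_superfamily is not None:
            # signal-less catalogue entry matched by propeptide (e.g. XXV)
            ref = catalog.entry(ann.matched_superfamily).propeptide
            ident = global_identity(ann.propeptide, ref, params) if ann.propeptide else 1.0
            out[i] = TaxonomyAssignment(
                ann.precursor_id, ann.matched_superfamily, identity_to_nearest=ident
            )
        else:
            deferred.append(i)
    # NEW-k superfamilies: single linkage among unassigned signals
    if unassigned:
        pairs = []
        for ai in range(len(unassigned)):
            for bi in range(ai + 1, len(unassigned)):
                a, b = unassigned[ai], unassigned[bi]
                if (
                    global_identity(annotations[a].signal, annotations[b].signal, params)
                    >= threshold
                ):
                    pairs.append((ai, bi))
        for k, comp in enumerate(_single_linkage_components(len(unassigned), pairs), 1):
            for ci in comp:
                i = unassigned[ci]
                out[i] = TaxonomyAssignment(
                    annotations[i].precursor_id, f"NEW-{k}", identity_to_nearest=0.0
                )
    # deferred: mature-peptide nearest neighbour against references
    refs: list[tuple[str, str]] = list(template_matures or [])
    for i, asn in enumerate(out):
        if asn is not None and annotations[i].mature:
            refs.append((asn.superfamily_id, annotations[i].mature))
    for i in deferred:
        best_sf, best_ident = "NEW-unplaced", 0.0
        for sf, mat in refs:
            ident = global_identity(annotations[i].mature, mat, params)
            if ident > best_ident:
                best_sf, best_ident = sf, ident
        out[i] = TaxonomyAssignment(
            annotations[i].precursor_id, best_sf, identity_to_nearest=best_ident, flagged=True
        )
    return [a for a in out if a is not None]


def cluster_families(
    members: Sequence[tuple[str, str, str]],
    family_threshold: float = 0.60,
    subfamily_threshold: float = 0.90,
    params: AnnotationParams = AnnotationParams(),
) -> dict[str, tuple[str, str]]:
    """Family / subfamily labels for one superfamily.

    ``members`` — (precursor_id, precursor_aa, mature_aa) tuples.  Families:
    single linkage on full-precursor identity; subfamilies (within a family):
    single linkage on mature identity.  Labels are ordered by descending
    cluster size, ties by lexicographically smallest member id.
    """
    if not members:
        raise ValueError("members must be non-empty")
    n = len(members)
    fam_pairs = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if global_identity(members[i][1], members[j][1], params) >= family_threshold
    ]
    fam_comps = _single_linkage_components(n, fam_pairs)
    fam_comps.sort(key=lambda c: (-len(c), min(members[i][0] for i in c)))
    labels: dict[str, tuple[str, str]] = {}
    for fi, comp in enumerate(fam_comps, 1):
        sub_pairs = [
            (a, b)
            for a in range(len(comp))
            for b in range(a + 1, len(comp))
            if global_identity(members[comp[a]][2], members[comp[b]][2], params)
            >= subfamily_threshold
        ]
        sub_comps = _single_linkage_components(len(comp), sub_pairs)
        sub_comps.sort(key=lambda c: (-len(c), min(members[comp[i]][0] for i in c)))
        for si, sub in enumerate(sub_comps, 1):
            for k in sub:
                labels[members[comp[k]][0]] = (f"F{fi}", f"F{fi}.s{si}")
    return labels


def assign_taxonomy(
    annotations: Sequence[PrecursorAnnotation],
    catalog: ReferenceCatalog,
    thresholds: TaxonomyThresholds = TaxonomyThresholds(),
    template_matures: Sequence[tuple[str, str]] | None = None,
    params: AnnotationParams = AnnotationParams(),
) -> list[TaxonomyAssignment]:
    """Full nested assignment: superfamily, then families and subfamilies."""
    assignments = assign_superfamilies(
        annotations, catalog, thresholds.superfamily, template_matures, params
    )
    by_id = {ann.precursor_id: ann for ann in annotations}
    groups: dict[str, list[TaxonomyAssignment]] = {}
    for asn in assignments:
        groups.setdefault(asn.superfamily_id, []).append(asn)
    for sf, group in groups.items():
        members = [
            (a.precursor_id, by_id[a.precursor_id].precursor, by_id[a.precursor_id].mature)
            for a in group
        ]
        labels = cluster_families(members, thresholds.family, thresholds.subfamily, params)
        for a in group:
            a.family_id, a.subfamily_id = labels[a.precursor_id]
    return assignments
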