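"""End-to-end pipeline orchestration with per-stage manifests and resume.

Stage order: simulate -> assemble -> annotate -> taxonomy -> variants ->
evolve -> report.  Each stage writes its outputs plus a manifest (input
checksums, parameters, output list) into the run directory; re-running with
an unchanged configuration skips stages whose manifests are still valid.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
import yaml

from . import simulate as sim
from .annotate import AnnotationParams, annotate_transcripts
from .assembly import AssemblyParams, assemble
from .catalog import ReferenceCatalog, load_catalog
from .evolution import (
    bootstrap_support,
    classify_selection,
    dnds,
    fisher_positive_selection,
    ng_counts,
    p_distance_matrix,
)
from .report import build_report, write_report
from .sequences import NucSequence, read_fasta, write_fasta
from .taxonomy import TaxonomyThresholds, assign_taxonomy
from .variants import (
    assign_tier,
    choose_reference,
    classify_variant_events,
    codon_alignment,
    project_onto_reference,
)

__all__ = [
    "PipelineConfig",
    "load_config",
    "run_pipeline",
    "evaluate_superfamily_recovery",
    "evaluate_event_recovery",
    "load_precursor_table",
]

log = logging.getLogger("venomtx")

STAGES = ("simulate", "assemble", "annotate", "taxonomy", "variants", "evolve", "report")


@dataclass(frozen=True)
class PipelineConfig:
    """Single configuration object for a full synthetic run."""

    seed: int = 1
    n_variants_per_template: int = 12
    #: when True, distribute 16 * n_variants_per_template variants over the
    #: templates following the published skewed superfamily size profile
    skewed_superfamily_sizes: bool = True
    n_background: int = 300
    mutation_rates: dict = field(default_factory=lambda: dict(sim.DEFAULT_MUTATION_RATES))
    read_model: sim.ReadModel = field(default_factory=sim.ReadModel)
    assembly: AssemblyParams = field(default_factory=AssemblyParams)
    annotation: AnnotationParams = field(default_factory=AnnotationParams)
    taxonomy: TaxonomyThresholds = field(default_factory=TaxonomyThresholds)
    bootstrap_replicates: int = 500
    max_tree_taxa: int = 24
    include_singletons: bool = True
    stages: tuple[str, ...] = STAGES

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML (or JSON) pipeline configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = dict(raw)
    if "read_model" in kwargs:
        kwargs["read_model"] = sim.ReadModel(**kwargs["read_model"])
    if "assembly" in kwargs:
        kwargs["assembly"] = AssemblyParams(**kwargs["assembly"])
    if "annotation" in kwargs:
        kwargs["annotation"] = AnnotationParams(**kwargs["annotation"])
    if "taxonomy" in kwargs:
        kwargs["taxonomy"] = TaxonomyThresholds(**kwargs["taxonomy"])
    if "stages" in kwargs:
        kwargs["stages"] = tuple(kwargs["stages"])
    return PipelineConfig(**kwargs)


# ---------------------------------------------------------------------------
# manifests


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _manifest_path(out_dir: Path, stage: str) -> Path:
    return out_dir / f"{stage}.manifest.json"


def _stage_fresh(out_dir: Path, stage: str, params: dict, inputs: list[Path]) -> bool:
    mpath = _manifest_path(out_dir, stage)
    if not mpath.exists():
        return False
    try:
        manifest = json.loads(mpath.read_text())
    except json.JSONDecodeError:
        return False
    if manifest.get("params") != json.loads(json.dumps(params)):
        return False
    for p in inputs:
        if not p.exists() or manifest.get("inputs", {}).get(p.name) != _sha256(p):
            return False
    return all((out_dir / name).exists() for name in manifest.get("outputs", []))


def _write_manifest(
    out_dir: Path, stage: str, params: dict, inputs: list[Path], outputs: list[str]
) -> None:
    manifest = {
        "stage": stage,
        "params": params,
        "inputs": {p.name: _sha256(p) for p in inputs},
        "outputs": outputs,
    }
    _manifest_path(out_dir, stage).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _require(out_dir: Path, stage: str, *names: str) -> None:
    missing = [n for n in names if not (out_dir / n).exists()]
    if missing:
        raise RuntimeError(f"stage '{stage}' missing inputs: {', '.join(missing)}")


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg: PipelineConfig, out_dir: Path) -> None:
    params = {
        "seed": cfg.seed,
        "n_variants_per_template": cfg.n_variants_per_template,
        "skewed_superfamily_sizes": cfg.skewed_superfamily_sizes,
        "n_background": cfg.n_background,
        "mutation_rates": cfg.mutation_rates,
        "read_model": dataclasses.asdict(cfg.read_model),
    }
    if _stage_fresh(out_dir, "simulate", params, []):
        log.info("simulate: up to date, skipping")
        return
    templates = sim.default_templates()
    n_variants: int | dict[str, int] = cfg.n_variants_per_template
    if cfg.skewed_superfamily_sizes:
        n_variants = sim.profile_variant_counts(
            templates, cfg.n_variants_per_template * len(templates)
        )
    variants, truth = sim.generate_variants(
        templates, n_variants, cfg.mutation_rates, seed=cfg.seed
    )
    model = dataclasses.replace(cfg.read_model, seed=cfg.seed + 1)
    reads = sim.generate_reads(variants, truth, model)
    background, bg_records = sim.generate_background(cfg.n_background, seed=cfg.seed + 2)
    truth.background = bg_records
    write_fasta(variants, out_dir / "variants.fasta")
    write_fasta(reads + background, out_dir / "reads.fasta")
    truth.to_tsv(out_dir / "truth.tsv")
    with open(out_dir / "background.tsv", "w") as fh:
        fh.write("seq_id\tcategory\n")
        for rec in bg_records:
            fh.write(f"{rec.seq_id}\t{rec.category}\n")
    (out_dir / "config_echo.json").write_text(
        json.dumps(cfg.to_dict(), indent=2, sort_keys=True, default=str)
    )
    outputs = ["variants.fasta", "reads.fasta", "truth.tsv", "background.tsv", "config_echo.json"]
    _write_manifest(out_dir, "simulate", params, [], outputs)
    log.info("simulate: %d variants, %d toxin reads, %d background", len(variants), len(reads), len(background))


def _stage_assemble(cfg: PipelineConfig, out_dir: Path) -> None:
    params = {
        "min_overlap": cfg.assembly.min_overlap,
        "include_singletons": cfg.include_singletons,
    }
    inputs = [out_dir / "reads.fasta"]
    _require(out_dir, "assemble", "reads.fasta")
    if _stage_fresh(out_dir, "assemble", params, inputs):
        log.info("assemble: up to date, skipping")
        return
    reads = read_fasta(out_dir / "reads.fasta")
    contigs, singletons = assemble(reads, cfg.assembly)
    transcripts = contigs + (singletons if cfg.include_singletons else [])
    write_fasta(
        [
            NucSequence(c.contig_id, c.bases, f"read_count={c.read_count}")
            for c in transcripts
        ],
        out_dir / "transcripts.fasta",
    )
    with open(out_dir / "membership.tsv", "w") as fh:
        fh.write("transcript_id\tread_id\n")
        for c in transcripts:
            for rid in c.member_read_ids:
                fh.write(f"{c.contig_id}\t{rid}\n")
    outputs = ["transcripts.fasta", "membership.tsv"]
    _write_manifest(out_dir, "assemble", params, inputs, outputs)
    log.info("assemble: %d contigs, %d singletons", len(contigs), len(singletons))


def _stage_annotate(cfg: PipelineConfig, out_dir: Path) -> None:
    params = {"annotation": dataclasses.asdict(cfg.annotation)}
    inputs = [out_dir / "transcripts.fasta"]
    _require(out_dir, "annotate", "transcripts.fasta")
    if _stage_fresh(out_dir, "annotate", params, inputs):
        log.info("annotate: up to date, skipping")
        return
    catalog = load_catalog()
    templates = sim.default_templates(catalog)
    toxin_db = [(t.template_id, t.precursor) for t in templates]
    cellular_db = sim.cellular_reference()
    unannotated_db = sim.unannotated_reference()
    transcripts = read_fasta(out_dir / "transcripts.fasta")
    annotations = annotate_transcripts(
        transcripts, catalog, toxin_db, cellular_db, unannotated_db, cfg.annotation
    )
    with open(out_dir / "categories.tsv", "w") as fh:
        fh.write("transcript_id\tcategory\tbest_hit\tscore\tevalue_like\n")
        for a in annotations:
            hit = a.best_hit
            fh.write(
                f"{a.transcript_id}\t{a.category}"
                f"\t{hit.subject_id if hit else '.'}"
                f"\t{hit.score if hit else '.'}"
                f"\t{hit.evalue_like if hit else '.'}\n"
            )
    with open(out_dir / "precursors.tsv", "w") as fh:
        fh.write(
            "transcript_id\tsignal\tpropeptide\tmature\tsignal_evidence"
            "\tmotifs\tframe\torf_start\torf_end\tmissing_start\tcds\n"
        )
        for a in annotations:
            if a.precursor is None or a.orf is None:
                continue
            p = a.precursor
            t = next(x for x in transcripts if x.id == a.transcript_id)
            cds = _orf_nt(t, a.orf)
            fh.write(
                f"{a.transcript_id}\t{p.signal}\t{p.propeptide}\t{p.mature}"
                f"\t{p.signal_evidence}\t{','.join(p.cleavage_motifs) or '.'}"
                f"\t{a.orf.frame:+d}\t{a.orf.start}\t{a.orf.end}"
                f"\t{int(a.orf.missing_start)}\t{cds}\n"
            )
    with open(out_dir / "frameworks.tsv", "w") as fh:
        fh.write("transcript_id\tscaffold\tn_cys\tpattern_class\tparity\n")
        for a in annotations:
            if a.framework is None:
                continue
            f = a.framework
            fh.write(f"{a.transcript_id}\t{f.scaffold}\t{f.n_cys}\t{f.pattern_class}\t{f.parity}\n")
    outputs = ["categories.tsv", "precursors.tsv", "frameworks.tsv"]
    _write_manifest(out_dir, "annotate", params, inputs, outputs)
    n_tox = sum(a.category == "Toxin_like" for a in annotations)
    log.info("annotate: %d transcripts, %d toxin-like", len(annotations), n_tox)


def _orf_nt(transcript: NucSequence, orf) -> str:
    span = transcript.bases[orf.start - 1 : orf.end]
    if orf.frame < 0:
        from .sequences import reverse_complement

        span = reverse_complement(span)
    return span


def _read_precursors(out_dir: Path) -> list[dict]:
    rows = []
    with open(out_dir / "precursors.tsv") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            rows.append(dict(zip(header, line.rstrip("\n").split("\t"))))
    return rows


def _stage_taxonomy(cfg: PipelineConfig, out_dir: Path) -> None:
    params = {"taxonomy": dataclasses.asdict(cfg.taxonomy)}
    inputs = [out_dir / "precursors.tsv"]
    _require(out_dir, "taxonomy", "precursors.tsv")
    if _stage_fresh(out_dir, "taxonomy", params, inputs):
        log.info("taxonomy: up to date, skipping")
        return
    from .annotate import PrecursorAnnotation

    catalog = load_catalog()
    templates = sim.default_templates(catalog)
    template_matures = [(t.superfamily_id, t.mature_peptide) for t in templates]
    rows = _read_precursors(out_dir)
    annotations = []
    for r in rows:
        try:
            annotations.append(
                PrecursorAnnotation(
                    precursor_id=r["transcript_id"],
                    signal=r["signal"],
                    propeptide=r["propeptide"],
                    mature=r["mature"],
                    signal_evidence=r["signal_evidence"],
                    matched_superfamily=None,
                )
            )
        except ValueError:
            continue
    # restore propeptide-key matches (signal-less catalogue superfamilies)
    refreshed = []
    from .annotate import segment_precursor

    for ann in annotations:
        refreshed.append(
            segment_precursor(
                ann.precursor, catalog, ann.precursor_id,
                missing_start=(ann.signal_evidence == "missing" and not ann.precursor.startswith("M")),
            )
        )
    assignments = assign_taxonomy(
        refreshed, catalog, cfg.taxonomy, template_matures, cfg.annotation
    )
    with open(out_dir / "assignments.tsv", "w") as fh:
        fh.write("precursor_id\tsuperfamily\tfamily\tsubfamily\tidentity_to_nearest\tflagged\n")
        for a in assignments:
            fh.write(
                f"{a.precursor_id}\t{a.superfamily_id}\t{a.family_id}\t{a.subfamily_id}"
                f"\t{a.identity_to_nearest:.4f}\t{int(a.flagged)}\n"
            )
    outputs = ["assignments.tsv"]
    _write_manifest(out_dir, "taxonomy", params, inputs, outputs)
    log.info("taxonomy: %d precursors assigned", len(assignments))


def _read_tsv(path: Path) -> list[dict]:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            rows.append(dict(zip(header, line.rstrip("\n").split("\t"))))
    return rows


def _transcript_read_counts(out_dir: Path) -> dict[str, int]:
    counts: dict[str, int] = {}
    for row in _read_tsv(out_dir / "membership.tsv"):
        counts[row["transcript_id"]] = counts.get(row["transcript_id"], 0) + 1
    return counts


def _stage_variants(cfg: PipelineConfig, out_dir: Path) -> None:
    params = {}
    inputs = [out_dir / "precursors.tsv", out_dir / "assignments.tsv", out_dir / "membership.tsv"]
    _require(out_dir, "variants", *[p.name for p in inputs])
    if _stage_fresh(out_dir, "variants", params, inputs):
        log.info("variants: up to date, skipping")
        return
    catalog = load_catalog()
    rows = _read_precursors(out_dir)
    cds_of = {r["transcript_id"]: r["cds"] for r in rows}
    asn = {r["precursor_id"]: r for r in _read_tsv(out_dir / "assignments.tsv")}
    counts = _transcript_read_counts(out_dir)
    groups: dict[tuple[str, str], list[str]] = {}
    for pid, a in asn.items():
        if pid in cds_of:
            groups.setdefault((a["superfamily"], a["family"]), []).append(pid)
    from .annotate import segment_precursor
    from .sequences import translate

    with open(out_dir / "events.tsv", "w") as ev, open(out_dir / "tiers.tsv", "w") as tf:
        ev.write("variant_id\treference_id\tkind\tnt_position\tdetail\n")
        tf.write("transcript_id\tread_count\ttier\n")
        for pid in sorted(cds_of):
            c = counts.get(pid, 1)
            tf.write(f"{pid}\t{c}\t{assign_tier(c).tier}\n")
        for (sf, fam), members in sorted(groups.items()):
            ref_id, ref_cds = choose_reference(
                [(pid, cds_of[pid], counts.get(pid, 1)) for pid in members]
            )
            try:
                ref_aa = translate(ref_cds).rstrip("*")
                ref_ann = segment_precursor(ref_aa, catalog, ref_id) if ref_aa else None
            except ValueError:
                ref_ann = None
            for pid in sorted(members):
                if pid == ref_id:
                    continue
                call = classify_variant_events(cds_of[pid], ref_cds, ref_ann, pid, ref_id)
                if call.flagged_unalignable:
                    ev.write(f"{pid}\t{ref_id}\tunalignable\t.\tidentity={call.identity:.3f}\n")
                    continue
                for e in call.events:
                    ev.write(f"{pid}\t{ref_id}\t{e.kind}\t{e.nt_position}\t{e.detail}\n")
    outputs = ["events.tsv", "tiers.tsv"]
    _write_manifest(out_dir, "variants", params, inputs, outputs)
    log.info("variants: events written for %d families", len(groups))


def _stage_evolve(cfg: PipelineConfig, out_dir: Path) -> None:
    params = {"bootstrap_replicates": cfg.bootstrap_replicates, "max_tree_taxa": cfg.max_tree_taxa}
    inputs = [out_dir / "precursors.tsv", out_dir / "assignments.tsv", out_dir / "membership.tsv"]
    _require(out_dir, "evolve", *[p.name for p in inputs])
    if _stage_fresh(out_dir, "evolve", params, inputs):
        log.info("evolve: up to date, skipping")
        return
    rows = _read_precursors(out_dir)
    cds_of = {r["transcript_id"]: r["cds"] for r in rows}
    asn = _read_tsv(out_dir / "assignments.tsv")
    counts = _transcript_read_counts(out_dir)
    by_sf: dict[str, list[str]] = {}
    for a in asn:
        if a["precursor_id"] in cds_of:
            by_sf.setdefault(a["superfamily"], []).append(a["precursor_id"])
    # the three most precursor-rich superfamilies with at least 4 members
    chosen = [
        sf
        for sf, members in sorted(by_sf.items(), key=lambda kv: (-len(kv[1]), kv[0]))
        if len(members) >= 4
    ][:3]
    newicks: dict[str, str] = {}
    with open(out_dir / "dnds.tsv", "w") as dn, open(out_dir / "selection.tsv", "w") as sel:
        dn.write("superfamily\tseq_a\tseq_b\tN\tS\tNd\tSd\tDn\tDs\tratio\tzone\tfisher_p\n")
        sel.write("superfamily\tpair\tzone\n")
        for sf in chosen:
            members = sorted(by_sf[sf], key=lambda p: (-counts.get(p, 1), p))[: cfg.max_tree_taxa]
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    a_id, b_id = members[i], members[j]
                    ca, cb = codon_alignment(cds_of[a_id], cds_of[b_id])
                    counts_ng = ng_counts(ca, cb)
                    if counts_ng.N <= 0 or counts_ng.S <= 0:
                        continue
                    res = dnds(counts_ng)
                    zone = classify_selection(res)
                    p = fisher_positive_selection(counts_ng)
                    dn.write(
                        f"{sf}\t{a_id}\t{b_id}\t{counts_ng.N:.4f}\t{counts_ng.S:.4f}"
                        f"\t{counts_ng.Nd:.4f}\t{counts_ng.Sd:.4f}"
                        f"\t{_fmt(res.Dn)}\t{_fmt(res.Ds)}\t{_fmt(res.ratio)}"
                        f"\t{zone}\t{p:.4g}\n"
                    )
                    sel.write(f"{sf}\t{a_id}|{b_id}\t{zone}\n")
            if len(members) >= 3:
                ref_id = members[0]
                aligned = [project_onto_reference(cds_of[m], cds_of[ref_id]) for m in members]
                tree = bootstrap_support(
                    aligned, members, replicates=cfg.bootstrap_replicates, seed=cfg.seed + 3
                )
                newicks[sf] = tree.newick()
    with open(out_dir / "trees.nwk", "w") as fh:
        for sf in sorted(newicks):
            fh.write(f"# superfamily {sf}\n{newicks[sf]}\n")
    outputs = ["dnds.tsv", "selection.tsv", "trees.nwk"]
    _write_manifest(out_dir, "evolve", params, inputs, outputs)
    log.info("evolve: %d superfamilies analysed", len(chosen))


def _fmt(x: float | None) -> str:
    return "." if x is None else f"{x:.4f}"


def _stage_report(cfg: PipelineConfig, out_dir: Path) -> None:
    params = {}
    input_names = [
        "categories.tsv",
        "assignments.tsv",
        "tiers.tsv",
        "frameworks.tsv",
        "events.tsv",
        "selection.tsv",
    ]
    inputs = [out_dir / n for n in input_names]
    _require(out_dir, "report", *input_names)
    if _stage_fresh(out_dir, "report", params, inputs):
        log.info("report: up to date, skipping")
        return
    categories = {r["transcript_id"]: r["category"] for r in _read_tsv(out_dir / "categories.tsv")}
    asn = _read_tsv(out_dir / "assignments.tsv")
    superfamily_of = {r["precursor_id"]: r["superfamily"] for r in asn}
    tiers_rows = _read_tsv(out_dir / "tiers.tsv")
    read_counts = {r["transcript_id"]: int(r["read_count"]) for r in tiers_rows}
    tiers = {r["transcript_id"]: r["tier"] for r in tiers_rows}
    frameworks = {
        r["transcript_id"]: r["pattern_class"] for r in _read_tsv(out_dir / "frameworks.tsv")
    }
    event_kinds = [r["kind"] for r in _read_tsv(out_dir / "events.tsv")]
    zones = [r["zone"] for r in _read_tsv(out_dir / "selection.tsv")]
    recovery = None
    if (out_dir / "truth.tsv").exists() and (out_dir / "variants.fasta").exists():
        truth = sim.SyntheticTruth.from_tsv(out_dir / "truth.tsv")
        recovery = {
            "superfamily_recovery": evaluate_superfamily_recovery(truth, out_dir),
            "event_kind_recovery": evaluate_event_recovery(truth, out_dir),
        }
    report = build_report(
        categories, superfamily_of, read_counts, tiers, frameworks, event_kinds, zones, recovery
    )
    write_report(report, out_dir)
    _write_manifest(out_dir, "report", params, inputs, ["report.json", "superfamilies.tsv"])
    log.info("report: written")


# ---------------------------------------------------------------------------
# ground-truth evaluation


def evaluate_superfamily_recovery(truth: sim.SyntheticTruth, out_dir: Path) -> float:
    """Fraction of toxin variants whose reads land in transcripts assigned to
    the variant's true superfamily (majority vote over reads; ties broken by
    the lexicographically smallest superfamily label)."""
    out_dir = Path(out_dir)
    templates = {t.template_id: t.superfamily_id for t in sim.default_templates()}
    transcript_of_read = {
        r["read_id"]: r["transcript_id"] for r in _read_tsv(out_dir / "membership.tsv")
    }
    sf_of_transcript = {
        r["precursor_id"]: r["superfamily"] for r in _read_tsv(out_dir / "assignments.tsv")
    }
    hits = total = 0
    for rec in truth.variants:
        true_sf = templates[rec.template_id]
        votes: dict[str, int] = {}
        for j in range(rec.read_count or 0):
            rid = f"{rec.variant_id}_r{j + 1}"
            tid = transcript_of_read.get(rid)
            sf = sf_of_transcript.get(tid) if tid else None
            if sf is not None:
                votes[sf] = votes.get(sf, 0) + 1
        total += 1
        if votes:
            called = min(votes, key=lambda s: (-votes[s], s))
            if called == true_sf:
                hits += 1
    return hits / total if total else 0.0


_RECOVERY_KINDS = {
    "point": {"point_synonymous", "point_nonsynonymous", "cysteine_loss", "cysteine_gain"},
    "premature_stop": {"premature_stop"},
    "stop_loss": {"stop_loss_elongation"},
}


def evaluate_event_recovery(truth: sim.SyntheticTruth, out_dir: Path) -> float:
    """Event-kind and position recovery over single-mutation variants.

    Each single-mutation variant's cDNA is re-annotated (longest ORF) and its
    CDS classified against the template CDS; the injected mutation counts as
    recovered when an event of the matching kind appears at the matching
    (left-normalised) position.
    """
    from .sequences import find_orfs
    from .variants import left_normalize_indel

    out_dir = Path(out_dir)
    templates = {t.template_id: t for t in sim.default_templates()}
    variants = {v.id: v for v in read_fasta(out_dir / "variants.fasta")}
    catalog = load_catalog()
    hits = total = 0
    for rec in truth.variants:
        if len(rec.mutations) != 1:
            continue
        spec = rec.mutations[0]
        tpl = templates[rec.template_id]
        ref_cds = tpl.cds()
        var = variants[rec.variant_id]
        orfs = find_orfs(var, min_aa=40)
        if not orfs:
            total += 1
            continue
        # mirror the annotation stage: the precursor ORF is the one with the
        # strongest similarity to the toxin catalog, not merely the longest
        from .annotate import local_align, segment_precursor, select_precursor_orf

        orf, best_score = None, -1.0
        for o in sorted(orfs, key=lambda o: (o.missing_start, -len(o.aa))):
            s = local_align(o.aa, tpl.precursor).score
            if s > best_score:
                orf, best_score = o, s
        if orf is None:
            orf = select_precursor_orf(orfs)
        var_cds = var.bases[orf.start - 1 : orf.end]
        if orf.frame < 0:
            from .sequences import reverse_complement

            var_cds = reverse_complement(var_cds)

        ref_ann = segment_precursor(tpl.precursor, catalog, tpl.template_id)
        call = classify_variant_events(var_cds, ref_cds, ref_ann, rec.variant_id, tpl.template_id)
        total += 1
        if _spec_recovered(spec, call.events, ref_cds):
            hits += 1
    return hits / total if total else 1.0


def _spec_recovered(spec: sim.MutationSpec, events, ref_cds: str) -> bool:
    from .variants import left_normalize_indel

    if spec.kind in _RECOVERY_KINDS:
        want_kinds = _RECOVERY_KINDS[spec.kind]
        want_pos = {spec.position}
        if spec.kind in ("premature_stop", "stop_loss"):
            # any base of the replaced codon identifies the event
            want_pos = {spec.position}
    elif spec.kind == "insertion":
        if len(spec.payload) % 3 == 0:
            want_kinds = {"inframe_insertion"}
        else:
            want_kinds = {"frameshift"}
        p, _ = left_normalize_indel(ref_cds, spec.position, spec.payload, True)
        want_pos = {p}
    elif spec.kind == "deletion":
        deleted = ref_cds[spec.position - 1 : spec.position - 1 + spec.length]
        if spec.length % 3 == 0:
            want_kinds = {"inframe_deletion"}
        else:
            want_kinds = {"frameshift"}
        p, _ = left_normalize_indel(ref_cds, spec.position, deleted, False)
        want_pos = {p}
    else:
        return False
    return any(e.kind in want_kinds and e.nt_position in want_pos for e in events)


# ---------------------------------------------------------------------------


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the configured stages in order; returns the final report dict
    (when the report stage runs).  Stage failure raises, leaving partial
    outputs and manifests in place for resume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    runners = {
        "simulate": _stage_simulate,
        "assemble": _stage_assemble,
        "annotate": _stage_annotate,
        "taxonomy": _stage_taxonomy,
        "variants": _stage_variants,
        "evolve": _stage_evolve,
        "report": _stage_report,
    }
    for stage in STAGES:
        if stage in cfg.stages:
            log.info("stage %s: start", stage)
            runners[stage](cfg, out)
    report_path = out / "report.json"
    return json.loads(report_path.read_text()) if report_path.exists() else {}


def load_precursor_table(path: str | Path) -> list[dict]:
    """Load a user-supplied precursor table (TSV/CSV) with at least
    ``precursor_id`` and ``superfamily`` columns (e.g. a supplementary
    catalogue export) for comparison against pipeline output."""
    import csv

    path = Path(path)
    delim = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    with open(path) as fh:
        rows = list(csv.DictReader(fh, delimiter=delim))
    if not rows:
        raise ValueError("empty precursor table")
    need = {"precursor_id", "superfamily"}
    if not need.issubset(rows[0]):
        raise ValueError(f"precursor table must provide columns {sorted(need)}")
    return rows
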