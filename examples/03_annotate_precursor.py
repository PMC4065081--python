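"""Classify transcripts and segment a toxin precursor.

Shows the five-category classifier and the signal | propeptide | mature
segmentation with its cleavage-motif evidence, plus the cysteine framework
of the mature peptide.
"""

from venomtx.annotate import annotate_transcripts, extract_framework, segment_precursor
from venomtx.catalog import load_catalog
from venomtx.sequences import NucSequence
from venomtx.simulate import cellular_reference, default_templates, unannotated_reference

catalog = load_catalog()
templates = default_templates(catalog)
toxin_db = [(t.template_id, t.precursor) for t in templates]

tpl = templates[0]
transcripts = [NucSequence("toxin_cdna", tpl.cdna())]
anns = annotate_transcripts(
    transcripts, catalog, toxin_db, cellular_reference(), unannotated_reference()
)
a = anns[0]
print(f"category: {a.category} (best hit {a.best_hit.subject_id}, "
      f"bits {a.best_hit.bits:.1f}, e-value-like {a.best_hit.evalue_like:.2e})")
p = a.precursor
print(f"signal     : {p.signal}")
print(f"propeptide : {p.propeptide}")
print(f"mature     : {p.mature}")
print(f"evidence   : {p.signal_evidence}; motifs {p.cleavage_motifs}")

fw = extract_framework(p.mature)
print(f"framework  : {fw.scaffold} -> class {fw.pattern_class} "
      f"({fw.n_cys} cysteines, {fw.parity})")
print("the scaffold writes isolated cysteines as -C- and adjacent pairs as CC;")
print("classes I-XI are the published catalogue, everything else is NOVEL.")
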