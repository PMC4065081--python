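"""Nei-Gojobori dN/dS, selection zones and a bootstrapped NJ tree.

Counts synonymous and nonsynonymous sites/differences codon by codon
(pathway averaging), corrects proportions with the Jukes-Cantor formula and
classifies each pair into a selection zone; then builds a neighbor-joining
tree with bootstrap supports from a small family alignment.
"""

from venomtx.evolution import (
    bootstrap_support,
    classify_selection,
    dnds,
    fisher_positive_selection,
    ng_counts,
)
from venomtx.simulate import apply_mutations, default_templates, generate_variants
from venomtx.variants import codon_alignment, project_onto_reference

# the worked single-codon pair: one nonsynonymous difference
c = ng_counts("TTT", "CTT")
r = dnds(c)
print(f"TTT vs CTT: N={c.N:.4f} S={c.S:.4f} Nd={c.Nd} Sd={c.Sd}")
print(f"  Dn={r.Dn:.4f} Ds={r.Ds:.4f} ratio={'undefined' if r.ratio is None else r.ratio}")

# a template against one of its mutated isoforms
templates = default_templates()
tpl = templates[0]
variants, truth = generate_variants([tpl], 8, seed=5)
rec = next(
    rr for rr in truth.variants if any(m.kind == "point" for m in rr.mutations)
)
var_cds = apply_mutations(tpl.cds(), rec.mutations)
ca, cb = codon_alignment(var_cds, tpl.cds())
counts = ng_counts(ca, cb)
res = dnds(counts)
zone = classify_selection(res)
p = fisher_positive_selection(counts)
ratio = "undefined" if res.ratio is None else f"{res.ratio:.3f}"
print(f"\n{rec.variant_id} vs {tpl.template_id}: Nd={counts.Nd:.2f} Sd={counts.Sd:.2f} "
      f"ratio={ratio} zone={zone} fisher_p={p:.3f}")
print("zones: ratio>1 positive selection, 0.27-1 lack of constraints,")
print("<=0.27 purifying; the Fisher test asks if nonsynonymous changes are enriched.")

# NJ tree over a handful of isoforms, projected onto the template frame
members = [v.id for v in variants[:6]]
cds_map = {v.id: apply_mutations(tpl.cds(), truth.record(v.id).mutations) for v in variants[:6]}
aligned = [project_onto_reference(cds_map[m], tpl.cds()) for m in members]
tree = bootstrap_support(aligned, members, replicates=100, seed=6)
print("\nNJ tree (bootstrap % on internal edges):")
print(tree.newick())
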