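"""Assemble reads into contigs by exact suffix-prefix overlap.

High-stringency EST assembly: merges require 100% identity over at least
50 nt, so only error-free overlaps (and containments) join.
"""

from venomtx.assembly import AssemblyParams, assemble
from venomtx.simulate import ReadModel, default_templates, generate_reads, generate_variants

templates = default_templates()[:4]
variants, truth = generate_variants(templates, 5, seed=3)
reads = generate_reads(variants, truth, ReadModel(seed=4))

contigs, singletons = assemble(reads, AssemblyParams(min_overlap=50))
print(f"{len(reads)} reads -> {len(contigs)} contigs + {len(singletons)} singletons")
for c in contigs[:3]:
    print(f"  {c.contig_id}: {len(c.bases)} nt from {c.read_count} reads")
print("contigs carry read support; singletons pass through as transcripts,")
print("since a single long read can already span a full toxin precursor.")
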