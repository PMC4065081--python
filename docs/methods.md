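# Methods

`venomtx` re-implements a venom-gland transcriptome analysis as a single
reproducible pipeline: synthetic (or user-supplied) cDNA reads are assembled
at 100% identity, classified into five annotation categories, segmented into
signal | propeptide | mature precursor regions, organised into a nested
superfamily / family / subfamily taxonomy, screened for the mutational
mechanisms behind low-abundance isoforms, and analysed for selection with the
original Nei–Gojobori method and neighbor-joining phylogenies. This note
records the models, parameter choices and numerical conventions, and what the
synthetic benchmark does and does not demonstrate.

## The precursor model

Spider toxin genes encode a precursor with a conserved N-terminal signal
peptide, an optional acidic propeptide, and a hypervariable, cysteine-rich
mature peptide. Two processing motifs anchor the segmentation:

* the signal peptidase site, which in the largest superfamily is flanked by
  the conserved `CYASE` pentapeptide (the signal ends `...CYA`, the
  propeptide begins `SE...`);
* the processing quadruplet motif (PQM) `X[ED][ED]R` (canonically `GEER` or
  `SEER`) that terminates the propeptide.

The bundled reference catalog (`venomtx/data/catalog.tsv`) transcribes the
16 published superfamily signal peptides and their cysteine-framework
labels; superfamily XXV has no signal peptide and is recognised by its
published propeptide `MTREETQSLGEHEKDEEVTGSEER`. Mature peptides are not
published as sequences, so the template set completes each catalogued
superfamily with a synthetic mature peptide realising its framework
(fixed internal seed; catalogue version v1).

Cysteine frameworks are written with `C` for an isolated cysteine, `CC` for
an adjacent pair and `-` for any spacer run; the eleven published classes
are

    I   -C-C-CC-C-C-          VI   -C-C-CC-C-C-C-C-C-C-
    II  -C-C-C-C-C-C-         VII  -C-C-CC-C-C-C-C-CC-C-C-
    III -C-C-CC-C-C-C-C-      VIII -C-C-C-C-C-
    IV  -C-C-C-CC-C-C-C-      IX   -C-C-C-C-
    V   -C-C-C-C-C-C-C-C-     X    -C-C-C-C-C-C-C-
    XI  -C-C-C-CC-C-C-

Any other scaffold is reported as `NOVEL`. The extractor is exact string
bookkeeping; class membership depends only on the scaffold.

## Synthetic data generator

The generator is first-class, tested code: it defines the study conditions
under which every downstream stage is validated.

**Templates.** One per catalogued superfamily: published signal (or, for
XXV, published propeptide), a synthetic propeptide ending in a PQM for
superfamilies that carry one (XI, XIV, XXIII and XXIV are propeptide-free),
and a synthetic mature expanding the superfamily's framework scaffold with
2–8 residue spacers. The spacer ahead of the first cysteine avoids D/E/R so
no spurious PQM can precede the mature region. Reverse translation uses a
fixed one-codon-per-amino-acid table (most-used human codons, versioned
`human-most-frequent-1`). Each cDNA is `5'UTR (24 nt) + CDS + 3'UTR
(33 nt)`; the 5' UTR contains no ATG and the 3' UTR carries an in-frame stop
four codons downstream, so stop-loss read-through produces a bounded,
observable elongation.

**Mutations.** Each variant draws one Bernoulli trial per mutation class
(defaults: point 0.55, insertion 0.08, deletion 0.08, premature stop 0.05,
stop loss 0.03), so roughly a third of isoforms are exact template copies
(canonical transcripts) and most mutated isoforms carry a single event.
Constraints keep every injected event *observable as its own class*, which
is what the recovery benchmark measures:

* point substitutions never create or destroy stop codons (those are the
  premature-stop / stop-loss classes);
* premature stops are nonsense point mutations proper: a single base change
  at a codon with a one-substitution stop neighbour;
* frameshift indels must translate at least four shifted codons before the
  new stop — an indel that terminates translation immediately is
  observationally indistinguishable from a nonsense mutation;
* truncating events (frameshifts, premature stops) sit at codon ≥ 45, so
  truncated isoforms keep an open reading frame above the 40-residue
  annotation floor, as any isoform discovered by such a pipeline must;
* in-frame insertions happen at codon boundaries with sense-codon payloads;
  in-frame deletions remove whole codons;
* events on one variant are ≥ 6 nt apart.

These constraints model the isoforms the analysis can see; mutations whose
products are intrinsically ambiguous (e.g. a deletion whose junction forms
an immediate stop) exist in nature but carry no recoverable class label, and
injecting them would only blur the benchmark.

**Abundance.** Per-variant read counts mix a 66% singleton mass with a
truncated Zipf(1.5) body on [2, 3000]. A single power law cannot
simultaneously give two-thirds single-read variants and the ~25 reads/variant
mean that a ~5,000-read run over ~200 variants requires; the explicit mixture
reproduces both the long rare tail (observed: ~65% of variants) and the
heavy-tailed bulk. Read lengths are normal (mean 327 nt, sd 60) clipped to
[40, 836] and to the cDNA length; reads are error-free substrings drawn from
either strand, because the assembler's 100%-identity contract makes
sequencing error a separate (out-of-scope) concern.

**Superfamily sizes.** The default pipeline distributes 16 × 12 = 192
variants over templates proportionally to the published superfamily sizes
(199, 133, 113, 66, 40, 14, 10, 9, 9, 7, 6, 6, 5, 4, 2, 1), scaled by
largest-remainder rounding with a one-variant floor. This skew is what makes
the reads-vs-precursors regression meaningful.

**Background.** Non-toxin transcripts are drawn i.i.d. from a category mix
(default 44% cellular-like, 20% no-hit-like, 7% unknown-like, 29%
cysteine-rich decoys). Cellular-like sequences are 20-codon-block shuffles
of bundled synthetic housekeeping-style proteins — block shuffling preserves
local similarity to the bundled cellular search db while guaranteeing no
cysteine-rich region; no-hit-like sequences are random nucleotides rejected
until no reading frame of ≥ 40 codons survives; decoys are cysteine-rich
ORFs with no catalogued signal, which is exactly the putative-toxin
definition and also seeds NEW superfamily clusters downstream.

**What the generator does not model.** Pyrosequencing homopolymer errors,
quality scores, chimeric RT artefacts, alternative splicing, allelic
variation between individuals, and post-translational processing. Passing
the synthetic benchmark therefore demonstrates the *logic* of the pipeline —
segmentation, classification, clustering and event calling under the
precursor model — not robustness to sequencing noise.

## Assembly

Greedy exact-overlap assembly: repeatedly join the pair with the longest
exact suffix–prefix overlap ≥ 50 nt (containment counts as a full-length
overlap), considering both orientations; ties break toward the
lexicographically smaller merged sequence. Exact duplicates collapse first
(they are containments of maximal overlap, so the greedy order is
unchanged). Candidate pairs are discovered through a prefix 50-mer index and
verified exactly; a final all-pairs sweep guarantees the output is a fixed
point (no two output sequences still share a ≥ 50 nt exact overlap). The
published assembly used two commercial tools; here determinism is the
contract, and identity < 1.0 is rejected outright. Singletons pass through
to annotation by default, since one long read can span a full precursor.

## Annotation

**Similarity search.** Smith–Waterman local alignment (BLOSUM62, gap open
11, extend 1) with a Karlin–Altschul-style statistic: `evalue_like = K·m·n·
exp(−λ·S)` with fixed constants λ = 0.267, K = 0.041 (the standard gapped
BLOSUM62 calibration; versioned, not refitted). A hit is significant only if
`evalue_like ≤ 1e−5` **and** the bit-equivalent score exceeds 40. This is a
search statistic, not a BLAST re-implementation.

**Categories.** First matching rule wins: significant toxin-catalog hit →
`Toxin_like`; significant cellular-reference hit → `Cellular_Proteins`;
significant hit to the unannotated reference → `Unknown_function`;
otherwise an ORF of 30–130 aa whose post-signal region has ≥ 4 cysteines at
≥ 6% frequency → `Putative_toxin`; else `No_Hit`. The cysteine-richness
bounds come from the observed mature-peptide range (30–60 aa, 4–12
cysteines); the 6% fraction is this package's documented default.

**ORF choice.** Six-frame scan reporting complete (ATG→stop) and 5'/3'-
partial open reading frames (min 40 aa). The precursor ORF is chosen by
translated length plus anchoring bonuses (+40 for an ATG start, +20 for a
stop): unanchored stop-free spans — e.g. an off-frame walk across a whole
cDNA — can be long without being coding. During annotation, score ties
resolve toward the ORF with the strongest toxin-catalog hit.

**Segmentation.** Signal evidence, in order: full-length match to a
catalogued signal with ≤ 2 mismatches; catalogued propeptide key (XXV);
heuristic (longest 15–30 aa N-terminal window with ≥ 50% hydrophobic
residues and a small residue A/G/S/C within its last five positions);
otherwise `missing` (5'-partial ORFs land here, matching the published
observation of precursors with missing signal peptides). The propeptide ends
at the rightmost PQM after the signal and before the first cysteine; no PQM
means no propeptide. Segmentation always covers the precursor exactly:
`|signal| + |propeptide| + |mature| = |precursor|`.

## Taxonomy

Superfamily: global-alignment identity (matches / alignment length, same
matrix and gaps as the search) of the signal against the 15 catalogued
signals; best identity ≥ 0.70 assigns, XXV assigns via its propeptide, and
unassigned signals cluster into `NEW-k` superfamilies by single linkage at
the same threshold (numbered in input order). Precursors without signal
evidence are assigned to the superfamily of their nearest mature peptide and
flagged. Families are single-linkage clusters of full-precursor identity at
0.60 within a superfamily; subfamilies of mature identity at 0.90 within a
family. The three thresholds are configuration values: the source analysis
never states its cut-offs, so the defaults are chosen to reproduce the
nested structure qualitatively and labels (`F1`, `F1.s2`, …) are ordered by
cluster size then representative id, without imitating the published letter
naming.

## Variant mechanism calls

Within each family the reference is the member with the highest read
support (ties: longer CDS, then lexicographic id). Variant and reference
CDSs are aligned globally with free end gaps (match +5, mismatch −4, gap
open −12, extend −0.5, end gaps 0), so 5'/3' truncation or extension hangs
off the alignment ends instead of forcing internal gaps. Differences map to
events in reference coordinates:

* substitutions are synonymous or nonsynonymous per codon; nonsynonymous
  changes that remove or add a cysteine in the mature region are reported as
  `cysteine_loss` / `cysteine_gain`;
* indels are in-frame when their length is divisible by three, else a
  `frameshift`; indel positions are left-normalised (leftmost equivalent
  placement), and everything downstream of a frameshift collapses into that
  single event;
* a variant stop codon upstream of the reference stop is a
  `premature_stop` (detected both codon-wise and structurally from the
  alignment end); reading through the reference stop is
  `stop_loss_elongation`;
* pairs under 30% identity are flagged unalignable and produce no events.

Expression tiers are read-support classes: high > 10 reads, low 2–10, rare
exactly 1. On synthetic data the recovery benchmark asks, for every variant
carrying exactly one injected mutation, whether an event of the matching
class appears at the matching (left-normalised) position.

## Selection analysis

**Nei–Gojobori (1986), original flavour.** Synonymous sites of a codon are
the per-position fractions of the three alternative bases that preserve the
amino acid, with changes to stop codons counted as nonsynonymous; sites are
averaged between the two sequences. Differences at codons that differ at
more than one position are averaged with equal weight over all minimal
substitution pathways, excluding pathways through stop codons; codon pairs
whose pathways all pass a stop — like gap- or N-containing codons and stop
codons themselves — are skipped pairwise. Proportions pN = Nd/N, pS = Sd/S
are corrected with Jukes–Cantor, `d = −(3/4)·ln(1 − (4/3)p)`, undefined at
p ≥ 3/4. The implementation is verified against brute-force pathway
enumeration on all 61 × 61 sense-codon pairs.

**Zones and test.** dN/dS > 1 positive (diversifying) selection;
0.27 < dN/dS ≤ 1 lack of constraints; ≤ 0.27 purifying. The published zone
boundaries are strict inequalities that leave the boundaries unassigned;
boundary ratios go to the lower zone here. The one-sided Fisher's exact
test for positive selection rounds the fractional NG counts to the nearest
integer (ties to even) into the 2×2 table {Nd, N−Nd; Sd, S−Sd}.

**Trees.** Saitou–Nei neighbor joining with the Q criterion; ties take the
smallest row-index pair, so trees are reproducible. Negative branch lengths
are kept internally and clamped to zero on newick output. Pairwise inputs
come from codon-aware projections of family members onto their reference
frame (a star alignment); bootstrap resamples alignment columns (default
500 replicates, seeded) and reports per-edge bipartition frequencies as
percentages. The implementation recovers topology and path distances
exactly on additive matrices and is cross-checked against an independent NJ
implementation in the test suite.

## Pipeline and problem sizes

Stages run in dependency order (simulate → assemble → annotate → taxonomy →
variants → evolve → report); each writes a manifest with parameter values
and input checksums, making reruns incremental and byte-stable under a fixed
seed. The default synthetic run uses 192 variants over 16 templates
(~4,500–10,000 reads depending on the abundance draw), 300 background
transcripts, and dN/dS plus bootstrapped trees for the three largest
superfamilies capped at 24 taxa each — sizes chosen so a complete run with
ground-truth evaluation stays in the tens of seconds on one core. The
evolve stage's selection census on synthetic same-family isoforms is
dominated by `undefined` ratios (most pairs differ by a single mutation, so
Ds = 0): detecting real selection regimes needs the deeper divergence of
biological families, which the generator deliberately does not fabricate.

## Known limitations

* The e-value-like statistic uses fixed calibration constants, adequate for
  thresholding at 1e−5 with short peptide queries but not a substitute for
  fitted Karlin–Altschul parameters.
* The signal-peptide heuristic is a hydrophobicity rule, not a trained
  predictor; catalogued signals are the primary evidence.
* Family/subfamily thresholds are qualitative defaults; on real data the
  resulting cluster counts are threshold-sensitive.
* Greedy exact-overlap assembly can produce chimeric contigs between
  isoforms sharing long identical stretches (as any 100%-identity assembler
  can); the taxonomy stage is robust to this because chimeras stay within
  their superfamily, but per-isoform attribution relies on read membership.
* The Fisher test on nearest-integer tables loses the fractional-site
  information; this mirrors common practice, not an optimality claim.
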