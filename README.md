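# venomtx

Analysis toolkit for venom-gland transcriptomes of spiders and other
venomous taxa, built around the toxin-precursor gene model: a conserved
signal peptide, an optional propeptide ending in a processing quadruplet
motif (PQM, `X[ED][ED]R`, e.g. `GEER`/`SEER`), and a hypervariable,
cysteine-rich mature peptide. The package takes cDNA reads (synthetic or
user-supplied) through:

1. **exact-overlap assembly** — greedy merging at 100% identity over ≥ 50 nt,
   singletons kept (one long pyrosequencing read can span a full precursor);
2. **five-category classification** — `Toxin_like`, `Putative_toxin`,
   `Cellular_Proteins`, `Unknown_function`, `No_Hit`, driven by
   Smith–Waterman search (BLOSUM62, significance: e-value-like ≤ 1e−5 *and*
   bit score > 40) plus a cysteine-richness rule;
3. **precursor segmentation** — signal | propeptide | mature via a
   16-superfamily signal-peptide catalog and PQM detection;
4. **cysteine-framework taxonomy** — scaffold strings such as
   `-C-C-CC-C-C-` classified into the published patterns I–XI or `NOVEL`;
5. **superfamily / family / subfamily clustering** — signal identity ≥ 0.70,
   precursor identity ≥ 0.60, mature identity ≥ 0.90 (single linkage);
6. **variant-mechanism calls** — synonymous/nonsynonymous points, cysteine
   loss/gain, in-frame indels, frameshifts, premature stops, stop-loss
   elongation; expression tiers (high > 10 reads, low 2–10, rare = 1);
7. **selection analysis** — original Nei–Gojobori dN/dS with Jukes–Cantor
   correction (`d = −¾ ln(1 − 4p/3)`), selection zones
   (dN/dS > 1 positive, 0.27–1 lack of constraints, ≤ 0.27 purifying),
   one-sided Fisher's exact tests, and neighbor-joining trees with
   bootstrap supports.

A first-class synthetic-data generator emulates the statistical structure
such studies report — precursor architecture, conserved cleavage motifs,
mutation classes, a Zipf-like abundance profile with a ~66% singleton tail,
and 454-style read lengths (mean ≈ 327 nt, range 40–836) — with a complete
ground-truth ledger, so the entire pipeline is testable end to end without
any download. See `docs/methods.md` for models, parameters and limitations.

## Worked example

```bash
python examples/03_annotate_precursor.py
```

prints (abridged):

```
category: Toxin_like (best hit HWTX-I, bits 186.4, e-value-like 5.63e-53)
signal     : MKASMFLAFAGLVLLFVVCYA
propeptide : SELEEESQLMEVGMPDTELEAVDEER
mature     : LHKPGCVWCIVLEDHFGCCYRVYLGCFIDHCVVLYHNRQ
evidence   : catalog_match; motifs ('CYASE', 'DEER')
framework  : -C-C-CC-C-C- -> class I (6 cysteines, even)
```

The transcript's best open reading frame hit the toxin catalog far beyond
both significance gates, so it is `Toxin_like`. Segmentation found the
superfamily-I signal peptide ending in the conserved `CYASE` cleavage
signal and a propeptide terminated by the PQM `DEER`; the mature peptide's
six cysteines, with one adjacent `CC` pair, form the scaffold
`-C-C-CC-C-C-` — framework class I, the inhibitor-cystine-knot pattern that
dominates spider venoms.

Running the full pipeline on a small synthetic dataset
(`python examples/06_full_pipeline.py`) ends with

```
superfamily recovery: 98.5%
event-kind recovery : 100.0%
```

meaning that after simulate → assemble → annotate → taxonomy, 98.5% of the
ground-truth isoforms were assigned to their true gene superfamily, and for
every isoform carrying exactly one injected mutation the variant classifier
recovered the mutation's class and position.

The other examples cover simulation (`01`), assembly (`02`), taxonomy
(`04`) and selection analysis (`05`); each prints a few numbers and one
line on what they mean. The same stages are scriptable from a shell:

```bash
venomtx run-all --out-dir run1 --seed 1        # full synthetic pipeline
venomtx assemble --in reads.fasta --min-overlap 50 --out-dir asm
```

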