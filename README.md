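# treemarker

A toolkit for genome-wide development of molecular markers in plant (and
especially tree) genomes, covering the full path from an assembly to a
screened marker panel:

- **SSR mining** — perfect microsatellites of the seven motif classes
  (monomer–heptamer) under per-class repeat thresholds
  (≥12, ≥6, ≥4, ≥3, ≥3, ≥2, ≥2), with motifs normalised to a canonical form
  under cyclic rotation and reverse complementation (AC, CA, TG and GT all
  report as AC).
- **ILP markers** — intron length polymorphism markers: primer pairs placed in
  the exons flanking each annotated intron, so the product length tracks the
  intron length.
- **PIP markers** — potential intron polymorphism markers for species with
  ESTs but no genome: ESTs are aligned to a model species' CDS, the model
  gene's intron positions are projected through the alignment, and primers
  flank each projected junction.
- **Primer design** — a deterministic designer picking one 18–27-nt pair per
  pair of 60-bp precursor flanks, using nearest-neighbor melting temperatures
  (SantaLucia 1998 unified parameters).
- **Electronic PCR** — genome-wide primer-pair amplification search (strict or
  mismatch-tolerant, 3'-anchored), with the screens built on it: marker
  self-validation, forward/reverse-primer deduplication, monomorphic vs
  polymorphic classification by amplification-site count, and the
  cross-species *universal marker* screen.
- **Diversity analysis** — dominant-marker band matrices (presence/absence),
  Dice / simple-matching / Jaccard distances, UPGMA trees with
  column-resampling bootstrap, Newick output.
- **Duplication detection** — collinear-block chaining of anchor pairs from
  multi-site SSR markers (or protein BLAST hits), an LIS-with-gap dynamic
  programme in the style of MCScanX's collinearity scan.
- **Synthetic fixtures** — a deterministic generator of genomes with planted
  SSRs, genes with known introns, spliced ESTs and duplicated segments; the
  planted truth backs every test in the suite.

## Worked example

Generate a small synthetic genome with known truth, then run the full
pipeline (scan → primer design → e-PCR validation → deduplication →
polymorphism screen) on it:

```bash
treemarker fixtures --preset small --seed 42 --out demo/
cat > demo/run.toml <<'TOML'
[input]
fasta = "genome.fa"
gff = "genes.gff3"
species = "demo"
[params]
seed = 1
TOML
treemarker pipeline --config demo/run.toml --out demo/run
```

The run directory holds `loci.tsv` (every mined SSR locus), `markers.tsv`
(the validated, deduplicated marker table), `polymorphism.tsv` (markers per
number of amplification sites) and `manifest.json` (input checksums, seed,
parameters, per-stage counts). On this preset the manifest counts read

```json
"counts": {
  "ssr_loci": 25,
  "ssr_candidates": 24,
  "ilp_candidates": 8,
  "validated": 32,
  "after_dedup": 27,
  "polymorphic": 5
}
```

— 25 SSR loci are mined (20 planted free-standing or inside the duplicated
segment, plus the 5 copies the duplication carries), 24 of them yield a
designable primer pair, all 24 SSR and 8 ILP candidates re-amplify their own
locus by e-PCR, the 5 markers whose cassettes were duplicated collapse with
their copies during deduplication, and the same 5 amplify two sites each and
are therefore classed polymorphic.

Individual stages are also exposed (`treemarker scan`, `ilp`, `pip`,
`design`, `epcr`, `dedup`, `polymorphism`, `universal`, `stats`, `phylo`,
`dupes`); see `treemarker --help`.

As a library:

```python
from treemarker import (read_fasta, scan_genome, design_ssr_markers,
                        validate_marker, deduplicate)

genome = read_fasta("genome.fa", species_id="demo")
loci = scan_genome(genome)
markers = [validate_marker(m, genome)
           for m in design_ssr_markers(genome, loci)]
markers = deduplicate([m for m in markers if m.status == "validated"])
```

## Documentation

`docs/methods.md` describes the models, parameter choices, numerical
conventions and the limits of what the synthetic fixtures can show.
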