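# ezgkit

Toolkit for discovering **early zygotic genes (EZGs)** from embryonic
RNA-seq time courses, and for characterizing the degenerate promoter
motifs associated with them.

The pipeline covers, end to end:

1. **Quantification** — per-transcript read hit counts over four
   embryonic time bins (0–2, 2–4, 4–8, 8–12 hr), normalized to reads per
   kilobase per million mapped reads (`ezgkit.quantify`).
2. **Temporal classification** — presence filters (presence ≡ ≥ 1 read
   hit): maternal transcripts are present at 0–2 hr; candidate EZGs are
   absent at 0–2 hr and present at 2–4 hr; later first-presence groups
   follow the same logic (`ezgkit.temporal`).
3. **Significance** — a reimplementation of the MA-plot-based
   random-sampling test for unreplicated count pairs (M vs A z-test
   under a binomial null with a plug-in proportion estimate), with
   Storey q-values (`ezgkit.mars`).
4. **Gene structure** — gene-level intronless scoring from cognate
   transcripts and chi-squared enrichment tests between groups
   (`ezgkit.structure`).
5. **Motif discovery** — overrepresented IUPAC-degenerate motifs in
   upstream sequence sets: exact-word beam enumeration followed by
   greedy degeneration, both-strand counting, exact binomial E-values
   against an order-0 background, coverage reporting, and query-motif
   evaluation against control sets (`ezgkit.motifs`).
6. **PWM homology** — position weight matrices from motif occurrences
   or consensus strings, ungapped PWM–PWM alignment by mean per-column
   Pearson correlation over both orientations, and an empirical
   permutation E-value (`ezgkit.pwm`).
7. **Synthetic data** — a seeded simulator that generates count
   matrices with class-specific temporal profiles, annotations with
   configurable intronless enrichment, and upstream sequences with a
   planted degenerate motif, all with ground-truth labels for recovery
   testing (`ezgkit.simulate`).

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion.
One assertion is expected to fail: the type-I calibration band at a 5:1
library-size ratio cannot be met by the faithful reference formulation
of the random-sampling test, whose conditional variance reduction is
anticonservative at strongly unequal library totals (see the module
docstring of `ezgkit.mars`). The `variance="unconditional"` option of
`mars_test`/`mars_table` restores calibration and is covered by its own
unit test.

## Command line

```sh
ezgkit simulate  --out-dir bundle --n-transcripts 2000 --seed 7
ezgkit normalize --counts bundle/counts.tsv --library-sizes bundle/library_sizes.tsv --out norm.tsv
ezgkit classify  --counts bundle/counts.tsv --out classes.tsv
ezgkit mars      --counts bundle/counts.tsv --pair 0-2:2-4 --out mars.tsv
ezgkit structure --annotations bundle/annotations.tsv --out-prefix structure
ezgkit discover  --fasta bundle/upstream.fasta --len 5:10 --beam 50 --out motifs.tsv
ezgkit scan      --motif VBRGGTA --fasta bundle/upstream.fasta --out hits.bed
ezgkit pwm-align --query VBRGGTA --target TAGGTAG --out align.tsv
ezgkit run-all   --config pipeline.yaml
```

`run-all` reads a YAML config (paths to counts/annotations/upstream
FASTA, thresholds, motif-search and alignment parameters, seed), runs
every stage, and writes a report bundle plus a JSON manifest with input
checksums and headline numbers.

Example `pipeline.yaml`:

```yaml
counts: bundle/counts.tsv
library_sizes: bundle/library_sizes.tsv
annotations: bundle/annotations.tsv
upstream_fasta: bundle/upstream.fasta
out_dir: out
seed: 7
```

## File formats

Counts, annotations, normalized values, motif tables and alignment
reports are TSV; upstream sequences are FASTA; motif hits are BED6
(minus-strand hits anchored at their plus-strand start, 0-based
half-open); PWMs are written in minimal MEME motif format; ground truth
and run manifests are JSON; configs are YAML. Annotation input may also
be GFF3 (per-transcript introns inferred as exon count − 1).
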