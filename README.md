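# trscape

Genome-wide tandem repeat (TR) analysis as a tested pipeline:

- **Detection** of perfect and imperfect tandem repeats (unit sizes 1–50 bp,
  minimum length 12 nt, minimum alignment score 12) by maximal-run
  enumeration plus seed-and-extend with wraparound dynamic programming.
  Default scoring is +1 match / −4 mismatch / −4 indel (configurable), so a
  perfect repeat's score equals its length.
- **Motif algebra**: canonical cyclic-rotation representatives (AAG for
  {AAG, AGA, GAA}), primitive-unit reduction, reverse complements (a motif
  and its reverse complement are distinct classes, displayed jointly as
  "AAG/CTT"), GC content over valid nucleotides.
- **Region schema** from GFF3 gene models: 5′-UTR, CDS, intron, 3′-UTR plus
  upstream/downstream intergenic windows (UI200/UI500/UI1000 at 1–200,
  201–700, 701–1700 nt before the transcript 5′ end; DI mirrors after the
  3′ end), strand-aware, anchored on gene ends when UTRs are unannotated.
- **Statistics**: TR density (bp/Mbp of valid A/C/G/T sequence), relative
  density (whole genome ≡ 100), decile positional profiles on a 0–99 scale,
  unit-size and top-motif tables, per-mRNA TR presence frequencies, and
  Pearson / one-way ANOVA / Tukey HSD comparisons.
- **Simulator**: synthetic genomes with gene annotations and planted
  perfect/imperfect repeat arrays at per-region-class target densities,
  with a full ground-truth table — every pipeline stage is testable offline.

## CLI

```sh
trscape detect   --fasta genome.fasta --out trs.tsv [--bed trs.bed] \
                 [--min-length 12 --min-score 12 --max-unit 50 \
                  --match 1 --mismatch -4 --indel -4 --config cfg.yaml]
trscape regions  --fasta genome.fasta --gff genes.gff3 --out regions.bed
trscape densities --fasta genome.fasta --gff genes.gff3 --trs trs.tsv --out dens.tsv
trscape profiles  --fasta genome.fasta --gff genes.gff3 --trs trs.tsv --out prof.tsv
trscape simulate --spec spec.yaml --seed 1 --out simdir/
trscape stats    --densities grouped.tsv --test anova|tukey|pearson --alpha 0.05 --out stats.tsv
```

All coordinates in TSV/BED outputs are 0-based half-open; GFF3 input/output
is 1-based inclusive. A YAML `--config` file mirrors the detector flags.

Example simulation spec:

```yaml
seed: 1
n_sequences: 2
sequence_length: 150000
background_gc: 36
genes:
  n_genes_per_sequence: 25
planting:
  FIVE_UTR: {density: 30000}
  UI200: {density: 25000}
  INTRON: {density: 6000, substitution_rate: 0.1}
```

## Acceptance

Acceptance is property-based (`tests/test_acceptance.py`): oracle
equivalence of perfect detection and alignment scoring, planted-repeat
recovery on a 1 Mbp synthetic genome, imperfect-score thresholding, exact
region arithmetic, normalization identities, qualitative density regimes,
and statistical conformance against reference implementations.

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs an end-to-end pipeline check and writes the (empty) numeric target
report; no headline numbers are reproducible offline because they depend
on 31 full genome assemblies.
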